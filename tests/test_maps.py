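"""Linkage-map construction, crossover statistics and the map-length model."""

import numpy as np
import pandas as pd
import pytest

from trisexscan.linkage_scan import (
    extract_informative_sites,
    mask_double_recombinants,
    phase_states,
)
from trisexscan.maps import (
    CrossoverEvent,
    build_map,
    cell_slope,
    haldane_cm,
    interval_recombination_fractions,
    kosambi_cm,
    locate_crossovers,
    maplength_model,
    quartile_density,
)
from trisexscan.simulate import MISSING, SimConfig, simulate_family

from test_linkage_scan import make_siteset


@pytest.mark.parametrize("r,cm", [
    (0.0, 0.0),
    (0.1, 25 * np.log(1.2 / 0.8)),   # 10.137
    (0.25, 25 * np.log(1.5 / 0.5)),  # 27.465
])
def test_kosambi_closed_form(r, cm):
    assert kosambi_cm(r) == pytest.approx(cm, abs=1e-9)


def test_mapping_functions_reject_r_half():
    for fn in (kosambi_cm, haldane_cm):
        with pytest.raises(ValueError):
            fn(0.5)
    assert haldane_cm(0.1) == pytest.approx(-50 * np.log(0.8))


def test_interval_recombination_fractions():
    a = np.zeros(40, dtype=np.int8)
    b = a.copy(); b[:4] = 1  # 4 recombinants of 40
    states = np.vstack([a, b])
    rs, bounds = interval_recombination_fractions(states, np.array([1000, 2000]), 5)
    assert rs[0] == pytest.approx(0.1)
    assert bounds == [(1000, 2000)]
    zero = interval_recombination_fractions(np.vstack([a, a]), np.array([1000, 2000]), 5)[0]
    assert zero[0] == 0.0
    empty = interval_recombination_fractions(a[None, :], np.array([1000]), 5)
    assert len(empty[0]) == 0


def test_phase_artifact_resolved_before_mapping():
    """A complete state flip in all offspring is a phase artifact, not 20
    recombinants: after re-phasing r = 0."""
    a = np.array([0] * 10 + [1] * 10, dtype=np.int8)
    ss = make_siteset(np.vstack([a, 1 - a]), [1000, 2000], ["female"] * 20)
    phased = phase_states(ss)
    rs, _ = interval_recombination_fractions(phased.states, np.array([1000, 2000]), 5)
    assert rs[0] == 0.0


def test_locate_crossovers_midpoints():
    col = np.array([0, 0, 1, 1], dtype=np.int8)
    ss = make_siteset(col[:, None], [8_000_000, 10_000_000, 12_000_000, 14_000_000], ["male"])
    events = locate_crossovers(ss, "male")
    assert len(events) == 1
    assert events[0].midpoint == 11_000_000
    flat = make_siteset(np.zeros((4, 1), dtype=np.int8),
                        [1, 2, 3, 4], ["male"])
    assert locate_crossovers(flat, "male") == []


def test_quartile_density_and_tip_bias():
    L = {"c": 100}
    ev = [CrossoverEvent("o", "c", 10, 12, "male") for _ in range(5)]
    counts, tip = quartile_density(ev, L)
    assert counts.tolist() == [5, 0, 0, 0] and tip == 1.0

    rng = np.random.default_rng(0)
    uniform = [CrossoverEvent("o", "c", int(x), int(x), "f")
               for x in rng.uniform(0, 100, 4000)]
    _, tip_u = quartile_density(uniform, L)
    assert tip_u == pytest.approx(0.5, abs=0.03)
    with pytest.raises(ValueError):
        quartile_density([], L)


def test_map_length_invariant_to_marker_order_reversal():
    rng = np.random.default_rng(1)
    states = rng.integers(0, 2, size=(20, 30)).astype(np.int8)
    pos = np.sort(rng.choice(10**6, 20, replace=False))
    rs, _ = interval_recombination_fractions(states, pos, 5)
    rev_rs, _ = interval_recombination_fractions(states[::-1], pos[::-1] * -1, 5)
    assert np.array(rs).sum() == pytest.approx(np.array(rev_rs).sum())


def test_recovered_crossovers_match_simulated_truth():
    """Error-free data: every located crossover interval contains a true one."""
    cfg = SimConfig(seed=0, chromosomes=(("Chr1", 100_000_000),),
                    rad_density_per_mb=5.0, het_to_hom_error_rate=0.0,
                    missing_rate=0.0, n_offspring=20,
                    sex_linked_region=("Chr1", 1, 2), sd_position=1,
                    suppress_recombination_in_w_carriers=False)
    fam = simulate_family(cfg, seed=2)
    ss = phase_states(extract_informative_sites(fam, "mother"))
    events = locate_crossovers(ss, "female")
    truth = {}
    for rec in fam.truth["crossovers"]:
        if rec["parent"] == "mother":
            truth.setdefault(rec["offspring"], []).extend(rec["positions"])
    for e in events:
        xs = truth.get(e.offspring, [])
        assert any(e.left_bp <= x <= e.right_bp for x in xs)


def test_realized_map_length_matches_config():
    """Mean recovered crossovers per gamete ~ Poisson(map length in Morgans)."""
    cfg = SimConfig(seed=0, chromosomes=(("Chr1", 100_000_000),),
                    rad_density_per_mb=8.0, het_to_hom_error_rate=0.0,
                    missing_rate=0.0, n_offspring=60,
                    sex_linked_region=("Chr1", 1, 2), sd_position=1,
                    suppress_recombination_in_w_carriers=False)
    counts = []
    for seed in range(10):
        fam = simulate_family(cfg, seed=seed)
        ss = phase_states(extract_informative_sites(fam, "mother"))
        events = locate_crossovers(ss, "female")
        counts.extend(np.bincount(
            [ss.offspring.index(e.offspring) for e in events], minlength=len(ss.offspring)
        ))
    mean = np.mean(counts)
    expected = cfg.female_cm_per_mb * 100.0 / 100.0  # Morgans per gamete
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(mean - expected) < 3 * se


def test_female_to_male_map_ratio_near_truth():
    """Estimated female/male total map length within 20% of the simulated 2.52."""
    cfg = SimConfig(seed=0, chromosomes=(("Chr1", 80_000_000), ("Chr2", 80_000_000)),
                    sex_linked_region=("Chr1", 1, 2), sd_position=1,
                    rad_density_per_mb=10.0, het_to_hom_error_rate=0.0,
                    missing_rate=0.0, n_offspring=40,
                    suppress_recombination_in_w_carriers=False)
    tot_f = tot_m = 0.0
    for seed in range(12):
        fam = simulate_family(cfg, seed=seed)
        for parent, acc in (("mother", "f"), ("father", "m")):
            ss = mask_double_recombinants(phase_states(extract_informative_sites(fam, parent)))
            cm = sum(m.total_cm for m in build_map(ss, "fam", parent))
            if acc == "f":
                tot_f += cm
            else:
                tot_m += cm
    ratio = tot_f / tot_m
    truth = cfg.female_cm_per_mb / cfg.male_cm_per_mb
    assert abs(ratio - truth) / truth < 0.20


def _synthetic_map_table(rng=None, noise=0.0, slopes=None):
    slopes = slopes or {("female", "fam1"): 30.0, ("male", "fam1"): 8.0,
                        ("female", "fam2"): 50.0, ("male", "fam2"): 15.0}
    rows = []
    for (sex, fam), slope in slopes.items():
        for i in range(10):
            bp = 0.5 + 0.15 * i  # in 100 Mb units
            ml = 10.0 + slope * bp
            if rng is not None and noise:
                ml += rng.normal(0, noise)
            rows.append({"maplength": ml, "sex": sex, "family": fam, "bpcovered": bp})
    return pd.DataFrame(rows)


def test_maplength_model_exact_recovery():
    table = _synthetic_map_table()
    res, diag = maplength_model(table)
    for (sex, fam), slope in {("female", "fam1"): 30.0, ("male", "fam1"): 8.0,
                              ("female", "fam2"): 50.0, ("male", "fam2"): 15.0}.items():
        est = cell_slope(res, sex, fam)
        assert est["slope"] == pytest.approx(slope, abs=1e-6)
        assert est["ci_high"] - est["ci_low"] == pytest.approx(0.0, abs=1e-5)


def test_maplength_model_null_slope_ci_covers_zero():
    rng = np.random.default_rng(5)
    table = _synthetic_map_table(rng, noise=5.0,
                                 slopes={("female", "fam1"): 0.0, ("male", "fam1"): 0.0,
                                         ("female", "fam2"): 0.0, ("male", "fam2"): 0.0})
    res, _ = maplength_model(table)
    est = cell_slope(res, "female", "fam1")
    assert est["ci_low"] <= 0.0 <= est["ci_high"]


def test_maplength_model_rejects_rank_deficient_design():
    table = _synthetic_map_table().groupby(["sex", "family"]).head(1)
    with pytest.raises(ValueError):
        maplength_model(table)
    with pytest.raises(ValueError):
        maplength_model(table.drop(columns=["bpcovered"]))


def test_percent_covered_reported():
    cfg = SimConfig(seed=0, chromosomes=(("Chr1", 100_000_000),),
                    rad_density_per_mb=4.0, sex_linked_region=("Chr1", 1, 2),
                    sd_position=1, het_to_hom_error_rate=0.0, missing_rate=0.0,
                    suppress_recombination_in_w_carriers=False)
    fam = simulate_family(cfg, seed=1)
    ss = phase_states(extract_informative_sites(fam, "mother"))
    (m,) = build_map(ss, "fam", "female")
    assert 80.0 < m.percent_covered(100_000_000) <= 100.0
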