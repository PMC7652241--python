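"""Informative-site extraction, phasing, error masking and the sex test."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from trisexscan.linkage_scan import (
    InformativeSiteSet,
    extract_informative_sites,
    mask_double_recombinants,
    phase_states,
    scan,
)
from trisexscan.linkage_scan import test_sex_association as sex_association_test
from trisexscan.model import CrossSpec, genotype
from trisexscan.simulate import MISSING, SimConfig, simulate_family

from conftest import FAST_CHROMS, make_family_dataset


def make_siteset(states, positions, sexes, parent="father", chrom="Chr1"):
    states = np.asarray(states, dtype=np.int8)
    sites = pd.DataFrame({"chrom": [chrom] * states.shape[0], "pos": positions})
    offspring = [f"o{i}" for i in range(states.shape[1])]
    return InformativeSiteSet(parent, sites, states, offspring, np.asarray(sexes))


def test_extract_informative_sites_recoding():
    # rows: father het/mother hom-ref; both het (excluded); father hom (excluded);
    # father het/mother hom-alt
    gt = np.array(
        [
            [0, 1, 0, 1, 2],   # mother 0/0, father 0/1: states 0,1, impossible->missing
            [1, 1, 0, 1, 2],   # both het: excluded
            [0, 0, 0, 0, 0],   # father hom: excluded
            [2, 1, 2, 1, 0],   # mother 1/1, father 0/1: states 1,0, impossible->missing
        ],
        dtype=np.int8,
    )
    ds = make_family_dataset(gt)
    ss = extract_informative_sites(ds, "father")
    assert ss.n_sites == 2
    assert list(ss.states[0]) == [0, 1, MISSING]
    assert list(ss.states[1]) == [1, 0, MISSING]


def test_extract_requires_valid_parent(default_family):
    with pytest.raises(ValueError):
        extract_informative_sites(default_family, "uncle")


def test_phasing_minimizes_recombinants():
    # two markers anti-correlated in 19/20 offspring: flipping the second
    # implies 1 recombinant, not 19
    a = np.array([0] * 10 + [1] * 10, dtype=np.int8)
    b = 1 - a
    b[0] = a[0]  # one true recombinant
    ss = make_siteset(np.vstack([a, b]), [1000, 2000], ["female"] * 10 + ["male"] * 10)
    phased = phase_states(ss)
    diff = (phased.states[0] != phased.states[1]).sum()
    assert diff == 1


def test_phasing_tie_keeps_current_phase():
    a = np.array([0, 0, 1, 1], dtype=np.int8)
    b = np.array([0, 1, 0, 1], dtype=np.int8)  # exactly half concordant
    ss = make_siteset(np.vstack([a, b]), [1000, 2000], ["female", "female", "male", "male"])
    phased = phase_states(ss)
    assert np.array_equal(phased.states[1], b)


def test_mask_double_recombinant_run():
    # states A,A,B,A,A at 1..5 Mb: the middle B is a double-recombination
    # signature within the window and is masked
    col = np.array([0, 0, 1, 0, 0], dtype=np.int8)
    states = col[:, None]
    ss = make_siteset(states, [1_000_000 * i for i in range(1, 6)], ["male"])
    masked = mask_double_recombinants(ss, window_bp=10_000_000)
    assert masked.states[2, 0] == MISSING
    assert masked.n_masked == 1
    # everything else untouched
    assert list(masked.states[[0, 1, 3, 4], 0]) == [0, 0, 0, 0]


def test_single_crossover_never_masked():
    col = np.array([0, 0, 1, 1, 1, 1], dtype=np.int8)
    ss = make_siteset(col[:, None], [1_000_000 * i for i in range(1, 7)], ["male"])
    masked = mask_double_recombinants(ss, window_bp=10_000_000)
    assert masked.n_masked == 0


def test_wide_double_recombinant_not_masked():
    # A,B,B,A with the B-run flanks spanning 15 Mb > 10 Mb window
    col = np.array([0, 1, 1, 0], dtype=np.int8)
    ss = make_siteset(col[:, None], [1_000_000, 5_000_000, 12_000_000, 16_000_000], ["male"])
    masked = mask_double_recombinants(ss, window_bp=10_000_000)
    assert masked.n_masked == 0


def test_masking_iterates_to_fixed_point():
    # after masking the singleton, the two flanking runs merge; a second pass
    # must not mask anything else
    col = np.array([0, 1, 0, 0, 1, 0], dtype=np.int8)
    ss = make_siteset(col[:, None], [i * 500_000 for i in range(1, 7)], ["male"])
    masked = mask_double_recombinants(ss, window_bp=10_000_000)
    remaining = masked.states[masked.states[:, 0] != MISSING, 0]
    assert (remaining == 0).all()


def test_fisher_p_matches_hypergeometric_enumeration():
    """5 sons all state B, 7 daughters all state A.

    Enumeration oracle: with margins fixed, the only table whose
    hypergeometric probability is <= the observed one is the observed table
    itself, so the two-sided p equals 1 / C(12,5).
    """
    states = np.array([[0] * 7 + [1] * 5], dtype=np.int8)
    sexes = ["female"] * 7 + ["male"] * 5
    ss = make_siteset(states, [1000], sexes)
    res = sex_association_test(ss, apply_fdr=False)
    expected = 1.0 / comb(12, 5, exact=True)
    assert res.table["p"].iloc[0] == pytest.approx(expected, rel=1e-9)


def test_balanced_states_give_p_one():
    states = np.array([[0, 1, 0, 1]], dtype=np.int8)
    ss = make_siteset(states, [1000], ["female", "female", "male", "male"])
    res = sex_association_test(ss, apply_fdr=False)
    assert res.table["p"].iloc[0] == 1.0


def test_family1_scale_perfect_linkage_p():
    """21 sons state B vs 22 daughters state A: p below 2e-11."""
    states = np.array([[0] * 22 + [1] * 21], dtype=np.int8)
    ss = make_siteset(states, [1000], ["female"] * 22 + ["male"] * 21)
    res = sex_association_test(ss, apply_fdr=False)
    p = res.table["p"].iloc[0]
    assert p == pytest.approx(1.0 / comb(43, 21, exact=True), rel=1e-9)
    assert p < 2e-11


def test_all_missing_site_flagged_p_one():
    states = np.full((1, 4), MISSING, dtype=np.int8)
    ss = make_siteset(states, [1000], ["female", "female", "male", "male"])
    res = sex_association_test(ss, apply_fdr=False)
    assert res.table["p"].iloc[0] == 1.0
    assert bool(res.table["all_missing"].iloc[0])


def test_q_values_at_least_p_values(default_family):
    res = scan(default_family, "father")
    t = res.table
    assert (t["q"] >= t["p"] - 1e-12).all()
    # count columns sum to the number of non-missing offspring states
    n_off = len(default_family.offspring_ids())
    counts = t[["n_state0_female", "n_state0_male", "n_state1_female", "n_state1_male"]].sum(axis=1)
    assert (counts <= n_off).all()


def test_scan_localizes_sex_linked_region_wwxwy():
    """Min-p paternal site falls in the SL region of WW x WY families."""
    cfg = SimConfig(cross=CrossSpec(genotype("WW"), genotype("WY")),
                    chromosomes=FAST_CHROMS, seed=0)
    hits = 0
    n_seeds = 25
    for seed in range(n_seeds):
        fam = simulate_family(cfg, seed=seed)
        res = scan(fam, "father")
        best = res.table.nsmallest(1, "p").iloc[0]
        hits += best["chrom"] == "Chr7" and best["pos"] <= 10_300_000
    assert hits >= 0.95 * n_seeds


def test_permutation_type_i_error_calibrated():
    """Under sex-label permutation, P(p < 0.05) stays near or below 0.05."""
    rng = np.random.default_rng(0)
    cfg = SimConfig(seed=0, chromosomes=(("Chr1", 120_000_000),), rad_density_per_mb=1.0,
                    sex_linked_region=("Chr1", 1, 2), sd_position=1,
                    suppress_recombination_in_w_carriers=False)
    fam = simulate_family(cfg, seed=3)
    ss = phase_states(extract_informative_sites(fam, "father"))
    n_perm = 200
    hits = 0
    total = 0
    for _ in range(n_perm):
        perm = ss.sexes.copy()
        rng.shuffle(perm)
        shuffled = InformativeSiteSet(ss.parent, ss.sites, ss.states, ss.offspring, perm)
        res = sex_association_test(shuffled, apply_fdr=False)
        # one site per permutation keeps draws independent-ish
        row = res.table.sample(1, random_state=rng.integers(2**31))
        hits += int(row["p"].iloc[0] < 0.05)
        total += 1
    rate = hits / total
    # Fisher's exact test is conservative; binomial 99% upper band at p=0.05
    assert rate < 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / total)
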