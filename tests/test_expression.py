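"""TPM, logFC, bias calling and regional enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from trisexscan.expression import (
    binomial_enrichment,
    call_bias,
    logfc,
    prefilter_counts,
    region_density,
    sex_bias_summary,
    tpm,
)
from trisexscan.simulate import SimConfig, simulate_expression

from conftest import FAST_CHROMS


def _counts(rows, ids=None):
    ids = ids or [f"i{k}" for k in range(len(next(iter(rows.values()))))]
    return pd.DataFrame(rows, index=ids).T


def test_prefilter_mean_boundary():
    counts = _counts({"a": [0, 2], "b": [1, 1], "c": [0, 0]})  # means 1.0, 1.0, 0
    counts.loc["a"] = [0, 2]
    out = prefilter_counts(counts)
    assert set(out.index) == {"a", "b"}
    low = _counts({"x": [0, 1]})  # mean 0.5 < 1
    assert prefilter_counts(low).empty
    assert prefilter_counts(_counts({"z": [0, 0]})).empty


def test_tpm_formula_and_invariances():
    counts = _counts({"a": [5, 10], "b": [15, 30]})
    lengths = pd.Series({"a": 1000, "b": 1000})
    x = tpm(counts, lengths)
    assert np.allclose(x["i0"], [250_000, 750_000])
    assert np.allclose(x.sum(axis=0), 1e6)
    # doubling one individual's counts leaves its TPM unchanged
    doubled = counts.copy()
    doubled["i1"] = doubled["i1"] * 2
    assert np.allclose(tpm(doubled, lengths)["i1"], x["i1"])
    # equal counts and lengths -> equal TPM
    eq = tpm(_counts({"a": [7, 7], "b": [7, 7]}), lengths)
    assert np.allclose(eq.to_numpy(), 500_000)
    with pytest.raises(ValueError):
        tpm(counts, pd.Series({"a": 0, "b": 1000}))


@pytest.mark.parametrize("m,f,expected", [
    (8.0, 2.0, np.log2(8.125 / 2.125)),  # ~1.935
    (5.0, 5.0, 0.0),
    (0.0, 0.0, 0.0),
])
def test_logfc(m, f, expected):
    assert logfc(m, f) == pytest.approx(expected, abs=1e-9)


def _bias_setup(q, lfc, female_zero=False):
    ids = ["m1", "m2", "f1", "f2"]
    row = [10, 12, 0 if female_zero else 9, 0 if female_zero else 11]
    counts = pd.DataFrame([row], index=["tx"], columns=ids)
    lengths = pd.Series({"tx": 1000})
    sexes = pd.Series({"m1": "male", "m2": "male", "f1": "female", "f2": "female"})
    de = pd.DataFrame({"logFC": [lfc], "FDR": [q]}, index=["tx"])
    return call_bias(counts, lengths, sexes, de_table=de)


@pytest.mark.parametrize("q,lfc,female_zero,expected", [
    (0.04, 2.5, True, "male_specific"),
    (0.04, 2.5, False, "male_biased"),
    (0.04, 1.5, False, "unbiased"),   # |logFC| <= 2
    (0.06, 5.0, False, "unbiased"),   # FDR fail
    (0.01, -3.0, False, "female_biased"),
])
def test_call_bias_rules(q, lfc, female_zero, expected):
    rec = _bias_setup(q, lfc, female_zero)
    assert rec["bias_class"].iloc[0] == expected


def test_transcripts_missing_from_de_table_flagged_unbiased():
    ids = ["m1", "f1"]
    counts = pd.DataFrame([[5, 5], [9, 1]], index=["a", "b"], columns=ids)
    de = pd.DataFrame({"logFC": [0.1], "FDR": [0.9]}, index=["a"])
    rec = call_bias(counts, pd.Series({"a": 1000, "b": 1000}),
                    pd.Series({"m1": "male", "f1": "female"}), de_table=de)
    assert rec.loc["b", "bias_class"] == "unbiased"
    assert bool(rec.loc["b", "missing_de"])


def _records(n_in_region, n_outside_male, n_outside_female):
    rows = []
    for i in range(n_in_region):
        rows.append(("sl%d" % i, "Chr7", 100_000 + i * 200_000, "male_biased"))
    for i in range(n_outside_male):
        rows.append(("bm%d" % i, "Chr1", 1_000_000 + i * 1000, "male_biased"))
    for i in range(n_outside_female):
        rows.append(("bf%d" % i, "Chr1", 50_000_000 + i * 1000, "female_biased"))
    df = pd.DataFrame(rows, columns=["transcript_id", "chrom", "start", "bias_class"])
    records = df.set_index("transcript_id")[["bias_class"]]
    records["logFC"] = 3.0
    records["FDR"] = 0.01
    transcripts = df.assign(end=df["start"] + 1000, length=1000)
    return records, transcripts


def test_region_density_printed_worked_numbers():
    """45 male-biased transcripts over 10.3 Mb -> 4.4/Mb (1 d.p.)."""
    records, transcripts = _records(45, 63, 44)
    d = region_density(records, transcripts, ("Chr7", 1, 10_300_000))
    assert round(d.density_per_mb, 1) == 4.4
    assert d.n_inside == 45

    # 21 transcripts over the 14 Mb span -> 1.5/Mb
    rec2, tx2 = _records(21, 0, 0)
    d2 = region_density(rec2, tx2, ("Chr7", 1, 14_000_000))
    assert round(d2.density_per_mb, 1) == 1.5

    empty = region_density(records.iloc[0:0], transcripts.iloc[0:0], ("Chr7", 1, 10_300_000))
    assert empty.density_per_mb == 0.0
    with pytest.raises(ValueError):
        region_density(records, transcripts, ("Chr7", 5, 5))


def binomial_tail_oracle(x, n, p0):
    return sum(comb(n, k, exact=True) * p0**k * (1 - p0) ** (n - k) for k in range(x, n + 1))


def test_binomial_enrichment_matches_bruteforce():
    """45 of 46 biased transcripts male at rest-of-genome rate 63/107."""
    p = binomial_enrichment(45, 46, 63, 44)
    assert p == pytest.approx(binomial_tail_oracle(45, 46, 63 / 107), rel=1e-9)
    assert p < 0.00001
    assert binomial_enrichment(1, 2, 5, 5) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        binomial_enrichment(1, 2, 0, 0)


def test_null_expression_keeps_empirical_fdr_controlled():
    """With no sex effect anywhere, few transcripts are called biased."""
    cfg = SimConfig(seed=0, chromosomes=FAST_CHROMS, sl_male_bias_fraction=0.0,
                    background_male_bias_fraction=0.0,
                    background_female_bias_fraction=0.0,
                    n_transcripts_sl=200, n_transcripts_background=1000)
    false_calls = 0
    total = 0
    for seed in range(10):
        ex = simulate_expression(cfg, seed=seed)
        counts = prefilter_counts(ex.counts)
        rec = call_bias(counts, ex.transcripts.set_index("transcript_id")["length"],
                        ex.pedigree.set_index("id")["sex"])
        false_calls += int((rec["bias_class"] != "unbiased").sum())
        total += len(rec)
    assert false_calls / total < 1.5 * 0.05


def test_simulated_sl_enrichment_recovered():
    """Default scenario: male-biased density in the SL region >> background."""
    ex = simulate_expression(SimConfig(seed=0, chromosomes=FAST_CHROMS), seed=21)
    counts = prefilter_counts(ex.counts)
    rec = call_bias(counts, ex.transcripts.set_index("transcript_id")["length"],
                    ex.pedigree.set_index("id")["sex"])
    summary = sex_bias_summary(rec, ex.transcripts, ("Chr7", 1, 10_300_000))
    genome_mb = sum(l for _, l in FAST_CHROMS) / 1e6
    background_density = summary["male_biased_inside"] and (
        rec["bias_class"].isin(["male_biased", "male_specific"]).sum()
        - summary["male_biased_inside"]
    ) / (genome_mb - 10.3)
    assert summary["male_density_per_mb"] > 10 * max(background_density, 1e-6)
    assert summary["binomial_p_male_enrichment"] < 1e-5


def test_subset_contrast_runs_through_same_path():
    """Genotype-class subsets (e.g. WW females vs WY males) reuse call_bias."""
    ex = simulate_expression(SimConfig(seed=0, chromosomes=FAST_CHROMS), seed=2)
    ped = ex.pedigree.set_index("id")
    keep = ped[ped["true_genotype"].isin(["WW", "WY"])].index
    if len(keep) < 4:
        pytest.skip("subset too small in this draw")
    counts = prefilter_counts(ex.counts[list(keep)])
    rec = call_bias(counts, ex.transcripts.set_index("transcript_id")["length"],
                    ped.loc[keep, "sex"])
    assert set(rec["bias_class"]).issubset(
        {"male_specific", "male_biased", "female_specific", "female_biased", "unbiased"}
    )
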