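"""Sex-biased expression calling and regional enrichment statistics.

Transcript counts are prefiltered (mean raw count >= 1), TPM-normalized,
and classified as male/female biased or specific using an external
differential-expression table (logFC, FDR) when available, or an internal
Welch t test on log2(TPM + prior) as a documented approximation.  A
significantly biased transcript requires FDR q < 0.05 and |logFC| > 2;
"specific" additionally requires zero raw counts in every individual of the
minor sex.  Regional statistics report transcript densities per Mb and an
exact binomial test of male:female bias proportions in a region against the
rest of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PRIOR = 0.125
DEFAULT_FDR_ALPHA = 0.05
DEFAULT_LOGFC_MIN = 2.0

BIAS_CLASSES = ("male_specific", "male_biased", "female_specific", "female_biased", "unbiased")
MALE_CLASSES = ("male_specific", "male_biased")
FEMALE_CLASSES = ("female_specific", "female_biased")


def prefilter_counts(counts: pd.DataFrame, min_mean: float = 1.0) -> pd.DataFrame:
    """Drop transcripts whose mean raw count across individuals is < min_mean."""
    return counts.loc[counts.mean(axis=1) >= min_mean]


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-corrected, scaled to 1e6 per individual."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every transcript needs a positive length")
    rate = counts.div(lengths / 1000.0, axis=0)
    total = rate.sum(axis=0)
    if (total == 0).any():
        bad = list(total.index[total == 0])
        raise ValueError(f"individuals with zero total expression: {bad}")
    return rate.div(total, axis=1) * 1e6


def logfc(mean_norm_male, mean_norm_female, prior: float = DEFAULT_PRIOR):
    """log2((male + prior) / (female + prior)); positive = male-biased."""
    m = np.asarray(mean_norm_male, dtype=float)
    f = np.asarray(mean_norm_female, dtype=float)
    if (m < 0).any() or (f < 0).any():
        raise ValueError("normalized means must be non-negative")
    out = np.log2((m + prior) / (f + prior))
    return float(out) if out.ndim == 0 else out


def welch_de_table(
    counts: pd.DataFrame,
    lengths: pd.Series,
    sexes: pd.Series,
    prior: float = DEFAULT_PRIOR,
) -> pd.DataFrame:
    """Internal DE test: Welch t on log2(TPM + prior), BH-FDR, TPM-based logFC.

    An approximation to a count-model DE analysis; the canonical path is an
    external DE table.
    """
    from statsmodels.stats.multitest import multipletests

    x = tpm(counts, lengths)
    is_male = (sexes.reindex(x.columns) == "male").to_numpy()
    logx = np.log2(x.to_numpy() + prior)
    t, p = stats.ttest_ind(logx[:, is_male], logx[:, ~is_male], axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    lfc = logfc(x.loc[:, is_male].mean(axis=1), x.loc[:, ~is_male].mean(axis=1), prior)
    return pd.DataFrame(
        {"transcript_id": x.index, "logFC": lfc, "FDR": multipletests(p, method="fdr_bh")[1]}
    ).set_index("transcript_id")


def call_bias(
    counts: pd.DataFrame,
    lengths: pd.Series,
    sexes: pd.Series,
    de_table: pd.DataFrame | None = None,
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
    logfc_min: float = DEFAULT_LOGFC_MIN,
    prior: float = DEFAULT_PRIOR,
) -> pd.DataFrame:
    """Per-transcript bias class from a DE table (external or internal).

    Returns a frame indexed by transcript with logFC, FDR, bias_class and a
    ``missing_de`` flag for transcripts absent from an external table (these
    are classified unbiased).
    """
    if de_table is None:
        de_table = welch_de_table(counts, lengths, sexes, prior)
    de = de_table.reindex(counts.index)
    missing = de["logFC"].isna() | de["FDR"].isna()
    lfc = de["logFC"].fillna(0.0).to_numpy()
    q = de["FDR"].fillna(1.0).to_numpy()

    is_male = (sexes.reindex(counts.columns) == "male").to_numpy()
    male_all_zero = (counts.loc[:, is_male] == 0).all(axis=1).to_numpy()
    female_all_zero = (counts.loc[:, ~is_male] == 0).all(axis=1).to_numpy()

    significant = (q < fdr_alpha) & (np.abs(lfc) > logfc_min)
    cls = np.full(len(counts), "unbiased", dtype=object)
    m = significant & (lfc > 0)
    f = significant & (lfc < 0)
    cls[m] = np.where(female_all_zero[m], "male_specific", "male_biased")
    cls[f] = np.where(male_all_zero[f], "female_specific", "female_biased")

    return pd.DataFrame(
        {"logFC": lfc, "FDR": q, "bias_class": cls, "missing_de": missing.to_numpy()},
        index=counts.index,
    )


@dataclass
class RegionEnrichment:
    region: tuple  # (chrom, start, end), 1-based inclusive
    classes: tuple
    n_inside: int
    n_outside: int
    density_per_mb: float
    binomial_p: float | None = None


def region_density(
    records: pd.DataFrame,
    transcripts: pd.DataFrame,
    region: tuple,
    classes=MALE_CLASSES,
) -> RegionEnrichment:
    """Density (transcripts/Mb) of the given bias classes inside a region.

    A transcript belongs to the region when its start coordinate falls
    inside; density uses full precision (round only for reporting).
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    meta = transcripts.set_index("transcript_id").reindex(records.index)
    hit = records["bias_class"].isin(classes).to_numpy()
    inside = ((meta["chrom"] == chrom) & (meta["start"] >= start) & (meta["start"] <= end)).to_numpy()
    n_in = int((hit & inside).sum())
    n_out = int((hit & ~inside).sum())
    mb = (end - start) / 1e6
    return RegionEnrichment((chrom, start, end), tuple(classes), n_in, n_out, n_in / mb)


def binomial_enrichment(x_region: int, n_region: int, male_rest: int, female_rest: int) -> float:
    """Exact upper-tail binomial P(X >= x | n, p0 = male_rest/(male+female rest))."""
    if male_rest + female_rest == 0:
        raise ValueError("rest-of-genome counts are all zero")
    if not 0 <= x_region <= n_region:
        raise ValueError("x_region must lie in [0, n_region]")
    p0 = male_rest / (male_rest + female_rest)
    return float(stats.binom.sf(x_region - 1, n_region, p0))


def sex_bias_summary(
    records: pd.DataFrame,
    transcripts: pd.DataFrame,
    region: tuple,
) -> dict:
    """Region report: densities, counts and the binomial enrichment test.

    The enrichment test asks whether the male share of significantly biased
    transcripts inside the region exceeds the male share in the rest of the
    genome.
    """
    male = region_density(records, transcripts, region, MALE_CLASSES)
    female = region_density(records, transcripts, region, FEMALE_CLASSES)
    x = male.n_inside
    n = male.n_inside + female.n_inside
    p = (
        binomial_enrichment(x, n, male.n_outside, female.n_outside)
        if n > 0 and (male.n_outside + female.n_outside) > 0
        else None
    )
    return {
        "region": male.region,
        "male_biased_inside": male.n_inside,
        "female_biased_inside": female.n_inside,
        "male_density_per_mb": male.density_per_mb,
        "female_density_per_mb": female.density_per_mb,
        "sex_biased_density_per_mb": (male.n_inside + female.n_inside) / ((region[2] - region[1]) / 1e6),
        "binomial_p_male_enrichment": p,
    }
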