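"""Between-sex FST genome scan with a moving window and autosomal null band.

Per-site differentiation between phenotypic females and males is measured
with the Weir & Cockerham (1984) two-population theta (Hudson's estimator
is available as an option); values are averaged over a moving window of 50
consecutive SNPs, and a genome-wide null band is obtained by resampling
window values measured on the autosomes — either a bootstrap confidence
interval for the autosomal mean or an envelope of the autosomal window
values themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MISSING

DEFAULT_WINDOW = 50


@dataclass
class FstTrack:
    per_site: pd.DataFrame  # chrom, pos, fst (NaN where undefined)
    windows: pd.DataFrame  # chrom, center_pos, start_pos, end_pos, mean_fst, n_snps
    band: tuple | None = None
    peak: dict | None = None
    estimator: str = "wc84"


def _group_stats(gt: np.ndarray, members: np.ndarray):
    """Sample size, alt-allele frequency and observed het per site for a group."""
    g = gt[:, members]
    called = g != MISSING
    n = called.sum(axis=1).astype(float)
    alt = np.where(called, g, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2 * n)
        h = np.where(called, g == 1, False).sum(axis=1) / n
    return n, p, h


def fst_per_site(
    gt: np.ndarray, is_group1: np.ndarray, estimator: str = "wc84", min_n: int = 2
) -> np.ndarray:
    """Per-site two-group FST; NaN where undefined.

    ``gt`` is sites x individuals alt-allele dosage (-1 missing);
    ``is_group1`` a boolean individual mask.  Sites monomorphic across both
    groups, or with fewer than ``min_n`` called genotypes in either group,
    are NaN.  Weir-Cockerham theta may be slightly negative; negative values
    are retained.
    """
    g1 = np.flatnonzero(is_group1)
    g2 = np.flatnonzero(~np.asarray(is_group1, dtype=bool))
    n1, p1, h1 = _group_stats(gt, g1)
    n2, p2, h2 = _group_stats(gt, g2)
    valid = (n1 >= min_n) & (n2 >= min_n)

    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "wc84":
            r = 2.0
            nbar = (n1 + n2) / r
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            denom = a + b + c
            fst = a / denom
            poly = denom > 0
        elif estimator == "hudson":
            # Hudson/Bhatia estimator: 1 - Hw/Hb from allele frequencies
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            fst = num / den
            poly = den > 0
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    out = np.where(valid & poly, fst, np.nan)
    return out


def moving_window(
    per_site: pd.DataFrame, window_size: int = DEFAULT_WINDOW, step: int = 1
) -> pd.DataFrame:
    """Moving average of per-site FST over runs of ``window_size`` SNPs.

    Windows never span chromosomes; sites with undefined FST are excluded
    before windowing; a chromosome with fewer than ``window_size`` usable
    SNPs yields no windows.  The window coordinate is the position of the
    median SNP (lower median for even sizes); first/last SNP positions are
    also reported.
    """
    rows = []
    for chrom, sub in per_site.groupby("chrom", sort=False):
        sub = sub.dropna(subset=["fst"]).sort_values("pos")
        vals = sub["fst"].to_numpy()
        pos = sub["pos"].to_numpy()
        if len(vals) < window_size:
            import warnings

            warnings.warn(f"{chrom}: fewer than {window_size} usable SNPs; no windows")
            continue
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        for start in range(0, len(vals) - window_size + 1, step):
            end = start + window_size
            rows.append(
                {
                    "chrom": chrom,
                    "center_pos": int(pos[start + (window_size - 1) // 2]),
                    "start_pos": int(pos[start]),
                    "end_pos": int(pos[end - 1]),
                    "mean_fst": (csum[end] - csum[start]) / window_size,
                    "n_snps": window_size,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "center_pos", "start_pos", "end_pos", "mean_fst", "n_snps"])


def autosomal_band(
    windows: pd.DataFrame,
    autosomes: list,
    mode: str = "bootstrap-mean",
    B: int = 1000,
    seed: int = 0,
) -> tuple:
    """(lo, hi) 95% null band from autosomal window values.

    "bootstrap-mean": percentile bootstrap CI for the autosomal mean window
    FST; "envelope": 2.5/97.5 percentiles of the window values themselves.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    vals = windows.loc[windows["chrom"].isin(autosomes), "mean_fst"].to_numpy()
    if vals.size == 0:
        raise ValueError("no autosomal windows available for the null band")
    if mode == "bootstrap-mean":
        rng = np.random.default_rng(seed)
        means = rng.choice(vals, size=(B, vals.size), replace=True).mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
    elif mode == "envelope":
        lo, hi = np.percentile(vals, [2.5, 97.5])
    else:
        raise ValueError(f"unknown band mode {mode!r}")
    return float(lo), float(hi)


def find_peak(windows: pd.DataFrame) -> dict:
    """Argmax window; ties broken by smallest (chrom, center_pos)."""
    if windows.empty:
        raise ValueError("no windows")
    best = windows.sort_values(["mean_fst", "chrom", "center_pos"],
                               ascending=[False, True, True]).iloc[0]
    return {"chrom": best["chrom"], "pos": int(best["center_pos"]), "value": float(best["mean_fst"])}


def between_sex_scan(
    gt: np.ndarray,
    sites: pd.DataFrame,
    sexes: np.ndarray,
    window_size: int = DEFAULT_WINDOW,
    estimator: str = "wc84",
    band_mode: str = "bootstrap-mean",
    autosomes: list | None = None,
    B: int = 1000,
    seed: int = 0,
) -> FstTrack:
    """Convenience wrapper: per-site FST, windows, null band, peak."""
    fst = fst_per_site(gt, np.asarray(sexes) == "female", estimator=estimator)
    per_site = sites[["chrom", "pos"]].copy()
    per_site["fst"] = fst
    windows = moving_window(per_site, window_size)
    band = None
    if autosomes:
        band = autosomal_band(windows, autosomes, band_mode, B=B, seed=seed)
    peak = find_peak(windows) if len(windows) else None
    return FstTrack(per_site, windows, band, peak, estimator)
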