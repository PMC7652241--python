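"""Sex-specific linkage maps, crossover localization and map-length model.

Markers are ordered by physical position; per-interval recombination
fractions come straight from counts of recombinant offspring among
informative offspring in phased, error-masked inheritance states (intervals
with too few informative offspring are merged into the next).  Fractions
convert to centimorgans with the Kosambi mapping function.  Crossovers are
localized to the interval between consecutive non-missing markers whose
state flips, and summarized as counts per physical quartile of each
chromosome (crossover activity concentrates towards the tips in males).
A linear model maplength ~ sex*family + sex:family:bpcovered relates map
length to the physical span covered by markers, with a separate slope per
(sex, family) cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .linkage_scan import InformativeSiteSet
from .simulate import MISSING


@dataclass
class SexSpecificMap:
    family: str
    parent_sex: str  # sex in which the recombination occurred
    chromosome: str
    marker_positions: np.ndarray
    interval_r: np.ndarray  # per merged interval
    interval_cm: np.ndarray
    interval_bounds: list  # (left bp, right bp) per merged interval
    total_cm: float
    n_markers: int
    bp_covered: int

    def percent_covered(self, chrom_length: int) -> float:
        return 100.0 * self.bp_covered / chrom_length


@dataclass
class CrossoverEvent:
    offspring: str
    chromosome: str
    left_bp: int
    right_bp: int
    parent_sex: str

    @property
    def midpoint(self) -> float:
        return (self.left_bp + self.right_bp) / 2.0


def kosambi_cm(r) -> float:
    """Kosambi map distance in cM: 25 * ln((1 + 2r) / (1 - 2r))."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fractions must lie in [0, 0.5)")
    out = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(out) if out.ndim == 0 else out


def haldane_cm(r) -> float:
    """Haldane map distance in cM: -50 * ln(1 - 2r)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("recombination fractions must lie in [0, 0.5)")
    out = -50.0 * np.log(1 - 2 * r)
    return float(out) if out.ndim == 0 else out


_MAPPING = {"kosambi": kosambi_cm, "haldane": haldane_cm}


def interval_recombination_fractions(
    states: np.ndarray, positions: np.ndarray, min_informative: int = 5
):
    """Merged-interval recombination fractions from inheritance states.

    ``states`` is markers x offspring (0/1/-1) for one chromosome, already
    phased and masked; markers must be in increasing physical order.  An
    adjacent-marker interval is informative for an offspring when both
    flanking states are non-missing; intervals accumulate until at least
    ``min_informative`` informative offspring are seen, then close.  r is
    capped just below 0.5.
    """
    n_sites = states.shape[0]
    if n_sites < 2:
        return np.array([]), []
    rs, bounds = [], []
    left = 0
    rec = 0
    inf = 0
    for i in range(1, n_sites):
        # adjacent-pair counting: offspring informative for (i-1, i)
        a, b = states[i - 1], states[i]
        both = (a != MISSING) & (b != MISSING)
        rec += int((a[both] != b[both]).sum())
        inf += int(both.sum())
        if inf >= min_informative or i == n_sites - 1:
            if inf > 0:
                r = min(rec / inf, 0.4999)
                rs.append(r)
                bounds.append((int(positions[left]), int(positions[i])))
            left = i
            rec = inf = 0
    return np.array(rs), bounds


def build_map(
    siteset: InformativeSiteSet,
    family: str,
    parent_sex: str,
    min_informative: int = 5,
    mapping_function: str = "kosambi",
) -> list:
    """One SexSpecificMap per chromosome from a phased, masked site set."""
    fn = _MAPPING[mapping_function]
    chroms = siteset.sites["chrom"].to_numpy()
    positions = siteset.sites["pos"].to_numpy()
    maps = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        if idx.size < 2:
            continue
        rs, bounds = interval_recombination_fractions(
            siteset.states[idx], positions[idx], min_informative
        )
        if rs.size == 0:
            continue
        cms = np.array([fn(r) for r in rs])
        maps.append(
            SexSpecificMap(
                family=family,
                parent_sex=parent_sex,
                chromosome=str(chrom),
                marker_positions=positions[idx],
                interval_r=rs,
                interval_cm=cms,
                interval_bounds=bounds,
                total_cm=float(cms.sum()),
                n_markers=int(idx.size),
                bp_covered=int(positions[idx].max() - positions[idx].min()),
            )
        )
    return maps


def locate_crossovers(siteset: InformativeSiteSet, parent_sex: str) -> list:
    """One CrossoverEvent per state flip between consecutive non-missing markers."""
    chroms = siteset.sites["chrom"].to_numpy()
    positions = siteset.sites["pos"].to_numpy()
    events = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        sub = siteset.states[idx]
        for j, oid in enumerate(siteset.offspring):
            nz = np.flatnonzero(sub[:, j] != MISSING)
            if nz.size < 2:
                continue
            s = sub[nz, j]
            flips = np.flatnonzero(np.diff(s) != 0)
            for f in flips:
                events.append(
                    CrossoverEvent(
                        offspring=str(oid),
                        chromosome=str(chrom),
                        left_bp=int(pos[nz[f]]),
                        right_bp=int(pos[nz[f + 1]]),
                        parent_sex=parent_sex,
                    )
                )
    return events


def quartile_density(events: list, chrom_lengths: dict):
    """Crossover counts per physical quartile, pooled over chromosomes.

    Returns (counts[4], tip_bias) where tip_bias = (Q1 + Q4) / total — the
    fraction of crossovers in the outer half of each chromosome.
    """
    if not events:
        raise ValueError("no crossover events")
    counts = np.zeros(4, dtype=int)
    for e in events:
        L = chrom_lengths[e.chromosome]
        q = min(int(e.midpoint / L * 4), 3)
        counts[q] += 1
    tip_bias = (counts[0] + counts[3]) / counts.sum()
    return counts, float(tip_bias)


def maplength_model(table: pd.DataFrame):
    """OLS fit of maplength ~ sex*family + sex:family:bpcovered.

    ``table`` needs columns maplength (cM), sex, family, bpcovered — one row
    per chromosome map.  The three-way interaction (with no lower-order
    bpcovered terms) gives each (sex, family) cell its own slope of map
    length on physical span.  Returns the fitted results plus a residual
    normality diagnostic (omnibus p).
    """
    import statsmodels.formula.api as smf
    from scipy import stats as sps

    required = {"maplength", "sex", "family", "bpcovered"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    model = smf.ols("maplength ~ sex * family + sex:family:bpcovered", data=table)
    try:
        res = model.fit()
    except np.linalg.LinAlgError as e:  # pragma: no cover
        raise ValueError(f"rank-deficient design: {e}")
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("rank-deficient design: every (sex, family) cell needs >= 2 maps")
    resid = res.resid
    norm_p = float(sps.normaltest(resid)[1]) if len(resid) >= 8 else float("nan")
    return res, {"residual_normality_p": norm_p}


def cell_slope(res, sex: str, family: str, alpha: float = 0.05):
    """Slope of map length on bp covered for one (sex, family) cell, with CI.

    Built as a design-matrix contrast (bpcovered + 1 minus bpcovered), so it
    is robust to the coding statsmodels/patsy chooses for the interaction.
    """
    from patsy import build_design_matrices

    di = res.model.data.design_info
    base = pd.DataFrame({"sex": [sex], "family": [family], "bpcovered": [0.0]})
    plus = base.assign(bpcovered=1.0)
    (m0,) = build_design_matrices([di], base)
    (m1,) = build_design_matrices([di], plus)
    contrast = np.asarray(m1)[0] - np.asarray(m0)[0]
    t = res.t_test(contrast)
    lo, hi = t.conf_int(alpha=alpha)[0]
    return {"slope": float(t.effect[0]), "ci_low": float(lo), "ci_high": float(hi)}
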