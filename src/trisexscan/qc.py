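"""Genotype quality-control cascade for F1 family data.

The cascade, applied in this fixed order, mirrors standard family RADseq
filtering practice:

1. per-genotype quality mask (depth < 15 or genotype quality < 20 -> missing)
2. drop sites where > 20% of offspring genotypes are missing
3. drop sites out of exact Hardy-Weinberg equilibrium in the offspring
4. drop sites where > 10% of offspring genotypes are Mendelian-impossible
   given the parents (a signature of het-called-as-hom genotyping error)
5. thin to one randomly selected SNP per RADtag
6. optionally drop offspring with > 20% missing genotypes (parents kept)

Boundary semantics: depth 15 and GQ 20 are retained ("minimum depth of 15",
"below 20"); the missingness and Mendel fractions are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import MISSING, FamilyDataset


@dataclass
class QcConfig:
    min_dp: int = 15
    min_gq: int = 20
    max_offspring_missing_frac: float = 0.20
    hwe_alpha: float = 0.01
    max_mendel_violation_frac: float = 0.10
    max_individual_missing_frac: float | None = 0.20  # None disables (Family-2 mode)
    one_snp_per_radtag_seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.max_offspring_missing_frac, self.max_mendel_violation_frac):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class QcReport:
    """Ordered ledger of what each filter removed."""

    steps: list = field(default_factory=list)

    def log(self, name: str, **counts) -> None:
        self.steps.append({"filter": name, **counts})

    def to_dict(self) -> dict:
        return {"steps": self.steps}

    def __str__(self) -> str:
        return "\n".join(
            f"{s['filter']}: " + ", ".join(f"{k}={v}" for k, v in s.items() if k != "filter")
            for s in self.steps
        )


# ---------------------------------------------------------------------------
# individual filters


def mask_low_quality(dataset: FamilyDataset, min_dp: int = 15, min_gq: int = 20):
    """Set genotypes failing the depth/quality thresholds to missing."""
    if dataset.dp is None or dataset.gq is None:
        raise ValueError("DP and GQ fields are required for quality masking")
    bad = (dataset.gt != MISSING) & ((dataset.dp < min_dp) | (dataset.gq < min_gq))
    gt = dataset.gt.copy()
    gt[bad] = MISSING
    out = FamilyDataset(dataset.pedigree, dataset.samples, dataset.sites, gt,
                        dataset.dp, dataset.gq, dataset.truth)
    return out, int(bad.sum())


def site_offspring_missing_filter(dataset: FamilyDataset, max_frac: float = 0.20):
    """Drop sites where the offspring missing fraction exceeds max_frac."""
    cols = [dataset.column(o) for o in dataset.offspring_ids()]
    miss_frac = (dataset.gt[:, cols] == MISSING).mean(axis=1)
    keep = miss_frac <= max_frac
    return dataset.subset_sites(keep), int((~keep).sum())


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, by genotype enumeration).

    Conditional on allele counts, heterozygote counts follow the classical
    Levene/Haldane distribution; the p-value sums the probabilities of all
    heterozygote counts no more probable than the observed one.  Monomorphic
    samples return 1.
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n == 0 or n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalized log-probabilities of each possible het count
    from scipy.special import gammaln

    def logprob(h):
        hom_rare = (rare - h) // 2
        hom_common = (max(n_a, n_b) - h) // 2
        return (
            h * np.log(2)
            - gammaln(hom_rare + 1)
            - gammaln(h + 1)
            - gammaln(hom_common + 1)
        )

    lp = logprob(hets.astype(float))
    lp -= lp.max()
    p = np.exp(lp)
    p /= p.sum()
    obs = p[hets == n_ab]
    if obs.size == 0:  # inconsistent input (parity) — treat as extreme
        return 0.0
    return float(min(1.0, p[p <= obs[0] + 1e-12].sum()))


def hwe_filter(dataset: FamilyDataset, alpha: float = 0.01, min_n: int = 5):
    """Drop sites violating exact HWE among offspring at level alpha."""
    cols = [dataset.column(o) for o in dataset.offspring_ids()]
    gt = dataset.gt[:, cols]
    keep = np.ones(dataset.n_sites, dtype=bool)
    for i in range(dataset.n_sites):
        g = gt[i]
        g = g[g != MISSING]
        if g.size < min_n:
            continue
        n_bb = int((g == 2).sum())
        n_ab = int((g == 1).sum())
        n_aa = int((g == 0).sum())
        if hwe_exact_pvalue(n_aa, n_ab, n_bb) < alpha:
            keep[i] = False
    return dataset.subset_sites(keep), int((~keep).sum())


_POSSIBLE = {}
for gm in (0, 1, 2):
    for gf in (0, 1, 2):
        mat = {0: {0}, 1: {0, 1}, 2: {1}}[gm]
        pat = {0: {0}, 1: {0, 1}, 2: {1}}[gf]
        _POSSIBLE[(gm, gf)] = {a + b for a in mat for b in pat}


def mendelian_filter(dataset: FamilyDataset, max_frac: float = 0.10):
    """Drop sites where too many offspring are Mendelian-impossible.

    Only evaluated where both parents are called; sites with a missing
    parent pass through unexamined.
    """
    try:
        mcol = dataset.column(dataset.parent_id("mother"))
        fcol = dataset.column(dataset.parent_id("father"))
    except ValueError:
        import warnings

        warnings.warn("pedigree lacks both parents; Mendelian filter skipped")
        return dataset, 0
    cols = [dataset.column(o) for o in dataset.offspring_ids()]
    keep = np.ones(dataset.n_sites, dtype=bool)
    for i in range(dataset.n_sites):
        gm, gf = int(dataset.gt[i, mcol]), int(dataset.gt[i, fcol])
        if gm == MISSING or gf == MISSING:
            continue
        off = dataset.gt[i, cols]
        off = off[off != MISSING]
        if off.size == 0:
            continue
        possible = _POSSIBLE[(gm, gf)]
        bad = np.array([g not in possible for g in off])
        if bad.mean() > max_frac:
            keep[i] = False
    return dataset.subset_sites(keep), int((~keep).sum())


def thin_one_snp_per_radtag(dataset: FamilyDataset, seed: int = 0):
    """Keep one randomly selected SNP per RADtag (seeded, reproducible)."""
    rng = np.random.default_rng(seed)
    tags = dataset.sites["radtag"].to_numpy()
    keep = np.zeros(dataset.n_sites, dtype=bool)
    # stable grouping in site order
    order = {}
    for i, t in enumerate(tags):
        order.setdefault(t, []).append(i)
    for t in sorted(order):
        idxs = order[t]
        keep[idxs[rng.integers(len(idxs))]] = True
    return dataset.subset_sites(keep), int((~keep).sum())


def drop_high_missing_individuals(dataset: FamilyDataset, max_frac: float = 0.20):
    """Drop offspring (never parents) with strictly > max_frac missing calls."""
    keep_ids = []
    dropped = 0
    for sid in dataset.samples:
        role = dataset.pedigree.set_index("id").loc[sid, "role"]
        if role != "offspring":
            keep_ids.append(sid)
            continue
        frac = float((dataset.gt[:, dataset.column(sid)] == MISSING).mean())
        if frac > max_frac:
            dropped += 1
        else:
            keep_ids.append(sid)
    return dataset.subset_individuals(keep_ids), dropped


def apply_qc(dataset: FamilyDataset, config: QcConfig | None = None):
    """Run the full cascade in its documented order; return (data, report)."""
    cfg = config or QcConfig()
    report = QcReport()

    dataset, n = mask_low_quality(dataset, cfg.min_dp, cfg.min_gq)
    report.log("quality_mask", genotypes_masked=n)

    dataset, n = site_offspring_missing_filter(dataset, cfg.max_offspring_missing_frac)
    report.log("offspring_missingness", sites_dropped=n)

    dataset, n = hwe_filter(dataset, cfg.hwe_alpha)
    report.log("hwe", sites_dropped=n)

    dataset, n = mendelian_filter(dataset, cfg.max_mendel_violation_frac)
    report.log("mendelian", sites_dropped=n)

    dataset, n = thin_one_snp_per_radtag(dataset, cfg.one_snp_per_radtag_seed)
    report.log("radtag_thinning", sites_dropped=n)

    if cfg.max_individual_missing_frac is not None:
        dataset, n = drop_high_missing_individuals(dataset, cfg.max_individual_missing_frac)
        report.log("individual_missingness", individuals_dropped=n)
    else:
        report.log("individual_missingness", individuals_dropped=0, skipped=True)

    return dataset, report
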