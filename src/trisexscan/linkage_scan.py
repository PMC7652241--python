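"""Parent-of-origin sex-linkage association scan with error masking.

For each family and each focal parent, sites heterozygous in that parent
and homozygous in the other are recoded to the allele the offspring
inherited from the focal parent.  Adjacent markers are phased to minimize
implied recombinants, and runs of genotypes that would imply a double
recombination event within a small physical window (default 10 Mb) are
treated as genotyping errors and set to missing — such errors otherwise
generate false-positive sex-association signals.  Each site is then tested
for association between the inherited allele and offspring sex with a
two-sided Fisher exact test (chi-square optional), with Benjamini-Hochberg
FDR across sites of the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MISSING, FamilyDataset

DEFAULT_MASK_WINDOW_BP = 10_000_000


@dataclass
class InformativeSiteSet:
    """Sites informative for one parent, with offspring inheritance states."""

    parent: str  # "mother" or "father"
    sites: pd.DataFrame  # chrom, pos (sorted)
    states: np.ndarray  # int8 sites x offspring: 0/1 inherited allele, -1 missing
    offspring: list
    sexes: np.ndarray  # str array aligned with offspring
    n_masked: int = 0

    @property
    def n_sites(self) -> int:
        return self.states.shape[0]


@dataclass
class SexLinkageResult:
    """Per-site association p-values (and optional BH-FDR q-values)."""

    parent: str
    table: pd.DataFrame  # chrom, pos, p, q?, counts, flags
    n_masked: int


def extract_informative_sites(dataset: FamilyDataset, parent: str) -> InformativeSiteSet:
    """Recode offspring genotypes to the focal parent's transmitted allele.

    Keeps sites where the focal parent is heterozygous and the other parent
    homozygous; offspring genotypes incompatible with the homozygous
    parent's contribution become missing.
    """
    if parent not in ("mother", "father"):
        raise ValueError("parent must be 'mother' or 'father'")
    other = "father" if parent == "mother" else "mother"
    fcol = dataset.column(dataset.parent_id(parent))
    ocol = dataset.column(dataset.parent_id(other))
    offspring = dataset.offspring_ids()
    ocols = [dataset.column(o) for o in offspring]

    focal_gt = dataset.gt[:, fcol]
    other_gt = dataset.gt[:, ocol]
    keep = (focal_gt == 1) & ((other_gt == 0) | (other_gt == 2))

    sub_gt = dataset.gt[np.ix_(keep, ocols)]
    other_sub = other_gt[keep]
    states = np.full(sub_gt.shape, MISSING, dtype=np.int8)
    # other parent homozygous ref: offspring dosage equals focal allele
    hom_ref = other_sub == 0
    states[hom_ref] = np.where(
        np.isin(sub_gt[hom_ref], (0, 1)), sub_gt[hom_ref], MISSING
    )
    # other parent homozygous alt: focal allele = dosage - 1
    hom_alt = ~hom_ref
    s = sub_gt[hom_alt]
    states[hom_alt] = np.where(np.isin(s, (1, 2)), s - 1, MISSING)
    states[sub_gt == MISSING] = MISSING

    sites = dataset.sites.loc[keep, ["chrom", "pos"]].reset_index(drop=True)
    order = sites.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    sites = sites.loc[order].reset_index(drop=True)
    states = states[order]

    ped = dataset.pedigree.set_index("id")
    sexes = np.array([ped.loc[o, "sex"] for o in offspring])
    if len(sites) == 0:
        import warnings

        warnings.warn(f"no {parent}-informative sites found")
    return InformativeSiteSet(parent, sites, states, offspring, sexes)


def phase_states(siteset: InformativeSiteSet) -> InformativeSiteSet:
    """Choose adjacent-marker relative phase to minimize implied recombinants.

    The first marker of each chromosome keeps its arbitrary phase; each
    subsequent marker is flipped when that reduces the number of offspring
    whose state differs from the previous (already phased) marker; ties keep
    the current phase.
    """
    states = siteset.states.copy()
    chroms = siteset.sites["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        prev = None
        for i in idx:
            if prev is None:
                prev = i
                continue
            both = (states[prev] != MISSING) & (states[i] != MISSING)
            same = int((states[prev][both] == states[i][both]).sum())
            diff = int(both.sum()) - same
            if diff > same:
                cur = states[i]
                states[i] = np.where(cur == MISSING, MISSING, 1 - cur)
            prev = i
    return InformativeSiteSet(
        siteset.parent, siteset.sites, states, siteset.offspring, siteset.sexes, siteset.n_masked
    )


def _mask_one(states: np.ndarray, positions: np.ndarray, window_bp: int) -> int:
    """Mask double-recombinant runs for one offspring on one chromosome.

    Operates in place on the 1-D ``states`` vector.  A maximal run of equal
    states, flanked on both sides by the opposite state, is masked when the
    physical distance between its flanking markers is <= window_bp.  Runs at
    chromosome ends are never masked.  Iterates to a fixed point; returns
    the number of genotypes masked.
    """
    masked = 0
    while True:
        nz = np.flatnonzero(states != MISSING)
        if nz.size < 3:
            return masked
        s = states[nz]
        # run boundaries in the compressed sequence
        change = np.flatnonzero(np.diff(s) != 0) + 1
        if change.size < 2:
            return masked
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [s.size]])
        did = False
        for k in range(1, len(starts) - 1):  # interior runs only
            left_flank = nz[starts[k] - 1]
            right_flank = nz[ends[k]]
            if positions[right_flank] - positions[left_flank] <= window_bp:
                run = nz[starts[k] : ends[k]]
                states[run] = MISSING
                masked += run.size
                did = True
                break  # recompute runs after each mask
        if not did:
            return masked


def mask_double_recombinants(
    siteset: InformativeSiteSet, window_bp: int = DEFAULT_MASK_WINDOW_BP
) -> InformativeSiteSet:
    """Mask genotype runs implying a double recombination within window_bp."""
    states = siteset.states.copy()
    chroms = siteset.sites["chrom"].to_numpy()
    positions = siteset.sites["pos"].to_numpy()
    n_masked = 0
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        pos = positions[idx]
        for j in range(states.shape[1]):
            col = states[idx, j]
            n_masked += _mask_one(col, pos, window_bp)
            states[idx, j] = col
    return InformativeSiteSet(
        siteset.parent, siteset.sites, states, siteset.offspring, siteset.sexes,
        siteset.n_masked + n_masked,
    )


def test_sex_association(
    siteset: InformativeSiteSet,
    apply_fdr: bool = True,
    method: str = "fisher",
) -> SexLinkageResult:
    """Per-site two-sided test of inherited allele x offspring sex.

    ``method`` is "fisher" (exact, default) or "chi2".  Sites with no
    informative offspring get p = 1 and an ``all_missing`` flag.  BH-FDR is
    applied across the sites of this scan when ``apply_fdr``.
    """
    sexes = siteset.sexes
    is_f = sexes == "female"
    if is_f.all() or (~is_f).all():
        raise ValueError("both offspring sexes are required for an association test")
    rows = []
    for i in range(siteset.n_sites):
        st = siteset.states[i]
        ok = st != MISSING
        a = int(((st == 0) & ok & is_f).sum())
        b = int(((st == 0) & ok & ~is_f).sum())
        c = int(((st == 1) & ok & is_f).sum())
        d = int(((st == 1) & ok & ~is_f).sum())
        if a + b + c + d == 0:
            p, flag = 1.0, True
        else:
            tab = [[a, b], [c, d]]
            if method == "fisher":
                p = float(stats.fisher_exact(tab, alternative="two-sided")[1])
            elif method == "chi2":
                p = float(stats.chi2_contingency(tab, correction=False)[1]) if min(a + b, c + d) > 0 and min(a + c, b + d) > 0 else 1.0
            else:
                raise ValueError(f"unknown method {method!r}")
            flag = False
        rows.append(
            {
                "chrom": siteset.sites["chrom"].iat[i],
                "pos": int(siteset.sites["pos"].iat[i]),
                "parent": siteset.parent,
                "n_state0_female": a, "n_state0_male": b,
                "n_state1_female": c, "n_state1_male": d,
                "p": min(p, 1.0),
                "all_missing": flag,
            }
        )
    table = pd.DataFrame(rows)
    if apply_fdr and len(table):
        from statsmodels.stats.multitest import multipletests

        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    return SexLinkageResult(siteset.parent, table, siteset.n_masked)


def scan(
    dataset: FamilyDataset,
    parent: str,
    window_bp: int = DEFAULT_MASK_WINDOW_BP,
    apply_fdr: bool = True,
    mask: bool = True,
    method: str = "fisher",
) -> SexLinkageResult:
    """Full scan: extract informative sites, phase, mask, test."""
    siteset = extract_informative_sites(dataset, parent)
    if siteset.n_sites == 0:
        return SexLinkageResult(parent, pd.DataFrame(
            columns=["chrom", "pos", "parent", "p", "all_missing"]), 0)
    siteset = phase_states(siteset)
    if mask:
        siteset = mask_double_recombinants(siteset, window_bp)
    return test_sex_association(siteset, apply_fdr=apply_fdr, method=method)
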