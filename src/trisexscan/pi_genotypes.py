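"""Sex-chromosome genotype inference from within-individual diversity.

For a diploid, pairwise nucleotide diversity within an individual is the
fraction of callable sites that are heterozygous — the per-site divergence
between the two haplotypes it carries.  In a system where W, Z and Y
gametologs have diverged, individuals whose two sex chromosomes are of
different types (WZ, WY, ZY) show elevated diversity in expressed
sex-linked (SL) transcripts relative to same-type individuals (WW, ZZ),
and the rank order of the between-type divergences identifies which
chromosome the Y derives from: d_ZY < min(d_WZ, d_WY) means the Y arose
from the Z.

The workflow: per-individual pi profiles over SL-region transcripts, a
two-level split of the per-sex pi distributions, genotype labels resolved
against the candidate parental crosses, and a bootstrap test of Y origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FEMALE, MALE, CrossSpec, cross_expectation, enumerate_crosses, genotype

DEFAULT_SL_REGION = ("Chr7", 1, 10_300_000)


@dataclass
class PiProfile:
    individual: str
    sex: str
    per_transcript: pd.DataFrame  # transcript_id, callable_sites, het_sites, pi, in_region
    pi_sl: float  # site-weighted mean over SL transcripts
    pi_background: float
    pi_sl_transcript_mean: float  # unweighted mean of per-transcript pi (alt summary)
    n_sl_transcripts: int


@dataclass
class GenotypeCall:
    individual: str
    sex: str
    genotype: str | None  # canonical string like "WZ"; None = abstained
    diversity_level: str  # "low" | "high" | "single"
    note: str = ""


def filter_site_calls(
    calls: pd.DataFrame, min_dp: int = 4, min_gq: int = 20, min_mq: int = 20
) -> pd.DataFrame:
    """Row-level filter of per-site genotype calls on DP/GQ/MQ thresholds.

    Genotypes with coverage < min_dp, genotype quality < min_gq or map
    quality < min_mq are removed (they count as neither callable nor het).
    """
    for col in ("dp", "gq", "mq"):
        if col not in calls.columns:
            raise ValueError(f"site call table lacks required column {col!r}")
    keep = (calls["dp"] >= min_dp) & (calls["gq"] >= min_gq) & (calls["mq"] >= min_mq)
    return calls.loc[keep]


def aggregate_site_calls(site_calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse one-row-per-callable-site calls to per (individual, transcript)."""
    g = site_calls.groupby(["individual", "transcript_id"], sort=True)
    out = g.agg(callable_sites=("is_het", "size"), het_sites=("is_het", "sum"))
    return out.reset_index()


def per_individual_pi(
    calls: pd.DataFrame,
    transcripts: pd.DataFrame,
    pedigree: pd.DataFrame,
    region: tuple = DEFAULT_SL_REGION,
    min_dp: int = 4,
    min_gq: int = 20,
    min_mq: int = 20,
) -> list:
    """PiProfiles for every individual.

    ``calls`` is either site-level (columns individual, transcript_id, dp,
    gq, mq, is_het; one row per callable site — filtered then aggregated) or
    pre-aggregated (columns individual, transcript_id, callable_sites,
    het_sites).  The SL summary is site-weighted: sum(het)/sum(callable)
    over region transcripts; an unweighted per-transcript mean is also
    reported.
    """
    if "callable_sites" not in calls.columns:
        calls = aggregate_site_calls(filter_site_calls(calls, min_dp, min_gq, min_mq))
    chrom, start, end = region
    meta = transcripts.set_index("transcript_id")
    in_region = (
        (meta["chrom"] == chrom) & (meta["start"] >= start) & (meta["start"] <= end)
    )
    sex_of_ind = pedigree.set_index("id")["sex"]

    profiles = []
    for ind, sub in calls.groupby("individual", sort=True):
        sub = sub.copy()
        sub["in_region"] = in_region.reindex(sub["transcript_id"]).fillna(False).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            sub["pi"] = sub["het_sites"] / sub["callable_sites"]
        sl = sub[sub["in_region"] & (sub["callable_sites"] > 0)]
        bg = sub[~sub["in_region"] & (sub["callable_sites"] > 0)]

        def _pooled(d):
            tot = d["callable_sites"].sum()
            return float(d["het_sites"].sum() / tot) if tot > 0 else float("nan")

        pi_sl = _pooled(sl)
        if not np.isfinite(pi_sl):
            import warnings

            warnings.warn(f"{ind}: zero callable sites in the SL region")
        profiles.append(
            PiProfile(
                individual=str(ind),
                sex=str(sex_of_ind.get(ind, "unknown")),
                per_transcript=sub[["transcript_id", "callable_sites", "het_sites", "pi", "in_region"]],
                pi_sl=pi_sl,
                pi_background=_pooled(bg),
                pi_sl_transcript_mean=float(sl["pi"].mean()) if len(sl) else float("nan"),
                n_sl_transcripts=int(len(sl)),
            )
        )
    return profiles


def split_two_levels(
    values: np.ndarray,
    background_spread: float,
    min_sep: float = 3.0,
    sampling_scale: float = 0.0,
):
    """Split a set of pi values into one or two groups at the largest gap.

    Two groups are accepted only when the largest gap between consecutive
    sorted values exceeds ``min_sep`` times the larger of (a) the spread
    (max - min) of background diversity across individuals and (b) the
    binomial sampling scale of the values themselves (``sampling_scale``,
    typically sqrt(pi (1 - pi) / callable sites) — without this floor, pure
    counting noise at elevated pi can mimic a split); otherwise a single
    group is returned.  Returns (k, labels) with labels in {"low", "high"}
    (all "low" for k = 1).  Deterministic.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("no values to split")
    if n == 1:
        return 1, np.array(["low"])
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    gaps = np.diff(sorted_vals)
    k_gap = int(np.argmax(gaps))
    threshold = min_sep * max(background_spread, sampling_scale, 1e-12)
    if gaps[k_gap] <= threshold:
        return 1, np.array(["low"] * n)
    labels = np.empty(n, dtype=object)
    cut = sorted_vals[k_gap]
    labels[values <= cut] = "low"
    labels[values > cut] = "high"
    return 2, labels


# expected diversity rank of each SL genotype: same-type pairs are lowest,
# the Z-Y pair is intermediate, W-involving pairs are highest
_PI_RANK = {"WW": 0, "ZZ": 0, "ZY": 1, "WZ": 2, "WY": 2}


def resolve_cross(
    n_levels_daughters: int,
    n_levels_sons: int,
    candidates: list | None = None,
) -> CrossSpec | None:
    """The unique candidate cross consistent with the per-sex level counts.

    A cross producing g distinct offspring genotypes of a sex can show at
    most g diversity levels in that sex, and a finite sample may show fewer
    (five sons are all one genotype in ~6% of WZ x WY draws), so observed
    level counts are treated as lower bounds.  Returns None when zero or
    several candidates remain.
    """
    if candidates is None:
        candidates = enumerate_crosses()
    matches = []
    for c in candidates:
        exp = cross_expectation(c)
        per_sex = {FEMALE: set(), MALE: set()}
        for g, p in exp.offspring_dist.items():
            if p > 0:
                per_sex[g.sex].add(str(g))
        if n_levels_daughters and len(per_sex[FEMALE]) < n_levels_daughters:
            continue
        if n_levels_sons and len(per_sex[MALE]) < n_levels_sons:
            continue
        if n_levels_daughters and not per_sex[FEMALE]:
            continue
        if n_levels_sons and not per_sex[MALE]:
            continue
        matches.append((c, per_sex))
    if len(matches) != 1:
        return None
    return matches[0][0]


def assign_genotypes(
    profiles: list,
    candidates: list | None = None,
    min_sep: float = 3.0,
) -> tuple:
    """Two-level split per sex, cross resolution, and genotype labels.

    Within each sex, groups ordered by mean pi are matched to that sex's
    possible genotypes under the resolved cross, ordered by expected
    diversity (same-type < ZY < WZ/WY).  If no unique cross is consistent,
    every call abstains (genotype None).  A genotype whose derived sex
    conflicts with the phenotype is never emitted.
    """
    by_sex = {FEMALE: [], MALE: []}
    for p in profiles:
        if p.sex in by_sex:
            by_sex[p.sex].append(p)
    bg = np.array([p.pi_background for p in profiles if np.isfinite(p.pi_background)])
    spread = float(bg.max() - bg.min()) if bg.size >= 2 else 0.0

    levels = {}
    labels_by_sex = {}
    for sex, plist in by_sex.items():
        if not plist:
            levels[sex] = 0
            labels_by_sex[sex] = np.array([], dtype=object)
            continue
        vals = np.array([p.pi_sl for p in plist])
        ses = []
        for p in plist:
            sl = p.per_transcript[p.per_transcript["in_region"]]
            tot = float(sl["callable_sites"].sum())
            if tot > 0 and np.isfinite(p.pi_sl):
                ses.append(np.sqrt(max(p.pi_sl, 1e-9) * (1 - p.pi_sl) / tot))
        scale = float(np.median(ses)) if ses else 0.0
        k, labels = split_two_levels(vals, spread, min_sep, sampling_scale=scale)
        levels[sex] = k
        labels_by_sex[sex] = labels

    cross = resolve_cross(levels[FEMALE], levels[MALE], candidates)
    calls = []
    for sex, plist in by_sex.items():
        labels = labels_by_sex[sex]
        if cross is None:
            for p, lab in zip(plist, labels):
                calls.append(GenotypeCall(p.individual, p.sex, None,
                                          lab if levels[sex] == 2 else "single",
                                          note="no unique consistent cross"))
            continue
        exp = cross_expectation(cross)
        sex_genos = sorted(
            {str(g) for g, pr in exp.offspring_dist.items() if pr > 0 and g.sex == sex},
            key=lambda s: _PI_RANK[s],
        )
        if len(sex_genos) != levels[sex]:
            for p, lab in zip(plist, labels):
                calls.append(GenotypeCall(p.individual, p.sex, None, "single",
                                          note="level count inconsistent with cross"))
            continue
        label_to_geno = (
            {"low": sex_genos[0], "high": sex_genos[-1]}
            if levels[sex] == 2
            else {"low": sex_genos[0]}
        )
        for p, lab in zip(plist, labels):
            gname = label_to_geno[lab]
            assert genotype(gname).sex == p.sex, "genotype/phenotype sex mismatch"
            calls.append(GenotypeCall(p.individual, p.sex, gname,
                                      lab if levels[sex] == 2 else "single"))
    return calls, cross


def infer_y_origin(
    profiles: list,
    calls: list,
    n_boot: int = 1000,
    support_threshold: float = 0.95,
    seed: int = 0,
) -> dict:
    """Which chromosome the Y derives from, with bootstrap support.

    Class mean pi over SL transcripts is computed for the WZ, WY and ZY
    classes; ``from_Z`` requires pi_ZY < min(pi_WZ, pi_WY) with bootstrap
    (resampling transcripts within class) support >= the threshold;
    ``from_W`` is the symmetric rule on pi_WY.  Missing classes give
    "undetermined".
    """
    geno_of = {c.individual: c.genotype for c in calls}
    per_class: dict = {}
    for p in profiles:
        g = geno_of.get(p.individual)
        if g not in ("WZ", "WY", "ZY"):
            continue
        sl = p.per_transcript[p.per_transcript["in_region"] & (p.per_transcript["callable_sites"] > 0)]
        per_class.setdefault(g, []).append(sl[["het_sites", "callable_sites"]].to_numpy(float))
    if set(per_class) != {"WZ", "WY", "ZY"}:
        return {"origin": "undetermined", "support": 0.0,
                "class_pi": {k: float(np.concatenate(v)[:, 0].sum() / np.concatenate(v)[:, 1].sum())
                             for k, v in per_class.items()}}

    stacked = {k: np.concatenate(v, axis=0) for k, v in per_class.items()}
    point = {k: float(v[:, 0].sum() / v[:, 1].sum()) for k, v in stacked.items()}

    rng = np.random.default_rng(seed)
    hits_z = hits_w = 0
    for _ in range(n_boot):
        boot = {}
        for k, v in stacked.items():
            idx = rng.integers(0, v.shape[0], size=v.shape[0])
            r = v[idx]
            tot = r[:, 1].sum()
            boot[k] = r[:, 0].sum() / tot if tot > 0 else np.nan
        if boot["ZY"] < min(boot["WZ"], boot["WY"]):
            hits_z += 1
        if boot["WY"] < min(boot["WZ"], boot["ZY"]):
            hits_w += 1
    sup_z, sup_w = hits_z / n_boot, hits_w / n_boot

    origin = "undetermined"
    support = 0.0
    if point["ZY"] < min(point["WZ"], point["WY"]) and sup_z >= support_threshold:
        origin, support = "from_Z", sup_z
    elif point["WY"] < min(point["WZ"], point["ZY"]) and sup_w >= support_threshold:
        origin, support = "from_W", sup_w
    else:
        support = max(sup_z, sup_w)
    return {"origin": origin, "support": support, "class_pi": point}
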