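"""Synthetic WZY families, RAD-like genotype matrices and RNAseq datasets.

The generator emulates the study design the downstream analyses assume:

* F1 families from any of the six W/Z/Y parental combinations, genotyped at
  RAD markers (restriction-site associated tags carrying 0-2 SNPs each)
  with negative-binomially overdispersed depth, parents sequenced at ~4x
  the offspring depth, het-miscalled-as-hom genotyping error, and random
  missingness.
* Sex-specific recombination: oogenesis produces far longer genetic maps
  than spermatogenesis, male crossovers are biased towards chromosome tips,
  and recombination is suppressed across the sex-linked (SL) region in
  parents that carry a W chromosome there (Z and Y are allowed to
  recombine).
* Gametolog divergence: marker alleles inside the SL region are assigned to
  the W, Z or Y branch of a three-taxon tree whose branch lengths are
  derived from the pairwise divergences d_WZ, d_WY, d_ZY, so that
  d_ZY < d_WZ = d_WY (a Y derived from the Z) holds by construction.
* Tadpole gonad/mesonephros RNAseq: a transcripts x individuals raw count
  matrix with a configurable fraction of SL-region transcripts male-biased
  or male-specific, plus per-transcript heterozygosity whose expectation is
  the divergence between the two SL haplotypes the individual carries.

Everything is driven by a single integer seed and is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ChromType,
    CrossSpec,
    FEMALE,
    MALE,
    SexChromGenotype,
    genotype,
    sex_of,
)

MISSING = -1  # genotype code for a no-call


# approximate v10 chromosome lengths (bp); a 4-chromosome subset keeps
# default runs light while retaining a full-length sex chromosome
DEFAULT_CHROMOSOMES = (
    ("Chr1", 217_471_166),
    ("Chr3", 153_873_357),
    ("Chr7", 133_565_930),
    ("Chr10", 52_432_566),
)


@dataclass
class SimConfig:
    """All knobs for family, genotype and expression simulation.

    Defaults reflect the study conditions: a WZ mother x WY father cross,
    ~40 genotyped offspring, RAD markers at ~2 tags/Mb, minimum-usable
    depth well above the QC threshold for parents, female:male map length
    ratio ~2.5, and gametolog divergences with d_ZY < d_WZ = d_WY.
    """

    cross: CrossSpec = field(default_factory=lambda: CrossSpec(genotype("WZ"), genotype("WY")))
    n_offspring: int = 40
    seed: int = 0
    family: str = "fam1"

    chromosomes: tuple = DEFAULT_CHROMOSOMES
    sex_linked_region: tuple = ("Chr7", 1, 10_300_000)
    sd_position: int = 9_940_000  # sex-determining locus within the SL region

    # recombination
    female_cm_per_mb: float = 0.63
    male_cm_per_mb: float = 0.25
    male_tip_bias: float = 0.4  # Beta(a, a) shape; a < 1 pushes crossovers to tips
    suppress_recombination_in_w_carriers: bool = True

    # RAD genotyping
    rad_density_per_mb: float = 2.0
    snps_per_radtag_probs: tuple = (0.1, 0.6, 0.3)  # P(0), P(1), P(2)
    depth_mean_offspring: float = 30.0
    depth_mean_parents: float = 120.0  # parents at ~4x offspring coverage
    depth_shape: float = 6.0
    het_to_hom_error_rate: float = 0.02
    missing_rate: float = 0.03

    # gametolog divergence (per-bp heterozygosity between haplotype types)
    d_wz: float = 0.01
    d_wy: float = 0.01
    d_zy: float = 0.002
    within_type_theta: float = 0.0005
    sl_diagnostic_fraction: float = 0.8

    # expression
    n_transcripts_sl: int = 800
    n_transcripts_background: int = 4000
    transcript_callable_bp: float = 50.0
    sl_male_bias_fraction: float = 0.12
    male_specific_fraction: float = 0.6
    background_male_bias_fraction: float = 0.008
    background_female_bias_fraction: float = 0.008
    logfc_min_effect: float = 2.0
    logfc_exp_scale: float = 1.5
    expr_log_mean: float = 4.0
    expr_log_sd: float = 1.0
    nb_dispersion: float = 0.2
    n_daughters_expr: int = 9
    n_sons_expr: int = 5

    def __post_init__(self) -> None:
        for name in ("het_to_hom_error_rate", "missing_rate", "sl_diagnostic_fraction",
                     "sl_male_bias_fraction", "male_specific_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.d_zy > min(self.d_wz, self.d_wy):
            raise ValueError("d_zy must not exceed min(d_wz, d_wy): the Y derives from the Z")
        chrom_lengths = dict(self.chromosomes)
        c, s, e = self.sex_linked_region
        if c not in chrom_lengths or not (0 <= s < e <= chrom_lengths[c]):
            raise ValueError("sex_linked_region must lie within a simulated chromosome")
        if not (s <= self.sd_position <= e):
            raise ValueError("sd_position must lie inside the sex-linked region")
        if self.n_offspring < 1:
            raise ValueError("n_offspring must be at least 1")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class FamilyDataset:
    """Pedigree plus a sites x individuals genotype matrix with QC fields."""

    pedigree: pd.DataFrame  # id, family, role, sex
    samples: list
    sites: pd.DataFrame  # chrom, pos (1-based), radtag
    gt: np.ndarray  # int8, sites x individuals; 0/1/2 alt-allele dosage, -1 missing
    dp: np.ndarray  # int32
    gq: np.ndarray  # int16
    truth: dict | None = None

    @property
    def n_sites(self) -> int:
        return self.gt.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gt.shape[1]

    def column(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def offspring_ids(self) -> list:
        ped = self.pedigree
        return list(ped.loc[ped["role"] == "offspring", "id"])

    def parent_id(self, role: str) -> str:
        ped = self.pedigree
        ids = list(ped.loc[ped["role"] == role, "id"])
        if len(ids) != 1:
            raise ValueError(f"expected exactly one {role}, found {len(ids)}")
        return ids[0]

    def subset_sites(self, keep: np.ndarray) -> "FamilyDataset":
        return FamilyDataset(
            pedigree=self.pedigree,
            samples=self.samples,
            sites=self.sites.loc[keep].reset_index(drop=True),
            gt=self.gt[keep],
            dp=self.dp[keep],
            gq=self.gq[keep],
            truth=self.truth,
        )

    def subset_individuals(self, keep_ids: list) -> "FamilyDataset":
        idx = [self.samples.index(i) for i in keep_ids]
        return FamilyDataset(
            pedigree=self.pedigree[self.pedigree["id"].isin(keep_ids)].reset_index(drop=True),
            samples=list(keep_ids),
            sites=self.sites,
            gt=self.gt[:, idx],
            dp=self.dp[:, idx],
            gq=self.gq[:, idx],
            truth=self.truth,
        )


@dataclass
class ExpressionDataset:
    """Raw transcript counts, transcript metadata and per-transcript calls."""

    counts: pd.DataFrame  # transcripts x individuals, raw integer counts
    transcripts: pd.DataFrame  # transcript_id, gene_id, chrom, start, end, length, truth cols
    calls: pd.DataFrame  # individual, transcript_id, callable_sites, het_sites, dp, gq, mq
    pedigree: pd.DataFrame  # id, sex, true_genotype
    truth: dict | None = None


# ---------------------------------------------------------------------------
# meiosis


def _branch_lengths(d_wz: float, d_wy: float, d_zy: float) -> dict:
    """Additive branch lengths of the W/Z/Y star tree from pairwise distances."""
    return {
        ChromType.W: max((d_wz + d_wy - d_zy) / 2.0, 0.0),
        ChromType.Z: max((d_wz + d_zy - d_wy) / 2.0, 0.0),
        ChromType.Y: max((d_wy + d_zy - d_wz) / 2.0, 0.0),
    }


def draw_crossover_positions(
    n: int,
    chrom_length: int,
    parent_sex: str,
    rng: np.random.Generator,
    male_tip_bias: float = 0.4,
    suppressed_region: tuple | None = None,
) -> np.ndarray:
    """Crossover positions along one chromosome for one meiosis.

    Female positions are uniform; male positions follow a symmetric
    Beta(a, a) with a = ``male_tip_bias`` < 1, concentrating crossovers
    near the chromosome tips.  Positions falling inside ``suppressed_region``
    (start, end) are redrawn.
    """
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    out = np.empty(n, dtype=float)
    filled = 0
    while filled < n:
        k = n - filled
        if parent_sex == FEMALE:
            pos = rng.uniform(0, chrom_length, size=k)
        else:
            pos = rng.beta(male_tip_bias, male_tip_bias, size=k) * chrom_length
        if suppressed_region is not None:
            s, e = suppressed_region
            pos = pos[(pos < s) | (pos > e)]
        out[filled : filled + pos.size] = pos
        filled += pos.size
    return np.sort(out)


def simulate_meiosis(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    chrom_length: int,
    map_cm: float,
    parent_sex: str,
    rng: np.random.Generator,
    male_tip_bias: float = 0.4,
    suppressed_region: tuple | None = None,
):
    """One gamete from a diploid parent: alleles, crossovers, start haplotype.

    ``haplotypes`` is (n_sites, 2); the crossover count is Poisson with mean
    equal to the map length in Morgans (no interference); the returned
    ``hap_index`` array gives, per site, which parental haplotype the gamete
    carries, so chromosome-type transmission can be read off at any locus.
    """
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    n_xo = rng.poisson(map_cm / 100.0)
    xos = draw_crossover_positions(
        n_xo, chrom_length, parent_sex, rng, male_tip_bias, suppressed_region
    )
    start = int(rng.integers(2))
    hap_index = (start + np.searchsorted(xos, positions)) % 2
    gamete = haplotypes[np.arange(len(positions)), hap_index]
    return gamete, xos, start, hap_index


# ---------------------------------------------------------------------------
# family simulation


def _make_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, length in cfg.chromosomes:
        n_tags = max(1, int(round(cfg.rad_density_per_mb * length / 1e6)))
        tag_starts = np.sort(rng.integers(1, length - 300, size=n_tags))
        n_snps = rng.choice([0, 1, 2], size=n_tags, p=cfg.snps_per_radtag_probs)
        for k, (start, ns) in enumerate(zip(tag_starts, n_snps)):
            offsets = np.sort(rng.choice(np.arange(1, 250), size=ns, replace=False))
            for off in offsets:
                rows.append((chrom, int(start + off), f"{chrom}_t{k}"))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "radtag"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def _founder_haplotypes(cfg: SimConfig, sites: pd.DataFrame, rng: np.random.Generator):
    """Alleles (n_sites x 4: mother h0,h1 then father h2,h3) + SL site classes.

    Inside the SL region a fraction of markers is type-diagnostic: the
    derived allele sits on exactly one branch (W, Z or Y) of the gametolog
    tree, drawn with probability proportional to branch length.  All other
    markers are ordinary biallelic polymorphisms shared across types.
    """
    n = len(sites)
    hap_types = list(cfg.cross.mother.alleles) + list(cfg.cross.father.alleles)
    alleles = rng.integers(0, 2, size=(n, 4)).astype(np.int8)

    sl_chrom, sl_start, sl_end = cfg.sex_linked_region
    in_sl = ((sites["chrom"] == sl_chrom) & (sites["pos"] >= sl_start) & (sites["pos"] <= sl_end)).to_numpy()
    branches = _branch_lengths(cfg.d_wz, cfg.d_wy, cfg.d_zy)
    total = sum(branches.values())
    site_branch = np.full(n, -9, dtype=np.int8)  # -9 = non-diagnostic
    if total > 0:
        probs = np.array([branches[ChromType.W], branches[ChromType.Z], branches[ChromType.Y]])
        probs = probs / probs.sum()
        sl_idx = np.flatnonzero(in_sl)
        diag = sl_idx[rng.random(sl_idx.size) < cfg.sl_diagnostic_fraction]
        chosen = rng.choice([ChromType.W, ChromType.Z, ChromType.Y], size=diag.size, p=probs)
        site_branch[diag] = chosen
        for h, t in enumerate(hap_types):
            alleles[diag, h] = (chosen == t).astype(np.int8)
    return alleles, np.array(hap_types, dtype=np.int8), site_branch, in_sl


def simulate_family(config: SimConfig, seed: int | None = None) -> FamilyDataset:
    """Simulate a genotyped F1 family under the configured W/Z/Y cross."""
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    sites = _make_sites(cfg, rng)
    alleles, hap_types, site_branch, in_sl = _founder_haplotypes(cfg, sites, rng)
    n_sites = len(sites)

    mother_id, father_id = f"{cfg.family}_mother", f"{cfg.family}_father"
    offspring_ids = [f"{cfg.family}_o{i:03d}" for i in range(cfg.n_offspring)]
    samples = [mother_id, father_id] + offspring_ids

    gt_true = np.empty((n_sites, len(samples)), dtype=np.int8)
    gt_true[:, 0] = alleles[:, 0] + alleles[:, 1]
    gt_true[:, 1] = alleles[:, 2] + alleles[:, 3]

    sl_chrom, sl_start, sl_end = cfg.sex_linked_region
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()

    true_genotypes: dict = {}
    true_sexes: dict = {}
    crossovers: list = []

    parents = [
        (FEMALE, cfg.cross.mother, alleles[:, 0:2], (hap_types[0], hap_types[1]), cfg.female_cm_per_mb),
        (MALE, cfg.cross.father, alleles[:, 2:4], (hap_types[2], hap_types[3]), cfg.male_cm_per_mb),
    ]

    for j, oid in enumerate(offspring_ids):
        col = 2 + j
        gamete_sum = np.zeros(n_sites, dtype=np.int8)
        sd_types = []
        for psex, pgeno, phaps, ptypes, cm_per_mb in parents:
            suppress = (
                cfg.suppress_recombination_in_w_carriers
                and ChromType.W in pgeno.alleles
            )
            for chrom, length in cfg.chromosomes:
                mask = chrom_arr == chrom
                region = None
                if suppress and chrom == sl_chrom:
                    region = (sl_start, sl_end)
                gamete, xos, start, hap_index = simulate_meiosis(
                    phaps[mask],
                    pos_arr[mask],
                    length,
                    cm_per_mb * length / 1e6,
                    psex,
                    rng,
                    cfg.male_tip_bias,
                    region,
                )
                gamete_sum[mask] += gamete
                if xos.size:
                    crossovers.append(
                        {"offspring": oid, "parent": "mother" if psex == FEMALE else "father",
                         "chrom": chrom, "positions": [float(x) for x in xos]}
                    )
                if chrom == sl_chrom:
                    # chromosome type transmitted at the sex-determining locus
                    hap_at_sd = (start + int(np.searchsorted(xos, cfg.sd_position))) % 2
                    sd_types.append(ChromType(int(ptypes[hap_at_sd])))
        gt_true[:, col] = gamete_sum
        g = SexChromGenotype(tuple(sd_types))
        true_genotypes[oid] = str(g)
        true_sexes[oid] = g.sex

    # sequencing depth: gamma-poisson (negative binomial) per genotype
    means = np.full(len(samples), cfg.depth_mean_offspring)
    means[0:2] = cfg.depth_mean_parents
    lam = rng.gamma(cfg.depth_shape, means[None, :] / cfg.depth_shape, size=gt_true.shape)
    dp = rng.poisson(lam).astype(np.int32)
    gq = np.clip(np.round(3.0 * dp + rng.normal(0, 3, size=dp.shape)), 0, 99).astype(np.int16)

    # het -> hom genotyping error, then missingness
    gt = gt_true.copy()
    err = (gt_true == 1) & (rng.random(gt.shape) < cfg.het_to_hom_error_rate)
    gt[err] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(err.sum()))
    miss = rng.random(gt.shape) < cfg.missing_rate
    gt[miss] = MISSING

    pedigree = pd.DataFrame(
        {
            "id": samples,
            "family": cfg.family,
            "role": ["mother", "father"] + ["offspring"] * cfg.n_offspring,
            "sex": [FEMALE, MALE] + [true_sexes[o] for o in offspring_ids],
        }
    )

    truth = {
        "cross": str(cfg.cross),
        "sex_linked_region": list(cfg.sex_linked_region),
        "sd_position": cfg.sd_position,
        "true_offspring_genotypes": true_genotypes,
        "crossovers": crossovers,
        "error_mask_count": int(err.sum()),
        "missing_mask_count": int(miss.sum()),
        "site_branch": site_branch,
        "in_sl": in_sl,
        "gt_true": gt_true,
        "error_mask": err,
        "missing_mask": miss,
    }
    return FamilyDataset(pedigree, samples, sites, gt, dp, gq, truth)


DEFAULT_TYPE_FREQS = {ChromType.W: 0.3, ChromType.Z: 0.5, ChromType.Y: 0.2}


def simulate_unrelated_cohort(
    config: SimConfig,
    n_females: int = 12,
    n_males: int = 26,
    type_freqs: dict | None = None,
    seed: int | None = None,
) -> FamilyDataset:
    """Unrelated wild-caught individuals for population-scale scans.

    Each individual draws two sex-chromosome types from the population
    frequencies (rejection-sampled to match its phenotypic sex).  Marker
    alleles inside the SL region follow the gametolog branch model shared
    with :func:`simulate_family`; all other markers are independent
    biallelic polymorphisms with a per-site population frequency, so there
    is no linkage disequilibrium outside the SL region — the situation a
    between-sex FST scan on unrelated samples assumes.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 7 if seed is None else seed)
    freqs = type_freqs or DEFAULT_TYPE_FREQS
    types = list(freqs)
    probs = np.array([freqs[t] for t in types], dtype=float)
    probs /= probs.sum()

    sites = _make_sites(cfg, rng)
    n = len(sites)
    sl_chrom, sl_start, sl_end = cfg.sex_linked_region
    in_sl = ((sites["chrom"] == sl_chrom) & (sites["pos"] >= sl_start) & (sites["pos"] <= sl_end)).to_numpy()
    branches = _branch_lengths(cfg.d_wz, cfg.d_wy, cfg.d_zy)
    bprobs = np.array([branches[ChromType.W], branches[ChromType.Z], branches[ChromType.Y]])
    bprobs = bprobs / bprobs.sum()
    site_branch = np.full(n, -9, dtype=np.int8)
    sl_idx = np.flatnonzero(in_sl)
    diag = sl_idx[rng.random(sl_idx.size) < cfg.sl_diagnostic_fraction]
    site_branch[diag] = rng.choice(
        [ChromType.W, ChromType.Z, ChromType.Y], size=diag.size, p=bprobs
    )
    base_freq = rng.uniform(0.05, 0.95, size=n)

    sexes = [FEMALE] * n_females + [MALE] * n_males
    ids = [f"wild_f{i:02d}" for i in range(n_females)] + [f"wild_m{i:02d}" for i in range(n_males)]
    gt_true = np.empty((n, len(ids)), dtype=np.int8)
    true_geno = {}
    for j, sex in enumerate(sexes):
        while True:
            pair = rng.choice(types, size=2, p=probs)
            g = SexChromGenotype((ChromType(int(pair[0])), ChromType(int(pair[1]))))
            if g.sex == sex and str(g) != "YY":
                break
        true_geno[ids[j]] = str(g)
        col = np.zeros(n, dtype=np.int8)
        for t in pair:
            hap = (rng.random(n) < base_freq).astype(np.int8)
            is_diag = site_branch != -9
            hap[is_diag] = (site_branch[is_diag] == int(t)).astype(np.int8)
            col += hap
        gt_true[:, j] = col

    lam = rng.gamma(cfg.depth_shape, cfg.depth_mean_offspring / cfg.depth_shape, size=gt_true.shape)
    dp = rng.poisson(lam).astype(np.int32)
    gq = np.clip(np.round(3.0 * dp + rng.normal(0, 3, size=dp.shape)), 0, 99).astype(np.int16)
    gt = gt_true.copy()
    err = (gt_true == 1) & (rng.random(gt.shape) < cfg.het_to_hom_error_rate)
    gt[err] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(err.sum()))
    gt[rng.random(gt.shape) < cfg.missing_rate] = MISSING

    pedigree = pd.DataFrame(
        {"id": ids, "family": "cohort", "role": "offspring", "sex": sexes}
    )
    truth = {"true_genotypes": true_geno, "sex_linked_region": list(cfg.sex_linked_region)}
    return FamilyDataset(pedigree, ids, sites, gt, dp, gq, truth)


# ---------------------------------------------------------------------------
# expression simulation

_PAIR_DIVERGENCE_KEYS = {
    "WW": "within_type_theta",
    "ZZ": "within_type_theta",
    "WZ": "d_wz",
    "WY": "d_wy",
    "ZY": "d_zy",
}


def expected_pi(cfg: SimConfig, sl_genotype: str) -> float:
    """Per-bp heterozygosity implied by an SL genotype's haplotype pair."""
    return getattr(cfg, _PAIR_DIVERGENCE_KEYS[str(genotype(sl_genotype))])


def _expression_pedigree(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Family-3-like tadpole pedigree with true SL genotypes given the cross."""
    from .model import cross_expectation

    exp = cross_expectation(cfg.cross)
    by_sex = {FEMALE: [], MALE: []}
    for g, p in exp.offspring_dist.items():
        by_sex[g.sex].append((str(g), float(p)))
    rows = []
    for sex, n, prefix in ((FEMALE, cfg.n_daughters_expr, "d"), (MALE, cfg.n_sons_expr, "s")):
        opts = by_sex[sex]
        if not opts and n > 0:
            raise ValueError(f"cross {exp.cross} produces no {sex} offspring")
        labels = [o[0] for o in opts]
        probs = np.array([o[1] for o in opts])
        probs = probs / probs.sum()
        draws = rng.choice(labels, size=n, p=probs)
        for i, g in enumerate(draws):
            rows.append({"id": f"{prefix}{i+1:02d}", "sex": sex, "true_genotype": g})
    return pd.DataFrame(rows)


def simulate_expression(
    config: SimConfig,
    pedigree: pd.DataFrame | None = None,
    seed: int | None = None,
) -> ExpressionDataset:
    """Transcript counts and per-transcript heterozygosity for one family.

    Counts are negative binomial around a gene-level baseline, with sex
    effects applied as mean * 2^(+-logFC/2) (logFC = log2 male/female);
    male-specific transcripts have a zero female mean.  Per-individual het
    site counts per transcript are Binomial(callable bp, pi) where pi is
    the divergence between the two SL haplotypes the individual truly
    carries (d_WZ, d_WY, d_ZY) or the within-type polymorphism theta.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    if pedigree is None:
        pedigree = _expression_pedigree(cfg, rng)
    ped = pedigree.reset_index(drop=True)
    ids = list(ped["id"])
    is_male = (ped["sex"] == MALE).to_numpy()

    sl_chrom, sl_start, sl_end = cfg.sex_linked_region
    background_chroms = [(c, l) for c, l in cfg.chromosomes]

    # --- transcript metadata -------------------------------------------------
    n_sl, n_bg = cfg.n_transcripts_sl, cfg.n_transcripts_background
    n_total = n_sl + n_bg
    lengths = np.maximum(200, rng.lognormal(7.2, 0.6, size=n_total)).astype(int)

    chroms = np.empty(n_total, dtype=object)
    starts = np.empty(n_total, dtype=np.int64)
    in_sl = np.zeros(n_total, dtype=bool)
    in_sl[:n_sl] = True
    chroms[:n_sl] = sl_chrom
    starts[:n_sl] = rng.integers(sl_start, sl_end, size=n_sl)
    # background transcripts: anywhere outside the SL region
    bg_lengths = np.array([l for _, l in background_chroms], dtype=float)
    pick = rng.choice(len(background_chroms), size=n_bg, p=bg_lengths / bg_lengths.sum())
    for k, (c, l) in enumerate(background_chroms):
        m = pick == k
        p = rng.integers(1, l, size=int(m.sum()))
        if c == sl_chrom:  # bounce out of the SL region onto the pseudoautosomal part
            inside = (p >= sl_start) & (p <= sl_end)
            p[inside] = rng.integers(sl_end + 1, l, size=int(inside.sum()))
        chroms[n_sl:][m] = c
        starts[n_sl:][m] = p

    # genes: 1-3 transcripts share a gene and its sex effect
    gene_ids = np.empty(n_total, dtype=object)
    tx_ids = np.array([f"tx{i:06d}" for i in range(n_total)], dtype=object)
    g = 0
    i = 0
    gene_first: list = []
    while i < n_total:
        size = int(rng.integers(1, 4))
        size = min(size, n_total - i)
        # transcripts of a gene stay in the same compartment
        size = min(size, (n_sl - i) if i < n_sl else size)
        size = max(size, 1)
        gene_ids[i : i + size] = f"g{g:05d}"
        gene_first.append(i)
        g += 1
        i += size
    gene_first = np.array(gene_first)
    n_genes = len(gene_first)

    # --- sex effects at gene level ------------------------------------------
    gene_logfc = np.zeros(n_genes)
    gene_specific = np.zeros(n_genes, dtype=bool)
    sl_genes = np.flatnonzero(in_sl[gene_first])
    biased = sl_genes[rng.random(sl_genes.size) < cfg.sl_male_bias_fraction]
    gene_logfc[biased] = cfg.logfc_min_effect + rng.exponential(cfg.logfc_exp_scale, biased.size)
    gene_specific[biased] = rng.random(biased.size) < cfg.male_specific_fraction
    # background sex-biased genes elsewhere in the genome, both directions
    bg_genes = np.flatnonzero(~in_sl[gene_first])
    u = rng.random(bg_genes.size)
    bg_m = bg_genes[u < cfg.background_male_bias_fraction]
    bg_f = bg_genes[
        (u >= cfg.background_male_bias_fraction)
        & (u < cfg.background_male_bias_fraction + cfg.background_female_bias_fraction)
    ]
    gene_logfc[bg_m] = cfg.logfc_min_effect + rng.exponential(cfg.logfc_exp_scale, bg_m.size)
    gene_logfc[bg_f] = -(cfg.logfc_min_effect + rng.exponential(cfg.logfc_exp_scale, bg_f.size))

    gene_of_tx = np.searchsorted(gene_first, np.arange(n_total), side="right") - 1
    tx_logfc = gene_logfc[gene_of_tx]
    tx_specific = gene_specific[gene_of_tx]

    # --- counts ---------------------------------------------------------------
    base = rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, size=n_total)
    mean = np.empty((n_total, len(ids)))
    male_mean = base * np.exp2(tx_logfc / 2.0)
    female_mean = base * np.exp2(-tx_logfc / 2.0)
    female_mean[tx_specific] = 0.0
    male_mean[tx_specific] = base[tx_specific]
    mean[:, is_male] = male_mean[:, None]
    mean[:, ~is_male] = female_mean[:, None]

    r = 1.0 / cfg.nb_dispersion
    counts = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    counts[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
    counts_df = pd.DataFrame(counts, index=tx_ids, columns=ids)

    bias_truth = np.where(
        tx_specific,
        "male_specific",
        np.where(tx_logfc > 0, "male_biased", np.where(tx_logfc < 0, "female_biased", "unbiased")),
    )
    transcripts = pd.DataFrame(
        {
            "transcript_id": tx_ids,
            "gene_id": gene_ids,
            "chrom": chroms,
            "start": starts,
            "end": starts + lengths,
            "length": lengths,
            "true_logfc": tx_logfc,
            "true_bias_class": bias_truth,
            "in_sl_region": in_sl,
        }
    )

    # --- per-transcript heterozygosity ---------------------------------------
    pi_by_ind = np.array([expected_pi(cfg, g) for g in ped["true_genotype"]])
    callable_bp = rng.poisson(cfg.transcript_callable_bp, size=(n_total, len(ids)))
    pi_matrix = np.where(in_sl[:, None], pi_by_ind[None, :], cfg.within_type_theta)
    het = rng.binomial(callable_bp, pi_matrix)
    dp_t = rng.poisson(20.0, size=het.shape) + 4
    rows = {
        "individual": np.repeat(ids, n_total),
        "transcript_id": np.tile(tx_ids, len(ids)),
        "callable_sites": callable_bp.T.ravel(),
        "het_sites": het.T.ravel(),
        "dp": dp_t.T.ravel(),
        "gq": np.full(het.size, 60, dtype=np.int16),
        "mq": np.full(het.size, 50, dtype=np.int16),
    }
    calls = pd.DataFrame(rows)

    truth = {
        "cross": str(cfg.cross),
        "sl_region": list(cfg.sex_linked_region),
        "true_pi_by_individual": dict(zip(ids, pi_by_ind)),
    }
    return ExpressionDataset(counts_df, transcripts, calls, ped, truth)


# ---------------------------------------------------------------------------
# writers (plain-text formats only)


def write_vcf(dataset: FamilyDataset, path) -> None:
    """Write the genotype matrix as VCF 4.2 with GT:DP:GQ fields."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=trisexscan-simulate",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##INFO=<ID=RT,Number=1,Type=String,Description="RADtag id">',
    ]
    for chrom in dataset.sites["chrom"].unique():
        lines.append(f"##contig=<ID={chrom}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(dataset.samples))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for i in range(dataset.n_sites):
        chrom = dataset.sites["chrom"].iat[i]
        pos = dataset.sites["pos"].iat[i]
        tag = dataset.sites["radtag"].iat[i]
        fields = [
            str(chrom), str(pos), f"{chrom}_{pos}", "A", "T", ".", "PASS", f"RT={tag}", "GT:DP:GQ",
        ]
        for j in range(dataset.n_individuals):
            fields.append(f"{gt_str[int(dataset.gt[i, j])]}:{int(dataset.dp[i, j])}:{int(dataset.gq[i, j])}")
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")


def write_sample_sheet(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def write_counts_tsv(dataset: ExpressionDataset, path) -> None:
    dataset.counts.rename_axis("transcript_id").to_csv(path, sep="\t")


def write_transcript_bed(dataset: ExpressionDataset, path) -> None:
    """0-based half-open BED of transcript locations."""
    bed = dataset.transcripts[["chrom", "start", "end", "transcript_id"]].copy()
    bed["start"] = bed["start"] - 1  # 1-based start -> BED 0-based
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_truth_json(dataset: FamilyDataset, path) -> None:
    truth = dataset.truth or {}
    serializable = {
        k: v
        for k, v in truth.items()
        if k in ("cross", "sex_linked_region", "sd_position", "true_offspring_genotypes",
                 "crossovers", "error_mask_count", "missing_mask_count")
    }
    Path(path).write_text(json.dumps(serializable, indent=2))
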