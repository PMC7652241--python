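"""End-to-end orchestration of the analysis stages on one dataset.

Stage order: qc -> scan-linkage -> scan-fst -> expression -> infer-genotypes
-> maps.  All randomness derives from a single global seed; outputs are
plain TSV/JSON with a header naming the producing stage, package version
and config hash, so identical config + inputs give identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import expression as expr
from . import fst as fst_mod
from . import linkage_scan, maps as maps_mod, pi_genotypes as pig
from .qc import QcConfig, apply_qc
from .simulate import ExpressionDataset, FamilyDataset, SimConfig, simulate_expression, simulate_family

ALL_STAGES = ("qc", "scan-linkage", "scan-fst", "expression", "infer-genotypes", "maps")


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "trisexscan_out"
    stages: tuple = ALL_STAGES
    qc: QcConfig = field(default_factory=QcConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    mask_window_bp: int = 10_000_000
    apply_fdr: bool = True
    fst_window: int = 50
    fst_band_mode: str = "bootstrap-mean"
    fst_bootstrap: int = 1000
    sl_region: tuple = ("Chr7", 1, 10_300_000)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # where outputs land must not change what they contain
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(cfg: RunConfig, stage: str) -> str:
    return f"stage={stage} version={__version__} config={cfg.config_hash()}"


def run_pipeline(
    config: RunConfig,
    family: FamilyDataset | None = None,
    expression_data: ExpressionDataset | None = None,
) -> dict:
    """Run the selected stages; simulate inputs when none are supplied.

    Returns a RunReport-like dict of per-stage summaries; files land under
    ``config.out_dir``.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    if family is None:
        family = simulate_family(cfg.sim, seed=cfg.seed)
    if expression_data is None:
        expression_data = simulate_expression(cfg.sim, seed=cfg.seed + 1)

    data = family
    if "qc" in cfg.stages:
        data, qc_report = apply_qc(family, cfg.qc)
        (out / "qc_report.json").write_text(json.dumps(
            {"header": _stamp(cfg, "qc"), **qc_report.to_dict()}, indent=2))
        report["stages"]["qc"] = {
            "sites_in": family.n_sites, "sites_out": data.n_sites,
            "individuals_out": data.n_individuals,
        }

    masked_sets = {}
    if "scan-linkage" in cfg.stages or "maps" in cfg.stages:
        for parent in ("mother", "father"):
            ss = linkage_scan.extract_informative_sites(data, parent)
            if ss.n_sites:
                ss = linkage_scan.phase_states(ss)
                ss = linkage_scan.mask_double_recombinants(ss, cfg.mask_window_bp)
            masked_sets[parent] = ss

    if "scan-linkage" in cfg.stages:
        frames = []
        for parent, ss in masked_sets.items():
            if ss.n_sites == 0:
                continue
            res = linkage_scan.test_sex_association(ss, apply_fdr=cfg.apply_fdr)
            frames.append(res.table)
        scan_table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        path = out / "sex_linkage.tsv"
        with path.open("w") as fh:
            fh.write(f"# {_stamp(cfg, 'scan-linkage')}\n")
            scan_table.to_csv(fh, sep="\t", index=False)
        sig = int((scan_table.get("q", scan_table.get("p", pd.Series(dtype=float))) < 0.05).sum())
        report["stages"]["scan-linkage"] = {"sites_tested": len(scan_table), "significant": sig}

    if "scan-fst" in cfg.stages:
        offspring = data.offspring_ids()
        cols = [data.column(o) for o in offspring]
        ped = data.pedigree.set_index("id")
        sexes = np.array([ped.loc[o, "sex"] for o in offspring])
        sl_chrom = cfg.sl_region[0]
        autosomes = [c for c in data.sites["chrom"].unique() if c != sl_chrom]
        track = fst_mod.between_sex_scan(
            data.gt[:, cols], data.sites, sexes,
            window_size=cfg.fst_window, band_mode=cfg.fst_band_mode,
            autosomes=autosomes, B=cfg.fst_bootstrap, seed=cfg.seed,
        )
        path = out / "fst_windows.tsv"
        with path.open("w") as fh:
            fh.write(f"# {_stamp(cfg, 'scan-fst')} estimator={track.estimator}\n")
            track.windows.to_csv(fh, sep="\t", index=False)
        (out / "fst_band.json").write_text(json.dumps(
            {"header": _stamp(cfg, "scan-fst"), "band": track.band, "peak": track.peak}, indent=2))
        report["stages"]["scan-fst"] = {"windows": len(track.windows), "peak": track.peak,
                                        "band": track.band}

    records = None
    if "expression" in cfg.stages:
        counts = expr.prefilter_counts(expression_data.counts)
        lengths = expression_data.transcripts.set_index("transcript_id")["length"]
        sexes = expression_data.pedigree.set_index("id")["sex"]
        records = expr.call_bias(counts, lengths, sexes)
        summary = expr.sex_bias_summary(records, expression_data.transcripts, cfg.sl_region)
        path = out / "expression_bias.tsv"
        with path.open("w") as fh:
            fh.write(f"# {_stamp(cfg, 'expression')}\n")
            records.rename_axis("transcript_id").to_csv(fh, sep="\t")
        (out / "region_enrichment.json").write_text(
            json.dumps({"header": _stamp(cfg, "expression"),
                        **{k: (list(v) if isinstance(v, tuple) else v) for k, v in summary.items()}},
                       indent=2))
        report["stages"]["expression"] = {
            k: summary[k] for k in ("male_biased_inside", "female_biased_inside",
                                    "male_density_per_mb", "binomial_p_male_enrichment")
        }

    if "infer-genotypes" in cfg.stages:
        profiles = pig.per_individual_pi(
            expression_data.calls, expression_data.transcripts,
            expression_data.pedigree, region=cfg.sl_region,
        )
        calls, cross = pig.assign_genotypes(profiles)
        origin = pig.infer_y_origin(profiles, calls, seed=cfg.seed)
        table = pd.DataFrame(
            [{"id": c.individual, "sex": c.sex, "genotype": c.genotype,
              "level": c.diversity_level, "note": c.note} for c in calls]
        )
        path = out / "genotype_calls.tsv"
        with path.open("w") as fh:
            fh.write(f"# {_stamp(cfg, 'infer-genotypes')}\n")
            table.to_csv(fh, sep="\t", index=False)
        (out / "y_origin.json").write_text(json.dumps(
            {"header": _stamp(cfg, "infer-genotypes"), **origin}, indent=2))
        report["stages"]["infer-genotypes"] = {
            "resolved_cross": str(cross) if cross else None,
            "y_origin": origin["origin"], "support": origin["support"],
        }

    if "maps" in cfg.stages:
        chrom_lengths = dict(cfg.sim.chromosomes)
        rows = []
        all_events = []
        fam = data.pedigree["family"].iloc[0]
        for parent, psex in (("mother", "female"), ("father", "male")):
            ss = masked_sets.get(parent)
            if ss is None or ss.n_sites == 0:
                continue
            for m in maps_mod.build_map(ss, fam, psex):
                rows.append({"family": m.family, "sex": m.parent_sex, "chrom": m.chromosome,
                             "total_cm": m.total_cm, "n_markers": m.n_markers,
                             "bp_covered": m.bp_covered,
                             "pct_covered": m.percent_covered(chrom_lengths[m.chromosome])})
            all_events.extend(maps_mod.locate_crossovers(ss, psex))
        map_table = pd.DataFrame(rows)
        path = out / "linkage_maps.tsv"
        with path.open("w") as fh:
            fh.write(f"# {_stamp(cfg, 'maps')}\n")
            map_table.to_csv(fh, sep="\t", index=False)
        summary = {}
        for psex in ("female", "male"):
            ev = [e for e in all_events if e.parent_sex == psex]
            total = float(map_table.loc[map_table["sex"] == psex, "total_cm"].sum()) if len(map_table) else 0.0
            entry = {"total_cm": total, "n_crossovers": len(ev)}
            if ev:
                counts, tip = maps_mod.quartile_density(ev, chrom_lengths)
                entry.update({"quartile_counts": counts.tolist(), "tip_bias": tip})
            summary[psex] = entry
        (out / "map_summary.json").write_text(json.dumps(
            {"header": _stamp(cfg, "maps"), **summary}, indent=2))
        report["stages"]["maps"] = summary

    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
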