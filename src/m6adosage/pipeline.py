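"""Pipeline driver chaining the analysis stages.

Stages read their inputs from files (the TSV/GTF/FASTA/BED dialects defined
in :mod:`m6adosage.io`) and write per-stage TSV outputs plus a JSON run
report with the config echo, derived seeds and filter ledgers. All
randomness flows from the single config seed; per-stage seeds are derived
from it and recorded.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import dosage as ds
from . import io as mio
from . import m6amap
from . import motifs as mo
from . import slamfit
from . import synth as sy

X_ALIASES = ("X", "chrX")

STAGE_ORDER = ("synth", "halflife", "m6a_landscape", "dosage", "motifs")


@dataclass
class RunConfig:
    """Pipeline configuration; threshold defaults are the standard analysis
    values (coverage > 100 Ts, half-life window 0.67-18 h, residual s.e.
    <= 0.3, expression bins 3-8, RPKM floors 1 and 10, 100 reference
    genes)."""

    stages: tuple = STAGE_ORDER
    outdir: str = "m6adosage_run"
    seed: int = 0
    paths: dict = field(default_factory=dict)
    synth: sy.SynthConfig | None = None
    min_t_cov: int = 100
    t_half_bounds: tuple = (0.67, 18.0)
    max_rse: float = 0.3
    bin_range: tuple = (3, 8)
    rpkm_floor_summary: float = 1.0
    reference_rpkm_floor: float = 10.0
    n_reference_genes: int = 100
    n_boot: int = 1000
    pseudocount: float = 0.5
    motif_pattern: str = "GGACH"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_cfg = None
        if "synth" in raw:
            synth_cfg = sy.SynthConfig(**raw.pop("synth"))
        cfg = cls(**raw)
        cfg.synth = synth_cfg
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def path(self, key: str, default: str) -> str:
        return self.paths.get(key, os.path.join(self.outdir, "synth", default))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _load_annotation_and_sites(cfg: RunConfig):
    transcripts, _ = mio.read_annotation(cfg.path("annotation", "annotation.gtf"))
    sites, ledger = mio.read_sites(cfg.path("sites", "m6a_sites.bed"), transcripts)
    return transcripts, sites, ledger


def stage_synth(cfg: RunConfig) -> dict:
    synth_cfg = cfg.synth or sy.SynthConfig(seed=cfg.seed)
    outdir = os.path.join(cfg.outdir, "synth")
    dataset = sy.simulate(synth_cfg, outdir=outdir)
    truth = dataset.truth
    return {
        "n_genes": int((~truth["is_spikein"]).sum()),
        "n_spikeins": int(truth["is_spikein"].sum()),
        "n_sites": len(dataset.sites),
        "seed": synth_cfg.seed,
        "outdir": outdir,
    }


def stage_halflife(cfg: RunConfig) -> dict:
    conversions = mio.read_table(cfg.path("conversions", "conversions.tsv"), "conversions")
    unlabeled = mio.read_table(cfg.path("unlabeled", "unlabeled.tsv"), "conversions")
    transcripts, sites, site_ledger = _load_annotation_and_sites(cfg)
    chrom_map = pd.Series({t.gene_id: t.chrom for t in transcripts})
    m6a_counts = sites.groupby("gene_id").size()

    normalized, excluded = slamfit.correct_and_normalize(conversions, unlabeled)
    fits = slamfit.fit_all(normalized)
    kept, ledger = slamfit.filter_fits(
        fits,
        min_t_cov=cfg.min_t_cov,
        bounds=cfg.t_half_bounds,
        max_rse=cfg.max_rse,
    )
    out = os.path.join(cfg.outdir, "halflife")
    os.makedirs(out, exist_ok=True)
    fits_out = fits.merge(
        kept[["utr_id", "condition"]].assign(kept=True),
        on=["utr_id", "condition"], how="left",
    )
    fits_out["kept"] = fits_out["kept"].eq(True)
    mio.write_table(os.path.join(out, "fits.tsv"), fits_out)

    conds = sorted(kept["condition"].unique())
    contrast = None
    if len(conds) == 2:
        ctrl = kept[kept["condition"] == conds[0]]
        trt = kept[kept["condition"] == conds[1]]
        contrast = slamfit.halflife_contrast(ctrl, trt, m6a_counts, chrom_map, X_ALIASES)
        with open(os.path.join(out, "contrast.json"), "w") as fh:
            json.dump(
                _jsonable(
                    {k: v for k, v in contrast.items() if k != "per_transcript"}
                ),
                fh, indent=1,
            )
    return {
        "filter_ledger": ledger,
        "n_excluded_normalization": len(excluded),
        "site_ledger": site_ledger,
        "median_t_half": _jsonable(kept.groupby("condition")["t_half"].median()),
        "contrast": None
        if contrast is None
        else _jsonable({k: v for k, v in contrast.items() if k != "per_transcript"}),
    }


def stage_m6a_landscape(cfg: RunConfig) -> dict:
    transcripts, sites, site_ledger = _load_annotation_and_sites(cfg)
    tpm = mio.read_table(cfg.path("tpm", "tpm.tsv"), "tpm")
    bins = m6amap.assign_bins(tpm)
    chrom_map = pd.Series({t.gene_id: t.chrom for t in transcripts})
    bins = bins.loc[bins.index.intersection(chrom_map.index)]
    counts, count_ledger = m6amap.count_sites_per_transcript(sites, transcripts)
    profile = m6amap.bin_profile(counts, bins["bin"], chrom_map)
    fc = m6amap.chrom_fold_change(
        counts, bins["bin"], chrom_map,
        bin_range=cfg.bin_range, x_aliases=X_ALIASES,
        n_boot=cfg.n_boot, seed=cfg.seed + 11,
    )
    out = os.path.join(cfg.outdir, "m6a_landscape")
    os.makedirs(out, exist_ok=True)
    mio.write_table(os.path.join(out, "bin_profile.tsv"), profile)
    mio.write_table(os.path.join(out, "chrom_fold_change.tsv"), fc["summary"])
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(
            _jsonable(
                {
                    "p_class_nb_wald": fc["p_class_nb_wald"],
                    "bin_range": fc["bin_range"],
                    "skipped_strata": fc["skipped_strata"],
                    "ledgers": {"sites": site_ledger, "counting": count_ledger},
                }
            ),
            fh, indent=1,
        )
    x_rows = fc["summary"][fc["summary"]["chrom_class"] == "X"]
    return {
        "x_summary_log2fc": None if x_rows.empty else float(x_rows["summary_log2fc"].iloc[0]),
        "p_class_nb_wald": fc["p_class_nb_wald"],
        "ledgers": {"sites": site_ledger, "counting": count_ledger},
    }


def stage_dosage(cfg: RunConfig) -> dict:
    counts = mio.read_table(cfg.path("counts", "counts.tsv"), "counts")
    rpkm = mio.read_table(cfg.path("rpkm", "rpkm.tsv"), "rpkm")["rpkm"]
    transcripts, sites, _ = _load_annotation_and_sites(cfg)
    chrom_map = pd.Series({t.gene_id: t.chrom for t in transcripts})
    site_counts = sites.groupby("gene_id").size()

    ctrl_cols = [c for c in counts.columns if c.startswith("control")]
    trt_cols = [c for c in counts.columns if c.startswith("depleted")]
    spikeins = [g for g in counts.index if str(g).startswith("spikein")]

    refs = ds.pick_reference_genes(
        site_counts, rpkm,
        n=cfg.n_reference_genes, min_rpkm=cfg.reference_rpkm_floor,
        seed=cfg.seed + 21, exclude=spikeins,
    )
    factors = ds.size_factors(counts, refs)
    fc = ds.gene_log2fc(counts, ctrl_cols, trt_cols, factors, cfg.pseudocount)
    fc_genes = fc.drop(index=spikeins, errors="ignore")
    summary = ds.chromosome_response(
        fc_genes["log2fc"], chrom_map, rpkm=rpkm,
        min_rpkm=cfg.rpkm_floor_summary, x_aliases=X_ALIASES,
    )
    norm = counts / factors
    expr = pd.DataFrame(
        {
            "control": norm[ctrl_cols].mean(axis=1),
            "depleted": norm[trt_cols].mean(axis=1),
        }
    ).drop(index=spikeins, errors="ignore")
    xa = ds.xa_expression_ratio(
        expr, chrom_map, min_expr=1.0, n_boot=cfg.n_boot,
        seed=cfg.seed + 22, x_aliases=X_ALIASES,
    )
    burden = ds.fc_vs_m6a_burden(fc_genes["log2fc"], site_counts)

    out = os.path.join(cfg.outdir, "dosage")
    os.makedirs(out, exist_ok=True)
    mio.write_table(os.path.join(out, "log2fc.tsv"), fc.reset_index())
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(
            _jsonable(
                {
                    "per_chrom_medians": summary.per_chrom_medians,
                    "median_autosome": summary.median_autosome,
                    "median_x": summary.median_x,
                    "effect_size_pct": summary.effect_size_pct,
                    "p_ranksum": summary.p_ranksum,
                    "xa_ratio": xa,
                    "burden": burden,
                    "reference_genes": refs,
                }
            ),
            fh, indent=1,
        )
    return {
        "median_autosome_log2fc": summary.median_autosome,
        "median_x_log2fc": summary.median_x,
        "effect_size_pct": summary.effect_size_pct,
        "p_ranksum": summary.p_ranksum,
        "xa_ratio": _jsonable({"rho": xa["rho"], "p_delta": xa.get("p_delta")}),
    }


def stage_motifs(cfg: RunConfig) -> dict:
    transcripts, _ = mio.read_annotation(cfg.path("annotation", "annotation.gtf"))
    genome = mio.read_fasta(cfg.path("genome", "genome.fa"))
    canonical, n_excluded = mo.select_canonical_isoforms(transcripts)
    out = os.path.join(cfg.outdir, "motifs")
    os.makedirs(out, exist_ok=True)
    densities = {}
    means = {}
    for region in ("utr5", "cds", "utr3"):
        d = mo.region_density(canonical, genome, cfg.motif_pattern, region)
        densities[region] = d
        mio.write_table(os.path.join(out, f"density_{region}.tsv"), d)
        is_x = d["chrom"].isin(X_ALIASES)
        means[region] = {
            "autosome_mean_per_kb": float(d.loc[~is_x, "density_per_kb"].mean()),
            "x_mean_per_kb": float(d.loc[is_x, "density_per_kb"].mean()),
        }
    return {"n_genes_excluded": n_excluded, "mean_density": means}


_STAGE_FUNCS = {
    "synth": stage_synth,
    "halflife": stage_halflife,
    "m6a_landscape": stage_m6a_landscape,
    "dosage": stage_dosage,
    "motifs": stage_motifs,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the selected stages in dependency order; fail fast."""
    os.makedirs(cfg.outdir, exist_ok=True)
    selected = [s for s in STAGE_ORDER if s in cfg.stages]
    unknown = set(cfg.stages) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    needs_synth = {"halflife", "m6a_landscape", "dosage", "motifs"}
    if "synth" not in selected and not cfg.paths:
        missing = needs_synth & set(selected)
        if missing:
            raise ValueError(
                "stages require input paths or the synth stage: " + ", ".join(sorted(missing))
            )
    report = {
        "config": _jsonable(cfg.to_dict()),
        "seed": cfg.seed,
        "stages": {},
    }
    for stage in selected:
        report["stages"][stage] = _STAGE_FUNCS[stage](cfg)
    with open(os.path.join(cfg.outdir, "run_report.json"), "w") as fh:
        json.dump(_jsonable(report), fh, indent=1)
    return report
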