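"""Synthetic "mini-mouse" transcriptome generator with known ground truth.

The generator emulates the statistical structure of the real study system:
lognormal expression, negative-binomial counts, GGACH motifs planted at a
Poisson rate per kb with reduced 3'UTR density on the X chromosome (3.1 vs
1.7 per kb by default), methylation of a fraction of motifs with
expression-bin-dependent detection, first-order-decay conversion time
courses over a uridine chase with a constant background, treatment-induced
per-gene fold changes proportional to m6A burden on autosomes only, and
unaffected spike-in rows.

Background sequence is scrubbed free of accidental GGACH before motifs are
planted at spaced positions, and the assembled transcript is re-scanned, so
the planted-motif truth always equals what a scan recovers.

Everything is driven by a single integer seed; identical configurations
produce byte-identical outputs.
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as mio
from .annotation import TranscriptModel, reverse_complement
from .m6amap import expression_bin
from .motifs import find_motifs

_GGACH = re.compile(r"(?=GGAC[ACT])")
_STOPS = ("TAA", "TAG", "TGA")

#: chase grid: geometric x1.5 spacing anchored so the last point is 12 h
#: (the 18 h half-life ceiling is 1.5x the last chase time point)
DEFAULT_CHASE_H = (
    0.0, 0.5, 0.75, 1.125, 1.6875, 2.53125, 3.796875, 5.6953125, 8.54296875, 12.0
)

DEFAULT_DETECTION_CURVE = (
    0.05, 0.10, 0.30, 0.60, 0.80, 0.90, 0.95, 0.95, 0.95, 0.95, 0.95, 0.95
)


@dataclass
class SynthConfig:
    """Parameters of the synthetic dataset; defaults are the study
    conditions every recovery test runs under."""

    n_chromosomes: int = 20          # chr1..chr19 + chrX
    genes_per_chromosome: int = 100
    # lognormal (mean of log nt, sd of log) per region
    region_length_params: dict = field(
        default_factory=lambda: {
            "utr5": (math.log(150.0), 0.4),
            "cds": (math.log(1200.0), 0.45),
            "utr3": (math.log(1000.0), 0.55),
        }
    )
    # GGACH motifs per kb, (autosome, X) per region
    ggach_density: dict = field(
        default_factory=lambda: {
            "utr5": (1.0, 1.0),
            "cds": (2.0, 1.2),
            "utr3": (3.1, 1.7),
        }
    )
    methylation_prob: float = 0.3
    methylation_prob_x: float | None = None   # None -> same as autosomes
    detection_curve: tuple = DEFAULT_DETECTION_CURVE
    halflife_base: tuple = (math.log(4.0), 0.5)  # lognormal, hours
    destabilization_per_site: float = 0.90       # multiplicative t1/2 factor
    destabilization_cap: int = 5
    destabilization_mode: str = "per_site"       # or "flat"
    background_conversion: float = 1.0e-3
    t0_conversion: float = 1.36e-2
    chase_timepoints: tuple = DEFAULT_CHASE_H
    coverage_params: tuple = (5000.0, 0.1)       # NB mean, dispersion of T coverage
    n_slam_replicates: int = 2
    n_unlabeled_replicates: int = 2
    expression_params: tuple = (math.log(30.0), 1.5)  # lognormal TPM
    nb_dispersion: float = 0.01
    library_size: float = 5.0e6
    n_count_replicates: int = 3
    beta_treatment: float = 0.1                  # log2FC per m6A site
    treatment_site_cap: int = 5
    treatment_affects_x: bool = False
    n_spikeins: int = 92
    spikein_tpm: float = 200.0
    spikein_dispersion: float = 0.01
    tpm_replicate_noise_sd: float = 0.05
    intergenic_length: int = 200
    seed: int = 0

    def chromosome_names(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes)] + ["chrX"]

    def validate(self) -> None:
        probs = [self.methylation_prob, *self.detection_curve]
        if self.methylation_prob_x is not None:
            probs.append(self.methylation_prob_x)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for r in (self.background_conversion, self.t0_conversion):
            if not (0.0 < r < 1.0):
                raise ValueError("conversion rates must lie in (0, 1)")
        for region, (da, dx) in self.ggach_density.items():
            if da < 0 or dx < 0:
                raise ValueError(f"negative motif density for {region}")
        for region, (mu, sd) in self.region_length_params.items():
            if sd < 0 or not np.isfinite(mu):
                raise ValueError(f"bad length params for {region}")
            if math.exp(mu) < 1.0:
                raise ValueError(f"zero-length region request for {region}")
        ts = self.chase_timepoints
        if len(ts) == 0:
            raise ValueError("chase_timepoints must not be empty")
        if ts[0] != 0 or any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("chase_timepoints must be strictly increasing from 0")
        if self.destabilization_mode not in ("per_site", "flat"):
            raise ValueError(f"unknown destabilization mode {self.destabilization_mode!r}")
        if len(self.detection_curve) != 12:
            raise ValueError("detection_curve needs one probability per expression bin")


# ---------------------------------------------------------------------------
# Sequence construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.int8)


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _scrub_ggach(seq: str, rng: np.random.Generator, protected: set[int] | None = None) -> str:
    """Destroy every GGACH match (mutating the C) outside protected starts."""
    protected = protected or set()
    arr = bytearray(seq, "ascii")
    while True:
        hits = [
            m.start() for m in _GGACH.finditer(bytes(arr).decode())
            if m.start() not in protected
        ]
        if not hits:
            return bytes(arr).decode()
        for h in hits:
            arr[h + 3] = ord(rng.choice(list("AGT")))


def _plant_positions(rng: np.random.Generator, length: int, density_per_kb: float) -> list[int]:
    """Poisson number of motif start positions, pairwise spaced >= 5 nt."""
    if length < 5 or density_per_kb <= 0:
        return []
    n = rng.poisson(density_per_kb * length / 1000.0)
    n = min(n, max(0, (length - 5) // 5 + 1))
    chosen: list[int] = []
    attempts = 0
    while len(chosen) < n and attempts < 50 * n + 50:
        p = int(rng.integers(0, length - 4))
        if all(abs(p - q) >= 5 for q in chosen):
            chosen.append(p)
        attempts += 1
    return sorted(chosen)


def _build_region(
    rng: np.random.Generator, length: int, density_per_kb: float, kind: str
) -> tuple[str, list[int]]:
    """Motif-free random sequence of ``length`` nt with GGACH planted at the
    configured density; CDS regions get start/stop codons."""
    arr = _to_str(_random_seq(rng, length))
    if kind == "cds":
        stop = _STOPS[int(rng.integers(0, 3))]
        arr = "ATG" + arr[3 : length - 3] + stop
    arr = _scrub_ggach(arr, rng)
    positions = _plant_positions(rng, length if kind != "cds" else length - 3, density_per_kb)
    if kind == "cds":
        positions = [p for p in positions if p >= 3]
    chars = list(arr)
    for p in positions:
        chars[p : p + 4] = "GGAC"
        chars[p + 4] = rng.choice(list("ACT"))
    return "".join(chars), positions


def _region_lengths(rng: np.random.Generator, cfg: SynthConfig) -> dict[str, int]:
    out = {}
    for region, (mu, sd) in cfg.region_length_params.items():
        n = int(round(rng.lognormal(mu, sd)))
        if region == "cds":
            n = max(60, 3 * round(n / 3))
        else:
            n = max(20, n)
        out[region] = n
    return out


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SynthConfig
    transcripts: list
    genome: dict
    truth: pd.DataFrame              # indexed by gene_id
    motifs: pd.DataFrame             # planted GGACH anchors (gene, region, tx/genomic pos)
    tpm: pd.DataFrame | None = None
    rpkm: pd.Series | None = None
    sites: pd.DataFrame | None = None
    conversions: pd.DataFrame | None = None
    unlabeled: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    sample_conditions: dict | None = None

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        mio.write_annotation(os.path.join(outdir, "annotation.gtf"), self.transcripts)
        mio.write_fasta(os.path.join(outdir, "genome.fa"), self.genome)
        if self.sites is not None:
            mio.write_sites(os.path.join(outdir, "m6a_sites.bed"), self.sites)
        if self.tpm is not None:
            self.tpm.reset_index().to_csv(
                os.path.join(outdir, "tpm.tsv"), sep="\t", index=False
            )
        if self.rpkm is not None:
            self.rpkm.rename("rpkm").reset_index().to_csv(
                os.path.join(outdir, "rpkm.tsv"), sep="\t", index=False
            )
        if self.conversions is not None:
            self.conversions.to_csv(
                os.path.join(outdir, "conversions.tsv"), sep="\t", index=False
            )
        if self.unlabeled is not None:
            self.unlabeled.to_csv(
                os.path.join(outdir, "unlabeled.tsv"), sep="\t", index=False
            )
        if self.counts is not None:
            self.counts.reset_index().to_csv(
                os.path.join(outdir, "counts.tsv"), sep="\t", index=False
            )
        truth = self.truth.reset_index().to_dict(orient="records")
        with open(os.path.join(outdir, "ground_truth.json"), "w") as fh:
            json.dump(
                {"config": _config_dict(self.config), "genes": truth},
                fh, indent=1, default=float,
            )


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    return d


# ---------------------------------------------------------------------------
# Stage 1: transcriptome
# ---------------------------------------------------------------------------

def gen_transcriptome(config: SynthConfig):
    """Annotation + genome + ground-truth skeleton + planted motif table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    transcripts: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    truth_rows = []
    motif_rows = []
    gene_no = 0
    for chrom in config.chromosome_names():
        is_x = chrom == "chrX"
        parts = []
        cursor = 0
        spacer = _to_str(_random_seq(rng, config.intergenic_length))
        parts.append(spacer)
        cursor += len(spacer)
        for _ in range(config.genes_per_chromosome):
            gene_no += 1
            gene_id = f"G{gene_no:05d}"
            tx_id = f"T{gene_no:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            lengths = _region_lengths(rng, config)
            seqs = {}
            planted = {}
            for region in ("utr5", "cds", "utr3"):
                da, dx = config.ggach_density[region]
                seqs[region], planted[region] = _build_region(
                    rng, lengths[region], dx if is_x else da, region
                )
            sense = seqs["utr5"] + seqs["cds"] + seqs["utr3"]
            # boundary junctions may spell accidental motifs: scrub them,
            # protecting planted starts, then record truth from a re-scan
            offsets = {
                "utr5": 0,
                "cds": lengths["utr5"],
                "utr3": lengths["utr5"] + lengths["cds"],
            }
            protected = {
                offsets[r] + p for r in planted for p in planted[r]
            }
            sense = _scrub_ggach(sense, rng, protected=protected)
            scan = find_motifs(sense, "GGACH")
            assert set(scan) == protected, "planted-motif bookkeeping broke"

            L = len(sense)
            start = cursor
            end = cursor + L
            exons = [(start, end)]
            if strand == "+":
                g_iv = lambda a, b: (start + a, start + b)
            else:
                g_iv = lambda a, b: (end - b, end - a)
            regions = {
                r: [g_iv(offsets[r], offsets[r] + lengths[r])]
                for r in ("utr5", "cds", "utr3")
            }
            transcripts.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=tx_id,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    regions=regions,
                    ccds_id=f"CCDS{gene_no:05d}",
                    transcript_support_level=1,
                    level=1,
                )
            )
            parts.append(sense if strand == "+" else reverse_complement(sense))
            spacer = _to_str(_random_seq(rng, config.intergenic_length))
            parts.append(spacer)
            cursor = end + len(spacer)

            region_of = {}
            for r in ("utr5", "cds", "utr3"):
                for p in planted[r]:
                    region_of[offsets[r] + p] = r
            for tx_start in sorted(protected):
                anchor_tx = tx_start + 2  # the methylatable A of GGACH
                gpos = start + anchor_tx if strand == "+" else end - 1 - anchor_tx
                motif_rows.append(
                    {
                        "gene_id": gene_id,
                        "chrom": chrom,
                        "strand": strand,
                        "region": region_of[tx_start],
                        "tx_pos": anchor_tx,
                        "pos": gpos,
                    }
                )
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": chrom,
                    "chrom_class": "X" if is_x else "autosome",
                    "strand": strand,
                    "length": L,
                    "utr5_len": lengths["utr5"],
                    "cds_len": lengths["cds"],
                    "utr3_len": lengths["utr3"],
                    "n_ggach": len(protected),
                    "n_ggach_utr3": len(planted["utr3"]),
                    "is_spikein": False,
                }
            )
        genome[chrom] = "".join(parts)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    motifs = pd.DataFrame(
        motif_rows, columns=["gene_id", "chrom", "strand", "region", "tx_pos", "pos"]
    )
    return transcripts, genome, truth, motifs


# ---------------------------------------------------------------------------
# Stage 2: expression
# ---------------------------------------------------------------------------

def gen_expression(truth: pd.DataFrame, config: SynthConfig, rng: np.random.Generator):
    """Lognormal TPM (scaled to sum 1e6, incl. spike-ins), NB baseline
    counts and length-consistent RPKM; appends spike-in rows to truth."""
    mu, sd = config.expression_params
    genes = truth.index[~truth["is_spikein"]]
    tpm_raw = rng.lognormal(mu, sd, size=len(genes))
    spike_ids = [f"spikein_{i + 1:03d}" for i in range(config.n_spikeins)]
    spike_tpm = np.full(config.n_spikeins, config.spikein_tpm) * rng.lognormal(
        0.0, 0.1, size=config.n_spikeins
    )
    all_ids = list(genes) + spike_ids
    raw = np.concatenate([tpm_raw, spike_tpm])
    tpm_mean = raw * 1.0e6 / raw.sum()

    for sid in spike_ids:
        if sid not in truth.index:
            truth.loc[sid] = {
                "chrom": "spikein", "chrom_class": "spikein", "strand": "+",
                "length": 1000, "utr5_len": 0, "cds_len": 0, "utr3_len": 0,
                "n_ggach": 0, "n_ggach_utr3": 0, "is_spikein": True,
            }
    lengths = truth.loc[all_ids, "length"].to_numpy(dtype=float)

    # replicate TPM columns with small lognormal measurement noise
    reps = {}
    for r in range(1, 4):
        noise = rng.lognormal(0.0, config.tpm_replicate_noise_sd, size=len(all_ids))
        reps[f"tpm_{r}"] = tpm_mean * noise
    tpm = pd.DataFrame(reps, index=pd.Index(all_ids, name="gene_id"))

    w = tpm_mean * lengths
    mean_counts = config.library_size * w / w.sum()
    rpkm = pd.Series(
        1.0e9 * mean_counts / (config.library_size * lengths),
        index=tpm.index, name="rpkm",
    )
    truth.loc[all_ids, "tpm"] = tpm_mean
    truth.loc[all_ids, "mean_counts"] = mean_counts
    truth.loc[all_ids, "rpkm"] = rpkm
    truth["expression_bin"] = expression_bin(truth["tpm"].to_numpy())
    return tpm, rpkm


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# Stage 3: m6A sites
# ---------------------------------------------------------------------------

def gen_m6a_sites(
    transcripts, truth: pd.DataFrame, motifs: pd.DataFrame,
    config: SynthConfig, rng: np.random.Generator,
) -> pd.DataFrame:
    """Methylate each planted GGACH with the class methylation probability,
    then observe methylated motifs with the expression-bin detection
    probability. Truth records the pre-detection counts."""
    p_auto = config.methylation_prob
    p_x = config.methylation_prob_x if config.methylation_prob_x is not None else p_auto
    det = np.asarray(config.detection_curve)
    bins = truth["expression_bin"]

    meth_flags = np.zeros(len(motifs), dtype=bool)
    obs_flags = np.zeros(len(motifs), dtype=bool)
    chrom_is_x = motifs["chrom"].eq("chrX").to_numpy()
    p_site = np.where(chrom_is_x, p_x, p_auto)
    meth_flags = rng.random(len(motifs)) < p_site
    gene_bins = motifs["gene_id"].map(bins).fillna(0).astype(int).to_numpy()
    p_det = np.where(gene_bins >= 1, det[np.clip(gene_bins, 1, 12) - 1], det[0])
    obs_flags = meth_flags & (rng.random(len(motifs)) < p_det)

    motifs = motifs.assign(methylated=meth_flags, observed=obs_flags)
    n_true = motifs.groupby("gene_id")["methylated"].sum()
    n_obs = motifs.groupby("gene_id")["observed"].sum()
    truth["n_m6a_true"] = n_true.reindex(truth.index).fillna(0).astype(int)
    truth["n_m6a_observed"] = n_obs.reindex(truth.index).fillna(0).astype(int)

    sites = motifs.loc[
        motifs["observed"], ["chrom", "pos", "strand", "gene_id"]
    ].reset_index(drop=True)
    sites["name"] = sites["gene_id"]
    return sites


# ---------------------------------------------------------------------------
# Stage 4: SLAM-seq profiles
# ---------------------------------------------------------------------------

def _halflife_factor(n_sites: np.ndarray, config: SynthConfig) -> np.ndarray:
    capped = np.minimum(n_sites, config.destabilization_cap)
    if config.destabilization_mode == "flat":
        return np.where(n_sites > 0, config.destabilization_per_site, 1.0)
    return config.destabilization_per_site ** capped


def gen_slam_profiles(
    truth: pd.DataFrame, config: SynthConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conversion time courses for control and treated conditions plus
    unlabeled background profiles.

    Control half-lives carry the per-site destabilization; the treated
    (methyltransferase-inhibited) condition removes it. Conversion counts
    are binomial draws at rate background + (r0 - background) *
    2**(-t / t_half) from NB-distributed T coverage.
    """
    if len(config.chase_timepoints) == 0:
        raise ValueError("chase_timepoints must not be empty")
    genes = truth.index[~truth["is_spikein"]]
    mu, sd = config.halflife_base
    base = rng.lognormal(mu, sd, size=len(genes))
    n_sites = truth.loc[genes, "n_m6a_true"].to_numpy()
    t_ctrl = base * _halflife_factor(n_sites, config)
    t_trt = base
    truth.loc[genes, "t_half_control"] = t_ctrl
    truth.loc[genes, "t_half_treated"] = t_trt
    truth.loc[genes, "k_control"] = math.log(2.0) / t_ctrl
    truth.loc[genes, "k_treated"] = math.log(2.0) / t_trt

    cov_mean, cov_disp = config.coverage_params
    bg, r0 = config.background_conversion, config.t0_conversion
    rows = []
    times = np.asarray(config.chase_timepoints)
    for cond, t_half in (("control", t_ctrl), ("treated", t_trt)):
        for rep in range(1, config.n_slam_replicates + 1):
            for t in times:
                rate = bg + (r0 - bg) * np.power(2.0, -t / t_half)
                cov = _nb_draw(rng, np.full(len(genes), cov_mean), cov_disp)
                cov = np.maximum(cov, 1)
                tc = rng.binomial(cov, rate)
                rows.append(
                    pd.DataFrame(
                        {
                            "utr_id": genes,
                            "time_h": t,
                            "condition": cond,
                            "replicate": rep,
                            "t_coverage": cov,
                            "tc_count": tc,
                        }
                    )
                )
    conversions = pd.concat(rows, ignore_index=True)

    un_rows = []
    for rep in range(1, config.n_unlabeled_replicates + 1):
        cov = _nb_draw(rng, np.full(len(genes), cov_mean), cov_disp)
        cov = np.maximum(cov, 1)
        tc = rng.binomial(cov, bg)
        un_rows.append(
            pd.DataFrame(
                {
                    "utr_id": genes,
                    "time_h": 0.0,
                    "condition": "unlabeled",
                    "replicate": rep,
                    "t_coverage": cov,
                    "tc_count": tc,
                }
            )
        )
    unlabeled = pd.concat(un_rows, ignore_index=True)
    return conversions, unlabeled


# ---------------------------------------------------------------------------
# Stage 5: treatment count matrices
# ---------------------------------------------------------------------------

def gen_treatment_counts(
    truth: pd.DataFrame, config: SynthConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Paired control/depleted NB count matrices with spike-in rows.

    Depleted-condition expected counts are multiplied by
    2**(beta * min(m6A count, cap)) for autosomal genes (optionally X as
    well); spike-ins are untouched. Per-sample library factors are drawn
    lognormally, so normalization is genuinely needed downstream.
    """
    ids = truth.index
    mean = truth["mean_counts"].to_numpy(dtype=float)
    burden = np.minimum(truth["n_m6a_true"].to_numpy(), config.treatment_site_cap)
    affected = truth["chrom_class"].eq("autosome").to_numpy()
    if config.treatment_affects_x:
        affected |= truth["chrom_class"].eq("X").to_numpy()
    log2fc = np.where(affected, config.beta_treatment * burden, 0.0)
    truth["true_log2fc"] = log2fc

    is_spike = truth["is_spikein"].to_numpy()
    disp = np.where(is_spike, config.spikein_dispersion, config.nb_dispersion)
    samples = {}
    conditions = {}
    for cond, factor in (("control", np.ones(len(ids))), ("depleted", 2.0 ** log2fc)):
        for rep in range(1, config.n_count_replicates + 1):
            lib = rng.lognormal(0.0, 0.1)
            name = f"{cond}_{rep}"
            mu_s = mean * factor * lib
            col = np.empty(len(ids), dtype=int)
            for d in np.unique(disp):
                m = disp == d
                col[m] = _nb_draw(rng, mu_s[m], float(d))
            samples[name] = col
            conditions[name] = cond
    counts = pd.DataFrame(samples, index=ids)
    return counts, conditions


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def simulate(config: SynthConfig, outdir: str | None = None) -> SyntheticDataset:
    """Run every generator stage under a single seed stream."""
    transcripts, genome, truth, motifs = gen_transcriptome(config)
    rng = np.random.default_rng(config.seed + 1)
    tpm, rpkm = gen_expression(truth, config, rng)
    sites = gen_m6a_sites(transcripts, truth, motifs, config, rng)
    conversions, unlabeled = gen_slam_profiles(truth, config, rng)
    counts, conditions = gen_treatment_counts(truth, config, rng)
    ds = SyntheticDataset(
        config=config,
        transcripts=transcripts,
        genome=genome,
        truth=truth,
        motifs=motifs,
        tpm=tpm,
        rpkm=rpkm,
        sites=sites,
        conversions=conversions,
        unlabeled=unlabeled,
        counts=counts,
        sample_conditions=conditions,
    )
    if outdir is not None:
        ds.write(outdir)
    return ds
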