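"""Expression-binned m6A site quantification and chromosome contrasts.

Transcripts are stratified into 12 expression bins on replicate-averaged
log10(TPM): transcripts with TPM <= 1 are unassigned, bin 1 collects
log10(TPM) in (0, 0.5), bins 2-11 are consecutive width-0.25 intervals over
[0.5, 3.0), and bin 12 collects everything >= 3. Detected sites per
transcript are then compared across chromosomes within bins, which controls
for the expression dependence of site detection in miCLIP-style data.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.discrete.discrete_model import NegativeBinomial

from .annotation import TranscriptModel, chromosome_class

N_BINS = 12


def expression_bin(tpm: np.ndarray | float) -> np.ndarray:
    """Bin index (1..12) per TPM value; 0 marks unassigned (TPM <= 1)."""
    tpm = np.asarray(tpm, dtype=float)
    out = np.zeros(tpm.shape, dtype=int)
    pos = tpm > 1.0
    log = np.full(tpm.shape, -np.inf)
    log[pos] = np.log10(tpm[pos])
    out[pos & (log < 0.5)] = 1
    out[pos & (log >= 3.0)] = N_BINS
    mid = pos & (log >= 0.5) & (log < 3.0)
    out[mid] = 2 + np.floor((log[mid] - 0.5) / 0.25).astype(int)
    return out


def assign_bins(
    tpm_table: pd.DataFrame, replicate_cols: Sequence[str] | None = None
) -> pd.DataFrame:
    """Replicate-averaged TPM -> expression bin per transcript.

    ``tpm_table`` is indexed by gene/transcript id; ``replicate_cols``
    defaults to all numeric columns.
    """
    cols = list(replicate_cols) if replicate_cols is not None else list(tpm_table.columns)
    mean_tpm = tpm_table[cols].mean(axis=1)
    bins = expression_bin(mean_tpm.to_numpy())
    return pd.DataFrame(
        {"tpm_mean": mean_tpm, "bin": bins}, index=tpm_table.index
    )


def count_sites_per_transcript(
    sites: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    region_filter: str | None = None,
    stop_window: tuple[int, int] = (-50, 150),
) -> tuple[pd.Series, dict]:
    """Detected m6A sites per transcript.

    With ``region_filter='stop_window'`` only sites whose spliced-transcript
    offset from the first base of the stop codon lies inside the inclusive
    window are counted (default -50..+150, i.e. 201 positions). Sites on
    genes absent from the annotation land in the orphan ledger.
    """
    if region_filter not in (None, "stop_window"):
        raise ValueError(f"unknown region filter {region_filter!r}")
    by_gene = {t.gene_id: t for t in transcripts}
    counts = pd.Series(0, index=pd.Index(sorted(by_gene), name="gene_id"), dtype=int)
    ledger = {"orphans": 0, "outside_window": 0, "non_exonic": 0}
    for row in sites.itertuples(index=False):
        t = by_gene.get(row.gene_id)
        if t is None:
            ledger["orphans"] += 1
            continue
        if region_filter == "stop_window":
            tx = t.genomic_to_transcript(row.pos)
            if tx is None:
                ledger["non_exonic"] += 1
                continue
            stop = t.stop_codon_offset
            if stop is None:
                ledger["outside_window"] += 1
                continue
            off = tx - stop
            if not (stop_window[0] <= off <= stop_window[1]):
                ledger["outside_window"] += 1
                continue
        counts[row.gene_id] += 1
    return counts, ledger


def bin_profile(
    counts: pd.Series,
    bins: pd.Series,
    chrom_map: pd.Series | None = None,
    z: float = 1.959963984540054,
) -> pd.DataFrame:
    """Mean sites/transcript with a normal-approximation 95% CI per bin.

    With ``chrom_map`` given, profiles are additionally computed per
    chromosome. Bins with fewer than two transcripts report no CI; empty
    bins are omitted.
    """
    df = pd.DataFrame({"count": counts, "bin": bins})
    df = df[df["bin"] > 0]
    groups = [("all", df)]
    if chrom_map is not None:
        df = df.join(chrom_map.rename("chrom"))
        groups += [(c, g) for c, g in df.groupby("chrom")]
    rows = []
    for label, g in groups:
        for b, gb in g.groupby("bin"):
            n = len(gb)
            mean = gb["count"].mean()
            if n >= 2:
                sem = gb["count"].std(ddof=1) / np.sqrt(n)
                lo, hi = mean - z * sem, mean + z * sem
            else:
                lo = hi = np.nan
            rows.append(
                {"group": label, "bin": b, "n": n, "mean": mean, "ci_low": lo, "ci_high": hi}
            )
    return pd.DataFrame(rows)


def _nb_class_test(counts: np.ndarray, bins: np.ndarray, is_x: np.ndarray) -> float:
    """Two-tailed Wald p for the X-class coefficient in a negative-binomial
    model with bin as a categorical covariate (dispersion fit by ML)."""
    bin_dummies = pd.get_dummies(pd.Categorical(bins), drop_first=True, dtype=float)
    exog = sm.add_constant(
        pd.concat([bin_dummies, pd.Series(is_x.astype(float), name="is_x",
                                          index=bin_dummies.index)], axis=1)
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = NegativeBinomial(counts, exog).fit(disp=0, maxiter=200)
            return float(res.pvalues["is_x"])
        except Exception:
            # fall back to Poisson GLM if the NB dispersion fit degenerates
            res = sm.GLM(counts, exog, family=sm.families.Poisson()).fit()
            return float(res.pvalues["is_x"])


def chrom_fold_change(
    counts: pd.Series,
    bins: pd.Series,
    chrom_map: pd.Series,
    bin_range: tuple[int, int] = (3, 8),
    x_aliases: tuple[str, ...] = ("X", "chrX"),
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> dict:
    """Per-chromosome m6A fold change relative to all chromosomes.

    Within each used expression bin, FC = (mean sites on the chromosome) /
    (mean sites on all chromosomes); the per-chromosome summary is the mean
    over used bins of log2(FC). Bootstrap CIs resample transcripts within
    each (chromosome, bin) stratum. A negative-binomial Wald test contrasts
    the X class against autosomes with bin as covariate.
    """
    lo, hi = bin_range
    df = pd.DataFrame({"count": counts, "bin": bins}).join(chrom_map.rename("chrom"))
    df = df[(df["bin"] >= lo) & (df["bin"] <= hi)].dropna(subset=["chrom"])
    rng = np.random.default_rng(seed)

    used_bins = sorted(df["bin"].unique())
    chroms = sorted(df["chrom"].unique())
    # point estimates and stratified bootstrap of per-stratum means
    strata: dict[tuple[str, int], np.ndarray] = {}
    boot_means: dict[tuple[str, int], np.ndarray] = {}
    for (c, b), g in df.groupby(["chrom", "bin"]):
        vals = g["count"].to_numpy(dtype=float)
        strata[(c, b)] = vals
        idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
        boot_means[(c, b)] = vals[idx].mean(axis=1)

    skipped = []
    per_bin_rows = []
    summaries = {}
    boot_summaries = {}
    for c in chroms:
        logs = []
        boot_logs = []
        for b in used_bins:
            if (c, b) not in strata:
                skipped.append((c, b))
                continue
            all_n = sum(len(strata[(cc, b)]) for cc in chroms if (cc, b) in strata)
            all_mean = (
                sum(strata[(cc, b)].sum() for cc in chroms if (cc, b) in strata) / all_n
            )
            m = strata[(c, b)].mean()
            fc = m / all_mean if all_mean > 0 else np.nan
            per_bin_rows.append(
                {"chrom": c, "bin": b, "n": len(strata[(c, b)]), "mean": m,
                 "all_mean": all_mean, "fc": fc}
            )
            if np.isfinite(fc) and fc > 0:
                logs.append(np.log2(fc))
                boot_all = (
                    sum(
                        boot_means[(cc, b)] * len(strata[(cc, b)])
                        for cc in chroms
                        if (cc, b) in strata
                    )
                    / all_n
                )
                with np.errstate(divide="ignore", invalid="ignore"):
                    boot_logs.append(np.log2(boot_means[(c, b)] / boot_all))
        summaries[c] = float(np.mean(logs)) if logs else np.nan
        if boot_logs:
            arr = np.vstack(boot_logs)
            arr = np.where(np.isfinite(arr), arr, np.nan)
            boot_summaries[c] = np.nanmean(arr, axis=0)

    alpha = (1.0 - ci) / 2
    summary_rows = []
    for c in chroms:
        row = {
            "chrom": c,
            "chrom_class": chromosome_class(c, x_aliases),
            "summary_log2fc": summaries[c],
        }
        if c in boot_summaries:
            bs = boot_summaries[c]
            row["ci_low"] = float(np.nanquantile(bs, alpha))
            row["ci_high"] = float(np.nanquantile(bs, 1 - alpha))
        else:
            row["ci_low"] = row["ci_high"] = np.nan
        summary_rows.append(row)

    is_x = df["chrom"].isin(x_aliases).to_numpy()
    p_class = _nb_class_test(
        df["count"].to_numpy(), df["bin"].to_numpy(), is_x
    )
    return {
        "per_bin": pd.DataFrame(per_bin_rows),
        "summary": pd.DataFrame(summary_rows),
        "skipped_strata": skipped,
        "p_class_nb_wald": p_class,
        "bin_range": bin_range,
    }


def subsample_fold_change(
    counts: pd.Series,
    bins: pd.Series,
    chrom_map: pd.Series,
    n_per_bin: int = 30,
    bin_range: tuple[int, int] = (3, 5),
    reps: int = 100,
    seed: int = 0,
) -> dict:
    """Fold-change distribution under repeated per-bin subsampling.

    For each repetition, up to ``n_per_bin`` transcripts are drawn without
    replacement per (chromosome, bin) stratum; strata with fewer transcripts
    contribute all of them and are flagged. Summaries as in
    :func:`chrom_fold_change` (without its bootstrap).
    """
    lo, hi = bin_range
    df = pd.DataFrame({"count": counts, "bin": bins}).join(chrom_map.rename("chrom"))
    df = df[(df["bin"] >= lo) & (df["bin"] <= hi)].dropna(subset=["chrom"])
    rng = np.random.default_rng(seed)
    strata = {k: g["count"].to_numpy(dtype=float) for k, g in df.groupby(["chrom", "bin"])}
    short = sorted(k for k, v in strata.items() if len(v) < n_per_bin)
    chroms = sorted(df["chrom"].unique())
    used_bins = sorted(df["bin"].unique())

    all_summaries = {c: [] for c in chroms}
    for _ in range(reps):
        sampled = {}
        for k, vals in strata.items():
            take = min(n_per_bin, len(vals))
            sampled[k] = vals[rng.choice(len(vals), size=take, replace=False)]
        for c in chroms:
            logs = []
            for b in used_bins:
                if (c, b) not in sampled:
                    continue
                pooled = np.concatenate(
                    [sampled[(cc, b)] for cc in chroms if (cc, b) in sampled]
                )
                all_mean = pooled.mean()
                m = sampled[(c, b)].mean()
                if all_mean > 0 and m > 0:
                    logs.append(np.log2(m / all_mean))
            if logs:
                all_summaries[c].append(float(np.mean(logs)))
    rows = []
    for c in chroms:
        vals = np.array(all_summaries[c])
        rows.append(
            {
                "chrom": c,
                "median": float(np.median(vals)) if len(vals) else np.nan,
                "iqr_low": float(np.quantile(vals, 0.25)) if len(vals) else np.nan,
                "iqr_high": float(np.quantile(vals, 0.75)) if len(vals) else np.nan,
                "n_reps": len(vals),
            }
        )
    return {"distribution": pd.DataFrame(rows), "short_strata": short}


def fraction_motifs_methylated(
    sites: pd.DataFrame,
    motif_positions: pd.DataFrame,
    expressed_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Fraction of motif positions overlapped by a detected site, per
    chromosome, over expressed transcripts.

    Both inputs carry genomic coordinates of the methylatable base
    (columns chrom/pos/strand/gene_id). Chromosomes without motifs are
    flagged undefined.
    """
    motifs = motif_positions
    if expressed_genes is not None:
        motifs = motifs[motifs["gene_id"].isin(expressed_genes)]
        sites = sites[sites["gene_id"].isin(expressed_genes)]
    site_keys = set(zip(sites["chrom"], sites["pos"], sites["strand"]))
    rows = []
    for chrom, g in motifs.groupby("chrom"):
        total = len(g)
        hit = sum(
            (c, p, s) in site_keys
            for c, p, s in zip(g["chrom"], g["pos"], g["strand"])
        )
        rows.append(
            {
                "chrom": chrom,
                "n_motifs": total,
                "n_methylated": hit,
                "fraction": hit / total if total else np.nan,
                "undefined": total == 0,
            }
        )
    return pd.DataFrame(rows)


def peak_density_ratio(
    peak_counts: Mapping[str, int] | pd.Series,
    chromosome_lengths: Mapping[str, int],
) -> pd.Series:
    """Length-normalized peak count per chromosome over the chromosome-median
    length-normalized count."""
    counts = pd.Series(peak_counts, dtype=float)
    lengths = pd.Series(chromosome_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("chromosome lengths must be positive")
    counts = counts.reindex(lengths.index, fill_value=0.0)
    dens = counts / lengths
    return dens / dens.median()
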