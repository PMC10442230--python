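"""Expression response to m6A depletion, stratified by chromosome.

Normalization uses DESeq-style median-of-ratios size factors computed on a
reference set of expressed genes without detected m6A sites (the in-silico
counterpart of spike-in normalization, which total-count normalization
cannot replace when most genes respond to the treatment). Chromosome-level
summaries are medians of per-gene log2 fold changes; the effect size is the
shift in group medians expressed as a percentage of the average
interquartile range of the two groups; the X:A ratio is the ratio of group
median expression with a paired gene-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def pick_reference_genes(
    site_counts: pd.Series,
    rpkm: pd.Series,
    n: int = 100,
    min_rpkm: float = 10.0,
    seed: int = 0,
    exclude: Sequence[str] = (),
) -> list[str]:
    """Seeded sample of ``n`` genes with zero m6A sites and RPKM above the
    floor. Raises with the shortfall if fewer are eligible."""
    universe = rpkm.index
    sites = site_counts.reindex(universe).fillna(0)
    eligible = universe[(sites == 0) & (rpkm > min_rpkm)]
    eligible = eligible.difference(pd.Index(exclude))
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} genes eligible as reference "
            f"(zero m6A sites, RPKM > {min_rpkm}); need {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.sort(eligible.to_numpy()), size=n, replace=False)
    return sorted(chosen)


def size_factors(counts: pd.DataFrame, reference_genes: Sequence[str]) -> pd.Series:
    """Median-of-ratios size factor per sample, restricted to the reference
    gene set (genes with a zero geometric mean are dropped)."""
    sub = counts.loc[counts.index.intersection(pd.Index(reference_genes))]
    log_counts = np.log(sub.where(sub > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = log_geomean.notna()
    if not usable.any():
        raise ValueError("no reference gene with nonzero counts in all samples")
    ratios = log_counts.loc[usable].sub(log_geomean.loc[usable], axis=0)
    factors = np.exp(ratios.median(axis=0))
    if factors.isna().any():
        bad = factors.index[factors.isna()].tolist()
        raise ValueError(f"all reference genes zero in sample(s) {bad}")
    return factors


def gene_log2fc(
    counts: pd.DataFrame,
    samples_ctrl: Sequence[str],
    samples_trt: Sequence[str],
    factors: pd.Series,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene log2 fold change of normalized mean counts (treated over
    control) with a pseudocount."""
    norm = counts / factors
    mean_ctrl = norm[list(samples_ctrl)].mean(axis=1)
    mean_trt = norm[list(samples_trt)].mean(axis=1)
    log2fc = np.log2((mean_trt + pseudocount) / (mean_ctrl + pseudocount))
    return pd.DataFrame(
        {"mean_ctrl": mean_ctrl, "mean_trt": mean_trt, "log2fc": log2fc}
    )


@dataclass
class DosageSummary:
    per_chrom_medians: pd.Series
    median_autosome: float
    median_x: float
    effect_size_pct: float
    p_ranksum: float
    curves: dict = field(default_factory=dict)
    n_used: int = 0
    n_dropped_unmapped: int = 0
    n_dropped_low_expression: int = 0


def effect_size_pct(a: np.ndarray, b: np.ndarray) -> float:
    """Median shift of ``a`` over ``b`` as percent of the average IQR.

    Antisymmetric under swapping the groups; zero iff the medians agree.
    """
    iqr_a = float(np.subtract(*np.percentile(a, [75, 25])))
    iqr_b = float(np.subtract(*np.percentile(b, [75, 25])))
    denom = (iqr_a + iqr_b) / 2.0
    if denom == 0:
        return 0.0 if np.median(a) == np.median(b) else math_inf_sign(a, b)
    return 100.0 * float(np.median(a) - np.median(b)) / denom


def math_inf_sign(a, b) -> float:
    return float(np.sign(np.median(a) - np.median(b)) * np.inf)


def chromosome_response(
    log2fc: pd.Series,
    chromosome_map: pd.Series,
    rpkm: pd.Series | None = None,
    min_rpkm: float = 1.0,
    x_aliases: tuple[str, ...] = ("X", "chrX"),
) -> DosageSummary:
    """Per-chromosome fold-change summaries and the X-vs-autosome contrast.

    Genes below the RPKM floor or without a chromosome label are dropped
    (counted). Curves hold the sorted per-chromosome log2FC values, i.e.
    the empirical cumulative distributions.
    """
    df = pd.DataFrame({"log2fc": log2fc}).join(chromosome_map.rename("chrom"))
    n_unmapped = int(df["chrom"].isna().sum())
    df = df.dropna(subset=["chrom"])
    n_low = 0
    if rpkm is not None:
        keep = df.index.isin(rpkm.index[rpkm > min_rpkm])
        n_low = int((~keep).sum())
        df = df[keep]
    df["chrom_class"] = np.where(df["chrom"].isin(x_aliases), "X", "autosome")
    a = df.loc[df["chrom_class"] == "autosome", "log2fc"].to_numpy()
    x = df.loc[df["chrom_class"] == "X", "log2fc"].to_numpy()
    if len(a) < 2 or len(x) < 2:
        raise ValueError("need at least two genes in each compared group")
    p = float(stats.mannwhitneyu(x, a, alternative="two-sided").pvalue)
    return DosageSummary(
        per_chrom_medians=df.groupby("chrom")["log2fc"].median(),
        median_autosome=float(np.median(a)),
        median_x=float(np.median(x)),
        effect_size_pct=effect_size_pct(a, x),
        p_ranksum=p,
        curves={c: np.sort(g["log2fc"].to_numpy()) for c, g in df.groupby("chrom")},
        n_used=len(df),
        n_dropped_unmapped=n_unmapped,
        n_dropped_low_expression=n_low,
    )


def xa_expression_ratio(
    expression: Mapping[str, pd.Series] | pd.DataFrame,
    chromosome_map: pd.Series,
    min_expr: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    x_aliases: tuple[str, ...] = ("X", "chrX"),
    baseline_condition: str | None = None,
) -> dict:
    """X:A expression ratio per condition with a paired gene bootstrap.

    rho = median(X-gene expression) / median(autosomal-gene expression).
    The expression floor is applied in the baseline condition (first column
    by default) so all conditions share one gene set; the bootstrap
    resamples genes within each chromosome group, using the same resample
    across conditions so between-condition differences are paired. The
    between-condition test is a two-sided bootstrap test on
    delta = rho_other - rho_baseline.
    """
    expr = pd.DataFrame(expression)
    conditions = list(expr.columns)
    base = baseline_condition or conditions[0]
    is_x = chromosome_map.reindex(expr.index).isin(x_aliases)
    mapped = chromosome_map.reindex(expr.index).notna()
    keep = mapped & (expr[base] > min_expr)
    expr = expr[keep]
    is_x = is_x[keep]
    xs = expr[is_x.to_numpy()]
    auto = expr[~is_x.to_numpy()]
    if len(xs) == 0 or len(auto) == 0:
        return {"rho": {}, "ci": {}, "flag": "empty_group"}

    rng = np.random.default_rng(seed)
    ix = rng.integers(0, len(xs), size=(n_boot, len(xs)))
    ia = rng.integers(0, len(auto), size=(n_boot, len(auto)))

    rho = {}
    ci = {}
    boots = {}
    for cond in conditions:
        xv = xs[cond].to_numpy()
        av = auto[cond].to_numpy()
        rho[cond] = float(np.median(xv) / np.median(av))
        b = np.median(xv[ix], axis=1) / np.median(av[ia], axis=1)
        boots[cond] = b
        ci[cond] = (float(np.quantile(b, 0.025)), float(np.quantile(b, 0.975)))

    out = {
        "rho": rho,
        "ci": ci,
        "n_x": len(xs),
        "n_autosome": len(auto),
        "baseline": base,
        "delta": {},
        "p_delta": {},
        "flag": "",
    }
    for cond in conditions:
        if cond == base:
            continue
        delta = rho[cond] - rho[base]
        bd = boots[cond] - boots[base]
        p_low = (np.sum(bd >= 0) + 1) / (n_boot + 1)
        p_high = (np.sum(bd <= 0) + 1) / (n_boot + 1)
        out["delta"][cond] = float(delta)
        out["p_delta"][cond] = float(min(1.0, 2.0 * min(p_low, p_high)))
    return out


def fc_vs_m6a_burden(
    log2fc: pd.Series,
    m6a_counts: pd.Series,
    burden_bins: Sequence[int] = (0, 1, 2, 3),
) -> pd.DataFrame:
    """Median log2FC per m6A-burden bin ({0, 1, 2, >=3} by default)."""
    counts = m6a_counts.reindex(log2fc.index).fillna(0).astype(int)
    edges = list(burden_bins)
    labels = [str(e) for e in edges[:-1]] + [f">={edges[-1]}"]
    idx = np.clip(
        np.searchsorted(edges, counts.to_numpy(), side="right") - 1, 0, len(edges) - 1
    )
    df = pd.DataFrame({"log2fc": log2fc, "burden": [labels[i] for i in idx]})
    rows = []
    for lab in labels:
        g = df[df["burden"] == lab]
        rows.append(
            {
                "burden": lab,
                "n": len(g),
                "median_log2fc": float(g["log2fc"].median()) if len(g) else np.nan,
                "empty": len(g) == 0,
            }
        )
    return pd.DataFrame(rows)


def timecourse_response(
    log2fc_by_time: Mapping[float, pd.Series],
    chromosome_map: pd.Series,
    x_aliases: tuple[str, ...] = ("X", "chrX"),
) -> dict:
    """Per-chromosome median fold-change trajectory over treatment time.

    Reports the earliest time point at which the X median lies outside the
    autosomal min-max band of per-chromosome medians. Time points where a
    chromosome is missing are flagged, not silently dropped.
    """
    if len(log2fc_by_time) < 2:
        raise ValueError("need at least two time points")
    rows = []
    flags = []
    first_sep = None
    for t in sorted(log2fc_by_time):
        fc = log2fc_by_time[t]
        df = pd.DataFrame({"log2fc": fc}).join(chromosome_map.rename("chrom")).dropna()
        med = df.groupby("chrom")["log2fc"].median()
        expected = set(chromosome_map.unique())
        missing = expected - set(med.index)
        if missing:
            flags.append({"time_h": t, "missing_chromosomes": sorted(missing)})
        x_meds = med[med.index.isin(x_aliases)]
        a_meds = med[~med.index.isin(x_aliases)]
        x_med = float(x_meds.iloc[0]) if len(x_meds) else np.nan
        lo = float(a_meds.min()) if len(a_meds) else np.nan
        hi = float(a_meds.max()) if len(a_meds) else np.nan
        separated = bool(np.isfinite(x_med) and (x_med < lo or x_med > hi))
        if separated and first_sep is None:
            first_sep = t
        rows.append(
            {
                "time_h": t,
                "x_median": x_med,
                "autosome_min": lo,
                "autosome_max": hi,
                "autosome_median": float(a_meds.median()) if len(a_meds) else np.nan,
                "separated": separated,
            }
        )
    return {
        "trajectory": pd.DataFrame(rows),
        "first_separation_time_h": first_sep,
        "flags": flags,
    }
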