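"""mRNA half-life estimation from T-to-C conversion-rate time courses.

The conversion rate of a 3'UTR after the chase onset follows first-order
decay: rate(t) = background + (r0 - background) * 2**(-t / t_half). After
subtracting the unlabeled background and normalizing to the chase-onset
time point (T0), the log of the normalized rate is linear in time with zero
intercept, so the decay constant is fit by least squares through the
origin; t_half = ln(2) / k. The residual standard error of that log-scale
fit is the goodness-of-fit statistic the filters act on.

Filters follow the standard SLAM-seq acceptance window: minimum T coverage
above 100, half-lives inside [0.67, 18] h, residual s.e. at most 0.3, and
(optionally) a valid fit in every condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2 = math.log(2.0)

FILTER_REASONS = ("low_coverage", "t_half_low", "t_half_high", "poor_fit")


def incorporation_rate(
    profiles: pd.DataFrame, group_keys: list[str] | None = None
) -> pd.DataFrame:
    """Pooled conversion rate per group: sum(tc_count) / sum(t_coverage).

    Groups with zero total coverage get NaN and the ``undefined`` flag.
    """
    if group_keys:
        g = profiles.groupby(group_keys, as_index=False)[["tc_count", "t_coverage"]].sum()
    else:
        g = profiles[["tc_count", "t_coverage"]].sum().to_frame().T
    cov = g["t_coverage"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(cov > 0, g["tc_count"].to_numpy(dtype=float) / cov, np.nan)
    g["rate"] = rate
    g["undefined"] = cov <= 0
    return g


def correct_and_normalize(
    labeled: pd.DataFrame,
    unlabeled: pd.DataFrame | None = None,
    background: float | pd.Series | None = None,
    floor: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Background-subtract and T0-normalize conversion-rate series.

    Replicates are pooled (coverage-weighted) per utr x condition x time.
    The background is the pooled unlabeled rate per UTR (or a scalar /
    per-UTR Series); excess rates are floored at ``floor`` before the log
    fit downstream. Series whose chase-onset excess is non-positive are
    excluded with a reason.

    Returns (normalized series, exclusions).
    """
    pooled = incorporation_rate(labeled, ["utr_id", "condition", "time_h"])
    if background is None:
        if unlabeled is None:
            raise ValueError("need either an unlabeled table or a background rate")
        bg_tab = incorporation_rate(unlabeled, ["utr_id"]).set_index("utr_id")["rate"]
        bg = pooled["utr_id"].map(bg_tab).fillna(bg_tab.mean())
    elif isinstance(background, pd.Series):
        bg = pooled["utr_id"].map(background)
    else:
        bg = pd.Series(float(background), index=pooled.index)
    raw_excess = pooled["rate"] - bg.to_numpy()
    pooled = pooled.assign(
        excess=np.maximum(raw_excess, floor), floored=raw_excess <= floor
    )

    t0 = pooled.groupby(["utr_id", "condition"])["time_h"].transform("min")
    is_t0 = pooled["time_h"] == t0
    t0_excess = (
        pooled[is_t0]
        .set_index(["utr_id", "condition"])["excess"]
        .rename("t0_excess")
    )
    pooled = pooled.join(t0_excess, on=["utr_id", "condition"])

    bad_t0 = pooled["t0_excess"] <= floor
    excluded_keys = pooled.loc[bad_t0, ["utr_id", "condition"]].drop_duplicates()
    excluded_keys["reason"] = "nonpositive_t0"
    keep = ~pooled.set_index(["utr_id", "condition"]).index.isin(
        excluded_keys.set_index(["utr_id", "condition"]).index
    )
    out = pooled.loc[keep].copy()
    out["norm_value"] = out["excess"] / out["t0_excess"]
    # floored points carry no decay signal; flag them so the fit drops them
    out.loc[out["floored"], "norm_value"] = 0.0
    cols = [
        "utr_id", "condition", "time_h", "t_coverage", "rate", "excess",
        "norm_value", "floored",
    ]
    return out[cols].reset_index(drop=True), excluded_keys.reset_index(drop=True)


def fit_decay(
    times: np.ndarray,
    values: np.ndarray,
    floor: float = 1e-6,
    min_points: int = 3,
) -> dict:
    """Least-squares exponential-decay fit on the log scale.

    The t=0 value is 1 by construction, so the log-linear fit is through
    the origin: slope = sum(t * log v) / sum(t^2), k = -slope. Values at or
    below the floor are dropped (counted) before taking logs. The residual
    standard error uses n - 1 degrees of freedom (one fitted parameter).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = values > floor
    n_dropped = int((~ok).sum())
    t, v = times[ok], values[ok]
    n = len(t)
    if n < min_points:
        return {
            "k": np.nan, "t_half": np.nan, "residual_se": np.nan,
            "n_timepoints": n, "n_dropped": n_dropped, "fit_ok": False,
        }
    logv = np.log(v)
    denom = float(np.sum(t * t))
    slope = float(np.sum(t * logv) / denom) if denom > 0 else np.nan
    k = -slope
    resid = logv - slope * t
    rss = float(np.sum(resid**2))
    residual_se = math.sqrt(rss / (n - 1)) if n > 1 else np.nan
    t_half = LOG2 / k if k > 0 else math.inf
    return {
        "k": k, "t_half": t_half, "residual_se": residual_se,
        "n_timepoints": n, "n_dropped": n_dropped, "fit_ok": np.isfinite(k),
    }


def fit_all(normalized: pd.DataFrame, floor: float = 1e-6) -> pd.DataFrame:
    """Fit every utr x condition series of a normalized table.

    ``t_coverage_min`` records the minimum pooled T coverage over the
    series' time points, feeding the coverage filter.
    """
    rows = []
    for (utr, cond), g in normalized.groupby(["utr_id", "condition"]):
        g = g.sort_values("time_h")
        fit = fit_decay(g["time_h"].to_numpy(), g["norm_value"].to_numpy(), floor=floor)
        fit["utr_id"] = utr
        fit["condition"] = cond
        fit["t_coverage_min"] = int(g["t_coverage"].min())
        rows.append(fit)
    cols = [
        "utr_id", "condition", "k", "t_half", "residual_se",
        "n_timepoints", "n_dropped", "t_coverage_min", "fit_ok",
    ]
    return pd.DataFrame(rows)[cols]


def filter_fits(
    fits: pd.DataFrame,
    min_t_cov: int = 100,
    bounds: tuple[float, float] = (0.67, 18.0),
    max_rse: float = 0.3,
    require_both_conditions: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Apply the half-life acceptance filters and build a rejection ledger.

    Verdict reasons (first failing check wins): low_coverage
    (T coverage <= min), t_half_low / t_half_high (outside bounds), poor_fit
    (unfittable series or residual s.e. above max). With
    ``require_both_conditions`` a transcript survives only if it passes in
    every condition present in the input.
    """
    fits = fits.copy()
    lo, hi = bounds

    def _verdict(row) -> str:
        if row.t_coverage_min <= min_t_cov:
            return "low_coverage"
        if not row.fit_ok or not np.isfinite(row.residual_se):
            return "poor_fit"
        if row.t_half < lo:
            return "t_half_low"
        if row.t_half > hi:
            return "t_half_high"
        if row.residual_se > max_rse:
            return "poor_fit"
        return "pass"

    fits["reason"] = [_verdict(r) for r in fits.itertuples(index=False)]
    fits["verdict"] = np.where(fits["reason"] == "pass", "pass", "fail")

    ledger = {r: int((fits["reason"] == r).sum()) for r in FILTER_REASONS}
    ledger["pass"] = int((fits["verdict"] == "pass").sum())
    ledger["input"] = len(fits)

    kept = fits[fits["verdict"] == "pass"].copy()
    if require_both_conditions:
        n_cond = fits["condition"].nunique()
        ok_counts = kept.groupby("utr_id")["condition"].nunique()
        full = set(ok_counts[ok_counts == n_cond].index)
        ledger["dropped_missing_condition"] = int(
            (~kept["utr_id"].isin(full)).sum()
        )
        kept = kept[kept["utr_id"].isin(full)]
    ledger["kept"] = len(kept)
    return kept.reset_index(drop=True), ledger


# ---------------------------------------------------------------------------
# Condition / chromosome contrasts
# ---------------------------------------------------------------------------

def _median_pct_change(log2fc: np.ndarray) -> float:
    return float((2.0 ** np.median(log2fc) - 1.0) * 100.0)


def halflife_contrast(
    fits_ctrl: pd.DataFrame,
    fits_trt: pd.DataFrame,
    m6a_counts: pd.Series,
    chromosome_map: pd.Series,
    x_aliases: tuple[str, ...] = ("X", "chrX"),
) -> dict:
    """Treated-vs-control half-life contrasts by methylation and chromosome.

    Computes per-transcript log2(t_half_trt / t_half_ctrl); group medians
    and median percent changes for methylated vs unmethylated and autosome
    vs X; per-chromosome medians; paired signed-rank tests within groups; a
    rank-sum test and a mixed model (X-class fixed effect, per-chromosome
    random intercept) for the X-vs-autosome comparison. P values are BH
    adjusted across the reported family.
    """
    merged = fits_ctrl.merge(
        fits_trt, on="utr_id", suffixes=("_ctrl", "_trt")
    )
    merged["log2fc"] = np.log2(merged["t_half_trt"] / merged["t_half_ctrl"])
    merged["m6a"] = merged["utr_id"].map(m6a_counts).fillna(0).astype(int)
    merged["chrom"] = merged["utr_id"].map(chromosome_map)
    merged["chrom_class"] = np.where(
        merged["chrom"].isin(x_aliases), "X", "autosome"
    )

    def _group_summary(mask: np.ndarray, label: str) -> dict:
        g = merged[mask]
        if len(g) == 0:
            return {
                "group": label, "n": 0, "absent": True,
                "median_log2fc": np.nan, "median_pct_change": np.nan,
                "p_signed_rank": np.nan,
            }
        out = {
            "group": label,
            "n": len(g),
            "absent": False,
            "median_log2fc": float(g["log2fc"].median()),
            "median_pct_change": _median_pct_change(g["log2fc"].to_numpy()),
        }
        if len(g) >= 10 and (g["t_half_trt"] != g["t_half_ctrl"]).any():
            out["p_signed_rank"] = float(
                stats.wilcoxon(g["t_half_trt"], g["t_half_ctrl"]).pvalue
            )
        else:
            out["p_signed_rank"] = np.nan
        return out

    groups = [
        _group_summary((merged["m6a"] > 0).to_numpy(), "methylated"),
        _group_summary((merged["m6a"] == 0).to_numpy(), "unmethylated"),
        _group_summary((merged["chrom_class"] == "autosome").to_numpy(), "autosome"),
        _group_summary((merged["chrom_class"] == "X").to_numpy(), "X"),
    ]

    per_chrom = (
        merged.groupby("chrom")["log2fc"].median().rename("median_log2fc").reset_index()
    )

    x_fc = merged.loc[merged["chrom_class"] == "X", "log2fc"]
    a_fc = merged.loc[merged["chrom_class"] == "autosome", "log2fc"]
    p_ranksum = (
        float(stats.mannwhitneyu(x_fc, a_fc, alternative="two-sided").pvalue)
        if len(x_fc) and len(a_fc)
        else np.nan
    )

    p_mixed = np.nan
    mixed_effect = np.nan
    if len(x_fc) and len(a_fc) and merged["chrom"].nunique() >= 3:
        exog = sm.add_constant((merged["chrom_class"] == "X").astype(float).rename("is_x"))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.MixedLM(
                    merged["log2fc"], exog, groups=merged["chrom"]
                ).fit(reml=True)
            p_mixed = float(res.pvalues["is_x"])
            mixed_effect = float(res.params["is_x"])
        except Exception:
            pass

    family = [g["p_signed_rank"] for g in groups] + [p_ranksum, p_mixed]
    labels = [g["group"] + "_signed_rank" for g in groups] + [
        "x_vs_autosome_ranksum",
        "x_vs_autosome_mixed",
    ]
    ok = [i for i, p in enumerate(family) if np.isfinite(p)]
    adjusted = {}
    if ok:
        adj = multipletests([family[i] for i in ok], method="fdr_bh")[1]
        adjusted = {labels[i]: float(a) for i, a in zip(ok, adj)}

    return {
        "per_transcript": merged,
        "groups": pd.DataFrame(groups),
        "per_chromosome": per_chrom,
        "p_x_vs_autosome_ranksum": p_ranksum,
        "p_x_vs_autosome_mixed": p_mixed,
        "mixed_effect_log2fc": mixed_effect,
        "p_adjusted": adjusted,
    }
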