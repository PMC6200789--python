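"""Behavioral summary statistics for observer-actor trial tables.

Performance in each context is summarised by three quantities computed over
the discrete sample values i = 1..N with trial counts n_i:

    bias_i = mean(produced_i) - correct_i
    var_i  = sample variance of produced_i

    BIAS  = sqrt( sum_i n_i * bias_i^2 / sum_i n_i )
    sqrtVAR = sqrt( sum_i n_i * var_i  / sum_i n_i )
    RMSE  = sqrt( VAR + BIAS^2 )

Trial-count weighting handles the unbalanced per-sample counts that arise
from drawing samples uniformly with replacement.  The module also provides
the analysis pipeline around these statistics: lapse removal (responses
more than three raw median-absolute-deviations from the cell mean), removal
of a constant offset, basic bootstrap confidence intervals (n = 1000),
null-hypothesis predictions for a remapped context assuming no additional
transformation noise, excess bias, a d-prime screening statistic, and the
across-subject Wilcoxon signed-rank comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .priors import Transform

__all__ = [
    "SummaryStats",
    "BootstrapCI",
    "included",
    "filter_lapses",
    "remove_offset",
    "summarize",
    "bootstrap_ci",
    "predict_h0",
    "excess_bias",
    "d_prime",
    "signed_rank_test",
]


@dataclass(frozen=True)
class SummaryStats:
    """BIAS / sqrt(VAR) / RMSE for one context, with the per-sample table
    behind them.  Satisfies ``rmse**2 == bias**2 + sqrt_var**2``."""

    bias: float
    sqrt_var: float
    rmse: float
    per_sample: pd.DataFrame = field(repr=False)
    offset_removed: float = 0.0
    units: str = ""

    def scaled(self, g: float) -> "SummaryStats":
        """All three statistics scaled by a gain g (homogeneity of the
        sum-of-squares identity keeps it intact)."""
        if g <= 0:
            raise ValueError("gain must be strictly positive")
        per = self.per_sample.copy()
        per["bias_i"] = per["bias_i"] * g
        per["var_i"] = per["var_i"] * g * g
        return SummaryStats(
            bias=self.bias * g,
            sqrt_var=self.sqrt_var * g,
            rmse=self.rmse * g,
            per_sample=per,
            offset_removed=self.offset_removed,
            units=self.units,
        )


@dataclass(frozen=True)
class BootstrapCI:
    statistic: str
    point: float
    lower: float
    upper: float
    n_boot: int
    seed: object

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError("bootstrap CI has lower > upper")


def included(table: pd.DataFrame) -> pd.DataFrame:
    """Rows not tagged with any exclusion reason."""
    return table[table["excluded_reason"].isna()]


def _single_context(table: pd.DataFrame) -> str:
    ctx = table["context"].unique()
    if len(ctx) != 1:
        raise ValueError(f"expected a single-context table, got contexts {sorted(ctx)}")
    return str(ctx[0])


def filter_lapses(table: pd.DataFrame, min_cell: int = 4) -> tuple[pd.DataFrame, dict]:
    """Tag lapse trials: per (context, sample) cell, responses farther than
    three raw median absolute deviations from the cell mean.

    The MAD is the unscaled median of |produced - cell mean| (no normal
    consistency factor).  The inequality is strict, so a degenerate cell with
    identical responses (MAD = 0) removes nothing.  Cells with fewer than
    `min_cell` included trials are skipped with a warning.  Already-excluded
    trials (e.g. adaptation) are ignored.  Returns the tagged table and the
    per-context removal counts.
    """
    out = table.copy()
    counts: dict[str, int] = {}
    ok = out["excluded_reason"].isna()
    for (ctx, s), idx in out[ok].groupby(["context", "sample"]).groups.items():
        vals = out.loc[idx, "produced"].to_numpy(dtype=float)
        if len(vals) < min_cell:
            warnings.warn(
                f"cell (context={ctx!r}, sample={s}) has {len(vals)} trials (< {min_cell}); "
                "lapse filter skipped for this cell",
                stacklevel=2,
            )
            continue
        dev = np.abs(vals - vals.mean())
        mad = float(np.median(dev))
        lapse = dev > 3.0 * mad
        if lapse.any():
            out.loc[np.asarray(idx)[lapse], "excluded_reason"] = "lapse"
            counts[str(ctx)] = counts.get(str(ctx), 0) + int(lapse.sum())
    return out, counts


def remove_offset(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Subtract the constant offset (mean signed error over included trials)
    from every production; single-context tables only."""
    if len(table) == 0:
        raise ValueError("cannot remove an offset from an empty table")
    _single_context(table)
    inc = included(table)
    if len(inc) == 0:
        raise ValueError("no included trials to estimate an offset from")
    offset = float((inc["produced"] - inc["correct"]).mean())
    out = table.copy()
    out["produced"] = out["produced"] - offset
    return out, offset


def _weighted_stats(n_i: np.ndarray, bias_i: np.ndarray, var_i: np.ndarray) -> tuple[float, float, float]:
    w = n_i / n_i.sum()
    bias = float(np.sqrt(np.sum(w * bias_i**2)))
    var = float(np.sum(w * var_i))
    return bias, float(np.sqrt(var)), float(np.sqrt(var + bias**2))


def summarize(table: pd.DataFrame, offset_removed: float = 0.0) -> SummaryStats:
    """BIAS / sqrt(VAR) / RMSE over the included trials of one context.

    Expects the pipeline exclusions (adaptation, lapse) to be tagged and any
    offset already removed.  Errors if any sample cell has fewer than two
    trials (its variance is undefined).
    """
    _single_context(table)
    inc = included(table)
    if len(inc) == 0:
        raise ValueError("no included trials to summarize")
    grp = inc.groupby("sample")
    per = grp.agg(
        n_i=("produced", "size"),
        mean_produced=("produced", "mean"),
        correct=("correct", "first"),
        var_i=("produced", lambda v: v.var(ddof=1)),
    ).reset_index()
    if (per["n_i"] < 2).any():
        bad = per.loc[per["n_i"] < 2, "sample"].tolist()
        raise ValueError(f"sample cells with < 2 trials (variance undefined): {bad}")
    per["bias_i"] = per["mean_produced"] - per["correct"]
    bias, sqrt_var, rmse = _weighted_stats(
        per["n_i"].to_numpy(dtype=float),
        per["bias_i"].to_numpy(dtype=float),
        per["var_i"].to_numpy(dtype=float),
    )
    units = str(inc["units"].iloc[0]) if "units" in inc else ""
    return SummaryStats(
        bias=bias,
        sqrt_var=sqrt_var,
        rmse=rmse,
        per_sample=per[["sample", "n_i", "bias_i", "var_i", "correct"]],
        offset_removed=offset_removed,
        units=units,
    )


_STAT_NAMES = ("BIAS", "SQRT_VAR", "RMSE")


def bootstrap_ci(
    table: pd.DataFrame,
    statistic: str = "RMSE",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Basic (reflected) bootstrap confidence interval for one summary
    statistic, resampling trials with replacement *within* each sample cell
    (stratified, preserving the per-sample design).  Deterministic given
    `seed`."""
    statistic = statistic.upper()
    if statistic not in _STAT_NAMES:
        raise ValueError(f"statistic must be one of {_STAT_NAMES}")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small for a percentile-based interval", stacklevel=2)
    _single_context(table)
    inc = included(table)
    rng = np.random.default_rng(seed)

    cells = []
    for s, sub in inc.groupby("sample"):
        produced = sub["produced"].to_numpy(dtype=float)
        if len(produced) < 2:
            raise ValueError(f"sample cell {s} has < 2 trials")
        cells.append((len(produced), produced, float(sub["correct"].iloc[0])))

    n_boot = int(n_boot)
    boot_bias2 = np.zeros(n_boot)
    boot_var = np.zeros(n_boot)
    total_n = sum(c[0] for c in cells)
    point_stats = summarize(table)
    for n_i, produced, correct in cells:
        idx = rng.integers(0, n_i, size=(n_boot, n_i))
        res = produced[idx]
        m = res.mean(axis=1)
        v = res.var(axis=1, ddof=1)
        w = n_i / total_n
        boot_bias2 += w * (m - correct) ** 2
        boot_var += w * v
    if statistic == "BIAS":
        reps, point = np.sqrt(boot_bias2), point_stats.bias
    elif statistic == "SQRT_VAR":
        reps, point = np.sqrt(boot_var), point_stats.sqrt_var
    else:
        reps, point = np.sqrt(boot_var + boot_bias2), point_stats.rmse
    qlo, qhi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return BootstrapCI(
        statistic=statistic,
        point=point,
        lower=float(2.0 * point - qhi),
        upper=float(2.0 * point - qlo),
        n_boot=n_boot,
        seed=seed,
    )


def predict_h0(identity_stats: SummaryStats, transform: Transform) -> SummaryStats:
    """Remapped-context statistics predicted under the null hypothesis of no
    additional transformation noise.

    For a gain remapping with scalar variability, estimates and their noise
    scale with the gain, so BIAS, sqrt(VAR), and RMSE are each multiplied by
    the gain.  For an additive (rotation) remapping with additive noise,
    the prediction equals the identity-context statistics unchanged.
    """
    if transform.kind == "gain":
        return identity_stats.scaled(transform.value)
    return replace(identity_stats, per_sample=identity_stats.per_sample.copy())


def excess_bias(observed: SummaryStats, predicted: SummaryStats) -> dict:
    """Componentwise observed minus H0-predicted statistics; a positive
    bias excess is the late-inference signature."""
    if observed.units and predicted.units and observed.units != predicted.units:
        raise ValueError(f"unit mismatch: {observed.units!r} vs {predicted.units!r}")
    return {
        "excess_bias": observed.bias - predicted.bias,
        "excess_sqrt_var": observed.sqrt_var - predicted.sqrt_var,
        "excess_rmse": observed.rmse - predicted.rmse,
    }


def d_prime(table: pd.DataFrame) -> float:
    """Separation between responses to the largest and smallest sample:
    difference of cell means over the pooled standard deviation.

    Used to screen subjects (extremes must be at least one d-prime apart).
    Returns ``inf`` when the pooled SD is zero but the means differ
    (noise-free responding)."""
    inc = included(table)
    samples = np.sort(inc["sample"].unique())
    if len(samples) < 2:
        raise ValueError("d_prime needs trials at both extreme sample values")
    lo = inc.loc[inc["sample"] == samples[0], "produced"].to_numpy(dtype=float)
    hi = inc.loc[inc["sample"] == samples[-1], "produced"].to_numpy(dtype=float)
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("need at least two trials in each extreme sample cell")
    diff = hi.mean() - lo.mean()
    pooled = np.sqrt(
        ((len(lo) - 1) * lo.var(ddof=1) + (len(hi) - 1) * hi.var(ddof=1)) / (len(lo) + len(hi) - 2)
    )
    if pooled == 0:
        return float("inf") if diff != 0 else 0.0
    return float(diff / pooled)


def signed_rank_test(pairs) -> dict:
    """Two-sided Wilcoxon signed-rank test on (predicted, observed) pairs.

    Uses the exact null distribution for n <= 25 (no zero differences),
    the normal approximation otherwise.  Errors when all differences are
    zero (the test is undefined)."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (predicted, observed) tuples")
    if len(arr) < 5:
        raise ValueError("signed-rank test needs at least 5 pairs")
    diffs = arr[:, 1] - arr[:, 0]
    if np.all(diffs == 0):
        raise ValueError("all differences are zero; signed-rank test undefined")
    method = "exact" if (len(diffs) <= 25 and not np.any(diffs == 0)) else "approx"
    res = sps.wilcoxon(diffs, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "two_sided_p": float(res.pvalue), "n": int(len(diffs))}
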