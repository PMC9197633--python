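"""Fitting and validating the abbreviated-to-total linear model.

The abbreviated scale is used through a simple conversion: ordinary
least squares of the full-scale total y on the subset sum x, y-hat =
slope * x + intercept. This module fits that model, scores it (explained
variance, Pearson and Spearman correlation), attaches resampling
uncertainty, and probes the properties a clinical user cares about:

* unbiasedness — the mean residual (actual - predicted) of the model on
  its own training data is exactly zero (an OLS identity), and its
  bootstrap interval on an independent cohort should cross zero;
* conditional bias — mean residuals within bands of the actual total
  expose systematic under- or over-estimation at the severe end;
* agreement — Bland-Altman bias and limits of agreement (bias +/- 1.96
  SD of the differences), with a proportional-bias slope;
* conversion spread — the conditional distribution of the total for each
  attainable subset-sum value, summarised by 2.5/25/50/75/97.5th
  percentiles.

Uncertainty intervals are seeded nonparametric case-resampling bootstrap
percentile intervals (default B = 10,000). The literature this follows
calls such intervals "credible intervals"; no Bayesian machinery is
involved, so outputs here label them bootstrap percentile intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AssessmentTable
from .scale_model import ItemSet

__all__ = [
    "LinearModel",
    "Metrics",
    "IntervalEstimate",
    "ResidualSummary",
    "AgreementSummary",
    "ConditionalDistribution",
    "TransferReport",
    "fit_sum_model",
    "predict_total",
    "compute_metrics",
    "bootstrap_interval",
    "interval_overlap",
    "residual_analysis",
    "bland_altman",
    "conditional_distribution",
    "transfer_evaluate",
    "evaluate_fixed_subset",
]

logger = logging.getLogger(__name__)

#: statistics bootstrap_interval knows how to resample
BOOT_STATS = ("evs", "pcc", "src", "mean_residual", "median")


@dataclass(frozen=True)
class LinearModel:
    """The subset-sum -> total conversion: y-hat = slope * x + intercept."""

    slope: float
    intercept: float
    subset: ItemSet
    n_fit: int

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


@dataclass(frozen=True)
class Metrics:
    evs: float
    pcc: float
    pcc_p: float
    src: float
    src_p: float


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    level: float = 0.95
    n_boot: int = 0
    seed: int = 0

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


@dataclass(frozen=True)
class AgreementSummary:
    bias: float
    loa_lower: float
    loa_upper: float
    proportional_bias_slope: float


@dataclass(frozen=True)
class ResidualSummary:
    mean_residual: float
    mean_residual_interval: IntervalEstimate
    skewness: float
    #: mean residual within bands of the actual total (band, n, mean)
    residuals_by_actual: pd.DataFrame


@dataclass(frozen=True)
class ConditionalDistribution:
    """Distribution of the total score conditional on the subset-sum value."""

    table: pd.DataFrame  # subset_sum, n, p2.5, p25, p50, p75, p97.5, suppressed
    display_min_n: int

    @property
    def displayed(self) -> pd.DataFrame:
        return self.table.loc[~self.table["suppressed"]].reset_index(drop=True)


@dataclass(frozen=True)
class TransferReport:
    """Train-fitted model evaluated on both cohorts, with interval overlaps."""

    model: LinearModel
    train_metrics: Metrics
    validation_metrics: Metrics
    train_intervals: dict[str, IntervalEstimate]
    validation_intervals: dict[str, IntervalEstimate]
    overlap: dict[str, bool]
    train_residuals: ResidualSummary
    validation_residuals: ResidualSummary


def _xy(table: AssessmentTable, subset: ItemSet) -> tuple[np.ndarray, np.ndarray]:
    x = table.subset_sums(subset).to_numpy(dtype=float)
    y = table.total_scores().to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("table must be complete on the subset and total")
    return x, y


def fit_sum_model(table: AssessmentTable, subset: ItemSet) -> LinearModel:
    """OLS of the full-scale total on the subset sum, with intercept."""
    x, y = _xy(table, subset)
    vx = x.var()
    if vx == 0:
        raise ValueError("subset sum has zero variance; cannot fit")
    slope = float(np.cov(x, y, ddof=1)[0, 1] / x.var(ddof=1))
    intercept = float(y.mean() - slope * x.mean())
    return LinearModel(slope=slope, intercept=intercept, subset=subset, n_fit=len(x))


def predict_total(model: LinearModel, x: float) -> float:
    """Convert a subset-sum value to an estimated full-scale total.

    The estimate is an approximation of the total, not an equivalent
    score: a range of totals is compatible with any one subset-sum value
    (see :func:`conditional_distribution`).
    """
    return float(model.slope * x + model.intercept)


def compute_metrics(actual: Sequence[float], estimated: Sequence[float]) -> Metrics:
    """EVS, Pearson and Spearman correlation between actual and estimate.

    EVS = 1 - Var(actual - estimated) / Var(actual); correlations carry
    two-sided p-values (t approximation; Spearman on midranks).
    """
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.shape != e.shape or a.ndim != 1:
        raise ValueError("actual and estimated must be equal-length 1-d series")
    if len(a) < 3:
        raise ValueError("need at least 3 observations")
    if a.var() == 0 or e.var() == 0:
        raise ValueError("zero variance in input series")
    evs = 1.0 - (a - e).var() / a.var()
    pcc = stats.pearsonr(a, e)
    src = stats.spearmanr(a, e)
    return Metrics(
        evs=float(evs),
        pcc=float(pcc.statistic),
        pcc_p=float(pcc.pvalue),
        src=float(src.statistic),
        src_p=float(src.pvalue),
    )


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", a, b)
    den = np.sqrt(np.einsum("ij,ij->i", a, a) * np.einsum("ij,ij->i", b, b))
    out = np.full(len(a), np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def _boot_stat_rows(
    stat: str,
    x: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    model: LinearModel | None,
) -> np.ndarray:
    """Statistic per bootstrap row; NaN marks a degenerate resample."""
    xs, ys = x[idx], y[idx]
    if stat == "median":
        return np.median(ys, axis=1)
    if stat == "mean_residual":
        if model is None:
            raise ValueError("mean_residual bootstrap requires a fitted model")
        return (ys - (model.slope * xs + model.intercept)).mean(axis=1)
    if stat == "pcc":
        return _pearson_rows(xs, ys)
    if stat == "src":
        rx = stats.rankdata(xs, axis=1)
        ry = stats.rankdata(ys, axis=1)
        return _pearson_rows(rx, ry)
    if stat == "evs":
        if model is not None:
            resid = ys - (model.slope * xs + model.intercept)
            vy = ys.var(axis=1)
            out = np.full(len(ys), np.nan)
            ok = vy > 0
            out[ok] = 1.0 - resid[ok].var(axis=1) / vy[ok]
            return out
        # refit per resample: with an intercept, EVS equals squared Pearson r
        r = _pearson_rows(xs, ys)
        return r**2
    raise ValueError(f"unknown bootstrap statistic {stat!r}; known: {BOOT_STATS}")


def _point_stat(
    stat: str, x: np.ndarray, y: np.ndarray, model: LinearModel | None
) -> float:
    return float(_boot_stat_rows(stat, x, y, np.arange(len(x))[None, :], model)[0])


def bootstrap_interval(
    stat: str,
    table: AssessmentTable,
    subset: ItemSet,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    model: LinearModel | None = None,
) -> IntervalEstimate:
    """Seeded case-resampling bootstrap percentile interval for a statistic.

    Resamples records with replacement; the statistic relates the table's
    total scores to the subset sums (for ``evs`` either through a fixed
    ``model``'s predictions, or refitting the sum regression within each
    resample when ``model`` is None). Degenerate resamples (zero
    variance) are redrawn, with the redraw count logged.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if stat not in BOOT_STATS:
        raise ValueError(f"unknown bootstrap statistic {stat!r}; known: {BOOT_STATS}")
    x, y = _xy(table, subset)
    n = len(x)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    vals = _boot_stat_rows(stat, x, y, idx, model)
    n_redrawn = 0
    while np.isnan(vals).any():
        bad = np.isnan(vals)
        n_redrawn += int(bad.sum())
        idx_bad = rng.integers(0, n, size=(int(bad.sum()), n))
        vals[bad] = _boot_stat_rows(stat, x, y, idx_bad, model)
    if n_redrawn:
        logger.info("bootstrap: redrew %d degenerate resamples", n_redrawn)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return IntervalEstimate(
        point=_point_stat(stat, x, y, model),
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_boot=n_boot,
        seed=seed,
    )


def interval_overlap(a: IntervalEstimate, b: IntervalEstimate) -> bool:
    """Whether two closed intervals of the same level intersect."""
    if a.level != b.level:
        raise ValueError(f"mismatched interval levels: {a.level} vs {b.level}")
    return a.lower <= b.upper and b.lower <= a.upper


def residual_analysis(
    model: LinearModel,
    table: AssessmentTable,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    band_width: int = 25,
    max_total: int = 260,
) -> ResidualSummary:
    """Residuals (actual - predicted) of the model on a cohort.

    Reports the mean residual with a bootstrap interval (unbiasedness:
    the interval should cross zero on an independent cohort; on the
    model's own training data the mean is exactly zero), the adjusted
    Fisher-Pearson sample skewness, and mean residuals within bands of
    the actual total (conditional bias at the severe end).
    """
    x, y = _xy(table, model.subset)
    resid = y - model.predict(x)
    interval = bootstrap_interval(
        "mean_residual", table, model.subset,
        n_boot=n_boot, level=level, seed=seed, model=model,
    )
    skew = float(stats.skew(resid, bias=False)) if len(resid) > 2 else 0.0
    edges = np.arange(0, max_total + band_width, band_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_band = (y >= lo) & (y < hi) if hi < max_total else (y >= lo) & (y <= hi)
        if in_band.any():
            rows.append(
                {
                    "band_lo": int(lo),
                    "band_hi": int(hi),
                    "n": int(in_band.sum()),
                    "mean_residual": float(resid[in_band].mean()),
                }
            )
    return ResidualSummary(
        mean_residual=float(resid.mean()),
        mean_residual_interval=interval,
        skewness=skew,
        residuals_by_actual=pd.DataFrame(rows),
    )


def bland_altman(
    actual: Sequence[float], estimated: Sequence[float]
) -> AgreementSummary:
    """Bland-Altman agreement between actual and estimated totals.

    Differences are oriented actual - estimated (matching the residual
    convention); limits of agreement are bias +/- 1.96 SD of the
    differences; the proportional-bias slope regresses differences on
    pair means.
    """
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.shape != e.shape or len(a) < 3:
        raise ValueError("need equal-length series with n >= 3")
    diff = a - e
    mean = (a + e) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if mean.var() > 0:
        slope = float(np.cov(mean, diff, ddof=1)[0, 1] / mean.var(ddof=1))
    else:
        slope = 0.0
    return AgreementSummary(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        proportional_bias_slope=slope,
    )


def conditional_distribution(
    table: AssessmentTable, subset: ItemSet, display_min_n: int = 5
) -> ConditionalDistribution:
    """Distribution of the total score for each observed subset-sum value.

    Per value: group size and the 2.5/25/50/75/97.5th percentiles of the
    total (linear interpolation between order statistics). Groups with
    n below ``display_min_n`` are flagged as suppressed for display but
    still counted — group sizes always sum to the table size.
    """
    x, y = _xy(table, subset)
    rows = []
    for v in np.unique(x):
        grp = y[x == v]
        p = np.percentile(grp, [2.5, 25, 50, 75, 97.5])
        rows.append(
            {
                "subset_sum": float(v),
                "n": int(len(grp)),
                "p2.5": p[0], "p25": p[1], "p50": p[2], "p75": p[3], "p97.5": p[4],
                "suppressed": len(grp) < display_min_n,
            }
        )
    return ConditionalDistribution(
        table=pd.DataFrame(rows), display_min_n=display_min_n
    )


_INTERVAL_METRICS = ("evs", "pcc", "src", "mean_residual")


def transfer_evaluate(
    model: LinearModel,
    subset: ItemSet,
    train: AssessmentTable,
    validation: AssessmentTable,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
) -> TransferReport:
    """Evaluate a train-fitted model on both cohorts, with overlap verdicts.

    All metrics use the fixed train-fitted model's predictions; for each
    of EVS, PCC, SRC and the mean residual, per-cohort bootstrap
    intervals are computed and their pairwise overlap reported. On a
    well-behaved external cohort the intervals should overlap and the
    validation mean-residual interval should cross zero.
    """
    reports: dict[str, dict[str, IntervalEstimate]] = {}
    for tag, tab, s in (("train", train, seed), ("validation", validation, seed + 1)):
        reports[tag] = {
            m: bootstrap_interval(
                m, tab, subset, n_boot=n_boot, level=level,
                seed=s + 7919 * i, model=model,
            )
            for i, m in enumerate(_INTERVAL_METRICS)
        }
    overlap = {
        m: interval_overlap(reports["train"][m], reports["validation"][m])
        for m in _INTERVAL_METRICS
    }

    def _metrics(tab: AssessmentTable) -> Metrics:
        x, y = _xy(tab, subset)
        return compute_metrics(y, model.predict(x))

    return TransferReport(
        model=model,
        train_metrics=_metrics(train),
        validation_metrics=_metrics(validation),
        train_intervals=reports["train"],
        validation_intervals=reports["validation"],
        overlap=overlap,
        train_residuals=residual_analysis(
            model, train, n_boot=n_boot, level=level, seed=seed + 13
        ),
        validation_residuals=residual_analysis(
            model, validation, n_boot=n_boot, level=level, seed=seed + 17
        ),
    )


def evaluate_fixed_subset(table: AssessmentTable, item_ids: ItemSet) -> Metrics:
    """Score any user-specified subset on a cohort.

    Fits the sum model on the table and returns the metrics — the
    entry point for evaluating an externally proposed short form (for
    instance a legacy clinically chosen 8-item scale) against a cohort.
    """
    model = fit_sum_model(table, item_ids)
    x, y = _xy(table, item_ids)
    return compute_metrics(y, model.predict(x))
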