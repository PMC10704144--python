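"""Paired app-vs-no-app statistical comparison.

For each outcome metric the paired differences across subjects are first
screened with the omnibus skew+kurtosis normality test
(K^2 = Z(skew)^2 + Z(kurtosis)^2, chi-square with 2 df); normally
distributed differences go to a paired t-test, the rest to the Wilcoxon
signed-rank test (zero differences dropped, average ranks for ties), at
alpha = 0.05 and without multiple-comparison correction.  An optional Holm
adjustment is available but off by default.

Normality is assessed on the paired differences — the quantity whose
distribution the paired t-test actually assumes — not on the raw
per-condition samples.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

DEFAULT_ALPHA = 0.05

#: metrics compared per exercise family
CYCLE_METRIC_FIELDS = ("rom_mean_deg", "rom_var_deg2", "freq_mean_hz", "freq_var_hz2")
BALANCE_METRIC_FIELDS = ("resultant_rom_deg", "fluency")


class DegenerateSampleError(ValueError):
    """Normality test on a zero-variance sample."""


class NoVariationError(ValueError):
    """All paired differences are zero; no test is possible."""


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    n: int
    small_sample_warning: bool  # n < 20: approximations unreliable


@dataclass(frozen=True)
class PairedComparison:
    """One metric's app-vs-no-app comparison across paired subjects."""

    metric_name: str
    exercise: Optional[str]
    n_pairs: int
    mean_app: float
    mean_noapp: float
    mean_diff: float               # mean(app - no_app)
    test_used: str                 # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    alpha: float
    significant: bool
    normality_p: float
    n_zero_diffs_dropped: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def omnibus_normality(x: Sequence[float]) -> NormalityResult:
    """Omnibus skew+kurtosis normality test (chi-square, 2 df).

    Raises :class:`DegenerateSampleError` on a zero-variance sample; flags
    (but still computes) results for n < 20, where the normalizing
    transforms are unreliable.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 8:
        raise ValueError("omnibus normality test needs at least 8 observations")
    if np.ptp(x) == 0.0 or np.var(x) == 0.0:
        raise DegenerateSampleError("zero-variance sample")
    stat, p = sstats.normaltest(x)
    return NormalityResult(
        statistic=float(stat),
        p_value=float(p),
        n=int(x.size),
        small_sample_warning=bool(x.size < 20),
    )


def paired_compare(
    app_values: Sequence[float],
    noapp_values: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    metric_name: str = "metric",
    exercise: Optional[str] = None,
    normality_alpha: float = 0.05,
) -> PairedComparison:
    """Paired test of app vs no-app values, aligned by subject.

    Differences are screened for normality; normal ones take the paired
    t-test, non-normal ones the Wilcoxon signed-rank test (zeros dropped).
    """
    app = np.asarray(app_values, dtype=float)
    noapp = np.asarray(noapp_values, dtype=float)
    if app.shape != noapp.shape:
        raise ValueError("app and no-app samples must have equal length")
    n = app.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diffs = app - noapp
    if np.all(diffs == 0.0):
        raise NoVariationError("all paired differences are zero")

    try:
        normality = omnibus_normality(diffs)
        normal = normality.p_value >= normality_alpha
        normality_p = normality.p_value
    except (ValueError, DegenerateSampleError):
        normal = False
        normality_p = float("nan")

    n_dropped = 0
    if normal:
        test_used = "paired_t"
        res = sstats.ttest_rel(app, noapp)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        test_used = "wilcoxon_signed_rank"
        nz = diffs[diffs != 0.0]
        n_dropped = int(n - nz.size)
        res = sstats.wilcoxon(nz, zero_method="wilcox", correction=False)
        stat, p = float(res.statistic), float(res.pvalue)

    return PairedComparison(
        metric_name=metric_name,
        exercise=exercise,
        n_pairs=int(n),
        mean_app=float(np.mean(app)),
        mean_noapp=float(np.mean(noapp)),
        mean_diff=float(np.mean(diffs)),
        test_used=test_used,
        statistic=stat,
        p_value=p,
        alpha=alpha,
        significant=bool(p < alpha),
        normality_p=float(normality_p),
        n_zero_diffs_dropped=n_dropped,
    )


def _metric_fields(metrics) -> dict:
    if metrics is None:
        return {}
    if metrics.kind == "cycle":
        return {f: getattr(metrics, f) for f in CYCLE_METRIC_FIELDS}
    out = {"resultant_rom_deg": metrics.resultant_rom_deg}
    if metrics.fluency is not None:
        out["fluency"] = metrics.fluency
    return out


def compare_cohort(
    records: Sequence,
    alpha: float = DEFAULT_ALPHA,
    holm: bool = False,
) -> list[PairedComparison]:
    """One paired comparison per (exercise, metric) over a cohort of records.

    Every subject must contribute both conditions of an exercise with
    computed metrics; incomplete subjects are excluded from that exercise
    with a warning naming them.  With ``holm=True`` p-values are
    Holm-adjusted before the significance call (off by default).
    """
    by_exercise: dict[str, dict[str, dict[str, object]]] = {}
    for rec in records:
        ex = rec.prescription.exercise
        by_exercise.setdefault(ex, {}).setdefault(rec.subject_id, {})[
            rec.condition
        ] = rec

    comparisons: list[PairedComparison] = []
    for exercise, subjects in sorted(by_exercise.items()):
        complete, excluded = {}, []
        for subject_id, conds in sorted(subjects.items()):
            if (
                "app" in conds
                and "no_app" in conds
                and conds["app"].metrics is not None
                and conds["no_app"].metrics is not None
            ):
                complete[subject_id] = conds
            else:
                excluded.append(subject_id)
        if excluded:
            warnings.warn(
                f"{exercise}: excluding unpaired/unanalyzed subject(s) "
                + ", ".join(excluded),
                stacklevel=2,
            )
        if len(complete) < 3:
            continue
        sample = next(iter(complete.values()))
        fields = _metric_fields(sample["app"].metrics)
        for field_name in fields:
            app_vals, noapp_vals = [], []
            for conds in complete.values():
                a = _metric_fields(conds["app"].metrics).get(field_name)
                b = _metric_fields(conds["no_app"].metrics).get(field_name)
                if a is None or b is None:
                    continue
                app_vals.append(a)
                noapp_vals.append(b)
            if len(app_vals) < 3:
                continue
            try:
                comparisons.append(
                    paired_compare(
                        app_vals, noapp_vals, alpha=alpha,
                        metric_name=field_name, exercise=exercise,
                    )
                )
            except NoVariationError:
                warnings.warn(
                    f"{exercise}/{field_name}: no variation in paired "
                    "differences; comparison skipped",
                    stacklevel=2,
                )
    if holm and comparisons:
        comparisons = _holm_adjust(comparisons)
    return comparisons


def _holm_adjust(comparisons: list[PairedComparison]) -> list[PairedComparison]:
    m = len(comparisons)
    order = np.argsort([c.p_value for c in comparisons])
    adjusted = [None] * m
    running_max = 0.0
    for rank, idx in enumerate(order):
        c = comparisons[idx]
        p_adj = min(1.0, (m - rank) * c.p_value)
        running_max = max(running_max, p_adj)
        adjusted[idx] = dataclasses.replace(
            c, p_value=running_max, significant=bool(running_max < c.alpha)
        )
    return adjusted


def comparison_table(comparisons: Sequence[PairedComparison]) -> pd.DataFrame:
    """Serializable summary table (one row per exercise/metric comparison)."""
    return pd.DataFrame(
        [
            {
                "exercise": c.exercise,
                "metric": c.metric_name,
                "n_pairs": c.n_pairs,
                "mean_app": c.mean_app,
                "mean_noapp": c.mean_noapp,
                "mean_diff": c.mean_diff,
                "test": c.test_used,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "significant": c.significant,
            }
            for c in comparisons
        ]
    )
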