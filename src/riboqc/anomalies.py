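"""Anomalous-sample screening over summary QC metrics.

Four independent strategies:

1. expert thresholds — fixed cutoffs on periodicity and rRNA/tRNA/CDS
   feature percentages (direction-aware: low periodicity/CDS% is bad,
   high rRNA/tRNA% is bad);
2. Tukey's fence across the user's own samples — flag metric values
   outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR];
3. percent error against designated control samples, flagged above a
   25% relative difference;
4. Tukey's fence against an external reference metric table (a corpus
   of known-good libraries), applied per metric as in strategy 2.

Every verdict is returned as an :class:`AnomalyFlag` carrying the
observed value, the reference value or fence, and a human-readable
reason, so reports can show both flagged and passing checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "AnomalyFlag",
    "DEFAULT_EXPERT_THRESHOLDS",
    "expert_threshold_flags",
    "tukey_fences",
    "tukey_flags",
    "control_flags",
    "reference_flags",
    "flags_to_frame",
    "default_metrics",
]

#: metric -> (direction, cutoff); "min" flags values below, "max" above.
#: Tool defaults, configurable; not derived from any published corpus.
DEFAULT_EXPERT_THRESHOLDS: dict[str, tuple[str, float]] = {
    "periodicity": ("min", 0.50),
    "pct_CDS": ("min", 50.0),
    "pct_rRNA": ("max", 20.0),
    "pct_tRNA": ("max", 10.0),
}


@dataclass
class AnomalyFlag:
    sample: str
    metric: str
    observed: float
    reference: float | tuple[float, float] | None
    method: str  # expert | tukey | control | reference
    flagged: bool
    detail: str


def flags_to_frame(flags: list[AnomalyFlag]) -> pd.DataFrame:
    cols = ["sample", "metric", "observed", "reference", "method", "flagged", "detail"]
    return pd.DataFrame([asdict(f) for f in flags], columns=cols)


def default_metrics(summary: pd.DataFrame) -> list[str]:
    """Numeric QC metric columns of a summary table."""
    skip = {"sample", "exp"}
    return [
        c for c in summary.columns
        if c not in skip and pd.api.types.is_numeric_dtype(summary[c])
    ]


def expert_threshold_flags(
    summary: pd.DataFrame,
    thresholds: dict[str, tuple[str, float]] | None = None,
) -> list[AnomalyFlag]:
    """Flag metric values violating fixed expert cutoffs.

    Metrics absent from the summary (or from the threshold config) emit
    no flag at all.
    """
    thresholds = DEFAULT_EXPERT_THRESHOLDS if thresholds is None else thresholds
    flags = []
    for _, row in summary.iterrows():
        for metric, (direction, cutoff) in thresholds.items():
            if metric not in summary.columns or pd.isna(row[metric]):
                continue
            obs = float(row[metric])
            bad = obs < cutoff if direction == "min" else obs > cutoff
            word = "below minimum" if direction == "min" else "above maximum"
            flags.append(
                AnomalyFlag(
                    sample=row["sample"],
                    metric=metric,
                    observed=obs,
                    reference=cutoff,
                    method="expert",
                    flagged=bool(bad),
                    detail=f"{metric}={obs:.4g} {word} {cutoff:g}" if bad
                    else f"{metric}={obs:.4g} within expert threshold",
                )
            )
    return flags


def tukey_fences(values: np.ndarray, k: float = 1.5) -> tuple[float, float]:
    """[Q1 - k*IQR, Q3 + k*IQR] with linearly interpolated quartiles."""
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return float(q1 - k * iqr), float(q3 + k * iqr)


def _tukey_screen(
    summary: pd.DataFrame,
    ref_values: dict[str, np.ndarray],
    method: str,
    metrics: list[str],
) -> list[AnomalyFlag]:
    flags = []
    for _, row in summary.iterrows():
        for metric in metrics:
            if metric not in ref_values or pd.isna(row.get(metric)):
                continue
            lo, hi = tukey_fences(ref_values[metric])
            obs = float(row[metric])
            bad = obs < lo or obs > hi  # boundary values are not outliers
            flags.append(
                AnomalyFlag(
                    sample=row["sample"],
                    metric=metric,
                    observed=obs,
                    reference=(lo, hi),
                    method=method,
                    flagged=bool(bad),
                    detail=f"{metric}={obs:.4g} outside fence [{lo:.4g}, {hi:.4g}]"
                    if bad else f"{metric}={obs:.4g} inside fence [{lo:.4g}, {hi:.4g}]",
                )
            )
    return flags


def tukey_flags(
    summary: pd.DataFrame,
    metrics: list[str] | None = None,
    min_samples: int = 4,
) -> list[AnomalyFlag]:
    """Screen each sample's metrics against fences from the user's own cohort.

    Needs at least ``min_samples`` samples for quartiles to be meaningful;
    below that the strategy is skipped with a warning.
    """
    if len(summary) < min_samples:
        warnings.warn(
            f"Tukey screening skipped: {len(summary)} samples < {min_samples}"
        )
        return []
    metrics = metrics if metrics is not None else default_metrics(summary)
    ref = {
        m: summary[m].dropna().to_numpy()
        for m in metrics
        if m in summary.columns and summary[m].notna().any()
    }
    return _tukey_screen(summary, ref, "tukey", list(ref))


def control_flags(
    summary: pd.DataFrame,
    controls: list[str],
    threshold: float = 0.25,
    metrics: list[str] | None = None,
) -> list[AnomalyFlag]:
    """Percent-error screen of non-control samples against control means.

    percent error = |observed - control mean| / |control mean|; a sample
    is flagged on a metric when the error strictly exceeds ``threshold``
    (default 25%).  Metrics whose control mean is zero are skipped with a
    warning; multiple controls are summarised by their mean.
    """
    ctrl = summary[summary["sample"].isin(controls)]
    if ctrl.empty:
        raise ValueError(f"no control samples found among {controls}")
    others = summary[~summary["sample"].isin(controls)]
    metrics = metrics if metrics is not None else default_metrics(summary)
    flags = []
    for metric in metrics:
        if metric not in summary.columns:
            continue
        mean = ctrl[metric].dropna().mean()
        if pd.isna(mean):
            continue
        if mean == 0:
            warnings.warn(f"control mean is zero for {metric}; metric skipped")
            continue
        for _, row in others.iterrows():
            if pd.isna(row[metric]):
                continue
            obs = float(row[metric])
            err = abs(obs - mean) / abs(mean)
            bad = err > threshold
            flags.append(
                AnomalyFlag(
                    sample=row["sample"],
                    metric=metric,
                    observed=obs,
                    reference=float(mean),
                    method="control",
                    flagged=bool(bad),
                    detail=f"{metric}: percent error {100 * err:.4g}% vs control "
                    f"mean {mean:.4g} ({'exceeds' if bad else 'within'} "
                    f"{100 * threshold:g}%)",
                )
            )
    return flags


def reference_flags(
    summary: pd.DataFrame,
    reference: pd.DataFrame,
    metrics: list[str] | None = None,
) -> list[AnomalyFlag]:
    """Tukey-fence screen against an external reference metric table.

    The reference table must be schema-compatible with the summary table
    (one row per reference sample, same metric column names).
    """
    if reference is None or len(reference) == 0:
        raise ValueError("reference metric table is empty or missing")
    metrics = metrics if metrics is not None else default_metrics(summary)
    ref = {
        m: reference[m].dropna().to_numpy()
        for m in metrics
        if m in reference.columns and reference[m].notna().any()
    }
    return _tukey_screen(summary, ref, "reference", list(ref))
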