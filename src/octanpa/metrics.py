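"""Perfusion metrics, longitudinal tables and inter-grader reproducibility.

Two scan-level quantities are reported per visit: the whole ischemic area
(mm², and as a percentage of the scan field) and the vessel density (the
percentage of pixels classified as vessel by this pipeline's binarised vessel
image — note the pipeline's own vessel image, not device software output).

Agreement between two graders' reviewed segmentations is summarised with the
intraclass correlation coefficient ICC(2,1): two-way random effects, absolute
agreement, single measures,

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n)

where MSR, MSC and MSE are the between-subject, between-rater and residual
mean squares of the subjects × raters table.  When several metrics are pooled
into one coefficient, each metric is first z-scored across subjects so scale
differences between metrics do not dominate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DegenerateInputError, ManifestError
from .io import BinaryMask, VisitManifest

__all__ = [
    "PerfusionMetrics",
    "ReproducibilityReport",
    "vessel_density",
    "ischemic_percent",
    "longitudinal_table",
    "icc_two_raters",
    "trajectory_figure",
]

_TIMEPOINT_ORDER = {"T0": 0, "T1": 1, "T2": 2, "T3": 3}


@dataclass(frozen=True)
class PerfusionMetrics:
    """Per-visit perfusion summary for one (patient, eye, plexus, timepoint)."""

    patient_id: str
    eye: str
    plexus: str
    timepoint: str
    ischemic_area_mm2: float
    ischemic_percent: float
    vessel_density_percent: float
    n_clusters: int

    def __post_init__(self) -> None:
        if not 0 <= self.vessel_density_percent <= 100:
            raise ContractError(
                f"vessel density must be in [0, 100] %, got {self.vessel_density_percent}"
            )
        if self.ischemic_area_mm2 < 0:
            raise ContractError("ischemic area cannot be negative")


@dataclass(frozen=True)
class ReproducibilityReport:
    """ICC-based agreement summary between raters."""

    icc: float
    n_subjects: int
    n_raters: int
    metric_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.icc > 1 + 1e-12:
            raise ContractError(f"ICC cannot exceed 1, got {self.icc}")


def vessel_density(vessels: BinaryMask) -> float:
    """Vessel density in percent: 100 × vessel pixels / total pixels."""
    if vessels.role != "vessel":
        raise ContractError(f"expected a mask with role 'vessel', got {vessels.role!r}")
    n = vessels.pixels.size
    if n == 0:
        raise ContractError("empty raster has no defined vessel density")
    return 100.0 * float(vessels.pixels.sum()) / n


def ischemic_percent(area_mm2: float, field_mm: tuple[float, float]) -> float:
    """Ischemic area as a percentage of the scan field: 100 × area / (h × w)."""
    h, w = field_mm
    if area_mm2 < 0:
        raise ContractError(f"area_mm2 must be >= 0, got {area_mm2}")
    if h <= 0 or w <= 0:
        raise ContractError(f"field dimensions must be positive, got {field_mm}")
    if area_mm2 > h * w * (1 + 1e-12):
        raise ContractError(
            f"ischemic area {area_mm2} mm2 exceeds the scan area {h * w} mm2"
        )
    return 100.0 * area_mm2 / (h * w)


def longitudinal_table(
    manifest: VisitManifest, results: Mapping[tuple, PerfusionMetrics]
) -> dict[str, pd.DataFrame]:
    """Tidy per-visit rows plus group summaries per (plexus, timepoint).

    ``results`` maps each manifest record key (patient_id, eye, plexus,
    timepoint) to its :class:`PerfusionMetrics`.  Returns ``{"rows": ...,
    "summary": ...}``: one row per observation, and per (plexus, timepoint)
    the group mean ± SD (sample SD, ddof=1; NaN for a single observation) of
    each metric together with the mean paired change from the previous
    timepoint among patients observed at both.
    """
    if len(manifest) == 0 or not results:
        raise ManifestError("empty manifest or results: nothing to tabulate")
    missing = [r.key for r in manifest if r.key not in results]
    if missing:
        raise ManifestError(f"missing results for manifest records: {missing[:5]}")

    rows = pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "eye": m.eye,
                "plexus": m.plexus,
                "timepoint": m.timepoint,
                "ischemic_area_mm2": m.ischemic_area_mm2,
                "ischemic_percent": m.ischemic_percent,
                "vessel_density_percent": m.vessel_density_percent,
                "n_clusters": m.n_clusters,
            }
            for m in (results[r.key] for r in manifest)
        ]
    ).sort_values(["plexus", "timepoint", "patient_id", "eye"], ignore_index=True)

    value_cols = ["ischemic_area_mm2", "ischemic_percent", "vessel_density_percent"]
    summaries = []
    for (plexus, tp), grp in rows.groupby(["plexus", "timepoint"], sort=True):
        entry: dict = {"plexus": plexus, "timepoint": tp, "n": len(grp)}
        for col in value_cols:
            entry[f"{col}_mean"] = grp[col].mean()
            entry[f"{col}_sd"] = grp[col].std(ddof=1) if len(grp) > 1 else np.nan
        # paired change vs the previous timepoint, same patient/eye/plexus
        prev_idx = _TIMEPOINT_ORDER[tp] - 1
        prev_tp = next((k for k, v in _TIMEPOINT_ORDER.items() if v == prev_idx), None)
        if prev_tp is not None:
            prev = rows[(rows.plexus == plexus) & (rows.timepoint == prev_tp)]
            merged = grp.merge(prev, on=["patient_id", "eye", "plexus"], suffixes=("", "_prev"))
            for col in value_cols:
                entry[f"{col}_change_mean"] = (
                    (merged[col] - merged[f"{col}_prev"]).mean() if len(merged) else np.nan
                )
        else:
            for col in value_cols:
                entry[f"{col}_change_mean"] = np.nan
        summaries.append(entry)
    return {"rows": rows, "summary": pd.DataFrame(summaries)}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("cannot z-score a metric with zero variance")
    return (x - x.mean()) / sd


def icc_two_raters(
    ratings: np.ndarray | Mapping[str, np.ndarray],
    normalize: bool = False,
) -> ReproducibilityReport:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``ratings`` is either a subjects × raters matrix or a mapping from metric
    name to such a matrix; with several metrics the (optionally z-scored)
    matrices are stacked along subjects before the ANOVA decomposition, per
    the "among-patients normalisation" pooling.  Requires ≥ 3 subjects, ≥ 2
    raters, no missing cells.
    """
    if isinstance(ratings, Mapping):
        names = tuple(ratings)
        mats = [np.asarray(ratings[n], dtype=float) for n in names]
        shapes = {m.shape for m in mats}
        if len({s[1] for s in shapes}) != 1:
            raise ContractError("all metric matrices must have the same number of raters")
        if normalize:
            mats = [_zscore(m) for m in mats]
        data = np.vstack(mats)
    else:
        names = ()
        data = np.asarray(ratings, dtype=float)
        if normalize:
            data = _zscore(data)
    if data.ndim != 2:
        raise ContractError(f"ratings must be a 2-D subjects × raters matrix, got {data.ndim}-D")
    n, k = data.shape
    if n < 3:
        raise ContractError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ContractError(f"need at least 2 raters, got {k}")
    if not np.all(np.isfinite(data)):
        raise ContractError("ratings contain missing or non-finite cells")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sse = np.sum((data - row_means[:, None] - col_means[None, :] + grand) ** 2)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    den = msr + (k - 1) * mse + k * (msc - mse) / n
    if den == 0:
        # constant ratings table: no between-subject variance anywhere
        raise DegenerateInputError("zero between-subject variance: ICC is undefined")
    icc = (msr - mse) / den
    return ReproducibilityReport(icc=float(icc), n_subjects=n, n_raters=k, metric_names=names)


def trajectory_figure(rows: pd.DataFrame, metric: str = "ischemic_area_mm2", ax=None):
    """Simple per-patient trajectory plot of one metric across timepoints.

    Returns the matplotlib Axes.  One line per (patient, eye, plexus).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for (pid, eye, plexus), grp in rows.groupby(["patient_id", "eye", "plexus"]):
        grp = grp.sort_values("timepoint", key=lambda s: s.map(_TIMEPOINT_ORDER))
        ax.plot(grp["timepoint"], grp[metric], marker="o", label=f"{pid} {eye} {plexus}")
    ax.set_xlabel("timepoint")
    ax.set_ylabel(metric)
    ax.legend(fontsize=7, loc="best")
    return ax
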