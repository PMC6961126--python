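"""Label-free flow volumetry.

Cell volumes are estimated from forward-scatter area (FSC-A) via a
calibration line fitted to beads of known diameter::

    FSC-A = slope * diameter + intercept

so that for each gated cell event

    d = (FSC-A - intercept) / slope          [um]
    V = (pi / 6) * d**3                      [um^3]

Event tables are plain :class:`pandas.DataFrame` objects with columns
``fsc_area``, ``ssc_area``, ``ssc_width`` (one row per event, linear
units).  Scatter units are instrument-specific and treated as opaque;
only the bead calibration makes them physical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("fsc_area", "ssc_area", "ssc_width")

#: Minimum acceptable coefficient of determination for a bead
#: calibration line; below this the bead suspension is suspect
#: (clumping) and should be re-mixed and re-acquired.
R_SQUARED_QUALITY_GATE = 0.95


def _as_event_table(events: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an event table (case-insensitive columns)."""
    cols = {c.lower(): c for c in events.columns}
    missing = [c for c in EVENT_COLUMNS if c not in cols]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    out = events.rename(columns={cols[c]: c for c in EVENT_COLUMNS})
    values = out[list(EVENT_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("event table contains non-finite values")
    if np.any(values < 0):
        raise ValueError("event table contains negative values; scatter "
                         "values must be linear-scale and non-negative")
    return out


@dataclass(frozen=True)
class GateSpec:
    """Rectangular gate on any subset of the three scatter axes.

    Bounds are inclusive; ``None`` leaves the corresponding side
    unbounded.  Used to exclude debris (very low FSC/SSC) and
    doublets/triplets.
    """

    fsc_area: tuple[float | None, float | None] = (None, None)
    ssc_area: tuple[float | None, float | None] = (None, None)
    ssc_width: tuple[float | None, float | None] = (None, None)

    def __post_init__(self) -> None:
        for axis in EVENT_COLUMNS:
            lo, hi = getattr(self, axis)
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(f"gate on {axis}: lower {lo} > upper {hi}")


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map from bead diameter (um) to FSC-A, with fit quality."""

    slope: float
    intercept: float
    r_squared: float


@dataclass
class VolumeDistribution:
    """Per-event diameters (um) and volumes (um^3) after calibration."""

    diameter_um: np.ndarray
    volume_um3: np.ndarray
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.diameter_um.size


@dataclass(frozen=True)
class BoxSummary:
    """Five-number summary plus the 7-value boxplot export.

    The export is the compact representation used to draw a boxplot from
    just seven numbers per condition: minimum, maximum, 25th percentile,
    75th percentile, and the median repeated three times.
    """

    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float
    seven_value_export: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group volume comparison (b relative to a)."""

    median_diff_um3: float
    pct_change: float
    rank_sum_p: float


def gate_events(events: pd.DataFrame, gate: GateSpec) -> pd.DataFrame:
    """Apply a rectangular gate, returning the retained events.

    Returns an empty table (with a logged warning) rather than raising
    when the gate excludes everything.
    """
    events = _as_event_table(events)
    if len(events) == 0:
        raise ValueError("event table is empty")
    keep = np.ones(len(events), dtype=bool)
    for axis in EVENT_COLUMNS:
        lo, hi = getattr(gate, axis)
        col = events[axis].to_numpy(dtype=float)
        if lo is not None:
            keep &= col >= lo
        if hi is not None:
            keep &= col <= hi
    retained = events.loc[keep]
    frac = len(retained) / len(events)
    logger.info("gate retained %d/%d events (%.1f%%)",
                len(retained), len(events), 100 * frac)
    if len(retained) == 0:
        logger.warning("gate excluded all %d events", len(events))
    return retained


def suggest_debris_gate(events: pd.DataFrame,
                        axis: str = "fsc_area") -> float:
    """Advisory lower cutoff for the debris gate.

    Returns the deepest valley of a Gaussian kernel density estimate of
    the given axis, i.e. the antimode separating the low-scatter debris
    population from the main population.  Advisory only — gates are
    user-supplied; no printed cutoffs exist for this step.
    """
    x = _as_event_table(events)[axis].to_numpy(dtype=float)
    kde = stats.gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    interior = slice(1, -1)
    is_min = (dens[interior] < dens[:-2]) & (dens[interior] < dens[2:])
    minima = np.flatnonzero(is_min) + 1
    if minima.size == 0:
        logger.warning("no KDE valley found on %s; returning the minimum", axis)
        return float(grid[0])
    return float(grid[minima[np.argmin(dens[minima])]])


def fit_bead_calibration(panel: pd.DataFrame) -> CalibrationCurve:
    """Ordinary least squares of bead FSC-A medians on bead diameter.

    Parameters
    ----------
    panel
        DataFrame with columns ``diameter_um`` and ``fsc_median``, one
        row per bead size.  Medians (not means) of the gated bead events
        are used, which is robust to residual debris in the bead gates.
    """
    d = np.asarray(panel["diameter_um"], dtype=float)
    y = np.asarray(panel["fsc_median"], dtype=float)
    if np.any(d <= 0):
        raise ValueError("bead diameters must be strictly positive")
    if np.unique(d).size < 2:
        raise ValueError("insufficient beads: need >= 2 distinct diameters")
    res = stats.linregress(d, y)
    r2 = float(res.rvalue ** 2)
    if r2 < R_SQUARED_QUALITY_GATE:
        logger.warning(
            "calibration R^2 = %.4f < %.2f: bead suspension may be clumped; "
            "re-mix beads and re-acquire", r2, R_SQUARED_QUALITY_GATE)
    return CalibrationCurve(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=r2)


def events_to_volumes(events: pd.DataFrame,
                      curve: CalibrationCurve) -> VolumeDistribution:
    """Invert the calibration per event and apply the sphere formula.

    Events whose computed diameter is <= 0 (FSC-A at or below the
    intercept) are non-physical; they are excluded and counted in
    ``n_excluded`` rather than clamped.
    """
    if curve.slope <= 0:
        raise ValueError("non-physical calibration: slope must be > 0")
    fsc = _as_event_table(events)["fsc_area"].to_numpy(dtype=float)
    diameter = (fsc - curve.intercept) / curve.slope
    keep = diameter > 0
    n_excluded = int(np.sum(~keep))
    if n_excluded:
        logger.info("excluded %d events with non-positive diameter", n_excluded)
    diameter = diameter[keep]
    volume = (math.pi / 6.0) * diameter ** 3
    return VolumeDistribution(diameter_um=diameter, volume_um3=volume,
                              n_excluded=n_excluded)


def summarize_volumes(vd: VolumeDistribution) -> BoxSummary:
    """Five-number summary and the 7-value boxplot export.

    Quantiles use linear interpolation between order statistics
    (the common "type 7" convention of mainstream plotting tools).
    """
    if vd.n == 0:
        raise ValueError("cannot summarize an empty volume distribution")
    v = vd.volume_um3
    q25, med, q75 = (float(q) for q in
                     np.quantile(v, [0.25, 0.5, 0.75], method="linear"))
    lo, hi = float(v.min()), float(v.max())
    return BoxSummary(minimum=lo, q25=q25, median=med, q75=q75, maximum=hi,
                      seven_value_export=[lo, hi, q25, q75, med, med, med])


def compare_volume_distributions(a: VolumeDistribution,
                                 b: VolumeDistribution) -> ComparisonResult:
    """Compare two volume distributions (b relative to a).

    Reports the median difference, the percent change of the median
    relative to ``a``, and a two-sided Wilcoxon rank-sum p-value —
    a rank-based test is used because cell-volume distributions are
    typically right-skewed.
    """
    if a.n == 0 or b.n == 0:
        raise ValueError("both distributions must be non-empty")
    med_a = float(np.median(a.volume_um3))
    med_b = float(np.median(b.volume_um3))
    p = float(stats.mannwhitneyu(a.volume_um3, b.volume_um3,
                                 alternative="two-sided").pvalue)
    return ComparisonResult(median_diff_um3=med_b - med_a,
                            pct_change=100.0 * (med_b - med_a) / med_a,
                            rank_sum_p=p)
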