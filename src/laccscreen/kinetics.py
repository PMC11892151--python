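"""Enzyme activity quantification from plate-reader kinetic absorbance traces.

A well's ABTS oxidation progress curve (A420 vs time) has a lag, a linear
phase, and saturation.  The linear phase is isolated by an exhaustive search
for the longest contiguous window whose least-squares fit reaches a target
R-squared, and the slope is converted to enzyme Units (µmol oxidized ABTS per
minute) through the Beer-Lambert law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "KineticTrace",
    "LinearFit",
    "KineticsParams",
    "ActivityRecord",
    "trim_to_linear",
    "activity_from_fit",
    "quantify_plate",
    "QC_OK",
    "QC_FLAT",
    "QC_NO_LINEAR_WINDOW",
]

QC_OK = "ok"
QC_FLAT = "flat"
QC_NO_LINEAR_WINDOW = "no_linear_window"

LAYOUT_ROLES = ("sample", "reference", "blank")


@dataclass(frozen=True)
class KineticTrace:
    """One well's A420 time series.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"A1"``.
    times : array-like of float
        Read times in minutes, strictly increasing.
    absorbance : array-like of float
        A420 readings (AU), same length as `times`.
    """

    well_id: str
    times: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.shape != y.shape:
            raise ValueError(f"well {self.well_id}: times/absorbance must be 1-D and equal length")
        if t.size < 2:
            raise ValueError(f"well {self.well_id}: a kinetic trace needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"well {self.well_id}: times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError(f"well {self.well_id}: non-finite values in trace")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", y)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class LinearFit:
    """Least-squares fit over the selected linear window (inclusive indices)."""

    start_index: int
    end_index: int
    slope: float  # AU/min
    intercept: float  # AU
    r_squared: float
    qc_flag: str

    @property
    def n_points(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class KineticsParams:
    """Parameters of linear-range detection and the Beer-Lambert conversion.

    `path_length_cm` has no scientific default: the optical path of a
    microplate well depends on fill volume, so it must be supplied.  Computed
    activities scale as 1/path_length.
    """

    path_length_cm: float
    r2_min: float = 0.999
    min_points: int = 10
    epsilon: float = 36000.0  # molar extinction coefficient of oxidized ABTS at 420 nm, 1/(M cm)
    reaction_volume_ul: float = 200.0
    dilution_factor: float = 1.0
    subtract_blank: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.r2_min <= 1):
            raise ValueError("r2_min must be in (0, 1]")
        for name in ("path_length_cm", "epsilon", "reaction_volume_ul", "dilution_factor"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")


@dataclass
class ActivityRecord:
    """Per-well quantification result."""

    strain_id: str
    replicate_id: str
    well_id: str
    fit: LinearFit
    activity_u: Optional[float]  # Units = µmol oxidized ABTS / min; None when QC failed
    od600: Optional[float] = None
    clamped: bool = field(default=False)


def _window_scan(
    t: np.ndarray, y: np.ndarray, length: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """OLS slope, intercept, R² and flatness flag for every window of `length`.

    Vectorized over window starts via prefix sums on globally centred data
    (centring keeps the cancellation in the corrected sums benign).  A window
    with zero response range is flat by definition: slope 0, R² = 1.
    """
    tc = t - t.mean()
    yc = y - y.mean()
    p1 = np.concatenate(([0.0], np.cumsum(tc)))
    p2 = np.concatenate(([0.0], np.cumsum(yc)))
    p11 = np.concatenate(([0.0], np.cumsum(tc * tc)))
    p12 = np.concatenate(([0.0], np.cumsum(tc * yc)))
    p22 = np.concatenate(([0.0], np.cumsum(yc * yc)))
    i = np.arange(0, t.size - length + 1)
    j = i + length
    st = p1[j] - p1[i]
    sy = p2[j] - p2[i]
    sxx = (p11[j] - p11[i]) - st * st / length
    sxy = (p12[j] - p12[i]) - st * sy / length
    syy = (p22[j] - p22[i]) - sy * sy / length

    win = np.lib.stride_tricks.sliding_window_view(y, length)
    flat = win.max(axis=1) == win.min(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(flat, 0.0, sxy / sxx)
        ss_res = np.maximum(syy - sxy * sxy / sxx, 0.0)
        r2 = np.where(flat, 1.0, np.clip(1.0 - ss_res / np.where(syy > 0, syy, 1.0), 0.0, 1.0))
    mean_y = sy / length + y.mean()
    mean_t = st / length + t.mean()
    intercept = np.where(flat, win[:, 0], mean_y - slope * mean_t)
    return slope, intercept, r2, flat


def trim_to_linear(trace: KineticTrace, params: KineticsParams) -> LinearFit:
    """Find the linear range of a progress curve by exhaustive window search.

    Returns the longest contiguous window of at least ``params.min_points``
    points whose OLS fit has R² >= ``params.r2_min``; ties are broken in
    favour of the earliest start.  A qualifying window with constant response
    is reported with ``qc_flag="flat"`` and slope 0.  When no window
    qualifies, the best-R² window of length exactly ``min_points`` is
    reported with ``qc_flag="no_linear_window"``.

    This generalizes trimming points from both curve ends until the target
    R² is reached: the search considers every such trimming and is
    deterministic and order-independent.
    """
    t, y = trace.times, trace.absorbance
    n = t.size
    if n < params.min_points:
        raise ValueError(
            f"well {trace.well_id}: trace has {n} points, fewer than min_points={params.min_points}"
        )
    # Longest window first, earliest start first.
    for length in range(n, params.min_points - 1, -1):
        slope, intercept, r2, flat = _window_scan(t, y, length)
        ok = r2 >= params.r2_min
        if ok.any():
            i = int(np.argmax(ok))
            qc = QC_FLAT if flat[i] else QC_OK
            return LinearFit(i, i + length - 1, float(slope[i]), float(intercept[i]), float(r2[i]), qc)
    slope, intercept, r2, _ = _window_scan(t, y, params.min_points)
    i = int(np.argmax(r2))  # argmax takes the earliest start on ties
    return LinearFit(
        i, i + params.min_points - 1, float(slope[i]), float(intercept[i]), float(r2[i]), QC_NO_LINEAR_WINDOW
    )


def activity_from_fit(fit: LinearFit, params: KineticsParams) -> float:
    """Convert a linear-window slope (AU/min) into enzyme Units.

    Beer-Lambert: d[ABTSox]/dt (M/min) = slope / (epsilon * path_length);
    multiplied by the reaction volume in litres and 10^6 this gives µmol of
    ABTS oxidized per minute, i.e. Units.  Negative slopes are clamped to 0
    (activity is physically non-negative) with a warning.
    """
    if fit.qc_flag not in (QC_OK, QC_FLAT):
        raise ValueError(f"cannot convert a fit with qc_flag={fit.qc_flag!r} to activity")
    slope = fit.slope
    if slope < 0:
        warnings.warn("negative slope clamped to zero activity", stacklevel=2)
        slope = 0.0
    volume_l = params.reaction_volume_ul * 1e-6
    rate_molar = slope / (params.epsilon * params.path_length_cm)  # M / min
    return rate_molar * volume_l * 1e6 * params.dilution_factor  # µmol / min


def _validate_layout(layout: pd.DataFrame) -> pd.DataFrame:
    required = {"well", "strain_id", "replicate_id", "role"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"layout is missing columns: {sorted(missing)}")
    dup = layout["well"][layout["well"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate wells in layout: {sorted(set(dup))}")
    bad = set(layout["role"]) - set(LAYOUT_ROLES)
    if bad:
        raise ValueError(f"unknown layout roles {sorted(bad)}; allowed: {LAYOUT_ROLES}")
    return layout


def quantify_plate(
    traces: Mapping[str, KineticTrace] | Iterable[KineticTrace],
    layout: pd.DataFrame,
    params: KineticsParams,
    od600: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Quantify every non-blank well of a plate.

    Parameters
    ----------
    traces
        Mapping well id -> KineticTrace (an iterable of traces is keyed by
        their ``well_id``).
    layout
        DataFrame with columns ``well, strain_id, replicate_id, role`` where
        role is one of ``sample``, ``reference``, ``blank``.
    params
        Kinetics parameters.  When ``params.subtract_blank`` is set, the mean
        slope of blank wells is subtracted from each sample/reference slope
        before unit conversion.
    od600
        Optional mapping well id -> OD600, carried through to the output.

    Returns
    -------
    DataFrame with columns ``strain_id, replicate_id, well, slope, r2,
    window_start, window_end, qc, activity_U, od600``.
    """
    if not isinstance(traces, Mapping):
        traces = {tr.well_id: tr for tr in traces}
    layout = _validate_layout(layout)
    missing = [w for w in layout["well"] if w not in traces]
    if missing:
        raise ValueError(f"layout wells missing from traces: {missing}")

    fits = {w: trim_to_linear(traces[w], params) for w in layout["well"]}

    blank_slope = 0.0
    blank_wells = layout.loc[layout["role"] == "blank", "well"]
    if params.subtract_blank and len(blank_wells):
        usable = [fits[w].slope for w in blank_wells if fits[w].qc_flag in (QC_OK, QC_FLAT)]
        if usable:
            blank_slope = float(np.mean(usable))

    rows = []
    for row in layout.itertuples(index=False):
        if row.role == "blank":
            continue
        fit = fits[row.well]
        clamped = False
        if fit.qc_flag in (QC_OK, QC_FLAT):
            adj_slope = fit.slope - blank_slope
            adj = LinearFit(fit.start_index, fit.end_index, adj_slope, fit.intercept, fit.r_squared, fit.qc_flag)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                activity = activity_from_fit(adj, params)
            clamped = adj_slope < 0
        else:
            activity = np.nan
        rows.append(
            {
                "strain_id": row.strain_id,
                "replicate_id": row.replicate_id,
                "well": row.well,
                "slope": fit.slope - (blank_slope if fit.qc_flag in (QC_OK, QC_FLAT) else 0.0),
                "r2": fit.r_squared,
                "window_start": fit.start_index,
                "window_end": fit.end_index,
                "qc": fit.qc_flag,
                "activity_U": activity,
                "od600": (od600 or {}).get(row.well, np.nan),
                "clamped": clamped,
            }
        )
    return pd.DataFrame(rows)
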