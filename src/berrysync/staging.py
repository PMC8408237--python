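"""Image-derived growth staging of single berries.

Projected berry areas are converted to volumes, each growth profile is
normalised to its softening volume (set to 1), the post-softening growth
peak is located, and every sampled berry is assigned a developmental stage:

* ``V`` -- veraison/softening, the onset of sugar accumulation;
* ``G`` -- growing at full speed between softening and the growth peak;
* ``P`` -- at (or within a small tolerance of) the growth peak, where
  phloem unloading arrests;
* ``S`` -- shrivelling, two weeks or more past the peak.

The softening date is an observed input (it is scored visually on the
plant); it is never inferred from the volume series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StagingRules",
    "BerryTrajectory",
    "estimate_volume",
    "normalize_growth",
    "detect_peak",
    "assign_stage",
    "stage_cohort",
    "read_growth_tsv",
    "trajectories_from_table",
    "write_staging_tsv",
]

#: Ordering used by the stage-monotonicity invariant.
STAGE_ORDER = {"V": 0, "G": 1, "P": 2, "S": 3}


class StagingError(ValueError):
    """Raised when a trajectory cannot be staged (e.g. softening outside range)."""


@dataclass(frozen=True)
class StagingRules:
    """Decision thresholds for stage assignment.

    g_gain : minimum relative volume gain reached within 14 d of softening
        for a berry to count as "growing at full speed" (default 0.4,
        i.e. v >= 1.4).
    p_tol : half-width (days) of the peak window for stage P.
    s_delay : minimum days past the peak for stage S.
    v_tol : half-width (days) of the softening window for stage V.
    """

    g_gain: float = 0.4
    p_tol: float = 3.0
    s_delay: float = 14.0
    v_tol: float = 2.0
    g_window: float = 14.0


@dataclass
class BerryTrajectory:
    """Dated volume series for one berry.

    ``days`` are calendar day offsets (float, strictly increasing);
    ``volume`` is in mL.  ``relative_volume`` is volume divided by the
    (interpolated) softening volume.  ``peak_day`` is derived by
    :func:`detect_peak`; ``peak_reached`` is False while the series is
    still rising through its last observation.
    """

    berry_id: str
    days: np.ndarray
    volume: np.ndarray
    softening_day: float
    relative_volume: np.ndarray | None = None
    peak_day: float | None = None
    peak_reached: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.volume.shape:
            raise ValueError("days and volume must be 1-D arrays of equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError(f"berry {self.berry_id}: dates must be strictly increasing")
        if np.any(self.volume <= 0):
            raise ValueError(f"berry {self.berry_id}: volumes must be positive")

    @property
    def n_obs(self) -> int:
        return int(self.days.size)

    def volume_at(self, day: float) -> float:
        """Linear interpolation inside the observed range (no extrapolation)."""
        if day < self.days[0] or day > self.days[-1]:
            raise StagingError(
                f"berry {self.berry_id}: day {day} outside observed range "
                f"[{self.days[0]}, {self.days[-1]}]"
            )
        return float(np.interp(day, self.days, self.volume))

    def relative_volume_at(self, day: float) -> float:
        if self.relative_volume is None:
            raise StagingError(f"berry {self.berry_id}: call normalize_growth first")
        if day < self.days[0] or day > self.days[-1]:
            raise StagingError(f"berry {self.berry_id}: day {day} outside observed range")
        return float(np.interp(day, self.days, self.relative_volume))


def estimate_volume(area=None, axes=None, mode: str = "equivalent_sphere"):
    """Convert a projected area (cm^2) or ellipse axes (cm) to a volume (mL).

    equivalent_sphere : r = sqrt(A / pi), V = (4/3) pi r^3.
    prolate_spheroid  : from diameters d1 >= d2, V = (pi/6) d1 d2^2.

    Scalars or numpy arrays are accepted.
    """
    if mode == "equivalent_sphere":
        if area is None:
            raise ValueError("equivalent_sphere mode requires a projected area")
        area = np.asarray(area, dtype=float)
        if np.any(area <= 0):
            raise ValueError("projected area must be positive")
        r = np.sqrt(area / math.pi)
        out = (4.0 / 3.0) * math.pi * r**3
    elif mode == "prolate_spheroid":
        if axes is None:
            raise ValueError("prolate_spheroid mode requires (d1, d2) diameters")
        d1, d2 = (np.asarray(a, dtype=float) for a in axes)
        if np.any(d1 <= 0) or np.any(d2 <= 0):
            raise ValueError("axes must be positive")
        lo, hi = np.minimum(d1, d2), np.maximum(d1, d2)
        out = (math.pi / 6.0) * hi * lo**2
    else:
        raise ValueError(f"unknown volume mode {mode!r}")
    return float(out) if np.ndim(out) == 0 else out


def normalize_growth(traj: BerryTrajectory, softening_day: float | None = None) -> np.ndarray:
    """Divide the volume series by the (interpolated) softening volume.

    Sets ``traj.relative_volume`` and returns it.  Scale-invariant: scaling
    all volumes by c > 0 leaves the result unchanged.
    """
    if softening_day is None:
        softening_day = traj.softening_day
    if softening_day < traj.days[0] or softening_day > traj.days[-1]:
        raise StagingError(
            f"berry {traj.berry_id}: softening day {softening_day} outside observations"
        )
    v_soft = float(np.interp(softening_day, traj.days, traj.volume))
    traj.softening_day = float(softening_day)
    traj.relative_volume = traj.volume / v_soft
    return traj.relative_volume


def _median3(x: np.ndarray) -> np.ndarray:
    """Running median of 3 with edge values replicated (nearest mode)."""
    if x.size < 3:
        return x.copy()
    padded = np.concatenate([x[:1], x, x[-1:]])
    return np.median(np.lib.stride_tricks.sliding_window_view(padded, 3), axis=1)


def detect_peak(traj: BerryTrajectory, smoother: str = "median3"):
    """Locate the post-softening growth peak.

    Returns the day of maximum (smoothed) volume, with ties broken to the
    earliest date.  If the series is still rising through its final
    observation the peak has not been reached yet: ``peak_reached`` is set
    False and ``None`` is returned (this is a flag, not an error).
    """
    if traj.n_obs < 3:
        raise StagingError(f"berry {traj.berry_id}: need >=3 observations to detect a peak")
    if smoother == "median3":
        smoothed = _median3(traj.volume)
    elif smoother == "none":
        smoothed = traj.volume
    else:
        raise ValueError(f"unknown smoother {smoother!r}")
    idx = int(np.argmax(smoothed))  # argmax returns the first maximum: earliest tie
    if idx == smoothed.size - 1:
        traj.peak_reached = False
        traj.peak_day = None
        return None
    traj.peak_reached = True
    traj.peak_day = float(traj.days[idx])
    return traj.peak_day


def _is_fast_growing(traj: BerryTrajectory, rules: StagingRules) -> bool:
    """True when the berry gained >= g_gain in relative volume within
    ``g_window`` days of softening ("growing at full speed")."""
    probe = min(traj.softening_day + rules.g_window, traj.days[-1])
    return traj.relative_volume_at(probe) - 1.0 >= rules.g_gain


def assign_stage(
    traj: BerryTrajectory,
    sampling_day: float,
    rules: StagingRules | None = None,
) -> str:
    """Assign V/G/P/S (or "unstaged") at a sampling date.

    Precedence P > G: a date that falls in both the peak window and the
    growth window is called P.  Requires normalised growth and an attempted
    peak detection.
    """
    rules = rules or StagingRules()
    if traj.relative_volume is None:
        normalize_growth(traj)
    peak = traj.peak_day
    if peak is not None and abs(sampling_day - peak) <= rules.p_tol:
        return "P"
    if peak is not None and sampling_day - peak >= rules.s_delay:
        return "S"
    if abs(sampling_day - traj.softening_day) <= rules.v_tol:
        return "V"
    upper = peak - rules.p_tol if peak is not None else traj.days[-1]
    if traj.softening_day < sampling_day < upper and _is_fast_growing(traj, rules):
        return "G"
    return "unstaged"


def stage_cohort(
    trajectories,
    sampling_days: dict,
    rules: StagingRules | None = None,
    smoother: str = "median3",
) -> pd.DataFrame:
    """Normalise, detect peaks and stage every berry of a cohort.

    ``sampling_days`` maps berry_id -> sampling day.  Returns a tidy frame
    with softening/peak days, the assigned stage, the relative volume at
    sampling and the days-from-peak audit column.
    """
    rules = rules or StagingRules()
    rows = []
    for traj in trajectories:
        normalize_growth(traj)
        detect_peak(traj, smoother=smoother)
        day = sampling_days[traj.berry_id]
        stage = assign_stage(traj, day, rules)
        rows.append(
            {
                "berry_id": traj.berry_id,
                "softening_day": traj.softening_day,
                "peak_day": traj.peak_day if traj.peak_reached else np.nan,
                "peak_reached": traj.peak_reached,
                "sampling_day": day,
                "stage": stage,
                "v_at_sampling": traj.relative_volume_at(day),
                "days_from_peak": (day - traj.peak_day) if traj.peak_day is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSV I/O


def read_growth_tsv(path) -> pd.DataFrame:
    """Read a growth table (berry_id, date, area_cm2 [, axis1_cm, axis2_cm,
    px_per_cm, softening_date]).  Dates are ISO-8601 or numeric day offsets."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"berry_id", "date"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    return df


def _days_from_dates(dates: pd.Series) -> tuple[np.ndarray, pd.Timestamp | None]:
    if pd.api.types.is_numeric_dtype(dates):
        return dates.to_numpy(dtype=float), None
    ts = pd.to_datetime(dates)
    origin = ts.min()
    return (ts - origin).dt.total_seconds().to_numpy() / 86400.0, origin


def trajectories_from_table(
    df: pd.DataFrame,
    softening: dict | None = None,
    mode: str = "equivalent_sphere",
) -> list[BerryTrajectory]:
    """Build trajectories from a growth table.

    Softening days come from ``softening`` (berry_id -> day/date) or from a
    ``softening_date`` column.  Areas in cm^2 are converted through
    :func:`estimate_volume`; a ``px_per_cm`` column rescales pixel areas.
    """
    days_all, origin = _days_from_dates(df["date"])
    df = df.assign(_day=days_all)
    out = []
    for berry_id, sub in df.groupby("berry_id", sort=True):
        sub = sub.sort_values("_day")
        if mode == "prolate_spheroid":
            vol = estimate_volume(axes=(sub["axis1_cm"], sub["axis2_cm"]), mode=mode)
        else:
            area = sub["area_cm2"].to_numpy(dtype=float)
            if "px_per_cm" in sub.columns and sub["px_per_cm"].notna().all():
                area = area / sub["px_per_cm"].to_numpy(dtype=float) ** 2
            vol = estimate_volume(area=area, mode=mode)
        if softening is not None:
            soft = softening[berry_id]
        elif "softening_date" in sub.columns:
            soft = sub["softening_date"].iloc[0]
        else:
            raise StagingError(f"berry {berry_id}: no softening date provided")
        if origin is not None and not isinstance(soft, (int, float)):
            soft = (pd.to_datetime(soft) - origin).total_seconds() / 86400.0
        out.append(
            BerryTrajectory(
                berry_id=str(berry_id),
                days=sub["_day"].to_numpy(),
                volume=np.asarray(vol, dtype=float),
                softening_day=float(soft),
                meta={"volume_mode": mode},
            )
        )
    return out


def write_staging_tsv(staged: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# berrysync staging: days are offsets (d); volumes relative to softening=1\n")
        staged.to_csv(fh, sep="\t", index=False)
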