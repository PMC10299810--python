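"""Microscopy quantification: nucleus rotation, positioning, filamentation dose-response.

Implements the statistics applied to fluorescence time-lapse measurements of
the phage nucleus and the PhuZ tubulin spindle:

* rotation speed of a tracked surface landmark (total frame-to-frame path
  length divided by rotation time) and the corresponding angular velocity
  (path length divided by the nucleus radius, per unit time, in °/s);
* nucleus positioning as the pole-distance / cell-length ratio, with the
  nucleus scored against one or two host nucleoid intervals;
* filament calling at ≥ 2× background fluorescence and a four-parameter
  Hill (log-agonist vs. response) fit of filamentation percentage against
  inducer (arabinose) concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RotationTrack",
    "CellGeometry",
    "DoseResponseData",
    "DoseResponseFit",
    "rotation_speed",
    "angular_velocity",
    "rotating_fraction",
    "positioning_ratio",
    "nucleoid_context",
    "call_filament",
    "fit_dose_response",
    "hill_response",
    "load_tracks_csv",
    "load_geometries_csv",
    "load_dose_response_csv",
    "summarize_tracks",
]

SINGLE_NUCLEOID = "single_nucleoid"
BETWEEN_TWO = "between_two"
NOT_BETWEEN_TWO = "not_between_two"
UNSUPPORTED = "unsupported"


@dataclass(frozen=True)
class RotationTrack:
    """A tracked point on the nucleus surface over a time lapse.

    ``t`` in seconds (strictly increasing, ≥ 2 points), ``x``/``y`` in nm,
    ``nucleus_radius`` in nm (half the nucleus diameter).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    nucleus_radius: float
    track_id: str = ""

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(t) == len(x) == len(y)):
            raise ValueError("t, x, y must have equal length")
        if len(t) < 2:
            raise ValueError("a track needs at least 2 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.nucleus_radius > 0:
            raise ValueError("nucleus_radius must be > 0")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def path_length(self, chord_correction: bool = False) -> float:
        """Total distance traveled, summing consecutive frame-to-frame steps.

        With ``chord_correction=True`` each chord ``d`` is converted to the
        arc it subtends on a circle of the nucleus radius,
        ``2 r asin(d / 2r)``; chords longer than the diameter are clipped to
        the half circle.  The default reports the raw chord sum, i.e. the
        segmented-line measurement made on the images.
        """
        steps = np.hypot(np.diff(self.x), np.diff(self.y))
        if chord_correction:
            r = self.nucleus_radius
            steps = 2 * r * np.arcsin(np.clip(steps / (2 * r), 0.0, 1.0))
        return float(steps.sum())


def rotation_speed(track: RotationTrack, chord_correction: bool = False) -> tuple[float, float]:
    """Linear rotation speed (nm/s) and rotation time (s).

    Speed is the total distance traveled by the tracked point divided by the
    rotation time (last minus first timestamp).
    """
    duration = track.duration
    if duration <= 0:
        raise ValueError("track duration must be positive")
    return track.path_length(chord_correction) / duration, duration


@dataclass(frozen=True)
class AngularVelocity:
    """Total rotation angle (degrees) and its rate (degrees per second)."""

    total_angle_deg: float
    omega_deg_per_s: float


def angular_velocity(track: RotationTrack, chord_correction: bool = False) -> AngularVelocity:
    """Angular velocity: total path over the nucleus radius, per second, in °/s.

    The total traveled distance divided by the radius is the swept angle in
    radians; dividing by the rotation time and converting to degrees gives
    the rate.  Both the raw angle and the rate are returned (exactly
    ``omega * r * pi/180 == linear speed`` since both derive from the same
    path length).
    """
    duration = track.duration
    if duration <= 0:
        raise ValueError("track duration must be positive")
    angle_deg = math.degrees(track.path_length(chord_correction) / track.nucleus_radius)
    return AngularVelocity(total_angle_deg=angle_deg, omega_deg_per_s=angle_deg / duration)


def rotating_fraction(rotating_flags: Iterable[bool]) -> tuple[float, int]:
    """Percentage of cells with an actively rotating nucleus, with cohort size n."""
    flags = [bool(f) for f in rotating_flags]
    n = len(flags)
    if n < 1:
        raise ValueError("at least one cell is required")
    return 100.0 * sum(flags) / n, n


@dataclass(frozen=True)
class CellGeometry:
    """Single-cell geometry: length, nucleus position and nucleoid intervals, in µm.

    ``nucleus_center`` is measured from the designated pole (position 0);
    ``nucleoid_intervals`` are (start, end) spans of the host chromosome(s),
    non-overlapping and within the cell.
    """

    cell_length: float
    nucleus_center: float
    nucleoid_intervals: tuple[tuple[float, float], ...] = ()
    cell_id: str = ""

    def __post_init__(self):
        if not self.cell_length > 0:
            raise ValueError("cell_length must be > 0")
        if not (0 <= self.nucleus_center <= self.cell_length):
            raise ValueError("nucleus_center must lie within [0, cell_length]")
        ivs = tuple(sorted((float(a), float(b)) for a, b in self.nucleoid_intervals))
        for a, b in ivs:
            if not (0 <= a < b <= self.cell_length):
                raise ValueError(f"nucleoid interval ({a}, {b}) outside cell or empty")
        for (_, b1), (a2, _) in zip(ivs, ivs[1:]):
            if a2 < b1:
                raise ValueError("nucleoid intervals overlap")
        object.__setattr__(self, "nucleoid_intervals", ivs)


def positioning_ratio(geometry: CellGeometry, pole_policy: str = "nearer") -> float:
    """Nucleus position as pole distance over cell length.

    ``pole_policy="nearer"`` measures from the nearer pole, giving a ratio in
    [0, 0.5] with 0.5 = midcell and symmetry to pole labeling;
    ``"designated"`` measures from pole 0 (ratio in [0, 1]), for time-lapse
    consistency.
    """
    d0 = geometry.nucleus_center
    if pole_policy == "nearer":
        d = min(d0, geometry.cell_length - d0)
    elif pole_policy == "designated":
        d = d0
    else:
        raise ValueError(f"pole_policy must be 'nearer' or 'designated', got {pole_policy!r}")
    return d / geometry.cell_length


def nucleoid_context(geometry: CellGeometry) -> str:
    """Score the nucleus against the host nucleoid layout.

    One nucleoid interval → ``single_nucleoid``.  Two intervals →
    ``between_two`` iff the nucleus center lies strictly inside the
    inter-nucleoid gap (boundary contact counts as ``not_between_two``).
    More than two intervals is reported as ``unsupported``; zero intervals
    raises.
    """
    ivs = geometry.nucleoid_intervals
    if len(ivs) == 0:
        raise ValueError("geometry has no nucleoid intervals")
    if len(ivs) == 1:
        return SINGLE_NUCLEOID
    if len(ivs) > 2:
        return UNSUPPORTED
    gap_lo, gap_hi = ivs[0][1], ivs[1][0]
    return BETWEEN_TWO if gap_lo < geometry.nucleus_center < gap_hi else NOT_BETWEEN_TWO


def call_filament(max_line_intensity: float, background_intensity: float) -> bool:
    """A filament is a visible line at least double the background fluorescence (inclusive)."""
    if not background_intensity > 0:
        raise ValueError("background_intensity must be > 0")
    return max_line_intensity >= 2.0 * background_intensity


def hill_response(conc: np.ndarray, bottom: float, top: float,
                  log_ec50: float, hill: float) -> np.ndarray:
    """Four-parameter log-agonist vs. response curve.

    ``response(c) = bottom + (top - bottom) / (1 + 10^((log_ec50 - log10 c) * hill))``
    with *conc* already on the log10 scale here (callers pass log10 c).
    """
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - conc) * hill))


@dataclass(frozen=True)
class DoseResponseData:
    """Filamentation counts per inducer concentration.

    Concentrations are arabinose mass fractions (%, w/v); at each one,
    ``n_with_filaments`` of ``n_cells`` scored cells showed a PhuZ filament.
    """

    concentrations: np.ndarray
    n_cells: np.ndarray
    n_with_filaments: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        n = np.asarray(self.n_cells, dtype=int)
        k = np.asarray(self.n_with_filaments, dtype=int)
        if not (len(c) == len(n) == len(k)):
            raise ValueError("arrays must have equal length")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(n < 1):
            raise ValueError("n_cells must be >= 1 at every concentration")
        if np.any((k < 0) | (k > n)):
            raise ValueError("need 0 <= n_with_filaments <= n_cells")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "n_cells", n)
        object.__setattr__(self, "n_with_filaments", k)

    @property
    def response_percent(self) -> np.ndarray:
        return 100.0 * self.n_with_filaments / self.n_cells


@dataclass
class DoseResponseFit:
    """Least-squares Hill-fit results: parameters, uncertainties and diagnostics."""

    bottom: float
    top: float
    log_ec50: float
    hill: float
    stderr: dict[str, float]
    rmse: float
    residuals: np.ndarray
    zero_floor: float | None
    success: bool = True
    message: str = "converged"

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    def predict(self, concentrations: np.ndarray) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        if self.zero_floor is not None:
            c = np.where(c <= 0, self.zero_floor, c)
        return hill_response(np.log10(c), self.bottom, self.top, self.log_ec50, self.hill)

    def summary(self) -> str:
        lines = [
            "Hill dose-response fit ([agonist] vs. response, 4 parameters)",
            f"  status: {'ok' if self.success else 'FAILED'} ({self.message})",
            f"  bottom  = {self.bottom:10.4g} %   +/- {self.stderr.get('bottom', float('nan')):.3g}",
            f"  top     = {self.top:10.4g} %   +/- {self.stderr.get('top', float('nan')):.3g}",
            f"  logEC50 = {self.log_ec50:10.4g}     +/- {self.stderr.get('log_ec50', float('nan')):.3g}",
            f"  EC50    = {self.ec50:10.4g}",
            f"  hill    = {self.hill:10.4g}     +/- {self.stderr.get('hill', float('nan')):.3g}",
            f"  RMSE    = {self.rmse:10.4g} %",
        ]
        return "\n".join(lines)


def fit_dose_response(
    data: DoseResponseData,
    zero_floor: float | None = None,
    weights: str = "binomial",
    max_nfev: int = 10000,
) -> DoseResponseFit:
    """Fit the four-parameter Hill curve to filamentation percentages.

    Zero concentrations cannot enter a log-dose model; they are mapped to
    ``zero_floor`` (default: one decade below the smallest nonzero
    concentration).  With ``weights="binomial"`` (default) the least-squares
    fit is iteratively reweighted by the binomial standard error of each
    percentage implied by the fitted curve — the proper chi-square for
    proportions of counted cells; ``weights="none"`` gives the plain
    unweighted fit.  Degenerate data (all responses equal, or fewer than 4
    distinct concentrations for 4 parameters) yields a fit flagged
    ``success=False`` with a diagnostic message rather than a silent result.
    """
    if weights not in ("binomial", "none"):
        raise ValueError("weights must be 'binomial' or 'none'")
    c = data.concentrations.copy()
    nonzero = c[c > 0]
    if nonzero.size == 0:
        raise ValueError("at least one nonzero concentration is required")
    if zero_floor is None:
        zero_floor = float(nonzero.min()) / 10.0
    c = np.where(c <= 0, zero_floor, c)
    logc = np.log10(c)
    y = data.response_percent

    def _failed(msg: str) -> DoseResponseFit:
        return DoseResponseFit(
            bottom=float("nan"), top=float("nan"), log_ec50=float("nan"),
            hill=float("nan"), stderr={}, rmse=float("nan"),
            residuals=np.full_like(y, np.nan), zero_floor=zero_floor,
            success=False, message=msg,
        )

    if len(np.unique(data.concentrations)) < 4:
        return _failed("need >= 4 distinct concentrations for a 4-parameter fit")
    if np.allclose(y, y[0]):
        return _failed("flat response: all percentages equal, curve is unidentifiable")

    p0 = (float(y.min()), float(y.max()), float(np.median(logc)), 1.0)
    bounds = ([-10.0, -10.0, logc.min() - 3, 0.05], [110.0, 110.0, logc.max() + 3, 20.0])
    try:
        popt, pcov = curve_fit(hill_response, logc, y, p0=p0, bounds=bounds, max_nfev=max_nfev)
        if weights == "binomial":
            for _ in range(2):
                phat = np.clip(hill_response(logc, *popt) / 100.0, 0.01, 0.99)
                sigma = 100.0 * np.sqrt(phat * (1 - phat) / data.n_cells)
                popt, pcov = curve_fit(hill_response, logc, y, p0=tuple(popt), bounds=bounds,
                                       sigma=sigma, max_nfev=max_nfev)
    except RuntimeError as exc:
        return _failed(f"optimizer did not converge: {exc}")
    resid = y - hill_response(logc, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    names = ("bottom", "top", "log_ec50", "hill")
    return DoseResponseFit(
        bottom=float(popt[0]), top=float(popt[1]), log_ec50=float(popt[2]),
        hill=float(popt[3]),
        stderr={k: float(e) for k, e in zip(names, perr)},
        rmse=rmse, residuals=resid, zero_floor=zero_floor,
    )


# ---------------------------------------------------------------------------
# tabular I/O


def load_tracks_csv(points_path: str | Path, meta_path: str | Path) -> list[RotationTrack]:
    """Load tracks from a points CSV (track_id,t_s,x_nm,y_nm) and a metadata
    CSV (track_id,nucleus_radius_nm)."""
    pts = pd.read_csv(points_path, comment="#")
    meta = pd.read_csv(meta_path, comment="#").set_index("track_id")
    tracks = []
    for tid, grp in pts.groupby("track_id", sort=True):
        grp = grp.sort_values("t_s")
        if tid not in meta.index:
            raise ValueError(f"track {tid!r} missing from metadata table")
        tracks.append(
            RotationTrack(
                t=grp["t_s"].to_numpy(), x=grp["x_nm"].to_numpy(), y=grp["y_nm"].to_numpy(),
                nucleus_radius=float(meta.loc[tid, "nucleus_radius_nm"]),
                track_id=str(tid),
            )
        )
    return tracks


def load_geometries_csv(path: str | Path) -> list[CellGeometry]:
    """Load cell geometries from CSV.

    Columns: cell_id, length_um, nucleus_center_um, nucleoids (semicolon-joined
    ``start:end`` pairs in µm; empty for none).
    """
    df = pd.read_csv(path, comment="#", dtype={"nucleoids": str})
    out = []
    for _, row in df.iterrows():
        ivs: list[tuple[float, float]] = []
        raw = row.get("nucleoids", "")
        if isinstance(raw, str) and raw.strip():
            for part in raw.split(";"):
                a, b = part.split(":")
                ivs.append((float(a), float(b)))
        out.append(
            CellGeometry(
                cell_length=float(row["length_um"]),
                nucleus_center=float(row["nucleus_center_um"]),
                nucleoid_intervals=tuple(ivs),
                cell_id=str(row["cell_id"]),
            )
        )
    return out


def load_dose_response_csv(path: str | Path) -> DoseResponseData:
    """Load a dose-response CSV with columns concentration, n_cells, n_filamented."""
    df = pd.read_csv(path, comment="#")
    return DoseResponseData(
        concentrations=df["concentration"].to_numpy(float),
        n_cells=df["n_cells"].to_numpy(int),
        n_with_filaments=df["n_filamented"].to_numpy(int),
    )


def summarize_tracks(tracks: Sequence[RotationTrack],
                     chord_correction: bool = False) -> pd.DataFrame:
    """Per-track rotation statistics: speed (nm/s), duration (s), total angle
    (deg) and angular velocity (°/s)."""
    rows = []
    for tr in tracks:
        speed, duration = rotation_speed(tr, chord_correction)
        ang = angular_velocity(tr, chord_correction)
        rows.append(
            {
                "track_id": tr.track_id,
                "n_points": len(tr.t),
                "duration_s": duration,
                "nucleus_radius_nm": tr.nucleus_radius,
                "speed_nm_s": speed,
                "total_angle_deg": ang.total_angle_deg,
                "omega_deg_s": ang.omega_deg_per_s,
            }
        )
    return pd.DataFrame(rows)
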