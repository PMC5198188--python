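"""Time-series-level preprocessing for resting-state ROI signals.

Stage order used by the pipeline: discard initial volumes (signal
stabilization), motion screening, linear detrend, ideal band-pass
(0.01-0.08 Hz by default), then nuisance regression.  The band-pass is
an exact frequency-domain projection (Fourier coefficients outside the
band zeroed), so applying it twice equals applying it once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _linear_detrend

from .models import RoiTimeSeries

__all__ = [
    "MotionParams",
    "MotionScreenResult",
    "read_motion_params",
    "discard_initial_volumes",
    "screen_motion",
    "remove_linear_trend",
    "bandpass",
    "regress_nuisance",
    "preprocess_series",
]

TRANSLATION_AXES = ("trans_x", "trans_y", "trans_z")
ROTATION_AXES = ("rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class MotionParams:
    """Per-timepoint rigid-body motion: translations (mm) and rotations (degrees)."""

    translations_mm: np.ndarray  # (T, 3)
    rotations_deg: np.ndarray  # (T, 3)

    def __post_init__(self) -> None:
        t = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        r = np.atleast_2d(np.asarray(self.rotations_deg, dtype=float))
        if t.shape[1] != 3 or r.shape[1] != 3 or t.shape[0] != r.shape[0]:
            raise ValueError("motion parameters must be T x 3 translations and T x 3 rotations")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
            raise ValueError("motion parameters must be finite")
        object.__setattr__(self, "translations_mm", t)
        object.__setattr__(self, "rotations_deg", r)

    @property
    def n_timepoints(self) -> int:
        return self.translations_mm.shape[0]

    def as_matrix(self) -> np.ndarray:
        """T x 6 matrix: translations (mm) then rotations (degrees)."""
        return np.hstack([self.translations_mm, self.rotations_deg])


@dataclass(frozen=True)
class MotionScreenResult:
    passed: bool
    offending_axes: tuple[str, ...]
    max_translation_mm: float
    max_rotation_deg: float


def read_motion_params(path, convention: str = "mcflirt") -> MotionParams:
    """Read a whitespace-delimited 6-column motion-parameter file.

    convention="mcflirt": FSL MCFLIRT ``.par`` layout — three rotations
    in radians followed by three translations in mm (converted here to
    degrees / mm).  convention="trans_mm_rot_deg": three translations in
    mm then three rotations in degrees, no conversion.
    """
    table = np.loadtxt(path, ndmin=2)
    if table.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, found {table.shape[1]}")
    if convention == "mcflirt":
        rotations = np.degrees(table[:, :3])
        translations = table[:, 3:]
    elif convention == "trans_mm_rot_deg":
        translations = table[:, :3]
        rotations = table[:, 3:]
    else:
        raise ValueError(f"unknown motion convention {convention!r}")
    return MotionParams(translations_mm=translations, rotations_deg=rotations)


def discard_initial_volumes(ts: RoiTimeSeries, n: int = 10) -> RoiTimeSeries:
    """Drop the first ``n`` volumes (BOLD steady-state stabilization)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if ts.n_timepoints <= n:
        raise ValueError(
            f"cannot discard {n} volumes from a series of length {ts.n_timepoints}"
        )
    return ts.with_data(ts.data[n:])


def screen_motion(
    mp: MotionParams,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> MotionScreenResult:
    """Flag subjects whose head motion exceeds the displacement thresholds.

    A subject fails if any translation axis exceeds ``max_translation_mm``
    in absolute value at any timepoint, or any rotation axis exceeds
    ``max_rotation_deg``.  Values exactly at the threshold pass ("no more
    than" 2.0 mm / 2.0 degrees).
    """
    offending = []
    t_max = np.max(np.abs(mp.translations_mm), axis=0)
    r_max = np.max(np.abs(mp.rotations_deg), axis=0)
    for axis, value in zip(TRANSLATION_AXES, t_max):
        if value > max_translation_mm:
            offending.append(axis)
    for axis, value in zip(ROTATION_AXES, r_max):
        if value > max_rotation_deg:
            offending.append(axis)
    return MotionScreenResult(
        passed=not offending,
        offending_axes=tuple(offending),
        max_translation_mm=float(t_max.max()),
        max_rotation_deg=float(r_max.max()),
    )


def remove_linear_trend(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Subtract the least-squares line (intercept + slope) from each channel."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    return ts.with_data(_linear_detrend(ts.data, axis=0, type="linear"))


def bandpass(
    ts: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> RoiTimeSeries:
    """Ideal frequency-domain band-pass filter.

    Real-FFT coefficients at frequencies outside the closed band
    ``[low_hz, high_hz]`` are zeroed and the series inverse-transformed.
    This is a projection: the filter is exactly idempotent, and with
    ``low_hz > 0`` the DC component (channel mean) is removed.
    """
    nyq = ts.nyquist
    if not (0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyq:
        raise ValueError(f"high_hz {high_hz} exceeds the Nyquist frequency {nyq}")
    t = ts.n_timepoints
    freqs = np.fft.rfftfreq(t, d=ts.dt)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(ts.data, axis=0)
    spectrum[~keep] = 0.0
    return ts.with_data(np.fft.irfft(spectrum, n=t, axis=0))


def _collinear_columns(design: np.ndarray) -> list[int]:
    """Indices of design columns that are (numerically) linear combinations
    of the others."""
    bad = []
    full_rank = np.linalg.matrix_rank(design)
    for j in range(design.shape[1]):
        reduced = np.delete(design, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            bad.append(j)
    return bad


def regress_nuisance(ts: RoiTimeSeries, covariates: np.ndarray) -> RoiTimeSeries:
    """Residualize every channel on the covariates (plus an intercept).

    Typical covariates: white-matter and CSF mean signals and the six
    head-motion parameters.  Residuals are orthogonal to every covariate
    column (and mean-zero, since the intercept is always included).
    """
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != ts.n_timepoints:
        raise ValueError("covariates must have one row per timepoint")
    if cov.shape[1] >= ts.n_timepoints:
        raise ValueError("more covariates than timepoints")
    design = np.column_stack([np.ones(ts.n_timepoints), cov])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = [j - 1 for j in _collinear_columns(design) if j > 0]
        raise ValueError(
            f"rank-deficient nuisance design; collinear covariate columns: {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, ts.data, rcond=None)
    return ts.with_data(ts.data - design @ beta)


def preprocess_series(
    ts: RoiTimeSeries,
    n_discard: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    covariates: np.ndarray | None = None,
    motion: MotionParams | None = None,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> RoiTimeSeries:
    """Full preprocessing chain: discard -> (screen) -> detrend -> band-pass
    -> nuisance regression.

    Motion screening, when motion parameters are provided, raises on
    failure rather than silently keeping a high-motion subject.  The
    motion table is expected to cover the same volumes as ``ts`` (i.e.
    already trimmed of discarded volumes, or longer — a longer table is
    trimmed from the front to match).
    """
    out = discard_initial_volumes(ts, n=n_discard) if n_discard else ts
    if motion is not None:
        mp = motion
        extra = mp.n_timepoints - out.n_timepoints
        if extra > 0:
            mp = MotionParams(
                translations_mm=mp.translations_mm[extra:],
                rotations_deg=mp.rotations_deg[extra:],
            )
        result = screen_motion(mp, max_translation_mm, max_rotation_deg)
        if not result.passed:
            raise ValueError(
                f"subject {ts.subject_id or '<unnamed>'} fails motion screening "
                f"on axes {result.offending_axes}"
            )
    out = remove_linear_trend(out)
    if low_hz is not None and high_hz is not None:
        out = bandpass(out, low_hz=low_hz, high_hz=high_hz)
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == ts.n_timepoints and n_discard:
            cov = cov[n_discard:]
        out = regress_nuisance(out, cov)
    return out
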