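"""Fourier-spectrum autofocus and scan-axis calibration.

The focus metric works on a single fluorescence image: take the 2-D power
spectrum, resample it on a polar grid, average over the angular dimension,
take the logarithm, and count how many radial-frequency bins rise above a
noise-derived threshold (mean + 3 sigma of the high-frequency baseline
band). Sharper images carry more power at high spatial frequencies, so the
count grows with sharpness. The largest above-threshold radius F also
yields a resolution estimate r = image_dim * pixel_dim / (2 F): half the
wavelength of the finest resolved frequency.

A focus sweep acquires images at a ladder of axial beam offsets (default
41 planes, 1 μm apart), normalizes the counts to [0, 1], fits a Gaussian,
and takes the fitted center as the best focus. Running sweeps at five
detection-objective (DO) positions and interpolating the resulting
(DO position, beam voltage) knots with a cubic gives the nonlinear
DO→beam-command calibration used by the waveform generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from skimage.transform import warp_polar

from .errors import (
    CalibrationDomainError,
    CalibrationError,
    DegenerateSweepError,
    EmptyImageError,
    FocusFitError,
    ResolutionUndefinedError,
)

#: Camera pixel size in μm used by default in the resolution formula.
DEFAULT_PIXEL_DIM = 0.405

#: Fraction of the highest radial-frequency bins treated as the noise
#: baseline when setting the threshold. Real images carry no signal there.
DEFAULT_BASELINE_FRACTION = 0.25

N_ANGULAR_BINS = 360


# ---------------------------------------------------------------------------
# Radial log spectrum and focus measure
# ---------------------------------------------------------------------------

@dataclass
class RadialSpectrum:
    """Angle-averaged log power spectrum on a polar radius grid.

    ``radii`` are pixel distances after the polar transform, starting at 1
    (the DC bin is excluded); ``values`` is log(mean power + eps) per bin.
    """

    values: np.ndarray
    radii: np.ndarray
    n_radial_bins: int
    n_angular_bins: int


@dataclass
class FocusMeasure:
    """Focus metric for one image.

    ``count``: number of radial bins above threshold (the sharpness score).
    ``f_max``: largest above-threshold radius (0 when count == 0) — the
    maximum resolved frequency component used in the resolution formula.
    """

    count: int
    f_max: int
    threshold: float


def radial_log_spectrum(image) -> RadialSpectrum:
    """Angle-averaged log power spectrum of a 2-D image.

    The power spectrum is fft-shifted, resampled on a polar grid with one
    radial bin per pixel distance up to floor(min(H, W)/2) and 360 angular
    bins (bilinear interpolation), averaged over angle, and
    log-transformed with an epsilon floor of 1e-12 x max(power). The DC
    bin is excluded.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be 2-D")
    if min(image.shape) < 16:
        raise ValueError("image must be at least 16x16")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    if (image < 0).any():
        raise ValueError("image must be non-negative")
    if not image.any():
        raise EmptyImageError("empty image")

    power = np.abs(np.fft.fftshift(np.fft.fft2(image))) ** 2
    h, w = power.shape
    center = (h // 2, w // 2)  # DC lands here after fftshift (even or odd dims)
    eps = 1e-12 * power.max()  # DC included: guaranteed > 0 for non-empty images
    # Zero DC before resampling: bilinear interpolation at small radii would
    # otherwise leak the (huge) DC power into the first bins.
    power[center] = 0.0
    n_radii = min(h, w) // 2
    polar = warp_polar(
        power,
        center=center,
        radius=n_radii,
        output_shape=(N_ANGULAR_BINS, n_radii),
        order=1,
    )
    profile = polar.mean(axis=0)
    values = np.log(profile[1:] + eps)  # drop DC bin
    radii = np.arange(1, n_radii)
    return RadialSpectrum(
        values=values,
        radii=radii,
        n_radial_bins=len(radii),
        n_angular_bins=N_ANGULAR_BINS,
    )


def focus_measure(image, baseline_fraction: float = DEFAULT_BASELINE_FRACTION) -> FocusMeasure:
    """Count of radial log-spectrum bins above the noise threshold.

    The threshold is mean + 3 x stdev over the baseline band: the outer
    ``baseline_fraction`` of radial bins, where real images are noise
    dominated. Invariant under multiplicative intensity scaling (both the
    spectrum and the threshold shift by the same log constant).
    """
    spec = radial_log_spectrum(image)
    n_base = max(2, int(round(baseline_fraction * spec.n_radial_bins)))
    baseline = spec.values[-n_base:]
    threshold = float(baseline.mean() + 3.0 * baseline.std())
    above = spec.values > threshold
    count = int(above.sum())
    f_max = int(spec.radii[above][-1]) if count else 0
    return FocusMeasure(count=count, f_max=f_max, threshold=threshold)


def estimate_resolution(image_dim: int, pixel_dim: float, f_max: int) -> float:
    """Image resolution in μm: half the wavelength of the finest resolved
    frequency, r = image_dim * pixel_dim / (2 * f_max).

    ``image_dim`` is the (shorter) image dimension in pixels, ``pixel_dim``
    the camera pixel size in μm/px, ``f_max`` the largest above-threshold
    radial bin (pixel distance after the polar transform).
    """
    if f_max < 1:
        raise ResolutionUndefinedError("f_max must be >= 1; no resolved frequency")
    return image_dim * pixel_dim / (2.0 * f_max)


# ---------------------------------------------------------------------------
# Sweep normalization and Gaussian best-focus fit
# ---------------------------------------------------------------------------

def normalize_measures(raw) -> np.ndarray:
    """Affine map of raw focus counts to [0, 1] (0 = worst, 1 = best)."""
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size < 3:
        raise ValueError("need at least 3 measures to normalize")
    span = raw.max() - raw.min()
    if span == 0:
        raise DegenerateSweepError("all focus measures are equal; sweep is degenerate")
    return (raw - raw.min()) / span


@dataclass
class GaussianFit:
    amplitude: float
    center: float
    width: float
    offset: float


def _gaussian(x, amplitude, center, width, offset):
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * width**2)) + offset


def fit_best_focus(positions, normalized, min_r_squared: float = 0.5):
    """Bounded least-squares Gaussian fit; returns (fit, best_position).

    The fitted center is the best focal position and must lie inside the
    swept range. Raises :class:`FocusFitError` when the optimizer fails,
    the center escapes the swept range, the width collapses onto its floor
    (a one-sample spike, not a focus peak), or the fit explains less than
    ``min_r_squared`` of the variance.
    """
    x = np.asarray(positions, dtype=np.float64)
    y = np.asarray(normalized, dtype=np.float64)
    if x.size < 5:
        raise ValueError("need at least 5 sweep points to fit")
    if np.ptp(y) == 0:
        raise DegenerateSweepError("normalized measures are all equal")
    span = float(x.max() - x.min())
    step = float(np.median(np.abs(np.diff(np.sort(x)))))
    width_floor = 0.5 * step
    p0 = [1.0, float(x[np.argmax(y)]), span / 4.0, 0.0]
    bounds = (
        [0.05, x.min() - span, width_floor, -1.0],
        [2.0, x.max() + span, 2.0 * span, 1.0],
    )
    try:
        popt, _ = curve_fit(_gaussian, x, y, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as exc:
        raise FocusFitError(f"Gaussian fit did not converge: {exc}") from exc
    fit = GaussianFit(*map(float, popt))
    residuals = y - _gaussian(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - float((residuals**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    if r_squared < min_r_squared:
        raise FocusFitError(
            f"Gaussian fit unreliable (R^2 = {r_squared:.3f} < {min_r_squared})"
        )
    if fit.width <= width_floor * 1.001:
        raise FocusFitError("fitted width collapsed to a single-sample spike")
    if not (x.min() <= fit.center <= x.max()):
        raise FocusFitError(
            f"fitted center {fit.center:.2f} μm lies outside the swept range"
        )
    return fit, fit.center


@dataclass
class FocusSweepResult:
    """Full record of one autofocus sweep."""

    positions: np.ndarray          # μm beam offsets relative to the linear estimate
    raw: np.ndarray                # integer focus counts per position
    measures: list                 # FocusMeasure per position
    normalized: np.ndarray         # counts mapped to [0, 1]
    fit: GaussianFit
    best_position: float           # μm, fitted Gaussian center


def run_focus_sweep(
    camera,
    do_position: float,
    n_planes: int = 41,
    step: float = 1.0,
) -> FocusSweepResult:
    """Sweep the axial beam offset and locate the best focus.

    Acquires exactly ``n_planes`` images at offsets centered on the
    current (linear-estimate) beam position, spaced ``step`` μm apart,
    via ``camera.acquire(do_position, beam_offset_um)``; computes the
    focus measure per image, normalizes, and fits a Gaussian. Degenerate
    sweeps and unreliable fits raise; the caller may widen the sweep.
    """
    offsets = (np.arange(n_planes) - (n_planes - 1) / 2.0) * step
    measures = []
    for off in offsets:
        image = camera.acquire(do_position, float(off))
        measures.append(focus_measure(image))
    raw = np.array([m.count for m in measures], dtype=np.int64)
    normalized = normalize_measures(raw)
    fit, best = fit_best_focus(offsets, normalized)
    return FocusSweepResult(
        positions=offsets,
        raw=raw,
        measures=measures,
        normalized=normalized,
        fit=fit,
        best_position=best,
    )


# ---------------------------------------------------------------------------
# DO-position → beam-voltage calibration
# ---------------------------------------------------------------------------

class CalibrationFunction:
    """Cubic interpolant through measured (DO position, beam voltage) knots.

    Evaluation is exact at every knot and refuses to extrapolate outside
    the knot domain. ``max_dev_from_linear`` reports the largest deviation
    (V) of the interpolant from the straight line through the first and
    last knots — the size of the scan-axis nonlinearity the calibration
    corrects.
    """

    def __init__(self, knots: Sequence[tuple]):
        knots = sorted((float(d), float(v)) for d, v in knots)
        if len(knots) < 2:
            raise ValueError("calibration needs at least 2 knots")
        xs = np.array([k[0] for k in knots])
        vs = np.array([k[1] for k in knots])
        if np.any(np.diff(xs) <= 0):
            raise ValueError("knot DO positions must be distinct")
        self.knots = knots
        self._xs = xs
        self._vs = vs
        if len(knots) >= 3:
            # not-a-knot matches scipy.interpolate.interp1d(kind="cubic")
            self._spline: Callable = CubicSpline(xs, vs, bc_type="not-a-knot")
        else:
            slope = (vs[1] - vs[0]) / (xs[1] - xs[0])
            self._spline = lambda x: vs[0] + (np.asarray(x) - xs[0]) * slope
        self.max_dev_from_linear = self._max_dev_from_linear()

    @classmethod
    def from_knots(cls, knots) -> "CalibrationFunction":
        return cls(knots)

    @property
    def domain(self) -> tuple:
        return (self._xs[0], self._xs[-1])

    def _linear(self, x):
        x0, x1 = self._xs[0], self._xs[-1]
        v0, v1 = self._vs[0], self._vs[-1]
        return v0 + (np.asarray(x, dtype=np.float64) - x0) * (v1 - v0) / (x1 - x0)

    def _max_dev_from_linear(self) -> float:
        grid = np.linspace(self._xs[0], self._xs[-1], 1001)
        return float(np.max(np.abs(np.asarray(self._spline(grid)) - self._linear(grid))))

    def eval(self, do_position):
        """Beam command voltage for DO position(s) in μm (no extrapolation)."""
        x = np.asarray(do_position, dtype=np.float64)
        lo, hi = self.domain
        if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
            raise CalibrationDomainError(
                f"DO position outside calibration domain [{lo}, {hi}] μm"
            )
        out = np.asarray(self._spline(np.clip(x, lo, hi)), dtype=np.float64)
        return float(out) if np.isscalar(do_position) else out

    __call__ = eval

    def __eq__(self, other):
        return isinstance(other, CalibrationFunction) and self.knots == other.knots

    def __repr__(self):
        return (
            f"CalibrationFunction({len(self.knots)} knots, "
            f"domain=[{self._xs[0]:g}, {self._xs[-1]:g}] μm, "
            f"max_dev_from_linear={self.max_dev_from_linear:.4g} V)"
        )


def calibrate_axial_mapping(
    camera,
    scan,
    n_do_positions: int = 5,
    sweep_planes: int = 41,
    sweep_step: float = 1.0,
) -> CalibrationFunction:
    """Measure the DO-position → beam-voltage mapping for one beam.

    Runs one focus sweep at each of ``n_do_positions`` evenly spaced DO
    positions over [do_start, do_end], converts each best beam offset to
    a command voltage through the linear gain, and interpolates the knots
    with a cubic. A failing sweep aborts the calibration, naming the DO
    position at which it failed.
    """
    do_positions = np.linspace(scan.do_start, scan.do_end, n_do_positions)
    gain = scan.beam_gain
    knots = []
    for do_pos in do_positions:
        try:
            sweep = run_focus_sweep(
                camera, float(do_pos), n_planes=sweep_planes, step=sweep_step
            )
        except (DegenerateSweepError, FocusFitError, EmptyImageError) as exc:
            raise CalibrationError(
                f"calibration aborted: focus sweep failed at DO position "
                f"{do_pos:.2f} μm ({exc})"
            ) from exc
        volt = scan.linear_beam_volt(float(do_pos)) + sweep.best_position * gain
        knots.append((float(do_pos), volt))
    return CalibrationFunction.from_knots(knots)
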