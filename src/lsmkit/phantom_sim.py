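"""Synthetic brain phantom and simulated camera.

The phantom emulates a nuclear-labelled larval-zebrafish brain: bright
Gaussian-profile nuclei (radii ~2–2.5 μm, diameters under 5 μm) at
non-overlapping random positions over a dim background. The simulated
camera renders 2-D planes from it with a defocus model that is the
ground truth for the autofocus and calibration modules: the rendered
blur grows linearly with the misalignment between the commanded axial
beam voltage and the voltage the (hidden) true DO→beam mapping demands,

    sigma_px = base_blur + blur_gain * |misalignment_um|,

so the focus-vs-misalignment curve is unimodal with its peak exactly at
zero misalignment. Shot noise (Poisson) and Gaussian read noise are
added at levels small enough not to break that unimodality. All
randomness flows from a single seed; rendering is deterministic given
(seed, plane, misalignment), so every test is reproducible.

The blur is an isotropic Gaussian, not an optical PSF: it is a monotone
sharpness ground truth, not a diffraction model.
"""

from __future__ import annotations

import threading
import time
from dataclasses import dataclass
from typing import Callable, List, Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import PhantomPackingError
from .stream_acquisition import Frame


@dataclass
class Nucleus:
    x: float          # μm
    y: float          # μm
    z: float          # μm
    radius: float     # μm (Gaussian profile sigma = radius / 2)
    brightness: float


@dataclass
class BrainPhantom:
    volume: np.ndarray       # (z, y, x) float32 intensities
    voxel_size: float        # μm, isotropic
    nuclei: List[Nucleus]
    seed: int

    @property
    def extent_um(self):
        return tuple(s * self.voxel_size for s in self.volume.shape)


def generate_phantom(
    seed: int,
    n_nuclei: int = 600,
    dims=(256, 160, 160),
    voxel_size: float = 1.0,
    background: float = 10.0,
    brightness_range=(600.0, 1200.0),
    radius_range=(2.0, 2.5),
    margin: float = 4.0,
    max_tries_per_nucleus: int = 1000,
) -> BrainPhantom:
    """Place Gaussian-profile nuclei at non-overlapping random centres.

    Centres are drawn uniformly inside the volume (keeping ``margin`` μm
    off the faces) and rejected while they overlap an already placed
    nucleus (centre distance below the radius sum plus 1 μm). Identical
    seeds give bit-identical volumes. Raises
    :class:`PhantomPackingError` when a centre cannot be placed within
    ``max_tries_per_nucleus`` draws (volume too crowded).
    """
    if n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    dims = tuple(int(d) for d in dims)
    if len(dims) != 3 or min(dims) < 32:
        raise ValueError("dims must be a 3-tuple with every dimension >= 32")
    rng = np.random.default_rng(seed)
    extent = np.array(dims, dtype=np.float64) * voxel_size  # (z, y, x) μm

    centers: List[np.ndarray] = []
    radii: List[float] = []
    for _ in range(n_nuclei):
        for _try in range(max_tries_per_nucleus):
            r = rng.uniform(*radius_range)
            c = rng.uniform(margin, extent - margin)  # (z, y, x)
            ok = all(
                np.linalg.norm(c - c2) >= r + r2 + 1.0
                for c2, r2 in zip(centers, radii)
            )
            if ok:
                centers.append(c)
                radii.append(r)
                break
        else:
            raise PhantomPackingError(
                f"could not place nucleus {len(centers) + 1}/{n_nuclei} after "
                f"{max_tries_per_nucleus} tries: volume too crowded"
            )

    volume = np.full(dims, background, dtype=np.float32)
    nuclei = []
    for c, r in zip(centers, radii):
        brightness = float(rng.uniform(*brightness_range))
        sigma_vox = (r / 2.0) / voxel_size
        half = max(2, int(np.ceil(4 * sigma_vox)))
        idx_c = c / voxel_size
        lo = np.maximum(np.floor(idx_c).astype(int) - half, 0)
        hi = np.minimum(np.floor(idx_c).astype(int) + half + 1, dims)
        zz, yy, xx = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        d2 = (zz - idx_c[0]) ** 2 + (yy - idx_c[1]) ** 2 + (xx - idx_c[2]) ** 2
        volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (
            brightness * np.exp(-d2 / (2.0 * sigma_vox**2))
        ).astype(np.float32)
        nuclei.append(
            Nucleus(x=float(c[2]), y=float(c[1]), z=float(c[0]),
                    radius=float(r), brightness=brightness)
        )
    return BrainPhantom(volume=volume, voxel_size=voxel_size, nuclei=nuclei, seed=seed)


# ---------------------------------------------------------------------------
# Ground-truth DO→beam-voltage mappings
# ---------------------------------------------------------------------------

def linear_mapping(scan) -> Callable[[float], float]:
    """Perfectly linear rig: the linear fallback is already correct."""
    return lambda z: scan.linear_beam_volt(z)


def offset_mapping(scan, offset_um: float) -> Callable[[float], float]:
    """Linear rig with a constant beam misalignment of ``offset_um`` μm."""
    gain = scan.beam_gain
    return lambda z: scan.linear_beam_volt(z) + offset_um * gain


def quadratic_mapping(scan, sag_v: float) -> Callable[[float], float]:
    """Quadratic nonlinearity anchored at the endpoints with a mid-range
    sag of ``sag_v`` volts — the shape a galvanometer's angle-to-position
    nonlinearity produces."""

    def mapping(z):
        u = (z - scan.do_start) / (scan.do_end - scan.do_start)
        return scan.linear_beam_volt(z) + 4.0 * sag_v * u * (1.0 - u)

    return mapping


# ---------------------------------------------------------------------------
# Simulated camera
# ---------------------------------------------------------------------------

@dataclass
class FrameSource:
    """Simulated camera rendering phantom planes with misalignment blur."""

    phantom: BrainPhantom
    scan: object
    true_mapping: Optional[Callable[[float], float]] = None
    shot_noise_scale: float = 1.0   # 0 disables shot noise
    read_noise: float = 2.0         # counts, Gaussian sigma; 0 disables
    blur_gain: float = 0.6          # px of blur sigma per μm of misalignment
    base_blur: float = 0.5          # px, in-focus blur floor
    seed: int = 0

    def __post_init__(self):
        if self.true_mapping is None:
            self.true_mapping = linear_mapping(self.scan)

    # -- rendering ---------------------------------------------------------

    def _slice_at(self, z_um: float) -> np.ndarray:
        vol = self.phantom.volume
        zf = z_um / self.phantom.voxel_size
        zf = float(np.clip(zf, 0, vol.shape[0] - 1))
        z0 = int(np.floor(zf))
        z1 = min(z0 + 1, vol.shape[0] - 1)
        w = zf - z0
        return (1.0 - w) * vol[z0] + w * vol[z1]

    def misalignment_um(self, do_position: float, commanded_v: float) -> float:
        return (commanded_v - self.true_mapping(do_position)) / self.scan.beam_gain

    def render_at(self, do_position: float, commanded_v: float) -> np.ndarray:
        """Render the focal plane at a DO position under a beam command.

        Blur sigma = base_blur + blur_gain * |misalignment|; then shot
        noise, read noise, and 16-bit quantization. Deterministic given
        (seed, plane, misalignment).
        """
        plane = self._slice_at(do_position).astype(np.float64)
        mis = self.misalignment_um(do_position, commanded_v)
        sigma = self.base_blur + self.blur_gain * abs(mis)
        if sigma > 0:
            plane = gaussian_filter(plane, sigma)
        rng = np.random.default_rng(
            [
                self.seed,
                int(round(do_position * 1000.0)) & 0x7FFFFFFF,
                int(np.float64(mis).view(np.uint64)),
            ]
        )
        if self.shot_noise_scale > 0:
            s = self.shot_noise_scale
            plane = rng.poisson(np.clip(plane, 0, None) * s) / s
        if self.read_noise > 0:
            plane = plane + rng.normal(0.0, self.read_noise, plane.shape)
        return np.clip(plane, 0, 65535).astype(np.uint16)

    def acquire(self, do_position: float, beam_offset_um: float) -> np.ndarray:
        """Autofocus camera protocol: image at a beam offset (μm) relative
        to the linear-estimate command for this DO position."""
        commanded = self.scan.linear_beam_volt(do_position) + beam_offset_um * self.scan.beam_gain
        return self.render_at(do_position, commanded)

    def render_plane(self, z_index: int, commanded_v: float,
                     volume_index: int = 0, sequence_number: int = 0) -> Frame:
        """Render plane ``z_index`` of the scan program as a Frame."""
        if not (0 <= z_index < self.scan.n_planes):
            raise ValueError(f"z_index {z_index} out of range")
        z = self.scan.plane_z(z_index)
        pixels = self.render_at(z, commanded_v)
        return Frame(
            pixels=pixels,
            volume_index=volume_index,
            plane_index=z_index,
            sequence_number=sequence_number,
            timestamp_ms=1000.0 * sequence_number / self.scan.frame_rate,
        )


def render_plane(source: FrameSource, z_index: int, commanded_beam_voltage: float) -> Frame:
    """Module-level convenience for :meth:`FrameSource.render_plane`."""
    return source.render_plane(z_index, commanded_beam_voltage)


# ---------------------------------------------------------------------------
# Frame stream (the "running camera")
# ---------------------------------------------------------------------------

class FrameStream:
    """Background thread emitting frames like a free-running camera.

    Frames carry strictly increasing gap-free sequence numbers and
    correct plane/volume indices; frame content depends only on the
    source, never on consumer speed. The internal bounded buffer models
    the camera driver's circular buffer: on overflow the oldest frame is
    overwritten and counted as a source drop (reported separately from
    writing-path drops, which are forbidden).
    """

    def __init__(
        self,
        source: FrameSource,
        n_frames: Optional[int] = None,
        realtime: bool = False,
        frame_interval_s: Optional[float] = None,
        buffer_depth: int = 4096,
    ):
        self.source = source
        self.n_frames = n_frames
        self.realtime = realtime
        self.frame_interval_s = frame_interval_s or 1.0 / source.scan.frame_rate
        self.buffer_depth = buffer_depth
        self.produced = 0
        self.source_drops = 0
        self._buf = []
        self._lock = threading.Lock()
        self._stop = threading.Event()
        self._pause = threading.Event()
        self._thread: Optional[threading.Thread] = None

    def start(self):
        if self._thread is not None:
            return
        self._thread = threading.Thread(target=self._produce, name="lsm-source")
        self._thread.start()

    def _produce(self):
        scan = self.source.scan
        single = scan.mode == "single_plane"
        t0 = time.monotonic()
        seq = 0
        while not self._stop.is_set():
            if self.n_frames is not None and seq >= self.n_frames:
                break
            if self._pause.is_set():
                time.sleep(0.001)
                continue
            if self.realtime:
                target = t0 + (seq + 1) * self.frame_interval_s
                delay = target - time.monotonic()
                if delay > 0:
                    time.sleep(delay)
            plane = 0 if single else seq % scan.n_planes
            volume = 0 if single else seq // scan.n_planes
            commanded = self.source.true_mapping(scan.plane_z(plane))
            frame = self.source.render_plane(
                plane, commanded, volume_index=volume, sequence_number=seq
            )
            with self._lock:
                if len(self._buf) >= self.buffer_depth:
                    self._buf.pop(0)
                    self.source_drops += 1
                self._buf.append(frame)
                self.produced += 1
            seq += 1

    def read(self, timeout: float = 0.0) -> Optional[Frame]:
        """Pop the oldest buffered frame, waiting up to ``timeout`` s."""
        deadline = time.monotonic() + timeout
        while True:
            with self._lock:
                if self._buf:
                    return self._buf.pop(0)
            if time.monotonic() >= deadline or self.finished:
                return None
            time.sleep(0.0005)

    def pause(self):
        self._pause.set()

    def resume(self):
        self._pause.clear()

    def stop(self):
        self._stop.set()
        if self._thread is not None:
            self._thread.join()

    @property
    def finished(self) -> bool:
        done = self._thread is not None and not self._thread.is_alive()
        with self._lock:
            return done and not self._buf


def start_stream(
    source: FrameSource,
    n_frames: Optional[int] = None,
    realtime: bool = False,
    frame_interval_s: Optional[float] = None,
    buffer_depth: int = 4096,
) -> FrameStream:
    """Create and start a frame stream from a simulated camera."""
    stream = FrameStream(
        source,
        n_frames=n_frames,
        realtime=realtime,
        frame_interval_s=frame_interval_s,
        buffer_depth=buffer_depth,
    )
    stream.start()
    return stream
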