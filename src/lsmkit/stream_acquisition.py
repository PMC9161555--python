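"""Zero-loss streaming acquisition: frame source → FIFO buffer → HDF5.

The pipeline mirrors a two-thread producer/consumer design: a reader
thread pulls frames out of the source's bounded (camera-driver-like)
circular buffer the moment they appear and appends them to an in-memory
first-in-first-out writing buffer; a writer thread drains that buffer
strictly in arrival order into uncompressed HDF5 files — one file per
volume in volumetric mode, or fixed-size chunks (default 100 frames) in
single-plane mode. The reader also taps every k-th frame into a small
overwrite-oldest preview buffer; preview losses are permitted, writing
losses never are.

Contracts: every produced frame is written exactly once, in order
(frames carry source-assigned sequence numbers so loss and ordering are
provable); the writing buffer is unbounded but monitored — if its depth
stays above a high-water mark longer than a grace period the run aborts
in a controlled way, signalling that the disk cannot sustain the camera
rate. A timestamped copy of the settings document is written beside the
output of every run.
"""

from __future__ import annotations

import itertools
import os
import queue
import threading
import time
from collections import deque
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Iterator, Optional

import h5py
import numpy as np

from .errors import BufferOverrunError

_run_counter = itertools.count()


@dataclass
class Frame:
    """One camera frame with provenance indices.

    ``sequence_number`` is assigned by the source and strictly increases
    across a run; ``plane_index`` cycles through [0, n_planes).
    """

    pixels: np.ndarray        # 2-D uint16
    volume_index: int
    plane_index: int
    sequence_number: int
    timestamp_ms: float


@dataclass
class AcquisitionStats:
    produced: int = 0
    written: int = 0
    dropped: int = 0            # writing-path drops; zero on every successful run
    source_drops: int = 0       # camera-buffer overwrites, reported separately
    files_written: int = 0
    max_write_buffer_depth: int = 0
    run_duration: float = 0.0   # s
    run_dir: str = ""


# ---------------------------------------------------------------------------
# Preview tap
# ---------------------------------------------------------------------------

class PreviewBuffer:
    """Bounded overwrite-oldest buffer feeding the display path.

    Unlike the writing FIFO, old previews are discarded when the consumer
    lags — display only ever wants recent frames.
    """

    def __init__(self, depth: int = 16):
        self._buf: deque = deque(maxlen=depth)
        self._lock = threading.Lock()
        self.pushed = 0

    def push(self, frame: Frame) -> None:
        with self._lock:
            self._buf.append(frame)
            self.pushed += 1

    def pop(self) -> Optional[Frame]:
        with self._lock:
            return self._buf.popleft() if self._buf else None

    def latest(self) -> Optional[Frame]:
        with self._lock:
            return self._buf[-1] if self._buf else None

    def __len__(self):
        with self._lock:
            return len(self._buf)


def preview_tap(frames: Iterable[Frame], every_k: int) -> Iterator[Frame]:
    """Yield every k-th frame of a stream (positions 0, k, 2k, ...)."""
    if every_k < 1:
        raise ValueError("every_k must be >= 1")
    for i, frame in enumerate(frames):
        if i % every_k == 0:
            yield frame


# ---------------------------------------------------------------------------
# HDF5 file output
# ---------------------------------------------------------------------------

def finalize_file(frames, path, metadata: Optional[dict] = None) -> None:
    """Write frames to one uncompressed HDF5 file.

    Layout: a single 3-D dataset ``frames`` of shape (n, rows, cols),
    uint16, uncompressed, plus per-frame ``sequence_numbers``,
    ``plane_indices`` and ``timestamps_ms`` datasets and scalar
    attributes from ``metadata``. A failed write removes the partial
    file.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("finalize_file needs at least one frame")
    path = str(path)
    try:
        with h5py.File(path, "w") as f:
            stack = np.stack([np.asarray(fr.pixels, dtype=np.uint16) for fr in frames])
            f.create_dataset("frames", data=stack)  # no compression: write speed first
            f.create_dataset(
                "sequence_numbers",
                data=np.array([fr.sequence_number for fr in frames], dtype=np.int64),
            )
            f.create_dataset(
                "plane_indices",
                data=np.array([fr.plane_index for fr in frames], dtype=np.int32),
            )
            f.create_dataset(
                "timestamps_ms",
                data=np.array([fr.timestamp_ms for fr in frames], dtype=np.float64),
            )
            f.attrs["n_frames"] = len(frames)
            for key, value in (metadata or {}).items():
                f.attrs[key] = value
    except Exception:
        if os.path.exists(path):
            os.remove(path)
        raise


def load_frames(path):
    """Read back one acquisition file: (pixel stack, sequence numbers, attrs)."""
    with h5py.File(str(path), "r") as f:
        return f["frames"][...], f["sequence_numbers"][...], dict(f.attrs)


def iter_run_files(run_dir):
    """Acquisition files of a run directory in write order."""
    names = sorted(
        n for n in os.listdir(str(run_dir))
        if n.endswith(".h5") and (n.startswith("vol_") or n.startswith("chunk_"))
    )
    return [os.path.join(str(run_dir), n) for n in names]


# ---------------------------------------------------------------------------
# The acquisition loop
# ---------------------------------------------------------------------------

def _default_high_water(scan) -> int:
    if scan.mode == "single_plane":
        return max(400, 4 * scan.single_plane_chunk)
    return 2 * scan.n_planes


def run_acquisition(
    source,
    scan,
    out_dir,
    stop_after_frames: Optional[int] = None,
    stop_after_s: Optional[float] = None,
    preview: Optional[PreviewBuffer] = None,
    preview_every: int = 1,
    writer_delay_s: float = 0.0,
    high_water: Optional[int] = None,
    grace_s: float = 5.0,
    settings_doc=None,
    run_name: Optional[str] = None,
) -> AcquisitionStats:
    """Run the full reader/writer pipeline until a stop condition.

    ``source`` follows the frame-stream protocol (``start``, ``read``,
    ``stop``, ``finished``, ``produced``, ``source_drops``) — see
    :class:`lsmkit.phantom_sim.FrameStream`. Exactly one of
    ``stop_after_frames`` / ``stop_after_s`` must be given.
    ``writer_delay_s`` throttles the writer per frame (used to emulate
    slow disks in benchmarks). Returns statistics; raises
    :class:`BufferOverrunError` if the writing buffer stays above
    ``high_water`` frames for more than ``grace_s`` seconds.
    """
    if (stop_after_frames is None) == (stop_after_s is None):
        raise ValueError("give exactly one of stop_after_frames / stop_after_s")
    if high_water is None:
        high_water = _default_high_water(scan)

    run_name = run_name or (
        f"run_{datetime.now().strftime('%Y%m%d-%H%M%S')}_{next(_run_counter):03d}"
    )
    run_dir = os.path.join(str(out_dir), run_name)
    os.makedirs(run_dir, exist_ok=True)

    # settings snapshot with time log, beside the data
    from .scan_model import SettingsDocument, write_settings_copy

    write_settings_copy(settings_doc or SettingsDocument(scan=scan), run_dir)

    write_q: queue.Queue = queue.Queue()
    stats = AcquisitionStats(run_dir=run_dir)
    stats_lock = threading.Lock()
    reader_done = threading.Event()
    abort = threading.Event()
    abort_reason = []

    chunk_size = scan.n_planes if scan.mode == "volumetric" else scan.single_plane_chunk

    def reader():
        taken = 0
        t0 = time.monotonic()
        over_since = None
        try:
            while not abort.is_set():
                if stop_after_frames is not None and taken >= stop_after_frames:
                    source.stop()
                    break
                if stop_after_s is not None and time.monotonic() - t0 >= stop_after_s:
                    source.stop()
                    break
                frame = source.read(timeout=0.05)
                if frame is None:
                    if source.finished:
                        break
                    continue
                write_q.put(frame)
                if preview is not None and frame.sequence_number % preview_every == 0:
                    preview.push(frame)
                taken += 1
                depth = write_q.qsize()
                with stats_lock:
                    stats.max_write_buffer_depth = max(stats.max_write_buffer_depth, depth)
                if depth > high_water:
                    over_since = over_since or time.monotonic()
                    if time.monotonic() - over_since > grace_s:
                        abort_reason.append(
                            f"write buffer above high-water mark ({high_water} frames) "
                            f"for more than {grace_s} s: disk too slow"
                        )
                        abort.set()
                        source.stop()
                        break
                else:
                    over_since = None
            # drain whatever the source buffered before it stopped
            if not abort.is_set():
                while True:
                    frame = source.read(timeout=0.01)
                    if frame is None:
                        if source.finished:
                            break
                        continue
                    write_q.put(frame)
                    taken += 1
        finally:
            reader_done.set()

    def writer():
        pending = []
        file_index = 0
        next_write = time.monotonic()
        while not abort.is_set():
            try:
                frame = write_q.get(timeout=0.05)
            except queue.Empty:
                if reader_done.is_set() and write_q.empty():
                    break
                continue
            pending.append(frame)
            if writer_delay_s:
                # absolute schedule: frame k is written no earlier than
                # t0 + k * writer_delay_s; transient stalls (file turnover)
                # are caught up instead of accumulating backlog
                next_write += writer_delay_s
                delay = next_write - time.monotonic()
                if delay > 0:
                    time.sleep(delay)
            if len(pending) >= chunk_size:
                _flush(pending, file_index)
                pending = []
                file_index += 1
        if pending and not abort.is_set():
            _flush(pending, file_index)  # remainder at stop → short final file

    def _flush(pending, file_index):
        if scan.mode == "volumetric":
            name = f"vol_{pending[0].volume_index:06d}.h5"
            meta = {"volume_index": pending[0].volume_index}
        else:
            name = f"chunk_{file_index:06d}.h5"
            meta = {"chunk_index": file_index}
        meta.update(n_planes=scan.n_planes, exposure=scan.exposure, mode=scan.mode)
        finalize_file(pending, os.path.join(run_dir, name), meta)
        with stats_lock:
            stats.written += len(pending)
            stats.files_written += 1

    t_start = time.monotonic()
    source.start()
    reader_t = threading.Thread(target=reader, name="lsm-reader")
    writer_t = threading.Thread(target=writer, name="lsm-writer")
    reader_t.start()
    writer_t.start()
    reader_t.join()
    writer_t.join()
    source.stop()

    stats.produced = source.produced
    stats.source_drops = source.source_drops
    stats.run_duration = time.monotonic() - t_start
    if abort_reason:
        raise BufferOverrunError(abort_reason[0], stats=stats)
    return stats
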