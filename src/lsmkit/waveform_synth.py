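"""Synchronized per-volume control waveforms.

One volumetric scan is driven by a bundle of sample trains that share a
single output clock (default 50 kHz):

* a camera trigger train whose pulse amplitudes encode volume boundaries
  (first plane 4.5 V, middle planes 4.0 V, last plane 3.5 V — all above
  the 3.3 V threshold, so behaviour software listening on the same line
  can count volumes by amplitude thresholding);
* a continuous piezo ramp moving the detection objective, circularly
  advanced by a user-set delay (10–20 ms typical) to compensate the
  piezo's mechanical lag;
* axial beam commands that track the objective, either as a linear ramp
  between the configured voltage endpoints or warped through a measured
  calibration function;
* a fast sheet-forming sweep confined to the centre of each exposure so
  the beam only paints the sample while the rolling shutter is fully
  open;
* laser gate trains (the side-beam gate carries the eye exclusion).

Continuous (rather than step-wise) axial motion matters because the piezo
cannot accelerate the objective with sub-millisecond accuracy; the ramp
plus a smooth flyback over the final 5% of the period avoids the
accelerations a staircase would demand.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from .errors import ConfigError


@dataclass
class TriggerTrain:
    """Camera trigger pulses with amplitude-encoded volume boundaries."""

    samples: np.ndarray        # V at sample_rate
    pulse_starts: np.ndarray   # sample index of each pulse
    pulse_amplitudes: np.ndarray  # V per pulse
    sample_rate: float


@dataclass
class AnalogTrain:
    samples: np.ndarray  # V at sample_rate
    label: str
    sample_rate: float


@dataclass
class GateTrain:
    samples: np.ndarray  # boolean, True = laser on
    label: str
    sample_rate: float


@dataclass
class WaveformBundle:
    """All trains for one volume on a common clock, equal length."""

    trigger: TriggerTrain
    piezo: AnalogTrain
    beam_axial_side: AnalogTrain
    beam_axial_front: AnalogTrain
    beam_sheet: AnalogTrain
    gate_side: GateTrain
    gate_front: GateTrain
    sample_rate: float


# ---------------------------------------------------------------------------
# Camera triggers
# ---------------------------------------------------------------------------

def build_camera_triggers(scan) -> TriggerTrain:
    """One pulse per plane; amplitudes [first, mid, ..., mid, last].

    Pulse ``i`` starts at round(i * sample_rate / frame_rate). A single
    plane (n_planes == 1) emits one pulse at the first-plane amplitude:
    the start-of-volume marker is what downstream behaviour software keys
    on. Pulse width is ``scan.trigger_pulse_width`` ms; overlap is
    rejected by config validation.
    """
    if scan.n_planes < 1:
        raise ConfigError("n_planes", "n_planes must be >= 1")
    n = scan.samples_per_volume
    samples = np.full(n, scan.trigger_low, dtype=np.float64)
    width = max(1, int(round(scan.trigger_pulse_width * scan.sample_rate / 1000.0)))
    amplitudes = np.full(scan.n_planes, scan.trigger_amp_mid, dtype=np.float64)
    amplitudes[0] = scan.trigger_amp_first
    if scan.n_planes > 1:
        amplitudes[-1] = scan.trigger_amp_last
    starts = np.array(
        [scan.plane_start_sample(i) for i in range(scan.n_planes)], dtype=np.int64
    )
    for start, amp in zip(starts, amplitudes):
        samples[start : min(start + width, n)] = amp
    return TriggerTrain(
        samples=samples,
        pulse_starts=starts,
        pulse_amplitudes=amplitudes,
        sample_rate=scan.sample_rate,
    )


# ---------------------------------------------------------------------------
# Axial motion (piezo + beam)
# ---------------------------------------------------------------------------

def do_position_profile(scan) -> np.ndarray:
    """DO position (μm) per output sample over one steady-state period.

    Linear ramp do_start→do_end over the first (1 − flyback_fraction) of
    the volume, then a cosine-eased return over the flyback window. The
    waveform is periodic: the sample after the last equals the first.
    """
    n = scan.samples_per_volume
    n_fly = int(round(scan.flyback_fraction * n))
    n_scan = n - n_fly
    pos = np.empty(n, dtype=np.float64)
    pos[:n_scan] = np.linspace(scan.do_start, scan.do_end, n_scan)
    if n_fly:
        phase = np.arange(1, n_fly + 1) / n_fly  # ends exactly at do_start
        pos[n_scan:] = scan.do_start + (scan.do_end - scan.do_start) * 0.5 * (
            1.0 + np.cos(np.pi * phase)
        )
    return pos


def build_piezo_command(scan) -> AnalogTrain:
    """Continuous piezo ramp in commanded volts, advanced by piezo_delay.

    The delay is a circular shift of the steady-state periodic waveform —
    scanning is continuous, so advancing the command simply rotates the
    period — sized so the objective's mechanical motion lines up with the
    beam despite the drive's lag.
    """
    if scan.piezo_delay >= scan.volume_duration_ms:
        raise ConfigError("piezo_delay", "piezo_delay exceeds the volume duration")
    pos = do_position_profile(scan)
    shift = int(round(scan.piezo_delay * scan.sample_rate / 1000.0))
    commanded = scan.piezo_gain * np.roll(pos, -shift)
    return AnalogTrain(samples=commanded, label="piezo", sample_rate=scan.sample_rate)


def build_axial_beam_command(scan, calib=None, label: str = "beam_axial") -> AnalogTrain:
    """Axial beam command tracking the DO position profile.

    With a calibration present, each sample is calib.eval(DO position);
    the calibration's knot domain must cover [do_start, do_end] and
    evaluation outside it raises (no extrapolation). Without one, the
    linear fallback maps [do_start, do_end] onto
    [beam_volt_start, beam_volt_end].
    """
    pos = do_position_profile(scan)
    if calib is not None:
        lo, hi = calib.domain
        if lo > scan.do_start + 1e-9 or hi < scan.do_end - 1e-9:
            from .errors import CalibrationDomainError

            raise CalibrationDomainError(
                f"calibration domain [{lo}, {hi}] μm does not cover the scan "
                f"range [{scan.do_start}, {scan.do_end}] μm"
            )
        volts = calib.eval(pos)
    else:
        volts = scan.linear_beam_volt(pos)
    return AnalogTrain(samples=np.asarray(volts, dtype=np.float64), label=label,
                       sample_rate=scan.sample_rate)


# ---------------------------------------------------------------------------
# Fast sheet axis
# ---------------------------------------------------------------------------

def build_sheet_command(scan) -> AnalogTrain:
    """Sheet-forming sweep confined to the shutter-open window.

    Within each plane period the linear sweep from y_start to y_end (in
    commanded volts, sheet_gain V/μm) occupies only the central
    ``shutter_open_fraction`` of the exposure; the command holds at the
    sweep start before it and at the sweep end after it, then resets at
    the next plane (sawtooth with flat shoulders).
    """
    n = scan.samples_per_volume
    v_start = scan.sheet_gain * scan.y_start
    v_end = scan.sheet_gain * scan.y_end
    samples = np.full(n, v_start, dtype=np.float64)
    exp_samples = int(round(scan.exposure * scan.sample_rate / 1000.0))
    sweep_len = max(2, int(round(scan.shutter_open_fraction * exp_samples)))
    for i in range(scan.n_planes):
        s0 = scan.plane_start_sample(i)
        s1 = scan.plane_start_sample(i + 1) if i + 1 < scan.n_planes else n
        sweep_start = s0 + (exp_samples - sweep_len) // 2
        sweep_end = min(sweep_start + sweep_len, s1, n)
        samples[s0:sweep_start] = v_start
        samples[sweep_start:sweep_end] = np.linspace(
            v_start, v_end, sweep_end - sweep_start
        )
        samples[sweep_end:s1] = v_end
    return AnalogTrain(samples=samples, label="beam_sheet", sample_rate=scan.sample_rate)


def sheet_y_positions(scan, sheet: AnalogTrain) -> np.ndarray:
    """In-plane beam position (μm) per sample, via the documented V→μm gain."""
    return sheet.samples / scan.sheet_gain


# ---------------------------------------------------------------------------
# Whole-volume assembly and HDF5 export
# ---------------------------------------------------------------------------

def assemble_volume_program(
    scan, calib_side=None, calib_front=None, roi=None
) -> WaveformBundle:
    """Build every train for one volume on a common clock.

    The eye-exclusion ROI gates only the side beam; the front beam, which
    scans the narrow strip between the eyes, is never gated by it.
    """
    from .eye_exclusion import gates_for_volume  # deferred: avoids import cycle

    trigger = build_camera_triggers(scan)
    piezo = build_piezo_command(scan)
    beam_side = build_axial_beam_command(scan, calib_side, label="beam_axial_side")
    beam_front = build_axial_beam_command(scan, calib_front, label="beam_axial_front")
    sheet = build_sheet_command(scan)
    n = scan.samples_per_volume
    if roi is not None:
        gate_side = gates_for_volume(roi, scan, sheet)
    else:
        gate_side = GateTrain(np.ones(n, dtype=bool), "gate_side", scan.sample_rate)
    gate_front = GateTrain(np.ones(n, dtype=bool), "gate_front", scan.sample_rate)
    return WaveformBundle(
        trigger=trigger,
        piezo=piezo,
        beam_axial_side=beam_side,
        beam_axial_front=beam_front,
        beam_sheet=sheet,
        gate_side=gate_side,
        gate_front=gate_front,
        sample_rate=scan.sample_rate,
    )


_ANALOG_KEYS = ("trigger", "piezo", "beam_axial_side", "beam_axial_front", "beam_sheet")
_GATE_KEYS = ("gate_side", "gate_front")


def export_bundle(bundle: WaveformBundle, path) -> None:
    """Write each train as a named HDF5 dataset (float64 V / uint8 gate)."""
    with h5py.File(str(path), "w") as f:
        f.attrs["sample_rate"] = bundle.sample_rate
        for key in _ANALOG_KEYS:
            train = getattr(bundle, key)
            f.create_dataset(key, data=np.asarray(train.samples, dtype=np.float64))
        for key in _GATE_KEYS:
            train = getattr(bundle, key)
            f.create_dataset(key, data=train.samples.astype(np.uint8))
        f.create_dataset("trigger_pulse_starts", data=bundle.trigger.pulse_starts)
        f.create_dataset("trigger_pulse_amplitudes", data=bundle.trigger.pulse_amplitudes)


def load_bundle(path) -> dict:
    """Read an exported bundle back as {dataset name: array} + sample_rate."""
    out = {}
    with h5py.File(str(path), "r") as f:
        out["sample_rate"] = float(f.attrs["sample_rate"])
        for key in f.keys():
            out[key] = f[key][...]
    return out


def export_bundle_csv(bundle: WaveformBundle, path) -> None:
    """Column-per-train CSV export for eyeball inspection."""
    cols = [getattr(bundle, k).samples for k in _ANALOG_KEYS]
    cols += [getattr(bundle, k).samples.astype(np.uint8) for k in _GATE_KEYS]
    header = ",".join(_ANALOG_KEYS + _GATE_KEYS)
    np.savetxt(str(path), np.column_stack(cols), delimiter=",", header=header, comments="")
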