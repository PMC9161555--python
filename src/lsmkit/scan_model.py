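"""Scan configuration, unit conventions, and XML settings persistence.

Unit conventions used across the whole package (enforced here, documented
once): positions in micrometres (μm), times in milliseconds (ms), command
voltages in volts (V), rates in hertz (Hz).

A :class:`ScanConfig` describes one volumetric or single-plane scan
program: how many planes, how far apart, camera exposure and frame rate,
the detection-objective (DO) travel, the axial beam-command endpoints used
as the linear fallback when no calibration is available, and the trigger
amplitude encoding that lets behaviour software detect volume boundaries.

A :class:`SettingsDocument` bundles a scan program with the optional eye
exclusion ROI, the optional scan-axis calibration, and a free-form device
parameter map, and round-trips losslessly through a flat XML file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional

from lxml import etree

from .autofocus import CalibrationFunction
from .errors import ConfigError, SettingsParseError
from .eye_exclusion import EllipseROI

SETTINGS_SCHEMA_VERSION = "1"

#: Fixed μm→V gain used to express piezo commands in volts. Real rigs
#: override this with the drive's documented gain.
DEFAULT_PIEZO_GAIN = 0.1


@dataclass
class ScanConfig:
    """All parameters of one volumetric or single-plane scan program.

    Defaults reproduce the whole-brain preset: 45 planes at 5 μm spacing
    scanned at 1 volume/s (45 frames/s), with amplitude-encoded camera
    triggers (4.5 V first plane, 4.0 V middle, 3.5 V last, all above the
    3.3 V behaviour-software threshold).
    """

    n_planes: int = 45                 # planes per volume
    plane_spacing: float = 5.0         # μm between plane centers
    exposure: float = 20.0             # ms of camera exposure per plane
    frame_rate: float = 45.0           # Hz (frames per second)
    do_start: float = 10.0             # μm, detection-objective start
    do_end: float = 235.0              # μm, detection-objective end
    beam_volt_start: float = 0.0       # V, axial beam command at do_start
    beam_volt_end: float = 2.25        # V, axial beam command at do_end
    piezo_delay: float = 15.0          # ms, piezo command advance (10–20 typical)
    sample_rate: float = 50_000.0      # Hz, output sample clock for all trains
    trigger_amp_first: float = 4.5     # V, first pulse of a volume
    trigger_amp_mid: float = 4.0       # V, middle pulses
    trigger_amp_last: float = 3.5      # V, last pulse of a volume
    trigger_threshold: float = 3.3     # V, camera/behaviour trigger threshold
    trigger_low: float = 0.0           # V, inter-pulse baseline
    single_plane_chunk: int = 100      # frames per file in single-plane mode
    mode: str = "volumetric"           # "volumetric" | "single_plane"
    trigger_pulse_width: float = 1.0   # ms, trigger pulse duration
    shutter_open_fraction: float = 0.8  # fraction of exposure with shutter fully open
    flyback_fraction: float = 0.05     # fraction of volume period used for flyback
    piezo_gain: float = DEFAULT_PIEZO_GAIN  # V/μm for piezo commands
    y_start: float = 0.0               # μm, in-plane sheet sweep start
    y_end: float = 400.0               # μm, in-plane sheet sweep end
    sheet_gain: float = 0.01           # V/μm for the fast sheet axis

    def __post_init__(self):
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def volume_duration_ms(self) -> float:
        """Duration of one volume in ms (n_planes frame periods)."""
        return 1000.0 * self.n_planes / self.frame_rate

    @property
    def samples_per_volume(self) -> int:
        return int(round(self.sample_rate * self.n_planes / self.frame_rate))

    def plane_start_sample(self, i: int) -> int:
        """Output-clock sample index at which plane ``i``'s period begins."""
        return int(round(i * self.sample_rate / self.frame_rate))

    def plane_z(self, i: int) -> float:
        """Nominal axial position (μm) of plane ``i``'s center."""
        return self.do_start + i * self.plane_spacing

    @property
    def beam_gain(self) -> float:
        """Linear axial-beam gain in V/μm implied by the voltage endpoints."""
        return (self.beam_volt_end - self.beam_volt_start) / (self.do_end - self.do_start)

    def linear_beam_volt(self, do_position: float) -> float:
        """Linear-fallback beam command (V) for a DO position (μm)."""
        return self.beam_volt_start + (do_position - self.do_start) * self.beam_gain

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the violated field(s)."""
        if int(self.n_planes) != self.n_planes or self.n_planes < 1:
            raise ConfigError("n_planes", "n_planes must be an integer >= 1")
        self.n_planes = int(self.n_planes)
        if self.mode not in ("volumetric", "single_plane"):
            raise ConfigError("mode", f"unknown mode {self.mode!r}")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate", "sample_rate must be positive")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate", "frame_rate must be positive")
        if self.exposure <= 0:
            raise ConfigError("exposure", "exposure must be positive")
        if self.sample_rate * self.exposure / 1000.0 < 2:
            raise ConfigError(
                ["sample_rate", "exposure"],
                "need at least 2 output samples per plane exposure",
            )
        if self.exposure > 1000.0 / self.frame_rate + 1e-9:
            raise ConfigError(
                ["exposure", "frame_rate"],
                "exposure cannot exceed the frame period",
            )
        min_amp = min(self.trigger_amp_first, self.trigger_amp_mid, self.trigger_amp_last)
        if not (self.trigger_low < self.trigger_threshold < min_amp):
            raise ConfigError(
                ["trigger_low", "trigger_threshold", "trigger_amp_first",
                 "trigger_amp_mid", "trigger_amp_last"],
                "require trigger_low < trigger_threshold < every pulse amplitude",
            )
        if not self.do_end > self.do_start:
            raise ConfigError(["do_start", "do_end"], "do_end must exceed do_start")
        if self.plane_spacing <= 0:
            raise ConfigError("plane_spacing", "plane_spacing must be positive")
        if self.piezo_delay < 0 or self.piezo_delay >= self.volume_duration_ms:
            raise ConfigError(
                "piezo_delay", "piezo_delay must lie in [0, volume duration)"
            )
        if self.trigger_pulse_width <= 0:
            raise ConfigError("trigger_pulse_width", "pulse width must be positive")
        if self.trigger_pulse_width >= 1000.0 / self.frame_rate:
            raise ConfigError(
                ["trigger_pulse_width", "frame_rate"],
                "trigger pulses must not overlap: width must be below the frame period",
            )
        if not (0.0 < self.shutter_open_fraction <= 1.0):
            raise ConfigError("shutter_open_fraction", "must lie in (0, 1]")
        if not (0.0 <= self.flyback_fraction < 0.5):
            raise ConfigError("flyback_fraction", "must lie in [0, 0.5)")
        if self.piezo_gain <= 0:
            raise ConfigError("piezo_gain", "piezo_gain must be positive")
        if self.sheet_gain <= 0:
            raise ConfigError("sheet_gain", "sheet_gain must be positive")
        if not self.y_end > self.y_start:
            raise ConfigError(["y_start", "y_end"], "y_end must exceed y_start")
        if int(self.single_plane_chunk) != self.single_plane_chunk or self.single_plane_chunk < 1:
            raise ConfigError("single_plane_chunk", "must be an integer >= 1")
        self.single_plane_chunk = int(self.single_plane_chunk)


@dataclass
class SettingsDocument:
    """A full microscope settings file: scan program plus optional blocks."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    eye_roi: Optional[EllipseROI] = None
    calibration: Optional[CalibrationFunction] = None
    device_params: dict = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: datetime.now().isoformat(timespec="seconds"))


# ---------------------------------------------------------------------------
# XML persistence
# ---------------------------------------------------------------------------

_SCAN_FIELDS = {f.name: f.type for f in dataclasses.fields(ScanConfig)}
_INT_FIELDS = {"n_planes", "single_plane_chunk"}
_STR_FIELDS = {"mode"}


def _fmt(value) -> str:
    # repr gives shortest round-trippable decimal for floats
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _scalar_to_xml(parent, name, value):
    el = etree.SubElement(parent, "param", name=name)
    if isinstance(value, bool):
        el.set("type", "bool")
        el.text = "1" if value else "0"
    elif isinstance(value, int):
        el.set("type", "int")
        el.text = str(value)
    elif isinstance(value, float):
        el.set("type", "float")
        el.text = repr(value)
    else:
        el.set("type", "str")
        el.text = str(value)


def _scalar_from_xml(el):
    kind = el.get("type", "str")
    text = el.text or ""
    if kind == "int":
        return int(text)
    if kind == "float":
        return float(text)
    if kind == "bool":
        return text.strip() in ("1", "true", "True")
    return text


def settings_to_xml(doc: SettingsDocument) -> etree._Element:
    root = etree.Element(
        "lsm_settings", version=SETTINGS_SCHEMA_VERSION, timestamp=doc.timestamp
    )
    scan_el = etree.SubElement(root, "scan")
    for name in _SCAN_FIELDS:
        el = etree.SubElement(scan_el, name)
        el.text = _fmt(getattr(doc.scan, name))
    if doc.eye_roi is not None:
        roi_el = etree.SubElement(root, "eye_roi")
        for name in ("center_y", "center_z", "semi_y", "semi_z"):
            el = etree.SubElement(roi_el, name)
            el.text = repr(getattr(doc.eye_roi, name))
    if doc.calibration is not None:
        cal_el = etree.SubElement(root, "calibration")
        for do_pos, volt in doc.calibration.knots:
            etree.SubElement(
                cal_el, "knot", do_position=repr(float(do_pos)), voltage=repr(float(volt))
            )
    if doc.device_params:
        dev_el = etree.SubElement(root, "device_params")
        for key, value in doc.device_params.items():
            _scalar_to_xml(dev_el, key, value)
    return root


def save_settings(doc: SettingsDocument, path) -> None:
    """Write a settings document as UTF-8 XML to ``path``."""
    tree = etree.ElementTree(settings_to_xml(doc))
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def settings_from_xml(root: etree._Element) -> SettingsDocument:
    if root.tag != "lsm_settings":
        raise SettingsParseError(
            f"unexpected root element <{root.tag}>; expected <lsm_settings>"
        )
    device_params: dict = {}
    scan_el = root.find("scan")
    if scan_el is None:
        raise ConfigError(sorted(_SCAN_FIELDS), "settings file has no <scan> element")
    kwargs = {}
    missing = []
    for name in _SCAN_FIELDS:
        el = scan_el.find(name)
        if el is None or el.text is None:
            missing.append(name)
            continue
        text = el.text.strip()
        try:
            if name in _INT_FIELDS:
                kwargs[name] = int(text)
            elif name in _STR_FIELDS:
                kwargs[name] = text
            else:
                kwargs[name] = float(text)
        except ValueError as exc:
            raise SettingsParseError(
                f"cannot parse scan element <{name}>: {text!r}"
            ) from exc
    if missing:
        raise ConfigError(missing, "settings file missing mandatory scan parameter(s)")
    # unknown children of <scan> are preserved, not dropped
    for el in scan_el:
        if el.tag not in _SCAN_FIELDS and isinstance(el.tag, str):
            device_params[el.tag] = (el.text or "").strip()

    scan = ScanConfig(**kwargs)

    eye_roi = None
    roi_el = root.find("eye_roi")
    if roi_el is not None:
        vals = {}
        for name in ("center_y", "center_z", "semi_y", "semi_z"):
            el = roi_el.find(name)
            if el is None or el.text is None:
                raise SettingsParseError(f"eye_roi element missing <{name}>")
            vals[name] = float(el.text)
        eye_roi = EllipseROI(**vals)

    calibration = None
    cal_el = root.find("calibration")
    if cal_el is not None:
        knots = []
        for knot in cal_el.findall("knot"):
            try:
                knots.append((float(knot.get("do_position")), float(knot.get("voltage"))))
            except (TypeError, ValueError) as exc:
                raise SettingsParseError("malformed <knot> element in calibration") from exc
        calibration = CalibrationFunction.from_knots(knots)

    dev_el = root.find("device_params")
    if dev_el is not None:
        for el in dev_el.findall("param"):
            device_params[el.get("name")] = _scalar_from_xml(el)
    # free-form: unknown top-level elements are retained as raw strings
    for el in root:
        if el.tag not in ("scan", "eye_roi", "calibration", "device_params") and isinstance(el.tag, str):
            device_params[el.tag] = (el.text or "").strip()

    return SettingsDocument(
        scan=scan,
        eye_roi=eye_roi,
        calibration=calibration,
        device_params=device_params,
        timestamp=root.get("timestamp", ""),
    )


def load_settings(path) -> SettingsDocument:
    """Parse a settings XML file into a fully populated document.

    Raises :class:`SettingsParseError` on malformed XML (naming the
    offending element where possible) and :class:`ConfigError` when
    mandatory scan fields are absent or invalid.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SettingsParseError(f"malformed settings XML: {exc}") from exc
    return settings_from_xml(tree.getroot())


def write_settings_copy(doc: SettingsDocument, out_dir) -> str:
    """Write a timestamped copy of the settings beside acquisition output.

    Returns the path written. Every acquisition run calls this so each
    experiment carries its exact configuration with a time log.
    """
    import os

    stamp = datetime.now().strftime("%Y%m%d-%H%M%S")
    doc = dataclasses.replace(doc, timestamp=datetime.now().isoformat(timespec="seconds"))
    path = os.path.join(str(out_dir), f"settings_{stamp}.xml")
    save_settings(doc, path)
    return path
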