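"""Synthetic gait cohort generator.

Emulates a 21-subject gait study (control, diabetic neuropathy (DN), and DN with a
previous diabetic foot ulcer (DFU)) recorded on a force plate with surface EMG of
three lower-limb muscles (gastrocnemius lateralis GL, vastus lateralis VL, tibialis
anterior TA) and the three ground-reaction-force components (GRFx, GRFy, GRFz),
all sampled at 1000 Hz.

Two class effects reported for diabetic gait are built in:

* a *delayed muscle-activation peak* — the EMG activation envelope peaks later in
  the cycle for DN subjects and later still for DFU subjects;
* a *reduced second vertical-GRF peak* — the push-off hump of the M-shaped vertical
  force curve is scaled down for both patient groups.

Subjects carry random effects (a Gaussian shift of the activation-peak time and a
log-normal amplitude factor) shared by all of a subject's cycles, which is what
makes subject-wise cross-validation genuinely harder than record-wise splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError

LABELS = ("control", "DN", "DFU")
EMG_CHANNELS = ("GL", "VL", "TA")
GRF_CHANNELS = ("GRFx", "GRFy", "GRFz")
CHANNELS = EMG_CHANNELS + GRF_CHANNELS

# EMG carrier passband (Hz); matches the analysis band so preprocessing is non-degenerate
_EMG_BAND = (25.0, 499.0)
# control activation envelope peaks in late stance (push-off), at 45% of the cycle
_CONTROL_PEAK_FRAC = 0.45
_ENVELOPE_WIDTH_FRAC = 0.08
# stance occupies the first ~60% of a gait cycle; the force plate reads zero in swing
_STANCE_SPAN = (0.01, 0.61)
# vertical GRF hump centres and width, as fractions of the stance phase
_GRFZ_PEAKS = (0.30, 0.70)
_GRFZ_WIDTH = 0.10


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults are the emulated study conditions: 6 control / 6 DN / 9 DFU subjects,
    1000 Hz sampling, one-second cycles, a 60 ms (DN) / 100 ms (DFU) activation-peak
    delay and a 15% second-peak reduction of the vertical GRF.
    """

    n_control: int = 6
    n_dn: int = 6
    n_dfu: int = 9
    cycles_per_subject: int = 20
    fs: float = 1000.0
    cycle_duration: float = 1.0
    dn_peak_delay: float = 0.060
    dfu_peak_delay: float = 0.100
    second_peak_reduction: float = 0.15
    noise_sd: float = 0.05
    subject_sd: float = 0.01
    subject_amp_sd: float = 0.15
    cycle_jitter_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_dn", "n_dfu", "cycles_per_subject"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.fs <= 0:
            raise ConfigurationError(f"fs must be positive, got {self.fs}")
        if self.cycle_duration <= 0:
            raise ConfigurationError(f"cycle_duration must be positive, got {self.cycle_duration}")
        if not 0.0 <= self.second_peak_reduction < 1.0:
            raise ConfigurationError(
                f"second_peak_reduction must lie in [0, 1), got {self.second_peak_reduction}"
            )
        if self.dfu_peak_delay < self.dn_peak_delay:
            raise ConfigurationError("dfu_peak_delay must be >= dn_peak_delay")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ConfigurationError("noise_sd and subject_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.cycle_duration * self.fs))

    def class_delay(self, label: str) -> float:
        if label == "control":
            return 0.0
        if label == "DN":
            return self.dn_peak_delay
        if label == "DFU":
            return self.dfu_peak_delay
        raise ConfigurationError(f"unknown class label {label!r}")


@dataclass
class SubjectEffect:
    """Random effects shared by all cycles of one subject."""

    peak_shift: float = 0.0   # additive shift of the activation-peak time (s)
    amp_factor: float = 1.0   # multiplicative amplitude factor (log-normal)


@dataclass
class GaitRecording:
    """One subject-cycle trial: six synchronized channels plus provenance."""

    subject_id: str
    label: str
    channels: dict[str, np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ConfigurationError(f"unknown class label {self.label!r}")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ConfigurationError(f"missing channels: {missing}")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ConfigurationError(f"channel lengths differ: {lengths}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))


def activation_envelope(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    """Non-negative unimodal (Gaussian) activation envelope."""
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean broadband EMG carrier: white noise band-passed 25-499 Hz, unit RMS."""
    lo, hi = _EMG_BAND
    hi = min(hi, 0.99 * fs / 2)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synth_emg_cycle(
    label: str,
    config: CohortConfig,
    subject_effect: SubjectEffect | float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize one EMG gait cycle for a muscle of a subject with the given label.

    The signal is a zero-mean broadband carrier modulated by a non-negative Gaussian
    activation envelope whose peak time is 45% of the cycle plus the class delay plus
    the subject's random shift (plus small per-cycle jitter), with additive noise.
    """
    if label not in LABELS:
        raise ConfigurationError(f"unknown class label {label!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eff = subject_effect if isinstance(subject_effect, SubjectEffect) else SubjectEffect(float(subject_effect))
    n = config.n_samples
    T = config.cycle_duration
    t = np.arange(n) / config.fs
    center = (
        _CONTROL_PEAK_FRAC * T
        + config.class_delay(label)
        + eff.peak_shift
        + rng.normal(0.0, config.cycle_jitter_sd)
    )
    env = activation_envelope(t, center, _ENVELOPE_WIDTH_FRAC * T, eff.amp_factor)
    carrier = _bandlimited_carrier(n, config.fs, rng)
    noise = config.noise_sd * eff.amp_factor * rng.standard_normal(n)
    return carrier * env + noise


def synth_grf_cycle(
    label: str,
    config: CohortConfig,
    subject_effect: SubjectEffect | float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Synthesize the three GRF components for one gait cycle.

    The curves occupy the stance phase (the first ~60% of the cycle; the plate
    reads zero during swing). GRFz is the classic M-shaped (double-hump) stance
    curve with exact zeros at the stance boundaries; for DN/DFU its second
    (push-off) hump is scaled by ``1 - second_peak_reduction``. GRFx is a
    lower-amplitude antisymmetric braking/propulsion shear curve and GRFy a
    small mediolateral shear.
    """
    if label not in LABELS:
        raise ConfigurationError(f"unknown class label {label!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    eff = subject_effect if isinstance(subject_effect, SubjectEffect) else SubjectEffect(float(subject_effect))
    n = config.n_samples
    u = np.linspace(0.0, 1.0, n)
    lo, hi = _STANCE_SPAN
    s = np.clip((u - lo) / (hi - lo), 0.0, 1.0)  # stance-local coordinate
    on_plate = (u >= lo) & (u <= hi)

    p1 = 1.0 * eff.amp_factor
    p2 = eff.amp_factor * (1.0 - (config.second_peak_reduction if label != "control" else 0.0))
    raw = p1 * np.exp(-0.5 * ((s - _GRFZ_PEAKS[0]) / _GRFZ_WIDTH) ** 2)
    raw = raw + p2 * np.exp(-0.5 * ((s - _GRFZ_PEAKS[1]) / _GRFZ_WIDTH) ** 2)
    # subtract the line through the stance endpoints so the noiseless curve is
    # exactly 0 at foot-strike and toe-off, then zero it through swing
    edge0 = raw[on_plate][0]
    edge1 = raw[on_plate][-1]
    grfz = (raw - (edge0 + (edge1 - edge0) * s)) * on_plate

    grfx = -0.17 * eff.amp_factor * np.sin(2 * np.pi * s) * np.sin(np.pi * s) * on_plate
    grfy = 0.06 * eff.amp_factor * np.sin(3 * np.pi * s) * np.sin(np.pi * s) * on_plate

    sd = config.noise_sd * eff.amp_factor
    if sd > 0:
        grfz = grfz + sd * rng.standard_normal(n)
        grfx = grfx + 0.3 * sd * rng.standard_normal(n)
        grfy = grfy + 0.3 * sd * rng.standard_normal(n)
    return {"GRFx": grfx, "GRFy": grfy, "GRFz": grfz}


def _subject_ids(config: CohortConfig) -> list[tuple[str, str]]:
    ids: list[tuple[str, str]] = []
    ids += [(f"CTRL{i + 1:02d}", "control") for i in range(config.n_control)]
    ids += [(f"DN{i + 1:02d}", "DN") for i in range(config.n_dn)]
    ids += [(f"DFU{i + 1:02d}", "DFU") for i in range(config.n_dfu)]
    return ids


def generate_cohort(config: CohortConfig) -> list[GaitRecording]:
    """Generate a full cohort: one :class:`GaitRecording` per subject per cycle.

    Deterministic for a fixed config (including its seed); subject-level random
    effects are drawn once per subject and shared across that subject's cycles.
    """
    rng = np.random.default_rng(config.seed)
    recordings: list[GaitRecording] = []
    for subject_id, label in _subject_ids(config):
        eff = SubjectEffect(
            peak_shift=rng.normal(0.0, config.subject_sd),
            amp_factor=float(np.exp(rng.normal(0.0, config.subject_amp_sd))),
        )
        for _ in range(config.cycles_per_subject):
            channels = {ch: synth_emg_cycle(label, config, eff, rng) for ch in EMG_CHANNELS}
            channels.update(synth_grf_cycle(label, config, eff, rng))
            recordings.append(GaitRecording(subject_id, label, channels, config.fs))
    return recordings
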