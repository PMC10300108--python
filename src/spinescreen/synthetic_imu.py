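"""Synthetic sit-to-stand IMU recordings.

Emulates the two-IMU screening protocol (one unit on the head, one on
the upper chest along the spine; 9-axis, 25 Hz): a person stands up
from a chair and sits back down, repeats after a rest, then repeats
the exercise twice more keeping head and back deliberately straight
and stiff.  Each repetition produces one movement impulse on the torso
vertical axis; the two movement patterns differ sharply:

* ``healthy`` — natural movement: tall narrow torso-Z impulses
  (amplitude ≈ 2 signal units, support ≈ 100 samples) and almost no
  lateral head motion;
* ``constrained`` — stiffened movement: shallow wide impulses
  (amplitude ≈ 0.6, support ≈ 300 samples) plus a pronounced lateral
  (head X) component, the sideways lean that unloads the spine.

Pulses are half-cosine arches — smooth, compact support, analytically
invertible for width recovery.  All channels carry Gaussian baseline
noise; only torso-Z and head-X carry structured signal by default
(the channels the screening features are read from), the remaining
ten are available for extension.  Every generator is deterministic
given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Sequence, Tuple

import numpy as np

from .signal_features import Channel, ImuRecording, DEFAULT_FS

__all__ = [
    "PulseSpec",
    "PatternParams",
    "SessionSpec",
    "HEALTHY",
    "CONSTRAINED",
    "CHANNEL_NAMES",
    "generate_pulse",
    "generate_recording",
    "generate_session",
    "pattern_params",
]

SENSORS = ("head", "torso")
INSTRUMENTS = ("accel", "gyro")
AXES = ("x", "y", "z")
CHANNEL_NAMES = tuple(f"{s}.{i}.{a}"
                      for s in SENSORS for i in INSTRUMENTS for a in AXES)

SIGNAL_CHANNEL = "torso.accel.z"   # vertical movement impulses
LATERAL_CHANNEL = "head.accel.x"   # sideways lean of stiffened movement

DEFAULT_GAP = 1500  # samples ≈ 1 min rest between repetitions at 25 Hz
LEAD = 100          # quiet samples before the first and after the last pulse

WIDTH_LEVEL = 0.05  # widths are nominal at this fraction of peak height


def support_for_width(nominal_width: float) -> int:
    """Half-cosine support whose 5%-level crossing width equals the
    nominal width.

    The pulse s(t) = A·sin(π(t+1)/(s+1)) crosses 0.05·A at
    u = asin(0.05)/π of its support, so a support of
    (W+1)/(1−2u) − 1 samples measures W samples at the 5% level —
    the same convention the feature extractor uses.
    """
    u = math.asin(WIDTH_LEVEL) / math.pi
    return max(int(round((nominal_width + 1.0) / (1.0 - 2.0 * u) - 1.0)), 3)


@dataclass(frozen=True)
class PulseSpec:
    """One half-cosine movement impulse."""

    amplitude: float
    width: int  # support length in samples
    onset: int = 0
    polarity: int = 1

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("pulse amplitude must be > 0")
        if self.width < 3:
            raise ValueError("pulse width must be ≥ 3 samples")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be ±1")


def generate_pulse(spec: PulseSpec) -> np.ndarray:
    """Samples of one pulse: s(t) = A·sin(π(t+1)/(W+1)) for
    t = 0..W−1 — exactly ``width`` nonzero samples, peak within one
    sample of the support midpoint, endpoints already small."""
    t = np.arange(spec.width, dtype=float)
    return (spec.polarity * spec.amplitude
            * np.sin(np.pi * (t + 1.0) / (spec.width + 1.0)))


@dataclass(frozen=True)
class PatternParams:
    """Distribution of one movement pattern's pulses.

    Amplitudes are in the same arbitrary signal units as the
    recordings; widths in samples.  The defaults encode the study
    conditions: healthy repetitions centre on amplitude 2.0 / width
    100, constrained on 0.6 / 300, with the lateral head-X component
    small (0.1) for healthy and large (0.8) for constrained movement.
    """

    pattern: str  # "healthy" | "constrained"
    amp_mean: float
    amp_sd: float
    width_mean: float
    width_sd: float
    lateral_amp_mean: float
    lateral_amp_sd: float
    noise_sd: float = 0.02
    fs: float = DEFAULT_FS
    gap: int = DEFAULT_GAP

    def __post_init__(self):
        if self.amp_mean <= 0 or self.width_mean <= 0:
            raise ValueError("pattern means must be > 0")
        if min(self.amp_sd, self.width_sd,
               self.lateral_amp_sd, self.noise_sd) < 0:
            raise ValueError("pattern standard deviations must be ≥ 0")


HEALTHY = PatternParams(pattern="healthy", amp_mean=2.0, amp_sd=0.1,
                        width_mean=100.0, width_sd=5.0,
                        lateral_amp_mean=0.1, lateral_amp_sd=0.01)
CONSTRAINED = PatternParams(pattern="constrained", amp_mean=0.6, amp_sd=0.05,
                            width_mean=300.0, width_sd=10.0,
                            lateral_amp_mean=0.8, lateral_amp_sd=0.08)

_PATTERNS = {"healthy": HEALTHY, "constrained": CONSTRAINED}


def pattern_params(name: str) -> PatternParams:
    try:
        return _PATTERNS[name]
    except KeyError:
        raise ValueError(
            f"unknown pattern {name!r}; expected one of "
            f"{sorted(_PATTERNS)}") from None


@dataclass(frozen=True)
class SessionSpec:
    """A full recording session: one pattern label per repetition.

    The default reproduces the four-step protocol — two natural
    repetitions followed by two stiffened ones, separated by rests.
    """

    repetitions: Tuple[str, ...] = ("healthy", "healthy",
                                    "constrained", "constrained")
    seed: int = 0
    gap: int = DEFAULT_GAP
    fs: float = DEFAULT_FS
    noise_sd: float = 0.02

    def __post_init__(self):
        if not self.repetitions:
            raise ValueError("session needs at least one repetition")
        for label in self.repetitions:
            pattern_params(label)


def _draw_pulses(patterns: Sequence[PatternParams], gap: int,
                 rng: np.random.Generator):
    """Draw per-repetition pulse parameters and lay out onsets."""
    main: List[PulseSpec] = []
    lateral: List[PulseSpec] = []
    nominal_widths: List[float] = []
    onset = LEAD
    for p in patterns:
        amp = max(float(rng.normal(p.amp_mean, p.amp_sd)), 1e-6)
        nominal = max(float(rng.normal(p.width_mean, p.width_sd)), 3.0)
        support = support_for_width(nominal)
        lat_amp = max(float(rng.normal(p.lateral_amp_mean,
                                       p.lateral_amp_sd)), 1e-6)
        main.append(PulseSpec(amplitude=amp, width=support, onset=onset))
        lateral.append(PulseSpec(amplitude=lat_amp, width=support,
                                 onset=onset))
        nominal_widths.append(nominal)
        onset += support + gap
    n_samples = onset - gap + LEAD
    return main, lateral, nominal_widths, n_samples


def _assemble(patterns: Sequence[PatternParams], labels: Sequence[str],
              seed: int, gap: int, fs: float, noise_sd: float) -> ImuRecording:
    rng = np.random.default_rng(seed)
    main, lateral, nominal_widths, n = _draw_pulses(patterns, gap, rng)
    signal = {name: rng.normal(0.0, noise_sd, n) if noise_sd > 0
              else np.zeros(n) for name in CHANNEL_NAMES}
    for spec in main:
        signal[SIGNAL_CHANNEL][spec.onset:spec.onset + spec.width] += \
            generate_pulse(spec)
    for spec in lateral:
        signal[LATERAL_CHANNEL][spec.onset:spec.onset + spec.width] += \
            generate_pulse(spec)
    metadata = {
        "protocol": "sit-to-stand",
        "seed": str(seed),
        "fs_hz": str(fs),
        "gap_samples": str(gap),
        "noise_sd": str(noise_sd),
        "repetitions": ",".join(labels),
        "nominal_amplitudes": ",".join(f"{s.amplitude:.6g}" for s in main),
        "nominal_widths": ",".join(f"{w:.6g}" for w in nominal_widths),
        "support_widths": ",".join(str(s.width) for s in main),
    }
    channels = {name: Channel(name=name, samples=samples, fs=fs)
                for name, samples in signal.items()}
    return ImuRecording(channels=channels, metadata=metadata)


def generate_recording(pattern: PatternParams, n_reps: int = 2,
                       seed: int = 0) -> ImuRecording:
    """Generate one single-pattern recording of ``n_reps`` repetitions.

    Torso-Z carries the vertical movement impulses, head-X the lateral
    component; all 12 channels share length, sampling rate and the
    Gaussian noise floor.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    return _assemble([pattern] * n_reps, [pattern.pattern] * n_reps,
                     seed=seed, gap=pattern.gap, fs=pattern.fs,
                     noise_sd=pattern.noise_sd)


def generate_session(session: SessionSpec) -> ImuRecording:
    """Generate a mixed-pattern session, one pulse per listed
    repetition in order.  With the default labels the torso-Z channel
    shows two tall narrow pulses followed by two shallow wide ones."""
    patterns = [replace(pattern_params(label), gap=session.gap,
                        fs=session.fs, noise_sd=session.noise_sd)
                for label in session.repetitions]
    return _assemble(patterns, list(session.repetitions),
                     seed=session.seed, gap=session.gap, fs=session.fs,
                     noise_sd=session.noise_sd)
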