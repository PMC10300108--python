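"""Impulse amplitude/width extraction from IMU channels.

Each sit-to-stand repetition shows up as one impulse on the vertical
(Z) axis of a torso-mounted IMU.  The screening policies consume two
temporal features per channel: the impulse *amplitude* (maximum
deviation from baseline, signal units are left arbitrary) and the
impulse *width* (duration in samples, measured between the crossings
of 5% of the impulse's own peak height).  A per-impulse relative width
level keeps widths comparable between the tall narrow impulses of
natural movement and the shallow wide impulses of stiffened movement.

The detector is deliberately simple and fully deterministic:

* baseline = channel median (robust to the impulses themselves);
* deviation = |x − baseline| (sign-agnostic: gyro impulses may be
  bipolar);
* candidate peaks = local maxima of the deviation above
  ``alpha`` × the global maximum deviation, thinned greedily in
  descending height with a ``min_gap`` exclusion radius;
* per-peak width between the nearest ``beta`` × peak-height crossings
  on each side; impulses narrower than ``min_width`` are dropped and
  overlapping impulses are merged keeping the taller peak.

A channel whose maximum deviation is not well clear of its noise floor
(robust σ from the MAD) is treated as movement-free and yields no
impulses, so a recording of pure sensor noise does not produce
phantom repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "Channel",
    "ImuRecording",
    "Impulse",
    "FeatureSet",
    "detect_impulses",
    "extract_features",
    "DEFAULT_FS",
]

DEFAULT_FS = 25.0  # Hz, the 9-axis IMU sampling rate


@dataclass
class Channel:
    """One uniformly sampled series, named ``sensor.instrument.axis``
    (e.g. ``torso.accel.z``); sample i is at time i/fs seconds."""

    name: str
    samples: np.ndarray
    fs: float = DEFAULT_FS

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be > 0")
        if self.samples.ndim != 1:
            raise ValueError("channel samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.name!r} has non-finite samples")

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other) -> bool:
        return (isinstance(other, Channel)
                and self.name == other.name
                and self.fs == other.fs
                and np.array_equal(self.samples, other.samples))

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class ImuRecording:
    """Named multi-channel recording; all channels share length and fs.

    Metadata is free-form string key/values (protocol, seed, nominal
    pulse parameters...) and survives CSV round-trips.
    """

    channels: Dict[str, Channel]
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.channels:
            lengths = {len(c) for c in self.channels.values()}
            rates = {c.fs for c in self.channels.values()}
            if len(lengths) != 1:
                raise ValueError("channels have unequal lengths")
            if len(rates) != 1:
                raise ValueError("channels have unequal sampling rates")
        for name, c in self.channels.items():
            if name != c.name:
                raise ValueError(
                    f"channel key {name!r} does not match channel "
                    f"name {c.name!r}")
        self.metadata = {str(k): str(v) for k, v in self.metadata.items()}

    def __eq__(self, other) -> bool:
        return (isinstance(other, ImuRecording)
                and self.metadata == other.metadata
                and set(self.channels) == set(other.channels)
                and all(self.channels[k] == other.channels[k]
                        for k in self.channels))

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def channel(self, name: str) -> Channel:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"recording has no channel {name!r}; available: "
                f"{sorted(self.channels)}") from None


@dataclass(frozen=True)
class Impulse:
    """One detected movement burst on a channel."""

    peak: int
    amplitude: float
    width: int  # end − start + 1, in samples
    start: int
    end: int

    def __post_init__(self):
        if not (self.start <= self.peak <= self.end):
            raise ValueError("impulse requires start ≤ peak ≤ end")
        if self.width != self.end - self.start + 1 or self.width <= 0:
            raise ValueError("impulse width inconsistent with bounds")
        if self.amplitude <= 0:
            raise ValueError("impulse amplitude must be > 0")


@dataclass(frozen=True)
class FeatureSet:
    """Per-impulse features of one channel plus their means; means are
    ``None`` (the set is *flagged*) when no impulse was detected."""

    channel: str
    impulses: tuple
    mean_amplitude: Optional[float]
    mean_width: Optional[float]

    @property
    def flagged(self) -> bool:
        return not self.impulses


# detector defaults; alpha/beta are fractions of the global/per-peak
# maximum deviation, so the detector is scale- and shift-invariant
ALPHA = 0.25
BETA = 0.05
MIN_GAP = 10
MIN_WIDTH = 5
SNR_MIN = 8.0


def _noise_sigma(dev: np.ndarray) -> float:
    """Robust noise scale: 1.4826 × median absolute deviation."""
    return 1.4826 * float(np.median(np.abs(dev - np.median(dev))))


def _width_bounds(dev: np.ndarray, peak: int, threshold: float):
    """Nearest crossings of ``threshold`` on each side of ``peak``."""
    start = peak
    while start > 0 and dev[start - 1] >= threshold:
        start -= 1
    end = peak
    last = len(dev) - 1
    while end < last and dev[end + 1] >= threshold:
        end += 1
    return start, end


def detect_impulses(channel: Channel, alpha: float = ALPHA,
                    beta: float = BETA, min_gap: int = MIN_GAP,
                    min_width: int = MIN_WIDTH,
                    snr_min: float = SNR_MIN) -> List[Impulse]:
    """Detect movement impulses on one channel.

    Parameters
    ----------
    alpha
        Candidate peaks must exceed ``alpha`` × the channel's maximum
        deviation from baseline (0 < beta < alpha < 1).
    beta
        Width is measured between the crossings of ``beta`` × the
        peak's own height on each side.
    min_gap
        Exclusion radius, in samples, around an accepted peak.
    min_width
        Impulses narrower than this are discarded.
    snr_min
        Movement floor: if the maximum deviation is below ``snr_min``
        noise sigmas (MAD-based), the channel is movement-free.
    """
    if not 0 < beta < alpha < 1:
        raise ValueError("thresholds must satisfy 0 < beta < alpha < 1")
    if len(channel) == 0:
        raise ValueError("channel is empty")
    x = channel.samples
    baseline = float(np.median(x))
    dev = np.abs(x - baseline)
    a_global = float(dev.max())
    if a_global == 0.0:
        return []
    sigma = _noise_sigma(dev)
    if sigma > 0.0 and a_global < snr_min * sigma:
        return []
    # find_peaks with `distance` performs exactly the greedy
    # descending-height thinning with a minimum peak separation
    peaks, _ = find_peaks(dev, height=alpha * a_global, distance=min_gap)
    impulses: List[Impulse] = []
    for p in peaks:
        height = dev[p]
        start, end = _width_bounds(dev, int(p), beta * height)
        width = end - start + 1
        if width < min_width:
            continue
        amplitude = float(dev[start:end + 1].max())
        impulses.append(Impulse(peak=int(p), amplitude=amplitude,
                                width=width, start=start, end=end))
    impulses.sort(key=lambda im: im.start)
    merged: List[Impulse] = []
    for im in impulses:
        if merged and im.start <= merged[-1].end:
            if im.amplitude > merged[-1].amplitude:
                merged[-1] = im
        else:
            merged.append(im)
    return merged


def extract_features(recording: ImuRecording, channel_name: str,
                     **detector_kwargs) -> FeatureSet:
    """Detect impulses on one channel and summarise them.

    The means of the per-impulse amplitudes and widths are the
    ``Amplitude`` / ``Width`` environment variables fed to the
    screening policies.
    """
    channel = recording.channel(channel_name)
    impulses = detect_impulses(channel, **detector_kwargs)
    if impulses:
        mean_amplitude = float(np.mean([im.amplitude for im in impulses]))
        mean_width = float(np.mean([im.width for im in impulses]))
    else:
        mean_amplitude = mean_width = None
    return FeatureSet(channel=channel_name, impulses=tuple(impulses),
                      mean_amplitude=mean_amplitude, mean_width=mean_width)
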