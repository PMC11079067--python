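"""Averaged-BAEP waveform synthesis and indicator extraction.

The feature layer normally consumes indicator tables directly; this module
closes the loop by rendering an indicator vector as a 0-10 ms averaged
waveform (vertex-positive convention, Cz vs ipsilateral mastoid) and reading
the indicators back, so the measurement step itself is testable.

Each wave is drawn as a Gaussian positive lobe followed by a matched negative
lobe; the component is scaled so its peak-to-trough distance equals the wave's
amplitude, matching the clinical measurement convention (positive peak to next
negative trough).  Residual noise on a ``k``-sweep average has standard
deviation ``noise_sd / sqrt(k)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .features import WAVES, WaveFeatures

#: canonical adult search windows, ms (half-open, ordered, non-overlapping)
DEFAULT_SEARCH_WINDOWS = {
    "i": (1.2, 2.2),
    "ii": (2.3, 3.3),
    "iii": (3.4, 4.5),
    "iv": (4.6, 5.4),
    "v": (5.4, 6.8),
}

#: peak half-width (Gaussian sigma) per wave, ms
DEFAULT_PEAK_WIDTH = 0.08

#: delay of the negative lobe after the positive peak, ms
TROUGH_GAP = 0.3

#: amplitude assumed for waves II-IV, whose amplitudes are not tracked
DEFAULT_UNTRACKED_AMPLITUDE = 0.2

#: below this peak-to-trough distance (uV) a wave is reported absent
DEFAULT_MIN_AMPLITUDE = 0.05


@dataclass
class Waveform:
    """One averaged post-stimulus sweep."""

    samples: np.ndarray          # uV
    sampling_rate: float         # Hz, >= 10 kHz for 0.1 ms latency resolution
    window: tuple = (0.0, 10.0)  # ms post-stimulus
    side: str = "affected"
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate < 10_000:
            raise ValueError("sampling_rate must be >= 10 kHz")
        self.samples = np.asarray(self.samples, dtype=float)

    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate
        return self.window[0] + dt * np.arange(len(self.samples))


def synthesize_waveform(
    features: WaveFeatures,
    peak_widths: Optional[dict] = None,
    noise_sd: float = 0.0,
    averages: int = 2000,
    sampling_rate: float = 40_000.0,
    window: tuple = (0.0, 10.0),
    untracked_amplitude: float = DEFAULT_UNTRACKED_AMPLITUDE,
    rng: Optional[np.random.Generator] = None,
) -> Waveform:
    """Render an indicator vector as an averaged waveform.

    Waves whose latency is present contribute a biphasic component at that
    latency; amplitudes of waves I and V come from the feature vector, the
    untracked waves II-IV use ``untracked_amplitude``.
    """
    if averages < 1:
        raise ValueError("averages must be >= 1")
    widths = dict.fromkeys(WAVES, DEFAULT_PEAK_WIDTH)
    if peak_widths:
        widths.update(peak_widths)

    dt = 1000.0 / sampling_rate
    t = window[0] + dt * np.arange(int(round((window[1] - window[0]) / dt)) + 1)
    y = np.zeros_like(t)

    for w in WAVES:
        lat = features.get(f"la_{w}")
        if lat is None:
            continue
        amp = features.get(f"am_{w}") if w in ("i", "v") else untracked_amplitude
        if amp is None:
            amp = untracked_amplitude
        if amp <= 0:
            raise ValueError(f"wave {w.upper()} amplitude must be positive")
        sigma = widths[w]
        if lat - 3 * sigma < window[0] or lat + TROUGH_GAP + 3 * sigma > window[1]:
            raise ValueError(
                f"recording window {window} ms too short for wave {w.upper()} "
                f"at {lat:.2f} ms")
        shape = (0.6 * np.exp(-0.5 * ((t - lat) / sigma) ** 2)
                 - 0.4 * np.exp(-0.5 * ((t - lat - TROUGH_GAP) / sigma) ** 2))
        # scale so peak-to-trough on the sample grid equals the amplitude
        y = y + amp / np.ptp(shape) * shape

    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd / np.sqrt(averages), size=t.shape)

    return Waveform(samples=y, sampling_rate=sampling_rate, window=window,
                    side=features.side, timestamp=features.timestamp)


def _validate_windows(windows: dict, wf_window: tuple) -> list:
    items = [(w, windows[w]) for w in WAVES if w in windows]
    prev_hi = None
    for w, (lo, hi) in items:
        if lo >= hi:
            raise ValueError(f"empty search window for wave {w.upper()}")
        if lo < wf_window[0] or hi > wf_window[1]:
            raise ValueError(f"search window for wave {w.upper()} outside recording")
        if prev_hi is not None and lo < prev_hi:
            raise ValueError("search windows must be ordered and non-overlapping")
        prev_hi = hi
    return items


def extract_wave_features(
    w: Waveform,
    search_windows: Optional[dict] = None,
    min_amplitude: float = DEFAULT_MIN_AMPLITUDE,
) -> WaveFeatures:
    """Read the wave indicators back from an averaged waveform.

    Per wave: latency is the time of the maximal positive deflection inside
    its search window (earliest sample on ties); amplitude is that peak minus
    the following local minimum, searched up to the start of the next wave's
    window (to the end of the recording for wave V).  A wave whose
    peak-to-trough distance falls below ``min_amplitude`` is reported absent.
    """
    windows = _validate_windows(search_windows or DEFAULT_SEARCH_WINDOWS, w.window)
    t = w.times_ms()
    y = w.samples
    n = len(y)

    def _idx(ms: float) -> int:
        return int(np.searchsorted(t, ms, side="left"))

    out = {}
    for k, (wave, (lo, hi)) in enumerate(windows):
        i0, i1 = _idx(lo), min(_idx(hi), n)
        if i1 <= i0:
            continue
        seg = y[i0:i1]
        peak = i0 + int(np.argmax(seg))          # argmax -> earliest on ties
        stop = _idx(windows[k + 1][1][0]) if k + 1 < len(windows) else n
        trough_seg = y[peak:max(stop, peak + 1)]
        amplitude = float(y[peak] - trough_seg.min())
        if amplitude < min_amplitude:
            continue
        out[f"la_{wave}"] = float(t[peak])
        if wave in ("i", "v"):
            out[f"am_{wave}"] = amplitude

    return WaveFeatures(side=w.side, timestamp=w.timestamp, **out).with_interpeaks()


# ---------------------------------------------------------------------------
# plain-text waveform exchange format: two columns, time_ms and amplitude_uv


def write_waveform_txt(path, w: Waveform) -> None:
    header = (f"baepstd.waveform.v1 sampling_rate_hz={w.sampling_rate} "
              f"side={w.side} timestamp_s={w.timestamp}")
    data = np.column_stack([w.times_ms(), w.samples])
    np.savetxt(path, data, fmt="%.6f", header=header)


def read_waveform_txt(path) -> Waveform:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    data = np.loadtxt(path)
    rate = float(meta.get("sampling_rate_hz", 0)) or None
    times, samples = data[:, 0], data[:, 1]
    if rate is None:
        rate = 1000.0 / float(np.median(np.diff(times)))
    return Waveform(samples=samples, sampling_rate=rate,
                    window=(float(times[0]), float(times[-1])),
                    side=meta.get("side", "affected"),
                    timestamp=float(meta.get("timestamp_s", 0.0)))
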