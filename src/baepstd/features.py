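"""Per-epoch BAEP indicator vectors.

A single averaged epoch yields up to ten indicators: the absolute latencies of
waves I-V (ms), the three interpeak latencies I-III, III-V and I-V (ms), and
the peak-to-trough amplitudes of waves I and V (uV).  A missing value means the
wave could not be identified in that epoch (e.g. it dropped below the detection
threshold); absence is a value, not an error, and it propagates through every
downstream index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

#: canonical wave order
WAVES = ("i", "ii", "iii", "iv", "v")

#: latency indicators in canonical order
LATENCY_INDICATORS = ("la_i", "la_ii", "la_iii", "la_iv", "la_v")

#: interpeak latency indicators
INTERPEAK_INDICATORS = ("la_i_iii", "la_iii_v", "la_i_v")

#: amplitude indicators (waves I and V only)
AMPLITUDE_INDICATORS = ("am_i", "am_v")

#: every indicator, in the column order of features.csv
INDICATORS = LATENCY_INDICATORS + INTERPEAK_INDICATORS + AMPLITUDE_INDICATORS

PHASES = ("pre_resection", "resection", "post_resection")


@dataclass
class WaveFeatures:
    """Indicator vector of one averaged epoch.

    Latencies in ms, amplitudes in uV; ``None`` marks an absent wave.
    Interpeak latencies, when both components are present, satisfy
    ``la_i_iii = la_iii - la_i`` etc. (use :meth:`with_interpeaks` to fill
    them consistently).
    """

    side: str = "affected"
    timestamp: float = 0.0
    phase: str = "pre_resection"
    la_i: Optional[float] = None
    la_ii: Optional[float] = None
    la_iii: Optional[float] = None
    la_iv: Optional[float] = None
    la_v: Optional[float] = None
    la_i_iii: Optional[float] = None
    la_iii_v: Optional[float] = None
    la_i_v: Optional[float] = None
    am_i: Optional[float] = None
    am_v: Optional[float] = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        for name in AMPLITUDE_INDICATORS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def get(self, indicator: str) -> Optional[float]:
        if indicator not in INDICATORS:
            raise KeyError(indicator)
        return getattr(self, indicator)

    def with_interpeaks(self) -> "WaveFeatures":
        """Return a copy with interpeak latencies recomputed from waves I/III/V."""
        out = WaveFeatures(**{f.name: getattr(self, f.name) for f in fields(self)})
        out.la_i_iii = _sub(self.la_iii, self.la_i)
        out.la_iii_v = _sub(self.la_v, self.la_iii)
        out.la_i_v = _sub(self.la_v, self.la_i)
        return out

    def as_dict(self) -> dict:
        d = {"side": self.side, "timestamp": self.timestamp, "phase": self.phase}
        for name in INDICATORS:
            d[name] = getattr(self, name)
        return d


def _sub(a: Optional[float], b: Optional[float]) -> Optional[float]:
    if a is None or b is None:
        return None
    return a - b


def check_interpeak_identities(f: WaveFeatures, tol: float = 1e-6) -> bool:
    """True when every interpeak latency matches its component difference."""
    for ip, (lo, hi) in (("la_i_iii", ("la_i", "la_iii")),
                         ("la_iii_v", ("la_iii", "la_v")),
                         ("la_i_v", ("la_i", "la_v"))):
        v = f.get(ip)
        a, b = f.get(lo), f.get(hi)
        if v is None or a is None or b is None:
            continue
        if not math.isclose(v, b - a, abs_tol=tol):
            return False
    return True
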