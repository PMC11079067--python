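"""Synchronous healthy-side referencing of affected-side BAEPs.

This is the analytic core.  Raw affected-side indicators are unreliable
because both ears share large session-wide interference; referencing each
affected-side epoch to a *synchronous* healthy-side epoch (recording interval
<= 3 min) cancels the shared component.  Three index families are computed
per indicator:

* ``STI`` (standardized index, dimensionless):
      affected / healthy - 1
  exactly invariant under any common multiplicative factor:
  STI(c*a, c*h) = STI(a, h).
* ``D`` (intraoperative difference, indicator units):
      affected_post - affected_pre
* ``STD`` (standardized difference, indicator units):
      D - (healthy_post - healthy_pre)
  invariant under any drift added equally to both ears' phase summaries.

When a constant laboratory normal reference value is supplied, the
reference-scaled quantities reference*(a/h) and reference*(a/h - 1) are also
reported; being a constant multiple of STI they carry no extra information.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from statistics import median
from typing import Optional

from .config import StandardizationConfig
from .features import INDICATORS, PHASES, WaveFeatures


@dataclass
class PairedEpoch:
    """A synchronous affected/healthy epoch pair."""

    affected: WaveFeatures
    healthy: WaveFeatures
    interval: float     # seconds, |t_affected - t_healthy|

    def __post_init__(self) -> None:
        if self.affected.phase != self.healthy.phase:
            raise ValueError("paired epochs must share a surgical phase")


@dataclass
class PhaseSummary:
    """Per-phase representative indicator vectors for both ears."""

    phase: str
    affected: WaveFeatures
    healthy: WaveFeatures
    n_pairs: int


@dataclass
class StandardizedIndices:
    """STI per indicator (affected/healthy - 1), one surgical phase."""

    phase: str
    sti: dict = field(default_factory=dict)   # indicator -> float | None

    def get(self, indicator: str) -> Optional[float]:
        return self.sti.get(indicator)


@dataclass
class DifferenceIndices:
    """D (affected post - pre) and STD (D minus healthy change) per indicator."""

    d: dict = field(default_factory=dict)
    std: dict = field(default_factory=dict)


class DivisionGuardError(ZeroDivisionError):
    """Healthy-side value is zero for an indicator being standardized."""


# ---------------------------------------------------------------------------


def pair_streams(
    affected: list,
    healthy: list,
    max_interval: float = 180.0,
) -> list[PairedEpoch]:
    """Greedily match affected and healthy epochs by timestamp proximity.

    Candidate pairs (same surgical phase, interval <= ``max_interval``
    seconds, the 3-min criterion inclusive) are taken in order of increasing
    interval; each epoch is used at most once.  Unmatched epochs are dropped.
    """
    for stream, name in ((affected, "affected"), (healthy, "healthy")):
        ts = [f.timestamp for f in stream]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"{name} stream timestamps must be strictly increasing")

    h_times = [h.timestamp for h in healthy]
    candidates = []
    for i, a in enumerate(affected):
        lo = bisect_left(h_times, a.timestamp - max_interval)
        hi = bisect_right(h_times, a.timestamp + max_interval)
        for j in range(lo, hi):
            if a.phase == healthy[j].phase:
                candidates.append((abs(a.timestamp - h_times[j]), i, j))
    candidates.sort()

    used_a, used_h, pairs = set(), set(), []
    for dt, i, j in candidates:
        if i in used_a or j in used_h:
            continue
        used_a.add(i)
        used_h.add(j)
        pairs.append(PairedEpoch(affected[i], healthy[j], dt))
    pairs.sort(key=lambda p: p.affected.timestamp)
    return pairs


def _representative(values: list, method: str) -> float:
    return median(values) if method == "median" else sum(values) / len(values)


def summarize_phase(
    pairs: list[PairedEpoch],
    phase: str,
    method: str = "median",
) -> Optional[PhaseSummary]:
    """Collapse a phase's paired epochs into one representative vector per ear.

    Per indicator and ear, the representative is the median (or mean) over the
    epochs where the indicator is present; an indicator absent in more than
    half of the phase's pairs is absent from the summary.  Returns ``None``
    when the phase has no pairs (absence, not an error, at patient level).
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    in_phase = [p for p in pairs if p.affected.phase == phase]
    if not in_phase:
        return None
    n = len(in_phase)
    reps = {}
    for side in ("affected", "healthy"):
        vals = {}
        for ind in INDICATORS:
            xs = [getattr(p, side).get(ind) for p in in_phase]
            xs = [x for x in xs if x is not None]
            if len(xs) * 2 > n:        # present in at least half of the pairs
                vals[ind] = _representative(xs, method)
        t = _representative([getattr(p, side).timestamp for p in in_phase], method)
        reps[side] = WaveFeatures(side=side, timestamp=t, phase=phase, **vals)
    return PhaseSummary(phase=phase, affected=reps["affected"],
                        healthy=reps["healthy"], n_pairs=n)


def compute_sti(summary: PhaseSummary) -> StandardizedIndices:
    """Standardized index per indicator: affected/healthy - 1.

    Dimensionless; exactly cancels any factor common to both ears.  Absence
    in either ear propagates.  A healthy-side zero raises
    :class:`DivisionGuardError` naming the indicator.
    """
    sti = {}
    for ind in INDICATORS:
        a, h = summary.affected.get(ind), summary.healthy.get(ind)
        if a is None or h is None:
            sti[ind] = None
        elif h == 0:
            raise DivisionGuardError(
                f"healthy-side {ind} is zero; cannot standardize")
        else:
            sti[ind] = a / h - 1.0
    return StandardizedIndices(phase=summary.phase, sti=sti)


def compute_differences(pre: PhaseSummary, post: PhaseSummary) -> DifferenceIndices:
    """Intraoperative difference D = post - pre on the affected side and its
    standardized form STD = D - (healthy post - healthy pre)."""
    d, std = {}, {}
    for ind in INDICATORS:
        a0, a1 = pre.affected.get(ind), post.affected.get(ind)
        h0, h1 = pre.healthy.get(ind), post.healthy.get(ind)
        d[ind] = None if (a0 is None or a1 is None) else a1 - a0
        if None in (a0, a1, h0, h1):
            std[ind] = None
        else:
            std[ind] = (a1 - a0) - (h1 - h0)
    return DifferenceIndices(d=d, std=std)


# ---------------------------------------------------------------------------
# reference-scaled diagnostics


def standardized_value(sti: StandardizedIndices, config: StandardizationConfig) -> dict:
    """reference * affected/healthy = reference * (STI + 1), per indicator."""
    return _scale_by_reference(sti, config, offset=1.0)


def standardized_difference_value(sti: StandardizedIndices,
                                  config: StandardizationConfig) -> dict:
    """reference * (affected/healthy - 1) = reference * STI, per indicator."""
    return _scale_by_reference(sti, config, offset=0.0)


def reference_difference(summary: PhaseSummary,
                         config: StandardizationConfig) -> dict:
    """Diagnostic only: affected value minus the constant normal reference."""
    out = {}
    ref = config.normal_reference or {}
    for ind, r in ref.items():
        a = summary.affected.get(ind)
        out[ind] = None if a is None else a - r
    return out


def _scale_by_reference(sti, config, offset):
    out = {}
    ref = config.normal_reference or {}
    for ind, r in ref.items():
        v = sti.get(ind)
        out[ind] = None if v is None else r * (v + offset)
    return out


# ---------------------------------------------------------------------------
# per-patient driver


@dataclass
class PatientIndices:
    """Everything the predictor battery needs from one surgery."""

    patient_id: str
    n_pairs: dict                     # phase -> pair count
    pre: Optional[PhaseSummary]
    post: Optional[PhaseSummary]
    sti_pre: Optional[StandardizedIndices]
    sti_post: Optional[StandardizedIndices]
    diff: Optional[DifferenceIndices]


def index_patient(
    patient_id: str,
    affected: list,
    healthy: list,
    config: Optional[StandardizationConfig] = None,
) -> PatientIndices:
    """Pair, summarize and standardize one patient's binaural streams.

    Epochs recorded during active resection are excluded from both phases.
    """
    cfg = config or StandardizationConfig()
    pairs = pair_streams(affected, healthy, cfg.max_interval)
    pre = summarize_phase(pairs, "pre_resection", cfg.summary_method)
    post = summarize_phase(pairs, "post_resection", cfg.summary_method)
    sti_pre = compute_sti(pre) if pre else None
    sti_post = compute_sti(post) if post else None
    diff = compute_differences(pre, post) if pre and post else None
    counts = {ph: sum(1 for p in pairs if p.affected.phase == ph) for ph in PHASES}
    return PatientIndices(patient_id=patient_id, n_pairs=counts, pre=pre,
                          post=post, sti_pre=sti_pre, sti_post=sti_post,
                          diff=diff)
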