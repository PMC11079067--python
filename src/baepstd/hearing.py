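"""AAO-HNS hearing classification and the hearing-preservation (HP) label.

Hearing is summarized by two scalars: the pure tone average (PTA, dB HL,
lower is better) and the word recognition score (WRS, percent correct,
higher is better).  The AAO-HNS grades are

* class A: PTA <= 30 dB and WRS >= 70%
* class B: PTA <= 50 dB and WRS >= 50% (and not A)
* class C: PTA >  50 dB and WRS >= 50%
* class D: WRS < 50%

Hearing preservation is defined as class A-C, which under these thresholds is
equivalent to WRS >= 50%.  HP is the dependent variable of every regression
in the predictor-evaluation battery.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

AAO_CLASSES = ("A", "B", "C", "D")


@dataclass
class Audiometry:
    """One ear's audiometric assessment at one stage."""

    pta: float              # dB HL, >= 0
    wrs: float              # percent, 0-100
    stage: str = "pre"      # pre | post

    def __post_init__(self) -> None:
        if self.pta < 0:
            raise ValueError(f"pta must be >= 0 dB, got {self.pta}")
        if not 0.0 <= self.wrs <= 100.0:
            raise ValueError(f"wrs must lie in [0, 100]%, got {self.wrs}")
        if self.stage not in ("pre", "post"):
            raise ValueError(f"stage must be 'pre' or 'post', got {self.stage!r}")


@dataclass(frozen=True)
class HearingClass:
    aao_class: str
    hp: bool


def classify_aao_hns(a: Audiometry) -> HearingClass:
    """Grade an audiogram A-D and derive the HP label (class A-C)."""
    if a.wrs < 50.0:
        cls = "D"
    elif a.pta <= 30.0 and a.wrs >= 70.0:
        cls = "A"
    elif a.pta <= 50.0:
        cls = "B"
    else:
        cls = "C"
    return HearingClass(aao_class=cls, hp=cls in ("A", "B", "C"))


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding, the convention of clinical report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _class_counts(classes: Iterable[str]) -> dict:
    counts = {c: 0 for c in AAO_CLASSES}
    for c in classes:
        counts[c] += 1
    return counts


def outcome_table(
    pre: Iterable[Audiometry],
    post: Optional[Iterable[Audiometry]] = None,
) -> dict:
    """Cohort hearing-outcome summary (per-class counts and HP rates).

    ``pre`` covers every patient.  ``post`` is the postoperative audiometry of
    the patients who had preoperative HP: postoperative class percentages use
    the preop-HP count as denominator, while the postoperative HP rate is also
    reported against the full cohort.
    """
    pre = list(pre)
    n = len(pre)
    pre_classes = [classify_aao_hns(a).aao_class for a in pre]
    pre_counts = _class_counts(pre_classes)
    n_pre_hp = sum(1 for c in pre_classes if c != "D")

    table = {
        "n_patients": n,
        "pre": {
            "class_counts": pre_counts,
            "class_pct": {c: round_half_up(100.0 * k / n) if n else 0.0
                          for c, k in pre_counts.items()},
            "hp_count": n_pre_hp,
            "hp_rate_pct": round_half_up(100.0 * n_pre_hp / n) if n else 0.0,
        },
    }
    if post is not None:
        post = list(post)
        m = len(post)
        post_classes = [classify_aao_hns(a).aao_class for a in post]
        post_counts = _class_counts(post_classes)
        n_post_hp = sum(1 for c in post_classes if c != "D")
        table["post"] = {
            "denominator": m,
            "class_counts": post_counts,
            "class_pct": {c: round_half_up(100.0 * k / m) if m else 0.0
                          for c, k in post_counts.items()},
            "hp_count": n_post_hp,
            "hp_rate_pct": round_half_up(100.0 * n_post_hp / m) if m else 0.0,
            "hp_rate_pct_of_cohort": round_half_up(100.0 * n_post_hp / n) if n else 0.0,
        }
    return table
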