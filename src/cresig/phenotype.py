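"""Drosophila cardiac-knockdown viability metrics.

In a balancer cross, knockdown progeny are straight-winged and their
balancer siblings curly-winged; with no lethality the two classes
emerge in equal numbers.  The mortality index

    MI = (curly - straight) / curly * 100

is the percentage of expected knockdown progeny missing as adults:
0 for a balanced cross, 100 for complete knockdown lethality, negative
(legal, classified unaffected) when straight-winged flies outnumber
curly ones.

Severity classes use contiguous half-open bins with edges at 10/30/60:
unaffected (MI <= 10), low (10 < MI <= 30), medium (30 < MI <= 60),
severe (MI > 60).  The edges are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

SEVERITY_CLASSES = ("unaffected", "low", "medium", "severe")
DEFAULT_EDGES = (10.0, 30.0, 60.0)
HIT_CUTOFF = 10.0


@dataclass(frozen=True)
class CrossCount:
    """Progeny counts from one balancer cross."""

    line_id: str
    curly: int
    straight: int

    def __post_init__(self) -> None:
        if self.curly < 0 or self.straight < 0:
            raise ValueError(f"line {self.line_id}: counts must be >= 0")


@dataclass(frozen=True)
class MortalityRecord:
    line_id: str
    mi: float
    severity: str


def mortality_index(cross: CrossCount) -> float:
    """MI = (curly - straight) / curly * 100; undefined for curly = 0."""
    if cross.curly == 0:
        raise ValueError(f"line {cross.line_id}: MI undefined with zero curly progeny")
    return (cross.curly - cross.straight) / cross.curly * 100.0


def severity_class(mi: float, edges: Sequence[float] = DEFAULT_EDGES) -> str:
    """Map an MI to its severity class; every real MI maps to exactly one."""
    e1, e2, e3 = edges
    if not (e1 < e2 < e3):
        raise ValueError("severity edges must be strictly increasing")
    if mi <= e1:
        return "unaffected"
    if mi <= e2:
        return "low"
    if mi <= e3:
        return "medium"
    return "severe"


def score_crosses(
    crosses: Sequence[CrossCount], edges: Sequence[float] = DEFAULT_EDGES
) -> list[MortalityRecord]:
    """MI and severity class for each cross."""
    return [
        MortalityRecord(c.line_id, mi, severity_class(mi, edges))
        for c in crosses
        for mi in (mortality_index(c),)
    ]


@dataclass(frozen=True)
class ScreenSummary:
    n_tested: int
    n_hits: int
    hit_rate_pct: int


def screen_summary(records: Sequence[MortalityRecord], mi_cut: float = HIT_CUTOFF) -> ScreenSummary:
    """Lines whose MI exceeds ``mi_cut`` (default 10, the ceiling of
    control-cross variation), with the hit rate as a whole percentage."""
    n = len(records)
    hits = sum(1 for r in records if r.mi > mi_cut)
    return ScreenSummary(n, hits, round(100.0 * hits / n) if n else 0)


def relative_rate(treated: Sequence[float], control: Sequence[float]) -> float:
    """Mean of ``treated`` as a percentage of the mean of ``control``
    (e.g. heart rates relative to sibling controls)."""
    if not treated or not control:
        raise ValueError("treated and control must be non-empty")
    control_mean = sum(control) / len(control)
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return (sum(treated) / len(treated)) / control_mean * 100.0
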