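"""Promoter/enhancer calling from histone-mark peaks and cross-tissue
specificity labelling.

Active promoters are taken as merged H3K4me3 peaks; active enhancers as
the basepair intersection of H3K4me1 and H3K27ac peaks (the overlapping
portions, not whole peaks).  A target tissue's CRE is *tissue-specific*
when it has no same-kind overlap in any other tissue of the panel, and
*ubiquitous* when it overlaps a same-kind CRE in every other tissue.
Specificity is assessed kind-matched against the other tissues' called
CREs (promoter vs promoter, enhancer vs enhancer), not their raw marks;
``compare_to="marks"`` switches to raw-mark comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import IntervalSet

H3K4ME1 = "H3K4me1"
H3K4ME3 = "H3K4me3"
H3K27AC = "H3K27ac"
MARKS = (H3K4ME1, H3K4ME3, H3K27AC)

PROMOTER = "promoter"
ENHANCER = "enhancer"

TARGET_SPECIFIC = "target_specific"
UBIQUITOUS = "ubiquitous"
OTHER = "other"


class ConfigurationError(ValueError):
    """A mark panel is missing a mark required by the requested call."""


@dataclass
class MarkPanel:
    """Histone-mark peak sets for one tissue."""

    tissue: str
    peaks: dict[str, IntervalSet] = field(default_factory=dict)

    def require(self, *marks: str) -> None:
        missing = [m for m in marks if m not in self.peaks]
        if missing:
            raise ConfigurationError(
                f"tissue {self.tissue!r}: missing mark(s) {missing}; have {sorted(self.peaks)}"
            )


@dataclass
class CRESet:
    """Called CREs of one kind for one tissue.

    ``intervals`` is always merged and sorted; ``specificity`` is
    ``other`` until a cross-tissue filter assigns it.
    """

    tissue: str
    kind: str
    intervals: IntervalSet
    specificity: str = OTHER

    def __post_init__(self) -> None:
        if self.kind not in (PROMOTER, ENHANCER):
            raise ValueError(f"kind must be promoter or enhancer, got {self.kind!r}")
        if not self.intervals.merged:
            self.intervals = self.intervals.merge() if self.intervals else IntervalSet()

    def __len__(self) -> int:
        return len(self.intervals)


def call_promoters(panel: MarkPanel) -> CRESet:
    """Active promoters: the merged H3K4me3 peak set."""
    panel.require(H3K4ME3)
    peaks = panel.peaks[H3K4ME3]
    return CRESet(panel.tissue, PROMOTER, peaks.merge() if peaks else IntervalSet())


def call_enhancers(panel: MarkPanel, exclude_promoter_overlap: bool = False) -> CRESet:
    """Active enhancers: merged H3K4me1 ∩ H3K27ac intersection regions.

    With ``exclude_promoter_overlap`` the H3K4me3-overlapping candidates
    are dropped, for callers who want enhancers strictly clear of
    promoter chromatin.
    """
    panel.require(H3K4ME1, H3K27AC)
    enh = panel.peaks[H3K4ME1].intersect(panel.peaks[H3K27AC])
    if exclude_promoter_overlap:
        panel.require(H3K4ME3)
        enh = enh.subtract_any(panel.peaks[H3K4ME3]).merge() if enh else enh
    return CRESet(panel.tissue, ENHANCER, enh)


def _check_comparable(target: CRESet, others: list[CRESet]) -> None:
    if not others:
        raise ValueError("specificity requires at least one other tissue")
    for o in others:
        if o.kind != target.kind:
            raise ValueError(
                f"kind mismatch: target is {target.kind}, {o.tissue} set is {o.kind}"
            )


def tissue_specific(target: CRESet, others: list[CRESet], min_overlap_bp: int = 1) -> CRESet:
    """Target CREs with no same-kind overlap (at the configured
    threshold) in any other tissue."""
    _check_comparable(target, others)
    kept = target.intervals
    for other in others:
        if not kept:
            break
        if other.intervals:
            kept = kept.subtract_any(other.intervals, min_overlap_bp)
    return CRESet(target.tissue, target.kind, IntervalSet(kept, _merged=True), TARGET_SPECIFIC)


def ubiquitous(target: CRESet, others: list[CRESet], min_overlap_bp: int = 1) -> CRESet:
    """Target CREs overlapping a same-kind CRE in every other tissue."""
    _check_comparable(target, others)
    kept = target.intervals
    for other in others:
        if not kept:
            break
        kept = kept.overlaps_any(other.intervals, min_overlap_bp) if other.intervals else IntervalSet()
    return CRESet(target.tissue, target.kind, IntervalSet(kept, _merged=True), UBIQUITOUS)
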