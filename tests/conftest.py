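"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own sweep-based
algebra: interval operations are checked against per-basepair boolean
arrays on a toy chromosome, and domain extension against a literal
basepair walk outward from each basal window.
"""

from __future__ import annotations

import numpy as np
import pytest

from cresig.intervals import GenomicInterval, IntervalSet
from cresig.io import ChromSizes, GeneModel

TOY_CHROM = "chrT"
TOY_LEN = 10_000


# -- per-basepair interval oracle ------------------------------------------


def bp_mask(spans: list[tuple[int, int]], length: int = TOY_LEN) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in spans:
        mask[s:e] = True
    return mask


def mask_to_spans(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def iset(spans: list[tuple[int, int]], chrom: str = TOY_CHROM) -> IntervalSet:
    return IntervalSet(GenomicInterval(chrom, s, e) for s, e in spans)


def spans_of(intervals: IntervalSet, chrom: str = TOY_CHROM) -> list[tuple[int, int]]:
    return intervals.spans(chrom)


def random_spans(rng: np.random.Generator, n_max: int = 20, length: int = TOY_LEN):
    n = int(rng.integers(0, n_max + 1))
    spans = []
    for _ in range(n):
        s = int(rng.integers(0, length - 1))
        e = int(rng.integers(s + 1, min(length, s + 1 + int(rng.integers(1, 400))) + 1))
        spans.append((s, min(e, length)))
    return spans


def oracle_overlaps_any(query, reference, min_overlap_bp=1):
    """Query spans kept when some single reference span shares enough bp."""
    kept = []
    for qs, qe in sorted(set(query)):
        for rs, re in reference:
            if min(qe, re) - max(qs, rs) >= min_overlap_bp:
                kept.append((qs, qe))
                break
    return kept


# -- domain-extension walk oracle ------------------------------------------


def oracle_extend(
    genes: list[GeneModel],
    sizes: ChromSizes,
    up_bp: int,
    down_bp: int,
    max_extension: int,
) -> dict[str, tuple[int, int]]:
    """Literal basepair walk of the basal+extension rule.

    From each basal boundary, walk outward basepair by basepair; stop at
    the chromosome edge, at ``max_extension`` from the TSS, or on the
    first bp lying inside another gene's basal window.  (The walk is
    expressed as a scan over a per-bp blocked mask so large annotations
    stay cheap; the semantics are the literal walk.)
    """

    def basal(g: GeneModel) -> tuple[int, int]:
        if g.strand == "+":
            s, e = g.tss - up_bp, g.tss + down_bp
        else:
            s, e = g.tss - down_bp, g.tss + up_bp
        return max(0, s), min(e, sizes[g.chrom])

    out = {}
    for g in genes:
        chrom_len = sizes[g.chrom]
        blocked = np.zeros(chrom_len, dtype=bool)
        for o in genes:
            if o.gene_id != g.gene_id and o.chrom == g.chrom:
                obs, obe = basal(o)
                blocked[obs:obe] = True
        bs, be = basal(g)
        # leftward walk from bs-1 down to the cap, stopping at the first blocked bp
        lo = max(0, g.tss - max_extension)
        seg = blocked[lo:bs][::-1]
        steps = int(np.argmax(seg)) if seg.any() else len(seg)
        ext_s = bs - steps
        # rightward walk from be up to the cap
        hi = min(chrom_len, g.tss + max_extension)
        seg = blocked[be:hi]
        steps = int(np.argmax(seg)) if seg.any() else len(seg)
        ext_e = be + steps
        out[g.gene_id] = (ext_s, ext_e)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
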