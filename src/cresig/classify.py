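"""Gene categorisation by cis-regulatory signature and expression.

Genes are binned into four categories from their assigned CREs:

* **I** — at least one target-specific promoter *and* one
  target-specific enhancer (the strongest tissue-specific signature),
* **II** — target-specific promoter(s) only,
* **III** — target-specific enhancer(s) only,
* **IV** — no target-specific CRE at all, but at least one ubiquitous
  promoter *and* one ubiquitous enhancer,
* **unclassified** — anything else (e.g. a ubiquitous promoter alone).

Any specific CRE takes precedence over ubiquitous status: a gene with a
specific enhancer is Category III even if it also carries a full
ubiquitous promoter+enhancer pair.  The categories therefore partition
the classified genes.

The expression filter keeps genes whose replicate-averaged FPKM is
strictly above the threshold (default 20), and reports the threshold's
percentile within the detectably expressed (FPKM_avg > 0) transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cre import ENHANCER, PROMOTER, TARGET_SPECIFIC, UBIQUITOUS
from .domains import CREAssignment
from .io import ExpressionTable

CATEGORIES = ("I", "II", "III", "IV", "unclassified")

EXPRESSION_THRESHOLD = 20.0

COUNT_COLUMNS = (
    "n_specific_promoters",
    "n_specific_enhancers",
    "n_ubiq_promoters",
    "n_ubiq_enhancers",
)


def category_from_counts(n_sp: int, n_se: int, n_up: int, n_ue: int) -> str:
    """The category rule on raw CRE counts (the single source of truth)."""
    if n_sp >= 1 and n_se >= 1:
        return "I"
    if n_sp >= 1:
        return "II"
    if n_se >= 1:
        return "III"
    if n_up >= 1 and n_ue >= 1:
        return "IV"
    return "unclassified"


def _count_unique(assignments: Iterable[CREAssignment]) -> dict[tuple[str, str], int]:
    """Distinct CREs per (gene_id, kind); duplicate records collapse."""
    seen: set[tuple] = set()
    counts: dict[tuple[str, str], int] = {}
    for a in assignments:
        key = (a.gene_id, a.kind, a.cre.chrom, a.cre.start, a.cre.end)
        if key in seen:
            continue
        seen.add(key)
        gk = (a.gene_id, a.kind)
        counts[gk] = counts.get(gk, 0) + 1
    return counts


def classify_genes(
    specific_assignments: Sequence[CREAssignment],
    ubiquitous_assignments: Sequence[CREAssignment],
) -> pd.DataFrame:
    """Per-gene CRE counts and category.

    Returns a DataFrame indexed by ``gene_id`` with the four count
    columns and ``category``.  Assignment order and duplicated records
    do not affect the result.
    """
    for a in specific_assignments:
        if a.specificity != TARGET_SPECIFIC:
            raise ValueError(f"specific assignment with specificity {a.specificity!r}")
    for a in ubiquitous_assignments:
        if a.specificity != UBIQUITOUS:
            raise ValueError(f"ubiquitous assignment with specificity {a.specificity!r}")

    spec = _count_unique(specific_assignments)
    ubiq = _count_unique(ubiquitous_assignments)
    gene_ids = sorted({g for g, _ in spec} | {g for g, _ in ubiq})

    rows = []
    for gid in gene_ids:
        n_sp = spec.get((gid, PROMOTER), 0)
        n_se = spec.get((gid, ENHANCER), 0)
        n_up = ubiq.get((gid, PROMOTER), 0)
        n_ue = ubiq.get((gid, ENHANCER), 0)
        rows.append((gid, n_sp, n_se, n_up, n_ue, category_from_counts(n_sp, n_se, n_up, n_ue)))
    return pd.DataFrame(
        rows, columns=["gene_id", *COUNT_COLUMNS, "category"]
    ).set_index("gene_id")


def attach_expression(
    table: pd.DataFrame,
    expression: ExpressionTable,
    threshold: float = EXPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """Join ``fpkm_avg`` and the strict-threshold ``passes_expression``
    flag onto a classification table.  Genes absent from the expression
    table get FPKM 0 and fail the filter."""
    out = table.copy()
    out["fpkm_avg"] = expression.fpkm_avg.reindex(out.index).fillna(0.0)
    out["passes_expression"] = out["fpkm_avg"] > threshold
    return out


def filter_expressed(
    expression: ExpressionTable, threshold: float = EXPRESSION_THRESHOLD
) -> tuple[frozenset[str], float]:
    """Genes with FPKM_avg strictly above ``threshold``.

    Returns the passing gene set and the percentage of detectably
    expressed genes (FPKM_avg > 0) that pass — e.g. a 20-FPKM cutoff
    sitting at the top 8% of the transcriptome reports ~8.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    avg = expression.fpkm_avg
    detectable = avg[avg > 0]
    if len(detectable) == 0:
        raise ValueError("no detectably expressed genes in table")
    passing = avg[avg > threshold]
    return frozenset(passing.index), 100.0 * len(passing) / len(detectable)


@dataclass(frozen=True)
class ExpressionBreadth:
    """Tissues in which one gene is detectably expressed."""

    gene_id: str
    detected_tissues: frozenset[str]
    exclusive_to_target: bool


def expression_breadth(
    genes: Iterable[str],
    per_tissue_expr: Mapping[str, ExpressionTable],
    target: str,
    detect_threshold: float = 0.0,
) -> tuple[list[ExpressionBreadth], list[str]]:
    """Cross-tissue detection pattern for each gene.

    A gene is detected in a tissue when its FPKM_avg exceeds
    ``detect_threshold`` there.  Genes missing from any tissue table
    cannot be matched across tissues and are returned separately.
    """
    if target not in per_tissue_expr:
        raise ValueError(f"target tissue {target!r} not in expression panel")
    avgs = {t: e.fpkm_avg for t, e in per_tissue_expr.items()}
    matched: list[ExpressionBreadth] = []
    unmatched: list[str] = []
    for gid in genes:
        if any(gid not in a.index for a in avgs.values()):
            unmatched.append(gid)
            continue
        detected = frozenset(t for t, a in avgs.items() if a[gid] > detect_threshold)
        matched.append(ExpressionBreadth(gid, detected, detected == frozenset({target})))
    return matched, unmatched


def category_summary(
    table: pd.DataFrame, expressed: frozenset[str] | set[str]
) -> dict[str, dict[str, float]]:
    """Per-category totals, expressed counts, and pass-rates.

    Pass-rates are percentages rounded to one decimal place (0.0 for an
    empty category).
    """
    out: dict[str, dict[str, float]] = {}
    for cat in CATEGORIES:
        members = table.index[table["category"] == cat]
        n = len(members)
        k = sum(1 for g in members if g in expressed)
        out[cat] = {
            "total": n,
            "expressed": k,
            "pct_expressed": round(100.0 * k / n, 1) if n else 0.0,
        }
    return out
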