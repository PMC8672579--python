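"""Category rules, the expression filter, and cross-tissue breadth."""

import itertools

import pandas as pd
import pytest

from cresig.classify import (
    attach_expression,
    category_from_counts,
    category_summary,
    classify_genes,
    expression_breadth,
    filter_expressed,
)
from cresig.cre import ENHANCER, PROMOTER, TARGET_SPECIFIC, UBIQUITOUS
from cresig.domains import CREAssignment
from cresig.intervals import GenomicInterval
from cresig.io import ExpressionTable


def assignment(gene, kind, specificity, start=1000):
    return CREAssignment(GenomicInterval("chr1", start, start + 500), kind, specificity, gene, 0)


def expr(values: dict[str, float], reps=2) -> ExpressionTable:
    return ExpressionTable(
        pd.DataFrame({f"r{i}": list(values.values()) for i in range(reps)}, index=list(values))
    )


# hand-written truth table over (specific prom, specific enh, ubiq prom, ubiq enh)
TRUTH_TABLE = {
    (0, 0, 0, 0): "unclassified",
    (0, 0, 0, 1): "unclassified",
    (0, 0, 1, 0): "unclassified",
    (0, 0, 1, 1): "IV",
    (0, 1, 0, 0): "III",
    (0, 1, 0, 1): "III",
    (0, 1, 1, 0): "III",
    (0, 1, 1, 1): "III",
    (1, 0, 0, 0): "II",
    (1, 0, 0, 1): "II",
    (1, 0, 1, 0): "II",
    (1, 0, 1, 1): "II",
    (1, 1, 0, 0): "I",
    (1, 1, 0, 1): "I",
    (1, 1, 1, 0): "I",
    (1, 1, 1, 1): "I",
}


def test_truth_table_exhaustive():
    """All 16 presence/absence combinations map to the documented
    category; specific CREs take precedence over ubiquitous ones."""
    for combo, expected in TRUTH_TABLE.items():
        assert category_from_counts(*combo) == expected

    # and via the full classify path, one synthetic gene per combination
    spec, ubiq = [], []
    for i, (sp, se, up, ue) in enumerate(TRUTH_TABLE):
        gid = f"g{i:02d}"
        if sp:
            spec.append(assignment(gid, PROMOTER, TARGET_SPECIFIC, 1000 + 10_000 * i))
        if se:
            spec.append(assignment(gid, ENHANCER, TARGET_SPECIFIC, 3000 + 10_000 * i))
        if up:
            ubiq.append(assignment(gid, PROMOTER, UBIQUITOUS, 5000 + 10_000 * i))
        if ue:
            ubiq.append(assignment(gid, ENHANCER, UBIQUITOUS, 7000 + 10_000 * i))
    table = classify_genes(spec, ubiq)
    for i, (combo, expected) in enumerate(TRUTH_TABLE.items()):
        gid = f"g{i:02d}"
        if any(combo):
            assert table.loc[gid, "category"] == expected, combo
        else:
            assert gid not in table.index  # no assignments, no row


def test_counts_invariant_to_order_and_duplication():
    spec = [
        assignment("g1", PROMOTER, TARGET_SPECIFIC, 100),
        assignment("g1", ENHANCER, TARGET_SPECIFIC, 700),
        assignment("g1", ENHANCER, TARGET_SPECIFIC, 700),  # exact duplicate
    ]
    t1 = classify_genes(spec, [])
    t2 = classify_genes(list(reversed(spec)), [])
    assert t1.equals(t2)
    assert t1.loc["g1", "n_specific_enhancers"] == 1
    assert t1.loc["g1", "category"] == "I"


def test_specificity_labels_validated():
    with pytest.raises(ValueError):
        classify_genes([assignment("g", PROMOTER, UBIQUITOUS)], [])
    with pytest.raises(ValueError):
        classify_genes([], [assignment("g", PROMOTER, TARGET_SPECIFIC)])


def test_filter_expressed_strict_threshold():
    table = expr({"a": 0.0, "b": 5.0, "c": 20.0, "d": 20.01, "e": 100.0})
    passing, pct = filter_expressed(table, 20.0)
    assert passing == {"d", "e"}
    assert pct == pytest.approx(100 * 2 / 4)  # of the 4 detectable genes
    all_detect, _ = filter_expressed(table, 0.0)
    assert all_detect == {"b", "c", "d", "e"}


def test_filter_expressed_empty_table_errors():
    with pytest.raises(ValueError):
        filter_expressed(expr({"a": 0.0, "b": 0.0}), 20.0)


def test_attach_expression_missing_genes_fail_filter():
    table = classify_genes([assignment("g1", PROMOTER, TARGET_SPECIFIC)], [])
    out = attach_expression(table, expr({"other": 50.0}), 20.0)
    assert out.loc["g1", "fpkm_avg"] == 0.0
    assert not out.loc["g1", "passes_expression"]


def test_category_summary_percentages():
    table = pd.DataFrame(
        {"category": ["I"] * 1311 + ["II"] * 4},
        index=[f"g{i}" for i in range(1315)],
    )
    expressed = {f"g{i}" for i in range(163)}  # 163 of the Category I genes
    summary = category_summary(table, expressed)
    assert summary["I"]["total"] == 1311
    assert summary["I"]["expressed"] == 163
    assert summary["I"]["pct_expressed"] == 12.4
    assert summary["II"]["pct_expressed"] == 0.0
    # all expressed -> 100% everywhere non-empty
    full = category_summary(table, set(table.index))
    assert full["I"]["pct_expressed"] == 100.0


def test_expression_breadth_patterns():
    tissues = {
        "heart": expr({"g1": 30.0, "g2": 10.0, "g3": 5.0}),
        "brain": expr({"g1": 0.0, "g2": 3.0, "g3": 1.0}),
        "liver": expr({"g1": 0.0, "g2": 0.0, "g3": 2.0}),
    }
    breadths, unmatched = expression_breadth(["g1", "g2", "g3", "gX"], tissues, target="heart")
    assert unmatched == ["gX"]
    by_gene = {b.gene_id: b for b in breadths}
    assert by_gene["g1"].exclusive_to_target
    assert by_gene["g2"].detected_tissues == {"heart", "brain"}
    assert by_gene["g3"].detected_tissues == {"heart", "brain", "liver"}
    assert not by_gene["g3"].exclusive_to_target


def test_expression_breadth_detect_threshold():
    tissues = {
        "heart": expr({"g1": 30.0}),
        "brain": expr({"g1": 0.5}),
    }
    loose, _ = expression_breadth(["g1"], tissues, target="heart", detect_threshold=0.0)
    strict, _ = expression_breadth(["g1"], tissues, target="heart", detect_threshold=1.0)
    assert loose[0].detected_tissues == {"heart", "brain"}
    assert strict[0].exclusive_to_target
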