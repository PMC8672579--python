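"""Synthetic multi-tissue epigenomes with planted ground truth.

The generator emulates the real study design — a four-tissue panel
(heart, brain, liver, limb) of H3K4me1/H3K4me3/H3K27ac peak sets plus
per-tissue replicate FPKM tables — at toy-genome scale, with known
ground truth for every planted signal:

* *Category I genes*: a target-tissue-only promoter (H3K4me3 peak) and
  enhancer (coincident H3K4me1+H3K27ac peaks) planted inside the gene's
  basal domain, high expression in the target tissue.
* *Category II / III genes*: only the promoter / only the enhancer.
* *Category IV genes*: a promoter+enhancer pair planted coincidently in
  every tissue.
* *Noise peaks*: per tissue per mark, placed uniformly; by default they
  avoid every planted locus so planted signals are never corrupted
  (set ``noise_avoid_planted=False`` to allow collisions).

Genes sit on an evenly spaced grid with per-gene jitter and random
strand, spaced widely enough that basal domains never overlap, so a CRE
planted inside a basal domain is assigned to exactly that gene.
Expression uses a high tier (uniform 25-500 FPKM) bracketing the
20-FPKM filter from above and a low tier (uniform 0.1-15) from below,
plus a zero-expression fraction; two technical replicates are drawn
with +/-10% multiplicative jitter around each gene's tier value.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cre import H3K27AC, H3K4ME1, H3K4ME3, MarkPanel
from .intervals import GenomicInterval, IntervalSet
from .io import (
    ChromSizes,
    ExpressionTable,
    GeneModel,
    write_bed,
    write_expression,
    write_tss_table,
)

DEFAULT_TISSUES = ("heart", "brain", "liver", "limb")


@dataclass
class SimConfig:
    """Study conditions for one simulated panel."""

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 40
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    target: str = "heart"
    n_cat1_genes: int = 5
    n_cat2_genes: int = 4
    n_cat3_genes: int = 4
    n_cat4_genes: int = 4
    n_noise_peaks_per_mark: int = 0
    noise_avoid_planted: bool = True
    peak_min_bp: int = 200
    peak_max_bp: int = 2_000
    mark_jitter_bp: int = 0  # offset between the two enhancer marks
    basal_up_bp: int = 5_000
    basal_down_bp: int = 1_000
    high_fpkm: tuple[float, float] = (25.0, 500.0)
    low_fpkm: tuple[float, float] = (0.1, 15.0)
    zero_fraction: float = 0.2  # undetected share of background genes
    high_fraction: float = 0.08  # highly expressed share of background genes
    other_high_fraction: float = 0.5  # cat II/III/IV genes highly expressed
    target_exclusive_fraction: float = 0.2  # cat I genes silent elsewhere
    n_replicates: int = 2

    def __post_init__(self) -> None:
        if self.target not in self.tissues:
            raise ValueError(f"target {self.target!r} not in tissues {self.tissues}")
        n_planted = self.n_cat1_genes + self.n_cat2_genes + self.n_cat3_genes + self.n_cat4_genes
        if n_planted > self.n_genes:
            raise ValueError(f"{n_planted} planted genes but only {self.n_genes} genes")
        if not (0 < self.peak_min_bp <= self.peak_max_bp):
            raise ValueError("require 0 < peak_min_bp <= peak_max_bp")
        if self.peak_max_bp > self.basal_up_bp + self.basal_down_bp:
            raise ValueError("peaks must fit inside a basal domain")
        if min(
            self.n_genes,
            self.n_noise_peaks_per_mark,
            self.n_chromosomes - 1,
            self.chrom_length,
        ) < 0:
            raise ValueError("counts must be non-negative (and >= 1 chromosome)")


@dataclass
class GroundTruth:
    """What was planted, per gene."""

    category: dict[str, str]  # gene_id -> I/II/III/IV/none
    expressed_target: dict[str, bool]  # FPKM_avg above 20 in target tissue
    detected_tissues: dict[str, list[str]]
    planted_cres: dict[str, dict[str, list[list]]]  # gene -> kind -> [[chrom,start,end],...]

    def genes_in_category(self, cat: str, expressed_only: bool = False) -> set[str]:
        out = {g for g, c in self.category.items() if c == cat}
        if expressed_only:
            out = {g for g in out if self.expressed_target[g]}
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimResult:
    config: SimConfig
    genes: list[GeneModel]
    chrom_sizes: ChromSizes
    panels: dict[str, MarkPanel]
    expression: dict[str, ExpressionTable]
    truth: GroundTruth

    def write_outputs(self, out_dir: str | Path) -> None:
        """Write the standard on-disk forms of every component."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tss_table(out / "genes.tsv", self.genes)
        with open(out / "chrom.sizes", "w") as fh:
            for chrom, length in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{length}\n")
        for tissue, panel in self.panels.items():
            for mark, peaks in panel.peaks.items():
                write_bed(out / f"{tissue}_{mark}.bed", peaks)
        for tissue, table in self.expression.items():
            write_expression(out / f"{tissue}_expression.tsv", table)
        (out / "ground_truth.json").write_text(self.truth.to_json())


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[GeneModel], ChromSizes]:
    sizes = ChromSizes({f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chromosomes)})
    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    margin = cfg.basal_up_bp + cfg.basal_down_bp
    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(sizes):
        n = per_chrom[ci]
        if n == 0:
            continue
        spacing = (cfg.chrom_length - 2 * margin) // n
        if spacing <= 2 * margin:
            raise ValueError(
                f"cannot place {n} genes on a {cfg.chrom_length} bp chromosome "
                "without overlapping basal domains"
            )
        jitter_span = max(1, (spacing - 2 * margin) // 2)
        for k in range(n):
            tss = margin + spacing * k + spacing // 2 + int(rng.integers(-jitter_span, jitter_span + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{gi:04d}", f"Sym{gi:04d}", chrom, strand, tss))
            gi += 1
    return genes, sizes


def _basal_span(gene: GeneModel, cfg: SimConfig) -> tuple[int, int]:
    if gene.strand == "+":
        return gene.tss - cfg.basal_up_bp, gene.tss + cfg.basal_down_bp
    return gene.tss - cfg.basal_down_bp, gene.tss + cfg.basal_up_bp


def _plant_peak(
    gene: GeneModel, cfg: SimConfig, rng: np.random.Generator, half: str
) -> GenomicInterval:
    """A peak inside one half of the gene's basal domain.

    Promoters go in the ``"left"`` half and enhancers in the ``"right"``
    half so the two planted CREs of a Category I gene never overlap.
    """
    bs, be = _basal_span(gene, cfg)
    mid = (bs + be) // 2
    lo, hi = (bs, mid) if half == "left" else (mid, be)
    max_len = min(cfg.peak_max_bp, hi - lo)
    length = int(rng.integers(cfg.peak_min_bp, max_len + 1)) if max_len > cfg.peak_min_bp else max_len
    start = int(rng.integers(lo, hi - length + 1))
    return GenomicInterval(gene.chrom, start, start + length)


def _jittered(iv: GenomicInterval, cfg: SimConfig, rng: np.random.Generator) -> GenomicInterval:
    """Second enhancer mark, optionally offset but always overlapping."""
    if cfg.mark_jitter_bp == 0:
        return iv
    shift = int(rng.integers(-cfg.mark_jitter_bp, cfg.mark_jitter_bp + 1))
    shift = max(shift, -(iv.length - 1), 1 - iv.length)  # keep >= 1 bp overlap
    return GenomicInterval(iv.chrom, max(0, iv.start + shift), max(0, iv.start + shift) + iv.length)


def _noise_peaks(
    cfg: SimConfig,
    rng: np.random.Generator,
    sizes: ChromSizes,
    forbidden: IntervalSet,
) -> list[GenomicInterval]:
    chroms = list(sizes)
    out: list[GenomicInterval] = []
    for _ in range(cfg.n_noise_peaks_per_mark):
        for _attempt in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            length = int(rng.integers(cfg.peak_min_bp, cfg.peak_max_bp + 1))
            start = int(rng.integers(0, sizes[chrom] - length))
            iv = GenomicInterval(chrom, start, start + length)
            if not cfg.noise_avoid_planted or not IntervalSet([iv]).overlaps_any(forbidden):
                out.append(iv)
                break
        else:
            raise ValueError("could not place noise peak disjoint from planted loci")
    return out


def simulate(config: SimConfig) -> SimResult:
    """Generate one synthetic panel with ground truth."""
    rng = np.random.default_rng(config.seed)
    genes, sizes = _place_genes(config, rng)

    # deterministic role assignment over a shuffled gene order
    order = list(rng.permutation(len(genes)))
    cursor = 0

    def take(n: int) -> list[GeneModel]:
        nonlocal cursor
        picked = [genes[i] for i in order[cursor : cursor + n]]
        cursor += n
        return picked

    cat1 = take(config.n_cat1_genes)
    cat2 = take(config.n_cat2_genes)
    cat3 = take(config.n_cat3_genes)
    cat4 = take(config.n_cat4_genes)

    category = {g.gene_id: "none" for g in genes}
    planted: dict[str, dict[str, list[list]]] = {}
    # per tissue per mark peak lists
    peaks: dict[str, dict[str, list[GenomicInterval]]] = {
        t: {m: [] for m in (H3K4ME1, H3K4ME3, H3K27AC)} for t in config.tissues
    }
    others = [t for t in config.tissues if t != config.target]

    def record(gene: GeneModel, kind: str, iv: GenomicInterval) -> None:
        planted.setdefault(gene.gene_id, {}).setdefault(kind, []).append(
            [iv.chrom, iv.start, iv.end]
        )

    def plant_promoter(gene: GeneModel, tissues: list[str]) -> None:
        iv = _plant_peak(gene, config, rng, "left")
        for t in tissues:
            peaks[t][H3K4ME3].append(iv)
        record(gene, "promoter", iv)

    def plant_enhancer(gene: GeneModel, tissues: list[str]) -> None:
        iv = _plant_peak(gene, config, rng, "right")
        for t in tissues:
            peaks[t][H3K4ME1].append(iv)
            peaks[t][H3K27AC].append(_jittered(iv, config, rng))
        record(gene, "enhancer", iv)

    for g in cat1:
        category[g.gene_id] = "I"
        plant_promoter(g, [config.target])
        plant_enhancer(g, [config.target])
    for g in cat2:
        category[g.gene_id] = "II"
        plant_promoter(g, [config.target])
    for g in cat3:
        category[g.gene_id] = "III"
        plant_enhancer(g, [config.target])
    for g in cat4:
        category[g.gene_id] = "IV"
        plant_promoter(g, list(config.tissues))
        plant_enhancer(g, list(config.tissues))

    forbidden = IntervalSet(
        iv for per_mark in peaks.values() for ivs in per_mark.values() for iv in ivs
    ).merge() if any(ivs for per_mark in peaks.values() for ivs in per_mark.values()) else IntervalSet()
    for t in config.tissues:
        for mark in (H3K4ME1, H3K4ME3, H3K27AC):
            peaks[t][mark].extend(_noise_peaks(config, rng, sizes, forbidden))

    panels = {
        t: MarkPanel(t, {m: IntervalSet(ivs) for m, ivs in per_mark.items()})
        for t, per_mark in peaks.items()
    }

    # -- expression ---------------------------------------------------------
    lo_hi = config.high_fpkm
    lo_lo = config.low_fpkm

    def tier_value(high: bool) -> float:
        lo, hi = lo_hi if high else lo_lo
        return float(rng.uniform(lo, hi))

    exclusive = {
        g.gene_id: bool(rng.random() < config.target_exclusive_fraction) for g in cat1
    }
    base: dict[str, dict[str, float]] = {t: {} for t in config.tissues}
    for g in genes:
        cat = category[g.gene_id]
        if cat == "I":
            target_high = True
        elif cat in ("II", "III", "IV"):
            target_high = bool(rng.random() < config.other_high_fraction)
        else:
            r = rng.random()
            target_high = r < config.high_fraction
            if config.high_fraction <= r < config.high_fraction + config.zero_fraction:
                base[config.target][g.gene_id] = 0.0
                for t in others:
                    base[t][g.gene_id] = 0.0 if rng.random() < 0.5 else tier_value(False)
                continue
        base[config.target][g.gene_id] = tier_value(target_high)
        silent_elsewhere = cat == "I" and exclusive[g.gene_id]
        for t in others:
            if silent_elsewhere:
                base[t][g.gene_id] = 0.0
            else:
                base[t][g.gene_id] = tier_value(bool(rng.random() < 0.5) and target_high)

    expression: dict[str, ExpressionTable] = {}
    for t in config.tissues:
        vals = np.array([base[t][g.gene_id] for g in genes])
        reps = {
            f"fpkm_rep{r + 1}": vals * rng.uniform(0.9, 1.1, size=len(vals))
            for r in range(config.n_replicates)
        }
        df = pd.DataFrame(reps, index=pd.Index([g.gene_id for g in genes], name="gene_id"))
        expression[t] = ExpressionTable(df)

    target_avg = expression[config.target].fpkm_avg
    expressed_target = {g.gene_id: bool(target_avg[g.gene_id] > 20.0) for g in genes}
    detected = {
        g.gene_id: sorted(
            t for t in config.tissues if expression[t].fpkm_avg[g.gene_id] > 0.0
        )
        for g in genes
    }

    truth = GroundTruth(
        category=category,
        expressed_target=expressed_target,
        detected_tissues=detected,
        planted_cres=planted,
    )
    return SimResult(config, genes, sizes, panels, expression, truth)
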