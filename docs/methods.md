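# Methods

## Coordinate conventions and interval algebra

All coordinates are 0-based half-open (`[start, end)`), the BED
convention of the input peak files. Consequences that matter:

* two spans sharing only a boundary do **not** overlap;
* `merge` nevertheless coalesces book-ended spans (bedtools-style), so
  a merged set is the minimal cover of the same basepairs;
* the overlap threshold `min_overlap_bp` (default 1: any shared
  basepair counts, the bedtools default) is applied **per reference
  interval**, not to summed overlap, which is why `overlaps_any` does
  not merge its reference first.

Interval sets have set semantics (duplicate spans collapse) and are
kept sorted per chromosome. The algebra is implemented as linear
sweeps over sorted span lists; every operation is property-tested
against a per-basepair boolean-array oracle on a toy chromosome.

## CRE calling and specificity

Active promoters are merged H3K4me3 peaks. Active enhancers are the
*intersection regions* of H3K4me1 and H3K27ac — the overlapping
portions, not whole peaks — because the two marks' peak boundaries
rarely coincide and the shared span is the defensible signal.
Enhancers overlapping H3K4me3 are kept by default;
`exclude_promoter_overlap=True` drops them for analyses that want
enhancers strictly clear of promoter chromatin.

Specificity is assessed kind-matched against the other tissues'
*called CREs* (promoter vs promoter, enhancer vs enhancer), not their
raw mark peaks: a target promoter is target-specific when no other
tissue's promoter set touches it (at `min_overlap_bp`), and ubiquitous
when every other tissue's promoter set does. Raw-mark comparison is a
stricter alternative a caller can compose manually
(`subtract_any(target, other_panel.peaks[mark])`); the kind-matched
default mirrors how the per-tissue CRE inventories are actually
compared. Specific and ubiquitous sets are provably disjoint subsets
of the target set, and specificity is monotone in the panel (adding a
tissue can only shrink it).

## Regulatory domains (basal + extension)

Each gene's basal window is strand-aware: 5,000 bp upstream and
1,000 bp downstream of the TSS (configurable), clipped to the
chromosome. The extended domain grows outward from each basal boundary
until the first basepair that is (a) beyond 1,000,000 bp from the
gene's own TSS, (b) off the chromosome, or (c) inside another gene's
basal window. Stated as boundaries: the extension stops at the nearest
flanking basal boundary owned by a gene whose basal window starts
strictly left (resp. ends strictly right) of ours; a neighbour whose
basal window straddles ours blocks extension entirely on that side,
and two genes with *identical* basal windows do not block each other
(neither owns a boundary inside the other's extension path). With
`max_extension=0` the domain degenerates to the basal window. The
implementation computes boundaries directly; the tests re-derive every
domain with a literal basepair walk of the rule above.

The hand-curated per-gene regulatory-domain exceptions that the GREAT
web service layers on top of this rule are deliberately not
implemented: they are an external, versioned list, and omitting them
is a documented source of small count differences against analyses
that used the service.

CRE-to-gene assignment produces one record per (CRE, gene) pair whose
extended domain the CRE overlaps — one CRE can serve several genes.
Signed TSS distance uses the CRE's floor midpoint, sign-flipped for
minus-strand genes so negative always means upstream; midpoint (rather
than nearest edge) is the default because it is unambiguous for CREs
spanning the TSS, and it is the only distance convention exposed.

## Gene categories and expression

Category assignment works on deduplicated per-gene CRE counts:

| specific promoter | specific enhancer | ubiquitous pair | category |
|---|---|---|---|
| ≥1 | ≥1 | — | I |
| ≥1 | 0 | — | II |
| 0 | ≥1 | — | III |
| 0 | 0 | promoter ≥1 and enhancer ≥1 | IV |
| 0 | 0 | anything less | unclassified |

Any specific CRE takes precedence over ubiquitous status, so the
categories partition the classified genes; all 16 presence/absence
combinations are pinned by an exhaustive truth-table test.

Expression uses replicate-averaged FPKM with a **strict** threshold
(FPKM<sub>avg</sub> > 20 by default); the filter also reports where the
threshold sits as a percentile of the detectably expressed
(FPKM<sub>avg</sub> > 0) transcriptome. Cross-tissue breadth marks a
gene detected in a tissue when FPKM<sub>avg</sub> exceeds a detection
threshold (default 0); genes absent from any tissue's table cannot be
matched across tissues and are reported separately rather than
silently dropped.

## Monte-Carlo overlap null

"Random CREs" are whole peaks resampled from the background pool —
peak resampling, not genome shuffling — because the question is
whether the *selected* peaks overlap validated regions more than an
arbitrary same-size selection from the same raw data would. Each
iteration draws `|query|` distinct pool regions (without replacement
within the iteration; iterations independent). Both p-values are
reported: the add-one empirical estimate `(r+1)/(n+1)`, which is never
exactly zero and conservative under ties, and a one-sided normal tail
from the null mean/SD (sample SD, ddof=1), flagged unusable when the
null is degenerate (SD = 0). Counting defaults to validated regions
hit by ≥1 query region; query-side counting is selectable. Tests
check the null mean and SD against exhaustive enumeration of all draws
on small pools, and type-I error calibration under a true null.

The Poisson enrichment helper is the upper tail P(X ≥ k) at the given
expectation, via `scipy.stats.poisson.sf(k-1, λ)`; k = 0 returns 1.

## Mortality index

MI = (curly − straight)/curly × 100 per cross; undefined (error) when
no curly progeny were scored, negative when straight-winged flies
outnumber curly (legal, classified unaffected). The published severity
legend has gaps between its bins (10–11, 30–31, 60–61); the
implementation uses contiguous half-open bins with edges at 10/30/60
(`unaffected ≤ 10 < low ≤ 30 < medium ≤ 60 < severe`) so every MI
classifies, with the edges configurable. The screen hit cutoff
(MI > 10) equals the ceiling of control-cross variation, so hits
coincide with non-unaffected records at default edges.

## Synthetic data

The generator emulates the study design, not the sequencing: a
four-tissue panel over a toy genome (default 2 chromosomes × 2 Mb, 40
genes on an evenly spaced, jittered grid with random strand, spacing
wide enough that basal windows never overlap). Planted signals:

* Category I genes (default 5): a target-only H3K4me3 peak in the
  upstream half of the basal window plus coincident H3K4me1+H3K27ac
  peaks in the downstream half (an optional jitter offsets the two
  enhancer marks while preserving overlap, exercising the
  partial-intersection path);
* Category II / III genes (4 each): promoter-only / enhancer-only;
* Category IV genes (4): the promoter+enhancer pair planted
  coincidently in **all** tissues;
* noise peaks: per tissue per mark, uniform positions, lengths uniform
  in 200–2,000 bp (typical of histone-mark peak calls); by default
  rejection-sampled to avoid every planted locus, so planted ground
  truth is never corrupted and noise only *adds* decoy calls.

Expression brackets the 20-FPKM filter from both sides: a high tier
uniform in [25, 500] FPKM (all Category-I genes; other planted genes
with probability 0.5), a low tier in [0.1, 15], a zero-expression
fraction (0.2) among background genes, and a high fraction (0.08)
of background genes mimicking a top-decile transcriptome share. Two
technical replicates apply ±10% multiplicative jitter; ground truth
(category, expression status, detected tissues, planted coordinates)
is recorded from what was actually drawn. A fraction (0.2) of
Category-I genes is made target-exclusive (zero FPKM elsewhere),
mirroring the observation that most — but not all — genes under
tissue-specific regulation are broadly expressed.

What the generator does **not** emulate: read-level noise, peak-caller
artefacts, correlated mark boundaries, chromatin domains, realistic
gene clustering, or mappability. Passing recovery tests therefore
demonstrates the pipeline's logic is exact under its own definitions,
not that those definitions are robust to real peak-calling noise —
that robustness is probed only coarsely by the decoy-peak regime.

## Problem sizes and determinism

Test and acceptance runs use toy scales chosen to keep brute-force
oracles exact and fast: 10 kb chromosomes for the per-basepair interval
oracle (1,000 random set pairs), 200 kb / ≤9 genes for the domain walk
oracle (100 annotations), pools of ≤12 regions for exhaustive
Monte-Carlo enumeration (C(12,4) draws), 500 replicate experiments for
null calibration, and 20 seeds × 40 genes for end-to-end recovery.
Every stochastic component takes an explicit seed (numpy
`default_rng`); the pipeline itself contains no randomness, and
identical seeds give bit-identical outputs, including on-disk files.

## Known limitations

* Specificity is binary at a basepair-overlap threshold; there is no
  signal-strength or differential-binding model.
* The GREAT curated-domain exceptions are omitted (above), so gene
  counts can differ slightly from service-based analyses.
* The Monte-Carlo null resamples peaks, so it conditions on the pool's
  length/GC composition only implicitly; no matched-sampling modes.
* Expression input is FPKM as published; no re-quantification or
  normalisation across tissues is attempted.
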