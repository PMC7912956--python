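# Methods

## Signal model

A paired-end library reads both ends of DNA fragments whose length
("insert size") is approximately normal. Against a reference genome,
two structural-variant signals survive in short-read data even when no
single read crosses a breakpoint informatively:

**Insertion signal — one-end-anchored pairs.** If the sample carries a
new insertion-sequence (IS) copy absent from the reference, fragments
spanning the insertion have one mate inside the element. Aligned
against reference + IS catalog, that mate either lands on the catalog
entry (class `IS_ANCHORED`) or fails to map (`MATE_UNMAPPED`). Both are
treated as insertion evidence: which of the two a real aligner produces
depends on whether the element is in the index and on its repeat copy
number, not on the biology. The anchored (reference-mapped) mate's
strand says which flank it comes from: forward-strand anchors sit on
the left flank of the breakpoint, reverse-strand anchors on the right.

**Deletion signal — stretched pairs.** A pair bridging a deletion of
size D maps with outer insert ≈ fragment + D. "Stretched" is defined
against a robust null model of the concordant insert distribution:
median m and σ = 1.4826·MAD, with the top 1% of inserts trimmed before
estimation so that genuine deletion-bridging pairs cannot inflate σ;
the threshold is m + k·σ with k = 5, putting the null false-positive
mass per pair near the normal 5σ tail (~3·10⁻⁷).

## Statistics

**Window scan.** Anchored-mate innermost coordinates are binned into
sliding windows (width 200 bp, step 50 bp) per replicon and flank side.
The background is Poisson with rate λ = window · (anchored mates on the
replicon / replicon length), floored at λ_min = 0.05 so that an
otherwise clean replicon still requires several co-located mates. A
window is significant when P(K ≥ k) ≤ α / n_windows, Bonferroni over
every window tested on any replicon and side, with family-wise
α = 0.01. Overlapping significant same-side windows merge (support =
max, window = union). A left cluster pairs with the nearest right
cluster starting within max_gap = insert_mean + 3·insert_sd downstream;
the breakpoint is the interval between the innermost window edges
(clamped to ≥ 1 base — paired-end evidence cannot localise to a base
without split reads). The element is the argmax of the pooled
mate-target histogram, `ambiguous` on ties or when only unmapped-mate
evidence exists; `MATE_UNMAPPED` pairs count toward support but not
toward the histogram. Significant clusters left unpaired (replicon
ends, repeat shadow) are emitted single-sided at doubled support
(2 × min_support) to avoid silent misses.

**Deletion calling.** Stretched pairs are single-linkage clustered on
their inner intervals (gap allowance = one σ). The reported interval is
the intersection of the cluster's inner intervals (which converges on
the deleted segment) or, if empty, their bounding interval. The size
estimate is

    est_size = median(cluster inserts) − m − σ²/(m − r)

where r is the read length. The last term corrects length-biased
selection: a fragment of length f can bridge the junction with both
mates mappable only over a start range of width ≈ f − r (each mate maps
to whichever side holds the larger half of the read), so bridging
fragments are sampled with weight ∝ (f − r) and run longer than the
library median by E[f(f−r)]/E[f−r] − m ≈ σ²/(m − r) (≈ 4.5 bp at
300 ± 30, r = 100). Without the correction the estimator fails its own
unbiasedness check (mean error within 3 SEM of 0 over 20 seeds for a
1 kb deletion at 50×); with it the residual bias — the median-vs-mean
offset of the weighted distribution — is a fraction of the SEM. Only
events with est_size > 200 bp are reported; 200 bp is the boundary
between this detector's scope and point-mutation/small-indel tooling,
and is the one deliberately fixed default. Cluster support gets the
same Poisson upper-tail annotation as insertion windows, against the
replicon-wide stretched-pair density.

## Simulator

The simulator is the package's validation instrument, not a fixture:
genomes are i.i.d. uniform nucleotides at a target GC; IS elements are
random sequences whose last ir_len bases are the reverse complement of
the first (terminal inverted repeats), rejection-sampled to < 60%
pairwise identity so mate mapping can discriminate elements;
transposition duplicates tsd_len host bases around the inserted element
(target-site duplication); fragments are truncated-normal with uniform
starts; errors are i.i.d. substitutions. The "ideal aligner" projects
each simulated mate back through the planted events: whole-segment
mates map at lifted coordinates, junction-straddling mates map to the
side with the larger contiguous anchor (soft-clipped) when that anchor
is ≥ min_anchor (default 20 bp) and are emitted unmapped otherwise.
With 100 bp reads the larger side is always ≥ 50 bp, so deletion
junctions produce soft-clipped concordant pairs rather than spurious
unmapped-mate insertion evidence — mirroring what bwa/minimap2 do —
while the insertion signal comes from mates fully inside the element.

### Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| coverage | 50× | sequenced bases per reference base |
| read_len | 100 bp | one mate |
| insert_mean ± sd | 300 ± 30 bp | fragment-length law (truncated at 2·read_len) |
| error_rate | 0.002 | per-base substitution probability |
| tsd_len / ir_len | 8 / 25 bp | typical IS-family values |
| k_sd | 5 | stretch threshold in robust σ units |
| min_mapq | 20 | pairs below are demoted to OTHER |
| window / step | 200 / 50 bp | anchor scan geometry |
| alpha | 0.01 | family-wise level, Bonferroni-corrected |
| lam_min | 0.05 | background floor per window |
| min_support | 4 | pairs per call (8 for single-sided) |
| min_event_size | 200 bp | deletion reporting cutoff |

Coverage, read length and the insert law are conventional values for a
bacterial Illumina resequencing run; the originating experiment's
library geometry is not on record, so these are the package's study
conditions, fixed once. At 50× each insertion flank collects ~40–60
anchored mates against a background λ ≈ 0.1 per window, so detection
operates many orders of magnitude beyond the significance boundary;
min_support, not α, is the practical floor.

### The `table4` scenario

Four replicons (chromosome, chromid and two megaplasmid stand-ins;
200 + 100 + 60 + 40 kb, GC 0.61 — a scaled-down CH34) with a
three-element catalog (IS1088 1050 bp, ISRme5 1200 bp, ISRme15
1500 bp) and seven planted transpositions disrupting seven annotated
loci: the locus tags, gene products and element identities (5× IS1088,
1× ISRme15, 1× ISRme5, including the IS1088 hit in the glpR repressor
Rmet_2235) are those observed in the zinc-resistant CH34 derivative;
the coordinates are synthetic stand-ins at the fixture genes' midpoints
because no genomic coordinates were published. Genome and catalog
sequences come from fixed seeds — a reference genome is a constant —
while read seeds vary per run.

### What the simulator does not emulate

- indel or homopolymer sequencing errors, quality-score variation
  (constant Q40), GC-coverage bias, chimeric fragments;
- pre-existing IS copies in the reference (in a real genome, mates of
  junction reads can map to an existing copy elsewhere — handled by the
  same IS_ANCHORED class, but the repeat-shadow mapping ambiguity is
  not exercised);
- a real aligner's mismapping noise: the projection is exact given the
  truth events.

Passing tests therefore demonstrate the detectors' statistical
machinery and bookkeeping, not robustness to aligner artefacts; on real
data the mapping-quality filter (min_mapq 20) is the main guard.

## Numerical and design choices

- Coordinates are 0-based half-open internally; SAM, GFF3 and all TSV
  outputs are 1-based per their conventions.
- Poisson tails use the scipy survival function (stable in the far
  tail); the test suite checks it against direct pmf summation to
  1e−12.
- Class assignment is evaluated in fixed priority order IS_ANCHORED →
  MATE_UNMAPPED → STRETCHED → CONCORDANT → OTHER, making the partition
  exhaustive and order-deterministic.
- Element ties (equal top histogram counts) report `ambiguous` rather
  than an arbitrary winner.
- Gene assignment uses the breakpoint-interval midpoint (ties: larger
  overlap, then lexicographic locus tag); deletions list every
  overlapped gene. Calls hitting no gene report
  `intergenic(upstream|downstream)`.
- Determinism: one `numpy.random.Generator` per simulation seeded from
  the config; identical configs give byte-identical FASTQ/SAM/TSV.
- Problem sizes in the validation suite (400 kb re-enactment at 50×;
  40–100 kb genomes for parameter-recovery and specificity batteries)
  were chosen so the full battery runs in minutes while keeping ≥ 15
  supporting pairs per flank and ≥ 9,000 model pairs, the regimes the
  statistics assume.

## Known limitations

- Breakpoints are interval-valued (window-edge resolution, typically
  tens of bp); split-read refinement is out of scope.
- Novel (non-catalog) element discovery and tandem-duplication vs
  insertion disambiguation are out of scope.
- Deletion size is estimated from insert excess only; coverage-drop
  corroboration would be a natural annotation but is not used.
- Sub-200 bp events are deliberately out of scope (point-mutation and
  small-indel callers own that regime).
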