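# Methods

This note records the analysis model, the synthetic-data generator, and the
numerical and design choices behind both.

## Coordinates and overlap

All intervals use the BED convention: 0-based, half-open `[start, end)`.
Two intervals overlap iff they share ≥1 base pair; abutting intervals
(`a.end == b.start`) do not overlap. Chromosome names are matched by exact
string comparison. Peaks are unstranded; their caller score is treated as an
opaque non-negative quantity and never re-derived from reads (primary peak
calling is out of scope).

## Master probes and novelty

Peaks from all samples are merged into *master probes*: connected components
of the ≥1 bp overlap graph over the pooled peaks, computed with a per-
chromosome sorted sweep (a new component starts whenever the next start is
≥ the running end). Each probe spans the union of its members and records a
sample → peak-id membership map. Probes within a set are pairwise
non-overlapping and sorted by (chrom, start).

A peak at titration level ℓ is **previous** iff its probe contains at least
one peak from a lower level (optionally: the immediately adjacent lower level
only), otherwise **new**. All level-0 peaks are new.

## Score structure

- *Score bins:* peaks of one level are sorted by (score descending, chrom,
  start) and chunked into consecutive bins of 1,000 (the last bin may be
  smaller); the new-peak fraction is reported per bin.
- *Score scaling:* for probes occupied at two chosen levels, each level
  contributes the maximum member score (0 if unoccupied). An ordinary
  least-squares fit (scipy `linregress`) of level-B on level-A scores
  estimates the per-level multiplier; probes absent from the lower level can
  be excluded so the slope reflects carried-over peaks only.

## Motif model

The consensus `GGGRN(Y)YYCC` is an IUPAC pattern in which the parenthesised
position is optional, expanding to 9- and 10-mer variants. Matching uses
compiled regular expressions with one overlap-permitting lookahead pattern
per variant width (a single alternation would report at most one variant per
offset), scanned on the forward sequence and its reverse complement; hit
coordinates always refer to the forward strand. Character classes enumerate
only A/C/G/T, so an `N` in the subject never satisfies a constrained
position.

PWM scanning scores every offset on both strands with the log2
likelihood ratio against a uniform background after adding a pseudocount of
1e-3 to the probability matrix and renormalising columns; windows containing
non-ACGT characters are skipped. The scan is vectorised with
`sliding_window_view`; the minus strand reuses the reversed-complemented LLR
matrix rather than rewriting the sequence.

## Enrichment test

A peak is a hit if its (optionally padded) sequence contains ≥1 motif match.
Enrichment of a target set over a disjoint background set is the exact
hypergeometric upper tail P(X ≥ k_target) for drawing n_target peaks from
the pooled population, computed as `scipy.stats.hypergeom.logsf` in log
space. Reporting −log10 p directly from the log survival function keeps
strongly enriched groups comparable instead of saturating at the float64
underflow limit (p < ~1e-308). No normal approximation is used anywhere; the
test suite checks the p-value against direct pmf enumeration with exact
integer binomial coefficients.

Background regions for enrichment are *neutral random regions*: fixed-width
intervals drawn uniformly (chromosome-weighted by length) while excluding
all peak intervals. Comparing each group against one common neutral
background — rather than against "peaks not in the group" — makes the
per-group −log10 p values directly comparable and independent of the other
groups' composition.

## Gene response and proximity

RPKM = count / (gene length in kbp × library size in millions). A gene is
*induced* if (mean post-stimulation RPKM + pseudocount) / (mean
pre-stimulation RPKM + pseudocount) strictly exceeds 5, with pseudocount 0.1;
division is guarded (0/0 → ratio 1, x/0 → ∞ so a clean
zero-to-expressed transition still classifies as induced).

Peaks are annotated to the nearest TSS by interval-midpoint distance
(`floor((start+end)/2)`), ties broken by lexicographic gene id. The signed
distance is negative upstream of the TSS with respect to gene strand. The
batch implementation uses `searchsorted` on per-chromosome sorted TSS arrays
and then collects *all* genes at the winning distance before applying the
tie-break, so duplicated TSS positions are handled exactly; the suite checks
it against exhaustive minimisation.

The proximity statistic splits each new-peak group into score deciles
(`np.array_split` on the score-sorted peaks, larger bins first) and reports
the induced-gene fraction per decile; empty bins report NaN, not 0.

## Cross-method comparison

- *Overlap matrix:* entry (r, c) is the percentage of sample c's peaks that
  overlap ≥1 peak of sample r; each column peak counts once no matter how
  many row peaks it touches; empty columns are NaN.
- *Venn partition:* master probes over both sets, partitioned into shared /
  A-only / B-only by membership; percentages are shared over each set's
  occupied probes. A peak-unit variant counts raw peaks instead.
- *Category groups:* each probe contributes one representative peak (the
  probe interval, maximum member score, minimum member p_adj) to exactly one
  of `both` / `a_only` / `b_only`, giving disjoint sets of equal interval
  width distribution for enrichment testing.

## Synthetic generator

All randomness flows from one `numpy.random.default_rng(seed)`; output files
are byte-identical across runs with the same configuration.

The generator produces a random genome (default 6 chromosomes × 1 Mb at 41%
GC), gene models with TSSs kept away from chromosome edges, and an RNA count
table (negative binomial, dispersion 0.3) in which a designed 25% of genes
are induced with fold changes in (8, 30). **Library sizes are drawn as
~10 M ± 5% rather than as count-table column sums**: the simulated genes
stand in for a small panel within a much larger transcriptome, and deriving
depth from the panel's own sums would let the induced genes inflate the
post-stimulation denominator and compress every RPKM ratio (a composition
bias that, at the designed effect sizes, misclassifies most induced genes).

Titration sites are placed by a bisect-based registry enforcing a minimum
gap (default 40 bp, > 2× the ±10 bp boundary jitter so jittered peaks can
never fuse across sites — peak counts per level are exact by construction).
Each level carries all previous sites (scores multiplied by d = 2.0 with
lognormal noise, cv 0.08) and adds new sites whose scores are drawn below
the 0.3 quantile of the carried scores (new peaks are weak by design). Sites
embed a consensus 10-mer at their centre (random strand) with per-level
probabilities (0.6, 0.4, 0.2, 0.1) and are placed within ±2 kb of an induced
TSS with per-level probabilities that likewise decrease; when no induced TSS
placement is available the site falls back to a uniform draw and the ground
truth records the actual outcome, not the intent.

The two-method pair lives on **dedicated "arena" chromosomes** separate from
the titration chromosomes. Sharing level-1 sites between the two experiments
would force one set of sites to satisfy two conflicting motif-rate designs
(per-titration-level rates vs per-category rates); separate arenas let each
design hold exactly. Method 2 re-calls a designed 55% of method-1 sites
(jittered boundaries, independent scores) plus its own exclusives; motif
embedding uses per-category rates (shared 0.6, method-1-only 0.25,
method-2-only 0.1).

Ground-truth tables record, per peak: the site id, first-appearance level,
motif embedding (and offset), nearest-induced placement, and category; per
gene: induced status and true fold.

### Scope and limits

The generator validates a pipeline's *inference logic*, not read-level
realism: there are no reads, no mappability or GC biases, no replicate
structure for peaks, no fragment-length model, and peak scores are drawn
from designed distributions rather than from coverage. Chance motif
occurrences in the random genome background are real (≈3% of 250 bp neutral
regions contain a consensus match) and are intentionally left in — the
enrichment statistics must stand out against a non-zero background rate.

## Validation

The test suite checks every fast path against an independent naive oracle
(per-pair union-find interval components, exhaustive nearest-gene
minimisation, integer pmf enumeration, explicit offset/strand motif scans)
and checks end-to-end parameter recovery on 20 fixed generator seeds:
novelty agreement 1.0 on every seed, slope within ±0.1 of 2.0 on every
seed, and the three enrichment/proximity orderings each holding in ≥95% of
seeds (in practice 20/20).
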