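# crosspeak

Analysis toolkit for crosslinker-titration ChIP-seq experiments and
cross-method peak-set comparison, with a fully synthetic data generator for
end-to-end validation.

## The problem

Standard ChIP-seq crosslinks chromatin with formaldehyde alone, which favours
direct, stable protein–DNA contacts. Adding a second, protein–protein
crosslinker (e.g. DSG) at increasing concentrations progressively stabilises
indirect and transient interactions, so each step up in crosslinker
concentration yields more called peaks. The scientific questions this package
addresses are:

1. **Which peaks are new at each titration level, and what are they like?**
   Peaks at a given level are classified as *previous* (their genomic location
   was already occupied at a lower level) or *new*. New peaks concentrate in
   the weak tail of the score distribution, are progressively depleted of the
   factor's consensus binding motif, and are less likely to sit near genes that
   respond transcriptionally to stimulation — the signature of indirect or
   opportunistic recruitment rather than direct sequence-specific binding.
2. **How do peak sets from two different methods compare?** An orthogonal
   low-crosslinking method (e.g. CUT&Tag) shares a core of peaks with ChIP-seq;
   shared peaks are the most motif-enriched, method-exclusive peaks the least.

## The model

All coordinates are BED convention: 0-based, half-open. Overlap means ≥1
shared base pair.

- **Master probes.** Peaks from all samples are merged into *master probes*:
  connected components of the ≥1 bp overlap graph (abutting intervals stay
  separate). Each probe records which peaks from which samples it contains.
- **Novelty.** A peak at level ℓ is *previous* iff its probe contains a peak
  from any level < ℓ, otherwise *new*. Level-0 peaks are all new.
- **Score scaling.** For probes occupied at two consecutive levels, an OLS fit
  of paired peak scores estimates the per-level score multiplier (the
  generator's designed value is 2.0).
- **Motif enrichment.** The consensus `GGGRN(Y)YYCC` (IUPAC; the parenthesised
  position is optional, so 9- and 10-mer variants both match) is scanned on
  both strands. Enrichment of a target peak set over a background set is an
  exact hypergeometric upper-tail test on ≥1-match-per-peak indicators,
  computed in log space. A PWM log-likelihood-ratio scanner is also provided.
- **Gene response.** RPKM per gene from a count table; a gene is *induced* if
  mean RPKM after stimulation exceeds 5× the pre-stimulation mean (with
  pseudocount). Peaks are annotated to the nearest TSS by midpoint distance.
- **Cross-method comparison.** Pairwise overlap matrix (percent of each
  sample's peaks overlapped by each other sample), probe-unit Venn partition,
  and shared / exclusive category groups for enrichment testing.
- **Synthetic generator.** Produces a genome, gene models, count tables and
  all peak sets with known ground truth: designed per-level motif-embedding
  rates (0.6, 0.4, 0.2, 0.1), induced-gene proximity rates, score doubling
  d = 2.0 with lognormal noise, and a designed shared/exclusive structure for
  the two-method pair. See `docs/methods.md` for details.

## Worked example

Venn percentages are plain shared/total ratios. With 3,638 shared regions in
a peak set of 6,616 regions:

```python
>>> from crosspeak.crossmethod import percent_shared
>>> round(percent_shared(3638, 6616))
55
```

A full synthetic run (`SynthConfig(seed=42)`, the default configuration used
by the `analysis/` scripts) recovers every designed property:

- Per-level peak counts 500 / 1,200 / 2,700 / 5,700; novelty classification
  finds 500 / 700 / 1,500 / 3,000 new peaks — exactly the generator's record.
- The paired-score OLS slope between the two highest levels is **1.993**
  (designed 2.0), Pearson r = 0.996.
- The fraction of new peaks per 1,000-peak score bin rises from 0.00 in the
  strongest bin to 0.97 in the weakest.
- Consensus-motif enrichment (−log10 p) by first-appearance group falls
  monotonically: 216.8 → 146.6 → 68.8 → 28.1.
- Top-score-decile induced-gene fractions of the new-peak groups decline
  0.54 → 0.40 → 0.35 → 0.24 across levels.
- The two-method comparison yields 55.0% of method-1 peaks shared, and
  category enrichment ranks shared (144.9) > method-1-only (41.2) >
  method-2-only (9.5).

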