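"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive — per-base coverage unions, exhaustive
minimisation, direct pmf enumeration — and shares no code with the package
paths it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np

from crosspeak.motifs import IUPAC


def overlap_components_bruteforce(intervals):
    """Spans of connected components under strict >=1 bp overlap.

    Quadratic union-find over all interval pairs; abutting intervals
    (end == start) share no base and therefore stay in separate components.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        si, ei = intervals[i]
        for j in range(i + 1, n):
            sj, ej = intervals[j]
            if si < ej and sj < ei:
                parent[find(i)] = find(j)
    spans = {}
    for i, (s, e) in enumerate(intervals):
        root = find(i)
        if root in spans:
            cs, ce = spans[root]
            spans[root] = (min(cs, s), max(ce, e))
        else:
            spans[root] = (s, e)
    return sorted(spans.values())


def ols_normal_equations(x, y):
    """Closed-form simple-regression coefficients and Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx * sx) * (n * (y * y).sum() - sy * sy))
    return slope, intercept, r


def hypergeom_upper_tail(k: int, population: int, successes: int, draws: int) -> float:
    """P(X >= k) by direct pmf summation."""
    total = comb(population, draws)
    acc = 0
    hi = min(draws, successes)
    for i in range(k, hi + 1):
        acc += comb(successes, i) * comb(population - successes, draws - i)
    return acc / total


_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def iupac_hits_bruteforce(sequence: str, pattern_variants):
    """All (start, width, strand) hits by per-position set membership."""
    seq = sequence.upper()
    rc = "".join(_RC[b] for b in reversed(seq))
    hits = set()
    for variant in pattern_variants:
        w = len(variant)
        sets = [set(IUPAC[c]) for c in variant]
        for strand, s in (("+", seq), ("-", rc)):
            for off in range(len(s) - w + 1):
                if all(s[off + j] in sets[j] for j in range(w)):
                    start = off if strand == "+" else len(seq) - off - w
                    hits.add((start, w, strand))
    return hits


def pwm_hits_bruteforce(sequence: str, pwm: np.ndarray, threshold: float,
                        background=(0.25, 0.25, 0.25, 0.25), pseudocount=1e-3):
    """All (start, strand, score) PWM hits by explicit offset/strand loops."""
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    p = pwm + pseudocount
    p = p / p.sum(axis=0)
    llr = np.log2(p / np.asarray(background)[:, None])
    w = llr.shape[1]
    seq = sequence.upper()
    rc = "".join(_RC[b] for b in reversed(seq))
    hits = []
    for strand, s in (("+", seq), ("-", rc)):
        for off in range(len(s) - w + 1):
            window = s[off : off + w]
            if any(b not in base_index for b in window):
                continue
            score = sum(llr[base_index[b], j] for j, b in enumerate(window))
            if score >= threshold:
                start = off if strand == "+" else len(seq) - off - w
                hits.append((start, strand, score))
    return hits


def nearest_gene_bruteforce(mid: int, chrom: str, genes):
    """Exhaustive nearest-TSS minimisation with the lexicographic tie-break."""
    candidates = [g for g in genes if g.chrom == chrom]
    if not candidates:
        return None
    return min(candidates, key=lambda g: (abs(mid - g.tss), g.gene_id))
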