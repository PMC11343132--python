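"""Consensus-motif matching, PWM scanning and hypergeometric peak enrichment.

The NF-κB (RelA:p50) recognition element is expressed here as the degenerate
consensus ``GGGRN(Y)YYCC`` — IUPAC codes with a parenthesised position that
may be skipped, so both the 10-mer and the 9-mer variant are scanned, on
both strands. Enrichment of a motif in a target peak group relative to a
background group is scored with an exact hypergeometric upper tail on the
per-peak "has at least one match" indicator; p-values are computed in log
space so strongly enriched groups remain comparable on the −log10(p) scale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .intervals import GenomicInterval, Peak, PeakSet

__all__ = [
    "IUPAC",
    "KB_CONSENSUS",
    "Motif",
    "MotifHit",
    "EnrichmentResult",
    "parse_iupac_pattern",
    "reverse_complement",
    "match_iupac",
    "find_iupac_hits",
    "scan_pwm",
    "extract_peak_sequences",
    "sample_peaks",
    "random_regions",
    "enrichment_test",
    "enrichment_report",
    "read_motif_tsv",
    "read_jaspar",
]

# IUPAC nucleotide ambiguity alphabet. A subject 'N' matches nothing:
# classes below enumerate concrete bases only.
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def parse_iupac_pattern(pattern: str) -> list[tuple[str, bool]]:
    """Parse e.g. ``GGGRN(Y)YYCC`` into ``[(code, optional_flag), ...]``."""
    positions: list[tuple[str, bool]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "(":
            j = pattern.find(")", i)
            if j != i + 2:
                raise ValueError(f"malformed optional position in {pattern!r}")
            code = pattern[i + 1].upper()
            if code not in IUPAC:
                raise ValueError(f"invalid IUPAC code {code!r} in {pattern!r}")
            positions.append((code, True))
            i = j + 1
        else:
            code = ch.upper()
            if code not in IUPAC:
                raise ValueError(f"invalid IUPAC code {code!r} in {pattern!r}")
            positions.append((code, False))
            i += 1
    return positions


@dataclass
class Motif:
    """A named motif: IUPAC consensus (with optional positions) and/or PWM.

    ``pwm`` is a 4 x width position-probability matrix, rows A/C/G/T,
    columns summing to 1. ``llr_threshold`` is the log2 likelihood-ratio
    cutoff (bits) for PWM hits.
    """

    name: str
    iupac: str | None = None
    pwm: np.ndarray | None = None
    llr_threshold: float | None = None

    _variants: list[str] = field(default_factory=list, repr=False)
    _regex_fwd: "re.Pattern[str] | None" = field(default=None, repr=False)
    _width_regexes: "list[re.Pattern[str]]" = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.iupac is None and self.pwm is None:
            raise ValueError(f"motif {self.name!r} needs an IUPAC pattern or a PWM")
        if self.iupac is not None:
            positions = parse_iupac_pattern(self.iupac)
            n_opt = sum(1 for _, opt in positions if opt)
            if n_opt > 2:
                raise ValueError("at most 2 optional positions are supported")
            self._variants = _expand_variants(positions)
            alts = sorted(set(self._variants), key=len, reverse=True)
            # One lookahead regex per variant width: a single alternation would
            # report at most one variant per offset, dropping same-start hits
            # of a different width.
            by_width: dict[int, list[str]] = {}
            for v in alts:
                by_width.setdefault(len(v), []).append(v)
            self._width_regexes = [
                re.compile(
                    "(?=("
                    + "|".join(
                        "".join(
                            f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in v
                        )
                        for v in group
                    )
                    + "))"
                )
                for _, group in sorted(by_width.items(), reverse=True)
            ]
            self._regex_fwd = self._width_regexes[0] if len(self._width_regexes) == 1 else re.compile(
                "|".join(p.pattern for p in self._width_regexes)
            )
        if self.pwm is not None:
            self.pwm = np.asarray(self.pwm, dtype=float)
            if self.pwm.shape[0] != 4:
                raise ValueError("PWM must have 4 rows (A, C, G, T)")
            if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError("PWM columns must each sum to 1")

    @property
    def variant_widths(self) -> list[int]:
        return sorted({len(v) for v in self._variants})


def _expand_variants(positions: list[tuple[str, bool]]) -> list[str]:
    variants = [""]
    for code, optional in positions:
        if optional:
            variants = [v + code for v in variants] + list(variants)
        else:
            variants = [v + code for v in variants]
    return variants


# The biochemically defined RelA:p50 recognition consensus.
KB_CONSENSUS = Motif(name="kB_consensus", iupac="GGGRN(Y)YYCC")


@dataclass(frozen=True)
class MotifHit:
    """A motif occurrence; ``start`` is on the forward strand of the subject."""

    start: int
    width: int
    strand: str
    score: float | None = None


def find_iupac_hits(sequence: str, motif: Motif) -> list[MotifHit]:
    """All occurrences of the consensus on both strands, overlapping allowed.

    Hit coordinates always refer to the forward strand of ``sequence``.
    """
    if motif._regex_fwd is None:
        raise ValueError(f"motif {motif.name!r} has no IUPAC pattern")
    seq = sequence.upper()
    rc = reverse_complement(seq)
    n = len(seq)
    hits: list[MotifHit] = []
    for regex in motif._width_regexes:
        for m in regex.finditer(seq):
            hits.append(MotifHit(m.start(), len(m.group(1)), "+"))
        for m in regex.finditer(rc):
            w = len(m.group(1))
            hits.append(MotifHit(n - m.start() - w, w, "-"))
    hits.sort(key=lambda h: (h.start, h.strand, h.width))
    return hits


def match_iupac(sequence: str, motif: Motif) -> bool:
    """True iff the sequence contains >= 1 consensus match on either strand."""
    if motif._regex_fwd is None:
        raise ValueError(f"motif {motif.name!r} has no IUPAC pattern")
    seq = sequence.upper()
    return bool(
        motif._regex_fwd.search(seq)
        or motif._regex_fwd.search(reverse_complement(seq))
    )


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PWM_PSEUDOCOUNT = 1e-3


def scan_pwm(
    sequence: str,
    motif: Motif,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> list[MotifHit]:
    """Score every offset on both strands with the PWM log-likelihood ratio.

    LLR(window) = sum over positions of log2(p[base] / background[base]),
    after adding a pseudocount of 1e-3 to the matrix entries and
    renormalising columns. Windows containing a base outside {A,C,G,T}
    (e.g. N) are skipped. A hit is an offset with LLR >= ``llr_threshold``.
    """
    if motif.pwm is None:
        raise ValueError(f"motif {motif.name!r} has no PWM")
    if motif.llr_threshold is None:
        raise ValueError(f"motif {motif.name!r} has no llr_threshold")
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background frequencies must sum to 1")
    p = motif.pwm + _PWM_PSEUDOCOUNT
    p = p / p.sum(axis=0)
    llr_matrix = np.log2(p / bg[:, None])  # 4 x w
    w = llr_matrix.shape[1]
    seq = sequence.upper()
    n = len(seq)
    if n < w:
        return []
    codes = np.fromiter((_BASE_INDEX.get(ch, -1) for ch in seq), dtype=np.int8, count=n)
    valid = codes >= 0
    hits: list[MotifHit] = []
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    window_valid = np.lib.stride_tricks.sliding_window_view(valid, w).all(axis=1)
    cols = np.arange(w)
    for strand in "+-":
        mat = llr_matrix if strand == "+" else llr_matrix[::-1, ::-1]
        scores = np.where(window_valid, mat[windows.clip(min=0), cols].sum(axis=1), -np.inf)
        for off in np.nonzero(scores >= motif.llr_threshold)[0]:
            hits.append(MotifHit(int(off), w, strand, float(scores[off])))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def extract_peak_sequences(
    peaks: PeakSet,
    genome: Mapping[str, str] | object,
    pad: int = 0,
) -> dict[str, str]:
    """Upper-case sequences under each peak, padded and clipped at chrom edges.

    ``genome`` is either a mapping chrom -> sequence string or a
    ``pyfaidx.Fasta``-like object (indexable by chrom, sliceable, with
    string conversion).
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    is_mapping = isinstance(genome, Mapping)
    available = set(genome.keys()) if is_mapping else set(genome.keys())  # pyfaidx has .keys()
    missing = sorted({p.interval.chrom for p in peaks} - available)
    if missing:
        raise KeyError(f"chromosomes absent from genome: {', '.join(missing)}")
    out: dict[str, str] = {}
    for p in peaks:
        iv = p.interval
        record = genome[iv.chrom]
        chrom_len = len(record)
        start = max(0, iv.start - pad)
        end = min(chrom_len, iv.end + pad)
        seq = record[start:end]
        out[p.peak_id] = str(seq).upper()
    return out


def sample_peaks(peak_set: PeakSet, n: int = 1000, seed: int = 0) -> PeakSet:
    """Uniform sample of peaks without replacement, deterministic in ``seed``.

    Returns all peaks when ``n`` is at least the set size. Sampled peaks
    keep their original relative order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= len(peak_set):
        return PeakSet(
            peak_set.label, list(peak_set.peaks),
            level=peak_set.level, level_value=peak_set.level_value,
            library_size=peak_set.library_size,
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(peak_set), size=n, replace=False))
    return PeakSet(
        f"{peak_set.label}_sample{n}",
        [peak_set.peaks[i] for i in idx],
        level=peak_set.level,
        level_value=peak_set.level_value,
        library_size=peak_set.library_size,
    )


def random_regions(
    chrom_sizes: Mapping[str, int],
    n: int,
    width: int,
    seed: int,
    exclude: Sequence[PeakSet] = (),
    label: str = "background",
    max_tries: int = 200,
) -> PeakSet:
    """Seeded uniform random fixed-width regions, optionally avoiding peaks.

    Intended as a neutral background for enrichment tests comparable across
    target groups.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_sizes)
    weights = np.array([chrom_sizes[c] - width for c in chroms], dtype=float)
    if (weights <= 0).any():
        raise ValueError("width exceeds a chromosome length")
    weights /= weights.sum()
    excluded: dict[str, list[tuple[int, int]]] = {}
    for ps in exclude:
        for p in ps:
            excluded.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
    for c in excluded:  # merge so searchsorted sees sorted, disjoint spans
        merged: list[tuple[int, int]] = []
        for s, e in sorted(excluded[c]):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        excluded[c] = merged
    starts = {c: np.array([s for s, _ in excluded.get(c, [])]) for c in chroms}
    ends = {c: np.array([e for _, e in excluded.get(c, [])]) for c in chroms}

    def clashes(chrom: str, s: int, e: int) -> bool:
        st, en = starts[chrom], ends[chrom]
        if len(st) == 0:
            return False
        i = np.searchsorted(en, s, side="right")
        return i < len(st) and st[i] < e

    peaks: list[Peak] = []
    for k in range(n):
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            s = int(rng.integers(0, chrom_sizes[chrom] - width))
            if not clashes(chrom, s, s + width):
                peaks.append(Peak(GenomicInterval(chrom, s, s + width), f"{label}_{k:06d}", 0.0))
                break
        else:
            raise RuntimeError("could not place a background region; genome too crowded")
    return PeakSet(label, peaks)


@dataclass(frozen=True)
class EnrichmentResult:
    motif_name: str
    n_target: int
    k_target: int
    n_background: int
    k_background: int
    p_value: float
    neg_log10_p: float


def _count_hits(
    peaks: PeakSet,
    motif: Motif,
    genome: Mapping[str, str] | object,
    mode: str,
) -> int:
    seqs = extract_peak_sequences(peaks, genome)
    if mode == "iupac":
        return sum(1 for s in seqs.values() if match_iupac(s, motif))
    return sum(1 for s in seqs.values() if scan_pwm(s, motif))


def enrichment_test(
    target: PeakSet,
    background: PeakSet,
    motif: Motif,
    genome: Mapping[str, str] | object,
    mode: str = "iupac",
) -> EnrichmentResult:
    """Exact hypergeometric upper-tail enrichment of >= 1-match peaks.

    The target and background peaks are pooled; p = P(X >= k_target) for X
    hypergeometric with population n_target + n_background, successes
    k_target + k_background, and n_target draws. No normal approximation.
    ``neg_log10_p`` is computed from the exact log tail, so it stays finite
    and comparable even when ``p_value`` underflows to 0.
    """
    if len(target) == 0:
        raise ValueError("target peak set is empty")
    if len(background) == 0:
        raise ValueError("background peak set is empty")
    if set(target.ids) & set(background.ids):
        raise ValueError("target and background peak-id spaces must be disjoint")
    if mode not in ("iupac", "pwm"):
        raise ValueError(f"unknown mode {mode!r}")
    k_t = _count_hits(target, motif, genome, mode)
    k_b = _count_hits(background, motif, genome, mode)
    n_t, n_b = len(target), len(background)
    log_p = stats.hypergeom.logsf(k_t - 1, n_t + n_b, k_t + k_b, n_t)
    return EnrichmentResult(
        motif_name=motif.name,
        n_target=n_t,
        k_target=k_t,
        n_background=n_b,
        k_background=k_b,
        p_value=float(np.exp(log_p)),
        neg_log10_p=float(-log_p / np.log(10.0)),
    )


def enrichment_report(
    groups: Mapping[str, PeakSet],
    background: PeakSet,
    motifs: Sequence[Motif],
    genome: Mapping[str, str] | object,
    mode: str = "iupac",
):
    """Enrichment of each motif in each peak group: a tidy table.

    Returns a pandas DataFrame with raw p-values (primary, matching the
    usual −log10(p) heat-map presentation) plus a Bonferroni-adjusted
    column over the motifs tested within each group.
    """
    import pandas as pd

    rows = []
    for label, ps in groups.items():
        for motif in motifs:
            res = enrichment_test(ps, background, motif, genome, mode=mode)
            rows.append(
                {
                    "group": label,
                    "motif": res.motif_name,
                    "n_target": res.n_target,
                    "k_target": res.k_target,
                    "n_background": res.n_background,
                    "k_background": res.k_background,
                    "p_value": res.p_value,
                    "neg_log10_p": res.neg_log10_p,
                }
            )
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = (df["p_value"] * len(motifs)).clip(upper=1.0)
    return df


def read_motif_tsv(path: str | Path) -> list[Motif]:
    """Read a two-column TSV (name, IUPAC pattern with optional parentheses)."""
    motifs: list[Motif] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, pattern = line.split("\t")[:2]
            motifs.append(Motif(name=name, iupac=pattern))
    return motifs


def read_jaspar(path: str | Path, llr_threshold: float = 6.0) -> list[Motif]:
    """Read JASPAR-format matrix blocks into PWM motifs (via Bio.motifs)."""
    from Bio import motifs as bio_motifs

    out: list[Motif] = []
    with open(path) as fh:
        for record in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([record.counts[b] for b in "ACGT"], dtype=float)
            ppm = counts / counts.sum(axis=0)
            out.append(Motif(name=record.name or record.matrix_id,
                             pwm=ppm, llr_threshold=llr_threshold))
    return out
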