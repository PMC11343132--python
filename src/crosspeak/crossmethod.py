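"""Cross-sample and cross-method peak-set concordance.

Two summaries of how peak collections agree: an asymmetric percent-overlap
matrix over an arbitrary list of samples (entry (r, c) = % of column-sample
c's peaks touched by row-sample r), and a two-set Venn partition counted in
merged-region (master-probe) units, the convention under which a single
overlap count can be percentaged against both samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    MasterProbeSet,
    Peak,
    PeakSet,
    merge_master_probes,
)

__all__ = [
    "OverlapMatrix",
    "VennPartition",
    "overlap_matrix",
    "venn_partition",
    "build_category_groups",
    "percent_shared",
]


@dataclass
class OverlapMatrix:
    """Asymmetric percent-overlap grid; NaN columns mark empty samples."""

    labels: list[str]
    percent: np.ndarray  # rows x columns
    n_peaks: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percent, index=self.labels, columns=self.labels)


@dataclass
class VennPartition:
    """Two-set partition in master-probe units."""

    label_a: str
    label_b: str
    shared_regions: int
    a_only: int
    b_only: int
    pct_of_a: float
    pct_of_b: float


def percent_shared(shared: int, total: int) -> float:
    """Percentage of a sample's regions that are shared (unrounded)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * shared / total


def _union_spans(ps: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Merged (start, end) arrays per chromosome for fast overlap queries."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in ps:
        by_chrom.setdefault(p.interval.chrom, []).append((p.interval.start, p.interval.end))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        merged: list[tuple[int, int]] = []
        for s, e in sorted(ivs):
            if merged and s < merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        out[chrom] = (
            np.array([s for s, _ in merged]),
            np.array([e for _, e in merged]),
        )
    return out


def _count_overlapping(column: PeakSet, row_spans: dict[str, tuple[np.ndarray, np.ndarray]]) -> int:
    """# of column peaks overlapping >= 1 bp of the row sample's union."""
    n = 0
    for p in column:
        entry = row_spans.get(p.interval.chrom)
        if entry is None:
            continue
        starts, ends = entry
        i = int(np.searchsorted(ends, p.interval.start, side="right"))
        if i < len(starts) and starts[i] < p.interval.end:
            n += 1
    return n


def overlap_matrix(samples: Sequence[PeakSet]) -> OverlapMatrix:
    """Pairwise asymmetric percent overlap across samples.

    Entry (r, c) = 100 x (# peaks of sample c overlapping >= 1 peak of
    sample r) / (# peaks of c). A column peak counts once no matter how
    many row peaks it touches; the diagonal is 100 for non-empty samples
    and an empty sample's column is NaN.
    """
    if not samples:
        raise ValueError("need at least one sample")
    labels = [s.label for s in samples]
    if len(labels) != len(set(labels)):
        raise ValueError("sample labels must be unique")
    spans = [_union_spans(s) for s in samples]
    n = len(samples)
    percent = np.full((n, n), np.nan)
    for c, col in enumerate(samples):
        if len(col) == 0:
            continue
        for r in range(n):
            percent[r, c] = 100.0 * _count_overlapping(col, spans[r]) / len(col)
    return OverlapMatrix(labels, percent, [len(s) for s in samples])


def venn_partition(a: PeakSet, b: PeakSet, unit: Literal["probe", "peak"] = "probe") -> VennPartition:
    """Two-set Venn counts over the merged master-probe universe of a ∪ b.

    With the default ``probe`` unit a "region" is a connected component of
    overlapping peaks from either set, so one shared count can be expressed
    as a percentage of the regions occupied by each sample. With
    ``unit="peak"`` the shared counts are raw peaks of each sample touching
    the other set (reported via the occupied totals; shared_regions then
    counts probes all the same).
    """
    probes = merge_master_probes([a, b])
    occ_a = occ_b = shared = 0
    for probe in probes:
        in_a, in_b = probe.occupied_by(a.label), probe.occupied_by(b.label)
        occ_a += in_a
        occ_b += in_b
        shared += in_a and in_b
    if unit == "peak":
        spans_a, spans_b = _union_spans(a), _union_spans(b)
        occ_a, occ_b = len(a), len(b)
        shared_a = _count_overlapping(a, spans_b)
        shared_b = _count_overlapping(b, spans_a)
        return VennPartition(
            a.label, b.label, shared,
            occ_a - shared_a, occ_b - shared_b,
            percent_shared(shared_a, occ_a) if occ_a else float("nan"),
            percent_shared(shared_b, occ_b) if occ_b else float("nan"),
        )
    return VennPartition(
        a.label, b.label, shared, occ_a - shared, occ_b - shared,
        percent_shared(shared, occ_a) if occ_a else float("nan"),
        percent_shared(shared, occ_b) if occ_b else float("nan"),
    )


def build_category_groups(a: PeakSet, b: PeakSet) -> dict[str, PeakSet]:
    """Partition the probe universe of a ∪ b into both / a-only / b-only.

    Each probe is represented by one synthetic peak carrying the probe
    interval, the maximum member score, and the minimum member p_adj, ready
    for downstream motif enrichment. The three groups are disjoint and
    together cover every probe.
    """
    probes = merge_master_probes([a, b])
    peaks_a, peaks_b = a.by_id(), b.by_id()
    groups: dict[str, list[Peak]] = {"both": [], "a_only": [], "b_only": []}
    for i, probe in enumerate(probes):
        members = [peaks_a[pid] for pid in probe.members.get(a.label, ())]
        members += [peaks_b[pid] for pid in probe.members.get(b.label, ())]
        rep = Peak(
            probe.interval,
            f"probe_{i:06d}",
            max(m.score for m in members),
            min(m.p_adj for m in members),
        )
        in_a, in_b = probe.occupied_by(a.label), probe.occupied_by(b.label)
        key = "both" if (in_a and in_b) else ("a_only" if in_a else "b_only")
        groups[key].append(rep)
    return {
        "both": PeakSet(f"{a.label}+{b.label}", groups["both"]),
        "a_only": PeakSet(f"{a.label}_only", groups["a_only"]),
        "b_only": PeakSet(f"{b.label}_only", groups["b_only"]),
    }
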