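"""Genomic-interval primitives, BED I/O, master-probe merging and peak filtering.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Two intervals overlap iff they share at least one base pair; abutting
intervals (``a.end == b.start``) do not overlap. The "master probe" universe
is the set of connected components of the any-overlap graph over all peaks
from all samples — the common comparison unit used when peak boundaries
shift between experimental conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "MasterProbe",
    "MasterProbeSet",
    "BedParseError",
    "read_bed",
    "write_bed",
    "merge_master_probes",
    "rpkm_peak",
    "filter_peaks",
]


class BedParseError(ValueError):
    """Raised for a malformed BED line; the message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if not self.start < self.end:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A scored peak-caller interval with its adjusted p-value.

    ``score`` is treated as an opaque non-negative caller score; ``p_adj``
    defaults to 0.0 when the source file carries no p-value column, so that
    score-only filtering behaves as expected.
    """

    interval: GenomicInterval
    peak_id: str
    score: float
    p_adj: float = 0.0

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"negative score for {self.peak_id}: {self.score}")
        if not 0.0 <= self.p_adj <= 1.0:
            raise ValueError(f"p_adj outside [0, 1] for {self.peak_id}: {self.p_adj}")


@dataclass
class PeakSet:
    """A labeled collection of peaks from one sample/condition.

    ``level`` is the ordinal position in a condition series (0 = lowest
    crosslinker concentration) and ``level_value`` the concentration itself
    (e.g. mM DSG or % formaldehyde). ``library_size`` is in millions of
    mapped reads when present.
    """

    label: str
    peaks: list[Peak] = field(default_factory=list)
    level: int = 0
    level_value: float = 0.0
    library_size: float | None = None

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate peak_id in {self.label!r}: {dup!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    @property
    def ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    def by_id(self) -> dict[str, Peak]:
        return {p.peak_id: p for p in self.peaks}


@dataclass
class MasterProbe:
    """A merged region with the peak ids of every contributing sample."""

    interval: GenomicInterval
    members: dict[str, set[str]] = field(default_factory=dict)

    def occupied_by(self, label: str) -> bool:
        return bool(self.members.get(label))


class MasterProbeSet:
    """Non-overlapping merged probes sorted by (chrom, start).

    Also indexes peak -> probe so downstream analyses can resolve peak
    identity across conditions through the probe graph.
    """

    def __init__(self, probes: list[MasterProbe]):
        self.probes = sorted(probes, key=lambda p: (p.interval.chrom, p.interval.start))
        for a, b in zip(self.probes, self.probes[1:]):
            if a.interval.overlaps(b.interval):
                raise ValueError("master probes must be pairwise non-overlapping")
        self._peak_index: dict[tuple[str, str], int] = {}
        for i, probe in enumerate(self.probes):
            for label, ids in probe.members.items():
                for pid in ids:
                    self._peak_index[(label, pid)] = i

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self) -> Iterator[MasterProbe]:
        return iter(self.probes)

    def probe_index_of(self, label: str, peak_id: str) -> int:
        return self._peak_index[(label, peak_id)]

    def probe_of(self, label: str, peak_id: str) -> MasterProbe:
        return self.probes[self.probe_index_of(label, peak_id)]

    def occupied_indices(self, label: str) -> set[int]:
        return {i for i, p in enumerate(self.probes) if p.occupied_by(label)}

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.probes]


def merge_master_probes(sets: Sequence[PeakSet]) -> MasterProbeSet:
    """Merge all peaks from all sets into a master-probe universe.

    Probes are the maximal unions of transitively overlapping intervals
    (connected components under the >= 1 bp overlap relation), computed by a
    single sorted sweep per chromosome.
    """
    if not sets:
        raise ValueError("merge_master_probes requires at least one PeakSet")
    events: list[tuple[str, int, int, str, str]] = []
    for ps in sets:
        for p in ps.peaks:
            iv = p.interval
            events.append((iv.chrom, iv.start, iv.end, ps.label, p.peak_id))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    probes: list[MasterProbe] = []
    cur_chrom: str | None = None
    cur_start = cur_end = 0
    cur_members: dict[str, set[str]] = {}

    def flush() -> None:
        if cur_chrom is not None:
            probes.append(
                MasterProbe(
                    GenomicInterval(cur_chrom, cur_start, cur_end),
                    {k: set(v) for k, v in cur_members.items()},
                )
            )

    for chrom, start, end, label, pid in events:
        if chrom != cur_chrom or start >= cur_end:
            flush()
            cur_chrom, cur_start, cur_end = chrom, start, end
            cur_members = {}
        else:
            cur_end = max(cur_end, end)
        cur_members.setdefault(label, set()).add(pid)
    flush()
    return MasterProbeSet(probes)


def rpkm_peak(read_count: int, peak: Peak, library_size_millions: float) -> float:
    """Reads per kb of peak per million mapped reads."""
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    if library_size_millions <= 0:
        raise ValueError("library size must be positive (millions of reads)")
    length_kbp = peak.interval.length / 1000.0
    return read_count / (length_kbp * library_size_millions)


def filter_peaks(peak_set: PeakSet, p_adj_max: float = 0.01, min_score: float = 19.0) -> PeakSet:
    """Keep peaks with ``p_adj < p_adj_max`` and ``score > min_score``.

    Both inequalities are strict: a peak scoring exactly ``min_score`` is
    removed, as is a peak with ``p_adj`` exactly at the cutoff.
    """
    kept = [p for p in peak_set.peaks if p.p_adj < p_adj_max and p.score > min_score]
    return replace(peak_set, peaks=kept)


def read_bed(
    path: str | Path,
    score_column: int = 4,
    p_adj_column: int | None = None,
    label: str | None = None,
    level: int = 0,
    level_value: float = 0.0,
) -> PeakSet:
    """Read a tab- or whitespace-separated BED-like file into a PeakSet.

    Column indices are 0-based; column 3 is used as the peak name when
    present, otherwise ids are synthesised as ``<label>_<lineno>``. Input
    order is preserved.
    """
    path = Path(path)
    set_label = label if label is not None else path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else f"{set_label}_{lineno}"
                score = float(fields[score_column]) if len(fields) > score_column else 0.0
                p_adj = (
                    float(fields[p_adj_column])
                    if p_adj_column is not None and len(fields) > p_adj_column
                    else 0.0
                )
                interval = GenomicInterval(chrom, start, end)
                peaks.append(Peak(interval, name, score, p_adj))
            except (ValueError, IndexError) as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(set_label, peaks, level=level, level_value=level_value)


def write_bed(peak_set: PeakSet, path: str | Path, p_adj_column: bool = True) -> None:
    """Write a PeakSet as BED6(+1): chrom start end name score strand [p_adj]."""
    with open(path, "w") as fh:
        for p in peak_set.peaks:
            iv = p.interval
            cols = [iv.chrom, str(iv.start), str(iv.end), p.peak_id, repr(p.score), iv.strand]
            if p_adj_column:
                cols.append(repr(p.p_adj))
            fh.write("\t".join(cols) + "\n")


def write_probes_bed(probes: MasterProbeSet, path: str | Path) -> None:
    """Write master probes as BED with a membership-summary column."""
    with open(path, "w") as fh:
        for probe in probes:
            iv = probe.interval
            summary = ";".join(
                f"{label}:{len(ids)}" for label, ids in sorted(probe.members.items())
            )
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{summary}\n")
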