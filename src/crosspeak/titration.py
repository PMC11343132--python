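"""Ordered condition-series analysis for crosslinker titrations.

A titration series is a list of peak sets at strictly increasing crosslinker
concentration. At each concentration a peak is *previous* if the master
probe it occupies was already occupied at any lower concentration, and
*new* otherwise. Downstream summaries — score-rank binning of the new
fraction, paired-score scatters between adjacent levels and the best-fit
slope — quantify how raising the crosslinker concentration inflates scores
of existing binding sites while adding many weak new ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .intervals import MasterProbeSet, Peak, PeakSet, merge_master_probes

__all__ = [
    "ConditionSeries",
    "NoveltyCall",
    "ScoreBin",
    "PairedScores",
    "classify_novelty",
    "first_appearance_levels",
    "bin_by_score",
    "paired_scores",
    "fit_slope",
]


@dataclass
class ConditionSeries:
    """Peak sets ordered by strictly increasing condition value."""

    series_label: str
    sets: list[PeakSet]

    def __post_init__(self) -> None:
        if len(self.sets) < 2:
            raise ValueError("a condition series needs at least two levels")
        values = [s.level_value for s in self.sets]
        if not all(a < b for a, b in zip(values, values[1:])):
            raise ValueError(f"level values must be strictly increasing, got {values}")
        for i, s in enumerate(self.sets):
            s.level = i

    @property
    def n_levels(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class NoveltyCall:
    peak_id: str
    level: int
    label: Literal["new", "previous"]


@dataclass
class ScoreBin:
    """One score-rank bin; index 0 holds the highest-scoring peaks."""

    bin_index: int
    peak_ids: list[str]
    fraction_new: float

    @property
    def n(self) -> int:
        return len(self.peak_ids)


@dataclass
class PairedScores:
    """Per-probe score pairs between two levels; 0 marks an unoccupied level."""

    level_pair: tuple[int, int]
    rows: list[tuple[str, float, float]]


def classify_novelty(
    series: ConditionSeries,
    against: Literal["all_lower", "adjacent"] = "all_lower",
) -> list[NoveltyCall]:
    """Label every peak at every level as new or previous.

    A peak is *previous* iff its master probe overlaps (>= 1 bp, resolved
    through the probe graph over the whole series) at least one peak from a
    lower level — any lower level by default, only the immediately preceding
    one with ``against="adjacent"``. All level-0 peaks are new.
    """
    probes = merge_master_probes(series.sets)
    # earliest level occupying each probe
    first_level = np.full(len(probes), len(series.sets), dtype=int)
    for i, probe in enumerate(probes.probes):
        for ps in series.sets:
            if probe.occupied_by(ps.label):
                first_level[i] = ps.level
                break
    occupied_at = [
        {i for i, p in enumerate(probes.probes) if p.occupied_by(ps.label)}
        for ps in series.sets
    ]
    calls: list[NoveltyCall] = []
    for ps in series.sets:
        for peak in ps.peaks:
            idx = probes.probe_index_of(ps.label, peak.peak_id)
            if against == "all_lower":
                prev = first_level[idx] < ps.level
            else:
                prev = ps.level > 0 and idx in occupied_at[ps.level - 1]
            calls.append(NoveltyCall(peak.peak_id, ps.level, "previous" if prev else "new"))
    return calls


def first_appearance_levels(series: ConditionSeries) -> tuple[MasterProbeSet, np.ndarray]:
    """Master probes of the series with each probe's earliest occupied level."""
    probes = merge_master_probes(series.sets)
    first = np.full(len(probes), len(series.sets), dtype=int)
    for i, probe in enumerate(probes.probes):
        for ps in series.sets:
            if probe.occupied_by(ps.label):
                first[i] = ps.level
                break
    return probes, first


def _rank_order(peaks: Sequence[Peak]) -> list[Peak]:
    # deterministic: score desc, then genomic position
    return sorted(peaks, key=lambda p: (-p.score, p.interval.chrom, p.interval.start))


def bin_by_score(
    peak_set: PeakSet,
    novelty: Iterable[NoveltyCall],
    bin_size: int = 1000,
) -> list[ScoreBin]:
    """Chunk score-ranked peaks into fixed-size bins and count the new fraction.

    Bin 0 holds the highest scores; a final partial bin keeps its true size.
    Only novelty calls matching this set's level are consulted.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    labels = {c.peak_id: c.label for c in novelty if c.level == peak_set.level}
    ranked = _rank_order(peak_set.peaks)
    bins: list[ScoreBin] = []
    for b, lo in enumerate(range(0, len(ranked), bin_size)):
        chunk = ranked[lo : lo + bin_size]
        ids = [p.peak_id for p in chunk]
        n_new = sum(1 for i in ids if labels.get(i) == "new")
        bins.append(ScoreBin(b, ids, n_new / len(ids)))
    return bins


def paired_scores(series: ConditionSeries, lower: int, higher: int) -> PairedScores:
    """Per-probe (lower, higher) max-score pairs for a scatter comparison.

    Probes are rebuilt from just the two levels. A probe unoccupied at one
    level carries score 0 there, reproducing the vertical line of new peaks
    on the x-axis of the titration scatters.
    """
    if not 0 <= lower < higher < series.n_levels:
        raise ValueError(f"invalid level pair ({lower}, {higher})")
    lo_set, hi_set = series.sets[lower], series.sets[higher]
    probes = merge_master_probes([lo_set, hi_set])
    lo_peaks = lo_set.by_id()
    hi_peaks = hi_set.by_id()
    rows: list[tuple[str, float, float]] = []
    for i, probe in enumerate(probes.probes):
        by_lo = probe.members.get(lo_set.label, set())
        by_hi = probe.members.get(hi_set.label, set())
        s_lo = max((lo_peaks[pid].score for pid in by_lo), default=0.0)
        s_hi = max((hi_peaks[pid].score for pid in by_hi), default=0.0)
        if s_lo == 0.0 and s_hi == 0.0:
            continue
        rows.append((f"probe_{i:06d}", s_lo, s_hi))
    return PairedScores((lower, higher), rows)


def fit_slope(pairs: PairedScores, include_new: bool = False) -> tuple[float, float, float]:
    """Ordinary least-squares fit of the higher-level score on the lower.

    Returns ``(slope, intercept, pearson_r)``. By default, rows with a zero
    lower-level score (peaks new at the higher level) are excluded so the
    slope reflects the score change of shared binding sites.
    """
    rows = pairs.rows if include_new else [r for r in pairs.rows if r[1] > 0.0]
    if len(rows) < 2:
        raise ValueError("need >= 2 rows to fit a line")
    x = np.array([r[1] for r in rows])
    y = np.array([r[2] for r in rows])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: lower-level scores are constant")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)
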