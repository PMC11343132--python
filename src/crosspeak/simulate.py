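"""Seeded generator of a complete toy crosslinker-titration study.

The generator emits everything the analysis consumes — a random genome,
gene models, replicate count tables, an ordered series of peak sets, and a
second-method peak pair — together with per-peak and per-gene ground truth,
so every pipeline stage can be checked against its designed answer.

The emulated statistical structure:

* an ordered series of peak sets in which carried-over binding sites
  roughly double in score per level (multiplicative lognormal noise),
  while each level adds new sites whose scores are drawn below a quantile
  cap of the existing score distribution (new peaks are weak);
* consensus-motif embedding probability and induced-gene proximity that
  decline with the level at which a site first appears;
* negative-binomial replicate counts at two time points with a designed
  induced-gene fraction and fold range;
* a second profiling method sharing a configured fraction of the first
  method's sites, generated on dedicated "arena" chromosomes with its own
  per-category motif-embedding rates (shared / method-1-only /
  method-2-only).

Identical seeds give byte-identical written bundles.
"""

from __future__ import annotations

import bisect
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genes import CountTable, GeneModel, write_gene_models
from .intervals import GenomicInterval, Peak, PeakSet, write_bed
from .motifs import IUPAC, parse_iupac_pattern, reverse_complement

__all__ = ["SynthConfig", "SynthBundle", "generate", "write_bundle", "truth_check"]


@dataclass
class SynthConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults encode the emulated study design: four crosslinker levels
    (0/1/2/4 mM-like), per-level new-peak counts 0/700/1500/3000 on a
    500-site base, score doubling (d = 2) with 5% multiplicative noise, and
    designed declining motif-embedding and induced-proximity gradients.
    """

    seed: int = 0
    # genome
    n_chroms: int = 4
    chrom_length_bp: int = 1_000_000
    n_arena_chroms: int = 2
    arena_chrom_length_bp: int = 1_000_000
    gc_content: float = 0.41
    # genes & expression
    n_genes: int = 600
    induced_fraction: float = 0.25
    induced_fold_range: tuple[float, float] = (8.0, 30.0)
    nb_dispersion: float = 0.1
    n_replicates: int = 3
    base_mean_count: float = 200.0
    # titration series
    n_levels: int = 4
    level_values: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0)
    base_peaks: int = 500
    new_peaks_per_level: tuple[int, ...] = (0, 700, 1500, 3000)
    score_doubling_factor: float = 2.0
    score_noise_cv: float = 0.05
    new_peak_score_quantile_cap: float = 0.3
    p_motif_per_level: tuple[float, ...] = (0.6, 0.4, 0.2, 0.1)
    p_near_induced_per_level: tuple[float, ...] = (0.5, 0.35, 0.2, 0.1)
    # cross-method arena
    method1_count: int = 1200
    method2_shared_fraction: float = 0.55
    method2_exclusive_count: int = 1500
    p_motif_shared: float = 0.6
    p_motif_m1_only: float = 0.25
    p_motif_m2_only: float = 0.1
    # geometry
    peak_width_range: tuple[int, int] = (150, 300)
    min_gap: int = 40
    jitter: int = 10
    near_tss_window: int = 2000

    def __post_init__(self) -> None:
        probs = (
            list(self.p_motif_per_level)
            + list(self.p_near_induced_per_level)
            + [self.p_motif_shared, self.p_motif_m1_only, self.p_motif_m2_only,
               self.method2_shared_fraction, self.induced_fraction, self.gc_content,
               self.new_peak_score_quantile_cap]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities/fractions must lie in [0, 1]")
        for name in ("p_motif_per_level", "p_near_induced_per_level"):
            seq = getattr(self, name)
            if len(seq) != self.n_levels:
                raise ValueError(f"{name} must have one entry per level")
            if any(a < b for a, b in zip(seq, seq[1:])):
                raise ValueError(f"{name} must be non-increasing in level")
        if len(self.new_peaks_per_level) != self.n_levels:
            raise ValueError("new_peaks_per_level must have one entry per level")
        if self.new_peaks_per_level[0] != 0:
            raise ValueError("level 0 adds no peaks beyond base_peaks (entry must be 0)")
        if len(self.level_values) != self.n_levels:
            raise ValueError("level_values must have one entry per level")
        if any(a >= b for a, b in zip(self.level_values, self.level_values[1:])):
            raise ValueError("level_values must be strictly increasing")
        if self.score_doubling_factor <= 0:
            raise ValueError("score_doubling_factor must be positive")
        if self.induced_fold_range[0] <= 5:
            raise ValueError("induced fold lower bound must exceed the x5 induction rule")
        if self.min_gap < 2 * self.jitter + 1:
            raise ValueError("min_gap must exceed twice the jitter to keep sites disjoint")
        w_hi = self.peak_width_range[1]
        n_sites = self.base_peaks + sum(self.new_peaks_per_level)
        if n_sites * (w_hi + self.min_gap) > 0.8 * self.n_chroms * self.chrom_length_bp:
            raise ValueError("titration sites exceed genome capacity")
        n_arena = self.method1_count + self.method2_exclusive_count
        if n_arena * (w_hi + self.min_gap) > 0.8 * self.n_arena_chroms * self.arena_chrom_length_bp:
            raise ValueError("arena sites exceed arena capacity")

    @classmethod
    def from_file(cls, path: str | Path) -> "SynthConfig":
        """Load a flat key-value config (YAML or TOML by extension)."""
        path = Path(path)
        if path.suffix in (".toml", ".tml"):
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            import yaml

            data = yaml.safe_load(path.read_text())
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in data.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs)


@dataclass
class SynthBundle:
    """Everything one seeded run of the generator produces."""

    config: SynthConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    counts: CountTable
    level_sets: list[PeakSet]
    method1: PeakSet
    method2: PeakSet
    truth_peaks: pd.DataFrame
    truth_genes: pd.DataFrame

    @property
    def titration_chroms(self) -> list[str]:
        return [c for c in self.genome if not c.startswith("chrA")]

    @property
    def arena_chroms(self) -> list[str]:
        return [c for c in self.genome if c.startswith("chrA")]


class _Registry:
    """Per-chromosome occupied intervals with a minimum-gap placement rule."""

    def __init__(self, gap: int):
        self.gap = gap
        self.starts: dict[str, list[int]] = {}
        self.ends: dict[str, list[int]] = {}

    def can_place(self, chrom: str, start: int, end: int) -> bool:
        starts = self.starts.get(chrom, [])
        ends = self.ends.get(chrom, [])
        i = bisect.bisect_left(starts, start)
        if i > 0 and ends[i - 1] + self.gap > start:
            return False
        if i < len(starts) and starts[i] < end + self.gap:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self.starts.setdefault(chrom, [])
        ends = self.ends.setdefault(chrom, [])
        i = bisect.bisect_left(starts, start)
        starts.insert(i, start)
        ends.insert(i, end)


@dataclass
class _Site:
    site_id: str
    chrom: str
    start: int
    end: int
    first_level: int  # -1 for arena sites
    category: str  # "level<k>" | "shared" | "m1_only" | "m2_only"
    near_induced: bool = False
    assigned_gene: str | None = None
    motif_embedded: bool = False
    embedded_offset: int = -1
    scores: dict[int, float] = field(default_factory=dict)


_KB_CHOICES = [IUPAC[c] for c, _ in parse_iupac_pattern("GGGRN(Y)YYCC")]


def _sample_consensus_10mer(rng: np.random.Generator) -> str:
    """A 10-mer drawn uniformly from the strings matching GGGRN(Y)YYCC."""
    return "".join(choices[rng.integers(len(choices))] for choices in _KB_CHOICES)


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> bytearray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return bytearray(rng.choice(alphabet, size=length, p=probs).tobytes())


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with mean exactly 1 and the given CV."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return rng.lognormal(-sigma * sigma / 2.0, sigma, size=size)


def _p_adj(rng: np.random.Generator) -> float:
    # comfortably below the 0.01 call threshold
    return float(10.0 ** rng.uniform(-8.0, -2.05))


def generate(config: SynthConfig) -> SynthBundle:
    """Generate the full bundle deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    cfg = config

    # --- genome ---------------------------------------------------------
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    arena = [f"chrA{i + 1}" for i in range(cfg.n_arena_chroms)]
    sizes = {c: cfg.chrom_length_bp for c in chroms}
    sizes.update({c: cfg.arena_chrom_length_bp for c in arena})
    genome = {c: _random_genome(rng, sizes[c], cfg.gc_content) for c in chroms + arena}

    # --- genes and counts ----------------------------------------------
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        tss = int(rng.integers(cfg.near_tss_window, sizes[chrom] - cfg.near_tss_window))
        strand = "+" if rng.random() < 0.5 else "-"
        length_kbp = float(rng.uniform(1.0, 10.0))
        genes.append(GeneModel(f"gene_{i:04d}", chrom, strand, tss, length_kbp))
    n_induced = round(cfg.induced_fraction * cfg.n_genes)
    induced_idx = set(rng.permutation(cfg.n_genes)[:n_induced].tolist())
    true_fold = np.empty(cfg.n_genes)
    for i in range(cfg.n_genes):
        if i in induced_idx:
            true_fold[i] = rng.uniform(*cfg.induced_fold_range)
        else:
            true_fold[i] = rng.lognormal(0.0, 0.1)
    base_mean = rng.lognormal(np.log(cfg.base_mean_count), 1.0, size=cfg.n_genes)
    samples = [(t, r + 1) for t in ("0h", "1h") for r in range(cfg.n_replicates)]
    r_nb = 1.0 / cfg.nb_dispersion
    counts = np.empty((cfg.n_genes, len(samples)), dtype=np.int64)
    for j, (t, _) in enumerate(samples):
        mean = base_mean * np.where(t == "1h", true_fold, 1.0)
        counts[:, j] = rng.negative_binomial(r_nb, r_nb / (r_nb + mean))
    # library sizes are total mapped reads per sample (~10 M); the gene panel
    # is a small slice of the transcriptome, so totals do not track its counts
    lib_sizes = np.round(1e7 * _lognormal_unit_mean(rng, 0.05, size=len(samples)))
    count_table = CountTable([g.gene_id for g in genes], samples, counts, lib_sizes)
    induced_genes = [genes[i] for i in sorted(induced_idx)]

    # --- titration sites ------------------------------------------------
    registry = _Registry(cfg.min_gap)
    sites: list[_Site] = []

    def place_uniform(pool: list[str]) -> tuple[str, int, int]:
        for _ in range(300):
            chrom = pool[int(rng.integers(len(pool)))]
            w = int(rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1))
            s = int(rng.integers(cfg.jitter, sizes[chrom] - w - cfg.jitter))
            if registry.can_place(chrom, s, s + w):
                registry.add(chrom, s, s + w)
                return chrom, s, s + w
        raise RuntimeError("genome too crowded for uniform placement")

    def place_near_induced() -> tuple[str, int, int, str] | None:
        for _ in range(60):
            g = induced_genes[int(rng.integers(len(induced_genes)))]
            w = int(rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1))
            center = g.tss + int(rng.integers(-cfg.near_tss_window, cfg.near_tss_window + 1))
            s = center - w // 2
            if s < cfg.jitter or s + w + cfg.jitter > sizes[g.chrom]:
                continue
            if registry.can_place(g.chrom, s, s + w):
                registry.add(g.chrom, s, s + w)
                return g.chrom, s, s + w, g.gene_id
        return None

    def new_site(level: int, idx: int) -> _Site:
        near = rng.random() < cfg.p_near_induced_per_level[level]
        placed = place_near_induced() if near and induced_genes else None
        if placed is not None:
            chrom, s, e, gene_id = placed
            site = _Site(f"s{idx:05d}", chrom, s, e, level, f"level{level}",
                         near_induced=True, assigned_gene=gene_id)
        else:
            chrom, s, e = place_uniform(chroms)
            site = _Site(f"s{idx:05d}", chrom, s, e, level, f"level{level}")
        if rng.random() < cfg.p_motif_per_level[level]:
            _embed(site)
        return site

    def _embed(site: _Site) -> None:
        mer = _sample_consensus_10mer(rng)
        if rng.random() < 0.5:
            mer = reverse_complement(mer)
        offset = site.start + (site.end - site.start - len(mer)) // 2
        genome[site.chrom][offset : offset + len(mer)] = mer.encode()
        site.motif_embedded = True
        site.embedded_offset = offset

    site_counter = 0
    for _ in range(cfg.base_peaks):
        s = new_site(0, site_counter)
        s.scores[0] = 20.0 + float(rng.lognormal(3.2, 0.6))
        sites.append(s)
        site_counter += 1
    for level in range(1, cfg.n_levels):
        noise = _lognormal_unit_mean(rng, cfg.score_noise_cv, size=len(sites))
        for site, eta in zip(sites, noise):
            site.scores[level] = site.scores[level - 1] * cfg.score_doubling_factor * float(eta)
        existing = np.array([site.scores[level] for site in sites])
        cap = float(np.quantile(existing, cfg.new_peak_score_quantile_cap))
        for _ in range(cfg.new_peaks_per_level[level]):
            s = new_site(level, site_counter)
            s.scores[level] = float(rng.uniform(19.5, max(cap, 21.0)))
            sites.append(s)
            site_counter += 1

    # --- per-level peak sets -------------------------------------------
    level_sets: list[PeakSet] = []
    truth_rows: list[dict] = []
    for level in range(cfg.n_levels):
        peaks: list[Peak] = []
        for site in sites:
            if site.first_level > level:
                continue
            j1 = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
            j2 = int(rng.integers(-cfg.jitter, cfg.jitter + 1))
            iv = GenomicInterval(site.chrom, site.start + j1, site.end + j2)
            pid = f"L{level}_{site.site_id}"
            peak = Peak(iv, pid, site.scores[level], _p_adj(rng))
            peaks.append(peak)
            truth_rows.append(
                {
                    "peak_id": pid, "set_label": f"level{level}",
                    "site_id": site.site_id, "chrom": site.chrom,
                    "site_start": site.start, "site_end": site.end,
                    "first_level": site.first_level, "category": site.category,
                    "motif_embedded": site.motif_embedded,
                    "embedded_offset": site.embedded_offset,
                    "assigned_gene": site.assigned_gene or "",
                    "near_induced": site.near_induced,
                    "score": site.scores[level],
                }
            )
        level_sets.append(
            PeakSet(f"level{level}", peaks, level=level, level_value=cfg.level_values[level])
        )

    # --- cross-method arena --------------------------------------------
    m1_sites: list[_Site] = []
    for k in range(cfg.method1_count):
        chrom, s, e = place_uniform(arena)
        m1_sites.append(_Site(f"a{k:05d}", chrom, s, e, -1, "m1_only"))
    n_shared = round(cfg.method2_shared_fraction * cfg.method1_count)
    shared_idx = set(rng.choice(cfg.method1_count, size=n_shared, replace=False).tolist())
    for i in shared_idx:
        m1_sites[i].category = "shared"
    m2_sites: list[_Site] = []
    for k in range(cfg.method2_exclusive_count):
        chrom, s, e = place_uniform(arena)
        m2_sites.append(_Site(f"a{cfg.method1_count + k:05d}", chrom, s, e, -1, "m2_only"))
    p_cat = {"shared": cfg.p_motif_shared, "m1_only": cfg.p_motif_m1_only,
             "m2_only": cfg.p_motif_m2_only}
    for site in m1_sites + m2_sites:
        if rng.random() < p_cat[site.category]:
            _embed(site)

    def arena_peak(site: _Site, prefix: str, jittered: bool) -> Peak:
        j1 = int(rng.integers(-cfg.jitter, cfg.jitter + 1)) if jittered else 0
        j2 = int(rng.integers(-cfg.jitter, cfg.jitter + 1)) if jittered else 0
        iv = GenomicInterval(site.chrom, site.start + j1, site.end + j2)
        return Peak(iv, f"{prefix}_{site.site_id}", 20.0 + float(rng.lognormal(3.2, 0.6)),
                    _p_adj(rng))

    m1_peaks = [arena_peak(s, "M1", jittered=False) for s in m1_sites]
    m2_peaks = [arena_peak(m1_sites[i], "M2", jittered=True) for i in sorted(shared_idx)]
    m2_peaks += [arena_peak(s, "M2", jittered=False) for s in m2_sites]
    method1 = PeakSet("method1_chip", m1_peaks)
    method2 = PeakSet("method2_cuttag", m2_peaks)
    for ps, peaks, site_list in (
        ("method1_chip", m1_peaks, m1_sites),
        ("method2_cuttag", m2_peaks, [m1_sites[i] for i in sorted(shared_idx)] + m2_sites),
    ):
        for peak, site in zip(peaks, site_list):
            truth_rows.append(
                {
                    "peak_id": peak.peak_id, "set_label": ps,
                    "site_id": site.site_id, "chrom": site.chrom,
                    "site_start": site.start, "site_end": site.end,
                    "first_level": -1, "category": site.category,
                    "motif_embedded": site.motif_embedded,
                    "embedded_offset": site.embedded_offset,
                    "assigned_gene": "", "near_induced": False,
                    "score": peak.score,
                }
            )

    truth_peaks = pd.DataFrame(truth_rows)
    truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "induced": [i in induced_idx for i in range(cfg.n_genes)],
            "true_fold": true_fold,
        }
    )
    return SynthBundle(
        config=cfg,
        genome={c: bytes(b).decode("ascii") for c, b in genome.items()},
        genes=genes,
        counts=count_table,
        level_sets=level_sets,
        method1=method1,
        method2=method2,
        truth_peaks=truth_peaks,
        truth_genes=truth_genes,
    )


def write_bundle(bundle: SynthBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; identical seeds give identical bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in bundle.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    paths["genome"] = fasta

    write_gene_models(bundle.genes, outdir / "genes.tsv")
    paths["genes"] = outdir / "genes.tsv"
    bundle.counts.to_tsv(outdir / "counts.tsv")
    paths["counts"] = outdir / "counts.tsv"

    for ps in bundle.level_sets:
        p = outdir / f"peaks_{ps.label}.bed"
        write_bed(ps, p)
        paths[ps.label] = p
    write_bed(bundle.method1, outdir / "peaks_method1.bed")
    write_bed(bundle.method2, outdir / "peaks_method2.bed")
    paths["method1"] = outdir / "peaks_method1.bed"
    paths["method2"] = outdir / "peaks_method2.bed"

    bundle.truth_peaks.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
    bundle.truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    paths["truth_peaks"] = outdir / "truth_peaks.tsv"
    paths["truth_genes"] = outdir / "truth_genes.tsv"

    import yaml

    cfg = dataclasses.asdict(bundle.config)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    paths["config"] = outdir / "config.yaml"
    return paths


def truth_check(bundle: SynthBundle, seed: int | None = None) -> dict:
    """Run the full analysis on a bundle and compare with its ground truth.

    Returns a report dict with, per property, the measured quantity and a
    boolean pass flag:

    * ``novelty_agreement`` — fraction of peaks whose new/previous call
      matches the generator's first-appearance record (target: 1.0);
    * ``slope`` — OLS score-doubling estimate between the two highest
      levels (target: the configured d);
    * ``enrichment_neg_log10`` — consensus-motif enrichment per
      first-appearance group against a neutral random background
      (target: strictly decreasing in level);
    * ``top_decile_fractions`` — induced-gene fraction of the top score
      decile per new-peak group (target: level 0 highest vs last level);
    * ``category_neg_log10`` — shared / method-1-only / method-2-only
      enrichment (target: shared > m1_only > m2_only).
    """
    from .crossmethod import build_category_groups
    from .genes import annotate_peaks, induced_fraction_by_bin, induction
    from .motifs import KB_CONSENSUS, enrichment_test, random_regions, sample_peaks
    from .titration import (
        ConditionSeries,
        bin_by_score,
        classify_novelty,
        first_appearance_levels,
        fit_slope,
        paired_scores,
    )

    cfg = bundle.config
    if seed is None:
        seed = cfg.seed
    series = ConditionSeries("titration", list(bundle.level_sets))
    report: dict = {"seed": cfg.seed}

    # novelty vs ground truth
    calls = classify_novelty(series)
    truth = bundle.truth_peaks.set_index("peak_id")["first_level"].to_dict()
    n_match = sum(
        1
        for c in calls
        if (c.label == "new") == (truth[c.peak_id] == c.level)
    )
    report["novelty_agreement"] = n_match / len(calls)
    report["novelty_ok"] = report["novelty_agreement"] == 1.0
    report["peaks_per_level"] = [len(s) for s in bundle.level_sets]

    # slope recovery between the two highest levels
    pairs = paired_scores(series, cfg.n_levels - 2, cfg.n_levels - 1)
    slope, intercept, r = fit_slope(pairs, include_new=False)
    report["slope"] = slope
    report["slope_target"] = cfg.score_doubling_factor
    report["slope_ok"] = abs(slope - cfg.score_doubling_factor) <= 0.1
    report["pearson_r"] = r

    # new-fraction gradient across score bins at the top level
    top = bundle.level_sets[-1]
    bins = bin_by_score(top, calls, bin_size=1000)
    fractions = [b.fraction_new for b in bins]
    from scipy import stats as _stats

    rho = _stats.spearmanr(range(len(fractions)), fractions).statistic
    report["fraction_new_by_bin"] = fractions
    report["new_fraction_rank_corr"] = float(rho)  # >0: more new peaks at low scores
    report["new_fraction_gradient_ok"] = rho > 0

    # consensus-motif enrichment per first-appearance group
    probes, first = first_appearance_levels(series)
    groups: dict[int, list] = {lv: [] for lv in range(cfg.n_levels)}
    for peak in top:
        idx = probes.probe_index_of(top.label, peak.peak_id)
        groups[int(first[idx])].append(peak)
    tit_sizes = {c: len(bundle.genome[c]) for c in bundle.titration_chroms}
    background = random_regions(
        tit_sizes, n=2000, width=250, seed=seed + 1, exclude=[top], label="bg_titration"
    )
    neg_log10 = []
    for lv in range(cfg.n_levels):
        target = sample_peaks(PeakSet(f"first_level{lv}", groups[lv]), n=1000, seed=seed + 10 + lv)
        res = enrichment_test(target, background, KB_CONSENSUS, bundle.genome)
        neg_log10.append(res.neg_log10_p)
    report["enrichment_neg_log10"] = neg_log10
    report["enrichment_gradient_ok"] = all(
        a > b for a, b in zip(neg_log10, neg_log10[1:])
    )

    # induced-gene proximity of new-peak groups, by score decile
    ind = induction(bundle.counts, bundle.genes)
    induced_ids = set(ind.index[ind["induced"]])
    new_ids_by_level = {
        lv: {c.peak_id for c in calls if c.level == lv and c.label == "new"}
        for lv in range(cfg.n_levels)
    }
    top_decile = []
    for lv, ps in enumerate(bundle.level_sets):
        new_peaks = [p for p in ps if p.peak_id in new_ids_by_level[lv]]
        group = PeakSet(f"new_level{lv}", new_peaks)
        ann = annotate_peaks(group, bundle.genes, induced_ids)
        table = induced_fraction_by_bin(group, ann, n_bins=10)
        top_decile.append(float(table.loc[0, "fraction_induced"]))
    report["top_decile_fractions"] = top_decile
    report["proximity_ok"] = top_decile[0] > top_decile[-1]

    # cross-method category enrichment
    cats = build_category_groups(bundle.method1, bundle.method2)
    arena_sizes = {c: len(bundle.genome[c]) for c in bundle.arena_chroms}
    bg_arena = random_regions(
        arena_sizes, n=1000, width=250, seed=seed + 2,
        exclude=[bundle.method1, bundle.method2], label="bg_arena",
    )
    cat_scores = {}
    for key in ("both", "a_only", "b_only"):
        target = sample_peaks(cats[key], n=500, seed=seed + 20)
        cat_scores[key] = enrichment_test(target, bg_arena, KB_CONSENSUS, bundle.genome).neg_log10_p
    report["category_neg_log10"] = cat_scores
    report["category_order_ok"] = (
        cat_scores["both"] > cat_scores["a_only"] > cat_scores["b_only"]
    )

    report["all_ok"] = all(
        report[k]
        for k in (
            "novelty_ok", "slope_ok", "new_fraction_gradient_ok",
            "enrichment_gradient_ok", "proximity_ok", "category_order_ok",
        )
    )
    return report
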