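"""End-to-end orchestration: filter → merge → classify → bin → slope →
sample → enrich → annotate → compare, with a reproducibility manifest.

Every stage writes a TSV under the output directory and records its row
count in ``manifest.json`` together with the seed and a hash of the run
configuration, so a rerun with identical inputs is verifiably identical.
Execution is single-threaded and deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .crossmethod import build_category_groups, overlap_matrix, venn_partition
from .genes import (
    annotate_peaks,
    induced_fraction_by_bin,
    induction,
    read_gene_models,
    CountTable,
)
from .intervals import filter_peaks, merge_master_probes, read_bed, write_probes_bed
from .motifs import (
    KB_CONSENSUS,
    enrichment_report,
    random_regions,
    read_motif_tsv,
    sample_peaks,
)
from .titration import (
    ConditionSeries,
    bin_by_score,
    classify_novelty,
    first_appearance_levels,
    fit_slope,
    paired_scores,
)

logger = logging.getLogger("crosspeak")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Inputs and thresholds for one end-to-end run.

    Threshold defaults are the peak-call and induction criteria of the
    emulated study: p-adj < 0.01, peak score > 19, induction > 5, random
    samples of 1,000 peaks, score bins of 1,000, ten annotation bins.
    """

    genome_fasta: str
    gene_models: str
    counts: str
    peak_beds: list[str]
    level_values: list[float]
    outdir: str
    method1_bed: str | None = None
    method2_bed: str | None = None
    motif_tsv: str | None = None
    p_adj_max: float = 0.01
    min_score: float = 19.0
    fold_threshold: float = 5.0
    pseudocount: float = 0.1
    sample_n: int = 1000
    bin_size: int = 1000
    n_bins: int = 10
    score_column: int = 4
    p_adj_column: int | None = 6
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_genome(path: str):
    from pyfaidx import Fasta

    return Fasta(path, sequence_always_upper=True)


def run_all(config: RunConfig) -> tuple[int, dict]:
    """Execute every stage; returns (exit_status, manifest).

    Any stage failure yields a nonzero status and a manifest whose failed
    stage carries a FAILED marker; outputs of completed stages are kept.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    status = 0

    def record(stage: str, rows: int, output: str | None = None) -> None:
        manifest["stages"][stage] = {"rows": rows, "output": output}
        logger.info("stage=%s rows=%d output=%s", stage, rows, output)

    try:
        for path in [config.genome_fasta, config.gene_models, config.counts,
                     *config.peak_beds]:
            if not Path(path).exists():
                raise FileNotFoundError(f"input not found: {path}")

        genome = _load_genome(config.genome_fasta)
        genes = read_gene_models(config.gene_models)
        counts = CountTable.from_tsv(config.counts)

        # filter
        raw_sets = [
            read_bed(p, score_column=config.score_column,
                     p_adj_column=config.p_adj_column,
                     label=f"level{i}", level=i, level_value=config.level_values[i])
            for i, p in enumerate(config.peak_beds)
        ]
        sets = [filter_peaks(s, config.p_adj_max, config.min_score) for s in raw_sets]
        filt = pd.DataFrame(
            {"level": range(len(sets)), "n_raw": [len(s) for s in raw_sets],
             "n_filtered": [len(s) for s in sets]}
        )
        filt.to_csv(outdir / "filtered_counts.tsv", sep="\t", index=False)
        record("filter", int(filt["n_filtered"].sum()), "filtered_counts.tsv")

        # merge
        probes = merge_master_probes(sets)
        write_probes_bed(probes, outdir / "master_probes.bed")
        record("merge", len(probes), "master_probes.bed")

        # classify
        series = ConditionSeries("titration", sets)
        calls = classify_novelty(series)
        pd.DataFrame(
            [{"peak_id": c.peak_id, "level": c.level, "label": c.label} for c in calls]
        ).to_csv(outdir / "novelty.tsv", sep="\t", index=False)
        record("classify", len(calls), "novelty.tsv")

        # bin
        bin_rows = []
        for ps in sets:
            for b in bin_by_score(ps, calls, config.bin_size):
                bin_rows.append(
                    {"level": ps.level, "bin_index": b.bin_index, "n": b.n,
                     "fraction_new": b.fraction_new}
                )
        pd.DataFrame(bin_rows).to_csv(outdir / "score_bins.tsv", sep="\t", index=False)
        record("bin", len(bin_rows), "score_bins.tsv")

        # scatter + slope for adjacent level pairs
        slope_rows = []
        for lo in range(len(sets) - 1):
            pairs = paired_scores(series, lo, lo + 1)
            pd.DataFrame(pairs.rows, columns=["probe_id", "score_low", "score_high"]).to_csv(
                outdir / f"paired_scores_{lo}_{lo + 1}.tsv", sep="\t", index=False
            )
            slope, intercept, r = fit_slope(pairs, include_new=False)
            slope_rows.append(
                {"lower": lo, "higher": lo + 1, "n_pairs": len(pairs.rows),
                 "slope": slope, "intercept": intercept, "pearson_r": r}
            )
        pd.DataFrame(slope_rows).to_csv(outdir / "slopes.tsv", sep="\t", index=False)
        record("slope", len(slope_rows), "slopes.tsv")

        # sample + enrich: new-peak groups by first-appearance level
        probes_all, first = first_appearance_levels(series)
        top = sets[-1]
        groups = {}
        for lv in range(len(sets)):
            members = [
                p for p in top
                if first[probes_all.probe_index_of(top.label, p.peak_id)] == lv
            ]
            from .intervals import PeakSet

            groups[f"first_level{lv}"] = sample_peaks(
                PeakSet(f"first_level{lv}", members), config.sample_n,
                seed=config.seed + 10 + lv,
            )
        chrom_sizes = {name: len(genome[name]) for name in genome.keys()}
        background = random_regions(
            chrom_sizes, n=2 * config.sample_n, width=250,
            seed=config.seed + 1, exclude=[top],
        )
        motifs = [KB_CONSENSUS]
        if config.motif_tsv:
            motifs += read_motif_tsv(config.motif_tsv)
        enrich = enrichment_report(groups, background, motifs, genome)
        enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        record("enrich", len(enrich), "enrichment.tsv")

        # annotate: induction + nearest gene + decile fractions
        ind = induction(counts, genes, config.fold_threshold, config.pseudocount)
        ind.to_csv(outdir / "induction.tsv", sep="\t")
        induced_ids = set(ind.index[ind["induced"]])
        new_by_level = {
            lv: {c.peak_id for c in calls if c.level == lv and c.label == "new"}
            for lv in range(len(sets))
        }
        decile_rows = []
        for ps in sets:
            from .intervals import PeakSet

            group = PeakSet(f"new_level{ps.level}",
                            [p for p in ps if p.peak_id in new_by_level[ps.level]])
            ann = annotate_peaks(group, genes, induced_ids)
            table = induced_fraction_by_bin(group, ann, config.n_bins)
            table.insert(0, "level", ps.level)
            decile_rows.append(table)
        deciles = pd.concat(decile_rows, ignore_index=True)
        deciles.to_csv(outdir / "induced_fraction_bins.tsv", sep="\t", index=False)
        record("annotate", len(deciles), "induced_fraction_bins.tsv")

        # compare
        compare_sets = list(sets)
        if config.method1_bed and config.method2_bed:
            m1 = read_bed(config.method1_bed, score_column=config.score_column,
                          p_adj_column=config.p_adj_column, label="method1_chip")
            m2 = read_bed(config.method2_bed, score_column=config.score_column,
                          p_adj_column=config.p_adj_column, label="method2_cuttag")
            compare_sets += [m1, m2]
        matrix = overlap_matrix(compare_sets)
        matrix.to_frame().to_csv(outdir / "overlap_matrix.tsv", sep="\t")
        record("compare", len(compare_sets), "overlap_matrix.tsv")
        if config.method1_bed and config.method2_bed:
            venn = venn_partition(m1, m2)
            pd.DataFrame([dataclasses.asdict(venn)]).to_csv(
                outdir / "venn.tsv", sep="\t", index=False
            )
            cats = build_category_groups(m1, m2)
            from .intervals import write_bed

            for key, ps in cats.items():
                write_bed(ps, outdir / f"category_{key}.bed")
            record("venn", venn.shared_regions, "venn.tsv")
    except Exception as exc:  # noqa: BLE001 - any stage failure is reported, not raised
        status = 1
        manifest["stages"]["FAILED"] = {"error": f"{type(exc).__name__}: {exc}"}
        logger.error("pipeline failed: %s", exc)

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return status, manifest
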