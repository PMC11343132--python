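#!/usr/bin/env python
"""Consensus-motif enrichment of first-appearance groups against a neutral
random background."""

from pathlib import Path

import pandas as pd

from crosspeak.intervals import PeakSet
from crosspeak.motifs import KB_CONSENSUS, enrichment_test, random_regions, sample_peaks
from crosspeak.simulate import SynthConfig, generate
from crosspeak.titration import ConditionSeries, first_appearance_levels

ROOT = Path(__file__).resolve().parents[1]
SEED = 42


def main() -> None:
    bundle = generate(SynthConfig(seed=SEED))
    series = ConditionSeries("titration", list(bundle.level_sets))
    probes, first = first_appearance_levels(series)

    top = bundle.level_sets[-1]
    groups: dict[int, list] = {lv: [] for lv in range(len(bundle.level_sets))}
    for p in top:
        groups[int(first[probes.probe_index_of(top.label, p.peak_id)])].append(p)

    sizes = {c: len(bundle.genome[c]) for c in bundle.titration_chroms}
    background = random_regions(
        sizes, n=2000, width=250, seed=SEED + 1, exclude=[top], label="bg"
    )

    rows = []
    for lv, members in groups.items():
        target = sample_peaks(PeakSet(f"first_level{lv}", members), n=1000, seed=SEED + lv)
        res = enrichment_test(target, background, KB_CONSENSUS, bundle.genome)
        rows.append(
            {
                "first_level": lv,
                "n_target": res.n_target,
                "k_target": res.k_target,
                "k_background": res.k_background,
                "neg_log10_p": round(res.neg_log10_p, 2),
            }
        )
    table = pd.DataFrame(rows)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "03_enrichment_by_first_level.tsv", sep="\t", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
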