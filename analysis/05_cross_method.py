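#!/usr/bin/env python
"""Cross-method comparison: overlap matrix, Venn partition, and consensus
enrichment by shared/exclusive category."""

from pathlib import Path

import pandas as pd

from crosspeak.crossmethod import build_category_groups, overlap_matrix, venn_partition
from crosspeak.motifs import KB_CONSENSUS, enrichment_test, random_regions, sample_peaks
from crosspeak.simulate import SynthConfig, generate

ROOT = Path(__file__).resolve().parents[1]
SEED = 42


def main() -> None:
    bundle = generate(SynthConfig(seed=SEED))
    m1, m2 = bundle.method1, bundle.method2

    matrix = overlap_matrix([m1, m2]).to_frame()
    venn = venn_partition(m1, m2)
    venn_table = pd.DataFrame(
        [
            {
                "shared_regions": venn.shared_regions,
                "a_only": venn.a_only,
                "b_only": venn.b_only,
                "pct_of_method1": round(venn.pct_of_a, 1),
                "pct_of_method2": round(venn.pct_of_b, 1),
            }
        ]
    )

    groups = build_category_groups(m1, m2)
    sizes = {c: len(bundle.genome[c]) for c in bundle.arena_chroms}
    background = random_regions(
        sizes, n=1000, width=250, seed=SEED + 2, exclude=[m1, m2], label="bg"
    )
    rows = []
    for key in ("both", "a_only", "b_only"):
        target = sample_peaks(groups[key], n=500, seed=SEED + 3)
        res = enrichment_test(target, background, KB_CONSENSUS, bundle.genome)
        rows.append(
            {"category": key, "n_target": res.n_target, "k_target": res.k_target,
             "neg_log10_p": round(res.neg_log10_p, 2)}
        )
    categories = pd.DataFrame(rows)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    matrix.to_csv(results / "05_overlap_matrix.tsv", sep="\t")
    venn_table.to_csv(results / "05_venn.tsv", sep="\t", index=False)
    categories.to_csv(results / "05_category_enrichment.tsv", sep="\t", index=False)
    print(matrix.to_string())
    print()
    print(venn_table.to_string(index=False))
    print()
    print(categories.to_string(index=False))


if __name__ == "__main__":
    main()
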