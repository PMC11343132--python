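#!/usr/bin/env python
"""Titration analysis: new/previous classification per level, new-peak
fraction across score bins, and the paired-score doubling slope."""

from pathlib import Path

import pandas as pd

from crosspeak.simulate import SynthConfig, generate
from crosspeak.titration import (
    ConditionSeries,
    bin_by_score,
    classify_novelty,
    fit_slope,
    paired_scores,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 42


def main() -> None:
    bundle = generate(SynthConfig(seed=SEED))
    series = ConditionSeries("titration", list(bundle.level_sets))
    calls = classify_novelty(series)

    per_level = []
    for lv, ps in enumerate(bundle.level_sets):
        level_calls = [c for c in calls if c.level == lv]
        per_level.append(
            {
                "level": lv,
                "level_value": series.sets[lv].level_value,
                "n_peaks": len(ps),
                "n_new": sum(c.label == "new" for c in level_calls),
                "n_previous": sum(c.label == "previous" for c in level_calls),
            }
        )
    novelty = pd.DataFrame(per_level)

    bins = bin_by_score(bundle.level_sets[-1], calls, bin_size=1000)
    bin_table = pd.DataFrame(
        {
            "bin": range(len(bins)),
            "n": [b.n for b in bins],
            "fraction_new": [round(b.fraction_new, 4) for b in bins],
        }
    )

    n_levels = len(bundle.level_sets)
    pairs = paired_scores(series, n_levels - 2, n_levels - 1)
    slope, intercept, r = fit_slope(pairs, include_new=False)
    slopes = pd.DataFrame(
        [{"pair": f"level{n_levels - 2}_vs_level{n_levels - 1}",
          "slope": round(slope, 4), "intercept": round(intercept, 4),
          "pearson_r": round(r, 4)}]
    )

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    novelty.to_csv(results / "02_novelty_per_level.tsv", sep="\t", index=False)
    bin_table.to_csv(results / "02_fraction_new_by_bin.tsv", sep="\t", index=False)
    slopes.to_csv(results / "02_slope.tsv", sep="\t", index=False)
    print(novelty.to_string(index=False))
    print()
    print(bin_table.to_string(index=False))
    print()
    print(slopes.to_string(index=False))


if __name__ == "__main__":
    main()
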