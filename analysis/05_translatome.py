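#!/usr/bin/env python
"""Translatome count filtering: expressed-gene thresholds, enrichment sets
and the congruence between two simulated comparisons.

Simulates two enrichment comparisons sharing most planted genes, normalizes
counts (reads per kilobase per million), counts genes above the expressed
(>10) and in-situ-detectable (>100) thresholds, filters enriched sets at
FDR <= 0.05 and fold >= 2 using the built-in NB test oracle, and reports
how congruent the two comparisons are.
"""

import argparse
import json
from pathlib import Path

from dorsalcode.studies import translatome_study
from dorsalcode.translatome import (
    DETECTABLE_THRESHOLD,
    EXPRESSED_THRESHOLD,
    congruence,
    count_expressed,
    de_filter,
    nb_two_group_test,
    normalize_counts,
)

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    out = ROOT / "results" / "translatome"
    out.mkdir(parents=True, exist_ok=True)

    comparisons = dict(zip(("vs_inh1", "vs_inh2"), translatome_study(seed=seed)))
    sets, truths = {}, {}
    for name, (counts, samples, genes, truth) in comparisons.items():
        lengths = genes.set_index("gene")["length"]
        libs = samples.set_index("sample")["library_size"]
        norm = normalize_counts(counts, lengths, libs)
        norm.round(3).to_csv(out / f"normalized_{name}.csv")
        for group in samples["group"].unique():
            n10 = count_expressed(norm, samples, group, EXPRESSED_THRESHOLD)
            n100 = count_expressed(norm, samples, group, DETECTABLE_THRESHOLD)
            print(f"{name}/{group}: {n10} genes >10 norm. counts, {n100} genes >100")
        other = [g for g in samples["group"].unique() if g != "exc"][0]
        table = nb_two_group_test(counts, samples, "exc", other, lengths, dispersion=0.15)
        table.round(6).to_csv(out / f"enrichment_{name}.csv")
        sets[name] = de_filter(table)["up"]
        truths[name] = truth["exc"]
        (out / f"enriched_{name}.txt").write_text("\n".join(sorted(sets[name])) + "\n")
        rec = 100 * len(sets[name] & truths[name]) / len(truths[name])
        print(
            f"{name}: {len(sets[name])} enriched (FDR<=0.05, fold>=2); "
            f"{rec:.1f}% of the {len(truths[name])} planted genes recovered"
        )

    cg = congruence(sets["vs_inh1"], sets["vs_inh2"])
    (out / "congruence.json").write_text(
        json.dumps(
            {"n_a": cg.n_a, "n_b": cg.n_b, "n_common": cg.n_common,
             "pct_of_a": cg.pct_of_a, "pct_of_b": cg.pct_of_b},
            indent=2,
        )
    )
    print(
        f"congruence: {cg.n_common} genes shared between the comparisons "
        f"({cg.pct_of_a:.1f}% of the first, {cg.pct_of_b:.1f}% of the second)"
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
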