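#!/usr/bin/env python
"""Calibrate thresholds, call positive cells and build co-expression matrices.

From the count-level experiment of 01: per-channel background thresholds
from the negative controls (90th nearest-rank percentile), positivity calls,
triple-probe Venn counts per animal, and pairwise co-expression matrices at
both stringency levels, compared against the closed-form generative matrix.
"""

import argparse
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from dorsalcode.classify import (
    background_threshold,
    call_positive,
    matrix_to_json_bundle,
    pairwise_matrix,
    venn_counts,
)
from dorsalcode.studies import coexpression_config, generative_coexpression_matrix

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    results = ROOT / "results" / "sim"
    out = ROOT / "results" / "coexpression"
    out.mkdir(parents=True, exist_ok=True)
    cells = pd.read_csv(results / "cells_measured.csv")
    negctrl = pd.read_csv(results / "negctrl_measured.csv")

    thresholds = background_threshold(negctrl)
    print(f"background thresholds (dots/cell): {thresholds.thresholds}")
    calls = call_positive(cells, thresholds)
    calls.to_csv(out / "calls.csv", index=False)

    genes = tuple(g for g in ("A", "B", "C"))
    vc = venn_counts(calls, genes, level="high")
    vc.to_csv(out / "venn_counts_high.csv", index=False)
    print("high-level Venn regions (pooled hemisections, per animal):")
    print(vc.pivot(index="region", columns="animal_id", values="count"))

    cfg = coexpression_config(seed=seed)
    target = generative_coexpression_matrix(cfg)
    for level in ("any", "high"):
        m = pairwise_matrix(calls, level=level)
        m.fraction.to_csv(out / f"coexpression_{level}.csv")
        (out / f"coexpression_{level}.json").write_text(
            json.dumps(matrix_to_json_bundle(m), indent=2)
        )
        print(f"\nco-expression matrix, level={level} (% of row gene also expressing column):")
        print(m.fraction.round(1))
        if level == "high":
            err = np.abs(m.fraction.to_numpy() - target)
            off = err[~np.eye(len(genes), dtype=bool)]
            print(
                f"vs generative matrix: max |error| {off.max():.2f} pp, "
                f"mean {off.mean():.2f} pp over {off.size} ordered pairs"
            )
            fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
            for ax, (mat, title) in zip(
                axes, [(m.fraction.to_numpy(), "estimated (high)"), (target, "generative")]
            ):
                im = ax.imshow(mat, vmin=0, vmax=100, cmap="viridis")
                ax.set_xticks(range(len(genes)), genes)
                ax.set_yticks(range(len(genes)), genes)
                ax.set_title(title)
            fig.colorbar(im, ax=axes, label="% co-expression")
            fig.savefig(out / "coexpression_high.png", dpi=120)


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
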