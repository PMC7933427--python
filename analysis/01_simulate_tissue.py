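#!/usr/bin/env python
"""Simulate a dorsal-horn smFISH experiment with full ground truth.

Renders one example hemisection image stack (plus its matched negative
control) to scratch/sim/ and writes the count-level cell tables of the full
2-animal x 2-hemisection experiment to results/sim/. Everything downstream
(02-04) starts from these outputs.
"""

import argparse
from pathlib import Path

from dorsalcode.io import write_image_stack
from dorsalcode.simulate import (
    generate_negative_control,
    generate_tissue,
    save_config,
    simulate_cell_tables,
)
from dorsalcode.studies import coexpression_config

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1) -> None:
    cfg = coexpression_config(seed=seed)
    results = ROOT / "results" / "sim"
    scratch = ROOT / "scratch" / "sim"
    results.mkdir(parents=True, exist_ok=True)
    scratch.mkdir(parents=True, exist_ok=True)

    save_config(cfg, results / "config.yaml")

    image, truth = generate_tissue(cfg, 1, 1)
    write_image_stack(image, scratch / "section_a1_s1.tif")
    truth.cells.to_csv(results / "section_a1_s1_cells.csv", index=False)
    truth.spots.to_csv(scratch / "section_a1_s1_spots.csv", index=False)

    nc_image, nc_truth = generate_negative_control(cfg, 1, 0)
    write_image_stack(nc_image, scratch / "negctrl_a1.tif")

    cells, negctrl = simulate_cell_tables(cfg)
    cells.to_csv(results / "cells_measured.csv", index=False)
    negctrl.to_csv(results / "negctrl_measured.csv", index=False)

    print(f"genes: {cfg.genes}; image stack {image.data.shape}")
    print(
        f"example section: {len(truth.cells)} cells, {len(truth.spots)} spots "
        f"({(truth.spots['cell_id'] == 0).sum()} background)"
    )
    print(
        f"negative control: {len(nc_truth.spots)} spots, all background="
        f"{bool((nc_truth.spots['cell_id'] == 0).all())}"
    )
    print(
        f"experiment tables: {len(cells)} cells, {len(negctrl)} control cells "
        f"-> {results}"
    )


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
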