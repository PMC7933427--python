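"""Named simulation configurations: the study conditions this package is
validated under.

Each function returns a fresh config for one validation scenario. The
scenarios fix the mixture model, sample sizes and imaging parameters once;
tests, analysis drivers and the acceptance script all import them from here
so that "the conditions" mean the same thing everywhere.
"""

from __future__ import annotations

import numpy as np

from .simulate import GeneExpression, PopulationSpec, SimulationConfig
from .template import default_template

#: lamina placement spread proportional to the default template's laminar
#: areas (uniform cell density) — used where laminar structure is not under test
SPREAD_LAMINAE = {"I": 0.03, "II": 0.13, "III": 0.23, "IV": 0.33, "V": 0.28}


def coexpression_config(seed: int = 0, n_cells: int = 400) -> SimulationConfig:
    """Three populations with a fixed generative co-expression structure.

    Mirrors the co-expression motifs quantified in the real tissue: one gene
    (A) private to two populations, a nested population co-expressing A and
    B (so B-cells are largely a subset of A-cells, the Tac2/Nmu motif), and
    a third population carrying C with a minority of B. 2 animals x 2
    hemisections, 400 cells each; dot counts high (mean 60) so expressing
    cells sit clearly above the >20 dots/cell stringent threshold;
    background at 0.5 stray dots per cell-equivalent area.
    """
    mk = lambda p: GeneExpression(prob=p, mean_dots=60.0, dispersion=0.05)
    pops = [
        PopulationSpec("A_only", 0.30, {"A": mk(1.0)}, SPREAD_LAMINAE),
        PopulationSpec("A_B", 0.25, {"A": mk(1.0), "B": mk(1.0)}, SPREAD_LAMINAE),
        PopulationSpec("C_B", 0.45, {"C": mk(1.0), "B": mk(0.2)}, SPREAD_LAMINAE),
    ]
    return SimulationConfig(
        template=default_template(),
        populations=pops,
        n_cells=n_cells,
        background_dot_rate=0.5,
        n_animals=2,
        hemisections_per_animal=2,
        seed=seed,
    )


def generative_coexpression_matrix(config: SimulationConfig) -> "np.ndarray":
    """Closed-form F[g, h] = 100 * P(h expressed | g expressed) implied by the
    mixture weights and per-gene expression probabilities (within-population
    independence). Returns a genes x genes array in the config's gene order."""
    genes = config.genes
    w = np.array([p.weight for p in config.populations])
    probs = np.array(
        [
            [p.expression[g].prob if g in p.expression else 0.0 for g in genes]
            for p in config.populations
        ]
    )  # (pop, gene)
    F = np.zeros((len(genes), len(genes)))
    for i in range(len(genes)):
        p_i = float(w @ probs[:, i])
        for j in range(len(genes)):
            if i == j:
                F[i, j] = 100.0 if p_i > 0 else np.nan
                continue
            p_ij = float(w @ (probs[:, i] * probs[:, j]))
            F[i, j] = 100.0 * p_ij / p_i if p_i > 0 else np.nan
    return F


def noiseless_recovery_config(seed: int = 0) -> SimulationConfig:
    """Exact-recovery conditions: 1 section, 200 cells, 3 genes, zero camera
    noise and zero background, spots kept resolvable (>= 4 px apart within a
    cell and channel) and somata disjoint, so measured dots/cell must equal
    ground truth exactly."""
    mk = lambda p: GeneExpression(prob=p, mean_dots=2.5, dispersion=0.05)
    pops = [
        PopulationSpec("p1", 0.5, {"A": mk(0.8), "B": mk(0.4)}, SPREAD_LAMINAE),
        PopulationSpec("p2", 0.5, {"B": mk(0.7), "C": mk(0.8)}, SPREAD_LAMINAE),
    ]
    return SimulationConfig(
        template=default_template(),
        populations=pops,
        n_cells=200,
        nucleus_radius_mean=4.5,
        nucleus_radius_sd=0.7,
        nucleus_radius_min=3.0,  # keeps every nucleus above the diameter filter
        soma_expansion_px=3.0,
        noise_sd=0.0,
        background_dot_rate=0.0,
        min_spot_separation_px=4.0,
        placement_margin_px=8.0,
        n_animals=1,
        hemisections_per_animal=1,
        seed=seed,
    )


def noiseless_detection_params():
    """Spot-detection parameters matched to the exact-recovery conditions.

    Non-maximum suppression runs on a square footprint, so a radius-2
    suppression can merge peaks up to ~2.8 px apart Euclidean; with the
    generator guaranteeing 4 px separation, suppression radius 1 keeps every
    resolvable spot while still de-duplicating single-peak neighborhoods.
    """
    from .spots import SpotDetectParams

    return SpotDetectParams(scale_px=1.0, min_separation_px=1.0)


def laminar_recovery_config(seed: int = 0, n_cells: int = 500) -> SimulationConfig:
    """One population expressing gene G, placed 90% in lamina II and 10% in
    lamina III, on a double-size template so the superficial laminae hold 500
    nuclei comfortably. Noise-free at the count level (no background)."""
    pops = [
        PopulationSpec(
            "G_pop",
            1.0,
            {"G": GeneExpression(prob=1.0, mean_dots=60.0, dispersion=0.05)},
            {"II": 0.9, "III": 0.1},
        )
    ]
    return SimulationConfig(
        template=default_template(width=800.0, depth=1000.0),
        populations=pops,
        n_cells=n_cells,
        nucleus_radius_mean=3.0,
        nucleus_radius_sd=0.5,
        background_dot_rate=0.0,
        n_animals=1,
        hemisections_per_animal=1,
        seed=seed,
    )


def translatome_study(seed: int = 0):
    """Two simulated enrichment comparisons sharing most planted genes.

    400 genes; comparison A (excitatory vs inhibitory line 1) plants 60
    enriched genes at fold 4, comparison B (vs inhibitory line 2) plants the
    same 60 plus 20 more — emulating two partially congruent differential
    analyses. Dispersion 0.15, 3 replicates per group.
    """
    from .simulate import generate_count_matrix

    base = [f"g{i:04d}" for i in range(1, 61)]
    extra = [f"g{i:04d}" for i in range(61, 81)]
    comp_a = generate_count_matrix(
        400, {"exc": 3, "inh1": 3}, {"exc": base}, 4.0, dispersion=0.15,
        seed=(seed * 2 + 11) % 2**31,
    )
    comp_b = generate_count_matrix(
        400, {"exc": 3, "inh2": 3}, {"exc": base + extra}, 4.0, dispersion=0.15,
        seed=(seed * 2 + 12) % 2**31,
    )
    return comp_a, comp_b
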