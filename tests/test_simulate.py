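"""Generator guarantees: counts by construction, determinism, conservation,
closed-form co-expression statistics, background Poisson behavior."""

import numpy as np
import pandas as pd
import pytest

from dorsalcode.simulate import (
    GeneExpression,
    PopulationSpec,
    SimulationConfig,
    generate_count_matrix,
    generate_negative_control,
    generate_tissue,
    measured_cell_table,
    sample_cells,
)
from dorsalcode.studies import SPREAD_LAMINAE
from dorsalcode.template import default_template

from conftest import small_config


def one_pop_config(expr, n_cells=100, **overrides):
    pops = [PopulationSpec("only", 1.0, expr, SPREAD_LAMINAE)]
    kwargs = dict(
        template=default_template(), populations=pops, n_cells=n_cells,
        n_animals=1, hemisections_per_animal=1, seed=5,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def test_cell_count_matches_config():
    cfg = one_pop_config({"A": GeneExpression(0.5)}, n_cells=100)
    cells = sample_cells(cfg, 1, 1)
    assert len(cells) == 100
    assert list(cells["cell_id"]) == list(range(1, 101))


def test_degenerate_probabilities_fix_expression():
    cfg = one_pop_config({"A": GeneExpression(1.0), "B": GeneExpression(0.0)})
    cells = sample_cells(cfg, 1, 1)
    assert cells["expr_A"].all()
    assert not cells["expr_B"].any()
    assert (cells["true_A"] > 0).all()
    assert (cells["true_B"] == 0).all()


def test_disjoint_populations_never_coexpress():
    """Two populations expressing A xor B: P(B | A) = 0 and P(A) ~ 1/2."""
    pops = [
        PopulationSpec("a", 0.5, {"A": GeneExpression(1.0), "B": GeneExpression(0.0)}, SPREAD_LAMINAE),
        PopulationSpec("b", 0.5, {"A": GeneExpression(0.0), "B": GeneExpression(1.0)}, SPREAD_LAMINAE),
    ]
    cfg = SimulationConfig(
        template=default_template(width=800, depth=1000), populations=pops,
        n_cells=2000, nucleus_radius_mean=3.0, nucleus_radius_sd=0.5,
        n_animals=1, hemisections_per_animal=1, seed=2,
    )
    cells = sample_cells(cfg, 1, 1)
    both = (cells["expr_A"] & cells["expr_B"]).sum()
    assert both == 0
    frac_a = cells["expr_A"].mean()
    sd = np.sqrt(0.25 / 2000)  # binomial SD of the mixture indicator
    assert abs(frac_a - 0.5) < 3 * sd


def test_cells_placed_inside_their_lamina(template):
    import shapely

    cfg = small_config(n_cells=80)
    cells = sample_cells(cfg, 1, 1)
    for lam, sub in cells.groupby("lamina"):
        poly = dict(cfg.template.laminae)[lam]
        assert shapely.contains_xy(poly, sub["x"].to_numpy(), sub["y"].to_numpy()).all()


def test_nuclei_do_not_overlap():
    cfg = small_config(n_cells=120)
    cells = sample_cells(cfg, 1, 1)
    xy = cells[["x", "y"]].to_numpy()
    r = cells["nucleus_radius"].to_numpy()
    d = np.sqrt(((xy[:, None] - xy[None]) ** 2).sum(-1))
    lim = r[:, None] + r[None]
    np.fill_diagonal(d, np.inf)
    assert (d > lim).all()


def test_placement_failure_raises():
    cfg = one_pop_config({"A": GeneExpression(1.0)}, n_cells=2000,
                         nucleus_radius_mean=8.0)
    with pytest.raises(RuntimeError, match="could not place"):
        sample_cells(cfg, 1, 1, max_tries_per_cell=30)


def test_ground_truth_spot_conservation():
    cfg = small_config(n_cells=60)
    _, truth = generate_tissue(cfg, 1, 1)
    truth.validate(cfg.genes)  # raises on any violation


def test_determinism_bit_identical():
    cfg = small_config(n_cells=40)
    img1, t1 = generate_tissue(cfg, 1, 1)
    img2, t2 = generate_tissue(cfg, 1, 1)
    assert np.array_equal(img1.data, img2.data)
    pd.testing.assert_frame_equal(t1.cells, t2.cells)
    pd.testing.assert_frame_equal(t1.spots, t2.spots)


def test_negative_control_zero_rate_has_no_spots():
    cfg = small_config(n_cells=40, background_dot_rate=0.0)
    img, truth = generate_negative_control(cfg, 1, 0)
    assert len(truth.spots) == 0
    for gene in cfg.genes:
        assert float(img.channel(gene).max()) < cfg.noise_sd * 6 + 1e-9


def test_negative_control_marks_all_spots_background():
    cfg = small_config(n_cells=40, background_dot_rate=1.0)
    _, truth = generate_negative_control(cfg, 1, 0)
    assert (truth.spots["cell_id"] == 0).all()


def test_negative_control_mean_dots_per_cell_matches_rate():
    """Mean measured dots/cell in controls ~ the configured rate (Poisson)."""
    rate = 0.8
    cfg = small_config(n_cells=200, background_dot_rate=rate, seed=9)
    rng = np.random.default_rng(17)
    cells = sample_cells(cfg, 1, 0, rng=rng)
    for g in cfg.genes:
        cells[f"true_{g}"] = 0
    measured = measured_cell_table(cells, cfg, rng)
    total = sum(measured[f"count_{g}"].sum() for g in cfg.genes)
    n = 200 * len(cfg.genes)
    assert abs(total / n - rate) < 3 * np.sqrt(rate / n)


def test_coexpression_fraction_matches_closed_form_over_seeds():
    """Statistical fidelity: realized co-expression tracks the mixture model."""
    from dorsalcode.studies import coexpression_config, generative_coexpression_matrix

    fracs = []
    for seed in range(20):
        cfg = coexpression_config(seed=seed, n_cells=150)
        cells = sample_cells(cfg, 1, 1)
        a = cells["expr_A"]
        fracs.append((a & cells["expr_B"]).sum() / a.sum())
    cfg = coexpression_config()
    target = generative_coexpression_matrix(cfg)[0, 1] / 100.0
    mean = np.mean(fracs)
    sd = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert abs(mean - target) < 3 * max(sd, 1e-3)


# ------------------------------------------------------------------ counts
def test_count_matrix_null_config_has_empty_truth():
    _, _, _, truth = generate_count_matrix(
        20, {"a": 3, "b": 3}, {"a": ["g0001", "g0002"]}, fold_changes=1.0, seed=0
    )
    assert truth["a"] == set()


def test_count_matrix_zero_dispersion_exact_fold():
    counts, samples, _, truth = generate_count_matrix(
        10, {"a": 3, "b": 3}, {"a": ["g0003"]}, fold_changes=4.0,
        dispersion=0.0, seed=1,
    )
    cols_a = samples.loc[samples["group"] == "a", "sample"]
    cols_b = samples.loc[samples["group"] == "b", "sample"]
    ratio = counts.loc["g0003", cols_a].mean() / counts.loc["g0003", cols_b].mean()
    assert ratio == pytest.approx(4.0, abs=0.02)  # integer rounding only
    assert truth["a"] == {"g0003"}


def test_count_matrix_rejects_bad_inputs():
    with pytest.raises(ValueError):
        generate_count_matrix(10, {"a": 3, "b": 3}, dispersion=-1.0)
    with pytest.raises(ValueError):
        generate_count_matrix(10, {"a": 1, "b": 3})
    with pytest.raises(ValueError):
        generate_count_matrix(
            10, {"a": 3, "b": 3}, {"a": ["g0001"]}, fold_changes={"g0001": 0.5}
        )


def test_config_yaml_round_trip(tmp_path):
    from dorsalcode.simulate import load_config, save_config

    cfg = small_config(n_cells=25)
    path = tmp_path / "sim.yaml"
    save_config(cfg, path)
    back = load_config(path)
    assert back.n_cells == cfg.n_cells
    assert back.genes == cfg.genes
    assert [p.name for p in back.populations] == [p.name for p in cfg.populations]
    c1 = sample_cells(cfg, 1, 1)
    c2 = sample_cells(back, 1, 1)
    pd.testing.assert_frame_equal(c1, c2)
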