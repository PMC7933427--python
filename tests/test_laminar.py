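"""Landmark alignment, lamina assignment and per-lamina counting."""

import numpy as np
import pandas as pd
import pytest

from dorsalcode.classify import ThresholdSet, call_positive
from dorsalcode.laminar import (
    OUTSIDE,
    AffineTransform2D,
    assign_lamina,
    fit_alignment,
    lamina_counts,
)
from dorsalcode.template import default_template


def ray_casting_contains(poly, x, y):
    """Independent even-odd point-in-polygon oracle (no shapely)."""
    coords = list(poly.exterior.coords)[:-1]
    inside = False
    n = len(coords)
    for i in range(n):
        x1, y1 = coords[i]
        x2, y2 = coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xint:
                inside = not inside
    return inside


class TestFitAlignment:
    def test_identity_for_identical_landmarks(self):
        pts = [[0, 0], [10, 0], [0, 10], [7, 3]]
        t = fit_alignment(pts, pts)
        assert np.allclose(t.matrix, np.eye(2), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-12)
        assert t.residual_rms < 1e-12

    def test_recovers_known_affine(self):
        theta, scale = np.deg2rad(30), 1.2
        M = scale * np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([15.0, -7.0])
        template_pts = np.array([[0, 0], [100, 0], [0, 100], [70, 30]], float)
        section_pts = template_pts @ M.T + shift
        t = fit_alignment(section_pts, template_pts)
        expected = np.linalg.inv(M)
        assert np.abs(t.matrix - expected).max() < 1e-6 * np.abs(expected).max()
        roundtrip = t.apply(section_pts)
        assert np.abs(roundtrip - template_pts).max() < 1e-6

    def test_residual_matches_normal_equations_oracle(self, rng):
        src = rng.uniform(0, 100, size=(4, 2))
        dst = src + rng.normal(0, 1, size=(4, 2))
        t = fit_alignment(src, dst)
        X = np.column_stack([src, np.ones(4)])
        beta = np.linalg.solve(X.T @ X, X.T @ dst)  # closed-form LS
        resid = X @ beta - dst
        assert t.residual_rms == pytest.approx(
            float(np.sqrt(np.mean(np.sum(resid**2, axis=1)))), rel=1e-9
        )

    @pytest.mark.parametrize(
        "src", [[[0, 0], [1, 1]], [[0, 0], [1, 1], [2, 2], [3, 3]]]
    )
    def test_too_few_or_collinear_rejected(self, src):
        with pytest.raises(ValueError):
            fit_alignment(src, src)

    def test_transform_round_trip(self, rng):
        t = AffineTransform2D(matrix=[[1.1, 0.2], [-0.3, 0.9]], translation=[4, -2])
        pts = rng.uniform(-50, 50, size=(100, 2))
        back = t.inverse().apply(t.apply(pts))
        assert np.abs(back - pts).max() < 1e-9


class TestAssignLamina:
    def cells_at(self, points):
        return pd.DataFrame(
            {"cell_id": range(1, len(points) + 1),
             "x": [p[0] for p in points], "y": [p[1] for p in points]}
        )

    def test_interior_point_gets_its_lamina(self, template):
        p = template.lamina("II").representative_point()
        out = assign_lamina(
            self.cells_at([(p.x, p.y)]), AffineTransform2D.identity(), template
        )
        assert out["lamina_assigned"][0] == "II"

    def test_point_outside_all_laminae(self, template):
        out = assign_lamina(
            self.cells_at([(395.0, 2.0)]), AffineTransform2D.identity(), template
        )
        assert out["lamina_assigned"][0] == OUTSIDE

    def test_boundary_point_goes_dorsal(self, template):
        # a point exactly on the lamina I/II boundary segment
        poly1 = template.lamina("I")
        y_bound = poly1.bounds[3]  # ventral edge of lamina I
        out = assign_lamina(
            self.cells_at([(50.0, y_bound)]), AffineTransform2D.identity(), template
        )
        assert out["lamina_assigned"][0] == "I"

    def test_matches_ray_casting_oracle(self, template, rng):
        pts = np.column_stack([rng.uniform(0, 400, 1000), rng.uniform(0, 500, 1000)])
        out = assign_lamina(
            self.cells_at([tuple(p) for p in pts]),
            AffineTransform2D.identity(),
            template,
        )
        for (x, y), got in zip(pts, out["lamina_assigned"]):
            expected = OUTSIDE
            for name, poly in template.laminae:
                if ray_casting_contains(poly, x, y):
                    expected = name
                    break
            assert got == expected

    def test_assignment_invariant_under_shared_affine(self, template, rng):
        """Transforming both the cells and the template by the same affine
        leaves the lamina assignment unchanged."""
        from shapely import transform as sh_transform

        from dorsalcode.template import TissueTemplate

        pts = np.column_stack([rng.uniform(0, 400, 200), rng.uniform(0, 500, 200)])
        cells = self.cells_at([tuple(p) for p in pts])
        base = assign_lamina(cells, AffineTransform2D.identity(), template)

        t = AffineTransform2D(matrix=[[0.8, 0.1], [-0.2, 1.1]], translation=[30, 12])
        warp = lambda c: t.apply(c)
        warped_template = TissueTemplate(
            outline=sh_transform(template.outline, warp),
            laminae=[(n, sh_transform(p, warp)) for n, p in template.laminae],
        )
        moved = cells.copy()
        moved[["x", "y"]] = t.apply(pts)
        again = assign_lamina(moved, AffineTransform2D.identity(), warped_template)
        assert (
            base["lamina_assigned"].to_numpy() == again["lamina_assigned"].to_numpy()
        ).mean() > 0.995  # float boundary jitter only


class TestLaminaCounts:
    def make_calls(self, template, n=60, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.column_stack([rng.uniform(0, 400, n), rng.uniform(0, 500, n)])
        cells = pd.DataFrame(
            {"cell_id": range(1, n + 1), "animal_id": 1, "section_id": 1,
             "x": pts[:, 0], "y": pts[:, 1], "count_G": rng.poisson(10, n)}
        )
        calls = call_positive(cells, ThresholdSet(thresholds={"G": 1.0}))
        return assign_lamina(calls, AffineTransform2D.identity(), template)

    def test_counts_partition_positive_cells(self, template):
        cells = self.make_calls(template)
        counts = lamina_counts(cells, "G", template)
        total_positive = int(cells["pos_G"].fillna(False).sum())
        assert counts["count"].sum() == total_positive

    def test_no_positive_cells_all_zero(self, template):
        cells = self.make_calls(template)
        cells["pos_G"] = False
        counts = lamina_counts(cells, "G", template)
        assert (counts["count"] == 0).all()
        # every lamina + outside listed for the hemisection
        assert set(counts["lamina"]) == set(template.lamina_names) | {OUTSIDE}

    def test_unknown_gene_rejected(self, template):
        with pytest.raises(KeyError):
            lamina_counts(self.make_calls(template), "Z", template)

    def test_single_lamina_population_counts_fall_in_that_lamina(self):
        """Simulator population placed only in lamina II: every positive cell
        counts in lamina II, zero elsewhere (no background)."""
        from dorsalcode.classify import background_threshold
        from dorsalcode.simulate import sample_cells, measured_cell_table
        from dorsalcode.studies import laminar_recovery_config

        cfg = laminar_recovery_config(seed=4, n_cells=200)
        cfg.populations[0].lamina_weights = {"II": 1.0}
        rng = np.random.default_rng(9)
        cells = sample_cells(cfg, 1, 1, rng=rng)
        measured = measured_cell_table(cells, cfg, rng)
        calls = call_positive(measured, ThresholdSet(thresholds={"G": 0.0}))
        assigned = assign_lamina(calls, AffineTransform2D.identity(), cfg.template)
        counts = lamina_counts(assigned, "G", cfg.template)
        by = counts.groupby("lamina")["count"].sum()
        assert by["II"] == 200
        assert by.drop("II").sum() == 0
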