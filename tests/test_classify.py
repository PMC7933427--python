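"""Threshold calibration, positivity calls, Venn counts and co-expression
matrices, including the reciprocity/monotonicity invariants."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dorsalcode.classify import (
    ThresholdSet,
    background_threshold,
    call_positive,
    nearest_rank_percentile,
    pairwise_matrix,
    per_animal_average,
    venn_counts,
)


def cell_table(counts: dict, animal=1, section=1):
    n = len(next(iter(counts.values())))
    df = pd.DataFrame({"cell_id": range(1, n + 1), "animal_id": animal,
                       "section_id": section})
    for g, c in counts.items():
        df[f"count_{g}"] = c
    return df


class TestBackgroundThreshold:
    def test_all_zero_control_gives_zero_threshold(self):
        thr = background_threshold(cell_table({"A": [0] * 12}))
        assert thr["A"] == 0

    def test_nearest_rank_example(self):
        vals = [0, 0, 0, 1, 1, 1, 2, 2, 3, 5]
        assert nearest_rank_percentile(vals, 90) == 3

    def test_percentile_100_is_max(self):
        vals = [0, 1, 2, 9]
        assert nearest_rank_percentile(vals, 100) == 9

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            background_threshold(cell_table({"A": []}))

    @settings(max_examples=200, derandomize=True)
    @given(
        vals=st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=60),
        p=st.sampled_from([50.0, 90.0, 95.0, 100.0]),
    )
    def test_matches_sort_and_index_oracle(self, vals, p):
        expected = sorted(vals)[math.ceil(p / 100 * len(vals)) - 1]
        assert nearest_rank_percentile(vals, p) == expected

    def test_raising_percentile_never_lowers_threshold(self, rng):
        vals = rng.poisson(1.0, size=200)
        thrs = [nearest_rank_percentile(vals, p) for p in (50, 75, 90, 95, 100)]
        assert all(a <= b for a, b in zip(thrs, thrs[1:]))


class TestCallPositive:
    thr = ThresholdSet(thresholds={"A": 3.0})

    @pytest.mark.parametrize(
        "dots,pos,high",
        [
            (3, False, False),  # exactly at background threshold: negative
            (4, True, False),
            (20, True, False),  # exactly 20: positive but not high
            (21, True, True),
        ],
    )
    def test_strict_boundaries(self, dots, pos, high):
        calls = call_positive(cell_table({"A": [dots]}), self.thr)
        assert bool(calls["pos_A"][0]) is pos
        assert bool(calls["high_A"][0]) is high

    def test_high_implies_positive_even_with_large_background(self):
        thr = ThresholdSet(thresholds={"A": 30.0})
        calls = call_positive(cell_table({"A": [25]}), thr)
        assert not calls["pos_A"][0] and not calls["high_A"][0]

    def test_missing_threshold_rejected(self):
        with pytest.raises(KeyError):
            call_positive(cell_table({"B": [1]}), self.thr)

    def test_unmeasured_counts_give_na_calls(self):
        thr = ThresholdSet(thresholds={"A": 0.0})
        calls = call_positive(cell_table({"A": [np.nan, 5]}), thr)
        assert pd.isna(calls["pos_A"][0])
        assert calls["pos_A"][1]


class TestVennCounts:
    def calls(self):
        # 5 A-only, 3 A&B, 2 A&B&C, 4 none
        rows = [("A",)] * 5 + [("A", "B")] * 3 + [("A", "B", "C")] * 2 + [()] * 4
        counts = {
            g: [30 if g in row else 0 for row in rows] for g in ("A", "B", "C")
        }
        thr = ThresholdSet(thresholds={g: 0.0 for g in "ABC"})
        return call_positive(cell_table(counts), thr)

    def test_enumerated_toy_counts(self):
        vc = venn_counts(self.calls(), ("A", "B", "C"), level="any")
        by = vc.set_index("region")["count"]
        assert by["A"] == 5 and by["A+B"] == 3 and by["A+B+C"] == 2
        assert by["none"] == 4
        assert by[["B", "C", "B+C", "A+C"]].sum() == 0

    def test_regions_partition_cells(self):
        vc = venn_counts(self.calls(), ("A", "B", "C"))
        assert vc["count"].sum() == 14

    def test_no_positive_cells_all_zero(self):
        thr = ThresholdSet(thresholds={g: 100.0 for g in "ABC"})
        calls = call_positive(
            cell_table({g: [1, 2, 3] for g in "ABC"}), thr
        )
        vc = venn_counts(calls, ("A", "B", "C"))
        assert vc.loc[vc["region"] != "none", "count"].sum() == 0

    def test_high_level_counts_bounded_by_any_level(self):
        calls = self.calls()
        any_vc = venn_counts(calls, ("A", "B", "C"), level="any")
        high_vc = venn_counts(calls, ("A", "B", "C"), level="high")
        merged = any_vc.merge(high_vc, on=["animal_id", "region"], suffixes=("_any", "_high"))
        pos = merged[merged["region"] != "none"]
        assert (pos["count_high"] <= pos["count_any"]).all()

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            venn_counts(self.calls(), ("A", "B", "Z"))


class TestPairwiseMatrix:
    def toy_calls(self):
        # one animal: N_A=4, N_B=2, N_AB=2
        counts = {"A": [9, 9, 9, 9, 0, 0], "B": [9, 9, 0, 0, 0, 0]}
        thr = ThresholdSet(thresholds={"A": 0.0, "B": 0.0})
        return call_positive(cell_table(counts), thr)

    def test_toy_fractions(self):
        m = pairwise_matrix(self.toy_calls())
        assert m.fraction.loc["A", "B"] == pytest.approx(50.0)
        assert m.fraction.loc["B", "A"] == pytest.approx(100.0)

    def test_diagonal_is_100(self):
        m = pairwise_matrix(self.toy_calls())
        for g in ("A", "B"):
            assert m.fraction.loc[g, g] == pytest.approx(100.0)

    def test_reciprocity_on_unrounded_counts(self):
        m = pairwise_matrix(self.toy_calls())
        for a in m.n_both:
            nb, nd = m.n_both[a], m.n_denominator[a]
            f = m.per_animal_fraction[a]
            for g in m.genes:
                for h in m.genes:
                    if np.isnan(nb.loc[g, h]):
                        continue
                    assert f.loc[g, h] * nd.loc[g, h] == pytest.approx(
                        100.0 * nb.loc[g, h]
                    )
                    assert nb.loc[g, h] == nb.loc[h, g]

    def test_never_cohybridised_pair_is_missing_not_zero(self):
        c1 = cell_table({"A": [9, 9], "B": [9, 0]})
        c1["count_C"] = np.nan
        c2 = cell_table({"A": [np.nan, np.nan], "B": [9, 0]}, section=2)
        c2["count_C"] = [9.0, 9.0]
        calls = call_positive(
            pd.concat([c1, c2], ignore_index=True),
            ThresholdSet(thresholds={g: 0.0 for g in "ABC"}),
        )
        with pytest.warns(UserWarning, match="never co-hybridised"):
            m = pairwise_matrix(calls)
        assert ("A", "C") in m.missing_pairs
        assert np.isnan(m.fraction.loc["A", "C"])
        assert not np.isnan(m.fraction.loc["B", "C"])

    def test_stringency_monotonicity(self, rng):
        counts = {g: rng.poisson(15, size=80) for g in ("A", "B")}
        calls = call_positive(
            cell_table(counts), ThresholdSet(thresholds={"A": 1.0, "B": 1.0})
        )
        m_any = pairwise_matrix(calls, level="any")
        m_high = pairwise_matrix(calls, level="high")
        for g in ("A", "B"):
            assert (
                m_high.n_denominator[1].loc[g, g] <= m_any.n_denominator[1].loc[g, g]
            )

    def test_raising_background_percentile_never_grows_n(self, rng):
        counts = {"A": rng.poisson(3, size=100)}
        nc = cell_table({"A": rng.poisson(1.0, size=100)})
        prev = np.inf
        for p in (50, 90, 100):
            thr = background_threshold(nc, percentile=p)
            calls = call_positive(cell_table(counts), thr)
            n = int(calls["pos_A"].fillna(False).sum())
            assert n <= prev
            prev = n

    def test_permissive_level_matches_background_aware_closed_form(self):
        """At level 'any' the estimated fractions match the closed form of the
        full generative process including Poisson false positives from the
        calibrated background threshold."""
        from dorsalcode.simulate import simulate_cell_tables
        from dorsalcode.studies import coexpression_config
        from scipy import stats

        cfg = coexpression_config(seed=42)
        cells, nc = simulate_cell_tables(cfg)
        thr = background_threshold(nc)
        m = pairwise_matrix(call_positive(cells, thr), level="any")

        genes = cfg.genes
        w = np.array([p.weight for p in cfg.populations])
        probs = np.array(
            [[p.expression[g].prob if g in p.expression else 0.0 for g in genes]
             for p in cfg.populations]
        )
        for i, g in enumerate(genes):
            q = stats.poisson.sf(thr[g], cfg.background_dot_rate)  # P(bg > thr)
            for j, h in enumerate(genes):
                if i == j:
                    continue
                qh = stats.poisson.sf(thr[h], cfg.background_dot_rate)
                pg = w @ probs[:, i]
                ph = w @ probs[:, j]
                pgh = w @ (probs[:, i] * probs[:, j])
                num = pgh + qh * (pg - pgh) + q * (ph - pgh) + q * qh * (1 - pg - ph + pgh)
                den = pg + q * (1 - pg)
                assert m.fraction.loc[g, h] == pytest.approx(
                    100 * num / den, abs=5.0
                )


class TestPerAnimalAverage:
    def test_single_animal(self):
        mean, sd, n = per_animal_average([42.0])
        assert (mean, sd, n) == (42.0, 0.0, 1)

    def test_two_animals(self):
        mean, sd, n = per_animal_average([40.0, 60.0])
        assert mean == 50.0 and n == 2
        assert sd == pytest.approx(np.std([40, 60], ddof=1))

    def test_equal_ratios_have_zero_sd(self):
        mean, sd, _ = per_animal_average([7.0, 7.0, 7.0])
        assert mean == 7.0 and sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            per_animal_average([])
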