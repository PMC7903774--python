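"""Balanced selection, correlation, sweep, and directional decomposition."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synconcord import (
    ParameterError,
    SyntheticConfig,
    UndefinedCorrelationError,
    correlate,
    directional_concordance,
    permutation_null,
    select_top_balanced,
    sweep_concordance,
)
from synconcord.concordance import sweep_to_frame
from synconcord.quantify import TRANSCRIPT_LAYERS

from conftest import make_profiles


def _profiles(mapping):
    frame = pd.DataFrame({"protein_log2fc": pd.Series(mapping, dtype=float)})
    frame.index.name = "id"
    return frame


class TestSelectTopBalanced:
    def test_enumerable_balanced_selection(self):
        subset = select_top_balanced(
            _profiles({"a": 3, "b": 2, "c": 1, "d": -1, "e": -2, "f": -3}), 4
        )
        assert subset.up_ids == ["a", "b"]
        assert subset.down_ids == ["f", "e"]
        assert subset.shortfall_up == subset.shortfall_down == 0

    def test_exhaustion_records_shortfall(self):
        subset = select_top_balanced(
            _profiles({"a": 3, "b": 2, "c": 1, "d": -1, "e": -2, "f": -3}), 10
        )
        assert subset.up_ids == ["a", "b", "c"]
        assert subset.down_ids == ["f", "e", "d"]
        assert subset.shortfall_up == subset.shortfall_down == 2

    def test_boundary_tie_broken_lexically(self):
        subset = select_top_balanced(_profiles({"b": 2.0, "a": 2.0, "c": 1.0}), 2)
        assert subset.up_ids == ["a"]

    def test_zero_fold_change_belongs_to_neither_direction(self):
        subset = select_top_balanced(_profiles({"a": 1.0, "b": 0.0, "c": -1.0}), 4)
        assert "b" not in subset.ids

    @pytest.mark.parametrize("n", [0, -2, 3])
    def test_invalid_subset_size_is_a_parameter_error(self, n):
        with pytest.raises(ParameterError):
            select_top_balanced(_profiles({"a": 1.0, "b": -1.0}), n)

    @given(st.permutations(list(range(12))))
    @settings(max_examples=30, derandomize=True)
    def test_selection_invariant_to_row_order(self, order):
        values = [3.0, 2.0, 2.0, 1.0, 0.5, 0.1, -0.1, -0.5, -1.0, -2.0, -2.0, -3.0]
        ids = [f"g{i}" for i in range(12)]
        frame = _profiles(
            {ids[i]: values[i] for i in order}
        )
        subset = select_top_balanced(frame, 6)
        reference = select_top_balanced(_profiles(dict(zip(ids, values))), 6)
        assert subset.up_ids == reference.up_ids
        assert subset.down_ids == reference.down_ids


def _pearson_brute(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    vx = sum((a - mx) ** 2 for a in x) / n
    vy = sum((b - my) ** 2 for b in y) / n
    return cov / math.sqrt(vx * vy)


def _ranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


class TestCorrelate:
    def test_self_correlation_is_one(self):
        x = [0.3, -1.2, 2.0, 0.7, -0.4]
        r, n = correlate(x, x)
        assert r == pytest.approx(1.0)
        assert n == 5

    def test_negated_vector_gives_minus_one(self):
        x = [0.3, -1.2, 2.0, 0.7]
        r, _ = correlate(x, [-v for v in x])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_pearson_example(self):
        r, n = correlate([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert n == 4

    def test_pairwise_complete_drops_missing_values(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.1, 2.2, 3.0, np.nan, 5.1]
        r, n = correlate(x, y)
        assert n == 3
        assert r == pytest.approx(_pearson_brute([1, 2, 5], [1.1, 2.2, 5.1]))

    def test_fewer_than_three_pairs_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError, match="pair"):
            correlate([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError, match="variance"):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.integers(0, 1000))
    @settings(max_examples=60, derandomize=True)
    def test_pearson_matches_textbook_formula_to_1e12(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        x = rng.normal(size=n) * rng.uniform(0.1, 10)
        y = rng.normal(size=n) * rng.uniform(0.1, 10)
        r, _ = correlate(x, y)
        assert r == pytest.approx(_pearson_brute(list(x), list(y)), abs=1e-12)

    @given(st.integers(0, 1000))
    @settings(max_examples=30, derandomize=True)
    def test_spearman_matches_rank_then_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 51))
        x = list(rng.normal(size=n))
        y = list(rng.normal(size=n))
        r, _ = correlate(x, y, method="spearman")
        assert r == pytest.approx(_pearson_brute(_ranks(x), _ranks(y)), abs=1e-12)


class TestSweep:
    def test_proteome_against_itself_gives_unit_correlation(self, default_profiles):
        profiles = default_profiles.copy()
        profiles["self"] = profiles["protein_log2fc"]
        results = sweep_concordance(profiles, layers=["self"])
        assert all(res.r == pytest.approx(1.0) for res in results)
        assert [res.n for res in results] == [700, 600, 500, 400, 300, 200, 100]

    def test_signal_layer_wins_at_every_subset_size(self):
        """The layer carrying the generative translational signal shows the
        highest correlation at every N, in every one of 20 seeds."""
        wins = 0
        for seed in range(20):
            profiles = make_profiles(SyntheticConfig(seed=seed))
            frame = sweep_to_frame(sweep_concordance(profiles)).pivot(
                index="n", columns="layer", values="r"
            )
            ok = (
                (frame["syn_polysome"] > frame["syn_input"])
                & (frame["syn_polysome"] > frame["whole_tissue"])
            ).all()
            wins += bool(ok)
        assert wins >= 19

    def test_permuted_layer_loses_all_correlation(self):
        """Shuffling one layer's identifiers before matching destroys its
        concordance: mean |r| over 20 seeds stays below 0.1."""
        rs = []
        for seed in range(20):
            profiles = make_profiles(SyntheticConfig(n_genes=1000, seed=seed))
            rng = np.random.default_rng(seed)
            profiles = profiles.copy()
            profiles["syn_polysome"] = rng.permutation(
                profiles["syn_polysome"].to_numpy()
            )
            frame = sweep_to_frame(
                sweep_concordance(profiles, layers=["syn_polysome"])
            )
            rs.extend(frame["r"].abs().tolist())
        assert np.mean(rs) < 0.1

    def test_locality_rows_outside_the_subset_do_not_matter(self, default_profiles):
        subset = select_top_balanced(default_profiles, 100)
        restricted = default_profiles.loc[subset.ids]
        full = sweep_concordance(default_profiles, n_grid=[100])
        local = sweep_concordance(restricted, n_grid=[100])
        for a, b in zip(full, local):
            assert a.layer == b.layer
            assert a.r == pytest.approx(b.r, abs=1e-15)
            assert a.n_pairs == b.n_pairs

    def test_undefined_cells_are_recorded_not_fatal(self):
        profiles = _profiles({"a": 1.0, "b": 2.0, "c": -1.0, "d": -2.0})
        profiles["syn_input"] = [0.1, np.nan, np.nan, np.nan]
        results = sweep_concordance(profiles, n_grid=[4], layers=["syn_input"])
        assert len(results) == 1
        assert math.isnan(results[0].r)
        assert results[0].note is not None
        assert results[0].n_pairs == 1

    def test_non_descending_grid_is_rejected(self, default_profiles):
        with pytest.raises(ParameterError, match="descending"):
            sweep_concordance(default_profiles, n_grid=[100, 200])

    def test_spearman_method_is_supported(self, default_profiles):
        results = sweep_concordance(
            default_profiles, n_grid=[100], layers=["syn_polysome"],
            method="spearman",
        )
        assert results[0].method == "spearman"
        assert -1.0 <= results[0].r <= 1.0


class TestDirectional:
    def test_up_biased_translation_gives_up_only_concordance(self):
        """With a fully up-biased translational signal, the top-50 up
        correlation with the polysome layer beats the top-50 down one in at
        least 19 of 20 seeds."""
        hits = 0
        for seed in range(20):
            profiles = make_profiles(
                SyntheticConfig(translational_up_bias=1.0, seed=seed)
            )
            res = {
                (d.layer, d.direction): d.r
                for d in directional_concordance(profiles)
            }
            hits += res[("syn_polysome", "up")] > res[("syn_polysome", "down")]
        assert hits >= 19

    def test_symmetric_translation_gives_symmetric_concordance(self):
        """With an unbiased translational signal the mean up and down
        correlations agree within Monte-Carlo tolerance."""
        diffs = []
        for seed in range(20):
            profiles = make_profiles(
                SyntheticConfig(translational_up_bias=0.5, seed=seed)
            )
            res = {
                (d.layer, d.direction): d.r
                for d in directional_concordance(profiles)
            }
            diffs.append(res[("syn_polysome", "up")] - res[("syn_polysome", "down")])
        assert abs(np.mean(diffs)) < 0.05

    def test_shortfall_uses_all_available_genes(self):
        profiles = _profiles(
            {"a": 3.0, "b": 2.0, "c": 1.0, "d": -1.0, "e": -2.0, "f": -3.0,
             "g": 0.5, "h": -0.5}
        )
        profiles["syn_input"] = profiles["protein_log2fc"] * 0.5
        results = directional_concordance(profiles, n_per_direction=50)
        for res in results:
            assert res.n_selected == 4
            assert res.n == 50

    def test_too_small_direction_size_is_rejected(self, default_profiles):
        with pytest.raises(ParameterError):
            directional_concordance(default_profiles, n_per_direction=2)


def test_permutation_null_is_centered_and_spread_as_expected(default_profiles):
    null = permutation_null(default_profiles, "syn_polysome", n=100,
                            n_permutations=300, seed=5)
    assert len(null) == 300
    assert abs(null.mean()) < 0.05
    # permuted r at n=100 pairs has sd ~ 1/sqrt(99)
    assert null.std() == pytest.approx(0.1, abs=0.04)
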