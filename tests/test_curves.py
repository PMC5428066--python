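import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from genelen import (ConditionContrast, ExpressionMatrix, GeneAnnotation,
                     bin_curve, compute_fold_change, curve_spearman,
                     mean_expression_curve, read_curve_tsv, sliding_windows,
                     write_curve_tsv)


def brute_force_starts(n, window, step):
    starts = []
    s = 0
    while s + window <= n:
        starts.append(s)
        s += step
    return starts


def brute_force_curve(profile, window, step):
    """Oracle: explicit re-sort and per-window loops."""
    rows = sorted(profile.itertuples(),
                  key=lambda r: (r.length, r.Index))
    out = []
    for start in brute_force_starts(len(rows), window, step):
        members = rows[start:start + window]
        fcs = [m.logfc for m in members]
        out.append({
            "window_start": start,
            "mean_length": float(np.mean([m.length for m in members])),
            "mean_stat": float(np.mean(fcs)),
            "sem": float(np.std(fcs, ddof=1) / np.sqrt(window)),
        })
    return pd.DataFrame(out)


class TestFoldChange:
    def test_hand_computed_logfc_and_variance(self, tiny_matrix, tiny_annot):
        contrast = ConditionContrast(("c1", "c2"), ("k1", "k2"))
        prof = compute_fold_change(tiny_matrix, contrast, tiny_annot)
        # G1: case {4,4} vs control {2,2} -> logfc 2, variance 0
        assert prof.loc["G1", "logfc"] == pytest.approx(2.0)
        assert prof.loc["G1", "variance"] == pytest.approx(0.0)
        # G2: case {1,3} vs control {0,0} -> logfc 2, variance 2 + 0
        assert prof.loc["G2", "logfc"] == pytest.approx(2.0)
        assert prof.loc["G2", "variance"] == pytest.approx(2.0)
        # G3: identical values -> logfc 0
        assert prof.loc["G3", "logfc"] == pytest.approx(0.0)
        assert prof.loc["G3", "length"] == 20000.0

    def test_missing_contrast_sample_is_error(self, tiny_matrix, tiny_annot):
        contrast = ConditionContrast(("c1", "nope"), ("k1",))
        with pytest.raises(ValueError, match="absent from matrix"):
            compute_fold_change(tiny_matrix, contrast, tiny_annot)

    def test_requires_log2(self, tiny_matrix, tiny_annot):
        linear = ExpressionMatrix(2.0 ** tiny_matrix.values, "linear",
                                  dict(tiny_matrix.conditions))
        with pytest.raises(ValueError, match="log2"):
            compute_fold_change(linear,
                                ConditionContrast(("c1", "c2"), ("k1", "k2")),
                                tiny_annot)

    def test_contrast_sets_must_be_disjoint(self):
        with pytest.raises(ValueError, match="both case and control"):
            ConditionContrast(("s1", "s2"), ("s2", "s3"))

    def test_single_sample_condition_has_zero_variance(self, tiny_annot):
        values = pd.DataFrame([[5.0, 1.0]], index=["G1"],
                              columns=["c1", "k1"])
        m = ExpressionMatrix(values, "log2")
        prof = compute_fold_change(m, ConditionContrast(("c1",), ("k1",)),
                                   tiny_annot)
        assert prof.loc["G1", "logfc"] == 4.0
        assert prof.loc["G1", "variance"] == 0.0


class TestSlidingWindows:
    @pytest.mark.parametrize("n, expected", [
        (200, [0]),
        (240, [0, 40]),
        (19881, 493),
    ])
    def test_examples(self, n, expected):
        starts = sliding_windows(n)
        if isinstance(expected, list):
            assert starts.tolist() == expected
        else:
            assert starts.size == expected
        assert starts.tolist() == brute_force_starts(n, 200, 40)

    def test_too_few_genes_is_error(self):
        with pytest.raises(ValueError, match="at least window"):
            sliding_windows(199)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(n=st.integers(200, 2000),
           window=st.integers(2, 300),
           step=st.integers(1, 300))
    def test_count_formula_matches_enumeration(self, n, window, step):
        if n < window:
            return
        starts = sliding_windows(n, window, step)
        assert starts.tolist() == brute_force_starts(n, window, step)
        assert starts.size == (n - window) // step + 1


def _random_profile(n, seed, logfc=None):
    rng = np.random.default_rng(seed)
    lengths = 10.0 ** rng.uniform(3, 6, size=n)
    if logfc is None:
        logfc = rng.normal(size=n)
    return pd.DataFrame({
        "logfc": logfc,
        "variance": rng.uniform(0, 1, size=n),
        "length": lengths,
    }, index=[f"G{i}" for i in range(n)])


class TestBinCurve:
    def test_constant_statistic_gives_flat_curve_zero_sem(self):
        prof = _random_profile(300, 1, logfc=np.full(300, 0.7))
        curve = bin_curve(prof, window=100, step=50)
        np.testing.assert_allclose(curve["mean_stat"], 0.7)
        np.testing.assert_allclose(curve["sem"], 0.0, atol=1e-12)
        assert (curve["n_genes"] == 100).all()
        assert curve["mean_length"].is_monotonic_increasing

    def test_signal_in_longest_genes_lands_in_last_window(self):
        prof = _random_profile(400, 2)
        order = prof["length"].sort_values().index
        prof.loc[order[:200], "logfc"] = 0.0
        prof.loc[order[200:], "logfc"] = 1.0
        curve = bin_curve(prof, window=200, step=200)
        assert curve["mean_stat"].tolist() == [0.0, 1.0]

    def test_matches_brute_force_oracle(self):
        prof = _random_profile(500, 3)
        curve = bin_curve(prof, window=150, step=60)
        oracle = brute_force_curve(prof, 150, 60)
        np.testing.assert_allclose(curve["mean_stat"], oracle["mean_stat"],
                                   atol=1e-10)
        np.testing.assert_allclose(curve["mean_length"],
                                   oracle["mean_length"], atol=1e-8)
        np.testing.assert_allclose(curve["sem"], oracle["sem"], atol=1e-10)

    def test_invariant_to_row_order(self):
        prof = _random_profile(300, 4)
        shuffled = prof.sample(frac=1, random_state=9)
        pd.testing.assert_frame_equal(bin_curve(prof, 100, 40),
                                      bin_curve(shuffled, 100, 40))

    def test_constant_shift_moves_means_not_sem(self):
        prof = _random_profile(300, 5)
        shifted = prof.assign(logfc=prof["logfc"] + 1.5)
        c0, c1 = bin_curve(prof, 100, 40), bin_curve(shifted, 100, 40)
        np.testing.assert_allclose(c1["mean_stat"], c0["mean_stat"] + 1.5)
        np.testing.assert_allclose(c1["sem"], c0["sem"], atol=1e-12)

    def test_window_equals_step_gives_block_means(self):
        prof = _random_profile(400, 6)
        curve = bin_curve(prof, window=100, step=100)
        ordered = prof.sort_index(kind="mergesort").sort_values(
            "length", kind="mergesort")
        blocks = ordered["logfc"].to_numpy().reshape(4, 100).mean(axis=1)
        np.testing.assert_allclose(curve["mean_stat"], blocks, atol=1e-12)

    def test_length_ties_broken_by_gene_id(self):
        prof = pd.DataFrame({
            "logfc": [1.0, 2.0, 3.0, 4.0],
            "variance": 0.0,
            "length": [100.0, 100.0, 100.0, 100.0],
        }, index=["Gd", "Gb", "Ga", "Gc"])
        curve = bin_curve(prof, window=2, step=2)
        # sorted by gene id: Ga(3), Gb(2), Gc(4), Gd(1)
        assert curve["mean_stat"].tolist() == [2.5, 2.5]

    def test_empty_profile_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            bin_curve(_random_profile(0, 0), 10, 5)


class TestMeanExpressionCurve:
    @staticmethod
    def _setup(n=400, seed=7):
        rng = np.random.default_rng(seed)
        lengths = 10.0 ** rng.uniform(3, 6, size=n)
        annot = GeneAnnotation(pd.DataFrame(
            {"gene_length": lengths},
            index=[f"G{i}" for i in range(n)]))
        return rng, annot

    def test_constant_group_gives_flat_curve(self):
        rng, annot = self._setup()
        values = pd.DataFrame(np.full((400, 2), 3.3),
                              index=annot.table.index, columns=["a1", "a2"])
        m = ExpressionMatrix(values, "log10")
        curves = mean_expression_curve(m, {"a1": "A", "a2": "A"}, annot,
                                       window=100, step=50)
        np.testing.assert_allclose(curves["A"]["mean_stat"], 3.3)

    def test_shift_equivariance_between_groups(self):
        rng, annot = self._setup()
        base = rng.normal(2, 1, size=(400, 2))
        values = pd.DataFrame(np.column_stack([base, base + 1.0]),
                              index=annot.table.index,
                              columns=["a1", "a2", "b1", "b2"])
        m = ExpressionMatrix(values, "log10")
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        curves = mean_expression_curve(m, groups, annot, window=100, step=50)
        np.testing.assert_allclose(curves["B"]["mean_stat"],
                                   curves["A"]["mean_stat"] + 1.0)
        np.testing.assert_allclose(curves["B"]["sem"], curves["A"]["sem"],
                                   atol=1e-12)

    def test_planted_positive_slope_gives_monotone_curve(self):
        rng, annot = self._setup(n=2000, seed=8)
        log10_len = np.log10(annot.lengths.to_numpy())
        mean = 2.0 + 0.5 * (log10_len - log10_len.mean())
        vals = mean[:, None] + rng.normal(0, 0.3, size=(2000, 5))
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=annot.table.index,
                         columns=[f"n{i}" for i in range(5)]), "log10")
        curves = mean_expression_curve(m, {f"n{i}": "neuron"
                                           for i in range(5)}, annot)
        assert curve_spearman(curves["neuron"]) > 0.9

    def test_unlabelled_sample_is_error(self):
        rng, annot = self._setup()
        values = pd.DataFrame(np.ones((400, 2)), index=annot.table.index,
                              columns=["a1", "a2"])
        m = ExpressionMatrix(values, "log10")
        with pytest.raises(ValueError, match="without a group label"):
            mean_expression_curve(m, {"a1": "A"}, annot, 100, 50)


def test_curve_tsv_round_trip(tmp_path):
    prof = _random_profile(300, 10)
    curve = bin_curve(prof, 100, 40)
    path = tmp_path / "curve.tsv"
    write_curve_tsv(curve, path, {"window": 100, "step": 40})
    back = read_curve_tsv(path)
    np.testing.assert_allclose(back["mean_stat"], curve["mean_stat"])
    np.testing.assert_allclose(back["mean_length"], curve["mean_length"],
                               rtol=1e-9)
    assert path.read_text().startswith("#")
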