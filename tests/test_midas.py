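"""Equilibrium-dialysis interactomics statistics, checked against
brute-force oracles and on synthetic screens with known truth."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allostery_screen.midas import (
    FoldChangeMatrix,
    MidasError,
    NORMAL_IQR_FACTOR,
    build_nosignal_model,
    build_nosignal_models,
    call_interactions,
    collapse_replicates,
    compute_log2_fold_changes,
    remove_principal_components,
    remove_triplicate_outliers,
    run_midas,
    score_interactions,
)


def _measurements(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "metabolite_id", "pool_id", "replicate",
            "protein_chamber_abundance", "metabolite_chamber_abundance",
        ],
    )


class TestFoldChanges:
    @pytest.mark.parametrize(
        "protein,metabolite,expected",
        [(100.0, 100.0, 0.0), (200.0, 100.0, 1.0), (25.0, 100.0, -2.0)],
    )
    def test_exact_ratios(self, protein, metabolite, expected):
        rows = [("P1", "M1", "pool1", r, protein, metabolite) for r in (1, 2, 3)]
        fc = compute_log2_fold_changes(_measurements(rows))
        assert fc.values.shape == (1, 1, 3)
        np.testing.assert_allclose(fc.values, expected)

    def test_zero_denominator_excluded_with_warning(self, caplog):
        rows = [("P1", "M1", "pool1", r, 100.0, 100.0) for r in (1, 2, 3)]
        rows += [("P1", "M2", "pool1", 1, 100.0, 0.0)]
        rows += [("P1", "M2", "pool1", 2, 100.0, 50.0), ("P1", "M2", "pool1", 3, 100.0, 50.0)]
        with caplog.at_level("WARNING"):
            fc = compute_log2_fold_changes(_measurements(rows))
        assert "non-positive" in caplog.text
        i = fc.row_ids.index("M2")
        assert np.isnan(fc.values[i, 0]).sum() == 1

    def test_duplicate_replicates_rejected(self):
        rows = [("P1", "M1", "pool1", 1, 100.0, 100.0)] * 2
        rows += [("P1", "M1", "pool1", 2, 100.0, 100.0)]
        with pytest.raises(MidasError, match="duplicate"):
            compute_log2_fold_changes(_measurements(rows))

    def test_pair_with_single_replicate_rejected(self):
        rows = [("P1", "M1", "pool1", 1, 100.0, 100.0)]
        with pytest.raises(MidasError, match="fewer than 2"):
            compute_log2_fold_changes(_measurements(rows))


def _fc3d(values):
    values = np.asarray(values, float)
    rows = [f"M{i}" for i in range(values.shape[0])]
    cols = [f"P{j}" for j in range(values.shape[1])]
    return FoldChangeMatrix(values, rows, cols, np.zeros_like(values, dtype=bool))


class TestOutlierRemoval:
    def test_no_dispersion_removes_nothing(self):
        fc = _fc3d([[[0.1, 0.1, 0.1]]] * 5)
        out = remove_triplicate_outliers(fc)
        assert out.outlier_mask.sum() == 0

    def test_gross_spike_removed_against_reference_scale(self, rng):
        # background triplicates with sd ~0.3 set the global scale; the
        # 9.0 point is the only one with |z| > 5 against it
        vals = rng.normal(0.0, 0.3, size=(30, 1, 3))
        vals[0, 0] = [0.0, 0.1, 9.0]
        out = remove_triplicate_outliers(_fc3d(vals))
        assert out.outlier_mask.sum() == 1
        assert out.outlier_mask[0, 0, 2]
        assert np.isnan(out.values[0, 0, 2])

    def test_at_most_one_removed_per_triplicate(self, rng):
        # two wild points in one triplicate: only the more extreme goes
        vals = rng.normal(0.0, 0.3, size=(30, 1, 3))
        vals[0, 0] = [0.0, -7.0, 9.0]
        out = remove_triplicate_outliers(_fc3d(vals))
        assert out.outlier_mask[0, 0].sum() == 1
        assert out.outlier_mask[0, 0, 2]

    def test_refuses_to_drop_below_two_replicates(self, rng):
        vals = rng.normal(0.0, 0.3, size=(30, 1, 3))
        vals[0, 0] = [0.0, np.nan, 9.0]
        with pytest.raises(MidasError, match="leave <2"):
            remove_triplicate_outliers(_fc3d(vals))


class TestCollapse:
    @pytest.mark.parametrize(
        "triplet,expected",
        [([1.0, 1.0, 1.0], 1.0), ([0.0, 1.0, 2.0], 1.0), ([0.0, 1.0, np.nan], 0.5)],
    )
    def test_mean_of_retained(self, triplet, expected):
        out = collapse_replicates(_fc3d([[triplet]]))
        assert out.values[0, 0] == pytest.approx(expected)

    def test_single_retained_replicate_rejected(self):
        with pytest.raises(MidasError):
            collapse_replicates(_fc3d([[[1.0, np.nan, np.nan]]]))


def _fc2d(values):
    values = np.asarray(values, float)
    rows = [f"M{i}" for i in range(values.shape[0])]
    cols = [f"P{j}" for j in range(values.shape[1])]
    return FoldChangeMatrix(values, rows, cols)


class TestPCRemoval:
    def test_k_zero_is_identity(self, rng):
        X = rng.normal(size=(20, 6))
        out, report = remove_principal_components(_fc2d(X), k=0)
        np.testing.assert_array_equal(out.values, X)
        assert report["variance_removed"] == 0.0

    def test_exact_rank_one_vanishes(self, rng):
        X = np.outer(rng.normal(size=30), rng.normal(size=8))
        out, report = remove_principal_components(_fc2d(X), k=1)
        centered = out.values - out.values.mean(axis=0)
        assert np.abs(centered).max() <= 1e-10
        assert report["variance_removed"] == pytest.approx(1.0)

    def test_variance_removed_matches_eigendecomposition(self, rng):
        """Fraction removed equals (l1+l2+l3)/sum(l) from an independent
        full eigendecomposition of the centred covariance."""
        X = rng.normal(size=(50, 10))
        _, report = remove_principal_components(_fc2d(X), k=3)
        Xc = X - X.mean(axis=0)
        lam = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        expected = lam[:3].sum() / lam.sum()
        assert report["variance_removed"] == pytest.approx(expected, abs=1e-10)

    def test_matches_full_svd_truncation_oracle(self, rng):
        X = rng.normal(size=(50, 10))
        out, _ = remove_principal_components(_fc2d(X), k=3)
        Xc = X - X.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=True)
        s_trunc = s.copy()
        s_trunc[:3] = 0.0
        oracle = (U[:, :10] * s_trunc) @ Vt + X.mean(axis=0)
        np.testing.assert_allclose(out.values, oracle, atol=1e-10)

    def test_k_at_or_above_rank_rejected(self, rng):
        X = np.outer(rng.normal(size=20), rng.normal(size=5))
        with pytest.raises(MidasError, match="rank"):
            remove_principal_components(_fc2d(X), k=2)
        with pytest.raises(MidasError, match="out of range"):
            remove_principal_components(_fc2d(rng.normal(size=(20, 5))), k=5)

    def test_missing_entries_imputed_and_remasked(self, rng):
        X = rng.normal(size=(20, 6))
        X[3, 2] = np.nan
        out, _ = remove_principal_components(_fc2d(X), k=1)
        assert np.isnan(out.values[3, 2])
        assert np.isfinite(np.delete(out.values.ravel(), 3 * 6 + 2)).all()


class TestNoSignalModel:
    def test_hand_population_formula(self):
        m = build_nosignal_model(np.array([-1.0, -1.0, 1.0, 1.0]), "x")
        assert m.center == 0.0
        assert m.sigma == pytest.approx(2.0 / NORMAL_IQR_FACTOR)
        assert m.sigma == pytest.approx(1.4826, abs=1e-4)

    def test_standard_normal_monte_carlo(self):
        rng = np.random.default_rng(99)
        m = build_nosignal_model(rng.normal(size=100_000), "x")
        assert abs(m.center) < 0.02
        assert m.sigma == pytest.approx(1.0, abs=0.02)

    def test_tail_robustness(self):
        """5% gross right-tail signal barely moves the scale estimate."""
        rng = np.random.default_rng(4)
        pop = rng.normal(size=10_000)
        pop[:500] = 10.0
        m = build_nosignal_model(pop, "x")
        assert m.sigma == pytest.approx(1.0, rel=0.10)

    def test_degenerate_population_rejected(self):
        with pytest.raises(MidasError, match="degenerate"):
            build_nosignal_model(np.zeros(10), "x")
        with pytest.raises(MidasError, match="too small"):
            build_nosignal_model(np.array([1.0, 2.0]), "x")

    def test_shrinkage_pulls_sigma_toward_pooled(self, rng):
        vals = rng.normal(0.0, 1.0, size=(50, 20))
        vals[0] *= 3.0  # one genuinely noisy metabolite
        raw = build_nosignal_models(_fc2d(vals), prior_df=0)
        mod = build_nosignal_models(_fc2d(vals), prior_df=20)
        pooled = np.sqrt(np.mean([m.sigma**2 for m in raw]))
        assert raw[0].sigma > mod[0].sigma > pooled
        # centres untouched by shrinkage
        assert raw[0].center == mod[0].center


class TestScoring:
    def test_center_scores_zero(self):
        m = build_nosignal_model(np.array([-1.0, -0.5, 0.5, 1.0]), "x")
        z, p = score_interactions(m.center, m)
        assert z == 0.0 and p == 1.0

    def test_two_sided_normal_tails(self):
        m = build_nosignal_model(np.array([-1.0, -1.0, 1.0, 1.0]), "x")
        z, p = score_interactions(m.center + 1.959964 * m.sigma, m)
        assert p == pytest.approx(0.05, abs=1e-4)
        z, p = score_interactions(m.center - 3.0 * m.sigma, m)
        assert z == pytest.approx(-3.0)
        assert p == pytest.approx(0.0027, abs=1e-4)

    def test_zscore_matches_explicit_quantile_brute_force(self, rng):
        """z against an independent sort-and-interpolate quantile oracle."""
        vals = rng.normal(size=(50, 10))
        fc = _fc2d(vals)
        models = build_nosignal_models(fc, prior_df=0)
        for i in range(50):
            pop = np.sort(vals[i])
            n = pop.size
            # normal-unbiased plotting positions: h = (n + 1/4)p + 3/8
            def quantile(pr):
                h = (n + 0.25) * pr + 0.375 - 1.0  # 0-based
                lo = int(np.floor(h))
                return pop[lo] + (h - lo) * (pop[min(lo + 1, n - 1)] - pop[lo])
            center = 0.5 * (quantile(0.5) + quantile(0.5))
            sigma = (quantile(0.75) - quantile(0.25)) / (2 * stats.norm.ppf(0.75))
            z_oracle = (vals[i] - np.median(pop)) / sigma
            z, _ = score_interactions(vals[i], models[i])
            np.testing.assert_allclose(z, z_oracle, atol=1e-10)


class TestCalls:
    @pytest.mark.parametrize(
        "p,q,fc,expect_sig,expect_dir",
        [
            (0.01, 0.05, 2.0, True, "enriched"),
            (0.04, 0.20, 2.0, False, "enriched"),
            (0.20, 0.05, -1.0, False, "depleted"),
            (0.05, 0.05, 1.0, False, "enriched"),  # strict inequality at p
        ],
    )
    def test_threshold_logic(self, p, q, fc, expect_sig, expect_dir):
        df = pd.DataFrame(
            {"protein_id": ["P"], "metabolite_id": ["M"],
             "corrected_log2fc": [fc], "z": [0.0], "p": [p], "q": [q]}
        )
        out, summary = call_interactions(df)
        assert bool(out["significant"].iloc[0]) is expect_sig
        assert out["direction"].iloc[0] == expect_dir
        assert summary["n_significant"] == int(expect_sig)


class TestEndToEnd:
    def test_recovers_programmed_binders(self, small_midas):
        meas, truth = small_midas
        calls, summary = run_midas(meas)
        sig = calls[calls["significant"]]
        called = set(zip(sig["metabolite_id"], sig["protein_id"]))
        true_pairs = set(zip(truth["metabolite_id"], truth["protein_id"]))
        assert len(called & true_pairs) / len(true_pairs) >= 0.8
        assert 0 < summary["variance_removed"] < 1

    def test_sign_preserved_for_strong_enrichment(self, small_midas):
        meas, truth = small_midas
        calls, _ = run_midas(meas)
        merged = truth.merge(calls, on=["metabolite_id", "protein_id"])
        enriched = merged[merged["direction_x"] == "enriched"]
        assert (enriched["corrected_log2fc"] > 0).all()

    def test_row_permutation_symmetry(self, small_midas):
        """Relabeling metabolites permutes outputs identically."""
        meas, _ = small_midas
        calls_a, _ = run_midas(meas)
        relabel = {m: f"X{m}" for m in meas["metabolite_id"].unique()}
        meas_b = meas.assign(metabolite_id=meas["metabolite_id"].map(relabel))
        calls_b, _ = run_midas(meas_b)
        calls_b = calls_b.assign(
            metabolite_id=calls_b["metabolite_id"].str.removeprefix("X")
        )
        key = ["metabolite_id", "protein_id"]
        a = calls_a.sort_values(key).reset_index(drop=True)
        b = calls_b.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
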