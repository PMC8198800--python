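"""k-means background, Shapley estimators and the filtering cascade."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from lnqspr.attribution import (
    AttributionMatrix,
    BackgroundSet,
    filter_contributions,
    importance_report,
    kmeans_background,
    shapley_attribute,
)
from lnqspr.exceptions import CapabilityError, ParameterError
from lnqspr.fingerprints import FingerprintMatrix, FingerprintSpec, BitEnvironment


def brute_force_shapley(x, background, f):
    """Independent oracle: direct evaluation of the Shapley sum over
    all coalitions of the differing bits."""
    nb = len(x)
    diff = [b for b in range(nb) if (background[:, b] != x[b]).any()]
    M = len(diff)
    phi = np.zeros(nb)

    def value(subset):
        Z = background.copy()
        for b in subset:
            Z[:, b] = x[b]
        return float(np.mean(f(Z)))

    for b in diff:
        others = [d for d in diff if d != b]
        for r in range(M):
            for S in itertools.combinations(others, r):
                w = math.factorial(r) * math.factorial(M - 1 - r) / math.factorial(M)
                phi[b] += w * (value(list(S) + [b]) - value(list(S)))
    return phi


def _bg(vectors):
    vectors = np.asarray(vectors, dtype=float)
    return BackgroundSet(
        vectors=vectors,
        objective=0.0,
        assignment=np.zeros(len(vectors), dtype=int),
        indices=None,
    )


class TestKMeansBackground:
    def test_k_equals_n_is_the_training_set(self):
        rng = np.random.default_rng(0)
        X = (rng.random((8, 10)) < 0.4).astype(float)
        bg = kmeans_background(X, k=8, seed=0)
        assert bg.objective == 0.0
        assert np.array_equal(np.sort(bg.indices), np.arange(8))

    def test_k_one_is_the_brute_force_medoid(self):
        rng = np.random.default_rng(1)
        X = (rng.random((12, 6)) < 0.5).astype(float)
        bg = kmeans_background(X, k=1, seed=0)
        costs = [np.sum((X - X[i]) ** 2) for i in range(len(X))]
        assert np.isclose(bg.objective, min(costs))

    def test_two_separated_clusters(self):
        X = np.zeros((12, 8))
        X[:6, :4] = 1.0
        X[6:, 4:] = 1.0
        X[0, 7] = 1.0  # slight within-cluster spread
        bg = kmeans_background(X, k=2, seed=0)
        # brute force over all 2-medoid choices
        best = min(
            float(
                np.minimum(
                    np.sum((X - X[i]) ** 2, axis=1),
                    np.sum((X - X[j]) ** 2, axis=1),
                ).sum()
            )
            for i, j in itertools.combinations(range(12), 2)
        )
        assert np.isclose(bg.objective, best)
        assert (bg.assignment[:6] != bg.assignment[6:]).all()

    def test_objective_not_worse_than_single_restarts(self):
        """The 10-restart medoid background beats the worst single
        restart (medoid-projected, so the objectives are comparable)."""
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(2)
        X = (rng.random((40, 16)) < 0.3).astype(float)
        bg = kmeans_background(X, k=5, seed=0)
        worst = 0.0
        for s in range(10):
            centres = KMeans(n_clusters=5, n_init=1, random_state=s).fit(X).cluster_centers_
            medoids = X[
                [int(np.argmin(np.sum((X - c) ** 2, axis=1))) for c in centres]
            ]
            d2 = np.min(
                np.sum((X[:, None, :] - medoids[None, :, :]) ** 2, axis=2), axis=1
            )
            worst = max(worst, float(d2.sum()))
        assert bg.objective <= worst + 1e-9

    def test_k_larger_than_n(self):
        with pytest.raises(ParameterError):
            kmeans_background(np.zeros((3, 4)), k=5)

    def test_medoids_are_training_rows(self):
        rng = np.random.default_rng(3)
        X = (rng.random((30, 12)) < 0.4).astype(float)
        bg = kmeans_background(X, k=4, seed=1)
        for v in bg.vectors:
            assert any(np.array_equal(v, row) for row in X)


class TestShapleyExact:
    def test_linear_closed_form(self):
        rng = np.random.default_rng(0)
        nb = 14
        w = rng.normal(size=nb)
        f = lambda Z: Z @ w + 2.0
        B = (rng.random((6, nb)) < 0.4).astype(float)
        X = (rng.random((5, nb)) < 0.5).astype(float)
        attr = shapley_attribute(f, X, _bg(B), mode="exact")
        closed = w[None, :] * (X - B.mean(axis=0)[None, :])
        assert np.abs(attr.phi - closed).max() < 1e-9

    def test_matches_brute_force_on_nonlinear_predictor(self):
        rng = np.random.default_rng(1)
        nb = 10
        w = rng.normal(size=nb)
        g = lambda Z: np.tanh(Z @ w) + Z[:, 0] * Z[:, 2]
        B = (rng.random((4, nb)) < 0.5).astype(float)
        x = (rng.random(nb) < 0.5).astype(float)
        attr = shapley_attribute(g, x[None, :], _bg(B), mode="exact")
        oracle = brute_force_shapley(x, B, g)
        assert np.abs(attr.phi[0] - oracle).max() < 1e-12

    def test_symmetry_axiom(self):
        f = lambda Z: Z[:, 0] + Z[:, 1]
        bg = _bg(np.zeros((1, 2)))
        attr = shapley_attribute(f, np.ones((1, 2)), bg, mode="exact")
        assert np.allclose(attr.phi[0], [1.0, 1.0])

    def test_molecule_equal_to_background_gets_zero(self):
        f = lambda Z: Z.sum(axis=1)
        B = np.array([[1.0, 0.0, 1.0]])
        attr = shapley_attribute(f, B.copy(), _bg(B), mode="exact")
        assert np.allclose(attr.phi, 0.0)

    def test_capability_error_beyond_exact_limit(self):
        nb = 40
        f = lambda Z: Z.sum(axis=1)
        B = np.zeros((1, nb))
        x = np.ones((1, nb))
        with pytest.raises(CapabilityError, match="sampled"):
            shapley_attribute(f, x, _bg(B), mode="exact", max_exact_bits=15)

    def test_efficiency_on_trained_ensemble(self, tiny_fit):
        ds, fp, model, res = tiny_fit
        Xtr = model.exog[model.train_idx]
        bg = kmeans_background(Xtr, k=1, seed=0)
        attr = shapley_attribute(
            res.ensemble.predict, Xtr[:6], bg, mode="exact", max_exact_bits=18
        )
        assert attr.efficiency_gap().max() < 1e-6


class TestShapleySampled:
    def test_enumerating_budget_matches_exact(self):
        rng = np.random.default_rng(2)
        nb = 9
        w = rng.normal(size=nb)
        g = lambda Z: np.sin(Z @ w) + 0.5 * Z[:, 1] * Z[:, 3]
        B = (rng.random((3, nb)) < 0.5).astype(float)
        X = (rng.random((3, nb)) < 0.5).astype(float)
        exact = shapley_attribute(g, X, _bg(B), mode="exact")
        M = max(
            int(((B != x[None, :]).any(axis=0)).sum()) for x in X
        )
        sampled = shapley_attribute(
            g, X, _bg(B), mode="sampled", budget=(2 ** M) * 8, seed=0
        )
        assert np.abs(exact.phi - sampled.phi).max() < 0.02

    def test_stochastic_budget_keeps_efficiency_exact(self):
        rng = np.random.default_rng(3)
        nb = 20
        w = rng.normal(size=nb)
        g = lambda Z: np.tanh(Z @ w)
        B = (rng.random((5, nb)) < 0.5).astype(float)
        X = (rng.random((4, nb)) < 0.5).astype(float)
        attr = shapley_attribute(g, X, _bg(B), mode="sampled", budget=256, seed=1)
        assert attr.efficiency_gap().max() < 1e-9

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        nb = 18
        w = rng.normal(size=nb)
        g = lambda Z: Z @ w + (Z[:, 0] - 0.5) * Z[:, 1]
        B = (rng.random((4, nb)) < 0.5).astype(float)
        X = (rng.random((3, nb)) < 0.5).astype(float)
        a = shapley_attribute(g, X, _bg(B), mode="sampled", budget=200, seed=7)
        b = shapley_attribute(g, X, _bg(B), mode="sampled", budget=200, seed=7)
        assert np.array_equal(a.phi, b.phi)


def _toy_fp(patterns: dict[int, np.ndarray], n_molecules: int, colliding=()):
    """Hand-built FingerprintMatrix: bit -> activity pattern."""
    n_bits = 16
    X = np.zeros((n_molecules, n_bits), dtype=np.uint8)
    provenance = {}
    for bit, pattern in patterns.items():
        X[:, bit] = pattern
        envs = {f"[C:1]frag{bit}": [
            BitEnvironment(int(m), 0, 1, f"[C:1]frag{bit}")
            for m in np.flatnonzero(pattern)
        ]}
        if bit in colliding:
            envs[f"[N:1]frag{bit}b"] = [
                BitEnvironment(int(np.flatnonzero(pattern)[0]), 1, 1, f"[N:1]frag{bit}b")
            ]
        provenance[bit] = envs
    return FingerprintMatrix(
        X=X, provenance=provenance, spec=FingerprintSpec(n_bits=n_bits),
        smiles=["C"] * n_molecules,
    )


class TestFilterCascade:
    def _attr(self, phi):
        phi = np.asarray(phi, dtype=float)
        return AttributionMatrix(
            phi=phi,
            base_value=0.0,
            predictions=phi.sum(axis=1),
            molecule_indices=np.arange(len(phi)),
            mode="exact",
        )

    def test_consistent_bit_survives_with_stats(self):
        pattern = np.array([1, 1, 1, 0, 0], dtype=np.uint8)
        fp = _toy_fp({3: pattern}, 5)
        phi = np.zeros((5, 16))
        phi[:3, 3] = [1.0, 1.1, 0.9]
        table = filter_contributions(self._attr(phi), fp, "Eu")
        assert len(table) == 1
        row = table.iloc[0]
        assert row.bit == 3 and row.support == 3
        assert np.isclose(row.mean_contribution, 1.0)
        assert np.isclose(row.dispersion, np.sqrt(0.02 / 3))

    def test_dispersed_bit_dropped(self):
        pattern = np.array([1, 1, 1, 0, 0], dtype=np.uint8)
        fp = _toy_fp({2: pattern}, 5)
        phi = np.zeros((5, 16))
        phi[:3, 2] = [1.0, -1.0, 0.3]
        assert len(filter_contributions(self._attr(phi), fp, "Eu")) == 0

    def test_support_below_three_dropped(self):
        pattern = np.array([1, 1, 0, 0, 0], dtype=np.uint8)
        fp = _toy_fp({1: pattern}, 5)
        phi = np.zeros((5, 16))
        phi[:2, 1] = [1.0, 1.0]
        assert len(filter_contributions(self._attr(phi), fp, "Eu")) == 0

    def test_colliding_bit_excluded(self):
        pattern = np.array([1, 1, 1, 1, 0], dtype=np.uint8)
        fp = _toy_fp({4: pattern}, 5, colliding=(4,))
        phi = np.zeros((5, 16))
        phi[:4, 4] = 1.0
        assert len(filter_contributions(self._attr(phi), fp, "Eu")) == 0

    def test_inactive_molecule_values_ignored(self):
        """Structural zero-discard: contributions from molecules where
        the bit is off never enter mean or dispersion."""
        pattern = np.array([1, 1, 1, 0, 0], dtype=np.uint8)
        fp = _toy_fp({5: pattern}, 5)
        phi = np.zeros((5, 16))
        phi[:3, 5] = 2.0
        phi[3:, 5] = -50.0  # sampled-mode noise on inactive molecules
        table = filter_contributions(self._attr(phi), fp, "Eu")
        assert np.isclose(table.iloc[0].mean_contribution, 2.0)


class TestImportanceReport:
    def _table(self, metal, rows):
        return pd.DataFrame(
            [
                {
                    "metal": metal, "bit": b, "environment_key": k,
                    "mean_contribution": m, "dispersion": d, "support": s,
                }
                for b, k, m, d, s in rows
            ]
        )

    def test_single_metal_single_row(self):
        long, pivot = importance_report(
            [self._table("Eu", [(3, "[C:1]C", 1.2, 0.1, 5)])]
        )
        assert len(long) == 1 and pivot.shape == (1, 1)

    def test_cross_metal_pivot_and_ordering(self):
        t1 = self._table("Eu", [(3, "[C:1]C", 0.5, 0.1, 5), (7, "[O:1]C", -2.0, 0.2, 4)])
        t2 = self._table("La", [(3, "[C:1]C", 1.5, 0.1, 6)])
        long, pivot = importance_report([t1, t2])
        assert list(long["metal"]) == ["Eu", "Eu", "La"]
        assert list(long["bit"]) == [7, 3, 3]  # |mean| descending within metal
        assert pivot.loc[(3, "[C:1]C"), "Eu"] == 0.5
        assert pivot.loc[(3, "[C:1]C"), "La"] == 1.5
        assert np.isnan(pivot.loc[(7, "[O:1]C"), "La"])

    def test_round_trip_through_csv(self, tmp_path):
        t = self._table("Eu", [(3, "[C:1]C", 0.5, 0.1, 5), (7, "[O:1]C", -2.0, 0.2, 4)])
        long, _ = importance_report([t])
        path = tmp_path / "long.csv"
        long.to_csv(path, index=False)
        back = pd.read_csv(path)
        pd.testing.assert_frame_equal(back, long)
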