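"""Decoding a trained ensemble into per-fragment logK contributions.

A fitted ensemble is a black box; Shapley attribution turns it back
into chemistry.  For every training molecule the prediction is
decomposed into additive per-bit contributions phi satisfying the
efficiency axiom

    base + sum_b phi[m, b] = f(x_m),

where the base value is the mean prediction over a background set.
The background is the training fingerprint space reduced to k
representatives by k-means; because fingerprints are binary, each
representative is taken as the *medoid* (the training vector nearest
its centroid) so the background stays chemically valid.  The value of
a coalition S is the interventional expectation
``mean_z f(x_S, z_!S)`` over the background vectors z.

Two estimators are provided: exact coalition enumeration over the
bits at which the molecule differs from the background (cost 2^M),
and a kernel-weighted least-squares estimator (the Shapley-kernel
regression) for larger M.  Bits identical across the molecule and all
background vectors provably carry zero attribution and are skipped.

The filtering cascade then reduces per-molecule attributions to a
per-fragment table: colliding bits are discarded, contributions are
pooled over the molecules in which the bit is active, bits whose
dispersion exceeds the magnitude of their mean contribution are
dropped, and a fragment must be supported by at least three molecules
to be reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .exceptions import CapabilityError, ParameterError
from .fingerprints import FingerprintMatrix, depict_bit, detect_collisions

Predictor = Callable[[np.ndarray], np.ndarray]

_PREDICT_CHUNK = 65536


@dataclass
class BackgroundSet:
    """k representatives of the training fingerprint space.

    ``objective`` is the total within-cluster squared Euclidean
    distance of the training vectors to their nearest representative,
    recomputable from ``assignment``.
    """

    vectors: np.ndarray
    objective: float
    assignment: np.ndarray
    indices: np.ndarray | None  # rows of X_train used as medoids; None for centroids


def _wcss(X: np.ndarray, reps: np.ndarray) -> tuple[float, np.ndarray]:
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        - 2.0 * X @ reps.T
        + np.sum(reps * reps, axis=1)[None, :]
    )
    assign = np.argmin(d2, axis=1)
    return float(np.maximum(d2[np.arange(len(X)), assign], 0.0).sum()), assign


def kmeans_background(
    X_train: np.ndarray, k: int = 30, seed: int = 0, medoid: bool = True
) -> BackgroundSet:
    """Summarise the training vectors into k background representatives.

    k-means (10 restarts) finds the centroids; with ``medoid=True``
    (default) each centroid is replaced by the nearest distinct
    training vector, so every representative is an actual fingerprint.
    """
    X = np.asarray(X_train, dtype=float)
    if k > len(X):
        raise ParameterError(f"k={k} exceeds the {len(X)} training vectors")
    if k == len(X):
        reps, idx = X.copy(), np.arange(len(X))
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        centres = km.cluster_centers_
        if medoid:
            idx = np.full(k, -1)
            d2 = (
                np.sum(X * X, axis=1)[None, :]
                - 2.0 * centres @ X.T
                + np.sum(centres * centres, axis=1)[:, None]
            )
            for i in range(k):
                for j in np.argsort(d2[i], kind="stable"):
                    if j not in idx:
                        idx[i] = j
                        break
            reps = X[idx]
        else:
            reps, idx = centres, None
    objective, assign = _wcss(X, reps)
    return BackgroundSet(
        vectors=reps,
        objective=objective,
        assignment=assign,
        indices=None if (idx is None) else np.asarray(idx),
    )


@dataclass
class AttributionMatrix:
    """Per-molecule, per-bit Shapley contributions to predicted logK."""

    phi: np.ndarray
    base_value: float
    predictions: np.ndarray
    molecule_indices: np.ndarray
    mode: str

    def efficiency_gap(self) -> np.ndarray:
        """|base + sum(phi) - prediction| per molecule."""
        return np.abs(self.base_value + self.phi.sum(axis=1) - self.predictions)


def _batched_predict(predictor: Predictor, rows: np.ndarray) -> np.ndarray:
    out = np.empty(len(rows), dtype=float)
    for lo in range(0, len(rows), _PREDICT_CHUNK):
        out[lo : lo + _PREDICT_CHUNK] = np.asarray(
            predictor(rows[lo : lo + _PREDICT_CHUNK]), dtype=float
        ).ravel()
    return out


def _exact_phi(
    predictor: Predictor,
    x: np.ndarray,
    background: np.ndarray,
    diff: np.ndarray,
    fx: float,
    base: float,
) -> np.ndarray:
    """Full coalition enumeration over the differing bits."""
    M = len(diff)
    k = len(background)
    n_masks = 1 << M
    v = np.empty(n_masks, dtype=float)
    # composites for all masks x backgrounds, chunked over masks
    mask_chunk = max(1, _PREDICT_CHUNK // k)
    for m0 in range(0, n_masks, mask_chunk):
        masks = np.arange(m0, min(m0 + mask_chunk, n_masks))
        z = (masks[:, None] >> np.arange(M)[None, :]) & 1  # (mc, M)
        rows = np.repeat(background[None, :, :], len(masks), axis=0)  # (mc,k,nb)
        sel = z.astype(bool)
        for j, b in enumerate(diff):
            rows[sel[:, j], :, b] = x[b]
        preds = _batched_predict(predictor, rows.reshape(-1, x.shape[0]))
        v[masks] = preds.reshape(len(masks), k).mean(axis=1)
    # pin the endpoints to their analytic values
    v[0] = base
    v[-1] = fx

    idx = np.arange(n_masks)
    popcount = np.zeros(n_masks, dtype=int)
    for j in range(M):
        popcount += (idx >> j) & 1
    from math import factorial

    W = np.array(
        [factorial(s) * factorial(M - 1 - s) / factorial(M) for s in range(M)]
    )
    phi = np.zeros(len(x), dtype=float)
    for j, b in enumerate(diff):
        without = idx[(idx >> j) & 1 == 0]
        phi[b] = float(
            np.sum(W[popcount[without]] * (v[without | (1 << j)] - v[without]))
        )
    return phi


def _kernel_weights(M: int, sizes: np.ndarray) -> np.ndarray:
    from scipy.special import comb

    return (M - 1) / (comb(M, sizes) * sizes * (M - sizes))


def _sampled_phi(
    predictor: Predictor,
    x: np.ndarray,
    background: np.ndarray,
    diff: np.ndarray,
    fx: float,
    base: float,
    budget: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shapley-kernel weighted least squares over sampled coalitions.

    ``budget`` counts model evaluations per molecule.  When the budget
    covers full enumeration against the full background the estimator
    enumerates (and then coincides with the exact values); otherwise
    coalitions are drawn from the Shapley-kernel size distribution in
    antithetic (coalition, complement) pairs, each evaluated against a
    cycling background vector.
    """
    M = len(diff)
    k = len(background)
    nb = x.shape[0]
    delta = fx - base
    phi = np.zeros(nb, dtype=float)
    if M == 1:
        phi[diff[0]] = delta
        return phi

    n_full = (1 << M) - 2
    enumerate_all = n_full * k <= budget
    if enumerate_all:
        masks = np.arange(1, (1 << M) - 1)
        z = ((masks[:, None] >> np.arange(M)[None, :]) & 1).astype(float)
        sizes = z.sum(axis=1).astype(int)
        w = _kernel_weights(M, sizes)
        rows = np.repeat(background[None, :, :], len(masks), axis=0)
        sel = z.astype(bool)
        for j, b in enumerate(diff):
            rows[sel[:, j], :, b] = x[b]
        preds = _batched_predict(predictor, rows.reshape(-1, nb))
        v = preds.reshape(len(masks), k).mean(axis=1)
    else:
        from scipy.special import comb

        n_coal = max(budget, 4 * M + 8)
        n_pairs = n_coal // 2
        sizes_grid = np.arange(1, M)
        # sample sizes proportionally to the kernel mass of each size class
        mass = _kernel_weights(M, sizes_grid) * comb(M, sizes_grid)
        mass = mass / mass.sum()
        half = rng.choice(sizes_grid, size=n_pairs, p=mass)
        z = np.zeros((2 * n_pairs, M), dtype=float)
        for i, s in enumerate(half):
            on = rng.choice(M, size=int(s), replace=False)
            z[2 * i, on] = 1.0
            z[2 * i + 1] = 1.0 - z[2 * i]  # antithetic complement
        w = np.ones(len(z))
        bg_order = rng.permutation(
            np.resize(np.arange(k), len(z))
        )
        rows = background[bg_order].copy()
        sel = z.astype(bool)
        for j, b in enumerate(diff):
            rows[sel[:, j], b] = x[b]
        v = _batched_predict(predictor, rows)

    # weighted least squares with the efficiency constraint eliminated
    # through the last differing feature
    sw = np.sqrt(w)
    t = z[:, -1]
    A = z[:, :-1] - t[:, None]
    y = (v - base) - t * delta
    coef, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
    phi[diff[:-1]] = coef
    phi[diff[-1]] = delta - coef.sum()
    return phi


def shapley_attribute(
    predictor: Predictor,
    X_explain: np.ndarray,
    background: BackgroundSet,
    mode: str = "exact",
    budget: int = 4096,
    seed: int = 0,
    max_exact_bits: int = 15,
    molecule_indices: np.ndarray | None = None,
) -> AttributionMatrix:
    """Shapley attributions of the predictor for each explained vector.

    ``predictor`` is any vector-to-real batch function (the estimator
    is model-agnostic); ``X_explain`` are the fingerprints to explain.
    Exact mode enumerates coalitions and requires at most
    ``max_exact_bits`` bits differing from the background per
    molecule; sampled mode is seed-reproducible and spends ``budget``
    model evaluations per molecule.
    """
    if mode not in ("exact", "sampled"):
        raise ValueError("mode must be 'exact' or 'sampled'")
    X = np.asarray(X_explain, dtype=float)
    B = np.asarray(background.vectors, dtype=float)
    rng = np.random.default_rng(seed)
    base = float(np.mean(_batched_predict(predictor, B)))
    preds = _batched_predict(predictor, X)
    phi = np.zeros_like(X, dtype=float)
    for m in range(len(X)):
        x = X[m]
        diff = np.flatnonzero((B != x[None, :]).any(axis=0))
        if len(diff) == 0:
            continue
        if mode == "exact":
            if len(diff) > max_exact_bits:
                raise CapabilityError(
                    f"molecule {m} differs from the background at {len(diff)} bits "
                    f"(> {max_exact_bits}); use mode='sampled'"
                )
            phi[m] = _exact_phi(predictor, x, B, diff, float(preds[m]), base)
        else:
            phi[m] = _sampled_phi(
                predictor, x, B, diff, float(preds[m]), base, budget, rng
            )
    if molecule_indices is None:
        molecule_indices = np.arange(len(X))
    return AttributionMatrix(
        phi=phi,
        base_value=base,
        predictions=preds,
        molecule_indices=np.asarray(molecule_indices),
        mode=mode,
    )


_TABLE_COLUMNS = [
    "metal", "bit", "environment_key",
    "mean_contribution", "dispersion", "support",
]


def filter_contributions(
    attr: AttributionMatrix,
    fp: FingerprintMatrix,
    metal: str,
    min_support: int = 3,
) -> pd.DataFrame:
    """Reduce per-molecule attributions to a fragment-importance table.

    Cascade, per bit: (1) colliding bits are discarded; (2) zero
    values are discarded - both structural (bit inactive, the fragment
    is absent) and exact numeric zeros (the l1 step of the sampled
    estimator deselected the bit for that molecule); (3) the mean and
    the dispersion (root mean squared deviation from the mean) of the
    kept values are computed and the bit is dropped when the
    dispersion exceeds |mean|; (4) at least ``min_support`` values
    must remain.  Surviving rows carry the bit's fragment SMILES.
    """
    colliding = detect_collisions(fp)
    active = fp.X[attr.molecule_indices] > 0
    rows = []
    for bit in range(fp.X.shape[1]):
        if bit in colliding or bit not in fp.provenance:
            continue
        mask = active[:, bit] & (attr.phi[:, bit] != 0.0)
        support = int(mask.sum())
        if support == 0:
            continue
        values = attr.phi[mask, bit]
        mean = float(values.mean())
        dispersion = float(np.sqrt(np.mean((values - mean) ** 2)))
        if dispersion > abs(mean):
            continue
        if support < min_support:
            continue
        rows.append(
            {
                "metal": metal,
                "bit": bit,
                "environment_key": depict_bit(fp, bit)[0],
                "mean_contribution": mean,
                "dispersion": dispersion,
                "support": support,
            }
        )
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return table.sort_values(
        "mean_contribution", key=lambda s: -s.abs(), ignore_index=True
    )


def importance_report(
    tables: Sequence[pd.DataFrame],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-metal summary: long-format table plus a fragment pivot.

    The long table is ordered by (metal, descending |mean
    contribution|); the pivot has one row per fragment and one column
    per metal, filled with the mean contribution where the fragment
    survived filtering.
    """
    if not len(tables):
        raise ValueError("at least one fragment table is required")
    long = pd.concat(tables, ignore_index=True)
    long["_absmean"] = long["mean_contribution"].abs()
    long = long.sort_values(
        ["metal", "_absmean"], ascending=[True, False], ignore_index=True
    ).drop(columns="_absmean")
    pivot = long.pivot_table(
        index=["bit", "environment_key"],
        columns="metal",
        values="mean_contribution",
    )
    return long, pivot
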