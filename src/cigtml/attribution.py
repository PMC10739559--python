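"""Additive (Shapley) feature attributions for fitted classifiers.

Attributions explain the case-probability output: for sample ``x`` and
feature ``j``, ``phi[x, j]`` is the Shapley value of feature ``j`` under
the interventional value function

    v(S) = E_b[ f(x_S, b_{~S}) ]

where the expectation runs over a background (reference) matrix ``b`` —
features in the coalition ``S`` take the sample's values, the rest take
background values. The baseline is ``v(emptyset)``, the mean model output
over the background, and local accuracy holds by construction:
``baseline + sum_j phi[x, j] == f(x)`` exactly (up to float roundoff).

Two evaluation strategies are provided: exact enumeration over all ``2^d``
coalitions (feasible for small selected-feature counts) and a seeded
permutation-sampling estimator whose per-permutation marginal
contributions telescope, so local accuracy remains exact even at small
sample counts; only the split of credit among features carries Monte
Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial
from typing import Callable, Literal

import numpy as np

PredictFn = Callable[[np.ndarray], np.ndarray]

#: largest feature count for which exact enumeration is attempted by default
EXACT_LIMIT = 8

#: rows predicted per chunk, bounding peak memory in the hybrid matrices
_CHUNK = 65536


@dataclass(frozen=True)
class AttributionMatrix:
    """Signed per-sample, per-feature attributions for one classifier."""

    classifier: str
    phi: np.ndarray  # (n_samples, n_features)
    baseline: np.ndarray  # (n_samples,), constant under the interventional game
    target: str = "case_probability"

    @property
    def n_samples(self) -> int:
        return self.phi.shape[0]

    @property
    def n_features(self) -> int:
        return self.phi.shape[1]

    def mean_abs(self) -> np.ndarray:
        """Global importance: mean |phi| per feature."""
        return np.abs(self.phi).mean(axis=0)


def _predict_chunked(predict: PredictFn, X: np.ndarray) -> np.ndarray:
    if len(X) <= _CHUNK:
        return np.asarray(predict(X), dtype=float)
    parts = [predict(X[i : i + _CHUNK]) for i in range(0, len(X), _CHUNK)]
    return np.concatenate([np.asarray(p, dtype=float) for p in parts])


def exact_shapley(
    predict: PredictFn, X: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact interventional Shapley values by coalition enumeration.

    Cost grows as ``2^d``; use only for small ``d`` (see ``EXACT_LIMIT``).
    Returns ``(phi, baseline)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n, d = X.shape
    n_bg = len(background)
    subsets = list(range(1 << d))
    weights = {s: factorial(s) * factorial(d - 1 - s) / factorial(d) for s in range(d)}
    phi = np.zeros((n, d))
    baseline = np.empty(n)
    member_cache = [
        np.array([j for j in range(d) if mask >> j & 1], dtype=int) for mask in subsets
    ]
    for i in range(n):
        hybrids = np.empty((len(subsets) * n_bg, d))
        for k, members in enumerate(member_cache):
            block = background.copy()
            block[:, members] = X[i, members]
            hybrids[k * n_bg : (k + 1) * n_bg] = block
        v = _predict_chunked(predict, hybrids).reshape(len(subsets), n_bg).mean(axis=1)
        baseline[i] = v[0]
        for mask in subsets:
            s = int(bin(mask).count("1"))
            w = weights.get(s)
            if w is None:
                continue
            for j in range(d):
                if not mask >> j & 1:
                    phi[i, j] += w * (v[mask | (1 << j)] - v[mask])
    return phi, baseline


def permutation_shapley(
    predict: PredictFn,
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling Shapley estimate with exact local accuracy.

    For each sampled feature ordering, features are switched from
    background to sample values one at a time and the marginal change in
    the background-averaged output is credited to the switched feature.
    Marginals telescope within each ordering, so attributions always sum
    to ``f(x) - baseline``; averaging over orderings (seeded, hence
    deterministic) reduces the variance of the per-feature split.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n, d = X.shape
    n_bg = len(background)
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(d) for _ in range(n_permutations)]
    phi = np.zeros((n, d))
    baseline = np.empty(n)
    for i in range(n):
        # rows: for each permutation, d+1 coalition states x n_bg background rows
        hybrids = np.empty((n_permutations * (d + 1) * n_bg, d))
        r = 0
        for perm in perms:
            block = background.copy()
            hybrids[r : r + n_bg] = block
            r += n_bg
            for j in perm:
                block[:, j] = X[i, j]
                hybrids[r : r + n_bg] = block
                r += n_bg
        v = (
            _predict_chunked(predict, hybrids)
            .reshape(n_permutations, d + 1, n_bg)
            .mean(axis=2)
        )
        baseline[i] = v[:, 0].mean()
        for p, perm in enumerate(perms):
            phi[i, perm] += v[p, 1:] - v[p, :-1]
        phi[i] /= n_permutations
    return phi, baseline


def compute_attributions(
    model_member: object,
    X: np.ndarray,
    background: np.ndarray,
    classifier: str = "model",
    algorithm: Literal["auto", "exact", "permutation"] = "auto",
    n_permutations: int = 20,
    seed: int = 0,
) -> AttributionMatrix:
    """Attribution matrix for one fitted probabilistic classifier.

    ``model_member`` must expose ``predict_proba``; column 1 (the case
    probability) is explained. ``X`` and ``background`` must share the
    model's feature columns. ``algorithm='auto'`` enumerates coalitions
    exactly up to ``EXACT_LIMIT`` features and falls back to seeded
    permutation sampling beyond that.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background matrix must be non-empty")
    if X.shape[1] != background.shape[1]:
        raise ValueError(
            f"column mismatch: X has {X.shape[1]} features, "
            f"background has {background.shape[1]}"
        )
    if not hasattr(model_member, "predict_proba"):
        raise TypeError(f"{classifier}: model must expose predict_proba")
    n_model = getattr(model_member, "n_features_in_", X.shape[1])
    if n_model != X.shape[1]:
        raise ValueError(
            f"column mismatch: model expects {n_model} features, X has {X.shape[1]}"
        )
    predict = lambda M: model_member.predict_proba(M)[:, 1]  # noqa: E731
    if algorithm == "auto":
        algorithm = "exact" if X.shape[1] <= EXACT_LIMIT else "permutation"
    if algorithm == "exact":
        phi, baseline = exact_shapley(predict, X, background)
    elif algorithm == "permutation":
        phi, baseline = permutation_shapley(
            predict, X, background, n_permutations=n_permutations, seed=seed
        )
    else:
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    return AttributionMatrix(classifier=classifier, phi=phi, baseline=baseline)


def check_local_accuracy(
    att: AttributionMatrix, predict: PredictFn, X: np.ndarray, tol: float = 1e-6
) -> float:
    """Max |baseline + sum(phi) - f(x)| over samples; raises above ``tol``."""
    outputs = _predict_chunked(predict, np.atleast_2d(X))
    gap = float(np.max(np.abs(att.baseline + att.phi.sum(axis=1) - outputs)))
    if gap > tol:
        raise AssertionError(
            f"{att.classifier}: local accuracy violated, max gap {gap:.3g} > {tol:.3g}"
        )
    return gap
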