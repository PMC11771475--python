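"""Evaluation metrics: parameter / prediction RMSE and Rand-type indices."""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score, rand_score

__all__ = [
    "rmse_params",
    "rmse_prediction",
    "adjusted_rand_index",
    "rand_index",
    "particle_averaged_ari",
]


def rmse_params(est_alpha, est_beta, true_alpha, true_beta) -> float:
    """RMSE over the concatenated (alpha, beta) parameter vector."""
    est_alpha, est_beta = np.asarray(est_alpha), np.asarray(est_beta)
    true_alpha, true_beta = np.asarray(true_alpha), np.asarray(true_beta)
    if est_alpha.shape != true_alpha.shape or est_beta.shape != true_beta.shape:
        raise ValueError("estimate/truth length mismatch")
    err = np.concatenate([est_alpha - true_alpha, est_beta - true_beta])
    return float(np.sqrt(np.mean(err**2)))


def rmse_prediction(y_pred, y_new) -> float:
    """RMSE of one-step-ahead forecasts against held-out observations."""
    y_pred, y_new = np.asarray(y_pred), np.asarray(y_new)
    if y_pred.shape != y_new.shape:
        raise ValueError("prediction/observation length mismatch")
    return float(np.sqrt(np.mean((y_pred - y_new) ** 2)))


def _labels(p) -> np.ndarray:
    return np.asarray(p.assignment if hasattr(p, "assignment") else p)


def adjusted_rand_index(p1, p2) -> float:
    """Hubert-Arabie chance-corrected Rand index between two partitions
    (assignment vectors or SpatialPartition objects)."""
    a, b = _labels(p1), _labels(p2)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same units")
    return float(adjusted_rand_score(a, b))


def rand_index(p1, p2) -> float:
    """Plain Rand index: proportion of unit pairs on which the two
    partitions agree."""
    a, b = _labels(p1), _labels(p2)
    if a.shape != b.shape:
        raise ValueError("partitions must cover the same units")
    return float(rand_score(a, b))


def particle_averaged_ari(particle_set, gamma_alpha_true, gamma_beta_true) -> tuple[float, float]:
    """Posterior-mean adjusted Rand indices approximated over the particle
    set, weighting distinct particles by their untempered truncated-posterior
    mass."""
    idx, w = particle_set.distinct_weights("untempered")
    ari_a = ari_b = 0.0
    for i, wt in zip(idx, w):
        p = particle_set.particles[i]
        ari_a += wt * adjusted_rand_index(p.gamma_alpha, gamma_alpha_true)
        ari_b += wt * adjusted_rand_index(p.gamma_beta, gamma_beta_true)
    return float(ari_a), float(ari_b)
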