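"""Neighborhood component analysis (NCA) feature weighting and selection.

Learns a nonnegative relevance weight per feature by maximizing the
regularized leave-one-out neighbor-classification objective

    F(w) = (1/n) sum_i sum_{j : y_j = y_i} p_ij  -  lambda * sum_r w_r^2

with per-feature weighted L1 distances d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|
and reference probabilities p_ij proportional to exp(-d_w(x_i, x_j) / sigma)
(p_ii = 0, rows normalized).  The squared-weight parameterization keeps the
effective metric nonnegative; weights are additionally floored at zero.
Only the diagonal (per-feature) weighting is learned, not a full linear
transform, which is what makes the weights usable for feature ranking.

Features may optionally be processed in overlapping blocks, each block
fitted independently and a feature's weight averaged over the blocks that
contain it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .backbone import FeatureMatrix


@dataclass
class NcaWeights:
    w: np.ndarray
    objective_trace: list[float]
    lam: float
    sigma: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if (self.w < 0).any():
            raise ValueError("NCA weights must be nonnegative")


@dataclass(frozen=True)
class BlockSpec:
    block_size: int
    stride: int

    def __post_init__(self) -> None:
        if not (1 <= self.stride <= self.block_size):
            raise ValueError("require 1 <= stride <= block_size")

    def blocks(self, d: int) -> list[np.ndarray]:
        if self.block_size > d:
            raise ValueError(f"block_size {self.block_size} exceeds {d} features")
        starts = list(range(0, d - self.block_size + 1, self.stride))
        if starts[-1] + self.block_size < d:
            starts.append(d - self.block_size)
        return [np.arange(s, s + self.block_size) for s in starts]


@dataclass(frozen=True)
class SelectedFeatures:
    indices: tuple[int, ...]
    k: int


def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (x - mean) / sd


def _abs_diff_tensor(z: np.ndarray, chunk: int = 64) -> np.ndarray:
    """|z_i - z_j| per feature as float32, built row-chunked to bound peaks."""
    n, d = z.shape
    z32 = z.astype(np.float32)
    out = np.empty((n, n, d), dtype=np.float32)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        out[start:stop] = np.abs(z32[start:stop, None, :] - z32[None, :, :])
    return out


def _objective_terms(absdiff: np.ndarray, same: np.ndarray, w: np.ndarray,
                     sigma: float) -> tuple[float, np.ndarray]:
    """Leave-one-out objective value (without regularizer) and P matrix."""
    n = absdiff.shape[0]
    dist = absdiff @ (w * w).astype(np.float32)
    logits = -dist / np.float32(sigma)
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    return float((p * same).sum() / n), p


def fit_nca_weights(
    data: FeatureMatrix,
    lam: float | None = None,
    step_size: float = 0.01,
    max_iter: int = 200,
    seed: int = 0,
    sigma: float = 1.0,
) -> NcaWeights:
    """Gradient-ascent NCA weighting from an all-ones start.

    ``lam`` defaults to 1/n.  A backtracking (step-halving) line search
    keeps the objective trace non-decreasing up to its tolerance; weights
    are clipped at zero after each step.  Features are standardized
    internally, so ``sigma = 1`` is a sensible kernel width.
    """
    x = np.asarray(data.values, dtype=float)
    y = np.asarray(data.labels)
    n, d = x.shape
    if n < 2:
        raise ValueError("NCA needs at least 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("NCA needs at least 2 classes")
    if not np.isfinite(x).all():
        raise ValueError("features contain non-finite values")
    if lam is None:
        lam = 1.0 / n
    z = _standardize(x)
    absdiff = _abs_diff_tensor(z)
    same = (y[:, None] == y[None, :]).astype(np.float32)
    np.fill_diagonal(same, 0.0)

    w = np.ones(d)
    loo, p = _objective_terms(absdiff, same, w, sigma)
    obj = loo - lam * float(w @ w)
    trace = [obj]
    step = step_size
    for _ in range(max_iter):
        # gradient of the leave-one-out term
        p_same = (p * same).sum(axis=1)  # p_i
        m = (p * p_same[:, None] - p * same).astype(np.float32)
        core = np.tensordot(m, absdiff, axes=([0, 1], [0, 1])).astype(float)
        grad = (2.0 * w / sigma) * core / n - 2.0 * lam * w
        if np.linalg.norm(grad) < 1e-8:
            break
        accepted = False
        for _ in range(25):
            w_new = np.clip(w + step * grad, 0.0, None)
            loo_new, p_new = _objective_terms(absdiff, same, w_new, sigma)
            obj_new = loo_new - lam * float(w_new @ w_new)
            if obj_new >= obj - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted or np.allclose(w_new, w):
            break
        w, p, obj = w_new, p_new, obj_new
        trace.append(obj)
        step *= 1.2
    return NcaWeights(w=w, objective_trace=trace, lam=lam, sigma=sigma)


def fit_nca_blockwise(
    data: FeatureMatrix,
    blocks: BlockSpec,
    lam: float | None = None,
    step_size: float = 0.01,
    max_iter: int = 200,
    seed: int = 0,
    sigma: float = 1.0,
) -> NcaWeights:
    """Fit NCA independently on overlapping feature blocks and average.

    A feature appearing in several blocks gets the mean of its per-block
    weights.  With ``block_size == stride == d`` this reduces to
    :func:`fit_nca_weights`.
    """
    d = data.n_features
    weight_sum = np.zeros(d)
    weight_count = np.zeros(d)
    trace: list[float] = []
    lam_used = sigma_used = None
    for block in blocks.blocks(d):
        sub = FeatureMatrix(values=data.values[:, block], labels=data.labels,
                            feature_ids=[data.feature_ids[j] for j in block])
        fitted = fit_nca_weights(sub, lam=lam, step_size=step_size,
                                 max_iter=max_iter, seed=seed, sigma=sigma)
        weight_sum[block] += fitted.w
        weight_count[block] += 1
        trace.extend(fitted.objective_trace)
        lam_used, sigma_used = fitted.lam, fitted.sigma
    return NcaWeights(w=weight_sum / weight_count, objective_trace=trace,
                      lam=lam_used, sigma=sigma_used)


def select_top_k(weights: NcaWeights, k: int) -> SelectedFeatures:
    """Indices of the k largest weights; ties broken by ascending index."""
    d = len(weights.w)
    if not (1 <= k <= d):
        raise ValueError(f"k must lie in [1, {d}], got {k}")
    order = np.lexsort((np.arange(d), -weights.w))
    return SelectedFeatures(indices=tuple(int(i) for i in order[:k]), k=k)


def save_weights_csv(
    weights: NcaWeights, selected: SelectedFeatures,
    feature_ids: list[str], path,
) -> None:
    """Persist per-feature weights and the selection flag as CSV."""
    chosen = set(selected.indices)
    pd.DataFrame({
        "feature_id": feature_ids,
        "weight": weights.w,
        "selected": [j in chosen for j in range(len(weights.w))],
    }).to_csv(path, index=False)
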