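"""Sparse generalized canonical correlation analysis (SGCCA).

Multi-block extension of CCA: for blocks ``X_1 .. X_K`` (samples shared,
features per block) find per-block weight vectors ``a_k`` maximizing

    sum_{k<l} c_kl * g(cov(X_k a_k, X_l a_l))

subject to ``||a_k||_2 = 1`` and a per-block sparsity constraint (an L1
bound or a keep-count of nonzero weights). ``C = (c_kl)`` is the design
matrix connecting blocks; ``g`` is the identity (horst scheme) or the
absolute value (centroid scheme, sign-robust). Optimization is cyclic
block-coordinate ascent: the update for block k linearizes the objective at
the current point, and the constrained maximizer of that linear minorant is
the (soft- or hard-)thresholded, renormalized gradient, so the objective is
monotone non-decreasing. Components beyond the first are obtained in
canonical mode: each block is deflated by the projection onto its own
component, treating blocks symmetrically.

Model quality is reported as AVE (average variance explained): the mean
squared correlation between a block's features and one of its components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .blocks import ConfigurationError, DataError, OmicsBlock, check_shared_samples

Sparsity = None | int | float | tuple


@dataclass
class SgccaConfig:
    """Settings for an SGCCA fit.

    sparsity maps block label -> constraint, where a constraint is an int
    keep-count, a float L1 bound, None (unconstrained), or a per-component
    sequence of those.
    """

    n_components: int = 2
    design: np.ndarray | None = None
    sparsity: dict[str, Sparsity] | None = None
    scheme: str = "centroid"
    tol: float = 1e-8
    max_iter: int = 1000
    init: str = "shared"
    n_starts: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ConfigurationError("n_components must be >= 1")
        if self.scheme not in ("horst", "centroid"):
            raise ConfigurationError("scheme must be 'horst' or 'centroid'")
        if self.init not in ("shared", "svd"):
            raise ConfigurationError("init must be 'shared' or 'svd'")
        if self.n_starts < 1:
            raise ConfigurationError("n_starts must be >= 1")
        if self.design is not None:
            C = np.asarray(self.design, dtype=float)
            if C.ndim != 2 or C.shape[0] != C.shape[1]:
                raise ConfigurationError("design must be a square matrix")
            if not np.allclose(C, C.T):
                raise ConfigurationError("design must be symmetric")
            if np.any(np.diag(C) != 0):
                raise ConfigurationError("design must have zero diagonal")
            if C.min() < 0 or C.max() > 1:
                raise ConfigurationError("design entries must lie in [0, 1]")

    def sparsity_for(self, label: str, component: int) -> Sparsity:
        if self.sparsity is None:
            return None
        setting = self.sparsity.get(label)
        if isinstance(setting, (list, tuple)):
            return setting[min(component, len(setting) - 1)]
        return setting


@dataclass
class SgccaModel:
    """Fitted SGCCA solution."""

    labels: list[str]
    weights: dict[str, pd.DataFrame]
    components: dict[str, pd.DataFrame]
    objective_trace: list[list[float]]
    ave: dict[str, list[float]]
    scaled_blocks: dict[str, pd.DataFrame]
    config: SgccaConfig
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return next(iter(self.weights.values())).shape[1]

    def selected_features(self, label: str | None = None) -> dict[str, list[str]]:
        """Features with a nonzero weight on at least one component."""
        labels = [label] if label else self.labels
        out = {}
        for lab in labels:
            W = self.weights[lab]
            out[lab] = [str(f) for f in W.index[(W != 0).any(axis=1)]]
        return out

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "weights": {k: v.to_dict(orient="index") for k, v in self.weights.items()},
            "ave": self.ave,
            "objective_trace": self.objective_trace,
            "n_components": self.n_components,
            "scheme": self.config.scheme,
            "warnings": self.warnings_,
        }


def scale_blocks(blocks: dict[str, OmicsBlock]) -> dict[str, pd.DataFrame]:
    """Standardize features (mean 0, SD 1) and divide each block by sqrt(p).

    The per-block division balances blocks of very different widths so no
    single omics layer dominates the covariance objective.
    """
    out = {}
    for label, block in blocks.items():
        X = block.values
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [block.feature_names[j] for j in np.flatnonzero(sd == 0)]
            raise DataError(f"zero-variance features in {label} block: {bad}")
        Z = (X - X.mean(axis=0)) / sd
        Z /= np.sqrt(X.shape[1])
        out[label] = pd.DataFrame(Z, index=block.data.index, columns=block.data.columns)
    return out


def soft_threshold_sparsify(w: np.ndarray, bound: Sparsity = None) -> np.ndarray:
    """Sparsify a weight vector and renormalize to unit L2 norm.

    int bound: keep that many largest-|w| entries (hard threshold; ties
    keep the earlier feature). float bound: soft-threshold with the smallest
    lambda making the L1 norm of the renormalized vector <= bound, found by
    bisection. None: plain L2 normalization.
    """
    w = np.asarray(w, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("cannot sparsify a zero vector")
    if bound is None:
        return w / norm
    if isinstance(bound, (int, np.integer)) and not isinstance(bound, bool):
        m = int(bound)
        if m < 1:
            raise ConfigurationError("keep-count must be >= 1")
        order = np.argsort(-np.abs(w), kind="stable")  # stable: earlier index wins ties
        out = np.zeros_like(w)
        keep = order[:m]
        out[keep] = w[keep]
        nrm = np.linalg.norm(out)
        if nrm == 0:
            raise ValueError("keep-count bound leaves only zero weights")
        return out / nrm
    s = float(bound)
    if s < 1:
        raise ConfigurationError("an L1 bound below 1 is infeasible for a unit vector")

    def _project(lam: float) -> np.ndarray:
        v = np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else v

    if np.abs(w / norm).sum() <= s:
        return w / norm
    # L1 of the renormalized soft-thresholded vector decreases in lambda, so
    # feasibility (L1 <= s) is monotone: bisect for the smallest feasible lambda
    lo, hi = 0.0, float(np.max(np.abs(w))) * (1 - 1e-12)
    v_hi = _project(hi)
    if np.linalg.norm(v_hi) == 0 or np.abs(v_hi).sum() > s:
        raise ValueError("L1 bound so tight that all weights vanish")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        v = _project(mid)
        if np.linalg.norm(v) > 0 and np.abs(v).sum() <= s:
            hi = mid
        else:
            lo = mid
    return _project(hi)


def _g(x: np.ndarray, scheme: str) -> np.ndarray:
    return np.abs(x) if scheme == "centroid" else x


def _g_prime(x: np.ndarray, scheme: str) -> np.ndarray:
    return np.sign(x) if scheme == "centroid" else np.ones_like(x)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    # deterministic sign: largest-magnitude entry positive
    s = np.sign(v[np.argmax(np.abs(v))])
    return v * (s if s != 0 else 1.0)


def _init_weights(
    X_list: Sequence[np.ndarray],
    config: SgccaConfig,
    rng: np.random.Generator,
    start: int,
) -> list[np.ndarray]:
    """Starting weight vectors for one optimization start.

    Start 0 is deterministic: either the leading shared direction of the
    concatenated blocks projected back into each block ('shared', which
    points every block at the same dominant cross-block axis) or each
    block's own first right singular vector ('svd'). Further starts are
    random unit vectors from the seeded generator.
    """
    if start == 0 and config.init == "shared":
        concat = np.hstack(X_list)
        gram = concat @ concat.T
        eigvals, eigvecs = np.linalg.eigh(gram)
        u = _fix_sign(eigvecs[:, -1])
        a = [X.T @ u for X in X_list]
    elif start == 0:
        a = []
        for X in X_list:
            _, _, vt = np.linalg.svd(X, full_matrices=False)
            a.append(_fix_sign(vt[0]))
    else:
        a = [rng.standard_normal(X.shape[1]) for X in X_list]
    out = []
    for X, ak in zip(X_list, a):
        nrm = np.linalg.norm(ak)
        ak = ak / nrm if nrm > 0 else np.ones(X.shape[1]) / np.sqrt(X.shape[1])
        out.append(ak)
    return out


@dataclass
class ComponentFit:
    weights: list[np.ndarray]
    scores: list[np.ndarray]
    objective_trace: list[float]
    converged: bool


def fit_component(
    X_list: Sequence[np.ndarray],
    config: SgccaConfig,
    bounds: Sequence[Sparsity] | None = None,
) -> ComponentFit:
    """Fit one SGCCA component on (already scaled, possibly deflated) blocks.

    Cyclic block updates: the inner gradient for block k is
    ``sum_l c_kl g'(cov_kl) X_k^T t_l / (n-1)``, which is then thresholded
    and renormalized. Iterates until the objective changes by less than
    ``config.tol`` or ``config.max_iter`` sweeps.
    """
    K = len(X_list)
    n = X_list[0].shape[0]
    C = (
        np.asarray(config.design, dtype=float)
        if config.design is not None
        else 1.0 - np.eye(K)
    )
    if C.shape != (K, K):
        raise ConfigurationError(f"design matrix shape {C.shape} != ({K}, {K})")
    if bounds is None:
        bounds = [None] * K
    rng = np.random.default_rng(config.seed)

    def objective(t: list[np.ndarray]) -> float:
        total = 0.0
        for k in range(K):
            for l in range(k + 1, K):
                if C[k, l]:
                    cov = float(t[k] @ t[l]) / (n - 1)
                    total += C[k, l] * float(_g(np.asarray(cov), config.scheme))
        return total

    best: ComponentFit | None = None
    for start in range(config.n_starts):
        a = [
            soft_threshold_sparsify(ak, b)
            for ak, b in zip(_init_weights(X_list, config, rng, start), bounds)
        ]
        t = [X @ ak for X, ak in zip(X_list, a)]
        trace = [objective(t)]
        converged = False
        for _ in range(config.max_iter):
            for k in range(K):
                grad = np.zeros(X_list[k].shape[1])
                for l in range(K):
                    if l == k or not C[k, l]:
                        continue
                    cov = float(t[k] @ t[l]) / (n - 1)
                    gp = float(_g_prime(np.asarray(cov), config.scheme))
                    if gp:
                        grad += C[k, l] * gp * (X_list[k].T @ t[l]) / (n - 1)
                if np.linalg.norm(grad) > 0:
                    a[k] = soft_threshold_sparsify(grad, bounds[k])
                    t[k] = X_list[k] @ a[k]
            trace.append(objective(t))
            if abs(trace[-1] - trace[-2]) < config.tol:
                converged = True
                break
        fit = ComponentFit(
            weights=a, scores=t, objective_trace=trace, converged=converged
        )
        if best is None or fit.objective_trace[-1] > best.objective_trace[-1]:
            best = fit
    assert best is not None
    return best


def deflate_blocks(
    X_list: Sequence[np.ndarray], scores: Sequence[np.ndarray]
) -> list[np.ndarray]:
    """Canonical-mode deflation: each block loses its own component.

    ``X_k <- X_k - t_k (t_k^T t_k)^{-1} t_k^T X_k``; later components of the
    same block are orthogonal to ``t_k``.
    """
    out = []
    for X, tk in zip(X_list, scores):
        ss = float(tk @ tk)
        if ss == 0:
            out.append(X.copy())
        else:
            out.append(X - np.outer(tk, (tk @ X) / ss))
    return out


def compute_ave(X: np.ndarray, t: np.ndarray) -> float:
    """Average variance explained: mean over features of cor^2(feature, t)."""
    t_sd = t.std(ddof=1)
    if t_sd == 0:
        raise DataError("component has zero variance")
    tc = (t - t.mean()) / t_sd
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    cors = np.zeros(X.shape[1])
    ok = sd > 0
    cors[ok] = (Xc[:, ok].T @ tc) / ((X.shape[0] - 1) * sd[ok])
    return float(np.mean(cors**2))


def fit_sgcca(blocks: dict[str, OmicsBlock], config: SgccaConfig | None = None) -> SgccaModel:
    """Fit the full multi-component SGCCA model on preprocessed blocks."""
    config = config or SgccaConfig()
    check_shared_samples(blocks)
    labels = list(blocks)
    scaled = scale_blocks(blocks)
    X_cur = [scaled[lab].to_numpy() for lab in labels]
    X_orig = [scaled[lab].to_numpy() for lab in labels]
    n = X_cur[0].shape[0]

    H = config.n_components
    all_weights: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    all_scores: dict[str, list[np.ndarray]] = {lab: [] for lab in labels}
    traces: list[list[float]] = []
    warn_list: list[str] = []

    for h in range(H):
        bounds = [config.sparsity_for(lab, h) for lab in labels]
        fit = fit_component(X_cur, config, bounds)
        if not fit.converged:
            msg = f"component {h + 1} did not converge in {config.max_iter} iterations"
            warn_list.append(msg)
            warnings.warn(msg, stacklevel=2)
        for k, lab in enumerate(labels):
            all_weights[lab].append(fit.weights[k])
            all_scores[lab].append(fit.scores[k])
        traces.append(fit.objective_trace)
        if h < H - 1:
            X_cur = deflate_blocks(X_cur, fit.scores)

    sample_index = blocks[labels[0]].data.index
    comp_names = [f"comp_{h + 1}" for h in range(H)]
    weights = {
        lab: pd.DataFrame(
            np.column_stack(all_weights[lab]),
            index=blocks[lab].data.columns,
            columns=comp_names,
        )
        for lab in labels
    }
    components = {
        lab: pd.DataFrame(
            np.column_stack(all_scores[lab]), index=sample_index, columns=comp_names
        )
        for lab in labels
    }
    ave = {
        lab: [compute_ave(X_orig[k], all_scores[lab][h]) for h in range(H)]
        for k, lab in enumerate(labels)
    }
    return SgccaModel(
        labels=labels,
        weights=weights,
        components=components,
        objective_trace=traces,
        ave=ave,
        scaled_blocks=scaled,
        config=config,
        warnings_=warn_list,
    )
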