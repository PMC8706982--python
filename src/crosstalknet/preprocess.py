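"""Per-block preprocessing.

Metabolite blocks: exclusion of features with too many missing cells,
iterative random-forest imputation of the remainder, then a rank-based
inverse normal transformation so every feature is approximately standard
normal. Genus counts: prevalence filtering, then the centered log-ratio
(CLR) transform to take compositions into unconstrained Euclidean space.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor

from .blocks import ConfigurationError, DataError, OmicsBlock

LOG_FILTER_MISSING = "filter_by_missingness"
LOG_IMPUTE = "impute_missing"
LOG_RANK_INT = "rank_inverse_normal"
LOG_PREVALENCE = "prevalence_filter"
LOG_CLR = "clr_transform"


def _guard_rerun(block: OmicsBlock, op: str) -> None:
    if block.has_transform(op):
        raise DataError(f"{op} already applied to this {block.block_label} block")


def filter_by_missingness(
    block: OmicsBlock, max_frac: float = 0.20
) -> tuple[OmicsBlock, list[str]]:
    """Drop features whose missing fraction exceeds ``max_frac``.

    Returns the filtered block (feature order preserved) and the list of
    removed feature names.
    """
    if not 0 <= max_frac <= 1:
        raise ConfigurationError("max_frac must be in [0, 1]")
    if block.n_samples < 1:
        raise DataError("block has no samples")
    _guard_rerun(block, LOG_FILTER_MISSING)
    frac = block.missing_fraction()
    removed = [str(c) for c in block.data.columns[frac > max_frac]]
    kept = block.data.loc[:, frac <= max_frac]
    return block.with_data(kept, LOG_FILTER_MISSING), removed


def impute_missing(
    block: OmicsBlock,
    seed: int = 0,
    n_estimators: int = 100,
    max_iter: int = 10,
    tol: float = 1e-3,
) -> OmicsBlock:
    """Iterative random-forest imputation of missing cells.

    Each feature with missing values is regressed on all other features with
    a random forest (``sqrt(p)`` candidate features per split, as the
    canonical forest imputer does), starting from feature-mean fill and
    sweeping features in order of increasing missingness until the relative
    change in the imputed values drops below ``tol`` or ``max_iter`` sweeps.
    Observed cells are never altered; the result is deterministic for a
    fixed seed.
    """
    _guard_rerun(block, LOG_IMPUTE)
    data = block.data.copy()
    mask = data.isna()
    fully_missing = [str(c) for c in data.columns[mask.all(axis=0)]]
    if fully_missing:
        raise DataError(f"features entirely missing (filter first): {fully_missing}")
    if not mask.any().any():
        return block.with_data(data, LOG_IMPUTE)

    X = data.to_numpy(dtype=float)
    M = mask.to_numpy()
    col_means = np.nanmean(X, axis=0)
    X = np.where(M, col_means, X)

    order = np.argsort(M.sum(axis=0), kind="stable")
    targets = [j for j in order if M[:, j].any()]
    rng = np.random.default_rng(seed)

    prev = X[M].copy()
    for _ in range(max_iter):
        for j in targets:
            obs = ~M[:, j]
            others = np.delete(np.arange(X.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(X[np.ix_(obs, others)], X[obs, j])
            X[M[:, j], j] = rf.predict(X[np.ix_(M[:, j], others)])
        cur = X[M]
        denom = float(np.sum(cur**2)) or 1.0
        change = float(np.sum((cur - prev) ** 2)) / denom
        prev = cur.copy()
        if change < tol:
            break

    out = pd.DataFrame(X, index=data.index, columns=data.columns)
    out[~mask] = data[~mask]  # observed cells bit-identical
    return block.with_data(out, LOG_IMPUTE)


def rank_inverse_normal(block: OmicsBlock, offset: float = 3.0 / 8.0) -> OmicsBlock:
    """Rank-based inverse normal transform, feature by feature.

    value <- Phi^{-1}((rank - c) / (n - 2c + 1)) with average ranks for ties
    and the Blom offset c = 3/8 by default. The output is monotone in the
    input, approximately N(0, 1) per feature.
    """
    _guard_rerun(block, LOG_RANK_INT)
    if block.data.isna().any().any():
        raise DataError("missing cells present; impute before transforming")
    n = block.n_samples
    X = block.values
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            warnings.warn(
                f"constant feature {block.feature_names[j]!r} maps to all zeros "
                "under rank inverse normal transformation",
                stacklevel=2,
            )
        ranks = rankdata(col, method="average")
        out[:, j] = ndtri((ranks - offset) / (n - 2 * offset + 1))
    data = pd.DataFrame(out, index=block.data.index, columns=block.data.columns)
    return block.with_data(data, LOG_RANK_INT)


def prevalence_filter(block: OmicsBlock, min_prevalence: float = 0.10) -> OmicsBlock:
    """Drop genera observed (count > 0) in fewer than ``min_prevalence * n`` samples."""
    if not 0 <= min_prevalence <= 1:
        raise ConfigurationError("min_prevalence must be in [0, 1]")
    _guard_rerun(block, LOG_PREVALENCE)
    if block.data.isna().any().any():
        raise DataError("count block must have no missing cells")
    present = (block.data > 0).sum(axis=0)
    keep = present >= min_prevalence * block.n_samples
    return block.with_data(block.data.loc[:, keep], LOG_PREVALENCE)


def clr_transform(block: OmicsBlock, pseudocount: float = 1.0) -> OmicsBlock:
    """Centered log-ratio transform of a count block.

    Adds ``pseudocount`` to every count, then maps each sample to
    ``ln x_j - mean_j ln x_j``; each output row sums to zero.
    """
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be nonnegative")
    _guard_rerun(block, LOG_CLR)
    X = block.values
    if np.isnan(X).any():
        raise DataError("count block must have no missing cells")
    if (X < 0).any():
        raise DataError("negative counts are not valid compositions")
    logs = np.log(X + pseudocount)
    out = logs - logs.mean(axis=1, keepdims=True)
    data = pd.DataFrame(out, index=block.data.index, columns=block.data.columns)
    return block.with_data(data, LOG_CLR)


def preprocess_metabolite_block(
    block: OmicsBlock,
    seed: int = 0,
    max_frac: float = 0.20,
    n_estimators: int = 100,
) -> tuple[OmicsBlock, dict]:
    """Full metabolite pipeline: missingness filter, RF imputation, rank-INT.

    Returns the processed block and a report of removed features and
    per-feature missingness.
    """
    if block.block_label == "genus":
        raise ConfigurationError("metabolite preprocessing applied to a genus block")
    frac = block.missing_fraction()
    filtered, removed = filter_by_missingness(block, max_frac=max_frac)
    imputed = impute_missing(filtered, seed=seed, n_estimators=n_estimators)
    transformed = rank_inverse_normal(imputed)
    report = {
        "block": block.block_label,
        "n_features_in": block.n_features,
        "n_features_out": transformed.n_features,
        "removed_features": removed,
        "max_missing_frac": max_frac,
        "missing_fraction": {str(k): float(v) for k, v in frac.items() if v > 0},
    }
    return transformed, report


def preprocess_genus_block(
    block: OmicsBlock,
    min_prevalence: float = 0.10,
    pseudocount: float = 1.0,
) -> tuple[OmicsBlock, dict]:
    """Genus pipeline: prevalence filter then CLR transform."""
    if block.block_label != "genus":
        raise ConfigurationError("genus preprocessing applied to a non-genus block")
    filtered = prevalence_filter(block, min_prevalence=min_prevalence)
    removed = [f for f in block.feature_names if f not in set(filtered.feature_names)]
    transformed = clr_transform(filtered, pseudocount=pseudocount)
    report = {
        "block": "genus",
        "n_features_in": block.n_features,
        "n_features_out": transformed.n_features,
        "removed_features": removed,
        "min_prevalence": min_prevalence,
        "pseudocount": pseudocount,
    }
    return transformed, report
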