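"""Score-outcome associations and member-outcome partial correlations.

Each multi-omics score is regressed against each cardiometabolic outcome by
OLS adjusting for age, sex and BMI; the score's effect (per 1-SD increase),
its SE and raw p-value are reported with Benjamini-Hochberg adjustment
within each score's family of outcomes. Individual cluster members are
related to outcomes by Pearson partial correlation (residual-on-residual)
with the same covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .blocks import DataError, OmicsBlock

COVARIATES = ("age", "sex", "BMI")


@dataclass
class AssociationTable:
    """Per (score, outcome) OLS effect of the score, covariate-adjusted."""

    table: pd.DataFrame  # columns: score, outcome, n, beta, se, p, p_adj, flag
    covariates: tuple[str, ...] = COVARIATES

    def for_score(self, score: str) -> pd.DataFrame:
        return self.table[self.table["score"] == score].reset_index(drop=True)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adj"] < alpha].reset_index(drop=True)


@dataclass
class PartialCorrelationMatrix:
    """Cluster-member x outcome partial correlations with adjusted p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    covariates: tuple[str, ...] = COVARIATES


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adjusted p_(i) = min_{j >= i} min(1, p_(j) * m / j), mapped back to the
    input order; m defaults to the number of p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if n == 0:
        return p.copy()
    m = n if m is None else int(m)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(n)
    out[order] = adjusted
    return out


def _complete_cases(*frames: pd.DataFrame) -> pd.Index:
    joined = pd.concat(frames, axis=1)
    return joined.dropna().index


def fit_score_associations(
    scores: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
    fdr_family: str = "per_score",
) -> AssociationTable:
    """OLS of each outcome on each score, adjusting for age, sex and BMI.

    Listwise deletion on outcome + covariates; BH adjustment within each
    score's family of outcomes (``fdr_family='global'`` pools everything).
    Constant outcomes are flagged, not fitted.
    """
    if fdr_family not in ("per_score", "global"):
        raise ValueError("fdr_family must be 'per_score' or 'global'")
    cov = covariates[list(COVARIATES)]
    rows = []
    for score_name in scores.columns:
        for outcome_name in outcomes.columns:
            idx = _complete_cases(
                scores[[score_name]], outcomes[[outcome_name]], cov
            )
            y = outcomes.loc[idx, outcome_name].to_numpy(dtype=float)
            row = {"score": score_name, "outcome": outcome_name, "n": len(idx)}
            if np.ptp(y) == 0:
                row.update(beta=np.nan, se=np.nan, p=np.nan, flag="constant_outcome")
            else:
                X = sm.add_constant(
                    pd.concat([scores.loc[idx, [score_name]], cov.loc[idx]], axis=1)
                )
                fit = sm.OLS(y, X.astype(float)).fit()
                se = fit.bse[score_name]
                row.update(
                    beta=float(fit.params[score_name]),
                    se=float(se),
                    p=float(fit.pvalues[score_name]),
                    flag="degenerate_se" if se < 1e-12 else "",
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    table["p_adj"] = np.nan
    if fdr_family == "per_score":
        for score_name in scores.columns:
            sel = (table["score"] == score_name) & table["p"].notna()
            table.loc[sel, "p_adj"] = bh_adjust(table.loc[sel, "p"].to_numpy())
    else:
        sel = table["p"].notna()
        table.loc[sel, "p_adj"] = bh_adjust(table.loc[sel, "p"].to_numpy())
    return AssociationTable(table=table)


def _residualize(values: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, values, rcond=None)
    return values - Z @ beta


def partial_correlations(
    members: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
) -> PartialCorrelationMatrix:
    """Pearson partial correlation of each member with each outcome.

    Both variables are residualized on an intercept plus age, sex and BMI;
    r is the Pearson correlation of the residuals, p comes from
    ``t = r * sqrt((n - 2 - k) / (1 - r^2))`` with k covariates, and the
    whole matrix is BH-adjusted.
    """
    cov = covariates[list(COVARIATES)]
    idx = _complete_cases(members, outcomes, cov)
    if len(idx) <= len(COVARIATES) + 2:
        raise DataError("too few complete cases for partial correlation")
    Z = np.column_stack([np.ones(len(idx)), cov.loc[idx].to_numpy(dtype=float)])
    M_raw = members.loc[idx].to_numpy(dtype=float)
    O_raw = outcomes.loc[idx].to_numpy(dtype=float)
    Mres = _residualize(M_raw, Z)
    Ores = _residualize(O_raw, Z)
    # a variable explained exactly by the covariates has residual 0, not
    # floating-point dust: clip residual columns that are numerically null
    for res, raw in ((Mres, M_raw), (Ores, O_raw)):
        scale = np.linalg.norm(raw - raw.mean(axis=0), axis=0)
        null = np.linalg.norm(res, axis=0) <= 1e-10 * np.maximum(scale, 1.0)
        res[:, null] = 0.0

    def _unit(R: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(R, axis=0)
        norms[norms == 0] = np.inf
        return R / norms

    r = np.clip(_unit(Mres).T @ _unit(Ores), -1.0, 1.0)
    n, k = len(idx), len(COVARIATES)
    df = n - 2 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p_adj = bh_adjust(p.ravel()).reshape(p.shape)
    mk = (members.columns, outcomes.columns)
    return PartialCorrelationMatrix(
        r=pd.DataFrame(r, index=mk[0], columns=mk[1]),
        p=pd.DataFrame(p, index=mk[0], columns=mk[1]),
        p_adj=pd.DataFrame(p_adj, index=mk[0], columns=mk[1]),
    )


def member_values(
    network_clusters: dict, processed_blocks: dict[str, OmicsBlock]
) -> pd.DataFrame:
    """Post-transformation values of every cluster member, one column each."""
    sample_ids = next(iter(processed_blocks.values())).data.index
    cols = {}
    for (feat, blk) in network_clusters:
        if blk not in processed_blocks or feat not in processed_blocks[blk].data.columns:
            raise DataError(f"cluster member {blk}:{feat} not found in processed blocks")
        cols[f"{blk}:{feat}"] = processed_blocks[blk].data[feat]
    return pd.DataFrame(cols, index=sample_ids)


def plot_partial_correlation_heatmap(pcm: PartialCorrelationMatrix, path, alpha: float = 0.05):
    """Heatmap of partial r with asterisks where the adjusted p is below alpha."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = pcm.r
    fig, ax = plt.subplots(
        figsize=(1 + 0.5 * r.shape[1], 1 + 0.35 * r.shape[0])
    )
    im = ax.imshow(r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(r.shape[1]), r.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(r.shape[0]), r.index, fontsize=7)
    for i in range(r.shape[0]):
        for j in range(r.shape[1]):
            if pcm.p_adj.iloc[i, j] < alpha:
                ax.text(j, i, "*", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="partial r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
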