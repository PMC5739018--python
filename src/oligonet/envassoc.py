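"""Eigengene-environment association: redundancy analysis and Spearman/FDR.

Module eigengenes summarise each guild's collective trajectory; redundancy
analysis (RDA) extracts the part of the eigengene matrix explained by a
linear model on standardized physicochemical variables and ordinates it
(an indirect gradient analysis, since the ordination is of eigengenes
rather than raw abundances).  Pairwise Spearman correlations between
eigengenes and variables, with Benjamini-Hochberg control of the false
discovery rate, identify each module's seasonal driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def zscore(env: pd.DataFrame) -> pd.DataFrame:
    """Standardize every column to mean 0, SD 1 (sample SD, ddof=1)."""
    num = env.select_dtypes(include=[np.number])
    sd = num.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant column(s): {bad}")
    return (num - num.mean()) / sd


@dataclass
class RDAResult:
    site_scores: pd.DataFrame       # samples x constrained axes
    response_scores: pd.DataFrame   # eigengenes x axes
    env_scores: pd.DataFrame        # variables x axes (correlations with axes)
    proportion_explained: float
    axis_eigenvalues: np.ndarray


def rda(me_matrix: pd.DataFrame, X: pd.DataFrame) -> RDAResult:
    """Redundancy analysis of eigengenes on standardized predictors.

    Fits Y_hat = X (X'X)^-1 X' Y on the column-centered response, then
    ordinates Y_hat by PCA: constrained axes are the principal components
    of the fitted values, site scores their sample projections, and the
    proportion explained is tr(Y_hat'Y_hat) / tr(Y'Y).  Collinear predictor
    columns are dropped with a warning.
    """
    if not me_matrix.index.equals(X.index):
        raise ValueError("samples of eigengene matrix and predictors must align")
    n = len(me_matrix)
    Xm = X.to_numpy(dtype=float)
    if n <= Xm.shape[1]:
        raise ValueError("need more samples than predictor variables")

    # drop collinear columns (greedy, keeps the earliest independent set)
    keep: list[int] = []
    for j in range(Xm.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(Xm[:, cand]) == len(cand):
            keep.append(j)
    if len(keep) < Xm.shape[1]:
        dropped = [c for i, c in enumerate(X.columns) if i not in keep]
        warnings.warn(f"dropping collinear predictor(s): {dropped}")
    Xk = Xm[:, keep]
    xcols = [X.columns[i] for i in keep]

    Y = me_matrix.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0, keepdims=True)
    Xc = Xk - Xk.mean(axis=0, keepdims=True)
    B, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    Yhat = Xc @ B

    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    n_axes = min(int(np.sum(s > 1e-10 * max(s[0], 1e-300))), len(xcols), Y.shape[1])
    n_axes = max(n_axes, 1)
    axes = [f"RDA{k + 1}" for k in range(n_axes)]
    site = U[:, :n_axes] * s[:n_axes]
    total = (Y**2).sum()
    prop = float((Yhat**2).sum() / total) if total > 0 else 0.0

    env_sc = np.zeros((Xc.shape[1], n_axes))
    for k in range(n_axes):
        if site[:, k].std() > 0:
            env_sc[:, k] = [
                np.corrcoef(Xc[:, j], site[:, k])[0, 1] if Xc[:, j].std() > 0 else 0.0
                for j in range(Xc.shape[1])
            ]
    return RDAResult(
        site_scores=pd.DataFrame(site, index=me_matrix.index, columns=axes),
        response_scores=pd.DataFrame(
            Vt[:n_axes].T, index=me_matrix.columns, columns=axes
        ),
        env_scores=pd.DataFrame(env_sc, index=xcols, columns=axes),
        proportion_explained=prop,
        axis_eigenvalues=(s[:n_axes] ** 2) / (n - 1),
    )


def spearman_bh(
    mes: pd.DataFrame, env: pd.DataFrame, per_me_families: bool = False
) -> pd.DataFrame:
    """Spearman rho and BH-adjusted p for every (eigengene, variable) pair.

    Pairs with a constant series get NaN rho and are excluded from the
    adjustment.  By default all pairs form one BH family; with
    ``per_me_families`` the correction is applied within each eigengene.
    """
    if not mes.index.equals(env.index):
        raise ValueError("eigengene and environment samples must align")
    if len(mes) < 4:
        raise ValueError("need at least 4 samples per pair")
    rows = []
    for me_name in mes.columns:
        for var in env.columns:
            a = mes[me_name].to_numpy(dtype=float)
            b = env[var].to_numpy(dtype=float)
            if np.std(a) == 0 or np.std(b) == 0:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(a, b)
            rows.append({"me": me_name, "variable": var, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    if per_me_families:
        for me_name, sub in out.groupby("me"):
            ok = sub["p"].notna()
            if ok.any():
                out.loc[sub.index[ok], "p_adj"] = multipletests(
                    sub.loc[ok, "p"], method="fdr_bh"
                )[1]
    else:
        ok = out["p"].notna()
        if ok.any():
            out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
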