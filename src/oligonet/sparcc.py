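"""Compositionality-robust correlation inference for count tables.

Relative abundances are compositional: closure to a unit sum induces
spurious (mostly negative) correlations between proportions, especially
when diversity is low.  The estimator implemented here infers correlations
between the unobserved *basis* (absolute) abundances from the variances of
pairwise log-ratios.  Writing t_ij = Var ln(x_i/x_j) and assuming the
correlation matrix is sparse, the basis variances omega solve the linear
system

    t_i = sum_j t_ij  =  (D - 2) * omega_i + sum_j omega_j,

and the basis correlations follow from
rho_ij = (omega_i + omega_j - t_ij) / (2 sqrt(omega_i omega_j)).  Strongly
correlated pairs violate the sparsity assumption, so the strongest pair is
iteratively excluded from the system and the variances re-solved.
Sampling noise in the fractions is integrated out by averaging over
posterior Dirichlet draws, and significance is assessed with two-sided
pseudo-p-values from column-permutation bootstraps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CorrelationNetwork:
    """Symmetric correlation estimate with optional pseudo-p-values."""

    rho: pd.DataFrame
    basis_variances: np.ndarray = None
    pvals: pd.DataFrame = None

    def edge_list(self) -> pd.DataFrame:
        """Long-format upper-triangle edge list (i, j, rho[, p])."""
        ids = self.rho.columns
        rows = []
        r = self.rho.to_numpy()
        p = self.pvals.to_numpy() if self.pvals is not None else None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                row = {"i": ids[i], "j": ids[j], "rho": r[i, j]}
                if p is not None:
                    row["p"] = p[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def _as_matrix(counts):
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), counts.columns
    arr = np.asarray(counts, dtype=float)
    return arr, pd.RangeIndex(arr.shape[1])


def dirichlet_fractions(counts, seed=0) -> np.ndarray:
    """Posterior fractions: one Dirichlet(counts_row + 1) draw per sample."""
    x, _ = _as_matrix(counts)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("every sample needs a positive total count")
    rng = np.random.default_rng(seed)
    return np.vstack([rng.dirichlet(row + 1.0) for row in x])


def _logratio_variances(fracs: np.ndarray) -> np.ndarray:
    """T_ij = Var over samples of ln(f_i / f_j); zero diagonal."""
    logf = np.log(fracs)
    C = np.cov(logf, rowvar=False)
    v = np.diag(C)
    T = v[:, None] + v[None, :] - 2.0 * C
    np.fill_diagonal(T, 0.0)
    return np.maximum(T, 0.0)


def basis_correlations(
    fractions,
    exclusion_iterations: int = 10,
    exclusion_threshold: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Basis correlations and variances from one fraction matrix.

    Returns ``(rho, omega)``.  Components excluded from ``D - 3`` or more
    pairs (or acquiring a non-positive variance estimate) are flagged: their
    off-diagonal correlations are set to 0.
    """
    fracs = np.asarray(fractions, dtype=float)
    n, D = fracs.shape
    if D < 4:
        raise ValueError("need at least 4 components for the sparse system")
    if n < 3:
        raise ValueError("need at least 3 samples")

    T = _logratio_variances(fracs)
    M = np.ones((D, D)) + np.diag(np.full(D, D - 2.0))
    t = T.sum(axis=1)
    excluded = np.zeros((D, D), dtype=bool)
    excl_count = np.zeros(D, dtype=int)
    dropped = np.zeros(D, dtype=bool)

    def solve() -> tuple[np.ndarray, np.ndarray]:
        omega = np.linalg.solve(M, t)
        bad = omega <= 0
        if bad.any() and not dropped[bad].all():
            warnings.warn(
                "non-positive basis variance after exclusion; "
                "flagging component(s) and zeroing their correlations"
            )
            dropped[bad] = True
        om = np.where(omega > 0, omega, np.nan)
        denom = 2.0 * np.sqrt(np.outer(om, om))
        with np.errstate(invalid="ignore"):
            rho = (om[:, None] + om[None, :] - T) / denom
        rho = np.clip(np.nan_to_num(rho, nan=0.0), -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        rho[dropped, :] = 0.0
        rho[:, dropped] = 0.0
        np.fill_diagonal(rho, 1.0)
        return rho, omega

    rho, omega = solve()
    for _ in range(exclusion_iterations):
        absr = np.abs(rho)
        absr[np.tril_indices(D)] = 0.0
        absr[excluded] = 0.0
        absr[dropped, :] = 0.0
        absr[:, dropped] = 0.0
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= exclusion_threshold:
            break
        # remove pair (i, j) from the sparse system
        excluded[i, j] = excluded[j, i] = True
        M[i, j] -= 1.0
        M[j, i] -= 1.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        t[i] -= T[i, j]
        t[j] -= T[i, j]
        for k in (i, j):
            excl_count[k] += 1
            if excl_count[k] >= D - 3 and not dropped[k]:
                dropped[k] = True
        rho, omega = solve()
    return rho, omega


def sparcc(
    counts,
    n_dirichlet: int = 10,
    seed: int = 0,
    exclusion_iterations: int = 10,
    exclusion_threshold: float = 0.1,
) -> CorrelationNetwork:
    """Average basis correlations over posterior Dirichlet draws."""
    x, ids = _as_matrix(counts)
    rhos = []
    omegas = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_dirichlet):
        fracs = dirichlet_fractions(x, seed=child)
        r, w = basis_correlations(
            fracs,
            exclusion_iterations=exclusion_iterations,
            exclusion_threshold=exclusion_threshold,
        )
        rhos.append(r)
        omegas.append(w)
    rho = np.mean(rhos, axis=0)
    np.fill_diagonal(rho, 1.0)
    return CorrelationNetwork(
        rho=pd.DataFrame(rho, index=ids, columns=ids),
        basis_variances=np.mean(omegas, axis=0),
    )


def bootstrap_pvalues(
    counts,
    n_boot: int = 100,
    seed: int = 0,
    n_dirichlet: int = 10,
    observed: CorrelationNetwork = None,
    add_one: bool = True,
) -> pd.DataFrame:
    """Two-sided pseudo-p-values from column-permutation bootstraps.

    Null data sets permute each component's counts independently across
    samples, destroying inter-component association while preserving the
    marginals; each is run through the full Dirichlet-averaged estimator.
    p_ij = (1 + #{null |rho| >= |rho_obs|}) / (n_boot + 1) by default; with
    ``add_one=False`` the plain #exceedances / n_boot convention is used.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    x, ids = _as_matrix(counts)
    n, D = x.shape
    ss = np.random.SeedSequence([seed, 1])
    if observed is None:
        observed = sparcc(x, n_dirichlet=n_dirichlet, seed=np.random.SeedSequence([seed, 0]).generate_state(1)[0])
    obs = np.abs(observed.rho.to_numpy())
    exceed = np.zeros((D, D))
    perm_rng = np.random.default_rng([seed, 2])
    for child in ss.spawn(n_boot):
        null = np.column_stack([perm_rng.permutation(x[:, k]) for k in range(D)])
        r = sparcc(null, n_dirichlet=n_dirichlet, seed=child.generate_state(1)[0])
        exceed += np.abs(r.rho.to_numpy()) >= obs
    if add_one:
        p = (1.0 + exceed) / (n_boot + 1.0)
    else:
        p = exceed / n_boot
    np.fill_diagonal(p, 0.0)
    return pd.DataFrame(p, index=ids, columns=ids)
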