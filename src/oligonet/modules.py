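"""Consensus module detection across two yearly correlation networks.

Correlations are mapped to [0, 1] adjacencies, each year's network is
summarised by its unsigned topological overlap matrix (TOM, a similarity
combining direct adjacency with shared neighbourhoods), the second year's
TOM is quantile-calibrated against the first, and the consensus TOM is the
elementwise (parallel) minimum — high only for pairs that are strongly and
consistently connected in BOTH years.  Modules are branches of the
average-linkage dendrogram of consensus-TOM dissimilarity, cut with a
two-phase dynamic procedure; each module is summarised per year by its
eigengene (first principal component of the members' clr-transformed
abundance profiles), and modules whose eigengenes are near-identical in
both years are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .tables import OligotypeTable

#: minimum relative separation (cross-branch mean dissimilarity vs the
#: looser child's internal mean, normalised by the cross mean) required to
#: keep bisecting a branch; indexed by deepSplit (0..4), larger deepSplit =
#: more aggressive splitting
_DEEPSPLIT_CONTRAST = {0: 0.10, 1: 0.05, 2: 0.01, 3: 0.005, 4: 0.0}


def _check_square(A, name="matrix"):
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    return A


def rescale_cor(rho) -> np.ndarray:
    """Map correlations in [-1, 1] to adjacency 0.5 * (cor + 1); unit diagonal."""
    rho = _check_square(rho, "correlation matrix")
    if np.abs(rho).max() > 1 + 1e-9:
        raise ValueError("correlations must lie in [-1, 1]")
    A = 0.5 * (np.clip(rho, -1.0, 1.0) + 1.0)
    np.fill_diagonal(A, 1.0)
    return A


def tom_similarity(A) -> np.ndarray:
    """Unsigned topological overlap of a weighted adjacency.

    TOM_ij = (sum_{u != i,j} A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)
    with k the connectivity excluding the diagonal; TOM_ii = 1.
    """
    A = _check_square(A, "adjacency")
    if A.min() < -1e-12 or A.max() > 1 + 1e-9:
        raise ValueError("adjacency entries must lie in [0, 1]")
    B = A.copy()
    np.fill_diagonal(B, 0.0)
    k = B.sum(axis=1)
    numer = B @ B + B
    denom = np.minimum.outer(k, k) + 1.0 - B
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def _offdiag(M) -> np.ndarray:
    iu = np.triu_indices_from(M, k=1)
    return M[iu]


def scale_tom(tom_b, tom_ref, q: float = 0.95) -> np.ndarray:
    """Quantile power calibration of one TOM against a reference.

    Raises the entries of ``tom_b`` to the power beta = ln(Q_ref)/ln(Q_b)
    where Q is the q-quantile of the off-diagonal entries, so the two
    q-quantiles match exactly while the entry order is preserved.
    """
    tom_b = _check_square(tom_b, "TOM")
    tom_ref = _check_square(tom_ref, "reference TOM")
    if tom_b.shape != tom_ref.shape:
        raise ValueError("TOM dimensions differ")
    # order-statistic quantiles (no interpolation) so that powering the
    # matrix maps the quantile exactly: Q(x^beta) = Q(x)^beta
    qb = float(np.quantile(_offdiag(tom_b), q, method="lower"))
    qr = float(np.quantile(_offdiag(tom_ref), q, method="lower"))
    if not (0 < qb < 1) or not (0 < qr < 1):
        raise ValueError("degenerate quantile (0 or 1); cannot calibrate")
    beta = np.log(qr) / np.log(qb)
    out = tom_b**beta
    np.fill_diagonal(out, 1.0)
    return out


def consensus_tom(tom_a, tom_b) -> np.ndarray:
    """Parallel minimum of two TOMs: high only if high in both years."""
    tom_a = _check_square(tom_a, "TOM A")
    tom_b = _check_square(tom_b, "TOM B")
    if tom_a.shape != tom_b.shape:
        raise ValueError("TOM dimensions differ")
    return np.minimum(tom_a, tom_b)


@dataclass
class ModuleSet:
    """Taxon -> module assignment (0 = unassigned) and per-year eigengenes."""

    assignment: pd.Series
    eigengenes: dict = field(default_factory=dict)   # year -> DataFrame (samples x modules)
    loadings: dict = field(default_factory=dict)     # year -> {module: Series}
    merge_history: list = field(default_factory=list)
    degenerate: bool = False

    @property
    def modules(self) -> dict:
        out: dict[int, list] = {}
        for taxon, lab in self.assignment.items():
            if lab != 0:
                out.setdefault(int(lab), []).append(taxon)
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules)


def detect_modules(
    consensus,
    ids=None,
    deepSplit: int = 2,
    cutHeight: float = 0.995,
    minClusterSize: int = 10,
) -> ModuleSet:
    """Branch modules of the consensus-TOM dendrogram.

    Average-linkage clustering on dissimilarity 1 - TOM, followed by a
    two-phase dynamic cut.  Phase 1 is a static cut at ``cutHeight``.
    Phase 2 recursively bisects each branch at its root merge: when both
    children hold at least ``minClusterSize`` members, the branch is split
    if the cross-children mean dissimilarity (exactly the merge height
    under average linkage) exceeds the looser child's internal mean
    dissimilarity by a deepSplit-dependent relative margin; when one child
    is a small fragment (e.g. a singleton chained high onto the branch) the
    procedure descends into the large child and, if substructure is found
    there, sets the fragment aside.  Set-aside leaves are re-attached to
    the cluster with the highest mean TOM affinity when that affinity
    beats their background mean, and are left unassigned (label 0)
    otherwise.  This is a transparent stand-in for the dynamic hybrid tree
    cut; the contract is recovery of planted structure, not replication of
    any particular implementation's labels.
    """
    tom = _check_square(consensus, "consensus TOM")
    D = tom.shape[0]
    if ids is None:
        ids = pd.RangeIndex(D)
    if D < minClusterSize:
        raise ValueError("fewer taxa than minClusterSize")
    if deepSplit not in _DEEPSPLIT_CONTRAST:
        raise ValueError("deepSplit must be in 0..4")
    min_contrast = _DEEPSPLIT_CONTRAST[deepSplit]

    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    root = to_tree(Z)
    degenerate = np.allclose(_offdiag(tom), _offdiag(tom)[0], atol=1e-12)

    def static_clusters(node, out):
        if node.dist <= cutHeight:
            out.append(node)
        else:
            static_clusters(node.left, out)
            static_clusters(node.right, out)

    def within_mean(leaves) -> float:
        if len(leaves) < 2:
            return 0.0
        sub = dissim[np.ix_(leaves, leaves)]
        return sub.sum() / (len(leaves) * (len(leaves) - 1))

    stragglers: list[int] = []

    def split(node) -> list:
        if node.is_leaf() or node.count < 2 * minClusterSize:
            return [node]
        left, right = node.left, node.right
        small, big = (left, right) if left.count <= right.count else (right, left)
        if small.count < minClusterSize:
            # chained fragment: look for substructure in the large child
            sub = split(big)
            if len(sub) >= 2:
                stragglers.extend(small.pre_order(lambda leaf: leaf.id))
                return sub
            return [node]
        w = max(
            within_mean(left.pre_order(lambda leaf: leaf.id)),
            within_mean(right.pre_order(lambda leaf: leaf.id)),
        )
        if node.dist <= 0 or (node.dist - w) / node.dist <= min_contrast:
            return [node]
        return split(left) + split(right)

    tops: list = []
    static_clusters(root, tops)
    finals: list = []
    for top in tops:
        finals.extend(split(top))

    labels = np.zeros(D, dtype=int)
    keep = [n for n in finals if n.count >= minClusterSize]
    keep.sort(key=lambda n: -n.count)
    for lab, node in enumerate(keep, start=1):
        labels[node.pre_order(lambda leaf: leaf.id)] = lab
    for node in finals:
        if node.count < minClusterSize:
            stragglers.extend(node.pre_order(lambda leaf: leaf.id))

    # re-attach chained-off leaves by mean TOM affinity
    if keep and stragglers:
        for i in stragglers:
            base = (tom[i].sum() - 1.0) / (D - 1)
            best_lab, best_aff = 0, -np.inf
            for lab in range(1, len(keep) + 1):
                members = np.flatnonzero(labels == lab)
                members = members[members != i]
                if members.size == 0:
                    continue
                aff = tom[i, members].mean()
                if aff > best_aff:
                    best_lab, best_aff = lab, aff
            if best_aff > base:
                labels[i] = best_lab
    return ModuleSet(
        assignment=pd.Series(labels, index=ids), degenerate=degenerate
    )


def clr_transform(table, pseudocount: float = 1e-6) -> pd.DataFrame:
    """Centered log-ratio transform of per-sample proportions.

    Counts are converted to proportions, the pseudocount is added to the
    proportions, and each sample row is log-transformed and centred so it
    sums to zero.
    """
    if isinstance(table, OligotypeTable):
        props = table.proportions()
    else:
        df = pd.DataFrame(table)
        tot = df.sum(axis=1)
        if (tot <= 0).any():
            raise ValueError("empty sample")
        props = df.div(tot, axis=0)
    logs = np.log(props.to_numpy(dtype=float) + pseudocount)
    logs = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(logs, index=props.index, columns=props.columns)


def module_eigengene(clr_data: pd.DataFrame, members) -> tuple[pd.Series, pd.Series]:
    """First principal component of the members' clr profiles.

    Returns ``(scores, loading)``: the per-sample eigengene time series and
    the unit-norm member loading vector.  The sign is oriented so that the
    eigengene correlates positively with the mean member profile.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("a module eigengene needs at least 2 members")
    X = clr_data.loc[:, members].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValueError("constant submatrix: eigengene undefined")
    v = Vt[0]
    scores = Xc @ v
    mean_profile = Xc.mean(axis=1)
    orient = np.dot(scores, mean_profile)
    if orient == 0:
        orient = v.sum()
    if orient < 0:
        scores, v = -scores, -v
    return (
        pd.Series(scores, index=clr_data.index),
        pd.Series(v, index=members),
    )


def eigengenes_by_year(
    assignment: pd.Series, clr_by_year: dict
) -> tuple[dict, dict]:
    """Eigengene time series and loadings per year for every module."""
    modules = {}
    for taxon, lab in assignment.items():
        if lab != 0:
            modules.setdefault(int(lab), []).append(taxon)
    mes, loads = {}, {}
    for year, clr in clr_by_year.items():
        cols, ldict = {}, {}
        for lab, members in sorted(modules.items()):
            scores, loading = module_eigengene(clr, members)
            cols[lab] = scores
            ldict[lab] = loading
        mes[year] = pd.DataFrame(cols)
        loads[year] = ldict
    return mes, loads


def _consensus_me_dissim(mes: dict) -> pd.DataFrame:
    """d(a, b) = max over years of 1 - Pearson(ME_a, ME_b)."""
    labels = list(next(iter(mes.values())).columns)
    d = np.zeros((len(labels), len(labels)))
    for me in mes.values():
        corr = np.corrcoef(me.to_numpy().T)
        d = np.maximum(d, 1.0 - corr)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, d.T)
    return pd.DataFrame(d, index=labels, columns=labels)


def merge_modules(
    module_set: ModuleSet,
    clr_by_year: dict,
    cutHeight: float = 0.25,
) -> ModuleSet:
    """Merge modules whose eigengenes are consistently similar across years.

    Modules are clustered (average linkage) on the consensus eigengene
    dissimilarity max_year(1 - cor); clusters joining below ``cutHeight``
    are merged, eigengenes of merged modules are recomputed, and the
    procedure iterates until no pair merges.
    """
    assignment = module_set.assignment.copy()
    history = list(module_set.merge_history)
    while True:
        mes, _ = eigengenes_by_year(assignment, clr_by_year)
        labels = list(next(iter(mes.values())).columns)
        if len(labels) < 2:
            break
        d = _consensus_me_dissim(mes)
        Z = linkage(squareform(d.to_numpy(), checks=False), method="average")
        from scipy.cluster.hierarchy import fcluster

        groups = fcluster(Z, t=cutHeight, criterion="distance")
        if len(set(groups)) == len(labels):
            break
        remap = {}
        for g in sorted(set(groups)):
            members = [labels[i] for i in range(len(labels)) if groups[i] == g]
            target = min(members)
            for lab in members:
                remap[lab] = target
            if len(members) > 1:
                history.append({"merged": members, "into": target})
        assignment = assignment.map(lambda lab: remap.get(lab, 0) if lab != 0 else 0)
    # relabel 1..K by size
    sizes = assignment[assignment != 0].value_counts()
    relabel = {old: new for new, old in enumerate(sizes.index, start=1)}
    assignment = assignment.map(lambda lab: relabel.get(lab, 0))
    mes, loads = eigengenes_by_year(assignment, clr_by_year)
    return ModuleSet(
        assignment=assignment,
        eigengenes=mes,
        loadings=loads,
        merge_history=history,
        degenerate=module_set.degenerate,
    )
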