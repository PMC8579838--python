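"""Alpha diversity, weighted UniFrac, PCoA and PERMANOVA.

The distance, ordination and permutation machinery is implemented here
directly (postorder branch accumulation, classical scaling, label
permutation) so every quantity is auditable against its definition; the
test suite cross-checks the results against scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .tables import CountTable

__all__ = [
    "alpha_diversity",
    "AlphaComparison",
    "compare_alpha",
    "weighted_unifrac",
    "PcoaResult",
    "pcoa",
    "PermanovaResult",
    "permanova",
]


def alpha_diversity(table: CountTable, simpson_form: str = "complement") -> pd.DataFrame:
    """Observed ASVs, Shannon entropy (nats) and Simpson's index per sample.

    Shannon is H = -sum p_i ln p_i over the non-zero proportions; Simpson is
    reported by default in the complement form 1 - sum p_i^2 (probability
    that two random reads differ), with ``simpson_form="reciprocal"`` giving
    1 / sum p_i^2 instead.
    """
    if simpson_form not in ("complement", "reciprocal"):
        raise ValueError("simpson_form must be 'complement' or 'reciprocal'")
    props = table.relative_abundance().to_numpy()
    observed = (props > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(props > 0, props * np.log(props), 0.0)
    shannon = -plogp.sum(axis=1)
    ssq = (props**2).sum(axis=1)
    simpson = 1.0 - ssq if simpson_form == "complement" else 1.0 / ssq
    return pd.DataFrame(
        {"observed_asvs": observed, "shannon": shannon, "simpson": simpson},
        index=table.data.index,
    )


@dataclass(frozen=True)
class AlphaComparison:
    test: str  # "t" or "ranksum"
    statistic: float
    p_value: float
    normal_a: bool
    normal_b: bool


def compare_alpha(
    values_a: Sequence[float], values_b: Sequence[float], alpha: float = 0.05
) -> AlphaComparison:
    """Two-group comparison with data-driven test choice.

    Shapiro–Wilk normality per group at ``alpha``; if both groups look
    normal a two-sample t test is used, otherwise the Wilcoxon rank-sum
    test (mid-ranks for ties).  Degenerate (constant) groups are treated as
    non-normal.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")

    def _normal(x: np.ndarray) -> bool:
        if np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue > alpha

    na, nb = _normal(a), _normal(b)
    if na and nb:
        res = stats.ttest_ind(a, b)
        return AlphaComparison("t", float(res.statistic), float(res.pvalue), na, nb)
    res = stats.ranksums(a, b)
    return AlphaComparison("ranksum", float(res.statistic), float(res.pvalue), na, nb)


def _branch_matrix(tree: TreeNode, table: CountTable) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and per-branch descendant abundance proportions.

    Returns ``(lengths, P)`` with ``P[l, s]`` the proportion of sample s's
    reads on tips below branch l, for every non-root branch in postorder.
    """
    tips = {t.name for t in tree.tips()}
    missing = [a for a in table.asv_ids if a not in tips]
    if missing:
        raise ValueError(f"ASVs missing from the tree: {missing}")
    props = table.relative_abundance()
    col = {a: i for i, a in enumerate(table.asv_ids)}
    n_samples = table.shape[0]
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = np.zeros(n_samples)
            if node.name in col:
                vec = props.iloc[:, col[node.name]].to_numpy(copy=True)
        else:
            vec = np.zeros(n_samples)
            for child in node.children:
                vec += partial.pop(id(child))
        partial[id(node)] = vec
        if node.parent is not None:
            lengths.append(float(node.length or 0.0))
            rows.append(vec)
    return np.asarray(lengths), np.vstack(rows) if rows else np.zeros((0, n_samples))


def weighted_unifrac(
    table: CountTable, tree: TreeNode, normalized: bool = True
) -> DistanceMatrix:
    """Weighted UniFrac distance between every pair of samples.

    Raw form: d(A,B) = sum_l b_l |p_A(l) - p_B(l)| over branches l with
    length b_l, where p_X(l) is the fraction of sample X's reads descending
    from l.  The normalized form divides by sum_l b_l (p_A(l) + p_B(l)),
    bounding the distance in [0, 1].
    """
    lengths, P = _branch_matrix(tree, table)
    n = table.shape[0]
    d = np.zeros((n, n))
    s = lengths @ P  # per-sample total branch-weighted mass
    for i in range(n):
        diff = np.abs(P[:, i : i + 1] - P[:, i + 1 :])
        raw = lengths @ diff
        if normalized:
            denom = s[i] + s[i + 1 :]
            raw = np.divide(raw, denom, out=np.zeros_like(raw), where=denom > 0)
        d[i, i + 1 :] = raw
        d[i + 1 :, i] = raw
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


def pcoa(dm: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> PcoaResult:
    """Principal-coordinate analysis by classical scaling.

    Double-centre -d^2/2, eigendecompose, keep the axes with positive
    eigenvalues (negative ones — non-Euclidean residue — are dropped and
    excluded from the explained-variance denominator).  Coordinates are
    eigenvectors scaled by sqrt(eigenvalue), ordered by decreasing
    eigenvalue.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.data
        ids = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("distance matrix must be square and symmetric")
        ids = list(ids) if ids is not None else [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if n else 0.0
    keep = evals > tol
    evals, evecs = evals[keep], evecs[:, keep]
    coords = evecs * np.sqrt(evals)
    explained = evals / evals.sum() if evals.size else evals
    frame = pd.DataFrame(
        coords, index=pd.Index(ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return PcoaResult(frame, evals, explained)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and integer group codes."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(
    dm: DistanceMatrix | np.ndarray,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Partitions the sum of squared distances into between- and within-group
    components; the p-value comes from ``n_perm`` random label permutations
    with the (1 + b) / (1 + m) estimator, so it is never exactly zero.
    """
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    groups = np.asarray(list(groups))
    if len(groups) != d.shape[0]:
        raise ValueError("one group label per sample is required")
    uniq, codes = np.unique(groups, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("at least two groups are required")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = uniq[sizes < 2].tolist()
        raise ValueError(f"every group needs n >= 2; too small: {small}")
    d2 = d**2
    f_obs, r2 = _permanova_stats(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        f_perm, _ = _permanova_stats(d2, perm, len(uniq))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, seed)
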