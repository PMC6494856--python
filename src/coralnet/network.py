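"""Sample-correlation network analysis.

Samples are nodes; edge weights derive from the Pearson correlation between
the samples' (normalized) OTU abundance vectors. On that graph the module
computes homophily/heterophily scores, leading-eigenvector community
detection with a stratified-shuffle Monte-Carlo modularity null, chi-square
module-factor association, majority-vote classification accuracy, and
eigenvector centrality with group-level comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .io import NormalizedTable, ValidationError
from .permanova import holm_adjust
from .results import TermTable

__all__ = [
    "sample_correlation",
    "CorrelationNetwork",
    "HomophilyScores",
    "homophily",
    "build_graph",
    "ModulePartition",
    "leading_eigenvector_communities",
    "modularity",
    "modularity_null",
    "module_factor_chisq",
    "classification_accuracy",
    "eigen_centrality",
    "CentralityResult",
    "centrality_group_tests",
]


def sample_correlation(table) -> pd.DataFrame:
    """Pearson correlation between every pair of samples' abundance vectors."""
    values = table.values if isinstance(table, NormalizedTable) else pd.DataFrame(table)
    arr = values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise ValidationError("sample correlation requires at least 2 OTUs")
    sd = arr.std(axis=1)
    if np.any(sd == 0):
        bad = values.index[int(np.argmin(sd))]
        raise ValidationError(f"constant abundance vector for sample {bad!r}")
    r = np.corrcoef(arr)
    return pd.DataFrame(r, index=values.index, columns=values.index)


@dataclass
class HomophilyScores:
    """Mean within-level (homophily) and between-level (heterophily)
    correlation for one grouping factor."""

    factor: str
    homophily: float
    heterophily: float
    per_level: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def homophily(r: pd.DataFrame, labels, factor: str = "") -> HomophilyScores:
    """Average correlation over unordered same-level / different-level sample
    pairs (self-pairs excluded)."""
    arr = np.asarray(r, dtype=float)
    lab = pd.Series(labels)
    if isinstance(r, pd.DataFrame) and not lab.index.equals(r.index):
        lab = lab.reindex(r.index)
    lab = lab.astype(str).to_numpy()
    n = arr.shape[0]
    iu = np.triu_indices(n, k=1)
    same = lab[iu[0]] == lab[iu[1]]
    vals = arr[iu]
    levels, counts = np.unique(lab, return_counts=True)
    if np.all(counts < 2):
        warnings.warn("no level has >= 2 samples: homophily undefined")
    homo = float(vals[same].mean()) if same.any() else float("nan")
    if (~same).any():
        hetero = float(vals[~same].mean())
    else:
        warnings.warn(f"single level in factor {factor!r}: heterophily undefined")
        hetero = float("nan")
    per_level = {}
    for lev in levels:
        mask = same & (lab[iu[0]] == lev)
        per_level[lev] = float(vals[mask].mean()) if mask.any() else float("nan")
    return HomophilyScores(factor, homo, hetero, pd.Series(per_level))


def _apply_negative_policy(r: np.ndarray, policy: str) -> np.ndarray:
    if policy == "truncate":
        w = np.maximum(r, 0.0)
    elif policy == "shift":
        w = (r + 1.0) / 2.0
    elif policy == "absolute":
        w = np.abs(r)
    else:
        raise ValueError(f"unknown negative_policy {policy!r}")
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


@dataclass
class CorrelationNetwork:
    """Correlation matrix plus its derived weighted undirected graph."""

    ids: list
    r: np.ndarray
    negative_policy: str = "truncate"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r < -1 - 1e-9) or np.any(self.r > 1 + 1e-9):
            raise ValidationError("correlations must lie in [-1, 1]")
        self.w = _apply_negative_policy(self.r, self.negative_policy)

    @classmethod
    def from_table(cls, table, negative_policy: str = "truncate") -> "CorrelationNetwork":
        r = sample_correlation(table)
        return cls(list(r.index), r.to_numpy(), negative_policy)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.w[i, j] > 0:
                    g.add_edge(self.ids[i], self.ids[j], weight=float(self.w[i, j]))
        return g

    def edge_list(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if self.w[i, j] > 0:
                    rows.append((self.ids[i], self.ids[j], float(self.w[i, j])))
        return pd.DataFrame(rows, columns=["sample_a", "sample_b", "weight"])


def build_graph(r, negative_policy: str = "truncate", ids=None) -> CorrelationNetwork:
    """Weighted undirected graph from a correlation matrix.

    Negative-correlation policies: ``truncate`` (w = max(r, 0), default),
    ``shift`` (w = (r+1)/2), ``absolute`` (w = |r|). Edges exist where w > 0.
    """
    if isinstance(r, pd.DataFrame):
        ids = list(r.index)
        r = r.to_numpy()
    elif ids is None:
        ids = list(range(np.asarray(r).shape[0]))
    return CorrelationNetwork(ids, np.asarray(r, dtype=float), negative_policy)


@dataclass
class ModulePartition:
    """Node -> module assignment with its modularity Q."""

    assignment: pd.Series  # index: node ids, values: module ints (0 = largest)
    modularity: float

    @property
    def n_modules(self) -> int:
        return int(self.assignment.nunique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.assignment.index, "module": self.assignment.to_numpy()}
        )


def modularity(w: np.ndarray, membership) -> float:
    """Newman-Girvan weighted modularity
    Q = (1/2m) sum_ij (w_ij - k_i k_j / 2m) delta(c_i, c_j)."""
    w = np.asarray(w, dtype=float)
    c = np.asarray(membership)
    if c.size != w.shape[0]:
        raise ValidationError("partition does not cover every node")
    k = w.sum(axis=1)
    m2 = k.sum()
    if m2 == 0:
        return 0.0
    q = 0.0
    for lab in np.unique(c):
        idx = np.flatnonzero(c == lab)
        q += w[np.ix_(idx, idx)].sum() - k[idx].sum() ** 2 / m2
    return float(q / m2)


def _canonical_membership(groups, n) -> np.ndarray:
    order = sorted(range(len(groups)), key=lambda i: (-len(groups[i]), min(groups[i])))
    member = np.empty(n, dtype=int)
    for new_id, gi in enumerate(order):
        member[list(groups[gi])] = new_id
    return member


def leading_eigenvector_communities(w, ids=None, tol: float = 1e-9) -> ModulePartition:
    """Recursive Newman spectral bisection on the weighted modularity matrix.

    Each candidate group is split by the sign of the leading eigenvector of
    its generalized modularity matrix; a split is accepted only if the
    leading eigenvalue is positive and the split strictly increases Q.
    Module ids are canonicalized by decreasing size.
    """
    if isinstance(w, nx.Graph):
        ids = list(w.nodes)
        w = nx.to_numpy_array(w, nodelist=ids, weight="weight")
    elif isinstance(w, CorrelationNetwork):
        ids = w.ids
        w = w.w
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if n == 0:
        raise ValidationError("empty graph")
    if ids is None:
        ids = list(range(n))
    k = w.sum(axis=1)
    m2 = k.sum()
    if m2 == 0:
        member = np.zeros(n, dtype=int)
        return ModulePartition(pd.Series(member, index=ids), 0.0)
    B = w - np.outer(k, k) / m2
    groups = []
    stack = [np.arange(n)]
    while stack:
        idx = stack.pop()
        if idx.size == 1:
            groups.append(idx)
            continue
        Bg = B[np.ix_(idx, idx)].copy()
        Bg[np.diag_indices(idx.size)] -= Bg.sum(axis=1)
        vals, vecs = np.linalg.eigh(Bg)
        if vals[-1] <= tol:
            groups.append(idx)
            continue
        s = np.where(vecs[:, -1] >= 0, 1.0, -1.0)
        if np.all(s > 0) or np.all(s < 0):
            groups.append(idx)
            continue
        dQ = float(s @ Bg @ s) / (2.0 * m2)
        if dQ <= tol:
            groups.append(idx)
            continue
        stack.append(idx[s > 0])
        stack.append(idx[s < 0])
    member = _canonical_membership(groups, n)
    return ModulePartition(pd.Series(member, index=ids), modularity(w, member))


def _stratified_shuffle(r: np.ndarray, strata: np.ndarray, rng) -> np.ndarray:
    """Permute each stratum's off-diagonal correlation values among its own
    row positions, then re-symmetrize by averaging the two copies."""
    n = r.shape[0]
    M = r.copy()
    off = ~np.eye(n, dtype=bool)
    for lev in np.unique(strata):
        rows = np.flatnonzero(strata == lev)
        mask = np.zeros_like(off)
        mask[rows] = off[rows]
        vals = M[mask]
        M[mask] = rng.permutation(vals)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return M


def modularity_null(
    network: CorrelationNetwork,
    host_labels,
    permutations: int = 999,
    seed=None,
    unit: str = "group",
) -> tuple:
    """Monte-Carlo modularity significance against stratified shuffles.

    Each replicate permutes the off-diagonal correlations within strata —
    the host group of the row sample (``unit='group'``) or each individual
    sample row (``unit='row'``) — re-symmetrizes by averaging, rebuilds the
    graph under the network's negative-weight policy, re-detects communities
    and records Q*. Returns (p, observed Q, null Q array) with
    p = #{Q* >= Q_obs} / permutations.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    lab = pd.Series(host_labels)
    if not lab.index.equals(pd.Index(network.ids)):
        lab = lab.reindex(network.ids)
    lab = lab.astype(str).to_numpy()
    if unit == "row":
        strata = np.arange(len(lab)).astype(str)
    elif unit == "group":
        strata = lab
    else:
        raise ValueError(f"unknown stratification unit {unit!r}")
    rng = np.random.default_rng(seed)
    q_obs = leading_eigenvector_communities(network.w, network.ids).modularity
    null_q = np.empty(permutations)
    for b in range(permutations):
        M = _stratified_shuffle(network.r, strata, rng)
        Wb = _apply_negative_policy(M, network.negative_policy)
        null_q[b] = leading_eigenvector_communities(Wb).modularity
    p = float(np.mean(null_q >= q_obs))
    return p, float(q_obs), null_q


def module_factor_chisq(partition: ModulePartition, labels, factor: str = "") -> TermTable:
    """Pearson chi-square association between module membership and a factor."""
    lab = pd.Series(labels)
    if not lab.index.equals(partition.assignment.index):
        lab = lab.reindex(partition.assignment.index)
    contingency = pd.crosstab(lab.astype(str), partition.assignment)
    if (contingency.sum(axis=0) == 0).any() or (contingency.sum(axis=1) == 0).any():
        raise ValidationError("empty module or factor level in contingency table")
    chi2, p, dof, _ = stats.chi2_contingency(contingency.to_numpy(), correction=False)
    frame = pd.DataFrame(
        {
            "term": [factor or getattr(lab, "name", "factor") or "factor"],
            "df": [dof],
            "statistic": [chi2],
            "effect_size": [np.nan],
            "p_value": [p],
        }
    )
    return TermTable(frame, statistic_name="chi2", effect_name="")


def classification_accuracy(partition: ModulePartition, labels, level_order=None) -> float:
    """Fraction of samples correctly classified when every module votes for
    its majority factor level (ties broken to the earliest level in
    ``level_order``); 1 minus this is the misclassification rate."""
    lab = pd.Series(labels)
    if not lab.index.equals(partition.assignment.index):
        lab = lab.reindex(partition.assignment.index)
    lab = lab.astype(str)
    if level_order is None:
        level_order = list(dict.fromkeys(lab))
    rank = {str(lev): i for i, lev in enumerate(level_order)}
    correct = 0
    for _, members in lab.groupby(partition.assignment):
        counts = members.value_counts()
        best = counts.max()
        winners = sorted(counts.index[counts == best], key=lambda x: rank.get(x, len(rank)))
        correct += int(counts[winners[0]])
    return correct / len(lab)


def eigen_centrality(w, ids=None, tol: float = 1e-10, max_iter: int = 10000) -> pd.Series:
    """Eigenvector centrality of the weighted graph, max-normalized to 1.

    Power iteration (uniform start, on w + I to damp bipartite oscillation)
    on the largest connected component; nodes outside it score 0.
    """
    if isinstance(w, CorrelationNetwork):
        ids = w.ids
        w = w.w
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if n == 0:
        raise ValidationError("empty graph")
    if ids is None:
        ids = list(range(n))
    from scipy.sparse.csgraph import connected_components

    n_comp, comp = connected_components((w > 0).astype(int), directed=False)
    sizes = np.bincount(comp)
    main = int(np.argmax(sizes))
    idx = np.flatnonzero(comp == main)
    sub = w[np.ix_(idx, idx)]
    x = np.ones(idx.size) / np.sqrt(idx.size)
    lam = 0.0
    for it in range(max_iter):
        y = sub @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        gap = _spectral_gap(sub)
        raise ValidationError(
            f"eigencentrality power iteration failed to converge in {max_iter} "
            f"iterations (spectral gap {gap:.3e})"
        )
    scores = np.zeros(n)
    x = np.abs(x)
    scores[idx] = x / x.max() if x.max() > 0 else x
    return pd.Series(scores, index=ids, name="eigen_centrality")


def _spectral_gap(sub: np.ndarray) -> float:
    vals = np.linalg.eigvalsh(sub)
    return float(vals[-1] - abs(vals[-2])) if vals.size > 1 else float("inf")


@dataclass
class CentralityResult:
    """Per-level centrality means/SE and Holm-adjusted pairwise Welch tests."""

    factor: str
    group_stats: pd.DataFrame  # level, mean, se, n
    pairwise: TermTable


def centrality_group_tests(scores: pd.Series, labels, factor: str = "", level_order=None) -> CentralityResult:
    lab = pd.Series(labels)
    if not lab.index.equals(scores.index):
        lab = lab.reindex(scores.index)
    lab = lab.astype(str)
    if level_order is None:
        level_order = list(dict.fromkeys(lab))
    level_order = [str(x) for x in level_order]
    rows = []
    for lev in level_order:
        vals = scores[lab == lev]
        rows.append(
            {
                "level": lev,
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            }
        )
    pairs = []
    for i in range(len(level_order)):
        for j in range(i + 1, len(level_order)):
            a = scores[lab == level_order[i]].to_numpy()
            b = scores[lab == level_order[j]].to_numpy()
            t, p = stats.ttest_ind(a, b, equal_var=False)
            pairs.append(
                {
                    "term": f"{level_order[i]} vs {level_order[j]}",
                    "df": 1,
                    "statistic": float(t),
                    "effect_size": float(a.mean() - b.mean()),
                    "p_value": float(p),
                }
            )
    frame = pd.DataFrame(pairs)
    if not frame.empty:
        frame["p_adjusted"] = holm_adjust(np.clip(frame["p_value"].to_numpy(), 1e-300, 1.0))
    return CentralityResult(
        factor=factor,
        group_stats=pd.DataFrame(rows),
        pairwise=TermTable(frame, statistic_name="t (Welch)", effect_name="mean diff"),
    )
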