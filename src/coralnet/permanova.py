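"""Sequential (Type-I) PERMANOVA on distance matrices for nested crossed
designs, in the McArdle-Anderson partitioning: Gower-center the squared
distances, project onto the cumulative column spaces of the design terms,
and take sequential traces as sums of squares. Significance comes from free
permutation of the sample labels of the distance matrix; degrees of freedom
are realized projector-rank differences, so nesting and missing design
cells are handled without explicit constraints.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import SampleMetadata, ValidationError
from .results import TermTable

__all__ = [
    "gower_center",
    "term_design_matrix",
    "Permanova",
    "PermanovaResults",
    "pairwise_permanova",
    "holm_adjust",
]

_RANK_TOL = 1e-8


def gower_center(d) -> np.ndarray:
    """Gower-centered inner-product matrix G = C(-1/2 d^2)C, C = I - 11'/n.

    trace(G) is the total sum of squares of the implied point configuration.
    """
    arr = d.data if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(arr, arr.T):
        raise ValidationError("distance matrix must be symmetric")
    A = -0.5 * arr**2
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    return A - row - col + A.mean()


def _parse_term(term: str) -> list:
    """Factor names referenced by a term: 'Genus', 'Species(Genus)',
    'Genus:Site', 'Species(Genus):Site:Time' -> flat factor list."""
    factors = []
    for part in term.split(":"):
        m = re.fullmatch(r"\s*(\w+)\s*\(\s*(\w+)\s*\)\s*", part)
        if m:
            factors.extend([m.group(2), m.group(1)])  # nest parent first
        else:
            factors.append(part.strip())
    return factors


def term_design_matrix(metadata: pd.DataFrame, term: str) -> np.ndarray:
    """Indicator matrix of the cells formed by crossing the term's factors.

    The sequential projector machinery extracts each term's incremental
    column space, so full cell indicators give the correct realized df for
    main effects, nested factors and interactions alike.
    """
    factors = _parse_term(term)
    cols = []
    for f in factors:
        key = f.lower()
        if key not in metadata.columns:
            raise ValidationError(f"unknown factor {f!r} in term {term!r}")
        cols.append(metadata[key].astype(str))
    combined = cols[0]
    for c in cols[1:]:
        combined = combined + "\x1f" + c
    return pd.get_dummies(combined).to_numpy(dtype=float)


def _orth_basis(X: np.ndarray) -> np.ndarray:
    if X.shape[1] == 0:
        return X
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return U[:, :0]
    return U[:, s > _RANK_TOL * s[0]]


def sequential_projectors(metadata: pd.DataFrame, terms) -> tuple:
    """Incremental hat-matrix differences and dfs for an ordered term list."""
    n = len(metadata)
    X = np.ones((n, 1))
    basis = _orth_basis(X)
    H_prev = basis @ basis.T
    rank_prev = basis.shape[1]
    deltas, dfs = [], []
    for term in terms:
        X = np.hstack([X, term_design_matrix(metadata, term)])
        basis = _orth_basis(X)
        H = basis @ basis.T
        df = basis.shape[1] - rank_prev
        if df == 0:
            raise ValidationError(
                f"term {term!r} is aliased by preceding terms (zero df)"
            )
        deltas.append(H - H_prev)
        dfs.append(df)
        H_prev, rank_prev = H, basis.shape[1]
    residual_proj = np.eye(n) - H_prev
    df_res = n - rank_prev
    return deltas, np.array(dfs), residual_proj, df_res


@dataclass
class PermanovaResults:
    """Fitted sequential PERMANOVA: per-term df, pseudo-F, R^2, permutation p."""

    table: TermTable
    total_ss: float
    permutations: int
    terms: list

    @property
    def r_squared(self) -> pd.Series:
        f = self.table.frame
        return pd.Series(f["effect_size"].to_numpy(), index=f["term"].to_numpy())

    def summary(self) -> str:
        head = (
            f"PERMANOVA (sequential SS, {self.permutations} permutations)\n"
            f"Total SS: {self.total_ss:.4f}\n"
        )
        return head + self.table.summary()


class Permanova:
    """Permutational MANOVA of a distance matrix against ordered design terms.

    Parameters
    ----------
    distmat : skbio.DistanceMatrix or square array
    metadata : SampleMetadata or DataFrame aligned to the distance ids
    terms : ordered term strings, e.g.
        ["Genus", "Site", "Time", "Species(Genus)", "Genus:Site"]
    """

    def __init__(self, distmat, metadata, terms):
        if isinstance(distmat, DistanceMatrix):
            ids = list(distmat.ids)
            d = distmat.data
        else:
            d = np.asarray(distmat, dtype=float)
            ids = None
        meta = metadata.table if isinstance(metadata, SampleMetadata) else pd.DataFrame(metadata)
        meta = meta.copy()
        meta.columns = [c.lower() for c in meta.columns]
        if ids is not None:
            meta.index = meta.index.astype(str)
            missing = [s for s in ids if s not in meta.index]
            if missing:
                raise ValidationError(f"samples missing from metadata: {missing[:5]}")
            meta = meta.loc[ids]
        elif len(meta) != d.shape[0]:
            raise ValidationError("metadata length does not match distance matrix")
        self.d = d
        self.metadata = meta
        self.terms = list(terms)
        self.G = gower_center(d)

    def fit(self, permutations: int = 999, seed=None) -> PermanovaResults:
        deltas, dfs, resid_proj, df_res = sequential_projectors(self.metadata, self.terms)
        G = self.G
        T = float(np.trace(G))
        ss = np.array([float(np.sum(dH * G)) for dH in deltas])
        ss_res = T - ss.sum()
        if df_res <= 0:
            raise ValidationError("saturated design: zero residual df")
        F = (ss / dfs) / (ss_res / df_res)
        r2 = ss / T
        pvals = np.full(len(self.terms), np.nan)
        if permutations and permutations > 0:
            rng = np.random.default_rng(seed)
            n = G.shape[0]
            exceed = np.zeros(len(self.terms))
            stack = np.stack(deltas)  # (k, n, n)
            for _ in range(permutations):
                p = rng.permutation(n)
                Gp = G[np.ix_(p, p)]
                ss_p = np.einsum("kij,ij->k", stack, Gp)
                ss_res_p = T - ss_p.sum()
                F_p = (ss_p / dfs) / (ss_res_p / df_res)
                exceed += F_p >= F  # ties count as exceedances
            pvals = (1.0 + exceed) / (1.0 + permutations)
        frame = pd.DataFrame(
            {
                "term": self.terms + ["Residual"],
                "df": list(dfs) + [df_res],
                "statistic": list(F) + [np.nan],
                "effect_size": list(r2) + [ss_res / T],
                "p_value": list(pvals) + [np.nan],
            }
        )
        return PermanovaResults(
            table=TermTable(frame, statistic_name="pseudo-F", effect_name="R2"),
            total_ss=T,
            permutations=permutations or 0,
            terms=self.terms,
        )


def holm_adjust(pvalues) -> np.ndarray:
    """Holm's step-down ('sequential Bonferroni') adjustment.

    Sort ascending, adj_(i) = min(1, max_{j<=i} (m-j+1) * p_(j)), then restore
    the input order. Monotone and never below the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def pairwise_permanova(
    distmat,
    metadata,
    factor: str,
    permutations: int = 999,
    seed=None,
) -> TermTable:
    """One-factor PERMANOVA restricted to each level pair of ``factor``,
    with Holm adjustment across the pairs."""
    if isinstance(distmat, DistanceMatrix):
        ids = np.array(distmat.ids)
        d = distmat.data
    else:
        d = np.asarray(distmat, dtype=float)
        ids = None
    meta = metadata.table if isinstance(metadata, SampleMetadata) else pd.DataFrame(metadata)
    meta = meta.copy()
    meta.columns = [c.lower() for c in meta.columns]
    if ids is not None:
        meta = meta.loc[list(ids)]
    labels = meta[factor.lower()].astype(str).to_numpy()
    if isinstance(metadata, SampleMetadata) and factor.lower() in metadata.levels:
        levels = [str(x) for x in metadata.levels[factor.lower()]]
    else:
        levels = list(dict.fromkeys(labels))
    if len(levels) < 2:
        raise ValidationError(f"factor {factor!r} has fewer than 2 levels")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a, b = levels[i], levels[j]
            mask = (labels == a) | (labels == b)
            if (labels == a).sum() < 2 or (labels == b).sum() < 2:
                raise ValidationError(f"level with < 2 samples in pair ({a}, {b})")
            sub_d = d[np.ix_(mask, mask)]
            sub_meta = meta.loc[mask, [factor.lower()]]
            res = Permanova(sub_d, sub_meta, [factor]).fit(
                permutations=permutations, seed=rng.integers(2**31 - 1)
            )
            row = res.table[factor]
            rows.append(
                {
                    "term": f"{a} vs {b}",
                    "df": row["df"],
                    "statistic": row["statistic"],
                    "effect_size": row["effect_size"],
                    "p_value": row["p_value"],
                }
            )
    frame = pd.DataFrame(rows)
    frame["p_adjusted"] = holm_adjust(frame["p_value"].to_numpy())
    return TermTable(frame, statistic_name="pseudo-F", effect_name="R2")
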