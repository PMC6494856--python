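"""Community-level metrics: Bray-Curtis dissimilarity, prevalence and core
microbiome detection, class-level abundance profiles, and SIMPER.

Prevalence is computed on raw counts (presence precedes normalization);
abundance-weighted quantities (class profiles, core composition, SIMPER)
use the normalized table, the same matrix the PERMANOVA runs on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io import CountTable, NormalizedTable, TaxonomyMap, ValidationError

__all__ = [
    "bray_curtis",
    "euclidean",
    "prevalence",
    "CoreMicrobiome",
    "core_microbiome",
    "class_abundance_profile",
    "SimperTable",
    "simper",
]


def _values(table) -> pd.DataFrame:
    if isinstance(table, NormalizedTable):
        return table.values
    if isinstance(table, CountTable):
        return table.counts.astype(float)
    return pd.DataFrame(table)


def bray_curtis(table) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(a,b) = sum|x_a - x_b| / sum(x_a + x_b)."""
    df = _values(table)
    arr = df.to_numpy(dtype=float)
    if np.any(arr.sum(axis=1) <= 0):
        bad = df.index[int(np.argmin(arr.sum(axis=1)))]
        raise ValidationError(f"zero-sum sample {bad!r}: Bray-Curtis undefined")
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in df.index])


def euclidean(table) -> DistanceMatrix:
    df = _values(table)
    d = squareform(pdist(df.to_numpy(dtype=float), metric="euclidean"))
    return DistanceMatrix(d, ids=[str(i) for i in df.index])


def _group_series(groups, index) -> pd.Series:
    g = pd.Series(groups)
    if not g.index.equals(pd.Index(index)):
        g = g.reindex(index)
    if g.isna().any():
        missing = list(g.index[g.isna()])[:5]
        raise ValidationError(f"samples without group assignment: {missing}")
    return g.astype(str)


def prevalence(table: CountTable, groups) -> pd.DataFrame:
    """Per-group per-OTU prevalence: fraction of the group's samples with count > 0."""
    counts = table.counts if isinstance(table, CountTable) else pd.DataFrame(table)
    g = _group_series(groups, counts.index)
    present = (counts > 0).astype(float)
    out = present.groupby(g, sort=False).mean()
    if (out.index.value_counts() == 0).any():  # pragma: no cover - defensive
        raise ValidationError("empty group")
    return out


@dataclass
class CoreMicrobiome:
    """Core OTU set of one host group with its class-level composition."""

    group: str
    prevalence: pd.Series  # per-OTU prevalence within the group
    core_otus: list
    class_abundance: pd.Series  # relative abundance of core OTUs by class, sums to 1
    threshold: float


def core_microbiome(
    table: CountTable,
    normalized: NormalizedTable,
    groups,
    taxonomy: TaxonomyMap,
    threshold: float = 0.95,
) -> dict:
    """Detect each group's core microbiome: OTUs with prevalence strictly
    greater than ``threshold`` within the group, plus the class-level relative
    abundance of those core OTUs (normalized abundances, renormalized to 1).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    prev = prevalence(table, groups)
    g = _group_series(groups, normalized.values.index)
    classes = taxonomy.classes_for(list(normalized.values.columns))
    out = {}
    for grp in prev.index:
        p = prev.loc[grp]
        core = list(p.index[p > threshold])
        if not core:
            warnings.warn(f"group {grp!r}: empty core set at threshold {threshold}")
            class_ab = pd.Series(dtype=float)
        else:
            sub = normalized.values.loc[g == grp, core]
            totals = sub.sum(axis=0)
            class_ab = totals.groupby(classes.loc[core].to_numpy()).sum()
            class_ab = class_ab / class_ab.sum()
        out[grp] = CoreMicrobiome(grp, p, core, class_ab, threshold)
    return out


def class_abundance_profile(normalized: NormalizedTable, taxonomy: TaxonomyMap, groups) -> pd.DataFrame:
    """Per-group relative abundance of taxonomic classes (rows sum to 1)."""
    values = normalized.values if isinstance(normalized, NormalizedTable) else pd.DataFrame(normalized)
    g = _group_series(groups, values.index)
    classes = taxonomy.classes_for(list(values.columns))
    by_class = values.T.groupby(classes.to_numpy()).sum().T
    totals = by_class.groupby(g, sort=False).sum()
    return totals.div(totals.sum(axis=1), axis=0)


@dataclass
class SimperTable:
    """SIMPER decomposition of mean between-group Bray-Curtis dissimilarity."""

    pair: tuple
    otu_contribution: pd.Series  # delta_i, sums to mean_dissimilarity
    class_contribution: pd.Series
    mean_dissimilarity: float

    @property
    def otu_percent(self) -> pd.Series:
        if self.mean_dissimilarity == 0:
            return self.otu_contribution * 0.0
        return 100.0 * self.otu_contribution / self.mean_dissimilarity

    @property
    def class_percent(self) -> pd.Series:
        if self.mean_dissimilarity == 0:
            return self.class_contribution * 0.0
        return 100.0 * self.class_contribution / self.mean_dissimilarity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "otu": self.otu_contribution.index,
                "contribution": self.otu_contribution.to_numpy(),
                "percent": self.otu_percent.to_numpy(),
            }
        )


def simper(normalized, groups, pair, taxonomy: TaxonomyMap | None = None) -> SimperTable:
    """Per-OTU contribution to the average between-group dissimilarity.

    delta_i = mean over all cross-group sample pairs (a, b) of
    |x_ai - x_bi| / sum_k (x_ak + x_bk); the contributions are additive and
    sum exactly to the mean cross-group Bray-Curtis dissimilarity. Class
    rows are sums of their member OTUs.
    """
    values = _values(normalized)
    g = _group_series(groups, values.index)
    a_label, b_label = pair
    A = values.loc[g == str(a_label)].to_numpy(dtype=float)
    B = values.loc[g == str(b_label)].to_numpy(dtype=float)
    if A.shape[0] == 0 or B.shape[0] == 0:
        raise ValidationError(f"empty group in pair {pair}")
    p = values.shape[1]
    total = np.zeros(p)
    n_pairs = A.shape[0] * B.shape[0]
    for a in A:
        num = np.abs(a[None, :] - B)  # (n_b, p)
        den = (a.sum() + B.sum(axis=1))[:, None]
        total += (num / den).sum(axis=0)
    delta = pd.Series(total / n_pairs, index=values.columns, name="contribution")
    if taxonomy is not None:
        classes = taxonomy.classes_for(list(values.columns))
        class_contrib = delta.groupby(classes.to_numpy()).sum()
    else:
        class_contrib = pd.Series(dtype=float)
    return SimperTable(
        pair=(str(a_label), str(b_label)),
        otu_contribution=delta,
        class_contribution=class_contrib.sort_values(ascending=False),
        mean_dissimilarity=float(delta.sum()),
    )
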