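"""Distance decay of community similarity: per-genus site-pair mean
Bray-Curtis dissimilarity against great-circle distance, and a sequential
ANCOVA on the log-log scale with Monte-Carlo significance obtained by
jointly shuffling the (distance, genus) design rows against the observed
dissimilarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .io import SampleMetadata, ValidationError
from .results import TermTable

__all__ = [
    "haversine_km",
    "distance_decay_table",
    "DistanceDecayAncova",
    "AncovaResults",
]

EARTH_RADIUS_KM = 6371.0
_F_CAP = 1e15  # stand-in for an infinite F on an exact fit


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two points in decimal degrees."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def distance_decay_table(distmat, metadata: SampleMetadata) -> pd.DataFrame:
    """Mean (+/- SE) cross-site Bray-Curtis per genus and unordered site pair.

    One row per genus x distinct site pair, pooling all time points; the
    distance column is the haversine distance between the pair's sites.
    """
    if metadata.site_coords is None:
        raise ValidationError("distance decay requires site coordinates")
    if isinstance(distmat, DistanceMatrix):
        d = distmat.data
        ids = list(distmat.ids)
        meta = metadata.table.loc[ids]
    else:
        d = np.asarray(distmat, dtype=float)
        meta = metadata.table
    genera = [str(g) for g in metadata.levels["genus"]]
    sites = [str(s) for s in metadata.levels["site"]]
    genus_arr = meta["genus"].astype(str).to_numpy()
    site_arr = meta["site"].astype(str).to_numpy()
    rows = []
    for g in genera:
        for sa, sb in combinations(sites, 2):
            ia = np.flatnonzero((genus_arr == g) & (site_arr == sa))
            ib = np.flatnonzero((genus_arr == g) & (site_arr == sb))
            if ia.size == 0 or ib.size == 0:
                warnings.warn(f"genus {g!r} absent at site pair ({sa}, {sb}); omitted")
                continue
            vals = d[np.ix_(ia, ib)].ravel()
            se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
            ca, cb = metadata.site_coords.loc[sa], metadata.site_coords.loc[sb]
            rows.append(
                {
                    "genus": g,
                    "site_a": sa,
                    "site_b": sb,
                    "mean_bray_curtis": float(vals.mean()),
                    "se": se,
                    "n_pairs": int(vals.size),
                    "distance_km": haversine_km(ca["lat"], ca["lon"], cb["lat"], cb["lon"]),
                }
            )
    return pd.DataFrame(rows)


def _sequential_anova(y: np.ndarray, blocks) -> tuple:
    """Sequential (Type-I) sums of squares of y on ordered design blocks.

    Returns (ss per term, df per term, ss_residual, df_residual, ss_total).
    """
    n = y.size
    X = np.ones((n, 1))
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    basis = U[:, s > 1e-10 * s[0]]
    fit_prev = basis @ (basis.T @ y)
    rank_prev = basis.shape[1]
    ss_list, df_list = [], []
    for B in blocks:
        X = np.hstack([X, B])
        U, s, _ = np.linalg.svd(X, full_matrices=False)
        basis = U[:, s > 1e-10 * s[0]]
        fit = basis @ (basis.T @ y)
        ss_list.append(float(np.sum((fit - fit_prev) ** 2)))
        df_list.append(basis.shape[1] - rank_prev)
        fit_prev, rank_prev = fit, basis.shape[1]
    ss_res = float(np.sum((y - fit_prev) ** 2))
    df_res = n - rank_prev
    ybar = y.mean()
    ss_total = float(np.sum((y - ybar) ** 2))
    return np.array(ss_list), np.array(df_list), ss_res, df_res, ss_total


def _design_blocks(log_dist: np.ndarray, genus: np.ndarray, genus_levels) -> list:
    """Ordered blocks: Distance (covariate), Genus, Distance x Genus."""
    blocks = [log_dist[:, None]]
    if len(genus_levels) > 1:
        dummies = np.stack([(genus == g).astype(float) for g in genus_levels], axis=1)
        blocks.append(dummies)
        blocks.append(dummies * log_dist[:, None])
    return blocks


@dataclass
class AncovaResults:
    """Sequential ANCOVA of log dissimilarity on log distance, genus and
    their interaction, with Monte-Carlo permutation p-values."""

    table: TermTable
    slope: float
    r_squared: float
    permutations: int

    def summary(self) -> str:
        head = (
            f"Distance-decay ANCOVA (log-log, {self.permutations} Monte-Carlo shuffles)\n"
            f"Distance slope: {self.slope:.4f}   model R^2: {self.r_squared:.4f}\n"
        )
        return head + self.table.summary()


class DistanceDecayAncova:
    """ANCOVA relating log mean Bray-Curtis to log geographic distance.

    Terms enter sequentially as Distance (km), Genus, Distance x Genus.
    Monte-Carlo significance: the (distance, genus) rows are shuffled
    jointly (``shuffle='joint'``, default) or independently against the
    dissimilarities; each term's p-value is the proportion of shuffles whose
    F meets or exceeds the observed one.
    """

    def __init__(self, decay_table: pd.DataFrame):
        ddt = decay_table
        if np.any(ddt["mean_bray_curtis"] <= 0) or np.any(ddt["distance_km"] <= 0):
            raise ValidationError("log transform requires positive dissimilarity and distance")
        self.y = np.log(ddt["mean_bray_curtis"].to_numpy(dtype=float))
        self.log_dist = np.log(ddt["distance_km"].to_numpy(dtype=float))
        self.genus = ddt["genus"].astype(str).to_numpy()
        self.genus_levels = list(dict.fromkeys(self.genus))
        L = len(self.genus_levels)
        n_par = 2 + (2 * (L - 1) if L > 1 else 0)  # intercept, slope, genus, interaction
        if self.y.size <= n_par:
            raise ValidationError("fewer rows than model parameters")

    def _terms(self):
        if len(self.genus_levels) > 1:
            return ["Distance (km)", "Genus", "Distance x Genus"]
        return ["Distance (km)"]

    def _fstats(self, log_dist, genus):
        blocks = _design_blocks(log_dist, genus, self.genus_levels)
        ss, df, ss_res, df_res, ss_total = _sequential_anova(self.y, blocks)
        if df_res <= 0:
            raise ValidationError("saturated design: zero residual df")
        ms_res = ss_res / df_res
        with np.errstate(divide="ignore"):
            F = np.where(ms_res > 0, (ss / df) / max(ms_res, 1e-300), _F_CAP)
        F = np.minimum(F, _F_CAP)
        return F, ss, df, ss_res, df_res, ss_total

    def fit(self, permutations: int = 999, seed=None, shuffle: str = "joint") -> AncovaResults:
        F, ss, df, ss_res, df_res, ss_total = self._fstats(self.log_dist, self.genus)
        eta2 = ss / ss_total
        pvals = np.full(F.size, np.nan)
        if permutations and permutations > 0:
            rng = np.random.default_rng(seed)
            exceed = np.zeros(F.size)
            n = self.y.size
            for _ in range(permutations):
                if shuffle == "joint":
                    p = rng.permutation(n)
                    F_p = self._fstats(self.log_dist[p], self.genus[p])[0]
                elif shuffle == "independent":
                    F_p = self._fstats(
                        self.log_dist[rng.permutation(n)], self.genus[rng.permutation(n)]
                    )[0]
                else:
                    raise ValueError(f"unknown shuffle mode {shuffle!r}")
                exceed += F_p >= F
            pvals = exceed / permutations  # proportion-of-shuffles rule
        # distance slope from the full model's covariate, via simple projection
        slope = float(np.polyfit(self.log_dist, self.y, 1)[0])
        frame = pd.DataFrame(
            {
                "term": self._terms() + ["Residual"],
                "df": list(df) + [df_res],
                "statistic": list(F) + [np.nan],
                "effect_size": list(eta2) + [ss_res / ss_total],
                "p_value": list(pvals) + [np.nan],
            }
        )
        return AncovaResults(
            table=TermTable(frame, statistic_name="F", effect_name="eta2"),
            slope=slope,
            r_squared=float(ss.sum() / ss_total),
            permutations=permutations or 0,
        )
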