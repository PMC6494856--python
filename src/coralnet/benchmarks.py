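"""Reproducibility experiments: type-I error calibration of the permutation
tests and end-to-end parameter recovery on synthetic surveys.

These are the package's own statistical quality checks; they generate data
with the bundled simulator, run the full analysis path, and report rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import bray_curtis
from .distance_decay import DistanceDecayAncova, distance_decay_table, haversine_km
from .io import normalize_median_of_ratios
from .network import (
    CorrelationNetwork,
    classification_accuracy,
    homophily,
    leading_eigenvector_communities,
    modularity_null,
    sample_correlation,
)
from .permanova import Permanova
from .simulate import DEFAULT_SITE_COORDS, SimulationConfig, simulate

__all__ = ["permanova_type1_rate", "ancova_type1_rate", "parameter_recovery"]


def _null_config(seed: int) -> SimulationConfig:
    """Exchangeable null survey: all effect scales zero, 24 samples."""
    return SimulationConfig(
        n_genera=2, species_per_genus=1, n_sites=2, n_times=2,
        colonies_per_cell=3, n_otus=40,
        sigma_genus=0.0, sigma_site=0.0, sigma_time=0.0,
        core_otus_per_genus=0, core_boost=0.0,
        seed=seed,
    )


def permanova_type1_rate(
    n_sims: int = 500, permutations: int = 199, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the genus term at level alpha under the null."""
    root = np.random.SeedSequence(seed)
    rejections = 0
    for i, ss in enumerate(root.spawn(n_sims)):
        sub = int(ss.generate_state(1)[0] % (2**31 - 1))
        counts, md, _, _ = simulate(_null_config(sub))
        dm = bray_curtis(normalize_median_of_ratios(counts, "pseudo-geomean"))
        res = Permanova(dm, md, ["Genus"]).fit(permutations=permutations, seed=sub + 1)
        if res.table["Genus"]["p_value"] <= alpha:
            rejections += 1
    return rejections / n_sims


def _null_decay_table(rng) -> pd.DataFrame:
    sites = list(DEFAULT_SITE_COORDS)
    rows = []
    for g in ("Porites", "Acropora", "Diploria"):
        for i in range(4):
            for j in range(i + 1, 4):
                rows.append(
                    {
                        "genus": g,
                        "site_a": sites[i],
                        "site_b": sites[j],
                        "mean_bray_curtis": float(rng.uniform(0.2, 0.8)),
                        "se": 0.0,
                        "distance_km": haversine_km(
                            *DEFAULT_SITE_COORDS[sites[i]], *DEFAULT_SITE_COORDS[sites[j]]
                        ),
                    }
                )
    return pd.DataFrame(rows)


def ancova_type1_rate(
    n_sims: int = 500, permutations: int = 199, alpha: float = 0.05, seed: int = 0
) -> float:
    """Rejection rate of the distance term when dissimilarity is independent
    of both distance and genus."""
    root = np.random.SeedSequence(seed)
    rejections = 0
    for ss in root.spawn(n_sims):
        sub = int(ss.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(sub)
        ddt = _null_decay_table(rng)
        res = DistanceDecayAncova(ddt).fit(permutations=permutations, seed=sub + 1)
        if res.table["Distance (km)"]["p_value"] <= alpha:
            rejections += 1
    return rejections / n_sims


def _recovery_config(seed: int) -> SimulationConfig:
    # generator defaults (dominant genus effect, spatial kernel on) at a
    # reduced problem size: 144 samples x 120 OTUs
    return SimulationConfig(seed=seed, colonies_per_cell=2, n_otus=120)


def parameter_recovery(
    n_reps: int = 50, null_permutations: int = 99, seed: int = 0
) -> dict:
    """Fraction of replicate synthetic surveys in which each planted feature
    is recovered by the pipeline.

    Checks per replicate: PERMANOVA R^2 ordering genus > site > time;
    homophily(genus) > homophily(site) > 0; module classification accuracy
    for genus at least that of site and time; modularity-null p <= 0.05;
    positive log-log distance-decay slope.
    """
    root = np.random.SeedSequence(seed)
    hits = {
        "r2_ordering": 0,
        "homophily_ordering": 0,
        "module_purity": 0,
        "modularity_null": 0,
        "decay_slope": 0,
    }
    for ss in root.spawn(n_reps):
        sub = int(ss.generate_state(1)[0] % (2**31 - 1))
        counts, md, _, _ = simulate(_recovery_config(sub))
        norm = normalize_median_of_ratios(counts, "pseudo-geomean")
        dm = bray_curtis(norm)

        r2 = Permanova(dm, md, ["Genus", "Site", "Time"]).fit(permutations=0).r_squared
        if r2["Genus"] > r2["Site"] > r2["Time"]:
            hits["r2_ordering"] += 1

        r = sample_correlation(norm)
        hg = homophily(r, md.factor("genus"), "genus")
        hs = homophily(r, md.factor("site"), "site")
        if hg.homophily > hs.homophily > 0:
            hits["homophily_ordering"] += 1

        net = CorrelationNetwork(list(r.index), r.to_numpy())
        part = leading_eigenvector_communities(net)
        acc = {
            f: classification_accuracy(part, md.factor(f), md.levels[f])
            for f in ("genus", "site", "time")
        }
        if acc["genus"] >= max(acc["site"], acc["time"]):
            hits["module_purity"] += 1

        p_null, _, _ = modularity_null(
            net, md.factor("genus"), permutations=null_permutations, seed=sub + 1
        )
        if p_null <= 0.05:
            hits["modularity_null"] += 1

        slope = DistanceDecayAncova(distance_decay_table(dm, md)).fit(permutations=0).slope
        if slope > 0:
            hits["decay_slope"] += 1
    return {k: v / n_reps for k, v in hits.items()}
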