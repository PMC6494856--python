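"""Synthetic coral-microbiome data with the statistical structure the
analysis pipeline assumes.

The generator emulates a repeated-measures reef survey: tagged colonies of
several coral species (nested in genera) at a handful of reef sites sampled
at a few time points. Per-OTU log-intensities combine a baseline, additive
genus/site/time effects and per-sample noise; site effects are spatially
correlated through an exponential kernel on great-circle distance, so
community dissimilarity decays with geography. Counts are overdispersed
(negative-binomial by default) with log-normal library sizes, and each genus
carries a planted set of high-occupancy core OTUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .distance_decay import haversine_km
from .io import CountTable, SampleMetadata, TaxonomyMap

__all__ = ["SimulationConfig", "SimulationTruth", "simulate", "fixture_small"]

# The four reef sites of the emulated survey (decimal degrees).
DEFAULT_SITE_COORDS = {
    "PC": (9.37804, -82.30335),
    "CB": (9.36028, -82.27760),
    "C14": (9.25398, -82.12595),
    "C4": (9.25862, -82.12708),
}

DEFAULT_GENERA = ("Porites", "Acropora", "Diploria")
DEFAULT_TIMES = ("December", "April", "October")

CLASS_POOL = (
    "Gammaproteobacteria",
    "Epsilonproteobacteria",
    "Betaproteobacteria",
    "Alphaproteobacteria",
    "Cytophagia",
    "Synechococcophycideae",
    "Bacilli",
    "Flavobacteriia",
)


@dataclass
class SimulationConfig:
    """Study-design and distributional parameters of the generator.

    Defaults encode the emulated survey: 3 genera x 2 species x 4 sites x
    3 times with 4 colonies per species-site cell (96 colonies, each
    resampled at every time point), a dominant host effect
    (sigma_genus > sigma_site > sigma_time, log-abundance sd), spatially
    correlated site effects with a 5 km range, log-normal sequencing depth
    with median 10^4 reads, and a shared negative-binomial dispersion.
    """

    n_genera: int = 3
    species_per_genus: int = 2
    n_sites: int = 4
    n_times: int = 3
    colonies_per_cell: int = 4  # colonies per species x site cell
    n_otus: int = 250
    sigma_genus: float = 1.0
    sigma_site: float = 0.5
    sigma_time: float = 0.25
    sigma_noise: float = 0.6
    sigma_base: float = 1.0
    spatial_range_km: float | None = 5.0  # None/0 -> independent site effects
    site_coords: dict = field(default_factory=lambda: dict(DEFAULT_SITE_COORDS))
    core_otus_per_genus: int = 10
    core_occupancy: float = 0.97
    core_boost: float = 2.5  # log-abundance lift of a genus's core OTUs
    depth_log_mean: float = float(np.log(1e4))
    depth_log_sd: float = 0.5
    dispersion: float = 0.5  # NB size parameter k; variance = mu + mu^2/k
    count_law: str = "nb"  # or "dirichlet-multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.core_occupancy <= 1:
            raise ValueError("core occupancy target must lie in (0, 1]")
        for name in ("sigma_genus", "sigma_site", "sigma_time", "sigma_noise", "sigma_base"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genera * self.core_otus_per_genus > self.n_otus:
            raise ValueError("not enough OTUs for the requested core sets")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the generated tables."""

    base_log_abundance: np.ndarray  # (n_otus,)
    genus_effects: pd.DataFrame  # genus x otu
    site_effects: pd.DataFrame  # site x otu
    time_effects: pd.DataFrame  # time x otu
    core_otus: dict  # genus -> list of otu ids
    expected_composition: pd.DataFrame  # sample x otu relative intensities
    config: SimulationConfig


def _names(prefix_list, n, fallback):
    if n <= len(prefix_list):
        return [str(x) for x in prefix_list[:n]]
    return [f"{fallback}{i + 1}" for i in range(n)]


def _site_layout(config) -> tuple:
    sites = _names(list(config.site_coords), config.n_sites, "S")
    coords = {}
    for i, s in enumerate(sites):
        if s in config.site_coords:
            coords[s] = config.site_coords[s]
        else:  # synthetic grid fallback for extra sites
            coords[s] = (9.3 + 0.02 * i, -82.3 + 0.03 * i)
    return sites, coords


def simulate(config: SimulationConfig):
    """Generate (CountTable, SampleMetadata, TaxonomyMap, SimulationTruth)."""
    rng = np.random.default_rng(config.seed)
    genera = _names(DEFAULT_GENERA, config.n_genera, "Genus")
    times = _names(DEFAULT_TIMES, config.n_times, "T")
    sites, coords = _site_layout(config)
    species = {
        g: [f"{g}_sp{k + 1}" for k in range(config.species_per_genus)] for g in genera
    }
    otus = [f"OTU_{i:04d}" for i in range(config.n_otus)]
    p = config.n_otus

    base = rng.normal(0.0, config.sigma_base, size=p)
    genus_eff = {g: rng.normal(0.0, config.sigma_genus, size=p) for g in genera}

    # planted core OTUs: first blocks of the OTU list, one block per genus
    core = {}
    for gi, g in enumerate(genera):
        ids = otus[gi * config.core_otus_per_genus : (gi + 1) * config.core_otus_per_genus]
        core[g] = ids
        for o in ids:
            genus_eff[g][otus.index(o)] += config.core_boost

    # spatially correlated site effects via exponential kernel on distance
    n_s = len(sites)
    D = np.zeros((n_s, n_s))
    for i in range(n_s):
        for j in range(n_s):
            D[i, j] = haversine_km(*coords[sites[i]], *coords[sites[j]])
    if config.spatial_range_km and config.spatial_range_km > 0:
        K = np.exp(-D / config.spatial_range_km)
    else:
        K = np.eye(n_s)
    L = np.linalg.cholesky(K + 1e-10 * np.eye(n_s))
    site_eff_mat = config.sigma_site * (L @ rng.normal(size=(n_s, p)))
    site_eff = {s: site_eff_mat[i] for i, s in enumerate(sites)}
    time_eff = {t: rng.normal(0.0, config.sigma_time, size=p) for t in times}

    rows, meta_rows, expected = [], [], []
    sample_ids = []
    colony_counter = 0
    for g in genera:
        for sp in species[g]:
            for s in sites:
                for _ in range(config.colonies_per_cell):
                    colony_counter += 1
                    colony = f"colony{colony_counter:03d}"
                    for t in times:
                        sid = f"{colony}_{t}"
                        eps = rng.normal(0.0, config.sigma_noise, size=p)
                        lam = np.exp(base + genus_eff[g] + site_eff[s] + time_eff[t] + eps)
                        rel = lam / lam.sum()
                        depth = rng.lognormal(config.depth_log_mean, config.depth_log_sd)
                        mu = rel * depth
                        if config.count_law == "nb":
                            k = config.dispersion
                            counts = rng.negative_binomial(k, k / (k + mu))
                        elif config.count_law == "dirichlet-multinomial":
                            alpha = np.maximum(rel * config.dispersion * p, 1e-9)
                            probs = rng.dirichlet(alpha)
                            counts = rng.multinomial(int(round(depth)), probs)
                        else:
                            raise ValueError(f"unknown count_law {config.count_law!r}")
                        if counts.sum() == 0:
                            counts[int(np.argmax(mu))] = 1
                        rows.append(counts)
                        expected.append(rel)
                        sample_ids.append(sid)
                        meta_rows.append(
                            {
                                "sample": sid,
                                "genus": g,
                                "species": sp,
                                "site": s,
                                "time": t,
                                "colony": colony,
                            }
                        )

    counts = pd.DataFrame(np.array(rows), index=sample_ids, columns=otus)
    meta = pd.DataFrame(meta_rows).set_index("sample")

    # occupancy floor: seed presences so every planted core OTU reaches the
    # target prevalence within its genus
    for g in genera:
        g_rows = meta.index[meta["genus"] == g]
        need = int(np.ceil(config.core_occupancy * len(g_rows)))
        for o in core[g]:
            present = counts.loc[g_rows, o] > 0
            deficit = need - int(present.sum())
            if deficit > 0:
                zeros = list(g_rows[~present])
                fill = rng.choice(len(zeros), size=deficit, replace=False)
                counts.loc[[zeros[i] for i in fill], o] = 1

    # taxonomy: each genus's core OTUs share a designated enriched class
    class_by_genus = dict(zip(genera, CLASS_POOL))
    lineages = {}
    for i, o in enumerate(otus):
        cls = None
        for g in genera:
            if o in core[g]:
                cls = class_by_genus[g]
        if cls is None:
            cls = CLASS_POOL[int(rng.integers(len(CLASS_POOL)))]
        lineages[o] = {
            "kingdom": "Bacteria",
            "phylum": "Proteobacteria" if "proteo" in cls.lower() else "Other",
            "class": cls,
            "order": f"o_{cls[:6]}",
            "family": f"f_{i % 17}",
            "genus": f"g_{i % 53}",
        }

    coord_df = pd.DataFrame(
        {"lat": [coords[s][0] for s in sites], "lon": [coords[s][1] for s in sites]},
        index=pd.Index(sites, name="site"),
    )
    metadata = SampleMetadata(meta, site_coords=coord_df)
    truth = SimulationTruth(
        base_log_abundance=base,
        genus_effects=pd.DataFrame(genus_eff, index=otus).T,
        site_effects=pd.DataFrame(site_eff, index=otus).T,
        time_effects=pd.DataFrame(time_eff, index=otus).T,
        core_otus=core,
        expected_composition=pd.DataFrame(np.array(expected), index=sample_ids, columns=otus),
        config=config,
    )
    return CountTable(counts), metadata, TaxonomyMap(lineages), truth


def fixture_small(seed: int = 0):
    """Deterministic miniature dataset: 12 samples, 20 OTUs, two genera with
    block-structured abundances (two planted network modules), one planted
    core OTU per genus, hand-checkable values."""
    rng = np.random.default_rng(seed)
    genera = ["Porites", "Acropora"]
    sites = ["PC", "CB"]
    times = ["December", "April", "October"]
    otus = [f"OTU_{i:02d}" for i in range(20)]
    sample_ids, meta_rows, rows = [], [], []
    colony = 0
    for gi, g in enumerate(genera):
        block = slice(gi * 10, gi * 10 + 10)
        for s in sites:
            colony += 1
            for t in times:
                sid = f"c{colony:02d}_{t}"
                counts = rng.integers(0, 3, size=20)
                counts[block] = 60 + rng.integers(0, 40, size=10)
                counts[gi * 10] = 80  # planted core OTU: always present
                rows.append(counts)
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample": sid, "genus": g, "species": f"{g}_sp1", "site": s, "time": t}
                )
    counts = pd.DataFrame(np.array(rows), index=sample_ids, columns=otus)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    coord_df = pd.DataFrame(
        {
            "lat": [DEFAULT_SITE_COORDS[s][0] for s in sites],
            "lon": [DEFAULT_SITE_COORDS[s][1] for s in sites],
        },
        index=pd.Index(sites, name="site"),
    )
    lineages = {}
    for i, o in enumerate(otus):
        cls = "Gammaproteobacteria" if i < 10 else "Epsilonproteobacteria"
        lineages[o] = {"kingdom": "Bacteria", "phylum": "Proteobacteria", "class": cls}
    truth = {
        "core_otus": {"Porites": ["OTU_00"], "Acropora": ["OTU_10"]},
        "blocks": {"Porites": otus[:10], "Acropora": otus[10:]},
    }
    return (
        CountTable(counts),
        SampleMetadata(meta, site_coords=coord_df),
        TaxonomyMap(lineages),
        truth,
    )
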