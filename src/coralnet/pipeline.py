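"""End-to-end orchestration: normalize -> core -> class profiles ->
Bray-Curtis -> PERMANOVA (+ pairwise) -> SIMPER -> distance decay ANCOVA ->
network suite, with a JSON manifest recording config, seeds and timings."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import bray_curtis, class_abundance_profile, core_microbiome, simper
from .distance_decay import DistanceDecayAncova, distance_decay_table
from .io import (
    normalize_median_of_ratios,
    read_count_table,
    read_metadata,
    read_taxonomy,
    write_results,
)
from .network import (
    CorrelationNetwork,
    centrality_group_tests,
    classification_accuracy,
    eigen_centrality,
    homophily,
    leading_eigenvector_communities,
    module_factor_chisq,
    modularity_null,
)
from .permanova import Permanova, pairwise_permanova
from .simulate import SimulationConfig, simulate

log = logging.getLogger("coralnet")

DEFAULT_TERMS = [
    "Genus",
    "Site",
    "Time",
    "Species(Genus)",
    "Genus:Site",
    "Genus:Time",
    "Site:Time",
    "Species(Genus):Site",
    "Species(Genus):Time",
    "Genus:Site:Time",
    "Species(Genus):Site:Time",
]


class StageError(RuntimeError):
    """A pipeline stage failed; earlier outputs are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat configuration of a full analysis run (YAML-loadable)."""

    counts: str | None = None
    counts_format: str = "tsv"
    metadata: str | None = None
    site_coords: str | None = None
    taxonomy: str | None = None
    simulate: bool = False
    simulation: dict = field(default_factory=dict)
    zero_policy: str = "pseudo-geomean"
    core_threshold: float = 0.95
    terms: list = field(default_factory=lambda: list(DEFAULT_TERMS))
    permutations: int = 999
    null_permutations: int = 999
    negative_policy: str = "truncate"
    seed: int = 17
    outdir: str = "coralnet_out"
    skip: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _load_inputs(config: RunConfig):
    if config.simulate:
        sim = SimulationConfig(**{**config.simulation, "seed": config.seed})
        counts, metadata, taxonomy, _ = simulate(sim)
        return counts, metadata, taxonomy
    if not (config.counts and config.metadata and config.taxonomy):
        raise ValueError("provide counts/metadata/taxonomy paths or set simulate: true")
    counts = read_count_table(config.counts, format=config.counts_format)
    metadata = read_metadata(config.metadata, coords_path=config.site_coords)
    metadata.check_samples(counts)
    metadata.table = metadata.table.loc[counts.sample_ids]
    taxonomy = read_taxonomy(config.taxonomy)
    return counts, metadata, taxonomy


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns the in-memory result bundle and
    writes per-stage CSV/JSON files plus ``manifest.json`` under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: int(ss.generate_state(1)[0] % (2**31 - 1))
        for name, ss in zip(
            ["permanova", "pairwise", "ancova", "network"],
            np.random.SeedSequence(config.seed).spawn(4),
        )
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "timings_s": {},
    }
    results: dict = {}
    skip = set(config.skip)

    def stage(name, fn):
        if name in skip:
            log.info("skipping stage %s", name)
            return None
        t0 = time.perf_counter()
        log.info("stage %s", name)
        try:
            out = fn()
        except Exception as exc:
            _write_manifest(outdir, manifest)
            raise StageError(name, exc) from exc
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        return out

    counts, metadata, taxonomy = stage("load", lambda: _load_inputs(config))
    genus = metadata.factor("genus")
    site = metadata.factor("site")
    tfac = metadata.factor("time")

    normalized = stage("normalize", lambda: normalize_median_of_ratios(counts, config.zero_policy))
    normalized.size_factors.to_csv(outdir / "size_factors.csv")
    results["normalized"] = normalized

    def _core():
        cores = core_microbiome(counts, normalized, genus, taxonomy, config.core_threshold)
        payload = {
            g: {
                "core_otus": c.core_otus,
                "prevalence": {o: float(c.prevalence[o]) for o in c.core_otus},
                "class_abundance": c.class_abundance.to_dict(),
            }
            for g, c in cores.items()
        }
        with open(outdir / "core_microbiome.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        return cores

    results["core"] = stage("core", _core)

    def _profiles():
        prof = class_abundance_profile(normalized, taxonomy, genus)
        prof.to_csv(outdir / "class_profiles.csv")
        cell = genus.astype(str) + "/" + site.astype(str) + "/" + tfac.astype(str)
        per_cell = class_abundance_profile(normalized, taxonomy, cell)
        per_cell.to_csv(outdir / "class_profiles_by_cell.csv")
        return prof

    results["class_profiles"] = stage("class_profiles", _profiles)

    dm = stage("bray_curtis", lambda: bray_curtis(normalized))
    results["distance"] = dm

    def _permanova():
        res = Permanova(dm, metadata, config.terms).fit(
            permutations=config.permutations, seed=seeds["permanova"]
        )
        res.table.to_csv(outdir / "permanova.csv")
        return res

    results["permanova"] = stage("permanova", _permanova)

    def _pairwise():
        out = {}
        for factor in ("genus", "site", "time"):
            tt = pairwise_permanova(
                dm, metadata, factor, permutations=config.permutations, seed=seeds["pairwise"]
            )
            tt.to_csv(outdir / f"pairwise_{factor}.csv")
            out[factor] = tt
        return out

    results["pairwise"] = stage("pairwise", _pairwise)

    def _simper():
        levels = [str(x) for x in metadata.levels["genus"]]
        out = {}
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                pair = (levels[i], levels[j])
                st = simper(normalized, genus, pair, taxonomy)
                write_results(st, outdir / f"simper_{pair[0]}_vs_{pair[1]}.csv")
                out[pair] = st
        return out

    results["simper"] = stage("simper", _simper)

    def _decay():
        ddt = distance_decay_table(dm, metadata)
        ddt.to_csv(outdir / "distance_decay.csv", index=False)
        res = DistanceDecayAncova(ddt).fit(
            permutations=config.permutations, seed=seeds["ancova"]
        )
        res.table.to_csv(outdir / "ancova.csv")
        return ddt, res

    results["distance_decay"] = stage("distance_decay", _decay)

    def _network():
        net = CorrelationNetwork.from_table(normalized, config.negative_policy)
        homo = {
            f: homophily(pd.DataFrame(net.r, index=net.ids, columns=net.ids), metadata.factor(f), f)
            for f in ("genus", "site", "time")
        }
        pd.DataFrame(
            [
                {"factor": f, "homophily": h.homophily, "heterophily": h.heterophily}
                for f, h in homo.items()
            ]
        ).to_csv(outdir / "homophily.csv", index=False)
        part = leading_eigenvector_communities(net)
        chisq = {}
        accuracy = {}
        for f in ("genus", "species", "site", "time"):
            chisq[f] = module_factor_chisq(part, metadata.factor(f), f)
            accuracy[f] = classification_accuracy(
                part, metadata.factor(f), metadata.levels[f]
            )
        pd.concat([c.to_frame() for c in chisq.values()]).to_csv(
            outdir / "module_chisq.csv", index=False
        )
        null_p, q_obs, _ = modularity_null(
            net, genus, permutations=config.null_permutations, seed=seeds["network"]
        )
        cent = eigen_centrality(net)
        cent_tests = {
            f: centrality_group_tests(cent, metadata.factor(f), f, metadata.levels[f])
            for f in ("genus", "species", "site", "time")
        }
        node_table = pd.DataFrame(
            {
                "sample": net.ids,
                "module": part.assignment.to_numpy(),
                "eigen_centrality": cent.to_numpy(),
            }
        )
        node_table.to_csv(outdir / "network_nodes.csv", index=False)
        net.edge_list().to_csv(outdir / "network_edges.csv", index=False)
        summary = {
            "n_modules": part.n_modules,
            "modularity": part.modularity,
            "modularity_null_p": null_p,
            "classification_accuracy": accuracy,
        }
        with open(outdir / "network_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        return {
            "network": net,
            "partition": part,
            "homophily": homo,
            "chisq": chisq,
            "accuracy": accuracy,
            "modularity_null_p": null_p,
            "centrality": cent,
            "centrality_tests": cent_tests,
        }

    results["network"] = stage("network", _network)

    _write_manifest(outdir, manifest)
    results["manifest"] = manifest
    return results


def _write_manifest(outdir: Path, manifest: dict) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
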