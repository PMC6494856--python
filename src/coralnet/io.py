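"""Readers, writers, validation and the core data model.

The canonical in-memory orientation is samples-as-rows x OTUs-as-columns,
held in pandas DataFrames. Readers accept either orientation (``transpose``
flag for TSV; BIOM v1.0 stores observations as rows and is transposed on
read). All downstream stages consume these containers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "CountTable",
    "NormalizedTable",
    "SampleMetadata",
    "TaxonomyMap",
    "read_count_table",
    "read_metadata",
    "read_taxonomy",
    "normalize_median_of_ratios",
    "write_results",
]

FACTORS = ("genus", "species", "site", "time")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class CountTable:
    """Samples x OTUs matrix of non-negative integer counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "OTU")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric counts in table")
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[r]!r}, OTU {df.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integers")
        totals = arr.sum(axis=1)
        if np.any(totals <= 0):
            bad = df.index[int(np.argmin(totals))]
            raise ValidationError(f"empty sample (total count 0): {bad!r}")
        self.counts = df.astype(np.int64)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, path, transpose: bool = False) -> "CountTable":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:  # malformed header / ragged rows
            raise ValidationError(f"malformed count table {path}: {exc}") from exc
        if df.empty:
            raise ValidationError(f"empty count table: {path}")
        if transpose:
            df = df.T
        for col in df.columns:
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise ValidationError(f"non-numeric counts in column {col!r}")
        df.index = pd.Index([str(x) for x in df.index], name=None)
        df.columns = pd.Index([str(x) for x in df.columns], name=None)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_biom_json(cls, path) -> "CountTable":
        with open(path) as fh:
            doc = json.load(fh)
        for key in ("rows", "columns", "shape", "matrix_type", "data"):
            if key not in doc:
                raise ValidationError(f"BIOM file missing field {key!r}")
        n_obs, n_samp = doc["shape"]
        otus = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        if len(otus) != n_obs or len(samples) != n_samp:
            raise ValidationError("BIOM shape does not match row/column lists")
        mat = np.zeros((n_obs, n_samp))
        if doc["matrix_type"] == "dense":
            mat[:] = np.asarray(doc["data"], dtype=float)
        elif doc["matrix_type"] == "sparse":
            for i, j, v in doc["data"]:
                mat[int(i), int(j)] = v
        else:
            raise ValidationError(f"unknown BIOM matrix_type {doc['matrix_type']!r}")
        # BIOM stores observations (OTUs) as rows; canonical orientation is samples x OTUs
        df = pd.DataFrame(mat.T, index=samples, columns=otus)
        return cls(df)

    def to_biom_json(self, path) -> None:
        arr = self.counts.to_numpy()
        data = [
            [int(i), int(j), int(arr[j, i])]
            for i in range(arr.shape[1])
            for j in range(arr.shape[0])
            if arr[j, i] != 0
        ]
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "coralnet",
            "date": "",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(self.otu_ids), len(self.sample_ids)],
            "rows": [{"id": o, "metadata": None} for o in self.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in self.sample_ids],
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


@dataclass
class NormalizedTable:
    """Library-size corrected abundances: values[j, i] = counts[j, i] / s_j."""

    values: pd.DataFrame
    size_factors: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.size_factors.to_numpy() <= 0):
            raise ValidationError("size factors must be strictly positive")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class SampleMetadata:
    """Per-sample design factors plus per-site coordinates.

    Factor levels are recorded in first-appearance order, which fixes the
    ordering used for deterministic permutation streams and tie-breaking.
    """

    table: pd.DataFrame
    site_coords: pd.DataFrame | None = None
    levels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        missing = [c for c in FACTORS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        self.table = self.table.astype({c: str for c in FACTORS})
        # species -> genus must be a function
        sp2g = {}
        for sp, g in zip(self.table["species"], self.table["genus"]):
            if sp in sp2g and sp2g[sp] != g:
                raise ValidationError(
                    f"species {sp!r} mapped to two genera: {sp2g[sp]!r} and {g!r}"
                )
            sp2g[sp] = g
        if not self.levels:
            self.levels = {
                c: list(dict.fromkeys(self.table[c])) for c in FACTORS
            }
        if self.site_coords is not None:
            sc = self.site_coords
            for col in ("lat", "lon"):
                if col not in sc.columns:
                    raise ValidationError(f"site coordinates missing column {col!r}")
            if not np.all(np.isfinite(sc[["lat", "lon"]].to_numpy())):
                raise ValidationError("non-finite site coordinate")
            if np.any(np.abs(sc["lat"]) > 90) or np.any(np.abs(sc["lon"]) > 180):
                raise ValidationError("site coordinate out of range")

    def check_samples(self, count_table: CountTable) -> None:
        meta = set(self.table.index)
        counts = set(count_table.sample_ids)
        only_counts = counts - meta
        only_meta = meta - counts
        if only_counts:
            raise ValidationError(
                f"samples in counts but not metadata: {sorted(only_counts)[:5]}"
            )
        if only_meta:
            raise ValidationError(
                f"samples in metadata but not counts: {sorted(only_meta)[:5]}"
            )

    def factor(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(name)
        return self.table[name]


RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
_RANK_PREFIX = dict(zip("kpcofg", RANKS))


@dataclass
class TaxonomyMap:
    """OTU -> ordered lineage; missing ranks rendered as unclassified_<parent>."""

    lineages: dict

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyMap":
        lineages = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.lower().startswith("otu"):
                    # tolerate a header row
                    if ln == 1 and "\t" in line and line.split("\t")[0].lower() in ("otu", "otu_id", "#otu id"):
                        continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValidationError(f"taxonomy line {ln}: expected 'otu<TAB>lineage'")
                lineages[parts[0]] = cls.parse_lineage(parts[1])
        return cls(lineages)

    @staticmethod
    def parse_lineage(s: str) -> dict:
        out = {}
        for token in s.split(";"):
            token = token.strip()
            if len(token) >= 3 and token[1:3] == "__":
                rank = _RANK_PREFIX.get(token[0])
                if rank:
                    out[rank] = token[3:].strip()
        return out

    def rank_of(self, otu: str, rank: str) -> str:
        lineage = self.lineages.get(otu, {})
        if lineage.get(rank):
            return lineage[rank]
        # fall back to the deepest named parent so aggregation conserves abundance
        parent = "unclassified"
        for r in RANKS:
            if r == rank:
                break
            if lineage.get(r):
                parent = lineage[r]
        return f"unclassified_{parent}" if parent != "unclassified" else "unclassified"

    def class_of(self, otu: str) -> str:
        return self.rank_of(otu, "class")

    def classes_for(self, otu_ids) -> pd.Series:
        return pd.Series({o: self.class_of(o) for o in otu_ids}).reindex(otu_ids)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("otu\tlineage\n")
            for otu, lin in self.lineages.items():
                tokens = [f"{r[0]}__{lin.get(r, '')}" for r in RANKS]
                fh.write(f"{otu}\t{'; '.join(tokens)}\n")


def read_count_table(path, format: str = "tsv", transpose: bool = False) -> CountTable:
    """Read an OTU count table from TSV or BIOM v1.0 JSON."""
    if format == "tsv":
        return CountTable.from_tsv(path, transpose=transpose)
    if format in ("biom-json", "biom"):
        return CountTable.from_biom_json(path)
    raise ValueError(f"unknown count-table format {format!r}")


def read_metadata(path, coords_path=None) -> SampleMetadata:
    """Read a sample metadata TSV (sample, genus, species, site, time).

    Site coordinates come either from inline ``lat``/``lon`` columns or from
    a separate TSV with columns site, lat, lon.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    df = df.set_index(first)
    df.index = df.index.astype(str)
    coords = None
    if coords_path is not None:
        coords = pd.read_csv(coords_path, sep="\t").set_index("site")
        coords = coords[["lat", "lon"]].astype(float)
    elif {"lat", "lon"} <= set(df.columns):
        coords = (
            df.groupby("site")[["lat", "lon"]]
            .first()
            .astype(float)
        )
        df = df.drop(columns=["lat", "lon"])
    return SampleMetadata(df, site_coords=coords)


def read_taxonomy(path) -> TaxonomyMap:
    return TaxonomyMap.from_tsv(path)


def normalize_median_of_ratios(
    table: CountTable, zero_policy: str = "all-positive-reference"
) -> NormalizedTable:
    """Median-of-ratios library-size normalization.

    Size factor s_j = median over reference OTUs of counts[j, i] / g_i where
    g_i is OTU i's geometric mean across samples. Under the default
    ``all-positive-reference`` policy the reference set is the OTUs with no
    zero count in any sample (the classical estimator); ``pseudo-geomean``
    computes geometric means over positive entries only and takes each
    sample's median over the OTUs it actually contains (poscounts-style),
    which is the practical choice for sparse 16S tables.
    """
    counts = table.counts.to_numpy(dtype=float)
    n, p = counts.shape
    if n < 2:
        raise ValidationError("normalization requires at least 2 samples")
    if zero_policy == "all-positive-reference":
        ref = np.all(counts > 0, axis=0)
        if not ref.any():
            raise ValidationError(
                "no OTU has positive counts in every sample; "
                "use zero_policy='pseudo-geomean'"
            )
        log_g = np.log(counts[:, ref]).mean(axis=0)
        ratios = np.log(counts[:, ref]) - log_g
        s = np.exp(np.median(ratios, axis=1))
    elif zero_policy == "pseudo-geomean":
        with np.errstate(divide="ignore"):
            logc = np.where(counts > 0, np.log(counts), np.nan)
        seen = (counts > 0).any(axis=0)  # OTUs absent everywhere carry no information
        log_g = np.full(p, np.nan)
        log_g[seen] = np.nanmean(logc[:, seen], axis=0)
        usable = np.isfinite(log_g)
        if not usable.any():
            raise ValidationError("no usable OTU for size-factor estimation")
        s = np.empty(n)
        for j in range(n):
            mask = (counts[j] > 0) & usable
            if not mask.any():
                raise ValidationError(
                    f"sample {table.sample_ids[j]!r} shares no OTU with the reference"
                )
            s[j] = np.exp(np.median(logc[j, mask] - log_g[mask]))
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    values = pd.DataFrame(
        counts / s[:, None], index=table.counts.index, columns=table.counts.columns
    )
    return NormalizedTable(values, pd.Series(s, index=table.counts.index, name="size_factor"))


def write_results(obj, path, format: str = "csv") -> None:
    """Serialize any result object that exposes ``to_frame``/``to_dict``.

    CSV output uses pandas' RFC-4180 quoting; JSON output is a plain dump of
    ``to_dict()`` (falling back to the frame's records).
    """
    if format == "csv":
        frame = obj.to_frame() if hasattr(obj, "to_frame") else pd.DataFrame(obj)
        frame.to_csv(path, index=False)
    elif format == "json":
        if hasattr(obj, "to_dict"):
            payload = obj.to_dict()
        elif hasattr(obj, "to_frame"):
            payload = obj.to_frame().to_dict(orient="records")
        else:
            payload = obj
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=_json_default)
    else:
        raise ValueError(f"unknown output format {format!r}")


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
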