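"""Core domain objects and tab-separated I/O.

The central object is the :class:`AsvTable` — a samples × ASVs matrix of
non-negative integer read counts — together with per-sample metadata placing
each sample at a site, habitat (bacterioplankton, biofilm or riparian soil),
sampling occasion and dendritic network position, and an environment table
keyed by (site, occasion). All joins between community and environment go
through the (site_id, occasion) key, never through parsing of sample names.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

HABITATS = ("bacterioplankton", "biofilm", "soil")

#: Named environmental variable sets. Membership is declared here, not inferred.
VARIABLE_SETS: dict[str, tuple[str, ...]] = {
    "water_chemistry": ("pH", "TotP", "NO2NO3", "SUVA"),
    "physical": ("temperature", "water_level"),
    "soil": ("soil_pH", "conductivity", "TotC", "TotN"),
}

METADATA_COLUMNS = (
    "sample_id",
    "site_id",
    "habitat",
    "occasion",
    "date",
    "dendritic_distance_km",
)


class ValidationError(ValueError):
    """A structural invariant of a domain object is violated."""


def _check_unique(ids: Sequence, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dups[:5]}")


class AsvTable:
    """Samples × ASVs matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame with sample identifiers as the index and ASV identifiers as
        columns, or anything coercible to one via ``pd.DataFrame``.
    """

    def __init__(self, counts: pd.DataFrame):
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(counts)
        if counts.shape[0] < 1 or counts.shape[1] < 1:
            raise ValidationError("AsvTable needs at least one sample and one ASV")
        _check_unique(counts.index, "sample")
        _check_unique(counts.columns, "ASV")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("AsvTable counts must be numeric")
        if np.isnan(values.astype(float)).any():
            raise ValidationError("AsvTable counts contain missing values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {counts.index[i]!r}, ASV {counts.columns[j]!r}"
            )
        if not np.allclose(values, np.round(values.astype(float))):
            i, j = np.argwhere(values != np.round(values.astype(float)))[0]
            raise ValidationError(
                f"non-integer count at sample {counts.index[i]!r}, ASV {counts.columns[j]!r}"
            )
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def richness(self) -> pd.Series:
        """Observed number of ASVs with count > 0 per sample."""
        return (self.counts > 0).sum(axis=1)

    def select_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        missing = [s for s in sample_ids if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown sample identifiers: {missing[:5]}")
        return AsvTable(self.counts.loc[list(sample_ids)])

    def __eq__(self, other) -> bool:
        return isinstance(other, AsvTable) and self.counts.equals(other.counts)

    def __repr__(self) -> str:
        return f"AsvTable({self.shape[0]} samples x {self.shape[1]} ASVs)"


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labelled matrix of pairwise dissimilarities.

    Missing pairs (e.g. environmental distances involving missing variables)
    are NaN; symmetry and the zero diagonal are enforced at construction.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        n = len(self.labels)
        _check_unique(self.labels, "distance-matrix")
        if values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {values.shape} does not match {n} labels"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(values - values.T), initial=0.0) > 1e-12:
                raise ValidationError("distance matrix is not symmetric within 1e-12")
        mism = np.isnan(values) != np.isnan(values.T)
        if mism.any():
            raise ValidationError("missing entries are not symmetric")
        if np.abs(np.diagonal(values)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal is not zero")
        finite = values[~np.isnan(values)]
        if (finite < 0).any():
            raise ValidationError("distance matrix has negative entries")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        """Restriction to ``keep``, preserving the order of ``keep``."""
        idx = [self.index(l) for l in keep]
        return DistanceMatrix(tuple(str(l) for l in keep), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LoggerSeries:
    """Sub-daily logger record for one site and one physical variable."""

    site_id: str
    variable: str
    timestamps: tuple  # datetime-like, strictly increasing
    values: tuple

    def __post_init__(self):
        ts = pd.DatetimeIndex(self.timestamps)
        if len(ts) != len(self.values):
            raise ValidationError("logger timestamps and values differ in length")
        if len(ts) > 1 and not (ts[1:] > ts[:-1]).all():
            raise ValidationError("logger timestamps must be strictly increasing")
        if self.variable not in ("temperature", "water_level"):
            raise ValidationError(f"unknown logger variable {self.variable!r}")
        object.__setattr__(self, "timestamps", tuple(ts))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))


# ---------------------------------------------------------------------------
# Metadata

def normalize_habitat(label: str) -> str:
    norm = str(label).strip().lower()
    if norm not in HABITATS:
        raise ValidationError(
            f"unknown habitat {label!r}; allowed values are {', '.join(HABITATS)}"
        )
    return norm


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample metadata frame.

    Enforces required columns, canonical habitat labels, uniqueness of
    (site, habitat, occasion), date monotone in occasion within each
    site/habitat series, and a single dendritic distance per site.
    """
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata is missing required columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    meta["site_id"] = meta["site_id"].astype(str)
    _check_unique(meta["sample_id"], "sample")
    meta["habitat"] = meta["habitat"].map(normalize_habitat)
    meta["occasion"] = pd.to_numeric(meta["occasion"], errors="raise").astype(int)
    if (meta["occasion"] < 1).any():
        raise ValidationError("occasion indices must be positive integers")
    meta["date"] = pd.to_datetime(meta["date"]).dt.date
    meta["dendritic_distance_km"] = meta["dendritic_distance_km"].astype(float)
    if (meta["dendritic_distance_km"] < 0).any():
        raise ValidationError("dendritic_distance_km must be non-negative")

    key = meta[["site_id", "habitat", "occasion"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValidationError(
            f"duplicate (site, habitat, occasion) record: "
            f"({dup.site_id}, {dup.habitat}, {dup.occasion})"
        )
    for (site, hab), grp in meta.groupby(["site_id", "habitat"]):
        grp = grp.sort_values("occasion")
        dates = pd.to_datetime(pd.Series(list(grp["date"])))
        if len(dates) > 1 and not dates.is_monotonic_increasing:
            raise ValidationError(
                f"dates are not monotone in occasion for site {site}, habitat {hab}"
            )
    ndist = meta.groupby("site_id")["dendritic_distance_km"].nunique()
    bad = ndist[ndist > 1]
    if not bad.empty:
        raise ValidationError(
            f"dendritic distance differs among samples of site(s) {list(bad.index)}"
        )
    return meta


# ---------------------------------------------------------------------------
# Environment table

def validate_env_table(env: pd.DataFrame) -> pd.DataFrame:
    """Validate an environment frame keyed by (site_id, occasion).

    Missing values are permitted (NaN) and propagate through downstream
    statistics; they are never imputed.
    """
    env = env.copy()
    if not (isinstance(env.index, pd.MultiIndex) and env.index.names == ["site_id", "occasion"]):
        if not {"site_id", "occasion"}.issubset(env.columns):
            raise ValidationError("environment table needs site_id and occasion")
        env["site_id"] = env["site_id"].astype(str)
        env["occasion"] = env["occasion"].astype(int)
        env = env.set_index(["site_id", "occasion"])
    if env.index.has_duplicates:
        raise ValidationError("duplicate (site_id, occasion) rows in environment table")
    env = env.astype(float)
    return env.sort_index()


def check_env_coverage(env: pd.DataFrame, meta: pd.DataFrame) -> list[tuple[str, int]]:
    """Return (site, occasion) pairs referenced by metadata but absent from env."""
    wanted = set(zip(meta["site_id"], meta["occasion"]))
    have = set(env.index)
    return sorted(wanted - have)


# ---------------------------------------------------------------------------
# Taxonomy

def validate_taxonomy(taxonomy: Mapping[str, str] | pd.Series, table: AsvTable | None = None) -> pd.Series:
    """ASV → phylum map; keys must be a subset of the table's ASVs when joined."""
    tax = pd.Series(dict(taxonomy) if not isinstance(taxonomy, pd.Series) else taxonomy)
    tax.index = tax.index.astype(str)
    _check_unique(tax.index, "taxonomy ASV")
    if table is not None:
        extra = tax.index.difference(pd.Index(table.asv_ids))
        if len(extra):
            raise ValidationError(
                f"taxonomy maps ASVs absent from the table: {list(extra[:5])}"
            )
    return tax.astype(str)


# ---------------------------------------------------------------------------
# TSV I/O

def _header_comment(checksum: str | None = None) -> str:
    line = f"# dendritemp v{__version__}"
    if checksum:
        line += f" input-sha256:{checksum}"
    return line


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def read_asv_table(path, orientation: str = "samples_as_rows") -> AsvTable:
    """Read a tab-separated ASV count table.

    ``orientation`` selects whether samples are rows or columns of the file;
    the returned table is always samples × ASVs.
    """
    if orientation not in ("samples_as_rows", "samples_as_columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if orientation == "samples_as_columns":
        df = df.T
    for i, row in enumerate(df.itertuples(index=True)):
        for j, v in enumerate(row[1:]):
            if not isinstance(v, (int, float, np.integer, np.floating)):
                raise ValidationError(
                    f"non-numeric cell at row {row[0]!r}, column {df.columns[j]!r}: {v!r}"
                )
    return AsvTable(df)


def write_asv_table(table: AsvTable, path, orientation: str = "samples_as_rows",
                    checksum: str | None = None) -> None:
    df = table.counts if orientation == "samples_as_rows" else table.counts.T
    with open(path, "w") as fh:
        fh.write(_header_comment(checksum) + "\n")
        df.to_csv(fh, sep="\t", index_label="id")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "site_id": str})
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path, checksum: str | None = None) -> None:
    cols = [c for c in METADATA_COLUMNS if c in meta.columns]
    cols += [c for c in meta.columns if c not in cols]
    with open(path, "w") as fh:
        fh.write(_header_comment(checksum) + "\n")
        meta[cols].to_csv(fh, sep="\t", index=False)


def read_env_table(path) -> pd.DataFrame:
    env = pd.read_csv(path, sep="\t", comment="#", dtype={"site_id": str})
    return validate_env_table(env)


def write_env_table(env: pd.DataFrame, path, checksum: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(checksum) + "\n")
        env.reset_index().to_csv(fh, sep="\t", index=False)


def read_taxonomy(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"asv_id", "phylum"}.issubset(df.columns):
        raise ValidationError("taxonomy file needs asv_id and phylum columns")
    return validate_taxonomy(pd.Series(df["phylum"].values, index=df["asv_id"]))


def write_taxonomy(taxonomy: pd.Series, path, checksum: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(checksum) + "\n")
        taxonomy.rename("phylum").rename_axis("asv_id").to_csv(fh, sep="\t")


def write_distance_matrix(D: DistanceMatrix, path, checksum: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(checksum) + "\n")
        D.to_dataframe().to_csv(fh, sep="\t", index_label="id")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return DistanceMatrix(tuple(df.index.astype(str)), df.to_numpy(float))


# ---------------------------------------------------------------------------
# Alignment

@dataclass
class AlignmentReport:
    only_in_table: list[str]
    only_in_metadata: list[str]

    @property
    def clean(self) -> bool:
        return not self.only_in_table and not self.only_in_metadata


def align(table: AsvTable, meta: pd.DataFrame) -> tuple[AsvTable, pd.DataFrame, AlignmentReport]:
    """Restrict table and metadata to their shared samples, metadata order.

    Samples present in exactly one input are reported, not silently dropped.
    """
    meta = validate_metadata(meta)
    table_ids = set(table.sample_ids)
    meta_ids = list(meta["sample_id"])
    shared = [s for s in meta_ids if s in table_ids]
    report = AlignmentReport(
        only_in_table=sorted(table_ids - set(meta_ids)),
        only_in_metadata=[s for s in meta_ids if s not in table_ids],
    )
    if not shared:
        raise ValidationError("no samples shared between ASV table and metadata")
    aligned_meta = meta.set_index("sample_id").loc[shared].reset_index()
    return table.select_samples(shared), aligned_meta, report
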