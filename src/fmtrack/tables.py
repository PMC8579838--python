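"""Count tables, taxonomy, sample metadata, prevalence filtering and rarefaction.

The central container is :class:`CountTable`, a samples x ASVs matrix of
non-negative integer read counts.  Everything downstream — source
classification, transfer detection, diversity, differential abundance —
consumes it.  Files on disk follow the common amplicon dialect of
ASVs-as-rows; in memory the orientation is always samples x ASVs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "UNCLASSIFIED_PREFIX",
    "CountTable",
    "Taxonomy",
    "SampleMeta",
    "FilterConfig",
    "RarefactionConfig",
    "read_count_table",
    "write_count_table",
    "prevalence_filter",
    "rarefy",
    "aggregate_by_rank",
]

#: The seven canonical taxonomic ranks, most to least inclusive.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

UNCLASSIFIED_PREFIX = "Unclassified_"


class CountTable:
    """Samples x ASVs matrix of non-negative integer counts.

    Parameters
    ----------
    data :
        DataFrame with sample identifiers as the index and ASV identifiers
        as columns.  Values must be non-negative integers.
    """

    def __init__(self, data: pd.DataFrame):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("CountTable needs at least one sample and one ASV")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV identifiers: {dups}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValueError("counts must be integers")
            values = values.astype(np.int64)
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        self._data = pd.DataFrame(
            values.astype(np.int64), index=data.index.astype(str), columns=data.columns.astype(str)
        )
        self._data.index.name = "sample_id"
        self._data.columns.name = "asv_id"

    # -- accessors ---------------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self._data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def depths(self) -> pd.Series:
        """Per-sample total read count."""
        return self._data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        depths = self.depths()
        if (depths == 0).any():
            zero = depths.index[depths == 0].tolist()
            raise ValueError(f"zero-depth samples: {zero}")
        return self._data.div(depths, axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        missing = [s for s in sample_ids if s not in self._data.index]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return CountTable(self._data.loc[list(sample_ids)])

    def select_asvs(self, asv_ids: Sequence[str]) -> "CountTable":
        missing = [a for a in asv_ids if a not in self._data.columns]
        if missing:
            raise KeyError(f"ASVs not in table: {missing}")
        return CountTable(self._data[list(asv_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:
        n, m = self.shape
        return f"CountTable({n} samples x {m} ASVs)"


def read_count_table(path: str | Path, orientation: str = "asvs_as_rows") -> CountTable:
    """Read a TSV count table.

    ``orientation`` declares the on-disk layout: ``"asvs_as_rows"`` (the
    common dialect; first column holds ASV ids, header holds sample ids) or
    ``"samples_as_rows"``.
    """
    if orientation not in ("asvs_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        numeric = df.astype(np.int64)
    except (TypeError, ValueError):
        # slow path only to name the offending cell
        for col in df.columns:
            for row, cell in df[col].items():
                try:
                    int(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-integer count {cell!r} at row {row!r}, column {col!r} in {path}"
                    ) from None
        raise
    if orientation == "asvs_as_rows":
        numeric = numeric.T
    return CountTable(numeric)


def write_count_table(
    table: CountTable, path: str | Path, orientation: str = "asvs_as_rows"
) -> None:
    """Write a TSV count table; bit-exact round-trip with :func:`read_count_table`."""
    if orientation not in ("asvs_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    out = table.data.T if orientation == "asvs_as_rows" else table.data
    label = "asv_id" if orientation == "asvs_as_rows" else "sample_id"
    out = out.copy()
    out.index.name = label
    out.to_csv(path, sep="\t")


class Taxonomy:
    """Seven-rank lineage per ASV.

    Missing or empty ranks are normalised to ``Unclassified_<parent>`` where
    ``<parent>`` is the nearest classified rank above, matching common
    amplicon-survey labelling (e.g. ``Unclassified_Ruminococcaceae``).
    """

    def __init__(self, data: pd.DataFrame):
        missing_cols = [r for r in RANKS if r not in data.columns]
        if missing_cols:
            raise ValueError(f"taxonomy missing rank columns: {missing_cols}")
        if data.index.has_duplicates:
            raise ValueError("duplicate ASV identifiers in taxonomy")
        df = data[list(RANKS)].copy()
        df.index = df.index.astype(str)
        df.index.name = "asv_id"
        self._data = _normalize_unclassified(df)

    @classmethod
    def from_lineages(cls, lineages: Mapping[str, str]) -> "Taxonomy":
        """Build from semicolon-delimited lineage strings (short lineages padded)."""
        rows = {}
        for asv, lineage in lineages.items():
            parts = [p.strip() for p in str(lineage).split(";")]
            parts = (parts + [""] * len(RANKS))[: len(RANKS)]
            rows[asv] = parts
        df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
        return cls(df)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Taxonomy":
        """Read taxonomy TSV: either 7 rank columns or a single lineage column."""
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        lowered = {c.lower(): c for c in df.columns}
        if all(r in lowered for r in RANKS):
            df = df.rename(columns={lowered[r]: r for r in RANKS})
            return cls(df)
        if len(df.columns) == 1:
            return cls.from_lineages(df.iloc[:, 0].to_dict())
        raise ValueError(
            f"taxonomy file {path} must have the 7 rank columns or one lineage column"
        )

    def write_tsv(self, path: str | Path) -> None:
        self._data.to_csv(path, sep="\t")

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def asv_ids(self) -> list[str]:
        return list(self._data.index)

    def rank_labels(self, asv_ids: Iterable[str], rank: str) -> pd.Series:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        asv_ids = list(asv_ids)
        missing = [a for a in asv_ids if a not in self._data.index]
        if missing:
            raise KeyError(f"ASVs missing from taxonomy: {missing}")
        return self._data.loc[asv_ids, rank]

    def __len__(self) -> int:
        return len(self._data)


def _normalize_unclassified(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    markers = {"", "na", "nan", "none", "unclassified", "unassigned", "uncultured"}
    for asv in df.index:
        parent = "root"
        for rank in RANKS:
            value = df.at[asv, rank]
            value = "" if pd.isna(value) else str(value).strip()
            if value.lower() in markers or value.startswith(UNCLASSIFIED_PREFIX):
                df.at[asv, rank] = UNCLASSIFIED_PREFIX + parent
            else:
                df.at[asv, rank] = value
                parent = value
    return df


class SampleMeta:
    """Per-sample annotations: subject, role (donor/recipient), group, timepoint."""

    REQUIRED = ("subject_id", "role", "group", "timepoint")
    ROLES = ("donor", "recipient")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        if data.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in metadata")
        df = data[list(self.REQUIRED)].copy()
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        bad_roles = sorted(set(df["role"]) - set(self.ROLES))
        if bad_roles:
            raise ValueError(f"unknown roles {bad_roles}; expected {self.ROLES}")
        for group, sub in df[df["role"] == "donor"].groupby("group"):
            if len(sub) != 1:
                raise ValueError(
                    f"group {group!r} must have exactly one pooled donor sample, found {len(sub)}"
                )
        self._data = df

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMeta":
        return cls(pd.read_csv(path, sep="\t", index_col=0, dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self._data.to_csv(path, sep="\t")

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return list(self._data.index)

    def validate_covers(self, table: CountTable) -> None:
        missing = [s for s in table.sample_ids if s not in self._data.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")

    def donor_sample(self, group: str) -> str:
        df = self._data
        hits = df[(df["role"] == "donor") & (df["group"] == group)]
        if len(hits) != 1:
            raise ValueError(f"expected one donor sample for group {group!r}, found {len(hits)}")
        return str(hits.index[0])

    def recipient_samples(self, group: str, timepoint: str | None = None) -> list[str]:
        df = self._data
        mask = (df["role"] == "recipient") & (df["group"] == group)
        if timepoint is not None:
            mask &= df["timepoint"] == timepoint
        return list(df.index[mask])

    def groups(self) -> list[str]:
        return sorted(self._data.loc[self._data["role"] == "recipient", "group"].unique())

    def recipient_timepoints(self) -> list[str]:
        """Recipient timepoint labels ordered by day number where parseable."""
        labels = list(dict.fromkeys(self._data.loc[self._data["role"] == "recipient", "timepoint"]))
        return sorted(labels, key=_day_number)


def _day_number(label: str) -> float:
    """'D-1' -> -1, 'D16' -> 16; unparseable labels sort last, alphabetically."""
    if label.startswith("D"):
        try:
            return float(label[1:])
        except ValueError:
            pass
    return math.inf


@dataclass(frozen=True)
class FilterConfig:
    """Prevalence filter: keep ASVs with >= ``min_count`` reads in at least
    ``ceil(min_sample_fraction * N)`` of the N samples whose role is not excluded."""

    min_count: int = 4
    min_sample_fraction: float = 0.065
    exclude_roles: frozenset[str] = field(default_factory=lambda: frozenset({"donor"}))

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if not (0 < self.min_sample_fraction <= 1):
            raise ValueError("min_sample_fraction must be in (0, 1]")


@dataclass(frozen=True)
class RarefactionConfig:
    depth: int = 16639
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def prevalence_filter(
    table: CountTable, meta: SampleMeta, cfg: FilterConfig = FilterConfig()
) -> CountTable:
    """Drop rare ASVs.

    The qualifying-sample denominator excludes samples whose role is in
    ``cfg.exclude_roles`` (the pooled donors by default), but excluded
    samples' counts are retained in the output.  The fractional threshold is
    applied with ceiling so that the criterion is attainable over a discrete
    sample count.  The sample set is unchanged.
    """
    meta.validate_covers(table)
    roles = meta.data.loc[table.sample_ids, "role"]
    counted = [s for s in table.sample_ids if roles[s] not in cfg.exclude_roles]
    if not counted:
        raise ValueError("no samples left in the filter denominator after role exclusion")
    threshold = math.ceil(cfg.min_sample_fraction * len(counted))
    qualifying = (table.data.loc[counted] >= cfg.min_count).sum(axis=0)
    keep = [a for a in table.asv_ids if qualifying[a] >= threshold]
    if not keep:
        raise ValueError(
            f"prevalence filter removed every ASV (min_count={cfg.min_count}, "
            f"threshold={threshold} of {len(counted)} samples)"
        )
    return table.select_asvs(keep)


def rarefy(table: CountTable, cfg: RarefactionConfig) -> CountTable:
    """Subsample every sample to exactly ``cfg.depth`` reads without replacement.

    Multivariate-hypergeometric draws, one independent substream per sample
    derived from ``cfg.seed`` so results do not depend on which other samples
    are present.  Samples shallower than the depth are dropped with a
    warning; if none is deep enough an error lists the offenders.
    """
    depths = table.depths()
    deep_enough = depths[depths >= cfg.depth].index.tolist()
    shallow = depths[depths < cfg.depth]
    if not deep_enough:
        raise ValueError(
            f"no sample reaches rarefaction depth {cfg.depth}; shallow samples: "
            f"{dict(shallow)}"
        )
    if len(shallow):
        warnings.warn(
            f"dropping {len(shallow)} sample(s) below depth {cfg.depth}: "
            f"{list(shallow.index)}",
            UserWarning,
            stacklevel=2,
        )
    root = np.random.SeedSequence(cfg.seed)
    out = {}
    for sample, child in zip(table.sample_ids, root.spawn(len(table.sample_ids))):
        if sample not in deep_enough:
            continue
        counts = table.data.loc[sample].to_numpy()
        if counts.sum() == cfg.depth:
            out[sample] = counts
        else:
            rng = np.random.default_rng(child)
            out[sample] = rng.multivariate_hypergeometric(counts, cfg.depth)
    return CountTable(pd.DataFrame.from_dict(out, orient="index", columns=table.asv_ids))


def aggregate_by_rank(table: CountTable, tax: Taxonomy, rank: str) -> CountTable:
    """Sum ASV counts into taxa at ``rank``; per-sample totals are conserved.

    ASVs unclassified at the rank are pooled under their normalised
    ``Unclassified_<parent>`` label.
    """
    labels = tax.rank_labels(table.asv_ids, rank)
    grouped = table.data.T.groupby(labels).sum().T
    grouped = grouped[sorted(grouped.columns)]
    return CountTable(grouped)
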