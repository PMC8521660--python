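"""ASV count tables, sample metadata, and taxonomy: domain types and TSV I/O.

The universal currency of the pipeline is the :class:`CountTable`, an integer
read-count matrix with samples as rows and ASVs as columns (a single
orientation convention, enforced everywhere, avoids transposition bugs).
Identifiers are opaque strings; nothing ever parses digits out of an ASV id.

Two on-disk dialects are supported for count tables:

* ``dense_tsv`` — first column ``sample_id``, remaining columns are ASV ids.
* ``sparse_triplet`` — three columns ``sample_id``, ``asv_id``, ``count``;
  cells absent from the file are zero.

Validation is total: malformed input raises :class:`TableFormatError` or
:class:`MetadataError` naming the offending row/column — never silent
coercion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class TableFormatError(ValueError):
    """A count/result table violated its format contract."""


class MetadataError(ValueError):
    """A sample-metadata file violated its contract."""


LOCATIONS = frozenset({"outside", "growth_chamber", "source"})
HABITATS = frozenset(
    {
        "soil_original",
        "soil_substitute",
        "rosette",
        "leaf_no_soil_contact",
        "flower",
        "negative_control",
        "mock_control",
    }
)
TREATMENTS = frozenset({"AG", "FO", "AG_filtrate", "FO_filtrate", "none"})
STAGES = frozenset({"start", "adult", "flowering", "not_applicable"})
CONTROL_HABITATS = frozenset({"negative_control", "mock_control"})

#: Taxonomic ranks stored for each ASV, domain -> genus.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")


@dataclass(frozen=True)
class CountTable:
    """Integer read-count matrix over samples (rows) x ASVs (columns).

    Wraps a :class:`pandas.DataFrame` with unique string ids on both axes and
    non-negative int64 values.  Instances are treated as immutable; every
    transforming operation returns a new table.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise TableFormatError(f"duplicate sample id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise TableFormatError(f"duplicate ASV id {dup!r}")
        if not all(df.dtypes == np.int64):
            bad = [c for c, t in df.dtypes.items() if t != np.int64]
            raise TableFormatError(f"non-integer count column(s): {bad[:3]}")
        if df.size and int(df.to_numpy().min(initial=0)) < 0:
            arr = df.to_numpy()
            i, j = np.argwhere(arr < 0)[0]
            raise TableFormatError(
                f"negative count at sample {df.index[i]!r}, ASV {df.columns[j]!r}"
            )

    # -- construction --------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        sample_ids: Sequence[str],
        asv_ids: Sequence[str],
        counts: np.ndarray,
    ) -> "CountTable":
        counts = np.asarray(counts)
        if counts.shape != (len(sample_ids), len(asv_ids)):
            raise TableFormatError(
                f"count matrix shape {counts.shape} does not match "
                f"({len(sample_ids)} samples, {len(asv_ids)} ASVs)"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            frac = counts != np.floor(counts)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise TableFormatError(
                    f"non-integer count {counts[i, j]!r} at sample "
                    f"{sample_ids[i]!r}, ASV {asv_ids[j]!r}"
                )
        df = pd.DataFrame(
            counts.astype(np.int64, copy=True),
            index=pd.Index([str(s) for s in sample_ids], name="sample_id"),
            columns=pd.Index([str(a) for a in asv_ids], name="asv_id"),
        )
        return cls(df)

    # -- views ---------------------------------------------------------

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def asv_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        """Read counts as an (n_samples, n_asvs) int64 array (copy-safe view)."""
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def row(self, sample_id: str) -> pd.Series:
        if sample_id not in self.data.index:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.data.loc[sample_id]

    # -- transforms ----------------------------------------------------

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing[:5]}")
        return CountTable(self.data.loc[ids])

    def drop_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        drop = set(sample_ids)
        keep = [s for s in self.data.index if s not in drop]
        return CountTable(self.data.loc[keep])

    def select_asvs(self, asv_ids: Iterable[str]) -> "CountTable":
        ids = list(asv_ids)
        missing = [a for a in ids if a not in self.data.columns]
        if missing:
            raise KeyError(f"unknown ASV id(s): {missing[:5]}")
        return CountTable(self.data[ids])

    def drop_asvs(self, asv_ids: Iterable[str]) -> "CountTable":
        drop = set(asv_ids)
        keep = [a for a in self.data.columns if a not in drop]
        return CountTable(self.data[keep])

    def with_counts(self, counts: np.ndarray) -> "CountTable":
        """Same axes, new count matrix."""
        return CountTable.from_arrays(self.sample_ids, self.asv_ids, counts)

    def __eq__(self, other: object) -> bool:  # order-sensitive equality
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample design metadata; defines every grouping used downstream."""

    sample_id: str
    location: str
    habitat: str
    treatment: str
    stage: str

    def __post_init__(self) -> None:
        for fieldname, value, allowed in (
            ("location", self.location, LOCATIONS),
            ("habitat", self.habitat, HABITATS),
            ("treatment", self.treatment, TREATMENTS),
            ("stage", self.stage, STAGES),
        ):
            if value not in allowed:
                raise MetadataError(
                    f"sample {self.sample_id!r}: unknown {fieldname} {value!r} "
                    f"(allowed: {sorted(allowed)})"
                )
        if self.habitat in CONTROL_HABITATS and self.treatment != "none":
            raise MetadataError(
                f"sample {self.sample_id!r}: control habitat {self.habitat!r} "
                f"must have treatment 'none', got {self.treatment!r}"
            )


@dataclass(frozen=True)
class TaxonomyRecord:
    """Stored taxonomic annotation for one ASV (annotation itself happens upstream)."""

    asv_id: str
    lineage: tuple[str, ...]  # ordered ranks domain -> genus, possibly empty strings
    source: str  # reference_db | blast | unassigned

    def __post_init__(self) -> None:
        if len(self.lineage) != len(RANKS):
            raise MetadataError(
                f"ASV {self.asv_id!r}: lineage must have {len(RANKS)} ranks, "
                f"got {len(self.lineage)}"
            )
        if self.source not in {"reference_db", "blast", "unassigned"}:
            raise MetadataError(
                f"ASV {self.asv_id!r}: unknown taxonomy source {self.source!r}"
            )


class SampleSheet:
    """Collection of :class:`SampleRecord` with declarative selection."""

    def __init__(self, records: Iterable[SampleRecord]):
        self.records = list(records)
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(s for s in ids if ids.count(s) > 1)
            raise MetadataError(f"duplicate sample id {dup!r} in metadata")
        self._by_id = {r.sample_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.sample_id, r.location, r.habitat, r.treatment, r.stage)
                for r in self.records
            ],
            columns=["sample_id", "location", "habitat", "treatment", "stage"],
        )

    def select(self, **criteria) -> list[str]:
        """Sample ids matching all criteria.

        Each criterion is ``field=value`` or ``field=[v1, v2, ...]`` over the
        SampleRecord fields; this is the declarative group selector used by
        the pipeline configuration.
        """
        out = []
        for r in self.records:
            ok = True
            for key, want in criteria.items():
                have = getattr(r, key)
                if isinstance(want, (list, tuple, set, frozenset)):
                    ok = have in want
                else:
                    ok = have == want
                if not ok:
                    break
            if ok:
                out.append(r.sample_id)
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _check_integer_frame(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    """Validate that every cell is a non-negative integer; name offenders."""
    out = {}
    for col in df.columns:
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = series.index[bad.argmax()]
            raise TableFormatError(
                f"{path}: non-numeric count {series[bad].iloc[0]!r} at sample "
                f"{row!r}, ASV {col!r}"
            )
        frac = numeric != np.floor(numeric)
        if frac.any():
            row = series.index[frac.argmax()]
            raise TableFormatError(
                f"{path}: non-integer count {numeric[frac].iloc[0]!r} at "
                f"sample {row!r}, ASV {col!r}"
            )
        if (numeric < 0).any():
            row = series.index[(numeric < 0).argmax()]
            raise TableFormatError(
                f"{path}: negative count at sample {row!r}, ASV {col!r}"
            )
        out[col] = numeric.astype(np.int64)
    return pd.DataFrame(out, index=df.index)


def read_count_table(path: str | Path, dialect: str = "dense_tsv") -> CountTable:
    """Read a count table in the ``dense_tsv`` or ``sparse_triplet`` dialect.

    Sample and ASV order is preserved as encountered in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "dense_tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
        seen: set[str] = set()
        for col in header[1:]:
            if col in seen:
                raise TableFormatError(f"{path}: duplicate ASV id {col!r}")
            seen.add(col)
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.columns[0] != "sample_id":
            raise TableFormatError(
                f"{path}: dense tables must start with a 'sample_id' column, "
                f"got {df.columns[0]!r}"
            )
        df = df.set_index("sample_id")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise TableFormatError(f"{path}: duplicate sample id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise TableFormatError(f"{path}: duplicate ASV id {dup!r}")
        checked = _check_integer_frame(df, path)
        checked.index.name = "sample_id"
        checked.columns.name = "asv_id"
        return CountTable(checked)
    if dialect == "sparse_triplet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        expected = ["sample_id", "asv_id", "count"]
        if list(df.columns[:3]) != expected:
            raise TableFormatError(
                f"{path}: sparse tables need columns {expected}, got "
                f"{list(df.columns[:3])}"
            )
        counts = pd.to_numeric(df["count"], errors="coerce")
        bad = counts.isna()
        if bad.any():
            k = int(bad.argmax())
            raise TableFormatError(
                f"{path}: non-numeric count {df['count'].iloc[k]!r} at sample "
                f"{df['sample_id'].iloc[k]!r}, ASV {df['asv_id'].iloc[k]!r}"
            )
        frac = counts != np.floor(counts)
        if frac.any():
            k = int(frac.argmax())
            raise TableFormatError(
                f"{path}: non-integer count {counts.iloc[k]!r} at sample "
                f"{df['sample_id'].iloc[k]!r}, ASV {df['asv_id'].iloc[k]!r}"
            )
        if (counts < 0).any():
            k = int((counts < 0).argmax())
            raise TableFormatError(
                f"{path}: negative count at sample {df['sample_id'].iloc[k]!r}, "
                f"ASV {df['asv_id'].iloc[k]!r}"
            )
        dup = df.duplicated(subset=["sample_id", "asv_id"])
        if dup.any():
            k = int(dup.argmax())
            raise TableFormatError(
                f"{path}: duplicate cell for sample {df['sample_id'].iloc[k]!r}, "
                f"ASV {df['asv_id'].iloc[k]!r}"
            )
        samples = list(dict.fromkeys(df["sample_id"]))
        asvs = list(dict.fromkeys(df["asv_id"]))
        arr = np.zeros((len(samples), len(asvs)), dtype=np.int64)
        si = {s: i for i, s in enumerate(samples)}
        ai = {a: j for j, a in enumerate(asvs)}
        arr[
            df["sample_id"].map(si).to_numpy(),
            df["asv_id"].map(ai).to_numpy(),
        ] = counts.astype(np.int64).to_numpy()
        return CountTable.from_arrays(samples, asvs, arr)
    raise ValueError(f"unknown count-table dialect {dialect!r}")


def read_metadata(path: str | Path) -> SampleSheet:
    """Read tab-separated sample metadata into a validated :class:`SampleSheet`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "location", "habitat", "treatment", "stage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing metadata column(s) {missing}")
    records = []
    for k, row in df.iterrows():
        try:
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"],
                    location=row["location"],
                    habitat=row["habitat"],
                    treatment=row["treatment"],
                    stage=row["stage"],
                )
            )
        except MetadataError as err:
            raise MetadataError(f"{path}: row {k + 2}: {err}") from None
    return SampleSheet(records)


def read_taxonomy(path: str | Path) -> list[TaxonomyRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["asv_id", *RANKS, "source"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing taxonomy column(s) {missing}")
    seen: set[str] = set()
    records = []
    for k, row in df.iterrows():
        if row["asv_id"] in seen:
            raise MetadataError(f"{path}: duplicate ASV id {row['asv_id']!r}")
        seen.add(row["asv_id"])
        try:
            records.append(
                TaxonomyRecord(
                    asv_id=row["asv_id"],
                    lineage=tuple(row[r] for r in RANKS),
                    source=row["source"] or "unassigned",
                )
            )
        except MetadataError as err:
            raise MetadataError(f"{path}: row {k + 2}: {err}") from None
    return records


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_table(result, path: str | Path, sort_by: str | None = "first") -> None:
    """Write a tabular result as TSV.

    Floats get at least 6 significant digits; rows are sorted by the primary
    identifier (first column) unless ``sort_by`` is None (keep given order) or
    names a specific column.
    """
    path = Path(path)
    if isinstance(result, CountTable):
        df = result.data.reset_index()
        sort_by = None  # count tables keep their axis order (round-trip identity)
    elif isinstance(result, SampleSheet):
        df = result.frame()
        sort_by = None
    elif isinstance(result, pd.DataFrame):
        df = result.copy()
    else:
        df = pd.DataFrame(result)
    if sort_by == "first":
        sort_by = df.columns[0]
    if sort_by is not None:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_count_table(
    table: CountTable, path: str | Path, dialect: str = "dense_tsv"
) -> None:
    path = Path(path)
    if dialect == "dense_tsv":
        table.data.reset_index().to_csv(path, sep="\t", index=False)
    elif dialect == "sparse_triplet":
        rows = []
        arr = table.counts
        nz = np.argwhere(arr > 0)
        samples, asvs = table.sample_ids, table.asv_ids
        for i, j in nz:
            rows.append((samples[i], asvs[j], int(arr[i, j])))
        pd.DataFrame(rows, columns=["sample_id", "asv_id", "count"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown count-table dialect {dialect!r}")


def write_taxonomy(records: Sequence[TaxonomyRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.asv_id, *r.lineage, r.source) for r in records],
        columns=["asv_id", *RANKS, "source"],
    )
    write_table(df, path)
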