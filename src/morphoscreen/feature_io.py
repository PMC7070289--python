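"""Read, write and subset per-object morphological feature tables.

The on-disk format is the CellProfiler-style per-object CSV: one header
row, one row per segmented object, metadata columns (``Metadata_*``,
``ImageNumber``, ``ObjectNumber``) alongside numeric feature columns such
as ``Cyto_AreaShape_Area``.  I/O is lossless: non-finite cells are kept as
NaN markers and cleaning is deferred to :mod:`morphoscreen.preprocess`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed vocabulary for the per-object group label.
GROUPS = ("naive", "model", "treated", "unknown")

#: Metadata roles a CSV column may be assigned to.
ROLES = ("object_id", "group", "compound_id", "extra")

#: Default mapping of CellProfiler-convention columns to metadata roles.
DEFAULT_METADATA_SPEC: dict[str, str] = {
    "ObjectNumber": "object_id",
    "ImageNumber": "extra",
    "Metadata_Group": "group",
    "Metadata_Compound": "compound_id",
}


class FeatureTableError(ValueError):
    """Raised on malformed feature tables or CSV files."""


@dataclass
class FeatureTable:
    """Objects-by-features numeric matrix with per-object metadata.

    Attributes
    ----------
    object_ids:
        One opaque identifier per row.
    group:
        Per-object group label, one of :data:`GROUPS`.
    compound_id:
        Per-object compound identifier; empty string when untreated.
    feature_names:
        Ordered, unique, non-empty feature names.
    values:
        ``(n_objects, n_features)`` float matrix.  May contain non-finite
        entries until cleaned.
    extra_metadata:
        Any further per-object metadata columns, carried through I/O.
    """

    object_ids: np.ndarray
    group: np.ndarray
    compound_id: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    extra_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.object_ids = np.asarray(self.object_ids)
        self.group = np.asarray(self.group, dtype=object)
        self.compound_id = np.asarray(self.compound_id, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FeatureTableError("values must be a 2-D matrix")
        self.feature_names = list(self.feature_names)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.object_ids)
        if self.values.shape != (n, len(self.feature_names)):
            raise FeatureTableError(
                f"values shape {self.values.shape} does not match "
                f"{n} objects x {len(self.feature_names)} features"
            )
        if len(self.group) != n or len(self.compound_id) != n:
            raise FeatureTableError("metadata length does not match object count")
        if any(not name for name in self.feature_names):
            raise FeatureTableError("feature names must be non-empty")
        dupes = _duplicates(self.feature_names)
        if dupes:
            raise FeatureTableError(f"duplicated feature names: {sorted(dupes)}")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise FeatureTableError(
                f"group labels {sorted(bad)} outside vocabulary {GROUPS}"
            )

    # -- conveniences ----------------------------------------------------
    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def take(self, rows: np.ndarray) -> "FeatureTable":
        """Row subset, order preserved; features unchanged."""
        extra = self.extra_metadata
        if len(extra):
            extra = extra.iloc[rows].reset_index(drop=True)
        return FeatureTable(
            object_ids=self.object_ids[rows],
            group=self.group[rows],
            compound_id=self.compound_id[rows],
            feature_names=list(self.feature_names),
            values=self.values[rows],
            extra_metadata=extra,
        )


def _duplicates(names: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for n in names:
        if n in seen:
            dup.add(n)
        seen.add(n)
    return dup


def _normalize_name(name: str) -> str:
    """Canonical feature key: spaces mapped to underscores."""
    return name.strip().replace(" ", "_")


def read_feature_table(
    path, metadata_spec: Mapping[str, str] | None = None
) -> FeatureTable:
    """Read a CellProfiler-style per-object CSV.

    Parameters
    ----------
    path:
        CSV file with a mandatory header row.
    metadata_spec:
        Mapping of CSV column name to metadata role (one of
        :data:`ROLES`).  Defaults to CellProfiler conventions: columns
        prefixed ``Metadata_`` plus ``ImageNumber``/``ObjectNumber`` are
        metadata; ``Metadata_Group`` is the group label and
        ``Metadata_Compound`` the compound id.

    Non-parsable numeric cells become NaN markers, never silent zeros.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            raw_header = next(reader)
        except StopIteration:
            raise FeatureTableError(f"{path}: empty file, header absent")
    if not raw_header or all(not c.strip() for c in raw_header):
        raise FeatureTableError(f"{path}: header absent")
    header = [_normalize_name(c) for c in raw_header]
    dupes = _duplicates(header)

    spec = dict(DEFAULT_METADATA_SPEC) if metadata_spec is None else {
        _normalize_name(k): v for k, v in metadata_spec.items()
    }
    for role in spec.values():
        if role not in ROLES:
            raise FeatureTableError(f"unknown metadata role {role!r}")

    def role_of(col: str) -> str | None:
        if col in spec:
            return spec[col]
        if metadata_spec is None and col.startswith("Metadata_"):
            return "extra"
        return None

    feature_cols = [c for c in header if role_of(c) is None]
    dup_features = dupes & set(feature_cols)
    if dup_features:
        raise FeatureTableError(
            f"{path}: duplicated feature names: {sorted(dup_features)}"
        )
    if dupes:
        raise FeatureTableError(f"{path}: duplicated columns: {sorted(dupes)}")
    if not feature_cols:
        raise FeatureTableError(f"{path}: zero feature columns after metadata")

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = header

    n = len(df)

    def parse(cell: str) -> float:
        # exact round-trip of repr-serialized floats; anything
        # unparsable becomes a non-finite marker, never a silent zero
        try:
            return float(cell)
        except ValueError:
            return float("nan")

    values = np.column_stack(
        [np.array([parse(c) for c in df[col]], dtype=float) for col in feature_cols]
    ) if n else np.empty((0, len(feature_cols)))

    id_cols = [c for c in header if role_of(c) == "object_id"]
    group_cols = [c for c in header if role_of(c) == "group"]
    compound_cols = [c for c in header if role_of(c) == "compound_id"]
    extra_cols = [c for c in header if role_of(c) == "extra"]

    object_ids = (
        df[id_cols[0]].to_numpy() if id_cols else np.arange(n).astype(str)
    )
    group = (
        df[group_cols[0]].to_numpy(dtype=object)
        if group_cols
        else np.full(n, "unknown", dtype=object)
    )
    compound_id = (
        df[compound_cols[0]].to_numpy(dtype=object)
        if compound_cols
        else np.full(n, "", dtype=object)
    )
    return FeatureTable(
        object_ids=object_ids,
        group=group,
        compound_id=compound_id,
        feature_names=feature_cols,
        values=values,
        extra_metadata=df[extra_cols].reset_index(drop=True),
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table as CellProfiler-style CSV.

    Round-trip guarantee: re-reading reproduces object count, feature
    names, metadata and values to full numeric precision (floats are
    serialized with ``repr``).
    """
    table.validate()
    cols: dict[str, object] = {"ObjectNumber": table.object_ids}
    for name in table.extra_metadata.columns:
        cols[name] = table.extra_metadata[name].to_numpy()
    cols["Metadata_Group"] = table.group
    cols["Metadata_Compound"] = table.compound_id
    df = pd.DataFrame(cols)
    feat = pd.DataFrame(table.values, columns=table.feature_names)
    # repr-based float text round-trips exactly through float()
    feat = feat.map(lambda v: "" if np.isnan(v) else repr(v))
    pd.concat([df, feat], axis=1).to_csv(path, index=False)


def subset_by_group(table: FeatureTable, groups: Sequence[str] | set) -> FeatureTable:
    """Rows whose group label is in ``groups``; order preserved."""
    groups = set(groups)
    if not groups:
        raise FeatureTableError("groups must be non-empty")
    mask = np.array([g in groups for g in table.group])
    return table.take(np.flatnonzero(mask))


def subset_by_compound(table: FeatureTable, compound_id: str) -> FeatureTable:
    """Rows carrying the given compound id; order preserved."""
    mask = np.array([c == compound_id for c in table.compound_id])
    return table.take(np.flatnonzero(mask))


def concat_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Stack tables sharing identical feature_names, in the given order."""
    if not tables:
        raise FeatureTableError("nothing to concatenate")
    names = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != names:
            raise FeatureTableError("feature_names differ across tables")
    extras = [t.extra_metadata for t in tables if len(t.extra_metadata)]
    return FeatureTable(
        object_ids=np.concatenate([np.asarray(t.object_ids, dtype=object) for t in tables]),
        group=np.concatenate([t.group for t in tables]),
        compound_id=np.concatenate([t.compound_id for t in tables]),
        feature_names=list(names),
        values=np.vstack([t.values for t in tables]),
        extra_metadata=pd.concat(extras, ignore_index=True) if extras else pd.DataFrame(),
    )
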