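"""Durable Parquet serialization of (possibly ragged) feature tensors.

Feature tensors produced by different featurizers — and even by the same
featurizer on different systems — need not share a shape, so records are
stored as nested list columns rather than padded homogeneous arrays:
a 1-D tensor becomes ``list<item>``, a 2-D (possibly ragged-rowed)
tensor becomes ``list<list<item>>``.  Bit tensors are stored as uint8,
float tensors as float64; both round-trip bit-exactly.

Column conventions: ``record_id``, ``y.value``, ``y.type``,
``meta.<key>`` (string metadata), ``feat.<name>`` (tensors).  A record
missing a feature that other records carry stores an explicit null.
File-level metadata embeds a schema version (readers refuse unknown
majors) plus store provenance (tool version, config hash, seed), and the
writer is deterministic: identical records and tool version produce
identical bytes, so content hashes are usable as provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pyarrow as pa
import pyarrow.parquet as pq

from .featurize import FeatureTensor

SCHEMA_VERSION = "1.0"
_META_SCHEMA_KEY = b"affinity_forge.schema_version"
_META_FEATURES_KEY = b"affinity_forge.features"
_META_PROVENANCE_KEY = b"affinity_forge.provenance"


class StoreVersionError(ValueError):
    """Raised when a store was written under an incompatible schema major."""


RaggedValues = Union[np.ndarray, Sequence[np.ndarray]]


@dataclass
class FeatureRecord:
    """One (x, y) pair: named tensors plus the measured value and metadata."""

    record_id: str
    features: dict[str, Optional[FeatureTensor]]
    y_value: float
    y_type: str
    metadata: dict[str, str] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureRecord):
            return NotImplemented
        if (
            self.record_id != other.record_id
            or self.y_type != other.y_type
            or self.metadata != other.metadata
            or set(self.features) != set(other.features)
        ):
            return False
        if not (
            self.y_value == other.y_value
            or (np.isnan(self.y_value) and np.isnan(other.y_value))
        ):
            return False
        for name, tensor in self.features.items():
            o = other.features[name]
            if tensor is None or o is None:
                if tensor is not o:
                    return False
                continue
            if tensor.dtype != o.dtype:
                return False
            if not _ragged_equal(tensor.values, o.values):
                return False
        return True


def _ragged_equal(a: RaggedValues, b: RaggedValues) -> bool:
    a_rows, b_rows = _as_rows(a), _as_rows(b)
    if (a_rows is None) != (b_rows is None):
        return False
    if a_rows is None:
        return np.array_equal(np.asarray(a), np.asarray(b))
    if len(a_rows) != len(b_rows):
        return False
    return all(np.array_equal(x, y) for x, y in zip(a_rows, b_rows))


def _as_rows(values: RaggedValues) -> Optional[list[np.ndarray]]:
    """Rows of a 2-D (possibly ragged) tensor, or None for 1-D."""
    if isinstance(values, np.ndarray):
        if values.ndim == 1:
            return None
        if values.ndim == 2:
            return [values[i] for i in range(values.shape[0])]
        raise ValueError(f"tensors of ndim {values.ndim} are not supported")
    return [np.asarray(row) for row in values]


def _feature_column(
    name: str,
    records: Sequence[FeatureRecord],
) -> tuple[pa.Array, dict]:
    """Build the arrow array and schema descriptor for one feature name."""
    dtype = None
    ndim = None
    for r in records:
        t = r.features.get(name)
        if t is None:
            continue
        if dtype is None:
            dtype = t.dtype
            ndim = 1 if _as_rows(t.values) is None else 2
        elif t.dtype != dtype:
            raise ValueError(
                f"feature {name!r} mixes dtypes {dtype!r} and {t.dtype!r} across records"
            )
        else:
            this_ndim = 1 if _as_rows(t.values) is None else 2
            if this_ndim != ndim:
                raise ValueError(
                    f"feature {name!r} mixes 1-D and 2-D tensors across records"
                )
    if dtype is None:
        raise ValueError(f"feature {name!r} is null in every record")

    item = pa.uint8() if dtype == "bit" else pa.float64()
    np_item = np.uint8 if dtype == "bit" else np.float64
    arrow_type = pa.list_(item) if ndim == 1 else pa.list_(pa.list_(item))

    cells = []
    for r in records:
        t = r.features.get(name)
        if t is None:
            cells.append(None)
        elif ndim == 1:
            cells.append(np.asarray(t.values, dtype=np_item))
        else:
            cells.append([np.asarray(row, dtype=np_item) for row in _as_rows(t.values)])
    return pa.array(cells, type=arrow_type), {"dtype": dtype, "ndim": ndim}


def write_store(
    records: Sequence[FeatureRecord],
    path,
    provenance: Optional[Mapping[str, object]] = None,
) -> None:
    """Write records to a Parquet store at *path*.

    Raises on duplicate record ids, on a feature mixing dtypes or
    dimensionalities across records, and on unsupported tensor ranks.
    """
    ids = [r.record_id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record_id(s): {', '.join(dupes)}")

    feature_names = sorted({n for r in records for n in r.features})
    meta_keys = sorted({k for r in records for k in r.metadata})

    columns: dict[str, pa.Array] = {
        "record_id": pa.array(ids, type=pa.string()),
        "y.value": pa.array([r.y_value for r in records], type=pa.float64()),
        "y.type": pa.array([r.y_type for r in records], type=pa.string()),
    }
    for key in meta_keys:
        columns[f"meta.{key}"] = pa.array(
            [r.metadata.get(key) for r in records], type=pa.string()
        )
    feature_schema: dict[str, dict] = {}
    for name in feature_names:
        columns[f"feat.{name}"], feature_schema[name] = _feature_column(name, records)

    from . import __version__

    file_meta = {
        _META_SCHEMA_KEY: SCHEMA_VERSION.encode(),
        _META_FEATURES_KEY: json.dumps(feature_schema, sort_keys=True).encode(),
        _META_PROVENANCE_KEY: json.dumps(
            {"tool_version": __version__, **dict(provenance or {})}, sort_keys=True
        ).encode(),
    }
    table = pa.table(columns)
    table = table.replace_schema_metadata(file_meta)
    pq.write_table(table, path, compression="snappy")


def read_provenance(path) -> dict:
    """Store-level provenance embedded at write time."""
    meta = pq.read_schema(path).metadata or {}
    return json.loads(meta.get(_META_PROVENANCE_KEY, b"{}"))


def read_store(path) -> list[FeatureRecord]:
    """Read a store back; inverse of :func:`write_store`.

    Refuses files written under a different schema major, naming both
    versions.  A truncated or corrupt file raises from the Parquet layer
    rather than yielding a partial silent read.
    """
    table = pq.read_table(path)
    meta = table.schema.metadata or {}
    version = meta.get(_META_SCHEMA_KEY, b"").decode()
    if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise StoreVersionError(
            f"store schema version {version or '<missing>'} is incompatible with "
            f"reader version {SCHEMA_VERSION}"
        )
    feature_schema = json.loads(meta.get(_META_FEATURES_KEY, b"{}"))

    n = table.num_rows
    cols = {name: table.column(name).to_pylist() for name in table.column_names}
    records: list[FeatureRecord] = []
    for i in range(n):
        features: dict[str, Optional[FeatureTensor]] = {}
        for name, desc in feature_schema.items():
            cell = cols[f"feat.{name}"][i]
            if cell is None:
                features[name] = None
                continue
            np_item = np.uint8 if desc["dtype"] == "bit" else np.float64
            if desc["ndim"] == 1:
                values: RaggedValues = np.asarray(cell, dtype=np_item)
            else:
                rows = [np.asarray(row, dtype=np_item) for row in cell]
                lengths = {len(r) for r in rows}
                if len(lengths) <= 1 and rows:
                    values = np.asarray(rows, dtype=np_item).reshape(
                        len(rows), lengths.pop() if lengths else 0
                    )
                else:
                    values = rows
            features[name] = _tensor(name, values, desc["dtype"])
        metadata = {
            key[len("meta.") :]: cols[key][i]
            for key in cols
            if key.startswith("meta.") and cols[key][i] is not None
        }
        records.append(
            FeatureRecord(
                record_id=cols["record_id"][i],
                features=features,
                y_value=cols["y.value"][i],
                y_type=cols["y.type"][i],
                metadata=metadata,
            )
        )
    return records


def _tensor(name: str, values: RaggedValues, dtype: str) -> FeatureTensor:
    # bypass FeatureTensor.__post_init__ coercion for ragged (list-of-array) values
    t = FeatureTensor.__new__(FeatureTensor)
    t.name = name
    t.values = values
    t.dtype = dtype
    return t
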