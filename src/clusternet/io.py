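"""Reading and writing localization tables and hierarchical graphs.

Localization tables hold one ROI (one DNA-origami structure) or one cell per
file. Coordinates are always nanometres, floating point; there are no pixel
units anywhere in the pipeline. Tables are stored as Apache Parquet (the class
label travels in the file-level metadata under ``gt_label``) or as CSV (CSV has
no metadata block, so the label is carried in a ``gt_label`` column repeated
per row).

Graphs are stored as a single ``.npz`` container: a zip archive of typed numpy
arrays plus a JSON header carrying the format version, class label and
provenance. The layout is documented in the README.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

from .exceptions import EmptyInputError, FormatError

logger = logging.getLogger(__name__)

#: optional per-localization quality columns, in canonical order
OPTIONAL_COLUMNS = ("frame", "channel", "photons", "psf_sigma", "psf_pvalue", "precision")

GRAPH_FORMAT_VERSION = 1


@dataclass
class LocalizationTable:
    """One ROI's (or one cell's) localizations plus label metadata.

    ``data`` always has float columns ``x`` and ``y`` in nm; any of
    :data:`OPTIONAL_COLUMNS` may be present, and must then be fully populated.
    """

    data: pd.DataFrame
    gt_label: str | None = None
    source_id: str | None = None
    extra_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("x", "y"):
            if col not in self.data.columns:
                raise FormatError(f"localization table lacks required column {col!r}")
        xy = self.data[["x", "y"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise FormatError("non-finite coordinates in localization table")
        for col in OPTIONAL_COLUMNS:
            if col in self.data.columns and self.data[col].isna().any():
                raise FormatError(f"optional column {col!r} is partially populated")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) float array of coordinates in nm."""
        return self.data[["x", "y"]].to_numpy(float)

    def replace(self, data: pd.DataFrame) -> "LocalizationTable":
        """New table with the same metadata but different rows."""
        return LocalizationTable(
            data.reset_index(drop=True),
            gt_label=self.gt_label,
            source_id=self.source_id,
            extra_metadata=dict(self.extra_metadata),
        )


def _canonical_frame(df: pd.DataFrame, column_map: dict[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns=column_map)
    # tolerate common vendor spellings
    aliases = {"x [nm]": "x", "y [nm]": "y", "X": "x", "Y": "y"}
    df = df.rename(columns={k: v for k, v in aliases.items() if k in df.columns})
    return df


def read_locs(
    path: str | Path,
    dialect: str = "parquet",
    column_map: dict[str, str] | None = None,
    keep_columns: tuple[str, ...] = (),
) -> LocalizationTable:
    """Read a localization table.

    Parameters
    ----------
    path : file path.
    dialect : {"parquet", "csv", "matlab-export-csv"}.
        "matlab-export-csv" is plain CSV read with a column map applied, for
        tables exported from MATLAB with nonstandard headers.
    column_map : optional mapping of on-disk column names to canonical ones.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect == "parquet":
        table = pq.read_table(path)
        df = table.to_pandas()
        meta = table.schema.metadata or {}
        gt_label = meta.get(b"gt_label")
        gt_label = gt_label.decode() if gt_label is not None else None
        source_id = meta.get(b"source_id")
        source_id = source_id.decode() if source_id is not None else None
        extra = {
            k.decode(): v.decode()
            for k, v in meta.items()
            if k not in (b"gt_label", b"source_id") and not k.startswith(b"pandas")
        }
    elif dialect in ("csv", "matlab-export-csv"):
        df = pd.read_csv(path)
        gt_label = None
        source_id = None
        extra = {}
        if "gt_label" in df.columns:
            labels = df.pop("gt_label").unique()
            if len(labels) > 1:
                raise FormatError("conflicting gt_label values within one CSV")
            gt_label = str(labels[0])
        if "source_id" in df.columns:
            source_id = str(df.pop("source_id").iloc[0])
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    df = _canonical_frame(df, column_map)
    if "x" not in df.columns or "y" not in df.columns:
        raise FormatError(f"{path} lacks x/y columns (found {list(df.columns)})")
    if len(df) == 0:
        raise EmptyInputError(f"{path} contains no localizations")
    keep = ["x", "y"] + [c for c in OPTIONAL_COLUMNS + tuple(keep_columns) if c in df.columns]
    return LocalizationTable(
        df[keep].reset_index(drop=True), gt_label=gt_label, source_id=source_id, extra_metadata=extra
    )


def write_locs(table: LocalizationTable, path: str | Path, dialect: str = "parquet") -> Path:
    """Write a localization table losslessly (see :func:`read_locs`)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "parquet":
        pa_table = pa.Table.from_pandas(table.data, preserve_index=False)
        meta = dict(pa_table.schema.metadata or {})
        if table.gt_label is not None:
            meta[b"gt_label"] = table.gt_label.encode()
        if table.source_id is not None:
            meta[b"source_id"] = table.source_id.encode()
        for k, v in table.extra_metadata.items():
            meta[str(k).encode()] = str(v).encode()
        pq.write_table(pa_table.replace_schema_metadata(meta), path)
    elif dialect == "csv":
        df = table.data.copy()
        if table.gt_label is not None:
            df["gt_label"] = table.gt_label
        if table.source_id is not None:
            df["source_id"] = table.source_id
        df.to_csv(path, index=False)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return path


def write_graph(graph, path: str | Path) -> Path:
    """Serialize a :class:`~clusternet.graphs.HierarchicalGraph` to ``.npz``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = {
        "format_version": GRAPH_FORMAT_VERSION,
        "label": graph.label,
        "source_id": graph.source_id,
        "has_features": graph.cluster_features is not None,
    }
    arrays = {
        "header": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
        "loc_pos": graph.loc_pos,
        "loc_cluster": graph.loc_cluster,
        "cluster_pos": graph.cluster_pos,
        "edges": graph.edges,
    }
    if graph.cluster_features is not None:
        arrays["cluster_features"] = graph.cluster_features
    np.savez_compressed(path, **arrays)
    return path


def read_graph(path: str | Path):
    """Read a graph written by :func:`write_graph`; validates the header."""
    from .graphs import HierarchicalGraph  # local import avoids a cycle

    path = Path(path)
    try:
        with np.load(path) as npz:
            header = json.loads(bytes(npz["header"]).decode())
            if header.get("format_version") != GRAPH_FORMAT_VERSION:
                raise FormatError(f"unsupported graph format version in {path}")
            feats = npz["cluster_features"] if header["has_features"] else None
            graph = HierarchicalGraph(
                loc_pos=npz["loc_pos"],
                loc_cluster=npz["loc_cluster"],
                cluster_pos=npz["cluster_pos"],
                cluster_features=feats,
                edges=npz["edges"],
                label=header["label"],
                source_id=header["source_id"],
            )
    except FormatError:
        raise
    except Exception as exc:  # corrupt zip, missing keys, bad JSON
        raise FormatError(f"cannot read graph container {path}: {exc}") from exc
    if graph.cluster_pos.shape[0] == 0:
        raise FormatError(f"graph container {path} holds an empty graph")
    return graph
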