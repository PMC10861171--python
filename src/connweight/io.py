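"""Readers and writers for all artifact formats.

Human-readable tables are tab-separated text with a header; connectivity
matrices are stored either as delimited text with a one-line metadata
header (round-trips to 1e-15) or as a compressed ``.npz`` archive with a
JSON metadata record (round-trips bit-exactly).  Node ids are 0-based in
every file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .community import CommunityPartition
from .connectome import ConnectivityMatrix
from .synthetic import AtlasDefinition, StreamlineTable

ATLAS_COLUMNS = ["node_id", "hemisphere", "network", "x", "y", "z"]


class FormatError(ValueError):
    """Raised when a file fails validation on read."""


# --------------------------------------------------------------------------
# atlas


def write_atlas(path, atlas: AtlasDefinition) -> None:
    df = atlas.nodes.sort_values("node_id")[ATLAS_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_atlas(path) -> AtlasDefinition:
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot parse atlas file {path}: {exc}") from exc
    missing = [c for c in ATLAS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"atlas file missing column(s): {missing}")
    if df["node_id"].duplicated().any():
        dupes = df.loc[df["node_id"].duplicated(), "node_id"].tolist()
        raise FormatError(f"duplicate node_id(s): {dupes}")
    try:
        return AtlasDefinition(df)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


# --------------------------------------------------------------------------
# streamline tables


def write_streamlines(path, tables: list[StreamlineTable]) -> None:
    frames = []
    for t in tables:
        df = t.rows.copy()
        df.insert(0, "subject", t.subject)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_streamlines(path) -> list[StreamlineTable]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["subject", "node_i", "node_j", "fa", "add"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"streamline file missing column(s): {missing}")
    return [
        StreamlineTable(rows=g.drop(columns="subject").reset_index(drop=True),
                        subject=str(sub))
        for sub, g in df.groupby("subject", sort=True)
    ]


# --------------------------------------------------------------------------
# matrices


def _meta(matrix: ConnectivityMatrix) -> dict:
    return {
        "kind": matrix.kind,
        "provenance": matrix.provenance,
        "normalized": bool(matrix.normalized),
    }


def write_matrix(path, matrix: ConnectivityMatrix) -> None:
    """Archive (`.npz`, bit-exact) or text (anything else, 1e-15)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(
            path, values=matrix.values, meta=np.array(json.dumps(_meta(matrix)))
        )
    else:
        header = "# " + json.dumps(_meta(matrix))
        with open(path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, matrix.values, delimiter="\t", fmt="%.17g")


def read_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as npz:
            values = npz["values"]
            meta = json.loads(str(npz["meta"]))
    else:
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# "):
                raise FormatError("matrix text file missing metadata header")
            meta = json.loads(first[2:])
            values = np.loadtxt(fh, delimiter="\t", ndmin=2)
    try:
        return ConnectivityMatrix(
            values=values,
            kind=meta["kind"],
            provenance=meta.get("provenance", "unknown"),
            normalized=bool(meta.get("normalized", False)),
        )
    except ValueError as exc:
        raise FormatError(f"invalid matrix in {path}: {exc}") from exc


# --------------------------------------------------------------------------
# metric vectors, partitions, configs


def write_node_metric(path, values: np.ndarray, meta: dict) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("node_id\tvalue\n")
        for i, v in enumerate(values):
            fh.write(f"{i}\t{v:.17g}\n")


def write_partition(path, partition: CommunityPartition, sidecar: dict) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("node_id\tcommunity_id\n")
        for i, c in enumerate(partition.assignment):
            fh.write(f"{i}\t{c}\n")
    meta = dict(sidecar)
    meta.update({"gamma": partition.gamma, "modularity": partition.modularity,
                 "n_communities": partition.n_communities})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_partition(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("node_id")["community_id"].to_numpy(int)


def load_config(path) -> dict:
    """YAML or JSON key-value configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
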