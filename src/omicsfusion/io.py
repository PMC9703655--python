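"""Readers and writers for omics matrices, interactome edge lists, drug
response tables and model checkpoints.

Matrix files are delimited text (tab by default): first row holds feature or
drug ids, first column holds cell-line ids. Interactome files are two-column
symbol lists. Checkpoints are directories of ``.npy`` arrays plus a JSON
manifest; reloading a checkpoint reproduces forward passes bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    DrugResponseTable,
    FormatError,
    InteractomeEdges,
    OmicsMatrix,
    StandardizationStats,
)
from .layers import AttentionParams, SubNetworkParams


class ParseError(ValueError):
    """Unparseable cell or line in an input file."""


class CheckpointError(ValueError):
    """Corrupt or incompatible checkpoint."""


def _read_table(path, sep: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    col_ids = [c for c in header[1:] if c != ""]
    dups = {c for c in col_ids if col_ids.count(c) > 1}
    if dups:
        raise FormatError(f"{path.name}: duplicate column id(s): {sorted(dups)}")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        bad = df.index[df.index.duplicated()].tolist()
        raise FormatError(f"{path.name}: duplicate row id(s): {bad}")
    return df


def _to_float(df: pd.DataFrame, path) -> np.ndarray:
    try:
        return df.to_numpy(dtype=np.float64)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            for i, row in enumerate(df.index):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{Path(path).name}: non-numeric value {df.iat[i, j]!r} "
                        f"at row {row!r}, column {col!r}"
                    ) from None
        raise  # pragma: no cover - unreachable


def read_omics_matrix(path, omics_name: str, embedding_kind: str,
                      sep: str = "\t") -> OmicsMatrix:
    """Read a (cell lines x features) matrix from delimited text."""
    df = _read_table(path, sep)
    values = _to_float(df, path)
    return OmicsMatrix(omics_name, list(df.index), list(df.columns),
                       values, embedding_kind)


def write_omics_matrix(m: OmicsMatrix, path, sep: str = "\t") -> None:
    df = pd.DataFrame(m.values, index=m.cell_line_ids, columns=m.feature_ids)
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_ppi_edges(path, sep=None) -> InteractomeEdges:
    """Read a two-column interaction list; unordered duplicates collapse."""
    edges = InteractomeEdges()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(sep) if sep else line.split()
            if len(fields) != 2:
                raise ParseError(
                    f"{Path(path).name}: line {lineno}: expected 2 fields, "
                    f"got {len(fields)}"
                )
            edges.add(fields[0], fields[1])
    return edges


def write_ppi_edges(edges: InteractomeEdges, path, sep: str = "\t") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(edges.edges):
            fh.write(f"{a}{sep}{b}\n")


def read_drug_responses(path, missing_token: str = "NA", sep: str = "\t",
                        log_transform: bool = False) -> DrugResponseTable:
    """Read a (cell lines x drugs) response table.

    Values are taken as already on the log IC50 scale; pass
    ``log_transform=True`` for raw micromolar IC50 inputs, which then get a
    natural log applied on load.
    """
    df = _read_table(path, sep)
    raw = df.to_numpy(dtype=object)
    mask = np.ones(raw.shape, dtype=bool)
    values = np.zeros(raw.shape, dtype=np.float64)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or str(cell).strip() in (missing_token, ""):
                mask[i, j] = False
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{Path(path).name}: non-numeric value {cell!r} at row "
                    f"{df.index[i]!r}, column {df.columns[j]!r}"
                ) from None
    if log_transform:
        values[mask] = np.log(values[mask])
    return DrugResponseTable(list(df.index), list(df.columns), values, mask)


def write_drug_responses(r: DrugResponseTable, path, missing_token: str = "NA",
                         sep: str = "\t") -> None:
    out = r.values.astype(object)
    out[~r.observed_mask] = missing_token
    df = pd.DataFrame(out, index=r.cell_line_ids, columns=r.drug_ids)
    df.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """A reloaded model state: per-omics parameters, attention parameters,
    standardization statistics and the run manifest."""

    subnetworks: dict          # omics name -> SubNetworkParams
    attention: AttentionParams
    stats: dict                # omics name -> StandardizationStats
    manifest: dict


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _manifest_digest(manifest: dict) -> str:
    core = {k: v for k, v in manifest.items() if k != "manifest_sha256"}
    return hashlib.sha256(
        json.dumps(core, sort_keys=True).encode()
    ).hexdigest()


def save_checkpoint(subnetworks: dict, attention: AttentionParams,
                    stats: dict, manifest: dict, path) -> None:
    """Write parameters as one ``.npy`` per array plus ``manifest.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name, p in subnetworks.items():
        arrays[f"{name}__W1"] = p.W1
        arrays[f"{name}__b1"] = p.b1
        arrays[f"{name}__W2"] = p.W2
        arrays[f"{name}__b2"] = p.b2
        arrays[f"{name}__Wh"] = p.Wh
        arrays[f"{name}__bh"] = p.bh
        if p.A is not None:
            arrays[f"{name}__A"] = p.A
        st = stats[name]
        arrays[f"{name}__mean"] = st.mean
        arrays[f"{name}__scale"] = st.scale
    arrays["attention__W3"] = attention.W3
    arrays["attention__b"] = attention.b
    for key, arr in arrays.items():
        np.save(path / f"{key}.npy", np.asarray(arr, dtype=np.float64))

    manifest = dict(manifest)
    manifest["arrays"] = {k: list(v.shape) for k, v in arrays.items()}
    manifest["subnet_meta"] = {
        name: {
            "embedding_kind": "graph" if p.A is not None else "dense",
            "dropout_embed": p.dropout_embed,
            "dropout_hidden": p.dropout_hidden,
        }
        for name, p in subnetworks.items()
    }
    manifest["feature_ids"] = {name: stats[name].feature_ids for name in stats}
    manifest["manifest_sha256"] = _manifest_digest(manifest)
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_checkpoint(path) -> Checkpoint:
    path = Path(path)
    mpath = path / "manifest.json"
    if not mpath.exists():
        raise CheckpointError(f"no manifest.json under {path}")
    with open(mpath) as fh:
        manifest = json.load(fh)
    if manifest.get("manifest_sha256") != _manifest_digest(manifest):
        raise CheckpointError("manifest digest mismatch: checkpoint tampered or corrupt")

    def load(key):
        f = path / f"{key}.npy"
        if not f.exists():
            raise CheckpointError(f"missing array {key}")
        arr = np.load(f)
        if list(arr.shape) != manifest["arrays"][key]:
            raise CheckpointError(f"array {key} shape differs from manifest")
        return arr

    subnetworks, stats = {}, {}
    for name, meta in manifest["subnet_meta"].items():
        A = load(f"{name}__A") if meta["embedding_kind"] == "graph" else None
        subnetworks[name] = SubNetworkParams(
            W1=load(f"{name}__W1"), b1=load(f"{name}__b1"), A=A,
            W2=load(f"{name}__W2"), b2=load(f"{name}__b2"),
            Wh=load(f"{name}__Wh"), bh=load(f"{name}__bh"),
            dropout_embed=meta["dropout_embed"],
            dropout_hidden=meta["dropout_hidden"],
        )
        stats[name] = StandardizationStats(
            manifest["feature_ids"][name],
            load(f"{name}__mean"), load(f"{name}__scale"),
        )
    attention = AttentionParams(W3=load("attention__W3"), b=load("attention__b"))
    return Checkpoint(subnetworks, attention, stats, manifest)
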