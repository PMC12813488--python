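"""Plain-text interchange: edge tables, phenotypes, labels, manifests.

All artifacts are TSV (or JSON sidecars). Edge tables carry a header
comment with the edge-order hash and parcel count so that readers can
verify the ordering before any dot product. Floats are written with a
fixed format so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import EdgeVector, edge_index, edge_order_hash
from .correspondence import ContrastSignature
from .pcr import Neurosignature

__all__ = [
    "write_edge_table",
    "read_edge_table",
    "write_signature",
    "read_signature",
    "write_phenotypes",
    "read_phenotypes",
    "write_labels",
    "read_labels",
    "write_manifest",
    "read_manifest",
]

_FLOAT_FMT = "%.17g"  # lossless float64 round trip


def _n_parcels_from_edges(n_edges: int) -> int:
    p = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if p * (p - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not a triangular number of edges")
    return p


def _write_edge_file(path, columns: dict, n_parcels: int, order_hash: str, meta: dict):
    idx = edge_index(n_parcels)
    header = {"schema": "connsig-edges-v1", "n_parcels": n_parcels, "order_hash": order_hash}
    header.update(meta)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header, sort_keys=True) + "\n")
        names = list(columns)
        fh.write("edge_i\tedge_j\t" + "\t".join(names) + "\n")
        cols = [np.asarray(columns[c], dtype=float) for c in names]
        for e in range(idx.shape[0]):
            vals = "\t".join(_FLOAT_FMT % c[e] for c in cols)
            fh.write(f"{idx[e, 0]}\t{idx[e, 1]}\t{vals}\n")


def _read_edge_file(path):
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path}:1: missing header comment")
        header = json.loads(first[2:])
        colnames = fh.readline().rstrip("\n").split("\t")
        if colnames[:2] != ["edge_i", "edge_j"]:
            raise ValueError(f"{path}:2: expected edge_i/edge_j columns")
        n_parcels = int(header["n_parcels"])
        n_edges = n_parcels * (n_parcels - 1) // 2
        data = np.empty((n_edges, len(colnames) - 2))
        expect = edge_index(n_parcels)
        for e in range(n_edges):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}:{e + 3}: truncated edge table "
                                 f"(expected {n_edges} edges)")
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(colnames):
                raise ValueError(f"{path}:{e + 3}: malformed row")
            if int(parts[0]) != expect[e, 0] or int(parts[1]) != expect[e, 1]:
                raise ValueError(f"{path}:{e + 3}: edge order violation")
            data[e] = [float(v) for v in parts[2:]]
    return header, colnames[2:], data


def write_edge_table(path, edge_vector: EdgeVector, meta: dict | None = None) -> None:
    _write_edge_file(
        path,
        {"z": edge_vector.values},
        edge_vector.n_parcels,
        edge_vector.order_hash,
        meta or {},
    )


def read_edge_table(path, labels=None) -> EdgeVector:
    header, _, data = _read_edge_file(path)
    n_parcels = int(header["n_parcels"])
    if labels is not None:
        if len(labels) != n_parcels:
            raise ValueError(
                f"parcel-label file has {len(labels)} labels but the edge table "
                f"declares {n_parcels} parcels"
            )
        expected = edge_order_hash(n_parcels, list(labels))
        if header["order_hash"] != expected:
            raise ValueError("edge-order hash mismatch between file and labels")
    ev = EdgeVector(data[:, 0], n_parcels, labels=list(labels) if labels else None)
    ev.order_hash = header["order_hash"]
    return ev


def write_signature(path, sig: Neurosignature, meta: dict | None = None) -> None:
    n_parcels = _n_parcels_from_edges(sig.weights.size)
    info = {
        "n_components": int(sig.n_components),
        "covariates": list(sig.covariate_spec),
        "intercept": sig.intercept,
        "n_subjects": int(sig.n_subjects),
    }
    info.update(meta or {})
    _write_edge_file(
        path,
        {"weight": sig.weights, "haufe": sig.haufe_pattern},
        n_parcels,
        sig.order_hash,
        info,
    )


def read_signature(path) -> Neurosignature:
    header, names, data = _read_edge_file(path)
    cols = dict(zip(names, data.T))
    return Neurosignature(
        weights=cols["weight"],
        haufe_pattern=cols["haufe"],
        n_components=int(header.get("n_components", 0)),
        covariate_spec=tuple(header.get("covariates", ())),
        intercept=float(header.get("intercept", 0.0)),
        n_subjects=int(header.get("n_subjects", 0)),
        order_hash=header["order_hash"],
    )


def write_contrast_signature(path, sig: ContrastSignature, meta: dict | None = None) -> None:
    n_parcels = _n_parcels_from_edges(sig.weights.size)
    info = {"n_components": int(sig.n_components), "covariates": list(sig.covariate_spec)}
    info.update(meta or {})
    _write_edge_file(path, {"weight": sig.weights}, n_parcels, sig.order_hash, info)


def write_phenotypes(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])


def write_labels(path, labels: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("parcel_id\tnetwork\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{lab}\n")


def read_labels(path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("parcel_id")["network"].astype(str).tolist()


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
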