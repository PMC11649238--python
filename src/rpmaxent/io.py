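"""Reading and writing rasters and model files.

Rasters travel as delimited text (CSV/TSV; rows = time bins, columns =
neurons, optional header) or as an ``.npz`` container for speed. Models
are a versioned JSON document holding the mask, weights, thresholds,
nonlinearity and λ, serialized with canonical (shortest round-trip)
float formatting so that regenerated files are byte-identical across
platforms.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, SchemaError
from .model import RPModel
from .projections import Nonlinearity, ProjectionSet
from .raster import SpikeRaster

__all__ = ["read_raster", "write_raster", "read_model", "write_model"]

MODEL_FORMAT = "rpmaxent-model"
MODEL_VERSION = 1

_SEPS = {"csv": ",", "tsv": "\t"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "tsv", "binary"):
            raise ParameterError(f"unknown raster format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    return {".tsv": "tsv", ".npz": "binary"}.get(suffix, "csv")


def read_raster(path, fmt: str | None = None, bin_width_ms: float = 20.0) -> SpikeRaster:
    """Read a binary raster; entries must parse to 0/1.

    Delimited text may carry one header row (detected automatically).
    Malformed or non-binary entries raise :class:`ParseError` naming the
    offending cell.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "binary":
        with np.load(path) as z:
            return SpikeRaster(z["data"], float(z["bin_width_ms"]))
    sep = _SEPS[fmt]
    first = path.open().readline()
    tokens = [t.strip() for t in first.rstrip("\n").split(sep)]
    has_header = not all(t in ("0", "1") for t in tokens)
    df = pd.read_csv(path, sep=sep, header=0 if has_header else None, dtype=str)
    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce").to_numpy()
    bad = ~np.isin(numeric, (0.0, 1.0)) | np.isnan(numeric)
    if bad.any():
        flat = int(np.flatnonzero(bad)[0])
        r, c = divmod(flat, values.shape[1])
        raise ParseError(
            f"{path}: entry {values[r, c]!r} at data row {r}, column {c} "
            "is not 0/1"
        )
    return SpikeRaster(numeric.reshape(values.shape).astype(np.uint8), bin_width_ms)


def write_raster(X: SpikeRaster, path, fmt: str | None = None) -> None:
    """Write a raster as delimited text (or ``.npz`` for ``binary``)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "binary":
        np.savez_compressed(path, data=X.data, bin_width_ms=X.bin_width_ms)
        return
    np.savetxt(path, X.data, fmt="%d", delimiter=_SEPS[fmt])


def _canonical_json(obj) -> str:
    # json round-trips floats through repr (shortest exact representation),
    # which is platform-stable for IEEE doubles
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def write_model(M: RPModel, path, metadata: dict | None = None) -> None:
    """Serialize a model losslessly to versioned JSON."""
    P = M.projections
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "n_neurons": P.n_neurons,
        "n_proj": P.n_proj,
        "nonlinearity": {"kind": P.nonlinearity.kind, "beta": P.nonlinearity.beta},
        "mask": P.mask.tolist(),
        "weights": P.weights.tolist(),
        "thresholds": P.thresholds.tolist(),
        "lambdas": M.lambdas.tolist(),
        "metadata": metadata or {},
    }
    Path(path).write_text(_canonical_json(doc) + "\n")


def read_model(path) -> RPModel:
    """Load a model file, validating the schema and format version."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise SchemaError(f"{path}: not a {MODEL_FORMAT} file")
    if doc.get("version") != MODEL_VERSION:
        raise SchemaError(
            f"{path}: model file version {doc.get('version')!r} != "
            f"supported version {MODEL_VERSION}"
        )
    required = ("nonlinearity", "mask", "weights", "thresholds", "lambdas")
    missing = [k for k in required if k not in doc]
    if missing:
        raise SchemaError(f"{path}: missing required field(s) {missing}")
    nl = doc["nonlinearity"]
    P = ProjectionSet(
        mask=np.array(doc["mask"], dtype=np.uint8),
        weights=np.array(doc["weights"], dtype=np.float64),
        thresholds=np.array(doc["thresholds"], dtype=np.float64),
        nonlinearity=Nonlinearity(kind=nl["kind"], beta=nl.get("beta")),
    )
    return RPModel(P, np.array(doc["lambdas"], dtype=np.float64))
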