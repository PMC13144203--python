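"""Readers and writers: count matrices and fitted-model serialization.

Count matrices are exchanged as MatrixMarket coordinate files (the standard
interchange format for sparse document-term and gene-count matrices) or as
small dense CSV tables. Fits are serialized as a directory of CSV matrices
plus a JSON metadata file; floating-point values are printed with %.17g so
IEEE doubles round-trip bit-identically.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .data import CountMatrix, DataError

__all__ = [
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "write_fit",
    "read_fit",
]

FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


# ----------------------------------------------------------------------
# count matrices


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def _read_csv_counts(path: Path) -> np.ndarray:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.strip():
        raise DataError(f"{path}: empty file")
    tokens = [t.strip() for t in first.strip().split(",")]
    # header iff the first row is not all numeric
    header = 0 if any(not _is_number(t) for t in tokens) else None
    df = pd.read_csv(path, header=header)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise DataError(f"{path}: empty matrix")
    # a non-numeric first column is a row-name column
    if df.iloc[:, 0].dtype == object:
        df = df.iloc[:, 1:]
    if df.shape[1] == 0:
        raise DataError(f"{path}: no numeric columns")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"{path}: non-numeric entries: {exc}") from exc
    return values


def read_count_matrix(path, format: str | None = None) -> CountMatrix:
    """Read a count matrix from MatrixMarket or CSV.

    Parameters
    ----------
    path : path-like
    format : {"matrixmarket", "csv"}, optional
        Inferred from the file suffix (``.mtx``/``.mm`` vs ``.csv``) when
        omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "matrixmarket" if suffix in {".mtx", ".mm"} else "csv"
    if format == "matrixmarket":
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:
            raise FormatError(f"{path}: not a valid MatrixMarket file: {exc}") from exc
        return CountMatrix(mat)
    if format == "csv":
        return CountMatrix(_read_csv_counts(path))
    raise ValueError(f"unknown format {format!r}")


def write_count_matrix(X: CountMatrix, path, format: str | None = None) -> None:
    """Write a count matrix as MatrixMarket coordinate (default) or CSV."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "matrixmarket"
    if format == "matrixmarket":
        scipy.io.mmwrite(str(path), X.csr.astype(np.int64))
    elif format == "csv":
        np.savetxt(path, X.toarray().astype(np.int64), fmt="%d", delimiter=",")
    else:
        raise ValueError(f"unknown format {format!r}")


# ----------------------------------------------------------------------
# fit serialization


def _save_matrix(path: Path, M: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(M, dtype=float)), fmt=FLOAT_FMT, delimiter=",")


def _load_matrix(path: Path) -> np.ndarray:
    if not path.exists():
        raise FormatError(f"missing component {path.name}")
    try:
        M = np.loadtxt(path, delimiter=",", ndmin=2)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable matrix: {exc}") from exc
    return M


def _config_to_jsonable(config):
    if config is None:
        return None
    d = dataclasses.asdict(config)
    pen = d.get("pen")
    if pen is not None:
        d["pen"] = {
            k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
            for k, v in pen.items()
        }
    return d


def write_fit(fit, path) -> None:
    """Serialize a fit to a directory of CSV matrices plus meta.json.

    Accepts either a :class:`~poistopics.model.PoissonNMFResults` or a
    :class:`~poistopics.model.TopicModelResults`; the round trip through
    :func:`read_fit` is lossless (bit-identical matrices and trace).
    """
    from .model import PoissonNMFResults, TopicModelResults

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(fit, PoissonNMFResults):
        kind = "pnmf"
        _save_matrix(path / "H.csv", fit.H)
        _save_matrix(path / "W.csv", fit.W)
        objective = fit.objective
        trace = fit.trace
        config = fit.config
    elif isinstance(fit, TopicModelResults):
        kind = "topic"
        _save_matrix(path / "L.csv", fit.L)
        _save_matrix(path / "F.csv", fit.F)
        _save_matrix(path / "s.csv", fit.s.reshape(-1, 1))
        _save_matrix(path / "u.csv", fit.u.reshape(-1, 1))
        if fit.pnmf is not None:
            _save_matrix(path / "H.csv", fit.pnmf.H)
            _save_matrix(path / "W.csv", fit.pnmf.W)
        objective = fit.pnmf.objective if fit.pnmf is not None else None
        trace = fit.pnmf.trace if fit.pnmf is not None else []
        config = fit.pnmf.config if fit.pnmf is not None else None
    else:
        raise TypeError(f"cannot serialize object of type {type(fit).__name__}")

    progress = pd.DataFrame(
        {
            "outer_iteration": [r.outer_iteration for r in trace],
            "objective": [r.objective for r in trace],
            "extrapolated": [r.extrapolated for r in trace],
            "beta": [r.beta for r in trace],
        }
    )
    buf = _io.StringIO()
    progress.to_csv(buf, index=False, float_format=FLOAT_FMT)
    (path / "progress.csv").write_text(buf.getvalue(), encoding="utf-8")

    meta = {
        "type": kind,
        "K": int(fit.K),
        "objective": objective,
        "config": _config_to_jsonable(config),
    }
    with open(path / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def _read_trace(path: Path):
    from .model import ProgressRecord

    if not path.exists():
        raise FormatError(f"missing component {path.name}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: unreadable progress table: {exc}") from exc
    required = {"outer_iteration", "objective", "extrapolated", "beta"}
    if df.shape[0] and not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    return [
        ProgressRecord(
            outer_iteration=int(r.outer_iteration),
            objective=float(r.objective),
            extrapolated=bool(r.extrapolated),
            beta=float(r.beta),
        )
        for r in df.itertuples()
    ]


def read_fit(path):
    """Read a fit directory written by :func:`write_fit`."""
    from .model import PoissonNMFResults, TopicModelResults, _config_from_dict

    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"{path}: missing meta.json")
    try:
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{meta_path}: invalid JSON: {exc}") from exc
    for key in ("type", "K"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing key {key!r}")
    trace = _read_trace(path / "progress.csv")
    config = _config_from_dict(meta.get("config"))
    if meta["type"] == "pnmf":
        H = _load_matrix(path / "H.csv")
        W = _load_matrix(path / "W.csv")
        return PoissonNMFResults(
            H=H,
            W=W,
            objective=float(meta["objective"]),
            trace=trace,
            config=config,
            model=None,
        )
    if meta["type"] == "topic":
        L = _load_matrix(path / "L.csv")
        F = _load_matrix(path / "F.csv")
        s = _load_matrix(path / "s.csv").ravel()
        u = _load_matrix(path / "u.csv").ravel()
        pnmf = None
        if (path / "H.csv").exists():
            pnmf = PoissonNMFResults(
                H=_load_matrix(path / "H.csv"),
                W=_load_matrix(path / "W.csv"),
                objective=(
                    float(meta["objective"]) if meta.get("objective") is not None else None
                ),
                trace=trace,
                config=config,
                model=None,
            )
        return TopicModelResults(L=L, F=F, s=s, u=u, pnmf=pnmf, model=None)
    raise FormatError(f"{meta_path}: unknown fit type {meta['type']!r}")
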