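"""Delimited-text input/output and structured run reports.

Point clouds and distance matrices travel as plain delimited text (one row
per observation; comma, tab or whitespace separated).  Results serialize to
JSON reports that round-trip losslessly and always record the seed, and
decimation curves additionally to 4-column TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .decimation import DecimationCurve
from .estimator import IdEstimate
from .exceptions import InsufficientDataError, ParseError
from .neighbors import validate_distance_matrix

__all__ = [
    "read_points",
    "read_distance_matrix",
    "write_points",
    "RunReport",
    "write_report",
    "read_report",
    "write_curve_tsv",
    "read_curve_tsv",
]


def _diagnose_table(path, delimiter, skip: int) -> str | None:
    """Locate the first ragged or non-numeric row (1-based line numbers)."""
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if lineno <= skip or not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split(delimiter) if delimiter else stripped.split()
            if ncols is None:
                ncols = len(parts)
            if len(parts) != ncols:
                return f"ragged row {lineno}: expected {ncols} columns, found {len(parts)}"
            for value in parts:
                try:
                    float(value)
                except ValueError:
                    return f"non-numeric value {value!r} in row {lineno}"
    return None


def _read_table(path, delimiter=None, header: bool = False) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    skip = 1 if header else 0
    if delimiter is None:
        # auto-detect: comma if the first data line contains one, else whitespace
        with open(path) as fh:
            for i, line in enumerate(fh):
                stripped = line.strip()
                if i < skip or not stripped or stripped.startswith("#"):
                    continue
                delimiter = "," if "," in stripped else None
                break
    elif not delimiter.strip():
        delimiter = None  # any whitespace
    try:
        # np.loadtxt parses floats exactly (round-trip safe)
        return np.loadtxt(path, delimiter=delimiter, comments="#", skiprows=skip, ndmin=2)
    except ValueError as exc:
        detail = _diagnose_table(path, delimiter, skip)
        raise ParseError(f"{path}: {detail or exc}") from exc


def read_points(path, delimiter=None, header: bool = False) -> np.ndarray:
    """Read an N x D coordinate matrix from delimited text (N >= 3).

    The delimiter is auto-detected among comma / tab / whitespace unless
    given; ``header=True`` skips the first line.
    """
    values = _read_table(path, delimiter=delimiter, header=header)
    if values.shape[0] < 3:
        raise InsufficientDataError(
            f"{path}: need at least 3 points, found {values.shape[0]}"
        )
    return values


def read_distance_matrix(path, delimiter=None, header: bool = False) -> np.ndarray:
    """Read and validate a square symmetric distance matrix from text."""
    values = _read_table(path, delimiter=delimiter, header=header)
    return validate_distance_matrix(values)


def write_points(path, X, delimiter: str = " ", header=None) -> None:
    """Write a coordinate matrix as delimited text at full precision."""
    X = np.asarray(X, dtype=float)
    head = delimiter.join(header) if header else ""
    np.savetxt(path, X, delimiter=delimiter, header=head, comments="", fmt="%.17g")


def _estimate_payload(est: IdEstimate) -> dict:
    return {
        "kind": "id_estimate",
        "d_hat": est.d_hat,
        "discard_fraction": est.discard_fraction,
        "n_total": est.n_total,
        "n_used": est.n_used,
        "residual_rms": est.residual_rms,
        "fit_x": [float(v) for v in est.fit_x],
        "fit_y": [float(v) for v in est.fit_y],
    }


def _curve_payload(curve: DecimationCurve) -> dict:
    return {
        "kind": "decimation_curve",
        "block_size": [int(v) for v in curve.block_size],
        "d_mean": [float(v) for v in curve.d_mean],
        "d_std": [float(v) for v in curve.d_std],
        "n_blocks": [int(v) for v in curve.n_blocks],
        "seed": curve.seed,
    }


def _result_payload(result) -> dict:
    if isinstance(result, IdEstimate):
        return _estimate_payload(result)
    if isinstance(result, DecimationCurve):
        return _curve_payload(result)
    raise TypeError(f"unsupported result type {type(result).__name__}")


def _result_from_payload(payload: dict):
    kind = payload.get("kind")
    if kind == "id_estimate":
        return IdEstimate(
            d_hat=payload["d_hat"],
            discard_fraction=payload["discard_fraction"],
            n_total=payload["n_total"],
            n_used=payload["n_used"],
            fit_x=np.asarray(payload["fit_x"], dtype=float),
            fit_y=np.asarray(payload["fit_y"], dtype=float),
            residual_rms=payload["residual_rms"],
        )
    if kind == "decimation_curve":
        return DecimationCurve(
            block_size=np.asarray(payload["block_size"], dtype=int),
            d_mean=np.asarray(payload["d_mean"], dtype=float),
            d_std=np.asarray(payload["d_std"], dtype=float),
            n_blocks=np.asarray(payload["n_blocks"], dtype=int),
            seed=payload.get("seed"),
        )
    raise ParseError(f"unknown result kind {kind!r}")


@dataclass
class RunReport:
    """Structured record of one run: command, inputs, seed, result.

    Serializes to JSON with deterministic field order and re-parses
    losslessly, so a recorded run can be replayed exactly.
    """

    command: str
    parameters: dict
    input_summary: dict
    result: object
    seed: int | None = None
    version: str = field(default="")
    timestamp: str = field(default="")

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "command": self.command,
            "parameters": self.parameters,
            "input_summary": self.input_summary,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "result": _result_payload(self.result),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunReport":
        return cls(
            command=payload["command"],
            parameters=payload["parameters"],
            input_summary=payload["input_summary"],
            result=_result_from_payload(payload["result"]),
            seed=payload.get("seed"),
            version=payload.get("version", ""),
            timestamp=payload.get("timestamp", ""),
        )


def write_report(report: RunReport, path) -> None:
    """Write a :class:`RunReport` as JSON (deterministic field order)."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def read_report(path) -> RunReport:
    with open(path) as fh:
        return RunReport.from_dict(json.load(fh))


def write_curve_tsv(curve: DecimationCurve, path) -> None:
    """Write a decimation curve as TSV: block_size, d_mean, d_std, n_blocks."""
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_curve_tsv(path) -> DecimationCurve:
    df = pd.read_csv(path, sep="\t")
    return DecimationCurve(
        block_size=df["block_size"].to_numpy(dtype=int),
        d_mean=df["d_mean"].to_numpy(dtype=float),
        d_std=df["d_std"].to_numpy(dtype=float),
        n_blocks=df["n_blocks"].to_numpy(dtype=int),
    )
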