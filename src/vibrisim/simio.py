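"""Structured text I/O: simulation logs, experiment results, run manifests.

Logs are delimited text (tab-separated, full float precision) with a YAML
metadata header in ``#``-prefixed lines, so they are diff-able and lossless
to round-trip.  Experiment results serialize to YAML documents with grids as
nested lists plus bin-edge metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import LOG_SCHEMA_VERSION, SimLog
from .experiments import CIAResult, HTAResult, SRResult
from .params import Params, dump_params

__all__ = ["write_log", "read_log", "LogFormatError", "RunManifest",
           "params_hash", "write_result", "result_to_dict"]


class LogFormatError(ValueError):
    """A log file does not match the expected schema."""


def params_hash(params: Params) -> str:
    """Stable short hash of a parameter set (for manifests and headers)."""
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run's outputs bit-for-bit."""

    experiment: str
    seed: int
    params_hash: str
    software_version: str
    outputs: tuple[str, ...]

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "experiment": self.experiment, "seed": self.seed,
            "params_hash": self.params_hash,
            "software_version": self.software_version,
            "outputs": list(self.outputs)}, sort_keys=False)


def write_log(log: SimLog, path: str | Path) -> None:
    """Write a log as tab-separated text with a ``#``-prefixed YAML header."""
    path = Path(path)
    meta = dict(log.meta)
    meta.setdefault("schema_version", LOG_SCHEMA_VERSION)
    meta["software_version"] = __version__
    header = yaml.safe_dump(meta, sort_keys=True)
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        log.df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_log(path: str | Path) -> SimLog:
    """Read a log written by :func:`write_log`; validates the schema."""
    path = Path(path)
    header_lines = []
    with open(path) as fh:
        pos = 0
        while True:
            line = fh.readline()
            if line.startswith("#"):
                # strip the comment marker but keep YAML indentation
                body = line[2:] if line.startswith("# ") else line[1:]
                header_lines.append(body.rstrip("\n"))
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        try:
            meta = yaml.safe_load("\n".join(header_lines)) or {}
        except yaml.YAMLError as exc:
            raise LogFormatError(f"unreadable log header: {exc}") from exc
        version = meta.get("schema_version")
        if version != LOG_SCHEMA_VERSION:
            raise LogFormatError(
                f"log schema version {version!r} != supported "
                f"{LOG_SCHEMA_VERSION}")
        try:
            df = pd.read_csv(fh, sep="\t")
        except pd.errors.ParserError as exc:
            raise LogFormatError(f"malformed log table: {exc}") from exc
    n = int(meta.get("n_whiskers_per_side", 7))
    expected = {"t", "tick", "fovea_x"} | {f"theta_base_L{i}" for i in range(1, n + 1)}
    missing = expected - set(df.columns)
    if missing:
        raise LogFormatError(f"log missing columns: {sorted(missing)}")
    return SimLog(df=df, meta=meta)


def result_to_dict(result) -> dict:
    """Convert an experiment result to a plain serializable mapping."""
    if isinstance(result, HTAResult):
        return {
            "kind": "hta", "slope": result.slope,
            "intercept": result.intercept, "correlation": result.correlation,
            "n": result.n,
        }
    if isinstance(result, CIAResult):
        return {
            "kind": "cia", "baseline_deg": result.baseline,
            "n_near": result.n_near, "n_far": result.n_far,
            "x_edges_mm": [float(v) for v in result.x_edges],
            "y_edges_mm": [float(v) for v in result.y_edges],
            "grid_mean_relative_deg": [
                [None if not np.isfinite(v) else float(v) for v in row]
                for row in result.grid],
            "grid_counts": [[int(v) for v in row] for row in result.counts],
        }
    if isinstance(result, SRResult):
        return {
            "kind": "sr", "n_selected": result.n_selected,
            "n_potential": result.n_potential,
            "spread_deg": result.stats, "spread_base_deg": result.stats_base,
        }
    raise TypeError(f"unknown result type: {type(result).__name__}")


def write_result(result, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(result_to_dict(result), fh, sort_keys=False)
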