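"""Structured file output with a reproducibility manifest.

Every CLI invocation writes plain CSV/JSON artifacts plus a
``manifest.json`` recording the full parameter snapshot, the seeds, the
package version, wall-clock bounds, and a SHA-256 checksum per output file —
enough to re-run the computation and verify byte-identical results.  Data
files are written atomically (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd

from . import __version__
from .config import params_to_dict
from .experiments import ComparisonResult, EnsembleSummary, SweepTable
from .observables import (RunRecord, histogram_to_frame, record_summary,
                          record_to_frame)
from .params import ModelParams

__all__ = ["RunManifest", "new_manifest", "write_outputs"]


@dataclass
class RunManifest:
    """Provenance of one invocation: config, seeds, and file checksums."""

    config: dict
    seeds: List[int]
    version: str = __version__
    started: Optional[str] = None
    finished: Optional[str] = None
    files: Dict[str, str] = field(default_factory=dict)   # name -> sha256

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def new_manifest(params: ModelParams, seeds: Union[int, List[int]]) -> RunManifest:
    if isinstance(seeds, int):
        seeds = [seeds]
    return RunManifest(config=params_to_dict(params), seeds=list(seeds),
                       started=_now())


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    _atomic_write(path, lambda p: df.to_csv(p, index=False))


def _write_json(obj: dict, path: Path) -> None:
    _atomic_write(path, lambda p: Path(p).write_text(
        json.dumps(obj, indent=2, default=_jsonable) + "\n"))


def _jsonable(x):
    try:
        return x.item()          # numpy scalars
    except AttributeError:
        return str(x)


def write_outputs(result, manifest: RunManifest,
                  out_dir: Union[str, Path]) -> RunManifest:
    """Write the artifacts for a run / ensemble / comparison / sweep.

    Returns the manifest updated with the file inventory; re-running with
    identical inputs produces byte-identical data files (the manifest's
    timestamps are the only fields that may differ).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: Dict[str, str] = {}

    def _put(name: str, write) -> None:
        path = out / name
        write(path)
        files[name] = _sha256(path)

    if isinstance(result, RunRecord):
        _put("timeseries.csv", lambda p: _write_csv(record_to_frame(result), p))
        if result.telomere_histogram is not None:
            _put("telomere_histogram.csv",
                 lambda p: _write_csv(histogram_to_frame(result), p))
        _put("summary.json", lambda p: _write_json(record_summary(result), p))
    elif isinstance(result, ComparisonResult):
        _put("ratios.json", lambda p: _write_json({
            "r_m": result.r_m, "r_l": result.r_l,
            "ts_constant": result.ts_constant,
            "sits": result.sits.to_dict(), "ts": result.ts.to_dict()}, p))
        _put("replicates.csv", lambda p: _write_csv(_replicates_frame(result), p))
    elif isinstance(result, EnsembleSummary):
        _put("ensemble.csv", lambda p: _write_csv(pd.DataFrame({
            "seed": result.seeds[:len(result.longevities)],
            "longevity": result.longevities,
            "mutation_rate": result.mutation_rates,
            "realized_damage": result.realized_damages}), p))
        _put("summary.json", lambda p: _write_json(result.to_dict(), p))
    elif isinstance(result, SweepTable):
        _put("sweep.csv", lambda p: _write_csv(result.to_frame(), p))
        _put("ratios.csv", lambda p: _write_csv(result.ratios_frame(), p))
    else:
        raise TypeError(f"don't know how to write a {type(result).__name__}")

    manifest.files.update(files)
    manifest.finished = _now()
    _write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


def _replicates_frame(comp: ComparisonResult) -> pd.DataFrame:
    n = len(comp.sits.longevities)
    return pd.DataFrame({
        "seed": comp.sits.seeds[:n],
        "sits_longevity": comp.sits.longevities,
        "ts_longevity": comp.ts.longevities,
        "sits_mutation_rate": comp.sits.mutation_rates,
        "ts_mutation_rate": comp.ts.mutation_rates,
    })
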