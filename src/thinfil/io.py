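"""Readers, writers and the run manifest.

Tabular artifacts are CSV with frozen column names; metrics, fits and
manifests are JSON. Schemas:

* pCa sweep — ``pca, force, force_se, drift_flag``
* trace — ``time, force[, force_se]``
* IVMA points — ``pca, velocity``
* grid cells (long format) — ``gamma_scale, kbc_scale, pca50, f_max,
  n_h, delta_pca50, pct_delta_vmax, sse``
* expression sweep — ``expression, f_peak, ttp, rt50, nfti,
  rt50_defined, pct_f_peak, pct_ttp, pct_rt50, pct_nfti``

Floats are written with 12 significant digits, so a read-back reproduces
values to better than 1e-9 relative error.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version_fallback

__all__ = ["write_table", "read_table", "write_json", "read_json", "RunManifest"]

_FLOAT_FORMAT = "%.12g"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)!r}")


@dataclass
class RunManifest:
    """Record of one pipeline run: the configuration snapshot, the
    provenance of the parameter sets, every seed used, the package
    version, and the path of every artifact each stage emitted.
    Re-running the same configuration and seed reproduces every
    stochastic artifact bit-identically."""

    config: dict
    seeds: dict = field(default_factory=dict)
    parameter_sets: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    stages_run: list = field(default_factory=list)
    stages_skipped: list = field(default_factory=list)
    version: str = _pkg_version_fallback

    def record(self, stage: str, name: str, path: str | Path) -> None:
        self.artifacts[f"{stage}:{name}"] = str(path)

    def save(self, path: str | Path) -> Path:
        return write_json(dataclasses.asdict(self), path)

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**read_json(path))
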