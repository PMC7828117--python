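"""Observation-table and configuration I/O.

One comma-separated long format serves both PK and PD data, NONMEM-style:

    ID, ARM, TIME, TYPE, DV, CENS, ULIM, AMT, EVID

Observation rows have EVID=0 (TYPE in plasma | lung | bioluminescence);
dose rows have EVID=1 with the amount in AMT.  Unknown extra columns are
preserved on round trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ARMS, ModelParams, flat_to_params

__all__ = [
    "REQUIRED_COLUMNS",
    "read_observations",
    "write_observations",
    "load_config",
    "RunConfig",
]

REQUIRED_COLUMNS = ("ID", "ARM", "TIME", "TYPE", "DV", "CENS", "ULIM", "AMT", "EVID")
_TYPES = ("plasma", "lung", "bioluminescence", "dose")


def _err(row, msg):
    raise ValueError(f"row {row}: {msg}")


def read_observations(path) -> pd.DataFrame:
    """Read and validate a long-format observation table.

    Rows with DV=0 and EVID=0 are loaded but flagged for exclusion
    (``EXCLUDE`` column), mirroring the exclusion of concentrations measured
    as zero; censored rows must carry an upper limit.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    for col in ("TIME", "DV", "CENS", "ULIM", "AMT", "EVID"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if col in ("TIME", "EVID") and (bad.any() or coerced.isna().any()):
            _err(int(np.argmax((bad | coerced.isna()).to_numpy())),
                 f"non-numeric {col}")
        if bad.any():
            _err(int(np.argmax(bad.to_numpy())), f"non-numeric {col}")
        df[col] = coerced
    obs = df.EVID == 0
    bad_dv = obs & df.DV.isna() & (df.CENS != 1)
    if bad_dv.any():
        _err(int(np.argmax(bad_dv.to_numpy())), "observation row without DV")
    cens_no_ulim = (df.CENS == 1) & ~(df.ULIM > 0)
    if cens_no_ulim.any():
        _err(int(np.argmax(cens_no_ulim.to_numpy())),
             "censored record without an upper limit")
    unknown_arm = ~df.ARM.isin(ARMS)
    if unknown_arm.any():
        _err(int(np.argmax(unknown_arm.to_numpy())),
             f"unknown ARM {df.ARM[unknown_arm].iloc[0]!r}")
    df["EXCLUDE"] = ((df.EVID == 0) & (df.CENS != 1) & ~(df.DV > 0))
    return df


def write_observations(df: pd.DataFrame, path) -> None:
    """Write an observation table; adds any missing canonical columns."""
    out = df.copy()
    for col, default in (("CENS", 0), ("ULIM", np.nan), ("AMT", np.nan),
                         ("EVID", 0)):
        if col not in out.columns:
            out[col] = default
    ordered = [c for c in REQUIRED_COLUMNS] + \
        [c for c in out.columns if c not in REQUIRED_COLUMNS and c != "EXCLUDE"]
    out[ordered].to_csv(path, index=False)


class RunConfig:
    """Validated run configuration.

    Sections: ``parameters`` (flat symbol->value overrides of the built-in
    published set), ``geometry`` (dynamic flag), ``design``, ``estimation``,
    ``simulation``, ``seeds``.  Unknown keys are rejected, not ignored.
    """

    _SECTIONS = ("parameters", "geometry", "design", "estimation",
                 "simulation", "seeds")
    _DESIGN_KEYS = ("n_per_time", "n_per_arm", "dose_ng", "pk_times",
                    "pd_schedule", "dropout_threshold", "loq")
    _EST_KEYS = ("n_starts", "method", "censoring", "maxiter", "n_nodes")
    _SIM_KEYS = ("horizon", "n", "grid_h", "with_ruv")

    def __init__(self, raw: dict = None):
        raw = dict(raw or {})
        unknown = set(raw) - set(self._SECTIONS)
        if unknown:
            raise KeyError(f"unknown config section(s): {sorted(unknown)}")
        self.parameters = dict(raw.get("parameters", {}))
        geometry = dict(raw.get("geometry", {}))
        unknown = set(geometry) - {"dynamic"}
        if unknown:
            raise KeyError(f"unknown geometry key(s): {sorted(unknown)}")
        self.dynamic = bool(geometry.get("dynamic", False))
        for section, allowed in (("design", self._DESIGN_KEYS),
                                 ("estimation", self._EST_KEYS),
                                 ("simulation", self._SIM_KEYS)):
            vals = dict(raw.get(section, {}))
            unknown = set(vals) - set(allowed)
            if unknown:
                raise KeyError(f"unknown {section} key(s): {sorted(unknown)}")
            setattr(self, section, vals)
        self.seeds = dict(raw.get("seeds", {}))
        # materialize the parameter set now so invariant violations surface
        # at load time with the offending symbol named
        self.params = flat_to_params(self.parameters, dynamic_geometry=self.dynamic)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls(json.loads(Path(path).read_text()))

    def model_params(self) -> ModelParams:
        return self.params

    def seed(self, stage: str, default: int = 0) -> int:
        return int(self.seeds.get(stage, self.seeds.get("global", default)))


def load_config(path=None) -> RunConfig:
    """Load a JSON run configuration; an absent or empty config yields the
    full built-in defaults (the published parameter set)."""
    if path is None:
        return RunConfig({})
    return RunConfig.from_file(path)
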