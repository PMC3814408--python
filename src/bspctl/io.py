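"""File formats and run configuration.

All tabular I/O is comma-separated with a header row, '.' decimal,
UTF-8, times in seconds as floats.  Configs are YAML or JSON with the
same schema.  Every CLI run writes a manifest (config digest, seed,
package version) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .controllers import LQRConfig, MPCConfig
from .estimator import BinaryObservation, EstimatorConfig
from .pk_model import PKParams
from .simulate import TargetSchedule

__all__ = [
    "read_eeg_csv", "read_observations_csv", "write_observations_csv",
    "read_infusions_csv", "write_estimates_csv", "load_config",
    "load_pk_params", "save_pk_params", "load_schedule", "save_schedule",
    "build_controller_configs", "manifest",
]


def load_config(path) -> dict:
    """YAML or JSON config file -> dict (by extension; YAML parses both)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def read_eeg_csv(path):
    """Two-column CSV (time_s, uV) -> (samples, fs). fs is inferred from
    the median time step."""
    df = pd.read_csv(path, float_precision="round_trip")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("EEG file must contain at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return v, fs


def read_observations_csv(path) -> list[BinaryObservation]:
    """CSV (t_index, N, n) -> BinaryObservation list."""
    df = pd.read_csv(path)
    need = {"t_index", "N", "n"}
    if not need <= set(df.columns):
        raise ValueError(f"observation CSV must have columns {sorted(need)}")
    return [
        BinaryObservation(t=int(r.t_index), n=int(r.n), N=int(r.N))
        for r in df.itertuples()
    ]


def write_observations_csv(observations, path):
    pd.DataFrame(
        {"t_index": [o.t for o in observations],
         "N": [o.N for o in observations],
         "n": [o.n for o in observations]}
    ).to_csv(path, index=False)


def read_infusions_csv(path) -> np.ndarray:
    """CSV with a column u_mg_min (or single column) -> rates array."""
    df = pd.read_csv(path, float_precision="round_trip")
    col = "u_mg_min" if "u_mg_min" in df.columns else df.columns[-1]
    return df[col].to_numpy(dtype=float)


def write_estimates_csv(results, path):
    """Filter output -> CSV (t_index, p_hat, z1_mean, z2_mean, var11,
    var22, cov12)."""
    rows = []
    for t, (belief, p_hat) in enumerate(results):
        m = belief.mean
        c = belief.cov
        z2 = m[1] if belief.dim > 1 else np.nan
        rows.append({
            "t_index": t, "p_hat": p_hat,
            "z1_mean": m[0], "z2_mean": z2,
            "var11": c[0, 0],
            "var22": c[1, 1] if belief.dim > 1 else np.nan,
            "cov12": c[0, 1] if belief.dim > 1 else np.nan,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_pk_params(source) -> PKParams:
    if isinstance(source, (str, Path)):
        return PKParams.from_dict(load_config(source))
    return PKParams.from_dict(dict(source))


def save_pk_params(params: PKParams, path):
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def load_schedule(source) -> TargetSchedule:
    if isinstance(source, (str, Path)):
        d = load_config(source)
    else:
        d = dict(source)
    return TargetSchedule.from_dict(d)


def save_schedule(schedule: TargetSchedule, path):
    Path(path).write_text(json.dumps(schedule.to_dict(), indent=2) + "\n")


def build_controller_configs(cfg: dict):
    """Controller config keys (q_e, q_c, r, u_min, u_max, mpc_horizon,
    terminal_cost) -> (LQRConfig, MPCConfig)."""
    q_e = float(cfg.get("q_e", 1.0))
    q_c = float(cfg.get("q_c", 0.0))
    u_min = float(cfg.get("u_min", 0.0))
    u_max = float(cfg.get("u_max", np.inf))
    lqr = LQRConfig(Q=np.diag([q_e, q_c]), R=float(cfg.get("r", 1.0)),
                    u_min=u_min, u_max=u_max)
    mpc = MPCConfig(horizon_T=int(cfg.get("mpc_horizon", 30)),
                    u_min=u_min, u_max=u_max,
                    terminal_cost=bool(cfg.get("terminal_cost", False)))
    return lqr, mpc


def build_estimator_config(cfg: dict) -> EstimatorConfig:
    w = cfg.get("process_noise", [1e-4, 1e-4])
    W = np.diag(np.asarray(w, dtype=float)) if np.ndim(w) == 1 else np.asarray(w, dtype=float)
    return EstimatorConfig(process_noise=W)


def manifest(config: dict, seed) -> dict:
    """Reproducibility manifest: config digest + seed + version."""
    digest = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {"config_sha256": digest, "seed": seed, "bspctl_version": __version__}
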