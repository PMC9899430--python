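"""File formats: trajectory CSV, posterior draws CSV, config YAML, manifests.

All CSV dialects are comma-separated UTF-8 with a mandatory header and '.'
decimal separator; floats are written with 17 significant digits so a
write/read round trip is bit-faithful.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .experiment import ExperimentConfig
from .inference import MCMCSettings, PosteriorSummary
from .simulators import Trajectory

__all__ = [
    "ConfigError",
    "trajectory_to_frame",
    "write_trajectory_csv",
    "write_ensemble_csv",
    "read_trajectory_csv",
    "write_draws_csv",
    "write_summary_json",
    "load_config",
    "config_to_dict",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"

_CONFIG_KEYS = {
    "sigma2_grid",
    "r_grid",
    "k",
    "n_steps",
    "n_discard",
    "n_replicates",
    "models_to_fit",
    "seed",
    "mcmc",
}
_MCMC_KEYS = {"n_chains", "n_iter", "n_burn", "thin", "seed", "proposal_scales"}


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def trajectory_to_frame(traj: Trajectory, replicate: int | None = None) -> pd.DataFrame:
    t = np.arange(len(traj.values))
    df = pd.DataFrame(
        {
            "t": t,
            "value": traj.values,
            "scale": traj.scale,
            "discard_flag": (t > 0) & (t <= traj.n_discard),
        }
    )
    if replicate is not None:
        df.insert(0, "replicate", replicate)
    return df


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    trajectory_to_frame(traj).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def write_ensemble_csv(trajs: Sequence[Trajectory], path: str | Path) -> Path:
    """Long-format ensemble CSV with a leading ``replicate`` column."""
    path = Path(path)
    frames = [trajectory_to_frame(traj, replicate=i) for i, traj in enumerate(trajs)]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def read_trajectory_csv(path: str | Path, replicate: int | None = None) -> Trajectory:
    """Read one trajectory from the documented CSV dialect.

    For long-format ensemble files, ``replicate`` selects which series to
    load.  The discard count is reconstructed from ``discard_flag``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    required = {"t", "value", "scale", "discard_flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required columns {sorted(missing)} "
            f"(found {list(df.columns)})"
        )
    if "replicate" in df.columns:
        if replicate is None:
            reps = df["replicate"].unique()
            if len(reps) > 1:
                raise ValueError(
                    f"{path} holds {len(reps)} replicates; pass replicate=<index>"
                )
            replicate = int(reps[0])
        df = df[df["replicate"] == replicate]
        if df.empty:
            raise ValueError(f"{path}: no rows for replicate {replicate}")
    df = df.sort_values("t")
    if not np.array_equal(df["t"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{path}: time index must be 0..n without gaps")
    scales = df["scale"].unique()
    if len(scales) != 1:
        raise ValueError(f"{path}: mixed scales {list(scales)}")
    values = df["value"].to_numpy(dtype=float)
    n_discard = int(df["discard_flag"].astype(bool).sum())
    return Trajectory(
        values=values,
        scale=str(scales[0]),
        y0=float(values[0]),
        n_total=len(values) - 1,
        n_discard=n_discard,
        seed=None,
        source="external",
    )


def write_draws_csv(post: PosteriorSummary, path: str | Path) -> Path:
    """Posterior draws in long format: chain,iter,parameter,value."""
    path = Path(path)
    frames = []
    for name, draws in post.draws.items():
        n_chain, n_draw = draws.shape
        frames.append(
            pd.DataFrame(
                {
                    "chain": np.repeat(np.arange(n_chain), n_draw),
                    "iter": np.tile(np.arange(n_draw), n_chain),
                    "parameter": name,
                    "value": draws.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    return path


def write_summary_json(obj, path: str | Path) -> Path:
    path = Path(path)
    if isinstance(obj, PosteriorSummary):
        obj = obj.to_dict()
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _build_mcmc(raw: dict) -> MCMCSettings:
    unknown = set(raw) - _MCMC_KEYS
    if unknown:
        raise ConfigError(f"unknown mcmc keys: {sorted(unknown)}")
    return MCMCSettings(**raw)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment configuration (YAML or JSON).

    Unknown keys are a hard error so typos cannot silently fall back to
    defaults.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "mcmc" in raw:
        raw = dict(raw)
        raw["mcmc"] = _build_mcmc(dict(raw["mcmc"]))
    try:
        return ExperimentConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def config_to_dict(config: ExperimentConfig) -> dict:
    d = asdict(config)
    d["sigma2_grid"] = list(config.sigma2_grid)
    d["r_grid"] = list(config.r_grid)
    d["models_to_fit"] = list(config.models_to_fit)
    return d


def write_manifest(
    path: str | Path,
    command: str,
    config: dict,
    seeds: dict,
    record_counts: dict | None = None,
    warnings: dict | None = None,
) -> Path:
    """Run manifest: config snapshot + seeds + tallies, enough to reproduce
    every output file bit for bit with the same package version."""
    from importlib.metadata import version
    import datetime

    path = Path(path)
    manifest = {
        "package": "densvar",
        "version": version("densvar"),
        "command": command,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config,
        "seeds": seeds,
        "record_counts": record_counts or {},
        "warnings": warnings or {},
    }
    path.write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")
    return path
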