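"""End-to-end analysis runs with config, logging, and deterministic reports.

:func:`run_analysis` composes the library: descriptive statistics of an
observed synapse set, the uniform-redistribution null ensemble, per-branch
envelopes, and observed-vs-null comparisons (fraction of branches outside
the envelope, KS tests on nearest-neighbor distances, clustering curves).
Reports are a function of (inputs, master seed) only: rerunning the same
config produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .morphology import branch_decomposition, read_swc, sholl_3d
from .null_model import (
    branch_envelope,
    fraction_outside_envelope,
    null_statistic_distribution,
    pooled,
    simulate_ensemble,
)
from .spatial_stats import (
    branch_density_table,
    clustering_curve,
    fraction_with_neighbor_within,
    fraction_within_path_radius,
    ks_two_sample,
    nearest_neighbor_distances,
    radial_path_histogram,
)
from .synapses import read_synapse_csv

__all__ = ["RunConfig", "ConfigError", "run_analysis"]


class ConfigError(ValueError):
    """Invalid run configuration (detected before any computation)."""


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end analysis run."""

    swc_path: str
    synapse_csv: str
    out_dir: str
    region: str = "basal"
    n_replicates: int = 1000
    level: float = 0.95
    seed: int = 0
    neighbor_d_um: float = 5.0
    clustering_d_grid: tuple = (2.0, 5.0, 10.0, 15.0, 20.0, 30.0)
    radial_bin_um: float = 25.0
    sholl_step_um: float = 25.0

    def validate(self) -> None:
        for p, what in ((self.swc_path, "SWC file"), (self.synapse_csv, "synapse CSV")):
            if not Path(p).is_file():
                raise ConfigError(f"{what} not found: {p}")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 0 < self.level < 1:
            raise ConfigError("level must be in (0, 1)")
        if self.neighbor_d_um <= 0 or self.radial_bin_um <= 0 or self.sholl_step_um <= 0:
            raise ConfigError("distance parameters must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from None
        cfg.validate()
        return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_analysis(config: RunConfig) -> dict:
    """Run the full observed-vs-null analysis; writes the report bundle to
    ``config.out_dir`` and returns the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tree = read_swc(config.swc_path)
    synapses = read_synapse_csv(config.synapse_csv, tree)
    region = config.region
    branches = branch_decomposition(tree, region)
    n = len(synapses)

    # descriptive statistics
    table = branch_density_table(tree, branches, synapses)
    table.to_csv(out / "branch_table.csv", index=False)
    nn_obs = nearest_neighbor_distances(tree, synapses)
    radial = radial_path_histogram(tree, synapses, config.radial_bin_um)
    radial.to_csv(out / "radial_histogram.csv", index=False)
    max_r = float(np.max(tree.dist_root)) + config.sholl_step_um
    radii = np.arange(config.sholl_step_um, max_r, config.sholl_step_um)
    sholl = sholl_3d(tree, radii)
    obs_curve = clustering_curve(tree, synapses, np.asarray(config.clustering_d_grid))

    # null ensemble and comparisons
    ens = simulate_ensemble(tree, region, n, config.n_replicates, config.seed)
    env = branch_envelope(ens, branches, level=config.level)
    env.to_csv(out / "envelope.csv", index=False)
    frac_outside = fraction_outside_envelope(table, env)
    nn_null = null_statistic_distribution(
        ens, lambda t, s: nearest_neighbor_distances(t, s).distances
    )
    nn_null_pooled = pooled(nn_null)
    ks_D, ks_p = ks_two_sample(nn_obs.distances, nn_null_pooled)
    frac5_obs = fraction_with_neighbor_within(tree, synapses, config.neighbor_d_um)
    frac5_null = [float(np.mean(v <= config.neighbor_d_um)) for v in nn_null]

    summary = {
        "version": __version__,
        "inputs": {
            "swc_path": str(config.swc_path),
            "swc_sha256": _sha256(config.swc_path),
            "synapse_csv": str(config.synapse_csv),
            "synapse_sha256": _sha256(config.synapse_csv),
        },
        "parameters": asdict(config),
        "seeds": {"master_seed": config.seed, "n_replicates": config.n_replicates},
        "observed": {
            "n_synapses": n,
            "total_length_um": round(tree.total_length(region), 6),
            "n_branches": len(branches),
            "nn_mean_um": round(float(np.mean(nn_obs.distances)), 6),
            "nn_median_um": round(float(np.median(nn_obs.distances)), 6),
            "fraction_neighbor_within_d": round(frac5_obs, 6),
            "fraction_within_200um_path": round(
                fraction_within_path_radius(tree, synapses, 200.0), 6
            ),
            "clustering_curve": {
                "d_um": list(map(float, obs_curve.thresholds)),
                "mean_coefficient": [
                    None if np.isnan(v) else round(float(v), 6)
                    for v in obs_curve.mean_coefficient
                ],
            },
            "sholl": {
                "radius_um": list(map(float, sholl.radii)),
                "intersections": list(map(int, sholl.intersections)),
            },
        },
        "null": {
            "nn_mean_um": round(float(np.mean(nn_null_pooled)), 6),
            "fraction_neighbor_within_d_mean": round(float(np.mean(frac5_null)), 6),
            "fraction_neighbor_within_d_sd": round(float(np.std(frac5_null)), 6),
        },
        "comparison": {
            "fraction_branches_outside_envelope": round(frac_outside, 6),
            "ks_statistic_nn": round(ks_D, 6),
            "ks_p_nn": float(f"{ks_p:.6g}"),
        },
    }
    _write_json(summary, out / "summary.json")
    return summary
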