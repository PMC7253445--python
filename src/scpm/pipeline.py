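"""End-to-end orchestration: simulate → connectivity → clusters → features →
outcomes → predictive model, with all artifacts written under one output
directory and every random draw governed by a single config seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .clusters import (cluster_extent_threshold, cluster_mean_features,
                       clusterize, group_contrast,
                       participant_condition_differences)
from .connectivity import EpochSpec, connectivity_maps, differential_maps
from .model import permutation_pvalue
from .outcomes import align_outcome, epoch_rating_means, relative_outcome
from .simulate import (SimTimeseriesConfig, default_layout, generate_ratings,
                       generate_timeseries_dataset)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated configuration of the demo study pipeline."""
    out_dir: str = "scpm_out"
    n_participants: int = 16
    grid_dims: tuple = (24, 24, 16)
    voxel_mm: float = 2.0
    seed: int = 0
    # simulation ground truth
    rho_neutral: float = 0.1
    rho_stress_range: tuple = (0.4, 0.9)
    evoked_amp: float = 0.5
    confound_amp: float = 0.3
    noise_sd: float = 0.1
    rating_coupling: float = 0.9
    rating_noise_sd: float = 0.2
    rating_base: float = 2.0
    # analysis
    outcome_label: str = "mean_stress"
    reference: str = "S-B"
    window: str = "all"
    voxel_p: float = 0.001
    alpha: float = 0.05
    selection_p: float = 0.05
    scheme: str = "loo"
    n_splits: int = 10
    n_perm: int = 200
    extent_n_perm: int = 200
    fwhm_mm: float = 0.0

    def __post_init__(self):
        for name in ("voxel_p", "alpha", "selection_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.n_participants < 4:
            raise ValueError("need at least 4 participants")
        self.grid_dims = tuple(self.grid_dims)
        self.rho_stress_range = tuple(self.rho_stress_range)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)


def simulate_study_diff_maps(cfg: PipelineConfig):
    """Simulate every participant and reduce to differential z maps.

    Per participant, a stressor-condition seed-cluster coupling is drawn from
    ``rho_stress_range``; the full background-connectivity stage (confound +
    evoked regression, bandpass, epoching, seed maps) is run per condition and
    the epoch-minus-baseline differentials kept.  Returns ``(diff_maps,
    truths, seed_mask, cluster_masks)`` where ``truths`` maps participant id
    to the drawn coupling.
    """
    rng = np.random.default_rng(cfg.seed)
    layout = default_layout(cfg.grid_dims)
    diff_maps, truths = {}, {}
    seed_mask = cluster_masks = None
    for i in range(cfg.n_participants):
        pid = f"p{i:03d}"
        rho_s = float(rng.uniform(*cfg.rho_stress_range))
        truths[pid] = rho_s
        scfg = SimTimeseriesConfig(
            grid_dims=cfg.grid_dims, voxel_mm=cfg.voxel_mm,
            seed_roi=layout["seed_roi"],
            target_clusters=((layout["cluster_a"], cfg.rho_neutral, rho_s),),
            evoked_amp=cfg.evoked_amp, confound_amp=cfg.confound_amp,
            noise_sd=cfg.noise_sd, seed=int(rng.integers(2 ** 31)))
        sim = generate_timeseries_dataset(scfg)
        per_cond = {}
        for cond, ts in sim.bold.items():
            ts.participant_id = pid
            maps = connectivity_maps(ts, sim.confounds[cond], sim.task[cond],
                                     sim.seed_mask, fwhm_mm=cfg.fwhm_mm,
                                     voxel_mm=cfg.voxel_mm)
            per_cond[cond] = differential_maps(maps)
        diff_maps[pid] = per_cond
        seed_mask, cluster_masks = sim.seed_mask, sim.cluster_masks
    return diff_maps, truths, seed_mask, cluster_masks


def run_pipeline(config) -> dict:
    """Execute the complete pipeline from a config dict / PipelineConfig.

    Writes the group stat map, cluster set, feature matrix, outcomes and the
    model result (JSON) under ``out_dir``; re-running with the same config
    reproduces identical JSON/TSV artifacts.  Returns the result bundle.
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_dict(dict(config))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.save_json(asdict(cfg), out / "config.json")

    stage = "simulate+connectivity"
    try:
        diff_maps, truths, seed_mask, _ = simulate_study_diff_maps(cfg)

        stage = "clusters"
        diffs, kept = participant_condition_differences(diff_maps)
        k_min = cluster_extent_threshold(diffs, voxel_p=cfg.voxel_p,
                                         alpha=cfg.alpha,
                                         n_perm=cfg.extent_n_perm,
                                         seed=cfg.seed)
        stat_map = group_contrast(diff_maps)
        cluster_set = clusterize(stat_map, voxel_p=cfg.voxel_p, extent=k_min)
        cluster_set.seed_label = seed_mask.label
        io.save_cluster_set(cluster_set, out / "clusters.nii.gz",
                            out / "clusters.json", cfg.voxel_mm)
        if len(cluster_set) == 0:
            raise ValueError("no supra-threshold group clusters")

        stage = "features"
        features = cluster_mean_features(diff_maps, cluster_set,
                                         reference=cfg.reference,
                                         window=cfg.window)
        io.save_tsv(features, out / "features.tsv")

        stage = "outcomes"
        rng = np.random.default_rng(cfg.seed + 1)
        tables = []
        for pid in features.index:
            drift = 1.0 + cfg.rating_coupling * np.arctanh(truths[pid]) \
                + rng.normal(0, cfg.rating_noise_sd)
            t = generate_ratings(1, drift=drift, noise_sd=0.0,
                                 seed=int(rng.integers(2 ** 31)),
                                 base=cfg.rating_base)
            t["participant"] = pid
            tables.append(t)
        ratings = pd.concat(tables, ignore_index=True)
        io.save_tsv(ratings, out / "ratings.tsv", index=False)
        means = epoch_rating_means(ratings)
        outcome = align_outcome(features,
                                relative_outcome(means, cfg.outcome_label,
                                                 reference=cfg.reference))
        io.save_tsv(outcome.to_frame(), out / "outcomes.tsv")

        stage = "fit"
        result = permutation_pvalue(features, outcome, n_perm=cfg.n_perm,
                                    seed=cfg.seed, scheme=cfg.scheme,
                                    n_splits=cfg.n_splits,
                                    p_thresh=cfg.selection_p)
        result.participant_ids = list(features.index)
        io.save_json(result.to_dict(), out / "result.json")
        np.savetxt(out / "null_rs.tsv",
                   np.column_stack([result.null["positive"],
                                    result.null["negative"]]),
                   delimiter="\t", header="positive\tnegative", comments="")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    return {"config": cfg, "clusters": cluster_set, "features": features,
            "outcome": outcome, "result": result,
            "cluster_extent_min": k_min, "truth_rho": truths}
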