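"""Synthetic datasets with planted ground truth.

Two levels of simulation:

* **Feature level** — participant x cluster matrices of i.i.d. standard-normal
  connectivity values with an outcome linearly coupled to the mean of a
  planted positive network minus the mean of a planted negative network.
  These exercise the predictive-modeling stages directly.

* **Timeseries level** — small 4D BOLD-like volumes emulating the acquisition
  design: per condition (Stressor / Neutral), two 66-s baseline runs followed
  by six 66-s image runs at TR = 1 s.  Seed-ROI voxels share a band-limited
  (0.01–0.1 Hz) latent signal; planted target clusters couple to it with a
  condition-dependent coefficient; a task-evoked response (5-s image boxcar
  convolved with a double-gamma HRF) and confound components are superimposed
  so the background-connectivity pipeline has something real to remove.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (BoldTimeseries, ConfoundSet, EpochSpec, RoiMask,
                           TaskDesign, hrf_double_gamma)

CONDITIONS = ("Stressor", "Neutral")


# ---------------------------------------------------------------------------
# feature-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SimFeatureConfig:
    """Planted-network feature dataset configuration.

    ``beta`` is the outcome change (rating units) per unit of network-strength
    z; ``noise_sd`` the SD of additive outcome noise.
    """
    n_participants: int = 60
    n_clusters: int = 73
    pos_ids: tuple = (0,)
    neg_ids: tuple = (1,)
    beta: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        pos, neg = set(self.pos_ids), set(self.neg_ids)
        if pos & neg:
            raise ValueError("pos_ids and neg_ids overlap")
        if not pos | neg <= set(range(self.n_clusters)):
            raise ValueError("network ids outside 0..n_clusters-1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_participants < 4:
            raise ValueError("need at least 4 participants")


def generate_feature_dataset(cfg: SimFeatureConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw features ~ N(0,1) i.i.d. and a linearly coupled outcome.

    outcome_i = beta * mean(features_i over pos_ids)
              - beta * mean(features_i over neg_ids) + N(0, noise_sd^2)

    (a term is dropped when its network is empty).  Returns a DataFrame with
    participant index ``p000..`` and cluster columns ``c000..``, plus the
    outcome vector.
    """
    rng = np.random.default_rng(cfg.seed)
    X = rng.standard_normal((cfg.n_participants, cfg.n_clusters))
    y = np.zeros(cfg.n_participants)
    if cfg.pos_ids:
        y += cfg.beta * X[:, list(cfg.pos_ids)].mean(axis=1)
    if cfg.neg_ids:
        y -= cfg.beta * X[:, list(cfg.neg_ids)].mean(axis=1)
    y = y + cfg.noise_sd * rng.standard_normal(cfg.n_participants)
    df = pd.DataFrame(X,
                      index=[f"p{i:03d}" for i in range(cfg.n_participants)],
                      columns=[f"c{j:03d}" for j in range(cfg.n_clusters)])
    return df, y


# ---------------------------------------------------------------------------
# timeseries-level simulation
# ---------------------------------------------------------------------------

@dataclass
class SimTimeseriesConfig:
    grid_dims: tuple = (24, 24, 16)
    voxel_mm: float = 2.0
    tr_s: float = 1.0
    run_len_s: float = 66.0
    n_baseline_runs: int = 2
    n_image_runs: int = 6
    seed_roi: tuple = ()                 # tuple of (x, y, z) voxel indices
    target_clusters: tuple = ()          # ((voxels, rho_neutral, rho_stress), ...)
    band: tuple = (0.01, 0.1)
    evoked_amp: float = 0.0
    confound_amp: float = 0.0
    noise_sd: float = 0.1
    image_duration_s: float = 5.0
    isi_s: float = 1.0
    seed: int = 0

    def __post_init__(self):
        seed_set = set(map(tuple, self.seed_roi))
        occupied = set(seed_set)
        for voxels, rho_n, rho_s in self.target_clusters:
            vs = set(map(tuple, voxels))
            if vs & seed_set:
                raise ValueError("target cluster overlaps the seed ROI")
            occupied |= vs
        nvox = int(np.prod(self.grid_dims))
        for v in occupied:
            if not all(0 <= v[i] < self.grid_dims[i] for i in range(3)):
                raise ValueError("grid too small to host all masks")
        if len(occupied) > nvox:
            raise ValueError("grid too small to host all masks")
        for _, rho_n, rho_s in self.target_clusters:
            if not (-1 <= rho_n <= 1 and -1 <= rho_s <= 1):
                raise ValueError("couplings must lie in [-1, 1]")
        n_samp = self.run_len_s / self.tr_s
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ValueError("run length must be an integer number of TRs")

    @property
    def n_runs(self) -> int:
        return self.n_baseline_runs + self.n_image_runs

    @property
    def samples_per_run(self) -> int:
        return int(round(self.run_len_s / self.tr_s))


def default_layout(cfg_dims=(24, 24, 16)) -> dict:
    """A convenient seed-ROI / cluster layout on the default grid."""
    seed_roi = tuple((x, y, z) for x in range(3, 6) for y in range(10, 13)
                     for z in range(6, 9))
    clus_a = tuple((x, y, z) for x in range(14, 17) for y in range(5, 8)
                   for z in range(6, 9))
    clus_b = tuple((x, y, z) for x in range(14, 17) for y in range(16, 19)
                   for z in range(6, 9))
    return {"seed_roi": seed_roi, "cluster_a": clus_a, "cluster_b": clus_b}


def band_limited_signal(n: int, tr_s: float, band, rng) -> np.ndarray:
    """Unit-variance signal whose spectrum is confined to ``band`` (Hz).

    Synthesized by inverse real FFT of a white complex spectrum restricted to
    the in-band frequency bins, giving exact band control.
    """
    freqs = np.fft.rfftfreq(n, d=tr_s)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError("no FFT bin falls inside the requested band")
    spec = np.zeros(freqs.size, dtype=complex)
    k = int(in_band.sum())
    spec[in_band] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass
class SimTimeseries:
    """Bundle returned by :func:`generate_timeseries_dataset`."""
    bold: dict                      # condition -> BoldTimeseries
    confounds: dict                 # condition -> ConfoundSet
    task: dict                      # condition -> TaskDesign
    seed_mask: RoiMask
    cluster_masks: list             # list of RoiMask, one per target cluster
    config: SimTimeseriesConfig = field(repr=False, default=None)


def _mask_from_voxels(voxels, dims, label) -> RoiMask:
    m = np.zeros(dims, dtype=bool)
    for v in voxels:
        m[tuple(v)] = True
    return RoiMask(mask=m, label=label)


def _make_events(cfg: SimTimeseriesConfig) -> TaskDesign:
    events = []
    period = cfg.image_duration_s + cfg.isi_s
    n_images = int(cfg.run_len_s // period)
    for run in range(cfg.n_baseline_runs, cfg.n_runs):
        run_start = run * cfg.run_len_s
        for i in range(n_images):
            events.append((run_start + i * period, cfg.image_duration_s, run))
    return TaskDesign(events=events, image_duration_s=cfg.image_duration_s,
                      isi_s=cfg.isi_s, run_duration_s=cfg.run_len_s)


def _evoked_regressor(cfg: SimTimeseriesConfig, task: TaskDesign) -> np.ndarray:
    """Boxcar at image on/offsets convolved per run with the double-gamma HRF."""
    spr = cfg.samples_per_run
    total = cfg.n_runs * spr
    box = np.zeros(total)
    for onset, dur, _run in task.events:
        i0 = int(round(onset / cfg.tr_s))
        i1 = int(round((onset + dur) / cfg.tr_s))
        box[i0:i1] = 1.0
    hrf = hrf_double_gamma(cfg.tr_s, 32.0)
    out = np.zeros(total)
    for r in range(cfg.n_runs):
        seg = box[r * spr:(r + 1) * spr]
        out[r * spr:(r + 1) * spr] = np.convolve(seg, hrf)[:spr]
    return out


def _make_confounds(cfg: SimTimeseriesConfig, rng) -> ConfoundSet:
    spr = cfg.samples_per_run
    t = cfg.n_runs * spr
    # slow drift plus frame-to-frame jitter; tissue/global signals broadband
    motion = (np.cumsum(rng.normal(0, 0.005, size=(t, 6)), axis=0)
              + rng.normal(0, 0.002, size=(t, 6)))
    wm = rng.standard_normal(t)
    csf = rng.standard_normal(t)
    glob = rng.standard_normal(t)
    outliers = np.zeros((t, 2))
    frames = rng.choice(t, size=2, replace=False)
    outliers[frames[0], 0] = 1.0
    outliers[frames[1], 1] = 1.0
    run_slices = [(r * spr, (r + 1) * spr) for r in range(cfg.n_runs)]
    return ConfoundSet(motion6=motion, wm=wm, csf=csf, global_signal=glob,
                       outlier_indicators=outliers, run_slices=run_slices)


def generate_timeseries_dataset(cfg: SimTimeseriesConfig) -> SimTimeseries:
    """Simulate both conditions of one participant's session.

    Per run, seed voxels carry a fresh band-limited latent s(t) (plus a small
    amount of independent noise so the ROI mean is non-degenerate); each
    target-cluster voxel is ``rho * s(t) + sqrt(1 - rho^2) * d(t)`` with d(t)
    an independent band-limited distractor, plus the evoked response
    (``evoked_amp``), a confound combination (``confound_amp``) and white
    noise (``noise_sd``).  Baseline runs use the neutral coupling in both
    conditions, so planted epoch-minus-baseline differentials at cluster
    voxels equal atanh(rho_condition) - atanh(rho_neutral).  All remaining
    voxels are pure white noise.
    """
    rng = np.random.default_rng(cfg.seed)
    dims = tuple(cfg.grid_dims)
    spr = cfg.samples_per_run
    total = cfg.n_runs * spr
    run_slices = [(r * spr, (r + 1) * spr) for r in range(cfg.n_runs)]
    task = _make_events(cfg)
    evoked = cfg.evoked_amp * _evoked_regressor(cfg, task)

    seed_vox = list(map(tuple, cfg.seed_roi))
    bold, confs, tasks = {}, {}, {}
    for cond in CONDITIONS:
        conf = _make_confounds(cfg, rng)
        conf_mix = cfg.confound_amp * (0.5 * conf.wm + 0.3 * conf.csf
                                       + 0.2 * conf.global_signal)
        data = rng.normal(0, 1.0, size=dims + (total,))
        for r, (a, b) in enumerate(run_slices):
            s = band_limited_signal(spr, cfg.tr_s, cfg.band, rng)
            seg_evoked = evoked[a:b]
            for v in seed_vox:
                data[v][a:b] = (s + 0.05 * rng.standard_normal(spr)
                                + seg_evoked + conf_mix[a:b])
            baseline_run = r < cfg.n_baseline_runs
            for voxels, rho_n, rho_s in cfg.target_clusters:
                rho = rho_n if (baseline_run or cond == "Neutral") else rho_s
                for v in map(tuple, voxels):
                    d = band_limited_signal(spr, cfg.tr_s, cfg.band, rng)
                    data[v][a:b] = (rho * s + np.sqrt(max(1 - rho ** 2, 0.0)) * d
                                    + seg_evoked + conf_mix[a:b]
                                    + cfg.noise_sd * rng.standard_normal(spr))
        bold[cond] = BoldTimeseries(data=data, tr_s=cfg.tr_s,
                                    run_slices=run_slices, condition=cond,
                                    participant_id="sim")
        confs[cond] = conf
        tasks[cond] = task

    seed_mask = _mask_from_voxels(seed_vox, dims, "custom")
    cluster_masks = [_mask_from_voxels(voxels, dims, f"planted{i}")
                     for i, (voxels, _, _) in enumerate(cfg.target_clusters)]
    return SimTimeseries(bold=bold, confounds=confs, task=tasks,
                         seed_mask=seed_mask, cluster_masks=cluster_masks,
                         config=cfg)


# ---------------------------------------------------------------------------
# ratings
# ---------------------------------------------------------------------------

def generate_ratings(n_participants: int, spec: EpochSpec | None = None,
                     drift: float = 1.0, noise_sd: float = 0.5,
                     seed: int = 0, base: float = 3.0) -> pd.DataFrame:
    """Per-run 9-point ratings of stress, arousal and focus.

    Under the Stressor condition the stress/arousal means increase by
    ``drift`` per image epoch (sustained stress induction); the Neutral
    condition stays flat at ``base``.  Focus is high (7) in both conditions.
    Gaussian noise is added, then values are rounded to integers and clipped
    to [1, 9].  Columns: participant, condition, run, stress, arousal, focus.
    """
    if not np.isfinite(drift):
        raise ValueError("drift must be finite")
    spec = spec or EpochSpec()
    rng = np.random.default_rng(seed)
    epoch_of_run = {}
    for name, runs in spec.mapping.items():
        for r in runs:
            epoch_of_run[r] = name
    image_order = [e for e in spec.epoch_order if e != spec.baseline_epoch]
    rows = []
    for i in range(n_participants):
        pid = f"p{i:03d}"
        for cond in CONDITIONS:
            for run in sorted(epoch_of_run):
                epoch = epoch_of_run[run]
                if cond == "Stressor" and epoch != spec.baseline_epoch:
                    level = base + drift * (image_order.index(epoch) + 1)
                else:
                    level = base
                vals = {}
                for scale, mu in (("stress", level), ("arousal", level),
                                  ("focus", 7.0)):
                    v = mu + (noise_sd * rng.standard_normal() if noise_sd else 0.0)
                    vals[scale] = int(np.clip(round(v), 1, 9))
                rows.append({"participant": pid, "condition": cond,
                             "run": run, **vals})
    return pd.DataFrame(rows)


def generate_pss(n_participants: int, seed: int = 0) -> pd.Series:
    """Perceived Stress Scale totals (0-40 range), one per participant."""
    rng = np.random.default_rng(seed)
    vals = np.clip(np.round(rng.normal(16, 6, n_participants)), 0, 40)
    return pd.Series(vals, index=[f"p{i:03d}" for i in range(n_participants)],
                     name="pss")
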