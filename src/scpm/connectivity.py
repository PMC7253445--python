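"""Background seed connectivity from multi-run task fMRI.

The pipeline isolates spontaneous ("background") coupling during sustained
task blocks: per run, a GLM removes motion, tissue/global signals (plus
temporal derivatives), motion-outlier spikes, and the trial-evoked response
(image boxcar convolved with a double-gamma HRF, plus derivative); residuals
are bandpass filtered to 0.01–0.1 Hz — the 1-image-per-6-s stimulus rate
(0.17 Hz) sits above the passband, so residual evoked structure is further
suppressed — and optionally spatially smoothed.  Runs are aggregated into
two-run epochs (baseline, early, mid, late; 132 s each), a seed-ROI mean
timeseries is correlated with every voxel, r maps are Fisher z-transformed,
and epoch-minus-baseline differential maps are formed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import ndimage
from scipy.special import gamma as gamma_fn

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
R_CLIP = 1.0 - 1e-7


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BoldTimeseries:
    """4D voxel signal (x, y, z, t) with run structure."""
    data: np.ndarray
    tr_s: float
    run_slices: list            # ordered [(start, end)) sample indices
    condition: str = ""
    participant_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (x, y, z, t)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("non-finite values in timeseries")
        t = self.data.shape[-1]
        prev = 0
        for a, b in self.run_slices:
            if a != prev or b <= a:
                raise ValueError("run_slices must be disjoint, ordered and "
                                 "cover the time axis exactly")
            prev = b
        if prev != t:
            raise ValueError("run_slices do not cover the time axis")

    @property
    def n_t(self) -> int:
        return self.data.shape[-1]

    @property
    def n_runs(self) -> int:
        return len(self.run_slices)

    def with_data(self, data: np.ndarray) -> "BoldTimeseries":
        return BoldTimeseries(data=data, tr_s=self.tr_s,
                              run_slices=list(self.run_slices),
                              condition=self.condition,
                              participant_id=self.participant_id)


@dataclass
class ConfoundSet:
    """Nuisance regressors aligned to a :class:`BoldTimeseries`."""
    motion6: np.ndarray            # (t, 6) translations mm, rotations rad
    wm: np.ndarray
    csf: np.ndarray
    global_signal: np.ndarray
    outlier_indicators: np.ndarray  # (t, k) one-hot spike regressors
    run_slices: list

    def __post_init__(self):
        self.motion6 = np.asarray(self.motion6, dtype=float)
        self.wm = np.asarray(self.wm, dtype=float).ravel()
        self.csf = np.asarray(self.csf, dtype=float).ravel()
        self.global_signal = np.asarray(self.global_signal, dtype=float).ravel()
        self.outlier_indicators = np.atleast_2d(
            np.asarray(self.outlier_indicators, dtype=float))
        if self.outlier_indicators.shape[0] != self.motion6.shape[0]:
            self.outlier_indicators = self.outlier_indicators.T
        t = self.motion6.shape[0]
        if self.motion6.shape != (t, 6):
            raise ValueError("motion6 must be (t, 6)")
        for v in (self.wm, self.csf, self.global_signal):
            if v.shape != (t,):
                raise ValueError("tissue/global vectors must have length t")
        ko = self.outlier_indicators
        if ko.size and (ko.sum(axis=0) > 1).any():
            raise ValueError("outlier indicator columns must be one-hot in time")

    @property
    def n_t(self) -> int:
        return self.motion6.shape[0]


@dataclass
class TaskDesign:
    """Image-presentation events: (onset_s, duration_s, run_index)."""
    events: list
    image_duration_s: float = 5.0
    isi_s: float = 1.0
    run_duration_s: float = 66.0

    def __post_init__(self):
        last = -np.inf
        for onset, dur, run in self.events:
            if onset < last:
                raise ValueError("event onsets must be non-decreasing")
            last = onset
            if not (run * self.run_duration_s - 1e-9 <= onset
                    and onset + dur <= (run + 1) * self.run_duration_s + 1e-9):
                raise ValueError(f"event at {onset}s falls outside run {run}")


@dataclass
class RoiMask:
    """Binary 3-D mask on the acquisition grid."""
    mask: np.ndarray
    label: str = "custom"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if not self.mask.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_set(self) -> set:
        return set(map(tuple, np.argwhere(self.mask)))


@dataclass
class EpochSpec:
    """Mapping of runs to two-run epochs (132 s each at the default design)."""
    mapping: dict = field(default_factory=lambda: {
        "baseline": (0, 1), "early": (2, 3), "mid": (4, 5), "late": (6, 7)})
    baseline_epoch: str = "baseline"
    epoch_order: tuple = ("baseline", "early", "mid", "late")

    def __post_init__(self):
        seen = set()
        for name, runs in self.mapping.items():
            runs = tuple(runs)
            if len(runs) != 2 or runs[1] != runs[0] + 1:
                raise ValueError(f"epoch {name!r} must span exactly two "
                                 "consecutive runs")
            if seen & set(runs):
                raise ValueError("epochs must be disjoint")
            seen |= set(runs)

    @property
    def image_epochs(self) -> list:
        return [e for e in self.epoch_order if e != self.baseline_epoch]


@dataclass
class SeedConnectivityMap:
    """Seed-to-voxel Fisher-z map for one participant/condition/epoch."""
    z_values: np.ndarray
    participant_id: str = ""
    condition: str = ""
    epoch: str = ""
    seed_label: str = ""

    def __post_init__(self):
        self.z_values = np.asarray(self.z_values, dtype=float)
        if not np.isfinite(self.z_values).all():
            raise ValueError("z map contains non-finite values")


# ---------------------------------------------------------------------------
# HRF and confound regression
# ---------------------------------------------------------------------------

def hrf_double_gamma(tr_s: float, duration_s: float = 32.0,
                     peak_delay_s: float = 6.0, undershoot_delay_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Difference of two gamma densities (response peaking near 6 s, undershoot
    near 16 s, undershoot 1/6 of the peak), normalized to unit peak.  The
    value at t = 0 is exactly 0.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0, duration_s + tr_s / 2, tr_s)
    disp = 1.0  # dispersion of both gammas, s

    def gpdf(x, shape, scale):
        x = np.maximum(x, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (x ** (shape - 1) * np.exp(-x / scale)
                   / (gamma_fn(shape) * scale ** shape))
        return np.where(x > 0, out, 0.0)

    h = gpdf(t, peak_delay_s / disp, disp) \
        - undershoot_ratio * gpdf(t, undershoot_delay_s / disp, disp)
    peak = np.abs(h).max()
    return h / peak if peak > 0 else h


def _derivative(x: np.ndarray) -> np.ndarray:
    """Backward differences, first element 0 (length preserving)."""
    d = np.zeros_like(np.asarray(x, dtype=float))
    d[1:] = np.diff(np.asarray(x, dtype=float), axis=0)
    return d


def task_regressor(task: TaskDesign, tr_s: float, n_t: int,
                   run_slices) -> np.ndarray:
    """Boxcar at image on/offsets convolved per run with the HRF."""
    box = np.zeros(n_t)
    for onset, dur, _run in task.events:
        i0 = int(round(onset / tr_s))
        i1 = min(int(round((onset + dur) / tr_s)), n_t)
        box[i0:i1] = 1.0
    hrf = hrf_double_gamma(tr_s)
    out = np.zeros(n_t)
    for a, b in run_slices:
        out[a:b] = np.convolve(box[a:b], hrf)[: b - a]
    return out


def _run_design(conf: ConfoundSet, task_reg: np.ndarray, a: int, b: int
                ) -> np.ndarray:
    """Per-run design: intercept, motion6 + derivatives, wm/csf/global +
    derivatives, outlier spikes, task regressor + derivative."""
    cols = [np.ones(b - a)]
    m = conf.motion6[a:b]
    cols += [m, _derivative(m)]
    for v in (conf.wm, conf.csf, conf.global_signal):
        seg = v[a:b][:, None]
        cols += [seg, _derivative(seg)]
    ko = conf.outlier_indicators[a:b]
    keep = ko.sum(axis=0) > 0   # spikes falling inside this run
    if keep.any():
        cols.append(ko[:, keep])
    tr = task_reg[a:b][:, None]
    cols += [tr, _derivative(tr)]
    D = np.column_stack(cols)
    # structurally absent regressors (e.g. the task column in baseline runs)
    D = D[:, (D != 0).any(axis=0)]
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        warnings.warn(f"rank-deficient design in run [{a}:{b}) "
                      f"({rank}/{D.shape[1]}); collinear columns ignored")
    return D


def confound_regress(ts: BoldTimeseries, conf: ConfoundSet,
                     task: TaskDesign | None = None) -> BoldTimeseries:
    """Per-run OLS residualization of every voxel on the nuisance design.

    Residuals are orthogonal to every regressor within each run (least-squares
    projection; rank-deficient designs are handled by the minimum-norm
    solution with a warning).
    """
    if conf.n_t != ts.n_t:
        raise ValueError("confound rows do not match timeseries length")
    task_reg = (task_regressor(task, ts.tr_s, ts.n_t, ts.run_slices)
                if task is not None else np.zeros(ts.n_t))
    flat = ts.data.reshape(-1, ts.n_t)
    resid = np.empty_like(flat)
    for a, b in ts.run_slices:
        D = _run_design(conf, task_reg, a, b)
        Y = flat[:, a:b].T                       # (t_run, n_voxels)
        beta, *_ = np.linalg.lstsq(D, Y, rcond=None)
        resid[:, a:b] = (Y - D @ beta).T
    return ts.with_data(resid.reshape(ts.data.shape))


# ---------------------------------------------------------------------------
# temporal filtering and spatial smoothing
# ---------------------------------------------------------------------------

def bandpass(ts: BoldTimeseries, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 4) -> BoldTimeseries:
    """Zero-phase Butterworth bandpass applied forward-backward per run.

    Each run is demeaned (DC is outside the passband) and filtered with
    Gustafsson edge handling, which keeps transients small on 66-sample
    runs.  Raises if a run is shorter than the filter warm-up length.
    """
    fs = 1.0 / ts.tr_s
    if high_hz >= fs / 2:
        raise ValueError("high_hz must be below the Nyquist frequency")
    b, a = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs)
    warmup = 3 * (max(len(a), len(b)) - 1)
    flat = ts.data.reshape(-1, ts.n_t)
    out = np.empty_like(flat)
    for ri, (i0, i1) in enumerate(ts.run_slices):
        if i1 - i0 <= warmup:
            raise ValueError(f"run {ri} ([{i0}:{i1})) shorter than the filter "
                             f"warm-up length {warmup}")
        seg = flat[:, i0:i1]
        seg = seg - seg.mean(axis=1, keepdims=True)
        out[:, i0:i1] = sps.filtfilt(b, a, seg, axis=1, method="gust")
    return ts.with_data(out.reshape(ts.data.shape))


def gaussian_smooth(ts: BoldTimeseries, fwhm_mm: float = 6.0,
                    voxel_mm: float = 2.0) -> BoldTimeseries:
    """Spatial Gaussian smoothing of each volume; ``fwhm_mm = 0`` is identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return ts.with_data(ts.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_mm
    out = ndimage.gaussian_filter(ts.data, sigma=(sigma_vox,) * 3 + (0,),
                                  mode="nearest")
    return ts.with_data(out)


# ---------------------------------------------------------------------------
# motion QC
# ---------------------------------------------------------------------------

def framewise_displacement(motion6: np.ndarray, radius_mm: float = 50.0
                           ) -> np.ndarray:
    """Per-frame FD: sum of |Δtranslation| plus radius x sum of |Δrotation|."""
    m = np.asarray(motion6, dtype=float)
    d = np.abs(np.diff(m, axis=0))
    fd = np.zeros(m.shape[0])
    fd[1:] = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return fd


def mean_framewise_displacement(motion6: np.ndarray, run_slices,
                                radius_mm: float = 50.0) -> np.ndarray:
    """Mean frame-to-frame displacement per run (first frame of each run
    excluded from the mean — there is no preceding frame within the run)."""
    fd = framewise_displacement(motion6, radius_mm)
    return np.array([fd[a + 1:b].mean() if b - a > 1 else 0.0
                     for a, b in run_slices])


def qc_exclude_runs(ts: BoldTimeseries, conf: ConfoundSet,
                    threshold_mm: float = 1.5, radius_mm: float = 50.0
                    ) -> list[int]:
    """Indices of runs retained after the motion criterion.

    Runs whose mean frame-to-frame displacement exceeds ``threshold_mm``
    (1.5 mm a priori) are dropped and logged; raises if nothing survives.
    """
    mfd = mean_framewise_displacement(conf.motion6, ts.run_slices, radius_mm)
    retained = [i for i, v in enumerate(mfd) if v <= threshold_mm]
    for i, v in enumerate(mfd):
        if v > threshold_mm:
            logger.warning("run %d excluded: mean FD %.3f mm > %.2f mm",
                           i, v, threshold_mm)
    if not retained:
        raise ValueError("all runs excluded by the motion criterion")
    return retained


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def split_longitudinal_thirds(roi: RoiMask, axis: int | None = None
                              ) -> tuple[RoiMask, RoiMask]:
    """Anterior- and posterior-most thirds of a mask along its long axis.

    By default the longitudinal axis is the first principal axis of the voxel
    cloud (oriented toward the grid's +y, the anterior direction); pass
    ``axis`` to force a grid axis instead.  Voxels whose projection falls in
    the anterior (posterior) third of the mask's extent form aHPC (pHPC).
    """
    coords = np.argwhere(roi.mask).astype(float)
    if axis is not None:
        proj = coords[:, axis]
    else:
        centered = coords - coords.mean(axis=0)
        cov = centered.T @ centered
        w, v = np.linalg.eigh(cov)
        direction = v[:, np.argmax(w)]
        if direction[1] < 0 or (direction[1] == 0 and direction.sum() < 0):
            direction = -direction
        proj = centered @ direction
    lo, hi = proj.min(), proj.max()
    if hi - lo <= 0 or len(np.unique(np.round(proj, 9))) < 3:
        raise ValueError("mask extent along the longitudinal axis is degenerate")
    third = (hi - lo) / 3.0
    ant = coords[proj > hi - third].astype(int)
    post = coords[proj < lo + third].astype(int)
    dims = roi.mask.shape
    a = np.zeros(dims, dtype=bool)
    p = np.zeros(dims, dtype=bool)
    a[tuple(ant.T)] = True
    p[tuple(post.T)] = True
    return RoiMask(a, label="aHPC"), RoiMask(p, label="pHPC")


def sphere_roi(center_mm, radius_mm: float = 7.0, grid_dims=(24, 24, 16),
               voxel_mm: float = 2.0,
               label: str = "control_sphere") -> RoiMask:
    """Mask of voxels whose center lies within ``radius_mm`` of ``center_mm``.

    Voxel (i, j, k) has center ``(i + 0.5) * voxel_mm`` etc.; world
    coordinates are grid-aligned mm.
    """
    center = np.asarray(center_mm, dtype=float)
    idx = np.indices(grid_dims).reshape(3, -1).T
    centers = (idx + 0.5) * voxel_mm
    d2 = ((centers - center) ** 2).sum(axis=1)
    inside = d2 <= radius_mm ** 2
    if not inside.any():
        raise ValueError("sphere contains no voxel centers")
    m = np.zeros(grid_dims, dtype=bool)
    m[tuple(idx[inside].T)] = True
    return RoiMask(m, label=label)


# ---------------------------------------------------------------------------
# epoching and connectivity maps
# ---------------------------------------------------------------------------

def epoch_segments(ts: BoldTimeseries, spec: EpochSpec | None = None,
                   retained_runs=None) -> dict:
    """Concatenate run pairs into epoch segments (baseline/early/mid/late).

    Returns ``{epoch: (voxels..., t_epoch) array}``; an epoch whose runs were
    excluded by QC is omitted with a log message.
    """
    spec = spec or EpochSpec()
    retained = set(range(ts.n_runs)) if retained_runs is None else set(retained_runs)
    out = {}
    for name in spec.epoch_order:
        runs = spec.mapping[name]
        if any(r >= ts.n_runs or r not in retained for r in runs):
            logger.warning("epoch %r unavailable (missing/excluded run)", name)
            continue
        segs = [ts.data[..., slice(*ts.run_slices[r])] for r in runs]
        out[name] = np.concatenate(segs, axis=-1)
    return out


def seed_map(segment: np.ndarray, roi: RoiMask, participant_id: str = "",
             condition: str = "", epoch: str = "", ) -> SeedConnectivityMap:
    """Seed-to-voxel Fisher-z map for one epoch segment.

    The seed timeseries is the mean over ROI voxels; per voxel, Pearson r is
    Fisher z-transformed after clipping |r| at 1 - 1e-7 so maps stay finite.
    Zero-variance voxels get z = 0 (count logged).
    """
    if segment.shape[-1] < 8:
        raise ValueError("segment too short for a connectivity estimate")
    if roi.mask.shape != segment.shape[:-1]:
        raise ValueError("ROI grid does not match the segment grid")
    seed_ts = segment[roi.mask].mean(axis=0)
    s = seed_ts - seed_ts.mean()
    ss = np.sqrt((s ** 2).sum())
    flat = segment.reshape(-1, segment.shape[-1])
    v = flat - flat.mean(axis=1, keepdims=True)
    sv = np.sqrt((v ** 2).sum(axis=1))
    bad = (sv == 0) | (ss == 0)
    if bad.any():
        logger.info("seed_map: %d zero-variance voxel(s) set to z=0",
                    int(bad.sum()))
    denom = np.where(bad, 1.0, sv * ss)
    r = np.where(bad, 0.0, v @ s / denom)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    return SeedConnectivityMap(z_values=z.reshape(segment.shape[:-1]),
                               participant_id=participant_id,
                               condition=condition, epoch=epoch,
                               seed_label=roi.label)


def differential_map(epoch_map: SeedConnectivityMap,
                     baseline_map: SeedConnectivityMap) -> np.ndarray:
    """Voxelwise epoch-minus-baseline z difference."""
    if epoch_map.z_values.shape != baseline_map.z_values.shape:
        raise ValueError("grid mismatch between epoch and baseline maps")
    for attr in ("participant_id", "condition", "seed_label"):
        if getattr(epoch_map, attr) != getattr(baseline_map, attr):
            raise ValueError(f"maps differ in {attr}")
    return epoch_map.z_values - baseline_map.z_values


def preprocess(ts: BoldTimeseries, conf: ConfoundSet,
               task: TaskDesign | None = None, fwhm_mm: float = 0.0,
               voxel_mm: float = 2.0, band=(0.01, 0.1)) -> BoldTimeseries:
    """Confound + evoked regression, bandpass, optional smoothing."""
    out = confound_regress(ts, conf, task)
    out = bandpass(out, band[0], band[1])
    if fwhm_mm:
        out = gaussian_smooth(out, fwhm_mm, voxel_mm)
    return out


def connectivity_maps(ts: BoldTimeseries, conf: ConfoundSet,
                      task: TaskDesign | None, roi: RoiMask,
                      spec: EpochSpec | None = None, fwhm_mm: float = 0.0,
                      voxel_mm: float = 2.0, qc_threshold_mm: float = 1.5
                      ) -> dict:
    """Full per-participant/condition stage: QC, preprocess, epoch, seed maps.

    Returns ``{epoch: SeedConnectivityMap}``.
    """
    spec = spec or EpochSpec()
    retained = qc_exclude_runs(ts, conf, threshold_mm=qc_threshold_mm)
    clean = preprocess(ts, conf, task, fwhm_mm=fwhm_mm, voxel_mm=voxel_mm)
    segs = epoch_segments(clean, spec, retained_runs=retained)
    return {name: seed_map(seg, roi, ts.participant_id, ts.condition, name)
            for name, seg in segs.items()}


def differential_maps(maps: dict, spec: EpochSpec | None = None) -> dict:
    """Epoch-minus-baseline z differences for every image epoch present."""
    spec = spec or EpochSpec()
    base = maps[spec.baseline_epoch]
    return {e: differential_map(maps[e], base)
            for e in spec.image_epochs if e in maps}
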