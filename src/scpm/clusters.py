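"""Group-level definition of stressor-modulated clusters.

Participant-level condition differences (Stressor minus Neutral differential
connectivity, averaged over image epochs) are tested voxelwise against zero;
supra-threshold voxels are grouped into clusters by first-nearest-neighbor
(face) adjacency with positive and negative voxels kept apart ("bi-sided"),
and a minimum cluster extent controlling the family-wise error rate is
derived from a sign-flip permutation null of the maximum cluster size.
Cluster means of the per-participant differential maps form the feature
matrix for predictive modeling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .connectivity import EpochSpec

logger = logging.getLogger(__name__)

FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # NN1 adjacency


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GroupStatMap:
    """Voxelwise signed test statistic and p-values for a group contrast."""
    stat: np.ndarray
    p: np.ndarray
    n_participants: int
    contrast: str = "Stressor vs Neutral"

    def __post_init__(self):
        self.stat = np.asarray(self.stat, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.stat.shape != self.p.shape:
            raise ValueError("stat and p grids differ")
        if np.nanmin(self.p) < 0 or np.nanmax(self.p) > 1:
            raise ValueError("p-values outside [0, 1]")


@dataclass
class Cluster:
    id: int
    voxels: np.ndarray      # (k, 3) int voxel indices
    sign: int               # +1 / -1 group-effect direction
    peak: tuple             # coordinate of max |stat|

    @property
    def size(self) -> int:
        return len(self.voxels)

    def voxel_set(self) -> set:
        return set(map(tuple, self.voxels))


@dataclass
class ClusterSet:
    clusters: list
    seed_label: str = ""
    adjacency: str = "faces"
    grid_dims: tuple = ()

    def __len__(self):
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def label_image(self) -> np.ndarray:
        img = np.zeros(self.grid_dims, dtype=int)
        for c in self.clusters:
            img[tuple(c.voxels.T)] = c.id
        return img


# ---------------------------------------------------------------------------
# group contrast
# ---------------------------------------------------------------------------

def participant_condition_differences(diff_maps: dict,
                                      spec: EpochSpec | None = None
                                      ) -> tuple[np.ndarray, list]:
    """Per-participant Stressor-minus-Neutral differential, epoch-pooled.

    ``diff_maps`` maps participant id -> condition -> {epoch: 3-D z-difference
    map}.  Image epochs are averaged within condition, then the Neutral value
    is subtracted.  Participants missing a condition are dropped with a log
    message.  Returns the stacked (n, x, y, z) array and the retained ids.
    """
    spec = spec or EpochSpec()
    diffs, kept = [], []
    for pid, conds in diff_maps.items():
        if not {"Stressor", "Neutral"} <= set(conds):
            logger.warning("participant %s dropped: missing a condition", pid)
            continue
        per_cond = {}
        for cond in ("Stressor", "Neutral"):
            epochs = [conds[cond][e] for e in spec.image_epochs
                      if e in conds[cond]]
            if not epochs:
                break
            per_cond[cond] = np.mean(epochs, axis=0)
        if len(per_cond) < 2:
            logger.warning("participant %s dropped: no usable epochs", pid)
            continue
        diffs.append(per_cond["Stressor"] - per_cond["Neutral"])
        kept.append(pid)
    if len(kept) < 4:
        raise ValueError("need at least 4 participants with both conditions")
    return np.stack(diffs), kept


def _one_sample_t(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
    t = np.where(sd == 0, 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    return t, p


def group_contrast(diff_maps: dict, covariates=None,
                   spec: EpochSpec | None = None) -> GroupStatMap:
    """One-sample test of the condition difference against zero per voxel.

    ``covariates`` (n, k), e.g. sex codes, are centered and regressed out of
    the per-participant differences before testing (degrees of freedom
    adjusted accordingly).
    """
    diffs, kept = participant_condition_differences(diff_maps, spec)
    n = diffs.shape[0]
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        Z = Z - Z.mean(axis=0)
        flat = diffs.reshape(n, -1)
        beta, *_ = np.linalg.lstsq(Z, flat, rcond=None)
        flat = flat - Z @ beta
        diffs = flat.reshape(diffs.shape)
        k = np.linalg.matrix_rank(Z)
        mean = diffs.mean(axis=0)
        sd = diffs.std(axis=0, ddof=1 + k)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / math.sqrt(n))
        t = np.where(sd == 0, 0.0, t)
        p = 2.0 * stats.t.sf(np.abs(t), n - 1 - k)
    else:
        t, p = _one_sample_t(diffs)
    return GroupStatMap(stat=t, p=p, n_participants=n)


# ---------------------------------------------------------------------------
# clusterization
# ---------------------------------------------------------------------------

def clusterize(stat_map: GroupStatMap, voxel_p: float = 0.001,
               extent: int = 1) -> ClusterSet:
    """Bi-sided first-nearest-neighbor clustering of supra-threshold voxels.

    Voxels with p < ``voxel_p`` are grouped into face-connected components,
    separately for positive and negative statistics (opposite signs are never
    merged); components smaller than ``extent`` voxels are discarded.
    Cluster ids are deterministic: descending size, ties broken by
    lexicographically smallest peak coordinate.
    """
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    supra = stat_map.p < voxel_p
    found = []
    for sign in (1, -1):
        mask = supra & (np.sign(stat_map.stat) == sign)
        labels, n = ndimage.label(mask, structure=FACE_STRUCTURE)
        for lab in range(1, n + 1):
            voxels = np.argwhere(labels == lab)
            if len(voxels) < extent:
                continue
            vals = np.abs(stat_map.stat[tuple(voxels.T)])
            peak = tuple(voxels[np.argmax(vals)])
            found.append((len(voxels), peak, sign, voxels))
    found.sort(key=lambda rec: (-rec[0], rec[1]))
    clusters = [Cluster(id=i + 1, voxels=rec[3], sign=rec[2], peak=rec[1])
                for i, rec in enumerate(found)]
    return ClusterSet(clusters=clusters, grid_dims=stat_map.stat.shape)


def cluster_extent_threshold(diffs: np.ndarray, voxel_p: float = 0.001,
                             alpha: float = 0.05, n_perm: int = 1000,
                             seed: int = 0) -> int:
    """Minimum cluster size controlling FWER at ``alpha``.

    Sign-flip permutations of the participant condition-differences generate
    the null distribution of the maximum supra-threshold cluster size; the
    returned extent is one voxel above its (1 - alpha) quantile, the smallest
    integer k with P(max null cluster size >= k) <= alpha.  ``alpha = 1``
    degenerates to k = 1 (every cluster passes).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if alpha >= 1.0:
        return 1
    rng = np.random.default_rng(seed)
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    max_sizes = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice((-1.0, 1.0), size=n)
        t, p = _one_sample_t(diffs * signs[:, None, None, None])
        supra = p < voxel_p
        biggest = 0
        for s in (1, -1):
            labels, nl = ndimage.label(supra & (np.sign(t) == s),
                                       structure=FACE_STRUCTURE)
            if nl:
                biggest = max(biggest, int(np.bincount(labels.ravel())[1:].max()))
        max_sizes[i] = biggest
    k = 1 + int(np.quantile(max_sizes, 1.0 - alpha, method="higher"))
    return max(k, 1)


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def cluster_mean_features(diff_maps: dict, clusters: ClusterSet,
                          reference: str = "S-B", window: str = "all",
                          spec: EpochSpec | None = None) -> pd.DataFrame:
    """Participant x cluster matrix of mean relative connectivity.

    Per participant and cluster, the mean over cluster voxels of the chosen
    relative differential: Stressor epoch-minus-baseline ("S-B") or its
    contrast against the Neutral analogue ("(S-B)-(N-B)"), averaged over all
    image epochs (``window="all"``) or the early epoch only.
    """
    spec = spec or EpochSpec()
    if reference not in ("S-B", "(S-B)-(N-B)"):
        raise ValueError(f"unknown reference {reference!r}")
    if window == "all":
        epochs = spec.image_epochs
    elif window == "early":
        epochs = [spec.image_epochs[0]]
    else:
        raise ValueError(f"unknown window {window!r}")
    rows, pids = [], []
    for pid, conds in diff_maps.items():
        maps = [conds["Stressor"][e] for e in epochs]
        rel = np.mean(maps, axis=0)
        if reference == "(S-B)-(N-B)":
            rel = rel - np.mean([conds["Neutral"][e] for e in epochs], axis=0)
        vals = []
        for c in clusters:
            if (c.voxels >= np.array(rel.shape)).any() or (c.voxels < 0).any():
                raise ValueError(f"cluster {c.id} lies outside the map grid")
            vals.append(rel[tuple(c.voxels.T)].mean())
        rows.append(vals)
        pids.append(pid)
    df = pd.DataFrame(rows, index=pids,
                      columns=[f"c{c.id:03d}" for c in clusters])
    df.attrs.update({"seed": clusters.seed_label, "reference": reference,
                     "window": window})
    return df
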