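"""Feature consistency across families of predictive models.

A cluster that is selected on *every* cross-validation fold of several models
(different outcomes, windows, reference schemes) is unlikely to be a selection
artifact.  The null model-count distribution is built by *linked* shuffles:
one participant relabeling per iteration, applied simultaneously to every
outcome in the family, so correlations among the outcomes are preserved while
their joint dependence on the brain features is broken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import SCPMResult, _batch_cv, _make_folds, cross_validate


def everyfold_clusters(result: SCPMResult) -> tuple[np.ndarray, np.ndarray]:
    """Cluster indices selected in every fold, per network sign."""
    pos = set(result.folds[0].pos_ids.tolist())
    neg = set(result.folds[0].neg_ids.tolist())
    for f in result.folds[1:]:
        pos &= set(f.pos_ids.tolist())
        neg &= set(f.neg_ids.tolist())
    return (np.array(sorted(pos), dtype=int), np.array(sorted(neg), dtype=int))


@dataclass
class ConsistencyResult:
    """Observed and null every-fold model-counts per cluster and sign."""
    cluster_ids: list
    observed_pos: np.ndarray     # (C,) number of models with every-fold inclusion
    observed_neg: np.ndarray
    null_pos: np.ndarray         # (n_perm, C)
    null_neg: np.ndarray
    p_pos: np.ndarray
    p_neg: np.ndarray
    family: list                 # descriptions of the member models
    n_perm: int
    seed: int

    def table(self) -> pd.DataFrame:
        rows = []
        for sign, obs, p in (("positive", self.observed_pos, self.p_pos),
                             ("negative", self.observed_neg, self.p_neg)):
            for cid, o, pv in zip(self.cluster_ids, obs, p):
                rows.append({"cluster": cid, "sign": sign,
                             "observed_models": int(o), "p": float(pv)})
        return pd.DataFrame(rows)


def consistency_permutation_test(family: list, n_perm: int = 1000,
                                 seed: int = 0, scheme: str = "loo",
                                 n_splits: int = 10, p_thresh: float = 0.05
                                 ) -> ConsistencyResult:
    """Linked-shuffle test of cross-model feature consistency.

    ``family`` is a list of ``(features, outcome)`` pairs sharing one
    participant set and one cluster set (features may be DataFrames with a
    common index, or aligned arrays).  Per permutation a single participant
    relabeling is applied to *all* outcomes; every model is refit and, per
    cluster and network sign, the number of models whose every-fold network
    contains the cluster is recorded.  ``p = (1 + #{null >= obs}) / (1 +
    n_perm)`` per cluster and sign.
    """
    if not family:
        raise ValueError("empty model family")
    mats, ys, descs = [], [], []
    index = None
    for i, (features, outcome) in enumerate(family):
        if isinstance(features, pd.DataFrame):
            if index is None:
                index = features.index
            elif not features.index.equals(index):
                raise ValueError("participant sets differ across family models")
        mats.append(np.asarray(features, dtype=float))
        ys.append(np.asarray(outcome, dtype=float))
        descs.append(getattr(features, "attrs", {}) or f"model{i}")
    n = len(ys[0])
    C = mats[0].shape[1]
    if any(m.shape != (n, C) for m in mats) or any(y.shape != (n,) for y in ys):
        raise ValueError("family models must share participants and clusters")

    obs_pos = np.zeros(C, dtype=int)
    obs_neg = np.zeros(C, dtype=int)
    for X, y in zip(mats, ys):
        res = cross_validate(X, y, scheme=scheme, n_splits=n_splits,
                             p_thresh=p_thresh, seed=seed)
        obs_pos[res.everyfold_pos] += 1
        obs_neg[res.everyfold_neg] += 1

    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    null_pos = np.zeros((n_perm, C), dtype=int)
    null_neg = np.zeros((n_perm, C), dtype=int)
    folds, _ = _make_folds(n, scheme, n_splits, seed)
    for X, y in zip(mats, ys):
        Y = y[perms]                                  # linked: same perms for all
        _, sel_pos, sel_neg = _batch_cv(X, Y, folds, p_thresh=p_thresh)
        null_pos += sel_pos.all(axis=1)
        null_neg += sel_neg.all(axis=1)

    p_pos = (1 + (null_pos >= obs_pos[None, :]).sum(axis=0)) / (1 + n_perm)
    p_neg = (1 + (null_neg >= obs_neg[None, :]).sum(axis=0)) / (1 + n_perm)
    ids = (list(family[0][0].columns)
           if isinstance(family[0][0], pd.DataFrame) else list(range(C)))
    return ConsistencyResult(cluster_ids=ids, observed_pos=obs_pos,
                             observed_neg=obs_neg, null_pos=null_pos,
                             null_neg=null_neg, p_pos=p_pos, p_neg=p_neg,
                             family=descs, n_perm=n_perm, seed=seed)


def seed_overlap(cluster_sets: dict, everyfold_ids: dict,
                 min_voxels: int = 1) -> list[list]:
    """Groups of anatomically overlapping every-fold clusters across seeds.

    ``cluster_sets`` maps seed label -> ClusterSet (all on one grid);
    ``everyfold_ids`` maps seed label -> iterable of cluster ids selected on
    every fold.  Clusters from *different* seeds sharing at least
    ``min_voxels`` voxels are linked; connected groups of linked clusters are
    returned as lists of ``(seed_label, cluster_id)``.
    """
    grids = {cs.grid_dims for cs in cluster_sets.values()}
    if len(grids) > 1:
        raise ValueError("cluster sets live on different grids")
    nodes, vox = [], []
    for label, cs in cluster_sets.items():
        wanted = set(everyfold_ids.get(label, ()))
        for c in cs:
            if c.id in wanted:
                nodes.append((label, c.id))
                vox.append(c.voxel_set())
    parent = list(range(len(nodes)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if nodes[i][0] == nodes[j][0]:
                continue  # same seed: never grouped by itself
            if len(vox[i] & vox[j]) >= min_voxels:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(len(nodes)):
        groups.setdefault(find(i), []).append(nodes[i])
    return sorted([sorted(g) for g in groups.values() if len(g) > 1])
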