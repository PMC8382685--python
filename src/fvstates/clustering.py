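"""Average-linkage RMSD clustering of trajectory frames.

Protocol: frames are pairwise-superposed over an alignment selection, the
RMSD over an analysis selection forms a symmetric distance matrix, and
unweighted average-linkage agglomeration is cut where the minimum
inter-cluster linkage distance exceeds a cutoff (1.2 A for the whole
paratope; 1.5 A / 2.5 A for individual light / heavy chain CDR loops).
The representative of each cluster is its medoid, i.e. a real frame.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from ._geometry import kabsch
from .errors import GeometryError, InputError
from .structures import AnnotatedFv, Trajectory

logger = logging.getLogger(__name__)

#: RMSD cutoffs (Angstrom) used in the loop-wise flexibility protocol.
HEAVY_LOOP_CUTOFF = 2.5
LIGHT_LOOP_CUTOFF = 1.5
#: RMSD cutoff (Angstrom) for whole-paratope ensemble clustering.
PARATOPE_CUTOFF = 1.2


@dataclass
class ClusterResult:
    """Partition of trajectory frames by average-linkage RMSD clustering."""

    labels: np.ndarray  # (frames,) int, 0-based, ordered by first occurrence
    cutoff: float
    representatives: np.ndarray  # (clusters,) medoid frame index
    populations: np.ndarray  # (clusters,) fraction of frames

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def rmsd_matrix(traj: Trajectory, selection, align_selection=None) -> np.ndarray:
    """Symmetric pairwise RMSD matrix (Angstrom) between all frames.

    Entry (i, j): frame j is superposed onto frame i over
    ``align_selection`` (default: same as ``selection``), then the RMSD is
    evaluated over ``selection``.  Per-pair alignment is direction
    dependent in principle, so the matrix is symmetrized by averaging; a
    discrepancy above 1e-6 A is logged.
    """
    if traj.n_frames < 2:
        raise InputError("need at least 2 frames for a distance matrix")
    selection = np.asarray(selection, int)
    align_selection = selection if align_selection is None else np.asarray(align_selection, int)
    if selection.size == 0 or align_selection.size == 0:
        raise GeometryError("empty selection")
    xa = traj.coords[:, align_selection]  # (F, A, 3)
    xs = traj.coords[:, selection]
    centered = xa - xa.mean(axis=1, keepdims=True)
    s = np.linalg.svd(centered[0], compute_uv=False)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise GeometryError("alignment selection is collinear")
    n = traj.n_frames
    d = np.zeros((n, n))
    for i in range(n):
        # batch-superpose every frame onto frame i over the align selection
        r, t = kabsch(xa, xa[i][None].repeat(n, axis=0))
        moved = np.einsum("fij,faj->fai", r, xs) + t[:, None, :]
        d[i] = np.sqrt(np.mean(np.sum((moved - xs[i]) ** 2, axis=-1), axis=-1))
    asym = np.max(np.abs(d - d.T))
    if asym > 1e-6:
        logger.info("rmsd matrix asymmetry %.3g A, symmetrizing by averaging", asym)
    return (d + d.T) / 2.0


class RMSDAgglomerative(BaseEstimator, ClusterMixin):
    """Average-linkage agglomerative clustering with a distance cutoff.

    scikit-learn style estimator over a precomputed symmetric distance
    matrix.  Merging stops exactly when the minimum inter-cluster
    unweighted-average linkage distance exceeds ``cutoff``.

    Attributes (after fit)
    ----------------------
    labels_ : (n,) cluster label per observation, 0-based, ordered by first
        occurrence so labeling is frame-permutation-equivariant.
    representatives_ : medoid index per cluster (minimum mean distance to
        its own cluster members).
    populations_ : member fraction per cluster.
    """

    def __init__(self, cutoff: float = PARATOPE_CUTOFF):
        self.cutoff = cutoff

    def fit(self, X, y=None):
        d = np.asarray(X, float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise InputError("distance matrix must be square")
        if np.max(np.abs(d - d.T)) > 1e-6:
            raise InputError("distance matrix not symmetric within 1e-6")
        if np.any(d < 0):
            raise InputError("distance matrix must be non-negative")
        d = (d + d.T) / 2.0
        n = d.shape[0]
        if n == 1:
            raw = np.zeros(1, dtype=int)
        else:
            z = linkage(squareform(d, checks=False), method="average")
            raw = fcluster(z, t=self.cutoff, criterion="distance") - 1
        # relabel by first occurrence for a deterministic, order-stable output
        remap: dict[int, int] = {}
        labels = np.empty(n, dtype=int)
        for i, lab in enumerate(raw):
            if lab not in remap:
                remap[lab] = len(remap)
            labels[i] = remap[lab]
        k = len(remap)
        reps = np.empty(k, dtype=int)
        pops = np.empty(k)
        for c in range(k):
            members = np.nonzero(labels == c)[0]
            mean_d = d[np.ix_(members, members)].mean(axis=1)
            reps[c] = members[int(np.argmin(mean_d))]
            pops[c] = len(members) / n
        self.labels_ = labels
        self.representatives_ = reps
        self.populations_ = pops
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def average_linkage(dist: np.ndarray, cutoff: float) -> ClusterResult:
    """Functional wrapper over :class:`RMSDAgglomerative`."""
    est = RMSDAgglomerative(cutoff=cutoff).fit(dist)
    return ClusterResult(
        labels=est.labels_,
        cutoff=cutoff,
        representatives=est.representatives_,
        populations=est.populations_,
    )


def cluster_frames(
    traj: Trajectory, selection, align_selection=None, cutoff: float = PARATOPE_CUTOFF
) -> ClusterResult:
    """RMSD-matrix + average-linkage in one call."""
    d = rmsd_matrix(traj, selection, align_selection)
    return average_linkage(d, cutoff)


def loop_cluster_counts(
    traj: Trajectory,
    fv: AnnotatedFv | None = None,
    heavy_cutoff: float = HEAVY_LOOP_CUTOFF,
    light_cutoff: float = LIGHT_LOOP_CUTOFF,
) -> tuple[dict[str, int], dict[str, ClusterResult]]:
    """Cluster each CDR loop separately, aligning on the loop's own chain.

    Heavy-chain loops use ``heavy_cutoff`` (default 2.5 A), light-chain
    loops ``light_cutoff`` (default 1.5 A); clustering runs on the loop's
    backbone N, CA, C, O atoms.  Returns per-loop cluster counts and the
    full :class:`ClusterResult` objects.
    """
    fv = fv or traj.topology
    counts: dict[str, int] = {}
    results: dict[str, ClusterResult] = {}
    for loop, members in fv.cdr_spans.items():
        if len(members) == 0:
            logger.warning("loop %s empty; skipped", loop)
            continue
        if traj.n_frames < 2:
            logger.warning("loop %s: fewer than 2 frames; skipped", loop)
            continue
        chain = loop[0]
        selection = fv.loop_backbone_indices(loop)
        align = fv.backbone_indices(chains=(chain,))
        cutoff = heavy_cutoff if chain == "H" else light_cutoff
        res = cluster_frames(traj, selection, align, cutoff)
        counts[loop] = res.n_clusters
        results[loop] = res
    return counts, results
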