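"""Sidechain orientation on the unit sphere.

To remove the backbone's contribution to apparent sidechain motion, each
residue's backbone triad (N, C-alpha, carbonyl C) is superposed onto its
trajectory-average in every frame.  A standardized internal frame is then
built: the x-axis along the average C-alpha -> C-beta vector, with the
average C-alpha -> carbonyl-C vector in the xy-plane (positive y).  The
unit vector from C-alpha to the mass-weighted sidechain center of mass,
expressed in this frame, is summarized as spherical coordinates: polar
angle theta in [0, 180] degrees from z, azimuth phi in (-180, 180]
degrees from x (phi = 0 at the poles, where the azimuth is undefined).

Discrete orientation states are found by spherical k-means (cosine
distance) with the state count selected by silhouette score.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

from ._geometry import kabsch
from .errors import InputError, UnsupportedResidueError
from .structures import Trajectory

logger = logging.getLogger(__name__)

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}


@dataclass
class ResidueLocalFrame:
    """Standardized per-residue frame plus per-frame alignment transforms."""

    res_index: int
    origin: np.ndarray  # average aligned C-alpha position
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray
    rotations: np.ndarray  # (frames, 3, 3) backbone-alignment rotations
    translations: np.ndarray  # (frames, 3)
    valid_frames: np.ndarray  # boolean, frames with complete backbone


@dataclass
class OrientationSeries:
    """Per-frame sidechain orientation unit vectors and spherical angles."""

    res_index: int
    label: str
    vectors: np.ndarray  # (frames, 3) unit vectors in the residue frame
    theta_deg: np.ndarray  # polar angle from z, [0, 180]
    phi_deg: np.ndarray  # azimuth from x, (-180, 180], 0 at the poles

    @property
    def n_frames(self) -> int:
        return len(self.theta_deg)


def _residue_atom(fv, res_index: int, name: str):
    idx = np.nonzero((fv.res_index == res_index) & (fv.atom_name == name))[0]
    return int(idx[0]) if len(idx) else None


def residue_frame(traj: Trajectory, res_index: int, n_align_iter: int = 5) -> ResidueLocalFrame:
    """Build the standardized internal frame for one residue.

    The alignment reference is the trajectory-average backbone triad,
    refined by a few align-average iterations (the average of unaligned
    triads would be contaminated by global motion).

    Raises
    ------
    UnsupportedResidueError
        For glycine (no C-beta anywhere in the trajectory).
    """
    fv = traj.topology
    n_i = _residue_atom(fv, res_index, "N")
    ca_i = _residue_atom(fv, res_index, "CA")
    c_i = _residue_atom(fv, res_index, "C")
    cb_i = _residue_atom(fv, res_index, "CB")
    if n_i is None or ca_i is None or c_i is None:
        raise InputError(f"residue {res_index} lacks backbone atoms N/CA/C")
    if cb_i is None:
        raise UnsupportedResidueError(
            f"residue {res_index} has no C-beta (glycine unsupported)"
        )
    triads = traj.coords[:, [n_i, ca_i, c_i]]  # (F, 3, 3)
    valid = ~np.any(np.isnan(triads), axis=(1, 2))
    if not np.any(valid):
        raise InputError(f"residue {res_index}: no frame with a complete backbone")
    if not np.all(valid):
        logger.warning(
            "residue %d: %d frame(s) missing backbone atoms dropped",
            res_index, int(np.sum(~valid)),
        )
    ref = triads[np.nonzero(valid)[0][0]]
    rot = np.zeros((traj.n_frames, 3, 3))
    trans = np.zeros((traj.n_frames, 3))
    for _ in range(n_align_iter):
        r, t = kabsch(triads[valid], ref[None].repeat(int(valid.sum()), axis=0))
        aligned = np.einsum("fij,faj->fai", r, triads[valid]) + t[:, None, :]
        new_ref = aligned.mean(axis=0)
        if np.max(np.abs(new_ref - ref)) < 1e-12:
            ref = new_ref
            break
        ref = new_ref
    r, t = kabsch(triads[valid], ref[None].repeat(int(valid.sum()), axis=0))
    rot[valid] = r
    trans[valid] = t

    ca_aligned = np.einsum("fij,fj->fi", r, traj.coords[valid, ca_i]) + t
    cb_aligned = np.einsum("fij,fj->fi", r, traj.coords[valid, cb_i]) + t
    c_aligned = np.einsum("fij,fj->fi", r, traj.coords[valid, c_i]) + t
    origin = ca_aligned.mean(axis=0)
    mean_cb = (cb_aligned - ca_aligned).mean(axis=0)
    mean_c = (c_aligned - ca_aligned).mean(axis=0)
    x = mean_cb / np.linalg.norm(mean_cb)
    y = mean_c - (mean_c @ x) * x
    ny = np.linalg.norm(y)
    if ny < 1e-10:
        raise InputError(f"residue {res_index}: degenerate frame (CB parallel to C)")
    y = y / ny  # mean C-alpha->C has positive y-component by construction
    z = np.cross(x, y)
    return ResidueLocalFrame(
        res_index=res_index,
        origin=origin,
        x_axis=x,
        y_axis=y,
        z_axis=z,
        rotations=rot,
        translations=trans,
        valid_frames=valid,
    )


def sidechain_vectors(
    traj: Trajectory,
    res_index: int,
    frame: ResidueLocalFrame | None = None,
    heavy_only: bool = False,
) -> OrientationSeries:
    """C-alpha -> sidechain-center-of-mass unit vectors in the residue frame.

    The center of mass is mass-weighted over all sidechain atoms (C-beta
    and beyond; hydrogens included when present unless ``heavy_only``).
    """
    fv = traj.topology
    if frame is None:
        frame = residue_frame(traj, res_index)
    mask = (fv.res_index == res_index) & ~np.isin(fv.atom_name, list(BACKBONE_NAMES))
    if heavy_only:
        mask &= fv.element != "H"
    side = np.nonzero(mask)[0]
    if len(side) == 0:
        raise UnsupportedResidueError(f"residue {res_index} has no sidechain atoms")
    masses = np.array([ATOMIC_MASS.get(str(e).upper(), 12.011) for e in fv.element[side]])
    ca_i = _residue_atom(fv, res_index, "CA")

    valid = frame.valid_frames
    r, t = frame.rotations[valid], frame.translations[valid]
    side_xyz = np.einsum("fij,faj->fai", r, traj.coords[valid][:, side]) + t[:, None, :]
    ca_xyz = np.einsum("fij,fj->fi", r, traj.coords[valid, ca_i]) + t
    com = (side_xyz * masses[None, :, None]).sum(axis=1) / masses.sum()
    v = com - ca_xyz
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    axes = np.column_stack([frame.x_axis, frame.y_axis, frame.z_axis])
    local = v @ axes  # components along x, y, z

    n_frames = traj.n_frames
    vectors = np.full((n_frames, 3), np.nan)
    vectors[valid] = local
    theta = np.full(n_frames, np.nan)
    phi = np.full(n_frames, np.nan)
    theta[valid] = np.degrees(np.arccos(np.clip(local[:, 2], -1.0, 1.0)))
    az = np.degrees(np.arctan2(local[:, 1], local[:, 0]))
    # pole convention: azimuth = 0 where sin(theta) ~ 0
    at_pole = np.abs(np.abs(local[:, 2]) - 1.0) < 1e-12
    az[at_pole] = 0.0
    phi[valid] = az
    table = fv.residue_table().set_index("res_index")
    row = table.loc[res_index]
    label = f"{row['chain']}:{int(row['author_resid'])}"
    return OrientationSeries(
        res_index=res_index, label=label, vectors=vectors, theta_deg=theta, phi_deg=phi
    )


# ---------------------------------------------------------------------------
# orientation states
# ---------------------------------------------------------------------------

class SphericalKMeans(BaseEstimator, ClusterMixin):
    """k-means on the unit sphere with cosine distance.

    Centers are renormalized means; initialization is a k-means++ scheme
    in cosine distance driven by ``random_state``.
    """

    def __init__(self, n_clusters: int = 2, random_state: int = 0, max_iter: int = 300):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y=None):
        x = np.asarray(X, float)
        x = x / np.linalg.norm(x, axis=1, keepdims=True)
        k = int(self.n_clusters)
        if x.shape[0] < k:
            raise InputError(f"k={k} exceeds number of vectors {x.shape[0]}")
        rng = np.random.default_rng(self.random_state)
        centers = np.empty((k, x.shape[1]))
        centers[0] = x[rng.integers(len(x))]
        for j in range(1, k):
            d = np.min(1.0 - x @ centers[:j].T, axis=1)
            d = np.clip(d, 0, None)
            if d.sum() <= 0:
                centers[j] = x[rng.integers(len(x))]
            else:
                centers[j] = x[rng.choice(len(x), p=d / d.sum())]
        labels = np.zeros(len(x), dtype=int)
        for _ in range(self.max_iter):
            new_labels = np.argmax(x @ centers.T, axis=1)
            for j in range(k):
                members = x[new_labels == j]
                if len(members):
                    m = members.mean(axis=0)
                    nm = np.linalg.norm(m)
                    if nm > 0:
                        centers[j] = m / nm
                else:  # re-seed empty cluster at the worst-fit vector
                    worst = int(np.argmin(np.max(x @ centers.T, axis=1)))
                    centers[j] = x[worst]
            if np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
        self.cluster_centers_ = centers
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


@dataclass
class OrientationStates:
    """Discrete sidechain orientation states ranked by population."""

    labels: np.ndarray  # per-frame state (rank order: 0 = most populated)
    populations: np.ndarray
    mean_directions: np.ndarray  # (k, 3) unit vectors
    circular_spread_deg: np.ndarray  # mean angular deviation from the mean direction
    silhouette: float  # of the selected k (NaN for k = 1)

    @property
    def n_states(self) -> int:
        return len(self.populations)


def _null_silhouette(k: int, n: int, seed: int, n_draws: int = 5) -> float:
    """Best cosine silhouette achievable by spherical k-means on isotropic
    random unit vectors (the no-structure null): partitioning a sphere into
    cones always scores well above zero, so the null sets the bar."""
    rng = np.random.default_rng(seed)
    n = min(n, 2000)
    best = -np.inf
    for _ in range(n_draws):
        x = rng.standard_normal((n, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        km = SphericalKMeans(n_clusters=k, random_state=int(rng.integers(2**31))).fit(x)
        if len(np.unique(km.labels_)) < 2:
            continue
        best = max(best, silhouette_score(x, km.labels_, metric="cosine"))
    return best + 0.02  # small margin above the best null draw


def orientation_states(
    series: OrientationSeries,
    max_states: int = 4,
    seed: int = 0,
    min_silhouette: float | None = None,
) -> OrientationStates:
    """Cluster orientation vectors into discrete states.

    Spherical k-means is run for k = 2..max_states and the best cosine
    silhouette wins -- but only if it beats the silhouette that isotropic
    random vectors of the same size achieve (null-model calibration;
    override with a fixed ``min_silhouette``).  Otherwise a single state
    is reported.  States are ranked by population.
    """
    v = series.vectors
    v = v[~np.any(np.isnan(v), axis=1)]
    if len(v) < 10:
        raise InputError("need at least 10 frames for orientation-state analysis")
    spread_all = float(np.degrees(np.arccos(np.clip(v @ _mean_dir(v), -1, 1))).mean())
    best = (1, None, -np.inf)
    if np.allclose(v, v[0], atol=1e-12):
        best = (1, None, np.nan)
    else:
        for k in range(2, max_states + 1):
            if len(np.unique(np.round(v, 12), axis=0)) < k:
                break
            km = SphericalKMeans(n_clusters=k, random_state=seed).fit(v)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(v, km.labels_, metric="cosine")
            if score > best[2]:
                best = (k, km, score)
        threshold = (
            min_silhouette
            if min_silhouette is not None
            else _null_silhouette(best[0], len(v), seed=seed)
        )
        if best[2] < threshold:
            best = (1, None, best[2] if np.isfinite(best[2]) else np.nan)
    k, km, score = best
    if k == 1:
        mean = _mean_dir(v)
        return OrientationStates(
            labels=np.zeros(len(v), dtype=int),
            populations=np.array([1.0]),
            mean_directions=mean[None],
            circular_spread_deg=np.array([spread_all]),
            silhouette=float(score) if score is not None else np.nan,
        )
    raw = km.labels_
    pops = np.bincount(raw, minlength=k) / len(raw)
    order = np.argsort(pops)[::-1]
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(k)
    labels = rank[raw]
    means = np.empty((k, 3))
    spreads = np.empty(k)
    for new, old in enumerate(order):
        members = v[raw == old]
        means[new] = _mean_dir(members)
        spreads[new] = float(
            np.degrees(np.arccos(np.clip(members @ means[new], -1, 1))).mean()
        )
    return OrientationStates(
        labels=labels,
        populations=pops[order],
        mean_directions=means,
        circular_spread_deg=spreads,
        silhouette=float(score),
    )


def _mean_dir(v: np.ndarray) -> np.ndarray:
    m = v.mean(axis=0)
    n = np.linalg.norm(m)
    return m / n if n > 0 else np.array([0.0, 0.0, 1.0])
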