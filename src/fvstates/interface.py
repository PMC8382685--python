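"""Relative V_H-V_L orientation: six plane-based interface measures.

Each variable domain carries a reference ("consensus") set of structurally
conserved C-alpha positions together with a plane spanned by the first two
principal components of the reference coordinate cloud.  Fitting the
consensus onto a structure's core positions (Kabsch) transports the plane
into the structure; between the two plane anchor points runs the distance
vector C.  The six measures are the torsion angle HL of the two planes
about C, four tilt angles (HC1, HC2, LC1, LC2) between the plane vectors
and C, and the length dc of C.  All angles are reported in degrees,
distances in Angstrom.

The published antibody reference bundle is external data; any conforming
bundle (TSV of core positions + coordinates per domain) can be loaded,
including the toy two-domain reference emitted by the synthetic generator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._geometry import angle_between, kabsch, signed_angle
from .errors import GeometryError, InputError
from .structures import AnnotatedFv, Trajectory

logger = logging.getLogger(__name__)

MEASURE_NAMES = ("HL", "HC1", "HC2", "LC1", "LC2", "dc")


@dataclass
class DomainReference:
    """Consensus core for one variable domain."""

    positions: np.ndarray  # IMGT positions of the core C-alpha set
    coords: np.ndarray  # (k, 3) consensus coordinates, own frame
    pc1: np.ndarray = None
    pc2: np.ndarray = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, int)
        self.coords = np.asarray(self.coords, float)
        if self.pc1 is None or self.pc2 is None:
            centered = self.coords - self.coords.mean(axis=0)
            _, _, vt = np.linalg.svd(centered)
            pc1, pc2 = vt[0], vt[1]
            # deterministic sign: point from first toward last core position
            span = self.coords[-1] - self.coords[0]
            if pc1 @ span < 0:
                pc1 = -pc1
            if pc2 @ np.cross(pc1, span) < 0:
                pc2 = -pc2
            self.pc1, self.pc2 = pc1, pc2
        self.pc1 = np.asarray(self.pc1, float)
        self.pc2 = np.asarray(self.pc2, float)
        if abs(self.pc1 @ self.pc2) > 1e-8:
            raise InputError("plane basis vectors must be orthonormal")

    @property
    def anchor(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class DomainFrameDefinition:
    """Reference bundle: one :class:`DomainReference` per domain (H, L)."""

    heavy: DomainReference
    light: DomainReference

    @classmethod
    def from_directory(cls, path) -> "DomainFrameDefinition":
        """Load a bundle directory with H_core.tsv and L_core.tsv
        (columns: imgt_position, x, y, z)."""
        path = Path(path)
        refs = {}
        for name in ("H", "L"):
            df = pd.read_csv(path / f"{name}_core.tsv", sep="\t")
            refs[name] = DomainReference(
                positions=df["imgt_position"].to_numpy(int),
                coords=df[["x", "y", "z"]].to_numpy(float),
            )
        return cls(heavy=refs["H"], light=refs["L"])

    def to_directory(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, ref in (("H", self.heavy), ("L", self.light)):
            pd.DataFrame(
                {
                    "imgt_position": ref.positions,
                    "x": ref.coords[:, 0],
                    "y": ref.coords[:, 1],
                    "z": ref.coords[:, 2],
                }
            ).to_csv(path / f"{name}_core.tsv", sep="\t", index=False)


@dataclass
class DomainFrames:
    """Fitted plane frames of both domains in the structure's coordinates."""

    h_anchor: np.ndarray
    h_pc1: np.ndarray
    h_pc2: np.ndarray
    l_anchor: np.ndarray
    l_pc1: np.ndarray
    l_pc2: np.ndarray
    h_rmsd: float
    l_rmsd: float

    @property
    def c_vector(self) -> np.ndarray:
        """Distance vector C, from the H anchor to the L anchor."""
        return self.l_anchor - self.h_anchor


def _core_coords(fv: AnnotatedFv, coords: np.ndarray, chain: str, positions: np.ndarray):
    """C-alpha coordinates at the requested IMGT positions; mask of found."""
    sub = fv.numbering[fv.numbering["chain"] == chain].set_index("imgt_position")[
        "author_resid"
    ]
    found, out = [], []
    for p in positions:
        if p in sub.index:
            try:
                idx = fv.atom_index(chain, int(sub.loc[p]), "CA")
            except KeyError:
                found.append(False)
                continue
            out.append(coords[idx])
            found.append(True)
        else:
            found.append(False)
    return np.asarray(out, float), np.asarray(found, bool)


def fit_domain_frames(
    fv: AnnotatedFv,
    definition: DomainFrameDefinition,
    coords: np.ndarray | None = None,
    min_coverage: float = 0.8,
) -> DomainFrames:
    """Superpose each consensus onto the structure core; transport planes.

    Raises :class:`GeometryError` when fewer than ``min_coverage`` of a
    domain's core positions can be matched.
    """
    coords = fv.coords if coords is None else np.asarray(coords, float)
    fitted = {}
    for chain, ref in (("H", definition.heavy), ("L", definition.light)):
        target, found = _core_coords(fv, coords, chain, ref.positions)
        coverage = found.mean() if len(found) else 0.0
        if coverage < min_coverage:
            missing = ref.positions[~found]
            raise GeometryError(
                f"domain {chain}: core coverage {coverage:.0%} < {min_coverage:.0%}; "
                f"missing IMGT positions {missing.tolist()}"
            )
        source = ref.coords[found]
        r, t = kabsch(source, target)
        moved = source @ r.T + t
        rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=-1))))
        fitted[chain] = dict(
            anchor=ref.anchor @ r.T + t, pc1=ref.pc1 @ r.T, pc2=ref.pc2 @ r.T, rmsd=rmsd
        )
    return DomainFrames(
        h_anchor=fitted["H"]["anchor"],
        h_pc1=fitted["H"]["pc1"],
        h_pc2=fitted["H"]["pc2"],
        l_anchor=fitted["L"]["anchor"],
        l_pc1=fitted["L"]["pc1"],
        l_pc2=fitted["L"]["pc2"],
        h_rmsd=fitted["H"]["rmsd"],
        l_rmsd=fitted["L"]["rmsd"],
    )


def measures_from_frames(frames: DomainFrames) -> dict[str, float]:
    """The six orientation measures from fitted domain frames.

    HL is the signed angle from the H plane vector 1 to the L plane vector
    1 about the distance vector C (projections onto the plane normal to
    C); tilt angles are between each plane vector and C (H side) or -C
    (L side); dc = |C|.
    """
    c = frames.c_vector
    dc = float(np.linalg.norm(c))
    if dc <= 0:
        raise GeometryError("coincident domain anchors")
    n = c / dc
    hl = signed_angle(frames.h_pc1, frames.l_pc1, n)
    return {
        "HL": float(np.degrees(hl)),
        "HC1": float(np.degrees(angle_between(frames.h_pc1, n))),
        "HC2": float(np.degrees(angle_between(frames.h_pc2, n))),
        "LC1": float(np.degrees(angle_between(frames.l_pc1, -n))),
        "LC2": float(np.degrees(angle_between(frames.l_pc2, -n))),
        "dc": dc,
    }


def interface_measures(
    traj: Trajectory,
    definition: DomainFrameDefinition,
    fv: AnnotatedFv | None = None,
) -> pd.DataFrame:
    """Per-frame six-tuple (HL, HC1, HC2, LC1, LC2, dc).

    Frames whose core fit fails are returned as NaN rows; the run
    continues.
    """
    fv = fv or traj.topology
    rows = []
    for i in range(traj.n_frames):
        try:
            frames = fit_domain_frames(fv, definition, coords=traj.coords[i])
            rows.append(measures_from_frames(frames))
        except GeometryError as exc:
            logger.warning("frame %d: interface fit failed (%s)", i, exc)
            rows.append({m: np.nan for m in MEASURE_NAMES})
    df = pd.DataFrame(rows, columns=list(MEASURE_NAMES))
    df.insert(0, "frame", np.arange(traj.n_frames))
    return df


# ---------------------------------------------------------------------------
# distributions and statistics
# ---------------------------------------------------------------------------

def angle_kde(
    values,
    bandwidth: float | None = None,
    grid: np.ndarray | None = None,
    min_bandwidth: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate of an angle series (degrees).

    Bandwidth defaults to Silverman's rule; a zero-variance sample falls
    back to ``min_bandwidth`` (delta-like density) with a warning.  Angles
    are treated as linear quantities (observed HL ranges sit far from the
    +-180 degree wrap).  Returns (grid, density); the density integrates
    to 1 over a grid that covers the sample.
    """
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size < 2:
        raise InputError("need at least 2 values for a KDE")
    if bandwidth is None:
        std = np.std(v, ddof=1)
        iqr = np.subtract(*np.percentile(v, [75, 25]))
        sigma = min(std, iqr / 1.349) if iqr > 0 else std
        bandwidth = 0.9 * sigma * v.size ** (-1.0 / 5.0)
    if bandwidth <= min_bandwidth:
        logger.warning("KDE bandwidth floored at %.3g (near-zero variance)", min_bandwidth)
        bandwidth = min_bandwidth
    if grid is None:
        lo = v.min() - 4 * bandwidth
        hi = v.max() + 4 * bandwidth
        grid = np.linspace(lo, hi, 512)
    grid = np.asarray(grid, float)
    z = (grid[:, None] - v[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (v.size * bandwidth * np.sqrt(2 * np.pi))
    return grid, density


def orientation_statistics(
    measures: pd.DataFrame, states: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-state mean, std and standard error for all six measures.

    ``states`` is a per-frame macrostate label array (None = one state).
    States with fewer than 2 frames get NaN std with a warning.
    """
    df = measures.copy()
    n = len(df)
    if states is None:
        states = np.zeros(n, dtype=int)
    states = np.asarray(states)
    if len(states) != n:
        raise InputError("state labels must align with measure frames")
    df["state"] = states
    rows = []
    for state, sub in df.groupby("state"):
        for m in MEASURE_NAMES:
            vals = sub[m].dropna().to_numpy()
            if len(vals) < 2:
                logger.warning("state %s, measure %s: <2 frames, std undefined", state, m)
            rows.append(
                {
                    "state": state,
                    "measure": m,
                    "n": len(vals),
                    "mean": np.mean(vals) if len(vals) else np.nan,
                    "std": np.std(vals, ddof=1) if len(vals) > 1 else np.nan,
                    "sem": (np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def dc_variance(measures: pd.DataFrame) -> float:
    """Variance of the interdomain distance dc over the whole ensemble."""
    vals = measures["dc"].dropna().to_numpy()
    return float(np.var(vals, ddof=1)) if len(vals) > 1 else 0.0


def dc_variance_tm_correlation(dc_variances: dict, melting_temperatures: dict):
    """Spearman rank correlation of per-ensemble dc variance vs. Tm.

    Returns (rho, p_value) over the ensembles present in both tables.
    """
    from scipy.stats import spearmanr

    keys = sorted(set(dc_variances) & set(melting_temperatures))
    if len(keys) < 3:
        raise InputError("need at least 3 ensembles for a rank correlation")
    rho, p = spearmanr(
        [dc_variances[k] for k in keys], [melting_temperatures[k] for k in keys]
    )
    return float(rho), float(p)
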