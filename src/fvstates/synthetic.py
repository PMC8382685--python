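"""Ground-truth-labelled synthetic Fv-like trajectories.

The generator replaces the MD sampling engine for all tests: two short
"domains" (independent chains H and L of 24 residues each, three
designated 4-residue "CDR loops" per chain) whose loop dihedrals switch
among K metastable macrostates under Markov jump dynamics with wrapped
Gaussian dihedral noise.  Each macrostate additionally carries

* a rigid rotation of the L domain about the interdomain axis (so the
  interface torsion HL shifts by a known angle between states),
* a rotation of a designated sidechain stub about a fixed axis through
  its C-alpha (so the orientation arc between state means is known), and
* a prescribed distance for one cross-domain atom pair (so a contact has
  occupancy 1 - pi of the broken state).

Loops are grafted branches on a rigid framework: a loop's internal-
coordinate continuation overwrites the loop residues' atoms and the next
residue's N, so phi/psi recomputed from coordinates equal the drawn
angles exactly while the framework C-alpha core never moves.  No claim of
structural realism is made; the generator validates algorithms.

All randomness flows from one integer seed through numpy SeedSequence
spawning, so every module's fixture is reproducible.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._geometry import rotation_about_axis
from .errors import InputError
from .features import TorsionLabel, TorsionSeries
from .interface import DomainFrameDefinition, DomainReference
from .structures import LOOPS, AnnotatedFv, Trajectory, build_fv, write_trajectory

# ideal backbone internal coordinates (Angstrom / degrees)
GEOMETRY = {
    "b_n_ca": 1.458,
    "b_ca_c": 1.525,
    "b_c_n": 1.329,
    "b_c_o": 1.231,
    "b_ca_cb": 1.530,
    "a_c_n_ca": 121.7,
    "a_n_ca_c": 111.2,
    "a_ca_c_n": 116.2,
    "a_ca_c_o": 120.5,
    "a_n_ca_cb": 110.5,
    "t_n_ca_cb": -122.0,  # torsion C(-1 slot: C)-N-CA-CB
}

ATOMS_PER_RES = ("N", "CA", "C", "O", "CB")

#: author residue ids of the three loops (same layout in both chains)
LOOP_RESIDUES = {1: (5, 6, 7, 8), 2: (11, 12, 13, 14), 3: (17, 18, 19, 20)}
N_RES = 24

#: author residue id -> IMGT position (both chains)
IMGT_MAP = {
    1: 1, 2: 2, 3: 3, 4: 4,
    5: 27, 6: 28, 7: 29, 8: 30,
    9: 45, 10: 46,
    11: 56, 12: 57, 13: 58, 14: 59,
    15: 70, 16: 71,
    17: 105, 18: 106, 19: 107, 20: 108,
    21: 120, 22: 121, 23: 122, 24: 123,
}

#: framework C-alpha core used for interface plane fitting (rigid by design)
CORE_AUTHOR_IDS = (1, 2, 3, 4, 9, 10, 15, 16, 21, 22, 23, 24)

PROBE_RESIDUE = ("H", 10)  # sidechain-stub probe (rigid framework backbone)
CONTACT_RESIDUES = (("H", 23), ("L", 23))  # cross-domain CB pair


def default_transition_matrix() -> tuple[np.ndarray, np.ndarray]:
    """Reversible 3-state chain with pi = (0.45, 0.30, 0.25) by detailed
    balance from symmetric flows c_12 = 0.004, c_13 = 0.002, c_23 = 0.003."""
    pi = np.array([0.45, 0.30, 0.25])
    c = np.array([[0.0, 0.004, 0.002], [0.004, 0.0, 0.003], [0.002, 0.003, 0.0]])
    t = c / pi[:, None]
    np.fill_diagonal(t, 1.0 - t.sum(axis=1))
    return t, pi


@dataclass
class SyntheticSystem:
    """Ground-truth parameters of the synthetic Fv-like system."""

    transition_matrix: np.ndarray = None
    # per-state mean loop torsions; states differ in both phi and psi so all
    # state pairs are well separated in loop RMSD (inter >> intra at the
    # default noise level)
    loop_psi_means_deg: tuple = (-30.0, 90.0, -150.0)
    loop_phi_means_deg: tuple = (-160.0, -70.0, 55.0)
    noise_sigma: float = 0.03  # radians, wrapped Gaussian on loop phi/psi
    interdomain_angles_deg: tuple = (0.0, 8.0, -5.0)  # per state, about C axis
    stub_angles_deg: tuple = (0.0, 40.0, 20.0)  # per state, probe stub rotation
    stub_jitter_deg: float = 2.0
    contact_distances: tuple = (3.0, 6.0, 3.0)  # Angstrom per state
    framework_phi_deg: float = -120.0
    framework_psi_deg: float = 135.0
    domain_separation: float = 28.0  # Angstrom between domain origins
    frame_spacing: float = 0.1  # ns
    geometry: dict = field(default_factory=lambda: dict(GEOMETRY))

    def __post_init__(self):
        if self.transition_matrix is None:
            self.transition_matrix, self._pi = default_transition_matrix()
        else:
            self.transition_matrix = np.asarray(self.transition_matrix, float)
            self._pi = None
        t = self.transition_matrix
        if np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-12:
            raise InputError("transition matrix rows must sum to 1")
        if not self.noise_sigma > 0:
            raise InputError("noise_sigma must be positive")
        k = t.shape[0]
        for name in ("loop_psi_means_deg", "loop_phi_means_deg",
                     "interdomain_angles_deg", "stub_angles_deg",
                     "contact_distances"):
            if len(getattr(self, name)) != k:
                raise InputError(f"{name} must have one entry per state ({k})")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def stationary_distribution(self) -> np.ndarray:
        if self._pi is not None:
            return self._pi
        import scipy.linalg

        vals, vecs = scipy.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.abs(np.real(vecs[:, i]))
        return pi / pi.sum()


def simulate_state_sequence(t: np.ndarray, n_frames: int, seed: int, start=None) -> np.ndarray:
    """Markov chain path of length ``n_frames``; reproducible per seed.

    The initial state is drawn from the stationary distribution unless
    ``start`` (a state index) is given.
    """
    t = np.asarray(t, float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise InputError("transition matrix must be square")
    if np.any(t < 0) or np.max(np.abs(t.sum(axis=1) - 1.0)) > 1e-8:
        raise InputError("transition matrix must be row-stochastic")
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    k = t.shape[0]
    cum = np.cumsum(t, axis=1)
    path = np.empty(n_frames, dtype=int)
    if start is None:
        import scipy.linalg

        vals, vecs = scipy.linalg.eig(t.T)
        pi = np.abs(np.real(vecs[:, int(np.argmin(np.abs(vals - 1.0)))]))
        pi = pi / pi.sum()
        path[0] = rng.choice(k, p=pi)
    else:
        path[0] = int(start)
    u = rng.random(n_frames)
    for i in range(1, n_frames):
        path[i] = np.searchsorted(cum[path[i - 1]], u[i], side="right")
    return path


# ---------------------------------------------------------------------------
# internal-coordinate backbone construction (NeRF)
# ---------------------------------------------------------------------------

def nerf_extend(a, b, c, bond: float, angle_deg: float, torsion) -> np.ndarray:
    """Place atom d from three predecessors via internal coordinates.

    ``angle_deg`` is the b-c-d angle; ``torsion`` the a-b-c-d dihedral in
    radians (scalar or (frames,) array).  Inputs broadcast over a leading
    frames dimension.
    """
    a, b, c = (np.asarray(v, float) for v in (a, b, c))
    torsion = np.asarray(torsion, float)
    theta = np.radians(angle_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc_hat)
    d_local = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(torsion),
            bond * np.sin(theta) * np.cos(torsion),
            bond * np.sin(theta) * np.sin(torsion),
        ],
        axis=-1,
    )
    return (
        c
        + bc_hat * d_local[..., :1]
        + m * d_local[..., 1:2]
        + n * d_local[..., 2:3]
    )


def build_backbone(
    phi: np.ndarray,
    psi: np.ndarray,
    geometry: dict | None = None,
    omega: float = np.pi,
) -> np.ndarray:
    """Sequential NeRF chain build from per-residue phi/psi.

    ``phi`` and ``psi`` have shape (n_res,) or (frames, n_res); phi[0] and
    psi[-1] are unused (no preceding C / following N).  Returns
    coordinates of shape (frames, n_res * 5, 3) with atoms N, CA, C, O,
    CB per residue (CB at ideal tetrahedral geometry), or (n_res * 5, 3)
    for unbatched input.
    """
    g = geometry or GEOMETRY
    batched = np.ndim(phi) == 2
    phi = np.atleast_2d(np.asarray(phi, float))
    psi = np.atleast_2d(np.asarray(psi, float))
    if phi.shape != psi.shape:
        raise InputError("phi and psi must have the same shape")
    f, nres = phi.shape
    coords = np.zeros((f, nres * 5, 3))

    def idx(i, name):
        return i * 5 + ATOMS_PER_RES.index(name)

    # seed residue 0 in the xy-plane
    n0 = np.zeros((f, 3))
    ca0 = np.tile([g["b_n_ca"], 0.0, 0.0], (f, 1))
    ang = np.radians(180.0 - g["a_n_ca_c"])
    c0 = ca0 + g["b_ca_c"] * np.stack(
        [np.cos(ang) * np.ones(f), np.sin(ang) * np.ones(f), np.zeros(f)], axis=-1
    )
    coords[:, idx(0, "N")] = n0
    coords[:, idx(0, "CA")] = ca0
    coords[:, idx(0, "C")] = c0
    for i in range(nres):
        n_i = coords[:, idx(i, "N")]
        ca_i = coords[:, idx(i, "CA")]
        c_i = coords[:, idx(i, "C")]
        if i + 1 < nres:
            n_next = nerf_extend(n_i, ca_i, c_i, g["b_c_n"], g["a_ca_c_n"], psi[:, i])
            coords[:, idx(i + 1, "N")] = n_next
            ca_next = nerf_extend(ca_i, c_i, n_next, g["b_n_ca"], g["a_c_n_ca"], omega)
            coords[:, idx(i + 1, "CA")] = ca_next
            c_next = nerf_extend(c_i, n_next, ca_next, g["b_ca_c"], g["a_n_ca_c"], phi[:, i + 1])
            coords[:, idx(i + 1, "C")] = c_next
            o_tor = psi[:, i] + np.pi
        else:
            o_tor = np.full(f, np.pi)
        coords[:, idx(i, "O")] = nerf_extend(n_i, ca_i, c_i, g["b_c_o"], g["a_ca_c_o"], o_tor)
        coords[:, idx(i, "CB")] = nerf_extend(
            c_i, n_i, ca_i, g["b_ca_cb"], g["a_n_ca_cb"], np.radians(g["t_n_ca_cb"])
        )
    return coords if batched else coords[0]


# ---------------------------------------------------------------------------
# torsion drawing
# ---------------------------------------------------------------------------

def _wrap(x):
    out = np.mod(x + np.pi, 2 * np.pi) - np.pi
    return np.where(np.isclose(out, -np.pi), np.pi, out)


def _loop_author_ids() -> list[int]:
    return [r for k in (1, 2, 3) for r in LOOP_RESIDUES[k]]


def _draw_loop_torsions(system: SyntheticSystem, states: np.ndarray, rng) -> dict:
    """Per-chain (frames, n_res) phi/psi arrays: framework constants plus
    state-dependent noisy loop torsions."""
    f = len(states)
    psi_means = np.radians(np.asarray(system.loop_psi_means_deg, float))
    phi_means = np.radians(np.asarray(system.loop_phi_means_deg, float))
    out = {}
    loop_ids = _loop_author_ids()
    offsets = np.linspace(-0.3, 0.3, len(loop_ids))  # per-residue spread, state-independent
    for chain in ("H", "L"):
        phi = np.full((f, N_RES), np.radians(system.framework_phi_deg))
        psi = np.full((f, N_RES), np.radians(system.framework_psi_deg))
        for j, rid in enumerate(loop_ids):
            col = rid - 1
            phi[:, col] = _wrap(
                phi_means[states] + offsets[j] + rng.normal(0.0, system.noise_sigma, size=f)
            )
            psi[:, col] = _wrap(
                psi_means[states] + offsets[j] + rng.normal(0.0, system.noise_sigma, size=f)
            )
        out[chain] = (phi, psi)
    return out


# ---------------------------------------------------------------------------
# topology and assembly
# ---------------------------------------------------------------------------

def _numbering_frame() -> pd.DataFrame:
    rows = [
        {"chain": c, "author_resid": r, "imgt_position": p}
        for c in ("H", "L")
        for r, p in IMGT_MAP.items()
    ]
    return pd.DataFrame(rows)


def _chain_atom_arrays(chain: str):
    names, elements, resnames, resids = [], [], [], []
    probe_chain, probe_id = PROBE_RESIDUE
    for rid in range(1, N_RES + 1):
        atom_names = list(ATOMS_PER_RES)
        resname = "ALA"
        if chain == probe_chain and rid == probe_id:
            atom_names.append("CG")
            resname = "LEU"
        for nm in atom_names:
            names.append(nm)
            elements.append(nm[0])
            resnames.append(resname)
            resids.append(rid)
    return names, elements, resnames, resids


def _graft_loops(template: np.ndarray, torsions: tuple, atom_offsets, g: dict) -> np.ndarray:
    """Overwrite loop residues (and the next residue's N) with per-frame
    NeRF continuations seeded on the rigid framework."""
    phi, psi = torsions
    f = phi.shape[0]
    coords = np.repeat(template[None], f, axis=0)

    def a(rid, name):
        return atom_offsets[(rid, name)]

    for k, resids in LOOP_RESIDUES.items():
        first, last = resids[0], resids[-1]
        prev = first - 1
        n_prev = coords[:, a(prev, "N")]
        ca_prev = coords[:, a(prev, "CA")]
        c_prev = coords[:, a(prev, "C")]
        for rid in resids:
            col = rid - 1
            n_i = nerf_extend(n_prev, ca_prev, c_prev, g["b_c_n"], g["a_ca_c_n"], psi[:, col - 1])
            ca_i = nerf_extend(ca_prev, c_prev, n_i, g["b_n_ca"], g["a_c_n_ca"], np.pi)
            c_i = nerf_extend(c_prev, n_i, ca_i, g["b_ca_c"], g["a_n_ca_c"], phi[:, col])
            coords[:, a(rid, "N")] = n_i
            coords[:, a(rid, "CA")] = ca_i
            coords[:, a(rid, "C")] = c_i
            coords[:, a(rid, "CB")] = nerf_extend(
                c_i, n_i, ca_i, g["b_ca_cb"], g["a_n_ca_cb"], np.radians(g["t_n_ca_cb"])
            )
            n_prev, ca_prev, c_prev = n_i, ca_i, c_i
        # next residue's N, so psi(last) is exactly the drawn angle
        n_after = nerf_extend(n_prev, ca_prev, c_prev, g["b_c_n"], g["a_ca_c_n"], psi[:, last - 1])
        coords[:, a(last + 1, "N")] = n_after
        # carbonyl O of the loop residues (torsion psi + pi)
        for rid in resids:
            col = rid - 1
            coords[:, a(rid, "O")] = nerf_extend(
                coords[:, a(rid, "N")],
                coords[:, a(rid, "CA")],
                coords[:, a(rid, "C")],
                g["b_c_o"], g["a_ca_c_o"], psi[:, col] + np.pi,
            )
    return coords


@dataclass
class SyntheticResult:
    """Trajectory plus every piece of ground truth needed by the tests."""

    trajectory: Trajectory
    fv: AnnotatedFv
    state_labels: np.ndarray
    torsions: TorsionSeries
    system: SyntheticSystem
    reference: DomainFrameDefinition
    truth: dict


def _torsion_labels(fv: AnnotatedFv) -> list[TorsionLabel]:
    labels = []
    for loop in LOOPS:
        for ri in fv.cdr_spans[loop]:
            chain = loop[0]
            rid = int(fv.res_id[np.nonzero(fv.res_index == ri)[0][0]])
            labels.append(
                TorsionLabel(
                    chain=chain,
                    loop=loop,
                    imgt_position=IMGT_MAP[rid],
                    author_resid=rid,
                    res_index=int(ri),
                )
            )
    return labels


def generate_torsion_series(
    system: SyntheticSystem, n_frames: int, seed: int
) -> tuple[TorsionSeries, np.ndarray]:
    """Draw the loop torsion series directly (no coordinate build).

    Identical to the torsions of :func:`generate_trajectory` for the same
    seed; by the grafting construction, recomputing torsions from the
    built coordinates reproduces these values exactly.
    """
    ss = np.random.SeedSequence(seed)
    s_path, s_noise, _ = ss.spawn(3)
    states = simulate_state_sequence(
        system.transition_matrix, n_frames, seed=s_path
    )
    rng = np.random.default_rng(s_noise)
    torsions = _draw_loop_torsions(system, states, rng)
    fv = _build_topology(system)
    labels = _torsion_labels(fv)
    phi = np.empty((n_frames, len(labels)))
    psi = np.empty((n_frames, len(labels)))
    for j, lab in enumerate(labels):
        col = lab.author_resid - 1
        phi[:, j] = torsions[lab.chain][0][:, col]
        psi[:, j] = torsions[lab.chain][1][:, col]
    return TorsionSeries(phi=phi, psi=psi, labels=labels), states


def _build_topology(system: SyntheticSystem, coords: np.ndarray | None = None) -> AnnotatedFv:
    names, elements, resnames, resids, chains = [], [], [], [], []
    for chain in ("H", "L"):
        n, e, rn, ri = _chain_atom_arrays(chain)
        names += n
        elements += e
        resnames += rn
        resids += ri
        chains += [chain] * len(n)
    if coords is None:
        coords = np.zeros((len(names), 3))
    return build_fv(
        atom_name=names,
        element=elements,
        chain=chains,
        res_name=resnames,
        res_id=resids,
        coords=coords,
        numbering=_numbering_frame(),
    )


def _template_chain(system: SyntheticSystem, chain: str):
    """Rigid framework chain (all torsions at framework constants) plus the
    probe stub geometry; returns (coords, atom offset lookup)."""
    g = system.geometry
    phi = np.full(N_RES, np.radians(system.framework_phi_deg))
    psi = np.full(N_RES, np.radians(system.framework_psi_deg))
    base = build_backbone(phi[None], psi[None], geometry=g)[0]
    names, _, _, resids = _chain_atom_arrays(chain)
    coords = np.zeros((len(names), 3))
    offsets = {}
    cursor = 0
    for rid in range(1, N_RES + 1):
        block = 5 + (1 if (chain, rid) == PROBE_RESIDUE else 0)
        for j in range(5):
            offsets[(rid, ATOMS_PER_RES[j])] = cursor + j
            coords[cursor + j] = base[(rid - 1) * 5 + j]
        if block == 6:
            offsets[(rid, "CG")] = cursor + 5
            coords[cursor + 5] = base[(rid - 1) * 5 + 4]  # placeholder, set per frame
        cursor += block
    return coords, offsets


def generate_trajectory(system: SyntheticSystem, n_frames: int, seed: int) -> SyntheticResult:
    """Full synthetic trajectory with coordinates and ground-truth labels."""
    if n_frames < 1:
        raise InputError("n_frames must be >= 1")
    g = system.geometry
    ss = np.random.SeedSequence(seed)
    s_path, s_noise, s_stub = ss.spawn(3)
    states = simulate_state_sequence(system.transition_matrix, n_frames, seed=s_path)
    rng = np.random.default_rng(s_noise)
    torsions = _draw_loop_torsions(system, states, rng)

    templates, offsets = {}, {}
    for chain in ("H", "L"):
        templates[chain], offsets[chain] = _template_chain(system, chain)

    # per-frame chains with grafted loops
    coords_h = _graft_loops_full(templates["H"], torsions["H"], offsets["H"], g)
    coords_l = _graft_loops_full(templates["L"], torsions["L"], offsets["L"], g)

    # place the L domain: rotate 180 deg about z, translate along +x
    r0 = rotation_about_axis([0.0, 0.0, 1.0], np.pi)
    t0 = np.array([system.domain_separation, 0.0, 0.0])
    coords_l = coords_l @ r0.T + t0
    template_l_placed = templates["L"] @ r0.T + t0

    # probe sidechain stub on the rigid H framework
    probe_chain, probe_rid = PROBE_RESIDUE
    off_h = offsets[probe_chain]
    ca = templates["H"][off_h[(probe_rid, "CA")]]
    n_at = templates["H"][off_h[(probe_rid, "N")]]
    cb_ideal = templates["H"][off_h[(probe_rid, "CB")]]
    axis = cb_ideal - ca
    axis = axis / np.linalg.norm(axis)
    u0 = np.cross(axis, n_at - ca)
    u0 = u0 / np.linalg.norm(u0)
    stub_rng = np.random.default_rng(s_stub)
    gamma = np.radians(np.asarray(system.stub_angles_deg, float))[states]
    gamma = gamma + np.radians(system.stub_jitter_deg) * stub_rng.standard_normal(n_frames)
    cosg, sing = np.cos(gamma), np.sin(gamma)
    w = np.cross(axis, u0)
    dirs = u0[None] * cosg[:, None] + w[None] * sing[:, None]  # rotate u0 about axis
    coords_h[:, off_h[(probe_rid, "CB")]] = ca + 1.53 * dirs
    coords_h[:, off_h[(probe_rid, "CG")]] = ca + 3.05 * dirs

    # interdomain rotation about the axis through the two core centroids
    core_h = np.array([templates["H"][off_h[(rid, "CA")]] for rid in CORE_AUTHOR_IDS])
    off_l = offsets["L"]
    core_l = np.array([template_l_placed[off_l[(rid, "CA")]] for rid in CORE_AUTHOR_IDS])
    c_h = core_h.mean(axis=0)
    c_l = core_l.mean(axis=0)
    axis_id = (c_l - c_h) / np.linalg.norm(c_l - c_h)
    angles = np.radians(np.asarray(system.interdomain_angles_deg, float))[states]
    # rotate every L frame about the fixed interdomain axis by its state angle
    for alpha in np.unique(angles):
        sel = angles == alpha
        r = rotation_about_axis(axis_id, float(alpha))
        coords_l[sel] = (coords_l[sel] - c_h) @ r.T + c_h

    # engineered cross-domain contact: L CB placed at a state-set distance
    (ch1, rid1), (ch2, rid2) = CONTACT_RESIDUES
    i1 = offsets[ch1][(rid1, "CB")]
    i2 = off_l[(rid2, "CB")]
    d_state = np.asarray(system.contact_distances, float)[states]
    coords_l[:, i2] = coords_h[:, i1] + d_state[:, None] * np.array([0.0, 0.0, 1.0])

    coords = np.concatenate([coords_h, coords_l], axis=1)
    fv = _build_topology(system, coords=coords[0])
    traj = Trajectory(topology=fv, coords=coords, frame_spacing=system.frame_spacing)

    # toy interface reference bundle: rigid core C-alphas of the reference pose
    core_positions = np.array([IMGT_MAP[r] for r in CORE_AUTHOR_IDS])
    reference = DomainFrameDefinition(
        heavy=DomainReference(positions=core_positions, coords=core_h),
        light=DomainReference(positions=core_positions, coords=core_l),
    )

    labels = _torsion_labels(fv)
    phi = np.empty((n_frames, len(labels)))
    psi = np.empty((n_frames, len(labels)))
    for j, lab in enumerate(labels):
        col = lab.author_resid - 1
        phi[:, j] = torsions[lab.chain][0][:, col]
        psi[:, j] = torsions[lab.chain][1][:, col]
    series = TorsionSeries(phi=phi, psi=psi, labels=labels)

    pi = system.stationary_distribution
    broken = [i for i, d in enumerate(system.contact_distances) if d > 4.5]
    truth = {
        "n_states": system.n_states,
        "transition_matrix": system.transition_matrix.tolist(),
        "stationary_distribution": pi.tolist(),
        "interdomain_angles_deg": list(system.interdomain_angles_deg),
        "stub_angles_deg": list(system.stub_angles_deg),
        "contact_distances": list(system.contact_distances),
        "expected_contact_occupancy": float(sum(pi[i] for i in range(system.n_states) if i not in broken)),
        "loop_psi_means_deg": list(system.loop_psi_means_deg),
        "loop_phi_means_deg": list(system.loop_phi_means_deg),
        "frame_spacing_ns": system.frame_spacing,
    }
    return SyntheticResult(
        trajectory=traj,
        fv=fv,
        state_labels=states,
        torsions=series,
        system=system,
        reference=reference,
        truth=truth,
    )


def _graft_loops_full(template, torsions, atom_offsets, g):
    return _graft_loops(template, torsions, atom_offsets, g)


def write_bundle(result: SyntheticResult, outdir) -> None:
    """Write trajectory PDB, numbering TSV, labels TSV, truth JSON and the
    interface reference bundle to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_trajectory(outdir / "trajectory.pdb", result.trajectory)
    _numbering_frame().to_csv(outdir / "numbering.tsv", sep="\t", index=False)
    pd.DataFrame({"frame": np.arange(len(result.state_labels)), "state": result.state_labels}).to_csv(
        outdir / "labels.tsv", sep="\t", index=False
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(result.truth, fh, indent=2)
    result.reference.to_directory(outdir / "reference")
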