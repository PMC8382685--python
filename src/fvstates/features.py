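"""Backbone torsions of the CDR loops and sin/cos feature matrices.

The psi torsions of the six CDR loops are the collective variables of the
enhanced-sampling protocol this package analyzes; sin/cos of the loop
backbone torsions are the featurization handed to tICA and the Markov
model.  Working on (sin, cos) pairs instead of raw angles removes the
periodicity seam at +-180 degrees.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import dihedral
from .errors import FeatureError
from .structures import LOOPS, AnnotatedFv, Trajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TorsionLabel:
    chain: str
    loop: str
    imgt_position: int
    author_resid: int
    res_index: int


@dataclass
class TorsionSeries:
    """Per-frame phi/psi angles (radians, (-pi, pi]) for a residue list.

    Missing torsions (chain termini, residues lacking a defining atom) are
    NaN, never silently zero.
    """

    phi: np.ndarray  # (frames, residues)
    psi: np.ndarray  # (frames, residues)
    labels: list[TorsionLabel]

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]


@dataclass(frozen=True)
class FeatureLabel:
    chain: str
    loop: str
    imgt_position: int
    torsion: str  # "phi" | "psi"
    trig: str  # "sin" | "cos"

    def __str__(self) -> str:  # column name used in TSV export
        return f"{self.trig}_{self.torsion}_{self.chain}{self.imgt_position}_{self.loop}"


@dataclass
class FeatureMatrix:
    """frames x features table of torsion-derived features in [-1, 1]."""

    values: np.ndarray
    labels: list[FeatureLabel]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=[str(l) for l in self.labels])


def _neighbor_map(fv: AnnotatedFv):
    """Previous/next residue index within each chain, by residue order."""
    table = fv.residue_table()
    prev_of: dict[int, int] = {}
    next_of: dict[int, int] = {}
    for _, sub in table.groupby("chain", sort=False):
        order = sub["res_index"].to_numpy()
        ids = sub["author_resid"].to_numpy()
        for a, b, ia, ib in zip(order[:-1], order[1:], ids[:-1], ids[1:]):
            if ib == ia + 1:  # only covalently plausible neighbors
                next_of[int(a)] = int(b)
                prev_of[int(b)] = int(a)
    return prev_of, next_of


def _atom_lookup(fv: AnnotatedFv):
    lut: dict[tuple[int, str], int] = {}
    for i in range(fv.n_atoms):
        lut[(int(fv.res_index[i]), str(fv.atom_name[i]))] = i
    return lut


def backbone_dihedrals(traj: Trajectory, residues=None) -> TorsionSeries:
    """Compute phi/psi for the given residue indices over all frames.

    phi(i) = dihedral C(i-1), N(i), CA(i), C(i);
    psi(i) = dihedral N(i), CA(i), C(i), N(i+1).
    Defaults to all CDR-loop residues of the topology.  A torsion whose
    defining atom is absent is NaN for all frames.
    """
    fv = traj.topology
    if residues is None:
        residues = np.concatenate([fv.cdr_spans[l] for l in LOOPS if len(fv.cdr_spans.get(l, []))])
    residues = [int(r) for r in residues]
    if len(residues) == 0:
        raise FeatureError("no residues to compute torsions for")
    prev_of, next_of = _neighbor_map(fv)
    lut = _atom_lookup(fv)
    table = fv.residue_table().set_index("res_index")
    loop_of = {}
    for name, members in fv.cdr_spans.items():
        for ri in members:
            loop_of[int(ri)] = name

    n_frames = traj.n_frames
    phi = np.full((n_frames, len(residues)), np.nan)
    psi = np.full((n_frames, len(residues)), np.nan)
    labels = []
    x = traj.coords
    for j, ri in enumerate(residues):
        row = table.loc[ri]
        labels.append(
            TorsionLabel(
                chain=str(row["chain"]),
                loop=loop_of.get(ri, ""),
                imgt_position=int(row["imgt_position"]) if pd.notna(row["imgt_position"]) else -1,
                author_resid=int(row["author_resid"]),
                res_index=ri,
            )
        )
        n = lut.get((ri, "N"))
        ca = lut.get((ri, "CA"))
        c = lut.get((ri, "C"))
        if n is None or ca is None or c is None:
            logger.warning("residue %s lacks backbone atoms; torsions missing", ri)
            continue
        pr = prev_of.get(ri)
        if pr is not None and (pr, "C") in lut:
            phi[:, j] = dihedral(x[:, lut[(pr, "C")]], x[:, n], x[:, ca], x[:, c])
        nx = next_of.get(ri)
        if nx is not None and (nx, "N") in lut:
            psi[:, j] = dihedral(x[:, n], x[:, ca], x[:, c], x[:, lut[(nx, "N")]])
    if np.all(np.isnan(phi)) and np.all(np.isnan(psi)):
        raise FeatureError("all torsions missing for the requested residues")
    return TorsionSeries(phi=phi, psi=psi, labels=labels)


def torsion_features(torsions: TorsionSeries, include_phi: bool = True) -> FeatureMatrix:
    """Build the (sin, cos) feature matrix from a torsion series.

    Column order is deterministic: residues in input order (chain then
    position), phi before psi, sin before cos.  Torsions containing any
    missing value are dropped with a warning rather than imputed.
    """
    cols: list[np.ndarray] = []
    labels: list[FeatureLabel] = []
    kinds = ("phi", "psi") if include_phi else ("psi",)
    for j, lab in enumerate(torsions.labels):
        for kind in kinds:
            series = (torsions.phi if kind == "phi" else torsions.psi)[:, j]
            if np.any(np.isnan(series)):
                logger.warning(
                    "dropping %s of %s%s (missing values)", kind, lab.chain, lab.imgt_position
                )
                continue
            for trig, fn in (("sin", np.sin), ("cos", np.cos)):
                cols.append(fn(series))
                labels.append(
                    FeatureLabel(
                        chain=lab.chain,
                        loop=lab.loop,
                        imgt_position=lab.imgt_position,
                        torsion=kind,
                        trig=trig,
                    )
                )
    if not cols:
        raise FeatureError("no valid torsions to featurize")
    return FeatureMatrix(values=np.column_stack(cols), labels=labels)


def metadynamics_cv(
    torsions: TorsionSeries, loop: str, coefficients=None
) -> np.ndarray:
    """Per-frame collective variable: sum_i a_i sin(psi_i) + b_i cos(psi_i).

    Defaults to unit weights over the valid psi torsions of ``loop``.
    ``coefficients`` may be an (n, 2) array of (a_i, b_i) per loop residue.
    Diagnostic only; no bias potential is ever applied here.
    """
    idx = [j for j, lab in enumerate(torsions.labels) if lab.loop == loop]
    if not idx:
        raise FeatureError(f"unknown or empty loop {loop!r}")
    psi = torsions.psi[:, idx]
    valid = ~np.any(np.isnan(psi), axis=0)
    if not np.any(valid):
        raise FeatureError(f"loop {loop!r} has no valid psi torsions")
    psi = psi[:, valid]
    n = psi.shape[1]
    if coefficients is None:
        a = np.ones(n)
        b = np.ones(n)
    else:
        coefficients = np.asarray(coefficients, float)
        a, b = coefficients[:n, 0], coefficients[:n, 1]
    return np.sin(psi) @ a + np.cos(psi) @ b
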