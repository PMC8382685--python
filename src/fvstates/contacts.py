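"""Interdomain hydrogen bonds and residue contacts across the V_H-V_L interface.

A small set of interdomain interactions is conserved across human
antibodies (L-Gln38 with H-Gln39, H-Leu45 with L-Phe98, L-Pro44 with
H-Trp103, L-Ala43 with H-Tyr91); their occupancy and fluctuation
statistics over a trajectory are indicators of interface stability.
Criteria: hydrogen bond = donor-heavy-atom to acceptor distance <= 3.5 A
and donor-H-acceptor angle >= 120 degrees; distance contact = any
heavy-atom pair <= 4.5 A.  Both cutoffs are configurable.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import angle_between
from .errors import InputError
from .structures import AnnotatedFv, Trajectory

logger = logging.getLogger(__name__)

HBOND_DISTANCE_CUTOFF = 3.5  # Angstrom, donor heavy atom to acceptor
HBOND_ANGLE_CUTOFF = 120.0  # degrees, donor-H-acceptor
DISTANCE_CUTOFF = 4.5  # Angstrom, any heavy-atom pair

#: Conserved interdomain core contacts, positions as printed in the source
#: literature (the numbering scheme for these positions is not named there;
#: kept verbatim rather than converted).
CONSERVED_CORE_PAIRS = (
    (("L", 38), ("H", 39)),
    (("H", 45), ("L", 98)),
    (("L", 44), ("H", 103)),
    (("L", 43), ("H", 91)),
)


@dataclass
class ContactSpec:
    """One residue-pair contact criterion.

    ``res1``/``res2`` are (chain, position) selectors; ``scheme`` selects
    whether the position is an IMGT position or an author residue id.
    """

    res1: tuple[str, int]
    res2: tuple[str, int]
    criterion: str = "distance"  # "hbond" | "distance"
    distance_cutoff: float | None = None
    angle_cutoff: float = HBOND_ANGLE_CUTOFF
    scheme: str = "author"  # "author" | "imgt"
    name: str = ""

    def __post_init__(self):
        if self.criterion not in ("hbond", "distance"):
            raise InputError(f"unknown criterion {self.criterion!r}")
        if self.distance_cutoff is None:
            self.distance_cutoff = (
                HBOND_DISTANCE_CUTOFF if self.criterion == "hbond" else DISTANCE_CUTOFF
            )
        if not self.distance_cutoff > 0 or not self.angle_cutoff > 0:
            raise InputError("cutoffs must be positive")
        if not self.name:
            self.name = (
                f"{self.res1[0]}{self.res1[1]}-{self.res2[0]}{self.res2[1]}"
                f"({self.criterion})"
            )


def conserved_core_specs(criterion: str = "hbond", scheme: str = "author") -> list[ContactSpec]:
    """The four conserved interdomain core contacts as a spec list."""
    return [
        ContactSpec(res1=a, res2=b, criterion=criterion, scheme=scheme)
        for a, b in CONSERVED_CORE_PAIRS
    ]


@dataclass
class ContactSeries:
    """Per-frame presence of one contact plus summary statistics."""

    spec: ContactSpec
    present: np.ndarray  # (frames,) bool
    occupancy: float = field(init=False)
    transitions: int = field(init=False)
    mean_lifetime: float = field(init=False)  # frames; NaN if never formed

    def __post_init__(self):
        p = np.asarray(self.present, bool)
        self.occupancy = float(p.mean()) if len(p) else 0.0
        self.transitions = int(np.sum(p[1:] != p[:-1]))
        runs = _run_lengths(p)
        self.mean_lifetime = float(np.mean(runs)) if runs else float("nan")


def _run_lengths(present: np.ndarray) -> list[int]:
    runs, current = [], 0
    for flag in present:
        if flag:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def _resolve_residue(fv: AnnotatedFv, selector, scheme: str) -> int:
    chain, pos = selector
    if scheme == "imgt":
        return fv.residue_index_of_imgt(chain, int(pos))
    return fv.residue_index_of(chain, int(pos))


def _heavy_indices(fv: AnnotatedFv, res_index: int) -> np.ndarray:
    mask = (fv.res_index == res_index) & (fv.element != "H")
    return np.nonzero(mask)[0]


def _polar_heavy(fv: AnnotatedFv, res_index: int) -> np.ndarray:
    mask = (fv.res_index == res_index) & np.isin(fv.element, ["N", "O", "S"])
    return np.nonzero(mask)[0]


def _bonded_hydrogens(fv: AnnotatedFv, coords: np.ndarray, heavy: int) -> np.ndarray:
    mask = (fv.res_index == fv.res_index[heavy]) & (fv.element == "H")
    hs = np.nonzero(mask)[0]
    if len(hs) == 0:
        return hs
    d = np.linalg.norm(coords[hs] - coords[heavy], axis=1)
    return hs[d < 1.3]


def _structure_has_hydrogens(fv: AnnotatedFv) -> bool:
    return bool(np.any(fv.element == "H"))


def detect_contact(fv: AnnotatedFv, spec: ContactSpec, coords: np.ndarray | None = None) -> bool:
    """Evaluate one contact criterion on a single coordinate frame."""
    coords = fv.coords if coords is None else np.asarray(coords, float)
    r1 = _resolve_residue(fv, spec.res1, spec.scheme)
    r2 = _resolve_residue(fv, spec.res2, spec.scheme)
    if spec.criterion == "distance":
        a = _heavy_indices(fv, r1)
        b = _heavy_indices(fv, r2)
        if len(a) == 0 or len(b) == 0:
            raise InputError(f"{spec.name}: no heavy atoms on one side")
        d = np.linalg.norm(coords[a][:, None, :] - coords[b][None, :, :], axis=-1)
        return bool(np.min(d) <= spec.distance_cutoff)
    # hydrogen-bond criterion
    if not _structure_has_hydrogens(fv):
        # no hydrogens in the topology: degrade to a polar heavy-atom
        # distance criterion at the donor-acceptor cutoff
        logger.warning(
            "%s: no hydrogens in topology; using heavy-atom distance <= %.2f A",
            spec.name, spec.distance_cutoff,
        )
        a = _polar_heavy(fv, r1)
        b = _polar_heavy(fv, r2)
        if len(a) == 0 or len(b) == 0:
            raise InputError(f"{spec.name}: no polar heavy atoms on one side")
        d = np.linalg.norm(coords[a][:, None, :] - coords[b][None, :, :], axis=-1)
        return bool(np.min(d) <= spec.distance_cutoff)
    for donor_res, acceptor_res in ((r1, r2), (r2, r1)):
        for donor in _polar_heavy(fv, donor_res):
            hs = _bonded_hydrogens(fv, coords, donor)
            if len(hs) == 0:
                continue
            for acceptor in _polar_heavy(fv, acceptor_res):
                d = np.linalg.norm(coords[donor] - coords[acceptor])
                if d > spec.distance_cutoff:
                    continue
                for h in hs:
                    ang = np.degrees(
                        angle_between(coords[donor] - coords[h], coords[acceptor] - coords[h])
                    )
                    if ang >= spec.angle_cutoff:
                        return True
    return False


def contact_series(
    traj: Trajectory, specs: list[ContactSpec], fv: AnnotatedFv | None = None
) -> tuple[list[ContactSeries], list[tuple[ContactSpec, str]]]:
    """Evaluate contact specs over all frames.

    Returns (series list, error report); unresolvable specs are reported
    and the remaining specs are processed.
    """
    fv = fv or traj.topology
    series: list[ContactSeries] = []
    errors: list[tuple[ContactSpec, str]] = []
    for spec in specs:
        try:
            present = np.array(
                [detect_contact(fv, spec, coords=traj.coords[i]) for i in range(traj.n_frames)]
            )
        except (InputError, KeyError) as exc:
            logger.warning("contact %s unresolvable: %s", spec.name, exc)
            errors.append((spec, str(exc)))
            continue
        series.append(ContactSeries(spec=spec, present=present))
    return series, errors


def contact_table(series: list[ContactSeries]) -> pd.DataFrame:
    """Summary table (contact, occupancy, transitions, mean_lifetime)."""
    return pd.DataFrame(
        {
            "contact": [s.spec.name for s in series],
            "occupancy": [s.occupancy for s in series],
            "transitions": [s.transitions for s in series],
            "mean_lifetime": [s.mean_lifetime for s in series],
        }
    )
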