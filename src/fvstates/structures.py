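"""Fv structures, trajectories, IMGT annotation and superposition.

The data model is deliberately small: an :class:`AnnotatedFv` is a flat
atom table (numpy annotation arrays + one coordinate frame) carrying a
residue-level IMGT numbering map and the resolved CDR spans; a
:class:`Trajectory` is a stack of coordinate frames over the same atom
set.  PDB reading/writing goes through biotite; binary trajectory formats
(XTC/DCD/...) go through mdtraj with a PDB topology.

Units: Angstrom for coordinates, nanoseconds for frame spacing.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._geometry import Superposition, superpose as _superpose_points
from .errors import GeometryError, InputError, StructureError, TopologyError

logger = logging.getLogger(__name__)

#: IMGT CDR spans (inclusive IMGT position ranges), identical for both chains.
DEFAULT_CDR_SPANS: dict[int, tuple[int, int]] = {1: (27, 38), 2: (56, 65), 3: (105, 117)}

LOOPS = ("H1", "H2", "H3", "L1", "L2", "L3")
BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class AnnotatedFv:
    """One Fv structure: atoms, one coordinate frame, IMGT annotation.

    Attributes
    ----------
    atom_name, element, chain, res_name : (n_atoms,) object/str arrays
    res_id : (n_atoms,) int array
        Author residue id per atom.
    res_index : (n_atoms,) int array
        0-based consecutive residue index per atom (unique over both chains).
    coords : (n_atoms, 3) float array, Angstrom
    numbering : DataFrame with columns (chain, author_resid, imgt_position)
    cdr_spans : dict mapping loop id (H1..L3) to ordered residue-index arrays
    incomplete_residues : set of residue indices lacking N, CA or C
    """

    atom_name: np.ndarray
    element: np.ndarray
    chain: np.ndarray
    res_name: np.ndarray
    res_id: np.ndarray
    res_index: np.ndarray
    coords: np.ndarray
    numbering: pd.DataFrame
    cdr_spans: dict[str, np.ndarray] = field(default_factory=dict)
    incomplete_residues: set[int] = field(default_factory=set)

    # -- basic queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def n_residues(self) -> int:
        return int(self.res_index.max()) + 1 if self.n_atoms else 0

    def residue_table(self) -> pd.DataFrame:
        """Per-residue table: res_index, chain, author_resid, res_name, imgt."""
        _, first = np.unique(self.res_index, return_index=True)
        df = pd.DataFrame(
            {
                "res_index": self.res_index[first],
                "chain": self.chain[first],
                "author_resid": self.res_id[first],
                "res_name": self.res_name[first],
            }
        )
        key = self.numbering.set_index(["chain", "author_resid"])["imgt_position"]
        df["imgt_position"] = [
            key.get((c, r), np.nan) for c, r in zip(df["chain"], df["author_resid"])
        ]
        return df

    def atom_indices(self, chain=None, res_index=None, names=None) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain == chain
        if res_index is not None:
            mask &= np.isin(self.res_index, np.atleast_1d(res_index))
        if names is not None:
            mask &= np.isin(self.atom_name, list(names))
        return np.nonzero(mask)[0]

    def atom_index(self, chain: str, author_resid: int, name: str) -> int:
        idx = np.nonzero(
            (self.chain == chain) & (self.res_id == author_resid) & (self.atom_name == name)
        )[0]
        if len(idx) == 0:
            raise KeyError(f"atom {chain}:{author_resid}:{name} not found")
        return int(idx[0])

    def residue_index_of(self, chain: str, author_resid: int) -> int:
        idx = np.nonzero((self.chain == chain) & (self.res_id == author_resid))[0]
        if len(idx) == 0:
            raise KeyError(f"residue {chain}:{author_resid} not found")
        return int(self.res_index[idx[0]])

    def residue_index_of_imgt(self, chain: str, imgt_position: int) -> int:
        sub = self.numbering[
            (self.numbering["chain"] == chain)
            & (self.numbering["imgt_position"] == imgt_position)
        ]
        if sub.empty:
            raise KeyError(f"IMGT position {chain}:{imgt_position} not in numbering map")
        return self.residue_index_of(chain, int(sub.iloc[0]["author_resid"]))

    def backbone_indices(self, chains=("H", "L"), names=BACKBONE_ATOMS) -> np.ndarray:
        mask = np.isin(self.chain, list(chains)) & np.isin(self.atom_name, list(names))
        return np.nonzero(mask)[0]

    def loop_backbone_indices(self, loop: str, names=BACKBONE_ATOMS) -> np.ndarray:
        if loop not in self.cdr_spans:
            raise KeyError(f"unknown loop {loop!r}")
        return self.atom_indices(res_index=self.cdr_spans[loop], names=names)

    def with_coords(self, coords: np.ndarray) -> "AnnotatedFv":
        coords = np.asarray(coords, float)
        if coords.shape != self.coords.shape:
            raise InputError("coordinate shape mismatch")
        return replace(self, coords=coords)


@dataclass
class Trajectory:
    """Ordered coordinate frames over the atom set of a topology Fv.

    coords has shape (n_frames, n_atoms, 3) in Angstrom; frame_spacing is
    the time between consecutive frames in nanoseconds.
    """

    topology: AnnotatedFv
    coords: np.ndarray
    frame_spacing: float = 0.1

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InputError("trajectory coordinates must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise InputError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"atom-count mismatch: trajectory has {self.coords.shape[1]}, "
                f"topology has {self.topology.n_atoms}"
            )
        if not self.frame_spacing > 0:
            raise InputError("frame_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> AnnotatedFv:
        return self.topology.with_coords(self.coords[i])


# ---------------------------------------------------------------------------
# numbering + CDR span resolution
# ---------------------------------------------------------------------------

def read_numbering(source) -> pd.DataFrame:
    """Load a residue numbering map (chain, author_resid, imgt_position).

    ``source`` may be a TSV path, a DataFrame with those columns, or a dict
    mapping ``(chain, author_resid) -> imgt_position``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, dict):
        df = pd.DataFrame(
            [(c, r, p) for (c, r), p in source.items()],
            columns=["chain", "author_resid", "imgt_position"],
        )
    else:
        df = pd.read_csv(source, sep="\t")
    required = {"chain", "author_resid", "imgt_position"}
    if not required.issubset(df.columns):
        raise InputError(f"numbering map must have columns {sorted(required)}")
    df["author_resid"] = df["author_resid"].astype(int)
    df["imgt_position"] = df["imgt_position"].astype(int)
    return df[["chain", "author_resid", "imgt_position"]]


def resolve_cdr_spans(
    fv_chain: np.ndarray,
    fv_res_id: np.ndarray,
    fv_res_index: np.ndarray,
    numbering: pd.DataFrame,
    spans: dict[int, tuple[int, int]] | None = None,
) -> dict[str, np.ndarray]:
    """Intersect the IMGT span table with the numbering map per chain."""
    spans = spans or DEFAULT_CDR_SPANS
    out: dict[str, np.ndarray] = {}
    resid_to_index = {}
    _, first = np.unique(fv_res_index, return_index=True)
    for i in first:
        resid_to_index[(fv_chain[i], int(fv_res_id[i]))] = int(fv_res_index[i])
    for chain in ("H", "L"):
        sub = numbering[numbering["chain"] == chain]
        for k, (lo, hi) in spans.items():
            rows = sub[(sub["imgt_position"] >= lo) & (sub["imgt_position"] <= hi)]
            rows = rows.sort_values("imgt_position")
            members = [
                resid_to_index[(chain, int(r))]
                for r in rows["author_resid"]
                if (chain, int(r)) in resid_to_index
            ]
            out[f"{chain}{k}"] = np.array(members, dtype=int)
    return out


def _find_incomplete(atom_name, res_index) -> set[int]:
    incomplete = set()
    for ri in np.unique(res_index):
        names = set(atom_name[res_index == ri])
        if not {"N", "CA", "C"}.issubset(names):
            incomplete.add(int(ri))
    return incomplete


def build_fv(
    atom_name,
    element,
    chain,
    res_name,
    res_id,
    coords,
    numbering,
    cdr_span_table: dict[int, tuple[int, int]] | None = None,
) -> AnnotatedFv:
    """Assemble and validate an AnnotatedFv from flat atom arrays."""
    atom_name = np.asarray(atom_name, dtype=object)
    element = np.asarray(element, dtype=object)
    chain = np.asarray(chain, dtype=object)
    res_name = np.asarray(res_name, dtype=object)
    res_id = np.asarray(res_id, dtype=int)
    coords = np.asarray(coords, dtype=float)
    for required in ("H", "L"):
        if not np.any(chain == required):
            raise StructureError(f"chain {required!r} missing from structure")
    # consecutive residue index over (chain, res_id) in order of appearance
    res_index = np.empty(len(atom_name), dtype=int)
    seen: dict[tuple, int] = {}
    for i, key in enumerate(zip(chain, res_id)):
        if key not in seen:
            seen[key] = len(seen)
        res_index[i] = seen[key]
    numbering = read_numbering(numbering)
    incomplete = _find_incomplete(atom_name, res_index)
    spans = resolve_cdr_spans(chain, res_id, res_index, numbering, cdr_span_table)
    fv = AnnotatedFv(
        atom_name=atom_name,
        element=element,
        chain=chain,
        res_name=res_name,
        res_id=res_id,
        res_index=res_index,
        coords=coords,
        numbering=numbering,
        cdr_spans=spans,
        incomplete_residues=incomplete,
    )
    for loop, members in spans.items():
        bad = [ri for ri in members if ri in incomplete]
        if bad:
            logger.warning(
                "loop %s: residues %s lack backbone atoms; excluded from torsions",
                loop,
                bad,
            )
    return fv


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _load_pdb_atoms(path):
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    # altloc="occupancy": highest-occupancy conformer wins; biotite keeps the
    # first-listed (lexicographically lowest altloc id) on ties.
    return pdb.get_structure(pdb_file, altloc="occupancy")


def read_structure(path, numbering, cdr_span_table=None) -> AnnotatedFv:
    """Read a PDB structure (model 1 of multi-model files) as AnnotatedFv."""
    stack = _load_pdb_atoms(path)
    atoms = stack[0] if stack.stack_depth() >= 1 else None
    if atoms is None or atoms.array_length() == 0:
        raise StructureError(f"no atoms parsed from {path}")
    return build_fv(
        atom_name=atoms.atom_name,
        element=atoms.element,
        chain=atoms.chain_id,
        res_name=atoms.res_name,
        res_id=atoms.res_id,
        coords=atoms.coord,
        numbering=numbering,
        cdr_span_table=cdr_span_table,
    )


def read_trajectory(
    path,
    topology: AnnotatedFv,
    frame_spacing: float = 0.1,
    topology_path=None,
) -> Trajectory:
    """Read a trajectory: multi-model PDB, or a binary format via mdtraj.

    For non-PDB formats a PDB topology file path must be given
    (``topology_path``); coordinates are converted from nm to Angstrom.
    """
    path = Path(path)
    if path.suffix.lower() in {".pdb", ".ent"}:
        stack = _load_pdb_atoms(path)
        coords = stack.coord
        if coords.ndim == 2:
            coords = coords[None]
    else:
        import mdtraj

        if topology_path is None:
            raise InputError("binary trajectory formats require topology_path (PDB)")
        t = mdtraj.load(str(path), top=str(topology_path))
        coords = t.xyz * 10.0  # nm -> Angstrom
    if coords.shape[0] == 0:
        raise InputError(f"no frames found in {path}")
    if coords.shape[1] != topology.n_atoms:
        raise TopologyError(
            f"atom-count mismatch: {coords.shape[1]} in trajectory, "
            f"{topology.n_atoms} in topology"
        )
    return Trajectory(topology=topology, coords=np.asarray(coords, float), frame_spacing=frame_spacing)


def _as_atom_array(fv: AnnotatedFv, coords: np.ndarray):
    import biotite.structure as struc

    n = fv.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, np.float32)
    arr.chain_id = fv.chain.astype("U4")
    arr.res_id = fv.res_id
    arr.res_name = fv.res_name.astype("U5")
    arr.atom_name = fv.atom_name.astype("U6")
    arr.element = fv.element.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_structure(path, fv: AnnotatedFv) -> None:
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    pdb.set_structure(f, _as_atom_array(fv, fv.coords))
    f.write(str(path))


def write_trajectory(path, traj: Trajectory) -> None:
    """Write a trajectory as a multi-model PDB."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_frames, n_atoms = traj.coords.shape[:2]
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    template = _as_atom_array(traj.topology, traj.topology.coords)
    for name in template.get_annotation_categories():
        stack.set_annotation(name, template.get_annotation(name))
    stack.coord = np.asarray(traj.coords, np.float32)
    f = pdb.PDBFile()
    pdb.set_structure(f, stack)
    f.write(str(path))


def write_summary(path, fv: AnnotatedFv) -> None:
    """Write the per-residue annotation summary as TSV."""
    df = fv.residue_table()
    loop = np.full(len(df), "", dtype=object)
    for name, members in fv.cdr_spans.items():
        loop[np.isin(df["res_index"].to_numpy(), members)] = name
    df["loop"] = loop
    df["incomplete"] = df["res_index"].isin(sorted(fv.incomplete_residues))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# superposition over atom selections
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, reference: np.ndarray, selection=None) -> Superposition:
    """Kabsch superposition of coordinate sets over an atom selection.

    ``mobile`` and ``reference`` are (n_atoms, 3); ``selection`` is an index
    list (defaults to all atoms).  The returned transform maps the full
    mobile set; the RMSD is evaluated over the selection.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if selection is None:
        selection = np.arange(mobile.shape[0])
    selection = np.asarray(selection, int)
    if selection.size == 0:
        raise GeometryError("empty selection")
    return _superpose_points(mobile[selection], reference[selection])
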