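"""End-to-end paratope-state analysis from a single config.

Orchestrates the full workflow: torsion featurization -> loop-wise RMSD
cluster counts -> tICA -> free-energy surface -> k-means microstates ->
reversible MSM -> PCCA+ macrostates -> per-macrostate interface-measure
distributions, sidechain orientations and contact statistics.  Stages
communicate through files in the report directory so any stage's output
can be inspected or re-consumed independently; a JSON manifest records
versions, the seed and a checksum per emitted table.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import HEAVY_LOOP_CUTOFF, LIGHT_LOOP_CUTOFF, loop_cluster_counts
from .contacts import ContactSpec, contact_series, contact_table
from .errors import FvStatesError, InputError
from .features import backbone_dihedrals, torsion_features
from .interface import (
    DomainFrameDefinition,
    angle_kde,
    dc_variance,
    interface_measures,
    orientation_statistics,
)
from .kinetics import (
    DEFAULT_LAG_NS,
    DEFAULT_N_MICROSTATES,
    DEFAULT_TEMPERATURE,
    TICA,
    estimate_msm,
    free_energy_surface,
    implied_timescales,
    kmeans_microstates,
    pcca,
)
from .sidechain import orientation_states, sidechain_vectors
from .structures import read_structure, read_trajectory
from .synthetic import SyntheticSystem, generate_trajectory

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Configuration of one paratope-state analysis run."""

    seed: int
    output_dir: str
    # input: either synthetic generation or files
    synthetic: bool = True
    n_frames: int = 20000
    trajectory: str | None = None
    topology: str | None = None
    numbering: str | None = None
    reference_bundle: str | None = None
    frame_spacing: float = 0.1  # ns
    # analysis parameters
    lag_ns: float = DEFAULT_LAG_NS
    n_microstates: int = DEFAULT_N_MICROSTATES
    n_macrostates: int = 3
    include_phi: bool = True
    temperature: float = DEFAULT_TEMPERATURE
    heavy_loop_cutoff: float = HEAVY_LOOP_CUTOFF
    light_loop_cutoff: float = LIGHT_LOOP_CUTOFF
    max_loop_cluster_frames: int = 400
    sidechain_residues: list = field(default_factory=list)  # ["H:10", ...]
    contact_pairs: list = field(default_factory=list)  # [["H:23", "L:23"], ...]
    contact_criterion: str = "distance"
    its_lag_factors: tuple = (1, 2, 3, 5)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if self.seed is None:
            raise InputError("seed is mandatory")
        if not self.synthetic:
            for name in ("trajectory", "topology", "numbering"):
                value = getattr(self, name)
                if value is None or not Path(value).exists():
                    raise InputError(f"input file for {name!r} missing: {value}")


def _parse_residue(token: str) -> tuple[str, int]:
    chain, pos = token.split(":")
    return chain, int(pos)


@dataclass
class ReportBundle:
    """Outcome of a pipeline run: written files, values, failures."""

    output_dir: Path
    files: dict
    failures: dict
    macrostate_populations: np.ndarray | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def run_paratope_analysis(config: AnalysisConfig) -> ReportBundle:
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    failures: dict[str, str] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        files[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    # ---- input ---------------------------------------------------------
    reference = None
    truth = None
    dc_var = None
    if config.synthetic:
        system = SyntheticSystem(frame_spacing=config.frame_spacing)
        result = generate_trajectory(system, config.n_frames, seed=config.seed)
        traj, fv = result.trajectory, result.fv
        reference = result.reference
        truth = result.truth
    else:
        fv = read_structure(config.topology, numbering=config.numbering)
        traj = read_trajectory(
            config.trajectory, fv, frame_spacing=config.frame_spacing,
            topology_path=config.topology,
        )
        if config.reference_bundle:
            reference = DomainFrameDefinition.from_directory(config.reference_bundle)

    lag_frames = max(1, int(round(config.lag_ns / traj.frame_spacing)))
    if traj.n_frames <= lag_frames:
        raise InputError(
            f"trajectory has {traj.n_frames} frame(s); tICA/MSM need more than "
            f"the lag of {lag_frames} frames ({config.lag_ns} ns at "
            f"{traj.frame_spacing} ns/frame)"
        )

    # ---- features ------------------------------------------------------
    torsions = backbone_dihedrals(traj)
    feats = torsion_features(torsions, include_phi=config.include_phi)
    states = None
    pops = None

    # ---- loop-wise cluster counts (subsampled for tractability) --------
    try:
        stride = max(1, traj.n_frames // config.max_loop_cluster_frames)
        sub = traj
        if stride > 1:
            from .structures import Trajectory

            sub = Trajectory(
                topology=fv, coords=traj.coords[::stride], frame_spacing=traj.frame_spacing * stride
            )
        counts, _ = loop_cluster_counts(
            sub, fv, heavy_cutoff=config.heavy_loop_cutoff, light_cutoff=config.light_loop_cutoff
        )
        emit(
            "loop_clusters.tsv",
            pd.DataFrame({"loop": list(counts), "n_clusters": list(counts.values())}),
        )
    except FvStatesError as exc:
        failures["loop_clusters"] = str(exc)

    # ---- kinetics ------------------------------------------------------
    try:
        tica = TICA(lag=lag_frames, n_components=2).fit(feats)
        proj = tica.transform(feats)
        fes = free_energy_surface(proj, temperature=config.temperature)
        emit("fes.tsv", fes.to_dataframe())

        k = min(config.n_microstates, max(2, proj.shape[0] // 10))
        centers, dtraj = kmeans_microstates(proj, k=k, seed=config.seed)
        msm = estimate_msm(dtraj, lag=lag_frames)
        lags = sorted({max(1, int(round(f * lag_frames))) for f in config.its_lag_factors})
        lags = [l for l in lags if l < traj.n_frames]
        lag_arr, its = implied_timescales(dtraj, lags, k=min(5, msm.n_states_ - 1))
        its_df = pd.DataFrame(its, columns=[f"t{i+2}_frames" for i in range(its.shape[1])])
        its_df.insert(0, "lag_frames", lag_arr)
        its_df.insert(1, "lag_ns", lag_arr * traj.frame_spacing)
        emit("implied_timescales.tsv", its_df)

        p = pcca(msm, config.n_macrostates)
        pops = p.populations_
        emit(
            "macrostates.tsv",
            pd.DataFrame(
                {
                    "macrostate": np.arange(config.n_macrostates),
                    "population_crisp": p.populations_,
                    "population_fuzzy": p.fuzzy_populations_,
                }
            ),
        )
        coarse = pd.DataFrame(
            p.coarse_transition_matrix_,
            columns=[f"to_{j}" for j in range(config.n_macrostates)],
        )
        coarse.insert(0, "from", np.arange(config.n_macrostates))
        emit("coarse_transitions.tsv", coarse)

        # per-frame macrostate labels via the microstate assignment
        micro_of_frame = np.asarray(dtraj)
        state_map = -np.ones(int(micro_of_frame.max()) + 1, dtype=int)
        state_map[msm.active_set_] = p.assignments_
        states = state_map[micro_of_frame]
        emit(
            "frame_states.tsv",
            pd.DataFrame({"frame": np.arange(len(states)), "macrostate": states}),
        )
    except FvStatesError as exc:
        failures["kinetics"] = str(exc)

    # ---- interface orientation -----------------------------------------
    if reference is not None:
        try:
            measures = interface_measures(traj, reference, fv)
            emit("interface_measures.tsv", measures)
            stats = orientation_statistics(
                measures, states if states is not None else None
            )
            emit("interface_statistics.tsv", stats)
            kde_rows = []
            groups = (
                measures.groupby(states) if states is not None else [(0, measures)]
            )
            for state, sub_df in groups:
                vals = sub_df["HL"].dropna().to_numpy()
                if len(vals) < 2:
                    continue
                grid, dens = angle_kde(vals)
                kde_rows.append(
                    pd.DataFrame({"state": state, "HL_deg": grid, "density": dens})
                )
            if kde_rows:
                emit("hl_kde.tsv", pd.concat(kde_rows, ignore_index=True))
            dc_var = dc_variance(measures)
        except FvStatesError as exc:
            failures["interface"] = str(exc)
    else:
        logger.info("no interface reference bundle; interface stage skipped")

    # ---- sidechain orientations ----------------------------------------
    tokens = config.sidechain_residues or (["H:10"] if config.synthetic else [])
    side_rows = []
    for token in tokens:
        try:
            chain, rid = _parse_residue(token)
            ri = fv.residue_index_of(chain, rid)
            series = sidechain_vectors(traj, ri)
            st = orientation_states(series, seed=config.seed)
            for rank, (pop, spread) in enumerate(
                zip(st.populations, st.circular_spread_deg)
            ):
                side_rows.append(
                    {
                        "residue": token,
                        "state": rank,
                        "population": pop,
                        "spread_deg": spread,
                        "mean_theta_deg": float(
                            np.degrees(np.arccos(np.clip(st.mean_directions[rank, 2], -1, 1)))
                        ),
                    }
                )
        except FvStatesError as exc:
            failures[f"sidechain:{token}"] = str(exc)
    if side_rows:
        emit("sidechain_states.tsv", pd.DataFrame(side_rows))

    # ---- contacts ------------------------------------------------------
    pairs = config.contact_pairs or ([["H:23", "L:23"]] if config.synthetic else [])
    specs = [
        ContactSpec(
            res1=_parse_residue(a), res2=_parse_residue(b), criterion=config.contact_criterion
        )
        for a, b in pairs
    ]
    if specs:
        series_list, errors = contact_series(traj, specs, fv)
        for spec, msg in errors:
            failures[f"contact:{spec.name}"] = msg
        if series_list:
            emit("contacts.tsv", contact_table(series_list))

    # ---- manifest ------------------------------------------------------
    manifest = {
        "fvstates_version": __version__,
        "seed": config.seed,
        "n_frames": traj.n_frames,
        "lag_frames": lag_frames,
        "files": files,
        "failures": failures,
    }
    if truth is not None:
        manifest["ground_truth"] = truth
    if dc_var is not None:
        manifest["dc_variance"] = dc_var
    if pops is not None:
        manifest["macrostate_populations"] = np.asarray(pops).tolist()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failures:
        logger.error("pipeline completed with failures: %s", failures)
    return ReportBundle(
        output_dir=out, files=files, failures=failures, macrostate_populations=pops
    )
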