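"""Trajectory container, multi-model PDB I/O, trimming and concatenation.

Internally all trajectory coordinates are in nm (matching the units in
which RMSD, RMSF and covariance eigenvalues are reported); Angstrom appears
only at the PDB boundary and in SASA/Rg reports.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .structure_io import Structure, read_structure, write_structure

A_PER_NM = 10.0

__all__ = [
    "Trajectory",
    "ReplicaSet",
    "trim_equilibration",
    "concatenate",
    "write_multimodel_pdb",
    "read_multimodel_pdb",
    "write_time_sidecar",
    "read_time_sidecar",
]


@dataclass
class Trajectory:
    """Coordinate frames sharing a :class:`Structure` topology.

    Attributes
    ----------
    topology:
        Atom labels (names, residues, chains); its coordinates are the
        reference/starting conformation in Angstrom.
    coords:
        (n_frames, n_atoms, 3) array in nm.
    times_ps:
        Strictly increasing frame times in ps.
    provenance:
        Optional DataFrame (frame, replica, time_ps_original) carried
        through concatenation.
    """

    topology: Structure
    coords: np.ndarray
    times_ps: np.ndarray
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times_ps = np.asarray(self.times_ps, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != len(self.times_ps):
            raise ValueError("times and frames disagree in length")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError("frame atom count does not match topology")
        if len(self.times_ps) > 1 and not np.all(np.diff(self.times_ps) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def reference_nm(self) -> np.ndarray:
        """Starting/reference conformation from the topology, in nm."""
        return self.topology.coords / A_PER_NM


@dataclass
class ReplicaSet:
    """Independent replicas of one system plus the equilibration window (ns)."""

    replicas: list[Trajectory]
    window_ns: tuple[float, float] = (10.0, 100.0)

    def __post_init__(self) -> None:
        start, end = self.window_ns
        if not start < end:
            raise ValueError("equilibration window start must be < end")
        n0 = self.replicas[0].n_atoms
        for k, rep in enumerate(self.replicas):
            if rep.n_atoms != n0:
                raise ValueError(f"replica {k} atom count {rep.n_atoms} != {n0}")

    def equilibrated(self) -> list[Trajectory]:
        start, end = self.window_ns
        return [trim_equilibration(r, start, end) for r in self.replicas]

    def joined(self) -> Trajectory:
        """Equilibrated portions of all replicas concatenated in order."""
        return concatenate(self.equilibrated())


def trim_equilibration(traj: Trajectory, start_ns: float, end_ns: float) -> Trajectory:
    """Keep frames with start <= t <= end (window in ns, inclusive).

    Frame times are preserved.  An empty result (window outside the data)
    is an error rather than an empty trajectory.
    """
    if not start_ns < end_ns:
        raise ValueError(f"window start ({start_ns} ns) must be < end ({end_ns} ns)")
    t_ns = traj.times_ps / 1000.0
    mask = (t_ns >= start_ns) & (t_ns <= end_ns)
    if not mask.any():
        raise ValueError(
            f"window {start_ns}-{end_ns} ns selects no frames "
            f"(data span {t_ns[0]:.3f}-{t_ns[-1]:.3f} ns)"
        )
    prov = traj.provenance.loc[mask].reset_index(drop=True) if traj.provenance is not None else None
    return Trajectory(
        topology=traj.topology,
        coords=traj.coords[mask],
        times_ps=traj.times_ps[mask],
        provenance=prov,
    )


def concatenate(replicas: list[Trajectory]) -> Trajectory:
    """Join replicas into one trajectory on a continuous re-indexed time axis.

    Frames keep replica order; a provenance table records, for every output
    frame, the source replica and its original time.  The output time axis
    is continuous: each segment keeps its internal spacing and starts one
    median step after the previous segment ends, so that integral-based
    diagnostics (cosine content) see a single uninterrupted axis.
    """
    if not replicas:
        raise ValueError("no replicas to concatenate")
    n0 = replicas[0].n_atoms
    for k, rep in enumerate(replicas):
        if rep.n_atoms != n0:
            raise ValueError(
                f"replica {k} has {rep.n_atoms} atoms, expected {n0}"
            )
        if list(rep.topology.names) != list(replicas[0].topology.names):
            raise ValueError(f"replica {k} atom labels differ from replica 0")

    coords = np.concatenate([r.coords for r in replicas], axis=0)
    times, prov_frames = [], []
    offset = 0.0
    for k, rep in enumerate(replicas):
        t = rep.times_ps - rep.times_ps[0]
        dt = float(np.median(np.diff(rep.times_ps))) if rep.n_frames > 1 else 10.0
        times.append(t + offset)
        offset += (t[-1] if rep.n_frames > 1 else 0.0) + dt
        prov_frames.append(pd.DataFrame({
            "replica": k,
            "time_ps_original": rep.times_ps,
        }))
    times_ps = np.concatenate(times)
    provenance = pd.concat(prov_frames, ignore_index=True)
    provenance.insert(0, "frame", np.arange(len(times_ps)))
    return Trajectory(
        topology=replicas[0].topology,
        coords=coords,
        times_ps=times_ps,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Multi-model PDB interchange
# ---------------------------------------------------------------------------

def write_multimodel_pdb(traj: Trajectory) -> str:
    """Serialize a trajectory as MODEL/ENDMDL blocks (coordinates in Angstrom)."""
    chunks = []
    for k in range(traj.n_frames):
        frame_struct = replace(traj.topology, coords=traj.coords[k] * A_PER_NM)
        chunks.append(write_structure(frame_struct, model_number=k + 1))
    return "".join(chunks) + "END\n"


def read_multimodel_pdb(
    pdb_text: str,
    times_ps: np.ndarray | None = None,
    dt_ps: float = 10.0,
) -> Trajectory:
    """Read a MODEL/ENDMDL trajectory.

    Frame times come from ``times_ps`` (e.g. a sidecar table) or default to
    a uniform ``dt_ps`` grid starting at 0 (10 ps matches the usual save
    interval of production MD output).
    """
    # split into models, parse each with the structure reader
    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in pdb_text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            current = []
        elif rec == "ENDMDL":
            if current:
                blocks.append(current)
            current = None
        elif rec in ("ATOM", "HETATM", "TER") and current is not None:
            current.append(line)
    if not blocks:
        # single-model file: treat the whole text as one frame
        blocks = [[l for l in pdb_text.splitlines()
                   if l[:6].strip() in ("ATOM", "HETATM", "TER")]]
    frames = [read_structure("\n".join(b) + "\nEND\n") for b in blocks]
    n0 = frames[0].n_atoms
    for k, f in enumerate(frames):
        if f.n_atoms != n0:
            raise ValueError(f"model {k + 1} has {f.n_atoms} atoms, expected {n0}")
    coords = np.stack([f.coords for f in frames]) / A_PER_NM
    if times_ps is None:
        times_ps = np.arange(len(frames), dtype=float) * dt_ps
    return Trajectory(topology=frames[0], coords=coords, times_ps=np.asarray(times_ps))


def write_time_sidecar(traj: Trajectory) -> str:
    """TSV sidecar: frame index, time (ps), replica id (-1 if unknown)."""
    if traj.provenance is not None:
        rep = traj.provenance["replica"].to_numpy()
    else:
        rep = np.full(traj.n_frames, -1)
    df = pd.DataFrame({
        "frame": np.arange(traj.n_frames),
        "time_ps": traj.times_ps,
        "replica": rep,
    })
    return df.to_csv(sep="\t", index=False)


def read_time_sidecar(text: str) -> np.ndarray:
    df = pd.read_csv(io.StringIO(text), sep="\t")
    return df["time_ps"].to_numpy(dtype=float)
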