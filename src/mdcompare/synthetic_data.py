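"""Seeded synthetic structures and trajectories with known ground truth.

Every pipeline stage is verifiable against these generators: Gaussian
ensembles with prescribed covariance (eigen-recovery), random-diffusion
walks (cosine content), two-state mixtures with known populations
(landscape free-energy differences), rigid hinge motions of a two-chain
dimer (self/non-self fitting), and a toy dimer with donors, hydrogens and
acceptors (contact and hydrogen-bond criteria).

All generators are pure functions of their arguments: the same seed gives
bit-identical output, and each returns a ground-truth record alongside the
trajectory.  No global random state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .structure_io import Structure
from .trajectory import A_PER_NM, Trajectory

__all__ = [
    "GroundTruth",
    "ca_chain_topology",
    "gaussian_ensemble",
    "diffusion_trajectory",
    "two_state_ensemble",
    "hinge_dimer_trajectory",
    "toy_dimer",
    "add_point_solvent",
]


@dataclass(frozen=True)
class GroundTruth:
    """Structured record of what a generator actually produced."""

    kind: str
    payload: dict

    def to_json(self) -> str:
        def _default(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            raise TypeError(type(x))
        return json.dumps({"kind": self.kind, **self.payload},
                          default=_default, indent=2)


def ca_chain_topology(
    coords_angstrom: np.ndarray, chain: str = "A", start_resnum: int = 1
) -> Structure:
    """A C-alpha-only polyalanine topology at the given coordinates (A)."""
    coords = np.asarray(coords_angstrom, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    return Structure(
        names=np.array(["CA"] * n, dtype=object),
        elements=np.array(["C"] * n, dtype=object),
        resnames=np.array(["ALA"] * n, dtype=object),
        resnums=np.arange(start_resnum, start_resnum + n),
        icodes=np.array([""] * n, dtype=object),
        chain_ids=np.array([chain] * n, dtype=object),
        occupancies=np.ones(n),
        coords=coords,
        is_hetatm=np.zeros(n, dtype=bool),
    )


def _default_reference(n_atoms: int) -> np.ndarray:
    """A non-degenerate spread-out reference (nm): points on a coarse helix."""
    t = np.arange(n_atoms, dtype=float)
    return np.column_stack((
        np.cos(0.6 * t), np.sin(0.6 * t), 0.15 * t
    ))


def gaussian_ensemble(
    n_frames: int,
    seed: int,
    reference_nm: np.ndarray | None = None,
    n_atoms: int | None = None,
    variances_nm2: np.ndarray | None = None,
    sigma_nm: float | None = None,
    modes: np.ndarray | None = None,
    mode_variances_nm2: np.ndarray | None = None,
):
    """I.i.d. Gaussian frames about a reference with prescribed covariance.

    The covariance is specified either diagonally — ``variances_nm2`` per
    coordinate (length 3N) or one isotropic ``sigma_nm`` — or as a
    low-rank model: ``modes`` (k x 3N, rows orthonormalized internally)
    with ``mode_variances_nm2``, optionally on top of an isotropic floor
    ``sigma_nm``.  Returns ``(Trajectory, GroundTruth)``; the ground truth
    records the exact target covariance diagonal or eigenstructure.
    """
    if reference_nm is None:
        if n_atoms is None:
            raise ValueError("give reference_nm or n_atoms")
        reference_nm = _default_reference(n_atoms)
    reference_nm = np.asarray(reference_nm, dtype=float).reshape(-1, 3)
    n = reference_nm.shape[0]
    dim = 3 * n
    rng = np.random.default_rng(seed)

    if modes is not None:
        modes = np.asarray(modes, dtype=float).reshape(-1, dim)
        mode_variances_nm2 = np.asarray(mode_variances_nm2, dtype=float)
        if np.any(mode_variances_nm2 < 0):
            raise ValueError("mode variances must be non-negative")
        q, _ = np.linalg.qr(modes.T)
        basis = q[:, : modes.shape[0]]
        floor = (sigma_nm or 0.0) ** 2
        z = rng.standard_normal((n_frames, modes.shape[0]))
        disp = z * np.sqrt(mode_variances_nm2) @ basis.T
        if floor > 0:
            disp = disp + np.sqrt(floor) * rng.standard_normal((n_frames, dim))
        truth = GroundTruth("gaussian_ensemble", {
            "mode_variances_nm2": mode_variances_nm2,
            "isotropic_floor_nm2": floor,
            "modes": basis.T,
            "seed": seed, "n_frames": n_frames,
        })
    else:
        if variances_nm2 is None:
            if sigma_nm is None:
                raise ValueError("give variances_nm2, sigma_nm, or modes")
            variances_nm2 = np.full(dim, float(sigma_nm) ** 2)
        variances_nm2 = np.asarray(variances_nm2, dtype=float)
        if variances_nm2.shape != (dim,):
            raise ValueError(f"variances_nm2 must have length 3N = {dim}")
        if np.any(variances_nm2 < 0):
            raise ValueError("variances must be non-negative")
        disp = rng.standard_normal((n_frames, dim)) * np.sqrt(variances_nm2)
        truth = GroundTruth("gaussian_ensemble", {
            "variances_nm2": variances_nm2, "seed": seed, "n_frames": n_frames,
        })

    coords = reference_nm[None, :, :] + disp.reshape(n_frames, n, 3)
    topology = ca_chain_topology(reference_nm * A_PER_NM)
    traj = Trajectory(topology=topology, coords=coords,
                      times_ps=10.0 * np.arange(n_frames, dtype=float))
    return traj, truth


def diffusion_trajectory(
    n_atoms: int, n_frames: int, step_sigma_nm: float, seed: int
):
    """Independent Gaussian random walks per coordinate (free diffusion).

    Frame k sits at the cumulative sum of k i.i.d. Gaussian steps, so the
    displacement variance grows linearly with frame index.  The principal
    components of such a walk resemble half-period cosines, which is the
    signature that the cosine-content diagnostic flags.
    """
    if step_sigma_nm <= 0:
        raise ValueError("step_sigma_nm must be positive")
    rng = np.random.default_rng(seed)
    ref = _default_reference(n_atoms)
    steps = step_sigma_nm * rng.standard_normal((n_frames, n_atoms, 3))
    steps[0] = 0.0
    coords = ref[None] + np.cumsum(steps, axis=0)
    topology = ca_chain_topology(ref * A_PER_NM)
    truth = GroundTruth("diffusion_trajectory", {
        "step_sigma_nm": step_sigma_nm, "seed": seed, "n_frames": n_frames,
    })
    return Trajectory(topology=topology, coords=coords,
                      times_ps=10.0 * np.arange(n_frames, dtype=float)), truth


def two_state_ensemble(
    conf_a_nm: np.ndarray,
    conf_b_nm: np.ndarray,
    p_a: float,
    jitter_sigma_nm: float,
    n_frames: int,
    seed: int,
):
    """Frames drawn from two conformations with populations (p_a, 1 - p_a).

    Each frame is conformation A with probability ``p_a`` else B, plus
    isotropic Gaussian jitter.  The ground truth records the drawn state
    labels, so landscape population estimates can be checked against the
    realized (not just nominal) mixture.
    """
    if not 0.0 < p_a <= 1.0:
        raise ValueError("p_a must be in (0, 1]")
    conf_a = np.asarray(conf_a_nm, dtype=float).reshape(-1, 3)
    conf_b = np.asarray(conf_b_nm, dtype=float).reshape(-1, 3)
    if conf_a.shape != conf_b.shape:
        raise ValueError("conformations must share a topology")
    if np.allclose(conf_a, conf_b, atol=3 * jitter_sigma_nm):
        import warnings
        warnings.warn("states closer than the jitter: unresolvable mixture",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    labels = rng.random(n_frames) < p_a
    base = np.where(labels[:, None, None], conf_a[None], conf_b[None])
    coords = base + jitter_sigma_nm * rng.standard_normal(base.shape)
    topology = ca_chain_topology(conf_a * A_PER_NM)
    truth = GroundTruth("two_state_ensemble", {
        "p_a": p_a, "labels_a": labels.astype(int),
        "jitter_sigma_nm": jitter_sigma_nm, "seed": seed,
    })
    return Trajectory(topology=topology, coords=coords,
                      times_ps=10.0 * np.arange(n_frames, dtype=float)), truth


def hinge_dimer_trajectory(
    dimer: Structure, angle_schedule_deg: np.ndarray, seed: int = 0
):
    """Rigid hinge opening of chain B about the inter-chain interface axis.

    Chain A stays fixed (internally rigid); chain B is rotated, per frame,
    by the scheduled angle about an axis through the midpoint of the two
    chain centroids and perpendicular to the centroid-separation vector.
    Self-fitting on chain A therefore reports zero RMSD while non-self
    fitting picks up the full inter-monomer displacement.
    """
    chains = dimer.chains
    if len(chains) != 2:
        raise ValueError("hinge generator needs exactly two chains")
    mask_b = dimer.chain_mask(chains[1])
    coords0 = dimer.coords / A_PER_NM
    cen_a = coords0[~mask_b].mean(axis=0)
    cen_b = coords0[mask_b].mean(axis=0)
    sep = cen_b - cen_a
    norm = np.linalg.norm(sep)
    if norm < 1e-9:
        raise ValueError("degenerate hinge axis: chain centroids coincide")
    # deterministic perpendicular to the separation vector
    trial = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(trial, sep / norm)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    axis = np.cross(sep / norm, trial)
    axis /= np.linalg.norm(axis)
    pivot = 0.5 * (cen_a + cen_b)

    angles = np.asarray(angle_schedule_deg, dtype=float)
    frames = np.repeat(coords0[None], len(angles), axis=0)
    for k, deg in enumerate(angles):
        theta = np.deg2rad(deg)
        K = np.array([
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ])
        R = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)
        frames[k, mask_b] = (coords0[mask_b] - pivot) @ R.T + pivot
    truth = GroundTruth("hinge_dimer_trajectory", {
        "angles_deg": angles, "axis": axis, "pivot_nm": pivot, "seed": seed,
    })
    return Trajectory(topology=dimer, coords=frames,
                      times_ps=10.0 * np.arange(len(angles), dtype=float)), truth


# Per-residue backbone template (name, element, offset in A).  Chain B's
# carbonyl oxygen points back toward chain A so that every A-chain amide
# N-H donates a collinear hydrogen bond to it (N...O = 2.9 A, angle 180).
_CHAIN_A_TEMPLATE = (
    ("N", "N", (0.0, 0.0, 0.0)),
    ("H", "H", (0.0, -1.0, 0.0)),
    ("CA", "C", (1.4, 0.8, 0.0)),
    ("C", "C", (2.6, 0.0, 0.0)),
    ("O", "O", (2.6, 1.2, 0.0)),
)
_CHAIN_B_TEMPLATE = (
    ("N", "N", (2.0, -5.6, 0.0)),
    ("H", "H", (2.0, -6.6, 0.0)),
    ("CA", "C", (0.8, -5.0, 0.0)),
    ("C", "C", (1.2, -4.1, 0.0)),
    ("O", "O", (0.0, -2.9, 0.0)),
)
_RESIDUE_SPACING_A = 3.5


def toy_dimer(n_res_per_chain: int, seed: int = 0) -> Structure:
    """A two-chain polyalanine-like dimer with a hydrogen-bonded interface.

    Each residue carries backbone N, H, CA, C, O with valid PDB naming, so
    the rule-based donor/acceptor typing applies unchanged.  By
    construction every chain-A amide donates a hydrogen bond across the
    interface (N...O = 2.9 A, collinear), and inter-chain contacts within
    6 A exist along the whole interface.  ``seed`` only jitters nothing —
    the structure is deterministic — but is accepted for API uniformity.
    """
    if n_res_per_chain < 3:
        raise ValueError("need at least 3 residues per chain")
    names, elements, resnames, resnums, chains, coords = [], [], [], [], [], []
    for chain, template in (("A", _CHAIN_A_TEMPLATE), ("B", _CHAIN_B_TEMPLATE)):
        for i in range(n_res_per_chain):
            x0 = _RESIDUE_SPACING_A * i
            for name, el, (dx, dy, dz) in template:
                names.append(name)
                elements.append(el)
                resnames.append("ALA")
                resnums.append(i + 1)
                chains.append(chain)
                # alternate CA pucker so the C-alpha trace is never
                # collinear (pleated-strand-like), leaving the in-plane
                # amide/carbonyl hydrogen-bond geometry untouched
                if name == "CA":
                    dz = 0.45 * (-1.0) ** i
                coords.append((x0 + dx, dy, dz))
    n = len(names)
    return Structure(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resnums=np.array(resnums, dtype=int),
        icodes=np.array([""] * n, dtype=object),
        chain_ids=np.array(chains, dtype=object),
        occupancies=np.ones(n),
        coords=np.array(coords, dtype=float),
        is_hetatm=np.zeros(n, dtype=bool),
    )


def add_point_solvent(
    structure: Structure, n_waters: int, seed: int, shell_A: float = 6.0
) -> Structure:
    """Append simple 3-point waters in a shell around the structure.

    Water oxygens are placed uniformly in the bounding box expanded by
    ``shell_A`` (rejecting positions closer than 2.4 A to any existing
    atom); the two hydrogens sit at fixed 0.96 A offsets.  Intended only to
    exercise protein-solvent hydrogen-bond counting.
    """
    rng = np.random.default_rng(seed)
    lo = structure.coords.min(axis=0) - shell_A
    hi = structure.coords.max(axis=0) + shell_A
    placed = []
    existing = structure.coords
    attempts = 0
    while len(placed) < n_waters and attempts < 200 * n_waters:
        attempts += 1
        pos = lo + (hi - lo) * rng.random(3)
        d = np.linalg.norm(existing - pos, axis=1).min()
        if placed:
            d = min(d, np.linalg.norm(np.array(placed) - pos, axis=1).min())
        if d > 2.4:
            placed.append(pos)
    names, elements, resnums, chains, coords = [], [], [], [], []
    for k, o_pos in enumerate(placed):
        for name, el, off in (
            ("OW", "O", (0.0, 0.0, 0.0)),
            ("HW1", "H", (0.96, 0.0, 0.0)),
            ("HW2", "H", (-0.24, 0.93, 0.0)),
        ):
            names.append(name)
            elements.append(el)
            resnums.append(k + 1)
            chains.append("W")
            coords.append(o_pos + np.array(off))
    nw = len(names)
    water = Structure(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(["HOH"] * nw, dtype=object),
        resnums=np.array(resnums, dtype=int),
        icodes=np.array([""] * nw, dtype=object),
        chain_ids=np.array(chains, dtype=object),
        occupancies=np.ones(nw),
        coords=np.array(coords, dtype=float),
        is_hetatm=np.ones(nw, dtype=bool),
    )
    return Structure(
        names=np.concatenate([structure.names, water.names]),
        elements=np.concatenate([structure.elements, water.elements]),
        resnames=np.concatenate([structure.resnames, water.resnames]),
        resnums=np.concatenate([structure.resnums, water.resnums]),
        icodes=np.concatenate([structure.icodes, water.icodes]),
        chain_ids=np.concatenate([structure.chain_ids, water.chain_ids]),
        occupancies=np.concatenate([structure.occupancies, water.occupancies]),
        coords=np.vstack([structure.coords, water.coords]),
        is_hetatm=np.concatenate([structure.is_hetatm, water.is_hetatm]),
        title=structure.title,
    )
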