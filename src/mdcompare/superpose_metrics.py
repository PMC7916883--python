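"""Least-squares superposition and fluctuation metrics built on it.

RMSD time series (including the self-/non-self-fitting variants used to
separate internal monomer fluctuation from inter-monomer displacement),
per-residue RMSF, region-level RMSF statistics, and radius of gyration.

Conventions
-----------
* RMSD is measured against the starting (reference) structure after
  least-squares fitting on the fit selection.
* RMSF is measured about the time-average position after fitting every
  frame to the reference; the average-position convention is the standard
  one and is declared here because tools differ.
* Region statistics use the population (n) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import RegionSet, Structure
from .trajectory import Trajectory

__all__ = [
    "FitSpec",
    "RMSDSeries",
    "RMSFProfile",
    "kabsch_superpose",
    "apply_transform",
    "fit_frames",
    "rmsd_series",
    "rmsf_profile",
    "region_rmsf_stats",
    "radius_of_gyration",
    "ATOMIC_MASSES",
]

#: Standard atomic masses (u) for mass-weighted Rg.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
}


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
):
    """Optimal proper rotation + translation of ``mobile`` onto ``reference``.

    Returns ``(rotation_matrix, translation, rmsd)`` such that
    ``mobile @ R.T + t`` minimizes the (weighted) RMSD to ``reference``.
    The rotation is always proper (determinant +1).

    Raises ``ValueError`` for fewer than 3 atoms or a degenerate
    (collinear) reference, where the optimal rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference shapes differ")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()

    ref_c = reference - np.average(reference, axis=0, weights=weights)
    mob_c = mobile - np.average(mobile, axis=0, weights=weights)
    sv = np.linalg.svd(ref_c * np.sqrt(weights)[:, None], compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1.0):
        raise ValueError("degenerate (collinear) reference: rotation not unique")

    rot, _ = Rotation.align_vectors(ref_c, mob_c, weights=weights)
    R = rot.as_matrix()
    ref_mean = np.average(reference, axis=0, weights=weights)
    mob_mean = np.average(mobile, axis=0, weights=weights)
    t = ref_mean - mob_mean @ R.T
    # recompute the residual directly: the solver's rssd loses precision
    # to cancellation near zero
    diff = mob_c @ R.T - ref_c
    rmsd = float(np.sqrt(np.sum(weights * np.sum(diff**2, axis=1)) / wsum))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


@dataclass
class FitSpec:
    """What to superpose on and what to measure over.

    ``fit_indices`` selects the atoms used in the least-squares fit;
    ``measure_indices`` the atoms the metric is computed over.  Self-fitting
    sets both to the same monomer; non-self-fitting fits on one monomer and
    measures the other.  The reference defaults to the trajectory's
    starting structure.  ``superpose=False`` skips fitting entirely
    (frames are taken as already aligned), which is what raw-sample
    cross-checks against prescribed covariances use.
    """

    fit_indices: np.ndarray
    measure_indices: np.ndarray
    reference_nm: np.ndarray | None = None
    weights: np.ndarray | None = None
    superpose: bool = True

    def __post_init__(self) -> None:
        self.fit_indices = np.asarray(self.fit_indices, dtype=int)
        self.measure_indices = np.asarray(self.measure_indices, dtype=int)
        if self.fit_indices.size == 0 or self.measure_indices.size == 0:
            raise ValueError("fit and measure selections must be non-empty")
        if self.fit_indices.size < 3:
            raise ValueError("fit selection needs at least 3 atoms")

    @classmethod
    def ca_dimer(cls, topology: Structure, reference_nm: np.ndarray | None = None):
        """Fit and measure on all standard-residue CA atoms."""
        ca = topology.ca_indices()
        return cls(fit_indices=ca, measure_indices=ca, reference_nm=reference_nm)

    @classmethod
    def monomer(
        cls,
        topology: Structure,
        fit_chain: str,
        measure_chain: str | None = None,
        reference_nm: np.ndarray | None = None,
    ):
        """CA selection fitting on one chain and measuring another.

        ``measure_chain=None`` measures the fit chain itself (self-fitting).
        """
        fit = topology.ca_indices(fit_chain)
        measure = topology.ca_indices(measure_chain or fit_chain)
        return cls(fit_indices=fit, measure_indices=measure, reference_nm=reference_nm)


@dataclass
class RMSDSeries:
    times_ps: np.ndarray
    values_nm: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.values_nm < 0):
            raise ValueError("RMSD values must be non-negative")

    def to_tsv(self) -> str:
        return pd.DataFrame(
            {"time_ps": self.times_ps, "rmsd_nm": self.values_nm}
        ).to_csv(sep="\t", index=False, float_format="%.6f")


@dataclass
class RMSFProfile:
    """Per-residue RMSF (nm) keyed by (chain, residue number)."""

    keys: list[tuple[str, int]]
    values_nm: np.ndarray

    def __post_init__(self) -> None:
        self.values_nm = np.asarray(self.values_nm, dtype=float)
        if len(self.keys) != len(self.values_nm):
            raise ValueError("keys/values length mismatch")
        if np.any(self.values_nm < 0):
            raise ValueError("RMSF values must be non-negative")

    def value(self, chain: str, resnum: int) -> float:
        return float(self.values_nm[self.keys.index((chain, resnum))])

    def to_tsv(self) -> str:
        df = pd.DataFrame({
            "chain": [k[0] for k in self.keys],
            "residue": [k[1] for k in self.keys],
            "rmsf_nm": self.values_nm,
        })
        return df.to_csv(sep="\t", index=False, float_format="%.6f")


def _resolve_reference(traj: Trajectory, spec: FitSpec) -> np.ndarray:
    ref = spec.reference_nm if spec.reference_nm is not None else traj.reference_nm
    ref = np.asarray(ref, dtype=float)
    if ref.shape != (traj.n_atoms, 3):
        raise ValueError("reference shape does not match trajectory atoms")
    return ref


def fit_frames(traj: Trajectory, spec: FitSpec) -> np.ndarray:
    """All frames least-squares fitted to the reference on the fit selection."""
    if not spec.superpose:
        return traj.coords.copy()
    ref = _resolve_reference(traj, spec)
    out = np.empty_like(traj.coords)
    for k in range(traj.n_frames):
        R, t, _ = kabsch_superpose(
            traj.coords[k, spec.fit_indices], ref[spec.fit_indices], spec.weights
        )
        out[k] = apply_transform(traj.coords[k], R, t)
    return out


def rmsd_series(traj: Trajectory, spec: FitSpec) -> RMSDSeries:
    """Per-frame RMSD (nm) over the measure selection after fitting.

    With ``fit_indices`` = ``measure_indices`` = one monomer this is the
    self-fitting RMSD of that monomer; fitting on the partner monomer
    instead gives the non-self-fitting RMSD, which additionally picks up
    inter-monomer displacement.
    """
    ref = _resolve_reference(traj, spec)
    fitted = fit_frames(traj, spec)
    diff = fitted[:, spec.measure_indices] - ref[spec.measure_indices]
    values = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    return RMSDSeries(times_ps=traj.times_ps.copy(), values_nm=values)


def rmsf_profile(traj: Trajectory, spec: FitSpec) -> RMSFProfile:
    """Per-residue RMSF about the time-average position of each CA atom.

    Frames are first fitted to the reference on the fit selection; the
    fluctuation of each measure atom is then taken about its time-average
    position: RMSF_i = sqrt(<|r_i - <r_i>|^2>).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF undefined for fewer than 2 frames")
    fitted = fit_frames(traj, spec)[:, spec.measure_indices]
    mean_pos = fitted.mean(axis=0)
    msf = np.sum(np.mean((fitted - mean_pos) ** 2, axis=0), axis=1)
    keys = [
        (str(traj.topology.chain_ids[i]), int(traj.topology.resnums[i]))
        for i in spec.measure_indices
    ]
    return RMSFProfile(keys=keys, values_nm=np.sqrt(msf))


def region_rmsf_stats(
    profile: RMSFProfile,
    regions: RegionSet,
    structure: Structure,
    monomer_chains: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Mean and population SD of RMSF over each region, per monomer.

    For the site owned by monomer A the partner contributions come from
    chain B and vice versa.  Output rows are regions, columns
    ``{region, monomer, n_residues, mean_nm, sd_nm}``.
    """
    lookup = dict(zip(profile.keys, profile.values_nm))
    rows = []
    chain_a, chain_b = monomer_chains
    for own, other in ((chain_a, chain_b), (chain_b, chain_a)):
        resolved = regions.resolve(structure, own_chain=own, other_chain=other)
        for name, members in resolved.items():
            vals = []
            for chain, num in members:
                if (chain, num) not in lookup:
                    raise ValueError(
                        f"region {name!r}: residue ({chain}, {num}) missing "
                        "from RMSF profile"
                    )
                vals.append(lookup[(chain, num)])
            if not vals:
                raise ValueError(f"region {name!r} is empty")
            vals = np.asarray(vals)
            rows.append({
                "region": name,
                "monomer": own,
                "n_residues": len(vals),
                "mean_nm": float(vals.mean()),
                "sd_nm": float(vals.std()),  # population SD
            })
    return pd.DataFrame(rows)


def radius_of_gyration(coords_angstrom: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration (Angstrom) about the center of mass.

    Rg^2 = sum_i m_i |r_i - r_cm|^2 / sum_i m_i — the root-mean-square
    (mass-weighted) distance of the atoms from their centroid.
    """
    coords = np.asarray(coords_angstrom, dtype=float).reshape(-1, 3)
    masses = np.asarray(masses, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("radius of gyration of an empty selection")
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = np.average(coords, axis=0, weights=masses)
    return float(np.sqrt(np.sum(masses * np.sum((coords - com) ** 2, axis=1)) / total))


def masses_for(structure: Structure) -> np.ndarray:
    """Standard atomic masses for every atom; unknown elements are an error."""
    masses = []
    missing = set()
    for el in structure.elements:
        el = str(el).upper()
        if el in ATOMIC_MASSES:
            masses.append(ATOMIC_MASSES[el])
        else:
            missing.add(el)
    if missing:
        raise ValueError(f"no mass for element(s): {sorted(missing)}")
    return np.asarray(masses)
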