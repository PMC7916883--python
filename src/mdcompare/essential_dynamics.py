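"""Essential dynamics: C-alpha covariance analysis and its diagnostics.

Builds the 3N x 3N positional covariance matrix of the fitted C-alpha
ensemble, diagonalizes it into collective motion modes (eigenvectors) and
their mean-square amplitudes (eigenvalues, nm^2), and provides the
derived quantities used to compare systems: total mean square fluctuation
(TMSF, the covariance trace), cumulative eigenvalue contributions,
trajectory projections onto modes, cosine-content sampling-convergence
diagnostics, and the two extreme conformations along a mode for porcupine
visualization.

Fitting uses a two-pass scheme: frames are first fitted to the starting
structure, their mean is taken, and all frames are re-fitted to that mean,
so the covariance is measured about the ensemble-mean conformation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .structure_io import write_structure
from .superpose_metrics import FitSpec, apply_transform, kabsch_superpose
from .trajectory import A_PER_NM, Trajectory

__all__ = [
    "CovarianceModel",
    "ProjectionSeries",
    "build_covariance",
    "cumulative_contribution",
    "project",
    "cosine_content",
    "porcupine_extremes",
]


@dataclass
class CovarianceModel:
    """Eigen-decomposed C-alpha covariance of a fitted ensemble.

    ``mean_nm`` is the ensemble-mean conformation of the analysis atoms,
    ``covariance_nm2`` the 3N x 3N matrix, ``eigenvalues_nm2`` sorted
    descending with orthonormal ``eigenvectors`` as columns.  TMSF is the
    trace, equal to the eigenvalue sum.  Eigenvector signs follow the
    convention that each vector's largest-magnitude component is positive.
    """

    mean_nm: np.ndarray
    covariance_nm2: np.ndarray
    eigenvalues_nm2: np.ndarray
    eigenvectors: np.ndarray
    analysis_indices: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.mean_nm.shape[0]

    @property
    def tmsf_nm2(self) -> float:
        return float(np.trace(self.covariance_nm2))

    def spectrum_tsv(self, k: int | None = None) -> str:
        """Eigenvalue spectrum with cumulative contributions (TSV)."""
        cum = cumulative_contribution(self.eigenvalues_nm2)
        df = pd.DataFrame({
            "eigenvector": np.arange(1, len(self.eigenvalues_nm2) + 1),
            "eigenvalue_nm2": self.eigenvalues_nm2,
            "cumulative_pct": cum,
        })
        if k is not None:
            df = df.head(k)
        return df.to_csv(sep="\t", index=False, float_format="%.8f")


@dataclass
class ProjectionSeries:
    """Scalar displacement along one eigenvector, per frame (nm)."""

    times_ps: np.ndarray
    values_nm: np.ndarray
    eigenvector_index: int

    def to_tsv(self) -> str:
        return pd.DataFrame({
            "time_ps": self.times_ps,
            f"projection_ev{self.eigenvector_index + 1}_nm": self.values_nm,
        }).to_csv(sep="\t", index=False, float_format="%.6f")


def _fit_to(coords: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for k in range(coords.shape[0]):
        R, t, _ = kabsch_superpose(coords[k, fit_idx], reference[fit_idx])
        out[k] = apply_transform(coords[k], R, t)
    return out


def build_covariance(
    traj: Trajectory,
    fit_spec: FitSpec | None = None,
    analysis_indices: np.ndarray | None = None,
) -> CovarianceModel:
    """Covariance model of the C-alpha ensemble after least-squares fitting.

    Frames are fitted to the starting structure on the fit selection, the
    ensemble mean is formed, frames are re-fitted to that mean, and the
    (population) covariance of the analysis atoms about the mean is
    diagonalized.  Eigenpairs come back sorted by decreasing eigenvalue.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a covariance model")
    if fit_spec is None:
        fit_spec = FitSpec.ca_dimer(traj.topology)
    if analysis_indices is None:
        analysis_indices = fit_spec.measure_indices
    analysis_indices = np.asarray(analysis_indices, dtype=int)

    if fit_spec.superpose:
        ref = (fit_spec.reference_nm if fit_spec.reference_nm is not None
               else traj.reference_nm)
        fitted = _fit_to(traj.coords, np.asarray(ref), fit_spec.fit_indices)
        mean1 = fitted.mean(axis=0)
        fitted = _fit_to(fitted, mean1, fit_spec.fit_indices)
    else:
        fitted = traj.coords.copy()

    sub = fitted[:, analysis_indices]
    mean = sub.mean(axis=0)
    x = (sub - mean).reshape(traj.n_frames, -1)
    cov = x.T @ x / traj.n_frames
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals, kind="stable")[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # sign convention: largest-magnitude component positive
    for j in range(evecs.shape[1]):
        i_max = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i_max, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return CovarianceModel(
        mean_nm=mean,
        covariance_nm2=cov,
        eigenvalues_nm2=evals,
        eigenvectors=evecs,
        analysis_indices=analysis_indices,
    )


def cumulative_contribution(eigenvalues: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Percent of TMSF carried by the leading k eigenvectors, for each k.

    Non-decreasing, ending at 100%.  Eigenvalues must be sorted descending
    and non-negative (tiny negative rounding is clipped; anything beyond
    ``tol`` of the total is an error).
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(ev) > 1e-12 * max(abs(ev[0]), 1.0)):
        raise ValueError("eigenvalues must be sorted in descending order")
    total = ev.sum()
    if total <= 0:
        raise ValueError("total fluctuation is zero")
    if np.any(ev < -tol * total):
        raise ValueError("negative eigenvalue beyond tolerance")
    ev = np.clip(ev, 0.0, None)
    return 100.0 * np.cumsum(ev) / ev.sum()


def project(traj: Trajectory, model: CovarianceModel, index: int,
            fit_spec: FitSpec | None = None) -> ProjectionSeries:
    """Project the fitted, mean-centered trajectory onto one eigenvector.

    The projection of frame t is the dot product of its centered analysis
    coordinates with eigenvector ``index`` (0-based).  By construction the
    series has mean ~0 and variance equal to the eigenvalue.
    """
    nvec = model.eigenvectors.shape[1]
    if not 0 <= index < nvec:
        raise IndexError(f"eigenvector index {index} out of range (0..{nvec - 1})")
    if fit_spec is None:
        fit_spec = FitSpec.ca_dimer(traj.topology)
    if fit_spec.superpose:
        ref = (fit_spec.reference_nm if fit_spec.reference_nm is not None
               else traj.reference_nm)
        fitted = _fit_to(traj.coords, np.asarray(ref), fit_spec.fit_indices)
        fitted = _fit_to(fitted, _embed_mean(model, traj), fit_spec.fit_indices)
    else:
        fitted = traj.coords.copy()
    x = (fitted[:, model.analysis_indices] - model.mean_nm).reshape(traj.n_frames, -1)
    values = x @ model.eigenvectors[:, index]
    return ProjectionSeries(times_ps=traj.times_ps.copy(), values_nm=values,
                            eigenvector_index=index)


def _embed_mean(model: CovarianceModel, traj: Trajectory) -> np.ndarray:
    """Full-topology coordinates whose analysis atoms sit at the model mean."""
    full = traj.reference_nm.copy()
    full[model.analysis_indices] = model.mean_nm
    return full


def cosine_content(series: ProjectionSeries, harmonic: int = 1) -> float:
    """Cosine content of a projection series for harmonic i.

    c_i = (2/T) * (integral cos(i*pi*t/T) p(t) dt)^2 / integral p(t)^2 dt,
    integrals by the trapezoid rule on the frame time grid.  Ranges over
    [0, 1]; values near 1 mean the mode looks like random diffusion
    (insufficient sampling), values near 0 mean converged sampling.
    """
    t = np.asarray(series.times_ps, dtype=float)
    p = np.asarray(series.values_nm, dtype=float)
    if len(t) < 3:
        raise ValueError("cosine content needs at least 3 frames")
    denom = np.trapezoid(p * p, t)
    if denom <= 0:
        raise ValueError("cosine content undefined for an all-zero series")
    t0, T = t[0], t[-1] - t[0]
    num = np.trapezoid(np.cos(harmonic * np.pi * (t - t0) / T) * p, t)
    return float(np.clip(2.0 / T * num**2 / denom, 0.0, 1.0))


def porcupine_extremes(
    model: CovarianceModel,
    series: ProjectionSeries,
    traj: Trajectory,
):
    """Extreme conformations along a mode plus per-atom displacement vectors.

    Returns ``(conf_min, conf_max, vectors)`` where the conformations are
    the analysis-atom coordinates (nm) at the minimum and maximum of the
    projection series and ``vectors`` is a DataFrame of per-atom
    displacement components (max minus min extreme) for porcupine-style
    rendering: each atom's arrow gives the direction and amplitude of its
    motion along the mode.
    """
    values = np.asarray(series.values_nm)
    if np.ptp(values) <= 0:
        raise ValueError("projection series is constant; extremes undefined")
    j = series.eigenvector_index
    vec = model.eigenvectors[:, j].reshape(-1, 3)
    lo, hi = float(values.min()), float(values.max())
    conf_min = model.mean_nm + lo * vec
    conf_max = model.mean_nm + hi * vec
    disp = (hi - lo) * vec
    top = traj.topology
    idx = model.analysis_indices
    vectors = pd.DataFrame({
        "chain": [str(top.chain_ids[i]) for i in idx],
        "residue": [int(top.resnums[i]) for i in idx],
        "atom": [str(top.names[i]) for i in idx],
        "dx_nm": disp[:, 0], "dy_nm": disp[:, 1], "dz_nm": disp[:, 2],
        "length_nm": np.linalg.norm(disp, axis=1),
    })
    return conf_min, conf_max, vectors


def porcupine_pdb(model: CovarianceModel, conf_min: np.ndarray,
                  conf_max: np.ndarray, traj: Trajectory) -> str:
    """Two-model PDB (extreme 1, extreme 2) for visualization tools."""
    sub = traj.topology.select(
        np.isin(np.arange(traj.topology.n_atoms), model.analysis_indices)
    )
    out = []
    for k, conf in enumerate((conf_min, conf_max)):
        out.append(write_structure(replace(sub, coords=conf * A_PER_NM),
                                   model_number=k + 1))
    return "".join(out) + "END\n"
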