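"""Two-dimensional free-energy landscapes by Boltzmann inversion.

The sampled density over the first two essential-dynamics projections is
binned on a 2-D grid and inverted to relative free energies,
F_i = -k_B T ln(N_i / N_max), which fixes F = 0 at the most populated bin
and leaves empty bins undefined (+inf).  Published landscapes from engine
tools often carry an arbitrary negative offset; basin analysis here is
offset-invariant, so counts at level L on this scale correspond to counts
at L + c on a shifted scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .essential_dynamics import ProjectionSeries

#: Boltzmann constant in kJ mol^-1 K^-1.
KB_KJ_PER_MOL_K = 0.0083144621

__all__ = ["FELGrid", "build_fel", "count_basins", "fel_report", "KB_KJ_PER_MOL_K"]

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class FELGrid:
    """Binned 2-D projection density and its Boltzmann-inverted free energy.

    ``free_energy`` is in kJ/mol with 0 at the most populated bin and
    ``inf`` in empty bins; ``counts`` sum to the number of frames.
    """

    edges1_nm: np.ndarray
    edges2_nm: np.ndarray
    counts: np.ndarray
    free_energy_kJmol: np.ndarray
    temperature_K: float

    @property
    def n_max(self) -> int:
        return int(self.counts.max())

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def centers(self):
        c1 = 0.5 * (self.edges1_nm[:-1] + self.edges1_nm[1:])
        c2 = 0.5 * (self.edges2_nm[:-1] + self.edges2_nm[1:])
        return c1, c2

    def to_tsv(self) -> str:
        c1, c2 = self.centers()
        rows = []
        for i, x in enumerate(c1):
            for j, y in enumerate(c2):
                f = self.free_energy_kJmol[i, j]
                rows.append({
                    "ev1_nm": x, "ev2_nm": y,
                    "count": int(self.counts[i, j]),
                    "free_energy_kJmol": "inf" if np.isinf(f) else f"{f:.6f}",
                })
        return pd.DataFrame(rows).to_csv(sep="\t", index=False, float_format="%.6f")


def build_fel(
    series1: ProjectionSeries,
    series2: ProjectionSeries,
    nbins: int | tuple[int, int] = 32,
    temperature_K: float = 300.0,
) -> FELGrid:
    """Histogram two projection series and Boltzmann-invert the counts.

    Bin edges span [min, max] of each series (numpy half-open bins, last
    bin closed, so extreme frames are counted).  F = -k_B T ln(N_i/N_max);
    the modal bin sits at F = 0 and all finite F are >= 0.
    """
    p1 = np.asarray(series1.values_nm, dtype=float)
    p2 = np.asarray(series2.values_nm, dtype=float)
    if p1.size == 0 or p2.size == 0:
        raise ValueError("cannot build a landscape from zero frames")
    if p1.size != p2.size:
        raise ValueError("projection series have different lengths")
    if isinstance(nbins, int):
        nbins = (nbins, nbins)
    if min(nbins) < 2:
        raise ValueError("need at least 2 bins per axis")
    counts, e1, e2 = np.histogram2d(p1, p2, bins=nbins)
    n_max = counts.max()
    with np.errstate(divide="ignore"):
        free = np.where(
            counts > 0,
            -KB_KJ_PER_MOL_K * temperature_K * np.log(counts / n_max),
            np.inf,
        )
    return FELGrid(
        edges1_nm=e1, edges2_nm=e2, counts=counts.astype(int),
        free_energy_kJmol=free, temperature_K=temperature_K,
    )


def count_basins(grid: FELGrid, level_kJmol: float):
    """Connected components of bins with F < level (8-neighbour lattice).

    Returns ``(n_basins, basins)`` where each basin is a dict with its
    minimum free energy, bin count (area), and member bin indices.
    Diagonal-touching bins belong to the same basin.
    """
    mask = grid.free_energy_kJmol < level_kJmol
    labels, n = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    basins = []
    for lab in range(1, n + 1):
        member = labels == lab
        basins.append({
            "min_free_energy_kJmol": float(grid.free_energy_kJmol[member].min()),
            "area_bins": int(member.sum()),
            "bins": [tuple(ij) for ij in np.argwhere(member)],
        })
    basins.sort(key=lambda b: b["min_free_energy_kJmol"])
    return n, basins


def fel_report(grid: FELGrid, levels_kJmol: list[float]) -> pd.DataFrame:
    """Basin census: per energy level, basin count, minima and areas."""
    rows = []
    for level in levels_kJmol:
        n, basins = count_basins(grid, level)
        rows.append({
            "level_kJmol": level,
            "n_basins": n,
            "basin_minima_kJmol": [b["min_free_energy_kJmol"] for b in basins],
            "basin_areas_bins": [b["area_bins"] for b in basins],
        })
    return pd.DataFrame(rows)
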