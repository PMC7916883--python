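"""Replica-level statistics and the two-system comparison report.

Per-replica RMSD means/SDs over the equilibration window, the one-sided
Welch t-test used to ask whether one system's replicas fluctuate more than
the other's, and assembly/serialization of the side-by-side comparison
(structural parameters, per-region RMSF, essential-dynamics and landscape
summaries).
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .structure_io import RegionSet, ResidueMap, Structure
from .superpose_metrics import FitSpec, RMSFProfile, rmsd_series
from .trajectory import ReplicaSet

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicaStats",
    "ComparisonReport",
    "replica_rmsd_stats",
    "one_sided_t_test",
    "build_comparison_report",
]


@dataclass
class ReplicaStats:
    """Per-replica mean and SD of the equilibrated RMSD series."""

    system: str
    means_nm: np.ndarray
    sds_nm: np.ndarray

    def __post_init__(self) -> None:
        self.means_nm = np.asarray(self.means_nm, dtype=float)
        self.sds_nm = np.asarray(self.sds_nm, dtype=float)
        if self.means_nm.shape != self.sds_nm.shape:
            raise ValueError("means and SDs must pair one-per-replica")
        if np.any(self.sds_nm < 0):
            raise ValueError("SDs must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "system": self.system,
            "replica": np.arange(len(self.means_nm)),
            "rmsd_mean_nm": self.means_nm,
            "rmsd_sd_nm": self.sds_nm,
        })


def replica_rmsd_stats(
    replicas: ReplicaSet, spec: FitSpec, system: str = ""
) -> ReplicaStats:
    """Mean and SD of each replica's RMSD series over the equilibration window."""
    if len(replicas.replicas) < 2:
        raise ValueError("need at least 2 replicas")
    means, sds = [], []
    for traj in replicas.equilibrated():
        series = rmsd_series(traj, spec)
        means.append(float(series.values_nm.mean()))
        sds.append(float(series.values_nm.std(ddof=0)))
    return ReplicaStats(system=system, means_nm=np.array(means), sds_nm=np.array(sds))


def one_sided_t_test(
    sds_a: np.ndarray,
    sds_b: np.ndarray,
    alternative: str = "a_greater",
    equal_var: bool = False,
):
    """One-sided two-sample t-test on two sets of replica SDs.

    Default is the Welch (unequal-variance) form with Welch-Satterthwaite
    degrees of freedom; ``equal_var=True`` selects the pooled-variance
    variant.  ``alternative='a_greater'`` tests whether group A's mean
    exceeds group B's.  Returns ``(t, df, p)``.

    Degenerate input (both groups constant with equal means) has no
    information either way; p = 0.5 is returned by convention and logged.
    """
    a = np.asarray(sds_a, dtype=float)
    b = np.asarray(sds_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if alternative not in ("a_greater", "b_greater"):
        raise ValueError("alternative must be 'a_greater' or 'b_greater'")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            logger.warning("zero variance in both groups with equal means; p = 0.5")
            df = float(a.size + b.size - 2)
            return 0.0, df, 0.5
        # infinite separation: direction decides
        p = 0.0 if ((a.mean() > b.mean()) == (alternative == "a_greater")) else 1.0
        return float("inf") if p == 0.0 else float("-inf"), float(a.size + b.size - 2), p
    scipy_alt = "greater" if alternative == "a_greater" else "less"
    res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=scipy_alt)
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


@dataclass
class ComparisonReport:
    """Side-by-side results for two systems under one configuration.

    Tables: structural/geometrical parameter summary (one row per
    parameter and system), per-region RMSF statistics, per-residue RMSF on
    the reference numbering, replica RMSD statistics, eigen/landscape
    summaries, and the SD t-test result.
    """

    system_a: str
    system_b: str
    geometry: pd.DataFrame
    region_rmsf: pd.DataFrame
    residue_rmsf: pd.DataFrame
    replica_stats: pd.DataFrame
    ed_summary: pd.DataFrame
    sd_test: dict

    _TABLES = ("geometry", "region_rmsf", "residue_rmsf", "replica_stats",
               "ed_summary")

    def write(self, outdir: str | Path) -> None:
        """Serialize as a directory of TSVs plus a JSON summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            # default float formatting is shortest-round-trip: lossless
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t",
                                       index=False)
        summary = {
            "system_a": self.system_a,
            "system_b": self.system_b,
            "sd_test": self.sd_test,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    @classmethod
    def read(cls, outdir: str | Path) -> "ComparisonReport":
        outdir = Path(outdir)
        tables = {
            name: pd.read_csv(outdir / f"{name}.tsv", sep="\t")
            for name in cls._TABLES
        }
        summary = json.loads((outdir / "summary.json").read_text())
        return cls(system_a=summary["system_a"], system_b=summary["system_b"],
                   sd_test=summary["sd_test"], **tables)


def _rmsf_on_reference_numbering(
    profile: RMSFProfile, residue_map: ResidueMap | None, direction: str
) -> pd.DataFrame:
    df = pd.DataFrame({
        "chain": [k[0] for k in profile.keys],
        "residue": [k[1] for k in profile.keys],
        "rmsf_nm": profile.values_nm,
    })
    if residue_map is not None and direction == "b_to_a":
        translate = residue_map.b_to_a()
        df["residue_ref"] = [translate.get(r, pd.NA) for r in df["residue"]]
    else:
        df["residue_ref"] = df["residue"]
    return df


def build_comparison_report(
    system_a: str,
    system_b: str,
    geometry_a: pd.DataFrame,
    geometry_b: pd.DataFrame,
    region_rmsf_a: pd.DataFrame,
    region_rmsf_b: pd.DataFrame,
    profile_a: RMSFProfile,
    profile_b: RMSFProfile,
    replica_stats_a: ReplicaStats,
    replica_stats_b: ReplicaStats,
    ed_summary_a: dict,
    ed_summary_b: dict,
    residue_map: ResidueMap | None = None,
) -> ComparisonReport:
    """Assemble the aligned two-system report.

    Per-residue RMSF of system B is plotted on system A's numbering through
    ``residue_map`` (column ``residue_ref``); region tables and parameter
    summaries are stacked with a ``system`` column.  The SD t-test is run
    one-sided with system A as the candidate larger-fluctuation system.
    """
    geometry = pd.concat([
        geometry_a.assign(system=system_a),
        geometry_b.assign(system=system_b),
    ], ignore_index=True)
    region = pd.concat([
        region_rmsf_a.assign(system=system_a),
        region_rmsf_b.assign(system=system_b),
    ], ignore_index=True)
    res_a = _rmsf_on_reference_numbering(profile_a, None, "identity").assign(
        system=system_a)
    res_b = _rmsf_on_reference_numbering(profile_b, residue_map, "b_to_a").assign(
        system=system_b)
    residue = pd.concat([res_a, res_b], ignore_index=True)
    replica = pd.concat(
        [replica_stats_a.to_frame(), replica_stats_b.to_frame()], ignore_index=True
    )
    ed = pd.DataFrame([
        {"system": system_a, **ed_summary_a},
        {"system": system_b, **ed_summary_b},
    ])
    t, df, p = one_sided_t_test(replica_stats_a.sds_nm, replica_stats_b.sds_nm)
    return ComparisonReport(
        system_a=system_a, system_b=system_b, geometry=geometry,
        region_rmsf=region, residue_rmsf=residue, replica_stats=replica,
        ed_summary=ed,
        sd_test={"t": t, "df": df, "p_value": p, "alternative": "a_greater"},
    )
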