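"""First-passage insertion detection and the association constant K_in.

The insertion metric follows the kinetic scheme in which a solute in the
water slab associates with the membrane at rate K_in = A * L_z / <W>, where
A is the lateral membrane area (Å²), L_z the thickness of the water layer
the solute diffuses through (Å), and <W> the mean first-passage time to the
membrane surface (ns).  With the Å³ -> M⁻¹ conversion constant the result is
reported in M⁻¹ s⁻¹.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "FirstPassageResult",
    "KinEstimate",
    "KinComparison",
    "detect_insertion",
    "mean_first_passage",
    "compute_kin",
    "percent_slower",
    "rank_analogues",
    "lipid_ratio",
    "C_VOL",
]

#: Å³ -> M⁻¹ conversion: N_A / 10²⁷ (one molecule per Å³ equals 1/C_VOL molar).
C_VOL = 6.02214e-4


@dataclass(frozen=True)
class FirstPassageResult:
    """Outcome of insertion detection for one replicate."""

    replicate_id: str
    inserted: bool
    W: float  # ns; first-passage time, or censoring time when censored
    censored: bool

    def __post_init__(self) -> None:
        if self.W < 0:
            raise ValueError("W must be non-negative")
        if self.censored and self.inserted:
            raise ValueError("a censored replicate cannot be marked inserted")


@dataclass(frozen=True)
class KinEstimate:
    analogue: str
    lipid: str
    A: float  # Å²
    L_z: float  # Å
    W_mean: float  # ns
    W_sem: float  # ns
    n_inserted: int
    n_censored: int
    K_in: float  # M⁻¹ s⁻¹

    def __post_init__(self) -> None:
        expected = compute_kin(self.A, self.L_z, self.W_mean)
        if abs(self.K_in - expected) > 1e-12 * abs(expected):
            raise ValueError("K_in inconsistent with A, L_z and W_mean")

    @classmethod
    def from_inputs(
        cls,
        analogue: str,
        lipid: str,
        A: float,
        L_z: float,
        W_mean: float,
        W_sem: float = float("nan"),
        n_inserted: int = 0,
        n_censored: int = 0,
    ) -> "KinEstimate":
        return cls(
            analogue=analogue,
            lipid=lipid,
            A=A,
            L_z=L_z,
            W_mean=W_mean,
            W_sem=W_sem,
            n_inserted=n_inserted,
            n_censored=n_censored,
            K_in=compute_kin(A, L_z, W_mean),
        )


@dataclass(frozen=True)
class KinComparison:
    """Table-level comparison of per-analogue K_in across lipids."""

    kin_table: pd.DataFrame  # index: lipid, columns: analogue
    percent_differences: pd.DataFrame  # vs the reference analogue, per lipid
    rank_order: dict[str, list[str]]  # lipid -> analogues by descending K_in
    lipid_ratios: pd.Series | None  # per-analogue ratio between two lipids
    mean_lipid_ratio: float | None


def detect_insertion(
    traj: Trajectory,
    surface_z: float,
    persistence: float = 0.5,
    replicate_id: str = "rep",
) -> FirstPassageResult:
    """Find the first persistent crossing of the drug COM below ``surface_z``.

    W is the earliest time t such that the drug center-of-mass z is at or
    below ``surface_z`` for every existing frame in [t, t + persistence].
    If no such t exists the replicate is censored at the last frame time.

    Raises
    ------
    ValueError
        For an empty trajectory, or when the drug starts at or below the
        surface (invalid setup: there is no approach to detect).
    """
    if traj.n_frames == 0:
        raise ValueError("cannot detect insertion in an empty trajectory")
    if persistence < 0:
        raise ValueError("persistence must be non-negative")
    z = traj.drug_com_z
    if z[0] <= surface_z:
        raise ValueError(
            f"drug starts at z = {z[0]:.2f} Å, already at/below surface_z = {surface_z:.2f} Å"
        )
    below = z <= surface_z
    times = traj.times
    n = len(times)
    for i in np.flatnonzero(below):
        j = int(np.searchsorted(times, times[i] + persistence, side="right"))
        if below[i:j].all():
            return FirstPassageResult(replicate_id, True, float(times[i]), False)
    return FirstPassageResult(replicate_id, False, float(times[-1]), True)


def mean_first_passage(
    results: list[FirstPassageResult], censor_policy: str = "drop"
) -> tuple[float, float, int, int]:
    """Aggregate replicate first-passage times into (W_mean, W_sem, n_inserted, n_censored).

    Policy ``drop`` averages uncensored replicates only and reports the
    censored count (warning above 25% censoring); policy ``error`` refuses
    any censored input.
    """
    if censor_policy not in ("drop", "error"):
        raise ValueError(f"unknown censor_policy {censor_policy!r}")
    censored = [r for r in results if r.censored]
    inserted = [r for r in results if not r.censored]
    if censor_policy == "error" and censored:
        raise ValueError(f"{len(censored)} censored replicate(s) under policy 'error'")
    if not inserted:
        raise ValueError("all replicates censored: no first-passage times to average")
    if results and len(censored) / len(results) > 0.25:
        warnings.warn(
            f"{len(censored)}/{len(results)} replicates censored (>25%); "
            "W_mean is biased toward fast insertions",
            stacklevel=2,
        )
    w = np.array([r.W for r in inserted])
    w_mean = float(w.mean())
    w_sem = float(w.std(ddof=1) / np.sqrt(len(w))) if len(w) > 1 else float("nan")
    return w_mean, w_sem, len(inserted), len(censored)


def compute_kin(A: float, L_z: float, W_mean: float) -> float:
    """K_in = A * L_z * C_VOL / (W_mean in seconds), in M⁻¹ s⁻¹."""
    if A <= 0 or L_z <= 0 or W_mean <= 0:
        raise ValueError("A, L_z and W_mean must all be positive")
    return A * L_z * C_VOL / (W_mean * 1e-9)


def percent_slower(K_ref: float, K_other: float) -> float:
    """How much slower ``K_other`` is than ``K_ref``, as (1 - K_other/K_ref)*100."""
    if K_ref <= 0:
        raise ValueError("K_ref must be positive")
    return (1.0 - K_other / K_ref) * 100.0


def rank_analogues(kin_table: dict[str, float] | pd.Series) -> list[str]:
    """Analogue labels by descending K_in; ties broken lexicographically."""
    series = pd.Series(kin_table)
    if series.empty:
        raise ValueError("empty K_in table")
    if series.index.duplicated().any():
        dupes = sorted(set(series.index[series.index.duplicated()]))
        raise ValueError(f"duplicate analogue labels: {dupes}")
    order = sorted(series.index, key=lambda lab: (-series[lab], lab))
    return list(order)


def lipid_ratio(
    kin_a: dict[str, float] | pd.Series, kin_b: dict[str, float] | pd.Series
) -> tuple[pd.Series, float]:
    """Element-wise K_b / K_a per analogue and the arithmetic mean ratio."""
    a, b = pd.Series(kin_a), pd.Series(kin_b)
    if set(a.index) != set(b.index):
        only_a = sorted(set(a.index) - set(b.index))
        only_b = sorted(set(b.index) - set(a.index))
        raise ValueError(
            f"analogue sets differ: only in first = {only_a}, only in second = {only_b}"
        )
    ratios = (b / a.reindex(b.index)).sort_index()
    return ratios, float(ratios.mean())


def compare_analogues(
    kin_table: pd.DataFrame, reference: str | None = None
) -> KinComparison:
    """Build the full comparison from a lipid x analogue K_in table.

    ``reference`` is the analogue percent differences are quoted against;
    defaults to the top-ranked analogue of the first lipid row.
    """
    ranks = {lipid: rank_analogues(kin_table.loc[lipid]) for lipid in kin_table.index}
    first = kin_table.index[0]
    ref = reference or ranks[first][0]
    pct = kin_table.apply(
        lambda row: pd.Series(
            {an: percent_slower(row[ref], row[an]) for an in kin_table.columns}
        ),
        axis=1,
    )
    ratios = mean_ratio = None
    if len(kin_table.index) == 2:
        lip_a, lip_b = kin_table.index
        ratios, mean_ratio = lipid_ratio(kin_table.loc[lip_a], kin_table.loc[lip_b])
    return KinComparison(
        kin_table=kin_table,
        percent_differences=pct,
        rank_order=ranks,
        lipid_ratios=ratios,
        mean_lipid_ratio=mean_ratio,
    )
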