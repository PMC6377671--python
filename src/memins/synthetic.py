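"""Synthetic bilayer-insertion data with known ground truth.

The generator emulates the study conditions of an unbiased drug-bilayer MD
campaign — a 128-lipid POPC or DMPC bilayer, the solute released 29 Å above
the bilayer center, twelve 100-ns repeats — with the simplest stochastic
model that still has closed-form answers: the solute's center-of-mass z
follows drift-diffusion toward the membrane, so its first-passage time to
the phosphate plane is inverse-Gaussian with mean d/v and shape d²/(2D).
Every analysis stage can therefore be tested against analytic ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .bilayer import BilayerModel
from .insertion_kinetics import FirstPassageResult
from .molecular_properties import IRSpectrum
from .trajectory import Trajectory

__all__ = [
    "KineticParams",
    "OrientationParams",
    "sample_first_passage_times",
    "simulate_insertion_trajectory",
    "trajectory_from_z_path",
    "generate_ir_table",
    "write_ground_truth_manifest",
]

#: Height of the solute above the bilayer center at t = 0 (Å).
DEFAULT_START_ABOVE_CENTER = 29.0

#: Pseudo-atoms per lipid: one choline, one phosphate, one glycerol/ester,
#: two tail beads.
ROLES_PER_LIPID = ("CHOL", "PO4", "GLY", "TAIL", "TAIL")

# Small rigid cloud of equal-mass beads standing in for the drug's heavy
# atoms; offsets sum to zero so the COM equals the simulated path.
_DRUG_OFFSETS = np.array(
    [
        [1.5, 0.0, 0.0], [-1.5, 0.0, 0.0],
        [0.0, 1.5, 0.0], [0.0, -1.5, 0.0],
        [0.0, 0.0, 1.5], [0.0, 0.0, -1.5],
        [1.0, 1.0, 1.0], [-1.0, -1.0, -1.0],
    ]
)


@dataclass(frozen=True)
class KineticParams:
    """Drift-diffusion parameters of the synthetic approach process.

    ``d`` is the starting height above the proximal phosphate plane, i.e.
    the first-passage distance.  The default corresponds to a release 29 Å
    above the center of a 37-Å bilayer (29 - 18.5 = 10.5 Å).
    """

    drift_speed: float = 1.0  # v, Å/ns toward the bilayer
    diffusion_coefficient: float = 2.0  # D, Å²/ns
    start_height: float = 10.5  # d, Å above the proximal phosphate plane
    n_replicates: int = 12
    max_time: float = 100.0  # ns
    frame_interval: float = 0.1  # ns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift_speed < 0 or self.diffusion_coefficient < 0:
            raise ValueError("drift and diffusion must be non-negative")
        if self.drift_speed == 0 and self.diffusion_coefficient == 0:
            raise ValueError("drift and diffusion cannot both be zero")
        if self.start_height <= 0:
            raise ValueError("start_height must be positive")
        if self.max_time <= 0:
            raise ValueError("max_time must be positive")

    @property
    def mean_first_passage(self) -> float:
        """Analytic mean d/v (infinite for pure diffusion)."""
        return self.start_height / self.drift_speed if self.drift_speed > 0 else np.inf

    @property
    def fpt_shape(self) -> float:
        """Inverse-Gaussian shape parameter λ = d²/(2D)."""
        if self.diffusion_coefficient == 0:
            return np.inf
        return self.start_height**2 / (2.0 * self.diffusion_coefficient)


@dataclass(frozen=True)
class OrientationParams:
    """Angular behaviour of one named molecular vector.

    The per-frame tilt relative to the bilayer normal concentrates around
    ``target_angle`` with spread 1/sqrt(concentration) radians; a zero
    concentration gives the isotropic (sin θ) distribution.  A positive
    ``switching_rate`` alternates between ``target_angle`` and
    ``second_target`` with exponential waiting times, which emulates a
    molecule with no single preference (the mixed horizontal/perpendicular
    case).
    """

    target_angle: float = 90.0  # degrees in [0, 180]
    concentration: float = 50.0  # unitless >= 0; 0 = isotropic
    switching_rate: float = 0.0  # 1/ns
    second_target: float | None = None

    def __post_init__(self) -> None:
        for ang in (self.target_angle, self.second_target):
            if ang is not None and not 0.0 <= ang <= 180.0:
                raise ValueError("target angles must lie in [0, 180] degrees")
        if not np.isfinite(self.concentration) or self.concentration < 0:
            raise ValueError("concentration must be finite and non-negative")
        if self.switching_rate > 0 and self.second_target is None:
            raise ValueError("switching requires a second_target angle")


def sample_first_passage_times(params: KineticParams) -> list[FirstPassageResult]:
    """Draw replicate first-passage times from the analytic drift-diffusion law.

    Draws exceeding ``max_time`` are returned censored at ``max_time``.
    The deterministic drift limit (D = 0) yields d/v exactly; pure diffusion
    (v = 0) follows the one-sided stable law and a warning is emitted since
    many replicates may censor.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_replicates
    d, v, D = params.start_height, params.drift_speed, params.diffusion_coefficient
    if D == 0:
        draws = np.full(n, d / v)
    elif v == 0:
        warnings.warn(
            "zero drift: first-passage times follow a heavy-tailed law and "
            "may censor at max_time in most replicates",
            stacklevel=2,
        )
        draws = stats.levy.rvs(scale=d**2 / (2 * D), size=n, random_state=rng)
    else:
        mean, lam = d / v, d**2 / (2 * D)
        draws = stats.invgauss.rvs(mean / lam, scale=lam, size=n, random_state=rng)
    results = []
    for i, w in enumerate(draws):
        censored = w > params.max_time
        results.append(
            FirstPassageResult(
                replicate_id=f"rep{i:03d}",
                inserted=not censored,
                W=float(min(w, params.max_time)),
                censored=bool(censored),
            )
        )
    return results


def _sample_angles(
    params: OrientationParams, times: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame tilt angles (degrees) for one molecular vector."""
    n = len(times)
    if n == 0:
        return np.empty(0)
    targets = np.full(n, params.target_angle)
    if params.switching_rate > 0 and n > 1:
        # telegraph process between the two targets
        state = 0
        t_next = rng.exponential(1.0 / params.switching_rate)
        pair = (params.target_angle, params.second_target)
        for i, t in enumerate(times):
            while t >= t_next:
                state ^= 1
                t_next += rng.exponential(1.0 / params.switching_rate)
            targets[i] = pair[state]
    if params.concentration == 0:
        return np.degrees(np.arccos(rng.uniform(-1.0, 1.0, size=n)))
    sigma_deg = np.degrees(1.0 / np.sqrt(params.concentration))
    theta = targets + rng.normal(0.0, sigma_deg, size=n)
    # reflect into [0, 180]
    theta = np.abs(theta)
    over = theta > 180.0
    theta[over] = 360.0 - theta[over]
    return theta


def _angles_to_vectors(theta_deg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit vectors with given polar angles and random azimuths."""
    theta = np.radians(theta_deg)
    phi = rng.uniform(0.0, 2 * np.pi, size=len(theta_deg))
    return np.column_stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )


def _place_lipids(
    bilayer: BilayerModel, n_frames: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lipid pseudo-atom coordinates per frame, with role and leaflet labels.

    Lateral positions are uniform in the box per lipid (jittered per frame);
    z positions are drawn from each component's Gaussian profile, mirrored
    for the lower leaflet.
    """
    n_per_leaf = bilayer.n_per_leaflet
    roles, leaflets, means, sds, signs = [], [], [], [], []
    for leaflet, sign in (("U", 1.0), ("L", -1.0)):
        for _ in range(n_per_leaf):
            for role in ROLES_PER_LIPID:
                prof = bilayer.component_profiles[role]
                roles.append(role)
                leaflets.append(leaflet)
                means.append(sign * prof.mean)
                sds.append(prof.sd)
                signs.append(sign)
    n_atoms = len(roles)
    means = np.array(means)
    sds = np.array(sds)
    xy = rng.uniform([0, 0], [bilayer.box_x, bilayer.box_y], size=(n_frames, n_atoms, 2))
    z = rng.normal(means, sds, size=(n_frames, n_atoms))
    coords = np.concatenate([xy, z[:, :, None]], axis=2)
    return coords, np.array(roles, dtype="U8"), np.array(leaflets, dtype="U1")


def _simulate_z_path(
    times: np.ndarray,
    start_z: float,
    kinetics: KineticParams,
    surface_z: float,
    top_z: float,
    settle_offset: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Euler-Maruyama drift-diffusion path, reflecting at ``top_z`` and
    absorbed (held just below the surface) once it crosses ``surface_z``."""
    n = len(times)
    z = np.empty(n)
    if n == 0:
        return z
    z[0] = start_z
    dt = kinetics.frame_interval
    sigma = np.sqrt(2.0 * kinetics.diffusion_coefficient * dt)
    absorbed = z[0] <= surface_z
    hold = surface_z - settle_offset
    for i in range(1, n):
        if absorbed:
            z[i] = hold
            continue
        step = -kinetics.drift_speed * dt + sigma * rng.normal()
        zi = z[i - 1] + step
        if zi > top_z:
            zi = 2 * top_z - zi
        if zi <= surface_z:
            absorbed = True
            zi = hold
        z[i] = zi
    return z


def simulate_insertion_trajectory(
    bilayer: BilayerModel,
    kinetics: KineticParams,
    orientation: dict[str, OrientationParams] | None = None,
    seed: int | None = None,
    start_above_center: float = DEFAULT_START_ABOVE_CENTER,
    settle_offset: float = 1.0,
    include_lipids: bool = True,
) -> Trajectory:
    """Generate one replicate trajectory of a solute approaching the bilayer.

    The COM starts ``start_above_center`` Å above z = 0, drifts/diffuses
    toward the upper phosphate plane, reflects at the far water boundary
    (box top), and after first crossing the plane is held ``settle_offset``
    Å below it.  Orientation vectors are sampled per named
    :class:`OrientationParams`; lipid pseudo-atoms are drawn from the
    bilayer's component profiles.
    """
    if kinetics.frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    n_steps = round(kinetics.max_time / kinetics.frame_interval)
    if abs(n_steps * kinetics.frame_interval - kinetics.max_time) > 1e-9:
        raise ValueError("frame_interval must divide max_time")
    rng = np.random.default_rng(kinetics.seed if seed is None else seed)
    times = np.arange(n_steps + 1) * kinetics.frame_interval if n_steps >= 0 else np.empty(0)
    if kinetics.max_time == 0:
        times = times[:1]

    surface = bilayer.phosphate_plane_upper
    z_path = _simulate_z_path(
        times, surface + kinetics.start_height if start_above_center is None
        else start_above_center,
        kinetics, surface, bilayer.box_z / 2.0, settle_offset, rng,
    )
    return trajectory_from_z_path(
        bilayer, times, z_path, rng=rng, orientation=orientation,
        include_lipids=include_lipids,
    )


def trajectory_from_z_path(
    bilayer: BilayerModel,
    times: np.ndarray,
    z_path: np.ndarray,
    rng: np.random.Generator | int | None = None,
    orientation: dict[str, OrientationParams] | None = None,
    include_lipids: bool = True,
) -> Trajectory:
    """Build a full labelled trajectory around a prescribed COM z series.

    Useful for analyses that need a controlled depth schedule (e.g. a solute
    held at phosphate depth, or descending into the tails at a set time).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    times = np.asarray(times, dtype=float)
    z_path = np.asarray(z_path, dtype=float)
    n = len(times)
    drug_com = np.column_stack(
        [np.full(n, bilayer.box_x / 2.0), np.full(n, bilayer.box_y / 2.0), z_path]
    )
    drug_coords = drug_com[:, None, :] + _DRUG_OFFSETS[None, :, :]
    orientations = {}
    for name, op in (orientation or {}).items():
        theta = _sample_angles(op, times, rng)
        orientations[name] = _angles_to_vectors(theta, rng)
    if include_lipids and n > 0:
        lipid_coords, roles, leaflets = _place_lipids(bilayer, n, rng)
    else:
        lipid_coords = np.empty((n, 0, 3))
        roles = np.empty(0, dtype="U8")
        leaflets = np.empty(0, dtype="U1")
    return Trajectory(
        times=times,
        drug_coords=drug_coords,
        lipid_coords=lipid_coords,
        lipid_roles=roles,
        lipid_leaflets=leaflets,
        box=np.array([bilayer.box_x, bilayer.box_y, bilayer.box_z]),
        orientations=orientations,
    )


def generate_ir_table(
    n_modes: int,
    window: tuple[float, float] = (0.0, 600.0),
    eps_range: tuple[float, float] = (0.0, 400.0),
    seed: int = 0,
    name: str = "synthetic",
) -> IRSpectrum:
    """Uniform random IR mode table, sorted by frequency, reproducible by seed."""
    if n_modes < 0:
        raise ValueError("n_modes must be non-negative")
    lo, hi = window
    if not (0.0 <= lo <= hi <= 4000.0):
        raise ValueError("window must be an ordered interval within [0, 4000] cm⁻¹")
    e_lo, e_hi = eps_range
    if e_lo > e_hi or e_lo < 0:
        raise ValueError("eps_range must be an ordered non-negative interval")
    rng = np.random.default_rng(seed)
    freqs = np.sort(rng.uniform(lo, hi, size=n_modes))
    eps = rng.uniform(e_lo, e_hi, size=n_modes)
    return IRSpectrum(name=name, frequencies=freqs, epsilons=eps)


def write_ground_truth_manifest(
    path: str | Path,
    kinetics: KineticParams,
    first_passage: list[FirstPassageResult],
    orientation: dict[str, OrientationParams] | None = None,
) -> None:
    """Record the generator's true parameters and per-replicate crossing times."""
    manifest = {
        "drift_speed_A_per_ns": kinetics.drift_speed,
        "diffusion_A2_per_ns": kinetics.diffusion_coefficient,
        "start_height_A": kinetics.start_height,
        "analytic_mean_W_ns": None
        if not np.isfinite(kinetics.mean_first_passage)
        else kinetics.mean_first_passage,
        "replicates": [
            {"id": r.replicate_id, "W_ns": r.W, "censored": r.censored}
            for r in first_passage
        ],
        "orientation_targets": {
            name: {
                "target_angle_deg": op.target_angle,
                "second_target_deg": op.second_target,
                "concentration": op.concentration,
                "switching_rate_per_ns": op.switching_rate,
            }
            for name, op in (orientation or {}).items()
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
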