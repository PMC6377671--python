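"""Tilt-angle analysis of molecular vectors against the bilayer normal.

Three named axes of the solute (by convention the amino-sugar, the terminal
phenyl ring D, and the long axis of the tetracyclic ring A) are tracked as
head-minus-tail centroid vectors; their per-frame angle to the +z bilayer
normal is classified as Horizontal (within 10° of 0° or 180°), Perpendicular
(within 10° of 90°) or unclassified, and summarised into an H / P / H-P
preference label over the post-insertion window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "VectorDefinition",
    "OrientationSeries",
    "PreferenceLabel",
    "angle_to_normal",
    "angles_from_vectors",
    "classify_angle",
    "summarize_preference",
    "angle_histogram",
    "series_from_trajectory",
]

STANDARD_VECTORS = ("angle1-Daunosamine", "angle2-PhenylRingD", "angle3-TetracyclicRingA")


@dataclass(frozen=True)
class VectorDefinition:
    """A molecular axis defined by two disjoint atom-label sets.

    The vector runs from the centroid of ``tail_atoms`` to the centroid of
    ``head_atoms``.
    """

    name: str
    tail_atoms: frozenset[str]
    head_atoms: frozenset[str]

    def __post_init__(self) -> None:
        if not self.tail_atoms or not self.head_atoms:
            raise ValueError("atom selections must be non-empty")
        if self.tail_atoms & self.head_atoms:
            raise ValueError("tail and head selections must be disjoint")


@dataclass
class OrientationSeries:
    """Per-frame tilt angles of one vector, in degrees, with times in ns."""

    name: str
    times: np.ndarray
    angles: np.ndarray
    window_start: float = 0.0  # ns; typically the insertion time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise ValueError("times and angles must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must strictly increase")
        if len(self.angles) and (self.angles.min() < 0 or self.angles.max() > 180):
            raise ValueError("angles must lie in [0, 180] degrees")


@dataclass(frozen=True)
class PreferenceLabel:
    value: str  # 'H', 'P' or 'H/P'
    fraction_H: float
    fraction_P: float
    fraction_unclassified: float

    def __post_init__(self) -> None:
        total = self.fraction_H + self.fraction_P + self.fraction_unclassified
        if not abs(total - 1.0) <= 1e-9:
            raise ValueError("fractions must sum to 1")


def angle_to_normal(tail_centroid: np.ndarray, head_centroid: np.ndarray) -> float:
    """Angle in degrees between the head-tail vector and the +z axis, in [0, 180]."""
    v = np.asarray(head_centroid, dtype=float) - np.asarray(tail_centroid, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("zero-length vector: centroids coincide")
    return float(np.degrees(np.arccos(np.clip(v[2] / norm, -1.0, 1.0))))


def angles_from_vectors(vectors: np.ndarray) -> np.ndarray:
    """Vectorised tilt angles (degrees) of an (n, 3) array of direction vectors."""
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-length vector in series")
    return np.degrees(np.arccos(np.clip(vectors[:, 2] / norms, -1.0, 1.0)))


def classify_angle(
    theta: float | np.ndarray,
    h_halfwidth: float = 10.0,
    p_halfwidth: float = 10.0,
):
    """Classify tilt angle(s) as 'H', 'P' or 'U'.

    The Horizontal class takes θ within ``h_halfwidth`` of 0° or 180° and
    the Perpendicular class θ within ``p_halfwidth`` of 90°; anything else
    is unclassified ('U').  Half-widths must stay below 45° so the windows
    cannot overlap.
    """
    if not (0 < h_halfwidth < 45) or not (0 < p_halfwidth < 45):
        raise ValueError("halfwidths must lie in (0, 45) degrees")
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr < 0) or np.any(theta_arr > 180):
        raise ValueError("theta must lie in [0, 180] degrees")
    out = np.full(theta_arr.shape, "U", dtype="U1")
    out[(theta_arr <= h_halfwidth) | (theta_arr >= 180.0 - h_halfwidth)] = "H"
    out[np.abs(theta_arr - 90.0) <= p_halfwidth] = "P"
    if np.isscalar(theta) or theta_arr.ndim == 0:
        return str(out.item() if out.ndim == 0 else out[0])
    return out


def summarize_preference(
    series: OrientationSeries,
    from_insertion: bool = True,
    dominance_threshold: float = 0.7,
    h_halfwidth: float = 10.0,
    p_halfwidth: float = 10.0,
) -> PreferenceLabel:
    """Reduce an angle series to an H / P / H-P label.

    Only frames at or after the series' ``window_start`` (the insertion
    time) are used when ``from_insertion`` is set.  Among classified frames,
    the label is H when fraction_H/(fraction_H+fraction_P) >= threshold, P
    when <= 1 - threshold, and 'H/P' otherwise.  Fractions are reported
    relative to all analysed frames; unclassified absorbs the remainder.
    """
    mask = series.times >= series.window_start if from_insertion else np.ones(
        len(series.times), dtype=bool
    )
    angles = series.angles[mask]
    if len(angles) == 0:
        raise ValueError("no frames in the analysis window")
    classes = classify_angle(angles, h_halfwidth, p_halfwidth)
    n = len(classes)
    n_h = int(np.sum(classes == "H"))
    n_p = int(np.sum(classes == "P"))
    if n_h + n_p == 0:
        q = np.percentile(angles, [0, 25, 50, 75, 100])
        raise ValueError(
            "no frames fall in either angular window; angle distribution "
            f"quartiles: {np.array2string(q, precision=1)}"
        )
    ratio = n_h / (n_h + n_p)
    if ratio >= dominance_threshold:
        value = "H"
    elif ratio <= 1.0 - dominance_threshold:
        value = "P"
    else:
        value = "H/P"
    return PreferenceLabel(
        value=value,
        fraction_H=n_h / n,
        fraction_P=n_p / n,
        fraction_unclassified=(n - n_h - n_p) / n,
    )


def angle_histogram(series: OrientationSeries, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Histogram counts over [0, 180] with the given bin width.

    Bins are half-open [low, high) except the last, which is closed, so the
    counts conserve the total frame number.  ``bin_width`` must divide 180.
    """
    n_bins = 180.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width {bin_width} does not divide 180")
    edges = np.linspace(0.0, 180.0, int(round(n_bins)) + 1)
    counts, _ = np.histogram(series.angles, bins=edges)
    return counts, edges


def series_from_trajectory(
    traj: Trajectory, vector_name: str, window_start: float = 0.0
) -> OrientationSeries:
    """Angle series of one of the trajectory's stored orientation vectors."""
    if vector_name not in traj.orientations:
        raise KeyError(
            f"trajectory carries no vector {vector_name!r}; "
            f"available: {sorted(traj.orientations)}"
        )
    return OrientationSeries(
        name=vector_name,
        times=traj.times,
        angles=angles_from_vectors(traj.orientations[vector_name]),
        window_start=window_start,
    )
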