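"""Drug-lipid contact localisation over lipid component regions.

Lipid atoms are binned into the four chemical regions of a PC lipid
(choline head, phosphate, glycerol/ester, acyl tail); a contact is any
drug-heavy-atom / lipid-heavy-atom pair within a distance cutoff under
lateral (x, y) minimum-image periodicity.  Contact counts aggregate into
percentage-occurrence histograms, optionally compared between the full run
and an early control window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = [
    "ComponentMap",
    "ContactHistogram",
    "assign_components",
    "count_contacts",
    "contact_histogram",
    "windowed_comparison",
    "DEFAULT_BIN_ORDER",
]

DEFAULT_BIN_ORDER = ("choline head", "phosphate", "glycerol/ester", "tail")

#: Generator pseudo-atom roles -> display bins.
_DEFAULT_ROLE_MAP = {
    "CHOL": "choline head",
    "PO4": "phosphate",
    "GLY": "glycerol/ester",
    "TAIL": "tail",
}


@dataclass(frozen=True)
class ComponentMap:
    """Mapping from lipid atom labels to component bins."""

    lipid_name: str
    mapping: dict[str, str]
    bin_order: tuple[str, ...] = DEFAULT_BIN_ORDER

    def __post_init__(self) -> None:
        bins = set(self.mapping.values())
        if len(bins) < 2:
            raise ValueError("component map must define at least two bins")
        unknown = bins - set(self.bin_order)
        if unknown:
            raise ValueError(f"bins {sorted(unknown)} missing from bin_order")

    @classmethod
    def default(cls, lipid_name: str = "POPC") -> "ComponentMap":
        return cls(lipid_name=lipid_name, mapping=dict(_DEFAULT_ROLE_MAP))


@dataclass
class ContactHistogram:
    """Percentage-occurrence of contacts per component bin."""

    percentages: dict[str, float]
    raw_counts: dict[str, int]
    window: tuple[float, float]  # ns
    cutoff: float  # Å
    empty: bool = False

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.percentages.values()):
            raise ValueError("percentages must be non-negative")
        total = sum(self.percentages.values())
        if not self.empty and abs(total - 100.0) > 1e-6:
            raise ValueError(f"percentages sum to {total}, expected 100")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": list(self.percentages),
                "raw_count": [self.raw_counts[b] for b in self.percentages],
                "percentage": list(self.percentages.values()),
            }
        )


def assign_components(
    lipid_atom_labels: np.ndarray | list[str],
    component_map: ComponentMap,
    strict: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Per-atom bin labels; returns (bins, unmapped_labels).

    Strict mode errors on any unmapped label; permissive mode marks them
    with an empty string and reports them.
    """
    labels = np.asarray(lipid_atom_labels, dtype="U16")
    bins = np.empty(len(labels), dtype="U32")
    unmapped: list[str] = []
    for i, lab in enumerate(labels):
        bin_ = component_map.mapping.get(lab)
        if bin_ is None:
            unmapped.append(str(lab))
            bins[i] = ""
        else:
            bins[i] = bin_
    if strict and unmapped:
        raise ValueError(f"unmapped lipid atom labels: {sorted(set(unmapped))}")
    return bins, unmapped


def _min_image_distances(
    drug: np.ndarray, lipid: np.ndarray, box_xy: np.ndarray
) -> np.ndarray:
    """Pairwise distances with minimum-image convention in x and y only."""
    delta = drug[:, None, :] - lipid[None, :, :]
    for k in (0, 1):
        delta[:, :, k] -= box_xy[k] * np.round(delta[:, :, k] / box_xy[k])
    return np.sqrt((delta**2).sum(axis=2))


def count_contacts(
    traj: Trajectory,
    cutoff: float = 4.0,
    window: tuple[float, float] | None = None,
    component_map: ComponentMap | None = None,
) -> pd.DataFrame:
    """Per-frame, per-bin contact counts.

    A contact is a (drug atom, lipid atom) pair at minimum-image distance
    <= ``cutoff`` Å; periodicity is applied laterally (x, y) only, since the
    bilayer normal is the analysis axis.  Returns a DataFrame indexed by
    frame time with one column per component bin.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    component_map = component_map or ComponentMap.default()
    lo, hi = window if window is not None else (traj.times[0], traj.times[-1])
    if lo < traj.times[0] - 1e-9 or hi > traj.times[-1] + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}] ns outside trajectory span "
            f"[{traj.times[0]}, {traj.times[-1]}] ns"
        )
    frame_mask = (traj.times >= lo - 1e-12) & (traj.times <= hi + 1e-12)
    bins, _ = assign_components(traj.lipid_roles, component_map)
    order = [b for b in component_map.bin_order if b in set(bins)] or list(
        component_map.bin_order
    )
    box_xy = traj.box[:2]
    rows = []
    idx = np.flatnonzero(frame_mask)
    for i in idx:
        if traj.n_lipid_atoms == 0 or traj.n_drug_atoms == 0:
            rows.append({b: 0 for b in order})
            continue
        dist = _min_image_distances(traj.drug_coords[i], traj.lipid_coords[i], box_xy)
        in_contact = dist <= cutoff
        per_lipid_atom = in_contact.sum(axis=0)
        rows.append({b: int(per_lipid_atom[bins == b].sum()) for b in order})
    return pd.DataFrame(rows, index=traj.times[idx])


def contact_histogram(counts: pd.DataFrame, cutoff: float = 4.0) -> ContactHistogram:
    """Aggregate per-frame counts into percentage occurrence per bin.

    Percentages are contact-count weighted: 100 * bin total / grand total.
    A zero-contact input yields all-zero percentages with ``empty`` set.
    """
    if len(counts) == 0:
        raise ValueError("need at least one frame of counts")
    totals = counts.sum(axis=0)
    grand = totals.sum()
    empty = grand == 0
    pct = {
        b: (0.0 if empty else 100.0 * totals[b] / grand) for b in counts.columns
    }
    return ContactHistogram(
        percentages=pct,
        raw_counts={b: int(totals[b]) for b in counts.columns},
        window=(float(counts.index[0]), float(counts.index[-1])),
        cutoff=cutoff,
        empty=bool(empty),
    )


def windowed_comparison(
    traj: Trajectory,
    cutoff: float = 4.0,
    full_window: tuple[float, float] | None = None,
    early_window: tuple[float, float] | None = None,
    component_map: ComponentMap | None = None,
) -> tuple[ContactHistogram, ContactHistogram, dict[str, float]]:
    """Full-run vs early-control contact histograms and per-bin |Δ%|.

    The early window defaults to the first 60 ns (clipped to the trajectory
    span), the control used to check that localisation preferences are not
    an artefact of slow insertion.
    """
    if full_window is None:
        full_window = (float(traj.times[0]), float(traj.times[-1]))
    if early_window is None:
        early_window = (full_window[0], min(full_window[0] + 60.0, full_window[1]))
    if early_window[0] < full_window[0] or early_window[1] > full_window[1]:
        raise ValueError("early_window must lie within full_window")
    full_counts = count_contacts(traj, cutoff, full_window, component_map)
    early_counts = count_contacts(traj, cutoff, early_window, component_map)
    full_hist = contact_histogram(full_counts, cutoff)
    early_hist = contact_histogram(early_counts, cutoff)
    diffs = {
        b: abs(full_hist.percentages[b] - early_hist.percentages[b])
        for b in full_hist.percentages
    }
    return full_hist, early_hist, diffs
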