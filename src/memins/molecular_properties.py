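"""Structure- and spectrum-level molecular metrics.

Point-charge dipole moments, intramolecular H-bond distances, counting of
significant low-frequency IR modes (a proxy for molecular rigidity), integer
absorbance ratios, and the rank correlation between rigidity and membrane
insertion order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, kendalltau

__all__ = [
    "MoleculeStructure",
    "IRSpectrum",
    "RigidityReport",
    "read_structure",
    "write_structure",
    "dipole_moment",
    "hbond_distance",
    "count_significant_modes",
    "absorbance_ratios",
    "rigidity_correlation",
    "DEBYE_PER_E_ANGSTROM",
]

#: 1 e·Å in Debye.
DEBYE_PER_E_ANGSTROM = 4.80321

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "K": 39.098, "NA": 22.990,
}


@dataclass
class MoleculeStructure:
    """Atomic structure with optional partial charges (units: Å, e)."""

    name: str
    atom_labels: list[str]
    elements: list[str]
    coords: np.ndarray  # (n, 3) Å
    charges: np.ndarray | None = None  # (n,) e

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if len(self.atom_labels) != len(set(self.atom_labels)):
            dupes = sorted({a for a in self.atom_labels if self.atom_labels.count(a) > 1})
            raise ValueError(f"duplicate atom labels: {dupes}")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            total = self.charges.sum()
            if abs(total - round(total)) > 1e-3:
                raise ValueError(
                    f"total charge {total:.5f} e is not within 1e-3 of an integer"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def atom_index(self, label: str) -> int:
        try:
            return self.atom_labels.index(label)
        except ValueError:
            raise KeyError(f"no atom labelled {label!r} in {self.name}") from None


@dataclass
class IRSpectrum:
    """Vibrational mode table: frequencies (cm⁻¹) and absorbances ε (M⁻¹ cm⁻¹)."""

    name: str
    frequencies: np.ndarray
    epsilons: np.ndarray
    has_imaginary: bool = False

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.epsilons = np.asarray(self.epsilons, dtype=float)
        if self.frequencies.shape != self.epsilons.shape:
            raise ValueError("frequencies and epsilons must have equal length")
        if len(self.frequencies) and np.any(np.diff(self.frequencies) < 0):
            raise ValueError("frequencies must be sorted ascending")
        if np.any(self.frequencies < 0) or np.any(self.epsilons < 0):
            raise ValueError("frequencies and epsilons must be non-negative")

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "IRSpectrum":
        df = pd.read_csv(path)
        freq_col = next(c for c in df.columns if c.lower().startswith("freq"))
        eps_col = next(c for c in df.columns if c.lower().startswith("eps"))
        df = df.sort_values(freq_col)
        return cls(
            name=name or Path(path).stem,
            frequencies=df[freq_col].to_numpy(),
            epsilons=df[eps_col].to_numpy(),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"frequency_cm-1": self.frequencies, "epsilon_M-1cm-1": self.epsilons}
        ).to_csv(path, index=False)


@dataclass
class RigidityReport:
    mode_counts: dict[str, int]
    insertion_order: list[str]  # fastest inserter first
    correlation: float
    method: str = "spearman"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.correlation <= 1.0 + 1e-12:
            raise ValueError("correlation must lie in [-1, 1]")


def _infer_element(atom_name: str) -> str:
    """Element from a PDB atom-name field (leading letters, digits stripped)."""
    stripped = atom_name.strip().lstrip("0123456789")
    letters = "".join(ch for ch in stripped if ch.isalpha())
    if not letters:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = letters[:2].upper()
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return two.capitalize()
    return letters[0].upper()


def read_structure(
    pdb_file: str | Path,
    charges_csv: str | Path | None = None,
    name: str | None = None,
) -> MoleculeStructure:
    """Read a single-model PDB into a :class:`MoleculeStructure`.

    Elements come from PDB columns 77-78 when present, otherwise they are
    inferred from the atom-name field.  Partial charges can be joined from a
    sidecar CSV with columns ``atom_label, charge_e``.
    """
    import biotite.structure.io.pdb as pdb_io

    path = Path(pdb_file)
    try:
        pdbf = pdb_io.PDBFile.read(str(path))
        atoms = pdbf.get_structure(model=1)
    except Exception as exc:
        # locate the first offending coordinate record for the error message
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if line[:6] in ("ATOM  ", "HETATM"):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: unparseable record") from exc
        raise
    labels = list(atoms.atom_name)
    # trust only explicit element columns (77-78); infer from the atom-name
    # field otherwise instead of accepting a reader's guess
    raw_elements = [
        line[76:78].strip()
        for line in path.read_text().splitlines()
        if line[:6] in ("ATOM  ", "HETATM")
    ][: len(labels)]
    elements = [
        el.capitalize() if el else _infer_element(nm)
        for el, nm in zip(raw_elements, atoms.atom_name)
    ]
    charges = None
    if charges_csv is not None:
        table = pd.read_csv(charges_csv).set_index("atom_label")["charge_e"]
        missing = [lab for lab in labels if lab not in table.index]
        if missing:
            raise ValueError(f"charge table missing atoms: {missing}")
        charges = table.reindex(labels).to_numpy(dtype=float)
    return MoleculeStructure(
        name=name or path.stem,
        atom_labels=labels,
        elements=elements,
        coords=atoms.coord,
        charges=charges,
    )


def write_structure(structure: MoleculeStructure, pdb_file: str | Path) -> None:
    """Write a structure as PDB (coordinates at the format's 1e-3 Å precision)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb_io

    atoms = struc.AtomArray(structure.n_atoms)
    atoms.coord = structure.coords
    atoms.atom_name = np.array(structure.atom_labels)
    atoms.element = np.array([el.upper() for el in structure.elements])
    atoms.res_name = np.full(structure.n_atoms, "LIG")
    atoms.res_id = np.ones(structure.n_atoms, dtype=int)
    atoms.hetero = np.ones(structure.n_atoms, dtype=bool)
    pdbf = pdb_io.PDBFile()
    pdbf.set_structure(atoms)
    pdbf.write(str(pdb_file))


def dipole_moment(structure: MoleculeStructure) -> tuple[float, np.ndarray | None]:
    """Point-charge dipole μ = Σ qᵢ rᵢ, returned as (magnitude in Debye, unit direction).

    For a net-charged molecule the dipole is origin-dependent; the origin is
    placed at the center of nominal mass and a warning is emitted.  A zero
    dipole returns direction ``None``.
    """
    if structure.charges is None:
        raise ValueError(f"structure {structure.name!r} carries no partial charges")
    q = structure.charges
    r = structure.coords
    net = q.sum()
    if abs(net) > 1e-3:
        masses = np.array([_MASSES.get(el.upper(), 12.0) for el in structure.elements])
        com = (masses[:, None] * r).sum(axis=0) / masses.sum()
        r = r - com
        warnings.warn(
            f"net charge {net:+.3f} e: dipole is origin-dependent; "
            "using the center of nominal mass as origin",
            stacklevel=2,
        )
    mu = (q[:, None] * r).sum(axis=0) * DEBYE_PER_E_ANGSTROM
    mag = float(np.linalg.norm(mu))
    if mag == 0.0:
        return 0.0, None
    return mag, mu / mag


def hbond_distance(
    structure: MoleculeStructure, donor_h_label: str, acceptor_label: str
) -> float:
    """Euclidean distance (Å) between a named hydrogen and acceptor heavy atom."""
    i = structure.atom_index(donor_h_label)
    j = structure.atom_index(acceptor_label)
    return float(np.linalg.norm(structure.coords[i] - structure.coords[j]))


def count_significant_modes(
    spectrum: IRSpectrum,
    eps_threshold: float = 200.0,
    window: tuple[float, float] = (0.0, 600.0),
) -> int:
    """Modes with ε strictly above threshold inside the closed frequency window."""
    lo, hi = window
    if eps_threshold < 0 or lo > hi:
        raise ValueError("threshold must be >= 0 and window must be ordered")
    if spectrum.has_imaginary:
        raise ValueError(
            f"{spectrum.name}: spectrum carries imaginary frequencies; "
            "not a valid minimum"
        )
    in_window = (spectrum.frequencies >= lo) & (spectrum.frequencies <= hi)
    return int(np.sum(in_window & (spectrum.epsilons > eps_threshold)))


def absorbance_ratios(epsilons: np.ndarray | list[float], max_scale: int = 12) -> list[int]:
    """Express absorbances as small integer ratios.

    Values are divided by their minimum, then multiplied by the smallest
    integer scale k in [1, max_scale] minimising the total distance to
    integers, and rounded.
    """
    eps = np.asarray(epsilons, dtype=float)
    if eps.size == 0:
        raise ValueError("empty absorbance list")
    if np.any(eps <= 0):
        raise ValueError("all absorbances must be positive")
    rel = eps / eps.min()
    best_k, best_err = 1, np.inf
    for k in range(1, max_scale + 1):
        scaled = rel * k
        err = np.abs(scaled - np.round(scaled)).sum()
        if err < best_err - 1e-12:
            best_k, best_err = k, err
    return [int(v) for v in np.round(rel * best_k)]


def rigidity_correlation(
    mode_counts: dict[str, int],
    insertion_order: list[str],
    method: str = "spearman",
) -> RigidityReport:
    """Rank correlation between rigidity (significant-mode count) and insertion slowness.

    ``insertion_order`` lists molecules from fastest to slowest inserter;
    +1 means the most rigid (fewest low-frequency modes) molecule inserts
    fastest and the ordering is perfectly concordant.
    """
    if set(mode_counts) != set(insertion_order):
        raise ValueError(
            f"molecule sets differ: counts={sorted(mode_counts)} vs "
            f"order={sorted(insertion_order)}"
        )
    if len(insertion_order) < 3:
        raise ValueError("need at least 3 molecules for a rank correlation")
    slowness = np.arange(1, len(insertion_order) + 1)
    counts = np.array([mode_counts[m] for m in insertion_order], dtype=float)
    if method == "spearman":
        rho = spearmanr(counts, slowness).statistic
    elif method == "kendall":
        rho = kendalltau(counts, slowness).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return RigidityReport(
        mode_counts=dict(mode_counts),
        insertion_order=list(insertion_order),
        correlation=float(rho),
        method=method,
    )
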