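"""Geometric model of a symmetric phosphatidylcholine bilayer.

The model carries only what the trajectory analyses need: the lateral area
``A`` available to an approaching solute, the water-slab thickness ``L_z``
it diffuses through, the mean phosphate planes that define the membrane
surface, and per-component Gaussian z-profiles used to place lipid
pseudo-atoms.  The bilayer center sits at z = 0; the upper leaflet occupies
z > 0.
"""

from __future__ import annotations

import math

import numpy as np
from dataclasses import dataclass, field

__all__ = [
    "ComponentProfile",
    "BilayerModel",
    "build_bilayer_model",
    "LIPID_LIBRARY",
]

#: Volume of one liquid water molecule, Å³ (standard 0.030 nm³ value); used to
#: convert a hydration level in waters/lipid into a water-slab thickness.
WATER_VOLUME_A3 = 30.0


@dataclass(frozen=True)
class ComponentProfile:
    """Gaussian z-distribution of one lipid component in the upper leaflet.

    The lower leaflet uses the mirror image (mean -> -mean).
    """

    mean: float  # Å, upper leaflet
    sd: float  # Å


@dataclass(frozen=True)
class BilayerModel:
    lipid_name: str
    n_lipids: int
    n_per_leaflet: int
    area_per_lipid: float  # Å²
    box_x: float  # Å
    box_y: float  # Å
    box_z: float  # Å
    phosphate_plane_upper: float  # Å, z of the mean upper phosphate plane
    phosphate_plane_lower: float  # Å
    component_profiles: dict[str, ComponentProfile]
    waters_per_lipid: float
    salt_molarity: float = 0.1
    ion_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        area = self.box_x * self.box_y
        expected = self.n_per_leaflet * self.area_per_lipid
        if not math.isclose(area, expected, rel_tol=1e-6):
            raise ValueError(
                f"box_x*box_y = {area:g} inconsistent with "
                f"n_per_leaflet*area_per_lipid = {expected:g}"
            )
        if not math.isclose(
            self.phosphate_plane_upper, -self.phosphate_plane_lower, rel_tol=1e-9
        ):
            raise ValueError("bilayer must be symmetric about z = 0")
        for name, prof in self.component_profiles.items():
            if not 0.0 <= prof.mean < self.box_z / 2:
                raise ValueError(
                    f"component {name!r} mean {prof.mean} outside [0, box_z/2)"
                )

    @property
    def lateral_area(self) -> float:
        """Lateral membrane area A in Å² (box_x * box_y)."""
        return self.box_x * self.box_y

    @property
    def thickness(self) -> float:
        """Phosphate-to-phosphate bilayer thickness, Å."""
        return self.phosphate_plane_upper - self.phosphate_plane_lower

    @property
    def water_slab_thickness(self) -> float:
        """One-sided water-slab thickness L_z, Å.

        Defined as the water layer on the solute's side of the membrane:
        (box_z - thickness) / 2.
        """
        return (self.box_z - self.thickness) / 2.0

    @property
    def water_slab_total(self) -> float:
        """Total water thickness (both sides), Å."""
        return self.box_z - self.thickness


def _default_profiles(thickness: float, box_z: float) -> dict[str, ComponentProfile]:
    """Canonical pseudo-atom z-profiles for a PC lipid of given thickness.

    Choline sits just above the phosphate plane, the glycerol/ester backbone
    just below it, and the acyl-tail density is centered midway between the
    backbone and the bilayer center with a broader spread.  Means are kept
    strictly inside the half-box (relevant only for unhydrated boxes).
    """
    half = thickness / 2.0
    cap = np.nextafter(box_z / 2, 0.0)
    return {
        "CHOL": ComponentProfile(mean=min(half + 1.0, cap), sd=2.0),
        "PO4": ComponentProfile(mean=min(half, cap), sd=2.0),
        "GLY": ComponentProfile(mean=half - 3.5, sd=2.0),
        "TAIL": ComponentProfile(mean=half / 2.0, sd=4.0),
    }


#: Built-in lipid geometries: area per lipid (Å²), phosphate-to-phosphate
#: thickness (Å), hydration (waters/lipid), and KCl ion-pair counts kept as
#: plain metadata.
LIPID_LIBRARY: dict[str, dict] = {
    "POPC": {
        "area_per_lipid": 65.0,
        "thickness": 37.0,
        "waters_per_lipid": 31.0,
        "ion_counts": {"K+": 9, "Cl-": 9},
    },
    "DMPC": {
        "area_per_lipid": 60.0,
        "thickness": 35.0,
        "waters_per_lipid": 26.6,
        "ion_counts": {"K+": 7, "Cl-": 7},
    },
}


def build_bilayer_model(
    lipid_name: str,
    area_per_lipid: float | None = None,
    thickness: float | None = None,
    waters_per_lipid: float | None = None,
    n_lipids: int = 128,
    salt_molarity: float = 0.1,
    component_profiles: dict[str, ComponentProfile] | None = None,
) -> BilayerModel:
    """Construct a :class:`BilayerModel` for a named lipid.

    Parameters default to the built-in POPC/DMPC geometries; any of them may
    be overridden.  The water slab on each side is derived from the hydration
    level via the per-water volume (``waters_per_lipid * n_lipids * 30 Å³``
    spread over the lateral area, split evenly between the two sides), so
    ``box_z = thickness + water_slab_total``.

    Raises
    ------
    KeyError
        If ``lipid_name`` is not in the library and no explicit
        ``component_profiles`` are supplied.
    """
    defaults = LIPID_LIBRARY.get(lipid_name.upper())
    if defaults is None and component_profiles is None:
        raise KeyError(
            f"unknown lipid {lipid_name!r}: no component z-profile map available; "
            f"known lipids: {sorted(LIPID_LIBRARY)} (or pass component_profiles)"
        )
    defaults = defaults or {}
    area_per_lipid = area_per_lipid if area_per_lipid is not None else defaults.get("area_per_lipid")
    thickness = thickness if thickness is not None else defaults.get("thickness")
    waters_per_lipid = (
        waters_per_lipid if waters_per_lipid is not None else defaults.get("waters_per_lipid", 0.0)
    )
    if area_per_lipid is None or thickness is None:
        raise ValueError("area_per_lipid and thickness are required for custom lipids")
    if area_per_lipid <= 0 or thickness <= 0:
        raise ValueError("area_per_lipid and thickness must be positive")
    if waters_per_lipid < 0:
        raise ValueError("waters_per_lipid must be non-negative")

    n_per_leaflet = n_lipids // 2
    if 2 * n_per_leaflet != n_lipids:
        raise ValueError("n_lipids must be even for a symmetric bilayer")
    lateral_area = n_per_leaflet * area_per_lipid
    box_x = box_y = math.sqrt(lateral_area)
    water_total = waters_per_lipid * n_lipids * WATER_VOLUME_A3 / lateral_area
    box_z = thickness + water_total

    return BilayerModel(
        lipid_name=lipid_name.upper(),
        n_lipids=n_lipids,
        n_per_leaflet=n_per_leaflet,
        area_per_lipid=area_per_lipid,
        box_x=box_x,
        box_y=box_y,
        box_z=box_z,
        phosphate_plane_upper=thickness / 2.0,
        phosphate_plane_lower=-thickness / 2.0,
        component_profiles=component_profiles or _default_profiles(thickness, box_z),
        waters_per_lipid=waters_per_lipid,
        salt_molarity=salt_molarity,
        ion_counts=dict(defaults.get("ion_counts", {})),
    )
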