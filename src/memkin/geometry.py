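"""Deterministic lattice-geometry and local-ion-concentration calculators.

The annexin-V (A5) 2D-lattice on a phosphatidylserine-rich membrane is a
p6 honeycomb with unit cell a = b = 17.7 nm, gamma = 60 deg, housing three
trimers (nine monomers).  Because each membrane-facing monomer chelates a
handful of Ca2+ ions within ~1 nm of the bilayer surface, the lattice pins
a very high local Ca2+ concentration above the membrane; these helpers turn
the crystallographic counts into molar concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Litres per cubic nanometre.
_L_PER_NM3 = 1e-24


@dataclass(frozen=True)
class LatticeGeometry:
    """Unit-cell geometry of the A5 2D-lattice.

    Parameters
    ----------
    a, b : float
        Lattice vectors in nm.
    gamma : float
        Angle between them in degrees, in (0, 180).
    trimers_per_cell : int
        Number of A5 trimers per unit cell (two p6 trimers plus one
        non-p6 trimer in the honeycomb lattice).
    monomers_per_trimer : int
    """

    a: float = 17.7
    b: float = 17.7
    gamma: float = 60.0
    trimers_per_cell: int = 3
    monomers_per_trimer: int = 3

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("lattice vectors must be positive")
        if not 0.0 < self.gamma < 180.0:
            raise ValueError("gamma must lie strictly between 0 and 180 degrees")

    @property
    def monomers_per_cell(self) -> int:
        return self.trimers_per_cell * self.monomers_per_trimer

    @property
    def area_nm2(self) -> float:
        return unit_cell_area(self.a, self.b, self.gamma)


@dataclass(frozen=True)
class CaEstimate:
    """Local Ca2+ concentration implied by a per-monomer ion count."""

    ca_per_monomer: float
    slab_thickness_nm: float
    concentration_mM: float


def unit_cell_area(a: float, b: float, gamma: float) -> float:
    """Area of a (a, b, gamma) unit cell in nm^2: a * b * sin(gamma)."""
    if a <= 0 or b <= 0:
        raise ValueError("lattice vectors must be positive")
    if not 0.0 < gamma < 180.0:
        raise ValueError("gamma must lie strictly between 0 and 180 degrees")
    return a * b * math.sin(math.radians(gamma))


def half_unit_cell_step(a: float) -> float:
    """Half the lattice constant: the radial step of one trimer event, nm."""
    if a <= 0:
        raise ValueError("lattice constant must be positive")
    return a / 2.0


def local_ca_concentration(
    ca_per_monomer: float,
    monomers_per_cell: int = 9,
    cell_area_nm2: float | None = None,
    slab_thickness_nm: float = 1.0,
) -> CaEstimate:
    """Local Ca2+ concentration in a thin slab above the bilayer, in mM.

    The ions carried by the monomers of one unit cell are confined to a
    volume of ``cell_area * slab_thickness``:

        c = n_ions / (N_A * V)

    Parameters
    ----------
    ca_per_monomer : float
        Ca2+ ions bound per A5 monomer on its membrane-facing side
        (crystal structures report 2 to 11).
    monomers_per_cell : int
        Monomers per unit cell (three trimers = 9).
    cell_area_nm2 : float, optional
        Unit-cell area; defaults to the A5 lattice cell (17.7, 17.7, 60 deg).
    slab_thickness_nm : float
        Thickness of the interfacial slab the ions occupy, nm.
    """
    if ca_per_monomer < 0:
        raise ValueError("ca_per_monomer must be non-negative")
    if monomers_per_cell <= 0 or slab_thickness_nm <= 0:
        raise ValueError("monomers_per_cell and slab_thickness_nm must be positive")
    if cell_area_nm2 is None:
        cell_area_nm2 = LatticeGeometry().area_nm2
    if cell_area_nm2 <= 0:
        raise ValueError("cell area must be positive (zero volume)")
    n_ions = ca_per_monomer * monomers_per_cell
    volume_l = cell_area_nm2 * slab_thickness_nm * _L_PER_NM3
    molar = n_ions / (N_AVOGADRO * volume_l)
    return CaEstimate(
        ca_per_monomer=ca_per_monomer,
        slab_thickness_nm=slab_thickness_nm,
        concentration_mM=molar * 1e3,
    )


def ca_per_monomer_stats(counts: list[int]) -> dict[str, float]:
    """Min / max / mean of per-structure Ca2+ counts supplied by the user."""
    if not counts:
        raise ValueError("counts must be a non-empty list")
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    return {
        "min": float(min(counts)),
        "max": float(max(counts)),
        "mean": float(sum(counts)) / len(counts),
    }
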