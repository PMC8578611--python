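"""Parametric geometry of spike-shaped 3D microelectrodes.

An electrode is a vertical gold cylinder (a bonded wire of diameter
``core_diameter_um``) standing on a flat pad, insulated by an SU-8 jacket
modelled in two parts: a conical base of fixed height and base diameter
whose outer radius tapers linearly down to the sleeve radius, and an
annular sleeve of constant thickness extending partway up the shaft.  The
bare shaft above the sleeve plus the end cap form the electrochemically
active (exposed) surface.

Lengths at this interface are in micrometres; areas and section properties
are returned in SI units (m**2, N*m**2).  The conical base is always
insulating, so the exposed length never includes the cone region, and the
pad is electrically and mechanically inert (it is bonded flat to the
substrate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "ElectrodeGeometry",
    "DesignGrid",
    "MaterialSet",
    "exposed_area",
    "geometric_area",
    "section_profile",
    "flexural_rigidity",
]

logger = logging.getLogger(__name__)

UM = 1e-6  # metres per micrometre


class GeometryError(ValueError):
    """A geometry violates the electrode construction constraints."""


@dataclass(frozen=True)
class ElectrodeGeometry:
    """One 3D electrode design point (lengths in micrometres).

    ``cone_height_um`` and ``sleeve_thickness_um`` may be zero, which
    collapses the insulation to nothing — the bare-column limit used for
    closed-form validation.
    """

    core_diameter_um: float
    total_height_um: float = 300.0
    cone_height_um: float = 50.0
    cone_base_diameter_um: float = 100.0
    sleeve_thickness_um: float = 5.0
    sleeve_height_um: float = 0.0
    pad_diameter_um: float = 200.0

    def __post_init__(self) -> None:
        if self.core_diameter_um <= 0:
            raise GeometryError("core_diameter_um must be > 0")
        if self.total_height_um <= 0:
            raise GeometryError("total_height_um must be > 0")
        if self.pad_diameter_um <= 0:
            raise GeometryError("pad_diameter_um must be > 0")
        if self.cone_height_um < 0 or self.sleeve_thickness_um < 0:
            raise GeometryError("cone_height_um and sleeve_thickness_um must be >= 0")
        if self.sleeve_height_um < 0:
            raise GeometryError("sleeve_height_um must be >= 0")
        if self.cone_height_um + self.sleeve_height_um > self.total_height_um + 1e-9:
            raise GeometryError(
                "cone_height_um + sleeve_height_um exceeds total_height_um"
            )
        if self.cone_height_um > 0 and (
            self.cone_base_diameter_um
            < self.core_diameter_um + 2.0 * self.sleeve_thickness_um - 1e-9
        ):
            raise GeometryError(
                "cone_base_diameter_um must be >= core_diameter_um + 2*sleeve_thickness_um"
            )

    @property
    def exposed_length_um(self) -> float:
        """Bare shaft length above the insulation (µm)."""
        return self.total_height_um - self.cone_height_um - self.sleeve_height_um

    @property
    def core_radius_um(self) -> float:
        return 0.5 * self.core_diameter_um


@dataclass(frozen=True)
class MaterialSet:
    """Physical constants of the electrode, coating and bath.

    Defaults are literature-typical values for gold and SU-8 in 0.9% NaCl
    at room temperature: saline conductivity 1.6 S/m; Young's moduli
    79 GPa (Au) and 4 GPa (SU-8); gold/electrolyte interface modelled as a
    constant-phase element Z_s = 1/(Q (j 2 pi f)**alpha) with
    Q = 0.40 S*s^alpha/m**2 (40 uS*s^alpha/cm**2) and alpha = 0.9.
    """

    sigma_saline: float = 1.6        # S/m
    E_gold: float = 79e9             # Pa
    E_su8: float = 4.0e9             # Pa
    cpe_Q: float = 0.40              # S*s^alpha per m**2
    cpe_alpha: float = 0.9           # dimensionless, in (0, 1]
    poisson_gold: float = 0.44
    poisson_su8: float = 0.22

    def __post_init__(self) -> None:
        for name in ("sigma_saline", "E_gold", "E_su8", "cpe_Q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.cpe_alpha <= 1.0:
            raise ValueError("cpe_alpha must be in (0, 1]")


@dataclass(frozen=True)
class DesignGrid:
    """Cartesian design grid over diameter, sleeve thickness and height.

    Iteration is lexicographic in (core diameter, sleeve thickness, sleeve
    height) in the order the axis lists are given.  Combinations violating
    the electrode invariants are skipped with a log message rather than
    raising, so one bad corner does not abort a sweep.
    """

    core_diameters_um: tuple[float, ...]
    sleeve_thicknesses_um: tuple[float, ...]
    sleeve_heights_um: tuple[float, ...]
    fixed: ElectrodeGeometry = field(
        default_factory=lambda: ElectrodeGeometry(core_diameter_um=25.0)
    )

    def __post_init__(self) -> None:
        for name in ("core_diameters_um", "sleeve_thicknesses_um", "sleeve_heights_um"):
            values = tuple(float(v) for v in getattr(self, name))
            if len(values) == 0:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, values)

    def __iter__(self) -> Iterator[ElectrodeGeometry]:
        for d in self.core_diameters_um:
            for t in self.sleeve_thicknesses_um:
                for h in self.sleeve_heights_um:
                    try:
                        yield replace(
                            self.fixed,
                            core_diameter_um=d,
                            sleeve_thickness_um=t,
                            sleeve_height_um=h,
                        )
                    except GeometryError as exc:
                        logger.warning(
                            "skipping design point d=%g t=%g h=%g: %s", d, t, h, exc
                        )

    def __len__(self) -> int:
        return sum(1 for _ in self)


def default_design_grid(fixed: ElectrodeGeometry | None = None) -> DesignGrid:
    """The published design grid: d in {10,17,25,50} µm, t in {2.5,5,10} µm,
    sleeve heights 0–250 µm in 50 µm steps, on a 300 µm tall electrode."""
    return DesignGrid(
        core_diameters_um=(10.0, 17.0, 25.0, 50.0),
        sleeve_thicknesses_um=(2.5, 5.0, 10.0),
        sleeve_heights_um=(0.0, 50.0, 100.0, 150.0, 200.0, 250.0),
        fixed=fixed or ElectrodeGeometry(core_diameter_um=25.0),
    )


def exposed_area(geom: ElectrodeGeometry) -> float:
    """Electrochemical surface area (ESA) in m**2.

    Lateral area of the bare shaft above the insulation plus the end cap:
    pi*d*l_exp + pi*d**2/4.  Strictly decreasing in sleeve height; the end
    cap keeps it positive even when the shaft is fully sleeved.
    """
    d = geom.core_diameter_um * UM
    l_exp = geom.exposed_length_um * UM
    return np.pi * d * l_exp + np.pi * d * d / 4.0


def geometric_area(geom: ElectrodeGeometry) -> float:
    """Geometric area (GA) in m**2: full gold lateral surface plus end cap,
    ignoring the insulation."""
    d = geom.core_diameter_um * UM
    h = geom.total_height_um * UM
    return np.pi * d * h + np.pi * d * d / 4.0


def _outer_radius_um(geom: ElectrodeGeometry, z_um: np.ndarray) -> np.ndarray:
    """Outer radius of the electrode+insulation assembly at height z (µm)."""
    z = np.asarray(z_um, dtype=float)
    r_core = geom.core_radius_um
    r_sleeve = r_core + geom.sleeve_thickness_um
    r = np.full_like(z, r_core)
    in_sleeve = z < geom.cone_height_um + geom.sleeve_height_um
    r[in_sleeve] = r_sleeve
    if geom.cone_height_um > 0:
        in_cone = z < geom.cone_height_um
        frac = z[in_cone] / geom.cone_height_um
        r_base = 0.5 * geom.cone_base_diameter_um
        r[in_cone] = r_base + frac * (r_sleeve - r_base)
    return r


def flexural_rigidity(
    geom: ElectrodeGeometry, mats: MaterialSet, z_um: np.ndarray
) -> np.ndarray:
    """Composite flexural rigidity EI (N*m**2) about the column axis at
    height z.  Gold core and concentric SU-8 annulus are perfectly bonded,
    so rigidities add: EI = E_Au*I_core + E_SU8*I_annulus."""
    z = np.atleast_1d(np.asarray(z_um, dtype=float))
    r_core = geom.core_radius_um * UM
    r_outer = _outer_radius_um(geom, z) * UM
    i_core = np.pi * r_core**4 / 4.0
    i_annulus = np.pi * (r_outer**4 - r_core**4) / 4.0
    return mats.E_gold * i_core + mats.E_su8 * np.maximum(i_annulus, 0.0)


def section_profile(
    geom: ElectrodeGeometry, mats: MaterialSet, n_segments: int
) -> list[tuple[float, float]]:
    """Discretise the column into ``n_segments`` (length m, EI N*m**2) pieces.

    Each of the three regions (tapered cone, constant sleeve annulus, bare
    shaft) that has nonzero extent receives at least one segment; the rest
    are allocated proportionally to region length.  EI is evaluated at each
    segment midpoint, and segment lengths sum exactly to the total height.
    """
    if n_segments < 3:
        raise ValueError("n_segments must be >= 3 to resolve the section regions")
    regions = [
        (0.0, geom.cone_height_um),
        (geom.cone_height_um, geom.cone_height_um + geom.sleeve_height_um),
        (geom.cone_height_um + geom.sleeve_height_um, geom.total_height_um),
    ]
    regions = [(a, b) for a, b in regions if b - a > 1e-12]
    total = geom.total_height_um
    # at least one segment per nonempty region, remainder by length
    counts = [1] * len(regions)
    remaining = n_segments - len(regions)
    if remaining < 0:
        raise ValueError("n_segments too small to resolve the section regions")
    lengths = [b - a for a, b in regions]
    extra = [int(round(remaining * l / total)) for l in lengths]
    while sum(extra) > remaining:
        extra[int(np.argmax(extra))] -= 1
    while sum(extra) < remaining:
        extra[int(np.argmax(lengths))] += 1
    segments: list[tuple[float, float]] = []
    for (a, b), base, add in zip(regions, counts, extra):
        n = base + add
        edges = np.linspace(a, b, n + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        eis = flexural_rigidity(geom, mats, mids)
        for i in range(n):
            segments.append(((edges[i + 1] - edges[i]) * UM, float(eis[i])))
    return segments
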