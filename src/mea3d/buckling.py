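"""Linear buckling of the composite gold/SU-8 column.

The electrode is a slender cantilever: fixed at the pad, free at the tip,
loaded by a downward axial force at the tip.  Critical loads are computed
by Euler-Bernoulli beam finite elements (cubic Hermite shape functions)
with the composite flexural rigidity EI(z) from
:func:`mea3d.geometry.section_profile`, solving the generalized
eigenproblem

    K_e phi = P_cr K_g phi

where ``K_e`` is the elastic bending stiffness and ``K_g`` the geometric
(initial-stress) stiffness for unit axial compression, constant along the
column for a tip load.  In the uniform limit this converges to the
fixed-free Euler load pi**2 EI / (4 L**2).

The critical load *factor* is the ratio of the buckling load to the
applied load — a linear safety factor.  For the same load applied across
designs, relative factors rank the load-bearing capacity of the designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .geometry import UM, DesignGrid, ElectrodeGeometry, MaterialSet, section_profile

__all__ = [
    "LoadSpec",
    "BucklingResult",
    "critical_load",
    "critical_load_factor",
    "buckling_sweep",
]

SWEEP_COLUMNS = [
    "core_diameter_um",
    "sleeve_thickness_um",
    "sleeve_height_um",
    "critical_load_n",
    "applied_load_n",
    "critical_load_factor",
    "n_elements",
]


@dataclass(frozen=True)
class LoadSpec:
    """Axial tip load: either a force in newtons (``direct_force``) or a
    pressure in pascals acting on the end cap (``pressure_on_tip``)."""

    mode: str = "direct_force"
    magnitude: float = 1e-3  # N or Pa

    def __post_init__(self) -> None:
        if self.mode not in ("direct_force", "pressure_on_tip"):
            raise ValueError("mode must be 'direct_force' or 'pressure_on_tip'")
        if self.magnitude <= 0:
            raise ValueError("load magnitude must be > 0")

    def applied_force(self, geom: ElectrodeGeometry) -> float:
        if self.mode == "direct_force":
            return self.magnitude
        cap_area = np.pi * (geom.core_radius_um * UM) ** 2
        return self.magnitude * cap_area


@dataclass(frozen=True)
class BucklingResult:
    critical_load: float         # N
    critical_load_factor: float  # dimensionless
    applied_load: float          # N
    n_elements: int

    def __post_init__(self) -> None:
        if self.critical_load <= 0:
            raise ValueError("critical_load must be > 0")


def _element_matrices(ei: float, length: float) -> tuple[np.ndarray, np.ndarray]:
    """Cubic-Hermite elastic and unit-load geometric stiffness (4x4)."""
    L = length
    ke = (ei / L**3) * np.array(
        [
            [12.0, 6.0 * L, -12.0, 6.0 * L],
            [6.0 * L, 4.0 * L**2, -6.0 * L, 2.0 * L**2],
            [-12.0, -6.0 * L, 12.0, -6.0 * L],
            [6.0 * L, 2.0 * L**2, -6.0 * L, 4.0 * L**2],
        ]
    )
    kg = (1.0 / (30.0 * L)) * np.array(
        [
            [36.0, 3.0 * L, -36.0, 3.0 * L],
            [3.0 * L, 4.0 * L**2, -3.0 * L, -(L**2)],
            [-36.0, -3.0 * L, 36.0, -3.0 * L],
            [3.0 * L, -(L**2), -3.0 * L, 4.0 * L**2],
        ]
    )
    return ke, kg


def critical_load(
    geom: ElectrodeGeometry, mats: MaterialSet, n_elements: int = 60
) -> float:
    """Smallest buckling load (N) of the fixed-free composite column."""
    if n_elements < 20:
        raise ValueError("n_elements must be >= 20")
    segments = section_profile(geom, mats, n_elements)
    ndof = 2 * (len(segments) + 1)
    K = np.zeros((ndof, ndof))
    G = np.zeros((ndof, ndof))
    for i, (length, ei) in enumerate(segments):
        if ei <= 0 or length <= 0:
            raise ValueError("degenerate segment in section profile")
        ke, kg = _element_matrices(ei, length)
        sl = slice(2 * i, 2 * i + 4)
        K[sl, sl] += ke
        G[sl, sl] += kg
    # clamp base: transverse displacement and rotation of node 0
    K = K[2:, 2:]
    G = G[2:, 2:]
    eigvals = scipy.linalg.eigh(K, G, eigvals_only=True)
    positive = eigvals[eigvals > 0]
    if positive.size == 0:
        raise RuntimeError("buckling eigenproblem returned no positive load factor")
    return float(positive.min())


def critical_load_factor(
    geom: ElectrodeGeometry,
    mats: MaterialSet,
    load: LoadSpec,
    n_elements: int = 60,
) -> BucklingResult:
    """Critical load and safety factor against the applied tip load."""
    applied = load.applied_force(geom)
    if applied <= 0:
        raise ValueError("applied load must be > 0")
    p_cr = critical_load(geom, mats, n_elements)
    return BucklingResult(
        critical_load=p_cr,
        critical_load_factor=p_cr / applied,
        applied_load=applied,
        n_elements=n_elements,
    )


def buckling_sweep(
    grid: DesignGrid,
    mats: MaterialSet | None = None,
    load: LoadSpec | None = None,
    n_elements: int = 60,
) -> pd.DataFrame:
    """Critical load and factor for every valid grid point, in grid order."""
    mats = mats or MaterialSet()
    load = load or LoadSpec()
    rows = []
    for geom in grid:
        res = critical_load_factor(geom, mats, load, n_elements)
        rows.append(
            (
                geom.core_diameter_um,
                geom.sleeve_thickness_um,
                geom.sleeve_height_um,
                res.critical_load,
                res.applied_load,
                res.critical_load_factor,
                n_elements,
            )
        )
    if not rows:
        raise ValueError("design grid produced no valid points")
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)
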