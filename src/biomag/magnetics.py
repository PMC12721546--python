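"""Magnetostatics of saturable-core electromagnet arrays.

This module computes the magnetic flux density **B** produced by circular
current loops, layered solenoid windings, and planar arrays of electromagnets
with saturable low-carbon-steel cores — the geometry used to retain
magnetically immobilized enzymes or microorganisms at the bottom of a
bioreactor vessel.

The single-loop field is the exact off-axis solution expressed through the
complete elliptic integrals K and E.  In loop-centred cylindrical coordinates
(radial distance ``rho``, height ``z``, loop radius ``a``, current ``I``)::

    alpha^2 = a^2 + r^2 - 2 a rho        r^2 = rho^2 + z^2
    beta^2  = a^2 + r^2 + 2 a rho        q^2 = 1 - alpha^2 / beta^2
    C       = mu0 I / pi

    B_x = C x z / (2 alpha^2 beta rho^2) * [(a^2 + r^2) E(q^2) - alpha^2 K(q^2)]
    B_y = (y / x) B_x
    B_z = C / (2 alpha^2 beta)          * [(a^2 - r^2) E(q^2) + alpha^2 K(q^2)]

On the axis (``rho -> 0``) the kernel reduces to the familiar closed form
``B_z = mu0 I a^2 / (2 (a^2 + z^2)^{3/2})``, which is used directly there to
avoid cancellation.

A winding is discretized into one loop per turn (vertical pitch equal to the
insulated wire diameter, radius growing by one wire diameter per filled
layer).  A ferromagnetic core of relative permeability ``mu_r`` and saturation
flux density ``b_sat`` amplifies the bare-coil field by the uniform gain

    g = min(mu_r, b_sat / B_ref)

where ``B_ref`` is the bare-coil flux density at the core centroid (the
conventional single-point evaluation of the magnetizing field H).  Below
saturation the core multiplies the coil field by ``mu_r``; once
``mu_r * B_ref`` would exceed ``b_sat`` the gain is capped so that the
amplified on-axis field never exceeds the material's saturation point.  The
classical magnetization route (``M = chi_m H`` capped at ``Msat``, dipole
far field ``mu0 m / (2 pi z^3)``) is kept as an independent cross-check.

Coordinates: z = 0 at the plane of the electromagnets' top faces, +z toward
the container interior; windings and cores occupy z in [-height, 0].  All
lengths are in metres, currents in amperes, fields in tesla.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.constants import mu_0 as MU0
from scipy.special import ellipe, ellipk

from .errors import ConfigError, DomainError, SingularityError

__all__ = [
    "MU0",
    "Point3",
    "FieldVector",
    "LoopSource",
    "WindingSpec",
    "CoreSpec",
    "Electromagnet",
    "EMArray",
    "FieldMap",
    "AxisProfile",
    "complete_elliptic_KE",
    "loop_field",
    "build_winding",
    "coil_field",
    "core_magnetization",
    "dipole_axis_field",
    "amplification_gain",
    "core_amplification",
    "electromagnet_field",
    "array_field",
    "plane_field_map",
    "axis_profile",
    "budget_electromagnet",
    "radius_sweep",
    "tangent_triangle_array",
]

# Relative rho below which a point is treated as on-axis (cancellation guard).
_AXIS_RTOL = 1e-9


class Point3(NamedTuple):
    """Cartesian point in metres (z = 0 at the array top surface, +z upward)."""

    x: float
    y: float
    z: float


class FieldVector(NamedTuple):
    """Magnetic flux density components in tesla."""

    bx: float
    by: float
    bz: float

    @property
    def magnitude(self) -> float:
        return math.sqrt(self.bx * self.bx + self.by * self.by + self.bz * self.bz)


@dataclass(frozen=True)
class LoopSource:
    """Single circular current loop with its axis parallel to +z.

    Parameters
    ----------
    radius : float
        Loop radius ``a`` in metres, > 0.
    current : float
        Signed loop current in amperes (positive current circulates so that
        B_z > 0 on the +z axis).
    center : Point3
        Loop centre in metres.
    """

    radius: float
    current: float
    center: Point3 = Point3(0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.radius > 0.0:
            raise ConfigError(f"LoopSource.radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class WindingSpec:
    """Layered solenoid winding built from a single wire.

    ``wire_diameter`` is the *effective* (insulated) diameter and sets both the
    vertical turn pitch and the radial layer pitch.  Turns fill each layer from
    z = -height upward; when a layer is full the radius grows by one wire
    diameter.
    """

    inner_radius: float
    height: float
    turns: int
    wire_diameter: float
    current_per_coil: float

    def __post_init__(self) -> None:
        if not self.inner_radius > 0.0:
            raise ConfigError("WindingSpec.inner_radius must be > 0")
        if not self.height > 0.0:
            raise ConfigError("WindingSpec.height must be > 0")
        if int(self.turns) != self.turns or self.turns < 1:
            raise ConfigError(f"WindingSpec.turns must be an integer >= 1, got {self.turns}")
        if not self.wire_diameter > 0.0:
            raise ConfigError("WindingSpec.wire_diameter must be > 0")
        if self.wire_diameter >= self.height:
            raise ConfigError(
                "WindingSpec.wire_diameter must be smaller than the winding height "
                f"({self.wire_diameter} >= {self.height})"
            )

    @property
    def turns_per_layer(self) -> int:
        return int(math.floor(self.height / self.wire_diameter))

    @property
    def n_layers(self) -> int:
        return int(math.ceil(self.turns / self.turns_per_layer))


@dataclass(frozen=True)
class CoreSpec:
    """Cylindrical ferromagnetic core (e.g. stacked A36 steel discs).

    ``mu_r`` is the relative permeability (dimensionless, >= 1) and ``b_sat``
    the saturation flux density in tesla (2.16 T for ASTM A36).
    """

    radius: float
    height: float
    mu_r: float
    b_sat: float

    def __post_init__(self) -> None:
        if not (self.radius > 0.0 and self.height > 0.0):
            raise ConfigError("CoreSpec.radius and CoreSpec.height must be > 0")
        if self.mu_r < 1.0:
            raise ConfigError(f"CoreSpec.mu_r must be >= 1, got {self.mu_r}")
        if not self.b_sat > 0.0:
            raise ConfigError(f"CoreSpec.b_sat must be > 0, got {self.b_sat}")

    @property
    def volume(self) -> float:
        """Core volume in m^3."""
        return math.pi * self.radius**2 * self.height


@dataclass(frozen=True)
class Electromagnet:
    """Winding plus saturable core; top face at local z = 0, axis vertical.

    ``center`` places the electromagnet in the array frame; its z component is
    the height of the top face (0 for a flat array).
    """

    winding: WindingSpec
    core: CoreSpec
    center: Point3 = Point3(0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.core.radius > self.winding.inner_radius + 1e-12:
            raise ConfigError(
                "core radius must not exceed the winding inner radius "
                f"({self.core.radius} > {self.winding.inner_radius})"
            )


@dataclass(frozen=True)
class EMArray:
    """Planar array of electromagnets with coplanar top faces at z = 0."""

    electromagnets: tuple[Electromagnet, ...]

    def __init__(self, electromagnets: Sequence[Electromagnet]):
        ems = tuple(electromagnets)
        if not ems:
            raise ConfigError("EMArray must contain at least one electromagnet")
        for em in ems:
            if abs(em.center.z) > 1e-12:
                raise ConfigError(
                    "all electromagnet top faces must be coplanar at z = 0 "
                    f"(found center.z = {em.center.z})"
                )
        object.__setattr__(self, "electromagnets", ems)

    def __len__(self) -> int:
        return len(self.electromagnets)


@dataclass
class FieldMap:
    """Gridded flux density on a horizontal plane above the array.

    ``bx, by, bz, magnitude`` are arrays of shape ``(len(grid_x), len(grid_y))``
    indexed ``[i, j] -> (grid_x[i], grid_y[j])``.
    """

    z_plane: float
    grid_x: np.ndarray
    grid_y: np.ndarray
    bx: np.ndarray
    by: np.ndarray
    bz: np.ndarray
    magnitude: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.magnitude = np.sqrt(self.bx**2 + self.by**2 + self.bz**2)

    @property
    def max_magnitude(self) -> float:
        return float(self.magnitude.max())

    @property
    def min_magnitude(self) -> float:
        return float(self.magnitude.min())

    @property
    def mean_magnitude(self) -> float:
        return float(self.magnitude.mean())

    def stats(self) -> dict:
        return {
            "z_m": self.z_plane,
            "max_T": self.max_magnitude,
            "min_T": self.min_magnitude,
            "mean_T": self.mean_magnitude,
        }

    def to_dataframe(self):
        """Long-format table with columns x_m, y_m, z_m, bx_T, by_T, bz_T, bmag_T."""
        import pandas as pd

        xx, yy = np.meshgrid(self.grid_x, self.grid_y, indexing="ij")
        return pd.DataFrame(
            {
                "x_m": xx.ravel(),
                "y_m": yy.ravel(),
                "z_m": np.full(xx.size, self.z_plane),
                "bx_T": self.bx.ravel(),
                "by_T": self.by.ravel(),
                "bz_T": self.bz.ravel(),
                "bmag_T": self.magnitude.ravel(),
            }
        )


@dataclass
class AxisProfile:
    """On-axis B_z profile of a single electromagnet.

    Transverse components vanish on the axis by symmetry and are not stored.
    ``saturated`` records whether the core amplification is capped by the
    material saturation point rather than by mu_r.
    """

    radius_label: float
    z_values: np.ndarray
    bz_values: np.ndarray
    saturated: bool
    turns: int | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z_values, dtype=float)
        if z.ndim != 1 or np.any(np.diff(z) <= 0.0):
            raise ConfigError("AxisProfile.z_values must be strictly increasing")
        self.z_values = z
        self.bz_values = np.asarray(self.bz_values, dtype=float)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "z_m": self.z_values,
                "bz_T": self.bz_values,
                "saturated": np.full(self.z_values.size, self.saturated),
            }
        )


# ---------------------------------------------------------------------------
# elementary field kernels
# ---------------------------------------------------------------------------


def complete_elliptic_KE(k_squared: float) -> tuple[float, float]:
    """Complete elliptic integrals K(k^2) and E(k^2) in the parameter convention.

    ``K = int_0^{pi/2} dtheta / sqrt(1 - k^2 sin^2 theta)`` and
    ``E = int_0^{pi/2} sqrt(1 - k^2 sin^2 theta) dtheta``.

    Raises :class:`DomainError` for ``k_squared`` outside [0, 1); K diverges at
    1, which corresponds to evaluating the loop field on the filament itself.
    """
    if not 0.0 <= k_squared < 1.0:
        raise DomainError(f"k_squared must lie in [0, 1), got {k_squared}")
    return float(ellipk(k_squared)), float(ellipe(k_squared))


def _loop_field_arrays(
    a: float,
    current: float,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    min_clearance: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized loop-field kernel in loop-centred coordinates.

    Raises :class:`SingularityError` if any point lies within ``min_clearance``
    of the filament (the distance to the filament ring is sqrt(alpha^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    x, y, z = np.broadcast_arrays(x, y, z)

    rho2 = x * x + y * y
    r2 = rho2 + z * z
    rho = np.sqrt(rho2)
    alpha2 = a * a + r2 - 2.0 * a * rho
    clearance2 = max(min_clearance, 0.0) ** 2
    if np.any(alpha2 <= clearance2):
        raise SingularityError(
            f"field evaluation within {min_clearance:g} m of a loop filament "
            f"(loop radius {a:g} m)"
        )
    beta2 = a * a + r2 + 2.0 * a * rho
    beta = np.sqrt(beta2)
    k2 = 1.0 - alpha2 / beta2
    K = ellipk(k2)
    E = ellipe(k2)
    C = MU0 * current / math.pi

    on_axis = rho <= _AXIS_RTOL * a
    rho2_safe = np.where(on_axis, 1.0, rho2)
    # B_x = C x z / (2 alpha^2 beta rho^2) [(a^2+r^2) E - alpha^2 K]
    b_trans = C * z / (2.0 * alpha2 * beta * rho2_safe) * ((a * a + r2) * E - alpha2 * K)
    bx = np.where(on_axis, 0.0, b_trans * x)
    by = np.where(on_axis, 0.0, b_trans * y)
    bz_axis = MU0 * current * a * a / (2.0 * (a * a + z * z) ** 1.5)
    bz_off = C / (2.0 * alpha2 * beta) * ((a * a - r2) * E + alpha2 * K)
    bz = np.where(on_axis, bz_axis, bz_off)
    return bx, by, bz


def loop_field(loop: LoopSource, p: Point3, min_clearance: float = 0.0) -> FieldVector:
    """Flux density of a single circular loop at point ``p`` (tesla).

    Exact elliptic-integral solution off axis, closed form on axis.  Raises
    :class:`SingularityError` on the filament (or within ``min_clearance``).
    """
    bx, by, bz = _loop_field_arrays(
        loop.radius,
        loop.current,
        np.array(p[0] - loop.center.x),
        np.array(p[1] - loop.center.y),
        np.array(p[2] - loop.center.z),
        min_clearance=min_clearance,
    )
    return FieldVector(float(bx), float(by), float(bz))


# ---------------------------------------------------------------------------
# windings and coils
# ---------------------------------------------------------------------------


def build_winding(spec: WindingSpec, center: Point3 = Point3(0.0, 0.0, 0.0)) -> list[LoopSource]:
    """Discretize a winding into one loop per turn.

    Turn ``n`` sits in layer ``n // turns_per_layer`` at radius
    ``inner_radius + (layer + 0.5) * wire_diameter`` and height
    ``-height + (index_in_layer + 0.5) * wire_diameter`` relative to ``center``.
    """
    per_layer = spec.turns_per_layer
    loops: list[LoopSource] = []
    for n in range(int(spec.turns)):
        layer, idx = divmod(n, per_layer)
        radius = spec.inner_radius + (layer + 0.5) * spec.wire_diameter
        z = -spec.height + (idx + 0.5) * spec.wire_diameter
        loops.append(
            LoopSource(
                radius,
                spec.current_per_coil,
                Point3(center.x, center.y, center.z + z),
            )
        )
    return loops


def _coil_field_arrays(
    loops: Sequence[LoopSource],
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    min_clearance: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    shape = np.broadcast_shapes(x.shape, y.shape, z.shape)
    bx = np.zeros(shape)
    by = np.zeros(shape)
    bz = np.zeros(shape)
    for loop in loops:
        lbx, lby, lbz = _loop_field_arrays(
            loop.radius,
            loop.current,
            x - loop.center.x,
            y - loop.center.y,
            z - loop.center.z,
            min_clearance=min_clearance,
        )
        bx += lbx
        by += lby
        bz += lbz
    return bx, by, bz


def coil_field(
    loops: Sequence[LoopSource], p: Point3, min_clearance: float = 0.0
) -> FieldVector:
    """Superposed flux density of a collection of loops at ``p`` (tesla)."""
    if len(loops) == 0:
        return FieldVector(0.0, 0.0, 0.0)
    bx, by, bz = _coil_field_arrays(
        loops, np.array(p[0]), np.array(p[1]), np.array(p[2]), min_clearance=min_clearance
    )
    return FieldVector(float(bx), float(by), float(bz))


# ---------------------------------------------------------------------------
# core models
# ---------------------------------------------------------------------------


def core_magnetization(core: CoreSpec, h_applied: float) -> tuple[float, float]:
    """Saturable core magnetization M (A/m) and dipole moment m (A m^2).

    ``M = min(chi_m H, Msat)`` with ``chi_m = mu_r - 1`` and
    ``Msat = b_sat / mu0``; the moment is ``m = M V``.
    """
    if h_applied < 0.0:
        raise DomainError(f"h_applied must be >= 0, got {h_applied}")
    m_sat = core.b_sat / MU0
    magnetization = min((core.mu_r - 1.0) * h_applied, m_sat)
    return magnetization, magnetization * core.volume


def dipole_axis_field(m_moment: float, z: float) -> float:
    """On-axis far field of a magnetic dipole: ``B_z = mu0 m / (2 pi z^3)``."""
    if not z > 0.0:
        raise DomainError(f"dipole_axis_field requires z > 0, got {z}")
    return MU0 * m_moment / (2.0 * math.pi * z**3)


def amplification_gain(b_reference: float, mu_r: float, b_sat: float) -> float:
    """Saturation-capped core gain ``g = min(mu_r, b_sat / b_reference)``.

    ``b_reference`` is the bare-coil flux density at the core reference point.
    ``g * b_reference <= b_sat`` always; ``g = mu_r`` exactly while the core is
    unsaturated (``mu_r * b_reference <= b_sat``).  Zero reference field (no
    current) returns ``mu_r`` by convention.
    """
    if b_reference <= 0.0:
        return mu_r
    return min(mu_r, b_sat / b_reference)


def core_amplification(em: Electromagnet, reference: str = "core_center") -> float:
    """Uniform field-amplification gain of an electromagnet's core.

    The magnetizing field is evaluated from the bare winding at a single
    reference point on the axis: the core centroid by default (``reference =
    "core_center"``, local z = -core.height / 2), or the pole-face centre
    (``"pole_face"``, local z = 0).  The centroid is where the applied H is
    largest on the axis and is the conventional single-point choice for a
    uniformly magnetized core; it is also what reproduces the observed
    saturation ordering of the radius sweep (small radii saturate, large ones
    do not).
    """
    if reference == "core_center":
        z_ref = -em.core.height / 2.0
    elif reference == "pole_face":
        z_ref = 0.0
    else:
        raise ConfigError(f"unknown reference point {reference!r}")
    loops = build_winding(em.winding)
    b_ref = coil_field(loops, Point3(0.0, 0.0, z_ref)).magnitude
    return amplification_gain(b_ref, em.core.mu_r, em.core.b_sat)


def _electromagnet_field_arrays(
    em: Electromagnet,
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray,
    loops: Sequence[LoopSource] | None = None,
    gain: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if loops is None:
        loops = build_winding(em.winding)
    if gain is None:
        gain = core_amplification(em)
    bx, by, bz = _coil_field_arrays(
        loops,
        np.asarray(x, float) - em.center.x,
        np.asarray(y, float) - em.center.y,
        np.asarray(z, float) - em.center.z,
        min_clearance=em.winding.wire_diameter,
    )
    return gain * bx, gain * by, gain * bz


def electromagnet_field(em: Electromagnet, p: Point3) -> FieldVector:
    """Flux density of a single electromagnet (winding + saturable core).

    The saturable core scales the bare-coil field uniformly by
    :func:`core_amplification`; evaluation within one wire diameter of a
    filament raises :class:`SingularityError`.
    """
    bx, by, bz = _electromagnet_field_arrays(
        em, np.array(p[0]), np.array(p[1]), np.array(p[2])
    )
    return FieldVector(float(bx), float(by), float(bz))


def array_field(array: EMArray, p: Point3) -> FieldVector:
    """Vector sum of all electromagnet contributions at ``p``."""
    bx = by = bz = 0.0
    for em in array.electromagnets:
        v = electromagnet_field(em, p)
        bx += v.bx
        by += v.by
        bz += v.bz
    return FieldVector(bx, by, bz)


def _array_field_arrays(
    array: EMArray, x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    shape = np.broadcast_shapes(
        np.asarray(x).shape, np.asarray(y).shape, np.asarray(z).shape
    )
    bx = np.zeros(shape)
    by = np.zeros(shape)
    bz = np.zeros(shape)
    for em in array.electromagnets:
        loops = build_winding(em.winding)
        gain = core_amplification(em)
        ebx, eby, ebz = _electromagnet_field_arrays(em, x, y, z, loops=loops, gain=gain)
        bx += ebx
        by += eby
        bz += ebz
    return bx, by, bz


# ---------------------------------------------------------------------------
# derived products: maps, profiles, sweeps
# ---------------------------------------------------------------------------


def tangent_triangle_array(em: Electromagnet, spacing: float | None = None) -> EMArray:
    """Three copies of ``em`` on an equilateral triangle about the origin.

    ``spacing`` is the distance between electromagnet centres; by default the
    coils are mutually tangent (spacing = 2 * winding outer-ish radius, taken
    as 2 * inner_radius), which puts the centres on a circle of radius
    ``spacing / sqrt(3)``.
    """
    if spacing is None:
        spacing = 2.0 * em.winding.inner_radius
    circumradius = spacing / math.sqrt(3.0)
    ems = []
    for k in range(3):
        ang = math.pi / 2.0 + 2.0 * math.pi * k / 3.0
        ems.append(
            Electromagnet(
                em.winding,
                em.core,
                Point3(circumradius * math.cos(ang), circumradius * math.sin(ang), 0.0),
            )
        )
    return EMArray(ems)


def plane_field_map(
    array: EMArray,
    z_plane: float,
    extent: float = 0.16,
    n: int = 81,
    center: tuple[float, float] = (0.0, 0.0),
) -> FieldMap:
    """Flux-density map on the horizontal plane ``z = z_plane``.

    ``extent`` is the full side length of the square map (metres) centred on
    ``center``; ``n`` grid nodes per axis.
    """
    if not z_plane > 0.0:
        raise ConfigError(f"z_plane must be > 0, got {z_plane}")
    if n < 2:
        raise ConfigError(f"grid resolution must be >= 2 per axis, got {n}")
    gx = center[0] + np.linspace(-extent / 2.0, extent / 2.0, n)
    gy = center[1] + np.linspace(-extent / 2.0, extent / 2.0, n)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    zz = np.full_like(xx, z_plane)
    bx, by, bz = _array_field_arrays(array, xx, yy, zz)
    return FieldMap(z_plane=z_plane, grid_x=gx, grid_y=gy, bx=bx, by=by, bz=bz)


def axis_profile(em: Electromagnet, z_max: float, n_points: int = 50) -> AxisProfile:
    """On-axis B_z of a single electromagnet for z in (0, z_max]."""
    if not z_max > 0.0:
        raise ConfigError(f"z_max must be > 0, got {z_max}")
    if n_points < 1:
        raise ConfigError("n_points must be >= 1")
    loops = build_winding(em.winding)
    gain = core_amplification(em)
    z = np.linspace(z_max / n_points, z_max, n_points)
    _, _, bz = _coil_field_arrays(
        loops, np.zeros_like(z), np.zeros_like(z), z, min_clearance=em.winding.wire_diameter
    )
    saturated = gain < em.core.mu_r * (1.0 - 1e-12)
    return AxisProfile(
        radius_label=em.winding.inner_radius,
        z_values=z,
        bz_values=gain * bz,
        saturated=saturated,
        turns=em.winding.turns,
    )


def budget_electromagnet(
    radius: float,
    wire_mass_budget: float,
    gauge,
    current: float,
    core_template: CoreSpec,
    wire_pitch: float | None = None,
) -> Electromagnet:
    """Electromagnet of a given radius wound from a fixed mass of wire.

    The turn count is ``N = floor(L / (2 pi (a + pitch/2)))`` with
    ``L = wire_mass_budget / gauge.linear_mass``; the core (and the winding
    height) are scaled from ``core_template`` proportionally to the candidate
    radius.  ``gauge`` is a :class:`~biomag.design_sizing.WireGauge`.
    """
    if not wire_mass_budget > 0.0:
        raise ConfigError("wire_mass_budget must be > 0")
    if not radius > 0.0:
        raise ConfigError(f"radius must be positive, got {radius}")
    pitch = wire_pitch if wire_pitch is not None else gauge.insulated_diameter
    wire_length = wire_mass_budget / gauge.linear_mass
    turns = int(math.floor(wire_length / (2.0 * math.pi * (radius + 0.5 * pitch))))
    if turns < 1:
        raise ConfigError(
            f"radius {radius:g} m leaves no complete turn within the wire budget"
        )
    scale = radius / core_template.radius
    core = CoreSpec(
        radius, core_template.height * scale, core_template.mu_r, core_template.b_sat
    )
    winding = WindingSpec(
        inner_radius=radius,
        height=core.height,
        turns=turns,
        wire_diameter=pitch,
        current_per_coil=current,
    )
    return Electromagnet(winding, core)


def radius_sweep(
    radii: Sequence[float],
    wire_mass_budget: float,
    gauge,
    current: float,
    core_template: CoreSpec,
    wire_pitch: float | None = None,
    z_max: float = 0.10,
    n_points: int = 50,
) -> list[AxisProfile]:
    """Axis profiles for candidate electromagnet radii under a wire-mass budget.

    Each candidate is built with :func:`budget_electromagnet`, so a larger
    radius costs turns (fixed wire length) while the core grows with it.
    """
    return [
        axis_profile(
            budget_electromagnet(a, wire_mass_budget, gauge, current, core_template, wire_pitch),
            z_max=z_max,
            n_points=n_points,
        )
        for a in radii
    ]
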