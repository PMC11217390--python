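"""Analytic small-angle-scattering form-factor models.

The catalogue covers the 46 model names of the KWS-1 virtual-experiment study;
13 of them ship with vectorised intensity kernels (the rest are registered by
name and label only, so class indices stay stable, and can be filled in through
:func:`register_kernel`). Class labels are the 0-based rank of the model name
under lexicographic ordering of the full catalogue (``adsorbed layer`` -> 0,
``sphere`` -> 39, ``teubner strey`` -> 44).

Intensities are in arbitrary (relative) units: only the shape of the detector
pattern matters downstream, so absolute cm^-1 calibration constants are
dropped. All kernels broadcast over numpy arrays in both ``q`` and the model
parameters, which is what lets the virtual instrument draw fresh polydisperse
sizes and orientations per neutron event at no interpreter cost.

Conventions: the neutron beam runs along +z; the orientation of an anisotropic
particle is the (theta, phi) polar/azimuthal pair of its principal axis in
radians; lengths are Angstrom and q is 1/Angstrom.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gamma as _gamma_fn, j1 as _bessel_j1

from .exceptions import (
    ConfigurationError,
    DomainError,
    UnsupportedOperationError,
    ValidationError,
)

__all__ = [
    "CATALOGUE_NAMES",
    "ModelParam",
    "SASModelSpec",
    "PolydispersitySpec",
    "list_models",
    "implemented_models",
    "get_model",
    "evaluate_Iq",
    "evaluate_Iqxy",
    "orientation_average",
    "polydisperse_average",
    "sampling_bounds",
    "catalogue_to_json",
    "register_kernel",
]

#: Full 46-name catalogue in lexicographic order; index == class label.
CATALOGUE_NAMES: tuple[str, ...] = (
    "adsorbed layer",                        # 0
    "barbell aniso",                         # 1
    "bcc paracrystal aniso",                 # 2
    "binary hard sphere",                    # 3
    "broad peak",                            # 4
    "capped cylinder aniso",                 # 5
    "core multi shell",                      # 6
    "core shell bicelle aniso",              # 7
    "core shell bicelle elliptical aniso",   # 8
    "core shell cylinder aniso",             # 9
    "core shell ellipsoid aniso",            # 10
    "core shell parallelepiped aniso",       # 11
    "core shell sphere",                     # 12
    "cylinder aniso",                        # 13
    "dab",                                   # 14
    "ellipsoid aniso",                       # 15
    "elliptical cylinder aniso",             # 16
    "fcc paracrystal aniso",                 # 17
    "flexible cylinder",                     # 18
    "fractal",                               # 19
    "fractal core shell",                    # 20
    "fuzzy sphere",                          # 21
    "gauss lorentz gel",                     # 22
    "gel fit",                               # 23
    "guinier porod",                         # 24
    "hollow rectangular prism aniso",        # 25
    "lamellar hg",                           # 26
    "lamellar hg stack caille",              # 27
    "lamellar stack paracrystal",            # 28
    "mass fractal",                          # 29
    "mono gauss coil",                       # 30
    "multilayer vesicle",                    # 31
    "onion",                                 # 32
    "parallelepiped aniso",                  # 33
    "pearl necklace",                        # 34
    "polymer micelle",                       # 35
    "power law",                             # 36
    "rectangular prism aniso",               # 37
    "sc paracrystal aniso",                  # 38
    "sphere",                                # 39
    "spherical sld",                         # 40
    "stacked disks aniso",                   # 41
    "star polymer",                          # 42
    "surface fractal",                       # 43
    "teubner strey",                         # 44
    "vesicle",                               # 45
)


@dataclass(frozen=True)
class ModelParam:
    """One entry of a model's parameter schema."""

    name: str
    default: float          # p0, the SasView default used as sampling centre
    lb: float
    ub: float
    unit: str
    kind: str               # one of {"length", "angle", "density-contrast", "dimensionless"}

    def __post_init__(self) -> None:
        if self.kind not in {"length", "angle", "density-contrast", "dimensionless"}:
            raise ValidationError(f"unknown parameter kind {self.kind!r} for {self.name!r}")
        if self.kind in {"length"} and self.lb < 0:
            raise ValidationError(f"length parameter {self.name!r} must have lb >= 0")


@dataclass(frozen=True)
class SASModelSpec:
    """A scattering model: schema, class label and intensity kernels.

    ``kernel_iso`` maps ``(q, **params) -> I`` and ``kernel_aniso`` maps
    ``(qx, qy, **params) -> I`` for a fixed particle orientation carried in the
    angle parameters. Catalogue entries without kernels keep their label so
    the 46-way class indexing of the published dataset is preserved.
    """

    name: str
    label: int
    params: tuple[ModelParam, ...] = ()
    anisotropic: bool = False
    kernel_iso: Callable | None = None
    kernel_aniso: Callable | None = None

    @property
    def implemented(self) -> bool:
        return self.kernel_iso is not None or self.kernel_aniso is not None

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.params)

    def param(self, name: str) -> ModelParam:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    def defaults(self) -> dict[str, float]:
        return {p.name: p.default for p in self.params}


@dataclass(frozen=True)
class PolydispersitySpec:
    """Spreads for size parameters and orientation angles.

    ``dr`` maps a length-parameter name to the standard deviation of a
    positive-truncated Gaussian centred on the parameter value (0 means
    monodisperse, at most r/2 is allowed). ``dtheta`` maps an angle-parameter
    name to the half-width of a uniform window centred on the angle value.
    """

    dr: dict[str, float] = field(default_factory=dict)
    dtheta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in {**self.dr, **self.dtheta}.items():
            if v < 0:
                raise ValidationError(f"spread for {name!r} must be >= 0, got {v}")

    @property
    def is_monodisperse(self) -> bool:
        return all(v == 0 for v in self.dr.values()) and all(
            v == 0 for v in self.dtheta.values()
        )

    def validate_against(self, model: "SASModelSpec", params: dict[str, float]) -> None:
        for name, dr in self.dr.items():
            p = model.param(name)
            if p.kind != "length":
                raise ValidationError(f"size spread given for non-length parameter {name!r}")
            r = params[name]
            if dr > r / 2 + 1e-12:
                raise ValidationError(
                    f"size spread for {name!r} must be <= r/2 = {r / 2}, got {dr}"
                )
        for name in self.dtheta:
            if model.param(name).kind != "angle":
                raise ValidationError(f"angle spread given for non-angle parameter {name!r}")


# --------------------------------------------------------------------------
# numerical helpers (small-x safe, broadcasting)
# --------------------------------------------------------------------------

def _sph_3j1x(x):
    """3 (sin x - x cos x) / x^3, the sphere amplitude function, with x->0 -> 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    return np.where(small, 1.0 - x**2 / 10.0, out)


def _sinc(x):
    """sin(x)/x with the removable singularity filled."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


def _j1c(x):
    """2 J1(x)/x with x->0 -> 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-6
    xs = np.where(small, 1.0, x)
    out = 2.0 * _bessel_j1(xs) / xs
    return np.where(small, 1.0 - x**2 / 8.0, out)


def _debye(x):
    """Debye function 2 (exp(-x) + x - 1) / x^2 with x->0 -> 1."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-5
    xs = np.where(small, 1.0, x)
    out = 2.0 * (np.exp(-xs) + xs - 1.0) / xs**2
    return np.where(small, 1.0 - x / 3.0, out)


def _axis_vector(theta, phi):
    st = np.sin(theta)
    return st * np.cos(phi), st * np.sin(phi), np.cos(theta)


def _cos_alpha(qx, qy, theta, phi):
    """Cosine of the angle between the (in-plane) q vector and the particle axis."""
    q = np.hypot(qx, qy)
    qsafe = np.where(q == 0, 1.0, q)
    nx, ny, _ = _axis_vector(theta, phi)
    c = (qx * nx + qy * ny) / qsafe
    return np.clip(np.where(q == 0, 0.0, c), -1.0, 1.0)


# --------------------------------------------------------------------------
# isotropic kernels
# --------------------------------------------------------------------------

def _sphere_Iq(q, scale, background, sld, sld_solvent, radius):
    V = 4.0 / 3.0 * np.pi * radius**3
    amp = V * (sld - sld_solvent) * _sph_3j1x(q * radius)
    return scale / V * amp**2 + background


def _fuzzy_sphere_Iq(q, scale, background, sld, sld_solvent, radius, fuzziness):
    V = 4.0 / 3.0 * np.pi * radius**3
    amp = (
        V
        * (sld - sld_solvent)
        * _sph_3j1x(q * radius)
        * np.exp(-0.5 * (fuzziness * q) ** 2)
    )
    return scale / V * amp**2 + background


def _core_shell_sphere_Iq(
    q, scale, background, sld_core, sld_shell, sld_solvent, radius, thickness
):
    rs = radius + thickness
    Vc = 4.0 / 3.0 * np.pi * radius**3
    Vs = 4.0 / 3.0 * np.pi * rs**3
    amp = Vc * (sld_core - sld_shell) * _sph_3j1x(q * radius) + Vs * (
        sld_shell - sld_solvent
    ) * _sph_3j1x(q * rs)
    return scale / Vs * amp**2 + background


def _mono_gauss_coil_Iq(q, scale, background, i_zero, rg):
    return scale * i_zero * _debye((q * rg) ** 2) + background


def _dab_Iq(q, scale, background, cor_length):
    return scale * cor_length**3 / (1.0 + (q * cor_length) ** 2) ** 2 + background


def _broad_peak_Iq(
    q,
    scale,
    background,
    porod_scale,
    porod_exp,
    lorentz_scale,
    lorentz_length,
    peak_pos,
    lorentz_exp,
):
    return (
        scale
        * (
            porod_scale / q**porod_exp
            + lorentz_scale
            / (1.0 + (np.abs(q - peak_pos) * lorentz_length) ** lorentz_exp)
        )
        + background
    )


def _teubner_strey_Iq(q, scale, background, d, xi):
    # microemulsion correlation gamma(r) = exp(-r/xi) sin(kr)/(kr), k = 2 pi / d
    k2 = (2.0 * np.pi / d) ** 2
    b2 = 1.0 / xi**2
    a2 = (k2 + b2) ** 2
    c1 = 2.0 * b2 - 2.0 * k2
    return scale * (8.0 * np.pi / xi) / (a2 + c1 * q**2 + q**4) + background


def _mass_fractal_Iq(q, scale, background, radius, fractal_dim_mass, cutoff_length):
    D = fractal_dim_mass
    P = _sph_3j1x(q * radius) ** 2
    S = (
        _gamma_fn(D - 1.0)
        * cutoff_length ** (D - 1.0)
        * np.sin((D - 1.0) * np.arctan(q * cutoff_length))
        / (q * (1.0 + (q * cutoff_length) ** 2) ** ((D - 1.0) / 2.0))
    )
    return scale * P * S + background


def _fractal_Iq(
    q, scale, background, volfraction, radius, fractal_dim, cor_length, sld_block, sld_solvent
):
    # Teixeira fractal of spherical building blocks
    D = fractal_dim
    V = 4.0 / 3.0 * np.pi * radius**3
    P = volfraction * V * (sld_block - sld_solvent) ** 2 * _sph_3j1x(q * radius) ** 2
    qr = q * radius
    S = 1.0 + (
        D
        * _gamma_fn(D - 1.0)
        * np.sin((D - 1.0) * np.arctan(q * cor_length))
        / (qr**D * (1.0 + 1.0 / (q * cor_length) ** 2) ** ((D - 1.0) / 2.0))
    )
    return scale * P * S + background


# --------------------------------------------------------------------------
# anisotropic kernels (fixed orientation, q in the detector plane)
# --------------------------------------------------------------------------

def _cylinder_Iqxy(qx, qy, scale, background, sld, sld_solvent, radius, length, theta, phi):
    q = np.hypot(qx, qy)
    ca = _cos_alpha(qx, qy, theta, phi)
    sa = np.sqrt(1.0 - ca**2)
    V = np.pi * radius**2 * length
    f = _sinc(0.5 * q * length * ca) * _j1c(q * radius * sa)
    amp = V * (sld - sld_solvent) * f
    return scale / V * amp**2 + background


def _core_shell_cylinder_Iqxy(
    qx,
    qy,
    scale,
    background,
    sld_core,
    sld_shell,
    sld_solvent,
    radius,
    thickness,
    length,
    theta,
    phi,
):
    q = np.hypot(qx, qy)
    ca = _cos_alpha(qx, qy, theta, phi)
    sa = np.sqrt(1.0 - ca**2)
    rs = radius + thickness
    ls = length + 2.0 * thickness
    Vc = np.pi * radius**2 * length
    Vs = np.pi * rs**2 * ls
    fc = _sinc(0.5 * q * length * ca) * _j1c(q * radius * sa)
    fs = _sinc(0.5 * q * ls * ca) * _j1c(q * rs * sa)
    amp = Vc * (sld_core - sld_shell) * fc + Vs * (sld_shell - sld_solvent) * fs
    return scale / Vs * amp**2 + background


def _ellipsoid_Iqxy(
    qx, qy, scale, background, sld, sld_solvent, radius_polar, radius_equatorial, theta, phi
):
    q = np.hypot(qx, qy)
    ca = _cos_alpha(qx, qy, theta, phi)
    r_eff = np.sqrt(radius_polar**2 * ca**2 + radius_equatorial**2 * (1.0 - ca**2))
    V = 4.0 / 3.0 * np.pi * radius_polar * radius_equatorial**2
    amp = V * (sld - sld_solvent) * _sph_3j1x(q * r_eff)
    return scale / V * amp**2 + background


def _elliptical_cylinder_Iqxy(
    qx,
    qy,
    scale,
    background,
    sld,
    sld_solvent,
    radius_minor,
    axis_ratio,
    length,
    theta,
    phi,
    psi,
):
    q = np.hypot(qx, qy)
    qsafe = np.where(q == 0, 1.0, q)
    nx, ny, nz = _axis_vector(theta, phi)
    qhx = np.where(q == 0, 0.0, qx / qsafe)
    qhy = np.where(q == 0, 0.0, qy / qsafe)
    ca = np.clip(qhx * nx + qhy * ny, -1.0, 1.0)
    sa = np.sqrt(1.0 - ca**2)
    # cross-section basis: minor axis m = rotation of (z x n) by psi about n;
    # if the particle axis is along the beam, fall back to the x axis reference.
    ex_x, ex_y, ex_z = ny, -nx, 0.0 * np.asarray(nx)  # z x n (unnormalised)
    norm = np.sqrt(ex_x**2 + ex_y**2)
    deg = norm < 1e-12
    nsafe = np.where(deg, 1.0, norm)
    ex_x, ex_y = np.where(deg, 1.0, ex_x / nsafe), np.where(deg, 0.0, ex_y / nsafe)
    # second in-plane basis vector e2 = n x e1
    e2_x = ny * ex_z - nz * ex_y
    e2_y = nz * ex_x - nx * ex_z
    e2_z = nx * ex_y - ny * ex_x
    m_x = np.cos(psi) * ex_x + np.sin(psi) * e2_x
    m_y = np.cos(psi) * ex_y + np.sin(psi) * e2_y
    # q component perpendicular to the axis, projected on the minor axis
    qperp_x = qhx - ca * nx
    qperp_y = qhy - ca * ny
    qperp_z = -ca * nz
    pn = np.sqrt(qperp_x**2 + qperp_y**2 + qperp_z**2)
    pnsafe = np.where(pn < 1e-12, 1.0, pn)
    cpsi = np.clip(
        (qperp_x * m_x + qperp_y * m_y + qperp_z * (np.cos(psi) * ex_z + np.sin(psi) * e2_z))
        / pnsafe,
        -1.0,
        1.0,
    )
    r = radius_minor * np.sqrt(cpsi**2 + axis_ratio**2 * (1.0 - cpsi**2))
    V = np.pi * radius_minor**2 * axis_ratio * length
    f = _sinc(0.5 * q * length * ca) * _j1c(q * r * sa)
    amp = V * (sld - sld_solvent) * f
    return scale / V * amp**2 + background


# --------------------------------------------------------------------------
# registry
# --------------------------------------------------------------------------

_L = "length"
_A = "angle"
_C = "density-contrast"
_D = "dimensionless"
_INF = math.inf


def _P(name, p0, lb, ub, unit, kind):
    return ModelParam(name, p0, lb, ub, unit, kind)


_COMMON = (
    _P("scale", 1.0, 0.0, _INF, "", _D),
    _P("background", 0.001, 0.0, _INF, "a.u.", _D),
)

_ORIENT = (
    _P("theta", 1.0, 0.0, math.pi, "rad", _A),
    _P("phi", 1.0, 0.0, 2.0 * math.pi, "rad", _A),
)

_SCHEMAS: dict[str, dict] = {
    "sphere": dict(
        params=_COMMON
        + (
            _P("sld", 1.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_solvent", 6.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("radius", 50.0, 1.0, _INF, "A", _L),
        ),
        kernel_iso=_sphere_Iq,
    ),
    "fuzzy sphere": dict(
        params=_COMMON
        + (
            _P("sld", 1.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_solvent", 3.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("radius", 60.0, 1.0, _INF, "A", _L),
            _P("fuzziness", 10.0, 0.0, _INF, "A", _L),
        ),
        kernel_iso=_fuzzy_sphere_Iq,
    ),
    "core shell sphere": dict(
        params=_COMMON
        + (
            _P("sld_core", 1.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_shell", 2.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_solvent", 3.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("radius", 60.0, 1.0, _INF, "A", _L),
            _P("thickness", 10.0, 0.5, _INF, "A", _L),
        ),
        kernel_iso=_core_shell_sphere_Iq,
    ),
    "mono gauss coil": dict(
        params=_COMMON
        + (
            _P("i_zero", 70.0, 0.0, _INF, "a.u.", _D),
            _P("rg", 75.0, 1.0, _INF, "A", _L),
        ),
        kernel_iso=_mono_gauss_coil_Iq,
    ),
    "dab": dict(
        params=_COMMON + (_P("cor_length", 50.0, 1.0, _INF, "A", _L),),
        kernel_iso=_dab_Iq,
    ),
    "broad peak": dict(
        params=_COMMON
        + (
            _P("porod_scale", 1e-5, 0.0, _INF, "", _D),
            _P("porod_exp", 3.0, 0.5, 6.0, "", _D),
            _P("lorentz_scale", 10.0, 0.0, _INF, "", _D),
            _P("lorentz_length", 50.0, 1.0, _INF, "A", _L),
            _P("peak_pos", 0.1, 0.001, 2.0, "1/A", _D),
            _P("lorentz_exp", 2.0, 0.5, 6.0, "", _D),
        ),
        kernel_iso=_broad_peak_Iq,
    ),
    "teubner strey": dict(
        params=_COMMON
        + (
            _P("d", 100.0, 2.0, _INF, "A", _L),
            _P("xi", 30.0, 1.0, _INF, "A", _L),
        ),
        kernel_iso=_teubner_strey_Iq,
    ),
    "mass fractal": dict(
        params=_COMMON
        + (
            _P("radius", 10.0, 1.0, _INF, "A", _L),
            # mass-fractal dimension: capped below 3 so (D-1) atan(q zeta) stays
            # inside the first sine lobe and the structure factor is non-negative
            _P("fractal_dim_mass", 1.9, 1.1, 2.9, "", _D),
            _P("cutoff_length", 100.0, 1.0, _INF, "A", _L),
        ),
        kernel_iso=_mass_fractal_Iq,
    ),
    "fractal": dict(
        params=_COMMON
        + (
            _P("volfraction", 0.05, 0.0, 1.0, "", _D),
            _P("radius", 5.0, 0.5, _INF, "A", _L),
            _P("fractal_dim", 2.0, 1.1, 2.9, "", _D),
            _P("cor_length", 250.0, 1.0, _INF, "A", _L),
            _P("sld_block", 2.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_solvent", 6.4, -_INF, _INF, "1e-6/A^2", _C),
        ),
        kernel_iso=_fractal_Iq,
    ),
    "cylinder aniso": dict(
        params=_COMMON
        + (
            _P("sld", 4.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_solvent", 1.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("radius", 20.0, 1.0, _INF, "A", _L),
            _P("length", 400.0, 1.0, _INF, "A", _L),
        )
        + _ORIENT,
        kernel_aniso=_cylinder_Iqxy,
    ),
    "core shell cylinder aniso": dict(
        params=_COMMON
        + (
            _P("sld_core", 4.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_shell", 4.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_solvent", 1.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("radius", 20.0, 1.0, _INF, "A", _L),
            _P("thickness", 20.0, 0.5, _INF, "A", _L),
            _P("length", 400.0, 1.0, _INF, "A", _L),
        )
        + _ORIENT,
        kernel_aniso=_core_shell_cylinder_Iqxy,
    ),
    "ellipsoid aniso": dict(
        params=_COMMON
        + (
            _P("sld", 4.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_solvent", 1.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("radius_polar", 20.0, 1.0, _INF, "A", _L),
            _P("radius_equatorial", 400.0, 1.0, _INF, "A", _L),
        )
        + _ORIENT,
        kernel_aniso=_ellipsoid_Iqxy,
    ),
    "elliptical cylinder aniso": dict(
        params=_COMMON
        + (
            _P("sld", 4.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("sld_solvent", 1.0, -_INF, _INF, "1e-6/A^2", _C),
            _P("radius_minor", 20.0, 1.0, _INF, "A", _L),
            _P("axis_ratio", 1.5, 1.0, 10.0, "", _D),
            _P("length", 400.0, 1.0, _INF, "A", _L),
        )
        + _ORIENT
        + (_P("psi", 1.0, 0.0, 2.0 * math.pi, "rad", _A),),
        kernel_aniso=_elliptical_cylinder_Iqxy,
    ),
}

#: aliases so the anisotropic entries can be looked up by their bare shape name
_ALIASES = {
    "cylinder": "cylinder aniso",
    "core shell cylinder": "core shell cylinder aniso",
    "ellipsoid": "ellipsoid aniso",
    "elliptical cylinder": "elliptical cylinder aniso",
}


def _build_catalogue() -> dict[str, SASModelSpec]:
    cat = {}
    for label, name in enumerate(CATALOGUE_NAMES):
        schema = _SCHEMAS.get(name)
        if schema is None:
            cat[name] = SASModelSpec(name=name, label=label)
        else:
            cat[name] = SASModelSpec(
                name=name,
                label=label,
                params=tuple(schema["params"]),
                anisotropic="kernel_aniso" in schema,
                kernel_iso=schema.get("kernel_iso"),
                kernel_aniso=schema.get("kernel_aniso"),
            )
    return cat


_CATALOGUE: dict[str, SASModelSpec] = _build_catalogue()


def list_models() -> list[SASModelSpec]:
    """The full 46-entry catalogue, in label order."""
    return [_CATALOGUE[n] for n in CATALOGUE_NAMES]


def implemented_models() -> list[SASModelSpec]:
    """Catalogue entries that ship with intensity kernels, in label order."""
    return [m for m in list_models() if m.implemented]


def get_model(name: str) -> SASModelSpec:
    """Look up a model by catalogue name (bare shape-name aliases accepted)."""
    name = _ALIASES.get(name, name)
    try:
        return _CATALOGUE[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}") from None


def register_kernel(
    name: str,
    params: Sequence[ModelParam],
    *,
    kernel_iso: Callable | None = None,
    kernel_aniso: Callable | None = None,
) -> SASModelSpec:
    """Attach kernels to a catalogue entry (extension point for the remaining models)."""
    if name not in _CATALOGUE:
        raise KeyError(f"{name!r} is not in the 46-name catalogue")
    spec = SASModelSpec(
        name=name,
        label=_CATALOGUE[name].label,
        params=tuple(params),
        anisotropic=kernel_aniso is not None,
        kernel_iso=kernel_iso,
        kernel_aniso=kernel_aniso,
    )
    _CATALOGUE[name] = spec
    return spec


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def _require_implemented(model: SASModelSpec) -> None:
    if not model.implemented:
        raise UnsupportedOperationError(
            f"model {model.name!r} has no intensity kernel registered"
        )


def resolve_params(model: SASModelSpec, params: dict[str, float] | None) -> dict[str, float]:
    """Merge user parameters over defaults and validate names and bounds."""
    _require_implemented(model)
    full = model.defaults()
    for k, v in (params or {}).items():
        if k not in full:
            raise ValidationError(f"unknown parameter {k!r} for model {model.name!r}")
        full[k] = float(v)
    for p in model.params:
        v = full[p.name]
        if not (p.lb <= v <= p.ub) or not np.isfinite(v):
            raise ValidationError(
                f"parameter {p.name!r}={v} out of bounds [{p.lb}, {p.ub}] "
                f"for model {model.name!r}"
            )
    return full


def _check_q_positive(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise DomainError("q must be strictly positive")
    return q


def evaluate_Iq(
    model: SASModelSpec | str,
    params: dict[str, float] | None = None,
    q=1e-2,
    *,
    n_nodes: int = 76,
):
    """1-D intensity I(q). Anisotropic models are orientation-averaged."""
    model = get_model(model) if isinstance(model, str) else model
    full = resolve_params(model, params)
    q = _check_q_positive(q)
    if model.kernel_iso is not None:
        return model.kernel_iso(q, **full)
    return orientation_average(model, full, q, n_nodes=n_nodes)


def evaluate_Iqxy(
    model: SASModelSpec | str,
    params: dict[str, float] | None = None,
    qx=0.0,
    qy=1e-2,
):
    """2-D intensity at (qx, qy) for the fixed orientation carried in ``params``."""
    model = get_model(model) if isinstance(model, str) else model
    _require_implemented(model)
    if not model.anisotropic:
        raise UnsupportedOperationError(
            f"model {model.name!r} is isotropic; use evaluate_Iq"
        )
    full = resolve_params(model, params)
    qx = np.asarray(qx, dtype=float)
    qy = np.asarray(qy, dtype=float)
    return model.kernel_aniso(qx, qy, **full)


def orientation_average(
    model: SASModelSpec | str,
    params: dict[str, float] | None = None,
    q=1e-2,
    n_nodes: int = 76,
    *,
    direction: float = 0.0,
):
    """Uniform-over-sphere orientation average of the 2-D kernel, as I(q).

    Gauss-Legendre nodes in cos(theta_axis) crossed with a uniform azimuthal
    grid; a cross-section rotation angle (``psi``) gets its own independent
    uniform grid. ``direction`` is the in-plane angle of the q vector — the
    average must not depend on it, which the tests exercise.
    """
    model = get_model(model) if isinstance(model, str) else model
    if not model.anisotropic:
        return evaluate_Iq(model, params, q)
    if n_nodes < 8:
        raise ValidationError("n_nodes must be >= 8")
    full = resolve_params(model, params)
    q = _check_q_positive(np.atleast_1d(q))

    u, w = np.polynomial.legendre.leggauss(n_nodes)
    phi = (np.arange(n_nodes) + 0.5) * (2.0 * np.pi / n_nodes)
    pp = dict(full)
    pp["theta"] = np.arccos(u)[:, None, None, None]       # (n, 1, 1, 1)
    pp["phi"] = phi[None, :, None, None]                  # (1, n, 1, 1)
    if "psi" in pp:
        pp["psi"] = phi[None, None, :, None]              # independent angle
    qv = q[None, None, None, :]
    I = model.kernel_aniso(qv * math.cos(direction), qv * math.sin(direction), **pp)
    avg = np.einsum("i,ik->k", w, I.mean(axis=(1, 2))) / w.sum()
    return avg if avg.size > 1 else float(avg[0])


def draw_polydisperse(
    model: SASModelSpec,
    params: dict[str, float],
    poly: PolydispersitySpec,
    n_draws: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-draw parameter arrays: positive-truncated Gaussian sizes, uniform angles."""
    poly.validate_against(model, params)
    out: dict[str, np.ndarray] = {}
    for name, dr in poly.dr.items():
        r = params[name]
        if dr == 0:
            continue
        draws = rng.normal(r, dr, size=n_draws)
        bad = draws <= 0
        while np.any(bad):          # rejection: re-draw until positive
            draws[bad] = rng.normal(r, dr, size=int(bad.sum()))
            bad = draws <= 0
        out[name] = draws
    for name, dth in poly.dtheta.items():
        if dth == 0:
            continue
        c = params[name]
        out[name] = rng.uniform(c - dth, c + dth, size=n_draws)
    return out


def polydisperse_average(
    model: SASModelSpec | str,
    params: dict[str, float] | None,
    poly: PolydispersitySpec,
    q_points,
    n_draws: int = 10_000,
    seed: int | None = 0,
    *,
    return_se: bool = False,
):
    """Monte-Carlo intensity average over size and orientation distributions.

    ``q_points`` is a 1-D |q| array for isotropic models or an ``(qx, qy)``
    pair of arrays for anisotropic ones. With all spreads zero this reduces
    exactly to the monodisperse evaluation. Deterministic given ``seed``.
    """
    model = get_model(model) if isinstance(model, str) else model
    full = resolve_params(model, params)
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    poly.validate_against(model, full)

    if model.anisotropic:
        qx, qy = (np.asarray(a, dtype=float) for a in q_points)
    else:
        q = _check_q_positive(np.atleast_1d(q_points))

    if poly.is_monodisperse:
        if model.anisotropic:
            val = model.kernel_aniso(qx, qy, **full)
        else:
            val = model.kernel_iso(q, **full)
        return (val, np.zeros_like(np.asarray(val, dtype=float))) if return_se else val

    rng = np.random.default_rng(seed)
    draws = draw_polydisperse(model, full, poly, n_draws, rng)
    pp = {k: (draws[k][:, None] if k in draws else v) for k, v in full.items()}
    if model.anisotropic:
        I = model.kernel_aniso(qx.ravel()[None, :], qy.ravel()[None, :], **pp)
        mean = I.mean(axis=0).reshape(np.shape(qx))
        se = (I.std(axis=0, ddof=1) / np.sqrt(n_draws)).reshape(np.shape(qx)) \
            if n_draws > 1 else np.zeros(np.shape(qx))
    else:
        I = model.kernel_iso(q[None, :], **pp)
        mean = I.mean(axis=0)
        se = I.std(axis=0, ddof=1) / np.sqrt(n_draws) if n_draws > 1 else np.zeros_like(mean)
    return (mean, se) if return_se else mean


def sampling_bounds(model: SASModelSpec | str) -> dict[str, tuple[float, float]]:
    """Per-parameter LHS interval [max(-3 p0, lb), min(3 p0, ub)].

    This is the bounds rule used to build the virtual-experiment sweep: the
    SasView default p0 is the centre of the sampling region. For positive p0
    with lb >= 0 the interval collapses to [lb, min(3 p0, ub)].
    """
    model = get_model(model) if isinstance(model, str) else model
    _require_implemented(model)
    out = {}
    for p in model.params:
        lo = max(-3.0 * p.default, p.lb)
        hi = min(3.0 * p.default, p.ub)
        if lo > hi:
            raise ConfigurationError(
                f"empty sampling interval for {p.name!r} of {model.name!r}: "
                f"[{lo}, {hi}]"
            )
        out[p.name] = (lo, hi)
    return out


def catalogue_to_json(path=None) -> str:
    """Export the catalogue (names, labels, schemas, bounds) as a JSON document."""
    doc = []
    for m in list_models():
        entry: dict = {
            "name": m.name,
            "label": m.label,
            "anisotropic": m.anisotropic,
            "implemented": m.implemented,
        }
        if m.implemented:
            entry["params"] = [
                {
                    "name": p.name,
                    "default": p.default,
                    "lb": None if math.isinf(p.lb) else p.lb,
                    "ub": None if math.isinf(p.ub) else p.ub,
                    "unit": p.unit,
                    "kind": p.kind,
                }
                for p in m.params
            ]
            entry["sampling_bounds"] = {
                k: list(v) for k, v in sampling_bounds(m).items()
            }
        doc.append(entry)
    text = json.dumps(doc, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
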