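"""Form-factor catalogue and kernel tests against independent numerical oracles."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import gamma, spherical_jn
from scipy.stats import norm

from sansml import models as M
from sansml.exceptions import (
    ConfigurationError,
    DomainError,
    UnsupportedOperationError,
    ValidationError,
)


class TestCatalogue:
    def test_full_catalogue_is_lexicographic_bijection(self):
        cat = M.list_models()
        names = [m.name for m in cat]
        assert len(names) == 46
        assert names == sorted(names)
        assert len(set(names)) == 46
        assert [m.label for m in cat] == list(range(46))

    @pytest.mark.parametrize(
        "name,label",
        [
            ("adsorbed layer", 0),
            ("barbell aniso", 1),
            ("bcc paracrystal aniso", 2),
            ("broad peak", 4),
            ("core shell cylinder aniso", 9),
            ("core shell sphere", 12),
            ("cylinder aniso", 13),
            ("dab", 14),
            ("ellipsoid aniso", 15),
            ("elliptical cylinder aniso", 16),
            ("fractal", 19),
            ("fuzzy sphere", 21),
            ("mass fractal", 29),
            ("mono gauss coil", 30),
            ("polymer micelle", 35),
            ("sphere", 39),
            ("star polymer", 42),
            ("teubner strey", 44),
        ],
    )
    def test_published_class_labels(self, name, label):
        """Labels must match the published classification-report table."""
        assert M.get_model(name).label == label

    def test_required_models_implemented(self):
        names = {m.name for m in M.implemented_models()}
        required_iso = {
            "sphere", "fuzzy sphere", "core shell sphere", "mono gauss coil",
            "dab", "broad peak", "teubner strey", "mass fractal", "fractal",
        }
        required_aniso = {
            "cylinder aniso", "elliptical cylinder aniso", "ellipsoid aniso",
            "core shell cylinder aniso",
        }
        assert required_iso <= names
        assert required_aniso <= names
        assert len(names) >= 12
        for n in required_aniso:
            assert M.get_model(n).anisotropic

    def test_bare_shape_aliases(self):
        assert M.get_model("cylinder").name == "cylinder aniso"
        assert M.get_model("ellipsoid").label == 15

    def test_catalogue_json_roundtrip(self, tmp_path):
        import json

        path = tmp_path / "catalogue.json"
        M.catalogue_to_json(path)
        doc = json.loads(path.read_text())
        assert len(doc) == 46
        sphere = next(e for e in doc if e["name"] == "sphere")
        assert sphere["label"] == 39
        assert any(p["name"] == "radius" for p in sphere["params"])


class TestIsotropicKernels:
    def test_sphere_zero_contrast_gives_background(self):
        v = M.evaluate_Iq("sphere", {"sld": 2.0, "sld_solvent": 2.0, "background": 0.25},
                          np.array([0.001, 0.01, 0.1]))
        assert np.allclose(v, 0.25)

    def test_sphere_first_minimum_at_root_of_tan(self):
        """First zero of the sphere amplitude sits at qR = 4.4934 (tan x = x)."""
        from scipy.optimize import brentq

        R = 50.0
        x0 = brentq(lambda x: np.tan(x) - x, 3.5, 4.6)
        assert x0 == pytest.approx(4.493409, abs=1e-5)
        I = M.evaluate_Iq("sphere", {"radius": R, "background": 0.0}, x0 / R)
        peak = M.evaluate_Iq("sphere", {"radius": R, "background": 0.0}, 1e-4)
        assert I / peak < 1e-12

    def test_debye_function_value(self):
        """P(x) = 2 e^-1 at x = (q Rg)^2 = 1."""
        v = M.evaluate_Iq(
            "mono gauss coil",
            {"scale": 1.0, "background": 0.0, "i_zero": 1.0, "rg": 1.0},
            1.0,
        )
        assert v == pytest.approx(2 * math.exp(-1), rel=1e-12)

    def test_dab_low_q_limit(self):
        v = M.evaluate_Iq("dab", {"scale": 1.0, "background": 0.5, "cor_length": 50.0}, 1e-9)
        assert v == pytest.approx(50.0**3 + 0.5, rel=1e-9)

    @pytest.mark.parametrize("name", [m.name for m in M.implemented_models() if not m.anisotropic])
    def test_kernel_matches_independent_oracle(self, name):
        """Each 1-D kernel agrees with a separately-written reference to < 1e-6."""
        q = np.logspace(-3, -0.5, 20)
        spec = M.get_model(name)
        p = M.resolve_params(spec, {"background": 0.0})
        I = spec.kernel_iso(q, **p)
        oracle = _oracle_1d(name, q, p)
        assert np.all(np.abs(I / oracle - 1) < 1e-6)


def _sphere_amp(q, R):
    # independent formulation via the spherical Bessel function j1
    x = q * R
    return 3.0 * spherical_jn(1, x) / x


def _oracle_1d(name, q, p):
    """Reference intensities written independently of the package kernels."""
    if name == "sphere":
        V = 4 / 3 * np.pi * p["radius"] ** 3
        return p["scale"] / V * (V * (p["sld"] - p["sld_solvent"]) * _sphere_amp(q, p["radius"])) ** 2
    if name == "fuzzy sphere":
        V = 4 / 3 * np.pi * p["radius"] ** 3
        amp = V * (p["sld"] - p["sld_solvent"]) * _sphere_amp(q, p["radius"]) * np.exp(
            -0.5 * (p["fuzziness"] * q) ** 2
        )
        return p["scale"] / V * amp**2
    if name == "core shell sphere":
        rc, rs = p["radius"], p["radius"] + p["thickness"]
        Vc, Vs = 4 / 3 * np.pi * rc**3, 4 / 3 * np.pi * rs**3
        amp = Vc * (p["sld_core"] - p["sld_shell"]) * _sphere_amp(q, rc) + Vs * (
            p["sld_shell"] - p["sld_solvent"]
        ) * _sphere_amp(q, rs)
        return p["scale"] / Vs * amp**2
    if name == "mono gauss coil":
        # Debye function via its integral representation 2 int_0^1 (1-t) e^{-xt} dt
        out = []
        for x in (q * p["rg"]) ** 2:
            val, _ = integrate.quad(lambda t: 2 * (1 - t) * np.exp(-x * t), 0, 1)
            out.append(val)
        return p["scale"] * p["i_zero"] * np.array(out)
    if name == "dab":
        # intensity is the 3-D Fourier transform of the correlation function
        # exp(-r/L); the transform at q = 0 equals int r^2 e^{-r/L} dr = 2 L^3,
        # so the normalised shape starts at L^3 like the closed form
        L = p["cor_length"]
        out = []
        for qq in q:
            val, _ = integrate.quad(
                lambda r: r**2 * np.exp(-r / L) * np.sinc(qq * r / np.pi), 0, 60 * L, limit=400
            )
            out.append(val / 2.0)
        return p["scale"] * np.array(out)
    if name == "broad peak":
        return p["scale"] * (
            p["porod_scale"] * q ** (-p["porod_exp"])
            + p["lorentz_scale"]
            / (1 + (np.abs(q - p["peak_pos"]) * p["lorentz_length"]) ** p["lorentz_exp"])
        )
    if name == "teubner strey":
        # numerical FT of gamma(r) = e^{-r/xi} sin(kr)/(kr)
        k, xi = 2 * np.pi / p["d"], p["xi"]
        out = []
        for qq in q:
            val, _ = integrate.quad(
                lambda r: 4 * np.pi * r**2 * np.exp(-r / xi) * np.sinc(k * r / np.pi)
                * np.sinc(qq * r / np.pi),
                0,
                80 * xi,
                limit=800,
            )
            out.append(val)
        ana = p["scale"] * (8 * np.pi / xi) / (
            ((k**2 + xi**-2) ** 2) + (2 * xi**-2 - 2 * k**2) * q**2 + q**4
        )
        # the FT carries a different constant prefactor; compare shapes
        ratio = np.array(out) / ana
        assert np.all(np.abs(ratio / ratio[0] - 1) < 1e-6)
        return ana
    if name == "mass fractal":
        D, z, R = p["fractal_dim_mass"], p["cutoff_length"], p["radius"]
        S = (
            gamma(D - 1)
            * z ** (D - 1)
            * (1 + (q * z) ** 2) ** (-(D - 1) / 2)
            * np.sin((D - 1) * np.arctan(q * z))
            / q
        )
        return p["scale"] * _sphere_amp(q, R) ** 2 * S
    if name == "fractal":
        D, xi, R = p["fractal_dim"], p["cor_length"], p["radius"]
        S = 1 + D * gamma(D - 1) * np.sin((D - 1) * np.arctan(q * xi)) / (
            (q * R) ** D * (1 + (q * xi) ** -2) ** ((D - 1) / 2)
        )
        V = 4 / 3 * np.pi * R**3
        P = p["volfraction"] * V * (p["sld_block"] - p["sld_solvent"]) ** 2 * _sphere_amp(q, R) ** 2
        return p["scale"] * P * S
    raise KeyError(name)


class TestAnisotropicKernels:
    def test_beam_axis_orientation_is_azimuthally_symmetric(self):
        p = {"background": 0.0, "theta": 0.0, "phi": 0.0}
        a = M.evaluate_Iqxy("cylinder aniso", p, 0.01, 0.0)
        b = M.evaluate_Iqxy("cylinder aniso", p, 0.0, 0.01)
        c = M.evaluate_Iqxy("cylinder aniso", p, 0.01 / np.sqrt(2), 0.01 / np.sqrt(2))
        assert a == pytest.approx(b, rel=1e-10)
        assert a == pytest.approx(c, rel=1e-10)

    @pytest.mark.parametrize(
        "name", ["cylinder aniso", "elliptical cylinder aniso", "ellipsoid aniso",
                 "core shell cylinder aniso"]
    )
    def test_inversion_symmetry(self, name):
        """Elastic scattering satisfies I(q) = I(-q)."""
        a = M.evaluate_Iqxy(name, {"background": 0.0}, 0.013, -0.007)
        b = M.evaluate_Iqxy(name, {"background": 0.0}, -0.013, 0.007)
        assert a == pytest.approx(b, rel=1e-12)

    def test_cylinder_matches_quadrature_amplitude(self):
        """|A|^2 with A = 2 rho V sinc(qL cos(a)/2) J1(qR sin(a))/(qR sin(a))."""
        from scipy.special import j1

        R, L, drho = 20.0, 400.0, 3.0
        params = {"radius": R, "length": L, "sld": 4.0, "sld_solvent": 1.0,
                  "background": 0.0, "theta": np.pi / 3, "phi": 0.2}
        qx, qy = 0.012, -0.004
        got = M.evaluate_Iqxy("cylinder aniso", params, qx, qy)
        # independent geometry: cos(alpha) between in-plane q and the axis
        q = np.hypot(qx, qy)
        n = np.array([np.sin(np.pi / 3) * np.cos(0.2), np.sin(np.pi / 3) * np.sin(0.2),
                      np.cos(np.pi / 3)])
        ca = (qx * n[0] + qy * n[1]) / q
        sa = np.sqrt(1 - ca**2)
        V = np.pi * R**2 * L
        arg1, arg2 = q * L * ca / 2, q * R * sa
        A = drho * V * (np.sin(arg1) / arg1) * (2 * j1(arg2) / arg2)
        assert got == pytest.approx(A**2 / V, rel=1e-10)

    def test_elliptical_cylinder_reduces_to_cylinder(self):
        p = {"background": 0.0, "axis_ratio": 1.0, "theta": 0.7, "phi": 0.3, "psi": 2.0,
             "radius_minor": 20.0, "length": 400.0}
        ec = M.evaluate_Iqxy("elliptical cylinder aniso", p, 0.01, 0.004)
        cy = M.evaluate_Iqxy(
            "cylinder aniso",
            {"background": 0.0, "theta": 0.7, "phi": 0.3, "radius": 20.0, "length": 400.0},
            0.01, 0.004,
        )
        assert ec == pytest.approx(cy, rel=1e-10)

    def test_iqxy_on_isotropic_model_is_rejected(self):
        with pytest.raises(UnsupportedOperationError):
            M.evaluate_Iqxy("sphere", {}, 0.01, 0.0)


class TestOrientationAverage:
    def test_isotropic_input_passthrough(self):
        q = np.array([0.01, 0.05])
        assert np.allclose(
            M.orientation_average("sphere", {"background": 0.0}, q),
            M.evaluate_Iq("sphere", {"background": 0.0}, q),
        )

    def test_cylinder_average_matches_monte_carlo(self):
        """Gauss-Legendre orientation average vs brute-force MC within 3 SE."""
        q = np.array([0.005, 0.01, 0.03, 0.08, 0.2])
        avg = M.orientation_average("cylinder aniso", {"background": 0.0}, q, n_nodes=256)
        spec = M.get_model("cylinder aniso")
        full = M.resolve_params(spec, {"background": 0.0})
        g = np.random.default_rng(0)
        n = 200_000
        th = np.arccos(g.uniform(-1, 1, n))
        ph = g.uniform(0, 2 * np.pi, n)
        for i, qq in enumerate(q):
            pp = dict(full, theta=th, phi=ph)
            I = spec.kernel_aniso(np.full(n, qq), np.zeros(n), **pp)
            se = I.std() / np.sqrt(n)
            assert abs(avg[i] - I.mean()) < 3 * se

    def test_node_doubling_converged(self):
        q = np.array([0.005, 0.03, 0.08])
        a = M.orientation_average("cylinder aniso", {"background": 0.0}, q, n_nodes=256)
        b = M.orientation_average("cylinder aniso", {"background": 0.0}, q, n_nodes=512)
        assert np.all(np.abs(a / b - 1) < 1e-3)

    def test_orientation_average_is_azimuthally_symmetric(self):
        """Full-sphere averaging must erase any (qx, qy) direction preference."""
        q = 0.02
        for name in ("cylinder aniso", "ellipsoid aniso", "elliptical cylinder aniso",
                     "core shell cylinder aniso"):
            vals = [
                M.orientation_average(name, {"background": 0.0}, q, n_nodes=128,
                                      direction=ang)
                for ang in (0.0, 0.7, 1.9)
            ]
            assert np.all(np.abs(np.array(vals) / vals[0] - 1) < 0.005), name


class TestPolydispersity:
    def test_zero_spread_reduces_to_monodisperse(self):
        q = np.array([0.005, 0.02, 0.08])
        poly = M.PolydispersitySpec(dr={"radius": 0.0})
        a = M.polydisperse_average("sphere", {"radius": 60.0}, poly, q, n_draws=100, seed=1)
        b = M.evaluate_Iq("sphere", {"radius": 60.0}, q)
        assert np.array_equal(a, b)

    def test_size_spread_fills_in_the_first_minimum(self):
        """A 10 A spread on R = 60 A lifts I at the sharp minimum; the MC mean
        agrees with deterministic quadrature over the truncated Gaussian."""
        q0 = 4.4934 / 60.0
        params = {"radius": 60.0, "background": 0.0}
        mono = M.evaluate_Iq("sphere", params, q0)
        mc, se = M.polydisperse_average(
            "sphere", params, M.PolydispersitySpec(dr={"radius": 10.0}),
            np.array([q0]), n_draws=50_000, seed=3, return_se=True,
        )
        assert mc[0] > mono
        spec = M.get_model("sphere")
        full = M.resolve_params(spec, params)
        Z = 1 - norm.cdf(0, 60, 10)

        def integrand(r):
            return spec.kernel_iso(q0, **dict(full, radius=r)) * norm.pdf(r, 60, 10) / Z

        quad, _ = integrate.quad(integrand, 1e-6, 200)
        assert abs(mc[0] - quad) < 3 * se[0]

    def test_seeded_determinism(self):
        poly = M.PolydispersitySpec(dr={"radius": 20.0})
        q = np.array([0.01, 0.03])
        a = M.polydisperse_average("sphere", {"radius": 60.0}, poly, q, n_draws=500, seed=9)
        b = M.polydisperse_average("sphere", {"radius": 60.0}, poly, q, n_draws=500, seed=9)
        assert np.array_equal(a, b)

    def test_spread_cap_enforced(self):
        with pytest.raises(ValidationError):
            M.polydisperse_average(
                "sphere", {"radius": 60.0}, M.PolydispersitySpec(dr={"radius": 40.0}),
                np.array([0.01]), n_draws=10, seed=0,
            )


class TestSamplingBounds:
    def test_printed_bounds_formula(self):
        """p0 = 60, lb = 1, ub large -> [1, 180]."""
        b = M.sampling_bounds("fuzzy sphere")
        assert b["radius"] == (1.0, 180.0)

    def test_upper_clamp(self):
        b = M.sampling_bounds("broad peak")
        assert b["peak_pos"][1] == pytest.approx(0.3)   # 3 * 0.1 < ub = 2
        assert b["lorentz_exp"] == (0.5, 6.0)           # clamped at ub

    def test_empty_interval_is_configuration_error(self):
        spec = M.register_kernel(
            "power law",
            [M.ModelParam("slope", 0.0, 1.0, 10.0, "", "dimensionless")],
            kernel_iso=lambda q, slope: q**0.0,
        )
        try:
            with pytest.raises(ConfigurationError):
                M.sampling_bounds(spec)
        finally:
            # restore the placeholder entry
            M._CATALOGUE["power law"] = M.SASModelSpec("power law", spec.label)

    def test_out_of_bounds_parameter_names_offender(self):
        with pytest.raises(ValidationError, match="radius"):
            M.evaluate_Iq("sphere", {"radius": -5.0}, 0.01)

    def test_negative_q_rejected(self):
        with pytest.raises(DomainError):
            M.evaluate_Iq("sphere", {}, -0.01)


class TestNonNegativity:
    @pytest.mark.parametrize("spec", M.implemented_models(), ids=lambda m: m.name)
    def test_kernels_non_negative_over_lhs_draws(self, spec, rng):
        """I >= 0 and finite over a 100-point q grid x 50 in-bounds draws."""
        bounds = M.sampling_bounds(spec)
        q = np.logspace(-3, 0, 100)
        for _ in range(50):
            params = {k: rng.uniform(lo, hi) for k, (lo, hi) in bounds.items()}
            full = M.resolve_params(spec, params)
            I = (
                spec.kernel_aniso(q, 0.4 * q, **full)
                if spec.anisotropic
                else spec.kernel_iso(q, **full)
            )
            assert np.all(np.isfinite(I))
            assert np.all(I >= 0)
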