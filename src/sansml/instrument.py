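"""Simplified Monte-Carlo virtual KWS-1 beamline.

The real instrument is a classic pinhole SANS camera: velocity selector,
collimation defined by two slit apertures, sample, evacuated flight tube and a
144 x 256 position-sensitive detector behind a beamstop. The simulator here
keeps exactly the pieces that shape a small-angle pattern — wavelength band,
two-slit divergence, per-event polydispersity/orientation draws, solid-angle
weighting and the beamstop shadow — and drops guide transport, gravity and
detector imperfections.

Every neutron is forced to scatter (importance sampling): the outgoing
direction is drawn uniformly over the detector area and the event deposits a
weight proportional to I(q) * dOmega * (1 - absorption) in the pixel it hits.
This is the standard variance-reduction trick of ray-tracing SANS simulations
and makes the azimuthal average of the accumulated image converge to the
instrument-smeared 1-D intensity.

Geometry conventions: beam along +z; the first image axis (144 pixels) is the
horizontal detector coordinate x, the second (256 pixels) vertical y; beam
centre at pixel (71.5, 127.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import json
import numpy as np
from scipy.stats import chi2 as _chi2

from .exceptions import ConfigurationError, ValidationError
from .models import (
    PolydispersitySpec,
    SASModelSpec,
    draw_polydisperse,
    get_model,
    resolve_params,
)

__all__ = [
    "SlitSetting",
    "InstrumentConfig",
    "QCalibration",
    "DetectorImage",
    "SLIT_SETTINGS",
    "enumerate_configs",
    "get_config",
    "pixel_to_q",
    "q_grid",
    "beamstop_mask",
    "simulate_pattern",
    "azimuthal_average",
    "azimuthal_uniformity",
    "beam_divergence_width",
    "configs_to_json",
]

N_ROWS, N_COLS = 144, 256


@dataclass(frozen=True)
class SlitSetting:
    """One of the three collimation-slit options (apertures in metres)."""

    slit_id: int
    aperture_h: float   # horizontal full width of both slit openings [m]
    aperture_v: float   # vertical full width [m]
    cell_mm: float      # width of the sample (Hellma) cell [mm], metadata


#: S1: 1.0 x 1.0 cm apertures + 2 cm cell; S2: 1.2 x 1.2 cm + 2 cm cell;
#: S3: 0.7 cm horizontal x 1.0 cm vertical + 1 cm cell.
SLIT_SETTINGS: tuple[SlitSetting, ...] = (
    SlitSetting(0, 0.010, 0.010, 20.0),
    SlitSetting(1, 0.012, 0.012, 20.0),
    SlitSetting(2, 0.007, 0.010, 10.0),
)

_WAVELENGTHS = (4.5, 6.0)                      # Angstrom
_DISTANCES = ((8.0, 1.0), (8.0, 8.0), (20.0, 20.0))   # (collimation, SDD) [m]
_HOLDERS = (1.0, 2.0)                          # mm


@dataclass(frozen=True)
class InstrumentConfig:
    """One discrete KWS-1 setting plus fixed detector geometry.

    The pixel pitch (5.25 mm), beamstop (4 x 4 cm) and triangular wavelength
    band (10% FWHM) are documented defaults, not published values, and can be
    overridden via :func:`dataclasses.replace`.
    """

    config_id: int
    wavelength_A: float
    collimation_m: float
    sdd_m: float
    slit: SlitSetting
    holder_mm: float
    wavelength_fwhm: float = 0.10      # fractional FWHM of the selector band
    pixel_mm: float = 5.25
    beamstop_m: tuple[float, float] = (0.04, 0.04)

    def __post_init__(self) -> None:
        for name in ("wavelength_A", "collimation_m", "sdd_m", "pixel_mm", "holder_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")

    @property
    def key(self) -> tuple:
        return (self.wavelength_A, self.collimation_m, self.sdd_m,
                self.slit.slit_id, self.holder_mm)

    def calibration(self) -> "QCalibration":
        return QCalibration(
            wavelength_A=self.wavelength_A,
            sdd_m=self.sdd_m,
            pixel_m=self.pixel_mm * 1e-3,
            beam_center=((N_ROWS - 1) / 2.0, (N_COLS - 1) / 2.0),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "config_id": self.config_id,
            "wavelength_A": self.wavelength_A,
            "collimation_m": self.collimation_m,
            "sdd_m": self.sdd_m,
            "slit_id": self.slit.slit_id,
            "holder_mm": self.holder_mm,
        }


def enumerate_configs(**overrides) -> list[InstrumentConfig]:
    """The 36 = 2 x 3 x 3 x 2 discrete instrument settings, in a fixed order.

    Wavelength varies outermost, then (collimation, SDD) pair, then slit
    setting, then holder thickness innermost; ``config_id`` is the position in
    this order. Keyword overrides (e.g. ``wavelength_fwhm=0``) are applied to
    every configuration.
    """
    out = []
    cid = 0
    for wl in _WAVELENGTHS:
        for coll, sdd in _DISTANCES:
            for slit in SLIT_SETTINGS:
                for holder in _HOLDERS:
                    out.append(
                        InstrumentConfig(
                            config_id=cid,
                            wavelength_A=wl,
                            collimation_m=coll,
                            sdd_m=sdd,
                            slit=slit,
                            holder_mm=holder,
                            **overrides,
                        )
                    )
                    cid += 1
    return out


def get_config(config_id: int, **overrides) -> InstrumentConfig:
    configs = enumerate_configs(**overrides)
    if not 0 <= config_id < len(configs):
        raise ConfigurationError(f"config_id must be in 0..35, got {config_id}")
    return configs[config_id]


@dataclass(frozen=True)
class QCalibration:
    """Pixel -> scattering-vector calibration for one detector distance."""

    wavelength_A: float
    sdd_m: float
    pixel_m: float
    beam_center: tuple[float, float]

    def xy(self, row, col):
        """In-plane detector coordinates [m] of pixel centres."""
        x = (np.asarray(row, dtype=float) - self.beam_center[0]) * self.pixel_m
        y = (np.asarray(col, dtype=float) - self.beam_center[1]) * self.pixel_m
        return x, y


def pixel_to_q(cal: QCalibration, row, col):
    """(qx, qy, |q|) in 1/Angstrom at the given pixel(s).

    theta = atan(r / SDD), |q| = (4 pi / lambda) sin(theta / 2), with (qx, qy)
    along the detector axes.
    """
    x, y = cal.xy(row, col)
    r = np.hypot(x, y)
    theta = np.arctan2(r, cal.sdd_m)
    qmag = 4.0 * np.pi / cal.wavelength_A * np.sin(theta / 2.0)
    rsafe = np.where(r == 0, 1.0, r)
    qx = np.where(r == 0, 0.0, qmag * x / rsafe)
    qy = np.where(r == 0, 0.0, qmag * y / rsafe)
    return qx, qy, qmag


def q_grid(cal: QCalibration):
    """Full-detector (qx, qy, |q|) grids of shape (144, 256)."""
    rows = np.arange(N_ROWS)[:, None]
    cols = np.arange(N_COLS)[None, :]
    return pixel_to_q(cal, rows, cols)


def beamstop_mask(config: InstrumentConfig) -> np.ndarray:
    """Boolean (144, 256) array, True where the beamstop shadows the detector."""
    cal = config.calibration()
    x, y = cal.xy(np.arange(N_ROWS)[:, None], np.arange(N_COLS)[None, :])
    bw, bh = config.beamstop_m
    return (np.abs(x) <= bw / 2.0) & (np.abs(y) <= bh / 2.0)


@dataclass
class DetectorImage:
    """Accumulated detector counts with full generation provenance.

    ``variance`` carries the per-pixel sum of squared event weights, i.e. the
    Monte-Carlo variance estimate of each pixel total.
    """

    counts: np.ndarray
    variance: np.ndarray
    model: str
    label: int
    params: dict[str, float]
    poly: PolydispersitySpec
    absorption: float
    config_id: int
    n_neutrons: int
    seed: int

    def __post_init__(self) -> None:
        if self.counts.shape != (N_ROWS, N_COLS):
            raise ValidationError(f"counts must be {(N_ROWS, N_COLS)}, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValidationError("detector counts must be non-negative")


def _triangular_wavelength(rng, wl0, fwhm_frac, n):
    # symmetric triangular band: FWHM of a triangle of half-width w is w
    w = fwhm_frac * wl0
    if w == 0:
        return np.full(n, wl0)
    return rng.triangular(wl0 - w, wl0, wl0 + w, size=n)


def simulate_pattern(
    model: SASModelSpec | str,
    params: dict[str, float] | None = None,
    poly: PolydispersitySpec | None = None,
    absorption: float = 0.0,
    config: InstrumentConfig | None = None,
    n_neutrons: int = 100_000,
    seed: int = 0,
    *,
    chunk: int = 250_000,
) -> DetectorImage:
    """Monte-Carlo detector image for one sample under one instrument setting.

    Per event: a wavelength from the triangular selector band, entry/exit
    points uniform in the two slit apertures (fixing the incident direction),
    fresh polydisperse sizes / orientation angles, and a forced-scattering
    direction uniform over the detector area with importance weight
    I(q) * dOmega * (1 - absorption). Deterministic given ``seed``.
    """
    model = get_model(model) if isinstance(model, str) else model
    full = resolve_params(model, params)
    poly = poly or PolydispersitySpec()
    poly.validate_against(model, full)
    if config is None:
        config = get_config(0)
    if n_neutrons < 0:
        raise ValidationError("n_neutrons must be >= 0")
    if not 0.0 <= absorption < 1.0:
        raise ValidationError("absorption must be in [0, 1)")

    rng = np.random.default_rng(seed)
    counts = np.zeros(N_ROWS * N_COLS)
    sumsq = np.zeros(N_ROWS * N_COLS)

    pitch = config.pixel_mm * 1e-3
    half_w = N_ROWS * pitch / 2.0
    half_h = N_COLS * pitch / 2.0
    area = (N_ROWS * pitch) * (N_COLS * pitch)
    sdd = config.sdd_m
    coll = config.collimation_m
    ah, av = config.slit.aperture_h, config.slit.aperture_v

    remaining = int(n_neutrons)
    while remaining > 0:
        n = min(remaining, chunk)
        remaining -= n

        wl = _triangular_wavelength(rng, config.wavelength_A, config.wavelength_fwhm, n)
        # two-slit collimation: entry in slit 1 (z = -coll), exit in slit 2 (z = 0)
        x1 = rng.uniform(-ah / 2, ah / 2, n)
        y1 = rng.uniform(-av / 2, av / 2, n)
        x2 = rng.uniform(-ah / 2, ah / 2, n)
        y2 = rng.uniform(-av / 2, av / 2, n)
        din = np.stack([(x2 - x1) / coll, (y2 - y1) / coll, np.ones(n)], axis=1)
        din /= np.linalg.norm(din, axis=1, keepdims=True)

        # forced scattering toward a uniform point on the detector
        xd = rng.uniform(-half_w, half_w, n)
        yd = rng.uniform(-half_h, half_h, n)
        dx, dy, dz = xd - x2, yd - y2, np.full(n, sdd)
        dist = np.sqrt(dx**2 + dy**2 + dz**2)
        dout = np.stack([dx / dist, dy / dist, dz / dist], axis=1)

        k = 2.0 * np.pi / wl                       # 1/Angstrom
        qvec = (dout - din) * k[:, None]
        qx, qy = qvec[:, 0], qvec[:, 1]
        qmag = np.maximum(np.linalg.norm(qvec, axis=1), 1e-10)

        draws = draw_polydisperse(model, full, poly, n, rng)
        pp = {name: draws.get(name, value) for name, value in full.items()}
        if model.anisotropic:
            I = model.kernel_aniso(qx, qy, **pp)
        else:
            I = model.kernel_iso(qmag, **pp)

        # dOmega of the sampled area element, relative to uniform-area sampling
        cos_t = dz / dist
        w = I * cos_t**3 * (1.0 - absorption) * (area / sdd**2) / max(n_neutrons, 1)

        row = np.floor(xd / pitch + N_ROWS / 2.0).astype(np.intp)
        col = np.floor(yd / pitch + N_COLS / 2.0).astype(np.intp)
        np.clip(row, 0, N_ROWS - 1, out=row)
        np.clip(col, 0, N_COLS - 1, out=col)
        idx = row * N_COLS + col
        counts += np.bincount(idx, weights=w, minlength=N_ROWS * N_COLS)
        sumsq += np.bincount(idx, weights=w**2, minlength=N_ROWS * N_COLS)

    counts = counts.reshape(N_ROWS, N_COLS)
    sumsq = sumsq.reshape(N_ROWS, N_COLS)
    shadow = beamstop_mask(config)
    counts[shadow] = 0.0
    sumsq[shadow] = 0.0

    return DetectorImage(
        counts=counts,
        variance=sumsq,
        model=model.name,
        label=model.label,
        params=dict(full),
        poly=poly,
        absorption=float(absorption),
        config_id=config.config_id,
        n_neutrons=int(n_neutrons),
        seed=int(seed),
    )


def azimuthal_average(
    image,
    cal: QCalibration,
    n_bins: int = 50,
    *,
    mask: np.ndarray | None = None,
    variance: np.ndarray | None = None,
    q_range: tuple[float, float] | None = None,
):
    """Mean counts per |q| annulus: (q_centres, I, mc_error, n_pixels).

    Masked pixels (beamstop shadow) are excluded; an empty annulus is reported
    with ``n_pixels = 0`` and NaN intensity rather than zero. The error column
    is the Monte-Carlo standard error of the annulus mean, propagated from the
    per-pixel sum of squared weights when available, otherwise estimated from
    the pixel-to-pixel scatter.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if isinstance(image, DetectorImage):
        if variance is None:
            variance = image.variance
        arr = image.counts
        if mask is None:
            mask = beamstop_mask(get_config(image.config_id))
    else:
        arr = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.zeros_like(arr, dtype=bool)

    _, _, qmag = q_grid(cal)
    keep = ~mask
    q = qmag[keep]
    v = arr[keep]
    lo, hi = q_range if q_range is not None else (q.min(), q.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.digitize(q, edges) - 1
    which = np.where(which == n_bins, n_bins - 1, which)  # include right edge
    inside = (which >= 0) & (which < n_bins)

    n_pix = np.bincount(which[inside], minlength=n_bins)
    sums = np.bincount(which[inside], weights=v[inside], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_pix > 0, sums / np.maximum(n_pix, 1), np.nan)

    if variance is not None:
        var = np.bincount(which[inside], weights=variance[keep][inside], minlength=n_bins)
        err = np.sqrt(var) / np.maximum(n_pix, 1)
    else:
        sq = np.bincount(which[inside], weights=v[inside] ** 2, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            pvar = sq / np.maximum(n_pix, 1) - mean**2
        err = np.sqrt(np.maximum(pvar, 0.0) / np.maximum(n_pix, 1))
    err = np.where(n_pix > 0, err, np.nan)
    centres = 0.5 * (edges[:-1] + edges[1:])
    return centres, mean, err, n_pix


def azimuthal_uniformity(
    image,
    cal: QCalibration | None = None,
    n_sectors: int = 12,
    *,
    q_range: tuple[float, float] | None = None,
):
    """Chi-square test of azimuthal uniformity: returns (stat, dof, p-value).

    Pixels in an annulus (by default everything outside 1.5 beamstop
    half-diagonals up to the largest fully-covered radius) are grouped into
    azimuthal sectors. Sector weight totals are compared against pixel-count
    proportions with a chi-square statistic using the effective event count
    n_eff = (sum w)^2 / (sum w^2), so importance-sampled weights behave like
    Poisson counts. Isotropic patterns pass at alpha = 0.01; tightly oriented
    anisotropic ones fail spectacularly.
    """
    if isinstance(image, DetectorImage):
        config = get_config(image.config_id)
        cal = cal or config.calibration()
        arr = image.counts
        var = image.variance
        mask = beamstop_mask(config)
        bs = max(config.beamstop_m) / 2.0
    else:
        if cal is None:
            raise ValidationError("cal required when image is a bare array")
        arr = np.asarray(image, dtype=float)
        var = None
        mask = np.zeros_like(arr, dtype=bool)
        bs = 0.0

    x, y = cal.xy(np.arange(N_ROWS)[:, None], np.arange(N_COLS)[None, :])
    x, y = np.broadcast_arrays(x, y)
    r = np.hypot(x, y)
    r_lo = 1.5 * bs * np.sqrt(2.0)
    r_hi = N_ROWS / 2.0 * cal.pixel_m          # largest fully-covered radius
    if q_range is not None:
        _, _, qmag = q_grid(cal)
        sel = (qmag >= q_range[0]) & (qmag <= q_range[1]) & ~mask
    else:
        sel = (r >= r_lo) & (r <= r_hi) & ~mask

    ang = np.mod(np.arctan2(y[sel], x[sel]), 2.0 * np.pi)
    sector = np.minimum((ang / (2.0 * np.pi) * n_sectors).astype(int), n_sectors - 1)
    w_s = np.bincount(sector, weights=arr[sel], minlength=n_sectors)
    n_s = np.bincount(sector, minlength=n_sectors)
    W = w_s.sum()
    if W <= 0:
        raise ValidationError("no counts in the test annulus")
    if var is not None:
        v_tot = var[sel].sum()
    else:
        v_tot = (arr[sel] ** 2).sum()
    n_eff = W**2 / max(v_tot, 1e-300)
    p_s = n_s / n_s.sum()
    obs = n_eff * w_s / W
    exp = n_eff * p_s
    stat = float(np.sum((obs - exp) ** 2 / np.maximum(exp, 1e-300)))
    dof = n_sectors - 1
    return stat, dof, float(_chi2.sf(stat, dof))


def beam_divergence_width(config: InstrumentConfig, n: int = 100_000, seed: int = 0):
    """(std_x, std_y) [m] of the unscattered direct-beam footprint at the detector.

    Pure two-slit geometry; used to verify that wider apertures strictly widen
    the divergence distribution (instrumental resolution).
    """
    rng = np.random.default_rng(seed)
    ah, av = config.slit.aperture_h, config.slit.aperture_v
    x1 = rng.uniform(-ah / 2, ah / 2, n)
    y1 = rng.uniform(-av / 2, av / 2, n)
    x2 = rng.uniform(-ah / 2, ah / 2, n)
    y2 = rng.uniform(-av / 2, av / 2, n)
    t = config.sdd_m / config.collimation_m
    xd = x2 + (x2 - x1) * t
    yd = y2 + (y2 - y1) * t
    return float(np.std(xd)), float(np.std(yd))


def configs_to_json(path=None, configs=None) -> str:
    """Export the configuration table as JSON (for reproducibility manifests)."""
    configs = configs if configs is not None else enumerate_configs()
    doc = [c.to_dict() for c in configs]
    text = json.dumps(doc, indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
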