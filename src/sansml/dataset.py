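"""Plan and execute the virtual-experiment sweep into an ML-ready dataset.

A sweep is the Cartesian grid (model x LHS parameter point x absorption level
x instrument configuration). Each record is one simulated detector image; the
collection is then cleaned of null / low-statistics / saturated images by the
quantile rules of the original campaign, split label-stratified into train/test/validation
and serialised as HDF5 (root datasets ``data`` and ``target``) with a CSV
metadata sibling, mirroring the layout of the published KWS-1 dataset.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.stats import qmc

from .exceptions import ConfigurationError, DomainError, ValidationError
from .instrument import N_COLS, N_ROWS, InstrumentConfig, enumerate_configs, simulate_pattern
from .models import (
    CATALOGUE_NAMES,
    PolydispersitySpec,
    SASModelSpec,
    get_model,
    implemented_models,
    sampling_bounds,
)

__all__ = [
    "combinatorial_size",
    "lhs_sample",
    "SamplingPlan",
    "ImageCollection",
    "DatasetPartition",
    "generate_dataset",
    "clean_dataset",
    "split_dataset",
    "write_partition",
    "read_partition",
]

log = logging.getLogger(__name__)

#: half-width cap of the orientation-angle uniform window sampled by LHS [rad]
MAX_ANGLE_SPREAD = math.pi


def combinatorial_size(choices) -> int:
    """Number of parameter combinations N = prod(n_i) for n_i choices each.

    With n_i = 2 for 15 parameters this is already 32768, which is why the
    sweep uses latin-hypercube sampling instead of a full grid.
    """
    n = 1
    for c in choices:
        c = int(c)
        if c < 1:
            raise DomainError(f"every choice count must be >= 1, got {c}")
        n *= c
    return n


def lhs_sample(
    model: SASModelSpec | str,
    n_points: int,
    seed: int = 0,
) -> list[tuple[dict[str, float], PolydispersitySpec]]:
    """Latin-hypercube parameter sets for one model.

    Every continuous model parameter is stratified over its sampling interval
    [max(-3 p0, lb), min(3 p0, ub)]; each length parameter r gets an extra
    spread dimension dr in [0, r/2] and each orientation angle a half-width
    dtheta in [0, pi]. Exactly one sample falls in each of the ``n_points``
    equal-width strata of every dimension.
    """
    model = get_model(model) if isinstance(model, str) else model
    if n_points < 1:
        raise ValidationError("n_points must be >= 1")
    bounds = sampling_bounds(model)  # raises ConfigurationError if empty

    names = list(bounds)
    spread_of = {
        p.name: ("dr" if p.kind == "length" else "dtheta")
        for p in model.params
        if p.kind in ("length", "angle")
    }
    dims = names + [f"d:{n}" for n in spread_of]
    sampler = qmc.LatinHypercube(d=len(dims), seed=seed)
    u = sampler.random(n=n_points)

    out = []
    for row in u:
        params = {}
        for j, name in enumerate(names):
            lo, hi = bounds[name]
            params[name] = lo + row[j] * (hi - lo)
        dr, dtheta = {}, {}
        for j, name in enumerate(spread_of, start=len(names)):
            if spread_of[name] == "dr":
                dr[name] = row[j] * params[name] / 2.0
            else:
                dtheta[name] = row[j] * MAX_ANGLE_SPREAD
        out.append((params, PolydispersitySpec(dr=dr, dtheta=dtheta)))
    return out


@dataclass
class SamplingPlan:
    """The full sweep definition.

    Defaults mirror the full-scale campaign: 100 LHS points per model, absorption in
    {0, 10%}, all 36 instrument configurations, 1e7 neutrons per image. The
    ``models`` list holds the implemented subset by default; ``expected_size``
    is pure arithmetic and also works for the full 46-model catalogue.
    """

    models: list[str] = field(default_factory=lambda: [m.name for m in implemented_models()])
    points_per_model: int = 100
    absorption_levels: tuple[float, ...] = (0.0, 0.10)
    configs: list[InstrumentConfig] = field(default_factory=enumerate_configs)
    n_neutrons: int = 10_000_000
    base_seed: int = 0

    @property
    def expected_size(self) -> int:
        return combinatorial_size(
            [
                len(self.models),
                self.points_per_model,
                len(self.absorption_levels),
                len(self.configs),
            ]
        )

    @classmethod
    def full_scale(cls) -> "SamplingPlan":
        """The full KWS-1 sweep arithmetic: 46 x 100 x 2 x 36 = 331,200 records."""
        return cls(models=list(CATALOGUE_NAMES))


def _record_seed(base_seed: int, label: int, point: int, a_idx: int, config_id: int) -> int:
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(label, point, a_idx, config_id))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ImageCollection:
    """Raw or cleaned sweep output: images, integer targets, metadata rows."""

    images: np.ndarray           # (n, 144, 256) float32
    targets: np.ndarray          # (n,) int
    meta: pd.DataFrame           # one row per record

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.targets) == len(self.meta)):
            raise ValidationError("images, targets and metadata must align")

    def __len__(self) -> int:
        return len(self.targets)

    def subset(self, idx) -> "ImageCollection":
        idx = np.asarray(idx)
        return ImageCollection(
            images=self.images[idx],
            targets=self.targets[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )


def _meta_row(model, params, poly, absorption, config, seed, ok=True):
    row = {
        "model": model.name,
        "label": model.label,
        "config_id": config.config_id,
        "wavelength_A": config.wavelength_A,
        "collimation_m": config.collimation_m,
        "sdd_m": config.sdd_m,
        "slit_id": config.slit.slit_id,
        "holder_mm": config.holder_mm,
        "absorption": absorption,
        "seed": seed,
        "ok": bool(ok),
    }
    for k, v in params.items():
        row[f"param:{k}"] = v
    for k, v in {**poly.dr, **poly.dtheta}.items():
        row[f"dparam:{k}"] = v
    return row


def generate_dataset(plan: SamplingPlan, *, log_every: int = 0) -> ImageCollection:
    """Run the sweep: one detector image per grid record.

    Per-record seeds derive deterministically from the base seed and the
    record's grid coordinates, so the sweep is reproducible and trivially
    parallelisable. A failed simulation is flagged in the metadata (``ok``
    column, zero image) rather than silently dropped.
    """
    n_total = plan.expected_size
    images = np.zeros((n_total, N_ROWS, N_COLS), dtype=np.float32)
    targets = np.zeros(n_total, dtype=np.int64)
    rows = []
    i = 0
    for name in plan.models:
        model = get_model(name)
        samples = lhs_sample(model, plan.points_per_model, seed=_record_seed(
            plan.base_seed, model.label, 0, 0, 0))
        for point, (params, poly) in enumerate(samples):
            for a_idx, absorption in enumerate(plan.absorption_levels):
                for config in plan.configs:
                    seed = _record_seed(
                        plan.base_seed, model.label, point, a_idx, config.config_id
                    )
                    ok = True
                    try:
                        img = simulate_pattern(
                            model, params, poly, absorption, config,
                            plan.n_neutrons, seed,
                        )
                        images[i] = img.counts
                    except Exception:  # noqa: BLE001 - flagged, not dropped
                        log.exception("simulation failed for record %d (%s)", i, name)
                        ok = False
                    targets[i] = model.label
                    rows.append(_meta_row(model, params, poly, absorption, config, seed, ok))
                    i += 1
                    if log_every and i % log_every == 0:
                        log.info("generated %d / %d images", i, n_total)
    meta = pd.DataFrame(rows)
    return ImageCollection(images=images, targets=targets, meta=meta)


def clean_dataset(collection: ImageCollection):
    """Quantile cleaning of the raw sweep; returns (filtered, report).

    Three rules, applied in order: (a) drop all-zero images; (b) drop images
    whose pixel standard deviation falls below the empirical 0.02 quantile of
    the remaining per-image standard deviations; (c) drop images whose maximum
    pixel exceeds the 0.99 quantile of per-image maxima. Removal is by strict
    inequality, so ties at the threshold survive.
    """
    if len(collection) == 0:
        raise ValidationError("cannot clean an empty collection")
    imgs = collection.images
    flat = imgs.reshape(len(imgs), -1)
    nonzero = flat.any(axis=1)
    n_zero = int((~nonzero).sum())

    sd = flat.std(axis=1, dtype=np.float64)
    mx = flat.max(axis=1)
    sd_thresh = float(np.quantile(sd[nonzero], 0.02)) if nonzero.any() else 0.0
    low = nonzero & (sd < sd_thresh)
    mx_thresh = float(np.quantile(mx[nonzero], 0.99)) if nonzero.any() else 0.0
    high = nonzero & (mx > mx_thresh)

    keep = nonzero & ~low & ~high
    report = {
        "n_input": len(collection),
        "removed_zero": n_zero,
        "removed_low_sd": int(low.sum()),
        "removed_high_max": int(high.sum()),
        "sd_quantile_0p02": sd_thresh,
        "max_quantile_0p99": mx_thresh,
        "n_kept": int(keep.sum()),
    }
    if not keep.any():
        raise ValidationError("cleaning removed every image")
    return collection.subset(np.flatnonzero(keep)), report


@dataclass
class DatasetPartition:
    """One of train/test/validation: images, labels and metadata rows."""

    name: str
    data: np.ndarray             # (n, 144, 256)
    target: np.ndarray           # (n,) int
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not (len(self.data) == len(self.target) == len(self.metadata)):
            raise ValidationError("partition components must align")
        if len(self.target) and not (
            (self.target >= 0).all() and (self.target < len(CATALOGUE_NAMES)).all()
        ):
            raise ValidationError("labels must lie in 0..45")

    def __len__(self) -> int:
        return len(self.target)


def split_dataset(
    collection: ImageCollection,
    proportions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    seed: int = 0,
) -> dict[str, DatasetPartition]:
    """Label-stratified random split into train/test/validation.

    Per class, records are shuffled and cut at the cumulative proportions
    (largest-share rounding), so each partition's class mix matches the global
    proportions within rounding. A class with fewer records than partitions is
    kept wholly in train with a warning.
    """
    props = np.asarray(proportions, dtype=float)
    if len(props) != 3 or np.any(props < 0) or not math.isclose(props.sum(), 1.0):
        raise ValidationError("proportions must be three non-negatives summing to 1")
    rng = np.random.default_rng(seed)
    names = ("train", "test", "validation")
    parts: dict[str, list[np.ndarray]] = {n: [] for n in names}

    for label in np.unique(collection.targets):
        idx = np.flatnonzero(collection.targets == label)
        if len(idx) < 3 and props.min() > 0:
            warnings.warn(
                f"class {label} has only {len(idx)} record(s); keeping it wholly in train",
                stacklevel=2,
            )
            parts["train"].append(idx)
            continue
        idx = rng.permutation(idx)
        n = len(idx)
        cuts = np.floor(np.cumsum(props) * n + 0.5).astype(int)
        cuts[-1] = n
        parts["train"].append(idx[: cuts[0]])
        parts["test"].append(idx[cuts[0]: cuts[1]])
        parts["validation"].append(idx[cuts[1]:])

    out = {}
    for name in names:
        idx = np.sort(np.concatenate(parts[name])) if parts[name] else np.array([], int)
        sub = collection.subset(idx)
        out[name] = DatasetPartition(
            name=name, data=sub.images, target=sub.targets, metadata=sub.meta
        )
    return out


def write_partition(partition: DatasetPartition, path) -> Path:
    """Serialise a partition as ``<path>.h5`` (+ ``<path>.csv`` metadata).

    The HDF file holds ``data`` (n x 144 x 256 float32) and ``target`` (n int)
    at the root; the CSV has one row per record in the same order.
    """
    path = Path(path)
    h5_path = path if path.suffix == ".h5" else path.with_suffix(".h5")
    csv_path = h5_path.with_suffix(".csv")
    with h5py.File(h5_path, "w") as fh:
        fh.create_dataset("data", data=partition.data.astype(np.float32))
        fh.create_dataset("target", data=partition.target.astype(np.int64))
        fh.attrs["partition"] = partition.name
    partition.metadata.to_csv(csv_path, index=False)
    return h5_path


def read_partition(path, name: str | None = None) -> DatasetPartition:
    """Inverse of :func:`write_partition`; validates the expected layout."""
    path = Path(path)
    h5_path = path if path.suffix == ".h5" else path.with_suffix(".h5")
    csv_path = h5_path.with_suffix(".csv")
    with h5py.File(h5_path, "r") as fh:
        for key in ("data", "target"):
            if key not in fh:
                raise ValidationError(f"{h5_path} is missing the {key!r} dataset")
        data = fh["data"][...]
        target = fh["target"][...]
        pname = name or fh.attrs.get("partition", h5_path.stem)
    if not csv_path.exists():
        raise ValidationError(f"metadata file {csv_path} not found")
    meta = pd.read_csv(csv_path)
    for col in ("model", "label", "config_id"):
        if col not in meta.columns:
            raise ValidationError(f"{csv_path} is missing the {col!r} column")
    if len(meta) != len(data):
        raise ValidationError("CSV row count does not match HDF record count")
    return DatasetPartition(name=str(pname), data=data, target=target, metadata=meta)
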