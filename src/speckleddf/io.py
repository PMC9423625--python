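"""Readers/writers for TIFF/HDF5 stacks, signal maps and run configuration."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .darkfield import summary_maps
from .model import GeometrySpec, SpeckleFrameSet
from .retrieval import SignalMaps, SolverConfig, WindowSpec

logger = logging.getLogger(__name__)

__all__ = [
    "DatasetLayout",
    "RunConfig",
    "read_dataset",
    "write_frames",
    "write_maps",
    "read_maps_bundle",
]


@dataclass
class DatasetLayout:
    """Where the sample/reference stacks live and how to interpret them."""

    sample: str | list[str]
    reference: str | list[str]
    sample_dataset: str = "sample"
    reference_dataset: str = "reference"
    geometry: GeometrySpec = field(
        default_factory=lambda: GeometrySpec(pixel_size=21.5e-6, distance_d=6.65)
    )
    dark: str | None = None
    flat: str | None = None


@dataclass
class RunConfig:
    """Serialisable reconstruction settings (YAML round-trip stable)."""

    window_size: int = 7
    levels: tuple[int, ...] = (4, 2, 1)
    max_shift: float = 5.0
    width_bounds: tuple[float, float] = (0.02, 3.0)
    stride: int = 1
    output_dir: str = "."
    map_format: str = "tiff"
    seed: int = 0
    verbosity: int = 1

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            window=WindowSpec.hamming(self.window_size),
            levels=tuple(self.levels),
            max_shift=self.max_shift,
            width_bounds=tuple(self.width_bounds),
            seed=self.seed,
        )

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["levels"] = list(self.levels)
        d["width_bounds"] = list(self.width_bounds)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        d["levels"] = tuple(d["levels"])
        d["width_bounds"] = tuple(d["width_bounds"])
        return cls(**d)


def _read_stack(source: str | list[str], dataset: str) -> np.ndarray:
    """Read a (N, H, W) stack from a TIFF (multi-page or list) or HDF5 file."""
    if isinstance(source, (list, tuple)):
        frames = [np.asarray(tifffile.imread(str(p)), float) for p in source]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            for p, f in zip(source, frames):
                if f.shape != frames[0].shape:
                    raise ValueError(
                        f"frame {p} has shape {f.shape}, expected {frames[0].shape}"
                    )
        return np.stack(frames)
    path = Path(source)
    if path.suffix.lower() in (".h5", ".hdf5", ".hdf"):
        with h5py.File(path, "r") as fh:
            if dataset not in fh:
                raise KeyError(f"dataset '{dataset}' not found in {path}")
            arr = np.asarray(fh[dataset], float)
    else:
        arr = np.asarray(tifffile.imread(str(path)), float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{source}: expected a 2-D or 3-D stack, got {arr.shape}")
    return arr


def read_dataset(layout: DatasetLayout) -> SpeckleFrameSet:
    """Load paired stacks, apply optional dark/flat correction, validate shapes."""
    sample = _read_stack(layout.sample, layout.sample_dataset)
    reference = _read_stack(layout.reference, layout.reference_dataset)
    if sample.shape != reference.shape:
        raise ValueError(
            f"sample stack {sample.shape} does not match reference stack "
            f"{reference.shape} (broadcasting is not supported)"
        )
    if layout.dark is not None:
        dark = np.asarray(tifffile.imread(layout.dark), float)
        sample = np.clip(sample - dark, 0.0, None)
        reference = np.clip(reference - dark, 0.0, None)
        logger.info("dark frame subtracted: %s", layout.dark)
    if layout.flat is not None:
        flat = np.asarray(tifffile.imread(layout.flat), float)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(flat > 0, 1.0 / flat, 0.0)
        sample = sample * scale
        reference = reference * scale
        logger.info("flat normalisation applied: %s", layout.flat)
    logger.info(
        "loaded %d frame pairs of shape %s", sample.shape[0], sample.shape[1:]
    )
    return SpeckleFrameSet(sample, reference, layout.geometry)


def write_frames(
    path: str | Path,
    frames: SpeckleFrameSet,
    truth: dict[str, np.ndarray] | None = None,
    attrs: dict | None = None,
) -> None:
    """Write a frame set (and optional ground truth) to one HDF5 file."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("sample", data=frames.sample)
        fh.create_dataset("reference", data=frames.reference)
        fh.attrs["pixel_size_m"] = frames.geometry.pixel_size
        fh.attrs["distance_d_m"] = frames.geometry.distance_d
        for key, val in (attrs or {}).items():
            fh.attrs[key] = val
        if truth:
            grp = fh.create_group("truth")
            for name, arr in truth.items():
                grp.create_dataset(name, data=arr)


_MAP_NAMES = ("T", "u_x", "u_y", "alpha1", "alpha2", "alpha3", "residual")


def write_maps(
    outdir: str | Path,
    maps: SignalMaps,
    config: RunConfig | None = None,
    write_tiffs: bool = True,
) -> dict[str, Path]:
    """Write 32-bit float TIFFs per map plus one HDF5 bundle.

    Emits the raw solver maps, the derived dark-field maps (sigma,
    eccentricity, theta_deg) and the 8-bit validity mask; the bundle stores
    everything with the serialised RunConfig and seed as attributes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    derived = summary_maps(maps.alpha1, maps.alpha2, maps.alpha3)
    payload: dict[str, np.ndarray] = {name: getattr(maps, name) for name in _MAP_NAMES}
    payload["sigma"] = derived["sigma"]
    payload["eccentricity"] = derived["eccentricity"]
    payload["theta_deg"] = derived["theta_deg"]
    written: dict[str, Path] = {}
    if write_tiffs:
        for name, arr in payload.items():
            p = outdir / f"{name}.tif"
            tifffile.imwrite(p, arr.astype(np.float32))
            written[name] = p
        p = outdir / "mask.tif"
        tifffile.imwrite(p, maps.valid.astype(np.uint8))
        written["mask"] = p
    bundle = outdir / "maps.h5"
    with h5py.File(bundle, "w") as fh:
        for name, arr in payload.items():
            fh.create_dataset(name, data=arr.astype(np.float32))
        fh.create_dataset("mask", data=maps.valid.astype(np.uint8))
        fh.attrs["margin"] = maps.margin
        if config is not None:
            fh.attrs["run_config"] = config.to_yaml()
            fh.attrs["seed"] = config.seed
    written["bundle"] = bundle
    return written


def read_maps_bundle(path: str | Path) -> dict[str, np.ndarray]:
    """Load every dataset of a maps bundle into a dict (plus 'attrs')."""
    out: dict = {}
    with h5py.File(path, "r") as fh:
        for name in fh:
            out[name] = np.asarray(fh[name])
        out["attrs"] = dict(fh.attrs)
    return out
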