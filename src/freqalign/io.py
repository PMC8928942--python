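"""Stack/file formats, run configuration, and result writing."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imageops import as_square
from .mrc import read_mrc, write_mrc

__all__ = ["ParticleStack", "RunConfig", "read_stack", "write_stack",
           "write_results"]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


@dataclass
class ParticleStack:
    """N square images of uniform side length plus file metadata."""

    images: np.ndarray  # (N, m, m) float
    pixel_size: float = 0.0  # Angstrom / pixel; 0 = unknown
    source: str = ""

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim == 2:
            self.images = self.images[None]
        if self.images.ndim != 3 or self.images.shape[0] < 1:
            raise ValueError("stack must hold at least one 2-D image")
        n, h, w = self.images.shape
        if h != w:
            raise ValueError(f"stack images are not square: {h}x{w}")

    def __len__(self):
        return self.images.shape[0]

    @property
    def m(self) -> int:
        return self.images.shape[1]


@dataclass
class RunConfig:
    """Settings of one classification run; defaults match the method as stated."""

    interpolate: bool = True  # spline peak refinement vs integer readout
    max_iter: int = 10
    n_classes: int = 100
    ns: int = 5
    k_override: int | None = None
    seed: int = 0
    eq9_literal: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def read_stack(path) -> ParticleStack:
    """Read an MRC/MRCS stack, or a single PNG/TIFF image, as a ParticleStack."""
    p = Path(path)
    if p.suffix.lower() in _IMAGE_SUFFIXES:
        import imageio.v3 as iio

        img = np.asarray(iio.imread(p), dtype=float)
        if img.ndim == 3:  # collapse color channels
            img = img.mean(axis=2)
        as_square(img)
        return ParticleStack(images=img[None], source=str(p))
    data, pixel_size = read_mrc(p)
    if data.shape[1] != data.shape[2]:
        raise ValueError(
            f"{p}: images are {data.shape[1]}x{data.shape[2]}, expected square"
        )
    return ParticleStack(images=data.astype(float), pixel_size=pixel_size,
                         source=str(p))


def write_stack(path, images, pixel_size: float = 1.0) -> None:
    write_mrc(path, np.asarray(images, dtype=np.float32), pixel_size=pixel_size)


def write_results(assignment, averages, params: pd.DataFrame, out_dir,
                  config: RunConfig | None = None, pixel_size: float = 1.0,
                  ) -> dict:
    """Write class averages (MRCS), per-image table (CSV) and a JSON manifest.

    Returns the manifest dictionary. Empty classes are recorded in the
    manifest and skipped in the averages stack.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    avg_images = [a.image for a in averages if a is not None]
    avg_classes = [c for c, a in enumerate(averages) if a is not None]
    if avg_images:
        write_stack(out / "class_averages.mrcs", np.array(avg_images),
                    pixel_size=pixel_size)

    table = params.sort_values("index").reset_index(drop=True)
    table.to_csv(out / "particles.csv", index=False)

    manifest = {
        "package": "freqalign",
        "version": __version__,
        "numpy": np.__version__,
        "config": (config or RunConfig()).to_dict(),
        "n_images": int(len(table)),
        "n_classes": int(assignment.n_classes),
        "class_sizes": [int(np.sum(assignment.labels == c))
                        for c in range(assignment.n_classes)],
        "medoids": [int(v) for v in assignment.medoids]
        if assignment.medoids is not None else None,
        "average_classes": avg_classes,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
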