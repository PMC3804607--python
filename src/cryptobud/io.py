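"""File formats: multi-channel TIFF stacks, annotations, tables and config.

All volumes are stored axis order ``(channel, z, y, x)`` with isotropic (or
explicitly anisotropic) voxel size in micrometres.  Stacks are written as
OME-TIFF with named channels (DAPI, bcat, ecad); annotations, ground truth
and run manifests are JSON; tables are UTF-8 comma-separated CSV with a
header row; configuration round-trips through YAML or JSON.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional
from xml.etree import ElementTree

import numpy as np
import pandas as pd
import tifffile
import yaml

from .morphometry import (
    AI_SYMMETRY_CUTOFF,
    BASAL_WIDTH_FRACTION,
    STAGE1_BOUNDARY,
    STAGE3_BOUNDARY,
    AnnotationError,
    CryptAnnotation,
)

CHANNEL_NAMES = ("dapi", "bcat", "ecad")


class StackFormatError(ValueError):
    """Raised for malformed image stacks."""


@dataclass
class VolumeImage:
    """A multi-channel 3D voxel grid: the unit every image operation consumes.

    ``data`` has shape ``(n_channels, nz, ny, nx)`` and 16-bit unsigned
    intensities in arbitrary units; ``voxel_size`` is the edge length of one
    voxel in micrometres (cubic voxels by default).
    """

    data: np.ndarray
    voxel_size: float = 1.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise StackFormatError(
                f"stack must be (channel, z, y, x), got shape {self.data.shape}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise StackFormatError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; available: {self.channel_names}"
            ) from None
        return self.data[idx]


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(path: str | Path, volume: VolumeImage) -> None:
    """Write a multi-channel stack as OME-TIFF with channel names and voxel size."""
    data = np.ascontiguousarray(volume.data.astype(np.uint16, copy=False))
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(volume.channel_names)},
            "PhysicalSizeX": volume.voxel_size,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": volume.voxel_size,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": volume.voxel_size,
            "PhysicalSizeZUnit": "µm",
        },
    )


def read_stack(path: str | Path) -> VolumeImage:
    """Read an OME-TIFF / multi-page TIFF stack written by :func:`write_stack`."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        names: tuple[str, ...] = CHANNEL_NAMES
        voxel = 1.0
        if tif.ome_metadata:
            root = ElementTree.fromstring(tif.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            chans = root.findall(".//ome:Channel", ns)
            if chans:
                names = tuple(c.get("Name") or f"ch{i}" for i, c in enumerate(chans))
            px = root.find(".//ome:Pixels", ns)
            if px is not None and px.get("PhysicalSizeX"):
                voxel = float(px.get("PhysicalSizeX"))
    if data.ndim == 3:  # single channel
        data = data[None]
    if data.ndim != 4:
        raise StackFormatError(f"unsupported stack dimensionality {data.shape}")
    return VolumeImage(data=data, voxel_size=voxel, channel_names=names)


def write_label_volume(path: str | Path, labels: np.ndarray, voxel_size: float = 1.0) -> None:
    tifffile.imwrite(str(path), labels.astype(np.uint8), metadata={"axes": "ZYX"})


def read_label_volume(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


# ---------------------------------------------------------------------------
# Annotations (JSON)
# ---------------------------------------------------------------------------

def _parse_points(obj, name: str) -> np.ndarray:
    try:
        arr = np.asarray(obj, dtype=float)
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"non-numeric coordinate in field {name!r}: {exc}") from None
    if arr.ndim != 2 or arr.shape[1] != 3 or not np.all(np.isfinite(arr)):
        raise AnnotationError(f"field {name!r} must be a list of finite 3D points")
    return arr


def annotation_to_dict(ann: CryptAnnotation) -> dict:
    d = {
        "crypt_id": ann.crypt_id,
        "region": ann.region,
        "age": ann.age,
        "axis": ann.axis.tolist(),
    }
    if ann.branches is not None:
        d["branches"] = {
            "parent": ann.branches[0].tolist(),
            "daughter": ann.branches[1].tolist(),
        }
    if ann.basal_width_segment is not None:
        d["basal_width_segment"] = ann.basal_width_segment.tolist()
    return d


def annotation_from_dict(d: dict) -> CryptAnnotation:
    if "axis" not in d:
        raise AnnotationError("annotation is missing the 'axis' field")
    branches = None
    if d.get("branches") is not None:
        branches = (
            _parse_points(d["branches"]["parent"], "branches.parent"),
            _parse_points(d["branches"]["daughter"], "branches.daughter"),
        )
    seg = None
    if d.get("basal_width_segment") is not None:
        seg = _parse_points(d["basal_width_segment"], "basal_width_segment")
    return CryptAnnotation(
        axis=_parse_points(d["axis"], "axis"),
        branches=branches,
        basal_width_segment=seg,
        crypt_id=str(d.get("crypt_id", "")),
        region=str(d.get("region", "")),
        age=d.get("age"),
    )


def write_annotations(path: str | Path, annotations: list[CryptAnnotation]) -> None:
    payload = {"micrometre_coordinates": True,
               "annotations": [annotation_to_dict(a) for a in annotations]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_annotations(path: str | Path) -> list[CryptAnnotation]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(
            f"malformed annotation file {path}: line {exc.lineno} col {exc.colno}: {exc.msg}"
        ) from None
    return [annotation_from_dict(d) for d in payload["annotations"]]


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunable knobs of the end-to-end pipeline, in one round-trippable record."""

    seed: int = 0
    out_dir: str = "cryptobud_out"
    # simulation
    preset: str = "proximal-4.0"
    n_crypts: int = 20
    exact_counts: bool = False
    n_volumes: int = 0          # how many crypts also get rendered volumes
    voxel_size: float = 1.0
    # channel map: channel name -> index in the stack
    channels: dict = field(default_factory=lambda: {"dapi": 0, "bcat": 1, "ecad": 2})
    # morphometry
    basal_width_fraction: float = BASAL_WIDTH_FRACTION
    stage1_boundary: float = STAGE1_BOUNDARY
    stage3_boundary: float = STAGE3_BOUNDARY
    ai_cutoff: float = AI_SYMMETRY_CUTOFF
    # segmentation / compartments
    smoothing_sigma: float = 0.5
    min_object_um3: float = 30.0
    n_regions: int = 5
    # phenotype
    theta_low: float = 0.6
    theta_high: float = 1.5
    n_profile_bins: int = 40
    min_cluster_voxels: int = 8

    def validate(self) -> None:
        for name in ("basal_width_fraction", "stage1_boundary", "stage3_boundary"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.stage1_boundary >= self.stage3_boundary:
            raise ValueError("stage1_boundary must be below stage3_boundary")
        if not (0.0 < self.theta_low < 1.0):
            raise ValueError(f"theta_low must be in (0, 1), got {self.theta_low}")
        if self.theta_high <= 1.0:
            raise ValueError(f"theta_high must exceed 1, got {self.theta_high}")
        if self.n_regions < 1 or self.n_profile_bins < 20:
            raise ValueError("n_regions >= 1 and n_profile_bins >= 20 required")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        missing = {"dapi", "bcat", "ecad"} - set(self.channels)
        if missing:
            raise ValueError(f"channel map is missing {sorted(missing)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
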