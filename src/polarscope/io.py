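"""On-disk formats: TSV abundance/design tables, TIFF stacks, configs.

Tables are plain TSV/CSV; image stacks are multi-frame grayscale TIFF
(labels written 16-bit); the surface atlas is one identifier per line;
run configuration is a flat YAML mapping that round-trips losslessly and
rejects unknown keys.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .proteome import AbundanceMatrix, SurfaceAtlas
from .segmentation import ImageStack, LabelStack

__all__ = [
    "RunConfig",
    "read_abundance",
    "write_abundance",
    "read_atlas",
    "read_stack",
    "write_stack",
    "write_labels",
    "read_labels",
    "load_config",
    "save_config",
]


@dataclass
class RunConfig:
    """Resolved parameters of a run; written beside every output set."""

    up_threshold: float = 1.0
    down_threshold: float = -1.0
    boundary_inclusive: bool = True
    variance_sigma: float = 5.0
    dog_sigma: float = 7.0
    dog_sigma_low: float = 1.0
    minima_depth_h: int = 10
    connectivity: int = 8
    min_area: float = 200.0
    cluster_area: float = 2000.0
    max_link_distance: float = 50.0
    min_track_length: int = 5
    frame_interval_min: float = 20.0
    seed: int = 0


def _read_table(path: Path, index_col=0) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=index_col)


def read_abundance(path, design_path) -> AbundanceMatrix:
    """Read an abundance table (protein_id first column) and its design.

    The design must map every sample column to subtype/donor/control;
    duplicate protein identifiers or unmapped samples are rejected with
    the offending names.
    """
    path, design_path = Path(path), Path(design_path)
    values = _read_table(path)
    bad = values.columns[
        ~values.apply(lambda c: pd.api.types.is_numeric_dtype(c))
    ].tolist()
    if bad:
        raise ValueError(f"non-numeric abundance column(s): {bad}")
    design = _read_table(design_path)
    if "is_control" in design.columns:
        design["is_control"] = design["is_control"].astype(bool)
    return AbundanceMatrix(values=values, design=design)


def write_abundance(matrix: AbundanceMatrix, path, design_path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="protein_id")
    matrix.design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_atlas(path, source_label: str | None = None) -> SurfaceAtlas:
    """Read a one-identifier-per-line surface-protein whitelist."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines()]
    ids = [i for i in ids if i and not i.startswith("#")]
    return SurfaceAtlas(identifiers=frozenset(ids), source_label=source_label or path.name)


def read_stack(path, frame_interval: float = 20.0) -> ImageStack:
    """Read a multi-frame grayscale TIFF into an ImageStack."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"expected grayscale frames, got shape {arr.shape}; "
            "convert RGB/multichannel input to single-channel first"
        )
    return ImageStack(frames=arr, frame_interval=frame_interval)


def write_stack(stack: ImageStack, path) -> None:
    frames = stack.frames
    if frames.dtype.kind == "f":
        frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")


def write_labels(label_stack: LabelStack, path, table_path=None) -> None:
    """Write label maps as 16-bit multi-frame TIFF (+ optional object CSV)."""
    labels = label_stack.labels
    if labels.max() >= 2**16:
        raise ValueError("label ids exceed 16-bit range")
    tifffile.imwrite(path, labels.astype(np.uint16), photometric="minisblack")
    if table_path is not None:
        label_stack.object_table.to_csv(table_path, index=False)


def read_labels(path, table_path=None) -> LabelStack:
    labels = tifffile.imread(path).astype(np.int32)
    if labels.ndim == 2:
        labels = labels[None]
    table = pd.read_csv(table_path) if table_path is not None else pd.DataFrame()
    return LabelStack(labels=labels, object_table=table)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def load_config(path) -> RunConfig:
    """Load a flat YAML config; unknown keys are errors (fail fast)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key: value mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {unknown}")
    return RunConfig(**data)
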