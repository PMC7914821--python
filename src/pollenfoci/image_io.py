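"""Reading and writing multi-channel confocal z-stacks and tabular artifacts.

The repository-wide conventions live here:

* volumes are indexed ``(z, y, x)``, 0-based, section 0 = first acquired plane;
* multi-channel TIFFs store planes in z-major order (for each z, each channel);
* intensities are kept in the acquired integer dtype and converted to floating
  point only inside metric computations;
* Ct tables and result tables are comma-delimited text with a header row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: required columns of a long-format Ct table
CT_COLUMNS = ("sample_id", "gene", "treatment", "timepoint", "bio_rep", "tech_rep", "ct")


@dataclass
class ZStack:
    """A multi-channel 3D intensity volume — the unit of analysis.

    Parameters
    ----------
    channels
        Mapping of channel name to a ``(z, y, x)`` array of non-negative
        intensities.  All channels must share one shape.
    voxel_size
        ``(z, y, x)`` voxel edge lengths in micrometres.
    bit_depth
        Nominal acquisition bit depth (metrics are dimensionless, this is
        bookkeeping only).
    sample_id, condition, replicate
        Experiment labels, e.g. ``condition="HS37_1h"``.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bit_depth: int = 16
    sample_id: str = ""
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.channels:
            raise ValueError("ZStack needs at least one channel")
        shapes = {name: v.shape for name, v in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 3 or first[0] < 1:
            raise ValueError(f"channel volumes must be 3D (z,y,x) with >=1 section, got {first}")
        if any(s != first for s in shapes.values()):
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, vol in self.channels.items():
            if np.min(vol) < 0:
                raise ValueError(f"negative intensities in channel {name!r}")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be strictly positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def n_sections(self) -> int:
        return self.shape[0]

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)


def write_stack(stack: ZStack, path: str | Path) -> Path:
    """Write *stack* as a multi-page TIFF, planes in z-major channel order.

    Channel names, voxel size and labels go into the ImageDescription tag as
    JSON, so :func:`read_stack` round-trips the stack losslessly.
    """
    path = Path(path)
    names = stack.channel_names
    z, y, x = stack.shape
    planes = np.stack([stack.channels[c] for c in names], axis=1)  # (z, c, y, x)
    meta = {
        "channel_names": names,
        "voxel_size_um": list(stack.voxel_size),
        "bit_depth": stack.bit_depth,
        "sample_id": stack.sample_id,
        "condition": stack.condition,
        "replicate": stack.replicate,
    }
    tifffile.imwrite(
        path,
        planes.reshape(z * len(names), y, x),
        photometric="minisblack",
        description=json.dumps(meta),
        metadata=None,
    )
    return path


def read_stack(
    path: str | Path,
    channel_map: Sequence[str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> ZStack:
    """Read a multi-channel TIFF z-stack.

    ``channel_map`` gives the in-file channel order; when omitted the embedded
    metadata written by :func:`write_stack` is used.  Voxel size falls back to
    ``(1, 1, 1)`` with a logged warning when neither the file nor the caller
    provides one.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        planes = tif.asarray()
        desc = tif.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if channel_map is None:
        channel_map = meta.get("channel_names")
        if channel_map is None:
            raise ValueError(f"{path}: no embedded channel names; pass channel_map")
    channel_map = list(channel_map)
    if len(set(channel_map)) != len(channel_map):
        raise ValueError(f"duplicate channel names in {channel_map}")
    if planes.ndim == 2:
        planes = planes[None]
    n_planes = planes.shape[0]
    n_ch = len(channel_map)
    if n_planes % n_ch != 0:
        raise ValueError(f"{path}: {n_planes} planes not divisible by {n_ch} channels")
    z = n_planes // n_ch
    planes = planes.reshape(z, n_ch, *planes.shape[1:])
    if voxel_size is None:
        vs = meta.get("voxel_size_um")
        if vs is not None:
            voxel_size = tuple(float(v) for v in vs)
        else:
            logger.warning("%s: no voxel-size metadata, assuming (1, 1, 1) um", path)
            voxel_size = (1.0, 1.0, 1.0)
    return ZStack(
        channels={c: planes[:, i].copy() for i, c in enumerate(channel_map)},
        voxel_size=voxel_size,
        bit_depth=int(meta.get("bit_depth", 16)),
        sample_id=str(meta.get("sample_id", path.stem)),
        condition=str(meta.get("condition", "")),
        replicate=int(meta.get("replicate", 0)),
    )


def write_mask_stack(masks: np.ndarray, path: str | Path) -> Path:
    """Export a boolean ``(z, y, x)`` mask set as a single-channel 8-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(masks, bool) * np.uint8(255)), photometric="minisblack")
    return path


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format qPCR Ct table from delimited text.

    Required columns: ``sample_id, gene, treatment, timepoint, bio_rep,
    tech_rep, ct``.  Rows with a non-numeric Ct are dropped with a logged
    count; Ct values outside the plausible cycler range (0, 45) raise.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    ct = pd.to_numeric(df["ct"], errors="coerce")
    bad = ct.isna()
    if bad.any():
        logger.warning("%s: dropped %d row(s) with non-numeric Ct", path, int(bad.sum()))
        df = df.loc[~bad].copy()
        ct = ct.loc[~bad]
    df["ct"] = ct.astype(float)
    if ((df["ct"] <= 0) | (df["ct"] >= 45)).any():
        raise ValueError(f"{path}: Ct values outside (0, 45)")
    return df.reset_index(drop=True)


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write any result table as comma-delimited text with a header row.

    List-valued cells (e.g. per-section CV values) are serialised as
    semicolon-joined strings so the file stays one row per sample/metric.
    """
    path = Path(path)
    out = table.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, (list, tuple, np.ndarray))).any():
            out[col] = out[col].map(
                lambda v: ";".join(format(x, ".10g") for x in v)
                if isinstance(v, (list, tuple, np.ndarray))
                else v
            )
    out.to_csv(path, index=False)
    return path
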