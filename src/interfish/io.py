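"""Readers and writers for images, masks, patches, and manifests.

Supported inputs: multi-page or multi-channel TIFF, or one PNG per
channel, with a JSON channel-map sidecar mapping channel name to the
TIFF page index or PNG file name.  Patch output is one TIFF stack per
patch plus a CSV manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .imaging_core import MultiChannelImage, NucleusMask, NucleusPatch


def read_channel_map(path: str | Path) -> dict[str, int | str]:
    with open(path) as fh:
        cmap = json.load(fh)
    if not isinstance(cmap, dict) or not cmap:
        raise ValueError("channel map must be a non-empty JSON object")
    return cmap


def _stack_pages(pages: np.ndarray) -> np.ndarray:
    """Normalize tifffile output to pages x rows x cols."""
    arr = np.asarray(pages)
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim == 3 and arr.shape[-1] <= 8 and arr.shape[0] > 8:
        arr = np.moveaxis(arr, -1, 0)  # rows x cols x C layout
    return arr


def read_image(
    image_path: str | Path, channel_map: dict[str, int | str] | str | Path
) -> MultiChannelImage:
    """Read a multi-channel image from TIFF pages or per-channel PNGs.

    ``channel_map`` maps channel name -> integer page index (TIFF) or
    file name relative to the image's directory (PNG mode, in which case
    ``image_path`` is the directory).
    """
    if not isinstance(channel_map, dict):
        channel_map = read_channel_map(channel_map)
    image_path = Path(image_path)
    names = list(channel_map)
    planes = []
    if all(isinstance(v, int) for v in channel_map.values()):
        pages = _stack_pages(tifffile.imread(image_path))
        for name in names:
            planes.append(pages[channel_map[name]])
    else:
        base = image_path if image_path.is_dir() else image_path.parent
        for name in names:
            planes.append(iio.imread(base / str(channel_map[name])))
    pixels = np.stack([np.asarray(p, dtype=np.uint8) for p in planes], axis=-1)
    return MultiChannelImage(
        pixels=pixels, channel_names=tuple(names), image_id=image_path.stem
    )


def write_image(path: str | Path, image: MultiChannelImage) -> dict[str, int]:
    """Write channels as TIFF pages; returns the channel map used."""
    tifffile.imwrite(path, np.moveaxis(image.pixels, -1, 0))
    return {name: i for i, name in enumerate(image.channel_names)}


def read_mask(path: str | Path) -> NucleusMask:
    return NucleusMask(labels=tifffile.imread(path).astype(np.int32))


def write_mask(path: str | Path, mask: NucleusMask) -> None:
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many instances for 16-bit label TIFF")
    tifffile.imwrite(path, mask.labels.astype(np.uint16))


def write_patches(
    out_dir: str | Path, patches: list[NucleusPatch], labels: list[str] | None = None
) -> pd.DataFrame:
    """Write patches as TIFF stacks plus a CSV manifest; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, patch in enumerate(patches):
        patch_id = f"{patch.source_image_id}_n{patch.nucleus_id}_w{patch.window_index}"
        px = patch.pixels
        if patch.rescaled:
            px = np.clip(np.rint(px * 255), 0, 255)
        tifffile.imwrite(
            out_dir / f"{patch_id}.tiff", np.moveaxis(px.astype(np.uint8), -1, 0)
        )
        if patch.nucleus_mask is not None:
            tifffile.imwrite(
                out_dir / f"{patch_id}_mask.tiff",
                patch.nucleus_mask.astype(np.uint8) * 255,
            )
        rows.append(
            {
                "patch_id": patch_id,
                "source_image": patch.source_image_id,
                "nucleus_id": patch.nucleus_id,
                "label": labels[i] if labels else "",
                "bbox": json.dumps(list(patch.bbox)),
                "window_index": patch.window_index,
                "boundary": patch.boundary,
                "channels": json.dumps(list(patch.channel_names)),
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_patches(out_dir: str | Path) -> list[NucleusPatch]:
    """Read patches written by :func:`write_patches`."""
    out_dir = Path(out_dir)
    manifest = pd.read_csv(out_dir / "manifest.csv", keep_default_na=False)
    patches = []
    for _, row in manifest.iterrows():
        px = np.moveaxis(_stack_pages(tifffile.imread(out_dir / f"{row.patch_id}.tiff")), 0, -1)
        mask_path = out_dir / f"{row.patch_id}_mask.tiff"
        nm = tifffile.imread(mask_path) > 0 if mask_path.exists() else None
        patches.append(
            NucleusPatch(
                pixels=px.astype(np.uint8),
                channel_names=tuple(json.loads(row.channels)),
                source_image_id=str(row.source_image),
                nucleus_id=int(row.nucleus_id),
                bbox=tuple(json.loads(row.bbox)),
                window_index=int(row.window_index),
                boundary=bool(row.boundary),
                nucleus_mask=nm,
            )
        )
    return patches
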