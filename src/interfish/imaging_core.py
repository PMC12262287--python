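"""Image and mask data model, patch extraction, channel rescaling, distortions.

Conventions used throughout the package: pixel grids are 0-based and
row-major; bounding boxes are half-open ``[row0, row1) x [col0, col1)``;
raw images are 8-bit (0-255); rescaled patches are unit-interval floats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize, rotate

PATCH_SIZE = 256

CHANNEL_NAMES = ("dapi", "target", "centromere", "rfp")

#: Distortion protocol used for robustness testing: each kind has one
#: fixed magnitude (scale factors, degrees, or contrast fraction).
DISTORTION_MAGNITUDES = {
    "shrink": 0.8,
    "enlarge": 1.2,
    "rotate": 45.0,
    "contrast_down": -0.4,
    "contrast_up": 0.4,
}


@dataclass
class MultiChannelImage:
    """A raw 8-bit fluorescence image with named channels.

    ``pixels`` is rows x cols x channels, uint8.  ``channel_names`` is an
    ordered subset of {dapi, target, centromere, rfp}; ``dapi`` and
    ``target`` must be present for pipeline entry.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.channel_names = tuple(self.channel_names)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be rows x cols x channels")
        if self.pixels.shape[2] != len(self.channel_names):
            raise ValueError("channel_names length must match pixel channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        unknown = set(self.channel_names) - set(CHANNEL_NAMES)
        if unknown:
            raise ValueError(f"unknown channel names: {sorted(unknown)}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, :, self.channel_names.index(name)]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


@dataclass
class NucleusMask:
    """Instance label mask: 0 = background, k > 0 = nucleus instance k."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = self.labels.astype(np.int32)

    @property
    def instance_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class NucleusPatch:
    """One nucleus normalized to a 256x256 multi-channel patch.

    ``pixels`` is 256x256xC; uint8 straight after cropping, unit-interval
    floats after :func:`rescale_channels`.  ``nucleus_mask`` marks the
    pixels belonging to this patch's nucleus (neighbouring content is
    preserved in ``pixels`` but not in the mask).  ``bbox`` is half-open
    in source-image coordinates; ``window_index`` is 0 except for
    sliding-window patches from oversized nuclei.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    source_image_id: str
    nucleus_id: int
    bbox: tuple[int, int, int, int]
    window_index: int = 0
    boundary: bool = False
    nucleus_mask: np.ndarray | None = None
    rescaled: bool = False
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        if self.pixels.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
            raise ValueError("patch spatial extent must be 256x256")
        if self.rescaled and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValueError("rescaled patch values must lie in [0, 1]")

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, :, self.channel_names.index(name)]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


@dataclass(frozen=True)
class DistortionSpec:
    """One distortion from the fixed robustness protocol."""

    kind: str
    magnitude: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in DISTORTION_MAGNITUDES:
            raise ValueError(f"unknown distortion kind: {self.kind}")
        allowed = DISTORTION_MAGNITUDES[self.kind]
        if self.magnitude is None:
            object.__setattr__(self, "magnitude", allowed)
        elif self.kind in ("contrast_down", "contrast_up"):
            # contrast magnitude is a signed fraction; any value consistent
            # with the kind's sign is accepted (0 = identity)
            if self.kind == "contrast_down" and self.magnitude > 0:
                raise ValueError("contrast_down magnitude must be <= 0")
            if self.kind == "contrast_up" and self.magnitude < 0:
                raise ValueError("contrast_up magnitude must be >= 0")
        elif self.magnitude != allowed:
            raise ValueError(
                f"{self.kind} magnitude must be {allowed}, got {self.magnitude}"
            )


def _window_starts(extent: int, size: int) -> list[int]:
    """Non-overlapping stride-`size` window origins tiling [0, extent).

    The final window is anchored to the far edge so the whole extent is
    covered; for extent <= size a single window at 0 is returned.
    """
    if extent <= size:
        return [0]
    starts = list(range(0, extent - size + 1, size))
    if starts[-1] != extent - size:
        starts.append(extent - size)
    return starts


def crop_patches(image: MultiChannelImage, mask: NucleusMask) -> list[NucleusPatch]:
    """Extract one or more 256x256 raw patches per labeled nucleus.

    Nuclei with bounding boxes up to 256x256 yield a single bilinearly
    resized patch; larger boxes are tiled with non-overlapping 256x256
    windows (final window edge-anchored), one patch per window with an
    incremented ``window_index``.  Pixels from neighbouring nuclei inside
    the box are preserved.  Nuclei touching the image border are flagged
    ``boundary=True`` for downstream exclusion (tagging analysis).
    """
    if mask.shape != image.shape:
        raise ValueError("mask extent must equal image extent")
    ids = mask.instance_ids
    if ids.size == 0:
        warnings.warn("empty nucleus mask: no patches produced", stacklevel=2)
        return []
    rows, cols = image.shape
    patches: list[NucleusPatch] = []
    for nucleus_id in ids:
        inside = mask.labels == nucleus_id
        rr, cc = np.nonzero(inside)
        r0, r1 = int(rr.min()), int(rr.max()) + 1
        c0, c1 = int(cc.min()), int(cc.max()) + 1
        boundary = r0 == 0 or c0 == 0 or r1 == rows or c1 == cols
        box_px = image.pixels[r0:r1, c0:c1]
        box_mask = inside[r0:r1, c0:c1]
        h, w = r1 - r0, c1 - c0
        if h <= PATCH_SIZE and w <= PATCH_SIZE:
            px = resize(
                box_px.astype(float),
                (PATCH_SIZE, PATCH_SIZE),
                order=1,
                preserve_range=True,
                anti_aliasing=False,
            )
            nm = resize(
                box_mask.astype(np.uint8),
                (PATCH_SIZE, PATCH_SIZE),
                order=0,
                preserve_range=True,
                anti_aliasing=False,
            ).astype(bool)
            patches.append(
                NucleusPatch(
                    pixels=np.clip(np.rint(px), 0, 255).astype(np.uint8),
                    channel_names=image.channel_names,
                    source_image_id=image.image_id,
                    nucleus_id=int(nucleus_id),
                    bbox=(r0, c0, r1, c1),
                    window_index=0,
                    boundary=boundary,
                    nucleus_mask=nm,
                )
            )
        else:
            windex = 0
            for wr in _window_starts(h, PATCH_SIZE):
                for wc in _window_starts(w, PATCH_SIZE):
                    # windows clipped against the box already have exact size
                    sub = np.zeros(
                        (PATCH_SIZE, PATCH_SIZE, box_px.shape[2]), dtype=np.uint8
                    )
                    subm = np.zeros((PATCH_SIZE, PATCH_SIZE), dtype=bool)
                    hh = min(PATCH_SIZE, h - wr)
                    ww = min(PATCH_SIZE, w - wc)
                    sub[:hh, :ww] = box_px[wr : wr + hh, wc : wc + ww]
                    subm[:hh, :ww] = box_mask[wr : wr + hh, wc : wc + ww]
                    patches.append(
                        NucleusPatch(
                            pixels=sub,
                            channel_names=image.channel_names,
                            source_image_id=image.image_id,
                            nucleus_id=int(nucleus_id),
                            bbox=(r0 + wr, c0 + wc, r0 + wr + hh, c0 + wc + ww),
                            window_index=windex,
                            boundary=boundary,
                            nucleus_mask=subm,
                        )
                    )
                    windex += 1
    return patches


def rescale_channels(patch: NucleusPatch) -> NucleusPatch:
    """Rescale a raw 8-bit patch to unit-interval intensities.

    DAPI is divided by its own patch maximum; the target and centromeric
    channels are divided by their *shared* maximum so their relative
    brightness is preserved.  The RFP channel is not max-rescaled: the
    tagging threshold is defined on the raw 0-255 scale, so the raw grid
    is stashed in ``flags['rfp_raw']`` and the stored plane is only
    divided by 255 to satisfy the unit-interval patch invariant.
    All-zero channels are left as zeros and flagged ``empty_channel``.
    """
    if patch.rescaled:
        return patch
    raw = patch.pixels.astype(float)
    out = np.zeros_like(raw)
    flags = dict(patch.flags)
    names = patch.channel_names
    empty: list[str] = []

    def _divide(idx: int, divisor: float, name: str) -> None:
        if divisor <= 0:
            empty.append(name)
            return
        out[:, :, idx] = raw[:, :, idx] / divisor

    if "dapi" in names:
        i = names.index("dapi")
        _divide(i, raw[:, :, i].max(), "dapi")
    joint = [n for n in ("target", "centromere") if n in names]
    if joint:
        shared_max = max(raw[:, :, names.index(n)].max() for n in joint)
        for n in joint:
            _divide(names.index(n), shared_max, n)
    if "centromere" in names:
        # the centromeric QC gate thresholds on the raw 0-255 scale
        flags["centromere_raw"] = patch.pixels[:, :, names.index("centromere")].copy()
    if "rfp" in names:
        i = names.index("rfp")
        flags["rfp_raw"] = patch.pixels[:, :, i].copy()
        out[:, :, i] = raw[:, :, i] / 255.0
    if empty:
        flags["empty_channel"] = empty
    return NucleusPatch(
        pixels=out,
        channel_names=names,
        source_image_id=patch.source_image_id,
        nucleus_id=patch.nucleus_id,
        bbox=patch.bbox,
        window_index=patch.window_index,
        boundary=patch.boundary,
        nucleus_mask=patch.nucleus_mask,
        rescaled=True,
        flags=flags,
    )


def _contrast(pixels: np.ndarray, fraction: float) -> np.ndarray:
    # linear scaling about the 8-bit midpoint, then clip
    out = 127.5 + (1.0 + fraction) * (pixels.astype(float) - 127.5)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def distort_image(image: MultiChannelImage, spec: DistortionSpec) -> MultiChannelImage:
    """Apply one distortion from the robustness protocol.

    Geometric operations resample bilinearly (rotation uses edge
    replication so constant images stay constant) and clip to [0, 255];
    contrast scales intensities about the midpoint 127.5 by (1 +/- 0.4).
    """
    px = image.pixels
    if spec.kind in ("contrast_down", "contrast_up"):
        out = _contrast(px, spec.magnitude)
    elif spec.kind in ("shrink", "enlarge"):
        f = spec.magnitude
        rows = int(round(f * px.shape[0]))
        cols = int(round(f * px.shape[1]))
        out = resize(
            px.astype(float),
            (rows, cols),
            order=1,
            preserve_range=True,
            anti_aliasing=f < 1,
        )
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    else:  # rotate
        out = rotate(
            px.astype(float),
            spec.magnitude,
            resize=False,
            order=1,
            mode="edge",
            preserve_range=True,
        )
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return MultiChannelImage(
        pixels=out, channel_names=image.channel_names, image_id=image.image_id
    )


def distortion_protocol() -> list[DistortionSpec]:
    """The five fixed distortions used in robustness testing."""
    return [DistortionSpec(kind=k) for k in DISTORTION_MAGNITUDES]


def otsu_baseline_mask(image: MultiChannelImage) -> NucleusMask:
    """Naive stand-in nucleus segmenter: Otsu threshold on DAPI + labeling.

    Only a baseline for exercising the pipeline without an external
    segmenter; real use expects masks from a dedicated nucleus segmenter.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label as cc_label

    dapi = image.channel("dapi")
    thr = threshold_otsu(dapi)
    return NucleusMask(labels=cc_label(dapi > thr, connectivity=1))
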