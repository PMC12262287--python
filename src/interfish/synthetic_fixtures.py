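"""Seeded synthetic interphase FISH images with known ground truth.

Emulates the three amplification phenotypes seen in interphase nuclei:

* ``EC-amp`` -- extrachromosomal DNA: many small bright puncta scattered
  through the nucleus (Poisson-distributed count);
* ``HSR-amp`` -- homogeneously staining region: one or two large
  contiguous bright regions;
* ``no-amp`` -- the normal 2-4 allelic hybridization spots.

Nuclei are filled ellipses on the DAPI channel with smooth texture; the
centromeric channel carries two control puncta per nucleus; the RFP
channel is bright over tagged nuclei only.  Everything is deterministic
under the seed.  The generator does not attempt photorealistic optics
(no PSF model, no tissue texture); see the methods note for what this
implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .imaging_core import PATCH_SIZE, MultiChannelImage, NucleusMask, NucleusPatch

CLASSES = ("EC-amp", "HSR-amp", "no-amp")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults are chosen so that the three classes are separable by the
    mean<10 / variance<64 copy-number heuristic, and so that an EC
    nucleus resembles the "many tiny bright particles" phenotype.
    ``rfp_tag_probability_ec`` defaults to 0.95, matching a tagged line
    sorted to ~95% marker positivity.
    """

    seed: int = 0
    n_nuclei: int = 20
    class_mixture: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    ec_foci_mean: float = 30.0
    hsr_blob_count: tuple[int, int] = (1, 2)
    hsr_blob_area_fraction: tuple[float, float] = (0.05, 0.15)
    noamp_foci_range: tuple[int, int] = (2, 4)
    spot_sigma_px: float = 1.5
    spot_amplitude: int = 200
    min_spot_separation_px: float | None = None  # default: 4 sigma + 1
    noise_sd: float = 4.0
    rfp_tag_probability_ec: float = 0.95
    nucleus_radius_px: tuple[int, int] = (25, 40)
    patch_nucleus_radius_px: tuple[int, int] = (70, 110)
    overlap_fraction: float = 0.0
    image_shape: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        if min(self.class_mixture) < 0:
            raise ValueError("class mixture proportions must be non-negative")
        if self.ec_foci_mean < 0 or self.noise_sd < 0:
            raise ValueError("counts and noise must be non-negative")
        if not 0 <= self.rfp_tag_probability_ec <= 1:
            raise ValueError("tag probability must lie in [0, 1]")
        if min(self.nucleus_radius_px) < 4 or min(self.patch_nucleus_radius_px) < 4:
            raise ValueError("degenerate nucleus radius (< 4 px)")

    @property
    def spot_separation(self) -> float:
        if self.min_spot_separation_px is not None:
            return self.min_spot_separation_px
        return 4 * self.spot_sigma_px + 1


@dataclass
class NucleusTruth:
    """Planted ground truth for one synthetic nucleus."""

    nucleus_id: int
    class_label: str
    foci_centers: np.ndarray  # (k, 2) row/col
    foci_amplitudes: np.ndarray
    tagged: bool
    mask: np.ndarray  # bool, in patch or field coordinates


@dataclass
class GroundTruth:
    nuclei: list[NucleusTruth] = field(default_factory=list)

    def __iter__(self):
        return iter(self.nuclei)

    def __len__(self) -> int:
        return len(self.nuclei)


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    angle: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _render_spots(
    canvas: np.ndarray,
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> None:
    """Add isotropic Gaussian puncta in place (float canvas)."""
    half = int(np.ceil(4 * sigma))
    ax = np.arange(-half, half + 1)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    bump = np.exp(-(rr**2 + cc**2) / (2 * sigma**2))
    H, W = canvas.shape
    for (r, c), amp in zip(centers, amplitudes):
        r, c = int(r), int(c)
        r0, r1 = max(0, r - half), min(H, r + half + 1)
        c0, c1 = max(0, c - half), min(W, c + half + 1)
        canvas[r0:r1, c0:c1] += (
            amp * bump[r0 - (r - half) : r1 - (r - half), c0 - (c - half) : c1 - (c - half)]
        )


def _sample_spot_centers(
    mask: np.ndarray, count: int, separation: float, margin: int, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample integer spot centers inside an eroded mask with a
    pairwise minimum separation; returns as many as fit within retries."""
    interior = mask.copy()
    if margin > 0:
        # keep spots away from the nucleus edge and the patch border
        interior = ~binary_dilation(~interior, iterations=margin)
        interior[:margin, :] = False
        interior[-margin:, :] = False
        interior[:, :margin] = False
        interior[:, -margin:] = False
    coords = np.argwhere(interior)
    if coords.size == 0:
        return np.zeros((0, 2), dtype=int)
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < count and attempts < 200 * max(count, 1):
        attempts += 1
        cand = coords[rng.integers(len(coords))]
        if all(np.hypot(*(cand - p)) >= separation for p in chosen):
            chosen.append(cand)
    return np.array(chosen, dtype=int).reshape(-1, 2)


def _grow_blob(
    mask: np.ndarray, target_area: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow one contiguous region inside ``mask`` to roughly target_area."""
    coords = np.argwhere(mask)
    seed = coords[rng.integers(len(coords))]
    blob = np.zeros_like(mask)
    blob[seed[0], seed[1]] = True
    while blob.sum() < target_area:
        grown = binary_dilation(blob) & mask
        if grown.sum() == blob.sum():
            break
        blob = grown
    return blob


def _spot_count(class_label: str, config: SimulationConfig, rng: np.random.Generator) -> int:
    if class_label == "EC-amp":
        return max(1, int(rng.poisson(config.ec_foci_mean)))
    if class_label == "no-amp":
        lo, hi = config.noamp_foci_range
        return int(rng.integers(lo, hi + 1))
    raise ValueError(class_label)


def _render_nucleus_channels(
    mask: np.ndarray,
    class_label: str,
    tagged: bool,
    config: SimulationConfig,
    rng: np.random.Generator,
    channels: dict[str, np.ndarray],
) -> NucleusTruth:
    """Paint one nucleus onto float channel canvases; returns its truth."""
    sigma = config.spot_sigma_px
    # DAPI: base fill plus smooth texture
    texture = gaussian_filter(rng.normal(0, 25, mask.shape), 6)
    channels["dapi"][mask] += np.clip(150 + texture, 60, 230)[mask]

    centers = np.zeros((0, 2), dtype=int)
    amplitudes = np.zeros(0)
    if class_label in ("EC-amp", "no-amp"):
        count = _spot_count(class_label, config, rng)
        margin = int(np.ceil(4 * sigma)) + 1
        centers = _sample_spot_centers(
            mask, count, config.spot_separation, margin, rng
        )
        amplitudes = np.full(len(centers), float(config.spot_amplitude))
        _render_spots(channels["target"], centers, amplitudes, sigma)
    else:  # HSR-amp: few large contiguous bright regions
        lo, hi = config.hsr_blob_count
        n_blobs = int(rng.integers(lo, hi + 1))
        area = int(mask.sum())
        blob_centers = []
        for _ in range(n_blobs):
            frac = rng.uniform(*config.hsr_blob_area_fraction)
            blob = _grow_blob(mask, int(frac * area), rng)
            channels["target"][blob] += config.spot_amplitude
            blob_centers.append(np.argwhere(blob).mean(axis=0))
        centers = np.array(blob_centers).reshape(-1, 2)
        amplitudes = np.full(len(centers), float(config.spot_amplitude))

    cen_centers = _sample_spot_centers(
        mask, 2, config.spot_separation, int(np.ceil(4 * sigma)) + 1, rng
    )
    _render_spots(
        channels["centromere"], cen_centers, np.full(len(cen_centers), 180.0), sigma
    )
    if tagged:
        channels["rfp"][mask] += 180.0
    return NucleusTruth(
        nucleus_id=0,
        class_label=class_label,
        foci_centers=centers,
        foci_amplitudes=amplitudes,
        tagged=tagged,
        mask=mask,
    )


def _finalize(channels: dict[str, np.ndarray], config, rng) -> np.ndarray:
    planes = []
    for name in ("dapi", "target", "centromere", "rfp"):
        plane = channels[name]
        if config.noise_sd > 0:
            plane = plane + rng.normal(0, config.noise_sd, plane.shape)
        planes.append(np.clip(np.rint(plane), 0, 255).astype(np.uint8))
    return np.stack(planes, axis=-1)


def generate_nucleus_patch(
    class_label: str,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[NucleusPatch, NucleusTruth]:
    """Generate one raw 8-bit 256x256 nucleus patch with ground truth."""
    config = config or SimulationConfig()
    if class_label not in CLASSES:
        raise ValueError(f"class_label must be one of {CLASSES}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = (PATCH_SIZE, PATCH_SIZE)
    lo, hi = config.patch_nucleus_radius_px
    radii = (rng.uniform(lo, hi), rng.uniform(lo, hi))
    center = (
        PATCH_SIZE / 2 + rng.uniform(-10, 10),
        PATCH_SIZE / 2 + rng.uniform(-10, 10),
    )
    mask = _ellipse_mask(shape, center, radii, rng.uniform(0, np.pi))
    channels = {n: np.zeros(shape) for n in ("dapi", "target", "centromere", "rfp")}
    tagged = bool(
        class_label == "EC-amp" and rng.random() < config.rfp_tag_probability_ec
    )
    truth = _render_nucleus_channels(mask, class_label, tagged, config, rng, channels)
    truth.nucleus_id = 1
    patch = NucleusPatch(
        pixels=_finalize(channels, config, rng),
        channel_names=("dapi", "target", "centromere", "rfp"),
        source_image_id="synthetic",
        nucleus_id=1,
        bbox=(0, 0, PATCH_SIZE, PATCH_SIZE),
        window_index=0,
        boundary=False,
        nucleus_mask=mask,
    )
    return patch, truth


def generate_field_image(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[MultiChannelImage, NucleusMask, GroundTruth]:
    """Generate a multi-nucleus field image, its instance mask, and truth.

    Nuclei are placed without touching unless ``config.overlap_fraction``
    > 0, in which case that fraction of nuclei (after the first) is
    deliberately placed overlapping an earlier one so that the fused
    foreground exercises instance splitting.  Mask labels correspond 1:1
    to ground-truth records (overlap pixels belong to the later nucleus).
    """
    config = config or SimulationConfig()
    if config.n_nuclei < 1:
        raise ValueError("n_nuclei must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    shape = config.image_shape
    labels = np.zeros(shape, dtype=np.int32)
    channels = {n: np.zeros(shape) for n in ("dapi", "target", "centromere", "rfp")}
    truth = GroundTruth()
    placed: list[tuple[tuple[float, float], float]] = []  # (center, max radius)
    lo, hi = config.nucleus_radius_px
    class_draws = rng.choice(3, size=config.n_nuclei, p=list(config.class_mixture))
    for k in range(config.n_nuclei):
        class_label = CLASSES[class_draws[k]]
        radii = (rng.uniform(lo, hi), rng.uniform(lo, hi))
        rmax = max(radii)
        want_overlap = bool(placed) and rng.random() < config.overlap_fraction
        mask = None
        for _ in range(300):
            if want_overlap:
                base_c, base_r = placed[rng.integers(len(placed))]
                ang = rng.uniform(0, 2 * np.pi)
                d = 0.8 * (base_r + rmax)
                center = (base_c[0] + d * np.cos(ang), base_c[1] + d * np.sin(ang))
            else:
                center = (
                    rng.uniform(rmax + 2, shape[0] - rmax - 2),
                    rng.uniform(rmax + 2, shape[1] - rmax - 2),
                )
            if not (rmax + 1 < center[0] < shape[0] - rmax - 1):
                continue
            if not (rmax + 1 < center[1] < shape[1] - rmax - 1):
                continue
            if not want_overlap and any(
                np.hypot(center[0] - c[0], center[1] - c[1]) < r + rmax + 3
                for c, r in placed
            ):
                continue
            mask = _ellipse_mask(shape, center, radii, rng.uniform(0, np.pi))
            break
        if mask is None:
            raise RuntimeError(
                f"could not place nucleus {k + 1}; placed {len(placed)} of "
                f"{config.n_nuclei}"
            )
        placed.append((center, rmax))
        tagged = bool(
            class_label == "EC-amp" and rng.random() < config.rfp_tag_probability_ec
        )
        rec = _render_nucleus_channels(mask, class_label, tagged, config, rng, channels)
        rec.nucleus_id = k + 1
        labels[mask] = k + 1
        truth.nuclei.append(rec)
    image = MultiChannelImage(
        pixels=_finalize(channels, config, rng),
        channel_names=("dapi", "target", "centromere", "rfp"),
        image_id=f"synthetic_field_{config.seed if seed is None else seed}",
    )
    return image, NucleusMask(labels=labels), truth
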