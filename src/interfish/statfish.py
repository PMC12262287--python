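"""Deterministic FISH foci detection by projection onto an orthogonalized
Gaussian kernel, plus copy-number and co-occurrence statistics.

The model: an isolated hybridization spot looks like an isotropic 2-D
Gaussian of width ``sigma`` sitting on a locally constant background,

    intensity(x, y) = c * exp(-((x-x0)^2 + (y-y0)^2) / (2 sigma^2)) + d.

For each pixel the flattened n x n neighborhood ``v`` is projected onto
the orthonormal basis of span{g, 1}, where ``g`` is the flattened
Gaussian kernel.  The component along ``g_perp`` (the unit vector of
``g`` minus its mean) measures spot-shaped local contrast ``c`` and is,
by construction, zero on any constant region.  Pixels are candidate
foci when this projection is at least ``c_min`` *and* the raw pixel
brightness is at least ``b_min``; 8-connected candidate components of
at least ``s_min`` pixels become foci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass
class StatFishParams:
    """Detection parameters.

    ``sigma`` (px) sets the expected spot width; ``kernel_size`` defaults
    to the smallest odd integer >= 6 sigma.  ``c_min`` thresholds the
    projection response (same intensity units as the channel), ``b_min``
    the raw brightness, and ``s_min`` (px) the focus component size.
    The defaults target raw 8-bit channels; when a channel was rescaled
    to [0, 1], pass thresholds on that same unit scale.
    """

    sigma: float = 1.5
    kernel_size: int | None = None
    c_min: float = 15.0
    b_min: float = 50.0
    s_min: int = 2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.kernel_size is None:
            n = int(np.ceil(6 * self.sigma))
            self.kernel_size = n if n % 2 == 1 else n + 1
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")
        if self.s_min < 1:
            raise ValueError("s_min must be >= 1")


@dataclass
class OrthogonalKernel:
    """Gaussian kernel and its unit-norm component orthogonal to constants."""

    g: np.ndarray
    g_perp: np.ndarray

    @property
    def size(self) -> int:
        return self.g.shape[0]


@dataclass
class FociSet:
    """Detected foci for one nucleus/channel."""

    component_labels: np.ndarray
    foci: list[tuple[tuple[float, float], int]]  # (centroid, pixel area)
    n_foci: int
    copy_number_signal: float | None = None
    params: StatFishParams | None = field(default=None, repr=False)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c for c, _ in self.foci]).reshape(-1, 2)

    @property
    def total_foci_pixels(self) -> int:
        return int(sum(a for _, a in self.foci))


def build_orthogonal_kernel(params: StatFishParams) -> OrthogonalKernel:
    """Construct g(i,j) = exp(-((i-c)^2+(j-c)^2) / (2 sigma^2)) and its
    Gram-Schmidt residual against the constant vector, normalized."""
    n = params.kernel_size
    c = (n - 1) / 2
    ax = np.arange(n) - c
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    g = np.exp(-(rr**2 + cc**2) / (2 * params.sigma**2))
    resid = g - g.mean()
    norm = np.linalg.norm(resid)
    if norm < 1e-9:
        raise ValueError(
            "degenerate kernel: sigma too large for the window, g is "
            "numerically constant"
        )
    return OrthogonalKernel(g=g, g_perp=resid / norm)


def projection_response(channel: np.ndarray, kernel: OrthogonalKernel) -> np.ndarray:
    """Per-pixel projection v . g_perp, zero-padded to the input size.

    Within ``floor(n/2)`` of the border the zero padding makes the
    response a partial projection; those pixels are excluded from
    candidacy in :func:`detect_foci`.
    """
    return ndimage.correlate(
        np.asarray(channel, dtype=float), kernel.g_perp, mode="constant", cval=0.0
    )


def detect_foci(
    channel: np.ndarray,
    nucleus_mask: np.ndarray,
    params: StatFishParams | None = None,
) -> FociSet:
    """Detect FISH foci in one channel restricted to a nucleus mask.

    Candidates are mask pixels whose projection response reaches
    ``c_min`` and whose raw brightness reaches ``b_min``; 8-connected
    candidate components of at least ``s_min`` pixels are reported with
    centroid and pixel area.
    """
    params = params or StatFishParams()
    channel = np.asarray(channel)
    nucleus_mask = np.asarray(nucleus_mask).astype(bool)
    if channel.shape != nucleus_mask.shape:
        raise ValueError("channel and mask extents differ")
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    kernel = build_orthogonal_kernel(params)
    response = projection_response(channel, kernel)
    candidates = (
        nucleus_mask & (response >= params.c_min) & (channel >= params.b_min)
    )
    half = kernel.size // 2
    if half > 0:  # zero padding corrupts the projection near the border
        border = np.zeros_like(candidates)
        border[half:-half, half:-half] = True
        candidates &= border
    eight = np.ones((3, 3), dtype=bool)
    labeled, n = ndimage.label(candidates, structure=eight)
    foci = []
    keep = np.zeros_like(labeled)
    next_id = 0
    for k in range(1, n + 1):
        comp = labeled == k
        area = int(comp.sum())
        if area < params.s_min:
            continue
        next_id += 1
        keep[comp] = next_id
        centroid = tuple(np.argwhere(comp).mean(axis=0))
        foci.append(((float(centroid[0]), float(centroid[1])), area))
    return FociSet(
        component_labels=keep, foci=foci, n_foci=len(foci), params=params
    )


def copy_number_signal(foci: FociSet, nucleus_mask: np.ndarray) -> float:
    """Percentage of the nucleus pixel area covered by detected foci."""
    area = int(np.asarray(nucleus_mask).astype(bool).sum())
    if area == 0:
        raise ValueError("zero-area nucleus mask")
    return 100.0 * foci.total_foci_pixels / area


def image_statistics(
    signals: list[float] | list[FociSet], foci_counts: list[int] | None = None
) -> dict:
    """Image-level mean and population variance of the per-nucleus copy
    number signal, plus the per-nucleus foci-count table.

    Accepts either the per-nucleus signal values directly, or FociSets
    whose ``copy_number_signal`` has been filled in.
    """
    if len(signals) == 0:
        raise ValueError("need at least one nucleus")
    if isinstance(signals[0], FociSet):
        if foci_counts is None:
            foci_counts = [fs.n_foci for fs in signals]
        signals = [fs.copy_number_signal for fs in signals]
        if any(s is None for s in signals):
            raise ValueError("FociSet.copy_number_signal not computed")
    arr = np.asarray(signals, dtype=float)
    out = {
        "mean": float(arr.mean()),
        "variance": float(arr.var()),  # population variance (ddof=0)
        "n_nuclei": len(signals),
    }
    if foci_counts is not None:
        out["foci_counts"] = list(foci_counts)
    return out


def foci_cooccurrence(foci_a: FociSet, foci_b: FociSet) -> tuple[int, int, int]:
    """Count exclusive and co-occurring foci between two probe channels.

    A focus co-occurs when its pixel component overlaps a focus of the
    other channel in at least one pixel; a focus overlapping several on
    the other side still counts once.  Returns
    ``(n_a_only, n_b_only, n_cooccurring)`` where the co-occurrence
    count is the number of A-foci with any overlap.
    """
    la, lb = foci_a.component_labels, foci_b.component_labels
    if la.shape != lb.shape:
        raise ValueError("FociSets cover different grids")
    overlap = (la > 0) & (lb > 0)
    a_hit = np.unique(la[overlap])
    b_hit = np.unique(lb[overlap])
    n_co = int((a_hit > 0).sum())
    n_a_only = foci_a.n_foci - n_co
    n_b_only = foci_b.n_foci - int((b_hit > 0).sum())
    return n_a_only, n_b_only, n_co


def calibrate_c_min(
    background_patches: list[np.ndarray],
    params: StatFishParams,
    factor: float = 3.0,
) -> float:
    """Set ``c_min`` to ``factor`` times the projection-response standard
    deviation over background-only calibration patches."""
    kernel = build_orthogonal_kernel(params)
    half = kernel.size // 2
    values = []
    for patch in background_patches:
        resp = projection_response(patch, kernel)
        values.append(resp[half:-half, half:-half].ravel())
    return factor * float(np.concatenate(values).std())
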