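"""Image- and nucleus-level quality gates.

Two branches are gated independently: the target-probe pipeline runs
only on images whose intensity histogram still shows a dominant
background peak (quality score Q), and the centromeric branch runs only
when the per-nucleus centromeric intensities are not too heavy-tailed
(Pearson kurtosis) and the nucleus actually carries centromeric signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imaging_core import NucleusPatch

N_BINS = 50
Q_THRESHOLD = 0.2
MEAN_SIGNAL_THRESHOLD = 0.05
KURTOSIS_THRESHOLD = 3.0
CENTROMERE_MAX_THRESHOLD = 10


@dataclass
class QualityReport:
    """Per-image quality gates; nucleus-level flags live on the patches."""

    q_score: float | None
    h1: int | None
    h2: int | None
    target_pass: bool
    centromere_kurtosis: float | None = None
    centromere_pass: bool = False
    reason: str | None = None


def _histogram_peaks(counts: np.ndarray) -> list[int]:
    """Indices of local maxima of a histogram, comparing neighbours.

    End bins compare against their single neighbour; a plateau bounded
    by strictly smaller values on both sides counts once, at its left
    edge.
    """
    peaks = []
    n = len(counts)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left_ok = i == 0 or counts[i - 1] < counts[i]
        right_ok = j == n - 1 or counts[j + 1] < counts[i]
        if left_ok and right_ok and not (i == 0 and j == n - 1):
            peaks.append(i)
        i = j + 1
    return peaks


def target_quality_score(target_channel: np.ndarray) -> QualityReport:
    """Histogram-based quality score of the target FISH channel.

    The channel is binned into 50 equal-width intensity buckets on
    [0, 256); Q = h1/h2 where h1 (h2) is the count of the highest peak
    among bins 0-24 (25-49).  Images with Q < 0.2 -- a weak background
    peak relative to the signal peak, typical of bled/saturated images
    -- fail the gate.
    """
    channel = np.asarray(target_channel)
    if channel.size == 0:
        raise ValueError("empty image")
    counts, _ = np.histogram(channel, bins=N_BINS, range=(0, 256))
    peaks = _histogram_peaks(counts)
    left = [p for p in peaks if p < 25]
    right = [p for p in peaks if p >= 25]
    if not left or not right:
        side = "left" if not left else "right"
        return QualityReport(
            q_score=None, h1=None, h2=None, target_pass=False,
            reason=f"no histogram peak on the {side} side of bin 25",
        )
    h1 = int(max(counts[p] for p in left))
    h2 = int(max(counts[p] for p in right))
    q = h1 / h2
    return QualityReport(q_score=q, h1=h1, h2=h2, target_pass=q >= Q_THRESHOLD)


def nucleus_signal_gate(patch: NucleusPatch) -> bool:
    """Keep a nucleus iff its mean rescaled target signal is >= 0.05."""
    if not patch.rescaled:
        raise ValueError("gate is defined on rescaled patches")
    target = patch.channel("target")
    mask = patch.nucleus_mask
    mean = float(target[mask].mean()) if mask is not None else float(target.mean())
    return mean >= MEAN_SIGNAL_THRESHOLD


def centromere_image_gate(
    nucleus_mean_intensities: list[float],
) -> tuple[float | None, bool]:
    """Image-level centromeric gate on the kurtosis of per-nucleus means.

    Pearson kurtosis (normal reference = 3) of the per-nucleus mean
    centromeric intensities; the centromeric branch is disabled when the
    kurtosis exceeds 3 (heavy-tailed, e.g. a few hybridization-failed
    nuclei) or is undefined.  Returns (kurtosis, pass).
    """
    values = np.asarray(nucleus_mean_intensities, dtype=float)
    if values.size < 4:
        raise ValueError("kurtosis gate needs at least 4 nuclei")
    if values.var() == 0:
        return None, False
    kurt = float(stats.kurtosis(values, fisher=False, bias=True))
    return kurt, kurt <= KURTOSIS_THRESHOLD


def centromere_nucleus_gate(centromere_channel: np.ndarray) -> bool:
    """Allow the centromeric branch for a nucleus iff its maximum raw
    centromeric intensity is >= 10 (0-255 scale)."""
    channel = np.asarray(centromere_channel)
    if channel.size == 0:
        return False
    return int(channel.max()) >= CENTROMERE_MAX_THRESHOLD


def patch_quality_flags(patch: NucleusPatch) -> dict[str, bool]:
    """Nucleus-level QC flags for one rescaled patch."""
    flags = {"low_target_signal": not nucleus_signal_gate(patch)}
    if patch.has_channel("centromere"):
        raw = patch.flags.get("centromere_raw")
        if raw is None:
            # reconstruct an upper bound from the rescaled plane if the raw
            # grid was not stashed; gate on the raw scale when available
            raise ValueError("raw centromere channel required for the QC gate")
        flags["low_centromere"] = not centromere_nucleus_gate(raw)
    return flags
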