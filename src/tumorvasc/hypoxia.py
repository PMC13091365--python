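"""Relative hypoxic fraction (RHF) from fluorescence section images.

The hypoxia marker accumulates in tissue below ~10 mmHg pO2; stained
sections are thresholded at an intensity derived from negative-control
sections (stained without pre-administered marker), and RHF is the
percentage of marker-positive area within viable tissue (necrosis
excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "FluorescenceSection",
    "RHFResult",
    "control_threshold",
    "relative_hypoxic_fraction",
]


@dataclass
class FluorescenceSection:
    """A stained tumor cryosection with tissue and necrosis masks.

    ``pixel_size`` is the lateral pixel pitch in um.  The necrosis mask must
    lie inside the tissue mask.
    """

    intensity: NDArray[np.float64]
    tissue_mask: NDArray[np.bool_]
    necrosis_mask: NDArray[np.bool_]
    pixel_size: float = 10.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        self.necrosis_mask = np.asarray(self.necrosis_mask, dtype=bool)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2D image")
        if self.tissue_mask.shape != self.intensity.shape:
            raise ValueError("tissue mask shape mismatch")
        if self.necrosis_mask.shape != self.intensity.shape:
            raise ValueError("necrosis mask shape mismatch")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensity must be finite and nonnegative")
        if np.any(self.necrosis_mask & ~self.tissue_mask):
            raise ValueError("necrosis mask must be contained in tissue mask")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def viable_mask(self) -> NDArray[np.bool_]:
        return self.tissue_mask & ~self.necrosis_mask


@dataclass(frozen=True)
class RHFResult:
    """RHF in percent plus the threshold and areas (mm^2) that produced it."""

    rhf: float
    threshold_used: float
    viable_area: float
    positive_area: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rhf <= 100.0):
            raise ValueError("rhf must be a percentage in [0, 100]")


def control_threshold(
    control_sections: list[FluorescenceSection], percentile: float = 99.5
) -> float:
    """Intensity threshold = the given percentile of pooled control tissue pixels.

    Controls are sections stained without the hypoxia marker, so their
    fluorescence is pure background; the high percentile bounds the
    false-positive area of the subsequent thresholding.
    """
    if not control_sections:
        raise ValueError("need at least one control section")
    if not (0.0 < percentile <= 100.0):
        raise ValueError("percentile must be in (0, 100]")
    pooled = np.concatenate(
        [s.intensity[s.tissue_mask] for s in control_sections]
    )
    if pooled.size < 1000:
        raise ValueError("controls must provide at least 1000 tissue pixels")
    return float(np.percentile(pooled, percentile))


def relative_hypoxic_fraction(
    section: FluorescenceSection,
    threshold: float,
    denominator: str = "viable",
) -> RHFResult:
    """RHF = 100 * |viable & (intensity >= threshold)| / |denominator| percent.

    The numerator always excludes necrosis.  The default denominator is the
    viable tissue area (necrosis excluded); ``denominator="tissue"`` uses
    the whole tissue section instead.
    """
    viable = section.viable_mask
    if denominator == "viable":
        denom_mask = viable
    elif denominator == "tissue":
        denom_mask = section.tissue_mask
    else:
        raise ValueError("denominator must be 'viable' or 'tissue'")
    n_denom = int(denom_mask.sum())
    if n_denom == 0:
        raise ValueError("section has no viable tissue area")
    positive = viable & (section.intensity >= threshold)
    px_area_mm2 = (section.pixel_size * 1e-3) ** 2
    return RHFResult(
        rhf=100.0 * positive.sum() / n_denom,
        threshold_used=float(threshold),
        viable_area=n_denom * px_area_mm2,
        positive_area=int(positive.sum()) * px_area_mm2,
    )
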