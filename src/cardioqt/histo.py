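"""Area-fraction metrics on co-registered binary histology masks.

Three metrics quantify gap-junction remodelling and fibrosis on mouse heart
sections:

* connexin-43 (Cx43) co-localisation with the intercalated disc (ICD),
  marked by N-Cadherin: ``100 * area(Cx43 & NCadh) / area(NCadh)``;
* Cx43 lateralisation: the lateral-membrane Cx43 area (WGA-positive
  membrane outside the ICD) relative to the ICD Cx43 area, as a percentage
  (can exceed 100 when more signal sits laterally than at the disc);
* fibrosis: picrosirius-red-positive area as a percentage of the tissue
  section area.

Segmentation of raw fluorescence into binary masks is upstream of this
module; a simple Otsu helper is provided for convenience only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MaskSet",
    "AreaFractions",
    "cx43_icd_fraction",
    "lateralization_ratio",
    "fibrosis_fraction",
    "quantify",
    "quantify_sections",
    "otsu_mask",
]

CHANNELS = ("cx43", "ncadh", "wga_lateral", "psr", "tissue")


@dataclass(frozen=True)
class MaskSet:
    """Co-registered binary masks for one section, with the pixel size (µm)."""

    masks: Mapping[str, np.ndarray]
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        masks = {k: np.asarray(v).astype(bool) for k, v in self.masks.items()}
        shapes = {m.shape for m in masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"masks differ in shape: {shapes}")
        object.__setattr__(self, "masks", masks)

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.masks[channel]


@dataclass(frozen=True)
class AreaFractions:
    """Per-section metrics, all in percent."""

    cx43_icd_pct: float
    lateralization_pct: float
    fibrosis_pct: float


def _as_bool(a: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.dtype != bool and not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} mask is not binary")
    return arr.astype(bool)


def cx43_icd_fraction(cx43: np.ndarray, ncadh: np.ndarray) -> float:
    """Percent of the N-Cadherin (ICD) area covered by Cx43 signal."""
    cx = _as_bool(cx43, "cx43")
    nc = _as_bool(ncadh, "ncadh")
    if cx.shape != nc.shape:
        raise ValueError("masks differ in shape")
    denom = nc.sum()
    if denom == 0:
        raise ValueError("empty N-Cadherin mask")
    return 100.0 * float((cx & nc).sum()) / float(denom)


def lateralization_ratio(
    cx43: np.ndarray, wga_lateral: np.ndarray, ncadh: np.ndarray
) -> float:
    """Lateral-membrane Cx43 area relative to ICD Cx43 area, percent.

    The lateral membrane is the WGA-positive membrane minus its overlap with
    the N-Cadherin ICD, so no pixel counts on both sides of the ratio.
    """
    cx = _as_bool(cx43, "cx43")
    wga = _as_bool(wga_lateral, "wga_lateral")
    nc = _as_bool(ncadh, "ncadh")
    if not (cx.shape == wga.shape == nc.shape):
        raise ValueError("masks differ in shape")
    lateral = wga & ~nc
    icd_area = (cx & nc).sum()
    if icd_area == 0:
        raise ValueError("no Cx43 signal at the ICD; ratio undefined")
    return 100.0 * float((cx & lateral).sum()) / float(icd_area)


def fibrosis_fraction(psr: np.ndarray, tissue: np.ndarray) -> float:
    """Picrosirius-red-positive area as a percent of the tissue area."""
    ps = _as_bool(psr, "psr")
    ti = _as_bool(tissue, "tissue")
    if ps.shape != ti.shape:
        raise ValueError("masks differ in shape")
    denom = ti.sum()
    if denom == 0:
        raise ValueError("empty tissue mask")
    return 100.0 * float((ps & ti).sum()) / float(denom)


def quantify(section: MaskSet) -> AreaFractions:
    """All three metrics for one section."""
    m = section.masks
    return AreaFractions(
        cx43_icd_pct=cx43_icd_fraction(m["cx43"], m["ncadh"]),
        lateralization_pct=lateralization_ratio(m["cx43"], m["wga_lateral"], m["ncadh"]),
        fibrosis_pct=fibrosis_fraction(m["psr"], m["tissue"]),
    )


def quantify_sections(sections: Sequence[MaskSet]) -> AreaFractions:
    """Per-animal metrics: the mean over sections (typically 3 per animal)."""
    if not sections:
        raise ValueError("no sections")
    per = [quantify(s) for s in sections]
    return AreaFractions(
        cx43_icd_pct=float(np.mean([p.cx43_icd_pct for p in per])),
        lateralization_pct=float(np.mean([p.lateralization_pct for p in per])),
        fibrosis_pct=float(np.mean([p.fibrosis_pct for p in per])),
    )


def otsu_mask(image: np.ndarray) -> np.ndarray:
    """Binarise a grayscale image with Otsu's threshold (helper, not part of
    the metric contract)."""
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    return img > threshold_otsu(img)
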