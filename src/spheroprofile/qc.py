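"""Pre-processing triage of spheroid fields of view.

A field of view may contain several spheroids. Before radial profiling,
each candidate is screened in sequence: is it fully in view, is it free of
contact with neighbours, and can a padded square crop be taken around it?
Candidates fail with the first applicable reason, mirroring a sequential
triage flowchart, and the report accounts for every detected candidate
exactly once.

The original workflow performed this triage by eye; here each decision is
a deterministic, parameterised test (Otsu foreground, border margin,
minimum pixel distance, padded-box fit + circularity) so the triage is
reproducible and auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .images import ImageGrid
from .profiling import mask_circularity

__all__ = [
    "CandidateRegion",
    "QCReport",
    "QCConfig",
    "detect_candidates",
    "qc_full_view",
    "qc_touching",
    "qc_croppable",
    "run_qc",
]


@dataclass
class CandidateRegion:
    """One 8-connected foreground component of a field of view."""

    label: int
    pixels: np.ndarray  # (n, 2) array of (row, col) indices
    bounding_box: tuple[int, int, int, int]  # row_min, row_max, col_min, col_max (inclusive)
    area_px: int

    @classmethod
    def from_pixels(cls, label: int, pixels: np.ndarray) -> "CandidateRegion":
        pixels = np.asarray(pixels)
        bbox = (
            int(pixels[:, 0].min()),
            int(pixels[:, 0].max()),
            int(pixels[:, 1].min()),
            int(pixels[:, 1].max()),
        )
        return cls(label=label, pixels=pixels, bounding_box=bbox, area_px=len(pixels))

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class QCReport:
    """Accounting of every candidate: accepted or rejected with a reason."""

    n_detected: int = 0
    n_accepted: int = 0
    rejections: list = field(default_factory=list)  # (label, reason)

    def to_dict(self) -> dict:
        return {
            "n_detected": self.n_detected,
            "n_accepted": self.n_accepted,
            "rejections": [
                {"label": int(lab), "reason": reason} for lab, reason in self.rejections
            ],
        }


@dataclass
class QCConfig:
    """Thresholds for the automated triage.

    ``min_area_px`` is calibrated to the 200 x 200 working grid; the
    remaining defaults are deliberately permissive so that only clear-cut
    failures are rejected.
    """

    min_area_px: int = 200
    border_margin_px: int = 2
    gap_px: int = 3
    pad_fraction: float = 0.15
    min_circularity: float = 0.4


def detect_candidates(image: ImageGrid, min_area_px: int,
                      rejections: list | None = None) -> list[CandidateRegion]:
    """Detect candidate spheroids as 8-connected Otsu-foreground components.

    Holes are filled before labelling. Components smaller than
    ``min_area_px`` are dropped (and, when ``rejections`` is provided,
    logged there as ``too_small``). Candidates are returned sorted by
    descending area.
    """
    values = image.values
    if np.ptp(values) == 0:
        return []
    fg = values > threshold_otsu(values)
    if not fg.any():
        return []
    fg = ndimage.binary_fill_holes(fg)
    labels = cc_label(fg, connectivity=2)
    regions: list[CandidateRegion] = []
    for lab in range(1, labels.max() + 1):
        pix = np.argwhere(labels == lab)
        region = CandidateRegion.from_pixels(lab, pix)
        if region.area_px < min_area_px:
            if rejections is not None:
                rejections.append((lab, "too_small"))
            continue
        regions.append(region)
    regions.sort(key=lambda r: -r.area_px)
    return regions


def qc_full_view(region: CandidateRegion, image_shape: tuple[int, int],
                 border_margin_px: int) -> bool:
    """True iff no pixel of the region lies within the border margin.

    A pixel at row r is "within" the margin when its distance to the
    nearest edge is <= border_margin_px, i.e. acceptance requires
    r > margin on all four sides.
    """
    rows, cols = image_shape
    r0, r1, c0, c1 = region.bounding_box
    m = border_margin_px
    return r0 > m and c0 > m and r1 < rows - 1 - m and c1 < cols - 1 - m


def qc_touching(region: CandidateRegion, others: list[CandidateRegion],
                gap_px: float) -> bool:
    """True (reject) iff another region comes within ``gap_px`` pixels.

    Distance is the minimum Euclidean distance between the two pixel sets.
    """
    if not others:
        return False
    tree = cKDTree(region.pixels)
    for other in others:
        d, _ = tree.query(other.pixels, k=1)
        if d.min() <= gap_px:
            return True
    return False


def _crop_window(region: CandidateRegion, pad_fraction: float):
    """Square crop window: side = max(bbox sides) * (1 + 2 * pad_fraction),
    centred on the bounding box centre. Returns integer (r0, r1, c0, c1),
    end-exclusive."""
    r0, r1, c0, c1 = region.bounding_box
    side = max(r1 - r0 + 1, c1 - c0 + 1) * (1 + 2 * pad_fraction)
    side = int(np.ceil(side))
    cr = (r0 + r1) / 2
    cc = (c0 + c1) / 2
    rs = int(np.floor(cr - side / 2 + 0.5))
    cs = int(np.floor(cc - side / 2 + 0.5))
    return rs, rs + side, cs, cs + side


def qc_croppable(region: CandidateRegion, image_shape: tuple[int, int],
                 pad_fraction: float, min_circularity: float = 0.4) -> bool:
    """True iff the padded square crop fits in the image and the region is
    round enough (circularity 4*pi*A/P^2 >= ``min_circularity``).

    The circularity gate rejects fused or highly irregular blobs that
    would defeat centroid-based radial profiling.
    """
    rows, cols = image_shape
    rs, re, cs, ce = _crop_window(region, pad_fraction)
    if rs < 0 or cs < 0 or re > rows or ce > cols:
        return False
    return mask_circularity(region.mask(image_shape)) >= min_circularity


def run_qc(image: ImageGrid, config: QCConfig | None = None):
    """Run the full triage on one field of view.

    Applies detect -> full-view -> touching -> croppable in order; each
    accepted region yields a square :class:`ImageGrid` crop. Every
    candidate appears exactly once in the report, with its first failing
    reason.

    Returns ``(crops, report)`` where ``crops`` is a list of
    ``(label, ImageGrid)`` pairs.
    """
    if config is None:
        config = QCConfig()
    report = QCReport()
    regions = detect_candidates(image, config.min_area_px, rejections=report.rejections)
    report.n_detected = len(regions) + len(report.rejections)
    crops = []
    for region in regions:
        if not qc_full_view(region, image.shape, config.border_margin_px):
            report.rejections.append((region.label, "not_full_view"))
            continue
        others = [r for r in regions if r.label != region.label]
        if qc_touching(region, others, config.gap_px):
            report.rejections.append((region.label, "touching"))
            continue
        if not qc_croppable(region, image.shape, config.pad_fraction,
                            config.min_circularity):
            report.rejections.append((region.label, "not_croppable"))
            continue
        rs, re, cs, ce = _crop_window(region, config.pad_fraction)
        crop = ImageGrid(
            image.values[rs:re, cs:ce].copy(),
            image.pixel_size_um,
            image.channel_name,
            image.bit_depth,
        )
        crops.append((region.label, crop))
        report.n_accepted += 1
    return crops, report
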