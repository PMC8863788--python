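"""Bead detection and population decoding for encoded-microbead chip images.

A chip image carries three channels: two encoding channels (the internal
blue/green dye intensities that, together with bead size, identify the bead
population) and one measurement channel (the surface halo of the labelled
aptamer).  This module finds the beads in the encoding channels, extracts
per-bead encoding features, and assigns each bead to a population from a
reference panel -- or to "unclassified" when it matches no population within
the gating distance.

Detection is multi-scale Laplacian-of-Gaussian blob detection on the sum of
the encoding channels, followed by sub-pixel centroid refinement, radius
refinement from the half-maximum of the radial intensity profile, and a
circularity filter.  Decoding operates in (log encoding ratio, bead
diameter) feature space with a per-dimension standardized Euclidean
distance, because the populations are encoded by dye *ratio* and size.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.feature import blob_log

__all__ = [
    "ChipImage",
    "BeadDetection",
    "PopulationCode",
    "ReferencePanel",
    "EncodingFeatures",
    "DetectionParams",
    "QCFlag",
    "UNCLASSIFIED",
    "default_panel",
    "read_chip_tiff",
    "detect_beads",
    "flag_doublets",
    "estimate_background",
    "measure_encoding",
    "decode_population",
]

UNCLASSIFIED = "unclassified"


class QCFlag(enum.Enum):
    """Enumerated per-bead quality-control outcomes."""

    OK = "ok"
    EDGE = "edge"
    DOUBLET = "doublet"
    RATIO_UNDEFINED = "ratio_undefined"
    UNCLASSIFIED = "unclassified"
    HALO_EDGE = "halo_edge"
    BACKGROUND_FALLBACK = "background_fallback"  # informative, not a failure
    AMBIGUOUS = "ambiguous"  # exact decode-distance tie, resolved by panel order


@dataclass(frozen=True)
class ChipImage:
    """One well at one time point: three co-registered 2-D channel rasters."""

    encode1: np.ndarray
    encode2: np.ndarray
    measure: np.ndarray
    pixel_size: float = 1.0
    well_id: str = "well"
    frame_index: int = 0

    def __post_init__(self) -> None:
        shapes = {self.encode1.shape, self.encode2.shape, self.measure.shape}
        if len(shapes) != 1 or self.encode1.ndim != 2:
            raise ValueError(f"all channels must share one 2-D shape, got {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.encode1.shape

    @property
    def channels(self) -> dict[str, np.ndarray]:
        return {"encode1": self.encode1, "encode2": self.encode2, "measure": self.measure}


def read_chip_tiff(path: str | Path, pixel_size: float | None = None,
                   well_id: str | None = None, frame_index: int = 0) -> ChipImage:
    """Read a three-page (encode1, encode2, measure) TIFF into a ChipImage."""
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if stack.ndim != 3 or stack.shape[0] != 3:
        raise ValueError(f"expected a 3-channel stack, got shape {stack.shape}")
    return ChipImage(
        encode1=stack[0], encode2=stack[1], measure=stack[2],
        pixel_size=float(pixel_size if pixel_size is not None else meta.get("pixel_size_um", 1.0)),
        well_id=str(well_id if well_id is not None else meta.get("well_id", Path(path).stem)),
        frame_index=int(meta.get("frame_index", frame_index)),
    )


@dataclass(frozen=True)
class PopulationCode:
    """One panel entry: the dye/size code and the coupled protein."""

    population_id: str
    protein: str
    diameter: float  # µm
    enc1: float  # nominal encoding intensity, a.u.
    enc2: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.enc1 <= 0 or self.enc2 <= 0:
            raise ValueError("nominal encoding intensities must be positive")

    @property
    def log_ratio(self) -> float:
        return float(np.log(self.enc1 / self.enc2))


@dataclass(frozen=True)
class ReferencePanel:
    """The code book: populations plus per-dimension feature dispersions.

    ``sd_log_ratio`` and ``sd_diameter_frac`` are the expected per-bead
    standard deviations of the decoding features (log encoding ratio;
    diameter, as a fraction of the nominal diameter) used to standardize the
    decoding distance.
    """

    populations: list[PopulationCode]
    sd_log_ratio: float = 0.1
    sd_diameter_frac: float = 0.05

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("panel must contain at least one population")
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError("population ids must be unique")
        pts = np.array([[p.log_ratio, p.diameter] for p in self.populations])
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                dz = (pts[i, 0] - pts[j, 0]) / self.sd_log_ratio
                dd = (pts[i, 1] - pts[j, 1]) / (self.sd_diameter_frac * pts[i, 1])
                if np.hypot(dz, dd) < 2.0:
                    warnings.warn(
                        f"populations {ids[i]} and {ids[j]} are closer than 2 SD "
                        "in (log ratio, diameter) space; decoding may be unreliable",
                        stacklevel=2,
                    )

    def __len__(self) -> int:
        return len(self.populations)

    @property
    def population_ids(self) -> list[str]:
        return [p.population_id for p in self.populations]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"population_id": p.population_id, "protein": p.protein,
                 "diameter": p.diameter, "enc1": p.enc1, "enc2": p.enc2}
                for p in self.populations
            ]
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ReferencePanel":
        df = pd.read_csv(path)
        pops = [
            PopulationCode(
                population_id=str(r.population_id), protein=str(getattr(r, "protein", "")),
                diameter=float(r.diameter), enc1=float(r.enc1), enc2=float(r.enc2),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(populations=pops, **kwargs)


_DEFAULT_PROTEINS = (
    "IFNg", "thrombin", "streptavidin", "PfLDH",
    "TNFa", "protein_A", "protein_G", "mouse_IgG",
    "enterotoxin_B", "HSA", "GST", "neutravidin",
    "prothrombin", "anti_lacZ_IgG", "Fc_IgG1", "ethanolamine_ctrl",
)


def default_panel(n_populations: int = 16) -> ReferencePanel:
    """A synthetic 16-population code book: two sizes x eight dye ratios.

    Diameters alternate between 10 and 15 µm; the enc1/enc2 ratio steps
    geometrically by a factor of 2 over eight levels, mirroring how
    commercial bead sets encode populations by size and two dye intensities.
    The first four populations carry the screen's aptamer targets; the rest
    are specificity controls.
    """
    if not 1 <= n_populations <= 16:
        raise ValueError("default panel supports 1-16 populations")
    pops = []
    for k in range(n_populations):
        level = k // 2
        ratio = 2.0 ** (level - 3.5)
        diameter = 10.0 if k % 2 == 0 else 15.0
        enc2 = 2000.0
        pops.append(
            PopulationCode(
                population_id=f"P{k:02d}",
                protein=_DEFAULT_PROTEINS[k],
                diameter=diameter,
                enc1=round(ratio * enc2, 1),
                enc2=enc2,
            )
        )
    return ReferencePanel(populations=pops)


@dataclass(frozen=True)
class BeadDetection:
    """One detected bead candidate (before decoding)."""

    center: tuple[float, float]  # (row, col), sub-pixel
    radius: float  # pixels
    circularity: float
    edge_flag: bool
    doublet_flag: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.circularity <= 1.0:
            raise ValueError("circularity must be in [0, 1]")


@dataclass(frozen=True)
class DetectionParams:
    """Settings for blob detection and refinement.

    Radii are in pixels and should bracket the panel's bead radii; the
    relative threshold is applied to the background-subtracted,
    max-normalized encoding sum.
    """

    min_radius: float = 3.5
    max_radius: float = 10.0
    num_scales: int = 8
    threshold_rel: float = 0.05
    min_circularity: float = 0.7
    overlap: float = 0.3


def _radial_profile(img: np.ndarray, center: tuple[float, float], r_max: float,
                    n_bins: int = 24) -> tuple[np.ndarray, np.ndarray]:
    h, w = img.shape
    r0 = max(int(center[0] - r_max), 0)
    r1 = min(int(center[0] + r_max) + 2, h)
    c0 = max(int(center[1] - r_max), 0)
    c1 = min(int(center[1] + r_max) + 2, w)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    rho = np.hypot(rr - center[0], cc - center[1]).ravel()
    vals = img[r0:r1, c0:c1].ravel()
    keep = rho < r_max
    rho, vals = rho[keep], vals[keep]
    edges = np.linspace(0.0, r_max, n_bins + 1)
    idx = np.clip(np.digitize(rho, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        prof = sums / np.where(counts > 0, counts, 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return mids, prof


def _refine_radius(img: np.ndarray, center: tuple[float, float], r_guess: float) -> float:
    """Radius at the half-maximum crossing of the radial intensity profile."""
    mids, prof = _radial_profile(img, center, r_guess * 2.0)
    inner = prof[mids < 0.6 * r_guess]
    plateau = float(np.median(inner)) if inner.size else float(prof[0])
    if plateau <= 0:
        return r_guess
    half = 0.5 * plateau
    below = np.nonzero(prof < half)[0]
    start = np.argmax(mids > 0.3 * r_guess)
    below = below[below >= start]
    if below.size == 0:
        return r_guess
    i = int(below[0])
    if i == 0:
        return float(mids[0])
    # linear interpolation between the bracketing bins
    x0, x1 = mids[i - 1], mids[i]
    y0, y1 = prof[i - 1], prof[i]
    if y0 == y1:
        return float(x0)
    return float(x0 + (half - y0) / (y1 - y0) * (x1 - x0))


def detect_beads(image: ChipImage, params: DetectionParams | None = None) -> list[BeadDetection]:
    """Detect beads in the encoding channels.

    Multi-scale Laplacian-of-Gaussian blob detection on the summed,
    background-subtracted encoding channels; each blob is refined to a
    sub-pixel intensity-weighted centroid and a half-maximum radius, scored
    for circularity from its intensity second moments, and flagged when it
    touches the image border.  Candidates below the circularity threshold
    are dropped.  A flat or empty image yields an empty list.
    """
    params = params or DetectionParams()
    signal = image.encode1.astype(float) + image.encode2.astype(float)
    bg = float(np.median(signal))
    signal = signal - bg
    peak = float(signal.max())
    if peak <= 0:
        return []
    norm = signal / peak

    sigmas = np.linspace(
        params.min_radius / np.sqrt(2.0), params.max_radius / np.sqrt(2.0), params.num_scales
    )
    blobs = blob_log(
        norm, min_sigma=sigmas[0], max_sigma=sigmas[-1], num_sigma=len(sigmas),
        threshold=params.threshold_rel, overlap=params.overlap,
    )
    h, w = image.shape
    detections: list[BeadDetection] = []
    for row, col, sigma in blobs:
        r_guess = float(sigma * np.sqrt(2.0))
        # sub-pixel centroid over the blob's footprint
        rr0 = max(int(row - r_guess), 0)
        rr1 = min(int(row + r_guess) + 2, h)
        cc0 = max(int(col - r_guess), 0)
        cc1 = min(int(col + r_guess) + 2, w)
        win = np.clip(signal[rr0:rr1, cc0:cc1], 0.0, None)
        tot = win.sum()
        if tot <= 0:
            continue
        rr, cc = np.meshgrid(np.arange(rr0, rr1), np.arange(cc0, cc1), indexing="ij")
        cr = float((rr * win).sum() / tot)
        cc_ = float((cc * win).sum() / tot)
        radius = _refine_radius(signal, (cr, cc_), r_guess)
        radius = float(np.clip(radius, 0.5 * params.min_radius, 1.5 * params.max_radius))
        # circularity: sqrt of the minor/major eigenvalue ratio of the
        # intensity covariance (1 for a circular footprint)
        drow = rr - cr
        dcol = cc - cc_
        srr = float((win * drow * drow).sum() / tot)
        scc = float((win * dcol * dcol).sum() / tot)
        src = float((win * drow * dcol).sum() / tot)
        tr = srr + scc
        det = srr * scc - src * src
        disc = max(tr * tr / 4.0 - det, 0.0)
        lam1 = tr / 2.0 + np.sqrt(disc)
        lam2 = tr / 2.0 - np.sqrt(disc)
        circ = float(np.sqrt(max(lam2, 0.0) / lam1)) if lam1 > 0 else 0.0
        if circ < params.min_circularity:
            continue
        edge = (
            cr - radius < 1.0 or cc_ - radius < 1.0
            or cr + radius > h - 2.0 or cc_ + radius > w - 2.0
        )
        detections.append(
            BeadDetection(center=(cr, cc_), radius=radius, circularity=circ, edge_flag=edge)
        )
    return detections


def flag_doublets(detections: Sequence[BeadDetection], factor: float = 1.2) -> list[BeadDetection]:
    """Flag beads whose nearest neighbour is closer than factor x (r_i + r_j).

    Clumped beads bias both encoding and halo statistics, so they are gated
    out downstream rather than analysed.
    """
    if len(detections) < 2:
        return list(detections)
    centers = np.array([d.center for d in detections])
    radii = np.array([d.radius for d in detections])
    from scipy.spatial import cKDTree

    tree = cKDTree(centers)
    max_reach = factor * 2.0 * radii.max()
    pairs = tree.query_pairs(max_reach, output_type="ndarray")
    flagged = np.zeros(len(detections), dtype=bool)
    if pairs.size:
        d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
        close = d < factor * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
        for i, j in pairs[close]:
            flagged[i] = flagged[j] = True
    return [
        replace(det, doublet_flag=bool(fl)) if fl else det
        for det, fl in zip(detections, flagged)
    ]


def estimate_background(
    image: ChipImage, detections: Sequence[BeadDetection], margin_factor: float = 2.0
) -> dict[str, float]:
    """Per-channel far-field background: median over pixels away from beads."""
    h, w = image.shape
    mask = np.zeros((h, w), dtype=bool)
    for det in detections:
        reach = det.radius * margin_factor
        r0 = max(int(det.center[0] - reach), 0)
        r1 = min(int(det.center[0] + reach) + 2, h)
        c0 = max(int(det.center[1] - reach), 0)
        c1 = min(int(det.center[1] + reach) + 2, w)
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        mask[r0:r1, c0:c1] |= np.hypot(rr - det.center[0], cc - det.center[1]) < reach
    free = ~mask
    if not free.any():  # fully covered chip: fall back to the global median
        free = np.ones((h, w), dtype=bool)
    return {name: float(np.median(ch[free])) for name, ch in image.channels.items()}


@dataclass(frozen=True)
class EncodingFeatures:
    """Background-corrected per-bead encoding features."""

    enc1: float
    enc2: float
    ratio: float
    radius: float  # pixels
    diameter: float  # µm

    @property
    def log_ratio(self) -> float:
        return float(np.log(self.ratio))


def measure_encoding(
    image: ChipImage,
    detection: BeadDetection,
    background: dict[str, float] | None = None,
    erosion_fraction: float = 0.3,
) -> EncodingFeatures:
    """Mean encoding intensities over the eroded inner disk of one bead.

    The disk radius is shrunk by ``erosion_fraction`` to stay clear of the
    soft bead edge; the far-field background is subtracted per channel and
    the enc1/enc2 ratio of the corrected means is formed.

    Raises ``ValueError`` with a gating code for edge-flagged beads
    (:attr:`QCFlag.EDGE`) and for beads whose corrected enc2 is not positive
    (:attr:`QCFlag.RATIO_UNDEFINED`).
    """
    if detection.edge_flag:
        raise ValueError(QCFlag.EDGE.value)
    if background is None:
        background = {
            "encode1": float(np.median(image.encode1)),
            "encode2": float(np.median(image.encode2)),
        }
    r_in = detection.radius * (1.0 - erosion_fraction)
    h, w = image.shape
    r0 = max(int(detection.center[0] - r_in), 0)
    r1 = min(int(detection.center[0] + r_in) + 2, h)
    c0 = max(int(detection.center[1] - r_in), 0)
    c1 = min(int(detection.center[1] + r_in) + 2, w)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    disk = np.hypot(rr - detection.center[0], cc - detection.center[1]) <= r_in
    if not disk.any():
        raise ValueError(QCFlag.EDGE.value)
    enc1 = float(image.encode1[r0:r1, c0:c1][disk].mean()) - background["encode1"]
    enc2 = float(image.encode2[r0:r1, c0:c1][disk].mean()) - background["encode2"]
    if enc2 <= 0:
        raise ValueError(QCFlag.RATIO_UNDEFINED.value)
    return EncodingFeatures(
        enc1=enc1, enc2=enc2, ratio=enc1 / enc2, radius=detection.radius,
        diameter=2.0 * detection.radius * image.pixel_size,
    )


def decode_population(
    features: EncodingFeatures,
    panel: ReferencePanel,
    max_distance: float = 3.0,
) -> tuple[str, float, bool]:
    """Assign encoding features to the nearest panel population.

    The distance is per-dimension standardized Euclidean in
    (log enc1/enc2 ratio, diameter) space, scaled by the panel's dispersion
    estimates; a bead farther than ``max_distance`` from every population is
    "unclassified".  Returns (population id, distance, ambiguous) where
    ``ambiguous`` marks an exact distance tie resolved by panel order.
    """
    if features.enc1 <= 0 or features.ratio <= 0 or not np.isfinite(features.ratio):
        return UNCLASSIFIED, float("inf"), False
    z = features.log_ratio
    dia = features.diameter
    best_id, best_d, second_d = UNCLASSIFIED, np.inf, np.inf
    for pop in panel.populations:
        dz = (z - pop.log_ratio) / panel.sd_log_ratio
        dd = (dia - pop.diameter) / (panel.sd_diameter_frac * pop.diameter)
        dist = float(np.hypot(dz, dd))
        if dist < best_d:
            best_id, second_d, best_d = pop.population_id, best_d, dist
        elif dist < second_d:
            second_d = dist
    if best_d > max_distance:
        return UNCLASSIFIED, best_d, False
    return best_id, best_d, bool(best_d == second_d)
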