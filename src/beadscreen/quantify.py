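"""Halo quantification and the per-population rMFI statistic.

Bound, fluorescently labelled aptamer images as a ring ("halo") at the rim
of each bead in the measurement channel.  For every detected bead the halo
is quantified as a background-corrected, geometry-calibrated ring intensity;
per population these are averaged into the referenced mean fluorescence
intensity (rMFI), the assay's reporting unit.

The ring statistic is an (optionally trimmed) mean over an annulus
straddling the bead radius; the default is the plain mean, which stays
exactly linear in the pixel values and therefore unbiased under zero-mean
noise.  Because the halo has a radial profile (it is brightest exactly at
the rim and falls off inwards and outwards), the raw annulus mean
understates the ring amplitude by a purely geometric factor; the statistic
is therefore divided by the expected profile attenuation over the same
annulus pixels, so that an ideal noise-free halo of amplitude A yields
halo_surface = A.  Set ``profile_calibration=False`` in the annulus settings
to obtain the uncalibrated annulus mean instead.

The local background is the median of an outer annulus well clear of the
halo, excluding pixels that belong to neighbouring beads; subtracting it
makes halo_surface invariant to constant offsets of the measurement channel.
Negative halo_surface values are retained so that population means stay
unbiased near zero binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import trim_mean

from .beadimg import (
    UNCLASSIFIED,
    BeadDetection,
    ChipImage,
    DetectionParams,
    EncodingFeatures,
    QCFlag,
    ReferencePanel,
    decode_population,
    detect_beads,
    estimate_background,
    flag_doublets,
    measure_encoding,
)

__all__ = [
    "AnnulusSettings",
    "BeadMeasurement",
    "PopulationSummary",
    "KineticTrace",
    "ChipAnalysis",
    "measure_halo",
    "summarize_population",
    "analyze_chip",
    "rmfi_timeseries",
]

#: QC flags that disqualify a bead from population statistics
_FAILING_FLAGS = frozenset(
    {QCFlag.EDGE, QCFlag.DOUBLET, QCFlag.RATIO_UNDEFINED, QCFlag.HALO_EDGE}
)


@dataclass(frozen=True)
class AnnulusSettings:
    """Geometry of the halo and background annuli (fractions of the bead
    radius r): ring pixels lie in [r(1-w_in), r(1+w_out)], background pixels
    in [r(1+bg_in), r(1+bg_out)].  ``halo_width`` (µm) is the expected
    Gaussian radial width of the halo, used for the profile calibration.
    """

    w_in: float = 0.1
    w_out: float = 0.3
    bg_in: float = 1.0
    bg_out: float = 1.6
    trim: float = 0.0
    halo_width: float = 1.5
    profile_calibration: bool = True
    refine_ring_radius: bool = False
    occlusion_factor: float = 1.3
    max_occluded_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.w_in < 1 or self.w_out <= 0:
            raise ValueError("ring annulus fractions out of range")
        if not 0 < self.bg_in < self.bg_out:
            raise ValueError("background annulus must satisfy 0 < bg_in < bg_out")
        if not 0 <= self.trim < 0.5:
            raise ValueError("trim fraction must be in [0, 0.5)")


def _annulus_pixels(
    shape: tuple[int, int], center: tuple[float, float], r_lo: float, r_hi: float
):
    h, w = shape
    r0 = max(int(np.floor(center[0] - r_hi)), 0)
    r1 = min(int(np.ceil(center[0] + r_hi)) + 1, h)
    c0 = max(int(np.floor(center[1] - r_hi)), 0)
    c1 = min(int(np.ceil(center[1] + r_hi)) + 1, w)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    rho = np.hypot(rr - center[0], cc - center[1])
    keep = (rho >= r_lo) & (rho <= r_hi)
    return rr[keep], cc[keep], rho[keep]


def measure_halo(
    image: ChipImage,
    detection: BeadDetection,
    annulus: AnnulusSettings | None = None,
    neighbors: Sequence[BeadDetection] = (),
    global_background: float | None = None,
) -> tuple[float, float, list[QCFlag]]:
    """Quantify one bead's halo in the measurement channel.

    Returns ``(halo_surface, local_background, flags)`` where halo_surface =
    (trimmed ring mean - local background) / kappa; kappa is the trimmed
    mean of the expected Gaussian ring profile over the same annulus pixels
    (1.0 with ``profile_calibration=False``).  The local background is the
    median of the outer annulus after excluding pixels inside any
    neighbouring detection (inflated by ``occlusion_factor``); if more than
    ``max_occluded_fraction`` of it is occluded the global image background
    is used instead and the measurement is flagged.

    A ring annulus that extends past the image border gates the bead with
    :attr:`QCFlag.HALO_EDGE`.
    """
    annulus = annulus or AnnulusSettings()
    r = detection.radius
    h, w = image.shape
    cy, cx = detection.center
    sigma_px = annulus.halo_width / image.pixel_size
    if cy - r - 3 * sigma_px < 0 or cx - r - 3 * sigma_px < 0 \
            or cy + r + 3 * sigma_px > h - 1 or cx + r + 3 * sigma_px > w - 1:
        return float("nan"), float("nan"), [QCFlag.HALO_EDGE]

    flags: list[QCFlag] = []
    meas = image.measure

    # local background first (from the unrefined radius): median of the
    # outer annulus, cleared of pixels inside neighbouring detections
    bg_rr, bg_cc, bg_rho = _annulus_pixels(
        image.shape, detection.center, r * (1.0 + annulus.bg_in), r * (1.0 + annulus.bg_out)
    )
    n_total = bg_rho.size
    if n_total:
        free = np.ones(n_total, dtype=bool)
        for nb in neighbors:
            if nb is detection:
                continue
            d2 = (bg_rr - nb.center[0]) ** 2 + (bg_cc - nb.center[1]) ** 2
            free &= d2 > (annulus.occlusion_factor * nb.radius) ** 2
    occluded_frac = 1.0 - (free.sum() / n_total) if n_total else 1.0
    if n_total == 0 or occluded_frac > annulus.max_occluded_fraction:
        if global_background is None:
            global_background = float(np.median(meas))
        local_background = global_background
        noise_scale = float(np.median(np.abs(meas - local_background)))
        flags.append(QCFlag.BACKGROUND_FALLBACK)
    else:
        bg_vals = meas[bg_rr[free], bg_cc[free]].astype(float)
        local_background = float(np.median(bg_vals))
        noise_scale = 1.4826 * float(np.median(np.abs(bg_vals - local_background)))

    if annulus.refine_ring_radius:
        # the ring crest may sit slightly off the detected bead radius (the
        # detection radius comes from the encoding channels); re-estimate it
        # from the measurement channel so the calibration is centred on the
        # crest.  The intensity-weighted radial centroid over a window
        # symmetric about the crest is first-order insensitive to the
        # initial radius, unlike the calibrated annulus mean itself.
        win_rr, win_cc, win_rho = _annulus_pixels(
            image.shape, detection.center,
            max(r - 2.5 * sigma_px, 0.3 * r), r + 2.5 * sigma_px,
        )
        vals = meas[win_rr, win_cc].astype(float)
        excess = vals - local_background
        # refine only when the ring clearly rises above the background noise;
        # weights are left unclipped so the zero-mean noise does not drag
        # the centroid toward the window midpoint
        if excess.size and excess.max() > 5.0 * noise_scale + 1e-9:
            # 1/rho weights cancel the ~rho growth of pixel count per shell,
            # so the centroid is unbiased for a radially symmetric crest
            u = excess / np.maximum(win_rho, 1e-9)
            denom = u.sum()
            if denom > 0:
                r_ring = float((u * win_rho).sum() / denom)
                if 0.6 * r <= r_ring <= 1.4 * r:
                    r = r_ring
    r_hi = r * (1.0 + annulus.w_out)
    rr, cc, rho = _annulus_pixels(image.shape, detection.center, r * (1.0 - annulus.w_in), r_hi)
    if rho.size < 4:
        return float("nan"), float("nan"), [QCFlag.HALO_EDGE]
    ring_vals = meas[rr, cc].astype(float)
    ring_stat = float(trim_mean(ring_vals, annulus.trim))

    if annulus.profile_calibration:
        profile = np.exp(-0.5 * ((rho - r) / sigma_px) ** 2)
        kappa = float(trim_mean(profile, annulus.trim))
        kappa = max(kappa, 1e-6)
    else:
        kappa = 1.0
    halo_surface = (ring_stat - local_background) / kappa
    return halo_surface, local_background, flags


@dataclass(frozen=True)
class BeadMeasurement:
    """One fully analysed bead: detection, decode and halo quantification."""

    detection: BeadDetection
    population_id: str  # panel id or "unclassified"
    features: EncodingFeatures | None
    halo_surface: float
    local_background: float
    qc_flags: tuple[QCFlag, ...] = ()
    decode_distance: float = float("nan")

    @property
    def passes_qc(self) -> bool:
        return not (_FAILING_FLAGS & set(self.qc_flags))

    @property
    def classified(self) -> bool:
        return self.population_id != UNCLASSIFIED


@dataclass(frozen=True)
class PopulationSummary:
    """Per-population aggregate for one well: the unit of reporting."""

    population_id: str
    n: int
    rmfi: float
    sd: float
    unclassified_count: int = 0
    valid: bool = True

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.valid and self.sd < 0:
            raise ValueError("SD must be >= 0")


def summarize_population(
    measurements: Sequence[BeadMeasurement],
    population_id: str,
    reference_scale: float = 1.0,
    min_beads: int = 10,
) -> PopulationSummary:
    """Aggregate one population's beads into rMFI +/- SD.

    rMFI is the arithmetic mean of halo_surface over QC-passing beads of the
    population, divided by ``reference_scale`` (the configurable "reference"
    of the rMFI convention; 1.0 reports plain background-corrected
    intensity).  QC-failed and unclassified beads are excluded but counted.
    With fewer than ``min_beads`` usable beads the summary is marked invalid
    rather than silently reported.
    """
    if reference_scale <= 0:
        raise ValueError("reference_scale must be positive")
    unclassified = sum(1 for m in measurements if not m.classified)
    vals = np.array(
        [
            m.halo_surface
            for m in measurements
            if m.population_id == population_id and m.passes_qc and np.isfinite(m.halo_surface)
        ]
    )
    n = int(vals.size)
    if n < min_beads:
        return PopulationSummary(
            population_id=population_id, n=n, rmfi=float("nan"), sd=float("nan"),
            unclassified_count=unclassified, valid=False,
        )
    scaled = vals / reference_scale
    return PopulationSummary(
        population_id=population_id, n=n, rmfi=float(scaled.mean()),
        sd=float(scaled.std(ddof=1)) if n > 1 else 0.0,
        unclassified_count=unclassified, valid=True,
    )


@dataclass(frozen=True)
class ChipAnalysis:
    """Result of the full detect -> decode -> quantify pass over one chip."""

    image_well: str
    frame_index: int
    measurements: list[BeadMeasurement]
    summaries: dict[str, PopulationSummary]

    @property
    def n_detections(self) -> int:
        return len(self.measurements)

    @property
    def n_unclassified(self) -> int:
        return sum(1 for m in self.measurements if not m.classified)

    @property
    def n_qc_failed(self) -> int:
        return sum(1 for m in self.measurements if m.classified and not m.passes_qc)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.measurements:
            rows.append(
                {
                    "well": self.image_well, "frame": self.frame_index,
                    "row": m.detection.center[0], "col": m.detection.center[1],
                    "radius_px": m.detection.radius,
                    "circularity": m.detection.circularity,
                    "population": m.population_id,
                    "halo_surface": m.halo_surface,
                    "local_background": m.local_background,
                    "qc": ";".join(f.value for f in m.qc_flags) or "ok",
                    "decode_distance": m.decode_distance,
                }
            )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"well": self.image_well, "population": s.population_id, "n": s.n,
                 "rMFI": s.rmfi, "SD": s.sd, "valid": s.valid}
                for s in self.summaries.values()
            ]
        )


def analyze_chip(
    image: ChipImage,
    panel: ReferencePanel,
    detection_params: DetectionParams | None = None,
    annulus: AnnulusSettings | None = None,
    max_distance: float = 3.0,
    reference_scale: float = 1.0,
    min_beads: int = 10,
) -> ChipAnalysis:
    """Run the full per-well pipeline: detect, gate, decode and quantify.

    Every detection ends up in exactly one bucket -- a population, the
    unclassified pool, or QC-failed -- so the per-population counts plus
    unclassified plus QC-failed always add up to the number of detections.
    """
    detections = flag_doublets(detect_beads(image, detection_params))
    background = estimate_background(image, detections)
    global_meas_bg = float(np.median(image.measure))

    # neighbour lookup for background-annulus occlusion masking
    ann = annulus or AnnulusSettings()
    if len(detections) > 1:
        from scipy.spatial import cKDTree

        centers = np.array([d.center for d in detections])
        max_r = max(d.radius for d in detections)
        tree = cKDTree(centers)
        reach = max_r * (1.0 + ann.bg_out) + ann.occlusion_factor * max_r
        neighbor_idx = tree.query_ball_point(centers, reach)
    else:
        neighbor_idx = [[] for _ in detections]

    measurements: list[BeadMeasurement] = []
    for i_det, det in enumerate(detections):
        flags: list[QCFlag] = []
        if det.doublet_flag:
            flags.append(QCFlag.DOUBLET)
        features = None
        pop_id = UNCLASSIFIED
        dist = float("nan")
        try:
            features = measure_encoding(image, det, background)
        except ValueError as exc:
            flags.append(QCFlag(exc.args[0]))
        if features is not None:
            pop_id, dist, ambiguous = decode_population(features, panel, max_distance)
            if pop_id == UNCLASSIFIED:
                flags.append(QCFlag.UNCLASSIFIED)
            elif ambiguous:
                flags.append(QCFlag.AMBIGUOUS)
        nearby = [detections[j] for j in neighbor_idx[i_det] if j != i_det]
        halo, local_bg, halo_flags = measure_halo(
            image, det, annulus, neighbors=nearby, global_background=global_meas_bg
        )
        flags.extend(halo_flags)
        measurements.append(
            BeadMeasurement(
                detection=det, population_id=pop_id, features=features,
                halo_surface=halo, local_background=local_bg,
                qc_flags=tuple(flags), decode_distance=dist,
            )
        )

    summaries = {
        pop.population_id: summarize_population(
            measurements, pop.population_id, reference_scale, min_beads
        )
        for pop in panel.populations
    }
    return ChipAnalysis(
        image_well=image.well_id, frame_index=image.frame_index,
        measurements=measurements, summaries=summaries,
    )


@dataclass(frozen=True)
class KineticTrace:
    """rMFI of one population followed over a frame series."""

    population_id: str
    times: tuple[float, ...]
    rmfi: tuple[float, ...]
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(t1 < t2 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("time stamps must be strictly increasing")


def rmfi_timeseries(
    frames: Sequence[ChipImage],
    panel: ReferencePanel,
    times: Sequence[float] | None = None,
    **analysis_kwargs,
) -> list[KineticTrace]:
    """Population-level binding kinetics over an ordered frame series.

    Each frame gets the full detect -> decode -> quantify pass independently
    (beads are not tracked between frames; the population aggregate is the
    kinetic observable).  ``times`` defaults to the frame indices.
    """
    if not frames:
        raise ValueError("need at least one frame")
    shape = frames[0].shape
    well = frames[0].well_id
    for f in frames[1:]:
        if f.shape != shape:
            raise ValueError("frames have incompatible shapes")
        if f.well_id != well:
            raise ValueError("frames must come from the same well")
    times = [float(f.frame_index) for f in frames] if times is None else [float(t) for t in times]
    if len(times) != len(frames):
        raise ValueError("times must match the number of frames")

    analyses = [analyze_chip(f, panel, **analysis_kwargs) for f in frames]
    traces = []
    for pop in panel.populations:
        traces.append(
            KineticTrace(
                population_id=pop.population_id,
                times=tuple(times),
                rmfi=tuple(a.summaries[pop.population_id].rmfi for a in analyses),
                n=tuple(a.summaries[pop.population_id].n for a in analyses),
            )
        )
    return traces
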