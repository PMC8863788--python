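"""Synthetic encoded-microbead chip simulator.

Generates multi-channel fluorescence images of bead chips together with a
per-bead ground-truth table, so that every downstream analysis stage
(detection, decoding, halo quantification, screening statistics) can be
tested against known truth without access to any instrument data.

The simulated chip emulates a settled monolayer of dye/size-encoded
microbeads in one well: each bead belongs to a population identified by its
diameter and by the ratio of its two internal encoding dyes (imaged in two
encoding channels), and carries a surface "halo" in the measurement channel
-- a ring of fluorescence at the bead rim whose amplitude encodes how much
labelled aptamer is bound.  Images are 16-bit with channel order
(encode1, encode2, measure); pixel coordinates are 0-based (row, col) with
pixel centers at integer positions.

Noise model: optional shot noise (Poisson, unit photon gain, so the variance
equals the mean) followed by additive Gaussian read noise, then clipping to
the 16-bit range.  Everything is driven by a single integer seed and is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .beadimg import ChipImage, PopulationCode, ReferencePanel, default_panel

__all__ = [
    "SimConfig",
    "BeadGroundTruth",
    "PlacementError",
    "sample_bead_layout",
    "render_chip_image",
    "generate_screen_dataset",
    "generate_timeseries",
    "layout_to_frame",
    "write_chip",
]

CHANNEL_NAMES = ("encode1", "encode2", "measure")
U16_MAX = 65535


class PlacementError(RuntimeError):
    """Bead layout could not be placed at the requested density."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated chip well.

    Geometry is in micrometres and converted with ``pixel_size`` (µm/pixel).
    ``halo_amplitude_map`` maps population id to the measurement-channel ring
    amplitude (a.u.); populations absent from the map get amplitude 0.
    ``encoding_cv`` is the per-bead coefficient of variation of the encoding
    dye intensities around the population nominal values.  The default bead
    count per population sits in the 500-1000 range typical of one well of a
    multiplex bead assay.
    """

    populations: tuple[PopulationCode, ...] = field(default_factory=lambda: tuple(default_panel().populations))
    image_shape: tuple[int, int] = (3072, 3072)
    pixel_size: float = 1.0
    beads_per_population: int = 500
    min_center_distance: float = 24.0
    halo_amplitude_map: Mapping[str, float] = field(default_factory=dict)
    halo_width: float = 1.5
    background_level: float = 200.0
    encoding_cv: float = 0.05
    read_noise_sd: float = 20.0
    shot_noise: bool = True
    edge_sigma: float = 0.7
    radius_cv: float = 0.02
    doublet_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.populations) == 0:
            raise ValueError("need at least one population")
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValueError("population ids must be unique")
        if self.beads_per_population < 0:
            raise ValueError("beads_per_population must be >= 0")
        for name in ("halo_width", "background_level", "read_noise_sd", "pixel_size"):
            if getattr(self, name) < 0 or (name == "pixel_size" and self.pixel_size <= 0):
                raise ValueError(f"{name} must be non-negative (pixel_size positive)")
        if not 0.0 <= self.encoding_cv < 1.0:
            raise ValueError("encoding_cv must be in [0, 1)")
        if not 0.0 <= self.doublet_fraction < 1.0:
            raise ValueError("doublet_fraction must be in [0, 1)")
        unknown = set(self.halo_amplitude_map) - set(ids)
        if unknown:
            raise ValueError(f"halo_amplitude_map references unknown populations: {sorted(unknown)}")
        if any(v < 0 for v in self.halo_amplitude_map.values()):
            raise ValueError("halo amplitudes must be >= 0")
        largest = max(p.diameter for p in self.populations)
        if self.doublet_fraction == 0.0 and self.min_center_distance < largest:
            raise ValueError(
                f"min_center_distance ({self.min_center_distance} µm) must be at least "
                f"the largest bead diameter ({largest} µm) when doublets are disabled"
            )

    @property
    def panel(self) -> ReferencePanel:
        return ReferencePanel(populations=list(self.populations))

    def with_amplitudes(self, amplitudes: Mapping[str, float]) -> "SimConfig":
        return replace(self, halo_amplitude_map=dict(amplitudes))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        pops = tuple(
            PopulationCode(
                population_id=str(p["population_id"]),
                protein=str(p.get("protein", "")),
                diameter=float(p["diameter"]),
                enc1=float(p["enc1"]),
                enc2=float(p["enc2"]),
            )
            for p in raw.pop("populations")
        )
        if "image_shape" in raw:
            raw["image_shape"] = tuple(int(v) for v in raw["image_shape"])
        if "halo_amplitude_map" in raw:
            raw["halo_amplitude_map"] = {
                str(k): float(v) for k, v in raw["halo_amplitude_map"].items()
            }
        return cls(populations=pops, **raw)


@dataclass(frozen=True)
class BeadGroundTruth:
    """True state of one simulated bead (the oracle for analysis tests)."""

    bead_id: int
    center: tuple[float, float]  # (row, col), sub-pixel
    radius: float  # pixels
    population_id: str
    enc1: float
    enc2: float
    halo_amplitude: float


def _truth_dataframe(layout: Sequence[BeadGroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bead_id": [b.bead_id for b in layout],
            "row": [b.center[0] for b in layout],
            "col": [b.center[1] for b in layout],
            "radius_px": [b.radius for b in layout],
            "population": [b.population_id for b in layout],
            "enc1": [b.enc1 for b in layout],
            "enc2": [b.enc2 for b in layout],
            "halo_amp": [b.halo_amplitude for b in layout],
        }
    )


def sample_bead_layout(config: SimConfig, rng: np.random.Generator | None = None) -> list[BeadGroundTruth]:
    """Place beads by rejection sampling with a minimum center distance.

    Every population contributes ``beads_per_population`` beads.  Candidate
    centers are drawn uniformly inside a margin that keeps the bead and its
    halo fully inside the image; a candidate closer than
    ``min_center_distance`` to an accepted bead is rejected (a grid-based
    neighbour lookup keeps this O(1) per attempt).  With
    ``doublet_fraction > 0`` that fraction of beads is instead attached to a
    random earlier bead at ~1 bead-diameter spacing to emulate clumps.

    Raises :class:`PlacementError` if the attempt budget (200 attempts per
    bead on average) is exhausted before all beads are placed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    h, w = config.image_shape
    total = config.beads_per_population * len(config.populations)
    if total == 0:
        return []

    min_d_px = config.min_center_distance / config.pixel_size
    cell = max(min_d_px, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    centers = np.empty((total, 2), dtype=float)

    # population assignment in round-robin blocks, then shuffled placement order
    pop_of_bead = np.repeat(np.arange(len(config.populations)), config.beads_per_population)
    rng.shuffle(pop_of_bead)

    radii_px = np.empty(total)
    for i, k in enumerate(pop_of_bead):
        pop = config.populations[k]
        r_nom = 0.5 * pop.diameter / config.pixel_size
        radii_px[i] = max(r_nom * (1.0 + config.radius_cv * rng.standard_normal()), 1.0)

    halo_reach = 3.0 * config.halo_width / config.pixel_size
    budget = 200 * total
    attempts = 0
    n_doublets = int(round(config.doublet_fraction * total))
    doublet_ids = set(rng.choice(total, size=n_doublets, replace=False)) if n_doublets else set()

    def neighbours(r: float, c: float):
        ci, cj = int(r // cell), int(c // cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for idx in grid.get((ci + di, cj + dj), ()):
                    yield idx

    placed = 0
    for i in range(total):
        margin = radii_px[i] + halo_reach + 2.0
        if 2 * margin >= min(h, w):
            raise PlacementError("bead (with halo) does not fit inside the image")
        ok = False
        as_doublet = i in doublet_ids and placed > 0
        while attempts < budget:
            attempts += 1
            if as_doublet:
                j = int(rng.integers(0, placed))
                ang = rng.uniform(0, 2 * np.pi)
                sep = (radii_px[i] + radii_px[j]) * 1.02
                r = centers[j, 0] + sep * np.sin(ang)
                c = centers[j, 1] + sep * np.cos(ang)
                if not (margin <= r <= h - 1 - margin and margin <= c <= w - 1 - margin):
                    continue
            else:
                r = rng.uniform(margin, h - 1 - margin)
                c = rng.uniform(margin, w - 1 - margin)
                reject = False
                for idx in neighbours(r, c):
                    dr = centers[idx, 0] - r
                    dc = centers[idx, 1] - c
                    if dr * dr + dc * dc < min_d_px * min_d_px:
                        reject = True
                        break
                if reject:
                    continue
            centers[i] = (r, c)
            grid.setdefault((int(r // cell), int(c // cell)), []).append(i)
            placed += 1
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place bead {i + 1}/{total} at min distance "
                f"{config.min_center_distance} µm within the attempt budget"
            )

    layout: list[BeadGroundTruth] = []
    for i in range(total):
        pop = config.populations[pop_of_bead[i]]
        enc1 = pop.enc1 * max(1.0 + config.encoding_cv * rng.standard_normal(), 0.05)
        enc2 = pop.enc2 * max(1.0 + config.encoding_cv * rng.standard_normal(), 0.05)
        amp = float(config.halo_amplitude_map.get(pop.population_id, 0.0))
        layout.append(
            BeadGroundTruth(
                bead_id=i,
                center=(float(centers[i, 0]), float(centers[i, 1])),
                radius=float(radii_px[i]),
                population_id=pop.population_id,
                enc1=float(enc1),
                enc2=float(enc2),
                halo_amplitude=amp,
            )
        )
    return layout


def _render_bead(
    channel: np.ndarray, bead: BeadGroundTruth, amplitude: float,
    profile: str, config: SimConfig,
) -> None:
    """Add one bead's footprint to a float channel raster in place."""
    from scipy.special import erf

    h, w = channel.shape
    halo_sigma = config.halo_width / config.pixel_size
    reach = bead.radius + (3.0 * halo_sigma if profile == "ring" else 3.0 * config.edge_sigma) + 1.0
    r0 = max(int(np.floor(bead.center[0] - reach)), 0)
    r1 = min(int(np.ceil(bead.center[0] + reach)) + 1, h)
    c0 = max(int(np.floor(bead.center[1] - reach)), 0)
    c1 = min(int(np.ceil(bead.center[1] + reach)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"bead {bead.bead_id} lies fully outside the image")
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    rho = np.hypot(rr - bead.center[0], cc - bead.center[1])
    if profile == "disk":
        # erf edge == disk convolved with a Gaussian of width edge_sigma
        footprint = 0.5 * (1.0 + erf((bead.radius - rho) / (np.sqrt(2.0) * config.edge_sigma)))
    else:
        footprint = np.exp(-0.5 * ((rho - bead.radius) / halo_sigma) ** 2)
    channel[r0:r1, c0:c1] += amplitude * footprint


def render_chip_image(
    layout: Sequence[BeadGroundTruth],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    well_id: str = "well",
    frame_index: int = 0,
) -> ChipImage:
    """Render a layout into a three-channel 16-bit chip image.

    Encoding channels hold soft-edged filled disks at each bead with the
    bead's true encoding intensities; the measurement channel holds, per
    bead, a Gaussian-profile ring centred on the bead radius whose amplitude
    is the bead's true halo amplitude.  All channels sit on
    ``background_level``; shot noise (if enabled) and Gaussian read noise
    are applied afterwards and the result is clipped to [0, 65535].
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    h, w = config.image_shape
    channels = {name: np.full((h, w), float(config.background_level)) for name in CHANNEL_NAMES}
    for bead in layout:
        if not (0 <= bead.center[0] < h and 0 <= bead.center[1] < w):
            raise ValueError(f"bead {bead.bead_id} center outside the image")
        _render_bead(channels["encode1"], bead, bead.enc1, "disk", config)
        _render_bead(channels["encode2"], bead, bead.enc2, "disk", config)
        if bead.halo_amplitude > 0:
            _render_bead(channels["measure"], bead, bead.halo_amplitude, "ring", config)

    out = {}
    for name in CHANNEL_NAMES:
        img = channels[name]
        if config.shot_noise:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if config.read_noise_sd > 0:
            img = img + config.read_noise_sd * rng.standard_normal(img.shape)
        out[name] = np.clip(np.rint(img), 0, U16_MAX).astype(np.uint16)

    return ChipImage(
        encode1=out["encode1"], encode2=out["encode2"], measure=out["measure"],
        pixel_size=config.pixel_size, well_id=well_id, frame_index=frame_index,
    )


def layout_to_frame(layout: Sequence[BeadGroundTruth]) -> pd.DataFrame:
    """Ground-truth table as a DataFrame (one row per bead)."""
    return _truth_dataframe(layout)


def write_chip(
    image: ChipImage, layout: Sequence[BeadGroundTruth], out_dir: str | Path,
    stem: str | None = None,
) -> tuple[Path, Path]:
    """Write a chip as a multi-page TIFF (one page per channel) plus a
    ground-truth CSV sidecar; returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{image.well_id}_f{image.frame_index:03d}"
    tiff_path = out_dir / f"{stem}.tiff"
    csv_path = out_dir / f"{stem}_truth.csv"
    stack = np.stack([image.encode1, image.encode2, image.measure])
    tifffile.imwrite(
        tiff_path, stack,
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": list(CHANNEL_NAMES),
                  "pixel_size_um": image.pixel_size, "well_id": image.well_id,
                  "frame_index": image.frame_index},
    )
    _truth_dataframe(layout).to_csv(csv_path, index=False)
    return tiff_path, csv_path


def generate_screen_dataset(
    design: pd.DataFrame,
    config: SimConfig,
    response_model: Callable[[str, float], float] | Mapping[str, object],
    out_dir: str | Path | None = None,
) -> list[tuple[ChipImage, pd.DataFrame, pd.Series]]:
    """Simulate one chip per design row with programmed halo amplitudes.

    ``design`` needs columns ``well`` and ``dose`` (the condition
    covariate, e.g. NaCl mM).  ``response_model`` maps
    (population id, dose) to the true halo amplitude; it may be a callable
    or a mapping from population id to a fitted-model-like object with a
    ``predict(dose)`` method (e.g. :class:`beadscreen.doseresponse.FittedModel`).
    Returns (image, truth table, design row) per well; with ``out_dir``
    given, each chip and truth table is also written to disk.
    """
    if callable(response_model):
        amp_fn = response_model
    else:
        known = set(response_model)
        pop_ids = {p.population_id for p in config.populations}
        unknown = known - pop_ids
        if unknown:
            raise ValueError(f"response_model references unknown populations: {sorted(unknown)}")

        def amp_fn(pop_id: str, dose: float) -> float:
            model = response_model.get(pop_id)
            return float(model.predict(dose)) if model is not None else 0.0

    results = []
    for i, (_, row) in enumerate(design.iterrows()):
        dose = float(row["dose"])
        amps = {
            p.population_id: max(float(amp_fn(p.population_id, dose)), 0.0)
            for p in config.populations
        }
        cfg = replace(config.with_amplitudes(amps), seed=config.seed + 1000 * (i + 1))
        rng = np.random.default_rng(cfg.seed)
        layout = sample_bead_layout(cfg, rng)
        image = render_chip_image(layout, cfg, rng, well_id=str(row["well"]))
        truth = _truth_dataframe(layout)
        if out_dir is not None:
            write_chip(image, layout, out_dir, stem=str(row["well"]))
        results.append((image, truth, row))
    return results


def generate_timeseries(
    config: SimConfig,
    amplitude_of_time: Callable[[str, float], float],
    times: Sequence[float],
    well_id: str = "well",
) -> list[tuple[float, ChipImage, pd.DataFrame]]:
    """Simulate a kinetic frame series over one fixed bead layout.

    The bead positions and encoding intensities are sampled once (beads do
    not move between frames); only the halo amplitudes evolve, following
    ``amplitude_of_time(population_id, t)``.  Per-frame noise is independent.
    """
    rng = np.random.default_rng(config.seed)
    base_layout = sample_bead_layout(config, rng)
    frames = []
    for k, t in enumerate(times):
        layout_t = [
            replace(b, halo_amplitude=max(float(amplitude_of_time(b.population_id, t)), 0.0))
            for b in base_layout
        ]
        image = render_chip_image(layout_t, config, rng, well_id=well_id, frame_index=k)
        frames.append((float(t), image, _truth_dataframe(layout_t)))
    return frames
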