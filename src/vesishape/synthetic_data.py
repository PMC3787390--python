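"""Seeded generators for every input the analysis pipeline consumes.

Three generators, each a pure function of its config (including the seed):

* single-structure STED/confocal frames of vesicles and tubules in random
  isotropic orientations, with per-frame ground truth — the shape-
  discrimination simulation design (110 nm vesicles; 30 nm tubules of 80,
  110, 150 and 300 nm length; 200^3 grid of 5 nm voxels; Lorentzian 80 nm
  FWHM PSF; Poisson noise; 150 frames per class);
* multi-channel spot fields with known per-spot category fractions, the
  substrate for the colocalization classifier;
* exchange / FRAP intensity timecourses with known kinetic parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, NamedTuple, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation as _ScipyRotation

from .errors import InvalidSpecError, PackingError
from .kinetics import TimeSeries
from .optics import NoiseParams, PSFSpec, image_structure
from .structures import (
    GridParams,
    Image2D,
    StructureSpec,
    project,
    render_structure,
    sample_orientation,
    tubule,
    vesicle,
)

__all__ = [
    "DEFAULT_CLASSES",
    "ShapeExperimentConfig",
    "SpotFieldConfig",
    "TimecourseConfig",
    "SpotField",
    "generate_shape_dataset",
    "generate_spot_field",
    "generate_timecourse",
]

_LN2 = np.log(2.0)

DEFAULT_CLASSES: Tuple[StructureSpec, ...] = (
    vesicle(110.0),
    tubule(30.0, 80.0),
    tubule(30.0, 110.0),
    tubule(30.0, 150.0),
    tubule(30.0, 300.0),
)


@dataclass(frozen=True)
class ShapeExperimentConfig:
    """Simulation design of the vesicle-vs-tubule discrimination study."""

    classes: Tuple[StructureSpec, ...] = DEFAULT_CLASSES
    n_per_class: int = 150
    psf: PSFSpec = PSFSpec("lorentzian", 80.0)
    grid: GridParams = GridParams(200, 5.0)
    noise: Optional[NoiseParams] = NoiseParams(50.0, 5.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise InvalidSpecError("n_per_class must be >= 1")
        if len(self.classes) == 0:
            raise InvalidSpecError("at least one structure class required")


def generate_shape_dataset(cfg: ShapeExperimentConfig) -> List[Tuple[Image2D, dict]]:
    """Render ``n_per_class`` frames per structure class.

    Each frame: draw an isotropic orientation, rasterize the labeled shell,
    project along the optical axis, convolve with the PSF and (optionally)
    apply Poisson noise with a per-frame child seed.  The ground-truth record
    carries the class label, geometry, orientation quaternion and seed.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    out: List[Tuple[Image2D, dict]] = []
    for spec in cfg.classes:
        for i in range(cfg.n_per_class):
            rot = sample_orientation(rng)
            frame_seed = int(rng.integers(0, 2**31))
            vg = render_structure(spec, cfg.grid, rot)
            img = project(vg)
            noise = (
                replace(cfg.noise, rng_seed=frame_seed) if cfg.noise is not None else None
            )
            frame = image_structure(img, cfg.psf, noise)
            record = {
                "label": spec.label,
                "shape": spec.shape,
                "diameter_nm": spec.diameter,
                "length_nm": spec.length if spec.length is not None else np.nan,
                "index": i,
                "quaternion": _ScipyRotation.from_matrix(rot).as_quat().tolist(),
                "rng_seed": frame_seed,
            }
            out.append((frame, record))
    return out


@dataclass(frozen=True)
class SpotFieldConfig:
    """Two-cargo spot field with known per-spot category ground truth.

    ``fractions`` are the (A_only, B_only, both) category probabilities; the
    printed experimental fractions round to a sum slightly off 1, so any
    vector within 0.05 of 1 is accepted and renormalized.  Spot layout
    (uniform with a minimum pairwise separation) and intensity model
    (log-normal peak counts, Gaussian sub-structure blobs) are generator
    conventions chosen to exercise the classifier with known truth, not a
    reconstruction of real fields.
    """

    field_size_px: int = 2048
    pixel_size: float = 5.0
    n_spots: int = 200
    fractions: Tuple[float, float, float] = (0.66, 0.20, 0.15)
    size_mean_nm: float = 60.0
    size_sd_nm: float = 25.0
    ref_peak_counts: float = 120.0
    cargo_peak_counts: float = 90.0
    peak_log_sd: float = 0.35
    psf: PSFSpec = PSFSpec("lorentzian", 80.0)
    signal_scale: float = 50.0
    background_rate: float = 5.0
    min_separation_nm: float = 400.0
    margin_nm: float = 400.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 0:
            raise InvalidSpecError("n_spots must be >= 0")
        f = np.asarray(self.fractions, dtype=float)
        if np.any(f < 0) or abs(f.sum() - 1.0) > 0.05:
            raise InvalidSpecError("fractions must be >= 0 and sum to ~1")
        if self.field_size_px < 8 or self.pixel_size <= 0:
            raise InvalidSpecError("invalid field geometry")

    @property
    def normalized_fractions(self) -> np.ndarray:
        f = np.asarray(self.fractions, dtype=float)
        return f / f.sum()


class SpotField(NamedTuple):
    reference: Image2D
    channel_a: Image2D
    channel_b: Image2D
    truth: pd.DataFrame


def _place_spots(rng, cfg: SpotFieldConfig) -> np.ndarray:
    extent = cfg.field_size_px * cfg.pixel_size
    lo, hi = cfg.margin_nm, extent - cfg.margin_nm
    if hi <= lo and cfg.n_spots > 0:
        raise PackingError("field too small for the requested margin")
    placed: List[np.ndarray] = []
    min_sep2 = cfg.min_separation_nm**2
    attempts = 0
    max_attempts = 400 * max(cfg.n_spots, 1)
    while len(placed) < cfg.n_spots:
        if attempts >= max_attempts:
            raise PackingError(
                f"could not place {cfg.n_spots} spots with "
                f"{cfg.min_separation_nm} nm separation"
            )
        attempts += 1
        p = rng.uniform(lo, hi, size=2)
        if all(((p - q) ** 2).sum() >= min_sep2 for q in placed):
            placed.append(p)
    return np.array(placed).reshape(cfg.n_spots, 2)


def _add_blob(label: np.ndarray, pixel_size: float, center: np.ndarray, fwhm: float, flux: float) -> None:
    """Accumulate a unit-flux-scaled Gaussian blob into a label image."""
    sigma = max(fwhm, 1e-6) / (2.0 * np.sqrt(2.0 * _LN2))
    half = max(3, int(np.ceil(4 * sigma / pixel_size)))
    ix = int(center[0] / pixel_size)
    iy = int(center[1] / pixel_size)
    x0, x1 = max(0, ix - half), min(label.shape[0], ix + half + 1)
    y0, y1 = max(0, iy - half), min(label.shape[1], iy + half + 1)
    xs = (np.arange(x0, x1) + 0.5) * pixel_size - center[0]
    ys = (np.arange(y0, y1) + 0.5) * pixel_size - center[1]
    g = np.exp(-(xs[:, None] ** 2 + ys[None, :] ** 2) / (2 * sigma**2))
    s = g.sum()
    if s > 0:
        label[x0:x1, y0:y1] += flux * g / s


def _lognormal(rng, mean: float, sd: float, size: int) -> np.ndarray:
    if mean <= 0:
        raise InvalidSpecError("log-normal mean must be > 0")
    if sd <= 0:
        return np.full(size, mean)
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return rng.lognormal(np.log(mean) - s2 / 2.0, np.sqrt(s2), size=size)


def generate_spot_field(cfg: SpotFieldConfig) -> SpotField:
    """Simulate a three-channel field of sub-diffraction spots.

    Every spot appears in the reference channel; its category (drawn from the
    configured fractions) decides which cargo channels also receive signal.
    Each channel is the blob image convolved with the PSF, scaled, offset by
    the background rate and Poisson-sampled with a child seed.
    """
    from .optics import make_psf

    rng = np.random.default_rng(cfg.rng_seed)
    positions = _place_spots(rng, cfg)
    n = cfg.n_spots
    kernel = make_psf(cfg.psf, cfg.pixel_size).values
    categories = rng.choice(
        np.array(["A_only", "B_only", "both"]), size=n, p=cfg.normalized_fractions
    )
    sizes = _lognormal(rng, cfg.size_mean_nm, cfg.size_sd_nm, n) if n else np.empty(0)
    peaks_ref = _lognormal_peaks(rng, cfg.ref_peak_counts, cfg.peak_log_sd, n)
    peaks_a = _lognormal_peaks(rng, cfg.cargo_peak_counts, cfg.peak_log_sd, n)
    peaks_b = _lognormal_peaks(rng, cfg.cargo_peak_counts, cfg.peak_log_sd, n)

    shape = (cfg.field_size_px, cfg.field_size_px)
    labels = {k: np.zeros(shape, dtype=np.float64) for k in ("ref", "A", "B")}
    rows = []
    for i in range(n):
        # exact peak of a unit-flux blob after PSF blur: <kernel, blob> at 0
        peak_per_flux = _blur_peak_per_flux(kernel, cfg.pixel_size, sizes[i])
        in_a = categories[i] in ("A_only", "both")
        in_b = categories[i] in ("B_only", "both")
        for key, present, peak in (
            ("ref", True, peaks_ref[i]),
            ("A", in_a, peaks_a[i]),
            ("B", in_b, peaks_b[i]),
        ):
            if present:
                flux = peak / (cfg.signal_scale * peak_per_flux)
                _add_blob(labels[key], cfg.pixel_size, positions[i], sizes[i], flux)
        rows.append(
            {
                "x_nm": positions[i, 0],
                "y_nm": positions[i, 1],
                "size_nm": sizes[i],
                "category": categories[i],
                "peak_ref": peaks_ref[i],
                "peak_a": peaks_a[i] if in_a else 0.0,
                "peak_b": peaks_b[i] if in_b else 0.0,
            }
        )

    noise = {
        k: NoiseParams(cfg.signal_scale, cfg.background_rate, int(rng.integers(0, 2**31)))
        for k in ("ref", "A", "B")
    }
    images = {
        k: image_structure(Image2D(labels[k], cfg.pixel_size), cfg.psf, noise[k])
        for k in ("ref", "A", "B")
    }
    truth = pd.DataFrame(
        rows,
        columns=["x_nm", "y_nm", "size_nm", "category", "peak_ref", "peak_a", "peak_b"],
    )
    return SpotField(images["ref"], images["A"], images["B"], truth)


def _blur_peak_per_flux(kernel: np.ndarray, pixel_size: float, fwhm: float) -> float:
    """Peak of a unit-flux Gaussian blob of the given FWHM after PSF blur.

    ``(kernel * blob)(0)`` equals the inner product of the (even) kernel with
    the normalized blob; both are evaluated on the kernel grid.
    """
    half = kernel.shape[0] // 2
    offs = (np.arange(kernel.shape[0]) - half) * pixel_size
    sigma = max(fwhm, 1e-6) / (2.0 * np.sqrt(2.0 * _LN2))
    g1 = np.exp(-(offs**2) / (2.0 * sigma**2))
    g = g1[:, None] * g1[None, :]
    g /= g.sum()
    return float((kernel * g).sum())


def _lognormal_peaks(rng, mean: float, log_sd: float, size: int) -> np.ndarray:
    if size == 0:
        return np.empty(0)
    if log_sd <= 0:
        return np.full(size, mean)
    return rng.lognormal(np.log(mean) - log_sd**2 / 2.0, log_sd, size=size)


@dataclass(frozen=True)
class TimecourseConfig:
    """Single-exponential acceptor-Golgi exchange curve with optional bleaches.

    The acceptor relaxes toward ``baseline * plateau_fold`` with rate
    ``rate_per_min``; the donor mirrors it so that donor + acceptor is
    constant (conservation of exchanged label).  Each bleach event
    ``(t_min, surviving_fraction)`` multiplies the acceptor intensity at that
    time.  A saturating exponential is the simplest monotone model matching
    the measured exchange curves; it is a test harness, not a kinetic claim.
    """

    plateau_fold: float = 10.2
    rate_per_min: float = 0.15
    baseline: float = 10.0
    noise_sd: float = 0.0
    frame_interval_min: float = 0.5
    duration_min: float = 30.0
    bleach_events: Tuple[Tuple[float, float], ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_fold < 0 or self.duration_min <= 0:
            raise InvalidSpecError("plateau_fold >= 0 and duration > 0 required")
        if self.frame_interval_min <= 0 or self.baseline <= 0:
            raise InvalidSpecError("frame interval and baseline must be > 0")
        for t, frac in self.bleach_events:
            if not 0.0 <= frac <= 1.0:
                raise InvalidSpecError("surviving fraction must be in [0, 1]")


def generate_timecourse(cfg: TimecourseConfig) -> Tuple[TimeSeries, TimeSeries]:
    """Return (donor, acceptor) ROI timecourses.

    Between frames the acceptor approaches the plateau exponentially from its
    current value, so recovery resumes after a bleach; Gaussian measurement
    noise (clipped at 0) is added independently per frame.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    times = np.arange(0.0, cfg.duration_min + 1e-9, cfg.frame_interval_min)
    plateau = cfg.baseline * cfg.plateau_fold
    total = cfg.baseline + plateau  # donor starts with everything still to transfer
    events = sorted(cfg.bleach_events)

    acceptor = np.empty_like(times)
    level = cfg.baseline
    decay = np.exp(-cfg.rate_per_min * cfg.frame_interval_min)
    next_event = 0
    for i, t in enumerate(times):
        while next_event < len(events) and events[next_event][0] <= t + 1e-9:
            level *= events[next_event][1]
            next_event += 1
        acceptor[i] = level
        level = plateau + (level - plateau) * decay
    donor = total - np.minimum(acceptor, total)

    if cfg.noise_sd > 0:
        acceptor = np.clip(acceptor + rng.normal(0, cfg.noise_sd, times.size), 0, None)
        donor = np.clip(donor + rng.normal(0, cfg.noise_sd, times.size), 0, None)
    return (
        TimeSeries(times, donor, "donor"),
        TimeSeries(times, acceptor, "acceptor"),
    )
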