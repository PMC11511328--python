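"""Synthetic dynamic-speckle dataset generation.

Frames are drawn as fully developed polarized speckle: a complex circular
Gaussian white field is low-pass filtered to set the grain size, the intensity
is the squared modulus of the field, and successive frames of a video evolve
by partial field replacement so that intensity decorrelates geometrically.
Per-drug mean brightness is driven by lipid concentration and refractive-index
contrast; per-sample acquisition sessions carry a multiplicative gain jitter.
"""

from __future__ import annotations

import csv
import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "OpticalConfig", "DrugSpec", "SimConfig", "FrameRecord", "Dataset",
    "default_catalog", "coherence_length_mm", "brightness_factor",
    "simulate_frame", "simulate_video", "build_dataset", "write_dataset",
]

N_LIPID_RANGE = (1.450, 1.485)
N_MATRIX_RANGE = (1.349, 1.361)


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition constants of the imaging instrument.

    ``incidence_angle_deg`` is recorded for provenance but does not enter the
    scalar brightness model.
    """

    wavelength_nm: float = 658.0
    linewidth_nm: float = 0.2
    incidence_angle_deg: float = 30.0
    bit_depth: int = 8
    frame_height_px: int = 1088
    frame_width_px: int = 1456

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError(f"wavelength_nm must be > 0, got {self.wavelength_nm}")
        if self.linewidth_nm <= 0:
            raise ValueError(f"linewidth_nm must be > 0, got {self.linewidth_nm}")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit acquisition is supported")
        if self.frame_height_px < 1 or self.frame_width_px < 1:
            raise ValueError("frame dimensions must be >= 1")

    @property
    def n_gray_levels(self) -> int:
        return 2 ** self.bit_depth


@dataclass(frozen=True)
class DrugSpec:
    """Composition and optical constants of one suspension drug."""

    name: str
    lipids_g_per_L: float
    amino_acids_g_per_L: float
    glucose_g_per_L: float
    calories_kcal_per_L: float
    n_lipid: float
    n_matrix: float

    def __post_init__(self) -> None:
        lo, hi = N_LIPID_RANGE
        if not (lo <= self.n_lipid <= hi):
            raise ValueError(f"n_lipid {self.n_lipid} outside [{lo}, {hi}]")
        lo, hi = N_MATRIX_RANGE
        if not (lo <= self.n_matrix <= hi):
            raise ValueError(f"n_matrix {self.n_matrix} outside [{lo}, {hi}]")
        if self.n_lipid <= self.n_matrix:
            raise ValueError("n_lipid must exceed n_matrix")
        for attr in ("lipids_g_per_L", "amino_acids_g_per_L", "glucose_g_per_L",
                     "calories_kcal_per_L"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")

    @property
    def delta_n(self) -> float:
        """Refractive-index contrast between micelles and liquid matrix."""
        return abs(self.n_lipid - self.n_matrix)


@dataclass(frozen=True)
class SimConfig:
    """Simulator knobs.

    grain_size_px
        Speckle correlation length in pixels (Gaussian field filter scale).
    temporal_mixing
        Fraction of the complex field replaced by fresh noise between
        successive frames; successive intensity frames correlate as
        ``1 - temporal_mixing``.
    session_gain_sd
        Standard deviation of the per-session multiplicative log-normal gain.
    mean_intensity_scale
        Mean 8-bit gray level of a drug with unit brightness factor.
    """

    grain_size_px: float = 3.0
    temporal_mixing: float = 0.3
    session_gain_sd: float = 0.03
    mean_intensity_scale: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grain_size_px < 1:
            raise ValueError("grain_size_px must be >= 1")
        if not (0.0 <= self.temporal_mixing <= 1.0):
            raise ValueError("temporal_mixing must be in [0, 1]")
        if self.session_gain_sd < 0:
            raise ValueError("session_gain_sd must be >= 0")
        if not (0.0 < self.mean_intensity_scale <= 255.0):
            raise ValueError("mean_intensity_scale must be in (0, 255]")


@dataclass(frozen=True)
class FrameRecord:
    """One labeled 8-bit frame with its acquisition coordinates."""

    image: np.ndarray
    drug_name: str
    sample_id: int
    video_id: int
    frame_index: int
    day: int


@dataclass
class Dataset:
    """Labeled frame collection with a fixed acquisition layout."""

    frames: list[FrameRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[FrameRecord]:
        return iter(self.frames)

    @property
    def drug_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for fr in self.frames:
            seen.setdefault(fr.drug_name, None)
        return list(seen)

    def frames_for_drug(self, drug_name: str) -> list[FrameRecord]:
        return [fr for fr in self.frames if fr.drug_name == drug_name]


def default_catalog() -> list[DrugSpec]:
    """The six-product commercial catalog used throughout.

    Lipid/amino-acid/glucose/calorie columns follow the published composition
    table.  The matrix index is not tabulated; it is assigned by rank-scaling
    the dissolved solids (glucose + amino acids) across the published matrix
    index range, since the matrix index is governed mainly by water and
    dissolved glucose.  The micelle index is fixed at the midpoint of its
    literature range.
    """
    rows = [
        # name, lipids, amino acids, glucose, kcal/L
        ("OLIMEL N5E", 40.00, 32.93, 115.00, 990),
        ("OLIMEL N7E", 40.00, 44.27, 140.00, 1140),
        ("OLIMEL N12E", 35.07, 76.00, 73.38, 954),
        ("OLIMEL N4E", 30.00, 25.30, 75.00, 700),
        ("FINOMEL", 28.20, 31.51, 70.69, 1091),
        ("NUMETA G13E", 25.00, 29.47, 133.33, 910),
    ]
    n_lipid = 0.5 * (N_LIPID_RANGE[0] + N_LIPID_RANGE[1])
    solids = np.array([aa + glu for _, _, aa, glu, _ in rows])
    ranks = np.argsort(np.argsort(solids)).astype(float)
    span = N_MATRIX_RANGE[1] - N_MATRIX_RANGE[0]
    n_matrix = N_MATRIX_RANGE[0] + span * ranks / (len(rows) - 1)
    return [
        DrugSpec(name, lip, aa, glu, kcal, n_lipid=n_lipid, n_matrix=nm)
        for (name, lip, aa, glu, kcal), nm in zip(rows, n_matrix)
    ]


def coherence_length_mm(cfg: OpticalConfig) -> float:
    """Coherence length of the source in millimetres, lambda^2 / d_lambda."""
    lam_m = cfg.wavelength_nm * 1e-9
    dlam_m = cfg.linewidth_nm * 1e-9
    return lam_m ** 2 / dlam_m * 1e3


def brightness_factor(drug: DrugSpec, catalog: Sequence[DrugSpec]) -> float:
    """Relative scattered-light brightness of ``drug`` within ``catalog``.

    Scattered power from a dilute suspension of small particles grows with
    scatterer concentration and with the square of the index contrast, so the
    unnormalized brightness is ``lipids * delta_n**2``; the returned value is
    normalized by the catalog maximum, giving B in [0, 1].
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    products = [d.lipids_g_per_L * d.delta_n ** 2 for d in catalog]
    top = max(products)
    if top <= 0:
        raise ValueError("catalog contains no scattering product (all zero)")
    return (drug.lipids_g_per_L * drug.delta_n ** 2) / top


def _filtered_complex_field(shape: tuple[int, int], sigma: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Unit-mean-intensity correlated circular Gaussian field."""
    re = rng.standard_normal(shape)
    im = rng.standard_normal(shape)
    a = gaussian_filter(re, sigma, mode="wrap") + 1j * gaussian_filter(im, sigma, mode="wrap")
    # Gaussian kernel shrinks the variance by sum(g^2); renormalize so
    # E[|A|^2] = 2 regardless of the grain size.
    a /= _kernel_rms(sigma)
    return a


_KERNEL_RMS_CACHE: dict[float, float] = {}


def _kernel_rms(sigma: float) -> float:
    rms = _KERNEL_RMS_CACHE.get(sigma)
    if rms is None:
        n = max(int(8 * sigma) | 1, 9)
        impulse = np.zeros((n, n))
        impulse[n // 2, n // 2] = 1.0
        g = gaussian_filter(impulse, sigma, mode="constant")
        rms = float(np.sqrt((g ** 2).sum()))
        _KERNEL_RMS_CACHE[sigma] = rms
    return rms


def _field_to_intensity(field: np.ndarray) -> np.ndarray:
    """Squared modulus normalized to unit mean for a unit-variance field."""
    return (field.real ** 2 + field.imag ** 2) / 2.0


def _quantize(intensity: np.ndarray, mean_gray: float) -> np.ndarray:
    img = intensity * mean_gray
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def simulate_frame(B: float, sim: SimConfig, cfg: OpticalConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """One 8-bit speckle frame with mean gray level B * mean_intensity_scale."""
    if not (0.0 <= B <= 1.0):
        raise ValueError(f"brightness factor must be in [0, 1], got {B}")
    shape = (cfg.frame_height_px, cfg.frame_width_px)
    if B == 0.0:
        return np.zeros(shape, dtype=np.uint8)
    field = _filtered_complex_field(shape, sim.grain_size_px / 2.0, rng)
    return _quantize(_field_to_intensity(field), B * sim.mean_intensity_scale)


def simulate_intensity(B: float, sim: SimConfig, cfg: OpticalConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Pre-quantization intensity of a single frame (mean B, continuous)."""
    if not (0.0 <= B <= 1.0):
        raise ValueError(f"brightness factor must be in [0, 1], got {B}")
    shape = (cfg.frame_height_px, cfg.frame_width_px)
    field = _filtered_complex_field(shape, sim.grain_size_px / 2.0, rng)
    return B * _field_to_intensity(field)


def simulate_video(B: float, n_frames: int, sim: SimConfig, cfg: OpticalConfig,
                   rng: np.random.Generator, gain: float = 1.0,
                   quantize: bool = True) -> list[np.ndarray]:
    """A stack of frames whose field evolves by partial replacement.

    A_{t+1} = sqrt(1 - eps) A_t + sqrt(eps) N_t with fresh filtered noise N_t,
    so successive intensity frames have Pearson correlation ~ (1 - eps).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not (0.0 <= B <= 1.0):
        raise ValueError(f"brightness factor must be in [0, 1], got {B}")
    shape = (cfg.frame_height_px, cfg.frame_width_px)
    sigma = sim.grain_size_px / 2.0
    eps = sim.temporal_mixing
    mean_gray = gain * B * sim.mean_intensity_scale

    frames: list[np.ndarray] = []
    if B == 0.0:
        zero = np.zeros(shape, dtype=np.uint8 if quantize else float)
        return [zero.copy() for _ in range(n_frames)]
    field = _filtered_complex_field(shape, sigma, rng)
    for _ in range(n_frames):
        intensity = _field_to_intensity(field)
        frames.append(_quantize(intensity, mean_gray) if quantize
                      else intensity * mean_gray)
        if eps > 0:
            fresh = _filtered_complex_field(shape, sigma, rng)
            field = np.sqrt(1.0 - eps) * field + np.sqrt(eps) * fresh
    return frames


def build_dataset(catalog: Sequence[DrugSpec], samples_per_drug: int = 4,
                  videos_per_sample: int = 3, frames_per_video: int = 100,
                  sim: SimConfig | None = None, cfg: OpticalConfig | None = None,
                  rng: np.random.Generator | None = None) -> Dataset:
    """Full labeled acquisition layout.

    Samples alternate between day 0 (first half) and day 2 (second half).
    Each (drug, sample) session draws one multiplicative log-normal gain
    applied to all of its frames.  Per-video random streams are spawned from
    a single seed sequence so any video is reproducible in isolation.
    """
    if min(samples_per_drug, videos_per_sample, frames_per_video) < 1:
        raise ValueError("layout counts must be >= 1")
    sim = sim or SimConfig()
    cfg = cfg or OpticalConfig()
    if rng is None:
        rng = np.random.default_rng(sim.seed)
    root_ss = np.random.SeedSequence(rng.integers(0, 2 ** 63 - 1))

    dataset = Dataset()
    for di, drug in enumerate(catalog):
        B = brightness_factor(drug, catalog)
        for si in range(samples_per_drug):
            day = 0 if si < (samples_per_drug + 1) // 2 else 2
            session_ss = np.random.SeedSequence(
                entropy=root_ss.entropy, spawn_key=(di, si))
            session_rng = np.random.default_rng(session_ss)
            gain = float(np.exp(session_rng.normal(0.0, sim.session_gain_sd))) \
                if sim.session_gain_sd > 0 else 1.0
            for vi in range(videos_per_sample):
                video_rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=root_ss.entropy, spawn_key=(di, si, vi)))
                frames = simulate_video(B, frames_per_video, sim, cfg,
                                        video_rng, gain=gain)
                for fi, img in enumerate(frames):
                    dataset.frames.append(FrameRecord(
                        image=img, drug_name=drug.name, sample_id=si,
                        video_id=vi, frame_index=fi, day=day))
    return dataset


def write_dataset(dataset: Dataset, root: str) -> str:
    """Write frames as 8-bit PNGs plus a CSV manifest; returns manifest path."""
    import imageio.v3 as iio

    manifest_path = os.path.join(root, "manifest.csv")
    os.makedirs(root, exist_ok=True)
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "drug", "sample", "video", "frame", "day"])
        for fr in dataset.frames:
            rel = os.path.join(fr.drug_name.replace(" ", "_"),
                               f"sample_{fr.sample_id}", f"video_{fr.video_id}",
                               f"frame_{fr.frame_index:04d}.png")
            path = os.path.join(root, rel)
            os.makedirs(os.path.dirname(path), exist_ok=True)
            iio.imwrite(path, fr.image)
            writer.writerow([rel, fr.drug_name, fr.sample_id, fr.video_id,
                             fr.frame_index, fr.day])
    return manifest_path


def load_dataset(root: str, manifest: str | None = None) -> Dataset:
    """Load a PNG dataset written by :func:`write_dataset`."""
    import imageio.v3 as iio

    manifest = manifest or os.path.join(root, "manifest.csv")
    dataset = Dataset()
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            img = np.asarray(iio.imread(os.path.join(root, row["path"])))
            dataset.frames.append(FrameRecord(
                image=img, drug_name=row["drug"], sample_id=int(row["sample"]),
                video_id=int(row["video"]), frame_index=int(row["frame"]),
                day=int(row["day"])))
    return dataset
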