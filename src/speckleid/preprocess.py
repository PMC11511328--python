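"""Cropping, train/test splitting, and per-drug intensity normalization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from speckleid.simulate import Dataset, FrameRecord

__all__ = [
    "SplitDataset", "NormalizationModel", "center_crop",
    "crop_representativeness_test", "split_train_test",
    "fit_normalizer", "apply_normalizer", "crop_dataset",
]


@dataclass
class SplitDataset:
    train: Dataset
    test: Dataset
    split_fraction: float
    seed: int


@dataclass
class NormalizationModel:
    """Per-drug gray-level mean/std, estimated on training frames only."""

    means: dict[str, float]
    stds: dict[str, float]

    def __post_init__(self) -> None:
        for drug, std in self.stds.items():
            if std <= 0:
                raise ValueError(f"non-positive std for drug {drug!r}")


def center_crop(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Centered ``size`` x ``size`` window of ``image``."""
    h, w = image.shape[:2]
    if h < size or w < size:
        raise ValueError(f"image {h}x{w} smaller than crop size {size}")
    top = (h - size) // 2
    left = (w - size) // 2
    return image[top:top + size, left:left + size]


def crop_dataset(dataset: Dataset, size: int = 224) -> Dataset:
    """Center-crop every frame of a dataset."""
    return Dataset(frames=[
        FrameRecord(image=center_crop(fr.image, size), drug_name=fr.drug_name,
                    sample_id=fr.sample_id, video_id=fr.video_id,
                    frame_index=fr.frame_index, day=fr.day)
        for fr in dataset.frames])


def crop_representativeness_test(full_image: np.ndarray,
                                 cropped_image: np.ndarray,
                                 alpha: float = 0.01,
                                 subsample_step: int = 1
                                 ) -> tuple[float, float, bool]:
    """Two-sample KS test that the crop's gray levels match the full frame.

    Returns (statistic, p-value, reject) with reject True iff p < alpha.
    The KS test assumes independent samples; speckle pixels are spatially
    correlated over the grain size, so pass ``subsample_step`` of about the
    grain size to decimate both images onto an approximately independent
    pixel lattice (step 1 over-rejects on correlated textures).
    """
    if full_image.size == 0 or cropped_image.size == 0:
        raise ValueError("images must be non-empty")
    if subsample_step < 1:
        raise ValueError("subsample_step must be >= 1")
    s = subsample_step
    a = np.asarray(full_image)[::s, ::s].ravel()
    b = np.asarray(cropped_image)[::s, ::s].ravel()
    if a.shape == b.shape and np.array_equal(a, b):
        return 0.0, 1.0, False
    res = ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha)


def _train_sizes(counts: dict[str, int], fraction: float) -> dict[str, int]:
    """Per-stratum training counts.

    The global training size is the banker's rounding of fraction * total;
    per-stratum counts start from floors and the residual is assigned to the
    largest strata first, keeping every stratum within 1 of exact
    proportionality.
    """
    total = sum(counts.values())
    target = round(fraction * total)  # Python round = round-half-even
    base = {k: int(np.floor(fraction * n)) for k, n in counts.items()}
    residual = target - sum(base.values())
    order = sorted(counts, key=lambda k: (-counts[k], k))
    i = 0
    while residual > 0:
        k = order[i % len(order)]
        if base[k] < counts[k]:
            base[k] += 1
            residual -= 1
        i += 1
    return base


def split_train_test(dataset: Dataset, fraction: float = 0.8,
                     seed: int = 0, unit: str = "frame") -> SplitDataset:
    """Stratified random partition of the dataset by drug.

    ``unit="frame"`` shuffles individual frames within each drug (the default,
    matching the published procedure); ``unit="video"`` keeps whole
    (sample, video) groups together to avoid intra-video leakage.
    """
    if not dataset.frames:
        raise ValueError("dataset is empty")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if unit not in ("frame", "video"):
        raise ValueError(f"unknown split unit {unit!r}")
    rng = np.random.default_rng(seed)

    by_drug: dict[str, list[int]] = {}
    for i, fr in enumerate(dataset.frames):
        by_drug.setdefault(fr.drug_name, []).append(i)

    train_idx: list[int] = []
    test_idx: list[int] = []
    sizes = _train_sizes({k: len(v) for k, v in by_drug.items()}, fraction)
    for drug, idx in by_drug.items():
        idx = np.asarray(idx)
        if unit == "frame":
            perm = rng.permutation(len(idx))
            take = sizes[drug]
            train_idx.extend(idx[perm[:take]])
            test_idx.extend(idx[perm[take:]])
        else:
            groups = {}
            for i in idx:
                fr = dataset.frames[i]
                groups.setdefault((fr.sample_id, fr.video_id), []).append(i)
            keys = list(groups)
            rng.shuffle(keys)
            taken = 0
            target = sizes[drug]
            for key in keys:
                members = groups[key]
                if taken < target:
                    train_idx.extend(members)
                    taken += len(members)
                else:
                    test_idx.extend(members)

    train = Dataset(frames=[dataset.frames[i] for i in sorted(train_idx)])
    test = Dataset(frames=[dataset.frames[i] for i in sorted(test_idx)])
    return SplitDataset(train=train, test=test, split_fraction=fraction,
                        seed=seed)


def fit_normalizer(train: Dataset) -> NormalizationModel:
    """Per-drug pixel mean and std from training frames only."""
    if not train.frames:
        raise ValueError("training dataset is empty")
    sums: dict[str, float] = {}
    sqsums: dict[str, float] = {}
    npix: dict[str, int] = {}
    for fr in train.frames:
        img = fr.image.astype(np.float64)
        sums[fr.drug_name] = sums.get(fr.drug_name, 0.0) + img.sum()
        sqsums[fr.drug_name] = sqsums.get(fr.drug_name, 0.0) + (img ** 2).sum()
        npix[fr.drug_name] = npix.get(fr.drug_name, 0) + img.size
    means = {k: sums[k] / npix[k] for k in sums}
    stds = {}
    for k in sums:
        var = sqsums[k] / npix[k] - means[k] ** 2
        stds[k] = float(np.sqrt(max(var, 0.0)))
        if stds[k] <= 0:
            raise ValueError(f"zero gray-level variance for drug {k!r}")
    return NormalizationModel(means=means, stds=stds)


def apply_normalizer(model: NormalizationModel, image: np.ndarray,
                     drug: str) -> np.ndarray:
    """Standardize by the drug's training statistics, then rescale to 8 bits.

    The pixel values are mapped to (x - mean_drug) / std_drug and the result
    is min-max rescaled to [0, 255] per image; a constant image maps to all
    zeros.  Returns uint8.
    """
    if drug not in model.means:
        raise KeyError(f"drug {drug!r} not seen during normalizer fitting")
    z = (image.astype(np.float64) - model.means[drug]) / model.stds[drug]
    lo, hi = z.min(), z.max()
    if hi == lo:
        return np.zeros_like(image, dtype=np.uint8)
    out = (z - lo) / (hi - lo) * 255.0
    return np.rint(out).astype(np.uint8)
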