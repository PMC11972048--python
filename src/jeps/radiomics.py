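"""Compact radiomics feature suite and the train-time variance filter.

Features are computed over the masked region of the *raw-HU* CT on the
aligned, resampled lattice (before any intensity normalization): first-
order intensity statistics, shape descriptors from the binary mask, and
gray-level co-occurrence texture at one-voxel offsets with 32-bin
intensity quantization.  The suite is deliberately compact; any callable
producing a :class:`FeatureVector` can be substituted through the
``feature_fn`` arguments of the higher-level APIs.

The variance filter min-max scales each feature to [0, 1] using training
rows only and drops features whose scaled training variance (population
convention) falls strictly below 0.05 — fitting it on anything but the
training rows of a fold would leak test information into preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import measure

N_GLCM_BINS = 32
VARIANCE_THRESHOLD = 0.05

# 13 unique direction offsets covering all 26-connected neighbor pairs
_OFFSETS = [(0, 0, 1), (0, 1, 0), (1, 0, 0), (0, 1, 1), (0, 1, -1),
            (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
            (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1)]


@dataclass
class FeatureVector:
    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("feature names and values disagree in length")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite feature values")

    def as_dict(self):
        return dict(zip(self.names, self.values))


def _first_order(vals: np.ndarray) -> dict[str, float]:
    hist, _ = np.histogram(vals, bins=N_GLCM_BINS)
    p = hist / hist.sum()
    nz = p[p > 0]
    return {
        "fo_mean": float(vals.mean()),
        "fo_std": float(vals.std()),
        "fo_min": float(vals.min()),
        "fo_max": float(vals.max()),
        "fo_median": float(np.median(vals)),
        "fo_iqr": float(np.percentile(vals, 75) - np.percentile(vals, 25)),
        "fo_range": float(vals.max() - vals.min()),
        "fo_skewness": float(stats.skew(vals)) if vals.std() > 0 else 0.0,
        "fo_kurtosis": float(stats.kurtosis(vals)) if vals.std() > 0 else 0.0,
        "fo_energy": float(np.mean(vals.astype(float) ** 2)),
        "fo_entropy": float(-(nz * np.log2(nz)).sum()),
    }


def _shape(mask: np.ndarray, spacing: tuple[float, float, float]) -> dict[str, float]:
    voxel_vol = float(np.prod(spacing))
    n = int(mask.sum())
    volume = n * voxel_vol
    # surface area from the marching-cubes mesh of the (padded) mask
    padded = np.pad(mask.astype(float), 1)
    try:
        verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
        surface = float(measure.mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        surface = 6.0 * voxel_vol ** (2 / 3) * n       # cube fallback for degenerate masks
    eq_diam = (6.0 * volume / np.pi) ** (1 / 3)
    idx = np.argwhere(mask)
    extents = (idx.max(axis=0) - idx.min(axis=0) + 1) * np.asarray(spacing)
    coords = idx * np.asarray(spacing)
    if n > 3:
        cov = np.cov(coords.T)
        ev = np.sort(np.maximum(np.linalg.eigvalsh(cov), 0.0))
        major, minor, least = 4 * np.sqrt(ev[2]), 4 * np.sqrt(ev[1]), 4 * np.sqrt(ev[0])
    else:
        major = minor = least = float(extents.max())
    sphericity = (np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3)) / surface if surface > 0 else 0.0
    return {
        "sh_volume": volume,
        "sh_voxel_count": float(n),
        "sh_surface_area": surface,
        "sh_surface_to_volume": surface / volume if volume > 0 else 0.0,
        "sh_equivalent_diameter": float(eq_diam),
        "sh_extent_axial": float(extents[0]),
        "sh_extent_height": float(extents[1]),
        "sh_extent_width": float(extents[2]),
        "sh_major_axis": float(major),
        "sh_minor_axis": float(minor),
        "sh_elongation": float(np.sqrt(minor / major)) if major > 0 else 0.0,
        "sh_flatness": float(np.sqrt(least / major)) if major > 0 else 0.0,
        "sh_sphericity": float(sphericity),
    }


def _glcm(ct: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """Co-occurrence texture at 1-voxel offsets, 32 bins over the masked range."""
    vals = ct[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        q = np.zeros_like(ct, dtype=np.int32)
    else:
        q = np.clip(((ct - lo) / (hi - lo) * N_GLCM_BINS).astype(np.int32),
                    0, N_GLCM_BINS - 1)
    glcm = np.zeros((N_GLCM_BINS, N_GLCM_BINS), dtype=np.float64)
    for dz, dy, dx in _OFFSETS:
        a = (slice(max(dz, 0), ct.shape[0] + min(dz, 0)),
             slice(max(dy, 0), ct.shape[1] + min(dy, 0)),
             slice(max(dx, 0), ct.shape[2] + min(dx, 0)))
        b = (slice(max(-dz, 0), ct.shape[0] + min(-dz, 0)),
             slice(max(-dy, 0), ct.shape[1] + min(-dy, 0)),
             slice(max(-dx, 0), ct.shape[2] + min(-dx, 0)))
        pair = mask[a] & mask[b]
        if not pair.any():
            continue
        np.add.at(glcm, (q[a][pair], q[b][pair]), 1.0)
    glcm += glcm.T          # symmetric
    total = glcm.sum()
    if total == 0:
        return {f"tx_{k}": 0.0 for k in
                ("contrast", "correlation", "energy", "homogeneity",
                 "entropy", "dissimilarity")}
    p = glcm / total
    i, j = np.mgrid[0:N_GLCM_BINS, 0:N_GLCM_BINS]
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    sd_i = np.sqrt((((i - mu_i) ** 2) * p).sum())
    sd_j = np.sqrt((((j - mu_j) ** 2) * p).sum())
    corr = ((((i - mu_i) * (j - mu_j)) * p).sum() / (sd_i * sd_j)
            if sd_i > 0 and sd_j > 0 else 1.0)
    nz = p[p > 0]
    return {
        "tx_contrast": float((((i - j) ** 2) * p).sum()),
        "tx_correlation": float(corr),
        "tx_energy": float((p ** 2).sum()),
        "tx_homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "tx_entropy": float(-(nz * np.log2(nz)).sum()),
        "tx_dissimilarity": float((np.abs(i - j) * p).sum()),
    }


def extract_radiomics(ct_hu: np.ndarray, mask: np.ndarray,
                      spacing: tuple[float, float, float]) -> FeatureVector:
    """Feature suite over mask voxels of the raw-HU CT."""
    ct_hu = np.asarray(ct_hu, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if ct_hu.shape != mask.shape:
        raise ValueError(f"CT {ct_hu.shape} and mask {mask.shape} shapes differ")
    if not mask.any():
        raise ValueError("empty mask: no voxels to extract features from")
    feats: dict[str, float] = {}
    feats.update(_first_order(ct_hu[mask]))
    feats.update(_shape(mask, spacing))
    feats.update(_glcm(ct_hu, mask))
    names = tuple(feats)
    return FeatureVector(names, np.array([feats[n] for n in names]))


@dataclass
class VarianceFilter:
    """Train-fitted min-max scaling plus low-variance rejection."""

    names: tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray
    keep: np.ndarray          # boolean per feature

    @property
    def kept_names(self):
        return tuple(n for n, k in zip(self.names, self.keep) if k)

    def transform(self, fv: FeatureVector) -> np.ndarray:
        if fv.names != self.names:
            raise ValueError("feature names do not match the fitted filter")
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        scaled = (fv.values - self.lo) / span
        return scaled[self.keep]

    def to_json(self) -> str:
        return json.dumps({"names": list(self.names), "lo": self.lo.tolist(),
                           "hi": self.hi.tolist(), "keep": self.keep.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "VarianceFilter":
        d = json.loads(text)
        return cls(tuple(d["names"]), np.asarray(d["lo"]), np.asarray(d["hi"]),
                   np.asarray(d["keep"], dtype=bool))


def fit_variance_filter(train_features: list[FeatureVector],
                        threshold: float = VARIANCE_THRESHOLD) -> VarianceFilter:
    """Fit scaling and the strict `< threshold` variance rejection on
    training rows only (population variance after min-max scaling)."""
    if len(train_features) < 2:
        raise ValueError("need at least 2 training rows")
    names = train_features[0].names
    mat = np.stack([fv.values for fv in train_features])
    lo, hi = mat.min(axis=0), mat.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (mat - lo) / span
    var = scaled.var(axis=0)                 # population (divide-by-n)
    keep = var >= threshold
    return VarianceFilter(names, lo, hi, keep)


def build_early_fusion_vector(features: FeatureVector, clinical_row: np.ndarray,
                              vfilter: VarianceFilter) -> np.ndarray:
    """Clinical encoding followed by the filtered, scaled radiomics."""
    return np.concatenate([np.asarray(clinical_row, dtype=float),
                           vfilter.transform(features)])
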