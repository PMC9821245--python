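"""Texture-feature engine for masked intensity stacks.

Computes radiomics-style texture features inside a binary region of
interest (ROI) of a small 3D image stack (a handful of midsagittal MRI
slices of an intervertebral disc).  The engine covers

* first-order statistics (maximum, range), intensity-histogram features
  (10th percentile, mode) and the intensity-volume-histogram feature
  ``int_at_vol_fraction_90``;
* Geary's C spatial autocorrelation over physical (mm) voxel distances;
* gray-level co-occurrence matrix (GLCM) features -- difference average,
  difference variance, contrast, dissimilarity -- under the standard
  2D/3D aggregation conventions (per-slice-per-direction averaged,
  direction-merged, slice-merged, volume-merged, 3D averaged, 3D merged);
* neighbourhood gray tone difference matrix (NGTDM) complexity;
* neighbourhood gray-level dependence matrix (NGLDM) dependence count
  energy.

All matrix features operate on intensities discretized to a fixed number
of gray levels inside the mask, so they are invariant to global intensity
shifts and scales.  Pairs and neighbourhoods are only counted when both
voxels lie inside the mask.

A :class:`FeatureRegistry` fixes an ordered feature set; the 22-feature
fissure-sensitive registry (:func:`table2_registry`) is the input layer of
the attention-mapping classifier, and :func:`full_registry` expands every
implemented family x aggregation combination for the main classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "IntensityROI",
    "DiscretizationConfig",
    "DiscretizedROI",
    "CooccurrenceMatrix",
    "FeatureUndefinedError",
    "discretize",
    "glcm",
    "glcm_features",
    "aggregate",
    "ngtdm_complexity",
    "ngldm_dependence_count_energy",
    "gearys_c",
    "GearyCache",
    "first_order_features",
    "FeatureDef",
    "FeatureRegistry",
    "table2_registry",
    "full_registry",
    "extract_features",
    "ExtractionContext",
]


class FeatureUndefinedError(ValueError):
    """A feature has no defined value on this ROI (e.g. all matrices empty)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntensityROI:
    """A real-valued image stack with a binary mask and physical spacing.

    ``image`` and ``mask`` are ``(slices, rows, cols)`` arrays;
    ``voxel_spacing`` is the (slice, row, col) spacing in mm.
    """

    image: np.ndarray
    mask: np.ndarray
    voxel_spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        image = np.asarray(self.image, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if image.ndim != 3 or mask.ndim != 3:
            raise ValueError("image and mask must be 3D (slices, rows, cols)")
        if image.shape != mask.shape:
            raise ValueError(
                f"image shape {image.shape} != mask shape {mask.shape}")
        if not mask.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "image", image)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "voxel_spacing",
                           tuple(float(s) for s in self.voxel_spacing))

    @property
    def masked_values(self) -> np.ndarray:
        return self.image[self.mask]


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed-bin-number intensity discretization settings."""

    method: str = "fixed-bin-number"
    n_bins: int = 32

    def __post_init__(self):
        if self.method != "fixed-bin-number":
            raise ValueError(f"unsupported discretization method {self.method!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class DiscretizedROI:
    """Integer gray levels in ``1..n_bins`` inside the mask (0 outside)."""

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int

    @property
    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


def discretize(roi: IntensityROI, cfg: DiscretizationConfig) -> DiscretizedROI:
    """Discretize masked intensities to ``cfg.n_bins`` fixed bins.

    level = floor(n_bins * (x - min) / (max - min)) + 1, clipped to
    ``n_bins`` (so the maximum falls in the top bin).  A constant ROI maps
    to level 1 everywhere.
    """
    x = roi.masked_values
    lo, hi = x.min(), x.max()
    levels = np.zeros(roi.image.shape, dtype=np.int32)
    if hi > lo:
        lv = np.floor(cfg.n_bins * (x - lo) / (hi - lo)).astype(np.int32) + 1
        np.clip(lv, 1, cfg.n_bins, out=lv)
    else:
        lv = np.ones(x.shape, dtype=np.int32)
    levels[roi.mask] = lv
    return DiscretizedROI(levels=levels, mask=roi.mask, n_bins=cfg.n_bins)


# ---------------------------------------------------------------------------
# co-occurrence matrices
# ---------------------------------------------------------------------------

#: the 4 unique in-plane (row, col) direction offsets at Chebyshev distance 1
DIRECTIONS_2D: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

#: the 13 unique 3D (slice, row, col) direction offsets at Chebyshev distance 1
DIRECTIONS_3D: Tuple[Tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13

GLCM_AGGREGATION_MODES = ("2Davg", "2Dmrg", "2DDmrg", "2Dvmrg", "3Davg", "3Dmrg")


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """A normalized, symmetric gray-level co-occurrence matrix.

    ``empty`` flags directions/slices with no valid voxel pair; empty
    matrices are excluded from aggregation averages.
    """

    p: np.ndarray
    empty: bool

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "CooccurrenceMatrix":
        total = counts.sum()
        if total == 0:
            return cls(p=np.zeros_like(counts, dtype=float), empty=True)
        return cls(p=counts / total, empty=False)


def _shifted_slices(offset: Sequence[int], shape: Sequence[int]):
    a = tuple(slice(max(0, -o), n - max(0, o)) for o, n in zip(offset, shape))
    b = tuple(slice(max(0, o), n - max(0, -o)) for o, n in zip(offset, shape))
    return a, b


def _glcm_counts(levels: np.ndarray, mask: np.ndarray, offset: Sequence[int],
                 n_bins: int) -> np.ndarray:
    """Symmetric pair counts for one direction (both orderings counted)."""
    a_sl, b_sl = _shifted_slices(offset, levels.shape)
    valid = mask[a_sl] & mask[b_sl]
    ia = levels[a_sl][valid].astype(np.int64) - 1
    ib = levels[b_sl][valid].astype(np.int64) - 1
    counts = np.bincount(ia * n_bins + ib, minlength=n_bins * n_bins)
    counts += np.bincount(ib * n_bins + ia, minlength=n_bins * n_bins)
    return counts.reshape(n_bins, n_bins).astype(float)


def glcm(d: DiscretizedROI, direction: Sequence[int],
         symmetric: bool = True) -> CooccurrenceMatrix:
    """Normalized symmetric GLCM for one Chebyshev-distance-1 direction.

    ``direction`` is a (row, col) offset for a single-slice computation on
    each plane independently, or a (slice, row, col) offset; pairs are
    counted only when both voxels are inside the mask.
    """
    if not symmetric:
        raise NotImplementedError("only symmetric GLCMs are supported")
    off = tuple(int(o) for o in direction)
    if len(off) == 2:
        off = (0,) + off
    if len(off) != 3 or max(abs(o) for o in off) != 1:
        raise ValueError(f"invalid Chebyshev-distance-1 direction {direction}")
    counts = _glcm_counts(d.levels, d.mask, off, d.n_bins)
    return CooccurrenceMatrix.from_counts(counts)


def _check_normalized(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    if not np.isclose(P.sum(), 1.0, atol=1e-8):
        raise ValueError("co-occurrence matrix is not normalized")
    return P


def glcm_features(P) -> Dict[str, float]:
    """Difference-distribution features of a normalized GLCM.

    With ``p(k) = sum_{|i-j|=k} P(i,j)``:

    * difference_average  DA = sum k p(k)
    * difference_variance = sum (k - DA)^2 p(k)
    * contrast            = sum (i-j)^2 P(i,j)
    * dissimilarity       = sum |i-j| P(i,j)

    For a symmetric P, dissimilarity equals the difference average.
    """
    if isinstance(P, CooccurrenceMatrix):
        if P.empty:
            raise FeatureUndefinedError("empty co-occurrence matrix")
        P = P.p
    P = _check_normalized(P)
    n = P.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    k = np.abs(i - j)
    pk = np.bincount(k.ravel(), weights=P.ravel(), minlength=n)
    ks = np.arange(pk.size)
    da = float(np.sum(ks * pk))
    dvar = float(np.sum((ks - da) ** 2 * pk))
    contrast = float(np.sum((i - j) ** 2 * P))
    dissim = float(np.sum(np.abs(i - j) * P))
    return {
        "difference_average": da,
        "difference_variance": dvar,
        "contrast": contrast,
        "dissimilarity": dissim,
    }


def _glcm_counts_2d_stack(d: DiscretizedROI) -> List[List[np.ndarray]]:
    """Per-slice, per-in-plane-direction symmetric pair counts."""
    out = []
    for z in range(d.levels.shape[0]):
        lv, mk = d.levels[z], d.mask[z]
        out.append([_glcm_counts(lv[None], mk[None], (0,) + off, d.n_bins)
                    for off in DIRECTIONS_2D])
    return out


def _glcm_counts_3d(d: DiscretizedROI) -> List[np.ndarray]:
    return [_glcm_counts(d.levels, d.mask, off, d.n_bins)
            for off in DIRECTIONS_3D]


def _mean_feature(count_mats: Iterable[np.ndarray], feature: str) -> float:
    vals = []
    for c in count_mats:
        m = CooccurrenceMatrix.from_counts(c)
        if not m.empty:
            vals.append(glcm_features(m)[feature])
    if not vals:
        raise FeatureUndefinedError("all co-occurrence matrices are empty")
    return float(np.mean(vals))


def _merged_feature(count_mats: Sequence[np.ndarray], feature: str) -> float:
    merged = np.sum(count_mats, axis=0)
    m = CooccurrenceMatrix.from_counts(merged)
    if m.empty:
        raise FeatureUndefinedError("merged co-occurrence matrix is empty")
    return glcm_features(m)[feature]


def aggregate(feature: str, d: DiscretizedROI, mode: str,
              _cache: Optional[dict] = None) -> float:
    """Aggregate a GLCM feature over slices/directions.

    Modes: ``2Davg`` (feature per slice per direction, averaged),
    ``2Dmrg`` (directions merged within each slice, averaged over slices),
    ``2DDmrg`` (slices merged per direction, averaged over directions),
    ``2Dvmrg`` (all in-plane matrices merged, single feature),
    ``3Davg`` (feature per 3D direction, averaged), ``3Dmrg`` (all 3D
    matrices merged, single feature).  Empty matrices are excluded from
    averages; if every matrix is empty a :class:`FeatureUndefinedError`
    is raised.
    """
    if mode not in GLCM_AGGREGATION_MODES:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    cache = _cache if _cache is not None else {}
    if mode.startswith("2D"):
        if "2d" not in cache:
            cache["2d"] = _glcm_counts_2d_stack(d)
        per_slice = cache["2d"]
        if mode == "2Davg":
            return _mean_feature((c for sl in per_slice for c in sl), feature)
        if mode == "2Dmrg":
            vals = []
            for sl in per_slice:
                merged = np.sum(sl, axis=0)
                m = CooccurrenceMatrix.from_counts(merged)
                if not m.empty:
                    vals.append(glcm_features(m)[feature])
            if not vals:
                raise FeatureUndefinedError("all slices empty")
            return float(np.mean(vals))
        if mode == "2DDmrg":
            n_dir = len(DIRECTIONS_2D)
            vals = []
            for k in range(n_dir):
                merged = np.sum([sl[k] for sl in per_slice], axis=0)
                m = CooccurrenceMatrix.from_counts(merged)
                if not m.empty:
                    vals.append(glcm_features(m)[feature])
            if not vals:
                raise FeatureUndefinedError("all directions empty")
            return float(np.mean(vals))
        # 2Dvmrg
        return _merged_feature([c for sl in per_slice for c in sl], feature)
    if "3d" not in cache:
        cache["3d"] = _glcm_counts_3d(d)
    mats = cache["3d"]
    if mode == "3Davg":
        return _mean_feature(mats, feature)
    return _merged_feature(mats, feature)


# ---------------------------------------------------------------------------
# NGTDM / NGLDM
# ---------------------------------------------------------------------------

def _neighbour_offsets(ndim3: bool) -> List[Tuple[int, int, int]]:
    if ndim3:
        offs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
    else:
        offs = [(0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    return offs


def _neighbour_sums(levels: np.ndarray, mask: np.ndarray, ndim3: bool):
    """Per-voxel sum and count of masked Chebyshev-1 neighbour levels."""
    nsum = np.zeros(levels.shape, dtype=float)
    ncnt = np.zeros(levels.shape, dtype=np.int32)
    for off in _neighbour_offsets(ndim3):
        a_sl, b_sl = _shifted_slices(off, levels.shape)
        nsum[a_sl] += np.where(mask[b_sl], levels[b_sl], 0)
        ncnt[a_sl] += mask[b_sl]
    return nsum, ncnt


def _ngtdm_tables(levels: np.ndarray, mask: np.ndarray, n_bins: int,
                  ndim3: bool):
    """NGTDM occurrence counts ``n_i`` and absolute-deviation sums ``s_i``."""
    nsum, ncnt = _neighbour_sums(levels, mask, ndim3)
    valid = mask & (ncnt > 0)
    lv = levels[valid]
    dev = np.abs(lv - nsum[valid] / ncnt[valid])
    n_i = np.bincount(lv - 1, minlength=n_bins).astype(float)
    s_i = np.bincount(lv - 1, weights=dev, minlength=n_bins)
    return n_i, s_i


def ngtdm_complexity(d: DiscretizedROI, mode: str = "3D") -> float:
    """NGTDM complexity under a Chebyshev-distance-1 neighbourhood.

    ``mode='2Dmrg'`` computes per-slice in-plane tables and merges them
    over slices before the feature; ``mode='3D'`` uses the full 26-voxel
    3D neighbourhood.
    """
    if mode == "2Dmrg":
        n_i = np.zeros(d.n_bins)
        s_i = np.zeros(d.n_bins)
        for z in range(d.levels.shape[0]):
            ni, si = _ngtdm_tables(d.levels[z][None], d.mask[z][None],
                                   d.n_bins, ndim3=False)
            n_i += ni
            s_i += si
    elif mode == "3D":
        n_i, s_i = _ngtdm_tables(d.levels, d.mask, d.n_bins, ndim3=True)
    else:
        raise ValueError(f"unknown NGTDM mode {mode!r}")
    n_vc = n_i.sum()
    if n_vc == 0:
        raise FeatureUndefinedError("no masked voxel has a masked neighbour")
    p_i = n_i / n_vc
    idx = np.nonzero(p_i > 0)[0]
    total = 0.0
    for a in idx:
        for b in idx:
            if a == b:
                continue
            total += abs(a - b) * (p_i[a] * s_i[a] + p_i[b] * s_i[b]) / (
                p_i[a] + p_i[b])
    return float(total / n_vc)


def ngldm_dependence_count_energy(d: DiscretizedROI, mode: str = "3Dmrg",
                                  alpha: int = 0) -> float:
    """NGLDM dependence count energy (coarseness ``alpha``, distance 1).

    The dependence count of a masked voxel is the number of its masked
    Chebyshev-distance-1 neighbours whose level differs by at most
    ``alpha``; ``s(i, j)`` counts voxels of level ``i`` with dependence
    count ``j`` and the energy is ``sum (s / N_s)^2``.
    """
    if mode in ("3Dmrg", "3D"):
        ndim3 = True
        planes = [(d.levels, d.mask)]
    elif mode == "2Dmrg":
        ndim3 = False
        planes = [(d.levels[z][None], d.mask[z][None])
                  for z in range(d.levels.shape[0])]
    else:
        raise ValueError(f"unknown NGLDM mode {mode!r}")
    max_nbrs = 26 if ndim3 else 8
    s = np.zeros((d.n_bins, max_nbrs + 1), dtype=float)
    for lv_vol, mk_vol in planes:
        dep = np.zeros(lv_vol.shape, dtype=np.int32)
        for off in _neighbour_offsets(ndim3):
            a_sl, b_sl = _shifted_slices(off, lv_vol.shape)
            hit = mk_vol[b_sl] & (np.abs(lv_vol[a_sl] - lv_vol[b_sl]) <= alpha)
            dep[a_sl] += hit
        lv = lv_vol[mk_vol]
        dp = dep[mk_vol]
        np.add.at(s, (lv - 1, dp), 1.0)
    n_s = s.sum()
    if n_s == 0:
        raise FeatureUndefinedError("empty mask")
    p = s / n_s
    return float(np.sum(p * p))


# ---------------------------------------------------------------------------
# Geary's C
# ---------------------------------------------------------------------------

class GearyCache:
    """Precomputed inverse-distance weights for Geary's C on a fixed mask.

    Spatial weights ``w_ij = 1 / d_ij`` (mm distances) depend only on the
    mask and voxel spacing, so they are computed once and reused across
    intensity changes (occlusion sweeps re-score the same mask many
    times).  When the mask exceeds ``max_voxels``, a seeded uniform
    subsample of voxels is used for both numerator and denominator.
    """

    def __init__(self, mask: np.ndarray, voxel_spacing, max_voxels: int = 3000,
                 seed: int = 0):
        flat_idx = np.flatnonzero(mask.ravel())
        n = flat_idx.size
        if n < 2:
            raise ValueError("Geary's C requires at least 2 masked voxels")
        if n > max_voxels:
            rng = np.random.default_rng(seed)
            sel = rng.choice(n, size=max_voxels, replace=False)
            sel.sort()
            flat_idx = flat_idx[sel]
        self.flat_idx = flat_idx
        pos = np.column_stack(np.unravel_index(flat_idx, mask.shape)).astype(float)
        pos *= np.asarray(voxel_spacing, dtype=float)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff ** 2).sum(axis=2))
        with np.errstate(divide="ignore"):
            w = 1.0 / dist
        np.fill_diagonal(w, 0.0)
        self.W = w.astype(np.float32)
        self.row_sums = self.W.sum(axis=1, dtype=np.float64)
        self.W_total = float(self.row_sums.sum())
        self.n = flat_idx.size

    def value(self, image: np.ndarray) -> float:
        x = image.ravel()[self.flat_idx].astype(np.float64)
        x = x - x.mean()  # centering: shift-invariant and well-conditioned
        denom = float(np.sum(x ** 2))
        if denom == 0.0:
            return float("nan")
        # sum_{i!=j} w_ij (x_i - x_j)^2 = 2 (r . x^2) - 2 x' W x
        wx = self.W @ x.astype(np.float32)
        num = 2.0 * float(self.row_sums @ (x * x)) - 2.0 * float(x @ wx)
        return (self.n - 1) / (2.0 * self.W_total) * num / denom


def gearys_c(roi: IntensityROI, max_voxels: int = 3000, seed: int = 0) -> float:
    """Geary's C of masked intensities with inverse-distance weights.

    Values near 1 indicate spatial randomness; below 1, positive spatial
    autocorrelation (smooth images).  Constant ROIs are undefined (NaN).
    """
    cache = GearyCache(roi.mask, roi.voxel_spacing, max_voxels=max_voxels,
                       seed=seed)
    return cache.value(roi.image)


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------

def first_order_features(roi: IntensityROI, d: DiscretizedROI) -> Dict[str, float]:
    """First-order statistics, histogram and intensity-volume features.

    maximum/range are computed on the raw masked intensities; the 10th
    percentile and mode on the discretized levels (mode ties break to the
    lowest level); ``int_at_vol_fraction_90`` is the smallest masked
    intensity gamma such that the fraction of masked voxels with
    intensity >= gamma is at most 0.90.
    """
    x = roi.masked_values
    lv = d.masked_levels
    hist = np.bincount(lv, minlength=d.n_bins + 1)[1:]
    mode = int(np.argmax(hist)) + 1
    uniq = np.unique(x)
    frac = (x[:, None] >= uniq[None, :]).mean(axis=0) if uniq.size <= 4096 else \
        1.0 - (np.searchsorted(np.sort(x), uniq, side="left") / x.size)
    ok = np.nonzero(frac <= 0.90)[0]
    gamma = float(uniq[ok[0]]) if ok.size else float(uniq[-1])
    return {
        "stat_maximum": float(x.max()),
        "stat_range": float(x.max() - x.min()),
        "ih_p10": float(np.percentile(lv, 10)),
        "ih_mode": float(mode),
        "ivh_int_at_vol_fraction_90": gamma,
    }


# ---------------------------------------------------------------------------
# feature registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    feature_id: str
    family: str
    aggregation: str
    fn: Callable[["ExtractionContext"], float]


class ExtractionContext:
    """Per-image computation cache shared by all registry entries."""

    def __init__(self, roi: IntensityROI, cfg: DiscretizationConfig,
                 geary_cache: Optional[GearyCache] = None, geary_seed: int = 0):
        self.roi = roi
        self.cfg = cfg
        self.d = discretize(roi, cfg)
        self._glcm_cache: dict = {}
        self._geary = geary_cache
        self._geary_seed = geary_seed
        self._first_order: Optional[Dict[str, float]] = None

    def glcm_feature(self, feature: str, mode: str) -> float:
        return aggregate(feature, self.d, mode, _cache=self._glcm_cache)

    def geary(self) -> float:
        if self._geary is None:
            self._geary = GearyCache(self.roi.mask, self.roi.voxel_spacing,
                                     seed=self._geary_seed)
        return self._geary.value(self.roi.image)

    def first_order(self, key: str) -> float:
        if self._first_order is None:
            self._first_order = first_order_features(self.roi, self.d)
        return self._first_order[key]


class FeatureRegistry:
    """Ordered, unique-id feature set; order defines classifier input order."""

    def __init__(self, entries: Sequence[FeatureDef], name: str = "custom"):
        ids = [e.feature_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in registry")
        if not entries:
            raise ValueError("registry is empty")
        self.entries: Tuple[FeatureDef, ...] = tuple(entries)
        self.name = name

    def __len__(self):
        return len(self.entries)

    @property
    def ids(self) -> List[str]:
        return [e.feature_id for e in self.entries]

    def fingerprint(self) -> str:
        return f"{self.name}:{len(self)}:" + ",".join(self.ids)

    def to_json(self) -> List[Dict[str, str]]:
        return [{"feature_id": e.feature_id, "family": e.family,
                 "aggregation": e.aggregation} for e in self.entries]


def _glcm_def(feature: str, mode: str) -> FeatureDef:
    return FeatureDef(
        feature_id=f"glcm{mode}_{feature}", family="glcm", aggregation=mode,
        fn=lambda ctx, f=feature, m=mode: ctx.glcm_feature(f, m))


def _fo_def(key: str, family: str) -> FeatureDef:
    return FeatureDef(feature_id=key, family=family, aggregation="3D",
                      fn=lambda ctx, k=key: ctx.first_order(k))


_GEARY = FeatureDef("morph_gearys_c", "morphology", "3D",
                    lambda ctx: ctx.geary())


def table2_registry() -> FeatureRegistry:
    """The 22-feature registry sensitive to tissue near outer annular fissures.

    Intensity, heterogeneity and gradient features whose values respond to
    thin bright streaks in the annulus fibrosus rather than to nucleus
    changes; this set is the input layer of the attention-mapping
    classifier.
    """
    entries = [
        _GEARY,
        _fo_def("stat_maximum", "statistics"),
        _fo_def("stat_range", "statistics"),
        _fo_def("ivh_int_at_vol_fraction_90", "intensity_volume"),
        _fo_def("ih_p10", "intensity_histogram"),
        _fo_def("ih_mode", "intensity_histogram"),
        _glcm_def("difference_average", "2Davg"),
        _glcm_def("dissimilarity", "2Davg"),
        _glcm_def("difference_average", "2DDmrg"),
        _glcm_def("difference_variance", "2DDmrg"),
        _glcm_def("contrast", "2DDmrg"),
        _glcm_def("dissimilarity", "2DDmrg"),
        _glcm_def("difference_average", "2Dmrg"),
        _glcm_def("difference_variance", "2Dvmrg"),
        _glcm_def("contrast", "2Dvmrg"),
        _glcm_def("dissimilarity", "2Dvmrg"),
        _glcm_def("difference_average", "3Davg"),
        _glcm_def("difference_variance", "3Davg"),
        _glcm_def("dissimilarity", "3Davg"),
        FeatureDef("ngtdm2Dmrg_complexity", "ngtdm", "2Dmrg",
                   lambda ctx: ngtdm_complexity(ctx.d, "2Dmrg")),
        FeatureDef("ngtdm3D_complexity", "ngtdm", "3D",
                   lambda ctx: ngtdm_complexity(ctx.d, "3D")),
        FeatureDef("ngldm3Dmrg_dependence_count_energy", "ngldm", "3Dmrg",
                   lambda ctx: ngldm_dependence_count_energy(ctx.d, "3Dmrg")),
    ]
    return FeatureRegistry(entries, name="table2_22")


def full_registry() -> FeatureRegistry:
    """Full family x aggregation expansion of all implemented features.

    Every GLCM difference feature under all six aggregation modes, NGTDM
    complexity and NGLDM dependence count energy in merged-2D and 3D
    variants, plus the morphology/first-order set.  The registry is
    extensible: additional :class:`FeatureDef` entries widen the
    classifier input without code changes elsewhere.
    """
    entries: List[FeatureDef] = [
        _GEARY,
        _fo_def("stat_maximum", "statistics"),
        _fo_def("stat_range", "statistics"),
        _fo_def("ivh_int_at_vol_fraction_90", "intensity_volume"),
        _fo_def("ih_p10", "intensity_histogram"),
        _fo_def("ih_mode", "intensity_histogram"),
    ]
    for feature in ("difference_average", "difference_variance", "contrast",
                    "dissimilarity"):
        for mode in GLCM_AGGREGATION_MODES:
            entries.append(_glcm_def(feature, mode))
    entries.append(FeatureDef("ngtdm2Dmrg_complexity", "ngtdm", "2Dmrg",
                              lambda ctx: ngtdm_complexity(ctx.d, "2Dmrg")))
    entries.append(FeatureDef("ngtdm3D_complexity", "ngtdm", "3D",
                              lambda ctx: ngtdm_complexity(ctx.d, "3D")))
    entries.append(FeatureDef("ngldm2Dmrg_dependence_count_energy", "ngldm",
                              "2Dmrg",
                              lambda ctx: ngldm_dependence_count_energy(
                                  ctx.d, "2Dmrg")))
    entries.append(FeatureDef("ngldm3Dmrg_dependence_count_energy", "ngldm",
                              "3Dmrg",
                              lambda ctx: ngldm_dependence_count_energy(
                                  ctx.d, "3Dmrg")))
    return FeatureRegistry(entries, name="full")


def extract_features(roi: IntensityROI, registry: FeatureRegistry,
                     cfg: Optional[DiscretizationConfig] = None,
                     geary_cache: Optional[GearyCache] = None,
                     geary_seed: int = 0) -> Dict[str, float]:
    """Compute every registry feature on one masked stack, in registry order.

    Undefined features (constant ROI for Geary's C, empty matrices) are
    imputed as 0 with a warning so downstream classifier inputs stay
    dense.
    """
    cfg = cfg or DiscretizationConfig()
    ctx = ExtractionContext(roi, cfg, geary_cache=geary_cache,
                            geary_seed=geary_seed)
    out: Dict[str, float] = {}
    for entry in registry.entries:
        try:
            v = float(entry.fn(ctx))
        except FeatureUndefinedError as exc:
            warnings.warn(f"feature {entry.feature_id} undefined ({exc}); "
                          "imputed as 0", stacklevel=2)
            v = 0.0
        if not np.isfinite(v):
            warnings.warn(f"feature {entry.feature_id} non-finite; imputed "
                          "as 0", stacklevel=2)
            v = 0.0
        out[entry.feature_id] = v
    return out
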