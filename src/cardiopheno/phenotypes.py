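"""Phenotype decision logic for high-content cardiomyocyte assays.

Four read-outs are implemented on top of the segmentation module:

* **Multinucleation** — percentages of mono-, bi- and multinucleated
  cells from per-cell nuclei counts.
* **Cardiomyocyte purity** — fraction of cells whose cytoplasmic
  sarcomeric-marker intensity exceeds a control-derived threshold.
* **BNP classification** — negative / medium / high perinuclear proBNP
  intensity classes, with the two thresholds derived from bosentan
  (negative control) and endothelin-1 (positive control) wells.
* **Sarcomeric disarray** — texture features (Haralick co-occurrence,
  Gabor bank, Gaussian-derivative, radial profile) feeding a linear
  two-class classifier whose "goodness" statistic diagnoses class
  separation (>1 means well separated).

All percentage outputs are exhaustive, mutually exclusive partitions
(each family sums to 100).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import graycomatrix, graycoprops
from skimage.filters import gabor_kernel
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .segmentation import ImageScene, subtract_background

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Counting phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultinucleationSummary:
    n_cells: int
    n_mono: int
    n_bi: int
    n_multi: int
    pct_mono: float
    pct_bi: float
    pct_multi: float


def classify_multinucleation(nuclei_counts) -> MultinucleationSummary:
    """Percentages of cells with 1, 2 and >2 nuclei ((a/b) x 100)."""
    counts = np.asarray(nuclei_counts, dtype=int)
    if counts.size == 0:
        raise ValueError("no cells to classify")
    if np.any(counts < 1):
        raise ValueError("every cell must have at least one nucleus")
    n = counts.size
    n_mono = int(np.sum(counts == 1))
    n_bi = int(np.sum(counts == 2))
    n_multi = int(np.sum(counts > 2))
    return MultinucleationSummary(
        n_cells=n, n_mono=n_mono, n_bi=n_bi, n_multi=n_multi,
        pct_mono=100.0 * n_mono / n,
        pct_bi=100.0 * n_bi / n,
        pct_multi=100.0 * n_multi / n,
    )


def derive_positive_threshold(control_intensities, percentile: float = 99.0,
                              min_n: int = 20) -> float:
    """Marker-positivity threshold from a negative control.

    The control is a secondary-antibody-only or non-cardiomyocyte
    (e.g. fibroblast) well; the threshold is a high percentile of its
    intensity distribution so that essentially all control cells score
    negative.
    """
    x = np.asarray(control_intensities, dtype=float)
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} control cells, got {x.size}")
    return float(np.percentile(x, percentile))


def compute_purity(cell_intensities, threshold: float) -> float:
    """% of cells whose mean marker intensity exceeds the threshold."""
    x = np.asarray(cell_intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no cells")
    return float(100.0 * np.mean(x > threshold))


# ---------------------------------------------------------------------------
# BNP classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdSet:
    """Negative/medium and medium/high BNP intensity cutoffs.

    ``ratio`` = med_high / neg_med; a value around 4 is typical for
    well-behaved control pairs.  ``flagged`` marks an inverted pair
    (med_high <= neg_med), which indicates overlapping controls.
    """

    neg_med: float
    med_high: float
    ratio: float
    flagged: bool = False


@dataclass(frozen=True)
class BnpSummary:
    n_cells: int
    pct_negative: float
    pct_medium: float
    pct_high: float
    pct_positive: float


def derive_bnp_thresholds(bos_intensities, et1_intensities,
                          p_bos: float = 95.0, p_et1: float = 50.0,
                          min_n: int = 50) -> ThresholdSet:
    """Control-derived BNP intensity thresholds.

    neg_med is the ``p_bos``-th percentile of the bosentan-well
    perinuclear intensities (so >90% of BOS cells classify negative);
    med_high is the ``p_et1``-th percentile of the endothelin-1-well
    intensities (ET1 wells should be >90% BNP-positive).  An inverted
    pair is returned flagged with a warning rather than raising.
    """
    bos = np.asarray(bos_intensities, dtype=float)
    et1 = np.asarray(et1_intensities, dtype=float)
    if bos.size < min_n or et1.size < min_n:
        raise ValueError(f"need >= {min_n} cells in each control well "
                         f"(got BOS {bos.size}, ET1 {et1.size})")
    neg_med = float(np.percentile(bos, p_bos))
    med_high = float(np.percentile(et1, p_et1))
    flagged = med_high <= neg_med
    if flagged:
        logger.warning(
            "BNP thresholds inverted (med_high %.3g <= neg_med %.3g): "
            "control distributions overlap; check ET1/BOS treatments",
            med_high, neg_med)
    ratio = med_high / neg_med if neg_med > 0 else float("inf")
    return ThresholdSet(neg_med=neg_med, med_high=med_high, ratio=ratio,
                        flagged=flagged)


def classify_bnp(ring_intensities, thresholds: ThresholdSet) -> BnpSummary:
    """Classify cardiomyocytes by perinuclear BNP intensity.

    negative: I <= neg_med; medium: neg_med < I <= med_high;
    high: I > med_high.  Boundary values go to the lower class so the
    classes are exhaustive and disjoint; positive = medium + high.
    """
    x = np.asarray(ring_intensities, dtype=float)
    if x.size == 0:
        raise ValueError("no cardiomyocytes to classify")
    n = x.size
    n_neg = int(np.sum(x <= thresholds.neg_med))
    n_high = int(np.sum(x > thresholds.med_high))
    n_med = n - n_neg - n_high
    return BnpSummary(
        n_cells=n,
        pct_negative=100.0 * n_neg / n,
        pct_medium=100.0 * n_med / n,
        pct_high=100.0 * n_high / n,
        pct_positive=100.0 * (n_med + n_high) / n,
    )


# ---------------------------------------------------------------------------
# Texture features
# ---------------------------------------------------------------------------

HARALICK_PROPS = ("contrast", "dissimilarity", "homogeneity", "ASM",
                  "energy", "correlation")
SER_NAMES = ("spot", "edge", "ridge", "valley", "saddle", "hole",
             "bright", "dark")


def feature_names(gabor_n_angles: int = 6, n_profile_bands: int = 4
                  ) -> list[str]:
    """Ordered names of the fixed-length texture feature vector."""
    names = [f"haralick_{p}" for p in HARALICK_PROPS]
    names += [f"gabor_energy_{i}" for i in range(gabor_n_angles)]
    names += [f"ser_{s}" for s in SER_NAMES]
    names += [f"profile_band_{i}" for i in range(n_profile_bands)]
    names += ["profile_slope", "profile_cv"]
    return names


def _haralick_features(image, mask, distance: int, levels: int):
    vals = image[mask]
    lo, hi = np.percentile(vals, [1, 99])
    if hi <= lo:
        # constant region: co-occurrence on a single level -> zero
        # contrast/dissimilarity, full homogeneity/energy
        q = np.ones(image.shape, dtype=np.uint8)
    else:
        q = np.clip((image - lo) / (hi - lo), 0, 1)
        q = (q * (levels - 1)).astype(np.uint8) + 1
    q[~mask] = 0
    angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    glcm = graycomatrix(q, [distance], angles, levels=levels + 1,
                        symmetric=True, normed=False)
    glcm = glcm[1:, 1:, :, :].astype(float)  # drop outside-mask level
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    sums[sums == 0] = 1.0
    glcm /= sums
    out = []
    for prop in HARALICK_PROPS:
        try:
            per_angle = graycoprops(glcm, prop)[0]
        except ValueError:
            per_angle = np.zeros(len(angles))
        per_angle = np.nan_to_num(per_angle)
        out.append(float(per_angle.mean()))
    return out


def _gabor_bank(scale_px: float, wavelength: float, n_angles: int):
    """Unit-L2 ("kernel normalized") Gabor filters at n_angles orientations.

    The Gaussian envelope has sigma = scale/2 px and the carrier period
    is wavelength * scale / 2 px (4 px at the published defaults),
    placing the passband over the few-pixel sarcomere striation band.
    """
    sigma = scale_px / 2.0
    period = wavelength * scale_px / 2.0
    kernels = []
    for i in range(n_angles):
        theta = np.pi * i / n_angles
        k = gabor_kernel(frequency=1.0 / period, theta=theta,
                         sigma_x=sigma, sigma_y=sigma)
        k = k / np.linalg.norm(k)
        kernels.append(k)
    return kernels


def _gabor_features(image, mask, scale_px, wavelength, n_angles):
    out = []
    for k in _gabor_bank(scale_px, wavelength, n_angles):
        re = ndi.convolve(image, np.real(k), mode="nearest")
        im = ndi.convolve(image, np.imag(k), mode="nearest")
        out.append(float(np.mean(re[mask] ** 2 + im[mask] ** 2)))
    return out


def _ser_features(image, mask, scale_px):
    """Gaussian-derivative (spot/edge/ridge/valley/...) response stats."""
    g = lambda *orders: ndi.gaussian_filter(image, scale_px, order=orders)
    lx, ly = g(0, 1), g(1, 0)
    lxx, lyy, lxy = g(0, 2), g(2, 0), g(1, 1)
    lap = lxx + lyy
    # Hessian eigenvalues lam1 <= lam2
    tr, det_root = lap / 2.0, np.sqrt(((lxx - lyy) / 2.0) ** 2 + lxy ** 2)
    lam1, lam2 = tr - det_root, tr + det_root
    m = mask
    return [
        float(np.mean(np.maximum(-lap[m], 0) ** 2)),        # spot
        float(np.mean(lx[m] ** 2 + ly[m] ** 2)),            # edge
        float(np.mean(np.maximum(-lam1[m], 0) ** 2)),       # ridge
        float(np.mean(np.maximum(lam2[m], 0) ** 2)),        # valley
        float(np.mean(np.maximum(-lam1[m] * lam2[m], 0))),  # saddle
        float(np.mean(np.maximum(lap[m], 0) ** 2)),         # hole
        float(np.mean(np.maximum(image[m], 0) ** 2)),       # bright
        float(np.mean(np.maximum(-image[m], 0) ** 2)),      # dark
    ]


def _radial_profile_features(image, mask, inner_mask, profile_width_px,
                             n_bands):
    """Mean intensity in concentric bands outward from the nucleus."""
    if inner_mask is not None and inner_mask.any():
        dist = ndi.distance_transform_edt(~inner_mask)
    else:
        cy, cx = ndi.center_of_mass(mask)
        yy, xx = np.indices(mask.shape)
        dist = np.hypot(yy - cy, xx - cx)
    band = (dist // profile_width_px).astype(int)
    means = []
    for b in range(n_bands):
        sel = mask & (band == b)
        means.append(float(image[sel].mean()) if sel.any() else 0.0)
    x = np.arange(n_bands, dtype=float)
    slope = float(np.polyfit(x, means, 1)[0])
    mu = float(np.mean(means))
    cv = float(np.std(means) / abs(mu)) if mu != 0 else 0.0
    return means + [slope, cv]


def extract_texture_features(
    image: np.ndarray,
    mask: np.ndarray,
    inner_mask: np.ndarray | None = None,
    haralick_distance: int = 1,
    haralick_levels: int = 32,
    gabor_scale_px: float = 4.0,
    gabor_wavelength: float = 2.0,
    gabor_n_angles: int = 6,
    ser_scale_px: float = 0.5,
    profile_width_px: int = 4,
    n_profile_bands: int = 4,
    min_pixels: int = 50,
) -> np.ndarray | None:
    """Fixed-length texture feature vector over one cell region.

    ``image`` is the (background-subtracted) sarcomeric channel cropped
    to the cell, ``mask`` its cytoplasm region and ``inner_mask`` the
    nucleus set (origin of the radial profile).  Intensities inside the
    region are z-scored before filtering so the Gabor and derivative
    features describe texture rather than staining brightness; the
    co-occurrence matrix is quantized to ``haralick_levels`` grey
    levels over the region's robust (1st-99th pct) range.

    Returns ``None`` (caller flags and excludes the cell) when the
    region has fewer than ``min_pixels`` pixels.  Deterministic:
    identical inputs give bitwise-identical vectors.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < min_pixels:
        logger.debug("region of %d px < %d: cell excluded from "
                     "texture analysis", int(mask.sum()), min_pixels)
        return None
    image = np.asarray(image, dtype=float)
    vals = image[mask]
    sd = vals.std()
    norm = (image - vals.mean()) / (sd if sd > 0 else 1.0)

    features = _haralick_features(image, mask, haralick_distance,
                                  haralick_levels)
    features += _gabor_features(norm, mask, gabor_scale_px,
                                gabor_wavelength, gabor_n_angles)
    features += _ser_features(norm, mask, ser_scale_px)
    features += _radial_profile_features(norm, mask, inner_mask,
                                         profile_width_px, n_profile_bands)
    return np.asarray(features, dtype=float)


def extract_features_for_cells(
    scene: ImageScene,
    cytoplasm_labels: np.ndarray,
    cell_labels: np.ndarray,
    channel: str = "ch488",
    curvature: float = 10.0,
    **feature_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Texture features for every segmented cell in a scene.

    The channel is sharpened with the sliding-parabola filter once per
    cell crop; cells whose cytoplasm region is too small are excluded.
    Returns ``(cell_ids, feature_matrix)``.
    """
    from skimage.measure import regionprops

    ids, rows = [], []
    for region in regionprops(cytoplasm_labels):
        pad = 8  # margin for filter support
        sl = tuple(slice(max(s.start - pad, 0), min(s.stop + pad, dim))
                   for s, dim in zip(region.slice, cytoplasm_labels.shape))
        mask = cytoplasm_labels[sl] == region.label
        inner = cell_labels[sl] == region.label
        crop = subtract_background(scene.channel(channel)[sl], curvature)
        fv = extract_texture_features(crop, mask & ~inner, inner,
                                      **feature_kwargs)
        if fv is not None:
            ids.append(region.label)
            rows.append(fv)
    if not rows:
        return np.array([], dtype=int), np.empty((0, len(feature_names())))
    return np.asarray(ids, dtype=int), np.vstack(rows)


# ---------------------------------------------------------------------------
# Disarray classifier
# ---------------------------------------------------------------------------

@dataclass
class DisarrayClassifier:
    """Standardized linear discriminant for organized vs disarrayed cells.

    Scores are ``(x - mean) / scale @ weights + bias``; positive scores
    classify as disarrayed.  ``goodness`` is the standardized two-class
    separation |mu1 - mu2| / sqrt(s1^2 + s2^2) of cross-validated
    discriminant scores; values above 1 indicate a well-separated
    training set.
    """

    mean: np.ndarray
    scale: np.ndarray
    weights: np.ndarray
    bias: float
    goodness: float
    n_organized: int
    n_disarrayed: int
    feature_names: list[str] = field(default_factory=feature_names)

    def scores(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.weights.size:
            raise ValueError(
                f"feature length {x.shape[1]} != model {self.weights.size}")
        return (x - self.mean) / self.scale @ self.weights + self.bias

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("mean", "scale", "weights"):
            d[k] = list(map(float, d[k]))
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DisarrayClassifier":
        d = json.loads(text)
        for k in ("mean", "scale", "weights"):
            d[k] = np.asarray(d[k], dtype=float)
        return cls(**d)


ORGANIZED, DISARRAYED = 0, 1


def _cv_goodness(xs: np.ndarray, y: np.ndarray, template) -> np.ndarray:
    """Standardized two-class separation of cross-validated scores.

    Discriminant scores are collected over stratified folds with the
    model refit on the complementary data, so the statistic is not
    inflated by training-set overfitting: with indistinguishable
    classes it concentrates near 0, and >1 genuinely means separated.
    Falls back to training scores when a class is too small to fold.
    """
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold

    n_splits = min(5, int(np.bincount(y).min()))
    scores = np.empty(len(y))
    if n_splits >= 2:
        folds = StratifiedKFold(n_splits=n_splits, shuffle=False)
        for train, test in folds.split(xs, y):
            m = clone(template).fit(xs[train], y[train])
            scores[test] = m.decision_function(xs[test])
    else:
        scores = template.decision_function(xs)
    s0, s1 = scores[y == ORGANIZED], scores[y == DISARRAYED]
    denom = np.sqrt(s0.var() + s1.var())
    return float(abs(s0.mean() - s1.mean()) / denom) if denom > 0 \
        else float("inf")


def train_disarray_classifier(features: np.ndarray, labels,
                              min_per_class: int = 100
                              ) -> DisarrayClassifier:
    """Fit the two-class linear discriminant on standardized features.

    ``labels`` holds 0 (organized) / 1 (disarrayed) per cell.  Training
    sets smaller than ``min_per_class`` per class are accepted with a
    "small training set" warning — heterogeneous cardiomyocyte
    preparations need large training sets for a stable boundary.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_org = int(np.sum(y == ORGANIZED))
    n_dis = int(np.sum(y == DISARRAYED))
    if n_org == 0 or n_dis == 0:
        raise ValueError("both classes must be present in the training set")
    if min(n_org, n_dis) < min_per_class:
        logger.warning("small training set (%d organized, %d disarrayed; "
                       "recommend >= %d per class)", n_org, n_dis,
                       min_per_class)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xs = (x - mean) / scale
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(xs, y)
    weights = lda.coef_[0]
    bias = float(lda.intercept_[0])
    goodness = _cv_goodness(xs, y, lda)
    return DisarrayClassifier(mean=mean, scale=scale, weights=weights,
                              bias=bias, goodness=goodness,
                              n_organized=n_org, n_disarrayed=n_dis)


@dataclass(frozen=True)
class DisarraySummary:
    n_cells: int
    pct_organized: float
    pct_disarrayed: float


def classify_disarray(features: np.ndarray,
                      model: DisarrayClassifier) -> DisarraySummary:
    """Percent organized vs disarrayed by sign of the discriminant score."""
    scores = model.scores(features)
    n = scores.size
    if n == 0:
        raise ValueError("no cells to classify")
    n_dis = int(np.sum(scores > 0))
    return DisarraySummary(n_cells=n,
                           pct_organized=100.0 * (n - n_dis) / n,
                           pct_disarrayed=100.0 * n_dis / n)
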