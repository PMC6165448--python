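"""Image-texture features for food-surface images.

Twenty-two features per grayscale image: four first-order histogram
statistics (mean, standard deviation, skewness, kurtosis), thirteen
gray-level co-occurrence (Haralick) statistics, and five run-length-matrix
statistics (SRE, LRE, GLNU, RLNU, RP).

Conventions
-----------
* First-order statistics use population moments on the *unquantized*
  grayscale image; skewness = m3/sd^3, kurtosis = m4/sd^4 (raw, so a
  normal field gives kurtosis 3).
* Co-occurrence and run-length statistics are computed on a uniformly
  quantized image (default 32 levels), offset d = 1, over the four
  principal directions {0, 45, 90, 135 degrees}; the co-occurrence matrix
  is symmetrized and each direction's features are averaged.
* Entropy-type features use log base 2.  IMC1 is base-invariant (a ratio
  of entropies); IMC2 is computed with natural-log entropies as in the
  original formulation.
* Features that are undefined on degenerate images (zero variance) are
  returned as NaN and flagged, never silently zero-filled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

__all__ = [
    "TextureConfig",
    "FIRST_ORDER_NAMES",
    "HARALICK_NAMES",
    "RLM_NAMES",
    "TEXTURE_NAMES",
    "to_grayscale",
    "quantize",
    "crop_roi",
    "first_order_stats",
    "cooccurrence",
    "haralick_features",
    "run_length",
    "rlm_features",
    "texture_vector",
]

FIRST_ORDER_NAMES = ("mean", "sd", "skewness", "kurtosis")
HARALICK_NAMES = (
    "ASM",
    "contrast",
    "correlation",
    "sum_of_squares",
    "IDM",
    "entropy",
    "sum_entropy",
    "sum_average",
    "sum_variance",
    "difference_variance",
    "difference_entropy",
    "IMC1",
    "IMC2",
)
RLM_NAMES = ("SRE", "LRE", "GLNU", "RLNU", "RP")
TEXTURE_NAMES = FIRST_ORDER_NAMES + HARALICK_NAMES + RLM_NAMES

#: angles (radians) passed to skimage per principal direction.  In the
#: classic texture convention 45 deg runs up-right, i.e. image offset
#: (-1, +1); skimage's angle theta yields offset (round(d sin theta),
#: round(d cos theta)) = (+1, -1) at 3pi/4, the symmetric equivalent.
_ANGLES = {0: 0.0, 45: 3 * np.pi / 4, 90: np.pi / 2, 135: np.pi / 4}

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class TextureConfig:
    """Quantization depth, co-occurrence offset and direction set."""

    levels: int = 32
    distance: int = 1
    directions: tuple[int, ...] = (0, 45, 90, 135)
    symmetric: bool = True
    roi_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        bad = set(self.directions) - set(_ANGLES)
        if bad:
            raise ValueError(f"unsupported directions: {sorted(bad)}")


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to grayscale by luma weighting.

    Weights (0.299, 0.587, 0.114); result rounded to nearest integer,
    256 levels.  A single-channel image is passed through unchanged.
    """
    arr = np.asarray(rgb)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB image, got shape {arr.shape}")
    gray = np.rint(arr.astype(np.float64) @ _LUMA)
    return np.clip(gray, 0, 255).astype(np.uint8)


def quantize(img: np.ndarray, levels: int, source_levels: int = 256) -> np.ndarray:
    """Uniformly re-bin ``img`` from ``source_levels`` down to ``levels``.

    pixel -> floor(pixel * levels / source_levels); intensity order is
    preserved.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if levels > source_levels:
        raise ValueError("levels must not exceed the current depth")
    img = np.asarray(img)
    out = (img.astype(np.int64) * levels) // source_levels
    return out.astype(np.uint8 if levels <= 256 else np.int64)


def crop_roi(img: np.ndarray, fraction: float = 0.6) -> np.ndarray:
    """Central rectangular crop covering ``fraction`` of each dimension."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    h, w = img.shape[:2]
    ch, cw = max(2, round(h * fraction)), max(2, round(w * fraction))
    top, left = (h - ch) // 2, (w - cw) // 2
    return img[top : top + ch, left : left + cw]


def first_order_stats(img: np.ndarray) -> tuple[float, float, float, float]:
    """Population mean, sd, skewness and (raw) kurtosis of pixel intensity.

    On a constant image sd = 0 and skewness/kurtosis are undefined (NaN).
    """
    x = np.asarray(img, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty image")
    mean = x.mean()
    centered = x - mean
    var = np.mean(centered**2)
    sd = math.sqrt(var)
    if sd == 0.0:
        return mean, 0.0, float("nan"), float("nan")
    skew = np.mean(centered**3) / sd**3
    kurt = np.mean(centered**4) / sd**4
    return mean, sd, float(skew), float(kurt)


def cooccurrence(
    img: np.ndarray,
    levels: int,
    distance: int = 1,
    directions: tuple[int, ...] = (0, 45, 90, 135),
    symmetric: bool = True,
) -> np.ndarray:
    """Normalized gray-level co-occurrence matrix.

    Pair counts at offset ``distance`` are accumulated over the requested
    directions, symmetrized if flagged, and normalized to sum 1.
    """
    P = _glcm_counts(img, levels, distance, directions, symmetric).sum(axis=-1)
    total = P.sum()
    if total == 0:
        raise ValueError("no valid pixel pair at the requested offset")
    return P / total


def _glcm_counts(img, levels, distance, directions, symmetric):
    """Raw per-direction GLCM counts, shape (levels, levels, n_directions)."""
    img = np.asarray(img)
    if img.max(initial=0) >= levels:
        raise ValueError("pixel value exceeds quantization depth")
    angles = [_ANGLES[d] for d in directions]
    counts = graycomatrix(
        img.astype(np.uint8),
        distances=[distance],
        angles=angles,
        levels=levels,
        symmetric=symmetric,
        normed=False,
    )
    return counts[:, :, 0, :].astype(np.float64)


def haralick_features(P: np.ndarray) -> dict[str, float]:
    """The 13 classic co-occurrence statistics of a normalized GLCM.

    Returns a dict keyed by :data:`HARALICK_NAMES`.  On a constant image
    (single nonzero cell) correlation, IMC1 and IMC2 are undefined (NaN).
    """
    P = np.asarray(P, dtype=np.float64)
    G = P.shape[0]
    if P.shape != (G, G):
        raise ValueError("GLCM must be square")
    total = P.sum()
    if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError("GLCM must be normalized to sum 1")

    i = np.arange(G, dtype=np.float64)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # sum/difference marginals: k = i+j in [0, 2G-2], |i-j| in [0, G-1]
    p_sum = np.bincount((ii + jj).astype(np.int64).ravel(), weights=P.ravel(), minlength=2 * G - 1)
    p_diff = np.bincount(np.abs(ii - jj).astype(np.int64).ravel(), weights=P.ravel(), minlength=G)
    k_sum = np.arange(2 * G - 1, dtype=np.float64)
    k_diff = np.arange(G, dtype=np.float64)

    asm = float((P**2).sum())
    contrast = float((k_diff**2) @ p_diff)
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    variance = float((((ii - mu_x) ** 2) * P).sum())
    entropy = _entropy2(P)
    sum_entropy = _entropy2(p_sum)
    sum_average = float(k_sum @ p_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ p_sum)
    diff_mean = float(k_diff @ p_diff)
    diff_variance = float(((k_diff - diff_mean) ** 2) @ p_diff)
    diff_entropy = _entropy2(p_diff)

    if var_x <= 0 or var_y <= 0:
        corr = imc1 = imc2 = float("nan")
    else:
        corr = float((((ii - mu_x) * (jj - mu_y)) * P).sum() / math.sqrt(var_x * var_y))
        # information measures; IMC1 is base-invariant, IMC2 uses nats
        hx = _entropy_nat(px)
        hy = _entropy_nat(py)
        hxy = _entropy_nat(P)
        outer = np.outer(px, py)
        mask = (P > 0) & (outer > 0)
        hxy1 = -float((P[mask] * np.log(outer[mask])).sum())
        m2 = outer > 0
        hxy2 = -float((outer[m2] * np.log(outer[m2])).sum())
        denom = max(hx, hy)
        imc1 = (hxy - hxy1) / denom if denom > 0 else float("nan")
        arg = 1.0 - math.exp(-2.0 * (hxy2 - hxy))
        imc2 = math.sqrt(max(arg, 0.0))

    return {
        "ASM": asm,
        "contrast": contrast,
        "correlation": corr,
        "sum_of_squares": variance,
        "IDM": idm,
        "entropy": entropy,
        "sum_entropy": sum_entropy,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "difference_variance": diff_variance,
        "difference_entropy": diff_entropy,
        "IMC1": imc1,
        "IMC2": imc2,
    }


def _entropy2(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=np.float64).ravel()
    nz = p[p > 0]
    return -float((nz * np.log2(nz)).sum())


def _entropy_nat(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=np.float64).ravel()
    nz = p[p > 0]
    return -float((nz * np.log(nz)).sum())


def run_length(img: np.ndarray, direction: int, levels: int | None = None) -> np.ndarray:
    """Run-length matrix R[g, l-1] = number of maximal runs of gray level
    ``g`` with length ``l`` along ``direction`` (0, 45, 90 or 135 degrees).
    """
    img = np.asarray(img)
    if direction not in _ANGLES:
        raise ValueError("direction must be one of 0, 45, 90, 135")
    if levels is None:
        levels = int(img.max()) + 1
    h, w = img.shape
    lmax = max(h, w)
    R = np.zeros((levels, lmax), dtype=np.int64)
    for line in _scan_lines(img, direction):
        if line.size == 0:
            continue
        # change points delimit maximal runs
        breaks = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate(([0], breaks))
        ends = np.concatenate((breaks, [line.size]))
        lengths = ends - starts
        grays = line[starts]
        np.add.at(R, (grays.astype(np.int64), lengths - 1), 1)
    return R


def _scan_lines(img: np.ndarray, direction: int):
    h, w = img.shape
    if direction == 0:
        yield from img
    elif direction == 90:
        yield from img.T
    elif direction == 135:  # down-right diagonals
        for k in range(-(h - 1), w):
            yield np.diagonal(img, offset=k)
    else:  # 45: up-right diagonals
        flipped = np.fliplr(img)
        for k in range(-(h - 1), w):
            yield np.diagonal(flipped, offset=k)


def rlm_features(R: np.ndarray, num_pixels: int) -> dict[str, float]:
    """SRE, LRE, GLNU, RLNU and RP of a run-length matrix."""
    R = np.asarray(R, dtype=np.float64)
    N = R.sum()
    if N == 0:
        raise ValueError("run-length matrix has no runs")
    lengths = np.arange(1, R.shape[1] + 1, dtype=np.float64)
    row_tot = R.sum(axis=1)  # per gray level
    col_tot = R.sum(axis=0)  # per run length
    return {
        "SRE": float((col_tot / lengths**2).sum() / N),
        "LRE": float((col_tot * lengths**2).sum() / N),
        "GLNU": float((row_tot**2).sum() / N),
        "RLNU": float((col_tot**2).sum() / N),
        "RP": float(N / num_pixels),
    }


def texture_vector(
    img: np.ndarray, cfg: TextureConfig = TextureConfig(), *, warn_undefined: bool = True
) -> dict[str, float]:
    """The full 22-feature texture vector of a grayscale image.

    First-order statistics are computed on the unquantized image;
    co-occurrence and run-length statistics on the quantized image,
    each direction computed separately and the features averaged.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("texture_vector expects a 2-D grayscale image")
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2x2")

    out: dict[str, float] = dict(zip(FIRST_ORDER_NAMES, first_order_stats(img)))

    q = quantize(img, cfg.levels)
    counts = _glcm_counts(q, cfg.levels, cfg.distance, cfg.directions, cfg.symmetric)
    per_dir = []
    for k in range(counts.shape[-1]):
        Pk = counts[:, :, k]
        tot = Pk.sum()
        if tot == 0:
            continue
        per_dir.append(haralick_features(Pk / tot))
    for name in HARALICK_NAMES:
        out[name] = float(np.mean([f[name] for f in per_dir]))

    rlm_acc = {name: [] for name in RLM_NAMES}
    for d in cfg.directions:
        feats = rlm_features(run_length(q, d, cfg.levels), q.size)
        for name in RLM_NAMES:
            rlm_acc[name].append(feats[name])
    for name in RLM_NAMES:
        out[name] = float(np.mean(rlm_acc[name]))

    if warn_undefined:
        undefined = [k for k, v in out.items() if math.isnan(v)]
        if undefined:
            warnings.warn(
                f"undefined texture features on degenerate image: {undefined}",
                stacklevel=2,
            )
    return out
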