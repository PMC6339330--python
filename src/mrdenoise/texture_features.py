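"""Candidate feature bank: statistical, GLCM, GLRLM, Tamura and noise features.

The full bank has 95 named scalars:

* 9 statistical / histogram features,
* 8 co-occurrence (GLCM) features x 4 directions,
* 11 run-length (GLRLM) features x 4 directions,
* 3 Tamura features (coarseness, contrast, directionality),
* 7 noise-level estimators, each reported as a fraction of ``MAX_I``.

Directions follow the row/column convention
0 deg = (0, +1), 45 deg = (-1, +1), 90 deg = (-1, 0), 135 deg = (-1, -1).
GLCM/GLRLM gray levels are min-max quantized (32 levels by default) so these
features are invariant to adding a constant to the image.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu

from .image import Image2D

__all__ = [
    "DIRECTIONS",
    "quantize",
    "statistical_features",
    "glcm",
    "glcm_features",
    "glrlm",
    "glrlm_features",
    "tamura_features",
    "noise_estimators",
    "feature_bank",
    "feature_names",
]

DIRECTIONS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_GLCM_NAMES = ("SDI", "SDJ", "ASM", "CON", "DIS", "HOM", "ENT", "COR")
_GLRLM_NAMES = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
                "SRLGE", "SRHGE", "LRLGE", "LRHGE")
_STAT_NAMES = ("mean", "sd", "var", "ent", "skewness", "kurtosis",
               "hist_var", "hist_ent", "hist_energy")
_TAMURA_NAMES = ("CRS", "CON", "DIR")
_NOISE_NAMES = ("LAP", "LOG", "GTFLAP", "AJA", "BRUM", "SIJ", "ACF")


def feature_names() -> list[str]:
    """The 95 feature names in bank order."""
    names = list(_STAT_NAMES)
    for d in DIRECTIONS:
        names += [f"{n}_{d}" for n in _GLCM_NAMES]
    for d in DIRECTIONS:
        names += [f"{n}_{d}" for n in _GLRLM_NAMES]
    names += list(_TAMURA_NAMES)
    names += list(_NOISE_NAMES)
    return names


def quantize(img: Image2D, levels: int = 32) -> np.ndarray:
    """Min-max quantize intensities to integer levels ``0 .. levels-1``."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    px = img.pixels
    lo, hi = px.min(), px.max()
    if hi == lo:
        return np.zeros(px.shape, dtype=np.intp)
    q = np.floor((px - lo) / (hi - lo) * levels).astype(np.intp)
    return np.minimum(q, levels - 1)


# ---------------------------------------------------------------- statistical

def statistical_features(img: Image2D, bins: int = 256) -> dict[str, float]:
    """Intensity moments plus gray-level-histogram descriptors.

    ``ent`` is the Shannon entropy of the histogram in nats; ``hist_ent`` is
    the same histogram's entropy in bits.  Kurtosis is non-excess (normal
    distribution -> 3).  Constant images get skewness/kurtosis 0 with a
    warning since the moments are undefined.
    """
    px = img.pixels
    counts, edges = np.histogram(px, bins=bins, range=(0.0, img.max_intensity))
    p = counts / counts.sum()
    nz = p[p > 0]
    centers = (edges[:-1] + edges[1:]) / 2.0

    mean = float(px.mean())
    var = float(px.var())
    sd = float(np.sqrt(var))
    ent_nats = float(-(nz * np.log(nz)).sum())
    ent_bits = float(-(nz * np.log2(nz)).sum())

    mu_h = float((p * centers).sum())
    var_h = float((p * (centers - mu_h) ** 2).sum())
    if sd == 0.0:
        warnings.warn("constant image: skewness and kurtosis undefined, returning 0",
                      RuntimeWarning, stacklevel=2)
        skew = kurt = 0.0
    else:
        sd_h = np.sqrt(var_h) if var_h > 0 else sd
        skew = float((p * (centers - mu_h) ** 3).sum() / sd_h**3)
        kurt = float((p * (centers - mu_h) ** 4).sum() / sd_h**4)
    return {
        "mean": mean, "sd": sd, "var": var, "ent": ent_nats,
        "skewness": skew, "kurtosis": kurt,
        "hist_var": var_h, "hist_ent": ent_bits,
        "hist_energy": float((p**2).sum()),
    }


# ---------------------------------------------------------------------- GLCM

def glcm(img: Image2D, direction: int, levels: int = 32) -> np.ndarray:
    """Normalized symmetric gray-level co-occurrence matrix at distance 1."""
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")
    q = quantize(img, levels)
    dr, dc = DIRECTIONS[direction]
    m, n = q.shape
    r0, r1 = max(0, -dr), min(m, m - dr)
    c0, c1 = max(0, -dc), min(n, n - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    if a.size == 0:
        raise ValueError("image too small for the requested offset")
    counts = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(counts, (a, b), 1.0)
    np.add.at(counts, (b, a), 1.0)  # symmetric accumulation
    return counts / counts.sum()


def glcm_features(matrix: np.ndarray, suffix: str = "") -> dict[str, float]:
    """Eight Haralick-style descriptors of a normalized co-occurrence matrix."""
    p = np.asarray(matrix, dtype=np.float64)
    levels = p.shape[0]
    i = np.arange(levels, dtype=np.float64)[:, None]
    j = np.arange(levels, dtype=np.float64)[None, :]
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    sd_i = float(np.sqrt(((i - mu_i) ** 2 * p).sum()))
    sd_j = float(np.sqrt(((j - mu_j) ** 2 * p).sum()))
    asm = float((p**2).sum())
    con = float(((i - j) ** 2 * p).sum())
    dis = float((np.abs(i - j) * p).sum())
    hom = float((p / (1.0 + (i - j) ** 2)).sum())
    nz = p[p > 0]
    ent = float(-(nz * np.log(nz)).sum())
    if sd_i == 0.0 or sd_j == 0.0:
        warnings.warn("zero-variance GLCM marginal: correlation set to 0",
                      RuntimeWarning, stacklevel=2)
        cor = 0.0
    else:
        cor = float((((i - mu_i) * (j - mu_j) * p).sum()) / (sd_i * sd_j))
    key = (lambda n: f"{n}_{suffix}") if suffix else (lambda n: n)
    return {key("SDI"): sd_i, key("SDJ"): sd_j, key("ASM"): asm, key("CON"): con,
            key("DIS"): dis, key("HOM"): hom, key("ENT"): ent, key("COR"): cor}


# --------------------------------------------------------------------- GLRLM

def _direction_lines(q: np.ndarray, direction: int) -> list[np.ndarray]:
    m, n = q.shape
    if direction == 0:
        return [q[r] for r in range(m)]
    if direction == 90:
        return [q[:, c] for c in range(n)]
    if direction == 135:  # runs along (-1,-1) <=> main diagonals
        return [np.diagonal(q, k) for k in range(-(m - 1), n)]
    if direction == 45:  # runs along (-1,+1) <=> anti-diagonals
        f = np.flipud(q)
        return [np.diagonal(f, k) for k in range(-(m - 1), n)]
    raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")


def glrlm(img: Image2D, direction: int, levels: int = 32) -> np.ndarray:
    """Run-length matrix ``counts[g, r-1]`` of maximal runs along a direction."""
    q = quantize(img, levels)
    max_run = max(q.shape)
    counts = np.zeros((levels, max_run), dtype=np.float64)
    for line in _direction_lines(q, direction):
        if line.size == 0:
            continue
        change = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [line.size]))
        for s, e in zip(starts, ends):
            counts[line[s], e - s - 1] += 1.0
    return counts


def glrlm_features(matrix: np.ndarray, suffix: str = "") -> dict[str, float]:
    """Eleven Galloway run-length descriptors (gray level indexed from 1)."""
    p = np.asarray(matrix, dtype=np.float64)
    if p.sum() == 0:
        raise ValueError("run-length matrix has no runs")
    g = np.arange(1, p.shape[0] + 1, dtype=np.float64)[:, None]
    r = np.arange(1, p.shape[1] + 1, dtype=np.float64)[None, :]
    n_runs = p.sum()
    n_px = float((p * r).sum())
    key = (lambda n: f"{n}_{suffix}") if suffix else (lambda n: n)
    return {
        key("SRE"): float((p / r**2).sum() / n_runs),
        key("LRE"): float((p * r**2).sum() / n_runs),
        key("GLN"): float((p.sum(axis=1) ** 2).sum() / n_runs),
        key("RLN"): float((p.sum(axis=0) ** 2).sum() / n_runs),
        key("RP"): float(n_runs / n_px),
        key("LGRE"): float((p / g**2).sum() / n_runs),
        key("HGRE"): float((p * g**2).sum() / n_runs),
        key("SRLGE"): float((p / (g**2 * r**2)).sum() / n_runs),
        key("SRHGE"): float((p * g**2 / r**2).sum() / n_runs),
        key("LRLGE"): float((p * r**2 / g**2).sum() / n_runs),
        key("LRHGE"): float((p * g**2 * r**2).sum() / n_runs),
    }


# -------------------------------------------------------------------- Tamura

def _shift(a: np.ndarray, d: int, axis: int) -> np.ndarray:
    """Shift with edge clamping (no wraparound)."""
    pad = [(0, 0), (0, 0)]
    pad[axis] = (max(d, 0), max(-d, 0))
    padded = np.pad(a, pad, mode="edge")
    sl = [slice(None), slice(None)]
    sl[axis] = slice(max(-d, 0), padded.shape[axis] - max(d, 0))
    return padded[tuple(sl)]


def _coarseness(px: np.ndarray, max_scale: int = 5) -> float:
    m, n = px.shape
    # largest usable scale: window 2**k must fit twice along each axis
    kmax = max(1, min(max_scale, int(np.floor(np.log2(max(2, min(m, n) // 2))))))
    stack = []
    for k in range(1, kmax + 1):
        size = 2**k
        avg = ndimage.uniform_filter(px, size=size, mode="nearest")
        half = size // 2
        eh = np.abs(_shift(avg, -half, 1) - _shift(avg, half, 1))
        ev = np.abs(_shift(avg, -half, 0) - _shift(avg, half, 0))
        stack.append(np.maximum(eh, ev))
    es = np.stack(stack)
    # drop the border band polluted by partial windows; ties pick the
    # smallest scale (np.argmax takes the first maximum)
    crop = 2 ** (kmax - 1)
    if m - 2 * crop >= 4 and n - 2 * crop >= 4:
        es = es[:, crop : m - crop, crop : n - crop]
    k_best = np.argmax(es, axis=0) + 1
    return float((2.0**k_best).mean())


def _contrast(px: np.ndarray) -> float:
    sd = px.std()
    if sd == 0:
        return 0.0
    mu4 = np.mean((px - px.mean()) ** 4)
    kurt = mu4 / sd**4
    return float(sd / kurt**0.25)


def _directionality(px: np.ndarray, max_i: float, bins: int = 16,
                    mag_threshold: float = 12.0 / 255.0) -> float:
    dh = ndimage.prewitt(px, axis=1, mode="nearest")
    dv = ndimage.prewitt(px, axis=0, mode="nearest")
    mag = (np.abs(dh) + np.abs(dv)) / 2.0
    theta = np.mod(np.arctan2(dv, dh), np.pi)
    mask = mag > mag_threshold * max_i
    if not mask.any():
        warnings.warn("no significant gradients: directionality set to 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    hist, edges = np.histogram(theta[mask], bins=bins, range=(0.0, np.pi))
    hd = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = centers[np.argmax(hd)]
    # wrapped angular distance to the dominant orientation
    d = np.abs(centers - peak)
    d = np.minimum(d, np.pi - d)
    spread = float((d**2 * hd).sum())
    # pi^2/12 is the spread of a uniform orientation histogram
    return float(np.clip(1.0 - spread / (np.pi**2 / 12.0), 0.0, 1.0))


def tamura_features(img: Image2D) -> dict[str, float]:
    """Tamura coarseness (CRS), contrast (CON) and directionality (DIR)."""
    px = img.pixels
    con = _contrast(px)
    if con == 0.0:
        warnings.warn("constant image: Tamura contrast/directionality set to 0",
                      RuntimeWarning, stacklevel=2)
    return {
        "CRS": _coarseness(px),
        "CON": con,
        "DIR": _directionality(px, img.max_intensity) if con > 0 else 0.0,
    }


# --------------------------------------------------------------------- noise

_LAP_MASK = np.array([[1.0, -2.0, 1.0], [-2.0, 4.0, -2.0], [1.0, -2.0, 1.0]])
_LOG_MASK = np.array([
    [0, 0, 1, 0, 0],
    [0, 1, 2, 1, 0],
    [1, 2, -16, 2, 1],
    [0, 1, 2, 1, 0],
    [0, 0, 1, 0, 0],
], dtype=np.float64)


def _mask_estimate(px: np.ndarray, mask: np.ndarray, keep: np.ndarray | None = None) -> float:
    """Immerkaer-style estimate: sqrt(pi/2) * mean|I * M| / ||M||_2.

    For i.i.d. Gaussian noise the convolution output is Gaussian with
    standard deviation ``sigma * ||M||_2``, whose mean absolute value is
    ``sigma * ||M||_2 * sqrt(2/pi)``; zero-sum masks cancel smooth signal.
    """
    half = mask.shape[0] // 2
    conv = ndimage.convolve(px, mask, mode="nearest")
    interior = conv[half:-half, half:-half]
    if keep is not None:
        keep = keep[half:-half, half:-half]
        interior = interior[keep] if keep.any() else interior
    return float(np.sqrt(np.pi / 2.0) * np.abs(interior).mean() / np.linalg.norm(mask))


def _background_mask(px: np.ndarray) -> np.ndarray:
    try:
        thr = threshold_otsu(px)
    except ValueError:
        thr = px.max()
    mask = px < thr
    if not mask.any() or mask.all():
        warnings.warn("background segmentation failed: using whole image",
                      RuntimeWarning, stacklevel=3)
        return np.ones(px.shape, dtype=bool)
    return mask


def noise_estimators(img: Image2D) -> dict[str, float]:
    """Seven scalar noise-level estimates, each as a fraction of ``MAX_I``.

    LAP/LOG are zero-sum convolution-mask estimators; GTFLAP repeats the
    Laplacian scheme restricted to low-gradient pixels (an edge-suppressing
    transfer correction); AJA takes the background mode of the local-means
    distribution; BRUM least-squares-fits a Rayleigh curve to the background
    histogram; SIJ is the Rayleigh maximum-likelihood fit on background
    pixels; ACF subtracts the smooth autocorrelation neighborhood from the
    zero-lag peak.
    """
    px = img.pixels
    max_i = img.max_intensity

    lap = _mask_estimate(px, _LAP_MASK) / max_i
    log_est = _mask_estimate(px, _LOG_MASK) / max_i

    gx = ndimage.sobel(px, axis=1, mode="nearest")
    gy = ndimage.sobel(px, axis=0, mode="nearest")
    grad = np.hypot(gx, gy)
    flat = grad <= np.percentile(grad, 90.0)
    gtflap = _mask_estimate(px, _LAP_MASK, keep=flat) / max_i

    background = _background_mask(px)
    bg = px[background]

    # AJA: the local-mean distribution peaks near sigma*sqrt(pi/2) over a
    # Rayleigh background
    local_mean = ndimage.uniform_filter(px, size=3, mode="nearest")
    lm_bg = local_mean[background]
    counts, edges = np.histogram(lm_bg, bins=100)
    mode = (edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2.0
    aja = float(mode * np.sqrt(2.0 / np.pi)) / max_i

    # SIJ: Rayleigh ML estimate sigma = sqrt(E[x^2] / 2).  The Otsu background
    # class can still contain dark tissue; if it is clearly bimodal (upper
    # cluster mean >> lower cluster mean) split it once more and keep the
    # darker cluster, which is the air region where the Rayleigh model holds.
    sij_px = bg
    try:
        t2 = threshold_otsu(bg)
        lower, upper = bg[bg < t2], bg[bg >= t2]
        if lower.size and upper.size and upper.mean() > 3.0 * max(lower.mean(), 1e-12 * max_i):
            sij_px = lower
    except ValueError:
        pass
    sij_sigma = float(np.sqrt(np.mean(sij_px**2) / 2.0))
    sij = sij_sigma / max_i

    # BRUM: least-squares Rayleigh fit to the background histogram, restricted
    # to the bulk around the noise peak so residual tissue structure in the
    # "background" class cannot skew the fit
    counts0, edges0 = np.histogram(bg, bins=64)
    peak = (edges0[np.argmax(counts0)] + edges0[np.argmax(counts0) + 1]) / 2.0
    upper = max(3.5 * peak, 6.0 * edges0[1])  # at least a few bins wide
    counts, edges = np.histogram(bg[bg <= upper], bins=48, density=True)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def rayleigh(x, a, s):
        return a * x / s**2 * np.exp(-(x**2) / (2.0 * s**2))

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(rayleigh, centers, counts,
                                p0=(1.0, max(sij_sigma, 1e-6 * max_i)),
                                bounds=([0.0, 1e-9 * max_i], [np.inf, max_i]),
                                maxfev=2000)
        brum = float(popt[1]) / max_i
    except (RuntimeError, ValueError):
        warnings.warn("Rayleigh histogram fit failed: falling back to ML estimate",
                      RuntimeWarning, stacklevel=2)
        brum = sij

    # ACF: zero-lag autocorrelation minus its immediate (smooth) neighborhood
    x = px - px.mean()
    spec = np.abs(np.fft.fft2(x)) ** 2
    acf = np.fft.ifft2(spec).real / x.size
    neighborhood = np.mean([acf[0, 1], acf[1, 0], acf[1, 1], acf[-1, 1]])
    acf_est = float(np.sqrt(max(acf[0, 0] - neighborhood, 0.0))) / max_i

    return {"LAP": lap, "LOG": log_est, "GTFLAP": gtflap, "AJA": aja,
            "BRUM": brum, "SIJ": sij, "ACF": acf_est}


# ---------------------------------------------------------------- full bank

def feature_bank(img: Image2D, levels: int = 32, subset: list[str] | None = None) -> dict[str, float]:
    """Compute the named feature vector (all 95 features, or a subset).

    When ``subset`` is given, only the feature groups needed to cover it are
    computed (run-length and noise groups are by far the cheapest).
    """
    wanted = set(subset) if subset is not None else None

    def needed(names) -> bool:
        return wanted is None or any(n in wanted for n in names)

    out: dict[str, float] = {}
    if needed(_STAT_NAMES):
        out.update(statistical_features(img))
    for d in DIRECTIONS:
        if needed([f"{n}_{d}" for n in _GLCM_NAMES]):
            out.update(glcm_features(glcm(img, d, levels), suffix=str(d)))
    for d in DIRECTIONS:
        if needed([f"{n}_{d}" for n in _GLRLM_NAMES]):
            out.update(glrlm_features(glrlm(img, d, levels), suffix=str(d)))
    if needed(_TAMURA_NAMES):
        out.update(tamura_features(img))
    if needed(_NOISE_NAMES):
        out.update(noise_estimators(img))
    if wanted is not None:
        missing = wanted - out.keys()
        if missing:
            raise KeyError(f"unknown feature names: {sorted(missing)}")
        return {k: out[k] for k in subset}
    return {k: out[k] for k in feature_names()}
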