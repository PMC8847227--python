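"""Plant/background segmentation via contrast-optimized band differences.

A flat tray gives no spectral contrast problem in principle, but uneven
illumination defeats plain global thresholding of any single band.  A
normalized band difference (NBD) image,

    I = (R@l1 - R@l2) / (R@l1 + R@l2),      l1 > l2,

cancels multiplicative illumination pixel-wise and, for a well chosen band
pair (NIR vs. blue for vegetation), is strongly bimodal: background near 0,
plant pixels near +0.8.  The pair is chosen by exhaustively scoring every
ordered pair with the Otsu contrast criterion (between-class variance over
total variance) on one calibration cube, then reused batch-wide.  The global
threshold on the NBD image comes from intermodes thresholding: smooth the
histogram with a three-point window until it is bimodal, then take the
midpoint of the two peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, disk, opening

from .io import HyperspectralCube

__all__ = [
    "BandPair",
    "NBDImage",
    "ContrastScore",
    "SegmentationConfig",
    "SegmentationResult",
    "ReferenceRegion",
    "make_band_pair",
    "compute_nbd",
    "otsu_contrast",
    "select_band_pair",
    "intermode_threshold",
    "segment_scene",
    "locate_reference",
]


@dataclass(frozen=True)
class BandPair:
    """An ordered wavelength pair (lambda1 > lambda2) with cube band indices."""

    lambda1: float
    lambda2: float
    index1: int
    index2: int

    def __post_init__(self) -> None:
        if not self.lambda1 > self.lambda2:
            raise ValueError(
                f"band pair requires lambda1 > lambda2, got {self.lambda1} <= {self.lambda2}"
            )


def make_band_pair(cube: HyperspectralCube, lambda1: float, lambda2: float) -> BandPair:
    """Resolve nominal wavelengths to the cube's nearest bands."""
    i1, i2 = cube.band_index(lambda1), cube.band_index(lambda2)
    return BandPair(
        lambda1=float(cube.wavelengths[i1]),
        lambda2=float(cube.wavelengths[i2]),
        index1=i1,
        index2=i2,
    )


@dataclass
class NBDImage:
    """Per-pixel normalized band difference; NaN where the denominator ~ 0."""

    values: np.ndarray
    defined: np.ndarray
    pair: BandPair
    eps: float

    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]


@dataclass(frozen=True)
class ContrastScore:
    """Otsu-style contrast: threshold and between/total variance ratio."""

    threshold: float
    score: float


def compute_nbd(
    cube: HyperspectralCube, pair: BandPair, eps: float | None = None
) -> NBDImage:
    """(R1 - R2)/(R1 + R2) per pixel, undefined where R1 + R2 <= eps.

    ``eps`` defaults to 1e-6 of the cube's dynamic range.  Defined values lie
    in [-1, 1] for any non-negative cube.
    """
    r1 = cube.values[:, :, pair.index1]
    r2 = cube.values[:, :, pair.index2]
    if eps is None:
        eps = 1e-6 * float(cube.values.max() - cube.values.min())
    denom = r1 + r2
    defined = denom > eps
    values = np.full(denom.shape, np.nan)
    np.divide(r1 - r2, denom, out=values, where=defined)
    return NBDImage(values=values, defined=defined, pair=pair, eps=float(eps))


def _otsu_scan(values: np.ndarray, n_candidates: int = 256):
    """Exact between/total variance ratio at each candidate threshold.

    Candidates are the ``n_candidates`` bin centers of a uniform grid over the
    observed range; class statistics are computed from the actual values (not
    bin approximations), so a brute-force per-candidate loop gives identical
    numbers.
    """
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    v = v[np.isfinite(v)]
    if v.size < 2 or v[0] == v[-1]:
        raise ValueError("otsu contrast needs >= 2 distinct defined values")
    lo, hi = v[0], v[-1]
    edges = np.linspace(lo, hi, n_candidates + 1)
    candidates = 0.5 * (edges[:-1] + edges[1:])

    n = v.size
    csum = np.cumsum(v)
    total_mean = csum[-1] / n
    total_var = np.mean((v - total_mean) ** 2)

    # n0[k] = count of values <= candidate k
    n0 = np.searchsorted(v, candidates, side="right")
    valid = (n0 > 0) & (n0 < n)
    n0v = n0[valid]
    mean0 = csum[n0v - 1] / n0v
    mean1 = (csum[-1] - csum[n0v - 1]) / (n - n0v)
    w0 = n0v / n
    between = w0 * (1 - w0) * (mean0 - mean1) ** 2
    scores = np.full(candidates.shape, -np.inf)
    scores[valid] = between / total_var
    return candidates, scores


def otsu_contrast(values: np.ndarray, n_candidates: int = 256) -> ContrastScore:
    """Best Otsu contrast over a uniform candidate grid.

    Returns the candidate threshold maximizing between-class variance and the
    contrast score (between-class variance / total variance, in [0, 1]).  Ties
    go to the lowest candidate.  A constant input has no defined contrast and
    raises ``ValueError``.
    """
    candidates, scores = _otsu_scan(values, n_candidates)
    k = int(np.argmax(scores))
    return ContrastScore(threshold=float(candidates[k]), score=float(min(scores[k], 1.0)))


def select_band_pair(
    cube: HyperspectralCube,
    stride: int = 1,
    eps: float | None = None,
    n_candidates: int = 256,
) -> tuple[BandPair, ContrastScore, np.ndarray]:
    """Contrast-optimal NBD pair by exhaustive search over a strided band grid.

    Every ordered pair (l1 > l2) on the grid is scored by
    ``otsu_contrast(compute_nbd(cube, pair))``; the argmax pair is returned
    with its score and the full score matrix (rows = l1 index on the grid,
    cols = l2 index; NaN where invalid).  Ties are broken toward larger l1,
    then smaller l2.  Intended to run once on a calibration cube; the chosen
    pair is then reused on all cubes of the batch.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    grid = np.arange(0, cube.n_bands, stride)
    if len(grid) < 2:
        raise ValueError("fewer than 2 bands after striding")
    if eps is None:
        eps = 1e-6 * float(cube.values.max() - cube.values.min())

    flat = cube.values.reshape(-1, cube.n_bands)
    ngrid = len(grid)
    score_matrix = np.full((ngrid, ngrid), np.nan)
    best = None  # (score, lambda1, -lambda2, pair, contrast)
    for a in range(ngrid):  # a indexes lambda1 (higher)
        i1 = grid[a]
        r1 = flat[:, i1]
        for b in range(a):  # b indexes lambda2 (lower)
            i2 = grid[b]
            r2 = flat[:, i2]
            denom = r1 + r2
            defined = denom > eps
            if defined.sum() < 2:
                continue
            nbd = (r1[defined] - r2[defined]) / denom[defined]
            try:
                contrast = otsu_contrast(nbd, n_candidates)
            except ValueError:
                continue
            score_matrix[a, b] = contrast.score
            key = (
                contrast.score,
                cube.wavelengths[i1],
                -cube.wavelengths[i2],
            )
            if best is None or key > best[0]:
                pair = BandPair(
                    lambda1=float(cube.wavelengths[i1]),
                    lambda2=float(cube.wavelengths[i2]),
                    index1=int(i1),
                    index2=int(i2),
                )
                best = (key, pair, contrast)
    if best is None:
        raise ValueError("no valid band pair found (degenerate cube)")
    return best[1], best[2], score_matrix


# ---------------------------------------------------------------------------
# Intermodes thresholding
# ---------------------------------------------------------------------------


def _histogram_peaks(hist: np.ndarray) -> list[float]:
    """Positions (bin indices, plateau midpoints) of strict local maxima.

    Runs of equal counts are collapsed to a single value before comparison;
    outside the histogram counts are treated as -inf, so a monotone edge run
    counts as a peak.
    """
    runs = []  # (value, start, end)
    start = 0
    for i in range(1, len(hist) + 1):
        if i == len(hist) or hist[i] != hist[start]:
            runs.append((hist[start], start, i - 1))
            start = i
    peaks = []
    for r, (val, s, e) in enumerate(runs):
        left = runs[r - 1][0] if r > 0 else -np.inf
        right = runs[r + 1][0] if r < len(runs) - 1 else -np.inf
        if val > left and val > right:
            peaks.append(0.5 * (s + e))
    return peaks


def _smooth3(hist: np.ndarray) -> np.ndarray:
    """Three-point moving average with edge replication."""
    padded = np.concatenate([hist[:1], hist, hist[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def intermode_threshold(
    values: np.ndarray, bins: int = 256, max_iter: int = 10000
) -> tuple[float, int, np.ndarray]:
    """Intermodes threshold of a value distribution.

    The histogram (``bins`` uniform bins over the observed range) is smoothed
    repeatedly with a three-point moving average until it has exactly two
    (plateau-collapsed) local maxima; the threshold is the midpoint of the two
    peak bin centers.  Returns (threshold, smoothing iterations performed,
    final histogram).

    Raises ``ValueError`` for constant input and ``RuntimeError`` if
    bimodality is not reached within ``max_iter`` iterations (e.g. the
    histogram collapses to a single mode first).
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    v = v[np.isfinite(v)]
    if v.size < 2 or v.min() == v.max():
        raise ValueError("intermodes threshold needs >= 2 distinct values")
    hist, edges = np.histogram(v, bins=bins, range=(v.min(), v.max()))
    hist = hist.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    iterations = 0
    while True:
        peaks = _histogram_peaks(hist)
        if len(peaks) == 2:
            break
        if len(peaks) < 2:
            raise RuntimeError(
                "histogram became unimodal before reaching bimodality; "
                "the value distribution has no two-mode structure"
            )
        if iterations >= max_iter:
            raise RuntimeError(f"histogram not bimodal after {max_iter} smoothings")
        hist = _smooth3(hist)
        iterations += 1

    pos = [edges[0] + width * (p + 0.5) for p in peaks]
    threshold = 0.5 * (pos[0] + pos[1])
    return float(threshold), iterations, hist


# ---------------------------------------------------------------------------
# Scene segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SegmentationConfig:
    bins: int = 256
    max_iter: int = 10000
    min_area: int = 50
    morphology_radius: int = 1


@dataclass
class SegmentationResult:
    pair: BandPair
    nbd: NBDImage
    threshold: float
    smoothing_iterations: int
    mask: np.ndarray
    regions: np.ndarray
    region_table: "object"  # pandas DataFrame: region_id, area, bbox
    reference_region: "ReferenceRegion | None" = None


@dataclass
class ReferenceRegion:
    """Located reference panel: pixel mask, source region id (if any), CV."""

    mask: np.ndarray
    region_id: int | None
    cv: float | None


def segment_scene(
    cube: HyperspectralCube,
    pair: BandPair,
    config: SegmentationConfig = SegmentationConfig(),
) -> SegmentationResult:
    """Segment plant material from the background of one cube.

    Pipeline: NBD image -> intermodes threshold (foreground = upper mode,
    i.e. NBD above threshold; undefined pixels are background) -> binary
    opening then closing with a disk structuring element -> 8-connected
    components below ``min_area`` removed -> regions labeled in raster order
    of their first pixel.
    """
    import pandas as pd

    nbd = compute_nbd(cube, pair)
    threshold, iterations, _ = intermode_threshold(
        nbd.defined_values(), bins=config.bins, max_iter=config.max_iter
    )
    mask = np.zeros(nbd.values.shape, dtype=bool)
    mask[nbd.defined] = nbd.values[nbd.defined] > threshold

    if config.morphology_radius > 0:
        selem = disk(config.morphology_radius)
        mask = closing(opening(mask, selem), selem)

    labels = cc_label(mask, connectivity=2)
    records = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for prop in regionprops(labels):
        if prop.area >= config.min_area:
            keep[prop.label] = True
    labels[~keep[labels]] = 0
    mask = labels > 0

    # Relabel 1..n in raster order of each region's first pixel.
    old_ids = []
    seen = set()
    for lab in labels.ravel():
        if lab != 0 and lab not in seen:
            seen.add(lab)
            old_ids.append(lab)
    remap = np.zeros(labels.max() + 1, dtype=np.int64)
    for new, old in enumerate(old_ids, start=1):
        remap[old] = new
    labels = remap[labels]

    for prop in regionprops(labels):
        records.append(
            {
                "region_id": int(prop.label),
                "area": int(prop.area),
                "bbox": tuple(int(b) for b in prop.bbox),
            }
        )
    if not records:
        warnings.warn("segmentation produced an empty foreground", stacklevel=2)
    table = pd.DataFrame(records, columns=["region_id", "area", "bbox"])
    return SegmentationResult(
        pair=pair,
        nbd=nbd,
        threshold=threshold,
        smoothing_iterations=iterations,
        mask=mask,
        regions=labels,
        region_table=table,
    )


def locate_reference(
    cube: HyperspectralCube,
    result: SegmentationResult,
    mode: str = "flatness",
    roi_rect: tuple | None = None,
    flatness_cutoff: float = 0.30,
    min_area: int = 50,
) -> ReferenceRegion | None:
    """Locate the in-frame reference panel.

    ``roi`` mode takes a configured rectangle (line0, pixel0, height, width)
    intersected with the image.  ``flatness`` mode segments bright pixels on
    the mean-over-bands image (a spectrally flat panel produces no NBD
    contrast, so it is invisible to the NBD mask by construction) and picks
    the candidate region whose mean spectrum has the lowest coefficient of
    variation, required to be below ``flatness_cutoff``; vegetation is never
    that flat.  Returns None when no candidate qualifies.
    """
    nl, npx = cube.n_lines, cube.n_pixels
    if mode == "roi":
        if roi_rect is None:
            raise ValueError("roi mode requires roi_rect")
        l0, p0, h, w = roi_rect
        if l0 >= nl or p0 >= npx or l0 + h <= 0 or p0 + w <= 0:
            raise ValueError("roi rectangle lies outside the image")
        mask = np.zeros((nl, npx), dtype=bool)
        mask[max(l0, 0) : min(l0 + h, nl), max(p0, 0) : min(p0 + w, npx)] = True
        spec = cube.values[mask].mean(axis=0)
        cv = float(np.std(spec) / np.mean(spec)) if np.mean(spec) > 0 else None
        ref = ReferenceRegion(mask=mask, region_id=None, cv=cv)
        result.reference_region = ref
        return ref

    if mode != "flatness":
        raise ValueError(f"unknown reference localization mode {mode!r}")

    brightness = cube.values.mean(axis=2)
    try:
        contrast = otsu_contrast(brightness)
    except ValueError:
        return None
    bright = brightness > contrast.threshold
    labels = cc_label(bright, connectivity=2)
    best: ReferenceRegion | None = None
    for prop in regionprops(labels):
        if prop.area < min_area:
            continue
        mask = labels == prop.label
        spec = cube.values[mask].mean(axis=0)
        mu = float(np.mean(spec))
        if mu <= 0:
            continue
        cv = float(np.std(spec) / mu)
        if cv < flatness_cutoff and (best is None or cv < best.cv):
            best = ReferenceRegion(mask=mask, region_id=int(prop.label), cv=cv)
    result.reference_region = best
    return best
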