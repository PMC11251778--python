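"""Receptor-noise-limited (RNL) observer model.

Cone-catch images are viewed through a model visual system (here parameterised
for the triggerfish *Rhinecanthus aculeatus*): chromatic discriminability is
computed with the trichromatic RNL model in ΔS units, luminance discriminability
from the double-cone channel in ΔL units, spatial resolution is imposed by an
acuity/viewing-distance blur, local noise is removed with an RNL ranked filter,
and the image is segmented into perceptually distinct pattern elements by
agglomerative RNL clustering.

Channel order everywhere is (sw, mw, lw, dbl); the double cone (index 3) is the
luminance channel, the first three channels carry chromatic information.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

CHANNELS = ("sw", "mw", "lw", "dbl")
MIN_MASK_PIXELS = 9


class InvalidParameterError(ValueError):
    pass


class InvalidInputError(ValueError):
    pass


@dataclass
class ConeCatchImage:
    """A 4-channel cone-catch image with a region-of-interest mask.

    catches : (H, W, 4) float array, non-negative inside the mask
    mask    : (H, W) boolean region of interest (>= 9 pixels)
    px_per_mm : image scale
    id      : identifier carried through the pipeline
    """

    catches: np.ndarray
    mask: np.ndarray
    px_per_mm: float
    id: str = ""

    def __post_init__(self):
        self.catches = np.asarray(self.catches, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.catches.ndim != 3 or self.catches.shape[2] != 4:
            raise InvalidInputError("catches must be an (H, W, 4) array")
        if self.mask.shape != self.catches.shape[:2]:
            raise InvalidInputError("mask shape does not match image")
        if self.mask.sum() < MIN_MASK_PIXELS:
            raise InvalidInputError(
                f"mask has {int(self.mask.sum())} pixels; at least "
                f"{MIN_MASK_PIXELS} are required"
            )
        if not float(self.px_per_mm) > 0:
            raise InvalidParameterError("px_per_mm must be positive")
        if np.any(self.catches[self.mask] < 0):
            raise InvalidInputError("negative cone catches inside the mask")

    @property
    def shape(self):
        return self.mask.shape

    def require_positive(self):
        if np.any(self.catches[self.mask] <= 0):
            raise InvalidInputError(
                "zero cone catch inside the mask: RNL distances need strictly "
                "positive catches (no silent epsilon is applied)"
            )


def weber_fractions(abundances, noise):
    """Per-channel Weber fractions from relative cone abundances and noise.

    omega_i = noise * sqrt(max(abundances) / abundances_i), so the most
    abundant channel has omega == noise. Scale-invariant in the abundances.
    """
    ab = np.asarray(abundances, dtype=float)
    if np.any(ab <= 0) or not float(noise) > 0:
        raise InvalidParameterError("abundances and noise must be positive")
    return float(noise) * np.sqrt(ab.max() / ab)


@dataclass
class VisualSystem:
    """Observer parameters: cone ratios, channel noise, acuity and thresholds.

    Defaults are the triggerfish parameterisation used throughout the
    pipeline: cone abundances 1:2:2:2 (sw:mw:lw:dbl), single-receptor noise
    0.05 (giving Weber fractions 0.07:0.05:0.05:0.05), spatial acuity
    3 cycles/degree, chromatic merge threshold 2 ΔS and luminance merge
    threshold 4 ΔL.
    """

    abundances: tuple = (1.0, 2.0, 2.0, 2.0)
    noise: float = 0.05
    acuity_cpd: float = 3.0
    chrom_threshold: float = 2.0
    lum_threshold: float = 4.0
    webers: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if not self.acuity_cpd > 0:
            raise InvalidParameterError("acuity_cpd must be positive")
        if not (self.chrom_threshold > 0 and self.lum_threshold > 0):
            raise InvalidParameterError("thresholds must be positive")
        self.webers = weber_fractions(self.abundances, self.noise)

    @property
    def chrom_webers(self):
        return self.webers[:3]

    @property
    def lum_weber(self):
        return float(self.webers[3])


def _check_positive_catches(*qs):
    for q in qs:
        if np.any(np.asarray(q, dtype=float) <= 0):
            raise InvalidInputError("cone catches must be strictly positive")


def chromatic_delta_s(qA, qB, webers):
    """Chromatic RNL distance ΔS between two trichromatic catch triplets.

    ΔS² = [ω1²(Δf3−Δf2)² + ω2²(Δf3−Δf1)² + ω3²(Δf2−Δf1)²]
          / [(ω1ω2)² + (ω1ω3)² + (ω2ω3)²],   Δf_i = ln(qA_i / qB_i)

    Symmetric, zero iff all channel ratios are equal, invariant to common
    rescaling of both stimuli.
    """
    qA = np.asarray(qA, dtype=float)
    qB = np.asarray(qB, dtype=float)
    _check_positive_catches(qA, qB)
    w1, w2, w3 = np.asarray(webers, dtype=float)
    df = np.log(qA / qB)
    f1, f2, f3 = df[..., 0], df[..., 1], df[..., 2]
    num = (w1 * (f3 - f2)) ** 2 + (w2 * (f3 - f1)) ** 2 + (w3 * (f2 - f1)) ** 2
    den = (w1 * w2) ** 2 + (w1 * w3) ** 2 + (w2 * w3) ** 2
    return np.sqrt(num / den)


def luminance_delta(qA_dbl, qB_dbl, w_dbl):
    """Luminance RNL distance ΔL = |ln(qA/qB)| / ω for the double-cone channel."""
    qA = np.asarray(qA_dbl, dtype=float)
    qB = np.asarray(qB_dbl, dtype=float)
    _check_positive_catches(qA, qB)
    return np.abs(np.log(qA / qB)) / float(w_dbl)


# ---------------------------------------------------------------------------
# vectorised helpers on log catches (internal; assume positivity pre-checked)

def _delta_s_from_logdiff(df3, webers3):
    w1, w2, w3 = webers3
    f1, f2, f3 = df3[..., 0], df3[..., 1], df3[..., 2]
    num = (w1 * (f3 - f2)) ** 2 + (w2 * (f3 - f1)) ** 2 + (w3 * (f2 - f1)) ** 2
    den = (w1 * w2) ** 2 + (w1 * w3) ** 2 + (w2 * w3) ** 2
    return np.sqrt(num / den)


# ---------------------------------------------------------------------------
# acuity blur

def resolvable_extent_mm(acuity_cpd, distance_mm):
    """Spatial extent subtended by the minimum resolvable angle at a distance.

    MRA = 1/acuity degrees; extent = 2 * d * tan(MRA / 2).
    """
    mra_deg = 1.0 / acuity_cpd
    return 2.0 * distance_mm * math.tan(math.radians(mra_deg / 2.0))


def acuity_blur(img: ConeCatchImage, acuity_cpd: float, distance_mm: float) -> ConeCatchImage:
    """Low-pass filter each channel to the observer's acuity at a viewing distance.

    An isotropic Gaussian with sigma_px = extent_mm * px_per_mm / 2 is applied
    with mask-normalised convolution so values outside the region of interest
    never bleed in. If the kernel would be narrower than a quarter pixel the
    image is already beyond acuity and is passed through with a warning.
    """
    if not distance_mm > 0:
        raise InvalidParameterError("distance_mm must be positive")
    s_mm = resolvable_extent_mm(acuity_cpd, distance_mm)
    sigma_px = s_mm * img.px_per_mm / 2.0
    if sigma_px < 0.25:
        logger.warning(
            "acuity blur sigma %.3f px < 0.25 px; image %s passed through",
            sigma_px, img.id,
        )
        return replace(img, catches=img.catches.copy())
    m = img.mask.astype(float)
    sm = ndimage.gaussian_filter(m, sigma_px)
    out = img.catches.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        for c in range(4):
            ch = ndimage.gaussian_filter(img.catches[:, :, c] * m, sigma_px)
            blurred = ch / sm
            out[:, :, c] = np.where(img.mask, blurred, img.catches[:, :, c])
    return replace(img, catches=out)


# ---------------------------------------------------------------------------
# RNL ranked filter

def _disk_offsets(radius):
    offs = []
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dy == 0 and dx == 0:
                continue
            if dy * dy + dx * dx <= radius * radius:
                offs.append((dy, dx))
    return offs


def rnl_ranked_filter(img: ConeCatchImage, vs: VisualSystem,
                      falloff: int = 3, radius: int = 5,
                      repetitions: int = 5) -> ConeCatchImage:
    """Noise-removing ranked filter driven by perceptual distance.

    Per repetition every in-mask pixel is replaced by a weighted mean of the
    in-mask pixels within a circular neighbourhood; neighbours (including the
    centre) are ranked by their combined RNL distance sqrt(ΔS² + ΔL²) to the
    centre pixel, nearest rank first, and weighted rank**(-falloff). Pixels at
    the mask boundary use whatever neighbourhood is available.
    """
    if radius < 1 or repetitions < 1:
        raise InvalidParameterError("radius and repetitions must be >= 1")
    img.require_positive()
    H, W = img.shape
    mask = img.mask
    ys, xs = np.nonzero(mask)
    npx = len(ys)
    offsets = [(0, 0)] + _disk_offsets(radius)
    noff = len(offsets)
    wch = vs.chrom_webers
    wl = vs.lum_weber

    catches = img.catches.copy()
    for _ in range(repetitions):
        logc = np.log(np.where(mask[:, :, None], catches, 1.0))
        # neighbour log-catches per offset: (npx, noff, 4); invalid -> nan
        nb = np.full((npx, noff, 4), np.nan)
        valid = np.zeros((npx, noff), dtype=bool)
        for k, (dy, dx) in enumerate(offsets):
            yy, xx = ys + dy, xs + dx
            ok = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
            ok[ok] &= mask[yy[ok], xx[ok]]
            nb[ok, k, :] = logc[yy[ok], xx[ok], :]
            valid[:, k] = ok
        centre = logc[ys, xs, :][:, None, :]
        df = centre - nb
        ds = _delta_s_from_logdiff(df[:, :, :3], wch)
        dl = np.abs(df[:, :, 3]) / wl
        dist = np.sqrt(ds * ds + dl * dl)
        dist[~valid] = np.inf
        order = np.argsort(dist, axis=1, kind="stable")
        ranks = np.empty_like(order)
        np.put_along_axis(ranks, order, np.arange(1, noff + 1)[None, :].repeat(npx, 0), axis=1)
        wts = ranks.astype(float) ** (-float(falloff))
        wts[~valid] = 0.0
        wts /= wts.sum(axis=1, keepdims=True)
        vals = np.exp(nb)
        vals[~valid] = 0.0
        new = np.einsum("nk,nkc->nc", wts, vals)
        catches[ys, xs, :] = new
    return replace(img, catches=catches)


# ---------------------------------------------------------------------------
# RNL clustering

@dataclass
class ClusteredPattern:
    """Perceptual segmentation of a cone-catch image.

    labels : (H, W) int map, 0 outside the ROI, clusters numbered 1..K
    cluster_catches : (K, 4) mean catches per cluster
    cluster_abundance : (K,) pixel-count proportions (sum to 1)
    px_per_mm : carried from the source image
    """

    labels: np.ndarray
    cluster_catches: np.ndarray
    cluster_abundance: np.ndarray
    px_per_mm: float

    @property
    def K(self):
        return len(self.cluster_abundance)


def _pair_dists(mi, mj, wch, wl):
    df = np.log(mi[:3] / mj[:3])
    ds = math.sqrt(
        ((wch[0] * (df[2] - df[1])) ** 2
         + (wch[1] * (df[2] - df[0])) ** 2
         + (wch[2] * (df[1] - df[0])) ** 2)
        / ((wch[0] * wch[1]) ** 2 + (wch[0] * wch[2]) ** 2 + (wch[1] * wch[2]) ** 2)
    )
    dl = abs(math.log(mi[3] / mj[3])) / wl
    return ds, dl


def rnl_cluster(img: ConeCatchImage, vs: VisualSystem) -> ClusteredPattern:
    """Segment an image into perceptually distinct elements.

    Agglomerative merging on the 4-connected region adjacency graph: every
    in-mask pixel starts as its own region; the adjacent pair with the
    smallest normalised combined distance max(ΔS/chrom_thr, ΔL/lum_thr) is
    merged whenever BOTH ΔS < chrom_threshold AND ΔL < lum_threshold (between
    region mean catches), means are updated, and merging stops when no
    adjacent pair qualifies. Ties break on the lower (label_i, label_j) pair.

    The image is expected to have been acuity-blurred and ranked-filtered
    first (not enforced).
    """
    img.require_positive()
    if img.mask.sum() == 0:
        raise InvalidInputError("empty mask")
    H, W = img.shape
    mask = img.mask
    wch = tuple(vs.chrom_webers)
    wl = vs.lum_weber
    cth, lth = vs.chrom_threshold, vs.lum_threshold

    idx = -np.ones((H, W), dtype=int)
    ys, xs = np.nonzero(mask)
    idx[ys, xs] = np.arange(len(ys))
    n = len(ys)
    sums = img.catches[ys, xs, :].astype(float).copy()
    counts = np.ones(n)
    parent = np.arange(n)
    version = np.zeros(n, dtype=np.int64)
    neighbors = [set() for _ in range(n)]
    for dy, dx in ((0, 1), (1, 0)):
        yy, xx = ys + dy, xs + dx
        ok = (yy < H) & (xx < W)
        ok[ok] &= mask[yy[ok], xx[ok]]
        for a, b in zip(idx[ys[ok], xs[ok]], idx[yy[ok], xx[ok]]):
            neighbors[a].add(int(b))
            neighbors[b].add(int(a))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def edge_entry(a, b):
        if a > b:
            a, b = b, a
        ma = sums[a] / counts[a]
        mb = sums[b] / counts[b]
        ds, dl = _pair_dists(ma, mb, wch, wl)
        if ds < cth and dl < lth:
            pr = max(ds / cth, dl / lth)
            return (pr, a, b, version[a], version[b])
        return None

    heap = []
    seen = set()
    for a in range(n):
        for b in neighbors[a]:
            if a < b:
                e = edge_entry(a, b)
                if e is not None:
                    heap.append(e)
    heapq.heapify(heap)

    while heap:
        pr, a, b, va, vb = heapq.heappop(heap)
        if parent[a] != a or parent[b] != b:
            continue
        if version[a] != va or version[b] != vb:
            continue
        if b not in neighbors[a]:
            continue
        # merge b into a (a < b by construction)
        parent[b] = a
        sums[a] += sums[b]
        counts[a] += counts[b]
        version[a] += 1
        neighbors[a].discard(b)
        for c in neighbors[b]:
            if c == a:
                continue
            neighbors[c].discard(b)
            neighbors[c].add(a)
            neighbors[a].add(c)
        neighbors[b] = set()
        for c in neighbors[a]:
            e = edge_entry(a, c)
            if e is not None:
                heapq.heappush(heap, e)

    roots = np.array([find(i) for i in range(n)])
    uniq, relabel = np.unique(roots, return_inverse=True)
    labels = np.zeros((H, W), dtype=int)
    labels[ys, xs] = relabel + 1
    K = len(uniq)
    cl_catch = np.stack([sums[r] / counts[r] for r in uniq])
    cl_ab = np.array([counts[r] for r in uniq], dtype=float)
    cl_ab /= cl_ab.sum()
    return ClusteredPattern(labels, cl_catch, cl_ab, img.px_per_mm)
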