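"""Spatiochromatic colour-pattern statistics (QCPA families).

Four statistic families are computed per individual per viewing distance and
assembled into a fixed 157-name vector:

* CAA  (colour adjacency analysis, 33 statistics) — pattern geometry from the
  transition matrix of a segmented image: element number, transition
  diversity/evenness, boundary density, aspect ratio, element size.
* VCA  (visual contrast analysis, 58) — pattern boldness from chromatic (ΔS),
  RNL luminance (ΔL) and Weber luminance contrasts between pattern elements,
  weighted by element abundance or boundary share.
* BSA  (boundary strength analysis, 42) — contrast distributions over boundary
  types, weighted by boundary-length fractions.
* LEIA (local edge intensity analysis, 24) — moments of the 1-px edge-contrast
  histograms of the unclustered (ranked-filtered) image.

Directional ``.Hrz``/``.Vrt`` variants use the horizontal / vertical transition
matrices only (vertical = along the body axis; animals are aligned head-up).
Statistics that need at least two pattern elements are NaN on single-element
patterns; NaNs are emitted, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np

from .vision import (ClusteredPattern, ConeCatchImage, InvalidInputError,
                     VisualSystem, _delta_s_from_logdiff, acuity_blur,
                     chromatic_delta_s, luminance_delta, rnl_cluster,
                     rnl_ranked_filter)

ORIENTS = ("", ".Hrz", ".Vrt")
_ORIENT_KEY = {"": "full", ".Hrz": "hrz", ".Vrt": "vrt"}


# ---------------------------------------------------------------------------
# registry

def _registry():
    names = []
    # CAA: 3 global + 10 per-matrix stats x 3 orientations = 33
    names += ["CAA.Sc", "CAA.Asp", "CAA.A"]
    for stat in ("C", "Qc", "Qt", "Pt", "St", "Jc", "Jt", "B", "Rt", "Td"):
        for o in ORIENTS:
            names.append(f"CAA.{stat}{o}")
    # VCA: 58
    for k in ("L", "S", "SL"):
        for pre in ("M", "s", "CV"):
            names.append(f"VCA.{pre}{k}")
    names += ["VCA.MDmax", "VCA.sDmax"]
    for o in ORIENTS:
        names.append(f"VCA.BMDmax{o}")
    for k in ("L", "S", "SL"):
        for pre in ("uM", "us", "uCV"):
            names.append(f"VCA.{pre}{k}")
    names += ["VCA.Lmax", "VCA.Smax", "VCA.SLmax"]
    for stat in ("BML", "BsL", "BCVL", "BMCS", "BsCS", "BCVCS",
                 "BMSL", "BsSL", "BCVSL"):
        for o in ORIENTS:
            names.append(f"VCA.{stat}{o}")
    names += ["VCA.Dom", "VCA.Even", "VCA.CVLum", "VCA.MichLum", "VCA.LumEven"]
    # BSA: 42
    for stat in ("BMCS", "BsCS", "BCVCS", "BmaxCS",
                 "BMSL", "BsSL", "BCVSL", "BmaxSL",
                 "BML", "BsL", "BCVL", "BmaxL",
                 "BDiv", "BDom"):
        for o in ORIENTS:
            names.append(f"BSA.{stat}{o}")
    # LEIA: 24
    for ch in ("Col", "Lum"):
        for mom in ("mean", "sd", "skew", "kurtosis"):
            for o in ORIENTS:
                names.append(f"LEIA.{ch}.{mom}{o}")
    return tuple(names)


METRIC_REGISTRY = _registry()
assert len(METRIC_REGISTRY) == 157 and len(set(METRIC_REGISTRY)) == 157

FAMILY_COUNTS = {"CAA": 33, "VCA": 58, "BSA": 42, "LEIA": 24}


# ---------------------------------------------------------------------------
# transition matrices

@dataclass
class TransitionMatrix:
    """Counts of unordered adjacent-pixel label pairs along one orientation.

    counts[i, j] == counts[j, i] holds the number of adjacencies between
    clusters i+1 and j+1; n_transitions sums each unordered pair once.
    """

    counts: np.ndarray
    orientation: str

    @property
    def n_transitions(self):
        c = self.counts
        return int(np.triu(c).sum())

    def offdiag_freqs(self):
        """Upper-triangle (i<j) boundary-type counts normalised to 1; None if no boundary."""
        iu = np.triu_indices_from(self.counts, k=1)
        c = self.counts[iu].astype(float)
        tot = c.sum()
        if tot == 0:
            return None, iu
        return c / tot, iu

    def diag_freqs(self):
        d = np.diag(self.counts).astype(float)
        tot = d.sum()
        return d / tot if tot > 0 else None


def transition_matrices(cp: ClusteredPattern) -> Dict[str, TransitionMatrix]:
    """Horizontal, vertical and pooled transition matrices of a label map."""
    K = cp.K
    labels = cp.labels
    out = {}
    for orientation, (dy, dx) in (("hrz", (0, 1)), ("vrt", (1, 0))):
        a = labels[:, :-1] if dx else labels[:-1, :]
        b = labels[:, 1:] if dx else labels[1:, :]
        ok = (a > 0) & (b > 0)
        ai, bi = a[ok] - 1, b[ok] - 1
        lo, hi = np.minimum(ai, bi), np.maximum(ai, bi)
        counts = np.zeros((K, K), dtype=np.int64)
        np.add.at(counts, (lo, hi), 1)
        counts = counts + np.triu(counts, k=1).T
        out[orientation] = TransitionMatrix(counts, orientation)
    out["full"] = TransitionMatrix(out["hrz"].counts + out["vrt"].counts, "full")
    return out


def _run_lengths(labels, axis):
    """Lengths of maximal same-label runs along rows (axis=1) or columns (axis=0)."""
    lab = labels if axis == 1 else labels.T
    runs = []
    for row in lab:
        prev, ln = 0, 0
        for v in row:
            if v == 0:
                if prev != 0:
                    runs.append(ln)
                prev, ln = 0, 0
            elif v == prev:
                ln += 1
            else:
                if prev != 0:
                    runs.append(ln)
                prev, ln = v, 1
        if prev != 0:
            runs.append(ln)
    return np.array(runs, dtype=float)


# ---------------------------------------------------------------------------
# small statistical helpers

def _inv_simpson(p):
    return 1.0 / float(np.sum(np.square(p)))


def _shannon(p):
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _wmoments(x, w):
    """Weighted mean / SD / CV; CV is NaN when the mean is 0."""
    m = float(np.sum(w * x))
    s = float(np.sqrt(np.sum(w * (x - m) ** 2)))
    cv = s / m if m != 0 else np.nan
    return m, s, cv


# ---------------------------------------------------------------------------
# CAA

def caa_metrics(cp: ClusteredPattern, tms: Dict[str, TransitionMatrix]) -> Dict[str, float]:
    K = cp.K
    out = {}
    out["CAA.Sc"] = float(K)
    mask_px = float((cp.labels > 0).sum())
    out["CAA.A"] = mask_px / cp.px_per_mm ** 2
    off_h = tms["hrz"].offdiag_freqs()[0]
    n_off_h = np.triu(tms["hrz"].counts, 1).sum()
    n_off_v = np.triu(tms["vrt"].counts, 1).sum()
    out["CAA.Asp"] = float(n_off_v) / float(n_off_h) if n_off_h > 0 else np.nan

    for o in ORIENTS:
        T = tms[_ORIENT_KEY[o]]
        off, _ = T.offdiag_freqs()
        d = T.diag_freqs()
        if off is None:
            for stat in ("C", "Qt", "Pt", "St", "Jt"):
                out[f"CAA.{stat}{o}"] = np.nan
        else:
            st = int(np.sum(off > 0))
            out[f"CAA.St{o}"] = float(st)
            out[f"CAA.C{o}"] = float(np.exp(_shannon(off)))
            out[f"CAA.Qt{o}"] = _inv_simpson(off) / st
            out[f"CAA.Jt{o}"] = _shannon(off) / np.log(st) if st > 1 else 1.0
            if o == "":
                runs = np.concatenate([_run_lengths(cp.labels, 1),
                                       _run_lengths(cp.labels, 0)])
            else:
                runs = _run_lengths(cp.labels, 1 if o == ".Hrz" else 0)
            out[f"CAA.Pt{o}"] = float(runs.mean()) / cp.px_per_mm
        if d is None:
            out[f"CAA.Qc{o}"] = np.nan
            out[f"CAA.Jc{o}"] = np.nan
        else:
            out[f"CAA.Qc{o}"] = _inv_simpson(d) / K
            out[f"CAA.Jc{o}"] = _shannon(d) / np.log(K) if K > 1 else 1.0
        tot = T.n_transitions
        n_off = tot - int(np.diag(T.counts).sum())
        n_diag = int(np.diag(T.counts).sum())
        out[f"CAA.B{o}"] = n_off / tot if tot > 0 else np.nan
        out[f"CAA.Rt{o}"] = n_off / n_diag if n_diag > 0 else np.nan
        out[f"CAA.Td{o}"] = tot / mask_px
    return out


# ---------------------------------------------------------------------------
# pairwise contrast kernels between clusters

def _cluster_pair_contrasts(cp: ClusteredPattern, vs: VisualSystem):
    """Weber-luminance, chromatic ΔS and RNL-luminance ΔL for all unordered cluster pairs."""
    K = cp.K
    iu = np.triu_indices(K, k=1)
    q = cp.cluster_catches
    L = q[:, 3]
    cw = np.abs(L[iu[0]] - L[iu[1]]) / (L[iu[0]] + L[iu[1]])
    ds = chromatic_delta_s(q[iu[0], :3], q[iu[1], :3], vs.chrom_webers)
    dl = luminance_delta(L[iu[0]], L[iu[1]], vs.lum_weber)
    return iu, np.atleast_1d(cw), np.atleast_1d(ds), np.atleast_1d(dl)


def vca_metrics(cp: ClusteredPattern, vs: VisualSystem,
                tms: Dict[str, TransitionMatrix]) -> Dict[str, float]:
    out = {n: np.nan for n in METRIC_REGISTRY if n.startswith("VCA.")}
    K = cp.K
    if K < 2:
        return out
    iu, cw, ds, dl = _cluster_pair_contrasts(cp, vs)
    p = cp.cluster_abundance
    w = p[iu[0]] * p[iu[1]]
    w = w / w.sum()
    kernels = {"L": cw, "S": ds, "SL": dl}
    for k, x in kernels.items():
        m, s, cv = _wmoments(x, w)
        out[f"VCA.M{k}"], out[f"VCA.s{k}"], out[f"VCA.CV{k}"] = m, s, cv
        um = float(x.mean())
        us = float(x.std())
        out[f"VCA.uM{k}"], out[f"VCA.us{k}"] = um, us
        out[f"VCA.uCV{k}"] = us / um if um != 0 else np.nan
    out["VCA.Lmax"] = float(cw.max())
    out["VCA.Smax"] = float(ds.max())
    out["VCA.SLmax"] = float(dl.max())

    # per-cluster max chromatic distance to any other cluster
    dsm = np.zeros((K, K))
    dsm[iu] = ds
    dsm += dsm.T
    row_max = dsm.max(axis=1)
    mdmax = float(np.sum(p * row_max))
    out["VCA.MDmax"] = mdmax
    out["VCA.sDmax"] = float(np.sqrt(np.sum(p * (row_max - mdmax) ** 2)))

    kern_names = {"L": "L", "S": "CS", "SL": "SL"}
    for o in ORIENTS:
        T = tms[_ORIENT_KEY[o]]
        off, oiu = T.offdiag_freqs()
        if off is None:
            continue
        b = off  # boundary-share weights aligned with iu ordering
        for k, x in kernels.items():
            m, s, cv = _wmoments(x, b)
            kn = kern_names[k]
            out[f"VCA.BM{kn}{o}"], out[f"VCA.Bs{kn}{o}"], out[f"VCA.BCV{kn}{o}"] = m, s, cv
        # boundary-involvement share per cluster for BMDmax
        offc = np.triu(T.counts, 1)
        inv = offc.sum(axis=0) + offc.sum(axis=1)
        bi = inv / inv.sum()
        out[f"VCA.BMDmax{o}"] = float(np.sum(bi * row_max))

    out["VCA.Dom"] = float(p.max())
    out["VCA.Even"] = _inv_simpson(p) / K
    L = cp.cluster_catches[:, 3]
    mL = float(np.sum(p * L))
    sL = float(np.sqrt(np.sum(p * (L - mL) ** 2)))
    out["VCA.CVLum"] = sL / mL
    out["VCA.MichLum"] = float((L.max() - L.min()) / (L.max() + L.min()))
    shares = p * L / np.sum(p * L)
    out["VCA.LumEven"] = _inv_simpson(shares) / K
    return out


def bsa_metrics(cp: ClusteredPattern, vs: VisualSystem,
                tms: Dict[str, TransitionMatrix]) -> Dict[str, float]:
    out = {n: np.nan for n in METRIC_REGISTRY if n.startswith("BSA.")}
    if cp.K < 2:
        return out
    iu, cw, ds, dl = _cluster_pair_contrasts(cp, vs)
    kernels = {"CS": ds, "SL": dl, "L": cw}
    for o in ORIENTS:
        T = tms[_ORIENT_KEY[o]]
        off, _ = T.offdiag_freqs()
        if off is None:
            continue
        present = off > 0
        b = off[present] / off[present].sum()
        for kn, x in kernels.items():
            xo = x[present]
            m, s, cv = _wmoments(xo, b)
            out[f"BSA.BM{kn}{o}"], out[f"BSA.Bs{kn}{o}"], out[f"BSA.BCV{kn}{o}"] = m, s, cv
            out[f"BSA.Bmax{kn}{o}"] = float(xo.max())
        out[f"BSA.BDiv{o}"] = float(np.exp(_shannon(b)))
        out[f"BSA.BDom{o}"] = float(b.max())
    return out


# ---------------------------------------------------------------------------
# LEIA

def _moments(x):
    """mean / sd / skew / excess kurtosis; degenerate distributions report 0."""
    n = len(x)
    m = float(np.mean(x))
    s = float(np.std(x))
    if s == 0 or n < 2:
        return m, 0.0, 0.0, 0.0
    z = (x - m) / s
    return m, s, float(np.mean(z ** 3)), float(np.mean(z ** 4) - 3.0)


def leia_metrics(img: ConeCatchImage, vs: VisualSystem) -> Dict[str, float]:
    """Moments of the local (1 px offset) chromatic and luminance edge contrasts.

    Operates on the unclustered (typically ranked-filtered) image; horizontal
    and vertical offsets are pooled for the undirected variant.
    """
    img.require_positive()
    logc = np.log(np.where(img.mask[:, :, None], img.catches, 1.0))
    sets = {}
    for key, (dy, dx) in (("hrz", (0, 1)), ("vrt", (1, 0))):
        a_mask = img.mask[:, :-1] if dx else img.mask[:-1, :]
        b_mask = img.mask[:, 1:] if dx else img.mask[1:, :]
        ok = a_mask & b_mask
        la = (logc[:, :-1] if dx else logc[:-1, :])[ok]
        lb = (logc[:, 1:] if dx else logc[1:, :])[ok]
        df = la - lb
        sets[key] = (_delta_s_from_logdiff(df[:, :3], vs.chrom_webers),
                     np.abs(df[:, 3]) / vs.lum_weber)
    if len(sets["hrz"][0]) + len(sets["vrt"][0]) == 0:
        raise InvalidInputError("mask too small for any 1-px offset pair")
    out = {}
    for ci, ch in ((0, "Col"), (1, "Lum")):
        pooled = {"": np.concatenate([sets["hrz"][ci], sets["vrt"][ci]]),
                  ".Hrz": sets["hrz"][ci], ".Vrt": sets["vrt"][ci]}
        for o, x in pooled.items():
            m, s, sk, ku = _moments(x) if len(x) else (np.nan,) * 4
            out[f"LEIA.{ch}.mean{o}"] = m
            out[f"LEIA.{ch}.sd{o}"] = s
            out[f"LEIA.{ch}.skew{o}"] = sk
            out[f"LEIA.{ch}.kurtosis{o}"] = ku
    return out


# ---------------------------------------------------------------------------
# assembly

@dataclass
class MetricVector:
    """The full 157-statistic description of one individual at one distance."""

    values: Dict[str, float]
    individual_id: str
    distance_mm: float
    valid: bool

    def __post_init__(self):
        if tuple(self.values.keys()) != METRIC_REGISTRY:
            raise InvalidInputError("metric vector does not match the registry")


def assemble_metric_vector(values, individual_id, distance_mm) -> MetricVector:
    ordered = {n: float(values[n]) for n in METRIC_REGISTRY}
    arr = np.array(list(ordered.values()))
    valid = bool(np.all(np.isfinite(arr)))
    return MetricVector(ordered, individual_id, distance_mm, valid)


def full_qcpa(img: ConeCatchImage, vs: VisualSystem, distance_mm: float,
              falloff: int = 3, radius: int = 5, repetitions: int = 5) -> MetricVector:
    """Run the full perceptual pipeline for one image at one viewing distance.

    acuity blur -> RNL ranked filter -> LEIA on the filtered image, and
    RNL clustering -> transition matrices -> CAA / VCA / BSA; returns the
    157-statistic vector (valid=False when any entry is non-finite, e.g. for
    patterns with fewer than two elements).
    """
    blurred = acuity_blur(img, vs.acuity_cpd, distance_mm)
    filtered = rnl_ranked_filter(blurred, vs, falloff, radius, repetitions)
    values = {}
    values.update(leia_metrics(filtered, vs))
    cp = rnl_cluster(filtered, vs)
    tms = transition_matrices(cp)
    values.update(caa_metrics(cp, tms))
    values.update(vca_metrics(cp, vs, tms))
    values.update(bsa_metrics(cp, vs, tms))
    return assemble_metric_vector(values, img.id, distance_mm)
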