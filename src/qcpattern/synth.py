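"""Synthetic inputs for every pipeline stage.

Generates body-shaped cone-catch images with planted pattern contrasts,
factor-structured metric tables, pure-birth species trees, assay tables and
factor scores drawn from known distributional-model parameters, so that the
whole pipeline is testable without any external data.

Cone catches are synthesised directly (no RGB intermediate): pattern-element
catches are solved in log-catch space so that the chromatic ΔS and luminance
ΔL between element and base colours hit their targets exactly (both distances
are linear in log-catch displacements, so the inverse problem is a scaling).
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field, replace
from typing import Dict

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .defence import classify
from .phylo import DISTANCE_LEVELS, _design_matrix, phylo_correlation
from .vision import (ConeCatchImage, InvalidInputError, VisualSystem,
                     chromatic_delta_s, luminance_delta)

DEFAULT_BASE_CATCHES = (0.12, 0.22, 0.30, 0.25)


# ---------------------------------------------------------------------------
# inverse contrast solver

def solve_element_catches(base, chrom_target, achro_target, vs: VisualSystem,
                          chrom_direction=(1.0, -1.0, 0.0), achro_sign=1.0):
    """Element catches at given chromatic ΔS and luminance ΔL from a base colour.

    Displacements are applied in log-catch space: the chromatic direction is
    scaled so the RNL ΔS equals ``chrom_target`` (ΔS is homogeneous of degree
    one in the log displacement) and the double-cone catch is scaled by
    exp(±ΔL·ω_dbl).
    """
    base = np.asarray(base, dtype=float)
    if np.any(base <= 0):
        raise InvalidInputError("base catches must be strictly positive")
    elem = base.copy()
    if chrom_target > 0:
        v = np.asarray(chrom_direction, dtype=float)
        ds_unit = chromatic_delta_s(base[:3] * np.exp(v), base[:3], vs.chrom_webers)
        if ds_unit == 0:
            raise ValueError("chromatic direction has zero RNL length")
        elem[:3] = base[:3] * np.exp(v * chrom_target / ds_unit)
    if achro_target > 0:
        elem[3] = base[3] * np.exp(achro_sign * achro_target * vs.lum_weber)
    if np.any(~np.isfinite(elem)) or np.any(elem <= 0):
        raise ValueError("contrast targets unreachable with positive catches")
    return elem


# ---------------------------------------------------------------------------
# image generation

@dataclass
class PatternRecipe:
    """Parameters of one synthetic patterned animal.

    ``achro_contrast`` / ``chrom_contrast`` are the target ΔL / ΔS between the
    pure element and base colours; ``regularity_jitter`` (px) perturbs element
    placement; ``noise_log_sd`` adds multiplicative log-normal pixel noise
    that the ranked filter is expected to remove.
    """

    body_axes: tuple = (22, 14)          # ellipse semi-axes (rows, cols) in px
    pattern: str = "stripes"             # stripes | spots | rim | uniform
    base_catches: tuple = DEFAULT_BASE_CATCHES
    element_size_px: float = 5.0
    regularity_jitter: float = 0.0
    achro_contrast: float = 8.0
    chrom_contrast: float = 1.0
    noise_log_sd: float = 0.02
    px_per_mm: float = 2.0
    seed: int = 0
    id: str = ""


def _ellipse_mask(a, b, margin=3):
    H, W = 2 * a + 2 * margin, 2 * b + 2 * margin
    yy, xx = np.mgrid[:H, :W]
    cy, cx = (H - 1) / 2, (W - 1) / 2
    return ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0, (H, W)


def _element_mask(recipe: PatternRecipe, mask, rng):
    H, W = mask.shape
    size = max(int(round(recipe.element_size_px)), 1)
    jit = recipe.regularity_jitter
    em = np.zeros((H, W), dtype=bool)
    if recipe.pattern == "uniform":
        return em
    if recipe.pattern == "stripes":
        # horizontal stripes (transitions along the vertical body axis);
        # per-column jitter makes edges ragged so horizontal transitions occur
        phase = int(rng.integers(0, 2 * size))
        off = (np.round(rng.normal(0, jit, size=W)).astype(int)
               if jit > 0 else np.zeros(W, dtype=int))
        yy, xx = np.mgrid[:H, :W]
        em = ((yy - phase - off[None, :]) % (2 * size)) < size
    elif recipe.pattern == "spots":
        r = max(size // 2, 1)
        step = max(2 * size, 3)
        yy, xx = np.mgrid[:H, :W]
        for cy in range(step // 2, H, step):
            for cx in range(step // 2, W, step):
                jy = rng.normal(0, jit) if jit > 0 else 0.0
                jx = rng.normal(0, jit) if jit > 0 else 0.0
                em |= (yy - cy - jy) ** 2 + (xx - cx - jx) ** 2 <= r * r
    elif recipe.pattern == "rim":
        inner = ndimage.binary_erosion(mask, iterations=size)
        em = mask & ~inner
    else:
        raise ValueError(f"unknown pattern {recipe.pattern!r}")
    return em & mask


def gen_image(recipe: PatternRecipe, vs: VisualSystem | None = None) -> ConeCatchImage:
    """Deterministically render a patterned cone-catch image from a recipe."""
    vs = vs or VisualSystem()
    rng = np.random.default_rng(recipe.seed)
    mask, (H, W) = _ellipse_mask(*recipe.body_axes)
    base = np.asarray(recipe.base_catches, dtype=float)
    elem = solve_element_catches(base, recipe.chrom_contrast,
                                 recipe.achro_contrast, vs)
    catches = np.ones((H, W, 4)) * base[None, None, :]
    em = _element_mask(recipe, mask, rng)
    catches[em] = elem
    if recipe.noise_log_sd > 0:
        catches *= np.exp(rng.normal(0, recipe.noise_log_sd, size=catches.shape))
    catches[~mask] = 0.0
    return ConeCatchImage(catches, mask, recipe.px_per_mm, id=recipe.id)


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class ClassPreset:
    """Mean recipe parameters and the among-individual variance dial of one class."""

    pattern: str
    achro_contrast: float
    chrom_contrast: float
    element_size_px: float
    variance_dial: float     # log-SD applied to the contrast targets
    jitter: float
    ed_range: tuple
    ld_range: tuple


# Study conditions: highly unpalatable species carry bold, achromatic,
# regular patterns; moderately unpalatable species carry more chromatic,
# weaker-boundary patterns; undefended species sit in between on the mean but
# with much larger among-individual variability.
DEFAULT_PRESETS: Dict[str, ClassPreset] = {
    "undefended": ClassPreset("spots", 5.0, 2.5, 4.0, 0.40, 1.5,
                              (0.0, 0.0), (0.0, 0.0)),
    "toxic_moderate": ClassPreset("spots", 5.0, 3.5, 5.0, 0.10, 0.5,
                                  (0.30, 0.70), (0.20, 0.90)),
    "toxic_high": ClassPreset("stripes", 12.0, 1.0, 5.0, 0.08, 0.6,
                              (0.76, 0.97), (0.40, 0.95)),
}


@dataclass
class GroupDesign:
    """Cohort layout: species per class, individuals per species, distances."""

    presets: Dict[str, ClassPreset] = field(default_factory=lambda: dict(DEFAULT_PRESETS))
    species_per_class: Dict[str, int] = field(
        default_factory=lambda: {"undefended": 3, "toxic_moderate": 5, "toxic_high": 5})
    n_individuals: int = 4
    distances_mm: tuple = DISTANCE_LEVELS
    body_axes: tuple = (22, 14)
    px_per_mm: float = 2.0


def gen_tree(n_tips: int = 13, seed: int = 0, labels=None) -> dendropy.Tree:
    """Pure-birth (Yule) tree with branch lengths, tips labelled sp01..spNN."""
    rng = _pyrandom.Random(int(seed))
    from dendropy.simulate import treesim
    tree = treesim.birth_death_tree(birth_rate=1.0, death_rate=0.0,
                                    num_extant_tips=n_tips, rng=rng)
    labels = labels or [f"sp{i + 1:02d}" for i in range(n_tips)]
    for leaf, lab in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = lab
    return tree


@dataclass
class Cohort:
    recipes: list
    species: list              # per-individual species label
    species_class: Dict[str, str]
    assays: pd.DataFrame
    tree: dendropy.Tree
    design: GroupDesign

    def images(self, vs: VisualSystem | None = None):
        return [gen_image(r, vs) for r in self.recipes]


def gen_cohort(design: GroupDesign | None = None, seed: int = 0,
               vs: VisualSystem | None = None) -> Cohort:
    """Draw a full synthetic cohort: recipes, species classes, assays, tree."""
    design = design or GroupDesign()
    vs = vs or VisualSystem()
    rng = np.random.default_rng(seed)
    species_class, species_names = {}, []
    for cls in ("undefended", "toxic_moderate", "toxic_high"):
        for _ in range(design.species_per_class[cls]):
            name = f"sp{len(species_names) + 1:02d}"
            species_names.append(name)
            species_class[name] = cls
    tree = gen_tree(len(species_names), seed=int(rng.integers(2 ** 31)),
                    labels=species_names)

    recipes, species = [], []
    assay_rows = []
    for sp in species_names:
        cls = species_class[sp]
        p = design.presets[cls]
        ed = float(rng.uniform(*p.ed_range))
        ld = float(rng.uniform(*p.ld_range))
        if cls != "undefended":
            assert classify(ed, ld) == cls
        assay_rows.append({"species": sp, "one_minus_ed50": ed,
                           "one_minus_ld50": ld, "extract_type": "whole_body"})
        # the class variance dial is the among-individual SD of the contrast
        # targets; a smaller species-level displacement keeps species distinct
        sp_shift = rng.normal(0, p.variance_dial / 2, size=2)
        for i in range(design.n_individuals):
            ind_shift = rng.normal(0, p.variance_dial, size=2)
            achro = p.achro_contrast * np.exp(sp_shift[0] + ind_shift[0])
            chrom = p.chrom_contrast * np.exp(sp_shift[1] + ind_shift[1])
            recipes.append(PatternRecipe(
                body_axes=design.body_axes, pattern=p.pattern,
                element_size_px=p.element_size_px,
                regularity_jitter=p.jitter,
                achro_contrast=float(achro), chrom_contrast=float(chrom),
                px_per_mm=design.px_per_mm,
                seed=int(rng.integers(2 ** 31)),
                id=f"{sp}_i{i + 1:02d}",
            ))
            species.append(sp)
    assays = pd.DataFrame(assay_rows)
    return Cohort(recipes, species, species_class, assays, tree, design)


# ---------------------------------------------------------------------------
# factor-structured metric tables

def block_loadings(p: int, k: int, loading: float = 0.7) -> np.ndarray:
    """Disjoint orthogonal block loading matrix (p metrics, k factors)."""
    L = np.zeros((p, k))
    sizes = [p // k + (1 if i < p % k else 0) for i in range(k)]
    start = 0
    for j, s in enumerate(sizes):
        L[start:start + s, j] = loading
        start += s
    return L


def gen_metric_table(n_rows: int, loadings: np.ndarray, noise_sd: float = 1.0,
                     seed=None, column_names=None) -> pd.DataFrame:
    """Rows = scores @ loadings' + noise, standardised per column."""
    rng = np.random.default_rng(seed)
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    scores = rng.standard_normal((n_rows, k))
    X = scores @ L.T
    if noise_sd > 0:
        X = X + rng.standard_normal((n_rows, p)) * noise_sd
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    if column_names is None:
        column_names = [f"m{i + 1:03d}" for i in range(p)]
    return pd.DataFrame(X, columns=column_names)


# ---------------------------------------------------------------------------
# scores from known distributional-model parameters

def gen_scores(tree, betas, gammas, sigma_phy: float, sigma_b: float,
               nu: float, n_per_species: int, species_class: Dict[str, str],
               seed=None) -> pd.DataFrame:
    """Draw factor scores from the distributional Student model itself.

    betas/gammas are the 6 treatment-coded cell coefficients for the mean and
    log residual SD; species effects come from MVN(0, sigma_phy^2 A) on the
    tree's Brownian correlation, slopes from N(0, sigma_b^2), residuals from
    a Student-t with ``nu`` degrees of freedom.
    """
    rng = np.random.default_rng(seed)
    A, taxa = phylo_correlation(tree, sorted(species_class))
    S = len(taxa)
    La = np.linalg.cholesky(A + 1e-10 * np.eye(S))
    a = sigma_phy * (La @ rng.standard_normal(S))
    b = sigma_b * rng.standard_normal(S)
    rows = []
    betas = np.asarray(betas, dtype=float)
    gammas = np.asarray(gammas, dtype=float)
    for si, sp in enumerate(taxa):
        cls = species_class[sp]
        for dist in DISTANCE_LEVELS:
            far = 1.0 if dist == DISTANCE_LEVELS[1] else 0.0
            x = _design_matrix(np.array([cls], dtype=object), np.array([far]))[0]
            mu = float(x @ betas) + a[si] + b[si] * far
            sig = float(np.exp(x @ gammas))
            eps = rng.standard_t(nu, size=n_per_species) * sig
            for e in eps:
                rows.append({"species": sp, "defence": cls,
                             "distance_mm": dist, "score": mu + e})
    return pd.DataFrame(rows)
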