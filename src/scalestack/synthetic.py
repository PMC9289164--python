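"""Synthetic multi-scale cohorts for end-to-end testing.

Real whole-slide cohorts are terabyte-scale; every stage of this
package is therefore exercised on generated cohorts that emulate the
statistical structure the methods rely on:

* a class-imbalanced slide table (slide id, patient id, class label),
* per-slide pyramids with exact grid geometry,
* binary QC masks with rectangular artifact regions,
* per-magnification tile embeddings drawn from class- and
  scale-dependent Gaussian mixtures over ``P`` latent tissue phenotypes.

A class ``c`` at magnification ``m`` has a phenotype distribution
``theta[c, m]``; a tile with phenotype ``p`` at magnification ``m`` gets
an embedding ``mu[p, m] + sigma * N(0, I)`` with the ``P`` means placed
at mutual distance ``s`` (the separation).  Phenotypes are drawn
hierarchically down the pyramid: a grid child copies its parent's
phenotype with probability ``coherence``, emulating spatial coherence of
tissue regions across scales.

``scale_complementary_config`` builds the cohort used to probe the value
of multi-scale fusion: one subset of classes is separable only at high
magnification, another only at low magnification, so no single
magnification can separate all classes but their combination can.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embeddings import EmbeddingMatrix
from .pyramid import PyramidSpec, QCMask, enumerate_grid_tiles

__all__ = [
    "CohortConfig",
    "SyntheticSlide",
    "ArtifactConfig",
    "generate_cohort",
    "generate_qc_mask",
    "render_tile_image",
    "scale_complementary_config",
    "write_cohort_csv",
]


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``slides_per_class`` may be an int (balanced) or a per-class vector
    (imbalance).  ``tiles_base`` is the 20x grid dimension per slide
    (8 -> 8x8 = 64 tiles at 20x, 16 at 10x, 4 at 5x).
    ``class_signatures`` is an optional (n_classes, n_mags, P) array of
    phenotype distributions; when absent, signatures are derived from
    ``scale_informativeness`` (mag -> list of class groups sharing a
    signature) or drawn from a Dirichlet prior (every class distinct at
    every magnification).
    """

    n_classes: int = 30
    slides_per_class: object = 100
    tiles_base: int = 8
    embedding_dim: int = 512
    n_phenotypes: int = 8
    class_signatures: object = None
    scale_informativeness: object = None
    separation: float = 6.0
    noise_sd: float = 1.0
    coherence: float = 0.8
    mags: tuple = (5, 10, 20)
    base_mag: float = 20
    tile_size: int = 224
    signature_smoothing: float = 0.2
    seed: int = 0

    def slides_for_class(self, c: int) -> int:
        if np.isscalar(self.slides_per_class):
            return int(self.slides_per_class)
        return int(self.slides_per_class[c])


@dataclass
class SyntheticSlide:
    """One generated slide: geometry, per-mag phenotypes and embeddings."""

    slide_id: str
    patient_id: str
    class_label: int
    spec: PyramidSpec
    phenotypes: dict = field(repr=False)  # mag -> (rows, cols) int array
    embeddings: dict = field(repr=False)  # mag -> EmbeddingMatrix


@dataclass
class ArtifactConfig:
    """Rectangular artifact/background regions for QC masks."""

    coverage: float = 0.1
    max_rect_frac: float = 0.25


def _resolve_signatures(config: CohortConfig, rng) -> np.ndarray:
    """(n_classes, n_mags, P) phenotype distributions, rows summing to 1."""
    C, P = config.n_classes, config.n_phenotypes
    mags = sorted(config.mags)
    if config.class_signatures is not None:
        theta = np.asarray(config.class_signatures, dtype=np.float64)
        if theta.shape != (C, len(mags), P):
            raise ValueError("invalid class signature")
        if not np.allclose(theta.sum(axis=-1), 1.0, atol=1e-9):
            raise ValueError("invalid class signature")
        return theta
    alpha = config.signature_smoothing
    theta = np.empty((C, len(mags), P))
    if config.scale_informativeness is None:
        for mi in range(len(mags)):
            theta[:, mi, :] = rng.dirichlet(np.full(P, 0.3), size=C)
        return theta
    for mi, m in enumerate(mags):
        groups = config.scale_informativeness.get(m)
        if groups is None:
            groups = [[c] for c in range(C)]
        if len(groups) > P:
            raise ValueError("more class groups than phenotypes at one magnification")
        assigned = set()
        for gi, group in enumerate(groups):
            sig = np.full(P, alpha / P)
            sig[gi] += 1.0 - alpha
            for c in group:
                theta[c, mi, :] = sig
                assigned.add(c)
        if len(assigned) != C:
            raise ValueError("scale_informativeness must cover every class")
    return theta


def _phenotype_means(config: CohortConfig, rng) -> dict:
    """mag -> (P, M) means at mutual Euclidean distance `separation`."""
    M, P = config.embedding_dim, config.n_phenotypes
    if P > M:
        raise ValueError("n_phenotypes cannot exceed embedding_dim")
    means = {}
    for m in sorted(config.mags):
        Q, _ = np.linalg.qr(rng.normal(size=(M, P)))
        means[m] = (config.separation / np.sqrt(2.0)) * Q.T
    return means


def _draw_slide_phenotypes(config: CohortConfig, spec: PyramidSpec, theta_c, rng) -> dict:
    """Hierarchical phenotype draw, lowest magnification first."""
    mags = sorted(config.mags)
    phen = {}
    parent_mag = None
    for mi, m in enumerate(mags):
        rows, cols = spec.grid_shape(m)
        # slides too small for a full low-mag tile have an empty level;
        # the first non-empty level then acts as the hierarchy root
        if parent_mag is None or rows == 0 or cols == 0:
            grid = rng.choice(
                config.n_phenotypes, size=(rows, cols), p=theta_c[mi]
            ).astype(np.int64)
        else:
            parent = phen[parent_mag]
            f = int(round(m / parent_mag))
            fresh = rng.choice(config.n_phenotypes, size=(rows, cols), p=theta_c[mi])
            copy = rng.random((rows, cols)) < config.coherence
            prow = np.minimum(np.arange(rows) // f, parent.shape[0] - 1)
            pcol = np.minimum(np.arange(cols) // f, parent.shape[1] - 1)
            inherited = parent[np.ix_(prow, pcol)]
            grid = np.where(copy, inherited, fresh)
        phen[m] = grid
        if rows > 0 and cols > 0:
            parent_mag = m
    return phen


def generate_cohort(config: CohortConfig):
    """Generate (cohort table, slides); deterministic given the seed.

    The cohort table has columns slide_id, patient_id, class_label and an
    unassigned split column.  A single global seed fans out to per-slide
    child seeds via :class:`numpy.random.SeedSequence` spawn keys, so the
    cohort is reproducible independent of generation order.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    theta = _resolve_signatures(config, rng)
    means = _phenotype_means(config, rng)
    records, slides = [], []
    idx = 0
    for c in range(config.n_classes):
        for _ in range(config.slides_for_class(c)):
            slide_id = f"S{idx:05d}"
            patient_id = f"P{idx:05d}"
            spec = PyramidSpec(
                slide_id=slide_id,
                base_width=config.tiles_base * config.tile_size,
                base_height=config.tiles_base * config.tile_size,
                base_mag=config.base_mag,
                mags=tuple(sorted(config.mags)),
                tile_size=config.tile_size,
            )
            srng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1, idx])
            )
            phen = _draw_slide_phenotypes(config, spec, theta[c], srng)
            embs = {}
            for m in sorted(config.mags):
                grid = phen[m]
                flat = grid.ravel()  # row-major = manifest order
                mat = means[m][flat] + config.noise_sd * srng.normal(
                    size=(flat.size, config.embedding_dim)
                )
                rows, cols = grid.shape
                rr, cc = np.divmod(np.arange(flat.size), cols)
                embs[m] = EmbeddingMatrix(
                    slide_id=slide_id,
                    mag=m,
                    matrix=mat.astype(np.float32),
                    tile_index=np.column_stack([rr, cc]),
                )
            slides.append(
                SyntheticSlide(
                    slide_id=slide_id,
                    patient_id=patient_id,
                    class_label=c,
                    spec=spec,
                    phenotypes=phen,
                    embeddings=embs,
                )
            )
            records.append(
                {
                    "slide_id": slide_id,
                    "patient_id": patient_id,
                    "class_label": c,
                    "split": "unassigned",
                }
            )
            idx += 1
    return pd.DataFrame(records), slides


def generate_qc_mask(spec: PyramidSpec, artifact_config: ArtifactConfig = None, seed: int = 0, mask_mag: float = 1.25) -> QCMask:
    """Binary tissue mask with rectangular artifact regions.

    The realized artifact coverage matches the request within 2% of the
    raster (excess zeros from overlapping rectangles are flipped back).
    """
    artifact_config = artifact_config or ArtifactConfig(coverage=0.0)
    cov = artifact_config.coverage
    if cov > 1 or cov < 0:
        raise ValueError("artifact coverage must lie in [0, 1]")
    d = spec.base_mag / mask_mag
    nrow = int(spec.base_height // d)
    ncol = int(spec.base_width // d)
    raster = np.ones((nrow, ncol), dtype=np.int8)
    if cov >= 1.0:
        raster[:] = 0
        return QCMask(slide_id=spec.slide_id, mask_mag=mask_mag, raster=raster)
    rng = np.random.default_rng(seed)
    target = int(round(cov * raster.size))
    max_side = max(1, int(artifact_config.max_rect_frac * min(nrow, ncol)))
    guard = 0
    while (raster == 0).sum() < target and guard < 10000:
        h = int(rng.integers(1, max_side + 1))
        w = int(rng.integers(1, max_side + 1))
        r = int(rng.integers(0, max(1, nrow - h + 1)))
        c = int(rng.integers(0, max(1, ncol - w + 1)))
        raster[r : r + h, c : c + w] = 0
        guard += 1
    excess = int((raster == 0).sum()) - target
    if excess > 0:
        zr, zc = np.nonzero(raster == 0)
        flip = rng.choice(len(zr), size=excess, replace=False)
        raster[zr[flip], zc[flip]] = 1
    return QCMask(slide_id=spec.slide_id, mask_mag=mask_mag, raster=raster)


def render_tile_image(phenotype: int, mag: float, size: int = 224, seed: int = 0) -> np.ndarray:
    """Deterministic procedural texture keyed by phenotype.

    Each phenotype gets a distinct grating frequency, orientation and
    base color, so phenotypes are separable by a small classifier while
    the texture remains cheap to generate.  Returns uint8 RGB.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(phenotype), int(round(mag * 4)), seed])
    )
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    angle = 0.61 * (phenotype + 1)
    freq = 0.02 * (1 + (phenotype % 7)) * (20.0 / max(mag, 1))
    wave = np.sin(2 * np.pi * freq * (xx * np.cos(angle) + yy * np.sin(angle)))
    base = rng.uniform(0.25, 0.85, size=3)
    img = np.empty((size, size, 3))
    for ch in range(3):
        img[..., ch] = base[ch] + 0.15 * wave + 0.05 * rng.normal(size=(size, size))
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def scale_complementary_config(
    n_classes: int = 10,
    slides_per_class: int = 30,
    tiles_base: int = 8,
    embedding_dim: int = 32,
    separation: float = 6.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    **kwargs,
) -> CohortConfig:
    """Cohort where no single magnification separates every class.

    The first half of the classes share one low-magnification signature
    but are mutually distinct at 20x (microscopic-detail classes); the
    second half are distinct at 5x but share one 20x signature
    (macroscopic-context classes); 10x is uninformative on its own.
    Cross-scale phenotype coherence is disabled so each magnification
    carries only its own signal and the complementarity holds exactly by
    construction.
    """
    half = n_classes // 2
    lo = list(range(half))
    hi = list(range(half, n_classes))
    informativeness = {
        20: [[c] for c in lo] + [hi],
        5: [lo] + [[c] for c in hi],
        10: [list(range(n_classes))],
    }
    n_groups = max(len(informativeness[m]) for m in informativeness)
    return CohortConfig(
        n_classes=n_classes,
        slides_per_class=slides_per_class,
        tiles_base=tiles_base,
        embedding_dim=embedding_dim,
        n_phenotypes=max(8, n_groups),
        scale_informativeness=informativeness,
        separation=separation,
        noise_sd=noise_sd,
        coherence=0.0,
        seed=seed,
        **kwargs,
    )


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)
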