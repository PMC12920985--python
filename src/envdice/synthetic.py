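"""Seeded synthetic phantoms, graded degradations, and a programmatic rubric.

Validating a segmentation metric means checking that its values track a
human's ordinal judgement of mask quality.  This module lets that whole
experiment run without any patient data: it generates ground-truth phantom
masks (unions of random ellipses/ellipsoids standing in for tumor masks
drawn by a physician), produces predictions degraded to a target quality
class 0-4, and scores reference/prediction pairs with a programmatic
approximation of the five-level rubric:

    4  excellent — perfect or nearly perfect, at most slight boundary noise
    3  good      — outlines clearly intersect, areas mostly overlap, no
                   fully-FP/FN components
    2  decent    — correct location but outlines fully outside/inside the
                   reference, or a fully-FP/FN component is present
    1  poor      — touches the reference at places, but mostly non-overlap
    0  fully wrong — no overlap anywhere, or an all-negative prediction

A "fully FP component" is a connected component of the prediction with no
reference overlap; "fully FN" is the converse.  The rubric constants that
operationalize the qualitative wording (majority overlap, near-perfect
error budget) are exposed on :class:`RubricConfig` since they are modelling
choices, not measured quantities.

All generation is a pure function of (spec, seed); there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core_metrics import Connectivity, MetricConfig, as_binary_mask

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "ScoredPair",
    "RubricConfig",
    "generate_phantom",
    "degrade",
    "rubric_score",
    "make_scored_suite",
    "write_fixture_set",
]

MIN_PHANTOM_POSITIVES = 6  # matches the slice inclusion filter


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one ground-truth phantom mask."""

    shape: tuple[int, ...] = (64, 64)
    n_blobs: int = 1
    radius_range: tuple[float, float] = (3.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) not in (2, 3):
            raise ValueError("phantoms are 2-D or 3-D")
        lo, hi = self.radius_range
        if not (0.5 <= lo <= hi):
            raise ValueError(f"invalid radius range {self.radius_range}")
        if self.n_blobs < 1:
            raise ValueError("need at least one blob")
        if any(hi * 2 + 2 > s for s in self.shape):
            raise ValueError(
                f"blob radius up to {hi} does not fit in grid {self.shape}"
            )


@dataclass(frozen=True)
class DegradationSpec:
    """Recipe for degrading a reference mask to a target quality class."""

    score_class: int
    seed: int = 0
    # class 4: fraction of boundary sites flipped is drawn from [0, magnitude]
    noise_magnitude: float = 0.12
    # class 0/2: minimum dilation gap kept between disjoint components and
    # the reference; > n guarantees zero WDC under the default config
    far_gap: int = 7

    def __post_init__(self) -> None:
        if self.score_class not in range(5):
            raise ValueError(f"score class must be 0-4, got {self.score_class}")
        if not (0.0 <= self.noise_magnitude <= 0.5):
            raise ValueError("noise magnitude must lie in [0, 0.5]")


@dataclass(frozen=True)
class ScoredPair:
    reference: np.ndarray
    prediction: np.ndarray
    score: int
    provenance: DegradationSpec | None = None

    def __post_init__(self) -> None:
        if self.reference.shape != self.prediction.shape:
            raise ValueError("reference and prediction shapes differ")


@dataclass(frozen=True)
class RubricConfig:
    """Constants operationalizing the qualitative rubric wording."""

    majority_fraction: float = 0.5  # below this overlap share -> class 1
    near_perfect_band: int = 1      # max dilation distance of class-4 errors
    near_perfect_fraction: float = 0.15  # max |X xor Y| / |X| for class 4
    connectivity: Connectivity = Connectivity.EDGE


DEFAULT_RUBRIC = RubricConfig()


def _struct(ndim: int, connectivity: Connectivity = Connectivity.EDGE) -> np.ndarray:
    rank = 1 if connectivity is Connectivity.EDGE else ndim
    return ndimage.generate_binary_structure(ndim, rank)


def _ellipsoid(shape: tuple[int, ...], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return dist2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate a seeded phantom mask as a union of filled ellipses.

    Deterministic given the spec; always has at least
    ``MIN_PHANTOM_POSITIVES`` positive elements.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    lo, hi = spec.radius_range
    for _ in range(64):
        mask = np.zeros(shape, dtype=bool)
        for _ in range(spec.n_blobs):
            radii = rng.uniform(lo, hi, size=len(shape))
            center = np.array(
                [rng.uniform(r + 1, s - r - 2) for r, s in zip(radii, shape)]
            )
            mask |= _ellipsoid(shape, center, radii)
        if int(mask.sum()) >= MIN_PHANTOM_POSITIVES:
            return mask
    raise RuntimeError("could not generate a phantom with enough positives")


def _translate(mask: np.ndarray, offset: tuple[int, ...]) -> np.ndarray:
    """Shift a mask by an integer offset, filling with background."""
    out = np.zeros_like(mask)
    src, dst = [], []
    for off, size in zip(offset, mask.shape):
        if abs(off) >= size:
            return out
        if off >= 0:
            src.append(slice(0, size - off))
            dst.append(slice(off, size))
        else:
            src.append(slice(-off, size))
            dst.append(slice(0, size + off))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _errors_within(x: np.ndarray, y: np.ndarray, steps: int, struct: np.ndarray) -> bool:
    """True iff every element of ``y`` outside ``x`` is within ``steps`` dilations of ``x``."""
    extra = y & ~x
    if not extra.any():
        return True
    env = ndimage.binary_dilation(x, structure=struct, iterations=steps)
    return bool((extra & ~env).sum() == 0)


def _fully_fp_fn_components(
    reference: np.ndarray, prediction: np.ndarray, struct: np.ndarray
) -> tuple[int, int]:
    """Counts of prediction components with no reference overlap and vice versa."""

    def count(mask: np.ndarray, other: np.ndarray) -> int:
        labels, n = ndimage.label(mask, structure=struct)
        if n == 0:
            return 0
        overlap = ndimage.labeled_comprehension(
            other, labels, np.arange(1, n + 1), np.any, bool, False
        )
        return int((~overlap).sum())

    return count(prediction, reference), count(reference, prediction)


def rubric_score(
    reference: np.ndarray,
    prediction: np.ndarray,
    rubric: RubricConfig = DEFAULT_RUBRIC,
) -> int:
    """Score a mask pair 0-4 with the programmatic rubric ladder.

    The ladder is evaluated top down: no overlap -> 0; minority overlap ->
    1; any fully-FP/FN component -> 2; errors confined to a one-step
    boundary band and small in total -> 4; one outline nested inside the
    other -> 2; everything else (clearly intersecting outlines, majority
    overlap) -> 3.
    """
    x = as_binary_mask(reference, "reference")
    y = as_binary_mask(prediction, "prediction")
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    struct = _struct(x.ndim, rubric.connectivity)

    nx, ny = int(x.sum()), int(y.sum())
    inter = int((x & y).sum())
    if ny == 0 or nx == 0 or inter == 0:
        return 0
    if inter / min(nx, ny) < rubric.majority_fraction:
        return 1
    n_fp, n_fn = _fully_fp_fn_components(x, y, struct)
    if n_fp or n_fn:
        return 2
    band = rubric.near_perfect_band
    small = (nx + ny - 2 * inter) <= rubric.near_perfect_fraction * nx
    if small and _errors_within(x, y, band, struct) and _errors_within(y, x, band, struct):
        return 4
    # "fully outside or inside the outlines": one mask nested in the other
    # with the two boundaries nowhere touching; a shared boundary stretch
    # means the outlines intersect, which is the good class
    nested = inter == nx or inter == ny
    if nested:
        bx = x & ~ndimage.binary_erosion(x, structure=struct)
        by = y & ~ndimage.binary_erosion(y, structure=struct)
        if not (bx & by).any():
            return 2
    return 3


# ---------------------------------------------------------------------------
# degradations


def _boundary_noise(x: np.ndarray, rng: np.random.Generator,
                    magnitude: float, struct: np.ndarray) -> np.ndarray:
    """Class 4: flip a small random subset of boundary-band pixels."""
    frac = rng.uniform(0.0, magnitude)
    outer = ndimage.binary_dilation(x, structure=struct) & ~x
    inner = x & ~ndimage.binary_erosion(x, structure=struct)
    y = x.copy()
    budget = int(frac * x.sum())
    sites = np.flatnonzero(outer.ravel())
    add = rng.choice(sites, size=min(budget // 2, sites.size), replace=False)
    y.ravel()[add] = True
    sites = np.flatnonzero(inner.ravel())
    rem = rng.choice(sites, size=min(budget // 2, sites.size), replace=False)
    y.ravel()[rem] = False
    # keep removals inside the one-step band of the remaining prediction
    stray = x & ~y & ~ndimage.binary_dilation(y, structure=struct)
    y |= stray
    # drop specks that got detached from the reference by the noise
    labels, n = ndimage.label(y, structure=struct)
    for lab in range(1, n + 1):
        comp = labels == lab
        if not (comp & x).any():
            y &= ~comp
    return y


def _halfspace(shape: tuple[int, ...], rng: np.random.Generator,
               anchor: np.ndarray) -> np.ndarray:
    direction = rng.normal(size=len(shape))
    direction /= np.linalg.norm(direction)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    proj = sum(d * (g - a) for d, g, a in zip(direction, grids, anchor))
    return proj > 0


def _intersecting_outlines(x: np.ndarray, rng: np.random.Generator,
                           struct: np.ndarray) -> np.ndarray:
    """Class 3: dilate one side of the mask two steps, erode the other one."""
    centroid = np.array(ndimage.center_of_mass(x))
    half = _halfspace(x.shape, rng, centroid)
    grown = ndimage.binary_dilation(x, structure=struct, iterations=2)
    y = x | (grown & half)
    if rng.uniform() < 0.7:
        shrunk = ndimage.binary_erosion(x, structure=struct)
        removed = (x & ~shrunk) & ~half
        y = y & ~removed
    return y


def _place_far_blob(x: np.ndarray, rng: np.random.Generator, size_frac: float,
                    gap: int, struct: np.ndarray) -> np.ndarray:
    """A filled ellipse disjoint from ``x`` with at least ``gap`` dilation steps of clearance."""
    forbidden = ndimage.binary_dilation(x, structure=struct, iterations=gap)
    target = max(3.0, size_frac * x.sum())
    ndim = x.ndim
    # radius giving roughly `target` elements for a ball in ndim dimensions
    r = (target / np.pi) ** 0.5 if ndim == 2 else (3 * target / (4 * np.pi)) ** (1 / 3)
    r = max(r, 1.2)
    for _ in range(500):
        center = np.array([rng.uniform(r + 1, s - r - 2) for s in x.shape])
        blob = _ellipsoid(x.shape, center, np.full(ndim, r))
        if blob.any() and not (blob & forbidden).any():
            return blob
    raise RuntimeError("no room to place a disjoint component")


def _nested_or_component(x: np.ndarray, rng: np.random.Generator,
                         gap: int, struct: np.ndarray) -> np.ndarray:
    """Class 2: uniform over/under-segmentation, or one substantial far component."""
    mode = rng.integers(3)
    if mode == 0:  # uniform over-segmentation
        k = int(rng.integers(2, 4))
        return ndimage.binary_dilation(x, structure=struct, iterations=k)
    if mode == 1:  # uniform under-segmentation, falling back to dilation
        shrunk = ndimage.binary_erosion(x, structure=struct, iterations=2)
        if shrunk.sum() >= MIN_PHANTOM_POSITIVES:
            return shrunk
        return ndimage.binary_dilation(x, structure=struct, iterations=2)
    blob = _place_far_blob(x, rng, rng.uniform(0.3, 0.7), gap, struct)
    return x | blob


def _barely_touching(x: np.ndarray, rng: np.random.Generator,
                     struct: np.ndarray) -> np.ndarray:
    """Class 1: translate so only a minority of the areas overlap."""
    ndim = x.ndim
    axes = list(range(ndim))
    rng.shuffle(axes)
    for axis in axes:
        idx = np.nonzero(x)[axis]
        extent = int(idx.max() - idx.min() + 1)
        for sign in rng.permutation([1, -1]):
            for d in range(extent + 1, 0, -1):
                offset = tuple(sign * d if a == axis else 0 for a in range(ndim))
                shifted = _translate(x, offset)
                inter = int((x & shifted).sum())
                denom = min(int(x.sum()), int(shifted.sum()) or 1)
                if 0 < inter / denom <= 0.45:
                    return shifted
    raise RuntimeError("could not construct a barely-touching translation")


def _relocate_far(x: np.ndarray, rng: np.random.Generator, gap: int,
                  struct: np.ndarray) -> np.ndarray:
    """Class 0: move the whole mask so its support clears the reference by > gap steps."""
    forbidden = ndimage.binary_dilation(x, structure=struct, iterations=gap)
    n = int(x.sum())
    bbox = ndimage.find_objects(x.astype(np.int8))[0]
    for _ in range(500):
        offset = tuple(
            int(rng.integers(-(sl.start), s - sl.stop + 1))
            for sl, s in zip(bbox, x.shape)
        )
        shifted = _translate(x, offset)
        if int(shifted.sum()) == n and not (shifted & forbidden).any():
            return shifted
    raise RuntimeError("no room to relocate the mask far from the reference")


def degrade(reference: np.ndarray, spec: DegradationSpec) -> ScoredPair:
    """Produce a prediction degraded to ``spec.score_class``.

    Deterministic given the spec seed.  Raises when the geometry makes the
    requested degradation impossible (e.g. no room to relocate far away).
    """
    x = as_binary_mask(reference, "reference")
    if not x.any():
        raise ValueError("reference mask is empty")
    rng = np.random.default_rng(spec.seed)
    struct = _struct(x.ndim)
    c = spec.score_class
    if c == 4:
        y = _boundary_noise(x, rng, spec.noise_magnitude, struct)
    elif c == 3:
        y = _intersecting_outlines(x, rng, struct)
    elif c == 2:
        y = _nested_or_component(x, rng, spec.far_gap, struct)
    elif c == 1:
        y = _barely_touching(x, rng, struct)
        if rng.uniform() < 0.4:
            y = y | _place_far_blob(x, rng, rng.uniform(0.1, 0.3), spec.far_gap, struct)
    else:
        if rng.uniform() < 0.3:
            y = np.zeros_like(x)
        else:
            try:
                y = _relocate_far(x, rng, spec.far_gap, struct)
            except RuntimeError:
                # grid too small to clear the gap: the all-negative
                # prediction is the other fully-wrong variant
                y = np.zeros_like(x)
    return ScoredPair(reference=x, prediction=y, score=c, provenance=spec)


def make_scored_suite(
    n_pairs: int,
    shape: tuple[int, ...] = (64, 64),
    seed: int = 0,
    radius_range: tuple[float, float] = (3.0, 8.0),
) -> list[ScoredPair]:
    """Generate a balanced suite of scored pairs cycling through classes 0-4.

    Each pair gets its own phantom and its own child seed, so the suite is
    reproducible and individual pairs can be regenerated in isolation.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_pairs) % (2**31)
    pairs: list[ScoredPair] = []
    for i in range(n_pairs):
        ref = generate_phantom(
            PhantomSpec(shape=shape, n_blobs=1, radius_range=radius_range,
                        seed=int(seeds[2 * i]))
        )
        spec = DegradationSpec(score_class=i % 5, seed=int(seeds[2 * i + 1]))
        pairs.append(degrade(ref, spec))
    return pairs


def write_fixture_set(pairs: list[ScoredPair], directory) -> "object":
    """Write pairs to disk (PNG for 2-D, NIfTI for 3-D) with a CSV manifest.

    Returns the manifest as a DataFrame with columns
    ``id, reference_path, prediction_path, score, seed``.
    """
    import pandas as pd

    from .cli_io import write_mask

    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pair in enumerate(pairs):
        ext = ".png" if pair.reference.ndim == 2 else ".nii"
        ref_path = directory / f"pair{i:04d}_ref{ext}"
        pred_path = directory / f"pair{i:04d}_pred{ext}"
        write_mask(pair.reference, ref_path)
        write_mask(pair.prediction, pred_path)
        rows.append(
            {
                "id": f"pair{i:04d}",
                "reference_path": str(ref_path),
                "prediction_path": str(pred_path),
                "score": pair.score,
                "seed": pair.provenance.seed if pair.provenance else -1,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
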