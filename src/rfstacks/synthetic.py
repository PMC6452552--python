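"""Synthetic TEM-like images of the glomerular basement membrane (GBM).

The clinical dataset behind the method is not public, so this module emulates
its documented properties: ribbon-shaped membranes (open strips, closed loops,
or compounds of both) that are darker than the surrounding tissue, a wide
spread of per-image membrane mean intensity, organelle-like background clutter
whose gray level is deliberately close to the membrane's (the hard,
low-contrast case), a linear illumination gradient, and additive Gaussian
noise.  Every image comes with an exact binary ground-truth mask.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import interpolate, ndimage

Morphology = Literal["strip", "closed", "compound"]

_MAX_GEOMETRY_RETRIES = 10


class GeometryError(RuntimeError):
    """Raised when no valid membrane curve fits the frame after retries."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic GBM image.

    Gray quantities are in 8-bit gray levels; lengths in pixels.  The membrane
    is drawn darker than the background by default (electron-dense GBM), with
    the sign controlled by ``membrane_darker``.
    """

    morphology: Morphology = "strip"
    height: int = 217
    width: int = 307
    gbm_mean: float = 110.0
    gbm_contrast: float = 30.0
    ribbon_width_range: tuple[float, float] = (3.0, 8.0)
    noise_sigma: float = 6.0
    illumination_amplitude: float = 10.0
    clutter_density: float = 1.0
    membrane_darker: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gbm_mean <= 255.0:
            raise ValueError(f"gbm_mean must be in [0, 255], got {self.gbm_mean}")
        if self.gbm_contrast < 0:
            raise ValueError("gbm_contrast must be >= 0")
        lo, hi = self.ribbon_width_range
        if lo < 1 or hi < lo:
            raise ValueError("ribbon widths must satisfy 1 <= min <= max")
        if self.height < 16 or self.width < 16:
            raise ValueError("frame must be at least 16x16 pixels")
        if self.noise_sigma < 0 or self.illumination_amplitude < 0:
            raise ValueError("noise_sigma and illumination_amplitude must be >= 0")
        if self.clutter_density < 0:
            raise ValueError("clutter_density must be >= 0")

    def replace(self, **kwargs) -> "SyntheticSpec":
        return dataclasses.replace(self, **kwargs)


@dataclass
class LabeledImage:
    """An 8-bit grayscale image paired with its binary GBM mask."""

    image: np.ndarray  # uint8, shape (H, W)
    mask: np.ndarray  # bool, shape (H, W)
    provenance: SyntheticSpec | str | None = None

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if self.mask.dtype != bool:
            raise ValueError("mask must be boolean")

    @property
    def mask_mean(self) -> float:
        """Mean image intensity over mask pixels (the image's GBM gray level)."""
        if not self.mask.any():
            raise ValueError("mask is empty; GBM mean undefined")
        return float(self.image[self.mask].mean())


# ---------------------------------------------------------------------------
# Curve models
# ---------------------------------------------------------------------------

def _strip_curve(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Open cubic spline crossing the frame, as dense (row, col) samples."""
    n_ctrl = rng.integers(4, 7)
    # control points march across the longer axis with jitter on the other
    if w >= h:
        cols = np.linspace(0.05 * w, 0.95 * w, n_ctrl)
        rows = rng.uniform(0.2 * h, 0.8 * h, size=n_ctrl)
    else:
        rows = np.linspace(0.05 * h, 0.95 * h, n_ctrl)
        cols = rng.uniform(0.2 * w, 0.8 * w, size=n_ctrl)
    tck, _ = interpolate.splprep([rows, cols], s=0, k=3)
    t = np.linspace(0.0, 1.0, 4 * (h + w))
    r, c = interpolate.splev(t, tck)
    return np.column_stack([r, c])


def _closed_curve(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Radially perturbed ellipse (closed contour), dense (row, col) samples."""
    cr = rng.uniform(0.4 * h, 0.6 * h)
    cc = rng.uniform(0.4 * w, 0.6 * w)
    ar = rng.uniform(0.18, 0.30) * h
    ac = rng.uniform(0.18, 0.30) * w
    theta = np.linspace(0.0, 2.0 * np.pi, 4 * (h + w), endpoint=False)
    # smooth periodic perturbation: a few low-order harmonics
    pert = np.zeros_like(theta)
    for k in range(2, 5):
        pert += rng.uniform(0.0, 0.08) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    r = cr + ar * (1.0 + pert) * np.sin(theta)
    c = cc + ac * (1.0 + pert) * np.cos(theta)
    return np.column_stack([r, c])


def _rasterize_ribbon(
    curve: np.ndarray,
    shape: tuple[int, int],
    rng: np.random.Generator,
    width_range: tuple[float, float],
) -> np.ndarray:
    """Dilate a sampled curve to a ribbon of smoothly varying half-width."""
    h, w = shape
    rr = np.clip(np.round(curve[:, 0]).astype(int), 0, h - 1)
    cc = np.clip(np.round(curve[:, 1]).astype(int), 0, w - 1)
    spine = np.zeros(shape, dtype=bool)
    spine[rr, cc] = True

    # smooth half-width profile along the curve
    lo, hi = width_range
    n_knots = 6
    knots = rng.uniform(lo, hi, size=n_knots)
    prof = np.interp(np.linspace(0, 1, len(curve)), np.linspace(0, 1, n_knots), knots)
    width_at = np.zeros(shape)
    # last write wins where samples collide; profile is smooth so it hardly matters
    width_at[rr, cc] = prof

    dist, (ir, ic) = ndimage.distance_transform_edt(~spine, return_indices=True)
    return dist <= width_at[ir, ic]


def _curve_for(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    if spec.morphology == "strip":
        return _strip_curve(rng, h, w)
    if spec.morphology == "closed":
        return _closed_curve(rng, h, w)
    if spec.morphology == "compound":
        return np.vstack([_strip_curve(rng, h, w), _closed_curve(rng, h, w)])
    raise ValueError(f"unknown morphology {spec.morphology!r}")


def _mask_is_valid(mask: np.ndarray, spec: SyntheticSpec) -> bool:
    frac = mask.mean()
    if not 0.01 <= frac <= 0.5:
        return False
    if spec.morphology in ("closed", "compound"):
        # the loop must enclose a lumen: background splits into >= 2 components
        n_bg = ndimage.label(~mask)[1]
        if n_bg < 2:
            return False
    return True


# ---------------------------------------------------------------------------
# Intensity model
# ---------------------------------------------------------------------------

def _paint_membrane(
    img: np.ndarray, mask: np.ndarray, gbm_mean: float, rng: np.random.Generator
) -> None:
    """Paint mask pixels so their mean equals gbm_mean exactly (pre-noise).

    A smooth integer-valued texture is added for realism, then its residual sum
    over the mask is cancelled pixel-by-pixel so the mask mean is exact even
    after 8-bit quantization (when gbm_mean itself is representable).
    """
    texture = ndimage.gaussian_filter(rng.normal(0.0, 6.0, size=img.shape), 3.0)
    t = np.round(texture).astype(np.int64)
    vals = np.round(gbm_mean + t[mask]).astype(np.int64)
    np.clip(vals, 0, 255, out=vals)
    target_sum = int(round(gbm_mean * mask.sum()))
    resid = int(vals.sum() - target_sum)
    if resid != 0:
        step = 1 if resid > 0 else -1
        # walk pixels in a fixed order, nudging by 1 gray level each
        order = np.argsort(vals if step > 0 else -vals, kind="stable")[::-1]
        i = 0
        while resid != 0 and i < len(order):
            j = order[i]
            nv = vals[j] - step
            if 0 <= nv <= 255:
                vals[j] = nv
                resid -= step
            i += 1
    img[mask] = vals.astype(np.float64)


def _add_clutter(
    img: np.ndarray, mask: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> None:
    """Organelle-like blobs in the background, gray level near the membrane's."""
    h, w = img.shape
    n = rng.poisson(spec.clutter_density * h * w / 1e4)
    for _ in range(n):
        cr = rng.uniform(0, h)
        cc = rng.uniform(0, w)
        a = rng.uniform(3.0, 10.0)
        b = rng.uniform(3.0, 10.0)
        ang = rng.uniform(0, np.pi)
        level = spec.gbm_mean + rng.uniform(-15.0, 15.0)
        rr, cols = np.ogrid[:h, :w]
        dr = rr - cr
        dc = cols - cc
        u = dr * np.cos(ang) + dc * np.sin(ang)
        v = -dr * np.sin(ang) + dc * np.cos(ang)
        blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        blob &= ~mask
        img[blob] = level


def generate_membrane(spec: SyntheticSpec) -> LabeledImage:
    """Generate one synthetic TEM image with its exact ground-truth mask.

    The membrane is a smooth random curve (open spline for ``strip``, perturbed
    closed contour for ``closed``, union of both for ``compound``) dilated to a
    spatially varying width.  Membrane pixels average exactly ``gbm_mean``
    before noise; the background sits at ``gbm_mean ± gbm_contrast`` (darker
    membrane by default).  Clutter blobs and the illumination ramp affect only
    the background; Gaussian noise is applied last and the result is clipped
    to [0, 255].

    Raises
    ------
    GeometryError
        If no valid curve fits the frame after a bounded number of retries.
    """
    rng = np.random.default_rng(spec.seed)
    mask = None
    for _ in range(_MAX_GEOMETRY_RETRIES):
        curve = _curve_for(spec, rng)
        cand = _rasterize_ribbon(curve, (spec.height, spec.width), rng, spec.ribbon_width_range)
        if _mask_is_valid(cand, spec):
            mask = cand
            break
    if mask is None:
        raise GeometryError(
            f"no valid {spec.morphology} membrane fit a "
            f"{spec.height}x{spec.width} frame after {_MAX_GEOMETRY_RETRIES} tries"
        )

    sign = 1.0 if spec.membrane_darker else -1.0
    bg_mean = float(np.clip(spec.gbm_mean + sign * spec.gbm_contrast, 0.0, 255.0))

    img = np.full((spec.height, spec.width), bg_mean, dtype=np.float64)
    # background texture
    img += ndimage.gaussian_filter(rng.normal(0.0, 8.0, size=img.shape), 2.0)
    _add_clutter(img, mask, spec, rng)
    if spec.illumination_amplitude > 0:
        ang = rng.uniform(0, 2 * np.pi)
        rr, cc = np.mgrid[: spec.height, : spec.width]
        ramp = (rr / max(spec.height - 1, 1)) * np.sin(ang) + (
            cc / max(spec.width - 1, 1)
        ) * np.cos(ang)
        ramp -= ramp.mean()
        span = ramp.max() - ramp.min()
        if span > 0:
            img += spec.illumination_amplitude * ramp / span

    _paint_membrane(img, mask, spec.gbm_mean, rng)

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    out = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return LabeledImage(image=out, mask=mask, provenance=spec)


# ---------------------------------------------------------------------------
# Grouped dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrayscaleGroup:
    """One contiguous bin of mean GBM intensity; interval is half-open [lo, hi)."""

    index: int  # 1-based
    lo: float
    hi: float

    def contains(self, value: float) -> bool:
        return self.lo <= value < self.hi


@dataclass
class GroupedTrainingSet:
    groups: list[GrayscaleGroup]
    images: dict[int, list[LabeledImage]] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def make_groups(n_groups: int, mean_start: float, bin_width: float) -> list[GrayscaleGroup]:
    """Contiguous half-open intensity bins: group g covers
    [mean_start + (g-1)*bin_width, mean_start + g*bin_width)."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    return [
        GrayscaleGroup(index=g, lo=mean_start + (g - 1) * bin_width, hi=mean_start + g * bin_width)
        for g in range(1, n_groups + 1)
    ]


_MORPHOLOGY_CYCLE: tuple[Morphology, ...] = ("strip", "closed", "compound")


def generate_grouped_dataset(
    n_groups: int,
    images_per_group: int,
    mean_start: float,
    bin_width: float,
    base_spec: SyntheticSpec | None = None,
    seed: int = 0,
) -> GroupedTrainingSet:
    """Generate a training set binned by mean GBM intensity.

    For group g (1-based) each image's target membrane mean is drawn uniformly
    from the group's half-open bin; the realized mask mean is verified to fall
    in the bin (regenerated with an interior target on the rare quantization
    near-miss).  Morphologies cycle through strip/closed/compound.
    """
    if images_per_group < 1:
        raise ValueError("images_per_group must be >= 1")
    base = base_spec or SyntheticSpec()
    groups = make_groups(n_groups, mean_start, bin_width)
    rng = np.random.default_rng(seed)
    out = GroupedTrainingSet(groups=groups, images={g.index: [] for g in groups})
    for grp in groups:
        for i in range(images_per_group):
            target = rng.uniform(grp.lo, grp.hi)
            morph = _MORPHOLOGY_CYCLE[i % len(_MORPHOLOGY_CYCLE)]
            child_seed = int(rng.integers(0, 2**31 - 1))
            labeled = _generate_in_bin(base, morph, target, grp, child_seed)
            out.images[grp.index].append(labeled)
    return out


def _generate_in_bin(
    base: SyntheticSpec,
    morph: Morphology,
    target: float,
    grp: GrayscaleGroup,
    seed: int,
) -> LabeledImage:
    spec = base.replace(morphology=morph, gbm_mean=float(target), seed=seed)
    labeled = generate_membrane(spec)
    if grp.contains(labeled.mask_mean):
        return labeled
    # quantization pushed the realized mean over the bin edge: aim at the centre
    warnings.warn(
        f"realized GBM mean {labeled.mask_mean:.2f} left bin "
        f"[{grp.lo}, {grp.hi}); regenerating at bin centre",
        stacklevel=2,
    )
    spec = base.replace(morphology=morph, gbm_mean=0.5 * (grp.lo + grp.hi), seed=seed + 1)
    labeled = generate_membrane(spec)
    if not grp.contains(labeled.mask_mean):
        raise GeometryError(f"could not realize a GBM mean inside bin [{grp.lo}, {grp.hi})")
    return labeled
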