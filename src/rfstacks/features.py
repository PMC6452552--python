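"""Per-pixel feature stacks for trainable pixel classification.

The stack follows the trainable-segmentation convention: local statistics
(mean/min/max/median/variance), boundary responses (Sobel magnitude, Hessian
eigenvalues, differences of Gaussians), texture responses (Gaussian blur,
local entropy, Kuwahara), plus membrane projections (directional line-kernel
responses), the lower Lipschitz cover, and raw shifted-neighbor values.
Scale-parameterized families emit one channel per scale; border handling is
by reflection throughout; channel order is deterministic and recorded in
``channel_names`` so trained models can refuse mismatched configurations.

Anisotropic diffusion and bilateral filtering are implemented but off by
default: diffusion is costly and degrades membrane accuracy in this pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import rank
from skimage.morphology import disk
from skimage.restoration import denoise_bilateral

DEFAULT_FAMILIES: tuple[str, ...] = (
    "mean",
    "minimum",
    "maximum",
    "median",
    "variance",
    "sobel",
    "hessian",
    "difference_of_gaussians",
    "gaussian_blur",
    "entropy",
    "kuwahara",
    "membrane_projections",
    "lipschitz",
    "neighbors",
)

# optional extras, off by default
EXTRA_FAMILIES: tuple[str, ...] = ("anisotropic_diffusion", "bilateral")

_EIGHT_NEIGHBORS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)


@dataclass(frozen=True)
class FeatureConfig:
    enabled_families: tuple[str, ...] = DEFAULT_FAMILIES
    scales: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0)
    membrane_kernel_size: int = 19
    membrane_orientations: int = 6
    neighbor_offsets: tuple[tuple[int, int], ...] = _EIGHT_NEIGHBORS
    lipschitz_slope: float = 10.0

    def __post_init__(self) -> None:
        if not self.enabled_families:
            raise ValueError("enabled_families must be non-empty")
        known = set(DEFAULT_FAMILIES) | set(EXTRA_FAMILIES)
        unknown = set(self.enabled_families) - known
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        s = tuple(self.scales)
        if any(x <= 0 for x in s) or any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scales must be positive and strictly increasing")

    def channel_names(self) -> list[str]:
        """Deterministic channel order implied by this configuration."""
        names: list[str] = []
        for fam in self.enabled_families:
            names.extend(_family_channel_names(fam, self))
        return names


@dataclass
class FeatureStack:
    values: np.ndarray  # float32, (H, W, F)
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != len(self.channel_names):
            raise ValueError("values depth must match channel_names")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def as_matrix(self) -> np.ndarray:
        """(H*W, F) view for classifier input, row-major pixel order."""
        h, w, f = self.values.shape
        return self.values.reshape(h * w, f)


def _family_channel_names(family: str, cfg: FeatureConfig) -> list[str]:
    scales = cfg.scales
    if family in ("mean", "minimum", "maximum", "median", "variance",
                  "sobel", "gaussian_blur", "entropy", "kuwahara",
                  "anisotropic_diffusion", "bilateral"):
        return [f"{family}_s{_fmt(s)}" for s in scales]
    if family == "hessian":
        return [f"hessian_{which}_s{_fmt(s)}" for s in scales for which in ("eig1", "eig2")]
    if family == "difference_of_gaussians":
        return [
            f"dog_s{_fmt(a)}_s{_fmt(b)}"
            for i, a in enumerate(scales)
            for b in scales[i + 1:]
        ]
    if family == "membrane_projections":
        return [f"membrane_{red}" for red in ("sum", "mean", "std", "median", "max", "min")]
    if family == "lipschitz":
        return ["lipschitz"]
    if family == "neighbors":
        return [f"neighbor_{dr}_{dc}" for dr, dc in cfg.neighbor_offsets]
    raise ValueError(f"unknown family {family!r}")


def _fmt(s: float) -> str:
    return f"{s:g}"


# ---------------------------------------------------------------------------
# Family implementations (float64 internally, reflect borders)
# ---------------------------------------------------------------------------

def _radius(scale: float) -> int:
    return max(1, int(round(scale)))


def _local_stats(img: np.ndarray, cfg: FeatureConfig, stat: str) -> list[np.ndarray]:
    out = []
    for s in cfg.scales:
        fp = disk(_radius(s))
        if stat == "mean":
            k = fp / fp.sum()
            out.append(ndimage.correlate(img, k, mode="reflect"))
        elif stat == "minimum":
            out.append(ndimage.minimum_filter(img, footprint=fp, mode="reflect"))
        elif stat == "maximum":
            out.append(ndimage.maximum_filter(img, footprint=fp, mode="reflect"))
        elif stat == "median":
            out.append(ndimage.median_filter(img, footprint=fp, mode="reflect"))
        elif stat == "variance":
            k = fp / fp.sum()
            m = ndimage.correlate(img, k, mode="reflect")
            m2 = ndimage.correlate(img * img, k, mode="reflect")
            out.append(np.maximum(m2 - m * m, 0.0))
    return out


def _sobel(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    out = []
    for s in cfg.scales:
        g = ndimage.gaussian_filter(img, s, mode="reflect")
        out.append(np.hypot(
            ndimage.sobel(g, axis=0, mode="reflect"),
            ndimage.sobel(g, axis=1, mode="reflect"),
        ))
    return out


def _hessian(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    out = []
    for s in cfg.scales:
        hrr = ndimage.gaussian_filter(img, s, order=(2, 0), mode="reflect")
        hcc = ndimage.gaussian_filter(img, s, order=(0, 2), mode="reflect")
        hrc = ndimage.gaussian_filter(img, s, order=(1, 1), mode="reflect")
        tr = hrr + hcc
        det = hrr * hcc - hrc * hrc
        disc = np.sqrt(np.maximum(tr * tr / 4.0 - det, 0.0))
        out.append(tr / 2.0 + disc)  # largest eigenvalue
        out.append(tr / 2.0 - disc)  # smallest eigenvalue
    return out


def _dog(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    blurred = {s: ndimage.gaussian_filter(img, s, mode="reflect") for s in cfg.scales}
    out = []
    for i, a in enumerate(cfg.scales):
        for b in cfg.scales[i + 1:]:
            out.append(blurred[a] - blurred[b])
    return out


def _gaussian_blur(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    return [ndimage.gaussian_filter(img, s, mode="reflect") for s in cfg.scales]


def _entropy(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    u8 = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return [rank.entropy(u8, disk(_radius(s))).astype(np.float64) for s in cfg.scales]


def _kuwahara_one(img: np.ndarray, r: int) -> np.ndarray:
    """Kuwahara filter: mean of the least-variance quadrant window.

    Quadrants are odd (2h+1)-sized windows centred at the four diagonal
    offsets (+-h, +-h) from the pixel, each containing the pixel itself.
    """
    h = max(1, r)
    k = 2 * h + 1
    pad = np.pad(img, h, mode="reflect")
    m_full = ndimage.uniform_filter(pad, size=k, mode="reflect")
    m2_full = ndimage.uniform_filter(pad * pad, size=k, mode="reflect")
    H, W = img.shape
    means, varis = [], []
    for dr in (-h, h):
        for dc in (-h, h):
            sl = (slice(h + dr, h + dr + H), slice(h + dc, h + dc + W))
            m = m_full[sl]
            v = np.maximum(m2_full[sl] - m * m, 0.0)
            means.append(m)
            varis.append(v)
    means_a = np.stack(means)
    varis_a = np.stack(varis)
    pick = np.argmin(varis_a, axis=0)
    return np.take_along_axis(means_a, pick[None], axis=0)[0]


def _kuwahara(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    return [_kuwahara_one(img, _radius(s)) for s in cfg.scales]


def _membrane_projections(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    """Line-kernel responses at evenly spaced orientations, reduced across
    orientations by sum/mean/std/median/max/min."""
    ksz = cfg.membrane_kernel_size
    base = np.zeros((ksz, ksz))
    base[:, ksz // 2] = 1.0
    responses = []
    for i in range(cfg.membrane_orientations):
        ang = 180.0 * i / cfg.membrane_orientations
        kern = ndimage.rotate(base, ang, reshape=False, order=1)
        responses.append(ndimage.correlate(img, kern, mode="reflect"))
    stack = np.stack(responses)
    return [
        stack.sum(axis=0),
        stack.mean(axis=0),
        stack.std(axis=0),
        np.median(stack, axis=0),
        stack.max(axis=0),
        stack.min(axis=0),
    ]


def _lipschitz_cover(img: np.ndarray, slope: float) -> np.ndarray:
    """Lower Lipschitz cover: the largest slope-bounded function <= the image.

    Computed as the grayscale erosion by a cone, via forward/backward chamfer
    passes iterated to a fixed point (two passes suffice on a grid).
    """
    u = img.astype(np.float64).copy()
    d1, d2 = slope, slope * np.sqrt(2.0)
    h, w = u.shape
    changed = True
    passes = 0
    while changed and passes < 4:
        changed = False
        # forward raster
        for i in range(h):
            for j in range(w):
                best = u[i, j]
                if j > 0:
                    best = min(best, u[i, j - 1] + d1)
                if i > 0:
                    best = min(best, u[i - 1, j] + d1)
                    if j > 0:
                        best = min(best, u[i - 1, j - 1] + d2)
                    if j < w - 1:
                        best = min(best, u[i - 1, j + 1] + d2)
                if best < u[i, j]:
                    u[i, j] = best
                    changed = True
        # backward raster
        for i in range(h - 1, -1, -1):
            for j in range(w - 1, -1, -1):
                best = u[i, j]
                if j < w - 1:
                    best = min(best, u[i, j + 1] + d1)
                if i < h - 1:
                    best = min(best, u[i + 1, j] + d1)
                    if j < w - 1:
                        best = min(best, u[i + 1, j + 1] + d2)
                    if j > 0:
                        best = min(best, u[i + 1, j - 1] + d2)
                if best < u[i, j]:
                    u[i, j] = best
                    changed = True
        passes += 1
    return u


def _neighbors(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    out = []
    for dr, dc in cfg.neighbor_offsets:
        pad = max(abs(dr), abs(dc))
        p = np.pad(img, pad, mode="reflect")
        h, w = img.shape
        out.append(p[pad + dr: pad + dr + h, pad + dc: pad + dc + w])
    return out


def _anisotropic_diffusion(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    """Perona-Malik diffusion, exponential conductance, iterations ~ scale."""
    out = []
    for s in cfg.scales:
        u = img.astype(np.float64).copy()
        kappa = 30.0
        for _ in range(int(round(5 * s))):
            dn = np.diff(u, axis=0, prepend=u[:1])
            ds = np.diff(u[::-1], axis=0, prepend=u[-1:][::-1])[::-1]
            de = np.diff(u[:, ::-1], axis=1, prepend=u[:, -1:][:, ::-1])[:, ::-1]
            dw = np.diff(u, axis=1, prepend=u[:, :1])
            c = lambda g: np.exp(-((g / kappa) ** 2))
            u = u + 0.2 * (c(dn) * -dn + c(ds) * -ds + c(de) * -de + c(dw) * -dw)
        out.append(u)
    return out


def _bilateral(img: np.ndarray, cfg: FeatureConfig) -> list[np.ndarray]:
    u = img / 255.0
    return [
        denoise_bilateral(u, sigma_color=0.1, sigma_spatial=float(s)) * 255.0
        for s in cfg.scales
    ]


_FAMILY_IMPL = {
    "mean": lambda img, cfg: _local_stats(img, cfg, "mean"),
    "minimum": lambda img, cfg: _local_stats(img, cfg, "minimum"),
    "maximum": lambda img, cfg: _local_stats(img, cfg, "maximum"),
    "median": lambda img, cfg: _local_stats(img, cfg, "median"),
    "variance": lambda img, cfg: _local_stats(img, cfg, "variance"),
    "sobel": _sobel,
    "hessian": _hessian,
    "difference_of_gaussians": _dog,
    "gaussian_blur": _gaussian_blur,
    "entropy": _entropy,
    "kuwahara": _kuwahara,
    "membrane_projections": _membrane_projections,
    "lipschitz": lambda img, cfg: [_lipschitz_cover(img, cfg.lipschitz_slope)],
    "neighbors": _neighbors,
    "anisotropic_diffusion": _anisotropic_diffusion,
    "bilateral": _bilateral,
}


def compute_feature_stack(image: np.ndarray, cfg: FeatureConfig) -> FeatureStack:
    """Compute the per-pixel feature stack for an 8-bit grayscale image.

    Families are computed independently, so disabling one leaves the remaining
    channels bit-identical.
    """
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    img = image.astype(np.float64)
    channels: list[np.ndarray] = []
    names: list[str] = []
    for fam in cfg.enabled_families:
        maps = _FAMILY_IMPL[fam](img, cfg)
        fam_names = _family_channel_names(fam, cfg)
        assert len(maps) == len(fam_names)
        channels.extend(maps)
        names.extend(fam_names)
    values = np.stack(channels, axis=-1).astype(np.float32)
    if not np.isfinite(values).all():
        raise ValueError("feature stack contains non-finite values")
    return FeatureStack(values=values, channel_names=names)
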