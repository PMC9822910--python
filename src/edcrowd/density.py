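"""Density-map ground truth from head-point annotations.

Each annotated head contributes one truncated Gaussian kernel (default size
15, sigma 4) centred on its pixel.  Kernels are renormalized to unit mass
after boundary truncation, so the total pixel value of the density map equals
the number of annotated heads exactly — including heads at image corners,
where plain Gaussian filtering would lose mass off the edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DensityConfig",
    "DensityMap",
    "annotation_map",
    "density_from_annotations",
    "count_from_density",
    "gaussian_kernel",
]


@dataclass(frozen=True)
class DensityConfig:
    """Gaussian kernel parameters for density-map generation."""

    kernel_size: int = 15
    sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.kernel_size <= 0 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and positive, got {self.kernel_size}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass
class DensityMap:
    """Non-negative grid whose total mass equals the source head count."""

    values: np.ndarray = field(repr=False)
    source_count: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("density values must be non-negative")
        total = float(self.values.sum())
        if self.source_count and abs(total - self.source_count) > 1e-6 * max(
            self.source_count, 1
        ):
            raise ValueError(
                f"density mass {total} does not match source count {self.source_count}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def total(self) -> float:
        return float(self.values.sum())


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Unit-mass 2-D Gaussian kernel, truncated to ``size`` x ``size``."""
    half = size // 2
    ax = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _check_heads(heads, shape: tuple[int, int]) -> np.ndarray:
    pts = np.asarray(heads, dtype=np.float64).reshape(-1, 2)
    h, w = shape
    for x, y in pts:
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(
                f"annotation ({x}, {y}) outside image bounds {w}x{h} (x=col, y=row)"
            )
    return pts


def annotation_map(scene) -> np.ndarray:
    """Impulse grid: value at each annotated pixel is its head multiplicity.

    ``scene`` is anything with ``image`` and ``heads`` attributes (an
    :class:`~edcrowd.scenes.AnnotatedScene`).  Coincident heads accumulate,
    so the grid sums to the head count.
    """
    img = np.asarray(scene.image)
    shape = img.shape[:2]
    pts = _check_heads(scene.heads, shape)
    grid = np.zeros(shape, dtype=np.float64)
    if len(pts):
        cols = pts[:, 0].astype(np.intp)
        rows = pts[:, 1].astype(np.intp)
        np.add.at(grid, (rows, cols), 1.0)
    return grid


def density_from_annotations(scene, config: DensityConfig | None = None) -> DensityMap:
    """Ground-truth density map with exact mass conservation.

    Every head deposits the truncated Gaussian kernel centred on its pixel;
    the in-bounds portion is rescaled to unit mass, so border and corner
    heads still contribute exactly one person to the map total.
    """
    config = config or DensityConfig()
    img = np.asarray(scene.image)
    h, w = img.shape[:2]
    pts = _check_heads(scene.heads, (h, w))
    kernel = gaussian_kernel(config.kernel_size, config.sigma)
    half = config.kernel_size // 2
    out = np.zeros((h, w), dtype=np.float64)
    for x, y in pts:
        r, c = int(y), int(x)
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        patch = kernel[r0 - r + half : r1 - r + half, c0 - c + half : c1 - c + half]
        out[r0:r1, c0:c1] += patch / patch.sum()
    return DensityMap(values=out, source_count=len(pts))


def count_from_density(density) -> float:
    """Total mass of a density map (= the people count it encodes)."""
    if isinstance(density, DensityMap):
        return density.total()
    return float(np.asarray(density, dtype=np.float64).sum())
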