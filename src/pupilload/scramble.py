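"""Baseline-image generation by pixel scrambling.

A baseline image is what the participant fixates before a task so that an
individual reference pupil size can be estimated.  Uniform white or black
slides are the classical choice, but they drive a strong pupillary light
reflex when the screen switches to the actual game frame.  Scrambling a
representative in-game frame preserves the global mean intensity of the
scene; the grid variant additionally preserves the *local* mean intensity by
permuting pixels only within the cells of an n x m grid (n columns, m rows),
so the retina sees roughly the same coarse luminance layout before and after
the transition while the semantic content of the frame is destroyed.

Images are numpy arrays of dtype uint8, either ``(H, W)`` grayscale or
``(H, W, 3)`` RGB.  RGB pixels are always permuted as intact triplets so the
joint colour distribution of the scene is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScrambleSpec",
    "uniform_baseline",
    "whole_scramble",
    "grid_scramble",
    "mean_intensity",
    "make_baseline_image",
    "grid_edges",
]

#: Rec. 709 luma weights used for grayscale conversion of RGB images.
_LUMA = np.array([0.2126, 0.7152, 0.0722])

METHODS = ("white", "black", "scramble", "grid_scramble")


@dataclass(frozen=True)
class ScrambleSpec:
    """Which baseline-image method to apply, and its grid geometry."""

    method: str
    n_cols: int = 1
    m_rows: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.n_cols < 1 or self.m_rows < 1:
            raise ValueError("grid dimensions must be >= 1")


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 2:
        pass
    elif image.ndim == 3 and image.shape[2] == 3:
        pass
    else:
        raise ValueError("image must be (H, W) grayscale or (H, W, 3) RGB")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must have positive dimensions")
    if image.dtype != np.uint8:
        if np.any((image < 0) | (image > 255)):
            raise ValueError("intensities must lie in [0, 255]")
        image = image.astype(np.uint8)
    return image


def uniform_baseline(width: int, height: int, color: str) -> np.ndarray:
    """A constant white (255) or black (0) slide of the given size."""
    if width < 1 or height < 1:
        raise ValueError("dimensions must be positive")
    if color == "white":
        value = 255
    elif color == "black":
        value = 0
    else:
        raise ValueError(f"color must be 'white' or 'black', got {color!r}")
    return np.full((height, width), value, dtype=np.uint8)


def whole_scramble(image: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniformly permute all pixels of the image.

    The pixel multiset — and therefore the mean intensity — is conserved
    exactly; only spatial arrangement is destroyed.
    """
    return grid_scramble(image, 1, 1, seed)


def grid_edges(size: int, n: int) -> np.ndarray:
    """Cell boundaries splitting ``size`` pixels into ``n`` contiguous runs.

    Uses floor division; the last run absorbs any remainder so the partition
    is exact.
    """
    if n > size:
        raise ValueError(f"grid of {n} cells larger than image extent {size}")
    step = size // n
    edges = np.arange(n + 1) * step
    edges[-1] = size
    return edges


def grid_scramble(
    image: np.ndarray, n_cols: int, m_rows: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Permute pixels independently within each cell of an n x m grid.

    Cells are rectangular, contiguous, and partition the image exactly; no
    pixel ever crosses a cell boundary, so every cell's pixel multiset — and
    its mean intensity — is preserved.  Cells consume random draws in
    row-major order from a single generator, so output is a pure function of
    (image, grid, seed).
    """
    image = _check_image(image)
    h, w = image.shape[:2]
    x_edges = grid_edges(w, n_cols)
    y_edges = grid_edges(h, m_rows)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = image.copy()
    for yi in range(m_rows):
        for xi in range(n_cols):
            ys, ye = y_edges[yi], y_edges[yi + 1]
            xs, xe = x_edges[xi], x_edges[xi + 1]
            cell = out[ys:ye, xs:xe]
            flat = cell.reshape(-1, *cell.shape[2:])  # pixels (RGB kept intact)
            perm = rng.permutation(flat.shape[0])
            out[ys:ye, xs:xe] = flat[perm].reshape(cell.shape)
    return out


def mean_intensity(image: np.ndarray) -> float:
    """Arithmetic mean of the grayscale-converted pixel values, in [0, 255]."""
    image = _check_image(image)
    if image.ndim == 3:
        gray = image.astype(float) @ _LUMA
    else:
        gray = image.astype(float)
    return float(gray.mean())


def make_baseline_image(frame: np.ndarray, spec: ScrambleSpec) -> np.ndarray:
    """Generate the baseline image named by ``spec`` from an in-test frame."""
    frame = _check_image(frame)
    h, w = frame.shape[:2]
    if spec.method == "white":
        return uniform_baseline(w, h, "white")
    if spec.method == "black":
        return uniform_baseline(w, h, "black")
    if spec.method == "scramble":
        return whole_scramble(frame, spec.seed)
    if spec.method == "grid_scramble":
        return grid_scramble(frame, spec.n_cols, spec.m_rows, spec.seed)
    raise ValueError(f"unknown baseline method {spec.method!r}")
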