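"""Seeded 2-D gradient (Perlin) noise.

Classic lattice gradient noise with quintic fade interpolation.  Used to
fade random regions of felt-pen overlays and to texture synthetic slide
backgrounds.  ``cells`` controls the spatial frequency: roughly that many
noise cells span each image axis.
"""

from __future__ import annotations

import numpy as np


def _fade(t: np.ndarray) -> np.ndarray:
    # 6t^5 - 15t^4 + 10t^3: C2-continuous ramp on [0, 1]
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def perlin_field(
    shape: tuple[int, int],
    cells: float = 4.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a gradient-noise field over an ``(H, W)`` pixel grid.

    Returns roughly zero-mean values in about [-0.75, 0.75]; deterministic
    for a given generator state.
    """
    if cells <= 0:
        raise ValueError(f"cells must be positive, got {cells}")
    rng = rng if rng is not None else np.random.default_rng()
    h, w = int(shape[0]), int(shape[1])

    # lattice of random unit gradients, one cell of padding
    ny, nx = int(np.ceil(cells)) + 2, int(np.ceil(cells)) + 2
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(ny, nx))
    gy, gx = np.sin(angles), np.cos(angles)

    ys = (np.arange(h) + 0.5) / h * cells
    xs = (np.arange(w) + 0.5) / w * cells
    yy, xx = np.meshgrid(ys, xs, indexing="ij")

    y0 = np.floor(yy).astype(int)
    x0 = np.floor(xx).astype(int)
    fy, fx = yy - y0, xx - x0

    def corner_dot(dy: int, dx: int) -> np.ndarray:
        gyc = gy[y0 + dy, x0 + dx]
        gxc = gx[y0 + dy, x0 + dx]
        return gxc * (fx - dx) + gyc * (fy - dy)

    u, v = _fade(fx), _fade(fy)
    top = corner_dot(0, 0) * (1 - u) + corner_dot(0, 1) * u
    bottom = corner_dot(1, 0) * (1 - u) + corner_dot(1, 1) * u
    return top * (1 - v) + bottom * v


def normalized_perlin(
    shape: tuple[int, int],
    cells: float = 4.0,
    rng: np.random.Generator | None = None,
    threshold: float | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """A Perlin field mapped into [0, 1].

    With ``normalize`` the raw field is min-max rescaled to span [0, 1]
    exactly; otherwise it is shifted/clipped as ``(value + 1) / 2``.  Values
    below ``threshold`` (if given) are zeroed afterwards, which sharpens the
    faded-region boundary.
    """
    field = perlin_field(shape, cells, rng)
    if normalize:
        lo, hi = field.min(), field.max()
        field = np.zeros_like(field) if hi - lo < 1e-12 else (field - lo) / (hi - lo)
    else:
        field = np.clip((field + 1.0) / 2.0, 0.0, 1.0)
    if threshold is not None:
        field = np.where(field < threshold, 0.0, field)
    return field
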