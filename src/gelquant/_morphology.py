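"""Rolling-ball style background estimation.

The background under a gel image is estimated by a grey-level morphological
opening with a paraboloid structuring element whose curvature matches a ball
of the requested radius under the ImageJ convention (ball height measured in
8-bit grey levels, so a radius-R ball has curvature 1/(2*R*255) on a [0, 1]
image).  A paraboloid is separable into two 1-D quadratic passes, and each
pass is a lower-envelope (distance-transform style) computation that runs in
O(N) per line independent of the radius — so very flat balls cost nothing
extra.  The numba-compiled envelope is used when available, with a pure
NumPy shift-and-min fallback.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rolling_ball_background", "subtract_rolling_ball"]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=False)
def _envelope_lines(f: np.ndarray, c: float, out: np.ndarray) -> None:
    """Row-wise lower envelope: out[i, x] = min_j f[i, j] + c*(x - j)^2."""
    n_lines, n = f.shape
    v = np.empty(n, dtype=np.int64)
    z = np.empty(n + 1, dtype=np.float64)
    for i in range(n_lines):
        k = 0
        v[0] = 0
        z[0] = -np.inf
        z[1] = np.inf
        for q in range(1, n):
            s = ((f[i, q] + c * q * q) - (f[i, v[k]] + c * v[k] * v[k])) / (
                2.0 * c * (q - v[k])
            )
            while s <= z[k]:
                k -= 1
                s = ((f[i, q] + c * q * q) - (f[i, v[k]] + c * v[k] * v[k])) / (
                    2.0 * c * (q - v[k])
                )
            k += 1
            v[k] = q
            z[k] = s
            z[k + 1] = np.inf
        k = 0
        for q in range(n):
            while z[k + 1] < q:
                k += 1
            d = q - v[k]
            out[i, q] = f[i, v[k]] + c * d * d


def _erode_axis(a: np.ndarray, c: float, axis: int) -> np.ndarray:
    """1-D grey erosion with the quadratic structuring function along ``axis``."""
    moved = np.ascontiguousarray(np.moveaxis(a, axis, -1), dtype=np.float64)
    out = np.empty_like(moved)
    if _HAVE_NUMBA:
        _envelope_lines(moved, c, out)
    else:  # O(N * support) fallback
        support = int(np.ceil(np.sqrt((moved.max() - moved.min() + 1e-12) / c))) + 1
        n = moved.shape[-1]
        out[:] = np.inf
        for j in range(-min(support, n - 1), min(support, n - 1) + 1):
            d = c * j * j
            src = np.clip(np.arange(n) + j, 0, n - 1)
            np.minimum(out, moved[..., src] + d, out=out)
    return np.moveaxis(out, -1, axis)


def _dilate_axis(a: np.ndarray, c: float, axis: int) -> np.ndarray:
    return -_erode_axis(-a, c, axis)


def rolling_ball_background(image: np.ndarray, radius: float) -> np.ndarray:
    """Estimate the smooth background of ``image`` (bright features on dark).

    Parameters
    ----------
    image : 2-D float array, intensities in [0, 1].
    radius : ball radius in pixels; larger values produce flatter backgrounds.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    c = 1.0 / (2.0 * radius * 255.0)  # paraboloid curvature, ImageJ height scale
    img = np.asarray(image, dtype=np.float64)
    eroded = _erode_axis(_erode_axis(img, c, 0), c, 1)
    opened = _dilate_axis(_dilate_axis(eroded, c, 1), c, 0)
    return np.minimum(opened, img)


def subtract_rolling_ball(image: np.ndarray, radius: float) -> np.ndarray:
    """Background-subtracted image, clamped at zero."""
    return np.clip(image - rolling_ball_background(image, radius), 0.0, None)
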