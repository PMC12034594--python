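"""Soft-edged primitive rendering shared by the phantom and the template bank.

Sensors appear in X-ray as dark (radiopaque) elongated blobs with blurry
edges; both the synthetic phantom and the synthetic matching templates draw
them with the same logistic soft-box profile so that the templates are a
faithful model of the rendered sensors.
"""

from __future__ import annotations

import numpy as np


def softbox(d: np.ndarray, half_width: float, edge: float = 1.2) -> np.ndarray:
    """Smooth indicator of ``|d| <= half_width`` with a logistic edge.

    Returns values in (0, 1): ~1 well inside the box, 0.5 exactly at the
    edge, ~0 outside.  ``edge`` controls the transition width in pixels.
    """
    return 1.0 / (1.0 + np.exp((np.abs(d) - half_width) / edge))


def stamp_bar(
    img: np.ndarray,
    center: tuple[float, float],
    tangent: tuple[float, float],
    length: float,
    width: float,
    depth: float,
    edge: float = 1.2,
) -> np.ndarray:
    """Subtract a soft dark bar from ``img`` (in place) and return its footprint.

    The bar is ``length`` px long along ``tangent`` (a unit (drow, dcol)
    vector) and ``width`` px across it, centered at ``center`` = (row, col).
    ``depth`` is the maximum intensity decrement.  The returned footprint is
    the unit-amplitude attenuation profile (same shape as the stamped window,
    embedded in a full-size zero array).
    """
    rows, cols = img.shape
    cr, cc = center
    tr, tc = tangent
    # window comfortably covering the bar plus its soft edge
    reach = 0.5 * max(length, width) + 5.0 * edge
    r0 = max(0, int(np.floor(cr - reach)))
    r1 = min(rows, int(np.ceil(cr + reach)) + 1)
    c0 = max(0, int(np.floor(cc - reach)))
    c1 = min(cols, int(np.ceil(cc + reach)) + 1)
    footprint = np.zeros_like(img, dtype=float)
    if r0 >= r1 or c0 >= c1:
        return footprint
    rr, cc_grid = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    dr = rr - cr
    dc = cc_grid - cc
    u = dr * tr + dc * tc  # along the bar
    v = -dr * tc + dc * tr  # across the bar
    prof = softbox(u, length / 2.0, edge) * softbox(v, width / 2.0, edge)
    img[r0:r1, c0:c1] -= depth * prof
    footprint[r0:r1, c0:c1] = prof
    return footprint
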