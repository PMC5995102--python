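"""Heat-map colouring and colour-coded 3D exports.

Colour semantics follow the workflow's figures: displacement magnitudes
run blue (small) to red (large); signed per-axis displacements run blue
(negative) through a pale neutral at zero to red (positive); p-value and
q-value fields use a red-to-green band below the significance threshold
and a yellow-to-blue band above it; ellipsoid overlap maps are black
(no overlap = group difference) or purple (overlap).  Gradients
interpolate linearly in RGB between anchor colours — a qualitative, not
bit-exact, match to the original figure palettes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_core import write_ply

__all__ = ["ColorMapSpec", "colorize", "render_model", "NEUTRAL_RGB"]

RED = np.array([1.0, 0.0, 0.0])
GREEN = np.array([0.0, 0.8, 0.0])
BLUE = np.array([0.0, 0.0, 1.0])
YELLOW = np.array([1.0, 0.9, 0.0])
BLACK = np.array([0.0, 0.0, 0.0])
PURPLE = np.array([0.5, 0.0, 0.5])
#: Neutral mid colour of the signed maps (pale yellow-white, "no shift").
NEUTRAL_RGB = np.array([1.0, 1.0, 0.85])

KINDS = ("magnitude", "signed", "pvalue", "qvalue", "overlap")


@dataclass
class ColorMapSpec:
    """Which palette to apply and at which threshold.

    ``threshold`` is used by the p/q kinds (strict ``value < threshold``
    selects the significant band, matching the figure captions) and
    ignored otherwise.
    """

    kind: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.kind in ("pvalue", "qvalue"):
            default = 0.01 if self.kind == "pvalue" else 0.005
            self.threshold = default if self.threshold is None else float(self.threshold)
            if not 0 < self.threshold < 1:
                raise ValueError("threshold must lie in (0, 1)")


def _lerp(c0: np.ndarray, c1: np.ndarray, t: np.ndarray) -> np.ndarray:
    return c0 + (c1 - c0) * t[:, None]


def colorize(values: np.ndarray, spec: ColorMapSpec) -> np.ndarray:
    """Map per-id values to RGB in [0, 1] according to ``spec``.

    ``values`` are the field at tested/valid ids only and must be finite
    (booleans for the overlap kind).  A constant field maps to a single
    uniform colour.
    """
    values = np.asarray(values)
    if spec.kind == "overlap":
        flags = values.astype(bool)
        out = np.where(flags[:, None], PURPLE[None, :], BLACK[None, :])
        return out
    values = values.astype(float)
    if np.any(~np.isfinite(values)):
        raise ValueError("NaN or infinite value at a tested id")
    n = len(values)
    if spec.kind == "magnitude":
        lo, hi = float(values.min()), float(values.max())
        t = np.zeros(n) if hi <= lo else (values - lo) / (hi - lo)
        return _lerp(BLUE, RED, t)
    if spec.kind == "signed":
        vmax = float(np.abs(values).max())
        if vmax == 0:
            return np.tile(NEUTRAL_RGB, (n, 1))
        t = values / vmax  # [-1, 1], 0 -> exactly neutral
        out = np.empty((n, 3))
        neg = t < 0
        out[neg] = _lerp(NEUTRAL_RGB, BLUE, -t[neg])
        out[~neg] = _lerp(NEUTRAL_RGB, RED, t[~neg])
        return out
    # p/q kinds: red->green below the threshold, yellow->blue at/above it
    thr = spec.threshold
    out = np.empty((n, 3))
    below = values < thr
    tb = values[below] / thr
    out[below] = _lerp(RED, GREEN, tb)
    ta = (values[~below] - thr) / max(1.0 - thr, 1e-12)
    out[~below] = _lerp(YELLOW, BLUE, np.clip(ta, 0.0, 1.0))
    return out


def render_model(
    model,
    colors: np.ndarray,
    out: str | Path,
    projection_image: str | Path | None = None,
) -> None:
    """Write a coloured point-cloud PLY of a model (µm preserved).

    ``colors`` must cover exactly the model's valid ids, in id order.
    Optionally also writes a 2D orthographic projection along z (the
    figure-style top view) as an image.
    """
    coords = np.asarray(model.coords, dtype=float)
    valid = np.asarray(model.valid, dtype=bool)
    pts = coords[valid]
    colors = np.asarray(colors, dtype=float)
    if len(colors) != len(pts):
        raise ValueError(
            f"colour count {len(colors)} does not match {len(pts)} valid model points"
        )
    write_ply(pts, colors, out, comment="morphowrap model render")
    if projection_image is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axis = plt.subplots(figsize=(6, 6))
        axis.scatter(pts[:, 0], pts[:, 1], c=np.clip(colors, 0, 1), s=2, linewidths=0)
        axis.set_aspect("equal")
        axis.set_xlabel("x [µm]")
        axis.set_ylabel("y [µm]")
        fig.savefig(projection_image, dpi=150)
        plt.close(fig)
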