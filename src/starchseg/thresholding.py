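"""Iterative automatic (ISODATA-style) thresholding.

A bright-field starch micrograph has a bimodal histogram: dark granules
and a light background.  The classic iterative scheme splits the pixels
at a threshold T, computes the two class means mu1 (below T) and mu2
(at or above T), moves T to their midpoint and repeats until the change
falls below a tolerance eps.  The converged T separates granules (dark,
class C1) from background (light, class C2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import GrayImage

DEFAULT_EPS = 0.2


@dataclass(frozen=True)
class ThresholdState:
    """Converged state of the iterative threshold.

    Attributes
    ----------
    t0, t : float
        Initial and converged threshold (intensity units).
    eps : float
        Stopping tolerance on successive thresholds.
    mu1, mu2 : float
        Final class means (pixels < t, pixels >= t).
    n_iter : int
        Number of threshold updates performed.
    degenerate : bool
        True when the image holds a single intensity value, in which
        case no meaningful split exists and ``t`` equals that value.
    """

    t0: float
    t: float
    eps: float
    mu1: float
    mu2: float
    n_iter: int
    degenerate: bool = False


@dataclass(frozen=True)
class BinaryMask:
    """Boolean foreground (granule) mask; True = foreground."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError(f"expected a 2-D mask, got shape {m.shape}")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def iterative_threshold(
    image: GrayImage, t0: float | None = None, eps: float = DEFAULT_EPS, max_iter: int = 500
) -> ThresholdState:
    """Run the iterative class-mean-midpoint threshold to convergence.

    ``t0`` defaults to the image mean.  An empty class keeps its mean at
    the current threshold so the midpoint update stays defined.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    px = image.pixels.ravel()
    lo, hi = float(px.min()), float(px.max())
    if lo == hi:
        return ThresholdState(t0=lo if t0 is None else float(t0), t=lo, eps=eps,
                              mu1=lo, mu2=lo, n_iter=0, degenerate=True)
    t = float(px.mean()) if t0 is None else float(t0)
    t_init = t
    mu1 = mu2 = t
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        below = px < t
        mu1 = float(px[below].mean()) if below.any() else t
        mu2 = float(px[~below].mean()) if (~below).any() else t
        t_new = 0.5 * (mu1 + mu2)
        done = abs(t_new - t) < eps
        t = t_new
        if done:
            break
    return ThresholdState(t0=t_init, t=t, eps=eps, mu1=mu1, mu2=mu2,
                          n_iter=n_iter, degenerate=False)


def binarize(image: GrayImage, state: ThresholdState, dark_foreground: bool = True) -> BinaryMask:
    """Apply a converged threshold; by default dark pixels are foreground.

    Pixels exactly equal to the threshold go to background (class C2),
    giving a total partition.  A degenerate state yields an all-background
    mask with a warning.
    """
    if state.degenerate:
        warnings.warn("degenerate (constant) image: returning an empty foreground mask")
        return BinaryMask(np.zeros(image.shape, dtype=bool))
    if dark_foreground:
        return BinaryMask(image.pixels < state.t)
    return BinaryMask(image.pixels > state.t)
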