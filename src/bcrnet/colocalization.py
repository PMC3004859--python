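"""Pixel-wise two-channel co-localization scoring.

The co-localization of two fluorophores is scored by the Pearson
coefficient over all pixels::

    R = sum((S1_i - S1_avg)(S2_i - S2_avg))
        / sqrt(sum((S1_i - S1_avg)^2) * sum((S2_i - S2_avg)^2))

computed per 2-D image (single slices or projections).  Optional 2-D
pre-filters (Gaussian smoothing, then unsharp sharpening) suppress
photomultiplier noise before scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

GAUSSIAN_SIGMA = 1.0   # px
UNSHARP_AMOUNT = 0.5


@dataclass
class ChannelPair:
    """Two equal-shape non-negative intensity matrices."""

    ch1: np.ndarray
    ch2: np.ndarray

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1, dtype=float)
        self.ch2 = np.asarray(self.ch2, dtype=float)
        if self.ch1.shape != self.ch2.shape:
            raise ValueError(
                f"channel shapes differ: {self.ch1.shape} vs {self.ch2.shape}"
            )
        if self.ch1.min() < 0 or self.ch2.min() < 0:
            raise ValueError("channel intensities must be non-negative")


def pearson_coefficient(pair: ChannelPair) -> float:
    """Pearson co-localization coefficient of a channel pair, in [-1, 1].

    Raises
    ------
    ValueError
        If either channel is constant (the coefficient is undefined).
    """
    a = pair.ch1.ravel() - pair.ch1.mean()
    b = pair.ch2.ravel() - pair.ch2.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        raise ValueError("undefined coefficient: at least one channel is constant")
    r = float(np.sum(a * b) / denom)
    # guard against floating-point excursions just outside [-1, 1]
    return max(-1.0, min(1.0, r))


def prefilter(
    matrix: np.ndarray,
    gaussian_sigma: float = GAUSSIAN_SIGMA,
    sharpen: bool = False,
    unsharp_amount: float = UNSHARP_AMOUNT,
) -> np.ndarray:
    """Gaussian smoothing followed by optional unsharp masking.

    Shape is preserved and the output floored at zero (sharpening can
    undershoot).  ``gaussian_sigma=0`` with ``sharpen=False`` is the
    identity.
    """
    if gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be non-negative")
    out = np.asarray(matrix, dtype=float)
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=gaussian_sigma)
    if sharpen:
        blur_sigma = gaussian_sigma if gaussian_sigma > 0 else GAUSSIAN_SIGMA
        blurred = ndimage.gaussian_filter(out, sigma=blur_sigma)
        out = out + unsharp_amount * (out - blurred)
    return np.clip(out, 0.0, None)


@dataclass
class BatchResult:
    mean: float
    sd: float
    n: int
    coefficients: list[float]
    single_pair: bool = False


def batch_coefficient(pairs: list[ChannelPair]) -> BatchResult:
    """Per-pair coefficients with mean and standard deviation.

    Pairs with an undefined coefficient (constant channel) are excluded
    with a warning; a single surviving pair reports sd = 0 with the
    single-pair flag set.
    """
    if not pairs:
        raise ValueError("need at least one channel pair")
    coefficients = []
    for i, pair in enumerate(pairs):
        try:
            coefficients.append(pearson_coefficient(pair))
        except ValueError:
            logger.warning("pair %d excluded: undefined coefficient", i)
    if not coefficients:
        raise ValueError("no pair yielded a defined coefficient")
    arr = np.asarray(coefficients)
    single = len(coefficients) == 1
    return BatchResult(
        mean=float(arr.mean()),
        sd=0.0 if single else float(arr.std(ddof=1)),
        n=len(coefficients),
        coefficients=coefficients,
        single_pair=single,
    )


def read_channel(path) -> np.ndarray:
    """Read one channel from TIFF (first page) or CSV matrix."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    return np.loadtxt(path, delimiter=",", dtype=float)
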