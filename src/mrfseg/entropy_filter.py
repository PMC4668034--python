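"""Local-entropy texture filtering.

Multicellular structures (tumour organoids, CAF strands) are textured while
the background is smooth, and fluorescence intensity is heterogeneous across
structures.  The per-pixel Shannon entropy of the intensity histogram in a
square window is invariant to the local mean intensity, so it separates
"textured object" from "smooth background" where a plain intensity threshold
cannot.  The filtered values are the observations fed to the mixture models
and to the MRF pairwise terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_stack import ImageStack, VoxelSpacing


@dataclass
class EntropyStack:
    """Per-voxel, per-channel local entropy in bits, axes (z, y, x, channel).

    Values lie in [0, log2(min(window**2, 256))] — a window cannot populate
    more histogram bins than it has pixels.
    """

    values: np.ndarray
    window: int
    spacing: VoxelSpacing

    @property
    def shape(self):
        return self.values.shape

    @property
    def max_entropy(self) -> float:
        return float(np.log2(min(self.window**2, 256)))


def _local_entropy_slice(img: np.ndarray, window: int) -> np.ndarray:
    """Windowed histogram entropy of one 8-bit 2D image, symmetric padding.

    Exact integer window counts are obtained per intensity level from a 2D
    integral image; the entropy sum -sum_k p_k log2 p_k then accumulates over
    the levels actually present.
    """
    half = window // 2
    padded = np.pad(img, half, mode="symmetric").astype(np.intp)
    n = window * window
    ny, nx = img.shape

    out = np.zeros((ny, nx), dtype=np.float64)
    # remap to the compact set of levels present to bound the loop
    levels = np.unique(padded)
    for lev in levels:
        mask = (padded == lev)
        # integral image with a leading zero row/col for clean differencing
        ii = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.intp)
        np.cumsum(mask, axis=0, out=ii[1:, 1:])
        np.cumsum(ii[1:, 1:], axis=1, out=ii[1:, 1:])
        counts = (ii[window:, window:] - ii[:-window, window:]
                  - ii[window:, :-window] + ii[:-window, :-window])
        p = counts / n
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(counts > 0, -p * np.log2(np.where(counts > 0, p, 1.0)), 0.0)
        out += term
    # clamp the tiny negative round-off a sum of -p log p terms can leave
    np.maximum(out, 0.0, out=out)
    return out


def local_entropy_stack(stack: ImageStack, window: int = 9) -> EntropyStack:
    """Apply the local entropy filter to every slice and channel of a stack.

    Filtering is strictly 2D within each slice (no mixing across z — with
    10-40 um between slices a 3D texture window would be physically
    meaningless) and each channel is filtered separately.  Borders use
    symmetric, edge-inclusive padding (..., v2, v1 | v1, v2, ...).

    Parameters
    ----------
    stack : ImageStack
        8-bit quantized input.
    window : int
        Odd side length of the square neighbourhood, default 9.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    nz, ny, nx, nc = stack.data.shape
    if window > 2 * min(ny, nx):
        raise ValueError("window larger than twice the smallest image dimension")
    values = np.empty((nz, ny, nx, nc), dtype=np.float64)
    for z in range(nz):
        for c in range(nc):
            values[z, :, :, c] = _local_entropy_slice(stack.data[z, :, :, c], window)
    return EntropyStack(values, window, stack.spacing)
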