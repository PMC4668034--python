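"""Comparison segmentations that 'build up' to the MRF method.

intOtsu  -- Otsu threshold per raw intensity channel, masks combined.
entOtsu  -- Otsu threshold per local-entropy channel, masks combined.
mixtures -- per-voxel argmax of the label densities (the MRF with
            lambda0 = lambda1 = 0, i.e. no neighbour information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density_model import LabelDensitySet
from .entropy_filter import EntropyStack
from .io_stack import CAF, TUMOUR, ImageStack, LabelMap


@dataclass
class BinaryMask:
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must have axes (z, y, x)")


def otsu_threshold(values: np.ndarray) -> tuple[int, bool]:
    """Otsu's threshold over a 256-bin histogram of 8-bit values.

    Returns ``(t, degenerate)``: pixels strictly above ``t`` are foreground;
    among thresholds maximising the between-class variance the smallest wins.
    Constant input sets the degenerate flag (all-background).
    """
    values = np.asarray(values).ravel()
    if values.min() < 0 or values.max() > 255:
        raise ValueError("otsu_threshold expects values in [0, 255]")
    hist = np.bincount(values.astype(np.intp), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        return 0, True
    p = hist / n
    omega0 = np.cumsum(p)                       # class {<= t}
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * omega0 - mu) ** 2 / (omega0 * omega1)
    sigma_b[~np.isfinite(sigma_b)] = -np.inf    # empty class: no valid split
    t = int(np.argmax(sigma_b))                 # argmax returns smallest tie
    return t, False


def bin_entropy(values: np.ndarray, max_entropy: float) -> np.ndarray:
    """Linearly bin continuous entropy values to 256 levels over [0, max]."""
    scaled = np.clip(values / max_entropy, 0.0, 1.0) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def combine_channel_masks(red_mask: BinaryMask, green_mask: BinaryMask,
                          seed: int = 0) -> LabelMap:
    """Combine per-channel foreground masks into a 3-class label map.

    Red-only voxels become tumour, green-only CAF, neither background; a
    voxel foreground in both channels is assigned tumour or CAF with
    probability 1/2 each (seeded).
    """
    r, g = red_mask.mask, green_mask.mask
    if r.shape != g.shape:
        raise ValueError("mask shapes differ")
    labels = np.zeros(r.shape, dtype=np.uint8)
    labels[r & ~g] = TUMOUR
    labels[g & ~r] = CAF
    overlap = r & g
    n_over = int(overlap.sum())
    if n_over:
        rng = np.random.default_rng(seed)
        labels[overlap] = rng.choice([TUMOUR, CAF], size=n_over)
    from .io_stack import VoxelSpacing
    return LabelMap(labels, VoxelSpacing(1, 1, 1))


def _otsu_labelmap(channel_images: list[np.ndarray], ref_slice: int,
                   spacing, seed: int) -> LabelMap:
    """Threshold each (z,y,x) 8-bit channel on its reference slice, combine."""
    masks = []
    for img in channel_images:
        t, degenerate = otsu_threshold(img[ref_slice])
        masks.append(BinaryMask(np.zeros(img.shape, dtype=bool) if degenerate
                                else img > t))
    out = combine_channel_masks(masks[0], masks[1], seed=seed)
    out.spacing = spacing
    return out


def int_otsu_segment(stack: ImageStack, reference_slice: int,
                     seed: int = 0) -> LabelMap:
    """'intOtsu': Otsu on raw intensities of the reference slice, per channel."""
    if stack.data.shape[3] != 2:
        raise ValueError("int_otsu_segment needs a two-channel stack")
    channels = [stack.data[..., c] for c in range(2)]
    return _otsu_labelmap(channels, reference_slice, stack.spacing, seed)


def ent_otsu_segment(entropy: EntropyStack, reference_slice: int,
                     seed: int = 0) -> LabelMap:
    """'entOtsu': Otsu on 256-level-binned local entropy of the reference slice."""
    if entropy.values.shape[3] != 2:
        raise ValueError("ent_otsu_segment needs a two-channel entropy stack")
    channels = [bin_entropy(entropy.values[..., c], entropy.max_entropy)
                for c in range(2)]
    return _otsu_labelmap(channels, reference_slice, entropy.spacing, seed)


def mixtures_segment(entropy: EntropyStack,
                     densities: LabelDensitySet) -> LabelMap:
    """'mixtures': per-voxel argmax_l pi_l(z_i), no neighbour information.

    Equivalent to the MRF with lambda0 = lambda1 = 0.  Ties break by label
    order (background, tumour, CAF) — argmax keeps the first maximum.  The
    densities are floored at eps exactly as in the unary potentials, so the
    equivalence with the zero-lambda MRF is voxel-for-voxel.
    """
    pi = np.maximum(densities.evaluate(entropy.values), densities.eps)
    labels = np.argmax(pi, axis=-1).astype(np.uint8)
    return LabelMap(labels, entropy.spacing)
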