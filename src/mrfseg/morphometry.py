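"""Tumour--stroma morphometry of segmented label maps.

Per stack: total volume (labelled voxel count), total surface area
(labelled voxels face-adjacent to a voxel of another label) and total
tumour--stroma contact (tumour voxels face-adjacent to CAF plus CAF voxels
face-adjacent to tumour).  All quantities are voxel counts on the same
6-neighbourhood as the MRF lattice; the stack boundary does not count as
another label.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .io_stack import BACKGROUND, CAF, TUMOUR, LabelMap

_OFFSETS_6 = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))


def _neighbour_differs(labels: np.ndarray, other: np.ndarray | None = None) -> np.ndarray:
    """Boolean grid: voxel has >= 1 6-neighbour whose label differs.

    With ``other`` given, instead: has >= 1 6-neighbour where ``other`` is
    True.  Out-of-grid neighbours never count.
    """
    out = np.zeros(labels.shape, dtype=bool)
    for dz, dy, dx in _OFFSETS_6:
        sl_c = tuple(slice(max(0, -o), labels.shape[k] - max(0, o))
                     for k, o in enumerate((dz, dy, dx)))
        sl_n = tuple(slice(max(0, o), labels.shape[k] - max(0, -o))
                     for k, o in enumerate((dz, dy, dx)))
        if other is None:
            out[sl_c] |= labels[sl_c] != labels[sl_n]
        else:
            out[sl_c] |= other[sl_n]
    return out


def _check_label(label: int) -> None:
    if label not in (BACKGROUND, TUMOUR, CAF):
        raise ValueError(f"unknown label {label}")


def total_volume(labelmap: LabelMap, label: int) -> int:
    """Number of voxels carrying ``label``."""
    _check_label(label)
    return int((labelmap.labels == label).sum())


def total_surface(labelmap: LabelMap, label: int) -> int:
    """Voxels of ``label`` with at least one differing-label 6-neighbour."""
    _check_label(label)
    differs = _neighbour_differs(labelmap.labels)
    return int((differs & (labelmap.labels == label)).sum())


def total_contact(labelmap: LabelMap) -> int:
    """Tumour voxels touching CAF plus CAF voxels touching tumour (faces)."""
    labels = labelmap.labels
    t_touch_c = _neighbour_differs(labels, other=(labels == CAF)) & (labels == TUMOUR)
    c_touch_t = _neighbour_differs(labels, other=(labels == TUMOUR)) & (labels == CAF)
    return int(t_touch_c.sum() + c_touch_t.sum())


@dataclass(frozen=True)
class ContactStats:
    """Morphometric summary of one label map (all voxel counts)."""

    volume_T: int
    volume_C: int
    surface_T: int
    surface_C: int
    contact: int

    def as_dict(self) -> dict:
        return asdict(self)


def contact_stats(labelmap: LabelMap) -> ContactStats:
    """All morphometric quantities of one label map in one pass."""
    return ContactStats(
        volume_T=total_volume(labelmap, TUMOUR),
        volume_C=total_volume(labelmap, CAF),
        surface_T=total_surface(labelmap, TUMOUR),
        surface_C=total_surface(labelmap, CAF),
        contact=total_contact(labelmap),
    )
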