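"""Nuclear-to-cytoplasmic signal ratios from an image plus two masks.

The cytoplasmic signal is the whole-cell integrated intensity minus the
nuclear integrated intensity; the N:C ratio divides nuclear by cytoplasmic
signal, per cell. Integrated (summed) signal is the default because the
subtraction rule is only meaningful for sums; a mean-intensity mode exists
behind a flag for labs that report mean-based N:C. Masks are inputs —
nucleus and cell outlines are drawn upstream, not segmented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError


@dataclass
class CellMeasurement:
    """Integrated signals and their ratio for one cell.

    ``nc_ratio`` is NaN (flagged by ``valid=False``) when the cytoplasmic
    signal is non-positive.
    """

    cell_id: str
    nuclear_signal: float
    cytoplasmic_signal: float
    nc_ratio: float
    valid: bool = True


def compute_nc_ratio(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    cell_id: str = "",
    background: float = 0.0,
    use_mean: bool = False,
) -> CellMeasurement:
    """N:C ratio of one cell from summed (default) or mean mask intensities.

    ``background`` is an optional constant subtracted per pixel before
    integration. Raises :class:`GeometryError` on empty masks or when the
    nucleus mask is not contained in the cell mask; a non-positive
    cytoplasmic signal yields a flagged, NaN ratio instead of a number.
    """
    image = np.asarray(image, float)
    nucleus_mask = np.asarray(nucleus_mask, bool)
    cell_mask = np.asarray(cell_mask, bool)
    if nucleus_mask.shape != image.shape or cell_mask.shape != image.shape:
        raise GeometryError("mask shape does not match image shape")
    if not nucleus_mask.any() or not cell_mask.any():
        raise GeometryError("masks must be non-empty")
    if (nucleus_mask & ~cell_mask).any():
        raise GeometryError("nucleus mask not contained in cell mask")

    corrected = image - background
    if use_mean:
        nuclear = float(corrected[nucleus_mask].mean())
        cyto_mask = cell_mask & ~nucleus_mask
        if not cyto_mask.any():
            return CellMeasurement(cell_id, nuclear, 0.0, float("nan"), valid=False)
        cytoplasmic = float(corrected[cyto_mask].mean())
    else:
        nuclear = float(corrected[nucleus_mask].sum())
        whole_cell = float(corrected[cell_mask].sum())
        cytoplasmic = whole_cell - nuclear
    if cytoplasmic <= 0:
        return CellMeasurement(cell_id, nuclear, cytoplasmic, float("nan"), valid=False)
    return CellMeasurement(cell_id, nuclear, cytoplasmic, nuclear / cytoplasmic)


def batch_nc(
    cells: Iterable[tuple[str, np.ndarray, np.ndarray, np.ndarray]],
    groups: Sequence[str] | None = None,
    background: float = 0.0,
    use_mean: bool = False,
) -> pd.DataFrame:
    """Measure many cells into a tidy table; per-cell errors are collected.

    ``cells`` yields (cell_id, image, nucleus_mask, cell_mask); ``groups``
    optionally labels each cell in order. Cells that raise a geometry error
    appear with NaN signals and the error message in the ``error`` column.
    """
    rows = []
    for i, (cell_id, image, nuc, cell) in enumerate(cells):
        group = groups[i] if groups is not None else ""
        try:
            m = compute_nc_ratio(
                image, nuc, cell, cell_id=cell_id,
                background=background, use_mean=use_mean,
            )
            rows.append(
                dict(
                    cell_id=cell_id,
                    group=group,
                    nuclear_signal=m.nuclear_signal,
                    cytoplasmic_signal=m.cytoplasmic_signal,
                    nc_ratio=m.nc_ratio,
                    valid=m.valid,
                    error="",
                )
            )
        except GeometryError as exc:
            rows.append(
                dict(
                    cell_id=cell_id,
                    group=group,
                    nuclear_signal=float("nan"),
                    cytoplasmic_signal=float("nan"),
                    nc_ratio=float("nan"),
                    valid=False,
                    error=str(exc),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "group",
            "nuclear_signal",
            "cytoplasmic_signal",
            "nc_ratio",
            "valid",
            "error",
        ],
    )
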