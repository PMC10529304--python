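"""PET semi-quantification: SUVmax and target-to-background ratio (TBR).

SUVmax is the maximum standardized uptake value over a node's voxels; the TBR
divides it by a background SUVmax measured on non-target tissue. TBR is
preferred over absolute SUVmax in the intraoperative setting because it is
robust to variability in background uptake and acquisition timing. Reported
TBR values are rounded half-away-from-zero to one decimal; full precision is
retained internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import LabelMask, VolumeGrid
from .morphology import StructuringElement, dilate

__all__ = [
    "QuantRecord",
    "suvmax",
    "tbr",
    "background_suvmax",
    "quantify",
    "suv_scale",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (5.25 -> 5.3 at 1 decimal), unlike banker's rounding."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class QuantRecord:
    """Per-node semi-quantification: SUVmax, background SUVmax and their ratio."""

    label: int
    voxels: int
    suvmax: float
    background_suvmax: float
    tbr: float

    def __post_init__(self):
        if self.suvmax < 0:
            raise ValueError("suvmax must be >= 0")
        if self.background_suvmax <= 0:
            raise ValueError("background_suvmax must be > 0")

    @property
    def tbr_reported(self) -> float:
        return round_half_away(self.tbr, 1)


def _check_aligned(pet: VolumeGrid, mask: LabelMask):
    if not pet.geometry.isclose(mask.geometry, tol=1e-6):
        raise ValueError(
            "PET volume and mask geometries differ "
            f"({pet.geometry} vs {mask.geometry}); resample the mask first"
        )


def suvmax(pet: VolumeGrid, mask: LabelMask, label: int) -> float:
    """Maximum PET value over the voxels carrying ``label``."""
    _check_aligned(pet, mask)
    sel = mask.labels == label
    if not sel.any():
        available = sorted(mask.label_set - {0})
        raise ValueError(f"label {label} not present in mask; available labels: {available}")
    return float(pet.values[sel].max())


def tbr(suvmax_value: float, background_suvmax: float) -> float:
    """Target-to-background ratio: node SUVmax divided by background SUVmax."""
    if background_suvmax <= 0:
        raise ValueError(f"background SUVmax must be > 0, got {background_suvmax}")
    return float(suvmax_value) / float(background_suvmax)


def background_suvmax(
    pet: VolumeGrid,
    node_mask: LabelMask,
    roi: LabelMask | None = None,
    margin_mm: float = 1.0,
) -> float:
    """SUVmax of the non-target background.

    With an explicit ``roi`` mask the maximum is taken over its foreground
    (node voxels excluded). Otherwise the background is every voxel outside
    the node mask dilated by ``margin_mm`` (a guard band against uptake
    spill-over at node boundaries).
    """
    _check_aligned(pet, node_mask)
    nodes = node_mask.as_bool()
    if roi is not None:
        _check_aligned(pet, roi)
        region = roi.as_bool() & ~nodes
    else:
        radius = max(1, int(round(margin_mm / min(node_mask.spacing))))
        guard = dilate(nodes, StructuringElement("ball", radius)) if nodes.any() else nodes
        region = ~guard
    if not region.any():
        raise ValueError("background region is empty; supply a background ROI")
    return float(pet.values[region].max())


def quantify(
    pet: VolumeGrid,
    mask: LabelMask,
    background_roi: LabelMask | None = None,
    background_margin_mm: float = 1.0,
) -> pd.DataFrame:
    """One QuantRecord per node label, as a table.

    Columns: ``label, voxels, suvmax, background_suvmax, tbr`` (tbr at full
    precision; use :func:`round_half_away` for display). An empty mask yields
    an empty table, not an error.
    """
    _check_aligned(pet, mask)
    labels = sorted(mask.label_set - {0})
    columns = ["label", "voxels", "suvmax", "background_suvmax", "tbr"]
    if not labels:
        return pd.DataFrame(columns=columns)
    bg = background_suvmax(pet, mask, roi=background_roi, margin_mm=background_margin_mm)
    rows = []
    for lab in labels:
        s = suvmax(pet, mask, lab)
        rec = QuantRecord(
            label=lab,
            voxels=int(np.count_nonzero(mask.labels == lab)),
            suvmax=s,
            background_suvmax=bg,
            tbr=tbr(s, bg),
        )
        rows.append(rec.__dict__ | {})
    return pd.DataFrame(rows, columns=columns)


def suv_scale(activity_conc_bq_ml: float, injected_dose_mbq: float, body_weight_kg: float) -> float:
    """Body-weight SUV from activity concentration (Bq/mL), dose (MBq), weight (kg).

    SUV = concentration x (weight in g) / (dose in Bq); utility for PET
    volumes not already expressed in SUV.
    """
    if injected_dose_mbq <= 0:
        raise ValueError(f"injected dose must be > 0 MBq, got {injected_dose_mbq}")
    if body_weight_kg <= 0:
        raise ValueError(f"body weight must be > 0 kg, got {body_weight_kg}")
    return float(activity_conc_bq_ml) * (body_weight_kg * 1000.0) / (injected_dose_mbq * 1e6)
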