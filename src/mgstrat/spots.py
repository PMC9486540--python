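"""Spot detection and per-cell positivity calls for AChR, MAC and Ig channels.

Clustered surface signal (receptor microclusters, deposited MAC, bound
immunoglobulin) appears as compact bright spots.  Spots are localized with
Laplacian-of-Gaussian blob detection, assigned to the cell containing their
centroid, and integrated over a disk after subtracting the local background
(median of a surrounding annulus).  The per-cell sum of integrated spot
fluorescence is the readout; a cell is called positive when its sum exceeds a
threshold, either a fixed configured value or an automatic two-class (Otsu)
split of log1p(spot sum) — computed on negative-control cells when provided,
mimicking a plate-level threshold set against controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import blob_log

from .segment import CellLabelMap
from .simulate import ImageField

__all__ = [
    "SpotParams",
    "detect_spots",
    "per_cell_spot_sum",
    "call_positive",
    "percent_positive",
    "mac_within_achr_pos",
]

_CHANNEL_ROLES = ("achr", "marker")


@dataclass(frozen=True)
class SpotParams:
    """LoG blob-detector settings.

    ``threshold`` is on the scale-space response, roughly half the peak
    amplitude of a matched Gaussian spot; the default rejects diffuse
    (unclustered) signal and camera noise at the simulator's default
    intensity scales while keeping true spots, whose peaks are an order of
    magnitude brighter.
    """

    min_sigma: float = 1.2
    max_sigma: float = 3.5
    num_sigma: int = 3
    threshold: float = 60.0
    overlap: float = 0.8
    integration_radius_sigmas: float = 2.5
    annulus_width_px: int = 3


def detect_spots(
    field: ImageField,
    cells: CellLabelMap,
    channel: str,
    params: SpotParams | None = None,
) -> pd.DataFrame:
    """Locate spots in one channel and integrate their fluorescence.

    Returns a table with ``spot_id, cell_id, channel, row, col, sigma,
    area_px, intensity`` — one row per spot whose centroid falls inside a
    segmented cell and whose background-subtracted integral is positive.
    A blank channel yields an empty table.
    """
    if channel not in _CHANNEL_ROLES:
        raise ValueError(f"unknown channel role {channel!r}; expected one of {_CHANNEL_ROLES}")
    params = params or SpotParams()
    img = np.asarray(field.channels[channel], dtype=float)
    if img.shape != cells.cell_labels.shape:
        raise ValueError("channel and cell label image shapes differ")

    cols = ["spot_id", "cell_id", "channel", "row", "col", "sigma", "area_px", "intensity"]
    if img.max() <= 0:
        return pd.DataFrame(columns=cols)

    blobs = blob_log(
        img,
        min_sigma=params.min_sigma,
        max_sigma=params.max_sigma,
        num_sigma=params.num_sigma,
        threshold=params.threshold,
        overlap=params.overlap,
    )
    rows = []
    spot_id = 0
    size = img.shape[0]
    for by, bx, bsigma in blobs:
        iy, ix = int(round(by)), int(round(bx))
        cell_id = int(cells.cell_labels[iy, ix])
        if cell_id == 0:
            continue
        r = max(2, int(math.ceil(params.integration_radius_sigmas * bsigma)))
        y0, y1 = max(0, iy - r), min(size, iy + r + 1)
        x0, x1 = max(0, ix - r), min(img.shape[1], ix + r + 1)
        yy, xx = np.ogrid[y0:y1, x0:x1]
        d2 = (yy - by) ** 2 + (xx - bx) ** 2
        disk_mask = d2 <= r ** 2
        ann_r = r + params.annulus_width_px
        ya0, ya1 = max(0, iy - ann_r), min(size, iy + ann_r + 1)
        xa0, xa1 = max(0, ix - ann_r), min(img.shape[1], ix + ann_r + 1)
        yya, xxa = np.ogrid[ya0:ya1, xa0:xa1]
        da2 = (yya - by) ** 2 + (xxa - bx) ** 2
        ann_mask = (da2 > r ** 2) & (da2 <= ann_r ** 2)
        background = float(np.median(img[ya0:ya1, xa0:xa1][ann_mask])) if ann_mask.any() else 0.0
        patch = img[y0:y1, x0:x1]
        integrated = float(patch[disk_mask].sum() - background * disk_mask.sum())
        if integrated <= 0:
            continue
        spot_id += 1
        rows.append({
            "spot_id": spot_id,
            "cell_id": cell_id,
            "channel": channel,
            "row": float(by),
            "col": float(bx),
            "sigma": float(bsigma),
            "area_px": int(disk_mask.sum()),
            "intensity": integrated,
        })
    return pd.DataFrame(rows, columns=cols)


def per_cell_spot_sum(spots: pd.DataFrame, cells: CellLabelMap) -> pd.DataFrame:
    """Sum of integrated spot fluorescence per cell; spotless cells get 0.

    The total over all cells equals the total over the spot table (each spot
    belongs to exactly one cell).
    """
    n = cells.n_cells
    sums = np.zeros(n)
    if len(spots):
        grouped = spots.groupby("cell_id")["intensity"].sum()
        idx = grouped.index.to_numpy(dtype=int)
        if (idx < 1).any() or (idx > n).any():
            raise ValueError("spot table refers to cell ids outside the label map")
        sums[idx - 1] = grouped.to_numpy()
    return pd.DataFrame({"cell_id": np.arange(1, n + 1), "spot_sum": sums})


def call_positive(
    spot_sums,
    threshold_rule="otsu",
    control_sums=None,
) -> np.ndarray:
    """Boolean positivity per cell: positive iff spot_sum > threshold.

    ``threshold_rule`` is either a number (fixed threshold) or ``"otsu"``: an
    automatic two-class split of log1p(spot sum), computed on ``control_sums``
    when given (the plate's negative-control cells) and on the sums themselves
    otherwise.  When the reference population has no spread to split (e.g. all
    sums zero), no cell is called positive.
    """
    sums = np.asarray(spot_sums, dtype=float)
    if (sums < 0).any():
        raise ValueError("spot sums must be nonnegative")
    if isinstance(threshold_rule, (int, float)) and not isinstance(threshold_rule, bool):
        return sums > float(threshold_rule)
    if threshold_rule != "otsu":
        raise ValueError(f"invalid threshold rule {threshold_rule!r}")
    ref = sums if control_sums is None else np.asarray(control_sums, dtype=float)
    ref = np.log1p(ref)
    if ref.size == 0 or np.ptp(ref) == 0:
        return np.zeros(sums.shape, dtype=bool)
    from skimage.filters import threshold_otsu

    thr = float(np.expm1(threshold_otsu(ref)))
    return sums > thr


def percent_positive(calls) -> float:
    """100 x positive cells / total cells; NaN (missing) for zero cells."""
    calls = np.asarray(calls, dtype=bool)
    if calls.size == 0:
        warnings.warn("no cells: percent positive undefined", stacklevel=2)
        return float("nan")
    return 100.0 * float(calls.sum()) / calls.size


def mac_within_achr_pos(achr_calls, marker_calls) -> float:
    """% marker-positive cells within the AChR-positive population.

    100 x (AChR & marker double-positive) / AChR-positive; NaN with a warning
    when there are no AChR-positive cells.
    """
    achr = np.asarray(achr_calls, dtype=bool)
    marker = np.asarray(marker_calls, dtype=bool)
    if achr.shape != marker.shape:
        raise ValueError("call vectors must have equal length")
    n_pos = int(achr.sum())
    if n_pos == 0:
        warnings.warn("no AChR-positive cells: readout undefined", stacklevel=2)
        return float("nan")
    return 100.0 * float((achr & marker).sum()) / n_pos
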