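"""Formats and configuration: multi-page TIFF fields, plate maps, CSV tables.

Images travel as multi-page TIFF (one page per channel) with a JSON sidecar
carrying the channel order/roles, arm, well and pixel size.  Tabular outputs
are CSV with a leading ``#`` provenance comment (config hash + seed); the
missing-value sentinel is an empty field, never 0.  Configuration is JSON,
validated on load.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .simulate import ARMS, ImageField

__all__ = [
    "write_field",
    "read_field",
    "read_platemap",
    "validate_platemap",
    "config_hash",
    "load_config",
    "write_table",
    "read_table",
]

logger = logging.getLogger("mgstrat")

_CHANNEL_ORDER = ("nuclear", "actin", "achr", "marker")
_MARKER_TARGETS = ("MAC", "IgG", "IgA", "IgM")


def write_field(field: ImageField, path: str | Path) -> Path:
    """Write a field as multi-page TIFF plus a ``.json`` channel-map sidecar."""
    path = Path(path)
    stack = np.stack([np.asarray(field.channels[c], dtype=np.float32)
                      for c in _CHANNEL_ORDER])
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "channels": list(_CHANNEL_ORDER),
        "marker_target": field.marker_target,
        "arm": field.arm,
        "well_id": field.well_id,
        "pixel_size_um": field.pixel_size_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_field(path: str | Path) -> ImageField:
    """Read a multi-page TIFF written by :func:`write_field`."""
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    channels = {role: np.asarray(stack[i], dtype=float)
                for i, role in enumerate(meta["channels"])}
    return ImageField(
        channels=channels,
        pixel_size_um=meta.get("pixel_size_um"),
        well_id=meta.get("well_id"),
        arm=meta.get("arm"),
        marker_target=meta.get("marker_target", "MAC"),
    )


def validate_platemap(plate_map: pd.DataFrame) -> pd.DataFrame:
    """Check a plate map's schema, arm vocabulary and NHS controls.

    Every plate must contain at least one ``NHS_only`` control well (fold
    changes are undefined without it).  Violations raise ``ValueError`` naming
    the offending rows/fields.
    """
    required = {"well_id", "patient_id", "arm", "plate_id", "marker_target"}
    missing = required - set(plate_map.columns)
    if missing:
        raise ValueError(f"plate map missing columns: {sorted(missing)}")
    bad = plate_map[~plate_map["arm"].isin(ARMS)]
    if len(bad):
        raise ValueError(
            f"unknown arm(s) {sorted(bad['arm'].unique())} in wells "
            f"{bad['well_id'].tolist()}")
    bad_marker = plate_map[~plate_map["marker_target"].isin(_MARKER_TARGETS)]
    if len(bad_marker):
        raise ValueError(
            f"unknown marker target(s) {sorted(bad_marker['marker_target'].unique())}")
    for plate, grp in plate_map.groupby("plate_id"):
        if not (grp["arm"] == "NHS_only").any():
            raise ValueError(f"plate {plate!r} has no NHS_only control well")
    return plate_map


def read_platemap(path: str | Path) -> pd.DataFrame:
    return validate_platemap(pd.read_csv(path, comment="#", dtype={"patient_id": str}))


def config_hash(config: dict) -> str:
    """Short sha256 of a canonical-JSON config, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    cfg = json.loads(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a JSON object")
    return cfg


def write_table(df: pd.DataFrame, path: str | Path, cfg_hash: str, seed: int) -> Path:
    """CSV with a provenance comment line; missing values as empty fields."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mgstrat config_sha256={cfg_hash} seed={seed}\n")
        df.to_csv(fh, index=False, na_rep="")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype={"patient_id": str})
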