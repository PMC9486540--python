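"""Pipeline driver: simulate -> segment -> quantify -> stratify.

Runs the whole stratification analysis from a single JSON-style configuration,
deterministically for a given seed, and writes per-stage tables (wells,
per-patient readouts in the shape of the published cohort table, cohort
summary) plus a run log recording every defaulted parameter.  Two input modes:

* ``mode="tabular"`` — the cohort fast path: well-level percentages straight
  from the generator, no imaging;
* ``mode="imaging"`` — full image route: for each patient x arm a field is
  simulated (complement assay for the AChR/MAC readouts, binding assay for
  the IgG readout), segmented and spot-quantified into well measurements.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .segment import detect_nuclei, segment_cells
from .simulate import (PhenotypeParams, SimulationConfig, generate_cohort_tables,
                       generate_field)
from .spots import (call_positive, detect_spots, mac_within_achr_pos,
                    per_cell_spot_sum, percent_positive)
from .stratify import cohort_summary, patient_readouts

__all__ = ["run_pipeline", "measure_well", "DEFAULT_CONFIG"]

logger = logging.getLogger("mgstrat")

_IMAGING_ARMS = ("NHS_only", "plasma_NHS", "plasma_NHS_antiC7",
                 "plasma_NHS_isotype", "ctrl_plasma_NHS")

DEFAULT_CONFIG = {
    "mode": "tabular",
    "seed": 0,
    "n_patients_per_category": {"cat1": 9, "cat2": 3, "cat3": 1, "cat4": 7},
    "n_replicates": 3,
    "ig_population": "all",
    # imaging-mode field parameters (SimulationConfig overrides)
    "field": {},
}


def measure_well(
    config: SimulationConfig,
    phenotype: PhenotypeParams,
    arm: str,
    ig_population: str = "all",
) -> dict:
    """Simulate, segment and quantify one patient/arm into well readouts.

    Generates the complement-assay field (AChR + MAC channels) and the
    matching binding-assay field (AChR + Ig channels, relevant on plasma
    arms), runs nuclei/cell segmentation and LoG spot quantification, and
    returns the four percentage readouts.  ``ig_population`` picks the
    denominator of the uncorrected Ig-positive percentage: all cells
    (default) or the AChR-positive population only.
    """
    field, _ = generate_field(config.with_(assay="complement"), phenotype, arm)
    nuclei = detect_nuclei(field)
    cells = segment_cells(field, nuclei)
    achr_sums = per_cell_spot_sum(detect_spots(field, cells, "achr"), cells)["spot_sum"]
    mac_sums = per_cell_spot_sum(detect_spots(field, cells, "marker"), cells)["spot_sum"]
    achr_pos = call_positive(achr_sums, "otsu")
    mac_pos = call_positive(mac_sums, 1.0)  # any detected MAC spot marks the cell
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pct_achr = percent_positive(achr_pos)
        pct_mac_in_achr = mac_within_achr_pos(achr_pos, mac_pos)

    pct_ig = pct_ig_neg = float("nan")
    if arm == "plasma_NHS":
        bfield, _ = generate_field(
            config.with_(assay="binding", seed=config.seed + 1), phenotype, arm)
        bnuclei = detect_nuclei(bfield)
        bcells = segment_cells(bfield, bnuclei)
        b_achr = per_cell_spot_sum(detect_spots(bfield, bcells, "achr"), bcells)["spot_sum"]
        b_ig = per_cell_spot_sum(detect_spots(bfield, bcells, "marker"), bcells)["spot_sum"]
        b_achr_pos = call_positive(b_achr, "otsu")
        b_ig_pos = call_positive(b_ig, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if ig_population == "achr_pos":
                pct_ig = percent_positive(b_ig_pos[b_achr_pos])
            else:
                pct_ig = percent_positive(b_ig_pos)
            pct_ig_neg = percent_positive(b_ig_pos[~b_achr_pos])
    return {
        "pct_achr_pos": pct_achr,
        "pct_marker_pos_in_achr_pos": pct_mac_in_achr,
        "pct_ig_pos": pct_ig,
        "pct_ig_pos_in_achr_neg": pct_ig_neg,
    }


def _imaging_wells(cfg: dict) -> pd.DataFrame:
    rng = np.random.default_rng(cfg["seed"])
    field_cfg = SimulationConfig(**cfg.get("field", {}))
    rows = []
    pid = 0
    for cat in ("cat1", "cat2", "cat3", "cat4"):
        for _ in range(int(cfg["n_patients_per_category"].get(cat, 0))):
            pid += 1
            patient = f"P{pid:03d}"
            phen = PhenotypeParams.archetype(cat)
            for rep in range(1, int(cfg["n_replicates"]) + 1):
                plate = f"{patient}-plate{rep}"
                for arm in _IMAGING_ARMS:
                    # independent field per well, seeded from the run seed
                    wseed = int(rng.integers(0, 2**31 - 1))
                    readouts = measure_well(field_cfg.with_(seed=wseed), phen, arm,
                                            ig_population=cfg["ig_population"])
                    rows.append({
                        "patient_id": patient, "true_category": int(cat[-1]),
                        "arm": arm, "replicate": rep, "plate_id": plate,
                        **readouts,
                    })
                    logger.info("measured %s %s rep%d %s", patient, cat, rep, arm)
    return pd.DataFrame(rows)


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run the full stratification pipeline and write all outputs.

    ``config`` is a dict (or path to a JSON file) with the keys of
    ``DEFAULT_CONFIG``; missing keys take defaults and are logged.  Writes
    ``wells.csv``, ``patients.csv`` (cohort-table shape), ``summary.json``
    and ``run.log`` under ``out_dir``; returns the cohort summary dict.
    Rerunning with the same config yields byte-identical tables.
    """
    if isinstance(config, (str, Path)):
        config = mio.load_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if cfg["mode"] not in ("tabular", "imaging"):
        raise ValueError("mode must be 'tabular' or 'imaging'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        for key in DEFAULT_CONFIG:
            if key not in config:
                logger.info("config: %s defaulted to %r", key, DEFAULT_CONFIG[key])
        chash = mio.config_hash(cfg)
        seed = int(cfg["seed"])
        logger.info("run start: mode=%s seed=%d config_sha256=%s",
                    cfg["mode"], seed, chash)

        if cfg["mode"] == "tabular":
            wells = generate_cohort_tables(
                cfg["n_patients_per_category"], seed=seed,
                n_replicates=int(cfg["n_replicates"]))
        else:
            wells = _imaging_wells(cfg)
        if len(wells) == 0:
            mio.write_table(wells, out / "wells.csv", chash, seed)
            logger.info("empty cohort; nothing to stratify")
            return {"n_patients": 0, "counts": {1: 0, 2: 0, 3: 0, 4: 0},
                    "complement_dependent_n": 0,
                    "complement_dependent_fraction": float("nan"),
                    "complement_dependent_pct": None}

        mio.write_table(wells, out / "wells.csv", chash, seed)
        readouts = patient_readouts(
            wells.drop(columns=["true_category"]), ig_population=cfg["ig_population"])
        readouts = readouts.merge(
            wells[["patient_id", "true_category"]].drop_duplicates(), on="patient_id")
        mio.write_table(readouts, out / "patients.csv", chash, seed)
        summary = cohort_summary(readouts)
        summary["config_sha256"] = chash
        summary["seed"] = seed
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        logger.info("run complete: %s", summary)
        return summary
    finally:
        logger.removeHandler(handler)
        handler.close()
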