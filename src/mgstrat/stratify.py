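"""Patient-level stratification of anti-AChR Myasthenia Gravis plasma samples.

The cell-based stratification assay measures, per patient and treatment arm,
the percentage of AChR-positive cells, the percentage of MAC-positive cells
within the AChR-positive population, and the percentage of immunoglobulin
(IgG/IgA/IgM)-positive cells.  This module turns those well-level percentages
into the published readout classes and patient categories:

* AChR-loss and MAC-deposition fold changes relative to the normal-human-serum
  (NHS) control well on the same plate;
* ordinal classes (``-``, ``+``, ``++``, ``+++``) from fixed numeric bands;
* background-corrected IgG cell binding and its ordinal class;
* whether AChR loss is blocked by an anti-C7 antibody (``yes`` /
  ``yes_partial`` / ``no`` / ``na``);
* the four patient categories: 1 = strong C7-blockable AChR loss,
  2 = low C7-blockable AChR loss, 3 = AChR binding without complement effect,
  4 = little or no binding or effect.

Class-band conventions
----------------------
The published bands share endpoints; intervals here are half-open with the
boundary assigned to the milder class for the fold-change scales (a fold of
exactly 0.8 is ``-``, 1.3 is ``-``) and lower-bound inclusive for the
percentage scale (exactly 15% is ``+``).  Values beyond the printed scale ends
saturate: AChR fold > 1 is ``-`` (no loss), < 0.3 is ``++`` (the scale max for
that readout); MAC fold < 1 is ``-``, > 3.5 is ``+++``.  A fold change of
exactly 1 maps to ``-`` on both scales.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "CLASS_ORDER",
    "class_rank",
    "background_correct_ig",
    "fold_change",
    "classify_achr_fold",
    "classify_mac_fold",
    "classify_igg_binding",
    "assess_blockade",
    "assign_category",
    "cohort_summary",
    "spearman_correlation",
    "SpearmanResult",
    "patient_readouts",
    "load_reference_cohort",
]

#: Ordinal readout classes, mildest first.
CLASS_ORDER = ("-", "+", "++", "+++")

_RANK = {c: i for i, c in enumerate(CLASS_ORDER)}

#: Treatment arms used by the complement (AChR loss / MAC deposition) assay.
ARMS = (
    "medium_only",
    "NHS_only",
    "plasma_NHS",
    "plasma_NHS_antiC7",
    "plasma_NHS_isotype",
    "ctrl_plasma_NHS",
)


def class_rank(symbol: str) -> int:
    """Position of an ordinal class on the ``- < + < ++ < +++`` scale."""
    try:
        return _RANK[symbol]
    except KeyError:
        raise ValueError(f"unknown ordinal class {symbol!r}") from None


# ---------------------------------------------------------------------------
# elementary readout transforms
# ---------------------------------------------------------------------------

def background_correct_ig(pct_ig_pos: float, pct_ig_pos_in_achr_neg: float) -> float:
    """Background-corrected immunoglobulin binding.

    Subtracts the % Ig-positive cells within the AChR-negative population
    (non-AChR-specific binding) from the % Ig-positive cells, floored at 0
    since a negative percentage is an artefact of the subtraction.  Missing
    inputs propagate as NaN.
    """
    if pct_ig_pos is None or pct_ig_pos_in_achr_neg is None:
        return float("nan")
    a, b = float(pct_ig_pos), float(pct_ig_pos_in_achr_neg)
    if math.isnan(a) or math.isnan(b):
        return float("nan")
    for v in (a, b):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"percentage {v} outside [0, 100]")
    return max(a - b, 0.0)


def fold_change(treatment_value: float, nhs_value: float) -> float:
    """Treatment readout divided by the NHS-only control readout (same plate)."""
    t, n = float(treatment_value), float(nhs_value)
    if math.isnan(t) or math.isnan(n):
        return float("nan")
    if n <= 0:
        raise ValueError("NHS control value must be positive (plate control failure)")
    if t < 0:
        raise ValueError("treatment value must be nonnegative")
    return t / n


def classify_achr_fold(fc: float) -> str:
    """Ordinal AChR-loss class from the fold change vs NHS.

    Bands: [0.8, inf) -> "-", [0.6, 0.8) -> "+", (0, 0.6) -> "++" (shared
    band endpoints go to the milder class).  The scale for this readout is
    capped at "++".
    """
    fc = float(fc)
    if not math.isfinite(fc) or fc <= 0:
        raise ValueError(f"fold change must be finite and positive, got {fc}")
    if fc >= 0.8:
        return "-"
    if fc >= 0.6:
        return "+"
    return "++"


def classify_mac_fold(fc: float) -> str:
    """Ordinal MAC-deposition class from the fold change vs NHS.

    Bands: (0, 1.3] -> "-", (1.3, 1.8] -> "+", (1.8, 2.3] -> "++",
    (2.3, inf) -> "+++".
    """
    fc = float(fc)
    if not math.isfinite(fc) or fc <= 0:
        raise ValueError(f"fold change must be finite and positive, got {fc}")
    if fc <= 1.3:
        return "-"
    if fc <= 1.8:
        return "+"
    if fc <= 2.3:
        return "++"
    return "+++"


def classify_igg_binding(corrected_pct: float) -> str:
    """Ordinal IgG cell-binding class from the background-corrected percentage.

    Bands: [0, 15) -> "-", [15, 40) -> "+", [40, 65) -> "++", [65, 100] -> "+++".
    """
    v = float(corrected_pct)
    if not 0.0 <= v <= 100.0:
        raise ValueError(f"corrected percentage {v} outside [0, 100]")
    if v < 15:
        return "-"
    if v < 40:
        return "+"
    if v < 65:
        return "++"
    return "+++"


def assess_blockade(
    achr_fold_plasma: float,
    achr_fold_antiC7: float,
    achr_fold_isotype: float,
) -> str:
    """Whether the anti-C7 antibody blocks the plasma-induced AChR loss.

    Returns ``"na"`` when the plasma arm shows no AChR loss (class ``-``);
    ``"yes"`` when the anti-C7 arm reverts to class ``-`` while the isotype
    control arm matches the plasma arm; ``"yes_partial"`` when the anti-C7 arm
    improves the class by at least one step without reaching ``-``; otherwise
    ``"no"``.  Missing arms give ``"na"`` with a warning.
    """
    if any(
        v is None or math.isnan(float(v))
        for v in (achr_fold_plasma, achr_fold_antiC7, achr_fold_isotype)
    ):
        warnings.warn("missing treatment arm; blockade status undetermined", stacklevel=2)
        return "na"
    c_plasma = classify_achr_fold(achr_fold_plasma)
    if c_plasma == "-":
        return "na"
    c_anti = classify_achr_fold(achr_fold_antiC7)
    c_iso = classify_achr_fold(achr_fold_isotype)
    if c_anti == "-" and c_iso == c_plasma:
        return "yes"
    if c_anti != "-" and class_rank(c_plasma) - class_rank(c_anti) >= 1:
        return "yes_partial"
    return "no"


def assign_category(achr_class: str, blockade: str, mac_class: str, igg_class: str) -> int:
    """Assign the four-way patient category from the readout classes.

    Category 1: strong (``++``) AChR loss; category 2: low (``+``) AChR loss;
    category 3: no AChR loss but at least moderate (``++``) IgG cell binding;
    category 4: neither.  Total over every class combination.
    """
    for c in (achr_class, mac_class, igg_class):
        class_rank(c)  # validates
    if blockade not in ("yes", "yes_partial", "no", "na"):
        raise ValueError(f"unknown blockade status {blockade!r}")
    if achr_class == "++":
        return 1
    if achr_class == "+":
        return 2
    if class_rank(igg_class) >= class_rank("++"):
        return 3
    return 4


def cohort_summary(readouts: pd.DataFrame) -> dict:
    """Per-category counts and the complement-dependent fraction of a cohort.

    ``readouts`` needs a ``category`` column (integers 1-4).  The
    complement-dependent fraction is the share of patients in categories 1 or 2
    (clear C7-dependent AChR loss); it is also reported as a percentage rounded
    to the nearest integer.
    """
    if len(readouts) == 0:
        raise ValueError("empty cohort")
    cats = readouts["category"].astype(int)
    if not cats.isin([1, 2, 3, 4]).all():
        raise ValueError("categories must be in {1, 2, 3, 4}")
    counts = {k: int((cats == k).sum()) for k in (1, 2, 3, 4)}
    n = int(len(cats))
    frac = (counts[1] + counts[2]) / n
    return {
        "n_patients": n,
        "counts": counts,
        "complement_dependent_n": counts[1] + counts[2],
        "complement_dependent_fraction": frac,
        "complement_dependent_pct": int(round(100 * frac)),
    }


# ---------------------------------------------------------------------------
# Spearman correlation with Fisher-z confidence interval
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


def spearman_correlation(x, y, confidence: float = 0.95) -> SpearmanResult:
    """Two-tailed Spearman rank correlation with a Fisher-z confidence interval.

    The CI transforms rho with arctanh, uses the large-sample standard error
    ``1/sqrt(n - 3)``, and back-transforms.  Constant vectors give an undefined
    rho, reported as NaN with a warning.  Requires n >= 4 finite pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input vector; Spearman rho undefined", stacklevel=2)
        return SpearmanResult(float("nan"), float("nan"), float("nan"), float("nan"), n)
    rho, p = _stats.spearmanr(x, y, alternative="two-sided")
    rho = float(rho)
    if abs(rho) >= 1.0:  # degenerate CI at perfect monotonicity
        return SpearmanResult(rho, float(p), rho, rho, n)
    z = math.atanh(rho)
    se = 1.0 / math.sqrt(n - 3)
    zc = _stats.norm.ppf(0.5 + confidence / 2)
    return SpearmanResult(rho, float(p), math.tanh(z - zc * se), math.tanh(z + zc * se), n)


# ---------------------------------------------------------------------------
# well-level table -> per-patient readouts
# ---------------------------------------------------------------------------

def patient_readouts(wells: pd.DataFrame, ig_population: str = "all") -> pd.DataFrame:
    """Aggregate well-level measurements into per-patient classified readouts.

    ``wells`` is a long-format table with one row per (patient, arm, replicate)
    and columns ``patient_id, arm, replicate, plate_id, pct_achr_pos,
    pct_marker_pos_in_achr_pos, pct_ig_pos, pct_ig_pos_in_achr_neg``.  For each
    patient and replicate, fold changes for the plasma, anti-C7 and isotype
    arms are computed against the NHS-only control well of the same plate,
    then averaged over replicates before classification (the per-patient value
    is the mean over independent experiments).

    ``ig_population`` selects the uncorrected minuend of the background
    correction: ``"all"`` (default) uses % Ig-positive among all cells;
    ``"achr_pos"`` expects ``pct_ig_pos`` to already be restricted to the
    AChR-positive population (the table supplies it either way; the switch
    only documents the convention used upstream).

    Returns one row per patient with fold changes, ordinal classes, blockade
    status and the assigned category.
    """
    if ig_population not in ("all", "achr_pos"):
        raise ValueError("ig_population must be 'all' or 'achr_pos'")
    required = {
        "patient_id", "arm", "replicate", "plate_id",
        "pct_achr_pos", "pct_marker_pos_in_achr_pos",
        "pct_ig_pos", "pct_ig_pos_in_achr_neg",
    }
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")
    bad_arms = set(wells["arm"]) - set(ARMS)
    if bad_arms:
        raise ValueError(f"unknown treatment arms: {sorted(bad_arms)}")

    rows = []
    for patient, grp in wells.groupby("patient_id", sort=True):
        achr_folds: dict[str, list[float]] = {a: [] for a in ARMS}
        mac_folds: dict[str, list[float]] = {a: [] for a in ARMS}
        ig_corrected: list[float] = []
        for _, rep_grp in grp.groupby("replicate"):
            by_arm = rep_grp.set_index("arm")
            if "NHS_only" not in by_arm.index:
                raise ValueError(
                    f"patient {patient!r}: replicate without NHS_only control well"
                )
            nhs_achr = by_arm.at["NHS_only", "pct_achr_pos"]
            nhs_mac = by_arm.at["NHS_only", "pct_marker_pos_in_achr_pos"]
            for arm in by_arm.index:
                if arm == "NHS_only":
                    continue
                achr_folds[arm].append(fold_change(by_arm.at[arm, "pct_achr_pos"], nhs_achr))
                mac_folds[arm].append(
                    fold_change(by_arm.at[arm, "pct_marker_pos_in_achr_pos"], nhs_mac)
                )
            plasma_rows = rep_grp[rep_grp["arm"] == "plasma_NHS"]
            for _, r in plasma_rows.iterrows():
                corr = background_correct_ig(r["pct_ig_pos"], r["pct_ig_pos_in_achr_neg"])
                if not math.isnan(corr):
                    ig_corrected.append(corr)

        def _mean(vals: list[float]) -> float:
            vals = [v for v in vals if not math.isnan(v)]
            return float(np.mean(vals)) if vals else float("nan")

        achr_fold = _mean(achr_folds["plasma_NHS"])
        mac_fold = _mean(mac_folds["plasma_NHS"])
        achr_fold_anti = _mean(achr_folds["plasma_NHS_antiC7"])
        achr_fold_iso = _mean(achr_folds["plasma_NHS_isotype"])
        igg_pct = _mean(ig_corrected)

        achr_class = classify_achr_fold(achr_fold) if not math.isnan(achr_fold) else None
        mac_class = classify_mac_fold(mac_fold) if not math.isnan(mac_fold) else None
        igg_class = classify_igg_binding(igg_pct) if not math.isnan(igg_pct) else None
        if None in (achr_class, mac_class, igg_class):
            raise ValueError(f"patient {patient!r}: incomplete readouts, cannot classify")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            blockade = assess_blockade(achr_fold, achr_fold_anti, achr_fold_iso)
        category = assign_category(achr_class, blockade, mac_class, igg_class)
        rows.append({
            "patient_id": patient,
            "igg_binding_pct": igg_pct,
            "igg_class": igg_class,
            "achr_fold": achr_fold,
            "mac_fold": mac_fold,
            "achr_class": achr_class,
            "mac_class": mac_class,
            "blockade": blockade,
            "category": category,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reference cohort (published readout classes of the 19-patient MG cohort)
# ---------------------------------------------------------------------------

# Readout classes, anti-C7 blockade status, autoantibody titres (nmol/L; empty
# where below the assay detection range) and printed category for the
# 19-patient MG study cohort plus the pooled healthy-control plasma row.
_REFERENCE_COHORT_CSV = """\
patient_id,achr_class,blockade,mac_class,igg_class,titre_nmol_l,category
2,++,yes,+,++,5.43,1
3,++,yes,++,+++,143.49,1
14,++,yes,+,++,13.65,1
15,++,yes,+,++,12.09,1
16,++,yes,+,++,23.60,1
17,++,yes,++,+++,67.52,1
MSDN04,++,yes_partial,+++,+++,130.32,1
MSDN09,++,yes,+++,+++,1.78,1
MSDN19,++,yes_partial,+++,+++,53.84,1
4,+,yes,-,++,4.80,2
12,+,yes,-,++,10.13,2
13,+,yes,-,+,3.80,2
1,-,na,-,++,18.40,3
5,-,na,-,+,16.28,4
8,-,na,-,+,2.18,4
9,-,na,-,+,3.21,4
11,-,na,-,+,4.37,4
18,-,na,-,-,41.89,4
MSDN12,-,na,+,-,,4
pooled_ctrl_plasma,-,na,-,-,,
"""

#: Per-category patient counts quoted in the published cohort figure legends.
#: The category-4 legend count (7) disagrees with the published per-patient
#: table, which lists 6 category-4 patients in a 19-patient cohort; the
#: discrepancy is reported, not resolved (see ``cohort_summary`` flags).
FIGURE_LEGEND_COUNTS = {1: 9, 2: 3, 3: 1, 4: 7}


def load_reference_cohort(include_control: bool = False) -> pd.DataFrame:
    """The published 19-patient MG cohort readout classes.

    One row per patient: ordinal AChR-loss / MAC / IgG classes, anti-C7
    blockade status, anti-AChR titre (NaN where below detection) and the
    printed category.  With ``include_control=True`` the pooled
    healthy-control plasma row (no category) is appended.
    """
    df = pd.read_csv(
        _io.StringIO(_REFERENCE_COHORT_CSV),
        dtype={"patient_id": str},
    )
    if not include_control:
        df = df[df["category"].notna()].copy()
        df["category"] = df["category"].astype(int)
    return df.reset_index(drop=True)
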