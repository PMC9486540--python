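"""Synthetic multi-channel fluorescence fields and cohort tables.

Generates seeded, fully ground-truthed stand-ins for the transfected-cell
stratification assay: an adherent monolayer of cells (nuclear + actin
channels) where a configurable fraction is transfected with the AChR subunits
and, optionally, Rapsyn.  With Rapsyn the surface AChR clusters into compact
spots (rendered as 2-D Gaussians); without it the receptor signal is spatially
diffuse and no spots exist.  Under the patient-plasma + serum arm, a
complement-activating phenotype strips the receptor clusters from a fraction
of cells (the loss factor is the retained fraction, so the mean AChR spot sum
is attenuated by it) and deposits MAC spots on AChR-bearing cells; the
anti-C7 arm reverts both to the serum-only baseline, while the
isotype-control arm matches the plasma arm.

Every stochastic choice flows from a single seed, so identical configurations
are bitwise reproducible.  Ground truth records, per cell, the nucleus
position, transfection state and the rendered (noiseless) spot intensity sums,
plus a per-spot table, letting the segmentation and spot-quantification
stages be validated against exact answers.

A tabular fast path (:func:`generate_cohort_tables`) emits well-level
percentage readouts for whole patient cohorts directly, bypassing imaging, so
the stratification stage can be exercised at scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "ARMS",
    "PhenotypeParams",
    "SimulationConfig",
    "ImageField",
    "FieldGroundTruth",
    "generate_field",
    "generate_cohort_tables",
]

#: Treatment arms of the complement assay.
ARMS = (
    "medium_only",
    "NHS_only",
    "plasma_NHS",
    "plasma_NHS_antiC7",
    "plasma_NHS_isotype",
    "ctrl_plasma_NHS",
)

#: Arms in which patient plasma (hence patient autoantibody) is present.
_PLASMA_ARMS = ("plasma_NHS", "plasma_NHS_antiC7", "plasma_NHS_isotype")
#: Arms in which the complement cascade can run to MAC on autoantibody-bound AChR.
_COMPLEMENT_ACTIVE_ARMS = ("plasma_NHS", "plasma_NHS_isotype")

# Archetype phenotypes. complement_activation drives both AChR loss
# (loss factor 1 - 0.55*ca) and MAC deposition (gain 1 + 2*max(0, ca-0.45)),
# so the archetypes land in the published class bands: cat1 -> AChR fold
# ~0.45 (++) with MAC fold ~2.1 (++); cat2 -> ~0.72 (+) with MAC ~1.1 (-);
# cat3 binds without complement effect; cat4 neither binds nor activates.
_ARCHETYPES = {
    "cat1": dict(igg_binding_strength=0.60, complement_activation=1.00, nonspecific_binding=0.03),
    "cat2": dict(igg_binding_strength=0.35, complement_activation=0.50, nonspecific_binding=0.03),
    "cat3": dict(igg_binding_strength=0.50, complement_activation=0.00, nonspecific_binding=0.03),
    "cat4": dict(igg_binding_strength=0.06, complement_activation=0.00, nonspecific_binding=0.03),
}

_ACHR_LOSS_SLOPE = 0.55
_MAC_GAIN_SLOPE = 2.0
_MAC_GAIN_KNEE = 0.45


@dataclass(frozen=True)
class PhenotypeParams:
    """Patient autoantibody phenotype.

    ``igg_binding_strength`` is the probability that a transfected cell is
    detectably coated by patient IgG; ``complement_activation`` (0-1) drives
    both the AChR loss factor and MAC deposition gain under active-complement
    arms; ``nonspecific_binding`` is the per-cell probability of non-AChR-
    specific immunoglobulin signal (the background subtracted downstream).
    """

    label: str
    igg_binding_strength: float
    complement_activation: float
    nonspecific_binding: float

    def __post_init__(self):
        for name in ("igg_binding_strength", "complement_activation"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (math.isfinite(self.nonspecific_binding) and self.nonspecific_binding >= 0):
            raise ValueError("nonspecific_binding must be finite and >= 0")

    @classmethod
    def archetype(cls, label: str) -> "PhenotypeParams":
        """Fixed archetype for categories ``"cat1"`` .. ``"cat4"``."""
        try:
            return cls(label=label, **_ARCHETYPES[label])
        except KeyError:
            raise ValueError(f"unknown archetype {label!r}; expected cat1..cat4") from None

    def achr_loss_factor(self, arm: str) -> float:
        """Multiplier on AChR spot intensity for a treatment arm (<= 1)."""
        _check_arm(arm)
        if arm in _COMPLEMENT_ACTIVE_ARMS:
            return 1.0 - _ACHR_LOSS_SLOPE * self.complement_activation
        return 1.0

    def mac_gain(self, arm: str) -> float:
        """Multiplier on the MAC spot rate for a treatment arm."""
        _check_arm(arm)
        if arm == "medium_only":
            return 0.0  # no serum, no complement source
        if arm in _COMPLEMENT_ACTIVE_ARMS:
            return 1.0 + _MAC_GAIN_SLOPE * max(0.0, self.complement_activation - _MAC_GAIN_KNEE)
        return 1.0


def _check_arm(arm: str) -> None:
    if arm not in ARMS:
        raise ValueError(f"unknown treatment arm {arm!r}; expected one of {ARMS}")


@dataclass(frozen=True)
class SimulationConfig:
    """Field-level simulation parameters.

    Defaults emulate a 10X wide-field capture of a transfected monolayer:
    1024x1024 px, ~500 cells, half of them transfected, Rapsyn present so the
    receptor clusters into compact Gaussian spots (count ~ Poisson, lognormal
    amplitude), CCD-like noise (Poisson shot + Gaussian read).  Identical
    config + seed yields bitwise-identical output.
    """

    seed: int = 0
    image_size: int = 1024
    n_cells_per_field: int = 500
    transfection_fraction: float = 0.5
    rapsyn: bool = True
    assay: str = "complement"  #: "complement" (marker=MAC) or "binding" (marker=Ig)
    spot_count_mean: float = 4.0
    spot_radius: float = 2.0  #: Gaussian sigma of a receptor cluster, px
    nucleus_radius: float = 7.0
    cell_radius: float = 16.0
    intensity_scales: dict = field(default_factory=lambda: {
        "nuclear": 1000.0, "actin": 600.0, "achr": 800.0, "marker": 800.0,
    })
    mac_base_rate: float = 0.15  #: expected MAC spots per AChR+ cell, NHS baseline
    read_noise_sd: float = 4.0
    shot_noise: bool = True
    pixel_size_um: float = 0.65

    def __post_init__(self):
        if self.assay not in ("complement", "binding"):
            raise ValueError("assay must be 'complement' or 'binding'")
        if not 0.0 <= self.transfection_fraction <= 1.0:
            raise ValueError("transfection_fraction must be in [0, 1]")
        for name in ("spot_count_mean", "spot_radius", "nucleus_radius",
                     "cell_radius", "mac_base_rate", "read_noise_sd", "pixel_size_um"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64 px")
        if self.n_cells_per_field < 0:
            raise ValueError("n_cells_per_field must be >= 0")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class ImageField:
    """One multi-channel field: role -> 2-D nonnegative intensity array."""

    channels: dict
    pixel_size_um: float | None = None
    well_id: str | None = None
    arm: str | None = None
    marker_target: str = "MAC"  #: what the marker channel stains (MAC or IgG/IgA/IgM)

    def __post_init__(self):
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channel arrays must share a shape")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape


@dataclass
class FieldGroundTruth:
    """Exact per-cell and per-spot truth for one simulated field.

    ``cells`` has one row per simulated cell (nucleus position, transfection
    state, rendered spot-intensity sums); ``spots`` one row per rendered spot
    (cell, channel, position, rendered intensity); ``spot_layer_integrals``
    maps channel -> integral of the noiseless spot layer, against which the
    per-cell sums conserve to numerical precision.
    """

    cells: pd.DataFrame
    spots: pd.DataFrame
    spot_layer_integrals: dict


def _add_gaussian(img: np.ndarray, cy: float, cx: float, sigma: float,
                  amplitude: float, truncate: float = 5.0) -> float:
    """Render an isotropic 2-D Gaussian into ``img``; return the added sum."""
    size = img.shape[0]
    r = int(math.ceil(truncate * sigma))
    y0, y1 = max(0, int(cy) - r), min(size, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(size, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return 0.0
    yy = np.arange(y0, y1, dtype=float)[:, None] - cy
    xx = np.arange(x0, x1, dtype=float)[None, :] - cx
    patch = amplitude * np.exp(-(yy ** 2 + xx ** 2) / (2.0 * sigma ** 2))
    img[y0:y1, x0:x1] += patch
    return float(patch.sum())


def _place_centers(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """Jittered-grid cell centers: dense, non-overlapping, deterministic."""
    if n == 0:
        return np.empty((0, 2))
    g = int(math.ceil(math.sqrt(n)))
    spacing = size / g
    ys, xs = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    centers = np.stack([(ys.ravel() + 0.5), (xs.ravel() + 0.5)], axis=1) * spacing
    jitter = rng.uniform(-0.22 * spacing, 0.22 * spacing, size=centers.shape)
    centers = centers + jitter
    keep = rng.choice(centers.shape[0], size=n, replace=False)
    return centers[np.sort(keep)]


def _sample_spot_offsets(rng: np.random.Generator, k: int, radius: float,
                         min_sep: float, max_tries: int = 60) -> np.ndarray:
    """Uniform offsets in a disk with pairwise separation >= min_sep.

    Receptor microclusters are discrete objects; enforcing a minimum
    separation keeps the per-cell spot count well-defined for validation.
    Spots that cannot be placed are dropped (rare at default densities).
    """
    placed: list[tuple[float, float]] = []
    for _ in range(k):
        for _ in range(max_tries):
            rr = radius * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            dy, dx = rr * math.sin(th), rr * math.cos(th)
            if all((dy - p[0]) ** 2 + (dx - p[1]) ** 2 >= min_sep ** 2 for p in placed):
                placed.append((dy, dx))
                break
    return np.asarray(placed).reshape(-1, 2)


def generate_field(
    config: SimulationConfig,
    phenotype: PhenotypeParams,
    arm: str,
) -> tuple[ImageField, FieldGroundTruth]:
    """Simulate one 4-channel field for a phenotype under a treatment arm.

    Returns the (noisy, per config) image plus exact ground truth.  The
    transfected fraction of cells carries AChR spots (Rapsyn on) or a diffuse
    receptor signal (Rapsyn off).  Under complement-active arms the AChR spot
    amplitudes are attenuated by the phenotype's loss factor and MAC spots are
    deposited on AChR-bearing cells; the anti-C7 arm reverts both to the
    serum-only baseline; the isotype arm matches the plasma arm.
    """
    _check_arm(arm)
    size = config.image_size
    scales = config.intensity_scales

    # Independent streams: layout/transfection, one per cell per channel, and
    # camera noise.  Per-cell streams couple the arms and phenotypes through
    # common random numbers, so e.g. raising complement_activation rescales a
    # cell's AChR spots by the loss factor (never increases the sum) and can
    # only add MAC spots (inverse-CDF Poisson count on a shared uniform).
    rng_layout = np.random.default_rng([config.seed, 0])
    rng_noise = np.random.default_rng([config.seed, 1])

    layers = {k: np.zeros((size, size)) for k in ("nuclear", "actin", "achr", "marker")}
    spot_layers = {"achr": np.zeros((size, size)), "marker": np.zeros((size, size))}

    centers = _place_centers(rng_layout, config.n_cells_per_field, size)
    n = centers.shape[0]
    transfected = rng_layout.uniform(size=n) < config.transfection_fraction

    cell_rows, spot_rows = [], []
    for i in range(n):
        cy, cx = centers[i]
        _add_gaussian(layers["nuclear"], cy, cx, config.nucleus_radius / 1.4, scales["nuclear"])
        _add_gaussian(layers["actin"], cy, cx, config.cell_radius / 1.6, scales["actin"])

        rng_achr = np.random.default_rng([config.seed, 10, i])
        rng_marker = np.random.default_rng([config.seed, 11, i])

        achr_sum = 0.0
        achr_count = 0
        achr_positions = np.empty((0, 2))
        achr_amps = np.empty(0)
        # no complement source in the binding assay (heat-inactivated plasma)
        loss = phenotype.achr_loss_factor(arm) if config.assay == "complement" else 1.0
        # complement attack strips the receptor clusters from whole cells:
        # the loss factor is the retained fraction of cluster-bearing cells
        # (a shared uniform couples arms, so more activation only ever ablates
        # more cells, never fewer)
        ablated = np.random.default_rng([config.seed, 13, i]).uniform() >= loss
        if transfected[i]:
            if config.rapsyn:
                if not ablated:
                    k = int(rng_achr.poisson(config.spot_count_mean))
                    offsets = _sample_spot_offsets(
                        rng_achr, k, 0.72 * config.cell_radius, 3.0 * config.spot_radius)
                    achr_amps = np.exp(rng_achr.normal(
                        math.log(max(scales["achr"], 1e-12)), 0.25, size=offsets.shape[0]))
                    achr_positions = centers[i] + offsets
                    for (sy, sx), amp in zip(achr_positions, achr_amps):
                        added = _add_gaussian(spot_layers["achr"], sy, sx,
                                              config.spot_radius, amp)
                        achr_sum += added
                        achr_count += 1
                        spot_rows.append({"cell_id": i + 1, "channel": "achr",
                                          "row": sy, "col": sx, "rendered_sum": added})
            else:
                # diffuse (unclustered) receptor: broad, low-amplitude layer,
                # not part of the spot layer and invisible to spot detection
                _add_gaussian(layers["achr"], cy, cx, 0.7 * config.cell_radius,
                              0.05 * scales["achr"] * loss)

        mac_sum, mac_count = 0.0, 0
        ig_signal = 0.0
        if config.assay == "complement":
            # MAC deposits on AChR-bearing cells; baseline rate under serum alone
            if transfected[i] and arm != "medium_only":
                lam = config.mac_base_rate * phenotype.mac_gain(arm)
                u = rng_marker.uniform()
                k = int(_stats.poisson.ppf(u, lam)) if lam > 0 else 0
                for _ in range(k):
                    off = _sample_spot_offsets(rng_marker, 1, 0.72 * config.cell_radius,
                                               3.0 * config.spot_radius)
                    if off.shape[0] == 0:
                        continue
                    sy, sx = centers[i] + off[0]
                    amp = math.exp(rng_marker.normal(
                        math.log(max(scales["marker"], 1e-12)), 0.25))
                    added = _add_gaussian(spot_layers["marker"], sy, sx,
                                          config.spot_radius, amp)
                    mac_sum += added
                    mac_count += 1
                    spot_rows.append({"cell_id": i + 1, "channel": "marker",
                                      "row": sy, "col": sx, "rendered_sum": added})
        else:
            # binding assay: patient Ig decorates the AChR clusters of bound
            # cells; nonspecific binders show sparse aggregates on any cell
            if (arm in _PLASMA_ARMS and transfected[i] and config.rapsyn
                    and achr_count > 0
                    and rng_marker.uniform() < phenotype.igg_binding_strength):
                amps = np.exp(rng_marker.normal(
                    math.log(max(scales["marker"], 1e-12)), 0.25, size=achr_count))
                for (sy, sx), amp in zip(achr_positions, amps):
                    added = _add_gaussian(spot_layers["marker"], sy, sx,
                                          config.spot_radius, amp)
                    ig_signal += added
                    spot_rows.append({"cell_id": i + 1, "channel": "marker",
                                      "row": sy, "col": sx, "rendered_sum": added})
            rng_ns = np.random.default_rng([config.seed, 12, i])
            if arm != "medium_only" and rng_ns.uniform() < min(phenotype.nonspecific_binding, 1.0):
                offsets = _sample_spot_offsets(rng_ns, 2, 0.72 * config.cell_radius,
                                               3.0 * config.spot_radius)
                for sy, sx in centers[i] + offsets:
                    added = _add_gaussian(spot_layers["marker"], sy, sx,
                                          config.spot_radius, 0.9 * scales["marker"])
                    ig_signal += added
                    spot_rows.append({"cell_id": i + 1, "channel": "marker",
                                      "row": sy, "col": sx, "rendered_sum": added})

        cell_rows.append({
            "cell_id": i + 1,
            "nucleus_row": cy,
            "nucleus_col": cx,
            "transfected": bool(transfected[i]),
            "rapsyn": bool(config.rapsyn),
            "true_achr_spot_count": achr_count,
            "true_achr_spot_sum": achr_sum,
            "true_mac_spot_count": mac_count,
            "true_mac_spot_sum": mac_sum,
            "true_ig_signal": ig_signal,
        })

    integrals = {ch: float(layer.sum()) for ch, layer in spot_layers.items()}
    layers["achr"] += spot_layers["achr"]
    layers["marker"] += spot_layers["marker"]

    for ch in ("nuclear", "actin", "achr", "marker"):
        img = layers[ch]
        if config.shot_noise:
            img = rng_noise.poisson(np.clip(img, 0, None)).astype(float)
        if config.read_noise_sd > 0:
            img = img + rng_noise.normal(0.0, config.read_noise_sd, size=img.shape)
        layers[ch] = np.clip(img, 0.0, None)

    field_obj = ImageField(
        channels=layers,
        pixel_size_um=config.pixel_size_um,
        arm=arm,
        marker_target="MAC" if config.assay == "complement" else "IgG",
    )
    spots_df = pd.DataFrame(
        spot_rows, columns=["cell_id", "channel", "row", "col", "rendered_sum"])
    truth = FieldGroundTruth(
        cells=pd.DataFrame(cell_rows),
        spots=spots_df,
        spot_layer_integrals=integrals,
    )
    return field_obj, truth


# ---------------------------------------------------------------------------
# tabular cohort fast path
# ---------------------------------------------------------------------------

def generate_cohort_tables(
    n_patients_per_category: dict,
    seed: int,
    n_replicates: int = 3,
    base_pct_achr_pos: float = 42.0,
    base_pct_mac_pos: float = 14.0,
    pct_noise_sd: float = 1.5,
    fold_noise_sd: float = 0.05,
    phenotype_jitter: float = 0.05,
) -> pd.DataFrame:
    """Well-level readout tables for a simulated patient cohort (no imaging).

    ``n_patients_per_category`` maps ``"cat1"``.. ``"cat4"`` to patient counts.
    Each patient gets a phenotype jittered around its category archetype and,
    per replicate experiment (one plate each), wells for the five treatment
    arms with multiplicative fold noise on treatment readouts, additive
    percentage noise, and IgG-binding columns on the plasma wells.  The
    emitted table feeds :func:`mgstrat.stratify.patient_readouts` directly.
    """
    for k in n_patients_per_category:
        if k not in _ARCHETYPES:
            raise ValueError(f"unknown category key {k!r}; expected cat1..cat4")
        if n_patients_per_category[k] < 0:
            raise ValueError("patient counts must be >= 0")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)

    rows = []
    patient_idx = 0
    for cat in ("cat1", "cat2", "cat3", "cat4"):
        for _ in range(int(n_patients_per_category.get(cat, 0))):
            patient_idx += 1
            pid = f"P{patient_idx:03d}"
            arch = _ARCHETYPES[cat]
            phen = PhenotypeParams(
                label=cat,
                igg_binding_strength=float(np.clip(
                    arch["igg_binding_strength"] + rng.normal(0, phenotype_jitter), 0, 1)),
                complement_activation=float(np.clip(
                    arch["complement_activation"] + rng.normal(0, phenotype_jitter), 0, 1)),
                nonspecific_binding=arch["nonspecific_binding"],
            )
            for rep in range(1, n_replicates + 1):
                plate = f"{pid}-plate{rep}"
                nhs_achr = base_pct_achr_pos * (1 + rng.normal(0, fold_noise_sd))
                nhs_mac = base_pct_mac_pos * (1 + rng.normal(0, fold_noise_sd))
                for arm in ("NHS_only", "plasma_NHS", "plasma_NHS_antiC7",
                            "plasma_NHS_isotype", "ctrl_plasma_NHS"):
                    if arm == "NHS_only":
                        achr, mac = nhs_achr, nhs_mac
                    else:
                        loss = phen.achr_loss_factor(arm)
                        # P(>=1 MAC spot) scales the % MAC-positive readout
                        lam0 = 0.15
                        p0 = 1 - math.exp(-lam0)
                        p1 = 1 - math.exp(-lam0 * phen.mac_gain(arm))
                        achr = nhs_achr * loss * (1 + rng.normal(0, fold_noise_sd))
                        mac = nhs_mac * (p1 / p0) * (1 + rng.normal(0, fold_noise_sd))
                    achr = float(np.clip(achr + rng.normal(0, pct_noise_sd), 0.1, 100))
                    mac = float(np.clip(mac + rng.normal(0, pct_noise_sd), 0.1, 100))
                    if arm == "plasma_NHS":
                        bg = 100 * phen.nonspecific_binding * (1 + abs(rng.normal(0, 0.3)))
                        ig_corr = 95.0 * phen.igg_binding_strength
                        ig_pos = float(np.clip(
                            ig_corr + bg + rng.normal(0, pct_noise_sd), 0, 100))
                        ig_neg = float(np.clip(bg + rng.normal(0, 0.5), 0, 100))
                    else:
                        ig_pos = ig_neg = float("nan")
                    rows.append({
                        "patient_id": pid,
                        "true_category": int(cat[-1]),
                        "arm": arm,
                        "replicate": rep,
                        "plate_id": plate,
                        "pct_achr_pos": achr,
                        "pct_marker_pos_in_achr_pos": mac,
                        "pct_ig_pos": ig_pos,
                        "pct_ig_pos_in_achr_neg": ig_neg,
                    })
    columns = ["patient_id", "true_category", "arm", "replicate", "plate_id",
               "pct_achr_pos", "pct_marker_pos_in_achr_pos",
               "pct_ig_pos", "pct_ig_pos_in_achr_neg"]
    return pd.DataFrame(rows, columns=columns)
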