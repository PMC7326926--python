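"""Synthetic multiplex-IF cores and survival cohorts with ground truth.

The original patient images and clinical tables are not publicly
available, so this module generates stand-ins that preserve the structure
the analysis depends on:

* TMA-core-like images containing CD20+ tumor (B) cells and CD3+ reactive
  T cells, each painted as concentric disks (nucleus, cytoplasm annulus,
  membrane annulus) with per-cell lognormal marker intensities. T cells
  may express BCL2 — exactly the contamination that tumor gating must
  remove.
* Patient cohorts whose overall and event-free survival depend on true
  BCL2/MYC expression groups through an exponential proportional-hazards
  model, with affine (shift + scale) batch effects on observed scores.

Every generator takes an explicit seed and is bit-reproducible; no global
random state is touched. Ground truth (per-cell phenotype and intensity,
per-patient risk group and linear predictor) is returned alongside the
data so downstream stages can be scored against it.

Default intensity parameters for tumor-cell BCL2 are calibrated so the
per-cell mean intensity distribution is strongly right-skewed with median
~11.5 and mean ~25.7 on the raw scale, the qualitative shape seen in
DLBCL cohorts; other markers' parameters are plausible but not claimed to
match any particular dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ChannelStack, ConfigurationError, PlacementError

CHANNELS = ("DAPI", "CD20", "CD3", "BCL2", "MYC")

# Lognormal (mu, sigma) of per-cell marker intensity on the raw scale,
# keyed by marker then phenotype. Tumor BCL2: median exp(mu) = 11.504 and
# mean exp(mu + sigma^2/2) = 25.739 give mu = 2.4428, sigma = 1.2691.
DEFAULT_INTENSITY_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "DAPI": {"tumor": (math.log(100.0), 0.3), "t_cell": (math.log(100.0), 0.3)},
    "CD20": {"tumor": (math.log(60.0), 0.4), "t_cell": (-np.inf, 0.0)},
    "CD3": {"tumor": (-np.inf, 0.0), "t_cell": (math.log(60.0), 0.4)},
    "BCL2": {"tumor": (2.4428, 1.2691), "t_cell": (math.log(6.0), 0.9)},
    "MYC": {"tumor": (math.log(9.0), 1.0), "t_cell": (-np.inf, 0.0)},
}

# Marker -> compartment it is painted in (and later quantified in).
MARKER_COMPARTMENT = {
    "DAPI": "nucleus",
    "CD20": "membrane",
    "CD3": "cytoplasm",
    "BCL2": "cytoplasm",
    "MYC": "nucleus",
}


@dataclass
class ImageSimParams:
    """Geometry, intensity model and noise for one synthetic core image."""

    image_size_px: tuple[int, int] = (512, 512)
    n_tumor_cells: int = 50
    n_t_cells: int = 20
    nucleus_radius_px: tuple[float, float] = (6.0, 1.0)  # (mean, sd)
    cytoplasm_width_px: float = 3.0
    membrane_width_px: float = 2.0
    marker_intensity_model: dict = field(
        default_factory=lambda: {
            m: dict(v) for m, v in DEFAULT_INTENSITY_MODEL.items()
        }
    )
    noise_sd: float = 0.5
    min_center_separation_px: float | None = None  # default derived from geometry
    max_placement_attempts: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor_cells < 0 or self.n_t_cells < 0:
            raise ConfigurationError("cell counts must be >= 0")
        if self.cytoplasm_width_px < 1 or self.membrane_width_px < 1:
            raise ConfigurationError("ring widths must be >= 1 px")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        mean_r, sd_r = self.nucleus_radius_px
        if mean_r <= 0 or sd_r < 0:
            raise ConfigurationError("nucleus radius mean must be > 0, sd >= 0")
        if self.min_center_separation_px is None:
            # Two cells never overlap: separation covers both outer radii at
            # the radius clip bound (mean + 2 sd), plus a 1-px guard band.
            outer = mean_r + 2.0 * sd_r + self.cytoplasm_width_px + self.membrane_width_px
            self.min_center_separation_px = 2.0 * outer + 1.0
        if self.min_center_separation_px < 2.0 * mean_r:
            raise ConfigurationError(
                "min_center_separation_px must be >= 2 x mean nucleus radius"
            )


@dataclass
class SimTruth:
    """Generator ground truth.

    ``cells``: one row per painted cell — label, phenotype, center
    (row, col), nucleus radius, and the true per-cell mean raw intensity
    of each marker (0 where the phenotype does not express it).

    ``patients``: one row per simulated patient — true risk groups, true
    (undistorted) scores, linear predictor, and latent event/censoring
    times. ``None`` for image-only simulations.
    """

    cells: pd.DataFrame | None = None
    patients: pd.DataFrame | None = None


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_sep: float,
    max_attempts: int,
) -> np.ndarray:
    """Rejection-sample ``n`` centers with pairwise distance >= min_sep."""
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if n > 0 and (hi_r <= lo_r or hi_c <= lo_c):
        raise PlacementError(
            f"image {shape} too small for cell margin {margin:.1f}px"
        )
    centers: list[tuple[float, float]] = []
    attempts = 0
    min_sep2 = min_sep * min_sep
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            density = n / (shape[0] * shape[1])
            raise PlacementError(
                f"could not place {n} cells at separation {min_sep:.1f}px in a "
                f"{shape[0]}x{shape[1]} image (density {density:.2e} cells/px^2) "
                f"after {max_attempts} attempts"
            )
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep2 for rr, cc in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=float).reshape(n, 2)


def _draw_intensity(rng: np.random.Generator, mu: float, sigma: float) -> float:
    if not np.isfinite(mu):
        return 0.0
    if sigma == 0.0:
        return float(math.exp(mu))
    return float(rng.lognormal(mu, sigma))


def simulate_core_image(params: ImageSimParams) -> tuple[ChannelStack, SimTruth]:
    """Render one synthetic 5-channel core and its cell-level truth.

    Cells are non-overlapping concentric disks. Each cell paints DAPI into
    its nucleus; tumor cells additionally paint CD20 into the membrane
    ring, BCL2 into the cytoplasm ring and MYC into the nucleus; T cells
    paint CD3 and BCL2 into the cytoplasm. Per-cell intensity is constant
    across the compartment (the drawn value IS the cell's true mean);
    additive Gaussian noise, clipped at zero, is applied afterwards.
    """
    rng = np.random.default_rng(params.seed)
    nrow, ncol = params.image_size_px
    mean_r, sd_r = params.nucleus_radius_px
    n_total = params.n_tumor_cells + params.n_t_cells

    margin = mean_r + 2.0 * sd_r + params.cytoplasm_width_px + params.membrane_width_px + 1.0
    centers = (
        _place_centers(
            rng, n_total, (nrow, ncol), margin,
            params.min_center_separation_px, params.max_placement_attempts,
        )
        if n_total
        else np.empty((0, 2))
    )

    phenotypes = ["tumor"] * params.n_tumor_cells + ["t_cell"] * params.n_t_cells
    radii = np.clip(
        rng.normal(mean_r, sd_r, size=n_total),
        max(2.0, mean_r - 2.0 * sd_r),
        mean_r + 2.0 * sd_r,
    )

    pixels = np.zeros((len(CHANNELS), nrow, ncol), dtype=float)
    chan_index = {m: i for i, m in enumerate(CHANNELS)}
    rows_truth: list[dict] = []

    for label, (center, phen, r_nuc) in enumerate(
        zip(centers, phenotypes, radii), start=1
    ):
        cr, cc = center
        r_cyt = r_nuc + params.cytoplasm_width_px
        r_mem = r_cyt + params.membrane_width_px

        r0 = max(0, int(math.floor(cr - r_mem - 1)))
        r1 = min(nrow, int(math.ceil(cr + r_mem + 2)))
        c0 = max(0, int(math.floor(cc - r_mem - 1)))
        c1 = min(ncol, int(math.ceil(cc + r_mem + 2)))
        rr, cj = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        dist = np.hypot(rr - cr, cj - cc)
        nucleus = dist <= r_nuc
        cytoplasm = (dist > r_nuc) & (dist <= r_cyt)
        membrane = (dist > r_cyt) & (dist <= r_mem)
        comp_masks = {"nucleus": nucleus, "cytoplasm": cytoplasm, "membrane": membrane}

        truth_row: dict = {
            "label": label,
            "phenotype": phen,
            "center_row": cr,
            "center_col": cc,
            "nucleus_radius": float(r_nuc),
        }
        for marker in CHANNELS:
            mu, sigma = params.marker_intensity_model[marker][phen]
            value = _draw_intensity(rng, mu, sigma)
            truth_row[f"true_{marker}"] = value
            if value > 0.0:
                comp = MARKER_COMPARTMENT[marker]
                mask = comp_masks[comp]
                pixels[chan_index[marker], r0:r1, c0:c1][mask] = value
        rows_truth.append(truth_row)

    if params.noise_sd > 0:
        pixels += rng.normal(0.0, params.noise_sd, size=pixels.shape)
        np.clip(pixels, 0.0, None, out=pixels)

    truth_cols = [
        "label", "phenotype", "center_row", "center_col", "nucleus_radius",
    ] + [f"true_{m}" for m in CHANNELS]
    cells = pd.DataFrame(rows_truth, columns=truth_cols)
    return ChannelStack(pixels, CHANNELS), SimTruth(cells=cells)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Default per-batch affine distortion applied to observed scores:
#: batch label -> (additive shift, multiplicative scale).
DEFAULT_BATCHES: dict[str, tuple[float, float]] = {
    "site_A": (0.0, 1.0),
    "site_B": (8.0, 1.25),
    "site_C": (-5.0, 0.8),
}

#: Marginal probabilities of clinical covariates, matching the frequencies
#: of a typical R-CHOP-treated DLBCL training cohort.
COVARIATE_MARGINALS = {
    "age_gt60": 0.443,
    "sex_male": 0.570,
    "ldh_high": 0.457,
    "b_symptoms": 0.265,
    "hb_low": 0.493,
    "stage34": 0.570,
    "ipi_high": 0.367,
    "bm_involvement": 0.205,
    "coo_non_gcb": 0.686,
    "coo_na": 0.063,
}


@dataclass
class CohortSimParams:
    """Cohort size, risk model and batch structure for survival simulation.

    Hazards follow an exponential proportional-hazards model: a patient's
    event rate is ``baseline_hazard * exp(lp)`` where the linear predictor
    ``lp`` sums the log hazard ratios of their true high-BCL2, high-MYC
    and high-IPI indicators. Censoring is independent exponential, capped
    at ``accrual_months``. Times are in months.
    """

    n_patients: int = 300
    high_bcl2_prevalence: float = 0.389
    high_myc_prevalence: float = 0.249
    true_log_hr_bcl2: float = math.log(2.0)
    true_log_hr_myc: float = math.log(1.5)
    true_log_hr_ipi: float = math.log(2.0)
    baseline_hazard: float = 0.004      # events/month in the all-low group
    censoring_rate: float = 0.006       # independent censoring, events/month
    accrual_months: float = 120.0
    efs_extra_hazard: float = 0.004     # added progression hazard (same lp)
    batches: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BATCHES)
    )
    # True (undistorted) score distributions per group: (mean, sd).
    bcl2_score_low: tuple[float, float] = (30.0, 7.0)
    bcl2_score_high: tuple[float, float] = (55.0, 8.0)
    myc_score_low: tuple[float, float] = (32.0, 8.0)
    myc_score_high: tuple[float, float] = (60.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        for p in (self.high_bcl2_prevalence, self.high_myc_prevalence):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"prevalence {p} outside [0, 1]")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.censoring_rate < 0 or self.efs_extra_hazard < 0:
            raise ConfigurationError("rates must be >= 0")
        for name, (_, scale) in self.batches.items():
            if scale <= 0:
                raise ConfigurationError(f"batch {name!r} scale must be > 0")


def _exp_times(rng: np.random.Generator, rate: float | np.ndarray, n: int) -> np.ndarray:
    rate = np.broadcast_to(np.asarray(rate, dtype=float), (n,))
    out = np.full(n, np.inf)
    pos = rate > 0
    out[pos] = rng.exponential(1.0 / rate[pos])
    return out


def simulate_cohort(
    params: CohortSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a patient cohort with PH-linked survival and batch effects.

    Returns
    -------
    scores : DataFrame
        One row per patient: observed (batch-distorted) BCL2/MYC scores,
        a proportion-only conventional percentage, and the batch label.
    clinical : DataFrame
        One row per patient: OS/EFS times and event flags plus covariates,
        in the layout expected by the clinical readers and Cox models.
    truth : SimTruth
        Per-patient true groups, true scores, linear predictor and latent
        times.

    The conventional percentage is driven by the fraction of positive
    cells alone, independent of intensity, so a patient can be
    conventional-high while truly low-risk — the discordance the
    reclassification analysis quantifies.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients

    high_bcl2 = rng.random(n) < params.high_bcl2_prevalence
    high_myc = rng.random(n) < params.high_myc_prevalence

    cov = {k: rng.random(n) < p for k, p in COVARIATE_MARGINALS.items()
           if k not in ("coo_non_gcb", "coo_na")}
    coo = np.where(
        rng.random(n) < COVARIATE_MARGINALS["coo_na"],
        "NA",
        np.where(rng.random(n) < COVARIATE_MARGINALS["coo_non_gcb"], "nonGCB", "GCB"),
    )

    lp = (
        params.true_log_hr_bcl2 * high_bcl2
        + params.true_log_hr_myc * high_myc
        + params.true_log_hr_ipi * cov["ipi_high"]
    )

    os_latent = _exp_times(rng, params.baseline_hazard * np.exp(lp), n)
    censor = _exp_times(rng, params.censoring_rate, n)
    censor = np.minimum(censor, params.accrual_months)
    os_months = np.minimum(os_latent, censor)
    os_event = os_latent <= censor

    progression = _exp_times(rng, params.efs_extra_hazard * np.exp(lp), n)
    efs_latent = np.minimum(os_latent, progression)
    efs_months = np.minimum(efs_latent, censor)
    efs_event = efs_latent <= censor

    def group_scores(high: np.ndarray, lo_par, hi_par) -> np.ndarray:
        mu = np.where(high, hi_par[0], lo_par[0])
        sd = np.where(high, hi_par[1], lo_par[1])
        return np.clip(rng.normal(mu, sd), 0.0, 100.0)

    bcl2_true = group_scores(high_bcl2, params.bcl2_score_low, params.bcl2_score_high)
    myc_true = group_scores(high_myc, params.myc_score_low, params.myc_score_high)

    # Proportion of marker-expressing cells: independent of intensity
    # group, so conventional (proportion-only) calls cut across true risk.
    prop_pos = rng.uniform(0.2, 0.95, size=n)
    conventional_pct = 100.0 * prop_pos

    batch_names = list(params.batches)
    batch = np.array(batch_names, dtype=object)[rng.integers(0, len(batch_names), n)]
    shift = np.array([params.batches[b][0] for b in batch])
    scale = np.array([params.batches[b][1] for b in batch])
    bcl2_obs = bcl2_true * scale + shift
    myc_obs = myc_true * scale + shift

    pid = np.array([f"P{i:04d}" for i in range(1, n + 1)])
    scores = pd.DataFrame({
        "patient_id": pid,
        "aqua_bcl2": bcl2_obs,
        "aqua_myc": myc_obs,
        "conventional_pct": conventional_pct,
        "batch": batch,
    })
    clinical = pd.DataFrame({
        "patient_id": pid,
        "os_months": os_months,
        "os_event": os_event.astype(int),
        "efs_months": efs_months,
        "efs_event": efs_event.astype(int),
        "age_gt60": cov["age_gt60"].astype(int),
        "sex": np.where(cov["sex_male"], "M", "F"),
        "ldh_high": cov["ldh_high"].astype(int),
        "b_symptoms": cov["b_symptoms"].astype(int),
        "hb_low": cov["hb_low"].astype(int),
        "stage34": cov["stage34"].astype(int),
        "ipi_group": np.where(cov["ipi_high"], "high", "low"),
        "bm_involvement": cov["bm_involvement"].astype(int),
        "coo": coo,
        "batch": batch,
    })
    patients = pd.DataFrame({
        "patient_id": pid,
        "true_high_bcl2": high_bcl2.astype(int),
        "true_high_myc": high_myc.astype(int),
        "true_bcl2_score": bcl2_true,
        "true_myc_score": myc_true,
        "true_lp": lp,
        "event_time_latent": os_latent,
        "censor_time": censor,
        "batch": batch,
    })
    return scores, clinical, SimTruth(patients=patients)


def simulate_chromogenic_cells(
    n_cells: int, bin_probs, seed: int = 0
) -> pd.DataFrame:
    """Draw per-cell DAB staining-intensity bins (0, 1+, 2+, 3+).

    Stands in for single-cell chromogenic IHC quantification: each cell is
    assigned one of four intensity bins by a multinomial draw. The output
    feeds the H-score directly.
    """
    probs = np.asarray(bin_probs, dtype=float)
    if probs.shape != (4,):
        raise ConfigurationError("bin_probs must have 4 entries (bins 0,1+,2+,3+)")
    if np.any(probs < 0):
        raise ConfigurationError("bin probabilities must be nonnegative")
    if not math.isclose(probs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ConfigurationError(f"bin_probs must sum to 1 (got {probs.sum()})")
    if n_cells < 0:
        raise ConfigurationError("n_cells must be >= 0")
    rng = np.random.default_rng(seed)
    bins = rng.choice(4, size=n_cells, p=probs)
    return pd.DataFrame({"cell_id": np.arange(1, n_cells + 1), "bin": bins})
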