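"""Patient-level expression scores from per-cell quantifications.

The central statistic is the tumor-specific AQUA (automated quantitative
analysis) score: over the CD20-gated tumor cells of a patient, the total
per-pixel marker intensity in the target compartment divided by the total
pixel area of that compartment,

    AQUA = sum_cells(intensity_sum) / sum_cells(pixel_area),

i.e. an area-weighted mean pixel intensity that blends staining intensity
and the proportion of expressing cells into one number. Companion scores
implemented here: the per-cell positivity fraction (cells at or above the
training-set 25th-percentile cytoplasmic intensity), the chromogenic
H-score (0-300), the conventional proportion-only call at 50%, and 0-100
normalization for cross-method comparison.

Conventions (recorded in output metadata by the pipeline): quantiles use
linear interpolation between order statistics; positivity and group
comparisons use >= (a value exactly at the threshold is positive/high).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    ConfigurationError,
    PhenotypeRule,
    PositivityThreshold,
    UndefinedScoreError,
)

#: Default marker -> target compartment for AQUA scoring.
AQUA_COMPARTMENTS = {"BCL2": "cytoplasm", "MYC": "nucleus"}


def gate_tumor_cells(cells: pd.DataFrame, rule: PhenotypeRule | None = None) -> pd.DataFrame:
    """Phenotype cells as tumor / t_cell / other from marker means.

    ``cells`` is the wide per-cell table (``mean_<MARKER>_<compartment>``
    columns). A cell is a tumor cell when its membrane tumor-marker mean
    is at or above the tumor threshold AND its cytoplasmic exclusion
    marker (CD3) is below the exclusion threshold; a cell at or above the
    exclusion threshold is a T cell regardless of CD20 — this is the gate
    that keeps BCL2-expressing reactive T cells out of the tumor score.
    Returns a copy with a ``phenotype`` column.
    """
    rule = rule or PhenotypeRule()
    tumor_col = f"mean_{rule.tumor_marker}_{rule.tumor_compartment}"
    excl_col = f"mean_{rule.exclusion_marker}_{rule.exclusion_compartment}"
    for col in (tumor_col, excl_col):
        if col not in cells.columns:
            raise ConfigurationError(
                f"cell table lacks {col!r}; was the marker quantified?"
            )
    tumor_mean = cells[tumor_col].to_numpy(dtype=float)
    excl_mean = cells[excl_col].to_numpy(dtype=float)

    phenotype = np.full(len(cells), "other", dtype=object)
    phenotype[excl_mean >= rule.exclusion_threshold] = "t_cell"
    phenotype[
        (tumor_mean >= rule.tumor_threshold)
        & (excl_mean < rule.exclusion_threshold)
    ] = "tumor"
    out = cells.copy()
    out["phenotype"] = phenotype
    return out


def aqua_score(
    quant: pd.DataFrame,
    marker: str,
    compartment: str | None = None,
    tumor_cell_ids=None,
) -> float:
    """Area-weighted mean compartment intensity over the selected cells.

    ``quant`` is the tidy per-cell quantification table. If
    ``tumor_cell_ids`` is given, only those cells contribute (the
    tumor-specific score); otherwise all quantified cells do. The
    compartment defaults to the marker's standard target (BCL2 ->
    cytoplasm, MYC -> nucleus).
    """
    if compartment is None:
        compartment = AQUA_COMPARTMENTS.get(marker)
        if compartment is None:
            raise ConfigurationError(
                f"no default compartment for marker {marker!r}; pass one"
            )
    sel = quant[(quant["marker"] == marker) & (quant["compartment"] == compartment)]
    if tumor_cell_ids is not None:
        sel = sel[sel["cell_id"].isin(tumor_cell_ids)]
    total_area = sel["pixel_area"].sum()
    if len(sel) == 0 or total_area == 0:
        raise UndefinedScoreError(
            f"AQUA score undefined: no {marker}/{compartment} pixels in "
            f"the selected cells"
        )
    return float(sel["intensity_sum"].sum() / total_area)


def positivity_threshold(
    training_means, provenance: str = "training_set"
) -> PositivityThreshold:
    """25th percentile of pooled per-cell mean cytoplasmic intensities.

    ``training_means`` pools the tumor-cell cytoplasmic marker means of
    every training-set patient. Uses the linear-interpolation quantile
    convention; the convention travels with the result for
    reproducibility.
    """
    means = np.asarray(training_means, dtype=float)
    if means.size == 0:
        raise UndefinedScoreError("cannot derive a positivity threshold from 0 cells")
    if means.size < 4:
        raise UndefinedScoreError(
            f"need >= 4 tumor cells to set a 25th-percentile threshold "
            f"(got {means.size})"
        )
    value = float(np.quantile(means, 0.25, method="linear"))
    return PositivityThreshold(value=value, provenance=provenance,
                               quantile_method="linear")


def positive_proportion(cell_means, threshold: PositivityThreshold | float) -> float:
    """Fraction of cells at or above the positivity threshold."""
    means = np.asarray(cell_means, dtype=float)
    if means.size == 0:
        raise UndefinedScoreError("positive proportion undefined for 0 tumor cells")
    cut = threshold.value if isinstance(threshold, PositivityThreshold) else float(threshold)
    return float(np.mean(means >= cut))


def h_score(cell_bins) -> tuple[float, dict[int, float]]:
    """Chromogenic H-score: 1*(%1+) + 2*(%2+) + 3*(%3+), range 0-300.

    ``cell_bins`` holds one intensity bin (0, 1, 2, 3) per cell;
    percentages are taken over ALL cells, so unstained (bin-0) cells count
    in the denominator. Returns the raw score and the bin percentages.
    """
    bins = np.asarray(
        cell_bins["bin"] if isinstance(cell_bins, pd.DataFrame) else cell_bins,
        dtype=int,
    )
    if bins.size == 0:
        raise UndefinedScoreError("H-score undefined for 0 cells")
    if bins.min() < 0 or bins.max() > 3:
        raise ConfigurationError("bins must be in {0, 1, 2, 3}")
    pct = {b: 100.0 * float(np.mean(bins == b)) for b in range(4)}
    score = 1.0 * pct[1] + 2.0 * pct[2] + 3.0 * pct[3]
    return score, pct


def conventional_positivity(
    cell_values, any_expression_threshold: float = 0.0, call_cutoff_pct: float = 50.0
) -> tuple[float, bool]:
    """Proportion-only positivity and the dichotomous call.

    A cell counts as expressing when its value is strictly above
    ``any_expression_threshold`` (default 0 — on binned chromogenic data
    this means bin >= 1+), regardless of intensity. The call is positive
    when the percentage is at or above ``call_cutoff_pct``.
    """
    values = np.asarray(
        cell_values["bin"] if isinstance(cell_values, pd.DataFrame) else cell_values,
        dtype=float,
    )
    if values.size == 0:
        raise UndefinedScoreError("conventional positivity undefined for 0 cells")
    pct = 100.0 * float(np.mean(values > any_expression_threshold))
    return pct, pct >= call_cutoff_pct


def normalize_scores_0_100(
    scores, basis: str = "cohort_minmax", theoretical_max: float = 300.0
) -> np.ndarray:
    """Rescale raw scores to 0-100 for cross-method comparison.

    ``cohort_minmax`` maps the observed min to 0 and max to 100
    (appropriate for AQUA scores, which have no natural ceiling);
    ``theoretical_max`` maps 0 to 0 and ``theoretical_max`` to 100
    (appropriate for the H-score, whose ceiling is 300). A constant vector
    under cohort_minmax maps to all zeros.
    """
    x = np.asarray(scores, dtype=float)
    if x.size == 0:
        raise UndefinedScoreError("cannot normalize an empty score vector")
    if basis == "cohort_minmax":
        lo, hi = float(x.min()), float(x.max())
        if hi == lo:
            import warnings

            warnings.warn("constant score vector; normalized to all zeros")
            return np.zeros_like(x)
        return 100.0 * (x - lo) / (hi - lo)
    if basis == "theoretical_max":
        return 100.0 * x / theoretical_max
    raise ConfigurationError(f"unknown normalization basis {basis!r}")


def score_sample(
    quant: pd.DataFrame,
    patient_id: str,
    rule: PhenotypeRule | None = None,
    bcl2_positivity: PositivityThreshold | float | None = None,
    min_tumor_cells: int = 20,
) -> dict:
    """Full per-sample scoring: gate, AQUA, and positivity in one pass.

    Returns a dict with the patient's raw AQUA scores, tumor-cell count,
    BCL2-positive proportion (when a threshold is supplied) and a
    ``qc_pass`` flag (False below ``min_tumor_cells`` gated tumor cells;
    such samples are excluded from cutoff and survival analysis
    downstream).
    """
    rule = rule or PhenotypeRule()
    wide = gate_tumor_cells(_wide(quant), rule)
    tumor_ids = wide.loc[wide["phenotype"] == "tumor", "cell_id"]
    n_tumor = int(len(tumor_ids))

    result: dict = {
        "patient_id": patient_id,
        "n_tumor_cells": n_tumor,
        "qc_pass": n_tumor >= min_tumor_cells,
        "aqua_bcl2": np.nan,
        "aqua_myc": np.nan,
        "prop_bcl2_pos": np.nan,
    }
    if n_tumor == 0:
        return result
    result["aqua_bcl2"] = aqua_score(quant, "BCL2", tumor_cell_ids=tumor_ids)
    result["aqua_myc"] = aqua_score(quant, "MYC", tumor_cell_ids=tumor_ids)
    if bcl2_positivity is not None:
        means = wide.loc[wide["phenotype"] == "tumor", "mean_BCL2_cytoplasm"].dropna()
        if len(means):
            result["prop_bcl2_pos"] = positive_proportion(means, bcl2_positivity)
    return result


def _wide(quant: pd.DataFrame) -> pd.DataFrame:
    from .segmentation import cell_means_wide

    return cell_means_wide(quant)
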