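"""End-to-end orchestration: simulate/segment/score/analyze stages.

``segment_and_quantify`` runs the image stages on one core;
``run_reproduce`` executes the full synthetic study — a handful of cores
through the pixel pipeline to exercise segmentation and scoring, plus a
simulated cohort through cutoff derivation, survival stratification, Cox
modelling, reclassification and AUROC method comparison — and writes all
artifacts as CSV/JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cs
from . import scoring, segmentation
from .io import RunConfig, write_image, write_run_log
from .synthetic import CohortSimParams, ImageSimParams, simulate_cohort, simulate_core_image
from .types import PAPER_DEFAULT_CUTOFFS, PhenotypeRule


def segment_and_quantify(
    stack, config: RunConfig | None = None, channel_max: dict | None = None
):
    """Normalize, segment and quantify one core.

    Returns (tidy per-cell quantification table, gated wide cell table).
    """
    config = config or RunConfig()
    norm = segmentation.normalize_stack(stack, channel_max=channel_max)
    labels = segmentation.detect_cells(
        norm,
        min_radius_px=config.min_radius_px,
        max_radius_px=config.max_radius_px,
        threshold=config.dapi_threshold,
    )
    mask = segmentation.derive_compartments(
        labels, config.cytoplasm_width_px, config.membrane_width_px
    )
    quant = segmentation.quantify_cells(norm, mask)
    rule = PhenotypeRule(
        tumor_threshold=config.tumor_threshold,
        exclusion_threshold=config.exclusion_threshold,
    )
    wide = (
        scoring.gate_tumor_cells(segmentation.cell_means_wide(quant), rule)
        if not quant.empty
        else pd.DataFrame()
    )
    return quant, wide


def _image_stage(config: RunConfig, seed: int, out_dir: Path | None) -> dict:
    """Run a few synthetic cores through the full pixel pipeline."""
    stacks, truths = [], []
    for k in range(config.n_image_cores):
        params = ImageSimParams(
            cytoplasm_width_px=config.cytoplasm_width_px,
            membrane_width_px=config.membrane_width_px,
            seed=(seed + 1000 + k) % (2**31),
        )
        stack, truth = simulate_core_image(params)
        stacks.append(stack)
        truths.append(truth)
    channel_max = segmentation.batch_channel_max(stacks)

    core_scores, cells_all = [], []
    for k, (stack, truth) in enumerate(zip(stacks, truths)):
        quant, wide = segment_and_quantify(stack, config, channel_max)
        sample = scoring.score_sample(
            quant, patient_id=f"core_{k}", min_tumor_cells=config.min_tumor_cells
        )
        sample["n_true_tumor"] = int((truth.cells["phenotype"] == "tumor").sum())
        sample["n_detected"] = int(wide["cell_id"].nunique()) if len(wide) else 0
        core_scores.append(sample)
        if not quant.empty:
            quant = quant.assign(core=f"core_{k}")
            cells_all.append(quant)
        if out_dir is not None:
            write_image(stack, out_dir / f"core_{k}.tif")
            truth.cells.to_csv(out_dir / f"core_{k}_truth.csv", index=False)
    per_core = pd.DataFrame(core_scores)
    if out_dir is not None and cells_all:
        pd.concat(cells_all, ignore_index=True).to_csv(
            out_dir / "per_cell_quant.csv", index=False
        )
        per_core.to_csv(out_dir / "per_core_scores.csv", index=False)
    return {"per_core_scores": per_core}


def run_reproduce(config: RunConfig | None = None, out_dir=None) -> dict:
    """Execute the full synthetic study and return the result bundle.

    Stages: (1) synthetic cores -> segmentation -> tumor-gated AQUA
    scores, demonstrating the pixel pipeline; (2) synthetic cohort ->
    batch adjustment -> training-set ROC cutoff -> group assignment ->
    Kaplan-Meier/log-rank, multivariate Cox, PH diagnostic, quantile
    groups, BCL2 x MYC cross-classification, conventional-vs-AQUA
    reclassification, and AUROC method comparison.
    """
    config = config or RunConfig()
    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed}

    if config.n_image_cores > 0:
        bundle.update(_image_stage(config, config.seed, out_path))

    cohort_params = CohortSimParams(
        n_patients=config.n_patients,
        high_bcl2_prevalence=config.high_bcl2_prevalence,
        true_log_hr_bcl2=float(np.log(config.true_hr_bcl2)),
        seed=(config.seed + 7) % (2**31),
    )
    scores, clinical, truth = simulate_cohort(cohort_params)

    scores = scores.copy()
    scores["aqua_bcl2_adj"] = cs.adjust_batch(scores["aqua_bcl2"], scores["batch"])
    scores["aqua_myc_adj"] = cs.adjust_batch(scores["aqua_myc"], scores["batch"])

    rng = np.random.default_rng((config.seed + 13) % (2**31))
    n = len(scores)
    train = np.zeros(n, dtype=bool)
    train[rng.choice(n, size=int(round(config.train_fraction * n)), replace=False)] = True
    bundle["n_train"] = int(train.sum())
    bundle["n_validation"] = int(n - train.sum())

    if config.cutoff_preset == "paper_defaults":
        bcl2_cut = PAPER_DEFAULT_CUTOFFS["bcl2_aqua"]
        myc_cut = PAPER_DEFAULT_CUTOFFS["myc_aqua"]
        bundle["cutoff_source"] = "paper_defaults preset"
        cutoff_result = None
    else:
        evaluable, outcome, definition = cs.binary_endpoint(clinical, config.endpoint)
        tr = train & evaluable
        cutoff_result = cs.optimal_cutoff(
            scores.loc[tr, "aqua_bcl2_adj"],
            outcome[train[evaluable]],
            outcome_definition=f"{definition}; derived on training set",
        )
        bcl2_cut = cutoff_result.cutoff
        myc_result = cs.optimal_cutoff(
            scores.loc[tr, "aqua_myc_adj"],
            outcome[train[evaluable]],
            outcome_definition=f"{definition}; derived on training set",
        )
        myc_cut = myc_result.cutoff
        bundle["cutoff_source"] = "ROC (Youden) on training set"
        bundle["bcl2_cutoff"] = cutoff_result.to_dict()
        bundle["myc_cutoff"] = myc_result.to_dict()

    bcl2_group = cs.assign_groups(scores["aqua_bcl2_adj"], bcl2_cut)
    myc_group = cs.assign_groups(scores["aqua_myc_adj"], myc_cut)
    scores["bcl2_group"] = bcl2_group
    scores["myc_group"] = myc_group
    bundle["high_bcl2_fraction"] = float(np.mean(bcl2_group == "high"))

    t = clinical["os_months"].to_numpy()
    e = clinical["os_event"].to_numpy()
    if len(set(bcl2_group)) >= 2:
        km = cs.km_logrank(t, e, bcl2_group)
        bundle["os_logrank_p_bcl2"] = km.logrank_p
        ph = cs.ph_diagnostic(t, e, bcl2_group)
        bundle["ph_gap_sd"] = ph.ph_gap_sd

    cov = pd.DataFrame({
        "bcl2_high": (bcl2_group == "high").astype(float),
        "myc_high": (myc_group == "high").astype(float),
        "ipi_high": (clinical["ipi_group"] == "high").astype(float),
        "coo_non_gcb": (clinical["coo"] == "nonGCB").astype(float),
    })
    with_coo = clinical["coo"].to_numpy() != "NA"
    try:
        cox = cs.cox_fit(cov[with_coo], t[with_coo], e[with_coo], "multivariate")
        bundle["cox_multivariate"] = cox.cox_summary.to_dict(orient="records")
        row = cox.cox_summary.set_index("covariate").loc["bcl2_high"]
        bundle["bcl2_hr_multivariate"] = float(row["hr"])
        bundle["bcl2_hr_p"] = float(row["p"])
    except Exception as exc:  # small cohorts can be degenerate
        bundle["cox_multivariate_error"] = str(exc)

    try:
        qgroups = cs.quantile_groups(scores["aqua_bcl2_adj"])
        qcov = pd.get_dummies(pd.Series(qgroups, name="q"), drop_first=True, dtype=float)
        qc = cs.cox_fit(qcov, t, e, "multivariate")
        bundle["quantile_group_hrs"] = {
            r["covariate"]: r["hr"] for r in qc.cox_summary.to_dict(orient="records")
        }
    except Exception as exc:
        bundle["quantile_group_error"] = str(exc)

    joint = cs.cross_classify(bcl2_group, myc_group)
    bundle["cross_class_counts"] = {
        k: int(v) for k, v in pd.Series(joint).value_counts().items()
    }
    if len(set(joint)) >= 2:
        km4 = cs.km_logrank(t, e, joint)
        bundle["os_logrank_p_bcl2xmyc"] = km4.logrank_p

    conventional_call = scores["conventional_pct"].to_numpy() >= 50.0
    bundle["reclassification"] = cs.reclassification_analysis(
        conventional_call, bcl2_group, t, e
    )

    evaluable, outcome, definition = cs.binary_endpoint(clinical, config.endpoint)
    if len(np.unique(outcome)) == 2:
        auroc = cs.compare_methods_auroc(
            {
                "aqua_bcl2": scores.loc[evaluable, "aqua_bcl2_adj"].to_numpy(),
                "conventional_pct": scores.loc[evaluable, "conventional_pct"].to_numpy(),
            },
            outcome,
            n_boot=200,
            seed=(config.seed + 29) % (2**31),
        )
        bundle["auroc_comparison"] = auroc.to_dict(orient="records")

    bundle["truth_high_bcl2_fraction"] = float(truth.patients["true_high_bcl2"].mean())
    bundle["group_vs_truth_agreement"] = float(
        np.mean((bcl2_group == "high") == (truth.patients["true_high_bcl2"] == 1))
    )

    if out_path is not None:
        scores.to_csv(out_path / "patient_scores.csv", index=False)
        clinical.to_csv(out_path / "clinical.csv", index=False)
        truth.patients.to_csv(out_path / "truth_patients.csv", index=False)
        with open(out_path / "analysis.json", "w") as fh:
            json.dump(_jsonable(bundle), fh, indent=2)
        config.to_yaml(out_path / "config.yaml")
        write_run_log(out_path, config, extra={"stage": "reproduce"})
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
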