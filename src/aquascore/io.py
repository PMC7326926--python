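"""File formats and run configuration.

Images travel as multipage TIFF, one page per channel with the marker
name stored in the page description tag (a plain-text sidecar
``<stem>.channels.txt`` is accepted as a fallback for TIFFs written by
other tools). Tables are CSV. Configuration is YAML; every output
directory gets a run log recording the seed, package version and the
convention choices that affect results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import ChannelStack, ConfigurationError


class FormatError(ValueError):
    """A file does not match the expected on-disk layout."""


def write_image(stack: ChannelStack, path) -> None:
    """Write a ChannelStack as a multipage TIFF, channel names in page tags."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for i, name in enumerate(stack.channel_names):
            tif.write(
                stack.pixels[i].astype(np.float32),
                description=name,
                contiguous=False,
            )


def read_image(path, channel_names: list[str] | None = None) -> ChannelStack:
    """Read a multipage TIFF into a ChannelStack.

    Channel names come from page description tags; a sidecar
    ``<stem>.channels.txt`` (one name per line) or the ``channel_names``
    argument overrides them. A DAPI channel is required.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
            tags = [p.description or "" for p in tif.pages]
    except Exception as exc:  # pragma: no cover - tifffile error text varies
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if channel_names is None:
        sidecar = path.with_suffix(".channels.txt")
        if all(tags) and len(set(tags)) == len(tags):
            channel_names = tags
        elif sidecar.exists():
            channel_names = sidecar.read_text().split()
        else:
            raise FormatError(
                f"{path}: no channel names in page tags and no sidecar "
                f"{sidecar.name}"
            )
    if len(channel_names) != len(pages):
        raise FormatError(
            f"{path}: {len(channel_names)} channel names for {len(pages)} pages"
        )
    pixels = np.stack(pages).astype(float)
    if not np.issubdtype(pixels.dtype, np.number):
        raise FormatError(f"{path}: non-numeric pixel data")
    stack = ChannelStack(pixels, tuple(channel_names))
    if not stack.has_channel("DAPI"):
        raise FormatError(f"{path}: required DAPI channel missing")
    return stack


CLINICAL_REQUIRED = [
    "patient_id", "os_months", "os_event", "efs_months", "efs_event",
]
CLINICAL_OPTIONAL = [
    "age_gt60", "sex", "ldh_high", "b_symptoms", "hb_low", "stage34",
    "ipi_group", "bm_involvement", "coo", "batch",
]


def read_clinical(path) -> pd.DataFrame:
    """Read and validate a clinical CSV.

    Required columns: patient_id, os_months, os_event, efs_months,
    efs_event. Times must be nonnegative with efs_months <= os_months;
    events must be 0/1. Cell-of-origin (``coo``) may be blank and is kept
    as the string ``"NA"`` — such patients stay in the cohort and are only
    dropped from models that use COO.
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    bad_rows = []
    for idx, row in df.iterrows():
        problems = []
        if row["os_months"] < 0 or row["efs_months"] < 0:
            problems.append("negative time")
        if row["efs_months"] > row["os_months"] + 1e-9:
            problems.append("efs_months > os_months")
        if row["os_event"] not in (0, 1) or row["efs_event"] not in (0, 1):
            problems.append("event flag not 0/1")
        if problems:
            bad_rows.append((int(idx) + 2, "; ".join(problems)))  # 1-based + header
    if bad_rows:
        detail = ", ".join(f"line {ln}: {msg}" for ln, msg in bad_rows[:10])
        raise FormatError(f"{path}: invalid rows — {detail}")
    if "coo" in df.columns:
        df["coo"] = df["coo"].fillna("NA").replace("", "NA")
    return df


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialisable to YAML.

    The seed is threaded into every random stage and recorded in outputs;
    two runs with equal configs produce identical artifacts.
    """

    output_dir: str = "aquascore_run"
    images_dir: str | None = None
    clinical_csv: str | None = None
    seed: int = 0
    # segmentation
    min_radius_px: float = 3.0
    max_radius_px: float = 12.0
    dapi_threshold: float | None = None
    cytoplasm_width_px: float = 3.0
    membrane_width_px: float = 2.0
    # phenotyping / scoring
    tumor_threshold: float = 0.05
    exclusion_threshold: float = 0.05
    min_tumor_cells: int = 20
    quantile_method: str = "linear"
    normalization_basis: str = "cohort_minmax"
    # cohort analysis
    cutoff_preset: str | None = None   # e.g. "paper_defaults"
    endpoint: str = "os_5y"
    train_fraction: float = 0.667
    # synthetic study
    n_patients: int = 300
    high_bcl2_prevalence: float = 0.389
    true_hr_bcl2: float = 2.0
    n_image_cores: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_run_log(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Write the machine-parsable run log (seed, hash, conventions)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = {
        "aquascore_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "quantile_method": config.quantile_method,
        "positivity_boundary": ">= (at-threshold is positive)",
        "group_boundary": ">= cutoff is high",
        "conventional_call_boundary": ">= 50% is positive",
        "cox_ties": "efron",
        "normalization_basis": config.normalization_basis,
        "endpoint": config.endpoint,
    }
    if extra:
        entries.update(extra)
    log_path = out_dir / "run_log.txt"
    with open(log_path, "w") as fh:
        for k, v in entries.items():
            fh.write(f"{k}={v}\n")
    return log_path
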