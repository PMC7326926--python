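"""Core in-memory containers shared across the pipeline.

The pipeline moves through three representations:

``ChannelStack``
    A registered multichannel fluorescence image (channel x row x col).
``CellQuant`` tables
    Per-cell, per-marker, per-compartment pixel sums and areas produced by
    the segmentation stage (held as a tidy :class:`pandas.DataFrame`).
``SampleScore``
    Patient-level scores (AQUA, H-score, positivity) consumed by the
    cohort statistics stage.

Coordinates are 0-based ``(row, col)`` with origin at the top-left pixel.
Label 0 is reserved for background everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Compartment names, in the order they are encoded in compartment maps.
COMPARTMENTS = ("nucleus", "cytoplasm", "membrane")

#: Integer codes used in ``CompartmentMask.compartment_of_pixel``.
BACKGROUND, NUCLEUS, CYTOPLASM, MEMBRANE = 0, 1, 2, 3

COMPARTMENT_CODES = {"nucleus": NUCLEUS, "cytoplasm": CYTOPLASM, "membrane": MEMBRANE}


class ConfigurationError(ValueError):
    """A required channel, marker or parameter is missing or malformed."""


class UndefinedScoreError(ValueError):
    """A score is requested over an empty cell set or zero total area."""


class PlacementError(RuntimeError):
    """Cell placement failed: requested density exceeds what the
    minimum-separation constraint admits in the given image."""


@dataclass
class ChannelStack:
    """A multichannel image with named markers.

    Parameters
    ----------
    pixels
        Array of shape ``(n_channels, n_rows, n_cols)`` with nonnegative
        raw (or normalized) intensities.
    channel_names
        Unique marker names, one per channel. A channel named ``"DAPI"``
        is required before segmentation.
    pixel_size_um
        Optional physical pixel size in micrometres.
    """

    pixels: np.ndarray
    channel_names: tuple[str, ...]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.pixels.ndim != 3:
            raise ConfigurationError(
                f"pixels must be (channel, row, col); got shape {self.pixels.shape}"
            )
        if len(self.channel_names) != self.pixels.shape[0]:
            raise ConfigurationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.pixels.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigurationError("channel names must be unique")
        if np.any(self.pixels < 0):
            raise ConfigurationError("intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (row, col) shape."""
        return self.pixels.shape[1], self.pixels.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D image of the named channel."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"channel {name!r} not present; have {self.channel_names}"
            ) from None
        return self.pixels[idx]

    def has_channel(self, name: str) -> bool:
        return name in self.channel_names


@dataclass
class CompartmentMask:
    """Per-pixel cell labels and subcellular compartment tags.

    ``cell_labels`` is a 2-D integer map (0 = background);
    ``compartment_of_pixel`` uses the codes ``NUCLEUS``, ``CYTOPLASM``,
    ``MEMBRANE`` and ``BACKGROUND``. The two maps are aligned: a pixel is
    background in one iff it is background in the other, and each
    non-background pixel belongs to exactly one cell and one compartment.
    """

    cell_labels: np.ndarray
    compartment_of_pixel: np.ndarray

    def __post_init__(self) -> None:
        self.cell_labels = np.asarray(self.cell_labels)
        self.compartment_of_pixel = np.asarray(self.compartment_of_pixel)
        if self.cell_labels.shape != self.compartment_of_pixel.shape:
            raise ConfigurationError("label and compartment maps must align")

    @property
    def labels(self) -> np.ndarray:
        """Sorted nonzero cell labels present in the mask."""
        out = np.unique(self.cell_labels)
        return out[out > 0]


@dataclass
class PhenotypeRule:
    """Marker thresholds used to gate tumor cells.

    Tumor cells are B cells, called by membrane CD20; reactive T cells are
    called by cytoplasmic CD3 and excluded from tumor scoring even when
    they express BCL2. Thresholds apply to per-cell mean normalized
    intensity and therefore live in [0, 1].
    """

    tumor_marker: str = "CD20"
    tumor_compartment: str = "membrane"
    exclusion_marker: str = "CD3"
    exclusion_compartment: str = "cytoplasm"
    tumor_threshold: float = 0.05
    exclusion_threshold: float = 0.05

    def __post_init__(self) -> None:
        for t in (self.tumor_threshold, self.exclusion_threshold):
            if not 0.0 <= t <= 1.0:
                raise ConfigurationError(f"threshold {t} outside [0, 1]")


@dataclass
class PositivityThreshold:
    """Per-cell positivity cutoff on mean cytoplasmic marker intensity.

    Derived as the 25th percentile of pooled per-cell means across the
    training set; ``provenance`` records where it came from.
    """

    value: float
    provenance: str = "unspecified"
    quantile_method: str = "linear"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ConfigurationError(
                f"positivity threshold {self.value} outside [0, 1]"
            )


@dataclass
class CutoffResult:
    """An ROC-derived score cutoff and its operating characteristics."""

    cutoff: float
    auroc: float
    sensitivity: float
    specificity: float
    outcome_definition: str
    n_positive: int = 0
    n_negative: int = 0

    def to_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "auroc": self.auroc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "outcome_definition": self.outcome_definition,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
        }


#: Published cutoffs on the 0-100 normalized scale, shipped as presets so
#: externally supplied normalized scores can be dichotomized without
#: re-deriving a cutoff.
PAPER_DEFAULT_CUTOFFS = {
    "bcl2_aqua": 41.47,
    "myc_aqua": 48.83,
    "bcl2_hscore": 66.73,
}


@dataclass
class SurvivalResult:
    """Bundle of survival-analysis outputs.

    Any subset of the fields may be populated depending on which analysis
    produced it: Kaplan-Meier curves and the log-rank test, Cox model
    summaries, or proportional-hazards diagnostic curves.
    """

    km_curves: dict | None = None          # group -> DataFrame(time, survival, at_risk)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    cox_summary: "object | None" = None    # DataFrame: covariate rows
    ph_curves: dict | None = None          # group -> DataFrame(log_time, loglog_surv)
    ph_gap_sd: float | None = None
    notes: list[str] = field(default_factory=list)
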