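"""Domain types shared across the pipeline.

The study system is a two-morph (planktivorous / benthivorous) lacustrine
cyprinid: specimens carry a 24-landmark body-shape configuration, a set of
linear head traits, gut-content records, and otolith ring radii used for
growth back-calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Number of landmarks in the digitization scheme.
N_LANDMARKS = 24

#: Morph labels used throughout.
MORPHS = ("planktivorous", "benthivorous")

#: Zero-based indices of the head-region landmarks (landmarks 1-13 and
#: 21-24 in the 1-based digitization scheme). Between-morph shape
#: differences are confined to this region.
HEAD_LANDMARKS = tuple(range(13)) + tuple(range(20, 24))

#: The six prey categories used for diet composition.
DIET_CATEGORIES = (
    "zooplankton",
    "small fishes",
    "hydrophilic insects",
    "periphytic algae",
    "zoobenthos",
    "others",
)

#: The seven linear head traits (ratio-normalized; see TraitTable docs).
TRAIT_NAMES = ("HeadH", "UpperL1", "HeadL", "SnoutL", "Upper2", "LowerL", "JawD")


class MalformedRecordError(ValueError):
    """A TPS record or table row violates the format contract."""


class SchemaError(ValueError):
    """A CSV table is missing required columns or has invalid values."""


class DegenerateConfigurationError(ValueError):
    """A landmark configuration has no usable geometry (all points coincide)."""


@dataclass
class LandmarkSet:
    """One specimen's digitized landmark configuration.

    coords are raw digitizing units (pixels or mm); when a TPS ``SCALE=``
    factor is present it is stored, not pre-multiplied, so downstream code
    can choose the unit system (Procrustes shape is invariant to it but
    centroid-size units are not).
    """

    specimen_id: str
    coords: np.ndarray
    scale: float | None = None
    morph: str = "unknown"
    sex: str = "unknown"
    image: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise MalformedRecordError(
                f"specimen {self.specimen_id!r}: expected {N_LANDMARKS} (x, y) "
                f"landmarks, got array of shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise MalformedRecordError(
                f"specimen {self.specimen_id!r}: non-finite coordinates"
            )
        if self.scale is not None:
            self.scale = float(self.scale)
            if not self.scale > 0:
                raise MalformedRecordError(
                    f"specimen {self.specimen_id!r}: SCALE must be positive, "
                    f"got {self.scale}"
                )
        if self.morph not in MORPHS + ("unknown",):
            raise MalformedRecordError(
                f"specimen {self.specimen_id!r}: morph must be one of "
                f"{MORPHS + ('unknown',)}, got {self.morph!r}"
            )
        if self.sex not in ("F", "M", "unknown"):
            raise MalformedRecordError(
                f"specimen {self.specimen_id!r}: sex must be 'F', 'M' or "
                f"'unknown', got {self.sex!r}"
            )

    @property
    def coords_scaled(self) -> np.ndarray:
        """Coordinates multiplied by the scale factor when one is present."""
        if self.scale is None:
            return self.coords
        return self.coords * self.scale


@dataclass
class AnalysisConfig:
    """Pipeline configuration (plumbing; not a quantity from the study)."""

    random_seed: int = 1
    distance_metric: str = "euclidean"
    standardize_features: bool = True
    allometry_size: str = "raw"  # or "log"
    arss_df_convention: str = "printed"  # or "chen1992"
    vbgf_init: str = "ford-walford"  # or "multistart"
    n_pcs: int = 2
    output_dir: str = "."
    stages: tuple[str, ...] = ("morpho", "diet", "growth")

    _ALLOWED = {
        "allometry_size": ("raw", "log"),
        "arss_df_convention": ("printed", "chen1992"),
        "vbgf_init": ("ford-walford", "multistart"),
        "distance_metric": ("euclidean", "cityblock", "cosine", "correlation"),
    }

    def __post_init__(self) -> None:
        for name, allowed in self._ALLOWED.items():
            value = getattr(self, name)
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")
        for stage in self.stages:
            if stage not in ("morpho", "diet", "growth"):
                raise ValueError(f"unknown stage {stage!r}")
        self.stages = tuple(self.stages)
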