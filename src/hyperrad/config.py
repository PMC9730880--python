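"""Run configuration with the study's published analysis constants."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, with published defaults.

    Preprocessing: 2 mm isotropic resampling, 5 HU / 0.25 SUV bin widths
    (anchored at -1000 HU / 0 SUV), 0.5 cc lesion volume filter.
    Modeling: tau 0.90 pruning, 5 outer folds, 10x-repeated 5-fold inner CV,
    100 random-search samples, <= 6 features per modality.
    Survival: 3-month landmark.
    """

    # paths (optional; stages fall back to generated data)
    lesions_csv: str | None = None
    patients_csv: str | None = None
    features_csv: str | None = None

    # preprocessing
    target_spacing_mm: float = 2.0
    bin_width_ct: float = 5.0
    bin_width_pet: float = 0.25
    anchor_ct: float = -1000.0
    anchor_pet: float = 0.0
    min_lesion_cc: float = 0.5

    # feature redundancy / modeling
    tau_threshold: float = 0.90
    outer_folds: int = 5
    inner_folds: int = 5
    inner_repeats: int = 10
    n_search: int = 100
    max_features_per_modality: int = 6
    modalities: list[str] = field(default_factory=lambda: ["CT", "PET", "PETCT"])

    # survival
    landmark_months: float = 3.0

    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
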