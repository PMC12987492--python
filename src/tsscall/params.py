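"""Prediction parameters and the five shipped threshold presets.

The step-height threshold (and its reduction value) is expressed relative to
the percentile value used for inter-library normalization: a threshold of 0.3
means 0.3 x Q_min in normalized coverage units.  :meth:`ParameterSet.scaled_by`
converts both to absolute units once Q_min is known.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources

import yaml

from .errors import ConfigurationError

REDUCTION_MODES = ("first", "strongest")
PRIMARY_MODES = ("strongest", "first")


@dataclass(frozen=True)
class ParameterSet:
    """All thresholds steering detection, consolidation and classification.

    Parameters
    ----------
    step_height:
        Minimum rise e(i) - e(i-1) on the enriched profile, in units of the
        percentile normalization value (T_h).
    step_factor:
        Minimum ratio e(i) / e(i-1) (T_f, >= 1).
    enrichment_factor:
        Minimum enriched/control ratio at the TSS (T_EF, >= 1).
    window:
        Close-candidate reduction window W in bp.
    cross_replicate_shift / cross_condition_shift:
        Maximum distance (bp) at which TSS from different replicates /
        conditions are considered the same position.
    height_reduction / factor_reduction:
        Subtractive reductions (rho_h, rho_f) applied to T_h and T_f when
        re-evaluating replicates that missed a TSS detected elsewhere.
    min_replicates:
        Number of replicates that must detect a TSS for it to survive (R_min).
    reduction_mode:
        Within a window of close candidates keep the 5'-most ("first") or the
        highest step ("strongest").
    primary_mode:
        Primary TSS of a gene is the strongest signal ("strongest") or the
        5'-most upstream signal ("first").
    utr_length / antisense_distance:
        Classification distances in bp (300 / 150 by convention).
    """

    step_height: float = 0.3
    step_factor: float = 2.0
    enrichment_factor: float = 2.0
    window: int = 2
    cross_replicate_shift: int = 1
    cross_condition_shift: int = 1
    height_reduction: float = 0.2
    factor_reduction: float = 0.5
    min_replicates: int = 1
    reduction_mode: str = "strongest"
    primary_mode: str = "strongest"
    utr_length: int = 300
    antisense_distance: int = 150
    percentile_rank: float = 0.9
    preset_name: str | None = None

    def __post_init__(self) -> None:
        if self.step_height < 0:
            raise ConfigurationError("step_height must be >= 0")
        if self.step_factor < 1:
            raise ConfigurationError("step_factor must be >= 1")
        if self.enrichment_factor < 1:
            raise ConfigurationError("enrichment_factor must be >= 1")
        if self.window < 0 or self.cross_replicate_shift < 0 \
                or self.cross_condition_shift < 0:
            raise ConfigurationError("shifts and window must be >= 0")
        if self.height_reduction < 0 or self.height_reduction > self.step_height:
            raise ConfigurationError("height_reduction must lie in [0, step_height]")
        if self.factor_reduction < 0 or self.factor_reduction > self.step_factor - 1:
            raise ConfigurationError(
                "factor_reduction must lie in [0, step_factor - 1]")
        if self.min_replicates < 1:
            raise ConfigurationError("min_replicates must be >= 1")
        if self.reduction_mode not in REDUCTION_MODES:
            raise ConfigurationError(f"reduction_mode must be one of {REDUCTION_MODES}")
        if self.primary_mode not in PRIMARY_MODES:
            raise ConfigurationError(f"primary_mode must be one of {PRIMARY_MODES}")
        if not 0 < self.percentile_rank <= 1:
            raise ConfigurationError("percentile_rank must lie in (0, 1]")

    def scaled_by(self, q: float) -> "ParameterSet":
        """Return a copy with step-height thresholds in absolute units (x q)."""
        return dataclasses.replace(
            self, step_height=self.step_height * q,
            height_reduction=self.height_reduction * q)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ParameterSet":
        presets = load_presets()
        key = name.strip().lower().replace(" ", "_").replace("-", "_")
        if key not in presets:
            raise ConfigurationError(
                f"unknown preset {name!r}; available: {', '.join(presets)}")
        values = dict(presets[key])
        values.update(overrides)
        return cls(preset_name=key, **values)


def load_presets() -> dict[str, dict[str, float]]:
    """Load the packaged preset table (an editable YAML file)."""
    text = resources.files("tsscall").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)
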