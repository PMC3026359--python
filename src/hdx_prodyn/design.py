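"""Experiment design shared by the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

from .uptake_core import CorrectionParams

__all__ = ["DEFAULT_TIMEPOINTS", "DEFAULT_CONDITIONS", "ExperimentDesign"]

DEFAULT_TIMEPOINTS = (0.0, 60.0, 240.0, 960.0, 1920.0, 3840.0)
DEFAULT_CONDITIONS = ("apo", "xylohexaose", "xylan")


@dataclass(frozen=True)
class ExperimentDesign:
    """Time course, condition labels, and analysis defaults.

    The first timepoint must be 0 (the nondeuterated reference); the first
    condition is treated as the ligand-free reference state downstream.
    """

    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    sn_threshold: float = 3.0
    last_k: int = 3
    alpha: float = 0.05
    correction: CorrectionParams = field(default_factory=CorrectionParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if len(self.timepoints) < 2:
            raise ValueError("need a time-0 reference plus at least one timepoint")
        if self.timepoints[0] != 0:
            raise ValueError("first timepoint must be 0 (nondeuterated reference)")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (1 <= self.last_k <= len(self.nonzero_timepoints)):
            raise ValueError("last_k must be between 1 and the number of nonzero timepoints")

    @property
    def nonzero_timepoints(self) -> tuple[float, ...]:
        return self.timepoints[1:]

    @property
    def apo_condition(self) -> str:
        return self.conditions[0]

    @property
    def holo_conditions(self) -> tuple[str, ...]:
        return self.conditions[1:]
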