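"""Run configuration: one object carrying every knob and the master seed."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .cohort import DiscretizationConfig
from .inference import DEFAULT_EXACT_BUDGET, DEFAULT_RESTARTS


@dataclass(frozen=True)
class RunConfig:
    """Defaults documented per field; round-trips through JSON.

    seed            master seed; every random draw in a run descends from it
    exact_budget    max vertex combinations for exact strong-extension mode
    restarts        local-search restarts when the budget is exceeded
    verbal_scale_path  path to a verbal scale JSON (None = packaged default)
    discretization  day-count binning for the classifier
    output_dir      where CLI commands write result files
    log_level       python logging level name
    """

    seed: int = 0
    exact_budget: int = DEFAULT_EXACT_BUDGET
    restarts: int = DEFAULT_RESTARTS
    verbal_scale_path: str | None = None
    discretization: DiscretizationConfig = field(default_factory=DiscretizationConfig)
    output_dir: str = "."
    log_level: str = "INFO"

    def to_obj(self) -> dict:
        obj = asdict(self)
        obj["discretization"] = self.discretization.to_obj()
        return obj

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_obj(), indent=1) + "\n")

    @classmethod
    def from_obj(cls, obj: dict) -> "RunConfig":
        obj = dict(obj)
        disc = obj.pop("discretization", None)
        config = cls(
            **obj,
            **(
                {}
                if disc is None
                else {
                    "discretization": DiscretizationConfig(
                        hospital_days_column=disc["hospital_days_column"],
                        hospital_days_cuts=tuple(disc["hospital_days_cuts"]),
                        assessment_column=disc["assessment_column"],
                    )
                }
            ),
        )
        return config

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_obj(json.loads(Path(path).read_text()))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_obj(), sort_keys=True).encode()
        ).hexdigest()[:12]
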