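"""Run configuration: every stage parameter with paper-default values."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class RunConfig:
    """All pipeline parameters; defaults match the published protocol.

    Unknown keys in a YAML file are errors (typo protection); a config
    round-trips losslessly through :meth:`to_yaml` / :meth:`from_yaml`.
    """

    n_rings: int = 4
    area_tol: float = 0.02
    rolling_ball_radius: int = 30
    subtract_background: bool = True
    detect_sigma: float = 1.5
    detect_threshold_rel: float = 0.1
    match_radius: float | None = None  # default: 2 * detect_sigma
    size_gate_um: float = 0.5
    t_test_equal_var: bool = True
    anova_adjust: str = "sidak"
    min_cells_warning: int = 30

    def __post_init__(self) -> None:
        if self.n_rings < 2:
            raise ParameterError("n_rings must be >= 2")
        if self.rolling_ball_radius < 1:
            raise ParameterError("rolling_ball_radius must be >= 1")
        if self.match_radius is None:
            self.match_radius = 2.0 * self.detect_sigma

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config {path} is not a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown config key(s) {sorted(unknown)}; known: {sorted(known)}"
            )
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
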