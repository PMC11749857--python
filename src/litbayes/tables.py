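"""Core data containers: categorical factor definitions and patient tables.

Every covariate in the cohort is categorical, coded in levels.  By convention
the first level of each factor denotes a missing measurement and serves as the
reference level of the dummy coding (for the treatment factor the first level
is "untreated" rather than missing, but the reference-level role is the same).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FactorSpec", "PatientTable", "OUTCOME_COLUMN"]

OUTCOME_COLUMN = "live_birth"


@dataclass(frozen=True)
class FactorSpec:
    """A categorical factor: ordered levels and (optionally) ground-truth
    log-odds effects used by the synthetic cohort generator.

    Parameters
    ----------
    name
        Factor identifier (a valid column name).
    levels
        Ordered level labels; the first level is the reference ("missing"
        for measured factors, "untreated" for the treatment factor).
    true_effects
        Per-level log-odds offsets relative to the reference level; the
        reference entry must be exactly 0.  ``None`` for factors read from
        files, where no ground truth exists.
    level_probs
        Marginal level probabilities used when simulating; ``None`` means the
        generator's default (missing rate on level 1, uniform on the rest).
    """

    name: str
    levels: tuple[str, ...]
    true_effects: tuple[float, ...] | None = None
    level_probs: tuple[float, ...] | None = None

    def __post_init__(self):
        levels = tuple(str(l) for l in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ValueError(f"factor {self.name!r} needs >= 2 levels")
        if len(set(levels)) != len(levels):
            raise ValueError(f"factor {self.name!r} has duplicate level labels")
        if self.true_effects is not None:
            eff = tuple(float(e) for e in self.true_effects)
            object.__setattr__(self, "true_effects", eff)
            if len(eff) != len(levels):
                raise ValueError(
                    f"factor {self.name!r}: {len(eff)} effects for {len(levels)} levels"
                )
            if eff[0] != 0.0:
                raise ValueError(
                    f"factor {self.name!r}: reference-level effect must be 0"
                )
        if self.level_probs is not None:
            pr = tuple(float(p) for p in self.level_probs)
            object.__setattr__(self, "level_probs", pr)
            if len(pr) != len(levels):
                raise ValueError(f"factor {self.name!r}: level_probs length mismatch")
            if any(p < 0 for p in pr) or not np.isclose(sum(pr), 1.0):
                raise ValueError(f"factor {self.name!r}: level_probs must sum to 1")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def reference(self) -> str:
        return self.levels[0]


@dataclass
class PatientTable:
    """Patient-level data: one binary live-birth outcome plus categorical
    factor columns, with the factor specifications they must conform to."""

    data: pd.DataFrame
    specs: list[FactorSpec]
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        if OUTCOME_COLUMN not in self.data.columns:
            raise ValueError(f"missing outcome column {OUTCOME_COLUMN!r}")
        y = self.data[OUTCOME_COLUMN]
        if not set(np.unique(y)).issubset({0, 1}):
            raise ValueError("outcome must be coded 0/1")
        for spec in self.specs:
            if spec.name not in self.data.columns:
                raise ValueError(f"factor column {spec.name!r} missing from table")
            observed = set(self.data[spec.name].astype(str))
            unknown = observed - set(spec.levels)
            if unknown:
                raise ValueError(
                    f"factor {spec.name!r} contains unknown levels {sorted(unknown)}"
                )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data[OUTCOME_COLUMN].to_numpy(dtype=int)

    @property
    def factor_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> FactorSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)
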