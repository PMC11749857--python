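"""The four-feature interaction model.

Main effects of treatment outcome (x1), age band (x2), paternal blood type
(x3) and ACAIgM (x4), plus interactions of the treatment factor with each of
the other three:

    logit p = beta0 + sum_i beta_i x_i + sum_{j=2..4} alpha_j (x1 x x_j)

on dummy-coded levels.  The treatment factor's reference level is "untreated";
for every other factor the first ("missing") level is the reference, so an
untreated patient contributes no interaction indicator at all.  Fitting
delegates to the shared logistic-regression engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import (
    DesignMatrix,
    PosteriorDraws,
    PriorSpec,
    build_design,
    sample_posterior,
)
from .tables import FactorSpec, PatientTable

__all__ = ["EmpiricalSpec", "EffectSummary", "build_interaction_design",
           "fit_empirical", "summarize_effects"]


@dataclass(frozen=True)
class EmpiricalSpec:
    """Level sets of the four clinical factors.

    x1: treatment outcome — untreated (reference), BA2 = treated without
    blocking-antibody conversion, BA3 = treated with conversion.
    x2: age band (years); x3: paternal ABO blood type; x4: anticardiolipin
    antibody IgM.  For x2..x4 the first level is "missing" (the reference).
    """

    treatment: str = "lit_outcome"
    treatment_levels: tuple[str, ...] = ("untreated", "BA2", "BA3")
    age: str = "age_band"
    age_levels: tuple[str, ...] = ("missing", "19-27", "27-29", "29-31", "31-34", "34-57")
    blood_type: str = "paternal_blood_type"
    blood_type_levels: tuple[str, ...] = ("missing", "A", "AB", "B", "O")
    aca_igm: str = "aca_igm"
    aca_igm_levels: tuple[str, ...] = ("missing", "negative", "positive")

    @property
    def factor_names(self) -> list[str]:
        return [self.treatment, self.age, self.blood_type, self.aca_igm]

    @property
    def level_sets(self) -> dict[str, tuple[str, ...]]:
        return {
            self.treatment: self.treatment_levels,
            self.age: self.age_levels,
            self.blood_type: self.blood_type_levels,
            self.aca_igm: self.aca_igm_levels,
        }

    def factor_specs(self) -> list[FactorSpec]:
        return [FactorSpec(name, levels, true_effects=tuple(0.0 for _ in levels))
                for name, levels in self.level_sets.items()]


def _validate_table(table: PatientTable, spec: EmpiricalSpec) -> None:
    for name, levels in spec.level_sets.items():
        tspec = table.spec(name)  # KeyError if absent
        if tuple(tspec.levels) != tuple(levels):
            raise ValueError(
                f"factor {name!r}: table levels {tspec.levels} do not match "
                f"the empirical specification {levels}"
            )


def build_interaction_design(table: PatientTable, spec: EmpiricalSpec | None = None) -> DesignMatrix:
    """Intercept + main-effect indicators for x1..x4 + product indicators for
    x1 x {x2, x3, x4} over non-reference levels, in deterministic order
    (mains in declaration order; interactions grouped BA2 block then BA3
    block, each running over x2, x3, x4 levels).

    With the clinical level sets (3, 6, 5, 3 levels) this yields
    1 + (2+5+4+2) + 2*(5+4+2) = 36 columns.
    """
    spec = spec or EmpiricalSpec()
    _validate_table(table, spec)
    main = build_design(table, spec.factor_names)
    treat_vals = table.data[spec.treatment].astype(str).to_numpy()
    cols = [main.X]
    labels = list(main.column_labels)
    others = [(spec.age, spec.age_levels), (spec.blood_type, spec.blood_type_levels),
              (spec.aca_igm, spec.aca_igm_levels)]
    for t_lev in spec.treatment_levels[1:]:
        t_ind = (treat_vals == t_lev).astype(float)
        for fname, levels in others:
            vals = table.data[fname].astype(str).to_numpy()
            for lev in levels[1:]:
                cols.append((t_ind * (vals == lev)).astype(float)[:, None])
                labels.append((f"{spec.treatment}:{fname}", f"{t_lev}:{lev}"))
    X = np.hstack([c if c.ndim == 2 else c for c in cols])
    factor_levels = dict(main.factor_levels)
    factors = list(main.factors)
    for t_lev in spec.treatment_levels[1:]:
        for fname, levels in others:
            pseudo = f"{spec.treatment}:{fname}"
            if pseudo not in factors:
                factors.append(pseudo)
    return DesignMatrix(X=X, column_labels=labels, factors=factors,
                        factor_levels=factor_levels)


def fit_empirical(
    table: PatientTable,
    spec: EmpiricalSpec | None = None,
    prior: PriorSpec | None = None,
    chains: int = 4,
    iterations: int = 4000,
    warmup: int = 2000,
    seed: int = 0,
) -> tuple[PosteriorDraws, DesignMatrix]:
    """Fit the interaction model; returns the posterior draws and the design
    (needed for summaries and model checking)."""
    spec = spec or EmpiricalSpec()
    design = build_interaction_design(table, spec)
    draws = sample_posterior(design, table.outcome, prior=prior, chains=chains,
                             iterations=iterations, warmup=warmup, seed=seed)
    return draws, design


@dataclass
class EffectSummary:
    """Per-coefficient posterior mean and 95% credible interval, grouped in
    blocks (intercept; main effects; BA2 interactions; BA3 interactions).
    Reference levels appear as exact zeros with zero-width intervals."""

    table: pd.DataFrame

    def block(self, name: str) -> pd.DataFrame:
        return self.table[self.table["block"] == name]


def summarize_effects(draws: PosteriorDraws, design: DesignMatrix,
                      spec: EmpiricalSpec | None = None) -> EffectSummary:
    """Summarize the fitted interaction model from the draw array directly
    (no re-fitting): posterior mean and central 95% interval per coefficient,
    with reference-level rows included as exact zeros, ordered as declared."""
    spec = spec or EmpiricalSpec()
    flat = draws.flat
    by_name = {n: flat[:, j] for j, n in enumerate(draws.names)}

    rows = []

    def add(block, factor, level, name_or_zero):
        if name_or_zero is None:
            rows.append((block, factor, level, 0.0, 0.0, 0.0))
        else:
            d = by_name[name_or_zero]
            lo, hi = np.percentile(d, [2.5, 97.5])
            rows.append((block, factor, level, float(d.mean()), float(lo), float(hi)))

    add("intercept", "intercept", "", "intercept")
    for fname, levels in spec.level_sets.items():
        add(f"main:{fname}", fname, levels[0], None)
        for lev in levels[1:]:
            add(f"main:{fname}", fname, lev, f"{fname}[{lev}]")
    others = [(spec.age, spec.age_levels), (spec.blood_type, spec.blood_type_levels),
              (spec.aca_igm, spec.aca_igm_levels)]
    for t_lev in spec.treatment_levels[1:]:
        for fname, levels in others:
            block = f"interaction:{t_lev}:{fname}"
            pseudo = f"{spec.treatment}:{fname}"
            add(block, pseudo, f"{t_lev}:{levels[0]}", None)
            for lev in levels[1:]:
                add(block, pseudo, f"{t_lev}:{lev}", f"{pseudo}[{t_lev}:{lev}]")
    table = pd.DataFrame(rows, columns=["block", "factor", "level", "mean", "lo95", "hi95"])
    return EffectSummary(table=table)
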