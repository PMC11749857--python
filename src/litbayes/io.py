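"""CSV/JSON input and output for patient tables, study tables and results.

All artifacts are plain text: patient and study tables as CSV with a header
row, ground truth and run summaries as JSON, posterior draws as long-format
CSV (chain, iteration, parameter, value).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .glm import PosteriorDraws
from .meta import MetaPosterior, StudyTable
from .projection import SelectionPath
from .tables import OUTCOME_COLUMN, FactorSpec, PatientTable

__all__ = [
    "read_patient_csv", "write_patient_csv",
    "read_study_csv", "write_study_csv",
    "write_draws_csv", "write_summary_json",
    "write_selection_csv", "write_forest_csv", "write_meta_json",
]

logger = logging.getLogger(__name__)


def write_patient_csv(table: PatientTable, path, ground_truth_path=None) -> None:
    """Write the table as CSV; optionally write the generating ground truth
    (true effects, configuration, seed) as a sidecar JSON."""
    table.data.to_csv(path, index=False)
    if ground_truth_path is not None:
        truth = table.truth or {}
        Path(ground_truth_path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def read_patient_csv(path, factor_specs: list[FactorSpec]) -> PatientTable:
    """Read a patient CSV and validate it against the factor specifications.

    Empty cells in a factor column are mapped to the factor's first ("missing")
    level.  Unknown levels and non-binary outcomes are reported with the
    offending row number (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if OUTCOME_COLUMN not in df.columns:
        raise ValueError(f"missing outcome column {OUTCOME_COLUMN!r} in {path}")
    y_raw = df[OUTCOME_COLUMN].str.strip()
    bad = ~y_raw.isin(["0", "1"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(
            f"outcome value {y_raw.iloc[row - 1]!r} outside {{0,1}} at row {row}"
        )
    df[OUTCOME_COLUMN] = y_raw.astype(int)
    for spec in factor_specs:
        if spec.name not in df.columns:
            raise ValueError(f"factor column {spec.name!r} missing from {path}")
        col = df[spec.name].str.strip()
        col = col.where(col != "", spec.levels[0])
        unknown = ~col.isin(spec.levels)
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0]) + 1
            raise ValueError(
                f"unknown level {col.iloc[row - 1]!r} for factor {spec.name!r} "
                f"at row {row}"
            )
        df[spec.name] = col
    keep = [OUTCOME_COLUMN] + [s.name for s in factor_specs]
    return PatientTable(data=df[keep], specs=list(factor_specs))


def write_study_csv(table: StudyTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_study_csv(path) -> StudyTable:
    """Read a study-level CSV with columns label, d1, n1, d0, n0 and optional
    outcome_type.  Count sanity (0 <= d <= n, n >= 1) is enforced by
    :class:`StudyTable`; duplicated labels are suffixed with a warning."""
    df = pd.read_csv(path)
    missing = [c for c in ("label", "d1", "n1", "d0", "n0") if c not in df.columns]
    if missing:
        raise ValueError(f"study CSV {path} missing columns {missing}")
    labels = df["label"].astype(str).tolist()
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            new = f"{lab}_{seen[lab]}"
            logger.warning("duplicated study label %r renamed to %r", lab, new)
            out.append(new)
        else:
            seen[lab] = 0
            out.append(lab)
    df["label"] = out
    return StudyTable(df)


def write_draws_csv(draws: PosteriorDraws, path) -> None:
    """Long-format draw export: chain, iteration, parameter, value."""
    n_chains, n_iter, n_par = draws.draws.shape
    chain = np.repeat(np.arange(n_chains), n_iter * n_par)
    iteration = np.tile(np.repeat(np.arange(n_iter), n_par), n_chains)
    parameter = np.tile(np.asarray(draws.names, dtype=object), n_chains * n_iter)
    pd.DataFrame(
        {"chain": chain, "iteration": iteration, "parameter": parameter,
         "value": draws.draws.ravel()}
    ).to_csv(path, index=False)


def write_summary_json(draws: PosteriorDraws, path) -> None:
    """Per-parameter mean, SD, 2.5/50/97.5 percentiles, split-R-hat and ESS."""
    summ = draws.summary()
    payload = {name: {k: float(v) for k, v in row.items()}
               for name, row in summ.iterrows()}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_selection_csv(path_obj: SelectionPath, path) -> None:
    """The data behind the accuracy/ELPD-versus-size figure."""
    path_obj.to_frame().to_csv(path, index=False)


def write_forest_csv(forest: pd.DataFrame, path) -> None:
    """Forest-plot data: raw and shrunk relative-risk intervals per study."""
    forest.to_csv(path, index=False)


def write_meta_json(post: MetaPosterior, path, seed: int = 0, force: bool = False) -> None:
    payload = post.summaries(force=force, seed=seed)
    payload["diagnostics_ok"] = bool(post.diagnostics_ok)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
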