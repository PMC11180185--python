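"""CSV/JSON readers and writers.

CSV is the interchange format for score and covariate tables (no domain
standard exists for semi-quantitative neuropathology scores); missing
scores may be encoded as empty cells or ``NA`` and are written as empty.
Fitted models serialise to JSON.  All writers are deterministic so that
re-running a pipeline with the same configuration reproduces outputs
byte-for-byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .scores import DEFAULT_MAX_LEVEL, DensityScoreTable, ScoreInputError
from .sequences import EventSequence, SubtypeModel

_NA_STRINGS = {"", "NA", "NaN", "nan"}


def read_scores(
    path,
    regions: list[str] | None = None,
    max_level: int = DEFAULT_MAX_LEVEL,
) -> DensityScoreTable:
    """Read a `subject_id, <region>, ...` CSV of ordinal scores.

    Malformed cells are reported with their row number and column name; if
    ``regions`` is given, the file's columns must match it exactly.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "subject_id" not in frame.columns:
        raise ValueError(f"{path}: first column must be 'subject_id'")
    frame = frame.set_index("subject_id")
    if regions is not None and list(frame.columns) != list(regions):
        raise ValueError(
            f"{path}: unknown or misordered regions {list(frame.columns)}; "
            f"expected {list(regions)}"
        )
    parsed = pd.DataFrame(index=frame.index, columns=frame.columns, dtype=float)
    for col in frame.columns:
        for row_number, (sid, raw) in enumerate(frame[col].items(), start=2):
            text = raw.strip()
            if text in _NA_STRINGS:
                parsed.loc[sid, col] = np.nan
                continue
            try:
                value = int(text)
            except ValueError:
                raise ScoreInputError(
                    f"{path} line {row_number}, column {col!r}: "
                    f"non-integer score {raw!r}"
                ) from None
            if not 0 <= value <= max_level:
                raise ScoreInputError(
                    f"{path} line {row_number}, column {col!r}: "
                    f"score {value} outside [0, {max_level}]"
                )
            parsed.loc[sid, col] = value
    return DensityScoreTable(parsed, max_level=max_level)


def write_scores(table: DensityScoreTable, path) -> None:
    frame = table.data.copy()
    out = frame.map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.index.name = "subject_id"
    out.to_csv(path)


def read_covariates(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "subject_id" not in frame.columns:
        raise ValueError(f"{path}: covariate CSV must have a subject_id column")
    return frame.set_index("subject_id")


def write_covariates(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=True)


def write_exclusion_log(log: pd.DataFrame, path) -> None:
    log.to_csv(path, index=False)


def write_model(model: SubtypeModel, path, include_samples: bool = False) -> None:
    """Serialise a fitted model to JSON.

    Sequences are stored as {region, level, position} records; the ML
    log-likelihood is stored at full precision.  MCMC samples (compact
    event-index form) are included only on request — they dominate file
    size and can be regenerated by refitting with the stored seed.
    """
    payload = {
        "format": "ordsustain-model",
        "version": 1,
        "n_subtypes": model.n_subtypes,
        "fractions": [float(f) for f in model.fractions],
        "ml_loglik": float(model.ml_loglik),
        "n_iterations": model.n_iterations,
        "seed": model.seed,
        "sequences": [
            {"label": seq.label, "events": seq.to_records()}
            for seq in model.sequences
        ],
    }
    if include_samples and model.mcmc_samples:
        regions = model.regions
        index = {r: i for i, r in enumerate(regions)}
        payload["sample_regions"] = regions
        payload["samples"] = [
            {
                "loglik": float(ll),
                "orders": [
                    [[index[r], z] for r, z in seq.events] for seq in seqs
                ],
            }
            for seqs, ll in model.mcmc_samples
        ]
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_model(path) -> SubtypeModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "ordsustain-model":
        raise ValueError(f"{path}: not an ordsustain model file")
    sequences = [
        EventSequence.from_records(entry["events"], label=entry.get("label"))
        for entry in payload["sequences"]
    ]
    samples = []
    if "samples" in payload:
        regions = payload["sample_regions"]
        for entry in payload["samples"]:
            seqs = tuple(
                EventSequence(tuple((regions[r], int(z)) for r, z in order))
                for order in entry["orders"]
            )
            samples.append((seqs, float(entry["loglik"])))
    return SubtypeModel(
        sequences=sequences,
        fractions=np.asarray(payload["fractions"], dtype=float),
        mcmc_samples=samples,
        ml_loglik=float(payload["ml_loglik"]),
        n_iterations=int(payload["n_iterations"]),
        seed=payload.get("seed"),
    )


def write_truth(truth, path) -> None:
    """Ground-truth JSON for a simulated cohort."""
    payload = {
        "fractions": [float(f) for f in truth.fractions],
        "seed": truth.seed,
        "params": truth.params,
        "sequences": [
            {"label": seq.label, "events": seq.to_records()}
            for seq in truth.sequences
        ],
        "subtype": [int(c) for c in truth.subtype],
        "stage": [int(k) for k in truth.stage],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
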