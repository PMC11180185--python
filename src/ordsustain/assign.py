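"""Subject-level subtyping and staging, and posterior ordering summaries.

Each subject receives a subtype posterior (proportional to the mixture
fraction times the stage-marginal likelihood, averaged over the retained
MCMC samples) and a maximum-likelihood stage under the assigned subtype.
Following the study's reporting rules, a subject is carried into downstream
statistics only if its ML stage is >= 1 (some pathology event has occurred)
and the winning subtype posterior exceeds 50%.  When several subtypes tie —
typical at early stages where orderings share a head — the more common
subtype (larger mixture fraction) wins.

Positional variance diagrams summarise ordering uncertainty: the (event,
stage) entry is the fraction of MCMC samples in which that event occupies
that position of the subtype's sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scores import ScoreProbabilityCube
from .sequences import SubtypeModel, stage_loglik_matrix, uniform_stage_prior

ASSIGNMENT_COLUMNS = [
    "subject_id",
    "subtype",
    "stage",
    "max_posterior",
    "included",
    "reason",
]


@dataclass
class PositionalVarianceDiagram:
    """Per-subtype event x stage matrices of posterior position certainty.

    ``matrices[c][e, k]`` is the fraction of retained samples in which event
    ``events[e]`` sits at (1-based) position ``k+1`` of subtype ``c``'s
    sequence.  Each event row sums to 1.
    """

    matrices: list[np.ndarray]
    events: list[tuple[str, int]]  # canonical (region, level) row order

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subtype, region, level, stage, certainty."""
        rows = []
        for c, mat in enumerate(self.matrices):
            for e, (region, level) in enumerate(self.events):
                for k in range(mat.shape[1]):
                    rows.append(
                        {
                            "subtype": c + 1,
                            "region": region,
                            "level": level,
                            "stage": k + 1,
                            "certainty": mat[e, k],
                        }
                    )
        return pd.DataFrame(rows)


def _sample_models(model: SubtypeModel):
    """Sequences to average over: the retained MCMC draws, or the ML
    sequences if no samples were stored."""
    if model.mcmc_samples:
        return [seqs for seqs, _ in model.mcmc_samples]
    return [tuple(model.sequences)]


def assign_subjects(
    cube: ScoreProbabilityCube,
    model: SubtypeModel,
    stage_prior: np.ndarray | None = None,
    confidence_threshold: float = 0.5,
) -> pd.DataFrame:
    """Assign every subject a subtype, stage, confidence and inclusion flag.

    Returns a DataFrame with columns ``subject_id, subtype, stage,
    max_posterior, included, reason`` plus ``posterior_<c>`` columns holding
    the full subtype posterior.  ``subtype`` is 1-based; ``stage`` is 0..K
    with 0 meaning no pathology events.
    """
    if list(cube.regions) != list(model.regions):
        # model regions may be ordered by first appearance; compare as sets
        if set(cube.regions) != set(model.regions):
            raise ValueError(
                "cube regions do not match the model's regions: "
                f"{cube.regions} vs {model.regions}"
            )
    if stage_prior is None:
        stage_prior = uniform_stage_prior(model.n_events)
    log_prior = np.log(np.clip(np.asarray(stage_prior, dtype=float), 1e-300, None))
    log_prob = cube.log_prob()
    n, C, K = cube.n_subjects, model.n_subtypes, model.n_events
    samples = _sample_models(model)

    # accumulate, per subject: mean over samples of the joint stage-subtype
    # likelihood surface, in a numerically shifted linear domain
    acc = np.zeros((n, C, K + 1))

    def _joint(seqs) -> np.ndarray:
        return np.stack(
            [
                stage_loglik_matrix(log_prob, *seq.to_arrays(cube.regions))
                + log_prior[None, :]
                for seq in seqs
            ],
            axis=1,
        )  # n x C x (K+1)

    # two passes: a per-subject shift keeps the exponentials in range
    # without holding every sample's likelihood surface in memory
    shift = np.full(n, -np.inf)
    for seqs in samples:
        np.maximum(shift, _joint(seqs).max(axis=(1, 2)), out=shift)
    for seqs in samples:
        acc += np.exp(_joint(seqs) - shift[:, None, None])
    acc /= len(samples)

    stage_lik = acc  # n x C x (K+1), shifted linear scale
    subtype_score = model.fractions[None, :] * stage_lik.sum(axis=2)
    posterior = subtype_score / subtype_score.sum(axis=1, keepdims=True)

    rows = []
    for j, sid in enumerate(cube.subject_ids):
        post = posterior[j]
        top = post.max()
        tied = np.flatnonzero(post >= top * (1 - 1e-9))
        # dominant-subtype tie-break: the larger mixture fraction wins
        c_star = int(tied[np.argmax(model.fractions[tied])])
        stage = int(np.argmax(stage_lik[j, c_star]))  # first max -> smaller stage
        included = stage >= 1 and top > confidence_threshold
        if stage < 1:
            reason = "stage-0"
        elif top <= confidence_threshold:
            reason = "low-confidence"
        else:
            reason = ""
        row = {
            "subject_id": sid,
            "subtype": c_star + 1,
            "stage": stage,
            "max_posterior": float(top),
            "included": included,
            "reason": reason,
        }
        for c in range(C):
            row[f"posterior_{c + 1}"] = float(post[c])
        rows.append(row)
    return pd.DataFrame(rows)


def positional_variance(model: SubtypeModel) -> PositionalVarianceDiagram:
    """Fraction of MCMC samples placing each event at each sequence position."""
    samples = _sample_models(model)
    if not samples:
        raise ValueError("model has no MCMC samples")
    regions = model.regions
    max_level = model.sequences[0].max_level
    events = [(r, z) for r in regions for z in range(1, max_level + 1)]
    index = {ev: e for e, ev in enumerate(events)}
    K = len(events)
    mats = [np.zeros((K, K)) for _ in range(model.n_subtypes)]
    for seqs in samples:
        for c, seq in enumerate(seqs):
            for pos, ev in enumerate(seq.events):
                mats[c][index[ev], pos] += 1.0
    for mat in mats:
        mat /= len(samples)
    return PositionalVarianceDiagram(matrices=mats, events=events)


def staging_histogram(assignments: pd.DataFrame, n_stages: int | None = None) -> pd.DataFrame:
    """Stage x subtype counts of included subjects.

    Rows are stages 1..K (stage-0 subjects are excluded by the inclusion
    flag), columns are subtypes; totals equal the number of included subjects.
    """
    included = assignments[assignments["included"]] if len(assignments) else assignments
    if n_stages is None:
        n_stages = int(included["stage"].max()) if len(included) else 0
    subtypes = sorted(assignments["subtype"].unique()) if len(assignments) else []
    table = pd.DataFrame(
        0,
        index=pd.RangeIndex(1, n_stages + 1, name="stage"),
        columns=pd.Index(subtypes, name="subtype"),
    )
    for _, row in included.iterrows():
        if row["stage"] >= 1:
            table.loc[row["stage"], row["subtype"]] += 1
    return table
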