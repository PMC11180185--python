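"""Event sequences and likelihoods of the ordinal subtype-and-stage model.

An *event* is a region reaching an ordinal severity level: the pair
``(region r, level z)`` with ``z`` in 1..Z.  A disease trajectory is a total
order over all R*Z events, constrained so that each region passes through
its levels in increasing order — i.e. a linear extension of R chains of
length Z.  With the default 10 regions and 4 score transitions the event
space has K = 40 stages; a subject's *stage* k in 0..K is the number of
events that have occurred, with stage 0 meaning no pathology events.

Stage-conditional likelihoods multiply, across regions, the probability of
the score level the sequence implies at that stage.  The subject marginal
sums these over a stage prior (uniform over the K+1 stages by default, so
that stage 0 remains in the support), and the mixture likelihood combines
subtypes through log-sum-exp.  All likelihood work is done in the log
domain; 40-event products underflow in linear arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .scores import ScoreProbabilityCube


@dataclass(frozen=True)
class EventSequence:
    """A valid total ordering of (region, level) progression events.

    ``events`` must be a permutation of ``{(r, z): r in regions, z in 1..Z}``
    in which, for every region, level z precedes level z+1.
    """

    events: tuple[tuple[str, int], ...]
    label: str | None = None

    def __post_init__(self) -> None:
        if not is_valid_sequence(self.events):
            raise ValueError("events are not a valid region-chain interleaving")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r, _ in self.events:
            seen.setdefault(r)
        return list(seen)

    @property
    def max_level(self) -> int:
        return max(z for _, z in self.events)

    def to_arrays(self, regions: list[str]) -> tuple[np.ndarray, np.ndarray]:
        """Region indices (into ``regions``) and levels, in event order."""
        pos = {r: i for i, r in enumerate(regions)}
        r_idx = np.array([pos[r] for r, _ in self.events], dtype=np.intp)
        z_idx = np.array([z for _, z in self.events], dtype=np.intp)
        return r_idx, z_idx

    @classmethod
    def from_arrays(
        cls,
        r_idx: np.ndarray,
        z_idx: np.ndarray,
        regions: list[str],
        label: str | None = None,
    ) -> "EventSequence":
        events = tuple((regions[int(r)], int(z)) for r, z in zip(r_idx, z_idx))
        return cls(events, label=label)

    def to_records(self) -> list[dict]:
        return [
            {"region": r, "level": z, "position": i + 1}
            for i, (r, z) in enumerate(self.events)
        ]

    @classmethod
    def from_records(cls, records: list[dict], label: str | None = None) -> "EventSequence":
        ordered = sorted(records, key=lambda d: d["position"])
        return cls(tuple((d["region"], int(d["level"])) for d in ordered), label=label)


def is_valid_sequence(events) -> bool:
    """True iff ``events`` is a permutation of a full (region, level) event
    set in which each region's levels appear in increasing order."""
    events = list(events)
    by_region: dict[str, list[int]] = {}
    for r, z in events:
        by_region.setdefault(r, []).append(int(z))
    if not events:
        return False
    sizes = {len(v) for v in by_region.values()}
    if len(sizes) != 1:
        return False
    z_max = sizes.pop()
    for levels in by_region.values():
        if sorted(levels) != list(range(1, z_max + 1)):
            return False  # not a permutation of the event set
        if levels != sorted(levels):
            return False
    return True


def count_valid_sequences(n_regions: int, max_level: int) -> int:
    """Number of valid orderings: (R*Z)! / (Z!)^R, exact integer."""
    return math.factorial(n_regions * max_level) // (
        math.factorial(max_level) ** n_regions
    )


def implied_scores(seq: EventSequence, stage: int) -> np.ndarray:
    """Score level of each region after the first ``stage`` events.

    Returns, per region (in the sequence's region order), the largest level z
    such that (r, z) is among the first ``stage`` events, else 0.  Because
    sequences are valid chains this is simply the count of that region's
    events among the first ``stage``.
    """
    if not 0 <= stage <= seq.n_events:
        raise ValueError(f"stage {stage} out of range 0..{seq.n_events}")
    regions = seq.regions
    counts = dict.fromkeys(regions, 0)
    for r, _ in seq.events[:stage]:
        counts[r] += 1
    return np.array([counts[r] for r in regions], dtype=int)


def uniform_stage_prior(n_events: int) -> np.ndarray:
    return np.full(n_events + 1, 1.0 / (n_events + 1))


def _check_prior(stage_prior: np.ndarray, n_events: int) -> np.ndarray:
    prior = np.asarray(stage_prior, dtype=float)
    if prior.shape != (n_events + 1,):
        raise ValueError(f"stage prior must have length {n_events + 1}")
    if not np.isclose(prior.sum(), 1.0, atol=1e-9):
        raise ValueError("stage prior must sum to 1")
    return prior


def stage_loglik_matrix(
    log_prob: np.ndarray, r_idx: np.ndarray, z_idx: np.ndarray
) -> np.ndarray:
    """N x (K+1) log-likelihood of every subject at every stage of one sequence.

    ``log_prob`` is the N x R x (Z+1) log-probability cube.  Stage 0 is the
    product of the level-0 probabilities; advancing one stage swaps region
    ``r`` from level ``z-1`` to ``z``, a rank-one update done by cumulative
    summation of per-event log-ratios.
    """
    base = log_prob[:, :, 0].sum(axis=1)
    delta = log_prob[:, r_idx, z_idx] - log_prob[:, r_idx, z_idx - 1]
    out = np.empty((log_prob.shape[0], r_idx.size + 1))
    out[:, 0] = base
    np.cumsum(delta, axis=1, out=out[:, 1:])
    out[:, 1:] += base[:, None]
    return out


def stage_likelihood(
    cube_row: np.ndarray, seq: EventSequence, stage: int
) -> float:
    """Likelihood of one subject at a given stage of a sequence.

    ``cube_row`` is that subject's R x (Z+1) probability block, with regions
    ordered as in ``seq.regions``.
    """
    implied = implied_scores(seq, stage)
    return float(np.prod(cube_row[np.arange(cube_row.shape[0]), implied]))


def subject_marginal_likelihood(
    cube_row: np.ndarray, seq: EventSequence, stage_prior: np.ndarray
) -> float:
    """Stage-marginal likelihood of one subject under one sequence."""
    prior = _check_prior(stage_prior, seq.n_events)
    return float(
        sum(
            prior[k] * stage_likelihood(cube_row, seq, k)
            for k in range(seq.n_events + 1)
        )
    )


def marginal_logliks(
    log_prob: np.ndarray,
    r_idx: np.ndarray,
    z_idx: np.ndarray,
    log_prior: np.ndarray,
) -> np.ndarray:
    """Length-N vector of stage-marginal log-likelihoods for one sequence."""
    return logsumexp(
        stage_loglik_matrix(log_prob, r_idx, z_idx) + log_prior[None, :], axis=1
    )


def kendall_distance(seq_a: EventSequence, seq_b: EventSequence) -> float:
    """Normalised Kendall tau distance between two orderings of the same
    event set: the fraction of event pairs ordered differently (0 =
    identical, 1 = reversed)."""
    if set(seq_a.events) != set(seq_b.events):
        raise ValueError("sequences must order the same event set")
    pos_b = {ev: i for i, ev in enumerate(seq_b.events)}
    ranks = [pos_b[ev] for ev in seq_a.events]
    n = len(ranks)
    discordant = sum(
        1 for i in range(n) for j in range(i + 1, n) if ranks[i] > ranks[j]
    )
    return discordant / (n * (n - 1) / 2)


@dataclass
class SubtypeModel:
    """A fitted mixture of event sequences.

    ``sequences`` are the maximum-likelihood orderings (one per subtype),
    ``fractions`` the mixture weights, ``mcmc_samples`` the retained draws as
    ``(tuple of EventSequence, log-likelihood)`` pairs, and ``ml_loglik`` the
    mixture log-likelihood of the stored ML model on the training cube.
    """

    sequences: list[EventSequence]
    fractions: np.ndarray
    mcmc_samples: list[tuple[tuple[EventSequence, ...], float]] = field(
        default_factory=list
    )
    ml_loglik: float = float("nan")
    n_iterations: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if len(self.sequences) != self.fractions.size:
            raise ValueError("one fraction per sequence required")
        if np.any(self.fractions < 0) or not np.isclose(
            self.fractions.sum(), 1.0, atol=1e-12
        ):
            raise ValueError("fractions must be >= 0 and sum to 1 within 1e-12")

    @property
    def n_subtypes(self) -> int:
        return len(self.sequences)

    @property
    def n_events(self) -> int:
        return self.sequences[0].n_events

    @property
    def regions(self) -> list[str]:
        return self.sequences[0].regions


def mixture_loglikelihood(
    cube: ScoreProbabilityCube,
    model: SubtypeModel,
    stage_prior: np.ndarray | None = None,
) -> float:
    """Data log-likelihood of a subtype mixture: sum over subjects of
    log sum_c f_c * P(subject | S_c)."""
    if cube.n_subjects == 0:
        import warnings

        warnings.warn("empty cube: mixture log-likelihood is 0 by convention")
        return 0.0
    if stage_prior is None:
        stage_prior = uniform_stage_prior(model.n_events)
    prior = _check_prior(stage_prior, model.n_events)
    log_prior = np.log(np.clip(prior, 1e-300, None))
    log_prob = cube.log_prob()
    per_subtype = np.empty((cube.n_subjects, model.n_subtypes))
    for c, seq in enumerate(model.sequences):
        r_idx, z_idx = seq.to_arrays(cube.regions)
        per_subtype[:, c] = marginal_logliks(log_prob, r_idx, z_idx, log_prior)
    log_f = np.log(np.clip(model.fractions, 1e-300, None))
    return float(logsumexp(per_subtype + log_f[None, :], axis=1).sum())
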