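"""Fitting the subtype-and-stage mixture.

The model is fitted in three stages, mirroring the usual practice for
event-based progression models:

1. *Greedy ascent.*  From random valid orderings, single events are
   relocated to the best improving position until no move improves the
   (responsibility-weighted) likelihood.  Each accepted move strictly
   increases the objective, so ascent is monotone.
2. *Hierarchical subtype splitting with EM.*  The C-subtype model is
   initialised from the fitted (C-1)-model by splitting one subtype's
   subjects into two random halves (responsibility weighted), refitting an
   ordering on each half, and keeping the best-likelihood split.  Soft EM
   then alternates subject responsibilities / mixture fractions with
   per-subtype re-optimisation of the orderings until the data
   log-likelihood improves by less than ``em_tolerance``.
3. *MCMC.*  Metropolis-Hastings over the constrained ordering space:
   a proposal relocates one uniformly chosen event to a uniformly chosen
   position and is rejected outright if the result violates the
   within-region level order; otherwise it is accepted by likelihood ratio.
   The sampler quantifies ordering uncertainty (positional variance) and
   tracks the maximum-likelihood model encountered.

Model selection uses 10-fold cross-validation: CVIC(C) = -2 x the summed
held-out mixture log-likelihood across folds, minimised over C (ties broken
toward the smaller C).

Implementation note: because every valid ordering contains the full event
set, the per-event log-likelihood increment of each subject (swapping a
region from level z-1 to z) does not depend on the ordering.  Those
increments are computed once per fit; evaluating a candidate ordering is
then a column permutation, a cumulative sum and a log-sum-exp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .scores import ScoreProbabilityCube
from .sequences import EventSequence, SubtypeModel, uniform_stage_prior

logger = logging.getLogger(__name__)

_LOG_FLOOR = 1e-300


@dataclass
class FitConfig:
    """Tuning knobs of the fit; defaults follow the study configuration
    (10,000 MCMC iterations, up to 5 subtypes) with desk-scale choices for
    the knobs the study leaves open."""

    n_mcmc_iterations: int = 10_000
    n_start_points: int = 25
    max_subtypes: int = 5
    em_tolerance: float = 1e-6
    max_em_iterations: int = 100
    seed: int | None = None
    mcmc_thin: int = 1
    max_greedy_passes: int = 30
    n_split_tries: int = 2

    def __post_init__(self) -> None:
        for name in (
            "n_mcmc_iterations",
            "n_start_points",
            "max_subtypes",
            "max_em_iterations",
            "mcmc_thin",
            "max_greedy_passes",
            "n_split_tries",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.em_tolerance <= 0:
            raise ValueError("em_tolerance must be positive")


# ---------------------------------------------------------------------------
# fast likelihood engine over event-id permutations
#
# Event id e = r * Z + (z - 1); an ordering is a permutation of 0..K-1.


class _SequenceLikelihood:
    """Per-fit cache of event-level log-likelihood increments."""

    def __init__(self, log_prob: np.ndarray, log_prior: np.ndarray) -> None:
        n, n_regions, z1 = log_prob.shape
        self.n_subjects = n
        self.n_regions = n_regions
        self.max_level = z1 - 1
        self.n_events = n_regions * self.max_level
        self.base = log_prob[:, :, 0].sum(axis=1)  # stage-0 log-likelihood
        # delta[:, r*Z + z-1] = log p[:, r, z] - log p[:, r, z-1]
        self.delta = (log_prob[:, :, 1:] - log_prob[:, :, :-1]).reshape(
            n, self.n_events
        )
        self.log_prior = log_prior

    def stage_matrix(self, perm: np.ndarray) -> np.ndarray:
        """N x (K+1) per-stage log-likelihoods of the ordering ``perm``."""
        out = np.empty((self.n_subjects, self.n_events + 1))
        out[:, 0] = self.base
        np.cumsum(self.delta[:, perm], axis=1, out=out[:, 1:])
        out[:, 1:] += self.base[:, None]
        return out

    def marginal(self, perm: np.ndarray) -> np.ndarray:
        """Length-N stage-marginal log-likelihood under the stage prior."""
        x = self.stage_matrix(perm) + self.log_prior[None, :]
        m = x.max(axis=1)
        with np.errstate(under="ignore"):
            return m + np.log(np.exp(x - m[:, None]).sum(axis=1))

    def objective(self, perm: np.ndarray, weights: np.ndarray | None = None) -> float:
        marg = self.marginal(perm)
        return float(marg.sum() if weights is None else weights @ marg)


def _event_ids(seq: EventSequence, regions: list[str]) -> np.ndarray:
    r_idx, z_idx = seq.to_arrays(regions)
    max_level = seq.max_level
    return (r_idx * max_level + (z_idx - 1)).astype(np.intp)


def _seq_from_perm(
    perm: np.ndarray, regions: list[str], max_level: int, label: str | None = None
) -> EventSequence:
    events = tuple(
        (regions[int(e) // max_level], int(e) % max_level + 1) for e in perm
    )
    return EventSequence(events, label=label)


def _random_perm(
    rng: np.random.Generator, n_regions: int, max_level: int
) -> np.ndarray:
    """Uniform draw from the valid orderings: shuffle the multiset of region
    labels; each region's levels then occur in increasing order."""
    r_idx = np.repeat(np.arange(n_regions), max_level)
    rng.shuffle(r_idx)
    counts = np.zeros(n_regions, dtype=np.intp)
    perm = np.empty(r_idx.size, dtype=np.intp)
    for i, r in enumerate(r_idx):
        perm[i] = r * max_level + counts[r]
        counts[r] += 1
    return perm


def _valid_span(perm: np.ndarray, i: int, max_level: int) -> tuple[np.ndarray, int]:
    """Positions (in the ordering with element i removed) where the event at
    position i may be re-inserted without breaking its region's chain.

    Returns ``(rest, lo..hi as range bounds)`` encoded as (rest, lo, hi)."""
    e = int(perm[i])
    r, z = e // max_level, e % max_level
    rest = np.delete(perm, i)
    same = rest // max_level == r
    lo, hi = 0, rest.size
    if same.any():
        positions = np.flatnonzero(same)
        levels = rest[positions] % max_level
        below = positions[levels < z]
        above = positions[levels > z]
        if below.size:
            lo = int(below.max()) + 1
        if above.size:
            hi = int(above.min())
    return rest, lo, hi


def _is_valid_perm(perm: np.ndarray, max_level: int) -> bool:
    for r in range(perm.size // max_level):
        levels = perm[perm // max_level == r] % max_level
        if np.any(np.diff(levels) < 0):
            return False
    return True


def _insertion_objectives(
    lik: _SequenceLikelihood,
    rest: np.ndarray,
    event: int,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Objective of re-inserting ``event`` at every position of ``rest``.

    All K insertion positions are scored in one O(N*K) sweep: with the
    event removed, the stage log-likelihoods split into a prefix part
    (stages before the insertion point) and a suffix part (stages after,
    shifted by the event's own increment), so cumulative sums of the
    exponentiated stage terms give every candidate's marginal at O(N) each.
    """
    n, M = lik.n_subjects, rest.size  # M = K - 1
    cum_rest = np.empty((n, M + 1))
    cum_rest[:, 0] = 0.0
    np.cumsum(lik.delta[:, rest], axis=1, out=cum_rest[:, 1:])
    d_e = lik.delta[:, event][:, None]
    base = lik.base[:, None]
    U = base + cum_rest + lik.log_prior[None, : M + 1]  # stage k <= j
    V = base + cum_rest + d_e + lik.log_prior[None, 1:]  # stage k > j
    shift = np.maximum(U.max(axis=1), V.max(axis=1))[:, None]
    with np.errstate(under="ignore"):
        EU = np.exp(U - shift)
        EV = np.exp(V - shift)
    CU = np.cumsum(EU, axis=1)
    CV = np.cumsum(EV, axis=1)
    # S[:, j] = sum over stages of the candidate with insertion at j
    S = CU + (CV[:, -1][:, None] - np.concatenate(
        [np.zeros((n, 1)), CV[:, :-1]], axis=1
    ))
    logmarg = shift + np.log(np.clip(S, _LOG_FLOOR, None))
    if weights is None:
        return logmarg.sum(axis=0)
    return weights @ logmarg


def _greedy_perm(
    lik: _SequenceLikelihood,
    perm: np.ndarray,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
    max_passes: int = 30,
) -> tuple[np.ndarray, float]:
    K = perm.size
    max_level = lik.max_level
    cur = lik.objective(perm, weights)
    for _ in range(max_passes):
        improved = False
        for e in rng.permutation(K):
            i = int(np.flatnonzero(perm == e)[0])
            rest, lo, hi = _valid_span(perm, i, max_level)
            vals = _insertion_objectives(lik, rest, int(e), weights)
            vals = vals[lo : hi + 1]
            j_best = lo + int(np.argmax(vals))
            if vals.max() > cur + 1e-9:
                perm = np.insert(rest, j_best, e)
                cur = float(vals.max())
                improved = True
        if not improved:
            break
    return perm, cur


def greedy_ascent(
    cube: ScoreProbabilityCube,
    init_seq: EventSequence,
    stage_prior: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    seed: int | None = None,
    max_passes: int = 30,
) -> EventSequence:
    """Monotone local search over single-event relocations.

    Returns a valid sequence whose single-subtype marginal log-likelihood on
    ``cube`` is at least that of ``init_seq``.
    """
    lik = _SequenceLikelihood(cube.log_prob(), _log_prior(stage_prior, cube))
    perm = _event_ids(init_seq, cube.regions)
    rng = np.random.default_rng(seed)
    perm, _ = _greedy_perm(lik, perm, rng, weights, max_passes)
    return _seq_from_perm(perm, cube.regions, cube.max_level, label=init_seq.label)


def _log_prior(
    stage_prior: np.ndarray | None, cube: ScoreProbabilityCube
) -> np.ndarray:
    n_events = cube.n_regions * cube.max_level
    if stage_prior is None:
        stage_prior = uniform_stage_prior(n_events)
    prior = np.asarray(stage_prior, dtype=float)
    if prior.shape != (n_events + 1,):
        raise ValueError(f"stage prior must have length {n_events + 1}")
    if not np.isclose(prior.sum(), 1.0, atol=1e-9):
        raise ValueError("stage prior must sum to 1")
    return np.log(np.clip(prior, _LOG_FLOOR, None))


# ---------------------------------------------------------------------------
# MCMC


def _mixture_total(marg: np.ndarray, log_f: np.ndarray) -> float:
    return float(logsumexp(marg + log_f[None, :], axis=1).sum())


def mcmc_sample(
    cube: ScoreProbabilityCube,
    init_seqs: list[EventSequence],
    fractions: np.ndarray,
    n_iterations: int,
    seed: int | None = None,
    stage_prior: np.ndarray | None = None,
    thin: int = 1,
) -> tuple[list[tuple[tuple[EventSequence, ...], float]], SubtypeModel]:
    """Metropolis-Hastings over the constrained ordering space.

    One iteration proposes, for each subtype in turn, relocating a uniformly
    chosen event to a uniformly chosen position; invalid orderings are
    rejected, valid ones accepted by mixture-likelihood ratio with the
    fractions held fixed.  Every ``thin``-th state is retained.  Returns the
    retained samples and the maximum-likelihood model encountered (including
    the initial state).  Fully deterministic given ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    lik = _SequenceLikelihood(cube.log_prob(), _log_prior(stage_prior, cube))
    fractions = np.asarray(fractions, dtype=float)
    log_f = np.log(np.clip(fractions, _LOG_FLOOR, None))
    C = len(init_seqs)
    K = init_seqs[0].n_events
    max_level = lik.max_level
    perms = [_event_ids(seq, cube.regions) for seq in init_seqs]
    marg = np.column_stack([lik.marginal(p) for p in perms])
    cur = _mixture_total(marg, log_f)
    best = (cur, [p.copy() for p in perms])
    samples: list[tuple[tuple[EventSequence, ...], float]] = []
    for it in range(n_iterations):
        for c in range(C):
            i = int(rng.integers(K))
            j = int(rng.integers(K))
            if j == i:
                continue
            perm = perms[c]
            e = perm[i]
            rest = np.delete(perm, i)
            cand = np.insert(rest, j, e)
            # validity: only the moved event's region chain can break
            sub = cand[cand // max_level == e // max_level] % max_level
            if np.any(np.diff(sub) < 0):
                continue  # invalid proposal rejected
            col = lik.marginal(cand)
            m_new = marg.copy()
            m_new[:, c] = col
            new = _mixture_total(m_new, log_f)
            if np.log(rng.random()) < new - cur:
                perms[c] = cand
                marg, cur = m_new, new
        if cur > best[0]:
            best = (cur, [p.copy() for p in perms])
        if (it + 1) % thin == 0:
            seqs = tuple(
                _seq_from_perm(p, cube.regions, max_level) for p in perms
            )
            samples.append((seqs, cur))
    ml_seqs = [
        _seq_from_perm(p, cube.regions, max_level, label=f"S{c + 1}")
        for c, p in enumerate(best[1])
    ]
    ml_model = SubtypeModel(
        sequences=ml_seqs,
        fractions=fractions,
        mcmc_samples=samples,
        ml_loglik=best[0],
        n_iterations=n_iterations,
        seed=seed,
    )
    return samples, ml_model


# ---------------------------------------------------------------------------
# EM + hierarchical fitting


def _responsibilities(marg: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    logpost = marg + np.log(np.clip(fractions, _LOG_FLOOR, None))[None, :]
    logpost -= logsumexp(logpost, axis=1, keepdims=True)
    with np.errstate(under="ignore"):
        return np.exp(logpost)


def _em_refine(
    lik: _SequenceLikelihood,
    perms: list[np.ndarray],
    fractions: np.ndarray,
    rng: np.random.Generator,
    config: FitConfig,
) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Soft EM: responsibility / fraction updates alternated with
    responsibility-weighted greedy re-optimisation of each ordering.
    Monotone in the mixture log-likelihood."""
    log_f = lambda f: np.log(np.clip(f, _LOG_FLOOR, None))
    marg = np.column_stack([lik.marginal(p) for p in perms])
    cur = _mixture_total(marg, log_f(fractions))
    converged = False
    for _ in range(config.max_em_iterations):
        resp = _responsibilities(marg, fractions)
        fractions = resp.mean(axis=0)
        for c in range(len(perms)):
            perms[c], _ = _greedy_perm(
                lik, perms[c], rng, weights=resp[:, c],
                max_passes=config.max_greedy_passes,
            )
        marg = np.column_stack([lik.marginal(p) for p in perms])
        new = _mixture_total(marg, log_f(fractions))
        if new - cur < config.em_tolerance:
            cur = max(cur, new)
            converged = True
            break
        cur = new
    if not converged:
        logger.warning(
            "EM did not converge within %d iterations", config.max_em_iterations
        )
    return perms, fractions, cur


def _fit_single(
    lik: _SequenceLikelihood,
    rng: np.random.Generator,
    config: FitConfig,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    best: tuple[float, np.ndarray] | None = None
    for _ in range(config.n_start_points):
        perm = _random_perm(rng, lik.n_regions, lik.max_level)
        perm, val = _greedy_perm(
            lik, perm, rng, weights, config.max_greedy_passes
        )
        if best is None or val > best[0]:
            best = (val, perm)
    assert best is not None
    return best[1], best[0]


def fit_subtypes(
    cube: ScoreProbabilityCube,
    n_subtypes: int,
    config: FitConfig | None = None,
    stage_prior: np.ndarray | None = None,
) -> SubtypeModel:
    """Fit an ``n_subtypes``-component mixture of orderings to ``cube``."""
    return fit_path(cube, n_subtypes, config, stage_prior)[-1]


def fit_path(
    cube: ScoreProbabilityCube,
    max_subtypes: int,
    config: FitConfig | None = None,
    stage_prior: np.ndarray | None = None,
) -> list[SubtypeModel]:
    """Hierarchically fit models with 1..max_subtypes subtypes.

    Returns one fitted :class:`SubtypeModel` per subtype count.  The
    maximum-likelihood log-likelihood is non-decreasing in the subtype count
    because each C-model's initialisation includes a candidate equivalent to
    the (C-1)-model (a duplicated subtype with split fraction).
    """
    config = config or FitConfig()
    if not 1 <= max_subtypes <= config.max_subtypes:
        raise ValueError(
            f"n_subtypes must be in 1..{config.max_subtypes} (max_subtypes)"
        )
    if cube.n_subjects < max_subtypes:
        raise ValueError("need at least as many subjects as subtypes")
    rng = np.random.default_rng(config.seed)
    lik = _SequenceLikelihood(cube.log_prob(), _log_prior(stage_prior, cube))

    models: list[SubtypeModel] = []
    perms: list[np.ndarray] = []
    fractions = np.array([1.0])
    for C in range(1, max_subtypes + 1):
        if C == 1:
            perm, _ = _fit_single(lik, rng, config)
            perms, fractions = [perm], np.array([1.0])
        else:
            perms, fractions, _ = _split_best(lik, perms, fractions, rng, config)
        seqs = [
            _seq_from_perm(p, cube.regions, cube.max_level, label=f"S{c + 1}")
            for c, p in enumerate(perms)
        ]
        _, model = mcmc_sample(
            cube,
            seqs,
            fractions,
            config.n_mcmc_iterations,
            seed=int(rng.integers(2**31)),
            stage_prior=stage_prior,
            thin=config.mcmc_thin,
        )
        # final fraction polish at the ML orderings (EM on fractions only)
        model = _polish_fractions(cube, model, lik, config)
        perms = [_event_ids(s, cube.regions) for s in model.sequences]
        fractions = model.fractions
        models.append(model)
    for prev, nxt in zip(models, models[1:]):
        if nxt.ml_loglik < prev.ml_loglik - 1e-9:  # pragma: no cover - guard
            logger.warning(
                "ml_loglik decreased from C=%d to C=%d", prev.n_subtypes, nxt.n_subtypes
            )
    return models


def _polish_fractions(
    cube: ScoreProbabilityCube,
    model: SubtypeModel,
    lik: _SequenceLikelihood,
    config: FitConfig,
) -> SubtypeModel:
    marg = np.column_stack(
        [lik.marginal(_event_ids(seq, cube.regions)) for seq in model.sequences]
    )
    fractions = model.fractions.copy()
    cur = _mixture_total(marg, np.log(np.clip(fractions, _LOG_FLOOR, None)))
    for _ in range(config.max_em_iterations):
        fractions = _responsibilities(marg, fractions).mean(axis=0)
        new = _mixture_total(marg, np.log(np.clip(fractions, _LOG_FLOOR, None)))
        if new - cur < config.em_tolerance:
            cur = max(cur, new)
            break
        cur = new
    fractions = fractions / fractions.sum()
    return SubtypeModel(
        sequences=model.sequences,
        fractions=fractions,
        mcmc_samples=model.mcmc_samples,
        ml_loglik=cur,
        n_iterations=model.n_iterations,
        seed=model.seed,
    )


def _split_best(
    lik: _SequenceLikelihood,
    perms: list[np.ndarray],
    fractions: np.ndarray,
    rng: np.random.Generator,
    config: FitConfig,
) -> tuple[list[np.ndarray], np.ndarray, float]:
    """Try splitting each subtype of the parent model; EM-refine each
    candidate and keep the best; fall back to duplicating the largest
    subtype (mixture likelihood unchanged) if no split improves it."""
    marg = np.column_stack([lik.marginal(p) for p in perms])
    resp = _responsibilities(marg, fractions)
    parent_ll = _mixture_total(marg, np.log(np.clip(fractions, _LOG_FLOOR, None)))
    n = lik.n_subjects
    best: tuple[float, list[np.ndarray], np.ndarray] | None = None
    for c in range(len(perms)):
        for _ in range(config.n_split_tries):
            mask = rng.random(n) < 0.5
            w = resp[:, c]
            halves = []
            for half in (mask, ~mask):
                p, _ = _greedy_perm(
                    lik,
                    perms[c].copy(),
                    rng,
                    weights=w * half,
                    max_passes=config.max_greedy_passes,
                )
                halves.append(p)
            cand_perms = [p for i, p in enumerate(perms) if i != c] + halves
            other_f = [f for i, f in enumerate(fractions) if i != c]
            cand_f = np.array(other_f + [fractions[c] / 2] * 2)
            cand_perms, cand_f, ll = _em_refine(lik, cand_perms, cand_f, rng, config)
            if best is None or ll > best[0]:
                best = (ll, cand_perms, cand_f)
    assert best is not None
    if best[0] < parent_ll:
        c = int(np.argmax(fractions))
        dup_perms = [p.copy() for p in perms] + [perms[c].copy()]
        dup_f = np.array(list(fractions) + [fractions[c] / 2])
        dup_f[c] /= 2
        return dup_perms, dup_f / dup_f.sum(), parent_ll
    return best[1], best[2], best[0]


# ---------------------------------------------------------------------------
# cross-validation / model selection


@dataclass
class CrossValidationResult:
    """Per-fold held-out log-likelihoods, CVIC per subtype count, and the
    selected count (lowest CVIC, ties toward fewer subtypes)."""

    folds: pd.DataFrame  # columns: n_subtypes, fold, heldout_loglik, n_heldout
    summary: pd.DataFrame  # columns: n_subtypes, cvic, mean_heldout_loglik
    selected: int


def cross_validate(
    cube: ScoreProbabilityCube,
    config: FitConfig | None = None,
    n_folds: int = 10,
    max_subtypes: int | None = None,
    stage_prior: np.ndarray | None = None,
) -> CrossValidationResult:
    """Seeded K-fold cross-validation of the subtype count.

    Subjects are partitioned into ``n_folds`` random folds (simple
    subject-level randomisation, no stratification); for each candidate
    count C the model is fitted on the training folds and the mixture
    log-likelihood of the held-out subjects is accumulated.
    CVIC(C) = -2 x (summed held-out log-likelihood).
    """
    config = config or FitConfig()
    max_subtypes = max_subtypes or config.max_subtypes
    n = cube.n_subjects
    if n < n_folds:
        raise ValueError("need at least one subject per fold")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    if any(f.size == 0 for f in folds):
        raise ValueError("empty cross-validation fold")
    rows = []
    for fold_id, heldout in enumerate(folds):
        train = np.setdiff1d(order, heldout)
        fold_cfg = replace(config, seed=int(rng.integers(2**31)))
        train_cube = cube.subset(train)
        heldout_cube = cube.subset(heldout)
        for model in fit_path(train_cube, max_subtypes, fold_cfg, stage_prior):
            ll = _heldout_loglik(heldout_cube, model, stage_prior)
            rows.append(
                {
                    "n_subtypes": model.n_subtypes,
                    "fold": fold_id,
                    "heldout_loglik": ll,
                    "n_heldout": int(heldout.size),
                }
            )
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("n_subtypes")["heldout_loglik"]
        .agg(total="sum", mean="mean")
        .reset_index()
    )
    summary["cvic"] = -2.0 * summary["total"]
    summary = summary.rename(columns={"mean": "mean_heldout_loglik"})[
        ["n_subtypes", "cvic", "mean_heldout_loglik"]
    ]
    best = summary.loc[summary["cvic"].idxmin()]
    # break exact ties toward the smaller count
    tol = 1e-9 * max(1.0, abs(float(best["cvic"])))
    tied = summary[summary["cvic"] <= float(best["cvic"]) + tol]
    selected = int(tied["n_subtypes"].min())
    return CrossValidationResult(folds=table, summary=summary, selected=selected)


def _heldout_loglik(
    cube: ScoreProbabilityCube, model: SubtypeModel, stage_prior: np.ndarray | None
) -> float:
    """Posterior-predictive held-out log-likelihood.

    Per held-out subject, the mixture likelihood is averaged over the
    retained MCMC draws of the training fit before taking the log, so the
    evaluation integrates over ordering uncertainty instead of plugging in
    the single maximum-likelihood ordering.  (A plug-in evaluation lets a
    richer mixture win merely by hedging the ordering uncertainty that a
    smaller model's point estimate ignores.)
    """
    lik = _SequenceLikelihood(cube.log_prob(), _log_prior(stage_prior, cube))
    log_f = np.log(np.clip(model.fractions, _LOG_FLOOR, None))
    draws = (
        [seqs for seqs, _ in model.mcmc_samples]
        if model.mcmc_samples
        else [tuple(model.sequences)]
    )
    n = cube.n_subjects
    per_draw = np.empty((len(draws), n))
    for d, seqs in enumerate(draws):
        marg = np.column_stack(
            [lik.marginal(_event_ids(seq, cube.regions)) for seq in seqs]
        )
        per_draw[d] = logsumexp(marg + log_f[None, :], axis=1)
    return float(logsumexp(per_draw, axis=0).sum() - n * np.log(len(draws)))
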