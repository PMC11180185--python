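"""Model/results interface to the ordinal subtype-and-stage fit.

`OrdinalSuStaIn` is built from a subjects x regions table of ordinal
density scores; :meth:`OrdinalSuStaIn.fit` runs greedy ascent, hierarchical
EM and MCMC and returns an :class:`OrdinalSuStaInResults` carrying the
maximum-likelihood event orderings, mixture fractions, posterior samples
and subject assignments, with a text ``summary()``.

Example
-------
>>> from ordsustain import OrdinalSuStaIn, simulate_cohort
>>> table, truth = simulate_cohort(n_subjects=200, seed=0)
>>> model = OrdinalSuStaIn.from_dataframe(table.data)
>>> res = model.fit(n_subtypes=2, n_mcmc_iterations=500, seed=0)
>>> res.fractions  # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import assign as _assign
from .inference import (
    CrossValidationResult,
    FitConfig,
    cross_validate as _cross_validate,
    fit_path,
)
from .scores import (
    DEFAULT_MAX_LEVEL,
    DEFAULT_SIGMA,
    DensityScoreTable,
    apply_inclusion_filters,
    build_probability_cube,
)
from .sequences import SubtypeModel, mixture_loglikelihood, uniform_stage_prior


class OrdinalSuStaIn:
    """Ordinal subtype-and-stage inference model.

    Parameters
    ----------
    table : DensityScoreTable
        Ordinal scores (0..Z, NaN = missing), one row per subject.
    sigma : float
        Width of the Gaussian score kernel, in score units.
    stage_prior : array, optional
        Prior over the K+1 stages; uniform (stage 0 included) by default.
    apply_filters : bool
        Apply the cohort inclusion rules (>= 1 region with score >= 1, at
        most ``max_missing`` missing regions) before modelling.
    """

    def __init__(
        self,
        table: DensityScoreTable,
        sigma: float = DEFAULT_SIGMA,
        stage_prior: np.ndarray | None = None,
        apply_filters: bool = True,
        max_missing: int = 3,
    ) -> None:
        if apply_filters:
            table, self.exclusion_log = apply_inclusion_filters(table, max_missing)
        else:
            self.exclusion_log = pd.DataFrame(columns=["subject_id", "reason"])
        if table.n_subjects == 0:
            raise ValueError("no subjects remain after the inclusion filters")
        self.table = table
        self.sigma = sigma
        self.cube = build_probability_cube(table, sigma)
        self.n_events = table.n_regions * table.max_level
        self.stage_prior = (
            uniform_stage_prior(self.n_events)
            if stage_prior is None
            else np.asarray(stage_prior, dtype=float)
        )

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        max_level: int = DEFAULT_MAX_LEVEL,
        **kwargs,
    ) -> "OrdinalSuStaIn":
        """Build from a DataFrame indexed by subject id with region columns."""
        return cls(DensityScoreTable.from_dataframe(frame, max_level), **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "OrdinalSuStaIn":
        from .io import read_scores

        return cls(read_scores(path), **kwargs)

    def _config(self, config: FitConfig | None, **kwargs) -> FitConfig:
        if config is None:
            config = FitConfig()
        if kwargs:
            config = dataclasses.replace(config, **kwargs)
        return config

    def fit(
        self,
        n_subtypes: int = 1,
        config: FitConfig | None = None,
        **kwargs,
    ) -> "OrdinalSuStaInResults":
        """Fit the mixture with a fixed number of subtypes.

        Keyword arguments override :class:`FitConfig` fields, e.g.
        ``fit(2, n_mcmc_iterations=2000, seed=7)``.
        """
        config = self._config(config, **kwargs)
        path = fit_path(self.cube, n_subtypes, config, self.stage_prior)
        return OrdinalSuStaInResults(self, path[-1], config, path=path)

    def cross_validate(
        self,
        max_subtypes: int | None = None,
        n_folds: int = 10,
        config: FitConfig | None = None,
        **kwargs,
    ) -> CrossValidationResult:
        """CVIC model selection over the number of subtypes."""
        config = self._config(config, **kwargs)
        return _cross_validate(
            self.cube, config, n_folds, max_subtypes, self.stage_prior
        )


class OrdinalSuStaInResults:
    """Results of an :class:`OrdinalSuStaIn` fit."""

    def __init__(
        self,
        model: OrdinalSuStaIn,
        subtype_model: SubtypeModel,
        config: FitConfig,
        path: list[SubtypeModel] | None = None,
    ) -> None:
        self.model = model
        self.subtype_model = subtype_model
        self.config = config
        self.path = path or [subtype_model]
        self._assignments: pd.DataFrame | None = None

    # -- estimates ---------------------------------------------------------
    @property
    def sequences(self):
        return self.subtype_model.sequences

    @property
    def fractions(self) -> np.ndarray:
        return self.subtype_model.fractions

    @property
    def ml_loglik(self) -> float:
        return self.subtype_model.ml_loglik

    @property
    def n_subtypes(self) -> int:
        return self.subtype_model.n_subtypes

    def loglikelihood(self, cube=None) -> float:
        """Mixture log-likelihood on the training (or a new) cube."""
        if cube is None:
            cube = self.model.cube
        return mixture_loglikelihood(cube, self.subtype_model, self.model.stage_prior)

    # -- subject-level outputs --------------------------------------------
    def assign(
        self, cube=None, confidence_threshold: float = 0.5
    ) -> pd.DataFrame:
        """Per-subject subtype posterior, ML stage and inclusion flags."""
        if cube is None:
            if self._assignments is None:
                self._assignments = _assign.assign_subjects(
                    self.model.cube,
                    self.subtype_model,
                    self.model.stage_prior,
                    confidence_threshold,
                )
            return self._assignments
        return _assign.assign_subjects(
            cube, self.subtype_model, self.model.stage_prior, confidence_threshold
        )

    def positional_variance(self) -> _assign.PositionalVarianceDiagram:
        return _assign.positional_variance(self.subtype_model)

    def staging_histogram(self) -> pd.DataFrame:
        return _assign.staging_histogram(self.assign(), self.subtype_model.n_events)

    # -- reporting ---------------------------------------------------------
    def summary(self, n_head: int = 10) -> str:
        """Human-readable fit summary (counts, fractions, leading events)."""
        m = self.subtype_model
        lines = [
            "Ordinal subtype-and-stage inference",
            "=" * 54,
            f"subjects: {self.model.cube.n_subjects}"
            f"   regions: {self.model.cube.n_regions}"
            f"   events (stages): {m.n_events}",
            f"subtypes: {m.n_subtypes}"
            f"   MCMC iterations: {m.n_iterations}"
            f"   seed: {self.config.seed}",
            f"ML log-likelihood: {m.ml_loglik:.3f}",
            "",
        ]
        assignments = self.assign()
        counts = assignments[assignments["included"]]["subtype"].value_counts()
        for c, (seq, f) in enumerate(zip(m.sequences, m.fractions), start=1):
            head = ", ".join(f"{r}:{z}" for r, z in seq.events[:n_head])
            lines.append(
                f"Subtype {c}: fraction {f:.3f}, "
                f"{int(counts.get(c, 0))} subjects assigned"
            )
            lines.append(f"  first {n_head} events: {head}")
        n_excl = len(self.model.exclusion_log)
        n_unstaged = int((assignments["stage"] == 0).sum())
        lines += [
            "",
            f"excluded by inclusion filters: {n_excl}",
            f"assigned stage 0 (insufficient pathology): {n_unstaged}",
        ]
        return "\n".join(lines)

    def save(self, path, include_samples: bool = False) -> None:
        from .io import write_model

        write_model(self.subtype_model, path, include_samples=include_samples)

    def plot_positional_variance(self, path=None):
        from .plotting import plot_positional_variance

        return plot_positional_variance(self.positional_variance(), path=path)
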