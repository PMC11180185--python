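"""Measurement model for semi-quantitative density scores.

Regional Lewy-type α-synuclein burden is graded on an ordinal 0-4 scale
(0 = none, 1 = mild, 2 = moderate, 3 = severe, 4 = very severe).  The
progression model does not consume the raw grades: each observed score is
converted into a probability vector over the Z+1 possible score levels by
centring a Gaussian kernel (default SD 0.5 score units) on the observed
grade and normalising over the integer levels.  A missing grade carries no
evidence and is mapped to the uniform vector 1/(Z+1).

The module also implements the cohort inclusion rules applied before
modelling: a subject must show pathology in at least one region
(some score >= 1) and may miss at most ``max_missing`` regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The ten standard brain regions sampled for Lewy-type α-synuclein density,
#: ordered roughly rostro-caudally within groups: olfactory bulb and tract,
#: three brainstem, three limbic, and three neocortical regions.
STANDARD_REGIONS: tuple[str, ...] = (
    "olfactory_bulb",
    "medulla",
    "pons",
    "substantia_nigra",
    "amygdala",
    "transentorhinal",
    "cingulate",
    "temporal",
    "frontal",
    "parietal",
)

#: The seven non-brain regions whose 0-4 density scores sum to the total
#: non-brain pathology burden (range 0-28).
NONBRAIN_REGIONS: tuple[str, ...] = (
    "cervical_cord",
    "thoracic_cord",
    "lumbar_cord",
    "sacral_cord",
    "vagus_nerve",
    "submandibular_gland",
    "esophagus",
)

#: Region groups used by the staging-system cross-walk and the presets.
REGION_GROUPS: dict[str, tuple[str, ...]] = {
    "olfactory": ("olfactory_bulb",),
    "brainstem": ("medulla", "pons", "substantia_nigra"),
    "limbic": ("amygdala", "transentorhinal", "cingulate"),
    "neocortical": ("temporal", "frontal", "parietal"),
}

#: Tiny floor applied to probabilities before logarithms; keeps log-domain
#: arithmetic finite without reordering likelihoods at double precision.
PROB_FLOOR = 1e-300

DEFAULT_SIGMA = 0.5
DEFAULT_MAX_LEVEL = 4


class ScoreInputError(ValueError):
    """Raised when a density score is non-integer or out of range."""


@dataclass
class DensityScoreTable:
    """Subjects x regions table of ordinal density scores with missingness.

    Parameters
    ----------
    data : pandas.DataFrame
        Index = subject identifiers, columns = region names.  Entries are
        integers in ``[0, max_level]`` or NaN for missing.
    max_level : int
        Highest score level Z (default 4).
    """

    data: pd.DataFrame
    max_level: int = DEFAULT_MAX_LEVEL

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        bad = np.where(
            ~np.isnan(values)
            & ((values != np.round(values)) | (values < 0) | (values > self.max_level))
        )
        if bad[0].size:
            j, r = bad[0][0], bad[1][0]
            raise ScoreInputError(
                f"invalid score {values[j, r]!r} for subject "
                f"{self.data.index[j]!r}, region {self.data.columns[r]!r}: "
                f"scores must be integers in [0, {self.max_level}] or missing"
            )

    @property
    def subject_ids(self) -> list:
        return list(self.data.index)

    @property
    def regions(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def to_array(self) -> np.ndarray:
        """Scores as a float array with NaN for missing."""
        return self.data.to_numpy(dtype=float)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, max_level: int = DEFAULT_MAX_LEVEL
    ) -> "DensityScoreTable":
        return cls(frame.copy(), max_level=max_level)


@dataclass
class ScoreProbabilityCube:
    """Per subject x region x level probabilities of each score.

    ``prob[j, r, z]`` is the probability that subject ``j``'s true grade in
    region ``r`` is ``z`` given the observed (noisy) grade; rows sum to one.
    """

    prob: np.ndarray
    subject_ids: list
    regions: list[str]
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.prob.ndim != 3:
            raise ValueError("prob must be N x R x (Z+1)")
        if np.any(self.prob < 0):
            raise ValueError("probabilities must be non-negative")
        sums = self.prob.sum(axis=2)
        if self.prob.shape[0] and not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            raise ValueError("probability rows must sum to 1 within 1e-12")

    @property
    def n_subjects(self) -> int:
        return self.prob.shape[0]

    @property
    def n_regions(self) -> int:
        return self.prob.shape[1]

    @property
    def max_level(self) -> int:
        return self.prob.shape[2] - 1

    def log_prob(self) -> np.ndarray:
        """Log-probabilities with the ``PROB_FLOOR`` clamp applied."""
        return np.log(np.clip(self.prob, PROB_FLOOR, None))

    def subset(self, index: np.ndarray) -> "ScoreProbabilityCube":
        """Cube restricted to the subjects selected by ``index``."""
        ids = [self.subject_ids[i] for i in np.atleast_1d(index)]
        return ScoreProbabilityCube(
            self.prob[index], ids, list(self.regions), self.sigma
        )


def score_to_probabilities(
    score: float | int | None,
    max_level: int = DEFAULT_MAX_LEVEL,
    sigma: float = DEFAULT_SIGMA,
) -> np.ndarray:
    """Probability vector over levels 0..Z for one observed score.

    For an observed grade ``s`` the weight of level ``z`` is
    ``exp(-(z - s)^2 / (2 sigma^2))`` normalised to sum to one (the Gaussian
    normalising constant cancels).  A missing grade (None or NaN) yields the
    uniform vector ``1/(Z+1)`` — 20% per level at the default Z = 4 — so that
    missing regions do not influence the model fit.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if score is None or (isinstance(score, float) and np.isnan(score)):
        return np.full(max_level + 1, 1.0 / (max_level + 1))
    if float(score) != int(score) or not (0 <= int(score) <= max_level):
        raise ScoreInputError(
            f"score {score!r} is not an integer in [0, {max_level}]"
        )
    levels = np.arange(max_level + 1, dtype=float)
    w = np.exp(-((levels - float(score)) ** 2) / (2.0 * sigma * sigma))
    return w / w.sum()


def build_probability_cube(
    table: DensityScoreTable, sigma: float = DEFAULT_SIGMA
) -> ScoreProbabilityCube:
    """Apply the score kernel elementwise to a density-score table."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z1 = table.max_level + 1
    scores = table.to_array()
    n, r = scores.shape
    # one kernel row per possible observed level, plus the uniform row
    kernel = np.stack(
        [score_to_probabilities(z, table.max_level, sigma) for z in range(z1)]
    )
    uniform = np.full(z1, 1.0 / z1)
    prob = np.empty((n, r, z1))
    missing = np.isnan(scores)
    prob[missing] = uniform
    if (~missing).any():
        idx = scores[~missing].astype(int)
        prob[~missing] = kernel[idx]
    return ScoreProbabilityCube(prob, table.subject_ids, table.regions, sigma)


def apply_inclusion_filters(
    table: DensityScoreTable, max_missing: int = 3
) -> tuple[DensityScoreTable, pd.DataFrame]:
    """Drop subjects without pathology or with too many missing regions.

    A subject is retained only if (a) at least one non-missing region has a
    score >= 1 and (b) at most ``max_missing`` regions are missing.  Missing
    entries never count toward rule (a).  Returns the filtered table and an
    exclusion log with columns ``subject_id, reason`` where reason is
    ``"no-pathology"`` or ``"missingness"`` (missingness reported first when
    both rules fire).
    """
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    scores = table.to_array()
    missing = np.isnan(scores)
    n_missing = missing.sum(axis=1)
    has_pathology = np.nansum(scores >= 1, axis=1) > 0 if scores.size else np.array([])
    reasons: list[tuple[object, str]] = []
    keep = np.ones(table.n_subjects, dtype=bool)
    for j, sid in enumerate(table.subject_ids):
        if n_missing[j] > max_missing:
            reasons.append((sid, "missingness"))
            keep[j] = False
        elif not has_pathology[j]:
            reasons.append((sid, "no-pathology"))
            keep[j] = False
    log = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    filtered = DensityScoreTable(table.data.loc[keep], max_level=table.max_level)
    return filtered, log


@dataclass
class RegionPreset:
    """Named region list with group structure (olfactory/brainstem/limbic/neocortical)."""

    regions: tuple[str, ...] = STANDARD_REGIONS
    groups: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(REGION_GROUPS)
    )

    def group_of(self, region: str) -> str:
        for name, members in self.groups.items():
            if region in members:
                return name
        raise KeyError(f"region {region!r} not in preset")
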