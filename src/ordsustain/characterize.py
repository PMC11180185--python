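"""Downstream subtype characterisation statistics.

Covers the statistical stages run after subtyping/staging: Spearman
correlations between stage and covariates; covariate-adjusted pairwise
subtype comparisons (linear, logistic or multinomial regression, adjusted
for age, sex and stage, with Benjamini-Hochberg FDR across the declared
family); the sliding-window re-analysis across stage intervals (width 10,
slide 1 giving 31 windows over 40 stages); LOESS trajectories of non-brain
pathology across stages; and a simplified version of the Unified Staging
System for Lewy Body Disorders (USSLB) for cross-tabulation against the
model-derived subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .scores import DEFAULT_MAX_LEVEL, NONBRAIN_REGIONS, RegionPreset

#: Upper end of the total non-brain pathology score (7 regions x levels 0-4).
MAX_NONBRAIN_TOTAL = len(NONBRAIN_REGIONS) * DEFAULT_MAX_LEVEL

USSLB_STAGES = ("I", "IIa", "IIb", "III", "IV", "unclassifiable")


@dataclass
class CorrelationResult:
    group: object
    rho: float
    pvalue: float
    n: int
    degenerate: bool = False


def stage_correlation(
    assignments: pd.DataFrame,
    covariate: pd.Series,
    by_subtype: bool = False,
) -> list[CorrelationResult]:
    """Two-sided Spearman correlation between stage and a covariate.

    Operates on included subjects only.  With ``by_subtype`` one correlation
    per subtype is returned, otherwise a single pooled result.  Constant
    inputs are flagged ``degenerate`` (rho/p = NaN) instead of silently
    propagating NaN.
    """
    merged = assignments[assignments["included"]].merge(
        covariate.rename("covariate"), left_on="subject_id", right_index=True
    )
    merged = merged.dropna(subset=["covariate"])
    groups = merged.groupby("subtype") if by_subtype else [("all", merged)]
    out = []
    for name, grp in groups:
        if len(grp) < 3:
            raise ValueError(f"need >= 3 paired observations in group {name!r}")
        if grp["stage"].nunique() < 2 or grp["covariate"].nunique() < 2:
            out.append(CorrelationResult(name, np.nan, np.nan, len(grp), True))
            continue
        rho, p = stats.spearmanr(grp["stage"], grp["covariate"])
        out.append(CorrelationResult(name, float(rho), float(p), len(grp)))
    return out


def _contrast_vector(params_index, a: int, b: int, reference: int) -> np.ndarray | None:
    """Contrast for subtype b minus subtype a under treatment coding."""
    vec = np.zeros(len(params_index))

    def coef_pos(s: int) -> int | None:
        name = f"C(subtype, Treatment({reference}))[T.{s}]"
        return list(params_index).index(name) if name in params_index else None

    if a != reference:
        pos = coef_pos(a)
        if pos is None:
            return None
        vec[pos] -= 1.0
    if b != reference:
        pos = coef_pos(b)
        if pos is None:
            return None
        vec[pos] += 1.0
    return vec


def subtype_comparison(
    outcome: pd.Series,
    outcome_kind: str,
    assignments: pd.DataFrame,
    covariates: pd.DataFrame,
    adjust_for: tuple[str, ...] = ("age_at_death", "sex", "stage"),
    fdr: bool = False,
) -> pd.DataFrame:
    """Pairwise subtype contrasts from a single covariate-adjusted model.

    ``outcome_kind`` is ``"continuous"`` (OLS), ``"binary"`` (logistic) or
    ``"nominal"`` (one-vs-reference logits with the largest subtype as
    reference).  Subjects flagged not included are dropped.  Returns a tidy
    table with one row per subtype pair (and per outcome category for
    nominal outcomes): estimate, standard error, p-value, and optionally a
    Benjamini-Hochberg corrected p across the returned rows.
    """
    if outcome_kind not in {"continuous", "binary", "nominal"}:
        raise ValueError(f"unknown outcome_kind {outcome_kind!r}")
    data = assignments[assignments["included"]][
        ["subject_id", "subtype", "stage"]
    ].merge(covariates, left_on="subject_id", right_index=True)
    data = data.merge(outcome.rename("outcome"), left_on="subject_id", right_index=True)
    data = data.dropna(subset=["outcome", *[c for c in adjust_for if c != "stage"]])
    subtypes = sorted(data["subtype"].unique())
    if len(subtypes) < 2:
        raise ValueError("need at least two subtypes with data")
    reference = int(data["subtype"].value_counts().idxmax())
    terms = " + ".join(
        [f"C(subtype, Treatment({reference}))"]
        + [f"C({c})" if data[c].dtype == object else c for c in adjust_for]
    )
    rows = []
    if outcome_kind == "nominal":
        # one-vs-reference logits, reference = most common outcome category
        ref_cat = data["outcome"].value_counts().idxmax()
        for cat in [c for c in data["outcome"].unique() if c != ref_cat]:
            sub = data[data["outcome"].isin([ref_cat, cat])].copy()
            sub["y"] = (sub["outcome"] == cat).astype(int)
            rows += _fit_pairwise(sub, f"y ~ {terms}", "binary", subtypes, reference, cat)
    else:
        data = data.copy()
        data["y"] = (
            data["outcome"].astype(float)
            if outcome_kind == "continuous"
            else data["outcome"].astype(int)
        )
        rows += _fit_pairwise(data, f"y ~ {terms}", outcome_kind, subtypes, reference, None)
    table = pd.DataFrame(rows)
    if fdr and len(table):
        ok = table["pvalue"].notna()
        adj = np.full(len(table), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = fdr_correct(table.loc[ok, "pvalue"].to_numpy())
        table["p_fdr"] = adj
    return table


def _fit_pairwise(data, formula, kind, subtypes, reference, category):
    rows = []
    flag = ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if kind == "continuous":
                fit = smf.ols(formula, data=data).fit()
            else:
                fit = smf.glm(formula, data=data, family=sm.families.Binomial()).fit()
                if not getattr(fit, "converged", True) or np.any(
                    np.abs(fit.params) > 15
                ):
                    flag = "possible-separation"
    except Exception as exc:  # singular design, separation, ...
        for a, b in _pairs(subtypes):
            rows.append(
                _row(a, b, category, np.nan, np.nan, np.nan, 0, f"fit-failed: {exc}")
            )
        return rows
    for a, b in _pairs(subtypes):
        vec = _contrast_vector(fit.params.index, a, b, reference)
        if vec is None:
            rows.append(_row(a, b, category, np.nan, np.nan, np.nan, 0, "missing-level"))
            continue
        test = fit.t_test(vec)
        rows.append(
            _row(
                a,
                b,
                category,
                float(np.squeeze(test.effect)),
                float(np.squeeze(test.sd)),
                float(np.squeeze(test.pvalue)),
                int(fit.nobs),
                flag,
            )
        )
    return rows


def _pairs(subtypes):
    return [(a, b) for i, a in enumerate(subtypes) for b in subtypes[i + 1 :]]


def _row(a, b, category, est, se, p, n, flag):
    row = {
        "subtype_a": a,
        "subtype_b": b,
        "estimate": est,
        "se": se,
        "pvalue": p,
        "n": n,
        "flag": flag,
    }
    if category is not None:
        row["outcome_category"] = category
    return row


def fdr_correct(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def sliding_window_analysis(
    outcome: pd.Series,
    outcome_kind: str,
    assignments: pd.DataFrame,
    covariates: pd.DataFrame,
    width: int = 10,
    step: int = 1,
    n_stages: int = 40,
    min_n: int = 10,
    adjust_for: tuple[str, ...] = ("age_at_death", "sex", "stage"),
) -> pd.DataFrame:
    """Repeat the subtype comparison inside sliding stage windows.

    Windows are the inclusive intervals [w, w + width - 1] for
    w = 1 .. n_stages - width + 1 (31 windows at the defaults).  Windows
    with fewer than ``min_n`` subjects, or without two subtypes, are
    reported as skipped (``status = "insufficient-n"``), never dropped.
    """
    if width < 2:
        raise ValueError("window width must be >= 2")
    if width > n_stages:
        raise ValueError("window width exceeds the stage range")
    rows = []
    for start in range(1, n_stages - width + 2, step):
        stop = start + width - 1
        window = assignments[
            assignments["included"]
            & assignments["stage"].between(start, stop)
        ]
        n_win = len(window)
        if n_win < min_n or window["subtype"].nunique() < 2:
            rows.append(
                {
                    "window_start": start,
                    "window_end": stop,
                    "n": n_win,
                    "status": "insufficient-n",
                }
            )
            continue
        try:
            table = subtype_comparison(
                outcome, outcome_kind, window, covariates, adjust_for=adjust_for
            )
        except ValueError:
            rows.append(
                {
                    "window_start": start,
                    "window_end": stop,
                    "n": n_win,
                    "status": "insufficient-n",
                }
            )
            continue
        for _, r in table.iterrows():
            rows.append(
                {
                    "window_start": start,
                    "window_end": stop,
                    "n": n_win,
                    "status": "ok",
                    **r.to_dict(),
                }
            )
    return pd.DataFrame(rows)


def peripheral_trajectory(
    assignments: pd.DataFrame,
    nonbrain_total: pd.Series,
    span: float = 0.75,
    n_stages: int = 40,
    min_subjects: int = 10,
    total_range: tuple[float, float] = (0.0, float(MAX_NONBRAIN_TOTAL)),
) -> pd.DataFrame:
    """LOESS-smoothed mean non-brain pathology across stages, per subtype.

    Returns a long table (subtype, stage, fitted) over stages 1..n_stages,
    with fitted values clipped to the score range [0, 28].  Subtypes with
    fewer than ``min_subjects`` observed totals are skipped with a warning.
    """
    merged = assignments[assignments["included"]].merge(
        nonbrain_total.rename("nonbrain"), left_on="subject_id", right_index=True
    )
    merged = merged.dropna(subset=["nonbrain"])
    grid = np.arange(1, n_stages + 1, dtype=float)
    rows = []
    for subtype, grp in merged.groupby("subtype"):
        if len(grp) < min_subjects:
            warnings.warn(
                f"subtype {subtype}: only {len(grp)} subjects with non-brain "
                "totals; trajectory skipped"
            )
            continue
        fitted = lowess(
            grp["nonbrain"].to_numpy(),
            grp["stage"].to_numpy(dtype=float),
            frac=span,
            xvals=grid,
        )
        fitted = np.clip(fitted, *total_range)
        rows += [
            {"subtype": subtype, "stage": int(s), "fitted": float(f)}
            for s, f in zip(grid, fitted)
        ]
    return pd.DataFrame(rows)


def usslb_stage(
    scores: pd.Series | dict,
    preset: RegionPreset | None = None,
    comparable_margin: int = 1,
) -> str:
    """Simplified Unified Staging System for Lewy Body Disorders.

    Stage I: olfactory-bulb pathology only.  Stage IV: any neocortical
    region with at least moderate (>= 2) pathology.  Otherwise IIa
    (brainstem sum exceeds limbic sum), IIb (limbic exceeds brainstem) or
    III (both involved at comparable levels, |difference| <=
    ``comparable_margin``).  All-zero profiles are unclassifiable.  Missing
    regional values are treated as zero.  This is a simplified
    operationalisation of the published system's qualitative description.
    """
    preset = preset or RegionPreset()
    values = pd.Series(dict(scores) if isinstance(scores, dict) else scores)
    if set(values.index) != set(preset.regions):
        raise ValueError(
            "scores must cover exactly the preset regions; got "
            f"{sorted(values.index)}"
        )
    values = values.fillna(0.0)
    obt = float(values[list(preset.groups["olfactory"])].sum())
    brainstem = float(values[list(preset.groups["brainstem"])].sum())
    limbic = float(values[list(preset.groups["limbic"])].sum())
    neocortical = values[list(preset.groups["neocortical"])]
    if obt > 0 and brainstem == 0 and limbic == 0 and (neocortical == 0).all():
        return "I"
    if (neocortical >= 2).any():
        return "IV"
    if brainstem > 0 and limbic > 0 and abs(brainstem - limbic) <= comparable_margin:
        return "III"
    if brainstem > limbic:
        return "IIa"
    if limbic > brainstem:
        return "IIb"
    return "unclassifiable"
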