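"""Lexical-decision trial filtering, mixed-model fitting, and corpus comparison.

The validation question this module answers: which corpus's frequency
measures best explain auditory lexical decision behavior? For each corpus
and each measure (Zipf-scaled frequency, or log10 contextual-diversity
count) a mixed-effects model is fitted to trial-level reaction times
(linear) or accuracy (logistic), always with the same control covariates
(token duration, number of phonemes, familiarity, prevalence, phonological
neighborhood density) and crossed random intercepts for participants and
items. Models are then compared through Akaike weights
``w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)``, and corpus-level
support is the ratio of summed weights (frequency model + CD model) of one
corpus over another.

Trials enter a DataFrame with columns ``participant``, ``item``, ``rt``
(ms), ``accuracy`` (0/1), optionally ``accent``, the covariates, and one
column per candidate predictor.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .mixedmodels import (
    MixedFitResult,
    fit_glmm_logit_crossed,
    fit_lmm_crossed,
)

__all__ = [
    "DEFAULT_COVARIATES",
    "ModelFit",
    "AkaikeComparison",
    "filter_rt_trials",
    "fit_rt_model",
    "fit_acc_model",
    "akaike_weights",
    "corpus_support_ratio",
    "corpus_support_log_ratio",
    "marginal_r2",
    "run_validation",
    "comparison_frame",
    "model_summary_frame",
    "plot_aic",
]

#: Control covariates entering every model, in fixed order.
DEFAULT_COVARIATES = ("duration", "n_phonemes", "familiarity", "prevalence", "pnd")

#: Latent-scale residual variance of the standard logistic distribution,
#: used as the level-1 variance of logit models in the marginal R^2.
LOGIT_RESIDUAL_VARIANCE = math.pi**2 / 3.0


@dataclass
class ModelFit:
    """A labelled fitted model plus its comparison quantities."""

    label: str
    outcome: str                # "rt" | "accuracy"
    predictor: str | None       # name of the frequency/CD column; None = baseline
    result: MixedFitResult
    formula: str = ""

    @property
    def aic(self) -> float:
        return self.result.aic

    @property
    def marginal_r2(self) -> float:
        return marginal_r2(self.result)


# ---------------------------------------------------------------------------
# Trial filtering
# ---------------------------------------------------------------------------

def filter_rt_trials(
    trials: pd.DataFrame,
    rt_range: tuple[float, float] = (200.0, 3000.0),
    sd_limit: float = 2.5,
    max_passes: int | None = None,
) -> pd.DataFrame:
    """Standard reaction-time trial exclusions for lexical decision data.

    In order: (1) incorrect responses are dropped; (2) RTs outside
    ``rt_range`` ms are dropped; (3) per participant, trials whose RT lies
    more than ``sd_limit`` standard deviations from that participant's mean
    are dropped, with the mean and SD seeded from the trials surviving
    steps 1-2 and the trim repeated until self-consistent (every retained
    trial lies within ``sd_limit`` SDs of the retained trials' own mean),
    which makes the filter idempotent. ``max_passes=1`` gives the
    conventional one-shot trim instead. Accuracy analyses use the
    unfiltered trials.

    A participant with fewer than two surviving trials has an undefined SD;
    their trials are retained with a warning.
    """
    for col in ("participant", "rt", "accuracy"):
        if col not in trials.columns:
            raise ValueError(f"trials frame missing required column {col!r}")
    out = trials[trials["accuracy"] == 1]
    out = out[(out["rt"] >= rt_range[0]) & (out["rt"] <= rt_range[1])]

    warned = False
    passes = 0
    while True:
        grp = out.groupby("participant")["rt"]
        mean = grp.transform("mean")
        sd = grp.transform("std")  # ddof=1
        counts = grp.transform("size")
        few = counts < 2
        if few.any() and not warned:
            warnings.warn(
                f"{out.loc[few, 'participant'].nunique()} participant(s) have fewer "
                "than 2 surviving trials; SD trimming skipped for them",
                stacklevel=2,
            )
            warned = True
        keep = few | ((out["rt"] - mean).abs() <= sd_limit * sd)
        passes += 1
        if keep.all() or (max_passes is not None and passes >= max_passes):
            return out[keep]
        out = out[keep]


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _build_design(
    trials: pd.DataFrame,
    predictor: str | None,
    covariates: tuple[str, ...],
) -> tuple[np.ndarray, list[str]]:
    cols = list(covariates) + ([predictor] if predictor else [])
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise ValueError(f"trials frame missing predictor column(s): {missing}")
    if trials[cols].isna().any().any():
        raise ValueError("predictor values must be present for all trials")
    X = np.column_stack(
        [np.ones(len(trials))] + [trials[c].to_numpy(dtype=float) for c in cols]
    )
    return X, ["intercept"] + cols


def _formula(outcome: str, names: list[str]) -> str:
    fixed = " + ".join(n for n in names if n != "intercept")
    return f"{outcome} ~ {fixed} + (1 | participant) + (1 | item)"


def fit_rt_model(
    trials: pd.DataFrame,
    predictor: str | None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    label: str | None = None,
) -> ModelFit:
    """Linear mixed model for reaction time, fitted by maximum likelihood.

    ``predictor`` names the corpus measure column (e.g. ``"nsc_zipf"``);
    ``None`` fits the covariates-only baseline. ML (not REML) estimation is
    used so AICs are comparable across fixed-effect structures.
    """
    X, names = _build_design(trials, predictor, covariates)
    result = fit_lmm_crossed(
        trials["rt"].to_numpy(dtype=float),
        X,
        trials["participant"].to_numpy(),
        trials["item"].to_numpy(),
        names=names,
    )
    return ModelFit(
        label=label or (predictor or "baseline"),
        outcome="rt",
        predictor=predictor,
        result=result,
        formula=_formula("rt", names),
    )


def fit_acc_model(
    trials: pd.DataFrame,
    predictor: str | None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    label: str | None = None,
) -> ModelFit:
    """Logistic mixed model (Laplace) for accuracy; estimates report as odds ratios."""
    X, names = _build_design(trials, predictor, covariates)
    result = fit_glmm_logit_crossed(
        trials["accuracy"].to_numpy(dtype=float),
        X,
        trials["participant"].to_numpy(),
        trials["item"].to_numpy(),
        names=names,
    )
    return ModelFit(
        label=label or (predictor or "baseline"),
        outcome="accuracy",
        predictor=predictor,
        result=result,
        formula=_formula("accuracy", names),
    )


def marginal_r2(fit: MixedFitResult) -> float:
    """Nakagawa-Schielzeth marginal R^2: fixed-effect variance over total.

    ``var(X beta) / (var(X beta) + sum tau00 + residual)`` with residual
    ``sigma^2`` for linear fits and ``pi^2/3`` (latent logit scale) for
    binomial fits.
    """
    var_f = fit.fitted_fixed_var
    resid = fit.scale if fit.kind == "linear" else LOGIT_RESIDUAL_VARIANCE
    total = var_f + sum(fit.vc.values()) + resid
    return var_f / total


# ---------------------------------------------------------------------------
# Akaike weights and support ratios
# ---------------------------------------------------------------------------

@dataclass
class AkaikeComparison:
    """Delta-AIC and Akaike weights over a labelled model set.

    Weights are computed in log space (shift-invariant, underflow-safe) and
    sum to 1. ``log_weights`` retains full precision for ratios whose
    weights underflow.
    """

    labels: tuple[str, ...]
    aics: dict[str, float]
    delta: dict[str, float] = field(init=False)
    log_weights: dict[str, float] = field(init=False)
    weights: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.aics) < 2:
            raise ValueError("need at least two AIC values to compare")
        best = min(self.aics.values())
        self.delta = {m: a - best for m, a in self.aics.items()}
        logw = {m: -d / 2.0 for m, d in self.delta.items()}
        norm = logsumexp(np.array(list(logw.values())))
        self.log_weights = {m: lw - norm for m, lw in logw.items()}
        self.weights = {m: math.exp(lw) for m, lw in self.log_weights.items()}


def akaike_weights(aics: dict[str, float]) -> AkaikeComparison:
    """Akaike weights ``w_i = exp(-Delta_i/2)/sum exp(-Delta_j/2)`` per model."""
    return AkaikeComparison(labels=tuple(aics), aics=dict(aics))


def _corpus_log_weight(comp: AkaikeComparison, corpus: str) -> float:
    members = [m for m in comp.labels if m == corpus or m.startswith(corpus + ":")]
    if not members:
        raise KeyError(f"no models found for corpus {corpus!r} in {comp.labels}")
    return float(logsumexp(np.array([comp.log_weights[m] for m in members])))


def corpus_support_log_ratio(
    comp: AkaikeComparison, corpus_a: str, corpus_b: str
) -> float:
    """Natural log of the summed-weight ratio of corpus A over corpus B."""
    return _corpus_log_weight(comp, corpus_a) - _corpus_log_weight(comp, corpus_b)


def corpus_support_ratio(comp: AkaikeComparison, corpus_a: str, corpus_b: str) -> float:
    """Summed Akaike-weight ratio (freq model + CD model) of corpus A over B.

    Models belonging to a corpus are those labelled ``corpus`` or
    ``corpus:<measure>``. Computed in log space, so the ratio stays finite
    and exact even when one corpus's weights underflow; may overflow to
    ``inf`` only if the true ratio exceeds float range (use
    :func:`corpus_support_log_ratio` then).
    """
    return float(np.exp(corpus_support_log_ratio(comp, corpus_a, corpus_b)))


# ---------------------------------------------------------------------------
# High-level comparison driver
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """All fitted models plus the Akaike comparison for one outcome (and accent)."""

    outcome: str
    accent: str | None
    models: dict[str, ModelFit]
    comparison: AkaikeComparison
    baseline: ModelFit | None

    def support_ratio(self, corpus_a: str, corpus_b: str) -> float:
        return corpus_support_ratio(self.comparison, corpus_a, corpus_b)


def run_validation(
    trials: pd.DataFrame,
    predictors: dict[str, dict[str, str]],
    outcome: str = "rt",
    accent: str | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    include_baseline_in_weights: bool = False,
    filter_rt: bool = True,
) -> ValidationReport:
    """Fit the per-corpus model set for one outcome and compare by Akaike weights.

    ``predictors`` maps a corpus label to its measure columns, e.g.
    ``{"NSC": {"freq": "nsc_zipf", "cd": "nsc_log10cd"}, ...}``; one model is
    fitted per (corpus, measure) with labels ``"NSC:freq"`` etc., plus a
    covariates-only baseline. By default the baseline is excluded from the
    weight normalization (corpus support ratios involve only corpus
    models); set ``include_baseline_in_weights=True`` to include it.
    """
    if outcome not in ("rt", "accuracy"):
        raise ValueError("outcome must be 'rt' or 'accuracy'")
    data = trials
    if accent is not None:
        data = data[data["accent"] == accent]
        if data.empty:
            raise ValueError(f"no trials for accent {accent!r}")
    fitter = fit_rt_model if outcome == "rt" else fit_acc_model
    if outcome == "rt" and filter_rt:
        data = filter_rt_trials(data)

    models: dict[str, ModelFit] = {}
    for corpus, measures in predictors.items():
        for measure, column in measures.items():
            lab = f"{corpus}:{measure}"
            models[lab] = fitter(data, column, covariates=covariates, label=lab)
    baseline = fitter(data, None, covariates=covariates, label="baseline")

    weight_set = {lab: m.aic for lab, m in models.items()}
    # weights need >= 2 models; with a single corpus model the baseline is
    # the only available comparator
    if include_baseline_in_weights or len(weight_set) < 2:
        weight_set["baseline"] = baseline.aic
    comparison = akaike_weights(weight_set)
    return ValidationReport(
        outcome=outcome,
        accent=accent,
        models=models,
        comparison=comparison,
        baseline=baseline,
    )


def comparison_frame(report: ValidationReport) -> pd.DataFrame:
    """Tabular comparison: AIC, delta-AIC, Akaike weight, marginal R^2 per model."""
    rows = []
    for lab, m in report.models.items():
        rows.append(
            {
                "model": lab,
                "outcome": report.outcome,
                "accent": report.accent,
                "aic": m.aic,
                "delta_aic": report.comparison.delta[lab],
                "weight": report.comparison.weights[lab],
                "marginal_r2": m.marginal_r2,
                "llf": m.result.llf,
                "k": m.result.k,
            }
        )
    if report.baseline is not None:
        rows.append(
            {
                "model": "baseline",
                "outcome": report.outcome,
                "accent": report.accent,
                "aic": report.baseline.aic,
                "delta_aic": report.comparison.delta.get("baseline", np.nan),
                "weight": report.comparison.weights.get("baseline", np.nan),
                "marginal_r2": report.baseline.marginal_r2,
                "llf": report.baseline.result.llf,
                "k": report.baseline.result.k,
            }
        )
    return pd.DataFrame(rows)


def model_summary_frame(fit: ModelFit) -> pd.DataFrame:
    """Per-model summary mirroring standard mixed-model tables.

    Linear fits report estimates and SEs; binomial fits report odds ratios
    with delta-method SEs. Variance components and marginal R^2 are
    appended as extra rows.
    """
    r = fit.result
    if r.kind == "binomial":
        est, se = r.odds_ratios, r.odds_ratio_bse
        est_name = "odds_ratio"
    else:
        est, se = r.fe_params, r.bse
        est_name = "estimate"
    rows = [
        {"term": term, est_name: est[term], "se": se[term]} for term in r.fe_params.index
    ]
    if r.scale is not None:
        rows.append({"term": "sigma2", est_name: r.scale, "se": np.nan})
    else:
        rows.append({"term": "sigma2", est_name: LOGIT_RESIDUAL_VARIANCE, "se": np.nan})
    for grp, tau in r.vc.items():
        rows.append({"term": f"tau00_{grp}", est_name: tau, "se": np.nan})
    rows.append({"term": "marginal_r2", est_name: fit.marginal_r2, "se": np.nan})
    rows.append({"term": "aic", est_name: r.aic, "se": np.nan})
    return pd.DataFrame(rows)


def plot_aic(reports: list[ValidationReport], path: str | Path) -> None:
    """Bar chart of AIC change from baseline per model, one panel per report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(reports), figsize=(5 * len(reports), 4), squeeze=False)
    for ax, rep in zip(axes[0], reports):
        base = rep.baseline.aic if rep.baseline is not None else 0.0
        labels = list(rep.models)
        deltas = [rep.models[m].aic - base for m in labels]
        ax.bar(range(len(labels)), deltas)
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=45, ha="right")
        ax.set_ylabel("AIC - baseline AIC")
        title = rep.outcome + (f" ({rep.accent})" if rep.accent else "")
        ax.set_title(title)
        ax.axhline(0.0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
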