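"""End-to-end orchestration: fit the scoring model, apply it, validate it.

``fit_pipeline`` runs the full derivation on a labeled cohort:

1. derive cc2/s2, account for the cohort;
2. descriptive statistics per parameter and outcome group;
3. quartile compartment schemes on the pooled population, per-compartment
   formation rates, rate-ranked individual scores;
4. univariate logistic screen of the six individual scores;
5. multivariate model by backward elimination among the significant ones;
6. Sc on the complete cases, Sc-quartile rates with the chi-squared test,
   Mann–Whitney comparison between outcome groups;
7. ROC, AUC with 95 % CI, and the minimal-sum-of-squares cut-off;
8. freeze the model artifact.

``apply_model`` scores an (optionally unlabeled) cohort with a frozen model;
``validate_model`` evaluates a frozen model on an independent labeled cohort
without refitting anything, reporting the frozen-boundary quartile rates and
a freshly computed cut-off on the validation curve alongside the stored one.

Every stage is deterministic given (input, config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .compartments import (
    build_compartment_scheme,
    build_score_map,
    compartment_rates,
    score_embryos,
    score_table_report,
)
from .descriptive import group_descriptives
from .errors import MorphoscoreError, NonIdentifiableError
from .io import PARAMETERS, MorphokineticTable, derive_relative_parameters, summarize_cohort
from .logistic import LogisticFit, ScreenResult, multivariate_select, univariate_screen
from .roc import RocResult, analyze_scores
from .score_model import (
    BlastFormationModel,
    ScQuartileReport,
    compute_sc,
    mann_whitney_u,
    sc_quartile_report,
    serialize_model,
)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the derivation pipeline.

    ``alpha`` is the significance level used both for the univariate screen
    and for backward elimination.  ``mc_replicates`` sizes the Monte-Carlo
    null of the Lilliefors test in the descriptives stage.
    """

    parameters: tuple[str, ...] = PARAMETERS
    alpha: float = 0.05
    ci_method: str = "delong"
    seed: int = 0
    mc_replicates: int = 2000
    descriptives: bool = True
    quantile_convention: str = "linear-interpolation(type7)"

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")


@dataclass
class FitResult:
    model: BlastFormationModel
    cohort_summary: dict
    descriptives: pd.DataFrame | None
    scores_report: pd.DataFrame
    univariate: ScreenResult
    multivariate: LogisticFit
    dropped_predictors: list[str]
    scored_frame: pd.DataFrame          # labeled cohort + s_* + Sc (complete cases)
    sc_report: ScQuartileReport
    mann_whitney: tuple[float, float, float]
    sc_group_medians: dict
    roc: RocResult
    stage_log: list[str] = field(default_factory=list)

    @property
    def model_json(self) -> str:
        return serialize_model(self.model)


def _stage(log: list[str], msg: str) -> None:
    log.append(msg)


def fit_pipeline(table: MorphokineticTable, config: PipelineConfig = PipelineConfig()) -> FitResult:
    """Derive the frozen scoring model from a labeled cohort."""
    log: list[str] = []
    table = derive_relative_parameters(table)
    summary = summarize_cohort(table).as_dict()
    _stage(log, f"ingest: {summary['n_embryos']} embryos, "
                f"{summary['n_developed']} developed ({summary['pct_developed']}%)")

    descriptives = None
    if config.descriptives:
        descriptives = group_descriptives(
            table, mc_replicates=config.mc_replicates, seed=config.seed
        )
        _stage(log, "descriptives: computed")

    schemes, maps, rates = {}, {}, {}
    for parameter in config.parameters:
        try:
            scheme = build_compartment_scheme(table, parameter)
            cr = compartment_rates(table, scheme)
            smap = build_score_map(table, scheme)
        except MorphoscoreError as e:
            raise type(e)(f"compartment stage [{parameter}]: {e}") from e
        schemes[parameter], maps[parameter], rates[parameter] = scheme, smap, cr
        _stage(log, f"compartments[{parameter}]: boundaries={scheme.boundaries}, "
                    f"scores={smap.scores}")
    scores_report = score_table_report(maps, rates)

    scored = score_embryos(table, {p: (schemes[p], maps[p]) for p in config.parameters})
    labeled = scored[scored["blastocyst"].notna()].copy()
    score_cols = [f"s_{p}" for p in config.parameters]

    screen = univariate_screen(labeled, score_cols)
    if not screen.fits:
        raise NonIdentifiableError(
            "univariate stage: every predictor failed: "
            + "; ".join(f"{k}: {v}" for k, v in screen.failures.items())
        )
    candidates = screen.significant(config.alpha)
    _stage(log, f"univariate: candidates at alpha={config.alpha}: {candidates}; "
                f"failures: {list(screen.failures)}")
    try:
        final_fit, dropped = multivariate_select(labeled, candidates, alpha=config.alpha)
    except MorphoscoreError as e:
        raise type(e)(f"multivariate stage: {e}") from e
    _stage(log, f"multivariate: retained {final_fit.predictor_names}, dropped {dropped}")

    retained = list(final_fit.predictor_names)
    weights = dict(zip(retained, final_fit.odds_ratios))
    complete = labeled.dropna(subset=retained).copy()
    n_excluded = len(labeled) - len(complete)
    _stage(log, f"Sc cohort: {len(complete)} complete cases "
                f"({n_excluded} excluded for missing model parameters)")
    complete["Sc"] = sum(
        complete[p].to_numpy() * weights[p] for p in retained
    )

    sc = complete["Sc"].to_numpy()
    y = complete["blastocyst"].to_numpy()
    sc_report = sc_quartile_report(sc, y)
    dev, nodev = sc[y == 1], sc[y == 0]
    mw = mann_whitney_u(dev, nodev)
    sc_group = {
        "developed": {
            "n": int(dev.size),
            "median": float(np.median(dev)),
            "q1": float(np.quantile(dev, 0.25)),
            "q3": float(np.quantile(dev, 0.75)),
        },
        "not_developed": {
            "n": int(nodev.size),
            "median": float(np.median(nodev)),
            "q1": float(np.quantile(nodev, 0.25)),
            "q3": float(np.quantile(nodev, 0.75)),
        },
    }
    roc = analyze_scores(sc, y, ci_method=config.ci_method)
    _stage(log, f"roc: AUC={roc.auc:.4f} CI={roc.auc_ci95}, cutoff={roc.cutoff:.4f}")

    bare = {p.removeprefix("s_"): p for p in retained}
    model = BlastFormationModel(
        parameters=tuple(retained),
        weights=weights,
        schemes={sp: schemes[p] for p, sp in ((bp, f"s_{bp}") for bp in bare)},
        score_maps={f"s_{bp}": maps[bp] for bp in bare},
        sc_quartiles=sc_report.boundaries,
        cutoff=roc.cutoff,
        fit_metadata={
            "n_fit": int(len(complete)),
            "n_cohort": int(summary["n_embryos"]),
            "seed": int(config.seed),
            "alpha": config.alpha,
            "package_version": __version__,
            "quantile_convention": config.quantile_convention,
        },
    )
    return FitResult(
        model=model,
        cohort_summary=summary,
        descriptives=descriptives,
        scores_report=scores_report,
        univariate=screen,
        multivariate=final_fit,
        dropped_predictors=dropped,
        scored_frame=complete,
        sc_report=sc_report,
        mann_whitney=mw,
        sc_group_medians=sc_group,
        roc=roc,
        stage_log=log,
    )


def apply_model(model: BlastFormationModel, table: MorphokineticTable) -> pd.DataFrame:
    """Score a cohort with a frozen model.

    Returns the cohort frame plus ``s_*`` columns for the model parameters,
    ``Sc``, ``predicted_class`` (Sc >= cutoff) and a ``reason`` column naming
    the missing parameter for records that cannot be scored.
    """
    table = derive_relative_parameters(table)
    bare = [p.removeprefix("s_") for p in model.parameters]
    scored = score_embryos(
        table, {bp: (model.schemes[f"s_{bp}"], model.score_maps[f"s_{bp}"]) for bp in bare}
    )
    sc_vals, classes, reasons = [], [], []
    for _, row in scored.iterrows():
        missing = [f"s_{bp}" for bp in bare if np.isnan(row[f"s_{bp}"])]
        if missing:
            sc_vals.append(np.nan)
            classes.append(np.nan)
            reasons.append("missing " + ", ".join(missing))
        else:
            sc = compute_sc(model, {f"s_{bp}": row[f"s_{bp}"] for bp in bare})
            sc_vals.append(sc)
            classes.append(
                np.nan if model.cutoff is None else float(sc >= model.cutoff)
            )
            reasons.append("")
    scored["Sc"] = sc_vals
    scored["predicted_class"] = classes
    scored["reason"] = reasons
    return scored


@dataclass
class ValidationReport:
    n: int
    n_scored: int
    sc_report: ScQuartileReport            # frozen-boundary quartile rates
    mann_whitney: tuple[float, float, float]
    sc_group_medians: dict
    roc: RocResult                         # with fresh cut-off on this cohort
    stored_cutoff: float | None
    stored_cutoff_sensitivity: float | None
    stored_cutoff_specificity: float | None


def validate_model(model: BlastFormationModel, table: MorphokineticTable) -> ValidationReport:
    """Evaluate a frozen model on an independent labeled cohort.

    Nothing is refit: compartment boundaries, score maps, weights and the
    Sc-quartile boundaries all come from the model.  The report carries both
    the stored cut-off's performance on this cohort and a freshly computed
    minimal-sum-of-squares cut-off on the validation ROC.
    """
    scored = apply_model(model, table)
    lab = scored[scored["blastocyst"].notna() & scored["Sc"].notna()]
    sc = lab["Sc"].to_numpy()
    y = lab["blastocyst"].to_numpy()
    sc_report = sc_quartile_report(sc, y, boundaries=model.sc_quartiles)
    dev, nodev = sc[y == 1], sc[y == 0]
    mw = mann_whitney_u(dev, nodev)
    sc_group = {
        "developed": {"n": int(dev.size), "median": float(np.median(dev))},
        "not_developed": {"n": int(nodev.size), "median": float(np.median(nodev))},
    }
    roc = analyze_scores(sc, y)
    stored_sens = stored_spec = None
    if model.cutoff is not None:
        pos = sc[y == 1] >= model.cutoff
        neg = sc[y == 0] < model.cutoff
        stored_sens = float(pos.mean())
        stored_spec = float(neg.mean())
    return ValidationReport(
        n=int(scored.shape[0]),
        n_scored=int(lab.shape[0]),
        sc_report=sc_report,
        mann_whitney=mw,
        sc_group_medians=sc_group,
        roc=roc,
        stored_cutoff=model.cutoff,
        stored_cutoff_sensitivity=stored_sens,
        stored_cutoff_specificity=stored_spec,
    )
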