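#!/usr/bin/env python
"""Derive the Sc scoring model on the derivation cohort and freeze it.

Runs quartile compartmentalisation, rate-ranked 0/1/2 individual scores,
the univariate logistic screen, backward-elimination multivariate model,
Sc computation, quartile/ROC evaluation; writes:

  results/scores_report.tsv   per-compartment n / formation rate / score
  results/univariate.tsv      per-score OR, 95% CI, p
  results/multivariate.tsv    retained predictors' OR, 95% CI, p
  results/sc_quartiles.tsv    Sc-quartile formation rates + chi-squared p
  results/roc_report.tsv      threshold / sensitivity / specificity sweep
  results/model.json          the frozen scoring model
"""
from pathlib import Path

import pandas as pd

from morphoscore import PipelineConfig, fit_pipeline, read_morphokinetic_table, save_model

RESULTS = Path(__file__).resolve().parent.parent / "results"

def main():
    table = read_morphokinetic_table(RESULTS / "derivation_cohort.csv")
    result = fit_pipeline(table, PipelineConfig(seed=0, descriptives=False))

    result.scores_report.to_csv(RESULTS / "scores_report.tsv", sep="\t", index=False)
    result.univariate.as_frame().to_csv(RESULTS / "univariate.tsv", sep="\t", index=False)
    result.multivariate.as_frame().to_csv(RESULTS / "multivariate.tsv", sep="\t", index=False)
    result.sc_report.as_frame().to_csv(RESULTS / "sc_quartiles.tsv", sep="\t", index=False)
    thr, sens, spec = result.roc.as_arrays()
    pd.DataFrame({
        "threshold": thr, "sensitivity": sens, "specificity": spec,
        "objective": (1 - sens) ** 2 + (1 - spec) ** 2,
    }).to_csv(RESULTS / "roc_report.tsv", sep="\t", index=False)
    save_model(result.model, str(RESULTS / "model.json"))

    print("retained:", ", ".join(
        f"{p} (OR={result.model.weights[p]:.3f})" for p in result.model.parameters))
    u, z, p = result.mann_whitney
    med = result.sc_group_medians
    print(f"Sc medians: developed {med['developed']['median']:.2f} vs "
          f"not developed {med['not_developed']['median']:.2f} "
          f"(Mann-Whitney p={p:.2e})")
    print(f"Sc-quartile rates (%): {result.sc_report.rates_pct} "
          f"(chi2 p={result.sc_report.p_value:.2e})")
    print(f"AUC={result.roc.auc:.3f} 95% CI=({result.roc.auc_ci95[0]:.3f}, "
          f"{result.roc.auc_ci95[1]:.3f}); cutoff Sc={result.roc.cutoff:.3f} "
          f"(sens {100*result.roc.cutoff_sensitivity:.1f}%, "
          f"spec {100*result.roc.cutoff_specificity:.1f}%)")
    print("frozen model -> model.json")

if __name__ == "__main__":
    main()
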