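#!/usr/bin/env python
"""Validate the frozen model on the independent validation cohort.

Nothing is refit: the stored compartment boundaries, score maps, OR weights
and Sc-quartile boundaries are applied as-is; only the cut-off is
recomputed on the validation ROC (reported alongside the stored one).
Writes results/validation_report.json and the per-record scores to
results/validation_scored.csv.
"""
import json
from pathlib import Path

from morphoscore import apply_model, load_model, read_morphokinetic_table, validate_model

RESULTS = Path(__file__).resolve().parent.parent / "results"

def main():
    model = load_model(str(RESULTS / "model.json"))
    table = read_morphokinetic_table(RESULTS / "validation_cohort.csv")
    apply_model(model, table).to_csv(RESULTS / "validation_scored.csv", index=False)
    rep = validate_model(model, table)

    payload = {
        "n": rep.n,
        "n_scored": rep.n_scored,
        "frozen_boundary_quartile_rates_pct": list(rep.sc_report.rates_pct),
        "chi2_p": rep.sc_report.p_value,
        "mann_whitney_p": rep.mann_whitney[2],
        "sc_median_developed": rep.sc_group_medians["developed"]["median"],
        "sc_median_not_developed": rep.sc_group_medians["not_developed"]["median"],
        "auc": rep.roc.auc,
        "auc_ci95": list(rep.roc.auc_ci95),
        "validation_cutoff": rep.roc.cutoff,
        "validation_cutoff_sens": rep.roc.cutoff_sensitivity,
        "validation_cutoff_spec": rep.roc.cutoff_specificity,
        "stored_cutoff": rep.stored_cutoff,
        "stored_cutoff_sens": rep.stored_cutoff_sensitivity,
        "stored_cutoff_spec": rep.stored_cutoff_specificity,
    }
    with open(RESULTS / "validation_report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    print(f"validated on {rep.n_scored}/{rep.n} scorable embryos: "
          f"AUC={rep.roc.auc:.3f} (CI {rep.roc.auc_ci95[0]:.3f}-{rep.roc.auc_ci95[1]:.3f}), "
          f"fresh cutoff Sc={rep.roc.cutoff:.3f} vs stored {rep.stored_cutoff:.3f}")
    print("-> validation_report.json, validation_scored.csv")

if __name__ == "__main__":
    main()
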