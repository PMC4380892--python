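#!/usr/bin/env python
"""Draw the derivation and validation cohorts used by the downstream steps.

Emulates the reference study conditions: a derivation cohort of 432 embryos
and an independent validation cohort of 271, ~36 % of which develop to the
blastocyst stage, with t5 unrecorded for most non-developed embryos.
Writes results/derivation_cohort.csv and results/validation_cohort.csv.
"""
from pathlib import Path

from morphoscore import GroupDistributionSpec, simulate_cohort, summarize_cohort, write_scored_table

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20240601

def main():
    RESULTS.mkdir(exist_ok=True)
    spec = GroupDistributionSpec()
    for name, n, seed in (("derivation", 432, SEED), ("validation", 271, SEED + 1)):
        table = simulate_cohort(spec, n, seed=seed)
        out = RESULTS / f"{name}_cohort.csv"
        write_scored_table(table, None, str(out))
        s = summarize_cohort(table)
        print(f"{name}: {s.n_embryos} embryos from {s.n_patients} patients "
              f"({s.embryos_per_patient}/patient), {s.n_developed} developed "
              f"({s.pct_developed}%) -> {out.name}")

if __name__ == "__main__":
    main()
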