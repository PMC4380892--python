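#!/usr/bin/env python
"""Describe the derivation cohort per parameter and outcome group.

Writes results/descriptives.tsv: one row per morphokinetic parameter per
outcome group with n, the five-number summary and the two-test normality
verdict (Lilliefors + Shapiro-Wilk, normal only if both p >= 0.05) —
division times are mostly skewed, which is why the whole pipeline works
with medians and quartiles.
"""
from pathlib import Path

from morphoscore import derive_relative_parameters, group_descriptives, read_morphokinetic_table

RESULTS = Path(__file__).resolve().parent.parent / "results"

def main():
    table = derive_relative_parameters(
        read_morphokinetic_table(RESULTS / "derivation_cohort.csv")
    )
    desc = group_descriptives(table, mc_replicates=2000, seed=0)
    out = RESULTS / "descriptives.tsv"
    desc.to_csv(out, sep="\t", index=False, float_format="%.4g")
    n_normal = int(desc["normal"].fillna(False).sum())
    print(f"{len(desc)} parameter/group cells, {n_normal} consistent with "
          f"normality at 5% -> {out.name}")

if __name__ == "__main__":
    main()
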