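import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoscore import (
    MorphokineticTable,
    assign_compartment,
    assign_individual_scores,
    build_compartment_scheme,
    compartment_rates,
    score_embryos,
)
from morphoscore.compartments import CompartmentScheme, assign_compartments
from morphoscore.errors import (
    AmbiguousRankingError,
    DegenerateCompartmentError,
    InsufficientDataError,
    InsufficientVariationError,
)

#: printed per-compartment formation-rate rows and their published score
#: vectors — the mandatory regression set for the assignment rule
REFERENCE_ROWS = {
    "t2": ((73.4, 77.0, 62.3, 24.3), (2, 2, 1, 0)),
    "t3": ((52.9, 77.6, 71.4, 40.9), (0, 2, 1, 0)),
    "t4": ((61.9, 69.2, 75.4, 29.7), (1, 1, 2, 0)),
    "t5": ((46.9, 63.6, 79.0, 62.9), (0, 1, 2, 1)),
    "cc2": ((39.1, 75.0, 85.0, 43.8), (0, 1, 2, 0)),
    "s2": ((60.3, 73.3, 50.0), (1, 2, 0)),
}


def _table(values, outcomes=None, param="t2"):
    n = len(values)
    df = pd.DataFrame({
        "embryo_id": [f"E{i}" for i in range(n)],
        "patient_id": ["P1"] * n,
        param: values,
        "blastocyst": outcomes if outcomes is not None else [np.nan] * n,
    })
    return MorphokineticTable(df)


class TestSchemeConstruction:
    def test_integer_grid_boundaries(self):
        scheme = build_compartment_scheme(_table(list(range(1, 9))), "t2")
        assert scheme.boundaries == (2.75, 4.5, 6.25)
        assert scheme.merged == ()
        assert scheme.effective_labels == ("C1", "C2", "C3", "C4")

    def test_quarter_of_values_at_minimum_merges_c1_c2(self):
        # s2-like: >25% of values equal the minimum, so Min = Q1 and the
        # first compartment would have zero width
        values = [0.0] * 3 + [0.5, 0.8, 1.0, 2.0, 4.0]
        scheme = build_compartment_scheme(_table(values, param="s2"), "s2")
        assert ("C1", "C2") in scheme.merged
        assert scheme.effective_labels == ("C1+C2", "C3", "C4")

    def test_constant_values_rejected(self):
        with pytest.raises(InsufficientVariationError):
            build_compartment_scheme(_table([3.0] * 10), "t2")

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            build_compartment_scheme(_table([1, 2, 3, 4, 5, 6, 7]), "t2")


class TestAssignment:
    scheme = CompartmentScheme("t2", (25.0, 30.0, 35.0))

    def test_below_q1(self):
        assert assign_compartment(20.0, self.scheme) == "C1"

    def test_left_closed_boundary(self):
        assert assign_compartment(25.0, self.scheme) == "C2"
        assert assign_compartment(30.0, self.scheme) == "C3"
        assert assign_compartment(35.0, self.scheme) == "C4"

    def test_below_fitting_minimum_still_c1(self):
        assert assign_compartment(0.1, self.scheme) == "C1"

    def test_merged_passthrough(self):
        merged = CompartmentScheme("s2", (0.0, 1.0, 3.0), (("C1", "C2"),))
        assert assign_compartment(1.0 - 1e-9, merged) == "C1+C2"
        assert assign_compartment(1.0, merged) == "C3"

    @given(st.floats(min_value=-100, max_value=100, allow_nan=False))
    @settings(deadline=None, max_examples=200)
    def test_partition_every_value_in_exactly_one_compartment(self, x):
        label = assign_compartment(x, self.scheme)
        edges = [-np.inf, 25.0, 30.0, 35.0, np.inf]
        hits = [
            lab for lab, lo, hi in zip(("C1", "C2", "C3", "C4"), edges[:-1], edges[1:])
            if lo <= x < hi or (lab == "C4" and x >= 35.0)
        ]
        assert [label] == hits[:1] and len(hits) >= 1

    def test_membership_counts_sum_to_n(self, rng):
        v = rng.normal(30, 5, size=500)
        comp = assign_compartments(v, self.scheme)
        counts = {lab: int((comp == lab).sum()) for lab in self.scheme.effective_labels}
        assert sum(counts.values()) == 500


class TestRates:
    def test_rate_arithmetic(self):
        # 10 developed of 55 in one compartment -> 0.1818...
        values = [1.0] * 55 + [2.0] * 55 + [3.0] * 55 + [4.0] * 55
        outcomes = ([1.0] * 10 + [0.0] * 45) * 4
        t = _table(values, outcomes)
        scheme = build_compartment_scheme(t, "t2")
        cr = compartment_rates(t, scheme)
        assert cr.rates[0] == pytest.approx(10 / 55, abs=1e-15)

    def test_all_developed_compartment(self):
        values = [1.0] * 10 + [2.0] * 10 + [3.0] * 10 + [4.0] * 10
        outcomes = [1.0] * 10 + [0.0] * 30
        t = _table(values, outcomes)
        cr = compartment_rates(t, build_compartment_scheme(t, "t2"))
        assert cr.rates[0] == 1.0

    def test_empty_compartment_raises(self):
        scheme = CompartmentScheme("t2", (100.0, 200.0, 300.0))
        t = _table([1.0, 2.0, 3.0, 4.0], [1.0, 0.0, 1.0, 0.0])
        with pytest.raises(DegenerateCompartmentError, match="merge"):
            compartment_rates(t, scheme)


class TestScoreAssignment:
    @pytest.mark.parametrize("param", list(REFERENCE_ROWS))
    def test_reference_rows_reproduced(self, param):
        """The nearest-pair rule (middle pair excluded) reproduces every
        published score vector from its printed rate row."""
        rates, expected = REFERENCE_ROWS[param]
        smap = assign_individual_scores(rates, parameter=param)
        assert smap.scores == expected

    def test_middle_pair_exclusion_forces_outer_pair(self):
        # the globally nearest pair (77.6, 71.4) is C2/C3 and must be
        # skipped; (52.9, 40.9) pairs instead
        smap = assign_individual_scores((52.9, 77.6, 71.4, 40.9))
        assert smap.paired == ("C1", "C4")

    def test_exactly_two_share_a_score_with_four_compartments(self, rng):
        for _ in range(50):
            rates = tuple(np.round(rng.uniform(0, 1, 4), 3))
            if len(set(rates)) < 3:
                continue
            try:
                smap = assign_individual_scores(rates)
            except AmbiguousRankingError:
                continue
            counts = sorted(np.bincount(smap.scores, minlength=3))
            assert counts == [1, 1, 2]
            # rate ordering of levels matches score ordering
            by_score = {}
            for r, s in zip(smap.rates, smap.scores):
                by_score.setdefault(s, []).append(r)
            means = {s: np.mean(v) for s, v in by_score.items()}
            assert means[2] >= means[1] >= means[0]

    def test_extreme_rates_get_extreme_scores(self):
        smap = assign_individual_scores((10.0, 50.0, 80.0, 40.0))
        rates, scores = smap.rates, smap.scores
        assert scores[int(np.argmax(rates))] == 2
        assert scores[int(np.argmin(rates))] == 0

    def test_three_way_tie_rejected(self):
        with pytest.raises(AmbiguousRankingError):
            assign_individual_scores((50.0, 50.0, 50.0, 20.0))

    def test_equal_difference_tiebreak_prefers_lower_indexed_pair(self):
        # |C1-C2| == |C3-C4| == 10: the pair containing C1 wins
        smap = assign_individual_scores((40.0, 50.0, 80.0, 70.0))
        assert smap.paired == ("C1", "C2")

    def test_structural_merge_ranks_directly(self):
        smap = assign_individual_scores((60.3, 73.3, 50.0),
                                        labels=("C1+C2", "C3", "C4"))
        assert smap.scores == (1, 2, 0)
        assert smap.paired is None


class TestScoreEmbryos:
    def test_matches_brute_force_rescoring(self, cohort_2000, fit_2000):
        """Vectorised scoring equals a per-record if-chain oracle."""
        schemes = {p.removeprefix("s_"): fit_2000.model.schemes[p]
                   for p in fit_2000.model.parameters}
        maps = {p.removeprefix("s_"): fit_2000.model.score_maps[p]
                for p in fit_2000.model.parameters}
        sub = cohort_2000.frame.head(100)
        scored = score_embryos(
            MorphokineticTable(sub),
            {p: (schemes[p], maps[p]) for p in schemes},
        )
        for p, scheme in schemes.items():
            edges = list(scheme.effective_edges)
            labels = scheme.effective_labels
            for i, row in scored.iterrows():
                v = row[p]
                if np.isnan(v):
                    assert np.isnan(row[f"s_{p}"])
                    continue
                k = 0
                while k < len(edges) and v >= edges[k]:
                    k += 1
                assert row[f"s_{p}"] == maps[p].score_of[labels[k]]

    def test_missing_parameter_gives_missing_score(self, fit_2000):
        df = pd.DataFrame({
            "embryo_id": ["E1"], "patient_id": ["P1"],
            "t2": [26.0], "blastocyst": [np.nan],
        })
        p0 = fit_2000.model.parameters[0]  # e.g. "s_t2"
        bare = p0.removeprefix("s_")
        scored = score_embryos(
            MorphokineticTable(df.drop(columns=[]).assign(**{bare: [np.nan]})),
            {bare: (fit_2000.model.schemes[p0], fit_2000.model.score_maps[p0])},
        )
        assert np.isnan(scored[p0].iloc[0])
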