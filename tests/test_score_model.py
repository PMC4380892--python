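import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from morphoscore import (
    BlastFormationModel,
    chi_square_independence,
    compute_sc,
    deserialize_model,
    mann_whitney_u,
    sc_quartile_report,
    serialize_model,
)
from morphoscore.compartments import CompartmentScheme, ScoreMap
from morphoscore.errors import (
    DegenerateQuarterError,
    DegenerateTableError,
    IncompleteRecordError,
    ModelValidationError,
    SchemaVersionError,
)
from morphoscore.score_model import quartile_report_from_counts

#: published multivariate odds ratios for (s_t2, s_t5, s_cc2)
REFERENCE_WEIGHTS = {"s_t2": 2.929, "s_t5": 2.331, "s_cc2": 2.356}


def _toy_model(weights=None, cutoff=None):
    weights = dict(weights or REFERENCE_WEIGHTS)
    schemes, maps = {}, {}
    for i, p in enumerate(weights):
        schemes[p] = CompartmentScheme(p.removeprefix("s_"),
                                       (10.0 + i, 20.0 + i, 30.0 + i))
        maps[p] = ScoreMap(p.removeprefix("s_"), ("C1", "C2", "C3", "C4"),
                           (0.5, 0.7, 0.6, 0.2), (1, 2, 1, 0), ("C1", "C3"))
    return BlastFormationModel(
        parameters=tuple(weights), weights=weights, schemes=schemes,
        score_maps=maps, sc_quartiles=(4.0, 7.0, 10.0), cutoff=cutoff,
        fit_metadata={"n_fit": 0, "seed": 0},
    )


class TestComputeSc:
    model = _toy_model()

    def test_zero_vector(self):
        assert compute_sc(self.model, {p: 0 for p in REFERENCE_WEIGHTS}) == 0.0

    def test_max_vector_hand_arithmetic(self):
        # 2*(2.929 + 2.331 + 2.356) = 15.232
        sc = compute_sc(self.model, {p: 2 for p in REFERENCE_WEIGHTS})
        assert sc == pytest.approx(15.232, abs=1e-12)
        assert sc == pytest.approx(self.model.max_sc, abs=1e-12)

    def test_single_score_hand_arithmetic(self):
        sc = compute_sc(self.model, {"s_t2": 0, "s_t5": 2, "s_cc2": 0})
        assert sc == pytest.approx(4.662, abs=1e-12)

    def test_missing_score_names_parameter(self):
        with pytest.raises(IncompleteRecordError, match="s_t5"):
            compute_sc(self.model, {"s_t2": 1, "s_cc2": 2})
        with pytest.raises(IncompleteRecordError, match="s_cc2"):
            compute_sc(self.model, {"s_t2": 1, "s_t5": 2, "s_cc2": float("nan")})

    @given(
        s=st.tuples(*[st.floats(0, 2) for _ in range(3)]),
        r=st.tuples(*[st.floats(0, 2) for _ in range(3)]),
        a=st.floats(0, 3), b=st.floats(0, 3),
    )
    @settings(deadline=None, max_examples=100)
    def test_linearity(self, s, r, a, b):
        names = list(REFERENCE_WEIGHTS)
        combo = {p: a * x + b * y for p, x, y in zip(names, s, r)}
        left = compute_sc(self.model, combo)
        right = (a * compute_sc(self.model, dict(zip(names, s)))
                 + b * compute_sc(self.model, dict(zip(names, r))))
        assert left == pytest.approx(right, abs=1e-9)


class TestChiSquare:
    def test_balanced_table_is_null(self):
        stat, df, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0 and df == 1

    def test_perfectly_dependent_2x2(self):
        stat, df, p = chi_square_independence([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0, abs=1e-12)
        assert df == 1

    def test_reference_quartile_counts_strongly_significant(self):
        dev = [10, 35, 47, 59]
        tot = [55, 52, 63, 66]
        table = [dev, [t - d for t, d in zip(tot, dev)]]
        stat, df, p = chi_square_independence(table)
        assert df == 3
        assert p < 1e-10

    def test_zero_column_rejected(self):
        with pytest.raises(DegenerateTableError):
            chi_square_independence([[5, 0], [3, 0]])


class TestMannWhitney:
    def test_exact_enumeration_small_sample(self):
        u, z, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples(self):
        u, z, p = mann_whitney_u([5.0, 5.0, 5.0], [5.0, 5.0])
        assert z == 0.0 and p == 1.0

    def test_exact_matches_scipy_exact(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(0.5, size=6)
        u, _, p = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_matches_scipy(self, rng):
        a = np.round(rng.normal(5, 2, size=40), 1)  # rounding creates ties
        b = np.round(rng.normal(6, 2, size=35), 1)
        u, z, p = mann_whitney_u(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_location_shift_like_reference_groups(self, rng):
        """Sc-like groups with medians near 9.95 vs 4.66 separate at p<0.001."""
        dev = rng.normal(9.95, 3.0, size=150)
        nodev = rng.normal(4.66, 3.0, size=85)
        _, _, p = mann_whitney_u(dev, nodev)
        assert p < 0.001


class TestScQuartileReport:
    def test_reference_counts_print_reference_rates(self):
        rep = quartile_report_from_counts([55, 52, 63, 66], [10, 35, 47, 59])
        assert rep.rates_pct == (18.2, 67.3, 74.6, 89.4)
        assert rep.p_value < 0.001

    def test_internal_consistency(self, fit_2000):
        rep = fit_2000.sc_report
        assert sum(rep.n) == len(fit_2000.scored_frame)
        for rate, d, t in zip(rep.rates, rep.developed, rep.n):
            assert rate == pytest.approx(d / t, abs=1e-15)

    def test_balanced_rates_give_null_chi2(self):
        sc = np.repeat([1.0, 2.0, 3.0, 4.0], 10)
        y = np.tile([1.0, 0.0], 20)
        rep = sc_quartile_report(sc, y)
        assert rep.chi2 == pytest.approx(0.0, abs=1e-12)
        assert rep.p_value == pytest.approx(1.0, abs=1e-12)

    def test_massive_ties_degenerate_quarter(self):
        sc = np.full(20, 3.0)
        y = np.tile([1.0, 0.0], 10)
        with pytest.raises(DegenerateQuarterError):
            sc_quartile_report(sc, y)

    def test_boundaries_are_type7_quartiles(self, fit_2000):
        sc = fit_2000.scored_frame["Sc"].to_numpy()
        assert fit_2000.sc_report.boundaries == tuple(
            np.quantile(sc, [0.25, 0.5, 0.75])
        )


class TestSerialization:
    def test_round_trip_bytes_and_sc(self, rng):
        model = _toy_model(cutoff=7.018)
        doc = serialize_model(model)
        back = deserialize_model(doc)
        assert serialize_model(back) == doc
        for _ in range(100):
            scores = {p: float(rng.integers(0, 3)) for p in model.parameters}
            assert compute_sc(model, scores) == compute_sc(back, scores)

    def test_missing_score_map_names_parameter(self):
        doc = json.loads(serialize_model(_toy_model()))
        del doc["score_maps"]["s_t5"]
        with pytest.raises(ModelValidationError, match="s_t5"):
            deserialize_model(json.dumps(doc))

    def test_unknown_schema_rejected(self):
        doc = json.loads(serialize_model(_toy_model()))
        doc["schema"] = "morphoscore-model-v999"
        with pytest.raises(SchemaVersionError):
            deserialize_model(json.dumps(doc))

    def test_hand_written_document_scores_correctly(self):
        """A document with the published weights gives Sc(1,2,2) = 12.303."""
        model = deserialize_model(serialize_model(_toy_model()))
        sc = compute_sc(model, {"s_t2": 1, "s_t5": 2, "s_cc2": 2})
        assert sc == pytest.approx(12.303, abs=1e-12)

    def test_corrupted_json_rejected(self):
        with pytest.raises(ModelValidationError):
            deserialize_model("{not json")
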