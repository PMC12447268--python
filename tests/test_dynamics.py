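"""Trajectories, the exact expansion test, kinetic/longevity classes,
and compartment sharing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, binomtest

from clonaltrack import (Clonotype, Timepoint, bh_adjust,
                         binomial_expansion_test, build_trajectories,
                         classify_kinetics, classify_longevity, shared_clones,
                         run_expansion_tests)
from clonaltrack.dynamics import (ClonotypeTrajectory, UntestableBaselineError,
                                  two_sided_binomial_p)

from conftest import make_sample


def enumeration_p(k, n, p0):
    """Independent oracle: full pmf summation over all outcomes."""
    pmf = binom.pmf(np.arange(n + 1), n, p0)
    return float(pmf[pmf <= pmf[k] * (1 + 1e-7)].sum())


class TestBinomialTest:
    def test_null_expectation_gives_p_near_one(self):
        assert binomial_expansion_test(10, 1000, 10, 1000) > 0.99

    def test_large_expansion_is_tiny(self):
        assert binomial_expansion_test(1, 1000, 30, 1000) < 1e-6

    def test_modal_outcome_is_one(self):
        assert binomial_expansion_test(5, 100, 5, 100) == pytest.approx(1.0, abs=1e-12)

    def test_untestable_baseline_refused(self):
        with pytest.raises(UntestableBaselineError):
            binomial_expansion_test(0, 1000, 5, 1000)

    @pytest.mark.parametrize("n2", [1, 2, 5, 10, 17, 33, 50])
    @pytest.mark.parametrize("p0", [0.001, 0.02, 0.3, 0.5, 0.77])
    def test_matches_enumeration_for_all_k(self, n2, p0):
        for k2 in range(n2 + 1):
            ours = two_sided_binomial_p(k2, n2, p0)
            assert ours == pytest.approx(enumeration_p(k2, n2, p0), abs=1e-12)

    @given(st.integers(0, 200), st.integers(1, 200),
           st.floats(1e-4, 1 - 1e-4))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_scipy_binomtest(self, k, n, p0):
        k = min(k, n)
        ours = two_sided_binomial_p(k, n, p0)
        ref = binomtest(k, n, p0).pvalue
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_pooled_null_mode(self):
        p = binomial_expansion_test(10, 1000, 50, 1000, test_mode="pooled_null")
        assert p == pytest.approx(enumeration_p(50, 1000, 60 / 2000), abs=1e-12)


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_and_constant_inputs(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([0.4, 0.4, 0.4]), [0.4] * 3)

    def test_q_at_least_p_and_order_preserved(self, rng):
        p = rng.uniform(size=30)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=25))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_permutation_equivariance(self, pvals):
        p = np.asarray(pvals)
        perm = np.random.RandomState(0).permutation(len(p))
        q = bh_adjust(p)
        q_perm = bh_adjust(p[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestTrajectories:
    def series(self):
        return [
            make_sample({"CASSA": 3, "CASSP": 5}, timepoint="pre"),
            make_sample({"CASSP": 2, "CASSC": 4}, timepoint="d14"),
        ]

    def test_union_with_zero_fill(self):
        trajs = {t.clonotype.aa_cdr3b: t for t in build_trajectories(self.series())}
        a = trajs["CASSA"]
        assert a.counts[Timepoint.PRE] == 3
        assert a.counts[Timepoint.D14] == 0
        assert a.totals[Timepoint.D14] == 6  # absent clone gets sample depth

    def test_counts_conserved_per_timepoint(self, rng):
        counts1 = {f"CASS{c}": int(k) for c, k in zip("ADEFG", rng.integers(1, 30, 5))}
        counts2 = {f"CASS{c}": int(k) for c, k in zip("FGHIK", rng.integers(1, 30, 5))}
        samples = [make_sample(counts1, timepoint="pre"),
                   make_sample(counts2, timepoint="d42")]
        trajs = build_trajectories(samples)
        for tp, expected in ((Timepoint.PRE, sum(counts1.values())),
                             (Timepoint.D42, sum(counts2.values()))):
            assert sum(t.counts[tp] for t in trajs) == expected

    def test_duplicate_timepoint_rejected(self):
        samples = [make_sample({"CASSA": 1}, timepoint="pre"),
                   make_sample({"CASSP": 1}, timepoint="pre")]
        with pytest.raises(ValueError):
            build_trajectories(samples)

    def test_mixed_compartment_rejected(self):
        samples = [make_sample({"CASSA": 1}, timepoint="pre"),
                   make_sample({"CASSP": 1}, timepoint="d14", compartment="PB")]
        with pytest.raises(ValueError):
            build_trajectories(samples)


def make_traj(counts_by_tp, totals=1000):
    tps = [Timepoint.parse(tp) for tp in counts_by_tp]
    return ClonotypeTrajectory(
        clonotype=Clonotype("CASSA"), compartment="BM", timepoints=tps,
        counts={Timepoint.parse(tp): k for tp, k in counts_by_tp.items()},
        totals={Timepoint.parse(tp): totals for tp in counts_by_tp})


class TestKineticClassification:
    def test_new_transient_and_stable(self):
        t = make_traj({"pre": 0, "d14": 10, "d42": 0})
        assert classify_kinetics(t) == "New_transient"
        t = make_traj({"pre": 0, "d14": 10, "d42": 8})
        assert classify_kinetics(t) == "New_stable"

    def test_undetected_within_window(self):
        t = make_traj({"pre": 0, "d14": 0, "d42": 0})
        assert classify_kinetics(t) == "Undetected"

    def test_significant_increase_is_inc(self):
        t = make_traj({"pre": 1, "d14": 10, "d42": 1})
        # q from the baseline-null oracle with a single test (BH with m=1)
        t.q_values = {Timepoint.D14: enumeration_p(10, 1000, 1 / 1000)}
        assert t.q_values[Timepoint.D14] < 0.05
        assert classify_kinetics(t) == "Inc"

    def test_nonsignificant_is_unchanged(self):
        t = make_traj({"pre": 10, "d14": 11, "d42": 9})
        t.q_values = {Timepoint.D14: 0.9, Timepoint.D42: 0.8}
        assert classify_kinetics(t) == "Unchanged"

    def test_frequency_only_mode(self):
        t = make_traj({"pre": 10, "d14": 30, "d42": 9})
        assert classify_kinetics(t, classification_mode="frequency_only") == "Inc"
        t = make_traj({"pre": 10, "d14": 2, "d42": 9})
        assert classify_kinetics(t, classification_mode="frequency_only") == "Dec"

    def test_missing_required_timepoint_rejected(self):
        t = make_traj({"pre": 1, "d14": 5})
        with pytest.raises(ValueError):
            classify_kinetics(t)

    def test_classes_partition_universe(self):
        samples = [
            make_sample({"CASSA": 50, "CASSP": 10, "CASSC": 40}, timepoint="pre"),
            make_sample({"CASSA": 250, "CASSP": 10, "CASSD": 30}, timepoint="d14"),
            make_sample({"CASSA": 250, "CASSP": 12, "CASSD": 25}, timepoint="d42"),
        ]
        trajs = build_trajectories(samples)
        run_expansion_tests(trajs)
        classes = [classify_kinetics(t) for t in trajs]
        assert all(c in ("Inc", "Dec", "New_transient", "New_stable",
                         "Unchanged", "Undetected") for c in classes)
        assert len(classes) == 4  # one class per clone in the universe


class TestLongevity:
    def test_three_bands(self):
        spans = {"pre": 5, "d14": 5, "d42": 5, "m6": 5, "m12": 5}
        assert classify_longevity(make_traj(spans)) == "long_lived"
        t = make_traj({"pre": 0, "d14": 5, "d42": 0, "m6": 0, "m12": 0})
        assert classify_longevity(t) == "transient"
        t = make_traj({"pre": 5, "d14": 5, "d42": 5, "m6": 0, "m12": 0})
        assert classify_longevity(t) == "medium_lived"

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            classify_longevity(make_traj({"pre": 5, "d14": 5, "d42": 5}))

    def test_never_detected_rejected(self):
        t = make_traj({"pre": 0, "d14": 0, "d42": 0, "m6": 0})
        with pytest.raises(ValueError):
            classify_longevity(t)


class TestSharedClones:
    def test_venn_counts(self):
        bm = [make_sample({"CASSA": 1, "CASSP": 2, "CASSC": 3}, timepoint="pre")]
        pb = [make_sample({"CASSP": 1, "CASSC": 1, "CASSD": 1}, timepoint="pre",
                          compartment="PB", platform="bulk")]
        report = shared_clones(bm, pb)
        assert report.venn_counts() == {"bm_only": 1, "pb_only": 1, "shared": 2}
        assert report.bm_only + report.shared == 3  # |BM set|

    def test_cumulative_bm_frequency(self):
        bm = [make_sample({"CASSP": 20, "CASSC": 30, "CASSW": 50},
                          timepoint="d14")]
        pb = [make_sample({"CASSP": 5, "CASSC": 5}, timepoint="d14",
                          compartment="PB", platform="bulk")]
        report = shared_clones(bm, pb)
        assert report.cumulative_bm_frequency["d14"] == pytest.approx(0.5)

    def test_disjoint_sets(self):
        bm = [make_sample({"CASSA": 1}, timepoint="pre")]
        pb = [make_sample({"CASSP": 1}, timepoint="pre", compartment="PB",
                          platform="bulk")]
        report = shared_clones(bm, pb)
        assert report.shared == 0
        assert report.cumulative_bm_frequency["pre"] == 0.0

    def test_patient_mismatch_rejected(self):
        bm = [make_sample({"CASSA": 1}, timepoint="pre", patient="P1")]
        pb = [make_sample({"CASSA": 1}, timepoint="pre", patient="P2",
                          compartment="PB", platform="bulk")]
        with pytest.raises(ValueError):
            shared_clones(bm, pb)


def test_clone_group_expression_means(small_params):
    from clonaltrack import clone_group_expression, normalize_log1p
    from clonaltrack.simulate import generate_clone_linked_expression, generate_repertoire

    _, truth = generate_repertoire(small_params)
    adata, cell_to_clone = generate_clone_linked_expression(small_params, truth)
    normalize_log1p(adata)
    groups = {
        cls: [Clonotype(aa) for aa in truth.loc[truth.kinetic_class == cls,
                                                "aa_cdr3b"]]
        for cls in ("Inc", "Dec", "New_stable")}
    table = clone_group_expression(groups, adata, cell_to_clone,
                                   ["GZMB", "PRF1", "NKG7", "NOT_A_GENE"])
    assert "NOT_A_GENE" not in table.columns  # missing gene skipped
    d14 = table[table.timepoint == "d14"].set_index("group")
    # planted reinvigoration: Inc clones upregulate cytotoxic genes at d14
    assert d14.loc["Inc", "GZMB"] > d14.loc["Dec", "GZMB"]
    # new clones have no pre-treatment cells -> absent, not zero
    assert not ((table.group == "New_stable") & (table.timepoint == "pre")).any()
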