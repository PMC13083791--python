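from itertools import product

import numpy as np
import pytest

from chromodyn import (
    DEFAULT_AXIS,
    GenomicInterval,
    ModuleLabel,
    PeakSet,
    SampleKey,
    StateMatrix,
    TimeAxis,
    UnionIntervalSet,
    assign_timing,
    call_state_matrix,
    classify_all,
    classify_condition,
    classify_endpoint,
    count_modules,
    module_venn,
    shared_excluding,
)
from chromodyn.dynamics import module_columns
from chromodyn.errors import ConfigurationError, UsageError

from _oracles import oracle_classify


def make_union(n):
    return UnionIntervalSet(
        tuple(GenomicInterval("chr1", i * 1000, i * 1000 + 500) for i in range(n)),
        n_sources=1,
    )


def matrix_from_patterns(patterns, conditions=("condA",)):
    """StateMatrix whose every condition follows the same 6-state patterns."""
    n = len(patterns)
    samples = [SampleKey("reference", "MEF")]
    for cond in conditions:
        samples += [SampleKey(cond, tp) for tp in ("D0", "D3", "D5", "D7")]
    samples.append(SampleKey("reference", "ESC"))
    states = np.zeros((n, len(samples)), dtype=bool)
    for i, pat in enumerate(patterns):
        states[i, 0] = pat[0]
        states[i, -1] = pat[5]
        for c in range(len(conditions)):
            states[i, 1 + 4 * c : 5 + 4 * c] = pat[1:5]
    return StateMatrix(
        union=make_union(n), samples=tuple(samples), states=states
    )


class TestTimeAxis:
    def test_default_axis(self):
        assert DEFAULT_AXIS.intermediates == ("D0", "D3", "D5", "D7")
        assert DEFAULT_AXIS.n_submodules == 5

    def test_anchor_validation(self):
        with pytest.raises(ConfigurationError):
            TimeAxis(("D0", "D3"), "MEF", "ESC")
        with pytest.raises(ConfigurationError):
            TimeAxis(("MEF", "D0", "ESC"), "MEF", "MEF")
        with pytest.raises(ConfigurationError):
            TimeAxis(("D0", "MEF", "ESC"))  # start anchor must come first

    def test_custom_axis_adapts_k(self):
        axis = TimeAxis(("start", "t1", "t2", "end"), "start", "end")
        assert axis.n_submodules == 3


class TestClassifyEndpoint:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(True, True, "PO"), (True, False, "OC"), (False, True, "CO"),
         (False, False, "NE")],
    )
    def test_truth_table(self, start, end, expected):
        assert classify_endpoint(start, end) == expected


class TestAssignTiming:
    def test_co_opens_immediately(self):
        assert assign_timing((1, 1, 1, 1, 1), True) == 1

    def test_co_opens_at_second_timepoint(self):
        assert assign_timing((0, 1, 1, 1, 1), True) == 2

    def test_flicker_breaks_maintenance(self):
        # open at D0, dips closed at D3: maintained suffix starts at D5
        assert assign_timing((1, 0, 1, 1, 1), True) == 3

    def test_oc_closes_at_second_timepoint(self):
        assert assign_timing((1, 0, 0, 0, 0), False) == 2

    def test_endpoint_mismatch_is_error(self):
        with pytest.raises(ValueError):
            assign_timing((1, 1, 1, 1, 0), True)

    def test_empty_trajectory_is_error(self):
        with pytest.raises(UsageError):
            assign_timing((), True)

    def test_monotonicity(self):
        # flipping any intermediate to the endpoint state never raises the index
        for pat in product([False, True], repeat=4):
            traj = list(pat) + [True]
            base = assign_timing(traj, True)
            for i in range(4):
                bumped = list(traj)
                bumped[i] = True
                assert assign_timing(bumped, True) <= base


class TestClassifierOracle:
    def test_all_64_patterns(self):
        patterns = list(product([False, True], repeat=6))
        matrix = matrix_from_patterns(patterns)
        codes = classify_condition(matrix, "condA").codes()
        for pat, code in zip(patterns, codes):
            assert code == oracle_classify(pat), pat

    def test_submodule_multiplicities(self):
        oc = [
            oracle_classify((True, *mid, False))
            for mid in product([False, True], repeat=4)
        ]
        co = [
            oracle_classify((False, *mid, True))
            for mid in product([False, True], repeat=4)
        ]
        assert [oc.count(f"OC{i}") for i in range(1, 6)] == [1, 1, 2, 4, 8]
        assert [co.count(f"CO{i}") for i in range(1, 6)] == [1, 1, 2, 4, 8]


class TestCallStateMatrix:
    def peak_sets(self):
        union_iv = GenomicInterval("chr1", 0, 200)
        sets = [
            PeakSet((GenomicInterval("chr1", 150, 400),), SampleKey("reference", "MEF")),
            PeakSet((GenomicInterval("chr1", 150, 400),), SampleKey("condA", "D0")),
            PeakSet((), SampleKey("condA", "D3")),
            PeakSet((GenomicInterval("chr2", 0, 100),), SampleKey("condA", "D5")),
            PeakSet((GenomicInterval("chr1", 0, 10),), SampleKey("condA", "D7")),
            PeakSet((), SampleKey("reference", "ESC")),
        ]
        return UnionIntervalSet((union_iv,), 6), sets

    def test_overlap_means_open(self):
        union, sets = self.peak_sets()
        m = call_state_matrix(union, sets)
        assert m.column(SampleKey("condA", "D0"))[0]

    def test_no_overlap_means_closed(self):
        union, sets = self.peak_sets()
        m = call_state_matrix(union, sets)
        assert not m.column(SampleKey("condA", "D5"))[0]  # wrong chromosome

    def test_empty_sample_column_closed(self):
        union, sets = self.peak_sets()
        m = call_state_matrix(union, sets)
        assert not m.column(SampleKey("condA", "D3"))[0]

    def test_min_overlap_fraction(self):
        union, sets = self.peak_sets()
        # peak covers 50/200 bases of the union interval
        m = call_state_matrix(union, sets, min_overlap=0.5)
        assert not m.column(SampleKey("condA", "D0"))[0]
        m = call_state_matrix(union, sets, min_overlap=0.25)
        assert m.column(SampleKey("condA", "D0"))[0]

    def test_missing_anchor_is_error(self):
        union, sets = self.peak_sets()
        with pytest.raises(ConfigurationError, match="anchor"):
            call_state_matrix(union, [s for s in sets if s.sample.timepoint != "MEF"])

    def test_duplicate_sample_is_error(self):
        union, sets = self.peak_sets()
        with pytest.raises(ConfigurationError, match="duplicate"):
            call_state_matrix(union, sets + [sets[1]])


class TestClassifyCondition:
    def test_co1_all_open(self):
        m = matrix_from_patterns([(False, True, True, True, True, True)])
        assert classify_condition(m, "condA").codes()[0] == "CO1"

    def test_co5_endpoint_only(self):
        m = matrix_from_patterns([(False, False, False, False, False, True)])
        assert classify_condition(m, "condA").codes()[0] == "CO5"

    def test_po_ignores_trajectory(self):
        for mid in product([False, True], repeat=4):
            m = matrix_from_patterns([(True, *mid, True)])
            assert classify_condition(m, "condA").codes()[0] == "PO"

    def test_missing_condition_is_error(self):
        m = matrix_from_patterns([(True, True, True, True, True, True)])
        with pytest.raises(ConfigurationError):
            classify_condition(m, "nope")

    def test_require_detection_forces_ne(self):
        # open only at the other condition's timepoints: undetected in condB
        n = 1
        samples = [SampleKey("reference", "MEF")]
        samples += [SampleKey("condA", tp) for tp in ("D0", "D3", "D5", "D7")]
        samples += [SampleKey("condB", tp) for tp in ("D0", "D3", "D5", "D7")]
        samples.append(SampleKey("reference", "ESC"))
        states = np.zeros((n, len(samples)), dtype=bool)
        states[0, 1:5] = True  # condA transiently open; anchors closed
        m = StateMatrix(make_union(n), tuple(samples), states)
        assert classify_condition(m, "condB").codes()[0] == "NE"
        assert (
            classify_condition(m, "condB", require_detection=True).codes()[0] == "NE"
        )
        assert classify_condition(m, "condA", require_detection=True).codes()[0] == "NE"

    def test_anchor_invariance_without_detection_filter(self):
        # PO and NE depend only on shared anchors, so counts match across conditions
        rng = np.random.default_rng(5)
        patterns = [
            tuple(bool(b) for b in rng.integers(0, 2, 6)) for _ in range(200)
        ]
        m = matrix_from_patterns(patterns, conditions=("condA", "condB"))
        # give condB a different trajectory by rebuilding states
        states = m.states.copy()
        states[:, 5:9] = rng.integers(0, 2, (200, 4)).astype(bool)
        m = StateMatrix(m.union, m.samples, states)
        table = count_modules(
            [classify_condition(m, "condA"), classify_condition(m, "condB")]
        )
        assert table.loc["condA", "PO"] == table.loc["condB", "PO"]
        assert table.loc["condA", "NE"] == table.loc["condB", "NE"]

    def test_anchored_mode_copies_timing(self):
        patterns = [(False, False, True, True, True, True)]  # CO2 in condA
        m = matrix_from_patterns(patterns, conditions=("condA", "condB"))
        states = m.states.copy()
        states[0, 5:9] = [True, True, True, True]  # condB alone would be CO1
        m = StateMatrix(m.union, m.samples, states)
        anchored = classify_all(
            m, ("condA", "condB"), mode="anchored", anchor_condition="condA"
        )
        assert anchored["condB"].codes()[0] == "CO2"
        per_cond = classify_all(m, ("condA", "condB"))
        assert per_cond["condB"].codes()[0] == "CO1"


class TestCountModules:
    def test_single_class(self):
        m = matrix_from_patterns([(True, True, True, True, True, True)] * 10)
        table = count_modules([classify_condition(m, "condA")])
        assert table.loc["condA", "PO"] == 10
        assert table.loc["condA"].sum() == 10

    def test_exhaustive_oc_counts(self):
        patterns = [(True, *mid, False) for mid in product([False, True], repeat=4)]
        m = matrix_from_patterns(patterns)
        table = count_modules([classify_condition(m, "condA")])
        assert [table.loc["condA", f"OC{i}"] for i in range(1, 6)] == [1, 1, 2, 4, 8]
        assert table.loc["condA"].sum() == 16

    def test_row_sums_equal_union_size(self):
        rng = np.random.default_rng(11)
        patterns = [tuple(bool(b) for b in rng.integers(0, 2, 6)) for _ in range(77)]
        m = matrix_from_patterns(patterns, conditions=("a", "b"))
        table = count_modules(
            [classify_condition(m, "a"), classify_condition(m, "b")]
        )
        assert (table.sum(axis=1) == 77).all()
        assert list(table.columns) == module_columns(5)

    def test_mixed_unions_rejected(self):
        m1 = matrix_from_patterns([(True,) * 6])
        m2 = matrix_from_patterns([(True,) * 6, (True,) * 6])
        with pytest.raises(ValueError):
            count_modules(
                [classify_condition(m1, "condA"), classify_condition(m2, "condA")]
            )


class TestModuleVenn:
    def build(self):
        # three intervals: OC in both, OC in A only, PO (never counted)
        samples = [SampleKey("reference", "MEF")]
        samples += [SampleKey(c, tp) for c in ("A", "B")
                    for tp in ("D0", "D3", "D5", "D7")]
        samples.append(SampleKey("reference", "ESC"))
        states = np.zeros((3, len(samples)), dtype=bool)
        states[0, 0] = True               # OC everywhere (anchors open/closed)
        states[1, 0] = True
        states[2, 0] = states[2, -1] = True  # PO
        m = StateMatrix(make_union(3), tuple(samples), states)
        return {c: classify_condition(m, c) for c in ("A", "B")}

    def test_partition_cells(self):
        venn = module_venn(self.build(), classes=["OC"])
        both = venn[(venn["A"]) & (venn["B"])]["count"]
        assert both.sum() == 2  # anchor-driven classes agree across conditions
        assert venn["count"].sum() == 2

    def test_specific_cell(self):
        assignments = self.build()
        # force one interval out of B's OC set by relabeling
        labels = list(assignments["B"].labels)
        labels[1] = ModuleLabel("NE")
        from chromodyn.dynamics import ModuleAssignment

        assignments["B"] = ModuleAssignment(
            "B", assignments["B"].union, tuple(labels), 5
        )
        venn = module_venn(assignments, classes=["OC"])
        a_only = venn[(venn["A"]) & (~venn["B"])]["count"]
        assert a_only.sum() == 1
        assert venn["count"].sum() == 2

    def test_empty_classes_rejected(self):
        with pytest.raises(UsageError):
            module_venn(self.build(), classes=[])

    def test_needs_two_conditions(self):
        assignments = self.build()
        with pytest.raises(UsageError):
            module_venn(assignments, classes=["OC"], exclude=["A"])

    def test_shared_excluding(self):
        assignments = self.build()
        assert shared_excluding(assignments, ["OC"], exclude=["B"]) == 2
        assert shared_excluding(assignments, ["OC"], exclude=[]) == 2
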