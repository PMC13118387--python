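import numpy as np
import pytest

from biomeshare.profiles_io import CountTable, SubjectPair, build_pairs
from biomeshare.sharing import (
    SubjectSharingRecord,
    co_sharing_patterns,
    exclusive_taxa,
    presence_set,
    shared_taxa,
    shared_taxa_records,
    sharing_distribution,
    sharing_summary,
)
from biomeshare.synthetic import CohortParams, generate_cohort

from conftest import GS, PH, SM, SO

GROUP_SIZES = {"case": 20, "control": 20}


class TestPresenceSet:
    def test_default_threshold(self):
        assert presence_set([0, 0, 3], ["A", "B", "C"]) == {"C"}

    def test_threshold_five(self):
        assert presence_set([4, 5], ["A", "B"], threshold=5) == {"B"}

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ValueError):
            presence_set([1], ["A"], threshold=0)

    def test_synthetic_support_matches_generator(self, default_cohort):
        _, (table, _, truth) = default_cohort
        for sample_id, support in truth.saliva_support.items():
            col = table.column(sample_id)
            assert presence_set(col, table.taxa) == support


class TestSharedTaxa:
    def _pair_table(self, saliva_counts, biopsy_counts, taxa):
        table = CountTable(
            taxa, ["X-SAL", "X-BIO"],
            np.column_stack([saliva_counts, biopsy_counts]),
        )
        pair = SubjectPair("X", "case", "X-SAL", "X-BIO")
        return pair, table

    def test_zero_biopsy_gives_empty_set(self):
        pair, table = self._pair_table([5, 3], [0, 0], ["G a", "G b"])
        rec = shared_taxa(pair, table)
        assert rec.shared_taxa == frozenset() and rec.k == 0

    def test_equal_supports_share_everything(self):
        pair, table = self._pair_table([5, 0, 3], [1, 0, 9], ["G a", "G b", "G c"])
        assert shared_taxa(pair, table).shared_taxa == {"G a", "G c"}

    def test_published_four_taxon_combination(self):
        taxa = [GS, PH, SO, SM, "Other sp"]
        pair, table = self._pair_table([9, 4, 2, 7, 1], [1, 2, 3, 4, 0], taxa)
        rec = shared_taxa(pair, table)
        assert rec.k == 4
        assert rec.shared_taxa == {GS, PH, SO, SM}

    def test_threshold_monotone_shrinkage(self, default_cohort):
        _, (table, metadata, _) = default_cohort
        pairs = build_pairs(metadata, table)[:10]
        for pair in pairs:
            prev = None
            for thr in (1, 2, 5, 20):
                cur = shared_taxa(pair, table, thr).shared_taxa
                if prev is not None:
                    assert cur <= prev
                prev = cur


class TestSharingSummary:
    def test_published_counts(self, table4_records):
        rows = {r.taxon: r for r in sharing_summary(table4_records, GROUP_SIZES)}
        so = rows[SO]
        assert (so.shared_count_case, so.shared_pct_case) == (8, 40.0)
        assert (so.shared_count_control, so.shared_pct_control) == (2, 10.0)
        assert so.pct_diff == pytest.approx(30.0)
        assert so.rel_diff == pytest.approx(75.0)
        sm = rows[SM]
        assert (sm.shared_count_case, sm.shared_pct_case) == (10, 50.0)
        assert sm.rel_diff == pytest.approx(40.0)
        ph = rows[PH]
        assert (ph.shared_count_case, ph.shared_pct_case) == (5, 25.0)
        assert ph.rel_diff == pytest.approx(80.0)
        gs = rows[GS]
        assert (gs.shared_count_case, gs.shared_count_control) == (4, 0)
        assert gs.rel_diff is None and gs.flag == "only-case"

    def test_sorted_by_pct_diff_then_case_count(self, table4_records):
        rows = sharing_summary(table4_records, GROUP_SIZES)
        keys = [(-r.pct_diff, -r.shared_count_case, r.taxon) for r in rows]
        assert keys == sorted(keys)

    def test_counts_bounded_by_group_size(self, table4_records):
        for r in sharing_summary(table4_records, GROUP_SIZES):
            assert 0 <= r.shared_count_case <= 20
            assert 0 <= r.shared_count_control <= 20

    def test_cross_check_per_subject_scan(self, table4_records):
        # invariant: per-taxon counts from sharing_summary equal an
        # independent per-subject recount
        rows = sharing_summary(table4_records, GROUP_SIZES)
        for r in rows:
            ca = sum(1 for rec in table4_records
                     if rec.group == "case" and r.taxon in rec.shared_taxa)
            co = sum(1 for rec in table4_records
                     if rec.group == "control" and r.taxon in rec.shared_taxa)
            assert (r.shared_count_case, r.shared_count_control) == (ca, co)

    def test_zero_group_size_rejected(self, table4_records):
        with pytest.raises(ValueError):
            sharing_summary(table4_records, {"case": 20, "control": 0})


class TestSharingDistribution:
    def test_published_histogram(self, table4_records):
        hist = sharing_distribution(table4_records, "case")
        assert {k: v[0] for k, v in hist.items()} == {0: 7, 1: 5, 2: 4, 3: 2, 4: 2}
        assert hist[0][1] == pytest.approx(35.0)
        assert sum(v[0] for v in hist.values()) == 20

    def test_all_empty_records(self):
        recs = [SubjectSharingRecord(f"s{i}", "case", frozenset()) for i in range(5)]
        hist = sharing_distribution(recs, "case")
        assert hist == {0: (5, 100.0)}

    def test_total_equals_group_size(self, default_cohort):
        _, (table, metadata, _) = default_cohort
        records = shared_taxa_records(build_pairs(metadata, table), table)
        for group in ("case", "control"):
            hist = sharing_distribution(records, group)
            assert sum(v[0] for v in hist.values()) == 20

    def test_tables_consistency_identity(self, table4_records):
        # sum over k of k * n_k == sum over taxa of shared counts
        rows = sharing_summary(table4_records, GROUP_SIZES)
        for group, attr in (("case", "shared_count_case"),
                            ("control", "shared_count_control")):
            hist = sharing_distribution(table4_records, group)
            lhs = sum(k * n for k, (n, _) in hist.items())
            rhs = sum(getattr(r, attr) for r in rows)
            assert lhs == rhs
        # the published case-side identity: 7*0 + 5*1 + 4*2 + 2*3 + 2*4 = 27
        case_hist = sharing_distribution(table4_records, "case")
        assert sum(k * n for k, (n, _) in case_hist.items()) == 27


class TestExclusiveTaxa:
    def test_published_case_only_set(self, table4_records):
        rows = sharing_summary(table4_records, GROUP_SIZES)
        case_only, control_only = exclusive_taxa(rows)
        assert case_only == {GS}
        assert control_only == set()

    def test_everything_shared_in_both(self):
        recs = [
            SubjectSharingRecord("a", "case", frozenset({"G x"})),
            SubjectSharingRecord("b", "control", frozenset({"G x"})),
        ]
        rows = sharing_summary(recs, {"case": 1, "control": 1})
        assert exclusive_taxa(rows) == (set(), set())


class TestCoSharingPatterns:
    def test_published_never_alone_flag(self, table4_records):
        patterns = co_sharing_patterns(table4_records)
        never_alone, partners = patterns[GS]
        assert never_alone
        assert set(partners) <= {SO, SM, PH}

    def test_singleton_not_flagged(self, table4_records):
        assert patterns_not_alone(table4_records, SO) is False

    def test_empty_records(self):
        assert co_sharing_patterns([]) == {}


def patterns_not_alone(records, taxon):
    return co_sharing_patterns(records)[taxon][0]


class TestRecoveryOnSynthetic:
    def test_forced_translocation_yields_exclusive_set(self):
        params = CohortParams(seed=5, transloc_prob=1.0, pool_overlap=0)
        table, metadata, truth = generate_cohort(params)
        records = shared_taxa_records(build_pairs(metadata, table), table)
        rows = sharing_summary(records, {"case": 20, "control": 20})
        case_only, _ = exclusive_taxa(rows)
        assert set(truth.translocator_taxa) <= case_only

    def test_no_overlap_no_translocation_no_sharing(self):
        params = CohortParams(seed=6, transloc_prob=0.0, pool_overlap=0,
                              transloc_saliva_rel_abundance=0.0, translocators=0)
        table, metadata, _ = generate_cohort(params)
        records = shared_taxa_records(build_pairs(metadata, table), table)
        assert all(rec.k == 0 for rec in records)

    @pytest.mark.slow
    def test_exclusive_detection_mostly_recovers_translocators(self):
        hits, n_rep = 0, 20
        for seed in range(n_rep):
            params = CohortParams(seed=seed, transloc_prob=1.0, pool_overlap=0)
            table, metadata, truth = generate_cohort(params)
            records = shared_taxa_records(build_pairs(metadata, table), table)
            rows = sharing_summary(records, {"case": 20, "control": 20})
            case_only, _ = exclusive_taxa(rows)
            if set(truth.translocator_taxa) <= case_only:
                hits += 1
        assert hits >= 0.9 * n_rep
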