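"""Window coverage and greedy non-redundant selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrannot.annotation_io import HOMOLOGY, TRANSCRIPT, AnnotationSet, GeneModel
from nrannot import nonredundant_selector as sel
from nrannot import synthetic_fixtures as fx
from oracles import naive_select, naive_window_counts


def model(mid, exons, strand="+", seq="chr1", evidence=TRANSCRIPT, orf=None):
    return GeneModel(mid, seq, strand, tuple(exons), evidence,
                     orf_len_aa=-1 if orf is None else orf)


class TestBuildWindows:
    def test_boundary_window_assignment(self):
        """Exon boundaries 101,190 / 301,360 / 501,512 land in windows 1,3,5."""
        m = model("a", [(101, 190), (301, 360), (501, 512)])
        cov = sel.build_windows(AnnotationSet("g", [m]), window_size=100)
        assert cov.counts == {
            ("chr1", "+", 1): 2,
            ("chr1", "+", 3): 2,
            ("chr1", "+", 5): 2,
        }
        assert cov.total() == 6

    def test_start_and_end_in_same_window_count_twice(self):
        m3 = model("a", [(150, 160), (300, 350), (500, 520)])
        cov = sel.build_windows(AnnotationSet("g", [m3]), window_size=100)
        assert cov.counts[("chr1", "+", 1)] == 2

    def test_bruteforce_tally_on_random_models(self, merged_fixture):
        aset, _ = merged_fixture
        for ws in (100, 37):
            cov = sel.build_windows(aset, window_size=ws)
            assert cov.counts == naive_window_counts(aset, ws)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(1, 5000), st.integers(1, 200)),
            min_size=1, max_size=6, unique_by=lambda t: t[0],
        ),
        st.integers(1, 250),
    )
    def test_counts_sum_to_twice_exon_total(self, locus_seeds, window_size):
        """Property: total coverage == 2 x number of exons, any window size."""
        models, n_exons = [], 0
        for i, (start, gap) in enumerate(sorted(locus_seeds)):
            exons = [(start + k * (gap + 50), start + k * (gap + 50) + 30) for k in range(3)]
            models.append(model(f"m{i}", exons))
            n_exons += 3
        cov = sel.build_windows(AnnotationSet("g", models), window_size=window_size)
        assert cov.total() == 2 * n_exons


def eligible3(mid, lo, orf, strand="+", seq="chr1"):
    """A 3-exon model spanning [lo, lo + 3*orf + 199] with the given ORF."""
    size = orf  # aa per exon chunk: distribute 3*orf bp over 3 exons
    e1 = (lo, lo + size - 1)
    e2 = (lo + size + 99, lo + size + 99 + size - 1)
    e3 = (lo + 2 * size + 198, lo + 2 * size + 198 + size - 1)
    return model(mid, [e1, e2, e3], strand=strand, seq=seq)


class TestSelectExamples:
    def test_longest_orf_wins_at_overlapping_locus(self):
        a = eligible3("A", 1000, 300)  # 300 aa
        b = eligible3("B", 1050, 240)  # 240 aa, overlapping span
        res = sel.select_nonredundant(AnnotationSet("g", [a, b]))
        assert res.selected.model_ids == ["A"]
        assert res.discarded == [("B", sel.REASON_OVERLAP)]

    def test_lone_two_exon_model_fails_exon_filter(self):
        m2 = model("X", [(1000, 1299), (1400, 1699)])  # 2 exons, 200 aa
        res = sel.select_nonredundant(AnnotationSet("g", [m2]))
        assert len(res.selected) == 0
        assert res.discarded == [("X", sel.REASON_EXONS)]

    def test_lone_short_orf_model_fails_orf_filter(self):
        m = eligible3("S", 1000, 30)  # 30 aa < 60
        res = sel.select_nonredundant(AnnotationSet("g", [m]))
        assert res.discarded == [("S", sel.REASON_ORF)]

    def test_non_overlapping_models_both_selected(self):
        a = eligible3("A", 1000, 100)
        b = eligible3("B", 10000, 100)
        res = sel.select_nonredundant(AnnotationSet("g", [a, b]))
        assert res.selected.model_ids == ["A", "B"]
        assert res.discarded == []

    def test_strands_are_independent(self):
        """Identical coordinates on + and - never compete."""
        a = eligible3("X", 1000, 100, strand="+")
        b = eligible3("Y", 1000, 100, strand="-")
        res = sel.select_nonredundant(AnnotationSet("g", [a, b]))
        assert sorted(res.selected.model_ids) == ["X", "Y"]

    def test_empty_input_gives_empty_result(self):
        res = sel.select_nonredundant(AnnotationSet("g"))
        assert len(res.selected) == 0 and res.discarded == [] and res.audit == []

    def test_orf_tie_broken_by_gene_start_then_id(self):
        a = eligible3("B_later", 1000, 100)
        b = eligible3("A_earlier", 998, 100)  # same ORF, smaller start
        res = sel.select_nonredundant(AnnotationSet("g", [a, b]))
        assert res.selected.model_ids == ["A_earlier"]


class TestMergeEvidence:
    def test_union_counts_and_prefixing(self):
        hom = AnnotationSet("g", [eligible3(f"h{i}", 1000 + 5000 * i, 100) for i in range(10)])
        txn_models = []
        for i in range(15):
            m = eligible3(f"t{i}", 100000 + 5000 * i, 100)
            txn_models.append(GeneModel(m.model_id, m.seq_id, m.strand, m.exons, TRANSCRIPT))
        hom_models = [
            GeneModel(m.model_id, m.seq_id, m.strand, m.exons, HOMOLOGY) for m in hom
        ]
        merged = sel.merge_evidence(
            AnnotationSet("g", hom_models), AnnotationSet("g", txn_models)
        )
        assert len(merged) == 25
        assert all(m.model_id.split(":")[0] in (HOMOLOGY, TRANSCRIPT) for m in merged)

    def test_empty_homology_is_identity_up_to_prefix(self):
        txn = AnnotationSet("g", [eligible3("t0", 1000, 100)])
        merged = sel.merge_evidence(AnnotationSet("g"), txn, prefix=False)
        assert merged == txn

    def test_evidence_counts_survive_selection(self, merged_fixture):
        """Selected-by-evidence tally equals a brute-force count."""
        merged, manifest = merged_fixture
        res = sel.select_nonredundant(merged)
        want = {}
        for locus in manifest.loci:
            want[locus.winner_evidence] = want.get(locus.winner_evidence, 0) + 1
        assert res.counts_by_evidence() == want

    def test_duplicate_ids_after_prefixing_rejected(self):
        a = AnnotationSet("g", [eligible3("same", 1000, 100)])
        b = AnnotationSet("g", [eligible3("same", 9000, 100)])
        with pytest.raises(ValueError, match="duplicate"):
            sel.merge_evidence(a, a)
        # same raw id on both tracks with same evidence still collides
        with pytest.raises(ValueError, match="duplicate"):
            sel.merge_evidence(a, b)


class TestGroundTruthRecovery:
    def test_planted_winner_recovered_at_every_locus(self, merged_fixture):
        merged, manifest = merged_fixture
        res = sel.select_nonredundant(merged)
        assert sorted(res.selected.model_ids) == sorted(manifest.winner_ids)

    def test_tie_mode_resolved_by_documented_tiebreak(self):
        """Planted exact-ORF ties fall to the smaller-gene-start rule."""
        hom, txn, manifest = fx.gen_locus_set(60, seed=19, tie_mode=True)
        merged = sel.merge_evidence(hom, txn)
        res = sel.select_nonredundant(merged)
        assert sorted(res.selected.model_ids) == sorted(manifest.winner_ids)


class TestSelectionInvariants:
    @pytest.mark.parametrize("seed,tie_mode", [(101, False), (102, True), (103, False)])
    def test_partition_filters_and_disjointness(self, seed, tie_mode):
        hom, txn, _ = fx.gen_locus_set(80, seed=seed, tie_mode=tie_mode)
        merged = sel.merge_evidence(hom, txn)
        res = sel.select_nonredundant(merged)
        # partition
        assert sorted(res.selected.model_ids + res.discarded_ids) == sorted(merged.model_ids)
        # filter soundness
        for m in res.selected:
            assert m.n_exons >= 3 and m.orf_len_aa >= 60
        # pairwise exon disjointness per (seq, strand)
        chosen = list(res.selected)
        for i, a in enumerate(chosen):
            for b in chosen[i + 1 :]:
                if (a.seq_id, a.strand) != (b.seq_id, b.strand):
                    continue
                for s1, e1 in a.exons:
                    for s2, e2 in b.exons:
                        assert e1 < s2 or e2 < s1

    def test_idempotence_on_own_output(self):
        """Re-selecting the selected set changes nothing and discards nothing."""
        for seed in range(104, 114):
            hom, txn, _ = fx.gen_locus_set(30, seed=seed)
            res = sel.select_nonredundant(sel.merge_evidence(hom, txn))
            again = sel.select_nonredundant(res.selected)
            assert sorted(again.selected.model_ids) == sorted(res.selected.model_ids)
            assert again.discarded == []

    def test_determinism_of_audit_log(self, merged_fixture):
        merged, _ = merged_fixture
        r1 = sel.select_nonredundant(merged)
        r2 = sel.select_nonredundant(merged)
        assert r1.audit == r2.audit and r1.discarded == r2.discarded

    def test_monotonicity_of_orf_threshold_on_fixtures(self):
        """Lowering min_orf_aa never shrinks total selected ORF length."""
        hom, txn, _ = fx.gen_locus_set(60, seed=121)
        merged = sel.merge_evidence(hom, txn)
        totals = [
            sum(m.orf_len_aa for m in
                sel.select_nonredundant(merged, min_orf_aa=t).selected)
            for t in (120, 60, 0)
        ]
        assert totals == sorted(totals)


class TestOracleEquivalence:
    @pytest.mark.parametrize("scope", ["model", "window"])
    def test_matches_naive_reimplementation(self, scope):
        """Production selector == from-scratch linear-scan selector."""
        for seed in (7, 8, 9):
            hom, txn, _ = fx.gen_locus_set(120, seed=seed, tie_mode=(seed == 8))
            merged = sel.merge_evidence(hom, txn)
            res = sel.select_nonredundant(merged, discard_scope=scope)
            o_sel, o_disc, _ = naive_select(list(merged), discard_scope=scope)
            assert set(res.selected.model_ids) == o_sel
            assert dict(res.discarded) == o_disc

    def test_matches_naive_on_adversarial_dense_overlaps(self):
        """Random dense (non-fixture) model piles agree with the oracle."""
        rng = np.random.default_rng(55)
        models = []
        for i in range(150):
            seq = f"chr{rng.integers(1, 3)}"
            strand = "+" if rng.random() < 0.5 else "-"
            lo = int(rng.integers(1, 4000))
            n_ex = int(rng.integers(1, 5))
            exons, pos = [], lo
            for _ in range(n_ex):
                size = int(rng.integers(10, 200))
                exons.append((pos, pos + size - 1))
                pos += size + int(rng.integers(20, 150))
            models.append(
                GeneModel(f"r{i:03d}", seq, strand, tuple(exons),
                          TRANSCRIPT if rng.random() < 0.5 else HOMOLOGY)
            )
        aset = AnnotationSet("dense", models)
        res = sel.select_nonredundant(aset)
        o_sel, o_disc, _ = naive_select(models)
        assert set(res.selected.model_ids) == o_sel
        assert dict(res.discarded) == o_disc
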