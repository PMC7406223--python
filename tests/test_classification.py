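"""Clustering, consensus, zinc motif, NJ tree, and AS-group assignment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecfcoev.classification import (
    DistanceParams,
    assign_groups,
    bisect_cluster,
    build_nj_tree,
    consensus_sequence,
    distance_matrix,
    ktuple_distance,
    nj_tree_from_matrix,
    summarize_subgroup_annotations,
    zinc_motif_scan,
)
from ecfcoev.classification import Subgroup


def _oracle_ktuple(a, b, k):
    """Independent tuple-count oracle: explicit enumeration over distinct k-mers."""
    ta = [a[i : i + k] for i in range(len(a) - k + 1)]
    tb = [b[i : i + k] for i in range(len(b) - k + 1)]
    shared = sum(min(ta.count(t), tb.count(t)) for t in set(ta) | set(tb))
    return 1.0 - shared / (min(len(a), len(b)) - k + 1)


class TestKtupleDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("PEPTIDE", "PEPTIDE", 0.0), ("AAA", "CCC", 1.0), ("AAB", "ABB", 1 / 3)],
    )
    def test_hand_values(self, a, b, expected):
        assert ktuple_distance(a, b) == pytest.approx(expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ktuple_distance("A", "AC", DistanceParams(k=2))

    @given(
        st.text(alphabet="ACDG", min_size=2, max_size=30),
        st.text(alphabet="ACDG", min_size=2, max_size=30),
        st.integers(1, 2),
    )
    @settings(deadline=None, max_examples=300)
    def test_matches_brute_force_oracle(self, a, b, k):
        p = DistanceParams(k=k)
        d = ktuple_distance(a, b, p)
        assert d == pytest.approx(_oracle_ktuple(a, b, k))
        assert d == pytest.approx(ktuple_distance(b, a, p))
        assert 0.0 <= d <= 1.0
        assert ktuple_distance(a, a, p) == 0.0


def _blob(letter, n, length=30):
    """n near-identical sequences dominated by one letter."""
    base = letter * length
    return {f"{letter}{i}": base[:i] + "G" + base[i + 1 :] for i in range(n)}


class TestBisectCluster:
    def test_single_sequence_is_ungrouped(self):
        subs, ungrouped = bisect_cluster({"x": "ACDEF"})
        assert subs == [] and ungrouped == ["x"]

    def test_tight_set_stays_together(self):
        seqs = _blob("A", 5)
        subs, ungrouped = bisect_cluster(seqs)
        assert len(subs) == 1 and not ungrouped
        assert sorted(subs[0].member_ids) == sorted(seqs)

    def test_two_planted_blobs_recovered(self):
        seqs = {**_blob("A", 4), **_blob("C", 5)}
        subs, ungrouped = bisect_cluster(seqs)
        assert len(subs) == 2 and not ungrouped
        parts = {frozenset(s.member_ids) for s in subs}
        expected = {frozenset(_blob("A", 4)), frozenset(_blob("C", 5))}
        assert parts == expected
        # exhaustive check: no 2-cut has smaller max within-cluster diameter
        ids = list(seqs)
        D = distance_matrix([seqs[i] for i in ids])
        best = min(
            max(
                (D[np.ix_(side, side)].max() if len(side) > 1 else 0.0)
                for side in (list(cut), [i for i in range(len(ids)) if i not in cut])
            )
            for r in range(1, len(ids))
            for cut in itertools.combinations(range(len(ids)), r)
        )
        got = max(s.diameter for s in subs)
        assert got == pytest.approx(best)

    @given(st.lists(st.text(alphabet="ACDEFG", min_size=3, max_size=12), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=50)
    def test_partition_and_diameter_certificate(self, seqs):
        named = {f"s{i}": s for i, s in enumerate(seqs)}
        params = DistanceParams()
        subs, ungrouped = bisect_cluster(named, params)
        emitted = [m for s in subs for m in s.member_ids] + ungrouped
        assert sorted(emitted) == sorted(named)  # exact partition
        for s in subs:
            assert len(s.member_ids) >= 2
            d = max(
                ktuple_distance(named[a], named[b], params)
                for a, b in itertools.combinations(s.member_ids, 2)
            )
            assert d < params.diameter_threshold  # recomputed certificate
            assert d == pytest.approx(s.diameter)


class TestConsensus:
    def test_identical_rows(self):
        assert consensus_sequence(["ACDE", "ACDE"]) == "ACDE"

    def test_alphabetical_tie(self):
        assert consensus_sequence(["AC", "AG", "AT"]) == "AC"

    def test_gap_majority_column_dropped(self):
        assert consensus_sequence(["A-C", "A-C", "AGC"]) == "AC"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_sequence([])


class TestZincMotif:
    @pytest.mark.parametrize(
        "seq, expected",
        [("MHTEACWACK", True), ("MHTEACWADK", False), ("AG" * 500, False)],
    )
    def test_pattern(self, seq, expected):
        assert zinc_motif_scan(seq) is expected

    def test_window_restricts_start(self):
        seq = "MMMMHTEACWAC"
        assert zinc_motif_scan(seq, window=(1, 6))
        assert not zinc_motif_scan(seq, window=(1, 3))


class TestNJTree:
    def test_additive_four_taxon_matrix_reproduced(self):
        # tree ((a:1,b:2):1,(c:3,d:4)) -> additive distances
        ids = ["a", "b", "c", "d"]
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj_tree_from_matrix(D, ids)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    assert tree.find(a).distance(tree.find(b)) == pytest.approx(D[i, j])

    def test_three_taxon_closed_form(self):
        ids = ["a", "b", "c"]
        D = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree_from_matrix(D, ids)
        # three-point formulas: la = (dab + dac - dbc)/2 etc.
        la = (0.4 + 0.6 - 0.8) / 2
        lb = (0.4 + 0.8 - 0.6) / 2
        lc = (0.6 + 0.8 - 0.4) / 2
        for name, expected in zip(ids, (la, lb, lc)):
            tip = tree.find(name)
            assert tip.distance(tree.root()) == pytest.approx(expected)

    def test_outgroup_rooting_and_missing_outgroup(self):
        seqs = {
            "x": "AAAAAAAA",
            "y": "AAAAAACC",
            "z": "CCCCCCCC",
            "og": "WWWWYYYY",
        }
        tree = build_nj_tree(seqs, "og")
        children = tree.children
        assert any(c.name == "og" for c in children)  # rooted on the outgroup edge
        with pytest.raises(ValueError, match="outgroup"):
            build_nj_tree(seqs, "missing")


class TestAssignGroups:
    @staticmethod
    def _tree(newick):
        import io as _stdio

        from skbio import TreeNode

        return TreeNode.read(_stdio.StringIO(newick))

    def test_uniform_tree_is_one_group(self):
        tree = self._tree("((a,b),(c,d));")
        groups = assign_groups(tree, {l: "ECF02" for l in "abcd"})
        assert len(groups) == 1
        assert groups[0].group_name == "AS02"
        assert sorted(groups[0].subgroup_ids) == list("abcd")

    def test_split_clades_get_suffixes(self):
        tree = self._tree("((a,b),(c,(d,e)));")
        labels = {"a": "ECF19", "b": "ECF19", "c": "ECF27", "d": "ECF19", "e": "ECF19"}
        groups = {g.group_name: sorted(g.subgroup_ids) for g in assign_groups(tree, labels)}
        assert groups == {"AS19-1": ["a", "b"], "AS27": ["c"], "AS19-2": ["d", "e"]}

    def test_maximality(self):
        tree = self._tree("(((a,b),c),d);")
        labels = {"a": "ECF1", "b": "ECF1", "c": "ECF1", "d": "ECF2"}
        groups = assign_groups(tree, labels)
        by_name = {g.group_name: sorted(g.subgroup_ids) for g in groups}
        assert by_name == {"AS1": ["a", "b", "c"], "AS2": ["d"]}

    def test_unlabeled_leaf_rejected(self):
        tree = self._tree("((a,b),c);")
        with pytest.raises(ValueError, match="unlabeled"):
            assign_groups(tree, {"a": "ECF1", "b": "ECF1"})


class TestAnnotations:
    def test_tmh_mode_and_domain_majority_and_zinc(self):
        sg = Subgroup("SG0001", ["a", "b", "c", "d"], 0.1)
        seqs = {
            "a": "MHTEACWAC",
            "b": "MHTEACWAC",
            "c": "MHTEACWAC",
            "d": "MAAAAAAAA",
        }
        tmh = {"a": 1, "b": 1, "c": 4, "d": 4}  # tie 1 vs 4 -> smaller
        pfam = {
            "a": [("Sigma_reg", 10, 50)],
            "b": [("Sigma_reg", 12, 52)],
            "c": [("Sigma_reg", 14, 54)],
            "d": [("Other", 1, 5)],
        }
        out = summarize_subgroup_annotations(sg, seqs, tmh_counts=tmh, pfam_hits=pfam)
        assert out.tmh_mode == 1
        assert out.zinc_fraction == pytest.approx(0.75)
        assert out.conserved_domains == [("Sigma_reg", 12.0, 52.0)]

    def test_half_occupancy_excluded(self):
        sg = Subgroup("SG0001", ["a", "b", "c", "d"], 0.1)
        seqs = {k: "MAAAA" for k in "abcd"}
        pfam = {"a": [("Dom", 1, 5)], "b": [("Dom", 1, 5)]}  # 2/4 is not >50%
        out = summarize_subgroup_annotations(sg, seqs, pfam_hits=pfam)
        assert out.conserved_domains == []
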