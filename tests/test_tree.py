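import pytest

from dtsb.alignment import AlignedSet
from dtsb.errors import IndistinguishableSpeciesError, UnclassifiableError
from dtsb.simulate import FixtureSpec, random_panel
from dtsb.tree import (
    best_split,
    build_tree,
    classify,
    load_tree,
    node_scores,
    save_tree,
    to_dot,
)
from oracles import brute_force_best_split


class TestBestSplit:
    def test_worked_example_root_is_position_six(self, fig3):
        assert best_split(fig3) == (6, "C")

    def test_single_variable_site(self):
        a = AlignedSet(labels=("a", "b"), rows=("AAGA", "AATA"))
        assert best_split(a) == (3, "G")  # pivot: alphabetically smaller base

    def test_max_score_tie_takes_lowest_position(self):
        # columns 2 and 4 both balanced biallelic (score 2)
        a = AlignedSet(
            labels=("a", "b", "c", "d"),
            rows=("AACA", "AACG", "ATCA", "ATCG"),
        )
        # col2: A,A,T,T score 2; col4: A,G,A,G score 2 -> position 2 wins
        position, pivot = best_split(a)
        assert position == 2
        assert pivot == "A"

    def test_agrees_with_brute_force_on_seeded_panels(self):
        for seed in range(20):
            panel = random_panel(FixtureSpec(n_species=6, n_sites=30, seed=seed))
            candidates = list(range(1, panel.length + 1))
            assert best_split(panel) == brute_force_best_split(panel.rows, candidates)

    def test_indistinguishable_subset_names_species(self, fig3):
        a = AlignedSet(labels=("x", "y", "z"), rows=("ACGT", "ACGT", "ACGA"))
        with pytest.raises(IndistinguishableSpeciesError) as exc:
            best_split(a, row_subset=[0, 1])
        assert set(exc.value.labels) == {"x", "y"}

    def test_unknown_criterion_rejected(self, fig3):
        with pytest.raises(ValueError, match="criterion"):
            best_split(fig3, criterion="chi2")


class TestBuildTree:
    def test_two_species_depth_one(self):
        a = AlignedSet(labels=("a", "b"), rows=("ACGT", "ACGA"))
        t = build_tree(a)
        assert t.position == 4 and t.level == 1
        assert len(t.leaves()) == 2 and len(t.decision_nodes()) == 1
        assert {l.species for l in t.leaves()} == {"a", "b"}

    def test_worked_example_tree_shape(self, fig3):
        t = build_tree(fig3)
        assert t.position == 6
        assert len(t.leaves()) == 8
        assert len(t.decision_nodes()) == 7
        assert {l.species for l in t.leaves()} == set(fig3.labels)

    def test_root_score_is_maximal_two(self, fig3):
        scores = {sb.position: sb.score for sb in node_scores(fig3)}
        assert scores[6] == 2
        assert max(scores.values()) == 2

    def test_left_branch_carries_pivot(self, fig3):
        t = build_tree(fig3)
        left_species = {l.species for l in t.left.leaves()}
        carriers = {
            lab for lab, row in zip(fig3.labels, fig3.rows)
            if row[t.position - 1] == t.pivot
        }
        assert left_species == carriers

    def test_positions_may_repeat_across_subtrees(self, fig3):
        positions = [n.position for n in build_tree(fig3).decision_nodes()]
        assert len(positions) > len(set(positions))

    def test_identical_sequences_raise(self):
        a = AlignedSet(labels=("a", "b", "c"), rows=("ACGT", "ACGT", "ACGA"))
        with pytest.raises(IndistinguishableSpeciesError):
            build_tree(a)

    def test_depth_bounded_by_n_minus_one(self, fig3):
        t = build_tree(fig3)
        assert t.depth() - 1 <= fig3.n_species - 1  # decision levels on any path

    @pytest.mark.parametrize("criterion", ["dtsb", "gain", "gini"])
    def test_all_criteria_yield_valid_singleton_trees(self, fig3, criterion):
        t = build_tree(fig3, criterion=criterion)
        assert len(t.leaves()) == 8 and len(t.decision_nodes()) == 7
        for lab, row in zip(fig3.labels, fig3.rows):
            assert classify(t, row) == lab

    def test_levels_increase_from_root(self, fig3):
        t = build_tree(fig3)
        for node in t.walk():
            if not node.is_leaf:
                assert node.left.level == node.level + 1
                assert node.right.level == node.level + 1


class TestClassify:
    def test_training_rows_self_consistent(self, fig3):
        t = build_tree(fig3)
        for lab, row in zip(fig3.labels, fig3.rows):
            assert classify(t, row) == lab

    def test_mutation_off_decision_positions_ignored(self, fig3):
        t = build_tree(fig3)
        decision_positions = {n.position for n in t.decision_nodes()}
        untouched = next(
            p for p in range(1, fig3.length + 1) if p not in decision_positions
        )
        row = fig3.rows[0]
        mutated = row[: untouched - 1] + "G" + row[untouched:]
        assert classify(t, mutated) == fig3.labels[0]

    def test_ambiguity_at_decision_position_unclassifiable(self, fig3):
        t = build_tree(fig3)
        row = fig3.rows[0]
        bad = row[: t.position - 1] + "N" + row[t.position :]
        with pytest.raises(UnclassifiableError) as exc:
            classify(t, bad)
        assert exc.value.position == t.position


class TestSerialization:
    def test_json_round_trip(self, fig3, tmp_path):
        t = build_tree(fig3)
        path = tmp_path / "tree.json"
        save_tree(t, path, alignment_length=fig3.length)
        back, meta = load_tree(path)
        assert back.to_dict() == t.to_dict()
        assert meta["alignment_length"] == 8
        for lab, row in zip(fig3.labels, fig3.rows):
            assert classify(back, row) == lab

    def test_dot_export_mentions_every_leaf(self, fig3):
        dot = to_dot(build_tree(fig3))
        assert dot.startswith("digraph")
        for lab in fig3.labels:
            assert lab in dot
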