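import numpy as np
import pytest

from twostate import (
    DesignError,
    MutationCandidate,
    DdGRecord,
    classify_layer,
    count_mutations,
    enumerate_cutoff_designs,
    load_ddg_tables,
    mutational_load,
    run_workflow,
    select_design,
    two_state_filter,
)
from twostate.config import DEFAULT_CUTOFFS, RunConfig
from twostate.constraints import FixedPositionSet
from twostate.design import apply_mutations, neighbor_count
from twostate.structures import Atom, Residue, Structure

EMPTY_FIXED = FixedPositionSet(positions=frozenset(), provenance={})


def _tsv(rows):
    out = ["position\twt\tmut\tddg"]
    out += [f"{p}\t{w}\t{m}\t{d}" for p, w, m, d in rows]
    return "\n".join(out) + "\n"


def _mut_at(pair, idx, mut="A"):
    wt = pair.sequence[idx]
    if mut == wt:
        mut = "V" if wt != "V" else "L"
    return pair.author_numbers[idx], wt, mut


class TestLoadDdgTables:
    def test_identical_tables_join_fully(self, small_pair):
        muts = [_mut_at(small_pair, i) for i in (10, 11, 12)]
        rows = [(p, w, m, d) for (p, w, m), d in zip(muts, [-1.0, -2.0, 0.5])]
        records, dropped = load_ddg_tables(_tsv(rows), _tsv(rows), small_pair)
        assert len(records) == 3 and dropped == 0

    def test_one_sided_candidate_dropped_with_warning(self, small_pair):
        shared = [_mut_at(small_pair, 10) + (-1.0,)]
        extra = shared + [_mut_at(small_pair, 11) + (-2.0,)]
        with pytest.warns(UserWarning, match="1 candidate"):
            records, dropped = load_ddg_tables(
                _tsv(extra), _tsv(shared), small_pair
            )
        assert len(records) == 1 and dropped == 1

    def test_wildtype_mismatch_names_position(self, small_pair):
        pos, wt, mut = _mut_at(small_pair, 10)
        wrong = "W" if wt != "W" else "Y"
        bad = _tsv([(pos, wrong, mut, -1.0)])
        with pytest.raises(DesignError, match=str(pos)):
            load_ddg_tables(bad, bad, small_pair)

    def test_join_equals_brute_force(self, small_bundle):
        """The pandas join reproduces a nested-loop join of the two tables."""
        records, _ = load_ddg_tables(
            small_bundle.ddg.open_tsv, small_bundle.ddg.closed_tsv,
            small_bundle.pair,
        )
        open_rows = {}
        for line in small_bundle.ddg.open_tsv.splitlines()[1:]:
            p, w, m, d = line.split("\t")
            open_rows[(int(p), w, m)] = float(d)
        oracle = set()
        for line in small_bundle.ddg.closed_tsv.splitlines()[1:]:
            p, w, m, d = line.split("\t")
            key = (int(p), w, m)
            if key in open_rows:
                oracle.add(key + (open_rows[key], float(d)))
        got = {
            (r.candidate.position, r.candidate.wt_aa, r.candidate.mut_aa,
             r.ddg_open, r.ddg_closed)
            for r in records
        }
        assert got == oracle


def _rec(pos, o, c, wt="A", mut="V"):
    return DdGRecord(MutationCandidate(pos, wt, mut), o, c)


class TestTwoStateFilter:
    @pytest.mark.parametrize(
        "ddg_open,ddg_closed,kept",
        [
            (-1.5, -0.3, True),   # stabilizing in both
            (-2.0, +0.5, False),  # destabilizing in the closed state
            (0.0, -1.0, False),   # boundary: zero is not stabilizing
            (-1e-9, -1e-9, True),
        ],
    )
    def test_strict_sign_rule(self, ddg_open, ddg_closed, kept):
        out = two_state_filter([_rec(1, ddg_open, ddg_closed)])
        assert (len(out) == 1) is kept

    def test_matches_planted_class(self, small_bundle):
        records, _ = load_ddg_tables(
            small_bundle.ddg.open_tsv, small_bundle.ddg.closed_tsv,
            small_bundle.pair,
        )
        kept = {r.candidate for r in two_state_filter(records)}
        assert kept == set(small_bundle.ddg.truth["both_stabilizing"])


class TestEnumerateCutoffDesigns:
    def test_threshold_membership(self):
        per = enumerate_cutoff_designs(
            [_rec(1, -3.0, -3.0)], DEFAULT_CUTOFFS, EMPTY_FIXED, None, "open"
        )
        absent = [c for c in (-4.0, -3.2) if per[c]]
        present = [c for c in (-2.88, -2.4, -2.0, 0.0) if not per[c]]
        assert absent == [] and present == []

    def test_lowest_score_wins_position(self):
        recs = [_rec(1, -2.0, -2.0, mut="V"), _rec(1, -3.0, -3.0, mut="W")]
        per = enumerate_cutoff_designs(
            recs, (-2.0,), EMPTY_FIXED, None, "open"
        )
        assert per[-2.0] == (MutationCandidate(1, "A", "W"),)

    def test_score_tie_breaks_alphabetically(self):
        recs = [_rec(1, -2.0, -2.0, mut="W"), _rec(1, -2.0, -2.0, mut="V")]
        per = enumerate_cutoff_designs(recs, (0.0,), EMPTY_FIXED, None, "open")
        assert per[0.0][0].mut_aa == "V"

    def test_fixed_positions_and_alphabet_respected(self):
        fixed = FixedPositionSet(
            positions=frozenset({2}), provenance={2: frozenset({"pocket"})}
        )
        recs = [_rec(1, -3.0, -3.0, mut="V"), _rec(2, -3.0, -3.0, mut="V"),
                _rec(3, -3.0, -3.0, mut="W")]
        allowed = {1: frozenset("AV"), 2: frozenset("AV"), 3: frozenset("AV")}
        per = enumerate_cutoff_designs(recs, (0.0,), fixed, allowed, "open")
        assert per[0.0] == (MutationCandidate(1, "A", "V"),)

    def test_matches_brute_force_on_planted_fixture(self, small_bundle):
        records, _ = load_ddg_tables(
            small_bundle.ddg.open_tsv, small_bundle.ddg.closed_tsv,
            small_bundle.pair,
        )
        per = enumerate_cutoff_designs(
            records, DEFAULT_CUTOFFS, EMPTY_FIXED, None, "max_of_both"
        )
        for c in DEFAULT_CUTOFFS:
            by_pos = {}
            for r in records:
                s = max(r.ddg_open, r.ddg_closed)
                if s <= c:
                    key = r.candidate.position
                    cur = by_pos.get(key)
                    if cur is None or (s, r.candidate.mut_aa) < cur[:2]:
                        by_pos[key] = (s, r.candidate.mut_aa, r.candidate)
            oracle = tuple(sorted(v[2] for v in by_pos.values()))
            assert per[c] == oracle


class TestSelectDesign:
    def _per_cutoff(self, sizes, length):
        out = {}
        for c, n in sizes.items():
            out[c] = tuple(
                MutationCandidate(i + 1, "A", "V") for i in range(n)
            )
        return out

    def test_strictest_in_range_wins(self):
        per = self._per_cutoff({-4.0: 2, -2.88: 5, 0.0: 12}, 100)
        cutoff, muts, oor = select_design(per, length=100)
        assert cutoff == -2.88 and len(muts) == 5 and not oor

    def test_all_below_range_flags_out_of_range(self):
        per = self._per_cutoff({-4.0: 1, -2.0: 2, 0.0: 3}, 100)
        cutoff, muts, oor = select_design(per, length=100)
        assert oor and len(muts) == 3  # 3% is closest to [4, 10]

    def test_empty_cutoffs_are_not_designs(self):
        per = self._per_cutoff({-4.0: 0, 0.0: 6}, 100)
        cutoff, muts, oor = select_design(per, length=100)
        assert cutoff == 0.0 and not oor

    def test_all_empty_raises(self):
        with pytest.raises(DesignError):
            select_design({-4.0: (), 0.0: ()}, length=100)


def _layer_structure(positions_cb, center_first=True):
    """Synthetic residues: each has CA 1.5 Å below its CB along z."""
    residues = []
    for i, cb in enumerate(positions_cb):
        ca = (cb[0], cb[1], cb[2] - 1.5)
        residues.append(
            Residue("A", i + 1, "", "VAL",
                    [Atom("CA", "C", ca), Atom("CB", "C", cb)])
        )
    return Structure(residues=residues)


class TestClassifyLayer:
    def test_isolated_residue_is_surface(self):
        s = _layer_structure([(0.0, 0.0, 0.0), (50.0, 0.0, 0.0)])
        assert classify_layer(s, 1) == "surface"

    def test_forward_cluster_is_core(self):
        """A residue whose side chain points into a dense cluster counts
        ~8 forward neighbors and classifies as core."""
        center = (0.0, 0.0, 0.0)
        ring = [
            (2.0 * np.cos(a), 2.0 * np.sin(a), 6.0)
            for a in np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ]
        s = _layer_structure([center] + ring)
        assert classify_layer(s, 1) == "core"

    def test_neighbor_count_matches_plain_loop(self):
        from twostate.design import _cone_weight, _distance_weight

        cbs = [(0.0, 0.0, 0.0), (1.0, 2.0, 6.0), (-3.0, 1.0, 8.0), (0.0, 9.5, 2.0)]
        s = _layer_structure(cbs)
        got = neighbor_count(s, 1)
        direction = np.array([0.0, 0.0, 1.0])
        expect = 0.0
        for other in cbs[1:]:
            vec = np.asarray(other) - np.asarray(cbs[0])
            d = np.linalg.norm(vec)
            expect += _distance_weight(d, 9.0, 11.0) * _cone_weight(
                float(np.dot(direction, vec / d))
            )
        assert got == pytest.approx(expect)

    def test_geometry_only_same_label_in_both_states(self, small_bundle):
        pair = small_bundle.pair
        # lobe A is untouched by closure, so its geometry (and labels) match
        pos_a = pair.author_numbers[8]
        closed_a = pair.closed_protein[pair.mapping[8]].number
        assert classify_layer(pair.open, pos_a) == classify_layer(
            pair.closed, closed_a
        )


class TestBookkeeping:
    def test_apply_and_count_roundtrip(self, small_pair):
        pos, wt, mut = _mut_at(small_pair, 15)
        seq = apply_mutations(
            small_pair.sequence,
            (MutationCandidate(pos, wt, mut),),
            small_pair.author_numbers,
        )
        assert count_mutations(small_pair.sequence, seq) == 1
        assert mutational_load(1, len(seq)) == pytest.approx(100.0 / len(seq))

    def test_count_requires_equal_length(self):
        with pytest.raises(DesignError):
            count_mutations("AAA", "AA")


@pytest.fixture(scope="module")
def base_result(small_bundle):
    return run_workflow(
        small_bundle.pair,
        msa=small_bundle.msa,
        ddg_open_tsv=small_bundle.ddg.open_tsv,
        ddg_closed_tsv=small_bundle.ddg.closed_tsv,
    )


class TestRunWorkflow:

    def test_emits_all_five_tiers(self, base_result):
        assert set(base_result.variants) == {"X.0", "X.1", "X.2", "X.3", "X.4"}
        assert base_result.variants["X.0"].n_mutations == 0

    def test_two_state_mutations_stabilize_both_states(self, base_result):
        recs = {r.candidate: r for r in base_result.records}
        for tier in ("X.3", "X.4"):
            for m in base_result.variants[tier].mutations:
                assert recs[m].ddg_open < 0 and recs[m].ddg_closed < 0

    def test_no_fixed_position_or_disallowed_identity(self, base_result, small_bundle):
        from twostate.pssm import allowed_identities, compute_pssm

        allowed = allowed_identities(
            compute_pssm(small_bundle.msa), small_bundle.pair.sequence
        )
        authors = small_bundle.pair.author_numbers
        for tier in ("X.1", "X.2", "X.3", "X.4"):
            fixed = base_result.fixed_sets[tier]
            for m in base_result.variants[tier].mutations:
                assert m.position not in fixed
                assert m.mut_aa in allowed[authors.index(m.position) + 1]

    def test_hinge_site_mutation_in_x3_not_x4(self):
        """A strongly both-state-stabilizing mutation at a hinge residue
        survives the two-state filter but is removed by hinge fixing."""
        from twostate.fixtures import FixtureSpec, make_structure_pair

        pair, _ = make_structure_pair(FixtureSpec(n_per_lobe=28, seed=3))

        def both_stab(author, ddg):
            i = pair.author_to_index(author)
            wt = pair.sequence[i]
            return DdGRecord(
                MutationCandidate(author, wt, "A" if wt != "A" else "V"),
                ddg, ddg,
            )

        probe = run_workflow(
            pair, records=[both_stab(a, -3.0) for a in pair.author_numbers]
        )
        hinge_only = sorted(
            probe.fixed_sets["X.4"].positions - probe.fixed_sets["X.3"].positions
        )
        assert hinge_only, "fixture must have a non-pocket hinge position"
        pos = hinge_only[0]
        free = [
            a for a in pair.author_numbers
            if a not in probe.fixed_sets["X.4"].positions
        ][:3]
        records = [both_stab(pos, -3.9)] + [both_stab(a, -3.0) for a in free]
        res = run_workflow(pair, records=records)
        x3 = {m.position for m in res.variants["X.3"].mutations}
        x4 = {m.position for m in res.variants["X.4"].mutations}
        assert pos in x3 and pos not in x4

    def test_x3_equals_x4_when_filters_idle(self, small_bundle, base_result):
        """Without hinge/interface-site candidates the extra fixing of X.4
        changes nothing."""
        pair = small_bundle.pair
        fixed4 = base_result.fixed_sets["X.4"].positions
        free = [a for a in pair.author_numbers if a not in fixed4][:4]
        records = []
        for a in free:
            i = pair.author_to_index(a)
            wt = pair.sequence[i]
            records.append(
                DdGRecord(
                    MutationCandidate(a, wt, "A" if wt != "A" else "V"),
                    -2.5, -2.5,
                )
            )
        res = run_workflow(pair, records=records)
        assert res.variants["X.3"].mutations == res.variants["X.4"].mutations

    def test_report_tables_cover_all_selected_mutations(self, base_result):
        table = base_result.mutation_table
        for tier in ("X.1", "X.2", "X.3", "X.4"):
            sel = base_result.variants[tier].mutations
            sub = table[table.tier == tier]
            assert len(sub) == len(sel)
        assert set(base_result.scatter_table.columns) >= {
            "position", "ddg_open", "ddg_closed", "layer"
        }
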