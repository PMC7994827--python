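"""Alignment, hinge classification and the X/Y/Z mutation-set rules."""

import numpy as np
import pandas as pd
import pytest

import hingeshift as hs
from hingeshift.enm_prs import percentile_pairwise_dci
from hingeshift.hinge_design import (
    COMMON,
    NON_COMMON_A,
    NON_COMMON_B,
    NON_HINGE,
    AlignmentMap,
    MutationSet,
)

from conftest import PAIR_SOFTEN, PAIR_STIFFEN


def make_profile(pct):
    pct = np.asarray(pct, dtype=float)
    return hs.FlexibilityProfile(dfi=pct / pct.sum(), pct_dfi=pct)


class TestAlignSequences:
    def test_identical_sequences_identity_map(self):
        amap = hs.align_sequences("ACDEFGHIK", "ACDEFGHIK")
        assert amap.pairs == [(i, i) for i in range(9)]
        assert amap.conserved.all()

    def test_single_substitution_flagged(self):
        amap = hs.align_sequences("ACDEFGHIK", "ACDEFGWIK")
        assert amap.pairs == [(i, i) for i in range(9)]
        assert amap.conserved.sum() == 8
        assert not amap.conserved[6]

    def test_deletion_creates_gap(self):
        # D of ACDEF aligned to a gap; 4 aligned pairs expected, verified
        # against exhaustive DP over all monotone matchings
        amap = hs.align_sequences("ACDEF", "ACEF")
        assert amap.n_pairs == 4
        matched_a = [a for a, _ in amap.pairs]
        assert 2 not in matched_a  # the D position
        assert amap.conserved.all()

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            hs.align_sequences("", "ACD")

    def test_mapping_table_bypass(self):
        amap = AlignmentMap(pairs=[(0, 0), (2, 1)], seq_a="ACD", seq_b="AD")
        assert amap.conserved.tolist() == [True, True]

    def test_non_monotone_mapping_rejected(self):
        with pytest.raises(ValueError):
            AlignmentMap(pairs=[(0, 1), (1, 0)], seq_a="AC", seq_b="CA")


class TestClassifyHinges:
    def test_identical_proteins_have_no_non_common_hinges(self):
        prof = make_profile([0.1, 0.5, 0.9, 0.15, 1.0])
        amap = hs.align_sequences("ACDEF", "ACDEF")
        table = hs.classify_hinges(prof, prof, amap)
        assert not (table.cls == NON_COMMON_A).any()
        assert not (table.cls == NON_COMMON_B).any()
        assert (table[table.pct_dfi_a < 0.2].cls == COMMON).all()

    def test_threshold_logic_on_single_pair(self):
        pa = make_profile([0.1, 0.5, 0.9])
        pb = make_profile([0.5, 0.1, 0.9])
        amap = hs.align_sequences("ACD", "ACD")
        table = hs.classify_hinges(pa, pb, amap)
        assert table.cls.tolist() == [NON_COMMON_A, NON_COMMON_B, NON_HINGE]

    def test_classes_partition_aligned_pairs(self, shift_pair_analysis):
        table = shift_pair_analysis["table"]
        counts = table.cls.value_counts()
        assert counts.sum() == len(table)
        assert set(counts.index) <= {COMMON, NON_COMMON_A, NON_COMMON_B, NON_HINGE}
        # class definitions are consistent with the hinge flags
        assert ((table.cls == COMMON) == (table.hinge_a & table.hinge_b)).all()
        assert ((table.cls == NON_COMMON_A) == (table.hinge_a & ~table.hinge_b)).all()

    def test_random_profiles_match_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        pa = make_profile(rng.permutation(np.arange(1, 21) / 20))
        pb = make_profile(rng.permutation(np.arange(1, 21) / 20))
        seq = "".join(rng.choice(list("ACDEFGHIKL"), size=20))
        seq_b = "".join(rng.choice(list("ACDEFGHIKL"), size=20))
        amap = AlignmentMap(pairs=[(i, i) for i in range(20)], seq_a=seq, seq_b=seq_b)
        table = hs.classify_hinges(pa, pb, amap, hinge_threshold=0.2)
        expected = {COMMON: 0, NON_COMMON_A: 0, NON_COMMON_B: 0, NON_HINGE: 0}
        for i in range(20):
            ha, hb = pa.pct_dfi[i] < 0.2, pb.pct_dfi[i] < 0.2
            key = COMMON if ha and hb else NON_COMMON_A if ha else \
                NON_COMMON_B if hb else NON_HINGE
            expected[key] += 1
        assert table.cls.value_counts().to_dict() == \
            {k: v for k, v in expected.items() if v}

    def test_hinge_sets_grow_with_threshold(self, shift_pair_analysis):
        d = shift_pair_analysis
        prev_a = prev_b = set()
        for thr in (0.1, 0.2, 0.3, 0.5, 0.8):
            table = hs.classify_hinges(d["prof_a"], d["prof_b"], d["amap"],
                                       hinge_threshold=thr)
            hinges_a = set(table[table.hinge_a].pos_a)
            hinges_b = set(table[table.hinge_b].pos_b)
            assert prev_a <= hinges_a and prev_b <= hinges_b
            prev_a, prev_b = hinges_a, hinges_b


def toy_table():
    """Hand-built hinge table: positions 0,1 non-common-A (non-conserved),
    2 common (non-conserved), 3 common (conserved), 4,5 non-common-B,
    6,7 non-hinge."""
    rows = [
        dict(pos_a=0, pos_b=0, aa_a="A", aa_b="C", pct_dfi_a=0.1, pct_dfi_b=0.5,
             hinge_a=True, hinge_b=False, cls=NON_COMMON_A, conserved=False),
        dict(pos_a=1, pos_b=1, aa_a="D", aa_b="E", pct_dfi_a=0.15, pct_dfi_b=0.6,
             hinge_a=True, hinge_b=False, cls=NON_COMMON_A, conserved=False),
        dict(pos_a=2, pos_b=2, aa_a="F", aa_b="G", pct_dfi_a=0.1, pct_dfi_b=0.1,
             hinge_a=True, hinge_b=True, cls=COMMON, conserved=False),
        dict(pos_a=3, pos_b=3, aa_a="H", aa_b="H", pct_dfi_a=0.05, pct_dfi_b=0.05,
             hinge_a=True, hinge_b=True, cls=COMMON, conserved=True),
        dict(pos_a=4, pos_b=4, aa_a="I", aa_b="K", pct_dfi_a=0.5, pct_dfi_b=0.1,
             hinge_a=False, hinge_b=True, cls=NON_COMMON_B, conserved=False),
        dict(pos_a=5, pos_b=5, aa_a="L", aa_b="L", pct_dfi_a=0.6, pct_dfi_b=0.15,
             hinge_a=False, hinge_b=True, cls=NON_COMMON_B, conserved=True),
        dict(pos_a=6, pos_b=6, aa_a="M", aa_b="M", pct_dfi_a=0.4, pct_dfi_b=0.4,
             hinge_a=False, hinge_b=False, cls=NON_HINGE, conserved=True),
        dict(pos_a=7, pos_b=7, aa_a="N", aa_b="P", pct_dfi_a=0.9, pct_dfi_b=0.9,
             hinge_a=False, hinge_b=False, cls=NON_HINGE, conserved=False),
    ]
    return pd.DataFrame(rows)


def ranked_matrix(strong_pairs, n=8):
    """Percentile matrix with chosen (responder, perturbed) entries set high."""
    m = np.full((n, n), 0.5)
    for i, j, v in strong_pairs:
        m[i, j] = v
    return m


class TestSelectSetX:
    def test_no_strong_couplings_gives_empty_set(self):
        s = hs.select_set_X(toy_table(), ranked_matrix([]), ranked=True)
        assert s.members == []

    def test_only_coupled_candidate_selected(self):
        # candidate 0 coupled at 0.9 (in B) to B-hinge 4; candidate 1 only 0.5
        pct = ranked_matrix([(0, 4, 0.9), (1, 4, 0.5)])
        s = hs.select_set_X(toy_table(), pct, ranked=True)
        assert s.positions == [0]
        assert s.members[0].from_aa == "A" and s.members[0].to_aa == "C"
        assert s.members[0].evidence["coupled_non_common_B"][0]["partner_pos_b"] == 4

    def test_conserved_positions_never_selected(self):
        pct = np.full((8, 8), 0.99)
        s = hs.select_set_X(toy_table(), pct, ranked=True)
        table = toy_table().set_index("pos_a")
        assert all(not table.loc[p].conserved for p in s.positions)
        assert all(table.loc[p].cls == NON_COMMON_A for p in s.positions)

    def test_shrinks_as_threshold_rises(self):
        pct = ranked_matrix([(0, 4, 0.9), (1, 4, 0.85)])
        sizes = [len(hs.select_set_X(toy_table(), pct, dci_threshold=t,
                                     ranked=True).members)
                 for t in (0.8, 0.87, 0.95)]
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_enumeration_oracle_on_fixture_pair(self, shift_pair_analysis):
        d = shift_pair_analysis
        table, pw_b = d["table"], d["pw_b"]
        got = hs.select_set_X(table, pw_b).positions

        pct = percentile_pairwise_dci(pw_b)
        expected = []
        for row in table.itertuples():
            if row.cls != NON_COMMON_A or row.conserved:
                continue
            partners = table[table.cls == NON_COMMON_B]
            if any(pct[row.pos_b, p.pos_b] >= 0.8 for p in partners.itertuples()
                   if p.pos_b != row.pos_b):
                expected.append(row.pos_a)
        assert got == expected and got  # non-empty on the canonical pair


class TestSelectSetY:
    def test_conserved_common_hinges_only_gives_empty_set(self):
        table = toy_table()
        table.loc[table.pos_a == 2, "conserved"] = True
        s = hs.select_set_Y(table, np.full((8, 8), 0.99), ranked=True)
        assert s.members == []

    def test_qualifying_common_hinge_selected(self):
        # common hinge 2 coupled (in A) to non-conserved non-common hinge 4
        pct = ranked_matrix([(2, 4, 0.9)])
        s = hs.select_set_Y(toy_table(), pct, ranked=True)
        assert s.positions == [2]
        # conserved non-common hinge 5 must not qualify as a partner
        pct2 = ranked_matrix([(2, 5, 0.9)])
        assert hs.select_set_Y(toy_table(), pct2, ranked=True).members == []

    def test_manual_include_honored_and_flagged(self):
        s = hs.select_set_Y(toy_table(), ranked_matrix([]), manual_include=[2],
                            ranked=True)
        assert s.positions == [2]
        assert s.members[0].evidence.get("manual_include") is True
        assert any("force-included" in d for d in s.diagnostics)

    def test_manual_include_of_non_common_hinge_rejected(self):
        s = hs.select_set_Y(toy_table(), ranked_matrix([]), manual_include=[4],
                            ranked=True)
        assert s.members == []
        assert any("rejected" in d for d in s.diagnostics)


class TestSelectSetZ:
    def make_structure(self):
        # 8 residues on a line, 5 Å apart; active site at position 0
        xyz = np.column_stack([5.0 * np.arange(8), np.zeros(8), np.zeros(8)])
        xyz[:, 1] = [0, 1, 0, 1, 0, 1, 0, 1]
        return hs.StructureModel(author_resid=[str(i + 1) for i in range(8)],
                                 chain_id="A", aa="ADFHIKMN", ca_xyz=xyz)

    def profile(self):
        return make_profile([0.9, 0.8, 0.35, 0.05, 0.45, 0.15, 0.4, 0.6])

    def test_distance_filter_excludes_near_residue(self):
        # candidates in band: 2 (10 Å), 4 (20 Å), 6 (30 Å); partner = conserved
        # non-common hinge 5; only 4 and 6 coupled strongly; 2 fails only distance
        pct = ranked_matrix([(2, 5, 0.9), (4, 5, 0.9)])
        s = hs.select_set_Z(self.profile(), self.make_structure(), pct,
                            toy_table(), active_site=[0], min_dist=12.0,
                            ranked=True)
        assert s.positions == [4]
        assert any("distance" in d for d in s.diagnostics)

    def test_all_near_active_site_gives_empty_set(self):
        pct = np.full((8, 8), 0.99)
        s = hs.select_set_Z(self.profile(), self.make_structure(), pct,
                            toy_table(), active_site=[0, 4], min_dist=40.0,
                            ranked=True)
        assert s.members == []

    def test_band_boundary_is_excluded(self):
        prof = make_profile([0.9, 0.8, 0.3, 0.05, 0.45, 0.15, 0.5, 0.6])
        # 2 and 6 sit exactly on the open band edges; only 4 remains eligible
        pct = np.full((8, 8), 0.99)
        s = hs.select_set_Z(prof, self.make_structure(), pct, toy_table(),
                            active_site=[0], min_dist=8.0, ranked=True)
        assert 2 not in s.positions and 6 not in s.positions
        assert s.positions == [4]

    def test_members_are_never_hinges_of_a(self, shift_pair_analysis):
        d = shift_pair_analysis
        pair_structure = d["prof_a"]
        s = hs.select_set_Z(d["prof_a"],
                            hs.make_structure(hs.FixtureSpec(topology="two-domain",
                                                             n_residues=30, seed=5)),
                            d["pw_a"], d["table"], active_site=[26])
        for p in s.positions:
            assert pair_structure.pct_dfi[p] > 0.2

    def test_empty_active_site_is_an_error(self):
        with pytest.raises(ValueError):
            hs.select_set_Z(self.profile(), self.make_structure(),
                            np.full((8, 8), 0.5), toy_table(), active_site=[])


class TestDesignReport:
    def test_three_empty_sets(self):
        empty = lambda sid: MutationSet(set_id=sid, members=[])
        rep = hs.design_report(empty("X"), empty("Y"), empty("Z"), toy_table())
        assert rep.all_positions == []
        assert rep.metadata["n_substitutions"] == 0

    def test_union_and_json_round_trip(self):
        import json
        pct_x = ranked_matrix([(0, 4, 0.9), (1, 4, 0.9)])
        pct_y = ranked_matrix([(2, 4, 0.9)])
        sx = hs.select_set_X(toy_table(), pct_x, ranked=True)
        sy = hs.select_set_Y(toy_table(), pct_y, ranked=True)
        sz = MutationSet(set_id="Z", members=[])
        rep = hs.design_report(sx, sy, sz, toy_table())
        assert rep.all_positions == [0, 1, 2]
        payload = json.loads(rep.to_json())
        assert {k: len(v["members"]) for k, v in payload["sets"].items()} == \
            {"X": 2, "Y": 1, "Z": 0}

    def test_overlap_raises_with_position_named(self):
        sx = MutationSet(set_id="X", members=[hs.hinge_design.MutationRecord(
            position=3, author_resid=None, from_aa="H", to_aa="Q")])
        sy = MutationSet(set_id="Y", members=[hs.hinge_design.MutationRecord(
            position=3, author_resid=None, from_aa="H", to_aa="Q")])
        with pytest.raises(ValueError, match="position 3"):
            hs.design_report(sx, sy, MutationSet(set_id="Z", members=[]),
                             toy_table())


class TestHingeShiftReenactment:
    def test_stiffened_positions_gain_hinges_softened_lose_them(self, shift_pair_analysis):
        table = shift_pair_analysis["table"].set_index("pos_a")
        for p in PAIR_STIFFEN:
            assert table.loc[p, "cls"] == NON_COMMON_B, f"{p} did not gain a hinge"
        for p in PAIR_SOFTEN:
            assert table.loc[p, "cls"] == NON_COMMON_A, f"{p} did not lose its hinge"
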