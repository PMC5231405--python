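"""Reaction-center location, measurement and mechanism classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from tcsgeom.fixtures import make_reaction_center
from tcsgeom.published import REFERENCE_CENTERS
from tcsgeom.reaction_center import (MechanismCall, ReactionCenterGeometry,
                                     ReactionCenterSpec, batch_table,
                                     classify_mechanism, locate_reactive_atoms,
                                     measure_center)
from tcsgeom.structure import Atom, StructureError
from tcsgeom.superpose import RigidTransform, apply_transform

SPEC = ReactionCenterSpec("A", 188, "B", 54)


class TestLocate:
    def test_his_asp_mg_handles_found(self):
        s, _ = make_reaction_center(6.0, 3.0, 5.0)
        ra = locate_reactive_atoms(s, SPEC)
        assert ra.ne2.name == "NE2" and ra.od.name == "OD1"
        assert ra.mg is not None and ra.mg.element == "MG"

    def test_auto_mg_absent_is_not_an_error(self):
        s, _ = make_reaction_center(6.0, 3.0, 5.0)
        s.atoms = [a for a in s.atoms if a.element != "MG"]
        ra = locate_reactive_atoms(s, SPEC)
        assert ra.mg is None

    def test_missing_ne2_names_the_atom(self):
        s, _ = make_reaction_center(6.0, 3.0, 5.0)
        s.atoms = [a for a in s.atoms if a.name != "NE2"]
        with pytest.raises(StructureError, match="NE2"):
            locate_reactive_atoms(s, SPEC)

    def test_bef_beryllium_recognized_as_surrogate(self):
        s, _ = make_reaction_center(6.0, 3.0, 5.0)
        od1 = s.find_atoms(name="OD1")[0]
        s.atoms.append(Atom(90, "BE", "BE", "BEF", "B", 300,
                            od1.position + [0.0, 1.6, 0.0], is_hetero=True))
        ra = locate_reactive_atoms(s, ReactionCenterSpec("A", 188, "B", 54,
                                                         surrogate="bef"))
        assert ra.surrogate_kind == "bef" and ra.surrogate.element == "BE"

    def test_atp_gamma_surrogate_with_bridge(self):
        s, _ = make_reaction_center(6.0, 3.0, 5.0)
        ne2 = s.find_atoms(name="NE2")[0]
        s.atoms.append(Atom(91, "PG", "P", "ACP", "C", 400,
                            ne2.position + [3.4, 0, 0], is_hetero=True))
        s.atoms.append(Atom(92, "C3B", "C", "ACP", "C", 400,
                            ne2.position + [5.0, 0, 0], is_hetero=True))
        ra = locate_reactive_atoms(s, ReactionCenterSpec("A", 188, "B", 54,
                                                         surrogate="atp_gamma"))
        assert ra.surrogate_kind == "atp_gamma" and ra.bridge is not None


class TestMeasure:
    def test_constructed_distances_recovered_exactly(self):
        s, truth = make_reaction_center(6.5, 3.0, 6.0)
        g = measure_center(s, SPEC)
        assert g.d_his_asp == pytest.approx(6.5, abs=1e-9)
        assert g.d_mg_asp == pytest.approx(3.0, abs=1e-9)
        assert g.d_mg_his == pytest.approx(6.0, abs=1e-9)
        assert g.r_mg == pytest.approx(0.5, abs=1e-12)

    def test_surrogate_gives_reaction_coordinate(self):
        s, truth = make_reaction_center(7.6, 3.0, 6.38, with_surrogate=True)
        g = measure_center(s, SPEC)
        assert g.surrogate_kind == "p_his"
        assert g.d_rxn == pytest.approx(truth["d_rxn"], abs=1e-9)

    def test_atp_center_measures_to_bridging_atom(self):
        s, _ = make_reaction_center(6.0, 3.0, 5.0)
        ne2 = s.find_atoms(name="NE2")[0]
        s.atoms.append(Atom(91, "PG", "P", "ACP", "C", 400,
                            ne2.position + [3.4, 0, 0], is_hetero=True))
        s.atoms.append(Atom(92, "O3B", "O", "ACP", "C", 400,
                            ne2.position + [5.0, 0, 0], is_hetero=True))
        g = measure_center(s, ReactionCenterSpec("A", 188, "B", 54,
                                                 surrogate="atp_gamma"))
        assert g.d_his_asp == pytest.approx(5.0, abs=1e-9)   # Nε2 -> β-γ bridge
        assert g.d_rxn == pytest.approx(3.4, abs=1e-9)       # γ-P -> Nε2

    def test_nearest_od_policy(self):
        s, _ = make_reaction_center(6.0, 3.0, 5.0)
        # put OD2 closer to the His than OD1
        od2 = s.find_atoms(name="OD2")[0]
        od2.position = np.array([4.0, 0.0, 0.0])
        g = measure_center(s, ReactionCenterSpec("A", 188, "B", 54,
                                                 od_policy="nearest"))
        assert g.od_used == "OD2" and g.d_his_asp == pytest.approx(4.0, abs=1e-9)

    def test_geometry_invariant_under_rigid_motion(self):
        s, _ = make_reaction_center(7.0, 3.2, 5.9, with_surrogate=True)
        g0 = measure_center(s, SPEC)
        t = RigidTransform(Rotation.from_euler("zx", [2.2, -0.8]).as_matrix(),
                           np.array([30.0, -12.0, 4.0]))
        g1 = measure_center(apply_transform(s, t), SPEC)
        for f in ("d_his_asp", "d_rxn", "d_mg_asp", "d_mg_his", "r_mg"):
            assert getattr(g1, f) == pytest.approx(getattr(g0, f), abs=1e-9)

    def test_monotonicity_of_ratio_in_mg_asp_distance(self):
        gs = [measure_center(make_reaction_center(7.0, d, 6.0)[0], SPEC).r_mg
              for d in (2.0, 3.0, 4.0, 5.0)]
        assert all(a < b for a, b in zip(gs, gs[1:]))


class TestClassify:
    @pytest.mark.parametrize("d,r,group", [
        (5.7, 0.82, "I"),       # tight center, symmetric cation
        (7.6, 0.47, "II"),      # loose center, Asp-biased cation
        (6.5, 0.6, "ambiguous"),   # both exactly at the cuts
        (6.5, 0.8, "ambiguous"),   # distance on the boundary
        (5.0, 0.5, "ambiguous"),   # discriminants disagree
        (8.0, 0.9, "ambiguous"),
    ])
    def test_threshold_partition(self, d, r, group):
        call = classify_mechanism(ReactionCenterGeometry(d_his_asp=d, r_mg=r))
        assert call.group == group
        assert isinstance(call, MechanismCall) and call.confident

    def test_distance_only_call_flagged_low_confidence(self):
        call = classify_mechanism(ReactionCenterGeometry(d_his_asp=7.3))
        assert call.group == "II" and not call.confident

    def test_dissociation_room_note_when_rxn_coordinate_long(self):
        g = ReactionCenterGeometry(d_his_asp=7.6, r_mg=0.47, d_rxn=5.8)
        call = classify_mechanism(g)
        assert "metaphosphate" in call.rationale

    def test_custom_cuts_respected(self):
        g = ReactionCenterGeometry(d_his_asp=6.0, r_mg=0.7)
        assert classify_mechanism(g).group == "I"
        assert classify_mechanism(g, d_cut=5.5, r_cut=0.8).group == "II"
        assert classify_mechanism(g, d_cut=5.5, r_cut=0.6).group == "ambiguous"

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(d=st.floats(3.0, 12.0), r=st.floats(0.05, 2.0),
           d_cut=st.floats(5.0, 8.0), r_cut=st.floats(0.3, 1.0))
    def test_pure_function_of_inputs(self, d, r, d_cut, r_cut):
        g = ReactionCenterGeometry(d_his_asp=d, r_mg=r)
        c1 = classify_mechanism(g, d_cut, r_cut)
        c2 = classify_mechanism(g, d_cut, r_cut)
        assert (c1.group, c1.mechanism) == (c2.group, c2.mechanism)
        expect = ("I" if (d < d_cut and r > r_cut)
                  else "II" if (d > d_cut and r < r_cut) else "ambiguous")
        assert c1.group == expect

    def test_reproduces_reference_partition(self):
        for ref in REFERENCE_CENTERS:
            g = ReactionCenterGeometry(d_his_asp=ref.d_his_asp, r_mg=ref.r_mg,
                                       d_rxn=ref.d_rxn)
            assert classify_mechanism(g).group == ref.group, ref.label


class TestBatch:
    def _entries(self, params):
        out = []
        for k, (d, dma, dmh) in enumerate(params):
            s, _ = make_reaction_center(d, dma, dmh, seed=100 + k)
            out.append((s, SPEC, f"syn-{k}"))
        return out

    def test_counts_match_brute_force_threshold_check(self):
        params = [(5.0, 3.0, 4.0), (5.5, 3.5, 4.5), (6.0, 4.0, 5.0),
                  (7.0, 3.0, 6.5), (7.6, 3.0, 6.4), (8.0, 2.8, 6.0),
                  (6.5, 3.0, 5.0), (6.2, 3.3, 5.6), (7.1, 4.4, 6.6),
                  (5.9, 2.4, 4.5)]
        table = batch_table(self._entries(params))
        assert len(table) == 10 and (table["error"] == "").all()
        for _, row in table.iterrows():
            d, r = row["d_his_asp"], row["r_mg"]
            expect = ("I" if (d < 6.5 and r > 0.6)
                      else "II" if (d > 6.5 and r < 0.6) else "ambiguous")
            assert row["group"] == expect

    def test_row_order_permutation_changes_no_values(self):
        entries = self._entries([(5.0, 3.0, 4.0), (7.6, 3.0, 6.4),
                                 (6.0, 4.0, 5.0)])
        t1 = batch_table(entries).set_index("label").sort_index()
        t2 = batch_table(entries[::-1]).set_index("label").sort_index()
        assert (t1["group"] == t2["group"]).all()
        assert np.allclose(t1["d_his_asp"], t2["d_his_asp"])

    def test_missing_mg_everywhere_flags_rows_without_crash(self):
        entries = self._entries([(5.0, 3.0, 4.0), (7.6, 3.0, 6.4)])
        for s, _, _ in entries:
            s.atoms = [a for a in s.atoms if a.element != "MG"]
        table = batch_table(entries)
        assert table["r_mg"].isna().all()
        assert (table["group"] != "").all()       # distance-only calls made

    def test_per_row_failure_recorded_and_batch_continues(self):
        entries = self._entries([(5.0, 3.0, 4.0)])
        broken, _ = make_reaction_center(6.0, 3.0, 5.0)
        broken.atoms = [a for a in broken.atoms if a.name != "OD1"]
        entries.append((broken, SPEC, "broken"))
        table = batch_table(entries)
        assert (table.loc[table["label"] == "broken", "error"] != "").all()
        assert (table.loc[table["label"] != "broken", "error"] == "").all()


def test_infeasible_fixture_geometry_raises():
    with pytest.raises(ValueError, match="triangle"):
        make_reaction_center(10.0, 1.0, 1.0)
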