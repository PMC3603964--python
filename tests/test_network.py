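"""Node network: topology, spreading law, causality, field feedback."""

import numpy as np
import pytest

from cryonet import params as P
from cryonet.iif_network import (Network, ae_spread_contribution,
                                 default_topology, node_ae_total)
from cryonet.transport import build_mesh


@pytest.fixture(scope="module")
def topo(geom):
    return default_topology(geom)


def make_network(geom, rp, mp, wp, cpa, **kw):
    return Network(default_topology(geom), geom, rp, P.NucleationParams(),
                   mp, wp, cpa, P.SpreadParams(), **kw)


class TestTopology:
    def test_region_tags_match_geometry(self, topo, geom):
        for lab in ("C", "D", "G"):
            rho, z = topo.coords[lab]
            assert (((z - geom.d_nlr) / geom.s_maj) ** 2
                    + (rho / geom.s_min) ** 2) < 1.0
            assert topo.regions[lab] == "nucleus"
        for lab in ("A", "B", "E", "F", "H", "I"):
            rho, z = topo.coords[lab]
            assert (((z - geom.d_nlr) / geom.s_maj) ** 2
                    + (rho / geom.s_min) ** 2) > 1.0
            assert topo.regions[lab] == "cytoplasm"

    def test_membrane_adjacent_nodes_inside_cell(self, topo, geom):
        for lab in ("A", "F", "I"):
            rho, z = topo.coords[lab]
            assert (z / geom.l_maj) ** 2 + (rho / geom.l_min) ** 2 < 1.0

    def test_narrated_edges_present(self, topo):
        edges = {frozenset(e) for e in topo.edges}
        for e in [("A", "B"), ("A", "F"), ("B", "C"), ("C", "D"), ("D", "G"),
                  ("B", "E"), ("F", "E")]:
            assert frozenset(e) in edges

    def test_path_from_trigger_to_far_side(self, topo):
        # BFS from A reaches I
        seen, stack = set(), ["A"]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(topo.neighbors(u))
        assert "I" in seen and len(seen) == 9


class TestSpreadLaw:
    def test_no_ice_no_spread(self):
        sp = P.SpreadParams()
        assert ae_spread_contribution(0.0, 1e-5, sp) == 0.0

    def test_zero_amplitude(self):
        sp = P.SpreadParams(Ae_sal=0.0, C_off=0.0)
        assert ae_spread_contribution(0.5, 1e-5, sp) == 0.0

    def test_hand_evaluated_value(self):
        sp = P.SpreadParams()
        assert ae_spread_contribution(0.05, 10e-6, sp) == pytest.approx(
            608.3350368585667, rel=1e-12)

    def test_decreasing_with_distance(self):
        sp = P.SpreadParams()
        vals = [ae_spread_contribution(0.1, r, sp)
                for r in (5e-6, 10e-6, 20e-6)]
        assert vals[0] > vals[1] > vals[2]

    def test_bad_distance(self):
        with pytest.raises(P.ConfigurationError):
            ae_spread_contribution(0.1, 0.0, P.SpreadParams())


class TestNodeAeTotal:
    def test_initial_areas(self, topo):
        sp = P.SpreadParams()
        x0 = {lab: 0.0 for lab in topo.coords}
        pos = {lab: np.asarray(c) for lab, c in topo.coords.items()}
        assert node_ae_total("B", topo, x0, pos, sp) == 0.0
        assert node_ae_total("A", topo, x0, pos, sp) == pytest.approx(
            sp.Ae_exo)

    def test_isolated_node_stays_zero(self, topo):
        sp = P.SpreadParams()
        lonely = default_topology(P.CellGeometry())
        lonely.edges = [e for e in lonely.edges if "I" not in e]
        x = {lab: 0.5 for lab in lonely.coords}
        pos = {lab: np.asarray(c) for lab, c in lonely.coords.items()}
        assert node_ae_total("I", lonely, x, pos, sp) == 0.0

    def test_equal_mode_uniform(self, topo):
        sp = P.SpreadParams()
        x = {lab: 0.3 for lab in topo.coords}
        pos = {lab: np.asarray(c) for lab, c in topo.coords.items()}
        for lab in topo.coords:
            assert node_ae_total(lab, topo, x, pos, sp, "equal") == sp.Ae_exo

    def test_causality_gate(self, topo):
        # with C_off = 0 a node acquires area only once a neighbour ices
        sp = P.SpreadParams()
        x = {lab: 0.0 for lab in topo.coords}
        x["A"] = 0.2
        pos = {lab: np.asarray(c) for lab, c in topo.coords.items()}
        for lab in topo.coords:
            ae = node_ae_total(lab, topo, x, pos, sp)
            if lab in ("A", "B", "F"):     # A itself + neighbours of A
                assert ae > 0
            else:
                assert ae == 0.0


class TestFeedback:
    def test_zero_increment_zero_sources(self, geom, rp, mp, wp, cpa):
        net = make_network(geom, rp, mp, wp, cpa)
        st = build_mesh(geom, (12, 12), rp, mp, 4.8, 0.142)
        d_ice = net.feedback_to_fields(np.zeros(len(net.nodes)), st)
        assert np.all(d_ice == 0.0)

    def test_single_node_localised(self, geom, rp, mp, wp, cpa):
        net = make_network(geom, rp, mp, wp, cpa)
        st = build_mesh(geom, (12, 12), rp, mp, 4.8, 0.142)
        d_x = np.zeros(len(net.nodes))
        k = [n.label for n in net.nodes].index("D")
        d_x[k] = 0.01
        d_ice = net.feedback_to_fields(d_x, st)
        cells = np.flatnonzero(d_ice > 0)
        pos_d = net.by_label("D").pos * 1e-6
        dist = np.linalg.norm(st.mesh.centroid[cells] - pos_d, axis=1)
        assert np.all(dist < 15e-6)

    def test_ice_volume_preserved(self, geom, rp, mp, wp, cpa):
        net = make_network(geom, rp, mp, wp, cpa)
        st = build_mesh(geom, (12, 12), rp, mp, 4.8, 0.142)
        owner = net.assign_cells(st.mesh)
        d_x = np.zeros(len(net.nodes))
        for k in range(len(net.nodes)):
            d_x[k] = 0.002 * (k + 1)
        d_ice = net.feedback_to_fields(d_x, st)
        expected = sum(d_x[k] * st.mesh.vol[owner == k].sum()
                       for k in range(len(net.nodes)))
        assert d_ice.sum() == pytest.approx(expected, rel=1e-8)

    def test_diagnostic_node_excluded(self, geom, rp, mp, wp, cpa):
        net = make_network(geom, rp, mp, wp, cpa,
                           extra_nodes={"CS": ("C",)},
                           fD_override={"CS": 0.3})
        cs = net.by_label("CS")
        assert cs.diagnostic and cs.f_D == 0.3
        st = build_mesh(geom, (12, 12), rp, mp, 4.8, 0.142)
        d_x = np.zeros(len(net.nodes))
        d_x[[n.label for n in net.nodes].index("CS")] = 0.5
        assert np.all(net.feedback_to_fields(d_x, st) == 0.0)
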