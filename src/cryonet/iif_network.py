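"""The intracellular ice-formation node network.

Nine labelled nodes sample the coupled transport field: A, F, I sit in the
cytoplasm against the plasma membrane, B, E, H in the cytoplasm near the
nuclear envelope, and C, D, G inside the nucleus (C proximal edge, D
centre, G distal edge).  Freezing starts from the exogenous-IIF trigger:
node A alone receives a heterogeneous nucleation area Ae_exo at t = 0;
every other node starts with Ae = 0 and acquires area only by spreading
from icing neighbours,

    Ae(i -> j) = Ae_sal * (X_i**M + C) * exp(-r_ij / d),

summed over the adjacency graph (node A adds its exogenous term).  With
C = 0 this enforces causality: a node cannot nucleate before some
neighbour carries ice.  Each node runs the diffusion-limited kinetics of
:mod:`cryonet.iif_kinetics` on its locally sampled composition, and its
ice increments are returned to the transport mesh over a Voronoi-style
partition of the cell volume among nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .free_volume import mutual_diffusion
from .iif_kinetics import (KineticNodeComposition, NodeKinetics, advance_node,
                           c_liq, supersaturation)
from .mesh import ellipse_radius, nucleus_radius
from .params import (CellGeometry, ConfigurationError, FreeVolumeCPAParams,
                     FreeVolumeWaterParams, MembraneParams, NucleationParams,
                     RegionProperties, SpreadParams)

__all__ = ["NetworkTopology", "NodeState", "Network", "default_topology",
           "ae_spread_contribution", "node_ae_total"]

#: node -> region tag of the default nine-node layout
_DEFAULT_REGIONS = {
    "A": "cytoplasm", "F": "cytoplasm", "I": "cytoplasm",
    "B": "cytoplasm", "E": "cytoplasm", "H": "cytoplasm",
    "C": "nucleus", "D": "nucleus", "G": "nucleus",
}

_DEFAULT_EDGES = [
    ("A", "B"), ("A", "F"), ("B", "C"), ("B", "E"), ("F", "E"),
    ("C", "D"), ("D", "G"), ("E", "H"), ("G", "H"), ("H", "I"),
]


@dataclass
class NetworkTopology:
    """Labelled node coordinates (um, (rho, z)), region tags and edges."""

    coords: dict
    regions: dict
    edges: list

    def neighbors(self, label):
        out = []
        for a, b in self.edges:
            if a == label:
                out.append(b)
            elif b == label:
                out.append(a)
        return out

    def validate(self):
        labels = set(self.coords)
        for a, b in self.edges:
            if a not in labels or b not in labels:
                raise ConfigurationError(f"edge ({a},{b}) references unknown node")
        # connectivity
        seen, stack = set(), [next(iter(labels))]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            stack.extend(self.neighbors(u))
        if seen != labels:
            raise ConfigurationError("network graph is not connected")


def default_topology(geom: CellGeometry) -> NetworkTopology:
    """Nine-node layout along the symmetry axis and its flanks.

    A sits on the nucleus-offset side of the membrane (the trigger side),
    the route B-C-D-G runs toward the far pole, F flanks A on the membrane,
    E and H flank the nuclear envelope, and I faces the far membrane.
    Membrane-adjacent nodes sit one boundary-film depth (a few um) inside
    the membrane, i.e. in the cytoplasm proper rather than in the thin
    layer that the osmotic efflux keeps pinned at the external liquidus.
    """
    inset = 4.0  # um, how far nodes sit inside their bounding surface
    z_prox = geom.d_nlr + geom.s_maj
    z_dist = geom.d_nlr - geom.s_maj
    th_f = np.pi / 8.0
    # F flanks the trigger on the membrane side; it sits deeper in its gap
    # (gap fraction 0.7) than A so that, like A, it samples the undercooled
    # cytoplasm proper rather than the equilibrated boundary film
    if geom.has_nucleus:
        b_f = nucleus_radius(th_f, geom)
        R_f = ellipse_radius(th_f, geom.l_maj, geom.l_min)
        r_f = b_f + 0.70 * (R_f - b_f)
    else:
        r_f = ellipse_radius(th_f, geom.l_maj, geom.l_min) - inset
    # E sits on the flank against the nuclear envelope, adjacent (and
    # roughly equidistant) to both B and F
    rho_e, z_e = 8.0, geom.d_nlr + geom.s_maj * 0.86
    coords = {
        "A": (0.0, geom.l_maj - inset),
        "B": (0.0, z_prox + 2.5),
        "C": (0.0, z_prox - inset),
        "D": (0.0, geom.d_nlr),
        "G": (0.0, z_dist + inset),
        "H": (0.0, z_dist - 4.5),
        "I": (0.0, -(geom.l_maj - inset)),
        "F": (r_f * np.sin(th_f), r_f * np.cos(th_f)),
        "E": (rho_e, z_e),
    }
    topo = NetworkTopology(coords=coords, regions=dict(_DEFAULT_REGIONS),
                           edges=list(_DEFAULT_EDGES))
    topo.validate()
    return topo


def ae_spread_contribution(X_i, r_ij, sp: SpreadParams, dt=None):
    """Nucleation-area contribution of a node with ice fraction X_i.

    The fitted spreading law is algebraic in the current ice fraction (dt
    is accepted for interface symmetry but unused): contributions vanish
    with X_i when C = 0 and decay with distance r_ij (metres).
    """
    if r_ij <= 0:
        raise ConfigurationError("internode distance must be positive")
    if X_i < 0:
        raise ValueError("ice fraction must be >= 0")
    return sp.Ae_sal * (X_i ** sp.M_exp + sp.C_off) * np.exp(-r_ij / sp.d_decay)


def node_ae_total(label, topology: NetworkTopology, x_by_label, pos_by_label,
                  sp: SpreadParams, ae_mode: str = "trigger"):
    """Total heterogeneous nucleation area available to one node.

    In the default exogenous-trigger mode every node sums spreading
    contributions from its neighbours and node A adds the exogenous area;
    in "equal" mode (the node-comparison protocol) every node is handed
    the same constant area with no spreading.
    """
    if ae_mode == "equal":
        return sp.Ae_exo
    if ae_mode == "none":
        return 0.0
    total = sp.Ae_exo if label == "A" else 0.0
    pj = pos_by_label[label]
    reg_j = topology.regions.get(label)
    for nb in topology.neighbors(label):
        r = float(np.linalg.norm(np.asarray(pj) - np.asarray(pos_by_label[nb]))) * 1e-6
        contrib = float(ae_spread_contribution(x_by_label[nb], r, sp))
        if topology.regions.get(nb) != reg_j:
            contrib *= sp.envelope_attenuation   # spreading through envelope pores
        total += contrib
    return total


# ----------------------------------------------------------------------
@dataclass
class NodeState:
    """One network node: placement, kinetics and bookkeeping."""

    label: str
    region: str
    f_D: float
    theta: float                  # polar angle of the node ray
    s_frac: float | None          # cytoplasm gap fraction (None: fixed node)
    pos: np.ndarray               # current (rho, z), um
    kin: NodeKinetics = field(default_factory=NodeKinetics)
    X_i: float = 0.0              # corrected ice volume fraction
    X_raw: float = 0.0
    Ae_total: float = 0.0
    C_j: float = 0.0
    comp: KineticNodeComposition | None = None
    diagnostic: bool = False      # excluded from field feedback


class Network:
    """Node collection coupled to the transport field."""

    def __init__(self, topology: NetworkTopology, geom: CellGeometry,
                 rp: RegionProperties, nucl: NucleationParams,
                 mp: MembraneParams, wp: FreeVolumeWaterParams,
                 cpa: FreeVolumeCPAParams, sp: SpreadParams,
                 ae_mode: str = "trigger", fD_override: dict | None = None,
                 extra_nodes: dict | None = None, max_cohorts: int = 400):
        self.topology = topology
        self.geom = geom
        self.rp = rp
        self.nucl = nucl
        self.mp = mp
        self.wp = wp
        self.cpa = cpa
        self.sp = sp
        self.ae_mode = ae_mode
        self.max_cohorts = max_cohorts
        fD_override = fD_override or {}
        self.nodes: list[NodeState] = []
        specs = [(lab, topology.coords[lab], topology.regions[lab], False)
                 for lab in topology.coords]
        for lab, (tmpl,) in (extra_nodes or {}).items():
            specs.append((lab, topology.coords[tmpl], topology.regions[tmpl], True))
        for lab, (rho, z), region, diag in specs:
            theta = float(np.arctan2(abs(rho), z))
            r = float(np.hypot(rho, z))
            b = float(nucleus_radius(theta, geom)) if geom.has_nucleus else 0.0
            big_r = float(ellipse_radius(theta, geom.l_maj, geom.l_min))
            s = None if (geom.has_nucleus and r <= b) else (r - b) / (big_r - b)
            f_d = fD_override.get(lab, rp.f_D(region if geom.has_nucleus else "cytoplasm"))
            self.nodes.append(NodeState(label=lab, region=region, f_D=f_d,
                                        theta=theta, s_frac=s,
                                        pos=np.array([rho, z]), diagnostic=diag))

    def by_label(self, label) -> NodeState:
        for n in self.nodes:
            if n.label == label:
                return n
        raise KeyError(label)

    # -------------------- geometry coupling --------------------
    def update_positions(self, mesh):
        """Track the shrinking boundary: cytoplasm nodes keep their gap fraction."""
        for n in self.nodes:
            if n.s_frac is None:
                continue
            big_r = float(np.interp(n.theta, mesh.theta, mesh.R)) * 1e6
            b = float(np.interp(n.theta, mesh.theta, mesh.b)) * 1e6
            r = b + n.s_frac * (big_r - b)
            n.pos = np.array([r * np.sin(n.theta), r * np.cos(n.theta)])

    def positions(self):
        return {n.label: n.pos for n in self.nodes}

    def sample_points(self):
        return np.array([n.pos for n in self.nodes]) * 1e-6

    # -------------------- kinetics step --------------------
    def set_compositions(self, samples, T):
        """Install sampled compositions; D_eff from local free-volume theory."""
        for k, n in enumerate(self.nodes):
            x_vw = float(np.clip(samples["x_vw"][k], 0.0, 1.0))
            d_bulk = float(mutual_diffusion(T, x_vw, self.wp, self.cpa))
            n.comp = KineticNodeComposition(
                c_w=float(np.clip(samples["c_w"][k], 0.0, 1.0 / self.mp.nu_w)),
                c_s=float(np.clip(samples["c_s"][k], 0.0, 1.0 / self.mp.nu_s)),
                c_g=float(np.clip(samples["c_g"][k], 0.0, 1.0 / self.mp.nu_g)),
                X_vice=n.X_i,
                X_vb=float(np.clip(samples["X_vb"][k], 0.0, 1.0)),
                D_eff=n.f_D * d_bulk,
                gamma_local=float(np.clip(samples["phi_liq"][k], 0.0, 1.0)))

    def step(self, T, dt, t_now):
        """Advance all node kinetics by dt; returns per-node ice increments.

        Each node's heterogeneous area is refreshed from the current ice
        fractions, the cohort system is advanced by RK4, and the raw
        growth is passed through the differential soft-impingement factor
        and capped by the water actually present at the node.
        """
        x_by = {n.label: n.X_i for n in self.nodes}
        pos_by = self.positions()
        d_x = np.zeros(len(self.nodes))
        for k, n in enumerate(self.nodes):
            n.Ae_total = node_ae_total(n.label, self.topology, x_by, pos_by,
                                       self.sp, self.ae_mode)
            comp = n.comp
            if comp is None:
                continue
            dx_raw = advance_node(n.kin, comp, T, n.Ae_total, dt, self.nucl,
                                  self.mp, t_now=t_now)
            n.kin.merge(self.max_cohorts)
            n.C_j = n.kin.C_j
            if dx_raw <= 0:
                n.X_raw = max(n.X_raw, 0.0)
                continue
            gamma_t = supersaturation(comp, T, self.mp) if T < self.mp.T_mw else 0.0
            if gamma_t <= 0:
                n.X_raw += dx_raw
                continue
            x_sat = gamma_t / (1.0 + gamma_t)
            soft = float(np.exp(-min(n.X_raw / x_sat, 700.0)))
            dx = soft * dx_raw * comp.gamma_local
            cl = c_liq(T, comp, self.mp)
            freezable = comp.gamma_local * self.mp.nu_w * max(comp.c_w - cl, 0.0)
            dx = min(dx, freezable)
            n.X_raw += dx_raw
            n.X_i = min(n.X_i + dx, 1.0 - comp.X_vb)
            d_x[k] = dx
        return d_x

    # -------------------- field feedback --------------------
    def assign_cells(self, mesh):
        """Voronoi-style partition: each mesh cell belongs to its nearest node."""
        pts = mesh.centroid
        active = [k for k, n in enumerate(self.nodes) if not n.diagnostic]
        npos = np.array([self.nodes[k].pos for k in active]) * 1e-6
        d2 = ((pts[:, None, :] - npos[None, :, :]) ** 2).sum(axis=2)
        return np.array(active)[np.argmin(d2, axis=1)]

    def feedback_to_fields(self, d_x, state):
        """Distribute node ice increments to mesh cells (volume preserving).

        Each node's increment (its fraction times its control volume) is
        spread over the node's cells proportionally to available water.
        """
        mesh = state.mesh
        owner = self.assign_cells(mesh)
        d_ice = np.zeros(mesh.n_cells)
        water_vol = state.n_w * state.mp.nu_w
        for k, n in enumerate(self.nodes):
            if n.diagnostic or d_x[k] <= 0:
                continue
            cells = np.flatnonzero(owner == k)
            if cells.size == 0:
                continue
            v_node = mesh.vol[cells].sum()
            target = d_x[k] * v_node
            wgt = water_vol[cells]
            tot = wgt.sum()
            if tot <= 0:
                continue
            add = target * wgt / tot
            cap = 0.9 * water_vol[cells]
            for _ in range(3):      # renormalise around capped cells
                over = add > cap
                if not over.any():
                    break
                excess = float((add[over] - cap[over]).sum())
                add[over] = cap[over]
                room = np.maximum(cap - add, 0.0)
                if room.sum() <= 0:
                    break
                add = add + excess * room / room.sum()
            d_ice[cells] += np.minimum(add, cap)
        return d_ice
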