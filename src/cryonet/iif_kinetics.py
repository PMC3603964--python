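"""Diffusion-limited intracellular ice nucleation and crystal growth.

Per network node, ice appears through classical nucleation (homogeneous in
the bulk liquid, heterogeneous on catalysing area Ae) and grows under
diffusion limitation:

  nucleation    J = Omega * (c_w nu_w) * exp(-kappa' / (T^3 (T_m - T)^2))
  crystal count dC_j/dt = [J_HOM + J_HET * Ae] * (1 - X_vice - X_vb)
  growth        dr_c/dt = alpha * D_eff * S / r_c,  S = gamma_t/(1+gamma_t)
  supersat      gamma_t = C_inf / C_liq(T) - 1

kappa' carries units K^5 so the Boltzmann-like exponent is dimensionless;
the (c_w nu_w) factor is the normalised water concentration of the local
solution.  Crystals nucleated in one time step form a cohort of common
radius; the local raw ice fraction is the cohort sum of n * (4/3) pi r^3,
and soft impingement (growing crystals competing for the same
supersaturated water) is corrected by an Avrami-type saturating transform.

Growth inherits the free-volume diffusivity, so as the residual solution
concentrates and cools toward its glass transition D_eff -> 0 and ice
growth arrests -- the plateau each node shows at deep supercooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .membrane import liquidus_mole_fraction, melting_point
from .params import MembraneParams, NucleationParams

__all__ = [
    "CrystalCohort", "KineticNodeComposition", "nucleation_rates",
    "crystal_growth_rate", "crystal_count_rate", "ice_fraction",
    "impingement_correction", "supersaturation", "c_liq",
    "advance_node", "NodeKinetics",
]


@dataclass
class CrystalCohort:
    """Crystals nucleated together: birth time, common radius, number density."""

    t_i: float            # s
    r_c: float            # m
    n: float              # m^-3


@dataclass
class KineticNodeComposition:
    """Local solution state handed from the transport model to a node."""

    c_w: float            # mol/m^3 liquid
    c_s: float
    c_g: float
    X_vice: float
    X_vb: float
    D_eff: float          # m^2/s
    gamma_local: float    # liquid (pore) fraction

    @property
    def c_total(self):
        return self.c_w + self.c_s + self.c_g


def _undercooling(T, comp: KineticNodeComposition, mp: MembraneParams):
    """Local undercooling from the node's own water mole fraction."""
    from .params import R_GAS
    osm = mp.salt_dissociation * comp.c_s + comp.c_g
    x_w = comp.c_w / max(comp.c_w + osm, 1e-300)
    inv_tm = 1.0 / mp.T_mw - (R_GAS / mp.dHf) * np.log(max(x_w, 1e-300))
    t_m = 1.0 / inv_tm
    return t_m - T, t_m


def nucleation_rates(T, comp: KineticNodeComposition, Ae_local,
                     p: NucleationParams, mp: MembraneParams):
    """(J_HOM per volume, J_HET per volume) at temperature T.

    Both vanish at zero undercooling; the heterogeneous rate is linear in
    the catalysing area Ae_local (m^2 per m^3).
    """
    if Ae_local < 0:
        raise ValueError("Ae_local must be >= 0")
    dT, _ = _undercooling(T, comp, mp)
    if dT <= 0:
        return 0.0, 0.0
    cfac = min(comp.c_w * mp.nu_w, 1.0)
    arg = 1.0 / (T ** 3 * dT ** 2)
    j_hom = p.omega_hom * cfac * np.exp(-p.kappa_hom * arg)
    j_het = p.omega_het * cfac * np.exp(-p.kappa_het * arg) * Ae_local
    return float(j_hom), float(j_het)


def crystal_count_rate(T, comp: KineticNodeComposition, Ae_local,
                       p: NucleationParams, mp: MembraneParams):
    """dC_j/dt: nucleation throttled by the remaining free volume."""
    j_hom, j_het = nucleation_rates(T, comp, Ae_local, p, mp)
    free = max(1.0 - comp.X_vice - comp.X_vb, 0.0)
    return (j_hom + j_het) * free


def c_liq(T, comp: KineticNodeComposition, mp: MembraneParams):
    """Equilibrium (liquidus) water concentration at T, mol/m^3 liquid.

    Keeps the local salt:glycerol ratio and finds the water content whose
    mole fraction sits on the liquidus; undefined above the melting point
    of pure water.
    """
    if T > mp.T_mw:
        raise ValueError("liquidus undefined above the melting point of water")
    x_w = float(liquidus_mole_fraction(T, mp))
    osm = mp.salt_dissociation * comp.c_s + comp.c_g
    vol_solute = comp.c_s * mp.nu_s + comp.c_g * mp.nu_g
    if osm <= 0:
        return 1.0 / mp.nu_w
    # water moles per current-liquid-volume basis at equilibrium
    n_w = osm * x_w / max(1.0 - x_w, 1e-12)
    scale = 1.0 / max(n_w * mp.nu_w + vol_solute, 1e-300)
    return n_w * scale


def supersaturation(comp: KineticNodeComposition, T, mp: MembraneParams):
    """gamma_t = C_inf/C_liq - 1 (zero at equilibrium, grows with excess water)."""
    cl = c_liq(T, comp, mp)
    return max(comp.c_w / max(cl, 1e-300) - 1.0, 0.0)


def crystal_growth_rate(cohort_r, comp: KineticNodeComposition, T,
                        p: NucleationParams, mp: MembraneParams,
                        gamma_t: float | None = None):
    """Diffusion-limited radius growth dr_c/dt (m/s) for cohort radii."""
    dT, _ = _undercooling(T, comp, mp)
    r = np.maximum(np.asarray(cohort_r, dtype=float), p.r_seed)
    if dT <= 0 or comp.D_eff <= 0:
        return np.zeros_like(r)
    if gamma_t is None:
        gamma_t = supersaturation(comp, T, mp)
    drive = gamma_t / (1.0 + gamma_t)
    return p.alpha_growth * comp.D_eff * drive / r


def ice_fraction(cohorts, comp=None):
    """Raw (uncorrected) ice volume fraction from the cohort history."""
    if isinstance(cohorts, NodeKinetics):
        return float(np.sum(cohorts.n * 4.0 / 3.0 * np.pi * cohorts.r ** 3))
    return float(sum(c.n * 4.0 / 3.0 * np.pi * c.r_c ** 3 for c in cohorts))


def impingement_correction(X_raw, gamma_t):
    """Soft-impingement (Avrami-type) correction of the raw ice fraction.

    The saturation limit gamma_t/(1+gamma_t) is the freezable share of the
    local liquid; the corrected fraction rises monotonically with X_raw and
    never exceeds it.
    """
    if X_raw < 0:
        raise ValueError("X_raw must be >= 0")
    if gamma_t <= 0:
        return 0.0
    x_sat = gamma_t / (1.0 + gamma_t)
    return x_sat * (1.0 - np.exp(-X_raw / x_sat))


# ----------------------------------------------------------------------
@dataclass
class NodeKinetics:
    """Mutable cohort system of one node (radii, counts, crystal density)."""

    r: np.ndarray = field(default_factory=lambda: np.empty(0))
    n: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_i: np.ndarray = field(default_factory=lambda: np.empty(0))
    C_j: float = 0.0

    def merge(self, max_cohorts: int):
        """Merge adjacent cohorts (volume- and count-conserving)."""
        if self.r.size <= max_cohorts:
            return
        k = self.r.size // 2 * 2
        r, n, t = self.r[:k], self.n[:k], self.t_i[:k]
        n2 = n[0::2] + n[1::2]
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = ((n[0::2] * r[0::2] ** 3 + n[1::2] * r[1::2] ** 3)
                  / np.maximum(n2, 1e-300)) ** (1.0 / 3.0)
        t2 = 0.5 * (t[0::2] + t[1::2])
        self.r = np.concatenate([r2, self.r[k:]])
        self.n = np.concatenate([n2, self.n[k:]])
        self.t_i = np.concatenate([t2, self.t_i[k:]])


def advance_node(node: NodeKinetics, comp: KineticNodeComposition, T, Ae,
                 dt, p: NucleationParams, mp: MembraneParams,
                 t_now: float = 0.0, method: str = "rk4",
                 seed_new_cohort: bool = True):
    """Advance one node's cohort system by dt (classical RK4 by default).

    The state vector is (squared cohort radii, crystal count C_j);
    composition and Ae are frozen over the step (they evolve on the slower
    transport time scale).  The radius equation dr/dt = alpha D S / r is
    integrated in the variable u = r^2, whose rate 2 alpha D S is regular
    at the seed radius (the 1/r form is stiff there and overshoots badly
    under any explicit scheme).  A new cohort with the step's nucleation
    increment is seeded at the critical radius afterwards.  Returns the
    raw ice-fraction increase.
    """
    x0 = ice_fraction(node)
    gamma_t = supersaturation(comp, T, mp)

    def rate(u, c_count):
        r = np.sqrt(np.maximum(u, 0.0))
        x_now = float(np.sum(node.n * 4.0 / 3.0 * np.pi * r ** 3))
        comp_now = KineticNodeComposition(
            c_w=comp.c_w, c_s=comp.c_s, c_g=comp.c_g,
            X_vice=min(comp.X_vice + (x_now - x0), 1.0), X_vb=comp.X_vb,
            D_eff=comp.D_eff, gamma_local=comp.gamma_local)
        du = 2.0 * r * crystal_growth_rate(r, comp_now, T, p, mp,
                                           gamma_t=gamma_t)
        dc = crystal_count_rate(T, comp_now, Ae, p, mp)
        return du, dc

    u0, c0 = node.r ** 2, node.C_j
    if method == "euler":
        du, dc = rate(u0, c0)
        u_new = u0 + dt * du
        node.C_j = c0 + dt * dc
    else:
        k1u, k1c = rate(u0, c0)
        k2u, k2c = rate(u0 + 0.5 * dt * k1u, c0 + 0.5 * dt * k1c)
        k3u, k3c = rate(u0 + 0.5 * dt * k2u, c0 + 0.5 * dt * k2c)
        k4u, k4c = rate(u0 + dt * k3u, c0 + dt * k3c)
        u_new = u0 + dt / 6.0 * (k1u + 2 * k2u + 2 * k3u + k4u)
        node.C_j = c0 + dt / 6.0 * (k1c + 2 * k2c + 2 * k3c + k4c)
    node.r = np.sqrt(np.maximum(u_new, 0.0))
    d_count = node.C_j - c0
    if seed_new_cohort and d_count > 1.0:
        node.r = np.append(node.r, p.r_seed)
        node.n = np.append(node.n, d_count)
        node.t_i = np.append(node.t_i, t_now)
    return ice_fraction(node) - x0
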