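"""Porous-media species transport on the moving cell mesh.

The liquid phase (free water + dissolved glycerol and salt) fills the pore
fraction of each region; the remainder (cytoskeleton, organelles, bound
water, and any ice) is inactive volume.  Each mesh cell carries conserved
amounts -- moles of water/glycerol/salt plus inactive and ice volumes --
and all concentrations are derived, so membrane efflux, icing and mesh
motion close an exact mole ledger.

Diffusion is solved implicitly (backward Euler, unconditionally stable)
with two-point fluxes driven by liquid-phase concentration differences;
face transmissibilities use the harmonic mean of phi*D_eff, which makes
region contrasts (cytoplasm 0.3 vs nucleus 0.78 modification factors) and
the nuclear-envelope film resistance enter naturally.  The scheme conserves
every species to machine precision in the absence of sources.

Boundary motion is Lagrangian layer rescaling (mesh.Mesh.move_membrane)
followed by a conservative 1-D remap of cell contents along each ray in
cumulative-volume coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .free_volume import envelope_transfer_coefficient, mutual_diffusion
from .mesh import Mesh, REGION_NUC
from .params import (CellGeometry, ConfigurationError, FreeVolumeCPAParams,
                     FreeVolumeWaterParams, MembraneParams, RegionProperties)

__all__ = ["FieldState", "build_mesh", "initial_state", "diffusion_step",
           "apply_membrane_source", "apply_iif_source", "move_boundary",
           "sample_at_points", "mass_inventory"]

_SAMPLE_FIELDS = ("c_w", "c_g", "c_s", "x_vw", "phi_liq", "X_vb", "X_vice")


@dataclass
class FieldState:
    """Conserved cell contents plus protocol time/temperature."""

    mesh: Mesh
    n_w: np.ndarray          # mol water per cell
    n_g: np.ndarray          # mol glycerol
    n_s: np.ndarray          # mol salt
    V_b: np.ndarray          # m^3 inactive (non-ice) volume
    V_ice: np.ndarray        # m^3 ice volume
    mp: MembraneParams
    T: float = 273.15
    t: float = 0.0
    efflux_mol: float = 0.0
    initial_water_mol: float = 0.0

    # -------------------- derived fields --------------------
    @property
    def V_liq(self):
        return (self.n_w * self.mp.nu_w + self.n_g * self.mp.nu_g
                + self.n_s * self.mp.nu_s)

    @property
    def phi_liq(self):
        return self.V_liq / self.mesh.vol

    @property
    def c_w(self):
        """Liquid-phase water concentration, mol/m^3."""
        return self.n_w / np.maximum(self.V_liq, 1e-300)

    @property
    def c_g(self):
        return self.n_g / np.maximum(self.V_liq, 1e-300)

    @property
    def c_s(self):
        return self.n_s / np.maximum(self.V_liq, 1e-300)

    @property
    def x_vw(self):
        """Water volume fraction of the liquid (glycerol basis)."""
        vw = self.n_w * self.mp.nu_w
        return vw / np.maximum(vw + self.n_g * self.mp.nu_g, 1e-300)

    @property
    def X_vb(self):
        return self.V_b / self.mesh.vol

    @property
    def X_vice(self):
        return self.V_ice / self.mesh.vol

    def field(self, name):
        extra = self.__dict__.get("extra_fields")
        if extra and name in extra:
            return extra[name]
        return getattr(self, name)

    def copy(self) -> "FieldState":
        import copy as _copy
        new = FieldState(mesh=_copy.deepcopy(self.mesh),
                         n_w=self.n_w.copy(), n_g=self.n_g.copy(),
                         n_s=self.n_s.copy(), V_b=self.V_b.copy(),
                         V_ice=self.V_ice.copy(), mp=self.mp,
                         T=self.T, t=self.t, efflux_mol=self.efflux_mol,
                         initial_water_mol=self.initial_water_mol)
        return new


def initial_state(mesh: Mesh, rp: RegionProperties, mp: MembraneParams,
                  cpa_molar: float, salt_molar: float,
                  T0: float = 273.15) -> FieldState:
    """Uniform loading: every region's liquid holds the loading solution."""
    gamma = np.where(mesh.region == REGION_NUC, rp.gamma_nuc, rp.gamma_cyto)
    v_liq = gamma * mesh.vol
    c_g0 = cpa_molar * 1e3
    c_s0 = salt_molar * 1e3
    c_w0 = (1.0 - c_g0 * mp.nu_g - c_s0 * mp.nu_s) / mp.nu_w
    if c_w0 <= 0:
        raise ConfigurationError("loading solution has no water")
    st = FieldState(mesh=mesh,
                    n_w=c_w0 * v_liq, n_g=c_g0 * v_liq, n_s=c_s0 * v_liq,
                    V_b=(1.0 - gamma) * mesh.vol,
                    V_ice=np.zeros(mesh.n_cells), mp=mp, T=T0)
    st.initial_water_mol = float(st.n_w.sum())
    return st


def build_mesh(geom: CellGeometry, resolution, rp: RegionProperties,
               mp: MembraneParams, cpa_molar: float, salt_molar: float,
               T0: float = 273.15) -> FieldState:
    """Mesh the geometry and return the uniformly loaded initial state."""
    n_r, n_theta = (resolution, resolution) if np.isscalar(resolution) else resolution
    mesh = Mesh.axisymmetric(geom, n_r, n_theta)
    return initial_state(mesh, rp, mp, cpa_molar, salt_molar, T0)


# ----------------------------------------------------------------------
def _transmissibilities(state: FieldState, dcoef, rp: RegionProperties | None,
                        wp=None, cpa=None):
    """Face transmissibilities tau (m^3/s per unit concentration)."""
    m = state.mesh
    phi_d = state.phi_liq * np.asarray(dcoef, dtype=float)
    a, b = phi_d[m.face_a], phi_d[m.face_b]
    harm = np.where(a + b > 0, 2.0 * a * b / np.maximum(a + b, 1e-300), 0.0)
    tau = m.face_area * harm / m.face_dist
    if rp is not None and np.any(m.face_envelope):
        env = m.face_envelope
        if wp is not None:
            x_face = 0.5 * (state.x_vw[m.face_a[env]] + state.x_vw[m.face_b[env]])
            d_bulk = mutual_diffusion(state.T, x_face, wp, cpa)
        else:  # fall back on the effective coefficient at the face
            d_bulk = 0.5 * (np.asarray(dcoef)[m.face_a[env]]
                            + np.asarray(dcoef)[m.face_b[env]])
        h = envelope_transfer_coefficient(d_bulk, rp)
        g_env = m.face_area[env] * h          # film conductance
        with np.errstate(divide="ignore"):
            tau_env = np.where((tau[env] > 0) & (g_env > 0),
                               1.0 / (1.0 / np.maximum(tau[env], 1e-300)
                                      + 1.0 / np.maximum(g_env, 1e-300)),
                               0.0)
        tau = tau.copy()
        tau[env] = tau_env
    return tau


def diffusion_step(state: FieldState, dt: float, dcoef,
                   rp: RegionProperties | None = None,
                   wp: FreeVolumeWaterParams | None = None,
                   cpa: FreeVolumeCPAParams | None = None,
                   salt_scale: float = 1.0, robin: dict | None = None):
    """Implicit diffusion update of all three species (in place).

    ``dcoef`` is the per-cell effective mutual diffusivity (m^2/s, already
    carrying the regional modification factor).  Fluxes are driven by
    liquid-phase concentrations; with uniform composition and no membrane
    term the step is an exact no-op.

    ``robin``, when given, couples the membrane water efflux implicitly as
    a linearised Robin boundary term on the water species:
    ``{"J0": flux at c0 (m/s, per column), "dJdc": slope, "c0": linearis.
    point (mol/m^3)}``.  Solving flux and film concentration together makes
    the dehydration rate insensitive to how finely the boundary film is
    meshed.  Returns the per-column water removal in moles (zeros without
    a membrane term).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    dcoef = np.asarray(dcoef, dtype=float)
    if np.any(dcoef < 0):
        raise ValueError("diffusivities must be >= 0")
    m = state.mesh
    tau = _transmissibilities(state, dcoef, rp, wp, cpa)
    removal = np.zeros(m.mem_cell.size)
    if not np.any(tau > 0) and robin is None:
        return removal
    v_liq = np.maximum(state.V_liq, 1e-9 * m.vol)
    fa, fb = m.face_a, m.face_b
    n = m.n_cells

    def base_matrix(tau_eff, extra_diag=None):
        diag = np.ones(n)
        np.add.at(diag, fa, dt * tau_eff / v_liq[fa])
        np.add.at(diag, fb, dt * tau_eff / v_liq[fb])
        if extra_diag is not None:
            diag = diag + extra_diag
        rows = np.concatenate([np.arange(n), fa, fb])
        cols = np.concatenate([np.arange(n), fb, fa])
        data = np.concatenate([diag, -dt * tau_eff / v_liq[fb],
                               -dt * tau_eff / v_liq[fa]])
        return sp.csc_matrix((data, (rows, cols)), shape=(n, n))

    if robin is not None:
        bc = m.mem_cell
        area = m.mem_area
        j0 = np.asarray(robin["J0"], dtype=float)
        jp = np.asarray(robin["dJdc"], dtype=float)
        c0 = np.asarray(robin["c0"], dtype=float)
        nu_w = state.mp.nu_w
        extra = np.zeros(n)
        extra[bc] = dt * area * jp / (nu_w * v_liq[bc])
        rhs_w = state.n_w.copy()
        rhs_w[bc] -= dt * area * (j0 - jp * c0) / nu_w
        A_w = base_matrix(tau, extra)
        n_w_new = spla.splu(A_w).solve(rhs_w)
        c_new = n_w_new[bc] / v_liq[bc]
        flux_mol = dt * area * (j0 + jp * (c_new - c0)) / nu_w
        removal = np.maximum(flux_mol, 0.0)
        # undo any spurious influx from the linearisation
        n_w_new[bc] = n_w_new[bc] + np.minimum(flux_mol, 0.0)
        n_w_new = np.maximum(n_w_new, 0.0)
        before = float(state.n_w.sum())
        state.n_w = n_w_new
        state.efflux_mol += before - float(n_w_new.sum())
        lu = spla.splu(base_matrix(tau))
        state.n_g = lu.solve(state.n_g)
        if salt_scale == 1.0:
            state.n_s = lu.solve(state.n_s)
        else:
            state.n_s = spla.splu(base_matrix(tau * salt_scale)).solve(state.n_s)
        return removal

    lu = spla.splu(base_matrix(tau))
    state.n_w = lu.solve(state.n_w)
    state.n_g = lu.solve(state.n_g)
    if salt_scale == 1.0:
        state.n_s = lu.solve(state.n_s)
    else:
        state.n_s = spla.splu(base_matrix(tau * salt_scale)).solve(state.n_s)
    return removal


def apply_membrane_source(state: FieldState, J_w, dt: float,
                          x_w_eq: float | None = None):
    """Remove water through membrane patches; returns the realised flux.

    ``J_w`` is the per-column outward water volume flux (m/s).  The
    removal from each boundary cell is capped at the amount that brings
    its liquid to the external equilibrium water mole fraction ``x_w_eq``
    (osmotic efflux stops at equilibrium; without the cap a thin boundary
    cell can be ratcheted far past the liquidus in discrete steps).  The
    realised fluxes, used for the boundary speed, are returned.  Solutes
    never cross.
    """
    m = state.mesh
    mp = state.mp
    J_w = np.asarray(J_w, dtype=float)
    dN = J_w * m.mem_area * dt / mp.nu_w            # mol water out per patch
    bc = m.mem_cell
    if x_w_eq is not None and x_w_eq < 1.0:
        osm = mp.salt_dissociation * state.n_s[bc] + state.n_g[bc]
        n_w_eq = osm * x_w_eq / (1.0 - x_w_eq)
        avail = np.maximum(state.n_w[bc] - n_w_eq, 0.0)
    else:
        avail = 0.5 * state.n_w[bc]
    scale = np.where(dN > avail,
                     np.where(dN > 0, avail / np.maximum(dN, 1e-300), 1.0), 1.0)
    dN = dN * scale
    state.n_w[bc] -= dN
    state.efflux_mol += float(dN.sum())
    return J_w * scale


def apply_iif_source(state: FieldState, d_ice, dt: float | None = None):
    """Convert local free water into ice (volume per cell, m^3).

    Implements the water sink of the governing equation: icing removes
    d_ice/nu_w moles of water from the liquid and books the same volume as
    ice (density change neglected; ice counts as inactive volume).
    """
    d_ice = np.asarray(d_ice, dtype=float)
    if np.any(d_ice < -1e-30):
        raise ValueError("ice increments must be >= 0")
    d_mol = d_ice / state.mp.nu_w
    over = d_mol > state.n_w
    if np.any(over):
        raise ValueError("ice increment exceeds available water")
    state.n_w = state.n_w - d_mol
    state.V_ice = state.V_ice + d_mol * state.mp.nu_w
    return state


def move_boundary(state: FieldState, v_s, dt: float):
    """Advance the membrane inward at v_s and conservatively remap contents."""
    m = state.mesh
    old_vol, new_vol = m.move_membrane(v_s, dt)
    i0 = m.n_nuc
    if i0 >= m.n_r:
        return state
    arrays = [state.n_w, state.n_g, state.n_s, state.V_b, state.V_ice]
    nt, nc = m.n_t, m.n_r - i0
    vo = old_vol[i0:, :].T            # (nt, nc)
    vn = new_vol[i0:, :].T
    co = np.concatenate([np.zeros((nt, 1)), np.cumsum(vo, axis=1)], axis=1)
    cn = np.concatenate([np.zeros((nt, 1)), np.cumsum(vn, axis=1)], axis=1)
    co = co / co[:, -1:]
    cn = cn / cn[:, -1:]
    lo = np.maximum(cn[:, :-1, None], co[:, None, :-1])
    hi = np.minimum(cn[:, 1:, None], co[:, None, 1:])
    w = np.clip(hi - lo, 0.0, None)               # (nt, nc_new, nc_old)
    dxo = np.maximum(co[:, 1:] - co[:, :-1], 1e-300)
    for q in arrays:
        block = q.reshape(m.n_r, nt)[i0:, :].T    # (nt, nc)
        newb = np.einsum("tno,to->tn", w, block / dxo)
        q.reshape(m.n_r, nt)[i0:, :] = newb.T
    return state


def sample_at_points(state: FieldState, points, order: int = 3,
                     fields=_SAMPLE_FIELDS, k_neighbors: int | None = None,
                     clip_to_neighbors: bool = False):
    """Interpolate cell fields at arbitrary interior points.

    Order 0 returns the nearest cell's values; orders 1-3 fit a local
    weighted least-squares polynomial of that total degree over the nearest
    centroids, which reproduces polynomial fields of matching degree
    exactly.  On axisymmetric meshes the stencil is mirrored across the
    symmetry axis (fields are even in rho), which keeps on-axis and
    near-boundary fits well posed.  ``clip_to_neighbors`` bounds each
    result by the local data range -- the monotone safeguard used for the
    field-to-network coupling, where extrapolation overshoot across the
    icing front would be amplified by the nucleation kinetics.  Points
    outside the current membrane raise LookupError.
    """
    m = state.mesh
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    centroids = m.centroid
    cell_of = np.arange(m.n_cells)
    if m.kind == "axisym":
        r = np.hypot(pts[:, 0], pts[:, 1])
        th = np.arctan2(np.abs(pts[:, 0]), pts[:, 1])
        R_at = np.interp(th, m.theta, m.R)
        if np.any(r > R_at * (1.0 + 1e-6) + 1e-12):
            raise LookupError("sample point outside the cell boundary")
        mirrored = centroids * np.array([-1.0, 1.0])
        centroids = np.vstack([centroids, mirrored])
        cell_of = np.concatenate([cell_of, cell_of])
    data = {name: state.field(name) for name in fields}
    tree = cKDTree(centroids)
    out = {name: np.empty(len(pts)) for name in fields}
    if order == 0:
        _, idx = tree.query(pts, k=1)
        for name in fields:
            out[name] = data[name][cell_of[idx]]
        return out
    ncoef_max = (order + 1) * (order + 2) // 2
    k = k_neighbors or min(max(3 * ncoef_max, 16), centroids.shape[0])
    dist, idx = tree.query(pts, k=k)
    for p in range(len(pts)):
        nb = cell_of[idx[p]]
        h = max(float(np.mean(dist[p])), 1e-300)
        d = (centroids[idx[p]] - pts[p]) / h
        wgt = np.sqrt(1.0 / (1.0 + (dist[p] / h) ** 3))
        # adaptively reduce the order where the local stencil is one-sided
        # or degenerate (e.g. against the moving boundary)
        for deg in range(order, 0, -1):
            cols = [d[:, 0] ** ix * d[:, 1] ** iy
                    for ix in range(deg + 1) for iy in range(deg + 1 - ix)]
            A = np.stack(cols, axis=1) * wgt[:, None]
            if deg == 1 or np.linalg.cond(A) < 1e7:
                break
        for name in fields:
            vals = data[name][nb]
            coef = np.linalg.lstsq(A, vals * wgt, rcond=None)[0]
            est = coef[0]               # basis value at the point itself
            if clip_to_neighbors:
                est = float(np.clip(est, vals.min(), vals.max()))
            out[name][p] = est
    return out


def mass_inventory(state: FieldState) -> dict:
    """Per-species totals and the water ledger.

    The ledger closes when remaining + ice-bound + effluxed water equals
    the initial loading.
    """
    ice_mol = float(state.V_ice.sum() / state.mp.nu_w)
    water = float(state.n_w.sum())
    total = water + ice_mol + state.efflux_mol
    init = state.initial_water_mol or total
    return {
        "water_mol": water,
        "ice_mol": ice_mol,
        "efflux_mol": state.efflux_mol,
        "glycerol_mol": float(state.n_g.sum()),
        "salt_mol": float(state.n_s.sum()),
        "initial_water_mol": init,
        "ledger_residual": (total - init) / init,
    }
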