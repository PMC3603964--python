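"""Plasma-membrane water transport and the extracellular liquidus state.

During freezing the extracellular solution is in equilibrium with external
ice, so its water activity is pinned to the liquidus; the intracellular
solution lags behind, and the chemical-potential difference drives osmotic
water efflux through the semi-permeable membrane:

    J_w = L_p(T) * (R T / nu_w) * [ln a_w(in) - ln a_w(ext)]     (m/s)

with ln a_w approximated by the mole-fraction of water (ideal dilute
solution, salt dissociating into ``salt_dissociation`` osmotically active
species) and, for an ice-equilibrated bath,

    ln a_w(ext) = (dHf / R) * (1/T_mw - 1/T).

The membrane passes water only: glycerol was loaded before freezing and
salt is non-permeating on the freezing time scale.  The local membrane
patch recedes along its inward normal at v_s = J_w (water volume lost per
unit area per unit time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import R_GAS, MembraneParams

__all__ = [
    "ExtracellularState", "permeability", "ln_water_activity",
    "water_flux", "boundary_speed", "melting_point", "liquidus_mole_fraction",
    "extracellular_state",
]


@dataclass
class ExtracellularState:
    """Composition of the unfrozen extracellular solution (per m^3 liquid)."""

    c_salt_ext: float       # mol/m^3
    c_gly_ext: float        # mol/m^3
    unfrozen_fraction: float = 1.0


def permeability(T, mp: MembraneParams):
    """Arrhenius membrane water permeability L_p(T), m^2 s/kg."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive")
    return mp.Lpg_ref * np.exp(-mp.E_Lp / R_GAS * (1.0 / T - 1.0 / mp.T_ref))


def ln_water_activity(c_w, c_s, c_g, mp: MembraneParams):
    """ln a_w of a solution given liquid-phase concentrations (mol/m^3)."""
    c_w = np.asarray(c_w, dtype=float)
    if np.any(c_w < 0) or np.any(np.asarray(c_s) < 0) or np.any(np.asarray(c_g) < 0):
        raise ValueError("concentrations must be non-negative")
    osm = mp.salt_dissociation * np.asarray(c_s, dtype=float) + np.asarray(c_g, dtype=float)
    x_w = c_w / np.maximum(c_w + osm, 1e-300)
    return np.log(np.maximum(x_w, 1e-300))


def liquidus_mole_fraction(T, mp: MembraneParams):
    """Water mole fraction of a solution in equilibrium with ice at T."""
    T = np.asarray(T, dtype=float)
    return np.exp(np.minimum(mp.dHf / R_GAS * (1.0 / mp.T_mw - 1.0 / T), 0.0))


def melting_point(c_salt, c_gly, mp: MembraneParams):
    """Equilibrium melting point (K) of a solution.

    Concentrations are per m^3 of liquid; the water concentration is
    recovered from the molar volumes (the three species fill the liquid).
    Pure water returns T_mw; more solute always lowers T_m.
    """
    c_salt = np.asarray(c_salt, dtype=float)
    c_gly = np.asarray(c_gly, dtype=float)
    if np.any(c_salt < 0) or np.any(c_gly < 0):
        raise ValueError("concentrations must be non-negative")
    c_w = (1.0 - c_salt * mp.nu_s - c_gly * mp.nu_g) / mp.nu_w
    c_w = np.maximum(c_w, 0.0)
    ln_xw = ln_water_activity(c_w, c_salt, c_gly, mp)
    inv_tm = 1.0 / mp.T_mw - (R_GAS / mp.dHf) * ln_xw
    return 1.0 / inv_tm


def water_flux(T, c_w_in, c_s_in, c_g_in, ext: ExtracellularState,
               mp: MembraneParams, T_m_ext=None):
    """Per-area water volume flux out of the cell (m/s, positive = efflux).

    Parameters
    ----------
    T : float
        Uniform temperature, K.
    c_w_in, c_s_in, c_g_in : array-like
        Intracellular liquid-phase concentrations at the membrane patch.
    ext : ExtracellularState
        Current extracellular composition (used above the bath liquidus).
    T_m_ext : float, optional
        Liquidus of the bath; below it the external water activity is the
        ice-equilibrium value regardless of ``ext``.
    """
    ln_in = ln_water_activity(c_w_in, c_s_in, c_g_in, mp)
    if T_m_ext is None:
        T_m_ext = melting_point(ext.c_salt_ext, ext.c_gly_ext, mp)
    if T < T_m_ext:
        ln_ext = mp.dHf / R_GAS * (1.0 / mp.T_mw - 1.0 / T)
    else:
        c_w_ext = (1.0 - ext.c_salt_ext * mp.nu_s - ext.c_gly_ext * mp.nu_g) / mp.nu_w
        ln_ext = ln_water_activity(c_w_ext, ext.c_salt_ext, ext.c_gly_ext, mp)
    lp = permeability(T, mp)
    return lp * R_GAS * T / mp.nu_w * (ln_in - ln_ext)


def boundary_speed(J_w):
    """Normal recession speed of the membrane surface, v_s = J_w (m/s).

    Positive flux (water efflux) moves the boundary along the inward
    surface normal; the sign convention is handled by the mesh mover.
    """
    return np.asarray(J_w, dtype=float)


def extracellular_state(T, cpa_molar, salt_molar, mp: MembraneParams) -> ExtracellularState:
    """Extracellular composition at temperature T.

    Above the loading-solution liquidus this is the initial loading; below
    it, external ice freeze-concentrates the residual liquid along the
    liquidus (ideal dilute law with the same dHf/T_mw constants as the
    membrane flux, so flux and liquidus are thermodynamically consistent).
    """
    c_s0 = salt_molar * 1e3     # mol/m^3
    c_g0 = cpa_molar * 1e3
    # moles per m^3 of initial solution
    n_w0 = (1.0 - c_s0 * mp.nu_s - c_g0 * mp.nu_g) / mp.nu_w
    if n_w0 <= 0:
        raise ValueError("loading solution has no water")
    t_m0 = float(melting_point(c_s0, c_g0, mp))
    if T >= t_m0:
        return ExtracellularState(c_salt_ext=c_s0, c_gly_ext=c_g0,
                                  unfrozen_fraction=1.0)
    x_w = float(liquidus_mole_fraction(T, mp))
    osm0 = mp.salt_dissociation * c_s0 + c_g0
    n_w = osm0 * x_w / max(1.0 - x_w, 1e-12)      # water moles left unfrozen
    n_w = min(n_w, n_w0)
    v_liq = n_w * mp.nu_w + c_s0 * mp.nu_s + c_g0 * mp.nu_g
    return ExtracellularState(c_salt_ext=c_s0 / v_liq, c_gly_ext=c_g0 / v_liq,
                              unfrozen_fraction=v_liq)
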