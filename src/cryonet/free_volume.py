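"""Free-volume theory of mutual diffusion in the glycerol-water system.

The cytosol at freezing temperatures is a highly concentrated glycerol-water
solution approaching a glassy state, where Stokes-Einstein scaling fails.
Diffusivity is therefore computed from free-volume theory: a molecule jumps
when a hole of sufficient size opens next to it, so

    D_W = D0 * exp(-dE / (R T))
             * exp(-(w_w V*_w + w_g xi V*_g) / V_FH)

with the specific hole free volume of the mixture

    V_FH = w_w k_w (T - T_gw + K21) + w_g k_g (T - T_ga + K22)   [ml/g]

(w_* mass fractions, V*_* critical hole free volumes, xi the ratio of
jumping-unit volumes).  V_FH vanishes as the mixture approaches its glass
transition, which is what arrests both diffusion and ice growth at deep
supercooling.

The bulk mutual diffusion coefficient combines D_W with a Darken-type
composition weighting (W = glycerol/water self-diffusion ratio at infinite
dilution) and a Flory-Huggins thermodynamic factor:

    D = D_W * [W x_vw + (1 - x_vw)] * (1 - 2 chi phi_w phi_g)

Region-effective diffusivities multiply D by the gross diffusion
modification factor f_D of the region (porous-media tortuosity/crowding),
and the nuclear envelope enters as the interface conductance
gamma_env * f_D_env * D * K / d.
"""

from __future__ import annotations

import numpy as np

from .params import (R_GAS, ConfigurationError, FreeVolumeCPAParams,
                     FreeVolumeWaterParams, RegionProperties)

__all__ = [
    "mass_fractions", "hole_free_volume", "water_self_diffusion",
    "mutual_diffusion", "effective_diffusion", "envelope_transfer_coefficient",
    "viscosity",
]


def mass_fractions(x_vw, cpa: FreeVolumeCPAParams):
    """Water/glycerol mass fractions from the water volume fraction x_vw."""
    x_vw = np.asarray(x_vw, dtype=float)
    phi_g = 1.0 - x_vw
    w_w = x_vw / (x_vw + phi_g / cpa.y_ratio)
    return w_w, 1.0 - w_w


def hole_free_volume(T, w_w, w_g, wp: FreeVolumeWaterParams,
                     cpa: FreeVolumeCPAParams):
    """Specific hole free volume of the mixture, ml/g (can reach 0 at T_g)."""
    fv_w = wp.fv_slope_w * (T - wp.T_gw + wp.fv_offset_w)
    fv_g = cpa.K12 * (T - cpa.T_ga + cpa.K22)
    return w_w * np.maximum(fv_w, 0.0) + w_g * np.maximum(fv_g, 0.0)


def water_self_diffusion(T, x_vw, wp: FreeVolumeWaterParams,
                         cpa: FreeVolumeCPAParams):
    """Self-diffusion coefficient of water in glycerol solution, m^2/s.

    Parameters
    ----------
    T : float or array
        Temperature (K), above the mixture glass transition for nonzero D.
    x_vw : float or array
        Water volume fraction of the liquid, in [0, 1].
    """
    x_vw = np.asarray(x_vw, dtype=float)
    if np.any(x_vw < -1e-12) or np.any(x_vw > 1 + 1e-12):
        raise ValueError("water volume fraction x_vw must lie in [0, 1]")
    x_vw = np.clip(x_vw, 0.0, 1.0)
    w_w, w_g = mass_fractions(x_vw, cpa)
    v_fh = hole_free_volume(T, w_w, w_g, wp, cpa)
    occupied = w_w * wp.specific_volume_w + w_g * cpa.xi * cpa.specific_volume_g
    with np.errstate(divide="ignore", over="ignore"):
        jump = np.where(v_fh > 0.0, np.exp(-occupied / np.maximum(v_fh, 1e-300)), 0.0)
    return wp.D0 * np.exp(-wp.dE / (R_GAS * np.asarray(T, dtype=float))) * jump


def mutual_diffusion(T, x_vw, wp: FreeVolumeWaterParams,
                     cpa: FreeVolumeCPAParams):
    """Bulk mutual diffusion coefficient of the glycerol-water pair, m^2/s."""
    x_vw = np.asarray(x_vw, dtype=float)
    d_w = water_self_diffusion(T, x_vw, wp, cpa)
    x = np.clip(x_vw, 0.0, 1.0)
    darken = cpa.W_ratio * x + (1.0 - x)
    thermo = 1.0 - 2.0 * cpa.chi * x * (1.0 - x)
    return d_w * darken * np.maximum(thermo, 0.0)


def effective_diffusion(D, region: str, rp: RegionProperties):
    """Region-effective diffusivity D_eff = f_D(region) * D."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("bulk diffusivity must be >= 0")
    return rp.f_D(region) * D


def envelope_transfer_coefficient(D, rp: RegionProperties):
    """Nuclear-envelope interface conductance, m/s.

    h = gamma_env * (f_D_env * D) * K / d_env for bulk diffusivity D at the
    interface; the envelope shell is thin enough (0.1 um) to act as a single
    resistive film.
    """
    if rp.d_env <= 0:
        raise ConfigurationError("envelope thickness d_env must be > 0")
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("bulk diffusivity must be >= 0")
    d_si = rp.d_env * 1e-6
    return rp.gamma_env * rp.f_D_env * D * rp.K_compat / d_si


def viscosity(T, x_vw, wp: FreeVolumeWaterParams, cpa: FreeVolumeCPAParams):
    """Diagnostic free-volume viscosity of the mixture, Pa s.

    Uses the same hole free volume as the diffusion model with a log-linear
    mixing of the pure-component pre-factors.  Exposed for inspection only;
    no model operation consumes it.
    """
    x_vw = np.clip(np.asarray(x_vw, dtype=float), 0.0, 1.0)
    w_w, w_g = mass_fractions(x_vw, cpa)
    v_fh = hole_free_volume(T, w_w, w_g, wp, cpa)
    occupied = w_w * wp.specific_volume_w + w_g * cpa.xi * cpa.specific_volume_g
    log_eta0 = w_w * np.log(wp.eta0_w) + w_g * np.log(cpa.eta0_g)
    with np.errstate(divide="ignore", over="ignore"):
        return np.where(v_fh > 0.0,
                        np.exp(log_eta0 + occupied / np.maximum(v_fh, 1e-300)),
                        np.inf)
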