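"""Simulation driver: cooling protocol, operator-split stepping, experiments.

Each step at uniform temperature T(t) = T0 - B t applies, in order:
membrane water efflux (source on boundary cells), boundary motion with
conservative remap, network ice kinetics with field feedback, and the
implicit diffusion solve.  The step size is slaved to the maximum
temperature increment (0.004 K for icing runs), with an automatic coarser
cadence while the whole cell is still above its liquidus and nothing can
happen.

The driver is fully deterministic: identical configurations yield
bit-identical traces and event lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import membrane as mem
from .free_volume import mutual_diffusion
from .iif_network import Network, default_topology
from .mesh import REGION_NUC
from .params import ModelConfig, R_GAS
from .transport import (apply_iif_source, build_mesh, diffusion_step,
                        mass_inventory, move_boundary, sample_at_points)

__all__ = ["SimulationResult", "run", "detect_crossing", "plateau_onset",
           "first_ice", "experiment_suite", "EXPERIMENTS"]


@dataclass
class SimulationResult:
    """Traces, frames and derived events of one simulation."""

    config: ModelConfig
    node_traces: pd.DataFrame | None     # time, T, per-node X/Ae/C_j/c_w
    frames: list                          # (t, T, dict of per-cell arrays)
    ledger: dict
    events: dict = field(default_factory=dict)
    stopped: str = "T_stop"

    def trace(self, label, column="X"):
        return self.node_traces[f"{column}_{label}"].to_numpy()

    @property
    def temperatures(self):
        return self.node_traces["T"].to_numpy()

    def node_labels(self):
        return sorted(c[2:] for c in self.node_traces.columns
                      if c.startswith("X_"))


def detect_crossing(trace_i, trace_j, temperatures, min_level: float = 0.0):
    """Temperature where trace_i first exceeds trace_j (linear interp).

    Returns None when no crossing occurs.  Crossings while both traces sit
    below ``min_level`` (dormant nodes) are ignored.
    """
    ti = np.asarray(trace_i, dtype=float)
    tj = np.asarray(trace_j, dtype=float)
    T = np.asarray(temperatures, dtype=float)
    diff = ti - tj
    live = (ti > min_level) | (tj > min_level)
    exceed = np.flatnonzero((diff > 0) & live)
    if exceed.size == 0:
        return None
    k = exceed[0]
    if k > 0 and diff[k - 1] < diff[k]:
        frac = -diff[k - 1] / (diff[k] - diff[k - 1])
        frac = min(max(frac, 0.0), 1.0)
        return float(T[k - 1] + frac * (T[k] - T[k - 1]))
    return float(T[k])


def first_ice(trace, temperatures, threshold=1e-4):
    """Temperature at which a node's ice fraction first exceeds threshold."""
    x = np.asarray(trace, dtype=float)
    idx = np.flatnonzero(x >= threshold)
    return float(np.asarray(temperatures)[idx[0]]) if idx.size else None


def plateau_onset(trace, temperatures, frac=0.01, min_x=1e-3):
    """Temperature where ice growth falls below ``frac`` of its peak rate.

    The onset is searched after the peak growth rate, on nodes that formed
    at least ``min_x`` of ice; returns None otherwise.
    """
    x = np.asarray(trace, dtype=float)
    if x.max() < min_x:
        return None
    rate = np.diff(x)
    peak = rate.max()
    if peak <= 0:
        return None
    kpeak = int(np.argmax(rate))
    slow = np.flatnonzero(rate[kpeak:] < frac * peak)
    if slow.size == 0:
        return None
    return float(np.asarray(temperatures)[kpeak + slow[0] + 1])


# ----------------------------------------------------------------------
def run(config: ModelConfig, progress: bool = False) -> SimulationResult:
    """Run the coupled dehydration + IIF network simulation."""
    config.validate()
    geo, rp, mp = config.geometry, config.regions, config.membrane
    wp, cpa = config.water, config.cpa
    pr, nm = config.protocol, config.numerics

    state = build_mesh(geo, (nm.n_r, nm.n_theta), rp, mp,
                       pr.initial_cpa_molar, pr.initial_salt_molar, pr.T0)
    f_d_cell = np.where(state.mesh.region == REGION_NUC, rp.f_D_nuc, rp.f_D_cyto)

    network = None
    if config.network_enabled:
        topo = default_topology(geo)
        network = Network(topo, geo, rp, config.nucleation, mp, wp, cpa,
                          config.spread, ae_mode=config.ae_mode,
                          fD_override=config.node_fD_override,
                          extra_nodes=config.extra_nodes,
                          max_cohorts=nm.max_cohorts)

    t_m_ext0 = float(mem.melting_point(pr.initial_salt_molar * 1e3,
                                       pr.initial_cpa_molar * 1e3, mp))
    dt_fine = pr.dT_max / pr.rate_B
    # nothing freezes or dehydrates above the bath liquidus; stride coarser
    dt_coarse = max(dt_fine, 0.5 / pr.rate_B)

    rows = []
    frames = []
    T, t = pr.T0, 0.0
    stopped = "T_stop"
    step = 0
    while T > pr.T_stop:
        dt = dt_fine if T < t_m_ext0 + 1.0 else dt_coarse
        ext = mem.extracellular_state(T, pr.initial_cpa_molar,
                                      pr.initial_salt_molar, mp)
        # --- membrane efflux (implicit Robin term in the diffusion solve)
        robin = None
        if T < t_m_ext0:
            bc = state.mesh.mem_cell
            c0 = np.maximum(state.c_w[bc], 0.0)
            c_s_b = np.maximum(state.c_s[bc], 0.0)
            c_g_b = np.maximum(state.c_g[bc], 0.0)
            j0 = mp.A_ef * mem.water_flux(T, c0, c_s_b, c_g_b,
                                          ext, mp, T_m_ext=t_m_ext0)
            osm = mp.salt_dissociation * c_s_b + c_g_b
            jp = (mp.A_ef * mem.permeability(T, mp) * R_GAS * T / mp.nu_w
                  * osm / np.maximum(c0 * (c0 + osm), 1e-300))
            robin = {"J0": j0, "dJdc": jp, "c0": c0}

        # --- network kinetics & feedback
        if network is not None:
            network.update_positions(state.mesh)
            samples = sample_at_points(state, network.sample_points(),
                                       order=nm.interp_order,
                                       clip_to_neighbors=True)
            network.set_compositions(samples, T)
            d_x = network.step(T, dt, t)
            if np.any(d_x > 0):
                d_ice = network.feedback_to_fields(d_x, state)
                apply_iif_source(state, d_ice)

        # --- implicit diffusion with the membrane efflux term
        d_bulk = mutual_diffusion(T, state.x_vw, wp, cpa)
        removal = diffusion_step(state, dt, f_d_cell * d_bulk, rp, wp, cpa,
                                 salt_scale=nm.salt_diffusion_scale,
                                 robin=robin)
        if np.any(removal > 0):
            v_s = removal * mp.nu_w / (state.mesh.mem_area * dt)
            try:
                move_boundary(state, v_s, dt)
            except RuntimeError:
                stopped = "boundary_collapse"
                break

        t += dt
        T -= pr.rate_B * dt
        state.t, state.T = t, T
        row = {"t": t, "T": T}
        if network is not None:
            for n in network.nodes:
                row[f"X_{n.label}"] = n.X_i
                row[f"Ae_{n.label}"] = n.Ae_total
                row[f"Cj_{n.label}"] = n.C_j
                row[f"cw_{n.label}"] = n.comp.c_w if n.comp else np.nan
        rows.append(row)
        if step % nm.frame_stride == 0:
            frames.append((t, T, {
                "centroid": state.mesh.centroid.copy(),
                "vol": state.mesh.vol.copy(),
                "region": state.mesh.region.copy(),
                "c_w": state.c_w.copy(), "c_g": state.c_g.copy(),
                "x_vw": state.x_vw.copy(), "phi_liq": state.phi_liq.copy(),
                "X_vice": state.X_vice.copy(), "X_vb": state.X_vb.copy(),
            }))
        step += 1
        if progress and step % 2000 == 0:
            print(f"  t={t:9.1f}s  T={T - 273.15:8.3f}C")

    traces = pd.DataFrame(rows) if rows else None
    result = SimulationResult(config=config, node_traces=traces,
                              frames=frames, ledger=mass_inventory(state),
                              stopped=stopped)
    if network is not None and traces is not None:
        result.events = _derive_events(result, config)
    result.final_state = state
    return result


def _derive_events(res: SimulationResult, config: ModelConfig) -> dict:
    nm = config.numerics
    T = res.temperatures
    events = {"first_ice": {}, "plateau": {}, "crossings": {}}
    for lab in res.node_labels():
        x = res.trace(lab)
        events["first_ice"][lab] = first_ice(x, T, nm.ice_threshold)
        events["plateau"][lab] = plateau_onset(x, T, nm.plateau_frac)
    for (a, b) in [("C", "F"), ("D", "E")]:
        if f"X_{a}" in res.node_traces and f"X_{b}" in res.node_traces:
            events["crossings"][f"{a}_over_{b}"] = detect_crossing(
                res.trace(a), res.trace(b), T, min_level=nm.ice_threshold)
    return events


# ----------------------------------------------------------------------
# the in-built experiment protocols
def _base_config(**kw) -> ModelConfig:
    cfg = ModelConfig()
    for k, v in kw.items():
        obj = cfg
        parts = k.split(".")
        for p in parts[:-1]:
            obj = getattr(obj, p)
        setattr(obj, parts[-1], v)
    return cfg


def experiment_network_trigger(resolution=24, T_stop=223.15) -> ModelConfig:
    """Exogenous trigger at node A; 4.8 mol/L CPA, 0.02 K/s, 0.004 K cap."""
    return _base_config(**{
        "protocol.initial_cpa_molar": 4.8, "protocol.rate_B": 0.02,
        "protocol.dT_max": 0.004, "protocol.T_stop": T_stop,
        "numerics.n_r": resolution, "numerics.n_theta": resolution,
        "ae_mode": "trigger"})


def experiment_equal_fD(resolution=24, T_stop=223.15) -> ModelConfig:
    """Same trigger run with the nucleus diffusion factor forced to 0.3."""
    cfg = experiment_network_trigger(resolution, T_stop)
    cfg.regions.f_D_nuc = cfg.regions.f_D_cyto
    return cfg


def experiment_node_C_vs_CS(resolution=24, T_stop=223.15) -> ModelConfig:
    """Equal constant Ae at every node; CS duplicates C with cytoplasm f_D."""
    cfg = experiment_network_trigger(resolution, T_stop)
    cfg.ae_mode = "equal"
    cfg.extra_nodes = {"CS": ("C",)}
    cfg.node_fD_override = {"CS": cfg.regions.f_D_cyto}
    return cfg


def experiment_gradient_vs_T(resolution=16, rate=0.1, T_stop=216.0) -> ModelConfig:
    """Dehydration-only run showing the growing water/CPA gradient."""
    return _base_config(**{
        "protocol.initial_cpa_molar": 6.0, "protocol.rate_B": rate,
        "protocol.dT_max": 0.05, "protocol.T_stop": T_stop,
        "numerics.n_r": resolution, "numerics.n_theta": resolution,
        "network_enabled": False, "ae_mode": "none"})


def experiment_nucleus_vs_ideal(resolution=16, T_stop=206.0):
    """Nucleated model vs homogeneous 'ideal solution' model, 6 M, 0.01 K/s."""
    nucleated = _base_config(**{
        "protocol.initial_cpa_molar": 6.0, "protocol.rate_B": 0.01,
        "protocol.dT_max": 0.05, "protocol.T_stop": T_stop,
        "numerics.n_r": resolution, "numerics.n_theta": resolution,
        "network_enabled": False, "ae_mode": "none"})
    ideal = _base_config(**{
        "protocol.initial_cpa_molar": 6.0, "protocol.rate_B": 0.01,
        "protocol.dT_max": 0.05, "protocol.T_stop": T_stop,
        "numerics.n_r": resolution, "numerics.n_theta": resolution,
        "network_enabled": False, "ae_mode": "none"})
    ideal.geometry.has_nucleus = False
    return nucleated, ideal


EXPERIMENTS = {
    "network_trigger": experiment_network_trigger,
    "equal_fD": experiment_equal_fD,
    "node_C_vs_CS": experiment_node_C_vs_CS,
    "gradient_vs_T": experiment_gradient_vs_T,
    "nucleus_vs_ideal": experiment_nucleus_vs_ideal,
}


def experiment_suite(name: str, resolution: int | None = None, **kw):
    """Run one of the named experiment protocols end to end."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {sorted(EXPERIMENTS)}")
    factory = EXPERIMENTS[name]
    args = {} if resolution is None else {"resolution": resolution}
    args.update(kw)
    cfg = factory(**args)
    if isinstance(cfg, tuple):
        return tuple(run(c) for c in cfg)
    return run(cfg)
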