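"""Parameter registry for the oocyte freezing model.

All tunable physical constants live here, grouped the way they enter the
model: cell geometry, free-volume diffusion parameters of the glycerol-water
system, per-region porous-media modification factors, plasma-membrane
transport, ice nucleation/growth kinetics, and the nucleation-area spreading
law of the IIF node network.

Units follow the source tables (lengths in micrometres, specific volumes in
ml/g, molar volumes in ml/mol); everything is converted to SI (m, s, K,
mol/m**3) at the point of use.  The few places where a table value must be
re-expressed are marked.

Symbol-to-value correspondence for the free-volume tables
---------------------------------------------------------
The free-volume parameter set for the glycerol-water pair is transcribed
once, here, and validated against bulk measurements (see docs/methods.md):

water:    molar volume 18 ml/mol, critical specific hole free volume
          V*_w = 0.91 ml/g, glass transition T_gw = 136 K, pre-exponential
          D0 = 1.39e-7 m^2/s, activation energy dE = 1.98e3 J/mol, viscosity
          pre-factor 3.33e-5 Pa s, free-volume offset K21 = -19.73 K and
          slope K11/gamma = 1.945e-3 ml/(g K).
glycerol: molar volume 73.3 ml/mol, V*_g = 0.716 ml/g, T_ga = 192.15 K,
          jumping-unit ratio xi = 0.92, Flory-Huggins chi = 0.29, viscosity
          pre-factor 1.44e11 Pa s, free-volume offset K22 = 30.12 K and
          slope K12/gamma = 5.93e-4 ml/(g K), self-diffusion ratio
          W = 0.427 at infinite dilution.

This mapping reproduces the self-diffusion coefficient of pure water at
293 K (2.05e-9 vs measured ~2.0e-9 m^2/s), the tracer diffusivity of water
in pure glycerol (~1.3e-11 vs ~1.4e-11 m^2/s) and the dilute-limit mutual
diffusivity of glycerol in water (~8.5e-10 m^2/s).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

#: universal gas constant, J/(mol K)
R_GAS = 8.314462618


class ConfigurationError(ValueError):
    """Raised for parameter sets that violate their physical invariants."""


@dataclass
class FreeVolumeWaterParams:
    """Free-volume parameters of pure water."""

    molar_volume_w: float = 18.0       # ml/mol
    specific_volume_w: float = 0.91    # ml/g, critical hole free volume V*_w
    T_gw: float = 136.0                # K
    D0: float = 1.39e-7                # m^2/s
    dE: float = 1.98e3                 # J/mol
    eta0_w: float = 3.33e-5            # Pa s
    fv_offset_w: float = -19.73        # K  (K21)
    fv_slope_w: float = 1.945e-3       # ml/(g K)  (K11/gamma)

    def validate(self) -> None:
        for name in ("molar_volume_w", "specific_volume_w", "T_gw", "D0",
                     "eta0_w", "fv_slope_w"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"water free-volume {name} must be >= 0")
        if not self.T_gw < 273.15:
            raise ConfigurationError("T_gw must lie below the water melting point")


@dataclass
class FreeVolumeCPAParams:
    """Free-volume and mixing parameters of glycerol (the CPA)."""

    molar_volume_g: float = 73.3       # ml/mol
    specific_volume_g: float = 0.716   # ml/g, V*_g
    T_ga: float = 192.15               # K
    xi: float = 0.92                   # jumping-unit volume ratio water/glycerol
    K12: float = 5.93e-4               # ml/(g K), free-volume slope K12/gamma
    K22: float = 30.12                 # K, free-volume offset
    eta0_g: float = 1.44e11            # Pa s
    chi: float = 0.29                  # Flory-Huggins interaction parameter
    y_ratio: float = 0.716 / 0.91      # specific-volume ratio glycerol/water
    fv_offset_g: float = 30.12         # K, alias of K22 (kept for registry mirror)
    fv_slope_g: float = 5.93e-4        # ml/(g K), alias of K12
    W_ratio: float = 0.427             # glycerol/water self-diffusion ratio
    # table entries that cannot be assigned to a surviving symbol
    extras: tuple = (0.55, 17.4, 7.4e-2)

    def validate(self) -> None:
        if not (0.0 < self.W_ratio <= 1.0):
            raise ConfigurationError("W_ratio must lie in (0, 1]")
        if not self.T_ga > 136.0:
            raise ConfigurationError("glycerol T_ga must exceed water T_gw")


@dataclass
class RegionProperties:
    """Per-region porous-media modification of bulk transport.

    f_D_* are gross diffusion modification factors (lumped tortuosity and
    crowding); gamma_* are free-water porosities.  The nuclear envelope is a
    0.1 um shell treated as an interface conductance gamma_env*f_D_env*D*K/d.
    """

    f_D_cyto: float = 0.3
    f_D_nuc: float = 0.78
    f_D_env: float = 0.078
    gamma_cyto: float = 0.45
    gamma_nuc: float = 0.85
    gamma_env: float = 0.2
    K_compat: float = 1.0      # molecule/membrane-material compatibility
    d_env: float = 0.1         # um, envelope-region thickness

    def f_D(self, region: str) -> float:
        try:
            return {"cytoplasm": self.f_D_cyto, "nucleus": self.f_D_nuc,
                    "envelope": self.f_D_env}[region]
        except KeyError:
            raise ConfigurationError(f"unknown region tag {region!r}") from None

    def gamma(self, region: str) -> float:
        try:
            return {"cytoplasm": self.gamma_cyto, "nucleus": self.gamma_nuc,
                    "envelope": self.gamma_env}[region]
        except KeyError:
            raise ConfigurationError(f"unknown region tag {region!r}") from None

    def validate(self) -> None:
        for name in ("f_D_cyto", "f_D_nuc", "f_D_env",
                     "gamma_cyto", "gamma_nuc", "gamma_env"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name}={v} must lie in (0, 1]")
        if self.d_env <= 0:
            raise ConfigurationError("envelope thickness d_env must be > 0")


@dataclass
class MembraneParams:
    """Plasma-membrane water permeability and thermodynamic constants."""

    Lpg_ref: float = 7.26e-15     # m^2 s/kg, permeability at T_ref
    E_Lp: float = 5.57e4          # J/mol, permeability activation energy
    T_ref: float = 273.15         # K
    dHf: float = 6016.52          # J/mol, fusion heat of water
    T_mw: float = 273.15          # K, melting point of pure water
    nu_w: float = 18.0e-6         # m^3/mol, molar volume of water
    nu_s: float = 16.6e-6         # m^3/mol, molar volume of salt (NaCl)
    nu_g: float = 73.3e-6         # m^3/mol, molar volume of glycerol
    salt_dissociation: float = 2.0
    #: effective transport area per geometric membrane area (microvilli and
    #: membrane folding amplify the osmotically active surface of an oocyte)
    A_ef: float = 4.0

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigurationError(f"membrane parameter {f.name} must be > 0")


@dataclass
class NucleationParams:
    """Ice nucleation and diffusion-limited growth coefficients."""

    omega_hom: float = 2.0e50     # 1/(s m^3), homogeneous kinetic coefficient
    kappa_hom: float = 1.1e12     # K^5, homogeneous thermodynamic coefficient
    omega_het: float = 3.56e8     # 1/(s m^2), heterogeneous kinetic coefficient
    kappa_het: float = 4.6e9      # K^5, heterogeneous thermodynamic coefficient
    alpha_growth: float = 1.0     # dimensionless crystal-growth parameter
    r_seed: float = 1.0e-8        # m, radius assigned to a fresh nucleus

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ConfigurationError(f"nucleation parameter {f.name} must be > 0")


@dataclass
class SpreadParams:
    """Parameters of the nucleation-area spreading law between network nodes.

    A node i with ice fraction X_i contributes
    ``Ae_sal * (X_i**M_exp + C_off) * exp(-r_ij / d_decay)``
    of heterogeneous nucleation area (per unit volume) to a neighbour j at
    distance r_ij.  Node A additionally carries the exogenous area Ae_exo
    from t = 0 (the exogenous-IIF trigger).
    """

    Ae_exo: float = 64416.476     # m^2/m^3 (model units)
    Ae_sal: float = 64416.476
    C_off: float = 0.0
    M_exp: float = 1.0
    #: decay length of the spreading law (m).  The fitted value is printed
    #: without units; a cell-scale decay is the only choice that makes the
    #: law a genuine distance gate, and 6 um yields the sequential
    #: node-by-node activation the exogenous-trigger hypothesis describes.
    d_decay: float = 6.0e-6
    #: attenuation of nucleation-area spreading across the nuclear
    #: envelope (ice reaches the nucleus through envelope pores); defaults
    #: to the envelope equivalent porosity.
    envelope_attenuation: float = 0.2

    def validate(self) -> None:
        if self.Ae_exo < 0 or self.Ae_sal < 0:
            raise ConfigurationError("nucleation areas must be >= 0")
        if self.d_decay <= 0:
            raise ConfigurationError("spreading decay length must be > 0")


@dataclass
class CellGeometry:
    """Ellipsoidal oocyte with an off-centre ellipsoidal nucleus (um)."""

    l_maj: float = 41.2
    l_min: float = 39.0
    s_maj: float = 15.15
    s_min: float = 12.99
    b_env: float = 0.1
    r_neu: float = 6.22     # nominal nucleus radius, used for node placement
    d_nlr: float = 8.0      # displacement of the nucleus along the symmetry axis
    has_nucleus: bool = True

    def validate(self) -> None:
        if min(self.l_maj, self.l_min) <= 0:
            raise ConfigurationError("cell semi-axes must be positive")
        if self.has_nucleus:
            if min(self.s_maj, self.s_min) <= 0:
                raise ConfigurationError("nucleus semi-axes must be positive")
            if self.d_nlr + self.s_maj >= self.l_maj or self.s_min >= self.l_min:
                raise ConfigurationError("nucleus must lie strictly inside the cell")
            if not self.b_env < self.s_min:
                raise ConfigurationError("envelope thickness must be << nucleus size")


@dataclass
class CoolingProtocol:
    """Linear cooling protocol T(t) = T0 - B t with a max temperature step."""

    T0: float = 273.15            # K
    rate_B: float = 0.02          # K/s
    dT_max: float = 0.004         # K, maximum temperature step per iteration
    T_stop: float = 223.15        # K
    initial_cpa_molar: float = 4.8    # mol/L glycerol
    initial_salt_molar: float = 0.142  # mol/L NaCl

    def validate(self) -> None:
        if self.rate_B <= 0 or self.dT_max <= 0:
            raise ConfigurationError("cooling rate and dT_max must be > 0")
        if self.T_stop >= self.T0:
            raise ConfigurationError("T_stop must lie below T0")


@dataclass
class Numerics:
    """Discretisation controls."""

    n_r: int = 24                 # radial layers
    n_theta: int = 24             # polar-angle columns
    interp_order: int = 3         # field-to-node sampling order
    frame_stride: int = 200       # steps between stored field frames
    salt_diffusion_scale: float = 1.0   # salt D relative to the mutual coefficient
    envelope_mode: str = "interface"    # "interface" | "meshed"
    max_cohorts: int = 400        # crystal cohorts kept per node before merging
    ice_threshold: float = 1e-4   # X_i marking "first ice" events
    plateau_frac: float = 0.01    # growth-rate fraction defining a plateau

    def validate(self) -> None:
        if self.n_r < 8 or self.n_theta < 8:
            raise ConfigurationError("resolution must be >= 8 cells per axis")
        if self.interp_order not in (0, 1, 2, 3):
            raise ConfigurationError("interp_order must be 0..3")
        if self.envelope_mode not in ("interface", "meshed"):
            raise ConfigurationError("envelope_mode must be 'interface' or 'meshed'")


@dataclass
class ModelConfig:
    """Aggregate, schema-validated model configuration."""

    geometry: CellGeometry = field(default_factory=CellGeometry)
    water: FreeVolumeWaterParams = field(default_factory=FreeVolumeWaterParams)
    cpa: FreeVolumeCPAParams = field(default_factory=FreeVolumeCPAParams)
    regions: RegionProperties = field(default_factory=RegionProperties)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    nucleation: NucleationParams = field(default_factory=NucleationParams)
    spread: SpreadParams = field(default_factory=SpreadParams)
    protocol: CoolingProtocol = field(default_factory=CoolingProtocol)
    numerics: Numerics = field(default_factory=Numerics)
    network_enabled: bool = True
    # Ae protocol: "trigger" (exogenous area at node A only) or "equal"
    # (the same constant area handed to every node, no spreading)
    ae_mode: str = "trigger"
    # optional per-node f_D overrides, e.g. {"CS": 0.3}
    node_fD_override: dict = field(default_factory=dict)
    # extra diagnostic nodes: label -> (template_label,) copied position
    extra_nodes: dict = field(default_factory=dict)

    def validate(self) -> "ModelConfig":
        for name in ("geometry", "water", "cpa", "regions", "membrane",
                     "nucleation", "spread", "protocol", "numerics"):
            getattr(self, name).validate()
        if self.ae_mode not in ("trigger", "equal", "none"):
            raise ConfigurationError("ae_mode must be 'trigger', 'equal' or 'none'")
        return self

    def to_dict(self) -> dict:
        return asdict(self)
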