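"""Model constants: rates, diffusivities, saturations, influxes.

All quantities are kept in a single unit system (gram, centimetre, day).
Blood lipid levels are conventionally quoted in mg/dL; they are converted
at the interface with :data:`MG_PER_DL`, i.e. 1 mg/dL = 1e-5 g/cm^3.

The registry below is the canonical default set.  Derivation utilities
(:func:`molar_to_mass_rate`, :func:`area_scaled_diffusion`) document how
several of the constants were obtained, but they never overwrite the
tabulated defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "MG_PER_DL",
    "SECONDS_PER_DAY",
    "ParameterSet",
    "SensitivityRange",
    "default_parameters",
    "load_parameters",
    "validate",
    "molar_to_mass_rate",
    "mass_to_molar_rate",
    "area_scaled_diffusion",
    "default_sensitivity_ranges",
    "mgdl_to_gcm3",
    "PARAMETER_REGISTRY",
]

#: 1 mg/dL expressed in g/cm^3.
MG_PER_DL = 1.0e-5
SECONDS_PER_DAY = 86400.0

# name -> (default value, unit, description)
# Groups: reaction/binding rates, diffusivities, production rates,
# degradation/death rates, chemotaxis, boundary sources, influx rates,
# saturation constants, closure/auxiliary.
PARAMETER_REGISTRY: dict[str, tuple[float, str, str]] = {
    # oxidation reaction rates
    "k_L": (2.35e-4, "cm^3 g^-1 day^-1", "reaction rate of LDL + radical -> ox-LDL"),
    "k_H": (5.29e-6, "cm^3 g^-1 day^-1", "reaction rate of HDL + radical -> ox-HDL"),
    # diffusion coefficients
    "D_L": (29.89, "cm^2 day^-1", "diffusion coefficient of LDL"),
    "D_H": (3.93, "cm^2 day^-1", "diffusion coefficient of HDL"),
    "D_Lox": (29.89, "cm^2 day^-1", "diffusion coefficient of ox-LDL"),
    "D_r": (2.05e-1, "cm^2 day^-1", "diffusion coefficient of free radicals"),
    "D_M": (8.64e-7, "cm^2 day^-1", "diffusion coefficient of macrophages"),
    "D_T": (8.64e-7, "cm^2 day^-1", "diffusion coefficient of T cells"),
    "D_Ig": (1.08e2, "cm^2 day^-1", "diffusion coefficient of IFN-gamma"),
    "D_S": (8.64e-7, "cm^2 day^-1", "diffusion coefficient of SMCs"),
    "D_P": (17.28, "cm^2 day^-1", "diffusion coefficient of MCP-1"),
    "D_I12": (1.08e2, "cm^2 day^-1", "diffusion coefficient of IL-12"),
    "D_G": (8.64e-2, "cm^2 day^-1", "diffusion coefficient of PDGF"),
    "D_Q": (4.32e-2, "cm^2 day^-1", "diffusion coefficient of MMP"),
    "D_Qr": (4.32e-2, "cm^2 day^-1", "diffusion coefficient of TIMP"),
    "D_F": (8.64e-7, "cm^2 day^-1", "diffusion coefficient of foam cells"),
    # production / activation rates
    "lambda_ox": (10.0, "g cm^-3 day^-1", "rate of ox-LDL ingestion by macrophages"),
    "lambda_MIg": (0.005, "day^-1", "activation rate of macrophages by IFN-gamma"),
    "lambda_P": (8.65e-10, "g cm^-3 day^-1", "production rate of MCP-1"),
    "lambda_TI12": (1.0e6, "day^-1", "activation rate of T cells by IL-12"),
    "lambda_IgT": (0.066, "day^-1", "production rate of IFN-gamma by T cells"),
    "lambda_I12M": (3.0e-7, "g cm^-3 day^-1", "production rate of IL-12 by macrophages"),
    "lambda_I12F": (1.0e-7, "g cm^-3 day^-1", "production rate of IL-12 by foam cells"),
    "lambda_GM": (0.1, "day^-1", "production rate of PDGF by macrophages"),
    "lambda_GF": (0.033, "day^-1", "production rate of PDGF by foam cells"),
    "lambda_GS": (0.5, "day^-1", "production rate of PDGF by SMCs"),
    "lambda_QS": (3.0e-4, "day^-1", "production rate of MMP by SMCs"),
    "lambda_QrS": (3.0e-5, "day^-1", "production rate of TIMP by SMCs"),
    "lambda_QrM": (6.0e-5, "day^-1", "production rate of TIMP by macrophages"),
    "lambda_rho": (0.432, "day^-1", "remodeling rate of ECM"),
    "lambda_F": (0.12, "day^-1", "activation rate of foam cells"),
    # degradation / death rates
    "d_M": (0.015, "day^-1", "death rate of macrophages"),
    "d_P": (1.73, "day^-1", "degradation rate of MCP-1"),
    "d_T": (0.33, "day^-1", "death rate of T cells"),
    "d_Ig": (0.69, "day^-1", "degradation rate of IFN-gamma"),
    "d_S": (0.86, "day^-1", "death rate of SMCs"),
    "d_I12": (1.188, "day^-1", "degradation rate of IL-12"),
    "d_G": (3.84, "day^-1", "degradation rate of PDGF"),
    "d_Q": (4.32, "day^-1", "degradation rate of MMP"),
    "d_Qr": (21.6, "day^-1", "degradation rate of TIMP"),
    "d_rhoQ": (2.59e7, "cm^3 g^-1 day^-1", "degradation rate of ECM due to MMP"),
    "d_F": (0.03, "day^-1", "death rate of foam cells"),
    "d_r": (0.26, "day^-1", "decay rate of free radicals"),
    # MMP/TIMP mutual binding
    "k_QQr": (4.98e8, "cm^3 g^-1 day^-1", "binding rate of MMP to TIMP"),
    "k_QrQ": (1.04e9, "cm^3 g^-1 day^-1", "binding rate of TIMP to MMP"),
    # chemotaxis / haptotaxis
    "chi_P": (0.1, "cm^5 g^-1 day^-1", "chemotactic sensitivity of SMCs to MCP-1"),
    "chi_G": (0.1, "cm^5 g^-1 day^-1", "chemotactic sensitivity of SMCs to PDGF"),
    "chi_rho": (1.0e-3, "cm^5 g^-1 day^-1", "haptotaxis sensitivity of SMCs to ECM"),
    # sources at the boundaries (blood / media levels)
    "r0": (0.26, "g cm^-3 day^-1", "source of free radicals in the intima"),
    "L0": (1.3e-3, "g cm^-3", "LDL concentration in blood (default 130 mg/dL)"),
    "H0": (5.0e-4, "g cm^-3", "HDL concentration in blood (default 50 mg/dL)"),
    "M0": (5.0e-5, "g cm^-3", "monocyte/macrophage density in blood"),
    "T0": (1.0e-3, "g cm^-3", "T-cell density in blood"),
    "S0": (6.0e-3, "g cm^-3", "SMC density in the media"),
    "rho0": (1.0, "g cm^-3", "reference (healthy) ECM density"),
    "P0": (3.0e-10, "g cm^-3", "MCP-1 concentration in blood"),
    "G0": (1.5e-8, "g cm^-3", "PDGF concentration in blood"),
    # influx (mass-transfer) coefficients
    "beta_L": (1.0, "cm^-1", "influx rate of LDL into the intima"),
    "beta_H": (1.0, "cm^-1", "influx rate of HDL into the intima"),
    "beta_M": (0.2, "cm^-1", "influx rate of macrophages into the intima"),
    "beta_T": (0.05, "cm^-1", "influx rate of T cells into the intima"),
    "beta_S": (0.2, "cm^-1", "influx rate of SMCs into the intima"),
    # saturation constants
    "K_Lox": (0.5, "g cm^-3", "ox-LDL saturation (MCP-1 production, ingestion)"),
    "K_M": (2.5e-5, "g cm^-3", "macrophage saturation (T-cell activation, IL-12 production)"),
    "K_F": (2.5e-5, "g cm^-3", "foam-cell saturation (IL-12 production)"),
    "K_Ig_act": (1.0e-11, "g cm^-3", "IFN-gamma saturation (macrophage activation)"),
    "K_Ig_I12": (7.0e-11, "g cm^-3", "IFN-gamma saturation (IL-12 production)"),
    # closure / interface constants
    "C_tot": (1.0, "g cm^-3", "total density of cells plus ECM"),
    "K_MLox": (2.0e-9, "g cm^-3", "ox-LDL scale for enhanced monocyte recruitment"),
    "K_MH": (7.0e-5, "g cm^-3", "HDL scale for inflammation damping"),
    "eta_cell": (6.0e-5, "cm^2 day^-1", "transendothelial migration coefficient (lumen)"),
    "eta_lipid": (2.0e-4, "cm^2 day^-1", "endothelial permeability to lipoproteins"),
    "eta_media": (2.0e-6, "cm^2 day^-1", "SMC migration coefficient across the media boundary"),
    "K_SG": (1.0e-5, "g cm^-3", "PDGF scale for enhanced SMC recruitment"),
    "K_ing": (2.0e-7, "g cm^-3", "macrophage half-saturation of ox-LDL ingestion"),
    "gamma_adh": (1.0e-9, "pressure cm", "cell-to-cell adhesion (surface tension) constant"),
}

# parameters that are genuinely signed/zero-allowed (none at present);
# everything in the registry must be strictly positive.
_POSITIVE = frozenset(PARAMETER_REGISTRY)

_CELL_DIFFUSIVITIES = ("D_M", "D_T", "D_S", "D_F")

# Table-4 diffusivities by species name, used by area_scaled_diffusion.
_TABULATED_DIFFUSION = {
    "LDL": 29.89,
    "HDL": 3.93,
    "ox-LDL": 29.89,
    "radical": 2.05e-1,
    "IFN-gamma": 1.08e2,
    "MCP-1": 17.28,
    "IL-12": 1.08e2,
    "PDGF": 8.64e-2,
    "MMP": 4.32e-2,
    "TIMP": 4.32e-2,
}

# Molecular weights (kDa) of the modelled proteins.
MOLECULAR_WEIGHTS = {
    "LDL": 549.0,
    "HDL": 105.0,
    "radical": 0.51,
    "IFN-gamma": 17.0,
    "PDGF": 35.0,
    "MCP-1": 8.9,
    "IL-12": 70.0,
    "MMP": 52.0,
    "TIMP": 25.0,
}


class ParameterError(ValueError):
    """Raised on unknown parameter names or invalid values."""


@dataclass(frozen=True)
class ParameterSet:
    """Immutable bag of model constants (g / cm / day units)."""

    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        merged = {k: float(v) for k, (v, _, _) in PARAMETER_REGISTRY.items()}
        for key, val in self.values.items():
            if key not in PARAMETER_REGISTRY:
                raise ParameterError(f"unknown parameter {key!r}")
            merged[key] = float(val)
        object.__setattr__(self, "values", merged)
        bad = [k for k in _POSITIVE if not merged[k] > 0.0]
        if bad:
            raise ParameterError(f"non-positive value for parameter(s) {bad}")

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def replace(self, **overrides: float) -> "ParameterSet":
        new = dict(self.values)
        new.update(overrides)
        return ParameterSet(new)

    def as_dict(self) -> dict[str, float]:
        return dict(self.values)

    @staticmethod
    def unit(name: str) -> str:
        return PARAMETER_REGISTRY[name][1]

    @staticmethod
    def description(name: str) -> str:
        return PARAMETER_REGISTRY[name][2]


def default_parameters() -> ParameterSet:
    return ParameterSet()


def load_parameters(config: Mapping[str, float] | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from defaults overlaid with ``config``.

    ``config`` is a flat mapping (``parameters.*`` namespace of a TOML/YAML
    document).  Unknown keys and non-positive values raise
    :class:`ParameterError` — the loader fails closed.
    """
    if config is None:
        return ParameterSet()
    if "parameters" in config and isinstance(config["parameters"], Mapping):
        config = config["parameters"]  # whole-document convenience
    return ParameterSet(dict(config))


def validate(p: ParameterSet) -> list[str]:
    """Report (never raise) violations of the parameter invariants."""
    out: list[str] = []
    for name in _POSITIVE:
        if not p[name] > 0.0:
            out.append(f"{name} must be strictly positive, got {p[name]!r}")
    if not p.k_L > p.k_H:
        out.append(
            f"k_L must exceed k_H (LDL oxidises faster): k_L={p.k_L!r}, k_H={p.k_H!r}"
        )
    cell_d = {name: p[name] for name in _CELL_DIFFUSIVITIES}
    if len(set(cell_d.values())) > 1:
        out.append(f"all cell diffusivities must be equal, got {cell_d}")
    return out


def mgdl_to_gcm3(level_mgdl: float) -> float:
    """Convert a blood lipid level from mg/dL to g/cm^3."""
    return float(level_mgdl) * MG_PER_DL


def molar_to_mass_rate(k_molar: float, mw_kda: float) -> float:
    """Convert a bimolecular rate from M^-1 s^-1 to cm^3 g^-1 day^-1.

    Mass-action bookkeeping in molar units divides by the partner's molar
    concentration; expressed per gram of partner the rate picks up a factor
    1/(molecular weight), with 86400 s/day and 1000 cm^3/L:

        k_mass = k_molar * 86400 * 1000 / (MW in g/mol)

    The Avogadro number cancels in the ratio of number density to mass
    density, leaving a pure unit conversion.
    """
    if not mw_kda > 0:
        raise ValueError(f"molecular weight must be positive, got {mw_kda!r}")
    if k_molar < 0:
        raise ValueError(f"rate must be non-negative, got {k_molar!r}")
    grams_per_mol = mw_kda * 1000.0
    return k_molar * SECONDS_PER_DAY * 1000.0 / grams_per_mol


def mass_to_molar_rate(k_mass: float, mw_kda: float) -> float:
    """Inverse of :func:`molar_to_mass_rate` (round-trips to machine precision)."""
    if not mw_kda > 0:
        raise ValueError(f"molecular weight must be positive, got {mw_kda!r}")
    grams_per_mol = mw_kda * 1000.0
    return k_mass * grams_per_mol / (SECONDS_PER_DAY * 1000.0)


# Accessible-surface-area power law A ~ MW^0.73 for monomeric globular
# proteins; the absolute scale of estimated diffusivities is pinned to the
# tabulated free-radical value (0.51 kDa, 0.205 cm^2/day) because the
# glucose calibration constant is not recoverable to better than its order
# of magnitude.
_ASA_EXPONENT = 0.73
_PIN_MW = 0.51
_PIN_D = 2.05e-1


def area_scaled_diffusion(
    species_or_mw: str | float, mode: str = "tabulated"
) -> float:
    """Diffusivity of a protein species, in cm^2/day.

    ``tabulated`` mode looks the species up in the canonical table and
    returns the value verbatim.  ``estimated`` mode applies the
    accessible-surface-area law D = K * MW^0.73 with K pinned at the
    free-radical entry; it accepts either a known species name or a
    molecular weight in kDa and is strictly increasing in MW.
    """
    if mode == "tabulated":
        if not isinstance(species_or_mw, str) or species_or_mw not in _TABULATED_DIFFUSION:
            raise KeyError(f"unknown species for tabulated diffusivity: {species_or_mw!r}")
        return _TABULATED_DIFFUSION[species_or_mw]
    if mode != "estimated":
        raise ValueError(f"mode must be 'tabulated' or 'estimated', got {mode!r}")
    if isinstance(species_or_mw, str):
        mw = MOLECULAR_WEIGHTS[species_or_mw]
    else:
        mw = float(species_or_mw)
    if not mw > 0:
        raise ValueError(f"molecular weight must be positive, got {mw!r}")
    return _PIN_D * (mw / _PIN_MW) ** _ASA_EXPONENT


@dataclass(frozen=True)
class SensitivityRange:
    """Uniform sampling range for one parameter of the sensitivity study."""

    name: str
    lower: float
    upper: float
    baseline: float

    def __post_init__(self):
        if not (self.lower < self.baseline < self.upper):
            raise ParameterError(
                f"{self.name}: require lower < baseline < upper, got "
                f"({self.lower!r}, {self.baseline!r}, {self.upper!r})"
            )


# The sensitivity study covers the 15 production/activation rates, the 5
# influx rates, and the two blood lipid levels L0 and H0.  Rows whose
# printed range survives use it; the remaining production rates use the
# uniform half-to-double band that every surviving row follows.
_SENSITIVITY_TABLE: list[tuple[str, float, float]] = [
    ("lambda_ox", 5.0, 20.0),
    ("lambda_MIg", 0.002, 0.01),
    ("lambda_P", 8.65e-10 / 2, 8.65e-10 * 2),
    ("lambda_TI12", 5.0e5, 2.0e6),
    ("lambda_IgT", 0.033, 0.132),
    ("lambda_I12M", 1.5e-7, 6.0e-7),
    ("lambda_I12F", 5.0e-8, 2.0e-7),
    ("lambda_GM", 0.05, 0.2),
    ("lambda_GF", 0.016, 0.066),
    ("lambda_GS", 0.25, 1.0),
    ("lambda_QS", 1.5e-4, 6.0e-4),
    ("lambda_QrS", 1.5e-5, 6.0e-5),
    ("lambda_QrM", 3.0e-5, 1.2e-4),
    ("lambda_rho", 0.216, 0.864),
    ("lambda_F", 0.06, 0.24),
    ("beta_L", 0.5, 2.0),
    ("beta_H", 0.5, 2.0),
    ("beta_M", 0.1, 0.4),
    ("beta_T", 0.025, 0.1),
    ("beta_S", 0.1, 0.4),
    ("L0", 7.0e-4, 1.9e-3),
    ("H0", 4.0e-4, 6.0e-4),
]


def default_sensitivity_ranges(p: ParameterSet | None = None) -> list[SensitivityRange]:
    p = p or default_parameters()
    return [
        SensitivityRange(name, lo, hi, p[name]) for name, lo, hi in _SENSITIVITY_TABLE
    ]
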