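"""Cellular-level rate laws for islet nutrient consumption and insulin secretion.

All consumption and release rates are Hill-type (generalized Michaelis-Menten)
functions of the *local* concentrations.  Insulin secretion is biphasic: a
sustained second phase driven by the local glucose concentration and a
transient first phase driven by its time derivative (non-zero only while
glucose rises).  Oxygen enters twice: consumption is Michaelis-Menten in
oxygen with a glucose-dependent metabolic demand factor, and secretion is
abruptly shut down by a steep Hill modulation when local oxygen becomes
critically low.  Tissue below a critical oxygen concentration is treated as
necrotic via a smoothed step cut-off.

Units are SI throughout: concentrations in mol m^-3 (numerically equal to
mM), rates in mol m^-3 s^-1, times in s.  Partial oxygen pressures (mmHg)
are converted at the interface with :func:`po2_to_conc`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HillParams",
    "KineticsConfig",
    "hill",
    "hill_fraction",
    "smoothed_step",
    "glucose_metabolic_factor",
    "oxygen_consumption_rate",
    "glucose_consumption_rate",
    "secretion_rate_phase2",
    "gradient_modulation",
    "secretion_rate_phase1",
    "oxygen_secretion_modulation",
    "necrosis_factor",
    "total_secretion_rate",
    "local_insulin_exchange",
    "po2_to_conc",
    "conc_to_po2",
]


class InvalidParameterError(ValueError):
    """Raised for non-finite inputs or ill-posed rate-law parameters."""


@dataclass(frozen=True)
class HillParams:
    """Parameters of the Hill rate law R(c) = r_max * c^n / (c^n + c_half^n).

    r_max : maximum rate, signed (mol m^-3 s^-1; 1.0 for dimensionless
        modulating functions).
    c_half : concentration of half-maximal response (mol m^-3; for the
        first-phase gradient term, mol m^-3 s^-1 applied to dc/dt).
    n : Hill slope (dimensionless, > 0); n = 1 is Michaelis-Menten.
    """

    r_max: float
    c_half: float
    n: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.r_max) and np.isfinite(self.c_half) and np.isfinite(self.n)):
            raise InvalidParameterError("HillParams fields must be finite")
        if self.c_half <= 0:
            raise InvalidParameterError(f"c_half must be > 0, got {self.c_half}")
        if self.n <= 0:
            raise InvalidParameterError(f"Hill slope n must be > 0, got {self.n}")


def hill(c, p: HillParams):
    """Hill rate law, vectorized; small negative numerical noise is clipped to 0."""
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise InvalidParameterError("hill: non-finite concentration input")
    c = np.maximum(c, 0.0)
    cn = c ** p.n
    return p.r_max * cn / (cn + p.c_half ** p.n)


def hill_fraction(c, c_half: float, n: float):
    """Dimensionless Hill saturation fraction c^n / (c^n + c_half^n) in [0, 1)."""
    return hill(c, HillParams(1.0, c_half, n))


def smoothed_step(x, scale: float):
    """Smoothed Heaviside step: 0 for x <= -scale, 1 for x >= +scale.

    Quintic smoothstep ramp on [-scale, +scale]: continuous first derivative,
    no overshoot (range exactly [0, 1]), value 1/2 at x = 0.
    """
    if not np.isfinite(scale) or scale <= 0:
        raise InvalidParameterError(f"smoothed_step scale must be > 0, got {scale}")
    t = np.clip((np.asarray(x, dtype=float) / scale + 1.0) / 2.0, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


@dataclass(frozen=True)
class KineticsConfig:
    """Calibrated rate-law constants for human islets.

    Defaults reproduce the model calibrated against dynamic GSIR perifusion
    data (glucose staircase for second phase, hypoxia series for the oxygen
    dependence).
    """

    #: Michaelis-Menten oxygen consumption; half-max at 1 uM O2 (0.7 mmHg).
    oxy_consumption: HillParams = field(default_factory=lambda: HillParams(-0.034, 1.0e-3, 1.0))
    #: Michaelis-Menten glucose consumption; saturated at physiological glucose.
    gluc_consumption: HillParams = field(default_factory=lambda: HillParams(-0.028, 1.0e-2, 1.0))
    #: Second-phase (sustained) secretion vs local glucose; sigmoid, half-max 7 mM.
    ins_phase2: HillParams = field(default_factory=lambda: HillParams(3.0e-5, 7.0, 2.5))
    #: First-phase (transient) secretion vs glucose time-gradient dc/dt (mM/s scale).
    ins_phase1: HillParams = field(default_factory=lambda: HillParams(21.0e-5, 0.03, 2.0))
    #: Oxygen limitation of secretion; abrupt (n=3) shut-off below ~6 uM O2.
    ins_oxy_mod: HillParams = field(default_factory=lambda: HillParams(1.0, 3.0e-3, 3.0))
    #: Base / metabolic split of oxygen consumption and its overall scale.
    phi_base: float = 0.5
    phi_metab: float = 0.5
    phi_scale: float = 1.8
    #: Critical oxygen concentration for necrosis and the step half-width.
    c_crit_oxy: float = 1.0e-4
    step_scale: float = 0.5e-4
    #: First-order release rate of the local insulin compartment (t_1/2 ~ 4 min).
    k_insL: float = 0.003
    #: Glucose concentration of maximal first-phase sensitivity.
    c_mid_sigma: float = 5.0
    #: Slope of the log-logistic bump in the first-phase glucose modulation:
    #: shallow enough that the gradient response survives every upward
    #: staircase step, steep enough to vanish at zero glucose and decay where
    #: the second phase is already elevated.
    sigma_slope: float = 2.0
    #: Henry-type conversion: mmHg per (mol m^-3) of dissolved oxygen.
    po2_per_conc: float = 700.0
    #: Insulin monomer molar mass (g/mol), for mass-unit conversions.
    insulin_molar_mass: float = 5808.0

    def __post_init__(self) -> None:
        for name in ("phi_base", "phi_metab", "phi_scale", "c_crit_oxy", "step_scale",
                     "k_insL", "c_mid_sigma", "sigma_slope", "po2_per_conc",
                     "insulin_molar_mass"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"KineticsConfig.{name} must be finite and >= 0")
        if self.sigma_slope <= 0:
            raise InvalidParameterError("sigma_slope must be > 0")


_DEFAULT = None


def default_config() -> KineticsConfig:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = KineticsConfig()
    return _DEFAULT


def glucose_metabolic_factor(c_gluc, cfg: KineticsConfig | None = None):
    """Glucose-dependent modulation phi_o,g of oxygen consumption.

    Base rate plus a metabolic component that parallels second-phase
    secretion, scaled so the factor is ~1 at resting (3 mM) glucose:
    phi = Phi_sc * (phi_base + phi_metab * hill_fraction(c_gluc)).
    Rises ~70% between 3 and 15 mM glucose.
    """
    cfg = cfg or default_config()
    f = hill_fraction(c_gluc, cfg.ins_phase2.c_half, cfg.ins_phase2.n)
    return cfg.phi_scale * (cfg.phi_base + cfg.phi_metab * f)


def necrosis_factor(c_oxy, cfg: KineticsConfig | None = None):
    """Viability step delta: ~0 below the critical oxygen concentration.

    Smoothed step centered at c_crit_oxy with half-width step_scale; necrotic
    tissue neither consumes nutrients nor secretes insulin.
    """
    cfg = cfg or default_config()
    return smoothed_step(np.asarray(c_oxy, dtype=float) - cfg.c_crit_oxy, cfg.step_scale)


def oxygen_consumption_rate(c_oxy, c_gluc, cfg: KineticsConfig | None = None):
    """Local oxygen consumption rate (<= 0), with metabolic demand and necrosis cut."""
    cfg = cfg or default_config()
    return (hill(c_oxy, cfg.oxy_consumption)
            * glucose_metabolic_factor(c_gluc, cfg)
            * necrosis_factor(c_oxy, cfg))


def glucose_consumption_rate(c_gluc, c_oxy, cfg: KineticsConfig | None = None):
    """Local glucose consumption rate (<= 0); zero in necrotic tissue."""
    cfg = cfg or default_config()
    return hill(c_gluc, cfg.gluc_consumption) * necrosis_factor(c_oxy, cfg)


def secretion_rate_phase2(c_gluc, cfg: KineticsConfig | None = None):
    """Sustained second-phase insulin secretion rate vs local glucose (>= 0)."""
    cfg = cfg or default_config()
    return hill(c_gluc, cfg.ins_phase2)


def gradient_modulation(c_gluc, cfg: KineticsConfig | None = None):
    """First-phase glucose modulation sigma_i1,g: a normalized sigmoid-derivative bump.

    sigma = 4 f (1 - f) with f the Hill saturation fraction centered at
    c_mid_sigma (5 mM) — i.e. the (normalized) derivative of the sigmoid with
    respect to log-concentration, the same family as the rate laws
    themselves.  Equals 1 at 5 mM, is exactly 0 at zero glucose, and decays
    at glucose levels where the islet already operates at an elevated
    second-phase rate.
    """
    cfg = cfg or default_config()
    f = hill_fraction(c_gluc, cfg.c_mid_sigma, cfg.sigma_slope)
    return 4.0 * f * (1.0 - f)


def secretion_rate_phase1(c_gluc, dcdt, cfg: KineticsConfig | None = None):
    """Transient first-phase secretion: Hill in dc_gluc/dt, only while glucose rises."""
    cfg = cfg or default_config()
    dcdt = np.maximum(np.asarray(dcdt, dtype=float), 0.0)
    return hill(dcdt, cfg.ins_phase1) * gradient_modulation(c_gluc, cfg)


def oxygen_secretion_modulation(c_oxy, cfg: KineticsConfig | None = None):
    """Oxygen limitation phi_i,o of secretion: steep Hill, half-max at 3 uM O2."""
    cfg = cfg or default_config()
    return hill(c_oxy, cfg.ins_oxy_mod)


def total_secretion_rate(c_gluc, dcdt, c_oxy, cfg: KineticsConfig | None = None):
    """Total local insulin secretion rate R_ins (>= 0).

    Sum of first- and second-phase rates, limited by local oxygen via
    phi_i,o and zeroed in necrotic tissue.
    """
    cfg = cfg or default_config()
    return ((secretion_rate_phase1(c_gluc, dcdt, cfg) + secretion_rate_phase2(c_gluc, cfg))
            * oxygen_secretion_modulation(c_oxy, cfg)
            * necrosis_factor(c_oxy, cfg))


def local_insulin_exchange(c_insL, c_ins, r_ins, cfg: KineticsConfig | None = None):
    """Source terms of the two insulin compartments.

    Secretion fills a 'local' (intra-tissue, readily-releasable-pool-like)
    compartment which empties into free insulin with first-order rate k_insL:

        d c_insL/dt = R_ins - k_insL (c_insL - c_ins)
        d c_ins/dt  =        + k_insL (c_insL - c_ins)   (plus transport)

    The two sources sum to R_ins exactly (insulin conservation).
    """
    cfg = cfg or default_config()
    transfer = cfg.k_insL * (np.asarray(c_insL, dtype=float) - np.asarray(c_ins, dtype=float))
    return np.asarray(r_ins, dtype=float) - transfer, transfer


def po2_to_conc(p, cfg: KineticsConfig | None = None):
    """Convert oxygen partial pressure (mmHg) to dissolved concentration (mol m^-3)."""
    cfg = cfg or default_config()
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("po2_to_conc: pressure must be finite and >= 0")
    return p / cfg.po2_per_conc


def conc_to_po2(c, cfg: KineticsConfig | None = None):
    """Convert dissolved oxygen concentration (mol m^-3) to partial pressure (mmHg)."""
    cfg = cfg or default_config()
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise InvalidParameterError("conc_to_po2: concentration must be finite and >= 0")
    return c * cfg.po2_per_conc
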