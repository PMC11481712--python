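"""Regional particle deposition in the respiratory tract.

Implements the empirical series-filter deposition model: the inhaled air
stream passes a fixed sequence of nine regional filters (ET1, ET2, BB, bb, AI
on inhalation; bb, BB, ET2, ET1 on exhalation), each with an aerodynamic
(inertial impaction + gravitational settling) and a thermodynamic (diffusion)
collection efficiency combined in quadrature.  Stage deposition follows the
recursion ``DE_j = DE_{j-1} * eta_j * (phi_j/phi_{j-1}) * (1/eta_{j-1} - 1)``
with ``DE_1 = phi_1 * eta_1``; the algebraically equivalent escape-fraction
form ``A_j = phi_j * prod_{k<j}(1 - eta_k)``, ``DE_j = A_j * eta_j`` is used
so stages with zero upstream efficiency need no special casing.

Uncertainty enters through positive per-region multipliers on the empirical
fitting parameters ``a_i`` of both efficiency components; all multipliers at 1
reproduce the reference model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fixtures import _read_bundled

REGIONS: tuple[str, ...] = ("ET1", "ET2", "BB", "bb", "AI")

#: Filter sequence: inhalation pass then exhalation pass.
STAGE_REGIONS: tuple[str, ...] = (
    "ET1", "ET2", "BB", "bb", "AI", "bb", "BB", "ET2", "ET1",
)

_BOLTZMANN_ERG_PER_K = 1.380649e-16


class DepositionError(ValueError):
    pass


@dataclass(frozen=True)
class AerosolSpec:
    """Lognormal aerosol: AMAD (um), GSD, particle density (g/cm^3), shape factor."""

    amad: float
    gsd: float = 2.5
    density: float = 3.0
    shape_factor: float = 1.5

    def __post_init__(self) -> None:
        if self.amad <= 0:
            raise DepositionError("amad must be positive")
        if self.gsd < 1:
            raise DepositionError("gsd must be >= 1")
        if self.density <= 0 or self.shape_factor <= 0:
            raise DepositionError("density and shape factor must be positive")


@dataclass(frozen=True)
class BreathingPattern:
    """One respiratory activity: ventilation, frequency, tidal volume, nose fraction."""

    activity: str
    ventilation_m3_h: float
    frequency_per_min: float
    tidal_volume_L: float
    fn: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fn <= 1.0):
            raise DepositionError("fn must lie in [0, 1]")
        if min(self.ventilation_m3_h, self.frequency_per_min, self.tidal_volume_L) <= 0:
            raise DepositionError("breathing rates and volumes must be positive")

    @property
    def tidal_volume_cm3(self) -> float:
        return self.tidal_volume_L * 1000.0

    @property
    def mean_inspiratory_flow_cm3_s(self) -> float:
        # inhalation occupies half the breathing cycle
        return self.tidal_volume_cm3 * self.frequency_per_min * 2.0 / 60.0


@dataclass(frozen=True)
class WorkerScenario:
    """Mixture of breathing activities weighted by the fraction of air breathed."""

    entries: tuple[tuple[BreathingPattern, float], ...]

    def __post_init__(self) -> None:
        fractions = [f for _, f in self.entries]
        if any(f < 0 for f in fractions):
            raise DepositionError("air fractions must be non-negative")
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise DepositionError(f"air fractions sum to {sum(fractions)}, expected 1")

    def with_fn(self, fn: float) -> "WorkerScenario":
        return WorkerScenario(
            tuple((replace(p, fn=fn), f) for p, f in self.entries)
        )

    @staticmethod
    def reference_worker() -> "WorkerScenario":
        patterns = _read_bundled("breathing_patterns.csv").set_index("activity")
        mix = _read_bundled("worker_scenario.csv")
        mix = mix[mix["scenario"] == "worker"]
        entries = []
        for row in mix.itertuples():
            p = patterns.loc[row.activity]
            entries.append(
                (
                    BreathingPattern(
                        activity=row.activity,
                        ventilation_m3_h=float(p.ventilation_m3_h),
                        frequency_per_min=float(p.frequency_per_min),
                        tidal_volume_L=float(p.tidal_volume_L),
                        fn=float(p.fn),
                    ),
                    float(row.air_fraction),
                )
            )
        # renormalise the transcribed two-activity split exactly
        total = sum(f for _, f in entries)
        entries = [(p, f / total) for p, f in entries]
        return WorkerScenario(tuple(entries))


@dataclass(frozen=True)
class DepositionMultipliers:
    """Positive multipliers on the aerodynamic/thermodynamic fitting parameters."""

    c_ae: Mapping[str, float] = field(default_factory=dict)
    c_th: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.c_ae, self.c_th):
            for region, value in table.items():
                if region not in REGIONS:
                    raise DepositionError(f"unknown region {region!r}")
                if value < 0:
                    raise DepositionError(f"multiplier for {region} must be >= 0")

    def ae(self, region: str) -> float:
        return float(self.c_ae.get(region, 1.0))

    def th(self, region: str) -> float:
        return float(self.c_th.get(region, 1.0))

    @staticmethod
    def neutral() -> "DepositionMultipliers":
        return DepositionMultipliers({}, {})


@dataclass(frozen=True)
class RegionalDeposition:
    """Fractional deposit per region plus exhaled and not-inhaled fractions."""

    fractions: Mapping[str, float]
    exhaled: float
    not_inhaled: float

    def __post_init__(self) -> None:
        parts = list(self.fractions.values()) + [self.exhaled, self.not_inhaled]
        if min(parts) < -1e-12:
            raise DepositionError(f"negative deposition component: {self.fractions}")
        if abs(sum(parts) - 1.0) > 1e-9:
            raise DepositionError(f"deposition components sum to {sum(parts)}")

    @property
    def total_deposited(self) -> float:
        return float(sum(self.fractions.values()))

    def as_series(self) -> pd.Series:
        data = dict(self.fractions)
        data["exhaled"] = self.exhaled
        data["not_inhaled"] = self.not_inhaled
        return pd.Series(data)


@dataclass(frozen=True)
class CompartmentDeposit:
    """Initial fractional deposit per particle-transport compartment."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        if min(self.fractions.values(), default=0.0) < 0:
            raise DepositionError("compartment deposits must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.fractions.values()))


# ---------------------------------------------------------------------------
# Constants


@dataclass(frozen=True)
class DepositionConstants:
    """Empirical efficiency terms, scaling constants and anatomical parameters."""

    terms: pd.DataFrame      # region, component, pathway, form, argument, a, p
    scaling: pd.DataFrame    # region, component, c
    misc: Mapping[str, float]
    _term_index: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for region in REGIONS:
            for component in ("ae", "th"):
                sub = self.terms[
                    (self.terms["region"] == region)
                    & (self.terms["component"] == component)
                ]
                if sub.empty:
                    raise DepositionError(
                        f"no {component} efficiency terms for region {region}"
                    )
        # flat lookup of (form, argument, a, p) tuples per slot; the row
        # filtering above runs once at load, never per evaluation
        index: dict[tuple[str, str, str], tuple] = {}
        for row in self.terms.itertuples():
            key = (row.region, row.component, row.pathway)
            index.setdefault(key, []).append(
                (row.form, row.argument, float(row.a), float(row.p))
            )
        for region in REGIONS:
            for component in ("ae", "th"):
                for pathway in ("nose", "mouth"):
                    rows = list(index.get((region, component, pathway), []))
                    rows += index.get((region, component, "any"), [])
                    if rows:
                        object.__setattr__(
                            self, "_term_index",
                            {**self._term_index, (region, component, pathway): tuple(rows)},
                        )

    def terms_for(self, region: str, component: str, pathway: str) -> tuple:
        """Efficiency terms for one slot as (form, argument, a, p) tuples."""
        try:
            return self._term_index[(region, component, pathway)]
        except KeyError:
            raise DepositionError(
                f"no {component} terms for region {region}, pathway {pathway}"
            ) from None

    def multiplier_gsd(self, region: str, component: str) -> float:
        sub = self.scaling[
            (self.scaling["region"] == region)
            & (self.scaling["component"] == component)
        ]
        return float(np.sqrt(sub["c"].iloc[0]))


@lru_cache(maxsize=1)
def load_deposition_constants() -> DepositionConstants:
    misc = _read_bundled("deposition_misc.csv").set_index("name")["value"].to_dict()
    return DepositionConstants(
        terms=_read_bundled("deposition_efficiency_terms.csv"),
        scaling=_read_bundled("deposition_scaling_constants.csv"),
        misc=misc,
    )


# ---------------------------------------------------------------------------
# Particle physics helpers


def slip_correction(d_um: np.ndarray | float, mean_free_path_um: float) -> np.ndarray:
    d = np.asarray(d_um, dtype=float)
    kn = 2.0 * mean_free_path_um / d
    return 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))


def diffusion_coefficient_cm2_s(
    d_th_um: np.ndarray | float, constants: DepositionConstants
) -> np.ndarray:
    """Brownian diffusion coefficient of a sphere of thermodynamic diameter d_th."""
    d = np.asarray(d_th_um, dtype=float)
    c = slip_correction(d, constants.misc["mean_free_path_um"])
    mu = constants.misc["air_viscosity_poise"]
    temp = constants.misc["air_temperature_K"]
    d_cm = d * 1e-4
    return _BOLTZMANN_ERG_PER_K * temp * c / (3.0 * np.pi * mu * d_cm)


def thermodynamic_diameter(
    d_ae_um: np.ndarray | float,
    density: float = 3.0,
    shape_factor: float = 1.5,
    constants: DepositionConstants | None = None,
    iterations: int = 30,
) -> np.ndarray:
    """Thermodynamic diameter matching a given aerodynamic diameter.

    Solves ``(rho/chi) d_th^2 C(d_th) = rho_0 d_ae^2 C(d_ae)`` by fixed-point
    iteration with the Cunningham slip correction.
    """
    constants = constants or load_deposition_constants()
    mfp = constants.misc["mean_free_path_um"]
    d_ae = np.asarray(d_ae_um, dtype=float)
    rho_eff = density / shape_factor
    d_th = d_ae / np.sqrt(rho_eff)
    c_ae = slip_correction(d_ae, mfp)
    for _ in range(iterations):
        d_th = d_ae * np.sqrt(c_ae / (rho_eff * slip_correction(d_th, mfp)))
    return d_th


def inhalability(d_ae_um: np.ndarray | float, constants: DepositionConstants) -> np.ndarray:
    d = np.asarray(d_ae_um, dtype=float)
    a = constants.misc["inhalability_a"]
    p = constants.misc["inhalability_p"]
    return 1.0 - 0.5 * (1.0 - 1.0 / (1.0 + a * d**p))


# ---------------------------------------------------------------------------
# Efficiencies


def _residence_time_s(region: str, pattern: BreathingPattern,
                      constants: DepositionConstants) -> float:
    flow = pattern.mean_inspiratory_flow_cm3_s
    v_et = constants.misc["dead_space_ET_cm3"]
    v_bb = constants.misc["dead_space_BB_cm3"]
    v_bbb = constants.misc["dead_space_bb_cm3"]
    if region in ("ET1", "ET2"):
        return 0.5 * v_et / flow
    if region == "BB":
        return v_bb / flow
    if region == "bb":
        return v_bbb / flow
    if region == "AI":
        vt = pattern.tidal_volume_cm3
        return max(vt - v_et - v_bb - v_bbb, 0.0) / flow
    raise DepositionError(f"unknown region {region!r}")


def _argument(kind: str, d_ae, d_th, pattern: BreathingPattern, region: str,
              constants: DepositionConstants) -> np.ndarray:
    t = _residence_time_s(region, pattern, constants)
    if kind == "impaction":
        return np.asarray(d_ae, dtype=float) ** 2 * pattern.mean_inspiratory_flow_cm3_s
    if kind == "settling":
        return np.asarray(d_ae, dtype=float) ** 2 * t
    if kind == "diffusion":
        return 1e4 * diffusion_coefficient_cm2_s(d_th, constants) * t
    raise DepositionError(f"unknown efficiency argument {kind!r}")


def _component_efficiency(region: str, component: str, pathway: str,
                          d_ae, d_th, pattern: BreathingPattern,
                          multiplier: float,
                          constants: DepositionConstants) -> np.ndarray:
    if multiplier < 0:
        raise DepositionError("efficiency multiplier must be >= 0")
    rows = constants.terms_for(region, component, pathway)
    x = np.zeros_like(np.asarray(d_ae, dtype=float))
    for form, argument, a, p in rows:
        arg = _argument(argument, d_ae, d_th, pattern, region, constants)
        x = x + multiplier * a * np.power(arg, p)
    form = rows[0][0]
    if form == "saturating":
        eta = x / (1.0 + x)
    else:
        eta = 1.0 - np.exp(-x)
    return np.clip(eta, 0.0, 1.0)


def aerodynamic_efficiency(
    region: str,
    d_ae_um: np.ndarray | float,
    pattern: BreathingPattern,
    multiplier: float = 1.0,
    pathway: str = "nose",
    constants: DepositionConstants | None = None,
) -> np.ndarray:
    """Impaction + settling collection efficiency of one regional filter."""
    if region not in REGIONS:
        raise DepositionError(f"unknown region {region!r}")
    constants = constants or load_deposition_constants()
    d_ae = np.asarray(d_ae_um, dtype=float)
    if np.any(d_ae <= 0):
        raise DepositionError("d_ae must be positive")
    d_th = thermodynamic_diameter(d_ae, constants=constants)
    return _component_efficiency(
        region, "ae", pathway, d_ae, d_th, pattern, multiplier, constants
    )


def thermodynamic_efficiency(
    region: str,
    d_th_um: np.ndarray | float,
    pattern: BreathingPattern,
    multiplier: float = 1.0,
    pathway: str = "nose",
    constants: DepositionConstants | None = None,
) -> np.ndarray:
    """Diffusional collection efficiency of one regional filter."""
    if region not in REGIONS:
        raise DepositionError(f"unknown region {region!r}")
    constants = constants or load_deposition_constants()
    d_th = np.asarray(d_th_um, dtype=float)
    if np.any(d_th <= 0):
        raise DepositionError("d_th must be positive")
    return _component_efficiency(
        region, "th", pathway, d_th, d_th, pattern, multiplier, constants
    )


def filtration_chain(
    eta: Sequence[float] | np.ndarray, phi: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Per-stage deposition fractions of a series of filters.

    ``eta[j]`` is the filtration efficiency of stage j, ``phi[j]`` the fraction
    of inhaled air reaching that stage.  Uses the escape-fraction recursion
    ``A_j = phi_j * prod_{k<j}(1 - eta_k)``, ``DE_j = A_j eta_j`` (identical to
    the stage recursion initialised with ``DE_1 = phi_1 eta_1`` but defined
    when an upstream efficiency is zero).  Stages are broadcast over trailing
    particle-size axes.
    """
    eta = np.asarray(eta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if eta.shape[0] != phi.shape[0]:
        raise DepositionError("eta and phi must have one entry per stage")
    if np.any(eta < 0) or np.any(eta > 1):
        raise DepositionError("filtration efficiencies must lie in [0, 1]")
    if np.any(phi <= 0) or np.any(phi > 1):
        raise DepositionError("volumetric factors must lie in (0, 1]")
    de = np.zeros(eta.shape)
    surviving = np.ones(eta.shape[1:])
    for j in range(eta.shape[0]):
        de[j] = phi[j] * surviving * eta[j]
        surviving = surviving * (1.0 - eta[j])
    return de


def _stage_phi(pattern: BreathingPattern, constants: DepositionConstants) -> np.ndarray:
    vt = pattern.tidal_volume_cm3
    v_et = constants.misc["dead_space_ET_cm3"]
    v_bb = constants.misc["dead_space_BB_cm3"]
    v_bbb = constants.misc["dead_space_bb_cm3"]
    phi_bb = (vt - v_et) / vt
    phi_bbb = (vt - v_et - v_bb) / vt
    phi_ai = (vt - v_et - v_bb - v_bbb) / vt
    return np.array([1.0, 1.0, phi_bb, phi_bbb, phi_ai, phi_bbb, phi_bb, 1.0, 1.0])


def _path_regional_deposits(
    d_ae: np.ndarray,
    pattern: BreathingPattern,
    multipliers: DepositionMultipliers,
    pathway: str,
    density: float,
    shape_factor: float,
    constants: DepositionConstants,
) -> dict[str, np.ndarray]:
    """Regional deposits per unit inhalable activity for one breathing path."""
    d_ae = np.atleast_1d(np.asarray(d_ae, dtype=float))
    d_th = thermodynamic_diameter(d_ae, density, shape_factor, constants)
    eta = np.zeros((len(STAGE_REGIONS),) + d_ae.shape)
    for j, region in enumerate(STAGE_REGIONS):
        if pathway == "mouth" and region == "ET1":
            continue  # oral path bypasses the anterior nose filter
        eta_ae = _component_efficiency(
            region, "ae", pathway, d_ae, d_th, pattern,
            multipliers.ae(region), constants,
        )
        eta_th = _component_efficiency(
            region, "th", pathway, d_th, d_th, pattern,
            multipliers.th(region), constants,
        )
        eta[j] = np.minimum(1.0, np.sqrt(eta_ae**2 + eta_th**2))
    de = filtration_chain(eta, _stage_phi(pattern, constants))
    deposits = {region: np.zeros(d_ae.shape) for region in REGIONS}
    for j, region in enumerate(STAGE_REGIONS):
        deposits[region] += de[j]
    # extrathoracic redistribution: part of the anterior-nose filter deposit
    # is assigned to the posterior extrathoracic region
    keep = constants.misc["et1_retention_fraction"]
    moved = deposits["ET1"] * (1.0 - keep)
    deposits["ET1"] = deposits["ET1"] * keep
    deposits["ET2"] = deposits["ET2"] + moved
    return deposits


def _monodisperse_arrays(
    d_ae: np.ndarray,
    scenario: WorkerScenario,
    multipliers: DepositionMultipliers,
    density: float,
    shape_factor: float,
    constants: DepositionConstants,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    d_ae = np.atleast_1d(np.asarray(d_ae, dtype=float))
    inhalable = inhalability(d_ae, constants)
    totals = {region: np.zeros(d_ae.shape) for region in REGIONS}
    for pattern, air_fraction in scenario.entries:
        nose = _path_regional_deposits(
            d_ae, pattern, multipliers, "nose", density, shape_factor, constants
        )
        if pattern.fn < 1.0:
            mouth = _path_regional_deposits(
                d_ae, pattern, multipliers, "mouth", density, shape_factor, constants
            )
        else:
            mouth = {region: np.zeros(d_ae.shape) for region in REGIONS}
        for region in REGIONS:
            mixed = pattern.fn * nose[region] + (1.0 - pattern.fn) * mouth[region]
            totals[region] += air_fraction * inhalable * mixed
    deposited = sum(totals.values())
    exhaled = inhalable - deposited
    not_inhaled = 1.0 - inhalable
    return totals, exhaled, not_inhaled


def monodisperse_deposition(
    d_ae_um: float,
    scenario: WorkerScenario,
    multipliers: DepositionMultipliers | None = None,
    density: float = 3.0,
    shape_factor: float = 1.5,
    constants: DepositionConstants | None = None,
) -> RegionalDeposition:
    """Regional deposition of a monodisperse aerosol, air-fraction weighted
    over the scenario's breathing activities and mixed over nose/mouth paths."""
    constants = constants or load_deposition_constants()
    multipliers = multipliers or DepositionMultipliers.neutral()
    totals, exhaled, not_inhaled = _monodisperse_arrays(
        np.array([d_ae_um]), scenario, multipliers, density, shape_factor, constants
    )
    return RegionalDeposition(
        fractions={region: float(v[0]) for region, v in totals.items()},
        exhaled=float(exhaled[0]),
        not_inhaled=float(not_inhaled[0]),
    )


@lru_cache(maxsize=8)
def _hermgauss_cached(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.hermite.hermgauss(n_nodes)


def _polydisperse_arrays(
    aerosol: AerosolSpec,
    scenario: WorkerScenario,
    multipliers: DepositionMultipliers,
    constants: DepositionConstants,
    n_nodes: int,
) -> tuple[dict[str, float], float, float]:
    nodes, weights = _hermgauss_cached(n_nodes)
    sigma = np.log(aerosol.gsd)
    d = aerosol.amad * np.exp(np.sqrt(2.0) * sigma * nodes)
    w = weights / np.sqrt(np.pi)
    totals, exhaled, not_inhaled = _monodisperse_arrays(
        d, scenario, multipliers, aerosol.density, aerosol.shape_factor, constants
    )
    region_totals = {region: float(v @ w) for region, v in totals.items()}
    return region_totals, float(exhaled @ w), float(not_inhaled @ w)


def polydisperse_deposition(
    aerosol: AerosolSpec,
    scenario: WorkerScenario,
    multipliers: DepositionMultipliers | None = None,
    constants: DepositionConstants | None = None,
    n_nodes: int = 64,
    refinement_tolerance: float = 1e-6,
) -> RegionalDeposition:
    """Deposition of a lognormal aerosol via Gauss-Hermite quadrature in ln d.

    Node count is doubled once as a refinement check; any component changing
    by more than ``refinement_tolerance`` raises.
    """
    constants = constants or load_deposition_constants()
    multipliers = multipliers or DepositionMultipliers.neutral()
    if aerosol.gsd == 1.0:
        return monodisperse_deposition(
            aerosol.amad, scenario, multipliers,
            aerosol.density, aerosol.shape_factor, constants,
        )
    coarse = _polydisperse_arrays(aerosol, scenario, multipliers, constants, n_nodes)
    fine = _polydisperse_arrays(aerosol, scenario, multipliers, constants, 2 * n_nodes)
    deltas = [abs(coarse[0][r] - fine[0][r]) for r in REGIONS]
    deltas += [abs(coarse[1] - fine[1]), abs(coarse[2] - fine[2])]
    if max(deltas) > refinement_tolerance:
        raise DepositionError(
            f"size quadrature not converged at {n_nodes} nodes "
            f"(max change {max(deltas):.2e})"
        )
    totals, exhaled, not_inhaled = fine
    return RegionalDeposition(
        fractions=totals, exhaled=exhaled, not_inhaled=not_inhaled
    )


def apportion_deposit(
    regional: RegionalDeposition,
    f_d: Mapping[str, float] | None = None,
) -> CompartmentDeposit:
    """Split regional deposits into particle-transport compartments.

    ``f_d`` maps region (ET2, BB, bb) to the sequestered fraction of that
    region's deposit; everything else goes to the prime compartment.  The AI
    deposit is assigned to ALV: the interstitium receives material only by
    transport.
    """
    f_d = dict(f_d or {})
    defaults = {"ET2": 0.002, "BB": 0.002, "bb": 0.002}
    defaults.update(f_d)
    for region, value in defaults.items():
        if not (0.0 <= value < 1.0):
            raise DepositionError(f"f_d for {region} must lie in [0, 1)")
    frac = regional.fractions
    out = {
        "ET1": frac["ET1"],
        "ETseq": frac["ET2"] * defaults["ET2"],
        "ET2prime": frac["ET2"] * (1.0 - defaults["ET2"]),
        "BBseq": frac["BB"] * defaults["BB"],
        "BBprime": frac["BB"] * (1.0 - defaults["BB"]),
        "bbseq": frac["bb"] * defaults["bb"],
        "bbprime": frac["bb"] * (1.0 - defaults["bb"]),
        "ALV": frac["AI"],
        "INT": 0.0,
    }
    return CompartmentDeposit(fractions=out)
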