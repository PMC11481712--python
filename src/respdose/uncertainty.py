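"""Uncertain-parameter catalogue, Latin-hypercube design and propagation.

Eighteen respiratory-tract parameters are treated as uncertain: ten lognormal
multipliers on the regional deposition-efficiency fitting parameters, three
lognormal sequestration fractions, the triangular nose-breathing fraction Fn,
three lognormal alveolar-interstitial transport rates and the lognormal
correlated-transport scale factor Kpt (``K_factor``).  Systemic and
dissolution rates stay at reference values during propagation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .biokinetics import DEFAULT_COMMITMENT_DAYS, RateModifiers, build_full_system, integrate_retention
from .deposition import AerosolSpec, DepositionMultipliers, WorkerScenario, apportion_deposit, polydisperse_deposition
from .dosimetry import STablePair, committed_effective, committed_equivalent_dose


class UncertaintyError(ValueError):
    pass


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution: lognormal (GM, GSD), triangular (min, mode, max)
    or a degenerate point mass ('fixed', (value,)) used for neutral designs."""

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family == "lognormal":
            gm, gsd = self.params
            if gm <= 0 or gsd <= 1:
                raise UncertaintyError("lognormal requires GM > 0 and GSD > 1")
        elif self.family == "triangular":
            lo, mode, hi = self.params
            if not (lo <= mode <= hi) or lo >= hi:
                raise UncertaintyError("triangular requires min <= mode <= max, min < max")
        elif self.family == "fixed":
            if len(self.params) != 1:
                raise UncertaintyError("fixed requires a single value")
        else:
            raise UncertaintyError(f"unknown family {self.family!r}")

    @property
    def median(self) -> float:
        return float(quantile(self, 0.5))


def quantile(spec: DistributionSpec, u: np.ndarray | float) -> np.ndarray:
    """Inverse CDF of the specification.

    The right-angled triangular case (mode = max) inverts
    ``F(x) = (x - min)^2 / ((max - min)(mode - min))`` directly.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise UncertaintyError("probabilities must lie in [0, 1]")
    if spec.family == "lognormal":
        gm, gsd = spec.params
        return np.exp(np.log(gm) + np.log(gsd) * st.norm.ppf(u))
    if spec.family == "fixed":
        return np.full_like(u, spec.params[0])
    lo, mode, hi = spec.params
    span = hi - lo
    f_mode = (mode - lo) / span
    with np.errstate(invalid="ignore"):
        left = lo + np.sqrt(u * span * (mode - lo))
        right = hi - np.sqrt((1.0 - u) * span * (hi - mode))
    if mode == hi:
        return left
    if mode == lo:
        return right
    return np.where(u <= f_mode, left, right)


@dataclass(frozen=True)
class UncertainParameter:
    name: str
    spec: DistributionSpec
    binding: tuple[str, ...]


@dataclass(frozen=True)
class UncertainParameterSet:
    parameters: tuple[UncertainParameter, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def __len__(self) -> int:
        return len(self.parameters)

    def replaced_with_medians(self) -> "UncertainParameterSet":
        """Point-mass copy at each parameter's neutral (median) value."""
        return UncertainParameterSet(
            tuple(
                UncertainParameter(
                    p.name, DistributionSpec("fixed", (p.spec.median,)), p.binding
                )
                for p in self.parameters
            )
        )


def reference_parameter_table() -> UncertainParameterSet:
    """The 18 uncertain respiratory-tract parameters of the stochastic study."""
    ln = lambda gm, gsd: DistributionSpec("lognormal", (gm, gsd))
    params = [
        UncertainParameter("Fn", DistributionSpec("triangular", (0.4, 1.0, 1.0)), ("fn",)),
        UncertainParameter("Cae_ET1", ln(1.00, 1.82), ("c_ae", "ET1")),
        UncertainParameter("Cae_ET2", ln(1.00, 1.82), ("c_ae", "ET2")),
        UncertainParameter("Cae_BB", ln(1.00, 1.58), ("c_ae", "BB")),
        UncertainParameter("Cae_bb", ln(1.00, 1.58), ("c_ae", "bb")),
        UncertainParameter("Cae_AI", ln(1.00, 1.30), ("c_ae", "AI")),
        UncertainParameter("Cth_ET1", ln(1.00, 1.18), ("c_th", "ET1")),
        UncertainParameter("Cth_ET2", ln(1.00, 1.18), ("c_th", "ET2")),
        UncertainParameter("Cth_BB", ln(1.00, 1.23), ("c_th", "BB")),
        UncertainParameter("Cth_bb", ln(1.00, 1.23), ("c_th", "bb")),
        UncertainParameter("Cth_AI", ln(1.00, 1.23), ("c_th", "AI")),
        UncertainParameter("fd_ETseq", ln(0.002, 1.73), ("f_d", "ET2")),
        UncertainParameter("fd_BBseq", ln(0.002, 1.73), ("f_d", "BB")),
        UncertainParameter("fd_bbseq", ln(0.002, 1.73), ("f_d", "bb")),
        UncertainParameter("L_ALV_INT", ln(0.001, 4.5), ("rate", "l_alv_int")),
        UncertainParameter("L_ALV_bb", ln(0.002, 3.2), ("rate", "l_alv_bb")),
        UncertainParameter("L_INT_LNTH", ln(0.00003, 3.0), ("rate", "l_int_lnth")),
        UncertainParameter("K_factor", ln(1.0, 1.73), ("kpt",)),
    ]
    return UncertainParameterSet(tuple(params))


@dataclass(frozen=True)
class DesignMatrix:
    values: np.ndarray
    names: tuple[str, ...]
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))


def lhs_design(
    params: UncertainParameterSet, n: int, seed: int
) -> DesignMatrix:
    """Latin-hypercube design: per column, one uniform draw in each of the n
    equal-probability strata, stratum order independently permuted."""
    if n < 1:
        raise UncertaintyError("n must be at least 1")
    rng = np.random.default_rng(seed)
    cols = []
    for p in params.parameters:
        strata = rng.permutation(n)
        u = (strata + rng.uniform(size=n)) / n
        cols.append(quantile(p.spec, u))
    return DesignMatrix(
        values=np.column_stack(cols), names=params.names, seed=seed
    )


def required_sample_size(
    sd: float, precision: float, confidence: float = 0.95
) -> int:
    """n = ceil((z_(1+conf)/2 * sd / E)^2), at least 1."""
    if precision <= 0:
        raise UncertaintyError("precision must be positive")
    if sd < 0 or not (0 < confidence < 1):
        raise UncertaintyError("invalid sample-size specification")
    z = st.norm.ppf(0.5 * (1.0 + confidence))
    return max(1, math.ceil((z * sd / precision) ** 2))


@dataclass(frozen=True)
class CEDCSample:
    values: np.ndarray
    design: DesignMatrix
    tau_d: float

    def __post_init__(self) -> None:
        if np.any(self.values <= 0):
            raise UncertaintyError("CEDC samples must be positive")


def _bindings_to_inputs(
    params: UncertainParameterSet, row: np.ndarray
) -> tuple[DepositionMultipliers, dict[str, float], float, RateModifiers]:
    c_ae: dict[str, float] = {}
    c_th: dict[str, float] = {}
    f_d: dict[str, float] = {}
    fn = 1.0
    rates: dict[str, float] = {}
    kpt = 1.0
    for p, value in zip(params.parameters, row):
        kind = p.binding[0]
        if kind == "c_ae":
            c_ae[p.binding[1]] = value
        elif kind == "c_th":
            c_th[p.binding[1]] = value
        elif kind == "f_d":
            f_d[p.binding[1]] = min(value, 1.0 - 1e-12)
        elif kind == "fn":
            fn = min(max(value, 0.0), 1.0)
        elif kind == "rate":
            rates[p.binding[1]] = value
        elif kind == "kpt":
            kpt = value
        else:
            raise UncertaintyError(f"unresolvable binding {p.binding!r}")
    modifiers = RateModifiers(kpt=kpt, **{
        k: rates.get(k, getattr(RateModifiers, k))
        for k in ("l_alv_int", "l_alv_bb", "l_int_lnth")
    })
    return DepositionMultipliers(c_ae, c_th), f_d, fn, modifiers


def propagate(
    design: DesignMatrix,
    aerosol: AerosolSpec,
    scenario: WorkerScenario,
    s_pair: STablePair,
    params: UncertainParameterSet | None = None,
    tau_d: float = DEFAULT_COMMITMENT_DAYS,
    tables=None,
    nuclide: str = "I-131",
    weights=None,
) -> CEDCSample:
    """Evaluate the deterministic dose chain at every design row.

    Row values bind to their model slots (multipliers to deposition, f_d to
    apportionment, Fn to the breathing mix, AI rates and Kpt to transport);
    systemic and dissolution rates remain at reference.  Any row failure
    aborts with the row index and bound values.
    """
    params = params or reference_parameter_table()
    if design.names != params.names:
        raise UncertaintyError("design columns do not match parameter set")
    from . import fixtures  # local import to avoid cycle at module load

    tables = tables or fixtures.load_all_rate_tables()
    if weights is None:
        weights = fixtures.load_tissue_weights()
    out = np.empty(design.values.shape[0])
    for i, row in enumerate(design.values):
        try:
            multipliers, f_d, fn, modifiers = _bindings_to_inputs(params, row)
            regional = polydisperse_deposition(
                aerosol, scenario.with_fn(fn), multipliers
            )
            deposit = apportion_deposit(regional, f_d)
            system, x0 = build_full_system(deposit, modifiers, tables, nuclide)
            integrated = integrate_retention(system, x0, tau_d)
            h_m = committed_equivalent_dose(integrated, s_pair.male)
            h_f = committed_equivalent_dose(integrated, s_pair.female)
            out[i] = committed_effective(h_m, h_f, weights)
        except Exception as exc:
            raise UncertaintyError(
                f"propagation failed at row {i} with values "
                f"{dict(zip(design.names, row))}: {exc}"
            ) from exc
    return CEDCSample(values=out, design=design, tau_d=tau_d)


def summarize(values: np.ndarray | CEDCSample) -> dict[str, float]:
    """Mean, sample SD (n-1), extrema and the 2.5/25/50/75/97.5 percentiles
    (linear interpolation between order statistics)."""
    if isinstance(values, CEDCSample):
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise UncertaintyError("empty sample")
    qs = np.percentile(values, [2.5, 25, 50, 75, 97.5])
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "min": float(values.min()),
        "max": float(values.max()),
        "p2.5": float(qs[0]),
        "p25": float(qs[1]),
        "p50": float(qs[2]),
        "p75": float(qs[3]),
        "p97.5": float(qs[4]),
    }


DEFAULT_FIT_FAMILIES: tuple[str, ...] = (
    "norm", "lognorm", "gamma", "loggamma", "beta",
    "weibull_min", "triang", "uniform",
)


@dataclass(frozen=True)
class FitResult:
    family: str
    params: tuple[float, ...]
    d_statistic: float
    p_value: float
    accepted: bool  # p > 0.05


def best_fit_distribution(
    values: np.ndarray | CEDCSample,
    candidates: Sequence[str] = DEFAULT_FIT_FAMILIES,
    significance: float = 0.05,
) -> list[FitResult]:
    """Fit candidate families by maximum likelihood and rank by the one-sample
    two-sided Kolmogorov-Smirnov sup-distance against each fitted CDF.

    Families that fail to fit are skipped with a warning.  The leading entry
    is additionally required to exceed the significance level to count as an
    accepted best fit (``accepted`` flag).
    """
    if isinstance(values, CEDCSample):
        values = values.values
    values = np.asarray(values, dtype=float)
    if values.size < 50:
        raise UncertaintyError("need at least 50 observations to fit")
    if not candidates:
        raise UncertaintyError("candidate family list is empty")
    if np.ptp(values) == 0:
        raise UncertaintyError("sample is constant; distribution fitting refused")
    results = []
    for name in candidates:
        dist = getattr(st, name, None)
        if dist is None:
            warnings.warn(f"unknown scipy family {name!r}; skipped")
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitted = dist.fit(values)
                ks = st.kstest(values, name, args=fitted)
            if not np.isfinite(ks.statistic):
                raise FloatingPointError("non-finite K-S statistic")
        except Exception as exc:  # fit failures are non-fatal
            warnings.warn(f"fit failed for family {name!r}: {exc}")
            continue
        results.append(
            FitResult(
                family=name,
                params=tuple(float(v) for v in fitted),
                d_statistic=float(ks.statistic),
                p_value=float(ks.pvalue),
                accepted=bool(ks.pvalue > significance),
            )
        )
    results.sort(key=lambda r: r.d_statistic)
    if not results:
        raise UncertaintyError("every candidate family failed to fit")
    return results


@dataclass(frozen=True)
class UFResult:
    """Uncertainty factor around a central estimate with 95% bounds."""

    central: float
    q_lower: float
    q_upper: float
    ratio_lower: float   # central / Q_L
    ratio_upper: float   # Q_U / central
    uf: float

    @property
    def rounded(self) -> float:
        return round(self.uf, 2)


def uncertainty_factor(central: float, q_lower: float, q_upper: float) -> UFResult:
    """UF = max(C / Q_L, Q_U / C); scale-invariant, >= 1 when Q_L <= C <= Q_U."""
    if min(central, q_lower, q_upper) <= 0:
        raise UncertaintyError("central estimate and bounds must be positive")
    rl = central / q_lower
    ru = q_upper / central
    return UFResult(
        central=central, q_lower=q_lower, q_upper=q_upper,
        ratio_lower=rl, ratio_upper=ru, uf=max(rl, ru),
    )
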