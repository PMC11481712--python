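"""Committed equivalent and effective dose coefficients.

Folds time-integrated source-region activity with sex-specific radiation
weighted S-coefficients into committed equivalent dose coefficients h(T) per
tissue, then combines the sexes with tissue weighting factors into the
committed effective dose coefficient E = sum_T w_T (h_M + h_F)/2, in Sv/Bq.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import fixtures
from .biokinetics import (
    DEFAULT_COMMITMENT_DAYS,
    IntegratedActivity,
    RateModifiers,
    build_full_system,
    integrate_retention,
)
from .deposition import (
    AerosolSpec,
    DepositionMultipliers,
    WorkerScenario,
    apportion_deposit,
    polydisperse_deposition,
)

#: S values are per nuclear transformation; integrated activity is Bq d.
TRANSFORMATIONS_PER_BQ_DAY = 86_400.0


class DosimetryError(ValueError):
    pass


@dataclass(frozen=True)
class STablePair:
    """Male and female (source, target) -> S maps, Sv per transformation."""

    male: Mapping[tuple[str, str], float]
    female: Mapping[tuple[str, str], float]

    @staticmethod
    def from_synthetic(table: fixtures.SyntheticSTable) -> "STablePair":
        return STablePair(male=table.sex_map("M"), female=table.sex_map("F"))

    @staticmethod
    def from_frame(frame: pd.DataFrame) -> "STablePair":
        def _map(sex: str) -> dict[tuple[str, str], float]:
            sub = frame[frame["sex"] == sex]
            return {
                (r.source, r.target): r.S_Sv_per_transformation
                for r in sub.itertuples()
            }

        return STablePair(male=_map("M"), female=_map("F"))

    def targets(self) -> tuple[str, ...]:
        return tuple(sorted({t for _, t in self.male}))


@dataclass(frozen=True)
class DoseCoefficientResult:
    h_male: Mapping[str, float]
    h_female: Mapping[str, float]
    effective: float
    tau_d: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"h_M_Sv_per_Bq": pd.Series(self.h_male),
             "h_F_Sv_per_Bq": pd.Series(self.h_female)}
        )


def committed_equivalent_dose(
    integrated: IntegratedActivity,
    s_map: Mapping[tuple[str, str], float],
) -> dict[str, float]:
    """h(T) = sum_S U(S) * S(T <- S), converted from Bq d to transformations."""
    targets = sorted({t for _, t in s_map})
    doses = {t: 0.0 for t in targets}
    for source, u in integrated.per_source.items():
        for target in targets:
            if (source, target) not in s_map:
                raise DosimetryError(
                    f"S-table missing pair (source={source}, target={target})"
                )
            doses[target] += (
                u * TRANSFORMATIONS_PER_BQ_DAY * s_map[(source, target)]
            )
    return doses


def committed_effective(
    h_male: Mapping[str, float],
    h_female: Mapping[str, float],
    weights: Mapping[str, float] | pd.Series | None = None,
) -> float:
    """Sex-averaged tissue-weighted combination E = sum w_T (h_M + h_F)/2."""
    if weights is None:
        weights = fixtures.load_tissue_weights()
    weights = dict(weights)
    if set(h_male) != set(h_female):
        raise DosimetryError("male and female tissue sets differ")
    missing = set(weights) - set(h_male)
    if missing:
        raise DosimetryError(f"equivalent doses missing weighted tissues: {sorted(missing)}")
    return float(
        sum(w * 0.5 * (h_male[t] + h_female[t]) for t, w in weights.items())
    )


def deterministic_cedc(
    aerosol: AerosolSpec,
    scenario: WorkerScenario,
    s_pair: STablePair,
    tau_d: float = DEFAULT_COMMITMENT_DAYS,
    multipliers: DepositionMultipliers | None = None,
    f_d: Mapping[str, float] | None = None,
    modifiers: RateModifiers | None = None,
    tables=None,
    nuclide: str = "I-131",
    weights=None,
) -> DoseCoefficientResult:
    """Full deterministic chain: deposition -> apportionment -> biokinetics ->
    integration -> sex-specific equivalent doses -> effective dose coefficient."""
    regional = polydisperse_deposition(aerosol, scenario, multipliers)
    deposit = apportion_deposit(regional, f_d)
    system, x0 = build_full_system(deposit, modifiers, tables, nuclide)
    integrated = integrate_retention(system, x0, tau_d)
    h_m = committed_equivalent_dose(integrated, s_pair.male)
    h_f = committed_equivalent_dose(integrated, s_pair.female)
    effective = committed_effective(h_m, h_f, weights)
    return DoseCoefficientResult(
        h_male=h_m, h_female=h_f, effective=effective, tau_d=tau_d
    )
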