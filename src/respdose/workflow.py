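"""Scenario configuration, orchestrated runs and reproducible manifests.

A run is fully determined by a flat key:value configuration and one global
seed; the seed is expanded into named per-stage child seeds so any stage can
be rerun in isolation.  Manifests record the configuration echo, bundled and
user table checksums, library versions and the output inventory.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import fixtures
from .biokinetics import RateModifiers
from .deposition import (
    AerosolSpec,
    DepositionMultipliers,
    WorkerScenario,
    polydisperse_deposition,
)
from .dosimetry import DoseCoefficientResult, STablePair, deterministic_cedc
from .sensitivity import EnsembleConfig, SensitivityReport, sensitivity_report
from .uncertainty import (
    CEDCSample,
    FitResult,
    UFResult,
    UncertaintyError,
    best_fit_distribution,
    lhs_design,
    propagate,
    reference_parameter_table,
    summarize,
    uncertainty_factor,
)

SCHEMA_VERSION = 1

#: Ordered stage names whose child seeds are derived from the global seed.
STAGES = ("s_table", "lhs", "sensitivity")


class ConfigError(ValueError):
    pass


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2^31."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class ScenarioConfig:
    """Flat, human-editable description of one exposure scenario run."""

    nuclide: str = "I-131"
    absorption_type: str = "F"
    amad_um: float = 5.0
    gsd: float = 2.5
    density_g_cm3: float = 3.0
    shape_factor: float = 1.5
    scenario: str = "worker"
    commitment_years: float = 50.0
    n_samples: int = 1000
    seed: int = 1
    s_table: str | None = None       # CSV path; None -> bundled synthetic stand-in
    explain_limit: int = 256
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema version {self.schema_version}")
        if self.scenario != "worker":
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.absorption_type != "F":
            raise ConfigError("only absorption type F is modelled")
        if self.commitment_years <= 0 or self.n_samples < 1:
            raise ConfigError("commitment period and sample count must be positive")
        if self.s_table is not None and not Path(self.s_table).exists():
            raise ConfigError(f"S-table file not found: {self.s_table}")

    @property
    def tau_d(self) -> float:
        return self.commitment_years * 365.25

    def aerosol(self) -> AerosolSpec:
        return AerosolSpec(
            amad=self.amad_um, gsd=self.gsd,
            density=self.density_g_cm3, shape_factor=self.shape_factor,
        )

    def worker_scenario(self) -> WorkerScenario:
        return WorkerScenario.reference_worker()

    def s_pair(self) -> STablePair:
        if self.s_table is not None:
            frame = fixtures.read_s_table(
                self.s_table,
                sources=fixtures.source_regions(),
                targets=fixtures.load_tissue_weights().index,
            )
            return STablePair.from_frame(frame)
        synthetic = fixtures.generate_synthetic_s_table(
            seed=child_seed(self.seed, "s_table")
        )
        return STablePair.from_synthetic(synthetic)

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> ScenarioConfig:
    """Load a flat key:value configuration document."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config {path} is not a flat key:value document")
    known = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return ScenarioConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass(frozen=True)
class RunManifest:
    config: dict[str, Any]
    seed: int
    child_seeds: dict[str, int]
    table_checksums: dict[str, str]
    versions: dict[str, str]
    outputs: dict[str, str]          # name -> sha256 of written file
    timestamp: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "respdose": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _bundled_checksums(config: ScenarioConfig) -> dict[str, str]:
    names = [
        "hrtm_transport.csv", "iodine_systemic.csv", "typeF_dissolution.csv",
        "alimentary_link.csv", "nuclides.csv", "tissue_weights.csv",
        "deposition_efficiency_terms.csv", "deposition_scaling_constants.csv",
        "deposition_misc.csv", "breathing_patterns.csv", "worker_scenario.csv",
        "source_regions.csv",
    ]
    sums = {n: fixtures.table_checksum(fixtures.data_path(n)) for n in names}
    if config.s_table is not None:
        sums["s_table"] = fixtures.table_checksum(config.s_table)
    return sums


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(config: ScenarioConfig, outputs: dict[str, Path]) -> RunManifest:
    return RunManifest(
        config=config.as_dict(),
        seed=config.seed,
        child_seeds={stage: child_seed(config.seed, stage) for stage in STAGES},
        table_checksums=_bundled_checksums(config),
        versions=_versions(),
        outputs={name: _file_digest(path) for name, path in outputs.items()},
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )


def run_deterministic(
    config: ScenarioConfig, out_dir: str | Path | None = None
) -> tuple[RunManifest, DoseCoefficientResult]:
    """Reference-parameter dose-coefficient run (all multipliers at unity)."""
    result = deterministic_cedc(
        aerosol=config.aerosol(),
        scenario=config.worker_scenario(),
        s_pair=config.s_pair(),
        tau_d=config.tau_d,
        multipliers=DepositionMultipliers.neutral(),
        modifiers=RateModifiers(),
        nuclide=config.nuclide,
    )
    outputs: dict[str, Path] = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {
            "h_M_Sv_per_Bq": dict(result.h_male),
            "h_F_Sv_per_Bq": dict(result.h_female),
            "E_Sv_per_Bq": result.effective,
            "tau_d": result.tau_d,
            "config": config.as_dict(),
            "table_checksums": _bundled_checksums(config),
        }
        path = out_dir / "dose_coefficient.json"
        path.write_text(json.dumps(payload, indent=2))
        outputs["dose_coefficient.json"] = path
    manifest = _manifest(config, outputs)
    if out_dir is not None:
        manifest.write(Path(out_dir) / "manifest.json")
    return manifest, result


@dataclass(frozen=True)
class StochasticRunResult:
    sample: CEDCSample
    summary: dict[str, float]
    fits: tuple[FitResult, ...] | None
    fit_message: str | None
    uf: UFResult | None
    sensitivity: SensitivityReport | None
    deterministic: DoseCoefficientResult


def run_stochastic(
    config: ScenarioConfig, out_dir: str | Path | None = None
) -> tuple[RunManifest, StochasticRunResult]:
    """Full stochastic pipeline: LHS design -> propagation -> summary ->
    distribution fitting -> uncertainty factor -> sensitivity ranking."""
    if config.n_samples < 2:
        raise ConfigError("stochastic runs need n_samples >= 2")
    params = reference_parameter_table()
    s_pair = config.s_pair()
    aerosol = config.aerosol()
    scenario = config.worker_scenario()
    design = lhs_design(params, config.n_samples, child_seed(config.seed, "lhs"))
    sample = propagate(
        design, aerosol, scenario, s_pair, params=params, tau_d=config.tau_d,
        nuclide=config.nuclide,
    )
    summary = summarize(sample)
    _, deterministic = run_deterministic(config)

    fits: tuple[FitResult, ...] | None
    fit_message: str | None = None
    uf: UFResult | None = None
    sens: SensitivityReport | None = None
    if summary["sd"] == 0.0:
        fits = None
        fit_message = (
            "CEDC sample is constant (degenerate parameter set); distribution "
            "fitting, uncertainty factor and sensitivity ranking are skipped"
        )
    else:
        uf = uncertainty_factor(
            deterministic.effective, summary["p2.5"], summary["p97.5"]
        )
        if config.n_samples >= 50:
            fits = tuple(best_fit_distribution(sample))
        else:
            fits = None
            fit_message = "fewer than 50 samples; distribution fitting skipped"
        if config.n_samples >= 40:
            sens = sensitivity_report(
                design.as_frame(), sample.values,
                EnsembleConfig(seed=child_seed(config.seed, "sensitivity")),
                explain_limit=config.explain_limit,
            )
    result = StochasticRunResult(
        sample=sample, summary=summary, fits=fits, fit_message=fit_message,
        uf=uf, sensitivity=sens, deterministic=deterministic,
    )
    outputs: dict[str, Path] = {}
    if out_dir is not None:
        outputs = export_results(result, out_dir)
    manifest = _manifest(config, outputs)
    if out_dir is not None:
        manifest.write(Path(out_dir) / "manifest.json")
    return manifest, result


def export_results(
    result: StochasticRunResult,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("csv", "json"),
) -> dict[str, Path]:
    """Write run outputs with stable column order; returns written paths."""
    unknown = set(formats) - {"csv", "json"}
    if unknown:
        raise ConfigError(f"unknown export format(s): {sorted(unknown)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if "csv" in formats:
        cedc = result.sample.design.as_frame().copy()
        cedc["CEDC_Sv_per_Bq"] = result.sample.values
        path = out_dir / "cedc_sample.csv"
        cedc.to_csv(path, index=False)
        written["cedc_sample.csv"] = path
        if result.sensitivity is not None:
            att = pd.DataFrame(
                result.sensitivity.attributions.values,
                columns=list(result.sensitivity.attributions.feature_names),
            )
            att.insert(0, "base_value", result.sensitivity.attributions.base_value)
            path = out_dir / "shap_attributions.csv"
            att.to_csv(path, index=False)
            written["shap_attributions.csv"] = path

    if "json" in formats:
        report: dict[str, Any] = {
            "summary": result.summary,
            "deterministic_E_Sv_per_Bq": result.deterministic.effective,
            "fit_message": result.fit_message,
        }
        if result.fits is not None:
            report["fits"] = [dataclasses.asdict(f) for f in result.fits]
        if result.uf is not None:
            report["uncertainty_factor"] = {
                "central": result.uf.central,
                "q_lower": result.uf.q_lower,
                "q_upper": result.uf.q_upper,
                "ratio_lower": result.uf.ratio_lower,
                "ratio_upper": result.uf.ratio_upper,
                "uf": result.uf.uf,
                "uf_2dp": result.uf.rounded,
            }
        if result.sensitivity is not None:
            report["sensitivity"] = {
                "ranking": list(result.sensitivity.ranking),
                "importances": result.sensitivity.importances.to_dict(),
                "mean_abs_shap": result.sensitivity.mean_abs_shap.to_dict(),
                "n_trees": result.sensitivity.n_trees,
                "metrics": dataclasses.asdict(result.sensitivity.metrics),
            }
        path = out_dir / "stochastic_report.json"
        path.write_text(json.dumps(report, indent=2))
        written["stochastic_report.json"] = path
    return written
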