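"""Bundled reference constants and synthetic stand-ins for external dosimetric data.

Every fixed constant used by the deposition, biokinetic and dosimetric chain is
housed here as versioned CSV data with a per-entry provenance citation, so that
corrections to a transcribed value never touch model logic.  Radiation-weighted
S-coefficient tables are external reference data; a seeded synthetic generator
produces structurally complete stand-ins so the full pipeline is exercisable
without them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Compartment vocabulary of the coupled inhalation model.
COMPARTMENTS: tuple[str, ...] = (
    "ET1", "ETseq", "ET2prime", "BBprime", "BBseq", "bbprime", "bbseq",
    "ALV", "INT", "LNET", "LNTH",
    "Oesophagus", "Gut",
    "Blood", "BloodOrganic", "Thyroid1", "Thyroid2",
    "SalivaryGlands", "StomachWall", "Other", "UBladder",
    "Environment", "Excreta",
)

#: The eight particle-transport routes scaled by the correlated factor Kpt
#: (surfaced as ``K_factor`` in sensitivity outputs).
KPT_ROUTES: tuple[tuple[str, str], ...] = (
    ("ET1", "ET2prime"),
    ("ET1", "Environment"),
    ("ETseq", "LNET"),
    ("ET2prime", "Oesophagus"),
    ("BBseq", "LNTH"),
    ("BBprime", "ET2prime"),
    ("bbseq", "LNTH"),
    ("bbprime", "BBprime"),
)

_MODEL_TABLES = {
    "hrtm_transport": "hrtm_transport.csv",
    "iodine_systemic": "iodine_systemic.csv",
    "typeF_dissolution": "typeF_dissolution.csv",
    "alimentary_link": "alimentary_link.csv",
}

#: Home tissue of each dosimetric source region, used by the synthetic
#: S-coefficient generator to boost self-irradiation terms.
DEFAULT_HOME_TISSUE: dict[str, str] = {
    "ET1": "Remainder",
    "ET2": "Remainder",
    "BB": "Lung",
    "bb": "Lung",
    "AI": "Lung",
    "LNET": "Remainder",
    "LNTH": "Lung",
    "Oesophagus-c": "Oesophagus",
    "Gut-c": "Colon",
    "Blood": "RedMarrow",
    "Thyroid": "Thyroid",
    "SalivaryGlands": "SalivaryGlands",
    "StomachWall": "Stomach",
    "Other": "Remainder",
    "UBladder-c": "Bladder",
}


def data_path(name: str) -> Path:
    """Return the filesystem path of a bundled data file."""
    return Path(resources.files("respdose.data") / name)


@lru_cache(maxsize=None)
def _read_bundled_cached(name: str) -> pd.DataFrame:
    return pd.read_csv(data_path(name))


def _read_bundled(name: str) -> pd.DataFrame:
    return _read_bundled_cached(name).copy()


def table_checksum(path: str | Path) -> str:
    """SHA-256 checksum of a table file, for run manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass(frozen=True)
class ReferenceRateTable:
    """First-order transfer coefficients (per day) with provenance.

    ``entries`` is a list of ``(source, destination, rate_per_day)`` triples;
    ``provenance`` holds one citation string per entry, in the same order.
    """

    name: str
    entries: tuple[tuple[str, str, float], ...]
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        for (src, dst, rate), cite in zip(self.entries, self.provenance):
            if rate < 0:
                raise ValueError(f"negative transfer rate {src}->{dst}: {rate}")
            for comp in (src, dst):
                if comp not in COMPARTMENTS:
                    raise ValueError(
                        f"unknown compartment {comp!r} in table {self.name!r}"
                    )
            if not cite:
                raise ValueError(f"missing provenance for {src}->{dst}")

    def rate(self, source: str, destination: str) -> float:
        for src, dst, r in self.entries:
            if src == source and dst == destination:
                return r
        raise KeyError(f"no route {source}->{destination} in table {self.name!r}")

    def provenance_of(self, source: str, destination: str) -> str:
        for (src, dst, _), cite in zip(self.entries, self.provenance):
            if src == source and dst == destination:
                return cite
        raise KeyError(f"no route {source}->{destination} in table {self.name!r}")

    def as_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.entries, columns=["source", "destination", "rate_per_day"]
        )
        frame["provenance"] = list(self.provenance)
        return frame


def load_reference_rates(model_name: str) -> ReferenceRateTable:
    """Load one of the bundled transfer-coefficient tables.

    Parameters
    ----------
    model_name:
        One of ``hrtm_transport`` (particle transport between respiratory-tract
        compartments), ``iodine_systemic`` (systemic iodine model),
        ``typeF_dissolution`` (fast dissolution to blood) or
        ``alimentary_link`` (oesophagus/lumped-gut link).
    """
    if model_name not in _MODEL_TABLES:
        raise KeyError(
            f"unknown rate table {model_name!r}; available: "
            + ", ".join(sorted(_MODEL_TABLES))
        )
    frame = _read_bundled(_MODEL_TABLES[model_name])
    entries = tuple(
        (row.source, row.destination, float(row.rate_per_day))
        for row in frame.itertuples()
    )
    return ReferenceRateTable(
        name=model_name,
        entries=entries,
        provenance=tuple(frame["provenance"]),
    )


def load_all_rate_tables() -> dict[str, ReferenceRateTable]:
    return {name: load_reference_rates(name) for name in _MODEL_TABLES}


def load_nuclides() -> pd.DataFrame:
    return _read_bundled("nuclides.csv").set_index("nuclide")


def decay_constant(nuclide: str) -> float:
    """Physical decay constant (per day), ln 2 / half-life."""
    table = load_nuclides()
    if nuclide not in table.index:
        raise KeyError(f"unknown nuclide {nuclide!r}; available: {list(table.index)}")
    return float(np.log(2.0) / table.loc[nuclide, "half_life_days"])


def load_tissue_weights() -> pd.Series:
    frame = _read_bundled("tissue_weights.csv")
    weights = frame.set_index("tissue")["w_T"]
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"tissue weights sum to {weights.sum()}, expected 1")
    return weights


def load_source_region_map() -> dict[str, str]:
    frame = _read_bundled("source_regions.csv")
    return dict(zip(frame["compartment"], frame["source_region"]))


def source_regions() -> tuple[str, ...]:
    seen: list[str] = []
    for region in load_source_region_map().values():
        if region not in seen:
            seen.append(region)
    return tuple(seen)


# ---------------------------------------------------------------------------
# Synthetic S-coefficient tables


@dataclass(frozen=True)
class SyntheticSTable:
    """Seeded synthetic S-coefficient grid (Sv per nuclear transformation).

    A structurally complete stand-in for the external radiation-weighted
    S-coefficient tables: one positive value per (source region, target
    tissue, sex) cell, reproducible from the seed.  Self-irradiation terms
    (source region whose home tissue equals the target) are boosted so the
    synthetic dosimetry is dominated by self-dose, as it is for a short-range
    beta/gamma emitter.
    """

    frame: pd.DataFrame  # columns: source, target, sex, S_Sv_per_transformation
    seed: int

    def sex_map(self, sex: str) -> dict[tuple[str, str], float]:
        sub = self.frame[self.frame["sex"] == sex]
        return {
            (row.source, row.target): row.S_Sv_per_transformation
            for row in sub.itertuples()
        }


def generate_synthetic_s_table(
    seed: int,
    sources: Sequence[str] | None = None,
    targets: Sequence[str] | None = None,
    magnitude: float = 1e-15,
    self_dose_boost: float = 50.0,
) -> SyntheticSTable:
    """Generate a complete synthetic source x target x sex S-coefficient grid.

    Values are lognormal spreads around ``magnitude`` with self-dose terms
    multiplied by ``self_dose_boost``; the female grid is drawn independently
    from the same stream so both sexes differ but share the seed.
    """
    if sources is None:
        sources = source_regions()
    if targets is None:
        targets = tuple(load_tissue_weights().index)
    if len(sources) == 0 or len(targets) == 0:
        raise ValueError("sources and targets must be non-empty")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for sex in ("M", "F"):
        for src in sources:
            home = DEFAULT_HOME_TISSUE.get(src)
            for tgt in targets:
                value = magnitude * float(np.exp(rng.normal(0.0, 1.0)))
                if home == tgt:
                    value *= self_dose_boost
                rows.append((src, tgt, sex, value))
    frame = pd.DataFrame(
        rows, columns=["source", "target", "sex", "S_Sv_per_transformation"]
    )
    return SyntheticSTable(frame=frame, seed=seed)


def write_s_table(table: SyntheticSTable | pd.DataFrame, path: str | Path) -> None:
    frame = table.frame if isinstance(table, SyntheticSTable) else table
    frame.to_csv(path, index=False)


def read_s_table(
    path: str | Path,
    sources: Iterable[str] | None = None,
    targets: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read an S-coefficient CSV and validate grid completeness and positivity."""
    frame = pd.read_csv(path)
    required = {"source", "target", "sex", "S_Sv_per_transformation"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"S-table {path} missing columns: {sorted(missing)}")
    if (frame["S_Sv_per_transformation"] < 0).any():
        raise ValueError("S-table contains negative values")
    src_set = set(sources) if sources is not None else set(frame["source"])
    tgt_set = set(targets) if targets is not None else set(frame["target"])
    for sex in ("M", "F"):
        sub = frame[frame["sex"] == sex]
        have = set(zip(sub["source"], sub["target"]))
        want = {(s, t) for s in src_set for t in tgt_set}
        gaps = want - have
        if gaps:
            example = sorted(gaps)[0]
            raise ValueError(
                f"S-table incomplete for sex {sex}: missing {len(gaps)} cells, "
                f"e.g. {example}"
            )
    return frame


# ---------------------------------------------------------------------------
# Deposition benchmark harness


def benchmark_deposition(
    calculated: Mapping[float, float] | pd.Series,
    reference: Mapping[float, float] | pd.Series,
) -> pd.DataFrame:
    """Compare total deposition fractions against a reference table by AMAD.

    Returns a frame with the percent relative difference
    ``RD% = (calc - ref)/ref * 100`` and the absolute difference ``AD`` in
    percentage points of deposition, ``(calc - ref) * 100``.
    """
    calc = pd.Series(dict(calculated)).sort_index()
    ref = pd.Series(dict(reference)).sort_index()
    if list(calc.index) != list(ref.index):
        raise ValueError(
            f"AMAD grids differ: {list(calc.index)} vs {list(ref.index)}"
        )
    if (ref <= 0).any():
        raise ValueError("reference totals must be positive")
    return pd.DataFrame(
        {
            "amad_um": calc.index,
            "rd_percent": ((calc - ref) / ref * 100.0).to_numpy(),
            "ad_percentage_points": ((calc - ref) * 100.0).to_numpy(),
        }
    )


def load_synthetic_reference_totals() -> pd.Series:
    """Frozen total-deposition curve of this package's reference model.

    Synthetic stand-in for the external ICRP reference-worker deposition
    table; used only to exercise the benchmark harness offline.
    """
    frame = _read_bundled("synthetic_reference_deposition_totals.csv")
    return frame.set_index("amad_um")["total_deposition_fraction"]
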