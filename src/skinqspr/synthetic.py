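"""Synthetic HuskinDB-like datasets with known ground truth.

The generator emulates the statistical structure the QSPR analysis assumes:
descriptors drawn within realistic medicinal-chemistry ranges
(logP in [-4, 5], TPSA in [0, 160] A^2, MV in [50, 500] A^3), and log Kp
values produced by a known linear model per experimental scenario plus
Gaussian noise.  Controls exist for planted metadata missingness (to
exercise completeness filtering), planted gross outliers (to exercise the
residual filter), and descriptor correlation (a Gaussian copula, since real
descriptors are not independent).  Everything is reproducible from the seed.

Defaults mirror the scale of the real resource the pipeline targets:
253 compounds, one to three measurements each, noise sd 0.3 log10 units
(the residual scale of the best validated model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm as _norm

from .io import CompoundDescriptors, Dataset, PermeabilityRecord
from .stratification import ScenarioKey, _BIN_EDGES

#: Default true coefficients (intercept, logP, TPSA, MV) — the best
#: validated model's values, so defaults generate data on a realistic scale.
DEFAULT_COEFFICIENTS = (-6.136, 0.818, -0.005, -0.007)

DEFAULT_SCENARIO = ScenarioKey("abdomen", "epidermis", "diluted", "20-25")

_STRAT_FIELDS = (
    "skin_source",
    "skin_layer",
    "donor_concentration",
    "donor_temperature_c",
)


@dataclass
class GeneratorConfig:
    """Knobs for one synthetic dataset.

    ``scenario_coefficients`` maps each scenario to its true
    (intercept, b_logP, b_TPSA, b_MV); records are spread uniformly over the
    configured scenarios.  ``noise_sd`` is the Gaussian noise sd in log10
    units.  ``missingness_rate`` blanks one stratification field on that
    fraction of records; ``outlier_fraction`` offsets that fraction of
    records by +/- ``outlier_offset``.  ``descriptor_correlation`` is a
    common pairwise correlation applied through a Gaussian copula.
    """

    n_compounds: int = 253
    records_per_compound: tuple[int, int] = (1, 3)
    descriptor_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "log_p": (-4.0, 5.0),
            "tpsa": (0.0, 160.0),
            "mv": (50.0, 500.0),
        }
    )
    scenario_coefficients: dict[ScenarioKey, tuple[float, float, float, float]] = field(
        default_factory=lambda: {DEFAULT_SCENARIO: DEFAULT_COEFFICIENTS}
    )
    noise_sd: float = 0.3
    missingness_rate: float = 0.0
    outlier_fraction: float = 0.0
    outlier_offset: float = 3.0
    descriptor_correlation: float = 0.0
    ph_range: tuple[float, float] = (5.0, 8.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("missingness_rate", self.missingness_rate),
            ("outlier_fraction", self.outlier_fraction),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1.0 < self.descriptor_correlation < 1.0:
            raise ValueError("descriptor_correlation must be in (-1, 1)")
        for name, (lo, hi) in self.descriptor_ranges.items():
            if lo > hi:
                raise ValueError(f"descriptor range for {name} is empty")
        if self.records_per_compound[0] < 1:
            raise ValueError("records_per_compound minimum must be >= 1")


@dataclass
class GroundTruth:
    """What the generator actually planted, for bookkeeping oracles."""

    coefficients: dict[ScenarioKey, tuple[float, float, float, float]]
    record_scenarios: list[ScenarioKey]
    missing_record_indices: list[int]
    outlier_record_indices: list[int]


def _draw_descriptors(cfg: GeneratorConfig, rng: np.random.Generator) -> list[CompoundDescriptors]:
    k = cfg.n_compounds
    rho = cfg.descriptor_correlation
    if rho == 0.0:
        u = rng.uniform(size=(k, 3))
    else:
        # Gaussian copula with common pairwise correlation
        cov = np.full((3, 3), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(3), cov, size=k)
        u = _norm.cdf(z)
    out = []
    for i in range(k):
        vals = {}
        for j, name in enumerate(("log_p", "tpsa", "mv")):
            lo, hi = cfg.descriptor_ranges[name]
            vals[name] = lo + u[i, j] * (hi - lo)
        out.append(
            CompoundDescriptors(
                compound_id=f"C{i + 1:04d}",
                log_p=vals["log_p"],
                tpsa=vals["tpsa"],
                mv=vals["mv"],
            )
        )
    return out


def generate(config: GeneratorConfig) -> tuple[Dataset, GroundTruth]:
    """Draw a dataset and its ground truth from one seeded generator.

    Each record is assigned a scenario uniformly over the configured
    scenarios; its temperature is drawn uniformly inside the scenario's bin
    and log_kp = true linear model + Normal(0, noise_sd).  Planted outliers
    receive an extra offset of +/- ``outlier_offset`` (random sign); planted
    missingness blanks one of the four stratification fields, chosen
    uniformly.  Counts of planted records are exact (rounded fractions of
    the record total) and disjoint between the two plants.
    """
    rng = np.random.default_rng(config.seed)
    descriptors = _draw_descriptors(config, rng)
    scenarios = list(config.scenario_coefficients)

    records: list[PermeabilityRecord] = []
    record_scenarios: list[ScenarioKey] = []
    for desc in descriptors:
        n_rec = int(rng.integers(config.records_per_compound[0],
                                 config.records_per_compound[1] + 1))
        for _ in range(n_rec):
            key = scenarios[int(rng.integers(len(scenarios)))]
            lo, hi = _BIN_EDGES[key.temperature_bin]
            temp = float(rng.uniform(lo, hi))
            b0, b1, b2, b3 = config.scenario_coefficients[key]
            log_kp = (
                b0
                + b1 * desc.log_p
                + b2 * desc.tpsa
                + b3 * desc.mv
                + (rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0)
            )
            records.append(
                PermeabilityRecord(
                    compound_id=desc.compound_id,
                    log_kp=float(log_kp),
                    skin_source=key.skin_source,
                    skin_layer=key.skin_layer,
                    donor_concentration=key.donor_concentration,
                    donor_temperature_c=temp,
                    donor_ph=float(rng.uniform(*config.ph_range)),
                )
            )
            record_scenarios.append(key)

    n_records = len(records)
    n_outliers = int(round(config.outlier_fraction * n_records))
    n_missing = int(round(config.missingness_rate * n_records))
    chosen = rng.choice(n_records, size=min(n_outliers + n_missing, n_records),
                        replace=False)
    outlier_idx = sorted(int(i) for i in chosen[:n_outliers])
    missing_idx = sorted(int(i) for i in chosen[n_outliers:])

    for i in outlier_idx:
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        records[i].log_kp += sign * config.outlier_offset
    for i in missing_idx:
        blank = _STRAT_FIELDS[int(rng.integers(len(_STRAT_FIELDS)))]
        setattr(records[i], blank, None)

    dataset = Dataset(
        records=records,
        descriptors={d.compound_id: d for d in descriptors},
    )
    truth = GroundTruth(
        coefficients=dict(config.scenario_coefficients),
        record_scenarios=record_scenarios,
        missing_record_indices=missing_idx,
        outlier_record_indices=outlier_idx,
    )
    return dataset, truth


def make_table1_like(
    config: Optional[GeneratorConfig] = None,
) -> tuple[Dataset, GroundTruth]:
    """A dataset whose non-empty scenarios and group sizes match the
    published 27-scenario model table.

    Each of the 27 scenarios receives exactly its printed number of rows
    (one row per synthetic compound, 342 rows total), generated from the
    published coefficients of that scenario plus Gaussian noise.  Useful for
    dress rehearsals of the full pipeline at the real study's scale.
    """
    from .published import load_registry  # local import avoids a cycle

    cfg = config or GeneratorConfig()
    registry = load_registry()
    rng = np.random.default_rng(cfg.seed)

    records: list[PermeabilityRecord] = []
    descriptors: dict[str, CompoundDescriptors] = {}
    record_scenarios: list[ScenarioKey] = []
    coefficients: dict[ScenarioKey, tuple[float, float, float, float]] = {}
    cid = 0
    for key, model in registry.scenario_models.items():
        beta = (model.intercept, model.coef_logp, model.coef_tpsa, model.coef_mv)
        coefficients[key] = beta
        lo_t, hi_t = _BIN_EDGES[key.temperature_bin]
        for _ in range(model.n):
            cid += 1
            vals = {}
            for name in ("log_p", "tpsa", "mv"):
                lo, hi = cfg.descriptor_ranges[name]
                vals[name] = float(rng.uniform(lo, hi))
            desc = CompoundDescriptors(
                compound_id=f"T{cid:04d}", log_p=vals["log_p"],
                tpsa=vals["tpsa"], mv=vals["mv"],
            )
            descriptors[desc.compound_id] = desc
            log_kp = (
                beta[0]
                + beta[1] * desc.log_p
                + beta[2] * desc.tpsa
                + beta[3] * desc.mv
                + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
            )
            records.append(
                PermeabilityRecord(
                    compound_id=desc.compound_id,
                    log_kp=float(log_kp),
                    skin_source=key.skin_source,
                    skin_layer=key.skin_layer,
                    donor_concentration=key.donor_concentration,
                    donor_temperature_c=float(rng.uniform(lo_t, hi_t)),
                    donor_ph=float(rng.uniform(*cfg.ph_range)),
                )
            )
            record_scenarios.append(key)

    dataset = Dataset(records=records, descriptors=descriptors)
    truth = GroundTruth(
        coefficients=coefficients,
        record_scenarios=record_scenarios,
        missing_record_indices=[],
        outlier_record_indices=[],
    )
    return dataset, truth
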