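"""Experimental-scenario grid for stratified skin-permeability modelling.

Permeability measurements are grouped by four experimental covariates known
to influence the measured permeability coefficient: anatomical skin source,
the skin layer mounted in the diffusion cell, the donor-solution
concentration class, and the donor-solution temperature (binned).  The full
cross-product of the levels gives 3 * 4 * 2 * 4 = 96 scenarios; each group
of measurements sharing a scenario is later fitted with its own QSPR model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .io import CompoundDescriptors, PermeabilityRecord

# Level orders are fixed so every report and table is reproducible
# byte-for-byte.  Scenario enumeration is lexicographic over these orders.
SKIN_SOURCES = ("breast", "abdomen", "thigh")
SKIN_LAYERS = ("epidermis", "dermis", "epidermis+dermis", "stratum_corneum")
CONCENTRATIONS = ("concentrated", "diluted")
TEMPERATURE_BINS = ("20-25", "26-30", "31-35", "36-40")

# Half-open intervals on the real line: the printed integer bin labels leave
# fractional temperatures (25.5 C) undefined, so each bin owns [lo, hi).
_BIN_EDGES = {
    "20-25": (20.0, 26.0),
    "26-30": (26.0, 31.0),
    "31-35": (31.0, 36.0),
    "36-40": (36.0, 41.0),
}


@dataclass(frozen=True)
class ScenarioKey:
    """One cell of the source x layer x concentration x temperature grid.

    Hashable and value-equal; serialized as ``source/layer/concentration/bin``
    (e.g. ``abdomen/epidermis/diluted/20-25``) in reports and CLI arguments.
    """

    skin_source: str
    skin_layer: str
    donor_concentration: str
    temperature_bin: str

    def __post_init__(self) -> None:
        if self.skin_source not in SKIN_SOURCES:
            raise ValueError(f"unknown skin_source {self.skin_source!r}")
        if self.skin_layer not in SKIN_LAYERS:
            raise ValueError(f"unknown skin_layer {self.skin_layer!r}")
        if self.donor_concentration not in CONCENTRATIONS:
            raise ValueError(
                f"unknown donor_concentration {self.donor_concentration!r}"
            )
        if self.temperature_bin not in TEMPERATURE_BINS:
            raise ValueError(f"unknown temperature_bin {self.temperature_bin!r}")

    def __str__(self) -> str:
        return "/".join(
            (
                self.skin_source,
                self.skin_layer,
                self.donor_concentration,
                self.temperature_bin,
            )
        )

    @classmethod
    def from_string(cls, token: str) -> "ScenarioKey":
        parts = token.strip().split("/")
        if len(parts) != 4:
            raise ValueError(
                f"scenario token must have 4 '/'-separated fields, got {token!r}"
            )
        return cls(*parts)


def enumerate_scenarios() -> list[ScenarioKey]:
    """Every scenario exactly once, in the documented lexicographic order."""
    return [
        ScenarioKey(src, layer, conc, tbin)
        for src, layer, conc, tbin in product(
            SKIN_SOURCES, SKIN_LAYERS, CONCENTRATIONS, TEMPERATURE_BINS
        )
    ]


def bin_temperature(t: float) -> Optional[str]:
    """Map a donor temperature in degrees C to its bin label, or None.

    Bins are half-open: [20, 26) -> ``20-25``, [26, 31) -> ``26-30``,
    [31, 36) -> ``31-35``, [36, 41) -> ``36-40``.  Temperatures outside
    [20, 41) belong to no bin.
    """
    for label, (lo, hi) in _BIN_EDGES.items():
        if lo <= t < hi:
            return label
    return None


@dataclass
class ScenarioAssignment:
    """Partition of complete permeability records into scenario groups.

    ``groups`` maps each non-empty scenario to its ordered list of
    (record, descriptors) pairs; input order is preserved within a group and
    repeat measurements of the same compound stay as separate rows.
    """

    groups: dict[ScenarioKey, list[tuple["PermeabilityRecord", "CompoundDescriptors"]]] = field(
        default_factory=dict
    )
    n_unassignable: int = 0
    n_missing_descriptors: int = 0

    @property
    def n_assigned(self) -> int:
        return sum(len(g) for g in self.groups.values())


def assign(
    records: list["PermeabilityRecord"],
    descriptors: dict[str, "CompoundDescriptors"],
) -> ScenarioAssignment:
    """Partition complete records into scenario groups.

    Records must already have the four stratification fields present (see
    :func:`skinqspr.io.filter_complete`).  Records whose temperature falls
    outside every bin are counted as unassignable; records whose compound has
    no descriptor entry are counted separately.  Each assignable record lands
    in exactly one group, so group sizes + the two counts sum to the input
    size.
    """
    out = ScenarioAssignment()
    for rec in records:
        desc = descriptors.get(rec.compound_id)
        if desc is None:
            out.n_missing_descriptors += 1
            continue
        tbin = bin_temperature(rec.donor_temperature_c)
        if tbin is None:
            out.n_unassignable += 1
            continue
        key = ScenarioKey(
            rec.skin_source, rec.skin_layer, rec.donor_concentration, tbin
        )
        out.groups.setdefault(key, []).append((rec, desc))
    return out
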