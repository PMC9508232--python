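"""Reading, validating and writing permeability and descriptor tables.

Input is delimited text (comma by default, tab accepted) with a required
header.  A permeability table carries one row per Kp measurement — the
compound, log10(Kp) with Kp in cm/s, and the experimental metadata used for
stratification.  A descriptor table carries one row per compound with the
three molecular descriptors (logP, TPSA in A^2, MV in A^3) the QSPR uses.

log_kp is stored and exchanged exactly as provided, as log10 of a
permeability coefficient in cm/s; no unit conversion happens anywhere in
the pipeline.  Missing values are an empty cell or "NA" on read and an
empty cell on write.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .stratification import CONCENTRATIONS, SKIN_LAYERS, SKIN_SOURCES

logger = logging.getLogger(__name__)

#: Default permeability-table column names; override via ``columns=`` for
#: exports that use different headers.
PERMEABILITY_COLUMNS = {
    "compound_id": "compound_id",
    "compound_name": "compound_name",
    "log_kp": "log_kp_cm_s",
    "skin_source": "skin_source",
    "skin_layer": "skin_layer",
    "donor_concentration": "donor_concentration",
    "donor_temperature_c": "donor_temperature_c",
    "donor_ph": "donor_ph",
}

DESCRIPTOR_COLUMNS = ("compound_id", "logp", "tpsa", "mv")

_MISSING_TOKENS = {"", "na", "n/a", "nan", "none"}

# "neat" and "saturated" are used interchangeably for an undiluted donor
# phase; all spellings normalise to the single level "concentrated".
_CONCENTRATION_ALIASES = {
    "neat": "concentrated",
    "saturated": "concentrated",
    "concentrated": "concentrated",
    "diluted": "diluted",
    "dilute": "diluted",
}

_LAYER_ALIASES = {
    "epidermis": "epidermis",
    "dermis": "dermis",
    "epidermis+dermis": "epidermis+dermis",
    "epidermis + dermis": "epidermis+dermis",
    "stratum_corneum": "stratum_corneum",
    "stratum corneum": "stratum_corneum",
}

# Typical log10(Kp/cm s^-1) range for skin permeation; values outside draw a
# warning but are kept.
LOG_KP_TYPICAL_RANGE = (-9.0, -2.0)


@dataclass
class PermeabilityRecord:
    """One Kp measurement with its experimental metadata.

    ``log_kp`` is log10 of the permeability coefficient in cm/s.  Categorical
    metadata take only the documented level vocabularies; anything else is
    mapped to missing (None) at read time.
    """

    compound_id: str
    log_kp: float
    compound_name: Optional[str] = None
    skin_source: Optional[str] = None
    skin_layer: Optional[str] = None
    donor_concentration: Optional[str] = None
    donor_temperature_c: Optional[float] = None
    donor_ph: Optional[float] = None


@dataclass(frozen=True)
class CompoundDescriptors:
    """logP / TPSA / MV triple for one compound.

    logP is the dimensionless octanol-water partition coefficient, TPSA the
    topological polar surface area in A^2 (non-negative), MV the molecular
    volume in A^3 (positive).
    """

    compound_id: str
    log_p: float
    tpsa: float
    mv: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_p):
            raise ValueError(f"{self.compound_id}: log_p must be finite")
        if not (self.tpsa >= 0):
            raise ValueError(f"{self.compound_id}: tpsa must be >= 0")
        if not (self.mv > 0):
            raise ValueError(f"{self.compound_id}: mv must be > 0")


@dataclass
class Dataset:
    """Permeability records plus the descriptor lookup they refer to."""

    records: list[PermeabilityRecord]
    descriptors: dict[str, CompoundDescriptors]

    def compounds_without_descriptors(self) -> list[str]:
        known = self.descriptors.keys()
        seen: list[str] = []
        for r in self.records:
            if r.compound_id not in known and r.compound_id not in seen:
                seen.append(r.compound_id)
        return seen


@dataclass
class ExclusionReport:
    """Bookkeeping for records dropped for incomplete experimental metadata.

    ``by_field`` counts excluded records per missing field; a record missing
    several fields is counted under each, but only once in
    ``n_excluded_records``.
    """

    n_excluded_records: int = 0
    n_excluded_compounds: int = 0
    by_field: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reason": k, "n_records": v} for k, v in sorted(self.by_field.items())
        ]
        rows.append(
            {"reason": "total_excluded", "n_records": self.n_excluded_records}
        )
        return pd.DataFrame(rows, columns=["reason", "n_records"])

    def write_csv(self, path) -> None:
        self.to_frame().assign(n_compounds=self.n_excluded_compounds).to_csv(
            path, index=False
        )


class SchemaError(ValueError):
    """A required column is absent or a cell cannot be parsed."""


def _is_missing(value) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return True
    return str(value).strip().lower() in _MISSING_TOKENS


def _sep_for(path, dialect: Optional[str]) -> str:
    if dialect in ("tsv", "\t", "tab"):
        return "\t"
    if dialect in ("csv", ",", None):
        return "\t" if str(path).endswith(".tsv") else ","
    return dialect


def _parse_categorical(
    raw, aliases: dict[str, str], field_name: str, row: int, warnings: list[str]
) -> Optional[str]:
    if _is_missing(raw):
        return None
    norm = aliases.get(str(raw).strip().lower())
    if norm is None:
        warnings.append(
            f"row {row}: unrecognised {field_name} {str(raw).strip()!r} -> missing"
        )
        return None
    return norm


def _parse_float(raw, field_name: str, row: int) -> Optional[float]:
    if _is_missing(raw):
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: non-numeric {field_name} {raw!r}") from None


def read_permeability_table(
    path,
    dialect: Optional[str] = None,
    columns: Optional[dict[str, str]] = None,
) -> tuple[list[PermeabilityRecord], list[str]]:
    """Read a permeability table into records, preserving row order.

    Returns ``(records, warnings)``.  Unparseable categorical values map to
    missing with a logged warning; a missing required column or a non-numeric
    log_kp is fatal (:class:`SchemaError`).  ``columns`` remaps logical field
    names to file headers for non-default exports.
    """
    colmap = dict(PERMEABILITY_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, keep_default_na=False)
    for logical in ("compound_id", "log_kp"):
        if colmap[logical] not in df.columns:
            raise SchemaError(
                f"{path}: missing required column {colmap[logical]!r}"
            )

    warnings: list[str] = []
    records: list[PermeabilityRecord] = []
    n_atypical = 0
    src_aliases = {s: s for s in SKIN_SOURCES}
    conc_aliases = _CONCENTRATION_ALIASES
    for i, row in enumerate(df.to_dict("records"), start=2):  # header = line 1
        def get(logical: str):
            return row.get(colmap[logical])

        raw_kp = get("log_kp")
        if _is_missing(raw_kp):
            raise SchemaError(f"row {i}: non-numeric log_kp {raw_kp!r}")
        log_kp = _parse_float(raw_kp, "log_kp", i)
        if not (LOG_KP_TYPICAL_RANGE[0] <= log_kp <= LOG_KP_TYPICAL_RANGE[1]):
            n_atypical += 1
        name = get("compound_name")
        rec = PermeabilityRecord(
            compound_id=str(get("compound_id")).strip(),
            log_kp=log_kp,
            compound_name=None if _is_missing(name) else str(name).strip(),
            skin_source=_parse_categorical(
                get("skin_source"), src_aliases, "skin_source", i, warnings
            ),
            skin_layer=_parse_categorical(
                get("skin_layer"), _LAYER_ALIASES, "skin_layer", i, warnings
            ),
            donor_concentration=_parse_categorical(
                get("donor_concentration"), conc_aliases, "donor_concentration",
                i, warnings,
            ),
            donor_temperature_c=_parse_float(
                get("donor_temperature_c"), "donor_temperature_c", i
            ),
            donor_ph=_parse_float(get("donor_ph"), "donor_ph", i),
        )
        records.append(rec)
    for w in warnings:
        logger.warning("%s: %s", path, w)
    if n_atypical:
        logger.warning(
            "%s: %d of %d log_kp values outside the typical range [%g, %g]",
            path, n_atypical, len(records), *LOG_KP_TYPICAL_RANGE,
        )
    return records, warnings


def write_permeability_table(records: list[PermeabilityRecord], path, sep: str = ",") -> None:
    """Write records with the default column names; missing -> empty cell."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "compound_name": r.compound_name or "",
                "log_kp_cm_s": repr(float(r.log_kp)),
                "skin_source": r.skin_source or "",
                "skin_layer": r.skin_layer or "",
                "donor_concentration": r.donor_concentration or "",
                "donor_temperature_c": "" if r.donor_temperature_c is None else repr(float(r.donor_temperature_c)),
                "donor_ph": "" if r.donor_ph is None else repr(float(r.donor_ph)),
            }
        )
    pd.DataFrame(rows, columns=list(PERMEABILITY_COLUMNS.values())).to_csv(
        path, sep=sep, index=False
    )


def read_descriptor_table(path, dialect: Optional[str] = None) -> dict[str, CompoundDescriptors]:
    """Read a compound-descriptor table keyed by compound_id.

    Duplicate compound ids, negative TPSA or non-positive MV are fatal.
    """
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in DESCRIPTOR_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out: dict[str, CompoundDescriptors] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        cid = str(row.compound_id).strip()
        if cid in out:
            raise SchemaError(f"row {i}: duplicate compound_id {cid!r}")
        try:
            out[cid] = CompoundDescriptors(
                compound_id=cid,
                log_p=float(row.logp),
                tpsa=float(row.tpsa),
                mv=float(row.mv),
            )
        except ValueError as exc:
            raise SchemaError(f"row {i}: {exc}") from None
    return out


def write_descriptor_table(descriptors: dict[str, CompoundDescriptors], path, sep: str = ",") -> None:
    rows = [
        {"compound_id": d.compound_id, "logp": repr(float(d.log_p)), "tpsa": repr(float(d.tpsa)), "mv": repr(float(d.mv))}
        for d in descriptors.values()
    ]
    pd.DataFrame(rows, columns=list(DESCRIPTOR_COLUMNS)).to_csv(path, sep=sep, index=False)


def load_dataset(permeability_path, descriptor_path, **read_kwargs) -> Dataset:
    """Load both tables and flag records whose compound lacks descriptors."""
    records, _ = read_permeability_table(permeability_path, **read_kwargs)
    descriptors = read_descriptor_table(descriptor_path)
    ds = Dataset(records=records, descriptors=descriptors)
    orphans = ds.compounds_without_descriptors()
    if orphans:
        logger.warning(
            "%d compound(s) in the permeability table have no descriptor entry: %s",
            len(orphans), ", ".join(orphans[:10]),
        )
    return ds


#: The four metadata fields a record must carry to be stratifiable.
STRATIFICATION_FIELDS = (
    "skin_source",
    "skin_layer",
    "donor_concentration",
    "donor_temperature_c",
)


def filter_complete(
    records: list[PermeabilityRecord],
) -> tuple[list[PermeabilityRecord], ExclusionReport]:
    """Drop records missing any of the four stratification fields.

    Kept records have skin source, skin layer, donor concentration and donor
    temperature all present.  The report counts excluded records (once each)
    and distinct excluded compounds, broken down by which field was missing.
    Idempotent, and |kept| + |excluded| = |input|.
    """
    kept: list[PermeabilityRecord] = []
    report = ExclusionReport()
    excluded_compounds: set[str] = set()
    for rec in records:
        missing = [f for f in STRATIFICATION_FIELDS if getattr(rec, f) is None]
        if not missing:
            kept.append(rec)
            continue
        report.n_excluded_records += 1
        excluded_compounds.add(rec.compound_id)
        for f in missing:
            report.by_field[f] = report.by_field.get(f, 0) + 1
    report.n_excluded_compounds = len(excluded_compounds)
    return kept, report
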