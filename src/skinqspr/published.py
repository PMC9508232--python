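"""Published skin-permeability equations as ready-to-use predictors.

Ships three things:

* the 27 scenario-specific QSPR equations transcribed from the source
  study's model table, loadable by scenario;
* the study's two validated equations — the best single-scenario model
  (``eq2``) and the pooled outlier-filtered model (``eq3``) — both in
  log10(cm/s);
* the classic Potts-Guy baseline, logKp = 0.71 logP - 0.0061 MW - 6.3,
  which uses molecular weight instead of TPSA/MV.  Its original publication
  used cm/h units and the transcription source does not reconcile this, so
  the model carries an explicit unit tag and is never converted.

The transcription is a version-controlled CSV fixture; its SHA-256 is
checked at load so any silent edit fails loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Union

from .io import _CONCENTRATION_ALIASES, _LAYER_ALIASES
from .regression import QsprModel
from .stratification import ScenarioKey, bin_temperature

_TABLE1_RESOURCE = "table1.csv"
_TABLE1_SHA256 = "0bbfdefc80ceb36cbf831d94f5954ab36c159fb7b1245b659f933122c6bef25d"

#: Best single-scenario model (abdomen / epidermis / diluted / 20-25 degC),
#: refitted on its 29-row training split.
EQ2 = QsprModel(
    intercept=-6.136,
    coef_logp=0.818,
    coef_tpsa=-0.005,
    coef_mv=-0.007,
    n=29,
    r_squared=0.8428,
    rmse=0.30,
    provenance="published",
    label="eq2: best scenario model (training fit)",
)

#: Pooled model after one-per-compound selection and +/-1.5 outlier removal,
#: refitted on its 171-row training split.
EQ3 = QsprModel(
    intercept=-5.820,
    coef_logp=0.319,
    coef_tpsa=-0.001,
    coef_mv=-0.005,
    n=171,
    r_squared=0.5042,
    rmse=0.73,
    provenance="published",
    label="eq3: pooled outlier-filtered model (training fit)",
)


@dataclass(frozen=True)
class PottsGuyInput:
    """logP and molecular weight (g/mol), the baseline's two descriptors."""

    log_p: float
    mw: float

    def __post_init__(self) -> None:
        if not (self.mw > 0):
            raise ValueError("mw must be > 0")


@dataclass(frozen=True)
class PottsGuyModel:
    """logKp = intercept + coef_logp*logP + coef_mw*MW (units as printed)."""

    intercept: float = -6.3
    coef_logp: float = 0.71
    coef_mw: float = -0.0061
    unit: str = "as published (original source used cm/h)"


POTTS_GUY = PottsGuyModel()


def predict_potts_guy(d: PottsGuyInput, model: PottsGuyModel = POTTS_GUY) -> float:
    """Baseline prediction from logP and molecular weight."""
    return model.intercept + model.coef_logp * d.log_p + model.coef_mw * d.mw


def _read_table1_text() -> str:
    text = (
        resources.files("skinqspr.data").joinpath(_TABLE1_RESOURCE).read_text()
    )
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            "packaged model-table transcription has been modified "
            f"(sha256 {digest} != expected {_TABLE1_SHA256})"
        )
    return text


class PublishedModelRegistry:
    """Scenario lookup over the 27 transcribed models, plus eq2/eq3/baseline.

    ``scenario_models`` maps :class:`ScenarioKey` to a published
    :class:`QsprModel` carrying the printed compound count and R-squared
    (missing where the source printed N/A).
    """

    def __init__(self) -> None:
        self.scenario_models: dict[ScenarioKey, QsprModel] = {}
        self._raw_rows: list[dict] = []
        text = _read_table1_text()
        lines = text.strip().split("\n")
        header = lines[0].split(",")
        for line in lines[1:]:
            vals = dict(zip(header, line.split(",")))
            key = ScenarioKey(
                vals["skin_source"],
                vals["skin_layer"],
                vals["donor_concentration"],
                vals["temperature_bin"],
            )
            r2 = vals["r_squared"]
            model = QsprModel(
                intercept=float(vals["intercept"]),
                coef_logp=float(vals["coef_logp"]),
                coef_tpsa=float(vals["coef_tpsa"]),
                coef_mv=float(vals["coef_mv"]),
                n=int(vals["n"]),
                n_compounds=int(vals["n"]),
                r_squared=None if r2 == "" else float(r2),
                underdetermined=int(vals["n"]) <= 4,
                provenance="published",
                scenario=key,
                label=f"published scenario model {key}",
            )
            self.scenario_models[key] = model
            self._raw_rows.append(vals)
        if len(self.scenario_models) != 27:
            raise RuntimeError(
                f"expected 27 scenario models, loaded {len(self.scenario_models)}"
            )
        self.eq2 = EQ2
        self.eq3 = EQ3
        self.potts_guy = POTTS_GUY

    def lookup(
        self,
        source: str,
        layer: str,
        concentration: str,
        temperature_c: float,
    ) -> Optional[QsprModel]:
        """Find the published model for raw experimental conditions.

        Concentration and layer spellings are normalised the same way the
        table readers normalise them; the temperature is binned.  Returns
        None when the conditions were never modelled.
        """
        conc = _CONCENTRATION_ALIASES.get(str(concentration).strip().lower())
        lay = _LAYER_ALIASES.get(str(layer).strip().lower())
        tbin = bin_temperature(float(temperature_c))
        if conc is None or lay is None or tbin is None:
            return None
        try:
            key = ScenarioKey(str(source).strip().lower(), lay, conc, tbin)
        except ValueError:
            return None
        return self.scenario_models.get(key)

    def predict_published(
        self, model_id: Union[str, ScenarioKey], log_p: float, tpsa: float, mv: float
    ) -> float:
        """Predict log10(Kp/cm s^-1) with a registry model.

        ``model_id`` is "eq2", "eq3", a :class:`ScenarioKey`, or a
        ``source/layer/concentration/bin`` token.
        """
        model = self.get(model_id)
        return float(model.predict(log_p, tpsa, mv))

    def get(self, model_id: Union[str, ScenarioKey]) -> QsprModel:
        if isinstance(model_id, ScenarioKey):
            key: Optional[ScenarioKey] = model_id
        elif model_id == "eq2":
            return self.eq2
        elif model_id == "eq3":
            return self.eq3
        else:
            try:
                key = ScenarioKey.from_string(model_id)
            except ValueError:
                key = None
        if key is not None and key in self.scenario_models:
            return self.scenario_models[key]
        available = ["eq2", "eq3"] + [str(k) for k in self.scenario_models]
        raise KeyError(
            f"unknown model id {model_id!r}; available: {', '.join(available)}"
        )

    def to_csv_text(self) -> str:
        """Re-serialize the registry; byte-identical to the packaged fixture."""
        header = "skin_source,skin_layer,donor_concentration,temperature_bin,n,r_squared,intercept,coef_logp,coef_tpsa,coef_mv"
        lines = [header]
        for vals in self._raw_rows:
            lines.append(",".join(vals[c] for c in header.split(",")))
        return "\n".join(lines) + "\n"


_registry: Optional[PublishedModelRegistry] = None


def load_registry() -> PublishedModelRegistry:
    """The validated registry, loaded once per process."""
    global _registry
    if _registry is None:
        _registry = PublishedModelRegistry()
    return _registry
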