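"""Predict skin permeability for a new compound with the published models.

Builds descriptor inputs for caffeine-like values (logP 0.0, TPSA 61.8 A^2,
MV 157.6 A^3, MW 194.2 g/mol), asks every shipped predictor for
log10(Kp / cm s^-1), and prints the results side by side.
"""

from skinqspr import PottsGuyInput, load_registry, predict_potts_guy

log_p, tpsa, mv, mw = 0.0, 61.8, 157.6, 194.2

registry = load_registry()
eq2 = registry.predict_published("eq2", log_p, tpsa, mv)
eq3 = registry.predict_published("eq3", log_p, tpsa, mv)
baseline = predict_potts_guy(PottsGuyInput(log_p=log_p, mw=mw))

print(f"descriptors: logP={log_p}, TPSA={tpsa} A^2, MV={mv} A^3, MW={mw} g/mol")
print(f"best scenario model (eq2):   logKp = {eq2:.3f}")
print(f"pooled filtered model (eq3): logKp = {eq3:.3f}")
print(f"Potts-Guy baseline:          logKp = {baseline:.3f}  (units as originally published)")

# Scenario-specific prediction: the model fitted only on measurements taken
# on abdominal epidermis with a diluted donor phase at 20-25 degC.
scenario = registry.lookup("abdomen", "epidermis", "diluted", 22.0)
print(
    f"scenario {scenario.scenario}: logKp = {scenario.predict(log_p, tpsa, mv):.3f}"
    f"  (fitted on n={scenario.n}, R^2={scenario.r_squared})"
)

# A negative logKp around -6 means Kp ~ 1e-6 cm/s: slow, typical passive
# permeation through intact human skin.  The spread across models shows how
# strongly the experimental conditions behind each model matter.
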