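# skinqspr

Quantitative structure–permeability relationship (QSPR) modelling of human
skin permeability from experimentally annotated permeability-coefficient
tables.

## The problem

The permeability coefficient Kp (cm/s) measures how fast a compound crosses
human skin from an aqueous vehicle at steady state. Measured values for the
same compound vary widely with the experimental setup — the anatomical site
the skin came from, which layer was mounted (epidermis, dermis, both, or
isolated stratum corneum), whether the donor solution was saturated or
diluted, and the donor temperature. Models that ignore these covariates mix
heterogeneous measurements and predict poorly.

`skinqspr` is for researchers working with permeation databases such as
HuskinDB who want predictive models rather than lookups. It stratifies
measurements by the four experimental covariates, fits a separate
three-descriptor linear QSPR per experimental scenario by ordinary least
squares,

    logKp = b0 + b1·logP + b2·TPSA + b3·MV

(logKp in log10 cm/s; logP the octanol–water partition coefficient; TPSA the
topological polar surface area in Å²; MV the molecular volume in Å³), selects
the best-supported scenario model, and also builds a pooled model over all
compounds with single-pass outlier removal at ±1.5 log units, validating both
with random 80/20 train/test splits checked for descriptor coverage.

It also ships ready-to-use published equations: the 27 scenario models from
the study this pipeline reproduces, the study's two validated equations
(`eq2`, the best scenario model; `eq3`, the pooled filtered model), and the
Potts–Guy baseline `logKp = 0.71 logP − 0.0061 MW − 6.3`.

Descriptors are inputs (e.g. exported from Molinspiration); no descriptor
computation and no database access is performed.

## Worked example

```python
from skinqspr import PottsGuyInput, load_registry, predict_potts_guy

registry = load_registry()
log_p, tpsa, mv, mw = 0.0, 61.8, 157.6, 194.2   # caffeine-like descriptors
print(registry.predict_published("eq2", log_p, tpsa, mv))   # -7.548
print(registry.predict_published("eq3", log_p, tpsa, mv))   # -6.670
print(predict_potts_guy(PottsGuyInput(log_p=log_p, mw=mw))) # -7.485
```

The three predictions are log10(Kp/cm s⁻¹): around −7 means Kp ≈ 10⁻⁷ cm/s,
slow passive permeation typical of a polar compound. The spread between
models reflects the experimental conditions each was trained on.

Fitting your own models (see `examples/` for full scripts):

```python
from skinqspr import (assign, build_scenario_table, filter_complete,
                      load_dataset, select_best)

ds = load_dataset("permeability.csv", "descriptors.csv")
kept, report = filter_complete(ds.records)       # drop incomplete metadata
table = build_scenario_table(assign(kept, ds.descriptors))
best = select_best(table, min_n=16)              # highest R² with n >= 16
```

The same pipeline is scriptable from a shell:

```sh
skinqspr --seed 7 simulate --out-prefix sim_
skinqspr --seed 7 fit-scenarios --permeability sim_permeability.csv \
         --descriptors sim_descriptors.csv --out models.csv
skinqspr predict --model eq2 --logp 0 --tpsa 0 --mv 0    # prints -6.136
```

Every command writes a JSON run manifest (config snapshot, input digests,
seed, stage counts) so runs can be reproduced byte-for-byte.

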