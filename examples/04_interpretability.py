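"""Which inputs drive the forecasts?

Variable-selection weights, averaged over steps and held-out windows and
renormalised, give a per-feature importance.  In the synthetic cohort
pulse drives spo2 with coupling 0.8, so pulse should surface near the top
of the time-series ranking.
"""

import vitalcast as vc
from vitalcast.synthetic import PRESSOR_NAMES

STATIC = [f"static_{k}" for k in range(4)]

cohort = vc.simulate_cohort(vc.SimulationParams(seed=2))  # 375 subjects
schema = vc.default_schema(vc.CHANNELS, STATIC)
ids = sorted(cohort.static_table.subject_id)
train_ids, test_ids = vc.split_subjects(ids, 0.8, seed=2)
ws, _ = vc.prepare_windows(
    cohort.long_table, cohort.static_table, schema, train_ids,
    pressor_names=list(PRESSOR_NAMES),
)

model = vc.TFTMulti(vc.ModelConfig.from_windowset(ws, state_size=16, dropout=0.1), seed=2)
model, _ = vc.train(model, ws.for_subjects(train_ids), vc.TrainingConfig(batch_size=32, max_epochs=30, seed=2))

fs = model.predict(ws.for_subjects(test_ids))
rep = vc.aggregate_importance(fs, list(schema.past_timeseries), STATIC)

print("time-series feature importance (sums to 1):")
for name in rep.timeseries_ranking:
    print(f"  {name:>10}: {rep.timeseries_importance[name]:.3f}")
print("\nstatic feature importance:")
for name in rep.static_ranking:
    print(f"  {name:>10}: {rep.static_importance[name]:.3f}")
print("\n'pulse' ranking high reflects the injected pulse->spo2 coupling, and")
print("'static_0' is the flag with a real additive effect on mean BP; weights")
print("are softmax outputs of the variable-selection networks.")
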