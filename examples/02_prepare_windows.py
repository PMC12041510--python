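"""From irregular observations to masked, role-annotated forecast windows.

Each encounter's first 100 fifteen-minute bins become one window: 75 past
steps and 25 future steps.  Bins holding at least one raw observation are
mask-1; forward-filled bins are mask-0 and will be invisible to the loss
and every metric.
"""

import vitalcast as vc
from vitalcast.synthetic import PRESSOR_NAMES

cohort = vc.simulate_cohort(vc.SimulationParams(n_subjects=50, seed=1))
schema = vc.default_schema(vc.CHANNELS, [f"static_{k}" for k in range(4)])

ids = sorted(cohort.static_table.subject_id)
train_ids, test_ids = vc.split_subjects(ids, train_frac=0.8, seed=1)
ws, report = vc.prepare_windows(
    cohort.long_table, cohort.static_table, schema, train_ids,
    pressor_names=list(PRESSOR_NAMES),
)

print(f"{len(ws)} windows ({report.excluded_short} encounters too short)")
print(f"past inputs   : {ws.past.shape}   (windows x steps x channels)")
print(f"known future  : {ws.known_future.shape}")
print(f"future truth  : {ws.future_truth.shape} (clinical units)")
print(f"future masks  : real-value fraction per target:")
for j, tgt in enumerate(schema.targets):
    print(f"  {tgt:>7}: {ws.future_masks[:, :, j].mean():.2f}")
print("\nnormalization (training real values only):")
for tgt in schema.targets:
    mu, sd = ws.normalization[tgt]
    print(f"  {tgt:>7}: center {mu:7.2f}  scale {sd:5.2f}")
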