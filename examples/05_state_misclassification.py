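"""How ecological state conditions site-class misclassification.

Uses the state-and-transition mosaic: each site class spans its full
degradation sequence, so degraded states (shrubland/bare, codes 6-7)
lose the seasonal amplitude that identifies their soil class.  The
script cross-validates the classifier, then stratifies the errors by
state code — the misclassification percentage should rise with
degradation — and shows which classes absorb the Loamy errors.
"""

import ecosite as es
from ecosite.classify import SampleSet

seed = 2
climate = es.simulate_precipitation(
    "1989-01-01",
    "1999-12-31",
    [("1989-01-01", "1994-12-31", 1.5), ("1995-01-01", "1999-12-31", 0.7)],
    seed=seed,
)
grid = es.build_time_grid("1990-01-05", "1999-12-20", 16)
config = es.paper_like_config(30, 30, layout="state_mixture", noise_sd=0.04, seed=seed)
stack, truth = es.simulate_scene(config, climate, grid)
filtered = es.preprocess_stack(stack)

frame = es.draw_samples(truth, 40, seed=seed + 1)
frame["row"], frame["col"] = config.transform.rowcol(frame["x"].values, frame["y"].values)
samples = SampleSet(frame)
table = es.extract_covariates(filtered, samples)
weights = es.inverse_frequency_weights(samples.labels)

_, _, records = es.lgocv(table, samples.labels, reps=30, C=4.0, gamma="scale",
                         class_weights=weights, seed=seed, return_records=True)
records["state_code"] = samples.state_codes[records["sample_index"]]
recs = es.classification_records(
    records.index, records["reference"], records["prediction"], records["state_code"]
)

print("misclassification by ecological state (1 = reference grassland,")
print("3 = reference savanna, 6/7 = shrubland & bare):")
print(es.misclassification_by_state(recs)[["n_total", "n_misclassified", "pct_rounded"]]
      .to_string(), "\n")

breakdown = es.misclassified_as_breakdown(recs, "Loamy")
print("Loamy errors by absorbing class (with state-code histogram):")
for assigned, info in sorted(breakdown.items(), key=lambda kv: -kv[1]["n"]):
    print(f"  -> {assigned:<13} n = {info['n']:>4}  states {info['states']}")
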