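"""Per-subtype one-vs-rest diagnostic report.

Each subtype is scored as its own binary screen (that subtype vs. all
others): Accuracy = (TP+TN)/n, Sensitivity = TP/(TP+FN), Specificity =
TN/(TN+FP), reported as percentages rounded half-up to two decimals.
Undefined metrics (empty denominator) print as "—", never as 0 or 100.
"""

import numpy as np

import leukotype as lt

rng = np.random.default_rng(3)
ids = [f"P{i:03d}" for i in range(160)]
subtypes = rng.choice(lt.SUBTYPES, size=160)
true = lt.SampleLabels(dict(zip(ids, subtypes)))

# a deliberately imperfect classifier: 10% of calls are wrong
predicted = {}
for s, sub in true.labels.items():
    if rng.random() < 0.10:
        predicted[s] = rng.choice([x for x in lt.SUBTYPES if x != sub])
    else:
        predicted[s] = sub

table = lt.evaluate_table(true, lt.SampleLabels(predicted))
print(table.to_string(index=False))
print(f"\nevery row sums to n: "
      f"{bool((table[['TP', 'FP', 'TN', 'FN']].sum(axis=1) == 160).all())}")
print(f"overall (micro) accuracy: "
      f"{100 * lt.overall_accuracy(true, lt.SampleLabels(predicted)):.2f}%")
# Sensitivity of a subtype is the fraction of its true patients the screen
# catches; Specificity is the fraction of other patients it does not flag.
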