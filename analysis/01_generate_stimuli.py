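"""Generate the synthetic study materials and summarize them.

Creates the cross-dataset pair of affective picture sets (two independent
draws of the same generative conditions: 150 images per category, effect
size 3 over unit noise) and the toy object-recognition task, then writes
per-category valence and statistic summaries to results/.
"""

import os

import numpy as np
import pandas as pd

from emosel import pipeline
from emosel.stimuli import CATEGORIES
from emosel.synth import generate_object_task, planted_statistics

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
os.makedirs(OUT, exist_ok=True)

set_a, set_b = pipeline.make_affective_pair(seed=1)
rows = []
for s in (set_a, set_b):
    stats = planted_statistics(s)
    for ci, cat in enumerate(CATEGORIES):
        mask = s.categories == cat
        rows.append(
            {
                "dataset": s.dataset,
                "category": cat,
                "n_images": int(mask.sum()),
                "valence_mean": s.valence[mask].mean(),
                "valence_min": s.valence[mask].min(),
                "valence_max": s.valence[mask].max(),
                "own_statistic_mean": stats[mask, ci].mean(),
                "other_statistic_mean": stats[~mask, ci].mean(),
            }
        )
summary = pd.DataFrame(rows)
summary.to_csv(os.path.join(OUT, "stimuli_summary.csv"), index=False)
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

task = generate_object_task(seed=11)
counts = np.bincount(task.labels)
print("\nObject task:", dict(zip(task.class_names, counts.tolist())))
print("Each category's own statistic clearly exceeds its value in other "
      "categories, so the sets carry recoverable category-linked structure.")
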