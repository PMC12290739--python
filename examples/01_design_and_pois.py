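"""Build the conditioning design and inspect the pattern-of-interest library.

The experiment presents six face stimuli (two CS+ and one CS- per task) in
seven unpaired and six paired blocks per task; paired-block CS+ trials are
accompanied by a valenced touch (brush stroke or painful pressure).  Each
POI is the idealized similarity matrix an ROI would show if it represented
exactly one theoretical construct.
"""

import pandas as pd

from pcmrsa import CONDITION_POIS, TRIAL_ONLY_POIS, DesignParams, condition_poi, generate_design

table = generate_design(DesignParams(seed=0))
print(f"trials: {len(table)}  per task: {table.groupby('task').size().to_dict()}")
print("\nfirst paired block (CS order randomized per block):")
print(table[(table.task == 'appetitive') & (table.block_index == 2)]
      [["trial_index", "condition", "touch_type", "us_delivered"]].to_string(index=False))

print("\ncondition-level POIs:", ", ".join(CONDITION_POIS))
print("trial-only POIs:     ", ", ".join(TRIAL_ONLY_POIS))

poi = condition_poi("Touch Valence")
print("\nTouch Valence (within-task touch pairs +1, cross-task touch pairs -1, CS- pairs 0):")
print(pd.DataFrame(poi.matrix, index=poi.labels, columns=poi.labels).to_string())
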