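"""Project new (possibly incomplete) days onto an already-trained map.

A practical benefit of the SOM for exposure work: the stored
standardization and codebooks classify new days, including days with
missing pollutant measurements (via a rescaled masked distance), without
retraining.
"""

import numpy as np

from airsom import (
    SOMGrid,
    TrainingSchedule,
    assign,
    complete_case_filter,
    generate,
    inject_missingness,
    standardize,
    table1_profile,
    train_with_restarts,
)
from airsom.som import UNLABELED

config = table1_profile(seed=5)
Z, _ = generate(config)
Zc = complete_case_filter(Z)
Zs, params = standardize(Zc)
model = train_with_restarts(
    Zs.values, SOMGrid(4, 4), TrainingSchedule(seed=5),
    n_restarts=10, standardization=params, columns=Zc.columns,
)

# a fresh year of data from the same process, with heavy missingness
config_new = table1_profile(n_days=365, seed=50, missing_rate=0.2)
Z_new, _ = generate(config_new)
labels = assign(Z_new, model)

n_missing_rows = int(np.isnan(Z_new.values).any(axis=1).sum())
n_unlabeled = int((labels == UNLABELED).sum())
print(f"projected {Z_new.n} new days onto the trained 4x4 map")
print(f"{n_missing_rows} days had missing entries; "
      f"{n_missing_rows - n_unlabeled} of them were still classifiable")
print(f"{n_unlabeled} days had no observations at all and stay unlabeled")
print("first ten assignments (node ids):", labels[:10].tolist())
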