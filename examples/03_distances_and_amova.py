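"""TN93(+gamma) distances and the AMOVA variance partition.

For the landlocked species, almost all molecular variance lies among
populations (each waterfall hosts its own lineage); for the amphidromous
source species, variance lies within populations (one panmictic pool).
"""

import numpy as np

from landlock import (
    DistanceModelSpec, SimulationConfig, amova_two_level, pairwise_matrix,
    simulate_sequences, within_group_diversity,
)
from landlock.gendist import DistanceMatrix

table = simulate_sequences(SimulationConfig(seed=42))
meta = table.meta

matrix = pairwise_matrix(table, DistanceModelSpec(model="TN93+G", gamma_shape=0.14))
br_ids = list(meta.loc[meta["species"] == "BR", "individual_id"])
print(f"within-source mean pairwise diversity: "
      f"{within_group_diversity(matrix, br_ids):.5f} "
      f"(configured 0.00184)")

plain = pairwise_matrix(table, DistanceModelSpec(model="TN93"))
for species in ("YB", "BR"):
    idx = np.flatnonzero((meta["species"] == species).to_numpy())
    sub = DistanceMatrix(
        labels=[plain.labels[i] for i in idx],
        values=plain.values[np.ix_(idx, idx)], model=plain.model,
    )
    res = amova_two_level(sub, meta.loc[idx, "population"].to_numpy(),
                          permutations=1000, rng=np.random.default_rng(0))
    print(f"{species}: {res.percent_among:.1f}% among / "
          f"{res.percent_within:.1f}% within populations, "
          f"phi-ST = {res.phi_ST:.3f}, p = {res.p_value:.4f}")
# High among-population % for the landlocked species mirrors independent
# founding above each waterfall; near-zero for the source pool mirrors
# panmixia maintained by the marine larval phase.
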