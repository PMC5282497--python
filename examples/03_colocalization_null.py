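"""The exact chance distribution of probe-chromocenter colocalization.

If n probe signals each land on one of k chromocenters uniformly and
independently, how many distinct chromocenters do they hit?  The closed form
(Stirling numbers) and a geometric simulation with the synthetic generator
are compared for the study's configuration: ~3 NOR signals, 7 chromocenters.
"""

import numpy as np

from spermtopo import (
    SyntheticSpec,
    associate_with_chromocenters,
    count_clusters,
    null_colocalization_pmf,
    simulate_cell,
)

pmf = null_colocalization_pmf(3, 7)
print("exact null for 3 signals x 7 chromocenters:")
for j, p in pmf.items():
    print(f"  P({j} distinct) = {p} = {float(p):.4f}")
print(f"  P(all in one chromocenter) = {float(pmf[1]):.4f}  (1/49)")

spec = SyntheticSpec(probe_jitter=0.1)
distinct = []
for i in range(1, 201):
    cell = simulate_cell(spec, cell_index=i,
                         channels=("pancentromere", "NOR"), render=False)
    chromo_pos, probes = {}, []
    for s in cell.spots:
        if s.channel == "pancentromere":
            chromo_pos.setdefault(s.cluster_id, []).append(s.position)
        elif s.channel == "NOR":
            probes.append(s.position)
    chromo = count_clusters(
        np.array([np.mean(v, axis=0) for v in chromo_pos.values()]), 0.0
    )
    rec = associate_with_chromocenters(np.array(probes), chromo, proximity=0.5)
    distinct.append(rec.n_distinct_chromocenters_associated)

print("\n200 simulated cells (uniform anchoring):")
for j in sorted(pmf):
    obs = np.mean(np.asarray(distinct) == j)
    print(f"  observed P({j} distinct) = {obs:.3f}  (exact {float(pmf[j]):.3f})")
print("Agreement shows the geometric pipeline reproduces the combinatorial "
      "null; excess clustering in real data would shift mass toward small j.")
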