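"""Generate a synthetic trajectory ensemble and write it to disk.

Builds a 4-state metastable chain with exactly known relaxation timescales,
samples a multi-trajectory ensemble (eight 5000-step segments, all started
in state 0), and writes one TSV per trajectory plus a JSON manifest.
"""

from pathlib import Path

import msmuq
from msmuq import io as mio

model = msmuq.build_metastable_chain(4, stay_prob=0.995, seed=0)
print("ground-truth implied timescales (steps):",
      [round(float(t), 1) for t in model.true_timescales])
# These are the exact relaxation times of the hidden chain; every estimate
# made later can be compared against them.

ensembles = msmuq.generate_ensemble(
    model, strategy="multi", T_total=40000, segment_length=5000,
    start_state=0, n_replicates=2, seed=1,
)
out = Path("scratch_example_data")
for ens in ensembles:
    manifest = mio.write_ensemble(ens, out, true_timescales=model.true_timescales)
    print(f"replicate {ens.replicate_id}: {ens.n_trajectories} trajectories "
          f"of {len(ens.trajectories[0])} steps -> {manifest}")

clone = mio.read_ensemble(out / "manifest_000.json")
print("reloaded:", clone.n_trajectories, "trajectories, strategy", clone.strategy)
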