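"""Full analysis of the 1-D three-basin landscape, stage by stage.

Builds synthetic discrete trajectories on a landscape with two deep basins
(A, B) and one shallow basin (C) near A, then runs every stage of the
multi-persistent clustering analysis and prints what each one finds.
"""

import numpy as np

import mpcluster as mpc

spec = mpc.make_three_basin_landscape()
dataset = mpc.metropolis_trajectories(spec, n_traj=100, n_steps=2000, seed=1)
print(f"simulated {len(dataset.trajectories.trajectories)} trajectories, "
      f"{dataset.trajectories.n_frames} frames, {spec.n_microstates} grid microstates")

result = mpc.run_pipeline(dataset.trajectories, mpc.RunConfig(seed=1))
model, D, gc = result.model, result.D, result.gridclust
print(f"ergodic model: {model.n_states} microstates, lag {model.lag}")
print(f"commute-time bounds: d_min={D.d_min:.1f}, D_star={D.D_star:.1f} (lag units)")

print("\ntop of the persistence summary (one row per cluster label):")
print(result.summary.head(5).to_string(index=False))

def well(label):
    return spec.well_names[dataset.ground_truth[model.state_map[label]]]

print("\nselected persistent clusters and the basin each core sits in:")
for lab in result.candidates.selected:
    print(f"  label {lab} (original bin {model.state_map[lab]}) -> basin {well(lab)}")

print("\nhierarchy (heights are density level indices; rare-state candidates")
print("appear as extra leaves named by the basin they fall in):")
print(" ", result.tree.to_newick({l: f"{well(l)}_{l}" for l in result.candidates.versions}))
print("C's core attaches to A at a low density level; B only joins near the")
print("root — the shallow basin C is kinetically closer to A, as planted.")

counts = np.bincount(result.partition.assignment)
print(f"\nfull partition sizes (microstates per cluster): "
      f"{ {well(l): int(c) for l, c in enumerate(counts) if c} }")
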