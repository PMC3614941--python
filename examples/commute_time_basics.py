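"""Commute-time distances from a hand-built Markov chain.

A two-state chain with escape probabilities p and q has hitting times 1/p
and 1/q, so the commute time (the symmetric kinetic distance used by the
clustering) is 1/p + 1/q.  This script verifies that and shows the scale
bounds on a small chain.
"""

import numpy as np

import mpcluster as mpc

p, q = 0.1, 0.2
T = np.array([[1 - p, p], [q, 1 - q]])
pi = mpc.stationary_distribution(T)
model = mpc.MicrostateModel(
    T=T, pi=pi, E=mpc.free_energies(pi), populations=np.array([1, 1])
)
print(f"two-state chain with p={p}, q={q}")
print(f"  hitting times to state 1: {mpc.hitting_times_to(T, 1)}  (expect [10, 0])")
print(f"  hitting times to state 0: {mpc.hitting_times_to(T, 0)}  (expect [0, 5])")
D = mpc.commute_time_matrix(model)
print(f"  commute time D[0,1] = {D.D[0, 1]:.1f}  (expect 1/p + 1/q = 15)")

# a 5-state chain: two tight pairs joined by a bottleneck state
counts = np.array(
    [
        [50, 40, 1, 0, 0],
        [40, 50, 1, 0, 0],
        [1, 1, 2, 1, 1],
        [0, 0, 1, 50, 40],
        [0, 0, 1, 40, 50],
    ]
)
cm = mpc.CountMatrix(counts, lag=1, populations=counts.sum(axis=1))
T5 = mpc.transition_matrix(cm)
pi5 = mpc.stationary_distribution(T5)
model5 = mpc.MicrostateModel(T=T5, pi=pi5, E=mpc.free_energies(pi5), populations=cm.populations)
D5 = mpc.commute_time_matrix(model5)
print("\nfive-state chain (two tight pairs bridged by a rare state):")
print(np.array_str(D5.D, precision=1))
print(f"d_min = {D5.d_min:.1f} (singletons below), "
      f"D_star = {D5.D_star:.1f} (single cluster above)")
print("within-pair distances are small; crossing the bottleneck costs ~100x more.")
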