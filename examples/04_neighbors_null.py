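"""Neighbor co-occurrence statistics against a Monte Carlo shuffle null.

A clustered array (sticky Markov chain over the realistic unit-type
spectrum, λ=0.6) shows elevated self-association of unit types at the
immediate-neighbor (10 kb) distance; the shuffle null (1000 label
permutations preserving the per-BAC slot structure) quantifies the excess,
and R² compares distance classes.
"""

from rdnakit import (SimConfig, count_pairs, normalize, null_frequencies,
                     pairwise_r2, simulate_nor)

config = SimConfig(n_units=1400, stickiness=0.6, n_bacs=0, overlap_plan=[], seed=3)
tokens = [u.feature.encode() for u in simulate_nor(config)]
catalog = {f"B{i:03d}": tokens[i * 7:(i + 1) * 7] for i in range(200)}

obs_k1 = normalize(count_pairs(catalog, 1))
obs_k2 = normalize(count_pairs(catalog, 2))
null = null_frequencies(catalog, 1, replicates=1000, seed=30)

print("type   observed self-assoc   null mean   null 97.5th pct")
for t in ("2001", "2003", "3001", "3111"):  # the four most common types
    print(f"{t}   {obs_k1.normalized[(t, t)]:.3f}               "
          f"{null.normalized_null[(t, t)]:.3f}       "
          f"{null.normalized_percentile((t, t), 97.5):.3f}")

r2_neighbors = pairwise_r2(obs_k1.normalized, obs_k2.normalized)
r2_null = pairwise_r2(obs_k1.normalized, null.normalized_null)
print(f"\nR2 10kb vs 20kb distance: {r2_neighbors:.3f}")
print(f"R2 10kb vs shuffle null:  {r2_null:.3f}")
print("pairs retained at frequency > 0.90:", len(null.retained))
# Common types self-associate far above the null's 97.5th percentile
# (clustering), and the 10 kb pair frequencies correlate with the 20 kb
# ones but barely with the exchangeable-null expectation.
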