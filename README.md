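# cascadist

Final-**size distributions** of contagion cascades on networks — not just
the mean.

Cascades (epidemic outbreaks, information spread, failure propagation)
are usually summarized by their expected final size, obtained from mean
field theory or belief propagation. But on finite networks the final-size
distribution can be broad and multi-modal — especially around hubs, where
the modes correspond to "no hub activates", "one hub activates", … — and
then the mean is a poor, sometimes improbable, summary of the risk.
`cascadist` computes the full distribution:

* **SDP (subtree distribution propagation)** — an exact, single upward
  message-passing pass on a tree. Each node n sends its parent the joint
  distribution of its subtree's final active count together with an
  indicator of n's own state, and the root assembles
  p_ρ(t/N) = P(T_r = t) for t = 0..N. Worst case O(N² log N); with the
  cascade size restricted to an equidistant grid of C points, O(N).
* **TDA (tree distribution approximation)** — for general networks:
  loopy belief propagation estimates directed activation probabilities
  p_ij = P(s_i = 1 ‖ s_j = 0), a random minimum spanning tree cuts the
  loops, each node keeps its lost neighbors as independent "ghosts"
  (initially active with probability p_ni, influencing the node's response
  but not counted in the size), and SDP runs on the tree. Exact on trees,
  accurate on locally tree-like networks.

## Cascade models

A model is defined per node by a response function R_i(a), a = 0..d_i+1:
the probability that node i activates exactly when a neighbors are active
(R_i(0) seeds the cascade; R_i(d_i+1) is the never-activate mass), with
cumulative R_i^c(a) = Σ_{l≤a} R_i(l) and Σ_a R_i(a) = 1. Built in:

* **Threshold model (TM)** — fractional thresholds θ_i ~ F_i;
  R_i(a) = F_i(a/d_i) − F_i((a−1)/d_i). Normal and tabulated CDFs.
* **Independent cascade model (ICM)** — SIR-like with seeding and
  transmission probability p; R_i(a) = p(1−p)^a,
  R_i(d_i+1) = (1−p)^{d_i+1}. Equivalent to bond percolation in final
  outcome (and tested against a percolation sampler).

Ground truth for validation: a vectorized threshold-coupled Monte Carlo
simulator, an exhaustive enumeration oracle (exact on *any* graph with a
small enough state space), and the ICM bond-percolation sampler.

## Worked example

A 60-node tree with two degree-20 hubs, thresholds θ ~ N(0.5, 0.5²):

```python
from cascadist import (ModelConfig, build_response, hub_tree,
                       monte_carlo_distribution, root_tree, run_sdp,
                       tv_distance)

g = hub_tree([20, 20], 60)
cfg = ModelConfig("threshold_normal", {"mu": 0.5, "sigma": 0.5})
resp = {n: build_response(cfg, n, g.degree(n)) for n in g.nodes}
dist = run_sdp(root_tree(g), resp)

print(f"mean final fraction: {dist.mean_rho():.4f}")
peaks = [t for t in range(1, 60)
         if dist.probs[t] > dist.probs[t-1] and dist.probs[t] >= dist.probs[t+1]]
print("local maxima at t =", peaks)

mc = monte_carlo_distribution(g, cfg, 100_000, seed=1)
print(f"TV(SDP, MC) = {tv_distance(dist.probs, mc.probs):.4f}")
```

prints

```
mean final fraction: 0.3212
local maxima at t = [12, 25, 38]
TV(SDP, MC) = 0.0079
```

The distribution is tri-modal — roughly zero, one or two hubs activating,
each dragging its leaves along — so the mean (ρ ≈ 0.32) sits in a valley
between modes and is itself an unlikely outcome. The exact curve agrees
with 10⁵ Monte Carlo draws to sampling error.

## Command line

Everything is also exposed as `cascadist` subcommands that read plain
two-column edge lists and JSON model configs and write a shared
`t  rho  probability` TSV, so outputs of all producers are diffable:

```sh
cascadist gen --kind power_law_config_model --n 543 --d-max 25 --seed 1 --out net.edges
echo '{"model": "icm", "p": 0.2}' > icm.json
cascadist tda --network net.edges --model icm.json --mst-seed 1 --out dist.tsv
cascadist mc  --network net.edges --model icm.json --reps 100000 --out mc.tsv
```

Subcommands: `gen`, `sdp`, `tda`, `bp`, `mc`, `oracle`, `perc`.

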