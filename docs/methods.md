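# Methods

## Model framework

A cascade runs on a fixed undirected simple graph G = (V, E), N = |V|.
Node states are binary (inactive/active); activation is monotone (no
recovery) and time-homogeneous. Node i's behavior is fully described by
its response function R_i(a), a = 0..d_i+1: the probability of activating
exactly when a neighbors are active and a−1 would not have sufficed.
R_i(0) is spontaneous seeding, R_i(d_i+1) the never-activate mass, and
R_i^c(a) = Σ_{l≤a} R_i(l) the probability of being active whenever a
neighbors are. We restrict to monotone cumulative responses (R_i^c equals
the cumulative sum of R_i), which covers both built-in models; responses
where additional active neighbors *reduce* activation (some
opinion-formation models) are out of scope. The quantity of interest is
the distribution of the final active count T (equivalently the fraction
ρ = T/N).

Built-in models and their parameters:

| model | parameters | defaults used in experiments |
|---|---|---|
| threshold (TM) | threshold CDF F_i; normal: mean μ, sd σ (threshold units: fraction of neighbors) | μ = 0.5, σ = 0.5 |
| independent cascade (ICM) | seeding/transmission probability p | p = 0.2 |

These defaults are deliberately non-critical (far from a phase
transition); broad or multi-modal distributions at these settings are a
genuine finite-network effect, not critical slowing.

Equivalent threshold coupling: drawing an integer threshold k_i with
P(k_i = a) = R_i(a) and activating i once at least k_i neighbors are
active reproduces the activation law exactly for monotone R^c and makes
the final state independent of the update schedule. The Monte Carlo
simulator and the enumeration oracle both use this coupling; synchronous
updates reach the fixed point in at most N steps.

## Exact pass on trees (SDP)

For a rooted tree, each non-root node n sends its parent two tables:

* pI(t, s): joint probability that n's subtree ends with t active nodes
  and n in state s, **given the parent held inactive**;
* pA(t, r): the same count jointly with the trigger indicator r — r = 1
  iff n activated before its parent (and so can trigger it), r = 0
  collects every case compatible with an active parent.

Conditioning on the parent's state removes the only dependence path
between sibling subtrees, so child tables combine by 2-D convolution
(counts add along t; indicators add along a, the number of active /
triggering children). The node's own response then turns the convolved
tables (p_I*, p_A*) into its message:

    pA(t,0) = Σ_a p_I*(t,a)(1−R^c(a+1)) + Σ_a p_A*(t−1,a)R(a+1)
    pA(t,1) = Σ_a p_A*(t−1,a)R^c(a)
    pI(t,0) = Σ_a p_I*(t,a)(1−R^c(a)),   pI(t,1) = pA(t,1)

and at the root P(T = t) = Σ_a p_I*(t,a)(1−R^c(a)) + Σ_a p_A*(t−1,a)R^c(a).
Leaves are the base case (equivalently, the identity convolution — one
unit of mass at (0,0) — fed through the same update; the implementation
exploits this so a single code path covers leaves, internal nodes,
isolated roots and single-node trees).

Correctness is asserted, not assumed: every message must sum to 1 within
1e−9 and satisfy pI(·,1) = pA(·,1); the whole pass is tested to 1e−10
against exhaustive enumeration over hundreds of random trees and both
models, and the result is invariant (1e−10) under the choice of root.

### Numerical choices

* Children are convolved pairwise smallest-first; this affects speed and
  round-off only (root invariance is tested).
* Convolutions with t-support ≤ 256 use direct summation (exact);
  larger ones use FFT with negatives clipped at tolerance 1e−12 and the
  mass renormalized — a clip beyond tolerance raises rather than
  silently corrupting the distribution.
* Default root is a tree center (found by the double-BFS diameter trick,
  ties broken by node order): it minimizes the maximum path length and
  keeps intermediate supports balanced. Any explicit root is honored and
  gives the identical distribution.
* Probabilities are written to TSV with 17 significant digits so a
  round trip is bit-stable.

### Grid mode

With `resolution=C`, any message whose t-support exceeds C+1 points is
re-binned onto the equidistant grid {0, N/C, …, N}: each mass is split
between the two nearest grid points so its expectation is unchanged.
Subsequent convolutions and the per-node shift (t → t+1, a fractional
offset on the grid) use the same two-point splitting. Rounding spill past
the last grid point (ceil splits can stack a ~1e−7 sliver beyond index C)
is folded back mean-preservingly. Grid mode is therefore *approximate*:
it preserves the distribution mean to ~1e−9 and is intended for shape
inspection at large N; it is off by default, and with C ≥ N no re-binning
triggers and the output is bit-identical to the exact mode. This
re-binning scheme is the package's own construction.

## Belief propagation

Directed-edge probabilities p_ij = P(s_i = 1 ‖ s_j = 0) — i activates
with j held inactive, i.e. before j could have helped — obey
self-consistent equations in which i's other neighbors contribute
independently. The sum over neighbor-state vectors is computed as
E[R^c(S)] with S Poisson-binomial of the incoming probabilities
(Bernoulli masses convolved iteratively; FFT beyond 64 terms). Node
marginals p_i use the same expression over all neighbors.

Defaults: initialization p_ij = R_i(0), 50 synchronous (Jacobi) sweeps —
a fixed iteration count rather than a convergence threshold; the final
sweep's largest update is reported so callers can detect
non-convergence, which is never fatal. An asynchronous in-place schedule
is available behind a flag; both schedules reach the same fixed point on
the tested graphs. On a tree, diameter+1 sweeps suffice for exactness
(tested to 1e−8 against enumeration, including the order-conditioned
p_ij via enumeration with the conditioning neighbor clamped inactive).

## Tree distribution approximation (TDA)

1. Loopy BP on G yields p_ij for every directed edge.
2. A minimum spanning forest under i.i.d. uniform seeded random edge
   weights cuts the loops (user-supplied weights can bias which edges are
   cut, e.g. hub–hub edges); dnb(i) records the neighbors i lost.
3. Each node's response is averaged over the initial states of its lost
   neighbors, treated as independent ghosts active with probability
   p_ni: with S the Poisson-binomial count of active ghosts,
   R̃^c(a) = E[R^c(a + S)] and R̃(a) = E[R(a + S)] for a ≥ 1. For a = 0
   the literal average E[R(S)] would break normalization and drop
   ghost-triggered seeding, so the package defines R̃(0) = E[R^c(S)]:
   this preserves Σ_a R̃(a) = 1, the cumulative-sum identity, and the
   integer-threshold semantics (a node with threshold k activates once
   active tree-neighbors plus active ghosts reach k).
4. SDP runs on each forest component with the updated responses; since
   components evolve independently, their size distributions are
   convolved into the distribution over t = 0..N (a flag restricts the
   analysis to the largest connected component instead). Ghosts are
   never counted in the final size.

On a tree, steps 2–3 are identities and TDA's output is byte-for-byte
the SDP output. On loopy graphs TDA neglects the dependence that loops
induce between a node and its ghosts; the error is largest on short
loops (on a 3-cycle with ICM p = 0.2 the total-variation error against
enumeration is ≈ 0.07, driven by BP's own feedback double-counting) and
small on locally tree-like networks, where TDA tracks 10⁵-replicate
Monte Carlo far better than a point mass at the mean (tested for both
models on a 200-node power-law configuration model).

## Synthetic networks

The generators produce the study's network classes:

* `star(N)`, `path(N)` — extreme topologies for closed-form checks.
* `uniform_tree(N, seed)` — uniformly random labeled tree via a random
  Prüfer sequence.
* `hub_tree(hub_degrees, N)` — hubs joined along a path, each padded
  with leaf neighbors to its requested degree; surplus nodes beyond the
  minimal construction are chained onto the leaf branches round-robin,
  which keeps hub degrees exact while adding the longer paths that
  smooth the distribution between hub-driven modes.
* `power_law_config_model(N, gamma, d_min, d_max, seed)` — i.i.d.
  degrees from p(d) ∝ d^−γ truncated to [d_min, d_max] (an odd sum is
  fixed by resampling one uniformly chosen degree), uniform stub
  matching, then self-loops erased and multi-edges collapsed with the
  degree distortion logged. d_min defaults to 1; the realized mean
  degree matches the truncated-law expectation to ±0.3 at N ≈ 500.

What the synthetic conditions do and do not show: experiments here use
trees up to N = 50 000, two-hub trees (degrees 20), and configuration
models around N = 200 with γ = 2.5, d ≤ 25 — sized so exhaustive
enumeration or 10⁵-replicate Monte Carlo can serve as ground truth on a
single CPU. These graphs reproduce the structural features that drive
the method (hubs → multi-modality; short loops → TDA error; locally
tree-like sparseness → TDA accuracy) but not the heavy-tailed hub sizes
(d_max in the hundreds) or the community structure of real networks, so
passing tests bound algorithmic correctness, not TDA's accuracy on an
arbitrary real network. Real networks enter through the same edge-list
loader.

## Degenerate inputs and tie-breaks

Single-node trees and degree-0 nodes use the identity convolution;
p = 0 (or F(0) = 0 with no achievable threshold) yields a point mass at
t = 0, p = 1 a point mass at t = N. Disconnected inputs are handled per
component and convolved. Root auto-selection tie-breaks by node order;
the MST tie-breaks through its random weights, so every run is
deterministic given its seeds.

## Known limitations

* TDA inherits loopy BP's bias on dense or short-loop graphs and tends
  to underestimate the distribution's variance there; no loop
  corrections (junction-tree style) are implemented.
* Grid mode's re-binning is approximate (mean-exact, shape-smoothing);
  quantiles read off a coarse grid inherit its resolution.
* No recovery dynamics (SIR's R state beyond the ICM equivalence), no
  time-resolved trajectories, no non-monotone responses, and no
  distributed O(height) execution of the tree pass.
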