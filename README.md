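# linklimit

How predictable is a network's structure? `linklimit` quantifies the intrinsic
structure predictability of undirected simple networks through two normalized
quantities and the machinery connecting them:

* **Normalized compression length `L*`** — a two-stage lossless, label-free
  (isomorphism-invariant) compression of the graph structure: a
  partition-refinement traversal emits per-cell neighbour bits/counts, which
  an adaptive arithmetic coder turns into a bit length `L`; dividing by the
  closed-form ceiling `R = C(N,2) h(q) − N log₂ N` (the structural entropy of
  an Erdős–Rényi graph with the same `N`, `E`) gives `L* = L/R`.
* **Normalized rank entropy `H*`** — leave-one-out link prediction: each edge
  is removed and ranked among all unlinked pairs by a similarity index; the
  ranks are binned with width `N` and the Shannon entropy of the binned
  distribution, divided by `log₂ N − 1`, measures how far the best available
  algorithm (minimum over a registered suite of 11 indices — CN, Jaccard, RA,
  Adamic-Adar, PA, Salton, Local Path, Katz, ACT, LRW, SPM) is from perfect
  prediction.

On top of these the package provides the empirical linear law
`H* ≈ 1.63 L* − 0.63`, the analytic theory for edge-independent random graphs
(structural entropy of a probability matrix `Q`, the ideal-predictor entropy
and the finite-size/limit line variants), entropy-constrained upper/lower
bounds on link-prediction precision `p₁`/`P_C`, and a conservative dataset
value estimate.

## Library quick start

```python
import linklimit as ll

g = ll.read_edge_list("network.txt")          # or er_graph / sample_from_q / ...
comp = ll.normalized_length(g, runs=50, seed=0)
est = ll.bpaa(g, algorithms=["CN", "RA", "PA"], seed=0)
print(comp.normalized, est.h_star, ll.line_gap(comp.normalized, est.h_star))
```

## Command line

The `linklimit` entry point exposes:

```bash
linklimit compress network.txt --runs 50 --seed 1        # {N, E, L_mean, L_std, R, L_star}
linklimit rank network.txt --algorithm RA --seed 1       # CSV of (u, v, rank)
linklimit predictability network.txt --algorithms CN,RA  # per-algorithm H, H*, BPAA
linklimit theory-line --n 10000 --k 16 --variant eq8     # {slope, intercept}
linklimit simulate-q --degrees degrees.txt --seed 1      # edge list from a Chung-Lu Q
linklimit bounds network.txt -c 1 -c 5 --theta 100       # precision bounds + value
linklimit law-experiment --graph network.txt --out out/  # shuffle-fraction sweep
linklimit regularity-experiment --graph network.txt      # ring-lattice admixture sweep
```

Edge lists are whitespace-delimited with `#` comments; GraphML is read when
the path ends in `.graphml`. All commands are deterministic given `--seed`.

## Notes and conventions

* Logs are base 2 throughout; `0·log 0 = 0`.
* ER graphs use the fixed-edge-count `G(N, M)` convention.
* Ranks of removed edges are placed uniformly at random (seeded) within
  score-tie blocks; `tie_break="midrank"` gives the deterministic expected
  rank instead.
* `L` counts only the two compressed streams; header side-information (N,
  run metadata) is excluded.
* The normalization `L*`/the bound equations require `R > 0`, i.e. networks
  that are not extremely sparse or dense (`ln N ≪ ⟨k⟩ ≪ N − ln N`).
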