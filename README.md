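# gmeb — groundwater microbial ecological baseline toolkit

Pristine groundwater (sampled from newly constructed monitoring wells,
before any human disturbance can reach the aquifer) hosts bacterial
communities with reproducible biogeographic structure: a unimodal
latitudinal diversity gradient, distance decay of community similarity,
diversity declining with well depth, a dominant generalist phylum holding
about half of all reads, and assembly governed mostly by deterministic,
niche-based processes. That baseline state can serve as a reference against
which anthropogenically impacted groundwater (e.g. reconstructed wells) is
judged. `gmeb` implements the full analysis chain for such surveys, for
microbial ecologists working with sample x OTU amplicon count tables:

* **Data model & I/O** — count table / 7-rank taxonomy / well metadata /
  Newick tree bundled into a validated `CommunityDataset`; rarefaction
  (multivariate hypergeometric, seeded), rank aggregation, proportions.
* **Diversity & biogeography** — Shannon `H = -Σ p ln p`, Faith's PD (root
  path included), Bray–Curtis `BC = 1 - 2 Σ min(x,y) / (Σx + Σy)`,
  haversine distances, latitudinal-gradient fits (linear + quadratic OLS,
  peak at `-b/2a`), distance–decay slope of `ln S` on `ln d` with a seeded
  Mantel test.
* **Core taxa & biomarkers** — core = occurrence > 50% and mean relative
  abundance > 0.01%; Wilcoxon rank-sum group preference; Kruskal–Wallis
  biomarker screen with BH-FDR.
* **Co-occurrence networks** — genus-level Spearman networks
  (|rho| > 0.6, FDR-adjusted P < 0.001), topology metrics, and keystone
  taxa = jointly high degree, high closeness, low betweenness.
* **Community assembly** — per-sample AIC comparison of six
  rank-abundance models: geometric-series/preemption, broken stick,
  log-normal, Zipf, Zipf–Mandelbrot (Poisson rank likelihood, the
  `vegan::radfit` convention) and the neutral zero-sum multinomial via the
  exact Etienne sampling formula in (θ, m); plus the normalized
  stochasticity ratio (NST, 50% boundary) with a richness-preserving,
  occurrence-proportional null model, and Levins niche breadth
  `B = 1/Σ P²`.
* **GMCI** — the Groundwater Microbial Community Index: an observed/expected
  multimetric index calibrated on a 60/40 split of baseline vs impacted
  samples, with per-indicator alarm O/E ratios, significance-screened
  vetting, accuracy-proportional weights, and an alarm threshold of 1.0.
* **Synthetic surveys** — a generator that reproduces all of the above
  statistical structure (and an "impact" treatment raising diversity and
  shifting composition), so the entire pipeline is testable end to end
  without sequence archives.

## Worked example

The `demo` subcommand simulates a 40-well survey and runs every stage:

```bash
gmeb demo --out demo_results --seed 3
```

prints (abridged):

```json
"diversity": {
  "ddr_slope": -0.1038,
  "ddr_mantel_r": 0.2087,
  "ddr_mantel_p": 0.001,
  "ldg_peak_latitude": 38.53,
  "ldg_adj_r2": 0.5225
},
"core_taxa": {"n_core": 88, "n_rare": 15},
"rad": {"n_samples": 6, "fraction_neutral": 0.0},
"nst": {"mean_nst_percent": 44.54, "verdict": "more_deterministic"},
"gmci": {"n_indicators": 15, "accuracy": 1.0, "error": 0.375}
```

Reading this: community similarity decays with distance (log-log slope
-0.10, Mantel P ≈ 0.001); alpha diversity peaks near 38.5° N; 88 taxa pass
the core filters; none of the six fitted samples is best described by the
neutral ZSM model and the mean NST of the largest water-type group is below
the 50% boundary — deterministic assembly, as expected for the simulated
niche-filtered survey; and the calibrated GMCI flags all impacted holdout
wells (accuracy 1.0) at a 37.5% false-alarm rate on this deliberately small
demo. A manifest with per-stage seeds and output checksums makes the run
bit-for-bit reproducible.

The same stages are available as library functions
(`gmeb.simulate_dataset`, `gmeb.alpha_diversity`, `gmeb.compare_rads`,
`gmeb.nst`, `gmeb.calibrate`, ...) and as individual subcommands
(`simulate`, `diversity`, `core-taxa`, `biomarkers`, `network`, `rad`,
`niche`, `nst`, `gmci`).

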