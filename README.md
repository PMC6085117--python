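# pancmorph

Stochastic branching morphogenesis and clonal lineage-tracing statistics for
the developing pancreas.

During the secondary transition, the embryonic pancreas expands from a
central ductal plexus into a branched arbor. Multicolor (confetti) clonal
tracing shows clones spanning orders of magnitude in size, cohesive along
individual ductal subtrees, and converting progressively to a single color
along the growing ducts. `pancmorph` implements the quantitative machinery
needed to model and analyse such data:

* **Branching-annihilating random walk (BARW) simulator** — equipotent
  ductal termini elongate (step δ), bifurcate stochastically (probability
  p_b per step, half-angle θ), and terminate irreversibly when within an
  annihilation radius r_a of another duct. All lengths are ratios to the
  mean separation of adjacent subtree roots along the central duct, the
  model's single key length scale; simulations start from 40 termini
  launching as side branches of the central duct.
* **Neutral precursor drift** — each terminus carries a pool of N
  self-renewing precursors, segregated ~equally at every bifurcation and
  duplicated back to N. The labeled count k along a lineage is a martingale
  (fixation probability k/N exactly), and the monoclonal-conversion rate
  scales as 1/N, which lets N be inferred from observed conversion profiles.
* **Clone statistics** — uni/bi/tri-potency classification over the acinar,
  ductal and islet compartments; mean-rescaled cumulative size
  distributions; quantile-quantile R² against the identity f(x)=x; exact
  (full-enumeration) and asymptotic Mann-Whitney and Kolmogorov-Smirnov
  tests; chi-square potency comparisons; center-vs-periphery splits.
* **Clonality QC** — distance-resolved same-color pair probability rescaled
  by the any-color pair probability, a 1000-fold bootstrap
  color-reassignment null envelope, and single-linkage merger correction
  for fragmented clones.
* **Synthetic data** — an end-to-end generator of confetti clone tables
  (four colors at RFP-heavy frequencies, <3 % labeling by volume, mixed
  precursor potencies) with ground-truth sidecars, so every stage of the
  pipeline is testable and parameter recovery can be validated.

It is aimed at quantitative/developmental biologists analysing clonal
lineage-tracing or branched-organ morphometry data, and at modellers who
want a tested reference implementation of the BARW + neutral-drift
framework.

## Worked example

```python
from pancmorph import SimParams, simulate, subtree_sizes, ensemble_subtree_distribution

net = simulate(SimParams(seed=17), record_history=True)
sizes = subtree_sizes(net)
dist = ensemble_subtree_distribution(SimParams(seed=17), n_sims=20)
```

Running `python examples/01_branching_simulation.py` prints:

```
one run: 40 subtrees, 3182 branches total
  smallest/median/largest subtree: 1/5/799 branches
  tip front radius grew 0.05 -> 12.57 spacings (traveling pulse at the periphery)
20-run ensemble: mean subtree size 125.6 branches
  tail(3) = 0.110  (fraction of subtrees larger than 3x the ensemble mean; ...)
```

Every terminus follows identical rules, yet subtree sizes span 1–799
branches: early termination of shadowed subtrees plus free expansion of the
survivors generates the heterogeneity, and ~11 % of subtrees end up larger
than three times the mean. The active tips self-organize into a front that
travels outward at constant speed.

`python examples/02_monoclonal_conversion.py` shows the drift side: the
exact fixation law P = k/N, a simulated conversion profile for N = 4 with
one initially labeled precursor, and its recovery by
`infer_precursor_number` (inferred N = 4 from candidates {2, 4, 8, 16});
the median generation to full labeling grows ~linearly with N
(0.5, 2.75, 9.1, 22.3 for N = 2, 4, 8, 16).

The other examples cover the clone-table statistics
(`03_clone_statistics.py`) and the clonality bootstrap + merger correction
(`04_clonality_qc.py`).

A thin CLI wraps the same library:

```bash
pancmorph simulate --n-sims 5 --seed 1 --out runs/
pancmorph synth fixtures --seed 11 --out fixtures/
pancmorph stats potency --clones fixtures/clones.csv --group-by color
pancmorph qc clonality --clones fixtures/clones_fragmented.csv \
    --n-boot 1000 --seed 7 --radius 80 --out qc.json
```

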