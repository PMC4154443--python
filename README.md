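# aiihub

Quantitative connectome analysis of the **AII amacrine cell hub** — the
narrow-field, multistratified glycinergic interneuron that collects rod
bipolar cell signals and redistributes them into ON and OFF cone pathways
through glycinergic synapses and heterocellular gap junctions.

The package is aimed at connectomics researchers working with
disc-annotation databases from serial-section electron microscopy, where
every cell is traced as a stack of per-slice inscribed discs and every
child structure (ribbon and conventional presynapses, postsynaptic
densities, gap junctions, adherens junctions, non-synaptic touches) is
annotated as per-slice discs of its Feret diameter. From such tables it
computes:

- **Structure geometry** — per-junction Feret diameter
  `D = max_slices(2r)`, contact area `A = Σ_slices D_slice · t` (slice
  thickness `t`), normalized inner-plexiform-layer depth (0 = amacrine cell
  layer side, 25 = ganglion cell layer side), compartment assignment
  (neck / lobule / waist / arboreal), depth-stratified contact-area
  profiles, lateral spreads and convex-hull arbor fields.
- **Mosaic statistics** — planar density, tile spacing `1/√density`,
  nearest-neighbor spacing with a boundary guard zone, Voronoi tile
  jitter, coverage factor `C = (arbor/spacing)²`, and the square-grid
  connectivity it predicts (the number of lattice offsets with
  `dx² + dy² < C`; `C = 4` → 8-connected).
- **Network summaries** — per-cell partner tables, a weighted signed
  multigraph (glutamate +, GABA/glycine −, coupling +), class × kind
  contact matrices, hop distances from the AII cohort, and category
  weight ratios.
- **Rule-based connectivity audit** — a declarative table of the AII
  cell's stereotyped compartment-specific contact rules (e.g. *arboreal
  dendrites are always postsynaptic to rod bipolar cells and never make
  gap junctions with them; outputs come only from lobules; every ON cone
  bipolar cell encountered at the arboreal level is coupled; ribbon input
  from ON cone bipolar cells is forbidden except for the CBb7 class*) and
  an auditor that counts proper connections and violations, including
  `required_on_encounter` rules evaluated over tracked touches.
- **Precision statistics** — coefficient-of-variation analysis of cell
  vs synapse sampling, the single-outlier CV argument, pooled-variance
  t-tests from summary statistics, a two-sample Kolmogorov–Smirnov test
  with the small-sample-corrected asymptotic p-value, and 25-nm junction
  size histograms.
- **A synthetic volume generator** — a rule-compliant connectome
  emulating the annotation export of a 0.243-mm retinal field (jittered
  square-lattice AII mosaic at 841 cells/mm², 104 rod bipolar cells,
  ~200 ON and 180 OFF cone bipolar cells, regulated ribbon budgets,
  truncated-normal gap-junction diameters) with a planted-truth ledger
  for parameter-recovery testing.

## Worked example

```python
from aiihub.pipeline import run, paper_check

bundle = run()                # default config, seed 1, ~3 s
print(bundle.summary()["precision"])
print(bundle.summary()["weight_ratios"])
print(paper_check(bundle).to_string(index=False))
```

prints (abridged):

```text
{'cells':   {'n': 39, 'mean': 9.95, 'sd': 2.91, 'cv': 0.293},
 'ribbons': {'n': 39, 'mean': 75.82, 'sd': 2.75, 'cv': 0.036}, 'fold': 8}
{'on_ac_to_rod_ribbon_area': 8.00, 'ac_to_off_bc_lobule_count': 5.85,
 'homo_to_hetero_coupling_area': 7.78, 'th1_to_coupling_area': 0.333}
 id                                  description      value  expected verdict
 t1              AII planar density (cells/mm^2) 841.000000    841.00    pass
 ...
 t8          rule violations on compliant volume   0.000000      0.00    pass
t10      measured AII::AII GJ mean diameter (nm) 265.889901    267.00    pass
```

Reading this: the generated mosaic holds 39 AII cells (841 cells/mm² in
the 0.243-mm field). Each AII contacts ~10 rod bipolar cells with high
variance (CV ≈ 0.29, purely geometric overlap) yet receives a tightly
regulated ~76 ribbons (CV ≈ 0.04) — the cells count synapses, not cells.
ON amacrine input outweighs rod ribbon input ~8-fold by area, homocellular
coupling outweighs heterocellular coupling ~7-fold per cell, and the rule
audit finds zero improper connections among ~6800 classified contacts.

The same pipeline is available from the shell:

```bash
connectome generate --seed 1 --out volume/
connectome validate --db volume/
connectome analyze --db volume/ --out report/
connectome paper-check --seed 1
```

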