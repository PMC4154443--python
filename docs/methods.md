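# Methods

## The annotation model

The package operates on the export schema of a disc-annotation connectome
database. A volume is a stack of `n_sections` serial sections (nominal
thickness 70–90 nm; default 80 nm). Every cell is traced as per-slice
inscribed discs; every child structure — ribbon presynapse, conventional
presynapse, postsynaptic density (PSD), gap junction, adherens junction,
or non-synaptic touch — is a stack of per-slice discs of the structure's
Feret diameter, owned by a parent cell and linked to its partner
structure (presynapse↔PSD, gap junction↔gap junction). On disk this is
five TSV tables (`meta`, `cells`, `structures`, `discs`, `links`) with
deterministic row ordering, so identical databases serialize
byte-identically. XY coordinates are nanometres with the origin at the
field's top-left corner; z is the integer section index.

## Measurement conventions

**Feret diameter.** `D = max over slices of (2 × disc radius)`. One value
per junction (the per-junction maximum), used for all size statistics.

**Contact area.** `A = Σ over slices of (slice diameter × section
thickness)`, converted to μm². This treats the disc stack as a profile
through a roughly planar junction; summing `π r²` per slice would inflate
areas of multi-slice structures. The synthetic generator slices structures
under the same convention, so planted and measured values agree to
floating-point round-off.

**IPL depth.** Normalized linear scale: depth
`= 25 (z − ipl_top_z) / (ipl_bottom_z − ipl_top_z)`; 0 at the amacrine
cell layer border, 25 at the ganglion cell layer border. Values outside
[0, 25] are legal (somas and necks sit above the layer). A contact's
depth is the area-weighted mean depth of its reference structure's discs.

**Compartments.** neck: depth < 0; lobule: [0, 10); waist: [10, 15);
arboreal: ≥ 15. The OFF/ON sublamina border is depth 10 (40% depth). These
thresholds are this package's convention, chosen to reproduce the
stratified zones of the AII cell; they are arguments, not constants.

**Depth profiles.** Contact areas are binned into unit-depth, half-open
bins spanning [−5, 30) so that the profile total equals the category's
summed contact area exactly (conservation is asserted at 1e−9 relative
tolerance in the tests).

**Tile spacing.** `1/√density` (square-measure convention): 841 cells/mm²
gives 34.5 μm, matching the reported ~34 μm; the hexagonal convention
(37 μm) was rejected for that reason.

**Grid connectivity.** With coverage factor `C = (arbor
diameter / spacing)²`, two square-lattice cells at offset (dx, dy) have
strictly overlapping arbors iff `dx² + dy² < C` (tangency excluded).
`C = 4` yields exactly 8 neighbors, the configuration the coverage
argument predicts; alternative readings (circular area ratios) give 4 or
20 and were rejected because only the strict-overlap convention
reproduces the 8-connected prediction.

**Edge effects.** Focal points within one tile spacing of the circular
field boundary are excluded from nearest-neighbor and Voronoi statistics
(guard-zone correction); they still serve as neighbors.

## Statistics

Sample standard deviations use the n−1 convention throughout — under this
convention, and only this one, the outlier solver reproduces the 20-SD
answer for the sixth-cell argument (the population convention gives 22).
The solver scans k = 0, 1, 2, … over the summary-statistics update and
returns the smallest k whose (n+1)-sample CV reaches the target, along
with a bracketing certificate (CV at k and at k−1).

The two-sample t-test is the pooled-variance (homoscedastic) form from
summary statistics with df = n₁ + n₂ − 2.

The two-sample Kolmogorov–Smirnov p-value uses the asymptotic Kolmogorov
distribution with the small-sample correction
`λ = (√ne + 0.12 + 0.11/√ne)·D`, `ne = nm/(n+m)`. This form reproduces
the reference p-values at the sample sizes of interest (e.g. complete
separation of 200 vs 7 gives D = 1, p ≈ 4.7 × 10⁻⁷). Its small-sample
accuracy is characterized exhaustively in the test suite against
permutation enumeration: for n + m ≤ 10 the asymptotic p stays within a
factor of 2.2 of the exact p while the samples overlap (D < 1), but at
complete separation of the very smallest samples it underestimates by up
to a factor of 3.4 (n = m = 2). For tiny samples, prefer the exact
permutation p.

CVs are reported to 2 decimals, percent differences and precision folds
to the nearest integer, each alongside full precision. The largest
homocellular vs heterocellular junctions (745 vs 592 nm reference values)
compute to a 26% diameter and 58% area difference; the module reports the
computed values rather than rounded prose.

## The rule table and auditor

Connectivity rules are declarative records: (focal class, partner class
or group, focal compartment(s), contact kind(s), mode, direction). Modes
are `permitted`, `forbidden`, and `required_on_encounter`. A contact is
matched to its most specific applicable rule (exact partner class >
group > wildcard, plus points for specific compartment and direction;
forbidden wins ties). Connections matching a forbidden rule — or no rule
at all — are violations; `required_on_encounter` rules are additionally
audited over cell pairs that carry at least one touch or specialization
in the rule's compartment, mirroring tracked-touch methodology (an
"encounter" is operationalized as any annotated touch or specialization
between two structures; the audit therefore reports encounter coverage,
not exhaustiveness). Cells of unknown class are excluded with a warning
rather than failed, since real volumes contain unclassified processes.
Contacts not involving the focal class are counted out of scope.

## The synthetic generator

The generator emulates the study conditions, not arbitrary data. Defaults:
0.243-mm circular field; 80-nm sections; AII somas on a jittered square
lattice at 841 cells/mm² (Gaussian jitter, SD 10% of spacing, random
lattice phase) — about 39 cells per field; exact censuses of 104 rod
bipolar cells, 180 OFF cone bipolar cells in six subclasses, 200 ON cone
bipolar cells including 7 CBb7, plus TH1, AI, glycinergic and GABAergic
amacrine cells and two OFF ganglion cells. Each AII gets a scaffold of
cell discs per compartment (soma/neck column; 5–6 lobule stalks reaching
10–17 μm, at most half the tile spacing; a 30-μm waist cone; a 70-μm
arboreal field).

Contacts are drawn from configured distributions and placed only where
the rule table permits:

- **Rod ribbon input** realizes the "cells count synapses, not cells"
  observation: each AII draws a regulated intake target (normal, mean
  75.6, SD 3) and allocates it multinomially over the rod bipolar cells
  whose terminal fields (radius 10–15 μm) overlap its 60-μm rod-input
  field, weighted by proximity — so partner counts vary geometrically
  (CV ≈ 0.3) while ribbon totals stay tight (CV ≈ 0.04). Rod bipolar
  cells short of their own budget (normal, mean 31, SD 3.9, ≥ 1) direct
  the remainder onto AI amacrine cells as dyad partners; cells whose
  geometric allocation exceeds the budget keep the excess, so the
  realized per-rod-BC mean sits slightly above 31.
- **Coupling**: exactly 525 homocellular junctions over all AII pairs
  with arboreal overlap (< 70 μm apart; every pair couples) and exactly
  172 heterocellular junctions, CBb7 first (2–7 each, with 1–3 ribbons
  onto a subset of their coupling partners so every arboreal encounter is
  coupled), the rest over nearby non-CBb7 ON cone bipolar cells.
  Diameters are truncated normals — homocellular (267, 95), heterocellular
  (238, 95), truncated to [50, 800] nm, the simplest family matching the
  reference mean/SD whose bounds span the reference maxima and the 25-nm
  bin floor.
- **Lobule traffic**: 2–5 OFF-bipolar ribbon inputs, 15–25 GABAergic
  inputs, 8–16 outputs to OFF bipolar cells and 6–12 to amacrine cells
  per AII; an OFF alpha (and delta) ganglion cell dendrite encounters
  lobules of ~12 AII cells, every encountered lobule making a synapse
  (touch + synapse pairs).
- **Declined connections**: touches with no specialization — arboreal
  AII/ganglion-cell touches, rod-bipolar axons passing lobules,
  lobule–lobule AII appositions, AI processes at lobules — plus AII–AI
  adherens junctions at the arboreal level.
- **Calibrated inputs**: ON-amacrine synapse diameters are rescaled
  (two-pass, through the slicing rule) so the planted ON-AC : rod-ribbon
  area ratio is exactly the configured 8; TH1 neck synapses are rescaled
  so TH1 area is 1/3 of the per-cell coupling area.

**Per-cell coupling convention.** A homocellular junction sits on two AII
membranes, so per-cell coupling weight counts it twice; a heterocellular
junction counts once. Under this convention the configured counts and
diameter distributions imply a homocellular : heterocellular area ratio
of ≈ 7.4 (`synthetic.expected_coupling_ratio` computes it by quadrature
over the truncated diameter distributions), which is what recovery tests
compare against; the volume-total convention would give ≈ 3.7.

Seeding: one master seed (default 1) feeds a single `numpy` Generator
consumed in fixed order, so a config + seed determines the exported
volume byte-for-byte. The planted ledger records every contact's cells,
kind, category, diameter, realized area and depth, plus the mosaic truth
and per-cell ribbon budgets; it is the ground truth the analysis pipeline
must recover and is what the recovery tests assert against (within 2
standard errors for means, 10% for ratios).

**What the generator does not emulate**: real arbor morphology (discs are
scaffolds, not traced processes), annotation noise and truncation at
volume margins, unclassified orphan processes, z-registration error, and
any dependence of junction size on location. Passing tests therefore
demonstrate that the measurement and audit machinery is correct and
self-consistent under the study conditions — not that a real volume would
yield these exact numbers.

## Problem sizes and determinism

The default volume holds ~550 cells, ~14,000 child structures and ~6,900
classified contacts; generation plus full analysis takes a few seconds.
Tests run the default volume once (shared fixture), use a smaller census
for end-to-end CLI tests, and keep brute-force oracle suites at 1000
random instances for geometry and ~250 enumerated configurations for the
KS oracle. Property tests (hypothesis) are derandomized. All Monte-Carlo
tolerances are stated in the tests as 2-standard-error or 10% bands
around config-implied expectations, fixed before measurement.

## Known limitations

- The rule table covers the cell classes named in the analysis; the
  class list and rules are user-extensible (JSON), and the shipped
  enumeration is not the full partner inventory of a real volume.
- The auditor treats the focal class as AII; auditing other hub
  candidates requires a new rule table.
- Voronoi jitter of a Gaussian-jittered lattice underestimates the
  planted offset SD (tile centroids co-move with their points); the
  generator exposes jitter as a free parameter rather than asserting it
  reproduces a particular nearest-neighbor spread.
- The corrected-asymptotic KS p-value is inaccurate for tiny samples at
  complete separation (see above).
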