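# Methods

## Scope and model

`memins` post-processes trajectories of a small molecule (the four clinical
anthracyclines DOX, EPI, IDA, DAU are the motivating case) released in the
water phase above a phosphatidylcholine bilayer, and reduces them to four
families of observables:

1. **Insertion kinetics.** The insertion event of replicate *r* is the first
   persistent crossing of the drug center of mass below the membrane
   surface; its time is the first-passage time W_r. The association
   constant is

       K_in = A · L_z / ⟨W⟩

   with A the lateral membrane area (Å²), L_z the thickness of the water
   layer the solute diffuses through (Å), and ⟨W⟩ the mean first-passage
   time. A·L_z is a volume; multiplying by N_A/10²⁷ = 6.02214×10⁻⁴ M⁻¹/Å³
   and dividing by ⟨W⟩ in seconds gives K_in in M⁻¹ s⁻¹ (a box of
   4160 Å² × 30 Å with ⟨W⟩ = 20 ns gives 3.76×10⁹ M⁻¹ s⁻¹).

2. **Orientation.** Three molecular axes (amino-sugar, terminal phenyl ring,
   tetracyclic long axis), each defined as head-centroid minus tail-centroid
   of configured atom sets, are reduced to per-frame tilt angles θ against
   the +z bilayer normal. θ within 10° of 0° or 180° is Horizontal, within
   10° of 90° Perpendicular, anything else unclassified. A post-insertion
   window is summarised as H, P, or H/P.

3. **Localisation.** Lipid atoms are binned into choline head / phosphate /
   glycerol-ester / tail regions; a contact is any drug-heavy-atom,
   lipid-heavy-atom pair within a cutoff under lateral minimum-image
   periodicity. Contact totals per bin, over the full run and over an early
   control window, become percentage-occurrence histograms.

4. **Rigidity and electronic metrics.** From optimized structures and IR
   mode tables: point-charge dipole moments (μ = Σqᵢrᵢ, 1 e·Å = 4.80321 D),
   intramolecular H-bond distances, the count of vibrational modes with
   ε > 200 M⁻¹cm⁻¹ in 0–600 cm⁻¹ (few low-frequency active modes = rigid
   molecule), small-integer absorbance ratios, and the Spearman rank
   correlation between rigidity and insertion order.

## Key parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| membrane surface | proximal mean phosphate plane | Å | "reaching the surface" is operationalised as crossing the phosphate plane; configurable |
| persistence | 0.5 | ns | rejects single-frame grazing contacts; the crossing must hold for all frames in [t, t+persistence] |
| L_z | (box_z − thickness)/2 | Å | one-sided water slab: the solute occupies one side of the membrane; the total-slab convention is available by passing `water_slab_total` |
| contact cutoff | 4.0 | Å | conventional heavy-atom contact distance; first-class config parameter |
| H/P half-widths | 10 / 10 | degrees | the horizontal window is ±10°; the perpendicular window mirrors it |
| dominance threshold | 0.7 | — | fraction of classified frames needed for a single-letter H or P label; between 0.3 and 0.7 the label is H/P |
| ε threshold, window | 200, [0, 600] | M⁻¹cm⁻¹, cm⁻¹ | strict `>` on ε, closed frequency window |
| integer-ratio scale cap | 12 | — | smallest scale k ≤ 12 minimising rounding error reproduces both the 6-mode and 12-mode printed ratio styles deterministically |
| per-water volume | 30 | Å³ | standard liquid-water value; converts hydration (waters/lipid) to water-slab thickness |

Censoring: replicates that never insert are censored at the trajectory end
and dropped from ⟨W⟩ (the censored count is always reported, with a warning
above 25% censoring). Averaging only inserting replicates biases ⟨W⟩ low
when censoring is heavy; the `error` policy is available for strict runs.

Degenerate inputs: zero-drift kinetics fall back to the one-sided stable
first-passage law with a censoring warning; zero-diffusion gives the exact
deterministic d/v; zero-contact histograms carry an explicit `empty` flag
rather than NaN percentages; ranking ties break lexicographically so all
orderings are deterministic.

## The synthetic generator

No trajectory data are deposited with the study this package emulates, so
every analysis is validated against a generator with analytic ground truth.
The generator reproduces the study conditions: a 128-lipid POPC or DMPC
bilayer (64 per leaflet; 65/60 Å² per lipid; 37/35 Å phosphate-to-phosphate
thickness; hydration 31/26.6 waters per lipid; 0.1 M KCl with 9/9 and 7/7
ion pairs stored as metadata), the solute released 29 Å above the bilayer
center, and twelve repeats of 100 ns per condition.

The solute's center-of-mass z follows Euler–Maruyama drift–diffusion
(dz = −v dt + √(2D) dW) toward the membrane, reflecting at the far water
boundary and held just below the phosphate plane after first crossing.
Its first-passage time over the release height d is therefore
inverse-Gaussian with mean d/v and shape d²/(2D) — the simplest law with
closed-form moments, enabling parameter-recovery tests of the whole
detect → average → K_in chain. Defaults are v ≈ 1 Å/ns and D = 2 Å²/ns:
the drift is calibrated once so the emulated POPC study reproduces the
~10⁹ M⁻¹s⁻¹ magnitude of the published association constants, and D is an
effective near-interface diffusivity (bulk-water values of 30–50 Å²/ns
describe free solution, not the hindered approach this stage models).

Lipids are represented as five pseudo-atoms per lipid (choline, phosphate,
glycerol/ester, two tail beads) drawn per frame from per-component Gaussian
z-profiles mirrored across the bilayer center, laterally uniform.
Orientation vectors concentrate around a per-axis target angle with spread
1/√κ radians (κ = 0 is isotropic); a telegraph process between two targets
emulates a molecule with no single orientational preference.

What the generator does *not* emulate — and therefore what passing tests do
not show about real membranes: no lipid–lipid correlations or acyl-tail
order parameters, no solute–lipid energetics (the drift coefficient stands
in for the thermodynamic driving force), no explicit water or ions, no
membrane deformation, and pre-insertion orientation is sampled rather than
coupled to the approach dynamics. The package's claims are about the
*analysis* operations: that they recover known ground truth exactly or
within quantified sampling error.

## Statistical behaviour at study scale

With D = 2 Å²/ns and approach speeds near 1 Å/ns, replicate first-passage
times have standard deviations comparable to their means (inverse-Gaussian
with shape/mean ≈ 1–3), so at the study's 12 repeats the standard error of
⟨W⟩ is 15–30%. Between-analogue K_in differences of 10–25% are therefore
*not* resolvable at n = 12 in the synthetic ensemble: rank-order recovery
tests run at n = 100 repeats with clearly separated configured speeds
(1.6/1.3/1.0/0.7 Å/ns). This mirrors the source study's own caveat that an
order-of-magnitude more repeats would be needed for statistical confidence
in the ordering.

Problem sizes used by the shipped checks: the sampler-level recovery uses
10⁴ analytic draws (⟨W⟩ to <1%); the trajectory-level chain uses 100
replicates of 60 ns at 0.1 ns frames; the desk-scale study profile is
3 repeats × 20 ns with `--paper-scale` restoring 12 × 100.

## Numerical choices

- Angles are computed as arccos of the clipped unit-vector z-component;
  the test oracle uses the atan2 form. Histogram bins are half-open with a
  closed last bin so counts conserve frames.
- Contact periodicity is applied in x and y only; the z axis is the
  analysis axis and synthetic boxes are non-periodic in z.
- The persistence window at the trajectory end is truncated: a crossing
  that holds for every *existing* frame in [t, t+persistence] counts even
  if the trajectory ends sooner.
- Dipoles of net-charged species are origin-dependent; the origin is placed
  at the center of nominal mass and a warning is emitted.
- Replicate seeds derive from the base seed as `base + 7919·cell + r`,
  giving independent, reproducible streams per study cell; all outputs are
  byte-identical across repeated fixed-seed runs.
- Integer absorbance ratios divide by the minimum ε, scan scales k = 1..12,
  and keep the smallest k minimising total distance to integers.

## Known limitations

- The atom sets defining the three orientation axes are configuration,
  not shipped defaults: the reference figures are pictorial and name no
  atoms, so any shipped default would be an invention presented as fact.
- The lipid component-to-bin maps for real force-field atom names are
  documented approximations; the generator's pseudo-atom map is exact.
- K_out and the partition coefficient K_mem are out of scope (they require
  exit statistics the insertion-phase model does not produce), as are PMF
  and alchemical free-energy routes.
- The published H-bond distances (2.3/2.2 Å) can only be reproduced from
  the optimized structures they were measured on; the shipped check uses a
  constructed synthetic fragment and the operation accepts any user PDB.
- PDB round-trips truncate coordinates to 10⁻³ Å and do not carry
  orientation vectors; orientation analyses on re-read trajectories need
  atom-set vector definitions instead.
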