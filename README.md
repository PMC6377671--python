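# memins

Trajectory- and property-analysis toolkit for **drug–membrane insertion
studies**: given trajectories of a small molecule (e.g. the anthracyclines
doxorubicin, epirubicin, idarubicin, daunorubicin) approaching a POPC or
DMPC lipid bilayer, it computes

- **insertion kinetics** — per-replicate first-passage times W to the
  membrane surface and the association constant
  **K_in = A·L_z/⟨W⟩** (A: lateral membrane area, L_z: water-layer
  thickness, ⟨W⟩: mean first-passage time), in M⁻¹ s⁻¹, with percent
  differences, rank ordering and between-lipid ratios;
- **orientation preferences** — tilt angles of named molecular axes against
  the bilayer normal, classified Horizontal (θ within 10° of 0°/180°),
  Perpendicular (within 10° of 90°) or mixed H/P over the post-insertion
  window;
- **localisation** — drug–lipid contact histograms over the choline head /
  phosphate / glycerol-ester / tail regions, with an early-window control;
- **rigidity and electronic metrics** — point-charge dipole moments,
  intramolecular H-bond distances, counting of significant IR modes
  (ε > 200 M⁻¹cm⁻¹ in 0–600 cm⁻¹), integer absorbance ratios, and the
  Spearman correlation between molecular rigidity and insertion order.

Because public drug–bilayer MD datasets matching this design are rare, the
package ships a **synthetic trajectory generator** with analytic ground
truth (inverse-Gaussian first-passage kinetics over a 128-lipid bilayer
model) so every analysis stage is testable end to end. It is aimed at
computational chemists post-processing unbiased insertion MD, and at
method developers who need a membrane-insertion analysis pipeline with
known-truth validation.

## Worked example

Comparing published association constants (POPC row: DOX 3.71, EPI 2.75,
IDA 3.09, DAU 3.42 ×10⁹ M⁻¹s⁻¹; DMPC row: 2.00, 1.40, 1.50, 1.88 ×10⁹):

```python
>>> from memins import compute_kin, percent_slower, rank_analogues, lipid_ratio
>>> compute_kin(A=4160.0, L_z=30.0, W_mean=20.0)   # Å², Å, ns -> M⁻¹s⁻¹
3757815360.0
>>> popc = {"DOX": 3.71e9, "EPI": 2.75e9, "IDA": 3.09e9, "DAU": 3.42e9}
>>> dmpc = {"DOX": 2.00e9, "EPI": 1.40e9, "IDA": 1.50e9, "DAU": 1.88e9}
>>> round(percent_slower(popc["DOX"], popc["DAU"]), 1)   # DAU vs DOX, %
7.8
>>> round(percent_slower(popc["DOX"], popc["EPI"]), 1)   # EPI vs DOX, %
25.9
>>> rank_analogues(popc)
['DOX', 'DAU', 'IDA', 'EPI']
>>> _, mean_ratio = lipid_ratio(popc, dmpc)
>>> round(mean_ratio, 3)                                 # DMPC ≈ half of POPC
0.521
```

The first number is the unit-conversion worked example: a 4160 Å² membrane
patch under a 30 Å water layer, entered in 20 ns on average, corresponds to
K_in ≈ 3.76×10⁹ M⁻¹ s⁻¹. The percent differences and ranking say DAU
inserts almost as readily as DOX (7.8% slower), EPI markedly less so
(25.9% slower), with the same DOX > DAU > IDA > EPI order in both lipids
and roughly halved constants in the stiffer, saturated DMPC bilayer.

Run the full synthetic study grid (4 analogues × 2 lipids) from the shell:

```sh
memins run --out demo --seed 1              # desk scale: 3 repeats × 20 ns
memins run --out demo --seed 1 --paper-scale  # 12 repeats × 100 ns
```

which writes `kin_table.csv/.md`, `preference_grid.csv`, per-cell contact
histograms and a `report.json`. Note that at 12 repeats the replicate
scatter of first-passage times is comparable to the between-analogue
differences, so the desk-scale ranking is noisy by design — rank-order
recovery is demonstrated at 100 repeats (see `docs/methods.md`).

Spectrum metrics from a CSV of (frequency, ε) modes:

```sh
$ memins props modes --spectrum dox_modes.csv
6 modes with eps > 200 in [0, 600] cm^-1
```

## Layout

- `src/memins/bilayer.py` — bilayer geometry (area, water slab, phosphate
  planes, component z-profiles)
- `src/memins/synthetic.py` — ground-truth generator (first-passage
  sampler, trajectory simulator, IR tables)
- `src/memins/trajectory.py` — trajectory container, multi-MODEL PDB / XYZ I/O
- `src/memins/insertion_kinetics.py` — insertion detection, ⟨W⟩, K_in,
  table comparisons
- `src/memins/orientation.py` — tilt angles, H/P classification, summaries
- `src/memins/localization.py` — component binning, contact counting,
  percentage histograms
- `src/memins/molecular_properties.py` — dipoles, H-bonds, IR mode metrics,
  rigidity correlation
- `src/memins/study.py`, `src/memins/cli.py` — study orchestration and the
  `memins` command
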