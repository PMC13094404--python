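# pocketmorph

Size-independent morphometrics of ligand-binding pockets in RNA and protein
structures.

Binding pockets on macromolecules differ wildly in size, but much of what
matters for molecular recognition is *shape*. `pocketmorph` represents a
pocket as the 3-D point cloud of the heavy atoms of all residues (or
nucleotides) with at least one heavy atom within 6 Å of any ligand heavy
atom, and summarizes its anisotropy with the gyration tensor

```
T = (1/N) Σᵢ (rᵢ − r̄)(rᵢ − r̄)ᵀ ,    λ₁ ≥ λ₂ ≥ λ₃ ≥ 0
```

through three scale-invariant eigenvalue ratios in [0, 1]:

- `rEV21 = λ₂/λ₁` — global elongation,
- `rEV32 = λ₃/λ₂` — symmetry within the minor plane,
- `rEV31 = λ₃/λ₁ = rEV21·rEV32` — overall anisotropy,

plus two size descriptors: the atom count and the radius of gyration
`Rg = √(λ₁+λ₂+λ₃)`. The global medians of `rEV21` and `rEV32` over a pooled
cohort partition the shape plane into four archetypes — sphere-like,
rod-like, disk-like, and strongly anisotropic — and the package quantifies
how stable that partition is under resampling (stratified bootstrap,
adjusted Rand index) and how two cohorts (typically RNA vs protein pockets)
differ: Welch's *t* tests with Holm correction per descriptor family,
Cohen's *d*, per-archetype MANOVA with Pillai's trace, archetype-frequency
chi-square, and unweighted Euclidean distances in the 3-ratio space.

Audience: structural bioinformaticians comparing binding-site geometry
across macromolecular classes, and anyone who needs reproducible,
size-independent pocket shape descriptors.

## Worked example

```python
import pocketmorph as pm

# a synthetic two-group cohort generated under the benchmark study
# conditions (300 RNA + 300 protein pockets)
cohort = pm.sample_cohort(seed=1)
model = pm.PocketShapeModel.from_dataframe(cohort, group_col="group")
res = model.fit(n_boot=1000, seed=17)
print(res.summary())
```

```
========================================================================
                    Pocket shape archetype analysis
========================================================================
Pockets: 600  (RNA vs protein)
Decision thresholds (global medians): m21 = 0.609, m32 = 0.576
------------------------------------------------------------------------
Archetype frequencies (count / % of group):
  sphere-like            RNA: 55 (18.3%)  protein: 88 (29.3%)  global: 143 (23.8%)
  rod-like               RNA: 82 (27.3%)  protein: 75 (25.0%)  global: 157 (26.2%)
  disk-like              RNA: 89 (29.7%)  protein: 68 (22.7%)  global: 157 (26.2%)
  strongly anisotropic   RNA: 74 (24.7%)  protein: 69 (23.0%)  global: 143 (23.8%)
Frequency chi-square: chi2 = 10.911, df = 3, p = 0.0122
------------------------------------------------------------------------
Descriptor comparison (Welch t, Holm within family, Cohen's d):
  descriptor        t    p(Holm)        d   median
  rEV21        -1.802     0.0721   -0.147    0.609
  rEV32        -3.288    0.00214   -0.268    0.576
  rEV31        -4.068   0.000161   -0.332    0.318
  n_atoms      10.428    6.6e-23    0.851  205.000
  Rg            4.580   5.75e-06    0.374    9.033
------------------------------------------------------------------------
Bootstrap stability (1000 replicates, seed 17): median ARI = 0.923 [0.830, 0.987]
  ARI >= 0.90 in 66.3% of replicates; >= 0.80 in 99.8%; median reclassified fraction = 3.0%
========================================================================
```

Reading the output: the thresholds are the pooled medians anchoring the
archetype partition; the frequency block shows how each group populates the
four shape regimes (here sphere-like pockets are enriched in the protein
group, the chi-square confirms frequencies differ); the descriptor block
shows that the shape-ratio differences are small (|d| < 0.35) while the
atom-count difference is large (d ≈ 0.85) — shape is largely shared, size
is not; and the bootstrap block shows the partition is stable under
resampling (median ARI 0.92, ~3% of pockets reclassified).

Pocket extraction from structure files works on PDB or mmCIF input:

```python
model = pm.preprocess(pm.load_structure("complex.pdb"))    # drop solvent/ions/H/altlocs
cloud = pm.extract_pocket(model, pm.LigandSelector.parse("VIB:A:101"), cutoff=6.0)
desc = pm.shape_descriptors(cloud)
```

or from the shell:

```sh
pocketmorph extract --structure complex.pdb --ligand VIB:A:101 --out pockets/
pocketmorph describe --pockets pockets/ --out descriptors.csv
pocketmorph classify --descriptors descriptors.csv --out assignments.csv
pocketmorph stability --descriptors cohort.csv --replicates 1000 --seed 17 --out stability.json
pocketmorph compare --descriptors cohort.csv --assignments assignments.csv --out report.json
```

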