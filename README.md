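# jawdisp

Two-track mandibular disparity analysis for turtle-like jaws:

1. **Functional track** — six biomechanical measurements per specimen from
   named 3D landmarks plus a mid-ramus cross-section ellipse (anterior,
   posterior, and opening mechanical advantage; standardized second moment
   of inertia; length–width ratio; relative triturating-surface width),
   Z-transformed and ordinated by PCA.
2. **Character track** — discrete character matrices (NEXUS or CSV, with
   missing and polymorphic cells), majority-rule polymorphism resolution,
   nominal Gower dissimilarity with pairwise-complete renormalization, and
   principal coordinate analysis.

Group disparities on either morphospace are compared with bootstrapped
sum-of-variances, two-sided Mann–Whitney tests on the replicate
distributions, and Bonferroni correction; group means are compared with
pooled-SD pairwise t-tests. A synthetic-data generator (lever-calibrated
jaw archetypes, group-structured character matrices, clade-confounded
ecological labels) stands in for scan-derived inputs so the entire
pipeline runs and is testable offline.

## Command line

The `jawdisp` entry point chains five stages through CSV artifacts; every
stage writes a JSON manifest (config, seed, row/column counts) sufficient
to reproduce it byte-for-byte.

```sh
# everything in one go on a synthetic dataset
jawdisp all --out run/ --seed 1 --n-boot 100 --group-scheme clade

# or stage by stage
jawdisp simulate --out run/ --seed 1 --counts generic=20,trionychid=10,pelomedusoid=10,chelid=10
jawdisp measure  --landmarks run/landmarks.csv --out run/
jawdisp ordinate --profiles run/profiles.csv --characters run/characters.nex \
                 --out run/ --polymorphism majority
jawdisp disparity --scores run/pca_scores.csv --groups run/groups.csv \
                  --group-scheme primary_diet --n-boot 100 --seed 1 --out run/
jawdisp report   --run-dir run/
```

Landmark CSV layout: one row per specimen with `specimen_id`,
`<landmark>_{x,y,z}` for each of `jaw_joint`, `coronoid_tip`,
`anterior_tip`, `posterior_tip`, `triturating_posterior`, `width_left`,
`width_right`, `trit_width_left`, `trit_width_right`, plus `cs_a`, `cs_b`
(cross-section ellipse axes) and `unit`.

Lever distances are measured in a configurable sagittal plane
(`--sagittal-axes`, default `xz`); the two width measurements are
transverse and always use full 3D distances.

## Package layout

- `jawdisp.measurements` — landmark/cross-section types, the six
  measurements, lever-proportion jaw-type classifier
- `jawdisp.characters` — character-matrix parsing, polymorphism
  resolution, Gower, PCoA
- `jawdisp.ordination` — Z-transform, PCA, shared `Ordination` container
- `jawdisp.disparity` — sum-of-variances, bootstrap, Mann–Whitney
  (exact enumeration for small tie-free samples), Bonferroni, group
  comparisons, pairwise t-tests, Pearson correlation
- `jawdisp.simulate` — jaw archetypes, character and ecology generators
- `jawdisp.cli` / `jawdisp.io` — orchestration, CSV/NEXUS/manifest glue
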