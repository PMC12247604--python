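# Methods

## The generative model

Every simulated regional time course is a weighted sum of unit-variance
Gaussian latent sources plus independent Gaussian noise:

```
x[s,R,h](t) = α·g_R(t) + β·u[s,R](t) + γ·v[s,h](t) + σ·e[s,R,h](t)
```

* `g_R` — stimulus drive, shared by every subject and both hemispheres.
  Distinct regions share it with a single equicorrelation `ρ_g ∈ [0,1]`,
  realised as `g_R = √ρ_g·c + √(1−ρ_g)·d_R` with independent `c`, `d_R`.
  One knob thus controls how much non-corresponding and intrahemispheric
  pairs inherit from the stimulus.
* `u[s,R]` — homotopic drive: shared by the two hemispheres of one
  subject's region and by nothing else. This is the component that makes
  interhemispheric coupling *idiosyncratic*: it correlates lX with rX
  within a subject but contributes nothing across subjects.
* `v[s,h]` — hemispheric drive: shared by all regions within one
  hemisphere of one subject. It is deliberately network-wide rather than
  pathway-specific — the minimal structure that makes intrahemispheric
  coupling exceed stimulus-driven coupling without introducing
  pair-specific parameters.
* `e` — independent noise, SD `σ`.

Because all sources have unit variance, expected Pearson correlations are
closed-form (`V = α²+β²+γ²+σ²`): within subject, corresponding
interhemispheric `(α²+β²)/V`, intrahemispheric `(α²ρ_g+γ²)/V`,
non-corresponding interhemispheric `α²ρ_g/V`; between subjects,
corresponding `α²/V` and both other classes `α²ρ_g/V`. These closed forms
are what the generator-fidelity tests check sampled correlations against.

Latents are white by default. An optional AR(1) coefficient
(`ar_phi ∈ [0,1)`) smooths every latent with a stationary recursion whose
innovations are scaled by `√(1−φ²)`, keeping the marginal variance at one
so the closed forms above continue to hold at lag zero; BOLD-like temporal
autocorrelation can therefore be added without invalidating the ground
truth. Sampling variability of correlations does increase with `φ` (the
effective number of independent samples drops by roughly
`(1−φ²)/(1+φ²)`), which matters for tolerance choices, not for means.

### Preset regimes

| preset | α | β | γ | σ | ρ_g | expected pattern |
|---|---|---|---|---|---|---|
| `face_scene` | 0.4 | 0.7 | 0.3 | 1.0 | 0.5 | homotopic bias (r: 0.374 vs 0.098 intra), strongly attenuated between subjects (0.092 vs 0.046) |
| `early_visual` | 0.6 | 0.3 | 0.7 | 1.0 | 0.6 | intrahemispheric coupling wins (0.364 vs 0.232) |
| `null` | 0.5 | 0.5 | 0.5 | 1.0 | 1.0 | corresponding-interhemispheric and intrahemispheric expectations coincide exactly; used for false-positive calibration |

The face/scene regime puts more weight on the homotopic than the
hemispheric component (`β² > γ²`), the early-visual regime reverses that
(`γ² > β²`) with a stronger stimulus share, matching the qualitative
contrast between category-selective and retinotopic cortex. The weights
were fixed once so that the headline class correlations fall in the
0.05–0.4 range typical of reported movie-watching connectivity; they are
regime descriptors, not fitted values.

Default simulation scales used throughout the behavioural tests: 20
subjects, 3 000 TRs (two runs of 1 500) for regime patterns over 10
seeded replicates; 500 TRs and 1 000 replicates for the null calibration;
50 000 TRs for checking sampled correlations against closed forms. These
sizes put Monte-Carlo error comfortably below the effects being checked
(`sd(Zr) ≈ 1/√(T−3) ≈ 0.018` at T = 3 000 against class gaps of ~0.25).

### What the simulator does not emulate

No haemodynamic convolution, no voxel level (series are already "ROI
means"), no head motion, physiological noise, scanner drift or
preprocessing artefacts, no inter-subject latency differences, and
stationary weights over time. Passing tests therefore demonstrate that the
*analysis* recovers the structure a correlated-latent world implies — not
that real BOLD satisfies those assumptions.

## ROI definition

Volumetric ROIs are grown from a seed voxel by flood fill with iterative
threshold adjustment. The threshold search is exact rather than numeric:
component size is monotone in the threshold, so the implementation bisects
over the sorted distinct finite map values and returns the seed's
connected component at the **largest threshold whose component reaches the
target size** (default 250 voxels ≙ 2000 mm³ at 2 mm isotropic). The
component is then trimmed to *exactly* the target by repeatedly removing
the lowest-valued boundary voxel — ties broken by lexicographic (x,y,z)
index — whose removal keeps the mask connected (checked by component
labelling on the mask's bounding box). Conventions:

* adjacency defaults to 26-connectivity (corner-touching), with 6 and 18
  available;
* NaN map values are treated as below every threshold and can never join
  a mask (masked-out tissue);
* a seed whose reachable component never reaches the target raises an
  `UnreachableTargetError` rather than returning a short mask;
* seeds are voxel indices; `StatMap.world_to_index` converts scanner-space
  coordinates through the NIfTI affine with nearest-index rounding.

Surface ROIs use the same threshold logic over edge-connected vertices,
with size measured in mm² via barycentric vertex areas (one third of each
incident triangle). Because vertex areas are lumpy, surface masks stop at
**minimal overshoot** of the target (default 380 mm²) instead of trimming
to an exact figure: after the threshold step the lowest-valued removable
member is pared away while the area stays at or above target, so the
returned mask satisfies `area ≥ target` and removing its cheapest
removable vertex would cross below.

Both growers are verified against independent brute-force references: an
incremental union-find sweep over every distinct map value for volumes,
and naive BFS accretion for surfaces.

## Time-course extraction

Percent signal change is computed per voxel per run
(`100·(x−mean)/mean`), voxels are averaged within the ROI afterwards, and
runs are concatenated last. The order matters — PSC-then-average is not
average-then-PSC under heterogeneous voxel means — and is pinned by a
regression test. Per-run normalisation removes inter-run baseline offsets,
so each concatenated segment is mean-zero on its own. Voxels with a zero
temporal mean are unnormalisable; they are dropped with a logged count
(error only if none survive). No detrending, filtering or nuisance
regression is performed here: the package consumes preprocessed series.

## Connectivity and statistics

* Correlations run over the full concatenated series, including run
  boundaries (each run is mean-zero, so boundaries add no step artefact).
* `Zr = atanh(r)`; `|r| = 1` is clipped to `1−1e−7` (logged) when clipping
  is enabled (the default in table building), otherwise an error.
  Zero-variance series yield NaN rows — flagged missing, never silent 0.
* Between-subject values average the `2(S−1)` cross-subject correlations
  per subject and pair **in z-space** (transform, then mean); averaging in
  r-space first is available as a sensitivity option.
* Per-region summaries pool both hemispheres' intrahemispheric pairs
  (lX:lY and rX:rY all enter the average); whether to summarise per
  hemisphere instead is genuinely open, and pooling was chosen as the
  default because the comparisons are per region, not per hemisphere.
* The "highest-correlating intrahemispheric pairing" is selected **once
  per dataset at group level** (highest group-mean `Zr`) and applied to
  every subject, so all subjects are compared against the same pairing;
  per-subject maximisation exists as an option but is upward-biased by
  construction.
* Paired t-tests are two-sided with `df = n−1`;
  `d_avg = mean(a−b)/((sd(a)+sd(b))/2)` uses the average-of-SDs
  denominator so that highly correlated conditions do not inflate the
  effect size. Identical vectors give zero-variance differences and raise
  a degenerate-contrast error rather than returning `t = 0/0`.
* Holm–Bonferroni families are `n_regions × 2` per network and mode
  (face 8, scene 6, early visual 12). The implementation accepts a family
  larger than the p-value list, starting the step-down multipliers at the
  full family size; the same family size is applied to the
  within-vs-between contrast.
* The within-vs-between contrast defaults to a **paired** test on the two
  per-subject difference vectors, because the same subjects appear in both
  analyses; a Welch unequal-variance test is implemented as the
  independent-groups alternative, and the method used is recorded in the
  output and the run log.

### Selection effects in the "highest pairing" comparison

Comparing the homotopic `Zr` against a pairing *selected for being
highest in the same data* is deliberately conservative for the direction
of interest (the bias must beat an upward-selected competitor), but by the
same token the raw two-sided test against it is anticonservative under a
true null — the winner's-curse elevation of the selected pairing shifts
the mean difference away from zero regardless of sample length. The
package therefore treats the Holm-adjusted p-value as the inferential
quantity for this comparison, exactly as every reported test in the
analysis is corrected. The null-calibration suite simulates the matched
null regime 1 000 times and verifies that (a) the bias test as reported
(Holm-corrected) rejects well under the nominal 5% and (b) the
non-selective vs-average comparison is calibrated at its raw nominal
level. The vs-average comparison involves no selection and is the cleaner
statistic when calibration at raw level matters.

## Determinism

One integer seed drives all randomness through `numpy.random.default_rng`;
identical spec + seed reproduces datasets bit-for-bit, and identical
pipeline config + seed reproduces every output file byte-for-byte (JSON
keys sorted, no timestamps). Tie-breaks in ROI growth are lexicographic,
making masks seed-independent given the map.

## Known limitations

* The simulator's ground truth is exact only because the world is linear,
  Gaussian and stationary; real attenuation of between-subject
  correlations also reflects latency and haemodynamic variability the
  model does not contain.
* The equicorrelation stimulus structure gives all within-network region
  pairs the same expected intra correlation, so the "highest" pairing is
  a pure selection among exchangeable competitors; real networks have
  structured pair differences (e.g. a genuinely dominant OFA:FFA route).
* Surface growth assumes a closed, edge-connected triangulation with
  meaningful areas; degenerate (zero-area) triangles are not repaired.
* Statistical maps are consumed, not estimated: no GLM, registration or
  atlas handling is included.
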