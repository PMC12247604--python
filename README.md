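# hemibias

Within- vs. between-subject analysis of **homotopic (interhemispheric)
functional connectivity** in category-selective and early visual cortical
networks, with a latent-component simulator of BOLD-like regional time
courses that provides exact ground truth for every comparison the analysis
makes.

## The scientific question

During naturalistic viewing, the time course of a functional region (say,
the left occipital face area, lOFA) is typically more strongly correlated
with its **corresponding region in the opposite hemisphere** (rOFA) than
with any *other* region in its own hemisphere (e.g. lFFA) — even the most
strongly coupled one. Is that homotopic bias a property of the shared
stimulus drive, or is it **idiosyncratic to each individual**? The analysis
answers this by comparing

* **within-subject** connectivity — Pearson correlation of one subject's
  two regional time courses, Fisher-transformed (`Zr = atanh r`), against
* **between-subject** connectivity — subject *i*'s region A correlated with
  every *other* subject's region B (and the reverse pairing), each
  transformed and averaged into one `Zr` per subject and pair. Only
  stimulus-locked signal survives this cross-subject correlation.

Every unordered pair of the `2·n` bilateral network nodes is classed as
*interhemispheric corresponding* (lX:rX), *interhemispheric
non-corresponding* (lX:rY), or *intrahemispheric* (lX:lY / rX:rY). Per
region, paired-sample t-tests compare the homotopic `Zr` with (1) the
average and (2) the highest-correlating intrahemispheric pairing, with
Holm–Bonferroni correction sized `n_regions × 2` per network (face: 8,
scene: 6, early visual: 12) and the paired effect size
`d_avg = mean(a−b) / ((sd(a)+sd(b))/2)`. A final contrast asks whether the
within-subject bias exceeds the between-subject bias — the signature of a
subject-specific homotopic coupling.

## The generative model behind the simulator

Each regional series mixes four unit-variance latent sources,

```
x[s,R,h](t) = α·g_R(t) + β·u[s,R](t) + γ·v[s,h](t) + σ·e(t)
```

with `g_R` the stimulus drive shared by all subjects (equicorrelation
`ρ_g` across regions), `u[s,R]` a subject-specific homotopic drive shared
by the two hemispheres of one subject's region, `v[s,h]` a
subject-specific hemispheric drive shared within one hemisphere, and `e`
independent noise. Expected correlations are closed-form; with
`V = α²+β²+γ²+σ²`:

| pairing class | expected r |
|---|---|
| inter corresponding (within) | `(α²+β²)/V` |
| intra (within) | `(α²ρ_g+γ²)/V` |
| inter non-corresponding (within) | `α²ρ_g/V` |
| inter corresponding (between) | `α²/V` |
| intra / non-corresponding (between) | `α²ρ_g/V` |

Named presets reproduce the qualitative regimes: `face`/`scene`
(`β² > γ²`: homotopic bias, attenuated between subjects), `early_visual`
(`γ² > β²`: intrahemispheric coupling wins), and `null` (`β = γ`,
`ρ_g = 1`: the bias statistic has zero expectation).

The package also implements the ROI-definition stage the real analysis
uses: seed-based **flood-fill growth with iterative thresholding** on
volumetric statistical maps (to exactly 250 voxels ≙ 2000 mm³) and on
triangulated surface meshes (to ≥ 380 mm² with minimal overshoot), plus
percent-signal-change normalisation, ROI averaging and run concatenation
for time-course extraction.

## Worked example

```python
from hemibias import HomotopicBiasModel

model = HomotopicBiasModel.from_preset("face", n_subjects=20,
                                       run_lengths=[1500, 1500], seed=7)
res = model.fit()
print(res.summary())
```

prints (abridged):

```
Network: face   regions: OFA, FFA, pSTS, AMG
Subjects: 20   TRs: 3000 (runs: [1500, 1500])
Holm family size: 8 (4 regions x 2 comparison types)

Within-subject paired tests (interhemispheric - intrahemispheric):
region    comparison  n  mean_diff      t  df     p  p_adj  d_avg  direction
   OFA vs_intra_high 20      0.292 40.481  19 0.000  0.000 14.780          1
   ...

Between-subject paired tests (interhemispheric - intrahemispheric):
   OFA vs_intra_high 20      0.045 33.732  19 0.000  0.000  9.410          1
   ...

Within-vs-between contrast (inter - intra_high differences):
   OFA within_vs_between paired 20      0.247 32.722  19 0.000 12.900   1  0.000
```

Reading it: within subjects the homotopic pair (lOFA:rOFA) out-correlates
even the best intrahemispheric pairing by ~0.29 `Zr`; between subjects the
same comparison shrinks to ~0.05, and the contrast (`t ≈ 33`, Holm-adjusted
`p < .001`) confirms the bias is carried by subject-specific homotopic
signal, not by the shared stimulus. `res.class_means("within")` gives the
group-mean `Zr` per pairing class (here 0.388 / 0.098 / 0.045 for
corresponding / intra / non-corresponding — compare the closed forms
`atanh` of 0.374 / 0.098 / 0.046 for the face preset).

The same analysis runs from the shell:

```bash
hemibias simulate --preset face --subjects 20 --run-lengths 1500,1500 \
    --seed 7 --out data/
hemibias stats --dataset data/ --out results/
hemibias roi-grow --map zstat.nii.gz --seed 20,20,20 --target 250 \
    --connectivity 26 --out mask.nii.gz
```

or from a single YAML config via `hemibias run --config cfg.yaml`, which
writes tidy connectivity tables, a `bias_results.tsv`, a JSON summary and a
log of every analysis setting (identical config + seed ⇒ byte-identical
outputs).

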