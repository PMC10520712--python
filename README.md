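# geoconverge

Tools for studying how the convergence of a healthcare industry with its
partner industries relates to regional public-health performance, using
spatial panel econometrics on balanced region-year panels.

The package implements the full analysis chain used in regional
public-health studies of industry convergence:

1. **Composite health index.** Three provincial indicators — life
   expectancy at birth (positive polarity), perinatal mortality and
   maternal mortality (negative polarity) — are min-max standardized
   within each year, `p_it = (y_it − min_t y) / (max_t y − min_t y)` (and
   reversed for negative indicators), then aggregated as
   `Health_it = Σ_j w_j p_itj` with objective entropy weights
   `w_j ∝ 1 − e_j`, where `e_j` is the normalized Shannon entropy of
   indicator *j*'s cross-observation proportions.

2. **Industry convergence (HICD).** Each industry's development level
   `U ∈ [0,1]` is an entropy-weighted composite of employment,
   fixed-asset investment and output.  For the focal healthcare industry
   H0 and each partner H1–H12, the coupling degree
   `C = 2√(U1U2)/(U1+U2)`, coordination level `T = αU1 + (1−α)U2`, and
   coupling coordination degree `D = √(CT)` score pairwise convergence;
   the 12 pairwise `D` columns are entropy-synthesized into one overall
   healthcare-industry convergence degree (HICD) per region-year.

3. **Spatial diagnostics.** Global Moran's I
   `I = Σ_ij w_ij(x_i−x̄)(x_j−x̄) / (S² Σ_ij w_ij)` per year with
   randomization-assumption z/p inference, and local Moran's I with
   HH/LH/LL/HL quadrant classification, over a binary contiguity matrix.

4. **Spatial panel models.** Maximum-likelihood estimation of FE, SLM,
   SEM and SDM panels with individual/time/two-way fixed effects, e.g.

   `ln Health_it = ρ Σ_j w_ij ln Health_jt + β ln X_it + θ Σ_j w_ij ln X_jt + μ_i + v_t + ε_it`,

   using the orthonormal-transformation likelihood that removes the
   short-panel demeaning bias, plus LR and Hausman specification tests,
   and direct / indirect (spillover) / total effect decomposition
   `S_r(W) = (I − ρW)⁻¹(Iβ_r + Wθ_r)` with Monte-Carlo inference.

Because provincial yearbook data are not redistributable, the package
ships a first-class synthetic-data module: a 30-region × 18-year rook
lattice whose outcomes follow a spatial Durbin process with known
parameters, health indicators inside published provincial ranges, and
industry tables whose derived convergence degrees span roughly 0.1–0.65.
Every stage is validated against independent brute-force oracles and
closed forms.

## Worked example

```python
import geoconverge as gc

report = gc.run_study(gc.StudyConfig(seed=1))
print(report.model_comparison.loc[["hicd", "rho"], "SDM"])
print(report.effects_national.loc["hicd", ["direct", "indirect", "total"]].round(3))
```

prints (estimate with t-value in parentheses)

```
parameter
hicd    0.7759 (7.02)
rho      0.3235 (6.96)
direct      0.770
indirect   -0.070
total       0.700
```

The SDM coefficient on the log convergence degree (`hicd`) and the
spatial parameter `rho` are both within sampling error of the generating
values (0.58 and 0.24): the direct effect of convergence on regional
health is positive and significant, while the spillover (indirect)
component is indistinguishable from zero at this seed — the same
qualitative pattern the method is designed to detect.  The report also
carries a Table-4-style descriptive summary, yearly Moran's I, the
SLM/SEM/FE comparison columns, LR and Hausman tests, and per-macro-region
(east/central/west) effect decompositions.

The same pipeline runs from the command line:

```bash
geoconverge run-all --seed 1 --outdir study_output
geoconverge simulate --rows 5 --cols 6 --years 18 --seed 0
geoconverge fit --panel merged.csv --weights W.csv --model SDM \
    --y health --x hicd,age,edu,rgdp,urb,gov
```

User data enter through tidy CSVs (`region, year, ...` health-indicator,
industry and covariate tables plus a two-column adjacency edge list); see
`StudyConfig` for the file-mode fields.

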