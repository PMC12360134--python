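# undulokin

Speed-dependent swimming kinematics for undulatory fishes, built around the
kind of dataset a flow-tank study of a small benthic shark produces:
high-speed orthogonal video digitized into per-frame body midlines
(200 points, dorsal view) and four anatomical landmarks (snout tip,
pectoral-fin insertion, pectoral-fin tip, pelvic-fin insertion) seen in
lateral and dorsal views. The package turns those coordinates into
per-trial kinematic variables, compares them across flow speeds, and ships
a synthetic traveling-wave swimmer so every estimator can be validated
against known ground truth.

## What it computes

Per trial (one complete tail-beat cycle, located by zero crossings of the
mean-centred tail-tip trace):

| variable | definition | units |
|---|---|---|
| TBF | tail beat frequency, 1/T of the cycle | Hz |
| A | peak-to-peak tail-tip lateral excursion | BL |
| c | body-wave speed, 2·π·TBF / \|dφ/du\| from the phase gradient of the TBF-frequency component along the body | BL s⁻¹ |
| λ | body wavelength, c / TBF | BL |
| k_max, MCL | max midline curvature (Savitzky–Golay-smoothed parametric curvature) and its arc-length location | BL⁻¹, – |
| BA | body angle: pitch of the snout → pelvic-insertion line (lateral view), cycle mean | deg |
| AA | 3-D angle of attack of the pectoral-tip → pelvic-insertion chord, cycle mean | deg |
| fin effort | TBF × A, a kinematic proxy for locomotor cost | BL s⁻¹ |
| Re | U·BL/ν (ν = 10⁻⁶ m² s⁻¹) | – |
| St | TBF·A/U = fin effort / speed; propulsion is most efficient for St ≈ 0.2–0.4 | – |

Across speeds: per variable, a Levene + Shapiro–Wilk assumption gate
selects a repeated-measures ANOVA (individuals as blocks, sequential sums
of squares on the unbalanced table) or an aligned-rank-transform ANOVA;
all pairwise speed contrasts get Tukey–Kramer adjustment and a compact
letter display; a PCA on the independent variables reports per-axis
variance and variable contributions.

## Worked example

Simulate the reference cohort design — 5 individuals × 11 speeds
(0.5–6 BL/s) with 4 trials missing for one individual, 51 trials at
1000 fps with 0.002 BL digitizing noise — and run the whole analysis:

```
python analysis/01_simulate_and_extract.py --seed 1
python analysis/02_cross_speed_stats.py
python analysis/03_pca.py
python analysis/04_strouhal_reynolds.py
```

which prints, among other lines:

```
simulated 51 trials (5 individuals x 11 speeds - 4 missing)
           tbf: median recovery error 0.25% (max 1.36%)
per-variable speed effects (df = 10, 36):
               tbf: RM-ANOVA  F =   78.54  p = 2.2e-21  [significant]
        body_angle: RM-ANOVA  F =  162.99  p = 7.12e-27  [significant]
   angle_of_attack: RM-ANOVA  F =    1.02  p = 0.45  [ns]
first two axes carry 64.6% of total variance
St within [0.2, 0.4] at speeds [1.0, 1.25, 1.5, 1.75, 2.0] BL/s
```

Reading this: the estimators recover the generator's ground truth to a
fraction of a percent; the speed ANOVA on the 51-trial unbalanced design
carries 10 and 36 degrees of freedom; tail beat frequency rises and body
angle flattens with speed (and they oppose each other on the PCA's speed
axis), while the angle of attack does not change; and the Strouhal number
sits in the efficient 0.2–0.4 band only at intermediate speeds, 1–2 BL/s.
Tables land in `results/analysis/`.

The same steps are available as a CLI over trial-bundle files
(`undulokin simulate | extract | stats | run | validate`), e.g.
`undulokin run --config run.yaml --out results/`.

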