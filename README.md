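# rcquant

Automatic quantification of rotator cuff (RC) muscle degeneration from
2D sagittal-oblique shoulder CT sections.

Degeneration of the four RC muscles — supraspinatus (SS), subscapularis
(SC), infraspinatus (IS), teres minor (TM) — drives surgical
decision-making in shoulder arthroplasty, but quantitative CT assessment
requires delineating each muscle's *premorbid* boundary: the
cross-section it occupied before atrophy and fatty infiltration, which
is not directly visible in the degenerated image.  `rcquant` implements
the full two-stage pipeline for researchers working on this problem:

1. **Premorbid boundary prediction** — a modified U-Net (one
   convolution + batch norm per level, 4 pooling stages; a 512×512 input
   yields a 32×32×512 bottleneck) predicts each muscle's premorbid mask
   from the CT section, trained per muscle with fivefold
   cross-validation on scale/rotation-augmented data, with raw
   predictions cleaned by largest-connected-component selection and hole
   filling.
2. **Threshold quantification** — inside the premorbid surface S,
   HU > −29 thresholding (islands removed, holes filled) gives the
   residual muscle outline Sa; fat is the surface Si below −29 HU and
   bone the surface So above 166 HU within Sa.  Reported ratios:

       Ra = (S − Sa)/S     atrophy
       Ri = Si/S           fatty infiltration
       Ro = So/S           secondary bone formation
       Rd = Ra + Ri + Ro   overall degeneration   (0 healthy … 1 degenerated)

Multi-rater references are built with the STAPLE
expectation-maximization algorithm; agreement is measured with Dice
coefficients and symmetric Hausdorff distances (mm), and quantification
accuracy with OLS regressions (slope, R²) of predicted against
reference ratios.

Because patient data cannot be distributed, the package ships a phantom
generator that renders CT-like sections (four star-convex muscles around
a bone structure, HU-realistic tissues, exact-pixel-count degeneration,
simulated rater variability) so the entire pipeline is testable end to
end.  See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Run the reduced-scale synthetic study (40 phantom cases at 128×128,
3 simulated raters, STAPLE references, fivefold cross-validation of one
64×64 network per muscle = 20 networks, then quantification and
evaluation; about 10 minutes on one CPU):

```bash
rcquant study --n-cases 40 --seed 1 --out study_out
```

which prints the summary (output of an actual run with seed 1):

```json
{
  "n_cases": 40,
  "n_networks": 20,
  "mean_dice_auto_vs_staple": 0.9382713652148255,
  "mean_dice_auto_vs_truth": 0.9640108796380845,
  "mean_dice_inter_rater": 0.9305416531176479,
  "mean_hausdorff_auto_vs_staple_mm": 1.408757893683579,
  "n_empty_auto_masks": 0,
  "slope_Ra_auto_vs_truth": 0.8717582596811666,
  "r2_Ra_auto_vs_truth": 0.9525691519186605,
  "slope_Ri_auto_vs_truth": 0.9900014904878662,
  "r2_Ri_auto_vs_truth": 0.997468460814646,
  "slope_Ro_auto_vs_truth": 1.0036839598137401,
  "r2_Ro_auto_vs_truth": 0.9992942327435985,
  "slope_Rd_auto_vs_truth": 0.9446615629593813,
  "r2_Rd_auto_vs_truth": 0.9850651336842099
}
```

Reading: cross-validated automatic segmentations overlap the ground
truth at Dice 0.96 and the STAPLE reference at 0.94 — slightly above
the simulated inter-rater agreement (0.93) — and the degeneration
ratios recovered from the automatic masks track the generator's ground
truth with near-unit regression slopes and R² ≥ 0.95.  The atrophy
ratio Ra is the most discretization-sensitive of the four (its fat band
is only 1–2 px wide at this scale), which is why its slope sits a few
points below the others.
`study_out/` holds the config snapshot, per-case quantification,
agreement records, regressions and t tests as CSV/JSON.

Other subcommands (`rcquant simulate|staple|train|predict|quantify|evaluate`)
expose the individual stages; `--help` shows options.  As a library:

```python
from rcquant.phantom import PhantomSpec, generate_phantom
from rcquant.quantify import quantify_degeneration

case = generate_phantom(PhantomSpec(fat_fraction=(0.3, 0, 0, 0), seed=7))
m = quantify_degeneration(case.section, case.premorbid_masks[0])
print(m.ri, m.rd)
# 0.29987608426270135 0.29987608426270135
# round(0.3·S)/S — exact agreement with the generator's bookkeeping
```

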