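# awapipe

Analysis pipeline for studying how internal state (feeding, stress) tunes
olfactory receptor expression and food-seeking behavior in *C. elegans*,
centred on the AWA olfactory neuron. The package reimplements, as tested and
reusable code, the quantitative procedures such a study needs:

* **Differential gene-set selection and chemoreceptor enrichment** — per-gene
  fasted/fed fold change `r = (mean_fasted + c) / (mean_fed + c)`, strict
  `r > 4` / `r < 1/4` selection of regulated gene sets, a one-sided Fisher
  exact test for family overrepresentation, and per-neuron enrichment against
  a binary neuron × gene expression atlas (CeNGEN-like) using the ratio
  statistic `(k/K)/(m/M)` — the fraction of upregulated chemoreceptors a
  neuron expresses divided by the fraction of all chemoreceptors it
  expresses — tested by Bonferroni-corrected chi-squared.
* **Reporter fluorescence scoring** from confocal z-stacks: max-intensity
  projection, soma box ROI, score = mean(top 5% of pixels) − mean(bottom 5%),
  normalized per session to fed wild-type controls.
* **Calcium-trace processing**, both paradigms: freely moving (background
  subtraction, 10-frame moving median, baseline = 5th percentile,
  ΔF/F₀ = (F − F₀)/F₀, peak detection with FWHM durations, 0.5 mm binning of
  signal by distance to the lawn boundary, two-way state × distance ANOVA)
  and microfluidic odor delivery (F₀ = mean over seconds 2–3, percent change
  (F/F₀ − 1)·100, Pre/Stim/Post epoch maxima).
* **Behavioral endpoints**: chemotaxis index (#odor − #control)/#total,
  food-choice index exp/(exp + ctrl), exploration grid coverage (3.5 mm
  squares, exact segment rasterization), centroid speed.
* **Synthetic-data generators** for every input class with planted ground
  truth (fold changes, atlas enrichment, soma amplitude, GCaMP transients and
  lawn-approach trajectories, multinomial assay counts), so each stage has a
  parameter-recovery test that needs no external data.

## Worked example

Run the end-to-end demo, which generates one fixture of every kind and runs
all stages:

```bash
awapipe demo --seed 3 --out demo_out
```

This prints the stage summary (values below are the actual seed-3 output):

```json
{
  "behavior": {
    "chemotaxis_index_mean": 0.6033333333333333,
    "chemotaxis_index_sem": 0.017266966964355614,
    "exploration_squares": 45.0,
    "food_choice_index_mean": 0.7801705641869432,
    "food_choice_index_sem": 0.016141910089189974,
    "mean_speed_mm_s": 2.84581923650806
  },
  "calcium": {
    "anova_state_p": 2.7736157048188826e-11,
    "mean_peak_amp_fasted": 1.5295531893796424,
    "mean_peak_amp_fed": 0.7336529318222229
  },
  "enrichment": {
    "family_fisher_p": 6.576878159049438e-10,
    "family_odds_ratio": 8.0,
    "n_down": 0,
    "n_up": 50,
    "significant_neurons": ["AWA"]
  },
  "reporter": {
    "fasted_over_fed_mean": 4.96377216484776,
    "t_p_adj": 2.0187546611114592e-28
  }
}
```

Reading it: the planted 50 upregulated genes are recovered and the
chemoreceptor family is overrepresented among them (Fisher p ≪ 0.001); only
the planted AWA row of the atlas is Bonferroni-significant; the 5×-brighter
reporter somas read out at ≈5.0 after per-session normalization; fasted
recordings planted with doubled transient amplitudes show larger detected
peaks and a significant feeding-state effect in the distance-binned ANOVA;
and the behavioral indices recover their planted preference parameters
(0.6 and 0.75). `demo_out/` holds the fixture files, per-stage tables, two
figures, and `results.json` with the config hash, seed and version.

Each stage is also exposed as a library module
(`awapipe.enrichment`, `.reporter_quant`, `.calcium`, `.behavior`,
`.synthetic_data`, `.stats`) and as CLI subcommands
(`simulate`, `enrich`, `quantify`, `calcium`, `behavior`).

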