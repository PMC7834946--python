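# pupilload

Measuring cognitive load from task-evoked pupillary responses (TEPRs) to
classify the perceived difficulty of educational-video-game levels.

Pupil diameter dilates with mental effort, which makes pupillometry an
attractive, imperceptible probe of how hard a game level feels — but on a
screen the pupillary light reflex dwarfs the cognitive signal. This package
implements a complete analysis chain around that problem:

- **Luminance-matched baseline images.** An individual's reference pupil
  size is estimated while they fixate a *baseline image*. Instead of a
  white/black slide (which triggers a large light reflex at the transition
  into the game), a representative in-game frame is *grid scrambled*: the
  frame is split into an *n* × *m* grid (*n* columns, *m* rows) and pixels
  are permuted within each cell. This preserves the global **and** local
  mean intensity of the scene exactly while destroying its meaning.
- **Preprocessing.** Binocular 60 Hz eye-tracker traces are merged, cleaned
  with a Hampel filter (window median ± *n*·1.4826·MAD), and short blink
  gaps are linearly interpolated, with per-sample provenance flags.
- **Features.** Per participant and level, four pupillary features against
  the baseline mean *b*:

  | feature | definition |
  |---|---|
  | MPDC | mean(d) − *b* (mean pupil diameter change, px) |
  | PD | max(d) − *b* (peak dilation, px) |
  | LP | time from interval start to the peak (s) |
  | APCPS | mean((d − *b*)/*b*) (average % change in pupil size) |

  and four gamer-telemetry features: TE (total errors), TC (completion
  time, ms), CP (position changes), A (attempts). Each (participant,
  level) register is labelled by its difficulty world (A = easy, B = hard),
  forming the dataset τ = {(Xᵢ, Yᵢ)}.
- **Statistics.** Shapiro–Wilk normality gate; paired Wilcoxon signed-rank
  feature selection (exact enumeration for n ≤ 12, tie-corrected normal
  approximation above) giving selected sets G′ ⊆ G = {TE, TC, CP, A} and
  P′ ⊆ P = {MPDC, PD, LP, APCPS}; one-way within-subject ANOVA with
  Mauchly's sphericity test and Greenhouse–Geisser correction, plus
  Bonferroni post hoc grouping.
- **Classification.** A random forest trained on a small random subset of
  participants (3 of 20) and evaluated on all registers of the rest, so no
  participant leaks across the split; accuracy is compared across the
  feature sets G, G′, P, P′ and G′ ∪ P′.
- **Synthetic cohorts.** No public recordings exist for this design, so a
  calibrated generator simulates participants (tonic diameter, light-reflex
  gain, TEPR gain, skill), pupil traces (steady-state light response +
  gamma-shaped TEPRs + noise, blinks, spikes), screens, and telemetry —
  making the whole pipeline runnable and testable offline.

## Worked example

```python
from pupilload import SimConfig, run_experiment1, run_experiment2

res1 = run_experiment1(SimConfig(seed=1))
print(res1.mpdc.mean().round(2).to_dict())
print(f"F={res1.anova.f:.1f}  eps={res1.anova.epsilon_gg:.2f}")
print([sorted(g) for g in res1.posthoc.groups])
```

prints (baseline-image comparison, 14 simulated participants):

```
{'white': 2.97, 'black': -2.19, 'scramble': 1.24, 'grid_8x6': 0.2,
 'grid_10x10': 0.22, 'grid_20x20': 0.28}
F=139.5  eps=0.51
[['white'], ['black'], ['scramble'], ['grid_10x10', 'grid_20x20', 'grid_8x6']]
```

i.e. the white slide inflates the apparent dilation by ~3 px and the black
slide flips its sign, whole-image scrambling leaves a ~1 px bias, while all
three grid scrambles are statistically indistinguishable from each other
with a residual bias of only ~0.2–0.3 px — the grid filter suppresses the
screen-luminance confound.

```python
res2 = run_experiment2(SimConfig(seed=1), n_seeds=50)
print(res2.selection.g_selected, res2.selection.p_selected)
print(res2.table[["set", "features", "mean_accuracy"]].to_string(index=False))
```

prints (difficulty study, 20 simulated participants × 4 levels):

```
('TE', 'TC') ('MPDC', 'PD')
  set            features  mean_accuracy
    G       TE, TC, CP, A       0.808235
   G'              TE, TC       0.818824
    P MPDC, PD, LP, APCPS       0.863824
   P'            MPDC, PD       0.859412
G'uP'    TE, TC, MPDC, PD       0.891471
```

Wilcoxon selection recovers exactly the informative features (errors,
completion time, mean diameter change, peak dilation), and combining the
selected game and pupillary features classifies level difficulty better
than the game features alone.

The same stages are available as CLI subcommands (`pupilload scramble`,
`preprocess`, `features`, `select-features`, `classify`, `simulate`,
`experiment1`, `experiment2`; see `pupilload --help`).

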