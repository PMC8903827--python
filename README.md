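# gazepolarity

**Does a uniformly white sclera make eye-gaze direction easier to read?**
Comparative experiments address this by asking human and chimpanzee
participants to judge the gaze direction of human and chimpanzee eye
images, while reversing the contrast polarity of the eyeball (turning the
dark-sclera/bright-iris chimpanzee eye into an artificial white-sclera eye
and vice versa) and degrading the stimuli in size and brightness to emulate
distancing and shading. `gazepolarity` implements that entire experimental
pipeline in silico, as a tested, reusable library:

* **`eye_image`** — parametric two-species eye stimuli (iris/sclera/pupil/
  skin colors in CIELAB, elliptical eye opening, 16 px normalized iris,
  6 px gaze shift ≈ 20° eyeball rotation) plus the image operations:
  polarity reversal (L\* → 100 − L\*, chromaticity preserved), the seven
  size/brightness levels L1–L4 (400 → 50 px width, 100 → 25% brightness),
  iris-diameter normalization, 4:1 eye-region cropping, and ROI
  colorimetry (mean CIELAB per region, iris–sclera ΔE = √(ΔL² + Δa² + Δb²)).
* **`schedule`** — constraint-satisfying trial schedules for a 96-trial,
  3-direction keypress task and 48-trial, 3-item visual-search sessions
  (balanced directions/locations/individuals, alternating species blocks,
  no 3-runs, no repeated individuals), the adaptive level staircase
  (+0.5 after two successive sessions above 85%) and the training-stage
  pass rule (>90% once or ≥80% twice, per species).
* **`observer_sim`** — a generative logistic observer,
  p = g + (1 − g − λ)·logistic(η), with crossed random effects and a 1/3
  chance floor, for end-to-end testing and parameter recovery.
* **`glmm`** — binomial mixed models with crossed, uncorrelated random
  effects fitted by Laplace-approximate maximum likelihood, likelihood-
  ratio tests χ² = 2(ℓ_full − ℓ_reduced), interaction pruning,
  Bonferroni-corrected simple effects, Pearson dispersion checks and
  nonparametric bootstrap CIs over participants/sessions.
* **`pipeline`/CLI** — a seeded stimuli → schedule → simulate → analyze
  pipeline with a hash manifest for byte-identical reruns.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Simulate the crossed species × level × polarity keypress experiment for 25
observers and run the pruning analysis:

```python
from gazepolarity import schedule, observer_sim, glmm

plan = schedule.build_study1_exp2(seed=12)
responses = observer_sim.simulate_responses(
    plan, observer_sim.PRESETS["full-threeway"], n_participants=25, seed=34)

spec = glmm.study1_exp2_spec(maximal_slopes=False)
results, needs_simple, final = glmm.prune_and_test(responses, spec, alpha=0.05)
for r in results:
    print(f"{r.term}: chi2 = {r.chi2:.2f}, df = {r.df}, p = {r.p_value:.2g}")
print("simple-effects follow-up needed:", needs_simple)

l4 = responses[responses["level"] == 4.0]
for stratum, r in glmm.simple_effects(
        l4, spec, focal="species",
        within={"polarity": ["normal", "reversed"]}, alpha=0.05 / 2):
    print(f"species effect | polarity={stratum['polarity']}: "
          f"chi2 = {r.chi2:.2f}, p = {r.p_value:.2g}")

for (sp, pol), sub in l4.groupby(["species", "polarity"]):
    ci = glmm.bootstrap_ci(sub, "participant_id", seed=99)
    print(f"{sp:10s} {pol:8s} L4: {ci.estimate:.3f} [{ci.lower:.3f}, {ci.upper:.3f}]")
```

Output:

```
species:level:polarity: chi2 = 7.07, df = 1, p = 0.0079
simple-effects follow-up needed: True
species effect | polarity=normal: chi2 = 35.86, p = 2.1e-09
species effect | polarity=reversed: chi2 = 15.63, p = 7.7e-05
chimpanzee normal   L4: 0.487 [0.423, 0.550]
chimpanzee reversed L4: 0.763 [0.707, 0.817]
human      normal   L4: 0.887 [0.843, 0.923]
human      reversed L4: 0.570 [0.500, 0.640]
```

The three-way interaction is significant, so main-effect testing stops and
simple effects take over. At the hardest level the simulated observers read
gaze far better from the white-sclera eye in *both* guises: the normal
human eye (0.89 vs 0.49 for the chimpanzee eye) and the polarity-reversed
chimpanzee eye (0.76 vs 0.57) — the qualitative signature the generative
preset encodes. Brackets are 95% bootstrap CIs over participants.

The same stages are scriptable from the shell:

```bash
gazepolarity stimuli render --species chimpanzee --polarity reversed --level 4 --out-dir out/
gazepolarity schedule study1-exp1 --seed 7 --out plan.csv
gazepolarity simulate --plan plan.csv --preset full-threeway --n 25 --seed 3 --out responses.csv
gazepolarity analyze --data responses.csv --design study1-exp1 --seed 1 --out analysis/
gazepolarity run --config config.yaml      # full pipeline with manifest
```

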