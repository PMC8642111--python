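# avdegrade

Simulation and analysis toolkit for audiovisual emotion-recognition
experiments with controlled sensory degradation. It reproduces, in code, the
two degradation devices used in aging research on audiovisual emotion
perception — a moderate sensorineural hearing-loss simulator for the audio
track and a gaze-contingent central scotoma for the video track — together
with the behavioral scoring, eye-movement pipeline, and mixed-model
statistics used to analyze such experiments, and synthetic-data generators
that make every stage testable without human data.

## The scientific problem

Older adults recognize emotions from voices and faces less accurately than
young adults, but age, hearing loss, and vision loss are confounded in
natural samples. One experimental solution presents *young, normally
sensing* participants with stimuli degraded to mimic sensory aging:

* **Hearing**: a moderate sloping sensorineural loss (audiogram N3) is
  simulated by (a) widening the auditory filters to 2 equivalent
  rectangular bandwidths (ERB), implemented by imposing 2-ERB-wide temporal
  envelopes onto the signal's fine structure, and (b) loudness recruitment,
  implemented as expansive level mapping in six octave bands so that a
  normal listener's loudness matches impaired categorical-loudness curves.
* **Vision**: progressed macular degeneration is simulated by a soft-edged,
  irregular, roughly semi-circular mask (bounding box 731 × 497 px, about
  17° × 11.5°) locked to the point of gaze, inside which the video is
  low-pass filtered with a Gaussian whose amplitude response falls to ½ at
  0.15 cycles/degree.

Recognition of 12 emotions (2 valence × 2 arousal quadrants × 3) expressed
by 8 actors is then measured in 8 conditions (audio/video × intact/degraded/
absent), scored with the **unbiased hit rate** Hu = correct² / (occurrences
× response uses) = recall × precision, arcsine-square-root transformed, and
modeled with linear mixed models selected by an AIC ladder (accept a more
complex model only if AIC drops by ≥ 2 and the fit converged and is not
singular), followed by type-III Wald tests and corrected post-hoc contrasts.
Eye movements are analyzed in the first 1000 ms of each trial: trials with a
single blink > 300 ms are discarded, saccades larger than the 49.6° screen
diagonal are removed, and fixations are scored against dynamic areas of
interest (eyes, nose, mouth, hands) built from per-frame track points.

## Modules

| Module | Contents |
| --- | --- |
| `avdegrade.hearing_sim` | Gammatone filterbank (1- and 2-ERB), iterative envelope imposition, categorical-loudness recruitment, RMS equalization, threshold measurement, WAV I/O |
| `avdegrade.vision_sim` | Scotoma mask generation (4 flip orientations), blur calibration, gaze-contingent compositing |
| `avdegrade.behavior_metrics` | Balanced-Latin-square schedule (832 trials/participant), confusion tables, unbiased hit rate, arcsine transform |
| `avdegrade.gaze_pipeline` | Trial windowing, blink/saccade exclusion rules, dynamic AOI construction, fixation proportions |
| `avdegrade.stats_models` | lme4-style mixed-model formulas on statsmodels `MixedLM`, AIC ladder, singular-fit detection, type-III Wald, Bonferroni/FDR post-hocs |
| `avdegrade.synthetic_data` | Seeded generators: speech-shaped modulated noise, face/hand track points, gaze event streams, confusion-structured responses |

## Worked example

```python
import numpy as np
from avdegrade import (behavior_metrics as bm, hearing_sim as hs,
                       stats_models as sm, synthetic_data as sd,
                       vision_sim as vs)

cfg = sd.GeneratorConfig(seed=0)

# 1. degrade audio: full hearing-impairment chain on speech-like noise
audio = sd.gen_speech_like_audio(cfg, seed=0)
impaired = hs.simulate_hearing_impairment(audio, hs.HearingSimConfig(n_iter=10))
print(hs.envelope_correlation(impaired, audio))   # 0.829
print(hs.measure_simulated_threshold(8000.0, rate=22050.0))  # 70.0 dB HL

# 2. degrade video: the scotoma mask
mask = vs.build_scotoma_mask(seed=0)
ys, xs = np.nonzero(mask.alpha > 0)
print(xs.max() - xs.min() + 1, ys.max() - ys.min() + 1)  # 731 497

# 3. simulate behavior and analyze it
participants = [f"y{i}" for i in range(8)] + [f"o{i}" for i in range(8)]
ages = {p: ("young" if p.startswith("y") else "older") for p in participants}
schedule = bm.build_schedule(participants, seed=0, age_groups=ages)
responded = sd.gen_responses(cfg, schedule, seed=1)
hu = bm.hu_table(responded, by=("participant", "condition"))
hu["age_group"] = hu["participant"].map(ages)
# mean Hu in the intact audiovisual condition: young 0.561, older 0.341

cell = (hu.groupby(["participant", "age_group", "condition"], observed=True)
          ["hu_asin"].mean().reset_index())
best, trace = sm.aic_ladder(
    ["hu_asin ~ condition + (1|participant)",
     "hu_asin ~ condition + age_group + (1|participant)",
     "hu_asin ~ condition * age_group + (1|participant)"], cell)
print(best.spec.formula)
# hu_asin ~ condition + age_group + (1|participant)
# (interaction rejected: AIC improvement < 2)
print(sm.wald_anova(best))
#                          chi2  df             p
# C(condition, Sum)  421.5       7  5.7e-87
# C(age_group, Sum)   31.7       1  1.8e-08
```

The command-line tools `hearing-sim`, `vision-sim` and `av-synth` wrap the
same functionality for WAV files, PNG frame sequences, and full mock
studies.

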