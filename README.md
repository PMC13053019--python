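# dirfix

Object-based classification of scene-viewing fixations into
**Detections**, **Inspections** and **Returns**, with the downstream
analyses that make the classification useful.

## The problem

Eye-tracking analyses of free viewing usually either pool fixations into
a heatmap (losing all temporal structure) or model full scanpaths
(gaining detail that is hard to interpret and compare). `dirfix`
implements a middle ground: most fixations land on objects, and they do
so in temporally distinct ways. Given per-object pixel masks for a scene
and a fixation sequence, each fixation *i* with hit set *H_i* (objects
within a tolerance margin, default 0.5 dva) is labelled per object
*o ∈ H_i*:

* **D** (Detection): *o ∉ H_j* for all *j < i* — first landing on *o*;
* **I** (Inspection): *o ∈ H_{i−1}* — same object as the previous
  fixation;
* **R** (Return): *o ∈ H_j* for some *j < i−1* and *o ∉ H_{i−1}* —
  revisit after going elsewhere.

Fixations hitting no object are unlabelled. Because of the margin, one
fixation can carry several flags (inspect one object while detecting a
neighbour); per object, every fixation assigns exactly one role, so
#hits = #D + #I + #R with at most one Detection per object.

The package is aimed at visual-neuroscience and eye-tracking researchers
working with annotated scene-viewing data (OSIE-style masks with binary
semantic attributes) or with no annotations at all — a content-agnostic
heuristic approximates the scheme by treating fixations closer than 10%
of the image width as landing on the same pseudo-object.

## What's in the box

| module | contents |
| --- | --- |
| `dirfix.gaze_io` | fixation data model, table IO, onset/duration filtering, dva↔px conversion |
| `dirfix.scene_masks` | mask IO, depth-ordered occlusion resolution, distance-transform hit testing |
| `dirfix.dir_classify` | the D/I/R classifier, the spatial heuristic, scheme agreement |
| `dirfix.fixmaps` | per-class fixation maps, split-half Fisher-z consistency matrix, diagonal bootstrap |
| `dirfix.dynamics` | dwell proportions, 50 ms-binned time courses, pooled-resampling group comparison |
| `dirfix.semantics` | attribute overlap policy, semantic dwell-time tables |
| `dirfix.synth` | seeded generator of scenes and scanpaths with ground-truth labels |
| `dirfix.cli` | `dirfix` command: synth / classify / agreement / consistency / timecourse / compare / semantics |

## Worked example

```python
from dirfix.synth import SynthSceneConfig, SynthGazeConfig, generate_corpus
from dirfix.scene_masks import build_hit_tester
from dirfix.dir_classify import (classify_object_based, classify_agnostic,
                                 HeuristicParams, label_agreement)
from dirfix.dynamics import dwell_proportions

scene_cfg = SynthSceneConfig(n_objects=8, seed=12)
gaze_cfg = SynthGazeConfig(n_observers=2, fixations_per_trial=12,
                           class_mix=(0.4, 0.4, 0.2, 0.0), seed=12)
(scene, trials), = generate_corpus(scene_cfg, gaze_cfg, n_images=1)

tester = build_hit_tester(scene)
trial, intended = trials[0]
labels = classify_object_based(trial, tester, scene.margin_px)
print([''.join(sorted(l.classes)) or '-' for l in labels])
print({k: round(v, 3) for k, v in dwell_proportions(labels, trial).items()})

agnostic = classify_agnostic(trial, HeuristicParams(0.10), scene.geometry)
print(label_agreement(labels, agnostic).match_fraction)
```

prints

```
['D', 'I', 'I', 'D', 'R', 'R', 'R', 'I', 'D', 'I', 'D', 'R']
{'D': 0.258, 'I': 0.321, 'R': 0.421, 'unlabelled': 0.0}
{'D': 1.0, 'I': 1.0, 'R': 1.0}
```

First line: the per-fixation class sequence — this trial opens with a
detection, dwells on the same object twice (inspections), later revisits
previously fixated objects (returns); the labels match the generator's
ground-truth intent exactly because the objects are well separated.
Second line: the share of total fixation time spent in each class.
Third line: on this clean scene the content-agnostic heuristic assigns
the same class to every fixation the object scheme labels.

The same pipeline from a shell:

```sh
dirfix synth --n-images 10 --seed 7 --out fixtures/
dirfix classify --fixations fixtures/fixations.csv --masks fixtures/ --out labels.csv
dirfix consistency --labels labels.csv --boot 10000 --seed 7 --out consistency.json
dirfix timecourse --labels labels.csv --t0 150 --t1 3000 --bin 50 --out timecourse.csv
```

Every output file gets a `.run.json` sidecar recording the resolved
parameters and where each came from (default / config file / flag).

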