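# scalegeom

Reusable pipeline for studying how the geometric structure of musical
scales (evenness, interval-class content) predicts perceptual sensitivity
to out-of-scale notes in melodies. Four stages, each usable on its own:

- **`scalegeom.settheory`** — pitch-class set algebra in generalized
  equal-division tunings (octave 12-EDO, 12-step tritave, or any
  divisions/span): subset and transpositional set-class enumeration,
  normal orders, modes, interval-class vectors, and an evenness score
  (negated SD of the deviation from a perfectly even template, minimized
  over rotations).
- **`scalegeom.stimuli`** — probe melodies by constrained pseudo-random
  walk (single-span range, no immediate repetition, leaps ≤ 6 steps, one
  mode per melody), note-deviant / contour-deviant test melodies,
  counterbalanced session plans, and export to frequency-timeline CSV or
  Standard MIDI Files (octave tuning only; other tunings get timelines).
- **`scalegeom.simulate`** — synthetic 2AFC cohorts: a logistic choice
  model over set-level features with participant random intercepts, lapse
  and no-difference rates, plus injectable exclusion-worthy structure.
- **`scalegeom.analysis`** — exclusions (comprehension ≤ 3; < 15 usable
  responses per condition), the bias statistic
  `(n_note − n_contour) / (n_note + n_contour)`, t-tests / Cohen's d /
  mixed ANOVA, evenness–bias Pearson correlation, and ridge regression of
  per-set mean bias on interval-class counts with permutation-based
  model/coefficient inference.

## CLI

Every command that involves randomness requires `--seed`; reruns with the
same seed are byte-identical, and output directories include a
`manifest.json` with the config and per-stage seeds.

```sh
scalegeom sets enumerate --divisions 12 --cardinality 5 -o sets.csv
scalegeom sets describe 02479
scalegeom stimuli generate --preset exp1 --length 12 --seed 1 -o stim/
scalegeom simulate cohort --preset exp2 --n-participants 500 --seed 1 -o responses.csv
scalegeom analyze bias responses.csv -o bias.csv
scalegeom analyze regression responses.csv --n-perm 10000 --seed 2 -o regression.json
scalegeom pipeline run --preset exp2 --seed 1 -o out/
```

Presets: `exp1` pentatonic vs chromatic (lengths 8/12/16); `exp2` all 66
five-note set classes, six per participant; `exp3` fully diminished 7th
vs whole-tone; `exp4` tritave tuning, pentatonic vs the {0,1,2,4,8}
control.

## Conventions worth knowing

- Evenness uses the population SD and is minimized over rotations
  re-anchored at 0, making it transposition- and mode-invariant; the
  continuous-offset alignment is deliberately not performed.
- In the ridge regression the six interval-class counts of fixed-
  cardinality sets sum to a constant, so the predictors are collinear;
  the penalty (default 1.0) is what identifies the fit. Coefficient CIs
  are `B ± q97.5(|B_perm − mean(B_perm)|)` from the permutation
  distribution, and p-values use the `(r+1)/(n+1)` floor.
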