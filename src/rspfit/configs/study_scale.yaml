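# Full-scale emulation of the study design: ~4600 km^2 landscape, 65 5x5 km
# quadrats, 20,000 availability points, species-level used counts matching
# the field sample sizes (maned wolf 952, anteater 504, armadillo 434
# burrows, puma 80, jaguar 36). Generating models use the published
# final-model structures and coefficients. Several hours of compute; the
# candidate ladders are reconstructions (the original ladders are not
# public).
seed: 1
outdir: runs/study_scale
landscape:
  extent_m: [80000, 57600]
  cell_m: 30
  park_fraction: 0.28
  n_quadrats: 65
survey:
  transects_per_quadrat: 6
  mean_transect_m: 7600
n_available: 20000
covariates: table1
window_mode: area
species:
  - name: armadillo
    n_used: 434
    model:
      form: logistic
      terms: [closedDist, natural, marsh, MainroadDist, natural*MainroadDist]
      beta: [-2.232, 0.514, 0.747, -3.910, -0.729, 1.894]
    candidates:
      - {label: final, form: logistic,
         terms: [closedDist, natural, marsh, MainroadDist, natural*MainroadDist]}
      - {label: no-interaction, form: logistic,
         terms: [closedDist, natural, marsh, MainroadDist]}
      - {label: exp-final, form: exponential,
         terms: [closedDist, natural, marsh, MainroadDist, natural*MainroadDist]}
  - name: anteater
    n_used: 504
    model:
      form: logistic
      terms: [nocrop, roadDist, forest, cerrado, open cerrado, pasture, unknown, nocrop*roadDist]
      beta: [-1.842, -0.931, -0.086, 1.287, 0.779, 1.858, 0.943, 1.883, 0.806]
    candidates:
      - {label: final, form: logistic,
         terms: [nocrop, roadDist, forest, cerrado, open cerrado, pasture, unknown, nocrop*roadDist]}
      - {label: classes-only, form: logistic,
         terms: [forest, cerrado, open cerrado, pasture, unknown]}
  - name: maned_wolf
    n_used: 952
    model:
      form: logistic
      terms: [agDist, (agDist)^2, closed, pasture]
      beta: [2.391, -1.267, 0.122, -2.913, -1.176]
    candidates:
      - {label: final, form: logistic, terms: [agDist, (agDist)^2, closed, pasture]}
      - {label: linear-agDist, form: logistic, terms: [agDist, closed, pasture]}
  - name: jaguar
    n_used: 36
    model: {form: logistic, terms: [closed, natural], beta: [-8.387, 2.670, 7.469]}
    candidates:
      - {label: final, form: logistic, terms: [closed, natural]}
      - {label: natural-only, form: logistic, terms: [natural]}
  - name: puma
    n_used: 80
    model: {form: logistic, terms: [closed, natural], beta: [-4.084, 25.620, 2.508]}
    candidates:
      - {label: final, form: logistic, terms: [closed, natural]}
      - {label: closed-only, form: logistic, terms: [closed]}
summaries:
  schemes: [habitat-class, natural, closed, park-membership]
  sites: used
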