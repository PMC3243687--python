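# Desk-scale end-to-end run: small landscape, two species, ~200 used points
# each. Completes in a few minutes on one CPU.
seed: 1
outdir: runs/quickstart
landscape:
  extent_m: [12000, 12000]
  cell_m: 30
  park_fraction: 0.25
  n_quadrats: 4
  n_rivers: 2
  n_roads: 4
  n_main_roads: 1
  n_springs: 10
survey:
  transects_per_quadrat: 3
  mean_transect_m: 5000
n_available: 2000
covariates: table1
window_mode: area
species:
  - name: closed-selector
    n_used: 200
    model: {form: logistic, terms: [closed, natural], beta: [-2.0, 2.0, 1.0]}
    candidates:
      - {label: closed+natural, form: logistic, terms: [closed, natural]}
      - {label: natural-only, form: logistic, terms: [natural]}
      - {label: exp-closed+natural, form: exponential, terms: [closed, natural]}
  - name: grassland-selector
    n_used: 200
    model: {form: logistic, terms: [grassland, roadDist], beta: [-1.5, 2.0, 0.3]}
    candidates:
      - {label: grassland+roadDist, form: logistic, terms: [grassland, roadDist]}
      - {label: grassland-only, form: logistic, terms: [grassland]}
summaries:
  schemes: [habitat-class, natural, closed, park-membership]
  sites: used
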