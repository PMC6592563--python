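# tissuecorr

Tools for asking *how* cells in a tissue coordinate their gene expression:
through physical contacts (juxtacrine signalling, e.g. gap junctions) or
through diffusing molecules (paracrine signalling).  Developed around
time-lapse reporter imaging of pituitary lactotroph tissue, where prolactin
promoter activity shows space–time correlation over ~100 µm and ~48 h, but
the machinery is generic: any per-cell time series with tracked centroids
will do.

## The idea

Every unordered cell pair gets three numbers:

- **r** — similarity of the two cells' expression histories (Pearson
  correlation of reconstructed signals at zero lag, or probability-weighted
  scores Sc1/Sc2 on inferred step-function transcription profiles),
- **d_E** — Euclidean distance between median centroids, in units of the
  mean cell diameter,
- **d_G** — geodesic distance: the minimal number of cell–cell contacts on a
  path between the pair, estimated by sampling contact networks from the
  tissue's Gamma cell-size distribution (999 samples, per-pair median).

Contact-mediated coupling makes r fall with d_G among pairs at similar d_E;
diffusion-mediated coupling makes r fall with d_E among pairs at equal d_G.
Each trend is fitted by median (quantile) regression — robust to the bounded,
skewed distribution of correlations — and its slope tested one-sided with a
bootstrap standard error.

The package also contains a stochastic tissue model (per-cell three-state
promoter cycles with mRNA birth–death, coupled through neighbours' active
gene copies, simulated exactly with a nonhomogeneous Gillespie algorithm)
and censored exponential / hypoexponential maximum-likelihood estimators
that recover the model's periods from switch profiles.

## Worked example

`examples/04_signalling_tests.py` simulates a 100-cell tissue whose gene
cycles are coupled *only* through contacts (coupling strength δ = 0.5),
converts the mRNA counts into two-channel tracked imaging data, and runs the
full analysis:

```
network_free           slope=-0.0436  p=0.0000  n=4950
juxtacrine_(0.0, 2.5)  slope=-0.0461  p=0.0000  n=1287
paracrine_(2, 3)       slope=-0.0833  p=0.1239  n=664
paracrine_(3, 4)       slope=+0.0344  p=0.7930  n=823
contact                slope=-0.0426  p=0.4060  n=225
```

Reading: correlation falls significantly with distance overall
(`network_free`), and falls with *contact count* among physically close pairs
(`juxtacrine`, p ≈ 0) — the signature of contact-mediated coupling.  Among
pairs at fixed contact count the Euclidean trend is not significant
(`paracrine`), matching how the data were generated.  Single replicates are
noisy (the `contact` subset here has only 225 pairs); the test suite checks
the population-level behaviour over 50 replicate tissues.

The other examples each demonstrate one capability — synthetic tissue and
track generation, dual-channel signal reconstruction, contact-network
distance estimation, the coupling-strength slope experiment, and period
estimation by censored MLE — and print a line on what their numbers mean.

## Layout

- `src/tissuecorr/synthetic.py` — tissue, two-channel track, switch-profile
  and duration generators
- `src/tissuecorr/geometry.py` — centroids, convex-hull size bounds,
  normalised Euclidean distances
- `src/tissuecorr/network.py` — contact-network sampling, median geodesics
- `src/tissuecorr/hdr.py` — dual-sensitivity channel calibration and merging
- `src/tissuecorr/scores.py` — Pearson, Sc1/Sc2, pair table
- `src/tissuecorr/signalling.py` — median regression, bootstrap slope tests,
  juxtacrine/paracrine/contact test battery, pooling
- `src/tissuecorr/simulator.py` — coupled three-state stochastic model,
  exact nonhomogeneous simulation, slope experiments
- `src/tissuecorr/estimation.py` — switch-train preprocessing, censored
  exponential/hypoexponential MLE, transcription-rate estimation
- `src/tissuecorr/pipeline.py` — end-to-end orchestration with provenance-
  stamped outputs

See `docs/methods.md` for the models, assumptions and numerical choices.
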