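# isoniche

Stable-isotope niche analysis of pinniped whiskers: from raw per-segment
δ13C/δ15N series to growth-rate chronologies, isotopic niche ellipses and
overlaps, Polar-Front foraging classification, ontogenetic mixed models and
individual-specialisation indices.

## The problem

Whiskers (vibrissae) are metabolically inert keratin that grows continuously,
so isotope ratios measured in segments cut along a whisker archive an
individual's foraging history: δ13C tracks latitude/habitat (strong gradients
across the Southern Ocean's Polar Front), δ15N tracks trophic position.  For
a colony of Antarctic fur seals (*Arctocephalus gazella*) — or any species
with comparable whisker records — this package answers:

- **How fast did each whisker grow?**  Migratory seals imprint one δ13C
  oscillation per year along the whisker.  A Morlet continuous wavelet
  transform finds the dominant spatial period λ (mm); under the
  annual-migration assumption the growth rate is λ/365.25 mm/day, which
  converts each segment position into an age.
- **How large and how distinct are isotopic niches?**  The standard ellipse
  area of a group's (δ13C, δ15N) cloud, SEA = π·√(det Σ̂), covering
  1 − e^(−1/2) ≈ 40% of the points; its small-sample correction
  SEAc = SEA·(n−1)/(n−2); its Bayesian counterpart SEA_B from a
  normal–inverse-Wishart posterior (mode and 95% credibility interval); and
  ellipse–ellipse overlap proportions computed by polygon clipping.
- **Who forages north of the Polar Front?**  Segments are classified by a
  δ13C threshold = mean prey δ13C at the front + the trophic discrimination
  factor (TDF) of whisker keratin; females split into two foraging groups by
  whole-whisker mean δ13C against the same threshold.
- **How do niches change with age, and how specialised are individuals?**
  Linear mixed models of δ13C/δ15N with group, age and their interaction as
  fixed effects, per-seal random intercepts and age slopes, optional AR(2)
  residual correlation along the whisker, refined by backward-stepwise
  likelihood-ratio deletion; variance components give the individual
  specialisation index WIC/TNW (within-individual variance over total niche
  width: 0 = complete specialists, 1 = fully generalised).

Because no raw colony data are released with the study this design follows,
the package ships a first-class synthetic generator (`isoniche.synthetic`)
that emulates the colony's statistical structure — sex-specific growth
rates, annual δ13C oscillations, ontogenetic trends, two female foraging
groups, suckling δ15N tip peaks, multi-reader tooth ages — so every stage is
testable end to end.

## Worked example

```sh
isoniche simulate --seed 1 --out data
isoniche run --seed 1 --out results --draws 10000 data
```

which logs (abridged):

```
INFO isoniche: ingest: 40 seals, 1658 segments, 20 prey samples
INFO isoniche: stage chronology
INFO isoniche: stage front
...
{
  "front_threshold_d13C": -18.879728385531887,
  "n_female_g1": 14,
  "n_female_g2": 6
}
```

The threshold (−18.88‰ here) is the simulated prey mean plus the default TDF
of 2.06‰; 14 females fall below it (southern foragers, group 1) and 6 above
(northern foragers, group 2).  `results/` then contains `chronology.csv`
(per-segment ages and growth rates), `classification.csv` (per-seal
proportion of segments north of the front), `niche_summary.csv` (per-group
SEA/SEAc/SEA_B with credibility intervals), `overlap.csv`,
`ontogenetic_niche.csv` (male niche by annual age window),
`model_summary.csv`, `specialisation.csv` and a provenance-stamped
`summary.json`.  On this run the male ellipse (SEA ≈ 4.0 ‰²) sits almost
entirely south of the front and overlaps the southern female group's ellipse
by ~5% and the northern group's by ~0%, the δ13C mixed model retains group
and age (slope ≈ −0.29 ‰/yr), and the δ13C specialisation index is ≈ 0.77
(highly generalised individuals).

The same functionality is importable:

```python
from isoniche.synthetic import SimConfig, write_population
from isoniche.pipeline import RunConfig, run_pipeline

write_population("data", SimConfig(seed=1))
summary = run_pipeline(RunConfig(input_dir="data", output_dir="results", seed=1))
```

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic colony from the
given seed and runs the complete pipeline — ageing (modal tooth ages, IAPE),
wavelet chronologies, front classification, ML and Bayesian niche ellipses
with overlaps, ontogenetic male ellipse series, mixed models with backward
selection, beta regression of proportions north, WIC/TNW indices and the
morphometric PCA — then writes the summary JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/isoniche/
  synthetic.py   # colony generator (whiskers, prey, tooth readings, morphometrics)
  chronology.py  # Morlet CWT, significance, reconstruction, age assignment
  niche.py       # SEA / SEAc / SEA_B, overlap geometry, ontogenetic windows
  front.py       # Polar-Front threshold and foraging classification
  stats.py       # mixed models, selection, WIC/TNW, beta regression, PCA
  ageing.py      # modal tooth ages and IAPE
  io.py          # CSV schemas and validation
  pipeline.py    # end-to-end orchestration (RunConfig)
  cli.py         # `isoniche` command
docs/methods.md  # modelling assumptions, defaults, limitations
```
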