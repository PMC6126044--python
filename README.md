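# digesta

Analysis toolkit for semi-continuously fed, thermophilic lignocellulose
digesters: carbohydrate-solubilization accounting and kinetics on the
reactor side, and cross-metagenome genome-bin matching with functional
profiling on the community side. It is written for the overlap of two
audiences — bioprocess engineers quantifying how fast and how completely
a feedstock solubilizes at a given residence time, and microbiome
researchers who need to recognize the *same organism* across bins
assembled independently from many metagenome samples.

## The models

**Solubilization kinetics.** Steady-state solubilization of a
particulate feedstock is modeled as first order in the *accessible*
substrate with a recalcitrant offset:

    r = k (C − C0·f_r)

where `C = C0(1 − FCS)` is the unutilized carbohydrate concentration,
`r = C0·FCS/RT` the volumetric solubilization rate at residence time RT,
`C0` the feed carbohydrate concentration (g monomer equivalent/L), `k` a
first-order rate constant (1/day) and `f_r` the fraction of entering
carbohydrate that is recalcitrant at infinite residence time. Steady
states at several residence times trace a line in the (C, r) plane;
`digesta` fits it by OLS (statsmodels-style `Model.fit() → Results`),
propagates the uncertainty of `f_r = −intercept/(k·C0)` by the delta
method, and predicts `FCS(RT) = (1 − f_r)·kRT/(1 + kRT)`. A
two-pool simulator reproduces the semi-continuous feeding protocol (10
events per RT, one-tenth volume each) that generates such steady states.

**Bin matching.** Two bins from different samples are called the same
organism when at least 70 % of either bin's proteins find a best hit
above 90 % identity in the other (exact local alignment, BLOSUM62,
affine gaps, lossless 8-mer prefilter). Calls are QC-filtered
(contamination ≤ 20 %, completeness ≥ 40 %), the match network is
pruned (bins with fewer than three edges removed iteratively), and
components spanning more than three samples become *organism tracks*
that receive ANI-based taxonomy (> 95 % delimits a species), coverage-
based relative abundance, majority-rule consensus markers, CAZyme
inventories and pathway-completeness calls (complete / > 70 % partial /
incomplete).

Synthetic generators with exact ground truth (reactor time series and
multi-sample bin sets) back every claim with a measurable benchmark.

## Worked example

Fit the rate law to the four steady-state solubilization means of a
thermophilic switchgrass digester (FCS 0.711, 0.654, 0.581, 0.538 at
RT = 20, 10, 5, 3.3 days; C0 = 17.3 g/L):

```python
from digesta import SolubilizationKinetics

model = SolubilizationKinetics.from_fcs(
    rt_days=[20, 10, 5, 3.3],
    fcs=[0.711, 0.654, 0.581, 0.538],
    c0=17.3)
res = model.fit()
print(res.summary())
print(f"predicted FCS at RT=20 d: {res.predict(20):.3f}")
```

```
Recalcitrant-fraction first-order solubilization fit
====================================================
  n points          : 4
  C0 (g/L)          : 17.300
  k (1/day)         : 0.7253 +/- 0.0730
  f_r (fraction)    : 0.2480 +/- 0.0148
  f_r (%)           : 24.8 +/- 1.5
  R-squared         : 0.9801
  FCS limit (RT→∞)  : 0.7520
predicted FCS at RT=20 d: 0.704
```

Read: solubilization proceeds at 0.73/day on the accessible fraction,
about a quarter of the entering carbohydrate is recalcitrant, so even at
infinite residence time only ~75 % would solubilize; at a 20-day RT the
model predicts 70.4 %, consistent with the measured 71.1 ± 2.1 %.

The same fit from the shell, on data the simulator generated (1 %
measurement noise):

```console
$ digesta make-synthetic reactor --rts 20,10,5,3.3 --noise-cv 0.01 \
      --seed 4 --out obs.csv --truth-out truth.json
wrote 4 steady states -> obs.csv
$ digesta fit-kinetics --observations obs.csv --c0 17.271 --out fit.json
Recalcitrant-fraction first-order solubilization fit
====================================================
  n points          : 4
  C0 (g/L)          : 17.271
  k (1/day)         : 0.7130 +/- 0.0328
  f_r (fraction)    : 0.2534 +/- 0.0068
  ...
```

And the community side, end to end on synthetic bins:

```console
$ digesta make-synthetic community --n-genomes 6 --proteins-per-genome 80 \
      --n-samples 4 --seed 1 --out-dir study
$ digesta match-bins --bins-dir study/bins --qc study/qc.tsv --out-dir out
216 pairs, 30 same-organism, 30 after QC, 2 tracks
$ digesta profile-markers --tracks out/tracks.json \
      --annotations study/annotations.tsv --out profiles.tsv
```

Other subcommands: `simulate-reactor`, `run-all` (YAML-configured full
pipeline). `digesta --help` lists everything.

## Layout

```
src/digesta/
  kinetics.py    FCS statistic, rate-law model/results, balances
  binmatch.py    identity engine, same-organism rule, tracks
  markers.py     consensus markers, pathways, CAZyme profiles
  synthetic.py   reactor simulator, community generator (ground truth)
  io.py          FASTA/TSV/YAML/GraphML readers and writers
  pipeline.py    staged end-to-end run with threshold accounting
  cli.py         the `digesta` command
docs/methods.md  modeling choices, assumptions, limitations
```
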