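# paleodiv

Diversity and turnover-rate estimation for specimen-count fossil
occurrence data under flexible time-binning schemes.

## The problem

Whether an interval of the fossil record contains a mass extinction
depends uncomfortably on how the record is cut into time bins: coarse
bins time-average richness and can either smear several small pulses
into one apparent event or hide a sharp event inside a long bin, and
uneven sampling between bins creates richness swings that have nothing
to do with biology.  `paleodiv` is aimed at paleobiologists analysing
a single well-sampled stratigraphic section — a taxon x stratigraphic
unit matrix of specimen counts plus unit ages — who want to test the
robustness of a diversity signal across binning schemes and sampling
corrections.  It implements:

* **Four binning schemes**: original biostratigraphic zones;
  zones redefined by stratigraphically constrained clustering;
  each unit as its own bin; and stochastic assignment of every
  specimen to equal-width absolute-age bins (each specimen is only
  known to lie between its unit's base and top ages, so membership is
  resampled over many replicate datasets).
* **Zone redefinition** (CONISS-style): pairwise faunal distances use
  a corrected Forbes similarity
  `F = a(n + √n) / [a(n + √n) + (3/2)bc]` (a shared taxa, b and c
  unique, n = a+b+c), computed on equal-size subsamples of each unit's
  abundance vector to standardise evenness; clustering merges only
  stratigraphically adjacent clusters, minimising the incremental
  sum-of-squares dispersion.
* **Coverage-standardised richness (SQS)**: coverage per bin is
  Good's `u = 1 − s₁/N` (s₁ single-specimen taxa, N specimens);
  subsampling draws specimens until the summed coverage shares
  `fᵢ = (nᵢ/N)·u` of the taxa seen reach a quorum (0.6–0.9), and the
  richness of the draw is averaged over trials.
* **Gap-filler turnover rates**: with two-timers t2, three-timers t3,
  part-timers p and gap-fillers g counted in a moving four-bin window,
  extinction is `μ = log[(t2 + p) / (t3 + p + g)]` per bin, computed
  under classical rarefaction (fixed occurrence quota per bin) on each
  stochastic replicate and summarised as median ± bootstrap standard
  error of the median; origination is the same estimator on the
  time-reversed record.
* **A synthetic fossil-record generator** (discrete-bin birth-death
  plus lognormal-abundance/Poisson preservation) with full truth
  records, so every estimator is testable against known answers.

## Worked example

The package ships a small synthetic fixture shaped like a real
early-Permian "best section" specimen table (11 units, ~100 taxa,
heavy singleton tail; unit names and ages are decorative placeholders).

```python
from paleodiv import bin_per_unit, summarize, taxic_richness
from paleodiv.diversity import diversity_table
from paleodiv.experiments import fixture_report
from paleodiv.synthetic import load_texas_like_fixture

fx = load_texas_like_fixture()
s = summarize(fx.table)
print(f"{s.n_taxa} taxa, {s.n_units} units, {s.n_specimens} specimens")
# 102 taxa, 11 units, 589 specimens
print(s.n_singleton_specimens, s.n_single_occurrence)
# 22 single-specimen taxa, 74 taxa confined to one unit

print(dict(taxic_richness(bin_per_unit(fx.table))))
# {'Pueblo': 12, 'Moran': 11, 'Putnam': 11, 'Admiral': 12,
#  'Belle Plains': 13, 'Clyde': 13, 'Lueders': 12,
#  'Arroyo': 36, 'Vale': 21, 'Choza': 6, 'San Angelo': 8}
```

Raw richness peaks in the Arroyo-like unit (36 taxa) and collapses to
6 in the Choza-like unit — less than a quarter of the peak, the kind
of drawdown the pipeline is built to interrogate.  Coverage-standardised
richness at quorum 0.6 keeps the same shape (Arroyo 14.5, Choza 3.8),
showing the collapse is not a sampling artefact of this fixture:

```python
div = diversity_table(bin_per_unit(fx.table), quorums=(0.6,), trials=500, seed=0)
print(div[div.reached][["bin", "raw_richness", "goods_u", "sqs_mean"]])
```

Redefining the five zones by constrained clustering moves unit
memberships exactly onto the community blocks the fixture was built
from:

```python
rep = fixture_report(fx, seed=0)
print(rep["recovered_partition"])
# [['Pueblo', 'Moran'], ['Putnam', 'Admiral'],
#  ['Belle Plains', 'Clyde', 'Lueders'],
#  ['Arroyo', 'Vale', 'Choza'], ['San Angelo']]
```

## Command line

The same pipeline is scriptable from a shell; `paleodiv run` executes
the full grid (schemes x levels x quorums, plus rate curves) from one
YAML config and writes tidy CSVs, a Newick dendrogram and a manifest
with every seed:

```sh
paleodiv simulate --seed 4 --n-bins 20 --taxa 200 --pulse-bin 12 --outdir sim
paleodiv summarize sim/occurrences.csv sim/units.csv
paleodiv run --config config.yaml --seed 1
paleodiv plot <outdir>
```

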