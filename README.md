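# clonalpop

Population genomics and demography of a nearly monoclonal, triploid
freshwater crayfish (marbled crayfish, *Procambarus virginalis*). All
animals descend clonally from a single founder, so classical population
genetics (allele frequencies, recombination-based structure) does not
apply: variation consists of a small number of single-nucleotide variants
accumulated by mutation. `clonalpop` implements the full analysis chain
for this setting, for researchers studying clonal or invasive populations:

- **variants** — VCF reading, SNV filtering (depth 20–200, quality ≥ 30,
  reference-covered, reference-homozygous), triploid genotype → dosage
  recoding (0/0/0 → 0 … 1/1/1 → 3), and SNV-sharing partitions
  (per-specimen, shared-by-k, two-group Venn) with gene-context
  annotation;
- **structure** — pairwise dosage distances, neighbor-joining trees
  (exact on additive matrices), PCA, and k-means row aggregation for
  heatmaps;
- **vafloh** — windowed variant-allele-frequency tracks at
  reference-heterozygous sites and a loss-of-heterozygosity scan
  (expected VAF = dosage/3; windows flagged at |obs − exp| > 0.10);
- **markrecapture** — Schnabel closed-population estimate
  N̂ = ΣCₜMₜ/ΣRₜ, saturation regression y = a(1 − e^(−cx)),
  bathymetry-stratified extrapolation, and a 10,000-replicate bootstrap
  SE combining all uncertainty components;
- **growth** — exponential / logistic / strong-Allee growth from a single
  founder and genetic-variability projection
  v(t) = μG·∫N(s)ds (μ = 3.6 × 10⁻⁹ /bp/yr, G ≈ 3.5 Gbp), with the time
  at which simulated variability reaches the current population's level;
- **synthdata** — generators for clonal triploid cohorts (truth + VCF)
  and multi-day mark-recapture surveys, so the whole pipeline is testable
  without any sequencing download.

## Worked example

The `analysis/` scripts run the whole chain on a synthetic cohort
(15 specimens in two geographic groups, 30,000 sites) and a simulated
10-day trap survey:

```bash
python analysis/01_simulate_data.py
python analysis/02_variant_pipeline.py
python analysis/03_population_structure.py
python analysis/06_growth_simulation.py
```

prints, among other things:

```
cohort: 15 specimens, 30000 sites, 14800 VCF records (7500 reference-het sites)
read 14800 sites; 3383 retained after depth [20,200] / quality 30.0 / reference-homozygous filters
Venn of within-group shared sets ['P1', 'P2']: 673 group-1 only, 709 group-2 only, 1164 both
PCA: PC1 explains 86.5% of variance; group label agreement with PC1 sign: 100%
current-population variability: 1.126e+09 (order of magnitude 1e+09)
  exponential  population-history   t* = 3.75 (+/- 0.39 from the 200+/-100 rate spread)
```

Reading: after filtering, each specimen carries ~1,900 SNVs relative to
the clonal reference; sites shared by *all* members of a group but not the
other group recover the group-private mutations exactly; the first
principal component alone separates the two geographic groups. The
current population's genetic variability (mean SNVs per specimen × census
size) sits at the 1e+09 level, and a population growing exponentially at
200 offspring/animal/year from one founder accumulates that much total
variability after ≈ 3.7 years — the quantitative basis for concluding
such populations reach large sizes within very few years.

The same stages are available as a CLI
(`clonalpop simulate|variants|structure|vaf|census|growth|all --seed N
--out DIR`), which writes a JSON run report with every seed and parameter.

See `docs/methods.md` for the models, parameter defaults and the design
decisions behind them.

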