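# metaevol

Comparative metabolomics of lineage-specific divergence: how fast has the
metabolome of each tissue evolved on each branch of the
human–chimpanzee–macaque–mouse species tree, and does the human lineage
show an excess of change in particular tissues?

The package is a tested re-implementation of the full analysis workflow for
peak-intensity tables from multi-species, multi-tissue mass-spectrometry
experiments, aimed at researchers who want to run, audit or calibrate this
kind of analysis:

- **peak QC** — the ordered LC-MS and GC filter criteria, PCA-based outlier
  samples, within-tissue quantile normalization with censored zeros, and
  exclusion of postmortem-delay-affected peaks;
- **divergence statistics** — permutation ANOVA (species, tissue,
  interaction, covariates) with permutation-estimated FDR, per-tissue
  lineage-specific classification (one-vs-rest Welch tests with an
  outgroup-homogeneity condition), composite tissue categories
  (cortex = PFC+V1, brain = PFC+V1+CBC), and the regression of divergence
  proportions on phylogenetic branch lengths with per-tissue
  human:chimpanzee fold excess;
- **functional analysis** — accurate-mass adduct annotation (5 ppm),
  complete-linkage profile clustering with silhouette model selection,
  dual hypergeometric + permutation pathway enrichment,
  environment-effect detection, metabolite–enzyme expression agreement,
  and functional-unit grouping;
- **`synthio`** — a synthetic-data generator that emulates the study design
  (4 species × 5 tissues × 14 individuals, pooled QC samples, postmortem
  and environment-condition macaques, detection-limit censoring) with a
  planted-effect truth ledger, so every stage can be exercised and
  calibrated without any external data.

## The model in brief

For peak $p$ in sample $s$ of species $i$ and tissue $t$, log
concentrations follow

$$\log_2 x_{ps} = \mu_p + \tau_{pt} + \beta_{p,\ell(i),t} + \varepsilon_{ps},$$

where a lineage effect $\beta = \pm\delta$ is present for a fraction
$\min(1,\ r \cdot L_\ell \cdot a_{\ell t})$ of peaks — proportional to the
branch length $L_\ell$ (in million years) with tissue-specific
accelerations $a_{\ell t}$. The pipeline estimates, per tissue category
and lineage, the proportion of peaks with significant lineage-specific
change (t-test at the largest level $\le 0.01$ whose label-permutation FDR
estimate is $\le 5\%$), regresses the 3 nonhuman lineages × 7 tissue
categories = 21 proportions on branch length, and reports each tissue's
human point as observed/predicted excess and human:chimp fold difference.

## Worked example

```python
from metaevol.pipeline import PipelineConfig, run_pipeline
from metaevol.synthio import SimConfig

config = PipelineConfig(
    sim=SimConfig(n_peaks=5000, rate_per_my=0.001,
                  human_accel={"muscle": 8.0, "PFC": 4.0},
                  condition_fractions={}, detection_limit=1000.0),
    n_perm=200, seed=1,
    run_clustering=False, run_expression=False,
)
report = run_pipeline(config)
reg = report["stages"]["regression"]
print(f"slope {reg['slope']:.5f}  r2 {reg['r_squared']:.2f}")
for t in ("muscle", "PFC", "V1", "kidney"):
    print(f"{t:7s} human:chimp fold excess {reg['fold_excess'][t]:.1f}")
```

prints (seed 1):

```
slope 0.00135  r2 0.74
muscle  human:chimp fold excess 6.5
PFC     human:chimp fold excess 5.1
V1      human:chimp fold excess 1.1
kidney  human:chimp fold excess 2.7
```

The simulation planted human accelerations of 8× in muscle and 4× in PFC
relative to the chimpanzee lineage and none elsewhere. The recovered fold
excesses in the accelerated tissues (6.5, 5.1) track the planted ratios,
V1 sits near 1, and the nonhuman proportions scale with branch length
(r² = 0.74 over the 21 regression points). Kidney illustrates the
small-count noise of per-tissue folds at this scale: with a 0.65% planted
rate per non-accelerated lineage and tissue, a handful of calls move the
ratio substantially — the dedicated recovery experiment
(`metaevol.experiments.acceleration_recovery`) averages over seeds for
that reason.

The same pipeline runs from the shell:

```sh
metaevol run --config config.yaml      # full pipeline from YAML
metaevol simulate --n-peaks 2000 --seed 1 --out data/sim
metaevol filter-lc --table data/lc --meta data/sim.samples.tsv --out data/lc_f
metaevol divergence --table data/norm --meta data/sim.samples.tsv --out results/
```

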