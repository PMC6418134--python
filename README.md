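# gcna — seed-anchored co-expression networks for recurrence prognosis

`gcna` implements a gene co-expression network analysis (GCNA) chain for
discovering prognostic genes in multi-cohort breast-cancer expression
studies. Starting from a list of literature-derived *seed* (candidate)
genes, it:

1. **harmonizes** cohorts of log2 expression data onto a reference cohort's
   pooled mean/sd and merges them (probe-to-gene median collapse included);
2. builds **seed-anchored co-expression networks** per phenotype stratum
   (recurrence +/-, node x recurrence): Spearman rho > 0.9, each
   co-expressed gene limited to its single strongest edge, complete-linkage
   clusters on 1 - rho cut at (max height)/1.5, and node annotation (cv
   icon size, diamond/circle/star shapes, red/yellow significance frames,
   up/down direction);
3. **compares** networks between strata (common vs exclusive co-expressed
   genes — the discovery surface for novel genes);
4. **screens** each co-expressed gene with a node-adjusted Cox
   proportional-hazards model, `recurrence ~ gene + node` (coefficient B,
   HR = exp(B), Efron ties), plus per-gene logistic regression for node
   status;
5. collapses the discovered gene block into an **immune index** — the
   standardized first principal component of the gene set — dichotomized at
   the empirical 40th percentile, and fits the continuous (Model 1) and
   discrete (Model 2) prognostic Cox models with predicted relapse-free
   survival curves.

A synthetic multi-cohort generator (`gcna.simulate`) plants exactly this
structure — a latent-factor co-expression block with exact Spearman
calibration, exponential proportional-hazards recurrence, logistic node
status, tuned censoring, cohort location/scale shifts — so the entire chain
is testable end to end with known ground truth. See `docs/methods.md` for
the models and design decisions.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts (four cohorts, 922 cases, 2,000 genes, a six-gene planted block at
Spearman 0.95 with per-gene HR 0.85):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_harmonize_merge.py
python analysis/03_build_networks.py
python analysis/04_survival_screen.py
python analysis/05_immune_index.py
```

Script 02 aligns each cohort's pooled moments to the reference and reports

```
 cohort     stage     mean       sd
cohortA    before 7.800283 1.299660
cohortA     after 6.999660 0.999286
...
merged: 922 samples (920 survival-analyzable, 2 missing recurrence), 2000 genes
```

— the two cases with unknown recurrence stay in the expression matrix but
are excluded listwise from survival fits. Script 03 finds the planted block
in every stratum's network:

```
recurrence-: 8 nodes, 6 edges, co-expressed = ['IGHA1', 'IGHD', 'IGHG1', 'IGHG3', 'IGLC2', 'IGLJ3']
```

Script 04 screens those genes (every one protective and significant after
node adjustment; node ORs ~3 reflect the planted node-block coupling), and
script 05 builds the index and fits the models:

```
score range -3.50..2.82 (mean -1.7e-17, sd 1.00), PC1 explains 96.0%
40th-percentile cutoff -0.247: low n=369, high n=553

Model 1 (continuous):
  immune_index   B=-0.915  HR=0.400  p=4.382e-50**
  node           B=+0.452  HR=1.572  p=0.02646*

Model 2 (discrete):
  high_index     B=-1.252  HR=0.286  p=3.723e-27**
  node           B=+0.066  HR=1.068  p=0.743
```

A higher index (high group) means higher expression of the protective block
and a lower hazard of recurrence; the low group is the reference. With six
tightly correlated genes each carrying HR 0.85, the index aggregates the
block effect, hence the strong HRs. Predicted survival curves per group x
node level are written as a tidy table.

The same chain is available as a CLI (`gcna simulate|harmonize|network|
screen|index|run`) and as a single `run_pipeline(PipelineConfig(...))` call
driven by one YAML config, which writes all tables, GraphML/JSON networks
and a JSON manifest deterministically (identical config + seed gives
byte-identical outputs).

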