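# metaprs

Construction and clinical evaluation of **meta polygenic risk scores**
(meta-PRSs) for complex disease, with type 2 diabetes as the motivating
setting.

A single GWAS rarely yields the most predictive polygenic score for a
heterogeneous disease.  A meta-PRS pools many component scores — built from
GWAS of the disease itself *and* of its risk factors, across ancestries —
into one score: each source's best candidate weight vector is picked by
logistic AUC, the selected component scores are combined with
cross-validated elasticnet logistic regression, and the fitted combination
is collapsed back into a single per-SNP weight table

&nbsp;&nbsp;&nbsp;&nbsp;`w_i = Σ_j (β_j / σ_j) · γ_{i,j}`

(γ the component weights, β the elasticnet coefficients, σ the training-SD
of each component score), deployable like any PGS Catalog scoring file.
The package also implements the clinical-integration question that follows:
does adding the score to a clinical 10-year risk model improve
discrimination (ΔC-index with a right-censored bootstrap), reclassification
(categorical NRI), and guideline-style two-stage screening (number needed
to screen / number needed to treat)?

Everything runs end to end on synthetic cohorts that emulate the relevant
data structure: biallelic dosages with population structure, multi-source
noisy GWAS weights sharing a causal architecture, liability-threshold
prevalent disease, proportional-hazards incident disease with midpoint
onset dating, and a pseudo-clinical risk score.  Real inputs (PGS Catalog
scoring files, dosage matrices/VCF, a cohort phenotype table) are accepted
through the same interfaces but never required.

## Who this is for

Statistical geneticists building or benchmarking combined polygenic scores;
epidemiologists quantifying the incremental clinical value of a PRS over an
established risk score; anyone needing reference implementations of
allele-harmonized PRS scoring, Harrell's C with an infinitesimal-jackknife
SE, censored-bootstrap ΔC, categorical NRI, or NNS/NNT screening arithmetic.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_build_and_evaluate_metaprs.py
python analysis/03_published_screening_arithmetic.py
python analysis/04_simulation_benchmarks.py
```

`01` simulates the demo cohort (2,000 samples, 1,000 variants, 6 GWAS-like
sources) and prints its realized epidemiology:

```
prevalent_fraction            0.075500
incident_fraction             0.053002
realized_genetic_variance     0.342041
target_heritability           0.350000
```

— a 7.6% prevalent fraction against the configured 7.9%, and genetic
liability variance 0.342 against the target heritability 0.35.

`02` tunes, combines, collapses and evaluates on the held-out split,
ending with:

```
Held-out prevalent OR/SD 3.76 (AUC 0.845); incident HR/SD 1.59 (C 0.662);
delta C over clinical +0.1159 (p = 0.0058).
```

so one standard deviation of the collapsed meta-score multiplies prevalent
odds by 3.8 in this (deliberately high-heritability-per-variant) demo
cohort, and adding it to the pseudo-clinical model lifts the incident
C-index by 0.116.

`03` feeds the published integer screening counts through the package's
screening operations and prints:

```
                   quantity   value
                   nns_base 22.1299
                    nns_prs 22.0344
                   nnt_base  5.6375
                    nnt_prs  6.2593
                  delta_nnt  0.6219
                case_up_pct 11.5157
               case_net_pct  8.0217
```

i.e. screening 75,153 of 190,293 participants catches 3,396 of 4,064
incident cases (NNS 22.13); adding the meta-PRS to both screening stages
moves NNS to 22.03 and NNT from 5.64 to 6.26, while 11.52% of cases are
correctly upgraded to high risk (net +8.02%).

The same machinery is scriptable:

```bash
metaprs simulate --config analysis/config.yaml --out sim/
metaprs score --genotypes sim/genotypes.tsv --weights sim/candidate_s0_c3.txt \
              --standardize --out scores.tsv
metaprs run --config analysis/config.yaml
```

## Package layout

| module | contents |
|---|---|
| `metaprs.simulate` | synthetic cohorts: genotypes, candidate weights, phenotypes |
| `metaprs.scoring` | PGS-Catalog scoring files, harmonization, PRS/PC/standardize algebra |
| `metaprs.elasticnet` | penalized logistic coordinate descent with penalty factors |
| `metaprs.combine` | candidate tuning, elasticnet CV, weight collapse |
| `metaprs.metrics` | OR/AUC, Cox HR, Harrell's C + IJ SE, ΔC bootstrap |
| `metaprs.clinical` | 10-year absolute risk, PRS integration, NRI, NNS/NNT |
| `metaprs.pipeline`, `metaprs.cli`, `metaprs.config` | YAML-configured end-to-end runner and CLI |

See `docs/methods.md` for the statistical conventions, generator model and
design choices.

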