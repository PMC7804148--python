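# netmodmut

Identification of significantly mutated, survival-associated gene
subnetworks from somatic copy-number alteration (CNA) data.

Recurrent somatic CNAs rarely concentrate in single genes; they hit groups
of interacting genes. `netmodmut` implements, as a reusable Python library,
a network pipeline for finding such groups and testing whether their
mutation burden predicts patient survival:

1. **Mutation matrix** — per-sample segment calls (5-level states HOMD /
   HETD / NEUT / GAIN / AMP) are quality-filtered (≥ 5 kb, ≥ 10 probes),
   collapsed to loss / neutral / gain and intersected with a gene
   annotation into a samples × genes matrix with entries v_ji ∈ {−1, 0, +1}.
2. **Scores** — per-gene gain and loss frequencies f_ig = n_g/N_s,
   f_il = n_l/N_s; heat f_i = f_ig + f_il; and a gene-pair mutation
   similarity, the cosine of the (gain, loss) frequency vectors, used to
   weight an otherwise unweighted interaction network.
3. **Hot subnetworks** (insulated heat diffusion) — influence matrix
   F = β(I − (1−β)W)⁻¹ over the column-stochastic walk matrix W, exchanged
   heat E = F·diag(h); thresholding E at a permutation-selected δ and
   extracting strongly connected components of ≥ k genes, with per-size
   empirical p-values and FDR estimates from a heat-permutation null.
4. **Cohesive clusters** (overlapping greedy clustering) — groups grown to
   maximize cohesiveness C(P) = w_in / (w_in + w_bound + p·|P|), merged
   when the overlap score ω(X,Y) = |X∩Y|²/(|X||Y|) ≥ 0.8, density-filtered,
   and scored by a one-sided Mann–Whitney U test on member in- vs
   out-weights with Benjamini–Hochberg adjustment.
5. **Two-cohort validation** — modules found independently in a discovery
   and a validation cohort are matched by overlap rate
   |A∩B| / min(|A|, |B|) at a 50% threshold.
6. **Survival** — per-sample mutation score p_j = Σ_i f_i·|v_ji| over a
   module's genes; Kaplan–Meier curves and log-rank tests at the minimum-p
   cut-point; module-level calibration against random same-size gene sets,
   p_perm = (1 + #{permuted p < real p}) / (n_perm + 1); optionally an
   expression risk score RS_j = Σ_i coeff_i·E_ij from Cox
   proportional-hazards coefficients.

A fully seeded synthetic-data generator (`SimConfig`, `make_two_cohorts`)
produces two cohorts of segment calls, an interaction network with a
planted highly-mutated near-clique module, and survival times whose hazard
rises with the planted module's mutation score — so the entire pipeline is
testable end-to-end without any external download.

The package is aimed at cancer-genomics methodologists who want the
pipeline as importable, tested building blocks rather than a monolithic
tool.

## Worked example

Each script in `examples/` exercises one capability on the synthetic
two-cohort experiment. For instance:

```bash
python examples/07_survival_association.py
```

prints (seeded, hence reproducible):

```
mutation scores: median 1.54, max 3.55
min-p cut-point 1.693: 148 high- vs 152 low-score samples, log-rank p = 1.01e-08
permutation-calibrated p = 0.0020 (500 random same-size gene sets)
```

The min-p log-rank p-value (1.01e-08) is optimistically biased by the
cut-point search; the calibrated p = 0.0020 says that only ~0.2% of random
8-gene sets separate survival this well, i.e. the planted module's mutation
pattern is genuinely prognostic. `examples/06_two_cohort_validation.py`
shows the same module recovered independently by both algorithms in both
cohorts (overlap rates 0.96 and 1.00 across cohorts).

The scored mutation matrix itself is built in two lines:

```python
import netmodmut as nm

bundle = nm.make_two_cohorts(nm.SimConfig(seed=11))
matrix = nm.build_matrix(
    nm.filter_segments(bundle.discovery.segments),
    bundle.annotation,
    list(bundle.discovery.states.index),
)
freqs = nm.gene_frequencies(matrix)          # f_gain, f_loss, heat per gene
```

## Layout

```
src/netmodmut/
  cna_matrix.py         segments -> mutation matrix (+ SEG/BED/TSV I/O)
  mutation_scores.py    frequencies, heat, cosine similarity, edge binning
  hot_subnetworks.py    insulated diffusion, delta selection, SCC extraction
  cohesive_clusters.py  greedy growth, overlap merging, density, MWU + BH
  validation.py         overlap rates, cross-cohort matching, overlap matrix
  survival.py           scores, KM, log-rank, min-p cut-point, permutation
                        null, Cox coefficients, expression risk score
  synthetic_data.py     seeded two-cohort generator with a planted module
examples/               one narrative script per capability
docs/methods.md         models, parameters, numerical choices, limitations
```
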