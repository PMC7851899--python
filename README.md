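# dcenet

Differential co-expression **edge** analysis for case/control transcriptomics.

Most differential-expression tools ask whether individual genes change level
between disease and control.  `dcenet` instead asks whether gene *pairs*
change their co-expression: it builds a WGCNA-style weighted network for each
group and calls the edges whose connection strength differs.  This is useful
when two diseases (or two cohorts) are compared through the rewiring of a
shared gene set — for example lncRNA co-expression networks across
neurodegeneration and cancer, where the interesting signal is a systematic
*loss* of connectivity in one disease against a *gain* in the other.

## Method

For each group (disease, control) of one cohort:

1. Compute the pairwise correlation matrix of the expression profiles —
   Spearman by default, appropriate for the modest sample sizes typical of
   microarray case/control cohorts (Pearson optional).
2. Form the soft-threshold adjacency `a_ij = |r_ij|^β` (default β = 6), the
   standard unsigned WGCNA weighting that drives the network toward
   scale-free topology.  A binned log–log R² fit index is provided as a
   diagnostic.

Then, per cohort:

3. Take the signed adjacency difference `Δ_ij = a_ij^disease − a_ij^control`.
   An edge with `|Δ_ij| > τ` (default τ = 0.3, roughly a strong correlation
   in one group versus a mild one in the other) is a **differentially
   correlated edge (DCE)**, signed `+1` for a gain of connectivity in disease
   and `−1` for a loss.
4. Rank **hub genes** by plain degree in the unweighted DCE graph (top 50 by
   default, ties alphabetical).

Across two cohorts:

5. Overlap the DCE sets by gene-symbol pair, classify each shared edge as
   same-sign or opposite-sign, and intersect the hub lists.

A synthetic-data module generates two-group Gaussian-copula expression with
*planted* differential correlations.  Because the data are Gaussian, the
population Spearman correlation of a planted pair is known exactly
(`ρ_s = (6/π)·arcsin(r/2)`), so the ground-truth DCE set at any β and τ is
computable in closed form and every pipeline stage is testable without
external data.

Pre-processing utilities cover probe-to-gene collapse (keep the probe with
the largest |log fold change|, i.e. the largest difference of group means on
the log2 scale) and gene-allowlist filtering (e.g. restricting to lncRNAs).
Normalisation and batch correction are *not* performed here: supply matrices
that are already normalised (fRMA-like) and batch-corrected.

## Worked example

```python
from dcenet import (PlantedNetworkSpec, generate_two_group_expression,
                    correlation_matrix, soft_threshold_adjacency, DceParams,
                    sign_proportion, evaluate_recovery)
from dcenet.differential_edges import dces_from_adjacencies

# 30 genes, 10 planted gain edges (r = 0.9 in disease, 0 in control),
# 64 disease vs 23 control samples
spec = PlantedNetworkSpec(
    n_genes=30,
    planted_edges=tuple((2*k, 2*k+1, 0.9, 0.0) for k in range(10)),
    n_samples_per_group=(64, 23),
    seed=42,
)
ds = generate_two_group_expression(spec)

params = DceParams(cutoff=0.3, beta=6)
adj_d = soft_threshold_adjacency(correlation_matrix(ds.expr_disease), 6, "disease")
adj_c = soft_threshold_adjacency(correlation_matrix(ds.expr_control), 6, "control")
dces = dces_from_adjacencies(adj_d, adj_c, params, "demo")

print("DCEs called:", len(dces))
print(sign_proportion(dces))
print(evaluate_recovery(dces, ds.truth))
print(dces.to_frame().head(3).to_string(index=False))
```

prints

```
DCEs called: 9
{'n_total': 9, 'n_positive': 9, 'n_negative': 0, 'pct_positive': 100.0, 'pct_negative': 0.0, 'empty': False}
{'sensitivity': 0.9, 'false_discoveries': 0, 'sign_accuracy': 1.0, 'empty_truth': False}
node1 node2  adj_disease  adj_control    delta  sign
  G00   G01     0.499657     0.000157 0.499500     1
  G02   G03     0.445144     0.000019 0.445125     1
  G04   G05     0.407237     0.000007 0.407230     1
```

Nine of the ten planted gain edges are recovered with the correct `+1` sign
and no false calls at this sample size; every called edge shows the expected
pattern of a strong disease adjacency (population value ≈ 0.5 at β = 6)
against a near-zero control adjacency.

## Command line

```bash
dcenet simulate --n-genes 30 --n-disease 64 --n-control 23 --out-dir sim/
dcenet dce --expression expr.tsv --annotation samples.tsv --out dce.tsv
dcenet overlap --dce-a pd.tsv --dce-b cc.tsv --out overlap.tsv
dcenet hubs --dce-tsv dce.tsv --top-k 50 --out hubs.tsv --sif network.sif
dcenet run-all --config run.yaml        # both cohorts + cross-cohort overlap
```

`run-all` reads a YAML config naming each cohort's expression/annotation
files (plus optional probe annotation and gene allowlist), runs the full
chain per cohort and writes DCE tables, hub lists, SIF network exports, a
cross-cohort overlap table and a manifest with parameters and input
checksums.  Reruns on unchanged inputs are byte-identical.

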