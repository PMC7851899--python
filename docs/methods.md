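# Methods

## Model and procedure

`dcenet` implements an edge-level differential co-expression procedure for
two-group (disease vs control) expression studies, optionally compared
across two cohorts.

**Per-group networks.** Given a features × samples matrix of log2 expression
values for one group, the pairwise correlation matrix is computed with
Spearman correlation by default (average ranks on ties).  Spearman is the
default because typical case/control cohorts at this scale (tens of disease
samples, around ten to twenty controls) are too small to lean on normality
of the marginals; Pearson is available.  The soft-threshold adjacency is
`a_ij = |r_ij|^β` for `i ≠ j`, with the diagonal defined as 0 so that node
connectivity never counts self-edges and differential calling can never emit
one.

**Differential edges.** For one cohort, `Δ_ij = a_ij^disease − a_ij^control`.
An edge is a differentially correlated edge (DCE) iff `|Δ_ij| > τ` — the
inequality is strict, so a boundary edge with `|Δ| = τ` is excluded and a
zero difference can never be called, making the sign
`s_ij = sign(Δ_ij) ∈ {−1, +1}` total on called edges.  `+1` is a gain of
connectivity in disease, `−1` a loss.

**Cross-cohort overlap.** DCE sets from two cohorts are matched by exact
gene-symbol pair (pairs stored canonically with the lexicographically
smaller symbol first).  Each shared edge is classified same-sign or
opposite-sign; the summary reports the counts and the proportion of
opposite-sign edges (defined as 0 when nothing is shared).

**Hubs.** The DCE graph is unweighted and undirected, one edge per called
DCE with the sign kept as an edge attribute.  Hubs are the top-k nodes by
plain degree (edge count, the "Degree" notion of cytoHubba-style rankings,
not weighted connectivity), ties broken alphabetically; an option includes
all nodes tied with the k-th degree.  The SIF exporter defaults to the
subgraph induced on the hub genes, with a flag for the full DCE graph.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `beta` | 6 | soft-threshold power; applied identically to both groups and both cohorts. Never auto-selected — the scale-free fit index is a diagnostic only. |
| `cutoff` (τ) | 0.3 | threshold on the absolute adjacency difference. At β = 6 it corresponds roughly to \|r\| ≳ 0.82 in one group vs a mild-to-moderate correlation in the other. Unitless, strictly inside (0, 1). |
| `method` | spearman | correlation estimator; spearman or pearson. |
| `top_k` | 50 | hub-list length. |
| minimum group size | 3 | smallest group accepted for correlation; smaller groups are rejected with a clear error. |

## Pre-processing

Input matrices are assumed normalised on the log2 scale and batch-corrected;
fRMA/ComBat-style algorithms are deliberately not reimplemented and no
per-batch centering shortcut is offered.  Two utilities are provided:

- **Probe collapse.** When several probes map to one gene symbol, the probe
  with the largest |LFC| is retained, where LFC is the difference of group
  means on the log2 scale (disease minus control).  Ties are broken by the
  lexicographically smallest probe id for determinism.  The collapse is
  idempotent, and the retained probe's |LFC| dominates every discarded probe
  of its gene.  The collapse step is optional: the pipeline runs at probe or
  gene level, defaulting to gene level when a probe annotation is supplied.
- **Allowlist filter.** Row restriction to a user-supplied symbol set (e.g.
  a lncRNA list), order-preserving, with retained/dropped counts logged.

## Synthetic data generator

The generator draws each group's samples i.i.d. from a multivariate Gaussian
with unit-variance margins (scaled by `noise_sd` and shifted to a baseline
log2 level of 8) and a specified correlation matrix: `background_r`
everywhere (default 0) with selected planted pairs set to per-group Pearson
values.  This is a Gaussian copula with normal margins, so the population
Spearman correlation of a planted pair is `ρ_s = (6/π)·arcsin(r/2)` and the
population adjacency difference at any β is exact; the ground-truth DCE set
is the planted pairs whose population |Δ| exceeds a stated margin (default
equal to the cutoff, 0.3), with the population sign.

Design choices:

- **PSD enforcement.** The block correlation matrix must admit a Cholesky
  factorisation; a non-positive-definite design is rejected with the order
  of the offending leading principal minor, never projected to a nearby PSD
  matrix — repair would silently change the planted truth.
- **`noise_sd` is a pure scale.** It multiplies the whole covariance, so it
  changes the variance of every gene without touching correlations; planted
  truth is unaffected.  Attenuating additive noise was deliberately avoided
  for the same reason.
- **Sample sizes** default to the scale of two-cohort case/control
  microarray studies (16 disease / 9 control), configurable up to larger
  designs (e.g. 64 / 23).
- **Determinism.** All randomness flows from the single integer seed through
  one `numpy` Generator; the same spec is bit-reproducible.

What the generator does *not* emulate: probe-level measurement error, batch
structure, heavy-tailed or skewed expression margins, correlated background
modules, and mean shifts between groups.  Passing recovery tests therefore
demonstrates correctness of the edge statistic and its implementation under
the stated sampling model, not robustness to microarray artefacts.

## Numerical choices

- Correlations are computed by ranking (Spearman) followed by
  `numpy.corrcoef`; tests cross-check every pair against scipy's independent
  per-pair estimators to 1e−10.
- Zero-variance features get correlation 0 (not NaN) with a logged warning,
  keeping all downstream matrices finite.
- Correlation matrices are symmetrised to machine precision and clipped to
  [−1, 1]; adjacency clipped to [0, 1]; diagonals fixed exactly.
- Sign percentages are reported to two decimals, rounding half away from
  zero.
- The scale-free fit index bins positive connectivities into `n_bins`
  (default 10) equal-width bins, drops empty bins, and returns the squared
  Pearson correlation of log10(frequency) on log10(mean connectivity);
  fewer than two non-empty bins is an error ("degenerate degree
  distribution").
- TSV outputs use 6 significant digits; rows are emitted in sorted edge
  order, so reruns on unchanged inputs are byte-identical (verified against
  the manifest's input checksums).

## Validation problem sizes

The test suite and the acceptance script validate the pipeline on synthetic
designs of 30 genes with 10 planted edges (planted Pearson 0.9 vs 0, i.e. a
population adjacency difference of ≈ 0.50 at β = 6) and 100 samples per
group, over 20 seeds; oracle-equivalence checks run 50 random 12-gene
datasets against an independent per-pair brute-force implementation.  These
sizes were chosen to make the statistical behaviour (sensitivity ≥ 0.9,
essentially no false discoveries) stable across seeds while the whole suite
runs in seconds.

## Known limitations

- The statistic uses |r|^β, so it is blind to correlation sign flips that
  preserve magnitude (r = +0.9 → −0.9 has Δ = 0).  Records can carry the
  per-group correlation signs as a diagnostic; the published-style statistic
  itself never uses them.
- The cutoff rule is a fixed effect-size threshold, not a hypothesis test:
  no permutation significance or Fisher-z comparison is computed and no
  multiple-testing correction applies.  DCE counts therefore grow with gene
  number and shrink with sample size in ways a calibrated test would not.
- Hub degree ignores edge weights and the gain/loss sign.
- Cross-cohort matching is exact string equality of gene symbols; symbol
  harmonisation across annotation versions is the user's responsibility.
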