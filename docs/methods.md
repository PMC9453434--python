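# Methods

This note documents the statistical machinery behind `metacov`: the model
assumptions, the numerical conventions, what the synthetic generators do
and do not emulate, and the design choices made where more than one
convention is defensible.

## Metabolic covariance networks

A covariance network treats each participant as one observation of a shared
regional metabolism pattern: the edge between two ROIs is the Pearson
correlation of their mean SUVR **across subjects**, not across time. This
requires at least 3 subjects (enforced), nonzero variance in every ROI
column (violations are reported by ROI name, never patched), and — because
Pearson correlation is affine-invariant — is unaffected by per-ROI scaling
or by subject ordering. Upstream of this, `normalize_suv_to_suvr` expresses
regional SUV relative to each subject's mean pons uptake, making values
comparable across scanners; ingestion rejects missing cells and
non-positive values outright, mirroring a QC policy of discarding bad scans
rather than imputing them.

The self-correlation diagonal is zeroed before clustering so the signed
totals v± carry no self-loop mass, and the matrix is kept dense and signed:
no thresholding, sparsification, partial correlation or covariance
shrinkage (deliberately out of scope).

## Signed modularity

For networks with negative edges the quality of a partition σ is

    M = M⁺ + [v⁻/(v⁺+v⁻)] M⁻,

with M⁺ the Newman-style modularity of the positive part and M⁻ its
negative-part mirror (higher when negative weight falls *between* modules).
Sums run over all ordered node pairs including i = j; at the original level
w_ii = 0, and on aggregated graphs the self-loop terms are module-invariant
so they cancel from every move gain. When one sign is absent its term is
defined to be zero; a network with no edges at all is rejected as
degenerate. Two checked consequences: the single-module partition always
scores exactly 0, and when v⁻ = 0 the function reduces to Newman–Girvan
weighted modularity (verified against networkx to 1e-12 in the tests).

## Louvain and the hierarchy-level convention

The maximiser is the standard two-phase heuristic. Phase 1 starts from
singletons and repeatedly sweeps the nodes in a seeded random order, moving
each node to the module with the greatest gain; gains below 1e-12 count as
zero (prevents floating-point livelock), and among equal-gain targets the
smallest canonical label wins, so the result is a deterministic function of
(network, seed). Phase 2 aggregates modules into super-nodes (positive and
negative weights summed separately, self-loops kept, totals v± unchanged)
and phase 1 repeats, producing a hierarchy of partitions whose modularity
is non-decreasing (asserted sweep by sweep in the tests).

`level="lowest"` (the default) returns the finest partition — the
assignment after the first level converges. This convention is used for
consensus clustering because on benchmark networks the finest Louvain level
tracks planted community structure better than the coarsest.
`level="final"` returns the hierarchy's endpoint, the M-maximising output.

An important and deliberately documented consequence: **the finest level is
not a global M optimiser.** Every partition it returns is single-move
stable (no single node reassignment can improve M — verified by brute
force), but on small unstructured signed networks the global maximum of M
typically *merges* whole blocks of that partition, which no sequence of
single-node moves from singletons can reach. Exhaustive enumeration on
8-node networks shows consensus clustering attains the global maximum in
only about half of dense random draws — while on networks with genuine
modular structure it recovers the planted modules exactly even when the
"optimal" partition is a spurious finite-sample merge of them. That
trade — structure fidelity over M-optimality — is the reason the finest
level is the default.

## Consensus clustering

For one network, Louvain runs `n_runs` times (default 100) with seeds
`master + run_index`. If all runs agree up to label permutation the
partition is stable and is returned together with its modularity evaluated
on the **original** network (the modularity on the final agreement network
is also recorded, since either convention could be meant by "the modularity
of the stable partition"). Otherwise the agreement matrix — co-assignment
frequencies, zero diagonal — becomes a new all-positive network and the
loop repeats; entries at or below `tau` (default 0, i.e. no thresholding)
can be zeroed first. Convergence is declared only on exact unanimity, the
strictest reading of "a single stable partition"; `max_iter` (default 50)
guards against oscillation, and on failure the last agreement matrix is
attached to the error for inspection. Practical networks converge in 1–3
iterations.

## Gene-metabolism correlation and the empirical null

Expression tables are cortical by construction (the donor-atlas conversion
covers cortex only), so subcortical columns are refused rather than carried
as empties, and all correlations — global and module-wise — run over the
68 cortical ROIs after aligning gene and profile ROIs by name. Genes are
filtered at consistency **strictly greater than** 0.446 (the wording
"above" is taken literally everywhere, including amyloid-positivity
thresholds). Per gene:

* Pearson r over the shared ROIs; flat (zero-variance) genes are returned
  flagged, never silently dropped.
* Two-tailed P from the exact transform t = r·√((n−2)/(1−r²)) with n−2
  degrees of freedom (checked against `scipy.stats.pearsonr`). Significance
  stars mark 0.05 / 0.01 / 0.001 / 0.0001.
* Null calibration: the same correlation is computed for **every** gene in
  the table; the empirical mean and SD (n−1 convention; with thousands of
  genes the n vs n−1 distinction is far below reporting precision) give
  z = (r − mean)/sd and p_e = Φ̄(|z|), the standard-normal upper tail. The
  null mean is *not* assumed zero, and the normal tail is used rather than
  the empirical percentile because the null is bell-shaped; by construction
  the z-scores of the null genes against their own null have mean 0 and
  SD 1 exactly (asserted to 1e-10). p_e therefore lies in (0, 0.5] and is
  symmetric in the sign of z.

Module-wise correlations intersect each module with the cortical ROIs
present in the gene table; modules with fewer than 3 eligible ROIs yield an
explicit "undefined" marker instead of a number.

## Synthetic data: what it emulates, what it does not

`simulate_suvr_table` draws subjects from a multivariate normal whose
correlation matrix has planted blocks: rho_within inside modules,
rho_between elsewhere. A Gaussian copula suffices because every downstream
statistic is second-order. Defaults are the reference conditions used
throughout the tests: 72 ROIs in modules of 30/24/18 (three modules,
mirroring the three-module organisation of the brain networks this package
targets), rho_within 0.7, rho_between 0.1, 100 subjects, baseline 1.5 and
residual SD 0.15 on the pons-normalised SUVR scale. With
0 ≤ rho_between < rho_within < 1 the matrix is provably positive definite
(sum of scaled block matrices and the identity); a Cholesky check guards
custom inputs anyway. Values at or below zero (vanishingly rare at the
default scale) are clipped to a small floor with a logged count. Group
presets step rho_between down from 0.45 to 0.10 to emulate, qualitatively,
the weakening of between-module coupling as dementia risk rises — they make
modularity *increase* along the risk gradient but are not calibrated to
reproduce any cohort's M values.

`simulate_transcriptome` plants genes at target correlation r_true via
g = r_true·ẑ(profile) + √(1−r_true²)·ε with unit-variance noise ε, among
`n_background_genes` background genes. Background genes are pure noise by
default; setting `background_corr_sd` > 0 gives each background gene a
random profile loading, widening the null r distribution the way a
spatially structured transcriptome does (the acceptance script uses 1/3,
which yields a null SD near 0.31 — the width implied by published
gene-metabolism z/r pairs — so calibrated z values land on a realistic
scale). Expression sits at a log-intensity-like level of 6 arbitrary units;
consistency scores are uniform on a configurable range.

What passing these tests shows: the estimator recovers planted second-order
structure and planted univariate effects at realistic sample sizes. What it
does not show: robustness to non-Gaussian SUVR marginals, site effects,
spatial autocorrelation of expression maps (no spin-test null is
implemented), donor-level variability, or diagnosis noise in group labels.

## Numerical and reproducibility choices

* All stochastic entry points take integer seeds; identical inputs and
  seeds give byte-identical outputs, including CLI artifacts. Run manifests
  omit wall-clock time unless `--timestamp` is passed, so manifests of
  identical reruns are byte-identical too.
* Exact float round-trips: tables are parsed with the correctly rounded
  float parser, so write → read → write reproduces files bit-identically.
* Correlation matrices are clipped to [−1, 1] and symmetrised exactly;
  partitions are canonicalised (labels 1..k by first appearance) so
  equality means identity up to relabelling.
* Amyloid positivity is strict (scores exactly at threshold are negative);
  an empty record list is "indeterminate" (None), never False.
* Problem sizes in the test suite: exhaustive enumeration up to 8 nodes
  (4140 partitions), 40 master seeds for planted-network recovery, 20 seeds
  × 5000 background genes for null calibration — sizes chosen to make the
  statistical assertions sharp while the whole suite runs in under a
  minute.
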