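# Methods

## Differential correlation model

For two experimental groups A and B (e.g. normoxia vs hypoxia within
one cell line), each metabolite pair (i, j) gets a Pearson
product-moment correlation per group, computed on pairwise-complete
observations (samples where both peaks were detected). The sampling
distribution of r is normalised with the Fisher transform
z = atanh(r), whose standard error 1/√(N−3) depends only on the number
of complete observations. Three consequences structure the method:

1. **Significance threshold.** An observed r is significant at Gaussian
   quantile z_T when |atanh(r)|·√(N−3) > z_T, i.e. when
   |r| > C_T = tanh(z_T/√(N−3)). At N = 27, C_T ranges from 0.380
   (α = 0.05) to 0.761 (α = 10⁻⁶).
2. **Minimum sample size.** The large-sample standard error
   SE = (1−ρ²)/√(n−1) at a reference correlation ρ = 0.7 first drops to
   ≤ 0.1 at n = 27 — under the convention that SE is rounded to four
   decimals before the comparison (SE(27) = 0.100019 → 0.1000). Under a
   strict inequality the answer is 28; both conventions are exposed
   (`min_samples(..., decimals=None)`) and asserted in the tests. Pairs
   with fewer than 27 complete observations are discarded
   (`valid = False`), never silently imputed.
3. **Minimum difference.** Comparing groups uses
   (z₁−z₂)/√(1/(N₁−3)+1/(N₂−3)). Solved for the correlation scale at
   the design point (reference r = 0.7, N₁ = N₂ = 27, two-sided 5%,
   z_T = 1.959964), the smallest significant difference is 0.407.

The default decision rule ("paper" mode) is the conjunction: one of the
two correlations must exceed 0.7 in magnitude AND the difference
|r_A − r_B| must exceed 0.407. "exact" mode replaces the fixed 0.407
with the two-sample z-statistic evaluated at each pair's own
(n_A, n_B), which matters when missingness makes sample sizes uneven;
the two modes agree at the design boundary (tested). The magnitude gate
is applied to |r|, so strong anti-correlations qualify — the underlying
sampling theory is sign-symmetric, and the alternative (signed r) would
silently discard discordant pairs.

The label "permutation test" is sometimes attached to this two-sample
comparison in the metabolomics literature; the implemented statistic is
the analytic Fisher-z form — no resampling is performed, matching the
formula rather than the name.

Note on the threshold table this implementation is checked against: its
α = 10⁻⁵ quantile is printed as 4.417117 where the exact two-sided
normal quantile is 4.417173 (the tabulated C_T = 0.717096 derives from
the former; the exact quantile gives 0.717101), and its α = 0.05
quantile is printed as 1.995996 while the tabulated C_T = 0.380014
derives from the correct 1.959964. The package always uses exact
quantiles (`scipy.stats.norm.ppf`); the regression tests document both
discrepancies where they assert the tabulated values.

## Preprocessing

* **Internal standard.** Every metabolite is divided by the per-sample
  peak area of a spiked standard (typically succinic acid-d4); the
  standard must be present and non-zero in every sample, and its column
  is dropped from the output. The operation is invariant to a common
  rescaling of all samples.
* **QC CV filter.** Pooled-QC injections estimate per-metabolite
  technical variability; metabolites with CV = SD/mean > 30% (sample
  SD, n−1 denominator, consistent with the sample moments used for r)
  across QC samples are removed from the whole matrix. CV is undefined
  with fewer than two non-missing QC values — such metabolites are kept
  and reported with CV = NaN, since an undefined CV is absence of
  evidence of unreliability. A QC mean of zero is an error, not a
  decision.
* **Outlier replacement.** Within each condition × cohort group, values
  more than k = 3 sample SDs from the group mean — mean and SD computed
  on the *original* values — are replaced by the mean of the remaining
  (non-outlier) group members. The replacement mean excludes the
  outlier itself so the imputed value is not dragged toward the
  artefact. One pass only: moments are never recomputed after a
  replacement, making the operation reproducible (an iterated scheme
  would depend on sweep order). Groups with fewer than 3 non-missing
  values are skipped with a warning. Missing cells pass through every
  operation untouched — a missing value never becomes a number, and
  zeros are data, never missingness.

## Network mapping

* **Reconstruction.** Any SBML Level 2/3 model. Reactant sides load as
  "consumed", product sides as "produced", with coefficients preserved.
  All reactions are treated as reversible, so the orientation stored in
  the file carries no meaning downstream. When a model declares exactly
  one compartment, a trailing `_<compartment>` id suffix is stripped;
  multi-compartment models load as-is (no merging — profiles from whole
  cell lysates should be mapped on un-compartmentalised models).
* **Currency purge.** A shipped 18-entry table (ATP, ADP, AMP, NAD,
  NADH, NADP, NADPH, CoA, UTP, UDP, UMP, GTP, GDP, H₂O, CO₂, O₂,
  orthophosphate, hydrogen — with synonyms and KEGG compound ids)
  is matched against species by id, normalised name/synonym, or KEGG
  annotation. These ubiquitous cofactors would otherwise put every
  metabolite two steps from every other. The table is a configuration
  input (`remove_currency(net, load_currency(path))`, CLI
  `--currency`), because species naming is model-specific. Purging can
  only remove adjacency between the remaining species, never create it
  (property-tested).
* **Connectivity.** Adjacency = sign(consumed · producedᵀ), OR-ed with
  its transpose, diagonal cleared. Coefficients beyond non-zeroness are
  deliberately ignored — the construction encodes "some reaction
  converts i into j", not flux. Each edge records the supporting
  reaction ids.
* **Shortest paths.** Unweighted breadth-first search; path length is
  the edge count. Ties between equal-length routes are broken
  deterministically by expanding neighbours in lexicographic order —
  shortest paths are generally non-unique and a reproducible
  representative is preferable to an arbitrary one;
  `networkx.all_shortest_paths` remains available on the same graph
  when the full set is wanted. Absent endpoints and disconnected pairs
  return explicit statuses (`source_absent`, `target_absent`,
  `disconnected`) rather than exceptions: in real reconstructions both
  happen routinely and are findings, not errors.
* **Multi-identity peaks.** A chromatographically unresolved peak may
  carry several candidate KEGG ids. The default policy evaluates every
  candidate combination and keeps the shortest found path (recording
  the chosen ids) — consistent with the shortest-route objective; a
  `first`-listed policy is available when the top candidate is trusted.
* **Sub-networks and comparison.** Per cohort, found paths are unioned
  (set semantics; overlapping edges merge their reaction annotations).
  Two cohorts' sub-networks are overlaid and every node/edge classed
  `A_only` / `B_only` / `shared` — the classes partition the union
  exactly. Exports: GraphML (attributes preserved; sets serialised as
  semicolon-joined strings) and SIF with relation `cc`
  ("connected conversion") for Cytoscape.

## Synthetic data

The generator draws, per group, samples from a multivariate normal
whose correlation matrix is identity plus planted pairs (or explicit
matrices). Indefinite targets are repaired by eigenvalue clipping with
re-normalisation to unit diagonal, and the repair is reported in the
gold standard. Defaults emulate the motivating study design: 2
conditions × 30 replicates, 52 metabolite peaks, log-normal marginals
(location 10, scale 0.4 on the log scale — median peak area ≈ 2·10⁴
counts with ~40% biological CV, typical of GC-MS cell-lysate
profiles), 5 pooled-QC injections at 5% technical CV, 2% missing
values injected completely at random, and 1% gross outliers at 5 SD.

When correlations are imposed on the log scale and the data
exponentiated, Pearson correlations on the natural scale are slightly
attenuated relative to the targets; recovery experiments therefore use
the normal-scale option (`lognormal=False`), where realised
correlations converge to targets at the Fisher-z rate 1/√(n−3)
(tested at n = 500). What the generator does **not** emulate: retention
drift, batch effects, censoring-driven missingness (an optional
limit-of-detection mode is a known omission — missingness here is
MCAR), or peak-area heteroscedasticity beyond the log-normal shape.
Passing recovery tests therefore demonstrate the statistics and
plumbing, not robustness to structured artefacts of real instruments.

The toy-network generator builds a random spanning chain (guaranteeing
connectivity) plus random extra reactions, writes valid SBML, and
computes all-pairs shortest path lengths by Floyd–Warshall over
adjacency read directly off the reaction lists — independent of the
package's graph construction and BFS, so it can serve as an oracle.

Recovery performance at the study design (planted r = 0.9 vs 0.0,
n = 30/group, 20 metabolites): the planted pair is recovered in ≥ 95%
of 200 seeded replicates, and null pairs are flagged in ≤ 1% of
pair-replicates — the |r| > 0.7 gate alone puts the per-pair null flag
probability near 10⁻⁵ at n = 30. These rates are computed by the test
suite, not quoted from elsewhere.

## Numerical and degenerate-input choices

* Pearson estimates are clamped to [−1, 1] against floating-point
  overshoot; zero-variance or <3-observation pairs raise in the scalar
  API and are flagged invalid (not NaN-propagated) in matrix building.
* `fisher_z` and its inverse are exact inverses to 1e−12 over
  |r| ≤ 0.999999 (property-tested); |r| ≥ 1 is a domain error.
* Differential results sort by descending |r_A − r_B| with
  lexicographic tie-breaking on the pair, so outputs are byte-stable.
* Reactions whose participants all turn out to be currency metabolites
  are dropped; a reaction consuming and producing the same species
  yields no self-loop.
* The CLI seeds every stochastic stage from an explicit `--seed`;
  fixed seed + fixtures give byte-identical stage outputs (tested,
  manifests normalised for paths only).

## Benchmark reproduction

The published benchmark (7 significant differential correlations for
MDA-MB-231, 18 for HCT116; 4-hydroxyproline–malate hypoxia r = 0.902)
is reproducible through `metcorrnet.benchmark.run_benchmark`, which
implements the import recipe for the supplementary workbook: one sheet
per cell line, sample labels N/H/A for normoxia/hypoxia/anoxia, data
already internal-standard normalised and QC-filtered, so only outlier
replacement and the correlation pipeline are applied. The workbook is
not redistributable with the package and must be supplied at
`data/benchmark/additional_file_1.xlsx`. Two provenance caveats limit
exact agreement: the published difference column is internally
inconsistent with its own coefficients by up to ~0.014 (we recompute
from data, never from that column), and whether the original outlier
means included the outlier itself is undocumented (we exclude it, which
can shift coefficients in the third decimal).

## Known limitations

* Pearson only; rank or robust correlation is out of scope by design
  (the framework assumes approximate normality after outlier
  replacement).
* No multiple-testing correction beyond the threshold scheme — the
  0.7/0.407 conjunction is already conservative at ~50 metabolites, but
  users profiling thousands of features should add FDR control.
* Shortest paths are unweighted; reaction-count or atom-mapping weights
  are not modelled.
* Compartmentalised models are accepted but not merged; mapping whole
  cell lysate data onto them will miss cross-compartment routes.
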