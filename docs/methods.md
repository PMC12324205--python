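# Methods

This note documents the models, parameter choices, and numerical
conventions behind `directppi`, and what the synthetic-data experiments
do and do not demonstrate.

## Co-occurrence statistic (weighted matrix model)

For one dataset of N experiments, a protein is *present* in an
experiment if it is the bait or any of its prey records satisfies the
dataset's presence rule (`score_threshold` / `psm_threshold` with a
`gt` or `ge` comparator, or `any_detection`). With A present in n
experiments, B in m, and both in k, the WMM p-value is the exact
hypergeometric upper tail P(#shared ≥ k | n, m, N). Conventions:

* Tail terms are summed in log space (`gammaln` + `logsumexp`), so the
  statistic is exact to double precision even for extreme counts; the
  exported feature is the natural log, `−ln p`, capped at 745 (the point
  where p itself underflows a double). k = 0 gives p = 1 exactly.
* Presence counts treat experiments as sets of seen proteins; bait/prey
  roles do not matter beyond the bait being unconditionally present.
* By default only co-observed pairs are emitted (sparse mode); an
  all-pairs mode scores every pair of observed proteins, with
  never-co-observed pairs at −ln p = 0, pair_count = 0.

## Co-elution similarity

Per elution experiment and protein pair: Pearson r (zero-variance
profiles score 0 — a flat row is "no evidence", not "undefined");
co-apex (indicator that the argmax fractions coincide, ties to the
lowest index); lag-weighted cross-correlation (max over |lag| ≤ 2 of
the overlap Pearson discounted by 1/(1+|lag|)); Poisson-noise Pearson
(mean over 10 replicates of Pearson after adding counts drawn from
Poisson(noise_scale·profile + pseudocount), defaults noise_scale = 1,
pseudocount = 1 — the perturbation damps correlations carried by sparse
coincidental counts; with both set to 0 the metric reduces to plain
Pearson); and a normalized Euclidean distance (`*_pq_euc` columns).
Noise replicates use per-pair seeds derived from a CRC32 hash of the
pair key XOR the global seed, so results are reproducible regardless of
iteration order. Pairs are retained only if some similarity-type score
(distance columns excluded) exceeds 0.5 in some experiment.

## Benchmark construction

Interaction entries (accession pair, type, structure id, per-chain
coverage) are used as the source of direct-contact truth; no interface
detection from coordinates is attempted. Rules:

* only `structure`-type entries; both chains must reach the coverage
  minimum (default 80 %, inclusive) — low-coverage pairs might interact
  through unresolved domains and cannot be trusted as indirect;
* complexes = entries grouped by structure id; a pair is direct if any
  surviving entry attests it;
* clustering: complexes are processed greedily in descending subunit
  count (ties by structure id) and merged with every cluster they share
  a protein with. Because overlap is binary, the result equals the
  connected components of the overlap graph and is independent of the
  processing order; cluster protein sets are pairwise disjoint by
  construction.
* split: the cluster with the most distinct direct pairs (ties by
  protein count) trains; the rest test. Train positives come from
  complexes of ≥ 3 subunits (dimers are trivially direct); train
  negatives are all remaining pairs of train-cluster proteins that are
  not direct in any complex, inter-complex pairs included. Test labels
  come only from complexes of ≥ 5 subunits with negatives strictly
  intra-complex; an extended negative list adding inter-complex test
  pairs is emitted separately. Direct pairs attested only by too-small
  complexes are excluded from negatives rather than relabeled.

## Classifier

One LightGBM gradient-boosted tree ensemble (500 trees, learning rate
0.05, 31 leaves, deterministic single-threaded mode) under stratified
K-fold cross-validation (default 5 folds, early stopping on fold binary
error after 25 rounds), then a refit on all labeled rows for deployment.
Missing feature cells go to the learner's native missing-value handling;
sparsity is informative and is never imputed. No class reweighting and
no post-hoc calibration: scores are the learner's raw probabilities,
tiered at ≥ 0.7 (confident) and ≥ 0.9 (highly confident). Feature
pruning drops columns with < 5 observed values or zero variance on
labeled rows ("no information"); an optional screen drops features whose
single-feature AUPRC fails to beat label prevalence by ε = 0.02 ("no
signal"). Network exports sort by descending score with pair-key
tie-breaks, so repeated runs at a fixed seed are byte-identical.

## Evaluation conventions

* PR curves are computed over benchmark pairs only; recall is always
  counted against every benchmark positive. `complete_benchmark`
  appends unscored benchmark pairs (both classes) at −∞ — not at an
  arbitrary small score — so recall can reach 1 and an uninformative
  (all-missing) ranking scores exactly the label prevalence.
  `add_tiny_noise` adds seeded uniform noise on [0, 1e−8] purely to
  split ties; with distinct scores it changes nothing. AUPRC integrates
  step-wise, precision held constant between recall steps.
* Mann–Whitney: exact two-sided p by full enumeration of label
  arrangements (midranks for ties) for combined n ≤ 20; beyond that,
  scipy's tie-corrected normal approximation.
* Fraction-confident-at-K ranks network pairs by score (key-stable
  ties) and reports the fraction whose structural-model score (e.g.
  pDockQ) reaches the cutoff at each K. Default denominator: pairs with
  models only; an `include_unmodeled` mode counts model-less pairs as
  failures. K values beyond the rankable pairs truncate with a warning.
* Bimodality of a score distribution is flagged when the two tallest
  local maxima of a 3-point-smoothed histogram are separated by a
  valley ≥ 10 % below the smaller peak.

## Crosslink analysis

Residue-level links collapse to one record set per unordered protein
pair; intra-protein links are dropped. The self-link screen removes a
pair if any identified peptide occurs verbatim in the partner sequence;
pairs with missing sequences are kept with a warning (a data gap should
not silently shrink the set). The overlap Z-score samples |XL| pairs
uniformly without replacement from all pairs over the crosslink
protein universe (the proteins actually occurring in the reduced set),
repeats 1,000 times, and standardizes the observed network overlap. A
zero-spread null with a non-deviating observation returns Z = 0; a
deviating one raises a degenerate-null error. Crosslink satisfaction
uses Cα–Cα distances with a configurable threshold, default 35 Å — a
conventional allowance for common crosslinker spacer arms plus side
chains; unmappable links are reported as such and never counted as
violated.

## Structure metrics

Models are read with gemmi (PDB or mmCIF, first model only); per-residue
confidence comes from the B-factor field, rescaled ×100 with a logged
notice when a file carries 0–1 plDDT. A cross-chain residue pair is an
interface contact when representative atoms (Cβ; Cα for glycine) lie
within 8 Å. pDockQ = L/(1+exp(−k(x−x0))) + b with x = mean interface
plDDT × ln(contacts), L = 0.724, k = 0.052, x0 = 152.611, b = 0.018;
the constants and the representative-atom rule follow the FoldDock
project's published scoring script and are configurable in
`PDockQParams`. Zero contacts score 0 by convention.

## Synthetic worlds

`make_world` builds disjoint complexes (chain, ring, or clique
topology) over uniquely named proteins. Default planted rates
p_direct = 0.8, p_indirect = 0.3, p_background = 0.02: a prey joins an
experiment at the rate given by its relation to the uniformly drawn
bait, independently across preys and experiments (the simplest
exchangeable null). Included preys carry Poisson(10) PSM-like counts so
presence-call thresholds are exercisable.

Elution profiles use an interface-level mixture: every direct edge
draws its own elution center (uniform over the usable fraction range)
and a protein's noise-free profile sums Gaussian bumps (height 100,
width 2 fractions, 60 fractions) over its incident edges; proteins with
no edges get a lone monomer bump. Direct partners therefore share a
peak exactly — the physical picture is subcomplexes that survive
fractionation — while indirect partners share none and correlate only
when centers collide by chance. Counts are integer, nonnegative, and
Poisson-corrupted (`noise_scale` interpolates between noise-free and
fully Poisson-resampled).

The generators emulate planted co-occurrence and co-elution only: no
chromatography physics, no spectral simulation, no decoy/FDR structure,
no shared-peptide ambiguity, and complexes never share subunits unless
constructed to. Passing recovery tests therefore shows the pipeline
extracts the statistical signal it is designed for — not that real
compendia carry that signal at the same strength.

## Parameter-recovery experiment

`pipeline.parameter_recovery` simulates 20 chain complexes of 5–8
subunits, one 300-experiment compendium, and three independent elution
experiments; features are two WMM blocks (any-detection and ≥ 4 PSM
rules) plus all co-elution metrics. Complexes alternate between
training and test by index — complexes are protein-disjoint, so the two
pair sets never overlap — rather than using the benchmark builder's
largest-cluster rule, which on disjoint synthetic complexes would leave
a single complex (~25 pairs) as the entire training set. Three elution
experiments are used because coincidental peak-center collisions do not
replicate across experiments while true co-elution does; a single
experiment leaves indirect pairs with a heavy high-correlation tail.
The label-shuffled control permutes training labels and re-evaluates,
landing near the held-out label prevalence. Measured at these settings:
held-out AUPRC ≥ 0.98 across seeds 1–5, shuffled controls within 0.09
of prevalence (`scripts/acceptance.py` recomputes both).

## Known limitations

* The WMM block enumerates pairs per experiment, which is quadratic in
  experiment size; it is sized for compendia where experiments contain
  tens of proteins, not whole-lysate lists.
* The exact Mann–Whitney enumerates C(n, n1) arrangements and is
  limited to combined n ≤ 20 by design.
* Crosslink residue mapping assumes model numbering equals sequence
  numbering up to a per-protein offset; insertion codes are not
  handled.
* `coelution_block` computes metrics pairwise in Python; for elution
  matrices beyond a few thousand proteins a vectorized correlation path
  would be needed.
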