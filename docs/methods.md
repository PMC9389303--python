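# Methods

This note documents the models, parameter choices and numerical decisions
behind `ms2transfer`, and what the synthetic benchmark does and does not
show about real data.

## Spectrum representation and the pairwise similarity model

Each MS2 spectrum is reduced to a set of integer fragment bins: the `top_k`
most intense peaks (default 40) outside the reporter-ion region (default
125–135 Th, excluded because every labeled spectrum carries reporter ions
there, so they hold no peptide-identity signal), binned at
`floor(m/z / bin_width)` with `bin_width = 0.02` Th. The defaults suit
high-resolution HCD fragment spectra; both are configurable, and for
low-resolution data a wider bin is appropriate.

Two spectra `a`, `b` with bin sets of sizes `n_a`, `n_b` and `k` shared
bins are scored by the upper tail of a hypergeometric null:

    s(a, b) = -log10 P(X >= k),   X ~ Hypergeometric(B, n_a, n_b)

where `B` is the number of available bins spanning the fragment range
(default 100–1500 Th, so `B = 70 000`). The score is symmetric, zero for
disjoint sets, and monotone in the shared-bin count; `scipy`'s `logsf`
keeps it accurate far into the tail (an underflow to `p = 0` is capped at
10^6). This is a deliberately simple stand-in for the cluster-scale
p-value machinery of dedicated spectrum-clustering tools: the transfer
logic downstream consumes only cluster assignments, and externally
produced cluster files can be imported (`--import-clusters`) whenever
fidelity to a specific external clusterer matters. No claim is made that
this null matches any external tool's p-values numerically — only the
semantics of the stringency ladder (cutoffs on −log10 p) is preserved.

## Partitioning and complete-linkage agglomeration

Spectra are compared only within a partition:

* **Charge**: spectra of different precursor charge are never compared
  (their fragment series differ). Spectra with no assigned charge form
  their own partition rather than being duplicated into every charge
  group — duplication could place one scan in two clusters, which the
  one-cluster-per-scan contract forbids.
* **Precursor mass**: within a charge group, neutral masses are sorted and
  chained while consecutive gaps stay within `precursor_tol_ppm` (default
  10 ppm). Single-linkage chaining avoids hard window edges: near-boundary
  pairs always share a partition.

Within a partition, clusters are agglomerated greedily under complete
linkage: at each step the cluster pair with the largest linkage value
(minimum pairwise score over all cross-members) is merged. Ties are broken
deterministically by the lexicographically smallest pair of cluster
representatives (a representative is the smallest `(raw_file, scan)` key),
so identical inputs always produce identical assignments. Complete linkage
is reducible, hence merge heights are non-increasing and the six ladder
assignments (p5–p30) are obtained by cutting a single merge sequence —
which also guarantees that each stricter partition refines every looser
one. The agglomeration is O(n³) per partition; partitions are small by
construction (spectra of one precursor species), so this is not a
bottleneck even for tens of thousands of spectra.

Spectra with no fragment peaks are excluded from clustering and re-enter
downstream as singletons.

## Categorization and transfer

Only *direct* (search-engine) identifications count when categorizing, so
the categorize-and-transfer cycle is idempotent. The six classes and the
transfer rules are described in the README. Decisions worth recording:

* "Identified" means a retained target PSM from the input table, which is
  assumed already filtered to the search engine's peptide/protein FDR.
  Optional extra score/PEP cutoffs are deliberately not applied by default.
* Decoy rows are parsed and flagged but never donate and never accept
  transfers; transferring onto a decoy scan has no meaningful readout in a
  target-filtered analysis.
* A fully identified cluster whose members agree on the unmodified
  sequence but differ in modification sites has no acceptors; it is
  counted as unanimous (site heterogeneity affects no transfer decision).
* PTM-isomeric clusters require all donors to carry the *same number* of
  modifications per type; clusters mixing, say, singly and doubly
  phosphorylated forms of one sequence are demoted to ambiguous. This is
  configurable (`require_equal_mod_counts=False` treats them as isomeric).
* Acceptors copy protein and accessory fields from the highest-scoring
  donor (ties broken by raw file, then scan number).
* Localization flags are 1-based on the unmodified sequence and rendered
  with a `p` prefix for phosphosites (`RASPSPRAA.1.p3/p5`); other
  modification types with positional variation use a `mod` prefix.
* A scan whose identification was filtered out upstream (or masked) is
  simply unidentified from the pipeline's perspective and may accept a
  transfer.

## Masking analysis

Masking is stratified per raw file: `round(fraction × n_identified)`
identified target PSMs per file are hidden, sampled uniformly without
replacement from a seeded generator (default seed 1). Correctness of a
transfer onto a masked scan is judged on the unmodified sequence — the
natural basis once PTM-isomeric clusters transfer flags rather than single
site assignments; a strict mode compares modified sequences for
class-(e)-only evaluation. Transfers onto scans that never had an
identification are unverifiable and excluded from both the precision
numerator and denominator; the report records how many transfers were
scored. A masking run with zero transfers onto masked scans reports
precision 1 with a `degenerate` flag. `FDR = 1 − precision` holds exactly
by construction in every report.

## Synthetic benchmark: what it emulates

`SyntheticConfig` defaults define the package's benchmark conditions:
three TMT10-plex batches; 3000 "real" peptides (length 8–14, tryptic-like
C-terminal K/R, 8 peptides per protein) fragmented once per batch;
per-batch identification probability 0.93 for real peptides; 25%
phosphopeptides, of which 5% form positional-isomer pairs (both forms
emitted per batch); and 5400 *background* species that are never
identified. The background mirrors the dominant unidentifiable fraction of
real MS2 data (real TMT datasets identify on the order of 12–22% of MS2
scans; the benchmark's overall identification rate is ~33%) and matters
for the FDR proxy, whose denominator is all clusters of size > 1.
Fragment templates use singly charged b/y ions from monoisotopic residue
masses (phospho = +79.966 Da at the site); per-spectrum noise applies 5%
peak dropout, 0.002 Th m/z jitter and 20% log-intensity noise. Reporter
intensities follow per-protein log2 channel patterns (sd 0.6) around a
spectrum-level base intensity, with channel noise sd 0.25 and the last
channel as the bridge reference.

Cross-peptide *look-alike* pairs plant controlled ambiguity: a fraction of
real peptides (`lookalike_pair_fraction`, default 0 — planting is an
explicit stress condition) receive a twin species whose precursor matches
within 3 ppm and whose peak list shares a uniformly drawn 30–95% of the
partner's fragment bins, so that twin pairs co-cluster at loose
stringencies and progressively separate toward p30. Twins are modeled as
poorly identifiable (identification probability 0.2): a look-alike whose
own spectra are rarely identified is precisely the species that produces
*wrong transfers* rather than only ambiguous clusters. Under these
conditions the masking FDR and the ambiguous-cluster fraction agree
closely across the whole stringency ladder, which is the behavior the
proxy is meant to exhibit; with symmetric, well-identified twins the same
planted rate would yield ambiguity with almost no wrong transfers, because
at 10% masking a masked acceptor is ~10× rarer than a surviving donor.

What the benchmark does *not* model: chimeric spectra, realistic fragment
intensity patterns, retention-time structure, charge-state mixtures of one
peptide, missed cleavages, protein inference beyond a fixed
peptide→protein map, and batch-to-batch instrument drift. Passing tests
therefore demonstrate the correctness of the clustering/transfer/
evaluation machinery under controlled conditions — not the transfer error
rates to expect on any particular real dataset, which depend on the
clusterer and data quality. With 8 peptides per protein and a 93%
identification rate, protein-level presence saturates (every protein is
seen in all three batches even before transfer), so the benchmark's
protein-level "found in all batches" gain is structurally zero; the
peptide-level curves carry the missing-value signal.

## Numerical and degenerate-input choices

* Pair scores are cached on `(k, n_a, n_b, B)`; `n_a ≤ n_b` by symmetry.
* Ties in top-K peak selection go to the lower m/z; binning is order-
  invariant.
* `round()` (banker's at .5, per Python) fixes the masked count per file.
* Empty cluster files yield an empty assignment (all scans become
  singletons downstream); duplicate scan lines are a hard error.
* An all-equal reporter vector has no defined ratio correlation; such PSMs
  are skipped and counted, as are proteins with fewer than 2 direct PSMs
  in a batch.
* Scores of unidentified rows are NaN; best-per-scan selection ranks
  identified rows above any unidentified row regardless of score.

## Known limitations

* The built-in clusterer is a simplified model; for production analyses of
  real cohorts, importing cluster files from a dedicated tool is
  recommended (the import path is first-class and tested).
* Localization flags enumerate candidate sites but do not score them;
  site-localization probabilities are out of scope.
* Protein grouping uses the leading identifier of the group; razor-peptide
  logic is not implemented.
* mzML support covers the common case (MS2 scans, 32/64-bit float arrays,
  zlib or uncompressed); exotic encodings are not handled.
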