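# Methods

## The concordance computation

All analysis operates on *detection sets*: for an expression table $v$ (one
platform × sample × batch, values in the platform's native unit) and cutoff
$c \ge 0$, the detection set is $\{g \in U : v(g) > c\}$, where $U$ is the
declared gene universe and a gene absent from the table has $v(g) = 0$. Two
deliberate contracts:

- **Comparator.** The default is strict (`>`), so a stored value of exactly
  0 is *not* a detection at cutoff 0. `>=` is first-class and recorded in
  each detection set's provenance, because both conventions are used in
  practice; note that at cutoff 0 the `>=` comparator calls every universe
  gene detected, which is rarely what is wanted.
- **No epsilon.** The cutoff comparison is exact floating point. An epsilon
  would be a second, undocumented threshold; the cutoff itself is the only
  threshold in the analysis.

Absent-row ≡ zero is the right reading when each table covers the declared
universe (the generator always emits all genes): it distinguishes
"measured, nothing there" from nothing at all only through the universe,
which is the object coverage is defined against anyway.

Agreement between two sets is the Tanimoto index
$T = |A \cap B| / (|A| + |B| - |A \cap B|)$ (the Jaccard index). When both
sets are empty, $T := 1$ — two platforms that both detect nothing do agree —
but the value is flagged `degenerate` in reports since it carries no
evidence. The interpretation bands are resolved as half-open intervals
$[0.7, 1]$ *identical*, $(0.55, 0.7)$ *weaker*, $[0, 0.55]$ *considerably
different*: the conventional ranges overlap on paper, and the only
non-contradictory reading honors "0.55 and below differs considerably" and
"0.7 and above is identical" exactly, splitting at those edges.

The Venn partition assigns every union gene to exactly one of the $2^k - 1$
exclusive platform subsets ($k \in [2, 4]$); reliability tiers count, per
gene, the number of platforms detecting it. The two are consistent by
construction (tier-$m$ gene count = sum of region counts over subsets of
size $m$), and the test suite enforces this against brute-force enumeration.
Coverage is $|{\cup}_i D_i \cap U| / |U|$; the undetected list is $U$ minus
the union, in universe order, so the genes invisible to every technology are
explicit output rather than a leftover.

Cutoffs are applied in each platform's native unit with **no cross-platform
normalization**: the analysis compares detection calls, not abundances, and
a shared ladder per platform is exactly how the underlying comparison is
defined. Consequently at cutoff 0 the comparison is scale-invariant
(rescaling a table changes nothing), which the replicate tests exploit.

## The synthetic observation model

No redistributable dataset accompanies the analysis, so the generator
produces data with the statistical structure the method presumes; its job is
structure, not realism. All parameters are exposed; the defaults are:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 275 | chromosome-scale universe |
| `silent_fraction` | 2/275 | probability a gene is truly unexpressed ($\lambda = 0$) |
| `mean_log`, `sd_log` | 1.0, 2.0 | log-normal law of true abundance $\lambda_g$ (arbitrary copies) |
| `efficiency` | 1.0 | platform scale from $\lambda$ to expected signal |
| `noise_sd_log` | 0.3 | log-scale measurement noise |
| `dropout_d0`, `dropout_lambda0` | 0.5, 1.0 | dropout probability $d_0 e^{-\lambda/\lambda_0}$ |
| `false_positive_rate` | 0.001 (long-read: 0.01) | silent gene yields spurious signal |
| `fp_max` | 0.1 | spurious signal uniform on $(0, 0.1]$ |
| `decay_rate` | 0.2 | batch drift $e^{-\kappa q_g}$, $q_g$ = abundance rank-quantile |
| `extra_noise_sd_log` | 0.1 | extra campaign-specific log noise |

An expressed gene drops out (value 0) with probability $d_0
e^{-\lambda/\lambda_0}$ — detection failure concentrates on low-copy
transcripts; otherwise its value is $\text{eff} \cdot \lambda_g \cdot
e^{\mathcal{N}(0, \sigma)}$, times $e^{-\kappa q_g + \mathcal{N}(0,
\sigma_b)}$ for a drifted second campaign, so the most abundant transcripts
drift the most (emulating faster decay of abundant transcripts between
campaigns years apart). A silent gene yields a spurious value uniform on
$(0, 0.1]$ with the platform's false-positive probability — *below the first
non-zero rung of the default ladder*, so cutoff 0.1 removes exactly this
noise band. The long-read false-positive rate is 10× the others, a nod to
the higher per-read error of nanopore sequencing. None of these defaults is
a calibrated estimate of a real instrument.

**Randomness.** Each (platform, batch) observation draws from an independent
`numpy` stream keyed by `SeedSequence(seed, spawn_key=(crc32(platform),
crc32(batch)))`, with a fixed per-gene array layout inside the stream
(dropout, noise, false-positive, magnitude, drift draws each occupy one
fixed array). Adding or removing a platform or batch therefore never
perturbs another's draws, and the whole path truth → tables → files is
byte-reproducible under a seed (the end-to-end golden test pins this).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level error profiles, gene length and GC
bias, correlated (library-level) dropout, unit-specific distributions
(cycle-number saturation for qPCR), isoform structure, and biological
replicate variance. Tests against this generator validate the *analysis
machinery* and the qualitative mechanisms (multi-platform confirmation,
cutoff/coverage trade-off, sub-cutoff noise), not platform performance
claims.

## Behavior under the default conditions

Three model-level properties are verified by simulation in the test suite:

- **Reliability ordering.** Mean precision (fraction of called genes truly
  expressed) of three-platform calls ≥ two-platform ≥ single-platform calls
  at cutoff 0, over 100 seeds. With only ~2 silent genes and small
  false-positive rates, single-platform calls are already ~99.8% precise;
  the ordering is the point, not the absolute level.
- **Cutoff trend.** Per-platform detected counts fall monotonically along
  the ladder. The between-campaign (drifted batch pair) Tanimoto *rises*
  from cutoff 0 (mean ≈ 0.82) to a peak at cutoff 1 (≈ 0.89) and then
  declines through 5 and 10 (≈ 0.83, 0.79): at cutoff 0 the unstable
  low-abundance calls (dropout ≈ $d_0$) inject disagreement, while at high
  cutoffs threshold-boundary flicker and systematic drift dominate. The
  early rise is a direct consequence of abundance-dependent dropout:
  independent spurious signal in $(0, 0.1]$ can only *lower* cutoff-0
  agreement (it lands in the union, never the intersection), so no
  parameterization of this observation model makes the batch-pair Tanimoto
  peak at cutoff 0.
- **Noise band.** Under the defaults the 0.1 cutoff strips only ~3% of
  cutoff-0 calls (2 silent genes leave the sub-0.1 band almost empty). The
  noise-pollution mechanism is therefore demonstrated in a dedicated
  noise-dominated configuration (silent fraction 0.5, false-positive rate
  0.9), where the 0.1 cutoff removes ≥ 40% of cutoff-0 calls — the
  mechanism by which a modest cutoff sharply deflates detected counts when
  a sub-cutoff noise band is populated.

## Numeric and format contracts

Reports are byte-deterministic: JSON with sorted keys and all reals rounded
to 6 significant digits before serialization; TSVs render reals with
`%.6g`; files are written to a temporary name and renamed, so failed runs
leave no partial artifacts. Expression tables round-trip exactly (values
written with shortest-round-trip `repr`). Problem sizes in the simulation
tests (100–200 seeds × 275 genes × 3 platforms) keep the full suite in the
tens of seconds while leaving Monte-Carlo error far below the asserted
margins (the closed-form checks use ±3–4 standard-deviation bounds).

## Known limitations

- Gene identifiers are opaque case-sensitive strings; no symbol/accession
  mapping. Comparing tables from different annotation namespaces is the
  caller's problem.
- Detection is gene-level; isoforms are out of scope.
- The Venn figure is fixed-layout (counts as labels, areas not
  proportional) and 3-set only; the tabular partition covers 2–4 sets.
- `replicate_concordance` reports Tanimoto between batch detection sets;
  whether a published "percent correspondence" between campaigns denotes a
  Tanimoto value, a count ratio, or a correlation is a question the caller
  must settle when comparing against external numbers.
- The qPCR observation is a generic non-negative abundance score; cycle
  thresholds must be converted upstream, and the unit is carried as
  metadata only.
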