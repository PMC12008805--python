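# Methods

`bitrexkit` models and analyses the copy-number dynamics of gene-sized
tandem arrays (e.g. the yeast *CUP1* array of ~2.0-kb units, or human
macrosatellites such as D4Z4) under nick-induced break-induced replication
(BIR), and implements the measurement stack used to genotype such arrays:
spanning-read unit counting from long reads, masked-depth copy number from
short reads, and a split-read rearrangement screen.  Everything runs on
synthetic data with exact truth tables.

## The expansion/contraction process

A replication fork collapsing at a nick placed just outside a tandem array
produces a one-ended break whose resected end can only re-invade the
allelic or an *upstream* repeat unit — the array either stays the same or
expands, never contracts through this route.  `synthetic_data.population`
implements this as a per-division branching process:

- each cell divides into a daughter that inherits the donor chromatid
  unchanged (copy number X) and a daughter that, with probability
  `p_eff`, gains a geometric step of repeat units (mean `step_mean`,
  default 1.5 — jump sizes are variable in practice but no distribution is
  established, so the simplest discrete heavy-ish law is used);
- expansion requires X ≥ 2: a single-copy unit has no upstream partner,
  which is why one-unit arrays never expand in the simulator or in vivo;
- independently, every lineage contracts by inter-unit homologous
  recombination with per-generation hazard `1 − exp(−kX²)`; the event
  magnitude is uniform on [1, X−1] by default (recombination between two
  uniformly chosen units), floor at X = 1;
- the population is diluted by multinomial resampling to `population_cap`
  whenever it exceeds the cap.

In `origin_mode="external"` the nick-proximal fork must outrun a fork
coming from an origin on the far side of the array.  Two constant-speed
forks give success probability `d_int / (d_int + d_ext + array_bp)`, so
the per-division expansion probability declines monotonically with array
length — the plateau observed for very long arrays.  The distances default
to `d_internal_side = 500` bp and `d_external = 10 kb`; they are geometry
placeholders, not estimates, since no empirical values exist for them (the
same holds for `p_exp` and `step_mean`).

## Contraction kinetics

Treating contraction as second-order in copy number,

    dX/dt = −kX²    ⇒    X(t) = X0 / (1 + k X0 t)

and the copy-number alteration per generation over a window of T days and
G generations is

    CNA/G = (X(T) − X0) / G = −(1/G) · X0² / (X0 + 1/(kT)),

a line plus a rectangular hyperbola in X0, asymptotically linear for large
arrays.  Both forms are implemented and verified against each other to
1e−12 and against an adaptive Runge–Kutta integration to 1e−6 relative
error.  Empirically, CNA/G = (copy_T − copy_0)/divisions, with the
division number taken as log2 of the optical-density fold change over the
growth window (the OD-based count is only specified as "from the change of
OD"; log2 of the fold change is this package's concrete choice).

The X² rate law is kept as published even though it is nonzero at X = 1,
where contraction is physically impossible; a pairwise X(X−1) variant
(closed form `1/(1 − (1 − 1/X0)e^{−kt})`) is available via
`pairwise=True` and documented as the biologically clean alternative.

**Simulator ↔ model correspondence.** The mean-field limit of the
stochastic contraction step matches dX/dt = −kX² only when each event
removes about one unit (expected loss ≈ hazard ≈ kX²).  With the default
uniform magnitude the expected loss is ~kX³/2 — faster than second order.
`SimParams.contraction_magnitude="single"` selects the regime in which the
simulator converges to the closed form; the default stays "uniform"
because single-event recombination between two random units is the more
faithful microscopic picture.

`fit_k` least-squares fits the closed form to a measured trajectory
(days), co-estimating X0 by default (or pinning it to the day-0 value),
with k bounded below by 0; a non-decreasing series returns k = 0 with a
warning rather than an error.  Uncertainty is a case-resampling bootstrap
over time points (percentile 2.5/97.5, default 1000 draws, seeded);
resamples with fewer than three distinct times are skipped.

`predict_fragment_size` does restriction-fragment accounting for an enzyme
with no site inside the unit: `(n_units · unit_kb + extra_kb)/1000` Mb,
rounded half-away-from-zero to one decimal, the precision at which
pulsed-field gels are read.

## Synthetic genomes and reads

Genomes are linear chromosomes of i.i.d. random bases with the array
written over a configurable offset (centred by default); the flank anchors
are the 1-kb (configurable) segments immediately outside the array and are
checked to occur exactly once in the genome (up to 10 re-draws).
Coordinates are 0-based half-open; minus-strand reads are stored
reverse-complemented.  Unit copies can diverge by i.i.d. substitutions
(`unit_divergence_rate`), and arrays may be interrupted by an intervening
segment (an integrated plasmid backbone, say).

Reads have fixed or lognormal lengths (the heavy-tailed nanopore-like
regime), uniform start positions on [0, L − ℓ] (reads longer than the
chromosome are truncated to it), optional strand flipping, and i.i.d.
substitution errors only — no indels or coverage bias, which keeps every
downstream expectation analytically enumerable.  Truth tables record the
source interval, strand, and whether the read fully contains the array
plus both anchors.

Engineered rearrangements for screen testing: a reciprocal translocation
at the array 3′ end, integration of an excised unit circle at a random
site on a partner chromosome, and whole-chromosome gain.  A gained
chromosome is part of the simulation genome (reads are drawn from it) but
excluded from the analysis reference, so aneuploidy appears as doubled
depth rather than universal multi-mapping — the same effect as mapping an
aneuploid sample against a haploid reference.

## Spanning-read genotyping

Anchors and unit copies are located by exact k-mer seeding (k = 15) with
all matches found via one sorted-array index per reference set; anchor
candidates vote for diagonals and the best diagonal (most seeds, leftmost
on ties) is refined by an infix edlib alignment of the full anchor,
accepted at identity ≥ 0.8.  A read spans the array iff both anchors hit
on one strand, in genomic order, and neither alignment is clipped by a
read edge (an edge-abutting alignment is accepted only when exact).  Unit
copies are counted as maximal collinear diagonal segments: seed matches
chain while read positions advance by at most 10% of the unit length and
the diagonal shifts by at most 20 bp; a wrap of the unit coordinate starts
the next copy.  A segment counts as one unit iff it covers ≥ 60% of the
unit (`min_unit_fraction`) — partial terminal diagonals below that are
reported but not counted, making the "2.5 copies → 2 or 3 hits" behaviour
explicit and configurable.  `export_dotplot` emits the underlying match
coordinates, one row per seed, for plotting.

With substitution-only errors the chain gap tolerance scales with the unit:
at 5% errors and 2.0-kb units the probability of an error hole exceeding
200 bp is negligible and ≥ 95% of spanning reads count exactly; very short
units (≲ 500 bp) at that error rate fragment their diagonals and
undercount, a documented limitation of the k-mer approach.

**Ascertainment.** A read of length ℓ spans a centrally placed region of
length S = array + 2 anchors from `min(max(0, ℓ − S + 1), L − ℓ + 1)` of
its `L − ℓ + 1` possible starts.  `AscertainmentModel` averages this over
the read-length distribution (exactly for fixed lengths; by numerical
integration over the lognormal density otherwise), giving P(span | array
length), strictly decreasing in array length.  `bias_corrected_mean`
weights each spanning read by 1/P(span | its allele length), with a
case-resampling bootstrap CI; alleles with zero spanning probability are
excluded and counted.  The per-read hit-count estimator
(`hit_count_estimate`) reports the full distribution and its maximum
rather than a single number, because aggregation of clipped-read counts is
underdetermined.

## Masked-depth copy number

The internal placer indexes the reference (21-mers), gathers candidate
placements from up to 8 probe k-mers per strand, verifies exactly and then
with edlib within a 10% edit budget, and accepts only a unique best
placement; ties are discarded as multi-mapped and counted.  Masked
intervals become 'N' before indexing, so reads from masked duplicate
copies place uniquely on the retained copy and reads crossing a masked
boundary drop out.  Coverage is binned (100 bp default, bin value = mean
per-base depth), normalized by the mean over background bins (everything
not masked and not on the user's exclusion list), after which single-copy
background reads 1 and the retained unit copy reads out the array copy
number.  Region estimates are mean ± SD over unmasked bins (SD flagged
undefined for single-bin regions); per-chromosome means classify ploidy
with strict thresholds (> 1.25 gain, < 0.75 loss; boundary values are
euploid).  Junction reads that straddle copy boundaries cannot be placed
and shave ~ℓ/unit_length off the estimate (~5% at 100-bp reads on 2-kb
units), within the 10% recovery tolerance; bin size and thresholds are
declared defaults, not inferred from data.

## Rearrangement screen

Unit-containing reads are split at their first/last accepted unit segment;
the flanking sequences (≥ 200 bp, else dropped) are uniquely placed on the
clean reference.  A flank landing within ±2 kb of either array flank locus
is "expected".  Both flanks expected → in situ; one expected, one placed
elsewhere → translocation; both at a shared unexpected locus → ectopic
integration (an integrated excised circle); any multi-mapped flank →
ambiguous, never evidence, because repeat-adjacent sequence would
otherwise create false positives.  Reads ending inside the array leave a
pure-repeat "flank" that multi-maps and is therefore inert.  The summary
reports raw counts and rates; no binary detected/not-detected verdict is
produced, since no detection threshold is established for "no detectable
levels".  Free (unintegrated) circles are out of scope.

## Pipeline and reproducibility

`pipeline.run_end_to_end` executes genome → population → qPCR series →
long reads → spanning genotyping → short reads → masked depth → screen →
kinetics from one config (JSON or TOML, unknown keys rejected with an
exhaustive error list).  The master seed derives one child seed per stage
through `numpy.random.SeedSequence`, making runs bit-reproducible; the
report pairs every estimate with its truth and carries a config hash.
Every generator is deterministic given its seed.

Default problem sizes (demo config: a 14 × 2.0-kb array in a 45-kb
chromosome, 120 long reads with median 35 kb, 25× short-read depth,
population cap 300 over 30 generations) are chosen so a full run completes
in seconds while leaving dozens of spanning reads and thousands of placed
short reads per estimate; all sizes scale up through the config.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the estimators assume:
uniform read starts (hence enumerable spanning probabilities), substitution
-only errors, identical (or mildly diverged) unit copies, i.i.d. random
background.  It does not emulate nanopore indel/homopolymer error
structure, coverage or GC bias, chimeric reads, real repeat families
(Ty/rRNA), or sequence-level BIR intermediates (strand invasion, template
switching).  Passing tests therefore demonstrate correctness of the
algorithms under their stated model, not end-to-end performance on real
sequencing runs; on real data the identity floor, edit budget and gap
tolerance are the knobs that absorb the richer error structure.

## Numerical choices

- seeds: k = 15 (anchors/units), k = 21 (placement); both configurable.
- chain slack 20 bp; gap tolerance max(k + 5, 0.1 · unit length).
- identity floor 0.8 for anchors; placement edit budget 0.1 · length.
- curve fits: `scipy.optimize.curve_fit` (TRF) with k ≥ 0, tolerances
  1e−15, X0 ≥ 1e−9; initial k from the endpoint secant of 1/X.
- ploidy thresholds strict; mode ties broken toward the smaller count;
  bootstrap CIs are percentile 2.5/97.5.
- all randomness flows from `numpy.random.default_rng(seed)`; no global
  state.
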