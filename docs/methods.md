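# Methods

This note documents the models, conventions and numerical choices behind
`structsignal`, in the order a dataset flows through the pipeline.

## Structure-annotated alignments

A matrix is an aligned FASTA over IUPAC nucleotides plus `-`; `U` is folded
to `T` on input.  The secondary structure is a dot-bracket mask of the same
length: `(`/`)` columns are the two sides of helices (stems), `.` columns
are unpaired (loops).  Bracket matching is done with a stack over the mask;
unmatched brackets are *not* an error — they are recorded as orphan paired
columns, because real matrices can contain half a helix when one strand was
not sequenced, which also makes an odd total paired count legal.  Orphans
are demoted to unpaired in written structure files (with a warning) so
downstream inference tools see a consistent pairing list.

Regions of ambiguous alignment (RAAs) are column spans whose positional
homology is not defensible; their subclasses (expansion/contraction,
non-pairing ambiguous, slipped-strand compensation) are recorded as block
metadata but processed identically.  Spans come from a sidecar TSV
(`block_id  start  end  [subclass]`, 0-based half-open) or, alternatively,
from a lowercase-residue convention auto-detected in the sequence rows.
Internally all coordinates are 0-based half-open; every written report is
1-based inclusive.

Site-pattern counting ignores gaps and ambiguity codes as states: a column
with one real state (plus any gaps/ambiguity) is constant, a
parsimony-informative column has at least two states each in at least two
taxa, and everything else variable-uninformative.  A `strict_constant`
switch additionally requires constant columns to be gap-free; the default
(lenient) convention is a deliberate choice where external tools differ.

## Composition diagnostics

Base counts are over ungapped positions, ambiguity codes contributing to
length but not to counts.  The tetrahedral embedding sends the four unit
compositions to the vertices of a regular tetrahedron centered at the
origin (vertices (1,1,1), (1,−1,−1), (−1,1,−1), (−1,−1,1)/√3); being
affine, it preserves convex combinations, which is the property the tests
pin.  GC-vs-length association uses Spearman's rho (mid-ranked ties,
t-approximation p-value) since no linearity is assumed.  The stationarity
test compares each taxon's composition to the pooled composition of all
taxa: chi² = Σ (o−e)²/e with e = taxon total × pooled frequencies, df = 3,
flagged at p < 0.05.  A leave-one-out pool and a pseudocount (for bases
absent from the pool) are available behind flags; pooled-with-self is the
default because the conventional tool chain does not document its choice.

## Saturation (Iss)

Per-column Shannon entropy (bits) is computed over observed unambiguous
states.  Iss is mean site entropy divided by the expected entropy at full
saturation for the observed taxon count and global base frequencies.  That
finite-sample expectation is estimated by Monte Carlo (default 10,000
i.i.d. columns, seeded) rather than a closed-form correction, because the
published finite-sample formulas exist in several variants; the MC estimate
is exact in the limit and reproducible under seed.  Identical sequences
give Iss = 0; an i.i.d. alignment gives Iss ≈ 1.

Critical values Iss.c are estimated by simulation: alignments are evolved
under Jukes–Cantor on a four-group topology (balanced quartet of clades,
or a ladder for the asymmetric shape) over a geometric ladder of divergence
depths; topology recovery is judged by the four-point condition on mean
inter-group JC-corrected distances; recovery probability is made monotone
by a running minimum and the Iss at the 0.95 recovery crossing is linearly
interpolated.  This reproduces the external tool's critical values only
approximately, which is sufficient for the below/above-critical verdict.
The test statistic compares Iss to Iss.c with a t-test whose standard error
comes from the among-site entropy variance.

## RAA rescue

Each RAA block is reduced to per-taxon ungapped subsequences and realigned
from scratch.  The aligner is progressive: profiles are merged in the
guide tree's postorder, each merge solved exactly by affine-gap (Gotoh)
dynamic programming where a profile-column pair is scored by the mean
pairwise cost of its residues.  The cost regime defaults to gap opening 4
with gap extension and substitution both 1; a gap of length k costs
open + k·extend (the opening surcharge is on top of the first extension —
the convention is mirrored by the brute-force oracle used in tests).  Ties
prefer the match move, then a gap in the first profile, giving
deterministic leftmost gap placement.  Taxa with empty subsequences join as
all-gap rows after alignment.  With several guide trees (e.g. a posterior
credible set) every guide is tried and the minimum sum-of-pairs-cost
alignment kept, ties broken by input order, all candidate costs logged —
an objective, deterministic reconciliation the source workflow leaves
unspecified.

Masking follows the Monte-Carlo random-similarity idea: for each taxon
pair, per-column scores (+1 match, −1 mismatch or any gap) are summed over
a sliding window (default 7).  The pair's null distribution pools window
scores from `reps` composition-preserving shuffles of both rows; an
observed window is non-random when it exceeds the null's 0.95 quantile.  A
site's pair profile is +1 when most windows covering it are non-random;
the consensus profile is the mean over pairs, and columns with positive
consensus are kept.  Exact reproduction of the external masking tool's
output is not promised — the scoring scheme and window default follow its
published description.

## Likelihood mapping

Quartet log-likelihoods are computed under GTR(+discrete-Γ, 4 categories)
with fixed model parameters (the intended workflow estimates them once on
the full matrix externally).  The rate matrix is normalized to one expected
substitution per unit length and exponentiated through the symmetrized
eigendecomposition; leaf ambiguity and gaps are marginalized via partial
likelihood vectors.  The five branch lengths of each of the three quartet
topologies are optimized by coordinate descent with bounded Brent searches
(floor 1e−8, ceiling 20, tolerance 1e−6, up to 10 sweeps).  Weights are
the normalized likelihoods; the simplex is partitioned into seven regions
as the Voronoi cells of the three corners, three edge midpoints and the
centroid — a clean geometry whose anchors (corner → resolved, centroid →
star, edge midpoint → partly resolved) match any published variant of the
method; boundary ties resolve to the lowest region id.  All quartets are
enumerated when at most 50,000 are possible (or `n_quartets` covers them);
otherwise a seeded uniform sample is drawn.  In cluster mode one taxon is
drawn per cluster and corners are labelled by cluster pairings, so corner
fractions answer which grouping hypothesis the data support.

## Split systems and internode certainty

Splits are canonicalized as the side not containing the first taxon;
trivial splits are excluded.  Compatibility is the four-intersection rule.
Consensus-network export writes a TAXA + SPLITS NEXUS block (weights =
frequencies, default filter 0.1) for external splits-graph viewers;
drawing is deliberately out of scope.  For a reference internode with
frequency f1 and strongest incompatible split f2:
IC = 1 + p1·log₂p1 + p2·log₂p2 with p_i = f_i/(f1+f2), negated when
f2 > f1; ICA generalizes over the reference split plus all incompatible
splits with frequency ≥ 0.05 (configurable), with log base k = size of
that set.  TC/TCA are sums over internal reference edges; the relative
forms divide by n − 3.  A reference edge never observed and never
contradicted is degenerate and scored 1 with a warning.

## Relative rates and trace comparison

For each tree of a posterior sample the reference clade's MRCA is
recomputed and each terminal's depth is the branch-length sum on the
MRCA-to-tip path.  Credible intervals are equal-tailed (default 95 %; HPD
was deliberately not used — "credible interval" without qualification is
read as equal-tailed).  A terminal is flagged as a rate outlier when its
interval misses the leave-one-out envelope of the other terminals'
intervals; a stricter pairwise-overlap mode is available.  Flags are
invariant to uniform branch-length rescaling.

The log harmonic mean of sampled likelihoods is computed in log space
(−logsumexp(−lnL) + log n).  AICM is pinned to 2·var(lnL) − 2·mean(lnL)
with the sample variance; this variance-penalty convention gives −2c for a
zero-variance trace at c and shift-equivariance Δ = 2s, both asserted in
tests.  Its SD comes from a seeded bootstrap over trace samples.  Trace
files are tab-separated with named columns; a bracketed first line
(MrBayes `.p` style) is skipped and the first 10 % of rows discarded by
default.

## Synthetic data

The generator emulates what the real matrices show, at desk scale:

* **Trees**: seeded birth–death (default 32 taxa, pure birth), rescaled so
  the mean root-to-tip path is 0.5 substitutions/site — a realistic
  overall divergence for an alignable rDNA matrix and one at which the
  stem/loop partitions stay below their saturation critical values.
* **Stems** (default 60 pairs): each doublet starts complementary; on each
  branch the pair is fully coupled with probability q = 0.9 (every
  substitution compensated by the partner) and evolves independently
  otherwise.  This event-coupled construction was chosen over a 16-state
  doublet rate matrix because consumers need realized compensation
  frequencies, not a normalized doublet likelihood; the truth record
  tallies changed and pair-preserving branch events.
* **Loops** (default 120 columns): i.i.d. GTR+Γ with A-rich stationary
  frequencies (π_A = 0.4) and shape 0.5.
* **RAAs** (default 3 blocks of base length 30): substitutions plus a
  Poisson indel process (geometric lengths, uniform positions) confined to
  the blocks, so RAAs carry essentially all length variation.  Per-taxon
  deletion-rate multipliers and terminal-branch composition overrides
  exist to plant GC–length covariation.
* **Tree sets**: bootstrap-like sets plant an internode at frequency f1
  against a chosen nearest-neighbour alternative at f2 (remainder spread
  over other one-swap alternatives); posterior-like samples apply lognormal
  branch jitter and per-lineage multipliers on a fixed topology.

What the generator does **not** emulate: thermodynamic folding, helix
numbering, alignment-to-structure conflict, base-composition
non-stationarity across lineages, autocorrelated rates, or real taxon
sampling.  Passing tests therefore demonstrate algorithmic correctness and
recovery of planted signal under idealized conditions, not robustness to
every pathology of real rDNA.

## Problem sizes and determinism

Defaults are sized for a single CPU: the test suite runs in well under a
minute and the acceptance script in under a minute (32-taxon matrices,
70-quartet exhaustive mappings on 8 taxa, 1000-tree bootstrap sets,
500-tree posterior samples, 200-shuffle masking).  Every stochastic
routine takes an explicit seed and is bit-reproducible under it; the
acceptance script derives all randomness from its `--seed` argument.

## Known limitations

* The affine aligner is exact per profile merge but progressive overall:
  no iterative refinement, no consistency scoring.
* Iss.c is a reduced-replicate simulation estimate; very short alignments
  give large, noisy critical values (reported as-is, not clamped).
* Likelihood mapping fixes the substitution model; it does not re-estimate
  GTR parameters per quartet.
* ICA ignores conflicting splits below its threshold; the sign convention
  follows the most-frequent-conflict rule.
* All trees in a set must share one leaf set; partial-overlap supertree
  situations are unsupported.
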