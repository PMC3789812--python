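# Methods

This note documents the models behind octadkit, their assumptions, the
defaults that matter, and the numerical and design choices made where the
underlying biology or literature leaves the procedure open.

## The octad data model

An octad is an 8-spored ascus in which each of the four meiotic products
has undergone one mitotic division, so the spores form four genotypically
identical sister pairs. Spores carry positional labels A–H along the
ascus; the order is physically meaningful only for *linear* asci (in
*S. japonicus* roughly a fifth of asci are discernibly linear, a
consequence of polar mating). Tables are one-spore-per-row TSV; cross
definitions are YAML listing, per marker: chromosome, arm, distance from
the centromere in centimorgans, and the allele symbol carried by each
parent. Coordinates are purely genetic — no base-pair positions anywhere.

Internally alleles are handled by parent of origin (parent 1 vs parent 2),
which makes parental-ditype/nonparental-ditype classification unambiguous
regardless of the display symbols (`P`/`M` for *mat1*, `+`/`−`
elsewhere). In the packaged fixture, parent 1 is Sjk10
(*mat1-P*, *ade6⁻*, *ura4⁻*, *mrc1* intact) and parent 2 is Sjk19
(*mat1-M* and prototrophic/`+` at the other three columns). The `+`
symbol in the *mrc1* column is taken to denote the *mrc1Δ::Nat*
cassette (nourseothricin resistance) carried by Sjk19; the source table
does not state the polarity, and this is the only reading under which the
columns are parent-consistent. Dead spores in the fixture keep the
genotypes recorded alongside the original table (deduced there by sister
matching); the package always re-deduces them from the live spores and a
test asserts the two agree.

## Sister matching and dead-spore imputation

Matching is multiset-parity driven: every genotype class must occur an
even number of times among the eight spores, so a live class with odd
multiplicity donates its genotype to a dead spore. Consequences:

- more odd classes than dead spores → no pairing exists (consistency
  error naming the ascus);
- dead spores beyond the odd classes come in pairs; one such *spare* pair
  is a whole dead sister pair whose genotype is unrecoverable — it is
  kept with unknown genotypes and the pairing is flagged *ambiguous*;
  two or more spare pairs are rejected as unresolvable;
- when two or more dead spores would receive two or more distinct
  genotypes, the genotype *multiset* is forced but the position
  assignment is not; the pairing is flagged ambiguous.

Ambiguous asci are excluded from position-sensitive statistics (the
discordance count) but still reduce to a tetrad when their product
multiset is complete. The within-class pairing of positions is arbitrary
(taken in A–H order); no downstream statistic depends on it. This rule
set generalises conservatively from tables whose asci carry at most one
dead spore each.

## Tetrad analytics

Octads reduce to tetrads (the four pair genotypes), checked for 2:2
segregation per marker. For a marker pair, a tetrad is PD when only the
two parental two-locus combinations occur, NPD when only the two
recombinant combinations occur, and TT otherwise. Map distance uses the
classical Perkins estimator, 100·(TT/2 + 3·NPD)/n cM, with no
interference correction; its known downward bias at large distances under
the Haldane model is a property of the estimator and is documented, not
"fixed" (the simulation studies therefore compare estimates against the
*Haldane-implied Perkins expectation*, computed from the closed-form
class probabilities, rather than against the nominal distance). The
linkage test is the standard PD-vs-NPD chi-square with 1 df against the
no-linkage expectation PD = NPD, α = 0.05 by default. Marker pairs are
reported independently with raw p-values; no multiple-testing correction
is applied.

The delta-method standard error reported for the Perkins estimate treats
(PD, NPD, TT) as one multinomial sample; it is the standard error of the
per-tetrad score {PD→0, TT→50, NPD→300} cM.

## Adjacent-pair discordance and arrangement models

For a linear ascus the four adjoining pairs are fixed to
(A,B), (C,D), (E,F), (G,H); a pair is discordant when the genotypes
differ at one or more markers. Asci with imputed dead spores are
included (the deduced genotype occupies the dead spore's position);
only ambiguous imputations and non-linear asci are excluded, and they are
listed with reasons.

Arrangement models map the four meiotic nuclei (1a, 1b from meiosis-I
pole 1; 2a, 2b from pole 2) to spore positions:

- `linear_ordered` — second-division spindles in line, mitotic daughters
  adjacent: sisters occupy exactly the adjoining pairs, so the null
  discordance is *identically zero*. The test against this model is
  exact (degenerate null; p = 0 whenever any discordant pair is
  observed) — no Monte-Carlo is wasted on it.
- `parallel` — spindles side by side (nucleus order 1a, 2a, 2b, 1b),
  daughters adjacent; the ascus *ends* carry non-sisters, but adjacent
  pairs are still sister pairs, so adjacent discordance is also zero.
- `random_nuclei` — nuclei shuffled, daughters adjacent: adjacent
  discordance is again zero. Distinguishing this model from
  `linear_ordered`/`parallel` requires non-adjacent statistics, which is
  why both "random" variants are exposed rather than one.
- `random_spores` — all eight spores shuffled. For an ascus whose four
  products are all distinct, the per-pair concordance probability is
  1/7 (the matching sister is 1 of the 7 remaining spores; confirmed by
  exhaustive enumeration of the 2520 arrangements), i.e. a mean
  discordant fraction of 6/7.

For stochastic models the null distribution of the table-level
discordant-pair count is simulated under the fitted cross configuration
with the same number of asci, and the p-value is the add-one upper-tail
proportion (b+1)/(m+1).

Observed discordance strictly between zero and the fully shuffled
expectation — as with 21/36 ≈ 0.58 against a `random_spores` mean of
0.78 on the packaged fixture — is reported as model-comparison output;
the package deliberately draws no hard-coded conclusion about partial
order.

## The meiosis simulator

Crossovers follow the no-interference model: per chromosome arm, the
crossover count in the four-chromatid bundle is Poisson with mean 2·d
(d = arm length in Morgans), each crossover joins one uniformly chosen
chromatid per homolog, and there is no chiasma or chromatid
interference. Meiosis I segregates centromeres, meiosis II chromatids;
two-locus recombination fractions then follow the Haldane map function
r = ½(1 − e^(−2d)), and a marker at 0 cM never shows second-division
segregation.

Implementation: rather than placing crossovers, the simulator propagates
the four chromatids' parental-origin vector outward from the centromere
as the exact 6-state Markov jump process this model implies; interval
transition matrices are matrix exponentials of the single-swap generator,
so arbitrarily spaced markers are exact and the whole simulation is
vectorised. A unit test pins the transition matrix against brute-force
enumeration of all 4^k crossover chromatid choices. The same chain gives
closed-form PD/NPD/TT probabilities at any distance (mixing the
per-crossover class walk over the Poisson count), used as the oracle for
simulator calibration and for recovery expectations.

Packing, viability and reproducibility are described in the module
docstring; the key contract is that each ascus consumes a fixed budget of
uniforms drawn row-wise from a single PCG64 stream, so ascus *i* depends
only on (seed, i) — identical configurations reproduce byte-identical
tables and growing `n_asci` never reshuffles earlier asci. Spore death
is uniform and independent per spore with no genetic cause; real spore
inviability (e.g. from aneuploidy) is not modelled. All simulated asci
are treated as linear; the minority status of linear asci in real
dissections affects yield, not the statistics computed here.

Default marker placement in the packaged cross mirrors the fixture's
genetics: *mat1* (chr 1, 1 cM) and *ade6* (chr 2, 1 cM) tightly
centromere-linked, *mrc1* on the other arm of chromosome 1 at 47.2 cM so
that the additive *mat1*–*mrc1* separation equals the 48.2 cM Perkins
estimate from the 38:7:39 tally, and *ura4* (chr 3, 30 cM) placed
mid-arm in the absence of a reported position.

What passing simulator-backed tests shows is internal consistency with
the Haldane model and the packing geometry — not that real
*S. japonicus* meiosis lacks interference, nor anything about real
viability patterns.

## Growth curves

The generator produces lag (flat), exponential growth at the stated
doubling time, and logistic saturation at the carrying capacity, with
multiplicative log-normal noise (`noise_sd` ≈ relative error).
Defaults — initial density 0.01, lag 60 min, capacity 8 (OD-like,
unitless), readings every 15 min for 12 h — describe a typical shaken
rich-medium culture followed into stationary phase.

The fitter regresses log2(density) on time. With an explicit window any
length ≥ 2 is accepted (and slope ≤ 0 raises a no-growth error). The
automatic window search is two-pass: first the noise floor is estimated
as the smallest residual variance among all 8-point windows (the
straightest stretch of the curve); then all windows of ≥ 4 points with
positive slope and r² ≥ 0.98 whose residual variance is at most 4× the
floor compete, and the longest wins (ties: higher r², then earlier
start). The two guards exist because each simple rule fails on sigmoid
data: "maximise r²" degenerates into a lottery among lucky 4-point
windows once readings are noisy (measured mean recovery error 6.4% at a
63-min truth), while "longest window above the r² gate" swallows the
entire sigmoid, whose r² is deceptively high (0.984; 13% error).
Anchoring acceptance to the empirical noise floor recovers 63- and
93-minute truths with ≈ 2–2.5% mean error at 2% noise and reproduces
noiseless exponentials exactly. The selected window is always reported.

The residual ≈ +2% bias at default settings comes from logistic shaving:
the true local rate is slightly below the nominal exponential rate
everywhere past the lag, so any honest window slightly underestimates the
slope. Published generation times for these organisms are therefore
recovery targets on synthetic data here — the raw readings behind them
are not available — and recovery, not reproduction, is what the tests
demonstrate.

## Problem sizes in the test suite

The suite calibrates the simulator at 50,000 meioses per distance,
checks shuffled-arrangement concordance on 10,000 asci, estimates
Perkins recovery as the mean of 25 replicates of 2,000 tetrads per
distance (a single 2,000-tetrad draw has ≈ 1.2 cM Monte-Carlo standard
error at 30 cM, so replicate means are the meaningful recovery
quantity), runs the type-I-error check at 100 tetrads × 400 replicates
against a ±3-SE binomial band around the nominal 5%, and averages growth
recovery over 100 seeds per truth. The whole suite runs in well under a
minute on one core.

## Known limitations

- No crossover or chromatid interference models; no gene conversion; no
  mating-type switching, imprinting, or diploid intermediates beyond a
  single meiosis.
- Second-division-segregation frequencies exist only in the simulator's
  truth channel: because real *S. japonicus* asci are unordered, SDS
  cannot be read from observed spore order, and the package deliberately
  offers no gene–centromere estimation from real data.
- The iodine multilocus model assumes fully penetrant, equally
  contributing, unlinked loci with an all-or-nothing requirement; the
  continuous estimate and nearest-integer reading are both reported and
  neither is asserted as the true locus count.
- Growth fitting assumes a single exponential phase; diauxic or biphasic
  curves will yield a window covering only one phase.
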