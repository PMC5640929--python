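# Methods

## Replication model

During steady-state exponential growth, bidirectional forks leave the
replication origin at equal speed and stop at the terminus. A locus whose
replication fraction is `a(x)` — the arc distance from *ori* toward *ter* on
the locus's replichore, normalised by that replichore's length — has relative
copy number

    n(x) = r^(1 - a(x)),   r = ori:ter copy-number ratio = 2^(C/τ),

which is the exact steady-state form for an exponential culture: `n(ori) = r`,
`n(ter) = 1`, log-linear on each arm. Unequal arm lengths (a terminus off the
antipode, as in inversion mutants) give unequal slopes and a kink — a shift
point — at *ter*. For biologically plausible ratios (`r ≤ 3`; growth that
would exceed a three-fold ori:ter difference is not compatible with the
single-round replication picture) the exponential is close to linear, which is
why per-contig straight-line fits summarise the gradient well. The simulator
also offers `shape="linear"` (`n(x) = 1 + (r-1)(1-a(x))`): under it, binned
depth of any within-arm contig is *exactly* collinear, so least-squares fits
are exact sufficient statistics and recovery can be tested against closed-form
oracles without model-mismatch bias.

Sequencing depth is `depth_at_ter · n(x)`, optionally Poisson-sampled per
base. No GC bias, mappability structure, repeat families or read-level
artefacts are modelled; passing tests therefore demonstrate correctness of the
arrangement logic under the replication model plus counting noise, not
robustness to mapping artefacts in real libraries.

## Arrangement algorithm

Per contig, depth is averaged in consecutive bins (default 1,000 bp; a
trailing bin of at most half the bin size merges into its neighbour) and an
ordinary least-squares line is fitted to bin depth versus bin midpoint.
Contigs shorter than `min_fraction` (default 1%) of the genome size — taken as
the sum of contig lengths unless an expected size is supplied — are excluded:
their slope cannot be estimated reliably. The fitted line's predicted depths
at the two contig ends (`cov_start`, `cov_end`) are the only quantities the
arranger uses; junction continuity between *fitted end depths*, rather than
contig means, is what makes the reconstructed gradient continuous and places
long contigs correctly.

The greedy reconstruction: orient all contigs to non-positive slope; the
highest-mean contig is the base. The descending branch repeatedly appends the
remaining contig minimising the junction delta
`|cov_end(tail) − cov_start(candidate)|`, subject to
`cov_start(candidate) ≤ cov_end(tail) + slack`, with `slack` defaulting to 5%
of the base contig's mean coverage. The branch switches (once) to ascending
when descending is stuck, or when the best descending and best ascending
continuations are *the same contig* and the ascending junction is strictly
better — the signature of the terminus, where appending that contig
reverse-oriented would merely absorb an ascending-branch contig into the
descending branch. After the switch, remaining contigs are re-oriented to
non-negative slope and appended by the same delta rule. Everything is placed;
ties break by longer contig, then lexicographic id. The output is defined up
to a global mirror (reverse the order, flip every orientation); the base rule
makes it deterministic, and the evaluation metrics treat mirrors (and
rotations of the circular chromosome) as equivalent.

Orientation ambiguity. A contig's orientation is read from its slope sign only
when that sign is trustworthy: when the predicted depth change across the
contig exceeds `max(zero_slope_tolerance, slack)` (below that, the two
orientations are indistinguishable at junction-matching scale) and the fit is
reasonably linear (`r² ≥ 0.5`; a contig straddling *ori* or *ter* has a tent-
or valley-shaped profile whose net slope is meaningless). Ambiguous contigs
try both orientations at insertion time and take the one minimising the
junction delta; an ambiguous *base* contig is oriented jointly with its first
junction.

Identifiability limits. No coverage-only method can orient a contig that
straddles a replichore end symmetrically: its profile is (nearly) invariant
under reverse complement. The simulator therefore places its linearization cut
at *ori* by default (`first_cut="ori"`), and `cut_sites` can force further
deterministic boundaries (the exact-recovery tests add *ter*), keeping the
recovery problem well-posed; `first_cut="random"` restores the fully
unconstrained case for robustness studies. Likewise, two contigs from
*opposite* arms whose junction depths coincide cannot be told apart by depth
continuity; under the exponential shape the line fit's extrapolation bias
(order 0.2 depth units at 100X) widens that confusion window slightly, which
is the dominant error mode seen in noisy simulations.

## Gradient diagnostic

`ratio_high_low` is the 90th over the 10th percentile of contig mean
coverages; `frac_sloped` is the fraction of contigs whose fitted depth change
exceeds twice its standard error. `clear_gradient` requires ratio ≥ 1.3 and
frac ≥ 0.5; ratio < 1.1 is `no_gradient` (stationary-phase sampling — the
arrangement is then uninformative); anything between is `weak_gradient`. The
thresholds are package choices exposed in the config; the biology fixes only
the qualitative exponential-versus-stationary contrast.

## Validation metric

The genome coverage rate compares the arranged and the correct contig order
through a dot-plot-style collinearity measure computed internally (no external
aligner): k-mers (default k = 31, odd so reverse-complement palindromes cannot
occur) whose canonical form is unique in both sequences become anchors
carrying a strand; anchors contiguous on one diagonal and strand form
collinear blocks; the best chain of blocks whose reference intervals increase
with query position — allowing one wrap, because the reference chromosome is
circular — gives the covered reference fraction, evaluated for the query and
its reverse complement (mirror invariance) and taken as the maximum. Spacer Ns
between contigs contain no valid k-mers and contribute nothing. The reported
rate is `100 × coverage(arranged) / coverage(correct)`; values slightly above
100 are possible and reported as-is. On unique-sequence genomes this agrees
with alignment-based dot-plot coverage; on repeat-rich genomes the anchor
density drops where sequence is non-unique, so absolute coverages (not the
ratio) would read lower than an aligner's. The negative control shuffles
contig order and orientation uniformly (default 100 replicates, seeded) and
reports the mean and standard deviation of its coverage rates.

Truth-based accuracies for simulations: adjacency is the fraction of adjacent
pairs in the arrangement that are adjacent on the true circle (unordered,
hence rotation- and mirror-invariant); orientation accuracy is the fraction of
contigs whose strand matches truth, maximised over the two mirror images.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `bin_size` | 1000 | bp | ≥ 10 bins on the smallest kept contig of a ~4 Mb genome at the 1% filter |
| `min_fraction` | 0.01 | — | short contigs carry no usable slope |
| `slack` | 0.05 | fraction of base coverage | junction-noise tolerance; ~5 depth units at 100X |
| `zero_slope_tolerance` | 1.0 | depth | below this predicted depth change a slope sign is noise |
| `ambiguity_r2` | 0.5 | — | flags tent/valley (replichore-end-straddling) profiles |
| `k_anchor` | 31 | nt | unique on desk-scale genomes, standard long-k-mer choice |
| `null_reps` | 100 | — | the negative-control design |
| `spacer_n` | 100 | bp | visible gap; contributes no anchors |
| `copy_ratio` | 2.0 | — | mid-exponential sampling; ≤ 3 in all defaults |
| `depth_at_ter` | 100 | reads/base | the depth regime the method needs |

All randomness flows from explicit integer seeds (`numpy.random.Generator`);
the CLI fans one global seed into per-stage seeds by fixed offsets, and every
run directory receives the verbatim config for bit-identical re-runs.

## Problem sizes used in the shipped experiments

The reproduction script and the test-suite run desk-scale versions of the
original 4.2 Mb experiments: 150–300 kb circular genomes, 5–20 contigs
(12–15 for the headline run, matching the "just over a dozen" regime), Poisson
depth 5–100X, 10 replicate seeds per condition, and a 100-replicate shuffled
null. At these sizes the full pipeline runs in a few seconds per dataset; the
method itself scales linearly in genome length and quadratically (trivially)
in contig count, and its documented envelope is ≲100 contigs on a single
replicon at ≳100X depth.

## Known limitations

- Single replicon only: plasmids/multiple chromosomes violate the one-V
  assumption and must be separated beforehand.
- Requires exponential-phase sampling; the diagnostic flags flat profiles but
  cannot rescue them.
- Arm assignment of depth-coincident contigs and orientation of
  replichore-end-straddling contigs are unidentifiable from coverage alone
  (see above); real assemblies add repeat/mapping noise the simulator does not
  model.
- No sequence-overlap detection or gap closing: the pseudo-molecule is an
  ordering hypothesis, not a finished genome.
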