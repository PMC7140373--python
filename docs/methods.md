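# Methods

## Model

The model treats methylation-induced CpG decay as the only mutational
force acting on dinucleotide composition. Its assumptions are: (i) all
CpG loss is caused by cytidine methylation (so the CpG deficit relative
to the assumed initial state counts the events); (ii) the decay rate is
independent of the CpG's sequence context (flanking bases only
redistribute the collateral changes, they do not modulate the rate);
and (iii) the total number of dinucleotides is conserved — every change
matrix has entries summing to zero, which is checked structurally in
the tests. All other mutations are taken as compositionally neutral:
whatever a C→A mutation does somewhere, an A→C elsewhere is assumed to
undo in expectation.

A forward-strand event NpCpG→NpTpG destroys one CpG and one NpC and
creates one TpG and one NpT; a reverse-strand event, read on the
forward strand as CpGpM→CpApM, destroys one CpG and one GpM and creates
one CpA and one ApM. Averaging over the flank distributions
(P_A..P_T for N, P′_A..P′_T for M) gives the 4×4 per-event matrices D
and D′, and an H-event budget split evenly across strands gives
Q = (H/2)(D + D′). One sign in D′ deserves note: the (G,T) entry is
−P′_T, since a CpGpT→CpApT event destroys a GpT; with that sign D + D′
has the closed form asserted entrywise in the test suite (in particular
(A,C) = P′_C − P_A and (G,T) = P_G − P′_T, the two entries whose sign
depends on the estimated parameters).

Two denominators coexist deliberately. Proportion shifts divide Q by
the total dinucleotide count N (which is L − 1 on a gap-free single
sequence), while the expected GC content divides H by the base count L:
each event removes exactly one C-or-G base from L bases, but shifts
dinucleotide counts out of N windows. At genome scale N/L → 1 and the
distinction is invisible; at toy scale it is kept exact.

By construction the expected CpG proportion equals the observed one
(the budget is defined by that deficit), expected proportions always
sum to 100%, and the prediction is linear in H. H is kept real-valued;
nothing downstream needs integrality. A negative H (observed CpG above
the assumed initial CpG, e.g. when running a GC_ini = 40% scenario on a
mammalian genome) violates the model's premise; the package warns and
proceeds rather than refusing, so counterfactual initial states can
still be explored.

## Parameter estimation

The trinucleotide method is the default: P_N is the share of NpCpG
among all NpCpG trinucleotides and P′_M the share of CpGpM, each
quadruple estimated independently on the forward strand (real genomes
are only approximately strand-symmetric; on an exactly strand-symmetric
input the complementarity relations P_A = P′_T etc. hold exactly, and
the tests verify this). The GC method sets all eight parameters from
the GC fraction p alone (A/T flanks (1−p)/2, C/G flanks p/2); it is
kept as the crude fallback because cumulative CpG decay changes the GC
content over time, biasing p relative to the historical value — the
trinucleotide method should be preferred.

CpG islands are excluded before estimation because they are typically
unmethylated: their flanking-base statistics describe sequence that
does not experience the modelled mutation channel. Coding-region
exclusion is not built in (the CpG fraction inside coding sequence is
small enough that its effect on flank shares is marginal); any BED mask
can be supplied and is united with the island mask.

## CpG-island detection

The detector implements the classical three-threshold definition —
length over 200 bp, GC content over 50%, observed/expected CpG ratio
over 0.6, all strict — as a deterministic scan: a 200 bp window slides
at step 1, qualifying window starts are flagged, sustained runs of
flagged starts are extended to window ends, merged when separated by
less than a window, and greedily trimmed (removing whichever terminal
base best restores the failing criterion) until the region as a whole
passes every threshold.

A run is only promoted to a candidate when it spans at least one full
window of consecutive flagged starts. This is a deliberate specificity
choice: on i.i.d. sequence the O/E ratio hovers near 1 and the GC
threshold alone gates detection, so isolated qualifying windows are
~3σ background fluctuations that occur every few kilobases at genomic
GC levels; requiring sustained signal suppresses them entirely while
keeping any homogeneous island longer than about 2·window − 1 ≈ 400 bp
detectable. Consequences: the detection floor is ~400 bp rather than
the nominal 201 bp, and reported coordinates are not expected to match
any particular external island-finder base-for-base (the thresholds are
standard; window, step and merge behaviour are this package's own).
Whole-region O/E uses per-region counts with the raw region length as
denominator; GC uses the ungapped length.

## Synthetic data and the simulation oracle

`generate_genome` draws i.i.d. bases at a configurable GC content —
exactly the model's initial-state hypothesis, realizing the product
form in expectation — optionally with embedded tandem-CG blocks to
stand in for islands. `simulate_cpg_decay` then applies the modelled
channel literally: each event picks a surviving CpG uniformly and
flips its C→T or its G→A with a fair coin (the fair coin is the
strand-symmetry argument behind the H/2 factor). Neither substitution
can create a CpG, so each event removes exactly one, changes exactly
one letter, and conserves length and dinucleotide count.

`oracle_check` closes the loop: it compares empirical per-dinucleotide
count changes against Q with H = the event count, scaled by an exact
per-event variance computed by enumerating the eight branch×flank
outcomes. The closed-form model ignores event interactions (one event
can consume another's context), so agreement is asserted only in the
sparse regime (events/base ≤ ~0.02), at 4σ. The default validation
runs 2,000 events on a 200 kb genome — large enough that every pooled
class moves several σ from zero, small enough to stay sparse and keep
the whole suite under half a minute.

What the synthetic genomes do *not* emulate: isochore structure,
repeat families, selection, context-dependent decay rates, and real
methylome geography. Passing the oracle therefore shows the arithmetic
of Q is right and the simulator implements the stated channel — it
does not show the channel suffices to explain a real genome; that
question is what the evaluation metrics on the bundled vertebrate
tables address.

## Evaluation

ΔProportion and ΔGC are relative absolute differences normalized by
the observed value. Trend classification against the initial state
uses a tolerance of 0.005 percentage points by default — half the last
printed digit of a 2-decimal table — so that values equal at table
precision are "unchanged"; with tolerance 0 it reduces to strict sign
comparison. The paired t-test runs two-sided over the 16 dinucleotides
(15 df); when only the 10 pooled classes are available, the 16-vector
is reconstructed by splitting each complementary pair evenly (the
error is second-order in the strand asymmetry, and the reconstruction
renormalizes rounded table rows to exactly 100%). All-zero differences
give p = 1 by convention; identical nonzero differences are degenerate
and reported as p = 0 with a warning. The ten per-genome tests are
reported uncorrected, as independent per-genome summaries.

## Bundled reference tables

`mdm.data` ships the published autosomal pooled proportions/GC and the
trinucleotide-method context probabilities for 10 vertebrate genomes
at their printed precision (2 and 4 decimals). Two published expected
cells are internally inconsistent with the model's own equations: the
human expected-GC cell (printed 44.98; the GC equation gives
50 − (6.25 − 0.98) = 44.73, and the other nine genomes agree with the
equation), and the expected row for pig, whose non-GC cells duplicate
the dog row (its printed expected CpG, 1.09, cannot equal pig's
observed 1.24 as the budget construction forces). The test suite
asserts the equation-consistent values for those cells and documents
the gap; printed 4-decimal probability quadruples may also sum to
0.9999/1.0001, so parameter validation tolerates 1e-3 while estimator
output is exactly normalized.

## Numerical and interface choices

Sequences are normalized to {A,C,G,T,N} on load (ambiguity codes → N);
k-mer windows never contain N and never span contigs; only the forward
strand is counted, since the model's complementarity argument already
accounts for the reverse strand. Coordinates are 0-based half-open
throughout. Proportions are carried at full precision and rounded only
in report writers (2 decimals; probabilities 4). All randomness flows
from a single integer seed per operation, and re-running any
subcommand with identical inputs and seed is byte-identical.
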