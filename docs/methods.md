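# Methods

## The question

Given (i) a protein structure and (ii) a ranked set of D "distinguishing"
residues — positions that most distinguish a protein subgroup from its
evolutionary relatives, each tagged with a hierarchy level (0 superfamily,
1 family, 2 subfamily, 3 sub-subfamily) — does the residue set concentrate
in a structurally coherent cluster more than chance allows?  A significant
overlap is doubly informative, because the residue set is derived from
sequences alone and the cluster from coordinates alone.

Two analyses are provided.

## Predefined clusters: the ball-in-urn route

When the cluster is fixed in advance (for example, all residues contacting
a partner chain or ligand), the overlap is a ball-in-urn problem.  With
N1 = D distinguishing residues (red balls), N2 = L − D others (black), and a
cluster of n residues (the draw), the probability that at least x of the n
are distinguishing is the cumulative hypergeometric tail

    P(x, n, N1, N2) = [ Σ_{i=max(x, n−N2)}^{min(n, N1)} C(N1, i) C(N2, n−i) ]
                      / C(N1+N2, n).

`hypergeom_tail` evaluates this with exact big-integer rationals, so tails
at the 1e-30 scale keep full double precision.  Contact clusters use a
heavy-atom distance cutoff (default 4.0 Å, `--contact-cutoff`); the rule is
deliberately simple and configurable because published analyses describe
contacts only qualitatively.

## Optimized clusters: Initial Cluster Analysis (ICA)

When no cluster is given, nested clusters are grown from a start residue
and the best one is selected.  An expansion mode turns the structure into a
deterministic permutation of all L residues (the start first); marking the
pattern residues along that permutation yields a binary string with D ones,
and the cluster question becomes: are the ones clustered near the *start*
of the string?

Expansion modes:

- **Spherical (S)** — remaining residues sorted by ascending distance to the
  start (min heavy-atom distance by default; Cβ optional).
- **Core (C)** — iterative: the cluster core is the start residue R plus
  every cluster residue whose distance to its k-th closest current-cluster
  member is below R's (k = 7 by default, a value that avoids both spherical
  and tentacle-shaped growth); the non-member nearest to any core residue
  joins next.  While the cluster has ≤ k members the k-th neighbor is
  undefined and the core is the whole cluster.
- **Hydrogen-bond network (H/B)** — greedily append the residue joined to
  the cluster by the shortest donor–acceptor hydrogen bond; H uses
  sidechain–sidechain and sidechain–backbone bonds, B also
  backbone–backbone.  Residues unreachable through the network are appended
  afterwards by distance to the start so L is preserved; the recorded
  `reachable_count` bounds meaningful cuts.  With explicit hydrogens a bond
  requires H···A ≤ 2.5 Å and a D–H···A angle ≥ 120°; without them, a
  chemically typed donor···acceptor cutoff of 3.5 Å.  Bonds are ranked by
  donor–acceptor distance so results do not depend on protonation.
- **DCA (DS/DC)** — direct-coupling scores replace distances: couplings are
  converted to rank-based pseudo-distances (strongest pair = smallest
  pseudo-distance), making orderings invariant under any monotone rescaling
  of the scores.  The package consumes a precomputed score matrix; it does
  not compute couplings.

All ties anywhere break toward the smaller (chain, residue number,
insertion code) key, so orderings are deterministic, invariant under rigid
motion and under input re-ordering.

### The cut statistic

A cut at x splits the string into an initial segment (x positions, m ones)
and a terminal segment (y = L − x positions, n = D − m ones).  The two-rate
model's maximum-likelihood probability of the data is

    p = (m/x)^m ((x−m)/x)^(x−m) (n/y)^n ((y−n)/y)^(y−n),

compared against the uniform fixed-D null in which every arrangement has
probability 1/C(L, D).  Maximizing the log likelihood ratio over x alone
favors extreme cuts, because the Fisher information of the cut parameter is
larger near the ends of the string.  We therefore maximize a *flattened*
score

    S(x) = log2 p(x) + log2 C(L, D) − ½ log2( 1 / (4 t (1−t)) ),  t = x/L,

the penalty being ½·log2 of the Jeffreys information of the continuous cut
fraction (constant chosen so the central cut pays nothing; additive
constants cancel from the p-value).  Under the null the selected cut
position is then nearly uniform: simulated end-bias is ≤ 1.4× uniform in
the first and last deciles.  Cuts whose initial segment is *depleted*
(m/x < D/L) are inadmissible: enrichment of the terminal segment is not
evidence of a cluster around the start residue.  Ties go to the smaller x
(the tighter cluster).

### Exact significance of the maximized score

The number of ones among the first x positions, m_x, is a Markov chain (a
hypergeometric walk), so the null distribution of max_x S(x) can be
computed exactly: propagate the distribution of m_x forward over x = 1..L−1
and absorb probability mass whenever S would reach the observed maximum
(first-passage recursion, O(L·D), vectorized over thresholds).  The
analytic p-value is this exact tail probability; the reported `score` is
−log2 p (net bits saved after charging for model optimization), so
p = 2^(−score) holds identically and a non-positive score means p = 1.
The recursion reproduces complete enumeration over all C(8,3) arrangements
to 1e-12 and agrees with large permutation samples to a few percent.

An a-priori Jeffreys-measure summary of the effective number of cut-point
theories, N ≈ 1 + (π/2)·sqrt(D(L−D)/L), is exposed for diagnostics
(`effective_tests`); it is not used in the p-value, which the exact
computation supersedes.

Permutation p-values (`empirical_pvalue`, add-one estimator over uniform
rearrangements of the D ones) remain available as an independent check and
as the `--empirical` CLI route.

### Multiple starts

Without a focal point, every pattern residue present in the structure is
used as a start in turn (default pattern depth 25, ranked by log-odds
score) and the best raw p-value is Bonferroni-adjusted by the number of
starts actually scanned — deliberately conservative.  A focal point (a
ligand, nucleotide or atom) selects the single nearest residue as start, so
no correction applies.  Modes are corrected separately, not jointly.
Pattern residues missing from the structure (disordered regions) are
dropped from D with a warning rather than counted as terminal-segment
members.

## Synthetic data

The generators supply ground-truth inputs without any downloads:

- **Structures** — an ideal α-helix (rise 1.5 Å/residue, twist 100°, radius
  2.3 Å; consecutive Cα ≈ 3.8 Å), a cubic lattice at 3.8 Å spacing, or a
  uniform random cloud; one Cα pseudo-atom per residue (optional Cβ).  The
  statistics only see the induced orderings, so simple geometry suffices.
- **Planted patterns** — `planted_count` pattern residues drawn uniformly
  from the `ball_size` residues nearest a center (default 50, matching the
  planted-recovery study condition), the rest uniform outside; enrichment 0
  yields a uniform null pattern.  Study conditions: L = 300, D = 25, 20
  planted in a 50-residue ball for power; L = 150, D = 25 for null
  calibration.
- **Bond graphs** — explicit synthetic hydrogen-bond lists with chosen
  lengths and classes, for testing the greedy network expansion apart from
  geometric detection.
- **DCA-like matrices** — score(i,j) = −distance(i,j) + Gaussian noise,
  symmetrized; zero noise makes DCA orderings equal structural ones.

What these fixtures do *not* emulate: real sidechain packing, real
hydrogen-bond geometry at scale, missing density, alternate conformations,
or the evolutionary structure of real distinguishing-residue sets.  Passing
tests therefore demonstrate the correctness and calibration of the
statistics and algorithms, not biological performance on real structures.

## Calibration harness

`calibration_run` compares analytic and permutation p-values over a grid of
planted profiles (defaults: L ∈ {100, 200, 300}, D = 25, enrichment ∈
{0.2, 0.5, 0.8}, 24 profiles per cell).  The permutation null depends only
on (L, D), so one sample is shared per configuration; the acceptance runs
use 4×10⁶ permutations, chosen so that at empirical p = 1e-4 the
estimator's own relative standard error is ~5%.  The summary reports the
maximum relative deviation over rows with empirical p ∈ [1e-4, 0.5]; below
1e-4, permutation estimates at feasible replication counts are too noisy
for a relative comparison.  Typical maxima are 3–10%, comfortably inside
the 20% band the method targets.

## Numerical choices and degenerate inputs

- Hypergeometric tails: exact rationals (no floating summation).
- Score table, optimizer, exact recursion and permutation sampler share one
  float64 table per (L, D) (cached), so score comparisons — including the
  `≥ observed` threshold — are bitwise consistent across routes.
- D = 0 or D = L: no informative cut; p = 1 by definition.
- Exact tails are floored at the probability of the single most extreme
  arrangement; probabilities that would underflow double precision are
  reported in mantissa–exponent form by `format_pvalue`.
- altLoc conformers resolve to highest occupancy (ties → 'A'); first model
  of multi-model files by default; waters are never polymer residues but
  may serve as focal points.
- Author (file) residue numbering is used everywhere, never renumbered.
- Sequence-to-structure mapping of alignment-column patterns is
  exact-substring (constant offset) only; full pairwise alignment is
  deliberately excluded to avoid silently wrong mappings.

## Known limitations

- Distances are measured within the selected chain set only; inter-subunit
  analyses require selecting both chains explicitly.
- No protonation step is bundled: supply pre-protonated files to use the
  angle-based hydrogen-bond rule, otherwise the heavy-atom fallback is
  used.
- The predefined-contact rule is a distance cutoff, not buried surface
  area.
- Optimized-mode p-values published for specific proteins cannot be
  reproduced bit-for-bit without the original tool's exact effective-test
  formula and input structures; this package's optimized mode is validated
  by exact enumeration, permutation agreement, null calibration and planted
  recovery instead.
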