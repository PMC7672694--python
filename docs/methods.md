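# Methods

## Problem and model

The package addresses the last step of Hi-C scaffolding: given a fixed
ordering of contigs into super-scaffolds, choose each contig's orientation
$\theta_i \in \{+,-\}$. Contact frequency between two loci decays with
their 1-D separation, so the set of read-pair offsets between two contigs
is informative about which ends face each other.

Assumptions the model makes:

* **Contig order is correct.** Only orientations are re-estimated; no
  reordering or translocation is attempted, and large block inversions are
  out of scope (they leave the relative orientations of neighbors intact
  and are better fixed by manual curation upstream).
* **No gaps between adjacent contigs.** The inter-contig distance $D$ is
  the summed length of intervening contigs. Real gaps bias distances
  upward; because the same bias applies to all four orientation cases of a
  pair, decisions are fairly robust to it, but this remains the model's
  strongest simplification.
* **Contacts are independent given orientations**, and contact placement
  depends on separation only — GC content, mappability and 3-D structure
  (TADs, loops) are ignored.
* **Orientations are a priori uniform**: $P(\Theta) = (1/2)^n$, which is
  constant and does not affect the argmax.

For a contact $r=(x,y)$ between contigs $i<j$ the separation under an
orientation pair is
$d = (\theta_i{=}-\,?\,x : L_i{-}x) + D + (\theta_j{=}+\,?\,y : L_j{-}y)$;
the convention is that with $\theta_i=+$ contig $i$'s native end faces
contig $j$, and with $\theta_j=+$ contig $j$'s native start faces contig
$i$. Contact probability is $p(d)/Z_{ij}$. Substituting $x \to L_i - x$
and/or $y \to L_j - y$ shows the normalization integral
$Z_{ij} = \int_0^{L_i}\!\int_0^{L_j} p(x + D + y)\,dx\,dy$ is identical
across the four cases, so it cancels in every likelihood ratio; the code
verifies this numerically by integrating each case's own integrand
(`normalization_Z_four_cases`) rather than assuming it. Absolute $Z$
values, when requested, use the exact 1-D reduction
$Z = \int p(u)\,\mathrm{overlap}(u)\,du$ with
$\mathrm{overlap}(u) = \min(u-D, L_i, L_j, L_i{+}L_j{+}D-u)$, evaluated by
adaptive quadrature split at the curve's junction points. All probability
arithmetic is in natural-log space; pair sets can hold thousands of reads
and would underflow otherwise.

## Estimating p(d)

The decay curve differs between samples and must be estimated per dataset.
The estimator uses the intra-contig separations of the longest contig (it
observes the decay over the widest range; `compare_top_contigs` checks
that the top contigs give consistent curves):

1. Gaussian KDE of $\log_{10} d$ (Silverman bandwidth). Log-scale KDE
   handles the heavy tail; smoothing an exponential-in-log density only
   shifts it by a constant, so the fitted slope is unbiased.
2. Least-squares fit of $\log p = \log c_1 - c_2 \log d$ on
   $[d_\text{short}, K]$, with $d_\text{short} = 3$ kb.
3. Below $d_\text{short}$, a cubic polynomial in $\log d$ captures the
   rise-then-fall seen at short range in real libraries; it is shifted
   vertically to join the power law continuously at the cutoff.
4. Beyond the tail threshold $K$, $p(d) \equiv p(K)$: at large separations
   contacts are effectively random and the empirical estimate is noise.
   $K$ defaults to the third quantile (linear-interpolation definition) of
   the observed separation distances; an explicit value overrides the rule
   (command line > configuration > automatic).
5. The curve is renormalized to integrate to 1 over
   $[d_{\min}, d_\text{cap}]$ with $d_\text{cap} = 10K$. Normalization is
   cosmetic — a global constant cancels everywhere — but makes reported
   log-likelihoods reproducible.

If the fitted $c_2$ is not positive (no decay), the estimator warns and
falls back to the raw KDE curve with the constant tail; the monotonicity
property then holds only trivially. Grid resolution (512 log-spaced
points), bandwidth rule and polynomial degree are configurable
(`DistributionConfig`); defaults were chosen once on the simulated regime
and are not sensitive at the scales tested.

## The orientation HMM

Since $p(d)$ is constant beyond $K$, a contig pair whose intervening
length reaches $K$ has the same likelihood under all four orientation
cases and can be ignored. Hidden state $t$ assigns orientations to a
window of contigs; each transition introduces exactly one new contig and
requires agreement on the overlap (probability 1/2, or 0 if
inconsistent). The observation of a window is the contact sets it newly
covers: all in-range pairs inside the first window, then the in-range
pairs ending at each new contig. Every in-range pair is scored in exactly
one observation, so the best path score equals
$\log P(R,\Theta)$ and Viterbi returns the exact global argmax — verified
against exhaustive $2^n$ enumeration in the tests.

* **Fixed mode** scores pairs with $|i-j| < k$ (window arity $k$).
* **Adaptive mode** sets the window ending at contig $j$ to exactly the
  contigs whose intervening length to $j$ is below $K$: arity collapses to
  2 between long contigs and grows over runs of short ones, where
  single-pair evidence is weakest. Window arity is capped at
  `k_max` (default 10) because state count grows as $2^k$; a cap that
  drops in-range pairs is logged and recorded in the state space.
* **Tie policy**: among equal-likelihood assignments, fewest flips
  relative to the input layout, then lexicographic ($+ < -$). This makes
  refinement conservative — a contig with no informative contacts
  provably keeps its input orientation — and deterministic. The brute
  force reference decoder applies the identical policy.
* Transition/prior constants ($n \log \tfrac12$) are included in reported
  scores for fidelity to the joint probability; they cannot change the
  argmax.

Super-scaffolds are decoded independently; cross-scaffold contacts are
dropped at input time.

## Diagnostics

**Relative orientation probability matrix.**
$M_{ij} = \sum_{\theta_j} P(R_{ij}\mid\hat\theta_i,\theta_j) \,/\,
\sum_{\theta_i,\theta_j} P(R_{ij}\mid\theta_i,\theta_j)$, computed by
log-sum-exp over the pair's four-case table ($Z$ cancels). $M_{ij}=1$:
contacts with $j$ pin down $i$'s reference orientation; $0.5$: no
information (empty pair, or all contact distances in the constant tail —
both returned as exactly 0.5); values below 0.5 mean the contacts support
the flip. $M$ is asymmetric: a short contig learns much from a long
neighbor, not vice versa.

**Error metrics against a truth table** (TSV of contig, reference rank,
reference orientation — produced by the simulator, or by the user from a
whole-genome alignment; running an aligner is out of scope). A contig is
*globally* erroneous when its orientation disagrees with the reference. It
is *locally* erroneous when it is globally erroneous while both of its
scaffold-adjacent neighbors — required to exist, be in the truth table and
have strictly monotone reference ranks (order-consistent up to block
reversal) — are globally correct. This isolates single-contig
misorientations, the error class the decoder targets, from block
inversions: a reversed block of three contigs has three global errors and
no local error. Requiring the middle contig itself to be erroneous keeps
local errors a subset of global errors; scaffold-end contigs are not
eligible for the local metric but stay in the denominator, which is all
evaluated contigs. Flip confusion counts treat a performed flip as a
positive call (TP + FP = flips performed; TP + FN = truly misoriented
inputs). `error_by_length` bins the local flags by contig length.

**Per-contig confidence** reported by `refine` is the conditional
posterior of the decoded orientation with all other contigs fixed at their
decoded values, via the pairwise tables; contact-free contigs report 0.5.

## Simulator

`simulate_instance` emulates the target regime: a chromosome of
`genome_length` partitioned into contigs by a log-normal length law
(truncated below at `contig_min`; the last contig absorbs the remainder so
lengths sum exactly), uniform-random truth orientations, contact
separations drawn by inverse-CDF from $d^{-c_2}$ truncated to
$[d_{\min}, d_\text{cap}]$, left endpoints uniform, both endpoints mapped
through the truth orientations into native-frame offsets. Same-contig
pairs feed the intra-contig distance pool, cross-contig pairs the pair
sets; each input orientation is then flipped independently with
probability `flip_rate`. Everything is reproducible from the seed.

Defaults — 10 Mb genome, median 50 kb, $\sigma = 0.6$, minimum 5 kb,
$c_2 = 1$, $d \in [1\,\text{kb}, 1\,\text{Mb}]$, $10^5$ contacts, 30%
flips — mirror the short-read scaffolding datasets this method targets
(contig N50 of tens of kb; upstream pipelines commonly filter at 5–50 kb,
and keeping 5 kb contigs retains the genuinely hard cases). The analytic
expectation `expected_pair_counts` (the same overlap kernel as $Z$,
weighted by the separation density) validates the sampler.

What the simulator does **not** emulate — read-level noise, restriction
sites, duplicate reads, mapping ambiguity, GC/mappability bias, 3-D
structure, real gaps between contigs — bounds what passing tests show:
they demonstrate correctness and statistical efficiency of the estimator
and decoder under the model's own assumptions, not robustness to every
bias of real libraries. One consequence of simulated truncation: the
automatic third-quantile $K$ on these instances is small (~6–15 kb,
versus tens of kb on real data, because intra-contig separations are
capped by contig length), so adaptive windows frequently collapse to
pairwise decoding; the wider-window benefit is therefore exercised
separately with a fixed larger $K$ in the unit tests.

## Problem sizes and numerical choices

The test suite decodes ~170–600-contig instances with $10^5$ contacts and
validates Viterbi exactly on $n \le 10$ instances against $2^n$
enumeration; exponent recovery uses $10^5$ samples per fit. The
acceptance script uses the same conditions with fewer replicate seeds
(4–6 per comparison), sizes at which every reported quantity is stable to
well within its acceptance margin. Quadrature tolerances are scipy
defaults with explicit breakpoints; the four-case $Z$ check uses a
96-node tensor Gauss–Legendre rule per case. Degenerate inputs (empty
contact sets, single-contig scaffolds, all-identical distances, empty
distance pools) raise explicit errors or take documented conservative
paths rather than guessing.

## Known limitations

* The no-gap assumption understates distances across real gaps.
* $p(d)$ from a single contig inherits that contig's local biases; the
  consistency diagnostic flags, but does not correct, disagreement.
* Orientation only: ordering errors upstream both violate the model and
  corrupt $D$; the truth-table metrics exclude order-inconsistent triples
  rather than repairing them.
* Window capping (`k_max`) can drop in-range pairs in pathological runs
  of tiny contigs; dropped pairs are reported.
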