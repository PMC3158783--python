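# Methods

This note records the models behind `samotif`, the parameters that
matter, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Fragment descriptors and chain continuity

A Cα trace is cut into overlapping 4-residue windows.  Each window
(p1..p4) is summarised by d13 = |p1−p3|, d14 = |p1−p4|, d24 = |p2−p4|
and the out-of-plane component h = n̂ · (p4−p1) with
n̂ = (p2−p1)×(p3−p1)/‖·‖.  **h is signed** along the right-handed
normal: backbones are chiral, and an unsigned projection would conflate
mirror-image conformations (a reflection of the input flips the sign
of h and nothing else).  Windows whose first three points are collinear
leave the plane undefined; they are dropped with a warning and treated
as breaks.

Chain breaks are declared when a consecutive Cα–Cα step exceeds
`max_ca_gap` (default 4.5 Å — comfortably above the 3.8 Å trans
peptide step, below genuine gaps) or when author residue numbering
jumps (insertion-coded residues share a number and count as
consecutive).  Each unbroken segment is encoded independently, so an
unbroken segment of n residues always yields n − 3 letters.

## The structural alphabet HMM

Letters are hidden states with **full-covariance** 4-D Gaussian
emissions (descriptor components are strongly correlated along a
helix, so diagonal covariances would misshape the classes) and a
letter-to-letter transition matrix.  Training is Baum–Welch with:

* k-means initialisation of the means (per-cluster covariances when a
  cluster is large enough, pooled otherwise);
* a ridge `reg · I` (default 1e-6) added to every covariance at every
  M-step, which also guards the Cholesky factorisations;
* the best of `restarts` (default 5) seeded initialisations by final
  log-likelihood; a run that empties a state or produces a singular
  covariance is abandoned and replaced by a fresh restart;
* a per-iteration assertion that the log-likelihood never decreases
  (beyond 1e-8 relative slack) — an EM implementation bug detector;
* convergence at relative improvement < 1e-6 or 200 iterations.

The forward–backward recursions use per-timestep scaling and are
batched over sequences of equal length, which is what keeps fits on
1e5 observations in the seconds range.  Alphabet size is selected by
BIC = −2 logL + p log N with p = (K−1) + K(K−1) + K·14 free
parameters.  Decoding is Viterbi in log space; ties break toward the
lowest letter index, making the encoding deterministic.

Letter classes (helix / strand / loop) are taken from the model file
when given.  Otherwise `assign_letter_classes` labels a letter by the
Mahalanobis distance (under the letter's own covariance) of its mean
to reference descriptors of an ideal α-helix (radius 2.3 Å, rise
1.5 Å/residue, 100°/residue) and an ideal extended strand (3.4 Å
rise zigzag at 3.8 Å steps); anything farther than `tol` (default 3)
from both is a loop.  The canonical 27-letter alphabet's classes
(helix {A, a, W, V}, strand {L, M, N, T, X}, 18 loop letters) ship as
a constant; the original 27-letter emission parameters were never
published, so the package trains alphabets or loads user-supplied
model files, and any bundled alphabet is synthetic by construction.

## Loops and words

Loops are maximal runs of loop-class letters — no minimum length is
imposed; loops shorter than the word length simply produce no words.
A loop of m letters yields m − L + 1 overlapping words of L letters
(default L = 4, i.e. 7-residue fragments; the 4-letter choice balances
fragment length against data sparsity).  Word types seen fewer than 5
times in the corpus are discarded (rare words track flexible or
poorly determined regions rather than motifs); independently, a word
must occur at least 5 times *within a group* to be tested there.
Residue coordinates are 1-based inclusive in all I/O and 0-based
half-open internally.

## Exact word statistics

The background is a homogeneous Markov model over the loop letters,
by default order 1 and fitted on the **whole loop corpus** (fitting
per group would absorb exactly the enrichment one is trying to
detect; per-group fitting remains available via `bg_scope`).  Initial
letters are drawn from the empirical initial distribution, not the
stationary one — loops do not start at stationarity.

For a word w, a KMP automaton with L + 1 states recognises
overlapping occurrences (after a match the automaton resumes from the
longest proper suffix of w that is a prefix).  The distribution of
the count N over a sequence of length ℓ is computed by a dynamic
program over (Markov context × automaton state × count), exactly, in
O(ℓ · A^(order+1) · L · cap) time.  Counts are capped at the observed
count N_obs with the cap bucket holding P(N ≥ cap) — only the tail is
needed for the p-value, and the cap keeps supports small.  The
per-sequence distributions depend only on sequence length, so they
are computed once per (word, length) at the word's corpus-maximal cap,
tail-folded down per group, and combined across a group's sequences by
convolution with repeated squaring over length multiplicities.  None
of these devices changes the result: the distribution matches
exhaustive enumeration over all sequence tuples to < 1e-12, and
p-values match Monte-Carlo tail frequencies over 1e5 simulated sets
within 3 binomial SE (both in the test suite).  Expected counts are
computed in closed form by propagating context marginals.

The score is Lp = −log10 P(N ≥ N_obs) (so Lp = 3 ⇔ p = 1e-3).  The
significance threshold is Bonferroni at α = 0.05 over the number of
(word, group) pairs **actually tested**, recomputed per run; the
constant 5.97 used by the original genome-scale survey is kept only as
a documented reference value, since the test count behind it depends
on that corpus.

## Taxonomy, coverage, annotations

Per word: Lp_max (maximum over tested groups, 0 when none) and nb_sf*
(tested groups with Lp ≥ threshold); nb_sf counts groups where the
word is seen at all.  Categories: over-represented iff Lp_max ≥
threshold; ubiquitous iff nb_sf* ≥ 5 (extreme at Lp_max ≥ 10);
superfamily-specific iff nb_sf* < 5 (moderately at Lp_max ≥ 10,
extreme at Lp_max ≥ 50).  Coverage rates of a word subset: word,
fragment, loop-length (union of residue spans — overlaps counted
once; an explicit choice, as overlapping words are common) and
protein coverage, all in percent and monotone under subset growth.

A fragment matches an annotation when they share ≥ `min_overlap`
residues (default 1 — the most permissive defensible rule; the right
overlap is genuinely unknowable without site-level curation) on the
same protein chain.  Precision of (word, label) = matched fragments /
all fragments of the word; sensitivity = covered loop-located
annotation instances / all loop-located instances, where one interval
record is one instance and instances with no residue in any loop are
discarded.  Description-level labels are whitespace-normalised exact
strings.  Functional words = extreme superfamily-specific with best
precision ≥ 0.40 over labels at either level (the 40% bar is
deliberately permissive because annotations are sparse).

## Fragment superposition

Kabsch superposition with the proper-rotation (determinant)
correction — fragments are chiral, reflections must not be allowed.
The residual is evaluated directly after applying the fitted rotation
(the closed-form RSSD loses precision near zero, where congruent
fragments must report ~0).  Two words are compared by the mean ± sd
RMSD over 30 randomly sampled cross pairs of their fragments, sampled
without replacement when enough distinct pairs exist (with
replacement otherwise), seeded.

## What the synthetic generator emulates — and what it does not

`generate_backbone` assembles ideal helix / strand segments and
self-avoiding random-walk loops at 3.8 Å steps with optional Gaussian
coordinate noise; `generate_alphabet` plants well-separated Gaussian
letters with sparse Dirichlet transitions; `sample_corpus` draws
grouped loop-letter corpora from an order-1 background and injects
designated words into designated groups by **overwriting** random
windows (loop lengths are preserved) until the in-group count reaches
the stated factor times the exact background expectation.  Every
occurrence of a planted word — injected or background-arising — is
annotated with probability q over its exact residue span; this is
what makes the measured precision converge to q, the property the
annotation stage is tested against.  Ground truth is returned with
the data, so recovery tests are self-auditing.

Default corpus conditions: 20 groups × 400 loops of 8–18 letters over
an 8-letter loop alphabet whose marginal is skewed (three letters near
0.22, five near 0.068).  The skew is a power choice: it gives the
frequent-letter words per-group expected counts around 13, comparable
to the ~20 mean occurrence of words in real loop corpora, so that a
3× plant is detectable above a Bonferroni threshold while a word of
rare letters stays below the testing floor — the regime the method is
meant for.  Note one systematic effect faithfully reproduced at this
scale: the corpus-fitted background partially absorbs planted
enrichment (a word planted in half the groups raises its own letters'
transition frequencies), so measured Lp values sit below the naive
Poisson expectation.  With thousands of groups, as in real corpora,
the absorption is negligible.

The generator does **not** emulate: amino-acid sequences, side
chains, physically realistic loop ensembles, evolutionary correlation
between groups, multi-domain architecture, or annotation noise
(wrong / shifted intervals).  Passing recovery tests therefore shows
the statistics and plumbing are correct under the stated model — not
that real loops satisfy an order-1 Markov background.

## Problem sizes used by the validation suite

Chosen as desk-scale study conditions: exhaustive-enumeration checks
use alphabets ≤ 3, lengths ≤ 8 and ≤ 3 sequences; Monte-Carlo
calibration uses 1e5 replicate sets (tail agreement) and 1e4 (null
sub-uniformity); Viterbi optimality is enumerated on 200 instances
with K ≤ 4, T ≤ 6; transition recovery uses 1e5 observations from a
planted 3-state model with the BIC scan over K ∈ {2..5} on 2e4
observations and 2 restarts (ample for well-separated states);
planted-enrichment recovery uses the default 20 × 400 corpus above,
and precision calibration a single-plant 10 × 300 corpus, where the
second, overlapping plant of the main corpus would contaminate the
measurement.

## Known limitations

* Backgrounds of order ≥ 2 are supported but the context space grows
  as A^order; the expected-count fast path also assumes word length ≥
  order (a slower exact fallback covers the rest).
* The enrichment engine computes, per group, every candidate word's
  observed count; corpora far beyond ~1e6 windows would want a
  suffix-automaton counting pass.
* `word_pair_rmsd` samples pairs rather than enumerating all; the
  estimator's SE is reported via the sd over sampled pairs.
* Under-representation and degenerate patterns (e.g. character
  classes) are out of scope.
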