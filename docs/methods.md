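# Methods

## The rally chain

A rally is modelled as an absorbing Markov chain over nine transient
states and two absorbing outcomes.  The serve (`SER`) is always shot 1.
Defensive returns (`DEF`) may repeat; once a first offensive shot (FOS)
is played the rally can never return to defensive states.  The FOS is
split by shot number — `FOS#2` (attacking the serve), `FOS#3`
(attacking the first defensive return), `FOS#>=4` (any later FOS) —
because these attack different kinds of balls and empirically carry
different risk.  The three shots after the FOS (`FOS+1..FOS+3`) are
one-time states; later shots pool into the offensive exchange (`OFF`),
a second self-looping transient set.  Every shot either continues the
rally, scores directly (`P`) or fails (`E`).

States map to phases: pre-offensive (`SER`, `DEF`), initial-offensive
(the six FOS-window states), final-offensive (`OFF`).  A rally "ends
in" the phase of the state it was absorbed from.

## From six criteria to state sequences

A rally record carries match id, set/rally number, gender, server,
rally length, FOS number, FOS player, winner, both players' world
rankings and the match result of the first-listed player.  Shot `k` is
played by the server when `k` is odd.  The state of shot `k` follows
purely from `k` and the FOS number; the absorbing outcome follows from
a terminal convention:

> **Terminal attribution.** `rally_length` counts the final shot
> *attempt*.  If the actor of the last shot is the rally winner, the
> rally ends `P` from that shot's state; otherwise it ends `E` (the
> last recorded shot was the losing attempt).

This is the unique convention under which every error column of the
transition matrix — including service faults (`SER → E`) — is
derivable from the six criteria alone.  The alternative reading
(length counts only good shots, with untouched winners vs. failed
returns distinguished) is not recoverable from the instrument and is
not implemented.  Lets and interrupted rallies are assumed absent from
the input (excluded at coding time).

`FOS+k` states are assigned purely by offset from the FOS even when
the rally ends inside the window; shot numbering is 1-based.

## Transition estimation

`P(X→Y)` is the count of `X→Y` transitions over all shots originating
from `X` (the last shot transitions into `P`/`E`).  Matrices are built

- per **player-side** (a transition belongs to the actor of its origin
  shot) — the unit for group comparisons, two per match;
- per **match** (both players pooled) — the unit for unweighted
  averaging, matching how a tournament-level "average matrix" is
  reported;
- **pooled** over all rallies.

Rows with no originating shots are *undefined* (NaN), never zero, and
are skipped by unit averaging and dropped from group tests — imputing
0 would bias error rates downward.  Internally all values are exact
ratios; percent formatting happens only at reporting time.

## Absorption analytics

The chain's structure (a DAG with two self-loops) gives closed forms
by first-step analysis: the `DEF` self-loop contributes a geometric
series (expected visits per entry `1/(1−d)`), reach probabilities
chain multiplicatively down the structural order, and `OFF` absorbs
everything that reaches it.  Printed matrices (3 significant figures,
rows summing to 99.9–100.1%) must be row-renormalized first; the
tolerance for accepting a row before rescaling is 0.005 absolute.
Empirical matrices are exact by construction and pass unchanged.
Chains whose self-loop probability is ≥ 1−1e−9 are rejected as
non-absorbing.

**DEF-exit split.** The lumped `DEF` row hides a positional
constraint: only the first defensive return can exit to `FOS#3`, later
ones to `FOS#>=4`.  The analytic profile splits the lumped exit mass
proportionally (`reach(FOS#3) = reach(DEF)·p₃/(1−d)`), which is exact
for the simulator's generating process below.

## The rally simulator

The simulator walks the chain shot by shot, tracking position so the
records it emits are structurally valid.  Its defaults are the study
conditions the analysis assumes: 105 matches (56 men's / 49 women's),
95 rallies per match (~9,925 rallies), alternating service, the
packaged averaged matrix as generating process, and world rankings
drawn so that 46.2% of player-sides fall in the top-40 class (the
published covariate balance).  Match results are emergent — the side
winning more simulated rallies is `W`, ties broken by extra rallies —
keeping the covariate structure internally consistent.  One integer
seed drives a single `numpy` generator; a fixed seed reproduces the
dataset byte-identically.

**Calibrated positional DEF rows.** Sampling the lumped `DEF` row
naively by position (first visit exits to `FOS#3`, later visits to
`FOS#>=4`, each with the full lumped exit mass) would pool back to
`P(DEF→FOS#3) = (1−d)(p₃+p₄) ≈ 0.434` instead of the generating 0.428
— a structural bias that breaks estimator consistency.  The default
policy instead uses the unique per-position rows (holding the P/E
cells fixed) whose visit-weighted mixture equals the lumped row
exactly:

    first DEF:  exit a = p₃/(1−d),  continue c₁ = T − a
    later DEF:  exit b = p₄/d,      continue c₂ = T − b,   T = d+p₃+p₄

This makes pooled re-estimation unbiased *and* realises exactly the
proportional split the closed-form profile assumes.  Feasibility
requires `p₃ ≤ (1−d)T` and `p₄ ≤ dT` (satisfied comfortably by the
packaged matrix); infeasible rows raise an error and can be handled by
supplying explicit per-position rows (`position_resolved`).

**Group effects** shift selected cells multiplicatively or additively
and rebalance the remaining cells of the row.  Effects attach to the
per-match factor (gender).  Per-side factors (ranking class, match
result) have no single-chain analogue — both players' shots share one
rally chain — so the simulator does not parameterize them; their
comparison machinery is exercised through the covariates the emergent
match results produce.

**What the simulator does not emulate:** momentum and score-state
dependence between rallies, set structure beyond bookkeeping,
defensive-style players (who return to chopping after attacks — a
different state system), and coder noise.  Passing tests therefore
demonstrate internal consistency of the pipeline and correctness of
the analytics under the model's assumptions, not behavioural realism
of any particular sample.

## Statistical battery

- **Mann–Whitney U** (two-sided): tie-corrected normal approximation
  without continuity correction — the convention of the major
  commercial packages at unit counts around 100 per group — with
  `r = |z|/√N`; exact enumeration available for small groups.
- **Kruskal–Wallis H** (tie-corrected) with `ε² = H(n+1)/(n²−1)`; the
  ε² formula is a fixed package convention.
- **Pairwise follow-ups** across the three FOS categories: pairwise
  U tests with Holm adjustment by default; Dunn's z-test on the joint
  ranking (the SPSS post-hoc) as an option.
- **Normality screen**: one-sample KS against a normal law with
  moment-matched parameters, α = 0.05; constant inputs are flagged
  degenerate rather than tested.
- **Cohen's κ** `(p_o − p_e)/(1 − p_e)`; when both raters are constant
  and identical, expected agreement is 1 and κ is reported undefined.
- α = 0.05 throughout; undefined unit rates propagate as missing.

## Numerical conventions and problem sizes

Row-stochasticity is enforced to 1e−9 on empirical matrices and to the
0.005 renormalization tolerance on printed ones.  End-to-end checks
use simulation sizes chosen to keep Monte-Carlo error well below the
assertion bands: 200,000 rallies for phase-share agreement (3 binomial
SEs) and 50,000 for parameter recovery.  At 50,000 rallies the rarest
row (`FOS#>=4`, ~0.135 visits per rally) has binomial SE ≈ 0.005 per
cell, so the 0.01 recovery bound is a ~2-SE statement for that row:
correct in expectation, with known sampling noise.  Test seeds are
fixed package defaults.

## Known limitations

- The terminal convention cannot distinguish an untouched winner from
  a failed return; both are `P` for the last actor.
- Lumped-row analytics assume the proportional DEF-exit split; codings
  from a process that violates it (e.g. strongly position-dependent
  error rates within `DEF`) would bias `FOS#3`/`FOS#>=4` reach
  attribution.
- Published factor tables from specific tournaments are not
  reproducible without their raw codings; the group machinery is
  validated on synthetic effects instead.
- Defensive-player transition patterns are out of scope.
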