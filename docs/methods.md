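# Methods

This note documents the modeling choices behind `ultistate`: the
possession state machine, the estimators, the inferential battery,
the synthetic match generator, and the numerical conventions.  It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Possession state machine

A possession is one uninterrupted spell of disc control.  Its state
sequence starts in `START_PULL` (pull received) or `START_EARNED_TO`
(possession gained from an opponent turnover), moves through the four
team-relative transient zones, and ends in exactly one absorbing
state: `POINT`, `TO_FORCED`, `TO_UNFORCED`, or `PERIOD_END`.

**Zones.** The field is 120 yards; boundary yard lines at
0/20/45/75/100/120 delimit own end zone (20 yd), rear (25 yd), mid
(30 yd), front (25 yd) and the attacked end zone (20 yd).  Both are
configurable.  Zone labels are team-relative and flip with possession;
positions are stored in absolute yards and converted through the
attacking-direction flag, which makes the flip lossless.  Boundary
ownership is a fixed convention: intervals are half-open in the
attacking direction, a shared yard line belongs to the downfield
zone.  This makes annotation deterministic; nothing else in the
pipeline depends on it.

**Transition matrix.** From a transient zone every transition is
possible: within-zone and adjacent-zone passes, cross-zone hucks,
scores, turnovers.  Structurally impossible are pull→point,
pull→turnover, earned-turnover→turnover, transitions out of absorbing
states, and earned-turnover→point except as a *Callahan*.  Scoring
directly out of one's own end zone (a 100+ yard throw) is kept in the
matrix as a legal-but-never-observed transition; the *generator*
treats it as a structural zero unless `allow_own_end_score` is set
(the zone-homogeneous closed-form scenario requires it).

**Callahan.** Modeled as a zero-throw possession of the intercepting
team: start `START_EARNED_TO`, nominal start zone the attacked end
zone, a single flagged scoring pseudo-event, end `POINT`.  It counts
toward the scorer's PPG/BPG and TTPCE numerator but not CPG (its
offense threw no pass), and it is excluded from earned-turnover
location distributions (its start zone lies outside the four
transient states) and from throw-outcome counts.

**PERIOD_END.** Quarter/half/game clocks can truncate a possession.
Such possessions keep their completed throws in the zone-conditional
outcome counts but contribute no absorbing event, and they are
excluded from the possession-outcome denominators that assume
absorption.  The conservation identity per team-game is
`#points + #forced TO + #unforced TO + #censored = #possessions`.

**Turnover location.** Outcome probabilities condition on the zone
the disc is held in before the throw (the origin).  Where the
turnover *occurred* — which locates the opponent's earned possession
— may differ (a failed downfield throw); the event record keeps the
origin, and the earned location is read directly from the next
possession's recorded start zone, so no information is lost.

## Estimators

All transition probabilities are maximum-likelihood multinomial
proportions of raw counts; no smoothing or priors.  Rows with zero
denominators are *flagged undefined* (NaN-valued but carrying a
defined-mask), never silently propagated; aggregation over team-games
excludes undefined entries pairwise and reports the contributing `n`.
Aggregate dispersion uses the n−1 sample SD.  Probabilities are
stored as proportions; rendered tables show percentages with two
decimals.

The default reporting grouping exposes 30 distinct probabilities:
4 pull + 4 earned-turnover + 4 within-zone passing + 6 adjacent-zone
passing + 8 turnover + 4 scoring.  Cross-zone (non-adjacent) passes
are estimated and stored but reported as a separate group, and the
4-zone attempted-pass origin marginal is derived and reported
alongside.  A `ReportGrouping` switch gives the 26-parameter variant
(no within-zone passes) and the 36-parameter full 4×4 passing matrix.

## Indicators

PPG, BPG, CPG, PPP, TTPG/UTPG/FTPG, TTPCE%, PO% per team-game.
Conventions worth stating:

* a scoring catch counts as a completed pass (CPG, PPP) — a goal is
  caught;
* PPP divides completed passes by *all* of the team's possessions,
  including censored and Callahan possessions;
* TTPCE% = 100 × (points scored on possessions starting
  `START_EARNED_TO`) / (opponent turnovers); undefined (None) when
  the opponent never turned the disc over;
* PO% defaults to pulls received / total pulls, under which the two
  teams of any match sum to exactly 100; the literal
  possessions-denominator variant sits behind
  `po_denominator="possessions"`.  The pulls denominator is the
  default because it is the definition under which equal possession
  opportunity is exact rather than approximate.

## Inferential battery

Per variable, winner-minus-loser paired differences over games are
gated by Shapiro–Wilk at α = 0.05 (constant samples fail the gate;
n < 3 defaults to the parametric branch): pass → paired t-test
(t = M/(SD/√n), df = n−1, central t, two-tailed), fail → Wilcoxon
signed-rank.  The Wilcoxon implementation is pinned to the
SPSS-compatible convention — zero differences dropped, mid-ranks for
tied |d|, normal approximation with tie-corrected variance
(subtracting Σ(t³−t)/48) and a 0.5 continuity correction toward the
null mean; the sign of Z follows the deviation of the positive-rank
sum from its null mean n(n+1)/4.  An exact sign-permutation p-value
(`method="exact"`, feasible to n ≈ 20) backs the approximation and is
what the property tests compare against an independent enumeration
oracle.  No multiple-testing correction is applied — each variable is
tested at α = 0.05 two-tailed, reproducing standard practice in this
literature; the per-family error rate is accordingly inflated, which
users should keep in mind.

Cohen's d ships in two variants because the field reports both
inconsistently: `dz` (mean/SD of the paired differences, the default
for magnitude classification) and `pooled_groups`
((m₁−m₂)/pooled SD).  Magnitude bands: trivial < 0.20 ≤ small <
0.50 ≤ medium < 0.80 ≤ large.

Cohen's kappa is computed from the contingency table with expected
agreement from the marginal products; the degenerate case of two
constant, identical raters (pₑ = 1, p₀ = 1) is defined as κ = 1.

## Synthetic match generator

The generator runs the state machine forward with a single seeded
`numpy.random.Generator` threaded through all sampling — a seed fully
determines a match log, and different seeds differ with probability
≈ 1.

Match bookkeeping follows AUDL structure: 4 quarters × 12 points by
default (timed quarters are not modeled; points-per-quarter is the
knob), the scoring team pulls the next point, the opening pull
assignment flips at half time, and a game tied after regulation
continues with sudden-death overtime points so every simulated log
has a winner.  Censoring (`period_end_prob`, default 0) truncates a
possession into `PERIOD_END` and ends the point unscored.  Callahans
(`callahan_prob`, default 0) may follow forced turnovers thrown from
the offense's own end zone.

**Default parameters** are the study conditions the package is tested
under: per-zone scoring (0/1.64/7.04/33.20%), forced-turnover
(4.04/3.66/4.09/3.72%) and unforced-turnover (4.02/3.58/4.68/5.63%)
per-throw probabilities and the pull landing distribution
(26.57/63.75/9.39/0.36%) are set to elite-league observed means.
Pass-destination splits within the remaining completion mass are not
observable from published summaries and were chosen once as realistic
flow-toward-goal kernels (dominant within-zone and one-zone-forward
movement, rare hucks); they shape zone occupancy, not the absorbing
rates.  Earned possessions start in the mirror of the turnover's
occurrence zone; a turnover occurs one zone downfield of its origin
with probability `turnover_downfield_prob` (default 0.5), which moves
earned possessions toward the earner's defensive half.  A single
scalar shift cannot reproduce the strong own-end-zone concentration
real data shows (failed throws into the attacked end zone); an
origin-dependent occurrence kernel would be needed and is a known
limitation.

`calibrate_from_table` closes the loop: an estimated table becomes a
parameter set (undefined rows are an error), and re-estimating from a
large simulation recovers every zone-conditional probability within
0.02 at ≥ 50,000 throws (checked in the test suite).

**What the generator does not emulate:** timed quarters and
clock-management behavior, wind and field-position tactics beyond the
zone kernels, player identity, stall counts, lateral field position,
and score-dependent strategy shifts.  Passing tests on synthetic data
therefore demonstrate the correctness of the bookkeeping, estimators
and statistics — not that real Ultimate follows the default kernels.

## Numerical conventions and problem sizes

* Distribution sanity is enforced at 1e-9 (`sums to 1 ± 1e-9`).
* Undefined quantities are flags/None, never silent NaN arithmetic.
* Event logs round-trip byte-identically (CSV and JSON); floats are
  serialized with `repr` to preserve exactness.
* Seeds for multi-match runs derive from one root seed via
  `SeedSequence`, keeping every derived seed below 2³¹.
* Test-suite simulation sizes — 100-match batches for symmetry and
  PO% checks, 120-match batches (≈ 50,000–60,000 throws) for
  parameter recovery, 10,000 possessions for the closed-form
  passes-per-possession check, 1,000 replicates for the type-I-error
  bound — were chosen so Monte-Carlo error sits comfortably inside
  the asserted tolerances while the whole suite runs in well under a
  minute of simulation time.

## Known limitations

* The annotation schema is a reconstruction of a per-possession
  observation sheet, not an import filter for any existing tool's
  format.
* Turnover-probability conditioning (origin vs occurrence zone) is a
  genuine ambiguity in field practice; both are representable in the
  log format, origin conditioning is the implemented default.
* The Wilcoxon normal approximation is what the battery reports even
  at small n (SPSS-compatible); the exact method exists but is not
  the default, so p-values at n ≤ 10 carry approximation error of a
  few hundredths.
* No lateral coordinate: the model is length-only.
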