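# Methods

## The case/non-case model

Spontaneous-report databases have no denominator of drug users, so
association screening compares *reporting* proportions. For a drug D and a
reaction query Q (a set of MedDRA-style preferred terms, matched by exact
string equality after canonicalization) within one age stratum, every
report falls into one cell of the 2×2 table (a, b, c, d): reports featuring
Q are cases, all others non-cases, cross-classified by whether D appears
with a suspected or interacting role. The reporting odds ratio
ROR = (a·d)/(b·c) estimates the exposure odds ratio of the case/non-case
design; its 95% CI uses the Woolf log-normal variance
1/a + 1/b + 1/c + 1/d with z = 1.96. When any cell is zero the
Haldane–Anscombe correction adds 0.5 to all four cells and the result is
flagged `corrected`; a table with a = c = 0 (the query PT absent from the
stratum) has no defined statistic and raises instead. A table where the
drug is absent (a = b = 0) is valid and simply uninformative.

The information component is the shrinkage-regularized log ratio of
observed to expected case counts, IC = log₂((O+0.5)/(E+0.5)) with O = a and
E = (a+b)(a+c)/N. The +0.5 terms pull pairs with tiny expected counts
toward zero, which is what makes the IC the conservative first-pass filter
for large databases. Its credibility lower bound uses the closed form
IC₀₂₅ = IC − 3.3(O+0.5)^−1/2 − 2(O+0.5)^−3/2; the exact posterior quantile
log₂ q_Gamma(0.025; shape O+0.5, rate E+0.5) is implemented separately
(`ic025_exact`) and used as an independent oracle in the tests — the two
agree within 0.05 bits for a ≥ 5 across an exhaustive grid of small tables.

A drug–query pair is a **signal** when all of: a ≥ `min_cases` (default 5),
IC₀₂₅ > 0, and the ROR CI lower bound > 1. The case threshold applies to
`a` per query and per stratum. No multiple-testing adjustment is applied;
disproportionality screening is hypothesis-generating by construction and
its false-signal behaviour is characterized empirically (below).

## Stratification and querying

Pediatric age bands are half-open in months — infants [0, 24), children
[24, 144), adolescents [144, 216) — so the under-18 range is partitioned
with no gap or overlap; the verbal convention "under 23 months" for infants
is resolved to [0, 24) because the next band starts at 2 years. Ages are
normalized to months (days ÷ 30.4375, years × 12). Age is a mandatory
field: an age-stratified analysis cannot place an ageless report, so such
records are rejected at ingest, and reports aged 18+ are excluded from all
banded analyses (counted in the run log).

Case attribution counts a drug once per report (set semantics) and only
for suspected or interacting roles by default; concomitant medication is
context, not exposure. This is configurable (`roles`). The comparator
population for a banded scan is the same age band (`background="stratum"`),
the conservative choice for age-stratified screening; a whole-database
comparator (`background="global"`, non-cases of any age) is provided for
sensitivity analysis.

Percentages anywhere in the output are 100·n/d rounded **half-up to one
decimal** in decimal arithmetic, so every printed cell recomputes exactly
from its printed numerator and denominator. Outcome percentages use the
known-outcome denominator; seriousness and death use the case total; all
denominators are printed. Age summaries use the sample SD (n−1), reported
in months for infants and years otherwise. Ranked tables break count ties
alphabetically.

## The synthetic report database

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as a plausible pediatric safety-report mix
(50,000 reports at `scale=1`):

- **Age mix** 8% infants, 17% children, 25% adolescents, 50% adults, ages
  uniform in months within band, recorded in the unit a notifier would use
  (days < 2 months, months < 2 years, else years) to exercise unit
  normalization.
- **Drugs**: the number per report is 1 + Poisson(0.7); identities are
  drawn without replacement proportional to the band's exposure weights
  (Gumbel top-k), so vaccines dominate infancy, immunosuppressants and
  corticosteroids childhood, psychotropics adolescence, over a common
  adult background. Roles are suspect with probability 0.8 (else
  concomitant); drugs carrying a planted association are always suspect.
- **Reactions**: each catalogued PT fires independently with baseline
  probability p₀ (catatonia-family terms 0.0005–0.004; common background
  reactions 0.025–0.08), multiplied by the rate ratio λ of every planted
  association whose drug is present and whose band matches, capped at 1.
  Because the p₀ are small, the case/non-case odds ratio of a planted pair
  is approximately λ, which makes recovery simulations interpretable.
  A report on which no PT fired receives one PT drawn proportional to its
  own PT probabilities (a report without a reaction does not exist).
- **Demographics** (sex, country, reporter qualification, seriousness,
  outcome) are independent categorical draws with fixed mixes; a fatal
  outcome forces the seriousness flag and the death criterion so the
  schema invariants hold by construction.

All randomness comes from one `numpy` PCG64 generator consumed in a fixed
phase order (bands, ages, demographics, drug counts, drug selection, roles,
reactions, fallback reactions, criteria), so one seed yields one dataset,
byte-for-byte, across runs and platforms. The emitted `GroundTruth` carries
the planted associations and the realized per-band margins (per drug, per
PT, per pair, suspect/interacting roles), asserted equal to naive recounts
in the tests.

What the generator does **not** emulate: co-prescription correlation
beyond the weighted draw, secular reporting trends, country reporting
cultures, masking/competition bias by design (though it emerges when
several planted associations share a PT — see below), duplicate reports,
and informative missingness. Passing calibration on these data therefore
shows the statistics and pipeline behave correctly under the stated
generative model, not that real-database signals are causal.

Two deliberate distortions are documented rather than removed. First, the
guaranteed-reaction rule inflates low-probability PTs slightly, so null
behaviour is asserted by simulation, not analytically. Second, λ
multipliers stack multiplicatively when several planted drugs co-occur on
a report and other planted drugs contaminate a pair's comparator group,
attenuating realized RORs below λ in the default configuration — a
realistic masking effect. The recovery study therefore plants a single
isolated pair per band.

## Simulation studies and problem sizes

- **Null calibration**: default configuration with every λ forced to 1;
  100 replicates of 50,000 reports in the test suite (30 in the
  acceptance script, which trades replicates for wall time). The fraction
  of eligible drug–PT pairs (a ≥ 5, three pediatric bands, all catalogued
  PTs) flagged as signals averages ≈ 1%, well under the 5% bound asserted
  — the IC₀₂₅ shrinkage dominates the dual criterion at small counts.
- **Recovery / coverage**: one isolated pair per band at λ = 20
  (pneumococcal vaccine, prednisolone, olanzapine — exposures chosen so
  the expected case count exceeds 10 at 20,000 reports), 100 seeds. The
  scan flags the planted pair in ≥ 95% of seeds per band and the ROR 95%
  CI covers λ in ≥ 90% — λ and the ROR estimand coincide here because
  reaction probabilities are small.
- **Determinism**: the pipeline run twice with the same config and seed
  (20,000 simulated reports) produces byte-identical TSVs; TSV headers
  carry the config hash and seed.
- **Oracle equivalence**: ROR and Woolf CI match an independent direct
  evaluation to < 1e-9 relative error over the exhaustive grid of 2×2
  tables with cells 0–30 (plus 1,000 random tables with cells up to 1e6),
  and match `statsmodels` `Table2x2` (with the exact normal quantile) on
  random tables.

## Implementation notes

- `run_signal_scan` counts in a single pass with hash maps;
  `scan_all_single_pts` vectorizes the same counting over all drug × PT
  pairs for the simulation studies, and is asserted row-identical to
  per-query scans.
- The generator constructs validated-model instances through a fast
  internal path (no re-validation of values it produced itself);
  round-trip tests assert equivalence with validated construction.
- JSON-Lines serialization uses a fixed key order and sorted set fields,
  making write → read → write byte-identical; the reader enforces schema,
  invariants and report-id uniqueness, naming the offending line.
- Degenerate inputs: empty case sets raise for percentage-bearing tables
  (undefined denominators) and return empty tables for scans; an empty
  stratum yields an all-zero contingency table, which is valid for
  construction but undefined for the statistics.

## Known limitations

Exact string matching of PTs (no MedDRA hierarchy, SMQs or roll-ups); no
duplicate-report detection; no PRR/EBGM or Bayesian hierarchical
alternatives; no time-to-onset analytics. The numeric ROR/IC values of a
real restricted-access database cannot be reproduced from synthetic data —
what is validated here is the statistical machinery, its calibration under
the stated model, and the reproducibility of the pipeline around it.
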