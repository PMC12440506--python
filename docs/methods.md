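# Methods

## Data model

A spontaneous reporting database arrives as five `$`-delimited ASCII tables
keyed by PRIMARYID (one row per report *version*): DEMO (demographics,
receipt date FDA_DT, event date EVENT_DT), DRUG (one row per drug mention
with role code PS/SS/C/I), REAC (one row per reported preferred term),
OUTC (outcome codes DE/DS/LT/HO/OT/RI/CA) and THER (therapy episodes with
START_DT). Dates are 4-, 6- or 8-digit tokens; the package parses them into
partial dates and only fully specified dates enter day arithmetic. Drug and
PT strings are trimmed and uppercased before comparison because free-text
capitalization in these files is inconsistent. Reported ages are normalized
to years (decades ×10, months /12, weeks /52, days /365.25).

The MedDRA dictionary is licensed and cannot ship with software, so the
PT → SOC hierarchy is supplied by the user as a two-column file. A PT
mapped to two SOCs is rejected at load; a PT missing from the mapping is
excluded from SOC-level tables and surfaced in a side report, never
silently defaulted.

## Deduplication

Cases accumulate versions; versions share CASEID and differ in PRIMARYID.
The collapse rule is: group by CASEID, keep the version with the latest
FDA_DT, break ties by the numerically larger PRIMARYID; an absent FDA_DT
sorts earliest. The rule is idempotent and invariant to input order
(property-tested), and the kept-set size equals the number of distinct
CASEIDs by construction. Cross-CASEID (probabilistic) duplicate detection is
out of scope.

## Cohort and descriptives

The cohort is the set of deduplicated reports with at least one drug mention
whose name or active-ingredient string matches a target name (generic or
brand) in the configured role — primary suspect by default. Matching is
exact after normalization; substring matching is available but off by
default because it catches combination products.

The descriptive summary partitions the cohort by sex, age bin (<18,
18–<65, ≥65, unknown), country, reporter occupation and report year — each
block sums to the cohort size — and tallies serious outcomes at report
level over the same denominator: a report with several outcome codes counts
once in each row, a report with none counts as "unknown", so outcome rows
need not sum to 100%. Percentages display as 100·count/cohort rounded to 2
decimals. Two country fields exist in DEMO (reporter vs occurrence); the
reporter country is the default and the choice is a config switch, as the
two are interchangeable in practice for largely single-country databases.
Report year is taken from the receipt date (FDA_DT).

## Contingency tables

For each term, exposure to the target drug is cross-classified against
mention of the term: `a` target-drug reports with the term, `b` without,
`c`/`d` the same for the rest of the database. The counting unit is the
unique report–event pair — the convention under which a term's "case
reports" column equals the number of reports mentioning it while the table
total `n` is the database's pair count. At SOC level each report's PTs are
first collapsed through the vocabulary, so a report with three PTs in one
SOC contributes a single pair. A report-level unit (each report counts once
toward `n`) is available via `unit="report"`; results differ only through
`d`, which is so large in either convention that the statistics barely
move. Tables are crude (unstratified), and every observed term gets a
table — rarity filtering happens in the signal criteria, keeping the single
`a ≥ 3` gate visible in one place.

## Disproportionality statistics

With `s = sqrt(1/a + 1/b + 1/c + 1/d)`:

- **ROR** = ad/bc, 95% CI `exp(ln ROR ± 1.96 s)`.
- **PRR** = [a/(a+b)]/[c/(c+d)] with the uncorrected Pearson χ² (one degree
  of freedom). Yates' continuity correction is omitted by default — at the
  case counts where signal criteria bite, the two are indistinguishable.
- **IC** = log₂ of the relative report rate `a·n/((a+b)(a+c))`,
  `IC025 = IC − 2 s/ln 2`.
- **EBGM** = the same relative report rate, `EBGM05 = EBGM·exp(−1.64 s)`.

The Bayesian pair (IC/EBGM) uses the closed-form variant: the point
estimate is the observed-to-expected ratio itself rather than the posterior
mean of a fitted hyperprior, which makes `IC = log₂(EBGM)` an exact identity
and keeps every number auditable by hand. The full BCPNN posterior and the
DuMouchel mixture-of-gammas EM fit shrink small counts harder; at the
counts the joint criterion accepts (a ≥ 3 with strong lower bounds) the
variants agree to the displayed precision. Full MGPS fitting and stratified
expected counts are known limitations, not goals.

Zero cells leave the affected statistics undefined (NaN), which can never
satisfy a flag; an optional Haldane-style +0.5 correction rescues them for
exploration, with flags still gated on the raw case count. No
multiple-testing adjustment is applied: the conjunction of all four
criteria (ROR: a ≥ 3 and CI low > 1; PRR: a ≥ 3, PRR ≥ 2, χ² ≥ 4;
IC025 > 0; EBGM05 > 2) is the only filter, and every threshold is
configurable.

## Time-to-onset

Onset is EVENT_DT − START_DT in calendar days, computed once per report.
Start dates come from THER (keyed to the drug sequence number) with
fallback to the DRUG table's start column; a report with several target PS
mentions uses its earliest complete start date (onset relative to first
exposure). Records are excluded with explicit statuses — missing date,
partial date, negative interval (event before start, a data-entry error) —
and conservation holds: evaluable + excluded = cohort size. Bins are 30-day
multiples (≤30, 31–60, 61–90, 91–180, 181–360, >360 days); true
calendar-month bins cannot partition day counts disjointly. The median is
the lower median of the evaluable day counts. Weibull modelling of the
onset distribution is out of scope.

## Synthetic data generator

The generator emulates a scaled-down spontaneous-report database around one
rare target drug. Per case: one PS drug (the target with probability
`target_prevalence`, else a uniform background drug), Poisson-distributed
extra mentions with SS/C/I roles, and — given the PS drug — each PT
reported independently with probability `min(1, RR·p_pt)`, where RR > 1 only
for injected (drug, PT) associations. The per-PT Bernoulli independence is
deliberate: it matches the independence the 2×2 statistics assume and makes
the expected table a closed form (`expected_table`), which the tests use as
a recovery oracle. The number of events per report is therefore implied by
the background probability vector rather than drawn from a separate
distribution, and a report may carry zero events (it still appears in
DEMO/DRUG, contributing nothing to pair counts).

Default conditions, chosen once as a realistic desk-scale emulation:
20,000 cases (50,000 in the recovery studies), target prevalence 2% — large
enough for stable counts at desk scale while keeping the target a small
fraction of the database, as a real single drug is — 20 background drugs, 50
PTs over 8 SOCs with background probabilities log-spaced over 0.002–0.03,
one association injected at RR = 5 on a PT with ≈1% background probability,
10% of cases duplicated into 2–3 versions with strictly increasing receipt
dates, exponential onset (scale 120 days), 20% missing and 5% partial event
dates, 2% deliberately negative intervals, and demographic mixtures typical
of a largely female, US-dominated, adult reporting population. All
randomness flows from one seed; identical configs produce byte-identical
files.

Because exposure margins contain the injected signal itself, the expected
EBGM at these conditions is slightly below the injected RR (≈4.3 at RR 5);
the recovery check therefore scores the estimate against the injected risk
with a ±25% allowance covering both this conditioning effect and sampling
noise. What the generator does **not** model — event–event correlation
within reports, drug co-prescription structure, name misspellings,
reporting-rate drift over calendar time — bounds what passing tests say
about real data: they validate the pipeline's arithmetic and rules, not its
robustness to real-world coding noise.

## Numerical and design choices

- Statistics are computed vectorized in double precision; the scalar
  single-table functions and the vectorized path are tested against an
  independent hand-arithmetic oracle at 10⁻¹² relative tolerance.
- Ordering is deterministic everywhere (stable sorts; results sorted by
  descending case count, then term), so identical inputs give
  byte-identical outputs.
- Display tables round to 2 decimals; machine-readable outputs keep full
  precision.
- The disproportionality core follows the model/fitted-results idiom
  (`Disproportionality.from_events(...).fit()` →
  `DisproportionalityResults` with `.frame`, `.signals`, `.summary()`);
  ingestion, deduplication, cohort, onset and the generator are functional
  stages orchestrated by `run_pipeline` and the CLI, since they transform
  data rather than estimate parameters.
- The deduplication tie-break compares PRIMARYID numerically, not
  lexicographically; non-numeric identifiers lose ties but are never
  dropped.
- Stage failures abort the pipeline naming the stage; all-stage record
  counts are logged and the monotone chain (versions ≥ cases ≥ cohort) is
  asserted.
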