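# Methods

## Sensing model

Each participant carries a BLE beacon (iBeacon identity: study UUID,
family-level `major`, member-level `minor`) and a phone whose app scans for
beacons of the study UUID roughly every 5 minutes.  Detection is two-sided
and asymmetric: the adolescent's phone logging the parent's beacon and the
parent's phone logging the adolescent's beacon are independent processes,
each requiring that phone to be scanning at that moment.  A detection implies
the pair is within a few metres in the same room; walls block the signal at
the −20 dBm transmission power used.

A *scan record* is (timestamp, observer device, beacon UUID/major/minor,
RSSI, beacon name).  RSSI is carried through but never used for distance
estimation: at this power level presence/absence of a detection is the
proximity signal, and a room-level model is the appropriate resolution.

## Cleaning

Five steps, in fixed order so audits are comparable across runs:

1. remove records from test-account devices (pilot phase);
2. remove records where either the observer or the detected beacon belongs
   to an excluded family;
3. repair identity errors: beacon reuse leaves records whose major/minor
   disagree with the roster (stale values after a reconfiguration failed to
   synchronise).  A record failing identity resolution is repaired only when
   exactly one roster assignment — excluding the observer's own beacons —
   agrees with it on at least two of {major, minor, observer-family,
   date-in-assignment-window} while disagreeing on exactly one of
   {major, minor}.  Ambiguous records (e.g. a stale minor in a household
   where two other members are candidates) are never guessed and fall
   through to step 4;
4. remove out-of-roster records: unknown observer devices, unresolvable
   beacon identities, self-detections, and cross-family detections (the
   returned-beacon scenario);
5. clip to the observer's participation period, inclusive at date
   granularity.

The audit counts every removed row under exactly one `removed_*` field;
`repaired_identity` and `unrepairable_identity` are informational (repaired
rows stay, unrepairable rows are counted again when removed in step 4), so
`rows_out = rows_in − Σ removed_*` holds exactly.  Cleaning is idempotent,
never adds records, and is invariant to input order.

## Occurrences and episodes

Within one scan cycle a device may log the same beacon several times;
detections of the same (device, beacon) within 1 minute collapse to one,
and the collapse count is reported.

**Two-sided merge.**  For one dyad, adolescent-side and parent-side
detection streams are merged by a greedy chronological one-to-one pairing:
walking both sorted streams, the earliest unpaired scans from opposite sides
with |Δt| ≤ 2.5 min pair into one `both` occurrence stamped with the
adolescent-side time; everything else becomes a one-sided occurrence.
Greedy pairing is deterministic and attains the maximum possible number of
pairs (verified against an exhaustive pairing oracle in the tests); with
nominal 5-min scan cycles conflicts are rare anyway, since the cycle exceeds
twice the merge window.  The occurrence count is bounded below by the larger
side and above by the sum of the sides.

**Daytime window.**  Occurrences are kept when their local wall-clock time
falls in Mon–Fri 07:00–21:30 or Sat–Sun 09:00–23:00, inclusive at minute
resolution (07:00:00 and 21:30:59 are both inside).  One study timezone is
assumed; timestamps are handled naive.

**Episodes.**  Per dyad, a maximal run of occurrences whose successive gaps
are ≤ 7 min (inclusive — the cutoff is a stated maximum) is an episode with
duration equal to the sum of its gaps, i.e. last minus first timestamp.
Runs of length one yield no episode and no duration: a single detection
carries no interval information.  Both cutoffs (2.5 and 7 min) correspond to
roughly half and ~1.4 nominal scan cycles.

**Metrics.**  Per dyad: occurrence count (primary frequency), episode count
(the alternative, exposed as `--frequency episodes`), total duration, and
per-day means.  Per-day denominators are all calendar days of the
participation window split by day type (a 14-day window starting Monday has
10 weekday and 4 weekend denominators), not only days with data — absence of
detections is informative, although true absence and sensing failure are
confounded (see Limitations).  Dyads with no data get an explicit zero row
flagged `no_data`.  The hourly profile bins occurrences by (weekday, hour,
parent role); `total` conserves the occurrence count, `mean_per_dyad`
divides by the number of roster dyads of that role.

## Trigger engine

Departure is operationalized as the last detection of a run followed by
silence longer than the 7-min gap cutoff (≈ two missed scans).  A run
spanning ≥ 10 min (last − first detection; identical to summed gaps on a
contiguous run, and observable online by the phone) schedules a
questionnaire at departure + 10 min, independently for both recipients (the
adolescent receives separate mother/father questionnaires).  The event is

* *canceled by reapproach* if any dyad occurrence falls in
  (departure, fire time];
* *suppressed by lockout* if a previously fired trigger for the same
  recipient–subject pair is < 4 h old (`lockout_scope="recipient"`
  implements the stricter variant in which an adolescent's mother- and
  father-questionnaires share one lockout);
* *fired* otherwise.

Candidates are resolved in global fire-time order, so recipient-scoped
lockouts couple correctly across dyads.  Two invariants hold universally
and are replay-tested on randomized streams: no trigger fires while its
dyad has been detected within the gap cutoff before the fire time, and
fired events per recipient–subject pair are ≥ 4 h apart.

A fired questionnaire resolves against the response log as *completed*
(submitted within the expiry window — 30 min, or 10 min in legacy mode),
*canceled* (started within expiry but not finished in time; the deployment's
"canceled" category is not operationally defined, and started-but-unfinished
is the reading adopted here), or *expired*.  Compliance summaries report
delivered/completed/canceled/expired counts, completion percentages (one
decimal), and per-recipient delivery statistics (mean over recipients with
≥ 1 delivery, two decimals); zero deliveries yield NaN, never 0 %.

## Questionnaire scoring

Items are 1–7 Likert.  Scales are plain means: positive affect = (happy,
relaxed); negative affect = (sad, irritated, guilty); parental warmth =
(listen, understand); parental criticism = (critical, dominant);
pleasantness is a single item.  A scale is computed only when all its items
are present (listwise per scale, no imputation — consistent with the small
per-scale observation discrepancies seen in practice).  Scores stay at full
precision; rounding (2 decimals) happens only at report time.  Person means
are unweighted over a person's scored interactions.  The interaction rate is
the percentage of answered questionnaires reporting that the pair actually
spoke.

## Statistics

Mother-vs-father comparisons pair within family and use the Wilcoxon
signed-rank test: zero differences dropped, midranks for ties.  The signed
statistic z = (W⁺ − n(n+1)/4)/σ uses the tie-corrected variance; an optional
continuity correction is off by default.  For ≤ 25 informative pairs the
p-value is exact, computed by dynamic programming over the sign-flip null
distribution of doubled midranks (ties handled exactly); beyond that the
normal approximation is used.  Exactness for small n matters: the worst-case
gap between the normal approximation and the exact two-sided p is ≈ 0.10 at
n = 6 (≈ 0.04 with continuity correction), and only from n ≈ 12 does the
corrected approximation stay within 0.02 everywhere.

Correlations are Pearson with pairwise-complete observations and per-cell n
(≥ 3 complete pairs required; constant variables yield NaN).  Frequency and
duration are typically right-skewed, so report tables always show median,
min and max alongside the mean.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated.

**Schedule layer (deterministic).**  Families of 2–3 members (adolescent +
mother, optionally father) follow day templates of location blocks tiling
each day: separate bedrooms at night, a shared kitchen at breakfast
(weekdays 07:15–08:00) and an afternoon snack (16:00–16:45) for the
adolescent and mother, a shared living room in the evening (18:30–21:15)
including the father, and on weekends a long brunch (10:00–11:30) and a
longer evening (17:30–21:30).  This reproduces the qualitative shape of
family co-presence — weekday afternoon/evening peaks, fuller weekends, more
mother- than father-proximity.  Ground-truth co-location is the overlap of
two members' blocks in the same room; `away` is never detectable (different
places), and co-presence at home in different rooms is undetectable too
(walls block).  Block boundaries sit on 5-minute marks so that, with
noiseless sensing, discretization loses exactly one scan interval per
episode.

**Sensor layer (stochastic, seeded).**  Per device: scan times advance by
5 min plus symmetric bounded jitter (default ±1 min) with occasional long
gaps (5 % chance of +5–25 min), emulating the substantial real-world
variation around the 5-min median.  Dropout (app terminated, phone left
behind, night mode — lumped into one process) is modeled as marked renewal
segments: the timeline is cut into ~3-h exponential segments, each with a
uniform mark, and the device is off where mark < dropout rate (default
0.15).  Marks are drawn identically regardless of the rate, so at a fixed
seed the off-set grows monotonically with the rate — paired comparisons
across dropout levels are exactly coupled, and rate 1 yields an empty log.
Identity errors (default probability 0.05 per person, matching the order of
frequency seen in deployment) replace a wearer's minor with a stale value
for the first three study days; in two-member families these are uniquely
retraceable and exercise the repair rule, in three-member families they are
ambiguous and must be dropped.  Optional cross-family contamination injects
returned-beacon detections.  RSSI is Gaussian nuisance noise (mean −75 dBm).

All randomness flows from one `numpy` `SeedSequence` spawned per device and
component, so outputs are byte-identical across runs and platforms at the
level of written files.

**Response simulation.**  Fired triggers are answered with group-specific
completion probabilities (defaults 0.52 adolescents / 0.50 parents, the
order observed in event-contingent family EMA), spoke-probabilities (0.66 /
0.80), submission latency within 90 % of the expiry window, and a rare
started-but-unfinished path.  Items come from per-person mean vectors
(pleasant, warm, low-negative defaults) plus Gaussian noise, rounded and
clipped to 1–7.

**What passing tests show — and what they don't.**  The simulator validates
the *algorithmic* chain: detection→merge→episode→metric→trigger logic
recovers known ground truth under controlled imperfections (duration error ≤
one scan interval per episode without noise; zero trigger misses and false
positives; monotone degradation under dropout).  It does not calibrate
human-mobility realism: real families have far more heterogeneous schedules,
device-specific scanning pathologies, and correlated missingness (e.g.
phones left together overnight), so field estimates carry biases the
simulator only samples in stylized form.

## Numerical and design choices

* Greedy chronological merge (deterministic; max-cardinality verified by an
  exhaustive oracle) with adolescent-side timestamps for merged occurrences,
  keeping duration on the adolescent's clock.
* Inclusive boundary semantics everywhere a cutoff is a stated maximum:
  |Δt| ≤ 2.5 min merges, gap ≤ 7.0 min continues an episode, daytime windows
  inclusive at minute resolution, participation period inclusive by date.
* Detections of one beacon by one device within 1 min collapse to one
  occurrence candidate (duplicate-broadcast guard); the collapse count is
  logged.
* Per-day averages divide by all calendar days in the window; days-with-data
  denominators can be derived from the exported occurrence table if wanted.
* Identity repair requires a unique candidate and never fires on ambiguous
  records; observers' own beacons are excluded from candidacy (a phone does
  not report its wearer's own beacon as another person).
* Rounding of reported percentages/means uses decimal half-up at report time
  only (1 decimal for percentages, 2 for per-recipient means).
* Problem sizes in tests and the acceptance script: 1–2 families over 14
  days (≈ 4–7 k scan records per study), 10–20 paired seeds for dropout
  monotonicity, 1000 randomized streams for trigger replay — large enough
  for the invariants to be exercised at full strength while keeping a run in
  seconds.

## Known limitations

* True absence and sensing failure are indistinguishable in the logs; all
  duration/frequency estimates are lower bounds under dropout.
* Proximity ≠ interaction: the spoke-question exists precisely because
  co-presence without conversation is common.
* One study timezone; daylight-saving transitions inside a participation
  window are not specially handled.
* The trigger engine evaluates the ≥ 10-min condition on the run span, as an
  online phone-side implementation must; summed-gap and span definitions
  differ only for non-contiguous runs, which the gap cutoff excludes.
* No RSSI-based distance modeling, no multilevel or time-series inference —
  reporting is deliberately descriptive.
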