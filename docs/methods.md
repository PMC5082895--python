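# Methods

This note documents the models and procedures implemented in
`vmstrips`, the assumptions behind them, the tunable parameters and
their defaults, and what the synthetic-data experiments do and do not
demonstrate about real VMS data.

## Geometry and units

All distances are great-circle distances on a sphere of radius 6371 km
(haversine form), expressed in nautical miles (1 nmi = 1.852 km);
speeds are in knots. At subarctic latitudes the spherical approximation
differs from a geodesic by well under 0.5%, far below the positional
information content of 30-min fixes. Every module uses the same
`vmstrips.geo` primitives so distances agree bit-for-bit across stages;
tests pin the convention against an independent Vincenty-form oracle at
1e-9 relative tolerance. Timestamps are treated as UTC throughout.

## Preprocessing

Duplicate `(vessel, timestamp)` records keep the first occurrence;
conflicting positions at one timestamp are logged. Derived per-record
fields are the distance and interval to the previous record, the
apparent speed (their ratio), the nearest port and distance to it, and
the statistical-area membership (point-in-polygon, boundary inclusive).
The first record of each vessel has undefined kinematics (NaN).

**Speed filter.** Records implying apparent speeds above 14 kn (a
conservative ceiling over the fleet's ~12-kn maximum) are removed
iteratively: removal re-links the neighbours, which can expose new
violations, so passes repeat until the chain is clean. When the
violating pair sits at the head of a vessel's stream the head itself
may be the outlier; a look-ahead test (does dropping the head rather
than its successor make both adjacent legs legal?) decides which record
to drop. Whether removal should cascade was an open design point; we
cascade, and validate the filter against an exhaustive minimal-removal
oracle on small fixtures.

## Trip segmentation

A record is an *in-port candidate* when it lies within its nearest
port's detection radius (10 nmi for the two protected hub ports,
individually smaller — 3–5 nmi — for exposed ports near fishing grounds
or transit lanes). Candidate runs are confirmed as port visits at run
level: any record at or below the per-port speed ceiling (default
2 kn), or a total dwell at or above the per-port minimum (default
60 min; 720 min for hubs), confirms the run. The hub dwell fallback is
deliberately long because genuine hub calls involve multi-hour dock
dwells that always produce near-zero-speed records, whereas a slow
fishing pass through a 10-nmi buffer can easily dwell three hours.
Records with undefined speed are neutral (they neither confirm nor
disconfirm). Declared *transit corridors* (e.g. between the two hub
ports) veto fast-moving candidates inside their polygons, so through
traffic does not register as a port call. These per-port constants are
configuration (`PortRuleSet`), not code: operational deployments tune
them port by port.

Trips are maximal at-sea runs between port visits. Within a run, any
transmission gap longer than `gap_bridge_max_min` (default 240 min,
the scale above which missed port calls dominate) is tested for a
hidden visit: a port qualifies if both flanking fixes are inside its
radius, or if the detour through the port barely lengthens the flight
line (≤ 10 nmi by default) *and* the gap leaves time to reach it at
≤ 14 kn plus a minimal visit (30 min). When a port qualifies, the run
splits there and both resulting trips share the inferred port. Trips
with four or fewer records are dropped as artifacts. Vessels with no
in-port records yield a single open trip with unknown ports.

## Trip metrics

Boundary records usually sit some distance from the dock, so raw
record-to-record sums understate trips. For ordinary ports the
trajectory is linearly extrapolated to zero distance-from-port at the
adjacent segment's speed (floored at 0.5 kn so a near-stationary
boundary cannot add unbounded time). For hub ports, whose large buffers
hide substantial in-port steaming, mean within-buffer travel constants
are added instead — but only when the boundary record lies at or beyond
the radius; corridor-adjacent trips whose boundary is observed inside
the buffer are extrapolated like any other.

**In-port constants estimation.** For each hub, traversals with
contiguous coverage (every interval ≤ 30 min) between dock and
threshold are measured with two refinements that remove the sampling
phase bias: the threshold crossing is linearly interpolated on
distance-from-port between the records spanning it, and the dock
departure/arrival is back-extrapolated from the first/last moving
record at that record's adjacent-segment speed. A record at the dock is
treated as docked even when its segment-average speed is nonzero (the
vessel moved mid-segment). Without any qualifying traversal the
registry defaults are retained with a warning; the shipped defaults for
the two hubs (Akutan 13 nmi/101 min outbound and 12 nmi/92 min inbound;
Dutch Harbor 10 nmi/80 min both ways) are the operational values for
that geography.

**Measurement-error model.** With records at interval Δ min on both
boundaries, the detected start can lag the true departure by up to
Δ − 1 min and likewise at the end, so the duration error is bounded by
`2Δ − 2` min (58 min at the 30-min cadence; 5% of a 1,160-min trip).
The bound for each trip uses the trip's own largest observed interval —
conservative, since the error grows with gap length. The within-bound
comparison uses a 1e-6-min slack purely for floating-point safety.

**Observer comparison.** Trips match observer trips when at least one
record falls inside the observed window; observed trips of ≤ 200 min
are excluded (by the dock-to-dock definition such trips never left
port, and VMS cannot resolve them). Percent error is signed with
positive = over-estimation; the summary reports the share within the
error bound, the share within 5%, their union, the Spearman rank
correlation and the aggregate (summed) duration error.

**Bias regression.** Observed duration is regressed on estimated
duration, both log-scaled, in two segments split at 700 min — the
duration separating the short-transit and multi-day-fishing modes of
the distribution. Degenerate segments (n < 10 or constant estimates)
fall back to the identity with a warning. Pre- and post-correction
errors are reported so the analyst can accept or reject the correction;
other functional forms can be swapped in by refitting on the same
comparison table.

## Classification

Ordered decision rules settle the unambiguous cases first: a matched
fish ticket ⇒ fishing; a trip entirely inside transit corridors ⇒
non-fishing; a charter/tender calendar entry ⇒ non-fishing; no records
at fishing speeds (0–5 kn) beyond 10 nmi from port ⇒ non-fishing.
Conflicts resolve first-match-wins.

The remainder is predicted by a penalized logistic GAM fit to the
rule-labeled trips, excluding trips shorter than 200 min or longer
than 15,000 min as unrepresentative. Smooth terms are penalized cubic
B-splines (6 basis functions each, penalty weight 1.0 by default) on
ln duration, `avesp`, `sddif` and `sdsp`; the duration-by-speed surface
is approximated by the two marginal smoothers plus a linear interaction
term, because no isotropic bivariate smoother is available in the
fitting backend — with the monotone features used here the additive
approximation reproduces the intended interaction direction (longer
trips contain more transits and hence higher mean speeds). Season and
start/end port-region enter as factors. Features with empty record
subsets are imputed with training medians and flagged with missingness
indicators. `avedif`, `avgspstat` and vessel size are computed as
candidate covariates but excluded from the default model. Predictions
clip features to the training range (flagged as extrapolation); the
0.5 threshold labels an exact tie as fishing.

Synthetic fleets are often perfectly separable in feature space, where
penalized IRLS diverges (the spline penalty's null space is
unpenalized). The fit then falls back to a ridge-stabilized penalized
IRLS (1e-3 on every coefficient) on the identical design, with a
warning; probabilities saturate but ranking and labels are stable.

The AFA/non-AFA partition of fishing trips uses ticket program codes
where matched; unmatched fishing trips in a month where the vessel
filed no AFA tickets are non-AFA, otherwise the pollock-season
(A: Jan 1–Jun 9, B: Jun 10–Oct 31) and pollock-grounds filters decide.

## Gap-bias experiment

From trips whose every interval lies in 25–35 min, each draw samples a
trip (with replacement) and a gap position, removes 1–4 consecutive
records (the extra removals extend the gap backwards), and measures the
percent reduction in over-water path length relative to the complete
trip (in-port constants are gap-invariant and excluded). Reductions are
nonnegative by the triangle inequality; float-epsilon negatives on
collinear paths are clamped to zero. Summaries per gap size report the
mean, the mean absolute deviation, quartiles and the count of draws
above 1.5 × the upper quartile, plus the ECDF of each input trip's
maximum gap. A Monte-Carlo run is checked against exhaustive
enumeration of all positions on small fixtures.

## The synthetic fleet

The generator emulates a pollock catcher-vessel fleet working from two
hub ports and three smaller ports: trawl trips of 1–4 days (lawnmower
tow patterns at 2.5–4.5 kn with ~180° reversals every 1–3 h, and
occasional fast repositioning legs at 8–12 kn with sharp course
reversals), longer trips for other fisheries, straight transits at
8–12 kn, and tender-like drifting trips; port dwells of 4–12 h between
trips; steady 10-kn steaming inside hub buffers. Grounds are placed
20–120 nmi from the home port and bouts keep ≥ 12 nmi clear of all
ports, reflecting the empirical observation that vessels enter harbor
approaches only to land. VMS sampling is nominally every 30 min with,
by default, 8.9% of intervals jittered to 35–60 min and 2.1% drawn
from a discrete gap mixture over {60, 90, 120, 150, 240, 480} min.
Observer logs cover a configurable fraction of trips with optional
clock-error modes (start logged while still at the dock; start logged
hours after departure); fish tickets can be dropped, date-swapped or
blanked. 80% of tendering assignments are assumed known from processor
calendars, which both feeds the non-fishing decision rule and seeds the
classifier's training data with tender-like negatives.

**What passing tests do and do not show.** Synthetic tracks are
smoother than real trawling at the 60–150-min scale, so the gap
experiment's mean reductions (≈0.1–1% for gaps of 60–150 min) sit below
what heavily tortuous real tows produce, although the qualitative
structure — zero lower range on straight segments, means growing
super-linearly with gap length — matches. Interval irregularity is
modeled i.i.d. per interval; real gaps cluster by vessel and period
(equipment and reception effects), which is why real data contain many
fully-regular multi-day trips while i.i.d. sampling almost never does —
dedicated gap experiments therefore run on regular-sampling fleets.
Synthetic behaviors are more separable than real ones, so the
classifier's ~97–99% held-out accuracy on 800-trip fleets demonstrates
the machinery, not field performance. Recovery and error-bound results
(≥ 95% one-to-one recovery under the realistic interval mix; 100% of
durations within `2Δ − 2` without gaps) are exact consequences of the
algorithm when its assumptions hold, and degrade gracefully as gaps
lengthen.

## Problem sizes and numerical choices

Test and demonstration fleets use 80–1,000 trips (the acceptance suite
uses 500-trip fleets for recovery and 800 for classification, with
2,000–5,000 Monte-Carlo draws), sizes at which every stochastic summary
is stable across seeds. All randomness flows through explicit
`numpy.random.Generator` instances, so identical seeds give identical
artifacts byte-for-byte. Tie-breaks: nearest port wins when two radii
overlap; first occurrence wins among duplicate records; first matching
rule wins in classification; a classification probability exactly at
threshold is fishing. Degenerate inputs (empty record sets, single-class
training labels, zero qualifying traversals, too few regression pairs)
raise or fall back with warnings as documented in the API docstrings.
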