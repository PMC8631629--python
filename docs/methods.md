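# Methods

## Trade-network construction

Input rows are bilateral trade reports: reporter, partner, year, flow
direction (import/export from the reporter's side), commodity and net
weight in kg.  Rows naming aggregate entities ("World", "Special
Categories", "Areas, nes", ...) are dropped, as are self-trades and rows
with negative or missing mass.  Country matching is exact string match
after whitespace trimming; naming variants are handled by a user-supplied
alias table rather than fuzzy matching, so every merge is auditable.

Every report is oriented origin → destination (an import report by *j*
about *i* describes the flow *i → j*).  Reports of the same
(origin, destination, year, commodity) flow are duplicates and are resolved
in two stages: if the focal country reported the flow, its value is kept
(its records are treated as authoritative because its border data
parameterise the rest of the pipeline); otherwise the higher reported
quantity is taken as true, the conservative choice for a risk analysis.
The resolved record is stored in export orientation, which makes the
operation idempotent and order-invariant — both are tested.

Flows are summed per directed edge over the study window (default 10
years).  Edges totalling less than `min_total_kg` (default 1000 kg per
window) are discarded as minor; the threshold is applied per directed edge,
not per unordered pair.  The edge weight is total kg / window years / 1000,
i.e. mean annual tonnes — the denominator is the full window, not the
number of years with nonzero trade, so intermittent flows are averaged
down.

Statistics: density is m / (n(n−1)) on the directed simple graph; the
diameter is the longest finite directed geodesic with unreachable pairs
ignored (the convention of the common graph libraries; recorded in the
stats metadata).  Degree summaries for the focal country's direct partners
(nodes sharing an edge with it in either direction) versus all other nodes
are computed on the full network's adjacency — the grouping only selects
which nodes are averaged — with sample (n−1) standard deviations.

## Inspection summaries

A seed lot is *contaminated* iff at least one non-crop taxon was found in
its working sample.  Distinct-species tallies count only taxa determined to
species level; genus- or family-level determinations ("Bromus sp.",
"Viscaceae") still mark the lot contaminated but are excluded from species
counts.  A *detection event* is a lot with at least one quarantine-listed
hit — one event per stopped shipment regardless of how many regulated
species it contained.  Incursion counts (regulated contaminants discovered
after lots cleared the border) come from incursion-response records, not
the inspection file, and are supplied as `IncursionSpec(events,
window_years)` with the observation window made explicit.

## Dispersal rates and edge probabilities

The base rate is r = events / (mean annual tonnes × window years), one
global rate per basis: detections default to a 5-year exposure window,
incursions to 20 years.  Both windows are configurable; with the default
inputs (3 detections, 1 incursion, 199 t/yr) the detection rate is
3.0 × 10⁻³ and the incursion rate 2.5 × 10⁻⁴ per tonne, a factor of 12
apart.  Rates are deliberately not per-origin or per-species: the events
are far too few to stratify, and a single network-wide rate keeps the
simulation an exercise in topology and volume rather than in over-fitted
rate tables.

The per-edge, per-step transmission probability compounds the rate over
the edge's annual volume, p = 1 − (1 − r)^V, evaluated in log space
(`expm1`/`log1p`) so that tiny rates on huge volumes lose no precision.
Compounding is the default because it is the only form in which the
transmission probability actually uses the traded volume per tonne; the
linear form p = min(1, rV) is retained as `mode="linear"` for sensitivity
analysis and agrees with compounding to first order as rV → 0 (tested at
5% tolerance).

## SI simulation

State is a 0/1 vector over countries.  Per step, one uniform draw per edge
realises a random adjacency A_t (edge present iff U < p); every realised
edge out of an infected node is logged as a dispersal event, *including*
transmissions to already-infected destinations — repeated arrivals are the
quantity of interest for focal-country risk.  The next state infects every
event destination and, by default, keeps all previously infected nodes
infected (persistence).  A strict reading of the update
s_{t+1} = 1(s_t A_t > 0) would let an infected node revert when it receives
no incoming event in a step; because the model's premise is that an
established contaminant is permanent (SI, no recovery), persistence is the
default and the literal non-persistent update is available behind
`persistence=False` for comparison.

Draws are made only for rows of currently infected nodes.  This halves to
quarters the uniform variates consumed without changing the law of the
chain (each edge out of an infected node still gets an independent
uniform), and is what keeps full all-exporter ensembles fast.

Ensembles spawn one RNG substream per replicate from a single
`SeedSequence`, so runs are bit-reproducible given the seed and replicates
are independent.  Replicates whose start country has no outgoing edges
simply record zero successes — import-only countries cannot seed spread.

Correctness is anchored two ways: an exhaustive-enumeration oracle computes
the exact distribution of ever-infected sets on ≤4-node, ≤2-step networks
by integrating over every per-step edge outcome, and ensemble frequencies
must agree within Monte-Carlo error; and with all p = 1 the ever-infected
set must equal the start node's forward-reachable set from an independent
graph-reachability computation.

## Risk metrics

Decile comparison uses rank-based equal-count bins (n-tiles) with ties
broken by stable input order, so the heavy mass of zero-dispersal edges
fills the lowest occupied bins deterministically and the binning is
invariant to positive rescaling of the counts.  Dispersal counts are
aggregated over ensembles from *all* exporting start countries before
binning; fewer than 10 edges raises an error advising a smaller quantile
count.  Countries-contaminated quantiles use linear interpolation (type 7,
numpy's default), recorded in the output metadata.  Countries-contaminated
counts exclude the start country by default (it is infected by
construction); the inclusive count is also carried on every trace.

## Synthetic data

The network generator emulates the structural features the pipeline must
survive, not any real country's marginals: a small hub core (default 8 of
134 countries) originating most edges, a 46% fraction of import-only leaf
countries, log-normal annual volumes (location 2.0, scale 2.0 on log
tonnes, hub origins scaled ×20 — spanning ~0.1 to ~10⁴ t/yr), an overall
density target of 0.086, mirrored duplicate reports on a configurable
fraction of edges with discrepant counterparty masses, and sub-threshold
minor flows.  Discrepancies are constructed so the dedup rules recover the
ground truth exactly: counterparties of focal-country edges over-report
(the focal report must win) and other counterparties under-report (the
higher value must win).  Defaults reproduce the shape of the ryegrass
network (134 nodes, density 0.086, 72 exporters).

The inspection generator draws lot-level Bernoulli contamination (default
16% over 560 lots spread unevenly across 8 exporting countries), 1 +
Poisson species per contaminated lot from an 80-species pool, and
independent rare quarantine hits (default per-lot probability 3/560, so a
five-year record yields about three detection events).

What passing on synthetic data does *not* show: the generators make no
attempt to match real trade marginals, real species co-occurrence, or
temporal volume fluctuations, so synthetic results validate the machinery
(round trips, estimator calibration, simulator law), not any real-world
risk number.

A parameter-recovery experiment closes the loop: with every node infected,
each edge is an independent Bernoulli trial per single-step replicate, and
the empirical per-edge event frequency must match the analytic p_ij within
three binomial standard errors on every edge.

## Problem sizes and numerical choices

Default study conditions are 200 replicates × 10 time-steps per start
country; a full all-exporter run on a 134-country network takes on the
order of a minute, and the packaged end-to-end pipeline example uses a
60-country network with the same replicate settings.  Tests use smaller
networks (3–40 nodes) with replicate counts chosen so that binomial
3-standard-error bounds are decisive.  Tolerances: closed-form checks at
relative 10⁻⁹–10⁻¹²; published-value checks at the printed precision;
stochastic checks at 3–4 standard errors with fixed seeds.  Degenerate
inputs: empty record sets build an empty network (valid); an empty network
has no statistics (error); a rate above 1 event per tonne is capped at 1
with a warning; contamination rate 1 gives a clean-sample probability of
exactly 0.

## Known limitations

One global rate per event basis (no per-species or per-origin variation);
no temporal variation in volumes or rates; no establishment lag,
metapopulation dynamics or recovery; dispersal is "at least one event" per
edge per step, not a per-seed-lot count.  The duplicate-resolution rules
(favour focal, else maximum) are heuristics for irreconcilable double
reporting, and the diameter/decile conventions are choices among several
defensible ones — all are recorded in output metadata so downstream
comparisons are explicit.
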