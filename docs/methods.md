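# Methods

## Scope and structure

`frsim` simulates a randomized, parallel-group, 1:1 two-arm multi-center
trial with *central* (unstratified) randomization executed by an IRT, a
Poisson-gamma recruitment process, and a trigger-based drug re-supply
chain. One replicate is a discrete-event run; operating characteristics are
aggregated over replicates. The package has six layers: `randomization`
(schedule + allocation rules), `recruitment`, `supply`, `engine`
(event loop), `metrics`, and `scenarios`/`cli` (presets, I/O,
orchestration).

## Randomization schedule and allocation rules

The central list is a permuted-block design: within every block of
`block_size` (default 4) positions each arm appears exactly
`block_size/2` times, with the six possible AABB arrangements equally
likely. Positions are FREE, USED or CROSSED_OUT and only ever move
FREE→USED or FREE→CROSSED_OUT. The schedule is generated with
`ceil(1.5 n / block_size)` blocks up front and extended on demand from the
saved generator state (so piecewise extension equals one-shot generation);
the 1.5 headroom absorbs positions consumed by FR1a cross-outs.

The four allocation rules are pure decision functions of list state and
site availability; the engine applies a decision in a separate step.
Scanning is strictly by ascending position ("next free number" = lowest
index). Conventions that the source material leaves open, and the choices
made:

* **Forced flag.** An allocation is *forced* iff its position deviates from
  the lowest-index free position at the time of the call, for FR1a and
  FR1b alike. An FR1b *backfill* — filling the lowest free (previously
  skipped) position behind already-used ones — satisfies the
  first-free-number rule and is therefore flagged `backfill` but not
  counted in the forced proportion. This uniform deviation rule reproduces
  the reported forced percentages across all three recruitment scenarios,
  whereas counting backfills as forced roughly doubles the FR1b figures.
  Under FR1a, a patient allocated to the position after a cross-out is not
  forced: the cross-out has made that position the next free number.
* **Forced-allocation cap.** If a cap is configured and already reached,
  FR1a/FR1b behave exactly as FR0b for that call (with cap 0 they replay
  FR0b trajectories bit-for-bit, which the tests assert).
* **Scrambled display IDs** are a seeded random bijection used only for
  export; allocation logic never sees them.

## Recruitment

Site rates are i.i.d. `Gamma(shape α, rate β)` (density
`β^α/Γ(α) x^{α−1} e^{−βx}`), activations i.i.d. `Uniform(0, W)`; each site
is a homogeneous Poisson stream from its activation. Defaults are the
study conditions: `N = 80` sites, `n = 500` patients, `α = 1.2`, and
`β ∈ {16, 28, 5}` for the base / slower / faster scenarios
(mean 0.525 / 0.3 / 1.68 patients per site per week); a small variant with
`N = 16, n = 100` is also provided. Months are converted at 30 days/month,
so the 4-month activation window is `W = 120` days; the 12-month target
horizon is informational only — the engine never censors, and the
completion time is the day of the n-th randomization. (A 30.44-day month
would shift completion times by under 2%.) Recruitment is competitive:
no per-site caps; arrival generation simply stops once the target is
reached.

## Supply chain

Each site receives its initial stock at activation (counted as shipped).
Reviews happen at days 7, 14, … for all active sites: any arm whose
uncommitted stock is at or below the trigger (`k_d(t) ≤ Crit`, inclusive)
is ordered up to its target level, independently per arm; shipments arrive
after a fixed 2-day lead from an unlimited central depot. Two refinements:

* An arm already covered by an in-transit shipment that would lift it above
  the trigger is not re-ordered (moot at 2-day lead under weekly reviews,
  but it prevents double-shipping if the lead exceeds the review interval).
* **Queue-aware ordering** (`SupplyStrategy.queue_aware`, default on): kits
  committed to patients already waiting at a site — the IRT knows its own
  waitlist, and the next q free schedule positions determine which arms q
  waiting patients will need — are netted out of the stock that the trigger
  inequality sees, so a delivery both serves the queue and restores the
  targets. With nobody waiting this reduces exactly to the plain rule (all
  the worked re-supply examples are unchanged). Without it, deliveries are
  drained by the backlog and sites starve, inflating sent-home proportions
  by ~25% over the reported values and producing a spurious waitlist under
  the all-kits configuration.

## Event loop semantics

Events are processed in time order with ties broken
`DELIVERY < ARRIVAL < REVIEW`, so a weekly review always sees
post-dispensing stock. On arrival the site's current stock is passed to the
allocation rule:

* assigned → one kit of the assigned arm is dispensed (exactly one kit per
  randomized patient);
* refused (FR0a/FR0b, required kit type missing but site not empty) → the
  patient is tallied *sent home* once, joins the site's FIFO queue, and
  re-attempts at each subsequent delivery to that site; a failed re-attempt
  tallies them *waitlisted* once;
* no stock (site completely empty) → the patient is tallied *waitlisted*
  and queues.

Deliveries add stock and then serve the queue FIFO until it empties or the
head cannot be served; queues are per-site and patients never migrate.
Recruitment stops the instant the n-th patient is randomized; everyone
still queued is *not allocated*. Sent-home and waitlisted tallies are per
patient (at most once each), and the sent-home denominator is the target n.

Scripted replays (`replay_scripted`) run the identical engine with
arrivals, initial stocks and shipments taken from a script instead of being
sampled; the packaged `toy_example.json` encodes the eight-patient
single-site worked example. The one quantity the script must add to that
narrative is the re-supply amount, which the source figure omits: (2 A,
2 B) is the smallest round shipment under which all four configurations
reproduce the narrated outcomes, and a spare block "AABB" is appended to
the scripted schedule because the no-backfill configuration consumes a 9th
position.

## Randomness and reproducibility

One master seed per replicate spawns independent sub-streams for list
generation, site sampling and arrivals, and the arrival stream is consumed
in an allocation-independent order — so different IRT configurations and
supply strategies run under common random numbers (identical sites,
arrivals and schedule), which the paired monotonicity tests exploit.
`derive_seed(master, scenario, rep)` is a pure function (independent of
execution order and below 2³¹), shared across modes and strategies.

## Monte Carlo summaries

Per-characteristic means, sample SDs (n−1 denominator), `1.645·SD`
half-widths (90% upper-confidence-limit convention for error bars) and
empirical quantiles, including the 90th percentile of the forced count and
the fraction of replicates whose forced count stays at or below a
prospective cap. A single replicate reports SD = 0 with a degeneracy flag.
Imbalance is summarized as the non-negative magnitude `|n_A − n_B|`.

## Problem sizes used by the tests and the acceptance script

The acceptance script and the Monte Carlo acceptance tests use 1,000
replicates per cell (Monte Carlo SEs of the forced and sent-home
proportions are then ≈ 0.04–0.1 percentage points); property and
monotonicity tests use the 16-site/100-patient variant at 500 paired
replicates. The exhaustive allocation oracle covers every two-block
schedule against every availability sequence on small instances.

## Known limitations and open conventions

* Two arms, 1:1 allocation, one kit per patient at randomization only; no
  kit expiry, damage, dispensing error, random lead times, or depot limits;
  no stratification or dynamic allocation.
* The synthetic recruitment model omits features of real enrollment (site
  ramp-up, seasonality, screening failures, dropout after a refusal), so
  passing tests validate the allocation/supply mechanics under the stated
  stochastic model, not forecasts for any real trial.
* The reported characteristics for the no-backfill configuration are
  sensitive to conventions that published accounts typically leave
  implicit (exactly which allocations count as forced, and how returning
  patients interact with re-supply quantities); the conventions adopted
  here are stated above and exposed as configuration switches
  (`queue_aware`, `ignore_in_transit`, `forced_cap`) so alternatives can be
  tested.
* Drug overage counts every kit shipped by stop time, including initial
  site stocks and kits still in transit.
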