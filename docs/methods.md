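# Methods

## Model overview

The endplate is a disc of diameter 300 px tiled by `n_sites` identical
circular contact sites of diameter 30 px. Each site is occupied by one of
three classes — terminal Schwann cell (tSC, S), vacancy (V), or an axon
terminal (A) carrying an identity in 1..9 — and all sites have equal
area, so site-count fractions equal area fractions. The default 100
sites make the newborn composition percentages exactly integral (30 or
31 tSC, 16–17 vacant, ~6 sites per axon), which is why that count was
chosen; it is configurable.

Dynamics are a discrete-time Markov chain over occupants. Every
iteration selects one site and applies one transition draw; draws that
leave the site unchanged still consume an iteration. This convention
matters for absolute iteration counts and is fixed package-wide.

### Vacancy-mediated chain

Axon and tSC sites can only vacate (probabilities `p_AV`, `p_SV`); a
selected vacancy becomes a tSC with `p_VS`, otherwise an axon site. The
chain's stationarity condition at a target composition `r = (r_S, r_V,
r_A)` leaves one free parameter, taken to be `p_VS`:

    p_SV = r_V * p_VS / r_S        p_AV = r_V * (1 - p_VS) / r_A

`p_VS` defaults to 0.6, the value at which every measured stage
composition (P3, P7, P16) yields probabilities inside [0, 1]. A derived
probability outside [0, 1] raises an infeasibility error naming the
violated bound.

Axon identity on V→A conversion is drawn proportionally to the number of
adjacent sites each surviving axon holds. When the vacancy has no axon
neighbour, weights fall back to each surviving axon's total site count —
the natural "takeover probability proportional to relative area" reading;
extinct axons have weight zero everywhere and can never return. If no
axon site exists anywhere the vacancy simply stays vacant. Completion:
exactly one axon identity holds at least one site. tSCs and vacancies
remain present at completion, which is the model's defining prediction.

### Random / equal contrast variants

In the neighbour-adoption variants a site can only be converted into a
copy of one of its neighbours: a uniformly chosen adjacent donor is
adopted (class, and identity for axon donors) with the selected site's
transition probability into the donor's class. For `random`, all three
probability rows are redrawn every step, each uniform on the 2-simplex
(Dirichlet(1,1,1)), so individual probabilities range over [0, 1] while
rows still sum to one; for `equal` every probability is 1/3. Copying an
identical occupant realises the "no transition" outcome.

Two readings of the adoption rule were rejected empirically during
development because they contradict the observable endpoint behaviour:
(i) drawing the outcome class first and requiring a donor only for axon
outcomes lets minority classes spread as easily as majorities, so
interfaces never coarsen and runs never reach a homogeneous state; (ii)
forbidding identity copy between axon sites deadlocks all-axon states
with several surviving identities. The implemented copy rule produces
the expected absorbing classes — a single axon without tSCs or
vacancies, all-tSC, all-vacant — on the 10³–10⁴ iteration scale for a
100-site endplate. Completion for these variants: the layout is
homogeneous in class (and in identity if axonal).

### Activity bias

An "active" axon's sites are selected for transition with weight
`1/selection_divisor` (default 2 — a two-fold lower chance) relative to
every other site, realised by rejection sampling, which reproduces the
weighted distribution exactly. The active set can be fixed or redrawn
uniformly per replicate (the default in sweeps, matching the
one-randomly-chosen-active-axon design). With several active axons, the
protected endgame between them is slower neutral drift; the package
reports this as measured (see Limitations).

## Geometry

Placement draws site centres uniformly in the disc (sites fully inside:
centre radius ≤ region_radius − site_radius) subject to a minimum centre
separation of `min_separation_factor × site_diameter` (default 0.8 — 100
sites of 30 px cannot fit without overlap in a 300 px disc, so mild
overlap is intrinsic to these conditions). At the default density the
required packing (~0.67 by the exclusion-area measure) exceeds the
jamming density of naive rejection sampling (~0.55), so placement uses
rejection sampling as a fast path and, on jamming, a deterministic
pairwise-repulsion relaxation: violating pairs are pushed symmetrically
toward a 5% inflated target separation (damping 0.8), stray centres are
projected back onto the disc, and the loop ends when all constraints
hold. A request above the hexagonal-packing bound fails fast with a
geometry error naming the attempted density. Occupants are assigned to
placed positions by a uniform random permutation, interleaving all
classes at start.

Adjacency is a centre-distance threshold, default 1.25 × site_diameter
(37.5 px), capturing touching and slightly separated circles under the
permitted overlap; it is symmetric, irreflexive, and configurable. Note
that sparse layouts (few sites in the full-size disc) give disconnected
contact graphs; small-scale demonstrations shrink the region diameter
to preserve connectivity (e.g. 30 sites in a 170 px disc).

## Statistics

Batches run independent replicates with per-replicate layout, run, and
activity-draw seeds expanded deterministically from one base seed (all
below 2³¹ and recorded in the results). Run streams are further split
into a site-selection and a transition stream. Summaries report the
mean and sample SD (ddof = 1) of the least completion iteration over
completed runs, the completion rate, and a per-winner table over all
replicates (so the win table sums to the completion rate); the SD is
undefined (None) below two completed runs. Active-set win probabilities
are computed over completed runs only.

Stage contrasts use two-tailed t-tests on the per-replicate iteration
samples — Welch by default, since equal variances are clearly violated
across stages; the pooled-variance form is a switch. The composite area
`r_S·r_V/r_A` is rank-correlated (two-tailed Spearman) with per-profile
mean iterations; degenerate rank variance is reported as an undefined
correlation rather than a number.

## Synthetic composition profiles

Per-endplate variability is emulated by Dirichlet draws with mean equal
to the P3 composition and concentration 50, chosen to give clearly
visible spread (component SDs of roughly 0.05–0.07, comparable to
endplate-to-endplate scatter in measured data) while keeping essentially
every draw feasible at `p_VS = 0.6`; infeasible draws are rejected and
redrawn, which slightly trims one tail of the distribution. The
generator reproduces from its seed. It emulates only compositional
variability — not correlated geometry, endplate size differences, or
measurement error — so passing correlation tests demonstrate the
model's composition→rate link, not agreement with any particular
measured endplate set.

## Numerical choices

- Stationary vectors are computed by a linear solve of the balance
  equations and cross-checked against power iteration via repeated
  squaring of the damped kernel (I + M)/2; the routes must agree to
  5e-9. Transition probabilities below 1e-8 are treated as structurally
  absent when testing irreducibility: below that the spectral gap makes
  the stationary vector numerically meaningless, and every physically
  relevant probability is orders of magnitude larger. Reducible chains
  raise rather than return a non-unique answer.
- Solver boundary cases: derived probabilities within 1e-12 above 1 are
  clamped to 1 (division round-off exactly on the feasibility frontier).
- Largest-remainder apportionment breaks remainder ties in class order
  (tSC, vacancy, axon); the axon pool splits evenly with remainders to
  the lowest identities — bias-free because identities are exchangeable
  and positions are shuffled.
- The engine buffers uniform variates in blocks per stream for speed;
  given a seed, every run is bit-reproducible.
- `max_iter` defaults to 50,000 (vacancy-mediated), 10,000 (random) and
  200,000 (equal). Stage-comparison experiments use 400,000 via the
  `stage_config` helper so that replicates at the slow P7/P16
  compositions essentially always run to completion — the intended
  "iterate until complete" design; capped runs report `completed=False`
  with winner NONE, never an exception.

## Problem sizes in the shipped tests

The test suite runs the full 100-replicate protocol for the stage,
activity, and composition-sweep experiments at the default 100-site
geometry. The nine-way winner-symmetry check uses 900 replicates at 60
sites in a proportionally smaller disc — symmetry among exchangeable
identities does not depend on site count, and the smaller substrate
keeps the tally cheap. Contrast-model demonstrations use 30 connected
sites. Exponential-decline fits use the batch-mean distinct-axon count
of 30 recorded runs against a three-parameter exponential
`a·exp(−b·t) + c`.

## Known limitations

- The time-scale mapping is relative: one iteration is one selection
  event, and no physical time constant is fitted, so only ratios and
  orderings of iteration counts are interpretable.
- Elimination time in this dynamics class scales like
  `(r_A·n)² / (r_A·p_AV)` (neutral-drift fixation of axon identities
  driven by the A↔V flux). Because `p_AV = r_V(1−p_VS)/r_A` collapses at
  small vacancy fractions, late-stage compositions (P7: 5%, P16: 6%
  vacancy) are penalised quadratically-over-linearly, and their absolute
  iteration counts are an order of magnitude above the P3 condition's —
  far more than the modest stage differences one might expect from
  endplate physiology. Absolute counts for small-vacancy compositions
  should therefore be read with this scaling in mind.
- All sites share one size; there is no site birth/death, no continuous
  time, and no fitting of `p_VS` to data.
- tSCs are one pooled class without identities.
- The activity model biases selection only; it does not couple activity
  to reclaim success or to the transition probabilities themselves.
  A consequence worth noting: with two or more coherently active axons
  the final competition is fought between protected axons whose sites
  turn over at half rate, so additional active axons lengthen completion
  rather than adding acceleration — only the single-active condition
  shows the full speed-up under this mechanism.
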