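# Methods

`whalesong` is an individual-based model of humpback whale (*Megaptera
novaeangliae*) song cultural evolution at the hemisphere scale, together
with the summary statistics and likelihood-free (PMC-ABC) machinery used
to fit its learning parameters to song-transcription data.

## The model

### Songs, themes and memory

A song is a fixed array of 11 slots, each holding a theme identifier or
left empty; lengths between 2 and 11 themes are emergent, not enforced.
Themes have no acoustic structure — two themes are either the same or
different — so theme identity always means cultural descent, and every
invented theme receives a globally fresh identifier.

Each male whale sings exactly one *current song* and keeps a *song
memory* of recently learned songs. The memory is a **time window**: a
song learned more than round(`L_sm`) learning epochs ago is forgotten
(the fitted value, ≈55 epochs, corresponds to ≈5.5 years). Because at
most one song is learned per epoch, a ring buffer of round(`L_sm`)
entries with an age mask stores the window exactly; when it overflows,
the overwritten oldest entry has always already expired. The forgetting
horizon matters: it is what allows a song that has circulated around the
hemisphere to be re-adopted by a population that sang it years earlier.

### The yearly cycle

Each year has 10 learning epochs: 9 breeding-season epochs with tutors
drawn only from the focal whale's own population, and 1 migration/
feeding-season epoch (scheduled last in the year) in which each tutor
is, with probability `P_n`, drawn from a uniformly chosen adjacent
population instead. Tutors (round(`N_t`) of them) are drawn without
replacement within a source population, never including the focal whale.

A tutor song is *novel* if, for every remembered song, it contains at
least one theme absent from that song — equivalently, if no remembered
song is a superset of it. If one or more heard songs are novel, one is
chosen uniformly and copied:

1. **Deletion.** Each theme of the chosen song is retained with
   probability `P_learn = 1/(1 + 0.5^(k + P_d))`, where `k` counts the
   heard tutor songs (all round(`N_t`) of them, duplicates included)
   containing that theme. At the fitted `P_d = 6.42` a theme heard once
   is deleted with probability 0.006.
2. **Insertion.** Each empty slot is filled with a newly invented theme
   with probability `P_insert = e^(−P_d) · P_i`, clamped to [0, 1]. The
   printed form of this expression is typographically ambiguous; the
   alternative reading `e^(−P_d·P_i)` is ≈5×10⁻¹¹ at the fitted values,
   which would make invention essentially impossible and songs
   monotonically shrink, so the multiplicative reading (≈0.006 at the
   fitted values, the same order as deletion) is the default;
   `LearningParams(insert_rule="joint")` selects the other.
3. **Substitution.** Each occupied slot is replaced by a fresh theme
   with probability `mu`. (Replacing a theme inserted in step 2 — itself
   brand new — only relabels a never-before-seen identifier, so the
   engine elides that unobservable case; the object-level reference
   implementation applies it literally.)

If nothing novel was heard, the whale keeps its song, with only
substitution applied (in place, without refreshing the memory
timestamp). All new songs are committed simultaneously at the end of
the epoch, so the outcome is independent of agent processing order.

### Demography

Populations recover logistically from the 1960 whaling bottleneck:
`N(t) = K·N₀·e^{rt} / (K + N₀(e^{rt} − 1))` with
`r = ln[N_2015(K − N_min)/(N_min(K − N_2015))]/T`, `T = 50` years by
default so the simulated endpoint equals `N_2015`. All abundances are
males only (total estimates halved). Growth is applied once per year
before the first breeding epoch; each recruit copies the current song of
a uniformly chosen incumbent and starts with that single memory entry
(the model is silent on newborn song state; copying an incumbent adds no
new themes). There is no mortality.

The shipped demography tables (`whalesong/data/*.yaml`) are **estimated
placeholders**: the supplementary abundance table behind the original
analysis is not reproduced in the main text. They preserve the feature
that matters qualitatively — South Pacific sizes decreasing from west to
east — and are meant to be edited.

### Topologies

The Southern Hemisphere is a ring of 11 populations (BR, GA, MZ, MD, WA,
EA, NC, TO, CrI, FP, CO in circular west-to-east order), each
interacting only with its two neighbours. The Northern Hemisphere is two
disconnected cliques — Atlantic (CB, CV) and Pacific (WP, HI, MX, CA) —
with full mixing within an ocean and none between; whether a specific
Pacific pair should be unlinked is left to the editable adjacency.
Directional statistics use the geographic order within each group, so
clique endpoints have no western (or eastern) neighbour and contribute
no directional terms.

## Summary statistics and diagnostics

Theme sharing between singer samples A and B is

    TS(A,B) = mean_j [ mean_k |t_Aj ∩ t_Bk| / |t_Aj| ],

with the self-pair excluded (inner denominator ns−1) in the
within-sample case. Applying the printed ns−1 denominators verbatim to
between-sample comparisons would allow values above 1, so they are read
as encoding the within-sample exclusion only.

The seven ABC statistics, averaged over populations and the last 11
simulated years: (1) singleton themes, (2) mean song length, (3)
within-population s.d. of song length, (4) within-year within-population
sharing TS_FC, (5) turnover TS_FC − TS_FP, (6) |TS_WP − TS_EP| over the
previous year's neighbour samples, (7) max(TS_WP, TS_EP). Statistics 1,
3, 5, 7 are square-root transformed (turnover clamped at zero first:
it can in principle be negative), then each is divided by its standard
deviation over a prior-predictive reference set (3000 simulations at
full scale; scaled-down runs use proportionally smaller reference sets).
Statistic 6 follows the prose definition; the garbled printed variant
(TS_FP − TS_EP) is available via `summarize(..., stat6_printed=True)`
for sensitivity analysis.

Run-level diagnostics average TS_FC, TS_FP, TS_WP, TS_EP over
populations and years; `Diff = TS_WP − TS_EP ≥ 0.2` labels a run as an
eastward revolutionary wave (sharing biased toward the western
neighbour's previous-year song means material travels west→east),
`Diff ≤ −0.2` a westward one. Previous-year comparisons always pair this
year's sample with last year's independently drawn sample.

## PMC-ABC

Priors follow the published fit: log-uniform `N_t` {1, 20}, `P_n`
{10⁻⁷, 0.25}, `mu` {10⁻¹⁰, 10⁻³}, `L_sm` {1, 100}; uniform `P_d`
{1, 20}, `P_i` {0.2, 6}. `N_t` and `L_sm` are sampled continuously and
used round-half-up (floor 1); posterior reporting keeps the continuous
values. The ε ladder is {6, 5.5, 5, 4.5, 4, 3.5, 3, 2.75, 2.5} with 1000
acceptances per round at full scale. The perturbation kernel is the
standard population-Monte-Carlo choice the source method names but does
not parameterise: component-wise Gaussian with variance twice the
weighted empirical variance of the previous round, applied in log₁₀
space for the log-uniform parameters; out-of-prior proposals are
redrawn, and importance weights are prior/(Σ wⱼKⱼ) (the prior is flat in
the sampling space). One simulation is run per proposed particle.
Acceptance uses `distance ≤ ε`. Degenerate kernels fall back to a jitter
of 10⁻⁹ prior widths; a round aborts with a report if the acceptance
rate falls below a configurable floor. Posterior summaries are weighted
quantiles (2.5%, 50%, 97.5%). Leave-one-out validation re-estimates each
held-out pseudo-observation from the remaining reference set with a
rejection neighbourhood at the final ε (k-nearest fallback when the
ε-ball is sparse).

No empirical summary vector is printed in the source material, so
`fit` accepts any observed vector; the packaged default path fits to
pseudo-observations from `synthetic_data`.

## Synthetic data

`synthetic_data` emulates the structure of the (unpublished) South
Pacific transcription dataset: 211 singers over 11 years across the five
sampled populations (EA, NC, TO, CrI, FP), songs of 2–11 themes. The
sample-size matrix is a gamma-weighted multinomial allocation repaired
so every year retains a usable (≥2-singer) sample; the true per-cell
counts are unpublished. Pseudo-observed tables are produced by the model
itself at known parameters (simulation-based calibration) — they share
the model's idealisations (no transcription error, no acoustic
similarity grading, exact theme identity), so recovery tests validate
the inference machinery, not the model's fit to real oceans.

## Numerical and implementation choices

- Song state is interned: each distinct theme set maps to a dense song
  id; novelty is evaluated as "no live remembered song id is a superset
  of the tutor's song id" via an incrementally cached superset index,
  with compiled (numba) inner loops for the novelty scan, theme-count
  tally and tutor sampling (Floyd's algorithm, a fixed number of draws
  per agent).
- All randomness derives from one master seed through keyed Philox
  streams per (population, epoch) drawn in agent-uid order, and
  invented theme ids are a deterministic injective function of
  (epoch, population, agent, slot). Runs are bit-reproducible and the
  committed epoch state is exactly invariant under permutations of
  agent storage order (tested).
- Per-slot Bernoulli substitution/insertion events are sampled as a
  binomial count plus a uniform choice of slots — equivalent because
  slots are exchangeable — to avoid full per-slot uniform matrices.
- An all-empty copied song is legal (no length floor is imposed); empty
  songs are never novel and empty-song singers are skipped by the
  sharing statistics (which require non-empty theme sets).

## Problem sizes used by the tests and the acceptance script

The acceptance script runs the equal-demography direction-symmetry
experiment at its stated scale (11 populations, 100→1000 males each,
50 years, 200 runs, posterior-median parameters). The test suite runs
its scaled twin and the other end-to-end checks at reduced sizes chosen
once: populations rescaled by 1/10 (with `P_n` rescaled ×10 to preserve
the per-population migration coupling `n·N_t·P_n`, the quantity that
controls how often foreign songs arrive), and parameter recovery on a
5-population ring growing to 80 males over 30 years with a truncated
ε ladder {5, 3} and 200 acceptances per round against a 100-simulation
reference set.

## Known limitations

- Copying dynamics at the published posterior-median point are more
  conformist than the sharing statistics reported for the original
  simulations: novelty-gated adoption sweeps a population within a few
  epochs, so within-population sharing stays high and year-to-year
  sharing well above the reported ≈0.17, and run-level directional wave
  signatures (|Diff| ≥ 0.2) are correspondingly rare. The quantities
  that depend on that regime (directional wave counts) are therefore
  reproduced qualitatively (sign symmetry, ring-vs-clique contrast in
  Diff dispersion) rather than at their printed rates. The printed
  posterior medians are marginal medians of a correlated posterior
  fitted to unpublished data with an unpublished abundance table, so the
  behaviour *at that single point* is not strongly constrained by the
  published numbers; the published credible interval for `P_d`
  (3.34–22.73) even exceeds its own prior bound of 20, indicating the
  printed parameter summary cannot be internally exact.
- No mortality, no stochastic demography, no sex structure, no
  density-dependent interaction rates, no spatial movement within the
  migration season.
- Theme identity is binary; acoustic similarity grading and within-song
  ordering are out of scope, which is also why only an upper limit on
  the substitution rate is identifiable.
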