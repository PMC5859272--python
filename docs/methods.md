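# Methods

## Model

The crypt stem-cell niche is a one-dimensional ring of `N` equipotent
positions, each holding one stem cell carrying a clone label and a genotype
(wild type, *Apc* heterozygous, *Apc* null). Replacement events occur at
total rate `N·λ` per crypt: a uniformly chosen cell divides and its progeny
displaces one of its two ring neighbours (uniform side choice). This is
exactly equivalent to every undirected ring edge "resolving" at rate λ. At
an edge between identical genotypes the winner is uniform; at an
*Apc*-null/non-null edge the null cell wins with probability `b` (the
bias); heterozygous vs wild-type edges resolve with a separate,
neutral-by-default heterozygote bias. Simulation is event-driven (Gillespie
exponential waiting times) over the heterogeneous edges only — homogeneous
edges are no-ops — with a single integer seed fanned out to counter-based
per-crypt streams (numpy `SeedSequence` spawn keys) so cohorts are
bit-reproducible and safe to parallelise.

**The λ convention.** λ is the replacement rate *per stem cell per day*; a
division-displacement event involving any particular edge occurs at rate λ.
A contiguous clone always has exactly two boundaries on the ring, so its
size performs a continuous-time birth–death walk with total stepping rate
`2λ` and up-step probability `b`. `build_clonal_chain` constructs exactly
this chain (sizes 0..N, 0 and N absorbing), `clone_size_distribution`
exponentiates its generator, and the test suite verifies simulator/chain
agreement (total-variation distance < 0.02 at 20,000 replicates) — so the
rate convention is pinned down by a test, not only by documentation.
Because the generator is linear in λ, the inference layer diagonalises the
unit-rate generator once per `N` and reuses it for every (λ, day) pair.

**Fixation.** Neutral fixation probability is `n0/N` (martingale);
biased fixation is the gambler's-ruin form `(1−ρ^n0)/(1−ρ^N)`, `ρ=(1−b)/b`,
with the `b → 0, ½, 1` limits handled continuously (the neutral branch is
taken when `|ρ−1| < 1e−9`).

## Niche structure and Wnt inhibition

Positions `0..n_centre−1` are "centre" (crypt base), the remaining
contiguous arc is "border" (adjacent to the transit-amplifying exit).
Porcupine-inhibitor treatment, which removes stem-cell activity at the
border while leaving centre kinetics untouched, is mapped in one of two
ways:

* `remove_border` — the border arc is deleted at the treatment switch; the
  competing pool shrinks to the centre cells. Used for fixed-tissue
  fixation cohorts.
* `border_loss` — each border cell is expelled at a rate (per cell per
  day); its position is refilled by a ring neighbour's progeny and the
  expelled lineage leaves the niche permanently (no re-entry; return of
  border cells to the centre is represented implicitly by ring replacement,
  not by an explicit migration rate). Used for the intravital-imaging
  cohorts, where the gradual loss over days 1–4 matters. In the strong-loss
  limit the two modes agree on fixation kinetics.

Treatment switches on at day 1 (24 h post induction) in all cohorts.

The imaging readout conditions on clones present at the first imaging day
(day 1), counts a clone as surviving while ≥ 1 of its cells occupies any
niche position (cells pushed to the transit-amplifying zone do not count),
and stratifies by the compartment of the single founding cell.

## Scoring conventions

* **Eighths.** Clone size 0 → 0; size `N` → 8; otherwise
  `round(8·size/N)` clamped to [1, 7], so a surviving clone never scores 0
  and a non-fixed clone never scores 8. The binning arithmetic is the
  package's choice (the unit itself comes from the experimental scoring).
* **Fraction fixed** is computed among surviving clones by default; clone
  loss is accounted separately by `clones_per_field` (surviving clones per
  field of 50 crypts, field size configurable). The alternative
  denominator (all induced clones) is available by flag.
* **Apc crypt categories.** A crypt is `full` when every competing position
  is *Apc*-null, `partial` when some are, `none` otherwise; the
  full-crypt ratio is `#full/(#full+#partial)`. Crypt-level "lost *Apc* in
  the majority of cells" means ≥ 50% of niche positions null; "still
  expresses *Apc*" means zero null positions (any intact cell gives an
  RNA-ISH signal, so a crypt with a minority of null cells falls in a
  middle, minority-loss category). Scoring is crypt-weighted.

## Recombination model

An induced cell recombines the reporter cassette with probability
`p_reporter` and each *Apc* allele independently with a conditional
per-allele probability `q` given the reporter outcome (equal conditionals —
the default — recover full three-allele independence). Among
reporter-positive cells the allele-count distribution is the trinomial
`((1−q)², 2q(1−q), q²)`; only cells with both alleles recombined are
*Apc*-null (one intact allele suffices for exon-14 expression). Regional
variation is carried by `q` alone (`p_reporter` shared), with distal > 
proximal.

## Synthetic cohorts

Labelled crypts draw a zero-truncated Poisson number of induced cells
(inverse-CDF sampling, stable for small means), placed uniformly without
replacement; all induced reporter-positive cells in a crypt share one clone
label, as in tdTomato tracing. Fixed-tissue cohorts are cross-sectional
(fresh mice per timepoint); dense day grids and Apc cohorts score the same
crypts longitudinally, which is equivalent for mean curves and much
cheaper. Adenoma counts are *initiation* events — crypts fully fixed for
the *Apc*-null clone by the final timepoint; growth beyond the crypt is out
of scope and the output metadata say so.

What the generator does **not** emulate: 2-D/3-D crypt geometry, cell-cycle
structure and division asynchrony, Paneth-cell label retention, crypt
fission or death, mouse-to-mouse biological variability beyond sampling
noise, and tamoxifen pharmacokinetics. Passing tests therefore show that
the analysis pipeline is correct under the stated model, not that the model
captures every feature of real tissue.

## Inference

The likelihood of an eighths record at day `t` is the chain mass over the
clone sizes mapping to its bin, starting from the zero-truncated-Poisson
initial size (truncated at `N`), optionally conditioned on survival to `t`
(dropping lost records and renormalising by `1−P(size 0)`). Records are
independent across crypts; the daily imaging tracks are excluded from the
likelihood (small n, strong within-clone correlation across days) and used
qualitatively instead. `fit_drift` profiles integer `N` (default grid
4–32): per `N`, λ is maximised on a log-spaced grid refined by bounded
Brent optimisation; the `N` support set and the λ profile interval use the
likelihood-ratio threshold χ²₁(0.95)/2 ≈ 1.92, the latter on a fine local
λ grid maximised over competitive `N`. An `IdentifiabilityWarning` fires
for single-timepoint data and whenever the `N` support set spans a two-fold
range — the (N, λ) ridge along which early fixation kinetics are nearly
invariant. Arm contrasts bootstrap mice (cluster bootstrap, percentile
intervals).

The survival-conditioned likelihood is the default because fixed-tissue
scoring cannot see lost clones; when a dataset does record losses (as the
synthetic cohorts do), fitting with `condition_on_survival=False` uses the
loss kinetics and resolves the ridge considerably better — the
parameter-recovery study runs in that mode with single-cell labelling, for
which the contiguous-clone chain is the exact observation model.

## Default parameters (one jointly calibrated set)

No direct measurements of `N`, λ, the bias, compartment sizes or per-allele
efficiencies are available; the experiments constrain them only through the
clonal kinetics. The defaults were therefore calibrated **once, jointly**,
against four observed anchors — ≥ 80% of surviving crypts fixed at day 21
under inhibition, ≤ 20% in vehicle, a months-scale vehicle median fixation
time, and an inhibitor clones-per-field plateau by day 10 — using the exact
chain to scan the space (the scan lives outside the package) and the
simulator to confirm, and are not tuned per readout. The plateau anchor is
the binding constraint: it forces the treated-pool interior relaxation time
`≈ 1/(2λ(1−cos(π/n_centre)))` well below nine days while the vehicle
median fixation time (which scales with `N²/λ`) must exceed two months, and
that ratio is only achievable when the centre pool is much smaller than
half the ring.

| parameter | value | units | meaning |
|---|---|---|---|
| `N` | 20 | positions | competing pool, untreated ring |
| `n_centre` | 4 | positions | pool surviving Wnt inhibition |
| λ | 0.75 | /cell/day | edge-resolution (replacement) rate |
| `b` (*Apc*-null) | 0.55 | — | null-vs-WT displacement probability |
| border loss | 0.5 | /cell/day | expulsion rate, `border_loss` mode |
| labelling mean (low) | 1.2 | cells | zero-truncated Poisson, sparse induction |
| labelling mean (high) | 8.0 | cells | high-dose induction (Apc cohorts) |
| `p_reporter` | 0.8 | — | reporter recombination, both regions |
| `q` proximal / distal | 0.32 / 0.85 | — | per-*Apc*-allele efficiency |
| discordance scoring day | 10 | days | crypt-level genotype readout |
| crypts per field | 50 | crypts | clones-per-field normalisation |

`N = 20` and `n_centre = 4` should be read as *effective competitive
positions*, not anatomical cell counts, and λ as the effective
boundary-resolution rate under this geometry. With this one set the
simulated discordance also lands on the observed pattern (~70–75% of
reporter-positive crypts fully *Apc*-intact and < 5% majority-null
proximally, > 20% majority-null distally at day 10), which is the joint
feasibility the three-allele model is asked to deliver.

## Numerical choices and degenerate inputs

* Matrix exponentials use `scipy.linalg.expm`; the spectral propagator used
  in fitting clips negative round-off mass and renormalises, and is tested
  against `expm` to 1e−9.
* Bin probabilities are floored at 1e−300 before logs; impossible bins are
  handled by the exact bin-to-size mapping, never by fudged probabilities.
* Zero-truncated Poisson sampling uses the inverse CDF, exact for means
  down to 1e−9 (used to force single-cell labelling).
* Degenerate data: an empty dataset has log-likelihood 0 by convention but
  cannot be fitted; all-fixed-at-all-days data drive the fit to the
  small-N/high-λ corner of the grid without error; a monoclonal initial
  state is absorbed at time 0 and stays constant.
* Simulation sizes in the shipped tests and the acceptance script
  (5,000–10,000 crypts per readout, 100 recovery replicates of 2,000
  crypts) were chosen so Monte-Carlo error sits well inside every asserted
  tolerance while the whole suite stays desk-scale.

## Known limitations

* The 1-D ring understates the boundary count of fragmented clones in real
  2-D niche packing; multi-cell labelling starts slightly "fragmented" and
  fixes marginally faster than the contiguous chain predicts (visible as a
  ~1–2 point gap in the vehicle day-21 fixed fraction).
* Whether border cells lost under Wnt inhibition die, differentiate or
  migrate is not distinguishable here; all are "removed from the niche".
* Adenoma counts conflate initiation with neither growth nor regression;
  region differences are carried by recombination efficiency only, not by
  regional drift parameters.
* The fixation-kinetics data constrain λ and `N` largely through `λ/N²`
  early on; absolute values are identifiable only with late timepoints or
  loss accounting, hence the explicit ridge warnings.
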