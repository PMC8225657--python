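# Methods

`stochastix` simulates dynamic cellular processes — differentiation,
cell cycling, fate decisions — at single-cell, single-molecule resolution,
and exports the ground truths that benchmarking those processes requires.
This note documents the model, its parameters, and the design decisions
behind the implementation.

## Model overview

A simulation is specified by a **module network** (the *backbone*): a small
graph of gene modules connected by signed, integer-weighted regulatory
interactions, together with a **state network** whose edges declare which
modules switch on or off along each transition of the process. Mutual
antagonism between modules is the canonical driver of fate decisions: two
modules repressing each other force one side to win, producing a
bifurcation. The catalogue ships 14 predefined backbones (linear, cyclic,
bifurcating, converging, disconnected, trees, loops, and compositions
thereof). Only five archetypes are canonical designs; the remaining
catalogue members are compositions chosen by this package, documented in
`backbone.py`. The `disconnected` backbone is modelled as two regulatorily
independent programmes entered from a common start state, so that the state
network remains traversable from one start while the expression manifolds
are disconnected.

The backbone is expanded to a **gene regulatory network** in four steps:

1. *Transcription factors.* Each module receives at least one TF
   (`min_per_module`, default 1); TFs inherit the module's basal expression
   and burn flag.
2. *TF wiring.* For each module interaction A→B, every TF of B receives at
   least one regulator among the TFs of A, inheriting effect and strength.
3. *Target genes.* Targets are sampled from a reference regulatory network
   weighted by PageRank (damping 0.85), with TFs mapped onto reference hubs
   first; each target gets at most 5 regulators and is always downstream of
   at least one TF (targets with no induced regulator are anchored to a
   random TF).
4. *Housekeeping genes.* A breadth-first sample from the in-degree-capped
   reference network, regulatorily isolated from TFs and targets.

The reference network stands in for a large experimentally derived
regulatory atlas. It can be supplied as an edge-list TSV, or generated
synthetically by sequential preferential attachment (new nodes choose
regulators with probability ∝ out-degree + 1), which reproduces the
structural features the sampling steps rely on: hub regulators with
heavy-tailed out-degree and bounded in-degree. Effects of induced edges are
drawn +1 with probability 0.75 (−1 otherwise) and strengths log-uniform on
[1, 10] (rounded up); the basal expression of non-TF genes is 1 when they
have no activator, 0.5 under mixed regulation and 0 when purely activated,
so that every gene is expressible in some regulatory state.

## Reactions and the transcription propensity

Every gene G is tracked through pre-mRNA x_G, mature mRNA y_G and protein
z_G, coupled by six reactions: transcription (∅→x), splicing (x→y),
translation (y→y+z), and one first-order degradation per species. All
propensities except transcription are mass-action (rate × copy number).

Transcription follows a thermodynamic promoter model. Each of the N
regulators H_i binds the promoter with Hill occupancy term
ν_i = (z_i/k_i)^{n_i}; a binding configuration j ∈ {0,…,2^N−1} has
Boltzmann weight w_j = ∏_{bound i} ν_i and relative activation α_j, and the
propensity is xpr · Σ_j α_j w_j / Σ_j w_j. With α_j = 0 whenever a
repressor is bound and 1 otherwise, the sum collapses to a closed form; a
basal activity ba ∈ [0,1] and regulator synergism sy ∈ [0,1] extend it to

    f(z_1..z_N) = xpr · (ba − sy^{|A|} + ∏_{i∈A}(ν_i + sy)) / ∏_{i∈R}(ν_i + 1)

with R all regulators and A its activating subset. The closed form is
verified against the brute-force 2^N-state enumeration (relative error
< 1e−12 over 1,000 random promoters, N ≤ 10) and is monotone in each
regulator with the expected sign. Because ∏(ν+sy) ≥ sy^{|A|}, the
numerator is bounded below by ba, so the propensity is non-negative by
construction (a clamp guards configurations outside the supported
parameter region). The regulator abundance entering ν is the **protein**
count of the regulator (proteins are the acting species); a configuration
switch selects mRNA instead.

## Kinetic constants

Units are molecules and reciprocal simulation-time. Defaults
(`KineticsConfig`):

| parameter | default | meaning |
|---|---|---|
| `base_mrna_production` | 1.0 | base mRNA production rate |
| `transcription_amplification` | 10 | xpr = 10 × base rate |
| `premrna_halflife`, `mrna_halflife` | 1.0 | degradation = ln 2 / half-life |
| `protein_halflife` | 2.0 | idem |
| `splicing_rate`, `translation_rate` | 2.0 | per-molecule rates |
| `hill_min`, `hill_max` | 2, 3 | Hill coefficient ~ U(2, 3) |
| `k_scale` | 4 | k = z*/(k_scale · strength) · U(0.75, 1.25) |
| `synergism` | 1.0 | per-target sy |

The half-occupation constant k is centred on a fraction 1/`k_scale` of the
regulator's full steady-state protein abundance z* = tr·(spl·x*/d_y)/d_z,
divided by interaction strength so stronger interactions respond at lower
regulator abundance. This calibration is deliberate: a regulatory cascade
only advances once each TF's protein crosses its targets' k, so with k at
full steady state and slow protein turnover a five-module backbone cannot
traverse within the usual simulation horizon T ∈ [10, 20] (trajectories
stall at ~25% progression). With half-lives of 1 (mRNA) and 2 (protein)
time units, Hill coefficients of 2–3 and k at a quarter of saturation, all
catalogue backbones traverse end-to-end within T = 10 while molecule counts
stay in the tens-to-hundreds range where stochasticity is visible.
Gene-level rates are taken deterministically from the configuration; the
interaction-level draws (n, k jitter) are what distinguishes independently
sampled kinetics of one GRN — the mechanism behind batch effects and
paired-trajectory datasets.

## Stochastic simulation

Exact direct-method Gillespie SSA (numba-compiled): time advances by
τ = ln(1/r)/P with r ~ U(0,1) and P the total propensity; one reaction
fires with probability ∝ its propensity. Inter-event times at frozen
propensities are Exponential(P) (KS-tested), and a constitutive gene's
stationary pre-mRNA count matches the analytic birth–death Poisson
(mean = xpr/(splicing + degradation), Fano ≈ 1).

Each run starts with a **burn phase** (default 2 time units) from the zero
state in which only burn-flagged genes may be transcribed (burn-module TFs;
targets and housekeeping genes are always transcribable, which lets
housekeeping expression and basal target expression equilibrate). Burn rows
carry negative times and are never sampled as cells. State is recorded on a
**census grid** (default every 0.01 time units): molecule counts, all
reaction propensities, and firing counts per interval, with the exact
bookkeeping invariant that stoichiometry × firings reproduces the count
deltas between rows. A census interval of 0 records every single event.
Absorbing states (zero total propensity) end a run early; remaining census
rows hold the final state with zero propensities. Defaults: T = 10,
16–32 independent runs per dataset, seeded via `SeedSequence` spawning so a
single master seed reproduces everything bit for bit.

## Ground-truth trajectory

For each state-network edge (breadth-first from the start state) a
noise-free reference branch is produced by **deterministic mean-field
integration** (LSODA) of the same propensity functions, starting from the
end state of the upstream branch, with only the edge's declared modules
allowed to change: a TF's transcription is masked to zero unless its module
is in the state's active set. A stochastic draw would also satisfy the
letter of "run a simulation per edge", but a noise-free reference makes
correlation-based cell mapping stable. Branch durations are proportional to
edge lengths L_i, scaled so the longest root-to-tip geodesic spans the
simulation horizon.

Cells are mapped to the branch row of highest **Spearman correlation over
the TF mRNA and TF protein features** (ties resolve to the earliest
pseudotime; zero-variance cells map to the start with a warning). TF mRNA
alone — integer counts of order 10 — gives too coarse a rank signal
(pseudotime-vs-time Spearman ≈ 0.67 on a linear benchmark); adding the
smoother protein layer raises it to ≈ 0.97. Pseudotime is the geodesic
distance from the trajectory start, (Σ upstream L_i + percentage · L_edge)
/ total path length, lying in [0, 1].

## Experiment emulation

*Snapshot* sampling allocates N cells across state-network transitions
proportionally to their lengths (largest-remainder rounding, so ΣN_i = N
exactly and every allocation is within 1 of its real-valued quota), then
draws uniformly among the census rows mapped to each transition;
transitions with no mapped rows donate their quota to populated ones with a
warning. *Time-series* sampling divides [0, T] into k equal windows of
width w = (T − (k−1)g)/k separated by gaps g (defaults k = 8, g = 0.75).

Molecule sampling draws each cell's library size ls_i from a reference
distribution of per-cell transcript totals — empirical totals of any
user-supplied Matrix Market count matrix, or a log-normal stand-in
parameterised by median 5,000 counts and coefficient of variation 0.6 —
then one capture rate per molecule species from N(1, 0.05) (standard
deviation, truncated at 0), and finally one multinomial draw of exactly
ls_i molecules with probabilities ∝ capture rate × true abundance.
Per-cell observed totals therefore equal the drawn library sizes exactly.
Batch effects: one GRN, independent kinetics per batch, full downstream
pipeline per batch. Paired-trajectory datasets: one GRN, two kinetics
draws, two gold standards, cells labelled by sub-dataset.

## Per-cell ground truths

*RNA velocity* of a gene at a recorded state is its transcription
propensity minus its mRNA decay propensity. On the mature layer (default,
matching the usual definition) decay is the mature-mRNA degradation
propensity; on the pre-mRNA layer it is splicing plus pre-mRNA degradation,
in which case the velocity equals d(pre-mRNA)/dt identically in the mean
field (Pearson r = 1.0 against the finite-difference derivative of the
gold-standard trace — the oracle used in tests). Note that the mature-layer
velocity anticipates dy/dt through the splicing delay and its stationary
mean is offset by the pre-mRNA degradation share d_x/(spl + d_x); the
zero-at-stationarity property holds exactly on the pre-mRNA layer.

The *cell-specific regulatory effect* of interaction R→T at state S is
(f_T(S) − f_T(S with the regulator's protein zeroed)) / xpr_T, which lies
in [−1, 1] and carries the sign of the static interaction whenever the
regulator is active (at sy = 1). The reference quantity zeroes the
**regulator's** abundance — the operative reading of "when R is set to
zero". Binarization for AUROC/AUPR uses |regeffect| ≥ 1e−4 by default (the
threshold is a free choice; a binary truth is required and no canonical
value exists).

## Metrics

*Trajectory alignment*: classical dynamic-time-warping (full DP, steps
→, ↓, ↘; verified against exhaustive path enumeration on small grids)
plus the ABWAP score: 1 − trapezoidal area under
(pt₁[i]+pt₂[j], |pt₁[i]−pt₂[j]|) along the path. Identity alignment of
matching unit pseudotimes scores 1; the worst monotone path scores 0.

*Velocity*: per-gene Spearman correlation with the ground truth (NaN for
zero-variance genes), and per-waypoint arrow cosines: 100 waypoints spread
uniformly over the geodesic coordinate, cells weighted by a Gaussian kernel
(bandwidth = waypoint spacing, a free choice), kernel-averaged embedded
velocity compared against the local trajectory direction estimated as the
kernel-weighted least-squares slope of the embedding versus the geodesic
coordinate. The embedding is caller-supplied; a deterministic PCA
projection is bundled.

*Cell-specific networks*: per cell, the top 10,000 scored interactions are
retained (unscored ground-truth interactions rank at the bottom), AUROC and
AUPR (average-precision convention) are computed against the binarized
truth, and means are taken over cells with both classes present.

## Problem sizes and limitations

Tests and the acceptance script run at desk scale: tens of genes, hundreds
of cells, a handful of SSA runs — sizes chosen so the full suite completes
in well under a minute while every statistical check retains power; the
engine itself scales linearly in events × reactions. Known limitations:
no tau-leaping or other SSA approximations; no motif/PWM data; no
amplification, UMI-collision, doublet or ambient-RNA modelling; hard
cell-to-trajectory assignment only; the synthetic reference network
reproduces degree structure but not the biological co-regulation patterns
of a curated atlas, so conclusions about network-inference methods
transfer to real atlases only qualitatively. Library-size emulation
reproduces total-count variation and multinomial sampling noise but not
gene-specific capture biases beyond the per-species capture rates.
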