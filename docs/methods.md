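# Methods

## The model

`sbstraffic` simulates the diffusion of transcription-factor-like
particles ("tracers") on a folded chromatin polymer, using the
strings-and-binders family of coarse-grained models. The system contains
four particle species, all spheres of radius scale σ (the simulation
length unit, mapped to 15 nm, roughly the width of a chromatin fiber):

* **p** — ordinary chain monomers;
* **a** — anchor monomers: a fraction φ of the chain, drawn uniformly at
  random without replacement, designated as binding sites;
* **b** — binders: diffusible bridging particles with a strong affinity
  (ε_ab = 10 kT) for anchors only; two binders are provided per anchor
  (n_b = 2φN), enough to saturate the binding sites and bridge anchor
  pairs into stable loops;
* **t** — tracers: diffusible particles with a uniform non-specific
  affinity ε for *every* chain monomer. They model transcription factors
  in search mode — no sequence-specific site exists anywhere on the
  chain.

Chain connectivity is harmonic, E = ½k(r − r₀)² with k = 330 kT/σ² and
rest length r₀ = 1.2 σ. All particle pairs interact through a truncated
Lennard-Jones potential

    E_ij(r) = 4 ε_ij [ (σ/r)¹² − ξ_ij (σ/r)⁶ ],   r < r_cut = 3 σ,

where ξ_ij switches the attractive branch: ξ = 1 for binder–anchor and
tracer–monomer pairs, ξ = 0 (hard-core repulsion only) for everything
else, with a 1 kT repulsive prefactor for the hard-core pairs. Binders
and tracers see each other only by volume exclusion, so specific
(loop-forming) and non-specific (tracer) bridging stay separate. The two
control parameters are the chain compaction φ (2–50%) and the tracer
affinity ε (0.9–2.7 kT). Internal units are kT = 1, σ = 1, drag γ = 1.

The potential is truncated without an energy shift; the resulting step
at the cutoff is 4ε(3⁻¹² − ξ3⁻⁶) ≈ −0.005 ε, far below thermal noise and
irrelevant to the contact statistics computed at 2 σ. An optional shift
flag exists for sensitivity checks and is used by the energy-conservation
test, where the step would otherwise masquerade as integrator drift.

## Dynamics

Particles follow Langevin dynamics at constant temperature in a cubic
periodic box of edge L = 50 σ. The production integrator is the BAOAB
splitting of underdamped Langevin dynamics with unit particle mass,
γ = 1 and dt = 0.005 σ²γ/kT. Underdamped stepping is essential here:
the 10 kT binder–anchor attraction creates a steep repulsive wall whose
forces reach hundreds of kT/σ, and any overdamped scheme that displaces
particles proportionally to the force overshoots through the core at
usable timesteps. BAOAB bounds the per-step displacement by |v|·dt and
integrates the wall stably; with γ = 0 it reduces to velocity Verlet,
which the test suite uses to verify energy conservation of the
deterministic forces (relative drift ~3·10⁻⁶ over 10⁴ steps at
dt = 2·10⁻⁴). An overdamped Euler–Maruyama scheme is retained for
free-diffusion and equipartition validation, where it is exact or
near-exact. Both schemes sample the same configurational Boltzmann
distribution, and every observable in the package is a configurational
equilibrium average.

Non-bonded forces are evaluated over a Verlet neighbor list (cell-list
construction, skin 0.45 σ) rebuilt whenever the two largest particle
displacements since the last build could sum to the skin — the exact
criterion under which the list provably contains every interacting pair.
Frozen particles (fixed-polymer runs) carry no neighbor lists, which
makes tracer-only control runs roughly two orders of magnitude cheaper
than full runs. A hard floor of 0.3 σ on any LJ-active pair distance
aborts a run as unstable; inert pairs (e.g. a harmonic tether in a test)
may approach freely.

## Initialization and equilibration

Chains are grown as self-avoiding-ish random walks (step r₀, rejection
below 0.9 σ, backtracking on dead ends); binders and tracers are
inserted uniformly at random with the same overlap rule, and a short
capped-displacement descent removes residual strain. Runs then
equilibrate before sampling. At desk scale the adequacy of equilibration
is judged by recorded stationarity diagnostics — the running chain
radius of gyration and the bound-tracer count — rather than by a fixed
step count: tracer binding at high affinity is the slowest mode
(~10³ time units), so the default desk protocol spends two thirds of a
3·10⁵-step run equilibrating (2·10⁵ steps) and samples the final 10⁵
steps, one snapshot every 100 steps.

## Statistics

All contact-based statistics use one rule: two particles are in contact
in a snapshot when their minimum-image distance is strictly below
t = 2 σ, the particle diameter (and a distance at which the LJ
interaction is practically zero). From each run the package computes:

* the **polymer contact matrix** H — boolean contacts summed over
  snapshots, bonded neighbors (|i−j| ≤ 1) excluded since they are
  trivially always in contact; its row sum R_i is the total amount of
  contact made by monomer i (the analogue of a Hi-C row sum);
* the **tracer traffic** C_i — contacts between tracers and monomer i
  summed over tracers and snapshots, and the analogous **binder
  occupancy**;
* the **correspondence** between traffic and polymer contacts: the
  Pearson correlation of the raw count profiles, and the divergence
  D(C|R) = Σᵢ Cᵢ log(Rᵢ/Cᵢ) evaluated on profiles normalized to unit
  sum (natural log; zero-traffic terms contribute nothing; monomers with
  R = 0 but C > 0 receive one pseudo-count in R to keep the sum finite).
  In this orientation the divergence is ≤ 0, zero exactly when the
  normalized profiles agree on the support of C; the package reports the
  signed value and its magnitude, small magnitude meaning high
  correspondence;
* the **coverage** — percentage of monomers visited by any tracer at
  least once;
* the **bound-time fraction** — share of (tracer, snapshot) observations
  with at least one monomer within 2 σ, the quantity that maps ε onto
  the measured chromatin/nucleoplasm partitioning of real factors;
* the chain **radius of gyration** from periodic-image-consistent
  coordinates reconstructed by walking the chain bond by bond (wrapped
  coordinates would corrupt it), and the local density
  ρ_local = N (σ/r_gyr)³.

Grid summaries average per-replicate statistics over replicates, never
statistics of pooled profiles. Every contact computation is pinned in the
test suite to plain-numpy brute-force oracles (and cross-checked against
MDAnalysis' periodic distance routines).

## Genomic stage

The in-vivo stage accepts an already-normalized binned contact matrix
(dense text or sparse 3-column, 50 kb bins by default); upstream read
processing and normalization are out of scope. For each window the local
contact-decay exponent α — contact probability falling as s^−α with
genomic separation s — is the OLS slope of log(signal) against
log(separation) over the nearest 20 windows on each side, self-contacts
excluded, zero-signal pairs dropped (a pseudo-count option exists for
sensitivity checks), windows with fewer than 5 usable points reported as
missing. More negative α means less compact local chromatin.

HOT regions (highly occupied targets: sub-kilobase loci bound by most
chromatin proteins) are tested for enrichment at chromosomal loops under
a binomial null: a HOT counts as overlapping when its midpoint falls in
the merged loop footprint (HOTs are typically < 1 kb, so midpoint and
any-overlap rules nearly coincide; both are available), and the null
overlap probability is footprint / genome size. The decay contrast at
HOTs uses Welch's unequal-variance t test with Welch–Satterthwaite
degrees of freedom, pooling one window estimate per HOT against all
window estimates genome-wide.

Interval inputs come in three dialects — BED (0-based half-open),
Arrowhead domain lists (domain bodies by default; the two boundary
intervals selectable, since which coordinates define "the basis of a
loop" is ambiguous in domain calls), and FASTA headers carrying 1-based
inclusive `chrom:start-end` loci (converted on read). All coordinates
are 0-based half-open internally.

## Synthetic data

Because the real matrices and interval sets are multi-gigabyte
downloads, the package generates faithful synthetic stand-ins:

* `synth_hic` builds a symmetric matrix signal(i,j) =
  base·|i−j|^((αᵢ+αⱼ)/2) with a per-window exponent field (background
  −1.22, the typical mammalian genome-wide decay, plus patches),
  multiplied by symmetric log-normal noise, plus Gaussian loop peaks.
  On noiseless input the decay estimator recovers the generating
  exponent to 10⁻⁶ at every window more than one flank from a patch
  boundary — the estimator's exactness anchor.
* `synth_intervals` places loops uniformly and HOT midpoints inside the
  merged loop footprint with probability ρ·p_null (ρ = 1 reproduces the
  null exactly, larger ρ gives ρ-fold enrichment in expectation). Under
  ρ = 1 the enrichment p-values are calibrated: across 200 seeds the
  rejection rate at 0.05 sits within [0.02, 0.08].

What the generators do not emulate: distance-dependent noise structure,
A/B compartment checkerboards, translocations, copy-number effects, and
mappability gaps of real Hi-C; clustering and chromatin-state biases of
real HOT catalogs. Passing the synthetic tests therefore demonstrates
estimator correctness and calibration, not robustness to every artifact
of real data — the published-data test tier (run when a local copy of
the GM12878 inputs is present) covers the latter.

## Fixtures

Three hand-built configurations give the analysis layer exact targets:
a two-bead chain at 1.5 σ (exactly one contact), a 100-bead chain whose
anchor monomers 25 and 75 are held 1.5 σ apart by construction — the
geometry is solved so that the anchor pair is the *only* non-neighbor
pair within 2 σ — and a 5×5×5 serpentine block whose surface bead set is
known a priori. The single-loop fixture doubles as the loop-enhancement
experiment: the two anchor monomers are pinned at their 1.5 σ
separation, the rest of the chain and the tracers move, and the package
reports the ratio of anchor traffic to the chain-interior mean
(monomers at least 5 bonds from any anchor and from the chain ends).
Pinning only the anchors matters: freezing the whole chain leaves a
rigid four-branch junction whose multivalent pockets trap tracers and
inflate the enhancement well past what a thermally breathing loop
shows; the frozen variant is available for comparison.

## Scaled study conditions

The published study grid (25 φ × 10 ε × 10 replicates, N ≈ 10³, 10⁸
steps per run) is far beyond a single-CPU session, so the package's
default experiments are trend-level reductions whose sizes are its own
standing choices:

* ε calibration: φ = 0.10, N = 300, 10 tracers, ε ∈ {0.9, …, 2.7},
  3 replicates, 3·10⁵ steps per run (the acceptance script);
* regime grid: φ ∈ {0.02, 0.50} × ε ∈ {0.9, 2.7}, 2 replicates at the
  same run length (the test suite);
* fixed-polymer controls: the polymer+binder system is equilibrated and
  frozen, then attractive (ε = 0.9) and hard-core-only tracers diffuse
  over the same structure for 2·10⁶ steps — frozen runs are cheap, and
  tracers that rarely touch the structure need long averaging before
  the spatial structure of their traffic rises above counting noise;
* loop fixture: 10 tracers at ε = 2.3 over the single-loop chain with
  pinned anchors, 6·10⁵ steps.

At these sizes every qualitative contrast of the full study reproduces:
the bound-time curve rises from a few percent at ε = 0.9 through 50%
near ε ≈ 2.2–2.3 kT; contacts predict traffic in open chains with sticky
tracers (r ≈ 0.7–0.8) and anti-predict it in dense globules with weakly
bound tracers; coverage falls with compaction and recovers with
affinity; binder–tracer occupancy correlations turn negative at high φ.
Absolute numbers (e.g. the bound fraction at the strongest affinity)
sit a little below the full-scale study's because a 300-monomer chain
offers ~3× less binding volume in the same box and desk-length windows
retain some residual equilibration bias; the acceptance script reports
whatever the runs produce.

## Numerical choices

* dt = 0.005 (BAOAB): stable against the 10 kT wall; bond-period
  resolution ωdt ≈ 0.09.
* Contact threshold comparisons are strict (<); ties at exactly t are
  excluded.
* Pearson correlations of zero-variance profiles are reported as
  missing, never as 0.
* Welch comparisons between two exactly constant samples are flagged
  degenerate (difference reported, p undefined).
* The ε-calibration precondition that bound time increase with ε is
  verified by rank correlation (Spearman ≥ 0.8 and net increase) rather
  than strict per-point monotonicity, which replicate noise at adjacent
  grid points would make brittle.
* Per-cell sweep seeds derive from (base seed, φ, ε, replicate) through
  a seed sequence, making results independent of execution order and
  sweeps resumable cell by cell.

## Known limitations

* Monovalent tracers, crowded media, and tracer-induced polymer collapse
  are outside the present scope (extension points only).
* No real-units mapping of the diffusion coefficient is attempted.
* Desk-scale runs equilibrate by diagnostic, not by the full-scale
  protocol; slow modes (globule annealing at φ = 0.5) retain some
  initialization memory that replicate averaging does not fully remove.
* The binomial enrichment null assumes independent HOT placement;
  clustered HOTs would make it anti-conservative.
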