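# sbstraffic

Coarse-grained molecular dynamics of transcription-factor search on
folded chromatin, plus the genomic analysis that connects the
simulations to Hi-C and ChIP-seq data.

Transcription factors find most of their binding sites while diffusing
in "search mode", hopping between the nucleoplasm and the chromatin
fiber. Where the fiber folds back on itself — at the base of a
chromosome loop — a searching factor can fall off one strand and
reattach to the other, so genome conformation shapes where factors
accumulate. `sbstraffic` implements a strings-and-binders polymer model
to study this: a bead–spring chain of `N` monomers in which a fraction
`φ` of monomers ("anchors") are bridged into stable loops by diffusible
binder particles (affinity 10 kT for anchors), while tracer particles
with a uniform non-specific affinity `ε` for the whole chain play the
role of searching transcription factors. All beads interact through a
truncated Lennard-Jones potential

    E_ij(r) = 4 ε_ij [ (σ/r)^12 − ξ_ij (σ/r)^6 ],   r < 3σ,

bonded neighbors through harmonic springs (k = 330 kT/σ², r₀ = 1.2 σ),
and the system evolves by Langevin dynamics (BAOAB) in a periodic box.

From each trajectory the package computes the statistics that define
the science: the intra-polymer contact matrix `H` and its row sums
(polymer contacts `R_i`), the tracer traffic `C_i` (tracer–monomer
contacts at threshold 2σ summed over tracers and snapshots), their
correspondence — Pearson r and the divergence
`D(C|R) = Σ_i C_i log(R_i/C_i)` on unit-normalized profiles — the
tracer coverage, the binder–tracer exclusion correlation, the
bound-time fraction that calibrates `ε` against measured
chromatin/nucleoplasm partitioning, and the chain radius of gyration
with the local density `ρ = N (σ/r_gyr)³`.

A second stage analyzes real or synthetic genomic data: windowed
contact-decay exponents (`contact probability ∝ s^−α`) from binned Hi-C
matrices by log–log regression over ±20 windows, and the enrichment of
HOTs (highly occupied targets — sub-kilobase loci bound promiscuously by
most chromatin proteins) at chromosomal loops under a binomial null.
Synthetic generators for both input kinds make the whole stage testable
offline.

## Worked example

Run a small simulation in the dilute-loop / sticky-tracer regime and
ask how well polymer contacts predict tracer traffic:

```python
from sbstraffic import SimulationConfig, run, analyze_run

config = SimulationConfig.from_params(
    N=300, phi=0.02, epsilon=2.7, n_tracers=10, seed=7,
    n_equil=200_000, n_total=300_000, sample_every=100,
)
traj = run(config)
for key, value in analyze_run(traj).items():
    print(f"{key:>20}: {value:.3f}")
```

prints (about half a minute on one CPU):

```
               r_gyr: 13.105
           rho_local: 0.133
           pearson_r: 0.731
                d_kl: -0.390
            abs_d_kl: 0.390
            coverage: 83.333
      bound_fraction: 88.730
  binder_exclusion_r: 0.128
```

The open chain (ρ ≈ 0.13) with strongly bound tracers (89% of tracer
time on the polymer at ε = 2.7) shows the loop-guided regime: the
per-monomer contact count predicts the tracer traffic with r ≈ 0.73 and
a small divergence. Rerunning with `phi=0.5, epsilon=0.9` produces the
opposite regime — a collapsed globule (ρ ≈ 0.9) whose contact profile
*anti*-predicts traffic (r < 0), because tracers only graze the globule
surface while interior monomers make the most contacts.

The same machinery drives the command line:

```bash
sbstraffic sweep --phi 0.02 --phi 0.5 --epsilon 0.9 --epsilon 2.7 \
    --replicates 3 --seed 1 --outdir sweep_out
sbstraffic synth --kind hic --seed 1 --outdir hic_demo
sbstraffic hic-decay --matrix hic_demo/matrix.tsv --out hic_demo/decay.bedgraph
```

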