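# Methods

## The model-building loop

`edafrag` predicts coarse-grained protein backbones by fragment assembly in
torsion space. A conformation is the vector of per-residue (φ, ψ, ω)
dihedrals; Cartesian N/CA/C coordinates are derived from it with fixed
ideal bond lengths and angles, so fragment insertion — replacing the
torsions of a 9- or 3-residue window with a library candidate's — is the
only move. Each model starts from the extended chain (φ = −150°, ψ = +150°,
ω = 180°) and is built in two stages: 9-mer windows establish the fold,
3-mer windows refine it. Within a stage the sampler alternates simulated
annealing (Metropolis acceptance, geometric cooling) with iterated hill
climbing (greedy descent plus unconditional perturbation "kicks", keeping
the best conformation ever visited).

Models are generated in T rounds (default 4), each contributing an equal
share of the total budget. Fragment choice within a window is
fitness-proportionate (roulette wheel) under that window's probability mass
function. Round 1 uses uniform probabilities; after every round, the
lowest-energy fraction of the cumulative pool (default 10%) forms the
sample set, and each window's distribution is updated with the
conservation-rate mixture

    p_i(t+1) = k · p_i(t) + (1 − k) · f_i ,     k = 0.6 by default,

where f_i is the frequency of fragment i among the sample-set models that
carry a record for the window (windows observed by no sample-set model keep
their current distribution rather than being reset — sparse coverage must
not erase learned mass). The update is affine on normalized vectors, so
normalization is preserved exactly; k = 1 reduces the method to independent
rounds, k = 0 to pure frequency following.

## Provenance

Every insertion records (window start → fragment index). Two bookkeeping
policies are implemented in one place (`apply_provenance`):

* `invalidate` — strict last-writer-wins: a record survives only while the
  window's torsions are still entirely the recorded fragment's; any
  partially overlapping later insertion clears it. This is the contract of
  the public `insert_fragment` operation.
* `keep` — usage tracking: only a same-window insertion overwrites; the map
  reads as "the last fragment used at this window during construction".

Model building defaults to `keep` (`SamplerConfig.provenance_policy`).
With dense stride-1 window sets the strict policy leaves only the few
mutually non-overlapping windows that were written last (~2–3 of 28 on a
36-residue target, biased toward the chain ends), which starves the
frequency estimator at desk-scale sample sizes; the usage-tracking policy
gives every window a vote from essentially every model. 9-mer and 3-mer
records are kept in separate maps; only 9-mer usage feeds the distribution
update unless `learn_3mers` is enabled.

## Energies

The driver ranks models by whatever `ScoreFunction` the configuration
names; the contract is a deterministic map from conformation to a scalar
(lower is better). Two scorers ship:

* **Reference score** (native-blind): soft-sphere CA clash penalty
  (Σ max(0, 4.0 − d_ij)² over pairs ≥ 3 residues apart), a radius-of-gyration
  term (Rg − 2.2·N^0.38)² pulling toward globular compactness, and a local
  contact reward (−1 per CA(i)–CA(i+3) distance inside [4.5, 5.5] Å, a
  proxy for helical hydrogen bonding). Weights are configurable; energies
  are unitless.
* **Oracle score** (native-aware): the CA RMSD to a hidden reference
  structure, optionally plus one Normal(0, σ) draw per finished model.
  It creates a perfectly funneled landscape and is the instrument for
  validating that the estimation step enriches near-native fragments when
  the energy is informative. Determinism of the contract is kept by adding
  the noise in `record_energy` (called once per model) rather than in the
  per-move evaluation.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `EdaConfig.budget` | 400 | total models per run |
| `EdaConfig.iterations` | 4 | rounds; budget/iterations models per round |
| `EdaConfig.sample_fraction` | 0.10 | lowest-energy fraction forming the sample set |
| `EdaConfig.conservation_rate` | 0.6 | k in the mixture update |
| `EdaConfig.sample_base` | cumulative | sample from the whole pool or the last round only |
| `SamplerConfig.sa_steps_per_window` | 20 | SA move attempts per window per stage |
| `SamplerConfig.t_start` / `t_end` | 2.0 / 0.01 | annealing temperatures (energy units) |
| `SamplerConfig.t_start_3mer` | 0.3 | start temperature of the 3-mer stage |
| `SamplerConfig.ihc_restarts` | 3 | greedy rounds in iterated hill climbing |
| `SamplerConfig.ihc_steps_per_window` | 8 | greedy moves per window per round |
| `SamplerConfig.kick_size` | 2 | unconditional insertions between greedy rounds |
| `SamplerConfig.provenance_policy` | keep | insertion bookkeeping (see above) |
| `OracleScore.sigma` | 0.0 | per-model energy noise (Å) |

The 3-mer stage anneals from a much lower temperature than the 9-mer
stage: it is a refinement pass, and restarting at the full temperature
re-melts the fold the 9-mers built (observed directly: with a shared
t_start the iteration-over-iteration energy shift disappears because every
model is annealed back to the same landscape floor).

The schedule defaults were chosen for desk-scale problem sizes
(20–40 residues, 10–25 fragments per window) where a model build takes
~0.1–0.2 s; all counts scale with the window count of the target.

## Randomness and reproducibility

One master seed per run. Each model's stream is derived from
(master_seed, iteration, model_id) via `numpy.random.SeedSequence`, so any
model is reproducible in isolation and results are bit-identical regardless
of build order or worker count (`workers > 1` distributes model builds over
a process pool). Fixture generation is likewise a pure function of its spec.

## Synthetic benchmark fixtures

`fixtures.make_fixture` invents a clash-free native backbone from
secondary-structure regimes — helix (−60, −45), strand (−120, 130) and coil
segments with small jitter, trans ω, resampled until no CA pair ≥ 3
residues apart is closer than 4 Å — and builds a dense fragment library
around it: per window, one near-native fragment (native torsions + 2°
jitter) hidden among decoys (native torsions + 60° jitter on φ/ψ),
shuffled so the planted fragment sits at a random index. Defaults (36
residues, 25 fragments per window) keep a full 4-round, 400-model run
around one minute on one CPU.

What the fixtures emulate — and what they do not: they reproduce the
*funnel structure* of the problem (a discrete choice space in which some
fragments are measurably closer to the native than others, and an energy
that correlates with that distance), which is exactly what the
distribution-estimation step feeds on. They do not emulate real
Ramachandran statistics, sequence-dependent fragment quality, non-ideal
native geometry, or the ruggedness of physical energy functions. Passing
tests therefore demonstrate that the loop *learns and exploits an
informative energy signal*, not that any particular real protein would be
predicted to a given accuracy.

## Numerical choices

* Torsions are canonicalized to (−180°, +180°], with −180 mapped to +180,
  removing the double representation that would break round-trip equality.
* Chain building places residue 1 in a fixed canonical frame; φ(1), ψ(n)
  and ω(n) have no flanking atoms, are geometrically inert, and are
  reported as NaN by the dihedral measurement. Build and measurement are
  mutual inverses to < 1e−6° on the defined entries.
* Incremental rebuilds after an insertion recompute only the affected
  suffix and are bit-identical to a full rebuild.
* `ca_rmsd` is the optimal-superposition (Kabsch/SVD) RMSD; near-zero
  values carry ~1e−6 Å of floating-point cancellation noise. The oracle
  scorer uses a closed-form 3×3 eigenvalue path against a pre-centered
  native (~5× faster, agrees with the SVD path to ~1e−7 Å).
* Energy ties in ranking, sample-set selection and blind selection are
  broken by model id, making every selection deterministic.
* Sample-set size is ⌈fraction·pool⌉; the budget must divide evenly by the
  iteration count (equal per-round shares).

## File formats

Fragment files are a documented subset of the Rosetta fragment-file layout:

    position:            1 neighbors:           25
                                                      ← blank line
     1xyz A    42 A H  -61.500  -44.200  179.100      ← source tag, aa, ss
     1xyz A    43 A H  -60.100  -45.800  178.600        then φ, ψ, ω
     ...                                              ← one line per residue;
                                                        blank line ends a fragment

Trailing columns are ignored; fragment order inside a window defines the
fragment index that probability vectors refer to, and serialization
preserves it. Sequences are single-record FASTA. Models are backbone-only
PDB (chain A, 1-based numbering); the B-factor column carries the 9-mer
provenance window start covering the residue (0.00 when uncovered).

## Known limitations

* Backbone N/CA/C only: no side chains, no centroid pseudo-atoms, no
  all-atom refinement stage — the `refine_hook` in `run_eda` is the seam
  where one would plug in.
* Ideal geometry means real natives can only be approximated to ~0.1 Å
  (torsion extraction + rebuild), which bounds the fragment-vs-native RMSD
  diagnostics.
* The reference score is a minimal compactness/clash potential, adequate
  for exercising the machinery but not for real structure prediction.
* Window scheduling is uniform; no reversible-insertion or replica-exchange
  moves.
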