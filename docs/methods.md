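# Methods

This note documents the models, rules and numerical choices implemented in
`mrpilot`, in the order data flows through a run.

## Template library curation (`template_library`)

The library holds protein chains as the basic entries, each with sequence,
Cα coordinates, and the resolution of the data it was refined against.

**Filter.** A chain is kept when its length is at least `min_length`
(default 16, i.e. strictly more than 15 residues) and its resolution is
known and at most `max_resolution` (default 3.5 Å). Unknown resolution is
represented as absent and fails the filter — a deliberately conservative
choice, since the redundancy rule below needs resolutions to pick
representatives.

**Redundancy reduction.** Two chains are redundant when their pairwise
sequence identity exceeds `dedup_identity` (0.80) *and* their Cα RMSD after
least-squares superposition over the aligned pairs is below `dedup_rmsd`
(1.0 Å). Entries are processed by resolution ascending (entry id as the
deterministic tie-break) and kept greedily unless redundant against an
already-kept entry, so every displaced chain is represented by one refined
at equal or better resolution. Pairs with high identity but RMSD at or
above the threshold are *both* kept: that is what preserves conformational
variability (open/closed domain motions) in the library. A chain with
fewer than 3 aligned Cα pairs to any retained entry is always kept, since
superposition is undefined. Identity is identical aligned pairs over
aligned (non-gap) columns; dividing by the shorter sequence length instead
is available as a config switch.

**Hierarchy.** Chains (and domains) are organized by average-linkage
agglomerative clustering on 1 − identity, via scipy. How a production
database would *correct* the sequence hierarchy with a structural
alignment is not specified anywhere we could adopt it from, so the two
trees are stored independently.

**Domain decomposition.** Domains are contiguous residue ranges chosen for
spatial compactness. The algorithm is a recursive single-cut search: for a
segment, count Cα–Cα contacts (≤ 8 Å, sequence separation ≥ 3) crossing
each admissible cut; split at the cut with the fewest crossings when both
parts reach `min_domain_len` (default 40) and the crossings are at most
`split_fraction` (default 0.04) of the segment's contacts; recurse.
A two-lobe chain splits at its linker (crossing contacts ≈ 0), while any
cut through a compact globule crosses far more than 4% of its contacts, so
globules stay whole. This is a simple reproducible stand-in for
curation-assisted domain definition; it only produces contiguous domains.

**Assemblies** are inputs — rotation/translation operators per chain
(orthogonal, det +1, checked to 1e-6) — not computed from interface areas.

## Homologue search and ranking (`model_search`)

Pairwise alignment uses Biopython's `PairwiseAligner` with BLOSUM62,
gap open 10, extend 1, global mode (a local mode is configurable). The
test suite pins it against an independent quadratic Gotoh dynamic
program. The pre-MR ranking score is

    prescore = identity × coverage,

identity over aligned columns and coverage the aligned fraction of the
target — the simplest monotone combination of alignment quality and
completeness; it is a pluggable strategy.

`search_hierarchy` reproduces the grouped presentation of candidates:
assembly hits for every subset of ≥ 2 target sequences (2^k − k − 1
subsets for k sequences, larger subsets first), then for each sequence up
to `max_structures_per_sequence` (5) source structures — selected by best
chain prescore — each contributing multimer, monomer and domain models
with indices `sq<seq>st<structure>m<model>`, then cross-structure domain
hits (`sq<seq>dm<k>`). Assembly hits are indexed `as<group>m<model>`.
Groups whose target has at least two matching chains are flagged
ensemble-eligible so ensembles are tried before single chains. The
reporting floor is 0.20 identity for chains and 0.10 for domains (domain
solutions at very low identity are a documented use case, so the floor is
per-model-type and configurable). `rank_templates` provides the flat
prescore-ranked list (capped at `max_whole_chain_models` = 15) used by
the exhaustive flow.

**Copy number.** Copies per asymmetric unit are estimated Matthews-style:
protein volume 1.35 Å³/Da (density 1.23 g/cm³, equivalent to the
conventional 2.69 Å³/Da Matthews coefficient at ~50% solvent). The count
whose implied solvent fraction is closest to 50% within the feasible band
[0.25, 0.75] is returned; 0 with a warning when nothing is feasible.

## Search-model preparation (`model_prep`)

Four model types are prepared per template in the exhaustive flow:
unmodified, mixed via the target pairwise alignment, mixed via a
multiple-alignment-informed pairing, and polyalanine. The two mixed
variants feed one pruning engine with different alignment sources: the
second uses a target-centred star alignment over the top templates and
drops target columns covered by fewer than half the templates (external
MSA programs can be substituted as adapters; with one template it reduces
to the pairwise map).

**Side-chain pruning.** A fixed shared-atom table drives truncation: each
residue type is stored as a tree of heavy atoms (parent pointers back to
Cα), and an atom is *shared* between two types when its full bonded path
exists in both — so Phe→Tyr keeps the ring through CZ but not OH, while
Ile CD1 is not kept for a Leu target (different parent). Substituted
residues keep the shared set (at minimum backbone + Cβ; a glycine target
keeps no Cβ) and are relabelled to the target type; unaligned template
residues are deleted. Pruning never adds atoms.

**Superposition** is least-squares (Kabsch, via Biopython's SVD
superimposer), requiring ≥ 3 non-collinear pairs; the tests cross-check it
against Horn's quaternion method to 1e-9.

**Ensembles.** Members are ordered deterministically (prescore descending,
then id), the common core is the set of first-member positions aligned in
every member, all members are superposed onto the first over the core's
Cα, and by default members are trimmed to the core so counts agree — an
explicit-core substitute for engines that down-weight divergent regions
internally; full-length retention is a config option.

## Solution scoring (`solution_scoring`)

The Q factor is computed from the final refinement statistics:

    Q = exp(-[(1 - w)·Rfree_final + (w/2)·R_final]),  w = 0.75.

It is strictly decreasing in both statistics and reproduces the two
reference solution summaries (Q = 0.842 for R 0.3730→0.2520 /
Rfree 0.4070→0.3100; Q = 0.829 for R 0.403→0.272 / Rfree 0.427→0.342).
Q > 0.75 is treated as definitely correct, Q < 0.25 as very unlikely.
The probability map is a logistic in Q, centred on the middle of that
band and scaled so the edges land on 0.99 and 0.01 — consistent with both
reference summaries displaying 99.0% under the report cap. Internal
probabilities are never capped; the report layer caps the *displayed*
value at 99.0% and shows one decimal.

The trajectory classification uses the final R<sub>free</sub> and its
total fall: good ⇔ final ≤ 0.45 and drop ≥ 0.05; marginal ⇔ final ≤ 0.52
and drop ≥ 0.02; poor otherwise. All four thresholds live in
`ScoringConfig`; boundaries are inclusive ("at least as good as the
threshold") so the classification of a borderline trace is deterministic,
and a flat high trace can never classify good. This is a conservative
screen — poor solutions can still merit inspection.

Solutions are ranked by final R<sub>free</sub> ascending, ties broken by
Q descending and then model index, with dense ranks 1..n.

## The simulated engine and synthetic problems (`engine_sim`)

The simulator exists to exercise decision logic, not to model
crystallography. Its constants are all in `SimulatorConfig` and are
inventions calibrated so that good/marginal/poor trajectories and Q on
both sides of the decision band are reachable:

* model quality `q* = identity × coverage × exp(−RMSD)` against the ground
  truth (alignment + superposition of the model onto the truth);
* placement succeeds when `q*` (plus seeded noise, σ = 0.005) clears a
  floor of 0.02, relaxed by 1/(1+n_fixed) when partial solutions are fixed
  (a smaller residual problem is easier, never harder);
* R<sub>free</sub> starts near 0.55 and decays exponentially
  (τ = 6 cycles) toward an asymptote `max(0.20, 0.55 − 0.35·q*)`;
  R runs below it by a gap `(0.02 + 0.05·(1 − q*))` that grows over the
  run (overfitting is worse for bad models); failed placements give a flat
  trace at 0.55 with σ = 0.002 noise;
* noise streams are keyed on (seed, model source, model type), so runs are
  bit-reproducible and invariant under batching or re-ranking.

Synthetic problems are generated from a seed: a compact pseudo-protein Cα
walk (step 3.8 Å, confined to a globule of radius 2.5·N^0.38 Å) with an
approximate backbone + Cβ built from local frames; homologues derived by
mutating the sequence to a requested identity and perturbing coordinates
with isotropic noise (per-axis σ/√3, so the Cα RMSD concentrates at σ);
unrelated decoys as fresh walks; an optional planted multimer record; and
a unit cell sized for one copy of the target content near 50% solvent.
Problem sizes used throughout the tests — chains of 50–100 residues, ~10
decoys, 20 seeds per statistical claim — are the package's own desk-scale
conditions.

What the generator does **not** emulate: real side-chain geometry beyond
Cβ, realistic secondary structure, crystal packing, diffraction data,
twinning or pseudo-translation (the scores are documented as potentially
misleading there, and the simulator does not model them). Passing tests
demonstrate that the *decision layer* behaves correctly given engines with
these qualitative properties — not that any particular real structure
would be solved.

## Orchestration (`orchestrator`)

The staged flow advances while the best-so-far Q is at or below the
definite threshold (0.75): assemblies (all-sequence subsets first), then
per-sequence models with ensembles tried before single chains, then the
combination stage — sequences ordered by best-solution Q descending, the
strongest fixed first, each remaining best placed in turn with the fixed
list growing, and the result indexed by concatenating the constituent
indices with underscores. Mid-band solutions (0.25–0.75) are accepted only
after all stages, with their probability reported.

The exhaustive flow processes prescore-ranked templates, four model types
each, early-exiting on the first *good* classification unless `try_all`
is set (the class, not a bare R<sub>free</sub> cutoff, is the exit
criterion). The pre-MR rank of each template is recorded on its solutions
so the displacement between sequence ranking and refinement ranking can be
reported. `batch_runner` partitions entry ids into consecutive batches and
merges the ranked lists; with the simulated engine the merged result
equals an unbatched run up to ranking ties. Local parallelism is a small
thread pool over batches — cluster schedulers are out of scope.

Space-group alternatives are carried as a config list and forwarded to
engines; the simulated engine ignores them.

## Known limitations

* For R statistics below 1 the Q form above is bounded below by
  exp(−0.625) ≈ 0.53, so the "very unlikely" band edge (0.25) acts as a
  guard rather than a reachable regime; in practice the 0.75 definite
  threshold does the discriminating (planted homologues score ≈ 0.82–0.87,
  flat decoy trajectories ≈ 0.70–0.73).
* The domain decomposition produces contiguous-range domains only.
* The MSA-informed mixed model uses a star alignment, not a true
  progressive MSA; it is an alignment-source plug-in point.
* The simulated engine's quality proxy reads the model *sequence*, so
  polyalanine models score poorly with it even when their coordinates are
  good; conclusions about polyalanine efficacy should not be drawn from
  the simulator.
* External-engine adapters build command lines but are not configured to
  run anywhere; they exist for contract parity.
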