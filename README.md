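# mrpilot

**The decision layer of automated molecular replacement, as a testable
Python package.**

When a crystallographer has diffraction amplitudes and a sequence but no
phases, molecular replacement (MR) solves the structure by placing a
homologous *search model* in the unit cell. Automated MR pipelines do far
more than run the placement program: they curate a template library, find
and rank homologues, edit them into search models (side-chain-pruned
"mixed" models, polyalanine, domains, multimers, superposed ensembles),
drive MR and restrained refinement over many candidates, and decide — from
the refinement statistics alone — which result, if any, is a solution.

`mrpilot` implements that decision layer end to end. The MR and refinement
engines themselves (rotation/translation search, reciprocal-space
refinement) are deliberately abstracted behind a small contract, with a
seeded *simulated engine* standing in so every decision path can be
exercised at desk scale; adapters for external engines share the same
contract.

## The scores at the core

After a candidate model is placed and put through restrained refinement
(30 cycles by default), its solution quality is scored from the final
agreement statistics *R* and *R*<sub>free</sub>:

```
Q = exp(-[(1 - w)·Rfree_final + (w/2)·R_final]),   w = 0.75
```

*Q* > 0.75 marks a solution that is definitely correct and *Q* < 0.25 one
that is very unlikely to be; in between, a logistic map

```
P_solution = 1 / (1 + exp(-k (Q - 1/2))),   k chosen so P(0.75) = 0.99, P(0.25) = 0.01
```

expresses how likely the solution is. Reports display the probability to
one decimal, capped at 99.0%. Independently, each refinement trajectory is
classified **good / marginal / poor** from its final R<sub>free</sub> and
how far it fell (defaults: good ⇔ final ≤ 0.45 and drop ≥ 0.05; marginal ⇔
final ≤ 0.52 and drop ≥ 0.02), and the processed models are ranked by
final R<sub>free</sub>.

Upstream of scoring, the library curation follows the standard
MR-database rules: chains longer than 15 residues refined to 3.5 Å or
better; of two chains with >80% sequence identity **and** <1 Å Cα RMSD the
higher-resolution one is kept (conformational variants are all kept);
chains and domains are organized hierarchically by sequence identity.
Candidate ranking uses identity × alignment-coverage; copy numbers per
asymmetric unit come from a Matthews-style solvent-content estimate.

Two orchestration strategies are provided:

* **staged flow** — assembly models over all sequence subsets first, then
  per-sequence models (ensembles before single chains), then a combination
  stage that fixes the best partial solution and searches with the others
  in turn (the result is indexed like `sq2st2m1_sq3st1m1_sq1st4m1`);
* **exhaustive flow** — every ranked template prepared in four model types
  (unmodified, pairwise-mixed, multiple-alignment-informed mixed,
  polyalanine), processed in prescore order with early exit on the first
  *good* trajectory unless `try_all` is set.

## Worked example

Everything below runs in a few seconds with no crystallographic software —
the simulated engine maps model quality (identity × coverage ×
exp(−RMSD-to-truth)) to placement success and refinement endpoints:

```python
import mrpilot as mp

prob = mp.make_synthetic_problem(7, n_residues=60,
                                 homologues=[(0.9, 0.2), (0.8, 0.4)],
                                 n_decoys=5)
res = mp.run_mrbump_flow(prob.target, prob.library, prob.engine(),
                         mp.RunConfig(try_all=True))
print(res.report())
```

```
A structure is suggested.
Its probability of being a solution is 99.0%.

Model index	sq1st1m3
...
R_initial/R_final	0.4985/0.2270
Rfree_initial/Rfree_final	0.5028/0.2552
Q factor	0.862

Processed search models (ranked by final Rfree):
rank	model_index	class	Rfree_final
1	sq1st1m3	good	0.2552
2	sq1st1m2	good	0.2616
3	sq1st1m1	good	0.2998
...
17	sq1st4m1	poor	0.5532
```

The best solution is the multiple-alignment-informed mixed model
(`m3`) of the strongest homologue: its refinement fell from ~0.50 to 0.255
R<sub>free</sub> (class *good*), giving Q = 0.862 — in the
definitely-correct band — while the five unrelated decoys stay flat near
0.55 and classify *poor*. The same machinery is available from a shell:

```sh
mrpilot library build templates/ -o index.json
mrpilot run --flow mrbump --target target.yaml --library index.json \
        --jobid 42 --try-all
```

which writes models, logs and the report under `search_42/` (one
subdirectory per template and model type under `search_42/data/`).

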