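"""End-to-end flows over an engine: the database-driven staged flow
(assemblies, then per-sequence models, then combination of the per-sequence
bests) and the exhaustive ranked-template flow with early exit, plus local
batching.

Both flows are pure functions of (target, library, engine, config); writing
models and reports into a job tree is optional.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence as TSequence

from .core import ChainEntry, Sequence
from .engine_sim import DEFAULT_N_CYCLES, Engine
from .formats_io import JobTree, TargetData, write_model, write_report
from .model_prep import (
    SearchModel,
    apply_assembly,
    as_search_model,
    build_ensemble,
    extract_domain,
    make_mixed_model,
    make_polyalanine,
    msa_informed_alignments,
)
from .model_search import (
    SearchConfig,
    TemplateHit,
    make_aligner,
    rank_templates,
    search_hierarchy,
)
from .solution_scoring import (
    RefinementTrace,
    ScoringConfig,
    SolutionScore,
    rank_solutions,
    score_solution,
)
from .template_library import AssemblyRecord, DomainEntry, LibraryIndex

__all__ = ["RunConfig", "Solution", "RunResult", "run_balbes_flow", "run_mrbump_flow",
           "batch_runner", "run"]

log = logging.getLogger("mrpilot")

#: The model types prepared per template in the exhaustive flow.
DEFAULT_MODEL_TYPES = ("unmodified", "mixed", "mixed_msa", "polyalanine")


@dataclass
class RunConfig:
    flow: str = "mrbump"
    try_all: bool = False
    n_refine_cycles: int = DEFAULT_N_CYCLES
    search: SearchConfig = field(default_factory=SearchConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    model_types: tuple[str, ...] = DEFAULT_MODEL_TYPES
    use_ensemble: bool = True
    job_id: str = "1"
    parallel_workers: int = 1
    space_groups: tuple[str, ...] = ()  # passthrough for engines that screen

    def __post_init__(self) -> None:
        if self.n_refine_cycles < 1:
            raise ValueError("n_refine_cycles must be >= 1")
        if self.search.batch_size is not None and self.search.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class Solution:
    """One scored MR attempt: the model, its trajectory and its scores."""

    model_index: str
    model: SearchModel
    trace: RefinementTrace
    score: SolutionScore
    template_id: str = ""
    pre_mr_rank: int | None = None
    pdb_path: str | None = None
    mtz_path: str | None = None


@dataclass
class RunResult:
    solutions: list[Solution] = field(default_factory=list)
    best: Solution | None = None
    combined_index: str | None = None

    def report(self, prob_cap: float = 0.990) -> str:
        return write_report(self, prob_cap=prob_cap)


def _rank(solutions: list[Solution]) -> list[Solution]:
    # same total order as rank_solutions; applied to Solution objects so
    # merged lists with clashing indices (batched runs) stay intact
    out = sorted(solutions, key=lambda s: (s.trace.rfree_final, -s.score.q, s.model_index))
    for rank, sol in enumerate(out, start=1):
        sol.score = replace(sol.score, rank=rank)
    return out


def _finish(solutions: list[Solution], combined_index: str | None = None) -> RunResult:
    ranked = _rank(solutions)
    return RunResult(
        solutions=ranked,
        best=ranked[0] if ranked else None,
        combined_index=combined_index,
    )


def _process(
    engine: Engine,
    target: TargetData,
    model: SearchModel,
    config: RunConfig,
    fixed: TSequence[SearchModel] = (),
    job_tree: JobTree | None = None,
    template_id: str = "",
    pre_mr_rank: int | None = None,
) -> Solution:
    placement = engine.place_model(target, model, fixed)
    trace = engine.refine(placement, config.n_refine_cycles)
    score = score_solution(trace, config.scoring)
    pdb_path = None
    if job_tree is not None and template_id:
        d = job_tree.model_dir(template_id, model.model_type)
        pdb_path = str(d / f"{model.model_index or model.model_type}.pdb")
        try:
            write_model(model, pdb_path)
        except ValueError:
            pdb_path = None
    return Solution(
        model_index=model.model_index,
        model=model,
        trace=trace,
        score=score,
        template_id=template_id or model.source,
        pre_mr_rank=pre_mr_rank,
        pdb_path=pdb_path,
    )


def _hit_model(hit: TemplateHit, library: LibraryIndex, targets: TSequence[Sequence],
               aligner: Callable) -> SearchModel | None:
    """Concrete search model for one hierarchical hit."""
    t = hit.template
    if isinstance(t, AssemblyRecord):
        parent = library.chain_by_id(t.entry_id)
        if parent is None:
            return None
        model = apply_assembly(parent, t)
    elif isinstance(t, DomainEntry):
        parent = library.chain_by_id(t.parent)
        if parent is None:
            return None
        model = extract_domain(parent, t)
    else:
        target = next((s for s in targets if s.id in hit.target_ids), targets[0])
        aln = hit.alignments.get(target.id)
        if aln is not None and len(aln.pairs) >= 3 and t.residues is not None:
            model = make_mixed_model(t, aln, target)
        else:
            model = as_search_model(t)
    model.model_index = hit.model_index
    model.alignment = next(iter(hit.alignments.values()), None)
    return model


def _combine(models: list[SearchModel]) -> SearchModel:
    """Concatenate placed models into one multi-chain solution (no loss)."""
    import string

    ids = string.ascii_uppercase + string.ascii_lowercase + string.digits
    chains = {}
    k = 0
    for m in models:
        for residues in m.chains.values():
            chains[ids[k % len(ids)]] = [r.copy() for r in residues]
            k += 1
    return SearchModel(
        model_type="combined",
        chains=chains,
        source="+".join(m.source for m in models),
    )


def run_balbes_flow(
    target: TargetData,
    library: LibraryIndex,
    engine: Engine,
    config: RunConfig | None = None,
    job_tree: JobTree | None = None,
) -> RunResult:
    """Staged flow: assemblies, per-sequence models (ensembles first),
    combination of per-sequence bests.

    Advances a stage while the best-so-far Q stays at or below the definite
    threshold; the combination stage fixes the best solution of the
    strongest sequence and searches with the others' bests in turn, naming
    the result by concatenating the constituent indices.
    """
    config = config or RunConfig(flow="balbes")
    aligner = make_aligner()
    targets = target.sequences
    hits = search_hierarchy(targets, library, config.search, aligner)
    solutions: list[Solution] = []
    if not hits:
        log.info("no template hits; returning empty result")
        return _finish(solutions)
    q_def = config.scoring.q_definite

    # stage 1: assemblies (all-sequence subsets first, as emitted)
    for hit in (h for h in hits if h.group.startswith("assembly")):
        model = _hit_model(hit, library, targets, aligner)
        if model is None:
            continue
        solutions.append(
            _process(engine, target, model, config, job_tree=job_tree,
                     template_id=hit.template_id)
        )
        if not config.try_all and solutions[-1].score.q > q_def:
            return _finish(solutions)
    best_stage1 = max((s.score.q for s in solutions), default=0.0)
    if best_stage1 > q_def:
        return _finish(solutions)

    # stage 2: per-sequence models, ensembles before single chains
    best_per_seq: dict[str, Solution] = {}
    for si, t in enumerate(targets, start=1):
        seq_hits = [h for h in hits if h.group.startswith("sequence:" + t.id + ":")]
        seq_solutions: list[Solution] = []
        ens_members = [
            h.template for h in seq_hits
            if isinstance(h.template, ChainEntry) and h.ensemble_eligible
        ]
        if config.use_ensemble and len(ens_members) >= 2:
            try:
                ens = build_ensemble(
                    [as_search_model(c) for c in ens_members[:4]], aligner
                )
                ens.model_index = f"sq{si}ens1"
                seq_solutions.append(
                    _process(engine, target, ens, config, job_tree=job_tree,
                             template_id=ens.source)
                )
            except ValueError:
                pass
        stop = (
            seq_solutions
            and not config.try_all
            and seq_solutions[-1].score.q > q_def
        )
        if not stop:
            for hit in seq_hits:
                model = _hit_model(hit, library, targets, aligner)
                if model is None:
                    continue
                seq_solutions.append(
                    _process(engine, target, model, config, job_tree=job_tree,
                             template_id=hit.template_id)
                )
                if not config.try_all and seq_solutions[-1].score.q > q_def:
                    break
        solutions.extend(seq_solutions)
        if seq_solutions:
            best_per_seq[t.id] = max(seq_solutions, key=lambda s: s.score.q)

    # stage 3: combination of per-sequence bests (strongest Q first)
    combined_index = None
    if len(best_per_seq) >= 2:
        order = sorted(best_per_seq.values(), key=lambda s: -s.score.q)
        fixed_models = [order[0].model]
        indices = [order[0].model_index]
        last: Solution | None = None
        for sol in order[1:]:
            placement_sol = _process(
                engine, target, sol.model, config, fixed=tuple(fixed_models)
            )
            fixed_models.append(sol.model)
            indices.append(sol.model_index)
            last = placement_sol
        combined_index = "_".join(indices)
        combined_model = _combine(fixed_models)
        combined_model.model_index = combined_index
        trace = last.trace if last is not None else order[0].trace
        combined = Solution(
            model_index=combined_index,
            model=combined_model,
            trace=trace,
            score=score_solution(trace, config.scoring),
            template_id=combined_model.source,
        )
        solutions.append(combined)
    return _finish(solutions, combined_index)


def _prepare_types(
    hit: TemplateHit,
    target: Sequence,
    library: LibraryIndex,
    aligner: Callable,
    model_types: TSequence[str],
    msa_templates: list[ChainEntry],
) -> list[SearchModel]:
    chain = hit.template
    if not isinstance(chain, ChainEntry):
        model = _hit_model(hit, library, [target], aligner)
        return [model] if model is not None else []
    aln = hit.alignments[target.id]
    models = []
    for mtype in model_types:
        try:
            if mtype == "unmodified":
                models.append(as_search_model(chain).copy())
            elif mtype == "mixed":
                models.append(make_mixed_model(chain, aln, target))
            elif mtype == "mixed_msa":
                msa = msa_informed_alignments(target, msa_templates, aligner)
                models.append(
                    make_mixed_model(chain, msa[chain.entry_id], target, model_type="mixed_msa")
                )
            elif mtype == "polyalanine":
                models.append(make_polyalanine(chain))
        except (ValueError, KeyError):
            continue
    return models


def run_mrbump_flow(
    target: TargetData,
    library: LibraryIndex,
    engine: Engine,
    config: RunConfig | None = None,
    job_tree: JobTree | None = None,
) -> RunResult:
    """Exhaustive flow: prescore-ranked templates, several prepared model
    types each, early exit on the first 'good' trajectory unless try_all.

    The pre-MR rank of each template is recorded on its solutions so the
    displacement between sequence-based and refinement-based ranking can be
    reported.
    """
    config = config or RunConfig(flow="mrbump")
    aligner = make_aligner()
    seq = target.sequences[0]
    hits = rank_templates(seq, library, config.search, aligner)
    solutions: list[Solution] = []
    if not hits:
        log.info("no template hits; returning empty result")
        return _finish(solutions)

    msa_templates = [h.template for h in hits if isinstance(h.template, ChainEntry)]

    stop = False
    if config.use_ensemble and len(msa_templates) >= 2:
        try:
            ens = build_ensemble([as_search_model(c) for c in msa_templates[:4]], aligner)
            ens.model_index = "ens1"
            solutions.append(
                _process(engine, target, ens, config, job_tree=job_tree,
                         template_id=ens.source, pre_mr_rank=0)
            )
            stop = (
                not config.try_all
                and solutions[-1].score.mrbump_class == "good"
            )
        except ValueError:
            pass

    if not stop:
        for rank, hit in enumerate(hits, start=1):
            models = _prepare_types(hit, seq, library, aligner, config.model_types,
                                    msa_templates)
            for j, model in enumerate(models, start=1):
                model.model_index = f"sq1st{rank}m{j}"
                model.pre_mr_rank = rank
                solutions.append(
                    _process(engine, target, model, config, job_tree=job_tree,
                             template_id=hit.template_id, pre_mr_rank=rank)
                )
                if not config.try_all and solutions[-1].score.mrbump_class == "good":
                    stop = True
                    break
            if stop:
                break
    result = _finish(solutions)
    if job_tree is not None:
        (job_tree.results_dir / "report.txt").write_text(
            result.report(config.scoring.report_prob_cap)
        )
        if result.best is not None:
            best_path = job_tree.results_dir / "best_solution.pdb"
            try:
                write_model(result.best.model, best_path)
                result.best.pdb_path = str(best_path)
            except ValueError:
                pass
    return result


def run(
    target: TargetData,
    library: LibraryIndex,
    engine: Engine,
    config: RunConfig,
    job_tree: JobTree | None = None,
) -> RunResult:
    if config.flow == "balbes":
        return run_balbes_flow(target, library, engine, config, job_tree)
    if config.flow == "mrbump":
        return run_mrbump_flow(target, library, engine, config, job_tree)
    raise ValueError(f"unknown flow {config.flow!r}")


def batch_runner(
    entry_ids: list[str],
    batch_size: int,
    runner: Callable[[list[str]], RunResult],
    workers: int = 1,
) -> RunResult:
    """Split entry ids into consecutive batches, run each, merge rankings.

    Equivalent to one unbatched run up to ranking ties; batches may run on a
    local worker pool.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    batches = [entry_ids[i : i + batch_size] for i in range(0, len(entry_ids), batch_size)]
    if workers > 1 and len(batches) > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(runner, batches))
    else:
        results = [runner(b) for b in batches]
    merged: list[Solution] = []
    combined = None
    for res in results:
        merged.extend(res.solutions)
        combined = combined or res.combined_index
    return _finish(merged, combined)
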