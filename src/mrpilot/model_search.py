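"""Homologue search and pre-MR ranking.

Pairwise alignment (affine-gap, BLOSUM62 by default) provides identity and
coverage; the pre-MR ranking score is their product. ``search_hierarchy``
groups candidate templates the way an automated MR pipeline presents them:
assembly hits over sequence subsets first, then up to five source structures
per sequence (each contributing multimer, monomer and domain models), then
cross-structure domain hits. ``estimate_copy_number`` is a Matthews-style
copies-per-asymmetric-unit estimate.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable

import gemmi
from Bio import Align
from Bio.Align import substitution_matrices

from .core import ChainEntry, Sequence, sequence_weight
from .formats_io import TargetData
from .template_library import AssemblyRecord, DomainEntry, LibraryIndex

__all__ = [
    "AlignmentResult",
    "AlignParams",
    "TemplateHit",
    "SearchConfig",
    "align_pair",
    "make_aligner",
    "prescore",
    "search_hierarchy",
    "rank_templates",
    "estimate_copy_number",
]

log = logging.getLogger("mrpilot")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment reduced to its residue-pair map.

    ``pairs`` holds (target_pos, template_pos) 0-based index pairs, strictly
    increasing in both coordinates. ``identity`` is identical pairs over
    aligned (non-gap) columns; ``coverage`` is the aligned fraction of the
    target.
    """

    pairs: tuple[tuple[int, int], ...]
    identity: float
    coverage: float
    score: float

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1 or not 0 <= self.coverage <= 1:
            raise ValueError("identity and coverage must lie in [0, 1]")


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0
    mode: str = "global"


def _build_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.mode = params.mode
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(a: Sequence, b: Sequence, params: AlignParams | None = None) -> AlignmentResult:
    """Optimal pairwise alignment of target ``a`` against template ``b``.

    Affine gap scoring: a gap of length L costs open + (L-1)*extend. The
    first optimal alignment is taken, which makes the pair map deterministic.
    """
    params = params or AlignParams()
    aligner = _build_aligner(params)
    alignment = aligner.align(a.residues, b.residues)[0]
    pairs: list[tuple[int, int]] = []
    n_ident = 0
    for (sa, ea), (sb, eb) in zip(*alignment.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            pairs.append((i, j))
            if a.residues[i] == b.residues[j]:
                n_ident += 1
    identity = n_ident / len(pairs) if pairs else 0.0
    coverage = len(pairs) / len(a)
    return AlignmentResult(
        pairs=tuple(pairs), identity=identity, coverage=coverage, score=float(alignment.score)
    )


def make_aligner(params: AlignParams | None = None) -> Callable[[Sequence, Sequence], AlignmentResult]:
    """A reusable aligner callable with results cached per sequence pair."""
    params = params or AlignParams()
    cache: dict[tuple[str, str], AlignmentResult] = {}

    def aligner(a: Sequence, b: Sequence) -> AlignmentResult:
        key = (a.residues, b.residues)
        if key not in cache:
            cache[key] = align_pair(a, b, params)
        return cache[key]

    return aligner


def prescore(hit_alignment: AlignmentResult) -> float:
    """Pre-MR ranking score: identity x coverage (alignment completeness)."""
    return hit_alignment.identity * hit_alignment.coverage


@dataclass
class SearchConfig:
    max_structures_per_sequence: int = 5
    max_whole_chain_models: int = 15
    identity_floor: float = 0.20
    domain_identity_floor: float = 0.10
    include_list: list[str] | None = None
    batch_size: int | None = None
    user_models: list[str] | None = None

    def __post_init__(self) -> None:
        if self.max_structures_per_sequence < 1 or self.max_whole_chain_models < 1:
            raise ValueError("model-count limits must be >= 1")


@dataclass
class TemplateHit:
    """One candidate search model with its hierarchical index (as1m1, sq2st1m3...)."""

    template: ChainEntry | DomainEntry | AssemblyRecord
    alignments: dict[str, AlignmentResult]
    prescore: float
    group: str
    model_index: str
    target_ids: tuple[str, ...]
    ensemble_eligible: bool = False
    is_domain: bool = False
    multimer_size: int = 1
    n_residues: int = 0

    @property
    def template_id(self) -> str:
        t = self.template
        if isinstance(t, AssemblyRecord):
            return t.entry_id
        if isinstance(t, DomainEntry):
            return f"{t.parent}_{t.domain_index}"
        return t.entry_id


def _domain_sequence(library: LibraryIndex, domain: DomainEntry) -> Sequence | None:
    parent = library.chain_by_id(domain.parent)
    if parent is None:
        return None
    seqids = parent.seqids
    keep = [
        i for i, sid in enumerate(seqids)
        if any(lo <= sid <= hi for lo, hi in domain.residue_ranges)
    ]
    if not keep:
        return None
    residues = "".join(parent.sequence.residues[i] for i in keep)
    return Sequence(id=f"{domain.parent}_{domain.domain_index}", residues=residues)


def search_hierarchy(
    targets: list[Sequence],
    library: LibraryIndex,
    config: SearchConfig | None = None,
    aligner: Callable[[Sequence, Sequence], AlignmentResult] | None = None,
) -> list[TemplateHit]:
    """Enumerate and index candidate models for the target sequence set.

    Emission order: (1) assembly hits for the full sequence set and every
    subset of >= 2 sequences, larger subsets first; (2) per-sequence groups,
    at most ``max_structures_per_sequence`` source structures each, every
    structure contributing its multimers, monomer chain and domains;
    (3) cross-structure domain hits from structures outside the per-sequence
    selection. Returns an empty list (with a log notice) when nothing clears
    the identity floor.
    """
    config = config or SearchConfig()
    aligner = aligner or make_aligner()
    hits: list[TemplateHit] = []

    chains = library.chains
    if config.include_list:
        allowed = set(config.include_list)
        chains = [c for c in chains if c.entry_id in allowed or c.structure_id in allowed]

    # target x chain alignments
    aln: dict[tuple[str, str], AlignmentResult] = {}
    for t in targets:
        for c in chains:
            aln[(t.id, c.entry_id)] = aligner(t, c.sequence)

    # --- stage 1: assemblies over sequence subsets (larger subsets first)
    as_group = 0
    k = len(targets)
    for size in range(k, 1, -1):
        for subset in itertools.combinations(range(k), size):
            sub = [targets[i] for i in subset]
            matched: list[tuple[float, AssemblyRecord]] = []
            for rec in library.assemblies:
                parent = library.chain_by_id(rec.entry_id)
                if parent is None or parent not in chains:
                    continue
                results = [aln[(t.id, rec.entry_id)] for t in sub]
                if all(r.identity >= config.identity_floor for r in results):
                    matched.append((sum(map(prescore, results)) / len(results), rec))
            if not matched:
                continue
            as_group += 1
            matched.sort(key=lambda x: (-x[0], x[1].entry_id))
            for m, (score, rec) in enumerate(matched, start=1):
                parent = library.chain_by_id(rec.entry_id)
                hits.append(
                    TemplateHit(
                        template=rec,
                        alignments={t.id: aln[(t.id, rec.entry_id)] for t in sub},
                        prescore=score,
                        group=f"assembly:as{as_group}",
                        model_index=f"as{as_group}m{m}",
                        target_ids=tuple(t.id for t in sub),
                        multimer_size=rec.multimer_size,
                        n_residues=parent.length * rec.multimer_size,
                    )
                )

    # --- stage 2: per-sequence structure groups
    domains_by_parent: dict[str, list[DomainEntry]] = {}
    for d in library.domains:
        domains_by_parent.setdefault(d.parent, []).append(d)
    assemblies_by_parent: dict[str, list[AssemblyRecord]] = {}
    for rec in library.assemblies:
        assemblies_by_parent.setdefault(rec.entry_id, []).append(rec)

    selected_structures: dict[str, list[str]] = {}
    for si, t in enumerate(targets, start=1):
        by_structure: dict[str, list[ChainEntry]] = {}
        for c in chains:
            if aln[(t.id, c.entry_id)].identity >= config.identity_floor:
                by_structure.setdefault(c.structure_id, []).append(c)
        ranked = sorted(
            by_structure.items(),
            key=lambda kv: (-max(prescore(aln[(t.id, c.entry_id)]) for c in kv[1]), kv[0]),
        )
        ranked = ranked[: config.max_structures_per_sequence]
        selected_structures[t.id] = [sid for sid, _ in ranked]
        n_matching_chains = sum(len(v) for v in by_structure.values())
        whole_chain_budget = config.max_whole_chain_models
        for sj, (sid, schains) in enumerate(ranked, start=1):
            schains = sorted(
                schains, key=lambda c: (-prescore(aln[(t.id, c.entry_id)]), c.entry_id)
            )
            m = 0
            group = f"sequence:{t.id}:st{sj}"
            for c in schains:
                a = aln[(t.id, c.entry_id)]
                for rec in assemblies_by_parent.get(c.entry_id, []):
                    if whole_chain_budget <= 0:
                        break
                    m += 1
                    whole_chain_budget -= 1
                    hits.append(
                        TemplateHit(
                            template=rec,
                            alignments={t.id: a},
                            prescore=prescore(a),
                            group=group,
                            model_index=f"sq{si}st{sj}m{m}",
                            target_ids=(t.id,),
                            multimer_size=rec.multimer_size,
                            n_residues=c.length * rec.multimer_size,
                        )
                    )
                if whole_chain_budget > 0:
                    m += 1
                    whole_chain_budget -= 1
                    hits.append(
                        TemplateHit(
                            template=c,
                            alignments={t.id: a},
                            prescore=prescore(a),
                            group=group,
                            model_index=f"sq{si}st{sj}m{m}",
                            target_ids=(t.id,),
                            ensemble_eligible=n_matching_chains >= 2,
                            n_residues=c.length,
                        )
                    )
                for dom in sorted(
                    domains_by_parent.get(c.entry_id, []), key=lambda d: d.domain_index
                ):
                    dseq = _domain_sequence(library, dom)
                    if dseq is None:
                        continue
                    da = aligner(t, dseq)
                    if da.identity < config.domain_identity_floor:
                        continue
                    m += 1
                    hits.append(
                        TemplateHit(
                            template=dom,
                            alignments={t.id: da},
                            prescore=prescore(da),
                            group=group,
                            model_index=f"sq{si}st{sj}m{m}",
                            target_ids=(t.id,),
                            is_domain=True,
                            n_residues=len(dseq),
                        )
                    )

    # --- stage 3: cross-structure domain hits (structures not selected above)
    for si, t in enumerate(targets, start=1):
        chosen = set(selected_structures.get(t.id, []))
        found: list[tuple[float, DomainEntry, AlignmentResult]] = []
        for dom in library.domains:
            parent = library.chain_by_id(dom.parent)
            if parent is None or parent.structure_id in chosen:
                continue
            dseq = _domain_sequence(library, dom)
            if dseq is None:
                continue
            da = aligner(t, dseq)
            if da.identity >= config.domain_identity_floor:
                found.append((prescore(da), dom, da))
        found.sort(key=lambda x: (-x[0], x[1].parent, x[1].domain_index))
        for m, (score, dom, da) in enumerate(found, start=1):
            hits.append(
                TemplateHit(
                    template=dom,
                    alignments={t.id: da},
                    prescore=score,
                    group=f"domains:{t.id}",
                    model_index=f"sq{si}dm{m}",
                    target_ids=(t.id,),
                    is_domain=True,
                )
            )

    if not hits:
        log.info("no template hits above the identity floor (%.2f)", config.identity_floor)
    return hits


def rank_templates(
    target: Sequence,
    library: LibraryIndex,
    config: SearchConfig | None = None,
    aligner: Callable[[Sequence, Sequence], AlignmentResult] | None = None,
) -> list[TemplateHit]:
    """Flat prescore-ranked whole-chain template list for the exhaustive flow.

    Every library chain above the identity floor, ranked by identity x
    coverage, capped at ``max_whole_chain_models``.
    """
    config = config or SearchConfig()
    aligner = aligner or make_aligner()
    chains = library.chains
    if config.include_list:
        allowed = set(config.include_list)
        chains = [c for c in chains if c.entry_id in allowed or c.structure_id in allowed]
    scored = []
    for c in chains:
        a = aligner(target, c.sequence)
        if a.identity >= config.identity_floor:
            scored.append((prescore(a), c, a))
    scored.sort(key=lambda x: (-x[0], x[1].entry_id))
    scored = scored[: config.max_whole_chain_models]
    hits = []
    for rank, (score, c, a) in enumerate(scored, start=1):
        hits.append(
            TemplateHit(
                template=c,
                alignments={target.id: a},
                prescore=score,
                group="ranked",
                model_index=f"sq1st{rank}m1",
                target_ids=(target.id,),
                ensemble_eligible=len(scored) >= 2,
                n_residues=c.length,
            )
        )
    return hits


#: Protein volume per dalton (Å³/Da) at density 1.23 g/cm³; gives the
#: conventional Matthews coefficient of ~2.69 Å³/Da at 50% solvent.
PROTEIN_A3_PER_DA = 1.35


def estimate_copy_number(
    target: TargetData,
    model_weight: float,
    solvent_bounds: tuple[float, float] = (0.25, 0.75),
    max_copies: int = 60,
) -> int:
    """Expected copies of a model per asymmetric unit (Matthews-style).

    Enumerates copy counts, computes the implied solvent fraction
    ``1 - 1.35 * n_sym * n * MW / V_cell`` and returns the count whose
    solvent fraction is closest to 50%, restricted to the feasible band.
    Returns 0 with a warning when no count is feasible.
    """
    if model_weight <= 0:
        raise ValueError("model weight must be positive")
    sg = gemmi.find_spacegroup_by_name(target.space_group)
    if sg is None:
        raise ValueError(f"unknown space group {target.space_group!r}")
    n_sym = len(list(sg.operations()))
    volume = gemmi.UnitCell(*target.cell).volume
    lo, hi = solvent_bounds
    best_n, best_dev = 0, None
    for n in range(1, max_copies + 1):
        solvent = 1.0 - PROTEIN_A3_PER_DA * n_sym * n * model_weight / volume
        if solvent < lo:
            break
        if solvent > hi:
            continue
        dev = abs(solvent - 0.5)
        if best_dev is None or dev < best_dev:
            best_n, best_dev = n, dev
    if best_n == 0:
        warnings.warn(
            f"no feasible copy count for MW {model_weight:.0f} Da in cell volume "
            f"{volume:.0f} Å³ ({target.space_group})"
        )
    return best_n


def model_weight_of(sequence: Sequence, copies: int = 1) -> float:
    return sequence_weight(sequence.residues) * copies
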