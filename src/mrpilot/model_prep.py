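"""Turning template hits into concrete MR search models.

Mixed models keep the side-chain atoms a template residue shares with the
aligned target residue type (never less than backbone + Cβ, never more than
the template has); polyalanine models are backbone + Cβ throughout; domain
models are range extractions; ensembles are common-core superpositions;
multimers are operator expansions. Superposition is least-squares (Kabsch,
via Biopython's SVD superimposer).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Sequence as TSequence

import numpy as np
from Bio.SVDSuperimposer import SVDSuperimposer

from .core import AA1_TO_3, Atom, ChainEntry, Residue, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .model_search import AlignmentResult
    from .template_library import AssemblyRecord, DomainEntry

__all__ = [
    "SearchModel",
    "Superposition",
    "make_mixed_model",
    "make_polyalanine",
    "extract_domain",
    "superpose",
    "build_ensemble",
    "apply_assembly",
    "shared_atoms",
    "msa_informed_alignments",
]

BACKBONE = ("N", "CA", "C", "O")

#: Side-chain heavy-atom topology: atom -> parent atom, per residue type.
#: Shared atoms between two residue types are those whose full ancestor
#: path exists in both types (so e.g. ILE CD1 is not "shared" with LEU CD1,
#: whose parent differs).
SIDECHAIN_PARENT: dict[str, dict[str, str]] = {
    "ALA": {"CB": "CA"},
    "ARG": {"CB": "CA", "CG": "CB", "CD": "CG", "NE": "CD", "CZ": "NE", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"CB": "CA", "CG": "CB", "OD1": "CG", "ND2": "CG"},
    "ASP": {"CB": "CA", "CG": "CB", "OD1": "CG", "OD2": "CG"},
    "CYS": {"CB": "CA", "SG": "CB"},
    "GLN": {"CB": "CA", "CG": "CB", "CD": "CG", "OE1": "CD", "NE2": "CD"},
    "GLU": {"CB": "CA", "CG": "CB", "CD": "CG", "OE1": "CD", "OE2": "CD"},
    "GLY": {},
    "HIS": {"CB": "CA", "CG": "CB", "ND1": "CG", "CD2": "CG", "CE1": "ND1", "NE2": "CD2"},
    "ILE": {"CB": "CA", "CG1": "CB", "CG2": "CB", "CD1": "CG1"},
    "LEU": {"CB": "CA", "CG": "CB", "CD1": "CG", "CD2": "CG"},
    "LYS": {"CB": "CA", "CG": "CB", "CD": "CG", "CE": "CD", "NZ": "CE"},
    "MET": {"CB": "CA", "CG": "CB", "SD": "CG", "CE": "SD"},
    "PHE": {"CB": "CA", "CG": "CB", "CD1": "CG", "CD2": "CG", "CE1": "CD1", "CE2": "CD2", "CZ": "CE1"},
    "PRO": {"CB": "CA", "CG": "CB", "CD": "CG"},
    "SER": {"CB": "CA", "OG": "CB"},
    "THR": {"CB": "CA", "OG1": "CB", "CG2": "CB"},
    "TRP": {
        "CB": "CA", "CG": "CB", "CD1": "CG", "CD2": "CG", "NE1": "CD1",
        "CE2": "CD2", "CE3": "CD2", "CZ2": "CE2", "CZ3": "CE3", "CH2": "CZ2",
    },
    "TYR": {
        "CB": "CA", "CG": "CB", "CD1": "CG", "CD2": "CG", "CE1": "CD1",
        "CE2": "CD2", "CZ": "CE1", "OH": "CZ",
    },
    "VAL": {"CB": "CA", "CG1": "CB", "CG2": "CB"},
    "UNK": {"CB": "CA"},
}


def _ancestor_path(res_type: str, atom: str) -> tuple[str, ...] | None:
    """Atom's parent chain back to CA, or None if the type lacks the atom."""
    topo = SIDECHAIN_PARENT.get(res_type)
    if topo is None or (atom not in topo and atom not in BACKBONE):
        return None
    if atom in BACKBONE:
        return (atom,)
    path = [atom]
    while path[-1] in topo:
        path.append(topo[path[-1]])
    return tuple(path)


def shared_atoms(template_type: str, target_type: str) -> set[str]:
    """Atom names a template residue may keep when relabelled to the target type.

    Backbone is always shared; a side-chain atom is shared when both residue
    types contain it with the identical bonded path back to CA.
    """
    shared = set(BACKBONE)
    for atom in SIDECHAIN_PARENT.get(template_type, {}):
        pa = _ancestor_path(template_type, atom)
        pb = _ancestor_path(target_type, atom)
        if pa is not None and pa == pb:
            shared.add(atom)
    return shared


@dataclass
class Superposition:
    """A rigid transform ``y = R x + t`` with its post-fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray,
    fixed: np.ndarray,
    pairs: TSequence[tuple[int, int]] | None = None,
) -> Superposition:
    """Optimal least-squares rigid superposition of mobile onto fixed.

    ``pairs`` maps (mobile_index, fixed_index); identity pairing when None.
    Requires >= 3 non-collinear pairs.
    """
    mobile = np.asarray(mobile, float).reshape(-1, 3)
    fixed = np.asarray(fixed, float).reshape(-1, 3)
    if pairs is not None:
        mi = [i for i, _ in pairs]
        fi = [j for _, j in pairs]
        mobile, fixed = mobile[mi], fixed[fi]
    if len(mobile) != len(fixed):
        raise ValueError("coordinate sets differ in length")
    n = len(mobile)
    if n < 3:
        raise ValueError("superposition needs at least 3 pairs")
    for arr in (mobile, fixed):
        centered = arr - arr.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise ValueError("degenerate (collinear) coordinates")
    sup = SVDSuperimposer()
    sup.set(fixed, mobile)
    sup.run()
    rot, tran = sup.get_rotran()  # row convention: mobile @ rot + tran
    return Superposition(
        rotation=np.ascontiguousarray(rot.T),
        translation=tran.copy(),
        rmsd=float(sup.get_rms()),
        n_pairs=n,
    )


@dataclass
class SearchModel:
    """An edited coordinate set ready for MR.

    ``chains`` maps chain id to residue records; ensembles additionally
    carry ``members`` (each a single-conformer SearchModel) and ``core``,
    the first member's seqids of the common superposition core.
    """

    model_type: str
    chains: dict[str, list[Residue]]
    source: str = ""
    alignment: "AlignmentResult | None" = None
    model_index: str = ""
    members: "list[SearchModel] | None" = None
    core: list[int] | None = None
    pre_mr_rank: int | None = None

    @property
    def residues(self) -> list[Residue]:
        return [r for residues in self.chains.values() for r in residues]

    @property
    def residue_count(self) -> int:
        return len(self.residues)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        cas = [r.ca.pos for r in self.residues if r.ca is not None]
        return np.array(cas).reshape(-1, 3)

    def sequence(self, id: str | None = None) -> Sequence:
        return Sequence(
            id=id or self.source or "model",
            residues="".join(r.one_letter for r in self.residues),
        )

    def copy(self) -> "SearchModel":
        return SearchModel(
            model_type=self.model_type,
            chains={cid: [r.copy() for r in res] for cid, res in self.chains.items()},
            source=self.source,
            alignment=self.alignment,
            model_index=self.model_index,
            members=[m.copy() for m in self.members] if self.members else None,
            core=list(self.core) if self.core else None,
            pre_mr_rank=self.pre_mr_rank,
        )


def as_search_model(template: ChainEntry | SearchModel, model_type: str = "unmodified") -> SearchModel:
    """Wrap a template chain as an (unmodified) search model."""
    if isinstance(template, SearchModel):
        return template
    if template.residues is None:
        raise ValueError(f"{template.entry_id}: no atom records available")
    return SearchModel(
        model_type=model_type,
        chains={template.chain_id: [r.copy() for r in template.residues]},
        source=template.entry_id,
    )


def make_mixed_model(
    template: ChainEntry,
    alignment: "AlignmentResult",
    target: Sequence,
    model_type: str = "mixed",
) -> SearchModel:
    """Prune nonconserved side chains of a template along a target alignment.

    Identical aligned residues keep all atoms; substituted residues keep the
    atoms shared with the target residue type and are relabelled to it;
    unaligned template residues are deleted. Output atoms are always a
    subset of the template's.
    """
    if template.residues is None:
        raise ValueError(f"{template.entry_id}: no atom records available")
    if len(alignment.pairs) < 3:
        raise ValueError("model too sparse: alignment covers fewer than 3 residues")
    out: list[Residue] = []
    for t_pos, p_pos in alignment.pairs:
        src = template.residues[p_pos]
        target_letter = target.residues[t_pos]
        target_type = AA1_TO_3.get(target_letter, "UNK")
        if src.name == target_type:
            out.append(src.copy())
            continue
        keep = shared_atoms(src.name, target_type)
        atoms = {
            name: Atom(a.name, a.pos.copy(), a.element)
            for name, a in src.atoms.items()
            if name in keep
        }
        out.append(Residue(target_type, src.seqid, atoms))
    return SearchModel(
        model_type=model_type,
        chains={template.chain_id: out},
        source=template.entry_id,
        alignment=alignment,
    )


def make_polyalanine(template: ChainEntry | SearchModel) -> SearchModel:
    """Reduce every residue to backbone + Cβ and relabel it ALA (GLY keeps no Cβ)."""
    model = as_search_model(template)
    chains: dict[str, list[Residue]] = {}
    for cid, residues in model.chains.items():
        out = []
        for r in residues:
            keep = set(BACKBONE) | ({"CB"} if r.name != "GLY" else set())
            atoms = {
                n: Atom(a.name, a.pos.copy(), a.element)
                for n, a in r.atoms.items()
                if n in keep
            }
            out.append(Residue("ALA" if r.name != "GLY" else "GLY", r.seqid, atoms))
        chains[cid] = out
    return SearchModel(
        model_type="polyalanine",
        chains=chains,
        source=model.source,
        alignment=model.alignment,
    )


def extract_domain(template: ChainEntry, domain: "DomainEntry") -> SearchModel:
    """The residues of a domain's seqid ranges, source numbering preserved."""
    if template.residues is None:
        raise ValueError(f"{template.entry_id}: no atom records available")
    out = [
        r.copy()
        for r in template.residues
        if any(lo <= r.seqid <= hi for lo, hi in domain.residue_ranges)
    ]
    if not out:
        raise ValueError(
            f"domain ranges {domain.residue_ranges} select no residues of {template.entry_id}"
        )
    return SearchModel(
        model_type="domain",
        chains={template.chain_id: out},
        source=f"{template.entry_id}_{domain.domain_index}",
    )


def _member_sort_key(model: SearchModel) -> tuple:
    score = 0.0
    if model.alignment is not None:
        score = model.alignment.identity * model.alignment.coverage
    return (-score, model.source, model.model_index)


def build_ensemble(
    models: list[SearchModel | ChainEntry],
    aligner: Callable[[Sequence, Sequence], "AlignmentResult"] | None = None,
    trim_to_core: bool = True,
) -> SearchModel:
    """Superpose >= 2 models over their common aligned core.

    Member order is normalized (prescore descending, then source id), the
    first member is the reference frame, and by default members are trimmed
    to the common core so all have identical residue counts.
    """
    members = sorted((as_search_model(m).copy() for m in models), key=_member_sort_key)
    if len(members) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    if aligner is None:
        from .model_search import make_aligner

        aligner = make_aligner()
    ref = members[0]
    ref_res = ref.residues
    ref_seq = ref.sequence("ref")
    # positions of the reference present in every member, via pairwise maps
    member_maps: list[dict[int, int]] = []
    core_ref = set(range(len(ref_res)))
    for m in members[1:]:
        aln = aligner(ref_seq, m.sequence("member"))
        amap = dict(aln.pairs)
        member_maps.append(amap)
        core_ref &= set(amap)
    core = sorted(core_ref)
    if len(core) < 3:
        raise ValueError("no common core across ensemble members")

    ref_ca = np.array([ref_res[i].ca.pos for i in core])
    keep_sets: list[set[int]] = [set(core)]
    for m, amap in zip(members[1:], member_maps):
        res = m.residues
        mob_idx = [amap[i] for i in core]
        mob_ca = np.array([res[i].ca.pos for i in mob_idx])
        sup = superpose(mob_ca, ref_ca)
        for r in m.residues:
            for a in r.atoms.values():
                a.pos = sup.rotation @ a.pos + sup.translation
        keep_sets.append(set(mob_idx))

    if trim_to_core:
        for m, keep in zip(members, keep_sets):
            for cid in list(m.chains):
                flat = m.residues
                m.chains = {cid: [flat[i] for i in sorted(keep)]}
    return SearchModel(
        model_type="ensemble",
        chains=members[0].chains,
        source="+".join(m.source for m in members),
        members=members,
        core=[ref_res[i].seqid for i in core],
    )


_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def apply_assembly(monomer: SearchModel | ChainEntry, record: "AssemblyRecord") -> SearchModel:
    """Expand a monomer into a multimer: one transformed copy per operator."""
    model = as_search_model(monomer)
    if not record.operators:
        raise ValueError(f"{record.entry_id}: assembly has no operators")
    base = model.residues
    chains: dict[str, list[Residue]] = {}
    for k, (rot, trans) in enumerate(record.operators):
        copy = []
        for r in base:
            rr = r.copy()
            for a in rr.atoms.values():
                a.pos = rot @ a.pos + trans
            copy.append(rr)
        chains[_CHAIN_IDS[k % len(_CHAIN_IDS)]] = copy
    return SearchModel(
        model_type="multimer",
        chains=chains,
        source=model.source,
        alignment=model.alignment,
    )


def msa_informed_alignments(
    target: Sequence,
    templates: list[ChainEntry],
    aligner: Callable[[Sequence, Sequence], "AlignmentResult"] | None = None,
    min_consensus: float = 0.5,
) -> "dict[str, AlignmentResult]":
    """Target-template pair maps derived from a target-centred star alignment.

    Each template is aligned to the target; target columns covered by fewer
    than ``min_consensus`` of the templates are treated as low-consensus and
    dropped from every pair map. With a single template this reduces to the
    plain pairwise alignment.
    """
    from .model_search import AlignmentResult, make_aligner

    aligner = aligner or make_aligner()
    raw = {t.entry_id: aligner(target, t.sequence) for t in templates}
    if len(templates) > 1:
        coverage_count = np.zeros(len(target), dtype=int)
        for aln in raw.values():
            for i, _ in aln.pairs:
                coverage_count[i] += 1
        ok = {i for i in range(len(target)) if coverage_count[i] >= min_consensus * len(templates)}
    else:
        ok = set(range(len(target)))
    out = {}
    for tid, aln in raw.items():
        pairs = tuple(p for p in aln.pairs if p[0] in ok)
        # identity recomputed over the trimmed map
        tpl = next(t for t in templates if t.entry_id == tid)
        n_ident = sum(1 for i, j in pairs if target.residues[i] == tpl.sequence.residues[j])
        identity = n_ident / len(pairs) if pairs else 0.0
        out[tid] = AlignmentResult(
            pairs=pairs,
            identity=identity,
            coverage=len(pairs) / len(target),
            score=aln.score,
        )
    return out
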