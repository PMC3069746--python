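"""Readers and writers: FASTA sequences, PDB/mmCIF structures, target
descriptors, the job directory tree and the final text report.

Structure IO is delegated to gemmi; only the light in-memory containers of
:mod:`mrpilot.core` cross the module boundary. Reflection data are never
parsed here — a target descriptor carries an opaque path that external
engine adapters may forward.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import gemmi
import numpy as np
import yaml

from .core import AA3_TO_1, Atom, ChainEntry, Residue, Sequence

__all__ = [
    "Sequence",
    "TargetData",
    "JobTree",
    "read_fasta",
    "read_structure",
    "write_model",
    "make_job_tree",
    "write_report",
    "load_target",
]

log = logging.getLogger("mrpilot")

PDB_ATOM_LIMIT = 99999


@dataclass
class TargetData:
    """Crystal metadata for a target: sequences, cell, symmetry, resolution.

    ``cell`` is (a, b, c, alpha, beta, gamma) in Å / degrees;
    ``reflections_path`` is an opaque path handed to external engines only.
    """

    sequences: list[Sequence]
    cell: tuple[float, float, float, float, float, float]
    space_group: str
    resolution: float
    reflections_path: str | None = None

    def __post_init__(self) -> None:
        self.cell = tuple(float(x) for x in self.cell)
        if len(self.cell) != 6:
            raise ValueError("cell needs six numbers (a, b, c, alpha, beta, gamma)")
        if any(x <= 0 for x in self.cell[:3]):
            raise ValueError("cell lengths must be positive")
        if any(not 0 < x < 180 for x in self.cell[3:]):
            raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


def load_target(path: str | Path) -> TargetData:
    """Read a YAML/JSON target descriptor.

    Expected keys: ``sequences`` (list of ``{id, residues}`` mappings or
    plain strings), ``cell``, ``space_group``, ``resolution`` and optional
    ``reflections``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    seqs = []
    for i, item in enumerate(doc["sequences"], start=1):
        if isinstance(item, str):
            seqs.append(Sequence(id=f"seq{i}", residues=item))
        else:
            seqs.append(Sequence(id=str(item.get("id", f"seq{i}")), residues=item["residues"]))
    return TargetData(
        sequences=seqs,
        cell=tuple(doc["cell"]),
        space_group=str(doc["space_group"]),
        resolution=float(doc["resolution"]),
        reflections_path=doc.get("reflections"),
    )


def dump_target(target: TargetData, path: str | Path) -> None:
    doc = {
        "sequences": [{"id": s.id, "residues": s.residues} for s in target.sequences],
        "cell": list(target.cell),
        "space_group": target.space_group,
        "resolution": target.resolution,
    }
    if target.reflections_path:
        doc["reflections"] = target.reflections_path
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[Sequence]:
    """Parse a FASTA file into :class:`Sequence` records, in file order.

    Raises ``ValueError("no sequences")`` on an empty file and a line-numbered
    error on malformed input (text before the first header, empty record).
    """
    records: list[Sequence] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        residues = "".join(chunks).upper()
        if not residues:
            raise ValueError(f"malformed record at line {header_line}: empty sequence")
        records.append(Sequence(id=header, residues=residues))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].strip() else f"seq{len(records) + 1}"
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"malformed record at line {lineno}: data before header")
                chunks.append(line)
    flush()
    if not records:
        raise ValueError("no sequences")
    return records


def write_fasta(sequences: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Structures

def read_structure(path: str | Path, dialect: str | None = None) -> list[ChainEntry]:
    """Read a PDB or mmCIF file into one :class:`ChainEntry` per polymer chain.

    Keeps the first altloc, drops waters and heteroatoms, and takes the
    resolution from the header when present (absent otherwise). Chains
    without a single Cα are skipped with a warning.
    """
    path = Path(path)
    if dialect not in (None, "pdb", "mmcif"):
        raise ValueError(f"unknown dialect {dialect!r}")
    fmt = gemmi.CoorFormat.Detect
    if dialect == "pdb":
        fmt = gemmi.CoorFormat.Pdb
    elif dialect == "mmcif":
        fmt = gemmi.CoorFormat.Mmcif
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_ligands_and_waters()
    st.remove_empty_chains()
    resolution = st.resolution if st.resolution and st.resolution > 0 else None

    entries: list[ChainEntry] = []
    if not len(st):
        raise ValueError(f"cannot parse {path}: no models")
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        letters: list[str] = []
        cas: list[np.ndarray] = []
        for res in chain:
            atoms: dict[str, Atom] = {}
            for atom in res:
                if atom.name in atoms:  # first altloc kept
                    continue
                atoms[atom.name] = Atom(
                    atom.name, np.array([atom.pos.x, atom.pos.y, atom.pos.z]), atom.element.name
                )
            if "CA" not in atoms:
                continue
            residues.append(Residue(res.name, res.seqid.num, atoms))
            letters.append(AA3_TO_1.get(res.name, "X"))
            cas.append(atoms["CA"].pos)
        if not residues:
            warnings.warn(f"{path.name}: chain {chain.name} has no CA atoms; skipped")
            continue
        entry_id = f"{path.stem}_{chain.name}"
        entries.append(
            ChainEntry(
                entry_id=entry_id,
                sequence=Sequence(id=entry_id, residues="".join(letters)),
                ca_coords=np.array(cas),
                resolution=resolution,
                residues=residues,
                chain_id=chain.name,
            )
        )
    return entries


def _model_chains(model: Any) -> list[tuple[str, list[Residue]]]:
    """Normalize a SearchModel-like or ChainEntry-like object to chain lists."""
    if hasattr(model, "chains"):
        return list(model.chains.items())
    if hasattr(model, "residues") and model.residues is not None:
        return [(getattr(model, "chain_id", "A"), model.residues)]
    raise ValueError("model carries no atom records")


def write_model(model: Any, path: str | Path) -> None:
    """Write a search model (or ensemble) as a PDB file.

    Ensembles are written as multi-MODEL files, one MODEL per member; chain
    ids and source residue numbering are preserved. Fails above the PDB
    fixed-format limit of 99999 atoms.
    """
    members = getattr(model, "members", None) or [model]
    st = gemmi.Structure()
    st.name = getattr(model, "model_index", "") or "model"
    n_atoms = 0
    for num, member in enumerate(members, start=1):
        gmodel = gemmi.Model(num)
        chains = _model_chains(member)
        if not chains or all(not residues for _, residues in chains):
            raise ValueError("empty model")
        for chain_id, residues in chains:
            gchain = gemmi.Chain(chain_id)
            for res in residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.seqid, " ")
                for atom in res.atoms.values():
                    ga = gemmi.Atom()
                    ga.name = atom.name
                    ga.element = gemmi.Element(atom.element or atom.name[:1])
                    ga.pos = gemmi.Position(*atom.pos)
                    ga.occ = 1.0
                    ga.b_iso = 20.0
                    gres.add_atom(ga)
                    n_atoms += 1
                gchain.add_residue(gres)
            gmodel.add_chain(gchain)
        st.add_model(gmodel)
    if n_atoms == 0:
        raise ValueError("empty model")
    if n_atoms > PDB_ATOM_LIMIT:
        raise ValueError(f"{n_atoms} atoms exceed the PDB format limit of {PDB_ATOM_LIMIT}")
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Job tree

@dataclass
class JobTree:
    """The ``search_<JobID>/`` working tree of one pipeline run.

    Per-template subtrees under ``data/`` are created lazily, one directory
    per model type, as models are processed.
    """

    root: Path
    data_dir: Path = field(init=False)
    results_dir: Path = field(init=False)
    logs_dir: Path = field(init=False)

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        self.data_dir = self.root / "data"
        self.results_dir = self.root / "results"
        self.logs_dir = self.root / "logs"

    def model_dir(self, template_id: str, model_type: str) -> Path:
        d = self.data_dir / template_id / model_type
        d.mkdir(parents=True, exist_ok=True)
        return d


def make_job_tree(job_id: str | int, workdir: str | Path, overwrite: bool = False) -> JobTree:
    """Create ``search_<job_id>`` with data/, results/ and logs/ inside."""
    root = Path(workdir) / f"search_{job_id}"
    if root.exists():
        if not overwrite:
            raise FileExistsError(f"{root} already exists (pass overwrite=True)")
        import shutil

        shutil.rmtree(root)
    tree = JobTree(root)
    for d in (tree.data_dir, tree.results_dir, tree.logs_dir):
        d.mkdir(parents=True)
    return tree


# ---------------------------------------------------------------------------
# Report

def _fmt_pct(p: float, cap: float) -> str:
    return f"{min(p, cap) * 100:.1f}%"


def write_report(result: Any, prob_cap: float = 0.990) -> str:
    """Render the final text report for a run.

    ``result`` is a RunResult-like object: ``best`` (None or a solution with
    ``model_index``, ``trace``, ``score`` and optional ``pdb_path`` /
    ``mtz_path``) plus ``solutions``, the ranked list. The displayed
    probability is capped at ``prob_cap`` and shown to one decimal.
    """
    lines: list[str] = []
    best = getattr(result, "best", None)
    if best is None:
        lines.append("No solution was found.")
    else:
        trace = best.trace
        score = best.score
        lines.append("A structure is suggested.")
        lines.append(
            f"Its probability of being a solution is {_fmt_pct(score.p, prob_cap)}."
        )
        lines.append("")
        lines.append(f"Model index\t{best.model_index}")
        lines.append(f"PDB file\t{getattr(best, 'pdb_path', '-') or '-'}")
        lines.append(f"MTZ file\t{getattr(best, 'mtz_path', '-') or '-'}")
        lines.append(f"R_initial/R_final\t{trace.r_initial:.4f}/{trace.r_final:.4f}")
        lines.append(
            f"Rfree_initial/Rfree_final\t{trace.rfree_initial:.4f}/{trace.rfree_final:.4f}"
        )
        lines.append(f"Q factor\t{score.q:.3f}")
    solutions = list(getattr(result, "solutions", []))
    if solutions:
        lines.append("")
        lines.append("Processed search models (ranked by final Rfree):")
        lines.append("rank\tmodel_index\tclass\tRfree_final")
        for sol in solutions:
            lines.append(
                f"{sol.score.rank}\t{sol.model_index}\t{sol.score.mrbump_class}\t"
                f"{sol.trace.rfree_final:.4f}"
            )
    combined = getattr(result, "combined_index", None)
    if combined:
        lines.append("")
        lines.append(f"Combined solution index: {combined}")
    return "\n".join(lines) + "\n"
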