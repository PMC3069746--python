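"""Template-library curation: filtering, redundancy reduction, hierarchical
clustering, domain decomposition and the serializable library index.

The curation rules follow the conventions of MR-oriented template databases:
chains longer than 15 residues refined to 3.5 Å or better are kept; of two
chains with sequence identity above 80% and Cα RMSD below 1 Å, only the one
refined at higher resolution is retained — conformational variants (high
identity, RMSD >= 1 Å) are all kept so the library preserves conformational
variability.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform

from .core import Atom, ChainEntry, Residue, Sequence

__all__ = [
    "ChainEntry",
    "DomainEntry",
    "AssemblyRecord",
    "CurationConfig",
    "ChainTree",
    "LibraryIndex",
    "filter_entries",
    "redundancy_reduce",
    "cluster_chains",
    "decompose_domains",
    "build_index",
    "build_library",
]

log = logging.getLogger("mrpilot")


@dataclass
class DomainEntry:
    """A compact sub-structure of a parent chain, as inclusive seqid ranges."""

    parent: str
    domain_index: int
    residue_ranges: list[tuple[int, int]]
    ca_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        ranges = sorted((int(a), int(b)) for a, b in self.residue_ranges)
        for (a, b) in ranges:
            if a > b:
                raise ValueError(f"invalid range ({a}, {b}) in domain of {self.parent}")
        for (_, b1), (a2, _) in zip(ranges, ranges[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping ranges in domain of {self.parent}")
        self.residue_ranges = ranges
        if self.ca_coords is not None:
            self.ca_coords = np.asarray(self.ca_coords, dtype=float).reshape(-1, 3)


@dataclass
class AssemblyRecord:
    """Multimeric organization of a chain as rotation/translation operators."""

    entry_id: str
    operators: list[tuple[np.ndarray, np.ndarray]]
    multimer_size: int = 0

    def __post_init__(self) -> None:
        ops = []
        for rot, trans in self.operators:
            rot = np.asarray(rot, dtype=float).reshape(3, 3)
            trans = np.asarray(trans, dtype=float).reshape(3)
            if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-6):
                raise ValueError(f"{self.entry_id}: operator rotation is not orthogonal")
            if not np.isclose(np.linalg.det(rot), 1.0, atol=1e-6):
                raise ValueError(f"{self.entry_id}: operator rotation has det != +1")
            ops.append((rot, trans))
        self.operators = ops
        if self.multimer_size == 0:
            self.multimer_size = len(ops)
        if self.multimer_size != len(ops):
            raise ValueError(f"{self.entry_id}: multimer_size != number of operators")


@dataclass
class CurationConfig:
    """Thresholds of the library curation filter and redundancy rule."""

    min_length: int = 16          # "greater than 15 residues" -> length >= 16
    max_resolution: float = 3.5   # Å; unknown resolution fails the filter
    dedup_identity: float = 0.80  # redundant when identity > this ...
    dedup_rmsd: float = 1.0       # ... AND Cα RMSD (Å) < this
    identity_denominator: str = "aligned"  # or "shorter"

    def __post_init__(self) -> None:
        if not 0 < self.dedup_identity <= 1:
            raise ValueError("dedup_identity must lie in (0, 1]")
        if self.min_length <= 0 or self.max_resolution <= 0 or self.dedup_rmsd <= 0:
            raise ValueError("curation thresholds must be positive")


def filter_entries(entries: list[ChainEntry], config: CurationConfig | None = None) -> list[ChainEntry]:
    """Keep chains meeting the length and resolution criteria, in order."""
    config = config or CurationConfig()
    kept = []
    for e in entries:
        if e.length < config.min_length:
            log.info("filtered %s: length %d < %d", e.entry_id, e.length, config.min_length)
        elif e.resolution is None:
            log.info("filtered %s: resolution unknown", e.entry_id)
        elif e.resolution > config.max_resolution:
            log.info(
                "filtered %s: resolution %.2f > %.2f", e.entry_id, e.resolution, config.max_resolution
            )
        else:
            kept.append(e)
    return kept


def _pair_identity(aln, a: Sequence, b: Sequence, config: CurationConfig) -> float:
    if config.identity_denominator == "shorter":
        if not aln.pairs:
            return 0.0
        n_ident = round(aln.identity * len(aln.pairs))
        return n_ident / min(len(a), len(b))
    return aln.identity


def _pair_rmsd(a: ChainEntry, b: ChainEntry, aln) -> float | None:
    """Cα RMSD over aligned pairs after least-squares superposition."""
    from .model_prep import superpose  # local import; model_prep is alignment-agnostic

    if len(aln.pairs) < 3:
        return None
    ia = [i for i, _ in aln.pairs]
    ib = [j for _, j in aln.pairs]
    try:
        sup = superpose(b.ca_coords[ib], a.ca_coords[ia])
    except ValueError:
        return None
    return sup.rmsd


def redundancy_reduce(
    entries: list[ChainEntry],
    config: CurationConfig | None = None,
    aligner: Callable | None = None,
) -> list[ChainEntry]:
    """Greedy redundancy reduction retaining the higher-resolution chain.

    Entries are processed by resolution (ascending, entry_id as tie-break);
    an entry is dropped when some already-retained entry has identity above
    ``dedup_identity`` and superposed Cα RMSD below ``dedup_rmsd``. Chains
    with fewer than 3 aligned pairs to every retained entry are always kept
    (superposition undefined). The output preserves the input order.
    """
    config = config or CurationConfig()
    if aligner is None:
        from .model_search import make_aligner

        aligner = make_aligner()
    order = sorted(entries, key=lambda e: (float("inf") if e.resolution is None else e.resolution, e.entry_id))
    retained: list[ChainEntry] = []
    for e in order:
        redundant = False
        for r in retained:
            aln = aligner(r.sequence, e.sequence)
            if _pair_identity(aln, r.sequence, e.sequence, config) <= config.dedup_identity:
                continue
            rmsd = _pair_rmsd(r, e, aln)
            if rmsd is not None and rmsd < config.dedup_rmsd:
                log.info("dedup: %s displaced by %s (rmsd %.2f)", e.entry_id, r.entry_id, rmsd)
                redundant = True
                break
        if not redundant:
            retained.append(e)
    keep_ids = {e.entry_id for e in retained}
    return [e for e in entries if e.entry_id in keep_ids]


@dataclass
class ChainTree:
    """Agglomerative hierarchy over entries (average linkage on 1 - identity)."""

    labels: list[str]
    merges: np.ndarray | None  # scipy linkage matrix, None for a single leaf

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def cluster_chains(
    entries: list[ChainEntry],
    aligner: Callable | None = None,
) -> ChainTree:
    """Average-linkage clustering of chains on pairwise sequence identity."""
    if not entries:
        raise ValueError("cannot cluster an empty entry list")
    if aligner is None:
        from .model_search import make_aligner

        aligner = make_aligner()
    labels = [e.entry_id for e in entries]
    if len(entries) == 1:
        return ChainTree(labels=labels, merges=None)
    n = len(entries)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = aligner(entries[i].sequence, entries[j].sequence).identity
            dist[i, j] = dist[j, i] = 1.0 - ident
    merges = linkage(squareform(dist, checks=False), method="average")
    return ChainTree(labels=labels, merges=merges)


def _contact_pairs(coords: np.ndarray, cutoff: float = 8.0, min_sep: int = 3) -> np.ndarray:
    """(i, j) Cα contact pairs with i + min_sep <= j and distance <= cutoff."""
    d = squareform(pdist(coords))
    i, j = np.nonzero(np.triu(d <= cutoff, k=min_sep))
    return np.column_stack([i, j])


def decompose_domains(
    entry: ChainEntry,
    min_domain_len: int = 40,
    contact_cutoff: float = 8.0,
    split_fraction: float = 0.04,
) -> list[DomainEntry]:
    """Partition a chain into compact contiguous domains by contact separation.

    Recursively searches single cut points: a segment splits at the cut
    minimizing the number of Cα contacts (<= ``contact_cutoff`` Å) crossing
    it, provided both parts reach ``min_domain_len`` and the crossing
    contacts are at most ``split_fraction`` of the segment's contacts. A
    chain shorter than twice ``min_domain_len`` is one whole-chain domain.
    """
    n = entry.length
    seqids = entry.seqids
    contacts = _contact_pairs(entry.ca_coords, contact_cutoff)

    segments: list[tuple[int, int]] = []

    def split(s: int, e: int) -> None:  # inclusive 0-based segment
        length = e - s + 1
        seg = contacts[(contacts[:, 0] >= s) & (contacts[:, 1] <= e)]
        if length < 2 * min_domain_len or len(seg) == 0:
            segments.append((s, e))
            return
        cuts = np.arange(s + min_domain_len - 1, e - min_domain_len + 1)
        if len(cuts) == 0:
            segments.append((s, e))
            return
        inter = np.array([(np.logical_and(seg[:, 0] <= c, seg[:, 1] > c)).sum() for c in cuts])
        best = int(np.argmin(inter))
        if inter[best] <= split_fraction * len(seg):
            split(s, cuts[best])
            split(cuts[best] + 1, e)
        else:
            segments.append((s, e))

    split(0, n - 1)
    segments.sort()
    return [
        DomainEntry(
            parent=entry.entry_id,
            domain_index=k,
            residue_ranges=[(seqids[s], seqids[e])],
            ca_coords=entry.ca_coords[s : e + 1],
        )
        for k, (s, e) in enumerate(segments, start=1)
    ]


@dataclass
class LibraryIndex:
    """The curated library: chains, domains, assemblies and their hierarchies."""

    chains: list[ChainEntry] = field(default_factory=list)
    domains: list[DomainEntry] = field(default_factory=list)
    assemblies: list[AssemblyRecord] = field(default_factory=list)
    chain_tree: ChainTree | None = None
    domain_tree: ChainTree | None = None

    def chain_by_id(self, entry_id: str) -> ChainEntry | None:
        for c in self.chains:
            if c.entry_id == entry_id:
                return c
        return None


def build_index(
    chains: list[ChainEntry],
    domains: list[DomainEntry] | None = None,
    assemblies: list[AssemblyRecord] | None = None,
    chain_tree: ChainTree | None = None,
    domain_tree: ChainTree | None = None,
) -> LibraryIndex:
    """Assemble and validate the library index; errors name dangling references."""
    domains = domains or []
    assemblies = assemblies or []
    ids = {c.entry_id for c in chains}
    for d in domains:
        if d.parent not in ids:
            raise ValueError(f"domain references unknown chain {d.parent!r}")
    for a in assemblies:
        if a.entry_id not in ids:
            raise ValueError(f"assembly references unknown chain {a.entry_id!r}")
    return LibraryIndex(
        chains=list(chains),
        domains=list(domains),
        assemblies=list(assemblies),
        chain_tree=chain_tree,
        domain_tree=domain_tree,
    )


def build_library(
    entries: list[ChainEntry],
    config: CurationConfig | None = None,
    aligner: Callable | None = None,
    min_domain_len: int = 40,
    assemblies: list[AssemblyRecord] | None = None,
) -> LibraryIndex:
    """Full curation pipeline: filter, dedup, decompose, cluster, index."""
    config = config or CurationConfig()
    if aligner is None:
        from .model_search import make_aligner

        aligner = make_aligner()
    kept = redundancy_reduce(filter_entries(entries, config), config, aligner)
    kept_ids = {c.entry_id for c in kept}
    domains = [d for c in kept for d in decompose_domains(c, min_domain_len)]
    assemblies = [a for a in (assemblies or []) if a.entry_id in kept_ids]
    tree = cluster_chains(kept, aligner) if kept else None
    return build_index(kept, domains, assemblies, chain_tree=tree)


# ---------------------------------------------------------------------------
# Serialization (JSON, round-trips bit-identically via float repr)

def _chain_to_json(c: ChainEntry) -> dict:
    doc = {
        "entry_id": c.entry_id,
        "sequence": c.sequence.residues,
        "ca_coords": c.ca_coords.tolist(),
        "resolution": c.resolution,
        "chain_id": c.chain_id,
    }
    if c.residues is not None:
        doc["residues"] = [
            {
                "name": r.name,
                "seqid": r.seqid,
                "atoms": [[a.name, a.element, a.pos.tolist()] for a in r.atoms.values()],
            }
            for r in c.residues
        ]
    return doc


def _chain_from_json(doc: dict) -> ChainEntry:
    residues = None
    if "residues" in doc:
        residues = [
            Residue(
                r["name"],
                r["seqid"],
                {name: Atom(name, np.array(pos), elem) for name, elem, pos in r["atoms"]},
            )
            for r in doc["residues"]
        ]
    return ChainEntry(
        entry_id=doc["entry_id"],
        sequence=Sequence(id=doc["entry_id"], residues=doc["sequence"]),
        ca_coords=np.array(doc["ca_coords"]).reshape(-1, 3),
        resolution=doc["resolution"],
        residues=residues,
        chain_id=doc.get("chain_id", "A"),
    )


def _tree_to_json(t: ChainTree | None) -> dict | None:
    if t is None:
        return None
    return {"labels": t.labels, "merges": None if t.merges is None else t.merges.tolist()}


def _tree_from_json(doc: dict | None) -> ChainTree | None:
    if doc is None:
        return None
    merges = None if doc["merges"] is None else np.array(doc["merges"])
    return ChainTree(labels=doc["labels"], merges=merges)


def save_index(index: LibraryIndex, path: str | Path) -> None:
    doc = {
        "chains": [_chain_to_json(c) for c in index.chains],
        "domains": [
            {
                "parent": d.parent,
                "domain_index": d.domain_index,
                "residue_ranges": [list(r) for r in d.residue_ranges],
                "ca_coords": None if d.ca_coords is None else d.ca_coords.tolist(),
            }
            for d in index.domains
        ],
        "assemblies": [
            {
                "entry_id": a.entry_id,
                "operators": [[rot.tolist(), trans.tolist()] for rot, trans in a.operators],
                "multimer_size": a.multimer_size,
            }
            for a in index.assemblies
        ],
        "chain_tree": _tree_to_json(index.chain_tree),
        "domain_tree": _tree_to_json(index.domain_tree),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_index(path: str | Path) -> LibraryIndex:
    doc = json.loads(Path(path).read_text())
    chains = [_chain_from_json(c) for c in doc["chains"]]
    domains = [
        DomainEntry(
            parent=d["parent"],
            domain_index=d["domain_index"],
            residue_ranges=[tuple(r) for r in d["residue_ranges"]],
            ca_coords=None if d["ca_coords"] is None else np.array(d["ca_coords"]),
        )
        for d in doc["domains"]
    ]
    assemblies = [
        AssemblyRecord(
            entry_id=a["entry_id"],
            operators=[(np.array(rot), np.array(trans)) for rot, trans in a["operators"]],
            multimer_size=a["multimer_size"],
        )
        for a in doc["assemblies"]
    ]
    return build_index(
        chains,
        domains,
        assemblies,
        chain_tree=_tree_from_json(doc.get("chain_tree")),
        domain_tree=_tree_from_json(doc.get("domain_tree")),
    )
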