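"""The MR/refinement engine contract, a seeded simulated engine and the
synthetic-problem generator.

The simulated engine exists to exercise decision logic, not to model
crystallography: placement success and the refinement endpoint are seeded
deterministic functions of a model-quality proxy

    q* = identity x coverage x exp(-RMSD_to_truth),

computed by aligning the candidate model to the problem's ground truth.
All simulator constants live in :class:`SimulatorConfig`; they are chosen so
good, marginal and poor trajectories, and Q values on both sides of the
decision band, are all reachable.
"""

from __future__ import annotations

import abc
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence as TSequence

import numpy as np

from .core import AA1, ChainEntry, Residue, Atom, Sequence, sequence_weight
from .formats_io import TargetData, dump_target, write_fasta, write_model
from .model_prep import SearchModel, Superposition, as_search_model, superpose
from .model_search import make_aligner
from .solution_scoring import RefinementTrace
from .template_library import AssemblyRecord, LibraryIndex, build_index, decompose_domains, save_index

__all__ = [
    "Placement",
    "Engine",
    "SimulatorConfig",
    "SimulatedEngine",
    "SyntheticProblem",
    "make_chain",
    "derive_homologue",
    "make_synthetic_problem",
    "write_problem",
    "EngineUnavailable",
    "MolrepEngine",
    "PhaserEngine",
]

DEFAULT_N_CYCLES = 30


@dataclass
class Placement:
    """Outcome envelope of one MR placement attempt (failure is an outcome)."""

    model: SearchModel
    transform: Superposition | None
    mr_score: float
    success: bool
    quality: float = 0.0

    def __post_init__(self) -> None:
        if self.success and self.transform is None:
            raise ValueError("successful placement requires a transform")


class Engine(abc.ABC):
    """Contract every MR/refinement engine honours."""

    @abc.abstractmethod
    def place_model(
        self,
        target: TargetData,
        model: SearchModel,
        fixed_models: TSequence[SearchModel] = (),
    ) -> Placement:
        """Attempt to place ``model``; failure is a returned outcome."""

    @abc.abstractmethod
    def refine(self, placement: Placement, n_cycles: int = DEFAULT_N_CYCLES) -> RefinementTrace:
        """Restrained refinement returning exactly ``n_cycles`` R/Rfree values."""


class EngineUnavailable(RuntimeError):
    pass


@dataclass
class SimulatorConfig:
    start_rfree: float = 0.55     # where unrefined solutions start
    asymptote_slope: float = 0.35  # Rfree asymptote = start - slope * q*
    asymptote_floor: float = 0.20
    tau: float = 6.0              # cycles; exponential decay constant
    noise_sigma: float = 0.005
    flat_noise_sigma: float = 0.002
    success_floor: float = 0.02   # q* below this fails placement
    gap_base: float = 0.02        # R runs below Rfree by gap_base ...
    gap_overfit: float = 0.05     # ... plus overfitting growing at low q*


def _stable_rng(seed: int, *keys: str) -> np.random.Generator:
    parts = [seed] + [zlib.crc32(k.encode()) for k in keys]
    return np.random.default_rng(parts)


class SimulatedEngine(Engine):
    """Deterministic seeded stand-in for the MR + refinement engines."""

    def __init__(
        self,
        truths: ChainEntry | TSequence[ChainEntry],
        seed: int = 0,
        config: SimulatorConfig | None = None,
    ) -> None:
        self.truths = [truths] if isinstance(truths, ChainEntry) else list(truths)
        self.seed = int(seed)
        self.config = config or SimulatorConfig()
        self._aligner = make_aligner()

    # -- model quality -----------------------------------------------------
    def _representative(self, model: SearchModel) -> SearchModel:
        if model.members:
            model = model.members[0]
        first_chain = next(iter(model.chains))
        return SearchModel(model.model_type, {first_chain: model.chains[first_chain]},
                           source=model.source)

    def model_quality(self, model: SearchModel) -> tuple[float, Superposition | None]:
        """q* against the closest ground truth, with the fitting transform."""
        rep = self._representative(model)
        seq = rep.sequence("model")
        best_q, best_sup = 0.0, None
        for truth in self.truths:
            aln = self._aligner(truth.sequence, seq)
            if len(aln.pairs) < 3:
                continue
            fixed_idx = [i for i, _ in aln.pairs]
            mob_idx = [j for _, j in aln.pairs]
            try:
                sup = superpose(rep.ca_coords[mob_idx], truth.ca_coords[fixed_idx])
            except ValueError:
                continue
            q = aln.identity * aln.coverage * float(np.exp(-sup.rmsd))
            if q > best_q:
                best_q, best_sup = q, sup
        return best_q, best_sup

    # -- contract ----------------------------------------------------------
    def place_model(
        self,
        target: TargetData,
        model: SearchModel,
        fixed_models: TSequence[SearchModel] = (),
    ) -> Placement:
        cfg = self.config
        q, sup = self.model_quality(model)
        # keyed on what the model is, not its run-dependent index, so results
        # are invariant under batching and re-ranking
        rng = _stable_rng(self.seed, "place", f"{model.source}:{model.model_type}")
        # fixing partial solutions shrinks the problem: the floor relaxes
        floor = cfg.success_floor / (1 + len(fixed_models))
        success = sup is not None and q + rng.normal(0.0, cfg.noise_sigma) >= floor
        mr_score = max(0.0, 100.0 * q + rng.normal(0.0, 0.5))
        return Placement(
            model=model,
            transform=sup if success else None,
            mr_score=mr_score,
            success=success,
            quality=q,
        )

    def refine(self, placement: Placement, n_cycles: int = DEFAULT_N_CYCLES) -> RefinementTrace:
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        cfg = self.config
        rng = _stable_rng(
            self.seed, "refine",
            f"{placement.model.source}:{placement.model.model_type}",
        )
        cycles = np.arange(1, n_cycles + 1)
        if not placement.success:
            rfree = cfg.start_rfree + rng.normal(0.0, cfg.flat_noise_sigma, n_cycles)
            r = rfree - cfg.gap_base
        else:
            q = placement.quality
            asym = max(cfg.asymptote_floor, cfg.start_rfree - cfg.asymptote_slope * q)
            decay = np.exp(-cycles / cfg.tau)
            rfree = asym + (cfg.start_rfree - asym) * decay + rng.normal(
                0.0, cfg.noise_sigma, n_cycles
            )
            gap = (cfg.gap_base + cfg.gap_overfit * (1.0 - q)) * (1.0 - decay)
            r = rfree - gap
        rfree = np.clip(rfree, 0.01, 0.99)
        r = np.clip(r, 0.01, 0.99)
        return RefinementTrace(r=r.tolist(), rfree=rfree.tolist())


# ---------------------------------------------------------------------------
# Synthetic problems

_BACKBONE_GEOM = (("N", -1.46), ("C", 1.52))


def _compact_walk(rng: np.random.Generator, n: int, step: float = 3.8) -> np.ndarray:
    """A compact pseudo-protein Cα trace: a random walk confined to a globule."""
    radius = 2.5 * n ** 0.38
    coords = np.zeros((n, 3))
    pos = np.zeros(3)
    for i in range(1, n):
        d = rng.normal(size=3)
        r = np.linalg.norm(pos)
        if r > 1e-9:
            d -= 1.5 * (r / radius) * pos / r  # pull back toward the centre
        d /= np.linalg.norm(d)
        pos = pos + step * d
        coords[i] = pos
    return coords - coords.mean(axis=0)


def _build_backbone(sequence: str, ca: np.ndarray) -> list[Residue]:
    """Approximate backbone + Cβ records around a Cα trace."""
    from .core import AA1_TO_3

    n = len(sequence)
    residues = []
    for i in range(n):
        prev_ca = ca[max(i - 1, 0)]
        next_ca = ca[min(i + 1, n - 1)]
        t = next_ca - prev_ca
        norm = np.linalg.norm(t)
        t = t / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        ref = np.array([0.0, 0.0, 1.0]) if abs(t[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        u = np.cross(t, ref)
        u /= np.linalg.norm(u)
        v = np.cross(t, u)
        name3 = AA1_TO_3.get(sequence[i], "UNK")
        atoms = {
            "N": Atom("N", ca[i] - 1.46 * (0.9 * t + 0.44 * u), "N"),
            "CA": Atom("CA", ca[i].copy(), "C"),
            "C": Atom("C", ca[i] + 1.52 * (0.9 * t - 0.44 * u), "C"),
        }
        atoms["O"] = Atom("O", atoms["C"].pos + 1.23 * u, "O")
        if name3 != "GLY":
            atoms["CB"] = Atom("CB", ca[i] + 1.53 * v, "C")
        residues.append(Residue(name3, i + 1, atoms))
    return residues


def _mutate(rng: np.random.Generator, residues: str, identity: float) -> str:
    n_mut = round((1.0 - identity) * len(residues))
    positions = rng.choice(len(residues), size=n_mut, replace=False)
    out = list(residues)
    for p in positions:
        choices = [a for a in AA1 if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _make_chain(entry_id: str, residues_str: str, ca: np.ndarray,
                resolution: float | None) -> ChainEntry:
    return ChainEntry(
        entry_id=entry_id,
        sequence=Sequence(id=entry_id, residues=residues_str),
        ca_coords=ca,
        resolution=resolution,
        residues=_build_backbone(residues_str, ca),
        chain_id=entry_id.rsplit("_", 1)[-1] if "_" in entry_id else "A",
    )


def make_chain(
    seed: int,
    n_residues: int = 80,
    entry_id: str = "syn_A",
    resolution: float | None = 2.0,
) -> ChainEntry:
    """One synthetic compact chain with backbone records (test fixture)."""
    rng = np.random.default_rng([seed, 0xC0DE])
    seq = "".join(AA1[i] for i in rng.integers(len(AA1), size=n_residues))
    return _make_chain(entry_id, seq, _compact_walk(rng, n_residues), resolution)


def derive_homologue(
    chain: ChainEntry,
    identity: float,
    sigma: float,
    seed: int,
    entry_id: str,
    resolution: float | None = 2.0,
) -> ChainEntry:
    """A homologue of ``chain`` at a given sequence identity and coordinate
    noise (Cα RMSD ≈ sigma, Å)."""
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"infeasible identity {identity}")
    rng = np.random.default_rng([seed, 0xD0C])
    seq = _mutate(rng, chain.sequence.residues, identity)
    ca = chain.ca_coords + rng.normal(0.0, sigma / np.sqrt(3.0), size=chain.ca_coords.shape)
    return _make_chain(entry_id, seq, ca, resolution)


@dataclass
class SyntheticProblem:
    """A seeded desk-scale MR problem: ground truth, target and library."""

    truth: ChainEntry
    target: TargetData
    library: LibraryIndex
    seed: int
    params: dict = field(default_factory=dict)

    def engine(self, config: SimulatorConfig | None = None) -> SimulatedEngine:
        return SimulatedEngine(self.truth, seed=self.seed, config=config)


def make_synthetic_problem(
    seed: int,
    n_residues: int = 100,
    homologues: TSequence[tuple[float, float]] = ((0.90, 0.3),),
    n_decoys: int = 10,
    n_sequences: int = 1,
    target_identity: float = 0.95,
    assembly_size: int = 0,
    space_group: str = "P 1",
    resolution: float = 2.0,
    with_domains: bool = False,
) -> SyntheticProblem:
    """Generate a reproducible synthetic MR problem.

    ``homologues`` lists (sequence identity, coordinate noise σ in Å) pairs;
    each produces a template derived from the ground truth. Decoys are
    unrelated compact chains. With ``n_sequences > 1`` the target carries
    several sequences, each a slight variant of the truth (so assembly and
    combination logic is exercised); ``assembly_size`` > 0 plants a multimer
    record on the first homologue. The unit cell is sized for one copy of
    the full target content near 50% solvent.
    """
    for identity, _ in homologues:
        if not 0.0 <= identity <= 1.0:
            raise ValueError(f"infeasible identity {identity}")
    if not 0.0 <= target_identity <= 1.0:
        raise ValueError(f"infeasible identity {target_identity}")
    rng = np.random.default_rng([seed, 0x5EED])
    truth_seq = "".join(AA1[i] for i in rng.integers(len(AA1), size=n_residues))
    truth_ca = _compact_walk(rng, n_residues)
    truth = _make_chain("truth_A", truth_seq, truth_ca, 1.0)

    chains: list[ChainEntry] = []
    for k, (identity, sigma) in enumerate(homologues, start=1):
        seq = _mutate(rng, truth_seq, identity)
        ca = truth_ca + rng.normal(0.0, sigma / np.sqrt(3.0), size=truth_ca.shape)
        chains.append(_make_chain(f"hom{k}_A", seq, ca, round(rng.uniform(1.2, 2.8), 2)))
    for k in range(1, n_decoys + 1):
        seq = "".join(AA1[i] for i in rng.integers(len(AA1), size=n_residues))
        ca = _compact_walk(rng, n_residues)
        chains.append(_make_chain(f"dec{k}_A", seq, ca, round(rng.uniform(1.2, 2.8), 2)))

    assemblies = []
    if assembly_size > 0 and homologues:
        ops = []
        for k in range(assembly_size):
            angle = 2.0 * np.pi * k / assembly_size
            c, s = np.cos(angle), np.sin(angle)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            trans = np.array([30.0 * k, 0.0, 0.0])
            ops.append((rot, trans))
        assemblies.append(AssemblyRecord(entry_id="hom1_A", operators=ops))

    domains = []
    if with_domains:
        domains = [d for c in chains for d in decompose_domains(c)]
    library = build_index(chains, domains, assemblies)

    targets = []
    for i in range(1, n_sequences + 1):
        seq = truth_seq if n_sequences == 1 else _mutate(rng, truth_seq, target_identity)
        targets.append(Sequence(id=f"target_{i}", residues=seq))
    total_weight = sum(sequence_weight(t.residues) for t in targets)
    volume = 2.70 * total_weight  # ~50% solvent for one copy in P 1
    a = volume ** (1.0 / 3.0)
    target = TargetData(
        sequences=targets,
        cell=(a, a, a, 90.0, 90.0, 90.0),
        space_group=space_group,
        resolution=resolution,
    )
    return SyntheticProblem(
        truth=truth,
        target=target,
        library=library,
        seed=seed,
        params={
            "n_residues": n_residues,
            "homologues": list(map(tuple, homologues)),
            "n_decoys": n_decoys,
            "n_sequences": n_sequences,
            "assembly_size": assembly_size,
        },
    )


def write_problem(problem: SyntheticProblem, outdir: str | Path) -> None:
    """Serialize a synthetic problem as FASTA + PDB + descriptor + index."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(problem.target.sequences, outdir / "target.fasta")
    dump_target(problem.target, outdir / "target.yaml")
    write_model(as_search_model(problem.truth), outdir / "truth.pdb")
    save_index(problem.library, outdir / "library.json")
    tpl_dir = outdir / "templates"
    tpl_dir.mkdir(exist_ok=True)
    for chain in problem.library.chains:
        write_model(as_search_model(chain), tpl_dir / f"{chain.entry_id}.pdb")


# ---------------------------------------------------------------------------
# External-engine adapters (command builders behind the same contract)

class _CommandEngine(Engine):
    """Structural adapter for an external MR engine; builds the command line
    but refuses to run unless an executable is configured."""

    program = ""

    def __init__(self, executable: str | None = None) -> None:
        self.executable = executable

    def build_place_command(self, target: TargetData, model_path: str) -> list[str]:
        cmd = [self.executable or self.program]
        if target.reflections_path:
            cmd += ["-f", str(target.reflections_path)]
        cmd += ["-m", str(model_path)]
        return cmd

    def place_model(self, target, model, fixed_models=()):
        raise EngineUnavailable(
            f"{self.program} adapter is not configured to run in this environment"
        )

    def refine(self, placement, n_cycles=DEFAULT_N_CYCLES):
        raise EngineUnavailable(
            f"{self.program} adapter is not configured to run in this environment"
        )


class MolrepEngine(_CommandEngine):
    program = "molrep"


class PhaserEngine(_CommandEngine):
    program = "phaser"
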