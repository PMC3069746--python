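import numpy as np
import pytest

from mrpilot.core import AA1_TO_3, Atom, ChainEntry, Residue, Sequence
from mrpilot.engine_sim import make_chain
from mrpilot.model_prep import SIDECHAIN_PARENT
from mrpilot.model_search import make_aligner


@pytest.fixture(scope="session")
def aligner():
    return make_aligner()


def full_atom_residue(name3: str, seqid: int, rng: np.random.Generator) -> Residue:
    """A residue carrying every heavy atom of its type, at arbitrary positions."""
    atoms = {}
    for atom_name in ("N", "CA", "C", "O", *SIDECHAIN_PARENT.get(name3, {})):
        atoms[atom_name] = Atom(atom_name, rng.uniform(-5, 5, 3))
    return Residue(name3, seqid, atoms)


def chain_from_letters(letters: str, entry_id: str = "tpl_A", seed: int = 0,
                       resolution: float = 2.0) -> ChainEntry:
    """A full-side-chain synthetic chain with the given one-letter sequence."""
    rng = np.random.default_rng(seed)
    base = make_chain(seed, n_residues=len(letters), entry_id=entry_id,
                      resolution=resolution)
    residues = []
    for i, letter in enumerate(letters):
        res = full_atom_residue(AA1_TO_3[letter], i + 1, rng)
        ca = base.ca_coords[i]
        for atom in res.atoms.values():
            atom.pos = ca + (atom.pos / 10.0 if atom.name != "CA" else 0.0)
        residues.append(res)
    return ChainEntry(
        entry_id=entry_id,
        sequence=Sequence(id=entry_id, residues=letters),
        ca_coords=base.ca_coords,
        resolution=resolution,
        residues=residues,
    )
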