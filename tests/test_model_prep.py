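import numpy as np
import pytest

from mrpilot.core import Sequence
from mrpilot.engine_sim import derive_homologue, make_chain
from mrpilot.model_prep import (
    SearchModel,
    apply_assembly,
    as_search_model,
    build_ensemble,
    extract_domain,
    make_mixed_model,
    make_polyalanine,
    msa_informed_alignments,
    shared_atoms,
    superpose,
)
from mrpilot.model_search import align_pair
from mrpilot.template_library import AssemblyRecord, DomainEntry

from conftest import chain_from_letters


def quaternion_rmsd(mobile: np.ndarray, fixed: np.ndarray) -> float:
    """Independent superposition RMSD via Horn's quaternion eigenvalue method."""
    x = mobile - mobile.mean(axis=0)
    y = fixed - fixed.mean(axis=0)
    S = x.T @ y
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = max(0.0, (np.sum(x**2) + np.sum(y**2) - 2.0 * lam) / len(x))
    return float(np.sqrt(msd))


# ---------------------------------------------------------------------------
# shared atoms / mixed models

def test_shared_atom_table_basics():
    assert shared_atoms("LYS", "ALA") == {"N", "CA", "C", "O", "CB"}
    assert shared_atoms("PHE", "TYR") == {
        "N", "CA", "C", "O", "CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"
    }
    assert shared_atoms("ALA", "GLY") == {"N", "CA", "C", "O"}
    # ILE CD1 hangs off CG1, LEU CD1 off CG: not shared
    assert "CD1" not in shared_atoms("ILE", "LEU")


def test_mixed_model_lysine_to_alanine():
    template = chain_from_letters("KAV" + "GLY")  # 6 residues, full side chains
    target = Sequence("t", "AAV" + "GLY")
    aln = align_pair(target, template.sequence)
    model = make_mixed_model(template, aln, target)
    res0 = model.residues[0]
    assert res0.name == "ALA"
    assert set(res0.atoms) == {"N", "CA", "C", "O", "CB"}


def test_mixed_model_phe_to_tyr_keeps_ring_no_oh():
    template = chain_from_letters("FKVLG")
    target = Sequence("t", "YKVLG")
    model = make_mixed_model(template, align_pair(target, template.sequence), target)
    res0 = model.residues[0]
    assert res0.name == "TYR"
    assert "CZ" in res0.atoms and "OH" not in res0.atoms


def test_mixed_model_tyr_to_phe_drops_oh():
    template = chain_from_letters("YKVLG")
    target = Sequence("t", "FKVLG")
    model = make_mixed_model(template, align_pair(target, template.sequence), target)
    assert "OH" not in model.residues[0].atoms
    assert "CZ" in model.residues[0].atoms


def test_identical_template_unchanged():
    template = chain_from_letters("MKVLGWYAHD")
    target = Sequence("t", "MKVLGWYAHD")
    model = make_mixed_model(template, align_pair(target, template.sequence), target)
    assert model.residue_count == 10
    for got, src in zip(model.residues, template.residues):
        assert got.name == src.name
        assert set(got.atoms) == set(src.atoms)
        for name in got.atoms:
            np.testing.assert_array_equal(got.atoms[name].pos, src.atoms[name].pos)


def test_mixed_model_never_adds_atoms():
    rng = np.random.default_rng(5)
    letters = "ACDEFGHIKLMNPQRSTVWY"
    template = chain_from_letters(letters, seed=5)
    shuffled = "".join(rng.permutation(list(letters)))
    target = Sequence("t", shuffled)
    model = make_mixed_model(template, align_pair(target, template.sequence), target)
    by_seqid = {r.seqid: r for r in template.residues}
    for res in model.residues:
        assert set(res.atoms) <= set(by_seqid[res.seqid].atoms)


def test_sparse_alignment_errors():
    template = chain_from_letters("MKVLG")

    class Tiny:
        pairs = ((0, 0), (1, 1))
        identity = coverage = 1.0
        score = 0.0

    with pytest.raises(ValueError, match="too sparse"):
        make_mixed_model(template, Tiny(), Sequence("t", "MK"))


# ---------------------------------------------------------------------------
# polyalanine

def test_polyalanine_reduction_and_atom_count():
    template = chain_from_letters("KWGAY")
    poly = make_polyalanine(template)
    names = [r.name for r in poly.residues]
    assert names == ["ALA", "ALA", "GLY", "ALA", "ALA"]
    n_gly = 1
    assert poly.n_atoms == 5 * 5 - n_gly  # 5 atoms per residue, Gly lacks CB
    assert set(poly.residues[2].atoms) == {"N", "CA", "C", "O"}


def test_polyalanine_idempotent():
    template = chain_from_letters("KWGAYMN")
    once = make_polyalanine(template)
    twice = make_polyalanine(once)
    assert [r.name for r in once.residues] == [r.name for r in twice.residues]
    for a, b in zip(once.residues, twice.residues):
        assert set(a.atoms) == set(b.atoms)
        for n in a.atoms:
            np.testing.assert_array_equal(a.atoms[n].pos, b.atoms[n].pos)


# ---------------------------------------------------------------------------
# extract_domain

def test_extract_domain_inclusive_range():
    chain = make_chain(14, 30, "d_A", 2.0)
    model = extract_domain(chain, DomainEntry("d_A", 1, [(10, 20)]))
    assert model.residue_count == 11
    assert [r.seqid for r in model.residues] == list(range(10, 21))


def test_extract_domain_two_ranges_concatenate():
    chain = make_chain(15, 30, "d_A", 2.0)
    model = extract_domain(chain, DomainEntry("d_A", 1, [(3, 5), (20, 22)]))
    assert [r.seqid for r in model.residues] == [3, 4, 5, 20, 21, 22]


def test_extract_domain_roundtrip_numbering(tmp_path):
    from mrpilot.formats_io import read_structure, write_model

    chain = make_chain(16, 30, "d_A", 2.0)
    model = extract_domain(chain, DomainEntry("d_A", 1, [(10, 20)]))
    path = tmp_path / "dom.pdb"
    write_model(model, path)
    back = read_structure(path)[0]
    assert min(back.seqids) == 10 and max(back.seqids) == 20


def test_extract_domain_empty_errors():
    chain = make_chain(17, 30, "d_A", 2.0)
    with pytest.raises(ValueError):
        extract_domain(chain, DomainEntry("d_A", 1, [(100, 110)]))


# ---------------------------------------------------------------------------
# superpose

def test_superpose_identity():
    pts = np.random.default_rng(0).normal(size=(20, 3))
    sup = superpose(pts, pts)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)


def test_superpose_recovers_known_transform():
    rng = np.random.default_rng(1)
    fixed = rng.normal(size=(30, 3))
    rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # 90° about z
    trans = np.array([5.0, -3.0, 2.0])
    mobile = fixed @ rot.T + trans  # mobile = R fixed + t; inverse recovers it
    sup = superpose(mobile, fixed)
    assert sup.rmsd < 1e-9
    np.testing.assert_allclose(sup.rotation, rot.T, atol=1e-9)
    np.testing.assert_allclose(sup.apply(mobile), fixed, atol=1e-9)


def test_superpose_matches_quaternion_oracle():
    rng = np.random.default_rng(2)
    mobile = rng.normal(size=(50, 3))
    fixed = rng.normal(size=(50, 3))
    sup = superpose(mobile, fixed)
    assert sup.rmsd == pytest.approx(quaternion_rmsd(mobile, fixed), abs=1e-9)


def test_superpose_rigid_invariance():
    rng = np.random.default_rng(3)
    mobile = rng.normal(size=(25, 3))
    fixed = rng.normal(size=(25, 3))
    base = superpose(mobile, fixed).rmsd
    theta = 0.7
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]
    ])
    shift = np.array([10.0, 5.0, -7.0])
    moved = superpose(mobile @ rot.T + shift, fixed @ rot.T + shift).rmsd
    assert moved == pytest.approx(base, abs=1e-9)


def test_superpose_degenerate_inputs():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    cloud = np.random.default_rng(4).normal(size=(4, 3))
    with pytest.raises(ValueError, match="collinear|degenerate"):
        superpose(line, cloud)
    with pytest.raises(ValueError, match="3 pairs"):
        superpose(cloud[:2], cloud[:2])


def test_superpose_with_pair_map():
    rng = np.random.default_rng(5)
    fixed = rng.normal(size=(10, 3))
    mobile = np.vstack([fixed[5:], fixed[:5]])  # rolled copy
    pairs = [(i, (i + 5) % 10) for i in range(10)]
    assert superpose(mobile, fixed, pairs).rmsd < 1e-12


# ---------------------------------------------------------------------------
# ensembles

def _conformers(n, sigma, seed, length=50):
    base = make_chain(seed, length, "base_A", 2.0)
    return [
        derive_homologue(base, 1.0, sigma, seed=seed + 1 + i, entry_id=f"m{i}_A")
        for i in range(n)
    ]


def test_ensemble_of_identical_models_core_rmsd_zero(aligner):
    base = make_chain(30, 40, "e_A", 2.0)
    twin = derive_homologue(base, 1.0, 0.0, seed=31, entry_id="f_A")
    ens = build_ensemble([base, twin], aligner)
    assert ens.model_type == "ensemble"
    assert len(ens.members) == 2
    a, b = (m.ca_coords for m in ens.members)
    assert np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))) < 1e-6


def test_ensemble_conformer_spread_matches_noise(aligner):
    rmsds = []
    for seed in range(100, 120):
        members = _conformers(4, 0.3, seed)
        ens = build_ensemble([as_search_model(m) for m in members], aligner)
        cas = [m.ca_coords for m in ens.members]
        for i in range(len(cas)):
            for j in range(i + 1, len(cas)):
                rmsds.append(np.sqrt(np.mean(np.sum((cas[i] - cas[j]) ** 2, axis=1))))
    assert 0.2 <= np.mean(rmsds) <= 0.6


def test_ensemble_members_share_core_residue_count(aligner):
    members = _conformers(3, 0.4, 200)
    ens = build_ensemble([as_search_model(m) for m in members], aligner)
    counts = {m.residue_count for m in ens.members}
    assert len(counts) == 1


def test_ensemble_without_common_core_errors(aligner):
    a = make_chain(40, 30, "a_A", 2.0)
    tiny = SearchModel("unmodified", {"A": as_search_model(a).residues[:2]}, source="tiny")
    with pytest.raises(ValueError, match="common core|at least"):
        build_ensemble([tiny, tiny.copy()], aligner)


def test_ensemble_permutation_stable(aligner):
    members = _conformers(4, 0.3, 300)
    e1 = build_ensemble([as_search_model(m) for m in members], aligner)
    e2 = build_ensemble([as_search_model(m) for m in reversed(members)], aligner)
    assert [m.source for m in e1.members] == [m.source for m in e2.members]
    assert e1.core == e2.core


# ---------------------------------------------------------------------------
# assemblies

def test_identity_operator_preserves_monomer():
    chain = make_chain(50, 20, "m_A", 2.0)
    rec = AssemblyRecord("m_A", [(np.eye(3), np.zeros(3))])
    multimer = apply_assembly(chain, rec)
    assert list(multimer.chains) == ["A"]
    np.testing.assert_allclose(multimer.ca_coords, chain.ca_coords)


def test_two_operators_double_atoms():
    chain = make_chain(51, 20, "m_A", 2.0)
    mono = as_search_model(chain)
    rec = AssemblyRecord(
        "m_A", [(np.eye(3), np.zeros(3)), (np.eye(3), np.array([30.0, 0, 0]))]
    )
    multimer = apply_assembly(chain, rec)
    assert multimer.n_atoms == 2 * mono.n_atoms
    assert list(multimer.chains) == ["A", "B"]


def test_assembly_relative_transform_recoverable():
    chain = make_chain(52, 25, "m_A", 2.0)
    theta = np.pi / 3
    rot = np.array([
        [np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]
    ])
    rec = AssemblyRecord("m_A", [(np.eye(3), np.zeros(3)), (rot, np.array([10.0, 5, 0]))])
    multimer = apply_assembly(chain, rec)
    a = np.array([r.ca.pos for r in multimer.chains["A"]])
    b = np.array([r.ca.pos for r in multimer.chains["B"]])
    sup = superpose(b, a)
    assert sup.rmsd < 1e-9
    np.testing.assert_allclose(sup.rotation, rot.T, atol=1e-9)


def test_zero_operators_error():
    chain = make_chain(53, 20, "m_A", 2.0)
    with pytest.raises(ValueError):
        apply_assembly(chain, AssemblyRecord("m_A", []))


# ---------------------------------------------------------------------------
# MSA-informed pairing

def test_msa_informed_reduces_to_pairwise_for_single_template(aligner):
    base = make_chain(55, 40, "base_A", 2.0)
    tpl = derive_homologue(base, 0.8, 0.3, seed=56, entry_id="tpl_A")
    msa = msa_informed_alignments(base.sequence, [tpl], aligner)
    assert msa["tpl_A"].pairs == aligner(base.sequence, tpl.sequence).pairs


def test_msa_informed_drops_low_consensus_columns(aligner):
    base = make_chain(57, 40, "base_A", 2.0)
    tpls = [
        derive_homologue(base, 0.9, 0.3, seed=58 + i, entry_id=f"t{i}_A")
        for i in range(3)
    ]
    # a template covering only the first half of the target
    half = tpls[0]
    from mrpilot.core import ChainEntry

    short = ChainEntry(
        "short_A",
        Sequence("short_A", half.sequence.residues[:20]),
        half.ca_coords[:20],
        2.0,
        half.residues[:20],
    )
    msa = msa_informed_alignments(base.sequence, tpls + [short], aligner)
    for tid, aln in msa.items():
        pair_targets = {i for i, _ in aln.pairs}
        raw = aligner(base.sequence, next(
            t for t in tpls + [short] if t.entry_id == tid).sequence)
        assert pair_targets <= {i for i, _ in raw.pairs}
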