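import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mrpilot.core import ChainEntry, Sequence
from mrpilot.engine_sim import derive_homologue, make_chain
from mrpilot.template_library import (
    AssemblyRecord,
    CurationConfig,
    DomainEntry,
    build_index,
    cluster_chains,
    decompose_domains,
    filter_entries,
    load_index,
    redundancy_reduce,
    save_index,
)


def _entry(n, resolution, seed=0, entry_id="e_A"):
    return make_chain(seed, n_residues=n, entry_id=entry_id, resolution=resolution)


# ---------------------------------------------------------------------------
# filter_entries

def test_filter_length_and_resolution_boundaries():
    config = CurationConfig()
    too_short = _entry(15, 2.0, entry_id="short_A")
    at_boundary = _entry(16, 3.5, entry_id="edge_A")
    no_resolution = _entry(200, None, entry_id="nores_A")
    too_coarse = _entry(50, 3.6, entry_id="coarse_A")
    kept = filter_entries([too_short, at_boundary, no_resolution, too_coarse], config)
    assert [e.entry_id for e in kept] == ["edge_A"]


def test_filter_is_idempotent_and_order_preserving():
    entries = [_entry(20 + i, 1.5 + 0.1 * i, seed=i, entry_id=f"c{i}_A") for i in range(6)]
    once = filter_entries(entries)
    assert filter_entries(once) == once
    assert [e.entry_id for e in once] == [e.entry_id for e in entries if e in once]


# ---------------------------------------------------------------------------
# redundancy_reduce

def _oracle_rmsd(a: ChainEntry, b: ChainEntry, aln) -> float | None:
    """Independent superposed Cα RMSD via scipy's rotation fit."""
    if len(aln.pairs) < 3:
        return None
    pa = a.ca_coords[[i for i, _ in aln.pairs]]
    pb = b.ca_coords[[j for _, j in aln.pairs]]
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)
    _, rssd = Rotation.align_vectors(pa, pb)
    return rssd / np.sqrt(len(pa))


def _oracle_reduce(entries, aligner, identity_thr=0.80, rmsd_thr=1.0):
    """Exhaustive pairwise greedy reference: full matrices, then the greedy
    higher-resolution-first retention rule."""
    order = sorted(entries, key=lambda e: (e.resolution, e.entry_id))
    retained = []
    for e in order:
        drop = False
        for r in retained:
            aln = aligner(r.sequence, e.sequence)
            if aln.identity > identity_thr:
                rmsd = _oracle_rmsd(r, e, aln)
                if rmsd is not None and rmsd < rmsd_thr:
                    drop = True
                    break
        if not drop:
            retained.append(e)
    return {e.entry_id for e in retained}


def test_identical_close_pair_keeps_higher_resolution(aligner):
    base = make_chain(5, n_residues=60, entry_id="a_A", resolution=1.5)
    twin = derive_homologue(base, 1.0, 0.2, seed=1, entry_id="b_A", resolution=2.0)
    kept = redundancy_reduce([base, twin], aligner=aligner)
    assert [e.entry_id for e in kept] == ["a_A"]


def test_conformational_variant_pair_both_retained(aligner):
    base = make_chain(6, n_residues=60, entry_id="a_A", resolution=1.5)
    variant = derive_homologue(base, 1.0, 1.8, seed=2, entry_id="b_A", resolution=2.0)
    kept = redundancy_reduce([base, variant], aligner=aligner)
    assert {e.entry_id for e in kept} == {"a_A", "b_A"}


def _planted_family(n_groups, members_per_group, seed0=100):
    """Chains in redundancy groups: within a group identity 1.0 / rmsd ~0.2;
    across groups unrelated."""
    chains = []
    rng = np.random.default_rng(seed0)
    for g in range(n_groups):
        base = make_chain(seed0 + g, n_residues=50, entry_id=f"g{g}m0_A",
                          resolution=round(float(rng.uniform(1.2, 2.8)), 2))
        chains.append(base)
        for m in range(1, members_per_group):
            chains.append(
                derive_homologue(base, 1.0, 0.2, seed=seed0 + 10 * g + m,
                                 entry_id=f"g{g}m{m}_A",
                                 resolution=round(float(rng.uniform(1.2, 2.8)), 2))
            )
    return chains


@pytest.mark.parametrize("n_groups,members", [(3, 2), (5, 4)])
def test_reduction_matches_exhaustive_oracle(aligner, n_groups, members):
    chains = _planted_family(n_groups, members)
    kept = {e.entry_id for e in redundancy_reduce(chains, aligner=aligner)}
    assert kept == _oracle_reduce(chains, aligner)
    assert len(kept) == n_groups  # one representative per planted group


def test_reduction_order_independent_and_fixed_point(aligner):
    chains = _planted_family(4, 3)
    kept = redundancy_reduce(chains, aligner=aligner)
    shuffled = list(chains)
    np.random.default_rng(0).shuffle(shuffled)
    kept_shuffled = redundancy_reduce(shuffled, aligner=aligner)
    assert {e.entry_id for e in kept} == {e.entry_id for e in kept_shuffled}
    again = redundancy_reduce(kept, aligner=aligner)
    assert [e.entry_id for e in again] == [e.entry_id for e in kept]
    assert len(kept) <= len(chains)


def test_retained_representative_has_better_resolution(aligner):
    chains = _planted_family(4, 3)
    kept = {e.entry_id for e in redundancy_reduce(chains, aligner=aligner)}
    by_id = {e.entry_id: e for e in chains}
    for e in chains:
        if e.entry_id in kept:
            continue
        displacers = [
            by_id[r] for r in kept
            if aligner(by_id[r].sequence, e.sequence).identity > 0.80
            and (_oracle_rmsd(by_id[r], e, aligner(by_id[r].sequence, e.sequence)) or 9) < 1.0
        ]
        assert any(d.resolution <= e.resolution for d in displacers)


# ---------------------------------------------------------------------------
# cluster_chains

def test_single_entry_tree():
    tree = cluster_chains([make_chain(1, 30, "solo_A", 2.0)])
    assert tree.labels == ["solo_A"]
    assert tree.merges is None


def test_identical_pair_merges_first(aligner):
    a = make_chain(3, 50, "a_A", 2.0)
    b = derive_homologue(a, 1.0, 0.1, seed=4, entry_id="b_A")
    c = make_chain(99, 50, "c_A", 2.0)  # unrelated
    tree = cluster_chains([a, b, c], aligner)
    first = tree.merges[0]
    assert {int(first[0]), int(first[1])} == {0, 1}


def _naive_average_linkage(dist):
    """Direct O(n^3) average-linkage agglomeration; returns merge heights and
    the member sets merged, for comparison with the library hierarchy."""
    clusters = {i: frozenset([i]) for i in range(len(dist))}
    merges = []
    d = {(i, j): dist[i][j] for i in range(len(dist)) for j in range(i + 1, len(dist))}

    def cdist(a, b):
        return float(np.mean([dist[i][j] for i in clusters[a] for j in clusters[b]]))

    keys = list(clusters)
    while len(keys) > 1:
        best = min(
            ((a, b) for ai, a in enumerate(keys) for b in keys[ai + 1:]),
            key=lambda ab: (cdist(*ab), ab),
        )
        h = cdist(*best)
        new = clusters[best[0]] | clusters[best[1]]
        merges.append((h, new))
        nid = max(clusters) + 1
        clusters[nid] = new
        for k in best:
            del clusters[k]
        keys = sorted(clusters)
    return merges


def test_tree_matches_direct_average_linkage(aligner):
    base = make_chain(40, 40, "f0_A", 2.0)
    chains = [base] + [
        derive_homologue(base, ident, 0.3, seed=50 + i, entry_id=f"f{i}_A")
        for i, ident in enumerate([0.95, 0.9, 0.6, 0.55, 0.3], start=1)
    ] + [make_chain(77, 40, "f6_A", 2.0), make_chain(78, 40, "f7_A", 2.0)]
    n = len(chains)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1 - aligner(chains[i].sequence, chains[j].sequence).identity
    tree = cluster_chains(chains, aligner)
    expected = _naive_average_linkage(dist)

    # reconstruct merged member sets from the scipy linkage matrix
    sets = {i: frozenset([i]) for i in range(n)}
    got = []
    for k, (a, b, h, _) in enumerate(tree.merges):
        new = sets[int(a)] | sets[int(b)]
        sets[n + k] = new
        got.append((h, new))
    assert len(got) == len(expected)
    for (h1, s1), (h2, s2) in zip(got, expected):
        assert s1 == s2
        assert h1 == pytest.approx(h2, abs=1e-9)


# ---------------------------------------------------------------------------
# decompose_domains

def _dumbbell(seed=8, n_lobe=60, n_linker=5, separation=40.0):
    rng = np.random.default_rng(seed)
    lobe1 = make_chain(seed, n_lobe, "l1_A", 2.0).ca_coords
    lobe2 = make_chain(seed + 1, n_lobe, "l2_A", 2.0).ca_coords + [separation, 0, 0]
    start, end = lobe1[-1], lobe2[0]
    linker = np.array([start + (end - start) * (k + 1) / (n_linker + 1) for k in range(n_linker)])
    ca = np.vstack([lobe1, linker, lobe2])
    from mrpilot.core import AA1

    seq = "".join(AA1[i] for i in rng.integers(len(AA1), size=len(ca)))
    return ChainEntry("db_A", Sequence("db_A", seq), ca, 2.0)


def test_compact_globule_single_domain():
    chain = make_chain(21, 100, "g_A", 2.0)
    domains = decompose_domains(chain)
    assert len(domains) == 1
    assert domains[0].residue_ranges == [(1, 100)]


def test_short_chain_single_domain():
    chain = make_chain(22, 50, "s_A", 2.0)
    assert len(decompose_domains(chain, min_domain_len=40)) == 1


def test_dumbbell_splits_at_linker():
    chain = _dumbbell()
    # exhaustive single-cut oracle: cut minimizing crossing contacts
    from mrpilot.template_library import _contact_pairs

    contacts = _contact_pairs(chain.ca_coords)
    cuts = range(39, chain.length - 40)
    inter = [
        ((contacts[:, 0] <= c) & (contacts[:, 1] > c)).sum() for c in cuts
    ]
    oracle_cut = list(cuts)[int(np.argmin(inter))]

    domains = decompose_domains(chain)
    assert len(domains) == 2
    split_at = domains[0].residue_ranges[-1][1] - 1  # 0-based index of the cut
    assert abs(split_at - oracle_cut) <= 2
    assert 55 <= split_at <= 70  # at the linker


@pytest.mark.parametrize("seed", [31, 32, 33])
def test_domains_partition_chain_exactly(seed):
    chain = make_chain(seed, 120, "p_A", 2.0)
    domains = decompose_domains(chain, min_domain_len=30)
    covered = []
    for d in domains:
        for lo, hi in d.residue_ranges:
            covered.extend(range(lo, hi + 1))
    assert sorted(covered) == chain.seqids


# ---------------------------------------------------------------------------
# build_index

def test_index_roundtrip_bit_identical(tmp_path):
    chains = [make_chain(i, 20, f"c{i}_A", 2.0) for i in range(3)]
    domains = [
        DomainEntry("c0_A", 1, [(1, 10)]),
        DomainEntry("c0_A", 2, [(11, 20)]),
    ]
    assemblies = [AssemblyRecord("c1_A", [(np.eye(3), np.zeros(3))])]
    index = build_index(chains, domains, assemblies)
    p1, p2 = tmp_path / "i1.json", tmp_path / "i2.json"
    save_index(index, p1)
    back = load_index(p1)
    save_index(back, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert [c.entry_id for c in back.chains] == [c.entry_id for c in chains]
    np.testing.assert_array_equal(back.chains[0].ca_coords, chains[0].ca_coords)


def test_dangling_domain_reference_errors():
    chains = [make_chain(0, 20, "c0_A", 2.0)]
    with pytest.raises(ValueError, match="ghost_A"):
        build_index(chains, [DomainEntry("ghost_A", 1, [(1, 5)])])


def test_empty_library_index():
    index = build_index([])
    assert index.chains == [] and index.domains == [] and index.assemblies == []
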