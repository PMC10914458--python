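import math

import numpy as np
import pytest

from protabc.alphabet import AMINO_ACIDS, AA_INDEX
from protabc.fixture import make_chain_structure, optimize_native_sequence
from protabc.structure import (
    ContactMap,
    ContactPotential,
    ProteinStructure,
    StabilityEngine,
    StabilityModel,
    StructureError,
    HomologyError,
    build_contact_map,
    build_stability_model,
    delta_g,
    get_engine,
    make_decoys,
    map_alignment_to_structure,
    misfold_free_energy,
    native_energy,
    read_pdb,
    rem_free_energy,
    write_pdb,
)
from protabc.io_models import Alignment

from conftest import random_sequence


def two_residue_structure(distance):
    coords = [
        np.array([[0.0, 0.0, 0.0]]),
        np.array([[distance, 0.0, 0.0]]),
    ]
    return ProteinStructure(native_seq="AC", residue_coords=coords)


class TestContactMap:
    def test_close_pair_contact(self):
        s = two_residue_structure(3.0)
        cmap = build_contact_map(s, cutoff=4.5, s_min=1)
        assert cmap.pairs == frozenset({(0, 1)})

    def test_far_pair_no_contact(self):
        s = two_residue_structure(50.0)
        cmap = build_contact_map(s, cutoff=4.5, s_min=1)
        assert not cmap.pairs

    def test_brute_force_oracle(self, rng):
        coords = [rng.normal(0, 4, size=(3, 3)) for _ in range(10)]
        s = ProteinStructure(native_seq="ACDEFGHIKL", residue_coords=coords)
        cutoff, s_min = 6.0, 2
        cmap = build_contact_map(s, cutoff=cutoff, s_min=s_min)
        expected = set()
        for i in range(10):
            for j in range(10):
                if j - i < s_min:
                    continue
                best = min(
                    math.dist(a, b)
                    for a in coords[i]
                    for b in coords[j]
                )
                if best <= cutoff:
                    expected.add((i, j))
        assert cmap.pairs == frozenset(expected)

    def test_too_small_structure(self):
        with pytest.raises(StructureError):
            ProteinStructure(native_seq="A", residue_coords=[np.zeros((1, 3))])

    def test_bad_params(self):
        s = two_residue_structure(3.0)
        with pytest.raises(ValueError):
            build_contact_map(s, cutoff=-1)
        with pytest.raises(ValueError):
            build_contact_map(s, s_min=0)


class TestNativeEnergy:
    def test_empty_map_zero(self, potential):
        cmap = ContactMap(L=4, pairs=frozenset())
        assert native_energy("ACDE", cmap, potential) == 0.0

    def test_single_pair(self, potential):
        cmap = ContactMap(L=2, pairs=frozenset({(0, 1)}))
        e = native_energy("AC", cmap, potential)
        assert e == potential.U[AA_INDEX["A"], AA_INDEX["C"]]

    def test_brute_force_oracle_100(self, potential, rng):
        for _ in range(100):
            L = int(rng.integers(5, 20))
            all_pairs = [(i, j) for i in range(L) for j in range(i + 1, L)]
            take = rng.choice(
                len(all_pairs), size=int(rng.integers(0, len(all_pairs))),
                replace=False,
            )
            pairs = frozenset(all_pairs[t] for t in take)
            cmap = ContactMap(L=L, pairs=pairs)
            seq = random_sequence(rng, L)
            expected = 0.0
            for i in range(L):
                for j in range(L):
                    if i < j and (i, j) in pairs:
                        expected += potential.U[AA_INDEX[seq[i]], AA_INDEX[seq[j]]]
            assert native_energy(seq, cmap, potential) == pytest.approx(expected)

    def test_length_mismatch(self, potential):
        cmap = ContactMap(L=3, pairs=frozenset())
        with pytest.raises(ValueError):
            native_energy("AC", cmap, potential)


class TestDecoys:
    def test_count_preserved(self, small_stab):
        decoys = make_decoys(small_stab.contact_map, M=2, seed=0)
        for d in decoys:
            assert d.n_contacts == small_stab.contact_map.n_contacts

    def test_no_decoy_equals_native(self, small_stab):
        decoys = make_decoys(small_stab.contact_map, M=10, seed=0)
        for d in decoys:
            assert d.pairs != small_stab.contact_map.pairs

    def test_determinism(self, small_stab):
        a = make_decoys(small_stab.contact_map, M=5, seed=3)
        b = make_decoys(small_stab.contact_map, M=5, seed=3)
        assert [d.pairs for d in a] == [d.pairs for d in b]

    def test_min_m(self, small_stab):
        with pytest.raises(ValueError):
            make_decoys(small_stab.contact_map, M=1, seed=0)

    def test_separation_respected(self, small_stab):
        for d in make_decoys(small_stab.contact_map, M=20, seed=1, s_min=3):
            assert all(j - i >= 3 for i, j in d.pairs)


class TestMisfoldFreeEnergy:
    def test_identical_energies_closed_form(self, potential):
        # sigma = 0, M decoys, T=1 -> mean - ln M
        cmap = ContactMap(L=6, pairs=frozenset({(0, 3)}))
        decoys = [cmap, cmap, cmap]
        g = misfold_free_energy("AAAAAA", decoys, potential, T=1.0)
        e = native_energy("AAAAAA", cmap, potential)
        assert g == pytest.approx(e - math.log(3))

    def test_high_t_entropy_dominated(self):
        mean, var, M = 2.0, 4.0, 100
        T = 1e6
        g = rem_free_energy(mean, var, M, T)
        assert g == pytest.approx(mean - T * math.log(M), rel=1e-6)

    def test_formula_oracle_random(self, rng):
        for _ in range(50):
            mean = rng.normal()
            var = float(rng.uniform(0.1, 5.0))
            M = int(rng.integers(2, 500))
            T = float(rng.uniform(0.05, 5.0))
            sd = math.sqrt(var)
            t_freeze = sd / math.sqrt(2 * math.log(M))
            if T >= t_freeze:
                expected = mean - var / (2 * T) - T * math.log(M)
            else:
                expected = mean - sd * math.sqrt(2 * math.log(M))
            assert rem_free_energy(mean, var, M, T) == pytest.approx(expected)

    def test_clamp_engages_below_freezing(self):
        mean, var, M = 0.0, 4.0, 50
        sd = 2.0
        t_freeze = sd / math.sqrt(2 * math.log(M))
        below = rem_free_energy(mean, var, M, t_freeze * 0.5)
        assert below == pytest.approx(mean - sd * math.sqrt(2 * math.log(M)))
        # without the clamp the formula would dive below the ground state
        raw = mean - var / (2 * (t_freeze * 0.5)) - (t_freeze * 0.5) * math.log(M)
        assert raw < below

    def test_non_increasing_in_t(self):
        temps = np.linspace(0.01, 5.0, 200)
        vals = [rem_free_energy(1.0, 3.0, 200, t) for t in temps]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_bad_temperature(self, potential):
        cmap = ContactMap(L=4, pairs=frozenset())
        with pytest.raises(ValueError):
            misfold_free_energy("AAAA", [cmap, cmap], potential, T=0.0)


class TestDeltaG:
    def test_zero_potential_closed_form(self, small_structure):
        zero = ContactPotential(U=np.zeros((20, 20)))
        stab = build_stability_model(
            small_structure, potential=zero, n_decoys=10, decoy_seed=0
        )
        seq = "A" * stab.L
        res = delta_g(seq, stab)
        T, M, L = stab.T, stab.M, stab.L
        assert res.E_nat == 0.0
        assert res.G_misf == pytest.approx(-T * math.log(M))
        expected = T * math.log(math.exp(stab.s_U * L) + math.exp(math.log(M)))
        assert res.dG == pytest.approx(expected)
        assert res.dG > 0

    def test_result_invariant(self, small_stab, rng):
        seq = random_sequence(rng, small_stab.L)
        res = delta_g(seq, small_stab)
        T = small_stab.T
        recon = res.E_nat - (
            -T * math.log(math.exp(-res.G_unf / T) + math.exp(-res.G_misf / T))
        )
        assert res.dG == pytest.approx(recon, abs=1e-9)

    def test_decoy_order_invariance(self, small_stab, rng):
        seq = random_sequence(rng, small_stab.L)
        res1 = delta_g(seq, small_stab)
        shuffled = StabilityModel(
            contact_map=small_stab.contact_map,
            potential=small_stab.potential,
            decoys=list(reversed(small_stab.decoys)),
            T=small_stab.T,
            s_U=small_stab.s_U,
        )
        res2 = delta_g(seq, shuffled)
        assert res1.dG == pytest.approx(res2.dG, abs=1e-12)

    def test_native_below_shuffled_null(self, scenario, rng):
        native = scenario.structure.native_seq
        native_dg = delta_g(native, scenario.stability).dG
        shuffled = [
            delta_g("".join(rng.permutation(list(native))), scenario.stability).dG
            for _ in range(100)
        ]
        assert native_dg < np.mean(shuffled)
        assert native_dg < np.quantile(shuffled, 0.025)

    def test_all_gaps_rejected(self, small_stab):
        with pytest.raises(ValueError):
            delta_g("-" * small_stab.L, small_stab)

    def test_favorable_contact_decreases_dg(self, potential, rng):
        # add one strongly favorable native contact; dG must strictly drop
        L = 20
        base_pairs = {(0, 5), (2, 9), (4, 12), (7, 15)}
        seq = random_sequence(rng, L)
        U = potential.U.copy()
        U[:, :] = U - U.min()  # nonneg potential; decoy means >= 0
        strong = ContactPotential(U=U)
        cmap1 = ContactMap(L=L, pairs=frozenset(base_pairs))
        cmap2 = ContactMap(L=L, pairs=frozenset(base_pairs | {(1, 10)}))
        decoys = make_decoys(cmap1, M=30, seed=5)
        U2 = U.copy()
        a, b = AA_INDEX[seq[1]], AA_INDEX[seq[10]]
        U2[a, b] = U2[b, a] = -50.0  # far below every decoy mean
        strong2 = ContactPotential(U=U2)
        m1 = StabilityModel(contact_map=cmap1, potential=strong2, decoys=decoys)
        m2 = StabilityModel(contact_map=cmap2, potential=strong2, decoys=decoys)
        assert delta_g(seq, m2).dG < delta_g(seq, m1).dG


class TestStabilityEngine:
    def test_incremental_matches_full(self, small_stab, rng):
        seq = random_sequence(rng, small_stab.L)
        engine = StabilityEngine(small_stab, seq)
        for _ in range(300):
            site = int(rng.integers(small_stab.L))
            new = int(rng.integers(20))
            dg_inc, d_nat, d_dec = engine.propose(site, new)
            engine.apply(site, new, d_nat, d_dec, new_dg=dg_inc)
            assert engine.dG == pytest.approx(
                delta_g(engine.sequence, small_stab).dG, abs=1e-9
            )

    def test_get_engine_reuses_tables(self, small_stab):
        e1 = get_engine(small_stab, "A" * small_stab.L)
        e2 = get_engine(small_stab, "C" * small_stab.L)
        assert e1 is e2
        assert e2.sequence == "C" * small_stab.L


class TestPDBRoundTrip:
    def test_write_read(self, tmp_path, scenario):
        path = tmp_path / "fixture.pdb"
        write_pdb(scenario.structure, path)
        back = read_pdb(path)
        assert back.native_seq == scenario.structure.native_seq
        for a, b in zip(back.residue_coords, scenario.structure.residue_coords):
            assert np.allclose(np.atleast_2d(a), np.atleast_2d(b), atol=1e-3)

    def test_contact_map_survives_round_trip(self, tmp_path, scenario):
        path = tmp_path / "fixture.pdb"
        write_pdb(scenario.structure, path)
        back = read_pdb(path)
        assert (
            build_contact_map(back).pairs
            == scenario.stability.contact_map.pairs
        )


class TestAlignmentStructureMapping:
    def test_identity_mapping(self, scenario):
        native = scenario.structure.native_seq
        aln = Alignment(ids=["a", "b"], rows=[native, native])
        trimmed, cmap = map_alignment_to_structure(aln, scenario.structure)
        assert trimmed.l == len(native)
        assert cmap == {i: i for i in range(len(native))}

    def test_extra_nterminal_columns_dropped(self, scenario):
        native = scenario.structure.native_seq
        padded = "AAAAA" + native
        aln = Alignment(ids=["a", "b"], rows=[padded, padded])
        with pytest.warns(UserWarning, match="dropped 5"):
            trimmed, cmap = map_alignment_to_structure(aln, scenario.structure)
        assert trimmed.l == len(native)
        assert set(cmap) == set(range(5, 5 + len(native)))

    def test_internal_deletions_ground_truth(self, scenario, rng):
        # delete ~30% of structure residues in internal blocks; kept columns
        # must map to the surviving residues exactly (fixture records the
        # ground-truth correspondence)
        native = random_sequence(rng, 60)
        coords = scenario.structure.residue_coords
        deleted = set(range(10, 16)) | set(range(30, 37)) | set(range(50, 55))
        keep = [i for i in range(60) if i not in deleted]
        sub_seq = "".join(native[i] for i in keep)
        sub_struct = ProteinStructure(
            native_seq=sub_seq,
            residue_coords=[coords[i] for i in keep],
        )
        aln = Alignment(ids=["a", "b"], rows=[native, native])
        with pytest.warns(UserWarning):
            trimmed, cmap = map_alignment_to_structure(aln, sub_struct)
        assert trimmed.l == len(keep)
        truth = {col: rank for rank, col in enumerate(keep)}
        cols = sorted(cmap)
        assert all(cmap[a] < cmap[b] for a, b in zip(cols, cols[1:]))
        agree = sum(1 for c, r in truth.items() if cmap.get(c) == r)
        # equal-scoring gap placements can shift a boundary by one residue
        assert agree / len(keep) >= 0.95

    def test_no_homology_errors(self, scenario):
        aln = Alignment(ids=["a", "b"], rows=["W" * 40, "W" * 40])
        with pytest.raises(HomologyError):
            map_alignment_to_structure(aln, scenario.structure)

    def test_dropped_column_report(self, scenario, tmp_path):
        native = scenario.structure.native_seq
        padded = "AAA" + native
        aln = Alignment(ids=["a", "b"], rows=[padded, padded])
        report = tmp_path / "dropped.tsv"
        with pytest.warns(UserWarning):
            map_alignment_to_structure(aln, scenario.structure, report_path=report)
        lines = report.read_text().strip().splitlines()
        assert lines[0] == "column\treason"
        assert len(lines) == 4  # 3 dropped columns
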