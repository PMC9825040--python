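import numpy as np
import pytest

from mmpcliff import mmp as mmp_mod
from mmpcliff.chem import canonical_smiles
from mmpcliff.io import ActivityClass, CompoundRecord
from mmpcliff.mmp import (
    build_mmps,
    enumerate_single_cut_fragmentations,
    passes_size_filters,
    reassemble,
)
from mmpcliff.synthetic import FIXTURE_BASELINES, FIXTURE_SUBSTITUENTS

from .oracles import brute_force_fragmentations, random_molecule, size_filter_rules


def frag_pairs(smiles):
    return {
        (f.core, f.substituent)
        for f in enumerate_single_cut_fragmentations(smiles)
    }


class TestEnumeration:
    def test_ethanol_has_two_cuts(self):
        expected = {
            (canonical_smiles("[*]CO"), canonical_smiles("[*]C")),
            (canonical_smiles("[*]CC"), canonical_smiles("[*]O")),
        }
        assert frag_pairs("CCO") == expected

    def test_benzene_has_no_acyclic_single_bonds(self):
        assert frag_pairs("c1ccccc1") == set()

    def test_toluene_single_exocyclic_cut(self):
        pairs = frag_pairs("Cc1ccccc1")
        assert pairs == {(canonical_smiles("[*]c1ccccc1"), canonical_smiles("[*]C"))}

    def test_symmetric_molecule_emits_both_orientations(self):
        # butane's central bond splits into two equal ethyl halves
        pairs = frag_pairs("CCCC")
        ethyl = canonical_smiles("[*]CC")
        assert (ethyl, ethyl) in pairs

    def test_matches_brute_force_oracle_on_random_molecules(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 60:
            smi = random_molecule(rng, max_heavy=30)
            if smi is None:
                continue
            assert frag_pairs(smi) == brute_force_fragmentations(smi), smi
            checked += 1

    def test_every_fragmentation_reassembles_to_parent(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 30:
            smi = random_molecule(rng, max_heavy=25)
            if smi is None:
                continue
            parent = canonical_smiles(smi)
            for frag in enumerate_single_cut_fragmentations(smi):
                assert reassemble(frag) == parent
            checked += 1


class TestSizeFilters:
    @pytest.mark.parametrize(
        "core,sa,sb,expected",
        [
            (10, 3, 5, True),
            (9, 1, 1, False),  # core below 10 heavy atoms
            (26, 13, 4, False),  # substituent difference 9 > 8
            (26, 13, 13, True),
            (12, 6, 6, True),
            (11, 6, 6, False),  # core below twice the larger substituent
            (30, 14, 14, False),  # substituent above 13
        ],
    )
    def test_rule_examples(self, core, sa, sb, expected):
        assert passes_size_filters(core, sa, sb) is expected

    def test_truth_table_matches_explicit_rules(self):
        for core in range(1, 31):
            for sa in range(1, 16):
                for sb in range(1, 16):
                    assert passes_size_filters(core, sa, sb) == size_filter_rules(
                        core, sa, sb
                    )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            passes_size_filters(0, 1, 1)


def _cls(records):
    return ActivityClass(
        class_id="T",
        compounds=[
            CompoundRecord(compound_id=cid, smiles=canonical_smiles(s), pki=p)
            for cid, s, p in records
        ],
    )


class TestBuildMMPs:
    def test_halogen_exchange_on_naphthalene(self):
        cls = _cls(
            [("a", "Clc1ccc2ccccc2c1", 6.0), ("b", "Brc1ccc2ccccc2c1", 7.5)]
        )
        mmps = build_mmps(cls)
        assert len(mmps) == 1
        m = mmps[0]
        assert (m.cid_low, m.cid_high) == ("a", "b")
        assert m.delta == pytest.approx(1.5)

    def test_identical_structures_give_no_mmp(self):
        cls = _cls([("a", "Clc1ccc2ccccc2c1", 6.0), ("b", "Clc1ccc2ccccc2c1", 7.0)])
        assert build_mmps(cls) == []

    def test_output_invariant_to_input_order(self, fix):
        cls, _ = fix
        shuffled = ActivityClass(
            class_id=cls.class_id, compounds=list(reversed(cls.compounds))
        )
        assert build_mmps(cls) == build_mmps(shuffled)

    def test_all_output_passes_size_filters(self, small_labeled):
        from mmpcliff.chem import heavy_atom_count

        _, mmps, _, _, _ = small_labeled
        for m in mmps:
            assert passes_size_filters(
                heavy_atom_count(m.core),
                heavy_atom_count(m.sub_low),
                heavy_atom_count(m.sub_high),
            )

    def test_relaxing_cutoffs_only_adds_mmps(self, fix, monkeypatch):
        cls, _ = fix
        baseline = {(m.cid_low, m.cid_high) for m in build_mmps(cls)}
        monkeypatch.setattr(mmp_mod, "MIN_CORE_ATOMS", 1)
        monkeypatch.setattr(mmp_mod, "CORE_SUBSTITUENT_RATIO", 0)
        monkeypatch.setattr(mmp_mod, "MAX_SUBSTITUENT_ATOMS", 99)
        monkeypatch.setattr(mmp_mod, "MAX_SUBSTITUENT_DIFFERENCE", 99)
        relaxed = {(m.cid_low, m.cid_high) for m in build_mmps(cls)}
        assert baseline <= relaxed
        assert len(relaxed) > len(baseline)  # benzyloxy pairs enter


class TestFixtureGoldenList:
    """Exhaustive hand enumeration of the fixture's MMPs.

    Within each scaffold the five small substituents (indices 0-4) pair
    through the scaffold core; the benzyloxy compound (index 5, 8 heavy
    atoms) violates the core >= 2x substituent rule on a 13-atom core
    and can only pair with the methoxy compound (index 2) through the
    larger shared ether core.
    """

    def golden(self):
        pairs = []
        betas = [b for _, b in FIXTURE_SUBSTITUENTS]
        for si, baseline in enumerate(FIXTURE_BASELINES):
            for ri in range(5):
                for rj in range(ri + 1, 5):
                    pairs.append((si, ri, rj, abs(betas[ri] - betas[rj])))
            pairs.append((si, 2, 5, abs(betas[2] - betas[5])))
        golden = set()
        for si, ri, rj, delta in pairs:
            a, b = f"FIX_s{si}r{ri}", f"FIX_s{si}r{rj}"
            betas_pair = (betas[ri], betas[rj])
            lo, hi = (a, b) if betas_pair[0] <= betas_pair[1] else (b, a)
            golden.add((lo, hi, round(delta, 6)))
        return golden

    def test_mmp_list_matches_hand_enumeration(self, fix_mmps):
        observed = {
            (m.cid_low, m.cid_high, round(m.delta, 6)) for m in fix_mmps
        }
        assert observed == self.golden()
        assert len(fix_mmps) == 22

    def test_methoxy_benzyloxy_pair_uses_extended_ether_core(self, fix_mmps):
        pair = [
            m
            for m in fix_mmps
            if {m.cid_low, m.cid_high} == {"FIX_s0r2", "FIX_s0r5"}
        ]
        assert len(pair) == 1
        assert "O" in pair[0].core  # ether linker absorbed into the core
        assert pair[0].core != canonical_smiles("[*]c1ccc2c(c1)oc1ccccc12")
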