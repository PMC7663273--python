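"""Interaction-index integration rules, structure filters, eligibility."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fuzzypcm import (
    AffinityRecord,
    Index,
    LigandStructure,
    Parameter,
    Relation,
    build_dataset,
    compute_interaction_index,
    eligibility_fixpoint,
    filter_structures,
)


def _records(rel_values, parameter=Parameter.KI, protein="p1", ligand="l1"):
    return [
        AffinityRecord(protein, ligand, parameter, rel, val) for rel, val in rel_values
    ]


EQ, LT, GT = Relation.EQ, Relation.LT, Relation.GT


class TestInteractionIndex:
    @pytest.mark.parametrize(
        "rel_values, cutoff_umol, expected",
        [
            # median of fixed values against the cutoff
            ([(EQ, 500), (EQ, 800), (EQ, 2000)], 1.0, Index.INTERACTS),
            ([(EQ, 500), (EQ, 8000), (EQ, 20000)], 1.0, Index.NON_INTERACTS),
            # fixed values win over contradicting intervals
            ([(EQ, 800), (GT, 50000)], 1.0, Index.INTERACTS),
            # lower bounds only: 0 if the maximal edge exceeds the cutoff
            ([(GT, 100), (GT, 1000), (GT, 5000)], 1.0, Index.NON_INTERACTS),
            ([(GT, 100), (GT, 500)], 1.0, Index.EXCLUDED),
            # upper bounds only: 1 if the minimal extreme is below the cutoff
            ([(LT, 100), (LT, 1000), (LT, 5000)], 10.0, Index.INTERACTS),
            ([(LT, 20000), (LT, 50000)], 10.0, Index.EXCLUDED),
            # mixed bounds without fixed values never resolve
            ([(LT, 100), (GT, 5000)], 1.0, Index.EXCLUDED),
            ([(GT, 100), (LT, 5000)], 1.0, Index.EXCLUDED),
            ([(LT, 100), (GT, 100)], 1.0, Index.EXCLUDED),
            # "did not exceed" is inclusive
            ([(EQ, 1000)], 1.0, Index.INTERACTS),
            # even count of fixed values: mean of the central pair
            ([(EQ, 900), (EQ, 1100)], 1.0, Index.INTERACTS),
            ([(EQ, 900), (EQ, 1101)], 1.0, Index.NON_INTERACTS),
        ],
    )
    def test_integration_rules(self, rel_values, cutoff_umol, expected):
        result = compute_interaction_index(_records(rel_values), cutoff_umol)
        assert result.index is expected

    def test_permutation_invariant(self):
        records = _records([(EQ, 500), (GT, 9000), (EQ, 2000), (LT, 10), (EQ, 800)])
        results = {
            compute_interaction_index(list(perm), 1.0).index
            for perm in itertools.permutations(records)
        }
        assert results == {Index.INTERACTS}

    @given(
        st.lists(
            st.tuples(st.sampled_from([EQ, LT, GT]), st.floats(1, 1e6)),
            min_size=1,
            max_size=6,
        )
    )
    def test_tightening_cutoff_never_flips_zero_to_one(self, rel_values):
        """10 -> 1 umol can flip 1 -> 0/EXCLUDED but never 0 -> 1."""
        records = _records(rel_values)
        loose = compute_interaction_index(records, 10.0).index
        tight = compute_interaction_index(records, 1.0).index
        if loose is Index.NON_INTERACTS:
            assert tight is not Index.INTERACTS

    def test_mixed_parameters_rejected(self):
        records = _records([(EQ, 500)]) + _records([(EQ, 700)], parameter=Parameter.IC50)
        with pytest.raises(ValueError, match="share"):
            compute_interaction_index(records, 1.0)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            AffinityRecord("p", "l", Parameter.KI, EQ, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_interaction_index([], 1.0)


def _lig(lig_id, smiles):
    lig = LigandStructure.from_smiles(lig_id, smiles)
    assert lig is not None
    return lig


class TestStructureFilter:
    def test_heavy_molecule_removed(self):
        heavy = _lig("heavy", "C" * 100)  # ~1400 Da alkane
        light = _lig("light", "CCO")
        assert heavy.mol_weight > 1250
        kept = filter_structures([heavy, light])
        assert [l.ligand_id for l in kept] == ["light"]

    def test_mass_threshold_is_strict(self):
        borderline = _lig("edge", "CCO")
        borderline.mol_weight = 1250.0
        over = _lig("over", "CCC")
        over.mol_weight = 1250.0001
        kept = filter_structures([borderline, over])
        assert [l.ligand_id for l in kept] == ["edge"]

    def test_charged_molecule_removed(self):
        quat = _lig("quat", "C[N+](C)(C)C")
        neutral = _lig("ok", "CN(C)C")
        report = {}
        kept = filter_structures([quat, neutral], report=report)
        assert [l.ligand_id for l in kept] == ["ok"]
        assert report["removed_charged"] == 1

    def test_duplicates_merged_with_source_ids(self):
        a = _lig("a", "OCC")  # ethanol, two spellings
        b = _lig("b", "CCO")
        c = _lig("c", "COC")  # same formula, different graph: kept separate
        kept = filter_structures([a, b, c])
        assert [l.ligand_id for l in kept] == ["a", "c"]
        assert kept[0].merged_ids == ("b",)

    def test_output_subset_of_input(self):
        ligs = [_lig(f"l{i}", smi) for i, smi in enumerate(["CCO", "CCN", "c1ccccc1"])]
        kept = filter_structures(ligs)
        assert all(l in ligs for l in kept)


def _brute_force_fixpoint(indices, min_count=3):
    """Independent oracle: union of all eligible (protein, ligand) subsets.

    Eligible subsets are closed under union, so the maximal one is the
    union over every eligible pair of subsets.
    """
    proteins = sorted({p for p, _ in indices})
    ligands = sorted({l for _, l in indices})
    best_p, best_l = set(), set()
    for r in range(len(proteins) + 1):
        for ps in itertools.combinations(proteins, r):
            for s in range(len(ligands) + 1):
                for ls in itertools.combinations(ligands, s):
                    ok = all(
                        sum(
                            indices.get((p, l)) == 1 for l in ls
                        ) >= min_count
                        for p in ps
                    ) and all(
                        sum(indices.get((p, l)) == 1 for p in ps) >= min_count
                        for l in ls
                    )
                    if ok:
                        best_p |= set(ps)
                        best_l |= set(ls)
    return {
        (p, l): v for (p, l), v in indices.items() if p in best_p and l in best_l
    }


class TestEligibilityFixpoint:
    def test_feasible_matrix_unchanged(self):
        indices = {(f"p{i}", f"l{j}"): 1 for i in range(3) for j in range(3)}
        assert eligibility_fixpoint(indices) == indices

    def test_cascading_removal(self):
        # p3 has only 2 positives; removing it leaves l0..l2 intact
        indices = {(f"p{i}", f"l{j}"): 1 for i in range(3) for j in range(3)}
        indices[("p3", "l0")] = 1
        indices[("p3", "l1")] = 1
        result = eligibility_fixpoint(indices)
        assert set(p for p, _ in result) == {"p0", "p1", "p2"}

    def test_empty_map(self):
        assert eligibility_fixpoint({}) == {}

    def test_idempotent(self, small_dataset):
        once = eligibility_fixpoint(small_dataset.indices)
        assert eligibility_fixpoint(once) == once

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            eligibility_fixpoint({("p", "l"): 2})

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_toys(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 6, 2)
        indices = {}
        for i in range(n):
            for j in range(m):
                r = rng.random()
                if r < 0.55:
                    indices[(f"p{i}", f"l{j}")] = 1
                elif r < 0.7:
                    indices[(f"p{i}", f"l{j}")] = 0
        assert eligibility_fixpoint(indices) == _brute_force_fixpoint(indices)


class TestBuildDataset:
    def test_invariants_hold(self, small_dataset):
        small_dataset.validate()

    def test_parameter_filtering(self, small_fixture):
        """Only records of the selected parameter are consulted."""
        mixed = list(small_fixture.records)
        # add junk IC50 records that would flip many pairs if consulted
        for r in small_fixture.records[:50]:
            mixed.append(
                AffinityRecord(r.protein_id, r.ligand_id, Parameter.IC50,
                               Relation.EQ, 5.0)
            )
        structures = [
            LigandStructure.from_smiles(lid, smi)
            for lid, smi in sorted(small_fixture.smiles.items())
        ]
        ds = build_dataset(
            mixed, small_fixture.sequences, structures,
            Parameter.KI, small_fixture.spec.cutoff_umol,
        )
        truth = {
            (p, l): v for p, l, v in small_fixture.truth.itertuples(index=False)
        }
        assert ds.indices == truth
        assert ds.curation_report["records_parameter"] == len(small_fixture.records)

    def test_missing_sequence_names_protein(self, small_fixture):
        sequences = dict(small_fixture.sequences)
        victim = sorted(sequences)[0]
        del sequences[victim]
        structures = [
            LigandStructure.from_smiles(lid, smi)
            for lid, smi in sorted(small_fixture.smiles.items())
        ]
        with pytest.raises(ValueError, match=victim):
            build_dataset(
                small_fixture.records, sequences, structures,
                small_fixture.spec.parameter, small_fixture.spec.cutoff_umol,
            )

    def test_all_excluded_raises_or_empty(self):
        records = [
            AffinityRecord(f"p{i}", f"l{j}", Parameter.KI, Relation.GT, 10.0)
            for i in range(3)
            for j in range(3)
        ]
        structures = [_lig(f"l{j}", "CCO" + "C" * j) for j in range(3)]
        sequences = {f"p{i}": "ACDEFGH" for i in range(3)}
        with pytest.raises(ValueError, match="empty"):
            build_dataset(records, sequences, structures, Parameter.KI, 1.0)
        ds = build_dataset(
            records, sequences, structures, Parameter.KI, 1.0, allow_empty=True
        )
        assert ds.indices == {}
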