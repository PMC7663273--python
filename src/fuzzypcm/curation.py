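"""Curation of raw affinity records into a binary interaction dataset.

Raw bioactivity extracts report IC50/Ki/Kd values measured by different
groups under different conditions: a protein--ligand pair may carry several
fixed values ("= 800 nM"), lower bounds ("> 5000 nM"), upper bounds
("< 100 nM"), or contradictory mixtures.  Curation integrates each pair's
records into a single binary interaction index against a concentration
cutoff, filters ligand structures to the applicability domain of the
descriptor-based classifier (neutral molecules up to 1250 Da, duplicates by
descriptor set + molecular weight merged), and prunes the sparse index
matrix to the eligibility fixpoint in which every protein keeps at least
three established (index-1) ligands and every ligand at least three
established targets.
"""

from __future__ import annotations

import enum
import logging
import math
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors

from .descriptors import mna_descriptors

logger = logging.getLogger(__name__)

__all__ = [
    "Parameter",
    "Relation",
    "Index",
    "AffinityRecord",
    "InteractionIndex",
    "LigandStructure",
    "InteractionDataset",
    "compute_interaction_index",
    "filter_structures",
    "eligibility_fixpoint",
    "build_dataset",
    "NM_PER_UMOL",
    "MAX_LIGAND_MASS_DA",
    "MIN_LIGANDS_PER_PROTEIN",
    "MIN_TARGETS_PER_LIGAND",
]

NM_PER_UMOL = 1000.0
MAX_LIGAND_MASS_DA = 1250.0
MIN_LIGANDS_PER_PROTEIN = 3
MIN_TARGETS_PER_LIGAND = 3


class Parameter(str, enum.Enum):
    """Affinity parameter type of a measurement."""

    IC50 = "IC50"
    KI = "Ki"
    KD = "Kd"


class Relation(str, enum.Enum):
    """Relation of the reported value to the true affinity."""

    EQ = "="
    LT = "<"
    GT = ">"


class Index(enum.Enum):
    """Integrated interaction index of a protein-ligand pair."""

    INTERACTS = 1
    NON_INTERACTS = 0
    EXCLUDED = "excluded"

    def to_int(self) -> int:
        if self is Index.EXCLUDED:
            raise ValueError("EXCLUDED index has no integer value")
        return int(self.value)


@dataclass(frozen=True)
class AffinityRecord:
    """One raw affinity measurement for a protein-ligand pair.

    ``value_nm`` is the concentration in nmol/L; ``relation`` EQ denotes a
    fixed value, LT/GT interval bounds (value is an upper / lower bound on
    the true affinity parameter, respectively).
    """

    protein_id: str
    ligand_id: str
    parameter: Parameter
    relation: Relation
    value_nm: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameter", Parameter(self.parameter))
        object.__setattr__(self, "relation", Relation(self.relation))
        if not math.isfinite(self.value_nm) or self.value_nm <= 0:
            raise ValueError(
                f"affinity value must be finite and positive, got {self.value_nm!r} "
                f"for pair ({self.protein_id}, {self.ligand_id})"
            )


@dataclass(frozen=True)
class InteractionIndex:
    protein_id: str
    ligand_id: str
    parameter: Parameter
    cutoff_umol: float
    index: Index


def compute_interaction_index(
    records: list[AffinityRecord], cutoff_umol: float
) -> InteractionIndex:
    """Integrate one pair's affinity records into a binary interaction index.

    Rules, applied in order:

    1. If any fixed (EQ) value exists, interval records are ignored entirely;
       the index is 1 if the median of the fixed values does not exceed the
       cutoff, 0 otherwise.
    2. With only interval records mixing lower (GT) and upper (LT) bounds the
       pair is EXCLUDED: the bounds either sit in non-intersecting areas
       (e.g. <100 and >5000) or delimit a two-sided range (e.g. >100 and
       <5000), neither of which resolves against a one-sided cutoff.
    3. Only lower bounds (GT): index 0 if the maximal bound exceeds the
       cutoff, else EXCLUDED.
    4. Only upper bounds (LT): index 1 if the minimal bound is below the
       cutoff, else EXCLUDED.

    The result is invariant to the order of ``records``.
    """
    if not records:
        raise ValueError("no affinity records supplied")
    if cutoff_umol <= 0 or not math.isfinite(cutoff_umol):
        raise ValueError(f"cutoff must be positive and finite, got {cutoff_umol}")
    keys = {(r.protein_id, r.ligand_id, r.parameter) for r in records}
    if len(keys) > 1:
        raise ValueError(
            f"records must share protein, ligand and parameter; got {sorted(map(str, keys))}"
        )
    protein_id, ligand_id, parameter = next(iter(keys))
    cutoff_nm = cutoff_umol * NM_PER_UMOL

    eq = [r.value_nm for r in records if r.relation is Relation.EQ]
    lower = [r.value_nm for r in records if r.relation is Relation.GT]
    upper = [r.value_nm for r in records if r.relation is Relation.LT]

    if eq:
        index = Index.INTERACTS if statistics.median(eq) <= cutoff_nm else Index.NON_INTERACTS
    elif lower and upper:
        index = Index.EXCLUDED
    elif lower:
        index = Index.NON_INTERACTS if max(lower) > cutoff_nm else Index.EXCLUDED
    else:
        index = Index.INTERACTS if min(upper) < cutoff_nm else Index.EXCLUDED

    return InteractionIndex(protein_id, ligand_id, parameter, cutoff_umol, index)


@dataclass
class LigandStructure:
    """A curated small-molecule ligand.

    ``merged_ids`` lists source identifiers of duplicate input records that
    were folded into this one (same MNA descriptor set and molecular weight).
    """

    ligand_id: str
    mol: Chem.Mol
    smiles: str
    mol_weight: float
    merged_ids: tuple[str, ...] = ()
    _descriptor_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_smiles(cls, ligand_id: str, smiles: str) -> "LigandStructure | None":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return None
        return cls(
            ligand_id=ligand_id,
            mol=mol,
            smiles=Chem.MolToSmiles(mol),
            mol_weight=RDDescriptors.MolWt(mol),
        )

    def descriptors(self, level: int = 2) -> frozenset[str]:
        if level not in self._descriptor_cache:
            self._descriptor_cache[level] = mna_descriptors(self.mol, level)
        return self._descriptor_cache[level]

    @property
    def has_charged_atom(self) -> bool:
        return any(a.GetFormalCharge() != 0 for a in self.mol.GetAtoms())


def filter_structures(
    ligands: list[LigandStructure],
    *,
    mna_level: int = 2,
    report: dict | None = None,
) -> list[LigandStructure]:
    """Apply the structure filters for the classifier's applicability domain.

    Removes molecules carrying any atom with nonzero formal charge and
    molecules heavier than 1250 Da (strictly greater).  Molecules sharing an
    identical MNA descriptor set *and* identical molecular weight are the
    same compound: the first occurrence is retained and records the merged
    identifiers.  Output order follows input order; no structure is invented.
    """
    if report is None:
        report = {}
    report.setdefault("removed_charged", 0)
    report.setdefault("removed_heavy", 0)
    report.setdefault("merged_duplicates", 0)

    kept: list[LigandStructure] = []
    seen: dict[tuple[frozenset[str], float], int] = {}
    for lig in ligands:
        if lig.has_charged_atom:
            report["removed_charged"] += 1
            logger.info("removing %s: charged atom", lig.ligand_id)
            continue
        if lig.mol_weight > MAX_LIGAND_MASS_DA:
            report["removed_heavy"] += 1
            logger.info("removing %s: mass %.1f Da > %.0f", lig.ligand_id, lig.mol_weight, MAX_LIGAND_MASS_DA)
            continue
        key = (lig.descriptors(mna_level), round(lig.mol_weight, 6))
        if key in seen:
            report["merged_duplicates"] += 1
            first = kept[seen[key]]
            first.merged_ids = first.merged_ids + (lig.ligand_id,)
            logger.info("merging %s into %s: identical descriptor set and weight", lig.ligand_id, first.ligand_id)
            continue
        seen[key] = len(kept)
        kept.append(lig)
    return kept


def eligibility_fixpoint(
    indices: dict[tuple[str, str], int],
    *,
    min_ligands: int = MIN_LIGANDS_PER_PROTEIN,
    min_targets: int = MIN_TARGETS_PER_LIGAND,
) -> dict[tuple[str, str], int]:
    """Prune the index map to its unique maximal eligible sub-matrix.

    Iteratively removes proteins with fewer than ``min_ligands`` established
    (index-1) ligands and ligands with fewer than ``min_targets`` established
    targets — removal deletes all of the entity's entries, including its
    0-entries — until stable.  Eligible sub-matrices are closed under union,
    so the fixpoint is the unique maximal one and independent of removal
    order.  The result may be empty.
    """
    bad = {v for v in indices.values() if v not in (0, 1)}
    if bad:
        raise ValueError(f"index map must contain only 0/1 entries, got {sorted(bad)}")
    idx = dict(indices)
    while True:
        pos_prot: Counter = Counter()
        pos_lig: Counter = Counter()
        proteins = set()
        ligs = set()
        for (p, l), v in idx.items():
            proteins.add(p)
            ligs.add(l)
            if v == 1:
                pos_prot[p] += 1
                pos_lig[l] += 1
        drop_p = {p for p in proteins if pos_prot[p] < min_ligands}
        drop_l = {l for l in ligs if pos_lig[l] < min_targets}
        if not drop_p and not drop_l:
            return idx
        idx = {
            (p, l): v
            for (p, l), v in idx.items()
            if p not in drop_p and l not in drop_l
        }


@dataclass
class InteractionDataset:
    """Curated sparse protein x ligand binary interaction dataset."""

    proteins: dict[str, str]
    ligands: dict[str, LigandStructure]
    indices: dict[tuple[str, str], int]
    parameter: Parameter
    cutoff_umol: float
    curation_report: dict = field(default_factory=dict)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    def indexed_ligands(self, protein_id: str) -> list[tuple[str, int]]:
        """(ligand_id, index) pairs measured on one protein, sorted by id."""
        return sorted(
            (l, v) for (p, l), v in self.indices.items() if p == protein_id
        )

    def indexed_targets(self, ligand_id: str) -> list[tuple[str, int]]:
        return sorted(
            (p, v) for (p, l), v in self.indices.items() if l == ligand_id
        )

    def positive_ligands(self, protein_id: str) -> list[str]:
        return [l for l, v in self.indexed_ligands(protein_id) if v == 1]

    def positive_targets(self, ligand_id: str) -> list[str]:
        return [p for p, v in self.indexed_targets(ligand_id) if v == 1]

    def validate(self) -> None:
        for p, l in self.indices:
            if p not in self.proteins:
                raise ValueError(f"index references unknown protein {p!r}")
            if l not in self.ligands:
                raise ValueError(f"index references unknown ligand {l!r}")
        for p in self.proteins:
            n = len(self.positive_ligands(p))
            if n < MIN_LIGANDS_PER_PROTEIN:
                raise ValueError(f"protein {p!r} has only {n} established ligands")
        for l in self.ligands:
            n = len(self.positive_targets(l))
            if n < MIN_TARGETS_PER_LIGAND:
                raise ValueError(f"ligand {l!r} has only {n} established targets")


def build_dataset(
    records: list[AffinityRecord],
    sequences: dict[str, str],
    structures: list[LigandStructure],
    parameter: Parameter | str,
    cutoff_umol: float,
    *,
    mna_level: int = 2,
    allow_empty: bool = False,
) -> InteractionDataset:
    """Compose curation: structure filters, index integration, eligibility.

    Only records of the chosen ``parameter`` are consulted.  Records of
    ligands merged as duplicates are pooled onto the retained identifier;
    records of filtered-out ligands are dropped.  EXCLUDED pairs are absent
    from the final index map.  A surviving protein without a sequence is an
    error naming the identifier.
    """
    parameter = Parameter(parameter)
    report: dict = {"parameter": parameter.value, "cutoff_umol": cutoff_umol}

    kept = filter_structures(structures, mna_level=mna_level, report=report)
    alias: dict[str, str] = {}
    for lig in kept:
        alias[lig.ligand_id] = lig.ligand_id
        for merged in lig.merged_ids:
            alias[merged] = lig.ligand_id
    ligand_map = {lig.ligand_id: lig for lig in kept}

    report["records_total"] = len(records)
    selected = [r for r in records if r.parameter is parameter]
    report["records_parameter"] = len(selected)

    by_pair: dict[tuple[str, str], list[AffinityRecord]] = defaultdict(list)
    dropped_ligand_records = 0
    for r in selected:
        lig_id = alias.get(r.ligand_id)
        if lig_id is None:
            dropped_ligand_records += 1
            continue
        by_pair[(r.protein_id, lig_id)].append(r)
    report["records_dropped_filtered_ligand"] = dropped_ligand_records

    raw_indices: dict[tuple[str, str], int] = {}
    excluded = 0
    for (p, l), pair_records in by_pair.items():
        # merged duplicates may pool records; relation/value integration is
        # per mapped pair, so re-key the records onto the retained ligand id
        rekeyed = [
            AffinityRecord(p, l, r.parameter, r.relation, r.value_nm)
            for r in pair_records
        ]
        result = compute_interaction_index(rekeyed, cutoff_umol)
        if result.index is Index.EXCLUDED:
            excluded += 1
        else:
            raw_indices[(p, l)] = result.index.to_int()
    report["pairs_indexed"] = len(raw_indices)
    report["pairs_excluded"] = excluded

    final = eligibility_fixpoint(raw_indices)
    report["pairs_after_eligibility"] = len(final)

    surviving_proteins = sorted({p for p, _ in final})
    surviving_ligands = sorted({l for _, l in final})
    missing = [p for p in surviving_proteins if p not in sequences]
    if missing:
        raise ValueError(f"sequence missing for surviving protein(s): {missing}")

    dataset = InteractionDataset(
        proteins={p: sequences[p] for p in surviving_proteins},
        ligands={l: ligand_map[l] for l in surviving_ligands},
        indices=final,
        parameter=parameter,
        cutoff_umol=cutoff_umol,
        curation_report=report,
    )
    report["n_proteins"] = dataset.n_proteins
    report["n_ligands"] = dataset.n_ligands
    if not final and not allow_empty:
        raise ValueError(
            "curation produced an empty dataset (every pair excluded or ineligible)"
        )
    return dataset
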