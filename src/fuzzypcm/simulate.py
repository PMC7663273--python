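"""Synthetic protein-ligand benchmark generator with known ground truth.

Emulates the shape of a curated bioactivity extract at desk scale: a sparse
protein x ligand affinity table with a planted, recoverable signal.
Proteins and ligands are partitioned into classes; class-matched pairs bind
(affinity below the cutoff) and mismatched pairs do not.  Each protein is a
point-mutated copy of a class-specific template carrying a protected class
motif, so sequence similarity tracks ligand-class specificity; each ligand
is a class-specific heterocyclic core decorated with random aliphatic
fragments, so MNA descriptors track the same classes from the chemistry
side.

Affinity values are fixed (EQ) measurements with bounded log-scale
replicate jitter; a configurable share of pairs is converted to interval
records that bracket the fixed value (upper bounds at twice the value for
interactors, lower bounds at half the value for non-interactors) so the
interval-integration rules get nontrivial work without ever changing the
intended index.  An optional noise rate flips the binding regime of a pair
(the truth table records the flipped index).  All randomness flows from a
single seeded generator; the same spec yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .curation import AffinityRecord, Parameter, Relation, NM_PER_UMOL

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "write_fixture", "CLASS_CORES"]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: class-defining heterocyclic cores (distinct MNA environments)
CLASS_CORES = (
    "c1ccncc1",      # pyridine
    "C1CCNCC1",      # piperidine
    "C1CCOC1",       # tetrahydrofuran
    "c1ccsc1",       # thiophene
    "C1COCCN1",      # morpholine
    "c1ccc2ccccc2c1",  # naphthalene
    "C1CCC(CC1)S",   # cyclohexanethiol
    "C1CNCCN1",      # piperazine
)

#: neutral aliphatic decorations, safe to concatenate onto any SMILES tail
DECORATIONS = ("C", "CC", "CCC", "CO", "CCO", "CN", "CCN", "C(C)C", "COC", "CC(C)O")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of a synthetic benchmark.

    Defaults give five ligand classes over 40 proteins x 120 ligands with
    300-residue sequences — large enough that curation eligibility
    (>= 3 established ligands per protein and targets per ligand) holds by
    construction, small enough for desk-scale evaluation.
    """

    n_proteins: int = 40
    n_ligands: int = 120
    n_classes: int = 5
    seq_len: int = 300
    motif_len: int = 15
    motif_rate: float = 1.0
    mutation_rate: float = 0.1
    interval_fraction: float = 0.2
    noise_rate: float = 0.0
    n_neg_per_ligand: int = 8
    parameter: Parameter = Parameter.KI
    cutoff_umol: float = 1.0
    seed: int = 1

    def validate(self) -> None:
        rates = {
            "motif_rate": self.motif_rate,
            "mutation_rate": self.mutation_rate,
            "interval_fraction": self.interval_fraction,
            "noise_rate": self.noise_rate,
        }
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {r}")
        if self.n_classes < 1 or self.n_classes > len(CLASS_CORES):
            raise ValueError(
                f"n_classes must be in [1, {len(CLASS_CORES)}], got {self.n_classes}"
            )
        if self.n_proteins < 3 * self.n_classes:
            raise ValueError(
                f"need >= 3 proteins per class: {self.n_proteins} proteins, "
                f"{self.n_classes} classes"
            )
        if self.n_ligands < 3 * self.n_classes:
            raise ValueError(
                f"need >= 3 ligands per class: {self.n_ligands} ligands, "
                f"{self.n_classes} classes"
            )
        if self.motif_len > self.seq_len:
            raise ValueError("motif_len exceeds seq_len")
        if self.n_neg_per_ligand > self.n_proteins - self.n_proteins // self.n_classes:
            raise ValueError("n_neg_per_ligand exceeds the off-class protein pool")
        if self.cutoff_umol <= 0:
            raise ValueError("cutoff_umol must be positive")


@dataclass
class Fixture:
    """Generated benchmark: raw inputs plus the generating truth."""

    spec: FixtureSpec
    sequences: dict[str, str]
    smiles: dict[str, str]
    records: list[AffinityRecord]
    truth: pd.DataFrame  # protein_id, ligand_id, true_index
    protein_classes: dict[str, int] = field(default_factory=dict)
    ligand_classes: dict[str, int] = field(default_factory=dict)


def _make_proteins(spec: FixtureSpec, rng: np.random.Generator):
    templates = [
        "".join(rng.choice(AMINO_ACIDS, spec.seq_len)) for _ in range(spec.n_classes)
    ]
    motif_starts = [
        int(rng.integers(0, spec.seq_len - spec.motif_len + 1))
        for _ in range(spec.n_classes)
    ]
    sequences: dict[str, str] = {}
    classes: dict[str, int] = {}
    for i in range(spec.n_proteins):
        cls = i % spec.n_classes
        template = templates[cls]
        seq = np.array(list(template))
        mutate = rng.random(spec.seq_len) < spec.mutation_rate
        seq[mutate] = rng.choice(AMINO_ACIDS, int(mutate.sum()))
        if rng.random() < spec.motif_rate:
            start = motif_starts[cls]
            seq[start : start + spec.motif_len] = list(
                template[start : start + spec.motif_len]
            )
        pid = f"prot{i:03d}"
        sequences[pid] = "".join(seq)
        classes[pid] = cls
    return sequences, classes


def _make_ligands(spec: FixtureSpec, rng: np.random.Generator):
    smiles: dict[str, str] = {}
    classes: dict[str, int] = {}
    seen: set[str] = set()
    for i in range(spec.n_ligands):
        cls = i % spec.n_classes
        core = CLASS_CORES[cls]
        for attempt in range(100):
            n_dec = int(rng.integers(1, 5))
            decs = rng.choice(DECORATIONS, n_dec)
            smi = core + "".join(decs) + "C" * attempt
            canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
            if canonical not in seen:
                break
        else:  # pragma: no cover - vocabulary is ample for supported sizes
            raise RuntimeError("could not generate a unique ligand structure")
        seen.add(canonical)
        lid = f"lig{i:03d}"
        smiles[lid] = smi
        classes[lid] = cls
    return smiles, classes


def _pair_records(
    spec: FixtureSpec,
    rng: np.random.Generator,
    protein_id: str,
    ligand_id: str,
    interacts: bool,
) -> list[AffinityRecord]:
    cutoff_nm = spec.cutoff_umol * NM_PER_UMOL
    if interacts:
        lo, hi = np.log10(10.0), np.log10(0.3 * cutoff_nm)
    else:
        lo, hi = np.log10(3.0 * cutoff_nm), np.log10(300.0 * cutoff_nm)
    base = 10.0 ** rng.uniform(lo, hi)
    n_rep = int(rng.integers(1, 3))
    values = [base * 10.0 ** rng.uniform(-0.1, 0.1) for _ in range(n_rep)]

    as_interval = rng.random() < spec.interval_fraction
    records = []
    for v in values:
        if as_interval and interacts:
            # upper bound at twice the value: still below the cutoff, so the
            # minimal-extreme rule recovers index 1
            rel, val = Relation.LT, 2.0 * v
        elif as_interval:
            # lower bound at half the value: still above the cutoff, so the
            # maximal-edge rule recovers index 0
            rel, val = Relation.GT, 0.5 * v
        else:
            rel, val = Relation.EQ, v
        records.append(
            AffinityRecord(protein_id, ligand_id, spec.parameter, rel, float(val))
        )
    return records


def generate_fixture(spec: FixtureSpec | None = None, **overrides) -> Fixture:
    """Generate a complete synthetic benchmark from a spec.

    Each ligand gets affinity records against every protein of its class
    (binders) and a seeded sample of off-class proteins (non-binders).
    """
    if spec is None:
        spec = FixtureSpec(**overrides)
    elif overrides:
        raise TypeError("pass either a FixtureSpec or keyword overrides, not both")
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    sequences, protein_classes = _make_proteins(spec, rng)
    smiles, ligand_classes = _make_ligands(spec, rng)

    by_class: dict[int, list[str]] = {}
    for pid, cls in protein_classes.items():
        by_class.setdefault(cls, []).append(pid)

    records: list[AffinityRecord] = []
    truth_rows = []
    all_proteins = sorted(sequences)
    for lid in sorted(smiles):
        cls = ligand_classes[lid]
        partners = list(by_class[cls])
        off_class = [p for p in all_proteins if protein_classes[p] != cls]
        partners += list(rng.choice(off_class, spec.n_neg_per_ligand, replace=False))
        for pid in partners:
            matched = protein_classes[pid] == cls
            interacts = matched != (rng.random() < spec.noise_rate)
            records.extend(_pair_records(spec, rng, pid, lid, interacts))
            truth_rows.append((pid, lid, int(interacts)))

    truth = pd.DataFrame(truth_rows, columns=["protein_id", "ligand_id", "true_index"])
    return Fixture(
        spec=spec,
        sequences=sequences,
        smiles=smiles,
        records=records,
        truth=truth,
        protein_classes=protein_classes,
        ligand_classes=ligand_classes,
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> None:
    """Write the standard input trio (affinities.tsv, proteins.fasta,
    ligands.smi) plus truth.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "proteins.fasta", "w") as fh:
        for pid in sorted(fixture.sequences):
            fh.write(f">{pid}\n{fixture.sequences[pid]}\n")
    with open(outdir / "ligands.smi", "w") as fh:
        for lid in sorted(fixture.smiles):
            fh.write(f"{fixture.smiles[lid]} {lid}\n")
    table = pd.DataFrame(
        [
            (r.protein_id, r.ligand_id, r.parameter.value, r.relation.value, r.value_nm)
            for r in fixture.records
        ],
        columns=["protein_id", "ligand_id", "parameter", "relation", "value_nM"],
    )
    table.to_csv(outdir / "affinities.tsv", sep="\t", index=False, float_format="%.6g")
    fixture.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
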