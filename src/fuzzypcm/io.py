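"""Readers and writers for the standard input/output formats.

Inputs: FASTA protein sequences (Biopython), SMILES tables (``.smi`` with
``SMILES id`` lines or CSV with a header), and delimited affinity tables
with columns ``protein_id, ligand_id, parameter, relation, value_nM``.
Outputs are TSV (SMILES can contain commas in principle, and tabs never
appear in any of our fields) and JSON reports; all text is UTF-8.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .curation import (
    AffinityRecord,
    InteractionDataset,
    LigandStructure,
    Parameter,
)
from .evaluation import ROCResult
from .model import PredictionResult

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "read_smiles_table",
    "read_affinity_table",
    "write_dataset",
    "load_dataset",
    "write_predictions",
    "write_report",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences; uppercased, duplicate identifiers rejected."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate FASTA identifier {record.id!r} in {path}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return sequences


def read_smiles_table(path: str | Path) -> dict[str, LigandStructure]:
    """Read ligand structures from ``.smi`` (``SMILES id`` per line) or a
    CSV/TSV with ``ligand_id`` and ``smiles`` columns.

    Unparseable structures are skipped with a warning; zero parseable
    records is an error.
    """
    path = Path(path)
    entries: list[tuple[str, str]] = []
    if path.suffix.lower() in (".csv", ".tsv"):
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
        table = pd.read_csv(path, sep=sep, dtype=str)
        missing = {"ligand_id", "smiles"} - set(table.columns)
        if missing:
            raise ValueError(f"{path} lacks required column(s) {sorted(missing)}")
        entries = list(zip(table["ligand_id"], table["smiles"]))
    else:
        with open(path) as fh:
            for line_no, line in enumerate(fh, 1):
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 2:
                    raise ValueError(
                        f"{path}:{line_no}: expected 'SMILES id', got {line.strip()!r}"
                    )
                entries.append((parts[1], parts[0]))

    ligands: dict[str, LigandStructure] = {}
    for lig_id, smi in entries:
        if lig_id in ligands:
            raise ValueError(f"duplicate ligand identifier {lig_id!r} in {path}")
        structure = LigandStructure.from_smiles(lig_id, smi)
        if structure is None:
            logger.warning("skipping %s: unparseable SMILES %r", lig_id, smi)
            continue
        ligands[lig_id] = structure
    if not ligands:
        raise ValueError(f"no parseable ligand structures in {path}")
    return ligands


def read_affinity_table(path: str | Path) -> list[AffinityRecord]:
    """Read raw affinity records from a CSV/TSV with header
    ``protein_id, ligand_id, parameter, relation, value_nM``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    required = {"protein_id", "ligand_id", "parameter", "relation", "value_nM"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path} lacks required column(s) {sorted(missing)}")
    return [
        AffinityRecord(
            protein_id=str(row.protein_id),
            ligand_id=str(row.ligand_id),
            parameter=Parameter(row.parameter),
            relation=row.relation,
            value_nm=float(row.value_nM),
        )
        for row in table.itertuples()
    ]


def write_dataset(dataset: InteractionDataset, outdir: str | Path) -> None:
    """Write a curated dataset directory: proteins.fasta, ligands.smi,
    interactions.tsv and a JSON curation report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "proteins.fasta", "w") as fh:
        for pid in sorted(dataset.proteins):
            fh.write(f">{pid}\n{dataset.proteins[pid]}\n")
    with open(outdir / "ligands.smi", "w") as fh:
        for lid in sorted(dataset.ligands):
            fh.write(f"{dataset.ligands[lid].smiles} {lid}\n")
    rows = [(p, l, v) for (p, l), v in sorted(dataset.indices.items())]
    pd.DataFrame(rows, columns=["protein_id", "ligand_id", "index"]).to_csv(
        outdir / "interactions.tsv", sep="\t", index=False
    )
    meta = {
        "parameter": dataset.parameter.value,
        "cutoff_umol": dataset.cutoff_umol,
        "version": __version__,
        "curation": dataset.curation_report,
    }
    (outdir / "dataset.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_dataset(indir: str | Path) -> InteractionDataset:
    """Load a curated dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    meta = json.loads((indir / "dataset.json").read_text())
    sequences = read_fasta(indir / "proteins.fasta")
    ligands = read_smiles_table(indir / "ligands.smi")
    table = pd.read_csv(indir / "interactions.tsv", sep="\t")
    indices = {
        (str(p), str(l)): int(v)
        for p, l, v in zip(table["protein_id"], table["ligand_id"], table["index"])
    }
    dataset = InteractionDataset(
        proteins=sequences,
        ligands=ligands,
        indices=indices,
        parameter=Parameter(meta["parameter"]),
        cutoff_umol=float(meta["cutoff_umol"]),
        curation_report=meta.get("curation", {}),
    )
    dataset.validate()
    return dataset


def write_predictions(results: list[PredictionResult], path: str | Path) -> None:
    """Write prediction results as TSV with 5-decimal floats."""
    if not results:
        raise ValueError("no prediction results to write")
    rows = [
        (r.protein_id, r.ligand_id, f"{r.t:.5f}", f"{r.t0:.5f}", f"{r.b:.5f}")
        for r in results
    ]
    pd.DataFrame(rows, columns=["protein_id", "ligand_id", "t", "t0", "B"]).to_csv(
        path, sep="\t", index=False
    )


def write_report(
    result: ROCResult,
    path: str | Path,
    *,
    config: dict | None = None,
    scores_path: str | Path | None = None,
) -> None:
    """Write a JSON evaluation report; optionally dump the full score table."""
    report = {
        "auc": result.auc,
        "n_pos": result.n_pos,
        "n_neg": result.n_neg,
        "n_pairs": result.n_pairs,
        "config": config or {},
        "version": __version__,
    }
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
    if scores_path is not None:
        result.scores.to_csv(scores_path, sep="\t", index=False, float_format="%.5f")
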