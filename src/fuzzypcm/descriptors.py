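"""Multilevel neighborhoods of atoms (MNA) structural descriptors.

An MNA descriptor encodes an atom together with its recursively enumerated
neighborhood up to a fixed level.  The level-0 descriptor of an atom is its
element symbol annotated with the number of attached hydrogens (and formal
charge, should one survive curation); the level-k descriptor prepends the
atom's own label to the lexicographically sorted multiset of its heavy-atom
neighbors' level-(k-1) descriptors.  The union of descriptors over all atoms
and all levels 0..L fingerprints the molecule: two molecules with the same
heavy-atom graph produce identical sets regardless of atom numbering.

Hydrogens are counted implicitly inside atom labels rather than walked as
graph nodes, so symmetric hydrogens never inflate the set.
"""

from __future__ import annotations

from rdkit import Chem

__all__ = ["mna_descriptors", "atom_label"]


def atom_label(atom: Chem.Atom) -> str:
    """Level-0 label: element symbol, hydrogen count, formal charge."""
    label = atom.GetSymbol()
    n_h = atom.GetTotalNumHs()
    if n_h:
        label += f"H{n_h}"
    charge = atom.GetFormalCharge()
    if charge > 0:
        label += "+" * charge
    elif charge < 0:
        label += "-" * (-charge)
    return label


def mna_descriptors(mol: Chem.Mol, level: int = 2) -> frozenset[str]:
    """Compute the MNA descriptor set of a molecule.

    Parameters
    ----------
    mol : rdkit.Chem.Mol
        Molecule with implicit hydrogens (as produced by ``MolFromSmiles``).
    level : int
        Maximum neighborhood depth; levels ``0..level`` all contribute.

    Returns
    -------
    frozenset of str
        Canonical descriptor strings, invariant under atom renumbering.
    """
    if level < 0:
        raise ValueError(f"MNA level must be >= 0, got {level}")
    if mol is None:
        raise ValueError("molecule is None (failed to parse?)")

    base = {atom.GetIdx(): atom_label(atom) for atom in mol.GetAtoms()}
    neighbors = {
        atom.GetIdx(): [nbr.GetIdx() for nbr in atom.GetNeighbors()]
        for atom in mol.GetAtoms()
    }

    descriptors: set[str] = set(base.values())
    previous = dict(base)
    for _ in range(level):
        current = {
            idx: base[idx] + "(" + ",".join(sorted(previous[j] for j in neighbors[idx])) + ")"
            for idx in base
        }
        descriptors.update(current.values())
        previous = current
    return frozenset(descriptors)
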