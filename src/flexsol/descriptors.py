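"""Kier kappa shape indices and the molecular flexibility index Phi.

Phi = kappa1 * kappa2 / NHA, where NHA is the heavy-atom count and the
kappa indices are computed from simple-path counts on the
hydrogen-suppressed skeleton::

    kappa1 = A * (A - 1)**2 / P1**2
    kappa2 = (A - 1) * (A - 2)**2 / P2**2

with A the heavy-atom count, P1 the bond count and P2 the number of
two-edge simple paths.  Bond orders and aromaticity do not enter the path
counts.  In the alpha-modified variant A is replaced by ``A + alpha``
(and each path count by ``P + alpha``), where alpha is the Hall-Kier
covalent-radius/hybridisation correction with sp3 carbon as the zero
reference; alpha is taken from RDKit.

Phi requires at least three heavy atoms (kappa2 is undefined below that);
smaller molecules get ``phi = nan`` and downstream model selection routes
them to the classic GSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdMolDescriptors

from .errors import InputError

RDLogger.DisableLog("rdApp.error")


@dataclass(frozen=True)
class MolecularGraph:
    """Hydrogen-suppressed molecular skeleton.

    ``nodes`` holds (element symbol, formal charge) per heavy atom; ``edges``
    holds unordered index pairs.  ``alpha`` is the summed Hall-Kier alpha
    correction for the molecule (0.0 when built from a bare graph).
    """

    nodes: tuple[tuple[str, int], ...]
    edges: frozenset[frozenset[int]]
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise InputError("molecular graph needs at least one atom")
        for e in self.edges:
            if len(e) != 2:
                raise InputError(f"self-loop or malformed edge: {set(e)}")
            if any(i < 0 or i >= len(self.nodes) for i in e):
                raise InputError(f"edge index out of range: {set(e)}")

    @property
    def n_heavy(self) -> int:
        return len(self.nodes)

    @property
    def degrees(self) -> list[int]:
        deg = [0] * len(self.nodes)
        for e in self.edges:
            for i in e:
                deg[i] += 1
        return deg


@dataclass(frozen=True)
class KappaIndices:
    """First/second-order kappa shape indices and the flexibility index."""

    kappa1: float
    kappa2: float
    nha: int
    phi: float


def _mol_from_smiles(smiles: str, record_id: str | None = None) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        label = f" (record {record_id})" if record_id else ""
        raise InputError(f"unparsable SMILES {smiles!r}{label}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) > 1:
        # salts / solvates: intrinsic solubility refers to the parent compound
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return mol


def parse_structure(smiles: str, record_id: str | None = None) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed skeleton graph.

    Multi-fragment inputs (salts) are reduced to the largest fragment.
    Raises :class:`InputError` on unparsable SMILES, naming ``record_id``
    when given.
    """
    mol = _mol_from_smiles(smiles, record_id)
    nodes = tuple(
        (a.GetSymbol(), a.GetFormalCharge()) for a in mol.GetAtoms()
    )
    edges = frozenset(
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in mol.GetBonds()
    )
    return MolecularGraph(
        nodes=nodes, edges=edges, alpha=rdMolDescriptors.CalcHallKierAlpha(mol)
    )


def count_paths(g: MolecularGraph, length: int) -> int:
    """Count simple paths of 1 or 2 edges in the skeleton.

    Length 1 is the bond count; length 2 counts unordered endpoint pairs
    joined through a middle atom, i.e. sum over atoms of deg*(deg-1)/2.
    """
    if length == 1:
        return len(g.edges)
    if length == 2:
        return sum(d * (d - 1) // 2 for d in g.degrees)
    raise ValueError(f"path length must be 1 or 2, got {length!r}")


def kappa_indices(g: MolecularGraph, alpha_modified: bool = True) -> KappaIndices:
    """Compute kappa1, kappa2 and Phi for a skeleton graph.

    With ``alpha_modified`` the atom and path counts are shifted by the
    molecule's Hall-Kier alpha.  kappa2 (and hence Phi) is ``nan`` for
    fewer than three heavy atoms or a vanishing two-path count.
    """
    nha = g.n_heavy
    alpha = g.alpha if alpha_modified else 0.0
    a = nha + alpha
    p1 = count_paths(g, 1) + alpha
    p2 = count_paths(g, 2) + alpha

    kappa1 = a * (a - 1.0) ** 2 / p1**2 if p1 > 0 else math.nan
    if nha >= 3 and p2 > 0:
        kappa2 = (a - 1.0) * (a - 2.0) ** 2 / p2**2
    else:
        kappa2 = math.nan
    phi = kappa1 * kappa2 / nha
    return KappaIndices(kappa1=kappa1, kappa2=kappa2, nha=nha, phi=phi)


def flexibility_index(
    smiles: str, alpha_modified: bool = True, record_id: str | None = None
) -> float:
    """Kier flexibility index Phi of a molecule given as SMILES.

    Returns ``nan`` for molecules with fewer than three heavy atoms.
    """
    return kappa_indices(parse_structure(smiles, record_id), alpha_modified).phi


def heavy_atom_count(smiles: str, record_id: str | None = None) -> int:
    """Number of heavy (non-hydrogen) atoms in the largest fragment."""
    return _mol_from_smiles(smiles, record_id).GetNumHeavyAtoms()


def molecular_weight(smiles: str, record_id: str | None = None) -> float:
    """Average molecular weight (Da) of the largest fragment."""
    return Descriptors.MolWt(_mol_from_smiles(smiles, record_id))
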