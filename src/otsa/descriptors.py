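"""Atom-level pharmacophore typing and 2-D descriptor families.

Six recognition elements are assigned per heavy atom: hydrogen-bond donor (D),
acceptor (A), hydrophobe (H), aromatic (R), positively ionizable (P) and
negatively ionizable (N).  An atom may carry several labels.  On top of the
typing sit three descriptor families used by the similarity method:

* PHRAG — a multiset of linear pharmacophore fragments: the feature-label
  sequences read along all shortest paths of 2..7 atoms, compared by a
  multiset Tanimoto coefficient.
* FPD — feature-pair distribution: counts of unordered feature pairs by
  topological distance (capped at L bonds), normalized to frequencies.
* SHED — one Shannon entropy (nats) per feature pair, over that pair's
  topological-distance distribution; vectors compared by Euclidean distance.

A hashed circular (Morgan) fingerprint with plain bit-Tanimoto similarity
serves the set-wise and cross-pharmacology methods.

All descriptors are functions of the stereo-stripped canonical graph, so
enantiomers are indistinguishable by construction.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement

import networkx as nx
import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chemdata import Molecule, as_rdkit

FEATURES = ("A", "D", "H", "N", "P", "R")
FOUR_FEATURES = ("A", "D", "H", "R")

#: 21 unordered feature pairs (10 in the four-feature variant)
PAIRS = tuple(combinations_with_replacement(FEATURES, 2))
PAIR_INDEX = {p: i for i, p in enumerate(PAIRS)}

# Pattern table for feature typing.  The hydrophobe rule admits carbons with at
# most one heteroatom neighbour, so a carbinol carbon is still a hydrophobe but
# carboxyl/amide/nitro carbons are not.
_DONOR = [Chem.MolFromSmarts(s) for s in ("[#7;!H0]", "[#8;H1;+0]")]
_ACCEPTOR = [
    Chem.MolFromSmarts(s)
    for s in (
        "[#8;+0]",                                     # any neutral oxygen
        "[nX2;+0]",                                    # pyridine-type aromatic N
        "[NX3;+0;!$([NX3][CX3]=[OX1])]",               # amine N, amides excluded
        "[NX2;+0;!$([NX2]=O)]",                        # imine-type N, nitroso excluded
        "[NX1;+0]",                                    # nitrile N
    )
]
_POS = [
    Chem.MolFromSmarts(s)
    for s in (
        # aliphatic amine: not amide, not aniline-conjugated, no heteroatom neighbour
        "[NX3;+0;!$([NX3][CX3]=[OX1]);!$([NX3][a]);!$([NX3][#7,#8,#16]);!$([NX3]=*)]",
        "[NX4;+1]",
        "[NX3;$([NX3][CX3]=[NX2])]",                   # amidine/guanidine N
    )
]
_NEG = [
    Chem.MolFromSmarts(s)
    for s in (
        "[CX3](=[OX1])[OX2H1]",                        # carboxylic acid
        "[SX4](=[OX1])(=[OX1])[OX2H1]",                # sulfonic acid
        "[PX4](=[OX1])[OX2H1]",                        # phosphonic acid
    )
]


def _match_atoms(mol: Chem.Mol, patterns: list[Chem.Mol], oxygens_only: bool = False) -> set[int]:
    hits: set[int] = set()
    for patt in patterns:
        for match in mol.GetSubstructMatches(patt):
            for idx in match:
                if not oxygens_only or mol.GetAtomWithIdx(idx).GetAtomicNum() == 8:
                    hits.add(idx)
    return hits


def assign_features(mol: Molecule | str, four_feature_variant: bool = False) -> tuple[frozenset, ...]:
    """Per-atom feature label sets, deterministic for a canonical molecule."""
    smiles = mol.smiles_canonical if isinstance(mol, Molecule) else mol
    m = as_rdkit(smiles)
    donors = _match_atoms(m, _DONOR)
    acceptors = _match_atoms(m, _ACCEPTOR)
    pos = _match_atoms(m, _POS)
    neg = _match_atoms(m, _NEG, oxygens_only=True)
    labels: list[frozenset] = []
    for atom in m.GetAtoms():
        idx = atom.GetIdx()
        tags = set()
        if idx in donors:
            tags.add("D")
        if idx in acceptors:
            tags.add("A")
        if atom.GetIsAromatic():
            tags.add("R")
        if atom.GetAtomicNum() == 6:
            hetero_nbrs = sum(
                1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() not in (1, 6)
            )
            if hetero_nbrs < 2:
                tags.add("H")
        if not four_feature_variant:
            if idx in pos:
                tags.add("P")
            if idx in neg:
                tags.add("N")
        labels.append(frozenset(tags))
    return tuple(labels)


def _pair_distance_counts(mol: Molecule | str, L: int = 10,
                          four_feature_variant: bool = False) -> np.ndarray:
    """Raw (pair, distance-bin) counts over all labelled atom pairs i<j."""
    smiles = mol.smiles_canonical if isinstance(mol, Molecule) else mol
    m = as_rdkit(smiles)
    labels = assign_features(smiles, four_feature_variant)
    dmat = Chem.GetDistanceMatrix(m)
    counts = np.zeros((len(PAIRS), L), dtype=float)
    n = m.GetNumAtoms()
    for i in range(n):
        if not labels[i]:
            continue
        for j in range(i + 1, n):
            if not labels[j]:
                continue
            d = dmat[i, j]
            if not np.isfinite(d) or d > 1e6 or d < 1:
                continue  # disconnected fragments carry no pair signal
            b = min(int(d), L) - 1
            for f in labels[i]:
                for g in labels[j]:
                    counts[PAIR_INDEX[tuple(sorted((f, g)))], b] += 1
    return counts


@dataclass
class FPDVector:
    frequencies: np.ndarray  # shape (21, L)
    featureless: bool
    L: int

    def flatten(self) -> np.ndarray:
        return self.frequencies.ravel()


def compute_fpd(mol: Molecule | str, L: int = 10, four_feature_variant: bool = False) -> FPDVector:
    """Feature-pair distribution, normalized to frequencies (sums to 1)."""
    counts = _pair_distance_counts(mol, L, four_feature_variant)
    total = counts.sum()
    if total == 0:
        return FPDVector(counts, featureless=True, L=L)
    return FPDVector(counts / total, featureless=False, L=L)


def compute_shed(mol: Molecule | str, L: int = 10, four_feature_variant: bool = False) -> np.ndarray:
    """Shannon entropy (nats) per feature pair; empty distributions give 0."""
    counts = _pair_distance_counts(mol, L, four_feature_variant)
    ent = np.zeros(len(PAIRS))
    for p in range(len(PAIRS)):
        row = counts[p]
        tot = row.sum()
        if tot == 0:
            continue
        q = row[row > 0] / tot
        ent[p] = float(-(q * np.log(q)).sum())
    return ent


def shed_distance(a: np.ndarray, b: np.ndarray) -> float:
    if a.shape != b.shape:
        raise ValueError(f"SHED dimensionality mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def _atom_label_string(tags: frozenset) -> str:
    return "".join(sorted(tags)) if tags else "0"


def compute_phrag(mol: Molecule | str, min_atoms: int = 2, max_atoms: int = 7) -> Counter:
    """Multiset of linear pharmacophore fragments along shortest paths.

    Fragment strings use the lexicographically smaller of the two reading
    directions, so the multiset is invariant under atom renumbering.
    """
    smiles = mol.smiles_canonical if isinstance(mol, Molecule) else mol
    m = as_rdkit(smiles)
    labels = [_atom_label_string(t) for t in assign_features(smiles)]
    g = nx.Graph()
    g.add_nodes_from(range(m.GetNumAtoms()))
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in m.GetBonds())
    dmat = Chem.GetDistanceMatrix(m)
    frags: Counter = Counter()
    n = m.GetNumAtoms()
    for i in range(n):
        for j in range(i + 1, n):
            d = dmat[i, j]
            if not np.isfinite(d) or d > 1e6:
                continue
            if not (min_atoms - 1 <= d <= max_atoms - 1):
                continue
            for path in nx.all_shortest_paths(g, i, j):
                seq = [labels[a] for a in path]
                fwd = "-".join(seq)
                rev = "-".join(reversed(seq))
                frags[min(fwd, rev)] += 1
    return frags


def phrag_similarity(a: Counter, b: Counter) -> float:
    """Multiset Tanimoto: sum of min counts over sum of max counts."""
    if not a or not b:
        return 0.0
    keys = set(a) | set(b)
    num = sum(min(a[k], b[k]) for k in keys)
    den = sum(max(a[k], b[k]) for k in keys)
    return num / den if den else 0.0


def compute_fingerprint(mol: Molecule | str, radius: int = 2, n_bits: int = 2048):
    """Hashed circular substructure fingerprint (Morgan, default radius 2)."""
    smiles = mol.smiles_canonical if isinstance(mol, Molecule) else mol
    gen = _fp_generator(radius, n_bits)
    return gen.GetFingerprint(as_rdkit(smiles))


_GENERATORS: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )
    return _GENERATORS[key]


def tanimoto(a, b) -> float:
    """Bit Tanimoto |a&b|/|a|b|; two empty fingerprints are defined as 0."""
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        return 0.0
    return float(DataStructs.TanimotoSimilarity(a, b))


@dataclass
class MolDescriptors:
    """All descriptors for one molecule, computed once and reused."""

    smiles_canonical: str
    fpd: FPDVector
    shed: np.ndarray
    phrag: Counter
    fingerprint: object


def compute_descriptors(mol: Molecule | str, L: int = 10, radius: int = 2,
                        n_bits: int = 2048) -> MolDescriptors:
    smiles = mol.smiles_canonical if isinstance(mol, Molecule) else mol
    return MolDescriptors(
        smiles_canonical=smiles,
        fpd=compute_fpd(smiles, L),
        shed=compute_shed(smiles, L),
        phrag=compute_phrag(smiles),
        fingerprint=compute_fingerprint(smiles, radius, n_bits),
    )
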