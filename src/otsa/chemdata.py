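"""Molecule and table I/O.

The canonicalization contract used by every downstream module: a molecule is
its 2-D heavy-atom graph.  Stereo descriptors and isotope labels are stripped
before canonical SMILES generation, so enantiomer pairs collapse to a single
compound — all six prediction methods are intentionally stereo-blind.  Salt
and mixture records are reduced to their largest fragment (logged in the parse
report).
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

ACTIVE, INACTIVE = "active", "inactive"


class MoleculeParseError(ValueError):
    """Raised for an unparseable chemical structure; carries the input string."""


class DataError(ValueError):
    """Fatal structural problem in an input table."""


@dataclass(frozen=True)
class Molecule:
    mol_id: str
    smiles_input: str
    smiles_canonical: str
    atom_count: int  # heavy atoms


@dataclass
class ParseReport:
    """Accounting of skipped records; nothing is ever silently dropped."""

    skipped: list[tuple[int, str, str]] = field(default_factory=list)  # (line, record, reason)
    notes: list[str] = field(default_factory=list)

    def skip(self, line_no: int, record: str, reason: str) -> None:
        self.skipped.append((line_no, record, reason))

    def note(self, message: str) -> None:
        self.notes.append(message)

    def summary(self) -> str:
        lines = [f"skipped records: {len(self.skipped)}"]
        lines += [f"  line {n}: {reason} ({rec!r})" for n, rec, reason in self.skipped]
        lines += [f"note: {m}" for m in self.notes]
        return "\n".join(lines)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.summary() + "\n")


def canonicalize(smiles: str) -> str:
    """Canonical stereo-stripped SMILES of the largest fragment.

    Idempotent and independent of input atom ordering; enantiomers and isotope
    variants map to the same output.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        # largest fragment by heavy-atom count; deterministic tie-break on SMILES
        mol = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    Chem.RemoveStereochemistry(mol)
    for atom in mol.GetAtoms():
        atom.SetIsotope(0)
    return Chem.MolToSmiles(mol)


_MOL_CACHE: dict[str, Chem.Mol] = {}


def as_rdkit(smiles_canonical: str) -> Chem.Mol:
    """RDKit Mol for a canonical SMILES (cached; molecules are immutable here)."""
    mol = _MOL_CACHE.get(smiles_canonical)
    if mol is None:
        mol = Chem.MolFromSmiles(smiles_canonical)
        if mol is None:
            raise MoleculeParseError(f"unparseable SMILES: {smiles_canonical!r}")
        _MOL_CACHE[smiles_canonical] = mol
    return mol


def make_molecule(mol_id: str, smiles: str) -> Molecule:
    canon = canonicalize(smiles)
    return Molecule(mol_id, smiles, canon, as_rdkit(canon).GetNumHeavyAtoms())


def _check_duplicate_ids(mols: list[Molecule]) -> None:
    counts = Counter(m.mol_id for m in mols)
    dupes = sorted(i for i, c in counts.items() if c > 1)
    if dupes:
        raise DataError(f"duplicate mol_id values: {dupes}")


def read_molecule_table(
    path: str | Path,
    fmt: str | None = None,
    id_col: str = "mol_id",
    smiles_col: str = "smiles",
) -> tuple[list[Molecule], ParseReport]:
    """Read molecules from a SMILES list, TSV table or SDF file.

    Returns the parseable molecules in file order together with a ParseReport
    naming every skipped record by line (or record) number.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if fmt is None:
        fmt = {".sdf": "sdf", ".tsv": "tsv"}.get(path.suffix.lower(), "smiles-list")

    report = ParseReport()
    mols: list[Molecule] = []

    if fmt == "smiles-list":
        auto = 0
        for line_no, line in enumerate(path.read_text().splitlines(), start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split()
            if len(parts) == 1:
                auto += 1
                mol_id, smi = f"mol{auto}", parts[0]
            else:
                mol_id, smi = parts[0], parts[1]
            try:
                mols.append(make_molecule(mol_id, smi))
            except MoleculeParseError:
                report.skip(line_no, text, "unparseable SMILES")
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        for col in (id_col, smiles_col):
            if col not in df.columns:
                raise DataError(f"missing column {col!r} in {path}")
        for row_no, row in enumerate(df.itertuples(index=False), start=2):
            mol_id = getattr(row, id_col)
            smi = getattr(row, smiles_col)
            try:
                mols.append(make_molecule(str(mol_id), str(smi)))
            except MoleculeParseError:
                report.skip(row_no, f"{mol_id}\t{smi}", "unparseable SMILES")
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        auto = 0
        for rec_no, mol in enumerate(supplier, start=1):
            if mol is None:
                report.skip(rec_no, f"record {rec_no}", "unparseable SDF record")
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            if not name:
                auto += 1
                name = f"sdf{auto}"
            try:
                mols.append(make_molecule(name, Chem.MolToSmiles(mol)))
            except MoleculeParseError:
                report.skip(rec_no, name, "unparseable structure")
    else:
        raise DataError(f"unknown format {fmt!r}")

    if any("." in m.smiles_input for m in mols):
        report.note("multi-fragment inputs reduced to their largest fragment")
    if not mols:
        raise DataError(f"no parseable records in {path}")
    _check_duplicate_ids(mols)
    return mols, report


def write_molecule_table(mols: list[Molecule], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "mol_id": [m.mol_id for m in mols],
            "smiles": [m.smiles_canonical for m in mols],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class TargetLigandSet:
    target_id: str
    target_family: str
    actives: set[str] = field(default_factory=set)
    inactives: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.actives & self.inactives:
            raise DataError(
                f"target {self.target_id}: compounds both active and inactive: "
                f"{sorted(self.actives & self.inactives)}"
            )


@dataclass(frozen=True)
class Interaction:
    mol_id: str
    target_id: str
    label: str
    potency_um: float | None = None


@dataclass
class ReferenceDatabase:
    """Per-target active ligand sets plus a deduplicated compound table."""

    compounds: dict[str, Molecule]
    targets: dict[str, TargetLigandSet]
    interactions: list[Interaction]
    aliases: dict[str, str] = field(default_factory=dict)
    dropped_targets: list[str] = field(default_factory=list)

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def compound_by_smiles(self) -> dict[str, str]:
        return {m.smiles_canonical: i for i, m in self.compounds.items()}

    def training_targets(self, smiles_canonical: str) -> set[str]:
        """Targets on which this exact structure is an annotated active."""
        mol_id = self.compound_by_smiles().get(smiles_canonical)
        if mol_id is None:
            return set()
        return {t for t, ls in self.targets.items() if mol_id in ls.actives}

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for it in sorted(self.interactions, key=lambda x: (x.mol_id, x.target_id, x.label)):
            h.update(f"{it.mol_id}\t{it.target_id}\t{it.label}\n".encode())
        return h.hexdigest()[:16]


def load_reference_database(activity_table: str | Path) -> ReferenceDatabase:
    """Load a TSV bioactivity table into a ReferenceDatabase.

    Columns: mol_id, smiles, target_id, label (active/inactive), optional
    potency (uM) and target_family.  Compounds are deduplicated by canonical
    SMILES (first id wins; aliases recorded); targets with no actives after
    loading are dropped with a warning; conflicting labels for the same
    (compound, target) pair are fatal.
    """
    path = Path(activity_table)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("mol_id", "smiles", "target_id", "label"):
        if col not in df.columns:
            raise DataError(f"missing column {col!r} in {path}")

    compounds: dict[str, Molecule] = {}
    by_canon: dict[str, str] = {}
    aliases: dict[str, str] = {}
    labels: dict[tuple[str, str], str] = {}
    potencies: dict[tuple[str, str], float | None] = {}
    families: dict[str, str] = {}

    conflicts = []
    for row in df.itertuples(index=False):
        try:
            mol = make_molecule(str(row.mol_id), str(row.smiles))
        except MoleculeParseError:
            logger.warning("skipping unparseable SMILES for %s", row.mol_id)
            continue
        kept = by_canon.get(mol.smiles_canonical)
        if kept is None:
            compounds[mol.mol_id] = mol
            by_canon[mol.smiles_canonical] = mol.mol_id
            kept = mol.mol_id
        elif kept != mol.mol_id:
            aliases[mol.mol_id] = kept
        label = str(row.label).strip().lower()
        if label not in (ACTIVE, INACTIVE):
            raise DataError(f"unknown activity label {label!r} for {row.mol_id}")
        key = (kept, str(row.target_id))
        if key in labels and labels[key] != label:
            conflicts.append(key)
        labels[key] = label
        pot = getattr(row, "potency", None)
        potencies[key] = float(pot) if pot not in (None, "", "nan") and not pd.isna(pot) else None
        fam = getattr(row, "target_family", None)
        if fam is not None and not pd.isna(fam) and str(row.target_id) not in families:
            families[str(row.target_id)] = str(fam)

    if conflicts:
        raise DataError(f"conflicting activity labels for pairs: {sorted(set(conflicts))}")

    target_sets: dict[str, TargetLigandSet] = {}
    for (mol_id, target_id), label in labels.items():
        ls = target_sets.setdefault(
            target_id, TargetLigandSet(target_id, families.get(target_id, "unknown"))
        )
        (ls.actives if label == ACTIVE else ls.inactives).add(mol_id)

    dropped = sorted(t for t, ls in target_sets.items() if not ls.actives)
    for t in dropped:
        logger.warning("dropping target %s: no active ligands", t)
        del target_sets[t]

    interactions = [
        Interaction(mol_id, target_id, label, potencies[(mol_id, target_id)])
        for (mol_id, target_id), label in sorted(labels.items())
        if target_id in target_sets
    ]
    db = ReferenceDatabase(compounds, target_sets, interactions, aliases, dropped)
    logger.info(
        "loaded reference database: %d compounds, %d targets, %d interactions",
        db.n_compounds, db.n_targets, len(interactions),
    )
    return db


@dataclass
class TruthTable:
    """Known (compound, target) interactions from prior in vitro evidence."""

    rows: set[tuple[str, str]]
    sources: dict[tuple[str, str], str] = field(default_factory=dict)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.rows


def load_truth_table(path: str | Path) -> TruthTable:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("mol_id", "target_id"):
        if col not in df.columns:
            raise DataError(f"missing column {col!r} in {path}")
    rows: set[tuple[str, str]] = set()
    sources: dict[tuple[str, str], str] = {}
    for row in df.itertuples(index=False):
        pair = (str(row.mol_id), str(row.target_id))
        rows.add(pair)
        src = getattr(row, "source", None)
        if src is not None and not pd.isna(src):
            sources[pair] = str(src)
    return TruthTable(rows, sources)


@dataclass
class ExpressionMatrix:
    """Target x tissue expression values (non-negative, units as given)."""

    values: pd.DataFrame  # index: target_id, columns: tissue names
    species: str = "unspecified"

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def lookup(self, target_id: str, tissue: str) -> float | None:
        if tissue not in self.values.columns:
            raise DataError(
                f"unknown tissue {tissue!r}; available: {sorted(self.values.columns)}"
            )
        if target_id not in self.values.index:
            return None
        return float(self.values.loc[target_id, tissue])


def load_expression_matrix(path: str | Path, species: str = "unspecified") -> ExpressionMatrix:
    """Parse a TSV expression matrix (first column target_id, rest tissues)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    lines = [
        ln for ln in path.read_text().splitlines() if ln.strip() and not ln.startswith("#")
    ]
    header = lines[0].split("\t")
    tissues = header[1:]
    if len(set(tissues)) != len(tissues):
        raise DataError("tissue names are not unique")
    records, index = [], []
    for row_no, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise DataError(f"ragged row {row_no}: {len(parts)} fields, expected {len(header)}")
        index.append(parts[0])
        try:
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise DataError(f"non-numeric entry in row {row_no}") from exc
        if any(v < 0 for v in vals):
            raise DataError(f"negative expression value in row {row_no}")
        records.append(vals)
    return ExpressionMatrix(pd.DataFrame(records, index=index, columns=tissues), species)
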