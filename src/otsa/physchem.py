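"""Physicochemical descriptors and rule classifications.

Properties per compound: molecular weight, Crippen atom-contribution clogP,
Ertl fragment TPSA, donor/acceptor counts from the pharmacophore feature
table, rotatable bonds, sp3 carbon count, representative pKa values from an
ionizable-group pattern table, and an ESOL-type estimated aqueous solubility.

Rule classifications: the 3/75 bins (clogP <= 3 combined with TPSA >= 75 A^2
is full compliance, both boundaries inclusive), the Lipinski rule-of-five
violation count, and a basicity flag for pKa between 7 and 10.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .chemdata import Molecule, as_rdkit
from .descriptors import assign_features

# Representative pKa values by ionizable-group pattern (config-overridable).
PKA_BASIC_PATTERNS: list[tuple[str, float]] = [
    ("[NX3;+0;!$([NX3][CX3]=[OX1]);!$([NX3][a]);!$([NX3][#7,#8,#16]);!$([NX3]=*)]", 10.6),  # aliphatic amine
    ("[NX3;$([NX3][CX3]=[NX2])]", 12.5),   # amidine / guanidine
    ("c1nc[nH]c1", 7.0),                   # imidazole
    ("[nX2;$([nX2]1ccccc1)]", 5.2),        # pyridine
    ("[NX3;$([NX3][a]);!$([NX3][CX3]=[OX1])]", 4.6),  # aniline
]
PKA_ACIDIC_PATTERNS: list[tuple[str, float]] = [
    ("[CX3](=[OX1])[OX2H1]", 4.2),         # carboxylic acid
    ("[SX4](=[OX1])(=[OX1])[OX2H1]", -0.6),  # sulfonic acid
    ("[PX4](=[OX1])[OX2H1]", 1.9),         # phosphonic acid
    ("[OX2H1][c]", 10.0),                  # phenol
    ("c1nnn[nH]1", 4.9),                   # tetrazole
]

_BASIC = [(Chem.MolFromSmarts(s), v) for s, v in PKA_BASIC_PATTERNS]
_ACIDIC = [(Chem.MolFromSmarts(s), v) for s, v in PKA_ACIDIC_PATTERNS]


@dataclass
class PropertyProfile:
    mol_id: str
    mw: float
    clogp: float
    tpsa: float
    hbd: int
    hba: int
    n_rotatable: int
    n_sp3_carbon: int
    pka_basic: float | None
    pka_acidic: float | None
    logs: float


@dataclass
class RuleClassification:
    rule_3_75_bin: str          # one of the four 3/75 quadrants
    compliant_3_75: bool
    ro5_violations: int
    pka_7_10: bool


def compute_properties(mol: Molecule, seed_unused: None = None) -> PropertyProfile:
    m = as_rdkit(mol.smiles_canonical)
    labels = assign_features(mol.smiles_canonical)
    hbd = sum(1 for t in labels if "D" in t)
    hba = sum(1 for t in labels if "A" in t)
    mw = Descriptors.MolWt(m)
    clogp = Crippen.MolLogP(m)
    n_rot = Lipinski.NumRotatableBonds(m)
    aromatic = sum(1 for a in m.GetAtoms() if a.GetIsAromatic())
    arom_prop = aromatic / m.GetNumHeavyAtoms()
    # ESOL-type linear solubility estimate (log mol/L)
    logs = 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * n_rot - 0.74 * arom_prop
    basic = [v for patt, v in _BASIC if patt is not None and m.HasSubstructMatch(patt)]
    acidic = [v for patt, v in _ACIDIC if patt is not None and m.HasSubstructMatch(patt)]
    return PropertyProfile(
        mol_id=mol.mol_id,
        mw=mw,
        clogp=clogp,
        tpsa=rdMolDescriptors.CalcTPSA(m),
        hbd=hbd,
        hba=hba,
        n_rotatable=n_rot,
        n_sp3_carbon=sum(
            1
            for a in m.GetAtoms()
            if a.GetAtomicNum() == 6 and a.GetHybridization() == Chem.HybridizationType.SP3
        ),
        pka_basic=max(basic) if basic else None,
        pka_acidic=min(acidic) if acidic else None,
        logs=logs,
    )


def classify_rules(profile: PropertyProfile) -> RuleClassification:
    """Deterministic 3/75 binning, Ro5 violation count and basicity flag.

    Boundary conventions: 3/75 compliance is clogP <= 3 AND TPSA >= 75 (both
    inclusive); Ro5 violations count MW >= 500, clogP >= 5, HBD > 5, HBA > 10.
    """
    low_p = profile.clogp <= 3.0
    high_t = profile.tpsa >= 75.0
    if high_t and low_p:
        bin_name = "TPSA>=75 & clogP<=3"
    elif not high_t and not low_p:
        bin_name = "TPSA<75 & clogP>3"
    elif high_t:
        bin_name = "TPSA>=75 & clogP>3"
    else:
        bin_name = "TPSA<75 & clogP<=3"
    violations = sum(
        [
            profile.mw >= 500.0,
            profile.clogp >= 5.0,
            profile.hbd > 5,
            profile.hba > 10,
        ]
    )
    return RuleClassification(
        rule_3_75_bin=bin_name,
        compliant_3_75=high_t and low_p,
        ro5_violations=violations,
        pka_7_10=profile.pka_basic is not None and 7.0 <= profile.pka_basic <= 10.0,
    )


MW_BINS = ((None, 200.0), (200.0, 300.0), (300.0, 500.0), (500.0, 700.0), (700.0, None))


def _mw_bin(mw: float) -> str:
    for lo, hi in MW_BINS:
        if (lo is None or mw >= lo) and (hi is None or mw < hi):
            lo_s = "" if lo is None else f"{lo:.0f}"
            hi_s = "" if hi is None else f"{hi:.0f}"
            if lo is None:
                return f"<{hi_s}"
            if hi is None:
                return f">={lo_s}"
            return f"{lo_s}-{hi_s}"
    raise AssertionError


def _tpsa_bin(tpsa: float) -> str:
    lo = int(tpsa // 50) * 50
    return f"{lo}-{lo + 50}"


def _clogp_bin(clogp: float) -> str:
    if clogp >= 7:
        return ">=7"
    lo = int(np.floor(clogp))
    return f"{lo}-{lo + 1}"


def promiscuity_profile(
    predictions: pd.DataFrame, profiles: dict[str, PropertyProfile]
) -> dict[str, pd.DataFrame]:
    """Cross-tabulate per-compound off-target counts against property bins.

    `predictions` needs columns mol_id / provenance / consensus_pass; only
    consensus-passing, non-training predictions count as off-targets.  Each
    axis reports the percentage of predicted off-targets falling in each bin
    (percentages sum to 100 when any off-target exists).
    """
    out: dict[str, pd.DataFrame] = {}
    if len(predictions):
        passing = predictions[
            predictions["consensus_pass"] & (predictions["provenance"] != "training_set")
        ]
        counts = passing.groupby("mol_id").size()
    else:
        counts = pd.Series(dtype=int)
    missing = sorted(set(counts.index) - set(profiles))
    counts = counts.drop(index=missing)
    axes = {"MW": _mw_bin, "TPSA": _tpsa_bin, "clogP": _clogp_bin}
    values = {"MW": "mw", "TPSA": "tpsa", "clogP": "clogp"}
    for axis, binner in axes.items():
        rows: dict[str, int] = {}
        for mol_id, n_off in counts.items():
            key = binner(getattr(profiles[mol_id], values[axis]))
            rows[key] = rows.get(key, 0) + int(n_off)
        total = sum(rows.values())
        df = pd.DataFrame(
            {
                "bin": sorted(rows),
                "n_off_targets": [rows[k] for k in sorted(rows)],
            }
        )
        df["pct_off_targets"] = (
            100.0 * df["n_off_targets"] / total if total else 0.0
        )
        df.attrs["n_excluded_no_profile"] = len(missing)
        out[axis] = df
    return out


def profiles_to_frame(profiles: list[PropertyProfile]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in profiles])
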