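"""Synthetic chemogenomics fixtures with known ground truth.

The generator emulates the structure of a curated bioactivity corpus at desk
scale: each target owns a few chemotype series (a shared scaffold with
enumerated small decorations), a stated fraction of some chemotypes is
additionally planted as active on an off-target (mimicking real
polypharmacology), and undecorated-by-activity decoy series populate the
chemical background.  A fraction of every chemotype is withheld from the
emitted database as queries with known expected interactions, so predictor
recall and precision are measurable without any external download.

Fixtures are engineered for testability, not for realism of chemical-space
statistics: within-series similarity is high by construction and series are
well separated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chemdata import (
    Interaction,
    Molecule,
    ReferenceDatabase,
    TargetLigandSet,
    make_molecule,
)
from .config import OTSAConfig

# ---------------------------------------------------------------------------
# scaffold library: templates with one decoration site "{R}", tagged by family

CHEMOTYPE_TEMPLATES: list[tuple[str, str]] = [
    # aminergic / GPCR-like
    ("gpcr", "CN1CCN(CC1)c1ccc({R})cc1"),
    ("gpcr", "CCN(CC)CCNC(=O)c1ccc({R})cc1"),
    ("gpcr", "c1ccc(CCN2CCC(c3ccc({R})cc3)CC2)cc1"),
    ("gpcr", "NCCc1c[nH]c2ccc({R})cc12"),
    ("gpcr", "CNCC(O)c1ccc(O)c({R})c1"),
    # kinase-like heteroaromatics
    ("kinase", "COc1cc2ncnc(Nc3ccc({R})cc3)c2cc1OC"),
    ("kinase", "O=C(Nc1ccccc1)Nc1ccc({R})cc1"),
    ("kinase", "c1ccc(-c2cc({R})nc(N3CCOCC3)n2)cc1"),
    ("kinase", "Nc1nc({R})nc2[nH]cnc12"),
    ("kinase", "N#Cc1ccc(Oc2ccc({R})cn2)cc1"),
    # acids / nuclear-receptor-like
    ("nuclear_receptor", "OC(=O)Cc1ccc(Oc2ccc({R})cc2)cc1"),
    ("nuclear_receptor", "OC(=O)c1ccc(NC(=O)c2ccc({R})cc2)cc1"),
    ("nuclear_receptor", "OC(=O)CCc1ccc(S(=O)(=O)c2ccc({R})cc2)cc1"),
    # ion-channel-like amides
    ("ion_channel", "O=C(Nc1cccc(C(F)(F)F)c1)c1ccc({R})o1"),
    ("ion_channel", "O=C(NCc1ccc({R})cc1)C1CCCN1C"),
    ("ion_channel", "Cc1ccc(S(=O)(=O)Nc2ccc({R})cc2)cc1"),
    # protease-like peptidomimetics
    ("protease", "CC(NC(=O)c1ccc({R})cc1)C(=O)NC1CCCC1"),
    ("protease", "CC(C)CC(NC(=O)c1cnc({R})cn1)C(N)=O"),
    # transporter-like
    ("transporter", "O=S(=O)(N)c1ccc({R})cc1"),
    ("transporter", "O=C(N1CCC({R})CC1)c1ccc2OCOc2c1"),
    ("transporter", "OCC(O)COc1ccc({R})cc1"),
    ("transporter", "O=C(N1CCC({R})CC1)Cn1cncc1"),
]

DECOY_TEMPLATES: list[str] = [
    "CCOC(=O)c1ccc({R})cc1",
    "CC(C)Oc1cccc({R})c1",
    "CC(=O)Nc1ccc({R})cc1",
    "c1ccc(COc2ccc({R})cc2)cc1",
    "CC(=O)N1CCC({R})CC1",
    "COc1ccc({R})cc1OC",
    "CCOCCOc1ccc({R})cc1",
]

DECORATIONS: list[str] = [
    "C", "CC", "CCC", "C(C)C", "F", "Cl", "Br", "OC", "CO",
    "C(F)(F)F", "CCO", "N", "C#N", "OCC",
]

FAMILIES = ("gpcr", "kinase", "nuclear_receptor", "ion_channel", "protease", "transporter")


@dataclass
class SyntheticSpec:
    n_targets: int = 8
    n_families: int = 5
    chemotypes_per_target: int = 2
    actives_per_chemotype: int = 12
    # (chemotype_id, off_target_id, fraction); None -> a default set of three
    planted_cross_activities: list[tuple[str, str, float]] | None = None
    decoy_count: int = 60
    withhold_fraction: float = 0.2
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("n_targets", "n_families", "chemotypes_per_target",
                     "actives_per_chemotype", "decoy_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.withhold_fraction < 1.0:
            raise ValueError("withhold_fraction must be in [0, 1)")

    def default_planted(self) -> list[tuple[str, str, float]]:
        if self.planted_cross_activities is not None:
            for _, _, frac in self.planted_cross_activities:
                if not 0.0 < frac <= 1.0:
                    raise ValueError("planted fractions must be in (0, 1]")
            return self.planted_cross_activities
        shift = max(self.n_targets // 2, 1)
        out = []
        for i in range(min(3, self.n_targets - 1)):
            off = f"t{(i + shift) % self.n_targets}"
            out.append((f"c{i}_0", off, 0.3))
        return out


@dataclass
class GroundTruth:
    # (mol_id, target_id, kind in {primary, planted_off_target})
    entries: list[tuple[str, str, str]]
    withheld_queries: list[Molecule]
    chemotype_of: dict[str, str] = field(default_factory=dict)

    def expected_pairs(self) -> set[tuple[str, str]]:
        withheld = {m.mol_id for m in self.withheld_queries}
        return {(m, t) for m, t, _ in self.entries if m in withheld}

    def expected_by_kind(self, kind: str) -> set[tuple[str, str]]:
        withheld = {m.mol_id for m in self.withheld_queries}
        return {(m, t) for m, t, k in self.entries if k == kind and m in withheld}


def _enumerate_members(template: str, prefix: str, n: int,
                       seen_canonical: set[str]) -> list[Molecule]:
    members: list[Molecule] = []
    k = 0
    for dec in DECORATIONS:
        if len(members) >= n:
            break
        smiles = template.replace("{R}", dec)
        try:
            mol = make_molecule(f"{prefix}_{k}", smiles)
        except Exception:
            continue
        if mol.smiles_canonical in seen_canonical:
            continue
        seen_canonical.add(mol.smiles_canonical)
        members.append(mol)
        k += 1
    return members


def generate_reference_db(spec: SyntheticSpec) -> tuple[ReferenceDatabase, GroundTruth]:
    """Build the synthetic database and its ground truth, deterministically.

    Chemotype c{i}_{j} is the j-th series of target t{i}.  Every member is
    active on its primary target; for each planted cross-activity a stated
    fraction of the chemotype's members is additionally active on the
    off-target.  A withheld fraction of each chemotype never enters the
    database and is returned as the query list with expected interactions.
    """
    rng = np.random.default_rng(spec.seed)
    n_needed = spec.n_targets * spec.chemotypes_per_target
    if n_needed > len(CHEMOTYPE_TEMPLATES):
        raise ValueError(
            f"scaffold library exhausted: need {n_needed} chemotypes, "
            f"have {len(CHEMOTYPE_TEMPLATES)} "
            f"(max {len(CHEMOTYPE_TEMPLATES) // spec.chemotypes_per_target} targets)"
        )
    families = FAMILIES[: spec.n_families]
    # group templates by family, assign chemotypes so a target's series share a family
    by_family: dict[str, list[str]] = {}
    for fam, tpl in CHEMOTYPE_TEMPLATES:
        by_family.setdefault(fam, []).append(tpl)

    seen_canonical: set[str] = set()
    chemotype_members: dict[str, list[Molecule]] = {}
    target_family: dict[str, str] = {}
    chemotype_of: dict[str, str] = {}
    fam_cursor = {f: 0 for f in by_family}
    flat_extra = [tpl for fam, tpl in CHEMOTYPE_TEMPLATES]  # fallback pool, file order
    extra_cursor = 0
    used_templates: set[str] = set()

    for i in range(spec.n_targets):
        t = f"t{i}"
        fam = families[i % len(families)]
        target_family[t] = fam
        for j in range(spec.chemotypes_per_target):
            pool = by_family.get(fam, [])
            tpl = None
            while fam_cursor.get(fam, 0) < len(pool):
                cand = pool[fam_cursor[fam]]
                fam_cursor[fam] += 1
                if cand not in used_templates:
                    tpl = cand
                    break
            if tpl is None:  # family pool exhausted: take next unused template
                while extra_cursor < len(flat_extra):
                    cand = flat_extra[extra_cursor]
                    extra_cursor += 1
                    if cand not in used_templates:
                        tpl = cand
                        break
            if tpl is None:
                raise ValueError("scaffold library exhausted during assignment")
            used_templates.add(tpl)
            cid = f"c{i}_{j}"
            members = _enumerate_members(tpl, cid, spec.actives_per_chemotype, seen_canonical)
            if len(members) < spec.actives_per_chemotype:
                raise ValueError(
                    f"chemotype {cid}: only {len(members)} members enumerable "
                    f"(requested {spec.actives_per_chemotype})"
                )
            chemotype_members[cid] = members
            for m in members:
                chemotype_of[m.mol_id] = cid

    decoys: list[Molecule] = []
    for d_idx, tpl in enumerate(DECOY_TEMPLATES):
        if len(decoys) >= spec.decoy_count:
            break
        decoys.extend(
            _enumerate_members(
                tpl, f"d{d_idx}",
                min(len(DECORATIONS), spec.decoy_count - len(decoys)),
                seen_canonical,
            )
        )
    decoys = decoys[: spec.decoy_count]

    # planted cross-activities: fraction of a chemotype's members, chosen by rng
    planted: dict[str, set[str]] = {}  # mol_id -> off-targets
    for cid, off_target, frac in spec.default_planted():
        if cid not in chemotype_members:
            raise ValueError(f"planted cross-activity names unknown chemotype {cid}")
        members = chemotype_members[cid]
        n_plant = int(round(frac * len(members)))
        idx = sorted(rng.choice(len(members), size=n_plant, replace=False))
        for k in idx:
            planted.setdefault(members[k].mol_id, set()).add(off_target)

    # withholding
    withheld_ids: set[str] = set()
    for cid in sorted(chemotype_members):
        members = chemotype_members[cid]
        n_hold = int(round(spec.withhold_fraction * len(members)))
        idx = sorted(rng.choice(len(members), size=n_hold, replace=False))
        withheld_ids.update(members[k].mol_id for k in idx)

    compounds: dict[str, Molecule] = {}
    interactions: list[Interaction] = []
    target_sets: dict[str, TargetLigandSet] = {
        f"t{i}": TargetLigandSet(f"t{i}", target_family[f"t{i}"]) for i in range(spec.n_targets)
    }
    truth_entries: list[tuple[str, str, str]] = []
    withheld_queries: list[Molecule] = []

    for i in range(spec.n_targets):
        t = f"t{i}"
        for j in range(spec.chemotypes_per_target):
            cid = f"c{i}_{j}"
            for m in chemotype_members[cid]:
                truth_entries.append((m.mol_id, t, "primary"))
                for off in sorted(planted.get(m.mol_id, ())):
                    truth_entries.append((m.mol_id, off, "planted_off_target"))
                if m.mol_id in withheld_ids:
                    withheld_queries.append(m)
                    continue
                compounds[m.mol_id] = m
                interactions.append(Interaction(m.mol_id, t, "active"))
                target_sets[t].actives.add(m.mol_id)
                for off in sorted(planted.get(m.mol_id, ())):
                    interactions.append(Interaction(m.mol_id, off, "active"))
                    target_sets[off].actives.add(m.mol_id)
    for d in decoys:
        compounds[d.mol_id] = d

    db = ReferenceDatabase(compounds, target_sets, sorted(
        interactions, key=lambda x: (x.mol_id, x.target_id)
    ))
    truth = GroundTruth(
        sorted(truth_entries),
        sorted(withheld_queries, key=lambda m: m.mol_id),
        chemotype_of,
    )
    return db, truth


def generate_query_set(
    db: ReferenceDatabase, truth: GroundTruth
) -> tuple[list[Molecule], set[tuple[str, str]]]:
    """Withheld molecules plus expected (query, target) pairs; asserts that no
    query structure leaks into the database."""
    db_canonical = {m.smiles_canonical for m in db.compounds.values()}
    for q in truth.withheld_queries:
        if q.smiles_canonical in db_canonical:
            raise AssertionError(f"query {q.mol_id} leaks into the reference database")
    return list(truth.withheld_queries), truth.expected_pairs()


def evaluate_recovery(
    predictions: list,
    expected: set[tuple[str, str]],
    truth: GroundTruth | None = None,
    config: OTSAConfig | None = None,
) -> dict:
    """Recall/precision of consensus-passing predictions against expectation.

    `predictions` are InteractionPrediction objects for the withheld query
    set.  Capture rate = |predicted n expected| / |expected|; precision is
    measured against non-expected targets.  Per-method coverage uses the same
    arithmetic as the cohort report.
    """
    from .ensemble import method_coverage

    config = config or OTSAConfig()
    passing = {(p.mol_id, p.target_id) for p in predictions if p.consensus_pass}
    hit = passing & expected
    metrics: dict = {
        "n_expected": len(expected),
        "n_predicted": len(passing),
        "n_hit": len(hit),
        "recall": len(hit) / len(expected) if expected else 0.0,
        "precision": len(hit) / len(passing) if passing else 0.0,
        "capture_rate": len(hit) / len(expected) if expected else 0.0,
    }
    if truth is not None:
        for kind in ("primary", "planted_off_target"):
            exp_k = truth.expected_by_kind(kind)
            metrics[f"recall_{kind}"] = (
                len(passing & exp_k) / len(exp_k) if exp_k else None
            )
    per_method: dict = {}
    for m in ("SAS", "SAR", "SIM", "SEA", "MLM", "XPI"):
        m_hits = {
            (p.mol_id, p.target_id)
            for p in predictions
            if p.consensus_pass and m in p.method_scores and config.passes_tau(p.method_scores[m])
        }
        per_method[m] = len(m_hits & expected) / len(expected) if expected else 0.0
    metrics["per_method_recall"] = per_method
    metrics["coverage"] = method_coverage(predictions, config)
    return metrics


def write_reference_tsv(db: ReferenceDatabase, activity_path, compound_path=None) -> None:
    """Emit the activity table (and optionally the full compound table,
    including decoys that carry no annotation)."""
    import pandas as pd

    rows = [
        {
            "mol_id": it.mol_id,
            "smiles": db.compounds[it.mol_id].smiles_canonical,
            "target_id": it.target_id,
            "label": it.label,
            "target_family": db.targets[it.target_id].target_family,
        }
        for it in db.interactions
    ]
    pd.DataFrame(rows).to_csv(activity_path, sep="\t", index=False)
    if compound_path is not None:
        crows = [
            {"mol_id": m.mol_id, "smiles": m.smiles_canonical}
            for m in sorted(db.compounds.values(), key=lambda x: x.mol_id)
        ]
        pd.DataFrame(crows).to_csv(compound_path, sep="\t", index=False)
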