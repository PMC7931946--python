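"""Pseudo-score aggregation, consensus filtering and report generation.

A predicted (compound, target) interaction carries one score per method; the
pseudo-score is the weighted mean of the present method scores (equal weights
by default), with the special rule that a pair present in the training corpus
as an annotated active scores exactly 1.0 — certainty.  An interaction is
high-confidence when at least k of the six methods score at or above tau
(default 3 of 6 at 0.6); training-set pairs pass unconditionally.

Passing interactions are classified by provenance — training_set (in the
reference corpus), confirmed (in the supplied truth table), new — and the
cohort report computes the standard summary arithmetic: totals per
provenance, mean interactions per compound, per-method coverage fractions
among non-training predictions and the all-six-methods fraction.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .chemdata import (
    ExpressionMatrix,
    Molecule,
    MoleculeParseError,
    ReferenceDatabase,
    TruthTable,
    canonicalize,
    make_molecule,
)
from .config import METHODS, OTSAConfig
from .predictors import FittedEnsemble, MethodScore, prepare_query

logger = logging.getLogger(__name__)

TRAINING_SET, CONFIRMED, NEW = "training_set", "confirmed", "new"


@dataclass
class InteractionPrediction:
    mol_id: str
    target_id: str
    pseudo_score: float
    method_scores: dict[str, float]
    evidence: dict[str, str]
    n_methods_above: int
    consensus_pass: bool
    provenance: str = NEW
    parent_id: str | None = None
    role: str = "parent"
    expression_unknown: bool = False
    alert: str | None = None


@dataclass
class QueryItem:
    molecule: Molecule
    parent_id: str
    role: str  # "parent" or "metabolite"


def merge_metabolite_list(
    parent: Molecule, metabolites: list[str]
) -> tuple[list[QueryItem], list[str]]:
    """Combine a parent with its metabolite SMILES into a deduplicated query
    set; unparseable metabolites are reported, never silently dropped."""
    items = [QueryItem(parent, parent.mol_id, "parent")]
    seen = {parent.smiles_canonical}
    skipped: list[str] = []
    for n, smi in enumerate(metabolites, start=1):
        try:
            canon = canonicalize(smi)
        except MoleculeParseError:
            skipped.append(smi)
            continue
        if canon in seen:
            continue
        seen.add(canon)
        items.append(
            QueryItem(make_molecule(f"{parent.mol_id}_M{n}", smi), parent.mol_id, "metabolite")
        )
    if skipped and len(items) == 1:
        logger.warning("all metabolites of %s unparseable; querying parent only", parent.mol_id)
    return items, skipped


def aggregate_pseudo_score(
    scores: dict[str, float],
    in_training: bool,
    weights: dict[str, float] | None = None,
    absent_as_zero: bool = False,
) -> float | None:
    """Normalized linear combination of the present method scores.

    Training-set membership overrides everything: the score is 1.0.  With no
    method score present the pseudo-score is undefined (None).
    """
    if in_training:
        return 1.0
    if weights is None:
        weights = {m: 1.0 for m in METHODS}
    if absent_as_zero:
        scores = {m: scores.get(m, 0.0) for m in METHODS}
    if not scores:
        return None
    num = sum(weights.get(m, 0.0) * s for m, s in scores.items())
    den = sum(weights.get(m, 0.0) for m in scores)
    if den == 0:
        return None
    return min(max(num / den, 0.0), 1.0)


def consensus_filter(
    scores: dict[str, float],
    config: OTSAConfig,
    in_training: bool = False,
) -> tuple[int, bool]:
    """(n_methods_above, pass).  Pass when >= k methods reach tau, or the
    pair is a training-set interaction (certainty override).  Monotone:
    raising any score never flips pass to fail."""
    n_above = sum(1 for s in scores.values() if config.passes_tau(s))
    return n_above, in_training or n_above >= config.k


def classify_interactions(
    predictions: list[InteractionPrediction],
    db: ReferenceDatabase,
    queries: dict[str, Molecule],
    truth: TruthTable | None = None,
) -> list[InteractionPrediction]:
    """Assign provenance to each prediction (training_set / confirmed / new).

    Training-set membership means the query's exact canonical structure is an
    annotated active for that target in the reference corpus; near-duplicates
    do not count."""
    for pred in predictions:
        mol = queries[pred.mol_id]
        if pred.target_id in db.training_targets(mol.smiles_canonical):
            pred.provenance = TRAINING_SET
            pred.pseudo_score = 1.0
        elif truth is not None and (pred.mol_id, pred.target_id) in truth:
            pred.provenance = CONFIRMED
        else:
            pred.provenance = NEW
    return predictions


def filter_by_expression(
    predictions: list[InteractionPrediction],
    expr: ExpressionMatrix,
    tissue: str,
    min_expr: float,
) -> list[InteractionPrediction]:
    """Keep predictions whose target is expressed in the tissue at or above
    min_expr; targets absent from the matrix are kept, flagged unknown."""
    kept: list[InteractionPrediction] = []
    for pred in predictions:
        value = expr.lookup(pred.target_id, tissue)
        if value is None:
            pred.expression_unknown = True
            kept.append(pred)
        elif value >= min_expr:
            kept.append(pred)
    return kept


# ---------------------------------------------------------------------------
# summary arithmetic


def summary_arithmetic(
    n_compounds: int, total: int, confirmed: int, new: int, training: int
) -> dict:
    """The cohort bookkeeping: conservation, percentages, mean per compound
    (reported to one decimal)."""
    if confirmed + new + training != total:
        raise ValueError("provenance counts do not sum to the total")
    non_training = total - training
    return {
        "n_compounds": n_compounds,
        "total_interactions": total,
        "confirmed": confirmed,
        "new": new,
        "training_set": training,
        "non_training": non_training,
        "pct_confirmed_of_total": 100.0 * confirmed / total if total else 0.0,
        "pct_new_of_total": 100.0 * new / total if total else 0.0,
        "pct_training_of_total": 100.0 * training / total if total else 0.0,
        "mean_interactions_per_compound": (
            round(total / n_compounds, 1) if n_compounds else 0.0
        ),
    }


def method_coverage(
    predictions: list[InteractionPrediction], config: OTSAConfig
) -> dict:
    """Per-method coverage among consensus-passing non-training predictions:
    the fraction each method scored at or above tau, plus the fraction
    reached by all six methods."""
    passing = [
        p for p in predictions if p.consensus_pass and p.provenance != TRAINING_SET
    ]
    n = len(passing)
    cov = {}
    for m in METHODS:
        hit = sum(
            1 for p in passing if m in p.method_scores and config.passes_tau(p.method_scores[m])
        )
        cov[m] = {"n": hit, "fraction": hit / n if n else 0.0}
    all_six = sum(
        1
        for p in passing
        if all(m in p.method_scores and config.passes_tau(p.method_scores[m]) for m in METHODS)
    )
    return {
        "n_non_training_passing": n,
        "per_method": cov,
        "all_six": {"n": all_six, "fraction": all_six / n if n else 0.0},
    }


@dataclass
class OTSAReport:
    predictions: pd.DataFrame       # consensus-passing, ranked
    summary: dict
    no_signal_pairs: int = 0

    def write(self, out_dir: str | Path, parse_report=None) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(self.summary, indent=2) + "\n")
        if parse_report is not None:
            parse_report.write(out / "parse_report.txt")


def _rank_key(p: InteractionPrediction):
    return (-p.pseudo_score, -p.n_methods_above, p.target_id)


def generate_report(
    predictions: list[InteractionPrediction],
    config: OTSAConfig,
    n_compounds: int | None = None,
    alert_table: dict[str, str] | None = None,
    no_signal_pairs: int = 0,
) -> OTSAReport:
    """Ranked per-compound tables plus the cohort summary.

    Ranking is per compound by descending pseudo-score, ties broken by the
    number of methods above threshold then target id, so reports are
    byte-reproducible."""
    passing = [p for p in predictions if p.consensus_pass]
    if alert_table:
        for p in passing:
            p.alert = alert_table.get(p.target_id)
    rows = []
    by_mol: dict[str, list[InteractionPrediction]] = {}
    for p in passing:
        by_mol.setdefault(p.mol_id, []).append(p)
    for mol_id in sorted(by_mol):
        for rank, p in enumerate(sorted(by_mol[mol_id], key=_rank_key), start=1):
            row = {
                "mol_id": p.mol_id,
                "rank": rank,
                "target_id": p.target_id,
                "pseudo_score": round(p.pseudo_score, 4),
                "n_methods_above": p.n_methods_above,
                "consensus_pass": p.consensus_pass,
                "provenance": p.provenance,
                "parent_id": p.parent_id or p.mol_id,
                "role": p.role,
                "expression_unknown": p.expression_unknown,
            }
            for m in METHODS:
                row[f"score_{m}"] = round(p.method_scores[m], 4) if m in p.method_scores else None
            row["alert"] = p.alert
            rows.append(row)
    df = pd.DataFrame(rows)
    counts = {prov: sum(1 for p in passing if p.provenance == prov)
              for prov in (TRAINING_SET, CONFIRMED, NEW)}
    n_comp = n_compounds if n_compounds is not None else len(by_mol)
    summary = summary_arithmetic(
        n_comp, len(passing), counts[CONFIRMED], counts[NEW], counts[TRAINING_SET]
    )
    summary["coverage"] = method_coverage(predictions, config)
    summary["no_signal_pairs"] = no_signal_pairs
    return OTSAReport(df, summary, no_signal_pairs)


# ---------------------------------------------------------------------------
# pipeline


def predict_interactions(
    ensemble: FittedEnsemble,
    queries: list[QueryItem],
    config: OTSAConfig,
    truth: TruthTable | None = None,
) -> tuple[list[InteractionPrediction], int]:
    """Score every query with all six methods and build predictions.

    Targets the query's structure is a training-set active for are always
    included (score 1.0) even if no method emitted them.  Returns the
    predictions plus the count of no-signal pairs (a scoreable target with no
    method score at all for a query)."""
    db = ensemble.prep.db
    predictions: list[InteractionPrediction] = []
    no_signal = 0
    query_mols = {q.molecule.mol_id: q.molecule for q in queries}
    for item in queries:
        q = prepare_query(item.molecule, config)
        rows = ensemble.score_query(q)
        per_target: dict[str, dict[str, float]] = {}
        evidence: dict[str, dict[str, str]] = {}
        for r in rows:
            per_target.setdefault(r.target_id, {})[r.method_id] = r.score
            evidence.setdefault(r.target_id, {})[r.method_id] = r.evidence
        training = db.training_targets(item.molecule.smiles_canonical)
        for t in training:
            per_target.setdefault(t, {})
            evidence.setdefault(t, {})
        no_signal += sum(1 for t in ensemble.prep.target_ids
                         if t not in per_target)
        for t, scores in sorted(per_target.items()):
            in_training = t in training
            s = aggregate_pseudo_score(
                scores, in_training, config.method_weights(), config.absent_as_zero
            )
            if s is None:
                no_signal += 1
                continue
            n_above, passed = consensus_filter(scores, config, in_training)
            predictions.append(
                InteractionPrediction(
                    mol_id=item.molecule.mol_id,
                    target_id=t,
                    pseudo_score=s,
                    method_scores=scores,
                    evidence=evidence[t],
                    n_methods_above=n_above,
                    consensus_pass=passed,
                    parent_id=item.parent_id,
                    role=item.role,
                )
            )
    classify_interactions(predictions, db, query_mols, truth)
    return predictions, no_signal


def run_pipeline(
    db: ReferenceDatabase,
    queries: list[QueryItem],
    config: OTSAConfig,
    seed: int | None = None,
    truth: TruthTable | None = None,
    expr: ExpressionMatrix | None = None,
    tissue: str | None = None,
    min_expr: float = 0.0,
    alert_table: dict[str, str] | None = None,
) -> tuple[list[InteractionPrediction], OTSAReport]:
    """Fit all six methods, score the queries, filter and report."""
    from .predictors import fit_all

    ensemble = fit_all(db, config, seed)
    predictions, no_signal = predict_interactions(ensemble, queries, config, truth)
    if expr is not None and tissue is not None:
        predictions = filter_by_expression(predictions, expr, tissue, min_expr)
    n_compounds = len({q.molecule.mol_id for q in queries})
    report = generate_report(predictions, config, n_compounds, alert_table, no_signal)
    return predictions, report
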