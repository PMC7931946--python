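"""Pseudo-score aggregation, consensus rule, classification and reporting."""
import numpy as np
import pytest

from otsa import OTSAConfig
from otsa.chemdata import TruthTable, load_expression_matrix, load_reference_database, make_molecule
from otsa.ensemble import (
    CONFIRMED, NEW, TRAINING_SET,
    InteractionPrediction,
    aggregate_pseudo_score,
    classify_interactions,
    consensus_filter,
    filter_by_expression,
    generate_report,
    merge_metabolite_list,
    method_coverage,
    summary_arithmetic,
)

DB_HEADER = "mol_id\tsmiles\ttarget_id\tlabel\n"


def _pred(mol_id="q1", target_id="t1", scores=None, s=0.7, n_above=3,
          passed=True, provenance=NEW):
    scores = scores if scores is not None else {"SIM": 0.7}
    return InteractionPrediction(
        mol_id=mol_id, target_id=target_id, pseudo_score=s, method_scores=scores,
        evidence={m: "x" for m in scores}, n_methods_above=n_above,
        consensus_pass=passed, provenance=provenance,
    )


class TestAggregatePseudoScore:
    def test_training_set_certainty(self):
        assert aggregate_pseudo_score({"SIM": 0.1}, in_training=True) == 1.0

    def test_mean_of_constants(self):
        scores = {m: 0.9 for m in ("SAS", "SAR", "SIM", "SEA", "MLM", "XPI")}
        assert aggregate_pseudo_score(scores, False) == pytest.approx(0.9)

    def test_renormalized_over_present_methods(self):
        assert aggregate_pseudo_score({"SIM": 0.6, "SEA": 0.8}, False) == pytest.approx(0.7)

    def test_no_scores_undefined(self):
        assert aggregate_pseudo_score({}, False) is None

    def test_absent_as_zero_flag(self):
        s = aggregate_pseudo_score({"SIM": 0.6}, False, absent_as_zero=True)
        assert s == pytest.approx(0.1)

    def test_custom_weights(self):
        w = {"SIM": 2.0, "SEA": 1.0}
        assert aggregate_pseudo_score({"SIM": 0.9, "SEA": 0.3}, False, w) == pytest.approx(0.7)


class TestConsensusFilter:
    def test_three_of_six_passes(self, default_config):
        scores = {"SAS": 0.7, "SAR": 0.65, "SIM": 0.61, "SEA": 0.2}
        n, passed = consensus_filter(scores, default_config)
        assert (n, passed) == (3, True)

    def test_two_of_six_fails(self, default_config):
        scores = {"SAS": 0.7, "SAR": 0.65, "SIM": 0.59, "SEA": 0.59, "MLM": 0.1, "XPI": 0.0}
        n, passed = consensus_filter(scores, default_config)
        assert (n, passed) == (2, False)

    def test_training_set_override(self, default_config):
        _, passed = consensus_filter({"SIM": 0.1}, default_config, in_training=True)
        assert passed

    def test_boundary_inclusive(self, default_config):
        n, passed = consensus_filter({"a": 0.6, "b": 0.6, "c": 0.6}, default_config)
        assert passed

    def test_strict_comparator_config(self):
        cfg = OTSAConfig(tau_comparator=">")
        n, passed = consensus_filter({"a": 0.6, "b": 0.6, "c": 0.6}, cfg)
        assert not passed

    def test_monotone_under_upward_perturbation(self, default_config):
        rng = np.random.default_rng(2)
        methods = ("SAS", "SAR", "SIM", "SEA", "MLM", "XPI")
        for _ in range(200):
            scores = dict(zip(methods, rng.uniform(size=6)))
            _, before = consensus_filter(scores, default_config)
            bumped = {m: min(1.0, s + rng.uniform(0, 0.5)) for m, s in scores.items()}
            _, after = consensus_filter(bumped, default_config)
            assert after or not before  # pass never flips to fail


class TestMergeMetaboliteList:
    def test_parent_plus_two(self):
        parent = make_molecule("p", "CCO")
        items, skipped = merge_metabolite_list(parent, ["CCN", "CCC"])
        assert len(items) == 3
        assert items[0].role == "parent"
        assert {i.role for i in items[1:]} == {"metabolite"}
        assert all(i.parent_id == "p" for i in items)
        assert skipped == []

    def test_metabolite_identical_to_parent_deduped(self):
        parent = make_molecule("p", "CCO")
        items, _ = merge_metabolite_list(parent, ["OCC"])
        assert len(items) == 1

    def test_empty_list(self):
        items, _ = merge_metabolite_list(make_molecule("p", "CCO"), [])
        assert len(items) == 1

    def test_unparseable_reported(self):
        items, skipped = merge_metabolite_list(make_molecule("p", "CCO"), ["C1CC"])
        assert len(items) == 1
        assert skipped == ["C1CC"]


class TestClassifyInteractions:
    def test_provenance_partition(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text(DB_HEADER + "m1\tCCO\tt1\tactive\n")
        db = load_reference_database(p)
        queries = {
            "q1": make_molecule("q1", "OCC"),   # same structure as m1
            "q2": make_molecule("q2", "CCN"),
        }
        truth = TruthTable({("q2", "t2")})
        preds = [
            _pred("q1", "t1", s=0.7),
            _pred("q2", "t2"),
            _pred("q2", "t3"),
        ]
        classify_interactions(preds, db, queries, truth)
        assert preds[0].provenance == TRAINING_SET
        assert preds[0].pseudo_score == 1.0   # certainty
        assert preds[1].provenance == CONFIRMED
        assert preds[2].provenance == NEW

    def test_near_duplicate_not_training(self, tmp_path):
        p = tmp_path / "db.tsv"
        p.write_text(DB_HEADER + "m1\tCCO\tt1\tactive\n")
        db = load_reference_database(p)
        queries = {"q": make_molecule("q", "CCCO")}  # homologue, not identical
        preds = [_pred("q", "t1")]
        classify_interactions(preds, db, queries, None)
        assert preds[0].provenance == NEW


class TestExpressionFilter:
    def _expr(self, tmp_path, body):
        p = tmp_path / "expr.tsv"
        p.write_text(body)
        return load_expression_matrix(p)

    def test_zero_matrix_keeps_only_unknown(self, tmp_path):
        expr = self._expr(tmp_path, "target_id\tliver\nt1\t0\nt2\t0\n")
        preds = [_pred("q", t) for t in ("t1", "t2", "t_unknown")]
        kept = filter_by_expression(preds, expr, "liver", min_expr=1.0)
        assert [p.target_id for p in kept] == ["t_unknown"]
        assert kept[0].expression_unknown

    def test_min_expr_zero_is_identity(self, tmp_path):
        expr = self._expr(tmp_path, "target_id\tliver\nt1\t0\nt2\t3\n")
        preds = [_pred("q", t) for t in ("t1", "t2")]
        assert len(filter_by_expression(preds, expr, "liver", 0.0)) == 2

    def test_two_of_eight_retained(self, tmp_path):
        # eight predicted off-targets, two expressed above threshold
        body = "target_id\tblood_vessel\n" + "".join(
            f"t{i}\t{10.0 if i in (0, 1) else 0.1}\n" for i in range(8)
        )
        expr = self._expr(tmp_path, body)
        preds = [_pred("q", f"t{i}") for i in range(8)]
        kept = filter_by_expression(preds, expr, "blood_vessel", min_expr=1.0)
        assert sorted(p.target_id for p in kept) == ["t0", "t1"]


class TestSummaryArithmetic:
    def test_conservation_enforced(self):
        with pytest.raises(ValueError):
            summary_arithmetic(10, 100, 50, 40, 5)

    def test_mean_one_decimal(self):
        s = summary_arithmetic(857, 7990, 5065, 2925, 0)
        assert s["mean_interactions_per_compound"] == 9.3

    def test_empty_cohort(self):
        s = summary_arithmetic(0, 0, 0, 0, 0)
        assert s["mean_interactions_per_compound"] == 0.0


class TestGenerateReport:
    def test_ranking_order_and_ties(self, default_config):
        preds = [
            _pred("q", "t_b", s=0.8, n_above=4),
            _pred("q", "t_a", s=1.0, n_above=1, provenance=TRAINING_SET),
            _pred("q", "t_c", s=0.8, n_above=3),
        ]
        report = generate_report(preds, default_config)
        order = report.predictions.sort_values("rank")["target_id"].tolist()
        assert order == ["t_a", "t_b", "t_c"]

    def test_empty_prediction_set(self, default_config):
        report = generate_report([], default_config, n_compounds=5)
        assert report.summary["total_interactions"] == 0
        assert len(report.predictions) == 0

    def test_conservation_and_brute_force_recount(self, default_config):
        rng = np.random.default_rng(0)
        provs = [TRAINING_SET, CONFIRMED, NEW]
        preds = [
            _pred(f"q{i%7}", f"t{i}", s=float(rng.uniform(0.6, 1)),
                  provenance=provs[i % 3])
            for i in range(40)
        ]
        report = generate_report(preds, default_config)
        s = report.summary
        assert s["confirmed"] + s["new"] + s["training_set"] == s["total_interactions"]
        # independent recount straight off the rendered table
        df = report.predictions
        for prov in provs:
            assert s[prov if prov != TRAINING_SET else "training_set"] == (
                (df["provenance"] == prov).sum()
            )

    def test_alert_annotation_join(self, default_config):
        preds = [_pred("q", "t1"), _pred("q", "t2")]
        report = generate_report(preds, default_config, alert_table={"t1": "QT prolongation"})
        df = report.predictions.set_index("target_id")
        assert df.loc["t1", "alert"] == "QT prolongation"
        assert df.loc["t2", "alert"] is None

    def test_method_coverage_all_six(self, default_config):
        full = {m: 0.9 for m in ("SAS", "SAR", "SIM", "SEA", "MLM", "XPI")}
        preds = [
            _pred("q", "t1", scores=dict(full), n_above=6),
            _pred("q", "t2", scores={"SIM": 0.9, "SAS": 0.9, "XPI": 0.9}, n_above=3),
        ]
        cov = method_coverage(preds, default_config)
        assert cov["n_non_training_passing"] == 2
        assert cov["all_six"]["n"] == 1
        assert cov["per_method"]["SIM"]["fraction"] == 1.0
        assert cov["per_method"]["SEA"]["fraction"] == 0.5
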