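"""The six target-prediction methods: fitting, scoring, statistics."""
import math

import numpy as np
import pytest

from otsa import OTSAConfig
from otsa.chemdata import load_reference_database, make_molecule
from otsa.predictors import (
    EULER_MASCHERONI,
    PreparedDatabase,
    SEABackground,
    fit_all,
    fit_power_law,
    mine_sas,
    prepare_query,
    raw_score,
    reduced_graph,
    sea_calibrate,
    sea_score_from_evalue,
    sea_statistics,
    xpi_matrix,
    _contains,
)

DB_HEADER = "mol_id\tsmiles\ttarget_id\tlabel\n"


def _db(tmp_path, rows):
    p = tmp_path / "db.tsv"
    p.write_text(DB_HEADER + "".join("\t".join(r) + "\n" for r in rows))
    return load_reference_database(p)


class TestXPI:
    def test_disjoint_targets_zero(self, tmp_path):
        db = _db(tmp_path, [
            ("m1", "CCO", "t1", "active"), ("m2", "CCN", "t1", "active"),
            ("m3", "CCC", "t2", "active"), ("m4", "CCCl", "t2", "active"),
        ])
        prep = PreparedDatabase(db, OTSAConfig())
        x = xpi_matrix(prep)
        assert x[0, 1] == 0.0
        assert x[0, 0] == x[1, 1] == 1.0

    def test_containment_gives_one(self, tmp_path):
        db = _db(tmp_path, [
            ("m1", "CCO", "t1", "active"), ("m2", "CCN", "t1", "active"),
            ("m3", "CCC", "t1", "active"),
            ("m1", "CCO", "t2", "active"), ("m2", "CCN", "t2", "active"),
        ])
        prep = PreparedDatabase(db, OTSAConfig())
        x = xpi_matrix(prep)
        i, j = prep.target_ids.index("t1"), prep.target_ids.index("t2")
        assert x[i, j] == 1.0

    def test_identical_query_propagates_cross_index(self, fitted_small):
        # query identical to an active of u scores X(u,t) on every linked t
        prep = fitted_small.prep
        model = fitted_small.models["XPI"]
        u = prep.target_ids[0]
        active0 = prep.actives[u][0]
        q = prepare_query(prep.db.compounds[active0], prep.config)
        scores = model.score(q)
        x = xpi_matrix(prep)
        for j, t in enumerate(prep.target_ids):
            expected = max(
                x[i, j] * 1.0 if prep.target_ids[i] == u else 0.0
                for i in range(len(prep.target_ids))
            )
            if t == u:
                assert scores[t][0] == pytest.approx(1.0)


class TestSEA:
    def test_raw_score_identical_singletons(self, fitted_small):
        prep = fitted_small.prep
        fp = prep.features[prep.mol_ids[0]].descriptors.fingerprint
        assert raw_score([fp], [fp], tau_T=0.57) == pytest.approx(1.0)

    def test_raw_score_below_threshold_zero(self):
        a = make_molecule("a", "CCCCCCCC")
        b = make_molecule("b", "O=S(=O)(N)c1ccc(F)cc1")
        from otsa.descriptors import compute_fingerprint

        fa, fb = compute_fingerprint(a), compute_fingerprint(b)
        assert raw_score([fa], [fb], tau_T=0.99) == 0.0

    def test_power_law_recovery_within_5pct(self):
        x = np.logspace(1, 4, 30)
        y = 0.01 * x**1.0
        a, b = fit_power_law(x, y)
        assert a == pytest.approx(0.01, rel=0.05)
        assert b == pytest.approx(1.0, rel=0.05)

    def test_statistics_closed_form_at_zero(self):
        bg = SEABackground(0.57, a=0.01, b=1.0, c=0.005, e=0.8, n_random_sets=0, seed=0)
        raw = bg.mu(100.0)
        z, p, e_val = sea_statistics(raw, 10, 10, bg, n_targets=50)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0 - math.exp(-math.exp(-EULER_MASCHERONI)), abs=1e-9)
        assert p == pytest.approx(0.4296, abs=5e-4)
        assert e_val == pytest.approx(p * 50)

    def test_statistics_tail_limits(self):
        bg = SEABackground(0.57, 0.01, 1.0, 0.005, 0.8, 0, 0)
        _, p_hi, e_hi = sea_statistics(1e6, 10, 10, bg, 50)
        _, p_lo, e_lo = sea_statistics(-1e6, 10, 10, bg, 50)
        assert p_hi == pytest.approx(0.0, abs=1e-12)
        assert e_hi == pytest.approx(0.0, abs=1e-12)
        assert p_lo == pytest.approx(1.0)
        assert e_lo == pytest.approx(50.0)

    def test_e_monotone_decreasing_in_raw(self):
        bg = SEABackground(0.57, 0.01, 1.0, 0.005, 0.8, 0, 0)
        evals = [sea_statistics(r, 5, 5, bg, 10)[2] for r in (0.0, 1.0, 5.0, 20.0)]
        assert all(a >= b for a, b in zip(evals, evals[1:]))

    def test_score_mapping_bounds(self):
        assert sea_score_from_evalue(1.0) == 0.0
        assert sea_score_from_evalue(2.0) == 0.0
        assert sea_score_from_evalue(1e-24) == pytest.approx(0.6)
        assert sea_score_from_evalue(1e-300) == 1.0

    def test_calibration_reproducible_and_positive_sigma(self, small_db, default_config):
        db, _ = small_db
        prep = PreparedDatabase(db, default_config)
        bg1 = sea_calibrate(prep, 0.57, 200, seed=3)
        bg2 = sea_calibrate(prep, 0.57, 200, seed=3)
        assert (bg1.a, bg1.b, bg1.c, bg1.e) == (bg2.a, bg2.b, bg2.c, bg2.e)
        for x in (4.0, 100.0, 2500.0):
            assert bg1.sigma(x) > 0

    def test_self_consistency_own_ligand_set(self, fitted_small):
        # a target's own full ligand set queried against itself gives z > 0
        prep = fitted_small.prep
        bg = fitted_small.models["SEA"].background
        t = prep.target_ids[0]
        fps = prep.fingerprints(prep.actives[t])
        rs = raw_score(fps, fps, bg.tau_T)
        z, _, _ = sea_statistics(rs, len(fps), len(fps), bg, len(prep.target_ids))
        assert z > 0


class TestSAS:
    def test_mining_recovers_planted_motif(self):
        cfg = OTSAConfig(f_a=0.8, f_b=0.1)
        actives = [
            reduced_graph(make_molecule(f"a{i}", smi).smiles_canonical)
            for i, smi in enumerate(
                ["OC(=O)c1ccc(C)cc1", "OC(=O)c1ccc(CC)cc1", "OC(=O)c1ccc(F)cc1",
                 "OC(=O)c1ccc(Cl)cc1", "OC(=O)c1ccc(OC)cc1"]
            )
        ]
        background = [
            reduced_graph(make_molecule(f"b{i}", smi).smiles_canonical)
            for i, smi in enumerate(
                ["CCCCCC", "CCOCC", "c1ccccc1", "CCNCC", "CCCCCl",
                 "c1ccncc1", "CCCO", "CC(C)CC", "CCSC", "CCCC(C)C"]
            )
        ]
        patterns = mine_sas(actives, background, cfg)
        assert patterns
        best = patterns[0]
        assert all(_contains(g, best.graph) for g in actives)
        assert best.background_fraction <= 0.1
        assert best.active_support >= 0.8

    def test_no_pattern_when_actives_generic(self):
        cfg = OTSAConfig(f_a=0.8, f_b=0.1, sas_max_size=4)
        graphs = [
            reduced_graph(make_molecule(f"g{i}", smi).smiles_canonical)
            for i, smi in enumerate(["CCCC", "CCCCC", "CCCCCC"])
        ]
        # background identical to actives: nothing can be specific
        assert mine_sas(graphs, graphs, cfg) == []

    def test_score_floor_and_bonus(self, fitted_small):
        model = fitted_small.models["SAS"]
        prep = fitted_small.prep
        t = next(iter(model.patterns))
        q = prepare_query(prep.db.compounds[prep.actives[t][0]], prep.config)
        scores = model.score(q)
        assert t in scores
        assert 0.6 <= scores[t][0] <= 1.0


class TestSIM:
    def test_training_active_scores_one(self, fitted_small):
        prep = fitted_small.prep
        t = prep.target_ids[0]
        q = prepare_query(prep.db.compounds[prep.actives[t][0]], prep.config)
        scores = fitted_small.models["SIM"].score(q)
        assert scores[t][0] == pytest.approx(1.0)

    def test_dissimilar_query_not_emitted(self, fitted_small):
        q = prepare_query(make_molecule("q", "[SiH3][SiH2][SiH3]"), fitted_small.prep.config)
        rows = [r for r in fitted_small.score_query(q) if r.method_id == "SIM"]
        assert rows == []


class TestSARMLMSanity:
    def test_held_out_actives_outscore_decoys(self, synthetic_db, default_config):
        """Held-out chemotype members score higher on their own target than
        size-matched foreign queries (median difference positive)."""
        db, truth = synthetic_db
        ens = fit_all(db, default_config, seed=17)
        withheld = truth.withheld_queries
        own = [q for q in withheld if truth.chemotype_of[q.mol_id].startswith("c0_")]
        foreign = [q for q in withheld if truth.chemotype_of[q.mol_id].startswith("c3_")]
        n = min(len(own), len(foreign))
        for method in ("SAR", "MLM"):
            model = ens.models[method]
            own_scores = [
                model.score(prepare_query(q, default_config)).get("t0", (0.0, ""))[0]
                for q in own[:n]
            ]
            foreign_scores = [
                model.score(prepare_query(q, default_config)).get("t0", (0.0, ""))[0]
                for q in foreign[:n]
            ]
            assert np.median(own_scores) - np.median(foreign_scores) > 0


class TestDeterminism:
    def test_fixed_seed_reproduces_score_table(self, small_db, default_config):
        db, truth = small_db
        query = truth.withheld_queries[0]
        rows = []
        for _ in range(2):
            ens = fit_all(db, default_config, seed=17)
            q = prepare_query(query, default_config)
            rows.append(ens.score_query(q))
        assert rows[0] == rows[1]

    def test_all_scores_in_unit_interval(self, fitted_small, small_db):
        _, truth = small_db
        for query in truth.withheld_queries[:4]:
            q = prepare_query(query, fitted_small.prep.config)
            for r in fitted_small.score_query(q):
                assert 0.0 <= r.score <= 1.0
                assert r.evidence
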