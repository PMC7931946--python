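"""The six ligand-centric target-prediction methods.

Each method is fitted against a ReferenceDatabase and scores a query molecule
per target on [0, 1]:

* SIM — nearest-ligand similarity: for each target, the maximum over actives
  of the mean of fingerprint Tanimoto, PHRAG multiset Tanimoto and a SHED
  Euclidean-distance decay exp(-d/sigma).
* SEA — set-wise similarity: the sum of above-threshold Tanimoto values
  between the query and a target's ligand set, standardized against a
  random-set background (power-law mean and spread in the product of set
  sizes) and converted to an extreme-value E-value; strong E-values map to
  high scores.
* SAS — similarity active subgraph: a minimal feature-labelled subgraph mined
  from a target's actives that is frequent among actives and rare in a
  background sample; a query matching the subgraph scores at least 0.6, plus
  a bonus for background specificity.
* SAR — a per-target regularized logistic classifier on standardized
  FPD + SHED + global-property vectors, actives versus sampled decoys.
* MLM — a per-target consensus of three classifiers on FPD vectors (decision
  tree ensemble, max-margin kernel classifier, small feed-forward network);
  the consensus score is the mean class probability when at least two
  classifiers vote positive, otherwise capped below threshold.
* XPI — cross-pharmacology: targets are linked by shared actives,
  X(t,u) = |actives(t) n actives(u)| / min(|actives(t)|, |actives(u)|); a
  query propagates its nearest-neighbour similarity through the matrix.

Scoring is deterministic given (model, query); every stochastic fitting step
takes an explicit seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
from networkx.algorithms import isomorphism
from rdkit import DataStructs
from rdkit.Chem import Crippen, Descriptors as RDDescriptors, rdMolDescriptors
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .chemdata import Molecule, ReferenceDatabase, as_rdkit
from .config import METHODS, OTSAConfig
from .descriptors import (
    MolDescriptors,
    assign_features,
    compute_descriptors,
    shed_distance,
    tanimoto,
)

logger = logging.getLogger(__name__)

EULER_MASCHERONI = 0.5772156649


class MethodScore(NamedTuple):
    mol_id: str
    target_id: str
    method_id: str
    score: float
    evidence: str


# ---------------------------------------------------------------------------
# shared preparation


def reduced_graph(smiles_canonical: str) -> nx.Graph:
    """Feature-reduced graph: atoms become feature-label nodes, bonds edges."""
    m = as_rdkit(smiles_canonical)
    labels = assign_features(smiles_canonical)
    g = nx.Graph()
    for i, tags in enumerate(labels):
        g.add_node(i, label="".join(sorted(tags)) if tags else "0")
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in m.GetBonds())
    return g


def _global_props(smiles_canonical: str) -> np.ndarray:
    m = as_rdkit(smiles_canonical)
    return np.array(
        [
            RDDescriptors.MolWt(m),
            Crippen.MolLogP(m),
            rdMolDescriptors.CalcTPSA(m),
            m.GetNumHeavyAtoms(),
            rdMolDescriptors.CalcNumRings(m),
        ]
    )


@dataclass
class QueryFeatures:
    """Everything the six methods need about one molecule, computed once."""

    molecule: Molecule
    descriptors: MolDescriptors
    graph: nx.Graph
    sar_vector: np.ndarray  # FPD + SHED + global properties
    fpd_vector: np.ndarray


def prepare_query(molecule: Molecule, config: OTSAConfig) -> QueryFeatures:
    desc = compute_descriptors(
        molecule, L=config.L, radius=config.fp_radius, n_bits=config.fp_bits
    )
    fpd_flat = desc.fpd.flatten()
    sar_vec = np.concatenate([fpd_flat, desc.shed, _global_props(molecule.smiles_canonical)])
    return QueryFeatures(
        molecule=molecule,
        descriptors=desc,
        graph=reduced_graph(molecule.smiles_canonical),
        sar_vector=sar_vec,
        fpd_vector=fpd_flat,
    )


class PreparedDatabase:
    """Descriptor cache over a ReferenceDatabase shared by all methods."""

    def __init__(self, db: ReferenceDatabase, config: OTSAConfig):
        self.db = db
        self.config = config
        self.mol_ids = sorted(db.compounds)
        self.features: dict[str, QueryFeatures] = {
            i: prepare_query(db.compounds[i], config) for i in self.mol_ids
        }
        self.target_ids = sorted(db.targets)
        self.actives: dict[str, list[str]] = {
            t: sorted(db.targets[t].actives) for t in self.target_ids
        }

    def fingerprints(self, mol_ids: list[str]):
        return [self.features[i].descriptors.fingerprint for i in mol_ids]


# ---------------------------------------------------------------------------
# SIM


class SIMModel:
    method_id = "SIM"

    def __init__(self, prep: PreparedDatabase):
        self.prep = prep
        self.sigma = prep.config.sigma_s

    def score(self, q: QueryFeatures) -> dict[str, tuple[float, str]]:
        out: dict[str, tuple[float, str]] = {}
        for t in self.prep.target_ids:
            best, best_id = 0.0, ""
            qd = q.descriptors
            for a in self.prep.actives[t]:
                ad = self.prep.features[a].descriptors
                tc = tanimoto(qd.fingerprint, ad.fingerprint)
                ph = _phrag_sim(qd.phrag, ad.phrag)
                sd = np.exp(-shed_distance(qd.shed, ad.shed) / self.sigma)
                s = (tc + ph + sd) / 3.0
                if s > best:
                    best, best_id = s, a
            if best > 0:
                out[t] = (min(best, 1.0), f"nn={best_id}")
        return out


def _phrag_sim(a, b) -> float:
    from .descriptors import phrag_similarity

    return phrag_similarity(a, b)


# ---------------------------------------------------------------------------
# SEA


@dataclass
class SEABackground:
    tau_T: float
    a: float  # mean fit  mu(x) = a * x^b
    b: float
    c: float  # spread fit sigma(x) = c * x^e
    e: float
    n_random_sets: int
    seed: int

    def mu(self, x: float) -> float:
        return self.a * x**self.b

    def sigma(self, x: float) -> float:
        return self.c * x**self.e


def fit_power_law(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of y = a * x^b on log-transformed values."""
    mask = (x > 0) & (y > 0)
    if mask.sum() < 2:
        raise ValueError("not enough positive points for a power-law fit")
    lx, ly = np.log(x[mask]), np.log(y[mask])
    b, log_a = np.polyfit(lx, ly, 1)
    return float(np.exp(log_a)), float(b)


def raw_score(fps_a: list, fps_b: list, tau_T: float) -> float:
    """Sum of pairwise Tanimoto values at or above the threshold."""
    total = 0.0
    for fa in fps_a:
        sims = DataStructs.BulkTanimotoSimilarity(fa, fps_b)
        total += sum(s for s in sims if s >= tau_T)
    return total


def sea_calibrate(
    prep: PreparedDatabase, tau_T: float, n_random_sets: int, seed: int
) -> SEABackground:
    """Fit the random-set background: power laws for the raw-score mean and
    spread as functions of the set-size product."""
    rng = np.random.default_rng(seed)
    ids = prep.mol_ids
    if len(ids) < 20:
        raise ValueError("SEA calibration needs at least 20 compounds")
    hi = min(prep.config.sea_max_set, len(ids) // 2)
    xs, rs = [], []
    for _ in range(n_random_sets):
        n1 = int(np.exp(rng.uniform(np.log(2), np.log(hi))))
        n2 = int(np.exp(rng.uniform(np.log(2), np.log(hi))))
        set_a = list(rng.choice(ids, size=n1, replace=False))
        set_b = list(rng.choice(ids, size=n2, replace=False))
        rs.append(raw_score(prep.fingerprints(set_a), prep.fingerprints(set_b), tau_T))
        xs.append(n1 * n2)
    xs_arr, rs_arr = np.array(xs, dtype=float), np.array(rs)
    if rs_arr.max() == 0:
        raise ValueError(
            f"degenerate SEA background: all raw scores zero at tau_T={tau_T}; lower tau_T"
        )
    # log-spaced bins over the product range; fit on bins with signal
    edges = np.exp(np.linspace(np.log(xs_arr.min()), np.log(xs_arr.max() + 1), 13))
    centers, means, stds = [], [], []
    for lo, hi_e in zip(edges[:-1], edges[1:]):
        m = (xs_arr >= lo) & (xs_arr < hi_e)
        if m.sum() >= 5:
            centers.append(np.sqrt(lo * hi_e))
            means.append(rs_arr[m].mean())
            stds.append(rs_arr[m].std(ddof=1))
    a, b = fit_power_law(np.array(centers), np.array(means))
    c, e = fit_power_law(np.array(centers), np.array(stds))
    return SEABackground(tau_T, a, b, c, e, n_random_sets, seed)


def sea_statistics(
    raw: float, n1: int, n2: int, bg: SEABackground, n_targets: int
) -> tuple[float, float, float]:
    """(z, p, E): extreme-value tail probability of the standardized raw score."""
    x = float(n1 * n2)
    sigma = bg.sigma(x)
    if sigma <= 0:
        raise ValueError(f"invalid SEA background: sigma({x}) <= 0")
    z = (raw - bg.mu(x)) / sigma
    arg = -z * np.pi / np.sqrt(6.0) - EULER_MASCHERONI
    # guard the double exponential against overflow at very negative z
    p = 1.0 - np.exp(-np.exp(min(arg, 700.0)))
    p = float(min(max(p, 0.0), 1.0))
    return float(z), p, p * n_targets


def sea_score_from_evalue(e_value: float) -> float:
    """Map an E-value to [0, 1]: 0 for E >= 1, else -log10(E)/40 capped at 1."""
    if e_value >= 1.0:
        return 0.0
    return min(1.0, -np.log10(max(e_value, 1e-300)) / 40.0)


class SEAModel:
    method_id = "SEA"

    def __init__(self, prep: PreparedDatabase, seed: int):
        cfg = prep.config
        self.prep = prep
        self.background = sea_calibrate(prep, cfg.tau_T, cfg.sea_n_random_sets, seed)
        self.n_targets = len(prep.target_ids)

    def score(self, q: QueryFeatures) -> dict[str, tuple[float, str]]:
        out: dict[str, tuple[float, str]] = {}
        for t in self.prep.target_ids:
            fps = self.prep.fingerprints(self.prep.actives[t])
            rs = raw_score([q.descriptors.fingerprint], fps, self.background.tau_T)
            _, _, e_val = sea_statistics(rs, 1, len(fps), self.background, self.n_targets)
            s = sea_score_from_evalue(e_val)
            if s > 0:
                out[t] = (s, f"E={e_val:.3g}")
        return out


# ---------------------------------------------------------------------------
# SAS


@dataclass
class SASPattern:
    graph: nx.Graph
    pattern_id: str
    active_support: float
    background_fraction: float

    @property
    def specificity(self) -> float:
        return 1.0 - self.background_fraction


def _node_match(n1: dict, n2: dict) -> bool:
    return n1["label"] == n2["label"]


def _contains(host: nx.Graph, pattern: nx.Graph) -> bool:
    gm = isomorphism.GraphMatcher(host, pattern, node_match=_node_match)
    return gm.subgraph_is_monomorphic()


def _connected_subgraphs(g: nx.Graph, size: int, cap: int) -> list[frozenset]:
    """Deterministic enumeration of connected node sets of a given size."""
    found: set[frozenset] = set()
    nodes = sorted(g.nodes)
    stack = [frozenset([n]) for n in nodes]
    seen: set[frozenset] = set(stack)
    while stack and len(found) < cap:
        cur = stack.pop(0)
        if len(cur) == size:
            found.add(cur)
            continue
        frontier = sorted(
            {nb for n in cur for nb in g.neighbors(n)} - cur
        )
        for nb in frontier:
            nxt = cur | {nb}
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return sorted(found, key=lambda s: tuple(sorted(s)))[:cap]


def mine_sas(
    active_graphs: list[nx.Graph],
    background_graphs: list[nx.Graph],
    config: OTSAConfig,
    n_patterns: int | None = None,
) -> list[SASPattern]:
    """Mine minimal labelled subgraphs frequent in actives, rare in background.

    Candidates are connected subgraphs of a seed active (the smallest), grown
    from size 2 upward; the first size with any qualifying pattern wins
    (minimality).  Up to `n_patterns` patterns are kept, preferring low
    background incidence then high active support.
    """
    if n_patterns is None:
        n_patterns = config.sas_n_patterns
    if not active_graphs:
        return []
    seed_graph = min(active_graphs, key=lambda g: (g.number_of_nodes(), _graph_key(g)))
    results: list[SASPattern] = []
    for size in range(2, config.sas_max_size + 1):
        candidates = _connected_subgraphs(seed_graph, size, config.sas_max_candidates)
        seen_hashes: set[str] = set()
        qualifying: list[SASPattern] = []
        for node_set in candidates:
            pat = seed_graph.subgraph(node_set).copy()
            if not nx.is_connected(pat):
                continue
            h = nx.weisfeiler_lehman_graph_hash(pat, node_attr="label", iterations=2)
            if h in seen_hashes:
                continue
            seen_hashes.add(h)
            support = sum(_contains(g, pat) for g in active_graphs) / len(active_graphs)
            if support < config.f_a:
                continue
            if background_graphs:
                bg = sum(_contains(g, pat) for g in background_graphs) / len(background_graphs)
            else:
                bg = 0.0
            if bg <= config.f_b:
                qualifying.append(SASPattern(pat, h[:12], support, bg))
        if qualifying:
            qualifying.sort(key=lambda p: (p.background_fraction, -p.active_support, p.pattern_id))
            results = qualifying[:n_patterns]
            break
    return results


def _graph_key(g: nx.Graph) -> str:
    return nx.weisfeiler_lehman_graph_hash(g, node_attr="label", iterations=2)


def _leader_clusters(prep: PreparedDatabase, mol_ids: list[str],
                     threshold: float = 0.6) -> list[list[str]]:
    """Deterministic leader clustering by fingerprint Tanimoto: a compound
    joins the first cluster whose leader it matches at or above threshold."""
    leaders: list[str] = []
    clusters: list[list[str]] = []
    for i in sorted(mol_ids):
        fp = prep.features[i].descriptors.fingerprint
        for k, lead in enumerate(leaders):
            if tanimoto(fp, prep.features[lead].descriptors.fingerprint) >= threshold:
                clusters[k].append(i)
                break
        else:
            leaders.append(i)
            clusters.append([i])
    return clusters


class SASModel:
    method_id = "SAS"

    def __init__(self, prep: PreparedDatabase, seed: int):
        self.prep = prep
        cfg = prep.config
        rng = np.random.default_rng(seed)
        self.patterns: dict[str, list[SASPattern]] = {}
        for t in prep.target_ids:
            actives = prep.actives[t]
            if len(actives) < cfg.min_actives:
                logger.info("SAS: skipping %s (<%d actives)", t, cfg.min_actives)
                continue
            pool = sorted(set(prep.mol_ids) - set(actives))
            n_bg = min(len(pool), max(len(actives), 20))
            bg_ids = sorted(rng.choice(pool, size=n_bg, replace=False)) if pool else []
            bg_graphs = [prep.features[i].graph for i in bg_ids]
            # a target's actives may span several chemotype series; one pattern
            # is mined per similarity cluster (largest first), up to the cap
            clusters = _leader_clusters(prep, actives)
            clusters.sort(key=lambda c: (-len(c), c[0]))
            mined: list[SASPattern] = []
            for cluster in clusters[: cfg.sas_n_patterns]:
                if len(cluster) < 2:
                    continue
                graphs = [prep.features[i].graph for i in cluster]
                mined.extend(mine_sas(graphs, bg_graphs, cfg, n_patterns=1))
            if mined:
                self.patterns[t] = mined[: cfg.sas_n_patterns]
            else:
                logger.info("SAS: no qualifying subgraph for %s", t)

    def score(self, q: QueryFeatures) -> dict[str, tuple[float, str]]:
        out: dict[str, tuple[float, str]] = {}
        for t, patterns in self.patterns.items():
            best: SASPattern | None = None
            for pat in patterns:
                if _contains(q.graph, pat.graph):
                    if best is None or pat.specificity > best.specificity:
                        best = pat
            if best is not None:
                out[t] = (
                    min(0.6 + 0.4 * best.specificity, 1.0),
                    f"sas={best.pattern_id}",
                )
        return out


# ---------------------------------------------------------------------------
# decoy sampling shared by SAR and MLM


def xpi_matrix(prep: PreparedDatabase) -> np.ndarray:
    """X(t,u) = |actives(t) n actives(u)| / min(|actives(t)|, |actives(u)|)."""
    ts = prep.target_ids
    x = np.eye(len(ts))
    for i, t in enumerate(ts):
        for j in range(i + 1, len(ts)):
            u = ts[j]
            at, au = set(prep.actives[t]), set(prep.actives[u])
            denom = min(len(at), len(au))
            val = len(at & au) / denom if denom else 0.0
            x[i, j] = x[j, i] = val
    return x


def sample_decoys(
    prep: PreparedDatabase, target: str, n: int, seed: int, x_matrix: np.ndarray
) -> list[str]:
    """Decoys for one target: other targets' actives, excluding the target's
    own actives, actives of strongly cross-pharmacological targets and
    compounds too similar to any active (likely unannotated cross-actives)."""
    cfg = prep.config
    ts = prep.target_ids
    ti = ts.index(target)
    excluded = set(prep.actives[target])
    for j, u in enumerate(ts):
        if j != ti and x_matrix[ti, j] > cfg.xpi_decoy_exclude:
            excluded |= set(prep.actives[u])
    pool = sorted(
        {i for t in ts for i in prep.actives[t]} - excluded
    )
    active_fps = prep.fingerprints(prep.actives[target])
    kept = []
    for cand in pool:
        fp = prep.features[cand].descriptors.fingerprint
        sims = DataStructs.BulkTanimotoSimilarity(fp, active_fps)
        if max(sims, default=0.0) < cfg.decoy_sim_threshold:
            kept.append(cand)
    rng = np.random.default_rng(seed)
    if len(kept) <= n:
        return kept
    return sorted(rng.choice(kept, size=n, replace=False))


# ---------------------------------------------------------------------------
# SAR


class SARModel:
    method_id = "SAR"

    def __init__(self, prep: PreparedDatabase, seed: int):
        self.prep = prep
        cfg = prep.config
        x = xpi_matrix(prep)
        self.models: dict[str, tuple[StandardScaler, LogisticRegression]] = {}
        for ti, t in enumerate(prep.target_ids):
            actives = prep.actives[t]
            if len(actives) < cfg.min_actives:
                continue
            decoys = sample_decoys(prep, t, cfg.decoy_ratio * len(actives), seed + ti, x)
            if not decoys:
                continue
            ids = list(actives) + list(decoys)
            xmat = np.array([prep.features[i].sar_vector for i in ids])
            y = np.array([1] * len(actives) + [0] * len(decoys))
            scaler = StandardScaler().fit(xmat)
            clf = LogisticRegression(
                C=1.0, class_weight="balanced", max_iter=2000, random_state=seed + ti
            ).fit(scaler.transform(xmat), y)
            self.models[t] = (scaler, clf)

    def score(self, q: QueryFeatures) -> dict[str, tuple[float, str]]:
        out: dict[str, tuple[float, str]] = {}
        for t, (scaler, clf) in self.models.items():
            p = float(clf.predict_proba(scaler.transform(q.sar_vector[None, :]))[0, 1])
            out[t] = (min(max(p, 0.0), 1.0), f"p={p:.3f}")
        return out


# ---------------------------------------------------------------------------
# MLM


class MLMModel:
    method_id = "MLM"

    def __init__(self, prep: PreparedDatabase, seed: int):
        self.prep = prep
        cfg = prep.config
        x = xpi_matrix(prep)
        self.models: dict[str, tuple[StandardScaler, list]] = {}
        for ti, t in enumerate(prep.target_ids):
            actives = prep.actives[t]
            if len(actives) < cfg.min_actives:
                continue
            decoys = sample_decoys(prep, t, cfg.decoy_ratio * len(actives), seed + 1000 + ti, x)
            if not decoys:
                continue
            ids = list(actives) + list(decoys)
            xmat = np.array([prep.features[i].fpd_vector for i in ids])
            y = np.array([1] * len(actives) + [0] * len(decoys))
            scaler = StandardScaler().fit(xmat)
            xs = scaler.transform(xmat)
            classifiers = [
                RandomForestClassifier(
                    n_estimators=100, class_weight="balanced", random_state=seed + ti
                ),
                CalibratedClassifierCV(
                    SVC(kernel="rbf", class_weight="balanced", random_state=seed + ti),
                    ensemble=False, cv=3,
                ),
                MLPClassifier(hidden_layer_sizes=(16,), max_iter=800,
                              random_state=seed + ti),
            ]
            for clf in classifiers:
                clf.fit(xs, y)
            self.models[t] = (scaler, classifiers)

    def score(self, q: QueryFeatures) -> dict[str, tuple[float, str]]:
        cfg = self.prep.config
        out: dict[str, tuple[float, str]] = {}
        for t, (scaler, classifiers) in self.models.items():
            xq = scaler.transform(q.fpd_vector[None, :])
            probs = [float(clf.predict_proba(xq)[0, 1]) for clf in classifiers]
            votes = sum(p >= cfg.mlm_vote_threshold for p in probs)
            mean_p = float(np.mean(probs))
            score = mean_p if votes >= 2 else min(mean_p, cfg.mlm_cap)
            out[t] = (min(max(score, 0.0), 1.0), f"votes={votes} p={mean_p:.3f}")
        return out


# ---------------------------------------------------------------------------
# XPI


class XPIModel:
    method_id = "XPI"

    def __init__(self, prep: PreparedDatabase):
        self.prep = prep
        self.x = xpi_matrix(prep)

    def score(self, q: QueryFeatures) -> dict[str, tuple[float, str]]:
        ts = self.prep.target_ids
        # nearest-neighbour similarity of the query to each target's actives
        sim_nn = np.zeros(len(ts))
        for i, t in enumerate(ts):
            fps = self.prep.fingerprints(self.prep.actives[t])
            sims = DataStructs.BulkTanimotoSimilarity(q.descriptors.fingerprint, fps)
            sim_nn[i] = max(sims, default=0.0)
        out: dict[str, tuple[float, str]] = {}
        for j, t in enumerate(ts):
            contrib = sim_nn * self.x[:, j]
            best = int(np.argmax(contrib))
            s = float(contrib[best])
            if s > 0:
                out[t] = (min(s, 1.0), f"via={ts[best]}")
        return out


# ---------------------------------------------------------------------------
# public fitting / scoring API


def fit_method(method_id: str, prep: PreparedDatabase, seed: int):
    if method_id == "SIM":
        return SIMModel(prep)
    if method_id == "SEA":
        return SEAModel(prep, seed)
    if method_id == "SAS":
        return SASModel(prep, seed)
    if method_id == "SAR":
        return SARModel(prep, seed)
    if method_id == "MLM":
        return MLMModel(prep, seed)
    if method_id == "XPI":
        return XPIModel(prep)
    raise ValueError(f"unknown method {method_id!r}")


@dataclass
class FittedEnsemble:
    prep: PreparedDatabase
    models: dict[str, object]
    db_fingerprint: str
    seed: int

    def score_query(self, q: QueryFeatures) -> list[MethodScore]:
        """All emitted method scores for one query (floored, clipped)."""
        floor = self.prep.config.report_floor
        rows: list[MethodScore] = []
        for method_id in METHODS:
            model = self.models[method_id]
            for target_id, (score, evidence) in sorted(model.score(q).items()):
                score = float(min(max(score, 0.0), 1.0))
                if score >= floor:
                    rows.append(
                        MethodScore(q.molecule.mol_id, target_id, method_id, score, evidence)
                    )
        return rows


def fit_all(db: ReferenceDatabase, config: OTSAConfig, seed: int | None = None) -> FittedEnsemble:
    seed = config.seed if seed is None else seed
    prep = PreparedDatabase(db, config)
    models = {m: fit_method(m, prep, seed) for m in METHODS}
    return FittedEnsemble(prep, models, db.fingerprint(), seed)
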