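"""Run-time configuration.

Every threshold that governs the prediction pipeline is named here so a run is
fully described by (reference database, query set, config, seed).  The defaults
are the conventional operating point: a predicted interaction is high-confidence
when at least ``k`` of the six methods score at or above ``tau``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

METHODS = ("SAS", "SAR", "SIM", "SEA", "MLM", "XPI")


@dataclass
class OTSAConfig:
    # consensus / aggregation
    tau: float = 0.6                  # per-method significance threshold
    k: int = 3                        # methods >= tau required for consensus
    tau_comparator: str = ">="        # ">=" or ">"
    weights: dict[str, float] | None = None  # None -> equal weights
    absent_as_zero: bool = False      # treat missing method scores as 0 in the mean
    report_floor: float = 0.2         # per-method scores below this are not emitted

    # descriptors
    L: int = 10                       # topological distance cap (bonds)
    four_feature_variant: bool = False  # restrict typing to D/A/H/R (10 pairs)
    fp_radius: int = 2
    fp_bits: int = 2048

    # SIM
    sigma_s: float = 1.0              # SHED-distance decay scale

    # SEA
    tau_T: float = 0.57               # Tanimoto floor for raw-score summation
    sea_n_random_sets: int = 300      # random set pairs for background calibration
    sea_max_set: int = 200

    # SAS mining
    f_a: float = 0.8                  # min fraction of actives containing the subgraph
    f_b: float = 0.1                  # max fraction of background containing it
    sas_max_size: int = 7             # subgraph node cap
    sas_max_candidates: int = 40      # candidate subgraphs evaluated per size
    sas_n_patterns: int = 3           # patterns stored per target

    # SAR / MLM
    min_actives: int = 5              # targets below this are skipped by SAS/SAR/MLM
    decoy_ratio: int = 3              # decoys per positive
    decoy_sim_threshold: float = 0.6  # decoys this similar to any active are excluded
    xpi_decoy_exclude: float = 0.8    # exclude actives of targets with X(u,t) above this
    mlm_vote_threshold: float = 0.5
    mlm_cap: float = 0.45             # MLM score cap when <2 classifiers vote positive

    seed: int = 17

    def method_weights(self) -> dict[str, float]:
        if self.weights is None:
            return {m: 1.0 for m in METHODS}
        w = {m: float(self.weights.get(m, 0.0)) for m in METHODS}
        if any(v < 0 for v in w.values()):
            raise ValueError("method weights must be non-negative")
        return w

    def passes_tau(self, score: float) -> bool:
        if self.tau_comparator == ">=":
            return score >= self.tau
        if self.tau_comparator == ">":
            return score > self.tau
        raise ValueError(f"unknown comparator {self.tau_comparator!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OTSAConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
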