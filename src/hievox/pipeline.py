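"""End-to-end experiment orchestration from a single config.

Synthesize (or load) calls -> extract features per call type -> common-
feature filter -> balance -> train flat and hierarchical classifiers ->
evaluate both (per-class metrics, paired Wilcoxon comparison) -> optional
feature-importance null test and sample-size sweep. A master seed
deterministically derives per-stage, per-call-type seeds, so rerunning the
same config reproduces every number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import audio_io, features
from .balance import BalanceRecipe, build_balanced_dataset
from .core import CALL_TYPES
from .evaluate import (chance_level_pct, evaluate_flat, evaluate_hierarchical,
                       paired_compare, sample_size_sweep)
from .importance import silhouette_null_test
from .synth import ColonySpec, generate_colony

log = logging.getLogger("hievox")


class SynthBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_females: int = 8
    n_males: int = 8
    calls_per_type: dict[str, int | list[int]] = Field(
        default_factory=lambda: {ct: 120 for ct in CALL_TYPES})
    twin_pairs: list[tuple[str, str, float]] = Field(default_factory=list)
    noise_snr_db: float = 20.0
    sample_rate_hz: int = 62_500
    sex_effect_hz: float = 500.0
    signature_scale: float = 1.0


class FeaturesBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    profile: str = "full"


class BalanceBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_calls: int = 25
    cap: int | None = None
    smote_k: int = 5


class ModelBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trees: int = 2500
    learning_rate: float = 0.1
    max_depth: int = 3
    n_folds: int = 10


class EvaluateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    roc_auc: bool = False


class ImportanceBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    k: int = 20
    n_draws: int = 100


class SweepBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    enabled: bool = False
    caps: list[int | None] = Field(default_factory=lambda: [50, 99, 197, None])


class ExperimentConfig(BaseModel):
    """Schema-validated experiment description; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str | None = None
    call_types: list[str] = Field(default_factory=lambda: list(CALL_TYPES))
    synth: SynthBlock | None = Field(default_factory=SynthBlock)
    manifest: str | None = None
    feature_table: dict[str, str] | None = None  # call_type -> path
    features: FeaturesBlock = Field(default_factory=FeaturesBlock)
    balance: BalanceBlock = Field(default_factory=BalanceBlock)
    model_sex: ModelBlock = Field(default_factory=lambda: ModelBlock(n_trees=500))
    model_id: ModelBlock = Field(default_factory=lambda: ModelBlock(n_trees=2500))
    evaluate: EvaluateBlock = Field(default_factory=EvaluateBlock)
    importance: ImportanceBlock = Field(default_factory=ImportanceBlock)
    sweep: SweepBlock = Field(default_factory=SweepBlock)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(master: int, *labels: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(("|".join((str(master),) + labels)).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def load_feature_matrices(cfg: ExperimentConfig) -> dict[str, "features.FeatureMatrix"]:
    """Produce one unfiltered feature matrix per call type from the
    configured source (synthetic colony, manifest, or feature tables)."""
    bank = features.get_bank(cfg.features.profile)
    out = {}
    if cfg.feature_table is not None:
        for ct, path in cfg.feature_table.items():
            out[ct] = audio_io.read_feature_table(path, allow_nonfinite=True)
        return out
    if cfg.manifest is not None:
        manifest, rejected = audio_io.read_manifest(cfg.manifest)
        if rejected:
            log.warning("manifest: %d row(s) rejected", len(rejected.rows))
        base = Path(cfg.manifest).parent
        by_type: dict[str, tuple[list, list]] = {}
        for rec in manifest.records:
            w = audio_io.read_wav(base / rec.file,
                                  expected_rate_hz=manifest.sample_rate_hz)
            lo = int(rec.start_s * w.rate_hz)
            hi = int(rec.end_s * w.rate_hz)
            from .core import Waveform
            seg = Waveform(samples=w.samples[lo:hi], rate_hz=w.rate_hz)
            by_type.setdefault(rec.call_type, ([], []))
            by_type[rec.call_type][0].append(seg)
            by_type[rec.call_type][1].append(rec)
        for ct, (ws, recs) in by_type.items():
            out[ct] = features.build_feature_matrix(ws, recs, bank=bank)
        return out
    # synthetic colony
    sb = cfg.synth or SynthBlock()
    spec = ColonySpec(
        n_females=sb.n_females, n_males=sb.n_males,
        calls_per_type={ct: sb.calls_per_type.get(ct, 0) for ct in cfg.call_types},
        twin_pairs=[tuple(p) for p in sb.twin_pairs],
        noise_snr_db=sb.noise_snr_db, sample_rate_hz=sb.sample_rate_hz,
        seed=_stage_seed(cfg.seed, "synth"),
        sex_effect_hz=sb.sex_effect_hz, signature_scale=sb.signature_scale)
    waveforms, records = generate_colony(spec)
    for ct in cfg.call_types:
        ws = [w for w, r in zip(waveforms, records) if r.call_type == ct]
        recs = [r for r in records if r.call_type == ct]
        if recs:
            out[ct] = features.build_feature_matrix(ws, recs, bank=bank)
    return out


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run every enabled stage and return the (JSON-serializable) report."""
    t0 = time.time()
    report: dict = {
        "provenance": {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                       "bank_version": features.get_bank(cfg.features.profile).bank_version},
        "call_types": {},
    }
    matrices = load_feature_matrices(cfg)
    sweep_input = {}
    for ct, raw in matrices.items():
        section: dict = {}
        try:
            t_stage = time.time()
            filtered = features.filter_common_features(raw)
            section["n_calls"] = filtered.n_calls
            section["n_features_raw"] = len(raw.feature_names)
            section["n_features_common"] = len(filtered.feature_names)
            sweep_input[ct] = filtered

            recipe = BalanceRecipe(
                min_calls=cfg.balance.min_calls, cap=cfg.balance.cap,
                smote_k=cfg.balance.smote_k,
                seed=_stage_seed(cfg.seed, "balance", ct))
            ds = build_balanced_dataset(filtered, target="individual",
                                        recipe=recipe)
            section["balance"] = {
                "counts_before": {str(k): int(v) for k, v in
                                  ds.class_counts_before.items()},
                "counts_after": {str(k): int(v) for k, v in
                                 ds.class_counts_after.items()},
                "dropped_classes": [str(c) for c in ds.dropped_classes],
                "n_synthetic": ds.n_synthetic,
            }
            n_classes = len(np.unique(ds.y))
            section["chance_pct"] = chance_level_pct(n_classes)

            flat_cfg = cfg.model_id.model_dump()
            flat_report, flat_model = evaluate_flat(
                ds, config=flat_cfg,
                random_state=_stage_seed(cfg.seed, "flat", ct),
                compute_roc_auc=cfg.evaluate.roc_auc)
            section["flat"] = flat_report.to_dict()

            hier = evaluate_hierarchical(
                ds, config_sex=cfg.model_sex.model_dump(),
                config_id=cfg.model_id.model_dump(),
                random_state=_stage_seed(cfg.seed, "hier", ct))
            section["hierarchical"] = {
                "sex": hier["sex_report"].to_dict(),
                "id": {s: r.to_dict() for s, r in hier["id_reports"].items()},
                "composed_per_individual": {
                    str(i): {"precision": float(row["precision"]),
                             "recall": float(row["recall"]),
                             "sex": str(row["sex"])}
                    for i, row in hier["composed"].iterrows()},
                "composed_summary": {
                    "precision_mean": float(hier["composed"]["precision"].mean()),
                    "precision_sd": float(hier["composed"]["precision"].std(ddof=1)),
                    "recall_mean": float(hier["composed"]["recall"].mean()),
                    "recall_sd": float(hier["composed"]["recall"].std(ddof=1)),
                },
                "routed": hier["routed_report"].to_dict(),
            }

            flat_p = flat_report.per_class["precision"]
            comp = hier["composed"].loc[flat_p.index]
            section["comparison"] = {
                "precision": paired_compare(flat_p.to_numpy(),
                                            comp["precision"].to_numpy()),
                "recall": paired_compare(
                    flat_report.per_class["recall"].to_numpy(),
                    comp["recall"].to_numpy()),
            }

            ranks = hier["model"].rank_features_per_component(
                top_k=cfg.importance.k)
            sets = {lvl: set(s.index) for lvl, s in ranks.items()}
            section["feature_overlap"] = _overlap_listing(sets)

            if cfg.importance.enabled:
                flat_rank = flat_model.rank_features(top_k=cfg.importance.k)
                nt = silhouette_null_test(
                    ds.X, ds.y, list(flat_rank.index), k=cfg.importance.k,
                    n_draws=cfg.importance.n_draws,
                    seed=_stage_seed(cfg.seed, "importance", ct))
                section["importance"] = nt.to_dict()
            section["elapsed_s"] = round(time.time() - t_stage, 2)
        except Exception as exc:
            raise RuntimeError(
                f"experiment stage failed for call type {ct!r}: {exc}") from exc
        report["call_types"][ct] = section

    if cfg.sweep.enabled and sweep_input:
        sweep = sample_size_sweep(
            sweep_input, caps=tuple(cfg.sweep.caps),
            config={"n_trees_sex": cfg.model_sex.n_trees,
                    "n_trees_id": cfg.model_id.n_trees,
                    "learning_rate": cfg.model_id.learning_rate,
                    "max_depth": cfg.model_id.max_depth,
                    "n_folds": cfg.model_id.n_folds},
            random_state=_stage_seed(cfg.seed, "sweep"))
        report["sweep"] = sweep.to_dict(orient="records")

    report["elapsed_s"] = round(time.time() - t0, 2)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        for ct, m in sweep_input.items():
            audio_io.write_feature_table(m, out / f"features_{ct}.csv")
    return report


def _overlap_listing(sets: dict[str, set]) -> dict:
    """Plain-set listing of mutual and distinct features across hierarchy
    levels (sex, per-sex identity)."""
    names = sorted(sets)
    out: dict = {"levels": {n: sorted(sets[n]) for n in names}}
    all_feats = set().union(*sets.values())
    exclusive = {n: sorted(sets[n] - set().union(
        *(sets[m] for m in names if m != n))) for n in names}
    shared_all = sorted(set.intersection(*sets.values())) if sets else []
    out["exclusive_counts"] = {n: len(v) for n, v in exclusive.items()}
    out["exclusive"] = exclusive
    out["shared_by_all"] = shared_all
    out["n_total"] = len(all_feats)
    if all_feats:
        sex_only = len(exclusive.get("sex", []))
        out["pct_sex_only"] = round(100.0 * sex_only / len(all_feats), 1)
    return out
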