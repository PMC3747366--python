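"""End-to-end orchestration of the ensemble-QSAR workflow.

Sequences the full study shape on real or synthetic inputs: rational
clustering-based partition -> low-information descriptor filtering ->
random-subspace pools -> stepwise-LDA model sweep -> validation ->
exhaustive 2-model fusion -> paired ROC / pAUC statistics -> decoy-
spiked screening simulation.  A run is reproducible from its config
and seed alone; every stage writes its artifacts (CSV/JSON) into a
deterministic directory layout and a manifest records the config and
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion as fusion_mod
from .enrichment import enrichment_report, run_screening_campaign
from .io import (NONSUBSTRATE, SUBSTRATE, CompoundRecord, DescriptorMatrix,
                 filter_low_information, read_compounds, write_compounds)
from .partition import PartitionConfig, rational_split
from .roc import ScoredRanking, compare_auc, empirical_roc, partial_auc
from .subspace import (DescriptorPool, DiscriminantModel, SelectionConfig,
                       build_model, generate_pools)
from .synthetic import (PolyspecificGeneratorConfig, SyntheticDataset,
                        generate_polyspecific, screening_library)
from .validation import model_confusion, validate_model

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run (with the seed)."""

    seed: int = 0
    out_dir: str = "run"
    # input: either CSV paths or the synthetic generator
    compounds_csv: str | None = None
    descriptors_csv: str | None = None
    synthetic: PolyspecificGeneratorConfig | None = None
    # stages
    partition: PartitionConfig = field(default_factory=PartitionConfig)
    n_pools: int = 102
    target_pool_size: int = 200
    tolerances: tuple[float, ...] = (0.1, 0.3, 0.5)
    max_steps_grid: tuple[int, ...] = (10, 15)
    min_cases_per_predictor: int = 11
    alpha_enter: float = 0.05
    sp_lo: float = 0.7
    n_boot: int = 2000
    n_random: int = 50
    lgo_rounds: int = 50
    lgo_group_size: int = 10
    n_decoys: int = 479
    bedroc_alpha: float = 20.0
    ef_fraction: float = 0.10

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))
        return json.dumps(dataclasses.asdict(self), default=enc, indent=1)


@dataclass
class PipelineResult:
    out_dir: Path
    models: list[DiscriminantModel]
    pools: list[DescriptorPool]
    best_individual: int
    best_candidates: list
    train_auc_best_individual: float
    train_auc_best_ensemble: float


def _load_inputs(cfg: PipelineConfig) -> tuple[list[CompoundRecord], DescriptorMatrix, SyntheticDataset | None]:
    if cfg.synthetic is not None:
        ds = generate_polyspecific(cfg.synthetic)
        return ds.records, ds.matrix, ds
    if not (cfg.compounds_csv and cfg.descriptors_csv):
        raise ValueError("config must provide CSV inputs or a synthetic generator config")
    records = read_compounds(cfg.compounds_csv)
    matrix = DescriptorMatrix.from_csv(cfg.descriptors_csv)
    return records, matrix, None


def _sweep_models(
    matrix: DescriptorMatrix,
    labels: np.ndarray,
    pools: list[DescriptorPool],
    cfg: PipelineConfig,
) -> list[tuple[DiscriminantModel, DescriptorPool]]:
    """Build one model per (pool, tolerance, max_steps); drop duplicates."""
    out: list[tuple[DiscriminantModel, DescriptorPool]] = []
    seen: set[tuple] = set()
    for pool in pools:
        for tol in cfg.tolerances:
            for steps in cfg.max_steps_grid:
                sel_cfg = SelectionConfig(
                    tolerance_min=tol, max_steps=steps,
                    alpha_enter=cfg.alpha_enter,
                    min_cases_per_predictor=cfg.min_cases_per_predictor,
                )
                model = build_model(matrix, labels, pool, sel_cfg)
                if model is None:
                    continue
                key = (pool.pool_id, tuple(model.descriptors))
                if key in seen:
                    continue
                seen.add(key)
                out.append((model, pool))
    return out


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    for sub in ("split", "pools", "models", "ensembles", "roc", "screening"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())

    records, matrix, synthetic_ds = _load_inputs(cfg)
    stage = "partition"
    try:
        # ---- partition -------------------------------------------------
        have_split = all(r.set in ("train", "test") for r in records)
        if not have_split:
            plan = rational_split(records, matrix, cfg.partition)
            plan.to_csv(out / "split" / "split.csv", records)
            plan.per_cluster.to_csv(out / "split" / "clusters.csv", index=False)
        write_compounds(records, out / "split" / "compounds.csv")
        train_ids = [r.id for r in records if r.set == "train"]
        test_ids = [r.id for r in records if r.set == "test"]
        labels = {r.id: r.label for r in records}
        y_train = np.array([labels[i] for i in train_ids])
        y_test = np.array([labels[i] for i in test_ids])
        _log_stage(out, "partition", {"n_train": len(train_ids), "n_test": len(test_ids)})

        # ---- descriptors / pools --------------------------------------
        stage = "pools"
        filtered = filter_low_information(matrix, train_ids)
        pools = generate_pools(
            filtered.blocks, cfg.n_pools, cfg.target_pool_size, seed=cfg.seed
        )
        pd.DataFrame(
            [{"pool_id": p.pool_id, "blocks": "+".join(p.block_names), "size": p.size}
             for p in pools]
        ).to_csv(out / "pools" / "pools.csv", index=False)
        _log_stage(out, "pools", {"n_pools": len(pools), "n_descriptors": filtered.shape[1]})

        # ---- model sweep ----------------------------------------------
        stage = "models"
        train_mat = filtered.subset_compounds(train_ids)
        built = _sweep_models(train_mat, y_train, pools, cfg)
        if len(built) < 2:
            raise RuntimeError("model sweep produced fewer than 2 models")
        models = [m for m, _ in built]
        for idx, (model, pool) in enumerate(built):
            d = model.to_dict()
            d["model_index"] = idx
            (out / "models" / f"model_{idx:04d}.json").write_text(json.dumps(d, indent=1))
        _log_stage(out, "models", {"n_models": len(models)})

        # ---- fusion ----------------------------------------------------
        stage = "ensembles"
        test_mat = filtered.subset_compounds(test_ids)
        test_scores = np.vstack([m.score(test_mat) for m in models])
        train_scores = np.vstack([m.score(train_mat) for m in models])
        candidates = fusion_mod.enumerate_ensembles(
            test_scores, y_test, ids=test_ids, sp_lo=cfg.sp_lo
        )
        pd.DataFrame(fusion_mod.leaderboard_rows(candidates[:200])).to_csv(
            out / "ensembles" / "leaderboard.csv", index=False
        )
        best = candidates[0]
        (out / "ensembles" / "best.json").write_text(json.dumps({
            "model_a": models[best.index_a].to_dict(),
            "model_b": models[best.index_b].to_dict(),
            "operator": best.operator,
            "fp_test": best.fp_count, "pauc": best.pauc, "auc": best.auc,
        }, indent=1))

        # best individual model by training ROC AUC (substrate orientation)
        def train_auc(scores: np.ndarray) -> float:
            r = ScoredRanking(ids=train_ids, scores=scores, is_hit=y_train == SUBSTRATE)
            return empirical_roc(r).auc

        individual_aucs = [train_auc(s) for s in train_scores]
        best_ind = int(np.argmax(individual_aucs))
        fused_train = fusion_mod.fuse_scores(
            train_scores[best.index_a], train_scores[best.index_b], best.operator
        )
        best_ens_train_auc = train_auc(fused_train)
        _log_stage(out, "ensembles", {
            "pairs_per_operator": len(candidates) // 2,
            "best": f"{best.index_a}+{best.index_b}/{best.operator}",
        })

        # ---- validation of the selected models ------------------------
        stage = "validation"
        if cfg.n_random or cfg.lgo_rounds:
            pool = built[best_ind][1]
            report = validate_model(
                models[best_ind], train_mat, y_train, test_mat, y_test,
                pool.descriptor_names,
                models[best_ind].config,
                n_random=cfg.n_random, lgo_rounds=cfg.lgo_rounds,
                lgo_group_size=cfg.lgo_group_size, seed=cfg.seed + 17,
            )
            (out / "models" / "best_individual_validation.json").write_text(
                json.dumps(report.as_dict(), indent=1)
            )
            (out / "models" / "best_individual_validation.txt").write_text(
                report.text_table() + "\n"
            )
        _log_stage(out, "validation", {})

        # ---- ROC statistics -------------------------------------------
        stage = "roc"
        def test_ranking(scores: np.ndarray) -> ScoredRanking:
            return ScoredRanking(
                ids=test_ids, scores=scores, is_hit=y_test == NONSUBSTRATE,
                higher_score_is_hit=False, hit_definition="nonsubstrate_is_hit",
            )

        fused_test = fusion_mod.fuse_scores(
            test_scores[best.index_a], test_scores[best.index_b], best.operator
        )
        cmp = compare_auc(test_ranking(test_scores[best_ind]), test_ranking(fused_test))
        pauc_ind = partial_auc(test_ranking(test_scores[best_ind]), cfg.sp_lo,
                               n_boot=cfg.n_boot, seed=cfg.seed + 31)
        pauc_ens = partial_auc(test_ranking(fused_test), cfg.sp_lo,
                               n_boot=cfg.n_boot, seed=cfg.seed + 32)
        roc_report = {
            "orientation": "hits = known nonsubstrates, ranked by ascending df",
            "best_individual": {"auc": cmp.auc_a,
                                "pauc": pauc_ind.pauc, "pauc_sd": pauc_ind.bootstrap_sd},
            "best_ensemble": {"auc": cmp.auc_b,
                              "pauc": pauc_ens.pauc, "pauc_sd": pauc_ens.bootstrap_sd},
            "paired_z": cmp.z, "p_value": cmp.p_value, "sp_lo": cfg.sp_lo,
            "n_boot": cfg.n_boot,
        }
        (out / "roc" / "comparison.json").write_text(json.dumps(roc_report, indent=1))
        _log_stage(out, "roc", {"z": round(cmp.z, 3)})

        # ---- screening simulation -------------------------------------
        stage = "screening"
        if synthetic_ds is not None and cfg.n_decoys > 0:
            lib_records, lib_matrix = screening_library(
                synthetic_ds, cfg.n_decoys, seed=cfg.seed + 57
            )
            def ens_score(mat: DescriptorMatrix) -> np.ndarray:
                return fusion_mod.fuse_scores(
                    models[best.index_a].score(mat),
                    models[best.index_b].score(mat), best.operator,
                )
            for name, scorer in (
                ("best_individual", models[best_ind].score),
                ("best_ensemble", ens_score),
            ):
                rep, ranking = run_screening_campaign(
                    scorer, lib_records, lib_matrix,
                    alpha=cfg.bedroc_alpha, ef_fraction=cfg.ef_fraction,
                )
                (out / "screening" / f"{name}.json").write_text(
                    json.dumps(rep.as_dict(), indent=1)
                )
                (out / "screening" / f"{name}.txt").write_text(rep.text_table() + "\n")
                pd.DataFrame({
                    "id": ranking.ids, "score": ranking.scores,
                    "is_hit": ranking.is_hit.astype(int),
                }).to_csv(out / "screening" / f"{name}_scores.csv", index=False)
        _log_stage(out, "screening", {})

    except Exception:
        logger.exception("pipeline failed at stage %r; partial outputs kept in %s",
                         stage, out)
        raise

    manifest = {
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(cfg.to_json().encode()).hexdigest(),
        "n_models": len(models),
        "best_individual_index": best_ind,
        "best_ensemble": {"a": best.index_a, "b": best.index_b, "operator": best.operator},
        "train_auc_best_individual": individual_aucs[best_ind],
        "train_auc_best_ensemble": best_ens_train_auc,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(
        out_dir=out, models=models, pools=pools,
        best_individual=best_ind, best_candidates=candidates,
        train_auc_best_individual=individual_aucs[best_ind],
        train_auc_best_ensemble=best_ens_train_auc,
    )


def _log_stage(out: Path, stage: str, info: dict) -> None:
    line = json.dumps({"stage": stage, **info})
    logger.info("%s", line)
    with (out / "pipeline.log").open("a") as fh:
        fh.write(line + "\n")
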