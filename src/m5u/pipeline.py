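"""End-to-end orchestration: encode -> select -> embed -> fuse -> train -> interpret.

Stage order mirrors the method's design: the four physicochemical
encoders are fused and the two-step selection (importance ranking + IFS)
runs on that fused view only; the distributed-representation features
are trained separately and concatenated with the *selected*
physicochemical features afterwards — embeddings never pass through IFS.
The fused multi-view matrix then feeds the SVM grid search, tenfold CV,
optional independent-test evaluation, composition analysis, and a
Shapley top-20 interpretation report.

Every stochastic stage derives its seed from the single pipeline seed,
and the run directory carries a manifest (config, seeds, versions,
per-stage wall time) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import SvmConfig, cross_validate, evaluate, train_svm
from .composition import enrichment
from .embedding import build_corpus, embed_matrix, train_skipgram
from .encoders import (
    PhyschemParams,
    PropertyTable,
    PseDncConfig,
    encode_matrix,
    encode_physchem,
)
from .selection import incremental_feature_selection, rank_features
from .shapley import explain, shap_summary
from .windows import WindowSet

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run."""

    window_length: int = 41
    # physicochemical encoders
    kmer_ks: tuple[int, ...] = (1, 2, 3)
    enac_window: int = 5
    cksnap_kmax: int = 5
    psednc_lam: int = 3
    psednc_w: float = 0.5
    property_table_path: Optional[str] = None
    # embedding
    embed_k: int = 3
    embed_w: int = 4
    embed_dim: int = 100
    embed_epochs: int = 30
    # selection
    selection_method: str = "gbdt_lightgbm"
    selection_folds: int = 10
    selection_step: int = 1
    # classifier
    svm_kernel: str = "rbf"
    svm_C_grid: tuple[float, ...] = tuple(float(2.0**e) for e in range(-5, 16, 2))
    svm_gamma_grid: tuple[float, ...] = tuple(float(2.0**e) for e in range(-15, 4, 2))
    cv_folds: int = 10
    # interpretation
    shap_top_n: int = 20
    shap_samples: int = 20
    shap_background: int = 50
    shap_perms: int = 30
    seed: int = 0
    out_dir: str = "m5u_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kmer_ks", "svm_C_grid", "svm_gamma_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def physchem_params(self) -> PhyschemParams:
        table = (
            PropertyTable.from_tsv(self.property_table_path)
            if self.property_table_path
            else PropertyTable.default()
        )
        return PhyschemParams(
            kmer_ks=tuple(self.kmer_ks),
            enac_window=self.enac_window,
            cksnap_kmax=self.cksnap_kmax,
            psednc=PseDncConfig(lam=self.psednc_lam, w=self.psednc_w),
            property_table=table,
        )

    def svm_config(self) -> SvmConfig:
        return SvmConfig(
            kernel=self.svm_kernel,
            C_grid=self.svm_C_grid,
            gamma_grid=self.svm_gamma_grid,
            seed=self.seed + 4,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    cfg: PipelineConfig, train: WindowSet, test: Optional[WindowSet] = None
) -> Path:
    """Execute the full pipeline; returns the run directory."""
    if train.L != cfg.window_length:
        raise ValueError(
            f"training window length {train.L} != configured {cfg.window_length}"
        )
    if test is not None and len(test) and test.L != train.L:
        raise ValueError("test window length differs from training")

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "config": {k: list(v) if isinstance(v, tuple) else v for k, v in asdict(cfg).items()},
        "version": __version__,
        "n_train": len(train),
        "n_test": len(test) if test is not None else 0,
    }

    def stage(name):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s ...", name)
                self.t0 = time.perf_counter()

            def __exit__(self, etype, e, tb):
                if e is not None:
                    raise StageError(name, e) from e
                timings[name] = round(time.perf_counter() - self.t0, 3)
                logger.info("stage %s done in %.1fs", name, timings[name])

        return _Ctx()

    y = train.labels()

    with stage("physchem_encode"):
        params = cfg.physchem_params()
        X_phys = encode_matrix(train, encode_physchem, params=params)
        X_phys.to_csv(out / "physchem_train.tsv", sep="\t")

    with stage("feature_selection"):
        ranking = rank_features(X_phys, y, method=cfg.selection_method, seed=cfg.seed + 1)
        sel = incremental_feature_selection(
            ranking,
            X_phys,
            y,
            classifier=SvmConfig(kernel=cfg.svm_kernel, seed=cfg.seed).estimator(),
            folds=cfg.selection_folds,
            step=cfg.selection_step,
            seed=cfg.seed + 2,
        )
        sel.save(out / "selection.tsv", out / "selection.json")
        X_sel = X_phys[sel.best_features]

    with stage("embedding"):
        corpus = build_corpus(train, cfg.embed_k)
        emb = train_skipgram(
            corpus,
            dim=cfg.embed_dim,
            window=cfg.embed_w,
            epochs=cfg.embed_epochs,
            seed=cfg.seed + 3,
        )
        emb.save(out / "embedding.tsv")
        X_emb = embed_matrix(train, emb)

    with stage("fuse"):
        X_fused = pd.concat([X_sel, X_emb], axis=1)
        X_fused.to_csv(out / "fused_train.tsv", sep="\t")

    with stage("svm_train"):
        svm_cfg = cfg.svm_config()
        model, (C, gamma), grid_acc = train_svm(
            X_fused.to_numpy(), y, svm_cfg, folds=cfg.cv_folds
        )
        svm_cfg.C, svm_cfg.gamma = C, gamma
        manifest["svm"] = {"C": C, "gamma": gamma, "grid_cv_accuracy": grid_acc}

    with stage("cross_validate"):
        cv_report = cross_validate(
            X_fused.to_numpy(), y, svm_cfg, folds=cfg.cv_folds, seed=cfg.seed + 5
        )
        cv_report.save(out / "cv_report.json")

    if test is not None and len(test):
        with stage("independent_test"):
            Xt_phys = encode_matrix(test, encode_physchem, params=params)
            Xt = pd.concat(
                [Xt_phys[sel.best_features], embed_matrix(test, emb)], axis=1
            )
            test_report = evaluate(model, Xt.to_numpy(), test.labels())
            test_report.save(out / "test_report.json")

    with stage("composition"):
        pos, neg = train.subset("positive"), train.subset("negative")
        if len(pos) and len(neg):
            enr = enrichment(pos, neg)
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    with stage("interpret"):
        rng = np.random.default_rng(cfg.seed + 6)
        M = X_fused.to_numpy()
        bg_idx = rng.choice(len(M), size=min(cfg.shap_background, len(M)), replace=False)
        sm_idx = rng.choice(len(M), size=min(cfg.shap_samples, len(M)), replace=False)
        res = explain(
            model.decision_function,
            M[sm_idx],
            M[bg_idx],
            feature_names=list(X_fused.columns),
            n_perm=cfg.shap_perms,
            seed=cfg.seed + 7,
        )
        res.save(out / "shap_values.tsv")
        summary = shap_summary(res, top_n=cfg.shap_top_n)
        summary.to_csv(out / "shap_summary.tsv", sep="\t", index=False)

    manifest["timings_s"] = timings
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()[:16]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
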