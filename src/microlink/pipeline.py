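"""End-to-end pipeline: similarities -> fusion -> embeddings -> classifier.

Two similarity-network stacks are fused independently (disease side:
semantic + symptom + interaction-profile kernel; microbe side:
disease-based functional + optional drug-based functional +
interaction-profile kernel), one variational graph autoencoder is trained
per side ("respectively" sharing hyperparameters), and a gradient-boosted
pair classifier is cross-validated on concatenated embeddings.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix, SymptomProfile
from .fusion import snf_fuse
from .io import log_stage
from .predictor import EvalReport, PairDataset, build_pairs, crossval
from .similarity import (
    dss1_matrix,
    dss2,
    functional_similarity,
    gip_kernel,
    merge_two_sources,
)
from .synthetic import PlantedWorld, make_dag_forest, make_symptom_matrix, substream
from .vgae import GraphInputs, train

__all__ = ["PipelineResult", "compute_views", "embed_both_sides",
           "run_pipeline", "run_planted_pipeline"]


@dataclass
class PipelineResult:
    report: EvalReport
    fused_disease: SimilarityMatrix
    fused_microbe: SimilarityMatrix
    Zd: np.ndarray
    Zm: np.ndarray
    pairs: PairDataset
    views: dict = field(default_factory=dict)


def _side_seed(seed: int, stage: str) -> int:
    return int(substream(seed, stage).integers(0, 2**31 - 1))


def compute_views(A: AssociationMatrix, cfg: RunConfig,
                  dags: dict[str, DiseaseDAG] | None = None,
                  symptoms: SymptomProfile | None = None,
                  drug_data: tuple | None = None
                  ) -> tuple[list[SimilarityMatrix], list[SimilarityMatrix]]:
    """Build the per-axis similarity views available from the inputs."""
    disease_views: list[SimilarityMatrix] = []
    sem = None
    if dags is not None:
        sem = dss1_matrix(dags, cfg.omega, labels=list(A.col_labels))
        disease_views.append(sem)
    if symptoms is not None:
        if list(symptoms.disease_labels) != list(A.col_labels):
            raise ValueError("symptom profile labels must match disease axis")
        disease_views.append(dss2(symptoms))
    disease_views.append(gip_kernel(A, axis="disease"))

    microbe_views: list[SimilarityMatrix] = []
    if sem is not None:
        microbe_views.append(functional_similarity(A, sem))
    if drug_data is not None:
        drug_a, drug_b, drug_sim = drug_data
        dfs2 = merge_two_sources(
            functional_similarity(drug_a, drug_sim),
            functional_similarity(drug_b, drug_sim),
        )
        microbe_views.append(dfs2)
    microbe_views.append(gip_kernel(A, axis="microbe"))
    return disease_views, microbe_views


def embed_both_sides(A: AssociationMatrix, fused_d: SimilarityMatrix,
                     fused_m: SimilarityMatrix, cfg: RunConfig
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Train one autoencoder per axis; disease features are the columns of
    A (profiles over microbes), microbe features the rows."""
    common = dict(
        scales=tuple(cfg.scales), hidden_dims=tuple(cfg.base_hidden_dims),
        learning_rate=cfg.learning_rate, lr_step=cfg.lr_step,
        lr_gamma=cfg.lr_gamma, epochs=cfg.epochs, wd_mode=cfg.wd_mode,
        sinkhorn_epsilon=cfg.sinkhorn_epsilon,
        sinkhorn_iters=cfg.sinkhorn_iters,
    )
    t0 = time.perf_counter()
    inputs_d = GraphInputs(fused_d.values, A.values.T.astype(float),
                           labels=list(fused_d.labels))
    _, state_d, _ = train(inputs_d, seed=_side_seed(cfg.seed, "vgae-disease"),
                          **common)
    log_stage("embed-disease", cfg.seed, time.perf_counter() - t0,
              nodes=A.n_diseases, dim=state_d["Z"].shape[1])
    t0 = time.perf_counter()
    inputs_m = GraphInputs(fused_m.values, A.values.astype(float),
                           labels=list(fused_m.labels))
    _, state_m, _ = train(inputs_m, seed=_side_seed(cfg.seed, "vgae-microbe"),
                          **common)
    log_stage("embed-microbe", cfg.seed, time.perf_counter() - t0,
              nodes=A.n_microbes, dim=state_m["Z"].shape[1])
    return state_d["Z"], state_m["Z"]


def run_pipeline(A: AssociationMatrix, cfg: RunConfig,
                 dags: dict[str, DiseaseDAG] | None = None,
                 symptoms: SymptomProfile | None = None,
                 drug_data: tuple | None = None) -> PipelineResult:
    """Full run on explicit inputs; missing optional inputs simply drop
    the corresponding similarity views."""
    t0 = time.perf_counter()
    disease_views, microbe_views = compute_views(A, cfg, dags, symptoms, drug_data)
    fused_d = snf_fuse(disease_views, K=min(cfg.knn_k_disease, A.n_diseases - 1),
                       t=cfg.snf_iterations)
    fused_m = snf_fuse(microbe_views, K=min(cfg.knn_k_microbe, A.n_microbes - 1),
                       t=cfg.snf_iterations)
    log_stage("similarity+fusion", cfg.seed, time.perf_counter() - t0,
              nd=A.n_diseases, nm=A.n_microbes,
              d_views=len(disease_views), m_views=len(microbe_views))
    Zd, Zm = embed_both_sides(A, fused_d, fused_m, cfg)
    t0 = time.perf_counter()
    pairs = build_pairs(A, Zm, Zd, negative_ratio=cfg.negative_ratio,
                        seed=_side_seed(cfg.seed, "negatives"))
    report = crossval(pairs, folds=cfg.cv_folds,
                      threshold=cfg.decision_threshold,
                      seed=_side_seed(cfg.seed, "cv"))
    log_stage("crossval", cfg.seed, time.perf_counter() - t0,
              pairs=len(pairs.labels), folds=cfg.cv_folds)
    return PipelineResult(report, fused_d, fused_m, Zd, Zm, pairs,
                          views={"disease": disease_views,
                                 "microbe": microbe_views})


def run_planted_pipeline(world: PlantedWorld, cfg: RunConfig,
                         with_symptoms: bool = True,
                         with_dags: bool = True) -> PipelineResult:
    """Convenience wrapper: generate the auxiliary inputs for a planted
    world from the same master seed and run the full pipeline."""
    dags = make_dag_forest(list(world.A.col_labels), world.disease_clusters,
                           seed=world.seed) if with_dags else None
    symptoms = make_symptom_matrix(world, seed=world.seed) if with_symptoms else None
    return run_pipeline(world.A, cfg, dags=dags, symptoms=symptoms)
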