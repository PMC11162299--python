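"""High-level workflow: sequences + PPI network -> embeddings -> classifier
-> mined complexes -> evaluation.

These functions wire the modules together the way the command-line tool
does, and are the programmatic entry point for end-to-end runs. Ablation
variants of the embedding stage are exposed by name:

* ``"full"``      - CT sequence features, hypergraph propagation (default);
* ``"no_ct"``     - one-hot node identity features, topology only;
* ``"no_pin"``    - CT features, no propagation (sequence only);
* ``"vgae"``      - CT features, conventional pairwise variational graph
  autoencoder (GCN propagation, adjacency reconstruction).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .classifier import (
    ClassifierConfig,
    ComplexDNN,
    EmbeddingTable,
    evaluate_classifier,
    sample_negative_complexes,
    train_classifier,
)
from .detection import DetectionConfig, detect_complexes, make_scorer
from .encoding import encode_catalog
from .hgvae import HGVAE, HGVAEConfig, train_hgvae
from .hypergraph import build_hypergraph
from .io import ComplexSet, InteractionNetwork, ProteinCatalog
from .metrics import EvalReport, evaluate_complexes

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineModel",
    "VARIANTS",
    "variant_config",
    "train_embeddings",
    "fit_pipeline",
    "run_detection",
    "run_end_to_end",
]

VARIANTS = ("full", "no_ct", "no_pin", "vgae")


@dataclass
class PipelineModel:
    embeddings: EmbeddingTable
    classifier: ComplexDNN
    hgvae: HGVAE
    negatives: ComplexSet


def variant_config(base: HGVAEConfig, variant: str, n_nodes: int) -> HGVAEConfig:
    """Adapt an HGVAE config to one of the named ablation variants."""
    if variant == "full":
        return base
    if variant == "no_ct":
        return replace(base, feature_mode="onehot", input_dim=n_nodes)
    if variant == "no_pin":
        return replace(base, propagation="identity")
    if variant == "vgae":
        return replace(base, propagation="gcn", decoder="adjacency")
    raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def _aligned_features(
    network: InteractionNetwork, catalog: ProteinCatalog
) -> np.ndarray:
    """CT features row-aligned to network node order."""
    X_cat = encode_catalog(catalog)
    row_of = {pid: i for i, pid in enumerate(catalog.ids)}
    missing = [n for n in network.nodes if n not in row_of]
    if missing:
        raise ValueError(
            f"{len(missing)} network node(s) lack sequences, e.g. {missing[:5]}"
        )
    return X_cat[[row_of[n] for n in network.nodes]]


def train_embeddings(
    network: InteractionNetwork,
    catalog: ProteinCatalog,
    config: HGVAEConfig | None = None,
    min_clique_size: int = 3,
    variant: str = "full",
) -> tuple[EmbeddingTable, HGVAE]:
    """Build the hypergraph, train the HGVAE, return node embeddings (mu)."""
    if config is None:
        config = HGVAEConfig()
    config = variant_config(config, variant, network.n_nodes)
    X = None
    if config.feature_mode == "ct":
        X = _aligned_features(network, catalog)
    hg = build_hypergraph(network, X=X, min_size=min_clique_size)
    logger.info(
        "hypergraph: %d nodes, %d hyperedges", hg.n_nodes, hg.n_hyperedges
    )
    model, latent = train_hgvae(hg, config)
    logger.info(
        "HGVAE trained: loss %0.4f -> %0.4f",
        model.loss_trace[0],
        model.loss_trace[-1],
    )
    return EmbeddingTable(network.nodes, latent.mu), model


def fit_pipeline(
    network: InteractionNetwork,
    catalog: ProteinCatalog,
    positives: ComplexSet,
    hgvae_config: HGVAEConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
    min_clique_size: int = 3,
    variant: str = "full",
    seed: int = 0,
) -> PipelineModel:
    """Train embeddings and the complex classifier on gold-standard positives."""
    if hgvae_config is None:
        hgvae_config = HGVAEConfig(seed=seed)
    if classifier_config is None:
        classifier_config = ClassifierConfig(seed=seed)
    embeddings, hgvae = train_embeddings(
        network, catalog, hgvae_config, min_clique_size, variant
    )
    negatives = sample_negative_complexes(
        positives, network, ratio=classifier_config.negative_ratio, seed=seed
    )
    classifier = train_classifier(
        embeddings, positives, negatives, classifier_config
    )
    return PipelineModel(
        embeddings=embeddings,
        classifier=classifier,
        hgvae=hgvae,
        negatives=negatives,
    )


def run_detection(
    model: PipelineModel,
    network: InteractionNetwork,
    config: DetectionConfig | None = None,
) -> ComplexSet:
    scorer = make_scorer(model.classifier, model.embeddings)
    return detect_complexes(network, scorer, config)


def run_end_to_end(
    network: InteractionNetwork,
    catalog: ProteinCatalog,
    positives: ComplexSet,
    reference: ComplexSet | None = None,
    hgvae_config: HGVAEConfig | None = None,
    classifier_config: ClassifierConfig | None = None,
    detection_config: DetectionConfig | None = None,
    variant: str = "full",
    seed: int = 0,
) -> tuple[ComplexSet, EvalReport | None, PipelineModel]:
    """Full workflow; evaluates against ``reference`` (default: positives)."""
    model = fit_pipeline(
        network,
        catalog,
        positives,
        hgvae_config,
        classifier_config,
        variant=variant,
        seed=seed,
    )
    predicted = run_detection(model, network, detection_config)
    report = None
    ref = reference if reference is not None else positives
    if len(predicted) > 0 and len(ref) > 0:
        report = evaluate_complexes(predicted, ref)
    return predicted, report, model
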