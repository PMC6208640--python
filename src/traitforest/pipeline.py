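"""End-to-end workflows wiring the simulator, forest and mechanism ranking.

These are the library-level entry points behind the command-line interface
and the reproducibility scripts: simulate a community, featurize it, train a
forest on the ordered coculture responses, and rank candidate mechanisms
for the samples with flux-derived ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contributions import QueryCountSummary, query_count_evaluation
from .forest import ForestModel, oob_votes, roc_auc, train_forest
from .seeding import subseed, substream
from .synthetic_community import (CampaignResult, competition_candidate_map,
                                  generate_community, pairwise_campaign,
                                  traits_from_models)
from .traitspace import (CompositeDataset, LabelRule, TraitMatrix,
                         assemble_dataset, jaccard_baseline_scores,
                         score_threshold_roc)

__all__ = ["simulate_community", "mechanism_recovery_study", "SimulatedStudy"]

#: sign-rule tolerance used for simulated relative yields: a |X| below this
#: is numerical residue of the discretized batch solver, not a real effect
SIMULATED_YIELD_TOLERANCE = 1e-6


@dataclass
class SimulatedStudy:
    """A simulated community with its featurized dataset and ground truth."""

    traits: TraitMatrix
    dataset: CompositeDataset
    campaign: CampaignResult
    metabolites: tuple[str, ...]
    design_notes: object


def simulate_community(seed: int, n_organisms: int = 20, n_metabolites: int = 50,
                       scenario: str = "single_competition",
                       rule: LabelRule | None = None,
                       **generator_kwargs) -> SimulatedStudy:
    """Generate a community, run the full pairwise dFBA campaign, featurize."""
    models, env, design = generate_community(
        n_organisms, n_metabolites, scenario,
        seed=subseed(seed, "simulate"), **generator_kwargs)
    campaign = pairwise_campaign(models, env)
    traits = traits_from_models(models, env.metabolites)
    if rule is None:
        rule = LabelRule(mode="sign", tolerance=SIMULATED_YIELD_TOLERANCE)
    dataset = assemble_dataset(traits, campaign.table, rule)
    return SimulatedStudy(traits, dataset, campaign, env.metabolites, design)


@dataclass
class MechanismRecoveryResult:
    """Outcome of the scaled-down mechanism-recovery experiment."""

    study: SimulatedStudy
    model: ForestModel
    summary: QueryCountSummary
    forest_auc: float
    jaccard_auc: float
    oob_balanced_accuracy: float
    n_candidates: int

    @property
    def median_rank(self) -> float:
        return self.summary.median_rank

    @property
    def random_baseline(self) -> float:
        # single-mechanism samples: (n_candidates + 1) / 2
        return (self.n_candidates + 1) / 2


def mechanism_recovery_study(seed: int, n_organisms: int = 20,
                             n_metabolites: int = 50, n_trees: int = 500,
                             m_try: int | None = None,
                             scenario: str = "single_competition",
                             shuffle_labels: bool = False,
                             **generator_kwargs) -> MechanismRecoveryResult:
    """Simulate, train, and rank contended metabolites for negative samples.

    Mirrors the query-count experiment: train a forest on all ordered
    responses of a simulated community, then for every negative sample whose
    flux-derived truth is exactly one contended metabolite, rank all
    candidate metabolites by net out-of-bag feature contribution (read from
    the negative end) and record the rank of the true one.

    ``shuffle_labels=True`` trains on permuted labels as a null control: the
    forest then carries no information and the ranks should match the
    analytic random baseline.
    """
    study = simulate_community(seed, n_organisms, n_metabolites, scenario,
                               **generator_kwargs)
    dataset = study.dataset
    train_dataset = dataset
    if shuffle_labels:
        # null control: the forest is fit on permuted labels, but sample
        # selection and reading direction keep the real labels — the
        # question is whether an uninformative forest still ranks the true
        # mechanism well on the genuine single-mechanism samples
        rng = substream(seed, "label-shuffle")
        shuffled = dataset.labels[rng.permutation(dataset.n_samples)]
        train_dataset = CompositeDataset(
            dataset.pairs, dataset.design, shuffled, dataset.feature_names,
            dataset.class_names, dataset.label_rule + " (label-shuffled)",
            dataset.responses)
    model = train_forest(train_dataset, n_trees, m_try,
                         seed=subseed(seed, "train"))
    votes = oob_votes(model, train_dataset)
    mask = votes.counted_mask()
    forest_roc = roc_auc(votes, train_dataset.labels)
    from .forest import balanced_accuracy_from_labels
    oob_ba = balanced_accuracy_from_labels(train_dataset.labels[mask],
                                           votes.predicted[mask])
    jd = jaccard_baseline_scores(study.traits, train_dataset)
    jaccard_roc = score_threshold_roc(jd, train_dataset.labels)

    truth = study.campaign.truth
    single = {}
    for sid, pair in enumerate(dataset.pairs):
        if dataset.labels[sid] != 0:
            continue
        contended = truth.contended_for(*pair)
        if len(contended) == 1:
            single[pair] = contended
    candidate_map = competition_candidate_map(study.metabolites)
    sample_ids = [sid for sid, pair in enumerate(dataset.pairs) if pair in single]
    summary = query_count_evaluation(model, dataset, single, candidate_map,
                                     sample_ids=sample_ids)
    return MechanismRecoveryResult(study, model, summary, forest_roc.auc,
                                   jaccard_roc.auc, oob_ba,
                                   len(candidate_map))
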