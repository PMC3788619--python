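"""High-level orchestration of the annotate → model → rewire → enrich flow.

These helpers glue the pure modules together for the CLI, the examples and
the reproduction script; they contain no statistics of their own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotation import (AnnotationSet, MissenseVariant, PhosphoSite,
                         annotate_psnvs, count_by_context, merge_regions)
from .config import DEFAULT_CONFIG, RunConfig
from .kinase_models import KinasePwm, MssBackground, evaluate_kinase
from .rewiring import (RewiredNetwork, assemble_network, direct_psnv_calls,
                       high_confidence_filter, scan_rewiring)

logger = logging.getLogger(__name__)


@dataclass
class KinaseModelSet:
    """Refined kinase models plus their cached background distributions."""

    models: dict[str, KinasePwm]
    backgrounds: dict[str, MssBackground] = field(default_factory=dict)

    @property
    def retained(self) -> list[KinasePwm]:
        return [m for m in self.models.values() if m.retained]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"kinase": m.kinase, "n_initial": m.n_initial,
              "n_retained": m.n_retained,
              "auroc": "" if m.auroc is None else round(m.auroc, 4),
              "retained": m.retained} for m in self.models.values()])


def build_kinase_models(kinase_peptides: Mapping[str, Sequence[str]],
                        sites: Sequence[PhosphoSite],
                        config: RunConfig = DEFAULT_CONFIG) -> KinaseModelSet:
    """Refine, cross-validate and gate a PWM per annotated kinase.

    For each kinase the empirical background is every phosphosite window
    with known kinases not including that kinase.  Cross-validation
    negatives are the refined binding peptides of all other retained
    kinases, minus any peptide also annotated to the focal kinase.
    """
    windows_by_kinase: dict[str, list[str]] = {}
    for s in sites:
        for k in s.known_kinases:
            windows_by_kinase.setdefault(k, []).append(s.window)
    all_windows = [(s.window, s.known_kinases) for s in sites
                   if s.known_kinases]

    models: dict[str, KinasePwm] = {}
    refined: dict[str, list[str]] = {}
    backgrounds: dict[str, MssBackground] = {}
    bg_peptides: dict[str, list[str]] = {}
    from .kinase_models import build_pwm, crossvalidate_auroc, refine_pwm

    for kinase in sorted(kinase_peptides):
        peptides = list(kinase_peptides[kinase])
        background = [w for w, known in all_windows if kinase not in known]
        bg_peptides[kinase] = background
        if len(peptides) < config.min_training_seqs or not background:
            model = build_pwm(kinase, peptides, config.pseudocount)
            model.retained = False
            models[kinase] = model
            continue
        model = refine_pwm(kinase, peptides, background,
                           cutoff=config.outlier_cutoff,
                           pseudocount=config.pseudocount,
                           min_training_seqs=config.min_training_seqs,
                           use_info_weights=config.use_info_weights,
                           leave_one_out=config.refine_leave_one_out)
        models[kinase] = model
        if model.retained:
            refined[kinase] = model.training_peptides

    for kinase, model in models.items():
        if not model.retained:
            continue
        focal = set(kinase_peptides[kinase])
        negatives = [p for other, peps in refined.items() if other != kinase
                     for p in peps if p not in focal]
        if not negatives:
            logger.warning("%s: no cross-validation negatives; AUROC gate "
                           "skipped", kinase)
        else:
            folds = min(10, model.n_retained)
            model.auroc = crossvalidate_auroc(
                kinase, model.training_peptides, negatives, folds=folds,
                seed=config.rng_seed, pseudocount=config.pseudocount,
                use_info_weights=config.use_info_weights)
            model.retained = model.auroc >= config.auroc_min
        if model.retained:
            backgrounds[kinase] = MssBackground(
                model, bg_peptides[kinase], config.use_info_weights,
                config.smooth_empirical_p)
    return KinaseModelSet(models, backgrounds)


@dataclass
class RewiringResult:
    flanking_events: list
    direct_events: list
    network: RewiredNetwork
    high_confidence: RewiredNetwork


def run_rewiring(annotations: AnnotationSet, model_set: KinaseModelSet,
                 config: RunConfig = DEFAULT_CONFIG,
                 known_only: bool = False) -> RewiringResult:
    """Scan all flanking pSNVs against all retained models, add direct calls."""
    flanking = scan_rewiring(annotations, model_set.retained,
                             model_set.backgrounds, config, known_only)
    direct = direct_psnv_calls(annotations)
    network = assemble_network(flanking + direct, config)
    return RewiringResult(flanking, direct, network,
                          high_confidence_filter(network))


def rewiring_truth_rates(events, truth, focal_kinase: str
                         ) -> tuple[float, float]:
    """Loss-detection and false-call rates against a synthetic truth table.

    Detection = fraction of motif-destroying variants with a predicted loss
    for the focal kinase; false-call = fraction of motif-neutral variants
    with such a loss.
    """
    loss_keys = {e.variant.key for e in events
                 if e.event == "loss" and e.kinase == focal_kinase}
    detected, false = [], []
    for r in truth.itertuples(index=False):
        key = (r.protein_id, r.position, r.ref_aa, r.alt_aa, r.sample_id)
        if r.truth == "motif_destroying":
            detected.append(key in loss_keys)
        elif r.truth == "motif_neutral":
            false.append(key in loss_keys)
    det = float(sum(detected)) / len(detected) if detected else float("nan")
    fal = float(sum(false)) / len(false) if false else 0.0
    return det, fal


@dataclass
class AnnotationResult:
    annotations: AnnotationSet
    regions: list
    context: object


def run_annotation(variants: Sequence[MissenseVariant],
                   sites: Sequence[PhosphoSite],
                   proteins: Mapping[str, object],
                   config: RunConfig = DEFAULT_CONFIG) -> AnnotationResult:
    regions = merge_regions(sites, config.flank_width, proteins)
    annotations = annotate_psnvs(variants, sites, proteins,
                                 config.flank_width, config.proximal_width)
    context = count_by_context(annotations, variants, proteins, regions)
    return AnnotationResult(annotations, regions, context)
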