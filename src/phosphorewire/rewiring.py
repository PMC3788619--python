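"""Prediction of kinase-network rewiring by phosphosite-flanking variants.

A flanking pSNV rewires signaling when it moves a phosphosite across the
significance boundary of a kinase model's background score distribution:

* loss-of-signaling — the reference window is a significant match
  (pRef < 0.05) and the mutated window is clearly non-significant
  (pMut > 0.1);
* gain-of-signaling — the mirror image (pRef > 0.1, pMut < 0.05);
* switch-of-signaling — the same variant has at least one loss and one gain
  with different kinase models.

Direct pSNVs replace the phospho-acceptor itself and abolish phosphorylation
without any scoring (the MSS ignores the central column by construction), so
they are called as unconditional losses attributed to the site's known
kinases.  The high-confidence network keeps only experimentally supported
losses and, per variant, the single top-scoring predicted gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import (CENTER, AnnotationSet, MissenseVariant, PhosphoSite,
                         PsnvAnnotation)
from .config import DEFAULT_CONFIG, RunConfig
from .errors import FormatError
from .kinase_models import KinasePwm, MssBackground, mss


@dataclass(frozen=True)
class RewiringEvent:
    """One predicted loss or gain of a kinase-substrate interaction."""

    variant: MissenseVariant
    site: PhosphoSite
    kinase: str
    event: str  # loss | gain
    p_ref: float | None
    p_mut: float | None
    mss_ref: float | None
    mss_mut: float | None
    kinase_known: bool


@dataclass
class RewiredNetwork:
    """All rewiring events plus the per-variant loss/gain/switch summary."""

    edges: list[RewiringEvent]
    psnv_summary: dict[tuple, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.psnv_summary:
            self.psnv_summary = summarize_events(self.edges)

    @property
    def n_switch(self) -> int:
        return sum(1 for s in self.psnv_summary.values() if s["switch"])


def summarize_events(events: Iterable[RewiringEvent]) -> dict[tuple, dict]:
    summary: dict[tuple, dict] = {}
    for e in events:
        s = summary.setdefault(e.variant.key,
                               {"loss": set(), "gain": set(), "switch": False})
        s[e.event].add(e.kinase)
    for s in summary.values():
        # switch requires loss and gain with different models; loss and gain
        # are mutually exclusive per kinase, so any pair qualifies
        s["switch"] = bool(s["loss"]) and bool(s["gain"])
    return summary


def mutate_window(site: PhosphoSite, variant: MissenseVariant) -> str:
    """Apply a substitution inside a site's 15-mer window."""
    offset = variant.position - site.position
    if abs(offset) > CENTER:
        raise FormatError(
            f"variant at {variant.position} outside ±{CENTER} window of "
            f"site {site.protein_id}:{site.position}")
    idx = CENTER + offset
    if site.window[idx] != variant.ref_aa:
        raise FormatError(
            f"window residue {site.window[idx]!r} at offset {offset} does "
            f"not match reference {variant.ref_aa!r}")
    return site.window[:idx] + variant.alt_aa + site.window[idx + 1:]


def event_from_pvalues(p_ref: float, p_mut: float,
                       config: RunConfig = DEFAULT_CONFIG) -> str | None:
    """Threshold rule mapping (pRef, pMut) to loss, gain or no call."""
    if p_ref < config.p_ref_sig and p_mut > config.p_mut_nonsig:
        return "loss"
    if p_ref > config.p_mut_nonsig and p_mut < config.p_ref_sig:
        return "gain"
    return None


def classify_rewiring(site: PhosphoSite, variant: MissenseVariant,
                      model: KinasePwm,
                      background: Sequence[str] | MssBackground,
                      config: RunConfig = DEFAULT_CONFIG
                      ) -> RewiringEvent | None:
    """Score a (variant, site) pair against one kinase model.

    Computes empirical p-values for the reference and mutated windows and
    applies the loss/gain threshold rule; returns None when neither
    threshold pattern holds.
    """
    bg = (background if isinstance(background, MssBackground)
          else MssBackground(model, background, config.use_info_weights,
                             config.smooth_empirical_p))
    ref_window = site.window
    mut_window = mutate_window(site, variant)
    mss_ref = mss(model, ref_window, config.use_info_weights)
    mss_mut = mss(model, mut_window, config.use_info_weights)
    p_ref = bg.p_value(mss_ref)
    p_mut = bg.p_value(mss_mut)
    event = event_from_pvalues(p_ref, p_mut, config)
    if event is None:
        return None
    return RewiringEvent(variant, site, model.kinase, event, p_ref, p_mut,
                         mss_ref, mss_mut,
                         model.kinase in site.known_kinases)


def scan_rewiring(annotations: AnnotationSet | Iterable[PsnvAnnotation],
                  models: Sequence[KinasePwm],
                  backgrounds: Mapping[str, MssBackground],
                  config: RunConfig = DEFAULT_CONFIG,
                  known_only: bool = False) -> list[RewiringEvent]:
    """Evaluate all flanking pSNVs against all retained kinase models.

    Direct annotations are excluded here (handled by
    :func:`direct_psnv_calls`); identical (variant, site) pairs reached
    through overlapping windows are evaluated once per window.
    """
    events: list[RewiringEvent] = []
    for a in annotations:
        if a.psnv_class == "direct":
            continue
        for model in models:
            if not model.retained:
                continue
            if known_only and model.kinase not in a.site.known_kinases:
                continue
            e = classify_rewiring(a.site, a.variant, model,
                                  backgrounds[model.kinase], config)
            if e is not None:
                events.append(e)
    return events


def direct_psnv_calls(annotations: AnnotationSet | Iterable[PsnvAnnotation]
                      ) -> list[RewiringEvent]:
    """Unconditional loss calls for direct pSNVs.

    Replacing the phospho-acceptor destroys the site for every kinase, so no
    PWM is needed; the loss is attributed to each known kinase of the site,
    or to ``unknown`` when none is annotated.  Offset-0 S↔T exchanges are
    proximal, not direct, and never reach this call.
    """
    events: list[RewiringEvent] = []
    seen: set[tuple] = set()
    for a in annotations:
        if a.psnv_class != "direct":
            continue
        kinases = sorted(a.site.known_kinases) or ["unknown"]
        for k in kinases:
            key = (a.variant.key, a.site.protein_id, a.site.position, k)
            if key in seen:
                continue
            seen.add(key)
            events.append(RewiringEvent(
                a.variant, a.site, k, "loss", None, None, None, None,
                kinase_known=k != "unknown"))
    return events


def assemble_network(events: Iterable[RewiringEvent],
                     config: RunConfig = DEFAULT_CONFIG) -> RewiredNetwork:
    """Aggregate per-(variant, kinase) events into a rewired network."""
    return RewiredNetwork(edges=list(events))


def high_confidence_filter(network: RewiredNetwork) -> RewiredNetwork:
    """Keep experimentally supported losses and top-scoring gains.

    Loss events survive only when the kinase is experimentally annotated to
    the site.  Gain events survive only when they are the single best mutant
    MSS among that variant's gains (ties: smaller pMut, then kinase name).
    Idempotent; only removes edges.
    """
    losses = [e for e in network.edges
              if e.event == "loss" and e.kinase_known]
    gains_by_variant: dict[tuple, list[RewiringEvent]] = {}
    for e in network.edges:
        if e.event == "gain":
            gains_by_variant.setdefault(e.variant.key, []).append(e)
    gains = []
    for cand in gains_by_variant.values():
        best = min(cand, key=lambda e: (-(e.mss_mut if e.mss_mut is not None
                                          else 0.0),
                                        e.p_mut if e.p_mut is not None else 1.0,
                                        e.kinase))
        gains.append(best)
    return RewiredNetwork(edges=losses + gains)
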