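"""Enrichment statistics for pSNV analyses.

The workhorse is the one-tailed Poisson exact test: an observed event count
is compared against the expectation ``λ = background rate × exposure``, where
the background rate is estimated from a matched reference stratum (e.g. SNVs
per residue of non-phosphosite sequence, pSNVs per residue of all
phospho-associated sequence, or mean mutations per gene).  On top of it sit:

* sequence-context tests (structured vs disordered phosphosite regions,
  depletion of direct pSNVs);
* protein-domain enrichment with the <3-protein pre-filters and BH-FDR 0.05;
* pathway enrichment with list-size filters, single-gene/single-sample
  discards, stratified BH-FDR per (source × mutation type × cancer type),
  and the pSNV-specific final selection (pan-cancer pSNV FDR < 0.01 while
  every SNV analysis stays non-significant at FDR > 0.1);
* PPI within/between-group interaction tests against a mean-degree
  background;
* the functional-impact bin binomial test and a label-permutation test for
  score comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DEFAULT_CONFIG, RunConfig
from .errors import FormatError

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One tested unit: observed count vs Poisson expectation."""

    unit_id: str
    observed: int
    exposure: float
    bg_rate: float
    expected: float
    p_value: float
    direction: str  # enriched | depleted
    fdr: float | None = None
    flagged: bool = False  # display flag (e.g. >= 25 pSNVs for domains)


@dataclass
class ImpactBinCounts:
    """Variant counts in one functional-impact confidence bin.

    Bins follow the five-predictor majority vote: low = 0-1 methods call
    the variant damaging, moderate = 2-4, high = 5.
    """

    bin: str  # low | moderate | high
    psnv_count: int
    other_snv_count: int


# ---------------------------------------------------------------------------
# core tests
# ---------------------------------------------------------------------------

def poisson_exact_p(observed: int, expected: float,
                    direction: str = "enriched") -> float:
    """One-tailed Poisson exact tail probability.

    ``enriched``: P(X >= observed); ``depleted``: P(X <= observed) for
    X ~ Poisson(expected).  Evaluated exactly via the regularized incomplete
    gamma function, never a normal approximation.
    """
    if expected <= 0:
        raise FormatError(f"expected must be positive, got {expected}")
    if observed < 0:
        raise FormatError("observed must be non-negative")
    if direction == "enriched":
        return float(stats.poisson.sf(observed - 1, expected))
    if direction == "depleted":
        return float(stats.poisson.cdf(observed, expected))
    raise FormatError(f"unknown direction {direction!r}")


def poisson_expected_range(expected: float, n_draws: int = 10000,
                           seed: int = 0) -> tuple[float, float]:
    """Robust expected range: median ± MAD of seeded Poisson draws."""
    if n_draws < 1000:
        raise FormatError("n_draws must be at least 1000")
    draws = np.random.default_rng(seed).poisson(expected, size=n_draws)
    med = float(np.median(draws))
    mad = float(np.median(np.abs(draws - med)))
    return med, mad


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR, original ordering preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise FormatError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def impact_bin_test(bins: Sequence[ImpactBinCounts]) -> dict[str, float]:
    """Two-sided binomial test of pSNV impact-bin frequencies.

    Background success probabilities are the bin frequencies of the other
    (non-phosphosite) SNVs.
    """
    total_psnv = sum(b.psnv_count for b in bins)
    total_other = sum(b.other_snv_count for b in bins)
    if total_other <= 0:
        raise FormatError("other-SNV totals must be positive")
    if total_psnv == 0:
        warnings.warn("empty pSNV set: impact bin test skipped", stacklevel=2)
        return {}
    out: dict[str, float] = {}
    for b in bins:
        freq = b.other_snv_count / total_other
        out[b.bin] = float(stats.binomtest(
            b.psnv_count, total_psnv, freq, alternative="two-sided").pvalue)
    return out


def permutation_mean_diff(scores_a: Sequence[float],
                          scores_b: Sequence[float],
                          n_perm: int = 10000, seed: int = 0) -> float:
    """Permutation p-value for |mean(a) - mean(b)|, plus-one smoothed."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise FormatError("both score groups must be non-empty")
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:a.size].mean() - pooled[a.size:].mean()) >= observed:
            k += 1
    return (k + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# sequence-context tests
# ---------------------------------------------------------------------------

def context_enrichment(counts, config: RunConfig = DEFAULT_CONFIG
                       ) -> list[EnrichmentResult]:
    """Test phosphosite regions for pSNV enrichment by structure class.

    For structured and disordered sequence separately, the observed pSNV
    count in phospho-associated residues is compared to the SNV rate of the
    matching non-phospho sequence.  Direct pSNVs are tested for depletion
    against the overall non-phospho SNV rate applied to the phospho-acceptor
    residues themselves.
    """
    results: list[EnrichmentResult] = []
    for st in ("structured", "disordered"):
        exposure = counts.exposure[("phospho", st)]
        bg_exp = counts.exposure[("other", st)]
        if exposure == 0 or bg_exp == 0:
            warnings.warn(f"zero exposure for context {st}; skipped",
                          stacklevel=2)
            continue
        rate = counts.mutations[("other", st)] / bg_exp
        if rate == 0:
            rate = 1.0 / bg_exp  # no background mutations: floor at one event
        expected = rate * exposure
        obs = counts.mutations[("phospho", st)]
        results.append(EnrichmentResult(
            st, obs, exposure, rate, expected,
            poisson_exact_p(obs, expected, "enriched"), "enriched"))
    other_exp = (counts.exposure[("other", "structured")]
                 + counts.exposure[("other", "disordered")])
    if counts.n_central > 0 and other_exp > 0:
        rate = (counts.mutations[("other", "structured")]
                + counts.mutations[("other", "disordered")]) / other_exp
        if rate == 0:
            rate = 1.0 / other_exp
        expected = rate * counts.n_central
        results.append(EnrichmentResult(
            "direct", counts.n_direct, counts.n_central, rate, expected,
            poisson_exact_p(counts.n_direct, expected, "depleted"),
            "depleted"))
    return results


# ---------------------------------------------------------------------------
# protein domains
# ---------------------------------------------------------------------------

def _interval_overlap(start: int, end: int,
                      regions: Sequence) -> set[int]:
    out: set[int] = set()
    for r in regions:
        lo, hi = max(start, r.start), min(end, r.end)
        if lo <= hi:
            out.update(range(lo, hi + 1))
    return out


def domain_enrichment(domains: pd.DataFrame, annotations, regions,
                      config: RunConfig = DEFAULT_CONFIG
                      ) -> list[EnrichmentResult]:
    """Poisson enrichment of pSNVs in protein domains.

    Domains present in fewer than 3 proteins, or with domain-specific pSNVs
    in fewer than 3 proteins, are filtered before testing.  Observed counts
    are distinct pSNVs inside the domain ∩ phospho-region intersection; the
    background rate is pSNVs per residue over all phospho-associated
    sequence.  BH-FDR at ``fdr_domain``; results with at least
    ``domain_display_min_psnvs`` pSNVs carry the display flag.
    """
    region_map: dict[str, list] = {}
    for r in regions:
        region_map.setdefault(r.protein_id, []).append(r)
    total_phospho_res = sum(r.end - r.start + 1 for r in regions)
    psnv_keys = annotations.psnv_variant_keys()
    psnv_pos: dict[str, list[tuple]] = {}
    for key in psnv_keys:
        psnv_pos.setdefault(key[0], []).append(key)
    total_psnvs = len(psnv_keys)
    if total_phospho_res == 0 or total_psnvs == 0:
        return []
    bg_rate = total_psnvs / total_phospho_res

    per_domain: dict[str, dict] = {}
    for row in domains.itertuples(index=False):
        d = per_domain.setdefault(row.domain_name, {
            "proteins": set(), "exposure": 0, "observed": 0,
            "mutated_proteins": set()})
        d["proteins"].add(row.protein_id)
        overlap = _interval_overlap(row.start, row.end,
                                    region_map.get(row.protein_id, ()))
        d["exposure"] += len(overlap)
        for key in psnv_pos.get(row.protein_id, ()):
            if key[1] in overlap:
                d["observed"] += 1
                d["mutated_proteins"].add(row.protein_id)

    results: list[EnrichmentResult] = []
    for name, d in sorted(per_domain.items()):
        if len(d["proteins"]) < 3 or len(d["mutated_proteins"]) < 3:
            continue
        if d["exposure"] == 0:
            warnings.warn(f"domain {name}: no overlap with phospho regions; "
                          "skipped", stacklevel=2)
            continue
        expected = bg_rate * d["exposure"]
        results.append(EnrichmentResult(
            name, d["observed"], d["exposure"], bg_rate, expected,
            poisson_exact_p(d["observed"], expected, "enriched"),
            "enriched",
            flagged=d["observed"] >= config.domain_display_min_psnvs))
    if results:
        fdrs = bh_fdr([r.p_value for r in results])
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

PAN_CANCER = "pancancer"


def pathway_enrichment(gene_sets: Mapping[str, dict],
                       variants: pd.DataFrame,
                       all_genes: Iterable[str],
                       phospho_genes: Iterable[str],
                       config: RunConfig = DEFAULT_CONFIG
                       ) -> tuple[pd.DataFrame, list[str]]:
    """Stratified Poisson pathway enrichment with the pSNV-specific filter.

    ``variants`` needs columns ``gene``, ``sample_id``, ``cancer_type`` and
    boolean ``is_psnv``.  Gene sets outside 3..1000 genes are excluded; a
    set whose in-stratum mutations come from a single gene or a single
    sample is discarded from that stratum.  Expected counts are member-gene
    count × mean mutations per gene of the stratum's gene universe (all
    genes for the SNV analysis, phosphosite-bearing genes for pSNVs).
    BH-FDR runs separately per (source, mutation type, cancer type).

    Returns the full result table and the final pan-cancer pSNV-specific
    selection: pan-cancer pSNV FDR < ``fdr_pathway`` while the pan-cancer
    and every per-cancer SNV analysis stay above ``snv_pathway_exclusion``.
    """
    required = {"gene", "sample_id", "cancer_type", "is_psnv"}
    if not required.issubset(variants.columns):
        raise FormatError(
            f"variant table missing columns {sorted(required - set(variants.columns))}")
    all_genes = frozenset(all_genes)
    phospho_genes = frozenset(phospho_genes)
    cancer_types = sorted(variants["cancer_type"].unique())
    usable = {name: info for name, info in gene_sets.items()
              if 3 <= len(info["genes"]) <= 1000}

    rows: list[dict] = []
    strata = [("snv", ct) for ct in cancer_types + [PAN_CANCER]]
    strata += [("psnv", ct) for ct in cancer_types + [PAN_CANCER]]
    for mut_type, cancer in strata:
        sub = variants if cancer == PAN_CANCER else variants[
            variants["cancer_type"] == cancer]
        if mut_type == "psnv":
            sub = sub[sub["is_psnv"]]
            universe = phospho_genes
        else:
            universe = all_genes
        sub = sub[sub["gene"].isin(universe)]
        if len(universe) == 0 or len(sub) == 0:
            continue
        mean_per_gene = len(sub) / len(universe)
        gene_counts = sub.groupby("gene").size()
        for name, info in sorted(usable.items()):
            members = info["genes"] & universe
            if not members:
                continue
            in_set = sub[sub["gene"].isin(members)]
            observed = len(in_set)
            if observed > 0 and (in_set["gene"].nunique() == 1
                                 or in_set["sample_id"].nunique() == 1):
                continue  # mutations in only single genes or samples
            expected = mean_per_gene * len(members)
            rows.append({
                "gene_set": name, "source": info["source"],
                "mutation_type": mut_type, "cancer_type": cancer,
                "observed": observed, "exposure": len(members),
                "expected": expected,
                "p_value": poisson_exact_p(observed, expected, "enriched"),
            })
    table = pd.DataFrame(rows)
    if table.empty:
        return table, []
    table["fdr"] = np.nan
    for _, idx in table.groupby(
            ["source", "mutation_type", "cancer_type"]).groups.items():
        table.loc[idx, "fdr"] = bh_fdr(table.loc[idx, "p_value"])

    selected: list[str] = []
    pan_psnv = table[(table["mutation_type"] == "psnv")
                     & (table["cancer_type"] == PAN_CANCER)]
    for row in pan_psnv.itertuples(index=False):
        if row.fdr >= config.fdr_pathway:
            continue
        snv = table[(table["gene_set"] == row.gene_set)
                    & (table["mutation_type"] == "snv")]
        if (snv["fdr"] <= config.snv_pathway_exclusion).any():
            continue
        selected.append(row.gene_set)
    return table, sorted(selected)


# ---------------------------------------------------------------------------
# PPI groups
# ---------------------------------------------------------------------------

def ppi_group_enrichment(ppi_edges: Sequence[frozenset[str]],
                         protein_groups: Mapping[str, Iterable[str]]
                         ) -> list[EnrichmentResult]:
    """Poisson tests of PPI density within and between protein groups.

    The background expectation uses the mean degree over all proteins of the
    analyzed network: within a group, expected = |group| × mean_degree / 2;
    between two groups, expected = min(|A|, |B|) × mean_degree.
    """
    import networkx as nx

    graph = nx.Graph()
    for e in ppi_edges:
        a, b = sorted(e)
        graph.add_edge(a, b)
    nodes = set(graph.nodes)
    groups = {name: frozenset(members)
              for name, members in protein_groups.items()}
    for name, members in groups.items():
        missing = sorted(members - nodes)
        if missing:
            raise FormatError(
                f"group {name!r} proteins not in network: {missing}")
    mean_degree = 2 * graph.number_of_edges() / max(1, len(nodes))

    results: list[EnrichmentResult] = []
    for name in sorted(groups):
        members = groups[name]
        observed = sum(1 for e in graph.edges
                       if e[0] in members and e[1] in members)
        expected = len(members) * mean_degree / 2
        if expected == 0:
            continue
        p = (1.0 if observed == 0
             else poisson_exact_p(observed, expected, "enriched"))
        results.append(EnrichmentResult(
            f"within:{name}", observed, len(members), mean_degree, expected,
            p, "enriched"))
    names = sorted(groups)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            a, b = groups[na], groups[nb]
            observed = sum(1 for e in graph.edges
                           if (e[0] in a and e[1] in b)
                           or (e[0] in b and e[1] in a))
            expected = min(len(a), len(b)) * mean_degree
            if expected == 0:
                continue
            p = (1.0 if observed == 0
                 else poisson_exact_p(observed, expected, "enriched"))
            results.append(EnrichmentResult(
                f"between:{na}|{nb}", observed, min(len(a), len(b)),
                mean_degree, expected, p, "enriched"))
    return results
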