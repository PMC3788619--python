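"""Synthetic proteomes, phosphosites, kinase motifs and mutation cohorts.

Every other module is testable without downloads because this module
generates structurally equivalent inputs with known ground truth.  The
generated world emulates the statistical structure of the real inputs:

* random protein sequences with contiguous intrinsically disordered
  segments;
* phosphosites (S/T/Y plus ±7 flanks) spaced so windows never collide;
* kinase motifs with an obligate anchor residue (as in proline-directed
  kinases, which require the +1 proline) plus several moderate positional
  preferences — and a phosphoproteome whose non-target sites share the
  anchor and the moderate preferences at realistic frequencies, because
  kinase families overlap heavily in specificity;
* mutation cohorts with per-sample Poisson counts, optional planted rate
  multipliers inside chosen region classes, and truth-labelled
  motif-destroying / motif-neutral variants at kinase target sites.

Everything is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (AMINO_ACIDS, CENTER, PHOSPHO_RESIDUES, WINDOW,
                         MissenseVariant, PhosphoSite, build_site_windows)
from .errors import FormatError
from .io_formats import (ProteinRecord, write_gmt, write_kinase_sites,
                         write_mutations, write_phosphosites, write_ppi,
                         write_proteome)
from .kinase_models import N_AA

AA_ARRAY = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class KinaseMotif:
    """Ground-truth specificity of one synthetic kinase.

    ``anchor_offset`` carries the obligate residue; ``moderate`` maps
    further offsets to preferred residues.  Strengths are the probability
    that a training peptide carries the consensus (on top of the uniform
    1/20 chance).
    """

    name: str
    anchor_offset: int
    anchor_residue: str
    moderate: tuple[tuple[int, str], ...]
    anchor_strength: float = 0.98
    moderate_strength: float = 0.9

    @property
    def offsets(self) -> frozenset[int]:
        return frozenset({self.anchor_offset}
                         | {o for o, _ in self.moderate})


DEFAULT_MOTIFS = (
    KinaseMotif("KIN_A", +1, "P", ((-3, "R"), (-2, "R"), (2, "L"), (3, "K"))),
    KinaseMotif("KIN_B", -1, "E", ((-5, "D"), (-4, "E"), (4, "G"), (5, "N"))),
)


@dataclass
class FixtureSpec:
    """All knobs of the synthetic world; defaults are the demo conditions."""

    n_proteins: int = 150
    length_range: tuple[int, int] = (360, 520)
    disorder_fraction: float = 0.37
    n_kinases: int = 2
    #: per-kinase motifs; None selects DEFAULT_MOTIFS[:n_kinases]
    motif_positions: tuple[KinaseMotif, ...] | None = None
    sites_per_protein: float = 2.4
    targets_per_kinase: int = 20
    training_peptides_per_kinase: int = 60
    n_bg_kinase_names: int = 25
    #: frequency at which non-target sites carry a kinase's anchor residue
    #: (proline-directed anchors are shared by a large minority of real sites)
    anchor_bg_match: float = 0.45
    #: frequency at which non-target sites carry a moderate preference
    moderate_bg_match: float = 0.5
    n_samples: int = 40
    n_cancer_types: int = 3
    base_mutation_rate: float = 0.002  # per residue per sample
    planted_enrichment: dict[str, float] = field(default_factory=dict)
    n_rewiring_variants: int = 40  # per truth class (destroying / neutral)
    n_domains: int = 12
    domain_length: tuple[int, int] = (60, 100)
    n_gene_sets: int = 15
    gene_set_size: tuple[int, int] = (8, 20)
    planted_set_size: int = 20
    ppi_edge_prob: float = 0.05
    ppi_clique_size: int = 0
    seed: int = 0

    def motifs(self) -> tuple[KinaseMotif, ...]:
        if self.motif_positions is not None:
            return tuple(self.motif_positions)
        if self.n_kinases > len(DEFAULT_MOTIFS):
            raise FormatError(
                f"no default motifs for {self.n_kinases} kinases; "
                "pass motif_positions explicitly")
        return DEFAULT_MOTIFS[:self.n_kinases]


@dataclass
class SyntheticBundle:
    """The complete generated input world plus its truth tables."""

    spec: FixtureSpec
    proteins: dict[str, ProteinRecord]
    sites: list[PhosphoSite]
    site_truth: pd.DataFrame  # protein_id, position, target_kinase ('' = bg)
    domains: pd.DataFrame
    gene_sets: dict[str, dict]
    ppi_edges: list[frozenset[str]]
    kinase_peptides: dict[str, list[str]]
    truth_pwms: dict[str, np.ndarray]

    def background_windows(self, kinase: str) -> list[str]:
        """Windows of sites with known kinases not associated to ``kinase``."""
        return [s.window for s in self.sites
                if s.known_kinases and kinase not in s.known_kinases]

    def target_sites(self, kinase: str) -> list[PhosphoSite]:
        return [s for s in self.sites if kinase in s.known_kinases]


def _disorder_mask(length: int, fraction: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Contiguous disordered blocks covering ≈ ``fraction`` of the protein."""
    mask = np.zeros(length, dtype=bool)
    pos = 0
    while pos < length:
        block = int(rng.integers(20, 61))
        if rng.random() < fraction:
            mask[pos:pos + block] = True
        pos += block
    return mask


def _truth_pwm(motif: KinaseMotif) -> np.ndarray:
    """The (20, 15) probability matrix peptides are sampled from."""
    probs = np.full((N_AA, WINDOW), 1.0 / N_AA)
    strengths = [(motif.anchor_offset, motif.anchor_residue,
                  motif.anchor_strength)]
    strengths += [(o, aa, motif.moderate_strength) for o, aa in motif.moderate]
    for off, aa, s in strengths:
        col = CENTER + off
        probs[:, col] = (1 - s) / N_AA
        probs[AMINO_ACIDS.index(aa), col] += s
    # central column: uniform over S/T/Y
    probs[:, CENTER] = 0.0
    for aa in PHOSPHO_RESIDUES:
        probs[AMINO_ACIDS.index(aa), CENTER] = 1.0 / 3
    return probs


def generate_kinase(spec: FixtureSpec, kinase_id: int,
                    rng: np.random.Generator | None = None,
                    n_peptides: int | None = None
                    ) -> tuple[np.ndarray, list[str]]:
    """Sample training peptides for one kinase from its ground-truth PWM."""
    motif = spec.motifs()[kinase_id]
    if 0 in motif.offsets:
        raise FormatError("motif offsets must exclude the central residue")
    if rng is None:
        rng = np.random.default_rng((spec.seed, 7, kinase_id))
    n = n_peptides if n_peptides is not None else spec.training_peptides_per_kinase
    pwm = _truth_pwm(motif)
    peptides = []
    for _ in range(n):
        chars = [AA_ARRAY[rng.choice(N_AA, p=pwm[:, c])]
                 for c in range(WINDOW)]
        peptides.append("".join(chars))
    return pwm, peptides


def sample_background_windows(spec: FixtureSpec, n: int,
                              rng: np.random.Generator,
                              exclude_kinase: int | None = None
                              ) -> list[str]:
    """Sample phosphosite windows with the background motif-sharing rates.

    Used for stand-alone kinase-model tests; the proteome generator embeds
    the same residue process into real protein sequences.
    """
    motifs = spec.motifs()
    out = []
    for _ in range(n):
        chars = list(AA_ARRAY[rng.integers(0, N_AA, size=WINDOW)])
        chars[CENTER] = rng.choice(list(PHOSPHO_RESIDUES))
        for motif in motifs:
            if rng.random() < spec.anchor_bg_match:
                chars[CENTER + motif.anchor_offset] = motif.anchor_residue
            for off, aa in motif.moderate:
                if rng.random() < spec.moderate_bg_match:
                    chars[CENTER + off] = aa
        out.append("".join(chars))
    return out


def generate_proteome(spec: FixtureSpec) -> SyntheticBundle:
    """Generate proteins, phosphosites, domains, gene sets and PPI edges."""
    rng = np.random.default_rng((spec.seed, 1))
    motifs = spec.motifs()
    seqs: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    genes: dict[str, str] = {}
    site_rows: list[dict] = []

    for i in range(spec.n_proteins):
        pid = f"PROT{i:04d}"
        genes[pid] = f"G{i:04d}"
        length = int(rng.integers(spec.length_range[0],
                                  spec.length_range[1] + 1))
        seq = AA_ARRAY[rng.integers(0, N_AA, size=length)].copy()
        seqs[pid] = seq
        masks[pid] = _disorder_mask(length, spec.disorder_fraction, rng)
        # candidate site centers on a 16-residue grid: windows never collide
        candidates = np.arange(10, length - 8, 16)
        if len(candidates):
            p_keep = min(1.0, spec.sites_per_protein / len(candidates))
            for pos in candidates[rng.random(len(candidates)) < p_keep]:
                residue = rng.choice(list(PHOSPHO_RESIDUES))
                seq[pos - 1] = residue
                site_rows.append({"protein_id": pid, "position": int(pos),
                                  "residue": residue})

    # assign target sites per kinase, label the rest with background kinases
    order = rng.permutation(len(site_rows))
    targets_needed = spec.targets_per_kinase * len(motifs)
    if len(site_rows) < targets_needed:
        raise FormatError(
            f"only {len(site_rows)} sites for {targets_needed} targets; "
            "increase n_proteins or sites_per_protein")
    for rank, idx in enumerate(order):
        row = site_rows[idx]
        if rank < targets_needed:
            row["target_kinase"] = motifs[rank % len(motifs)].name
        else:
            row["target_kinase"] = ""
            row["bg_kinase"] = f"BGK{int(rng.integers(spec.n_bg_kinase_names)):03d}"

    # write motif residues into the flanks
    for row in site_rows:
        seq = seqs[row["protein_id"]]
        pos = row["position"]
        for motif in motifs:
            if row["target_kinase"] == motif.name:
                seq[pos - 1 + motif.anchor_offset] = motif.anchor_residue
                for off, aa in motif.moderate:
                    seq[pos - 1 + off] = aa
            else:
                if rng.random() < spec.anchor_bg_match:
                    seq[pos - 1 + motif.anchor_offset] = motif.anchor_residue
                for off, aa in motif.moderate:
                    if rng.random() < spec.moderate_bg_match:
                        seq[pos - 1 + off] = aa

    proteins = {pid: ProteinRecord(pid, genes[pid], "".join(seqs[pid]),
                                   masks[pid])
                for pid in seqs}

    sites: list[PhosphoSite] = []
    for row in site_rows:
        kin = row["target_kinase"] or row.get("bg_kinase", "")
        sites.extend(build_site_windows(
            proteins[row["protein_id"]],
            [(row["position"], row["residue"], {kin} if kin else set())]))
    site_truth = pd.DataFrame(
        [{"protein_id": r["protein_id"], "position": r["position"],
          "target_kinase": r["target_kinase"]} for r in site_rows])

    domains = _generate_domains(spec, proteins, site_truth, rng)
    gene_sets = _generate_gene_sets(spec, proteins, site_truth, rng)
    ppi_edges = _generate_ppi(spec, proteins, rng)

    kinase_peptides: dict[str, list[str]] = {}
    truth_pwms: dict[str, np.ndarray] = {}
    for k, motif in enumerate(motifs):
        pwm, peptides = generate_kinase(spec, k)
        truth_pwms[motif.name] = pwm
        kinase_peptides[motif.name] = peptides

    return SyntheticBundle(spec, proteins, sites, site_truth, domains,
                           gene_sets, ppi_edges, kinase_peptides, truth_pwms)


def _generate_domains(spec, proteins, site_truth, rng) -> pd.DataFrame:
    rows = []
    names = [f"DOM{i:02d}" for i in range(spec.n_domains)]
    sources = ["SMART" if i % 2 == 0 else "Pfam"
               for i in range(spec.n_domains)]
    for pid, rec in proteins.items():
        for _ in range(int(rng.integers(1, 3))):
            j = int(rng.integers(spec.n_domains))
            dlen = int(rng.integers(*spec.domain_length))
            start = int(rng.integers(1, max(2, len(rec.sequence) - dlen)))
            rows.append({"protein_id": pid, "domain_name": names[j],
                         "start": start, "end": start + dlen - 1,
                         "source": sources[j]})
    # planted domain: cover two adjacent site windows in several proteins
    planted = [k.split(":", 1)[1] for k in spec.planted_enrichment
               if k.startswith("domain:")]
    for name in planted:
        by_protein = site_truth.groupby("protein_id")["position"].apply(list)
        hosts = [pid for pid, ps in by_protein.items() if len(ps) >= 2][:5]
        for pid in hosts:
            ps = sorted(by_protein[pid])[:2]
            rows.append({"protein_id": pid, "domain_name": name,
                         "start": max(1, ps[0] - 7), "end": ps[1] + 7,
                         "source": "Pfam"})
    return pd.DataFrame(rows)


def _generate_gene_sets(spec, proteins, site_truth, rng) -> dict[str, dict]:
    genes = [rec.gene_symbol for rec in proteins.values()]
    gene_by_pid = {pid: rec.gene_symbol for pid, rec in proteins.items()}
    phospho_pids = sorted(site_truth["protein_id"].unique())
    sources = ["GO", "Reactome", "CORUM"]
    sets: dict[str, dict] = {}
    for i in range(spec.n_gene_sets):
        size = int(rng.integers(*spec.gene_set_size))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sets[f"SET{i:02d}"] = {"source": sources[i % 3],
                               "genes": frozenset(members)}
    planted = {k.split(":", 1)[1] for k in spec.planted_enrichment
               if k.startswith(("geneset_psnv:", "geneset_snv:"))}
    # planted sets are pairwise disjoint so their rate multipliers never stack
    pool = list(rng.permutation(phospho_pids))
    for name in sorted(planted):
        take = min(spec.planted_set_size, len(pool))
        members, pool = pool[:take], pool[take:]
        sets[name] = {"source": "GO",
                      "genes": frozenset(gene_by_pid[p] for p in members)}
    return sets


def _generate_ppi(spec, proteins, rng) -> list[frozenset[str]]:
    pids = sorted(proteins)
    edges: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for i, a in enumerate(pids):
        for b in pids[i + 1:]:
            if rng.random() < spec.ppi_edge_prob:
                e = frozenset((a, b))
                seen.add(e)
                edges.append(e)
    for i in range(spec.ppi_clique_size):
        for j in range(i + 1, spec.ppi_clique_size):
            e = frozenset((pids[i], pids[j]))
            if e not in seen:
                seen.add(e)
                edges.append(e)
    return edges


# ---------------------------------------------------------------------------
# mutation cohorts
# ---------------------------------------------------------------------------

def _member_pids(gene_sets, proteins, name) -> set[str]:
    genes = gene_sets[name]["genes"]
    return {pid for pid, rec in proteins.items() if rec.gene_symbol in genes}


def generate_cohort(spec: FixtureSpec, bundle: SyntheticBundle
                    ) -> tuple[list[MissenseVariant], pd.DataFrame]:
    """Sample a mutation cohort with optional planted enrichments.

    Returns the variants plus a truth table with one row per variant and a
    ``truth`` label: ``background``, ``motif_destroying`` or
    ``motif_neutral``.  Planted multipliers (``phospho_window``,
    ``phospho_window_structured``, ``domain:<name>``,
    ``geneset_psnv:<name>``, ``geneset_snv:<name>``) scale the local
    mutation rate inside the corresponding region class.
    """
    rng = np.random.default_rng((spec.seed, 2))
    proteins = bundle.proteins
    pids = sorted(proteins)
    offsets = {}
    total = 0
    for pid in pids:
        offsets[pid] = total
        total += len(proteins[pid].sequence)

    weights = np.ones(total)
    covered = np.zeros(total, dtype=bool)
    for s in bundle.sites:
        base = offsets[s.protein_id]
        lo = max(1, s.position - 7)
        hi = min(len(proteins[s.protein_id].sequence), s.position + 7)
        covered[base + lo - 1: base + hi] = True
    disordered = np.concatenate(
        [proteins[pid].disorder_mask for pid in pids])

    for key, mult in spec.planted_enrichment.items():
        if key == "phospho_window":
            weights[covered] *= mult
        elif key == "phospho_window_structured":
            weights[covered & ~disordered] *= mult
        elif key.startswith("domain:"):
            name = key.split(":", 1)[1]
            sel = bundle.domains[bundle.domains["domain_name"] == name]
            for row in sel.itertuples(index=False):
                base = offsets[row.protein_id]
                hi = min(row.end, len(proteins[row.protein_id].sequence))
                weights[base + row.start - 1: base + hi] *= mult
        elif key.startswith("geneset_psnv:"):
            # emulate site-directed selection: concentrate the gene's
            # mutation burden into phospho windows without changing the
            # gene-level total, so only the pSNV analysis sees the signal
            for pid in _member_pids(bundle.gene_sets, proteins,
                                    key.split(":", 1)[1]):
                base = offsets[pid]
                n = len(proteins[pid].sequence)
                idx = np.arange(base, base + n)
                cov = covered[idx]
                c = int(cov.sum())
                if c == 0 or c == n:
                    continue
                comp = max(1e-9, (n - mult * c) / (n - c))
                weights[idx[cov]] *= mult
                weights[idx[~cov]] *= comp
        elif key.startswith("geneset_snv:"):
            for pid in _member_pids(bundle.gene_sets, proteins,
                                    key.split(":", 1)[1]):
                base = offsets[pid]
                weights[base: base + len(proteins[pid].sequence)] *= mult
        else:
            raise FormatError(f"unknown planted_enrichment key {key!r}")

    samples = [f"S{i:03d}" for i in range(spec.n_samples)]
    cancers = [f"CT{i % spec.n_cancer_types + 1}"
               for i in range(spec.n_samples)]
    pid_index = np.empty(total, dtype=object)
    pos_index = np.empty(total, dtype=np.int64)
    for pid in pids:
        base = offsets[pid]
        n = len(proteins[pid].sequence)
        pid_index[base: base + n] = pid
        pos_index[base: base + n] = np.arange(1, n + 1)

    n_mut = int(rng.poisson(spec.base_mutation_rate * spec.n_samples
                            * weights.sum()))
    probs = weights / weights.sum()
    picks = rng.choice(total, size=n_mut, p=probs)
    variants: list[MissenseVariant] = []
    truth_rows: list[dict] = []
    for flat in picks:
        pid = pid_index[flat]
        pos = int(pos_index[flat])
        ref = proteins[pid].sequence[pos - 1]
        if ref == "X":
            continue
        alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
        si = int(rng.integers(spec.n_samples))
        v = MissenseVariant(pid, pos, ref, alt, samples[si], cancers[si])
        variants.append(v)
        truth_rows.append({"protein_id": pid, "position": pos,
                           "ref_aa": ref, "alt_aa": alt,
                           "sample_id": samples[si], "truth": "background"})

    # truth-labelled rewiring variants at focal-kinase target sites
    if spec.n_rewiring_variants > 0 and spec.n_kinases >= 1:
        motifs = spec.motifs()
        focal = motifs[0]
        used = frozenset().union(*(m.offsets for m in motifs))
        free = sorted(set(range(-CENTER, CENTER + 1)) - set(used) - {0})
        targets = bundle.target_sites(focal.name)
        if not targets:
            raise FormatError("no target sites for the focal kinase")
        for j in range(spec.n_rewiring_variants):
            site = targets[j % len(targets)]
            seq = proteins[site.protein_id].sequence
            # destroying: remove the obligate anchor residue
            pos = site.position + focal.anchor_offset
            ref = seq[pos - 1]
            alt = str(rng.choice([a for a in AMINO_ACIDS
                                  if a not in (ref, focal.anchor_residue)]))
            si = int(rng.integers(spec.n_samples))
            v = MissenseVariant(site.protein_id, pos, ref, alt,
                                samples[si], cancers[si])
            variants.append(v)
            truth_rows.append({"protein_id": v.protein_id, "position": pos,
                               "ref_aa": ref, "alt_aa": alt,
                               "sample_id": v.sample_id,
                               "truth": "motif_destroying"})
            # neutral: touch a flanking position outside every motif
            off = int(rng.choice(free))
            pos = site.position + off
            ref = seq[pos - 1]
            alt = str(rng.choice([a for a in AMINO_ACIDS if a != ref]))
            si = int(rng.integers(spec.n_samples))
            v = MissenseVariant(site.protein_id, pos, ref, alt,
                                samples[si], cancers[si])
            variants.append(v)
            truth_rows.append({"protein_id": v.protein_id, "position": pos,
                               "ref_aa": ref, "alt_aa": alt,
                               "sample_id": v.sample_id,
                               "truth": "motif_neutral"})
    return variants, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# writing the complete input bundle
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle,
                 variants: Sequence[MissenseVariant],
                 truth: pd.DataFrame, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle in exactly the formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("fasta", "proteome.fasta"), ("disorder", "disorder.tsv"),
        ("phosphosites", "phosphosites.tsv"), ("mutations", "mutations.tsv"),
        ("kinase_sites", "kinase_peptides.tsv"), ("domains", "domains.tsv"),
        ("gene_sets", "gene_sets.gmt"), ("ppi", "ppi.tsv"),
        ("truth", "truth.tsv")]}
    write_proteome(bundle.proteins, paths["fasta"], paths["disorder"])
    write_phosphosites(bundle.sites, paths["phosphosites"])
    write_mutations(variants, paths["mutations"])
    write_kinase_sites(bundle.kinase_peptides, paths["kinase_sites"])
    bundle.domains.to_csv(paths["domains"], sep="\t", index=False)
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    write_ppi(bundle.ppi_edges, paths["ppi"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
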