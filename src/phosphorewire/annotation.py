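"""Mapping of missense variants onto phosphorylation sites.

A phosphosite is an experimentally observed phospho-acceptor residue (S/T/Y)
together with its ±7-residue flanking window — the sequence neighbourhood a
protein kinase reads when it selects a substrate.  A missense variant that
falls inside such a window is a phosphorylation-related SNV (pSNV) and is
classified by its offset from the central residue:

* ``direct``   — substitution of the phospho-acceptor itself (offset 0),
  except serine↔threonine exchanges, which kinases treat as equivalent;
* ``proximal`` — within ±2 residues (or an offset-0 S↔T exchange);
* ``distal``   — within ±3..±7 residues.

Overlapping site windows are merged into continuous regions so that residue
exposures and per-region mutation counts are never double counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import FormatError

logger = logging.getLogger(__name__)

#: the 20 standard amino acids, alphabetical
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
PAD = "_"
WINDOW = 15
CENTER = 7  # 0-based index of the phospho-residue in the 15-mer
PHOSPHO_RESIDUES = frozenset("STY")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhosphoSite:
    """One phospho-acceptor residue with its 15-mer sequence window."""

    protein_id: str
    position: int  # 1-based
    residue: str  # S, T or Y
    known_kinases: frozenset[str] = frozenset()
    window: str = ""

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise FormatError(
                f"{self.protein_id}:{self.position}: central residue "
                f"{self.residue!r} is not S/T/Y"
            )
        if self.window:
            if len(self.window) != WINDOW:
                raise FormatError(
                    f"{self.protein_id}:{self.position}: window length "
                    f"{len(self.window)} != {WINDOW}"
                )
            if self.window[CENTER] != self.residue:
                raise FormatError(
                    f"{self.protein_id}:{self.position}: window center "
                    f"{self.window[CENTER]!r} != residue {self.residue!r}"
                )


@dataclass(frozen=True)
class SiteRegion:
    """A maximal run of overlapping/abutting site windows on one protein."""

    protein_id: str
    start: int
    end: int
    member_sites: tuple[PhosphoSite, ...]

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class MissenseVariant:
    """One protein-level amino-acid substitution in one tumor sample."""

    protein_id: str
    position: int  # 1-based
    ref_aa: str
    alt_aa: str
    sample_id: str
    cancer_type: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise FormatError(
                f"{self.protein_id}:{self.position}: identity substitution "
                f"{self.ref_aa}>{self.alt_aa}"
            )
        if self.position <= 0:
            raise FormatError(f"{self.protein_id}: position {self.position} <= 0")

    @property
    def key(self) -> tuple:
        """Identity used to de-duplicate a variant across site windows."""
        return (self.protein_id, self.position, self.ref_aa, self.alt_aa,
                self.sample_id)


@dataclass(frozen=True)
class PsnvAnnotation:
    """A (variant, site) pair with |offset| <= flank width."""

    variant: MissenseVariant
    site: PhosphoSite
    distance: int  # variant position - site position, signed
    psnv_class: str  # direct | proximal | distal
    disorder_context: bool


def _is_st_swap(ref: str, alt: str) -> bool:
    return {ref, alt} == {"S", "T"}


def classify_distance(distance: int, ref_aa: str, alt_aa: str,
                      proximal_width: int = 2, flank_width: int = 7) -> str | None:
    """Classify a substitution by its offset from the phospho-residue.

    Returns ``direct``/``proximal``/``distal`` or None when the offset is
    outside the flanking window.  Offset-0 S↔T exchanges are proximal, not
    direct, because kinases phosphorylate serine and threonine equivalently.
    """
    d = abs(distance)
    if d > flank_width:
        return None
    if d == 0:
        return "proximal" if _is_st_swap(ref_aa, alt_aa) else "direct"
    if d <= proximal_width:
        return "proximal"
    return "distal"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_site_windows(protein, sites: Iterable) -> list[PhosphoSite]:
    """Extract 15-mer windows for phosphosites on one protein.

    ``sites`` yields ``(position, residue, known_kinases)`` triples (kinases
    optional).  Windows at the protein termini are padded with ``_``.
    """
    seq = protein.sequence
    out: list[PhosphoSite] = []
    for entry in sites:
        position, residue, *rest = entry
        kinases = frozenset(rest[0]) if rest and rest[0] else frozenset()
        if not (1 <= position <= len(seq)):
            raise FormatError(
                f"{protein.protein_id}: site position {position} outside "
                f"sequence of length {len(seq)}"
            )
        if residue not in PHOSPHO_RESIDUES:
            raise FormatError(
                f"{protein.protein_id}:{position}: non-S/T/Y residue {residue!r}"
            )
        if seq[position - 1] != residue:
            raise FormatError(
                f"{protein.protein_id}:{position}: annotated residue "
                f"{residue!r} does not match sequence {seq[position - 1]!r}"
            )
        chars = []
        for off in range(-CENTER, CENTER + 1):
            p = position + off
            chars.append(seq[p - 1] if 1 <= p <= len(seq) else PAD)
        out.append(PhosphoSite(protein.protein_id, position, residue,
                               kinases, "".join(chars)))
    return out


def merge_regions(sites: Iterable[PhosphoSite], flank_width: int = 7,
                  proteins: Mapping[str, object] | None = None
                  ) -> list[SiteRegion]:
    """Merge overlapping or abutting ±flank windows into continuous regions.

    Intervals are clipped to ``[1, len(sequence)]`` when the protein record is
    available.  The result is disjoint, sorted, and idempotent under re-merge.
    """
    by_protein: dict[str, list[PhosphoSite]] = {}
    for s in sites:
        by_protein.setdefault(s.protein_id, []).append(s)
    regions: list[SiteRegion] = []
    for pid in sorted(by_protein):
        length = None
        if proteins is not None and pid in proteins:
            length = len(proteins[pid].sequence)
        members = sorted(by_protein[pid], key=lambda s: s.position)
        cur_start = cur_end = None
        cur_members: list[PhosphoSite] = []
        for s in members:
            start = max(1, s.position - flank_width)
            end = s.position + flank_width
            if length is not None:
                end = min(length, end)
            if cur_end is not None and start <= cur_end + 1:
                cur_end = max(cur_end, end)
                cur_members.append(s)
            else:
                if cur_members:
                    regions.append(SiteRegion(pid, cur_start, cur_end,
                                              tuple(cur_members)))
                cur_start, cur_end, cur_members = start, end, [s]
        if cur_members:
            regions.append(SiteRegion(pid, cur_start, cur_end,
                                      tuple(cur_members)))
    return regions


@dataclass
class AnnotationSet:
    """pSNV annotations plus the variants excluded for reference mismatch."""

    annotations: list[PsnvAnnotation] = field(default_factory=list)
    ref_mismatches: list[MissenseVariant] = field(default_factory=list)

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self) -> int:
        return len(self.annotations)

    def psnv_variant_keys(self) -> set[tuple]:
        """Distinct variant identities with at least one annotation."""
        return {a.variant.key for a in self.annotations}


def annotate_psnvs(variants: Sequence[MissenseVariant],
                   sites: Sequence[PhosphoSite],
                   proteins: Mapping[str, object],
                   flank_width: int = 7,
                   proximal_width: int = 2) -> AnnotationSet:
    """Annotate every (variant, site) pair within the flanking window.

    A variant inside two overlapping windows yields two annotations; counting
    helpers de-duplicate by variant identity.  Variants whose reference amino
    acid disagrees with the protein sequence are excluded and reported.
    """
    sites_by_protein: dict[str, list[PhosphoSite]] = {}
    for s in sites:
        sites_by_protein.setdefault(s.protein_id, []).append(s)
    result = AnnotationSet()
    bad_keys: set[tuple] = set()
    for v in variants:
        rec = proteins.get(v.protein_id)
        if rec is not None:
            seq = rec.sequence
            if v.position > len(seq) or seq[v.position - 1] != v.ref_aa:
                if v.key not in bad_keys:
                    bad_keys.add(v.key)
                    result.ref_mismatches.append(v)
                continue
        for s in sites_by_protein.get(v.protein_id, ()):
            d = v.position - s.position
            cls = classify_distance(d, v.ref_aa, v.alt_aa,
                                    proximal_width, flank_width)
            if cls is None:
                continue
            disorder = False
            if rec is not None:
                disorder = bool(rec.disorder_mask[v.position - 1])
            result.annotations.append(
                PsnvAnnotation(v, s, d, cls, disorder))
    if result.ref_mismatches:
        logger.warning("excluded %d variants with reference mismatch",
                       len(result.ref_mismatches))
    return result


# ---------------------------------------------------------------------------
# context counting
# ---------------------------------------------------------------------------

@dataclass
class ContextCounts:
    """Residue exposures and variant counts split by sequence context.

    Keys are ``(region, structure)`` with region in {phospho, other} and
    structure in {structured, disordered}.  Exposures partition the proteome
    residues exactly; mutation counts partition the mappable variants.
    """

    exposure: dict[tuple[str, str], int]
    mutations: dict[tuple[str, str], int]
    n_direct: int
    n_central: int
    n_unmapped_variants: int

    @property
    def total_residues(self) -> int:
        return sum(self.exposure.values())

    @property
    def total_variants(self) -> int:
        return sum(self.mutations.values())


def count_by_context(annotations: AnnotationSet,
                     variants: Sequence[MissenseVariant],
                     proteins: Mapping[str, object],
                     regions: Sequence[SiteRegion]) -> ContextCounts:
    """Tally residue exposures and mutation counts by sequence context.

    Variants are counted once each (multiple overlapping windows do not
    double count); variants on unknown proteins or excluded for reference
    mismatch are reported as unmapped.
    """
    region_map: dict[str, list[SiteRegion]] = {}
    for r in regions:
        region_map.setdefault(r.protein_id, []).append(r)

    exposure = {(reg, st): 0 for reg in ("phospho", "other")
                for st in ("structured", "disordered")}
    for pid, rec in proteins.items():
        covered = [False] * len(rec.sequence)
        for r in region_map.get(pid, ()):
            for p in range(r.start, min(r.end, len(rec.sequence)) + 1):
                covered[p - 1] = True
        for i in range(len(rec.sequence)):
            reg = "phospho" if covered[i] else "other"
            st = "disordered" if rec.disorder_mask[i] else "structured"
            exposure[(reg, st)] += 1

    mismatched = {v.key for v in annotations.ref_mismatches}
    mutations = {k: 0 for k in exposure}
    seen: set[tuple] = set()
    unmapped = 0
    for v in variants:
        if v.key in seen:
            continue
        seen.add(v.key)
        rec = proteins.get(v.protein_id)
        if rec is None or v.key in mismatched or v.position > len(rec.sequence):
            unmapped += 1
            continue
        covered = any(v.position in r for r in region_map.get(v.protein_id, ()))
        reg = "phospho" if covered else "other"
        st = ("disordered" if rec.disorder_mask[v.position - 1]
              else "structured")
        mutations[(reg, st)] += 1

    direct_keys = {a.variant.key for a in annotations
                   if a.psnv_class == "direct"}
    n_central = len({(s.protein_id, s.position)
                     for r in regions for s in r.member_sites})
    return ContextCounts(exposure, mutations, len(direct_keys), n_central,
                         unmapped)
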