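"""Readers and writers for every on-disk format the pipeline touches.

Protein sequences travel as FASTA; mutations, phosphosites, kinase binding
peptides, protein domains, PPI edges and all result tables are
tab-separated text with a header row; gene sets use the GMT convention; and
kinase position weight matrices use a small versioned text format so a model
can be rebuilt byte-identically from disk.  All protein coordinates are
1-based inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotation import (AA_INDEX, AMINO_ACIDS, PHOSPHO_RESIDUES, WINDOW,
                         MissenseVariant, PhosphoSite, PsnvAnnotation)
from .errors import FormatError

logger = logging.getLogger(__name__)

PWM_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

@dataclass
class ProteinRecord:
    """A protein sequence with a per-residue disorder mask.

    The mask is True where the residue is predicted intrinsically
    disordered; it has exactly one entry per residue.
    """

    protein_id: str
    gene_symbol: str
    sequence: str
    disorder_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"{self.protein_id}: empty sequence")
        allowed = set(AMINO_ACIDS) | {"X"}
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in allowed:
                raise FormatError(
                    f"{self.protein_id}: invalid residue {aa!r} at position {i}"
                )
        if self.disorder_mask is None:
            self.disorder_mask = np.zeros(len(self.sequence), dtype=bool)
        else:
            self.disorder_mask = np.asarray(self.disorder_mask, dtype=bool)
        if len(self.disorder_mask) != len(self.sequence):
            raise FormatError(
                f"{self.protein_id}: disorder mask length "
                f"{len(self.disorder_mask)} != sequence length "
                f"{len(self.sequence)}"
            )


def read_proteome(fasta_path: str | Path,
                  disorder_path: str | Path | None = None
                  ) -> dict[str, ProteinRecord]:
    """Read a proteome FASTA plus an optional disorder-mask table.

    FASTA headers are ``>protein_id gene_symbol`` (gene defaults to the id).
    The disorder table has columns ``protein_id`` and ``mask`` (a 0/1
    string).  Proteins without a mask default to fully structured, with a
    logged warning.
    """
    masks: dict[str, np.ndarray] = {}
    if disorder_path is not None:
        tab = pd.read_csv(disorder_path, sep="\t", dtype=str)
        for _, row in tab.iterrows():
            masks[row["protein_id"]] = np.array(
                [c == "1" for c in row["mask"]], dtype=bool)
    records: dict[str, ProteinRecord] = {}
    missing_masks = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        pid = rec.id
        if pid in records:
            raise FormatError(f"duplicate protein_id {pid!r} in {fasta_path}")
        parts = rec.description.split()
        gene = parts[1] if len(parts) > 1 else pid
        mask = masks.get(pid)
        if disorder_path is not None and mask is None:
            missing_masks += 1
        records[pid] = ProteinRecord(pid, gene, str(rec.seq).upper(), mask)
    if missing_masks:
        logger.warning("%d proteins without disorder mask default to "
                       "fully structured", missing_masks)
    return records


def write_proteome(records: Mapping[str, ProteinRecord],
                   fasta_path: str | Path,
                   disorder_path: str | Path | None = None) -> None:
    with open(fasta_path, "w") as fh:
        for rec in records.values():
            fh.write(f">{rec.protein_id} {rec.gene_symbol}\n{rec.sequence}\n")
    if disorder_path is not None:
        rows = [{"protein_id": r.protein_id,
                 "mask": "".join("1" if b else "0" for b in r.disorder_mask)}
                for r in records.values()]
        pd.DataFrame(rows).to_csv(disorder_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def read_mutations(tsv_path: str | Path,
                   cap: int | None = None) -> list[MissenseVariant]:
    """Read a protein-level missense mutation table.

    Rows with ``ref_aa == alt_aa`` are rejected.  When ``cap`` is given,
    every mutation from a sample with more than ``cap`` rows is dropped (a
    hypermutated-sample filter hook) and the dropped sample count logged.
    """
    tab = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"protein_id", "position", "ref_aa", "alt_aa", "sample_id",
                "cancer_type"}
    if not required.issubset(tab.columns):
        raise FormatError(
            f"{tsv_path}: missing columns {sorted(required - set(tab.columns))}")
    tab["position"] = tab["position"].astype(int)
    n_identity = int((tab["ref_aa"] == tab["alt_aa"]).sum())
    if n_identity:
        logger.info("dropping %d identity substitutions", n_identity)
        tab = tab[tab["ref_aa"] != tab["alt_aa"]]
    if cap is not None:
        sizes = tab.groupby("sample_id")["position"].transform("size")
        dropped = tab.loc[sizes > cap, "sample_id"].nunique()
        if dropped:
            logger.info("dropping %d hypermutated samples (cap=%d)",
                        dropped, cap)
        tab = tab[sizes <= cap]
    return [MissenseVariant(r.protein_id, int(r.position), r.ref_aa,
                            r.alt_aa, r.sample_id, r.cancer_type)
            for r in tab.itertuples(index=False)]


def write_mutations(variants: Sequence[MissenseVariant],
                    tsv_path: str | Path) -> None:
    pd.DataFrame(
        [{"protein_id": v.protein_id, "position": v.position,
          "ref_aa": v.ref_aa, "alt_aa": v.alt_aa, "sample_id": v.sample_id,
          "cancer_type": v.cancer_type} for v in variants]
    ).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phosphosites, kinase peptides, domains, gene sets, PPI
# ---------------------------------------------------------------------------

def read_phosphosites(tsv_path: str | Path,
                      proteins: Mapping[str, ProteinRecord] | None = None
                      ) -> list[tuple[str, int, str, frozenset[str]]]:
    """Read phosphosite annotations: protein_id, position, residue, kinases.

    ``kinases`` is a comma-separated list, possibly empty.  When the protein
    is known the annotated residue must match the sequence.
    """
    tab = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in tab.itertuples(index=False):
        pos = int(r.position)
        residue = r.residue
        if residue not in PHOSPHO_RESIDUES:
            raise FormatError(
                f"{tsv_path}: {r.protein_id}:{pos} residue {residue!r} "
                "is not S/T/Y")
        if proteins is not None and r.protein_id in proteins:
            seq = proteins[r.protein_id].sequence
            if pos > len(seq) or seq[pos - 1] != residue:
                raise FormatError(
                    f"{tsv_path}: {r.protein_id}:{pos} residue {residue!r} "
                    f"does not match sequence")
        kin = frozenset(k for k in str(r.kinases).split(",") if k)
        out.append((r.protein_id, pos, residue, kin))
    return out


def write_phosphosites(sites: Iterable[PhosphoSite],
                       tsv_path: str | Path) -> None:
    pd.DataFrame(
        [{"protein_id": s.protein_id, "position": s.position,
          "residue": s.residue,
          "kinases": ",".join(sorted(s.known_kinases))} for s in sites]
    ).to_csv(tsv_path, sep="\t", index=False)


def read_kinase_sites(tsv_path: str | Path) -> dict[str, list[str]]:
    """Read kinase binding-site peptides: columns kinase, peptide (15-mer)."""
    tab = pd.read_csv(tsv_path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for r in tab.itertuples(index=False):
        if len(r.peptide) != WINDOW:
            raise FormatError(
                f"{tsv_path}: peptide {r.peptide!r} is not {WINDOW} residues")
        out.setdefault(r.kinase, []).append(r.peptide)
    return out


def write_kinase_sites(peptides: Mapping[str, Sequence[str]],
                       tsv_path: str | Path) -> None:
    rows = [{"kinase": k, "peptide": p}
            for k in peptides for p in peptides[k]]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_domains(tsv_path: str | Path) -> pd.DataFrame:
    """Read domain intervals: protein_id, domain_name, start, end, source."""
    tab = pd.read_csv(tsv_path, sep="\t", dtype={"protein_id": str,
                                                 "domain_name": str,
                                                 "source": str})
    tab["start"] = tab["start"].astype(int)
    tab["end"] = tab["end"].astype(int)
    if (tab["start"] > tab["end"]).any():
        raise FormatError(f"{tsv_path}: domain interval with start > end")
    return tab


def read_gmt(gmt_path: str | Path) -> dict[str, dict]:
    """Read gene sets from GMT: name, description/source, member genes."""
    sets: dict[str, dict] = {}
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description "
                    "and at least one gene")
            name, desc = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise FormatError(f"{gmt_path}:{lineno}: empty gene set")
            sets[name] = {"source": desc, "genes": genes}
    return sets


def write_gmt(sets: Mapping[str, dict], gmt_path: str | Path) -> None:
    with open(gmt_path, "w") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]["genes"]))
            fh.write(f"{name}\t{sets[name]['source']}\t{genes}\n")


def read_ppi(tsv_path: str | Path) -> list[frozenset[str]]:
    """Read undirected PPI edges, dropping self-edges and duplicates."""
    tab = pd.read_csv(tsv_path, sep="\t", dtype=str)
    edges: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for r in tab.itertuples(index=False):
        a, b = r.protein_a, r.protein_b
        if a == b:
            continue
        e = frozenset((a, b))
        if e not in seen:
            seen.add(e)
            edges.append(e)
    return edges


def write_ppi(edges: Iterable[frozenset[str]], tsv_path: str | Path) -> None:
    rows = [dict(zip(("protein_a", "protein_b"), sorted(e))) for e in edges]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PWM round-trip
# ---------------------------------------------------------------------------

def write_pwm(model, path: str | Path) -> None:
    """Serialize a kinase PWM to the versioned text format."""
    with open(path, "w") as fh:
        fh.write(f"# pwm_format_version: {PWM_FORMAT_VERSION}\n")
        fh.write(f"# kinase: {model.kinase}\n")
        fh.write(f"# n_initial: {model.n_initial}\n")
        fh.write(f"# n_retained: {model.n_retained}\n")
        auroc = "NA" if model.auroc is None else f"{model.auroc:.6f}"
        fh.write(f"# auroc: {auroc}\n")
        fh.write(f"# retained: {str(model.retained).lower()}\n")
        fh.write("aa\t" + "\t".join(f"pos{i + 1}" for i in range(WINDOW)) + "\n")
        for a, aa in enumerate(AMINO_ACIDS):
            row = "\t".join(f"{model.probs[a, i]:.12g}" for i in range(WINDOW))
            fh.write(f"{aa}\t{row}\n")


def read_pwm(path: str | Path):
    """Read a kinase PWM; columns must sum to 1 within 1e-6."""
    from .kinase_models import KinasePwm, information_weights

    header: dict[str, str] = {}
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition(":")
                header[key.strip()] = value.strip()
            elif line and not line.startswith("aa\t"):
                parts = line.split("\t")
                if len(parts) != WINDOW + 1:
                    raise FormatError(
                        f"{path}: expected {WINDOW} probabilities per row, "
                        f"got {len(parts) - 1}")
                rows[parts[0]] = [float(x) for x in parts[1:]]
    if set(rows) != set(AMINO_ACIDS):
        raise FormatError(f"{path}: expected one row per amino acid A..Y")
    probs = np.array([rows[aa] for aa in AMINO_ACIDS], dtype=float)
    sums = probs.sum(axis=0)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise FormatError(
            f"{path}: column {bad + 1} sums to {sums[bad]:.8f}, not 1")
    auroc = None if header.get("auroc", "NA") == "NA" else float(header["auroc"])
    return KinasePwm(
        kinase=header.get("kinase", Path(path).stem),
        probs=probs,
        info_weights=information_weights(probs),
        training_peptides=[],
        n_initial=int(header.get("n_initial", 0)),
        n_retained=int(header.get("n_retained", 0)),
        auroc=auroc,
        retained=header.get("retained", "false") == "true",
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_annotations(annotations: Iterable[PsnvAnnotation],
                      tsv_path: str | Path) -> None:
    pd.DataFrame(
        [{"protein_id": a.variant.protein_id, "position": a.variant.position,
          "ref_aa": a.variant.ref_aa, "alt_aa": a.variant.alt_aa,
          "sample_id": a.variant.sample_id,
          "cancer_type": a.variant.cancer_type,
          "site_position": a.site.position, "site_residue": a.site.residue,
          "distance": a.distance, "psnv_class": a.psnv_class,
          "disorder_context": int(a.disorder_context)} for a in annotations]
    ).to_csv(tsv_path, sep="\t", index=False)


def read_annotations(tsv_path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(tsv_path, sep="\t",
                      dtype={"protein_id": str, "sample_id": str,
                             "cancer_type": str})
    missing = {"protein_id", "position", "site_position",
               "psnv_class"} - set(tab.columns)
    if missing:
        raise FormatError(f"{tsv_path}: missing columns {sorted(missing)}")
    return tab


def write_regions(regions, tsv_path: str | Path) -> None:
    pd.DataFrame(
        [{"protein_id": r.protein_id, "start": r.start, "end": r.end,
          "n_sites": len(r.member_sites)} for r in regions]
    ).to_csv(tsv_path, sep="\t", index=False)


def write_events(events, tsv_path: str | Path) -> None:
    """Write rewiring events as a plain edge list for network tools."""
    rows = []
    for e in events:
        rows.append({
            "kinase": e.kinase, "protein_id": e.variant.protein_id,
            "site_position": e.site.position, "event": e.event,
            "p_ref": "" if e.p_ref is None else f"{e.p_ref:.6g}",
            "p_mut": "" if e.p_mut is None else f"{e.p_mut:.6g}",
            "mss_ref": "" if e.mss_ref is None else f"{e.mss_ref:.6g}",
            "mss_mut": "" if e.mss_mut is None else f"{e.mss_mut:.6g}",
            "kinase_known": int(e.kinase_known),
            "variant_position": e.variant.position,
            "ref_aa": e.variant.ref_aa, "alt_aa": e.variant.alt_aa,
            "sample_id": e.variant.sample_id,
            "cancer_type": e.variant.cancer_type,
        })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_events(tsv_path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(tsv_path, sep="\t",
                      dtype={"kinase": str, "protein_id": str,
                             "sample_id": str})
    missing = {"kinase", "protein_id", "site_position",
               "event"} - set(tab.columns)
    if missing:
        raise FormatError(f"{tsv_path}: missing columns {sorted(missing)}")
    return tab


def write_enrichment(results, tsv_path: str | Path) -> None:
    pd.DataFrame(
        [{"unit_id": r.unit_id, "observed": r.observed,
          "exposure": f"{r.exposure:.6g}", "expected": f"{r.expected:.6g}",
          "p_value": f"{r.p_value:.6g}",
          "fdr": "" if r.fdr is None else f"{r.fdr:.6g}",
          "direction": r.direction} for r in results]
    ).to_csv(tsv_path, sep="\t", index=False)
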