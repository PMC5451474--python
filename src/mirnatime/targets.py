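"""Seed-based miRNA target prediction on 3'-UTR sequences.

The seed is nucleotides 2-8 (1-based, from the 5' end) of the mature miRNA.
A target site is an exact, Watson-Crick, 7-nt match of the seed's reverse
complement on the UTR sense strand (a 7mer-m8-like site; no wobble pairing,
no conservation or context scoring).  miRNA sequences may arrive in the RNA
alphabet and UTRs in DNA; scanning normalizes case and U/T.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = ["MatureMiRNA", "SeedMatch", "extract_seed", "seed_site_motif",
           "scan_utr", "predict_targets", "read_fasta"]

_DNA_OK = set("ACGTN")


@dataclass(frozen=True)
class MatureMiRNA:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = _to_rna(self.sequence)
        if set(seq) - set("ACGU"):
            raise ValueError(f"miRNA {self.id}: alphabet outside ACGU after normalization")
        if len(seq) < 8:
            raise ValueError(f"miRNA {self.id}: sequence shorter than 8 nt")


@dataclass(frozen=True)
class SeedMatch:
    """One predicted site; coordinates are 1-based inclusive on the UTR."""

    mirna_id: str
    gene_id: str
    start: int
    end: int
    motif: str
    site_class: str = "7mer-m8"


def _to_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def _to_dna(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


def extract_seed(mirna: MatureMiRNA | str) -> str:
    """Positions 2-8 (1-based) of the mature sequence, in the RNA alphabet."""
    seq = _to_rna(mirna.sequence if isinstance(mirna, MatureMiRNA) else mirna)
    if len(seq) < 8:
        raise ValueError("mature sequence must be at least 8 nt to carry a 2-8 seed")
    return seq[1:8]


def seed_site_motif(seed: str) -> str:
    """DNA reverse complement of a 7-nt seed: the motif searched in UTRs."""
    return str(Seq(_to_dna(seed)).reverse_complement())


def scan_utr(seed: str, utr: str, mirna_id: str = "", gene_id: str = "") -> list[SeedMatch]:
    """All (possibly overlapping) seed-complement sites on the UTR sense strand.

    N is accepted in UTRs but never matches, so sites overlapping N are
    skipped; any other non-ACGTN character is rejected.
    """
    utr_dna = _to_dna(utr)
    bad = set(utr_dna) - _DNA_OK
    if bad:
        raise ValueError(f"UTR contains non-ACGTN characters: {sorted(bad)}")
    if len(utr_dna) < 7:
        raise ValueError("UTR shorter than 7 nt cannot carry a seed site")
    motif = seed_site_motif(seed)
    sites = []
    pos = utr_dna.find(motif)
    while pos != -1:
        sites.append(SeedMatch(mirna_id=mirna_id, gene_id=gene_id,
                               start=pos + 1, end=pos + 7, motif=motif))
        pos = utr_dna.find(motif, pos + 1)
    return sites


def predict_targets(
    mirnas: dict[str, str],
    utrs: dict[str, str],
    restrict_to: set[str] | None = None,
) -> pd.DataFrame:
    """Unique (miRNA, gene) pairs with site counts and positions.

    ``mirnas`` maps id -> mature sequence; ``utrs`` maps gene id -> UTR
    sequence.  ``restrict_to`` optionally limits the gene universe (e.g. to
    the expressed-gene set).  Genes with zero sites for a miRNA are not
    listed.
    """
    if not mirnas or not utrs:
        raise ValueError("mirnas and utrs must be non-empty")
    genes = {g: s for g, s in utrs.items() if restrict_to is None or g in restrict_to}
    rows = []
    for mid in sorted(mirnas):
        seed = extract_seed(mirnas[mid])
        for gene in sorted(genes):
            sites = scan_utr(seed, genes[gene], mirna_id=mid, gene_id=gene)
            if sites:
                rows.append({
                    "mirna_id": mid,
                    "gene_id": gene,
                    "n_sites": len(sites),
                    "positions": ",".join(f"{s.start}-{s.end}" for s in sites),
                })
    return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "n_sites", "positions"])


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence dict, rejecting duplicate ids."""
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValueError(f"duplicate FASTA id {record.id!r} in {path}")
        out[record.id] = str(record.seq)
    return out
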