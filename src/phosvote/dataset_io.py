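"""Building candidate-site datasets from protein sequences and annotations.

A site universe is constructed from (a) protein sequences (FASTA) and (b) a
site-annotation table (protein id, 1-based position, residue S/T/Y, label).
Experimentally verified phospho-sites are the positive class; every other
S/T/Y residue in the annotated proteins is a candidate negative. Each site
carries its 25-mer sequence window (12 residues either side of the site,
'X'-padded at protein termini), and classes are balanced by seeded random
undersampling of the majority class before cross-validation.

Positions are 1-based in all external files (Swiss-Prot feature-table
convention); in-memory indexing is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ProteinRecord",
    "SiteRecord",
    "AMINO_ACIDS",
    "PHOSPHO_RESIDUES",
    "read_fasta",
    "write_fasta",
    "extract_window",
    "derive_negative_sites",
    "build_site_records",
    "balance_dataset",
    "read_site_table",
    "write_site_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS + "X")
PHOSPHO_RESIDUES = ("S", "T", "Y")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession id plus its amino-acid sequence (uppercase)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty protein id")
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"illegal residue(s) {sorted(bad)} in protein {self.id!r}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteRecord:
    """One candidate site: protein, 1-based position, residue, label, window."""

    protein_id: str
    position: int  # 1-based
    residue: str
    label: int  # 1 positive, 0 negative
    window: str

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.position < 1:
            raise ValueError("positions are 1-based")
        mid = (len(self.window) - 1) // 2
        if self.window[mid] != self.residue:
            raise ValueError(
                f"window centre {self.window[mid]!r} does not match residue "
                f"{self.residue!r} at {self.protein_id}:{self.position}"
            )

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}:{self.position}"


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a FASTA file into validated, order-preserving protein records."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path, proteins: Sequence[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i:i + width] + "\n")


def extract_window(sequence: str, position: int, halfwidth: int = 12) -> str:
    """Sequence context around a 1-based position, padded with 'X' at termini.

    The returned string has length 2*halfwidth + 1 with the site residue at
    the centre (index ``halfwidth``).
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(
            f"position {position} out of range 1..{len(sequence)}"
        )
    i = position - 1
    left = sequence[max(0, i - halfwidth):i]
    right = sequence[i + 1:i + 1 + halfwidth]
    return ("X" * (halfwidth - len(left)) + left + sequence[i]
            + right + "X" * (halfwidth - len(right)))


def derive_negative_sites(proteins: Sequence[ProteinRecord],
                          positive_sites: Sequence[tuple[str, int]],
                          halfwidth: int = 12) -> list[SiteRecord]:
    """All S/T/Y residues not annotated positive become negative sites.

    ``positive_sites`` is a collection of (protein_id, 1-based position)
    pairs; a positive at a non-S/T/Y residue indicates an inconsistent
    annotation and raises.
    """
    by_id = {p.id: p for p in proteins}
    pos_keys = set()
    for pid, pos in positive_sites:
        prot = by_id.get(pid)
        if prot is None:
            raise KeyError(f"positive site references unknown protein {pid!r}")
        if not 1 <= pos <= len(prot):
            raise ValueError(f"positive site {pid}:{pos} out of range")
        if prot.sequence[pos - 1] not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"annotated phospho-site {pid}:{pos} is "
                f"{prot.sequence[pos - 1]!r}, not S/T/Y"
            )
        pos_keys.add((pid, pos))
    negatives = []
    for p in proteins:
        for i, aa in enumerate(p.sequence, start=1):
            if aa in PHOSPHO_RESIDUES and (p.id, i) not in pos_keys:
                negatives.append(SiteRecord(
                    protein_id=p.id, position=i, residue=aa, label=0,
                    window=extract_window(p.sequence, i, halfwidth),
                ))
    return negatives


def build_site_records(proteins: Sequence[ProteinRecord],
                       annotations: pd.DataFrame,
                       halfwidth: int = 12) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Positive records from an annotation table plus derived negatives.

    ``annotations`` needs columns protein_id, position (1-based), residue;
    rows may carry a ``label`` column (default all positive).
    """
    by_id = {p.id: p for p in proteins}
    positives = []
    pos_pairs = []
    for row in annotations.itertuples(index=False):
        if getattr(row, "label", 1) != 1:
            continue
        prot = by_id[row.protein_id]
        expected = prot.sequence[row.position - 1]
        if expected != row.residue:
            raise ValueError(
                f"annotation says {row.residue} at {row.protein_id}:{row.position}, "
                f"sequence has {expected}"
            )
        positives.append(SiteRecord(
            protein_id=row.protein_id, position=int(row.position),
            residue=row.residue, label=1,
            window=extract_window(prot.sequence, int(row.position), halfwidth),
        ))
        pos_pairs.append((row.protein_id, int(row.position)))
    negatives = derive_negative_sites(proteins, pos_pairs, halfwidth)
    return positives, negatives


def balance_dataset(positives: Sequence[SiteRecord],
                    negatives: Sequence[SiteRecord],
                    rng_seed: int = 0,
                    ) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Equalize class sizes by uniform undersampling without replacement.

    The majority class is downsampled to the minority size (usually the
    negatives, since S/T/Y residues vastly outnumber phospho-sites); both
    returned lists have equal length and preserve input order.
    """
    if not positives or not negatives:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(rng_seed)
    n = min(len(positives), len(negatives))

    def sample(records, k):
        if len(records) == k:
            return list(records)
        idx = np.sort(rng.choice(len(records), size=k, replace=False))
        return [records[i] for i in idx]

    return sample(positives, n), sample(negatives, n)


_SITE_COLUMNS = ["protein_id", "position", "residue", "label", "window"]


def write_site_table(path, sites: Sequence[SiteRecord]) -> None:
    pd.DataFrame(
        [(s.protein_id, s.position, s.residue, s.label, s.window) for s in sites],
        columns=_SITE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_site_table(path) -> list[SiteRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in _SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing column(s) {missing}")
    return [
        SiteRecord(protein_id=r.protein_id, position=int(r.position),
                   residue=r.residue, label=int(r.label), window=r.window)
        for r in df.itertuples(index=False)
    ]
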