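"""Proteome-wide enumeration and scoring of candidate phospho-acceptor sites.

Every serine or threonine in every protein defines one candidate window
(padded at the termini); windows are scored against a
:class:`~ypkscreen.motif.MotifMatrix` and filtered by constraint mode and a
likelihood threshold.  Coordinates are 1-based on the protein, matching the
site numbering conventions of the field (e.g. Fps1 T147, S181, S185).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import (
    ACCEPTORS,
    AMINO_ACIDS,
    PAD,
    UNKNOWN,
    MotifError,
    MotifMatrix,
    MotifWindow,
    check_constraints,
    score_window,
)
from .motif import SiteScore

_ALLOWED = set(AMINO_ACIDS) | {UNKNOWN}


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id}")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(f"{self.id}: symbols outside alphabet: {sorted(bad)}")


@dataclass(frozen=True)
class SiteHit:
    """A scored candidate acceptor site: 1-based position of the S/T."""

    protein_id: str
    position: int
    window: MotifWindow
    score: SiteScore


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Load a protein FASTA, order-preserving.

    Sequences are uppercased and a trailing ``*`` terminator is stripped;
    duplicate identifiers are rejected.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        records.append(ProteinRecord(rec.id, rec.description, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def extract_window(sequence: str, position: int, offsets: Sequence[int]) -> MotifWindow:
    """Window around a 1-based position, padded beyond the sequence ends."""
    residues = []
    for o in offsets:
        i = position - 1 + o
        residues.append(sequence[i] if 0 <= i < len(sequence) else PAD)
    return MotifWindow(tuple(residues), tuple(offsets))


def enumerate_candidate_windows(
    protein: ProteinRecord, offsets: Sequence[int]
) -> list[tuple[int, MotifWindow]]:
    """One (position, window) pair per S or T residue, in sequence order."""
    if 0 not in offsets:
        raise ValueError("offsets must include the acceptor offset 0")
    return [
        (pos, extract_window(protein.sequence, pos, offsets))
        for pos, res in enumerate(protein.sequence, start=1)
        if res in ACCEPTORS
    ]


def scan_proteome(
    proteins: Iterable[ProteinRecord],
    matrix: MotifMatrix,
    mode: str = "core",
    min_likelihood: float = 0.0,
) -> list[SiteHit]:
    """Score all candidate windows and keep accepted hits.

    A hit must satisfy the constraint mode (``core``: invariant Arg -5/-3
    and S/T acceptor; ``strict``: additionally hydrophobic +1) and reach
    ``min_likelihood``.  Output is sorted by (protein_id, position).
    """
    if mode not in ("core", "strict"):
        raise MotifError(f"invalid mode {mode!r}")
    if not 0.0 <= min_likelihood <= 1.0:
        raise ValueError("min_likelihood must be in [0, 1]")
    hits: list[SiteHit] = []
    for protein in proteins:
        for pos, window in enumerate_candidate_windows(protein, matrix.offsets):
            _, _, accepted = check_constraints(
                window, mode, matrix.constrained_offsets, matrix.preference_offsets
            )
            if not accepted:
                continue
            score = score_window(matrix, window)
            if score.likelihood >= min_likelihood:
                hits.append(SiteHit(protein.id, pos, window, score))
    hits.sort(key=lambda h: (h.protein_id, h.position))
    return hits


def hits_to_frame(hits: Iterable[SiteHit]) -> pd.DataFrame:
    """Tabulate hits with one row per site."""
    rows = [
        {
            "protein_id": h.protein_id,
            "position": h.position,
            "window": str(h.window),
            "raw_logodds": h.score.raw_logodds,
            "likelihood": h.score.likelihood,
            "core_ok": h.score.core_ok,
            "plus1_hydrophobic": h.score.plus1_hydrophobic,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "position",
            "window",
            "raw_logodds",
            "likelihood",
            "core_ok",
            "plus1_hydrophobic",
        ],
    )


def write_hits(hits: Iterable[SiteHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)
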