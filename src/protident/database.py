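"""Protein sequence databases: FASTA IO, curation and background frequencies.

The target database for identification is a set of canonical protein
sequences (for the human proteome, ~20 000 reviewed canonical entries).
Curation removes extreme-length outliers (e.g. titin) by discarding records
whose length lies strictly above a chosen percentile of the length
distribution. Background amino-acid frequencies computed from the curated
records define the null model used by the scoring engine.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AMINO_ACIDS, RESIDUE_MAP, encode

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein: accession plus a canonical amino-acid sequence."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if any(c not in AA_INDEX for c in self.sequence):
            bad = sorted({c for c in self.sequence if c not in AA_INDEX})
            raise ValueError(f"{self.accession}: non-canonical residue(s) {bad!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceDatabase:
    """An ordered collection of :class:`ProteinRecord` with a background model.

    Attributes
    ----------
    records:
        Records in input (file) order. Accessions are unique.
    background:
        Length-20 vector of amino-acid frequencies over all residues in
        ``records`` (order ``ACDEFGHIKLMNPQRSTVWY``), summing to 1.
    length_percentile_cut:
        The length threshold applied during curation, or None for an
        uncurated database.
    meta:
        Free-form provenance (e.g. counts of records dropped at parse time).
    """

    records: list[ProteinRecord]
    background: np.ndarray
    length_percentile_cut: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.records]
        if len(set(accs)) != len(accs):
            seen, dup = set(), set()
            for a in accs:
                (dup if a in seen else seen).add(a)
            raise ValueError(f"duplicate accessions: {sorted(dup)[:5]}")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (N_AMINO_ACIDS,):
            raise ValueError("background must be a length-20 vector")
        if (self.background < 0).any() or abs(self.background.sum() - 1.0) > 1e-12:
            raise ValueError("background must be non-negative and sum to 1")

    @classmethod
    def from_records(
        cls,
        records: Iterable[ProteinRecord],
        length_percentile_cut: float | None = None,
        meta: dict | None = None,
    ) -> "SequenceDatabase":
        records = list(records)
        if not records:
            raise ValueError("database contains no valid records")
        return cls(
            records=records,
            background=_background_of(records),
            length_percentile_cut=length_percentile_cut,
            meta=meta or {},
        )

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, accession: str) -> ProteinRecord:
        for r in self.records:
            if r.accession == accession:
                return r
        raise KeyError(accession)

    def encoded(self) -> list[np.ndarray]:
        """Integer-encoded sequences, cached on first use."""
        cached = self.__dict__.get("_encoded")
        if cached is None:
            cached = [encode(r.sequence) for r in self.records]
            self.__dict__["_encoded"] = cached
        return cached


def _background_of(records: list[ProteinRecord]) -> np.ndarray:
    counts = np.zeros(N_AMINO_ACIDS, dtype=np.int64)
    for r in records:
        counts += np.bincount(encode(r.sequence), minlength=N_AMINO_ACIDS)
    return counts / counts.sum()


def _clean_sequence(seq: str) -> str | None:
    """Apply the residue-mapping policy; None if the record must be dropped.

    U→C and O→K are mapped; any remaining non-canonical letter (B, Z, J, X,
    '*', ...) disqualifies the record.
    """
    seq = seq.upper().strip("*")
    for src, dst in RESIDUE_MAP.items():
        if src in seq:
            seq = seq.replace(src, dst)
    if not seq or any(c not in AA_INDEX for c in seq):
        return None
    return seq


def read_fasta(path: str | Path) -> SequenceDatabase:
    """Read a FASTA file (plain or gzip) into an uncurated database.

    Sequences are upper-cased; U/O are mapped to C/K; records still
    containing other non-canonical letters are dropped (counts recorded in
    ``meta['n_dropped']`` and logged).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[ProteinRecord] = []
    dropped: list[str] = []
    with opener(path, "rt") as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            seq = _clean_sequence(str(entry.seq))
            if seq is None:
                dropped.append(entry.id)
                continue
            records.append(ProteinRecord(accession=entry.id, sequence=seq))
    if dropped:
        logger.warning(
            "dropped %d record(s) with unmappable residues: %s%s",
            len(dropped),
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    if not records:
        raise ValueError(f"{path}: no valid FASTA records")
    return SequenceDatabase.from_records(
        records, meta={"n_dropped": len(dropped), "dropped": dropped}
    )


def write_fasta(db: SequenceDatabase, path: str | Path, width: int = 60) -> None:
    """Write the database as plain FASTA (gzip if the path ends in .gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in db.records:
            fh.write(f">{r.accession}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def curate(db: SequenceDatabase, percentile: float = 0.99) -> SequenceDatabase:
    """Drop records whose length is strictly above the given length percentile.

    The percentile is computed with linear interpolation between order
    statistics. The background is recomputed from the retained records and
    the cut is recorded on the returned database.

    Curation is defined against the database's original length
    distribution: a database that already records a length cut is returned
    unchanged (recomputing the percentile on the truncated distribution
    would keep shaving the tail on every pass), which makes the operation
    idempotent.
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError(f"percentile must be in (0, 1], got {percentile}")
    if db.n == 0:
        raise ValueError("cannot curate an empty database")
    if db.length_percentile_cut is not None:
        return SequenceDatabase.from_records(
            db.records, length_percentile_cut=db.length_percentile_cut,
            meta=dict(db.meta),
        )
    lengths = np.array([len(r) for r in db.records], dtype=float)
    cut = float(np.percentile(lengths, percentile * 100, method="linear"))
    kept = [r for r in db.records if len(r) <= cut]
    return SequenceDatabase.from_records(
        kept, length_percentile_cut=cut, meta=dict(db.meta)
    )


def curation_report(uncurated: SequenceDatabase, curated: SequenceDatabase):
    """Per-record keep/drop table for a curation run (pandas DataFrame)."""
    import pandas as pd

    kept_accs = {r.accession for r in curated.records}
    cut = curated.length_percentile_cut
    rows = [
        {
            "accession": r.accession,
            "length": len(r),
            "kept": r.accession in kept_accs,
            "reason": "" if r.accession in kept_accs else f"length > {cut:g}",
        }
        for r in uncurated.records
    ]
    return pd.DataFrame(rows)


def compute_background(db: SequenceDatabase) -> np.ndarray:
    """Amino-acid frequencies over all residues of the database (sums to 1)."""
    if db.n == 0:
        raise ValueError("empty database has no background")
    return _background_of(db.records)


def abundance_ranking(background: np.ndarray) -> list[str]:
    """Amino acids ordered most→least frequent; ties broken alphabetically."""
    background = np.asarray(background, dtype=float)
    if background.shape != (N_AMINO_ACIDS,):
        raise ValueError("background must be a length-20 vector")
    order = sorted(range(N_AMINO_ACIDS), key=lambda i: (-background[i], AMINO_ACIDS[i]))
    return [AMINO_ACIDS[i] for i in order]
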