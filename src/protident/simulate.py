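"""Hypothetical single-molecule sequencer: posterior-probability readouts.

The device reads a protein (or a fragment of one) residue by residue and
emits, for each position, a posterior probability vector over the 20 amino
acids. Signal quality is a single knob ``p_max``: the posterior assigned to
the correct residue, with the remaining mass spread equally over the other
19. ``p_max = 1`` is a perfect reader; ``p_max = 0.05`` makes all residues
indistinguishable (uniform posteriors). A device may discriminate only a
subset of amino acids (e.g. fluorescently labelled ones); residues outside
the detection set yield uniform posteriors.

Sequencing errors are modelled as column indels on the readout: deletions
(missed detections / fast translocation) remove posterior columns, and
insertions (spurious detections / slow translocation) add columns drawn
from a random amino acid's posterior. Counts are exact — rate × length,
rounded half away from zero — with deletions applied before insertions so
that inserted columns are never subsequently deleted.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AMINO_ACIDS, encode
from .database import ProteinRecord

FULL_DETECTION_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class DeviceConfig:
    """Operating condition of the sequencer.

    Parameters
    ----------
    p_max:
        Posterior probability assigned to the correct amino acid, in
        [0.05, 1]. 0.05 (= 1/20) is the indistinguishable limit.
    detection_set:
        Amino acids the device can discriminate. Residues outside this set
        produce uniform (1/20) posterior columns.
    """

    p_max: float
    detection_set: frozenset = FULL_DETECTION_SET

    def __post_init__(self) -> None:
        if not 0.05 <= self.p_max <= 1.0:
            raise ValueError(f"p_max must be in [0.05, 1], got {self.p_max}")
        det = frozenset(self.detection_set)
        if not det or not det <= set(AMINO_ACIDS):
            raise ValueError("detection_set must be a non-empty subset of the 20 AAs")
        object.__setattr__(self, "detection_set", det)


@dataclass(frozen=True)
class ErrorModel:
    """Exact-count indel error process.

    Rates are fractions of the pre-error readout length, not per-position
    Bernoulli probabilities: a deletion rate of 0.1 on a length-100 readout
    removes exactly 10 columns.
    """

    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.insertion_rate < 0:
            raise ValueError("insertion_rate must be >= 0")
        if not 0.0 <= self.deletion_rate < 1.0:
            raise ValueError("deletion_rate must be in [0, 1)")


@dataclass(frozen=True)
class FragmentPlan:
    """How fragments are drawn from a protein: fixed length, n independent draws."""

    length: int
    n_fragments: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("fragment length must be >= 1")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")


@dataclass
class Readout:
    """A decoded readout: 20×L' posterior matrix plus provenance.

    Rows follow the fixed alphabet order ``ACDEFGHIKLMNPQRSTVWY``; columns
    are readout positions. Every column sums to 1. After indel errors,
    L' = original length − n_deletions + n_insertions.
    """

    matrix: np.ndarray
    source_accession: str = ""
    fragment_start: int | None = None
    fragment_end: int | None = None
    n_insertions: int = 0
    n_deletions: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != N_AMINO_ACIDS:
            raise ValueError("readout matrix must be 20 x L")
        if self.matrix.shape[1] < 1:
            raise ValueError("readout must have at least one column")
        if (self.matrix < 0).any():
            raise ValueError("posterior probabilities must be non-negative")
        colsums = self.matrix.sum(axis=0)
        if np.abs(colsums - 1.0).max() > 1e-12:
            raise ValueError("every readout column must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def readout_id(self) -> str:
        if self.fragment_start is None:
            return self.source_accession or "readout"
        return f"{self.source_accession}:{self.fragment_start}-{self.fragment_end}"


def posterior_column(aa: str, device: DeviceConfig) -> np.ndarray:
    """Posterior vector the device emits when reading amino acid ``aa``.

    Detected residue: ``p_max`` on the true amino acid, (1−p_max)/19 on each
    of the other 19. Undetected residue: uniform 1/20.
    """
    if aa not in AA_INDEX:
        raise ValueError(f"non-canonical amino acid {aa!r}")
    if aa not in device.detection_set or device.p_max == 0.05:
        # p_max = 1/20 is the indistinguishable limit: (1-p_max)/19 equals
        # 1/20 exactly, so return the uniform column without rounding error
        return np.full(N_AMINO_ACIDS, 1.0 / N_AMINO_ACIDS)
    col = np.full(N_AMINO_ACIDS, (1.0 - device.p_max) / 19.0)
    col[AA_INDEX[aa]] = device.p_max
    return col


def _posterior_matrix(sequence: str, device: DeviceConfig) -> np.ndarray:
    codes = encode(sequence)
    base = np.full((N_AMINO_ACIDS, len(codes)), 1.0 / N_AMINO_ACIDS)
    if device.p_max == 0.05:
        return base  # indistinguishable limit: exactly uniform everywhere
    detected = np.array([aa in device.detection_set for aa in AMINO_ACIDS])
    det_mask = detected[codes]
    if det_mask.any():
        cols = np.where(det_mask)[0]
        base[:, cols] = (1.0 - device.p_max) / 19.0
        base[codes[cols], cols] = device.p_max
    return base


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def apply_errors(
    matrix: np.ndarray,
    errors: ErrorModel,
    device: DeviceConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int, int]:
    """Apply exact-count column indels to a posterior matrix.

    Deletions first: ``round(deletion_rate × L)`` distinct columns, chosen
    uniformly, are removed. Then insertions: ``round(insertion_rate × L)``
    columns (L is still the pre-error length) are placed at gap positions of
    the post-deletion matrix, chosen uniformly with replacement; each
    inserted column is the posterior of an amino acid drawn uniformly from
    the 20 under the same device configuration.

    Returns ``(matrix', n_deletions, n_insertions)``.
    """
    matrix = np.asarray(matrix, dtype=float)
    L = matrix.shape[1]
    n_del = _round_half_away(errors.deletion_rate * L)
    n_ins = _round_half_away(errors.insertion_rate * L)
    if n_del >= L:
        raise ValueError(f"cannot delete {n_del} of {L} columns")
    if rng is None:
        rng = np.random.default_rng(errors.seed)
    if n_del:
        drop = rng.choice(L, size=n_del, replace=False)
        keep = np.setdiff1d(np.arange(L), drop)
        matrix = matrix[:, keep]
    if n_ins:
        n_gaps = matrix.shape[1] + 1
        gaps = np.sort(rng.integers(0, n_gaps, size=n_ins))
        inserted_aas = rng.integers(0, N_AMINO_ACIDS, size=n_ins)
        cols = [posterior_column(AMINO_ACIDS[a], device) for a in inserted_aas]
        pieces, prev = [], 0
        for g, c in zip(gaps, cols):
            pieces.append(matrix[:, prev:g])
            pieces.append(c[:, None])
            prev = g
        pieces.append(matrix[:, prev:])
        matrix = np.concatenate(pieces, axis=1)
    return matrix, n_del, n_ins


def simulate_readout(
    sequence: str,
    device: DeviceConfig,
    errors: ErrorModel | None = None,
    *,
    accession: str = "",
    fragment: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> Readout:
    """Sequence a protein (or fragment) into a posterior readout.

    The error-free readout has one posterior column per residue; if an
    :class:`ErrorModel` is supplied, column indels are applied on top.
    """
    if not sequence:
        raise ValueError("cannot sequence an empty sequence")
    matrix = _posterior_matrix(sequence, device)
    n_del = n_ins = 0
    if errors is not None:
        matrix, n_del, n_ins = apply_errors(matrix, errors, device, rng=rng)
    start, end = fragment if fragment is not None else (None, None)
    return Readout(
        matrix=matrix,
        source_accession=accession,
        fragment_start=start,
        fragment_end=end,
        n_insertions=n_ins,
        n_deletions=n_del,
    )


def sample_fragments(
    record: ProteinRecord,
    plan: FragmentPlan,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Draw ``n_fragments`` random same-length windows from a protein.

    Starts are uniform over the valid range; draws are independent, so
    duplicate windows are possible. A protein shorter than the fragment
    length contributes its full sequence for every draw.
    """
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    L = len(record)
    if L <= plan.length:
        return [(0, L)] * plan.n_fragments
    starts = rng.integers(0, L - plan.length + 1, size=plan.n_fragments)
    return [(int(s), int(s) + plan.length) for s in starts]


def protein_rng(seed: int | None, accession: str) -> np.random.Generator:
    """Deterministic per-protein RNG substream.

    Derived from ``(seed, crc32(accession))`` so that per-protein simulation
    is independent of iteration order and safe to parallelize.
    """
    key = zlib.crc32(accession.encode())
    return np.random.default_rng(np.random.SeedSequence([0 if seed is None else seed, key]))


# ---------------------------------------------------------------------------
# Readout TSV format: '#'-prefixed metadata lines, a header of the 20 AA
# letters, then one row per readout position.

_META_FIELDS = (
    "source_accession",
    "fragment_start",
    "fragment_end",
    "n_insertions",
    "n_deletions",
)


def write_readout_tsv(readout: Readout, path: str | Path, extra_meta: dict | None = None) -> None:
    """Write a readout as TSV (positions as rows, amino acids as columns)."""
    with open(path, "w") as fh:
        meta = {f: getattr(readout, f) for f in _META_FIELDS}
        if extra_meta:
            meta.update(extra_meta)
        for k, v in meta.items():
            fh.write(f"# {k}={'' if v is None else v}\n")
        fh.write("\t".join(AMINO_ACIDS) + "\n")
        for col in readout.matrix.T:
            fh.write("\t".join(f"{p:.17g}" for p in col) + "\n")


def read_readout_tsv(path: str | Path) -> Readout:
    """Read a readout written by :func:`write_readout_tsv`."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                k, _, v = line.lstrip("# ").partition("=")
                meta[k.strip()] = v.strip()
            elif header is None:
                header = line.split("\t")
                if header != list(AMINO_ACIDS):
                    raise ValueError(f"{path}: header must list the 20 AAs in order")
            else:
                rows.append([float(x) for x in line.split("\t")])
    if header is None or not rows:
        raise ValueError(f"{path}: no readout data")

    def _int_or_none(key: str) -> int | None:
        v = meta.get(key, "")
        return int(v) if v not in ("", "None") else None

    return Readout(
        matrix=np.array(rows).T,
        source_accession=meta.get("source_accession", ""),
        fragment_start=_int_or_none("fragment_start"),
        fragment_end=_int_or_none("fragment_end"),
        n_insertions=int(meta.get("n_insertions", 0) or 0),
        n_deletions=int(meta.get("n_deletions", 0) or 0),
    )
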