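"""Synthetic protein databases and canned worked-example readouts.

Real proteome databases are external downloads; everything in this package
is testable against databases of i.i.d. random sequences drawn from a
configurable residue background. The ``human-like`` preset is a fixed
20-vector approximating the composition of the human proteome, so that
reduced-alphabet experiments behave qualitatively like the real database:
L, S, E, A and G are the five most abundant residues and W, M, C, H and Y
the five least. Synthetic databases do not reproduce homology structure
(paralog families, repeats, shared domains) — identification on them is, if
anything, easier than on a real proteome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO_ACIDS, N_AMINO_ACIDS
from .database import ProteinRecord, SequenceDatabase
from .simulate import DeviceConfig, Readout, posterior_column

# Approximate human proteome amino-acid composition (percent, alphabet order
# ACDEFGHIKLMNPQRSTVWY). Fixed and version-controlled so experiments do not
# depend on an external download.
_HUMAN_LIKE_PERCENT = np.array(
    [7.0, 2.3, 4.7, 7.1, 3.7, 6.6, 2.6, 4.3, 5.7, 10.0,
     2.1, 3.6, 6.3, 4.8, 5.6, 8.3, 5.4, 6.0, 1.2, 2.7]
)
HUMAN_LIKE_BACKGROUND: np.ndarray = _HUMAN_LIKE_PERCENT / _HUMAN_LIKE_PERCENT.sum()

UNIFORM_BACKGROUND: np.ndarray = np.full(N_AMINO_ACIDS, 1.0 / N_AMINO_ACIDS)

BACKGROUND_PRESETS = {
    "uniform": UNIFORM_BACKGROUND,
    "human-like": HUMAN_LIKE_BACKGROUND,
}

# length distributions: ("fixed", L) | ("uniform", lo, hi) | ("lognormal", median, sigma)
DEFAULT_LENGTH_DISTRIBUTION = ("lognormal", 411, 0.55)


@dataclass(frozen=True)
class SynthDbSpec:
    """Specification of an i.i.d. synthetic protein database.

    ``length_distribution`` is ``("fixed", L)``, ``("uniform", lo, hi)``
    (inclusive bounds) or ``("lognormal", median, sigma)``; the lognormal
    default has median 411 residues, matching a curated proteome's median.
    ``background`` is a 20-vector, or a preset name (``"uniform"``,
    ``"human-like"``).
    """

    n: int
    length_distribution: tuple = DEFAULT_LENGTH_DISTRIBUTION
    background: object = "human-like"
    seed: int = 0
    enforce_distinct: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        kind = self.length_distribution[0]
        if kind not in ("fixed", "uniform", "lognormal"):
            raise ValueError(f"unknown length distribution {kind!r}")

    def background_vector(self) -> np.ndarray:
        if isinstance(self.background, str):
            try:
                return BACKGROUND_PRESETS[self.background]
            except KeyError:
                raise ValueError(f"unknown background preset {self.background!r}")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (N_AMINO_ACIDS,) or (bg < 0).any() or abs(bg.sum() - 1) > 1e-9:
            raise ValueError("background must be a valid 20-vector of frequencies")
        return bg

    def min_length(self) -> int | None:
        """Hard lower bound on sequence length, or None if unbounded."""
        kind = self.length_distribution
        if kind[0] == "fixed":
            return int(kind[1])
        if kind[0] == "uniform":
            return int(kind[1])
        return None  # lognormal: no hard bound; rely on redraw failure


def _sample_lengths(spec: SynthDbSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    kind, *args = spec.length_distribution
    if kind == "fixed":
        return np.full(size, int(args[0]))
    if kind == "uniform":
        lo, hi = int(args[0]), int(args[1])
        return rng.integers(lo, hi + 1, size=size)
    median, sigma = args
    lengths = np.rint(np.exp(rng.normal(np.log(median), sigma, size=size))).astype(int)
    return np.maximum(lengths, 1)


def generate_database(spec: SynthDbSpec) -> SequenceDatabase:
    """Generate ``n`` i.i.d. sequences with accessions SYN000001, SYN000002, …

    Residues are drawn from the requested background and lengths from the
    length distribution. With ``enforce_distinct``, duplicated sequences are
    redrawn until all are unique (which fails fast when the sequence space
    is too small to hold ``n`` distinct sequences).
    """
    min_len = spec.min_length()
    if spec.enforce_distinct and min_len is not None and N_AMINO_ACIDS ** min(min_len, 64) < spec.n:
        raise ValueError(
            f"cannot draw {spec.n} distinct sequences of minimum length {min_len}"
        )
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_vector()
    lengths = _sample_lengths(spec, rng, spec.n)
    seen: set[str] = set()
    records: list[ProteinRecord] = []
    for i, L in enumerate(lengths):
        attempts = 0
        while True:
            seq = "".join(
                AMINO_ACIDS[c] for c in rng.choice(N_AMINO_ACIDS, size=int(L), p=bg)
            )
            if not spec.enforce_distinct or seq not in seen:
                break
            attempts += 1
            if attempts > 1000:
                raise ValueError("could not draw distinct sequences; space too small")
        seen.add(seq)
        records.append(ProteinRecord(accession=f"SYN{i + 1:06d}", sequence=seq))
    return SequenceDatabase.from_records(records, meta={"synthetic": True, "seed": spec.seed})


def fixture_readouts() -> dict:
    """Small worked-example readouts with known truth, for demos and tests.

    ``clean``: the peptide QFEGSAL read with p_max = 1/2 and all 20 amino
    acids detectable (a 20×7 matrix). ``labelled_indel``: the same peptide
    read at p_max = 9/10 with detection set {L, S, E}; the column for F is
    deleted and a spurious column suggesting L is inserted after E, so the
    matrix is again 20×7 (7 − 1 deletion + 1 insertion). Each fixture comes
    with a tiny synthetic database that contains the source peptide.
    """
    peptide = "QFEGSAL"
    truth = "SYNQFE01"
    decoys = ["GAVLIMSW", "TSYNQHKE", "PRDCWFYA", "MKELVING"]
    records = [ProteinRecord(truth, peptide)] + [
        ProteinRecord(f"SYNDEC{i:02d}", s) for i, s in enumerate(decoys, 1)
    ]
    db = SequenceDatabase.from_records(records, meta={"synthetic": True})

    device_a = DeviceConfig(p_max=0.5)
    clean = Readout(
        matrix=np.column_stack([posterior_column(aa, device_a) for aa in peptide]),
        source_accession=truth,
    )

    device_b = DeviceConfig(p_max=0.9, detection_set=frozenset("LSE"))
    observed = ["Q", "E", "L", "G", "S", "A", "L"]  # F deleted, L inserted after E
    labelled = Readout(
        matrix=np.column_stack([posterior_column(aa, device_b) for aa in observed]),
        source_accession=truth,
        n_deletions=1,
        n_insertions=1,
    )
    return {
        "clean": {"readout": clean, "database": db, "truth": truth, "device": device_a},
        "labelled_indel": {
            "readout": labelled,
            "database": db,
            "truth": truth,
            "device": device_b,
        },
    }
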