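"""Database search: score every protein against a readout's profile and
infer the originating protein, optionally pooling several fragments.

The inferred protein is the highest-scoring hit; ties are broken by the
lexicographically smallest accession and flagged, and a tie resolved away
from the true protein counts as incorrect (conservative accuracy).
Multi-fragment identification sums per-target scores over all fragment
readouts of a molecule before taking the argmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._dp import forward_bits_many
from .database import SequenceDatabase
from .hmm import ProfileHMM, _em_ratio, _entry_exit

__all__ = [
    "HitScore",
    "IdentificationResult",
    "score_database",
    "infer",
    "combine_fragments",
]


@dataclass(frozen=True)
class HitScore:
    """One target protein's forward log-odds score against a profile."""

    accession: str
    score_bits: float


@dataclass(frozen=True)
class IdentificationResult:
    """Ranked hits for one readout and the argmax inference."""

    readout_id: str
    ranked_hits: tuple
    inferred_accession: str
    correct: bool | None
    tie_flag: bool


def _rank(hits: list[HitScore]) -> list[HitScore]:
    return sorted(hits, key=lambda h: (-h.score_bits, h.accession))


def score_database(profile: ProfileHMM, db: SequenceDatabase) -> list[HitScore]:
    """Forward-score every database sequence against the profile.

    The null model uses the database background frequencies. Deterministic;
    results are independent of evaluation order.
    """
    if db.n == 0:
        raise ValueError("cannot search an empty database")
    p = profile.params
    em_ratio = _em_ratio(profile, db.background)
    entry_m, exit_m = _entry_exit(profile)
    encoded = db.encoded()
    cat = db.__dict__.get("_concat")
    if cat is None:
        offsets = np.zeros(db.n + 1, dtype=np.int64)
        offsets[1:] = np.cumsum([len(c) for c in encoded])
        concat = np.concatenate(encoded).astype(np.int64)
        cat = (concat, offsets)
        db.__dict__["_concat"] = cat
    concat, offsets = cat
    scores = forward_bits_many(
        em_ratio,
        concat,
        offsets,
        p.t_mm, p.t_mi, p.t_md, p.t_im, p.t_ii, p.t_dm, p.t_dd,
        entry_m, exit_m,
    )
    return [HitScore(r.accession, float(s)) for r, s in zip(db.records, scores)]


def infer(
    scores: list[HitScore],
    truth: str | None = None,
    readout_id: str = "",
) -> IdentificationResult:
    """Take the top-scoring hit as the inferred protein.

    Ties at the top are broken by accession (ascending) and flagged; with a
    known truth, a tie resolved away from it counts as incorrect.
    """
    if not scores:
        raise ValueError("cannot infer from an empty score list")
    ranked = _rank(list(scores))
    top = ranked[0]
    tie = len(ranked) > 1 and ranked[1].score_bits == top.score_bits
    return IdentificationResult(
        readout_id=readout_id,
        ranked_hits=tuple(ranked),
        inferred_accession=top.accession,
        correct=None if truth is None else top.accession == truth,
        tie_flag=tie,
    )


def combine_fragments(
    per_fragment_scores: list[tuple[str, list[HitScore]]],
) -> list[HitScore]:
    """Sum per-target scores over fragment readouts of one molecule.

    Every fragment must have been scored against the same database (same
    accession set); the summed scores are returned ranked descending.
    """
    if not per_fragment_scores:
        raise ValueError("no fragment scores to combine")
    totals: dict[str, float] = {}
    ref_keys: set[str] | None = None
    for _readout_id, hits in per_fragment_scores:
        keys = {h.accession for h in hits}
        if ref_keys is None:
            ref_keys = keys
            totals = {k: 0.0 for k in keys}
        elif keys != ref_keys:
            raise ValueError("fragments were scored against different databases")
        for h in hits:
            totals[h.accession] += h.score_bits
    return _rank([HitScore(acc, s) for acc, s in totals.items()])
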