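"""Profile HMMs built from sequencer readouts, and log-odds scoring.

Identification reverses the classical profile search: each readout becomes
the *query* profile — one match state per readout column whose emission
distribution is the posterior column itself — and every database protein is
scored as a *target* sequence. Transitions out of each match state are
fixed a priori (M→M 0.8, M→I 0.1, M→D 0.1 by default) to tolerate indel
errors while preferring matches; insert states emit at background
frequencies.

Scores are log-odds in bits against an i.i.d. background null model. The
default alignment mode is glocal over the query (every readout column must
be matched or deleted — a readout is one complete sequenced molecule) and
local over the target (a fragment may come from anywhere inside a protein;
flanking target residues are absorbed at zero log-odds cost). Boundary
scoring: entering the first match state and leaving the last match/delete
state are free, and entering the first delete state costs t_MD — so a
one-state profile with emission 1 on the target's residue scores exactly
log2(1/background) via the single path Begin→M1→End.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _dp
from .alphabet import AMINO_ACIDS, N_AMINO_ACIDS, encode
from .simulate import Readout

GLOCAL = "glocal"  # glocal-query / local-target (default)
LOCAL = "local"  # local-query / local-target


def _uniform_background() -> np.ndarray:
    return np.full(N_AMINO_ACIDS, 1.0 / N_AMINO_ACIDS)


@dataclass(frozen=True)
class ProfileParams:
    """Core transition probabilities and the null background.

    The match-state triplet (t_mm, t_mi, t_md) follows the a-priori choice
    of 0.8/0.1/0.1; the insert/delete continuation values default to
    0.9/0.1, standing in for a profile engine's defaults, and are
    configurable when device error rates are known.
    """

    t_mm: float = 0.8
    t_mi: float = 0.1
    t_md: float = 0.1
    t_im: float = 0.9
    t_ii: float = 0.1
    t_dm: float = 0.9
    t_dd: float = 0.1
    background: np.ndarray = field(default_factory=_uniform_background)

    def __post_init__(self) -> None:
        object.__setattr__(self, "background", np.asarray(self.background, dtype=float))
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if abs(self.t_mm + self.t_mi + self.t_md - 1.0) > 1e-12:
            raise ValueError("t_mm + t_mi + t_md must sum to 1")
        if abs(self.t_im + self.t_ii - 1.0) > 1e-12:
            raise ValueError("t_im + t_ii must sum to 1")
        if abs(self.t_dm + self.t_dd - 1.0) > 1e-12:
            raise ValueError("t_dm + t_dd must sum to 1")
        bg = self.background
        if bg.shape != (N_AMINO_ACIDS,) or (bg < 0).any() or abs(bg.sum() - 1) > 1e-9:
            raise ValueError("background must be a valid 20-vector of frequencies")


@dataclass
class ProfileHMM:
    """A left-to-right profile with one match state per readout column."""

    match_emissions: np.ndarray  # (20, Lq), columns sum to 1
    params: ProfileParams
    alignment_mode: str = GLOCAL
    name: str = "readout"

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        if self.match_emissions.ndim != 2 or self.match_emissions.shape[0] != N_AMINO_ACIDS:
            raise ValueError("match_emissions must be 20 x Lq")
        if self.match_emissions.shape[1] < 1:
            raise ValueError("profile needs at least one match state")
        if np.abs(self.match_emissions.sum(axis=0) - 1.0).max() > 1e-9:
            raise ValueError("match emission columns must sum to 1")
        if self.alignment_mode not in (GLOCAL, LOCAL):
            raise ValueError(f"unknown alignment mode {self.alignment_mode!r}")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[1]


@dataclass(frozen=True)
class ScoreResult:
    """Forward and Viterbi log-odds scores (bits) for one profile/target pair."""

    forward_bits: float
    viterbi_bits: float


def build_profile(
    readout: Readout,
    params: ProfileParams | None = None,
    alignment_mode: str = GLOCAL,
) -> ProfileHMM:
    """Turn a readout into a profile: posteriors become match emissions."""
    if params is None:
        params = ProfileParams()
    return ProfileHMM(
        match_emissions=readout.matrix.copy(),
        params=params,
        alignment_mode=alignment_mode,
        name=readout.readout_id,
    )


def _entry_exit(profile: ProfileHMM) -> tuple[np.ndarray, np.ndarray]:
    """Effective odds vectors for Begin→M_j and M_j→End (wing-retracted).

    In glocal mode the begin/end delete chains (Begin→D_1…D_j→M_{j+1} and
    M_j→D_{j+1}…D_Lq→End) are folded into per-column entry/exit weights, so
    every alignment uses at least one match state and the empty all-delete
    alignment is excluded. Interior delete states stay explicit in the DP.
    Entry into M_1 and exit from M_Lq are free (odds 1).
    """
    Lq = profile.length
    p = profile.params
    entry_m = np.zeros(Lq)
    exit_m = np.zeros(Lq)
    if profile.alignment_mode == GLOCAL:
        entry_m[0] = 1.0
        exit_m[-1] = 1.0
        for j in range(1, Lq):
            entry_m[j] = p.t_md * p.t_dd ** (j - 1) * p.t_dm
        for j in range(Lq - 1):
            exit_m[j] = p.t_md * p.t_dd ** (Lq - 2 - j)
    else:  # local-query: uniform entry over columns, free exit anywhere
        entry_m[:] = 1.0 / Lq
        exit_m[:] = 1.0
    return entry_m, exit_m


def _em_ratio(profile: ProfileHMM, background: np.ndarray) -> np.ndarray:
    bg = np.asarray(background, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = profile.match_emissions / bg[:, None]
    # a background-zero residue never occurs in any target drawn from it
    ratio[bg == 0.0, :] = 0.0
    return ratio


def _score(profile: ProfileHMM, target: str, background: np.ndarray | None, kernel) -> float:
    if background is None:
        background = profile.params.background
    codes = encode(target)
    p = profile.params
    entry_m, exit_m = _entry_exit(profile)
    return float(
        kernel(
            _em_ratio(profile, background),
            codes.astype(np.int64),
            p.t_mm, p.t_mi, p.t_md, p.t_im, p.t_ii, p.t_dm, p.t_dd,
            entry_m, exit_m,
        )
    )


def forward_score(profile: ProfileHMM, target: str, background: np.ndarray | None = None) -> float:
    """log2 P(target | profile) / P(target | null), summed over alignments."""
    return _score(profile, target, background, _dp.forward_bits)


def viterbi_score(profile: ProfileHMM, target: str, background: np.ndarray | None = None) -> float:
    """log2 odds of the single best alignment."""
    return _score(profile, target, background, _dp.viterbi_bits)


def score(profile: ProfileHMM, target: str, background: np.ndarray | None = None) -> ScoreResult:
    return ScoreResult(
        forward_bits=forward_score(profile, target, background),
        viterbi_bits=viterbi_score(profile, target, background),
    )


# ---------------------------------------------------------------------------
# Brute-force oracle: exhaustive path enumeration, independent of the DP.

_MAX_ORACLE_STATES = 5
_MAX_ORACLE_TARGET = 6


def brute_force_score(
    profile: ProfileHMM,
    target: str,
    background: np.ndarray | None = None,
    mode: str = "sum",
) -> float:
    """Exact log-odds by enumerating every legal state path (tiny instances).

    Ground truth for the DP implementations; limited to profiles of at most
    5 match states and targets of at most 6 residues.
    """
    if profile.length > _MAX_ORACLE_STATES or len(target) > _MAX_ORACLE_TARGET:
        raise ValueError("instance too large for brute-force enumeration")
    if mode not in ("sum", "max"):
        raise ValueError(f"mode must be 'sum' or 'max', got {mode}")
    if background is None:
        background = profile.params.background
    codes = encode(target).tolist()
    Lt = len(codes)
    p = profile.params
    Lq = profile.length

    # Entry/exit weights derived here independently of the DP helpers: in
    # glocal mode a path enters at the first matched column j through a
    # Begin->D_1..D_j->M_{j+1} delete chain and leaves its last matched
    # column through a delete chain to the end; both chains are single
    # paths, so their odds are plain products. Local mode enters any column
    # at odds 1/Lq and exits any column freely.
    if profile.alignment_mode == GLOCAL:
        entry = [1.0 if j == 0 else p.t_md * p.t_dd ** (j - 1) * p.t_dm for j in range(Lq)]
        exit_ = [1.0 if j == Lq - 1 else p.t_md * p.t_dd ** (Lq - 2 - j) for j in range(Lq)]
    else:
        entry = [1.0 / Lq] * Lq
        exit_ = [1.0] * Lq
    ratio = _em_ratio(profile, background)

    acc = {"sum": 0.0, "max": 0.0}

    def finish(w: float) -> None:
        # remaining target residues are absorbed by the free C flank
        if mode == "sum":
            acc["sum"] += w
        else:
            acc["max"] = max(acc["max"], w)

    def walk(state: str, j: int, i: int, w: float) -> None:
        """Arrived in `state` at column j with i residues consumed; w includes
        this state's emission odds."""
        if w == 0.0:
            return
        if state == "M":
            finish(w * exit_[j])
        if state in ("M", "D"):
            if j + 1 < Lq:
                t_to_m = p.t_mm if state == "M" else p.t_dm
                t_to_d = p.t_md if state == "M" else p.t_dd
                if i < Lt:
                    walk("M", j + 1, i + 1, w * t_to_m * ratio[codes[i], j + 1])
                walk("D", j + 1, i, w * t_to_d)
            if state == "M" and j < Lq - 1 and i < Lt:
                walk("I", j, i + 1, w * p.t_mi)  # insert emits at odds 1
        else:  # insert state
            if i < Lt:
                walk("I", j, i + 1, w * p.t_ii)
                if j + 1 < Lq:
                    walk("M", j + 1, i + 1, w * p.t_im * ratio[codes[i], j + 1])

    # the N flank consumes any prefix of the target for free
    for s in range(Lt):
        for j in range(Lq):
            walk("M", j, s + 1, entry[j] * ratio[codes[s], j])

    total = acc["sum"] if mode == "sum" else acc["max"]
    return float(np.log2(total)) if total > 0.0 else float("-inf")


# ---------------------------------------------------------------------------
# HMMER3 ASCII export for external cross-validation.


def _fmt(p: float) -> str:
    """Probability as negative natural log, '*' for zero."""
    return "  *" if p <= 0.0 else f"  {-np.log(p):.5f}"


def write_hmmer3_profile(profile: ProfileHMM, path: str | Path, name: str | None = None) -> None:
    """Write the profile in HMMER3/f ASCII so hmmsearch can consume it.

    Match emission lines hold −ln(posterior) of the readout columns, insert
    emissions the background, and transition lines the core parameters.
    Zero probabilities use the format's '*' token. The engine reading the
    file applies its own begin/end configuration, so this export is for
    cross-validation of rankings, not for bit-score equality.
    """
    p = profile.params
    bg = p.background
    em = profile.match_emissions
    Lq = profile.length
    name = name or profile.name or "readout"

    with open(path, "w") as fh:
        fh.write("HMMER3/f [3.4 | protident export]\n")
        fh.write(f"NAME  {name}\n")
        fh.write(f"LENG  {Lq}\n")
        fh.write("ALPH  amino\n")
        fh.write("RF    no\nMM    no\nCONS  yes\nCS    no\nMAP   no\n")
        # generic score-distribution parameters so engines that insist on
        # E-value bookkeeping accept the file; rankings use raw bit scores
        # and are unaffected by these constants.
        fh.write("STATS LOCAL MSV       -9.0000  0.70000\n")
        fh.write("STATS LOCAL VITERBI  -10.0000  0.70000\n")
        fh.write("STATS LOCAL FORWARD   -4.0000  0.70000\n")
        fh.write("HMM     " + "".join(f"     {aa}    " for aa in AMINO_ACIDS) + "\n")
        fh.write(
            "        "
            + "   m->m     m->i     m->d     i->m     i->i     d->m     d->d\n"
        )
        compo = em.mean(axis=1)
        fh.write("  COMPO" + "".join(_fmt(x) for x in compo) + "\n")
        fh.write("       " + "".join(_fmt(x) for x in bg) + "\n")
        # node 0: Begin transitions; no delete state to continue from
        fh.write(
            "       "
            + _fmt(p.t_mm) + _fmt(p.t_mi) + _fmt(p.t_md)
            + _fmt(p.t_im) + _fmt(p.t_ii) + _fmt(1.0) + "  *\n"
        )
        for k in range(Lq):
            cons = AMINO_ACIDS[int(np.argmax(em[:, k]))].lower()
            fh.write(
                f"{k + 1:7d}" + "".join(_fmt(x) for x in em[:, k])
                + f"      - {cons} - - -\n"
            )
            fh.write("       " + "".join(_fmt(x) for x in bg) + "\n")
            if k < Lq - 1:
                fh.write(
                    "       "
                    + _fmt(p.t_mm) + _fmt(p.t_mi) + _fmt(p.t_md)
                    + _fmt(p.t_im) + _fmt(p.t_ii) + _fmt(p.t_dm) + _fmt(p.t_dd)
                    + "\n"
                )
            else:
                # last node: M->E certain, no M->D / D->D continuation
                fh.write(
                    "       "
                    + _fmt(1.0) + "  *" + "  *"
                    + _fmt(p.t_im) + _fmt(p.t_ii) + _fmt(1.0) + "  *\n"
                )
        fh.write("//\n")
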