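"""Numerical kernels for Forward/Viterbi profile-HMM log-odds scoring.

The dynamic programming runs in linear (odds-ratio) space with periodic
adaptive rescaling, which is substantially faster than log-space
log-sum-exp and exact enough for the 1e-9-bit oracle tolerance. All match
emissions enter as odds ratios against the null background, so insert and
flank emissions are identically 1; exit mass is accumulated in the same
adaptive scale and a single log2 at the end yields the log-odds score.

State layout per query column j (0-based): match M_j, insert I_j (after
column j; the last column has no insert state), delete D_j. Begin/end
delete wings are folded into the per-column entry/exit odds vectors by the
caller, so every alignment contains at least one match state and the
kernels only track interior delete states.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2E = 1.4426950408889634
_RESCALE_HI = 1e80
_RESCALE_LO = 1e-80
_CHECK_MASK = 15  # rescale check every 16 target rows


@njit(cache=True, fastmath=True)
def forward_bits(
    em_ratio,  # (20, Lq) match emission odds ratios vs background
    tgt,  # (Lt,) int64 target residue codes
    tMM, tMI, tMD, tIM, tII, tDM, tDD,
    entry_m,  # (Lq,) odds for Begin -> M_j (incl. folded delete wing)
    exit_m,  # (Lq,) odds for M_j -> End (incl. folded delete wing)
):
    """Forward log-odds score in bits (sum over all alignments)."""
    Lq = em_ratio.shape[1]
    Lt = tgt.shape[0]

    M = np.zeros(Lq)
    I = np.zeros(Lq)
    D = np.zeros(Lq)
    Mn = np.empty(Lq)
    In = np.empty(Lq)
    Dn = np.empty(Lq)

    logscale = 0.0  # log2 of the cumulative rescaling factor
    bs = 1.0  # Begin value in the rescaled frame (absolute value 1)
    etot = 0.0  # accumulated exit mass, in the rescaled frame

    for i in range(Lt):
        row = em_ratio[tgt[i]]
        Mn[0] = row[0] * entry_m[0] * bs
        for j in range(1, Lq):
            Mn[j] = row[j] * (
                tMM * M[j - 1] + tIM * I[j - 1] + tDM * D[j - 1] + entry_m[j] * bs
            )
        for j in range(Lq - 1):
            In[j] = tMI * M[j] + tII * I[j]
        In[Lq - 1] = 0.0  # no insert state after the last column
        d = 0.0
        Dn[0] = 0.0
        for j in range(1, Lq):
            d = tMD * Mn[j - 1] + tDD * d
            Dn[j] = d
        e = 0.0
        for j in range(Lq):
            e += exit_m[j] * Mn[j]
        etot += e
        M, Mn = Mn, M
        I, In = In, I
        D, Dn = Dn, D
        if (i & _CHECK_MASK) == _CHECK_MASK:
            hi = 0.0
            for j in range(Lq):
                if M[j] > hi:
                    hi = M[j]
                if I[j] > hi:
                    hi = I[j]
                if D[j] > hi:
                    hi = D[j]
            if hi > _RESCALE_HI or (0.0 < hi < _RESCALE_LO):
                inv = 1.0 / hi
                for j in range(Lq):
                    M[j] *= inv
                    I[j] *= inv
                    D[j] *= inv
                etot *= inv
                logscale += np.log(hi) * _LOG2E
                bs = 0.0 if logscale > 1000.0 else 2.0 ** (-logscale)

    if etot <= 0.0:
        return -np.inf
    return np.log(etot) * _LOG2E + logscale


@njit(cache=True, fastmath=True)
def viterbi_bits(
    em_ratio,
    tgt,
    tMM, tMI, tMD, tIM, tII, tDM, tDD,
    entry_m,
    exit_m,
):
    """Viterbi log-odds score in bits (best single alignment)."""
    Lq = em_ratio.shape[1]
    Lt = tgt.shape[0]

    M = np.zeros(Lq)
    I = np.zeros(Lq)
    D = np.zeros(Lq)
    Mn = np.empty(Lq)
    In = np.empty(Lq)
    Dn = np.empty(Lq)

    logscale = 0.0
    bs = 1.0
    ebest = 0.0  # best exit mass seen, in the rescaled frame

    for i in range(Lt):
        row = em_ratio[tgt[i]]
        Mn[0] = row[0] * entry_m[0] * bs
        for j in range(1, Lq):
            w = tMM * M[j - 1]
            v = tIM * I[j - 1]
            if v > w:
                w = v
            v = tDM * D[j - 1]
            if v > w:
                w = v
            v = entry_m[j] * bs
            if v > w:
                w = v
            Mn[j] = row[j] * w
        for j in range(Lq - 1):
            In[j] = max(tMI * M[j], tII * I[j])
        In[Lq - 1] = 0.0
        d = 0.0
        Dn[0] = 0.0
        for j in range(1, Lq):
            d = max(tMD * Mn[j - 1], tDD * d)
            Dn[j] = d
        for j in range(Lq):
            v = exit_m[j] * Mn[j]
            if v > ebest:
                ebest = v
        M, Mn = Mn, M
        I, In = In, I
        D, Dn = Dn, D
        if (i & _CHECK_MASK) == _CHECK_MASK:
            hi = 0.0
            for j in range(Lq):
                if M[j] > hi:
                    hi = M[j]
                if I[j] > hi:
                    hi = I[j]
                if D[j] > hi:
                    hi = D[j]
            if hi > _RESCALE_HI or (0.0 < hi < _RESCALE_LO):
                inv = 1.0 / hi
                for j in range(Lq):
                    M[j] *= inv
                    I[j] *= inv
                    D[j] *= inv
                ebest *= inv
                logscale += np.log(hi) * _LOG2E
                bs = 0.0 if logscale > 1000.0 else 2.0 ** (-logscale)

    if ebest <= 0.0:
        return -np.inf
    return np.log(ebest) * _LOG2E + logscale


@njit(cache=True)
def forward_bits_many(
    em_ratio,
    targets,  # concatenated residue codes
    offsets,  # (n+1,) start offsets into `targets`
    tMM, tMI, tMD, tIM, tII, tDM, tDD,
    entry_m,
    exit_m,
):
    """Forward score of one profile against many targets."""
    n = offsets.shape[0] - 1
    out = np.empty(n)
    for k in range(n):
        out[k] = forward_bits(
            em_ratio,
            targets[offsets[k] : offsets[k + 1]],
            tMM, tMI, tMD, tIM, tII, tDM, tDD,
            entry_m, exit_m,
        )
    return out
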