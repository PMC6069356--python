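"""Interval dynamic programme for the secondary-structure partition function.

Computes Q = sum_s exp(-dG(s)/kT) over all pseudoknot-free structures of a
single strand or of an ordered multi-strand complex. The multi-strand case
follows the polymer-graph rule for connected complexes: every loop may expose
at most one nick, and a loop containing a nick is scored as an exterior face
(zero energy). With the strand ordering fixed, the structures generated this
way are exactly the connected structures of the complex.

The recursions track, for every interval [a, b]:

``Qb[i, j]``
    structures in which (i, j) is a pair (hairpin / two-loop / multiloop /
    one-nick exterior face inside).
``S0/S1[a, b]``
    exterior-style series of branches and unpaired bases exposing exactly
    zero / one nick (candidate nicks are those at a-1 .. b).
``M/M2[a, b]``
    multiloop series with >= 1 / >= 2 branches, multiloop weighting, no
    exposed nick.

Two-loops (stack/bulge/interior) are scanned up to ``two_loop_max`` total
unpaired bases, the usual MAXLOOP convention; for the short sequences the
exhaustive oracle can check, that bound never binds, so the DP and the
enumeration agree exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["partition_function_dp"]


@njit(cache=True)
def _pf_kernel(seq, nick, stack, hp, bg, il, ml_a, ml_b, ml_c, kT, cap):
    N = seq.shape[0]
    # prefix nick counts: pn[x] = nicks at positions < x
    pn = np.zeros(N + 1, np.int64)
    for p in range(N):
        c = pn[p]
        if p <= N - 2 and nick[p]:
            c += 1
        pn[p + 1] = c

    def _nicks(x, y):
        # nicks p in [x, y] clipped to [0, N-2]
        lo = x if x > 0 else 0
        hi = y if y < N - 2 else N - 2
        if hi < lo:
            return 0
        return pn[hi + 1] - pn[lo]

    Qb = np.zeros((N, N))
    S0 = np.zeros((N + 1, N + 1))
    S1 = np.zeros((N + 1, N + 1))
    M = np.zeros((N + 1, N + 1))
    M2 = np.zeros((N + 1, N + 1))

    w_mlclose = np.exp(-(ml_a + ml_b) / kT)
    w_b = np.exp(-ml_b / kT)
    w_c = np.exp(-ml_c / kT)

    for b in range(N):
        # empty-interval base cases S(b+1, b): candidate nick is position b
        has = 1.0 if (b <= N - 2 and nick[b]) else 0.0
        S0[b + 1, b + 1] = 1.0 - has
        S1[b + 1, b + 1] = has
        if b == 0:
            # S(1,0) set above; also need S(0,-1)? not used at top level
            pass
        for a in range(b, -1, -1):
            # ---- Qb(a, b) ----
            if seq[a] + seq[b] == 3 and b > a:
                tot = 0.0
                h = b - a - 1
                if h >= 3 and h < hp.shape[0] and _nicks(a, b - 1) == 0:
                    tot += np.exp(-hp[h] / kT)
                # two-loops
                for k in range(a + 1, b - 1):
                    g1 = k - a - 1
                    if g1 > cap:
                        break
                    if _nicks(a, k - 1) > 0:
                        break
                    for l in range(b - 1, k, -1):
                        g2 = b - l - 1
                        if g1 + g2 > cap:
                            break
                        if _nicks(l, b - 1) > 0:
                            break
                        q = Qb[k, l]
                        if q > 0.0 and seq[k] + seq[l] == 3:
                            if g1 == 0 and g2 == 0:
                                e = stack[seq[a], seq[a + 1]]
                            elif g1 == 0 or g2 == 0:
                                e = bg[g1 + g2]
                            else:
                                e = il[g1 + g2]
                            tot += np.exp(-e / kT) * q
                # multiloop (no nick) and one-nick exterior face
                if b - a >= 2:
                    tot += w_mlclose * M2[a + 1, b]
                tot += S1[a + 1, b]
                Qb[a, b] = tot
            # ---- series S0/S1, M, M2 on [a, b] ----
            n0 = a - 1 >= 0 and a - 1 <= N - 2 and nick[a - 1]
            sum0 = S0[a + 1, b + 1]
            sum1 = S1[a + 1, b + 1]
            m = w_c * M[a + 1, b + 1]
            m2 = w_c * M2[a + 1, b + 1]
            for l in range(a + 1, b + 1):
                q = Qb[a, l]
                if q > 0.0:
                    sum0 += q * S0[l + 1, b + 1]
                    sum1 += q * S1[l + 1, b + 1]
                    tail = 0.0
                    if _nicks(l, b) == 0:
                        tail = w_c ** (b - l)
                    m += q * w_b * (tail + M[l + 1, b + 1])
                    m2 += q * w_b * M[l + 1, b + 1]
            if n0:
                S0[a, b + 1] = 0.0
                S1[a, b + 1] = sum0
                M[a, b + 1] = 0.0
                M2[a, b + 1] = 0.0
            else:
                S0[a, b + 1] = sum0
                S1[a, b + 1] = sum1
                M[a, b + 1] = m
                M2[a, b + 1] = m2

    return S0[0, N]


def partition_function_dp(seq_codes, nick_after, model) -> float:
    """Partition function of one ordered complex (or single strand).

    Parameters
    ----------
    seq_codes:
        int8 codes over the concatenation (A=0, C=1, G=2, T=3).
    nick_after:
        boolean array, ``nick_after[p]`` true when a strand break lies
        between positions p and p+1.
    """
    seq = np.ascontiguousarray(seq_codes, dtype=np.int8)
    n = seq.shape[0]
    nick = np.zeros(n, dtype=np.bool_)
    nick[: len(nick_after)] = np.asarray(nick_after, dtype=np.bool_)[:n]
    stack, hp, bg, il = model.tables(n)
    return float(
        _pf_kernel(
            seq,
            nick,
            stack,
            hp,
            bg,
            il,
            model.multiloop_init,
            model.multiloop_branch,
            model.multiloop_unpaired,
            model.kT,
            model.two_loop_max,
        )
    )
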