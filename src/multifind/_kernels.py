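"""Numba dynamic-programming kernels for the folding core.

All kernels are parameterized by per-position-pair matrices rather than raw
sequences, so the same recursions serve both single-sequence folding and
column-consensus folding over an alignment:

``pairable[i, j]``  whether positions (columns) i < j may pair
``pairpen[i, j]``   additive penalty charged once per pair (i, j)
``tau[i, j]``       helix-end (terminal AU/GU) penalty for pair (i, j)
``stk[i, j]``       stacking increment for pair (i, j) over pair (i+1, j-1)

plus dense loop-penalty tables and the multibranch linear model
(offset ``ml_a``, per-helix ``ml_b``, per-unpaired ``ml_c``).

Energy decomposition convention: each loop charges the helix-end penalty of
every pair bordering it (its closing pair and each directly nested pair);
stacked pairs charge only the stacking increment.  The scoring here matches
``folding.energy_of`` term for term, which is what makes the exhaustive
enumeration oracle exact.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

BIG = 1.0e18


@njit(cache=True)
def mfe_matrix(n, pairable, pairpen, tau, stk, hp, bl, il, ml_a, ml_b, ml_c, maxloop):
    """Minimum-free-energy fold.  Returns (energy, pairs) with pairs[i] = -1 or partner.

    Tie-breaking is deterministic: candidate cases are evaluated in a fixed
    order (stack, internal, multibranch, hairpin; splits in ascending index)
    and only a strictly lower energy replaces the incumbent, so paired
    configurations win ties against less-paired ones.
    """
    V = np.full((n, n), BIG)
    M = np.full((n, n), BIG)   # multibranch segment, >= 1 branch
    M1 = np.full((n, n), BIG)  # multibranch segment, branch starting at i
    # traceback bookkeeping
    Vc = np.full((n, n), -1, dtype=np.int8)    # 0 hairpin 1 stack 2 internal 3 multi
    Vk = np.zeros((n, n), dtype=np.int64)
    Vl = np.zeros((n, n), dtype=np.int64)
    Mc = np.full((n, n), -1, dtype=np.int8)    # 0: i unpaired; 1: M1 here; 2: split
    Mk = np.zeros((n, n), dtype=np.int64)
    M1c = np.full((n, n), -1, dtype=np.int8)   # 0: j unpaired; 1: branch (i,j)

    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            # ---- V ----
            if pairable[i, j]:
                best = BIG
                case = -1
                bk = 0
                bl_ = 0
                # stack
                if i + 1 < j - 1 and pairable[i + 1, j - 1]:
                    cand = stk[i, j] + V[i + 1, j - 1]
                    if cand < best:
                        best = cand
                        case = 1
                # internal / bulge
                kmax = min(i + 1 + maxloop, j - 1)
                for k in range(i + 1, kmax + 1):
                    sz1 = k - i - 1
                    lmin = max(k + 1, j - 1 - (maxloop - sz1))
                    for l in range(j - 1, lmin - 1, -1):
                        if not pairable[k, l]:
                            continue
                        sz2 = j - l - 1
                        if sz1 == 0 and sz2 == 0:
                            continue
                        sz = sz1 + sz2
                        lp = bl[sz] if (sz1 == 0 or sz2 == 0) else il[sz]
                        cand = lp + tau[i, j] + tau[k, l] + V[k, l]
                        if cand < best:
                            best = cand
                            case = 2
                            bk = k
                            bl_ = l
                # multibranch closure
                a, b = i + 1, j - 1
                for k in range(a + 1, b):
                    if M[a, k - 1] < BIG / 2 and M1[k, b] < BIG / 2:
                        cand = ml_a + ml_b + tau[i, j] + M[a, k - 1] + M1[k, b]
                        if cand < best:
                            best = cand
                            case = 3
                            bk = k
                # hairpin
                cand = hp[d - 1] + tau[i, j]
                if cand < best:
                    best = cand
                    case = 0
                if case >= 0:
                    V[i, j] = pairpen[i, j] + best
                    Vc[i, j] = case
                    Vk[i, j] = bk
                    Vl[i, j] = bl_
            # ---- M1 ----
            if pairable[i, j] and V[i, j] < BIG / 2:
                M1[i, j] = V[i, j] + ml_b + tau[i, j]
                M1c[i, j] = 1
            if j > i and M1[i, j - 1] < BIG / 2 and M1[i, j - 1] + ml_c < M1[i, j]:
                M1[i, j] = M1[i, j - 1] + ml_c
                M1c[i, j] = 0
            # ---- M ----
            best = BIG
            case = -1
            bk = 0
            if M[i + 1, j] < BIG / 2:
                best = M[i + 1, j] + ml_c
                case = 0
            if M1[i, j] < best:
                best = M1[i, j]
                case = 1
            for k in range(i + 1, j + 1):
                if M[i, k - 1] < BIG / 2 and M1[k, j] < BIG / 2:
                    cand = M[i, k - 1] + M1[k, j]
                    if cand < best:
                        best = cand
                        case = 2
                        bk = k
            if case >= 0:
                M[i, j] = best
                Mc[i, j] = case
                Mk[i, j] = bk

    # exterior
    W = np.zeros(n + 1)
    Wi = np.full(n + 1, -2, dtype=np.int64)  # -2: j unpaired; else helix start i
    for j in range(n):
        best = BIG
        bi = -2
        for i in range(j + 1):
            if V[i, j] < BIG / 2:
                cand = W[i] + V[i, j] + tau[i, j]
                if cand < best:
                    best = cand
                    bi = i
        if W[j] < best:  # leave j unpaired only on strict improvement
            best = W[j]
            bi = -2
        W[j + 1] = best
        Wi[j + 1] = bi

    # traceback
    pairs = np.full(n, -1, dtype=np.int64)
    stack_t = np.zeros((2 * n + 4, 3), dtype=np.int64)  # (kind, i, j); kind 1=V 2=M 3=M1
    top = 0
    j = n
    while j > 0:
        bi = Wi[j]
        if bi == -2:
            j -= 1
        else:
            stack_t[top, 0] = 1
            stack_t[top, 1] = bi
            stack_t[top, 2] = j - 1
            top += 1
            j = bi
    while top > 0:
        top -= 1
        kind, i, j = stack_t[top, 0], stack_t[top, 1], stack_t[top, 2]
        if kind == 1:
            pairs[i] = j
            pairs[j] = i
            c = Vc[i, j]
            if c == 1:
                stack_t[top, 0] = 1
                stack_t[top, 1] = i + 1
                stack_t[top, 2] = j - 1
                top += 1
            elif c == 2:
                stack_t[top, 0] = 1
                stack_t[top, 1] = Vk[i, j]
                stack_t[top, 2] = Vl[i, j]
                top += 1
            elif c == 3:
                k = Vk[i, j]
                stack_t[top, 0] = 2
                stack_t[top, 1] = i + 1
                stack_t[top, 2] = k - 1
                top += 1
                stack_t[top, 0] = 3
                stack_t[top, 1] = k
                stack_t[top, 2] = j - 1
                top += 1
        elif kind == 2:
            c = Mc[i, j]
            if c == 0:
                stack_t[top, 0] = 2
                stack_t[top, 1] = i + 1
                stack_t[top, 2] = j
                top += 1
            elif c == 1:
                stack_t[top, 0] = 3
                stack_t[top, 1] = i
                stack_t[top, 2] = j
                top += 1
            elif c == 2:
                k = Mk[i, j]
                stack_t[top, 0] = 2
                stack_t[top, 1] = i
                stack_t[top, 2] = k - 1
                top += 1
                stack_t[top, 0] = 3
                stack_t[top, 1] = k
                stack_t[top, 2] = j
                top += 1
        else:  # M1: strip trailing unpaired, then the branch is a V task
            while M1c[i, j] == 0:
                j -= 1
            stack_t[top, 0] = 1
            stack_t[top, 1] = i
            stack_t[top, 2] = j
            top += 1

    return W[n], pairs


@njit(cache=True)
def pf_matrix(n, pairable, pairpen, tau, stk, hp, bl, il, ml_a, ml_b, ml_c,
              maxloop, rt, sf):
    """McCaskill partition function with inside-outside pair probabilities.

    All inside arrays are scaled by ``sf`` per nucleotide to keep doubles
    finite on long sequences.  Returns (logQ, pairprob) where pairprob is the
    symmetric base-pair probability matrix.
    """
    qb = np.zeros((n, n))
    qm = np.zeros((n, n))
    qm1 = np.zeros((n, n))
    qmA = np.zeros((n, n))  # single-branch part of qm (leading unpaired + qm1)
    cc = math.exp(-ml_c / rt) / sf
    eb_closing = 1.0 / (sf * sf)

    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            if pairable[i, j]:
                pp = math.exp(-pairpen[i, j] / rt)
                # hairpin
                s = math.exp(-(hp[d - 1] + tau[i, j]) / rt) / sf ** (d + 1)
                # stack
                if i + 1 < j - 1 and pairable[i + 1, j - 1]:
                    s += math.exp(-stk[i, j] / rt) * qb[i + 1, j - 1] * eb_closing
                # internal / bulge
                kmax = min(i + 1 + maxloop, j - 1)
                for k in range(i + 1, kmax + 1):
                    sz1 = k - i - 1
                    lmin = max(k + 1, j - 1 - (maxloop - sz1))
                    for l in range(j - 1, lmin - 1, -1):
                        if not pairable[k, l]:
                            continue
                        sz2 = j - l - 1
                        if sz1 == 0 and sz2 == 0:
                            continue
                        sz = sz1 + sz2
                        lp = bl[sz] if (sz1 == 0 or sz2 == 0) else il[sz]
                        s += (math.exp(-(lp + tau[i, j] + tau[k, l]) / rt)
                              * qb[k, l] / sf ** (sz + 2))
                # multibranch closure: >= 2 branches inside
                mb = 0.0
                for k in range(i + 2, j - 1):
                    if qm[i + 1, k - 1] > 0.0 and qm1[k, j - 1] > 0.0:
                        mb += qm[i + 1, k - 1] * qm1[k, j - 1]
                s += (math.exp(-(ml_a + ml_b + tau[i, j]) / rt) * mb * eb_closing)
                qb[i, j] = pp * s
            # qm1: branch starts at i, trailing unpaired
            v = qm1[i, j - 1] * cc if j > i else 0.0
            if qb[i, j] > 0.0:
                v += qb[i, j] * math.exp(-(ml_b + tau[i, j]) / rt)
            qm1[i, j] = v
            # qmA: leading unpaired then a single branch segment
            qmA[i, j] = qm1[i, j]
            if i + 1 <= j:
                qmA[i, j] += cc * qmA[i + 1, j]
            # qm: >= 1 branch
            s = qmA[i, j]
            for k in range(i + 1, j + 1):
                if qm[i, k - 1] > 0.0 and qm1[k, j] > 0.0:
                    s += qm[i, k - 1] * qm1[k, j]
            qm[i, j] = s

    # exterior prefix / suffix
    qpre = np.zeros(n + 1)
    qpre[0] = 1.0
    for j in range(n):
        s = qpre[j] / sf
        for i in range(j + 1):
            if qb[i, j] > 0.0:
                s += qpre[i] * qb[i, j] * math.exp(-tau[i, j] / rt)
        qpre[j + 1] = s
    qsuf = np.zeros(n + 2)
    qsuf[n] = 1.0
    for i in range(n - 1, -1, -1):
        s = qsuf[i + 1] / sf
        for l in range(i, n):
            if qb[i, l] > 0.0:
                s += qb[i, l] * math.exp(-tau[i, l] / rt) * qsuf[l + 1]
        qsuf[i] = s

    logq = math.log(qpre[n]) + n * math.log(sf)

    # outside: pair probabilities, largest spans first
    pr = np.zeros((n, n))
    for d in range(n - 1, 0, -1):
        for i in range(n - d):
            j = i + d
            if qb[i, j] <= 0.0:
                continue
            p = pr[i, j] + qpre[i] * qb[i, j] * math.exp(-tau[i, j] / rt) * qsuf[j + 1] / qpre[n]
            pr[i, j] = p
            if p <= 0.0:
                continue
            fac = p / qb[i, j]
            pp = math.exp(-pairpen[i, j] / rt)
            # stack
            if i + 1 < j - 1 and qb[i + 1, j - 1] > 0.0 and pairable[i + 1, j - 1]:
                pr[i + 1, j - 1] += (fac * pp * math.exp(-stk[i, j] / rt)
                                     * qb[i + 1, j - 1] * eb_closing)
            # internal
            kmax = min(i + 1 + maxloop, j - 1)
            for k in range(i + 1, kmax + 1):
                sz1 = k - i - 1
                lmin = max(k + 1, j - 1 - (maxloop - sz1))
                for l in range(j - 1, lmin - 1, -1):
                    if qb[k, l] <= 0.0:
                        continue
                    sz2 = j - l - 1
                    if sz1 == 0 and sz2 == 0:
                        continue
                    sz = sz1 + sz2
                    lp = bl[sz] if (sz1 == 0 or sz2 == 0) else il[sz]
                    pr[k, l] += (fac * pp
                                 * math.exp(-(lp + tau[i, j] + tau[k, l]) / rt)
                                 * qb[k, l] / sf ** (sz + 2))
            # multibranch: (k,l) a branch of the loop closed by (i,j)
            mlfac = fac * pp * math.exp(-(ml_a + ml_b + tau[i, j]) / rt) * eb_closing
            for k in range(i + 1, j - 1):
                for l in range(k + 1, j):
                    if qb[k, l] <= 0.0:
                        continue
                    uleft = cc ** (k - i - 1)
                    uright = cc ** (j - 1 - l)
                    fill = 0.0
                    qmr = qm[l + 1, j - 1] if l + 1 <= j - 1 else 0.0
                    qml = qm[i + 1, k - 1] if i + 1 <= k - 1 else 0.0
                    fill += uleft * qmr
                    fill += qml * uright
                    fill += qml * qmr
                    if fill > 0.0:
                        pr[k, l] += (mlfac * math.exp(-(ml_b + tau[k, l]) / rt)
                                     * qb[k, l] * fill)

    # symmetrize and clip tiny numerical negatives
    for i in range(n):
        for j in range(i + 1, n):
            v = pr[i, j]
            if v < 0.0:
                v = 0.0
            if v > 1.0:
                v = 1.0
            pr[i, j] = v
            pr[j, i] = v
    return logq, pr


@njit(cache=True)
def mea_matrix(n, pairprob, unpaired, gamma, min_hairpin):
    """Maximum-expected-accuracy structure: maximize
    sum(2*gamma*p_ij over pairs) + sum(p_unpaired over unpaired positions).

    At gamma = 1 the optimum minimizes the ensemble defect over all
    pseudoknot-free structures in the pairing space.  Deterministic
    tie-breaking: pairing candidates (ascending partner) beat leaving i
    unpaired only on strict improvement, mirroring the MFE convention of
    preferring the first-evaluated case.
    """
    F = np.zeros((n + 1, n + 1))
    for i in range(n):
        F[i, i] = unpaired[i]
    ch = np.full((n, n), -2, dtype=np.int64)  # -2: i unpaired; k: i pairs k
    for d in range(1, n):
        for i in range(n - d):
            j = i + d
            best = -1.0
            bk = -2
            for k in range(i + min_hairpin + 1, j + 1):
                if pairprob[i, k] > 0.0:
                    inner = F[i + 1, k - 1] if k - 1 >= i + 1 else 0.0
                    outer = F[k + 1, j] if k + 1 <= j else 0.0
                    cand = 2.0 * gamma * pairprob[i, k] + inner + outer
                    if cand > best:
                        best = cand
                        bk = k
            cand = unpaired[i] + F[i + 1, j]
            if cand > best:
                best = cand
                bk = -2
            F[i, j] = best
            ch[i, j] = bk
    # traceback
    pairs = np.full(n, -1, dtype=np.int64)
    stack_t = np.zeros((2 * n + 4, 2), dtype=np.int64)
    top = 0
    if n > 1:
        stack_t[top, 0] = 0
        stack_t[top, 1] = n - 1
        top += 1
    while top > 0:
        top -= 1
        i, j = stack_t[top, 0], stack_t[top, 1]
        if i >= j:
            continue
        k = ch[i, j]
        if k == -2:
            stack_t[top, 0] = i + 1
            stack_t[top, 1] = j
            top += 1
        else:
            pairs[i] = k
            pairs[k] = i
            if k - 1 > i + 1:
                stack_t[top, 0] = i + 1
                stack_t[top, 1] = k - 1
                top += 1
            if k + 1 < j:
                stack_t[top, 0] = k + 1
                stack_t[top, 1] = j
                top += 1
    return pairs
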