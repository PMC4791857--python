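"""Independent brute-force oracle for the multistate likelihood.

Enumerates every hidden state sequence (S live strata plus the dead state)
compatible with an encounter history and sums the path probabilities.  Kept
deliberately loop-based and index-naive so it shares no code with the
vectorised forward-pass implementation it cross-checks.
"""

import itertools

DEAD = -1


def history_probability(codes, phi, p, psi):
    """P(history | first release) by exhaustive enumeration.

    codes: per-occasion observation (0 unseen, else 1-based stratum).
    phi[t][s]: survival over interval t for a bird in stratum s.
    p[t][s]: detection at occasion t+1 in stratum s.
    psi[t][r][s]: movement r -> s over interval t (rows sum to 1).
    """
    T = len(codes)
    S = len(psi[0])
    release = next(t for t, c in enumerate(codes) if c > 0)
    start = codes[release] - 1
    total = 0.0
    n_steps = T - 1 - release
    for path in itertools.product(list(range(S)) + [DEAD], repeat=n_steps):
        prob = 1.0
        state = start
        ok = True
        for j, nxt in enumerate(path):
            t = release + j
            if state == DEAD:
                if nxt != DEAD or codes[t + 1] != 0:
                    ok = False
                    break
                continue
            if nxt == DEAD:
                prob *= 1.0 - phi[t][state]
                if codes[t + 1] != 0:
                    ok = False
                    break
            else:
                prob *= phi[t][state] * psi[t][state][nxt]
                c = codes[t + 1]
                if c > 0:
                    if c - 1 != nxt:
                        ok = False
                        break
                    prob *= p[t][nxt]
                else:
                    prob *= 1.0 - p[t][nxt]
            state = nxt
        if ok:
            total += prob
    return total
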