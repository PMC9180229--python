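"""Numba inner loops for the Metropolis-Hastings dyad-toggle chain.

All state-dependent structure in the supported term family reduces to the
reciprocal tie, so the log-odds of a toggle split into a precomputed static
part ``D[i, j]`` (every term except ``mutual``) plus ``theta_mutual * y_ji``.
The full change-statistic vector is only materialized when a toggle is
accepted, to update the running statistics vector ``z`` in place.

The uniform-proposal and sparse-dyad (TNT) variants are compiled separately
with the proposal mode as a closure constant; the TNT bookkeeping arrays are
dummies in the uniform variant.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def delta_stats(A, attrs, terms, i, j, out):
    """Change statistics of dyad (i, j) given the rest of A, written to out."""
    for t in range(terms.shape[0]):
        k = terms[t, 0]
        if k == 0:  # edges
            v = 1.0
        elif k == 1:  # mutual
            v = 1.0 if A[j, i] else 0.0
        else:
            a = terms[t, 1]
            p = terms[t, 2]
            q = terms[t, 3]
            if k == 2:  # nodematch
                v = 1.0 if attrs[i, a] == attrs[j, a] else 0.0
            elif k == 3:  # nodematch_level
                v = 1.0 if (attrs[i, a] == p and attrs[j, a] == p) else 0.0
            elif k == 4:  # nodeifactor (receiver)
                v = 1.0 if attrs[j, a] == p else 0.0
            else:  # nodemix
                v = 1.0 if (attrs[i, a] == p and attrs[j, a] == q) else 0.0
        out[t] = v


def _build(tnt):
    """Compile the chain kernels with the proposal mode baked in."""

    @njit(cache=True, fastmath=True)
    def step(A, z, attrs, terms, D, tmut, has_mutual, delta, ei, ej, pos, ne):
        n = A.shape[0]
        nd = n * (n - 1)
        if tnt and ne > 0 and np.random.random() < 0.5:
            e = np.random.randint(ne)
            i = ei[e]
            j = ej[e]
        else:
            i = np.random.randint(n)
            j = np.random.randint(n - 1)
            if j >= i:
                j += 1
        y = A[i, j]
        s = D[i, j]
        if has_mutual and A[j, i]:
            s += tmut
        if y:
            s = -s
        if tnt:
            # Hastings correction: selection probability of this ordered pair
            if y:  # delete (ne >= 1 here)
                qf = 0.5 / nd + 0.5 / ne
                qr = (0.5 / nd) if ne > 1 else (1.0 / nd)
            else:  # add
                qf = (0.5 / nd) if ne > 0 else (1.0 / nd)
                qr = 0.5 / nd + 0.5 / (ne + 1)
            s += np.log(qr / qf)
        if s >= 0.0 or np.random.random() < np.exp(s):
            delta_stats(A, attrs, terms, i, j, delta)
            if y:
                A[i, j] = 0
                for t in range(z.shape[0]):
                    z[t] -= delta[t]
                if tnt:
                    e = pos[i, j]
                    last = ne - 1
                    ei[e] = ei[last]
                    ej[e] = ej[last]
                    pos[ei[e], ej[e]] = e
                    pos[i, j] = -1
                    ne = last
            else:
                A[i, j] = 1
                for t in range(z.shape[0]):
                    z[t] += delta[t]
                if tnt:
                    if ne >= ei.shape[0]:
                        raise ValueError("TNT edge-list capacity exceeded")
                    ei[ne] = i
                    ej[ne] = j
                    pos[i, j] = ne
                    ne += 1
        return ne

    @njit(cache=True, fastmath=True)
    def advance(A, z, attrs, terms, D, tmut, has_mutual, n_props, seed, ei, ej, pos, ne):
        np.random.seed(seed)
        delta = np.empty(z.shape[0])
        for _ in range(n_props):
            ne = step(A, z, attrs, terms, D, tmut, has_mutual, delta, ei, ej, pos, ne)
        return ne

    @njit(cache=True, fastmath=True)
    def stats(
        A, z, attrs, terms, D, tmut, has_mutual, interval, n_draws, seed, ei, ej, pos, ne
    ):
        np.random.seed(seed)
        k = z.shape[0]
        delta = np.empty(k)
        out = np.empty((n_draws, k))
        for d in range(n_draws):
            for _ in range(interval):
                ne = step(A, z, attrs, terms, D, tmut, has_mutual, delta, ei, ej, pos, ne)
            for t in range(k):
                out[d, t] = z[t]
        return out, ne

    @njit(cache=True, fastmath=True)
    def codes(
        A, z, attrs, terms, D, tmut, has_mutual, interval, n_draws, seed, ei, ej, pos, ne,
        dyads,
    ):
        np.random.seed(seed)
        delta = np.empty(z.shape[0])
        out = np.empty(n_draws, dtype=np.int64)
        for d in range(n_draws):
            for _ in range(interval):
                ne = step(A, z, attrs, terms, D, tmut, has_mutual, delta, ei, ej, pos, ne)
            code = 0
            for b in range(dyads.shape[0]):
                if A[dyads[b, 0], dyads[b, 1]]:
                    code |= 1 << b
            out[d] = code
        return out, ne

    return advance, stats, codes


mh_advance_uniform, mh_stats_uniform, mh_codes_uniform = _build(False)
mh_advance_tnt, mh_stats_tnt, mh_codes_tnt = _build(True)
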