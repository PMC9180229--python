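"""Independent test oracles, kept deliberately naive.

``brute_force_statistics`` recounts every term with an explicit double loop
over ordered pairs.  ``dyad_mle`` exploits the fact that the supported term
family is dyad-separable (the reciprocal tie is the only state-dependent
configuration), so the exact likelihood factorizes over unordered pairs
into four-state multinomials and the exact MLE is computable at any n —
completely independently of the package's estimators.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from adocnet.terms import _ATTR_INDEX


def _edge_value(term, X, i, j):
    if term.kind == "edges":
        return 1
    a = _ATTR_INDEX[term.attribute]
    if term.kind == "nodematch":
        return int(X[i, a] == X[j, a])
    if term.kind == "nodematch_level":
        return int(X[i, a] == term.level and X[j, a] == term.level)
    if term.kind == "nodeifactor":
        return int(X[j, a] == term.level)
    if term.kind == "nodemix":
        return int(X[i, a] == term.level and X[j, a] == term.level2)
    raise AssertionError(term.kind)


def brute_force_statistics(network, attrs, spec):
    A = network.adjacency()
    X = attrs.matrix(network.node_ids)
    n = network.n_nodes
    out = np.zeros(len(spec))
    for k, term in enumerate(spec.terms):
        c = 0
        for i in range(n):
            for j in range(n):
                if i == j or not A[i, j]:
                    continue
                if term.kind == "mutual":
                    c += int(A[j, i])
                else:
                    c += _edge_value(term, X, i, j)
        out[k] = c / 2 if term.kind == "mutual" else c
    return out


def _dyad_design(network, attrs, spec):
    """Static per-direction designs X_ij, X_ji for all unordered pairs."""
    X = attrs.matrix(network.node_ids)
    n = network.n_nodes
    k = len(spec)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    F = np.zeros((len(pairs), k))  # i -> j direction
    B = np.zeros((len(pairs), k))  # j -> i direction
    for t, term in enumerate(spec.terms):
        if term.kind == "mutual":
            continue
        for p, (i, j) in enumerate(pairs):
            F[p, t] = _edge_value(term, X, i, j)
            B[p, t] = _edge_value(term, X, j, i)
    mutual_col = spec.index("mutual") if spec.has("mutual") else None
    em = np.zeros(k)
    if mutual_col is not None:
        em[mutual_col] = 1.0
    A = network.adjacency()
    state = np.array([2 * int(A[i, j]) + int(A[j, i]) for i, j in pairs])
    return F, B, em, state


def dyad_mle(network, attrs, spec):
    """Exact MLE via the dyad-factorized likelihood (any n)."""
    F, B, em, state = _dyad_design(network, attrs, spec)
    zeros = np.zeros(F.shape[0])

    def neg_loglik_grad(theta):
        # state exponents per pair: 00, 01 (j->i only), 10 (i->j only), 11
        e01 = B @ theta
        e10 = F @ theta
        e11 = (F + B + em) @ theta
        E = np.stack([zeros, e01, e10, e11], axis=1)
        lse = logsumexp(E, axis=1)
        chosen = np.choose(state, [zeros, e01, e10, e11])
        ll = float(np.sum(chosen - lse))
        P = np.exp(E - lse[:, None])
        # gradient: observed minus expected design per pair
        D = np.stack([np.zeros_like(F), B, F, F + B + em[None, :]], axis=1)
        obs = D[np.arange(len(state)), state]
        exp_d = np.einsum("ps,psk->pk", P, D)
        g = (obs - exp_d).sum(axis=0)
        return -ll, -g

    x0 = np.zeros(len(spec))
    res = minimize(neg_loglik_grad, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10})
    assert res.success, res.message
    return res.x
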