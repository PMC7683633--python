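"""Independent brute-force oracles used by the model tests."""

import itertools

import numpy as np
from scipy.special import gammaln


def exact_posterior(pairs, W, K, alpha, beta):
    """Exact collapsed posterior over all K^|B| topic assignments.

    Returns the per-biterm topic marginals and the pairwise co-assignment
    probabilities P(z_b = z_c), computed by enumeration of the collapsed
    joint (Dirichlet-multinomial in both the topic and the event counts).
    """

    def joint_log(z):
        n_k = np.zeros(K)
        n_ek = np.zeros((K, W))
        for b, (i, j) in enumerate(pairs):
            n_k[z[b]] += 1
            n_ek[z[b], i] += 1
            n_ek[z[b], j] += 1
        lp = gammaln(n_k + alpha).sum()
        for k in range(K):
            lp += gammaln(W * beta) - gammaln(n_ek[k].sum() + W * beta)
            lp += (gammaln(n_ek[k] + beta) - gammaln(beta)).sum()
        return lp

    assignments = list(itertools.product(range(K), repeat=len(pairs)))
    logp = np.array([joint_log(z) for z in assignments])
    p = np.exp(logp - logp.max())
    p /= p.sum()
    n_b = len(pairs)
    marg = np.zeros((n_b, K))
    co = np.zeros((n_b, n_b))
    for z, pz in zip(assignments, p):
        for b in range(n_b):
            marg[b, z[b]] += pz
            for c in range(n_b):
                if z[b] == z[c]:
                    co[b, c] += pz
    return marg, co
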