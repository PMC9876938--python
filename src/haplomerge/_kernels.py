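"""Numba forward-backward kernels for the haplotype-copying HMM.

States are conditioning haplotypes; transitions between adjacent sites follow
the usual copying model (switch to a specific other haplotype with
probability r/K, stay otherwise), and emissions allow a symmetric per-allele
copying error. Forward values are rescaled per site; no log-space is needed
at the error rates used.
"""
from __future__ import annotations

import numpy as np
from numba import njit

MISSING = -1


@njit(cache=True)
def _emission_diploid(g, pj, pk):
    """P(observed genotype g | alt-emission probs of the two copied alleles)."""
    if g == 0:
        return (1.0 - pj) * (1.0 - pk)
    if g == 1:
        return pj * (1.0 - pk) + (1.0 - pj) * pk
    if g == 2:
        return pj * pk
    return 1.0  # missing


@njit(cache=True)
def diploid_fb_posterior(geno, pm, rec):
    """Plain forward-backward genotype posterior, (S, 3).

    The emitted-genotype posterior given the copying states; observed sites
    keep their (error-model) emission distribution under the state posterior.
    Label-symmetric by construction — suitable for imputation posteriors and
    oracle comparisons, not for phase orientation.
    """
    K, S = pm.shape
    alpha = np.empty((S, K, K))
    work = np.empty((K, K))

    for j in range(K):
        pj = pm[j, 0]
        for k in range(K):
            alpha[0, j, k] = _emission_diploid(geno[0], pj, pm[k, 0]) / (K * K)
    c = alpha[0].sum()
    if c <= 0.0:
        c = 1e-300
    alpha[0] /= c

    for s in range(1, S):
        r = rec[s]
        stay = 1.0 - r
        move = r / K
        for k in range(K):
            col = 0.0
            for j in range(K):
                col += alpha[s - 1, j, k]
            for j in range(K):
                work[j, k] = stay * alpha[s - 1, j, k] + move * col
        for j in range(K):
            row = 0.0
            for k in range(K):
                row += work[j, k]
            pj = pm[j, s]
            for k in range(K):
                pred = stay * work[j, k] + move * row
                alpha[s, j, k] = pred * _emission_diploid(geno[s], pj, pm[k, s])
        c = alpha[s].sum()
        if c <= 0.0:
            c = 1e-300
        alpha[s] /= c

    post = np.empty((S, 3))
    beta = np.ones((K, K))
    tmp = np.empty((K, K))
    for s in range(S - 1, -1, -1):
        tot = 0.0
        q0 = q1 = q3 = 0.0
        for j in range(K):
            pj = pm[j, s]
            for k in range(K):
                g = alpha[s, j, k] * beta[j, k]
                pk = pm[k, s]
                tot += g
                q0 += g * (1.0 - pj) * (1.0 - pk)
                q1 += g * (pj * (1.0 - pk) + (1.0 - pj) * pk)
                q3 += g * pj * pk
        if tot <= 0.0:
            tot = 1e-300
        post[s, 0], post[s, 1], post[s, 2] = q0 / tot, q1 / tot, q3 / tot
        if s > 0:
            r = rec[s]
            stay = 1.0 - r
            move = r / K
            for j in range(K):
                pj = pm[j, s]
                for k in range(K):
                    tmp[j, k] = beta[j, k] * _emission_diploid(geno[s], pj, pm[k, s])
            for k in range(K):
                col = 0.0
                for j in range(K):
                    col += tmp[j, k]
                for j in range(K):
                    work[j, k] = stay * tmp[j, k] + move * col
            norm = 0.0
            for j in range(K):
                row = 0.0
                for k in range(K):
                    row += work[j, k]
                for k in range(K):
                    beta[j, k] = stay * work[j, k] + move * row
                    norm += beta[j, k]
            if norm <= 0.0:
                norm = 1e-300
            for j in range(K):
                for k in range(K):
                    beta[j, k] /= norm
    return post


@njit(cache=True)
def diploid_phase_sample(geno, pm, rec):
    """Sequentially decode one diploid sample against K conditioning haplotypes.

    The diploid copying HMM is label-symmetric under genotype emissions, so
    per-site marginals cannot orient the phase. Decoding therefore runs in
    two passes: a backward pass stores the future-evidence table beta(s, j, k)
    = P(genotypes after s | states at s) under symmetric emissions (exact,
    since future genotypes carry no orientation information), and a forward
    walk then picks each heterozygous site's orientation by its posterior
    given all previous *chosen* orientations and all genotype data, folding
    the chosen ordered emission into the running forward vector.

    Parameters
    ----------
    geno : (S,) int8 genotypes in {0,1,2,-1}
    pm   : (K,S) float64, P(emit alt | copying haplotype k) per site
    rec  : (S,) float64 switch probability of the interval ending at each
           site (rec[0] ignored)

    Returns
    -------
    h1, h2 : (S,) uint8 phased haplotypes (sum to genotype where observed)
    cert   : (S,) float64 orientation/fill certainty
    post   : (S,3) float64 sequential posterior of the emitted genotype
             (used to fill missing sites)
    """
    K, S = pm.shape
    beta = np.empty((S, K, K))
    work = np.empty((K, K))
    tmp = np.empty((K, K))

    # backward pass: beta[s] = P(g_{s+1:} | states at s), rescaled per site
    for j in range(K):
        for k in range(K):
            beta[S - 1, j, k] = 1.0
    for s in range(S - 1, 0, -1):
        r = rec[s]
        stay = 1.0 - r
        move = r / K
        for j in range(K):
            pj = pm[j, s]
            for k in range(K):
                tmp[j, k] = beta[s, j, k] * _emission_diploid(geno[s], pj, pm[k, s])
        for k in range(K):
            col = 0.0
            for j in range(K):
                col += tmp[j, k]
            for j in range(K):
                work[j, k] = stay * tmp[j, k] + move * col
        norm = 0.0
        for j in range(K):
            row = 0.0
            for k in range(K):
                row += work[j, k]
            for k in range(K):
                beta[s - 1, j, k] = stay * work[j, k] + move * row
                norm += beta[s - 1, j, k]
        if norm <= 0.0:
            norm = 1e-300
        for j in range(K):
            for k in range(K):
                beta[s - 1, j, k] /= norm

    # forward sequential decode
    h1 = np.zeros(S, dtype=np.uint8)
    h2 = np.zeros(S, dtype=np.uint8)
    cert = np.ones(S)
    post = np.empty((S, 3))
    a = np.empty((K, K))       # running forward vector (pre-emission at s)
    for j in range(K):
        for k in range(K):
            a[j, k] = 1.0 / (K * K)

    for s in range(S):
        if s > 0:
            r = rec[s]
            stay = 1.0 - r
            move = r / K
            for k in range(K):
                col = 0.0
                for j in range(K):
                    col += a[j, k]
                for j in range(K):
                    work[j, k] = stay * a[j, k] + move * col
            for j in range(K):
                row = 0.0
                for k in range(K):
                    row += work[j, k]
                for k in range(K):
                    a[j, k] = stay * work[j, k] + move * row

        # orientation-resolved posterior masses at s given past + future
        q0 = q1 = q2 = q3 = 0.0
        for j in range(K):
            pj = pm[j, s]
            for k in range(K):
                w = a[j, k] * beta[s, j, k]
                pk = pm[k, s]
                q0 += w * (1.0 - pj) * (1.0 - pk)
                q1 += w * pj * (1.0 - pk)
                q2 += w * (1.0 - pj) * pk
                q3 += w * pj * pk
        tot = q0 + q1 + q2 + q3
        if tot <= 0.0:
            tot = 1e-300
        post[s, 0] = q0 / tot
        post[s, 1] = (q1 + q2) / tot
        post[s, 2] = q3 / tot

        # choose the emission (and with it the phase) at s
        gg = geno[s]
        if gg == 0:
            h1[s] = 0
            h2[s] = 0
            cert[s] = 1.0
        elif gg == 2:
            h1[s] = 1
            h2[s] = 1
            cert[s] = 1.0
        elif gg == 1:
            den = q1 + q2
            if q1 >= q2:
                h1[s] = 1
                h2[s] = 0
                cert[s] = q1 / den if den > 0 else 0.5
            else:
                h1[s] = 0
                h2[s] = 1
                cert[s] = q2 / den if den > 0 else 0.5
        else:  # missing: fill with the sequential posterior mode
            p0, p1, p2 = post[s, 0], post[s, 1], post[s, 2]
            if p0 >= p1 and p0 >= p2:
                h1[s] = 0
                h2[s] = 0
                cert[s] = p0
            elif p2 >= p1:
                h1[s] = 1
                h2[s] = 1
                cert[s] = p2
            else:
                if q1 >= q2:
                    h1[s] = 1
                    h2[s] = 0
                else:
                    h1[s] = 0
                    h2[s] = 1
                cert[s] = p1

        # fold the chosen ordered emission into the forward vector; missing
        # sites fold nothing so a guessed fill cannot bias the decode
        if gg != MISSING:
            norm = 0.0
            x1 = h1[s]
            x2 = h2[s]
            for j in range(K):
                pj = pm[j, s] if x1 == 1 else 1.0 - pm[j, s]
                for k in range(K):
                    pk = pm[k, s] if x2 == 1 else 1.0 - pm[k, s]
                    a[j, k] *= pj * pk
                    norm += a[j, k]
            if norm <= 0.0:
                norm = 1e-300
            for j in range(K):
                for k in range(K):
                    a[j, k] /= norm

    return h1, h2, cert, post


@njit(cache=True)
def haploid_posterior_alt(obs, pm, rec):
    """Forward-backward alt-allele posterior for one haplotype.

    obs : (S,) int8 observed allele per site (-1 = unobserved)
    pm  : (K,S) float64 alt-emission probability per conditioning haplotype
    rec : (S,) switch probability per interval (rec[0] ignored)

    Returns (S,) posterior probability that the emitted allele is alt.
    """
    K, S = pm.shape
    alpha = np.empty((S, K))
    for k in range(K):
        e = 1.0
        if obs[0] == 1:
            e = pm[k, 0]
        elif obs[0] == 0:
            e = 1.0 - pm[k, 0]
        alpha[0, k] = e / K
    c = alpha[0].sum()
    if c <= 0.0:
        c = 1e-300
    alpha[0] /= c

    for s in range(1, S):
        r = rec[s]
        stay = 1.0 - r
        move = r / K
        tot = alpha[s - 1].sum()
        for k in range(K):
            e = 1.0
            if obs[s] == 1:
                e = pm[k, s]
            elif obs[s] == 0:
                e = 1.0 - pm[k, s]
            alpha[s, k] = (stay * alpha[s - 1, k] + move * tot) * e
        c = alpha[s].sum()
        if c <= 0.0:
            c = 1e-300
        alpha[s] /= c

    p_alt = np.empty(S)
    beta = np.ones(K)
    tmp = np.empty(K)
    for s in range(S - 1, -1, -1):
        tot = 0.0
        num = 0.0
        for k in range(K):
            g = alpha[s, k] * beta[k]
            tot += g
            num += g * pm[k, s]
        if tot <= 0.0:
            tot = 1e-300
        p_alt[s] = num / tot
        if s > 0:
            r = rec[s]
            stay = 1.0 - r
            move = r / K
            acc = 0.0
            for k in range(K):
                e = 1.0
                if obs[s] == 1:
                    e = pm[k, s]
                elif obs[s] == 0:
                    e = 1.0 - pm[k, s]
                tmp[k] = beta[k] * e
                acc += tmp[k]
            norm = 0.0
            for k in range(K):
                beta[k] = stay * tmp[k] + (r / K) * acc
                norm += beta[k]
            if norm <= 0.0:
                norm = 1e-300
            for k in range(K):
                beta[k] /= norm
    return p_alt
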