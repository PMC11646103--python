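"""Compiled Gibbs-sampler kernel.

Everything here operates on integer-encoded colonies: alleles are 0..k-1 per
locus, unordered diploid genotypes are triangular indices (see
``error_model.genotype_pairs``), missing observations are -1. Arrays are
padded to the widest locus; padded allele slots carry frequency 0 and so
never contribute to sums.

The chain state is (partition z with per-group mother flags, latent queen and
drifter true genotypes per locus, error rates e1/e2). One sweep = a
restricted-CRP Gibbs pass over offspring assignments, an exact full-
conditional draw of each mother's latent genotype per locus, and a
Metropolis logit random-walk update of each error rate (step size adapted
during burn-in toward 20-50% acceptance).
"""

import math

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=True, inline="always")
def _pidx(a, b, k):
    if a > b:
        a, b = b, a
    return a * k - (a * (a - 1)) // 2 + (b - a)


@njit(cache=True, inline="always")
def _mis(u, v, e2, k):
    if u == v:
        return 1.0 - e2
    return e2 / (k - 1)


@njit(cache=True, inline="always")
def _stage(c, d, x, y, e2, k):
    # P(intermediate ordered (c,d) scored as unordered (x,y)), x <= y
    if x == y:
        return _mis(c, x, e2, k) * _mis(d, x, e2, k)
    return (_mis(c, x, e2, k) * _mis(d, y, e2, k)
            + _mis(c, y, e2, k) * _mis(d, x, e2, k))


@njit(cache=True)
def _fill_obs_matrices(e1, e2, kvec, nG, ga, gb, OM):
    L = kvec.shape[0]
    for l in range(L):
        k = kvec[l]
        for t in range(nG[l]):
            a = ga[l, t]
            b = gb[l, t]
            for o in range(nG[l]):
                x = ga[l, o]
                y = gb[l, o]
                if a == b:
                    tot = _stage(a, b, x, y, e2, k)
                else:
                    tot = ((1.0 - e1) * _stage(a, b, x, y, e2, k)
                           + 0.5 * e1 * _stage(a, a, x, y, e2, k)
                           + 0.5 * e1 * _stage(b, b, x, y, e2, k))
                OM[l, t, o] = tot


@njit(cache=True)
def _fill_W(W, obs, gm_row, OM, kvec, ga, gb, Kmax):
    # W[i, l, a] = P(obs_il | mother genotype gm_row[l], father allele a)
    n, L = obs.shape
    for l in range(L):
        k = kvec[l]
        m1 = ga[l, gm_row[l]]
        m2 = gb[l, gm_row[l]]
        for i in range(n):
            o = obs[i, l]
            for a in range(Kmax):
                if o < 0 or a >= k:
                    W[i, l, a] = 1.0
                else:
                    W[i, l, a] = 0.5 * (OM[l, _pidx(m1, a, k), o]
                                        + OM[l, _pidx(m2, a, k), o])


@njit(cache=True)
def _fill_W_locus(W, obs, gml, OM, l, k, ga, gb, Kmax):
    n = obs.shape[0]
    m1 = ga[l, gml]
    m2 = gb[l, gml]
    for i in range(n):
        o = obs[i, l]
        for a in range(Kmax):
            if o < 0 or a >= k:
                W[i, l, a] = 1.0
            else:
                W[i, l, a] = 0.5 * (OM[l, _pidx(m1, a, k), o]
                                    + OM[l, _pidx(m2, a, k), o])


@njit(cache=True)
def _rates_loglik(OM, Wq, Wd, z, gmom, G, qobs, gm, p, kvec,
                  queen_obs_err, Pg):
    """Rate-dependent part of the log joint: queen observation term plus all
    group marginal likelihoods, conditional on partition and latent
    genotypes. Pg is a (maxG, L, Kmax) scratch buffer."""
    n = z.shape[0]
    L = kvec.shape[0]
    Kmax = p.shape[1]
    ll = 0.0
    if queen_obs_err == 1:
        for l in range(L):
            if qobs[l] >= 0:
                v = OM[l, gm[0, l], qobs[l]]
                if v <= 0.0:
                    return NEG_INF
                ll += math.log(v)
    for g in range(G):
        for l in range(L):
            for a in range(Kmax):
                Pg[g, l, a] = 1.0
    for j in range(n):
        g = z[j]
        if gmom[g] == 0:
            for l in range(L):
                for a in range(Kmax):
                    Pg[g, l, a] *= Wq[j, l, a]
        else:
            for l in range(L):
                for a in range(Kmax):
                    Pg[g, l, a] *= Wd[j, l, a]
    for g in range(G):
        for l in range(L):
            s = 0.0
            for a in range(kvec[l]):
                s += p[l, a] * Pg[g, l, a]
            if s <= 0.0:
                return NEG_INF
            ll += math.log(s)
    return ll


@njit(cache=True)
def _update_partition(z, gmom, size, G, obs, Wq, Wd, p, kvec,
                      alpha, dprior, Pg, logw):
    n = z.shape[0]
    L = kvec.shape[0]
    Kmax = p.shape[1]
    use_drifter = dprior > 0.0
    log_dp = math.log(dprior) if use_drifter else 0.0
    log_qp = math.log(1.0 - dprior) if use_drifter else 0.0
    for i in range(n):
        # detach offspring i
        g_old = z[i]
        size[g_old] -= 1
        if size[g_old] == 0:
            last = G - 1
            if g_old != last:
                for j in range(n):
                    if z[j] == last:
                        z[j] = g_old
                size[g_old] = size[last]
                gmom[g_old] = gmom[last]
            G -= 1
        z[i] = -1
        # per-group father-allele products without i
        for g in range(G):
            for l in range(L):
                for a in range(Kmax):
                    Pg[g, l, a] = 1.0
        for j in range(n):
            if j == i:
                continue
            g = z[j]
            if gmom[g] == 0:
                for l in range(L):
                    for a in range(Kmax):
                        Pg[g, l, a] *= Wq[j, l, a]
            else:
                for l in range(L):
                    for a in range(Kmax):
                        Pg[g, l, a] *= Wd[j, l, a]
        # candidate log-weights
        for g in range(G):
            Wi = Wq if gmom[g] == 0 else Wd
            s = math.log(float(size[g])) + (log_qp if gmom[g] == 0 else log_dp)
            for l in range(L):
                num = 0.0
                den = 0.0
                for a in range(kvec[l]):
                    v = Pg[g, l, a]
                    num += p[l, a] * v * Wi[i, l, a]
                    den += p[l, a] * v
                if num <= 0.0 or den <= 0.0:
                    s = NEG_INF
                    break
                s += math.log(num) - math.log(den)
            logw[g] = s
        s = math.log(alpha) + log_qp
        for l in range(L):
            num = 0.0
            for a in range(kvec[l]):
                num += p[l, a] * Wq[i, l, a]
            if num <= 0.0:
                s = NEG_INF
                break
            s += math.log(num)
        logw[G] = s
        ncand = G + 1
        if use_drifter:
            s = math.log(alpha) + log_dp
            for l in range(L):
                num = 0.0
                for a in range(kvec[l]):
                    num += p[l, a] * Wd[i, l, a]
                if num <= 0.0:
                    s = NEG_INF
                    break
                s += math.log(num)
            logw[G + 1] = s
            ncand = G + 2
        # sample
        mx = NEG_INF
        for c in range(ncand):
            if logw[c] > mx:
                mx = logw[c]
        choice = G  # fallback: fresh queen group
        if mx > NEG_INF:
            tot = 0.0
            for c in range(ncand):
                tot += math.exp(logw[c] - mx)
            u = np.random.random() * tot
            acc = 0.0
            for c in range(ncand):
                acc += math.exp(logw[c] - mx)
                if u <= acc:
                    choice = c
                    break
        if choice < G:
            z[i] = choice
            size[choice] += 1
        else:
            z[i] = G
            size[G] = 1
            gmom[G] = 0 if choice == G else 1
            G += 1
    return G


@njit(cache=True)
def _update_maternal(mother, gm, z, gmom, G, obs, qobs, OM, p, kvec, nG,
                     ga, gb, queen_obs_err, Wq, Wd, fa_prod, cand_lw):
    """Draw mother ``mother`` (0=queen, 1=drifter) latent genotype per locus
    from its exact full conditional, then refresh that mother's W rows."""
    n = z.shape[0]
    L = kvec.shape[0]
    for l in range(L):
        k = kvec[l]
        if mother == 0 and queen_obs_err == 0 and qobs[l] >= 0:
            if gm[0, l] != qobs[l]:
                gm[0, l] = qobs[l]
                _fill_W_locus(Wq, obs, qobs[l], OM, l, k, ga, gb, p.shape[1])
            continue
        ncand = nG[l]
        for cand in range(ncand):
            a = ga[l, cand]
            b = gb[l, cand]
            hwe = p[l, a] * p[l, b]
            if a != b:
                hwe *= 2.0
            lw = math.log(hwe) if hwe > 0.0 else NEG_INF
            if mother == 0 and queen_obs_err == 1 and qobs[l] >= 0:
                v = OM[l, cand, qobs[l]]
                lw = lw + math.log(v) if v > 0.0 else NEG_INF
            if lw > NEG_INF and G > 0:
                for g in range(G):
                    if gmom[g] != mother:
                        continue
                    for fa in range(k):
                        fa_prod[g, fa] = p[l, fa]
                for j in range(n):
                    g = z[j]
                    if gmom[g] != mother:
                        continue
                    o = obs[j, l]
                    if o < 0:
                        continue
                    for fa in range(k):
                        fa_prod[g, fa] *= 0.5 * (
                            OM[l, _pidx(a, fa, k), o]
                            + OM[l, _pidx(b, fa, k), o])
                for g in range(G):
                    if gmom[g] != mother:
                        continue
                    s = 0.0
                    for fa in range(k):
                        s += fa_prod[g, fa]
                    if s <= 0.0:
                        lw = NEG_INF
                        break
                    lw += math.log(s)
            cand_lw[cand] = lw
        mx = NEG_INF
        for cand in range(ncand):
            if cand_lw[cand] > mx:
                mx = cand_lw[cand]
        pick = gm[mother, l]
        if mx > NEG_INF:
            tot = 0.0
            for cand in range(ncand):
                tot += math.exp(cand_lw[cand] - mx)
            u = np.random.random() * tot
            acc = 0.0
            for cand in range(ncand):
                acc += math.exp(cand_lw[cand] - mx)
                if u <= acc:
                    pick = cand
                    break
        if pick != gm[mother, l]:
            gm[mother, l] = pick
            if mother == 0:
                _fill_W_locus(Wq, obs, pick, OM, l, k, ga, gb, p.shape[1])
            else:
                _fill_W_locus(Wd, obs, pick, OM, l, k, ga, gb, p.shape[1])


@njit(cache=True)
def _log_prior_state(z, gmom, size, G, gm, p, kvec, ga, gb, alpha, dprior):
    n = z.shape[0]
    L = kvec.shape[0]
    lp = G * math.log(alpha) + math.lgamma(alpha) - math.lgamma(alpha + n)
    for g in range(G):
        lp += math.lgamma(float(size[g]))
    if dprior > 0.0:
        nd = 0
        for i in range(n):
            if gmom[z[i]] == 1:
                nd += 1
        lp += nd * math.log(dprior) + (n - nd) * math.log(1.0 - dprior)
    n_mothers = 2 if dprior > 0.0 else 1
    for m in range(n_mothers):
        for l in range(L):
            a = ga[l, gm[m, l]]
            b = gb[l, gm[m, l]]
            hwe = p[l, a] * p[l, b]
            if a != b:
                hwe *= 2.0
            lp += math.log(hwe)
    return lp


@njit(cache=True)
def _run_chain(obs, qobs, kvec, nG, ga, gb, p,
               alpha, dprior, sweeps, burn_in, thin, seed,
               e1_init, e2_init, fix_rates, step_init, queen_obs_err):
    np.random.seed(seed)
    n, L = obs.shape
    Kmax = p.shape[1]
    Gmax = n + 2
    n_ret = (sweeps - burn_in) // thin

    # state
    z = np.zeros(n, dtype=np.int64)
    gmom = np.zeros(Gmax, dtype=np.int64)
    size = np.zeros(Gmax, dtype=np.int64)
    size[0] = n
    G = 1
    gm = np.zeros((2, L), dtype=np.int64)
    e1 = e1_init
    e2 = e2_init

    OM = np.zeros((L, ga.shape[1], ga.shape[1]))
    OM2 = np.zeros_like(OM)
    Wq = np.zeros((n, L, Kmax))
    Wd = np.zeros((n, L, Kmax))
    W2q = np.zeros((n, L, Kmax))
    W2d = np.zeros((n, L, Kmax))
    Pg = np.zeros((Gmax, L, Kmax))
    logw = np.zeros(Gmax + 2)
    fa_prod = np.zeros((Gmax, Kmax))
    cand_lw = np.zeros(ga.shape[1])

    _fill_obs_matrices(e1, e2, kvec, nG, ga, gb, OM)
    _fill_W(Wq, obs, gm[0], OM, kvec, ga, gb, Kmax)
    _fill_W(Wd, obs, gm[1], OM, kvec, ga, gb, Kmax)
    _update_maternal(0, gm, z, gmom, G, obs, qobs, OM, p, kvec, nG, ga, gb,
                     queen_obs_err, Wq, Wd, fa_prod, cand_lw)
    if dprior > 0.0:
        _update_maternal(1, gm, z, gmom, G, obs, qobs, OM, p, kvec, nG,
                         ga, gb, queen_obs_err, Wq, Wd, fa_prod, cand_lw)

    # outputs
    zs = np.zeros((n_ret, n), dtype=np.int64)
    moms = np.zeros((n_ret, n), dtype=np.int64)
    e1s = np.zeros(n_ret)
    e2s = np.zeros(n_ret)
    gmqs = np.zeros((n_ret, L), dtype=np.int64)
    ret_lp = np.zeros(n_ret)
    trace = np.zeros(sweeps)

    steps = np.full(2, step_init)
    acc_win = np.zeros(2)
    try_win = np.zeros(2)
    acc_tot = np.zeros(2)
    try_tot = np.zeros(2)
    relabel = np.zeros(Gmax, dtype=np.int64)
    ridx = 0

    for sweep in range(sweeps):
        G = _update_partition(z, gmom, size, G, obs, Wq, Wd, p, kvec,
                              alpha, dprior, Pg, logw)
        _update_maternal(0, gm, z, gmom, G, obs, qobs, OM, p, kvec, nG,
                         ga, gb, queen_obs_err, Wq, Wd, fa_prod, cand_lw)
        if dprior > 0.0:
            _update_maternal(1, gm, z, gmom, G, obs, qobs, OM, p, kvec, nG,
                             ga, gb, queen_obs_err, Wq, Wd, fa_prod, cand_lw)

        ll_cur = _rates_loglik(OM, Wq, Wd, z, gmom, G, qobs, gm, p, kvec,
                               queen_obs_err, Pg)
        if fix_rates == 0:
            for r in range(2):
                cur = e1 if r == 0 else e2
                t = math.log(cur / (0.5 - cur))
                t_new = t + steps[r] * np.random.standard_normal()
                new = 0.5 / (1.0 + math.exp(-t_new))
                ne1 = new if r == 0 else e1
                ne2 = new if r == 1 else e2
                _fill_obs_matrices(ne1, ne2, kvec, nG, ga, gb, OM2)
                _fill_W(W2q, obs, gm[0], OM2, kvec, ga, gb, Kmax)
                _fill_W(W2d, obs, gm[1], OM2, kvec, ga, gb, Kmax)
                ll_new = _rates_loglik(OM2, W2q, W2d, z, gmom, G, qobs, gm,
                                       p, kvec, queen_obs_err, Pg)
                # uniform prior on (0, 0.5); Jacobian of the logit transform
                log_ratio = (ll_new - ll_cur
                             + math.log(new * (0.5 - new))
                             - math.log(cur * (0.5 - cur)))
                try_win[r] += 1.0
                try_tot[r] += 1.0
                if ll_new > NEG_INF and math.log(np.random.random() + 1e-320) < log_ratio:
                    if r == 0:
                        e1 = new
                    else:
                        e2 = new
                    OM[:, :, :] = OM2
                    Wq[:, :, :] = W2q
                    Wd[:, :, :] = W2d
                    ll_cur = ll_new
                    acc_win[r] += 1.0
                    acc_tot[r] += 1.0
            if sweep < burn_in and (sweep + 1) % 50 == 0:
                for r in range(2):
                    if try_win[r] > 0:
                        rate = acc_win[r] / try_win[r]
                        if rate < 0.2:
                            steps[r] *= 0.7
                        elif rate > 0.5:
                            steps[r] *= 1.4
                    acc_win[r] = 0.0
                    try_win[r] = 0.0

        lp = ll_cur + _log_prior_state(z, gmom, size, G, gm, p, kvec,
                                       ga, gb, alpha, dprior)
        trace[sweep] = lp

        if sweep >= burn_in and (sweep - burn_in + 1) % thin == 0 and ridx < n_ret:
            for g in range(Gmax):
                relabel[g] = -1
            nxt = 0
            for i in range(n):
                if relabel[z[i]] < 0:
                    relabel[z[i]] = nxt
                    nxt += 1
                zs[ridx, i] = relabel[z[i]]
                moms[ridx, i] = gmom[z[i]]
            e1s[ridx] = e1
            e2s[ridx] = e2
            for l in range(L):
                gmqs[ridx, l] = gm[0, l]
            ret_lp[ridx] = lp
            ridx += 1

    acc_rate = np.zeros(2)
    for r in range(2):
        acc_rate[r] = acc_tot[r] / try_tot[r] if try_tot[r] > 0 else 0.0
    return zs, moms, e1s, e2s, gmqs, ret_lp, trace, acc_rate, steps
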