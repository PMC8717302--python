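"""Compiled MCMC chain kernel shared by the A00- and A10-style samplers.

The whole chain loop is one numba ``njit`` function operating on flattened
arrays (per-locus gene trees live in contiguous blocks addressed through
``node_off``).  Moves:

* per locus, an independence Metropolis–Hastings proposal that resimulates
  the genealogy from the censored coalescent at the current (tau, theta)
  (prior and proposal cancel, leaving the likelihood ratio), and a
  node-age window move (multiplicative above the root's lower bound);
* conjugate inverse-gamma Gibbs updates for every population theta
  (the coalescent density depends on theta only through the per-population
  sufficient statistics C_p, A_p);
* rubber-band tau updates (window within structural bounds, multiplicative
  at the root): gene-node ages in the three populations meeting at the
  moved node are rescaled piecewise-linearly with the matching Jacobian,
  so divergence times and genealogies move together;
* a global scale ("mixing") move multiplying all node ages and tau values;
* in A10 mode, reversible-jump split/merge moves toggling internal-node
  split flags under ancestry closure; a split proposes tau uniformly below
  the smallest cross-clade coalescence age (so the likelihood term is
  untouched and the move reduces to a coalescent-density and prior ratio).

Randomness comes from numba's internal MT19937 seeded once per chain, so a
chain is fully reproducible from its integer seed.
"""

import numpy as np
from numba import njit

from .likelihood import _coal_stats, _sp_mrca

# acceptance-counter slots
ACC_RESIM, ACC_AGE, ACC_TAU, ACC_MIX, ACC_RJ, N_ACC = 0, 1, 2, 3, 4, 5


@njit(cache=True)
def _fill_children_first(left, right, root, out):
    """Reverse preorder: every child precedes its parent; root is last."""
    n = out.shape[0]
    stack = np.empty(n, np.int64)
    top = 0
    stack[top] = root
    top += 1
    idx = n - 1
    while top > 0:
        top -= 1
        v = stack[top]
        out[idx] = v
        idx -= 1
        if left[v] >= 0:
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1


@njit(cache=True)
def _prune_flat(post, parent, left, right, age, codes, weights, partial):
    """JC69 pruning log-likelihood; ``codes`` rows cover tips only."""
    n_nodes = post.shape[0]
    n_pat = weights.shape[0]
    for i in range(n_nodes):
        v = post[i]
        if left[v] < 0:
            for p in range(n_pat):
                c = codes[v, p]
                for s in range(4):
                    partial[v, p, s] = 1.0 if (c == 4 or c == s) else 0.0
        else:
            for p in range(n_pat):
                for s in range(4):
                    partial[v, p, s] = 1.0
            for ci in range(2):
                ch = left[v] if ci == 0 else right[v]
                e = np.exp(-4.0 * (age[v] - age[ch]) / 3.0)
                for p in range(n_pat):
                    tot = (
                        partial[ch, p, 0]
                        + partial[ch, p, 1]
                        + partial[ch, p, 2]
                        + partial[ch, p, 3]
                    )
                    base = 0.25 * (1.0 - e) * tot
                    for s in range(4):
                        partial[v, p, s] *= base + e * partial[ch, p, s]
    root = post[n_nodes - 1]
    ll = 0.0
    for p in range(n_pat):
        site = 0.25 * (
            partial[root, p, 0]
            + partial[root, p, 1]
            + partial[root, p, 2]
            + partial[root, p, 3]
        )
        ll += weights[p] * np.log(site)
    return ll


@njit(cache=True)
def _resim_locus(
    n_tips, tip_sp, sp_order, sp_parent, sp_tau, sp_theta,
    pool, pool_n, p_age, p_parent, p_left, p_right,
):
    """Draw a genealogy from the censored coalescent into the p_* arrays."""
    n_pops = sp_parent.shape[0]
    for p in range(n_pops):
        pool_n[p] = 0
    for t in range(n_tips):
        s = tip_sp[t]
        pool[s, pool_n[s]] = t
        pool_n[s] += 1
        p_age[t] = 0.0
        p_parent[t] = -1
        p_left[t] = -1
        p_right[t] = -1
    nxt = n_tips
    for oi in range(n_pops):
        p = sp_order[oi]
        t_cur = sp_tau[p]
        par = sp_parent[p]
        t_end = sp_tau[par] if par >= 0 else np.inf
        th = sp_theta[p]
        k = pool_n[p]
        while k > 1:
            rate = k * (k - 1) / th
            w = -np.log(np.random.random()) / rate
            if t_cur + w >= t_end:
                break
            t_cur += w
            i = int(np.random.random() * k)
            j = int(np.random.random() * (k - 1))
            if j >= i:
                j += 1
            a = pool[p, i]
            b = pool[p, j]
            p_age[nxt] = t_cur
            p_left[nxt] = a
            p_right[nxt] = b
            p_parent[nxt] = -1
            p_parent[a] = nxt
            p_parent[b] = nxt
            pool[p, i] = nxt
            pool[p, j] = pool[p, k - 1]
            k -= 1
            nxt += 1
        if par >= 0:
            for x in range(k):
                pool[par, pool_n[par] + x] = pool[p, x]
            pool_n[par] += k
        pool_n[p] = k


@njit(cache=True)
def _node_species(post, left, right, tip_sp, sp_parent, sp_depth, node_sp):
    for i in range(post.shape[0]):
        v = post[i]
        if left[v] < 0:
            node_sp[v] = tip_sp[v]
        else:
            node_sp[v] = _sp_mrca(
                node_sp[left[v]], node_sp[right[v]], sp_parent, sp_depth
            )


@njit(cache=True)
def _locus_logdens(c_row, a_row, sp_theta):
    out = 0.0
    for p in range(sp_theta.shape[0]):
        if c_row[p] > 0:
            out += c_row[p] * np.log(2.0 / sp_theta[p])
        out -= a_row[p] / sp_theta[p]
    return out


@njit(cache=True)
def _logprior_tau(sp_parent, sp_left, sp_tau, split, a10, root, alpha, beta_tau):
    """Log prior density of the tau vector (up to constants).

    A00: inverse-gamma on the root, flat uniform-order-statistics below
    (density 1/tau_root per non-root internal).  A10: inverse-gamma on a
    split root, Uniform(0, tau_parent) for every other split node.
    """
    lp = 0.0
    n = sp_parent.shape[0]
    n_nonroot_internal = 0
    for v in range(n):
        if sp_left[v] < 0:
            continue
        if a10 == 1:
            if split[v] == 0:
                continue
            par = sp_parent[v]
            if par < 0:
                lp += -(alpha + 1.0) * np.log(sp_tau[v]) - beta_tau / sp_tau[v]
            else:
                lp += -np.log(sp_tau[par])
        else:
            par = sp_parent[v]
            if par < 0:
                lp += -(alpha + 1.0) * np.log(sp_tau[v]) - beta_tau / sp_tau[v]
            else:
                n_nonroot_internal += 1
    if a10 == 0 and n_nonroot_internal > 0:
        lp += -n_nonroot_internal * np.log(sp_tau[root])
    return lp


@njit(cache=True)
def _all_stats(
    n_loci, node_off, post_flat, g_left, g_right, g_age, tip_sp_flat,
    sp_parent, sp_depth, sp_tau, c_out, a_out,
):
    """Coalescent sufficient statistics for every locus; False if invalid."""
    for l in range(n_loci):
        s, e = node_off[l], node_off[l + 1]
        ok = _coal_stats(
            post_flat[s:e], g_left[s:e], g_right[s:e], g_age[s:e],
            tip_sp_flat[s:e], sp_parent, sp_depth, sp_tau,
            c_out[l], a_out[l],
        )
        if not ok:
            return False
    return True


@njit(cache=True)
def _min_cross_age(
    v_target, n_loci, node_off, post_flat, g_left, g_right, g_age,
    tip_sp_flat, sp_parent, sp_depth, node_sp_buf,
):
    """Smallest age of any coalescence joining the two clades under v_target."""
    m = np.inf
    for l in range(n_loci):
        s, e = node_off[l], node_off[l + 1]
        _node_species(
            post_flat[s:e], g_left[s:e], g_right[s:e], tip_sp_flat[s:e],
            sp_parent, sp_depth, node_sp_buf[s:e],
        )
        for v in range(e - s):
            if g_left[s + v] >= 0 and node_sp_buf[s + v] == v_target:
                if g_age[s + v] < m:
                    m = g_age[s + v]
    return m


@njit(cache=True)
def _run_chain(
    # species tree (state: sp_tau, sp_theta, split mutate in place)
    sp_parent, sp_left, sp_right, sp_depth, sp_order, sp_root, sp_desc,
    sp_tau, sp_theta, split,
    # flattened loci (state: g_age/g_parent/g_left/g_right/post_flat)
    n_loci, node_off, tip_counts, tip_sp_flat,
    g_age, g_parent, g_left, g_right, post_flat,
    code_off, codes_flat, pat_off, pat_counts, weights_flat,
    # run configuration
    n_iter, burnin, thin, seed,
    use_like, estimate_theta, a10,
    alpha, beta_theta, beta_tau, tau_prior_mean,
    lam_root_age, lam_root_tau, lam_mix, mix_every,
    # outputs
    out_tau, out_theta, out_ll, out_flags, acc, prop,
):
    np.random.seed(seed)
    n_pops = sp_parent.shape[0]
    n_internal_sp = (n_pops - 1) // 2
    max_nodes = 0
    max_tips = 0
    max_pat = 0
    for l in range(n_loci):
        nn = node_off[l + 1] - node_off[l]
        if nn > max_nodes:
            max_nodes = nn
        if tip_counts[l] > max_tips:
            max_tips = tip_counts[l]
        if pat_counts[l] > max_pat:
            max_pat = pat_counts[l]
    partial = np.empty((max_nodes, max_pat, 4))
    pool = np.empty((n_pops, 2 * max_tips), np.int64)
    pool_n = np.empty(n_pops, np.int64)
    p_age = np.empty(max_nodes)
    p_parent = np.empty(max_nodes, np.int64)
    p_left = np.empty(max_nodes, np.int64)
    p_right = np.empty(max_nodes, np.int64)
    p_post = np.empty(max_nodes, np.int64)
    node_sp = np.empty(max_nodes, np.int64)
    node_sp_flat = np.empty(node_off[n_loci], np.int64)
    g_age2 = np.empty(node_off[n_loci])
    c_loc = np.zeros((n_loci, n_pops), np.int64)
    a_loc = np.zeros((n_loci, n_pops))
    tmp_c = np.zeros((n_loci, n_pops), np.int64)
    tmp_a = np.zeros((n_loci, n_pops))
    row_c = np.zeros(n_pops, np.int64)
    row_a = np.zeros(n_pops)
    ll_loc = np.zeros(n_loci)
    new_ll = np.zeros(n_loci)

    # ---- initialization: genealogies from the coalescent at init params
    for l in range(n_loci):
        s, e = node_off[l], node_off[l + 1]
        nt = tip_counts[l]
        _resim_locus(
            nt, tip_sp_flat[s:e], sp_order, sp_parent, sp_tau, sp_theta,
            pool, pool_n, g_age[s:e], g_parent[s:e], g_left[s:e], g_right[s:e],
        )
        root_l = 0
        for v in range(e - s):
            if g_parent[s + v] < 0:
                root_l = v
        _fill_children_first(g_left[s:e], g_right[s:e], root_l, post_flat[s:e])
        _coal_stats(
            post_flat[s:e], g_left[s:e], g_right[s:e], g_age[s:e],
            tip_sp_flat[s:e], sp_parent, sp_depth, sp_tau, c_loc[l], a_loc[l],
        )
        if use_like == 1:
            cs, ce = code_off[l], code_off[l + 1]
            ps, pe = pat_off[l], pat_off[l + 1]
            codes = codes_flat[cs:ce].reshape(nt, pat_counts[l])
            ll_loc[l] = _prune_flat(
                post_flat[s:e], g_parent[s:e], g_left[s:e], g_right[s:e],
                g_age[s:e], codes, weights_flat[ps:pe], partial,
            )
    c_tot = np.zeros(n_pops)
    a_tot = np.zeros(n_pops)
    for l in range(n_loci):
        for p in range(n_pops):
            c_tot[p] += c_loc[l, p]
            a_tot[p] += a_loc[l, p]

    n_gene_internal = 0
    for l in range(n_loci):
        n_gene_internal += tip_counts[l] - 1

    sample_i = 0
    for it in range(n_iter):
        # ---------------- per-locus genealogy moves
        for l in range(n_loci):
            s, e = node_off[l], node_off[l + 1]
            nt = tip_counts[l]
            nn = e - s
            cs = code_off[l]
            ps, pe = pat_off[l], pat_off[l + 1]
            codes = codes_flat[cs : code_off[l + 1]].reshape(nt, pat_counts[l])
            weights = weights_flat[ps:pe]

            # (a) independence resimulation from the coalescent
            prop[ACC_RESIM] += 1
            _resim_locus(
                nt, tip_sp_flat[s:e], sp_order, sp_parent, sp_tau, sp_theta,
                pool, pool_n, p_age[:nn], p_parent[:nn], p_left[:nn], p_right[:nn],
            )
            root_l = 0
            for v in range(nn):
                if p_parent[v] < 0:
                    root_l = v
            _fill_children_first(p_left[:nn], p_right[:nn], root_l, p_post[:nn])
            if use_like == 1:
                llnew = _prune_flat(
                    p_post[:nn], p_parent[:nn], p_left[:nn], p_right[:nn],
                    p_age[:nn], codes, weights, partial,
                )
            else:
                llnew = 0.0
            if llnew - ll_loc[l] >= np.log(np.random.random()):
                acc[ACC_RESIM] += 1
                for v in range(nn):
                    g_age[s + v] = p_age[v]
                    g_parent[s + v] = p_parent[v]
                    g_left[s + v] = p_left[v]
                    g_right[s + v] = p_right[v]
                    post_flat[s + v] = p_post[v]
                for p in range(n_pops):
                    c_tot[p] -= c_loc[l, p]
                    a_tot[p] -= a_loc[l, p]
                _coal_stats(
                    post_flat[s:e], g_left[s:e], g_right[s:e], g_age[s:e],
                    tip_sp_flat[s:e], sp_parent, sp_depth, sp_tau,
                    c_loc[l], a_loc[l],
                )
                for p in range(n_pops):
                    c_tot[p] += c_loc[l, p]
                    a_tot[p] += a_loc[l, p]
                ll_loc[l] = llnew

            # (b) node-age window move
            if nt < 2:
                continue
            prop[ACC_AGE] += 1
            v = nt + int(np.random.random() * (nt - 1))
            _node_species(
                post_flat[s:e], g_left[s:e], g_right[s:e], tip_sp_flat[s:e],
                sp_parent, sp_depth, node_sp[:nn],
            )
            lb = sp_tau[node_sp[v]]
            cl = g_left[s + v]
            cr = g_right[s + v]
            if g_age[s + cl] > lb:
                lb = g_age[s + cl]
            if g_age[s + cr] > lb:
                lb = g_age[s + cr]
            par = g_parent[s + v]
            old_age = g_age[s + v]
            log_hast = 0.0
            if par >= 0:
                ub = g_age[s + par]
                new_age = lb + np.random.random() * (ub - lb)
            else:
                x = old_age - lb
                xn = x * np.exp(lam_root_age * (np.random.random() - 0.5))
                new_age = lb + xn
                log_hast = np.log(xn / x)
            g_age[s + v] = new_age
            ok = _coal_stats(
                post_flat[s:e], g_left[s:e], g_right[s:e], g_age[s:e],
                tip_sp_flat[s:e], sp_parent, sp_depth, sp_tau, row_c, row_a,
            )
            if ok:
                if use_like == 1:
                    llnew = _prune_flat(
                        post_flat[s:e], g_parent[s:e], g_left[s:e], g_right[s:e],
                        g_age[s:e], codes, weights, partial,
                    )
                else:
                    llnew = 0.0
                delta = (
                    llnew
                    - ll_loc[l]
                    + _locus_logdens(row_c, row_a, sp_theta)
                    - _locus_logdens(c_loc[l], a_loc[l], sp_theta)
                    + log_hast
                )
            else:
                delta = -np.inf
            if delta >= np.log(np.random.random()):
                acc[ACC_AGE] += 1
                for p in range(n_pops):
                    c_tot[p] += row_c[p] - c_loc[l, p]
                    a_tot[p] += row_a[p] - a_loc[l, p]
                    c_loc[l, p] = row_c[p]
                    a_loc[l, p] = row_a[p]
                ll_loc[l] = llnew
            else:
                g_age[s + v] = old_age

        # ---------------- conjugate theta Gibbs
        if estimate_theta == 1:
            for p in range(n_pops):
                shape = alpha + c_tot[p]
                scale = beta_theta + a_tot[p]
                sp_theta[p] = scale / np.random.gamma(shape, 1.0)

        # ---------------- rubber-band tau moves
        for v in range(n_pops):
            if sp_left[v] < 0:
                continue
            if a10 == 1 and split[v] == 0:
                continue
            prop[ACC_TAU] += 1
            t_lo = 0.0
            if sp_tau[sp_left[v]] > t_lo:
                t_lo = sp_tau[sp_left[v]]
            if sp_tau[sp_right[v]] > t_lo:
                t_lo = sp_tau[sp_right[v]]
            par = sp_parent[v]
            old_tau = sp_tau[v]
            lp_old = _logprior_tau(
                sp_parent, sp_left, sp_tau, split, a10, sp_root, alpha, beta_tau
            )
            log_hast = 0.0
            if par >= 0:
                t_up = sp_tau[par]
                new_tau = t_lo + np.random.random() * (t_up - t_lo)
            else:
                t_up = np.inf
                x = old_tau - t_lo
                xn = x * np.exp(lam_root_tau * (np.random.random() - 0.5))
                new_tau = t_lo + xn
                log_hast = np.log(xn / x)
            # piecewise-linear age transform within (t_lo, t_up) for gene
            # nodes whose descendant species all lie in the clade of v
            r_low = (new_tau - t_lo) / (old_tau - t_lo)
            r_up = (t_up - new_tau) / (t_up - old_tau) if par >= 0 else 1.0
            shift = new_tau - old_tau
            log_jac = 0.0
            for l in range(n_loci):
                s, e = node_off[l], node_off[l + 1]
                _node_species(
                    post_flat[s:e], g_left[s:e], g_right[s:e], tip_sp_flat[s:e],
                    sp_parent, sp_depth, node_sp_flat[s:e],
                )
                for u in range(e - s):
                    y = g_age[s + u]
                    g_age2[s + u] = y
                    if g_left[s + u] < 0:
                        continue
                    if sp_desc[node_sp_flat[s + u], v] == 1 and t_lo < y < t_up:
                        if y <= old_tau:
                            g_age2[s + u] = t_lo + (y - t_lo) * r_low
                            log_jac += np.log(r_low)
                        elif par >= 0:
                            g_age2[s + u] = t_up - (t_up - y) * r_up
                            log_jac += np.log(r_up)
                        else:
                            g_age2[s + u] = y + shift
            sp_tau[v] = new_tau
            ok = _all_stats(
                n_loci, node_off, post_flat, g_left, g_right, g_age2,
                tip_sp_flat, sp_parent, sp_depth, sp_tau, tmp_c, tmp_a,
            )
            if ok:
                lp_new = _logprior_tau(
                    sp_parent, sp_left, sp_tau, split, a10, sp_root, alpha, beta_tau
                )
                delta = lp_new - lp_old + log_hast + log_jac
                for l in range(n_loci):
                    delta += _locus_logdens(tmp_c[l], tmp_a[l], sp_theta)
                    delta -= _locus_logdens(c_loc[l], a_loc[l], sp_theta)
                if use_like == 1 and delta <= -30.0:
                    delta = -np.inf
                elif use_like == 1:
                    for l in range(n_loci):
                        s, e = node_off[l], node_off[l + 1]
                        nt = tip_counts[l]
                        cs = code_off[l]
                        ps, pe = pat_off[l], pat_off[l + 1]
                        codes = codes_flat[cs : code_off[l + 1]].reshape(
                            nt, pat_counts[l]
                        )
                        new_ll[l] = _prune_flat(
                            post_flat[s:e], g_parent[s:e], g_left[s:e],
                            g_right[s:e], g_age2[s:e], codes,
                            weights_flat[ps:pe], partial,
                        )
                        delta += new_ll[l] - ll_loc[l]
            else:
                delta = -np.inf
            if delta >= np.log(np.random.random()):
                acc[ACC_TAU] += 1
                for p in range(n_pops):
                    c_tot[p] = 0.0
                    a_tot[p] = 0.0
                for l in range(n_loci):
                    for p in range(n_pops):
                        c_loc[l, p] = tmp_c[l, p]
                        a_loc[l, p] = tmp_a[l, p]
                        c_tot[p] += tmp_c[l, p]
                        a_tot[p] += tmp_a[l, p]
                for u in range(node_off[n_loci]):
                    g_age[u] = g_age2[u]
                if use_like == 1:
                    for l in range(n_loci):
                        ll_loc[l] = new_ll[l]
            else:
                sp_tau[v] = old_tau

        # ---------------- reversible-jump split/merge (A10)
        if a10 == 1 and n_internal_sp > 0:
            prop[ACC_RJ] += 1
            # pick a random internal node
            k = int(np.random.random() * n_internal_sp)
            v = -1
            cnt = 0
            for u in range(n_pops):
                if sp_left[u] >= 0:
                    if cnt == k:
                        v = u
                        break
                    cnt += 1
            par = sp_parent[v]
            cl = sp_left[v]
            cr = sp_right[v]
            cl_split = sp_left[cl] >= 0 and split[cl] == 1
            cr_split = sp_left[cr] >= 0 and split[cr] == 1
            can_split = split[v] == 0 and (par < 0 or split[par] == 1)
            can_merge = split[v] == 1 and (not cl_split) and (not cr_split)
            if can_split or can_merge:
                m = _min_cross_age(
                    v, n_loci, node_off, post_flat, g_left, g_right, g_age,
                    tip_sp_flat, sp_parent, sp_depth, node_sp_flat,
                )
                hi = m
                if par >= 0 and sp_tau[par] < hi:
                    hi = sp_tau[par]
                cap = 1e6 * tau_prior_mean
                if hi > cap:
                    hi = cap
                if np.isfinite(hi) and hi > 0.0:
                    lp_old = _logprior_tau(
                        sp_parent, sp_left, sp_tau, split, a10, sp_root,
                        alpha, beta_tau,
                    )
                    old_tau = sp_tau[v]
                    if can_split:
                        sp_tau[v] = np.random.random() * hi
                        split[v] = 1
                        log_q = np.log(hi)
                    else:
                        sp_tau[v] = 0.0
                        split[v] = 0
                        log_q = -np.log(hi)
                    ok = _all_stats(
                        n_loci, node_off, post_flat, g_left, g_right, g_age,
                        tip_sp_flat, sp_parent, sp_depth, sp_tau, tmp_c, tmp_a,
                    )
                    if ok:
                        lp_new = _logprior_tau(
                            sp_parent, sp_left, sp_tau, split, a10, sp_root,
                            alpha, beta_tau,
                        )
                        delta = lp_new - lp_old + log_q
                        for l in range(n_loci):
                            delta += _locus_logdens(tmp_c[l], tmp_a[l], sp_theta)
                            delta -= _locus_logdens(c_loc[l], a_loc[l], sp_theta)
                    else:
                        delta = -np.inf
                    if delta >= np.log(np.random.random()):
                        acc[ACC_RJ] += 1
                        for p in range(n_pops):
                            c_tot[p] = 0.0
                            a_tot[p] = 0.0
                        for l in range(n_loci):
                            for p in range(n_pops):
                                c_loc[l, p] = tmp_c[l, p]
                                a_loc[l, p] = tmp_a[l, p]
                                c_tot[p] += tmp_c[l, p]
                                a_tot[p] += tmp_a[l, p]
                    else:
                        sp_tau[v] = old_tau
                        split[v] = 1 if can_merge else 0

        # ---------------- global scale (mixing) move
        if mix_every > 0 and it % mix_every == 0:
            prop[ACC_MIX] += 1
            c = np.exp(lam_mix * (np.random.random() - 0.5))
            lp_old = _logprior_tau(
                sp_parent, sp_left, sp_tau, split, a10, sp_root, alpha, beta_tau
            )
            n_scaled = n_gene_internal
            for u in range(n_pops):
                if sp_left[u] >= 0 and (a10 == 0 or split[u] == 1):
                    n_scaled += 1
            delta = n_scaled * np.log(c)
            for p in range(n_pops):
                delta -= (c - 1.0) * a_tot[p] / sp_theta[p]
            # scale taus for the prior term
            for u in range(n_pops):
                sp_tau[u] *= c
            lp_new = _logprior_tau(
                sp_parent, sp_left, sp_tau, split, a10, sp_root, alpha, beta_tau
            )
            delta += lp_new - lp_old
            if use_like == 1:
                for l in range(n_loci):
                    s, e = node_off[l], node_off[l + 1]
                    nt = tip_counts[l]
                    for vv in range(s + nt, e):
                        g_age[vv] *= c
                    cs = code_off[l]
                    ps, pe = pat_off[l], pat_off[l + 1]
                    codes = codes_flat[cs : code_off[l + 1]].reshape(
                        nt, pat_counts[l]
                    )
                    new_ll[l] = _prune_flat(
                        post_flat[s:e], g_parent[s:e], g_left[s:e], g_right[s:e],
                        g_age[s:e], codes, weights_flat[ps:pe], partial,
                    )
                    delta += new_ll[l] - ll_loc[l]
            else:
                for l in range(n_loci):
                    s, e = node_off[l], node_off[l + 1]
                    nt = tip_counts[l]
                    for vv in range(s + nt, e):
                        g_age[vv] *= c
            if delta >= np.log(np.random.random()):
                acc[ACC_MIX] += 1
                if use_like == 1:
                    for l in range(n_loci):
                        ll_loc[l] = new_ll[l]
                for l in range(n_loci):
                    for p in range(n_pops):
                        a_loc[l, p] *= c
                for p in range(n_pops):
                    a_tot[p] *= c
            else:
                inv = 1.0 / c
                for u in range(n_pops):
                    sp_tau[u] *= inv
                for l in range(n_loci):
                    s, e = node_off[l], node_off[l + 1]
                    nt = tip_counts[l]
                    for vv in range(s + nt, e):
                        g_age[vv] *= inv

        # ---------------- record
        if it >= burnin and (it - burnin + 1) % thin == 0:
            for p in range(n_pops):
                out_tau[sample_i, p] = sp_tau[p]
                out_theta[sample_i, p] = sp_theta[p]
            tot = 0.0
            for l in range(n_loci):
                tot += ll_loc[l]
            out_ll[sample_i] = tot
            flags = 0
            n_tips_sp = (n_pops + 1) // 2
            for u in range(n_pops):
                if sp_left[u] >= 0 and split[u] == 1:
                    flags |= 1 << ((u - n_tips_sp) % 63)
            out_flags[sample_i] = flags
            sample_i += 1
    return sample_i
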