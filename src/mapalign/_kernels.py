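"""Compiled inner loops of the annealer.

The chunk runners execute a block of annealing steps in place and return
the accumulated energy change plus acceptance counters.  Each step
proposes one contact addition at a uniformly random (SC site, V1 site)
pair and one removal at a uniformly random existing contact
(count-weighted via an explicit contact list), accepting each sub-move
independently with the sigmoid probability ``1 / (1 + exp(gain * dE))``.

For the correlational model every energy term is either contact-local
(table ``L``) or a closed-form marginal update, so a step is O(1).  The
integrational axon-axon term couples all axons converging on one SC site;
the runner keeps per-site caches,

* ``SD[s]``   = sum_q D(s,q) n(s,q),
* ``C[s,l]``  = sum_{q != l} D(s,q) n(s,q) K(l,q)  (valid where n(s,l) > 0),
* active-source lists per site,

so one sub-move costs O(active sources at the site).  The caches are
rebuilt from the counts at every snapshot to cap floating-point drift.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _accept(dE, gain):
    z = gain * dE
    if z > 700.0:
        z = 700.0
    return np.random.random() < 1.0 / (1.0 + np.exp(z))


@njit(cache=True)
def run_chunk_correlational(counts, n_A, n_D, con_s, con_l, ncon, L,
                            beta_c, alpha_c, gamma_c, gain, nsteps, seed):
    """Run up to ``nsteps`` correlational steps; returns
    (dE_accumulated, ncon, accepted_adds, accepted_removals, steps_done).

    Stops early (steps_done < nsteps) if the contact list is full so the
    caller can grow it.
    """
    np.random.seed(seed)
    Ms, Ml = counts.shape
    cap = con_s.shape[0]
    dE_acc = 0.0
    acc_add = 0
    acc_rem = 0
    for it in range(nsteps):
        if ncon >= cap:
            return dE_acc, ncon, acc_add, acc_rem, it
        # --- addition ---
        s = np.random.randint(0, Ms)
        l = np.random.randint(0, Ml)
        dE = (L[s, l] + beta_c * (2.0 * n_A[l] + 1.0) - alpha_c
              + gamma_c * (2.0 * n_D[s] + 1.0))
        if _accept(dE, gain):
            counts[s, l] += 1
            n_A[l] += 1
            n_D[s] += 1
            con_s[ncon] = s
            con_l[ncon] = l
            ncon += 1
            dE_acc += dE
            acc_add += 1
        # --- removal ---
        if ncon > 0:
            j = np.random.randint(0, ncon)
            s = con_s[j]
            l = con_l[j]
            dE = (-L[s, l] + beta_c * (1.0 - 2.0 * n_A[l]) + alpha_c
                  + gamma_c * (1.0 - 2.0 * n_D[s]))
            if _accept(dE, gain):
                counts[s, l] -= 1
                n_A[l] -= 1
                n_D[s] -= 1
                ncon -= 1
                con_s[j] = con_s[ncon]
                con_l[j] = con_l[ncon]
                dE_acc += dE
                acc_rem += 1
    return dE_acc, ncon, acc_add, acc_rem, nsteps


@njit(cache=True)
def rebuild_integrational_cache(counts, D, K, C, SD, act_list, act_n, act_pos):
    """Recompute the per-site caches exactly from the counts."""
    Ms, Ml = counts.shape
    for s in range(Ms):
        k = 0
        sd = 0.0
        for l in range(Ml):
            act_pos[s, l] = -1
            if counts[s, l] > 0:
                act_list[s, k] = l
                act_pos[s, l] = k
                k += 1
                sd += D[s, l] * counts[s, l]
        act_n[s] = k
        SD[s] = sd
        for i in range(k):
            l = act_list[s, i]
            c = 0.0
            for j in range(k):
                q = act_list[s, j]
                if q != l:
                    c += D[s, q] * counts[s, q] * K[l, q]
            C[s, l] = c


@njit(cache=True)
def _delta_add_integ(s, l0, counts, L, D, K, C, SD, act_list, act_n,
                     n_A, n_D, beta_c, alpha_c, gamma_c, gamma_u):
    d0 = D[s, l0]
    dA = 0.0
    for i in range(act_n[s]):
        l = act_list[s, i]
        if l == l0:
            continue
        nl = counts[s, l]
        W = SD[s] - D[s, l] * nl
        A_old = C[s, l] / W if W > 1e-12 else 0.0
        Wn = W + d0
        A_new = (C[s, l] + d0 * K[l, l0]) / Wn if Wn > 1e-12 else 0.0
        dA += nl * (A_new - A_old)
    n0 = counts[s, l0]
    if n0 > 0:
        C0 = C[s, l0]
    else:
        C0 = 0.0
        for i in range(act_n[s]):
            l = act_list[s, i]
            C0 += D[s, l] * counts[s, l] * K[l0, l]
    W0 = SD[s] - d0 * n0
    A0 = C0 / W0 if W0 > 1e-12 else 0.0
    d_comp = (beta_c * (2.0 * n_A[l0] + 1.0) - alpha_c
              + gamma_c * (2.0 * n_D[s] + 1.0))
    return L[s, l0] + d_comp - gamma_u * (A0 + dA), C0


@njit(cache=True)
def _delta_rem_integ(s, l0, counts, L, D, K, C, SD, act_list, act_n,
                     n_A, n_D, beta_c, alpha_c, gamma_c, gamma_u):
    d0 = D[s, l0]
    dA = 0.0
    for i in range(act_n[s]):
        l = act_list[s, i]
        if l == l0:
            continue
        nl = counts[s, l]
        W = SD[s] - D[s, l] * nl
        A_old = C[s, l] / W if W > 1e-12 else 0.0
        Wn = W - d0
        A_new = (C[s, l] - d0 * K[l, l0]) / Wn if Wn > 1e-12 else 0.0
        dA += nl * (A_new - A_old)
    W0 = SD[s] - d0 * counts[s, l0]
    A0 = C[s, l0] / W0 if W0 > 1e-12 else 0.0
    d_comp = (beta_c * (1.0 - 2.0 * n_A[l0]) + alpha_c
              + gamma_c * (1.0 - 2.0 * n_D[s]))
    return -L[s, l0] + d_comp + gamma_u * A0 - gamma_u * dA


@njit(cache=True)
def run_chunk_integrational(counts, n_A, n_D, con_s, con_l, ncon, L, D, K,
                            C, SD, act_list, act_n, act_pos,
                            beta_c, alpha_c, gamma_c, gamma_u, gain,
                            nsteps, seed):
    """Integrational counterpart of :func:`run_chunk_correlational`."""
    np.random.seed(seed)
    Ms, Ml = counts.shape
    cap = con_s.shape[0]
    dE_acc = 0.0
    acc_add = 0
    acc_rem = 0
    for it in range(nsteps):
        if ncon >= cap:
            return dE_acc, ncon, acc_add, acc_rem, it
        # --- addition ---
        s = np.random.randint(0, Ms)
        l0 = np.random.randint(0, Ml)
        dE, C0 = _delta_add_integ(s, l0, counts, L, D, K, C, SD, act_list,
                                  act_n, n_A, n_D, beta_c, alpha_c, gamma_c,
                                  gamma_u)
        if _accept(dE, gain):
            d0 = D[s, l0]
            newly_active = counts[s, l0] == 0
            counts[s, l0] += 1
            n_A[l0] += 1
            n_D[s] += 1
            SD[s] += d0
            for i in range(act_n[s]):
                l = act_list[s, i]
                if l != l0:
                    C[s, l] += d0 * K[l, l0]
            if newly_active:
                C[s, l0] = C0
                act_pos[s, l0] = act_n[s]
                act_list[s, act_n[s]] = l0
                act_n[s] += 1
            con_s[ncon] = s
            con_l[ncon] = l0
            ncon += 1
            dE_acc += dE
            acc_add += 1
        # --- removal ---
        if ncon > 0:
            j = np.random.randint(0, ncon)
            s = con_s[j]
            l0 = con_l[j]
            dE = _delta_rem_integ(s, l0, counts, L, D, K, C, SD, act_list,
                                  act_n, n_A, n_D, beta_c, alpha_c, gamma_c,
                                  gamma_u)
            if _accept(dE, gain):
                d0 = D[s, l0]
                counts[s, l0] -= 1
                n_A[l0] -= 1
                n_D[s] -= 1
                SD[s] -= d0
                for i in range(act_n[s]):
                    l = act_list[s, i]
                    if l != l0:
                        C[s, l] -= d0 * K[l, l0]
                if counts[s, l0] == 0:
                    p = act_pos[s, l0]
                    last = act_n[s] - 1
                    ll = act_list[s, last]
                    act_list[s, p] = ll
                    act_pos[s, ll] = p
                    act_n[s] = last
                    act_pos[s, l0] = -1
                    C[s, l0] = 0.0
                ncon -= 1
                con_s[j] = con_s[ncon]
                con_l[j] = con_l[ncon]
                dE_acc += dE
                acc_rem += 1
    return dE_acc, ncon, acc_add, acc_rem, nsteps
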