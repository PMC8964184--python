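"""Numba kernel: structured-coalescent branch-class length accumulation.

The kernel simulates genealogies of ``n1 + n2`` sampled lineages backward in
time through an epoch-encoded two-deme history and accumulates, per
replicate, the total branch length subtending exactly ``i`` of the pop-1
leaves and ``j`` of the pop-2 leaves.  Time is in units of ``2*N_ref``
generations: a lineage pair inside a deme of relative size ``nu`` coalesces
at rate ``1/nu``, and a lineage in deme ``d`` jumps to the other deme at the
epoch's backward migration rate for ``d``.  Exponentially changing deme
sizes are handled by closed-form inversion of the integrated coalescence
rate.

Epoch encoding (arrays over ``ne`` epochs, recent first; the last epoch is
the unbounded ancestral deme and all lineages are relabelled to deme 0 on
entry):

* ``dur[e]``      epoch duration (last entry effectively infinite)
* ``g0[e, d]``    deme size at the recent edge of the epoch
* ``beta[e, d]``  exponential rate so size(u) = g0 * exp(beta * u)
* ``mig[e, d]``   backward per-lineage migration rate out of deme ``d``
"""

import numpy as np
from numba import njit

__all__ = ["sim_branch_classes"]


@njit(cache=True)
def _pick_pair(k):
    a = int(np.random.random() * k)
    if a == k:
        a = k - 1
    b = int(np.random.random() * (k - 1))
    if b == k - 1:
        b = k - 2
    if b >= a:
        b += 1
    return a, b


@njit(cache=True)
def _coal_wait(k, g_cur, beta):
    """Waiting time to the next coalescence in a deme of current size g_cur
    growing as g_cur*exp(beta*u); returns a large sentinel when no event."""
    if k < 2:
        return 1e30
    rate0 = 0.5 * k * (k - 1) / g_cur
    e = np.random.exponential(1.0)
    if beta > 1e-12 or beta < -1e-12:
        arg = 1.0 - e * beta / rate0
        if arg <= 0.0:
            return 1e30
        return -np.log(arg) / beta
    return e / rate0


@njit(cache=True)
def sim_branch_classes(n1, n2, dur, g0, beta, mig, nreps, seed):
    """Accumulate branch-class lengths over ``nreps`` genealogies.

    Returns ``(lsum, lsq)``: per-class sums and sums of squares over
    replicates of the branch length in class ``(i, j)`` (the root class
    ``(n1, n2)`` is zero by construction).
    """
    np.random.seed(seed)
    n = n1 + n2
    ne = dur.shape[0]
    nslot = 2 * n  # each replicate creates at most 2n-1 lineages
    ci = np.zeros(nslot, dtype=np.int64)
    cj = np.zeros(nslot, dtype=np.int64)
    birth = np.zeros(nslot)
    slot_deme = np.zeros(nslot, dtype=np.int64)
    slot_pos = np.zeros(nslot, dtype=np.int64)
    dlist = np.zeros((2, nslot), dtype=np.int64)
    lsum = np.zeros((n1 + 1, n2 + 1))
    lsq = np.zeros((n1 + 1, n2 + 1))
    lrep = np.zeros((n1 + 1, n2 + 1))

    for _rep in range(nreps):
        lrep[:, :] = 0.0
        # sample n1 lineages in deme 0, n2 in deme 1
        kd = np.zeros(2, dtype=np.int64)
        next_slot = 0
        for d in range(2):
            nd = n1 if d == 0 else n2
            for _ in range(nd):
                s = next_slot
                next_slot += 1
                ci[s] = 1 if d == 0 else 0
                cj[s] = 0 if d == 0 else 1
                birth[s] = 0.0
                slot_deme[s] = d
                slot_pos[s] = kd[d]
                dlist[d, kd[d]] = s
                kd[d] += 1

        t = 0.0      # global backward time
        u = 0.0      # time within current epoch
        e = 0
        if ne == 1:  # degenerate: sampling directly in the ancestral deme
            for s2 in range(next_slot):
                if slot_deme[s2] == 1:
                    # relabel into deme 0
                    p = slot_pos[s2]
                    last = dlist[1, kd[1] - 1]
                    dlist[1, p] = last
                    slot_pos[last] = p
                    kd[1] -= 1
                    slot_deme[s2] = 0
                    slot_pos[s2] = kd[0]
                    dlist[0, kd[0]] = s2
                    kd[0] += 1

        while kd[0] + kd[1] > 1:
            k0 = kd[0]
            k1 = kd[1]
            mig_rate = k0 * mig[e, 0] + k1 * mig[e, 1]
            w_mig = 1e30
            if mig_rate > 0.0:
                w_mig = np.random.exponential(1.0) / mig_rate
            gc0 = g0[e, 0] * np.exp(beta[e, 0] * u)
            gc1 = g0[e, 1] * np.exp(beta[e, 1] * u)
            w_c0 = _coal_wait(k0, gc0, beta[e, 0])
            w_c1 = _coal_wait(k1, gc1, beta[e, 1])

            w = w_mig
            ev = 0
            if w_c0 < w:
                w = w_c0
                ev = 1
            if w_c1 < w:
                w = w_c1
                ev = 2

            remaining = dur[e] - u
            if w >= remaining:
                # advance to the next epoch
                t += remaining
                u = 0.0
                e += 1
                if e == ne - 1:
                    # merge: all lineages join the ancestral deme 0
                    while kd[1] > 0:
                        s2 = dlist[1, kd[1] - 1]
                        kd[1] -= 1
                        slot_deme[s2] = 0
                        slot_pos[s2] = kd[0]
                        dlist[0, kd[0]] = s2
                        kd[0] += 1
                continue

            t += w
            u += w
            if ev == 0:
                # migration: choose source deme proportionally to its rate
                r = np.random.random() * mig_rate
                d = 0 if r < k0 * mig[e, 0] else 1
                o = 1 - d
                idx = int(np.random.random() * kd[d])
                if idx == kd[d]:
                    idx = kd[d] - 1
                s = dlist[d, idx]
                last = dlist[d, kd[d] - 1]
                dlist[d, idx] = last
                slot_pos[last] = idx
                kd[d] -= 1
                slot_deme[s] = o
                slot_pos[s] = kd[o]
                dlist[o, kd[o]] = s
                kd[o] += 1
            else:
                d = ev - 1
                ia, ib = _pick_pair(kd[d])
                sa = dlist[d, ia]
                sb = dlist[d, ib]
                # close both branch segments
                lrep[ci[sa], cj[sa]] += t - birth[sa]
                lrep[ci[sb], cj[sb]] += t - birth[sb]
                # parent lineage replaces sa; remove sb (swap with last)
                sp = next_slot
                next_slot += 1
                ci[sp] = ci[sa] + ci[sb]
                cj[sp] = cj[sa] + cj[sb]
                birth[sp] = t
                dlist[d, ia] = sp
                slot_deme[sp] = d
                slot_pos[sp] = ia
                last = dlist[d, kd[d] - 1]
                if last != sb:
                    dlist[d, slot_pos[sb]] = last
                    slot_pos[last] = slot_pos[sb]
                else:
                    # sb was the last entry already
                    pass
                kd[d] -= 1

        lrep[n1, n2] = 0.0  # root class carries no mutation-visible length
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                v = lrep[i, j]
                lsum[i, j] += v
                lsq[i, j] += v * v
    return lsum, lsq
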