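"""Numba kernels for the structured coalescent.

The simulator works backward in time on a flattened model encoding:
per-population diploid sizes, a time-sorted schedule of split / size-change
events, and an optional backward migration-rate matrix. Within a population
of diploid size Ne, every lineage pair coalesces at rate 1/(2Ne) per
generation; at a split, all lineages of the derived population move into the
ancestor. Each SNP is an independent genealogy carrying exactly one mutation
on a branch chosen proportionally to its length (infinite sites, SNP mode),
so every emitted site is polymorphic in the total sample.

All kernels are seeded explicitly and single-threaded; identical arguments
give bit-identical output.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event kinds
EV_SPLIT = 0
EV_SIZE = 1


@njit(cache=True)
def _coalesce_one(
    samples,
    ne0,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_ne,
    mig,
    use_mig,
    node_time,
    left,
    right,
    pop_counts,
    members,
    k,
    ne,
    alive,
):
    """Simulate one genealogy in place; returns the root node id (or -1 if
    lineages are stranded with no remaining events)."""
    n_pops = samples.shape[0]
    n_tot = 0
    for p in range(n_pops):
        n_tot += samples[p]
    nid = 0
    for p in range(n_pops):
        k[p] = samples[p]
        ne[p] = ne0[p]
        alive[p] = True
        for j in range(samples[p]):
            members[p, j] = nid
            node_time[nid] = 0.0
            left[nid] = -1
            right[nid] = -1
            for q in range(n_pops):
                pop_counts[nid, q] = 0
            pop_counts[nid, p] = 1
            nid += 1
    t = 0.0
    iev = 0
    n_ev = ev_time.shape[0]
    n_active = n_tot
    while n_active > 1:
        total = 0.0
        for p in range(n_pops):
            kp = k[p]
            if kp > 1:
                total += kp * (kp - 1) / (4.0 * ne[p])
        if use_mig:
            for p in range(n_pops):
                if k[p] > 0 and alive[p]:
                    row = 0.0
                    for q in range(n_pops):
                        if alive[q]:
                            row += mig[p, q]
                    total += k[p] * row
        advance_to_event = False
        if total <= 0.0:
            if iev >= n_ev:
                return -1
            advance_to_event = True
        else:
            w = np.random.exponential(1.0 / total)
            if iev < n_ev and t + w >= ev_time[iev]:
                advance_to_event = True
            else:
                t += w
        if advance_to_event:
            t = ev_time[iev]
            if ev_kind[iev] == EV_SPLIT:
                a = ev_a[iev]
                b = ev_b[iev]
                for j in range(k[a]):
                    members[b, k[b] + j] = members[a, j]
                k[b] += k[a]
                k[a] = 0
                alive[a] = False
            else:
                ne[ev_a[iev]] = ev_ne[iev]
            iev += 1
            continue
        # choose the event type / population
        u = np.random.random() * total
        acc = 0.0
        done = False
        for p in range(n_pops):
            kp = k[p]
            if kp > 1:
                acc += kp * (kp - 1) / (4.0 * ne[p])
                if u < acc:
                    i = int(np.random.random() * kp)
                    j = int(np.random.random() * (kp - 1))
                    if j >= i:
                        j += 1
                    ci = members[p, i]
                    cj = members[p, j]
                    m = nid
                    nid += 1
                    node_time[m] = t
                    left[m] = ci
                    right[m] = cj
                    for q in range(n_pops):
                        pop_counts[m, q] = pop_counts[ci, q] + pop_counts[cj, q]
                    members[p, i] = m
                    members[p, j] = members[p, kp - 1]
                    k[p] = kp - 1
                    n_active -= 1
                    done = True
                    break
        if not done and use_mig:
            for p in range(n_pops):
                if done:
                    break
                if k[p] > 0 and alive[p]:
                    for q in range(n_pops):
                        if alive[q] and mig[p, q] > 0.0:
                            acc += k[p] * mig[p, q]
                            if u < acc:
                                i = int(np.random.random() * k[p])
                                lin = members[p, i]
                                members[p, i] = members[p, k[p] - 1]
                                k[p] -= 1
                                members[q, k[q]] = lin
                                k[q] += 1
                                done = True
                                break
        # if u fell through due to float rounding, draw again next loop
    return nid - 1


@njit(cache=True)
def _total_length(node_time, left, right, n_tot, root):
    total = 0.0
    for m in range(n_tot, root + 1):
        tm = node_time[m]
        total += (tm - node_time[left[m]]) + (tm - node_time[right[m]])
    return total


@njit(cache=True)
def _place_mutation(node_time, left, right, n_tot, root):
    """Pick the node below the mutated branch, probability proportional to
    branch length. Every non-root node subtends a proper, non-empty leaf
    subset, so the resulting site is polymorphic."""
    total = _total_length(node_time, left, right, n_tot, root)
    u = np.random.random() * total
    acc = 0.0
    for m in range(n_tot, root + 1):
        tm = node_time[m]
        c = left[m]
        acc += tm - node_time[c]
        if u < acc:
            return c
        c = right[m]
        acc += tm - node_time[c]
        if u < acc:
            return c
    return left[root]


#: burn-in proposals for the length-biased tree chain (independence
#: Metropolis converges geometrically; 16 steps is far past any visible bias)
_LB_BURN = 16


@njit(cache=True)
def sim_snp_pop_counts(
    seed, samples, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig, n_snps
):
    """Simulate ``n_snps`` SNPs; return the (n_snps, n_pops) matrix of
    derived-allele counts per population.

    SNP sites arise from mutations, so a SNP's genealogy is length-biased:
    the marginal law of (tree, mutated branch) is f(T) * branch_length, the
    low-mutation-rate infinite-sites limit. Trees are drawn from an
    independence-Metropolis chain with target proportional to L(T) f(T)
    (acceptance min(1, L_new/L_cur)); a rejected proposal reuses the current
    tree for the next SNP with a freshly drawn branch.
    """
    np.random.seed(seed)
    n_pops = samples.shape[0]
    n_tot = int(samples.sum())
    nn = 2 * n_tot - 1
    node_time = np.empty((2, nn), np.float64)
    left = np.empty((2, nn), np.int32)
    right = np.empty((2, nn), np.int32)
    pop_counts = np.empty((2, nn, n_pops), np.int32)
    members = np.empty((n_pops, n_tot), np.int32)
    k = np.empty(n_pops, np.int32)
    ne = np.empty(n_pops, np.float64)
    alive = np.empty(n_pops, np.bool_)
    out = np.empty((n_snps, n_pops), np.int32)
    cur = 0
    l_cur = -1.0
    root_cur = -1
    s = -_LB_BURN
    while s < n_snps:
        prop = 1 - cur
        root = _coalesce_one(
            samples, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig,
            node_time[prop], left[prop], right[prop], pop_counts[prop],
            members, k, ne, alive,
        )
        if root < 0:
            return out[:0]
        l_new = _total_length(node_time[prop], left[prop], right[prop], n_tot, root)
        if l_cur < 0.0 or np.random.random() * l_cur < l_new:
            cur = prop
            l_cur = l_new
            root_cur = root
        if s >= 0:
            c = _place_mutation(node_time[cur], left[cur], right[cur], n_tot, root_cur)
            for p in range(n_pops):
                out[s, p] = pop_counts[cur, c, p]
        s += 1
    return out


@njit(cache=True)
def sim_snp_haplotypes(
    seed, samples, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig, n_snps
):
    """Simulate ``n_snps`` SNPs; return the (n_snps, n_lineages) 0/1 matrix
    of derived states per haploid lineage (lineages numbered contiguously by
    population in model order). Same length-biased tree chain as
    :func:`sim_snp_pop_counts`."""
    np.random.seed(seed)
    n_pops = samples.shape[0]
    n_tot = int(samples.sum())
    nn = 2 * n_tot - 1
    node_time = np.empty((2, nn), np.float64)
    left = np.empty((2, nn), np.int32)
    right = np.empty((2, nn), np.int32)
    pop_counts = np.empty((2, nn, n_pops), np.int32)
    members = np.empty((n_pops, n_tot), np.int32)
    k = np.empty(n_pops, np.int32)
    ne = np.empty(n_pops, np.float64)
    alive = np.empty(n_pops, np.bool_)
    stack = np.empty(nn, np.int32)
    out = np.zeros((n_snps, n_tot), np.int8)
    cur = 0
    l_cur = -1.0
    root_cur = -1
    s = -_LB_BURN
    while s < n_snps:
        prop = 1 - cur
        root = _coalesce_one(
            samples, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig,
            node_time[prop], left[prop], right[prop], pop_counts[prop],
            members, k, ne, alive,
        )
        if root < 0:
            return out[:0]
        l_new = _total_length(node_time[prop], left[prop], right[prop], n_tot, root)
        if l_cur < 0.0 or np.random.random() * l_cur < l_new:
            cur = prop
            l_cur = l_new
            root_cur = root
        if s >= 0:
            c = _place_mutation(node_time[cur], left[cur], right[cur], n_tot, root_cur)
            sp = 0
            stack[sp] = c
            sp += 1
            while sp > 0:
                sp -= 1
                m = stack[sp]
                if m < n_tot:
                    out[s, m] = 1
                else:
                    stack[sp] = left[cur, m]
                    sp += 1
                    stack[sp] = right[cur, m]
                    sp += 1
        s += 1
    return out


@njit(cache=True)
def sim_tree_stats(
    seed, samples, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig, n_reps
):
    """TMRCA and total branch length for ``n_reps`` independent genealogies."""
    np.random.seed(seed)
    n_pops = samples.shape[0]
    n_tot = int(samples.sum())
    nn = 2 * n_tot - 1
    node_time = np.empty(nn, np.float64)
    left = np.empty(nn, np.int32)
    right = np.empty(nn, np.int32)
    pop_counts = np.empty((nn, n_pops), np.int32)
    members = np.empty((n_pops, n_tot), np.int32)
    k = np.empty(n_pops, np.int32)
    ne = np.empty(n_pops, np.float64)
    alive = np.empty(n_pops, np.bool_)
    tmrca = np.empty(n_reps, np.float64)
    tlen = np.empty(n_reps, np.float64)
    for r in range(n_reps):
        root = _coalesce_one(
            samples, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig,
            node_time, left, right, pop_counts, members, k, ne, alive,
        )
        if root < 0:
            return tmrca[:0], tlen[:0]
        tmrca[r] = node_time[root]
        tlen[r] = _total_length(node_time, left, right, n_tot, root)
    return tmrca, tlen


@njit(cache=True)
def sim_one_tree(seed, samples, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig):
    """One full genealogy: (node_time, left, right, root)."""
    np.random.seed(seed)
    n_pops = samples.shape[0]
    n_tot = int(samples.sum())
    nn = 2 * n_tot - 1
    node_time = np.empty(nn, np.float64)
    left = np.empty(nn, np.int32)
    right = np.empty(nn, np.int32)
    pop_counts = np.empty((nn, n_pops), np.int32)
    members = np.empty((n_pops, n_tot), np.int32)
    k = np.empty(n_pops, np.int32)
    ne = np.empty(n_pops, np.float64)
    alive = np.empty(n_pops, np.bool_)
    root = _coalesce_one(
        samples, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig,
        node_time, left, right, pop_counts, members, k, ne, alive,
    )
    return node_time, left, right, root
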