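"""Numba kernel for the linked (exact) Wright-Fisher engine.

Design notes
------------
* Haplotypes are sparse site-sorted lists of mutation-table indices held in
  one flat pool; a gamete with no crossover and no new mutation is a
  reference to its parental haplotype (copy-on-write), so per-generation
  work is dominated by fitness evaluation and parent sampling.
* Per-haplotype fitness contributions (product of heterozygous factors over
  its selected mutations) are cached at haplotype creation; the only
  per-individual work is the homozygosity correction over shared selected
  mutations, found by a two-pointer walk over index-sorted selected lists.
* Parents are sampled by rejection against the maximum individual weight;
  crossover and mutation events are drawn as per-generation totals
  (Poisson superposition) and assigned to uniform random gametes, exactly
  equivalent to per-gamete Poisson draws.
* When zero mutations segregate the population is exchangeable and the
  kernel fast-forwards to the next mutation event (geometric waiting time,
  conditioned event count); this is exact, not an approximation.
* Lost mutations are pruned periodically; fixed non-resistance mutations
  are removed from haplotypes (relative fitness unchanged); fixed
  resistance (TSR) mutations stay tracked at frequency 1.
* Randomness comes from an inline xorshift64* stream seeded per call, so
  runs are deterministic given their seed.

All arrays use 0-based site coordinates; generation labels are <= 0 during
burn-in (0 = selection onset) and 1..T during the selection phase.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# herbicide modes
MODE_RATIO = 0        # dominant carriers get parental weight * survival_ratio
MODE_COEFFICIENT = 1  # TSR genotype fitness 1 / 1+h*s / 1+s

_INV_2_53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _rand(st):
    x = st[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    st[0] = x
    y = (x * np.uint64(0x2545F4914F6CDD1D)) >> np.uint64(11)
    return float(y) * _INV_2_53


@njit(cache=True, inline="always")
def _randint(st, n):
    v = int(_rand(st) * n)
    if v >= n:
        v = n - 1
    return v


@njit(cache=True)
def _poisson(st, lam):
    if lam <= 0.0:
        return 0
    if lam > 100.0:
        # superposition of bounded chunks keeps the product method stable
        k = 0
        rem = lam
        while rem > 100.0:
            k += _poisson(st, 100.0)
            rem -= 100.0
        return k + _poisson(st, rem)
    thr = np.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= _rand(st)
        if p <= thr:
            return k
        k += 1


@njit(cache=True)
def _normal(st):
    u1 = _rand(st)
    while u1 <= 0.0:
        u1 = _rand(st)
    u2 = _rand(st)
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(6.283185307179586 * u2)


@njit(cache=True)
def _gamma(st, shape, scale):
    """Marsaglia-Tsang gamma deviate (any shape > 0)."""
    boost = 1.0
    a = shape
    if a < 1.0:
        u = _rand(st)
        while u <= 0.0:
            u = _rand(st)
        boost = u ** (1.0 / a)
        a += 1.0
    d = a - 1.0 / 3.0
    c = 1.0 / np.sqrt(9.0 * d)
    while True:
        x = _normal(st)
        v = 1.0 + c * x
        if v <= 0.0:
            continue
        v = v * v * v
        u = _rand(st)
        if u < 1.0 - 0.0331 * x * x * x * x:
            return d * v * boost * scale
        if u > 0.0 and np.log(u) < 0.5 * x * x + d * (1.0 - v + np.log(v)):
            return d * v * boost * scale


@njit(cache=True)
def _cond_poisson_ge1(st, lam):
    """Draw K ~ Poisson(lam) conditioned on K >= 1 (inverse CDF)."""
    q0 = np.exp(-lam)
    u = q0 + _rand(st) * (1.0 - q0)
    k = 0
    cum = q0
    pk = q0
    while cum < u and k < 10_000:
        k += 1
        pk = pk * lam / k
        cum += pk
    if k == 0:
        k = 1
    return k


@njit(cache=True, inline="always")
def _grow_i4(arr, need):
    if need <= arr.shape[0]:
        return arr
    new = np.empty(max(need, arr.shape[0] * 2), np.int32)
    new[: arr.shape[0]] = arr
    return new


@njit(cache=True, inline="always")
def _grow_i8(arr, need):
    if need <= arr.shape[0]:
        return arr
    new = np.empty(max(need, arr.shape[0] * 2), np.int64)
    new[: arr.shape[0]] = arr
    return new


@njit(cache=True, inline="always")
def _grow_f8(arr, need):
    if need <= arr.shape[0]:
        return arr
    new = np.empty(max(need, arr.shape[0] * 2), np.float64)
    new[: arr.shape[0]] = arr
    return new


@njit(cache=True, inline="always")
def _grow_u1(arr, need):
    if need <= arr.shape[0]:
        return arr
    new = np.empty(max(need, arr.shape[0] * 2), np.uint8)
    new[: arr.shape[0]] = arr
    return new


@njit(cache=True)
def wf_kernel(
    seed,
    N,
    gen_start,
    gen_end,
    site_class,          # uint8[L]: 0 noncoding, 1 exonic, 2 TSR target
    mu_site,
    rec_site,
    p_neutral_exon,
    gamma_shape,
    gamma_scale,         # already multiplied by the rescaling factor
    h_del,
    tsr_s,               # TSR selection coefficient outside herbicide (scaled)
    tsr_h,
    herbicide,           # bool: herbicide phase active
    herb_mode,           # MODE_RATIO or MODE_COEFFICIENT
    survival_ratio,
    s_ben,               # scaled; coefficient mode only
    h_ben,
    mutation_on,
    imp_site,
    imp_s,
    imp_h,
    imp_is_tsr,
    imp_ogen,
    imp_oid,
    imp_pop_off,
    imp_pop_muts,
    next_oid0,
    prune_every,
    census_every,
    record_traj,
):
    st = np.empty(1, np.uint64)
    st[0] = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1442695040888963407)
    for _ in range(8):
        _rand(st)
    L = site_class.shape[0]
    two_n = 2 * N
    lam_mut = two_n * mu_site * L if mutation_on else 0.0
    lam_rec = two_n * rec_site * (L - 1)

    # ---- mutation table ----
    n_imp = imp_site.shape[0]
    mcap = max(1024, 2 * n_imp + 64)
    m_site = np.zeros(mcap, np.int32)
    m_s = np.zeros(mcap, np.float64)
    m_h = np.zeros(mcap, np.float64)
    m_whet = np.ones(mcap, np.float64)
    m_whom = np.ones(mcap, np.float64)
    m_homf = np.ones(mcap, np.float64)   # (1+s) / (1+hs)^2
    m_is_tsr = np.zeros(mcap, np.uint8)
    m_ogen = np.zeros(mcap, np.int32)
    m_oid = np.zeros(mcap, np.int64)
    n_mut = n_imp
    for m in range(n_imp):
        m_site[m] = imp_site[m]
        m_is_tsr[m] = imp_is_tsr[m]
        m_ogen[m] = imp_ogen[m]
        m_oid[m] = imp_oid[m]
        s = imp_s[m]
        h = imp_h[m]
        if imp_is_tsr[m] == 1:
            if herbicide and herb_mode == MODE_COEFFICIENT:
                s = s_ben
                h = h_ben
            elif herbicide:
                s = 0.0  # ratio mode: carrier weighting handles the advantage
                h = 0.5
        m_s[m] = s
        m_h[m] = h
        whet = 1.0 + h * s
        whom = 1.0 + s
        m_whet[m] = whet
        m_whom[m] = whom
        m_homf[m] = whom / (whet * whet)
    next_oid = next_oid0

    # TSR event registry (every origin ever created, never pruned)
    tcap = 256
    treg_oid = np.zeros(tcap, np.int64)
    treg_site = np.zeros(tcap, np.int32)
    treg_gen = np.zeros(tcap, np.int32)
    n_treg = 0

    # ---- haplotype pool ----
    hcap = max(4096, two_n + 64)
    bufcap = max(1 << 14, 2 * imp_pop_muts.shape[0] + 1024)
    hap_start = np.zeros(hcap, np.int64)
    hap_len = np.zeros(hcap, np.int32)
    hap_selstart = np.zeros(hcap, np.int64)
    hap_sellen = np.zeros(hcap, np.int32)
    hap_wsel = np.ones(hcap, np.float64)     # product of whet over selected muts
    hap_whom = np.ones(hcap, np.float64)     # product of whom over selected muts
    hap_homfp = np.ones(hcap, np.float64)    # product of homf over selected muts
    hap_ntsr = np.zeros(hcap, np.int32)
    buf = np.zeros(bufcap, np.int32)         # site-sorted mutation lists
    selbuf = np.zeros(bufcap, np.int32)      # index-sorted selected sublists
    n_hap = 0
    buf_used = 0
    sel_used = 0

    pop = np.zeros(two_n, np.int32)
    newpop = np.zeros(two_n, np.int32)
    n_sel_alive = 0
    n_tsr_alive = 0
    n_alive = 0
    wselmax = 1.0
    squeeze_ok = True

    if imp_pop_off.shape[0] == two_n + 1:
        # import: one pool haplotype per population slot
        for slot in range(two_n):
            a = imp_pop_off[slot]
            b = imp_pop_off[slot + 1]
            ln = np.int32(b - a)
            buf = _grow_i4(buf, buf_used + ln)
            selbuf = _grow_i4(selbuf, sel_used + ln)
            w = 1.0
            wo = 1.0
            hf = 1.0
            ntsr = 0
            sl = 0
            for k in range(ln):
                m = imp_pop_muts[a + k]
                buf[buf_used + k] = m
                if m_whet[m] != 1.0 or m_whom[m] != 1.0:
                    selbuf[sel_used + sl] = m
                    sl += 1
                    w *= m_whet[m]
                    wo *= m_whom[m]
                    hf *= m_homf[m]
                if m_is_tsr[m] == 1:
                    ntsr += 1
            # index-sort the selected sublist (tiny)
            for x in range(1, sl):
                v = selbuf[sel_used + x]
                y = x - 1
                while y >= 0 and selbuf[sel_used + y] > v:
                    selbuf[sel_used + y + 1] = selbuf[sel_used + y]
                    y -= 1
                selbuf[sel_used + y + 1] = v
            hap_start[n_hap] = buf_used
            hap_len[n_hap] = ln
            hap_selstart[n_hap] = sel_used
            hap_sellen[n_hap] = sl
            hap_wsel[n_hap] = w
            hap_whom[n_hap] = wo
            hap_homfp[n_hap] = hf
            hap_ntsr[n_hap] = ntsr
            if w > wselmax:
                wselmax = w
            buf_used += ln
            sel_used += sl
            pop[slot] = n_hap
            n_hap += 1
        for m in range(n_mut):
            if m_homf[m] > 1.0:
                squeeze_ok = False
            if m_whet[m] != 1.0 or m_whom[m] != 1.0:
                n_sel_alive += 1
            if m_is_tsr[m] == 1:
                n_tsr_alive += 1
                treg_oid = _grow_i8(treg_oid, n_treg + 1)
                treg_site = _grow_i4(treg_site, n_treg + 1)
                treg_gen = _grow_i4(treg_gen, n_treg + 1)
                treg_oid[n_treg] = m_oid[m]
                treg_site[n_treg] = m_site[m]
                treg_gen[n_treg] = m_ogen[m]
                n_treg += 1
        n_alive = n_mut
    else:
        # start mutation-free: a single empty haplotype shared by everyone
        n_hap = 1
        hap_len[0] = 0
        hap_sellen[0] = 0

    # ---- working scratch ----
    wvec = np.ones(N, np.float64)
    gsrc = np.zeros(two_n, np.int64)   # source gamete slot per offspring gamete
    counts = np.zeros(mcap, np.int32)

    # ---- outputs ----
    traj_cap = 1024
    traj_gen = np.zeros(traj_cap, np.int32)
    traj_oid = np.zeros(traj_cap, np.int64)
    traj_cnt = np.zeros(traj_cap, np.int32)
    n_traj = 0
    cen_cap = 256
    cen_gen = np.zeros(cen_cap, np.int32)
    cen_cnt = np.zeros(cen_cap, np.int32)
    n_cen = 0

    g = gen_start
    gens_since_prune = 0

    # record the gen_start state (selection-onset trajectory row / census 0)
    if record_traj or (census_every > 0):
        for m in range(n_mut):
            counts[m] = 0
        for slot in range(two_n):
            h = pop[slot]
            if hap_ntsr[h] > 0:
                stt = hap_start[h]
                for k in range(hap_len[h]):
                    m = buf[stt + k]
                    if m_is_tsr[m] == 1:
                        counts[m] += 1
        if record_traj:
            for m in range(n_mut):
                if m_is_tsr[m] == 1 and counts[m] > 0:
                    traj_gen = _grow_i4(traj_gen, n_traj + 1)
                    traj_oid = _grow_i8(traj_oid, n_traj + 1)
                    traj_cnt = _grow_i4(traj_cnt, n_traj + 1)
                    traj_gen[n_traj] = g
                    traj_oid[n_traj] = m_oid[m]
                    traj_cnt[n_traj] = counts[m]
                    n_traj += 1
        if census_every > 0:
            nseg = 0
            for m in range(n_mut):
                if m_is_tsr[m] == 1 and 0 < counts[m] < two_n:
                    nseg += 1
            cen_gen = _grow_i4(cen_gen, n_cen + 1)
            cen_cnt = _grow_i4(cen_cnt, n_cen + 1)
            cen_gen[n_cen] = g
            cen_cnt[n_cen] = nseg
            n_cen += 1

    while g < gen_end:
        # ---------- exact fast-forward over mutation-free spans ----------
        if n_alive == 0:
            if lam_mut == 0.0:
                if census_every > 0:
                    gg = g + 1
                    while gg <= gen_end:
                        if (gg - gen_start) % census_every == 0:
                            cen_gen = _grow_i4(cen_gen, n_cen + 1)
                            cen_cnt = _grow_i4(cen_cnt, n_cen + 1)
                            cen_gen[n_cen] = gg
                            cen_cnt[n_cen] = 0
                            n_cen += 1
                        gg += 1
                g = gen_end
                break
            q = np.exp(-lam_mut)
            u = _rand(st)
            if u <= 0.0:
                u = 1e-300
            skip = 1 + int(np.log(u) / np.log(q))
            if skip < 1:
                skip = 1
            target = g + skip
            if target > gen_end:
                target = gen_end
                hit = False
            else:
                hit = True
            if census_every > 0:
                gg = g + 1
                last = target - 1 if hit else target
                while gg <= last:
                    if (gg - gen_start) % census_every == 0:
                        cen_gen = _grow_i4(cen_gen, n_cen + 1)
                        cen_cnt = _grow_i4(cen_cnt, n_cen + 1)
                        cen_gen[n_cen] = gg
                        cen_cnt[n_cen] = 0
                        n_cen += 1
                    gg += 1
            g = target
            if not hit:
                break
            # the generation `g` carries >= 1 mutation event; reproduction
            # itself is a no-op on an exchangeable mutation-free population.
            kev = _cond_poisson_ge1(st, lam_mut)
            for _e in range(kev):
                slot = _randint(st, two_n)
                site = _randint(st, L)
                cls = site_class[site]
                s = 0.0
                h = 0.5
                is_t = np.uint8(0)
                if cls == 2:
                    is_t = np.uint8(1)
                    if herbicide and herb_mode == MODE_COEFFICIENT:
                        s = s_ben
                        h = h_ben
                    elif not herbicide:
                        s = tsr_s
                        h = tsr_h
                elif cls == 1:
                    if _rand(st) >= p_neutral_exon:
                        s = -_gamma(st, gamma_shape, gamma_scale)
                        if s < -0.999999:
                            s = -0.999999
                        if s == 0.0:
                            s = -1e-300
                        h = h_del
                if n_mut + 1 > m_site.shape[0]:
                    m_site = _grow_i4(m_site, n_mut + 1)
                    m_s = _grow_f8(m_s, n_mut + 1)
                    m_h = _grow_f8(m_h, n_mut + 1)
                    m_whet = _grow_f8(m_whet, n_mut + 1)
                    m_whom = _grow_f8(m_whom, n_mut + 1)
                    m_homf = _grow_f8(m_homf, n_mut + 1)
                    m_is_tsr = _grow_u1(m_is_tsr, n_mut + 1)
                    m_ogen = _grow_i4(m_ogen, n_mut + 1)
                    m_oid = _grow_i8(m_oid, n_mut + 1)
                    counts = _grow_i4(counts, m_site.shape[0])
                m = n_mut
                m_site[m] = site
                m_s[m] = s
                m_h[m] = h
                whet = 1.0 + h * s
                m_whet[m] = whet
                m_whom[m] = 1.0 + s
                m_homf[m] = (1.0 + s) / (whet * whet)
                m_is_tsr[m] = is_t
                m_ogen[m] = g
                m_oid[m] = next_oid
                next_oid += 1
                n_mut += 1
                n_alive += 1
                if m_homf[m] > 1.0:
                    squeeze_ok = False
                if whet != 1.0 or 1.0 + s != 1.0:
                    n_sel_alive += 1
                if is_t == 1:
                    n_tsr_alive += 1
                    treg_oid = _grow_i8(treg_oid, n_treg + 1)
                    treg_site = _grow_i4(treg_site, n_treg + 1)
                    treg_gen = _grow_i4(treg_gen, n_treg + 1)
                    treg_oid[n_treg] = next_oid - 1
                    treg_site[n_treg] = site
                    treg_gen[n_treg] = g
                    n_treg += 1
                # put the mutation on a fresh haplotype for `slot`
                old = pop[slot]
                ln = hap_len[old]
                buf = _grow_i4(buf, buf_used + ln + 1)
                selbuf = _grow_i4(selbuf, sel_used + ln + 1)
                wrote = False
                nl = 0
                ost = hap_start[old]
                for k in range(ln):
                    mm = buf[ost + k]
                    if m_site[mm] == site and not wrote:
                        continue  # replace-on-collision at the same site
                    if m_site[mm] > site and not wrote:
                        buf[buf_used + nl] = m
                        nl += 1
                        wrote = True
                    buf[buf_used + nl] = mm
                    nl += 1
                if not wrote:
                    buf[buf_used + nl] = m
                    nl += 1
                w = 1.0
                wo = 1.0
                hf = 1.0
                ntsr = 0
                sl = 0
                for k in range(nl):
                    mm = buf[buf_used + k]
                    if m_whet[mm] != 1.0 or m_whom[mm] != 1.0:
                        selbuf[sel_used + sl] = mm
                        sl += 1
                        w *= m_whet[mm]
                        wo *= m_whom[mm]
                        hf *= m_homf[mm]
                    if m_is_tsr[mm] == 1:
                        ntsr += 1
                for x in range(1, sl):
                    v = selbuf[sel_used + x]
                    y = x - 1
                    while y >= 0 and selbuf[sel_used + y] > v:
                        selbuf[sel_used + y + 1] = selbuf[sel_used + y]
                        y -= 1
                    selbuf[sel_used + y + 1] = v
                if n_hap + 1 > hap_start.shape[0]:
                    hap_start = _grow_i8(hap_start, n_hap + 1)
                    hap_len = _grow_i4(hap_len, n_hap + 1)
                    hap_selstart = _grow_i8(hap_selstart, n_hap + 1)
                    hap_sellen = _grow_i4(hap_sellen, n_hap + 1)
                    hap_wsel = _grow_f8(hap_wsel, n_hap + 1)
                    hap_whom = _grow_f8(hap_whom, n_hap + 1)
                    hap_homfp = _grow_f8(hap_homfp, n_hap + 1)
                    hap_ntsr = _grow_i4(hap_ntsr, n_hap + 1)
                hap_start[n_hap] = buf_used
                hap_len[n_hap] = nl
                hap_selstart[n_hap] = sel_used
                hap_sellen[n_hap] = sl
                hap_wsel[n_hap] = w
                hap_whom[n_hap] = wo
                hap_homfp[n_hap] = hf
                hap_ntsr[n_hap] = ntsr
                if w > wselmax:
                    wselmax = w
                buf_used += nl
                sel_used += sl
                pop[slot] = n_hap
                n_hap += 1
            gens_since_prune += 1
        else:
            g += 1
            # ---------- parent sampling (fitness evaluated lazily) ----------
            ratio_active = herbicide and herb_mode == MODE_RATIO and n_tsr_alive > 0
            weighted = (n_sel_alive > 0) or ratio_active
            if weighted and squeeze_ok:
                # Rejection sampling against an upper weight bound.  The
                # cheap bound w_up = wsel[a]*wsel[b]*(ratio) brackets the
                # exact weight from above, and w_up*max(homfp[a], homfp[b])
                # from below (every homozygote factor <= 1), so the exact
                # shared-mutation intersection is needed only for draws in
                # the narrow gray zone.
                rfac = survival_ratio if ratio_active else 1.0
                wmax_up = wselmax * wselmax * rfac
                for j in range(two_n):
                    while True:
                        v = _rand(st) * two_n
                        slot = int(v)
                        if slot >= two_n:
                            slot = two_n - 1
                        i2 = (slot >> 1) << 1
                        a = pop[i2]
                        b = pop[i2 + 1]
                        wu = hap_wsel[a] * hap_wsel[b]
                        if ratio_active and (hap_ntsr[a] > 0 or hap_ntsr[b] > 0):
                            wu *= survival_ratio
                        t = (v - slot) * wmax_up
                        if t > wu:
                            continue
                        cf = hap_homfp[a]
                        if hap_homfp[b] > cf:
                            cf = hap_homfp[b]
                        if t <= wu * cf:
                            break
                        # gray zone: exact weight
                        if a == b:
                            wex = wu * hap_homfp[a]
                        else:
                            wex = wu
                            sla = hap_sellen[a]
                            slb = hap_sellen[b]
                            if sla > 0 and slb > 0:
                                sa = hap_selstart[a]
                                sb = hap_selstart[b]
                                ia = 0
                                ib = 0
                                while ia < sla and ib < slb:
                                    ma = selbuf[sa + ia]
                                    mb = selbuf[sb + ib]
                                    if ma == mb:
                                        wex *= m_homf[ma]
                                        ia += 1
                                        ib += 1
                                    elif ma < mb:
                                        ia += 1
                                    else:
                                        ib += 1
                        if t <= wex:
                            break
                    gsrc[j] = slot
                    newpop[j] = pop[slot]
            elif weighted:
                # general path (some homozygote factor > 1): full per-
                # individual fitness scan, then rejection against its max
                wmax = 0.0
                for i in range(N):
                    a = pop[2 * i]
                    b = pop[2 * i + 1]
                    if a == b:
                        w = hap_whom[a]  # fully homozygous at every mutation
                    else:
                        w = hap_wsel[a] * hap_wsel[b]
                        sla = hap_sellen[a]
                        slb = hap_sellen[b]
                        if sla > 0 and slb > 0:
                            sa = hap_selstart[a]
                            sb = hap_selstart[b]
                            ia = 0
                            ib = 0
                            while ia < sla and ib < slb:
                                ma = selbuf[sa + ia]
                                mb = selbuf[sb + ib]
                                if ma == mb:
                                    w *= m_homf[ma]
                                    ia += 1
                                    ib += 1
                                elif ma < mb:
                                    ia += 1
                                else:
                                    ib += 1
                    if ratio_active and (hap_ntsr[a] > 0 or hap_ntsr[b] > 0):
                        w *= survival_ratio
                    if w < 0.0:
                        w = 0.0
                    wvec[i] = w
                    if w > wmax:
                        wmax = w
                for j in range(two_n):
                    while True:
                        v = _rand(st) * two_n
                        slot = int(v)
                        if slot >= two_n:
                            slot = two_n - 1
                        if (v - slot) * wmax <= wvec[slot >> 1]:
                            break
                    gsrc[j] = slot
                    newpop[j] = pop[slot]
            else:
                for j in range(two_n):
                    slot = _randint(st, two_n)
                    gsrc[j] = slot
                    newpop[j] = pop[slot]

            # ---------- crossover / mutation events (totals) ----------
            k_rec = _poisson(st, lam_rec)
            k_mut = _poisson(st, lam_mut)
            if k_rec + k_mut > 0:
                ne = k_rec + k_mut
                ev_slot = np.empty(ne, np.int64)
                ev_kind = np.empty(ne, np.uint8)  # 0 cross, 1 mut
                ev_pos = np.empty(ne, np.int64)
                for e in range(k_rec):
                    ev_slot[e] = _randint(st, two_n)
                    ev_kind[e] = 0
                    ev_pos[e] = 1 + _randint(st, L - 1)  # breakpoint
                for e in range(k_mut):
                    ev_slot[k_rec + e] = _randint(st, two_n)
                    ev_kind[k_rec + e] = 1
                    ev_pos[k_rec + e] = _randint(st, L)  # site
                done = np.zeros(ne, np.uint8)
                for e in range(ne):
                    if done[e] == 1:
                        continue
                    slot = ev_slot[e]
                    bps = np.empty(ne, np.int64)
                    msites = np.empty(ne, np.int64)
                    nb = 0
                    nm = 0
                    for e2 in range(e, ne):
                        if done[e2] == 0 and ev_slot[e2] == slot:
                            done[e2] = 1
                            if ev_kind[e2] == 0:
                                bps[nb] = ev_pos[e2]
                                nb += 1
                            else:
                                msites[nm] = ev_pos[e2]
                                nm += 1
                    for x in range(1, nb):
                        v = bps[x]
                        y = x - 1
                        while y >= 0 and bps[y] > v:
                            bps[y + 1] = bps[y]
                            y -= 1
                        bps[y + 1] = v
                    src = gsrc[slot]
                    ha = pop[src]
                    hb = pop[src ^ 1]
                    la = hap_len[ha]
                    lb = hap_len[hb]
                    need = la + lb + nm
                    buf = _grow_i4(buf, buf_used + 2 * need + 2)
                    selbuf = _grow_i4(selbuf, sel_used + need + 1)
                    # meiosis: alternate strands at breakpoints
                    tmp_off = buf_used + need + 1  # scratch region in buf
                    ia = 0
                    ib = 0
                    nl = 0
                    cur = 0
                    sta = hap_start[ha]
                    stb = hap_start[hb]
                    for seg in range(nb + 1):
                        limit = bps[seg] if seg < nb else np.int64(L)
                        if cur == 0:
                            while ia < la and m_site[buf[sta + ia]] < limit:
                                buf[tmp_off + nl] = buf[sta + ia]
                                nl += 1
                                ia += 1
                            while ib < lb and m_site[buf[stb + ib]] < limit:
                                ib += 1
                        else:
                            while ib < lb and m_site[buf[stb + ib]] < limit:
                                buf[tmp_off + nl] = buf[stb + ib]
                                nl += 1
                                ib += 1
                            while ia < la and m_site[buf[sta + ia]] < limit:
                                ia += 1
                        cur = 1 - cur
                    # new mutations: create records, then merge by site with
                    # replace-on-collision (latest event wins at a site)
                    if nm > 0:
                        newm = np.empty(nm, np.int64)
                        for x in range(nm):
                            site = msites[x]
                            cls = site_class[site]
                            s = 0.0
                            h = 0.5
                            is_t = np.uint8(0)
                            if cls == 2:
                                is_t = np.uint8(1)
                                if herbicide and herb_mode == MODE_COEFFICIENT:
                                    s = s_ben
                                    h = h_ben
                                elif not herbicide:
                                    s = tsr_s
                                    h = tsr_h
                            elif cls == 1:
                                if _rand(st) >= p_neutral_exon:
                                    s = -_gamma(st, gamma_shape, gamma_scale)
                                    if s < -0.999999:
                                        s = -0.999999
                                    if s == 0.0:
                                        s = -1e-300
                                    h = h_del
                            if n_mut + 1 > m_site.shape[0]:
                                m_site = _grow_i4(m_site, n_mut + 1)
                                m_s = _grow_f8(m_s, n_mut + 1)
                                m_h = _grow_f8(m_h, n_mut + 1)
                                m_whet = _grow_f8(m_whet, n_mut + 1)
                                m_whom = _grow_f8(m_whom, n_mut + 1)
                                m_homf = _grow_f8(m_homf, n_mut + 1)
                                m_is_tsr = _grow_u1(m_is_tsr, n_mut + 1)
                                m_ogen = _grow_i4(m_ogen, n_mut + 1)
                                m_oid = _grow_i8(m_oid, n_mut + 1)
                                counts = _grow_i4(counts, m_site.shape[0])
                            mnew = n_mut
                            m_site[mnew] = site
                            m_s[mnew] = s
                            m_h[mnew] = h
                            whet = 1.0 + h * s
                            m_whet[mnew] = whet
                            m_whom[mnew] = 1.0 + s
                            m_homf[mnew] = (1.0 + s) / (whet * whet)
                            m_is_tsr[mnew] = is_t
                            m_ogen[mnew] = g
                            m_oid[mnew] = next_oid
                            next_oid += 1
                            n_mut += 1
                            n_alive += 1
                            if m_homf[mnew] > 1.0:
                                squeeze_ok = False
                            if whet != 1.0 or 1.0 + s != 1.0:
                                n_sel_alive += 1
                            if is_t == 1:
                                n_tsr_alive += 1
                                treg_oid = _grow_i8(treg_oid, n_treg + 1)
                                treg_site = _grow_i4(treg_site, n_treg + 1)
                                treg_gen = _grow_i4(treg_gen, n_treg + 1)
                                treg_oid[n_treg] = next_oid - 1
                                treg_site[n_treg] = site
                                treg_gen[n_treg] = g
                                n_treg += 1
                            newm[x] = mnew
                        for x in range(1, nm):
                            v = newm[x]
                            y = x - 1
                            while y >= 0 and m_site[newm[y]] > m_site[v]:
                                newm[y + 1] = newm[y]
                                y -= 1
                            newm[y + 1] = v
                        out = buf_used
                        oi = 0
                        xi = 0
                        nl2 = 0
                        while oi < nl or xi < nm:
                            if xi >= nm:
                                buf[out + nl2] = buf[tmp_off + oi]
                                nl2 += 1
                                oi += 1
                            elif oi >= nl:
                                mm = newm[xi]
                                if xi + 1 < nm and m_site[newm[xi + 1]] == m_site[mm]:
                                    xi += 1
                                    continue
                                buf[out + nl2] = np.int32(mm)
                                nl2 += 1
                                xi += 1
                            else:
                                so = m_site[buf[tmp_off + oi]]
                                sx = m_site[newm[xi]]
                                if so < sx:
                                    buf[out + nl2] = buf[tmp_off + oi]
                                    nl2 += 1
                                    oi += 1
                                elif so == sx:
                                    oi += 1  # replaced by the new event
                                else:
                                    if xi + 1 < nm and m_site[newm[xi + 1]] == sx:
                                        xi += 1
                                        continue
                                    buf[out + nl2] = np.int32(newm[xi])
                                    nl2 += 1
                                    xi += 1
                        nl = nl2
                    else:
                        for k in range(nl):
                            buf[buf_used + k] = buf[tmp_off + k]
                    # finalize haplotype
                    w = 1.0
                    wo = 1.0
                    hf = 1.0
                    ntsr = 0
                    sl = 0
                    for k in range(nl):
                        mm = buf[buf_used + k]
                        if m_whet[mm] != 1.0 or m_whom[mm] != 1.0:
                            selbuf[sel_used + sl] = mm
                            sl += 1
                            w *= m_whet[mm]
                            wo *= m_whom[mm]
                            hf *= m_homf[mm]
                        if m_is_tsr[mm] == 1:
                            ntsr += 1
                    for x in range(1, sl):
                        v = selbuf[sel_used + x]
                        y = x - 1
                        while y >= 0 and selbuf[sel_used + y] > v:
                            selbuf[sel_used + y + 1] = selbuf[sel_used + y]
                            y -= 1
                        selbuf[sel_used + y + 1] = v
                    if n_hap + 1 > hap_start.shape[0]:
                        hap_start = _grow_i8(hap_start, n_hap + 1)
                        hap_len = _grow_i4(hap_len, n_hap + 1)
                        hap_selstart = _grow_i8(hap_selstart, n_hap + 1)
                        hap_sellen = _grow_i4(hap_sellen, n_hap + 1)
                        hap_wsel = _grow_f8(hap_wsel, n_hap + 1)
                        hap_whom = _grow_f8(hap_whom, n_hap + 1)
                        hap_homfp = _grow_f8(hap_homfp, n_hap + 1)
                        hap_ntsr = _grow_i4(hap_ntsr, n_hap + 1)
                    hap_start[n_hap] = buf_used
                    hap_len[n_hap] = nl
                    hap_selstart[n_hap] = sel_used
                    hap_sellen[n_hap] = sl
                    hap_wsel[n_hap] = w
                    hap_whom[n_hap] = wo
                    hap_homfp[n_hap] = hf
                    hap_ntsr[n_hap] = ntsr
                    if w > wselmax:
                        wselmax = w
                    buf_used += nl
                    sel_used += sl
                    newpop[slot] = n_hap
                    n_hap += 1
            # swap populations
            tmp = pop
            pop = newpop
            newpop = tmp
            gens_since_prune += 1

        # ---------- recording ----------
        if record_traj or (census_every > 0 and (g - gen_start) % census_every == 0):
            for m in range(n_mut):
                counts[m] = 0
            any_tsr = False
            for slot in range(two_n):
                h = pop[slot]
                if hap_ntsr[h] > 0:
                    any_tsr = True
                    stt = hap_start[h]
                    for k in range(hap_len[h]):
                        m = buf[stt + k]
                        if m_is_tsr[m] == 1:
                            counts[m] += 1
            if record_traj and any_tsr:
                for m in range(n_mut):
                    if m_is_tsr[m] == 1 and counts[m] > 0:
                        traj_gen = _grow_i4(traj_gen, n_traj + 1)
                        traj_oid = _grow_i8(traj_oid, n_traj + 1)
                        traj_cnt = _grow_i4(traj_cnt, n_traj + 1)
                        traj_gen[n_traj] = g
                        traj_oid[n_traj] = m_oid[m]
                        traj_cnt[n_traj] = counts[m]
                        n_traj += 1
            if census_every > 0 and (g - gen_start) % census_every == 0:
                nseg = 0
                for m in range(n_mut):
                    if m_is_tsr[m] == 1 and 0 < counts[m] < two_n:
                        nseg += 1
                cen_gen = _grow_i4(cen_gen, n_cen + 1)
                cen_cnt = _grow_i4(cen_cnt, n_cen + 1)
                cen_gen[n_cen] = g
                cen_cnt[n_cen] = nseg
                n_cen += 1

        # ---------- periodic prune & compaction ----------
        if gens_since_prune >= prune_every or g >= gen_end:
            gens_since_prune = 0
            for m in range(n_mut):
                counts[m] = 0
            for slot in range(two_n):
                h = pop[slot]
                stt = hap_start[h]
                for k in range(hap_len[h]):
                    counts[buf[stt + k]] += 1
            newidx = np.full(n_mut, -1, np.int32)
            nkeep = 0
            for m in range(n_mut):
                c = counts[m]
                if c == 0:
                    continue
                if c == two_n and m_is_tsr[m] == 0:
                    continue  # fixed background mutation: drop from lists
                newidx[m] = nkeep
                nkeep += 1
            for m in range(n_mut):
                ni = newidx[m]
                if ni >= 0:
                    m_site[ni] = m_site[m]
                    m_s[ni] = m_s[m]
                    m_h[ni] = m_h[m]
                    m_whet[ni] = m_whet[m]
                    m_whom[ni] = m_whom[m]
                    m_homf[ni] = m_homf[m]
                    m_is_tsr[ni] = m_is_tsr[m]
                    m_ogen[ni] = m_ogen[m]
                    m_oid[ni] = m_oid[m]
            hap_map = np.full(n_hap, -1, np.int32)
            nb_start = np.zeros(hap_start.shape[0], np.int64)
            nb_len = np.zeros(hap_start.shape[0], np.int32)
            nb_selstart = np.zeros(hap_start.shape[0], np.int64)
            nb_sellen = np.zeros(hap_start.shape[0], np.int32)
            nb_wsel = np.ones(hap_start.shape[0], np.float64)
            nb_whom = np.ones(hap_start.shape[0], np.float64)
            nb_homfp = np.ones(hap_start.shape[0], np.float64)
            nb_ntsr = np.zeros(hap_start.shape[0], np.int32)
            nbuf = np.empty(buf.shape[0], np.int32)
            nsel = np.empty(selbuf.shape[0], np.int32)
            nh = 0
            nb_used = 0
            ns_used = 0
            for slot in range(two_n):
                h = pop[slot]
                if hap_map[h] < 0:
                    stt = hap_start[h]
                    nl = 0
                    w = 1.0
                    wo = 1.0
                    hf = 1.0
                    ntsr = 0
                    sl = 0
                    for k in range(hap_len[h]):
                        mm = newidx[buf[stt + k]]
                        if mm < 0:
                            continue
                        nbuf[nb_used + nl] = mm
                        nl += 1
                        if m_whet[mm] != 1.0 or m_whom[mm] != 1.0:
                            nsel[ns_used + sl] = mm
                            sl += 1
                            w *= m_whet[mm]
                            wo *= m_whom[mm]
                            hf *= m_homf[mm]
                        if m_is_tsr[mm] == 1:
                            ntsr += 1
                    for x in range(1, sl):
                        v = nsel[ns_used + x]
                        y = x - 1
                        while y >= 0 and nsel[ns_used + y] > v:
                            nsel[ns_used + y + 1] = nsel[ns_used + y]
                            y -= 1
                        nsel[ns_used + y + 1] = v
                    nb_start[nh] = nb_used
                    nb_len[nh] = nl
                    nb_selstart[nh] = ns_used
                    nb_sellen[nh] = sl
                    nb_wsel[nh] = w
                    nb_whom[nh] = wo
                    nb_homfp[nh] = hf
                    nb_ntsr[nh] = ntsr
                    nb_used += nl
                    ns_used += sl
                    hap_map[h] = nh
                    nh += 1
                pop[slot] = hap_map[h]
            hap_start = nb_start
            hap_len = nb_len
            hap_selstart = nb_selstart
            hap_sellen = nb_sellen
            hap_wsel = nb_wsel
            hap_whom = nb_whom
            hap_homfp = nb_homfp
            hap_ntsr = nb_ntsr
            buf = nbuf
            selbuf = nsel
            n_hap = nh
            buf_used = nb_used
            sel_used = ns_used
            n_mut = nkeep
            n_alive = nkeep
            n_sel_alive = 0
            n_tsr_alive = 0
            for m in range(n_mut):
                if m_whet[m] != 1.0 or m_whom[m] != 1.0:
                    n_sel_alive += 1
                if m_is_tsr[m] == 1:
                    n_tsr_alive += 1
            wselmax = 1.0
            for h2 in range(n_hap):
                if hap_wsel[h2] > wselmax:
                    wselmax = hap_wsel[h2]

    # ---------- export ----------
    out_site = m_site[:n_mut].copy()
    out_s = m_s[:n_mut].copy()
    out_h = m_h[:n_mut].copy()
    out_is_tsr = m_is_tsr[:n_mut].copy()
    out_ogen = m_ogen[:n_mut].copy()
    out_oid = m_oid[:n_mut].copy()
    pop_off = np.zeros(two_n + 1, np.int64)
    total = 0
    for slot in range(two_n):
        total += hap_len[pop[slot]]
        pop_off[slot + 1] = total
    pop_muts = np.empty(total, np.int32)
    idx = 0
    for slot in range(two_n):
        h = pop[slot]
        stt = hap_start[h]
        for k in range(hap_len[h]):
            pop_muts[idx] = buf[stt + k]
            idx += 1
    return (
        out_site,
        out_s,
        out_h,
        out_is_tsr,
        out_ogen,
        out_oid,
        pop_off,
        pop_muts,
        next_oid,
        treg_oid[:n_treg].copy(),
        treg_site[:n_treg].copy(),
        treg_gen[:n_treg].copy(),
        traj_gen[:n_traj].copy(),
        traj_oid[:n_traj].copy(),
        traj_cnt[:n_traj].copy(),
        cen_gen[:n_cen].copy(),
        cen_cnt[:n_cen].copy(),
    )
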