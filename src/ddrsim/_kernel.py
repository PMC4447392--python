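"""Numba kernel for network-free stochastic simulation of one cell.

The kernel executes the exact direct-method SSA over a hybrid state:

* the 50 DNA break sites are explicit agents with a small per-site state
  machine (break type, H2AX/focus status, bound repair factors);
* every other molecule is a well-mixed pool count.

Propensities are recomputed from state on every event (the per-event work
is a few hundred arithmetic operations, which keeps an 80-hour cell in the
hundred-millisecond range).  Scheduled protocol events (irradiation pulses,
Nutlin factor changes, background-ROS scaling) interrupt the SSA clock:
the next-reaction time is truncated at the event time, which is exact for
piecewise-constant propensities.

Randomness comes from a self-contained xorshift64* generator seeded via
splitmix64, so trajectories are bit-reproducible for a given seed
independent of the surrounding numpy state.

The kernel is hand-wired to the rule set declared in :mod:`ddrsim.model`;
:mod:`ddrsim.engine` verifies the rule names match before running, and the
test suite cross-checks the kernel against a plain SSA on the enumerated
network for reduced models.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# parameter vector layout (filled by engine.py from the ModelSpec)
# ---------------------------------------------------------------------------

PARAM_ORDER = (
    "k_ros_prod_norm", "k_ros_prod_sen", "theta_gadd45_ros", "k_ros_dec",
    "k_dmg_sdsb", "k_dmg_cdsb", "k_complexify", "dsb_yield", "fc_max", "fc_half",
    "k_ku_bind", "k_ku_bind_sen", "k_ku_off_red", "k_ku_off_ox", "k_ku_ox",
    "k_ku_red", "k_pk_bind", "k_pk_off", "k_pk_autophos", "k_pk_dephos_site",
    "k_liIV_bind", "k_liIV_off", "k_lig_d_sdsb", "k_lig_d_cdsb", "k_ox_breakup",
    "k_parp_bind", "k_parp_off", "k_liIII_bind", "k_liIII_off", "k_lig_b_sdsb",
    "k_lig_b_cdsb", "k_h2ax_phos_atm", "k_h2ax_phos_pk", "k_h2ax_dephos",
    "k_atm_bind", "k_focus_form", "k_focus_res", "k_atm_act", "k_atm_deact",
    "k_p53_syn", "k_p53_deg", "k_p53_phos", "k_p53_dephos", "k_mdm2_phos",
    "k_mdm2p_deg", "k_mdm2u_deg", "k_mdm2_txn_lo", "k_mdm2_txn_hi",
    "theta_p53_mdm2", "k_mdm2_mrna_dec", "k_mdm2_syn", "k_p21_txn_lo",
    "k_p21_txn_hi", "theta_p53_p21", "k_p21_mrna_dec", "k_p21_syn", "k_p21_dec",
    "k_gadd_prod_lo", "k_gadd_prod_hi", "theta_p21_gadd", "k_gadd_dec",
    "k_sen_plus", "k_sen_minus", "theta_p21_sen", "k_sen_switch",
    "k_ku_dep", "ku_floor", "k_parp_dep", "parp_floor",
)
P = {name: i for i, name in enumerate(PARAM_ORDER)}

# pool vector layout
POOL_ORDER = (
    "ros", "ku_r", "ku_o", "pk_u", "pk_p", "liIV", "parp", "liIII",
    "atm0", "atm1", "p53u", "p53p", "mdm2u", "mdm2p", "mdm2_mrna",
    "p53_mrna", "p21_mrna", "p21", "gadd45", "sen_int", "sen_state",
    "source", "deg_ku", "deg_parp",
)
PI = {name: i for i, name in enumerate(POOL_ORDER)}
N_POOL = len(POOL_ORDER)

# (indices used as compile-time constants inside the kernel)
ROS, KU_R, KU_O, PK_U, PK_P, LIIV, PARPF, LIIII = 0, 1, 2, 3, 4, 5, 6, 7
ATM0, ATM1, P53U, P53P, MDM2U, MDM2P, MDM2M = 8, 9, 10, 11, 12, 13, 14
P53M, P21M, P21, GADD, SEN_INT, SEN_STATE, SOURCE = 15, 16, 17, 18, 19, 20, 21
DEG_KU, DEG_PARP = 22, 23

# site state codes
S_OK, S_SDSB, S_CDSB = 0, 1, 2
H_U, H_P, H_PA, H_FA = 0, 1, 2, 3  # u / p / p+ATM / focus+ATM
# bound-factor codes
B_NONE, B_KR, B_KO, B_KRPU, B_KRPP, B_KOPU, B_KOPP, B_KRPL, B_KOPL, B_PARP, B_PARPL = (
    0, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
)

N_POOL_CH = 25

# timed event kinds
EV_IR, EV_NUTLIN, EV_ROSMULT = 0, 1, 2

_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(cache=True, inline="always")
def _next_u64(rng):
    x = rng[0]
    x ^= x >> np.uint64(12)
    x ^= (x << np.uint64(25)) & _MASK
    x ^= x >> np.uint64(27)
    rng[0] = x
    return (x * np.uint64(2685821657736338717)) & _MASK


@njit(cache=True, inline="always")
def _rand(rng):
    # uniform in (0, 1): top 53 bits, offset to exclude 0
    return (np.float64(_next_u64(rng) >> np.uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def seed_rng(seed):
    # splitmix64 expansion of a small integer seed
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & _MASK
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9) & _MASK
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB) & _MASK
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x106689D45497FDB5)
    out = np.empty(1, dtype=np.uint64)
    out[0] = z
    return out


# ---------------------------------------------------------------------------
# propensities
# ---------------------------------------------------------------------------


@njit(cache=True)
def _pool_props(pp, pools, pars, n_broken, n_ku_bound, n_parp_bound, nutlin, ros_mult):
    gadd_hi = pools[GADD] > pars[2]          # theta_gadd45_ros
    k_ros = pars[1] if gadd_hi else pars[0]
    pp[0] = k_ros * ros_mult * pools[SOURCE]                      # ros_prod
    pp[1] = pars[3] * pools[ROS]                                  # ros_dec
    pp[2] = pars[37] * n_broken * pools[ATM0]                     # atm_act
    pp[3] = pars[38] * pools[ATM1]                                # atm_deact
    pp[4] = pars[39] * pools[P53M]                                # p53_syn
    pp[5] = pars[40] * nutlin * pools[P53U] * pools[MDM2U]        # p53_deg
    pp[6] = pars[41] * pools[P53U] * pools[ATM1]                  # p53_phos
    pp[7] = pars[42] * pools[P53P]                                # p53_dephos
    pp[8] = pars[43] * pools[MDM2U] * pools[ATM1]                 # mdm2_phos
    pp[9] = pars[44] * pools[MDM2P]                               # mdm2p_deg
    pp[10] = pars[45] * pools[MDM2U]                              # mdm2u_deg
    p53_tot = pools[P53U] + pools[P53P]
    pp[11] = pars[47] if p53_tot > pars[48] else pars[46]         # mdm2_txn
    pp[12] = pars[49] * pools[MDM2M]                              # mdm2_mrna_dec
    pp[13] = pars[50] * pools[MDM2M]                              # mdm2_syn
    pp[14] = pars[52] if p53_tot > pars[53] else pars[51]         # p21_txn
    pp[15] = pars[54] * pools[P21M]                               # p21_mrna_dec
    pp[16] = pars[55] * pools[P21M]                               # p21_syn
    pp[17] = pars[56] * pools[P21]                                # p21_dec
    pp[18] = pars[58] if pools[P21] > pars[59] else pars[57]      # gadd_prod
    pp[19] = pars[60] * pools[GADD]                               # gadd_dec
    sen = pools[SEN_STATE] >= 1.0
    ku_total = pools[KU_R] + pools[KU_O] + n_ku_bound
    parp_total = pools[PARPF] + n_parp_bound
    pp[20] = pars[65] * pools[KU_R] if (sen and ku_total > pars[66]) else 0.0
    pp[21] = pars[67] * pools[PARPF] if (sen and parp_total > pars[68]) else 0.0
    p21_hi = pools[P21] > pars[63]
    norm = pools[SEN_STATE] < 1.0
    pp[22] = pars[61] if (norm and p21_hi and pools[SEN_INT] < 10.0) else 0.0
    pp[23] = pars[62] if (norm and (not p21_hi) and pools[SEN_INT] > 1.0) else 0.0
    pp[24] = pars[64] if (norm and pools[SEN_INT] >= 10.0) else 0.0
    total = 0.0
    for i in range(N_POOL_CH):
        total += pp[i]
    return total


@njit(cache=True)
def _site_props(st, hx, bd, pools, pars, ev_prop, ev_code):
    """Fill per-site event propensities; return (count, total)."""
    k = 0
    total = 0.0
    ros = pools[ROS]
    sen = pools[SEN_STATE] >= 1.0
    k_ku_bind = pars[11] if sen else pars[10]
    if st == S_OK:
        a = pars[4] * ros
        if a > 0.0:
            ev_prop[k] = a; ev_code[k] = 0; total += a; k += 1
        a = pars[5] * ros
        if a > 0.0:
            ev_prop[k] = a; ev_code[k] = 1; total += a; k += 1
    else:
        if st == S_SDSB:
            a = pars[6] * ros
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 2; total += a; k += 1
        if hx == H_U:
            if bd != B_NONE:
                a = pars[31] * pools[ATM1]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 3; total += a; k += 1
            if bd == B_KRPP or bd == B_KOPP or bd == B_KRPL or bd == B_KOPL:
                a = pars[32]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 4; total += a; k += 1
        elif hx == H_P:
            a = pars[34] * pools[ATM1]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 6; total += a; k += 1
        elif hx == H_PA:
            a = pars[35]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 7; total += a; k += 1
        # repair-factor transitions
        if bd == B_NONE:
            a = k_ku_bind * pools[KU_R]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 9; total += a; k += 1
            a = k_ku_bind * pools[KU_O]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 10; total += a; k += 1
            a = pars[25] * pools[PARPF]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 11; total += a; k += 1
        elif bd == B_KR:
            a = pars[12]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 12; total += a; k += 1
            a = pars[14] * ros
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 14; total += a; k += 1
            a = pars[16] * pools[PK_U]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 16; total += a; k += 1
            a = pars[16] * pools[PK_P]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 17; total += a; k += 1
        elif bd == B_KO:
            a = pars[13]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 13; total += a; k += 1
            a = pars[15]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 15; total += a; k += 1
            a = pars[16] * pools[PK_U]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 16; total += a; k += 1
            a = pars[16] * pools[PK_P]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 17; total += a; k += 1
        elif bd == B_KRPU or bd == B_KRPP:
            a = pars[17]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 18; total += a; k += 1
            a = pars[14] * ros
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 14; total += a; k += 1
            if bd == B_KRPU:
                a = pars[18]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 19; total += a; k += 1
            else:
                a = pars[19]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 20; total += a; k += 1
                a = pars[20] * pools[LIIV]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 21; total += a; k += 1
        elif bd == B_KOPU or bd == B_KOPP:
            a = pars[17]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 18; total += a; k += 1
            a = pars[15]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 15; total += a; k += 1
            a = pars[24]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 24; total += a; k += 1
            if bd == B_KOPU:
                a = pars[18]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 19; total += a; k += 1
            else:
                a = pars[19]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 20; total += a; k += 1
                a = pars[20] * pools[LIIV]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 21; total += a; k += 1
        elif bd == B_KRPL:
            a = pars[21]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 22; total += a; k += 1
            a = pars[14] * ros
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 14; total += a; k += 1
            if hx == H_FA:
                a = pars[22] if st == S_SDSB else pars[23]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 23; total += a; k += 1
        elif bd == B_KOPL:
            a = pars[21]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 22; total += a; k += 1
            a = pars[15]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 15; total += a; k += 1
            if hx == H_FA:
                a = pars[22] if st == S_SDSB else pars[23]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 23; total += a; k += 1
        elif bd == B_PARP:
            a = pars[26]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 25; total += a; k += 1
            a = pars[27] * pools[LIIII]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 26; total += a; k += 1
        elif bd == B_PARPL:
            a = pars[28]
            if a > 0.0:
                ev_prop[k] = a; ev_code[k] = 27; total += a; k += 1
            if hx == H_FA:
                a = pars[29] if st == S_SDSB else pars[30]
                if a > 0.0:
                    ev_prop[k] = a; ev_code[k] = 28; total += a; k += 1
    # H2AX dephosphorylation and focus resolution apply on any site type
    if hx == H_P:
        a = pars[33]
        if a > 0.0:
            ev_prop[k] = a; ev_code[k] = 5; total += a; k += 1
    elif hx == H_FA:
        a = pars[36]
        if a > 0.0:
            ev_prop[k] = a; ev_code[k] = 8; total += a; k += 1
    return k, total


# ---------------------------------------------------------------------------
# main advance loop
# ---------------------------------------------------------------------------


@njit(cache=True)
def advance_kernel(
    pools,            # float64[N_POOL], mutated
    site, h2x, bnd,   # int32[n_sites], mutated
    pars,             # float64[len(PARAM_ORDER)]
    rng,              # uint64[1]
    t_start, t_end,
    mods,             # float64[2]: nutlin factor, ros multiplier (mutated by events)
    ev_time, ev_kind, ev_value,  # scheduled protocol events (sorted)
    ev_next,          # int64[1]: index of next pending event, mutated
    grid,             # float64[m] sample times (subset within (t_start, t_end])
    samples,          # float64[m, 11] output
    focus_log,        # float64[cap, 3]: site, t_form, t_res(nan if open)
    open_focus,       # int64[n_sites]: row of open episode or -1
    focus_n,          # int64[1]
    break_log,        # float64[cap, 4]: site, t_break, t_ligate(nan), type
    open_break,       # int64[n_sites]
    break_n,          # int64[1]
    sen_switch_time,  # float64[1], nan until switch
):
    """Run the SSA from t_start to t_end; returns final time.

    Returns a negative value on log-buffer overflow (the wrapper raises).
    """
    n = site.shape[0]
    pp = np.empty(N_POOL_CH)
    sp_tot = np.empty(n)
    ev_prop = np.empty(24)
    ev_code = np.empty(24, dtype=np.int64)

    # incremental tallies
    n_broken = 0
    n_ku_bound = 0
    n_parp_bound = 0
    for i in range(n):
        if site[i] != S_OK:
            n_broken += 1
        if B_KR <= bnd[i] <= B_KOPL:
            n_ku_bound += 1
        elif bnd[i] >= B_PARP:
            n_parp_bound += 1

    t = t_start
    gi = 0
    m = grid.shape[0]
    while True:
        # next hard interrupt: scheduled event or end of run
        if ev_next[0] < ev_time.shape[0]:
            t_stop = min(t_end, ev_time[ev_next[0]])
        else:
            t_stop = t_end

        total = _pool_props(pp, pools, pars, n_broken, n_ku_bound,
                            n_parp_bound, mods[0], mods[1])
        for i in range(n):
            kk, s_tot = _site_props(site[i], h2x[i], bnd[i], pools, pars,
                                    ev_prop, ev_code)
            sp_tot[i] = s_tot
            total += s_tot

        if total <= 0.0:
            t_next = t_stop + 1.0  # jump straight to the interrupt
        else:
            t_next = t - np.log(_rand(rng)) / total

        if t_next > t_stop:
            # record samples up to the interrupt, then apply it
            while gi < m and grid[gi] <= t_stop:
                _record(samples, gi, grid[gi], pools, site, h2x, n)
                gi += 1
            t = t_stop
            if t >= t_end:
                return t
            # apply the scheduled event atomically
            kind = ev_kind[ev_next[0]]
            val = ev_value[ev_next[0]]
            ev_next[0] += 1
            if kind == EV_NUTLIN:
                mods[0] = val
            elif kind == EV_ROSMULT:
                mods[1] = val
            elif kind == EV_IR:
                p_hit = 1.0 - np.exp(-pars[7] * val / n)
                fc = pars[8] * val / (val + pars[9]) if val > 0.0 else 0.0
                for i in range(n):
                    if site[i] == S_OK and _rand(rng) < p_hit:
                        if _rand(rng) < fc:
                            site[i] = S_CDSB
                        else:
                            site[i] = S_SDSB
                        n_broken += 1
                        r = break_n[0]
                        if r >= break_log.shape[0]:
                            return -1.0
                        break_log[r, 0] = i
                        break_log[r, 1] = t
                        break_log[r, 2] = np.nan
                        break_log[r, 3] = site[i]
                        open_break[i] = r
                        break_n[0] = r + 1
            continue

        # record samples strictly before the event time
        while gi < m and grid[gi] < t_next:
            _record(samples, gi, grid[gi], pools, site, h2x, n)
            gi += 1
        t = t_next

        # select channel
        r = _rand(rng) * total
        pool_sum = 0.0
        for i in range(N_POOL_CH):
            pool_sum += pp[i]
        if r < pool_sum:
            ci = 0
            acc = pp[0]
            while r > acc and ci < N_POOL_CH - 1:
                ci += 1
                acc += pp[ci]
            _fire_pool(ci, pools, t, sen_switch_time)
            continue
        r -= pool_sum
        si = 0
        while si < n - 1 and r > sp_tot[si]:
            r -= sp_tot[si]
            si += 1
        kk, s_tot = _site_props(site[si], h2x[si], bnd[si], pools, pars,
                                ev_prop, ev_code)
        if kk == 0:
            # float-rounding residual landed on an inert site; skip the draw
            continue
        ci = 0
        acc = ev_prop[0]
        while r > acc and ci < kk - 1:
            ci += 1
            acc += ev_prop[ci]
        code = ev_code[ci]
        ok = _fire_site(code, si, site, h2x, bnd, pools, t,
                        focus_log, open_focus, focus_n,
                        break_log, open_break, break_n)
        if ok < 0:
            return -1.0
        # refresh tallies affected by site events
        if code <= 1:
            n_broken += 1
        elif code == 23 or code == 28:
            n_broken -= 1
        if code == 9 or code == 10:
            n_ku_bound += 1
        elif code == 12 or code == 13 or code == 24:
            n_ku_bound -= 1
        elif code == 23:
            n_ku_bound -= 1
        if code == 11:
            n_parp_bound += 1
        elif code == 25 or code == 28:
            n_parp_bound -= 1
    return t


@njit(cache=True, inline="always")
def _record(samples, gi, tg, pools, site, h2x, n):
    foci = 0
    nsd = 0
    ncd = 0
    for i in range(n):
        if h2x[i] == H_FA:
            foci += 1
        if site[i] == S_SDSB:
            nsd += 1
        elif site[i] == S_CDSB:
            ncd += 1
    samples[gi, 0] = tg
    samples[gi, 1] = pools[ROS]
    samples[gi, 2] = foci
    samples[gi, 3] = pools[P53U] + pools[P53P]
    samples[gi, 4] = pools[P53P]
    samples[gi, 5] = pools[P21]
    samples[gi, 6] = pools[MDM2U] + pools[MDM2P]
    samples[gi, 7] = pools[SEN_INT]
    samples[gi, 8] = pools[SEN_STATE]
    samples[gi, 9] = nsd
    samples[gi, 10] = ncd


@njit(cache=True)
def _fire_pool(ci, pools, t, sen_switch_time):
    if ci == 0:
        pools[ROS] += 1
    elif ci == 1:
        pools[ROS] -= 1
    elif ci == 2:
        pools[ATM0] -= 1; pools[ATM1] += 1
    elif ci == 3:
        pools[ATM1] -= 1; pools[ATM0] += 1
    elif ci == 4:
        pools[P53U] += 1
    elif ci == 5:
        pools[P53U] -= 1
    elif ci == 6:
        pools[P53U] -= 1; pools[P53P] += 1
    elif ci == 7:
        pools[P53P] -= 1; pools[P53U] += 1
    elif ci == 8:
        pools[MDM2U] -= 1; pools[MDM2P] += 1
    elif ci == 9:
        pools[MDM2P] -= 1
    elif ci == 10:
        pools[MDM2U] -= 1
    elif ci == 11:
        pools[MDM2M] += 1
    elif ci == 12:
        pools[MDM2M] -= 1
    elif ci == 13:
        pools[MDM2U] += 1
    elif ci == 14:
        pools[P21M] += 1
    elif ci == 15:
        pools[P21M] -= 1
    elif ci == 16:
        pools[P21] += 1
    elif ci == 17:
        pools[P21] -= 1
    elif ci == 18:
        pools[GADD] += 1
    elif ci == 19:
        pools[GADD] -= 1
    elif ci == 20:
        pools[KU_R] -= 1; pools[DEG_KU] += 1
    elif ci == 21:
        pools[PARPF] -= 1; pools[DEG_PARP] += 1
    elif ci == 22:
        pools[SEN_INT] += 1
    elif ci == 23:
        pools[SEN_INT] -= 1
    elif ci == 24:
        pools[SEN_STATE] = 1.0
        sen_switch_time[0] = t


@njit(cache=True)
def _fire_site(code, i, site, h2x, bnd, pools, t,
               focus_log, open_focus, focus_n,
               break_log, open_break, break_n):
    if code == 0 or code == 1:  # new break from ROS
        pools[ROS] -= 1
        site[i] = S_SDSB if code == 0 else S_CDSB
        r = break_n[0]
        if r >= break_log.shape[0]:
            return -1
        break_log[r, 0] = i
        break_log[r, 1] = t
        break_log[r, 2] = np.nan
        break_log[r, 3] = site[i]
        open_break[i] = r
        break_n[0] = r + 1
    elif code == 2:  # sdsb -> cdsb under oxidative attack
        pools[ROS] -= 1
        site[i] = S_CDSB
        if open_break[i] >= 0:
            break_log[open_break[i], 3] = S_CDSB
    elif code == 3 or code == 4:  # H2AX phosphorylation (pool ATM / on-site PK)
        h2x[i] = H_P
    elif code == 5:
        h2x[i] = H_U
    elif code == 6:  # ATM recruitment to p-H2AX
        pools[ATM1] -= 1
        h2x[i] = H_PA
    elif code == 7:  # focus maturation
        h2x[i] = H_FA
        r = focus_n[0]
        if r >= focus_log.shape[0]:
            return -1
        focus_log[r, 0] = i
        focus_log[r, 1] = t
        focus_log[r, 2] = np.nan
        open_focus[i] = r
        focus_n[0] = r + 1
    elif code == 8:  # focus resolution: disassemble to p-H2AX, release ATM
        h2x[i] = H_P
        pools[ATM1] += 1
        if open_focus[i] >= 0:
            focus_log[open_focus[i], 2] = t
            open_focus[i] = -1
    elif code == 9:
        pools[KU_R] -= 1
        bnd[i] = B_KR
    elif code == 10:
        pools[KU_O] -= 1
        bnd[i] = B_KO
    elif code == 11:
        pools[PARPF] -= 1
        bnd[i] = B_PARP
    elif code == 12:
        pools[KU_R] += 1
        bnd[i] = B_NONE
    elif code == 13:
        pools[KU_O] += 1
        bnd[i] = B_NONE
    elif code == 14:  # on-site Ku oxidation
        pools[ROS] -= 1
        if bnd[i] == B_KR:
            bnd[i] = B_KO
        elif bnd[i] == B_KRPU:
            bnd[i] = B_KOPU
        elif bnd[i] == B_KRPP:
            bnd[i] = B_KOPP
        else:
            bnd[i] = B_KOPL
    elif code == 15:  # on-site Ku re-reduction
        if bnd[i] == B_KO:
            bnd[i] = B_KR
        elif bnd[i] == B_KOPU:
            bnd[i] = B_KRPU
        elif bnd[i] == B_KOPP:
            bnd[i] = B_KRPP
        else:
            bnd[i] = B_KRPL
    elif code == 16:
        pools[PK_U] -= 1
        bnd[i] = B_KRPU if bnd[i] == B_KR else B_KOPU
    elif code == 17:
        pools[PK_P] -= 1
        bnd[i] = B_KRPP if bnd[i] == B_KR else B_KOPP
    elif code == 18:  # DNA-PKcs dissociation (keeps its phosphostate)
        if bnd[i] == B_KRPU:
            pools[PK_U] += 1; bnd[i] = B_KR
        elif bnd[i] == B_KRPP:
            pools[PK_P] += 1; bnd[i] = B_KR
        elif bnd[i] == B_KOPU:
            pools[PK_U] += 1; bnd[i] = B_KO
        else:
            pools[PK_P] += 1; bnd[i] = B_KO
    elif code == 19:
        bnd[i] = B_KRPP if bnd[i] == B_KRPU else B_KOPP
    elif code == 20:
        bnd[i] = B_KRPU if bnd[i] == B_KRPP else B_KOPU
    elif code == 21:
        pools[LIIV] -= 1
        bnd[i] = B_KRPL if bnd[i] == B_KRPP else B_KOPL
    elif code == 22:
        pools[LIIV] += 1
        bnd[i] = B_KRPP if bnd[i] == B_KRPL else B_KOPP
    elif code == 23:  # D-NHEJ ligation (requires formed focus)
        pools[LIIV] += 1
        pools[PK_U] += 1  # autophosphorylation reset on release
        if bnd[i] == B_KRPL:
            pools[KU_R] += 1
        else:
            pools[KU_O] += 1
        bnd[i] = B_NONE
        site[i] = S_OK
        if open_break[i] >= 0:
            break_log[open_break[i], 2] = t
            open_break[i] = -1
    elif code == 24:  # oxidized Ku destabilizes the whole complex
        pools[KU_O] += 1
        if bnd[i] == B_KOPU:
            pools[PK_U] += 1
        else:
            pools[PK_P] += 1
        bnd[i] = B_NONE
    elif code == 25:
        pools[PARPF] += 1
        bnd[i] = B_NONE
    elif code == 26:
        pools[LIIII] -= 1
        bnd[i] = B_PARPL
    elif code == 27:
        pools[LIIII] += 1
        bnd[i] = B_PARP
    elif code == 28:  # B-NHEJ ligation (requires formed focus)
        pools[LIIII] += 1
        pools[PARPF] += 1
        bnd[i] = B_NONE
        site[i] = S_OK
        if open_break[i] >= 0:
            break_log[open_break[i], 2] = t
            open_break[i] = -1
    return 0
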