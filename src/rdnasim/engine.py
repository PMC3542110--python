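"""Array-level simulation engine.

The whole population lives in one padded ``int64`` matrix: one row per X
chromosome (females hold two consecutive rows, males one), with the same unit
encoding as :mod:`rdnasim._kernels` (0 uninserted, +label full-length,
-label truncated) and a per-row length vector.  One numba kernel advances the
population a block of generations; the Python driver in
:mod:`rdnasim.population` handles seeding, capacity growth and bookkeeping.

Per-generation event order (fixed contract):

1. place the transcription domain on every chromosome;
2. retrotransposition (domain mode: Poisson(p * sqrt(n_FL)) per individual
   with n_FL pooled over the individual's domain(s) and the target
   chromosome drawn uniformly; legacy modes: Bernoulli per
   full-length-bearing locus, uniform position);
3. loop deletions per chromosome;
4. interchromosomal exchange (ICE) in females, domains re-placed locally;
5. re-place all domains;
6. fitness -> gamete count per individual;
7. gametes are emitted into the pool (each female gamete picks one of her
   chromosomes by fair coin) and 3N/2 are drawn without replacement; the
   first N pair into N/2 females, the remaining N/2 become males;
8. each transmitted chromosome independently undergoes a sister-chromatid
   exchange with probability ``sce_rate`` (each meiosis is one
   post-replication exchange opportunity); one of the two crossover
   products, chosen by fair coin, is what the offspring inherits.

Localization scales: crossover cuts are Normal around the domain midpoint
with sigma = S * locus length (the S range spans "within the domain" to
"across the whole locus"); insertion positions and deletion midpoints are
domain-proximal events and use sigma = S * domain size.

The kernel uses numba's internal global random state; seed it once per
replicate with :func:`seed_engine` and successive kernel calls continue the
same stream, so chunk boundaries do not affect trajectories.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from ._kernels import crossover_fill, domain_counts, largest_run, place_domain_kernel

MODE_DOMAIN = 0
MODE_LEGACY_UNIFORM = 1
MODE_LEGACY_CENTERED = 2

STATUS_OK = 0
STATUS_POP_EXTINCT = 1

MODE_CODES = {"domain": MODE_DOMAIN, "legacy_uniform": MODE_LEGACY_UNIFORM,
              "legacy_centered": MODE_LEGACY_CENTERED}

#: columns of the per-generation series matrix
SERIES_COLUMNS = ("generation", "mean_locus_size", "mean_r2_per_locus",
                  "mean_full_length_per_locus", "fraction_active_males",
                  "fraction_active_females", "r2_extinct")


@njit(cache=True)
def seed_engine(seed):
    np.random.seed(seed)


@njit(cache=True)
def _signed_offset(max_offset):
    k = np.random.randint(1, max_offset + 1)
    if np.random.random() < 0.5:
        return k
    return -k


@njit(cache=True)
def _sample_pos(center, sigma, lo, hi, uniform):
    """Localized integer position in [lo, hi]; clamped after 1000 misses."""
    if uniform:
        return np.random.randint(lo, hi + 1)
    for _ in range(1000):
        p = int(np.floor(np.random.normal(center, sigma) + 0.5))
        if lo <= p <= hi:
            return p
    p = int(np.floor(center + 0.5))
    if p < lo:
        p = lo
    if p > hi:
        p = hi
    return p


@njit(cache=True)
def _insert_element(row, L, dom_start, dom_size, s_retro, trunc_frac, mode,
                    label):
    """Try to place one new R2 on a chromosome; returns hit position or -1.

    Domain mode localizes the insertion around the domain midpoint
    (sigma = s_retro * domain size); legacy modes draw uniformly.  Up to
    1000 tries for an uninserted unit, otherwise the event is dropped — an
    existing insertion is never overwritten.
    """
    center = dom_start + (dom_size - 1) / 2.0
    sigma = s_retro * dom_size
    for _ in range(1000):
        if mode == MODE_DOMAIN:
            pos = int(np.floor(np.random.normal(center, sigma) + 0.5))
        else:
            pos = np.random.randint(0, L)
        if 0 <= pos < L and row[pos] == 0:
            if np.random.random() < trunc_frac:
                row[pos] = -label
            else:
                row[pos] = label
            return pos
    return -1


@njit(cache=True)
def run_generations(units, lengths, buf_units, buf_lengths,
                    n_f, n_m, n_gen, gen0, total_gens,
                    mode, D, D_f, F_req, f_max,
                    sce_rate, ice_rate, max_offset, s_cross,
                    del_base, del_elem, del_max, s_del,
                    retro_p, trunc_frac, s_retro,
                    legacy_retro_p, legacy_F_req,
                    label_counter, record_every, out_series):
    """Advance the population ``n_gen`` generations in place.

    Returns ``(label_counter, status, n_recorded, bottlenecks, skipped)``.
    ``skipped`` counts crossover events abandoned because no valid alignment
    fit the capacity of the padded matrix.
    """
    R = 2 * n_f + n_m
    n_ind = n_f + n_m
    cap = units.shape[1]
    uniform_cuts = mode == MODE_LEGACY_UNIFORM

    dom_start = np.zeros(R, dtype=np.int64)
    dom_size = np.zeros(R, dtype=np.int64)
    n_full_dom = np.zeros(R, dtype=np.int64)
    n_un_dom = np.zeros(R, dtype=np.int64)
    gam = np.zeros(n_ind, dtype=np.int64)
    pool = np.zeros(n_ind * f_max, dtype=np.int64)
    tmp1 = np.zeros(cap, dtype=np.int64)
    tmp2 = np.zeros(cap, dtype=np.int64)

    n_rec = 0
    bottlenecks = 0
    skipped = 0

    for g in range(n_gen):
        gen = gen0 + g + 1

        # (1) place domains
        for r in range(R):
            Dr = D_f if r < 2 * n_f else D
            s, d = place_domain_kernel(units[r], lengths[r], Dr)
            dom_start[r] = s
            dom_size[r] = d
            nf, nt, nu = domain_counts(units[r], s, d)
            n_full_dom[r] = nf
            n_un_dom[r] = nu

        # (2) retrotransposition
        if mode == MODE_DOMAIN:
            for i in range(n_ind):
                if i < n_f:
                    r0 = 2 * i
                    nfl = n_full_dom[r0] + n_full_dom[r0 + 1]
                    n_chrom = 2
                else:
                    r0 = 2 * n_f + (i - n_f)
                    nfl = n_full_dom[r0]
                    n_chrom = 1
                if nfl <= 0:
                    continue
                n_ev = np.random.poisson(retro_p * np.sqrt(nfl))
                for _ in range(n_ev):
                    c = r0 + np.random.randint(0, n_chrom)
                    label_counter += 1
                    pos = _insert_element(units[c], lengths[c], dom_start[c],
                                          dom_size[c], s_retro, trunc_frac,
                                          mode, label_counter)
                    if pos < 0:
                        label_counter -= 1
                    elif dom_start[c] <= pos < dom_start[c] + dom_size[c]:
                        n_un_dom[c] -= 1
                        if units[c][pos] > 0:
                            n_full_dom[c] += 1
        else:
            for r in range(R):
                has_fl = False
                for i in range(lengths[r]):
                    if units[r][i] > 0:
                        has_fl = True
                        break
                if has_fl and np.random.random() < legacy_retro_p:
                    label_counter += 1
                    pos = _insert_element(units[r], lengths[r], dom_start[r],
                                          dom_size[r], s_retro, trunc_frac,
                                          mode, label_counter)
                    if pos < 0:
                        label_counter -= 1

        # (3) loop deletions
        for r in range(R):
            L = lengths[r]
            if L < 2:
                continue
            if mode == MODE_DOMAIN:
                p = del_base * L + del_elem * n_full_dom[r]
            else:
                p = del_base * L
            if p > 1.0:
                p = 1.0
            if np.random.random() >= p:
                continue
            size = np.random.randint(1, del_max + 1)
            center = dom_start[r] + (dom_size[r] - 1) / 2.0
            mid = _sample_pos(center, s_del * dom_size[r], 0, L - 1,
                              mode != MODE_DOMAIN)
            start = mid - size // 2
            if start < 0:
                start = 0
            end = start + size
            if end > L:
                end = L
            cut = end - start
            if cut >= 1 and L - cut >= 1:
                for i in range(end, L):
                    units[r][i - cut] = units[r][i]
                lengths[r] = L - cut

        # (4) ICE in females (domains re-placed locally: deletions above may
        # have shifted coordinates)
        for i in range(n_f):
            if np.random.random() >= ice_rate:
                continue
            a = 2 * i
            b = a + 1
            La = lengths[a]
            Lb = lengths[b]
            sa, da = place_domain_kernel(units[a], La, D_f)
            sb, db = place_domain_kernel(units[b], Lb, D_f)
            ca = sa + (da - 1) / 2.0
            cb = sb + (db - 1) / 2.0
            ok = False
            shift = 0
            for _ in range(1000):
                k = _signed_offset(max_offset)
                shift = int(np.floor(cb - ca + 0.5)) + k
                if 1 - La < shift < Lb:
                    if Lb - shift <= cap and La + shift <= cap:
                        ok = True
                        break
            if not ok:
                skipped += 1
                continue
            lo = 0 if -shift < 0 else -shift
            hi = La if La < Lb - shift else Lb - shift
            if mode == MODE_LEGACY_CENTERED:
                center = La / 2.0
            else:
                center = ca
            cut = _sample_pos(center, s_cross * La, lo, hi, uniform_cuts)
            l1, l2 = crossover_fill(units[a], La, units[b], Lb,
                                    cut, cut + shift, tmp1, tmp2)
            units[a][:l1] = tmp1[:l1]
            lengths[a] = l1
            units[b][:l2] = tmp2[:l2]
            lengths[b] = l2

        # (5) re-place domains
        for r in range(R):
            Dr = D_f if r < 2 * n_f else D
            s, d = place_domain_kernel(units[r], lengths[r], Dr)
            dom_start[r] = s
            dom_size[r] = d
            nf, nt, nu = domain_counts(units[r], s, d)
            n_full_dom[r] = nf
            n_un_dom[r] = nu

        # (6) fitness -> gamete counts (round half away from zero)
        for i in range(n_ind):
            if mode == MODE_DOMAIN:
                if i < n_f:
                    u = n_un_dom[2 * i] + n_un_dom[2 * i + 1]
                else:
                    u = n_un_dom[2 * n_f + (i - n_f)]
                req = F_req
            else:
                if i < n_f:
                    u = 0
                    for r in (2 * i, 2 * i + 1):
                        for j in range(lengths[r]):
                            if units[r][j] == 0:
                                u += 1
                else:
                    r = 2 * n_f + (i - n_f)
                    u = 0
                    for j in range(lengths[r]):
                        if units[r][j] == 0:
                            u += 1
                req = legacy_F_req
            frac = 1.0 if req == 0 else u / req
            if frac > 1.0:
                frac = 1.0
            gam[i] = int(np.floor(f_max * frac + 0.5))

        # series recording (state at reproduction, after all mutation steps)
        if gen % record_every == 0 or gen == total_gens:
            tot_units = 0
            tot_r2 = 0
            tot_fl = 0
            for r in range(R):
                tot_units += lengths[r]
                for j in range(lengths[r]):
                    if units[r][j] != 0:
                        tot_r2 += 1
                        if units[r][j] > 0:
                            tot_fl += 1
            act_m = 0
            for j in range(n_m):
                if n_full_dom[2 * n_f + j] > 0:
                    act_m += 1
            act_f = 0
            for i in range(n_f):
                if n_full_dom[2 * i] > 0 or n_full_dom[2 * i + 1] > 0:
                    act_f += 1
            out_series[n_rec, 0] = gen
            out_series[n_rec, 1] = tot_units / R
            out_series[n_rec, 2] = tot_r2 / R
            out_series[n_rec, 3] = tot_fl / R
            out_series[n_rec, 4] = act_m / n_m
            out_series[n_rec, 5] = act_f / n_f
            out_series[n_rec, 6] = 1.0 if tot_r2 == 0 else 0.0
            n_rec += 1


        # (7) build the gamete pool and draw the next generation
        total = 0
        for i in range(n_f):
            g_i = gam[i]
            if g_i > 0:
                ka = np.random.binomial(g_i, 0.5)
                for _ in range(ka):
                    pool[total] = 2 * i
                    total += 1
                for _ in range(g_i - ka):
                    pool[total] = 2 * i + 1
                    total += 1
        for j in range(n_m):
            g_i = gam[n_f + j]
            for _ in range(g_i):
                pool[total] = 2 * n_f + j
                total += 1

        if total == 0:
            return label_counter, STATUS_POP_EXTINCT, n_rec, bottlenecks, skipped
        if total >= R:
            for t in range(R):
                u = t + np.random.randint(0, total - t)
                swap = pool[t]
                pool[t] = pool[u]
                pool[u] = swap
        else:
            bottlenecks += 1
            for t in range(R):
                pool[t] = pool[np.random.randint(0, total)]
        # (8) each transmitted gamete chromosome independently undergoes an
        # SCE with probability sce_rate (one meiosis = one post-replication
        # exchange opportunity); one of the two products is transmitted.
        for t in range(R):
            src = pool[t]
            L = lengths[src]
            done_sce = False
            if L >= 2 and np.random.random() < sce_rate:
                k = _signed_offset(max_offset)
                if abs(k) < L:
                    lo = 0 if -k < 0 else -k
                    hi = L if L < L - k else L - k
                    if mode == MODE_LEGACY_CENTERED:
                        center = L / 2.0
                    else:
                        center = dom_start[src] + (dom_size[src] - 1) / 2.0
                    cut = _sample_pos(center, s_cross * L, lo, hi,
                                      uniform_cuts)
                    cb2 = cut + k
                    if np.random.random() < 0.5:
                        new_len = L - k
                        if 1 <= new_len <= cap:
                            j = 0
                            for x in range(cut):
                                buf_units[t][j] = units[src][x]
                                j += 1
                            for x in range(cb2, L):
                                buf_units[t][j] = units[src][x]
                                j += 1
                            buf_lengths[t] = new_len
                            done_sce = True
                        else:
                            skipped += 1
                    else:
                        new_len = L + k
                        if 1 <= new_len <= cap:
                            j = 0
                            for x in range(cb2):
                                buf_units[t][j] = units[src][x]
                                j += 1
                            for x in range(cut, L):
                                buf_units[t][j] = units[src][x]
                                j += 1
                            buf_lengths[t] = new_len
                            done_sce = True
                        else:
                            skipped += 1
            if not done_sce:
                buf_units[t][:L] = units[src][:L]
                buf_lengths[t] = L
        for t in range(R):
            Ls = buf_lengths[t]
            units[t][:Ls] = buf_units[t][:Ls]
            lengths[t] = Ls

    return label_counter, STATUS_OK, n_rec, bottlenecks, skipped


#: columns of the final per-locus record matrix
RECORD_COLUMNS = ("individual", "sex_code", "chromosome", "locus_size",
                  "n_full", "n_trunc", "largest_free_block", "domain_start",
                  "domain_size", "n_full_in_domain", "n_trunc_in_domain",
                  "n_uninserted_in_domain")


@njit(cache=True)
def final_state_records(units, lengths, n_f, n_m, D, D_f):
    """Per-locus end-state table (one row per chromosome), as int64 matrix."""
    R = 2 * n_f + n_m
    out = np.zeros((R, 12), dtype=np.int64)
    for r in range(R):
        L = lengths[r]
        if r < 2 * n_f:
            ind = r // 2
            sex = 0
            chrom = r % 2
            Dr = D_f
        else:
            ind = n_f + (r - 2 * n_f)
            sex = 1
            chrom = 0
            Dr = D
        s, d = place_domain_kernel(units[r], L, Dr)
        nf, nt, nu = domain_counts(units[r], s, d)
        _, block = largest_run(units[r], L)
        n_full = 0
        n_trunc = 0
        for j in range(L):
            if units[r][j] > 0:
                n_full += 1
            elif units[r][j] < 0:
                n_trunc += 1
        out[r, 0] = ind
        out[r, 1] = sex
        out[r, 2] = chrom
        out[r, 3] = L
        out[r, 4] = n_full
        out[r, 5] = n_trunc
        out[r, 6] = block
        out[r, 7] = s
        out[r, 8] = d
        out[r, 9] = nf
        out[r, 10] = nt
        out[r, 11] = nu
    return out
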