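"""Numba kernels for the lattice dynamics.

The lattice is stored as flat arrays over a padded grid of shape
``(height + 2, width + 2)``; the one-site-thick padding ring holds the
scenario's static padding species (it contributes to energies but never
swaps or reacts).  Species codes (maintained incrementally in ``code``)::

    0  unbound RBP           (rna == 0)
    1  RNA-bound RBP         (rna >= 1)
    2  inactive chromatin
    3  active chromatin
    4  inert (padding "none")

Randomness comes from an explicit splitmix64 stream carried in a one-element
uint64 array, so every run is exactly reproducible from its seed; draws
happen in a fixed, documented order (proposal index, then the acceptance
uniform only when 0 < P < 1; chemistry draws one uniform per reaction
channel per eligible site in row-major site order, chains first).
"""

from __future__ import annotations

import numpy as np
from numba import njit

KIND_RBP = 0
KIND_CHROM = 1
KIND_INERT = 2

# proposal/energy neighborhood: 8 Chebyshev neighbors; offsets are added to
# flat indices on the padded grid (set up by the caller as dy * Wp + dx)
NEIGHBOR_STEPS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)

# swap outcome codes
REJ_PADDING = 0
REJ_TETHER = 1
REJ_CONNECTIVITY = 2
REJ_ENERGY = 3
ACCEPTED = 4

# ---------------------------------------------------------------------------
# splitmix64 PRNG (explicit state => reproducible, fast)

_G = np.uint64(0x9E3779B97F4A7C15)
_C1 = np.uint64(0xBF58476D1CE4E5B9)
_C2 = np.uint64(0x94D049BB133111EB)
_S30 = np.uint64(30)
_S27 = np.uint64(27)
_S31 = np.uint64(31)
_S32 = np.uint64(32)
_S11 = np.uint64(11)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(cache=True, inline="always")
def _u64(rs):
    rs[0] = rs[0] + _G
    z = rs[0]
    z = (z ^ (z >> _S30)) * _C1
    z = (z ^ (z >> _S27)) * _C2
    return z ^ (z >> _S31)


@njit(cache=True, inline="always")
def _randint(rs, n):
    """Uniform int in [0, n) for n < 2**32 (multiply-shift on the top bits)."""
    return np.int64(((_u64(rs) >> _S32) * np.uint64(n)) >> _S32)


@njit(cache=True, inline="always")
def _randf(rs):
    return np.float64(_u64(rs) >> _S11) * _INV53


@njit(cache=True)
def rand_uniform(rs):
    """Public helper: one uniform draw from the stream (testing hook)."""
    return _randf(rs)


@njit(cache=True, inline="always")
def _binomial(rs, n, p):
    """Exact Binomial(n, p) draw by CDF inversion (one uniform).

    Expected work is O(1 + n*p); used for per-transcript decay where each
    transcript decays independently with small probability p per interval.
    """
    u = _randf(rs)
    q = 1.0 - p
    c = np.exp(n * np.log(q))
    t = c
    k = 0
    while u > c and k < n:
        k += 1
        t *= (n - k + 1) / k * (p / q)
        c += t
    return k


# ---------------------------------------------------------------------------
# energetics


@njit(cache=True, fastmath=True, inline="always")
def _delta_e(code, dmat, offs, a, b):
    """Energy change of swapping the occupants of interior sites a and b.

    Sums pair costs over the 8-neighborhoods of both sites before and after;
    the a-b partner pair itself cancels, and shared neighbors cancel
    arithmetically.  ``dmat`` holds precomputed cost differences,
    ``dmat[(ca*5 + cb)*5 + cn] = cost[cb, cn] - cost[ca, cn]``.
    The partner terms are summed branchlessly and subtracted afterwards
    (t with a + offs[t] == b contributes dmat[kab + cb], and vice versa).
    """
    ca = np.int64(code[a])
    cb = np.int64(code[b])
    kab = (ca * 5 + cb) * 5
    kba = (cb * 5 + ca) * 5
    d = 0.0
    for t in range(8):
        d += dmat[kab + np.int64(code[a + offs[t]])]
        d += dmat[kba + np.int64(code[b + offs[t]])]
    return d - dmat[kab + cb] - dmat[kba + ca]


@njit(cache=True, inline="always")
def _chain_move_ok(chain, cidx, ch_sites, ch_len, yco, xco, s, newpos, a, b):
    """True if moving the chain member at ``s`` to ``newpos`` keeps its
    links within Chebyshev distance 1 (accounting for the partner's move).

    ``yco``/``xco`` are per-flat-index coordinate lookup tables.
    """
    cid = chain[s]
    if cid < 0:
        return True
    idx = cidx[s]
    ny = yco[newpos]
    nx = xco[newpos]
    for step in range(-1, 2, 2):
        j = idx + step
        if j < 0 or j >= ch_len[cid]:
            continue
        p = ch_sites[cid, j]
        # a chain neighbor sitting on one of the swapped sites moves too
        if p == a:
            p = b
        elif p == b:
            p = a
        dy = ny - yco[p]
        if dy < 0:
            dy = -dy
        dx = nx - xco[p]
        if dx < 0:
            dx = -dx
        if (dy if dy > dx else dx) > 1:
            return False
    return True


@njit(cache=True, inline="always")
def _p_accept(dE, rule, delta_e_min):
    """Acceptance probability.  rule 0: Metropolis min(1, e^-dE);
    rule 1: normalized min(1, e^(dE_min - dE))."""
    if rule == 0:
        x = -dE
    else:
        x = delta_e_min - dE
    if x >= 0.0:
        return 1.0
    return np.exp(x)


@njit(cache=True, inline="always")
def _do_swap(kind, active, rna, code, chain, cidx, teth, bring, ch_sites,
             tether_on, a, b):
    """Exchange the occupants of a and b (transcripts travel with their
    site) and refresh chain bookkeeping and boundary tethering."""
    kind[a], kind[b] = kind[b], kind[a]
    active[a], active[b] = active[b], active[a]
    rna[a], rna[b] = rna[b], rna[a]
    code[a], code[b] = code[b], code[a]
    chain[a], chain[b] = chain[b], chain[a]
    cidx[a], cidx[b] = cidx[b], cidx[a]
    if chain[a] >= 0:
        ch_sites[chain[a], cidx[a]] = a
    if chain[b] >= 0:
        ch_sites[chain[b], cidx[b]] = b
    if tether_on == 1:
        if kind[a] == KIND_CHROM and bring[a] == 1:
            teth[a] = 1
        if kind[b] == KIND_CHROM and bring[b] == 1:
            teth[b] = 1


@njit(cache=True)
def attempt_once(kind, active, rna, code, chain, cidx, teth, valid, bring,
                 ch_sites, ch_len, dmat, offs, yco, xco, tether_on,
                 rule, delta_e_min, a, b, u):
    """Single externally-driven attempt (used by the Python-level API).

    ``u`` is the acceptance uniform; it is only consulted when 0 < P < 1.
    Returns (status, dE, p).
    """
    if valid[b] == 0:
        return REJ_PADDING, 0.0, 0.0
    if teth[a] == 1 or teth[b] == 1:
        return REJ_TETHER, 0.0, 0.0
    if chain[a] >= 0 or chain[b] >= 0:
        if not _chain_move_ok(chain, cidx, ch_sites, ch_len, yco, xco, a, b, a, b):
            return REJ_CONNECTIVITY, 0.0, 0.0
        if not _chain_move_ok(chain, cidx, ch_sites, ch_len, yco, xco, b, a, a, b):
            return REJ_CONNECTIVITY, 0.0, 0.0
    dE = 0.0 if code[a] == code[b] else _delta_e(code, dmat, offs, a, b)
    p = _p_accept(dE, rule, delta_e_min)
    if p >= 1.0 or u < p:
        _do_swap(kind, active, rna, code, chain, cidx, teth, bring, ch_sites,
                 tether_on, a, b)
        return ACCEPTED, dE, p
    return REJ_ENERGY, dE, p


@njit(cache=True, fastmath=True)
def swap_batch(kind, active, rna, code, chain, cidx, teth, valid, bring,
               ch_sites, ch_len, dmat, offs, interior, yco, xco, tether_on,
               rule, delta_e_min, n_attempts, rs,
               exp_qinv=0.0, exp_table=np.zeros(1)):
    """Run ``n_attempts`` random swap proposals; returns accepted count.

    When every pair cost is an integer multiple of a common quantum,
    ``exp_qinv``/``exp_table`` provide a tabulated Metropolis factor
    (``exp_table[round(dE * exp_qinv)] = exp(-dE)``), avoiding an exp per
    uphill proposal; ``exp_qinv = 0`` falls back to the closed form.
    """
    n8 = interior.shape[0] * 8
    accepted = 0
    for _ in range(n_attempts):
        r = _randint(rs, n8)
        a = interior[r >> 3]
        b = a + offs[r & 7]
        if teth[a] == 1 or teth[b] == 1:
            continue  # tethered or padding (the padding ring is tethered)
        if code[a] == code[b]:
            if chain[a] < 0 and chain[b] < 0:
                # identical free species: the exchange only moves transcripts
                if rna[a] != rna[b]:
                    rna[a], rna[b] = rna[b], rna[a]
                accepted += 1
                continue
            if not _chain_move_ok(chain, cidx, ch_sites, ch_len, yco, xco, a, b, a, b):
                continue
            if not _chain_move_ok(chain, cidx, ch_sites, ch_len, yco, xco, b, a, a, b):
                continue
            dE = 0.0
        else:
            if chain[a] >= 0 or chain[b] >= 0:
                if not _chain_move_ok(chain, cidx, ch_sites, ch_len, yco, xco, a, b, a, b):
                    continue
                if not _chain_move_ok(chain, cidx, ch_sites, ch_len, yco, xco, b, a, a, b):
                    continue
            dE = _delta_e(code, dmat, offs, a, b)
        if rule == 0 and exp_qinv > 0.0:
            if dE > 0.0:
                p = exp_table[np.int64(dE * exp_qinv + 0.5)]
                if _randf(rs) >= p:
                    continue
        else:
            p = _p_accept(dE, rule, delta_e_min)
            if p < 1.0:
                if _randf(rs) >= p:
                    continue
        _do_swap(kind, active, rna, code, chain, cidx, teth, bring, ch_sites,
                 tether_on, a, b)
        accepted += 1
    return accepted


@njit(cache=True)
def chem_step(kind, active, rna, code, chain, valid, ch_perm, ch_len, offs,
              interior, p_chrom_on, p_chrom_off, p_prod, p_transfer,
              p_decay, p_chain_on, p_chain_off, decay_on_chrom, counts, rs):
    """One chemical interval: chain switching, then per-site conversions in
    row-major order (activation/deactivation, production, transfer, decay).

    ``counts`` accumulates [activations, deactivations, productions,
    transfers, decays, chain_on, chain_off].
    """
    if p_chain_on > 0.0 or p_chain_off > 0.0:
        for c in range(ch_perm.shape[0]):
            if ch_len[c] == 0:
                continue
            if ch_perm[c] == 1:
                if p_chain_off > 0.0 and _randf(rs) < p_chain_off:
                    ch_perm[c] = 0
                    counts[6] += 1
            else:
                if p_chain_on > 0.0 and _randf(rs) < p_chain_on:
                    ch_perm[c] = 1
                    counts[5] += 1
    for ii in range(interior.shape[0]):
        i = interior[ii]
        k = kind[i]
        if k == KIND_CHROM:
            if active[i] == 1:
                if p_chrom_off > 0.0 and _randf(rs) < p_chrom_off:
                    active[i] = 0
                    code[i] = 2
                    counts[1] += 1
            else:
                if (
                    p_chrom_on > 0.0
                    and chain[i] >= 0
                    and ch_perm[chain[i]] == 1
                    and _randf(rs) < p_chrom_on
                ):
                    active[i] = 1
                    code[i] = 3
                    counts[0] += 1
            if active[i] == 1 and p_prod > 0.0 and _randf(rs) < p_prod:
                rna[i] += 1
                counts[2] += 1
            if rna[i] > 0 and p_transfer > 0.0 and _randf(rs) < p_transfer:
                # uniform choice among interior RBP neighbors; no-op if none
                nrbp = 0
                for t in range(8):
                    n = i + offs[t]
                    if valid[n] == 1 and kind[n] == KIND_RBP:
                        nrbp += 1
                if nrbp > 0:
                    pick = _randint(rs, nrbp)
                    seen = 0
                    for t in range(8):
                        n = i + offs[t]
                        if valid[n] == 1 and kind[n] == KIND_RBP:
                            if seen == pick:
                                rna[i] -= 1
                                rna[n] += 1
                                code[n] = 1
                                counts[3] += 1
                                break
                            seen += 1
        if rna[i] > 0 and p_decay > 0.0:
            if k == KIND_CHROM and decay_on_chrom == 0:
                continue
            lost = _binomial(rs, rna[i], p_decay)
            if lost > 0:
                rna[i] -= lost
                counts[4] += lost
                if rna[i] == 0 and k == KIND_RBP:
                    code[i] = 0


@njit(cache=True)
def run_chunk(kind, active, rna, code, chain, cidx, teth, valid, bring,
              ch_sites, ch_len, ch_perm, dmat, offs, interior, yco, xco,
              tether_on, rule, delta_e_min, n_steps, swaps_per_step,
              do_chem, p_chrom_on, p_chrom_off, p_prod, p_transfer,
              p_decay, p_chain_on, p_chain_off, decay_on_chrom, counts, rs,
              exp_qinv=0.0, exp_table=np.zeros(1)):
    """``n_steps`` chemical intervals of ``swaps_per_step`` swap attempts
    followed (when ``do_chem``) by one chemical update each."""
    accepted = 0
    for _ in range(n_steps):
        accepted += swap_batch(
            kind, active, rna, code, chain, cidx, teth, valid, bring,
            ch_sites, ch_len, dmat, offs, interior, yco, xco, tether_on,
            rule, delta_e_min, swaps_per_step, rs, exp_qinv, exp_table,
        )
        if do_chem == 1:
            chem_step(
                kind, active, rna, code, chain, valid, ch_perm, ch_len, offs,
                interior, p_chrom_on, p_chrom_off, p_prod, p_transfer,
                p_decay, p_chain_on, p_chain_off, decay_on_chrom, counts, rs,
            )
    return accepted
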