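"""Compiled numeric cores for the entropy estimators.

The multiscale feature pipeline evaluates every estimator on a few thousand
short coarse-grained series per subject, so the per-call cost must stay in
the microsecond range; every counting/pairwise core therefore lives here as
a cached numba kernel.  The pure-python wrappers in :mod:`cmsehrv.entropy`
own parameter handling and edge cases; independent brute-force references
used for verification live with the tests.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

LOG2 = math.log(2.0)


@njit(cache=True, inline="always")
def _entropy_bits_sorted(codes):
    """Shannon entropy (bits) of run-lengths in a *sorted* code array."""
    n = codes.shape[0]
    if n == 0:
        return 0.0
    h = 0.0
    run = 1
    for i in range(1, n):
        if codes[i] == codes[i - 1]:
            run += 1
        else:
            p = run / n
            h -= p * math.log(p)
            run = 1
    p = run / n
    h -= p * math.log(p)
    return h / LOG2


# ---------------------------------------------------------------------------
# template-matching family


@njit(cache=True)
def sampen_counts(x, m, r):
    """Pair counts (A, B) for sample entropy: templates of length m and m+1
    both at offsets 0..n-m-1 (Richman & Moorman), self-matches excluded,
    Chebyshev distance."""
    n = x.shape[0]
    nt = n - m
    A = 0
    B = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return A, B


@njit(cache=True)
def apen_phi(x, m, r):
    """Pincus Phi^m(r): mean over i of ln(C_i/(n-m+1)), self-match included;
    symmetric pair counting."""
    n = x.shape[0]
    nt = n - m + 1
    c = np.ones(nt)
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            ok = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    ok = False
                    break
            if ok:
                c[i] += 1.0
                c[j] += 1.0
    s = 0.0
    for i in range(nt):
        s += math.log(c[i] / nt)
    return s / nt


@njit(cache=True)
def fuzzy_mean_membership(U, r, nexp):
    """Mean exp(-(d/r)^nexp) over template pairs i<j; U rows mean-centred.

    The ratio form keeps the estimator invariant to amplitude scaling when
    the tolerance is expressed as a fraction of the series SD."""
    nt = U.shape[0]
    m = U.shape[1]
    tot = 0.0
    square = nexp == 2.0
    inv = 1.0 / r
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                diff = abs(U[i, k] - U[j, k])
                if diff > d:
                    d = diff
            ratio = d * inv
            if square:
                tot += math.exp(-(ratio * ratio))
            else:
                tot += math.exp(-(ratio ** nexp))
    npairs = nt * (nt - 1) // 2
    return tot / npairs


@njit(cache=True)
def disten_histogram(x, m, nbins):
    """Equal-width histogram over [0, dmax] of pairwise Chebyshev distances
    between m-embeddings; two passes to avoid the n^2/2 distance array."""
    n = x.shape[0]
    nt = n - m + 1
    dmax = 0.0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            if d > dmax:
                dmax = d
    counts = np.zeros(nbins, dtype=np.int64)
    if dmax == 0.0:
        return counts, dmax
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                diff = abs(x[i + k] - x[j + k])
                if diff > d:
                    d = diff
            b = int(d / dmax * nbins)  # floor((d/dmax)*B), capped
            if b >= nbins:
                b = nbins - 1
            counts[b] += 1
    return counts, dmax


# ---------------------------------------------------------------------------
# ordinal / symbolic family


@njit(cache=True)
def perm_entropy(x, m, delay):
    """Permutation entropy (bits), ties broken stably (order of occurrence)."""
    n = x.shape[0]
    nwin = n - (m - 1) * delay
    codes = np.empty(nwin, dtype=np.int64)
    w = np.empty(m)
    for i in range(nwin):
        for k in range(m):
            w[k] = x[i + k * delay]
        code = 0
        mult = 1
        for k in range(m):
            # stable rank of w[k] within the window
            rank = 0
            for l in range(m):
                if w[l] < w[k] or (w[l] == w[k] and l < k):
                    rank += 1
            code += rank * mult
            mult *= m
        codes[i] = code
    codes.sort()
    return _entropy_bits_sorted(codes)


@njit(cache=True)
def dispersion_entropy_core(x, m, c, delay, mu, sd):
    """Dispersion entropy (bits): normal-CDF map to classes 1..c, patterns of
    length m at the given delay."""
    n = x.shape[0]
    cls = np.empty(n, dtype=np.int64)
    inv = 1.0 / (sd * math.sqrt(2.0))
    for i in range(n):
        y = 0.5 * (1.0 + math.erf((x[i] - mu) * inv))
        v = np.rint(c * y + 0.5)
        if v < 1.0:
            v = 1.0
        elif v > c:
            v = float(c)
        cls[i] = np.int64(v)
    nwin = n - (m - 1) * delay
    codes = np.empty(nwin, dtype=np.int64)
    for i in range(nwin):
        code = 0
        mult = 1
        for k in range(m):
            code += (cls[i + k * delay] - 1) * mult
            mult *= c
        codes[i] = code
    codes.sort()
    return _entropy_bits_sorted(codes)


@njit(cache=True)
def symbolic_dynamic_entropy_core(x, m, c):
    """Joint (length-m pattern, next symbol) entropy (bits) under an
    equal-frequency partition into c classes; ties ranked stably (by order
    of occurrence) so the partition is well defined on tied data."""
    n = x.shape[0]
    order = np.argsort(x, kind="mergesort")
    symbols = np.empty(n, dtype=np.int64)
    for rank in range(n):
        symbols[order[rank]] = (rank * c) // n
    nwin = n - m
    codes = np.empty(nwin, dtype=np.int64)
    for i in range(nwin):
        code = 0
        mult = 1
        for k in range(m + 1):
            code += symbols[i + k] * mult
            mult *= c
        codes[i] = code
    codes.sort()
    return _entropy_bits_sorted(codes)


@njit(cache=True)
def incremental_entropy_core(x, m, R):
    """Entropy (bits) of words of m (sign, magnitude-quantile) increment
    symbols; quantile q = min(R, floor(|d| R / SD(d)))."""
    n = x.shape[0]
    nd = n - 1
    d = np.empty(nd)
    mean = 0.0
    for i in range(nd):
        d[i] = x[i + 1] - x[i]
        mean += d[i]
    mean /= nd
    var = 0.0
    for i in range(nd):
        var += (d[i] - mean) ** 2
    sd = math.sqrt(var / nd)
    sym = np.empty(nd, dtype=np.int64)
    for i in range(nd):
        if sd > 0.0:
            q = int(abs(d[i]) * R / sd)
            if q > R:
                q = R
        else:
            q = 0
        if d[i] > 0.0:
            s = 2
        elif d[i] < 0.0:
            s = 0
        else:
            s = 1
        sym[i] = s * (R + 1) + q
    base = 3 * (R + 1)
    nwin = nd - m + 1
    codes = np.empty(nwin, dtype=np.int64)
    for i in range(nwin):
        code = 0
        mult = 1
        for k in range(m):
            code += sym[i + k] * mult
            mult *= base
        codes[i] = code
    codes.sort()
    return _entropy_bits_sorted(codes)


@njit(cache=True)
def slope_entropy_core(x, m, gamma, delta):
    """Entropy (bits) of words of m-1 five-class slope symbols
    (thresholds +-delta, +-gamma)."""
    n = x.shape[0]
    nd = n - 1
    sym = np.empty(nd, dtype=np.int64)
    for i in range(nd):
        d = x[i + 1] - x[i]
        if d > gamma:
            s = 4
        elif d > delta:
            s = 3
        elif d >= -delta:
            s = 2
        elif d >= -gamma:
            s = 1
        else:
            s = 0
        sym[i] = s
    width = m - 1
    nwin = nd - width + 1
    codes = np.empty(nwin, dtype=np.int64)
    for i in range(nwin):
        code = 0
        mult = 1
        for k in range(width):
            code += sym[i + k] * mult
            mult *= 5
        codes[i] = code
    codes.sort()
    return _entropy_bits_sorted(codes)


@njit(cache=True)
def phase_entropy_core(x, sectors):
    """Radially weighted angular entropy (bits) of the second-order
    difference plot."""
    n = x.shape[0]
    npts = n - 2
    mass = np.zeros(sectors)
    total = 0.0
    width = 2.0 * math.pi / sectors
    for i in range(npts):
        u = x[i + 1] - x[i]
        v = x[i + 2] - x[i + 1]
        r = math.hypot(u, v)
        if r == 0.0:
            continue
        theta = math.atan2(v, u)
        idx = int((theta + math.pi) / width)
        if idx >= sectors:
            idx = sectors - 1
        mass[idx] += r
        total += r
    if total <= 0.0:
        return 0.0
    h = 0.0
    for s in range(sectors):
        if mass[s] > 0.0:
            p = mass[s] / total
            h -= p * math.log(p)
    return h / LOG2


@njit(cache=True)
def gridded_distribution_entropy_core(x, grid):
    """Occupancy entropy (bits) of Poincare points on a grid x grid lattice
    spanning [min, max]^2 (upper edges inclusive)."""
    n = x.shape[0]
    lo = x[0]
    hi = x[0]
    for i in range(n):
        if x[i] < lo:
            lo = x[i]
        if x[i] > hi:
            hi = x[i]
    if hi == lo:
        return 0.0
    # bin = floor((v - lo)/(hi - lo) * grid), capped: keep this exact
    # arithmetic shape so edge values (common in tied data) bin predictably
    span = hi - lo
    counts = np.zeros(grid * grid, dtype=np.int64)
    for i in range(n - 1):
        a = int((x[i] - lo) / span * grid)
        b = int((x[i + 1] - lo) / span * grid)
        if a >= grid:
            a = grid - 1
        if b >= grid:
            b = grid - 1
        counts[a * grid + b] += 1
    total = n - 1
    h = 0.0
    for k in range(grid * grid):
        if counts[k] > 0:
            p = counts[k] / total
            h -= p * math.log(p)
    return h / LOG2


@njit(cache=True)
def attention_entropy_core(x):
    """Mean entropy (bits) of the four key-point interval streams
    (max-max, min-min, max-next-min, min-next-max); strict local extrema."""
    n = x.shape[0]
    maxima = np.empty(n, dtype=np.int64)
    minima = np.empty(n, dtype=np.int64)
    nmax = 0
    nmin = 0
    for i in range(1, n - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            maxima[nmax] = i
            nmax += 1
        elif x[i] < x[i - 1] and x[i] < x[i + 1]:
            minima[nmin] = i
            nmin += 1
    total = 0.0
    # same-type streams
    for sel in range(2):
        pts = maxima if sel == 0 else minima
        cnt = nmax if sel == 0 else nmin
        if cnt >= 3:  # >= 2 intervals
            iv = np.empty(cnt - 1, dtype=np.int64)
            for i in range(cnt - 1):
                iv[i] = pts[i + 1] - pts[i]
            iv.sort()
            total += _entropy_bits_sorted(iv)
    # cross-type streams: from each point of one type to the next of the other
    for sel in range(2):
        src = maxima if sel == 0 else minima
        nsrc = nmax if sel == 0 else nmin
        dst = minima if sel == 0 else maxima
        ndst = nmin if sel == 0 else nmax
        iv = np.empty(nsrc, dtype=np.int64)
        cnt = 0
        j = 0
        for i in range(nsrc):
            while j < ndst and dst[j] < src[i]:
                j += 1
            if j < ndst:
                iv[cnt] = dst[j] - src[i]
                cnt += 1
        if cnt >= 2:
            out = iv[:cnt]
            out.sort()
            total += _entropy_bits_sorted(out)
    return total / 4.0


@njit(cache=True)
def bubble_renyi2(x, width):
    """Renyi-2 entropy (nats) of bubble-sort swap counts over sliding
    windows of the given width."""
    n = x.shape[0]
    nwin = n - width + 1
    ncounts = width * (width - 1) // 2 + 1
    counts = np.zeros(ncounts, dtype=np.int64)
    for i in range(nwin):
        swaps = 0
        for a in range(width - 1):
            for b in range(a + 1, width):
                if x[i + a] > x[i + b]:
                    swaps += 1
        counts[swaps] += 1
    s2 = 0.0
    for k in range(ncounts):
        if counts[k] > 0:
            p = counts[k] / nwin
            s2 += p * p
    return -math.log(s2)
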