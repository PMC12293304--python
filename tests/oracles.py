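"""Naive reference implementations of the entropy estimators.

Written straight from the definitions with explicit python loops (O(n^2) or
worse), deliberately sharing no code with the package, so agreement with the
fast implementations is meaningful.  Only suitable for short series.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def _shannon_bits(counter: Counter) -> float:
    total = sum(counter.values())
    if total == 0:
        return 0.0
    h = 0.0
    for c in counter.values():
        p = c / total
        h -= p * math.log2(p)
    return h


def psd_entropy(x) -> float:
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    x = [v - mean for v in x]
    powers = []
    for f in range(1, n // 2 + 1):  # positive frequencies, explicit DFT
        re = sum(x[t] * math.cos(2 * math.pi * f * t / n) for t in range(n))
        im = sum(x[t] * math.sin(2 * math.pi * f * t / n) for t in range(n))
        powers.append(re * re + im * im)
    total = sum(powers)
    if total <= 0:
        return 0.0
    h = 0.0
    for p in powers:
        if p > 0:
            h -= (p / total) * math.log2(p / total)
    return h


def energy_entropy(x, K=10) -> float:
    x = [float(v) for v in x]
    seg_len = len(x) // K
    energies = []
    for k in range(K):
        seg = x[k * seg_len:(k + 1) * seg_len]
        energies.append(sum(v * v for v in seg))
    total = sum(energies)
    if total <= 0:
        return 0.0
    h = 0.0
    for e in energies:
        if e > 0:
            h -= (e / total) * math.log2(e / total)
    return h


def _cheb(a, b) -> float:
    return max(abs(u - v) for u, v in zip(a, b))


def approximate_entropy(x, m=2, r=0.2, r_absolute=False) -> float:
    x = [float(v) for v in x]
    n = len(x)
    if not r_absolute:
        mean = sum(x) / n
        r = r * math.sqrt(sum((v - mean) ** 2 for v in x) / n)

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        nt = len(templates)
        s = 0.0
        for u in templates:
            c = sum(1 for v in templates if _cheb(u, v) <= r)
            s += math.log(c / nt)
        return s / nt

    return phi(m) - phi(m + 1)


def sample_entropy(x, m=2, r=0.2, r_absolute=False) -> float:
    x = [float(v) for v in x]
    n = len(x)
    if not r_absolute:
        mean = sum(x) / n
        r = r * math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    a = b = 0
    for i in range(n - m - 1):
        for j in range(i + 1, n - m):
            if _cheb(x[i:i + m], x[j:j + m]) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def fuzzy_entropy(x, m=2, r=0.2, n_exp=2.0, r_absolute=False) -> float:
    x = [float(v) for v in x]
    n = len(x)
    if not r_absolute:
        mean = sum(x) / n
        r = r * math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if r <= 0:
        return 0.0 if len(set(x)) == 1 else float("nan")

    def mean_membership(mm):
        templates = []
        for i in range(n - m):  # same offsets for both lengths
            t = x[i:i + mm]
            mu = sum(t) / mm
            templates.append([v - mu for v in t])
        tot, cnt = 0.0, 0
        for i in range(len(templates) - 1):
            for j in range(i + 1, len(templates)):
                d = _cheb(templates[i], templates[j])
                tot += math.exp(-((d / r) ** n_exp))
                cnt += 1
        return tot / cnt

    return math.log(mean_membership(m)) - math.log(mean_membership(m + 1))


def permutation_entropy(x, m=3, delay=1) -> float:
    x = [float(v) for v in x]
    n = len(x)
    patterns = Counter()
    for i in range(n - (m - 1) * delay):
        w = [x[i + k * delay] for k in range(m)]
        order = tuple(sorted(range(m), key=lambda k: (w[k], k)))  # stable
        patterns[order] += 1
    return _shannon_bits(patterns)


def attention_entropy(x) -> float:
    x = [float(v) for v in x]
    n = len(x)
    maxima = [i for i in range(1, n - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]]
    minima = [i for i in range(1, n - 1) if x[i] < x[i - 1] and x[i] < x[i + 1]]

    def next_of(src, dst):
        out = []
        for s in src:
            nxt = [d for d in dst if d >= s]
            if nxt:
                out.append(nxt[0] - s)
        return out

    streams = [
        [b - a for a, b in zip(maxima, maxima[1:])],
        [b - a for a, b in zip(minima, minima[1:])],
        next_of(maxima, minima),
        next_of(minima, maxima),
    ]
    vals = []
    for s in streams:
        vals.append(_shannon_bits(Counter(s)) if len(s) >= 2 else 0.0)
    return sum(vals) / 4.0


def bubble_entropy(x, m=10) -> float:
    x = [float(v) for v in x]

    def swap_count(window):
        w = list(window)
        swaps = 0
        for i in range(len(w)):  # actual bubble sort
            for j in range(len(w) - 1 - i):
                if w[j] > w[j + 1]:
                    w[j], w[j + 1] = w[j + 1], w[j]
                    swaps += 1
        return swaps

    def renyi2(width):
        counts = Counter(swap_count(x[i:i + width])
                         for i in range(len(x) - width + 1))
        total = sum(counts.values())
        return -math.log(sum((c / total) ** 2 for c in counts.values()))

    return (renyi2(m + 1) - renyi2(m)) / math.log((m + 1) / (m - 1))


def dispersion_entropy(x, m=2, c=6, delay=1) -> float:
    x = [float(v) for v in x]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    if sd == 0:
        return 0.0
    classes = []
    for v in x:
        y = 0.5 * (1.0 + math.erf((v - mean) / (sd * math.sqrt(2))))
        z = float(np.round(c * y + 0.5))  # numpy round-half-even convention
        classes.append(int(min(max(z, 1), c)))
    patterns = Counter()
    for i in range(n - (m - 1) * delay):
        patterns[tuple(classes[i + k * delay] for k in range(m))] += 1
    return _shannon_bits(patterns)


def distribution_entropy(x, m=2, B=64) -> float:
    x = [float(v) for v in x]
    n = len(x)
    templates = [x[i:i + m] for i in range(n - m + 1)]
    dists = []
    for i in range(len(templates) - 1):
        for j in range(i + 1, len(templates)):
            dists.append(_cheb(templates[i], templates[j]))
    dmax = max(dists)
    if dmax == 0:
        return 0.0
    counts = Counter()
    for d in dists:
        counts[min(int(d / dmax * B), B - 1)] += 1
    return _shannon_bits(counts) / math.log2(B)


def gridded_distribution_entropy(x, grid=10) -> float:
    x = [float(v) for v in x]
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    cells = Counter()
    for a, b in zip(x, x[1:]):
        ia = min(int((a - lo) / (hi - lo) * grid), grid - 1)
        ib = min(int((b - lo) / (hi - lo) * grid), grid - 1)
        cells[(ia, ib)] += 1
    return _shannon_bits(cells)


def incremental_entropy(x, m=2, R=4) -> float:
    x = [float(v) for v in x]
    d = [b - a for a, b in zip(x, x[1:])]
    mean = sum(d) / len(d)
    sd = math.sqrt(sum((v - mean) ** 2 for v in d) / len(d))
    symbols = []
    for v in d:
        q = min(R, int(abs(v) * R / sd)) if sd > 0 else 0
        s = 1 if v > 0 else (-1 if v < 0 else 0)
        symbols.append((s, q))
    words = Counter(tuple(symbols[i:i + m]) for i in range(len(symbols) - m + 1))
    return _shannon_bits(words)


def phase_entropy(x, sectors=8) -> float:
    x = [float(v) for v in x]
    d = [b - a for a, b in zip(x, x[1:])]
    mass = [0.0] * sectors
    total = 0.0
    for u, v in zip(d, d[1:]):
        r = math.hypot(u, v)
        if r == 0:
            continue
        theta = math.atan2(v, u)
        idx = min(int((theta + math.pi) / (2 * math.pi / sectors)), sectors - 1)
        mass[idx] += r
        total += r
    if total <= 0:
        return 0.0
    h = 0.0
    for mv in mass:
        if mv > 0:
            h -= (mv / total) * math.log2(mv / total)
    return h


def slope_entropy(x, m=3, gamma=1.0, delta=0.001) -> float:
    x = [float(v) for v in x]
    d = [b - a for a, b in zip(x, x[1:])]
    symbols = []
    for v in d:
        if v > gamma:
            symbols.append(2)
        elif v > delta:
            symbols.append(1)
        elif v >= -delta:
            symbols.append(0)
        elif v >= -gamma:
            symbols.append(-1)
        else:
            symbols.append(-2)
    width = m - 1
    words = Counter(tuple(symbols[i:i + width])
                    for i in range(len(symbols) - width + 1))
    return _shannon_bits(words)


def symbolic_dynamic_entropy(x, m=2, c=6) -> float:
    x = [float(v) for v in x]
    n = len(x)
    order = sorted(range(n), key=lambda i: x[i])
    symbols = [0] * n
    for rank, idx in enumerate(order):
        symbols[idx] = (rank * c) // n
    events = Counter(tuple(symbols[i:i + m + 1]) for i in range(n - m))
    return _shannon_bits(events)


ORACLES = {
    "PsdEn": psd_entropy,
    "Een": energy_entropy,
    "ApEn": approximate_entropy,
    "SampEn": sample_entropy,
    "FuzzyEn": fuzzy_entropy,
    "PEn": permutation_entropy,
    "Aen": attention_entropy,
    "BubbEn": bubble_entropy,
    "DispEn": dispersion_entropy,
    "DistEn": distribution_entropy,
    "GdEn": gridded_distribution_entropy,
    "IncrEn": incremental_entropy,
    "PhaseEn": phase_entropy,
    "SlopEn": slope_entropy,
    "SyDyEn": symbolic_dynamic_entropy,
}
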