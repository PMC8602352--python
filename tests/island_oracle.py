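"""Independent brute-force re-derivation of the island caller for tiny genomes.

Deliberately written with plain Python loops, its own Poisson-tail series and
its own BH step-up, so it shares no code path with the package implementation.
"""

import math


def _pois_tail(k: int, lam: float) -> float:
    """P(X >= k) by direct series, accumulated in log space for stability."""
    if k <= 0:
        return 1.0
    logs = [-lam + i * math.log(lam) - math.lgamma(i + 1) for i in range(k)]
    peak = max(logs)
    cdf = math.exp(peak) * sum(math.exp(v - peak) for v in logs)
    return max(1.0 - cdf, 0.0)


def _bh(ps):
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        prev = min(prev, ps[i] * m / rank)
        q[i] = prev
    return q


def oracle_call_islands(ip_frags, input_frags, chrom_sizes, w=200, gap=3,
                        p0=0.2, q_max=0.05, floor_factor=1.25):
    """Enumerate every window run by direct scanning and apply the caller's
    published formulas; returns retained islands as dicts."""
    ip_lib = len(ip_frags)
    in_lib = len(input_frags)
    genome_len = sum(chrom_sizes.values())

    def bins(frags):
        out = {c: [0] * math.ceil(L / w) for c, L in chrom_sizes.items()}
        for chrom, start, end in frags:
            out[chrom][((start + end) // 2) // w] += 1
        return out

    ip_bins, in_bins = bins(ip_frags), bins(input_frags)
    lam = ip_lib * w / genome_len
    candidates = []
    for chrom, counts in ip_bins.items():
        eligible = [k >= 1 and _pois_tail(k, lam) <= p0 for k in counts]
        run = []  # indices of eligible windows in the current run
        for i, e in enumerate(eligible):
            if e:
                if run and i - run[-1] - 1 > gap:
                    candidates.append((chrom, run[0], run[-1] + 1))
                    run = []
                run.append(i)
        if run:
            candidates.append((chrom, run[0], run[-1] + 1))
    scored = []
    for chrom, a, b in candidates:
        start, end = a * w, min(b * w, chrom_sizes[chrom])
        ip_n = sum(ip_bins[chrom][a:b])
        in_n = sum(in_bins[chrom][a:b])
        expected = max(in_n * ip_lib / in_lib,
                       floor_factor * (end - start) * ip_lib / genome_len)
        scored.append(dict(chrom=chrom, start=start, end=end, ip_count=ip_n,
                           expected=expected, fold=ip_n / expected,
                           p=_pois_tail(ip_n, expected)))
    qs = _bh([s["p"] for s in scored])
    for s, q in zip(scored, qs):
        s["q"] = q
    retained = [s for s in scored if s["q"] <= q_max and s["fold"] > 1.0]
    return sorted(retained, key=lambda s: (s["chrom"], s["start"]))
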