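"""Independent naive re-implementations used as test oracles.

Everything here is written as a direct, unoptimized transcription of the
scoring rules — plain scans over runs and junctions — deliberately sharing
no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

from proteosubtype.io import GenomeBuild, Segment, SegmentProfile


# ---------------------------------------------------------------------------
# naive allele-specific instability scoring
# ---------------------------------------------------------------------------

def _sorted_merged(segs):
    """Merge touching equal-state segments by brute scan."""
    segs = sorted(segs, key=lambda s: s.start_bp)
    out = []
    for s in segs:
        if out:
            p = out[-1]
            if p.end_bp == s.start_bp and (p.major_cn, p.minor_cn) == (s.major_cn, s.minor_cn):
                out[-1] = Segment(s.chrom, p.start_bp, s.end_bp, s.total_cn,
                                  s.major_cn, s.minor_cn)
                continue
        out.append(s)
    return out


def naive_scores(profile: SegmentProfile, genome: GenomeBuild) -> dict:
    autos = set(genome.autosomes)
    by_chrom: dict[str, list[Segment]] = {}
    for s in profile.segments:
        if s.chrom in autos:
            by_chrom.setdefault(s.chrom, []).append(s)
    by_chrom = {c: _sorted_merged(v) for c, v in by_chrom.items()}

    # ploidy / WGD
    total_len = sum(s.length for segs in by_chrom.values() for s in segs)
    ploidy = sum(s.length * s.total_cn for segs in by_chrom.values() for s in segs) / total_len
    genome_len = sum(genome.length(c) for c in autos)
    frac_major2 = sum(s.length for segs in by_chrom.values() for s in segs
                      if s.major_cn >= 2) / genome_len
    wgd = frac_major2 > 0.5

    # CIN components
    n_gain = sum(1 for segs in by_chrom.values() for s in segs if s.total_cn > 2)
    n_loss = sum(1 for segs in by_chrom.values() for s in segs if s.total_cn < 2)
    n_loh = sum(1 for segs in by_chrom.values() for s in segs
                if s.minor_cn == 0 and s.total_cn >= 1)

    # HRD-LOH: scan maximal contiguous LOH runs per chromosome
    hrd_loh = 0
    for chrom, segs in by_chrom.items():
        runs = []
        cur = None
        for s in segs:
            loh = s.minor_cn == 0 and s.total_cn >= 1
            if loh:
                if cur is not None and cur[1] == s.start_bp:
                    cur = (cur[0], s.end_bp)
                else:
                    if cur is not None:
                        runs.append(cur)
                    cur = (s.start_bp, s.end_bp)
            else:
                if cur is not None:
                    runs.append(cur)
                    cur = None
        if cur is not None:
            runs.append(cur)
        for a, b in runs:
            if b - a > 15_000_000 and not (a == 0 and b == genome.length(chrom)):
                hrd_loh += 1

    # LST: per arm, drop <3 Mb pieces, re-merge same-state, scan junctions
    lst = 0
    for chrom, segs in by_chrom.items():
        cs, ce = genome.centromere(chrom)
        for lo, hi in ((0, cs), (ce, genome.length(chrom))):
            arm = []
            for s in segs:
                a, b = max(s.start_bp, lo), min(s.end_bp, hi)
                if b > a:
                    arm.append(Segment(chrom, a, b, s.total_cn, s.major_cn, s.minor_cn))
            arm = [s for s in arm if s.length >= 3_000_000]
            merged = []
            for s in arm:
                if merged and (merged[-1].major_cn, merged[-1].minor_cn) == (s.major_cn, s.minor_cn):
                    p = merged.pop()
                    s = Segment(chrom, p.start_bp, s.end_bp, s.total_cn, s.major_cn, s.minor_cn)
                merged.append(s)
            for i in range(len(merged) - 1):
                a, b = merged[i], merged[i + 1]
                if (a.major_cn, a.minor_cn) != (b.major_cn, b.minor_cn) \
                        and a.length >= 10_000_000 and b.length >= 10_000_000 \
                        and b.start_bp - a.end_bp <= 3_000_000:
                    lst += 1

    # TAI: imbalance runs touching a telomere, not crossing the centromere
    tai = 0
    for chrom, segs in by_chrom.items():
        cs, ce = genome.centromere(chrom)
        clen = genome.length(chrom)
        runs = []
        cur = None
        for s in segs:
            if s.major_cn != s.minor_cn:
                if cur is not None and cur[1] == s.start_bp:
                    cur = (cur[0], s.end_bp)
                else:
                    if cur is not None:
                        runs.append(cur)
                    cur = (s.start_bp, s.end_bp)
            else:
                if cur is not None:
                    runs.append(cur)
                    cur = None
        if cur is not None:
            runs.append(cur)
        for a, b in runs:
            touches = a == 0 or b == clen
            whole = a == 0 and b == clen
            crosses = a < cs and b > ce
            if touches and not whole and not crosses and b - a > 0:
                tai += 1

    return {"ploidy": ploidy, "wgd": wgd, "n_gain": n_gain, "n_loss": n_loss,
            "n_loh_segments": n_loh, "cin": n_gain + n_loss + n_loh,
            "hrd_loh": hrd_loh, "lst": lst, "tai": tai,
            "hrd": hrd_loh + lst + tai}


def random_profile(genome: GenomeBuild, rng: np.random.Generator,
                   sample_id: str = "rand") -> SegmentProfile:
    """A random valid allele-specific profile: random walk over each chromosome
    with random states, gaps and segment lengths."""
    segs = []
    for chrom in genome.chroms:
        clen = genome.length(chrom)
        pos = int(rng.integers(0, 5_000_000)) if rng.random() < 0.5 else 0
        while pos < clen - 1_000_000:
            length = int(rng.integers(500_000, 80_000_000))
            end = min(pos + length, clen)
            major = int(rng.integers(0, 4))
            minor = int(rng.integers(0, major + 1))
            if major + minor > 0 or rng.random() < 0.3:
                segs.append(Segment(chrom, pos, end, major + minor, major, minor))
            pos = end
            if rng.random() < 0.3:  # open a gap
                pos += int(rng.integers(500_000, 10_000_000))
    return SegmentProfile(sample_id, segs)


# ---------------------------------------------------------------------------
# brute-force enrichment statistics
# ---------------------------------------------------------------------------

def naive_ssgsea_score(values, membership, weight):
    """Literal running-sum area statistic, one explicit position at a time.

    ``values``/``membership`` already ordered by decreasing value.
    """
    values = list(values)
    membership = list(membership)
    denom = sum(abs(v) ** weight for v, m in zip(values, membership) if m)
    n_out = sum(1 for m in membership if not m)
    if denom == 0 or n_out == 0:
        return 0.0
    running = 0.0
    area = 0.0
    for v, m in zip(values, membership):
        if m:
            running += abs(v) ** weight / denom
        else:
            running -= 1.0 / n_out
        area += running
    return area


def naive_es(values, membership, weight):
    """Classic GSEA enrichment score by explicit scan (max |running sum|)."""
    denom = sum(abs(v) ** weight for v, m in zip(values, membership) if m)
    n_out = sum(1 for m in membership if not m)
    if denom == 0 or n_out == 0:
        return 0.0
    running, best = 0.0, 0.0
    for v, m in zip(values, membership):
        running += (abs(v) ** weight / denom) if m else (-1.0 / n_out)
        if abs(running) > abs(best):
            best = running
    return best


def hypergeom_upper_tail(overlap, universe, set_size, n_hits):
    """P(X >= overlap) by explicit summation of the hypergeometric mass."""
    def comb(n, k):
        return math.comb(n, k)
    denom = comb(universe, n_hits)
    total = 0.0
    for x in range(overlap, min(set_size, n_hits) + 1):
        if n_hits - x <= universe - set_size:
            total += comb(set_size, x) * comb(universe - set_size, n_hits - x) / denom
    return total


def fisher_two_sided(table):
    """Two-sided Fisher exact p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def p_of(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = p_of(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(p_of(x) for x in range(lo, hi + 1) if p_of(x) <= p_obs * (1 + 1e-9))


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recursion."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


# ---------------------------------------------------------------------------
# brute-force normalization oracles
# ---------------------------------------------------------------------------

def naive_knn_impute(X, k):
    """Exhaustive nearest-feature search; X is a 2-D array with NaNs."""
    X = np.asarray(X, dtype=float)
    out = X.copy()
    n = X.shape[0]
    for i in range(n):
        for j in range(X.shape[1]):
            if not np.isnan(X[i, j]):
                continue
            dists = []
            for u in range(n):
                if u == i or np.isnan(X[u, j]):
                    continue
                shared = ~np.isnan(X[i]) & ~np.isnan(X[u])
                if not shared.any():
                    continue
                d = np.sqrt(np.mean((X[i, shared] - X[u, shared]) ** 2))
                dists.append((d, u))
            dists.sort(key=lambda t: t[0])
            if not dists:
                out[i, j] = np.nanmean(X[i])
            else:
                out[i, j] = np.mean([X[u, j] for _, u in dists[:k]])
    return out


def naive_tmm_factors(X, trim_m=0.30, trim_a=0.05):
    """Plain re-implementation of the trimmed-mean-of-M scale factors."""
    X = np.asarray(X, dtype=float)
    sums = X.sum(axis=0)
    ref = int(np.argmin(np.abs(sums - sums.mean())))
    raw = []
    for j in range(X.shape[1]):
        M = np.log2(X[:, j] / X[:, ref])
        A = 0.5 * np.log2(X[:, j] * X[:, ref])
        n = len(M)
        order_m = np.argsort(np.argsort(M)) + 1.0
        order_a = np.argsort(np.argsort(A)) + 1.0
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        keep = ((order_m >= lo_m) & (order_m <= n + 1 - lo_m)
                & (order_a >= lo_a) & (order_a <= n + 1 - lo_a))
        raw.append(2 ** M[keep].mean() if keep.any() else 1.0)
    raw = np.array(raw)
    return raw / np.exp(np.log(raw).mean())
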