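"""Independent straight-line oracles used to cross-check the implementation.

Everything here is deliberately naive — plain dicts, explicit loops,
math.log2 and math.comb — and shares no code with the package beyond the
dataclass field names it reads.
"""

from __future__ import annotations

import math


def brute_force_screen(dataset, threshold=0.5, min_hits=2, require_concordance=True):
    """Recompute gene hit/triple-hit sets straight from raw wells.

    Returns (hit_gene_keys, triple_hit_gene_keys) as sets of gene identity
    keys (NCBI id string, else upper-cased symbol). Per-plate control
    anchoring; a siRNA's wells assumed groupable by plate (weighted-mean
    combination across plates mirrors the documented rule).
    """
    role_of, gene_of = {}, {}
    for rec in dataset.library:
        role_of[rec.sirna_id] = rec.role
        if rec.gene_ncbi_id is not None:
            gene_of[rec.sirna_id] = str(int(rec.gene_ncbi_id))
        else:
            gene_of[rec.sirna_id] = rec.gene_symbol.upper()

    # collect log2 ratios per (plate, sirna)
    logs = {}
    for w in dataset.wells:
        if not w.valid or w.firefly <= 0 or w.renilla <= 0:
            continue
        logs.setdefault((w.plate_id, w.sirna_id), []).append(math.log2(w.renilla / w.firefly))

    def mean(xs):
        return sum(xs) / len(xs)

    # per-plate control means
    plates = {p for (p, _) in logs}
    neg_mean, pos_mean = {}, {}
    for p in plates:
        neg = [v for (pp, s), vs in logs.items() if pp == p and role_of[s] == "negative_control" for v in vs]
        pos = [v for (pp, s), vs in logs.items() if pp == p and role_of[s] == "positive_control" for v in vs]
        if neg:
            neg_mean[p] = mean(neg)
        if pos:
            pos_mean[p] = mean(pos)
    # screen-wide fallback
    all_neg = [v for (p, s), vs in logs.items() if role_of[s] == "negative_control" for v in vs]
    all_pos = [v for (p, s), vs in logs.items() if role_of[s] == "positive_control" for v in vs]
    for p in plates:
        neg_mean.setdefault(p, mean(all_neg))
        pos_mean.setdefault(p, mean(all_pos))

    # per-siRNA effect
    sirna_ids = sorted({s for (_, s) in logs if role_of[s] == "library"})
    magnitude, sign = {}, {}
    for s in sirna_ids:
        parts = []  # (delta, delta_pos, n)
        for p in plates:
            vs = logs.get((p, s))
            if vs:
                parts.append((mean(vs) - neg_mean[p], pos_mean[p] - neg_mean[p], len(vs)))
        n = sum(k for _, _, k in parts)
        delta = sum(d * k for d, _, k in parts) / n
        dpos = sum(dp * k for _, dp, k in parts) / n
        magnitude[s] = abs(delta) / abs(dpos)
        sign[s] = 0 if delta == 0 else (1 if delta > 0 else -1)

    genes = {}
    for s in sirna_ids:
        genes.setdefault(gene_of[s], []).append(s)

    hits, triples = set(), set()
    for g, members in genes.items():
        hit_sirnas = [s for s in members if magnitude[s] >= threshold]
        signs = {sign[s] for s in hit_sirnas}
        concordant = len(signs) <= 1
        ok = len(hit_sirnas) >= min_hits and (concordant or not require_concordance)
        if ok:
            hits.add(g)
            if len(hit_sirnas) == len(members) >= 3:
                triples.add(g)
    return hits, triples


def permutation_p_two_sided(a, b):
    """Exact two-sided permutation p for a difference of means, enumerating
    every reassignment of the pooled values with itertools-free recursion."""
    from itertools import combinations

    pooled = list(a) + list(b)
    na = len(a)
    obs = abs(sum(a) / len(a) - sum(b) / len(b))
    hits = total = 0
    for idx in combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(sum(ga) / len(ga) - sum(gb) / len(gb)) >= obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def hypergeom_upper_tail(k, universe, size_a, size_b):
    """P(X >= k) for the overlap of two fixed-size subsets of a universe,
    by direct summation of counting terms."""
    total = math.comb(universe, size_b)
    acc = 0
    for x in range(k, min(size_a, size_b) + 1):
        if size_b - x > universe - size_a:
            continue
        acc += math.comb(size_a, x) * math.comb(universe - size_a, size_b - x)
    return acc / total
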