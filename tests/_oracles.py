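"""Independent brute-force oracles used by the tests.

Deliberately naive double-loop implementations of the aggregation,
binning, classification and score computations; they share no code with
the package paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def naive_region_averages(calls, regions, weighted: bool, min_cpgs: int):
    """Double loop over regions x CpGs; returns {(sample, region): (avg, n)}."""
    out = {}
    for table in calls:
        for reg in regions.data.itertuples(index=False):
            wsum = 0.0
            wbsum = 0.0
            n = 0
            for row in table.data.itertuples(index=False):
                if row.chrom != reg.chrom:
                    continue
                if not (reg.start <= row.pos < reg.end):
                    continue
                w = math.log10(row.depth + 0.1) if weighted else 1.0
                wsum += w
                wbsum += w * row.beta
                n += 1
            avg = wbsum / wsum if n >= min_cpgs else None
            out[(table.sample_id, reg.region_id)] = (avg, n)
    return out


def naive_decile_counts(avg_beta_df):
    """Per-sample decile histogram by explicit interval checks."""
    counts = {}
    for sample, row in avg_beta_df.iterrows():
        hist = [0] * 10
        for value in row:
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            for d in range(1, 11):
                lo, hi = (d - 1) / 10, d / 10
                if (lo <= value < hi) or (d == 10 and value == 1.0):
                    hist[d - 1] += 1
                    break
        counts[sample] = hist
    return counts


def naive_classify(avg_beta_df, low=0.3, high=0.7, consistency_min=0.9):
    """Exhaustive per-gene trichotomisation and consistency check."""

    def slot(b):
        return "unmethylated" if b < low else ("methylated" if b > high else "undefined")

    lists = {"unmethylated": [], "undefined": [], "methylated": []}
    excluded = []
    for gene in avg_beta_df.columns:
        vals = [v for v in avg_beta_df[gene] if not math.isnan(v)]
        if not vals:
            excluded.append(gene)
            continue
        per_sample = [slot(v) for v in vals]
        modal = max(sorted(set(per_sample)), key=per_sample.count)
        frac = per_sample.count(modal) / len(vals)
        if frac > consistency_min:
            lists[modal].append(gene)
    return lists, excluded


def naive_cox_score(x, time, event, s0=0.0):
    """Risk-set loop for the modified Cox score (Breslow ties)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    U = 0.0
    V = 0.0
    for i in range(len(x)):
        if event[i] != 1:
            continue
        risk = x[time >= time[i]]
        U += x[i] - risk.mean()
        V += risk.var()  # population variance of the risk set
    return U / (math.sqrt(V) + s0)


def naive_bh(p):
    """Benjamini-Hochberg by sort + cumulative minimum from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
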