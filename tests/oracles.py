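"""Independent brute-force oracles, written as literal loops over the
defining formulas. Deliberately naive and kept separate from the package's
vectorized implementations so transcription errors in either are caught.
"""

from __future__ import annotations

import math


def mean_of(xs):
    return sum(xs) / len(xs)


def sample_sd(xs):
    m = mean_of(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def bestkeeper_stats_oracle(values):
    """Per-gene descriptive statistics from their textbook definitions."""
    n = len(values)
    ar = mean_of(values)
    geo = math.exp(sum(math.log(v) for v in values) / n)
    mad = mean_of([abs(v - ar) for v in values])
    sd = sample_sd(values)
    return {
        "geo_mean": geo,
        "ar_mean": ar,
        "min_ct": min(values),
        "max_ct": max(values),
        "mad": mad,
        "sample_sd": sd,
        "cv_mad": mad / ar * 100.0,
    }


def flag_count_oracle(matrix, threshold):
    """Exhaustive scan: number of cells with Ct >= threshold."""
    count = 0
    for row in matrix:
        for v in row:
            if v >= threshold:
                count += 1
    return count


def mean_pair_sd_oracle(matrix):
    """Comparative ΔCt stability (== first-pass geNorm M, base 2) by loops.

    ``matrix`` is a list of per-gene lists of Ct over the same samples.
    """
    n_genes = len(matrix)
    out = []
    for j in range(n_genes):
        sds = []
        for k in range(n_genes):
            if k == j:
                continue
            diffs = [a - b for a, b in zip(matrix[j], matrix[k])]
            sds.append(sample_sd(diffs))
        out.append(mean_of(sds))
    return out


def normfinder_oracle(matrix, labels):
    """Literal nested-loop evaluation of the stability formulas.

    ``matrix``: genes × samples Ct values; ``labels``: per-sample group.
    Returns per-gene rho. Mirrors the model: sample-centering within each
    group, two-way residual variances with the k/(k-2) correction, raw
    intergroup differences double-centered, gamma² from the interaction
    degrees of freedom, shrinkage, rho = mean(|d~| + sqrt(sigma²/n)).
    """
    k = len(matrix)
    groups = []
    for lab in labels:
        if lab not in groups:
            groups.append(lab)
    g = len(groups)

    a = [[0.0] * g for _ in range(k)]  # gene × group profile means
    sigma2 = [[0.0] * g for _ in range(k)]
    n_per = []
    for gi, lab in enumerate(groups):
        cols = [j for j, l in enumerate(labels) if l == lab]
        n = len(cols)
        n_per.append(n)
        # sample-centering
        centered = [[0.0] * n for _ in range(k)]
        for cj, j in enumerate(cols):
            col_mean = mean_of([matrix[i][j] for i in range(k)])
            for i in range(k):
                centered[i][cj] = matrix[i][j] - col_mean
        s2 = []
        for i in range(k):
            ai = mean_of(centered[i])
            a[i][gi] = ai
            resid = [centered[i][cj] - ai for cj in range(n)]
            s2.append(sum(r * r for r in resid) / (n - 1))
        total_s2 = sum(s2)
        for i in range(k):
            sigma2[i][gi] = max(0.0, (k / (k - 2)) * (s2[i] - total_s2 / (k * (k - 1))))

    if g == 1:
        return [math.sqrt(sigma2[i][0]) for i in range(k)]

    d = [[a[i][gi] - mean_of(a[i]) for gi in range(g)] for i in range(k)]
    v = [[sigma2[i][gi] / n_per[gi] for gi in range(g)] for i in range(k)]
    sum_d2 = sum(d[i][gi] ** 2 for i in range(k) for gi in range(g))
    mean_v = mean_of([v[i][gi] for i in range(k) for gi in range(g)])
    gamma2 = max(0.0, sum_d2 / ((k - 1) * (g - 1)) - mean_v)

    rho = []
    for i in range(k):
        terms = []
        for gi in range(g):
            shrink = gamma2 / (gamma2 + v[i][gi]) if gamma2 > 0 else 0.0
            terms.append(abs(d[i][gi] * shrink) + math.sqrt(v[i][gi]))
        rho.append(mean_of(terms))
    return rho
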