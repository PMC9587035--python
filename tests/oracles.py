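"""Independent brute-force reference implementations used as oracles.

Everything here is written as plain, slow loops straight from the
defining formulas, deliberately sharing no code with the package.
"""

import math

import numpy as np


def sd(xs):
    m = sum(xs) / len(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def genorm_m(a):
    """a: dict gene -> list of relative quantities. Returns dict gene -> M."""
    genes = list(a)
    out = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            ratios = [math.log2(x / y) for x, y in zip(a[j], a[k])]
            vs.append(sd(ratios))
        out[j] = sum(vs) / len(vs)
    return out


def genorm_ladder(a, order):
    """V(n/n+1) from explicit normalization factors (geometric means)."""
    out = {}
    nsamp = len(next(iter(a.values())))
    for n in range(2, len(order)):
        nf_n = [math.prod(a[g][s] for g in order[:n]) ** (1 / n) for s in range(nsamp)]
        nf_n1 = [
            math.prod(a[g][s] for g in order[: n + 1]) ** (1 / (n + 1))
            for s in range(nsamp)
        ]
        out[f"V{n}/{n + 1}"] = sd([math.log2(x / y) for x, y in zip(nf_n, nf_n1)])
    return out


def normfinder_components(z, groups):
    """z: dict gene -> dict sample -> value; groups: dict label -> samples.

    Returns (sigma2, dtilde, gamma2, sv) with sigma2/dtilde as
    dict[gene][group], following the intra/intergroup decomposition
    with de-mixing corrections and zero-truncation.
    """
    genes = sorted(z)
    k = len(genes)
    G = len(groups)
    sigma2 = {g: {} for g in genes}
    for label, samples in groups.items():
        vs = {g: sd([z[g][s] for s in samples]) ** 2 for g in genes}
        S = (k / (k - 1)) * sum(vs.values())
        for g in genes:
            sigma2[g][label] = max(0.0, (vs[g] - S / k**2) * k / (k - 2))
    zbar = {
        g: {label: np.mean([z[g][s] for s in samples]) for label, samples in groups.items()}
        for g in genes
    }
    dhat = {
        g: {
            label: zbar[g][label] - np.mean(list(zbar[g].values()))
            for label in groups
        }
        for g in genes
    }
    if G < 2:
        sv = {g: math.sqrt(sigma2[g][next(iter(groups))]) for g in genes}
        return sigma2, None, None, sv
    sum_d2 = sum(dhat[g][l] ** 2 for g in genes for l in groups)
    sum_var = sum(sigma2[g][l] / len(groups[l]) for g in genes for l in groups)
    gamma2 = max(0.0, sum_d2 / ((G - 1) * (k - 1)) - sum_var / (G * k))
    dtilde, sv = {g: {} for g in genes}, {}
    for g in genes:
        acc = 0.0
        for label, samples in groups.items():
            vt = sigma2[g][label] / len(samples)
            denom = gamma2 + vt
            shrink = gamma2 / denom if denom > 0 else 0.0
            dtilde[g][label] = dhat[g][label] * shrink
            acc += abs(dtilde[g][label]) + math.sqrt(vt * shrink)
        sv[g] = acc / G
    return sigma2, dtilde, gamma2, sv


def seq_knn(values, k):
    """Sequential KNN on a probes x arrays array with NaN holes."""
    v = np.array(values, dtype=float)
    miss = np.isnan(v)
    donors = [i for i in range(v.shape[0]) if not miss[i].any()]
    order = sorted(
        (i for i in range(v.shape[0]) if miss[i].any()),
        key=lambda i: (miss[i].sum(), i),
    )
    for i in order:
        obs = [j for j in range(v.shape[1]) if not miss[i, j]]
        dist = []
        for d in donors:
            dist.append(
                (math.sqrt(np.mean([(v[d, j] - v[i, j]) ** 2 for j in obs])), d)
            )
        dist.sort(key=lambda t: t[0])
        nearest = dist[: min(k, len(dist))]
        zero = [d for dd, d in nearest if dd == 0]
        for j in range(v.shape[1]):
            if miss[i, j]:
                if zero:
                    v[i, j] = np.mean([v[d, j] for d in zero])
                else:
                    w = [1.0 / dd for dd, _ in nearest]
                    v[i, j] = sum(
                        wi * v[d, j] for wi, (_, d) in zip(w, nearest)
                    ) / sum(w)
        miss[i] = False
        donors.append(i)
    return v


def dotplot(X, genes, celltypes, timepoints, detection=0.0):
    """X: dense cells x genes array; returns dict keyed (gene, ct, tp)."""
    out = {}
    for gi, g in enumerate(genes):
        for ct in sorted(set(celltypes)):
            for tp in sorted(set(timepoints)):
                idx = [
                    i
                    for i in range(X.shape[0])
                    if celltypes[i] == ct and timepoints[i] == tp
                ]
                if not idx:
                    out[(g, ct, tp)] = (float("nan"), float("nan"))
                    continue
                vals = [X[i, gi] for i in idx]
                frac = sum(v > detection for v in vals) / len(vals)
                out[(g, ct, tp)] = (frac, sum(vals) / len(vals))
    return out
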