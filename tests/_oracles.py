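"""Brute-force oracles kept independent of the library code paths."""


def oracle_quantile(diameters, weights, level):
    """Scan the sorted weighted empirical CDF with linear interpolation
    between consecutive unique diameters (ties aggregated)."""
    pairs = {}
    for d, w in zip(diameters, weights):
        pairs[d] = pairs.get(d, 0.0) + w
    ds = sorted(pairs)
    total = sum(pairs.values())
    cum = []
    acc = 0.0
    for d in ds:
        acc += pairs[d] / total
        cum.append(acc)
    if level <= cum[0]:
        return ds[0]
    for i in range(1, len(ds)):
        if level <= cum[i]:
            frac = (level - cum[i - 1]) / (cum[i] - cum[i - 1])
            return ds[i - 1] + frac * (ds[i] - ds[i - 1])
    return ds[-1]
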