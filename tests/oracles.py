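"""Independent naive-loop oracles used to cross-check the implementation.

Everything here is written directly from the printed feature/score
definitions using plain Python loops, deliberately sharing no code with
the package.
"""

import math


def oracle_time_features(x, wamp_thr=0.01, myop_thr=0.01, log_eps=1e-12, wl_conventional=True):
    n = len(x)
    mav = sum(abs(v) for v in x) / n
    rms = math.sqrt(sum(v * v for v in x) / n)
    var = sum(v * v for v in x) / (n - 1)
    aac = sum(abs(x[p + 1] - x[p]) for p in range(n - 1)) / n
    dasdv = math.sqrt(sum((x[p + 1] - x[p]) ** 2 for p in range(n - 1)) / (n - 1))
    zc = sum(
        1
        for p in range(n - 1)
        if (x[p] > 0 and x[p + 1] < 0) or (x[p] < 0 and x[p + 1] > 0)
    )
    if wl_conventional:
        wl = sum(abs(x[p + 1] - x[p]) for p in range(n - 1))
    else:
        wl = var
    wamp = sum(1 for p in range(n - 1) if abs(x[p + 1] - x[p]) >= wamp_thr)
    iemg = sum(abs(v) for v in x)
    myop = sum(1 for v in x if abs(v) >= myop_thr) / n
    logd = math.exp(sum(math.log(abs(v) + log_eps) for v in x) / n)
    return {
        "MAV": mav, "RMS": rms, "VAR": var, "AAC": aac, "DASDV": dasdv,
        "ZC": float(zc), "WL": wl, "WAMP": float(wamp), "iEMG": iemg,
        "MYOP": myop, "LOG": logd,
    }


def oracle_freq_features(power, freqs, low_band=(10.0, 250.0), high_band=(250.0, 500.0),
                         pkf_conventional=True):
    m = len(power)
    tp = sum(power)
    mnp = tp / m
    if pkf_conventional:
        best = 0
        for k in range(m):
            if power[k] > power[best]:
                best = k
        pkf = freqs[best]
    else:
        pkf = tp / 2.0
    mnf = sum(f * p for f, p in zip(freqs, power)) / tp
    cum = 0.0
    mdf = freqs[-1]
    for k in range(m):
        cum += power[k]
        if cum >= tp / 2.0:
            mdf = freqs[k]
            break
    low = sum(p for f, p in zip(freqs, power) if low_band[0] <= f <= low_band[1])
    high = sum(p for f, p in zip(freqs, power) if high_band[0] <= f <= high_band[1])
    fr = low / high
    return {"TP": tp, "PKF": pkf, "FR": fr, "MNF": mnf, "MDF": mdf, "MNP": mnp}


def oracle_segment_starts(n_samples, w, step):
    """Enumerate window start indices directly."""
    starts = []
    s = 0
    while s + w <= n_samples:
        starts.append(s)
        s += step
    return starts


def _entropy_bits(counts):
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def oracle_split_score(left, right):
    """Normalized information gain from first principles (bits)."""
    parent = [l + r for l, r in zip(left, right)]
    total = sum(parent)
    h_class = _entropy_bits(parent)
    h_split = _entropy_bits([sum(left), sum(right)])
    cond = sum(left) / total * _entropy_bits(left) + sum(right) / total * _entropy_bits(right)
    info = h_class - cond
    denom = h_class + h_split
    if denom == 0:
        return 0.0
    return 2 * info / denom


def oracle_lehmer(values, gains):
    wsum = sum(gains)
    w = [g / wsum for g in gains]
    num = sum(wi * s * s for wi, s in zip(w, values))
    den = sum(wi * s for wi, s in zip(w, values))
    return num / den
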