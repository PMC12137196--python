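"""Independent brute-force oracles, written from definitions with plain loops.

These deliberately avoid the package's vectorized code paths (and numpy
reductions where feasible) so they can serve as an independent check of the
feature chain, the bout detector and the confusion-matrix metrics.
"""

from __future__ import annotations

import cmath
import math


def brute_static(raw: list[list[float]], i: int, before: int = 12, after: int = 11) -> list[float]:
    """Centred truncated running mean at sample i, by direct summation."""
    n = len(raw)
    lo = max(0, i - before)
    hi = min(n, i + after + 1)
    out = []
    for ax in range(3):
        s = 0.0
        for j in range(lo, hi):
            s += raw[j][ax]
        out.append(s / (hi - lo))
    return out


def brute_periodogram_max(x: list[float], fs: float) -> float:
    """Max one-sided spectral density over positive frequencies, direct DFT."""
    n = len(x)
    mean = sum(x) / n
    xc = [v - mean for v in x]
    best = 0.0
    for j in range(1, n // 2 + 1):
        X = sum(xc[k] * cmath.exp(-2j * math.pi * j * k / n) for k in range(n))
        dens = abs(X) ** 2 / (fs * n)
        if j != n // 2 or n % 2 == 1:  # interior one-sided bins are doubled
            dens *= 2.0
        best = max(best, dens)
    return best


def brute_features(window_raw: list[list[float]], window_dba: list[list[float]], fs: float) -> dict[str, float]:
    """All 36 window features from their definitions."""
    n = len(window_raw)
    mag = [math.sqrt(sum(v**2 for v in s)) for s in window_raw]
    channels = {
        "x": [s[0] for s in window_raw],
        "y": [s[1] for s in window_raw],
        "z": [s[2] for s in window_raw],
        "mag": mag,
    }
    out: dict[str, float] = {}
    for ch, v in channels.items():
        mean = sum(v) / n
        ss = sum((u - mean) ** 2 for u in v)
        out[f"mean_{ch}"] = mean
        out[f"std_{ch}"] = math.sqrt(ss / (n - 1)) if n > 1 else 0.0
        out[f"max_{ch}"] = max(v)
        out[f"min_{ch}"] = min(v)
        m2 = ss / n
        if m2 == 0.0:
            out[f"skew_{ch}"] = 0.0
            out[f"kurt_{ch}"] = 0.0
        else:
            m3 = sum((u - mean) ** 3 for u in v) / n
            m4 = sum((u - mean) ** 4 for u in v) / n
            out[f"skew_{ch}"] = m3 / m2**1.5
            out[f"kurt_{ch}"] = m4 / m2**2
    for name, (a, b) in {
        "cor_xy": (channels["x"], channels["y"]),
        "cor_xz": (channels["x"], channels["z"]),
        "cor_yz": (channels["y"], channels["z"]),
    }.items():
        ma, mb = sum(a) / n, sum(b) / n
        sa = math.sqrt(sum((u - ma) ** 2 for u in a) / n)
        sb = math.sqrt(sum((u - mb) ** 2 for u in b) / n)
        if sa == 0.0 or sb == 0.0:
            out[name] = 0.0
        else:
            cov = sum((u - ma) * (w - mb) for u, w in zip(a, b)) / n
            out[name] = max(-1.0, min(1.0, cov / (sa * sb)))
    for i, ax in enumerate(("x", "y", "z")):
        out[f"mean_dba_{ax}"] = sum(s[i] for s in window_dba) / n
    od = [abs(s[0]) + abs(s[1]) + abs(s[2]) for s in window_dba]
    out["odba_total"] = sum(od)
    out["odba_mean"] = sum(od) / n
    for ch, v in channels.items():
        out[f"dps_{ch}"] = 0.0 if max(v) == min(v) else brute_periodogram_max(v, fs)
    return out


def brute_bouts(labels: list[str], target: str) -> list[tuple[int, int]]:
    """Run-length encoding: (start index, run length) of maximal target runs."""
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == target:
            j = i
            while j < n and labels[j] == target:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def brute_metrics(counts: list[list[int]]) -> dict:
    """One-vs-rest precision/recall/MCC and overall error from definitions."""
    k = len(counts)
    total = sum(sum(row) for row in counts)
    out = {"per_class": [], "overall_error": None}
    correct = sum(counts[i][i] for i in range(k))
    out["overall_error"] = (total - correct) / total
    for i in range(k):
        tp = counts[i][i]
        fn = sum(counts[i]) - tp
        fp = sum(counts[r][i] for r in range(k)) - tp
        tn = total - tp - fn - fp
        prec = tp / (tp + fp) if tp + fp else math.nan
        rec = tp / (tp + fn) if tp + fn else math.nan
        den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / math.sqrt(den) if den else math.nan
        out["per_class"].append({"TP": tp, "FP": fp, "TN": tn, "FN": fn,
                                 "precision": prec, "recall": rec, "mcc": mcc})
    return out
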