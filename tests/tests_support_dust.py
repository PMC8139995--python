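"""Brute-force low-complexity scoring oracle, independent of the package's
rolling-window implementation."""
from collections import Counter


def brute_dust(seq, window=64, threshold=20.0):
    seq = seq.upper()
    raw = []
    for i in range(len(seq)):
        w = seq[i : i + window]
        if len(w) < 3:
            break
        counts = Counter(
            w[j : j + 3] for j in range(len(w) - 2) if "N" not in w[j : j + 3]
        )
        score = sum(c * (c - 1) // 2 for c in counts.values())
        if score / (len(w) - 2) > threshold:
            raw.append((i, i + len(w)))
    merged = []
    for s, e in raw:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
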