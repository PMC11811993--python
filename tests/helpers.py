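"""Independent brute-force oracles used to cross-check the implementation.

Each oracle recomputes a quantity by naive enumeration, deliberately sharing
no code with the library path it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def brute_force_digest(seq: str, cleave_after="KR", suppress_before="P",
                       min_length=7, max_length=30, missed_cleavages=0) -> list[str]:
    """Enumerate every substring and keep those consistent with the cut rules."""
    n = len(seq)

    def is_cut(i: int) -> bool:  # a cut between positions i-1 and i
        return 0 < i < n and seq[i - 1] in cleave_after and seq[i] not in suppress_before

    peptides = set()
    for a in range(n):
        if not (a == 0 or is_cut(a)):
            continue
        for b in range(a + 1, n + 1):
            if not (b == n or is_cut(b)):
                continue
            internal = sum(1 for i in range(a + 1, b) if is_cut(i))
            if internal <= missed_cleavages and min_length <= b - a <= max_length:
                peptides.add(seq[a:b])
    return sorted(peptides)


def sort_slice_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Sort present values (stably, by value then input position), slice the
    sorted list into n_bins nearly equal chunks, map bin labels back."""
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    present_idx = [i for i in range(len(values)) if not np.isnan(values[i])]
    ordered = sorted(present_idx, key=lambda i: (values[i], i))
    n = len(ordered)
    sizes = [n // n_bins + (1 if b < n % n_bins else 0) for b in range(n_bins)]
    pos = 0
    for b, size in enumerate(sizes, start=1):
        for i in ordered[pos : pos + size]:
            out[i] = b
        pos += size
    return out


def pairwise_r2_oracle(values: pd.DataFrame, min_common: int = 3):
    """Materialize each pair's common-gene sub-vectors and correlate them."""
    cols = list(values.columns)
    m = len(cols)
    r2 = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(m):
            sub = values[[cols[i], cols[j]]].dropna() if i != j else (
                values[[cols[i]]].dropna().assign(_dup=lambda d: d.iloc[:, 0])
            )
            x = sub.iloc[:, 0].to_numpy(float)
            y = sub.iloc[:, 1].to_numpy(float)
            if len(x) < min_common or np.std(x) == 0 or np.std(y) == 0:
                continue
            r2[i, j] = np.corrcoef(x, y)[0, 1] ** 2
    return pd.DataFrame(r2, index=cols, columns=cols)
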