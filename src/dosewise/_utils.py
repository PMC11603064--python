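"""Shared small statistical helpers."""

from __future__ import annotations

import hashlib

import numpy as np


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    m = int(ok.sum())
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / (np.arange(m) + 1.0)
    # enforce monotonicity from the largest p downwards
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def round_sigfigs(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures (reporting convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def stable_label_seed(seed: int, label: str) -> np.random.Generator:
    """Independent PRNG stream keyed by (seed, label), stable across runs."""
    digest = hashlib.sha256(str(label).encode()).digest()
    key = int.from_bytes(digest[:4], "little")
    return np.random.default_rng([int(seed), key])
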