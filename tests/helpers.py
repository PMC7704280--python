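"""Independent straight-line oracles used to cross-check the engine.

These deliberately mirror the definitions one-for-one with nested Python
loops and no shared code with the package internals.
"""

import numpy as np
import pandas as pd


def nested_loop_match(real_df, syn_df, pop_df, qi):
    """O(n*m) pairwise-equality matching oracle.

    Returns (f, F, I, partners) with missing-QI rows treated as unmatchable
    singletons.
    """
    def row_key(df, i):
        vals = [df[q].iloc[i] for q in qi]
        if any(pd.isna(v) for v in vals):
            return None
        return tuple(vals)

    n = len(real_df)
    f = np.zeros(n, int)
    F = np.zeros(n, int)
    I = np.zeros(n, int)
    partners = [[] for _ in range(n)]
    for s in range(n):
        ks = row_key(real_df, s)
        if ks is None:
            f[s] = 1
            F[s] = 1
            continue
        for s2 in range(n):
            if row_key(real_df, s2) == ks:
                f[s] += 1
        for p in range(len(pop_df)):
            if row_key(pop_df, p) == ks:
                F[s] += 1
        for t in range(len(syn_df)):
            if row_key(syn_df, t) == ks:
                partners[s].append(t)
        I[s] = 1 if partners[s] else 0
    return f, F, I, partners


def loop_risks(f, F, I, R, lambda_c, n, N):
    """Literal per-record transcription of the two directional risk sums."""
    A = 0.0
    B = 0.0
    for s in range(len(f)):
        A += lambda_c[s] * (1.0 / f[s]) * I[s] * R[s]
        B += lambda_c[s] * (1.0 / F[s]) * I[s] * R[s]
    return A / N, B / n
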