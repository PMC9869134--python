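"""Shared oracles and lightweight builders used across test modules."""

from itertools import product

import numpy as np
from scipy import stats

from bifuse.containers import Epoch


def fake_trial_pairs(n, label_of=lambda i: "left" if i % 2 else "right",
                     duration_s=10.0, rate=128.0):
    """Paired (eeg, fnirs) 10-s epochs with distinct parent ids."""
    out = []
    ns = int(duration_s * rate)
    for i in range(n):
        lab = label_of(i)
        eeg = Epoch("eeg", np.zeros((2, ns)), rate, 0.0, lab, f"t{i:03d}")
        fn = Epoch("hbo", np.zeros((2, ns)), rate, 0.0, lab, f"t{i:03d}")
        out.append((eeg, fn))
    return out


def whitening_oracle(c0, c1):
    """Independent CSP construction: whiten the composite covariance, then
    eigendecompose the whitened class-0 covariance."""
    evals, evecs = np.linalg.eigh(c0 + c1)
    P = np.diag(evals ** -0.5) @ evecs.T
    lam, rot = np.linalg.eigh(P @ c0 @ P.T)
    order = np.argsort(lam)[::-1]
    return (rot[:, order].T @ P), lam[order]


def exact_wilcoxon_enumeration(d):
    """Two-sided exact signed-rank p-value by enumerating all sign
    assignments of the ranked absolute differences."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in product([0, 1], repeat=n)
    ])
    w_min = min(w_obs, ws.max() - w_obs)
    p = np.mean(ws <= w_min) + np.mean(ws >= ws.max() - w_min)
    return min(1.0, float(p))
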