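"""Independent brute-force oracles for the test suite.

Everything here is written directly from the detection rules / classical
formulas with plain Python loops, deliberately sharing no code with the
package implementation, so agreement between the two is informative.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --------------------------------------------------------------------------
# head-movement detection: direct transcription of the rules
# --------------------------------------------------------------------------

def head_scan(times, angles, threshold=3.0, window=10):
    """Return (onset_idx, offset_idx, peak_idx, smoothed) by direct scan."""
    n = len(times)
    v = []
    for i in range(n - 1):
        v.append((angles[i + 1] - angles[i]) / (times[i + 1] - times[i]))
    s = []
    for i in range(len(v)):
        chunk = v[i:i + window]
        s.append(sum(chunk) / len(chunk))
    peak = 0
    for i in range(len(s)):
        if abs(s[i]) > abs(s[peak]):
            peak = i
    onset = 0
    for i in range(peak):
        if abs(s[i]) < threshold:
            onset = i
    # the loop above keeps the *last* below-threshold index before the peak
    found = any(abs(s[i]) < threshold for i in range(peak))
    if not found:
        onset = 0
    offset = len(s) - 1
    for i in range(peak + 1, len(s)):
        if abs(s[i]) < threshold:
            offset = i
            break
    return onset, offset, peak, s


# --------------------------------------------------------------------------
# saccade detection: direct transcription of the rules
# --------------------------------------------------------------------------

def saccade_scan(times, angles, onset_thr=1.0, offset_thr=0.1,
                 min_dur=0.030):
    """Return a list of (onset_idx, offset_idx, truncated) by direct scan."""
    n = len(times)
    if times[-1] - times[0] < min_dur:
        return []
    events = []
    i = 0
    while i < n - 1:
        if abs(angles[i + 1] - angles[i]) >= onset_thr:
            onset = i
            offset = None
            for j in range(onset + 1, n):
                if (times[j] - times[onset] >= min_dur
                        and abs(angles[j] - angles[j - 1]) < offset_thr):
                    offset = j
                    break
            truncated = offset is None
            if truncated:
                offset = n - 1
            events.append((onset, offset, truncated))
            i = offset
        else:
            i += 1
    return events


# --------------------------------------------------------------------------
# psychometric fitting: dense grid-search MLE
# --------------------------------------------------------------------------

def _phi(z):
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def grid_mle(positions, n_right, n_total, mu_grid, sigma_grid):
    """Return (mu_hat, sigma_hat, max_ll) over the cartesian grid."""
    best = (None, None, -math.inf)
    for mu in mu_grid:
        for sigma in sigma_grid:
            ll = 0.0
            for x, r, m in zip(positions, n_right, n_total):
                p = _phi((x - mu) / sigma)
                p = min(max(p, 1e-12), 1 - 1e-12)
                ll += r * math.log(p) + (m - r) * math.log(1 - p)
            if ll > best[2]:
                best = (mu, sigma, ll)
    return best


def normal_cdf_by_quadrature(z, lo=-12.0, n=200001):
    """Phi(z) via trapezoidal integration of the standard normal density."""
    xs = np.linspace(lo, z, n)
    dens = np.exp(-xs ** 2 / 2.0) / math.sqrt(2.0 * math.pi)
    return float(np.trapezoid(dens, xs))


# --------------------------------------------------------------------------
# within-subject ANOVA oracles
# --------------------------------------------------------------------------

def longhand_2x2(y):
    """Fully written-out SS decomposition of a subjects x 2 x 2 array.

    Returns dict effect -> (SS_effect, SS_error, F) with effects 'A', 'B',
    'A x B'; every sum is spelled out with explicit loops.
    """
    ns, na, nb = y.shape
    assert na == 2 and nb == 2
    grand = sum(y[s, i, j] for s in range(ns) for i in range(na)
                for j in range(nb)) / (ns * na * nb)
    subj = [sum(y[s, i, j] for i in range(na) for j in range(nb)) / (na * nb)
            for s in range(ns)]
    a_m = [sum(y[s, i, j] for s in range(ns) for j in range(nb)) / (ns * nb)
           for i in range(na)]
    b_m = [sum(y[s, i, j] for s in range(ns) for i in range(na)) / (ns * na)
           for j in range(nb)]
    ab = [[sum(y[s, i, j] for s in range(ns)) / ns for j in range(nb)]
          for i in range(na)]
    sa = [[sum(y[s, i, j] for j in range(nb)) / nb for i in range(na)]
          for s in range(ns)]
    sb = [[sum(y[s, i, j] for i in range(na)) / na for j in range(nb)]
          for s in range(ns)]

    out = {}
    ss_a = ns * nb * sum((a_m[i] - grand) ** 2 for i in range(na))
    ss_as = nb * sum((sa[s][i] - subj[s] - a_m[i] + grand) ** 2
                     for s in range(ns) for i in range(na))
    out["A"] = (ss_a, ss_as,
                (ss_a / (na - 1)) / (ss_as / ((na - 1) * (ns - 1))))

    ss_b = ns * na * sum((b_m[j] - grand) ** 2 for j in range(nb))
    ss_bs = na * sum((sb[s][j] - subj[s] - b_m[j] + grand) ** 2
                     for s in range(ns) for j in range(nb))
    out["B"] = (ss_b, ss_bs,
                (ss_b / (nb - 1)) / (ss_bs / ((nb - 1) * (ns - 1))))

    ss_ab = ns * sum((ab[i][j] - a_m[i] - b_m[j] + grand) ** 2
                     for i in range(na) for j in range(nb))
    ss_abs = sum((y[s, i, j] - ab[i][j] - sa[s][i] - sb[s][j]
                  + a_m[i] + b_m[j] + subj[s] - grand) ** 2
                 for s in range(ns) for i in range(na) for j in range(nb))
    dfn = (na - 1) * (nb - 1)
    out["A x B"] = (ss_ab, ss_abs, (ss_ab / dfn) / (ss_abs / (dfn * (ns - 1))))
    return out


def _orth_contrast(k):
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
    return h / np.linalg.norm(h, axis=0, keepdims=True)


def contrast_anova(y, factor_axes=None):
    """Contrast-projection RM-ANOVA oracle for a subjects x k1 x ... array.

    For each effect, project the per-subject scores (averaged over the other
    factors) onto the Kronecker product of orthonormal factor contrasts;
    SS_effect = g * n * ||mean(Z)||^2, SS_error = g * sum((Z - mean)^2),
    with g the number of averaged-over cells. Algebraically equivalent to the
    classical decomposition on balanced data, computed by a different route.
    """
    n = y.shape[0]
    axes = list(range(1, y.ndim))
    out = {}
    for r in range(1, len(axes) + 1):
        for eff in itertools.combinations(axes, r):
            other = [ax for ax in axes if ax not in eff]
            scores = y.mean(axis=tuple(other)) if other else y
            scores = scores.reshape(n, -1)
            c = np.array([[1.0]])
            mats = [_orth_contrast(y.shape[ax]) for ax in eff]
            c = mats[0]
            for m in mats[1:]:
                c = np.kron(c, m)
            g = int(np.prod([y.shape[ax] for ax in other])) if other else 1
            z = scores @ c
            zbar = z.mean(axis=0)
            ss_eff = g * n * float(zbar @ zbar)
            ss_err = g * float(np.sum((z - zbar) ** 2))
            dfn = c.shape[1]
            dfd = dfn * (n - 1)
            f = (ss_eff / dfn) / (ss_err / dfd)
            out[eff] = (ss_eff, ss_err, f)
    return out
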