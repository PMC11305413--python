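"""Within-subject inferential statistics.

Implements the inferential machinery used on per-subject, per-condition
summaries (PHAs, JNDs, fixation fractions, movement amplitudes):

* fully-crossed, balanced repeated-measures ANOVA with Greenhouse-Geisser
  (GG) sphericity correction, partial eta-squared and SPSS-style observed
  power, for any number of 2- or 3-level within-subject factors;
* two-tailed paired (and unpaired) t-tests with explicit Bonferroni
  correction;
* per-subject least-squares regressions of PHA on visual velocity gain and
  one-sample t-tests of the resulting slopes against zero.

The ANOVA uses the classical sums-of-squares decomposition for balanced
within-subject designs: each effect is tested against its interaction with
subjects. GG epsilon comes from the sample covariance of the subject-level
scores projected onto orthonormal effect contrasts,
``eps = tr(M)^2 / (d * tr(M^2))`` with ``M = C' S C``; it equals 1 for a
compound-symmetric covariance and is bounded below by ``1/d``. Observed
power follows the convention of mainstream GUI statistics packages:
noncentrality ``lambda = F * df_num`` evaluated against the central-F
critical value at alpha = 0.05 (approximate by construction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectResult",
    "SlopeFit",
    "AnovaResults",
    "RepeatedMeasuresANOVA",
    "rm_anova",
    "paired_t",
    "fit_gain_slopes",
    "slopes_vs_zero",
]

ALPHA = 0.05


@dataclass
class EffectResult:
    """One inferential result (an ANOVA effect or a t-test).

    For ANOVA effects ``F``, ``eta_sq`` (partial), ``power`` and
    ``gg_epsilon`` are set and ``df_num``/``df_den`` are the GG-scaled
    degrees of freedom. For t-tests ``t`` and ``df_num`` (= df) are set.
    P-values are kept at full precision; Bonferroni correction multiplies p
    by the family size, capped at 1.
    """

    name: str
    p: float
    df_num: float
    df_den: Optional[float] = None
    F: Optional[float] = None
    t: Optional[float] = None
    eta_sq: Optional[float] = None
    power: Optional[float] = None
    gg_epsilon: Optional[float] = None
    degenerate: bool = False

    @property
    def statistic(self) -> float:
        return self.F if self.F is not None else self.t


@dataclass
class SlopeFit:
    """Per-subject OLS line through the (gain, PHA) triples."""

    subject: str
    slope: float
    intercept: float


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) matrix with orthonormal columns orthogonal to the constant."""
    helmert = np.zeros((k, k - 1))
    for j in range(1, k):
        helmert[:j, j - 1] = 1.0
        helmert[j, j - 1] = -j
    return helmert / np.linalg.norm(helmert, axis=0, keepdims=True)


def _gg_epsilon(scores: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject x cell scores for one effect."""
    d = contrasts.shape[1]
    if d <= 1:
        return 1.0
    cov = np.cov(scores, rowvar=False)
    m = contrasts.T @ cov @ contrasts
    tr = np.trace(m)
    tr2 = np.trace(m @ m)
    if tr2 <= 0:
        return 1.0
    eps = tr ** 2 / (d * tr2)
    return float(np.clip(eps, 1.0 / d, 1.0))


@dataclass
class AnovaResults:
    """Collection of :class:`EffectResult` rows with a summary table."""

    effects: list[EffectResult]
    dv: str = "value"
    n_subjects: int = 0

    def __iter__(self):
        return iter(self.effects)

    def __getitem__(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "effect": e.name, "F": e.F, "df_num": e.df_num,
            "df_den": e.df_den, "p": e.p, "eta_sq_partial": e.eta_sq,
            "power": e.power, "gg_epsilon": e.gg_epsilon,
            "degenerate": e.degenerate,
        } for e in self.effects])

    def summary(self) -> str:
        header = (f"Repeated-measures ANOVA on '{self.dv}' "
                  f"({self.n_subjects} subjects)")
        df = self.as_dataframe()
        with pd.option_context("display.float_format", "{:0.4f}".format):
            return header + "\n" + "-" * len(header) + "\n" + df.to_string(
                index=False)


class RepeatedMeasuresANOVA:
    """Balanced fully-crossed within-subject ANOVA.

    Parameters
    ----------
    data : DataFrame
        Long format, one measurement per subject x cell.
    dv : str
        Column holding the dependent variable.
    within : sequence of str
        Within-subject factor columns (2 or more levels each).
    subject : str
        Subject-identifier column. At least two subjects required; missing
        or duplicated cells raise ``ValueError``.
    """

    def __init__(self, data: pd.DataFrame, dv: str,
                 within: Sequence[str], subject: str = "subject"):
        self.dv = dv
        self.within = list(within)
        self.subject = subject

        counts = data.pivot_table(index=subject, columns=self.within,
                                  values=dv, aggfunc="size", fill_value=0)
        if counts.size == 0 or not np.all(counts.to_numpy() == 1):
            raise ValueError(
                "design must be balanced with exactly one value per "
                "subject x cell")
        cells = data.pivot_table(index=subject, columns=self.within, values=dv)
        self.subjects = list(cells.index)
        if len(self.subjects) < 2:
            raise ValueError("need at least two subjects")
        self.levels = [sorted(data[f].unique().tolist()) for f in self.within]
        shape = [len(self.subjects)] + [len(lv) for lv in self.levels]
        # pivot_table sorts level combinations lexicographically, matching
        # the sorted per-factor level lists, so a plain reshape is correct
        self.array = cells.to_numpy().reshape(shape)

    def _marginal(self, keep_axes: tuple[int, ...]) -> np.ndarray:
        """Mean over all axes not in ``keep_axes`` (axis 0 = subjects)."""
        drop = tuple(ax for ax in range(self.array.ndim)
                     if ax not in keep_axes)
        return self.array.mean(axis=drop, keepdims=True)

    def _effect_term(self, axes: tuple[int, ...]) -> np.ndarray:
        """Inclusion-exclusion estimate of the effect on the kept axes."""
        term = np.zeros_like(self._marginal(axes))
        for r in range(len(axes) + 1):
            for sub in itertools.combinations(axes, r):
                sign = (-1) ** (len(axes) - len(sub))
                term = term + sign * self._marginal(sub)
        return term

    def fit(self, alpha: float = ALPHA) -> AnovaResults:
        """Run the full decomposition for every main effect and interaction."""
        arr = self.array
        n_subj = arr.shape[0]
        factor_axes = list(range(1, arr.ndim))
        k = {ax: arr.shape[ax] for ax in factor_axes}
        total_cells = int(np.prod([k[ax] for ax in factor_axes]))

        effects: list[EffectResult] = []
        for r in range(1, len(factor_axes) + 1):
            for axes in itertools.combinations(factor_axes, r):
                name = " x ".join(self.within[ax - 1] for ax in axes)
                reps_eff = n_subj * total_cells // int(
                    np.prod([k[ax] for ax in axes]))
                ss_eff = reps_eff * float(np.sum(self._effect_term(axes) ** 2))

                err_axes = (0,) + axes
                reps_err = total_cells // int(
                    np.prod([k[ax] for ax in axes]))
                ss_err = reps_err * float(
                    np.sum(self._effect_term(err_axes) ** 2))

                df_num = float(np.prod([k[ax] - 1 for ax in axes]))
                df_den = (n_subj - 1) * df_num

                # GG epsilon from subject-level scores for this effect
                scores = self._marginal(err_axes).reshape(n_subj, -1)
                contrasts = np.array([[1.0]])
                if df_num > 1:
                    mats = [_orthonormal_contrasts(k[ax]) for ax in axes]
                    contrasts = mats[0]
                    for m in mats[1:]:
                        contrasts = np.kron(contrasts, m)
                eps = _gg_epsilon(scores, contrasts) if df_num > 1 else 1.0

                degenerate = ss_err <= 1e-300 * max(ss_eff, 1.0)
                if degenerate and ss_eff > 0:
                    f_stat, p = float("inf"), 0.0
                    eta = 1.0
                    power = 1.0
                else:
                    if ss_err == 0.0:
                        f_stat, p, eta, power = 0.0, 1.0, 0.0, alpha
                    else:
                        ms_eff = ss_eff / df_num
                        ms_err = ss_err / df_den
                        f_stat = ms_eff / ms_err
                        d1, d2 = eps * df_num, eps * df_den
                        p = float(stats.f.sf(f_stat, d1, d2))
                        eta = ss_eff / (ss_eff + ss_err)
                        fcrit = stats.f.isf(alpha, d1, d2)
                        lam = f_stat * d1
                        power = float(stats.ncf.sf(fcrit, d1, d2, lam))
                effects.append(EffectResult(
                    name=name, p=p, df_num=eps * df_num, df_den=eps * df_den,
                    F=float(f_stat), eta_sq=float(eta), power=power,
                    gg_epsilon=eps, degenerate=bool(degenerate and ss_eff > 0),
                ))
        return AnovaResults(effects=effects, dv=self.dv, n_subjects=n_subj)


def rm_anova(data: pd.DataFrame, dv: str, within: Sequence[str],
             subject: str = "subject") -> AnovaResults:
    """Functional shorthand for ``RepeatedMeasuresANOVA(...).fit()``."""
    return RepeatedMeasuresANOVA(data, dv, within, subject=subject).fit()


def paired_t(a: Sequence[float], b: Sequence[float], correction_m: int = 1,
             name: str = "paired t", paired: bool = True) -> EffectResult:
    """Two-tailed paired t-test with explicit Bonferroni correction.

    ``correction_m`` is the number of comparisons in the post hoc family; the
    p-value is multiplied by it and capped at 1. ``paired=False`` gives the
    pooled-variance unpaired variant (equal group sizes not required).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        if a.size < 2:
            raise ValueError("need at least two pairs")
        d = a - b
        sd = d.std(ddof=1)
        df = a.size - 1
        if sd == 0:
            t_stat = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
            p = 1.0 if d.mean() == 0 else 0.0
            return EffectResult(name=name, p=min(p * correction_m, 1.0),
                                df_num=df, t=float(t_stat), degenerate=True)
        t_stat = d.mean() / (sd / np.sqrt(a.size))
        p = 2.0 * stats.t.sf(abs(t_stat), df)
    else:
        res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
        df = a.size + b.size - 2
        if not np.isfinite(t_stat):
            return EffectResult(name=name, p=0.0, df_num=df, t=t_stat,
                                degenerate=True)
    return EffectResult(name=name, p=float(min(p * correction_m, 1.0)),
                        df_num=float(df), t=float(t_stat))


def fit_gain_slopes(pha_by_gain: pd.DataFrame,
                    gain_col: str = "gain", pha_col: str = "pha",
                    subject: str = "subject") -> list[SlopeFit]:
    """Per-subject least-squares line through the three (gain, PHA) points.

    Each subject must contribute exactly three gain levels (the 1.0 / 1.15 /
    1.3 presets in the background-motion experiment).
    """
    fits = []
    for subj, grp in pha_by_gain.groupby(subject, sort=True):
        if len(grp) != 3 or grp[gain_col].nunique() != 3:
            raise ValueError(
                f"subject {subj!r} must have exactly 3 distinct gains")
        slope, intercept = np.polyfit(grp[gain_col].to_numpy(dtype=float),
                                      grp[pha_col].to_numpy(dtype=float), 1)
        fits.append(SlopeFit(subject=str(subj), slope=float(slope),
                             intercept=float(intercept)))
    return fits


def slopes_vs_zero(slopes: Sequence[SlopeFit] | Sequence[float],
                   tails: str = "one", name: str = "slopes vs 0",
                   correction_m: int = 1) -> EffectResult:
    """One-sample t-test of the per-subject gain slopes against zero.

    ``tails="one"`` (default) tests the directed hypothesis that the slope is
    positive — stronger visual background motion shifts the perceived probe
    position further; ``tails="two"`` gives the undirected test.
    """
    vals = np.array([s.slope if isinstance(s, SlopeFit) else float(s)
                     for s in slopes], dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two slopes")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    df = vals.size - 1
    sd = vals.std(ddof=1)
    if sd == 0:
        t_stat = 0.0 if vals.mean() == 0 else np.inf * np.sign(vals.mean())
        p = 1.0 if vals.mean() == 0 else (0.0 if vals.mean() > 0 else 1.0)
        return EffectResult(name=name, p=min(p * correction_m, 1.0),
                            df_num=df, t=float(t_stat), degenerate=True)
    t_stat = vals.mean() / (sd / np.sqrt(vals.size))
    if tails == "one":
        p = float(stats.t.sf(t_stat, df))
    else:
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return EffectResult(name=name, p=float(min(p * correction_m, 1.0)),
                        df_num=float(df), t=float(t_stat))
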