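"""Cumulative-Gaussian psychometric fitting for 2AFC localization data.

The observer judges, trial by trial, whether a comparison stimulus appeared
left or right of a previously seen probe. Aggregating the binary responses
per comparison offset x gives binomial counts that are fitted by maximum
likelihood with

    P(right; x) = Phi((x - mu) / sigma),

where mu is the point of horizontal alignment (PHA; the offset judged
aligned with the probe, the accuracy measure) and sigma the spread of the
function (the precision measure). The just-noticeable difference (JND) is
``JND_SCALE * sigma``; the default convention ``JND_SCALE = 1`` takes the
50%-to-84.1% half-width. The alternative 75%-point convention
(0.6745 * sigma) is a one-line change of that constant.

The module follows the Model/Results idiom: build a
:class:`PsychometricModel` from counts or raw trials, call :meth:`fit`, and
read PHA/JND off the returned :class:`PsychometricFit`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .synthetic import TrialRecord

__all__ = [
    "JND_SCALE",
    "STIMULUS_RANGE",
    "ResponseTable",
    "PsychometricModel",
    "PsychometricFit",
    "fit_psychometric",
    "compute_jnd",
    "check_inclusion",
]

#: JND as a multiple of the fitted sigma. 1.0 = the 84.1%-point convention.
JND_SCALE = 1.0

#: Half-range (deg) of the comparison-stimulus offsets; a participant whose
#: PHA falls outside it did not perceive the stimulus of interest within the
#: presented range and is excluded.
STIMULUS_RANGE = 1.37

_LOG_SIGMA_BOUNDS = (np.log(1e-4), np.log(100.0))


@dataclass
class ResponseTable:
    """Binomial response counts per comparison position.

    ``positions`` must be sorted ascending; ``n_right[i]`` of ``n_total[i]``
    responses at ``positions[i]`` were "right".
    """

    positions: np.ndarray
    n_right: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.n_right = np.asarray(self.n_right, dtype=float)
        self.n_total = np.asarray(self.n_total, dtype=float)
        if not (self.positions.size == self.n_right.size == self.n_total.size):
            raise ValueError("positions, n_right, n_total must align")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be sorted ascending and unique")
        if np.any(self.n_right < 0) or np.any(self.n_right > self.n_total):
            raise ValueError("need 0 <= n_right <= n_total")

    @classmethod
    def from_trials(
        cls, trials: Union[pd.DataFrame, Iterable[TrialRecord]],
    ) -> "ResponseTable":
        """Aggregate raw trials (records or a DataFrame with columns
        ``comparison_deg`` and ``response``) into counts per position."""
        if not isinstance(trials, pd.DataFrame):
            trials = pd.DataFrame(
                {"comparison_deg": [t.comparison_deg for t in trials],
                 "response": [t.response for t in trials]})
        if trials["response"].isna().any():
            raise ValueError("trials without responses cannot be aggregated")
        grouped = trials.groupby("comparison_deg")["response"].agg(
            n_right=lambda s: int((s == "right").sum()), n_total="size")
        grouped = grouped.sort_index()
        return cls(grouped.index.to_numpy(), grouped["n_right"].to_numpy(),
                   grouped["n_total"].to_numpy())


@dataclass
class PsychometricFit:
    """Result of a cumulative-Gaussian fit.

    ``included`` records the participant-inclusion rule: the fit converged
    and the PHA lies within the presented stimulus range.
    """

    pha: float
    sigma: float
    log_likelihood: float
    converged: bool
    included: bool
    n_trials: int
    model: Optional["PsychometricModel"] = None

    @property
    def jnd(self) -> float:
        """Just-noticeable difference under the module's JND convention."""
        return JND_SCALE * self.sigma

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        """Fitted P(right) at comparison offset ``x``."""
        return norm.cdf((np.asarray(x, float) - self.pha) / self.sigma)

    def summary(self) -> str:
        lines = [
            "Cumulative-Gaussian psychometric fit (2AFC)",
            "-------------------------------------------",
            f"n trials          {self.n_trials:>10d}",
            f"PHA (mu)          {self.pha:>10.4f} deg",
            f"sigma             {self.sigma:>10.4f} deg",
            f"JND               {self.jnd:>10.4f} deg",
            f"log-likelihood    {self.log_likelihood:>10.3f}",
            f"converged         {str(self.converged):>10s}",
            f"included          {str(self.included):>10s}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot counts and the fitted function; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            tab = self.model.table
            ax.plot(tab.positions, tab.n_right / tab.n_total, "ko",
                    label="observed")
            lo, hi = tab.positions[0], tab.positions[-1]
        else:
            lo, hi = self.pha - 3 * self.sigma, self.pha + 3 * self.sigma
        xs = np.linspace(lo, hi, 200)
        ax.plot(xs, self.predict(xs), "C0-", label="fit")
        ax.axhline(0.5, color="grey", lw=0.5)
        ax.axvline(self.pha, color="grey", lw=0.5)
        ax.set_xlabel("comparison offset (deg)")
        ax.set_ylabel("P(right)")
        ax.legend()
        return ax


class PsychometricModel:
    """Maximum-likelihood cumulative-Gaussian model for binomial 2AFC counts.

    Parameters
    ----------
    table : ResponseTable
        Counts per comparison position; needs at least two positions with
        observations. All-left or all-right data leave the location
        unidentified: :meth:`fit` then returns an unconverged result with no
        PHA rather than raising.
    """

    def __init__(self, table: ResponseTable):
        if np.count_nonzero(table.n_total > 0) < 2:
            raise ValueError("need >= 2 positions with observations")
        self.table = table

    @classmethod
    def from_trials(
        cls, trials: Union[pd.DataFrame, Iterable[TrialRecord]],
    ) -> "PsychometricModel":
        return cls(ResponseTable.from_trials(trials))

    def loglike(self, mu: float, sigma: float) -> float:
        """Binomial log-likelihood (up to the fixed combinatorial constant)."""
        tab = self.table
        p = norm.cdf((tab.positions - mu) / sigma)
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return float(np.sum(tab.n_right * np.log(p)
                            + (tab.n_total - tab.n_right) * np.log(1.0 - p)))

    def _starts(self) -> list[tuple[float, float]]:
        """Five deterministic multistart points in (mu, sigma).

        The data-driven start interpolates the 50% crossing of the empirical
        proportions, which makes the start set (and hence the optimum found)
        transform covariantly under translation and reflection of the
        stimulus axis.
        """
        tab = self.table
        props = np.where(tab.n_total > 0, tab.n_right / np.maximum(tab.n_total, 1), 0.5)
        span = float(tab.positions[-1] - tab.positions[0])
        centre = float(tab.positions.mean())
        # crossing of the empirical proportions through 0.5
        crossing = centre
        above = props >= 0.5
        for i in range(props.size - 1):
            if above[i] != above[i + 1] and props[i + 1] != props[i]:
                w = (0.5 - props[i]) / (props[i + 1] - props[i])
                crossing = float(tab.positions[i]
                                 + w * (tab.positions[i + 1] - tab.positions[i]))
                break
        return [
            (crossing, span / 4.0),
            (crossing, span / 10.0),
            (crossing, span),
            (centre, span / 4.0),
            (crossing, span / 2.0),
        ]

    def fit(self, tol: float = 1e-8) -> PsychometricFit:
        """Maximise the binomial likelihood over (mu, sigma).

        Quasi-Newton (L-BFGS-B) in (mu, log sigma) from five deterministic
        multistarts; ties broken by highest log-likelihood, then smallest
        sigma. Degenerate all-left/all-right data yield
        ``converged = False`` with NaN parameters.
        """
        tab = self.table
        total_right = tab.n_right.sum()
        total = tab.n_total.sum()
        if total_right == 0 or total_right == total:
            return PsychometricFit(
                pha=float("nan"), sigma=float("nan"),
                log_likelihood=float("nan"), converged=False, included=False,
                n_trials=int(total), model=self)

        def nll(theta: np.ndarray) -> float:
            return -self.loglike(theta[0], float(np.exp(theta[1])))

        best = None
        best_ok = None
        for mu0, sigma0 in self._starts():
            res = minimize(
                nll, x0=np.array([mu0, np.log(max(sigma0, 1e-3))]),
                method="L-BFGS-B",
                bounds=[(None, None), _LOG_SIGMA_BOUNDS],
                options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
            )
            cand = (-res.fun, -np.exp(res.x[1]), res)
            if best is None or cand[:2] > best[:2]:
                best = cand
            if res.success and (best_ok is None or cand[:2] > best_ok[:2]):
                best_ok = cand
        # a start that stalls in the line search *at* the optimum can edge
        # out a cleanly converged one by rounding error; prefer the latter
        if best_ok is not None and \
                best_ok[0] >= best[0] - 1e-6 * (1.0 + abs(best[0])):
            best = best_ok
        ll, _, res = best
        mu = float(res.x[0])
        sigma = float(np.exp(res.x[1]))
        converged = bool(res.success and np.isfinite(ll))
        fit = PsychometricFit(
            pha=mu, sigma=sigma, log_likelihood=float(ll),
            converged=converged, included=False, n_trials=int(total),
            model=self)
        fit.included = check_inclusion(fit)
        return fit


def fit_psychometric(table: ResponseTable) -> PsychometricFit:
    """Functional shorthand for ``PsychometricModel(table).fit()``."""
    return PsychometricModel(table).fit()


def compute_jnd(fit: PsychometricFit) -> float:
    """JND of a converged fit under the module's convention (sigma by default)."""
    if not fit.converged:
        raise ValueError("cannot compute a JND from an unconverged fit")
    return JND_SCALE * fit.sigma


def check_inclusion(fit: PsychometricFit,
                    stimulus_range: float = STIMULUS_RANGE) -> bool:
    """Participant-inclusion rule: converged and |PHA| within the range."""
    return bool(fit.converged and abs(fit.pha) <= stimulus_range)
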