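"""Negative-exponential model of the pause-score distribution.

Binned pause-score counts decay roughly exponentially with score.  Fitting
ln(count) against bin-center score by ordinary least squares gives a decay
rate ``lambda_hat`` and an amplitude; the score at which the fitted line
crosses an expected count of one (its x-axis intercept on the log scale)
is the threshold above which a pause is expected less than once per
genome — pauses beyond it are stronger than chance under the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FitError(RuntimeError):
    """The score distribution cannot support the exponential fit."""


@dataclass
class ScoreDistributionFit:
    """Results of the log-linear exponential fit (statsmodels-style results
    object: estimates plus a summary())."""

    bin_width: float
    lambda_hat: float
    log_amplitude: float
    unique_threshold: float  # NaN when lambda_hat <= 0
    r_squared: float
    n_scores: int
    n_bins_used: int

    def summary(self) -> str:
        lines = [
            "Negative-exponential score distribution fit",
            "-------------------------------------------",
            f"scores               {self.n_scores}",
            f"bin width            {self.bin_width:g}",
            f"bins used            {self.n_bins_used}",
            f"decay rate lambda    {self.lambda_hat:.6g} per score unit",
            f"log amplitude        {self.log_amplitude:.6g}",
            f"once-per-genome s*   {self.unique_threshold:.6g}",
            f"R^2 (ln counts)      {self.r_squared:.4f}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "bin_width": self.bin_width, "lambda_hat": self.lambda_hat,
            "log_amplitude": self.log_amplitude,
            "unique_threshold": self.unique_threshold,
            "r_squared": self.r_squared, "n_scores": self.n_scores,
        }


class ExponentialScoreModel:
    """Model object for the binned exponential decay of pause counts.

    Parameters
    ----------
    scores : array-like
        Pause scores (one per called pause).
    bin_width : float
        Histogram bin width in score units.  A width on the order of the
        mean score makes the fitted intercept match the once-per-genome
        count interpretation (see docs).
    score_floor : float, optional
        Discard scores below this value before binning (fit only the tail).
    """

    def __init__(self, scores, bin_width: float = 50.0,
                 score_floor: float | None = None):
        scores = np.asarray(scores, dtype=float)
        if score_floor is not None:
            scores = scores[scores >= score_floor]
        self.scores = scores
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        self.bin_width = float(bin_width)
        self.score_floor = 0.0 if score_floor is None else float(score_floor)

    def fit(self) -> ScoreDistributionFit:
        if self.scores.size == 0:
            raise FitError("no scores to fit")
        lo = self.score_floor
        hi = self.scores.max() + self.bin_width
        edges = np.arange(lo, hi + self.bin_width, self.bin_width)
        counts, edges = np.histogram(self.scores, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts >= 1  # ln(0) undefined; zero-count bins excluded
        if keep.sum() < 3:
            raise FitError(f"only {int(keep.sum())} non-empty bins (need >= 3)")
        x, y = centers[keep], np.log(counts[keep])
        # Weighted least squares with weights = bin counts: Var[ln N] ~ 1/N
        # for Poisson bins, so low-count tail bins no longer dominate the
        # slope through sheer leverage.
        w = counts[keep].astype(float)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        intercept, slope = beta
        lam = -slope
        resid = y - X @ beta
        ybar = np.average(y, weights=w)
        sst = np.sum(w * (y - ybar) ** 2)
        r2 = 1.0 - np.sum(w * resid ** 2) / sst if sst > 0 else 1.0
        threshold = intercept / lam if lam > 0 else float("nan")
        return ScoreDistributionFit(
            bin_width=self.bin_width, lambda_hat=float(lam),
            log_amplitude=float(intercept),
            unique_threshold=float(threshold),
            r_squared=float(r2),
            n_scores=int(self.scores.size), n_bins_used=int(keep.sum()),
        )


def fit_negative_exponential(scores, bin_width: float) -> ScoreDistributionFit:
    """Functional wrapper around :class:`ExponentialScoreModel`."""
    return ExponentialScoreModel(scores, bin_width=bin_width).fit()


def genome_unique_threshold(fit: ScoreDistributionFit) -> float:
    """Score s* where the fitted expected count crosses 1:
    ``log_amplitude - lambda_hat * s* = 0``."""
    if fit.lambda_hat <= 0:
        raise FitError("no decay: lambda_hat <= 0")
    return fit.log_amplitude / fit.lambda_hat
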