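"""Skellam null model and local false discovery rate for window count differences.

A ChIP experiment with a matched knockout (KO) control yields, per genomic
window, a wild-type tag count ``R`` and a control tag count ``N``.  When both
are marginally Poisson with rates ``lam_r`` and ``lam_n``, their difference
``D = R - N`` follows a Skellam distribution,

    P(D = d) = exp(-(lam_r + lam_n)) * (lam_r / lam_n)**(d/2) * I_d(2 * sqrt(lam_r * lam_n)),

with ``I_d`` the modified Bessel function of the first kind of order ``d``.
The observed density of ``D`` across windows is modelled as the two-component
mixture ``f(d) = p0 * f0(d) + p1 * f1(d)`` with null density ``f0`` (Skellam)
and signal density ``f1``; the local false discovery rate

    fdr(d) = p0 * f0(d) / f(d)

is estimated by plugging in the empirical histogram for ``f``.  The critical
difference ``d0`` is the smallest ``d >= 1`` at which the (regularized) local
fdr drops to or below a fixed threshold ``f_p``; windows with ``D >= d0`` are
declared significantly enriched.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
from scipy import special


@dataclass(frozen=True)
class SkellamNull:
    """Null distribution of D = R - N for independent Poisson counts.

    Parameters
    ----------
    lam_r : float
        Expected wild-type tag count per window.
    lam_n : float
        Expected knockout (control) tag count per window.

    The degenerate rates ``lam_r == 0`` and/or ``lam_n == 0`` are handled as
    pure (possibly negated) Poisson distributions; the Bessel form is
    undefined there.
    """

    lam_r: float
    lam_n: float

    def __post_init__(self) -> None:
        if self.lam_r < 0 or self.lam_n < 0:
            raise ValueError(
                f"Poisson rates must be non-negative, got lam_r={self.lam_r}, "
                f"lam_n={self.lam_n}"
            )
        if not (np.isfinite(self.lam_r) and np.isfinite(self.lam_n)):
            raise ValueError("Poisson rates must be finite")

    # --- moments -----------------------------------------------------------
    @property
    def mean(self) -> float:
        return self.lam_r - self.lam_n

    @property
    def var(self) -> float:
        return self.lam_r + self.lam_n

    # --- pmf ---------------------------------------------------------------
    def pmf(self, d):
        """P(D = d) for integer d (scalar or array)."""
        d = np.asarray(d)
        scalar = d.ndim == 0
        d = np.atleast_1d(d).astype(np.int64)
        lr, ln = self.lam_r, self.lam_n
        if lr == 0.0 and ln == 0.0:
            out = (d == 0).astype(float)
        elif ln == 0.0:
            out = np.where(d >= 0, _poisson_pmf(np.maximum(d, 0), lr), 0.0)
        elif lr == 0.0:
            out = np.where(d <= 0, _poisson_pmf(np.maximum(-d, 0), ln), 0.0)
        else:
            # log-space to survive small rates / large |d|
            x = 2.0 * np.sqrt(lr * ln)
            # ive = iv * exp(-x); I_{-d} = I_d for integer order
            ive = special.ive(np.abs(d), x)
            with np.errstate(divide="ignore"):
                log_iv = np.log(ive) + x
                logp = -(lr + ln) + 0.5 * d * np.log(lr / ln) + log_iv
            out = np.exp(logp)
            out = np.where(np.isfinite(out), out, 0.0)
        return float(out[0]) if scalar else out

    def _support(self) -> tuple[int, int]:
        """Integer range outside which pmf mass is < 1e-15."""
        sigma = np.sqrt(self.var) if self.var > 0 else 0.0
        lo = int(np.floor(self.mean - 40.0 * sigma - 60.0))
        hi = int(np.ceil(self.mean + 40.0 * sigma + 60.0))
        return lo, hi

    def sf(self, d):
        """Upper tail P(D >= d), truncated where mass is negligible."""
        d = np.asarray(d)
        scalar = d.ndim == 0
        d = np.atleast_1d(d).astype(np.int64)
        lo, hi = self._support()
        support = np.arange(lo, hi + 1)
        p = self.pmf(support)
        # cumulative from the top: tail[i] = sum_{j>=i} p[j]
        tail = np.cumsum(p[::-1])[::-1]
        idx = np.clip(d - lo, 0, len(support))
        out = np.where(
            d <= lo, 1.0, np.where(d > hi, 0.0, tail[np.minimum(idx, len(support) - 1)])
        )
        return float(out[0]) if scalar else out


def _poisson_pmf(k, lam):
    k = np.asarray(k, dtype=float)
    if lam == 0.0:
        return (k == 0).astype(float)
    return np.exp(k * np.log(lam) - lam - special.gammaln(k + 1.0))


def skellam_pmf(d, null: SkellamNull):
    """Probability mass of the window-count difference under the null."""
    return null.pmf(d)


def skellam_sf(d, null: SkellamNull):
    """Upper-tail probability P(D >= d) under the null."""
    return null.sf(d)


def estimate_lambda(window_counts, estimator: str = "mean") -> float:
    """Estimate the per-window Poisson rate from non-excluded window counts.

    ``estimator="mean"`` is the arithmetic mean over all windows (default).
    ``estimator="null_fit"`` averages only windows with count <= 3, damping the
    influence of the rare enriched windows on the background rate.
    """
    counts = np.asarray(window_counts)
    if counts.size == 0:
        raise ValueError("cannot estimate a rate from zero windows")
    if estimator == "mean":
        return float(counts.mean())
    if estimator == "null_fit":
        bg = counts[counts <= 3]
        if bg.size == 0:
            raise ValueError("null_fit estimator found no windows with count <= 3")
        return float(bg.mean())
    raise ValueError(f"unknown lambda estimator: {estimator!r}")


@dataclass
class LocFdrModel:
    """Fitted local-fdr mixture over the integer histogram of D.

    Attributes
    ----------
    null : SkellamNull
        The Skellam null density f0.
    d_min, d_max : int
        Observed range of D (histogram support).
    counts : np.ndarray
        Raw window counts per D bin over [d_min, d_max].
    n_windows : int
        Total number of windows in the histogram.
    fhat : np.ndarray
        Empirical density per bin; empty bins receive a 0.5 pseudo-count
        before normalization so fdr is defined across the whole range.
    p0 : float
        Null mixing weight (fixed or estimated by central matching).
    f_p : float
        Local-fdr threshold defining the critical difference.
    fdr_raw : np.ndarray
        clip(p0 * f0 / fhat, 0, 1) per bin.
    fdr : np.ndarray
        Regularized fdr: running minimum over d >= 1 (non-increasing there).
    d0 : int | None
        Smallest d >= 1 with regularized fdr(d) <= f_p, or None.
    """

    null: SkellamNull
    d_min: int
    d_max: int
    counts: np.ndarray
    n_windows: int
    fhat: np.ndarray
    p0: float
    f_p: float
    fdr_raw: np.ndarray = field(repr=False, default=None)
    fdr: np.ndarray = field(repr=False, default=None)
    d0: int | None = None

    def _idx(self, d: int) -> int:
        if d < self.d_min or d > self.d_max:
            raise ValueError(f"d={d} outside observed histogram range "
                             f"[{self.d_min}, {self.d_max}]")
        return d - self.d_min

    def fdr_at(self, d: int) -> float:
        """Regularized local fdr at an observed difference d."""
        return float(self.fdr[self._idx(d)])

    def fhat_at(self, d: int) -> float:
        return float(self.fhat[self._idx(d)])

    def table(self):
        """Audit table (d, f0, fhat, raw and regularized fdr) as a DataFrame."""
        import pandas as pd

        ds = np.arange(self.d_min, self.d_max + 1)
        return pd.DataFrame(
            {
                "d": ds,
                "count": self.counts,
                "f0": self.null.pmf(ds),
                "fhat": self.fhat,
                "fdr_raw": self.fdr_raw,
                "fdr": self.fdr,
            }
        )


def fit_locfdr(d_values, null: SkellamNull, p0="auto", f_p: float = 0.01) -> LocFdrModel:
    """Fit the local-fdr mixture from per-window differences D.

    Parameters
    ----------
    d_values : array of int, or Mapping[int, int]
        Either the per-window D values themselves or a precomputed integer
        histogram ``{d: count}``.
    null : SkellamNull
        The Skellam null f0.
    p0 : float or "auto"
        Null mixing weight.  "auto" uses central matching:
        ``p0 = min(1, min_{d in [-2, 2]} fhat(d) / f0(d))`` over observed bins.
    f_p : float
        Threshold in (0, 1) defining the critical difference d0.
    """
    if not (0.0 < f_p < 1.0):
        raise ValueError(f"f_p must lie in (0, 1), got {f_p}")

    if isinstance(d_values, Mapping):
        if len(d_values) == 0:
            raise ValueError("empty histogram")
        items = {int(k): int(v) for k, v in d_values.items()}
        if any(v < 0 for v in items.values()):
            raise ValueError("histogram counts must be non-negative")
        d_min, d_max = min(items), max(items)
        counts = np.zeros(d_max - d_min + 1, dtype=np.int64)
        for k, v in items.items():
            counts[k - d_min] = v
    else:
        d_arr = np.asarray(d_values, dtype=np.int64)
        if d_arr.size == 0:
            raise ValueError("empty histogram")
        d_min, d_max = int(d_arr.min()), int(d_arr.max())
        counts = np.bincount(d_arr - d_min, minlength=d_max - d_min + 1)

    n = int(counts.sum())
    if n == 0:
        raise ValueError("histogram holds zero windows")

    fhat = counts.astype(float)
    fhat[counts == 0] = 0.5
    fhat /= n

    ds = np.arange(d_min, d_max + 1)
    f0 = null.pmf(ds)

    if p0 == "auto":
        central = (ds >= -2) & (ds <= 2) & (f0 > 0)
        if not central.any():
            raise ValueError("no central bins (d in [-2, 2]) to estimate p0 from")
        p0_val = float(min(1.0, np.min(fhat[central] / f0[central])))
    else:
        p0_val = float(p0)
        if not (0.0 <= p0_val <= 1.0):
            raise ValueError(f"p0 must lie in [0, 1], got {p0_val}")

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_raw = np.clip(p0_val * f0 / fhat, 0.0, 1.0)

    # running-minimum regularization on d >= 1: histogram noise in sparse
    # bins can make the raw fdr non-monotone, which would leave d0 ill-defined
    fdr = fdr_raw.copy()
    pos = ds >= 1
    if pos.any():
        fdr[pos] = np.minimum.accumulate(fdr_raw[pos])

    d0 = None
    hit = pos & (fdr <= f_p)
    if hit.any():
        d0 = int(ds[hit][0])

    return LocFdrModel(
        null=null,
        d_min=d_min,
        d_max=d_max,
        counts=counts,
        n_windows=n,
        fhat=fhat,
        p0=p0_val,
        f_p=f_p,
        fdr_raw=fdr_raw,
        fdr=fdr,
        d0=d0,
    )


def tail_fdr(model: LocFdrModel, d: int):
    """Tail false discovery rate FDR(d) = p0 * P0(D >= d) / Phat(D >= d).

    This is the expectation of the local fdr over the declared set
    ``{D >= d}`` under the empirical density.  Returns None (undefined) when
    the empirical tail mass is zero, i.e. ``d`` lies beyond the observed
    maximum difference.
    """
    if d < model.d_min:
        tail_hat = float(model.fhat.sum())
    elif d > model.d_max:
        return None
    else:
        tail_hat = float(model.fhat[d - model.d_min:].sum())
    if tail_hat <= 0.0:
        return None
    tail_null = float(model.null.sf(d))
    return float(np.clip(model.p0 * tail_null / tail_hat, 0.0, 1.0))
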