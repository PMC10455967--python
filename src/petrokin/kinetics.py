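"""Sequential two-site H/D-exchange kinetics.

The exchange of two equivalent protons for deuterium in a deuterated
solvent follows the consecutive first-order scheme

    d0 --k1--> d1 --k2--> d2

whose closed-form fractions (the two-step Bateman solution) are

    f_d0(t) = exp(-k1 t)
    f_d1(t) = k1/(k2 - k1) * (exp(-k1 t) - exp(-k2 t))
    f_d2(t) = 1 - f_d0 - f_d1

with the degenerate limit f_d1 = k1 t exp(-k1 t) when k1 == k2.  For two
equivalent sites with identical per-site rate and no primary kinetic
isotope effect the macroscopic rates satisfy the statistical factor
k1/k2 = 2: the first exchange can happen at either site, the second only
at the remaining one.  Departure from 2 signals a kinetic isotope effect
or site inequivalence, so the fitted ratio carries mechanistic content.

The fitting interface follows the Model/Results convention: build a
:class:`SequentialExchange` model from fraction time courses, call
``fit()``, and read estimates, covariance, confidence intervals and the
ratio test off the returned :class:`SequentialExchangeResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .quant import IsotopologueTimeSeries

__all__ = [
    "SequentialExchangeModel",
    "model_fractions",
    "half_exchange_time",
    "SequentialExchange",
    "SequentialExchangeResults",
    "RatioTestResult",
    "ratio_test",
    "fit_exchange",
    "ExchangeFitError",
    "STATISTICAL_FACTOR",
]

#: Expected k1/k2 for two equivalent exchangeable sites, no isotope effect.
STATISTICAL_FACTOR = 2.0

# Relative |k1 - k2| below which the degenerate closed form is used;
# avoids catastrophic cancellation in the k2 -> k1 limit.
_DEGENERATE_RTOL = 1e-9


class ExchangeFitError(RuntimeError):
    """Raised when the nonlinear fit fails; carries residual and iterations."""

    def __init__(self, message: str, final_residual: float, n_iterations: int):
        super().__init__(f"{message} (residual={final_residual:.3g}, nfev={n_iterations})")
        self.final_residual = final_residual
        self.n_iterations = n_iterations


@dataclass(frozen=True)
class SequentialExchangeModel:
    """Rate-constant pair for the sequential d0 -> d1 -> d2 scheme."""

    k1: float
    k2: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("rate constants must be > 0")

    @property
    def ratio(self) -> float:
        return self.k1 / self.k2


def model_fractions(model: SequentialExchangeModel, t) -> np.ndarray:
    """Closed-form (f_d0, f_d1, f_d2) at time(s) *t*.

    Returns shape ``(3,)`` for scalar *t*, ``(len(t), 3)`` for a vector.
    All components lie in [0, 1] and sum to 1 exactly.
    """
    t_arr = np.asarray(t, float)
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    k1, k2 = model.k1, model.k2
    f0 = np.exp(-k1 * t_arr)
    if abs(k1 - k2) < _DEGENERATE_RTOL * max(k1, k2):
        f1 = k1 * t_arr * f0
    else:
        f1 = k1 / (k2 - k1) * (f0 - np.exp(-k2 * t_arr))
    f1 = np.clip(f1, 0.0, 1.0)
    f2 = 1.0 - f0 - f1
    out = np.stack([f0, f1, np.clip(f2, 0.0, 1.0)], axis=-1)
    return out


def half_exchange_time(model: SequentialExchangeModel, xtol: float = 1e-6) -> float:
    """Smallest t with f_d2(t) >= 1/2, by bracketed root finding.

    f_d2 rises monotonically from 0 to 1 for positive rates, so the root
    exists and is unique.
    """

    def g(t: float) -> float:
        return float(model_fractions(model, t)[2]) - 0.5

    hi = 1.0 / min(model.k1, model.k2)
    while g(hi) < 0:
        hi *= 2.0
    return float(optimize.brentq(g, 0.0, hi, xtol=xtol))


@dataclass(frozen=True)
class RatioTestResult:
    """k1/k2 with first-order propagated uncertainty and the factor-2 check."""

    ratio: float
    sigma: float
    interval95: tuple[float, float]
    consistent_with_statistical_factor: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "consistent" if self.consistent_with_statistical_factor else "inconsistent"
        return (
            f"k1/k2 = {self.ratio:.3f} +/- {self.sigma:.3f} "
            f"(95% {self.interval95[0]:.3f}-{self.interval95[1]:.3f}); "
            f"{verdict} with the statistical factor {STATISTICAL_FACTOR}"
        )


class SequentialExchange:
    """Nonlinear-regression model for isotopologue fraction time courses.

    Parameters
    ----------
    times_s, fractions
        Pooled observation times (length N) and the matching ``(N, 3)``
        array of (f_d0, f_d1, f_d2) rows.  Replicates are pooled: repeat a
        time for every replicate observed at it.
    replicate_ids
        Optional length-N labels; used for replicate bootstrap resampling
        and reporting.
    weights
        Optional per-row weights for the least-squares loss (default
        unweighted).
    correction_matrix
        The natural-abundance correction matrix the fractions came
        through, if any.  When present, ``fit`` propagates a
        proportional (multiplicative) channel-noise model through the
        correction to build each scan's fraction covariance and solves
        the whitened (generalized) least-squares problem, which is what
        makes the reported confidence intervals calibrated: corrected
        fractions are strongly heteroscedastic and correlated within a
        scan, and an unweighted fit misallocates uncertainty between
        the two rate constants.
    """

    def __init__(
        self,
        times_s,
        fractions,
        replicate_ids: Sequence[str] | None = None,
        weights=None,
        correction_matrix=None,
    ):
        self.times_s = np.asarray(times_s, float)
        self.fractions = np.asarray(fractions, float)
        if self.fractions.ndim != 2 or self.fractions.shape[1] != 3:
            raise ValueError("fractions must have shape (n_obs, 3)")
        if len(self.times_s) != len(self.fractions):
            raise ValueError("times and fractions length mismatch")
        if len(np.unique(self.times_s)) < 4:
            raise ValueError("need >= 4 distinct timepoints to fit two rate constants")
        if np.any(self.fractions < -1e-9) or np.any(self.fractions > 1 + 1e-9):
            raise ValueError("fractions must lie in [0, 1]")
        self.replicate_ids = (
            np.asarray(replicate_ids)
            if replicate_ids is not None
            else np.array(["r1"] * len(self.times_s))
        )
        self.weights = None if weights is None else np.asarray(weights, float)
        self.correction_matrix = (
            None if correction_matrix is None else np.asarray(correction_matrix, float)
        )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_series(
        cls,
        series: Iterable[IsotopologueTimeSeries],
        correction_matrix=None,
    ) -> "SequentialExchange":
        """Pool one or more per-replicate corrected time series."""
        times, fracs, reps = [], [], []
        for s in series:
            flags = s.quality_flags or ("ok",) * len(s.times_s)
            for t, f, flag in zip(s.times_s, s.fractions, flags):
                if flag == "no_signal":
                    continue
                times.append(t)
                fracs.append(f[:3])
                reps.append(s.replicate_id)
        return cls(np.array(times), np.array(fracs), reps, correction_matrix=correction_matrix)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, correction_matrix=None) -> "SequentialExchange":
        """Build from a tidy frame with time_s, f_d0, f_d1, f_d2 columns."""
        if "quality_flag" in df.columns:
            df = df[df["quality_flag"] != "no_signal"]
        reps = df["replicate_id"].astype(str) if "replicate_id" in df.columns else None
        return cls(
            df["time_s"].to_numpy(float),
            df[["f_d0", "f_d1", "f_d2"]].to_numpy(float),
            None if reps is None else reps.to_numpy(),
            correction_matrix=correction_matrix,
        )

    # -- fitting ----------------------------------------------------------

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        pred = model_fractions(SequentialExchangeModel(*params), self.times_s)
        res = pred - self.fractions
        if self.weights is not None:
            res = res * np.sqrt(self.weights)[:, None]
        return res.ravel()

    def _initial_guess(self) -> tuple[float, float]:
        """k1 from log-linear decay of f_d0; k2 = k1/2 (statistical prior)."""
        f0 = self.fractions[:, 0]
        mask = (f0 > 1e-6) & (f0 < 1.0)
        if mask.sum() >= 2 and np.ptp(self.times_s[mask]) > 0:
            slope = np.polyfit(self.times_s[mask], np.log(f0[mask]), 1)[0]
            k1 = max(-slope, 1e-6)
        else:
            tspan = np.ptp(self.times_s)
            k1 = 1.0 / tspan if tspan > 0 else 1e-3
        return k1, k1 / STATISTICAL_FACTOR

    def _scan_whiteners(self, params: np.ndarray) -> list[np.ndarray]:
        """Per-scan whitening transforms under proportional channel noise.

        With multiplicative noise eps on the channel intensities
        u = M f, the corrected-and-renormalized fractions are
        x ~ f + (I - f 1^T) M^{-1} diag(u) eps to first order, so each
        scan's fraction covariance is sigma^2 C C^T with
        C = (I - f 1^T) M^{-1} diag(M f).  The covariance has rank 2
        (fractions sum to 1); whitening projects onto that subspace and
        scales it to unit variance, leaving one unknown overall scale
        sigma (the channel CV) estimated from the residuals.
        """
        M = self.correction_matrix
        Minv = np.linalg.inv(M)
        f = model_fractions(SequentialExchangeModel(*params), self.times_s)
        ones = np.ones(M.shape[0])
        out = []
        for fg in f:
            C = (np.eye(M.shape[0]) - np.outer(fg, ones)) @ Minv @ np.diag(M @ fg)
            B = C @ C.T
            lam, V = np.linalg.eigh(B)
            keep = lam > lam.max() * 1e-10
            out.append((V[:, keep] / np.sqrt(lam[keep])).T)
        return out

    def fit(
        self,
        init: tuple[float, float] | None = None,
        bounds: tuple[float, float] = (1e-6, 10.0),
        ci: str = "wald",
        n_boot: int = 1000,
        seed: int | None = 0,
    ) -> "SequentialExchangeResults":
        """Least-squares fit of (k1, k2) over all three trajectories.

        Without a correction matrix this is unweighted least squares on
        the pooled fractions, with the covariance from the Jacobian at
        the optimum.  With one, a second whitened (GLS) pass under the
        proportional channel-noise model refines the solution and its
        covariance (see :meth:`_scan_whiteners`).  ``ci="wald"`` gives
        t-based intervals; ``ci="bootstrap"`` resamples replicates with
        replacement (``n_boot`` draws, seeded) and reports percentile
        intervals.
        """
        k10, k20 = init if init is not None else self._initial_guess()
        lo, hi = bounds
        x0 = np.clip([k10, k20], lo, hi)
        sol = optimize.least_squares(
            self._residuals, x0, bounds=([lo, lo], [hi, hi]), method="trf", xtol=1e-12
        )
        if not sol.success:
            raise ExchangeFitError("exchange fit did not converge", float(sol.cost), sol.nfev)

        if self.correction_matrix is not None:
            whiteners = self._scan_whiteners(sol.x)

            def wres(params: np.ndarray) -> np.ndarray:
                pred = model_fractions(SequentialExchangeModel(*params), self.times_s)
                r = pred - self.fractions
                return np.concatenate([W @ rg for W, rg in zip(whiteners, r)])

            sol = optimize.least_squares(
                wres, sol.x, bounds=([lo, lo], [hi, hi]), method="trf", xtol=1e-12
            )
            if not sol.success:
                raise ExchangeFitError(
                    "whitened exchange fit did not converge", float(sol.cost), sol.nfev
                )

        k1_hat, k2_hat = sol.x
        at_bounds = bool(
            np.any(np.isclose(sol.x, lo, rtol=0, atol=lo * 10))
            or np.any(np.isclose(sol.x, hi, rtol=1e-6))
        )
        nobs = self.fractions.size
        dof = max(sol.fun.size - 2, 1)
        s2 = 2.0 * sol.cost / dof
        cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)

        boot: np.ndarray | None = None
        if ci == "bootstrap":
            boot = self._bootstrap(n_boot, seed, (k1_hat, k2_hat), bounds)
        elif ci != "wald":
            raise ValueError(f"unknown ci method {ci!r}")

        return SequentialExchangeResults(
            model=self,
            params=np.array([k1_hat, k2_hat]),
            cov_params=cov,
            resid=self._residuals(sol.x),
            nobs=nobs,
            dof=dof,
            scale=float(np.sqrt(s2)),
            ci_method=ci,
            boot_samples=boot,
            at_bounds=at_bounds,
            seed=seed,
        )

    def _bootstrap(self, n_boot, seed, init, bounds) -> np.ndarray:
        reps = np.unique(self.replicate_ids)
        rng = np.random.default_rng(seed)
        lo, hi = bounds
        draws = []
        for _ in range(n_boot):
            chosen = rng.choice(reps, size=len(reps), replace=True)
            idx = np.concatenate([np.flatnonzero(self.replicate_ids == r) for r in chosen])
            sub = SequentialExchange(
                self.times_s[idx], self.fractions[idx], self.replicate_ids[idx],
                correction_matrix=self.correction_matrix,
            )
            try:
                sol = optimize.least_squares(
                    sub._residuals, init, bounds=([lo, lo], [hi, hi]), method="trf"
                )
                draws.append(sol.x)
            except (ValueError, ExchangeFitError):
                continue
        return np.array(draws)


class SequentialExchangeResults:
    """Fit results: estimates, covariance, CIs, diagnostics, ratio test."""

    def __init__(
        self, model, params, cov_params, resid, nobs, ci_method, boot_samples, at_bounds,
        seed, dof=None, scale=None,
    ):
        self.model = model
        self.params = params
        self.cov_params = cov_params
        self.resid = resid
        self.nobs = nobs
        self._dof = dof
        self.scale = scale
        self.ci_method = ci_method
        self.boot_samples = boot_samples
        self.at_bounds = at_bounds
        self.seed = seed

    # -- point estimates and uncertainty ----------------------------------

    @property
    def k1(self) -> float:
        return float(self.params[0])

    @property
    def k2(self) -> float:
        return float(self.params[1])

    @property
    def label_swapped(self) -> bool:
        """True when the optimizer settled on k2 > k1.

        f_d2 is symmetric under k1 <-> k2 but f_d0/f_d1 are not, so the
        joint three-trajectory fit is identifiable; a swapped optimum is
        reported, not silently reordered.
        """
        return self.k2 > self.k1

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def dof(self) -> int:
        return self._dof if self._dof is not None else max(self.nobs - 2, 1)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Per-parameter CIs, shape (2, 2): rows (k1, k2), cols (lo, hi)."""
        if self.ci_method == "bootstrap" and self.boot_samples is not None and len(self.boot_samples):
            lo = np.percentile(self.boot_samples, 100 * alpha / 2, axis=0)
            hi = np.percentile(self.boot_samples, 100 * (1 - alpha / 2), axis=0)
            return np.column_stack([lo, hi])
        tval = stats.t.ppf(1 - alpha / 2, self.dof)
        return np.column_stack([self.params - tval * self.bse, self.params + tval * self.bse])

    @property
    def ci95_k1(self) -> tuple[float, float]:
        lo, hi = self.conf_int()[0]
        return float(lo), float(hi)

    @property
    def ci95_k2(self) -> tuple[float, float]:
        lo, hi = self.conf_int()[1]
        return float(lo), float(hi)

    # -- diagnostics -------------------------------------------------------

    @property
    def ssr(self) -> float:
        return float(self.resid @ self.resid)

    @property
    def rsquared(self) -> float:
        y = self.model.fractions.ravel()
        sst = float(((y - y.mean()) ** 2).sum())
        return 1.0 - self.ssr / sst if sst > 0 else float("nan")

    @property
    def n_replicates(self) -> int:
        return len(np.unique(self.model.replicate_ids))

    @property
    def n_timepoints(self) -> int:
        return len(np.unique(self.model.times_s))

    # -- derived quantities ------------------------------------------------

    @property
    def ratio(self) -> float:
        return self.k1 / self.k2

    @property
    def ratio_sigma(self) -> float:
        """First-order (delta-method) standard error of k1/k2."""
        v1, v2 = np.diag(self.cov_params)
        c12 = self.cov_params[0, 1]
        r = self.ratio
        var = r * r * (v1 / self.k1**2 + v2 / self.k2**2 - 2 * c12 / (self.k1 * self.k2))
        return float(np.sqrt(max(var, 0.0)))

    def ratio_test(self) -> RatioTestResult:
        return ratio_test(self)

    def predict(self, t) -> np.ndarray:
        return model_fractions(SequentialExchangeModel(self.k1, self.k2), t)

    def half_exchange_time(self) -> float:
        return half_exchange_time(SequentialExchangeModel(self.k1, self.k2))

    def to_dict(self) -> dict:
        rt = self.ratio_test()
        return {
            "k1": self.k1,
            "k2": self.k2,
            "ci95_k1": list(self.ci95_k1),
            "ci95_k2": list(self.ci95_k2),
            "ratio": rt.ratio,
            "ratio_sigma": rt.sigma,
            "consistent_with_statistical_factor": rt.consistent_with_statistical_factor,
            "r2": self.rsquared,
            "n": self.nobs,
            "n_replicates": self.n_replicates,
            "n_timepoints": self.n_timepoints,
            "method": self.ci_method,
            "seed": self.seed,
            "at_bounds": self.at_bounds,
        }

    def summary(self) -> str:
        """Human-readable fit report."""
        ci1, ci2 = self.ci95_k1, self.ci95_k2
        rt = self.ratio_test()
        lines = [
            "Sequential H/D exchange fit (d0 -> d1 -> d2)",
            "=" * 48,
            f"observations: {self.nobs}  replicates: {self.n_replicates}  "
            f"timepoints: {self.n_timepoints}",
            f"CI method: {self.ci_method}   R^2 = {self.rsquared:.5f}",
            "-" * 48,
            f"k1 = {self.k1:.4f} s^-1   95% CI [{ci1[0]:.4f}, {ci1[1]:.4f}]",
            f"k2 = {self.k2:.4f} s^-1   95% CI [{ci2[0]:.4f}, {ci2[1]:.4f}]",
            str(rt),
            f"half-exchange time t(f_d2=0.5) = {self.half_exchange_time():.2f} s",
        ]
        if self.at_bounds:
            lines.append("WARNING: estimate at parameter bounds — fit unreliable")
        if self.label_swapped:
            lines.append("note: k2 > k1 (swapped labeling at optimum)")
        return "\n".join(lines)

    def plot(self, ax=None, t_max: float | None = None):
        """Overlay the fitted trajectories on the pooled data."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t_max = t_max if t_max is not None else float(self.model.times_s.max())
        tt = np.linspace(0, t_max, 200)
        pred = self.predict(tt)
        for i, (label, color) in enumerate(zip(("$f_{d0}$", "$f_{d1}$", "$f_{d2}$"),
                                               ("C0", "C1", "C2"))):
            ax.plot(tt, pred[:, i], color=color, label=label)
            ax.scatter(self.model.times_s, self.model.fractions[:, i], s=12, color=color)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("isotopologue fraction")
        ax.legend()
        return ax


def ratio_test(fit: SequentialExchangeResults) -> RatioTestResult:
    """Test whether k1/k2 is consistent with the statistical factor 2.

    The uncertainty is first-order propagation through the parameter
    covariance; consistency holds when ratio +/- 1.96 sigma contains 2.0.
    """
    if fit.k2 <= 0 or fit.k1 <= 0:
        raise ValueError("ratio test requires positive rate estimates")
    r, s = fit.ratio, fit.ratio_sigma
    lo, hi = r - 1.96 * s, r + 1.96 * s
    return RatioTestResult(r, s, (lo, hi), bool(lo <= STATISTICAL_FACTOR <= hi))


def fit_exchange(
    series: Iterable[IsotopologueTimeSeries] | IsotopologueTimeSeries | pd.DataFrame,
    init: tuple[float, float] | None = None,
    bounds: tuple[float, float] = (1e-6, 10.0),
    ci: str = "wald",
    n_boot: int = 1000,
    seed: int | None = 0,
    correction_matrix=None,
) -> SequentialExchangeResults:
    """One-call fit: accepts time series, a list of them, or a tidy frame.

    Pass the correction matrix the fractions came through to enable the
    calibrated channel-noise (GLS) covariance.
    """
    if isinstance(series, pd.DataFrame):
        model = SequentialExchange.from_dataframe(series, correction_matrix=correction_matrix)
    elif isinstance(series, IsotopologueTimeSeries):
        model = SequentialExchange.from_series([series], correction_matrix=correction_matrix)
    else:
        model = SequentialExchange.from_series(series, correction_matrix=correction_matrix)
    return model.fit(init=init, bounds=bounds, ci=ci, n_boot=n_boot, seed=seed)
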