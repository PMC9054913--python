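"""Lifetime fitting of TCSPC histograms.

Two fitting strategies are provided, both as model classes whose ``fit()``
returns a :class:`DecayFitResults`:

* :class:`ReconvolutionModel` — fits ``shift-aligned (IRF (x) sum_i a_i
  exp(-t/tau_i)) + scatter * IRF + background`` to the full histogram,
  accounting for the finite instrument response. This is the standard way to
  resolve lifetimes comparable to or shorter than the IRF.
* :class:`TailFitModel` — fits the bare multi-exponential plus background on
  a window starting after the IRF has decayed.

Residuals are weighted by Poisson (Neyman) counting statistics,
``w_c = 1 / max(obs_c, 1)``, the standard choice for photon-counting data.
Lifetimes are always reported in ascending order with amplitudes normalized
to unit sum; the intensity-weighted average lifetime is
``<tau> = sum a_i tau_i^2 / sum a_i tau_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .histogram import DecayHistogram

__all__ = [
    "DecayFitResults",
    "ReconvolutionModel",
    "TailFitModel",
    "GlobalDecayModel",
    "reconvolution_fit",
    "tail_fit",
    "intensity_weighted_tau",
    "reduced_chi2",
]

_TAU_BOUNDS = (1e-4, 1e4)  # ns


# --------------------------------------------------------------------------
# shared helpers
# --------------------------------------------------------------------------
def poisson_weights(observed: np.ndarray) -> np.ndarray:
    """Neyman weights 1/max(obs, 1) for Poisson-distributed counts."""
    return 1.0 / np.maximum(np.asarray(observed, dtype=float), 1.0)


def reduced_chi2(observed: np.ndarray, fitted: np.ndarray, n_params: int,
                 weights: np.ndarray | None = None) -> float:
    """Weighted reduced chi-square, ``sum w (obs - fit)^2 / (N - p)``."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if weights is None:
        weights = poisson_weights(observed)
    dof = observed.size - n_params
    if dof <= 0:
        raise ValueError("zero or negative degrees of freedom")
    return float(np.sum(weights * (observed - fitted) ** 2) / dof)


def intensity_weighted_tau(fit_or_amplitudes, lifetimes=None) -> float:
    """Intensity-weighted average lifetime, sum a tau^2 / sum a tau (ns).

    Accepts either a :class:`DecayFitResults` or explicit
    ``(amplitudes, lifetimes)`` arrays. Invariant under uniform amplitude
    rescaling.
    """
    if lifetimes is None:
        a, tau = fit_or_amplitudes.amplitudes, fit_or_amplitudes.lifetimes
    else:
        a, tau = np.asarray(fit_or_amplitudes, float), np.asarray(lifetimes, float)
    a = np.asarray(a, dtype=float)
    tau = np.asarray(tau, dtype=float)
    denom = np.sum(a * tau)
    if denom == 0:
        raise ValueError("all amplitudes are zero; weighted lifetime undefined")
    return float(np.sum(a * tau**2) / denom)


def _default_window(counts: np.ndarray, floor_frac: float = 0.02) -> slice:
    """Default fit window: 10% of the rising edge to the tail noise floor.

    The window ends at the last channel holding at least ``max(1,
    floor_frac * peak)`` counts. Neyman (1/obs) weights are only unbiased in
    the Gaussian limit, so channels far below ~2% of a >= 10^4-count peak
    would distort both the parameters and the reduced chi-square if kept.
    """
    peak = int(np.argmax(counts))
    thresh = 0.1 * counts[peak]
    rise = 0
    for i in range(peak, -1, -1):
        if counts[i] < thresh:
            rise = i + 1
            break
    floor = max(1.0, floor_frac * counts[peak])
    nz = np.nonzero(counts >= floor)[0]
    end = int(nz[-1]) + 1 if nz.size else counts.size
    return slice(rise, end)


def _shifted_irf(time: np.ndarray, irf_norm: np.ndarray, shift: float) -> np.ndarray:
    if shift == 0.0:
        return irf_norm
    return np.interp(time - shift, time, irf_norm, left=0.0, right=0.0)


def _conv_components(irf: np.ndarray, time: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """(n_exp, n_channels) array of IRF (x) exp(-t/tau_i)."""
    kernels = np.exp(-time[None, :] / taus[:, None])
    out = fftconvolve(irf[None, :], kernels, axes=1)[:, : time.size]
    return np.maximum(out, 0.0)


# --------------------------------------------------------------------------
# results object
# --------------------------------------------------------------------------
@dataclass
class DecayFitResults:
    """Converged (or flagged) decay-fit parameters and diagnostics.

    Amplitudes are normalized to unit sum and ordered by ascending lifetime.
    ``fitted`` is the model curve on the full time axis; ``window`` is the
    channel slice the fit used. Standard errors come from the Jacobian at
    the optimum, scaled by the reduced chi-square.
    """

    method: str
    n_exp: int
    amplitudes: np.ndarray
    lifetimes: np.ndarray
    scatter_fraction: float
    background: float
    irf_shift: float
    reduced_chi2: float
    fitted: np.ndarray
    window: slice
    converged: bool
    degenerate: bool = False
    message: str = ""
    amplitude_stderr: np.ndarray | None = None
    lifetime_stderr: np.ndarray | None = None
    nfev: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def tau_w(self) -> float:
        """Intensity-weighted average lifetime (ns)."""
        return intensity_weighted_tau(self.amplitudes, self.lifetimes)

    def summary(self) -> str:
        lines = [
            f"{self.method} fit, {self.n_exp} exponential(s)",
            f"  converged: {self.converged}"
            + (f"  [{self.message}]" if self.message else ""),
        ]
        if self.degenerate:
            lines.append("  flagged DEGENERATE (amplitude ~ 0 or parameter at bound)")
        for i, (a, tau) in enumerate(zip(self.amplitudes, self.lifetimes), 1):
            err = ""
            if self.lifetime_stderr is not None and np.isfinite(self.lifetime_stderr[i - 1]):
                err = f" +/- {self.lifetime_stderr[i - 1]:.3g}"
            lines.append(f"  a{i} = {a:.4f}   tau{i} = {tau:.4g}{err} ns")
        lines.append(f"  scatter = {self.scatter_fraction:.4g}   "
                     f"background = {self.background:.4g} cts/ch   "
                     f"IRF shift = {self.irf_shift * 1e3:.1f} ps")
        lines.append(f"  <tau> = {self.tau_w:.4g} ns   reduced chi2 = {self.reduced_chi2:.4f}")
        return "\n".join(lines)

    def plot(self, decay: DecayHistogram, ax=None):
        """Overlay data, fit and weighted residuals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        decay.plot(ax=ax, label="data", lw=0.8)
        ax.semilogy(decay.time, np.maximum(self.fitted, 1e-300), label="fit")
        ax.legend()
        return ax


# --------------------------------------------------------------------------
# models
# --------------------------------------------------------------------------
class ReconvolutionModel:
    """IRF-reconvolution lifetime model for a single decay histogram.

    Parameters
    ----------
    decay, irf : DecayHistogram
        The measured decay and the instrument response, on the same time
        axis. The IRF is normalized to unit sum internally.
    n_exp : int
        Number of exponential components (1-3).
    window : slice or (float, float), optional
        Fit window as a channel slice or a (t_start, t_stop) pair in ns.
        Default: 10% of the rising edge to the last channel with >= 1 count.
    fit_shift, fit_scatter : bool
        Whether the IRF temporal shift and the scattered-light fraction are
        free parameters (both default True; instrument color shift is
        essentially always present in real data).
    """

    def __init__(self, decay: DecayHistogram, irf: DecayHistogram, n_exp: int = 1,
                 window=None, fit_shift: bool = True, fit_scatter: bool = True):
        if n_exp not in (1, 2, 3):
            raise ValueError("n_exp must be 1, 2 or 3")
        if not decay.same_axis(irf):
            raise ValueError("decay and IRF must share the same time axis")
        self.decay = decay
        self.irf = irf
        self.n_exp = n_exp
        self.fit_shift = fit_shift
        self.fit_scatter = fit_scatter
        self.window = self._resolve_window(window)
        irf_counts = np.asarray(irf.counts, dtype=float)
        self._irf_norm = irf_counts / irf_counts.sum()

    def _resolve_window(self, window) -> slice:
        counts = self.decay.counts
        if window is None:
            return _default_window(counts)
        if isinstance(window, slice):
            sl = window
        else:
            t0, t1 = window
            idx = np.searchsorted(self.decay.time, [t0, t1])
            sl = slice(int(idx[0]), int(idx[1]) + 1)
        if sl.start is not None and (sl.start < 0 or sl.start >= counts.size):
            raise ValueError("fit window outside the time axis")
        return sl

    # --- model evaluation -------------------------------------------------
    def _eval(self, params: np.ndarray) -> np.ndarray:
        """Model curve on the full time axis (convolution needs the rise)."""
        time = self.decay.time
        n = self.n_exp
        alphas = params[:n]
        taus = params[n:2 * n]
        scatter = params[2 * n] if self.fit_scatter else 0.0
        bg = params[2 * n + self.fit_scatter]
        shift = params[2 * n + self.fit_scatter + 1] if self.fit_shift else 0.0
        irf_s = _shifted_irf(time, self._irf_norm, shift)
        comps = _conv_components(irf_s, time, taus)
        return alphas @ comps + scatter * irf_s + bg

    def _initial_params(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        counts = self.decay.counts
        time = self.decay.time
        peak = int(np.argmax(counts))
        tail_bg = float(np.median(counts[-max(counts.size // 20, 4):]))
        tau0 = _crude_tail_tau(time, counts, peak, tail_bg)
        amp0 = max(counts[peak] - tail_bg, 1.0) / self.n_exp
        p0 = np.concatenate([
            np.full(self.n_exp, amp0),
            _tau_starts(tau0, self.n_exp)[0],
            [0.0] if self.fit_scatter else [],
            [tail_bg],
            [0.0] if self.fit_shift else [],
        ])
        lo = np.concatenate([
            np.zeros(self.n_exp),
            np.full(self.n_exp, _TAU_BOUNDS[0]),
            [0.0] if self.fit_scatter else [],
            [0.0],
            [-0.5] if self.fit_shift else [],
        ])
        hi = np.concatenate([
            np.full(self.n_exp, np.inf),
            np.full(self.n_exp, _TAU_BOUNDS[1]),
            [np.inf] if self.fit_scatter else [],
            [np.inf],
            [0.5] if self.fit_shift else [],
        ])
        return p0, lo, hi

    def fit(self, multi_start: bool | None = None) -> DecayFitResults:
        """Run the bounded least-squares fit; never raises on non-convergence.

        ``multi_start`` (default: on for n_exp >= 2) tries several lifetime
        initializations spread around a crude tail estimate and keeps the
        best chi-square, which resolves the permutation/local-minimum
        ambiguity of multi-exponential fits.
        """
        return _run_fit(self, method="reconvolution", multi_start=multi_start)


class TailFitModel(ReconvolutionModel):
    """Multi-exponential tail fit (no IRF) from a user-chosen start time."""

    def __init__(self, decay: DecayHistogram, n_exp: int = 1,
                 start: float | None = None, end: float | None = None):
        if n_exp not in (1, 2, 3):
            raise ValueError("n_exp must be 1, 2 or 3")
        self.decay = decay
        self.n_exp = n_exp
        self.fit_shift = False
        self.fit_scatter = False
        time = decay.time
        if start is None:
            # heuristic: one peak position past the maximum
            peak = int(np.argmax(decay.counts))
            start = time[min(peak + max(peak, 1), time.size - 1)]
        if start >= time[-1]:
            raise ValueError("tail-fit start lies beyond the data range")
        i0 = int(np.searchsorted(time, start))
        i1 = time.size if end is None else int(np.searchsorted(time, end)) + 1
        nz = np.nonzero(decay.counts[:i1] >= 1)[0]
        if nz.size:
            i1 = min(i1, int(nz[-1]) + 1)
        self.window = slice(i0, i1)
        self._irf_norm = None

    def _eval(self, params: np.ndarray) -> np.ndarray:
        time = self.decay.time
        n = self.n_exp
        alphas, taus, bg = params[:n], params[n:2 * n], params[2 * n]
        return np.sum(alphas[:, None] * np.exp(-time[None, :] / taus[:, None]), axis=0) + bg

    def fit(self, multi_start: bool | None = None) -> DecayFitResults:
        return _run_fit(self, method="tail", multi_start=multi_start)


def _crude_tail_tau(time, counts, peak, bg) -> float:
    """Log-linear slope estimate of the dominant lifetime from the tail."""
    tail = counts[peak:] - bg
    ok = np.nonzero(tail > max(1.0, 0.001 * counts[peak]))[0]
    if ok.size < 10:
        return 1.0
    i0, i1 = ok[ok.size // 4], ok[-1]
    t = time[peak + i0: peak + i1]
    y = np.log(np.maximum(tail[i0:i1], 1e-12))
    if t.size < 2:
        return 1.0
    slope = np.polyfit(t, y, 1)[0]
    return float(np.clip(-1.0 / slope if slope < 0 else 1.0, 1e-3, 1e3))


def _tau_starts(tau0: float, n_exp: int) -> list[np.ndarray]:
    """Lifetime initializations for the multi-start search."""
    if n_exp == 1:
        return [np.array([tau0])]
    if n_exp == 2:
        return [np.array(s) * tau0 for s in ((0.3, 1.0), (0.1, 1.0), (1.0, 3.0), (0.5, 1.5))]
    return [np.array(s) * tau0 for s in ((0.1, 0.5, 1.0), (0.3, 1.0, 3.0), (0.05, 0.3, 1.2))]


def _run_fit(model, method: str, multi_start: bool | None) -> DecayFitResults:
    decay = model.decay
    sl = model.window
    time_w = decay.time[sl]
    obs_w = decay.counts[sl]
    sqrt_w = np.sqrt(poisson_weights(obs_w))
    p0, lo, hi = model._initial_params()
    n = model.n_exp

    def residuals(p):
        return (model._eval(p)[sl] - obs_w) * sqrt_w

    if multi_start is None:
        multi_start = n >= 2
    starts = [p0]
    if multi_start and n >= 2:
        for taus in _tau_starts(float(np.mean(p0[n:2 * n])), n):
            p = p0.copy()
            p[n:2 * n] = np.clip(taus, *_TAU_BOUNDS)
            starts.append(p)

    best = None
    for p_init in starts:
        try:
            res = least_squares(residuals, p_init, bounds=(lo, hi),
                                x_scale="jac", xtol=1e-12, ftol=1e-12,
                                gtol=1e-12, max_nfev=2000)
        except Exception as exc:  # pragma: no cover - solver failure path
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:  # pragma: no cover
        nan = np.full(n, np.nan)
        return DecayFitResults(method=method, n_exp=n, amplitudes=nan, lifetimes=nan,
                               scatter_fraction=np.nan, background=np.nan, irf_shift=np.nan,
                               reduced_chi2=np.nan, fitted=np.full_like(decay.counts, np.nan),
                               window=sl, converged=False, message="optimizer failed")

    p = best.x
    alphas = p[:n]
    taus = p[n:2 * n]
    scatter_counts = p[2 * n] if model.fit_scatter else 0.0
    bg = p[2 * n + model.fit_scatter]
    shift = p[2 * n + model.fit_scatter + 1] if model.fit_shift else 0.0

    n_free = p.size
    fitted_full = model._eval(p)
    redchi = reduced_chi2(obs_w, fitted_full[sl], n_free, weights=sqrt_w**2)

    # standard errors from the Jacobian at the optimum
    stderr = np.full(p.size, np.nan)
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * redchi
        stderr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except Exception:  # pragma: no cover
        pass

    order = np.argsort(taus, kind="stable")
    alphas, taus = alphas[order], taus[order]
    a_err = stderr[:n][order]
    tau_err = stderr[n:2 * n][order]
    a_sum = alphas.sum()
    decay_counts = float(np.sum(alphas @ _np_exp_matrix(time_w, taus))) if a_sum > 0 else 0.0
    total_sig = decay_counts + scatter_counts * (1.0 if model.fit_scatter else 0.0)
    scatter_fraction = scatter_counts / total_sig if total_sig > 0 else 0.0
    amp_norm = alphas / a_sum if a_sum > 0 else alphas
    a_err_norm = a_err / a_sum if a_sum > 0 else a_err

    # degenerate when the decaying signal is below the shot-noise floor of
    # the window, or a lifetime ran into its bounds
    degenerate = bool(
        a_sum <= 0
        or decay_counts < 3.0 * np.sqrt(max(obs_w.sum(), 1.0))
        or np.any(taus < 5 * _TAU_BOUNDS[0]) or np.any(taus > 0.2 * _TAU_BOUNDS[1])
    )
    converged = best.status > 0 and np.all(np.isfinite(p))
    msg = "" if converged else f"solver status {best.status}: {best.message}"
    if degenerate:
        msg = (msg + "; " if msg else "") + "degenerate fit (no decaying signal resolved)"

    return DecayFitResults(
        method=method, n_exp=n, amplitudes=amp_norm, lifetimes=taus,
        scatter_fraction=float(scatter_fraction), background=float(bg),
        irf_shift=float(shift), reduced_chi2=redchi, fitted=fitted_full,
        window=sl, converged=converged, degenerate=degenerate, message=msg,
        amplitude_stderr=a_err_norm, lifetime_stderr=tau_err, nfev=best.nfev,
        extras={"amplitude_scale": float(a_sum)},
    )


def _np_exp_matrix(time: np.ndarray, taus: np.ndarray) -> np.ndarray:
    return np.exp(-time[None, :] / taus[:, None])


# --------------------------------------------------------------------------
# global (linked-lifetime) fitting
# --------------------------------------------------------------------------
class GlobalDecayModel:
    """Joint fit of several decays with shared lifetimes, free amplitudes.

    The lifetimes (and IRF shift) are linked across all histograms; each
    histogram keeps its own amplitudes and background. This is the global
    reconvolution analysis used for wavelength-stepped decay sets.
    """

    def __init__(self, decays: Sequence[DecayHistogram], irf: DecayHistogram,
                 n_exp: int = 1, fit_shift: bool = True):
        if not decays:
            raise ValueError("need at least one decay")
        for d in decays:
            if not d.same_axis(irf):
                raise ValueError("all decays must share the IRF time axis")
        self.decays = list(decays)
        self.irf = irf
        self.n_exp = n_exp
        self.fit_shift = fit_shift
        irf_counts = np.asarray(irf.counts, dtype=float)
        self._irf_norm = irf_counts / irf_counts.sum()
        self.windows = [_default_window(d.counts) for d in self.decays]

    def fit(self) -> list[DecayFitResults]:
        """Fit jointly; returns one :class:`DecayFitResults` per decay.

        Uses variable projection: only the shared lifetimes (and IRF shift)
        are searched nonlinearly, while each histogram's amplitudes and
        background — linear in the model — are solved per evaluation by
        non-negative weighted least squares. This keeps the joint fit fast
        for dozens of wavelengths.
        """
        from scipy.optimize import nnls

        n, m = self.n_exp, len(self.decays)
        time = self.decays[0].time
        obs = [d.counts[w] for d, w in zip(self.decays, self.windows)]
        sqw = [np.sqrt(poisson_weights(o)) for o in obs]

        peak_seed = max(self.decays, key=lambda d: d.counts.max())
        seed_fit = ReconvolutionModel(peak_seed, self.irf, n_exp=n,
                                      fit_shift=self.fit_shift).fit()
        tau0 = np.clip(seed_fit.lifetimes, *_TAU_BOUNDS)
        p0 = np.concatenate([tau0, [seed_fit.irf_shift]] if self.fit_shift
                            else [tau0])
        lo = np.concatenate([np.full(n, _TAU_BOUNDS[0]),
                             [-0.5] if self.fit_shift else []])
        hi = np.concatenate([np.full(n, _TAU_BOUNDS[1]),
                             [0.5] if self.fit_shift else []])

        def solve_linear(p):
            taus = p[:n]
            shift = p[n] if self.fit_shift else 0.0
            irf_s = _shifted_irf(time, self._irf_norm, shift)
            comps = _conv_components(irf_s, time, taus)
            per = np.empty((m, n + 1))
            res_parts = []
            for k, w in enumerate(self.windows):
                design = np.concatenate([comps[:, w], np.ones((1, obs[k].size))]).T
                coef, _ = nnls(design * sqw[k][:, None], obs[k] * sqw[k])
                per[k] = coef
                res_parts.append((design @ coef - obs[k]) * sqw[k])
            return comps, per, np.concatenate(res_parts)

        def residuals(p):
            return solve_linear(p)[2]

        res = least_squares(residuals, p0, bounds=(lo, hi), x_scale="jac",
                            xtol=1e-10, ftol=1e-10, max_nfev=500)
        taus = res.x[:n]
        shift = res.x[n] if self.fit_shift else 0.0
        _, per, _ = solve_linear(res.x)
        order = np.argsort(taus, kind="stable")
        taus = taus[order]
        irf_s = _shifted_irf(time, self._irf_norm, shift)
        comps = _conv_components(irf_s, time, taus)
        results = []
        for k, (d, w) in enumerate(zip(self.decays, self.windows)):
            alphas = per[k, :n][order]
            bg = per[k, n]
            fitted = alphas @ comps + bg
            a_sum = alphas.sum()
            redchi = reduced_chi2(obs[k], fitted[w], n + 1, weights=sqw[k]**2)
            results.append(DecayFitResults(
                method="global-reconvolution", n_exp=n,
                amplitudes=alphas / a_sum if a_sum > 0 else alphas,
                lifetimes=taus.copy(), scatter_fraction=0.0, background=float(bg),
                irf_shift=float(shift), reduced_chi2=redchi, fitted=fitted,
                window=w, converged=res.status > 0, degenerate=a_sum <= 0,
                nfev=res.nfev, extras={"amplitude_scale": float(a_sum)},
            ))
        return results


# --------------------------------------------------------------------------
# functional wrappers (spec-level operations)
# --------------------------------------------------------------------------
def reconvolution_fit(decay: DecayHistogram, irf: DecayHistogram, n_exp: int = 1,
                      window=None, **kwargs) -> DecayFitResults:
    """Fit ``decay`` by IRF reconvolution; see :class:`ReconvolutionModel`."""
    return ReconvolutionModel(decay, irf, n_exp=n_exp, window=window, **kwargs).fit()


def tail_fit(decay: DecayHistogram, n_exp: int = 1, start: float | None = None,
             **kwargs) -> DecayFitResults:
    """Tail-fit ``decay`` from ``start`` (ns); see :class:`TailFitModel`."""
    return TailFitModel(decay, n_exp=n_exp, start=start, **kwargs).fit()
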