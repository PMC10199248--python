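"""Two-regime voxelwise decay fitting for the sphere ("dot") fraction.

The STE signal of cerebellar grey matter is analysed in two b-value
regimes, each with its own model:

* **high b** (b >= 10,000 s/mm^2 by default): all compartments with
  appreciable diffusivity are suppressed and the residual decay is
  mono-exponential, ``S = S0s * exp(-b * Ds)``, whose intercept S0,s and
  slope Ds characterise the isotropically restricted sphere compartment;
* **low b** (b <= 1,500 s/mm^2): a bi-exponential free-water elimination,
  ``S = S0 * [ft * exp(-b * MD) + (1 - ft) * exp(-b * D_fw)]`` with the
  free-water diffusivity fixed (D_fw = 3 um^2/ms), yielding the tissue
  fraction ft, tissue mean diffusivity MD and b=0 signal S0 with CSF
  partial volume removed.

The sphere signal fraction of the tissue is then ``fs = S0,s / (ft * S0)``.
Both fits are bounded nonlinear least squares solved with the
trust-region-reflective algorithm, initialised from log-linear regression.

The per-voxel fitters are exposed as scikit-learn style estimators
(:class:`MonoExponentialDecay`, :class:`FreeWaterElimination`) operating on
an ``(n_voxels, n_volumes)`` signal matrix, and as the plain functions
:func:`fit_highb_monoexp` / :func:`fit_lowb_freewater` /
:func:`fit_voxelwise` they wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .dataset import DwiDataset
from .maps import ParameterMaps
from .preprocess import modified_zscore
from .signal_model import FREE_WATER_DIFFUSIVITY, b_to_ms_per_um2, compute_fs

__all__ = [
    "FitConfig",
    "MonoExponentialDecay",
    "FreeWaterElimination",
    "fit_highb_monoexp",
    "fit_lowb_freewater",
    "fit_voxelwise",
]


@dataclass(frozen=True)
class FitConfig:
    """Thresholds, bounds and solver settings for both fit regimes.

    b-value cutoffs are in s/mm^2; diffusivities in um^2/ms.
    """

    b_low: float = 1500.0
    b_high: float = 10000.0
    d_fw: float = FREE_WATER_DIFFUSIVITY
    ds_bounds: tuple[float, float] = (0.0, 1.0)
    md_bounds: tuple[float, float] = (0.0, 3.0)
    ft_bounds: tuple[float, float] = (0.0, 1.0)
    zmax: float = 3.5
    shell_rician: bool = True
    max_nfev: int = 1000
    xtol: float = 1e-13
    ftol: float = 1e-13
    gtol: float = 1e-13

    def __post_init__(self):
        if not self.b_low < self.b_high:
            raise ValueError("low-b cutoff must be below the high-b cutoff")
        if self.d_fw <= 0:
            raise ValueError("free-water diffusivity must be positive")


@dataclass(frozen=True)
class FitDiagnostics:
    converged: bool
    n_points: int
    cost: float = np.nan
    message: str = ""


def _loglinear(y, b_ms):
    """Slope/intercept of log(y) vs b over positive samples; None if < 2."""
    pos = y > 0
    if pos.sum() < 2 or np.unique(b_ms[pos]).size < 2:
        return None
    slope, intercept = np.polyfit(b_ms[pos], np.log(y[pos]), 1)
    return slope, intercept


def _fit_mono(y, b_ms, config: FitConfig):
    """Scalar-voxel mono-exponential fit. Returns (s0s, ds, diagnostics)."""
    return _fit_mono_generic(y, b_ms, config.ds_bounds, config)


def _fit_mono_generic(y, b_ms, decay_bounds, config: FitConfig):
    """Mono-exponential a*exp(-b*d) with configurable decay bounds."""
    y = np.asarray(y, dtype=float)
    b_ms = np.asarray(b_ms, dtype=float)
    lo, hi = decay_bounds
    if y.size < 2 or np.unique(b_ms).size < 2 or not np.any(y > 0):
        return np.nan, np.nan, FitDiagnostics(False, y.size, message="insufficient data")
    ll = _loglinear(y, b_ms)
    if ll is not None:
        ds0 = np.clip(-ll[0], lo + 1e-6, hi - 1e-6)
        s0s0 = max(np.exp(ll[1]), 1e-12)
    else:  # Rician correction can zero all but one sample
        ds0 = 0.1
        s0s0 = float(y[y > 0].min())

    def resid(p):
        return p[0] * np.exp(-b_ms * p[1]) - y

    def jac(p):
        e = np.exp(-b_ms * p[1])
        return np.column_stack([e, -p[0] * b_ms * e])

    try:
        sol = least_squares(
            resid, x0=[s0s0, ds0], jac=jac, bounds=([0.0, lo], [np.inf, hi]),
            method="trf", xtol=config.xtol, ftol=config.ftol, gtol=config.gtol,
            max_nfev=config.max_nfev,
        )
    except Exception as exc:  # pragma: no cover - solver failure path
        return np.nan, np.nan, FitDiagnostics(False, y.size, message=str(exc))
    if not np.all(np.isfinite(sol.x)):
        return np.nan, np.nan, FitDiagnostics(False, y.size, message="non-finite solution")
    return float(sol.x[0]), float(sol.x[1]), FitDiagnostics(True, y.size, sol.cost, sol.message)


def _fit_biexp(y, b_ms, config: FitConfig):
    """Scalar-voxel free-water bi-exponential fit. Returns (s0, ft, md, diag)."""
    y = np.asarray(y, dtype=float)
    b_ms = np.asarray(b_ms, dtype=float)
    if np.unique(b_ms).size < 3 or not np.any(y > 0):
        return np.nan, np.nan, np.nan, FitDiagnostics(False, y.size, message="insufficient data")
    mdlo, mdhi = config.md_bounds
    ftlo, fthi = config.ft_bounds
    b0 = b_ms == 0
    s0_init = float(y[b0].mean()) if np.any(b0) else float(y.max())
    s0_init = max(s0_init, 1e-12)
    ll = _loglinear(y, b_ms)
    md0 = np.clip(-ll[0], mdlo + 1e-6, mdhi - 1e-6) if ll is not None else 1.0
    ft0 = np.clip(0.9, ftlo + 1e-6, fthi - 1e-6)
    dfw = config.d_fw

    def model(p):
        s0, ft, md = p
        return s0 * (ft * np.exp(-b_ms * md) + (1 - ft) * np.exp(-b_ms * dfw))

    def resid(p):
        return model(p) - y

    def jac(p):
        s0, ft, md = p
        et = np.exp(-b_ms * md)
        ew = np.exp(-b_ms * dfw)
        return np.column_stack([
            ft * et + (1 - ft) * ew,
            s0 * (et - ew),
            -s0 * ft * b_ms * et,
        ])

    try:
        sol = least_squares(
            resid, x0=[s0_init, ft0, md0], jac=jac,
            bounds=([1e-12, ftlo, mdlo], [np.inf, fthi, mdhi]),
            method="trf", xtol=config.xtol, ftol=config.ftol, gtol=config.gtol,
            max_nfev=config.max_nfev,
        )
    except Exception as exc:  # pragma: no cover
        return np.nan, np.nan, np.nan, FitDiagnostics(False, y.size, message=str(exc))
    if not np.all(np.isfinite(sol.x)):
        return np.nan, np.nan, np.nan, FitDiagnostics(False, y.size, message="non-finite solution")
    s0, ft, md = sol.x
    cost = sol.cost

    # Active-set polish. Two degeneracies leave trust-region steps stalled
    # near a boundary of the (ft, md) box: a pure-tissue voxel (ft -> 1,
    # free-water term vanishes) and a free-water voxel (ft -> 0, or md ->
    # d_fw where the two compartments are indistinguishable). Refit the
    # reduced model with ft pinned and keep it when the fit is no worse.
    if ft > fthi - 1e-2 and fthi == 1.0:
        s0_b, md_b, diag_b = _fit_mono_generic(y, b_ms, (mdlo, mdhi), config)
        if diag_b.converged and diag_b.cost <= cost + 1e-15:
            s0, ft, md, cost = s0_b, 1.0, md_b, diag_b.cost
    elif (ft < ftlo + 1e-2 or md > dfw - 1e-2) and ftlo == 0.0:
        e = np.exp(-b_ms * dfw)
        s0_b = max(float(e @ y) / float(e @ e), 1e-12)
        cost_b = 0.5 * float(np.sum((s0_b * e - y) ** 2))
        if cost_b <= cost + 1e-15:
            s0, ft, cost = s0_b, 0.0, cost_b  # md unidentifiable; keep estimate
    return float(s0), float(ft), float(md), FitDiagnostics(True, y.size, cost, sol.message)


def fit_highb_monoexp(signals, b_values, config: FitConfig = FitConfig()):
    """Fit ``S0s * exp(-b * Ds)`` to high-b samples of one voxel.

    Parameters
    ----------
    signals : array
        Signal samples (same length as ``b_values``).
    b_values : array
        Their b-values in s/mm^2; should all be >= ``config.b_high``.

    Returns ``(s0s, ds, diagnostics)`` with Ds in um^2/ms; non-convergence
    yields NaNs and a flag, never an exception.
    """
    return _fit_mono(np.asarray(signals, float), b_to_ms_per_um2(b_values), config)


def fit_lowb_freewater(signals, b_values, config: FitConfig = FitConfig()):
    """Fit the free-water bi-exponential to low-b samples of one voxel.

    ``b_values`` (s/mm^2, b0 included) should be <= ``config.b_low``.
    Returns ``(s0, ft, md, diagnostics)`` with MD in um^2/ms.
    """
    return _fit_biexp(np.asarray(signals, float), b_to_ms_per_um2(b_values), config)


# --- scikit-learn style estimators -----------------------------------------


class _DecayFitBase(BaseEstimator):
    """Shared input handling for per-voxel decay estimators."""

    def _validate(self, X):
        X = check_array(X, dtype=float, ensure_min_features=2)
        if self.b_values is None:
            raise ValueError("b_values must be set before fitting")
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size != X.shape[1]:
            raise ValueError(
                f"b_values has length {b.size} but X has {X.shape[1]} columns"
            )
        return X, b


class MonoExponentialDecay(_DecayFitBase):
    """Per-voxel mono-exponential decay estimator for the sphere compartment.

    Rows of ``X`` are voxels, columns are high-b measurements with b-values
    ``b_values`` (s/mm^2). :meth:`fit` estimates per-row ``S0s_`` and
    ``Ds_`` (um^2/ms) with bounded trust-region least squares.

    Examples
    --------
    >>> import numpy as np
    >>> b = np.array([10500., 12000., 13500., 15000.])
    >>> X = 0.08 * np.exp(-b / 1000 * 0.1)[None, :]
    >>> est = MonoExponentialDecay(b_values=b).fit(X)
    >>> float(np.round(est.Ds_[0], 6))
    0.1
    """

    def __init__(self, b_values=None, config: FitConfig = FitConfig()):
        self.b_values = b_values
        self.config = config

    def fit(self, X, y=None):
        X, b = self._validate(X)
        b_ms = b_to_ms_per_um2(b)
        n = X.shape[0]
        self.S0s_ = np.empty(n)
        self.Ds_ = np.empty(n)
        self.converged_ = np.empty(n, dtype=bool)
        for i in range(n):
            s0s, ds, diag = _fit_mono(X[i], b_ms, self.config)
            self.S0s_[i], self.Ds_[i], self.converged_[i] = s0s, ds, diag.converged
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the ``(n_voxels, 2)`` array ``[S0s, Ds]``."""
        self.fit(X)
        return np.column_stack([self.S0s_, self.Ds_])


class FreeWaterElimination(_DecayFitBase):
    """Per-voxel bi-exponential free-water elimination estimator.

    Columns are low-b measurements (b0 included). :meth:`fit` estimates
    per-row ``S0_``, ``ft_`` and ``MD_`` with the free-water diffusivity
    fixed at ``config.d_fw``.
    """

    def __init__(self, b_values=None, config: FitConfig = FitConfig()):
        self.b_values = b_values
        self.config = config

    def fit(self, X, y=None):
        X, b = self._validate(X)
        b_ms = b_to_ms_per_um2(b)
        n = X.shape[0]
        self.S0_ = np.empty(n)
        self.ft_ = np.empty(n)
        self.MD_ = np.empty(n)
        self.converged_ = np.empty(n, dtype=bool)
        for i in range(n):
            s0, ft, md, diag = _fit_biexp(X[i], b_ms, self.config)
            self.S0_[i], self.ft_[i], self.MD_[i] = s0, ft, md
            self.converged_[i] = diag.converged
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the ``(n_voxels, 3)`` array ``[S0, ft, MD]``."""
        self.fit(X)
        return np.column_stack([self.S0_, self.ft_, self.MD_])


# --- full voxelwise pipeline ------------------------------------------------


def _exclude_outliers(y, b, zmax):
    """Per-shell modified-Z outlier flags for one voxel's measurement vector."""
    keep = np.ones(y.size, dtype=bool)
    for shell in np.unique(b):
        cols = np.flatnonzero(b == shell)
        if cols.size < 3:
            continue
        report = modified_zscore(y[cols], threshold=zmax)
        keep[cols[report.excluded]] = False
    return keep


def _aggregate_shells(y, b, keep, sigma, shell_rician):
    """Collapse surviving repeats of each nominal shell to one datum.

    With ``shell_rician`` and a known noise level, the shell value is the
    method-of-moments noise-floor-corrected quadratic mean
    ``sqrt(max(mean(M^2) - 2 sigma^2, 0))``: mean(M^2) is unbiased for
    A^2 + 2 sigma^2 and the square root is monotone, so the shell estimate
    is approximately median-unbiased even at unit SNR. Without a noise
    level (or with ``shell_rician=False``) the plain mean of the surviving
    repeats is used. Returns (shell_b, shell_y).
    """
    shells = np.unique(b)
    vals, bs = [], []
    for shell in shells:
        cols = (b == shell) & keep
        if not cols.any():
            continue
        if shell_rician and sigma is not None:
            vals.append(np.sqrt(max(float(np.mean(y[cols] ** 2)) - 2.0 * sigma**2, 0.0)))
        else:
            vals.append(float(y[cols].mean()))
        bs.append(shell)
    return np.asarray(bs), np.asarray(vals)


def fit_voxelwise(dataset: DwiDataset, config: FitConfig = FitConfig(),
                  mask: np.ndarray | None = None) -> ParameterMaps:
    """Run outlier exclusion and both regime fits in every (masked) voxel.

    Per voxel: signals are grouped by nominal shell and scored with the
    modified Z-score (threshold ``config.zmax``, shells with >= 3 repeats);
    surviving repeats of each shell (b0 included) are then collapsed to a
    single datum -- by the noise-floor-corrected quadratic mean when the
    dataset carries a ``sigma_map`` and ``config.shell_rician`` is on (the
    default), by the plain mean otherwise. The low-b bi-exponential and
    high-b mono-exponential fits run on their shell points, using per-voxel
    effective b-values ``b * beff_map`` when a ``beff_map`` is present;
    ``fs`` is derived where both fits converged and ``ft * S0 > 0``.
    Unfittable voxels carry NaN plus flags; the result is deterministic
    given the inputs.

    ``mask`` defaults to voxels whose mean b0 signal is positive.
    """
    scheme = dataset.scheme
    scheme.validate_for_fitting(config.b_low, config.b_high)
    b = scheme.b_values
    grid = dataset.grid
    if mask is None:
        mask = dataset.signal[..., scheme.is_b0].mean(axis=-1) > 0
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} != grid {grid}")

    nan = np.full(grid, np.nan)
    out = {
        "md": nan.copy(), "ft": nan.copy(), "s0": nan.copy(),
        "s0s": nan.copy(), "ds": nan.copy(), "fs": nan.copy(),
        "n_excluded_lowb": np.zeros(grid, dtype=int),
        "n_excluded_highb": np.zeros(grid, dtype=int),
        "converged_low": np.zeros(grid, dtype=bool),
        "converged_high": np.zeros(grid, dtype=bool),
    }

    low_sel = b <= config.b_low  # includes b0
    high_sel = b >= config.b_high
    beff = dataset.beff_map
    sigma_map = dataset.sigma_map

    for vox in np.argwhere(mask):
        i, j, k = vox
        y = dataset.signal[i, j, k]
        keep = _exclude_outliers(y, b, config.zmax)
        sigma = float(sigma_map[i, j, k]) if sigma_map is not None else None
        shell_b, shell_y = _aggregate_shells(y, b, keep, sigma, config.shell_rician)
        shell_b_eff = shell_b * (beff[i, j, k] if beff is not None else 1.0)

        out["n_excluded_lowb"][i, j, k] = int((~keep & low_sel).sum())
        out["n_excluded_highb"][i, j, k] = int((~keep & high_sel).sum())

        sel = shell_b <= config.b_low  # includes the aggregated b0
        if np.unique(shell_b_eff[sel]).size >= 3:
            s0, ft, md, diag = _fit_biexp(
                shell_y[sel], b_to_ms_per_um2(shell_b_eff[sel]), config
            )
            if diag.converged:
                out["s0"][i, j, k] = s0
                out["ft"][i, j, k] = ft
                out["md"][i, j, k] = md
                out["converged_low"][i, j, k] = True

        sel = shell_b >= config.b_high
        if np.unique(shell_b_eff[sel]).size >= 2:
            s0s, ds, diag = _fit_mono(
                shell_y[sel], b_to_ms_per_um2(shell_b_eff[sel]), config
            )
            if diag.converged:
                out["s0s"][i, j, k] = s0s
                out["ds"][i, j, k] = ds
                out["converged_high"][i, j, k] = True

    both = out["converged_low"] & out["converged_high"]
    with np.errstate(invalid="ignore"):
        fs = compute_fs(np.where(both, out["s0s"], np.nan), out["ft"], out["s0"])
    out["fs"] = np.where(both, fs, np.nan)
    return ParameterMaps(**out)
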