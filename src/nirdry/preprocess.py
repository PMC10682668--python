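"""Spectral preprocessing: Savitzky-Golay smoothing, iterative polynomial
baseline correction, standard normal variate (SNV), and global min-max
scaling for neural-network inputs.

All operators act row-wise on arrays of shape ``(n_obs, n_wavelengths)`` (a
single 1-D spectrum is also accepted) and preserve length.  The default PLS
pipeline is smoothing, then baseline removal, then SNV — SNV last guarantees
every spectrum enters the regression standardized to mean 0 / SD 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import SpectralDataset

_STAGES = ("savitzky_golay", "baseline", "snv")


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the PLS preprocessing pipeline.

    Defaults: window-7 / order-3 smoothing, third-order iterative baseline
    with relative coefficient-change tolerance 1e-4, SNV last.
    """

    sg_window: int = 7
    sg_order: int = 3
    baseline_order: int = 3
    baseline_tol: float = 1e-4
    baseline_max_iter: int = 100
    pipeline_order: tuple = _STAGES

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if self.baseline_order < 1 or self.baseline_max_iter < 1 or self.baseline_tol <= 0:
            raise ValueError("invalid baseline parameters")
        unknown = set(self.pipeline_order) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown pipeline stages: {sorted(unknown)}")


def _rows(x: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        return arr[None, :], True
    if arr.ndim != 2:
        raise ValueError("expected a 1-D spectrum or 2-D (n_obs, n) array")
    return arr, False


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per spectrum subtract the mean and divide by
    the population standard deviation, giving mean 0 / SD 1 rows.

    SNV is invariant to positive affine transforms of a spectrum and
    idempotent.  A constant spectrum has zero spread and is rejected.
    """
    arr, single = _rows(x)
    if arr.shape[1] < 2:
        raise ValueError("SNV needs at least 2 points per spectrum")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population (1/N) SD
    if np.any(sd == 0):
        raise ValueError("SNV undefined for a constant spectrum (zero spread)")
    out = (arr - mean) / sd
    return out[0] if single else out


def savgol_weights(window: int, order: int) -> np.ndarray:
    """Central convolution weights of the Savitzky-Golay filter.

    Solves the local least-squares problem on symmetric offsets
    ``-h..h`` and returns the row that evaluates the fitted polynomial at
    the window centre (for window 7 / order 3: (-2, 3, 6, 7, 6, 3, -2)/21).
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    h = window // 2
    offsets = np.arange(-h, h + 1, dtype=float)
    A = np.vander(offsets, order + 1, increasing=True)
    # value at offset 0 is coefficient c0; weights = e0^T (A^T A)^-1 A^T
    return np.linalg.solve(A.T @ A, A.T)[0]


def savitzky_golay(x: np.ndarray, window: int = 7, order: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing with truncated windows at the edges.

    Interior points are the classic fixed convolution; each edge point is
    the value, at that point, of a least-squares polynomial fitted to the
    one-sided truncated window (no padding).  The filter is linear and
    reproduces polynomials up to ``order`` exactly at interior points.
    """
    arr, single = _rows(x)
    n = arr.shape[1]
    if n < window:
        raise ValueError(f"spectrum length {n} shorter than window {window}")
    h = window // 2
    w = savgol_weights(window, order)
    out = np.empty_like(arr)
    # interior: correlation with the fixed central weights
    for j in range(h, n - h):
        out[:, j] = arr[:, j - h : j + h + 1] @ w
    # edges: per-point truncated-window least squares
    for j in list(range(h)) + list(range(n - h, n)):
        lo, hi = max(0, j - h), min(n, j + h + 1)
        offs = np.arange(lo, hi, dtype=float) - j
        deg = min(order, hi - lo - 1)
        A = np.vander(offs, deg + 1, increasing=True)
        coef = np.linalg.lstsq(A, arr[:, lo:hi].T, rcond=None)[0]
        out[:, j] = coef[0]  # polynomial evaluated at offset 0
    return out[0] if single else out


@dataclass
class BaselineResult:
    corrected: np.ndarray
    baseline: np.ndarray
    n_iter: int
    converged: bool


def baseline_correct(
    x: np.ndarray,
    order: int = 3,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> BaselineResult:
    """Iterative modified-polyfit baseline estimation and removal.

    Repeatedly fits a degree-``order`` polynomial to the working spectrum
    and clips the working spectrum to the elementwise minimum of itself and
    the fit, so the polynomial slides under positive peaks.  Iteration stops
    when the relative L2 change of the coefficient vector drops below
    ``tol`` (a huge tolerance therefore stops after the first plain
    least-squares fit).  Non-convergence within ``max_iter`` is reported via
    ``converged=False`` with the partial result.

    Applied per spectrum for 2-D input.
    """
    arr, single = _rows(x)
    n = arr.shape[1]
    if n <= order + 1:
        raise ValueError(f"need more than order+1={order + 1} points, got {n}")
    u = np.linspace(-1.0, 1.0, n)  # conditioning: fit on [-1, 1]
    corrected = np.empty_like(arr)
    baselines = np.empty_like(arr)
    iters, all_conv = 0, True
    for i in range(arr.shape[0]):
        work = arr[i].copy()
        prev = np.zeros(order + 1)
        converged = False
        for it in range(1, max_iter + 1):
            coeffs = np.polynomial.polynomial.polyfit(u, work, order)
            base = np.polynomial.polynomial.polyval(u, coeffs)
            denom = np.linalg.norm(coeffs)
            rel = 1.0 if denom == 0 else np.linalg.norm(coeffs - prev) / denom
            if rel < tol:
                converged = True
                break
            prev = coeffs
            work = np.minimum(work, base)
        baselines[i] = base
        corrected[i] = arr[i] - base
        iters = max(iters, it)
        all_conv = all_conv and converged
    if single:
        return BaselineResult(corrected[0], baselines[0], iters, all_conv)
    return BaselineResult(corrected, baselines, iters, all_conv)


@dataclass
class MinMaxScale:
    """Global dataset min-max scaling to [0, 1] with stored inverse."""

    lo: float
    hi: float

    @classmethod
    def fit(cls, x: np.ndarray) -> "MinMaxScale":
        arr = np.asarray(x, dtype=float)
        lo, hi = float(arr.min()), float(arr.max())
        if hi <= lo:
            raise ValueError("degenerate constant dataset: global max equals min")
        return cls(lo, hi)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo)

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * (self.hi - self.lo) + self.lo


def minmax_normalize(x: np.ndarray) -> tuple[np.ndarray, MinMaxScale]:
    """Scale a whole dataset to [0, 1] by its single global (min, max) pair."""
    scale = MinMaxScale.fit(x)
    return scale.transform(x), scale


def preprocess_for_pls(ds: SpectralDataset, config: PreprocessConfig | None = None) -> SpectralDataset:
    """Apply the configured preprocessing stages in order to a dataset.

    Default order: Savitzky-Golay -> baseline correction -> SNV.  The applied
    stages and their parameters are appended to the dataset provenance.
    """
    config = PreprocessConfig() if config is None else config
    values = ds.absorbance
    applied = []
    for stage in config.pipeline_order:
        if stage == "savitzky_golay":
            values = savitzky_golay(values, config.sg_window, config.sg_order)
            applied.append({"stage": stage, "window": config.sg_window, "order": config.sg_order})
        elif stage == "baseline":
            res = baseline_correct(
                values, config.baseline_order, config.baseline_tol, config.baseline_max_iter
            )
            values = res.corrected
            applied.append(
                {
                    "stage": stage,
                    "order": config.baseline_order,
                    "tol": config.baseline_tol,
                    "converged": res.converged,
                }
            )
        elif stage == "snv":
            values = snv(values)
            applied.append({"stage": stage})
    if not applied:
        return ds.copy()
    out = ds.with_absorbance(values, stage=None)
    out.provenance.extend(applied)
    return out
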