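"""Image-quality metrics: relative ℓ₂ error, PSNR, and SSIM.

All three operate on magnitude images; complex inputs are magnituded
first. SSIM comes in two modes:

* ``global`` — a single evaluation of the SSIM formula using whole-image
  means, standard deviations and cross-covariance with the absolute
  stabilizing constants c₁ = 0.01 and c₂ = 0.03 (no dynamic-range
  scaling);
* ``windowed`` — the standard Wang et al. form: mean of the local SSIM
  map over 11×11 Gaussian-weighted windows (σ = 1.5), constants
  (0.01·D)² and (0.03·D)² with D the dynamic range of the ground truth.

``windowed`` is the default reporting mode; ``global`` is retained for
literal reproduction of the simpler formula.
"""

from __future__ import annotations

import numpy as np

from .fourier import ComplexImage

__all__ = ["relative_error", "psnr", "ssim", "MetricsReport", "evaluate"]

SSIM_WINDOW = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03


def _as_magnitude(x) -> np.ndarray:
    if isinstance(x, ComplexImage):
        return x.magnitude()
    arr = np.asarray(x)
    if np.iscomplexobj(arr):
        arr = np.abs(arr)
    return arr.astype(np.float64)


def _check_pair(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def relative_error(reconstruction, truth) -> float:
    """‖x̂ − x‖₂ / ‖x‖₂ over all pixels (magnitude images)."""
    xhat, x = _as_magnitude(reconstruction), _as_magnitude(truth)
    _check_pair(xhat, x)
    denom = np.linalg.norm(x)
    if denom == 0:
        raise ValueError("ground truth has zero norm")
    return float(np.linalg.norm(xhat - x) / denom)


def psnr(reconstruction, truth) -> float:
    """10·log₁₀(MAXₓ² / MSE) in dB, MAXₓ the peak of the ground truth.

    Identical images return ``inf`` (documented sentinel).
    """
    xhat, x = _as_magnitude(reconstruction), _as_magnitude(truth)
    _check_pair(xhat, x)
    mse = np.mean((xhat - x) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(x.max() ** 2 / mse))


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_formula(mu_x, mu_y, var_x, var_y, cov, c1, c2):
    return ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x**2 + mu_y**2 + c1) * (var_x + var_y + c2)
    )


def ssim(reconstruction, truth, mode: str = "windowed") -> float:
    """Structural similarity between reconstruction and ground truth."""
    xhat, x = _as_magnitude(reconstruction), _as_magnitude(truth)
    _check_pair(xhat, x)
    if mode == "global":
        mu_x, mu_y = xhat.mean(), x.mean()
        var_x, var_y = xhat.var(), x.var()
        cov = ((xhat - mu_x) * (x - mu_y)).mean()
        return float(
            _ssim_formula(mu_x, mu_y, var_x, var_y, cov, SSIM_K1, SSIM_K2)
        )
    if mode != "windowed":
        raise ValueError(f"ssim mode must be 'global' or 'windowed', got {mode!r}")

    # joint dynamic range keeps the metric symmetric in its two arguments
    d = float(max(x.max(), xhat.max()) - min(x.min(), xhat.min()))
    if d == 0:
        d = 1.0  # constant pair: constants still stabilize the ratio
    c1, c2 = (SSIM_K1 * d) ** 2, (SSIM_K2 * d) ** 2
    win = SSIM_WINDOW
    if min(x.shape) < win:
        raise ValueError(f"image smaller than the {win}×{win} SSIM window")
    kern = _gaussian_kernel(win, SSIM_SIGMA)

    def local_stats(img):
        w = np.lib.stride_tricks.sliding_window_view(img, (win, win))
        mu = np.tensordot(w, kern, axes=([2, 3], [0, 1]))
        m2 = np.tensordot(w * w, kern, axes=([2, 3], [0, 1]))
        return w, mu, m2 - mu**2

    wx, mu_x, var_x = local_stats(xhat)
    wy, mu_y, var_y = local_stats(x)
    cross = np.tensordot(wx * wy, kern, axes=([2, 3], [0, 1]))
    cov = cross - mu_x * mu_y
    smap = _ssim_formula(mu_x, mu_y, var_x, var_y, cov, c1, c2)
    return float(smap.mean())


class MetricsReport(dict):
    """Plain dict of the three metrics with attribute access."""

    def __getattr__(self, item):
        try:
            return self[item]
        except KeyError:
            raise AttributeError(item) from None


def evaluate(reconstruction, truth, ssim_mode: str = "windowed") -> MetricsReport:
    """All three metrics at once; relative error reported as a fraction."""
    return MetricsReport(
        relative_error=relative_error(reconstruction, truth),
        psnr=psnr(reconstruction, truth),
        ssim=ssim(reconstruction, truth, mode=ssim_mode),
        ssim_mode=ssim_mode,
    )
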