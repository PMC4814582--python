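"""Dammann grating design: transition-point optimization for equal orders.

A Dammann grating is a binary {0, π} phase grating whose transition points
within one period are chosen so that a prescribed set of diffraction orders
carry (nearly) equal power.  An N-beam grating (N odd) needs
``2·int[(N−1)/4] + 2`` transition points per period.  The far-field order
amplitudes of the square profile have a closed form in the transition
positions, so the design reduces to a small nonlinear least-squares problem:
equalize the N central order intensities while keeping the diffraction
efficiency into those orders high.  The search is a multi-start trust-region
least-squares run from seeded random starts (the grating family is classical
but no closed-form solution exists for general N), followed by quantization
of the transitions to the SLM pixel grid.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from .slm_patterns import DammannSpec, transition_count

__all__ = ["design_dammann", "order_intensities", "grating_orders"]

_EFFICIENCY_WEIGHT = 0.05  # gentle pull toward high power in the designed orders
_MIN_GAP = 2e-3  # transitions closer than this are treated as collapsed


def order_intensities(transitions: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """Far-field intensities |c_m|² of a binary grating with given transitions.

    The profile starts at phase 0 at x = 0 and toggles at each transition;
    ``c_m = ∫ s(x)·e^{−2πimx} dx`` with ``s = e^{iφ} ∈ {+1, −1}``.
    """
    t = np.asarray(transitions, dtype=float)
    edges = np.r_[0.0, t, 1.0]
    signs = (-1.0) ** np.arange(edges.size - 1)
    m = np.asarray(orders)[:, None]
    c = np.zeros(m.shape[0], dtype=complex)
    nonzero = (m != 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        seg = (
            np.exp(-2j * math.pi * m * edges[None, 1:])
            - np.exp(-2j * math.pi * m * edges[None, :-1])
        ) / (-2j * math.pi * m)
    seg0 = edges[1:] - edges[:-1]
    c[nonzero] = (signs[None, :] * seg[nonzero]).sum(axis=1)
    if (~nonzero).any():
        c[~nonzero] = (signs * seg0).sum()
    return np.abs(c) ** 2


def grating_orders(profile: np.ndarray) -> np.ndarray:
    """Order intensities of a sampled one-period binary phase profile via DFT."""
    field = np.exp(1j * np.asarray(profile))
    c = np.fft.fft(field) / field.size
    return np.abs(c) ** 2  # index m and -m wrap per FFT convention


def _residuals(t_sorted: np.ndarray, half_orders: np.ndarray, weights: np.ndarray) -> np.ndarray:
    # s(x) is real, so |c_-m| = |c_m|: only orders 0..half are independent
    inten = order_intensities(t_sorted, half_orders)
    eff = float(weights @ inten)
    mean = eff / (2 * half_orders[-1] + 1) if half_orders[-1] else eff
    return np.r_[inten - mean, _EFFICIENCY_WEIGHT * (1.0 - eff)]


def _optimize(n_beams: int, n_starts: int, rng: np.random.Generator) -> np.ndarray:
    k = transition_count(n_beams)
    half = (n_beams - 1) // 2
    half_orders = np.arange(0, half + 1)
    weights = np.where(half_orders == 0, 1.0, 2.0)
    best, best_score = None, np.inf
    for _ in range(n_starts):
        t0 = np.sort(rng.uniform(0.02, 0.98, size=k))
        if np.min(np.diff(t0)) < 1e-3:
            continue
        res = least_squares(
            lambda t: _residuals(np.sort(t), half_orders, weights),
            t0,
            bounds=(0.0, 1.0),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=400,
        )
        t = np.sort(res.x)
        gaps = np.diff(np.r_[t, 1 + t[0]])
        if np.min(gaps) < _MIN_GAP:
            continue  # collapsed transitions: a lower-order grating in disguise
        inten = order_intensities(t, np.arange(-half, half + 1))
        spread = inten.std() / inten.mean()
        # prefer equally good solutions with higher efficiency
        score = spread - 0.01 * inten.sum()
        if score < best_score:
            best, best_score = t, score
        if spread < 0.005 and inten.sum() > 0.6:
            break
    if best is None:
        raise RuntimeError(f"Dammann optimization failed for {n_beams} beams")
    return best


def _quantize(t: np.ndarray, period_px: int) -> np.ndarray:
    q = np.round(t * period_px) / period_px
    q = np.unique(q)
    return q


@lru_cache(maxsize=None)
def _designed_transitions(n_beams: int) -> tuple[float, ...]:
    # deterministic: design depends only on n_beams
    rng = np.random.default_rng(20160712)
    n_starts = 40 if n_beams <= 9 else 400
    return tuple(_optimize(n_beams, n_starts, rng))


def design_dammann(
    n_beams: int,
    period_px: int | None = None,
    max_spread: float = 0.05,
) -> DammannSpec:
    """Design a binary Dammann grating with ``n_beams`` equal central orders.

    Parameters
    ----------
    n_beams:
        Odd number of target diffraction orders (centered on 0).
    period_px:
        Pixels per grating period on the SLM.  Defaults to 128 for small
        arrays and 1024 for arrays needing many transitions.  Transitions are
        quantized to this grid; adjacent transitions must stay more than one
        pixel apart, otherwise the minimum feasible period is reported.
    max_spread:
        Accepted relative intensity spread (std/mean) of the designed orders
        after pixel quantization.

    Returns
    -------
    DammannSpec
        Transition points quantized to the pixel grid.
    """
    if n_beams < 1 or n_beams % 2 == 0:
        raise ValueError("n_beams must be an odd positive integer")
    if n_beams == 1:
        return DammannSpec(1, period_px or 2, ())
    if period_px is None:
        period_px = 128 if n_beams <= 9 else 1024
    t = np.asarray(_designed_transitions(n_beams))
    gaps = np.diff(np.r_[t, 1 + t[0]])
    min_period = math.ceil(1.0 / np.min(gaps))
    if period_px < min_period:
        raise ValueError(
            f"period {period_px} px puts transitions closer than one pixel; "
            f"minimum feasible period is {min_period} px"
        )
    q = _quantize(t, period_px)
    if q.size != t.size:
        raise ValueError(
            f"period {period_px} px merges transitions after quantization; "
            f"minimum feasible period is {min_period} px"
        )
    spec = DammannSpec(n_beams, period_px, tuple(q))
    half = (n_beams - 1) // 2
    inten = order_intensities(q, np.arange(-half, half + 1))
    spread = inten.std() / inten.mean()
    if spread > max_spread:
        raise RuntimeError(
            f"designed {n_beams}-beam grating has {spread:.1%} order spread at "
            f"period {period_px} px (limit {max_spread:.0%}); increase the period"
        )
    return spec
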