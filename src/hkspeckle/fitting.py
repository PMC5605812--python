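"""Maximum-likelihood fitting of the four speckle models.

The likelihood is maximized with a cyclic Newton-Raphson scheme on the score
equations: each parameter is updated in turn from a one-dimensional Newton
step (central finite differences), the updated value feeding the next
parameter's step, until the summed absolute parameter change drops below the
stopping tolerance.  A bounded Nelder-Mead direct search is used as fallback
when the Newton iteration diverges.  Model comparison uses the Schwarz
Bayesian information criterion, BIC = -2 log L + m log n.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize

from hkspeckle.models import (
    HKParams,
    KParams,
    LOG_FLOOR,
    RayleighParams,
    RicianParams,
    hk_log_pdf,
    k_log_pdf,
    rayleigh_log_pdf,
    rician_log_pdf,
)

__all__ = [
    "AmplitudeHistogram",
    "FitResult",
    "ModelComparison",
    "SolverConfig",
    "MODEL_NAMES",
    "log_likelihood",
    "fit_mle",
    "bic_value",
    "select_okrr",
    "compare_hk_okrr",
    "fit_all_models",
]

MODEL_NAMES = ("rayleigh", "rician", "k", "hk")

# single-model tie-break preference: fewest parameters first, then Rician
_TIE_ORDER = {"rayleigh": 0, "rician": 1, "k": 2}

_OKRR_LABELS = {"rayleigh": "RA", "rician": "RI", "k": "K"}


@dataclass(frozen=True)
class AmplitudeHistogram:
    """Binned envelope amplitudes: strictly increasing edges plus counts."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        counts = np.asarray(self.counts)
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "counts", counts)
        if edges.ndim != 1 or counts.ndim != 1 or len(counts) != len(edges) - 1:
            raise ValueError("need len(counts) == len(edges) - 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if edges[0] < 0:
            raise ValueError("amplitude bins must start at a nonnegative edge")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_samples(
        cls,
        amplitudes: np.ndarray,
        n_bins: int = 256,
        amp_range: tuple[float, float] = (0.0, 1.0),
    ) -> "AmplitudeHistogram":
        counts, edges = np.histogram(np.asarray(amplitudes, float), bins=n_bins, range=amp_range)
        return cls(edges=edges, counts=counts)


@dataclass(frozen=True)
class SolverConfig:
    tol: float = 1e-8
    max_iter: int = 25
    fd_step: float = 1e-5
    raw_bin_threshold: int = 1200  # raw samples above this are finely binned
    damping: float = 0.5  # max relative per-parameter change per Newton step
    bounds: dict = field(
        default_factory=lambda: {
            "rayleigh": [(1e-3, 10.0)],
            "rician": [(0.0, 10.0), (1e-3, 10.0)],
            "k": [(0.05, 500.0), (1e-2, 1e3)],
            "hk": [(0.01, 10.0), (1e-3, 10.0), (1.0, 100.0)],
        }
    )

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValueError("tol must be > 0")


@dataclass(frozen=True)
class FitResult:
    model: str
    params: Union[RayleighParams, RicianParams, KParams, HKParams]
    loglik: float
    bic: float
    n_iter: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": {k: float(v) for k, v in _param_items(self.params)},
            "loglik": self.loglik,
            "bic": self.bic,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


@dataclass(frozen=True)
class ModelComparison:
    hk: FitResult
    okrr: FitResult
    okrr_label: str
    rel_diff_pct: float


def _param_items(p):
    return [(f, getattr(p, f)) for f in p.__dataclass_fields__]


# per-model plumbing: vector <-> params, log-pdf
_LOGPDF = {
    "rayleigh": lambda a, v: rayleigh_log_pdf(a, RayleighParams(v[0])),
    "rician": lambda a, v: rician_log_pdf(a, RicianParams(v[0], v[1])),
    "k": lambda a, v: k_log_pdf(a, KParams(v[0], v[1])),
    # coarser mixture step: still ~1e-13 accurate (auto-refined for large c)
    "hk": lambda a, v: hk_log_pdf(a, HKParams(v[0], v[1], v[2]), step=0.15),
}

_PACK = {
    "rayleigh": lambda p: np.array([p.d]),
    "rician": lambda p: np.array([p.l, p.g]),
    "k": lambda p: np.array([p.m, p.a]),
    "hk": lambda p: np.array([p.epsilon, p.sigma, p.c]),
}

_UNPACK = {
    "rayleigh": lambda v: RayleighParams(float(v[0])),
    "rician": lambda v: RicianParams(float(v[0]), float(v[1])),
    "k": lambda v: KParams(float(v[0]), float(v[1])),
    "hk": lambda v: HKParams(float(v[0]), float(v[1]), float(v[2])),
}

N_PARAMS = {"rayleigh": 1, "rician": 2, "k": 2, "hk": 3}


def _as_points_weights(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, AmplitudeHistogram):
        mask = data.counts > 0
        return data.centers[mask], data.counts[mask].astype(float)
    a = np.asarray(data, dtype=float).ravel()
    return a, np.ones_like(a)


def log_likelihood(data, model: str, params) -> float:
    """Log-likelihood of raw amplitudes or of a histogram (count-weighted).

    Histograms contribute ``sum_b counts_b * ln P(center_b)``.  Densities are
    floored at 1e-300 so the value is always finite.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    pts, wts = _as_points_weights(data)
    if pts.size == 0 or wts.sum() == 0:
        raise ValueError("empty data")
    v = _PACK[model](params)
    lp = np.maximum(_LOGPDF[model](pts, v), LOG_FLOOR)
    return float(np.dot(wts, lp))


def bic_value(loglik: float, m_params: int, n: int) -> float:
    """Schwarz criterion -2 log L + m log n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if m_params < 0:
        raise ValueError("m_params must be >= 0")
    return -2.0 * loglik + m_params * math.log(n)


# ---------------------------------------------------------------------------
# Moment-based initialization: cheap starting points guaranteed inside the
# solver bounds
# ---------------------------------------------------------------------------


def _weighted_moments(pts, wts):
    w = wts / wts.sum()
    m1 = float(np.dot(w, pts))
    m2 = float(np.dot(w, pts * pts))
    m4 = float(np.dot(w, pts**4))
    return m1, m2, m4


def _initial_guess(model: str, pts, wts, bounds) -> np.ndarray:
    m1, m2, m4 = _weighted_moments(pts, wts)
    m2 = max(m2, 1e-12)
    if model == "rayleigh":
        v = np.array([math.sqrt(m2 / 2.0)])
    elif model == "rician":
        l0 = math.sqrt(max(2.0 * m1 * m1 - m2, 0.0))
        g0 = math.sqrt(max((m2 - l0 * l0) / 2.0, 1e-8))
        v = np.array([l0, g0])
    elif model == "k":
        var_i = max(m4 - m2 * m2, 1e-12)
        snr_i = m2 / math.sqrt(var_i)
        # Rayleigh gives intensity SNR 1; K gives sqrt(m/(m+2))... solve crudely
        s2 = snr_i * snr_i
        m0 = 2.0 * s2 / max(1.0 - s2, 0.05) if s2 < 1.0 else 10.0
        m0 = min(max(m0, 0.1), 400.0)
        v = np.array([m0, 2.0 * math.sqrt(m0 / m2)])
    else:  # hk
        e0 = math.sqrt(max(2.0 * m1 * m1 - m2, 0.0))
        c0 = 3.0
        s0 = math.sqrt(max((m2 - e0 * e0) / (2.0 * c0), 1e-8))
        v = np.array([max(e0, 0.02), s0, c0])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(v, lo, hi)


# ---------------------------------------------------------------------------
# Cyclic Newton-Raphson on the score equations
# ---------------------------------------------------------------------------


def fit_mle(
    data,
    model: str,
    cfg: Optional[SolverConfig] = None,
    init=None,
    seed: int = 0,
) -> FitResult:
    """Fit one model by maximum likelihood.

    ``data`` is either raw amplitudes or an :class:`AmplitudeHistogram`.  The
    cyclic Newton iteration updates one parameter at a time from the score and
    its derivative (central differences), feeding each update into the next
    parameter's step; it stops when ``sum_i |s_i^(k+1) - s_i^(k)| <= tol``.
    On divergence the fit falls back to bounded Nelder-Mead.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}")
    cfg = cfg or SolverConfig()
    pts, wts = _as_points_weights(data)
    if pts.size == 0:
        raise ValueError("empty data")
    if not isinstance(data, AmplitudeHistogram) and pts.size > cfg.raw_bin_threshold:
        # fine binning: likelihood error is negligible, evaluation much cheaper
        hist = AmplitudeHistogram.from_samples(pts, n_bins=1024, amp_range=(0.0, float(pts.max()) * (1 + 1e-9)))
        pts, wts = _as_points_weights(hist)
    bounds = cfg.bounds[model]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    logpdf = _LOGPDF[model]

    def nll(v) -> float:
        with np.errstate(over="ignore", invalid="ignore"):
            lp = logpdf(pts, v)
        lp = np.where(np.isfinite(lp), lp, LOG_FLOOR)
        lp = np.maximum(lp, LOG_FLOOR)
        return -float(np.dot(wts, lp))

    if init is not None:
        v = np.clip(_PACK[model](init).astype(float), lo, hi)
    else:
        v = _initial_guess(model, pts, wts, bounds)

    v, n_iter, converged = _cyclic_newton(nll, v, lo, hi, cfg)

    if not converged:
        res = optimize.minimize(
            nll,
            v,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"xatol": 1e-7, "fatol": 1e-7, "maxfev": 2000},
        )
        if np.isfinite(res.fun) and res.fun <= nll(v) + 1e-12:
            v = np.clip(res.x, lo, hi)
            converged = bool(res.success)

    ll = -nll(v)
    params = _UNPACK[model](v)
    n = int(wts.sum())
    return FitResult(
        model=model,
        params=params,
        loglik=ll,
        bic=bic_value(ll, N_PARAMS[model], n),
        n_iter=n_iter,
        converged=converged,
    )


def _cyclic_newton(nll, v, lo, hi, cfg: SolverConfig):
    """Coordinate-wise Newton on the score; returns (v, n_iter, converged)."""
    v = v.copy()
    m = len(v)
    best = nll(v)
    bad_iters = 0
    for it in range(1, cfg.max_iter + 1):
        v_old = v.copy()
        for i in range(m):
            h = cfg.fd_step * max(abs(v[i]), 1e-4)
            vp, vm = v.copy(), v.copy()
            vp[i] = min(v[i] + h, hi[i])
            vm[i] = max(v[i] - h, lo[i])
            span = vp[i] - vm[i]
            if span <= 0:
                continue
            f0 = nll(v)
            fp = nll(vp)
            fm = nll(vm)
            grad = (fp - fm) / span  # dNLL/ds_i
            curv = (fp - 2.0 * f0 + fm) / (0.5 * span) ** 2
            if not np.isfinite(grad):
                continue
            if np.isfinite(curv) and curv > 1e-12:
                step = -grad / curv
            else:
                # non-convex direction: damped gradient descent on NLL
                step = -np.sign(grad) * cfg.damping * max(abs(v[i]), 1e-3)
            cap = cfg.damping * max(abs(v[i]), 1e-3)
            step = float(np.clip(step, -cap, cap))
            v[i] = float(np.clip(v[i] + step, lo[i], hi[i]))
        delta = float(np.abs(v - v_old).sum())
        cur = nll(v)
        if not np.isfinite(cur) or cur > best + 1e-6 * max(1.0, abs(best)):
            bad_iters += 1
            if bad_iters >= 2:
                return v, it, False  # diverging; caller falls back
        else:
            bad_iters = 0
            best = min(best, cur)
        if delta <= cfg.tol:
            return v, it, True
    return v, cfg.max_iter, False


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def rel_diff_pct(bic_hk: float, bic_okrr: float) -> float:
    """Unsigned relative BIC difference, |hk - okrr| / |hk| * 100."""
    if bic_hk == 0:
        return 0.0
    return abs(bic_hk - bic_okrr) / abs(bic_hk) * 100.0


def select_okrr(fits: Sequence[FitResult]) -> FitResult:
    """Pick the BIC-optimal of the three single models (K, Rayleigh, Rician).

    Ties break toward fewer parameters (Rayleigh), then Rician.
    """
    by_model = {f.model: f for f in fits}
    if set(by_model) != {"rayleigh", "rician", "k"}:
        raise ValueError("need exactly one fit each for rayleigh, rician, k")
    return min(by_model.values(), key=lambda f: (f.bic, _TIE_ORDER[f.model]))


def okrr_label(fit: FitResult) -> str:
    return _OKRR_LABELS[fit.model]


def fit_all_models(data, cfg: Optional[SolverConfig] = None, seed: int = 0) -> dict:
    cfg = cfg or SolverConfig()
    return {m: fit_mle(data, m, cfg=cfg, seed=seed) for m in MODEL_NAMES}


def compare_hk_okrr(data, cfg: Optional[SolverConfig] = None, seed: int = 0) -> ModelComparison:
    """Fit all four models, select the best single model, compare BICs.

    ``rel_diff_pct = |BIC_hk - BIC_okrr| / BIC_hk * 100`` (unsigned).
    """
    fits = fit_all_models(data, cfg=cfg, seed=seed)
    best_single = select_okrr([fits["rayleigh"], fits["rician"], fits["k"]])
    hk = fits["hk"]
    return ModelComparison(
        hk=hk,
        okrr=best_single,
        okrr_label=okrr_label(best_single),
        rel_diff_pct=rel_diff_pct(hk.bic, best_single.bic),
    )
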