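"""Assessment experiments: the (alpha, rho) grid study and the estimator bias study.

``run_grid`` drives the full chain per grid cell and realization -- phantom ->
envelope simulation -> analysis-window crop -> normalization -> histogram ->
four-model MLE -> best-single-model selection -- and aggregates means and
standard deviations across realizations.  ``bias_study`` measures relative
bias and normalized SD of the HK estimates (clustering c and coherent ratio
k = epsilon/sigma) on raw synthetic samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from hkspeckle.fitting import AmplitudeHistogram, SolverConfig, compare_hk_okrr
from hkspeckle.models import HKParams, ParameterError, hk_intensity_snr, sample
from hkspeckle.phantom import PhantomSpec, build_phantom
from hkspeckle.simulate import AcousticConfig, simulate_envelope

__all__ = [
    "GridSpec",
    "GridCellResult",
    "GridResult",
    "BiasStudyResult",
    "run_grid",
    "snr_table",
    "snr_table_from_params",
    "bias_study",
    "classify_section",
    "load_reference_hk_means",
]

log = logging.getLogger(__name__)

SECTION_LABELS = {"K": "*", "RA": "**", "RI": "***"}
EDGE_MARGIN = 0.10  # fraction of depth excluded at top and bottom


@dataclass(frozen=True)
class GridSpec:
    alphas: tuple = (0.1, 1.0, 100.0)
    rhos: tuple = (1.0, 10.0, 100.0)
    n_realizations: int = 5
    base_seed: int = 0
    scale: str = "desk"  # "desk": 4 mm cube, capped N; "full": 12 mm cube

    def __post_init__(self) -> None:
        if not self.alphas or not self.rhos:
            raise ValueError("alpha and rho grids must be nonempty")
        if self.n_realizations < 2:
            raise ValueError("need at least 2 realizations")
        if self.scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")

    @classmethod
    def full_grid(cls, base_seed: int = 0, n_realizations: int = 30) -> "GridSpec":
        return cls(
            alphas=(0.1, 1.0, 10.0, 100.0),
            rhos=(1.0, 5.0, 10.0, 50.0, 100.0),
            n_realizations=n_realizations,
            base_seed=base_seed,
            scale="full",
        )

    @property
    def cube_side(self) -> float:
        return 0.004 if self.scale == "desk" else 0.012

    @property
    def max_scatterers(self) -> int | None:
        return 200_000 if self.scale == "desk" else None


@dataclass(frozen=True)
class GridCellResult:
    alpha: float
    rho: float
    comparisons: list  # per-realization ModelComparison, failures excluded
    n_excluded: int

    def _hk_param_matrix(self) -> np.ndarray:
        return np.array(
            [[c.hk.params.epsilon, c.hk.params.sigma, c.hk.params.c] for c in self.comparisons]
        )

    @property
    def hk_means(self) -> HKParams:
        eps, sig, c = self._hk_param_matrix().mean(axis=0)
        return HKParams(float(eps), float(sig), float(c))

    @property
    def okrr_label(self) -> str:
        labels = [c.okrr_label for c in self.comparisons]
        vals, counts = np.unique(labels, return_counts=True)
        return str(vals[np.argmax(counts)])

    @property
    def rel_diff_pct(self) -> float:
        return float(np.mean([c.rel_diff_pct for c in self.comparisons]))

    @property
    def snr(self) -> float:
        return hk_intensity_snr(self.hk_means)

    @property
    def section(self) -> str:
        return classify_section(self.okrr_label, self.alpha, self.rho)

    def summary_rows(self) -> list[dict]:
        rows = []
        mat = self._hk_param_matrix()
        sds = mat.std(axis=0, ddof=1)
        means = mat.mean(axis=0)
        hk_bics = [c.hk.bic for c in self.comparisons]
        okrr_bics = [c.okrr.bic for c in self.comparisons]
        base = {"alpha": self.alpha, "rho": self.rho, "section": self.section}
        for name, mu, sd in zip(("epsilon", "sigma", "c"), means, sds):
            rows.append({**base, "model": "hk", "param": name, "mean": mu, "sd": sd})
        rows.append(
            {
                **base,
                "model": "hk",
                "param": "bic",
                "mean": float(np.mean(hk_bics)),
                "sd": float(np.std(hk_bics, ddof=1)),
            }
        )
        rows.append(
            {
                **base,
                "model": f"okrr:{self.okrr_label}",
                "param": "bic",
                "mean": float(np.mean(okrr_bics)),
                "sd": float(np.std(okrr_bics, ddof=1)),
            }
        )
        return rows


@dataclass(frozen=True)
class GridResult:
    spec: GridSpec
    cells: list

    def cell(self, alpha: float, rho: float) -> GridCellResult:
        for c in self.cells:
            if c.alpha == alpha and c.rho == rho:
                return c
        raise KeyError((alpha, rho))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.extend(c.summary_rows())
        return pd.DataFrame(rows)


def _stage_seed(base_seed: int, stage: str, *indices: int) -> int:
    tag = sum(ord(ch) for ch in stage)
    ss = np.random.SeedSequence([base_seed, tag, *indices])
    return int(ss.generate_state(1)[0])


def _crop_analysis_window(img, cfg: AcousticConfig, cube_side: float) -> np.ndarray:
    """Drop the top/bottom EDGE_MARGIN of cube depth (specular edge artifacts)."""
    def idx(z):
        return int(round(2.0 * (cfg.standoff + z) / cfg.c0 * cfg.fs))

    lo = idx(EDGE_MARGIN * cube_side)
    hi = min(idx((1.0 - EDGE_MARGIN) * cube_side), img.amplitudes.shape[0])
    return img.amplitudes[lo:hi, :]


def realize_cell_histogram_samples(
    alpha: float,
    rho: float,
    seed: int,
    acoustic: AcousticConfig,
    cube_side: float,
    max_scatterers: int | None,
) -> np.ndarray:
    """One realization up to the normalized analysis window (2D array in [0,1])."""
    spec = PhantomSpec(
        alpha=alpha,
        rho=rho,
        cube_side=cube_side,
        wavelength=acoustic.wavelength,
        seed=seed,
        max_scatterers=max_scatterers,
    )
    phantom = build_phantom(spec)
    env = simulate_envelope(phantom, acoustic, cube_side)
    window = _crop_analysis_window(env, acoustic, cube_side)
    peak = window.max(initial=0.0)
    if peak <= 0:
        raise ValueError("empty analysis window")
    return window / peak


def realize_cell_histogram(
    alpha: float,
    rho: float,
    seed: int,
    acoustic: AcousticConfig,
    cube_side: float,
    max_scatterers: int | None,
    n_bins: int = 256,
) -> AmplitudeHistogram:
    """One realization: phantom -> envelope -> crop -> normalize -> histogram."""
    window = realize_cell_histogram_samples(
        alpha, rho, seed, acoustic, cube_side, max_scatterers
    )
    return AmplitudeHistogram.from_samples(window.ravel(), n_bins=n_bins)


def run_grid(
    spec: GridSpec,
    acoustic: AcousticConfig | None = None,
    solver: SolverConfig | None = None,
) -> GridResult:
    """Run the full grid experiment; deterministic from ``spec.base_seed``."""
    acoustic = acoustic or AcousticConfig()
    solver = solver or SolverConfig()
    cells = []
    for ia, alpha in enumerate(spec.alphas):
        for ir, rho in enumerate(spec.rhos):
            comparisons = []
            n_excluded = 0
            for r in range(spec.n_realizations):
                seed = _stage_seed(spec.base_seed, "grid", ia, ir, r)
                try:
                    hist = realize_cell_histogram(
                        alpha, rho, seed, acoustic, spec.cube_side, spec.max_scatterers
                    )
                    comparisons.append(compare_hk_okrr(hist, cfg=solver))
                except Exception:  # noqa: BLE001 - failed realizations are excluded
                    log.exception("realization failed at alpha=%s rho=%s r=%d", alpha, rho, r)
                    n_excluded += 1
            if n_excluded > 0.2 * spec.n_realizations:
                raise RuntimeError(
                    f"cell (alpha={alpha}, rho={rho}): {n_excluded} of "
                    f"{spec.n_realizations} realizations failed"
                )
            cells.append(GridCellResult(alpha=alpha, rho=rho, comparisons=comparisons, n_excluded=n_excluded))
    return GridResult(spec=spec, cells=cells)


def snr_table(grid: GridResult) -> pd.DataFrame:
    """Closed-form intensity SNR at each cell's mean HK parameters."""
    rows = [
        {"alpha": c.alpha, "rho": c.rho, "snr": hk_intensity_snr(c.hk_means)}
        for c in grid.cells
    ]
    return pd.DataFrame(rows)


def snr_table_from_params(params: pd.DataFrame) -> pd.DataFrame:
    """Fixture mode: SNR per row of a (epsilon, sigma, c) parameter table."""
    out = params.copy()
    out["snr"] = [
        hk_intensity_snr(HKParams(r.epsilon, r.sigma, r.c)) for r in params.itertuples()
    ]
    return out


def load_reference_hk_means() -> pd.DataFrame:
    """Bundled mean HK parameter estimates per (alpha, rho) grid cell."""
    with resources.files("hkspeckle.data").joinpath("table1_means.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


@dataclass(frozen=True)
class BiasStudyResult:
    c_grid: tuple
    k_grid: tuple
    rel_bias_c: np.ndarray  # (len(c_grid), len(k_grid))
    rel_bias_k: np.ndarray
    nsd_c: np.ndarray
    nsd_k: np.ndarray
    n_excluded: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.c_grid):
            for j, k in enumerate(self.k_grid):
                rows.append(
                    {
                        "c": c,
                        "k": k,
                        "rel_bias_c": self.rel_bias_c[i, j],
                        "rel_bias_k": self.rel_bias_k[i, j],
                        "nsd_c": self.nsd_c[i, j],
                        "nsd_k": self.nsd_k[i, j],
                    }
                )
        return pd.DataFrame(rows)


def bias_study(
    c_set,
    k_set,
    n_samples: int = 1000,
    n_reps: int = 10,
    sigma_fixed: float = 1.0,
    seed: int = 0,
    solver: SolverConfig | None = None,
) -> BiasStudyResult:
    """Relative bias and normalized SD of HK estimates on raw samples.

    For each (c, k) cell, draw ``n_samples`` HK amplitudes with
    epsilon = k * sigma_fixed, sigma = sigma_fixed, fit the HK model on the
    raw samples (rescaled to unit peak so the solver bounds apply, then
    unscaled), and aggregate over ``n_reps`` repetitions.
    """
    c_set = tuple(c_set)
    k_set = tuple(k_set)
    if any(k <= 0 for k in k_set):
        raise ParameterError("k = epsilon/sigma must be > 0 (epsilon = 0 makes k unidentifiable)")
    if any(c <= 0 for c in c_set):
        raise ParameterError("c must be > 0")
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    solver = solver or SolverConfig()
    from hkspeckle.fitting import fit_mle

    shape = (len(c_set), len(k_set))
    rb_c = np.full(shape, np.nan)
    rb_k = np.full(shape, np.nan)
    nsd_c = np.full(shape, np.nan)
    nsd_k = np.full(shape, np.nan)
    n_excluded = 0
    for i, c_true in enumerate(c_set):
        for j, k_true in enumerate(k_set):
            c_hats, k_hats = [], []
            for r in range(n_reps):
                s = _stage_seed(seed, "bias", i, j, r)
                amps = sample(
                    "hk", HKParams(k_true * sigma_fixed, sigma_fixed, c_true), n_samples, s
                )
                scale = amps.max()
                fit = fit_mle(amps / scale, "hk", cfg=solver, seed=s)
                if not fit.converged:
                    n_excluded += 1
                    continue
                c_hats.append(fit.params.c)
                k_hats.append(fit.params.epsilon / fit.params.sigma)
            if len(c_hats) >= 2:
                c_hats = np.array(c_hats)
                k_hats = np.array(k_hats)
                rb_c[i, j] = (c_hats.mean() - c_true) / c_true
                rb_k[i, j] = (k_hats.mean() - k_true) / k_true
                nsd_c[i, j] = c_hats.std(ddof=1) / c_true
                nsd_k[i, j] = k_hats.std(ddof=1) / k_true
    return BiasStudyResult(
        c_grid=c_set,
        k_grid=k_set,
        rel_bias_c=rb_c,
        rel_bias_k=rb_k,
        nsd_c=nsd_c,
        nsd_k=nsd_k,
        n_excluded=n_excluded,
    )


def classify_section(
    okrr_label: str,
    alpha: float,
    rho: float,
    total_reflection_flag: bool | None = None,
) -> str:
    """Map a cell to its regime section: * (K), ** (Rayleigh), *** (Rician),
    **** (K-like under the near-specular high-alpha/high-rho regime).

    The flag defaults to the configuration rule alpha >= 1 and rho >= 50.
    """
    if okrr_label not in SECTION_LABELS:
        raise ValueError(f"unknown OKRR label {okrr_label!r}")
    if total_reflection_flag is None:
        total_reflection_flag = alpha >= 1.0 and rho >= 50.0
    if total_reflection_flag:
        return "****"
    return SECTION_LABELS[okrr_label]
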