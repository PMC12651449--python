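"""Synthetic kiwifruit shelf-life data generator.

Emulates the measured structure of a two-cultivar, four-stage (day 0/3/6/9,
30 fruits per cultivar per day) shelf-life experiment:

* quality-parameter trajectories — SSC rising from ~12 to ~16.5 degBrix,
  firmness falling from ~13.5 to ~7 kg cm^-2, L* 55->45, a* -9->-6, b* 30->22,
  with chroma derived as sqrt(a*^2 + b*^2) (~31.4 -> ~22.9);
* the pooled Pearson correlation structure among the six quality parameters
  (e.g. r(SSC, firmness) ~ -0.78, r(b*, chroma) ~ 0.99), induced by a dominant
  shared "ripeness" latent plus a small secondary latent;
* VNIR reflectance spectra (256 bands, 400-1000 nm) with chlorophyll
  absorption dips near 420 and 670 nm, a NIR shoulder near 830 nm whose level
  declines over shelf life, and the 970 nm water band, each feature amplitude
  affine in the fruit's quality state.

The generative model, on the standardized scale of each quality variable v:

    z_v = l1_v * theta1 + l2_v * theta2 + u_v * eps_v,   u_v^2 = 1 - l1^2 - l2^2

where theta1 is the ripeness latent (mean increasing with shelf-life day,
within-day spread ``within_day_sd``), theta2 is an independent standard-normal
nuisance latent and eps_v is independent noise.  Loadings are calibrated so
the implied pooled correlation matrix matches the target matrix; trajectory
endpoints then fix each variable's mean and SD exactly (balanced day design).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hsi import HyperCube, ReferenceFrames, SpectralAxis, scaled_roi_size

__all__ = [
    "SimConfig",
    "QUALITY_PARAMETERS",
    "SPECTRAL_FEATURES",
    "simulate_quality_table",
    "simulate_spectrum",
    "simulate_spectra",
    "simulate_cube",
]

#: the six measured quality parameters, in canonical column order
QUALITY_PARAMETERS = ("ssc", "firmness", "L", "a", "b", "chroma")

#: variables generated from the latent model (chroma is derived)
_PRIMITIVE = ("ssc", "firmness", "L", "a", "b")

# Latent loadings calibrated (least squares) against the target pooled
# correlation matrix; primary loading signs encode each variable's direction
# of change with ripeness.
_DEFAULT_LOADINGS = {
    #        l1 (ripeness)  l2 (nuisance)
    "ssc":      (+0.876, +0.214),
    "firmness": (-0.939, +0.200),
    "L":        (-0.660, -0.147),
    "a":        (+0.652, -0.236),
    "b":        (-0.616, -0.093),
}

# (day-0 cohort mean, day-9 cohort mean)
_DEFAULT_ENDPOINTS = {
    "ssc":      (12.0, 16.5),   # degBrix
    "firmness": (13.5, 7.0),    # kg cm^-2
    "L":        (55.0, 45.0),
    "a":        (-9.0, -6.0),
    "b":        (30.0, 22.0),
}

#: moisture proxy: loading on the ripeness latent (moisture falls as fruit ripens)
_MOISTURE_LOADING = -0.9

# Spectral forward model: Gaussian features on a smooth sigmoidal baseline.
# amplitude = base + scale * mixed_driver;  sign=-1 -> absorption dip.
# Drivers are linear combinations (normalized to unit variance) of the
# standardized quality variables / moisture proxy.
SPECTRAL_FEATURES = (
    # name        center  width   sign   base   scale  driver weights
    ("chl_blue",   420.0,  12.0,  -1.0,  0.080, 0.025, {"a": -1.0}),
    ("chl_red",    670.0,  18.0,  -1.0,  0.140, 0.045, {"a": -1.0}),
    ("vis_level",  550.0,  60.0,  +1.0,  0.060, 0.020, {"L": +1.0}),
    ("yellow",     600.0,  35.0,  +1.0,  0.050, 0.018, {"b": +1.0}),
    ("nir_shoulder", 830.0, 70.0, +1.0,  0.100, 0.030, {"firmness": +0.7, "ssc": -0.5}),
    ("water",      970.0,  28.0,  -1.0,  0.130, 0.025, {"moisture": +1.0}),
)

_ETA_COLUMNS = tuple(f"eta_{name}" for name, *_ in SPECTRAL_FEATURES)

# rng stream tags (kept < 2**31 and combined with the user seed)
_TAG_TABLE, _TAG_SPECTRUM, _TAG_CUBE = 11, 23, 37


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the synthetic experiment."""

    n_per_group: int = 30
    cultivars: tuple[str, ...] = ("Xuxiang", "Cuixiang")
    days: tuple[int, ...] = (0, 3, 6, 9)
    latent_loadings: dict = field(default_factory=lambda: dict(_DEFAULT_LOADINGS))
    trajectory_endpoints: dict = field(default_factory=lambda: dict(_DEFAULT_ENDPOINTS))
    within_day_sd: float = 0.15          # ripeness latent SD, day-fraction units
    spectral_noise_sd: float = 0.005     # reflectance units, per band
    explainable_fraction: float = 0.9    # signal fraction per spectral feature
    n_bands: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not (0.0 < self.explainable_fraction <= 1.0):
            raise ValueError("explainable_fraction must be in (0, 1]")
        if self.within_day_sd < 0:
            raise ValueError("within_day_sd must be >= 0")
        if self.spectral_noise_sd < 0:
            raise ValueError("spectral_noise_sd must be >= 0")
        for v in _PRIMITIVE:
            if v not in self.latent_loadings or v not in self.trajectory_endpoints:
                raise ValueError(f"missing loadings/endpoints for variable {v!r}")
            l1, l2 = self.latent_loadings[v]
            if l1 * l1 + l2 * l2 > 1.0 + 1e-12:
                raise ValueError(
                    "implied correlation matrix is not positive semi-definite: "
                    f"communality of {v!r} is {l1 * l1 + l2 * l2:.3f} > 1"
                )

    # -- analytic pooled moments (exact for the balanced day design) --------

    @property
    def day_fractions(self) -> np.ndarray:
        d = np.asarray(self.days, dtype=float)
        return d / d.max() if d.max() > 0 else d

    @property
    def latent_sd(self) -> float:
        """Pooled SD of the ripeness latent (between-day + within-day)."""
        t = self.day_fractions
        return float(np.sqrt(t.var() + self.within_day_sd**2))

    def population_moments(self, var: str) -> tuple[float, float]:
        """Pooled (mean, SD) of a primitive quality variable, by construction."""
        m0, m9 = self.trajectory_endpoints[var]
        l1, _ = self.latent_loadings[var]
        sd = abs(m9 - m0) * self.latent_sd / abs(l1)
        return (m0 + m9) / 2.0, sd

    def spectral_axis(self) -> SpectralAxis:
        return SpectralAxis(np.linspace(400.0, 1000.0, self.n_bands))


def simulate_quality_table(config: SimConfig | None = None) -> pd.DataFrame:
    """One row per fruit: design labels, quality parameters and latent state.

    Besides the six quality parameters the table carries the simulation
    latents needed to render spectra deterministically: the ripeness latent
    ``theta`` (standardized), the ``moisture`` proxy and one ``eta_*``
    distortion draw per spectral feature (the ``1 - explainable_fraction``
    share of each feature's variance).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng([cfg.seed, _TAG_TABLE])
    t_frac = cfg.day_fractions
    t_mid = float(t_frac.mean())
    sd_th = cfg.latent_sd

    rows: dict[str, list] = {k: [] for k in ("cultivar", "day", "fruit")}
    n_total = cfg.n_per_group * len(cfg.cultivars) * len(cfg.days)
    day_col, cult_col, fruit_col = [], [], []
    fid = 0
    for cultivar in cfg.cultivars:
        for day, tf in zip(cfg.days, t_frac):
            for _ in range(cfg.n_per_group):
                cult_col.append(cultivar)
                day_col.append(day)
                fruit_col.append(fid)
                fid += 1
    n = len(fruit_col)
    tf_arr = np.array([dict(zip(cfg.days, t_frac))[d] for d in day_col])

    theta1 = (tf_arr + rng.normal(0.0, cfg.within_day_sd, n) - t_mid) / sd_th
    theta2 = rng.normal(0.0, 1.0, n)

    data = {"cultivar": cult_col, "day": day_col, "fruit": fruit_col}
    for v in _PRIMITIVE:
        l1, l2 = cfg.latent_loadings[v]
        u = np.sqrt(max(1.0 - l1 * l1 - l2 * l2, 0.0))
        mean, sd = cfg.population_moments(v)
        z = l1 * theta1 + l2 * theta2 + u * rng.normal(0.0, 1.0, n)
        data[v] = mean + sd * z
    data["chroma"] = np.sqrt(np.asarray(data["a"]) ** 2 + np.asarray(data["b"]) ** 2)
    data["theta"] = theta1
    u_m = np.sqrt(1.0 - _MOISTURE_LOADING**2)
    data["moisture"] = _MOISTURE_LOADING * theta1 + u_m * rng.normal(0.0, 1.0, n)
    for col in _ETA_COLUMNS:
        data[col] = rng.normal(0.0, 1.0, n)
    return pd.DataFrame(data)


def _standardized_drivers(row, cfg: SimConfig) -> dict[str, float]:
    z = {}
    for v in _PRIMITIVE:
        mean, sd = cfg.population_moments(v)
        z[v] = (float(row[v]) - mean) / sd
    z["moisture"] = float(row["moisture"])  # already unit scale
    return z


def _analytic_corr(cfg: SimConfig, u: str, v: str) -> float:
    if u == v:
        return 1.0
    def load(name):
        if name == "moisture":
            return (_MOISTURE_LOADING, 0.0)
        return cfg.latent_loadings[name]
    (a1, a2), (b1, b2) = load(u), load(v)
    return a1 * b1 + a2 * b2


def feature_amplitudes(row, cfg: SimConfig) -> dict[str, float]:
    """Noiseless feature amplitudes (the 'dip-depth parameters') for a fruit.

    Each feature's driver is the unit-variance linear combination of
    standardized quality drivers named in :data:`SPECTRAL_FEATURES`, blended
    with the fruit's stored independent distortion at signal fraction
    ``explainable_fraction``.
    """
    z = _standardized_drivers(row, cfg)
    f = cfg.explainable_fraction
    out = {}
    for name, _c, _w, _s, base, scale, weights in SPECTRAL_FEATURES:
        drv = sum(w * z[k] for k, w in weights.items())
        # normalize driver to unit variance using the analytic correlations
        var = sum(
            wi * wj * _analytic_corr(cfg, ki, kj)
            for ki, wi in weights.items() for kj, wj in weights.items()
        )
        drv /= np.sqrt(var)
        eta = float(row[f"eta_{name}"])
        mixed = np.sqrt(f) * drv + np.sqrt(1.0 - f) * eta
        out[name] = base + scale * mixed
    return out


def _baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth reflectance baseline: low in the visible, plateau in the NIR."""
    x = (wavelengths - 400.0) / 600.0
    return 0.30 + 0.25 * (3.0 * x**2 - 2.0 * x**3)


def simulate_spectrum(
    row,
    axis: SpectralAxis,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """ROI-mean reflectance spectrum for one fruit (values clamped to [0, 1]).

    Gaussian absorption/reflection features on a smooth baseline, feature
    amplitudes affine in the fruit's quality state, plus homoscedastic
    per-band Gaussian noise of SD ``config.spectral_noise_sd``.
    """
    if axis.n_bands != config.n_bands:
        raise ValueError(
            f"axis has {axis.n_bands} bands, config expects {config.n_bands}"
        )
    wl = axis.wavelengths
    spec = _baseline(wl).copy()
    amps = feature_amplitudes(row, config)
    for name, center, width, sign, *_ in SPECTRAL_FEATURES:
        spec += sign * amps[name] * np.exp(-0.5 * ((wl - center) / width) ** 2)
    if config.spectral_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(
                [config.seed, _TAG_SPECTRUM, int(row["fruit"])]
            )
        spec += rng.normal(0.0, config.spectral_noise_sd, spec.shape)
    return np.clip(spec, 0.0, 1.0)


def simulate_spectra(
    table: pd.DataFrame, config: SimConfig, axis: SpectralAxis | None = None
) -> np.ndarray:
    """Stack of ROI-mean spectra for every fruit in ``table`` (n x n_bands)."""
    axis = axis or config.spectral_axis()
    return np.vstack(
        [simulate_spectrum(row, axis, config) for _, row in table.iterrows()]
    )


_WHITE_LEVEL = 3000.0
_DARK_LEVEL = 100.0
_BACKGROUND_REFLECTANCE = 0.03


def simulate_cube(
    row,
    axis: SpectralAxis,
    config: SimConfig,
    height: int = 64,
    width: int = 64,
    pixel_variation: float = 0.01,
) -> tuple[HyperCube, ReferenceFrames]:
    """Raw intensity cube + reference frames for one fruit.

    An elliptical fruit on a dark background; each fruit pixel carries the
    fruit's mean spectrum modulated by a spatially smooth multiplicative
    brightness field (SD ``pixel_variation``).  The raw cube is constructed by
    inverting the white/dark correction, so correcting it recovers the
    generating reflectance exactly (up to float arithmetic).
    """
    from scipy.ndimage import zoom

    rng = np.random.default_rng([config.seed, _TAG_CUBE, int(row["fruit"])])
    spec = simulate_spectrum(row, axis, config, rng=rng)

    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    mask = ((yy - cy) / (0.38 * height)) ** 2 + ((xx - cx) / (0.32 * width)) ** 2 <= 1.0

    roi_size = scaled_roi_size(height, width)
    if mask.sum() < roi_size * roi_size:
        warnings.warn(
            f"fruit mask ({int(mask.sum())} px) smaller than the scaled "
            f"{roi_size}x{roi_size} ROI; downstream ROI extraction will fail",
            stacklevel=2,
        )

    coarse = rng.normal(0.0, pixel_variation, (8, 8))
    fieldmap = zoom(coarse, (height / 8.0, width / 8.0), order=3)[:height, :width]

    refl = np.empty((height, width, axis.n_bands))
    refl[:] = _BACKGROUND_REFLECTANCE
    refl[mask] = spec[None, :] * (1.0 + fieldmap[mask][:, None])
    np.clip(refl, 0.0, 1.0, out=refl)

    white = np.full(axis.n_bands, _WHITE_LEVEL)
    dark = np.full(axis.n_bands, _DARK_LEVEL)
    raw = refl * (white - dark) + dark
    cube = HyperCube(
        raw, axis, kind="raw",
        provenance=f"synthetic fruit={int(row['fruit'])} seed={config.seed}",
    )
    return cube, ReferenceFrames(white=white, dark=dark)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=int(seed))
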