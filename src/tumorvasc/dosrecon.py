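"""Diffuse optical spectroscopy: forward reflectance model and inversion.

The forward model composes hemoglobin absorption, power-law reduced
scattering and the steady-state diffusion-approximation reflectance of a
semi-infinite homogeneous medium (extrapolated-boundary dipole solution),
evaluated at two source-detector separations over the green/yellow band
(520-590 nm) where hemoglobin dominates tissue absorption.

Two inverse routes recover blood oxygen saturation (StO2), total hemoglobin
(tHb) and the scattering law from measured spectra:

* :func:`lsq_invert` -- bounded multi-start nonlinear least squares on
  log-reflectance; the reference (oracle) inversion.
* :class:`InverseModel` -- a feed-forward neural regressor trained on
  simulated spectra (:func:`make_training_set` / :func:`train_inverse_model`),
  the fast inversion used for routine measurements.

A shared multiplicative gain models the unknown instrument calibration; the
spectral features fed to either solver are constructed to be invariant to it.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import least_squares
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

__all__ = [
    "DEFAULT_DISTANCES_MM",
    "DEFAULT_RANGES",
    "DEFAULT_WAVELENGTHS_NM",
    "ExtinctionTable",
    "InverseModel",
    "ReflectanceSpectra",
    "TissueParams",
    "absorption_spectrum",
    "diffuse_reflectance",
    "forward_spectra",
    "invert_spectra",
    "lsq_invert",
    "make_training_set",
    "scattering_spectrum",
    "spectra_features",
    "train_inverse_model",
]

#: Measurement wavelength grid (nm) and probe source-detector separations (mm).
DEFAULT_WAVELENGTHS_NM = np.arange(520.0, 591.0, 2.0)
DEFAULT_DISTANCES_MM = (1.75, 3.5)

#: Physiological parameter ranges used for training, fitting bounds and
#: output clipping.  tHb in uM of hemoglobin tetramer equivalents
#: (10-120 uM ~ 0.4-5 % blood volume at 2.3 mM whole-blood hemoglobin).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "sto2": (0.0, 1.0),
    "thb": (10.0, 120.0),
    "a": (0.5, 2.5),
    "b": (0.5, 2.0),
    "gain": (0.5, 2.0),
}

_LN10 = np.log(10.0)
_SCATTER_REF_NM = 560.0


@dataclass(frozen=True)
class ExtinctionTable:
    """Molar extinction of oxy-/deoxyhemoglobin on a wavelength grid.

    Units are 1/(cm*M).  The bundled default is a synthetic
    landmark-interpolated table (see ``data/hemoglobin_extinction_synthetic
    .csv``): monotone-cubic interpolation through the textbook Q-band
    landmarks (HbO2 peaks at 542/577 nm, HHb peak at 555 nm, isosbestic
    points at 529/545/570/584 nm), emulating the shape of the standard
    published compilations.  Users may load their own table via
    :meth:`from_csv`.
    """

    wavelengths: NDArray[np.float64]
    eps_hbo2: NDArray[np.float64]
    eps_hhb: NDArray[np.float64]

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        for name in ("eps_hbo2", "eps_hhb"):
            eps = np.asarray(getattr(self, name), dtype=float)
            if eps.shape != wl.shape or np.any(eps <= 0):
                raise ValueError(f"{name} must be positive and match the grid")
        sel = (wl >= 520.0) & (wl <= 590.0)
        diff = self.eps_hbo2[sel] - self.eps_hhb[sel]
        if not np.any(np.sign(diff[:-1]) * np.sign(diff[1:]) <= 0):
            raise ValueError("no isosbestic crossing within 520-590 nm")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExtinctionTable":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1], data[:, 2])

    @classmethod
    def default(cls) -> "ExtinctionTable":
        ref = resources.files("tumorvasc.data").joinpath(
            "hemoglobin_extinction_synthetic.csv"
        )
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def interp(self, wavelengths: NDArray) -> tuple[NDArray, NDArray]:
        """Extinction coefficients at ``wavelengths``; no extrapolation."""
        wl = np.asarray(wavelengths, dtype=float)
        if wl.min() < self.wavelengths[0] or wl.max() > self.wavelengths[-1]:
            raise ValueError(
                "requested wavelengths outside the extinction table range "
                f"[{self.wavelengths[0]:g}, {self.wavelengths[-1]:g}] nm"
            )
        return (
            np.interp(wl, self.wavelengths, self.eps_hbo2),
            np.interp(wl, self.wavelengths, self.eps_hhb),
        )

    def isosbestic_wavelengths(self, lo: float = 520.0, hi: float = 590.0) -> NDArray:
        """Wavelengths (linear-interpolated) where the two extinctions cross."""
        wl = self.wavelengths
        d = self.eps_hbo2 - self.eps_hhb
        out = []
        for i in range(wl.size - 1):
            if wl[i + 1] < lo or wl[i] > hi:
                continue
            if d[i] == 0.0:
                out.append(wl[i])
            elif d[i] * d[i + 1] < 0:
                out.append(wl[i] - d[i] * (wl[i + 1] - wl[i]) / (d[i + 1] - d[i]))
        return np.asarray(out)


@dataclass
class TissueParams:
    """Chromophore and scattering state of the probed tissue.

    ``sto2`` is the oxygen saturation fraction, ``thb`` total hemoglobin in
    uM; ``scatter_amp`` (1/mm at 560 nm) and ``scatter_power`` define the
    reduced-scattering power law; ``gain`` is the multiplicative instrument
    nuisance shared by both separations.
    """

    sto2: float
    thb: float
    scatter_amp: float
    scatter_power: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sto2 <= 1.0):
            raise ValueError("sto2 must be in [0, 1]")
        if self.thb < 0 or self.scatter_amp <= 0 or self.gain <= 0:
            raise ValueError("thb must be >= 0; scatter_amp and gain > 0")

    @property
    def c_hbo2(self) -> float:
        """Oxyhemoglobin concentration, uM."""
        return self.sto2 * self.thb

    @property
    def c_hhb(self) -> float:
        """Deoxyhemoglobin concentration, uM."""
        return (1.0 - self.sto2) * self.thb


@dataclass
class ReflectanceSpectra:
    """Reflectance matrix (distance x wavelength) from the two-separation probe."""

    wavelengths: NDArray[np.float64]
    distances: tuple[float, ...]
    r: NDArray[np.float64]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.distances), self.wavelengths.size):
            raise ValueError("r must have shape (n_distances, n_wavelengths)")
        if np.any(self.r <= 0):
            raise ValueError("reflectance must be strictly positive")
        d_order = np.argsort(self.distances)
        rr = self.r[d_order]
        if np.any(np.diff(rr, axis=0) >= 0):
            raise ValueError("reflectance must decrease with source-detector distance")


def absorption_spectrum(
    params: TissueParams, table: ExtinctionTable, wavelengths: NDArray
) -> NDArray:
    """Absorption coefficient mu_a(lambda) in 1/mm.

    mu_a = ln(10) * (c_HbO2 * eps_HbO2 + c_HHb * eps_HHb), with
    concentrations in M and extinctions in 1/(cm*M), converted to 1/mm.
    """
    e_hbo2, e_hhb = table.interp(wavelengths)
    mua_cm = _LN10 * 1e-6 * (params.c_hbo2 * e_hbo2 + params.c_hhb * e_hhb)
    return mua_cm / 10.0


def scattering_spectrum(
    a: float, b: float, wavelengths: NDArray, lam0: float = _SCATTER_REF_NM
) -> NDArray:
    """Reduced scattering mu_s'(lambda) = a * (lambda/lam0)^(-b), 1/mm."""
    if a <= 0:
        raise ValueError("scattering amplitude must be positive")
    wl = np.asarray(wavelengths, dtype=float)
    return a * (wl / lam0) ** (-b)


def _internal_reflection_factor(n_rel: float) -> float:
    # Mismatch parameter A = (1+r_d)/(1-r_d) with the standard empirical
    # polynomial for the effective internal reflection coefficient.
    r_d = -1.440 * n_rel**-2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_d) / (1.0 - r_d)


def diffuse_reflectance(
    mua: NDArray | float,
    musp: NDArray | float,
    rho: float,
    n_rel: float = 1.4,
) -> NDArray | float:
    """Steady-state diffuse reflectance R(rho) of a semi-infinite medium, 1/mm^2.

    Extrapolated-boundary dipole solution: an isotropic source at depth
    z0 = 1/(mua+musp') and its image mirrored across the extrapolated
    boundary at z = -2*zb, zb = 2*A*D, D = z0/3.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(mua <= 0) or np.any(musp <= 0) or rho <= 0:
        raise ValueError("mua, musp and rho must be strictly positive")
    mut = mua + musp
    z0 = 1.0 / mut
    d_coef = z0 / 3.0
    mueff = np.sqrt(3.0 * mua * mut)
    zb = 2.0 * _internal_reflection_factor(n_rel) * d_coef
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho**2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    return (term1 + term2) / (4.0 * np.pi)


def forward_spectra(
    params: TissueParams,
    table: ExtinctionTable | None = None,
    wavelengths: NDArray | None = None,
    distances: tuple[float, ...] = DEFAULT_DISTANCES_MM,
) -> ReflectanceSpectra:
    """Model reflectance spectra at each source-detector distance."""
    table = table or ExtinctionTable.default()
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths is None else np.asarray(wavelengths)
    mua = absorption_spectrum(params, table, wl)
    musp = scattering_spectrum(params.scatter_amp, params.scatter_power, wl)
    r = np.stack(
        [params.gain * diffuse_reflectance(mua, musp, rho) for rho in distances]
    )
    return ReflectanceSpectra(wl, tuple(distances), r)


# ---------------------------------------------------------------------------
# Inversion
# ---------------------------------------------------------------------------

def spectra_features(r: NDArray) -> NDArray:
    """Gain-invariant feature vector(s) from reflectance matrices.

    ``r`` has shape (n_dist, n_wl) or (n_samples, n_dist, n_wl).  Features:
    log-spectrum at each distance, mean-centered per distance (removes the
    shared gain), plus the inter-distance log-ratio spectrum (gain cancels,
    effective-attenuation information preserved).
    """
    rr = np.asarray(r, dtype=float)
    single = rr.ndim == 2
    if single:
        rr = rr[None]
    logr = np.log(rr)
    centered = logr - logr.mean(axis=2, keepdims=True)
    ratio = logr[:, 0, :] - logr[:, 1, :]
    feats = np.concatenate(
        [centered.reshape(rr.shape[0], -1), ratio], axis=1
    )
    return feats[0] if single else feats


_PARAM_ORDER = ("sto2", "thb", "a", "b")


def make_training_set(
    ranges: dict[str, tuple[float, float]] | None = None,
    n: int = 20000,
    noise_sd: float = 0.0,
    wavelengths: NDArray | None = None,
    distances: tuple[float, ...] = DEFAULT_DISTANCES_MM,
    seed: int = 0,
    table: ExtinctionTable | None = None,
) -> tuple[NDArray, NDArray]:
    """Simulated (features, labels) pairs for training the neural inverse.

    Parameters are drawn uniformly within ``ranges`` (gain included, though
    features are invariant to it); ``noise_sd`` is the fractional SD of
    multiplicative (1 + eps) Gaussian measurement noise.
    """
    if n < 100:
        raise ValueError("need at least 100 training samples")
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    table = table or ExtinctionTable.default()
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths is None else np.asarray(wavelengths)
    rng = np.random.default_rng(seed)
    draws = {k: rng.uniform(*ranges[k], size=n) for k in (*_PARAM_ORDER, "gain")}

    e_hbo2, e_hhb = table.interp(wl)
    c_hbo2 = draws["sto2"] * draws["thb"]
    c_hhb = (1.0 - draws["sto2"]) * draws["thb"]
    mua = _LN10 * 1e-7 * (np.outer(c_hbo2, e_hbo2) + np.outer(c_hhb, e_hhb))
    musp = draws["a"][:, None] * (wl[None, :] / _SCATTER_REF_NM) ** (
        -draws["b"][:, None]
    )
    r = np.stack(
        [diffuse_reflectance(mua, musp, rho) for rho in distances], axis=1
    )
    r *= draws["gain"][:, None, None]
    if noise_sd > 0:
        r = r * (1.0 + noise_sd * rng.standard_normal(r.shape))
        r = np.clip(r, 1e-30, None)
    labels = np.column_stack([draws[k] for k in _PARAM_ORDER])
    return spectra_features(r), labels


@dataclass
class InverseModel:
    """Trained feed-forward spectral-inversion regressor.

    Stores the fitted network together with its feature/label normalization
    and the wavelength/distance grids it is valid for; prediction on any
    other grid is refused.
    """

    mlp: MLPRegressor
    x_scaler: StandardScaler
    y_scaler: StandardScaler
    wavelengths: NDArray[np.float64]
    distances: tuple[float, ...]
    ranges: dict[str, tuple[float, float]]
    seed: int
    holdout_rmse: dict[str, float] = field(default_factory=dict)

    def predict_features(self, feats: NDArray) -> NDArray:
        feats = np.atleast_2d(feats)
        y = self.y_scaler.inverse_transform(
            self.mlp.predict(self.x_scaler.transform(feats))
        )
        for j, k in enumerate(_PARAM_ORDER):
            y[:, j] = np.clip(y[:, j], *self.ranges[k])
        return y

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path: str | Path) -> "InverseModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError("file does not contain an InverseModel")
        return model


def train_inverse_model(
    features: NDArray,
    labels: NDArray,
    hidden: tuple[int, ...] = (64, 64),
    seed: int = 0,
    wavelengths: NDArray | None = None,
    distances: tuple[float, ...] = DEFAULT_DISTANCES_MM,
    ranges: dict[str, tuple[float, float]] | None = None,
    max_iter: int = 600,
) -> InverseModel:
    """Train the neural inversion on a :func:`make_training_set` output.

    Uses a held-out validation split for early stopping; raises if training
    diverges (final validation loss above the initial one).
    """
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    wl = DEFAULT_WAVELENGTHS_NM if wavelengths is None else np.asarray(wavelengths)
    x_scaler = StandardScaler().fit(features)
    y_scaler = StandardScaler().fit(labels)
    mlp = MLPRegressor(
        hidden_layer_sizes=hidden,
        activation="relu",
        solver="adam",
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=25,
        max_iter=max_iter,
        random_state=seed,
        learning_rate_init=1e-3,
    )
    mlp.fit(x_scaler.transform(features), y_scaler.transform(labels))
    curve = np.asarray(mlp.validation_scores_)
    if curve.size >= 2 and curve[-1] < curve[0]:
        raise RuntimeError(
            "inverse-model training diverged: validation score fell from "
            f"{curve[0]:.4f} to {curve[-1]:.4f}"
        )
    model = InverseModel(
        mlp=mlp,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        wavelengths=wl,
        distances=tuple(distances),
        ranges=ranges,
        seed=seed,
    )
    pred = model.predict_features(features)
    model.holdout_rmse = {
        k: float(np.sqrt(np.mean((pred[:, j] - labels[:, j]) ** 2)))
        for j, k in enumerate(_PARAM_ORDER)
    }
    return model


def _params_from_vector(x: NDArray) -> TissueParams:
    return TissueParams(
        sto2=float(x[0]),
        thb=float(x[1]),
        scatter_amp=float(x[2]),
        scatter_power=float(x[3]),
        gain=float(x[4]),
    )


def lsq_invert(
    spectra: ReflectanceSpectra,
    table: ExtinctionTable | None = None,
    n_starts: int = 5,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> TissueParams:
    """Reference inversion: bounded multi-start least squares on log-reflectance.

    Minimizes the squared log-residual over (sto2, thb, a, b, gain) at both
    separations jointly; the best-objective converged start wins.
    """
    table = table or ExtinctionTable.default()
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    keys = (*_PARAM_ORDER, "gain")
    lo = np.array([ranges[k][0] for k in keys])
    hi = np.array([ranges[k][1] for k in keys])
    wl = spectra.wavelengths
    log_meas = np.log(spectra.r)

    def residual(x: NDArray) -> NDArray:
        p = _params_from_vector(x)
        mua = absorption_spectrum(p, table, wl)
        musp = scattering_spectrum(p.scatter_amp, p.scatter_power, wl)
        model = np.stack(
            [p.gain * diffuse_reflectance(mua, musp, rho) for rho in spectra.distances]
        )
        return (np.log(model) - log_meas).ravel()

    rng = np.random.default_rng(seed)
    # coarse pre-scan: rank seeded candidate points by residual cost and
    # refine only the most promising basins (weak-absorption corners have
    # near-zero-cost local minima that blind random restarts miss)
    candidates = np.vstack(
        [0.5 * (lo + hi), rng.uniform(lo, hi, size=(max(256, 8 * n_starts), lo.size))]
    )
    costs = [0.5 * np.sum(residual(x) ** 2) for x in candidates]
    order = np.argsort(costs)
    starts = [candidates[i] for i in order[:n_starts]]

    best = None
    for x0 in starts:
        try:
            sol = least_squares(residual, x0, bounds=(lo, hi), method="trf")
        except ValueError:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("no least-squares start converged; check spectra validity")

    # deterministic tHb-profile polish: at weak absorption the residual
    # surface has shallow tHb/scattering trade-off valleys whose local
    # minima random restarts can land in.  The profile cost v(tHb) --
    # the remaining parameters re-solved with tHb pinned -- is evaluated on
    # a coarse grid and its best bracket refined by bounded scalar
    # minimization, which locates the global valley reliably.
    thb_lo, thb_hi = ranges["thb"]
    center = 0.5 * (lo + hi)
    eps = 1e-6 * (thb_hi - thb_lo)

    def profile(thb_fix: float):
        lo_f, hi_f = lo.copy(), hi.copy()
        lo_f[1], hi_f[1] = thb_fix - eps, thb_fix + eps
        out = None
        for base in (best.x, center):
            x0 = np.clip(base, lo_f, hi_f)
            x0[1] = thb_fix
            try:
                sol = least_squares(residual, x0, bounds=(lo_f, hi_f), method="trf")
            except ValueError:
                continue
            if sol.success and (out is None or sol.cost < out.cost):
                out = sol
        return out

    grid = np.linspace(thb_lo, thb_hi, 9)
    prof = [profile(t) for t in grid]
    costs = [np.inf if s is None else s.cost for s in prof]
    k = int(np.argmin(costs))
    if np.isfinite(costs[k]):
        from scipy.optimize import minimize_scalar

        bracket_lo = grid[max(0, k - 1)]
        bracket_hi = grid[min(len(grid) - 1, k + 1)]
        scalar = minimize_scalar(
            lambda t: np.inf if (s := profile(t)) is None else s.cost,
            bounds=(bracket_lo, bracket_hi),
            method="bounded",
            options={"xatol": 1e-3 * (thb_hi - thb_lo)},
        )
        for start in (prof[k], profile(float(scalar.x))):
            if start is None:
                continue
            refined = least_squares(
                residual, np.clip(start.x, lo, hi), bounds=(lo, hi), method="trf"
            )
            if refined.success and refined.cost < best.cost:
                best = refined
    return _params_from_vector(best.x)


def invert_spectra(
    spectra: ReflectanceSpectra | list[ReflectanceSpectra],
    model: InverseModel,
    average: bool = True,
) -> TissueParams:
    """Neural inversion of one spectrum or of 3-6 replicate probe placements.

    Replicates are inverted individually and the recovered parameters
    averaged (the probe-repositioning protocol); pass ``average=False``
    to get the per-replicate list instead.
    """
    replicates = spectra if isinstance(spectra, list) else [spectra]
    feats = []
    for sp in replicates:
        if sp.wavelengths.shape != model.wavelengths.shape or not np.allclose(
            sp.wavelengths, model.wavelengths
        ):
            raise ValueError("spectra wavelength grid does not match the model")
        if tuple(sp.distances) != model.distances:
            raise ValueError("spectra distances do not match the model")
        feats.append(spectra_features(sp.r))
    preds = model.predict_features(np.asarray(feats))
    if not average:
        return [
            TissueParams(sto2=p[0], thb=p[1], scatter_amp=p[2], scatter_power=p[3])
            for p in preds
        ]
    mean = preds.mean(axis=0)
    return TissueParams(
        sto2=float(np.clip(mean[0], 0.0, 1.0)),
        thb=float(mean[1]),
        scatter_amp=float(mean[2]),
        scatter_power=float(mean[3]),
    )
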