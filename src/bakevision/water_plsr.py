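"""Water-content prediction from mean cookie spectra by NIPALS PLSR.

Gravimetric reference: the water fraction is ``X = (m_initial - m_dried) /
m_initial``, reported in percent.  Each cookie contributes one mean surface
spectrum; a partial least squares regression (PLS1, NIPALS algorithm, mean
centering, no variance scaling by default — the bands share units) maps
spectra to water percent.  The component count is chosen by fivefold
cross-validation on a random two-thirds training split, accuracy is reported
as RMSEP on the held-out third, and the fitted coefficient vector applied
per pixel yields spatial water maps.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .spectral_io import SpectralImage

__all__ = [
    "PLSRModel",
    "SplitSpec",
    "water_fraction",
    "mean_spectrum",
    "split_train_test",
    "fit_plsr",
    "cv_select_components",
    "rmsep",
    "water_map",
    "pca_mean_spectra",
]


def water_fraction(initial_mass_g: float, dried_mass_g: float) -> float:
    """Percent water per total cookie weight: ``100 * (initial - dried) / initial``."""
    if not 0 < dried_mass_g <= initial_mass_g:
        raise ValueError(
            f"need 0 < dried ({dried_mass_g} g) <= initial ({initial_mass_g} g)"
        )
    return 100.0 * (initial_mass_g - dried_mass_g) / initial_mass_g


def mean_spectrum(
    img: SpectralImage,
    mask: np.ndarray,
    exclude_nm: Sequence[float] | None = None,
) -> np.ndarray:
    """Per-band mean over surface pixels, optionally dropping listed bands.

    ``exclude_nm`` entries are matched to the nearest band; use it to run an
    analysis on a reduced grid (e.g. 18 of 19 bands).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    spec = img.cube[mask].astype(np.float64).mean(axis=0)
    if exclude_nm:
        drop = {img.band_nearest(w) for w in exclude_nm}
        keep = [i for i in range(img.n_bands) if i not in drop]
        spec = spec[keep]
    return spec


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Train/test split and cross-validation layout."""

    train_fraction: float = 2.0 / 3.0
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("need at least two folds")


def split_train_test(ids: Sequence, spec: SplitSpec) -> tuple[list, list]:
    """Seeded random split into disjoint, exhaustive train/test id lists.

    ``|train| = round(train_fraction * n)`` — 99 samples at 2/3 give 66
    train / 33 test.
    """
    ids = list(ids)
    if len(ids) < 3:
        raise ValueError("need at least three records to split")
    n_train = int(round(spec.train_fraction * len(ids)))
    perm = np.random.default_rng(spec.seed).permutation(len(ids))
    train = [ids[i] for i in perm[:n_train]]
    test = [ids[i] for i in perm[n_train:]]
    return train, test


@dataclasses.dataclass
class PLSRModel:
    """Fitted PLS1 regression: centering/scaling, latent structure, coefficients.

    ``coefficient_vector`` has one entry per input band (zero for dropped
    zero-variance bands); prediction is
    ``y_hat = y_mean + ((x - x_mean) / x_scale) . coefficient_vector``.
    """

    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray       # (n_components, n_bands)
    x_loadings: np.ndarray    # (n_components, n_bands)
    y_loadings: np.ndarray    # (n_components,)
    coefficient_vector: np.ndarray
    wavelengths_nm: np.ndarray | None = None
    cv_seed: int | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.y_mean + ((X - self.x_mean) / self.x_scale) @ self.coefficient_vector

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficient_vector": self.coefficient_vector.tolist(),
            "wavelengths_nm": None if self.wavelengths_nm is None else self.wavelengths_nm.tolist(),
            "cv_seed": self.cv_seed,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSRModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_components=int(d["n_components"]),
            x_mean=np.asarray(d["x_mean"], float),
            x_scale=np.asarray(d["x_scale"], float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], float),
            x_loadings=np.asarray(d["x_loadings"], float),
            y_loadings=np.asarray(d["y_loadings"], float),
            coefficient_vector=np.asarray(d["coefficient_vector"], float),
            wavelengths_nm=None if d["wavelengths_nm"] is None else np.asarray(d["wavelengths_nm"], float),
            cv_seed=d["cv_seed"],
        )


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    scale: bool = False,
) -> PLSRModel:
    """Fit PLS1 by NIPALS with mean centering (variance scaling optional).

    Each component takes the weight vector ``w = X'y / ||X'y||``, scores
    ``t = Xw``, loadings ``p = X't/(t't)``, ``q = y't/(t't)``, then deflates
    ``X <- X - t p'`` and ``y <- y - q t``.  The final coefficient vector is
    ``B = W (P'W)^-1 q``, which reproduces the latent-space regression; with
    as many components as the predictor rank it coincides with ordinary
    least squares.  Zero-variance bands are dropped with a warning and get a
    zero coefficient.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if n_components < 1:
        raise ValueError("need at least one component")
    if n <= n_components:
        raise ValueError("need more samples than components")

    x_mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    # constant columns accumulate ~1e-16 rounding noise; treat those as zero
    keep = sd > 1e-10 * max(1.0, float(np.abs(X).max()))
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance band(s) before PLSR",
            stacklevel=2,
        )
    x_scale_full = np.where(keep, sd, 1.0) if scale else np.ones(p)
    Xw = ((X - x_mean) / x_scale_full)[:, keep]
    y_mean = float(y.mean())
    yw = y - y_mean

    k = min(n_components, int(np.linalg.matrix_rank(Xw)))
    pk = Xw.shape[1]
    W = np.zeros((k, pk))
    P = np.zeros((k, pk))
    q = np.zeros(k)
    for a in range(k):
        w = Xw.T @ yw
        nw = np.linalg.norm(w)
        if nw == 0:
            k = a
            break
        w /= nw
        t = Xw @ w
        tt = float(t @ t)
        if tt == 0:
            k = a
            break
        pvec = Xw.T @ t / tt
        qa = float(yw @ t / tt)
        Xw = Xw - np.outer(t, pvec)
        yw = yw - qa * t
        W[a], P[a], q[a] = w, pvec, qa
    W, P, q = W[:k], P[:k], q[:k]
    if k == 0:
        raise ValueError("response has no covariance with any predictor")
    b_kept = W.T @ np.linalg.solve(P @ W.T, q)
    coef = np.zeros(p)
    coef[keep] = b_kept
    return PLSRModel(
        n_components=k,
        x_mean=x_mean,
        x_scale=x_scale_full,
        y_mean=y_mean,
        weights=_embed(W, keep, p),
        x_loadings=_embed(P, keep, p),
        y_loadings=q,
        coefficient_vector=coef,
    )


def _embed(M: np.ndarray, keep: np.ndarray, p: int) -> np.ndarray:
    out = np.zeros((M.shape[0], p))
    out[:, keep] = M
    return out


def cv_select_components(
    X: np.ndarray,
    y: np.ndarray,
    spec: SplitSpec,
    max_components: int = 10,
) -> int:
    """Component count minimizing mean cross-validated RMSEP.

    Samples are shuffled with the split seed and partitioned into ``n_folds``
    contiguous folds.  Tie rule: the smallest count whose CV-RMSEP is within
    1% of the minimum, so pure-noise responses fall back to one component.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    if n < spec.n_folds:
        raise ValueError("fewer samples than folds")
    max_components = min(max_components, X.shape[1], n - 1 - n // spec.n_folds)
    perm = np.random.default_rng(spec.seed).permutation(n)
    folds = np.array_split(perm, spec.n_folds)
    cv_err = np.zeros(max_components)
    for k in range(1, max_components + 1):
        errs = []
        for fold in folds:
            train = np.setdiff1d(perm, fold)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_plsr(X[train], y[train], k)
            errs.append(rmsep(model.predict(X[fold]), y[fold]))
        cv_err[k - 1] = float(np.mean(errs))
    best = cv_err.min()
    return int(np.argmax(cv_err <= 1.01 * best)) + 1


def rmsep(predicted: np.ndarray, measured: np.ndarray) -> float:
    """Root mean squared error of prediction, ``sqrt(sum((y_hat-y)^2)/n)``."""
    predicted = np.asarray(predicted, float).ravel()
    measured = np.asarray(measured, float).ravel()
    if predicted.shape != measured.shape:
        raise ValueError("predicted and measured lengths differ")
    if predicted.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((predicted - measured) ** 2)))


def water_map(
    img: SpectralImage,
    mask: np.ndarray,
    model: PLSRModel,
    gaussian_sigma: float = 0.0,
) -> np.ndarray:
    """Per-pixel water percent by projecting each spectrum through the model.

    Masked Gaussian smoothing (background excluded) removes pixel noise;
    background is NaN.  Because the model is linear, the map's surface
    average equals the prediction from the mean spectrum when ``sigma=0``.
    """
    if model.wavelengths_nm is not None and model.wavelengths_nm.size:
        if not np.array_equal(model.wavelengths_nm, img.wavelengths_nm):
            raise ValueError("image wavelength grid does not match the fitted model")
    elif img.n_bands != model.coefficient_vector.size:
        raise ValueError("band count does not match the fitted model")
    mask = np.asarray(mask, bool)
    pred = model.y_mean + (
        (img.cube.astype(np.float64) - model.x_mean) / model.x_scale
    ) @ model.coefficient_vector
    if gaussian_sigma > 0:
        num = ndimage.gaussian_filter(np.where(mask, pred, 0.0), gaussian_sigma)
        den = ndimage.gaussian_filter(mask.astype(float), gaussian_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = num / den
    return np.where(mask, pred, np.nan)


def pca_mean_spectra(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA of mean spectra: (scores, explained variance ratio)."""
    X = np.asarray(X, float)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = u * s
    var = s**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    return scores, ratio
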