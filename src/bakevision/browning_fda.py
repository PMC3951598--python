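"""Sensory-anchored browning score by Fisher discriminant analysis.

Surface pixels from all cookies are pooled, each labelled with its cookie's
consensus sensory class (underbaked / adequately baked / overbaked).  FDA
finds the projection w maximizing between-class relative to within-class
scatter, i.e. the leading eigenvectors of ``(S_W + ridge*I)^-1 S_B``.  The
first loading, oriented and offset so the underbaked (lightest) class mean
maps to 0 and browner pixels score lower, is the browning score; class limits
on the score axis are midpoints of adjacent baking-time group means (4/6 min
and 10/12 min), and both pixels and whole cookies are classified by
thresholding.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy import ndimage

from .spectral_io import SpectralImage

__all__ = [
    "CLASS_LABELS",
    "FDAModel",
    "consensus_class",
    "build_pixel_dataset",
    "fit_fda",
    "score_pixels",
    "mean_browning_score",
    "compute_class_limits",
    "classify_pixels",
    "classify_cookie",
]

#: Canonical class order, lightest to darkest.  Integer codes in pixel label
#: images follow this order; background is -1.
CLASS_LABELS: tuple[str, str, str] = ("underbaked", "adequately_baked", "overbaked")


def consensus_class(votes_under: int, votes_adequate: int, votes_over: int) -> str:
    """Panel consensus by majority vote; ties break toward adequately baked."""
    counts = {
        "underbaked": votes_under,
        "adequately_baked": votes_adequate,
        "overbaked": votes_over,
    }
    best = max(counts.values())
    tied = [cls for cls, n in counts.items() if n == best]
    if "adequately_baked" in tied or len(tied) > 1:
        return "adequately_baked"
    return tied[0]


@dataclasses.dataclass
class FDAModel:
    """Fitted Fisher discriminant browning-score model.

    ``loadings`` holds up to two unit-norm discriminant directions (rows);
    the score uses only the first, as
    ``score = orientation_sign * (loadings[0] . spectrum) + score_offset``.
    """

    loadings: np.ndarray
    within_scatter: np.ndarray | None
    between_scatter: np.ndarray | None
    class_mean_scores: dict[str, float]
    orientation_sign: float
    score_offset: float
    wavelengths_nm: np.ndarray
    limit_under_adequate: float | None = None
    limit_adequate_over: float | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "class_mean_scores": self.class_mean_scores,
            "orientation_sign": self.orientation_sign,
            "score_offset": self.score_offset,
            "wavelengths_nm": self.wavelengths_nm.tolist(),
            "limit_under_adequate": self.limit_under_adequate,
            "limit_adequate_over": self.limit_adequate_over,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FDAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            loadings=np.asarray(d["loadings"], float),
            within_scatter=None,
            between_scatter=None,
            class_mean_scores={k: float(v) for k, v in d["class_mean_scores"].items()},
            orientation_sign=float(d["orientation_sign"]),
            score_offset=float(d["score_offset"]),
            wavelengths_nm=np.asarray(d["wavelengths_nm"], float),
            limit_under_adequate=d["limit_under_adequate"],
            limit_adequate_over=d["limit_adequate_over"],
        )


def build_pixel_dataset(
    images: Sequence[SpectralImage],
    masks: Sequence[np.ndarray],
    class_labels: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Pool surface pixels across cookies into (pixel matrix, group labels).

    Every masked pixel inherits its cookie's consensus class.  An empty mask
    contributes no rows (with a warning); a canonical class with no cookies
    at all is an error, since the discriminant needs every group populated.
    """
    if not (len(images) == len(masks) == len(class_labels)):
        raise ValueError("images, masks and class_labels must have equal length")
    for cls in CLASS_LABELS:
        if cls not in class_labels:
            raise ValueError(f"class {cls!r} has zero cookies")
    blocks: list[np.ndarray] = []
    groups: list[np.ndarray] = []
    for img, mask, cls in zip(images, masks, class_labels):
        mask = np.asarray(mask, bool)
        if not mask.any():
            warnings.warn("empty mask: cookie contributes no pixels", stacklevel=2)
            continue
        px = img.cube[mask].astype(np.float64)
        blocks.append(px)
        groups.append(np.full(px.shape[0], cls, dtype=object))
    return np.concatenate(blocks, axis=0), np.concatenate(groups)


def _scatter_matrices(
    pixels: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Within- and between-class scatter (S_W, S_B) plus class means."""
    overall = pixels.mean(axis=0)
    p = pixels.shape[1]
    s_w = np.zeros((p, p))
    s_b = np.zeros((p, p))
    means: dict[str, np.ndarray] = {}
    for g in np.unique(groups):
        x = pixels[groups == g]
        mu = x.mean(axis=0)
        means[str(g)] = mu
        xc = x - mu
        s_w += xc.T @ xc
        d = (mu - overall)[:, None]
        s_b += x.shape[0] * (d @ d.T)
    return s_w, s_b, means


def fit_fda(
    pixels: np.ndarray,
    groups: Iterable[str],
    ridge: float | None = None,
) -> FDAModel:
    """Fit the Fisher discriminant on pooled pixel spectra.

    Solves the symmetric generalized eigenproblem ``S_B v = lam (S_W + r I) v``
    and keeps at most ``n_groups - 1`` leading eigenvectors, renormalized to
    unit Euclidean norm.  The default ridge is ``1e-6 * trace(S_W) / n_bands``.
    Orientation and offset anchor the lightest (underbaked) class: its mean
    pixel score is the maximum across classes and is mapped to 0, so the
    score decreases with increasing browning.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    groups = np.asarray(list(groups), dtype=object)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if pixels.shape[0] < pixels.shape[1] + 1:
        raise ValueError("need more pixels than bands")
    p = pixels.shape[1]
    s_w, s_b, means = _scatter_matrices(pixels, groups)
    if ridge is None:
        ridge = 1e-6 * np.trace(s_w) / p
    try:
        evals, evecs = scipy.linalg.eigh(s_b, s_w + ridge * np.eye(p))
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError):
        raise ValueError(
            "within-class scatter is singular; refit with a positive ridge"
        ) from None
    order = np.argsort(evals)[::-1]
    n_keep = min(2, len(uniq) - 1)
    if evals[order[0]] <= 1e-12 * max(1.0, np.trace(s_b)):
        raise ValueError("no separation: class means coincide (S_B has no signal)")
    loadings = evecs[:, order[:n_keep]].T
    loadings = loadings / np.linalg.norm(loadings, axis=1, keepdims=True)

    raw = {g: float(loadings[0] @ mu) for g, mu in means.items()}
    lightest = "underbaked" if "underbaked" in raw else max(raw, key=raw.get)
    sign = 1.0 if raw[lightest] >= max(raw.values()) else -1.0
    offset = -sign * raw[lightest]
    class_scores = {g: sign * v + offset for g, v in raw.items()}
    return FDAModel(
        loadings=loadings,
        within_scatter=s_w,
        between_scatter=s_b,
        class_mean_scores=class_scores,
        orientation_sign=sign,
        score_offset=offset,
        wavelengths_nm=np.array([]),
    )


def score_pixels(img: SpectralImage, mask: np.ndarray, model: FDAModel) -> np.ndarray:
    """Per-pixel browning score map; background pixels are NaN."""
    if model.wavelengths_nm.size and not np.array_equal(model.wavelengths_nm, img.wavelengths_nm):
        raise ValueError("image wavelength grid does not match the fitted model")
    if model.wavelengths_nm.size == 0 and img.n_bands != model.loadings.shape[1]:
        raise ValueError("band count does not match the fitted model")
    mask = np.asarray(mask, bool)
    scores = model.orientation_sign * (img.cube.astype(np.float64) @ model.loadings[0]) + model.score_offset
    return np.where(mask, scores, np.nan)


def mean_browning_score(score_image: np.ndarray, mask: np.ndarray) -> float:
    """Whole-cookie browning score: arithmetic mean over surface pixels."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    return float(np.asarray(score_image)[mask].mean())


def compute_class_limits(group_mean_scores: Mapping[float, float]) -> tuple[float, float]:
    """Class limits on the score axis from baking-time group means.

    The under/adequate limit is the midpoint of the 4 and 6 min group means;
    the adequate/over limit the midpoint of 10 and 12 min.
    """
    needed = (4.0, 6.0, 10.0, 12.0)
    scores = {float(k): float(v) for k, v in group_mean_scores.items()}
    missing = [t for t in needed if t not in scores]
    if missing:
        raise ValueError(f"missing baking-time groups for limits: {missing}")
    return (scores[4.0] + scores[6.0]) / 2.0, (scores[10.0] + scores[12.0]) / 2.0


def classify_cookie(mean_score: float, limits: tuple[float, float]) -> str:
    """Classify a whole cookie by its mean score; ties go to the browner class."""
    limit_ua, limit_ao = limits
    if mean_score > limit_ua:
        return "underbaked"
    if mean_score > limit_ao:
        return "adequately_baked"
    return "overbaked"


def classify_pixels(
    score_image: np.ndarray,
    mask: np.ndarray,
    limits: tuple[float, float],
    gaussian_sigma: float = 1.0,
) -> np.ndarray:
    """Label every surface pixel by browning stage after masked smoothing.

    The score map is smoothed with a masked (normalized) Gaussian — background
    never bleeds into the surface — then thresholded with the class limits.
    Returns an int8 image with codes indexing :data:`CLASS_LABELS`
    (0 underbaked, 1 adequately baked, 2 overbaked) and -1 outside the mask.
    """
    if gaussian_sigma < 0:
        raise ValueError("gaussian_sigma must be >= 0")
    mask = np.asarray(mask, bool)
    scores = np.where(mask, np.asarray(score_image, float), 0.0)
    if gaussian_sigma > 0:
        num = ndimage.gaussian_filter(scores, gaussian_sigma)
        den = ndimage.gaussian_filter(mask.astype(float), gaussian_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(mask, num / den, 0.0)
    limit_ua, limit_ao = limits
    labels = np.full(mask.shape, -1, dtype=np.int8)
    labels[mask & (scores > limit_ua)] = 0
    labels[mask & (scores <= limit_ua) & (scores > limit_ao)] = 1
    labels[mask & (scores <= limit_ao)] = 2
    return labels
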