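"""Synthetic multispectral cookie-baking data generator.

The analysis in this package (browning score, response surface, water model)
was designed for multispectral images of butter cookies baked over a grid of
oven temperatures and baking times.  No such images are publicly deposited, so
this module generates statistically equivalent data: reflectance cubes with
Beer–Lambert-style browning and water absorption, gravimetric mass pairs, and
sensory panel votes.

The generator is statistical, not mechanistic.  Its key construction is a
scalar *exposure* in minute-equivalents, ``E = t + (T - T_ref) / k`` with
``k = 10`` °C per minute, which encodes the empirical rule that one extra
minute of baking has about the same effect as a 10 °C hotter oven.  Exposure
drives three monotone responses:

* water mass fraction decays exponentially from the dough value toward a
  dry floor, ``X(E) = floor + (initial - floor) * exp(-E / tau)``;
* brown pigment accumulates after a short lag, ``c(E) = rate * max(0, E - lag)``;
* browning leads at the cookie rim: a pixel at normalized radius ``rho``
  experiences ``E_local = E * (edge_lead + (1 - edge_lead) * rho)``, so the
  browning (and drying) front propagates edge -> center.

Per-pixel reflectance follows a Beer–Lambert composition
``R(lam) = R_base(lam) * exp(-c * A_brown(lam)) * exp(-w * A_water(lam)) + eps``
clipped to [0, 1], where ``c`` is the local pigment and ``w`` the local
*evaporated* water fraction (initial minus current).  Driving the 970 nm
channel by the water deficit keeps the unbaked cookie exactly at the base
reflectance and makes reflectance decrease monotonically with baking time at
every band — most strongly in the visible range, weakly in the NIR — which is
the covariance direction the real instrument records; the current water
content remains recoverable from the 970 nm band up to sign and offset.  The
brown absorbance template peaks at 395 and 525 nm (melanoidin-like,
near-UV/green); the water template peaks at 970 nm (the short-wave NIR water
overtone).

Real images are not noiseless functions of a single latent variable, so three
heterogeneity terms break that degeneracy: per-cookie drying-speed jitter
(lognormal on the time constant tau — replicates of the same oven setting dry
at slightly different rates), per-cookie browning-rate jitter (replicates
brown slightly differently), and per-pixel lognormal surface texture on both
pigment and water (surface mottle).  Without them every band would be an
exact function of exposure, discriminant directions would be arbitrary, and
the visible bands would be a perfect (physically spurious) water predictor.

Two experimental designs are built in: ``set1`` (fixed 180 °C, ten baking
times 4–20 min, triplicates; used to anchor the browning score to a sensory
panel) and ``set2`` (5 temperatures x 7 times x 3 replicates = 105 cookies;
used for the response surface and the water model).
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .spectral_io import SpectralImage

__all__ = [
    "BakingCondition",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "SET1_TIMES_MIN",
    "SET2_TIMES_MIN",
    "SET2_TEMPS_C",
    "exposure",
    "water_curve",
    "pigment_curve",
    "render_image",
    "simulate_gravimetry",
    "simulate_panel",
    "generate_set",
]

#: Set 1 design: fixed 180 degC, baking times in minutes, triplicates.
SET1_TIMES_MIN: tuple[float, ...] = (4, 6, 7, 8, 9, 10, 12, 14, 16, 20)
#: Set 2 design: full time x temperature grid, triplicates.
SET2_TIMES_MIN: tuple[float, ...] = (4, 6, 8, 10, 12, 14, 16)
SET2_TEMPS_C: tuple[float, ...] = (150, 160, 170, 180, 200)

#: 19-band grid spanning 385-970 nm.  The instrument class this emulates uses
#: 19 LED bands; the exact grid is configurable but must include the
#: wavelengths the analysis refers to (385, 395, 470, 525, 630, 970 nm).
DEFAULT_WAVELENGTHS_NM: tuple[float, ...] = (
    385, 395, 430, 450, 470, 505, 525, 565, 590, 630,
    645, 660, 700, 850, 890, 910, 940, 950, 970,
)


@dataclasses.dataclass(frozen=True)
class BakingCondition:
    """One oven setting: baking time (min), air temperature (degC), replicate."""

    time_min: float
    temp_c: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.time_min <= 0:
            raise ValueError("baking time must be positive")
        if not (140.0 <= self.temp_c <= 210.0):
            raise ValueError(f"temperature {self.temp_c} outside simulated range [140, 210] degC")


def _brown_template(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Melanoidin-like absorbance: Gaussian peaks at 395 nm and 525 nm.

    Widths and amplitudes (sigma 12 nm / 1.0 at 395; sigma 40 nm / 0.75 at
    525) are chosen so the two largest template entries on the default grid
    sit exactly at 395 and 525 nm.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    return np.exp(-0.5 * ((lam - 395.0) / 12.0) ** 2) + 0.75 * np.exp(
        -0.5 * ((lam - 525.0) / 40.0) ** 2
    )


def _water_template(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Water absorbance: single Gaussian peak at the 970 nm overtone.

    Width 25 nm keeps the neighbouring NIR LED bands (940/950 nm) on the
    shoulder, so the 970 nm channel carries the bulk of the water signal; the
    moderate amplitude keeps the Beer-Lambert response quasi-linear over the
    simulated water range, as a linear calibration model assumes.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    return 1.2 * np.exp(-0.5 * ((lam - 970.0) / 25.0) ** 2)


def _base_reflectance(wavelengths_nm: np.ndarray) -> np.ndarray:
    """Unbaked dough reflectance: bright, with a mild downward NIR slope."""
    lam = np.asarray(wavelengths_nm, dtype=float)
    return 0.85 - 0.05 * (lam - lam[0]) / (lam[-1] - lam[0])


@dataclasses.dataclass
class SimulationConfig:
    """All tunable constants of the generator.

    Kinetic defaults are calibrated so that the ``set2`` design spans a true
    water fraction of ~1.2–9.4 % (drying time constant ``water_decay_tau``)
    and so a 180 degC / 4 min cookie is underbaked while >= 12 min is
    overbaked (panel thresholds).
    """

    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM
    image_size: tuple[int, int] = (256, 256)
    cookie_radius_px: int = 96
    exposure_ref_temp_c: float = 180.0
    temp_per_min_equiv: float = 10.0
    water_initial_frac: float = 0.115
    water_floor_frac: float = 0.010
    water_decay_tau: float = 4.48
    pigment_lag: float = 0.5
    pigment_rate: float = 0.04
    brown_absorb_template: np.ndarray | None = None
    water_absorb_template: np.ndarray | None = None
    edge_lead: float = 0.88
    tau_jitter_sd: float = 0.05
    pigment_jitter_sd: float = 0.03
    pigment_texture_sd: float = 0.10
    water_texture_sd: float = 0.10
    noise_sd: float = 0.004
    background_reflectance: float = 0.08
    nominal_mass_g: float = 11.0
    mass_noise_sd_g: float = 0.005
    n_panelists: int = 6
    panel_thresholds: tuple[float, float] = (5.0, 11.0)
    vote_noise: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths_nm, dtype=float)
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        self.wavelengths_nm = tuple(float(w) for w in lam)
        if self.brown_absorb_template is None:
            self.brown_absorb_template = _brown_template(lam)
        else:
            self.brown_absorb_template = np.asarray(self.brown_absorb_template, float)
        if self.water_absorb_template is None:
            self.water_absorb_template = _water_template(lam)
        else:
            self.water_absorb_template = np.asarray(self.water_absorb_template, float)
        for name in ("brown_absorb_template", "water_absorb_template"):
            tmpl = getattr(self, name)
            if tmpl.shape != lam.shape:
                raise ValueError(f"{name} length does not match wavelength grid")
            if np.any(tmpl < 0):
                raise ValueError(f"{name} must be non-negative")
        if min(self.noise_sd, self.tau_jitter_sd, self.pigment_jitter_sd,
               self.pigment_texture_sd, self.water_texture_sd) < 0:
            raise ValueError("noise and heterogeneity standard deviations must be >= 0")
        if not (0.0 < self.edge_lead <= 1.0):
            raise ValueError("edge_lead must be in (0, 1]")
        if not (0.0 <= self.water_floor_frac < self.water_initial_frac < 1.0):
            raise ValueError("need 0 <= water_floor_frac < water_initial_frac < 1")
        if list(self.panel_thresholds) != sorted(self.panel_thresholds):
            raise ValueError("panel thresholds must be ordered")

    @property
    def wavelength_array(self) -> np.ndarray:
        return np.asarray(self.wavelengths_nm, dtype=float)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Latent state of one simulated cookie."""

    exposure_minequiv: float
    water_frac_true: float
    pigment_mean: float
    true_class: str


@dataclasses.dataclass
class SimulatedDataset:
    """One generated design: images, per-cookie metadata, and latent truth."""

    images: list[SpectralImage]
    records: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def exposure(condition: BakingCondition, config: SimulationConfig) -> float:
    """Thermal exposure in minute-equivalents.

    ``E = t + (T - T_ref) / k`` with ``k = temp_per_min_equiv`` (degC per
    minute), a linear-additive form that makes the 1 min ~ 10 degC
    equivalence exact by construction.
    """
    if condition.time_min <= 0:
        raise ValueError("baking time must be positive")
    return condition.time_min + (condition.temp_c - config.exposure_ref_temp_c) / config.temp_per_min_equiv


def water_curve(E: float | np.ndarray, config: SimulationConfig) -> float | np.ndarray:
    """True water mass fraction after exposure ``E`` (negatives clamp to 0).

    Exponential drying toward a floor:
    ``X(E) = floor + (initial - floor) * exp(-E / tau)``.
    """
    E = np.maximum(np.asarray(E, dtype=float), 0.0)
    floor, initial = config.water_floor_frac, config.water_initial_frac
    out = floor + (initial - floor) * np.exp(-E / config.water_decay_tau)
    return float(out) if out.ndim == 0 else out


def pigment_curve(E: float | np.ndarray, config: SimulationConfig) -> float | np.ndarray:
    """Brown pigment concentration (arbitrary units): linear after a lag."""
    E = np.asarray(E, dtype=float)
    out = config.pigment_rate * np.maximum(E - config.pigment_lag, 0.0)
    return float(out) if out.ndim == 0 else out


def _true_class(E: float, config: SimulationConfig) -> str:
    lo, hi = config.panel_thresholds
    if E < lo:
        return "underbaked"
    if E < hi:
        return "adequately_baked"
    return "overbaked"


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------

def render_image(
    condition: BakingCondition,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[SpectralImage, GroundTruth]:
    """Render one cookie as a reflectance cube plus its latent ground truth.

    The cookie is a centered disk on a flat dark background.  Browning and
    drying lead at the rim via the local-exposure gradient
    ``E_local(rho) = E * (edge_lead + (1 - edge_lead) * rho)``.  Each cookie
    draws one drying time constant (``tau * exp(N(0, tau_jitter_sd))``) that
    drives both its rendered NIR signal and its gravimetric ground truth, and
    per-pixel lognormal texture multiplies the pigment and water-deficit
    fields.  For a fixed seed the output is bit-reproducible.
    """
    h, w = config.image_size
    if config.cookie_radius_px >= min(h, w) / 2:
        raise ValueError("cookie_radius_px must be smaller than half the image side")
    rng = np.random.default_rng(seed)
    E = exposure(condition, config)

    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    inside = r <= config.cookie_radius_px
    rho = np.where(inside, r / config.cookie_radius_px, 0.0)

    tau = config.water_decay_tau * float(np.exp(rng.normal(0.0, config.tau_jitter_sd))) \
        if config.tau_jitter_sd > 0 else config.water_decay_tau
    rate_mult = float(np.exp(rng.normal(0.0, config.pigment_jitter_sd))) \
        if config.pigment_jitter_sd > 0 else 1.0
    floor, initial = config.water_floor_frac, config.water_initial_frac

    e_local = max(E, 0.0) * (config.edge_lead + (1.0 - config.edge_lead) * rho)
    c_local = rate_mult * np.asarray(pigment_curve(e_local, config))
    water_local = floor + (initial - floor) * np.exp(-e_local / tau)
    deficit_local = initial - water_local  # evaporated water drives the NIR signal
    if config.pigment_texture_sd > 0:
        c_local = c_local * np.exp(rng.normal(0.0, config.pigment_texture_sd, size=c_local.shape))
    if config.water_texture_sd > 0:
        deficit_local = deficit_local * np.exp(
            rng.normal(0.0, config.water_texture_sd, size=deficit_local.shape)
        )

    base = _base_reflectance(config.wavelength_array)
    att = np.exp(
        -c_local[..., None] * config.brown_absorb_template[None, None, :]
        - deficit_local[..., None] * config.water_absorb_template[None, None, :]
    )
    cube = np.where(inside[..., None], base[None, None, :] * att, config.background_reflectance)
    if config.noise_sd > 0:
        cube = cube + rng.normal(0.0, config.noise_sd, size=cube.shape)
    cube = np.clip(cube, 0.0, 1.0).astype(np.float32)

    truth = GroundTruth(
        exposure_minequiv=float(E),
        water_frac_true=float(floor + (initial - floor) * np.exp(-max(E, 0.0) / tau)),
        pigment_mean=float(c_local[inside].mean()),
        true_class=_true_class(E, config),
    )
    return SpectralImage(cube=cube, wavelengths_nm=config.wavelength_array), truth


# ---------------------------------------------------------------------------
# Reference measurements
# ---------------------------------------------------------------------------

def simulate_gravimetry(
    truth: GroundTruth,
    nominal_mass_g: float,
    noise_sd_g: float,
    seed: int | np.random.SeedSequence,
) -> tuple[float, float]:
    """Simulate drying-cabinet gravimetry: (initial, dried) mass in grams.

    The cookie is weighed before and after oven drying; the mass loss is the
    water.  Balance noise is i.i.d. Gaussian on each weighing; dried mass is
    clamped to never exceed initial.
    """
    if nominal_mass_g <= 0:
        raise ValueError("nominal mass must be positive")
    rng = np.random.default_rng(seed)
    initial = nominal_mass_g + rng.normal(0.0, noise_sd_g)
    dried = initial * (1.0 - truth.water_frac_true) + rng.normal(0.0, noise_sd_g)
    return float(initial), float(min(dried, initial))


def simulate_panel(
    E: float,
    n_panelists: int,
    thresholds: Sequence[float],
    vote_noise: float,
    seed: int | np.random.SeedSequence,
) -> dict[str, int]:
    """Simulate a sensory panel classifying one cookie by surface browning.

    Each panelist perceives the cookie's exposure with independent Gaussian
    error (``vote_noise``, minute-equivalents) and assigns exactly one of the
    three categories by comparing to the shared thresholds.
    """
    if n_panelists < 1:
        raise ValueError("need at least one panelist")
    lo, hi = thresholds
    if not lo < hi:
        raise ValueError("thresholds must be ordered (under/adequate < adequate/over)")
    rng = np.random.default_rng(seed)
    perceived = E + rng.normal(0.0, vote_noise, size=n_panelists) if vote_noise > 0 else np.full(n_panelists, E)
    votes = {"underbaked": 0, "adequately_baked": 0, "overbaked": 0}
    for p in perceived:
        if p < lo:
            votes["underbaked"] += 1
        elif p < hi:
            votes["adequately_baked"] += 1
        else:
            votes["overbaked"] += 1
    return votes


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------

def _design_conditions(design: str) -> list[BakingCondition]:
    if design == "set1":
        return [
            BakingCondition(time_min=t, temp_c=180.0, replicate=r)
            for t in SET1_TIMES_MIN
            for r in range(3)
        ]
    if design == "set2":
        return [
            BakingCondition(time_min=t, temp_c=temp, replicate=r)
            for temp in SET2_TEMPS_C
            for t in SET2_TIMES_MIN
            for r in range(3)
        ]
    raise ValueError(f"unknown design {design!r}; expected 'set1' or 'set2'")


def generate_set(
    design: Literal["set1", "set2"],
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> SimulatedDataset:
    """Generate a full experimental set: images, sample table, ground truth.

    ``set1``: 10 baking times x 3 replicates at 180 degC (30 cookies).
    ``set2``: 5 temperatures x 7 times x 3 replicates (105 cookies).

    All randomness derives from ``seed`` (default ``config.seed``) through a
    spawned seed sequence, so equal seeds give byte-identical datasets.
    """
    config = config if config is not None else SimulationConfig()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    conditions = _design_conditions(design)
    # three independent streams per cookie: image, balance, panel
    child_seeds = root.spawn(3 * len(conditions))

    images: list[SpectralImage] = []
    rec_rows: list[dict] = []
    truth_rows: list[dict] = []
    for i, cond in enumerate(conditions):
        img, truth = render_image(cond, config, child_seeds[3 * i])
        initial, dried = simulate_gravimetry(
            truth, config.nominal_mass_g, config.mass_noise_sd_g, child_seeds[3 * i + 1]
        )
        votes = simulate_panel(
            truth.exposure_minequiv,
            config.n_panelists,
            config.panel_thresholds,
            config.vote_noise,
            child_seeds[3 * i + 2],
        )
        cid = f"{design}_{cond.time_min:g}min_{cond.temp_c:g}C_r{cond.replicate}"
        images.append(img)
        rec_rows.append(
            {
                "set": design,
                "id": cid,
                "time_min": cond.time_min,
                "temp_c": cond.temp_c,
                "replicate": cond.replicate,
                "initial_mass_g": initial,
                "dried_mass_g": dried,
                "votes_under": votes["underbaked"],
                "votes_adequate": votes["adequately_baked"],
                "votes_over": votes["overbaked"],
            }
        )
        truth_rows.append(
            {
                "id": cid,
                "exposure_minequiv": truth.exposure_minequiv,
                "water_frac_true": truth.water_frac_true,
                "pigment_mean": truth.pigment_mean,
                "true_class": truth.true_class,
            }
        )
    return SimulatedDataset(
        images=images,
        records=pd.DataFrame(rec_rows),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )
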