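"""Synthetic data generators with known ground truth.

Every downstream stage is testable offline against these generators:

* :func:`make_core` builds a ²¹⁰Pb core under the constant-rate-of-supply
  premise — excess activity at cumulative mass m is flux/MAR(t(m))·e^(−λ·t(m))
  — for an arbitrary accumulation history, with multiplicative measurement
  noise, and returns the true ages/rates alongside.
* :func:`make_lake_dataset` draws per-class burial-rate populations from
  lognormals moment-matched to target (mean, SE·√n), with classification
  covariates consistent with the intended class.
* :func:`make_source_samples` scatters (δ¹³C, C:N) points inside endmember
  boxes with known mixing proportions (remainder outside all boxes).
* :func:`make_forest_gradient` builds an exponential forest-cover→burial
  gradient observed through several buffer sizes, only one of which carries
  the true signal.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .classify import ANTHROPIC_CLASSES, NATURAL_BIOMES
from .geochron import LAMBDA_PB210, CoreInterval, CoreProfile
from .sources import EndmemberSet, default_endmembers

__all__ = [
    "CoreScenario",
    "ClassSpec",
    "ClassScenario",
    "make_core",
    "make_lake_dataset",
    "make_source_samples",
    "make_forest_gradient",
    "default_class_scenario",
]


@dataclass(frozen=True)
class CoreScenario:
    """Generative settings for one synthetic ²¹⁰Pb core.

    ``mar_history`` and ``oc_history`` may be constants or callables of age
    (yr).  Defaults describe an organic-rich 60-cm core cut in 2-cm slabs
    with supported ²¹⁰Pb of 25 Bq kg⁻¹ and an atmospheric flux chosen so
    the surface excess is ~10× the supported level.
    """

    flux: float = 0.02  # Bq cm⁻² yr⁻¹ unsupported ²¹⁰Pb
    mar_history: object = 0.08  # g cm⁻² yr⁻¹, constant or f(age)
    oc_history: object = 4.0  # %OC, constant or f(age)
    supported: float = 25.0  # Bq kg⁻¹ (²²⁶Ra)
    noise_cv: float = 0.0  # relative SD of multiplicative noise
    interval_cm: float = 2.0
    core_length_cm: float = 60.0
    dry_bulk_density: float = 0.25  # g cm⁻³
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flux <= 0:
            raise ValueError("flux must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _as_func(v):
    return v if callable(v) else (lambda t, _v=float(v): np.full_like(np.asarray(t, dtype=float), _v))


def make_core(
    scenario: CoreScenario, lake_id: str = "synthetic", collection_year: int = 2015
) -> tuple[CoreProfile, pd.DataFrame]:
    """Generate a core profile plus its truth record.

    The deposition history is integrated on a fine age grid to map age to
    cumulative mass; each slab's reported activity is the mass-weighted
    mean excess concentration over the slab (what a homogenised slab
    measures) scaled by mean-one lognormal noise of relative SD
    ``noise_cv``, plus the supported activity.

    Returns ``(profile, truth)`` where truth has per-slab true mid ages,
    MAR, SAR and OC burial.
    """
    sc = scenario
    mar_f = _as_func(sc.mar_history)
    oc_f = _as_func(sc.oc_history)
    rng = np.random.default_rng(sc.seed)

    n_slabs = int(round(sc.core_length_cm / sc.interval_cm))
    slab_mass = sc.dry_bulk_density * sc.interval_cm
    total_mass = n_slabs * slab_mass

    # age -> cumulative mass on a fine grid (extended until the core's
    # mass is covered), then invert
    t_max = 400.0
    for _ in range(12):
        t_grid = np.linspace(0.0, t_max, 80001)
        mar_grid = np.maximum(mar_f(t_grid), 1e-12)
        m_grid = cumulative_trapezoid(mar_grid, t_grid, initial=0.0)
        if m_grid[-1] >= total_mass:
            break
        t_max *= 2.0
    else:
        raise ValueError("accumulation history too slow for requested core length")
    t_of_m = lambda m: np.interp(m, m_grid, t_grid)

    intervals = []
    truth_rows = []
    n_sub = 20  # sub-steps per slab for the slab-average activity
    for i in range(n_slabs):
        m_top = i * slab_mass
        m_bot = (i + 1) * slab_mass
        m_sub = np.linspace(m_top, m_bot, n_sub + 1)
        t_sub = t_of_m(m_sub)
        conc_sub = sc.flux / np.maximum(mar_f(t_sub), 1e-12) * np.exp(-LAMBDA_PB210 * t_sub)
        excess_bq_g = np.trapezoid(conc_sub, m_sub) / slab_mass  # Bq g⁻¹
        excess = excess_bq_g * 1e3  # Bq kg⁻¹
        if sc.noise_cv > 0:
            # mean-one lognormal noise on the unsupported profile
            excess *= np.exp(rng.normal(0.0, sc.noise_cv) - 0.5 * sc.noise_cv**2)
        total = excess + sc.supported
        ra = sc.supported
        t_mid = float(t_of_m(0.5 * (m_top + m_bot)))
        mar_mid = float(mar_f(np.array([t_mid]))[0])
        oc_mid = float(oc_f(np.array([t_mid]))[0])
        intervals.append(
            CoreInterval(
                top_depth=i * sc.interval_cm,
                thickness=sc.interval_cm,
                dry_bulk_density=sc.dry_bulk_density,
                pb210_total=float(total),
                ra226=float(ra),
                oc_percent=oc_mid,
            )
        )
        truth_rows.append(
            {
                "mid_depth_cm": (i + 0.5) * sc.interval_cm,
                "age_yr": t_mid,
                "mar": mar_mid,
                "sar_cm_yr": mar_mid / sc.dry_bulk_density,
                "oc_percent": oc_mid,
                "oc_burial": mar_mid * oc_mid / 100.0 * 1e4,
                "excess_true": float(excess),
            }
        )
    profile = CoreProfile(lake_id, intervals, collection_year)
    return profile, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class ClassSpec:
    """Target moments for one lake class' burial-rate population."""

    n: int
    mean: float  # g C m⁻² yr⁻¹
    se: float  # standard error of the mean at size n
    temp_mean: float  # °C
    temp_sd: float
    temp_range: tuple[float, float] = (-30.0, 40.0)

    @property
    def sd(self) -> float:
        return self.se * np.sqrt(self.n)


@dataclass(frozen=True)
class ClassScenario:
    classes: dict[str, ClassSpec]
    seed: int = 0


def default_class_scenario(seed: int = 0) -> ClassScenario:
    """The global study conditions: per-class sample sizes, means and SEs.

    Natural classes carry their reported means/SEs; the three human-altered
    classes share the pooled human-altered mean (47.6, SE 3.1 over 143
    lakes — per-class SDs set so the pooled SE matches).  Temperatures are
    drawn to be consistent with each class (anthropic classes truncated to
    their defining bins).
    """
    anth_sd = 3.1 * np.sqrt(143)  # pooled SE back to an SD
    c = {
        "Humid tropical forest": ClassSpec(44, 113.5, 18.1, 26.0, 1.5, (20.0, 32.0)),
        "Temperate forest": ClassSpec(161, 38.9, 8.4, 9.0, 3.0, (-2.0, 18.0)),
        "Boreal forest": ClassSpec(25, 36.7, 3.2, 0.0, 3.0, (-10.0, 7.0)),
        "Other mid-latitude": ClassSpec(16, 15.4, 3.9, 8.0, 4.0, (-2.0, 18.0)),
        "Subpolar and polar": ClassSpec(9, 10.9, 2.7, -8.0, 4.0, (-25.0, 2.0)),
        "Cold anthropic": ClassSpec(90, 47.6, anth_sd / np.sqrt(90), 3.5, 2.0, (-10.0, 7.49)),
        "Moderate anthropic": ClassSpec(29, 47.6, anth_sd / np.sqrt(29), 11.0, 2.0, (7.5, 15.0)),
        "Warm anthropic": ClassSpec(24, 47.6, anth_sd / np.sqrt(24), 20.0, 2.5, (15.01, 32.0)),
    }
    return ClassScenario(classes=c, seed=seed)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if mean <= 0:
        raise ValueError("target mean must be > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - 0.5 * sigma2
    return mu, np.sqrt(sigma2)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # resample the tails
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def make_lake_dataset(scenario: ClassScenario, seed: int | None = None) -> pd.DataFrame:
    """Draw a lake table (one row per lake) from the class scenario.

    Burial rates are lognormal with moments matched to (mean, SE·√n).
    Natural classes get their biome label and a natural land cover;
    anthropic classes get ``cropland`` and a temperature inside the
    defining bin.  Column ``class_true`` records the generating class.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    rows = []
    k = 0
    for label, spec in scenario.classes.items():
        mu, sigma = _lognormal_params(spec.mean, spec.sd)
        burial = rng.lognormal(mu, sigma, spec.n)
        temps = _truncated_normal(
            rng, spec.temp_mean, spec.temp_sd, *spec.temp_range, size=spec.n
        )
        anthropic = label in ANTHROPIC_CLASSES
        for b, t in zip(burial, temps):
            rows.append(
                {
                    "lake_id": f"L{k:05d}",
                    "biome": (
                        label if not anthropic else str(rng.choice(NATURAL_BIOMES))
                    ),
                    "land_cover": "cropland" if anthropic else "forest",
                    "annual_temp": float(t),
                    "burial": float(b),
                    "class_true": label,
                }
            )
            k += 1
    return pd.DataFrame(rows)


def make_source_samples(
    endmembers: EndmemberSet | None = None,
    proportions: dict[str, float] | None = None,
    n: int = 100,
    jitter: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw (δ¹³C, C:N) samples with known source labels.

    ``proportions`` maps endmember labels to target fractions; they may sum
    to < 1, with the remainder drawn outside every box (truth label
    ``unclassified``).  ``jitter`` adds isotropic Gaussian noise (‰ on δ¹³C,
    ratio units on C:N) after placement, so with jitter > 0 and touching
    boxes the truth labels may disagree with a box classification.
    """
    if endmembers is None:
        endmembers = default_endmembers()
    if proportions is None:
        proportions = {lab: 1.0 / len(endmembers.labels) for lab in endmembers.labels}
    unknown = set(proportions) - set(endmembers.labels)
    if unknown:
        raise ValueError(f"proportions for unknown endmembers {sorted(unknown)}")
    p_total = sum(proportions.values())
    if p_total > 1.0 + 1e-9:
        raise ValueError("proportions must sum to <= 1")
    if jitter > 0 and endmembers.overlapping_pairs():
        import warnings

        warnings.warn("overlapping boxes with jitter: ambiguity possible", stacklevel=2)
    rng = np.random.default_rng(seed)
    labels = list(proportions) + ["unclassified"]
    probs = [proportions[k] for k in proportions] + [max(0.0, 1.0 - p_total)]
    probs = np.asarray(probs) / np.sum(probs)
    counts = rng.multinomial(n, probs)
    rows = []
    d_lo = min(b.d13c_min for b in endmembers.boxes)
    d_hi = max(b.d13c_max for b in endmembers.boxes)
    c_lo = min(b.cn_min for b in endmembers.boxes)
    c_hi = max(b.cn_max for b in endmembers.boxes)
    for label, cnt in zip(labels, counts):
        for _ in range(cnt):
            if label == "unclassified":
                # rejection-sample a point outside every box, within a
                # margin around the boxes' joint bounding region
                while True:
                    d = rng.uniform(max(-45.0, d_lo - 4.0), min(0.0, d_hi + 4.0))
                    c = rng.uniform(max(0.5, c_lo - 3.0), c_hi + 10.0)
                    if not any(b.contains(d, c) for b in endmembers.boxes):
                        break
            else:
                box = endmembers[label]
                d = rng.uniform(box.d13c_min, box.d13c_max)
                c = rng.uniform(box.cn_min, box.cn_max)
            if jitter > 0:
                d += rng.normal(0.0, jitter)
                c += rng.normal(0.0, jitter)
            rows.append(
                {"lake_id": f"S{len(rows):04d}", "d13c": d, "cn_molar": c, "source_true": label}
            )
    return pd.DataFrame(rows)


def make_forest_gradient(
    n_lakes: int = 20,
    a: float = 56.21,
    b: float = 0.01608,
    buffers: tuple[float, ...] = (3.0, 4.0, 6.0, 8.0, 12.0, 18.0),
    signal_buffer: float = 6.0,
    noise_cv: float = 0.15,
    buffer_corr_per_octave: float = 0.4,
    forest_range: tuple[float, float] = (10.0, 95.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential forest-cover→burial gradient observed through buffers.

    Burial is ``a·e^(b·f)`` of the forest fraction f in the
    ``signal_buffer``-km² buffer, with multiplicative lognormal noise of
    relative SD ``noise_cv``.  The other buffers see a nested mosaic:
    their fraction mixes the signal buffer's with an independent landscape
    component, the mixing weight decaying as
    ``buffer_corr_per_octave ** |log2(buffer / signal_buffer)|`` — doubling
    or halving the window brings in substantially different land cover.

    Columns: lake_id, burial, forest_pct_<buffer> per buffer.
    """
    rng = np.random.default_rng(seed)
    f_true = rng.uniform(*forest_range, n_lakes)
    burial = a * np.exp(b * f_true)
    if noise_cv > 0:
        burial = burial * np.exp(rng.normal(0.0, noise_cv, n_lakes) - 0.5 * noise_cv**2)
    data = {"lake_id": [f"A{i:03d}" for i in range(n_lakes)], "burial": burial}
    for buf in buffers:
        if buf == signal_buffer:
            f = f_true.copy()
        else:
            w = buffer_corr_per_octave ** abs(np.log2(buf / signal_buffer))
            f = np.clip(
                w * f_true + (1.0 - w) * rng.uniform(*forest_range, n_lakes),
                0.0,
                100.0,
            )
        data[f"forest_pct_{buf:g}"] = f
    return pd.DataFrame(data)
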