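"""Synthetic lifespan cohorts of regional cortical metric means.

Stands in for a cross-sectional cohort of 190 healthy participants aged
5-74: each simulated subject contributes one mean value per hemisphere,
region and metric, generated from a known trajectory family plus Gaussian
residual noise.  The null structure matches the analysis assumptions — sex
has no effect, and left/right hemispheres share a subject-level effect
giving a configurable correlation but no systematic difference — so both
the group tests (calibration under the null) and the trajectory fits
(planted-parameter recovery) are verifiable against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .core import AGE_RANGE
from .trajectory import (
    FAMILY_K,
    cubic_through_points,
    exponential_from_anchors,
    poisson_from_min_and_point,
    predict,
    quadratic_from_vertex_and_endpoints,
)

__all__ = [
    "TrajectorySpec",
    "DEFAULT_NOISE_SD",
    "DEFAULT_RHO",
    "sample_ages",
    "simulate_cohort",
    "average_hemispheres",
    "whole_cortex_reference_specs",
]

#: Default residual standard deviations per metric, in metric units.
#: Chosen at roughly 1-2x the practical-significance margins so that
#: recovery tests are neither trivial nor hopeless.
DEFAULT_NOISE_SD = {
    "thickness": 0.1,       # mm
    "radiality": 0.02,
    "FA": 0.01,
    "MD": 0.02e-3,          # mm^2/s
    "AD": 0.02e-3,
    "RD": 0.02e-3,
}

#: Default left/right correlation of per-subject regional means.
DEFAULT_RHO = 0.8


@dataclass(frozen=True)
class TrajectorySpec:
    """Generating model for one region x metric: family, parameters, noise."""

    family: str
    params: tuple
    noise_sd: float
    rho: float = DEFAULT_RHO
    heavy_tails: bool = False    # Student-t(4) residuals for robustness runs

    def __post_init__(self):
        k = FAMILY_K.get(self.family)
        if k is None:
            raise ValueError(f"unknown trajectory family: {self.family!r}")
        if len(self.params) != k:
            raise ValueError(
                f"{self.family} expects {k} parameters, got {len(self.params)}")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")

    def mean(self, ages: np.ndarray) -> np.ndarray:
        return predict(self.family, np.asarray(self.params), ages)


def _load_age_histogram() -> tuple[np.ndarray, np.ndarray]:
    ref = resources.files("cortexdti.data").joinpath("age_histogram.yaml")
    spec = yaml.safe_load(ref.read_text())
    edges = np.asarray(spec["bin_edges"], dtype=float)
    weights = np.asarray(spec["weights"], dtype=float)
    if weights.size != edges.size - 1:
        raise ValueError("age histogram fixture is inconsistent")
    return edges, weights


def sample_ages(n: int, mode: str = "uniform",
                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` ages in years from the cohort span.

    ``uniform`` draws Uniform(5, 74); ``paper_hist`` draws a 5-year bin from
    the weight fixture, then uniformly within the bin.  Deterministic given
    the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lo, hi = AGE_RANGE
    if mode == "uniform":
        return rng.uniform(lo, hi, size=n)
    if mode == "paper_hist":
        edges, weights = _load_age_histogram()
        p = weights / weights.sum()
        bins = rng.choice(weights.size, size=n, p=p)
        return rng.uniform(edges[bins], edges[bins + 1])
    raise ValueError(f"unknown age sampling mode: {mode!r}")


def simulate_cohort(specs: dict,
                    n: int = 190,
                    seed: int = 0,
                    age_mode: str = "uniform") -> pd.DataFrame:
    """Simulate a cohort table from per-(region, metric) trajectory specs.

    Parameters
    ----------
    specs
        Mapping ``(region, metric) -> TrajectorySpec``.
    n
        Number of subjects.
    seed
        Seed for ages, sexes, and residuals.

    Each subject gets an age, a sex drawn Bernoulli(0.5) with **no** effect
    on any value (the sex null is true by construction), and, per spec, left
    and right hemisphere values ``mean(age) + u + e_h`` where the shared
    subject effect ``u`` and hemisphere-specific ``e_h`` split the residual
    variance so that Var = noise_sd^2 and Corr(left, right) = rho.

    Returns a tidy frame with columns
    subject, age, sex, hemisphere, region, metric, value.
    """
    rng = np.random.default_rng(seed)
    ages = sample_ages(n, mode=age_mode, seed=rng)
    sexes = np.where(rng.random(n) < 0.5, "F", "M")
    subjects = np.array([f"sub-{i:04d}" for i in range(n)])

    frames = []
    for (region, metric), spec in specs.items():
        if not isinstance(spec, TrajectorySpec):
            raise TypeError("specs values must be TrajectorySpec")
        mu = spec.mean(ages)
        sd_shared = spec.noise_sd * np.sqrt(spec.rho)
        sd_hemi = spec.noise_sd * np.sqrt(1.0 - spec.rho)
        if spec.heavy_tails:
            scale = np.sqrt(0.5)                 # t(4) has variance 2
            draw = lambda sd, size: sd * scale * rng.standard_t(4, size=size)
        else:
            draw = lambda sd, size: rng.normal(0.0, sd, size=size)
        u = draw(sd_shared, n)
        for hemi in ("left", "right"):
            vals = mu + u + draw(sd_hemi, n)
            frames.append(pd.DataFrame({
                "subject": subjects, "age": ages, "sex": sexes,
                "hemisphere": hemi, "region": region, "metric": metric,
                "value": vals,
            }))
    return pd.concat(frames, ignore_index=True)


def average_hemispheres(cohort: pd.DataFrame) -> pd.DataFrame:
    """Collapse left/right rows to their per-subject mean (the form the
    trajectory analysis consumes)."""
    keys = ["subject", "age", "sex", "region", "metric"]
    out = (cohort.groupby(keys, as_index=False)["value"].mean())
    return out


def whole_cortex_reference_specs(
        noise_sd: dict | None = None,
        rho: float = DEFAULT_RHO) -> dict:
    """Generating specs for the total-cortex lifespan trajectories.

    Parameters are solved at run time from landmark anchors of the reported
    healthy-lifespan course of each metric:

    * thickness — decreasing exponential through 2.87 mm at age 5 and
      2.60 mm at age 30, levelling to 2.55 mm by 74 (the post-30 plateau
      value is a stated design choice).
    * radiality — cubic through 0.76 @ 5, 0.73 @ 19, 0.71 @ 55, 0.65 @ 74
      (childhood decline, adult plateau near 0.72, late decline).
    * FA — Poisson curve with its minimum 0.12 at age 30, passing through
      0.14 at age 5.
    * MD / AD / RD — U-shaped quadratics with vertices at ages 34 / 36 / 32
      and endpoint values (0.83, 0.84) / (0.94, 0.95) / (0.77, 0.78)
      x 1e-3 mm^2/s at ages 5 and 74.
    """
    sd = dict(DEFAULT_NOISE_SD)
    if noise_sd:
        sd.update(noise_sd)

    thick = exponential_from_anchors(5, 2.87, 30, 2.60, 74, 2.55)
    radial = cubic_through_points([(5, 0.76), (19, 0.73),
                                   (55, 0.71), (74, 0.65)])
    fa = poisson_from_min_and_point(30, 0.12, 5, 0.14)
    md = quadratic_from_vertex_and_endpoints(34, 5, 0.83e-3, 74, 0.84e-3)
    ad = quadratic_from_vertex_and_endpoints(36, 5, 0.94e-3, 74, 0.95e-3)
    rd = quadratic_from_vertex_and_endpoints(32, 5, 0.77e-3, 74, 0.78e-3)

    def spec(family, params, metric):
        return TrajectorySpec(family=family, params=tuple(params),
                              noise_sd=sd[metric], rho=rho)

    return {
        ("total", "thickness"): spec("exponential", thick, "thickness"),
        ("total", "radiality"): spec("cubic", radial, "radiality"),
        ("total", "FA"): spec("poisson", fa, "FA"),
        ("total", "MD"): spec("quadratic", md, "MD"),
        ("total", "AD"): spec("quadratic", ad, "AD"),
        ("total", "RD"): spec("quadratic", rd, "RD"),
    }
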