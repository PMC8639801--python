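"""Canonical simulation scenarios for calibration and signal-recovery studies.

Two fixed study conditions are used throughout the package's validation:

* ``null_signal`` -- every outcome coefficient is zero and the intercept is
  ``logit(0.1)``, so readmission is a coin flip at 10% regardless of the
  covariates.  A correctly wired pipeline must score at chance level
  (AUROC ~ 0.5) on held-out data.
* ``strong_w`` -- strong weather coefficients (0.35-0.5 log-odds per W-score
  point on PM10, heavy rain and heat) on top of moderate clinical effects
  (odds ratio ~1.5 per Charlson point).  A correct pipeline must recover the
  signal: useful discrimination internally, the weather block adding skill
  over clinical covariates alone, and the frozen model transporting to the
  shifted external site.

The gradient-boosting settings used for these studies are a deliberately
small grid (shallow, shrunk, early-stopped trees) so the whole recovery study
runs in minutes on one CPU.
"""

from __future__ import annotations

from scipy.special import logit

from .exposure import SCORED_ELEMENTS
from .simulate import OutcomeModel, SimConfig

#: single-point gradient-boosting configuration for repeated-seed studies
GBM_POINT_GRID: dict[str, dict[str, list]] = {
    "GBM": {
        "learning_rate": [0.05],
        "max_depth": [2],
        "n_estimators": [300],
        "min_samples_leaf": [20],
        "n_iter_no_change": [25],
        "validation_fraction": [0.1],
    }
}

#: small multi-point grid for the headline grid-search run
GBM_SMALL_GRID: dict[str, dict[str, list]] = {
    "GBM": {
        "learning_rate": [0.05, 0.1],
        "max_depth": [2, 3],
        "n_estimators": [300],
        "min_samples_leaf": [20],
        "n_iter_no_change": [25],
        "validation_fraction": [0.1],
    }
}


def null_outcome_model(incidence: float = 0.1) -> OutcomeModel:
    """All coefficients zero; marginal readmission probability = ``incidence``."""
    return OutcomeModel(
        intercept=float(logit(incidence)),
        beta_age=0.0, beta_los=0.0, beta_charlson=0.0,
        beta_w={e: 0.0 for e in SCORED_ELEMENTS},
        beta_condition={"F": 0.0, "I": 0.0, "J": 0.0, "M": 0.0},
    )


def strong_w_outcome_model() -> OutcomeModel:
    """Strong weather effects over moderate clinical effects."""
    return OutcomeModel(
        intercept=-2.9,
        beta_age=0.02,
        beta_los=0.05,
        beta_charlson=0.4,
        beta_w={"pm10": 0.5, "rainfall": 0.4, "humidity": 0.0, "tmin": 0.0, "tmax": 0.5},
        beta_condition={"F": 0.25, "I": 0.05, "J": 0.2, "M": 0.0},
    )


#: W-score elements carrying signal in the strong_w scenario, and the nulls
STRONG_W_INJECTED = ("pm10", "rainfall", "tmax")
STRONG_W_NULL = ("humidity", "tmin")


def null_signal_config(seed: int, n_persons_per_site: int = 5000) -> SimConfig:
    return SimConfig(seed=seed, n_persons_per_site=n_persons_per_site,
                     outcome_model=null_outcome_model())


def strong_w_config(seed: int, n_persons_per_site: int = 5000) -> SimConfig:
    return SimConfig(seed=seed, n_persons_per_site=n_persons_per_site,
                     outcome_model=strong_w_outcome_model())
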