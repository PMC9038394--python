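"""Synthetic imbalanced clinical tables shaped like the UCI heart layout.

The generator draws continuous features class-conditionally Gaussian — the
disease class shifted by ``effect`` standard deviations — and categorical
features from per-class multinomials whose distributions differ by
``categorical_skew`` in total variation (mass moved onto the last, "risk",
category).  It emulates controllable class geometry for testing the
resampler and classifiers; it does not emulate the correlation structure of
real clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ColumnSpec, Dataset, load_heart_schema
from .errors import ConfigError

# plausible clinical location/scale for the continuous columns
_CONT_PARAMS = {
    "age": (54.0, 9.0),        # years
    "trestbps": (131.0, 17.0),  # mm Hg
    "chol": (246.0, 51.0),     # mg/dl
    "thalach": (149.0, 22.0),  # bpm
    "oldpeak": (1.0, 1.1),     # ST depression
}
_DEFAULT_CONT = (0.0, 1.0)


def _base_probs(n_levels: int) -> np.ndarray:
    """Mildly decreasing baseline category distribution."""
    w = 1.0 / (np.arange(n_levels) + 1.0)
    return w / w.sum()


def _skewed_probs(p0: np.ndarray, skew: float) -> np.ndarray:
    """Move ``skew`` total-variation mass onto the last category."""
    delta = min(skew, 1.0 - p0[-1])
    p1 = p0 * (1.0 - delta / (1.0 - p0[-1]))
    p1[-1] = p0[-1] + delta
    return p1


@dataclass
class GenConfig:
    """Study conditions for one synthetic table.

    ``effect`` is the standardized between-class mean shift d applied to every
    continuous column; ``categorical_skew`` the total-variation distance
    between the per-class category distributions.
    """

    n_samples: int = 303
    minority_fraction: float = 0.35
    effect: float = 1.0
    categorical_skew: float = 0.1
    seed: int = 0
    schema: list[ColumnSpec] = field(default_factory=lambda: load_heart_schema()[0])

    def __post_init__(self) -> None:
        if not 0.0 < self.minority_fraction <= 0.5:
            raise ConfigError("minority_fraction must be in (0, 0.5]")
        if self.effect < 0:
            raise ConfigError("effect must be >= 0")
        if not 0.0 <= self.categorical_skew <= 1.0:
            raise ConfigError("categorical_skew must be in [0, 1]")
        if round(self.n_samples * self.minority_fraction) < 2:
            raise ConfigError("need at least two minority samples (A-SMOTE precondition)")


def generate(cfg: GenConfig) -> Dataset:
    """Draw one dataset under the configured study conditions.

    The minority class is the disease-present label 1; its realized count is
    ``round(minority_fraction * n_samples)``.  Rows are shuffled so class
    blocks do not align with row order.  Deterministic per seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    n_min = int(round(cfg.minority_fraction * n))
    y = np.zeros(n, dtype=int)
    y[:n_min] = 1

    X = np.empty((n, len(cfg.schema)))
    for j, col in enumerate(cfg.schema):
        if col.is_categorical:
            codes = np.asarray(col.categories)
            p0 = _base_probs(len(codes))
            p1 = _skewed_probs(p0, cfg.categorical_skew)
            X[y == 1, j] = rng.choice(codes, size=n_min, p=p1)
            X[y == 0, j] = rng.choice(codes, size=n - n_min, p=p0)
        else:
            mu, sd = _CONT_PARAMS.get(col.name, _DEFAULT_CONT)
            X[y == 1, j] = rng.normal(mu + cfg.effect * sd, sd, size=n_min)
            X[y == 0, j] = rng.normal(mu, sd, size=n - n_min)

    perm = rng.permutation(n)
    return Dataset(X=X[perm], y=y[perm], columns=list(cfg.schema),
                   positive_label="YES", negative_label="NO", target_name="num")


# ---------------------------------------------------------------------------
# canned fixtures for the test suite
# ---------------------------------------------------------------------------

# a printable 12-row, 2-feature toy table: 8 majority, 4 minority
_TINY_X = np.array([
    [1.0, 0], [1.5, 0], [2.0, 1], [2.5, 0],
    [3.0, 1], [3.5, 0], [4.0, 1], [4.5, 0],   # majority (no disease)
    [8.0, 1], [8.5, 1], [9.0, 0], [9.5, 1],   # minority (disease)
])
_TINY_Y = np.array([0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1])

_FIXTURES = {
    # an 8-sigma shift keeps per-feature class overlap ~3e-5, so n=200 draws
    # are linearly separable (on single features, even) with probability ~1
    "separable": dict(n_samples=200, minority_fraction=0.3, effect=8.0, categorical_skew=0.4),
    "overlapping": dict(n_samples=400, minority_fraction=0.25, effect=1.0, categorical_skew=0.1),
    "null": dict(n_samples=300, minority_fraction=0.5, effect=0.0, categorical_skew=0.0),
}


def make_fixture(name: str, seed: int = 0) -> Dataset:
    """Canned datasets: ``separable``, ``overlapping``, ``null`` (exactly
    balanced, zero signal) and ``tiny`` (12 hand-written rows)."""
    if name == "tiny":
        cols = [ColumnSpec("x1", "continuous"),
                ColumnSpec("x2", "categorical", (0.0, 1.0))]
        return Dataset(X=_TINY_X.copy(), y=_TINY_Y.copy(), columns=cols,
                       positive_label="YES", negative_label="NO", target_name="num")
    if name not in _FIXTURES:
        raise ConfigError(f"unknown fixture {name!r}")
    return generate(GenConfig(seed=seed, **_FIXTURES[name]))
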