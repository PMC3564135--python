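"""Latent area constructs scored by the leading principal component.

Ecological studies of suicide and self-harm summarise each area risk
dimension — material deprivation, social fragmentation, rurality — as the
first principal component of a small panel of observed indicators
(poverty rates, one-person households, service-access distances, ...).
This module builds such scores from an :class:`IndicatorPanel`, resolves
the PCA sign indeterminacy with declared indicator polarities, and
simulates correlated indicator panels whose scores reproduce a target
between-construct correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "IndicatorPanel",
    "ConstructScore",
    "DegenerateIndicatorError",
    "leading_component_score",
    "simulate_indicator_panels",
    "read_panel",
    "write_panel",
]

DEFAULT_VARIANCE_FRACTIONS = (0.79, 0.77, 0.68)
"""Leading-component variance fractions typical of deprivation,
fragmentation and rurality indicator panels for English small areas."""

DEFAULT_SCORE_CORRELATIONS = np.array(
    [
        [1.00, 0.51, -0.47],
        [0.51, 1.00, -0.51],
        [-0.47, -0.51, 1.00],
    ]
)
"""Pairwise score correlations (deprivation, fragmentation, rurality)
observed for English middle-layer areas."""

CONSTRUCT_NAMES = ("deprivation", "fragmentation", "rurality")


class DegenerateIndicatorError(ValueError):
    """An indicator column is constant and cannot be standardized."""


@dataclass(frozen=True)
class IndicatorPanel:
    """n_areas x p matrix of area-level indicator values.

    ``polarity`` flags whether each indicator measures the construct
    positively (+1) or negatively (-1); e.g. "married couple households
    with dependent children" is a negative indicator of fragmentation.
    """

    values: np.ndarray
    names: tuple[str, ...]
    polarity: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D area-by-indicator matrix")
        p = vals.shape[1]
        if p < 2:
            raise ValueError("a panel needs at least two indicators")
        if len(self.names) != p or len(self.polarity) != p:
            raise ValueError("names and polarity must match the column count")
        if any(s not in (-1, 1) for s in self.polarity):
            raise ValueError("polarity flags must be +1 or -1")
        if not np.isfinite(vals).all():
            raise ValueError("panel contains missing or non-finite values")

    @property
    def n_areas(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConstructScore:
    """Standardized leading-component score with PCA metadata.

    ``score`` has mean 0 and standard deviation 1; ``variance_explained``
    is the share of total (standardized) indicator variance carried by
    the leading component; ``loadings`` are the component's correlations
    direction in indicator space (unit-norm eigenvector).
    """

    name: str
    score: np.ndarray
    variance_explained: float
    loadings: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.score, dtype=np.float64)
        object.__setattr__(self, "score", s)
        object.__setattr__(
            self, "loadings", np.asarray(self.loadings, dtype=np.float64)
        )
        if abs(float(s.mean())) > 1e-8 or abs(float(s.std()) - 1.0) > 1e-8:
            raise ValueError("score must be standardized (mean 0, sd 1)")
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-12:
            raise ValueError("variance_explained must lie in [0, 1]")


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateIndicatorError(
            f"indicator column(s) {bad.tolist()} are constant"
        )
    return (values - mu) / sd


def leading_component_score(
    panel: IndicatorPanel, name: str = "construct"
) -> ConstructScore:
    """Score areas on the leading principal component of a panel.

    Columns are z-standardized first (correlation-matrix PCA), since
    indicators arrive on incommensurate scales.  The component sign is
    chosen so that the majority of positive-polarity indicators load
    positively, ties broken by the first positive-polarity indicator
    (or indicator 0 if none is positive).
    """
    z = _standardize(panel.values)
    pca = PCA(n_components=1, svd_solver="full")
    raw = pca.fit_transform(z)[:, 0]
    loadings = pca.components_[0]
    # leading eigenvalue of the correlation matrix over its trace p
    var_explained = float(pca.explained_variance_ratio_[0])

    pos = [k for k, s in enumerate(panel.polarity) if s == 1]
    signs = np.sign(loadings)
    n_pos_loading = int(sum(signs[k] > 0 for k in pos))
    if 2 * n_pos_loading < len(pos):
        flip = -1.0
    elif 2 * n_pos_loading > len(pos):
        flip = 1.0
    else:  # tie: defer to the first positive-polarity indicator
        anchor = pos[0] if pos else 0
        flip = 1.0 if loadings[anchor] >= 0 else -1.0
    raw = raw * flip
    loadings = loadings * flip

    sd = raw.std()
    if sd == 0:
        raise DegenerateIndicatorError("leading component has zero variance")
    score = (raw - raw.mean()) / sd
    return ConstructScore(name, score, var_explained, loadings)


def _factor_loading(variance_fraction: float, p: int) -> float:
    """Equal single-factor loading giving the requested leading-eigenvalue
    fraction for a p-indicator correlation matrix: v = (1+(p-1)λ²)/p."""
    if not 1.0 / p <= variance_fraction <= 1.0:
        raise ValueError(
            f"variance fraction {variance_fraction} outside [{1 / p:.3f}, 1]"
        )
    lam2 = (variance_fraction * p - 1.0) / (p - 1.0)
    return float(np.sqrt(lam2))


def _score_factor_correlation(lam: float, p: int) -> float:
    """Correlation between the equal-loading panel mean (∝ leading PC)
    and the latent factor; used to de-attenuate target correlations."""
    if lam >= 1.0:
        return 1.0
    return lam / np.sqrt(lam**2 + (1.0 - lam**2) / p)


def simulate_indicator_panels(
    n_areas: int,
    target_correlations: np.ndarray | None = None,
    variance_fractions: tuple[float, float, float] = DEFAULT_VARIANCE_FRACTIONS,
    seed: int = 0,
    n_indicators: int = 4,
    names: tuple[str, str, str] = CONSTRUCT_NAMES,
) -> tuple[IndicatorPanel, IndicatorPanel, IndicatorPanel]:
    """Simulate three correlated indicator panels, one per construct.

    Each construct is a single Gaussian factor; its indicators load
    equally (in magnitude) on that factor, with one negative-polarity
    indicator per panel.  Factor correlations are inflated to compensate
    for score-factor attenuation, so that the *leading-component scores*
    of the generated panels hit ``target_correlations`` as n grows.

    Parameters
    ----------
    n_areas
        Number of areas; targets are met within about +-0.05 for
        n_areas >= 2000.
    target_correlations
        3x3 positive-definite correlation matrix for the scores
        (default: the English-areas values 0.51 / -0.47 / -0.51).
    variance_fractions
        Leading-component variance fraction per construct, each in
        (1/n_indicators, 1].
    """
    if n_areas <= 0:
        raise ValueError("n_areas must be positive")
    R = (
        DEFAULT_SCORE_CORRELATIONS
        if target_correlations is None
        else np.asarray(target_correlations, dtype=np.float64)
    )
    if R.shape != (3, 3) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
        raise ValueError("target_correlations must be a 3x3 correlation matrix")
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValueError("target_correlations must be positive definite")

    lams = [_factor_loading(v, n_indicators) for v in variance_fractions]
    atten = np.array([_score_factor_correlation(l, n_indicators) for l in lams])
    R_factor = R / np.outer(atten, atten)
    np.fill_diagonal(R_factor, 1.0)
    if np.linalg.eigvalsh(R_factor).min() <= 0:
        raise ValueError(
            "de-attenuated factor correlation matrix is not positive definite; "
            "targets too strong for the requested variance fractions"
        )

    rng = np.random.default_rng(seed)
    factors = rng.multivariate_normal(
        np.zeros(3), R_factor, size=n_areas, method="cholesky"
    )
    panels = []
    for k, cname in enumerate(names):
        lam = lams[k]
        signs = np.ones(n_indicators)
        signs[1] = -1.0  # one negative-polarity indicator per panel
        noise_sd = np.sqrt(max(1.0 - lam**2, 0.0))
        noise = rng.standard_normal((n_areas, n_indicators)) * noise_sd
        values = factors[:, k][:, None] * (lam * signs)[None, :] + noise
        ind_names = tuple(f"{cname}_ind{j + 1}" for j in range(n_indicators))
        polarity = tuple(int(s) for s in signs)
        panels.append(IndicatorPanel(values, ind_names, polarity))
    return tuple(panels)


def write_panel(panel: IndicatorPanel, path: str | Path, area_ids=None) -> None:
    """Write a panel as delimited text: area_id column then indicators."""
    n = panel.n_areas
    ids = area_ids if area_ids is not None else [f"area_{i + 1}" for i in range(n)]
    df = pd.DataFrame(panel.values, columns=list(panel.names))
    df.insert(0, "area_id", list(ids))
    df.to_csv(path, sep="\t", index=False)


def read_panel(path: str | Path, polarity: tuple[int, ...]) -> IndicatorPanel:
    """Read a panel written by :func:`write_panel`; polarity comes from
    the run configuration, not the file."""
    df = pd.read_csv(path, sep="\t")
    names = tuple(df.columns[1:])
    return IndicatorPanel(df[list(names)].to_numpy(float), names, tuple(polarity))
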