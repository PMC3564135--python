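"""Model-family structures for hierarchical Poisson disease mapping.

The model family is a 3 x 4 grid: covariate effects enter linearly, as a
first-order random-walk (RW1) smooth over covariate bins, or as a cubic
B-spline with percentile-placed interior knots; area random effects are
absent, pure heterogeneity (iid), spatially structured (intrinsic CAR),
or the convolution of both (BYM).  This module turns a declarative
:class:`ModelSpec` into the concrete design structures the sampler needs:
spline bases, RW1 bin maps and difference penalties, and the sparse ICAR
precision matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import BSpline

from .geography import AreaLattice

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "SplineBasis",
    "RW1Structure",
    "EFFECT_FORMS",
    "AREA_EFFECTS",
    "cubic_spline_basis",
    "rw1_design",
    "icar_precision",
]

EFFECT_FORMS = ("linear", "rw1_smooth", "cubic_spline")
AREA_EFFECTS = ("none", "heterogeneity", "spatial", "spatial_and_heterogeneity")

DEFAULT_INNER_PERCENTILES = (16.6, 33.3, 50.0, 66.7, 83.3)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative choice of one cell of the model family.

    ``effect_form`` applies to every included covariate; ``covariates``
    is an ordered subset of the available construct names.  The reduced
    rurality-only regression, for instance, is
    ``ModelSpec(("rurality",), "linear", "spatial")``.
    """

    covariates: tuple[str, ...]
    effect_form: str = "linear"
    area_effects: str = "spatial"
    outcome_label: str = "outcome"

    def __post_init__(self) -> None:
        if self.effect_form not in EFFECT_FORMS:
            raise ValueError(
                f"effect_form must be one of {EFFECT_FORMS}, got {self.effect_form!r}"
            )
        if self.area_effects not in AREA_EFFECTS:
            raise ValueError(
                f"area_effects must be one of {AREA_EFFECTS}, "
                f"got {self.area_effects!r}"
            )
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("duplicate covariate names")

    @property
    def has_spatial(self) -> bool:
        return self.area_effects in ("spatial", "spatial_and_heterogeneity")

    @property
    def has_heterogeneity(self) -> bool:
        return self.area_effects in ("heterogeneity", "spatial_and_heterogeneity")

    def label(self) -> str:
        return f"{self.outcome_label}:{self.effect_form}/{self.area_effects}"


@dataclass(frozen=True)
class PriorSpec:
    """Prior settings for the hierarchical Poisson model.

    Fixed effects (intercept and regression coefficients) get diffuse
    zero-mean Gaussians; random-effect precisions (spatial, heterogeneity,
    RW1 / spline smoothing levels) get the historical disease-mapping
    default Gamma(1, 0.0005), i.e. prior mean precision 2000 with large
    variance.
    """

    fixed_effect_precision: float = 1e-4
    precision_shape: float = 1.0
    precision_rate: float = 5e-4

    def __post_init__(self) -> None:
        if min(
            self.fixed_effect_precision, self.precision_shape, self.precision_rate
        ) <= 0:
            raise ValueError("all prior hyperparameters must be strictly positive")


@dataclass(frozen=True)
class SplineBasis:
    """Centered cubic B-spline basis on percentile-placed interior knots.

    ``raw_basis`` (n x (n_inner + 4)) is the untouched B-spline design and
    forms a partition of unity row-wise.  ``basis`` drops the first raw
    column (absorbed by the intercept) and centers the remaining columns,
    so every column has zero mean and the fitted curve is identified
    jointly with the model intercept.
    """

    knots: np.ndarray
    raw_basis: np.ndarray = field(repr=False)
    basis: np.ndarray = field(repr=False)
    degree: int = 3

    @property
    def n_free(self) -> int:
        return self.basis.shape[1]


def cubic_spline_basis(
    x: np.ndarray,
    inner_percentiles: tuple[float, ...] = DEFAULT_INNER_PERCENTILES,
) -> SplineBasis:
    """Cubic B-spline basis with interior knots at score percentiles.

    Interior knots sit at the empirical 16.6/33.3/50/66.7/83.3 percentiles
    of ``x`` by default; boundary knots at min(x), max(x).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size <= 10:
        raise ValueError("need more than 10 observations for a spline basis")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; spline basis undefined")
    inner = np.percentile(x, inner_percentiles)
    lo, hi = float(x.min()), float(x.max())
    knots = np.concatenate([[lo], inner, [hi]])
    if np.unique(knots).size != knots.size:
        raise ValueError(
            "duplicate knots: heavily tied x makes percentile knots degenerate"
        )
    degree = 3
    t = np.concatenate([[lo] * degree, knots, [hi] * degree])
    raw = BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()
    centered = raw[:, 1:] - raw[:, 1:].mean(axis=0)
    return SplineBasis(knots=knots, raw_basis=raw, basis=centered, degree=degree)


@dataclass(frozen=True)
class RW1Structure:
    """Discretization of a continuous covariate for an RW1 smooth.

    The covariate range is cut into ``n_bins`` equal-width bins; the
    smooth effect is one level per bin under a first-order random-walk
    (first-difference) penalty.  Empty bins are retained — the walk
    bridges them.
    """

    bin_edges: np.ndarray
    bin_index: np.ndarray
    n_bins: int

    def precision(self) -> sp.csr_matrix:
        """First-difference penalty matrix D'D, rank ``n_bins - 1``."""
        m = self.n_bins
        D = sp.diags([-np.ones(m - 1), np.ones(m - 1)], [0, 1], shape=(m - 1, m))
        return (D.T @ D).tocsr()

    def bin_midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def rw1_design(x: np.ndarray, n_bins: int = 100) -> RW1Structure:
    """Map a continuous covariate onto equal-width RW1 bins."""
    x = np.asarray(x, dtype=np.float64)
    if n_bins < 3:
        raise ValueError("n_bins must be at least 3")
    if x.size <= n_bins / 2:
        raise ValueError("too few observations for the requested bin count")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("x is constant; RW1 design undefined")
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(((x - lo) / (hi - lo) * n_bins).astype(np.int64), 0, n_bins - 1)
    return RW1Structure(bin_edges=edges, bin_index=idx, n_bins=n_bins)


def icar_precision(lattice: AreaLattice) -> sp.csr_matrix:
    """Intrinsic CAR precision Q = D - A.

    Q has neighbour counts on the diagonal and -1 for each adjacent pair;
    its rows sum to zero, and on a connected lattice its rank is n - 1
    with the constant vector as null space.  The implied conditional law
    is s_i | s_(-i) ~ N(mean of neighbouring s, 1 / (tau * d_i)).
    """
    A = lattice.adjacency_matrix()
    D = sp.diags(lattice.degrees().astype(np.float64))
    return (D - A).tocsr()
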