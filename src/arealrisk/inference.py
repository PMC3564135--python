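"""MCMC inference for hierarchical Poisson disease-mapping models.

Fits any cell of the model family (linear / RW1-smooth / cubic-spline
covariate effects crossed with none / iid / ICAR / BYM area effects) by
Metropolis-within-Gibbs:

* fixed effects and spline coefficients — adaptive scalar random-walk
  Metropolis on the Poisson log-likelihood with diffuse Gaussian priors;
* spatial field ``s`` — blocked single-site Metropolis over graph-colour
  classes (areas in one class are mutually non-adjacent, so their ICAR
  full conditionals are independent given the rest), recentred to sum to
  zero every sweep with the mean transferred to the intercept;
* RW1 smooth levels — the same colour-class scheme on the even/odd bins
  of the first-difference chain graph;
* heterogeneity ``h`` — vectorised single-site Metropolis (iid prior);
* random-effect precisions — conjugate Gamma Gibbs draws.

Deviance is tracked per retained draw (including the y! term, so it is a
true -2 log-likelihood) which yields the Deviance Information Criterion
as mean deviance plus the effective parameter count
``p_D = mean(D) - D(posterior mean)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .constructs import ConstructScore
from .geography import AreaLattice
from .model import (
    ModelSpec,
    PriorSpec,
    SplineBasis,
    RW1Structure,
    cubic_spline_basis,
    icar_precision,
    rw1_design,
)

__all__ = [
    "McmcSettings",
    "FitResult",
    "DICReport",
    "EffectCurve",
    "ConvergenceWarning",
    "fit",
    "compute_dic",
    "compare_models",
    "dic_verdict",
    "count_significant_effects",
]

_QLEVELS = (0.025, 0.05, 0.5, 0.95, 0.975)
_QNAMES = ("q2.5", "q5", "median", "q95", "q97.5")


class ConvergenceWarning(UserWarning):
    """Split-chain convergence statistic exceeded its threshold."""


@dataclass(frozen=True)
class McmcSettings:
    """Sampler run lengths and seeds.

    Defaults (2 chains of 6,000 sweeps, 2,000 burn-in, thin 2) are sized
    for lattices of up to a few thousand areas.
    """

    n_chains: int = 2
    n_iter: int = 6000
    burn_in: int = 2000
    thin: int = 2
    seed: int = 0
    n_rw1_bins: int = 100
    adapt_interval: int = 50

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_iter <= self.burn_in or self.thin < 1:
            raise ValueError("invalid MCMC settings")


@dataclass(frozen=True)
class EffectCurve:
    """Posterior-mean covariate effect, evaluable at new score values.

    For ``linear`` the curve is ``beta * x``; for ``cubic_spline`` it
    evaluates the centred B-spline basis at ``x``; for ``rw1_smooth`` it
    is the step function of posterior-mean bin levels (values outside
    the training range clamp to the boundary bins).
    """

    kind: str
    beta: float = 0.0
    spline: SplineBasis | None = None
    rw1: RW1Structure | None = None
    levels: np.ndarray | None = None

    def __call__(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        if self.kind == "linear":
            return self.beta * x
        if self.kind == "cubic_spline":
            from scipy.interpolate import BSpline

            sb = self.spline
            lo, hi = sb.knots[0], sb.knots[-1]
            t = np.concatenate([[lo] * sb.degree, sb.knots, [hi] * sb.degree])
            xc = np.clip(x, lo, hi)
            raw = BSpline.design_matrix(xc, t, sb.degree, extrapolate=False).toarray()
            centered = raw[:, 1:] - sb.raw_basis[:, 1:].mean(axis=0)
            return centered @ self.levels
        if self.kind == "rw1_smooth":
            edges = self.rw1.bin_edges
            m = self.rw1.n_bins
            lo, hi = edges[0], edges[-1]
            idx = np.clip(
                ((x - lo) / (hi - lo) * m).astype(np.int64), 0, m - 1
            )
            return self.levels[idx]
        raise ValueError(f"unknown curve kind {self.kind!r}")


@dataclass
class FitResult:
    """Posterior summaries and deviance bookkeeping for one model fit."""

    spec: ModelSpec
    summaries: pd.DataFrame
    effect_curves: dict[str, EffectCurve]
    s_summary: pd.DataFrame | None
    h_summary: pd.DataFrame | None
    fitted_rho: np.ndarray
    deviance_trace: np.ndarray
    deviance_at_mean: float
    diagnostics: pd.DataFrame
    acceptance: dict[str, float]
    n_areas: int
    constraint_violation: float = 0.0

    def __post_init__(self) -> None:
        if (self.fitted_rho <= 0).any():
            raise ValueError("fitted relative risks must be positive")


@dataclass(frozen=True)
class DICReport:
    """Deviance Information Criterion decomposition."""

    mean_deviance: float
    deviance_at_posterior_mean: float
    p_d: float
    dic: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.p_d):
            raise ValueError("p_D must be finite")
        if abs(self.dic - (2 * self.mean_deviance - self.deviance_at_posterior_mean)) > 1e-6:
            raise ValueError("DIC identity violated")


# ---------------------------------------------------------------------------
# design assembly


class _Design:
    """Concrete structures for one ModelSpec on one dataset."""

    def __init__(
        self,
        spec: ModelSpec,
        scores: Mapping[str, ConstructScore],
        lattice: AreaLattice | None,
        n_areas: int,
        settings: McmcSettings,
    ):
        self.spec = spec
        for name in spec.covariates:
            if name not in scores:
                raise ValueError(f"covariate {name!r} not among supplied scores")
            if scores[name].score.shape != (n_areas,):
                raise ValueError(f"score {name!r} length mismatch")
        self.x = {name: scores[name].score for name in spec.covariates}
        self.splines: dict[str, SplineBasis] = {}
        self.rw1s: dict[str, RW1Structure] = {}
        if spec.effect_form == "cubic_spline":
            self.splines = {
                name: cubic_spline_basis(self.x[name]) for name in spec.covariates
            }
        elif spec.effect_form == "rw1_smooth":
            self.rw1s = {
                name: rw1_design(self.x[name], settings.n_rw1_bins)
                for name in spec.covariates
            }
        self.lattice = lattice
        if spec.has_spatial:
            if lattice is None:
                raise ValueError("spatial area effects require a lattice")
            if lattice.n_areas != n_areas:
                raise ValueError("lattice size does not match data")
            self.adj = lattice.adjacency_matrix()
            self.deg = lattice.degrees().astype(np.float64)
            colors = lattice.coloring()
            self.color_classes = [
                np.flatnonzero(colors == c) for c in range(colors.max() + 1)
            ]


# ---------------------------------------------------------------------------
# per-chain sampler


class _Chain:
    def __init__(
        self,
        design: _Design,
        y: np.ndarray,
        log_e: np.ndarray,
        priors: PriorSpec,
        settings: McmcSettings,
        rng: np.random.Generator,
    ):
        self.d = design
        self.y = y.astype(np.float64)
        self.log_e = log_e
        self.n = y.size
        self.priors = priors
        self.settings = settings
        self.rng = rng
        spec = design.spec

        alpha0 = float(np.log(self.y.sum() / np.exp(log_e).sum()))
        self.alpha = alpha0 + 0.05 * rng.standard_normal()
        self.beta = {name: 0.0 for name in design.x} if spec.effect_form == "linear" else {}
        self.theta_sp = {
            name: np.zeros(sb.n_free) for name, sb in design.splines.items()
        }
        self.theta_rw = {
            name: np.zeros(rw.n_bins) for name, rw in design.rw1s.items()
        }
        self.tau_sp = {name: 1.0 for name in design.splines}
        self.tau_rw = {name: 10.0 for name in design.rw1s}

        # crude data-driven starting values keep the precision Gibbs steps
        # from freezing the random effects at zero
        resid = np.log((self.y + 0.5) / (np.exp(log_e) * np.exp(alpha0)))
        self.s = np.zeros(self.n)
        self.h = np.zeros(self.n)
        self.tau_s = 10.0
        self.tau_h = 10.0
        if spec.has_spatial:
            smooth = 0.5 * (resid + design.adj @ resid / design.deg)
            s0 = 0.5 * np.clip(smooth, -2.5, 2.5)
            s0 = s0 - s0.mean()
            self.s = s0 + 0.01 * rng.standard_normal(self.n)
            self.s -= self.s.mean()
            self.tau_s = 1.0 / max(float(self.s.var()), 1e-2)
        if spec.has_heterogeneity:
            left = resid - self.s
            self.h = 0.5 * np.clip(left, -2.0, 2.0) + 0.01 * rng.standard_normal(self.n)
            self.tau_h = 1.0 / max(float(self.h.var()), 1e-2)

        if spec.effect_form == "linear" and design.x:
            X = np.column_stack([design.x[n_] for n_ in spec.covariates])
            coefs = _iwls_poisson(
                np.column_stack([np.ones(self.n), X]),
                self.y,
                log_e + self.s + self.h,
            )
            self.alpha = float(coefs[0]) + 0.02 * rng.standard_normal()
            for k, name in enumerate(spec.covariates):
                self.beta[name] = float(coefs[1 + k]) + 0.02 * rng.standard_normal()
        elif spec.effect_form == "rw1_smooth":
            for name, rw in design.rw1s.items():
                ybin = np.bincount(rw.bin_index, weights=self.y, minlength=rw.n_bins)
                ebin = np.bincount(
                    rw.bin_index,
                    weights=np.exp(log_e + alpha0),
                    minlength=rw.n_bins,
                )
                t0 = np.where(ebin > 0, np.log((ybin + 0.5) / (ebin + 0.5)), 0.0)
                w = np.bincount(rw.bin_index, minlength=rw.n_bins).astype(float)
                t0 -= np.average(t0, weights=np.maximum(w, 1e-12))
                self.theta_rw[name] = 0.5 * t0
                self.tau_rw[name] = 1.0 / max(float(np.diff(t0).var()), 1e-2)

        # proposal scales (adapted during burn-in)
        self.sc_alpha = 0.05
        self.sc_beta = {name: 0.05 for name in self.beta}
        self.sc_theta_sp = {name: 0.05 * np.ones(v.size) for name, v in self.theta_sp.items()}
        self.sc_theta_rw = {name: 0.3 * np.ones(v.size) for name, v in self.theta_rw.items()}
        self.sc_s = 0.5 * np.ones(self.n)
        self.sc_h = 0.5 * np.ones(self.n)

        self.acc: dict[str, float] = {}
        self.try_: dict[str, float] = {}

        self.eta = self._full_eta()
        self.w = np.exp(self.eta)

    # -- linear predictor --------------------------------------------------

    def _fixed_contrib(self) -> np.ndarray:
        out = np.full(self.n, self.alpha)
        for name, b in self.beta.items():
            out += b * self.d.x[name]
        for name, th in self.theta_sp.items():
            out += self.d.splines[name].basis @ th
        for name, th in self.theta_rw.items():
            out += th[self.d.rw1s[name].bin_index]
        return out

    def _full_eta(self) -> np.ndarray:
        return self.log_e + self._fixed_contrib() + self.s + self.h

    def _count(self, key: str, acc, ntries) -> None:
        self.acc[key] = self.acc.get(key, 0.0) + float(np.sum(acc))
        self.try_[key] = self.try_.get(key, 0.0) + float(ntries)

    # -- scalar Metropolis on a column ------------------------------------

    def _update_scalar(self, key: str, value: float, scale: float,
                       col: np.ndarray | None, prior_prec: float,
                       prior_center: float = 0.0) -> tuple[float, bool]:
        d = scale * self.rng.standard_normal()
        if col is None:  # intercept: column of ones
            delta_ll = d * self.y.sum() - (np.exp(d) - 1.0) * self.w.sum()
        else:
            fac = np.exp(d * col)
            delta_ll = d * float(self.y @ col) - float(self.w @ (fac - 1.0))
        new = value + d
        delta_pr = -0.5 * prior_prec * (
            (new - prior_center) ** 2 - (value - prior_center) ** 2
        )
        if np.log(self.rng.random()) < delta_ll + delta_pr:
            if col is None:
                self.eta += d
                self.w *= np.exp(d)
            else:
                self.eta += d * col
                self.w *= fac
            self._count(key, 1, 1)
            return new, True
        self._count(key, 0, 1)
        return value, False

    # -- sweeps ------------------------------------------------------------

    def sweep(self) -> None:
        pr = self.priors
        self.alpha, _ = self._update_scalar(
            "alpha", self.alpha, self.sc_alpha, None, pr.fixed_effect_precision
        )
        for name in self.beta:
            self.beta[name], _ = self._update_scalar(
                f"beta_{name}", self.beta[name], self.sc_beta[name],
                self.d.x[name], pr.fixed_effect_precision,
            )
        for name, th in self.theta_sp.items():
            B = self.d.splines[name].basis
            tau = self.tau_sp[name]
            for j in range(th.size):
                d = self.sc_theta_sp[name][j] * self.rng.standard_normal()
                col = B[:, j]
                fac = np.exp(d * col)
                delta_ll = d * float(self.y @ col) - float(self.w @ (fac - 1.0))
                delta_pr = -0.5 * tau * ((th[j] + d) ** 2 - th[j] ** 2)
                if np.log(self.rng.random()) < delta_ll + delta_pr:
                    th[j] += d
                    self.eta += d * col
                    self.w *= fac
                    self._count(f"spline_{name}", 1, 1)
                else:
                    self._count(f"spline_{name}", 0, 1)
        for name in self.theta_rw:
            self._update_rw1(name)
        if self.d.spec.has_spatial:
            self._update_s()
        if self.d.spec.has_heterogeneity:
            self._update_h()
        self._update_precisions()

    def _update_rw1(self, name: str) -> None:
        rw = self.d.rw1s[name]
        th = self.theta_rw[name]
        tau = self.tau_rw[name]
        m = rw.n_bins
        ybin = getattr(self, f"_ybin_{name}", None)
        if ybin is None:
            ybin = np.bincount(rw.bin_index, weights=self.y, minlength=m)
            setattr(self, f"_ybin_{name}", ybin)
            setattr(
                self,
                f"_nbin_{name}",
                np.bincount(rw.bin_index, minlength=m).astype(float),
            )
        for parity in (0, 1):
            idx = np.arange(parity, m, 2)
            wbin = np.bincount(rw.bin_index, weights=self.w, minlength=m)
            d = self.sc_theta_rw[name][idx] * self.rng.standard_normal(idx.size)
            delta_ll = d * ybin[idx] - wbin[idx] * (np.exp(d) - 1.0)
            # RW1 prior: neighbours of an even bin are odd bins (fixed here)
            delta_pr = np.zeros(idx.size)
            new = th[idx] + d
            has_left = idx > 0
            has_right = idx < m - 1
            left = th[np.maximum(idx - 1, 0)]
            right = th[np.minimum(idx + 1, m - 1)]
            delta_pr -= 0.5 * tau * has_left * ((new - left) ** 2 - (th[idx] - left) ** 2)
            delta_pr -= 0.5 * tau * has_right * ((new - right) ** 2 - (th[idx] - right) ** 2)
            acc = np.log(self.rng.random(idx.size)) < delta_ll + delta_pr
            accepted = idx[acc]
            if accepted.size:
                th[accepted] += d[acc]
                change = np.zeros(m)
                change[accepted] = d[acc]
                delta_eta = change[rw.bin_index]
                nz = delta_eta != 0
                self.eta[nz] += delta_eta[nz]
                self.w[nz] = np.exp(self.eta[nz])
            self._count(f"rw1_{name}", acc.sum(), idx.size)
        # recentre (area-weighted) into the intercept
        nbin = getattr(self, f"_nbin_{name}")
        mu = float(np.average(th, weights=np.maximum(nbin, 1e-12)))
        th -= mu
        self.alpha += mu

    def _update_s(self) -> None:
        for cls in self.d.color_classes:
            m_nb = (self.d.adj[cls] @ self.s) / self.d.deg[cls]
            d = self.sc_s[cls] * self.rng.standard_normal(cls.size)
            new = self.s[cls] + d
            delta_ll = d * self.y[cls] - self.w[cls] * (np.exp(d) - 1.0)
            delta_pr = -0.5 * self.tau_s * self.d.deg[cls] * (
                (new - m_nb) ** 2 - (self.s[cls] - m_nb) ** 2
            )
            acc = np.log(self.rng.random(cls.size)) < delta_ll + delta_pr
            upd = cls[acc]
            self.s[upd] += d[acc]
            self.eta[upd] += d[acc]
            self.w[upd] = np.exp(self.eta[upd])
            self._count("s", acc.sum(), cls.size)
        mu = self.s.mean()
        self.s -= mu
        self.alpha += mu

    def _update_h(self) -> None:
        d = self.sc_h * self.rng.standard_normal(self.n)
        new = self.h + d
        delta_ll = d * self.y - self.w * (np.exp(d) - 1.0)
        delta_pr = -0.5 * self.tau_h * (new**2 - self.h**2)
        acc = np.log(self.rng.random(self.n)) < delta_ll + delta_pr
        self.h[acc] += d[acc]
        self.eta[acc] += d[acc]
        self.w[acc] = np.exp(self.eta[acc])
        self._count("h", acc.sum(), self.n)

    def _update_precisions(self) -> None:
        a, b = self.priors.precision_shape, self.priors.precision_rate
        g = self.rng.gamma
        if self.d.spec.has_spatial:
            quad = float(self.s @ (self.d.deg * self.s) - self.s @ (self.d.adj @ self.s))
            self.tau_s = min(g(a + 0.5 * (self.n - 1), 1.0 / (b + 0.5 * quad)), 1e7)
        if self.d.spec.has_heterogeneity:
            self.tau_h = min(g(a + 0.5 * self.n, 1.0 / (b + 0.5 * float(self.h @ self.h))), 1e7)
        for name, th in self.theta_rw.items():
            quad = float(np.sum(np.diff(th) ** 2))
            self.tau_rw[name] = min(
                g(a + 0.5 * (th.size - 1), 1.0 / (b + 0.5 * quad)), 1e7
            )
        for name, th in self.theta_sp.items():
            self.tau_sp[name] = min(
                g(a + 0.5 * th.size, 1.0 / (b + 0.5 * float(th @ th))), 1e7
            )

    # -- adaptation --------------------------------------------------------

    def adapt(self, batch: int) -> None:
        """Robbins-Monro scale adaptation toward ~0.44 acceptance."""
        gain = min(0.5, 5.0 / np.sqrt(batch + 1.0))
        for key in list(self.try_):
            if self.try_[key] == 0:
                continue
            rate = self.acc[key] / self.try_[key]
            factor = float(np.exp(gain * (rate - 0.44)))
            if key == "alpha":
                self.sc_alpha *= factor
            elif key.startswith("beta_"):
                self.sc_beta[key[5:]] *= factor
            elif key.startswith("spline_"):
                self.sc_theta_sp[key[7:]] *= factor
            elif key.startswith("rw1_"):
                self.sc_theta_rw[key[4:]] *= factor
            elif key == "s":
                self.sc_s *= factor
            elif key == "h":
                self.sc_h *= factor
        self.acc.clear()
        self.try_.clear()

    def refresh(self) -> None:
        """Recompute eta and w from state to cancel float drift."""
        self.eta = self._full_eta()
        self.w = np.exp(self.eta)

    def deviance(self) -> float:
        return -2.0 * float(
            self.y @ self.eta - self.w.sum() - gammaln(self.y + 1.0).sum()
        )


def _iwls_poisson(X: np.ndarray, y: np.ndarray, offset: np.ndarray,
                  n_iter: int = 25, ridge: float = 1e-8) -> np.ndarray:
    """Poisson-regression Newton iterations, used for starting values."""
    k = X.shape[1]
    coef = np.zeros(k)
    coef[0] = np.log(max(y.sum(), 0.5) / np.exp(offset).sum())
    for _ in range(n_iter):
        eta = offset + X @ coef
        mu = np.exp(np.clip(eta, -30, 30))
        z = eta - offset + (y - mu) / mu
        WX = X * mu[:, None]
        A = X.T @ WX + ridge * np.eye(k)
        coef_new = np.linalg.solve(A, WX.T @ z)
        if np.max(np.abs(coef_new - coef)) < 1e-10:
            coef = coef_new
            break
        coef = coef_new
    return coef


# ---------------------------------------------------------------------------
# diagnostics


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chains`` is (n_chains, n_draws); each chain is split in half before
    computing the classic between/within variance ratio.
    """
    n_chains, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    parts = chains[:, : 2 * half].reshape(n_chains * 2, half)
    means = parts.mean(axis=1)
    variances = parts.var(axis=1, ddof=1)
    W = variances.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """ESS via initial-positive-sequence autocorrelation truncation."""
    n_chains, n = chains.shape
    if n < 8:
        return float(n_chains * n)
    acov = np.zeros(n)
    for c in chains:
        x = c - c.mean()
        f = np.fft.rfft(x, 2 * n)
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += ac
    acov /= n_chains
    if acov[0] <= 0:
        return float(n_chains * n)
    rho = acov / acov[0]
    ess_sum = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        ess_sum += 2 * pair
        t += 2
    return float(n_chains * n / max(ess_sum, 1.0))


# ---------------------------------------------------------------------------
# public fitting API


def fit(
    spec: ModelSpec,
    outcomes,
    scores: Mapping[str, ConstructScore],
    lattice: AreaLattice | None = None,
    priors: PriorSpec = PriorSpec(),
    mcmc: McmcSettings = McmcSettings(),
) -> FitResult:
    """Fit one disease-mapping model by Metropolis-within-Gibbs.

    Parameters
    ----------
    spec
        The model cell: covariates, effect form, area-effect structure.
    outcomes
        An :class:`~arealrisk.synthetic_data.OutcomeTable`; censored rows
        must be removed beforehand (see the drop-before-fit policy).
    scores
        Mapping of construct name to :class:`ConstructScore`.
    lattice
        Adjacency structure; required iff the spec has spatial effects.

    Raises a :class:`ConvergenceWarning` (warning, not error) when the
    split-chain statistic of any fixed effect exceeds 1.05.
    """
    y = outcomes.observed
    e = outcomes.expected
    if outcomes.censored.any():
        raise ValueError(
            "outcome table contains censored rows; drop them before fitting"
        )
    if (e <= 0).any():
        raise ValueError("expected counts must be positive")
    n = y.size
    design = _Design(spec, scores, lattice if spec.has_spatial else lattice, n, mcmc)
    log_e = np.log(e)

    n_kept = (mcmc.n_iter - mcmc.burn_in) // mcmc.thin
    scalars: dict[str, np.ndarray] = {}
    s_draws = np.empty((mcmc.n_chains, n_kept, n), dtype=np.float32) if spec.has_spatial else None
    h_draws = np.empty((mcmc.n_chains, n_kept, n), dtype=np.float32) if spec.has_heterogeneity else None
    dev = np.empty((mcmc.n_chains, n_kept))
    eta_sum = np.zeros(n)
    rho_sum = np.zeros(n)
    s_sum_abs_max = 0.0
    acceptance: dict[str, float] = {}
    acc_tries: dict[str, float] = {}

    def record(name: str, chain_i: int, k: int, value: float) -> None:
        arr = scalars.setdefault(name, np.empty((mcmc.n_chains, n_kept)))
        arr[chain_i, k] = value

    curve_names = list(spec.covariates)
    for chain_i in range(mcmc.n_chains):
        rng = np.random.default_rng(mcmc.seed + 10_000 * chain_i + 1)
        ch = _Chain(design, y, log_e, priors, mcmc, rng)
        k = 0
        for it in range(mcmc.n_iter):
            ch.sweep()
            if it < mcmc.burn_in and (it + 1) % mcmc.adapt_interval == 0:
                ch.adapt(it // mcmc.adapt_interval)
            if (it + 1) % 500 == 0:
                ch.refresh()
            if it == mcmc.burn_in - 1:
                # reset acceptance accounting for the reporting phase
                ch.acc.clear()
                ch.try_.clear()
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                record("alpha", chain_i, k, ch.alpha)
                for name, b in ch.beta.items():
                    record(f"beta_{name}", chain_i, k, b)
                for name, th in ch.theta_sp.items():
                    for j, v in enumerate(th):
                        record(f"spline_{name}[{j}]", chain_i, k, v)
                    record(f"tau_spline_{name}", chain_i, k, ch.tau_sp[name])
                for name, th in ch.theta_rw.items():
                    record(f"tau_rw1_{name}", chain_i, k, ch.tau_rw[name])
                    arr = scalars.setdefault(
                        f"_rw1_levels_{name}",
                        np.empty((mcmc.n_chains, n_kept, th.size)),
                    )
                    arr[chain_i, k] = th
                if spec.has_spatial:
                    record("tau_spatial", chain_i, k, ch.tau_s)
                    s_draws[chain_i, k] = ch.s
                    s_sum_abs_max = max(s_sum_abs_max, abs(float(ch.s.sum())))
                if spec.has_heterogeneity:
                    record("tau_heterogeneity", chain_i, k, ch.tau_h)
                    h_draws[chain_i, k] = ch.h
                dev[chain_i, k] = ch.deviance()
                eta_sum += ch.eta
                rho_sum += np.exp(ch.eta - log_e)
                k += 1
        for key in ch.try_:
            acceptance[key] = acceptance.get(key, 0.0) + ch.acc[key]
            acc_tries[key] = acc_tries.get(key, 0.0) + ch.try_[key]

    total = mcmc.n_chains * n_kept
    eta_mean = eta_sum / total
    fitted_rho = rho_sum / total
    y_f = y.astype(np.float64)
    deviance_at_mean = -2.0 * float(
        y_f @ eta_mean - np.exp(eta_mean).sum() - gammaln(y_f + 1.0).sum()
    )

    rows, diag_rows = [], []
    for name, arr in scalars.items():
        if name.startswith("_rw1_levels_"):
            continue
        flat = arr.reshape(-1)
        qs = np.quantile(flat, _QLEVELS)
        rows.append(
            dict(
                parameter=name,
                mean=flat.mean(),
                sd=flat.std(ddof=1),
                **dict(zip(_QNAMES, qs)),
            )
        )
        diag_rows.append(
            dict(
                parameter=name,
                rhat=split_rhat(arr),
                ess=effective_sample_size(arr),
            )
        )
    summaries = pd.DataFrame(rows).set_index("parameter")
    diagnostics = pd.DataFrame(diag_rows).set_index("parameter")

    for name in summaries.index:
        if name.startswith(("alpha", "beta_")):
            rh = diagnostics.loc[name, "rhat"]
            if np.isfinite(rh) and rh > 1.05:
                warnings.warn(
                    f"split-chain statistic {rh:.3f} for {name} exceeds 1.05",
                    ConvergenceWarning,
                    stacklevel=2,
                )

    effect_curves: dict[str, EffectCurve] = {}
    for name in curve_names:
        if spec.effect_form == "linear":
            effect_curves[name] = EffectCurve(
                "linear", beta=float(summaries.loc[f"beta_{name}", "mean"])
            )
        elif spec.effect_form == "cubic_spline":
            sb = design.splines[name]
            means = np.array(
                [
                    summaries.loc[f"spline_{name}[{j}]", "mean"]
                    for j in range(sb.n_free)
                ]
            )
            effect_curves[name] = EffectCurve(
                "cubic_spline", spline=sb, levels=means
            )
        else:
            levels = scalars[f"_rw1_levels_{name}"].reshape(-1, design.rw1s[name].n_bins)
            effect_curves[name] = EffectCurve(
                "rw1_smooth", rw1=design.rw1s[name], levels=levels.mean(axis=0)
            )

    def _field_summary(draws: np.ndarray | None) -> pd.DataFrame | None:
        if draws is None:
            return None
        flat = draws.reshape(-1, n).astype(np.float64)
        qs = np.quantile(flat, _QLEVELS, axis=0)
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                **{qn: qs[i] for i, qn in enumerate(_QNAMES)},
            }
        )

    result = FitResult(
        spec=spec,
        summaries=summaries,
        effect_curves=effect_curves,
        s_summary=_field_summary(s_draws),
        h_summary=_field_summary(h_draws),
        fitted_rho=fitted_rho,
        deviance_trace=dev.reshape(-1),
        deviance_at_mean=deviance_at_mean,
        diagnostics=diagnostics,
        acceptance={
            key: acceptance[key] / acc_tries[key] for key in acceptance if acc_tries[key]
        },
        n_areas=n,
        constraint_violation=s_sum_abs_max,
    )
    return result


# ---------------------------------------------------------------------------
# DIC


def compute_dic(fit_result: FitResult) -> DICReport:
    """DIC = mean deviance + p_D, with p_D = mean(D) - D(posterior mean)."""
    if fit_result.deviance_trace.size == 0:
        raise ValueError("empty deviance trace")
    d_bar = float(fit_result.deviance_trace.mean())
    d_at_mean = float(fit_result.deviance_at_mean)
    p_d = d_bar - d_at_mean
    return DICReport(
        mean_deviance=d_bar,
        deviance_at_posterior_mean=d_at_mean,
        p_d=p_d,
        dic=d_bar + p_d,
    )


def dic_verdict(dic_a: float, dic_b: float) -> str:
    """Spiegelhalter comparison rule for a pair of DIC values.

    Differences of 3 or more favour the lower-DIC model; under 2 the
    comparison is inconclusive; the gap [2, 3) is labelled
    ``inconclusive_leaning`` (leaning toward the lower-DIC model).
    """
    delta = abs(dic_a - dic_b)
    if delta >= 3.0:
        return "favours_lower"
    if delta < 2.0:
        return "inconclusive"
    return "inconclusive_leaning"


def compare_models(reports: Mapping[str, DICReport]) -> pd.DataFrame:
    """Rank a suite of fitted models by DIC.

    Returns a table sorted ascending by DIC with each model's deviance
    decomposition, its DIC gap to the best model, and the pairwise
    verdict of that comparison.
    """
    if len(reports) < 2:
        raise ValueError("need at least two models to compare")
    df = pd.DataFrame(
        {
            "dic": {k: r.dic for k, r in reports.items()},
            "mean_deviance": {k: r.mean_deviance for k, r in reports.items()},
            "p_d": {k: r.p_d for k, r in reports.items()},
        }
    ).sort_values("dic")
    best = df["dic"].iloc[0]
    df["delta_dic"] = df["dic"] - best
    df["verdict_vs_best"] = [
        "best" if i == 0 else dic_verdict(best, d)
        for i, d in enumerate(df["dic"])
    ]
    df.index.name = "model"
    return df


def count_significant_effects(
    fit_result: FitResult, which: str = "spatial", level: float = 0.90
) -> int:
    """Count area effects whose central credible interval excludes zero.

    The field study convention is the 90% interval; 95% is also
    available from the stored quantiles.
    """
    table = {
        "spatial": fit_result.s_summary,
        "heterogeneity": fit_result.h_summary,
    }.get(which)
    if table is None:
        raise ValueError(f"fit has no {which!r} effects")
    if abs(level - 0.90) < 1e-9:
        lo, hi = table["q5"], table["q95"]
    elif abs(level - 0.95) < 1e-9:
        lo, hi = table["q2.5"], table["q97.5"]
    else:
        raise ValueError("level must be 0.90 or 0.95")
    return int(((lo > 0) | (hi < 0)).sum())
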