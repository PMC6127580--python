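"""Scikit-learn-style estimators for Bayesian animal models.

Three estimators share one surface:

* :class:`LinearAnimalModel` — single continuous (or score-coded) trait,
  y = X beta + Z alpha + e with alpha ~ N(0, A sigma_a^2), e ~ N(0, I sigma_e^2),
  flat priors on beta and on both variances.
* :class:`ThresholdAnimalModel` — single ordinal trait via the liability
  model: latent U = X beta + Z alpha + e, e ~ N(0, I) (residual variance fixed
  at 1 for identifiability), fixed thresholds cut U into K categories; the
  first interior threshold is pinned at 0.
* :class:`BivariateAnimalModel` — one ordinal and one continuous trait fitted
  jointly with genetic covariance G0 (x) A and residual covariance R0 (x) I,
  R0[cat, cat] constrained to 1.

``fit`` consumes a :class:`~pedgibbs.records.RecordSet` and a
:class:`~pedgibbs.pedigree.Pedigree`; fitted attributes carry the retained
chain (``samples_``), posterior summaries, DIC pieces, and posterior-mean
breeding values (``predict``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import ndtri
from sklearn.base import BaseEstimator

from . import _gibbs
from .design import DEFAULT_FACTORS, ModelMatrices, build_design
from .pedigree import Pedigree, a_inverse
from .records import RecordSet

__all__ = [
    "ChainSamples",
    "LinearAnimalModel",
    "ThresholdAnimalModel",
    "BivariateAnimalModel",
    "heritability",
    "genetic_correlation",
    "category_prob",
    "sample_liability",
    "solve_mme",
]

LOG2PI = np.log(2.0 * np.pi)


def heritability(sigma_a2: float, sigma_e2: float) -> float:
    """h^2 = sigma_a^2 / (sigma_a^2 + sigma_e^2)."""
    if sigma_a2 < 0 or sigma_e2 < 0:
        raise ValueError("variance components must be non-negative")
    tot = sigma_a2 + sigma_e2
    if tot == 0:
        raise ValueError("heritability undefined when both variances are zero")
    return sigma_a2 / tot


def genetic_correlation(g0) -> float:
    """r_g = G0[0,1] / sqrt(G0[0,0] * G0[1,1])."""
    g0 = np.asarray(g0, dtype=float)
    if g0[0, 0] <= 0 or g0[1, 1] <= 0:
        raise ValueError("genetic correlation undefined for zero diagonal variance")
    return g0[0, 1] / np.sqrt(g0[0, 0] * g0[1, 1])


def _full_thresholds(thresholds) -> np.ndarray:
    """Interior thresholds (t_1..t_{K-1}) -> full vector with +-inf ends."""
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or np.any(np.diff(t) <= 0):
        raise ValueError("interior thresholds must be strictly increasing")
    return np.concatenate([[-np.inf], t, [np.inf]])


def category_prob(eta: float, thresholds, j: int, sigma_e: float = 1.0) -> float:
    """P(y = j | eta, t) = Phi((t_j - eta)/sigma_e) - Phi((t_{j-1} - eta)/sigma_e).

    ``thresholds`` are the K-1 interior thresholds of a K-category trait;
    categories are 1..K.
    """
    from scipy.stats import norm

    t = _full_thresholds(thresholds)
    k = len(t) - 1
    if not 1 <= j <= k:
        raise ValueError(f"category {j} outside 1..{k}")
    return float(norm.cdf((t[j] - eta) / sigma_e) - norm.cdf((t[j - 1] - eta) / sigma_e))


def sample_liability(eta: float, thresholds, j: int, rng=None, sigma_e: float = 1.0) -> float:
    """Draw the latent liability U ~ N(eta, sigma_e^2) truncated to category j's
    interval (t_{j-1}, t_j]."""
    from scipy.stats import truncnorm

    t = _full_thresholds(thresholds)
    k = len(t) - 1
    if not 1 <= j <= k:
        raise ValueError(f"category {j} outside 1..{k}")
    lo, hi = t[j - 1], t[j]
    if not lo < hi:
        raise ValueError("zero-width liability interval")
    rng = np.random.default_rng(rng)
    a, b = (lo - eta) / sigma_e, (hi - eta) / sigma_e
    return float(truncnorm.rvs(a, b, loc=eta, scale=sigma_e, random_state=rng))


def _check_chain(n_cycles: int, burn_in: int, thin: int) -> int:
    if burn_in < 0 or n_cycles <= burn_in:
        raise ValueError("need n_cycles > burn_in >= 0")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    if (n_cycles - burn_in) % thin != 0:
        raise ValueError("(n_cycles - burn_in) must be divisible by thin")
    return (n_cycles - burn_in) // thin


@dataclass
class ChainSamples:
    """Retained post-burn-in, thinned Gibbs draws plus chain metadata."""

    draws: pd.DataFrame
    n_cycles: int
    burn_in: int
    thin: int
    seed: int

    @property
    def n_retained(self) -> int:
        return len(self.draws)

    def to_csv(self, path) -> None:
        """Write draws as CSV with a YAML metadata sidecar (`<path>.meta.yaml`)."""
        import yaml

        self.draws.to_csv(path, index=False)
        meta = {
            "n_cycles": int(self.n_cycles),
            "burn_in": int(self.burn_in),
            "thin": int(self.thin),
            "seed": int(self.seed),
            "n_retained": int(self.n_retained),
            "columns": list(self.draws.columns),
        }
        with open(f"{path}.meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)


def _anim_csr(mm: ModelMatrices):
    zc = mm.Z.tocsc()
    return zc.indptr.astype(np.int64), zc.indices.astype(np.int64)


def _ainv_arrays(ped: Pedigree):
    ai = a_inverse(ped)
    return ai.indptr.astype(np.int64), ai.indices.astype(np.int64), ai.data.astype(np.float64)


def _threshold_init(ycat: np.ndarray, K: int) -> np.ndarray:
    """Initial interior thresholds from empirical cumulative frequencies,
    shifted so t_1 = 0."""
    counts = np.bincount(ycat, minlength=K + 1)[1:]
    if np.any(counts == 0):
        empty = [j + 1 for j in range(K) if counts[j] == 0]
        raise ValueError(
            f"categories {empty} unobserved; merge adjacent categories before fitting"
        )
    cum = np.cumsum(counts)[:-1] / counts.sum()
    raw = ndtri(cum)
    return raw - raw[0]


class _AnimalModelBase(BaseEstimator):
    def __init__(
        self,
        factors=DEFAULT_FACTORS,
        n_cycles: int = 20_000,
        burn_in: int = 10_000,
        thin: int = 10,
        seed: int = 0,
        prior_df: float = -2.0,
        start_h2: float = 0.5,
    ):
        self.factors = factors
        self.n_cycles = n_cycles
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.prior_df = prior_df
        self.start_h2 = start_h2

    # -- shared plumbing ---------------------------------------------------
    def _prepare(self, records: RecordSet, ped: Pedigree, trait: str):
        m = _check_chain(self.n_cycles, self.burn_in, self.thin)
        mm = build_design(records, ped, factors=tuple(self.factors), trait=trait)
        return m, mm

    def _finalize_common(self, mm: ModelMatrices, ped: Pedigree, beta_sum, alpha_sum, kept):
        self.beta_mean_ = beta_sum / kept
        self.ebv_ = pd.Series(alpha_sum / kept, index=ped.labels, name="ebv")
        self.column_names_ = list(mm.column_names)
        self.n_records_ = mm.n_records
        self.n_animals_ = mm.n_animals
        self.trait_ = mm.trait

    def predict(self, animal_labels=None) -> pd.Series:
        """Posterior-mean breeding values, for all pedigree animals or a subset."""
        if not hasattr(self, "ebv_"):
            raise RuntimeError("call fit first")
        if animal_labels is None:
            return self.ebv_
        return self.ebv_.loc[list(animal_labels)]


class LinearAnimalModel(_AnimalModelBase):
    """Single-trait linear animal model fitted by single-site Gibbs sampling."""

    def fit(self, records: RecordSet, ped: Pedigree, trait: str):
        m, mm = self._prepare(records, ped, trait)
        n_anim = mm.n_animals
        if n_anim + self.prior_df <= 0:
            raise ValueError("pedigree too small for the flat variance prior")
        anim_indptr, anim_recs = _anim_csr(mm)
        ai_indptr, ai_indices, ai_data = _ainv_arrays(ped)

        vary = float(np.var(mm.y))
        if vary == 0.0:
            vary = 1.0
        sa2_0 = max(self.start_h2 * vary, 1e-6)
        se2_0 = max((1.0 - self.start_h2) * vary, 1e-6)

        out, beta_sum, alpha_sum, kept, err = _gibbs.linear_kernel(
            np.ascontiguousarray(mm.y, dtype=np.float64),
            mm.col_indptr.astype(np.int64),
            mm.col_recs.astype(np.int64),
            mm.xtx_diag.astype(np.float64),
            anim_indptr,
            anim_recs,
            ai_indptr,
            ai_indices,
            ai_data,
            int(self.n_cycles),
            int(self.burn_in),
            int(self.thin),
            int(self.seed) % (2**31),
            float(self.prior_df),
            float(self.prior_df),
            sa2_0,
            se2_0,
        )
        if err >= 0:
            raise RuntimeError(f"non-finite Gibbs state at cycle {err}")
        assert kept == m

        draws = pd.DataFrame(out, columns=["sigma_a2", "sigma_e2", "loglik"])
        draws["h2"] = draws["sigma_a2"] / (draws["sigma_a2"] + draws["sigma_e2"])
        draws["deviance"] = -2.0 * draws["loglik"]
        self.samples_ = ChainSamples(draws, self.n_cycles, self.burn_in, self.thin, self.seed)
        self._finalize_common(mm, ped, beta_sum, alpha_sum, kept)

        self.sigma_a2_mean_ = float(draws["sigma_a2"].mean())
        self.sigma_e2_mean_ = float(draws["sigma_e2"].mean())
        self.h2_mean_ = float(draws["h2"].mean())
        self.loglik_draws_ = draws["loglik"].to_numpy()

        # deviance at posterior means, for DIC
        eta = mm.X @ self.beta_mean_ + self.ebv_.to_numpy()[mm.animal_index]
        resid = mm.y - eta
        self.deviance_at_mean_ = float(
            mm.n_records * (LOG2PI + np.log(self.sigma_e2_mean_))
            + np.sum(resid**2) / self.sigma_e2_mean_
        )
        from .compare import dic

        self.dic_, self.p_d_, self.dbar_ = dic(
            draws["deviance"].to_numpy(), self.deviance_at_mean_
        )
        return self


class ThresholdAnimalModel(_AnimalModelBase):
    """Single ordinal trait via the liability (threshold) animal model.

    Identification (K >= 3 categories): by default all thresholds are fixed
    at the probit quantiles of the observed category frequencies (t_1 = 0)
    and the liability residual variance is estimated — the scheme of the
    THRGIBBS1F90 family, which keeps flat priors proper.  Setting
    ``sample_thresholds=True`` switches to the Albert-Chib scheme
    (sigma_e^2 = 1, interior thresholds sampled from uniform conditionals);
    that scheme can drift along a scale-expansion ridge when the fixed-effect
    classes nearly separate the categories, so it is not the default.  Binary
    traits always use sigma_e^2 = 1.
    """

    def __init__(
        self,
        factors=DEFAULT_FACTORS,
        n_cycles: int = 20_000,
        burn_in: int = 10_000,
        thin: int = 10,
        seed: int = 0,
        prior_df: float = -2.0,
        start_h2: float = 0.5,
        sample_thresholds: bool = False,
    ):
        super().__init__(factors, n_cycles, burn_in, thin, seed, prior_df, start_h2)
        self.sample_thresholds = sample_thresholds

    def fit(self, records: RecordSet, ped: Pedigree, trait: str):
        m, mm = self._prepare(records, ped, trait)
        if mm.ordinal_k is None:
            raise ValueError(
                f"trait {trait!r} is not declared ordinal; pass ordinal_traits "
                "when building the RecordSet"
            )
        K = mm.ordinal_k
        ycat = mm.y.astype(np.int64)
        t_init = _threshold_init(ycat, K)
        if mm.n_animals + self.prior_df <= 0:
            raise ValueError("pedigree too small for the flat variance prior")
        anim_indptr, anim_recs = _anim_csr(mm)
        ai_indptr, ai_indices, ai_data = _ainv_arrays(ped)

        h0 = min(max(self.start_h2, 0.05), 0.9)
        if K > 2 and not self.sample_thresholds:
            # probit-quantile thresholds give the marginal liability unit
            # variance, so start from a unit phenotypic split
            sa2_0, se2_0 = h0, 1.0 - h0
        else:
            sa2_0, se2_0 = h0 / (1.0 - h0), 1.0

        out, out_t, beta_sum, alpha_sum, t_sum, kept, err = _gibbs.threshold_kernel(
            ycat,
            mm.col_indptr.astype(np.int64),
            mm.col_recs.astype(np.int64),
            mm.xtx_diag.astype(np.float64),
            anim_indptr,
            anim_recs,
            ai_indptr,
            ai_indices,
            ai_data,
            int(K),
            t_init.astype(np.float64),
            int(self.n_cycles),
            int(self.burn_in),
            int(self.thin),
            int(self.seed) % (2**31),
            float(self.prior_df),
            float(self.prior_df),
            sa2_0,
            se2_0,
            bool(self.sample_thresholds),
        )
        if err >= 0:
            raise RuntimeError(f"non-finite Gibbs state at cycle {err}")
        assert kept == m

        draws = pd.DataFrame(out, columns=["sigma_a2", "sigma_e2", "h2", "loglik"])
        if self.sample_thresholds:
            for j in range(2, K):
                draws[f"t{j}"] = out_t[:, j - 2]
        draws["deviance"] = -2.0 * draws["loglik"]
        self.samples_ = ChainSamples(draws, self.n_cycles, self.burn_in, self.thin, self.seed)
        self._finalize_common(mm, ped, beta_sum, alpha_sum, kept)

        self.k_ = K
        self.sigma_a2_mean_ = float(draws["sigma_a2"].mean())
        self.sigma_e2_mean_ = float(draws["sigma_e2"].mean())
        self.h2_mean_ = float(draws["h2"].mean())
        self.loglik_draws_ = draws["loglik"].to_numpy()
        t_mean = t_sum / kept
        t_mean[0] = -np.inf
        t_mean[K] = np.inf
        self.thresholds_mean_ = t_mean

        eta = mm.X @ self.beta_mean_ + self.ebv_.to_numpy()[mm.animal_index]
        sd = np.sqrt(self.sigma_e2_mean_)
        lo = t_mean[ycat - 1]
        hi = t_mean[ycat]
        from scipy.stats import norm

        prob = np.clip(norm.cdf((hi - eta) / sd) - norm.cdf((lo - eta) / sd), 1e-300, None)
        self.deviance_at_mean_ = float(-2.0 * np.sum(np.log(prob)))
        from .compare import dic

        self.dic_, self.p_d_, self.dbar_ = dic(
            draws["deviance"].to_numpy(), self.deviance_at_mean_
        )
        return self


class BivariateAnimalModel(_AnimalModelBase):
    """One ordinal plus one continuous trait fitted jointly.

    Only animals with both traits observed enter the analysis.  The ordinal
    trait needs K >= 3 categories: its thresholds are fixed at probit
    quantiles of the category frequencies (t_1 = 0), which pins the liability
    scale so the full 2x2 residual covariance R0 is estimable alongside the
    genetic covariance G0.  The retained chain carries g11, g12, g22, r11,
    r12, r22, the genetic correlation ``rg`` and both heritabilities; trait
    index 0 is the ordinal trait.
    """

    def __init__(
        self,
        factors=DEFAULT_FACTORS,
        n_cycles: int = 20_000,
        burn_in: int = 10_000,
        thin: int = 10,
        seed: int = 0,
        prior_df: float = -3.0,
        start_h2: float = 0.5,
    ):
        super().__init__(factors, n_cycles, burn_in, thin, seed, prior_df, start_h2)

    def fit(self, records: RecordSet, ped: Pedigree, traits: tuple[str, str]):
        cat_trait, cont_trait = traits
        if cat_trait not in records.ordinal_traits:
            raise ValueError(f"first trait {cat_trait!r} must be declared ordinal")
        m = _check_chain(self.n_cycles, self.burn_in, self.thin)

        both = records.data[cat_trait].notna() & records.data[cont_trait].notna()
        sub = RecordSet(
            records.data.loc[both].drop(columns=["cg"], errors="ignore").reset_index(drop=True),
            ordinal_traits=dict(records.ordinal_traits),
        )
        mm = build_design(sub, ped, factors=tuple(self.factors), trait=cat_trait)
        ycat = mm.y.astype(np.int64)
        ycont = sub.data[cont_trait].to_numpy(dtype=np.float64)
        K = mm.ordinal_k
        if K < 3:
            raise ValueError(
                "the bivariate sampler needs an ordinal trait with >= 3 "
                "categories (fixed thresholds identify the liability scale)"
            )
        t_init = _threshold_init(ycat, K)
        anim_indptr, anim_recs = _anim_csr(mm)
        ai_indptr, ai_indices, ai_data = _ainv_arrays(ped)

        varc = float(np.var(ycont))
        if varc == 0.0:
            varc = 1.0
        out, kept, err, jitter = _gibbs.bivariate_kernel(
            np.ascontiguousarray(ycont),
            ycat,
            mm.col_indptr.astype(np.int64),
            mm.col_recs.astype(np.int64),
            mm.xtx_diag.astype(np.float64),
            anim_indptr,
            anim_recs,
            ai_indptr,
            ai_indices,
            ai_data,
            int(K),
            t_init.astype(np.float64),
            int(self.n_cycles),
            int(self.burn_in),
            int(self.thin),
            int(self.seed) % (2**31),
            float(self.prior_df),
            0.5,
            0.5 * varc,
            0.5,
            0.5 * varc,
        )
        if err >= 0:
            raise RuntimeError(f"non-finite Gibbs state at cycle {err}")
        assert kept == m

        cols = ["g11", "g12", "g22", "r11", "r12", "r22", "rg", "h2_cat", "h2_cont"]
        draws = pd.DataFrame(out, columns=cols)
        self.samples_ = ChainSamples(draws, self.n_cycles, self.burn_in, self.thin, self.seed)
        self.thresholds_ = np.concatenate([[-np.inf], t_init, [np.inf]])

        self.traits_ = (cat_trait, cont_trait)
        self.k_ = K
        self.n_records_ = mm.n_records
        self.n_animals_ = mm.n_animals
        self.jitter_count_ = int(jitter)
        self.g0_mean_ = np.array(
            [
                [draws["g11"].mean(), draws["g12"].mean()],
                [draws["g12"].mean(), draws["g22"].mean()],
            ]
        )
        self.r0_mean_ = np.array(
            [
                [draws["r11"].mean(), draws["r12"].mean()],
                [draws["r12"].mean(), draws["r22"].mean()],
            ]
        )
        self.rg_mean_ = float(draws["rg"].mean())
        self.h2_cat_mean_ = float(draws["h2_cat"].mean())
        self.h2_cont_mean_ = float(draws["h2_cont"].mean())
        return self

    def predict(self, animal_labels=None):  # pragma: no cover - not meaningful here
        raise NotImplementedError(
            "per-draw breeding values are not retained by the bivariate sampler"
        )


def solve_mme(mm: ModelMatrices, ainv: sparse.spmatrix, lam: float):
    """Exact mixed-model-equation solve at a fixed variance ratio.

    Returns (beta_hat, alpha_hat) solving
    [X'X, X'Z; Z'X, Z'Z + lam * A^-1] [beta; alpha] = [X'y; Z'y].
    With flat priors this is the posterior mode of the location effects given
    the variances; used to validate the Gibbs conditionals on toy data.
    """
    X, Z, y = mm.X, mm.Z, mm.y
    top = sparse.hstack([X.T @ X, X.T @ Z])
    bot = sparse.hstack([Z.T @ X, Z.T @ Z + lam * ainv])
    C = sparse.vstack([top, bot]).tocsc()
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    sol = sparse.linalg.spsolve(C, rhs)
    p = X.shape[1]
    return sol[:p], sol[p:]
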