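"""Synthetic pedigrees and records with the structure the analysis assumes.

The default configuration emulates a small goat breeding study: a pedigree
of roughly 793 animals over founders plus four overlapping generations, 385
of which carry records; two ordinal traits — body condition score (BCS,
5 categories) and rib-eye marbling (MRE, 6 categories) — generated from the
liability model, and five continuous anchors (rib-eye area, sternal fat
thickness, hip height, leg perimeter, body weight); fixed effects CG
(farm x birth year x sex), collection year (YC), age class (AC, 3 levels)
and animal category (CAT, 3 levels).

Breeding values are simulated by gene dropping: founders draw from
N(0, G0), non-founders take the parent average plus a Mendelian deviate with
variance (1/2 - (F_s + F_d)/4) G0, so the realized covariance follows
G0 (x) A including inbreeding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree, inbreeding
from .records import RecordSet

__all__ = [
    "TraitSpec",
    "SimConfig",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_records",
    "simulate_study",
]


@dataclass
class TraitSpec:
    """One simulated trait.

    For an ordinal trait (``n_categories`` set) the liability has residual
    variance 1, additive variance h2/(1-h2), intercept ``mean`` on the
    liability scale and interior thresholds starting at 0.  For a continuous
    trait the phenotypic variance is split as h2 / (1-h2).
    """

    name: str
    h2: float
    mean: float = 0.0
    phenotypic_var: float = 1.0
    n_categories: int | None = None
    thresholds: tuple | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if self.n_categories is not None:
            if self.thresholds is None:
                # evenly spaced interior thresholds starting at 0
                self.thresholds = tuple(0.9 * j for j in range(self.n_categories - 1))
            if list(self.thresholds) != sorted(self.thresholds) or len(
                set(self.thresholds)
            ) != len(self.thresholds):
                raise ValueError("thresholds must be strictly increasing")
            if len(self.thresholds) != self.n_categories - 1:
                raise ValueError("need K-1 interior thresholds")

    @property
    def is_ordinal(self) -> bool:
        return self.n_categories is not None

    @property
    def sigma_a2(self) -> float:
        if self.is_ordinal:
            return self.h2 / (1.0 - self.h2) if self.h2 < 1 else np.inf
        return self.h2 * self.phenotypic_var

    @property
    def sigma_e2(self) -> float:
        if self.is_ordinal:
            return 1.0
        return (1.0 - self.h2) * self.phenotypic_var


def _default_traits() -> list:
    return [
        TraitSpec("bcs", h2=0.13, mean=1.35, n_categories=5),
        TraitSpec("mre", h2=0.09, mean=1.30, n_categories=6, thresholds=(0.0, 0.7, 1.4, 2.1, 2.8)),
        TraitSpec("rea", h2=0.28, mean=8.0, phenotypic_var=2.82),
        TraitSpec("fts", h2=0.24, mean=2.5, phenotypic_var=2.32),
        TraitSpec("hh", h2=0.32, mean=70.0, phenotypic_var=12.20),
        TraitSpec("lp", h2=0.41, mean=30.0, phenotypic_var=16.30),
        TraitSpec("weight", h2=0.54, mean=45.0, phenotypic_var=115.01),
    ]


def _default_genetic_corr() -> dict:
    # low-to-moderate positive genetic associations between the score traits
    # and the continuous anchors, strongest for marbling vs. fat / frame size
    return {
        ("bcs", "mre"): 0.58,
        ("mre", "rea"): 0.03,
        ("mre", "fts"): 0.58,
        ("mre", "hh"): 0.88,
        ("mre", "lp"): 0.03,
        ("mre", "weight"): 0.13,
        ("bcs", "rea"): 0.32,
        ("bcs", "fts"): 0.04,
        ("bcs", "hh"): 0.0,
        ("bcs", "lp"): 0.09,
        ("bcs", "weight"): 0.30,
    }


@dataclass
class SimConfig:
    n_founders: int = 93
    n_generations: int = 4
    n_per_generation: int = 175
    n_recorded: int = 385
    n_farms: int = 4
    base_year: int = 2008
    collection_years: tuple = (2012, 2013, 2014)
    traits: list = field(default_factory=_default_traits)
    genetic_corr: dict = field(default_factory=_default_genetic_corr)
    fixed_effect_scale: float = 0.5  # fixed-effect contrasts, in residual SDs
    seed: int = 0

    @property
    def n_pedigree_target(self) -> int:
        return self.n_founders + self.n_generations * self.n_per_generation

    def trait(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(name)

    def g0(self, names=None) -> np.ndarray:
        """Additive-genetic covariance matrix over the named traits.

        Off-diagonals come from the configured genetic correlations; if the
        assembled matrix is not positive definite its eigenvalues are clipped
        at a small positive floor and the matrix rescaled back to the target
        variances.
        """
        names = [t.name for t in self.traits] if names is None else list(names)
        sd = np.array([np.sqrt(self.trait(n).sigma_a2) for n in names])
        corr = np.eye(len(names))
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if i < j:
                    r = self.genetic_corr.get((a, b), self.genetic_corr.get((b, a), 0.0))
                    corr[i, j] = corr[j, i] = r
        w, v = np.linalg.eigh(corr)
        if w.min() < 1e-8:
            w = np.clip(w, 1e-8, None)
            corr = v @ np.diag(w) @ v.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
        return corr * np.outer(sd, sd)


def simulate_pedigree(cfg: SimConfig, rng=None) -> Pedigree:
    """Random-mating multi-generation pedigree, topologically ordered.

    Sires and dams for each generation are drawn from the previous one
    (founders for generation 1); selfing is impossible (parents have opposite
    sex), full-sib matings are allowed.  Sex and generation are attached to
    the returned pedigree as ``sex`` / ``generation`` arrays.
    """
    if cfg.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    n_total = cfg.n_pedigree_target

    sire = np.zeros(n_total, dtype=np.int64)
    dam = np.zeros(n_total, dtype=np.int64)
    sex = np.empty(n_total, dtype="U1")
    generation = np.zeros(n_total, dtype=np.int64)

    sex[: cfg.n_founders] = rng.choice(["M", "F"], size=cfg.n_founders)
    # ensure both sexes exist among founders
    if (sex[: cfg.n_founders] == "M").sum() in (0, cfg.n_founders):
        sex[0] = "M" if sex[0] == "F" else "F"

    prev = np.arange(1, cfg.n_founders + 1)
    nid = cfg.n_founders
    for g in range(1, cfg.n_generations + 1):
        males = prev[sex[prev - 1] == "M"]
        females = prev[sex[prev - 1] == "F"]
        if males.size == 0 or females.size == 0:
            raise ValueError(
                f"generation {g} has no eligible {'sires' if males.size == 0 else 'dams'}; "
                "increase n_founders"
            )
        new = []
        for _ in range(cfg.n_per_generation):
            nid += 1
            sire[nid - 1] = rng.choice(males)
            dam[nid - 1] = rng.choice(females)
            sex[nid - 1] = rng.choice(["M", "F"])
            generation[nid - 1] = g
            new.append(nid)
        prev = np.array(new)

    ped = Pedigree(sire=sire, dam=dam)
    ped.sex = sex
    ped.generation = generation
    return ped


def simulate_breeding_values(ped: Pedigree, g0, seed=None, rng=None) -> np.ndarray:
    """Gene-drop true breeding values: (N, n_traits) array."""
    g0 = np.atleast_2d(np.asarray(g0, dtype=float))
    t = g0.shape[0]
    if not np.all(np.linalg.eigvalsh(g0) >= -1e-10):
        raise ValueError("G0 must be positive semidefinite")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = ped.n_animals
    f = inbreeding(ped)
    # eigen factor handles semidefinite G0 (zero matrix gives exactly zero BVs)
    w, v = np.linalg.eigh(g0)
    chol = v * np.sqrt(np.clip(w, 0.0, None))
    bv = np.zeros((n, t))
    z = rng.standard_normal((n, t))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == 0 and d == 0:
            bv[i] = chol @ z[i]
            continue
        pa = np.zeros(t)
        mend = 1.0
        fs = f[s - 1] if s else -1.0
        fd = f[d - 1] if d else -1.0
        if s:
            pa += 0.5 * bv[s - 1]
        if d:
            pa += 0.5 * bv[d - 1]
        mend = 0.5 - 0.25 * (fs + fd)
        bv[i] = pa + np.sqrt(mend) * (chol @ z[i])
    return bv


def simulate_records(
    ped: Pedigree, bvs: np.ndarray, cfg: SimConfig, rng=None, trait_names=None
) -> RecordSet:
    """Assign records to animals and generate phenotypes.

    The recorded animals are drawn from the latest generations (the cohorts
    measured in the collection campaign); environmental factor levels are
    assigned at random with level effects spaced over +-``fixed_effect_scale``
    residual SDs.  Ordinal traits are produced by thresholding the liability.
    """
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    traits = cfg.traits if trait_names is None else [cfg.trait(n) for n in trait_names]
    bvs = np.atleast_2d(np.asarray(bvs, dtype=float))
    if bvs.shape[0] != ped.n_animals:
        raise ValueError("breeding values do not match pedigree size")
    if bvs.shape[1] != len(traits):
        raise ValueError("breeding-value columns do not match trait list")

    if not hasattr(ped, "generation"):
        ped.generation = np.zeros(ped.n_animals, dtype=np.int64)
        ped.sex = np.asarray(rng.choice(["M", "F"], size=ped.n_animals))
    gen = ped.generation
    last3 = gen >= max(gen.max() - 2, 1) if gen.max() > 0 else np.ones_like(gen, bool)
    pool = np.nonzero(last3)[0]
    if pool.size < cfg.n_recorded:
        pool = np.arange(ped.n_animals)
    if pool.size < cfg.n_recorded:
        raise ValueError("pedigree smaller than n_recorded")
    rec_idx = np.sort(rng.choice(pool, size=cfg.n_recorded, replace=False))
    nr = rec_idx.size

    farms = rng.integers(1, cfg.n_farms + 1, size=nr)
    birth_year = cfg.base_year + gen[rec_idx]
    sexes = ped.sex[rec_idx]
    yc = rng.choice(cfg.collection_years, size=nr)
    ac = rng.integers(1, 4, size=nr)
    cat = rng.choice(["pregnant", "kidding", "dry"], size=nr)

    df = pd.DataFrame(
        {
            "animal": [ped.labels[i] for i in rec_idx],
            "farm": farms,
            "birth_year": birth_year,
            "sex": sexes,
            "yc": yc,
            "ac": ac,
            "cat": cat,
        }
    )

    def factor_effects(levels, sd_e):
        levels = np.sort(np.unique(levels))
        span = cfg.fixed_effect_scale * sd_e
        vals = np.linspace(-span, span, len(levels)) if len(levels) > 1 else np.zeros(1)
        return dict(zip(levels, vals))

    ordinal = {}
    for ti, spec in enumerate(traits):
        sd_e = np.sqrt(spec.sigma_e2)
        eff = np.zeros(nr)
        cg_key = list(zip(farms, birth_year, sexes))
        for col in (pd.Series(cg_key), df["yc"], df["ac"], df["cat"]):
            mapping = factor_effects(col.to_numpy(), sd_e)
            eff += np.array([mapping[v] for v in col])
        genetic = bvs[rec_idx, ti]
        if spec.is_ordinal:
            thr = np.asarray(spec.thresholds, dtype=float)
            for attempt in range(10):
                liab = spec.mean + eff + genetic + rng.standard_normal(nr)
                codes = np.searchsorted(thr, liab) + 1
                if len(np.unique(codes)) == spec.n_categories:
                    break
                warnings.warn(
                    f"trait {spec.name!r}: empty category, resampling (attempt {attempt + 1})"
                )
            else:
                raise ValueError(
                    f"trait {spec.name!r}: could not occupy all {spec.n_categories} "
                    "categories in 10 attempts; widen thresholds or raise n_recorded"
                )
            df[spec.name] = codes
            ordinal[spec.name] = spec.n_categories
        else:
            df[spec.name] = spec.mean + eff + genetic + sd_e * rng.standard_normal(nr)

    return RecordSet(df, ordinal_traits=ordinal)


def simulate_study(cfg: SimConfig | None = None, seed: int | None = None):
    """One full synthetic dataset: (pedigree, records, true breeding values, G0)."""
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    ped = simulate_pedigree(cfg)
    g0 = cfg.g0()
    bvs = simulate_breeding_values(ped, g0, seed=cfg.seed + 7)
    recs = simulate_records(ped, bvs, cfg)
    return ped, recs, bvs, g0
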