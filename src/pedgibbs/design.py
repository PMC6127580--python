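"""Design structures for the animal model y = X beta + Z alpha + e.

``build_design`` turns a :class:`~pedgibbs.records.RecordSet` plus a
:class:`~pedgibbs.pedigree.Pedigree` into the incidence structures the
Gibbs samplers consume.  Fixed effects use full-rank treatment coding: a
global intercept plus, for each factor, indicators for all levels but the
first — with flat priors a rank-deficient X would leave individual levels
without a proper posterior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .records import RecordSet, make_contemporary_groups
from .pedigree import Pedigree

__all__ = ["ModelMatrices", "build_design"]

DEFAULT_FACTORS = ("cg", "yc", "ac", "cat")


@dataclass
class ModelMatrices:
    """Response and incidence structures for one trait.

    ``X`` has an intercept column followed by the retained (non-reference)
    level indicators of each factor, in the factor order given.  ``Z`` is the
    n x N record-to-animal incidence; animals without records simply have
    all-zero columns and their breeding values are tied in through A-inverse.
    """

    trait: str
    y: np.ndarray
    X: sparse.csr_matrix
    Z: sparse.csr_matrix
    animal_index: np.ndarray          # 0-based pedigree index per record
    level_maps: dict                  # factor -> list of level labels (index 0 = reference)
    column_names: list
    n_dropped: int = 0
    ordinal_k: int | None = None

    # kernel-facing layout -------------------------------------------------
    #: per-record retained X column indices (CSR over records)
    rec_indptr: np.ndarray = field(default=None, repr=False)
    rec_cols: np.ndarray = field(default=None, repr=False)
    #: records carrying each X column (CSR over columns)
    col_indptr: np.ndarray = field(default=None, repr=False)
    col_recs: np.ndarray = field(default=None, repr=False)
    xtx_diag: np.ndarray = field(default=None, repr=False)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def n_animals(self) -> int:
        return self.Z.shape[1]

    def __post_init__(self) -> None:
        xc = self.X.tocsc()
        self.rec_indptr = self.X.indptr.copy()
        self.rec_cols = self.X.indices.copy()
        self.col_indptr = xc.indptr.copy()
        self.col_recs = xc.indices.copy()
        self.xtx_diag = np.asarray(xc.multiply(xc).sum(axis=0)).ravel()


def build_design(
    records: RecordSet,
    ped: Pedigree,
    factors=DEFAULT_FACTORS,
    trait: str | None = None,
) -> ModelMatrices:
    """Assemble :class:`ModelMatrices` for one trait.

    Rows with a missing trait value are dropped (count kept in
    ``n_dropped``).  Factors must be a subset of {cg, yc, ac, cat}; ``cg``
    levels are formed from (farm, birth_year, sex) on the fly if absent.
    """
    if trait is None or trait not in records.data.columns:
        raise ValueError(f"trait {trait!r} not found in records")
    if trait in factors:
        raise ValueError(
            f"trait name {trait!r} collides with a fixed-effect factor; "
            "rename the trait column"
        )
    bad = [f for f in factors if f not in DEFAULT_FACTORS]
    if bad:
        raise ValueError(f"unknown factors {bad}; choose from {DEFAULT_FACTORS}")
    records.validate_against(ped)
    df = records.data
    if "cg" in factors and "cg" not in df.columns:
        make_contemporary_groups(records)
        df = records.data

    keep = df[trait].notna()
    n_dropped = int((~keep).sum())
    sub = df.loc[keep].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError(f"no records with trait {trait!r} observed")

    y = sub[trait].to_numpy(dtype=float)
    n = len(sub)

    cols = [np.ones((n, 1))]
    names = ["intercept"]
    level_maps: dict = {}
    for fac in factors:
        codes, levels = _factorize(sub[fac])
        level_maps[fac] = list(levels)
        if len(levels) < 2:
            warnings.warn(f"factor {fac!r} has a single level; absorbed into intercept")
            continue
        ind = np.zeros((n, len(levels) - 1))
        nz = codes > 0
        ind[np.nonzero(nz)[0], codes[nz] - 1] = 1.0
        cols.append(ind)
        names += [f"{fac}:{lv}" for lv in levels[1:]]
    X = sparse.csr_matrix(np.hstack(cols))

    idx = ped.index_of
    animal_index = np.array([idx[a] - 1 for a in sub["animal"]], dtype=np.int64)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), animal_index)), shape=(n, ped.n_animals)
    )

    k = records.ordinal_traits.get(trait)
    return ModelMatrices(
        trait=trait,
        y=y,
        X=X,
        Z=Z,
        animal_index=animal_index,
        level_maps=level_maps,
        column_names=names,
        n_dropped=n_dropped,
        ordinal_k=int(k) if k else None,
    )


def _factorize(s):
    codes, levels = pd.factorize(s, sort=True)
    if (codes < 0).any():
        raise ValueError(f"missing factor value in column {s.name!r}")
    return codes, levels
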