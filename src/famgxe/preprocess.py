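"""Covariate residualization and rank-based inverse-normal transform.

Analysis phenotypes are produced in two steps: the raw trait is regressed
on the fixed covariate polynomial [1, age, sex, age², sex·age, sex·age²]
and the OLS residuals are mapped to normal scores with the Blom variant of
the rank-based inverse-normal transform.  The resulting phenotype has mean
~0 and variance ~1, and the mixed models downstream then carry an
intercept-only fixed-effect design.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "covariate_design",
    "residualize_trait",
    "inverse_normal",
    "prepare_phenotype",
    "read_trait_table",
]

_SEX_MAP = {"female": 0.0, "male": 1.0, "f": 0.0, "m": 1.0, "2": 0.0, "1": 1.0,
            0: 0.0, 1: 1.0, 2: 0.0, 0.0: 0.0, 1.0: 1.0, 2.0: 0.0}


def _sex_indicator(sex) -> np.ndarray:
    out = np.empty(len(sex))
    for i, s in enumerate(sex):
        key = s.lower() if isinstance(s, str) else s
        if isinstance(key, str) and key not in _SEX_MAP:
            raise ValueError(f"unrecognized sex value {s!r}")
        out[i] = _SEX_MAP[key]
    return out


def covariate_design(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Design matrix [1, age_c, sex, age_c², sex·age_c, sex·age_c²].

    Age is centered at its sample mean before the polynomial is formed;
    this changes coefficients, not the residuals.  Sex is an indicator with
    female = 0 (residuals do not depend on the coding).
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    a = age - age.mean()
    return np.column_stack([np.ones_like(a), a, sex, a**2, sex * a, sex * a**2])


def residualize_trait(trait, age, sex) -> np.ndarray:
    """OLS residuals of the trait on the age/sex covariate polynomial.

    A rank-deficient design (e.g. a single-sex sample) has its aliased
    columns dropped with a logged warning; the residuals are unaffected by
    which basis of the column space is kept.
    """
    y = np.asarray(trait, dtype=float)
    x = covariate_design(np.asarray(age, dtype=float), _sex_indicator(np.asarray(sex)))
    if not (len(y) == x.shape[0]):
        raise ValueError("trait, age and sex must have equal lengths")
    if np.isnan(y).any() or np.isnan(x).any():
        raise ValueError("missing values must be dropped before residualization")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # greedy forward selection of a full-rank column subset
        keep: list[int] = []
        for j in range(x.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(x[:, trial]) == len(trial):
                keep.append(j)
        dropped = sorted(set(range(x.shape[1])) - set(keep))
        logger.warning(
            "covariate design rank-deficient; dropped aliased columns %s", dropped
        )
        x = x[:, keep]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def inverse_normal(values) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    Returns ``Φ⁻¹((r − 3/8) / (n + 1/4))`` where r is the average rank
    (ties share a rank, hence an identical normal score).  Strictly
    rank-preserving among distinct values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    if np.all(v == v[0]):
        raise ValueError("degenerate trait: all values identical")
    r = stats.rankdata(v, method="average")
    return stats.norm.ppf((r - 3.0 / 8.0) / (len(v) + 0.25))


def read_trait_table(path, na_token: str = "NA") -> pd.DataFrame:
    """Read a TSV phenotype/covariate/environment table with a header row."""
    df = pd.read_csv(path, sep="\t", na_values=[na_token], dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError("trait table must carry an 'id' column")
    return df


def prepare_phenotype(
    table: pd.DataFrame,
    trait: str,
    age_col: str = "age",
    sex_col: str = "sex",
    min_n: int = 30,
) -> tuple[np.ndarray, list[str]]:
    """Analysis-ready phenotype: residualize on covariates, then normalize.

    Rows missing the trait, age or sex are dropped (and logged).  Returns
    the transformed vector together with the retained ids, aligned.
    """
    for col in ("id", trait, age_col, sex_col):
        if col not in table.columns:
            raise ValueError(f"trait table lacks column {col!r}")
    sub = table[["id", trait, age_col, sex_col]].dropna()
    n_dropped = len(table) - len(sub)
    if n_dropped:
        logger.info("dropped %d rows with missing %s/%s/%s", n_dropped, trait,
                    age_col, sex_col)
    if len(sub) < min_n:
        raise ValueError(
            f"insufficient sample: {len(sub)} complete rows (< {min_n})"
        )
    resid = residualize_trait(
        sub[trait].to_numpy(), sub[age_col].to_numpy(), sub[sex_col].to_numpy()
    )
    return inverse_normal(resid), [str(s) for s in sub["id"]]
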