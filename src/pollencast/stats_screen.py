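"""Spearman rank-correlation screening of features against season characteristics.

Every feature/characteristic pair is correlated across years; only
pairs significant at the chosen level (default 0.01, two-tailed) are
retained, mirroring the per-pair screening tables of classic
aerobiological studies.  No multiple-testing correction is applied;
the number of tests performed is reported so users can judge the
family-wise risk themselves.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from pollencast.io_core import ValidationError


class ConstantInputError(ValidationError):
    """Correlation is undefined when an input has no variation."""


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    characteristic: str
    rho: float
    p: float
    n: int


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with average ranks on ties.

    The two-tailed p value comes from the t approximation with n-2
    degrees of freedom (the behaviour of the desktop statistics
    packages this reproduces).  ``exact=True`` switches to full
    permutation enumeration, available for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("spearman needs two equal-length 1-d samples")
    n = x.size
    if n < 4:
        raise ValidationError(f"spearman needs n >= 4, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ConstantInputError("spearman undefined for a constant sample")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if exact:
        if n > 10:
            raise ValidationError("exact permutation mode limited to n <= 10")
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.asarray(perm))
            count += abs(r) >= obs - 1e-12
            total += 1
        return rho, count / total
    return rho, float(p)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom)


def screen(
    features: pd.DataFrame,
    characteristics: pd.DataFrame,
    alpha: float = 0.01,
    min_years: int = 8,
) -> pd.DataFrame:
    """All pairwise Spearman correlations, retaining p < alpha.

    Years with a missing feature or characteristic are dropped
    pairwise; the per-pair n is reported.  The result carries the total
    number of tests performed in ``.attrs["n_tests"]`` and is sorted by
    characteristic, then feature column order.
    """
    common = features.index.intersection(characteristics.index)
    if common.empty:
        raise ValidationError("no common years between features and characteristics")
    if len(common) < min_years:
        raise ValidationError(
            f"screening needs >= {min_years} common years, got {len(common)}"
        )
    feats = features.loc[common]
    chars = characteristics.loc[common]
    records = []
    n_tests = 0
    for char_name in chars.columns:
        for feat_name in feats.columns:
            pair = pd.concat(
                [feats[feat_name], chars[char_name]], axis=1
            ).dropna()
            if len(pair) < 4:
                continue
            x = pair.iloc[:, 0].to_numpy()
            y = pair.iloc[:, 1].to_numpy()
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            rho, p = spearman(x, y)
            n_tests += 1
            if p < alpha:
                records.append(
                    CorrelationResult(feat_name, char_name, rho, p, len(pair))
                )
    out = pd.DataFrame(
        [r.__dict__ for r in records],
        columns=["feature", "characteristic", "rho", "p", "n"],
    )
    out.attrs["n_tests"] = n_tests
    out.attrs["alpha"] = alpha
    return out
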