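"""Ordinal agreement on TCF scores and the accompanying group tests.

The central statistic is the weighted Cohen kappa with quadratic
disagreement weights ``w_ij = (i - j)^2 / (k - 1)^2``:

    kappa = 1 - sum(w * O) / sum(w * E)

with ``O`` the observed joint proportion matrix of the two raters and
``E`` the outer product of their marginals. The p-value defaults to a
seeded permutation test (one rating vector permuted), with the
large-sample normal approximation reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingPair",
    "AgreementResult",
    "bin_tcf",
    "weighted_kappa",
    "compare_groups",
    "agreement_matrix",
]


def bin_tcf(values, bin_width: int = 1) -> np.ndarray:
    """Bin percent TCF scores to ordinal category indices.

    ``index = floor(value / bin_width)`` with the top edge (100) merged
    into the last bin, so a width of 1 keeps the raw integer-percent
    ordinal scale. The number of categories is ``ceil(100 / bin_width)``.
    """
    vals = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("TCF values must be finite")
    if vals.size and (vals.min() < 0 or vals.max() > 100):
        raise ValueError("TCF values must lie in [0, 100]")
    n_bins = int(np.ceil(100.0 / bin_width))
    idx = np.floor(vals / bin_width).astype(int)
    return np.minimum(idx, n_bins - 1)


@dataclass(frozen=True)
class RatingPair:
    """Two aligned ordinal rating vectors on a common k-category scale."""

    ratings_a: np.ndarray
    ratings_b: np.ndarray
    k: int

    def __post_init__(self) -> None:
        a = np.asarray(self.ratings_a, dtype=int)
        b = np.asarray(self.ratings_b, dtype=int)
        object.__setattr__(self, "ratings_a", a)
        object.__setattr__(self, "ratings_b", b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("rating vectors must be 1-D and the same length")
        if a.size and (min(a.min(), b.min()) < 0 or max(a.max(), b.max()) >= self.k):
            raise ValueError(f"rating indices must lie in [0, {self.k})")


@dataclass(frozen=True)
class AgreementResult:
    """A pairwise agreement statistic with its significance.

    ``kappa`` is None when the expected weighted disagreement is zero
    (both raters constant on the same category), in which case ``note``
    explains the degeneracy.
    """

    kappa: float | None
    p_value: float | None
    p_value_asymptotic: float | None
    n: int
    k: int
    weights: str = "quadratic"
    null: str = "permutation"
    n_perm: int = 0
    note: str = ""


def _weight_matrix(k: int, weights: str) -> np.ndarray:
    i, j = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weights == "quadratic":
        return (i - j) ** 2 / float((k - 1) ** 2) if k > 1 else np.zeros((k, k))
    if weights == "linear":
        return np.abs(i - j) / float(k - 1) if k > 1 else np.zeros((k, k))
    if weights == "unweighted":
        return (i != j).astype(float)
    raise ValueError(f"unknown weight scheme {weights!r}")


def _kappa_from_counts(counts: np.ndarray, w: np.ndarray) -> tuple[float | None, float]:
    n = counts.sum()
    O = counts / n
    pa = O.sum(axis=1)
    pb = O.sum(axis=0)
    E = np.outer(pa, pb)
    wE = float((w * E).sum())
    if wE == 0.0:
        return None, 0.0
    return 1.0 - float((w * O).sum()) / wE, wE


def _asymptotic_p(counts: np.ndarray, w: np.ndarray, kappa: float) -> float | None:
    """Normal-approximation p under H0 (Fleiss-Cohen-Everitt variance).

    Uses agreement weights ``v = 1 - w``; under independence
    ``var0 = [sum_ij pa_i pb_j (v_ij - (vbar_i. + vbar_.j))^2 - vbar_E^2]
    / (n (1 - vbar_E)^2)``.
    """
    n = counts.sum()
    if n < 2:
        return None
    O = counts / n
    pa = O.sum(axis=1)
    pb = O.sum(axis=0)
    v = 1.0 - w
    v_e = float(pa @ v @ pb)
    if v_e >= 1.0:
        return None
    vbar_row = v @ pb          # vbar_i.
    vbar_col = pa @ v          # vbar_.j
    term = (v - (vbar_row[:, None] + vbar_col[None, :])) ** 2
    var0 = (float((np.outer(pa, pb) * term).sum()) - v_e**2) / (
        n * (1.0 - v_e) ** 2
    )
    if var0 <= 0:
        return None
    z = kappa / np.sqrt(var0)
    return float(2.0 * stats.norm.sf(abs(z)))


def weighted_kappa(
    pair: RatingPair,
    weights: str = "quadratic",
    null: str = "permutation",
    n_perm: int = 10_000,
    seed: int = 0,
) -> AgreementResult:
    """Weighted Cohen kappa of a rating pair with a permutation p-value.

    The permutation null shuffles one rating vector with a seeded
    generator; the two-sided p-value uses the add-one estimator
    ``(1 + #{|kappa_perm| >= |kappa|}) / (n_perm + 1)``. The asymptotic
    normal p-value is always reported alongside. ``null="asymptotic"``
    skips the permutations.
    """
    a, b, k = pair.ratings_a, pair.ratings_b, pair.k
    if a.size < 2:
        raise ValueError("need at least two rated cases")
    if k < 2:
        raise ValueError("need at least two ordinal categories")
    w = _weight_matrix(k, weights)
    counts = np.zeros((k, k))
    np.add.at(counts, (a, b), 1.0)
    kappa, _ = _kappa_from_counts(counts, w)
    if kappa is None:
        return AgreementResult(
            kappa=None, p_value=None, p_value_asymptotic=None,
            n=a.size, k=k, weights=weights, null=null, n_perm=0,
            note="expected weighted disagreement is zero (constant ratings); "
                 "kappa is undefined",
        )
    p_asym = _asymptotic_p(counts, w, kappa)
    p_perm: float | None = None
    if null == "permutation":
        rng = np.random.default_rng(seed)
        w_lookup = w
        obs = abs(kappa)
        # E (hence sum wE) is permutation-invariant; only sum wO changes.
        n = a.size
        pa = counts.sum(axis=1) / n
        pb = counts.sum(axis=0) / n
        wE = float(pa @ w_lookup @ pb)
        hits = 0
        b_work = b.copy()
        for _ in range(n_perm):
            rng.shuffle(b_work)
            wO = w_lookup[a, b_work].mean()
            if abs(1.0 - wO / wE) >= obs - 1e-12:
                hits += 1
        p_perm = (1.0 + hits) / (n_perm + 1.0)
    elif null != "asymptotic":
        raise ValueError(f"unknown null procedure {null!r}")
    return AgreementResult(
        kappa=float(kappa),
        p_value=p_perm if p_perm is not None else p_asym,
        p_value_asymptotic=p_asym,
        n=int(a.size),
        k=k,
        weights=weights,
        null=null,
        n_perm=n_perm if null == "permutation" else 0,
    )


def compare_groups(sample_a, sample_b, test: str = "t") -> tuple[float, float]:
    """Two-sided group comparison: ``t``, ``mann_whitney``, or ``chi2``.

    For ``chi2`` the inputs form a contingency table (e.g. the two rows
    of an adequacy table, below/above the 20% TCF threshold) and the
    statistic is the uncorrected Pearson chi-square. For the other tests
    the inputs are the two samples of continuous scores.
    """
    if test == "chi2":
        table = np.asarray([sample_a, sample_b], dtype=float)
        if table.size == 0 or (table < 0).any():
            raise ValueError("chi2 requires a non-empty table of non-negative counts")
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p)
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if test == "t":
        res = stats.ttest_ind(a, b)
    elif test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)


def agreement_matrix(
    ratings: pd.DataFrame,
    truth: pd.Series | None = None,
    bin_width: int = 1,
    weights: str = "quadratic",
    null: str = "permutation",
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise weighted kappa over all observer columns (and vs truth).

    Returns a long-format DataFrame with one row per observer pair
    (columns: rater_a, rater_b, kappa, p_value, p_value_asymptotic, n).
    """
    k = int(np.ceil(100.0 / bin_width))
    cols = {name: bin_tcf(ratings[name].to_numpy(), bin_width) for name in ratings}
    if truth is not None:
        cols["truth"] = bin_tcf(truth.reindex(ratings.index).to_numpy(), bin_width)
    names = list(cols)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            pair = RatingPair(cols[na], cols[nb], k)
            res = weighted_kappa(
                pair, weights=weights, null=null, n_perm=n_perm, seed=seed
            )
            rows.append(
                dict(
                    rater_a=na, rater_b=nb, kappa=res.kappa,
                    p_value=res.p_value,
                    p_value_asymptotic=res.p_value_asymptotic, n=res.n,
                )
            )
    return pd.DataFrame(rows)
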