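"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: the HWE oracle
enumerates the exact conditional distribution of the heterozygote count
under random allele pairing; the LDA oracle is a plain pooled-covariance
Mahalanobis nearest-mean classifier; the forward-step oracle exhaustively
evaluates every candidate with the LDA oracle.
"""

from __future__ import annotations

from fractions import Fraction
from math import factorial

import numpy as np


def exact_hwe_p(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Exact two-sided p-value of the heterozygote-count statistic under
    random pairing of the 2N alleles (enumeration of Levene's conditional
    distribution), using the same statistic |het - n_A n_B / (2N - 1)|."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = n_ab + 2 * n_bb
    if n_a == 0 or n_b == 0:
        return Fraction(1)
    e_het = Fraction(n_a * n_b, 2 * n - 1)
    obs_dev = abs(Fraction(n_ab) - e_het)
    total = Fraction(0)
    p_extreme = Fraction(0)
    h_max = min(n_a, n_b)
    for h in range(n_a % 2, h_max + 1, 2):
        haa = (n_a - h) // 2
        hbb = (n_b - h) // 2
        prob = Fraction(
            factorial(n) * (2 ** h) * factorial(n_a) * factorial(n_b),
            factorial(haa) * factorial(h) * factorial(hbb) * factorial(2 * n),
        )
        total += prob
        if abs(Fraction(h) - e_het) >= obs_dev:
            p_extreme += prob
    assert total == 1
    return p_extreme


class OracleLDA:
    """Linear discriminant analysis via pooled-covariance Mahalanobis
    distance to class means, equal priors, ties to the earliest sorted
    class label."""

    def fit(self, x: np.ndarray, y: list[str]) -> "OracleLDA":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=object)
        self.classes_ = np.array(sorted(set(y.tolist())), dtype=object)
        k = self.classes_.size
        n, p = x.shape
        self.means_ = np.stack([x[y == c].mean(axis=0) for c in self.classes_])
        resid = x - self.means_[[np.flatnonzero(self.classes_ == c)[0] for c in y]]
        cov = resid.T @ resid / max(n - k, 1)
        self.cov_inv_ = np.linalg.pinv(cov)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d2 = np.empty((x.shape[0], self.classes_.size))
        for j, mu in enumerate(self.means_):
            diff = x - mu
            d2[:, j] = np.einsum("ij,jk,ik->i", diff, self.cov_inv_, diff)
        return self.classes_[np.argmin(np.round(d2, 9), axis=1)]

    def training_accuracy(self, x: np.ndarray, y: list[str]) -> float:
        pred = self.predict(x)
        y = np.asarray(y, dtype=object)
        return float(np.mean(pred == y))


def oracle_ssw_ssb(values: np.ndarray, y: np.ndarray) -> float:
    """Direct two-pass SSW/SSB computation."""
    values = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=object)
    grand = values.mean()
    ssw = ssb = 0.0
    for c in np.unique(y):
        grp = values[y == c]
        ssw += float(((grp - grp.mean()) ** 2).sum())
        ssb += grp.size * (grp.mean() - grand) ** 2
    return ssw / ssb if ssb > 0 else float("inf")


def exhaustive_forward_step(
    x: np.ndarray,
    y: list[str],
    feature_ids: list[str],
    current: list[int],
) -> int:
    """Index of the candidate chosen by exhaustively refitting the oracle
    classifier on current-set + each candidate; ties by minimum univariate
    SSW/SSB of the candidate, then lexicographic feature id."""
    y_arr = np.asarray(y, dtype=object)
    best = None
    for j in range(x.shape[1]):
        if j in current:
            continue
        cols = current + [j]
        acc = OracleLDA().fit(x[:, cols], y).training_accuracy(x[:, cols], y)
        ratio = oracle_ssw_ssb(x[:, j], y_arr)
        key = (-round(acc, 12), round(ratio, 12), str(feature_ids[j]))
        if best is None or key < best[0]:
            best = (key, j)
    assert best is not None
    return best[1]
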