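"""Resampling statistics for bivariate (ring, fiber) area-fraction data.

Two tools: a bootstrap of the per-condition mean vector (for visualising
the uncertainty of the mean) and a randomization test between two
conditions.  The test permutes the pooled rows into groups of the
original sizes, collects the difference-of-means cloud, fits a bivariate
normal to it and reports the chi-squared (2 df) upper-tail probability
of the Mahalanobis distance of the observed difference.  The parametric
tail is primary -- an empirical tail over 10,000 permutations can never
be exactly 0, while extremely separated data legitimately report p
values far below 1e-4 -- but the empirical tail fraction is always
reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "BootstrapResult", "RandomizationResult", "bootstrap_means",
    "randomization_test", "compare_conditions",
]


@dataclass
class BootstrapResult:
    mean_vectors: np.ndarray  # (n_rep, d)
    n_rep: int
    condition: str
    seed: int


@dataclass
class RandomizationResult:
    d_raw: np.ndarray         # mu_A - mu_B
    d_rand: np.ndarray        # (n_rep, d)
    p_value: float            # parametric (MVN / chi-squared) tail
    p_empirical: float        # (1 + #{more extreme}) / (n_rep + 1)
    n_a: int
    n_b: int
    seed: int
    degenerate: bool = False  # covariance was singular; p_value fell back


def _rows(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    return a


def bootstrap_means(
    samples,
    n_rep: int = 10_000,
    seed: int = 0,
    condition: str = "",
) -> BootstrapResult:
    """Distribution of the mean vector under resampling with replacement."""
    a = _rows(samples)
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_rep, n))
    means = a[idx].mean(axis=1)
    return BootstrapResult(mean_vectors=means, n_rep=n_rep,
                           condition=condition, seed=seed)


def randomization_test(
    a_rows,
    b_rows,
    n_rep: int = 10_000,
    seed: int = 0,
) -> RandomizationResult:
    """Permutation test on the difference of mean vectors.

    Pools both groups, reassigns rows without replacement to the original
    group sizes ``n_rep`` times, and compares the observed difference to
    the fitted multivariate-normal null cloud.
    """
    a = _rows(a_rows)
    b = _rows(b_rows)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 rows")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups have different dimensionality")
    n_a, n_b = len(a), len(b)
    d = a.shape[1]
    pooled = np.concatenate([a, b], axis=0)
    d_raw = a.mean(axis=0) - b.mean(axis=0)

    rng = np.random.default_rng(seed)
    # one permutation per replicate, independent of execution order
    keys = rng.random((n_rep, n_a + n_b))
    perm = np.argsort(keys, axis=1)
    d_rand = (pooled[perm[:, :n_a]].mean(axis=1)
              - pooled[perm[:, n_a:]].mean(axis=1))

    mu = d_rand.mean(axis=0)
    cov = np.cov(d_rand.T, ddof=0).reshape(d, d)
    degenerate = False
    try:
        cov_inv = np.linalg.inv(cov)
        cond = np.linalg.cond(cov)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned covariance")
    except np.linalg.LinAlgError:
        degenerate = True
        cov_inv = None

    if not degenerate:
        def maha(x):
            delta = x - mu
            return np.einsum("...i,ij,...j->...", delta, cov_inv, delta)
        d2_raw = float(maha(d_raw))
        d2_rand = maha(d_rand)
        p_param = float(chi2.sf(d2_raw, df=d))
    else:
        warnings.warn("degenerate permutation covariance; using empirical tail "
                      "on the Euclidean norm")
        norm_raw = float(np.linalg.norm(d_raw - mu))
        d2_raw = norm_raw
        d2_rand = np.linalg.norm(d_rand - mu, axis=1)
        p_param = None
    p_emp = float((1 + np.sum(d2_rand >= d2_raw)) / (n_rep + 1))
    return RandomizationResult(
        d_raw=d_raw, d_rand=d_rand,
        p_value=p_param if p_param is not None else p_emp,
        p_empirical=p_emp, n_a=n_a, n_b=n_b, seed=seed, degenerate=degenerate,
    )


MEASURE_COLUMNS = ["ring_area_fraction", "fiber_area_fraction"]


def compare_conditions(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    n_rep: int = 10_000,
    seed: int = 0,
    columns: list[str] = MEASURE_COLUMNS,
    bonferroni: bool = False,
) -> dict:
    """Pairwise randomization tests plus per-condition bootstrap summaries.

    No multiple-testing correction is applied by default; ``bonferroni``
    multiplies the parametric p values by the number of pairs.
    """
    present = set(table["condition"])
    for pair in pairs:
        for name in pair:
            if name not in present:
                raise KeyError(f"unknown condition {name!r}")

    groups = {
        name: table.loc[table["condition"] == name, columns].to_numpy(dtype=float)
        for name in present
    }
    for name, rows in groups.items():
        if len(rows) < 2:
            raise ValueError(f"condition {name!r} has fewer than 2 images")

    boots = {
        name: bootstrap_means(rows, n_rep=n_rep, seed=seed + 1000 + i,
                              condition=name)
        for i, (name, rows) in enumerate(sorted(groups.items()))
    }
    tests = []
    for i, (name_a, name_b) in enumerate(pairs):
        res = randomization_test(groups[name_a], groups[name_b],
                                 n_rep=n_rep, seed=seed + i)
        p = res.p_value * len(pairs) if bonferroni else res.p_value
        tests.append({
            "condition_a": name_a, "condition_b": name_b,
            "d_raw": res.d_raw.tolist(),
            "p_value": min(float(p), 1.0),
            "p_empirical": res.p_empirical,
            "n_a": res.n_a, "n_b": res.n_b,
            "degenerate": res.degenerate,
        })
    return {
        "tests": pd.DataFrame(tests),
        "bootstrap": boots,
        "n_rep": n_rep,
        "bonferroni": bonferroni,
    }
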