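"""Two-group differential expression engines.

Count layers (miRNA, isomiR, mRNA, intron-spanning reads) use a negative
binomial exact test in the edgeR tradition: counts are rescaled to a common
effective library size, group sums are modeled as NB with a shared common
dispersion, and a two-sided conditional exact p-value is computed by
minimum-likelihood ordering over all splits of the total.  Protein spectral
counts use an unpaired beta-binomial likelihood-ratio test (the design is
8-vs-11, which a paired test cannot accommodate).

Significance follows the thresholds used throughout the pipeline: count
layers require p < 0.05 AND |log2FC| > 1; the protein layer requires
p < 0.05 only.  Raw p-values are thresholded; a Benjamini-Hochberg column is
emitted for reference but never used for the flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import betaln, gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .normfilter import CountMatrix, cpm, normalize

logger = logging.getLogger("tepomics.diffexp")

ALPHA_DEFAULT = 0.05
LFC_CUT_DEFAULT = 1.0
#: pseudo-count added to group-mean CPM before the log2 ratio
LFC_PRIOR = 0.5


@dataclass
class DispersionEstimate:
    """Common NB dispersion (phi >= 0) with the estimator tag."""

    phi: float
    method: str = "moments"

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be non-negative")


@dataclass
class DEResult:
    feature: str
    layer: str
    log2fc: float
    p_value: float
    mean_a: float
    mean_b: float
    significant: bool
    direction: str  # up_A | up_B


def estimate_common_dispersion(m: CountMatrix) -> DispersionEstimate:
    """Method-of-moments common dispersion on library-size-adjusted counts.

    Counts are rescaled to the geometric-mean effective library; for each
    feature and group with positive mean, ``(s^2 - mu) / mu^2`` estimates the
    NB dispersion (variance ``mu + phi mu^2``).  The common value is the mean
    over features and groups, floored at zero.  Simpler than edgeR's qCML,
    and adequate for a shared-dispersion exact test.
    """
    counts = m.counts.to_numpy(dtype=float)
    if counts.sum() == 0:
        logger.warning("all-zero matrix; dispersion set to 0")
        return DispersionEstimate(0.0)
    libs = counts.sum(axis=0)
    if m.norm_factors is not None:
        libs = libs * m.norm_factors.to_numpy()
    common = np.exp(np.mean(np.log(libs)))
    adj = counts * (common / libs)

    vals = []
    groups = m.groups.to_numpy()
    for g in ("A", "B"):
        sub = adj[:, groups == g]
        if sub.shape[1] < 2:
            raise ValueError("need >= 2 samples per group")
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = mu > 0
        vals.append((s2[ok] - mu[ok]) / mu[ok] ** 2)
    phi = float(np.mean(np.concatenate(vals))) if vals else 0.0
    return DispersionEstimate(max(0.0, phi))


def _group_sum_logpmf(k: np.ndarray, n_samples: int, mean_total: float, phi: float) -> np.ndarray:
    """log P(sum of n iid NB(mean, phi) = k); the sum is NB(n/phi, n*mean)."""
    mu = n_samples * mean_total
    if phi <= 0:
        return stats.poisson.logpmf(k, mu)
    r = n_samples / phi
    p = r / (r + mu)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(
    a_counts: np.ndarray,
    b_counts: np.ndarray,
    lib_sizes: np.ndarray,
    phi: float,
) -> float:
    """Two-sided NB exact test on group sums after library equalization.

    Counts are linearly rescaled to the geometric-mean library and rounded
    to integers (a simplified stand-in for quantile-adjusted pseudo-counts).
    Conditional on the total S = Sa + Sb, each split (k, S-k) has probability
    proportional to the product of the two group-sum NB pmfs under H0 (equal
    per-sample means); the p-value sums the probabilities of all splits no
    more likely than the observed one.
    """
    if phi < 0:
        raise ValueError("phi must be non-negative")
    a = np.asarray(a_counts, dtype=float)
    b = np.asarray(b_counts, dtype=float)
    libs = np.asarray(lib_sizes, dtype=float)
    y = np.concatenate([a, b])
    if y.size != libs.size:
        raise ValueError("lib_sizes length must match total sample count")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(y, np.round(y)):
        raise ValueError("counts must be integers")
    if np.any(libs <= 0):
        raise ValueError("library sizes must be positive")

    common = np.exp(np.mean(np.log(libs)))
    pseudo = np.round(y * (common / libs)).astype(np.int64)
    na, nb = a.size, b.size
    sa = int(pseudo[:na].sum())
    sb = int(pseudo[na:].sum())
    total = sa + sb
    if total == 0:
        return 1.0

    mean_per_sample = total / (na + nb)
    k = np.arange(total + 1)
    lp = _group_sum_logpmf(k, na, mean_per_sample, phi) + _group_sum_logpmf(
        total - k, nb, mean_per_sample, phi
    )
    lp -= logsumexp(lp)
    # minimum-likelihood ordering with a tie tolerance for float equality
    p = float(np.exp(logsumexp(lp[lp <= lp[sa] + 1e-10])))
    return min(1.0, p)


# ---------------------------------------------------------------------------
# beta-binomial likelihood-ratio test (protein spectral counts)
# ---------------------------------------------------------------------------

def _bb_loglik(k: np.ndarray, n: np.ndarray, mu: float, rho: float) -> float:
    """Beta-binomial log likelihood; mu = mean proportion, rho = overdispersion."""
    a = mu * (1.0 - rho) / rho
    b = (1.0 - mu) * (1.0 - rho) / rho
    ll = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )
    return float(np.sum(ll))


_EPS = 1e-8


def _minimize_bounded(nll, x0, bounds) -> tuple[float, bool]:
    """L-BFGS-B with a clipped Nelder-Mead fallback for stubborn features."""
    res = optimize.minimize(nll, x0=x0, bounds=bounds, method="L-BFGS-B")
    best, ok = float(res.fun), bool(res.success)
    if not ok:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        res2 = optimize.minimize(
            lambda th: nll(np.clip(th, lo, hi)), x0=x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 2000},
        )
        if res2.success and np.isfinite(res2.fun):
            best, ok = min(best, float(res2.fun)), True
    return -best, ok


def _fit_bb_null(k: np.ndarray, n: np.ndarray) -> tuple[float, bool]:
    mu0 = min(max(k.sum() / n.sum(), _EPS), 1 - _EPS)

    def nll(theta):
        return -_bb_loglik(k, n, theta[0], theta[1])

    return _minimize_bounded(nll, [mu0, 0.01], [(_EPS, 1 - _EPS), (_EPS, 0.999)])


def _fit_bb_alt(
    k_a: np.ndarray, n_a: np.ndarray, k_b: np.ndarray, n_b: np.ndarray
) -> tuple[float, bool]:
    mu_a = min(max(k_a.sum() / n_a.sum(), _EPS), 1 - _EPS)
    mu_b = min(max(k_b.sum() / n_b.sum(), _EPS), 1 - _EPS)

    def nll(theta):
        return -(
            _bb_loglik(k_a, n_a, theta[0], theta[2])
            + _bb_loglik(k_b, n_b, theta[1], theta[2])
        )

    return _minimize_bounded(
        nll, [mu_a, mu_b, 0.01], [(_EPS, 1 - _EPS), (_EPS, 1 - _EPS), (_EPS, 0.999)]
    )


def bb_test(
    k_a: np.ndarray,
    k_b: np.ndarray,
    n_a: np.ndarray,
    n_b: np.ndarray,
) -> float:
    """Unpaired beta-binomial LRT for spectral counts.

    H0: one beta-binomial success probability for all samples; H1:
    group-specific probabilities with a shared overdispersion.  The
    likelihood-ratio statistic is referred to F(1, N - 3) rather than
    chi-square(1): with ~20 samples and an estimated overdispersion the
    chi-square reference is anticonservative, and an F reference on the
    residual degrees of freedom (the quasi-likelihood convention) restores
    the nominal level.  Returns NaN (with a log message) if either
    optimization fails.
    """
    k_a = np.asarray(k_a, dtype=float)
    k_b = np.asarray(k_b, dtype=float)
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if np.any(k_a < 0) or np.any(k_b < 0) or np.any(k_a > n_a) or np.any(k_b > n_b):
        raise ValueError("require 0 <= k <= n per sample")
    if k_a.sum() + k_b.sum() == 0:
        return 1.0

    k = np.concatenate([k_a, k_b])
    n = np.concatenate([n_a, n_b])
    ll0, ok0 = _fit_bb_null(k, n)
    ll1, ok1 = _fit_bb_alt(k_a, n_a, k_b, n_b)
    if not (ok0 and ok1):
        logger.warning("beta-binomial optimizer did not converge; p = NaN")
        return float("nan")
    lr = max(0.0, 2.0 * (ll1 - ll0))
    df2 = max(1, k.size - 3)
    return float(stats.f.sf(lr, 1, df2))


# ---------------------------------------------------------------------------
# per-layer differential tables
# ---------------------------------------------------------------------------

def _log2fc(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    return np.log2((mean_a + LFC_PRIOR) / (mean_b + LFC_PRIOR))


def differential_table(
    m: CountMatrix,
    engine: str = "nb_exact",
    alpha: float = ALPHA_DEFAULT,
    lfc_cut: float = LFC_CUT_DEFAULT,
    phi: float | None = None,
) -> pd.DataFrame:
    """Per-feature two-group DE table for one layer.

    ``engine`` is ``nb_exact`` for count layers or ``beta_binomial`` for the
    protein layer.  log2FC is group A over group B on mean normalized CPM
    with a 0.5 pseudo-count, so ``up_A`` reads as up-regulated in the
    PDAC-like group.  Rows are sorted by p-value, ties broken by descending
    |log2FC| then feature id.
    """
    if engine not in ("nb_exact", "beta_binomial"):
        raise ValueError(f"unknown engine {engine!r}")
    if len(m.features) == 0:
        return pd.DataFrame(
            columns=[
                "feature", "layer", "log2fc", "p_value", "padj",
                "mean_a", "mean_b", "direction", "significant",
            ]
        )
    a_samples = m.samples_in_group("A")
    b_samples = m.samples_in_group("B")

    if engine == "nb_exact":
        norm = normalize(m)
        if phi is None:
            phi = estimate_common_dispersion(m).phi
        libs = m.lib_sizes.astype(float)
        if m.norm_factors is not None:
            libs = libs * m.norm_factors
        eff = np.concatenate([libs[a_samples].to_numpy(), libs[b_samples].to_numpy()])
        a_mat = m.counts[a_samples].to_numpy()
        b_mat = m.counts[b_samples].to_numpy()
        pvals = np.array(
            [nb_exact_test(a_mat[i], b_mat[i], eff, phi) for i in range(len(m.features))]
        )
    else:
        norm = cpm(m)
        tot_a = m.counts[a_samples].sum(axis=0).to_numpy(dtype=float)
        tot_b = m.counts[b_samples].sum(axis=0).to_numpy(dtype=float)
        a_mat = m.counts[a_samples].to_numpy(dtype=float)
        b_mat = m.counts[b_samples].to_numpy(dtype=float)
        pvals = np.array(
            [bb_test(a_mat[i], b_mat[i], tot_a, tot_b) for i in range(len(m.features))]
        )

    mean_a = norm[a_samples].mean(axis=1).to_numpy()
    mean_b = norm[b_samples].mean(axis=1).to_numpy()
    lfc = _log2fc(mean_a, mean_b)
    with np.errstate(invalid="ignore"):
        if engine == "beta_binomial":
            sig = pvals < alpha
        else:
            sig = (pvals < alpha) & (np.abs(lfc) > lfc_cut)
    sig = np.where(np.isnan(pvals), False, sig)
    finite = ~np.isnan(pvals)
    padj = np.full_like(pvals, np.nan)
    if finite.any():
        padj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "feature": m.features,
            "layer": m.layer,
            "log2fc": lfc,
            "p_value": pvals,
            "padj": padj,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "direction": np.where(lfc >= 0, "up_A", "up_B"),
            "significant": sig,
        }
    )
    out = out.sort_values(
        by=["p_value", "log2fc", "feature"],
        key=lambda s: -s.abs() if s.name == "log2fc" else s,
        na_position="last",
    ).reset_index(drop=True)
    return out
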