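"""Count-matrix container, presence filtering and TMM normalization.

The expression layers handled by the pipeline (canonical miRNA, isomiR,
mRNA, intron-spanning reads) are non-negative integer count matrices with a
two-group design (group ``A`` = PDAC-like, group ``B`` = benign-like).  This
module provides

* counts-per-million (CPM) conversion,
* a presence filter: a feature is kept when it reaches ``min_cpm`` in
  strictly more than ``min_frac`` of all samples, with a "black and white"
  rescue for features expressed almost exclusively in one group (all-zero in
  the other group, zero in at most ``bw_max_zero_frac`` of the expressing
  group's samples),
* trimmed-mean-of-M-values (TMM) scaling factors and CPM on the resulting
  effective library sizes.

Protein spectral counts bypass CPM/TMM — their differential test conditions
on per-sample totals directly — and get a median-scaling helper for
reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("tepomics.normfilter")

VALID_LAYERS = ("mirna", "isomir", "mrna", "intron", "protein")

#: reasons emitted by :func:`presence_filter`
REASON_GLOBAL = "global"
REASON_BLACK_WHITE = "black_white"
REASON_DROPPED = "dropped"


@dataclass
class CountMatrix:
    """Features x samples counts for one omics layer plus the group design.

    Parameters
    ----------
    layer
        One of ``mirna``, ``isomir``, ``mrna``, ``intron``, ``protein``.
    counts
        Non-negative counts, features in rows, samples in columns.
    groups
        Sample -> group label (``A`` or ``B``); must cover every column.
    norm_factors
        Optional per-sample positive scaling factors with geometric mean 1
        (the TMM convention, so CPMs stay comparable across samples).
    """

    layer: str
    counts: pd.DataFrame
    groups: pd.Series
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError(f"negative counts in layer {self.layer!r}")
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[self.counts.columns]
        bad = set(self.groups.unique()) - {"A", "B"}
        if bad:
            raise ValueError(f"group labels must be 'A'/'B', got {sorted(bad)}")
        if self.norm_factors is not None:
            self.set_norm_factors(self.norm_factors)

    # -- basic accessors ---------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def set_norm_factors(self, factors: pd.Series) -> None:
        factors = factors.loc[self.counts.columns].astype(float)
        if (factors <= 0).any():
            raise ValueError("norm factors must be positive")
        gmean = float(np.exp(np.mean(np.log(factors))))
        if abs(gmean - 1.0) > 1e-9:
            raise ValueError(f"norm factors must have geometric mean 1, got {gmean}")
        self.norm_factors = factors

    def subset(self, features=None, samples=None) -> "CountMatrix":
        c = self.counts
        if features is not None:
            c = c.loc[features]
        if samples is not None:
            c = c[samples]
        nf = None
        if self.norm_factors is not None and samples is None:
            nf = self.norm_factors
        return CountMatrix(self.layer, c.copy(), self.groups.copy(), nf)


def cpm(m: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Counts per million: ``count / column_sum * 1e6`` (raw library sizes)."""
    counts = m.counts if isinstance(m, CountMatrix) else m
    libs = counts.sum(axis=0)
    zero = libs[libs <= 0]
    if len(zero):
        raise ValueError(f"zero-sum library for sample(s) {list(zero.index)}")
    return counts.div(libs, axis=1) * 1e6


def presence_filter(
    m: CountMatrix,
    min_cpm: float = 1.0,
    min_frac: float = 0.40,
    bw_max_zero_frac: float = 0.18,
    require_other_all_zero: bool = True,
) -> tuple[list, pd.Series]:
    """Apply the presence filter and the black-and-white rescue rule.

    Global rule: keep a feature with CPM >= ``min_cpm`` in *strictly more*
    than ``min_frac`` of all samples.  Black-and-white rescue: a feature
    whose counts are zero in every sample of one group ("white") while zero
    in at most ``bw_max_zero_frac`` of the other, expressing ("positive",
    "black") group is kept even if it fails the global rule.  With
    ``require_other_all_zero=False`` the non-expressing group may contain
    nonzero samples as long as all of the feature's nonzero samples are
    concentrated enough in one group — a looser reading kept behind a switch.

    Returns
    -------
    kept, reasons
        ``kept`` preserves the input feature order; ``reasons`` maps every
        feature to ``global`` / ``black_white`` / ``dropped``.
    """
    c = cpm(m)
    n = len(m.samples)
    frac = (c >= min_cpm).sum(axis=1) / n
    reasons = pd.Series(REASON_DROPPED, index=m.features, dtype=object)
    reasons[frac > min_frac] = REASON_GLOBAL

    a = m.samples_in_group("A")
    b = m.samples_in_group("B")
    counts = m.counts
    for f in m.features:
        if reasons[f] != REASON_DROPPED:
            continue
        row = counts.loc[f]
        for pos, neg in ((a, b), (b, a)):
            pos_vals = row[pos]
            neg_vals = row[neg]
            if len(pos) == 0 or (pos_vals > 0).sum() == 0:
                continue
            if require_other_all_zero and (neg_vals > 0).any():
                continue
            if not require_other_all_zero and (neg_vals > 0).sum() > (pos_vals > 0).sum():
                continue
            zero_frac = (pos_vals == 0).sum() / len(pos)
            if zero_frac <= bw_max_zero_frac:
                reasons[f] = REASON_BLACK_WHITE
                break
    kept = [f for f in m.features if reasons[f] != REASON_DROPPED]
    return kept, reasons


def _tmm_one(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    min_features: int,
) -> float:
    mask = (obs > 0) & (ref > 0)
    obs, ref = obs[mask], ref[mask]
    if obs.size < min_features:
        logger.warning("TMM: only %d shared nonzero features, factor set to 1", obs.size)
        return 1.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m_val = np.log2(p_obs / p_ref)
    a_val = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic variance of M per feature (delta method on two binomials)
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = m_val.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m_val)
    ra = rankdata(a_val)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() < min_features:
        logger.warning("TMM: only %d features survive trimming, factor set to 1", int(keep.sum()))
        return 1.0
    w = 1.0 / var[keep]
    return float(2 ** (np.sum(w * m_val[keep]) / np.sum(w)))


def tmm_factors(
    m: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    min_features: int = 10,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean of those percentiles across samples.  For each sample, over
    features nonzero in both it and the reference, the log2 ratio of library
    proportions (M) is doubly trimmed — ``trim_m`` on each M tail, ``trim_a``
    on each A (mean log2 proportion) tail — and averaged with inverse
    asymptotic-variance weights.
    """
    if len(m.samples) < 2:
        raise ValueError("TMM requires at least two samples")
    counts = m.counts.to_numpy(dtype=float)
    libs = counts.sum(axis=0)
    q75 = np.percentile(counts / libs * 1e6, 75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = counts[:, ref_idx]
    n_ref = libs[ref_idx]

    factors = np.ones(len(m.samples))
    for j in range(len(m.samples)):
        if j == ref_idx:
            factors[j] = _tmm_one(ref, ref, n_ref, n_ref, trim_m, trim_a, min_features)
        else:
            factors[j] = _tmm_one(counts[:, j], ref, libs[j], n_ref, trim_m, trim_a, min_features)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.samples, name="tmm_factor")


def normalize(
    m: CountMatrix,
    log2: bool = False,
    prior_count: float = 1.0,
) -> pd.DataFrame:
    """CPM on effective library sizes (library x TMM factor).

    With ``log2=True`` values are ``log2(CPM + prior_count)``.  Identity
    factors reduce to plain CPM; doubling every count leaves the output
    unchanged.
    """
    libs = m.lib_sizes.astype(float)
    if (libs <= 0).any():
        bad = list(libs[libs <= 0].index)
        raise ValueError(f"zero-sum library for sample(s) {bad}")
    if m.norm_factors is not None:
        libs = libs * m.norm_factors
    vals = m.counts.div(libs, axis=1) * 1e6
    if log2:
        vals = np.log2(vals + prior_count)
    return vals


def median_scale(m: CountMatrix) -> pd.DataFrame:
    """Median scaling for protein spectral counts (reporting only).

    Each sample is rescaled so its median nonzero count equals the global
    median of those medians.  The protein differential test itself works on
    raw spectral counts and per-sample totals; this output exists so protein
    tables are comparable by eye across samples.
    """
    counts = m.counts.astype(float)
    meds = counts.where(counts > 0).median(axis=0)
    if meds.isna().any():
        raise ValueError("sample with no nonzero counts")
    target = float(np.median(meds))
    return counts.div(meds, axis=1) * target
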