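"""Normalization, filtering and moderated-t differential expression.

The DE engine follows the standard bulk RNA-seq recipe: TMM scaling factors,
a CPM-based expression filter, log-CPM transformation, and a per-gene linear
model (tumor status plus ordinal Gleason score) with empirical-Bayes variance
shrinkage.  This is a moderated-t approximation of the limma pipeline on
log-CPM values; voom precision weights are intentionally not used, so
numerical parity with limma-voom is not expected (selection behaviour on
well-separated effects is).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .synthetic import CountData

__all__ = [
    "cpm",
    "filter_low_expression",
    "tmm_factors",
    "log_cpm",
    "fit_de",
    "bh_fdr",
    "select_de",
    "overlap_summary",
    "overlap_from_counts",
    "match_cohorts",
]


def cpm(counts: pd.DataFrame | CountData, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million: 1e6 * count / (library size * scaling factor)."""
    mat = counts.counts if isinstance(counts, CountData) else counts
    lib = mat.sum(axis=0).astype(float)
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    if factors is not None:
        lib = lib * pd.Series(factors, index=mat.columns)
    return mat / lib * 1e6


def filter_low_expression(
    data: CountData, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> CountData:
    """Drop genes not exceeding ``min_cpm`` CPM in at least ``min_fraction`` of samples."""
    if not 0 <= min_fraction <= 1:
        raise ValueError("min_fraction must be in [0, 1]")
    if data.counts.shape[1] == 0 or data.counts.shape[0] == 0:
        return data
    frac = (cpm(data.counts) > min_cpm).mean(axis=1)
    keep = frac >= min_fraction
    return CountData(counts=data.counts.loc[keep], sample_meta=data.sample_meta)


def _tmm_one(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
             trim_m: float, trim_a: float) -> float:
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        warnings.warn("sample shares no positive gene with reference; factor set to 1")
        return 1.0
    o = obs[pos] / n_obs
    r = ref[pos] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic (delta-method) variance of M
    w = (n_obs - obs[pos]) / (n_obs * obs[pos]) + (n_ref - ref[pos]) / (n_ref * ref[pos])
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any() or not np.isfinite(w[keep]).all():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame | CountData, trim_m: float = 0.3, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors (geometric mean 1).

    The reference sample is the one whose upper-quartile CPM is closest to
    the mean upper quartile; M and A statistics are doubly trimmed and the
    factor is 2^(inverse-variance weighted mean M).
    """
    mat = counts.counts if isinstance(counts, CountData) else counts
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = mat.sum(axis=0).astype(float).to_numpy()
    c = cpm(mat).to_numpy()
    uq = np.array([np.quantile(c[:, j][c[:, j] > 0], 0.75) if (c[:, j] > 0).any() else 0.0
                   for j in range(c.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    vals = mat.to_numpy().astype(float)
    factors = np.array([
        1.0 if j == ref_j else _tmm_one(vals[:, j], vals[:, ref_j], lib[j], lib[ref_j],
                                        trim_m, trim_a)
        for j in range(vals.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="tmm_factor")


def log_cpm(
    counts: pd.DataFrame | CountData,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 CPM with a prior count: log2((y + prior) / (lib*factor + 2*prior) * 1e6)."""
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    mat = counts.counts if isinstance(counts, CountData) else counts
    lib = mat.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * pd.Series(factors, index=mat.columns)
    return np.log2((mat + prior_count) / (lib + 2 * prior_count) * 1e6)


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(x: float) -> float:
    # Newton iterations on trigamma(y) = x (limma-style)
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Moment-matching on log variances: the prior degrees of freedom d0 and
    scale s0^2 solve the mean/variance equations of log s^2 under the scaled
    F distribution.  Returns (posterior variances, d0, s0^2).
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), np.inf, float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2)
    if excess > 0:
        d0 = 2 * _trigamma_inverse(excess)
        s02 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        warnings.warn("log-variance spread below sampling noise; using full shrinkage")
        d0 = np.inf
        s02 = float(np.exp(e_mean))
    if np.isfinite(d0):
        post = (d0 * s02 + df * s2) / (d0 + df)
    else:
        post = np.full_like(s2, s02)
    return post, float(d0), s02


def fit_de(
    logcpm: pd.DataFrame,
    sample_meta: pd.DataFrame,
    case: str = "tumorA",
    reference: str = "normal",
    gleason_col: str = "gleason",
) -> pd.DataFrame:
    """Per-gene moderated-t differential expression, case vs reference.

    Fits ordinary least squares on log-CPM with intercept, a case indicator
    and an ordinal Gleason covariate (0 for reference normals), then shrinks
    the residual variances with empirical Bayes and reports a moderated t
    with d0 + d degrees of freedom.  Constant genes get log2fc 0 and p 1.

    Returns a DataFrame indexed by gene with columns log2fc, p_raw, fdr,
    direction.
    """
    samples = sample_meta.index[sample_meta["cohort"].isin([case, reference])]
    meta = sample_meta.loc[samples]
    counts_per_level = meta["cohort"].value_counts()
    if counts_per_level.get(case, 0) < 2 or counts_per_level.get(reference, 0) < 2:
        raise ValueError("need at least 2 samples per level of the primary factor")
    y = logcpm[samples].to_numpy()
    indicator = (meta["cohort"] == case).to_numpy().astype(float)
    gleason = meta[gleason_col].to_numpy().astype(float) if gleason_col in meta else np.zeros(len(meta))
    # centre the ordinal score within the graded (tumor) samples so the
    # covariate is orthogonal to case status rather than collinear with it
    graded = gleason > 0
    if graded.any():
        gleason = np.where(graded, gleason - gleason[graded].mean(), 0.0)
    x = np.column_stack([np.ones(len(meta)), indicator, gleason])
    # drop constant covariate columns (e.g. Gleason in tumorA-vs-tumorB when matched)
    keep_cols = [0, 1] + [j for j in range(2, x.shape[1]) if np.ptp(x[:, j]) > 0]
    x = x[:, keep_cols]
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            "rank-deficient design; confounded columns among "
            "[intercept, case indicator, gleason]"
        )
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = y @ x @ xtx_inv.T  # genes x p
    resid = y - beta @ x.T
    df_resid = x.shape[0] - x.shape[1]
    s2 = (resid**2).sum(axis=1) / df_resid
    post_var, d0, _ = _squeeze_var(s2, df_resid)
    se = np.sqrt(post_var * xtx_inv[1, 1])
    coef = beta[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    df_total = d0 + df_resid if np.isfinite(d0) else np.inf
    if np.isfinite(df_total):
        p = 2 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2 * stats.norm.sf(np.abs(t))
    constant = np.ptp(y, axis=1) == 0
    coef = np.where(constant, 0.0, coef)
    p = np.where(constant, 1.0, p)
    out = pd.DataFrame(
        {
            "log2fc": coef,
            "p_raw": p,
            "fdr": bh_fdr(p),
            "direction": np.where(coef >= 0, "up", "down"),
        },
        index=logcpm.index,
    )
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def select_de(
    de: pd.DataFrame,
    annotation: pd.DataFrame,
    fc_linear: float = 2.0,
    fdr_max: float = 0.01,
) -> dict[str, list[str]]:
    """Apply the selection rule |log2fc| > log2(fc_linear) and fdr < fdr_max.

    Returns gene-id lists partitioned into keys ``{mrna,lncrna}_{up,down}``.
    The input ``de`` table gains a boolean ``selected`` column as a side
    effect of the returned partition being consistent with it.
    """
    missing = [g for g in de.index if g not in annotation.index]
    if missing:
        raise ValueError(f"genes without biotype annotation: {missing[:10]}")
    cut = np.log2(fc_linear)
    selected = (de["log2fc"].abs() > cut) & (de["fdr"] < fdr_max)
    de["selected"] = selected
    out: dict[str, list[str]] = {}
    biotype = annotation["biotype"]
    for bt, bt_key in (("mRNA", "mrna"), ("lncRNA", "lncrna")):
        for direction in ("up", "down"):
            mask = selected & (de["direction"] == direction) & (biotype.reindex(de.index) == bt)
            out[f"{bt_key}_{direction}"] = list(de.index[mask])
    return out


@dataclass(frozen=True)
class OverlapRow:
    size_a: int
    size_b: int
    shared: int
    pct_a_shared: float
    pct_b_shared: float


def _round1(x: float) -> float:
    # round-half-up at one decimal, matching printed-percentage conventions
    return float(np.floor(x * 10 + 0.5) / 10)


def overlap_from_counts(size_a: int, size_b: int, shared: int) -> OverlapRow:
    if shared > min(size_a, size_b):
        raise ValueError("shared exceeds a set size")
    pct_a = _round1(100.0 * shared / size_a) if size_a else 0.0
    pct_b = _round1(100.0 * shared / size_b) if size_b else 0.0
    return OverlapRow(size_a, size_b, shared, pct_a, pct_b)


def overlap_summary(
    sets_a: dict[str, list[str]], sets_b: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-category set-overlap sizes and percentages (one decimal)."""
    rows = {}
    for key in sets_a:
        a, b = set(sets_a[key]), set(sets_b.get(key, []))
        rows[key] = overlap_from_counts(len(a), len(b), len(a & b)).__dict__
    return pd.DataFrame.from_dict(rows, orient="index")


def match_cohorts(
    samples_a: pd.DataFrame,
    samples_b: pd.DataFrame,
    key: str = "gleason",
    seed: int = 0,
) -> list[str]:
    """1:1 random matching of cohort B samples to cohort A within ``key`` strata.

    Returns the selected subset of B's sample ids (|selection| = |A|), drawn
    uniformly without replacement within each stratum.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for value, group_a in samples_a.groupby(key):
        pool = samples_b.index[samples_b[key] == value]
        if len(pool) < len(group_a):
            raise ValueError(
                f"stratum {key}={value}: need {len(group_a)} samples, have {len(pool)}"
            )
        chosen.extend(rng.choice(pool, size=len(group_a), replace=False))
    return sorted(chosen)
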