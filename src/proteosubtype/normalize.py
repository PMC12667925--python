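"""TMT proteome preprocessing chain.

The chain runs in a fixed order, mirroring how multiplexed isobaric-label
experiments are cleaned before any biology is read off them:

1. **missingness filter** — drop features with valid values in fewer than
   30% of samples;
2. **KNN imputation** — fill remaining gaps from the k nearest features
   (log2 scale);
3. **sample-loading (SL) normalization** — equalize per-channel totals,
   removing pipetting/labelling differences within a plex;
4. **internal reference scaling (IRS)** — per feature, rescale each plex
   so its pooled-reference channels agree across plexes, removing the
   plex batch effect;
5. **TMM** — trimmed-mean-of-M-values scale factors for final
   median-centring between batches.

SL/IRS/TMM are scale transforms on raw intensities; the filter, imputation
and the differential-abundance test operate on log2 values. A
``NormalizationReport`` records stage-by-stage feature/sample counts and
all factors.

Differential abundance uses Welch's t-test with Benjamini-Hochberg FDR
(count-model tests do not transfer to TMT log-intensities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix, SampleTable, logger


@dataclass
class NormalizationReport:
    stages: list[dict] = field(default_factory=dict)
    sl_factors: dict = field(default_factory=dict)
    irs_factors: dict = field(default_factory=dict)
    tmm_factors: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def record(self, stage: str, m: OmicsMatrix) -> None:
        if not isinstance(self.stages, list):
            self.stages = []
        self.stages.append({
            "stage": stage,
            "n_features": len(m.feature_ids),
            "n_samples": len(m.sample_ids),
            "n_missing": m.n_missing,
        })

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "sl_factors": self.sl_factors,
            "irs_factors": self.irs_factors,
            "tmm_factors": self.tmm_factors,
            "parameters": self.parameters,
        }


# ---------------------------------------------------------------------------
# stage 1: missingness filter
# ---------------------------------------------------------------------------

def filter_missing(m: OmicsMatrix, min_valid_frac: float = 0.30) -> OmicsMatrix:
    """Retain features whose observed fraction is >= ``min_valid_frac``.

    A feature valid in 29 of 100 samples is dropped at the default 0.30;
    one valid in exactly 30 of 100 is retained.
    """
    if not (0 < min_valid_frac <= 1):
        raise ValueError(f"min_valid_frac must be in (0, 1], got {min_valid_frac}")
    valid_frac = m.mask.mean(axis=1)
    keep = valid_frac >= min_valid_frac
    return m.with_data(m.data.loc[keep])


# ---------------------------------------------------------------------------
# stage 2: KNN imputation
# ---------------------------------------------------------------------------

def knn_impute(m: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Impute missing cells from the k nearest features (log2 scale).

    Distance between two features is the root-mean-square difference over
    their jointly observed samples; features with no overlap are infinitely
    far. A missing cell becomes the unweighted mean of the k nearest
    features that are observed at that sample; if none is observed there
    (no candidate neighbours), the feature's own observed mean is used as a
    fallback. Observed values are never altered.
    """
    if m.scale_tag != "log2":
        raise ValueError("knn_impute expects a log2-scale matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.data.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if (obs.sum(axis=1) == 0).any():
        bad = [m.feature_ids[i] for i in np.where(obs.sum(axis=1) == 0)[0]]
        raise ValueError(f"features with zero observed values (filter first): {bad[:5]}")
    if not np.isnan(X).any():
        return m

    Xz = np.where(obs, X, 0.0)
    # pairwise sums of squared differences over jointly observed columns
    o = obs.astype(float)
    joint = o @ o.T
    sq = (Xz ** 2) @ o.T + o @ (Xz ** 2).T - 2.0 * (Xz @ Xz.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(joint > 0, sq / np.maximum(joint, 1), np.inf)
    np.fill_diagonal(d2, np.inf)

    out = X.copy()
    for i in np.where(~obs.all(axis=1))[0]:
        order = np.argsort(d2[i], kind="stable")
        for j in np.where(~obs[i])[0]:
            cands = order[obs[order, j] & np.isfinite(d2[i, order])]
            if cands.size == 0:
                out[i, j] = X[i, obs[i]].mean()
            else:
                out[i, j] = X[cands[:k], j].mean()
    return m.with_data(pd.DataFrame(out, index=m.data.index, columns=m.data.columns))


# ---------------------------------------------------------------------------
# stage 3: sample-loading normalization
# ---------------------------------------------------------------------------

def sample_loading_normalize(m: OmicsMatrix,
                             report: NormalizationReport | None = None) -> OmicsMatrix:
    """Rescale each column so all column totals equal the original grand mean."""
    if m.scale_tag != "raw_intensity":
        raise ValueError("sample_loading_normalize expects raw intensities")
    sums = m.data.sum(axis=0, skipna=True)
    if (sums == 0).any():
        bad = list(sums.index[sums == 0])
        raise ValueError(f"columns summing to zero: {bad}")
    factors = sums.mean() / sums
    if report is not None:
        report.sl_factors = factors.to_dict()
    return m.with_data(m.data * factors)


# ---------------------------------------------------------------------------
# stage 4: internal reference scaling
# ---------------------------------------------------------------------------

def irs_correct(m: OmicsMatrix, samples: SampleTable,
                report: NormalizationReport | None = None) -> OmicsMatrix:
    """Per-feature cross-plex rescaling anchored on pooled-reference channels.

    For each feature, each plex's reference mean ``r_p`` is brought to the
    geometric mean ``g`` of all reference means by scaling the plex's
    values by ``g / r_p``. After correction all plexes' reference means
    agree per feature. Where a feature has no observed (positive)
    reference value in a plex, that plex's values for the feature become
    missing rather than guessed.
    """
    if m.scale_tag != "raw_intensity":
        raise ValueError("irs_correct expects raw intensities")
    meta = samples.table.set_index("sample_id")
    missing_meta = [s for s in m.sample_ids if s not in meta.index]
    if missing_meta:
        raise ValueError(f"samples absent from metadata: {missing_meta[:5]}")
    plex = meta.loc[m.sample_ids, "plex_id"]
    is_ref = meta.loc[m.sample_ids, "is_pooled_reference"].astype(bool)
    plexes = list(pd.unique(plex))
    for p in plexes:
        if not is_ref[plex == p].any():
            raise ValueError(f"plex {p!r} has no pooled-reference channel in the matrix")

    ref_means = pd.DataFrame(index=m.data.index, columns=plexes, dtype=float)
    for p in plexes:
        cols = [s for s, pl, r in zip(m.sample_ids, plex, is_ref) if pl == p and r]
        rm = m.data[cols].mean(axis=1, skipna=True)
        ref_means[p] = rm.where(rm > 0)  # zero/absent reference => undefined

    with np.errstate(divide="ignore"):
        log_g = np.log(ref_means).mean(axis=1, skipna=True)
    g = np.exp(log_g)

    out = m.data.copy()
    factors: dict[str, dict[str, float]] = {}
    for p in plexes:
        cols = [s for s, pl in zip(m.sample_ids, plex) if pl == p]
        fac = g / ref_means[p]
        n_dropped = int((fac.isna() & out[cols].notna().any(axis=1)).sum())
        if n_dropped:
            logger.info("IRS: %d features lack a reference in plex %s; set missing", n_dropped, p)
        out[cols] = out[cols].mul(fac, axis=0)
        factors[str(p)] = {"median_factor": float(fac.median(skipna=True))}
    if report is not None:
        report.irs_factors = factors
    return m.with_data(out)


# ---------------------------------------------------------------------------
# stage 5: TMM
# ---------------------------------------------------------------------------

def tmm_factors(m: OmicsMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                ref_col: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values scale factor per column.

    The reference column is the one whose total is closest to the mean
    total. Per column, M = log2(x/x_ref) and A = 0.5*log2(x*x_ref) are
    computed over features observed and positive in both; the top/bottom
    ``trim_m`` fraction by M and ``trim_a`` fraction by A are removed, and
    the factor is 2**mean(M) of the survivors (unweighted mean — the
    count-based precision weights of the RNA-seq formulation do not apply
    to intensities). Factors are rescaled to geometric mean 1.
    """
    if m.scale_tag != "raw_intensity":
        raise ValueError("tmm expects raw intensities")
    X = m.data
    if (X.to_numpy() <= 0).any():
        raise ValueError("tmm requires strictly positive observed values")
    sums = X.sum(axis=0, skipna=True)
    if ref_col is None:
        ref_col = (sums - sums.mean()).abs().idxmin()
    elif ref_col not in X.columns:
        raise ValueError(f"reference column {ref_col!r} not in the matrix")
    ref = X[ref_col]
    factors = {}
    for col in X.columns:
        x = X[col]
        ok = x.notna() & ref.notna()
        xi, ri = x[ok].to_numpy(), ref[ok].to_numpy()
        M = np.log2(xi / ri)
        A = 0.5 * np.log2(xi * ri)
        n = len(M)
        keep = np.ones(n, dtype=bool)
        if n > 0:
            rm = stats.rankdata(M, method="average")
            ra = stats.rankdata(A, method="average")
            lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
            lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
            keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if keep.sum() == 0:
            factors[col] = 1.0 if np.allclose(M, 0) else float(2 ** np.mean(M))
        else:
            factors[col] = float(2 ** np.mean(M[keep]))
    f = pd.Series(factors)
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    return f


def tmm_normalize(m: OmicsMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
                  report: NormalizationReport | None = None
                  ) -> tuple[OmicsMatrix, pd.Series]:
    """Divide each column by its TMM factor; returns (matrix, factors)."""
    f = tmm_factors(m, trim_m=trim_m, trim_a=trim_a)
    if report is not None:
        report.tmm_factors = f.to_dict()
    return m.with_data(m.data / f), f


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def differential_abundance(m: OmicsMatrix, group_a: list[str],
                           group_b: list[str]) -> pd.DataFrame:
    """Two-group Welch t-test per feature with BH correction.

    log2FC = mean(group_a) - mean(group_b) on the log2 matrix. Features
    constant and equal in both groups get p = 1; constant but unequal get
    p = 0 (a zero-variance shift is unambiguous).
    """
    if m.scale_tag != "log2":
        raise ValueError("differential_abundance expects a log2-scale matrix")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    A = m.data[list(group_a)].to_numpy(dtype=float)
    B = m.data[list(group_b)].to_numpy(dtype=float)
    mean_a, mean_b = np.nanmean(A, axis=1), np.nanmean(B, axis=1)
    log2fc = mean_a - mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    var_a = np.nanvar(A, axis=1)
    var_b = np.nanvar(B, axis=1)
    degenerate = (var_a == 0) & (var_b == 0)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    p = np.where(np.isnan(p), 1.0, p)
    q = bh_adjust(p)
    return pd.DataFrame({
        "feature_id": m.feature_ids, "log2FC": log2fc, "t": np.asarray(t, dtype=float),
        "p": p, "q": q,
    }).set_index("feature_id")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------

def normalize_pipeline(m: OmicsMatrix, samples: SampleTable,
                       min_valid_frac: float = 0.30, knn_k: int = 10,
                       trim_m: float = 0.30, trim_a: float = 0.05,
                       ) -> tuple[OmicsMatrix, NormalizationReport]:
    """filter -> impute -> SL -> IRS -> TMM; returns a log2 matrix + report."""
    report = NormalizationReport(stages=[], parameters={
        "min_valid_frac": min_valid_frac, "knn_k": knn_k,
        "tmm_trim_m": trim_m, "tmm_trim_a": trim_a,
    })
    raw = m.to_raw()
    report.record("input", raw)
    filt = filter_missing(raw, min_valid_frac)
    report.record("filter_missing", filt)
    imputed = knn_impute(filt.to_log2(), k=knn_k)
    report.record("knn_impute", imputed)
    sl = sample_loading_normalize(imputed.to_raw(), report)
    report.record("sample_loading", sl)
    irs = irs_correct(sl, samples, report)
    report.record("irs", irs)
    # IRS may (re)introduce missing cells for features lacking a plex reference
    irs_filled = irs
    if irs.n_missing:
        irs_filled = knn_impute(irs.to_log2(), k=knn_k).to_raw()
        report.record("irs_reimpute", irs_filled)
    tmm, _ = tmm_normalize(irs_filled, trim_m, trim_a, report)
    report.record("tmm", tmm)
    out = tmm.to_log2()
    return out, report
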