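"""Cross-omic association stages.

* cis/trans mapping of gene copy number against mRNA and protein
  abundance (Spearman, BH within declared families);
* alteration frequencies and pairwise co-occurrence (Fisher exact);
* differential-expression feature filtering and subtype-transfer
  classification (random-forest by default, pluggable);
* Kaplan-Meier survival stratification with log-rank testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

from .io import AlterationMatrix, OmicsMatrix, SampleTable
from .normalize import bh_adjust, differential_abundance


# ---------------------------------------------------------------------------
# cis/trans CNA-expression mapping
# ---------------------------------------------------------------------------

def _spearman_vs(cna_vec: np.ndarray, expr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and p of one CNA vector against every expression row."""
    n = cna_vec.size
    r_c = stats.rankdata(cna_vec)
    r_e = np.apply_along_axis(stats.rankdata, 1, expr)
    r_c = (r_c - r_c.mean())
    r_e = r_e - r_e.mean(axis=1, keepdims=True)
    denom = np.sqrt((r_c ** 2).sum() * (r_e ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (r_e @ r_c) / denom
    rho = np.clip(np.where(np.isfinite(rho), rho, 0.0), -1.0, 1.0)
    # t approximation for the null distribution of Spearman's rho
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1 - rho ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def cis_trans_map(cna: OmicsMatrix, mrna: OmicsMatrix | None = None,
                  protein: OmicsMatrix | None = None, fdr: float = 0.1,
                  include_trans: bool = False) -> tuple[pd.DataFrame, dict]:
    """Spearman correlation of gene copy number with expression levels.

    Cis records pair each CNA gene with its own mRNA/protein; BH runs
    within the cis family of each level. With ``include_trans=True`` every
    (CNA gene, other target) pair is tested too, corrected within each CNA
    gene's trans family. The summary reports cis counts at q < ``fdr`` per
    level and their overlap.
    """
    levels = {}
    if mrna is not None:
        levels["mrna"] = mrna
    if protein is not None:
        levels["protein"] = protein
    if not levels:
        raise ValueError("need at least one of mrna/protein")
    records = []
    cis_genes: dict[str, set[str]] = {}
    for level, expr in levels.items():
        shared = [s for s in cna.sample_ids if s in set(expr.sample_ids)]
        if len(shared) < 10:
            raise ValueError(f"only {len(shared)} shared samples with {level}; need >= 10")
        C = cna.data[shared]
        E = expr.data[shared]
        genes = [g for g in C.index if g in set(E.index)]
        # cis family: one test per gene, BH across genes
        rhos, ps = [], []
        for g in genes:
            rho, p = stats.spearmanr(C.loc[g].to_numpy(), E.loc[g].to_numpy())
            if not np.isfinite(rho):
                rho, p = 0.0, 1.0
            rhos.append(rho)
            ps.append(p)
        qs = bh_adjust(np.array(ps))
        for g, rho, p, q in zip(genes, rhos, ps, qs):
            records.append({"cna_gene": g, "target_feature": g, "level": level,
                            "rho": rho, "p": p, "q": q, "is_cis": True})
        cis_genes[level] = {g for g, q in zip(genes, qs) if q < fdr}
        if include_trans:
            E_arr = E.to_numpy(dtype=float)
            targets = np.array(E.index)
            for g in genes:
                rho, p = _spearman_vs(C.loc[g].to_numpy(dtype=float), E_arr)
                keep = targets != g
                q = bh_adjust(p[keep])
                for tgt, r_, p_, q_ in zip(targets[keep], rho[keep], p[keep], q):
                    records.append({"cna_gene": g, "target_feature": tgt,
                                    "level": level, "rho": r_, "p": p_, "q": q_,
                                    "is_cis": False})
    df = pd.DataFrame(records, columns=["cna_gene", "target_feature", "level",
                                        "rho", "p", "q", "is_cis"])
    summary = {f"n_cis_{level}": len(gset) for level, gset in cis_genes.items()}
    if len(cis_genes) == 2:
        a, b = cis_genes.values()
        summary["n_cis_overlap"] = len(a & b)
    summary["fdr"] = fdr
    return df, summary


# ---------------------------------------------------------------------------
# alteration frequencies and co-occurrence
# ---------------------------------------------------------------------------

def alteration_frequencies(alts: AlterationMatrix) -> pd.DataFrame:
    """Per-gene altered-sample counts and frequencies, sorted descending."""
    calls = alts.calls
    if calls.shape[1] == 0:
        raise ValueError("alteration matrix has zero samples")
    altered = (calls != "none").sum(axis=1)
    freq = altered / calls.shape[1]
    out = pd.DataFrame({"n_altered": altered, "frequency": freq})
    return out.sort_values("frequency", ascending=False)


def cooccurrence_fisher(alts: AlterationMatrix, gene_a: str, gene_b: str
                        ) -> tuple[np.ndarray, float, float]:
    """Two-sided Fisher exact test on the altered/unaltered 2x2 table."""
    for g in (gene_a, gene_b):
        if g not in alts.calls.index:
            raise ValueError(f"gene {g!r} absent from the alteration matrix")
    a = alts.calls.loc[gene_a] != "none"
    b = alts.calls.loc[gene_b] != "none"
    table = np.array([
        [int((a & b).sum()), int((a & ~b).sum())],
        [int((~a & b).sum()), int((~a & ~b).sum())],
    ])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return table, float(odds), float(p)


# ---------------------------------------------------------------------------
# subtype transfer
# ---------------------------------------------------------------------------

def select_transfer_features(expr: OmicsMatrix, labels: pd.Series,
                             fdr: float = 0.01, min_abs_fc: float = 2.0
                             ) -> list[str]:
    """Union over one-vs-rest contrasts of features with q < ``fdr`` and
    linear |fold change| > ``min_abs_fc`` (i.e. |log2FC| > log2(min_abs_fc))."""
    labels = labels.loc[[s for s in expr.sample_ids if s in labels.index]]
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = labels.value_counts()
    if (counts < 3).any():
        raise ValueError(f"classes with < 3 samples: {list(counts.index[counts < 3])}")
    min_abs_log2fc = np.log2(min_abs_fc)
    selected: set[str] = set()
    for cls in classes:
        in_cls = list(labels.index[labels == cls])
        rest = list(labels.index[labels != cls])
        de = differential_abundance(expr, in_cls, rest)
        hit = de[(de["q"] < fdr) & (de["log2FC"].abs() > min_abs_log2fc)]
        selected.update(hit.index)
    return [f for f in expr.feature_ids if f in selected]


def fit_subtype_classifier(expr: OmicsMatrix, labels: pd.Series,
                           features: list[str], train_frac: float = 0.7,
                           n_folds: int = 10, seed: int = 0,
                           model=None) -> tuple[object, pd.Series, float]:
    """Train a classifier on the selected features; report held-out macro F1.

    Default model is a random forest (bagged decision-tree ensemble); any
    sklearn-style classifier can be passed instead. A stratified
    ``train_frac`` split is drawn, stratified k-fold cross-validation on
    the training part reports model stability, and per-class + macro F1
    come from the held-out part. Same seed => identical split and scores.
    """
    missing = [f for f in features if f not in set(expr.feature_ids)]
    if missing:
        raise ValueError(f"features absent from the matrix: {missing[:5]}")
    labels = labels.loc[[s for s in expr.sample_ids if s in labels.index]]
    X = expr.data.loc[features, labels.index].T.to_numpy(dtype=float)
    y = labels.to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_frac, stratify=y, random_state=seed)
    if len(np.unique(y_tr)) < len(np.unique(y)):
        raise ValueError("a class is absent from the training split")
    if model is None:
        model = RandomForestClassifier(n_estimators=500, random_state=seed)
    folds = min(n_folds, np.bincount(pd.factorize(y_tr)[0]).min())
    cv_scores = None
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        cv_scores = cross_val_score(model, X_tr, y_tr, cv=cv, scoring="f1_macro")
    model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    class_order = sorted(np.unique(y))
    per_class = pd.Series(
        f1_score(y_te, pred, labels=class_order, average=None, zero_division=0),
        index=class_order, name="f1")
    macro = float(f1_score(y_te, pred, average="macro", zero_division=0))
    model.cv_f1_macro_ = None if cv_scores is None else float(np.mean(cv_scores))
    model.selected_features_ = list(features)
    return model, per_class, macro


def predict_subtypes(model, expr: OmicsMatrix) -> pd.Series:
    """Apply a trained classifier to any matrix carrying its feature set."""
    features = model.selected_features_
    missing = [f for f in features if f not in set(expr.feature_ids)]
    if missing:
        raise ValueError(f"matrix lacks classifier features: {missing[:5]}")
    X = expr.data.loc[features].T.to_numpy(dtype=float)
    return pd.Series(model.predict(X), index=expr.sample_ids, name="subtype")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def km_logrank(samples: SampleTable, groups: pd.Series, endpoint: str = "os"
               ) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group and the log-rank test across groups.

    ``endpoint`` selects (os_time, os_event) or (rfs_time, rfs_event).
    Returns ({group: survival curve}, chi2, p).
    """
    if endpoint not in ("os", "rfs"):
        raise ValueError("endpoint must be 'os' or 'rfs'")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    meta = samples.table.set_index("sample_id")
    groups = groups.dropna()
    ids = [s for s in groups.index if s in meta.index]
    t = meta.loc[ids, tcol].astype(float)
    e = meta.loc[ids, ecol].astype(float)
    ok = t.notna() & e.notna()
    t, e, g = t[ok], e[ok], groups.loc[ids][ok]
    if (t < 0).any():
        raise ValueError("negative survival times")
    if g.nunique() < 2:
        raise ValueError("need >= 2 groups for a log-rank test")
    if e.sum() == 0:
        raise ValueError("no events observed")
    curves = {}
    for name, idx in g.groupby(g).groups.items():
        kmf = KaplanMeierFitter()
        kmf.fit(t.loc[idx], e.loc[idx], label=str(name))
        curves[str(name)] = kmf.survival_function_
    res = multivariate_logrank_test(t, g, e)
    return curves, float(res.test_statistic), float(res.p_value)
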