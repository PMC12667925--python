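"""Gene-set enrichment: single-sample GSEA, preranked GSEA, and ORA.

One engine serves pathway scores, immune/stemness/cell-cycle signature
scores and site-centric PTM signatures.

* ``ssgsea_scores`` — per sample, features are ranked by (log-)abundance
  and a rank-weighted running enrichment statistic is accumulated; the
  score is the area under the running curve (signed sum over all ranks),
  with in-set increments weighted by |value|^weight and uniform
  out-of-set decrements. Per-set scores are z-scored across samples
  ("NES") by default.
* ``preranked_gsea`` — classic weighted Kolmogorov-Smirnov enrichment
  score on a fold-change-ranked list, with feature-label permutation
  p-values and sign-matched NES normalization.
* ``ora_test`` — upper-tail hypergeometric over-representation against an
  explicit background universe, BH-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSetCollection, OmicsMatrix, logger
from .normalize import bh_adjust


@dataclass
class EnrichmentResult:
    set_name: str
    score: float
    p: float | None
    q: float | None
    n_overlap: int
    direction: int


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

def _ssgsea_sample_scores(values: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Area-under-running-enrichment score for one sample and one set.

    ``values`` are the transformed abundances, ``in_set`` the membership
    indicator, both ordered by decreasing value.
    """
    w = np.abs(values) ** weight
    w_in = np.where(in_set, w, 0.0)
    denom_in = w_in.sum()
    n_out = (~in_set).sum()
    if denom_in == 0 or n_out == 0:
        return 0.0
    inc = w_in / denom_in - np.where(in_set, 0.0, 1.0 / n_out)
    running = np.cumsum(inc)
    return float(running.sum())


def ssgsea_scores(m: OmicsMatrix, sets: GeneSetCollection, weight: float = 0.75,
                  min_overlap: int = 3, norm: str = "z_score",
                  sample_norm: str = "log") -> pd.DataFrame:
    """Single-sample GSEA score matrix (set x sample).

    ``sample_norm='log'`` log2-transforms raw intensities before ranking
    (already-log2 matrices pass through). Sets overlapping the matrix by
    fewer than ``min_overlap`` features are omitted with a warning. With
    ``norm='z_score'`` each set's scores are z-scored across samples; with
    ``norm='none'`` raw area scores are returned.
    """
    if m.n_missing:
        raise ValueError("ssgsea_scores expects a complete (imputed) matrix")
    if norm not in ("z_score", "none"):
        raise ValueError(f"unknown norm {norm!r}")
    data = m.to_log2().data if sample_norm == "log" else m.data
    features = np.array(data.index)
    X = data.to_numpy(dtype=float)
    n_feat, n_samp = X.shape

    order = np.argsort(-X, axis=0, kind="stable")
    kept, rows = [], []
    for name, (_, members) in sets:
        member_mask = np.isin(features, list(members))
        n_overlap = int(member_mask.sum())
        if n_overlap < min_overlap:
            logger.warning("set %s overlaps matrix by %d < min_overlap=%d; omitted",
                           name, n_overlap, min_overlap)
            continue
        scores = np.empty(n_samp)
        for j in range(n_samp):
            idx = order[:, j]
            scores[j] = _ssgsea_sample_scores(X[idx, j], member_mask[idx], weight)
        kept.append(name)
        rows.append(scores)
    out = pd.DataFrame(rows, index=kept, columns=data.columns)
    if norm == "z_score" and not out.empty:
        sd = out.std(axis=1, ddof=1)
        centred = out.sub(out.mean(axis=1), axis=0)
        flat = sd == 0
        if flat.any():
            logger.warning("sets with zero score variance across samples: %s",
                           list(out.index[flat]))
        out = centred.div(sd.where(~flat, 1.0), axis=0)
    return out


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _es(ranked_values: np.ndarray, in_set: np.ndarray, weight: float) -> float:
    """Classic GSEA enrichment score: max-deviation of the running sum."""
    w = np.abs(ranked_values) ** weight
    w_in = np.where(in_set, w, 0.0)
    denom = w_in.sum()
    n_out = (~in_set).sum()
    if denom == 0 or n_out == 0:
        return 0.0
    running = np.cumsum(w_in / denom - np.where(in_set, 0.0, 1.0 / n_out))
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(ranked: pd.Series, sets: GeneSetCollection, weight: float = 1.0,
                   n_perm: int = 1000, seed: int = 0, min_overlap: int = 3
                   ) -> pd.DataFrame:
    """Weighted-KS enrichment on a ranking (e.g. log2 fold changes).

    p-values come from ``n_perm`` feature-label permutations; NES divides
    the ES by the mean |ES| of same-sign permutations; q is BH over the
    reported sets.
    """
    if ranked.index.duplicated().any():
        raise ValueError("duplicate features in the ranking")
    if not np.isfinite(ranked.to_numpy()).all():
        raise ValueError("ranking contains non-finite values")
    ranked = ranked.sort_values(ascending=False)
    values = ranked.to_numpy(dtype=float)
    features = np.array(ranked.index)
    rng = np.random.default_rng(seed)
    rows = []
    for name, (_, members) in sets:
        in_set = np.isin(features, list(members))
        n_overlap = int(in_set.sum())
        if n_overlap < min_overlap:
            continue
        es = _es(values, in_set, weight)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(in_set)
            perm_es[b] = _es(values, perm, weight)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        denom = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        if es >= 0:
            p = (1 + (perm_es >= es).sum()) / (1 + (perm_es >= 0).sum())
        else:
            p = (1 + (perm_es <= es).sum()) / (1 + (perm_es <= 0).sum())
        rows.append({"set_name": name, "es": es, "nes": nes, "p": min(p, 1.0),
                     "n_overlap": n_overlap, "direction": int(np.sign(es))})
    out = pd.DataFrame(rows, columns=["set_name", "es", "nes", "p", "n_overlap", "direction"])
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out.set_index("set_name")


# ---------------------------------------------------------------------------
# ORA
# ---------------------------------------------------------------------------

def ora_test(hits: set[str], universe: set[str], sets: GeneSetCollection,
             min_overlap: int = 1) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation with BH correction.

    ``p = P(X >= observed overlap)`` where X is hypergeometric with the
    universe size, the set size restricted to the universe, and the number
    of hits drawn.
    """
    hits, universe = set(hits), set(universe)
    stray = hits - universe
    if stray:
        raise ValueError(f"hits not contained in universe: {sorted(stray)[:5]}")
    N, n_hits = len(universe), len(hits)
    rows = []
    for name, (_, members) in sets:
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        overlap = len(in_universe & hits)
        if overlap < min_overlap and overlap == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, N, K, n_hits))
        rows.append({"set_name": name, "n_overlap": overlap, "set_size": K,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set_name", "n_overlap", "set_size", "p"])
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out.set_index("set_name")


def signature_scores(m: OmicsMatrix, signatures: GeneSetCollection,
                     **kwargs) -> pd.DataFrame:
    """Signature scoring (immune / stemness / cell-cycle style): the ssGSEA
    engine applied to user-supplied signature GMTs."""
    return ssgsea_scores(m, signatures, **kwargs)
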