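"""Unsupervised subtype discovery by consensus non-negative matrix factorization.

The merged protein + phosphoprotein matrix is reduced to its top-N most
variable rows (mean absolute deviation), median-centred and split into
non-negative positive/negative parts, then factorized V ~ WH many times
from random initializations. Each restart clusters samples by the argmax
row of H; the fraction of restarts co-clustering each sample pair forms
the consensus matrix, from which rank-selection metrics (cophenetic
correlation, mean silhouette on 1 - consensus) and final labels follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.metrics import silhouette_score

from .io import OmicsMatrix, logger


# ---------------------------------------------------------------------------
# input preparation
# ---------------------------------------------------------------------------

def mean_abs_deviation(x: np.ndarray, axis: int = 1) -> np.ndarray:
    return np.mean(np.abs(x - x.mean(axis=axis, keepdims=True)), axis=axis)


def prepare_nmf_input(protein: OmicsMatrix, phospho: OmicsMatrix | None = None,
                      top_n: int = 500) -> pd.DataFrame:
    """Merge, select top-``top_n`` rows by MAD, median-centre, and split each
    row into non-negative positive/negative parts (doubling the row count).

    ``(pos - neg)`` reconstructs the centred input exactly.
    """
    if top_n < 2:
        raise ValueError("top_n must be >= 2")
    mats = [protein] + ([phospho] if phospho is not None else [])
    for m in mats:
        if m.scale_tag != "log2":
            raise ValueError("prepare_nmf_input expects log2-scale matrices")
        if m.n_missing:
            raise ValueError("prepare_nmf_input expects complete (imputed) matrices")
    frames = []
    for m, prefix in zip(mats, ("prot:", "phos:")):
        df = m.data.copy()
        df.index = [prefix + f for f in df.index]
        frames.append(df)
    if phospho is not None:
        if list(frames[0].columns) != list(frames[1].columns):
            raise ValueError("protein and phospho matrices must share the sample set")
    merged = pd.concat(frames, axis=0)
    mad = mean_abs_deviation(merged.to_numpy())
    if len(merged) < top_n:
        warnings.warn(f"only {len(merged)} features available for top_n={top_n}; using all",
                      stacklevel=2)
        top_n = len(merged)
    order = np.argsort(-mad, kind="stable")[:top_n]
    sel = merged.iloc[np.sort(order)]
    centred = sel.sub(sel.median(axis=1), axis=0)
    pos = centred.clip(lower=0)
    neg = (-centred).clip(lower=0)
    pos.index = [f + "+" for f in pos.index]
    neg.index = [f + "-" for f in neg.index]
    return pd.concat([pos, neg], axis=0)


# ---------------------------------------------------------------------------
# multiplicative-update NMF
# ---------------------------------------------------------------------------

@dataclass
class NmfFactorization:
    W: np.ndarray
    H: np.ndarray
    objective_trace: list[float]
    seed: int


def nmf_factorize(V: np.ndarray | pd.DataFrame, k: int, seed: int,
                  max_iter: int = 2000, tol: float = 1e-6) -> NmfFactorization:
    """Multiplicative-update minimization of ||V - WH||_F.

    Stops at ``max_iter`` or when the relative objective change falls below
    ``tol``. The per-iteration Frobenius error trace is recorded and is
    non-increasing (a property of the updates). Same seed => identical
    factors.
    """
    V = np.asarray(V, dtype=float)
    if V.min() < 0:
        raise ValueError("NMF input must be non-negative")
    n, m = V.shape
    if not (1 <= k < min(n, m)):
        raise ValueError(f"rank k={k} out of range for a {n}x{m} matrix")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), 1e-12) / k)
    W = rng.uniform(1e-4, 1.0, size=(n, k)) * scale
    H = rng.uniform(1e-4, 1.0, size=(k, m)) * scale
    eps = 1e-12
    v_norm2 = float((V * V).sum())
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        WtV = W.T @ V
        H *= WtV / (W.T @ W @ H + eps)
        VHt = V @ H.T
        W *= VHt / (W @ (H @ H.T) + eps)
        # ||V - WH||^2 = ||V||^2 - 2<W^T V, H> + <W^T W, H H^T>
        gram = (W.T @ W) * (H @ H.T)
        cross = float((W.T @ V * H).sum())
        obj2 = max(v_norm2 - 2.0 * cross + float(gram.sum()), 0.0)
        obj = np.sqrt(obj2)
        trace.append(obj)
        if prev < np.inf and prev - obj < tol * max(prev, 1e-12):
            break
        prev = obj
    return NmfFactorization(W=W, H=H, objective_trace=trace, seed=seed)


# ---------------------------------------------------------------------------
# consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    k: int
    consensus: pd.DataFrame  # sample x sample in [0, 1]
    labels: pd.Series  # per-sample cluster in 1..k
    cophenetic: float
    mean_silhouette: float
    n_init: int
    degenerate: bool = False


def consensus_cluster(V: pd.DataFrame, k: int, n_init: int = 1000, seed: int = 0,
                      max_iter: int = 100, tol: float = 1e-4) -> ConsensusResult:
    """Consensus over ``n_init`` random NMF restarts at rank ``k``.

    Each restart assigns samples to the argmax row of H; consensus[i,j] is
    the co-clustering fraction. Final labels cut an average-linkage tree of
    (1 - consensus) into k groups; the cophenetic coefficient is the
    Pearson correlation between (1 - consensus) distances and the tree's
    cophenetic distances, and the silhouette uses (1 - consensus) as the
    dissimilarity. Restarts run a capped number of multiplicative updates:
    the partition stabilises long before the objective converges.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    samples = list(V.columns)
    n = len(samples)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({n})")
    Va = V.to_numpy(dtype=float)
    child_seeds = np.random.SeedSequence(seed).spawn(n_init)
    co = np.zeros((n, n))
    for ss in child_seeds:
        fit = nmf_factorize(Va, k, seed=int(ss.generate_state(1)[0] % (2 ** 31)),
                            max_iter=max_iter, tol=tol)
        assign = fit.H.argmax(axis=0)
        co += (assign[:, None] == assign[None, :])
    consensus = co / n_init
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = average(condensed)
    coph_d = cophenet(Z)
    if np.ptp(condensed) == 0 or np.ptp(coph_d) == 0:
        cophenetic = float("nan")  # degenerate: all distances identical
    else:
        cophenetic = float(pearsonr(condensed, coph_d)[0])
    labels = fcluster(Z, t=k, criterion="maxclust")
    degenerate = len(np.unique(labels)) < k
    if degenerate:
        logger.warning("consensus at k=%d yields only %d distinct clusters",
                       k, len(np.unique(labels)))
    if len(np.unique(labels)) >= 2 and np.ptp(condensed) > 0:
        sil = float(silhouette_score(dist, labels, metric="precomputed"))
    else:
        sil = float("nan")
    return ConsensusResult(
        k=k,
        consensus=pd.DataFrame(consensus, index=samples, columns=samples),
        labels=pd.Series(labels, index=samples, name="cluster"),
        cophenetic=cophenetic, mean_silhouette=sil, n_init=n_init,
        degenerate=degenerate,
    )


def rank_survey(V: pd.DataFrame, k_range: range | list[int] = range(2, 8),
                n_init: int = 1000, seed: int = 0, max_iter: int = 100,
                tol: float = 1e-4) -> tuple[pd.DataFrame, dict[int, ConsensusResult]]:
    """One ConsensusResult per rank; returns (metric table sorted by k, results)."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty k range")
    results = {}
    rows = []
    for k in ks:
        res = consensus_cluster(V, k, n_init=n_init, seed=seed,
                                max_iter=max_iter, tol=tol)
        results[k] = res
        rows.append({"k": k, "cophenetic": res.cophenetic,
                     "mean_silhouette": res.mean_silhouette,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows).set_index("k"), results


def assign_subtypes(survey: pd.DataFrame, results: dict[int, ConsensusResult],
                    k_override: int | None = None, drop_tol: float = 0.05,
                    min_class: int = 5) -> tuple[pd.Series, int]:
    """Choose the rank and return final labels (renamed by class size).

    Default rule: the largest k whose cophenetic coefficient is within
    ``drop_tol`` of the maximum over the surveyed range and whose smallest
    class has >= ``min_class`` samples. ``k_override`` bypasses the rule.
    Labels are renamed P1, P2, ... by decreasing class size (nominal, not
    ordinal).
    """
    if survey.empty:
        raise ValueError("empty rank survey")
    if k_override is not None:
        chosen = int(k_override)
        if chosen not in results:
            raise ValueError(f"k_override={chosen} not among surveyed ranks {list(results)}")
    else:
        best = survey["cophenetic"].max()
        chosen = None
        for k in sorted(results):
            counts = results[k].labels.value_counts()
            if survey.loc[k, "cophenetic"] >= best - drop_tol and counts.min() >= min_class:
                chosen = k
        if chosen is None:
            raise ValueError(
                f"no surveyed k satisfies min_class={min_class}; "
                "use k_override or lower min_class")
    raw = results[chosen].labels
    order = raw.value_counts().index  # decreasing size
    rename = {old: f"P{i + 1}" for i, old in enumerate(order)}
    return raw.map(rename).rename("subtype"), chosen
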