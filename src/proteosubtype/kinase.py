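"""Kinase-activity inference from phosphosite fold changes.

Phosphosite-level log2 fold changes between groups are aggregated over
each kinase's annotated substrate sites into a KSEA-style z-statistic:

    z = (mean substrate FC - mean of all site FCs) * sqrt(m) / SD of all site FCs

with m the number of annotated sites present. A positive z means the
kinase's substrates shifted up relative to the global site distribution,
i.e. inferred activation. The substrate aggregation function is exposed so
alternative statistics can be plugged in.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import KinaseSubstrateMap, OmicsMatrix, logger
from .normalize import bh_adjust

# feature IDs like "P12345_S10" or multi-site "P12345_S10;T14":
# a site is one residue letter followed by its position
_SITE_RE = re.compile(r"^[A-Za-z]\d+$")


def expand_sites(phospho: OmicsMatrix) -> OmicsMatrix:
    """Expand multi-site phosphopeptide rows into one row per (protein, site).

    ``"P1_S10;T14"`` becomes rows ``"P1_S10"`` and ``"P1_T14"`` with
    identical values. When an expanded row collides with an existing row
    for the same site, the values are averaged (logged).
    """
    rows: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    for fid in phospho.feature_ids:
        if "_" not in fid:
            raise ValueError(f"unparseable phosphosite feature ID (no protein_site): {fid!r}")
        protein, site_part = fid.rsplit("_", 1)
        sites = site_part.split(";")
        for site in sites:
            if not _SITE_RE.match(site):
                raise ValueError(f"unparseable site annotation {site!r} in feature {fid!r}")
            key = f"{protein}_{site}"
            if key not in rows:
                rows[key] = []
                order.append(key)
            rows[key].append(phospho.data.loc[fid].to_numpy(dtype=float))
    data = {}
    for key in order:
        vals = rows[key]
        if len(vals) > 1:
            logger.info("site %s measured %d times; values averaged", key, len(vals))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns stay NaN
            data[key] = np.nanmean(np.vstack(vals), axis=0)
    out = pd.DataFrame(data, index=phospho.sample_ids).T
    return OmicsMatrix(out, phospho.scale_tag, "phosphosite")


@dataclass
class KinaseScore:
    kinase_id: str
    z: float
    n_substrate_sites: int
    mean_site_fc: float
    p: float
    q: float


def substrate_fold_changes(site_fc: pd.Series, ks: KinaseSubstrateMap,
                           kinase: str) -> pd.Series:
    """The fold changes of a kinase's annotated sites present in the data."""
    sites = [s for s in ks.sites_of(kinase) if s in site_fc.index]
    return site_fc.loc[sites]


def kinase_scores(site_fc: pd.Series, ks: KinaseSubstrateMap,
                  min_sites: int = 3) -> pd.DataFrame:
    """Score every kinase with >= ``min_sites`` annotated sites present.

    Negating all fold changes negates every z exactly; duplicated
    (kinase, substrate, site) records are deduplicated on load and do not
    affect scores.
    """
    site_fc = site_fc.astype(float)
    if not np.isfinite(site_fc.to_numpy()).all():
        raise ValueError("fold changes must be finite")
    all_fc = site_fc.to_numpy()
    mu, sd = all_fc.mean(), all_fc.std(ddof=1)
    rows = []
    any_overlap = False
    for kinase in ks.kinases:
        sub = substrate_fold_changes(site_fc, ks, kinase)
        m = len(sub)
        if m > 0:
            any_overlap = True
        if m < min_sites:
            continue
        if sd == 0:
            z = 0.0
        else:
            z = float((sub.mean() - mu) * np.sqrt(m) / sd)
        p = float(2 * stats.norm.sf(abs(z)))
        rows.append({"kinase_id": kinase, "z": z, "n_substrate_sites": m,
                     "mean_site_fc": float(sub.mean()), "p": p})
    if not any_overlap:
        raise ValueError("no kinase-substrate annotation overlaps the fold-change sites")
    out = pd.DataFrame(rows, columns=["kinase_id", "z", "n_substrate_sites",
                                      "mean_site_fc", "p"])
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out.set_index("kinase_id")


def kinase_substrate_edges(scores: pd.DataFrame, site_fc: pd.Series,
                           ks: KinaseSubstrateMap) -> pd.DataFrame:
    """Plain edge list (kinase, site, site_fc, kinase_z) for network export."""
    rows = []
    for kinase in scores.index:
        for site in ks.sites_of(kinase):
            if site in site_fc.index:
                rows.append({"kinase_id": kinase, "site_id": site,
                             "site_fc": float(site_fc[site]),
                             "kinase_z": float(scores.loc[kinase, "z"])})
    return pd.DataFrame(rows, columns=["kinase_id", "site_id", "site_fc", "kinase_z"])
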