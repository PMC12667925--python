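"""Benchmark harnesses: planted-truth recovery under the study conditions.

These helpers compose the pipeline stages into repeatable benchmarks on
synthetic cohorts — subtype recovery with rank-survey metrics, IRS batch
removal, differential-abundance calibration, cis-effect recovery and
subtype-transfer classification — returning plain dictionaries of the
measured quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .associate import (cis_trans_map, fit_subtype_classifier,
                        select_transfer_features)
from .instability import score_profiles
from .io import OmicsMatrix, default_genome
from .normalize import (differential_abundance, irs_correct, normalize_pipeline,
                        sample_loading_normalize)
from .simulate import SimulationConfig, simulate_cohort
from .subtype import assign_subtypes, prepare_nmf_input, rank_survey

#: cohort dimensions used by the benchmarks (scaled-down feature space;
#: the clustering input is the top-500 MAD features either way)
BENCH_SIZES = dict(n_proteins=700, n_phosphosites=600, n_mrna=700)


def _tumor_only(m: OmicsMatrix, samples) -> OmicsMatrix:
    refs = set(samples.reference_samples())
    return m.with_data(m.data[[s for s in m.sample_ids if s not in refs]])


def subtype_recovery_benchmark(n_seeds: int = 5, n_samples: int = 60,
                               n_init: int = 200, seed: int = 0,
                               k_range: tuple[int, int] = (2, 5),
                               top_n: int = 500) -> dict:
    """Full-pipeline planted-subtype recovery under the study conditions:
    3 balanced subtypes, 1.0 log2 signature effect, plex batch effects on,
    20% missingness. Reports per-seed and median ARI (labels at the known
    rank k=3, the cohort design's fixed choice) and the consensus rank
    survey metrics.
    """
    rows = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_samples=n_samples, seed=seed + i, signature_effect=1.0,
            missing_rate=0.20, missing_mode="random", **BENCH_SIZES)
        cohort = simulate_cohort(cfg)
        prot, _ = normalize_pipeline(cohort.protein, cohort.samples)
        phos, _ = normalize_pipeline(cohort.phospho, cohort.samples)
        V = prepare_nmf_input(_tumor_only(prot, cohort.samples),
                              _tumor_only(phos, cohort.samples), top_n=top_n)
        survey, results = rank_survey(
            V, range(k_range[0], k_range[1] + 1), n_init=n_init,
            seed=1000 + seed + i)
        labels, _ = assign_subtypes(survey, results, k_override=3)
        truth = cohort.truth.true_labels.loc[labels.index]
        co = survey["cophenetic"]
        rows.append({
            "ari": adjusted_rand_score(truth, labels),
            "cophenetic_k2": co.get(2, np.nan),
            "cophenetic_k3": co.get(3, np.nan),
            "cophenetic_k4": co.get(4, np.nan),
            "drop_k4": co.get(3, np.nan) - co.get(4, np.nan),
        })
    per_seed = pd.DataFrame(rows)
    out = {f"median_{c}": float(per_seed[c].median()) for c in per_seed.columns}
    out["per_seed"] = rows
    out["n_samples"] = n_samples
    out["n_seeds"] = n_seeds
    return out


def irs_batch_removal_benchmark(seed: int = 0, n_samples: int = 30) -> dict:
    """Between-plex variance of pooled-reference channels before vs after IRS."""
    cfg = SimulationConfig(n_samples=n_samples, samples_per_plex=11,
                           batch_effect_sd=0.5, missing_rate=0.0, seed=seed,
                           **BENCH_SIZES)
    cohort = simulate_cohort(cfg)
    refs = cohort.samples.reference_samples()
    sl = sample_loading_normalize(cohort.protein)
    corrected = irs_correct(sl, cohort.samples)

    def ref_variance(m: OmicsMatrix) -> float:
        return float(np.nanvar(np.log2(m.data[refs].to_numpy()), axis=1).mean())

    before, after = ref_variance(sl), ref_variance(corrected)
    return {"variance_before": before, "variance_after": after,
            "ratio": after / before, "n_plexes": len(refs)}


def de_calibration_benchmark(seed: int = 0, n_features: int = 1000,
                             n_shifted: int = 100, n_per_group: int = 20,
                             shift_sds: float = 2.0) -> dict:
    """Type-I error at p<0.05 on null features and power at q<0.05 for
    features shifted by ``shift_sds`` pooled standard deviations."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(n_features, 2 * n_per_group))
    X[:n_shifted, n_per_group:] += shift_sds
    df = pd.DataFrame(X, index=[f"f{i}" for i in range(n_features)],
                      columns=[f"s{j}" for j in range(2 * n_per_group)])
    m = OmicsMatrix(df, "log2", "protein")
    res = differential_abundance(m, [f"s{j}" for j in range(n_per_group)],
                                 [f"s{j}" for j in range(n_per_group, 2 * n_per_group)])
    return {
        "power": float((res["q"][:n_shifted] < 0.05).mean()),
        "type_i_error": float((res["p"][n_shifted:] < 0.05).mean()),
        "n_features": n_features, "n_per_group": n_per_group,
    }


def cis_effect_benchmark(seed: int = 0, n_samples: int = 60) -> dict:
    """Null cis false-discovery proportion and planted cis-gene recovery."""
    rng = np.random.default_rng(seed)
    n_genes, n_samp = 1000, 40
    cn = rng.integers(0, 5, size=(n_genes, n_samp)).astype(float)
    expr = rng.normal(0, 1, size=(n_genes, n_samp))
    genes = [f"g{i}" for i in range(n_genes)]
    cols = [f"s{j}" for j in range(n_samp)]
    _, null_summary = cis_trans_map(
        OmicsMatrix(pd.DataFrame(cn, index=genes, columns=cols),
                    "raw_intensity", "cna_gene"),
        mrna=OmicsMatrix(pd.DataFrame(expr, index=genes, columns=cols),
                         "log2", "mrna"), fdr=0.1)
    null_fdp = null_summary["n_cis_mrna"] / n_genes

    cohort = simulate_cohort(SimulationConfig(
        n_samples=n_samples, cis_gene_count=100, cis_effect_slope=0.5,
        seed=seed, **BENCH_SIZES))
    records, _ = cis_trans_map(cohort.cna, mrna=cohort.mrna, fdr=0.1)
    hits = set(records[(records["is_cis"]) & (records["level"] == "mrna")
                       & (records["q"] < 0.1)]["cna_gene"])
    planted = set(cohort.truth.cis_genes)
    return {"null_fdp": float(null_fdp),
            "recovery": float(len(hits & planted) / len(planted)),
            "n_planted": len(planted), "n_samples": n_samples}


def transfer_benchmark(seed: int = 0, n_per_class: int = 12) -> dict:
    """DE-filtered feature selection (FDR<0.01, |FC|>2) + held-out macro F1 of
    the default classifier on separable synthetic classes."""
    rng = np.random.default_rng(seed)
    n = 3 * n_per_class
    labels = pd.Series(["P1", "P2", "P3"] * n_per_class,
                       index=[f"s{i}" for i in range(n)])
    X = rng.normal(0, 0.4, size=(200, n))
    for k, cls in enumerate(["P1", "P2", "P3"]):
        members = np.flatnonzero((labels == cls).to_numpy())
        X[k * 10:(k + 1) * 10, members] += 3.0
    expr = OmicsMatrix(pd.DataFrame(X, index=[f"g{i}" for i in range(200)],
                                    columns=labels.index), "log2", "mrna")
    features = select_transfer_features(expr, labels, fdr=0.01, min_abs_fc=2.0)
    _, per_class, macro = fit_subtype_classifier(expr, labels, features, seed=seed)
    return {"macro_f1": float(macro), "n_features": len(features), "n_samples": n}


def instability_consistency_benchmark(seed: int = 0) -> dict:
    """Deterministic generator/scorer agreement across a grid of targets."""
    from .simulate import InstabilityTargets, simulate_segments
    from .instability import hrd_score
    genome = default_genome()
    rng = np.random.default_rng(seed)
    max_err = 0
    n = 0
    for _ in range(30):
        n_lst = int(rng.integers(0, 10))
        n_tai = int(rng.integers(0, 8))
        t = InstabilityTargets(
            n_hrd_loh=int(rng.integers(0, 10)), n_lst=n_lst, n_tai=n_tai,
            n_loss=int(rng.integers(0, 8)),
            n_gain=n_lst + n_tai + int(rng.integers(0, 6)),
            wgd_prob=float(rng.random()))
        prof, exp = simulate_segments(t, genome,
                                      seed=int(rng.integers(0, 2 ** 31)))
        s = hrd_score(prof, genome)
        err = max(abs(s.hrd_loh - t.n_hrd_loh), abs(s.lst - t.n_lst),
                  abs(s.tai - t.n_tai), abs(s.hrd - (t.n_hrd_loh + t.n_lst + t.n_tai)),
                  abs(s.cin - exp["cin"]))
        max_err = max(max_err, err)
        n += 1
    return {"max_abs_error": int(max_err), "n_profiles": n}
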