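"""Synthetic multi-omic sarcoma-like cohort with planted ground truth.

The generator emits everything the pipeline consumes — TMT-style protein
and phosphosite intensity matrices with plex batch effects and pooled
reference channels, an mRNA matrix, gene-level copy-number values with
planted cis effects, per-sample allele-specific segment profiles built to
hit requested instability scores, a kinase-substrate annotation map with
planted kinase-driven phosphosite shifts, an alteration-call matrix, gene
sets and subtype-dependent survival — together with a ``SyntheticTruth``
record of every planted parameter.

Model choices:

* batch effects are multiplicative on raw intensity (additive on log2),
  constant per plex per feature — the structure internal reference
  scaling assumes and removes;
* pooled-reference channels equal the arithmetic mean of their plex's
  raw intensities before batch and noise are applied — the premise of
  IRS correction;
* intensity-dependent missingness is a logistic dropout on log2
  abundance, emulating MS detection limits;
* survival is exponential with one hazard rate per subtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    AlterationMatrix,
    ALTERATION_PRECEDENCE,
    GeneSetCollection,
    GenomeBuild,
    KinaseSubstrateMap,
    OmicsMatrix,
    SampleTable,
    Segment,
    SegmentProfile,
    default_genome,
)

MB = 1_000_000
GUARD = 4 * MB  # uncovered gap flanking every planted scar element

# element geometries: (length, (total, major, minor))
_TAI_ELEMENT = (20 * MB, (3, 2, 1))
_LOH_ELEMENT = (20 * MB, (2, 2, 0))      # copy-neutral LOH, > 15 Mb
_LST_LEFT = (12 * MB, (2, 1, 1))
_LST_RIGHT = (12 * MB, (3, 2, 1))
_GAIN_ELEMENT = (8 * MB, (5, 3, 2))
_LOSS_ELEMENT = (8 * MB, (0, 0, 0))


@dataclass
class InstabilityTargets:
    """Requested per-sample instability profile.

    ``n_gain`` is the total gain-segment count and must be at least
    ``n_lst + n_tai`` because each planted LST and TAI element carries one
    gained segment. ``n_loh_segments`` equals ``n_hrd_loh`` by
    construction (every planted LOH scar is copy-neutral LOH).
    """

    ploidy: float = 2.0
    wgd_prob: float = 0.0
    n_hrd_loh: int = 0
    n_lst: int = 0
    n_tai: int = 0
    n_gain: int = 0
    n_loss: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hrd_loh, self.n_lst, self.n_tai, self.n_gain, self.n_loss) < 0:
            raise ValueError("instability counts must be >= 0")
        if not 0 <= self.wgd_prob <= 1:
            raise ValueError("wgd_prob must be in [0, 1]")
        if self.n_gain < self.n_lst + self.n_tai:
            raise ValueError(
                f"n_gain={self.n_gain} < n_lst + n_tai = {self.n_lst + self.n_tai}: "
                "each LST and TAI element contributes one gain segment")


DEFAULT_TARGETS = {
    # stable subtype; CIN subtype; WGD + proliferative subtype
    "P1": InstabilityTargets(ploidy=2.0, wgd_prob=0.0, n_hrd_loh=1, n_lst=1,
                             n_tai=1, n_gain=4, n_loss=2),
    "P2": InstabilityTargets(ploidy=2.0, wgd_prob=0.1, n_hrd_loh=8, n_lst=8,
                             n_tai=6, n_gain=18, n_loss=8),
    "P3": InstabilityTargets(ploidy=4.0, wgd_prob=0.9, n_hrd_loh=6, n_lst=6,
                             n_tai=5, n_gain=14, n_loss=6),
}


@dataclass
class SimulationConfig:
    n_samples: int = 72
    n_subtypes: int = 3
    samples_per_plex: int = 16  # TMT plex width, includes 1 pooled-reference channel
    n_proteins: int = 1200
    n_phosphosites: int = 800
    n_mrna: int = 1000
    signature_size: int = 50  # per subtype, per matrix
    signature_effect: float = 1.0  # log2 shift on signature features
    batch_effect_sd: float = 0.4  # log2 SD of per-plex per-feature batch factors
    biological_sd: float = 0.35  # log2 SD of per-sample within-subtype variation
    noise_sd: float = 0.15  # log2 SD of per-channel technical measurement noise
    missing_rate: float = 0.30
    missing_mode: str = "intensity_dependent"  # or "random"
    n_programs: int = 8  # latent expression programs shared across subtypes
    program_sd: float = 0.30  # log2 amplitude of program loadings
    program_density: float = 0.25  # fraction of features loading on each program
    program_subtype_shift: float = 0.5  # SD of per-subtype program mean offsets
    mixed_fraction: float = 0.15  # samples with partial identity in a 2nd subtype
    n_crosscut_states: int = 3  # binary sample states orthogonal to subtype
    crosscut_effect: float = 0.4  # log2 shift of state-positive samples
    crosscut_fraction: float = 0.3  # fraction of samples positive per state
    crosscut_size: int = 40  # features per state, per matrix
    cis_gene_count: int = 100
    cis_effect_slope: float = 0.5  # log2 per copy
    kinase_count: int = 20
    substrates_per_kinase: int = 8
    kinase_effect: float = 1.0  # log2 shift on active kinases' substrate sites
    multi_site_fraction: float = 0.03
    instability_targets: dict[str, InstabilityTargets] = field(
        default_factory=lambda: dict(DEFAULT_TARGETS))
    segment_mode: str = "deterministic"  # or "stochastic"
    hazard_rates: tuple[float, ...] = (0.10, 0.50, 0.25)  # per subtype, events / time unit
    censor_horizon: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_subtypes", "n_proteins", "n_phosphosites",
                     "n_mrna", "signature_size", "cis_gene_count", "kinase_count",
                     "substrates_per_kinase"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.samples_per_plex < 2:
            raise ValueError("samples_per_plex must be >= 2 (one channel is the pooled reference)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.missing_mode not in ("random", "intensity_dependent"):
            raise ValueError(f"unknown missing_mode {self.missing_mode!r}")
        if self.signature_size * self.n_subtypes > self.n_proteins:
            raise ValueError("signature_size * n_subtypes exceeds n_proteins")
        if self.signature_size * self.n_subtypes > self.n_phosphosites:
            raise ValueError("signature_size * n_subtypes exceeds n_phosphosites")
        for eff in (self.signature_effect, self.batch_effect_sd, self.noise_sd,
                    self.biological_sd, self.cis_effect_slope, self.kinase_effect):
            if not np.isfinite(eff):
                raise ValueError("effects must be finite")
        if len(self.hazard_rates) < self.n_subtypes:
            raise ValueError("need one hazard rate per subtype")


@dataclass
class SyntheticTruth:
    true_labels: pd.Series
    signature_features: dict[str, dict[str, list[str]]]
    cis_genes: list[str]
    kinase_targets: dict[str, tuple[str, list[str]]]  # kinase -> (active subtype, sites)
    expected_instability: pd.DataFrame
    hazard_rates: dict[str, float]
    alteration_frequencies: pd.Series
    seed: int


@dataclass
class SyntheticCohort:
    protein: OmicsMatrix
    phospho: OmicsMatrix
    mrna: OmicsMatrix
    cna: OmicsMatrix
    samples: SampleTable
    segment_profiles: list[SegmentProfile]
    ks_map: KinaseSubstrateMap
    gene_sets: GeneSetCollection
    alterations: AlterationMatrix
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# segment simulation
# ---------------------------------------------------------------------------

def simulate_segments(targets: InstabilityTargets, genome: GenomeBuild | None = None,
                      seed: int = 0, mode: str = "deterministic",
                      sample_id: str = "synthetic",
                      ) -> tuple[SegmentProfile, dict]:
    """Build a segment profile scoring at the requested instability targets.

    In ``deterministic`` mode the profile scores *exactly* at
    (n_hrd_loh, n_lst, n_tai) and at the derived gain/loss/LOH counts; in
    ``stochastic`` mode element counts are Poisson-drawn around the
    targets (the expectation matches). Every scar element sits inside one
    chromosome arm with >= 4 Mb uncovered guard gaps so elements never
    interact; the rest of the genome is diploid (2,1,1) filler, or
    tetraploid (4,2,2) filler in whole-genome-doubled samples (whose
    maximal filler runs each count as one gain). Returns the profile and
    the expected-score accounting.
    """
    if genome is None:
        genome = default_genome()
    if mode not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if mode == "deterministic":
        n_loh, n_lst, n_tai = targets.n_hrd_loh, targets.n_lst, targets.n_tai
        n_gain_extra = targets.n_gain - targets.n_lst - targets.n_tai
        n_loss = targets.n_loss
        wgd = targets.wgd_prob >= 0.5
    else:
        n_lst = int(rng.poisson(targets.n_lst))
        n_tai = int(rng.poisson(targets.n_tai))
        n_loh = int(rng.poisson(targets.n_hrd_loh))
        n_gain_extra = int(rng.poisson(max(targets.n_gain - targets.n_lst - targets.n_tai, 0)))
        n_loss = int(rng.poisson(targets.n_loss))
        wgd = bool(rng.random() < targets.wgd_prob)

    autos = genome.autosomes
    planted: dict[str, list[tuple[int, int, tuple[int, int, int]]]] = {c: [] for c in autos}
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in autos}

    # telomeric TAI elements: p- then q-telomere slots, one per arm
    tai_len, tai_state = _TAI_ELEMENT
    slots = []
    for c in autos:
        cs, ce = genome.centromere(c)
        ln = genome.length(c)
        if tai_len + GUARD <= cs:
            slots.append((c, "p"))
        if ce + GUARD <= ln - tai_len:
            slots.append((c, "q"))
    if n_tai > len(slots):
        raise ValueError(
            f"n_tai={n_tai} exceeds the {len(slots)} available telomere slots")
    tai_arm_used: set[tuple[str, str]] = set()
    for (c, arm) in slots[:n_tai]:
        ln = genome.length(c)
        if arm == "p":
            start, end = 0, tai_len
        else:
            start, end = ln - tai_len, ln
        planted[c].append((start, end, tai_state))
        blocked[c].append((max(start - GUARD, 0), min(end + GUARD, ln)))
        tai_arm_used.add((c, arm))

    # interior elements, first-fit across arms with a per-arm cursor
    interior: list[list[tuple[int, tuple[int, int, int]]]] = []
    for _ in range(n_lst):
        interior.append([(_LST_LEFT[0], _LST_LEFT[1]), (_LST_RIGHT[0], _LST_RIGHT[1])])
    for _ in range(n_loh):
        interior.append([(_LOH_ELEMENT[0], _LOH_ELEMENT[1])])
    for _ in range(n_gain_extra):
        interior.append([(_GAIN_ELEMENT[0], _GAIN_ELEMENT[1])])
    for _ in range(n_loss):
        interior.append([(_LOSS_ELEMENT[0], _LOSS_ELEMENT[1])])

    cursors: dict[tuple[str, str], int] = {}
    arm_list = []
    for c in autos:
        for arm, (lo, hi) in genome.arms(c).items():
            arm_list.append((c, arm, lo, hi))
            # skip past any telomeric TAI element on this arm
            if (c, arm) in tai_arm_used:
                cursors[(c, arm)] = (tai_len if arm == "p"
                                     else lo)  # q-arm TAI sits at the far end
            else:
                cursors[(c, arm)] = lo
    # q-arm TAI occupies [len - tai_len, len): shrink that arm's usable end
    arm_end: dict[tuple[str, str], int] = {}
    for c, arm, lo, hi in arm_list:
        if (c, arm) in tai_arm_used and arm == "q":
            arm_end[(c, arm)] = hi - tai_len
        else:
            arm_end[(c, arm)] = hi

    for piece_group in interior:
        total_len = sum(L for L, _ in piece_group)
        placed = False
        for c, arm, lo, hi in arm_list:
            cur = cursors[(c, arm)]
            start = cur + GUARD
            end = start + total_len
            if end + GUARD <= arm_end[(c, arm)]:
                pos = start
                for L, state in piece_group:
                    planted[c].append((pos, pos + L, state))
                    pos += L
                blocked[c].append((start - GUARD, end + GUARD))
                cursors[(c, arm)] = end
                placed = True
                break
        if not placed:
            raise ValueError(
                "cannot place all requested scar elements: genome arm capacity "
                f"exhausted at a {total_len / MB:.0f} Mb element")

    # filler: complement of blocked regions
    filler_cn = (4, 2, 2) if wgd else (2, 1, 1)
    segments: list[Segment] = []
    n_filler_runs = 0
    for c in autos:
        ln = genome.length(c)
        for start, end, (t, ma, mi) in planted[c]:
            segments.append(Segment(c, start, end, t, ma, mi))
        ivs = sorted(blocked[c])
        merged: list[list[int]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        pos = 0
        for a, b in merged + [[ln, ln]]:
            if a > pos:
                segments.append(Segment(c, pos, a, filler_cn[0],
                                        filler_cn[1], filler_cn[2]))
                n_filler_runs += 1
            pos = max(pos, b)

    profile = SegmentProfile(sample_id, segments)

    # expected-score accounting by direct interval arithmetic
    covered = sum(s.length for s in profile.segments)
    ploidy = sum(s.length * s.total_cn for s in profile.segments) / covered
    major_ge2 = sum(s.length for s in profile.segments if s.major_cn >= 2)
    expected = {
        "ploidy": ploidy,
        "wgd": major_ge2 / genome.autosomal_length() > 0.5,
        "hrd_loh": n_loh, "lst": n_lst, "tai": n_tai,
        "hrd": n_loh + n_lst + n_tai,
        "n_gain": n_gain_extra + n_lst + n_tai + (n_filler_runs if wgd else 0),
        "n_loss": n_loss,
        "n_loh_segments": n_loh,
    }
    expected["cin"] = expected["n_gain"] + expected["n_loss"] + expected["n_loh_segments"]
    return profile, expected


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _subtype_names(n: int) -> list[str]:
    return [f"P{i + 1}" for i in range(n)]


def _tmt_matrix(rng: np.random.Generator, feature_ids: list[str],
                sample_ids: list[str], plex_of: dict[str, str],
                base_log2: np.ndarray, effects_log2: np.ndarray,
                cfg: SimulationConfig) -> pd.DataFrame:
    """Raw-intensity matrix with pooled-reference channels, batch and noise.

    ``base_log2``: per-feature baseline; ``effects_log2``: feature x sample
    planted shifts. Biological between-sample variation enters before the
    pooled-reference channels (IDs ``REF_<plex>``) are formed — the pool is
    made from the samples themselves — so references equal the plex's
    arithmetic mean raw intensity pre-batch, pre-technical-noise; batch
    factors and technical noise then apply to every channel alike.
    """
    L0 = base_log2[:, None] + effects_log2
    if cfg.biological_sd > 0:
        L0 = L0 + rng.normal(0.0, cfg.biological_sd, size=L0.shape)
    raw0 = np.power(2.0, L0)
    plexes = list(dict.fromkeys(plex_of[s] for s in sample_ids))
    cols = {}
    for j, s in enumerate(sample_ids):
        cols[s] = raw0[:, j]
    for p in plexes:
        members = [j for j, s in enumerate(sample_ids) if plex_of[s] == p]
        cols[f"REF_{p}"] = raw0[:, members].mean(axis=1)
    all_ids = sample_ids + [f"REF_{p}" for p in plexes]
    M = np.column_stack([cols[s] for s in all_ids])
    batch = np.power(2.0, rng.normal(0.0, cfg.batch_effect_sd,
                                     size=(len(feature_ids), len(plexes))))
    plex_index = {p: i for i, p in enumerate(plexes)}
    col_plex = [plex_index[plex_of.get(s, s.removeprefix("REF_"))] for s in all_ids]
    M = M * batch[:, col_plex]
    if cfg.noise_sd > 0:
        M = M * np.power(2.0, rng.normal(0.0, cfg.noise_sd, size=M.shape))
    return pd.DataFrame(M, index=feature_ids, columns=all_ids)


def _inject_missing(rng: np.random.Generator, df: pd.DataFrame,
                    cfg: SimulationConfig) -> pd.DataFrame:
    if cfg.missing_rate == 0:
        return df
    if cfg.missing_mode == "random":
        drop = rng.random(df.shape) < cfg.missing_rate
    else:
        # logistic dropout on log2 abundance around the missing_rate quantile
        L = np.log2(df.to_numpy())
        x0 = np.quantile(L, cfg.missing_rate)
        p = 1.0 / (1.0 + np.exp((L - x0) / 1.0))
        p *= cfg.missing_rate / max(p.mean(), 1e-9)  # calibrate the overall rate
        drop = rng.random(df.shape) < np.clip(p, 0, 1)
    out = df.to_numpy(dtype=float).copy()
    out[drop] = np.nan
    # keep every feature observed somewhere (the filter/impute contract)
    lost = np.isnan(out).all(axis=1)
    out[lost, 0] = df.to_numpy()[lost, 0]
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def simulate_cohort(config: SimulationConfig | None = None,
                    genome: GenomeBuild | None = None) -> SyntheticCohort:
    """Generate the full synthetic cohort. Identical seed => identical output."""
    cfg = config or SimulationConfig()
    if genome is None:
        genome = default_genome()
    rng = np.random.default_rng(cfg.seed)
    subtypes = _subtype_names(cfg.n_subtypes)
    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    labels = pd.Series([subtypes[i % cfg.n_subtypes] for i in range(cfg.n_samples)],
                       index=sample_ids, name="subtype")

    # plex layout: consecutive chunks of (samples_per_plex - 1) real channels
    real_per_plex = cfg.samples_per_plex - 1
    plex_of = {s: f"plex{(i // real_per_plex) + 1}" for i, s in enumerate(sample_ids)}

    n_genes = max(cfg.n_proteins, cfg.n_mrna)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    prot_genes = genes[:cfg.n_proteins]
    mrna_genes = genes[:cfg.n_mrna]

    # disjoint feature allocations: per-subtype protein signatures, cis genes
    pool = rng.permutation(min(cfg.n_proteins, cfg.n_mrna))
    sig_prot: dict[str, list[str]] = {}
    at = 0
    for st in subtypes:
        sig_prot[st] = sorted(genes[i] for i in pool[at:at + cfg.signature_size])
        at += cfg.signature_size
    if at + cfg.cis_gene_count > len(pool):
        raise ValueError("cis_gene_count + signatures exceed the shared gene space")
    cis_genes = sorted(genes[i] for i in pool[at:at + cfg.cis_gene_count])

    # gene-level integer copy number for a panel: cis genes + matched controls
    at += cfg.cis_gene_count
    n_ctrl = min(cfg.cis_gene_count, len(pool) - at)
    control_genes = sorted(genes[i] for i in pool[at:at + n_ctrl])
    panel = cis_genes + control_genes
    cn_vals = rng.choice([0, 1, 2, 3, 4], size=(len(panel), cfg.n_samples),
                         p=[0.05, 0.20, 0.40, 0.25, 0.10])
    cna = OmicsMatrix(pd.DataFrame(cn_vals.astype(float), index=panel,
                                   columns=sample_ids), "raw_intensity", "cna_gene")

    # latent expression programs: continuous per-sample activities shared by
    # both proteome layers, loading on random sparse feature subsets — the
    # within- and across-subtype heterogeneity real tumors carry. Programs
    # are partially subtype-aligned (a proliferation-like axis is higher in
    # some subtypes), so they crosscut rather than nest within subtypes.
    subtype_idx = np.array([subtypes.index(labels[s]) for s in sample_ids])
    program_means = rng.normal(0.0, cfg.program_subtype_shift,
                               size=(cfg.n_programs, cfg.n_subtypes))
    program_scores = program_means[:, subtype_idx] + \
        rng.normal(0.0, 1.0, size=(cfg.n_programs, cfg.n_samples))

    def program_effects(n_features: int) -> np.ndarray:
        load = (rng.random((n_features, cfg.n_programs)) < cfg.program_density)
        amp = rng.normal(0.0, 1.0, size=(n_features, cfg.n_programs)) * load
        # equalize program strengths so they genuinely compete for components
        norms = np.linalg.norm(amp, axis=0)
        target = cfg.program_sd * np.sqrt(cfg.program_density * n_features)
        amp = amp * (target / np.maximum(norms, 1e-9))
        return amp @ program_scores

    # binary crosscutting states (immune-hot/cold-like): subsets of samples
    # drawn independently of subtype share a block signature; several states
    # of equal strength compete for any extra factorization component
    state_members = [rng.random(cfg.n_samples) < cfg.crosscut_fraction
                     for _ in range(cfg.n_crosscut_states)]

    # intermediate samples: a fraction of the cohort carries a convex mix of
    # its own subtype signature and a second subtype's (tumors on a
    # biological continuum); the dominant side stays the true label
    mix_weight = np.ones(cfg.n_samples)  # weight on the own-subtype signature
    mix_partner = np.full(cfg.n_samples, -1)
    mixed = np.flatnonzero(rng.random(cfg.n_samples) < cfg.mixed_fraction)
    for i in mixed:
        others = [j for j in range(cfg.n_subtypes) if j != i % cfg.n_subtypes]
        mix_partner[i] = others[int(rng.integers(len(others)))]
        mix_weight[i] = rng.uniform(0.6, 0.85)
    # per-(subtype, sample) signature weights implied by the mixing
    subtype_weight = np.zeros((cfg.n_subtypes, cfg.n_samples))
    for i in range(cfg.n_samples):
        subtype_weight[i % cfg.n_subtypes, i] = mix_weight[i]
        if mix_partner[i] >= 0:
            subtype_weight[mix_partner[i], i] = 1.0 - mix_weight[i]

    def crosscut_effects(eff: np.ndarray, feature_pool: np.ndarray, at: int) -> int:
        for members in state_members:
            idx = feature_pool[at:at + cfg.crosscut_size]
            at += cfg.crosscut_size
            if len(idx) < cfg.crosscut_size:
                raise ValueError("crosscut states exceed available features")
            eff[np.ix_(idx, np.flatnonzero(members))] += cfg.crosscut_effect
        return at

    # ---- protein matrix -------------------------------------------------
    base_prot = rng.normal(18.0, 1.5, size=cfg.n_proteins)
    eff_prot = program_effects(cfg.n_proteins)
    prot_index = {g: i for i, g in enumerate(prot_genes)}
    for t, st in enumerate(subtypes):
        rows = [prot_index[g] for g in sig_prot[st]]
        eff_prot[rows] += cfg.signature_effect * subtype_weight[t]
    cn_centered = cn_vals - 2.0
    for gi, g in enumerate(panel):
        if g in prot_index and g in set(cis_genes):
            eff_prot[prot_index[g]] += 0.7 * cfg.cis_effect_slope * cn_centered[gi]
    at += n_ctrl
    # crosscut blocks need no mRNA counterpart: extend the pool with
    # protein-only indices before allocating them
    prot_only = rng.permutation(np.arange(len(pool), cfg.n_proteins))
    crosscut_pool = np.concatenate([pool[at:], prot_only])
    crosscut_effects(eff_prot, crosscut_pool, 0)
    prot_df = _tmt_matrix(rng, prot_genes, sample_ids, plex_of, base_prot, eff_prot, cfg)

    # ---- phosphosite matrix ---------------------------------------------
    residues = np.array(["S", "T", "Y"])
    host = rng.integers(0, cfg.n_proteins, size=cfg.n_phosphosites)
    positions = rng.integers(1, 999, size=cfg.n_phosphosites)
    res = residues[rng.integers(0, 3, size=cfg.n_phosphosites)]
    site_ids = []
    seen = set()
    for h, r, pos in zip(host, res, positions):
        sid = f"{prot_genes[h]}_{r}{pos}"
        while sid in seen:
            pos += 1
            sid = f"{prot_genes[h]}_{r}{pos}"
        seen.add(sid)
        site_ids.append(sid)
    n_multi = int(cfg.multi_site_fraction * cfg.n_phosphosites)
    multi_idx = rng.choice(cfg.n_phosphosites, size=n_multi, replace=False)
    feature_ids = list(site_ids)
    for i in multi_idx:
        extra_pos = int(positions[i]) + 1000
        r2 = residues[rng.integers(0, 3)]
        feature_ids[i] = f"{site_ids[i]};{r2}{extra_pos}"

    base_phos = rng.normal(16.0, 1.5, size=cfg.n_phosphosites)
    eff_phos = program_effects(cfg.n_phosphosites)
    phos_pool = rng.permutation(cfg.n_phosphosites)
    sig_phos: dict[str, list[str]] = {}
    at = 0
    for st in subtypes:
        idx = phos_pool[at:at + cfg.signature_size]
        sig_phos[st] = sorted(feature_ids[i] for i in idx)
        t = subtypes.index(st)
        eff_phos[idx] += cfg.signature_effect * subtype_weight[t]
        at += cfg.signature_size

    # kinase-driven shifts on disjoint substrate-site blocks
    need = cfg.kinase_count * cfg.substrates_per_kinase
    if at + need > cfg.n_phosphosites:
        raise ValueError("kinase substrate demand exceeds available phosphosites")
    kinase_targets: dict[str, tuple[str, list[str]]] = {}
    ks_rows = []
    for ki in range(cfg.kinase_count):
        kid = f"KIN{ki + 1:02d}"
        idx = phos_pool[at:at + cfg.substrates_per_kinase]
        at += cfg.substrates_per_kinase
        active = subtypes[ki % cfg.n_subtypes]
        sites = []
        for i in idx:
            sid = site_ids[i]  # single-site ID (map refers to expanded sites)
            gene = sid.rsplit("_", 1)[0]
            ks_rows.append({"kinase_id": kid, "substrate_id": gene, "site_id": sid})
            sites.append(sid)
            eff_phos[i, (labels == active).to_numpy()] += cfg.kinase_effect
        kinase_targets[kid] = (active, sorted(sites))
    at = crosscut_effects(eff_phos, phos_pool, at)
    ks_map = KinaseSubstrateMap(pd.DataFrame(ks_rows))
    phos_df = _tmt_matrix(rng, feature_ids, sample_ids, plex_of, base_phos, eff_phos, cfg)

    protein = OmicsMatrix(_inject_missing(rng, prot_df, cfg), "raw_intensity", "protein")
    phospho = OmicsMatrix(_inject_missing(rng, phos_df, cfg), "raw_intensity", "phosphosite")

    # ---- mRNA matrix (log2, complete) ------------------------------------
    base_mrna = rng.normal(8.0, 1.0, size=cfg.n_mrna)
    mrna_vals = base_mrna[:, None] + rng.normal(
        0.0, np.hypot(cfg.biological_sd, cfg.noise_sd),
        size=(cfg.n_mrna, cfg.n_samples))
    mrna_index = {g: i for i, g in enumerate(mrna_genes)}
    for gi, g in enumerate(panel):
        if g in mrna_index and g in set(cis_genes):
            mrna_vals[mrna_index[g]] += cfg.cis_effect_slope * cn_centered[gi]
    for st in subtypes:  # mild subtype structure at the transcript level
        members = (labels == st).to_numpy()
        for g in sig_prot[st]:
            if g in mrna_index:
                mrna_vals[mrna_index[g], members] += 0.5 * cfg.signature_effect
    mrna = OmicsMatrix(pd.DataFrame(mrna_vals, index=mrna_genes, columns=sample_ids),
                       "log2", "mrna")

    # ---- segments --------------------------------------------------------
    seg_seed = np.random.SeedSequence(cfg.seed).spawn(1)[0]
    seg_rngs = seg_seed.spawn(cfg.n_samples)
    profiles = []
    expected_rows = []
    for s, ss in zip(sample_ids, seg_rngs):
        targets = cfg.instability_targets[labels[s]]
        prof, exp = simulate_segments(
            targets, genome, seed=int(ss.generate_state(1)[0] % (2 ** 31)),
            mode=cfg.segment_mode, sample_id=s)
        profiles.append(prof)
        expected_rows.append({"sample_id": s, **exp})
    expected_instability = pd.DataFrame(expected_rows).set_index("sample_id")

    # ---- survival + sample table -----------------------------------------
    rate = {st: cfg.hazard_rates[i] for i, st in enumerate(subtypes)}
    os_draw = rng.exponential(1.0 / np.array([rate[labels[s]] for s in sample_ids]))
    rfs_draw = rng.exponential(1.0 / (1.5 * np.array([rate[labels[s]] for s in sample_ids])))
    os_time = np.minimum(os_draw, cfg.censor_horizon)
    os_event = (os_draw <= cfg.censor_horizon).astype(int)
    rfs_time = np.minimum(rfs_draw, cfg.censor_horizon)
    rfs_event = (rfs_draw <= cfg.censor_horizon).astype(int)

    rows = []
    for i, s in enumerate(sample_ids):
        rows.append({"sample_id": s, "plex_id": plex_of[s],
                     "channel_id": f"ch{(i % real_per_plex) + 1}",
                     "is_pooled_reference": False, "subtype_label": labels[s],
                     "tumor_status": "primary", "pair_id": np.nan,
                     "os_time": os_time[i], "os_event": os_event[i],
                     "rfs_time": rfs_time[i], "rfs_event": rfs_event[i]})
    for p in sorted(set(plex_of.values()), key=lambda x: int(x.removeprefix("plex"))):
        rows.append({"sample_id": f"REF_{p}", "plex_id": p,
                     "channel_id": f"ch{cfg.samples_per_plex}",
                     "is_pooled_reference": True, "subtype_label": np.nan,
                     "tumor_status": np.nan, "pair_id": np.nan,
                     "os_time": np.nan, "os_event": np.nan,
                     "rfs_time": np.nan, "rfs_event": np.nan})
    samples = SampleTable(pd.DataFrame(rows))

    # ---- gene sets --------------------------------------------------------
    sets = {f"SIG_{st}": (f"planted {st} protein signature", frozenset(sig_prot[st]))
            for st in subtypes}
    for i in range(10):
        members = rng.choice(prot_genes, size=20, replace=False)
        sets[f"RANDOM_{i + 1}"] = ("random control set", frozenset(members))
    gene_sets = GeneSetCollection(sets)

    # ---- alteration calls --------------------------------------------------
    alt_genes = [f"ALT{i + 1:02d}" for i in range(30)]
    freqs = pd.Series(rng.uniform(0.05, 0.7, size=len(alt_genes)), index=alt_genes)
    # plant a strongly co-occurring pair on the first two genes
    co_mask = rng.random(cfg.n_samples) < 0.5
    calls = pd.DataFrame("none", index=alt_genes, columns=sample_ids)
    call_types = list(ALTERATION_PRECEDENCE)
    for gi, g in enumerate(alt_genes):
        if gi < 2:
            hit = co_mask
        else:
            hit = rng.random(cfg.n_samples) < freqs[g]
        kinds = rng.choice(call_types, size=cfg.n_samples)
        calls.loc[g, hit] = kinds[hit]
        freqs[g] = hit.mean()
    alterations = AlterationMatrix(calls)

    truth = SyntheticTruth(
        true_labels=labels,
        signature_features={st: {"protein": sig_prot[st], "phospho": sig_phos[st]}
                            for st in subtypes},
        cis_genes=cis_genes,
        kinase_targets=kinase_targets,
        expected_instability=expected_instability,
        hazard_rates=rate,
        alteration_frequencies=freqs,
        seed=cfg.seed,
    )
    return SyntheticCohort(protein=protein, phospho=phospho, mrna=mrna, cna=cna,
                           samples=samples, segment_profiles=profiles, ks_map=ks_map,
                           gene_sets=gene_sets, alterations=alterations, truth=truth)
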