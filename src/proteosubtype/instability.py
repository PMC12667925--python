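"""Allele-specific copy-number instability scoring.

Given integer allele-specific segments (total, major, minor copy number per
genomic interval) this module computes, per sample:

* **ploidy** — length-weighted mean total copy number over autosomes;
* **WGD** — whole-genome doubling, called when more than half of the
  autosomal genome carries major copy number >= 2;
* **CIN** — chromosomal instability, the count of gain segments
  (total > 2) + loss segments (total < 2) + LOH segments
  (minor = 0, total >= 1);
* the three homologous-recombination-deficiency (HRD) scar components:

  - **HRD-LOH**: maximal LOH runs longer than 15 Mb that do not span an
    entire chromosome;
  - **LST** (large-scale state transitions): junctions between adjacent
    differing-state regions where both flanks are >= 10 Mb after removing
    segments shorter than 3 Mb, with the flanks no more than 3 Mb apart,
    counted per chromosome arm;
  - **TAI** (telomeric allelic imbalance): allelic-imbalance runs
    (major != minor) that reach a telomere, do not cross the centromere
    and do not span the whole chromosome;

* **HRD** = HRD-LOH + LST + TAI.

Segments are taken as already purity/ploidy-resolved integers (the output
of an allele-specific caller such as FACETS); sex chromosomes are excluded
from all scores by default. Adjacent segments with identical
(major, minor) state are merged before any counting, so all scores are
invariant to how a constant-state region was subdivided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .io import GenomeBuild, Segment, SegmentProfile

MB = 1_000_000

#: default rule thresholds (base pairs)
HRD_LOH_MIN_LEN = 15 * MB
LST_MIN_SEG = 10 * MB
LST_MAX_GAP = 3 * MB
LST_SMOOTH_LEN = 3 * MB


@dataclass
class InstabilityScores:
    sample_id: str
    ploidy: float
    wgd: bool
    autosomal_coverage: float
    n_gain: int
    n_loss: int
    n_loh_segments: int
    cin: int
    hrd_loh: int
    lst: int
    tai: int
    hrd: int

    def __post_init__(self) -> None:
        assert self.cin == self.n_gain + self.n_loss + self.n_loh_segments
        assert self.hrd == self.hrd_loh + self.lst + self.tai


def _is_loh(seg: Segment) -> bool:
    return seg.minor_cn == 0 and seg.total_cn >= 1


def _merge(segs: list[Segment]) -> list[Segment]:
    """Merge contiguous same-state neighbours (per chromosome, sorted input)."""
    out: list[Segment] = []
    for s in segs:
        if out and out[-1].chrom == s.chrom and out[-1].end_bp == s.start_bp \
                and out[-1].state == s.state and out[-1].total_cn == s.total_cn:
            prev = out.pop()
            s = Segment(s.chrom, prev.start_bp, s.end_bp, s.total_cn, s.major_cn, s.minor_cn)
        out.append(s)
    return out


def merged_profile(p: SegmentProfile) -> SegmentProfile:
    """Normalize a profile by merging adjacent equal-state segments."""
    segs: list[Segment] = []
    for chrom_segs in p.by_chrom().values():
        segs.extend(_merge(chrom_segs))
    return SegmentProfile(p.sample_id, segs)


def _autosomal(p: SegmentProfile, genome: GenomeBuild) -> list[Segment]:
    autos = set(genome.autosomes)
    return [s for s in p.segments if s.chrom in autos]


def ploidy_wgd(p: SegmentProfile, genome: GenomeBuild) -> tuple[float, bool, float]:
    """Length-weighted ploidy and the >50%-major>=2 WGD call.

    Returns ``(ploidy, wgd, autosomal_coverage_fraction)``. The WGD
    fraction denominator is the full autosomal genome length; ploidy is
    weighted over covered autosomal length. A coverage fraction below 0.5
    triggers a warning (the WGD call is then unreliable).
    """
    segs = _autosomal(p, genome)
    if not segs:
        raise ValueError(f"{p.sample_id}: no autosomal segments")
    genome_len = genome.autosomal_length()
    covered = sum(s.length for s in segs)
    coverage = covered / genome_len
    if coverage < 0.5:
        warnings.warn(
            f"{p.sample_id}: segments cover only {coverage:.1%} of the autosomal "
            "genome; ploidy/WGD calls may be unreliable", stacklevel=2)
    ploidy = sum(s.length * s.total_cn for s in segs) / covered
    major_ge2 = sum(s.length for s in segs if s.major_cn >= 2)
    wgd = major_ge2 / genome_len > 0.5
    return ploidy, wgd, coverage


def cin_score(p: SegmentProfile, genome: GenomeBuild,
              exclusive: bool = False) -> tuple[int, int, int, int]:
    """Gain/loss/LOH segment counts and their sum (the CIN score).

    Counts merged autosomal segments: gain iff total > 2, loss iff
    total < 2, LOH iff minor = 0 and total >= 1. By default a segment
    contributes to every category it satisfies (e.g. total=1, minor=0 is
    both a loss and an LOH); ``exclusive=True`` counts each segment once,
    with precedence gain > loss > LOH.
    """
    segs = _merge_by_chrom(_autosomal(p, genome))
    n_gain = n_loss = n_loh = 0
    for s in segs:
        gain, loss, loh = s.total_cn > 2, s.total_cn < 2, _is_loh(s)
        if exclusive:
            if gain:
                loss = loh = False
            elif loss:
                loh = False
        n_gain += gain
        n_loss += loss
        n_loh += loh
    return n_gain, n_loss, n_loh, n_gain + n_loss + n_loh


def _merge_by_chrom(segs: list[Segment]) -> list[Segment]:
    by_chrom: dict[str, list[Segment]] = {}
    for s in segs:
        by_chrom.setdefault(s.chrom, []).append(s)
    out: list[Segment] = []
    for chrom_segs in by_chrom.values():
        out.extend(_merge(sorted(chrom_segs, key=lambda s: s.start_bp)))
    return out


def _runs(segs: list[Segment], predicate) -> list[tuple[str, int, int]]:
    """Maximal runs of contiguous predicate-true segments, as (chrom, start, end).

    A coverage gap (end < next start) breaks a run.
    """
    runs: list[tuple[str, int, int]] = []
    cur: tuple[str, int, int] | None = None
    for s in segs:
        if predicate(s):
            if cur is not None and cur[0] == s.chrom and cur[2] == s.start_bp:
                cur = (cur[0], cur[1], s.end_bp)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = (s.chrom, s.start_bp, s.end_bp)
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
    if cur is not None:
        runs.append(cur)
    return runs


def hrd_loh_count(p: SegmentProfile, genome: GenomeBuild,
                  min_len: int = HRD_LOH_MIN_LEN) -> int:
    """LOH scar count: maximal LOH runs > ``min_len`` not spanning a whole chromosome."""
    count = 0
    autos = set(genome.autosomes)
    for chrom, segs in merged_profile(p).by_chrom().items():
        if chrom not in autos:
            continue
        chrom_len = genome.length(chrom)
        for _, start, end in _runs(segs, _is_loh):
            if end - start > min_len and not (start == 0 and end == chrom_len):
                count += 1
    return count


def _clip_to_arm(segs: list[Segment], lo: int, hi: int) -> list[Segment]:
    out = []
    for s in segs:
        a, b = max(s.start_bp, lo), min(s.end_bp, hi)
        if b > a:
            out.append(Segment(s.chrom, a, b, s.total_cn, s.major_cn, s.minor_cn))
    return out


def _smooth(segs: list[Segment], smooth_len: int) -> list[Segment]:
    """Drop segments shorter than ``smooth_len`` and re-merge same-state flanks
    across the removed span (regardless of the gap the removal opened)."""
    kept = [s for s in segs if s.length >= smooth_len]
    out: list[Segment] = []
    for s in kept:
        if out and out[-1].state == s.state and out[-1].total_cn == s.total_cn:
            prev = out.pop()
            s = Segment(s.chrom, prev.start_bp, s.end_bp, s.total_cn, s.major_cn, s.minor_cn)
        out.append(s)
    return out


def lst_count(p: SegmentProfile, genome: GenomeBuild, min_seg: int = LST_MIN_SEG,
              max_gap: int = LST_MAX_GAP, smooth_len: int = LST_SMOOTH_LEN) -> int:
    """Large-scale state transitions, counted per chromosome arm.

    After <3 Mb smoothing, a junction between consecutive differing-state
    segments counts when both flanks are >= ``min_seg`` and the gap between
    them is <= ``max_gap``. Two segments differ in state when their
    (major, minor) pairs differ, so a copy-neutral LOH boundary is a
    transition.
    """
    count = 0
    autos = set(genome.autosomes)
    by_chrom = merged_profile(p).by_chrom()
    for chrom, segs in by_chrom.items():
        if chrom not in autos:
            continue
        for lo, hi in genome.arms(chrom).values():
            arm = _smooth(_clip_to_arm(segs, lo, hi), smooth_len)
            for left, right in zip(arm, arm[1:]):
                if left.state == right.state:
                    continue
                if left.length >= min_seg and right.length >= min_seg \
                        and right.start_bp - left.end_bp <= max_gap:
                    count += 1
    return count


def tai_count(p: SegmentProfile, genome: GenomeBuild, min_len: int = 0) -> int:
    """Telomeric allelic-imbalance count.

    An imbalance run (major != minor) qualifies when it touches a telomere
    (position 0 or the chromosome end), does not cross the centromere
    (runs ending exactly at a centromere edge count as non-crossing),
    does not span the whole chromosome, and is longer than ``min_len``.
    """
    count = 0
    autos = set(genome.autosomes)
    for chrom, segs in merged_profile(p).by_chrom().items():
        if chrom not in autos:
            continue
        chrom_len = genome.length(chrom)
        cen_start, cen_end = genome.centromere(chrom)
        for _, start, end in _runs(segs, lambda s: s.major_cn != s.minor_cn):
            if end - start <= min_len:
                continue
            if not (start == 0 or end == chrom_len):
                continue
            if start == 0 and end == chrom_len:
                continue  # whole-chromosome imbalance is not telomere-specific
            if start < cen_start and end > cen_end:
                continue  # crosses the centromere
            count += 1
    return count


def hrd_score(p: SegmentProfile, genome: GenomeBuild,
              exclusive_cin: bool = False) -> InstabilityScores:
    """Assemble all instability scores for one sample; HRD = LOH + LST + TAI."""
    ploidy, wgd, coverage = ploidy_wgd(p, genome)
    n_gain, n_loss, n_loh, cin = cin_score(p, genome, exclusive=exclusive_cin)
    loh = hrd_loh_count(p, genome)
    lst = lst_count(p, genome)
    tai = tai_count(p, genome)
    return InstabilityScores(
        sample_id=p.sample_id, ploidy=ploidy, wgd=wgd, autosomal_coverage=coverage,
        n_gain=n_gain, n_loss=n_loss, n_loh_segments=n_loh, cin=cin,
        hrd_loh=loh, lst=lst, tai=tai, hrd=loh + lst + tai,
    )


def score_profiles(profiles: list[SegmentProfile], genome: GenomeBuild,
                   **kwargs) -> pd.DataFrame:
    """Score many profiles into a tidy table (one row per sample)."""
    rows = [hrd_score(p, genome, **kwargs).__dict__ for p in profiles]
    return pd.DataFrame(rows).set_index("sample_id")
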