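"""Domain types and tabular readers/writers.

Every table the pipeline touches is plain delimited text:

* feature x sample abundance matrices (TSV, first column = feature ID,
  empty cells or ``NA`` = missing),
* SEG-style allele-specific copy-number segments (1-based inclusive
  coordinates on disk, 0-based half-open internally),
* GMT gene-set collections,
* a genome-build table (chromosome lengths + centromere intervals),
* sample metadata, kinase-substrate maps and gene x sample alteration calls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("proteosubtype")

SCALE_TAGS = ("raw_intensity", "log2")
FEATURE_KINDS = ("protein", "phosphosite", "mrna", "cna_gene")

#: Precedence used to collapse multiple alteration events in one cell.
ALTERATION_PRECEDENCE = ("mutation", "deep_deletion", "amplification", "loh")
ALTERATION_CALLS = ("none",) + ALTERATION_PRECEDENCE


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Series(ids)
    dup = s[s.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate {what} ID(s): {sorted(dup.unique())}")


# ---------------------------------------------------------------------------
# OmicsMatrix
# ---------------------------------------------------------------------------

@dataclass
class OmicsMatrix:
    """Feature x sample abundance grid with explicit missingness (NaN).

    ``scale_tag`` distinguishes raw reporter intensities (non-negative)
    from log2-transformed abundances; normalization stages check it so
    that scale conversions are always explicit.
    """

    data: pd.DataFrame  # features x samples, NaN = missing
    scale_tag: str
    feature_kind: str

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {SCALE_TAGS}, got {self.scale_tag!r}")
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}")
        _check_unique(list(self.data.index), "feature")
        _check_unique(list(self.data.columns), "sample")
        self.data = self.data.astype(float)
        if self.scale_tag == "raw_intensity":
            vals = self.data.to_numpy()
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError("raw_intensity values must be >= 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-value mask (True = observed)."""
        return self.data.notna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def with_data(self, data: pd.DataFrame, scale_tag: Optional[str] = None) -> "OmicsMatrix":
        return OmicsMatrix(data, scale_tag or self.scale_tag, self.feature_kind)

    def to_log2(self) -> "OmicsMatrix":
        if self.scale_tag == "log2":
            return self
        with np.errstate(divide="ignore"):
            out = np.log2(self.data.where(self.data > 0))
        return OmicsMatrix(out, "log2", self.feature_kind)

    def to_raw(self) -> "OmicsMatrix":
        if self.scale_tag == "raw_intensity":
            return self
        return OmicsMatrix(np.power(2.0, self.data), "raw_intensity", self.feature_kind)


def read_matrix(path, scale_tag: str, feature_kind: str) -> OmicsMatrix:
    """Read a delimited feature x sample matrix.

    First column holds feature IDs, header row sample IDs; empty cells or
    ``NA`` denote missing values. Non-numeric cells are a hard error with
    coordinates; duplicated IDs are a hard error naming the duplicate.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0, keep_default_na=False)
    _check_unique(list(raw.index), "feature")
    _check_unique(list(raw.columns), "sample")
    parsed = raw.replace({"": np.nan, "NA": np.nan, "NaN": np.nan, "nan": np.nan})
    numeric = parsed.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & parsed.notna()
    if bad.to_numpy().any():
        f, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at feature {raw.index[f]!r}, sample {raw.columns[s]!r}: "
            f"{raw.iloc[f, s]!r}"
        )
    return OmicsMatrix(numeric, scale_tag, feature_kind)


def write_matrix(m: OmicsMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", na_rep="NA", index_label="feature_id")


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = [
    "sample_id", "plex_id", "channel_id", "is_pooled_reference",
    "subtype_label", "tumor_status", "pair_id",
    "os_time", "os_event", "rfs_time", "rfs_event",
]


@dataclass
class SampleTable:
    """Per-sample metadata: TMT plex/channel layout, pooled-reference flags,
    optional subtype labels, primary/metastasis pairing and survival."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "sample_id" not in df.columns:
            raise ValueError("sample table requires a sample_id column")
        for col in SAMPLE_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        _check_unique(list(df["sample_id"]), "sample")
        def _as_flag(v) -> bool:
            if pd.isna(v):
                return False
            if isinstance(v, str):
                return v.strip().lower() in ("true", "1", "yes")
            return bool(v)

        df["is_pooled_reference"] = df["is_pooled_reference"].map(_as_flag)
        for col in ("os_time", "rfs_time"):
            t = pd.to_numeric(df[col], errors="coerce")
            if (t.dropna() < 0).any():
                raise ValueError(f"{col} must be nonnegative")
            df[col] = t
        for col in ("os_event", "rfs_event"):
            e = pd.to_numeric(df[col], errors="coerce")
            if not e.dropna().isin([0, 1]).all():
                raise ValueError(f"{col} flags must be 0/1")
            df[col] = e
        plexes = df["plex_id"].dropna().unique()
        for p in plexes:
            sub = df[df["plex_id"] == p]
            if not sub["is_pooled_reference"].any():
                raise ValueError(f"plex {p!r} has no pooled-reference channel")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def plex_of(self) -> pd.Series:
        return self.table.set_index("sample_id")["plex_id"]

    def reference_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[t["is_pooled_reference"], "sample_id"])

    def subtype_labels(self) -> pd.Series:
        t = self.table
        return t.set_index("sample_id")["subtype_label"].dropna()


def read_samples(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t"))


def write_samples(s: SampleTable, path) -> None:
    s.table.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# SegmentProfile
# ---------------------------------------------------------------------------

class Segment(NamedTuple):
    """Allele-specific copy-number segment, 0-based half-open coordinates."""

    chrom: str
    start_bp: int
    end_bp: int
    total_cn: int
    major_cn: int
    minor_cn: int

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def state(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)


@dataclass
class SegmentProfile:
    """Per-sample allele-specific segments; validated and sorted on build."""

    sample_id: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        segs = []
        for s in self.segments:
            s = Segment(str(s[0]), int(s[1]), int(s[2]), int(s[3]), int(s[4]), int(s[5]))
            if s.end_bp <= s.start_bp:
                raise ValueError(f"{self.sample_id}: segment end <= start: {s}")
            if min(s.total_cn, s.major_cn, s.minor_cn) < 0:
                raise ValueError(f"{self.sample_id}: negative copy number: {s}")
            if s.major_cn < s.minor_cn:
                raise ValueError(f"{self.sample_id}: major_cn < minor_cn: {s}")
            if s.major_cn + s.minor_cn != s.total_cn:
                raise ValueError(f"{self.sample_id}: major+minor != total: {s}")
            segs.append(s)
        segs.sort(key=lambda s: (s.chrom, s.start_bp))
        prev: dict[str, Segment] = {}
        for s in segs:
            p = prev.get(s.chrom)
            if p is not None and s.start_bp < p.end_bp:
                raise ValueError(
                    f"{self.sample_id}: overlapping segments on {s.chrom}: {p} / {s}"
                )
            prev[s.chrom] = s
        self.segments = segs

    def by_chrom(self) -> dict[str, list[Segment]]:
        out: dict[str, list[Segment]] = {}
        for s in self.segments:
            out.setdefault(s.chrom, []).append(s)
        return out


SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "major_cn", "minor_cn"]


def read_segments(path) -> list[SegmentProfile]:
    """Read a SEG-style table (1-based inclusive on disk) into profiles.

    Coordinates convert to the internal 0-based half-open convention:
    ``start_bp = start - 1``, ``end_bp = end``.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"segment table missing columns: {missing}")
    profiles = []
    for sample, grp in df.groupby("sample", sort=False):
        segs = [
            Segment(str(r.chrom), int(r.start) - 1, int(r.end),
                    int(r.total_cn), int(r.major_cn), int(r.minor_cn))
            for r in grp.itertuples()
        ]
        profiles.append(SegmentProfile(str(sample), segs))
    return profiles


def write_segments(profiles: Iterable[SegmentProfile], path) -> None:
    rows = []
    for p in profiles:
        for s in p.segments:
            rows.append((p.sample_id, s.chrom, s.start_bp + 1, s.end_bp,
                         s.total_cn, s.major_cn, s.minor_cn))
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenomeBuild
# ---------------------------------------------------------------------------

@dataclass
class GenomeBuild:
    """Chromosome lengths and centromere intervals; arms are the regions on
    either side of the centromere. Sex chromosomes are parsed but flagged so
    autosome-restricted scores can exclude them."""

    table: pd.DataFrame  # index chrom; length_bp, centromere_start_bp, centromere_end_bp, is_autosome

    def __post_init__(self) -> None:
        df = self.table
        need = ["length_bp", "centromere_start_bp", "centromere_end_bp", "is_autosome"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise ValueError(f"genome build missing columns: {missing}")
        _check_unique(list(df.index), "chromosome")
        bad = ~(
            (0 < df["centromere_start_bp"])
            & (df["centromere_start_bp"] < df["centromere_end_bp"])
            & (df["centromere_end_bp"] < df["length_bp"])
        )
        if bad.any():
            raise ValueError(f"centromere outside chromosome for: {list(df.index[bad])}")
        df["is_autosome"] = df["is_autosome"].astype(bool)

    @property
    def chroms(self) -> list[str]:
        return list(self.table.index)

    @property
    def autosomes(self) -> list[str]:
        return list(self.table.index[self.table["is_autosome"]])

    def length(self, chrom: str) -> int:
        return int(self.table.loc[chrom, "length_bp"])

    def centromere(self, chrom: str) -> tuple[int, int]:
        row = self.table.loc[chrom]
        return int(row["centromere_start_bp"]), int(row["centromere_end_bp"])

    def arms(self, chrom: str) -> dict[str, tuple[int, int]]:
        """p arm = [0, cen_start), q arm = [cen_end, length)."""
        cs, ce = self.centromere(chrom)
        return {"p": (0, cs), "q": (ce, self.length(chrom))}

    def arm_length(self, chrom: str, arm: str) -> int:
        a, b = self.arms(chrom)[arm]
        return b - a

    def autosomal_length(self) -> int:
        t = self.table
        return int(t.loc[t["is_autosome"], "length_bp"].sum())


def read_genome_build(path) -> GenomeBuild:
    df = pd.read_csv(path, sep="\t").set_index("chrom")
    return GenomeBuild(df)


def default_genome() -> GenomeBuild:
    """Bundled GRCh37-like build (22 autosomes + X/Y, rounded centromeres)."""
    ref = resources.files("proteosubtype.data") / "genome_grch37like.tsv"
    with resources.as_file(ref) as path:
        return read_genome_build(path)


# ---------------------------------------------------------------------------
# GeneSetCollection
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene/site sets; members are unordered, duplicates collapse."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for name, (desc, members) in self.sets.items():
            members = frozenset(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = (desc, members)
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names})


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: fewer than 3 fields")
            name, desc, *members = parts
            if name in sets:
                raise ValueError(f"GMT line {lineno}: duplicate set name {name!r}")
            sets[name] = (desc, frozenset(m for m in members if m))
    if not sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in gsc:
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# KinaseSubstrateMap
# ---------------------------------------------------------------------------

@dataclass
class KinaseSubstrateMap:
    """(kinase, substrate, site) annotation records; duplicates dropped."""

    records: pd.DataFrame  # columns kinase_id, substrate_id, site_id

    def __post_init__(self) -> None:
        need = ["kinase_id", "substrate_id", "site_id"]
        missing = [c for c in need if c not in self.records.columns]
        if missing:
            raise ValueError(f"kinase-substrate map missing columns: {missing}")
        self.records = self.records[need].drop_duplicates().reset_index(drop=True)

    @property
    def kinases(self) -> list[str]:
        return sorted(self.records["kinase_id"].unique())

    def sites_of(self, kinase: str) -> list[str]:
        r = self.records
        return sorted(r.loc[r["kinase_id"] == kinase, "site_id"].unique())


def read_ks_map(path) -> KinaseSubstrateMap:
    return KinaseSubstrateMap(pd.read_csv(path, sep="\t"))


def write_ks_map(ks: KinaseSubstrateMap, path) -> None:
    ks.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# AlterationMatrix
# ---------------------------------------------------------------------------

@dataclass
class AlterationMatrix:
    """Gene x sample categorical alteration calls (oncoprint semantics).

    Each cell carries exactly one call; when a gene has several event types
    in one sample they collapse by precedence mutation > deep_deletion >
    amplification > loh, with the full list retained in ``provenance``.
    """

    calls: pd.DataFrame  # genes x samples of ALTERATION_CALLS strings
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(list(self.calls.index), "gene")
        _check_unique(list(self.calls.columns), "sample")
        vals = set(np.unique(self.calls.to_numpy().astype(str)))
        bad = vals - set(ALTERATION_CALLS)
        if bad:
            raise ValueError(f"unknown alteration calls: {sorted(bad)}")

    @classmethod
    def from_events(cls, events: pd.DataFrame, genes: Sequence[str] | None = None,
                    samples: Sequence[str] | None = None) -> "AlterationMatrix":
        """Build from a long table of (gene, sample, call) events."""
        need = ["gene", "sample", "call"]
        missing = [c for c in need if c not in events.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        genes = list(genes) if genes is not None else sorted(events["gene"].unique())
        samples = list(samples) if samples is not None else sorted(events["sample"].unique())
        calls = pd.DataFrame("none", index=genes, columns=samples)
        rank = {c: i for i, c in enumerate(ALTERATION_PRECEDENCE)}
        provenance: dict[tuple[str, str], list[str]] = {}
        for (g, s), grp in events.groupby(["gene", "sample"], sort=False):
            evs = sorted(set(grp["call"]), key=lambda c: rank[c])
            calls.loc[g, s] = evs[0]
            if len(evs) > 1:
                provenance[(g, s)] = evs
        return cls(calls, {"multi_event_cells": provenance})


def read_alterations(path) -> AlterationMatrix:
    return AlterationMatrix(pd.read_csv(path, sep="\t", index_col=0))


def write_alterations(a: AlterationMatrix, path) -> None:
    a.calls.to_csv(path, sep="\t", index_label="gene")
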