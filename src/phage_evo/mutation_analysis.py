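"""Variant filtering, receptor-pathway mapping and sweep trajectories.

Consumes mutation calls for clonal isolates or whole-population samples —
either breseq genome-diff (GD) files or a flat TSV — and applies the
study-style bookkeeping: retain putative loss-of-function calls (nonsense,
missense, frameshift, large indel) above a population frequency floor,
subtract pre-existing ancestral background mutations, map genes to the
phage-receptor pathway they disrupt (O-antigen vs core oligosaccharide of
LPS, or the BtuB outer-membrane transporter), summarise the mutation
spectrum, and build per-gene or per-class allele-frequency trajectories
across serial-passage timepoints to detect the order in which resistance
to different receptors is acquired.

The receptor-class map is phenotype-based: a gene (or for *rfaJ*, a
specific allele) is labelled by the range of phages its disruption
confers resistance to. Core truncation also removes the O-antigen, so
deep *rfa*-cluster lesions score as resistant to both LPS-targeting
groups, while *rfb*/*rfc* lesions affect the O-antigen only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

MUTATION_TYPES = (
    "nonsense",
    "missense",
    "frameshift",
    "large_indel",
    "synonymous",
    "intergenic",
    "other",
)

#: Mutation classes retained by the loss-of-function filter.
LOF_TYPES = frozenset({"nonsense", "missense", "frameshift", "large_indel"})

#: Default minimum population frequency (5%).
DEFAULT_MIN_FREQ = 0.05

#: Default size (bp) from which an indel counts as "large".
DEFAULT_LARGE_INDEL_MIN = 30

RECEPTOR_CLASSES = ("O-antigen-only", "core-only", "both-LPS", "BtuB", "other")
PATHWAY_GROUPS = (
    "rfb-cluster",
    "rfc",
    "rfa-cluster",
    "LPS-regulator",
    "sugar-precursor",
    "btuB",
    "other",
)

#: Receptor classes that disrupt LPS (either region).
LPS_CLASSES = frozenset({"O-antigen-only", "core-only", "both-LPS"})


@dataclass(frozen=True)
class VariantRecord:
    """One mutation call (clonal isolate or population-frequency)."""

    sample_id: str
    gene: str
    mutation_type: str
    nt_change: str
    aa_change: str | None = None
    frequency: float = 1.0
    timepoint: float | None = None
    indel_len: int | None = None

    def __post_init__(self) -> None:
        if self.mutation_type not in MUTATION_TYPES:
            raise ValueError(f"unknown mutation_type {self.mutation_type!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")


@dataclass(frozen=True)
class GeneClassMap:
    """Gene -> resistance-phenotype class and biosynthesis pathway group.

    ``allele_class_overrides`` handles genes whose phenotype is
    allele-dependent: keyed by (gene, aa_change).
    """

    class_of_gene: Mapping[str, str]
    group_of_gene: Mapping[str, str]
    allele_class_overrides: Mapping[tuple[str, str], str] = field(default_factory=dict)

    def lookup(self, gene: str, aa_change: str | None = None) -> tuple[str, str]:
        group = self.group_of_gene.get(gene, "other")
        if aa_change is not None and (gene, aa_change) in self.allele_class_overrides:
            return self.allele_class_overrides[(gene, aa_change)], group
        return self.class_of_gene.get(gene, "other"), group


def default_gene_class_map() -> GeneClassMap:
    """Built-in receptor-pathway map for the Salmonella LPS/BtuB system.

    O-antigen biosynthesis (rfb cluster, rfc ligase) lesions remove the
    O-antigen only; deep core lesions (rfaF/G/I/J, regulator rfaH) truncate
    the core and with it the O-antigen (both-LPS); rfaP (core phosphates),
    rfaK, sugar-precursor genes pgm/galE and (by pathway analogy, inferred)
    hldE alter the core only; btuB is its own class. Specific rfaJ missense
    alleles alter the core without losing the O-antigen and override to
    core-only.
    """
    o_antigen = {g: "O-antigen-only" for g in
                 ("rfbD", "rfbC", "rfbV", "rfbU", "rfbP", "rfc")}
    both = {g: "both-LPS" for g in ("rfaF", "rfaG", "rfaI", "rfaJ", "rfaH")}
    core = {g: "core-only" for g in ("rfaP", "rfaK", "pgm", "galE", "hldE")}
    classes = {**o_antigen, **both, **core, "btuB": "BtuB"}

    groups = {g: "rfb-cluster" for g in ("rfbD", "rfbC", "rfbV", "rfbU", "rfbP")}
    groups["rfc"] = "rfc"
    groups.update({g: "rfa-cluster"
                   for g in ("rfaF", "rfaG", "rfaI", "rfaJ", "rfaP", "rfaK")})
    groups["rfaH"] = "LPS-regulator"
    groups.update({g: "sugar-precursor" for g in ("pgm", "galE", "hldE")})
    groups["btuB"] = "btuB"

    overrides = {("rfaJ", aa): "core-only"
                 for aa in ("A198V", "L229P", "A275E", "D216E")}
    return GeneClassMap(classes, groups, overrides)


# ---------------------------------------------------------------------------
# Parsing

_GD_POSITIONAL = {
    # fields following (type, id, parent_ids, seq_id, position)
    "SNP": ("new_seq",),
    "SUB": ("size", "new_seq"),
    "DEL": ("size",),
    "INS": ("new_seq",),
    "MOB": ("repeat_name", "strand", "duplication_size"),
    "AMP": ("size", "new_copy_number"),
    "CON": ("size", "region"),
    "INV": ("size",),
}

_SNP_TYPE_MAP = {
    "nonsynonymous": "missense",
    "missense": "missense",
    "nonsense": "nonsense",
    "synonymous": "synonymous",
    "intergenic": "intergenic",
    "noncoding": "other",
    "pseudogene": "other",
}


def _parse_gd_line(line: str) -> dict | None:
    fields = line.rstrip("\n").split("\t")
    kind = fields[0]
    if kind not in _GD_POSITIONAL:
        return None
    positional = _GD_POSITIONAL[kind]
    base = {"type": kind, "seq_id": fields[3], "position": fields[4]}
    for name, value in zip(positional, fields[5 : 5 + len(positional)]):
        base[name] = value
    for token in fields[5 + len(positional) :]:
        if "=" in token:
            key, _, value = token.partition("=")
            base[key] = value
    return base


def _classify_indel(size: int, in_cds: bool, large_indel_min: int) -> str:
    if size >= large_indel_min:
        return "large_indel"
    if in_cds and size % 3 != 0:
        return "frameshift"
    return "other"


def _record_from_gd(entry: dict, sample_id: str, timepoint, large_indel_min: int
                    ) -> VariantRecord:
    gene = entry.get("gene_name", entry.get("gene", "")).strip()
    frequency = float(entry.get("frequency", 1.0))
    in_cds = bool(gene) and "intergenic" not in entry.get("gene_position", "") \
        and "/" not in gene  # breseq writes "geneA/geneB" for intergenic hits
    kind = entry["type"]
    aa_change = None
    indel_len = None

    if kind == "SNP":
        snp_type = entry.get("snp_type", "")
        mutation_type = _SNP_TYPE_MAP.get(snp_type)
        if mutation_type is None:
            warnings.warn(f"unmappable snp_type {snp_type!r}; kept as 'other'",
                          stacklevel=3)
            mutation_type = "other"
        if not in_cds and mutation_type not in ("intergenic",):
            mutation_type = mutation_type if gene else "intergenic"
        ref = entry.get("ref_seq", "")
        nt_change = f"{entry['position']}:{ref}>{entry.get('new_seq', '')}"
        if {"aa_ref_seq", "aa_position", "aa_new_seq"} <= entry.keys():
            new_aa = entry["aa_new_seq"]
            aa_change = f"{entry['aa_ref_seq']}{entry['aa_position']}" \
                        f"{'*' if new_aa == '*' else new_aa}"
    elif kind in ("DEL", "INV", "AMP", "CON", "SUB"):
        indel_len = int(entry.get("size", 0))
        mutation_type = _classify_indel(indel_len, in_cds, large_indel_min)
        nt_change = f"{indel_len} bp del." if kind == "DEL" else \
            f"{entry['position']}:{kind}:{indel_len}"
    elif kind == "INS":
        indel_len = len(entry.get("new_seq", ""))
        mutation_type = _classify_indel(indel_len, in_cds, large_indel_min)
        nt_change = f"{indel_len} bp ins."
    elif kind == "MOB":
        indel_len = int(entry.get("duplication_size", 0)) or None
        mutation_type = "large_indel"
        nt_change = f"{entry['position']}:{entry.get('repeat_name', 'IS')} ins."
    else:  # pragma: no cover - filtered earlier
        mutation_type = "other"
        nt_change = entry["position"]

    return VariantRecord(
        sample_id=sample_id,
        gene=gene,
        mutation_type=mutation_type,
        nt_change=nt_change,
        aa_change=aa_change,
        frequency=frequency,
        timepoint=timepoint,
        indel_len=indel_len,
    )


def read_variant_table(
    path,
    dialect: Literal["gd", "tsv"],
    sample_id: str | None = None,
    timepoint: float | None = None,
    large_indel_min: int = DEFAULT_LARGE_INDEL_MIN,
) -> list[VariantRecord]:
    """Read mutation calls from a breseq genome-diff file or a flat TSV.

    GD dialect: SNP/INS/DEL/MOB (and other mutation) lines are mapped onto
    the closed mutation-type vocabulary — the SNP class follows the
    annotated ``snp_type``; deletions/insertions of ``large_indel_min`` bp
    or more become ``large_indel``, smaller in-CDS indels with length not a
    multiple of 3 become ``frameshift``, the rest ``other``. TSV dialect:
    direct column mapping (sample, timepoint, gene, mutation_type,
    nt_change, aa_change, frequency, indel_len).
    """
    path = Path(path)
    if dialect == "gd":
        sid = sample_id or path.stem
        records = []
        for line in path.read_text().splitlines():
            if not line or line.startswith("#") or line.startswith(" "):
                continue
            entry = _parse_gd_line(line)
            if entry is None:
                first = line.split("\t", 1)[0]
                if first.isupper() and len(first) <= 4 and not first[0].isdigit():
                    # evidence lines (RA, MC, JC, UN) back mutations; skip silently
                    if first not in ("RA", "MC", "JC", "UN"):
                        warnings.warn(
                            f"unmappable GD line type {first!r}; skipped", stacklevel=2
                        )
                continue
            records.append(_record_from_gd(entry, sid, timepoint, large_indel_min))
        return records
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        records = []
        for r in df.itertuples(index=False):
            records.append(
                VariantRecord(
                    sample_id=str(getattr(r, "sample", sample_id or path.stem)),
                    gene=str(r.gene),
                    mutation_type=str(r.mutation_type),
                    nt_change=str(r.nt_change),
                    aa_change=None if pd.isna(getattr(r, "aa_change", None))
                    else str(r.aa_change),
                    frequency=float(getattr(r, "frequency", 1.0)),
                    timepoint=None if pd.isna(getattr(r, "timepoint", None))
                    else float(r.timepoint),
                    indel_len=None if pd.isna(getattr(r, "indel_len", None))
                    else int(r.indel_len),
                )
            )
        return records
    raise ValueError(f"unknown dialect {dialect!r}; use 'gd' or 'tsv'")


# ---------------------------------------------------------------------------
# Filtering

def filter_lof_variants(
    records: Sequence[VariantRecord],
    min_freq: float = DEFAULT_MIN_FREQ,
    large_indel_min: int = DEFAULT_LARGE_INDEL_MIN,
) -> list[VariantRecord]:
    """Retain loss-of-function calls at or above the frequency floor.

    Keeps nonsense, missense, frameshift and large-indel records with
    frequency >= ``min_freq``, preserving order. Records carrying an
    ``indel_len`` are first re-classified against ``large_indel_min`` so
    the threshold is honoured regardless of how the table was produced.
    Idempotent.
    """
    if not 0.0 <= min_freq < 1.0:
        raise ValueError("min_freq must be in [0, 1)")
    out = []
    for rec in records:
        if rec.indel_len is not None and rec.mutation_type in (
            "frameshift", "large_indel"
        ):
            new_type = ("large_indel" if rec.indel_len >= large_indel_min
                        else "frameshift")
            if new_type != rec.mutation_type:
                rec = replace(rec, mutation_type=new_type)
        if rec.mutation_type in LOF_TYPES and rec.frequency >= min_freq:
            out.append(rec)
    return out


def subtract_background(
    records: Sequence[VariantRecord], ancestor: Sequence[VariantRecord]
) -> list[VariantRecord]:
    """Drop calls already present in the ancestral (wild-type) strain.

    Matching key is (gene, nt_change); everything else is untouched.
    """
    background = {(a.gene, a.nt_change) for a in ancestor}
    return [r for r in records if (r.gene, r.nt_change) not in background]


def assign_receptor_class(
    record: VariantRecord, class_map: GeneClassMap | None = None
) -> tuple[str, str]:
    """Resistance-phenotype class and pathway group of a variant's gene.

    Unmapped genes return ("other", "other").
    """
    class_map = class_map or default_gene_class_map()
    return class_map.lookup(record.gene, record.aa_change)


# ---------------------------------------------------------------------------
# Spectra

@dataclass(frozen=True)
class MutationSpectrum:
    """Count tables over genes, pathway groups and phenotype classes."""

    gene_counts: pd.Series
    group_counts: pd.Series
    class_counts: pd.Series
    distinct_genes_by_category: dict[str, int]
    n_records: int


def mutation_spectrum(
    records: Sequence[VariantRecord], class_map: GeneClassMap | None = None
) -> MutationSpectrum:
    """Summarise an (already filtered) record list.

    ``distinct_genes_by_category`` counts unique gene symbols per broad
    receptor target: "LPS" (any LPS-affecting class), "BtuB", "other".
    """
    class_map = class_map or default_gene_class_map()
    genes, groups, classes = [], [], []
    for rec in records:
        cls, grp = class_map.lookup(rec.gene, rec.aa_change)
        genes.append(rec.gene)
        groups.append(grp)
        classes.append(cls)
    gene_counts = pd.Series(genes, dtype=object).value_counts().sort_index()
    group_counts = pd.Series(groups, dtype=object).value_counts().sort_index()
    class_counts = pd.Series(classes, dtype=object).value_counts().sort_index()

    distinct: dict[str, set] = {"LPS": set(), "BtuB": set(), "other": set()}
    for gene, cls in zip(genes, classes):
        if cls in LPS_CLASSES:
            distinct["LPS"].add(gene)
        elif cls == "BtuB":
            distinct["BtuB"].add(gene)
        else:
            distinct["other"].add(gene)
    return MutationSpectrum(
        gene_counts=gene_counts,
        group_counts=group_counts,
        class_counts=class_counts,
        distinct_genes_by_category={k: len(v) for k, v in distinct.items()},
        n_records=len(records),
    )


# ---------------------------------------------------------------------------
# Trajectories

@dataclass(frozen=True)
class TrajectorySet:
    """Allele-frequency trajectories per gene or receptor class.

    ``series`` maps each key to a frame with one row per replicate
    (sample_id) and one column per timepoint; missing observations are 0.
    """

    timepoints: tuple[float, ...]
    series: dict[str, pd.DataFrame]
    aggregate: str


def build_trajectories(
    records: Sequence[VariantRecord],
    aggregate: Literal["gene", "class"] = "gene",
    combine: Literal["max", "sum-capped"] = "max",
    class_map: GeneClassMap | None = None,
) -> TrajectorySet:
    """Aggregate population records into frequency-over-time series.

    Within one (replicate, timepoint, key) cell, distinct alleles combine
    by ``max`` (alternative sweeps of the same gene) or ``sum-capped``
    (summed, capped at 1.0). Timepoints missing for a replicate are 0.
    """
    if aggregate not in ("gene", "class"):
        raise ValueError(f"unknown aggregate level {aggregate!r}")
    if combine not in ("max", "sum-capped"):
        raise ValueError(f"unknown combine rule {combine!r}")
    class_map = class_map or default_gene_class_map()

    rows = []
    for rec in records:
        if rec.timepoint is None:
            raise ValueError(
                f"record {rec.gene} {rec.nt_change} lacks a timepoint; "
                "trajectories need population records"
            )
        key = (rec.gene if aggregate == "gene"
               else class_map.lookup(rec.gene, rec.aa_change)[0])
        rows.append({"replicate": rec.sample_id, "timepoint": rec.timepoint,
                     "key": key, "frequency": rec.frequency})
    if not rows:
        return TrajectorySet(timepoints=(), series={}, aggregate=aggregate)

    long = pd.DataFrame(rows)
    timepoints = tuple(sorted(long["timepoint"].unique()))
    replicates = sorted(long["replicate"].unique())
    series: dict[str, pd.DataFrame] = {}
    for key, sub in long.groupby("key"):
        agg = sub.groupby(["replicate", "timepoint"])["frequency"]
        cell = agg.max() if combine == "max" else agg.sum().clip(upper=1.0)
        frame = cell.unstack("timepoint").reindex(
            index=replicates, columns=list(timepoints)
        ).fillna(0.0)
        series[str(key)] = frame
    return TrajectorySet(timepoints=timepoints, series=series, aggregate=aggregate)


@dataclass(frozen=True)
class AcquisitionEvent:
    """First passage of a trajectory above the dominance threshold."""

    key: str
    timepoint: float
    tied: bool


def detect_sequential_acquisition(
    traj: TrajectorySet, threshold: float = 0.5
) -> list[AcquisitionEvent]:
    """Order receptor classes (or genes) by when they first become dominant.

    For each trajectory key, replicate frequencies are combined by median
    per timepoint and the earliest timepoint with median frequency >=
    ``threshold`` is recorded; keys that never cross are omitted. Events
    are sorted by crossing time; simultaneous crossings carry the tie
    flag.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    crossings = []
    for key, frame in traj.series.items():
        median = frame.median(axis=0)
        above = median[median >= threshold]
        if len(above):
            crossings.append((float(above.index[0]), str(key)))
    crossings.sort()
    times = [t for t, _ in crossings]
    return [
        AcquisitionEvent(key=key, timepoint=t, tied=times.count(t) > 1)
        for t, key in crossings
    ]
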