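"""Cohort input/output: variant tables, copy-number segments, clinical data, gene models.

All coordinates are 1-based inclusive internally. BED input (0-based,
half-open) is converted on read; VCF and SEG positions are taken unchanged.
Chromosome names are normalized by stripping a leading ``chr``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_BASES = frozenset("ACGT")
SUBTYPES = ("POLE", "MSI", "CN-low", "CN-high")

MSI_HIGH = "MSI-high"
MSS = "MSS"
MSI_UNKNOWN = "unknown"

_MSI_ALIASES = {
    "msi-high": MSI_HIGH,
    "msi high": MSI_HIGH,
    "msi_high": MSI_HIGH,
    "msi-h": MSI_HIGH,
    "high": MSI_HIGH,
    "mss": MSS,
    "msi-low": MSS,
    "msi low": MSS,
    "msi_low": MSS,
    "msi-l": MSS,
    "mss/msi-low": MSS,
    "stable": MSS,
    "": MSI_UNKNOWN,
    "na": MSI_UNKNOWN,
    "nan": MSI_UNKNOWN,
    "unknown": MSI_UNKNOWN,
}


class CohortIOError(ValueError):
    """Raised for malformed or inconsistent cohort input files."""


def normalize_chromosome(name: str) -> str:
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if not name:
        raise CohortIOError("empty chromosome name")
    return name


def classify_variant(ref: str, alt: str) -> str:
    """Derive the variant class {SNV, insertion, deletion, other} from alleles."""
    ref, alt = ref.upper(), alt.upper()
    if len(ref) == 1 and len(alt) == 1:
        if ref in VALID_BASES and alt in VALID_BASES and ref != alt:
            return "SNV"
        return "other"
    if len(ref) > len(alt):
        return "deletion"
    if len(alt) > len(ref):
        return "insertion"
    return "other"


@dataclass(frozen=True)
class VariantRecord:
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_class: str = field(default="")

    def __post_init__(self):
        if self.position < 1:
            raise CohortIOError(f"variant position must be >= 1, got {self.position}")
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        object.__setattr__(
            self, "variant_class", classify_variant(self.ref_allele, self.alt_allele)
        )

    @property
    def key(self):
        return (self.chromosome, self.position, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class SomaticVariantSet:
    """Per-sample somatic small-variant calls (duplicates collapsed on load)."""

    sample_id: str
    variants: tuple[VariantRecord, ...]

    def __post_init__(self):
        if not self.sample_id:
            raise CohortIOError("sample_id must be non-empty")
        seen, unique = set(), []
        for v in self.variants:
            if v.key not in seen:
                seen.add(v.key)
                unique.append(v)
        object.__setattr__(self, "variants", tuple(unique))

    def __len__(self):
        return len(self.variants)


@dataclass(frozen=True)
class CNSegment:
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    copy_number: float

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start > self.end:
            raise CohortIOError(
                f"segment start > end ({self.chromosome}:{self.start}-{self.end})"
            )
        if self.copy_number < 0:
            raise CohortIOError(f"negative copy number {self.copy_number}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CNProfile:
    sample_id: str
    segments: tuple[CNSegment, ...]
    ploidy: float = 2.0

    def __post_init__(self):
        if not self.sample_id:
            raise CohortIOError("sample_id must be non-empty")
        if self.ploidy <= 0:
            raise CohortIOError(f"ploidy must be positive, got {self.ploidy}")
        by_chrom: dict[str, list[CNSegment]] = {}
        for s in self.segments:
            by_chrom.setdefault(s.chromosome, []).append(s)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise CohortIOError(
                        f"overlapping segments for sample {self.sample_id} on "
                        f"chromosome {chrom}: {a.start}-{a.end} and {b.start}-{b.end}"
                    )


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    msi_status: str | float = MSI_UNKNOWN
    followup_months: float | None = None
    event: bool | None = None
    tcga_subtype: str | None = None
    cn_cluster: int | None = None

    def __post_init__(self):
        if not self.sample_id:
            raise CohortIOError("sample_id must be non-empty")
        if isinstance(self.msi_status, str):
            norm = _MSI_ALIASES.get(self.msi_status.strip().lower())
            if norm is None:
                raise CohortIOError(
                    f"unrecognized msi_status {self.msi_status!r} for {self.sample_id}"
                )
            object.__setattr__(self, "msi_status", norm)
        else:
            score = float(self.msi_status)
            if not 0.0 <= score <= 1.0:
                raise CohortIOError(f"MSI score must be in [0,1], got {score}")
            object.__setattr__(self, "msi_status", score)
        if self.followup_months is not None and self.followup_months < 0:
            raise CohortIOError(
                f"negative follow-up for {self.sample_id}: {self.followup_months}"
            )
        if self.tcga_subtype is not None and self.tcga_subtype not in SUBTYPES:
            raise CohortIOError(
                f"unknown subtype label {self.tcga_subtype!r} for {self.sample_id}"
            )
        if self.cn_cluster is not None and int(self.cn_cluster) not in (1, 2, 3, 4):
            raise CohortIOError(f"cn_cluster must be 1-4, got {self.cn_cluster}")


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self):
        object.__setattr__(self, "chromosome", normalize_chromosome(self.chromosome))
        if self.start > self.end:
            raise CohortIOError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class GeneModel:
    genes: tuple[Gene, ...]

    def __post_init__(self):
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise CohortIOError("duplicate gene_id in gene model")

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


# ---------------------------------------------------------------------------
# readers


def _variant_set_from_vcf(path: str | os.PathLike, sample_id: str | None) -> SomaticVariantSet:
    from cyvcf2 import VCF

    sid = sample_id or Path(path).name.split(".")[0]
    records = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            # cyvcf2 reports PASS / missing FILTER as None; anything else is a
            # failing filter and the record is excluded.
            if v.FILTER is not None:
                continue
            for alt in v.ALT:  # multi-allelic records split per alt allele
                records.append(VariantRecord(v.CHROM, v.POS, v.REF, alt))
    finally:
        vcf.close()
    return SomaticVariantSet(sid, tuple(records))


_TSV_VARIANT_COLS = ("chromosome", "position", "ref", "alt")


def _variant_sets_from_tsv(path: str | os.PathLike) -> dict[str, SomaticVariantSet]:
    """Parse the minimal MAF-like tab-separated dialect.

    Required columns: sample, chromosome, position, ref, alt. An optional
    ``filter`` column restricts loading to rows whose value is PASS (or '.').
    Parsed by hand so malformed lines can be reported with their line number.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise CohortIOError(f"{path}: empty variant table (missing header)")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    missing = [c for c in ("sample", *_TSV_VARIANT_COLS) if c not in header]
    if missing:
        raise CohortIOError(f"{path}: missing columns {missing}")
    idx = {c: header.index(c) for c in header}
    has_filter = "filter" in idx
    per_sample: dict[str, list[VariantRecord]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise CohortIOError(
                f"{path}: line {lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        try:
            sample = fields[idx["sample"]].strip()
            pos = int(fields[idx["position"]])
            rec = VariantRecord(
                fields[idx["chromosome"]], pos, fields[idx["ref"]], fields[idx["alt"]]
            )
        except (ValueError, CohortIOError) as exc:
            raise CohortIOError(f"{path}: line {lineno}: {exc}") from exc
        if has_filter and fields[idx["filter"]].strip() not in ("PASS", ".", ""):
            continue
        per_sample.setdefault(sample, []).append(rec)
    return {
        sid: SomaticVariantSet(sid, tuple(recs)) for sid, recs in sorted(per_sample.items())
    }


def read_variant_table(
    path: str | os.PathLike, dialect: str = "vcf", sample_id: str | None = None
) -> SomaticVariantSet:
    """Read a single sample's somatic variants from a VCF or MAF-like TSV.

    For the ``tsv`` dialect the file must contain exactly one sample unless
    ``sample_id`` selects one.
    """
    if dialect == "vcf":
        return _variant_set_from_vcf(path, sample_id)
    if dialect == "tsv":
        sets = _variant_sets_from_tsv(path)
        if sample_id is not None:
            if sample_id not in sets:
                raise CohortIOError(f"{path}: sample {sample_id!r} not present")
            return sets[sample_id]
        if len(sets) > 1:
            raise CohortIOError(
                f"{path}: {len(sets)} samples present; use load_variant_cohort or pass sample_id"
            )
        if not sets:
            raise CohortIOError(f"{path}: no variant rows and no sample to infer")
        return next(iter(sets.values()))
    raise CohortIOError(f"unknown variant dialect {dialect!r}")


def load_variant_cohort(path: str | os.PathLike) -> dict[str, SomaticVariantSet]:
    """Load a cohort of variant sets from a directory of per-sample VCFs or a TSV."""
    p = Path(path)
    if p.is_dir():
        out = {}
        for f in sorted(p.iterdir()):
            if f.suffix == ".vcf" or f.name.endswith(".vcf.gz"):
                vs = _variant_set_from_vcf(f, None)
                out[vs.sample_id] = vs
        if not out:
            raise CohortIOError(f"{path}: no VCF files found")
        return out
    return _variant_sets_from_tsv(p)


def read_seg(
    path: str | os.PathLike, seg_log2: bool = False
) -> dict[str, CNProfile]:
    """Read SEG-style TSV: sample, chromosome, start, end, copy_number [, ploidy].

    ``copy_number`` is absolute total copy number by default; with
    ``seg_log2=True`` the column is a log2 ratio converted via
    ``copy_number = ploidy * 2**value``. Missing ploidy column defaults to 2.0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chromosome": str})
    required = {"sample", "chromosome", "start", "end", "copy_number"}
    missing = required - set(df.columns)
    if missing:
        raise CohortIOError(f"{path}: missing columns {sorted(missing)}")
    has_ploidy = "ploidy" in df.columns
    profiles = {}
    for sid, grp in df.groupby("sample", sort=True):
        if has_ploidy:
            ploidies = grp["ploidy"].astype(float).unique()
            if len(ploidies) != 1:
                raise CohortIOError(f"{path}: inconsistent ploidy for sample {sid}")
            ploidy = float(ploidies[0])
        else:
            ploidy = 2.0
        segs = []
        for row in grp.itertuples(index=False):
            cn = float(row.copy_number)
            if seg_log2:
                cn = ploidy * 2.0 ** cn
            segs.append(CNSegment(str(row.chromosome), int(row.start), int(row.end), cn))
        profiles[str(sid)] = CNProfile(str(sid), tuple(segs), ploidy)
    return profiles


def read_clinical(path: str | os.PathLike) -> dict[str, ClinicalRecord]:
    """Read the clinical/MSI TSV: sample, msi_status, followup_months, event
    [, tcga_subtype, cn_cluster]."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise CohortIOError(f"{path}: missing 'sample' column")
    if df["sample"].duplicated().any():
        dups = sorted(df.loc[df["sample"].duplicated(), "sample"].unique())
        raise CohortIOError(f"{path}: duplicate sample ids {dups}")
    records = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        msi = d.get("msi_status", MSI_UNKNOWN)
        if pd.isna(msi):
            msi = MSI_UNKNOWN
        else:
            try:
                msi = float(msi)
            except (TypeError, ValueError):
                msi = str(msi)
        followup = d.get("followup_months")
        followup = None if followup is None or pd.isna(followup) else float(followup)
        event = d.get("event")
        event = None if event is None or pd.isna(event) else bool(int(event))
        subtype = d.get("tcga_subtype")
        subtype = None if subtype is None or pd.isna(subtype) else str(subtype)
        cluster = d.get("cn_cluster")
        cluster = None if cluster is None or pd.isna(cluster) else int(cluster)
        rec = ClinicalRecord(str(row.sample), msi, followup, event, subtype, cluster)
        records[rec.sample_id] = rec
    return records


def read_gene_bed(path: str | os.PathLike) -> GeneModel:
    """Read a BED gene model (0-based half-open) into 1-based inclusive genes."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise CohortIOError(f"{path}: line {lineno}: BED needs 4 columns")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            genes.append(Gene(name, chrom, start + 1, end))
    return GeneModel(tuple(genes))


# ---------------------------------------------------------------------------
# call table writer/reader (see cascade.SubtypeCall)

_CALL_COLUMNS = (
    "sample",
    "subtype",
    "snv_count",
    "ca_rate",
    "cg_rate",
    "msi_high",
    "cn_high_posterior",
)


def write_calls(calls: Sequence, path: str | os.PathLike) -> None:
    """Write subtype calls as TSV; numeric evidence at 6 decimals (lossless round-trip)."""
    if not calls:
        raise CohortIOError("no calls to write")
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for c in calls:
            post = "NA" if c.cn_high_posterior is None else f"{c.cn_high_posterior:.6f}"
            fh.write(
                f"{c.sample_id}\t{c.subtype}\t{c.snv_count}\t{c.ca_rate:.6f}\t"
                f"{c.cg_rate:.6f}\t{int(c.msi_high)}\t{post}\n"
            )


def read_calls(path: str | os.PathLike) -> list:
    from .cascade import SubtypeCall

    df = pd.read_csv(path, sep="\t", dtype={"sample": str}, na_values=["NA"])
    calls = []
    for row in df.itertuples(index=False):
        post = None if pd.isna(row.cn_high_posterior) else float(row.cn_high_posterior)
        calls.append(
            SubtypeCall(
                sample_id=str(row.sample),
                subtype=str(row.subtype),
                snv_count=int(row.snv_count),
                ca_rate=float(row.ca_rate),
                cg_rate=float(row.cg_rate),
                msi_high=bool(row.msi_high),
                cn_high_posterior=post,
            )
        )
    return calls
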