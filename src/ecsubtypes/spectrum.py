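"""Substitution spectra, the POLE ultramutated rule, and the MSI-high gate.

Substitutions are collapsed to the six pyrimidine-centric classes
(C>A, C>G, C>T, T>A, T>C, T>G): a purine-reference change is reported as the
substitution of the complementary pyrimidine on the opposite strand, so both
strand representations of the same somatic event land in one class.

POLE-ultramutated tumors are called by the spectrum rule: more than 500
somatic SNVs, a C>A fraction above 0.2 and a C>G fraction below 0.03 — the
canonical mutation-spectrum signature of polymerase-epsilon exonuclease-domain
mutants. All three comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import ClinicalRecord, SomaticVariantSet, MSI_HIGH, MSI_UNKNOWN

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def collapse_substitution(ref: str, alt: str) -> str:
    """Map a single-base substitution to its pyrimidine-centric class."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref in ("G", "A"):  # purine reference: report the opposite strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class SubstitutionSpectrum:
    """Counts over the six collapsed substitution classes for one sample."""

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        full = {c: int(self.counts.get(c, 0)) for c in SPECTRUM_CLASSES}
        if any(v < 0 for v in full.values()):
            raise ValueError("negative class count")
        unknown = set(self.counts) - set(SPECTRUM_CLASSES)
        if unknown:
            raise ValueError(f"unknown substitution classes {sorted(unknown)}")
        object.__setattr__(self, "counts", full)

    @property
    def total_snv(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "SubstitutionSpectrum") -> "SubstitutionSpectrum":
        return SubstitutionSpectrum(
            {c: self.counts[c] + other.counts[c] for c in SPECTRUM_CLASSES}
        )

    def rate(self, cls: str) -> float:
        if cls not in SPECTRUM_CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        total = self.total_snv
        return self.counts[cls] / total if total else 0.0


def compute_spectrum(sample: SomaticVariantSet) -> SubstitutionSpectrum:
    """Count a sample's SNVs by collapsed class; indels and other classes are ignored."""
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for v in sample.variants:
        if v.variant_class == "SNV":
            counts[collapse_substitution(v.ref_allele, v.alt_allele)] += 1
    return SubstitutionSpectrum(counts)


def ca_rate(s: SubstitutionSpectrum) -> float:
    """Fraction of SNVs in the collapsed C>A class (0 for an empty spectrum)."""
    return s.rate("C>A")


def cg_rate(s: SubstitutionSpectrum) -> float:
    """Fraction of SNVs in the collapsed C>G class (0 for an empty spectrum)."""
    return s.rate("C>G")


@dataclass(frozen=True)
class PoleRuleParams:
    """Thresholds of the POLE spectrum rule and the numeric MSI-high cutoff."""

    snv_min: int = 500
    ca_min: float = 0.2
    cg_max: float = 0.03
    msi_high_threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.ca_min <= 1.0:
            raise ValueError("ca_min must be in [0,1]")
        if not 0.0 <= self.cg_max <= 1.0:
            raise ValueError("cg_max must be in [0,1]")
        if self.snv_min < 0:
            raise ValueError("snv_min must be >= 0")


def is_pole(s: SubstitutionSpectrum, params: PoleRuleParams | None = None) -> bool:
    """POLE rule: total_snv > snv_min AND ca_rate > ca_min AND cg_rate < cg_max.

    All inequalities are strict; a zero-SNV sample is never POLE.
    """
    p = params or PoleRuleParams()
    return (
        s.total_snv > p.snv_min
        and ca_rate(s) > p.ca_min
        and cg_rate(s) < p.cg_max
    )


def is_msi_high(record: ClinicalRecord, params: PoleRuleParams | None = None) -> bool:
    """MSI-high gate: categorical MSI-high, or numeric score >= msi_high_threshold."""
    p = params or PoleRuleParams()
    status = record.msi_status
    if isinstance(status, str):
        if status == MSI_UNKNOWN:
            raise ValueError(f"MSI status unknown for sample {record.sample_id}")
        return status == MSI_HIGH
    return float(status) >= p.msi_high_threshold
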