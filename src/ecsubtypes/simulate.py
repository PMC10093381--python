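"""Synthetic endometrial-cancer cohort generator.

Emulates the statistical structure the cascade assumes, per subtype:

* SNV burden (log-normal) and six-class substitution spectrum — POLE samples
  ultramutated with a C>A-skewed, C>G-depleted spectrum;
* MSI-high status (Bernoulli, near-certain for MSI samples);
* copy-number segment profiles — per-chromosome tilings with
  subtype-dependent alteration probability and ploidy (aneuploid CN-high);
* CN cluster labels (cluster 4 for CN-high, 1-3 otherwise);
* subtype-dependent exponential survival with independent exponential
  censoring, hazards ordered POLE < CN-low < MSI < CN-high.

Default cohort composition is 7% POLE, 28% MSI, 39% CN-low, 26% CN-high at
n = 232. Default event hazards are back-solved from 36-month survival
targets of 1.00 / 0.87 / 0.81 / 0.60 via S(t) = exp(-h t). A single master
seed fans out to per-stage substreams, so each stage is independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    ClinicalRecord,
    CNProfile,
    CNSegment,
    Gene,
    GeneModel,
    SomaticVariantSet,
    SUBTYPES,
    VariantRecord,
)
from .spectrum import SPECTRUM_CLASSES

# rounded hg-scale chromosome lengths in Mb (female genome, no Y)
CHROM_LENGTHS_MB = {
    "1": 249, "2": 243, "3": 198, "4": 190, "5": 182, "6": 171, "7": 159,
    "8": 145, "9": 138, "10": 134, "11": 135, "12": 133, "13": 114,
    "14": 107, "15": 102, "16": 90, "17": 83, "18": 80, "19": 59,
    "20": 64, "21": 47, "22": 51, "X": 155,
}

_CLASS_REF_ALT = {
    "C>A": (("C", "A"), ("G", "T")),
    "C>G": (("C", "G"), ("G", "C")),
    "C>T": (("C", "T"), ("G", "A")),
    "T>A": (("T", "A"), ("A", "T")),
    "T>C": (("T", "C"), ("A", "G")),
    "T>G": (("T", "G"), ("A", "C")),
}


@dataclass(frozen=True)
class SubtypeParams:
    """Generative parameters for one molecular subtype."""

    snv_log_mean: float
    snv_log_sd: float
    spectrum: tuple[float, ...]  # probabilities over SPECTRUM_CLASSES
    msi_high_prob: float
    segments_per_chrom_mean: float
    alteration_prob: float
    gain_prob: float
    ploidy_mean: float
    ploidy_sd: float
    event_hazard: float  # monthly
    censor_hazard: float  # monthly

    def __post_init__(self):
        if len(self.spectrum) != len(SPECTRUM_CLASSES):
            raise ValueError("spectrum needs six class probabilities")
        if abs(sum(self.spectrum) - 1.0) > 1e-9:
            raise ValueError("spectrum probabilities must sum to 1")
        for p in (self.msi_high_prob, self.alteration_prob, self.gain_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")
        if self.event_hazard < 0 or self.censor_hazard < 0:
            raise ValueError("hazards must be >= 0")


DEFAULT_SUBTYPE_PARAMS: dict[str, SubtypeParams] = {
    # ultramutated, C>A-rich / C>G-poor spectrum, quiet genome, best outcome
    "POLE": SubtypeParams(
        snv_log_mean=float(np.log(3000.0)), snv_log_sd=0.35,
        spectrum=(0.30, 0.01, 0.35, 0.09, 0.15, 0.10),
        msi_high_prob=0.35,
        segments_per_chrom_mean=1.5, alteration_prob=0.03, gain_prob=0.5,
        ploidy_mean=2.0, ploidy_sd=0.05,
        event_hazard=0.0, censor_hazard=0.008,
    ),
    # hypermutated but with an ordinary spectrum; MSI-high nearly always
    "MSI": SubtypeParams(
        snv_log_mean=float(np.log(1200.0)), snv_log_sd=0.5,
        spectrum=(0.08, 0.04, 0.45, 0.06, 0.27, 0.10),
        msi_high_prob=0.97,
        segments_per_chrom_mean=1.5, alteration_prob=0.05, gain_prob=0.5,
        ploidy_mean=2.0, ploidy_sd=0.08,
        event_hazard=0.0058534, censor_hazard=0.008,  # S(36) ~ 0.81
    ),
    # copy-number quiet endometrioid-like residue
    "CN-low": SubtypeParams(
        snv_log_mean=float(np.log(60.0)), snv_log_sd=0.6,
        spectrum=(0.08, 0.05, 0.45, 0.07, 0.25, 0.10),
        msi_high_prob=0.02,
        segments_per_chrom_mean=1.5, alteration_prob=0.03, gain_prob=0.5,
        ploidy_mean=2.0, ploidy_sd=0.08,
        event_hazard=0.0038684, censor_hazard=0.008,  # S(36) ~ 0.87
    ),
    # serous-like: heavily altered, aneuploid, worst outcome
    "CN-high": SubtypeParams(
        snv_log_mean=float(np.log(90.0)), snv_log_sd=0.5,
        spectrum=(0.10, 0.06, 0.42, 0.08, 0.24, 0.10),
        msi_high_prob=0.02,
        segments_per_chrom_mean=3.0, alteration_prob=0.45, gain_prob=0.5,
        ploidy_mean=3.2, ploidy_sd=0.3,
        event_hazard=0.0141896, censor_hazard=0.008,  # S(36) ~ 0.60
    ),
}


@dataclass(frozen=True)
class SimConfig:
    n_samples: int = 232
    proportions: tuple[float, ...] = (0.07, 0.28, 0.39, 0.26)  # POLE, MSI, CN-low, CN-high
    seed: int = 7
    n_genes: int = 200
    exact_proportions: bool = False

    def __post_init__(self):
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if len(self.proportions) != 4:
            raise ValueError("need four subtype proportions")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if any(p < 0 for p in self.proportions):
            raise ValueError("proportions must be non-negative")


@dataclass
class SimulatedCohort:
    variants: dict[str, SomaticVariantSet]
    profiles: dict[str, CNProfile]
    clinical: dict[str, ClinicalRecord]
    labels: dict[str, str]
    gene_model: GeneModel
    config: SimConfig = field(default=None)


def _apportion(n: int, proportions) -> list[int]:
    """Largest-remainder apportionment of n into integer class counts."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _draw_labels(config: SimConfig, rng: np.random.Generator) -> list[str]:
    if config.exact_proportions:
        counts = _apportion(config.n_samples, config.proportions)
        labels = [s for s, c in zip(SUBTYPES, counts) for _ in range(c)]
        rng.shuffle(labels)
        return labels
    return [str(s) for s in rng.choice(SUBTYPES, size=config.n_samples, p=config.proportions)]


def simulate_gene_model(n_genes: int, rng: np.random.Generator) -> GeneModel:
    chroms = list(CHROM_LENGTHS_MB)
    weights = np.array([CHROM_LENGTHS_MB[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    genes = []
    for i in range(n_genes):
        c = chroms[rng.choice(len(chroms), p=weights)]
        length = int(rng.integers(20_000, 2_000_000))
        start = int(rng.integers(1, CHROM_LENGTHS_MB[c] * 1_000_000 - length))
        genes.append(Gene(f"G{i + 1:04d}", c, start, start + length - 1))
    return GeneModel(tuple(genes))


def _simulate_variants(
    sid: str, params: SubtypeParams, rng: np.random.Generator
) -> SomaticVariantSet:
    n_snv = max(0, int(round(rng.lognormal(params.snv_log_mean, params.snv_log_sd))))
    class_counts = rng.multinomial(n_snv, params.spectrum)
    chroms = list(CHROM_LENGTHS_MB)
    weights = np.array([CHROM_LENGTHS_MB[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    records = []
    for cls, count in zip(SPECTRUM_CLASSES, class_counts):
        if count == 0:
            continue
        chrom_idx = rng.choice(len(chroms), size=count, p=weights)
        strands = rng.random(count) < 0.5
        for ci, plus in zip(chrom_idx, strands):
            c = chroms[ci]
            pos = int(rng.integers(1, CHROM_LENGTHS_MB[c] * 1_000_000))
            ref, alt = _CLASS_REF_ALT[cls][0 if plus else 1]
            records.append(VariantRecord(c, pos, ref, alt))
    n_indel = int(rng.poisson(0.02 * n_snv + 2))
    for _ in range(n_indel):
        c = chroms[rng.choice(len(chroms), p=weights)]
        pos = int(rng.integers(1, CHROM_LENGTHS_MB[c] * 1_000_000))
        if rng.random() < 0.5:
            records.append(VariantRecord(c, pos, "CT", "C"))
        else:
            records.append(VariantRecord(c, pos, "A", "AG"))
    return SomaticVariantSet(sid, tuple(records))


def _simulate_profile(
    sid: str, params: SubtypeParams, rng: np.random.Generator
) -> CNProfile:
    ploidy = float(np.clip(rng.normal(params.ploidy_mean, params.ploidy_sd), 1.2, 6.0))
    segments = []
    for c, length_mb in CHROM_LENGTHS_MB.items():
        length = length_mb * 1_000_000
        n_seg = 1 + int(rng.poisson(params.segments_per_chrom_mean))
        if n_seg > 1:
            breaks = np.unique(rng.integers(2, length, size=n_seg - 1))
        else:
            breaks = np.array([], dtype=int)
        starts = np.concatenate([[1], breaks])
        ends = np.concatenate([breaks - 1, [length]])
        for s, e in zip(starts, ends):
            if rng.random() < params.alteration_prob:
                if rng.random() < params.gain_prob:
                    cn = ploidy + rng.uniform(0.8, 2.5)
                else:
                    cn = max(0.1, ploidy - rng.uniform(0.8, 1.8))
            else:
                cn = max(0.1, ploidy + rng.uniform(-0.35, 0.35))
            segments.append(CNSegment(c, int(s), int(e), round(float(cn), 4)))
    return CNProfile(sid, tuple(segments), round(ploidy, 4))


def simulate_survival(
    labels: dict[str, str],
    params: dict[str, SubtypeParams] | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> dict[str, tuple[float, bool]]:
    """Exponential event and censoring times per sample; follow-up is the
    minimum of the two with an event flag. A zero event hazard yields a
    censored sample (survival 1.0 throughout)."""
    params = params or DEFAULT_SUBTYPE_PARAMS
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    out = {}
    for sid, label in labels.items():
        p = params[label]
        t_event = rng.exponential(1.0 / p.event_hazard) if p.event_hazard > 0 else np.inf
        t_cens = (
            rng.exponential(1.0 / p.censor_hazard) if p.censor_hazard > 0 else np.inf
        )
        if not np.isfinite(t_event) and not np.isfinite(t_cens):
            t_cens = 120.0  # administrative fallback when both hazards are zero
        followup = float(min(t_event, t_cens))
        out[sid] = (round(followup, 3), bool(t_event <= t_cens))
    return out


def simulate_cohort(
    params: dict[str, SubtypeParams] | None = None,
    config: SimConfig | None = None,
) -> SimulatedCohort:
    """Generate a full synthetic cohort, reproducible from ``config.seed``."""
    params = params or DEFAULT_SUBTYPE_PARAMS
    config = config or SimConfig()
    ss = np.random.SeedSequence(config.seed)
    rng_label, rng_gene, rng_var, rng_cn, rng_msi, rng_surv = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    labels_list = _draw_labels(config, rng_label)
    sample_ids = [f"S{i + 1:04d}" for i in range(config.n_samples)]
    labels = dict(zip(sample_ids, labels_list))
    gene_model = simulate_gene_model(config.n_genes, rng_gene)
    variants = {sid: _simulate_variants(sid, params[labels[sid]], rng_var) for sid in sample_ids}
    profiles = {sid: _simulate_profile(sid, params[labels[sid]], rng_cn) for sid in sample_ids}
    survival = simulate_survival(labels, params, rng=rng_surv)
    clinical = {}
    for sid in sample_ids:
        label = labels[sid]
        msi = "MSI-high" if rng_msi.random() < params[label].msi_high_prob else "MSS"
        followup, event = survival[sid]
        clinical[sid] = ClinicalRecord(
            sample_id=sid,
            msi_status=msi,
            followup_months=followup,
            event=event,
            tcga_subtype=label,
            cn_cluster=4 if label == "CN-high" else int(rng_msi.integers(1, 4)),
        )
    return SimulatedCohort(variants, profiles, clinical, labels, gene_model, config)


def simulate_cn_training_cohort(
    n: int = 240,
    seed: int = 7,
    params: dict[str, SubtypeParams] | None = None,
) -> tuple[list[CNProfile], np.ndarray, GeneModel]:
    """Synthetic CN-cluster-4 training set: n samples at the default subtype
    mix with exact apportionment (cluster 4 = CN-high, ~26% positives).

    Returns (profiles, binary labels, gene model).
    """
    cohort = simulate_cohort(
        params,
        SimConfig(n_samples=n, seed=seed, exact_proportions=True),
    )
    sids = sorted(cohort.profiles)
    profiles = [cohort.profiles[s] for s in sids]
    y = np.array([1 if cohort.labels[s] == "CN-high" else 0 for s in sids])
    return profiles, y, cohort.gene_model


# ---------------------------------------------------------------------------
# on-disk output in the cohort_io dialects


def write_cohort(cohort: SimulatedCohort, outdir) -> None:
    """Write variants (per-sample VCF), segments (SEG TSV), clinical (TSV),
    truth labels (TSV), and the gene model (BED)."""
    outdir = Path(outdir)
    (outdir / "variants").mkdir(parents=True, exist_ok=True)
    contig_lines = "".join(
        f"##contig=<ID={c},length={mb * 1_000_000}>\n" for c, mb in CHROM_LENGTHS_MB.items()
    )
    chrom_order = {c: i for i, c in enumerate(CHROM_LENGTHS_MB)}
    for sid, vs in cohort.variants.items():
        with open(outdir / "variants" / f"{sid}.vcf", "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(contig_lines)
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for v in sorted(
                vs.variants, key=lambda v: (chrom_order[v.chromosome], v.position)
            ):
                fh.write(
                    f"{v.chromosome}\t{v.position}\t.\t{v.ref_allele}\t"
                    f"{v.alt_allele}\t.\tPASS\t.\n"
                )
    with open(outdir / "segments.seg", "w") as fh:
        fh.write("sample\tchromosome\tstart\tend\tcopy_number\tploidy\n")
        for sid, prof in cohort.profiles.items():
            for s in sorted(prof.segments, key=lambda s: (chrom_order[s.chromosome], s.start)):
                fh.write(
                    f"{sid}\t{s.chromosome}\t{s.start}\t{s.end}\t"
                    f"{s.copy_number:.4f}\t{prof.ploidy:.4f}\n"
                )
    with open(outdir / "clinical.tsv", "w") as fh:
        fh.write("sample\tmsi_status\tfollowup_months\tevent\ttcga_subtype\tcn_cluster\n")
        for sid, rec in cohort.clinical.items():
            fh.write(
                f"{sid}\t{rec.msi_status}\t{rec.followup_months}\t{int(rec.event)}\t"
                f"{rec.tcga_subtype}\t{rec.cn_cluster}\n"
            )
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("sample\tsubtype\n")
        for sid, label in cohort.labels.items():
            fh.write(f"{sid}\t{label}\n")
    with open(outdir / "genes.bed", "w") as fh:
        for g in sorted(cohort.gene_model, key=lambda g: (chrom_order[g.chromosome], g.start)):
            # BED is 0-based half-open
            fh.write(f"{g.chromosome}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")
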