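"""Copy-number feature engineering for the CN-cluster-4 model.

Per-sample feature vector, in fixed order:

* gains and losses per sample (segment counts),
* gains and losses per chromosome (fixed universe chr1-22, X),
* gains and losses per gene for the k most frequently altered genes
  (selected on training samples only),
* ploidy,
* total length of altered segments per genome megabase.

A segment is a gain when its copy number is at least ``ploidy + gain_margin``
and a loss when at most ``ploidy - loss_margin``; calls are relative to the
sample's own ploidy so that whole-genome duplication does not flood the counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CNProfile, CNSegment, GeneModel

CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X",)


@dataclass(frozen=True)
class CNFeatureSpec:
    gain_margin: float = 0.5
    loss_margin: float = 0.5
    top_k_genes: int = 25
    genome_length_mb: float = 3100.0

    def __post_init__(self):
        if self.gain_margin <= 0 or self.loss_margin <= 0:
            raise ValueError("margins must be positive")
        if self.top_k_genes < 1:
            raise ValueError("top_k_genes must be >= 1")
        if self.genome_length_mb <= 0:
            raise ValueError("genome_length_mb must be positive")


@dataclass(frozen=True)
class CNFeatureMatrix:
    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # samples x features
    selected_genes: tuple[str, ...]

    def __post_init__(self):
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("matrix dimensions do not match ids/names")


def call_gain_loss(seg: CNSegment, ploidy: float, spec: CNFeatureSpec | None = None) -> str:
    spec = spec or CNFeatureSpec()
    if seg.copy_number >= ploidy + spec.gain_margin:
        return "gain"
    if seg.copy_number <= ploidy - spec.loss_margin:
        return "loss"
    return "neutral"


def sample_counts(profile: CNProfile, spec: CNFeatureSpec | None = None) -> tuple[int, int]:
    """Counts of gain and loss segments over the whole profile."""
    spec = spec or CNFeatureSpec()
    calls = [call_gain_loss(s, profile.ploidy, spec) for s in profile.segments]
    return calls.count("gain"), calls.count("loss")


def chromosome_counts(
    profile: CNProfile, spec: CNFeatureSpec | None = None
) -> dict[str, tuple[int, int]]:
    """Per-chromosome (gain, loss) segment counts over the fixed chr1-22,X universe."""
    spec = spec or CNFeatureSpec()
    counts = {c: [0, 0] for c in CHROMOSOMES}
    for s in profile.segments:
        if s.chromosome not in counts:
            raise ValueError(
                f"chromosome {s.chromosome!r} outside the fixed universe 1-22,X"
            )
        call = call_gain_loss(s, profile.ploidy, spec)
        if call == "gain":
            counts[s.chromosome][0] += 1
        elif call == "loss":
            counts[s.chromosome][1] += 1
    return {c: tuple(v) for c, v in counts.items()}


def _altered_segments(profile: CNProfile, spec: CNFeatureSpec) -> list[CNSegment]:
    return [
        s
        for s in profile.segments
        if call_gain_loss(s, profile.ploidy, spec) != "neutral"
    ]


def _gene_hit(gene, segments) -> bool:
    # 1-based inclusive intervals overlap iff start <= other end on both sides
    return any(
        s.chromosome == gene.chromosome and s.start <= gene.end and gene.start <= s.end
        for s in segments
    )


def select_top_genes(
    training_profiles: list[CNProfile],
    genes: GeneModel,
    spec: CNFeatureSpec | None = None,
) -> tuple[str, ...]:
    """The k genes most frequently overlapped by an altered segment across
    training samples; ties broken by genomic order (chromosome, start, gene_id).

    Genes never altered in training are not selectable, so the list may be
    shorter than k. Must only ever see training-fold samples.
    """
    spec = spec or CNFeatureSpec()
    if len(genes) == 0:
        raise ValueError("empty gene model")
    altered = [_altered_segments(p, spec) for p in training_profiles]
    chrom_order = {c: i for i, c in enumerate(CHROMOSOMES)}
    scored = []
    for g in genes:
        freq = sum(_gene_hit(g, segs) for segs in altered)
        if freq > 0:
            key = (-freq, chrom_order.get(g.chromosome, len(chrom_order)), g.start, g.gene_id)
            scored.append((key, g.gene_id))
    scored.sort()
    return tuple(gid for _, gid in scored[: spec.top_k_genes])


def gene_counts(
    profile: CNProfile,
    selected_genes: tuple[str, ...],
    genes: GeneModel,
    spec: CNFeatureSpec | None = None,
) -> dict[str, tuple[int, int]]:
    """Per selected gene, the number of gain and loss segments overlapping it
    by at least one base."""
    spec = spec or CNFeatureSpec()
    by_id = {g.gene_id: g for g in genes}
    gains = [s for s in profile.segments if call_gain_loss(s, profile.ploidy, spec) == "gain"]
    losses = [s for s in profile.segments if call_gain_loss(s, profile.ploidy, spec) == "loss"]
    out = {}
    for gid in selected_genes:
        g = by_id[gid]
        n_gain = sum(
            s.chromosome == g.chromosome and s.start <= g.end and g.start <= s.end
            for s in gains
        )
        n_loss = sum(
            s.chromosome == g.chromosome and s.start <= g.end and g.start <= s.end
            for s in losses
        )
        out[gid] = (n_gain, n_loss)
    return out


def altered_length_per_mb(profile: CNProfile, spec: CNFeatureSpec | None = None) -> float:
    """Total altered bases divided by genome length in bases (unitless density)."""
    spec = spec or CNFeatureSpec()
    total = sum(s.length for s in _altered_segments(profile, spec))
    return total / (spec.genome_length_mb * 1e6)


def ploidy_feature(profile: CNProfile) -> float:
    return profile.ploidy


def feature_names(selected_genes: tuple[str, ...]) -> tuple[str, ...]:
    names = ["sample_gains", "sample_losses"]
    for c in CHROMOSOMES:
        names += [f"chr{c}_gains", f"chr{c}_losses"]
    for g in selected_genes:
        names += [f"{g}_gains", f"{g}_losses"]
    names += ["ploidy", "altered_length_per_mb"]
    return tuple(names)


def build_feature_matrix(
    profiles: list[CNProfile],
    genes: GeneModel,
    spec: CNFeatureSpec | None = None,
    selected_genes: tuple[str, ...] | None = None,
) -> CNFeatureMatrix:
    """Build the samples-by-features matrix.

    With ``selected_genes`` omitted the gene list is selected on the given
    profiles (training mode); supplying it (test mode) never re-selects.
    """
    spec = spec or CNFeatureSpec()
    if selected_genes is None:
        selected_genes = select_top_genes(profiles, genes, spec)
    rows = []
    for p in profiles:
        row = list(sample_counts(p, spec))
        cc = chromosome_counts(p, spec)
        for c in CHROMOSOMES:
            row += list(cc[c])
        gc = gene_counts(p, selected_genes, genes, spec)
        for gid in selected_genes:
            row += list(gc[gid])
        row += [ploidy_feature(p), altered_length_per_mb(p, spec)]
        rows.append(row)
    values = np.asarray(rows, dtype=float).reshape(len(profiles), -1)
    return CNFeatureMatrix(
        sample_ids=tuple(p.sample_id for p in profiles),
        feature_names=feature_names(tuple(selected_genes)),
        values=values,
        selected_genes=tuple(selected_genes),
    )


class CNFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from copy-number profiles to feature vectors.

    ``fit`` selects the top-k most frequently altered genes on the training
    profiles; ``transform`` builds feature rows using that fixed gene list,
    so a pipeline using this transformer cannot leak held-out alteration
    patterns into the feature definition.

    Parameters mirror :class:`CNFeatureSpec`; ``gene_model`` is the gene
    universe used for the per-gene features.
    """

    def __init__(
        self,
        gene_model: GeneModel = None,
        gain_margin: float = 0.5,
        loss_margin: float = 0.5,
        top_k_genes: int = 25,
        genome_length_mb: float = 3100.0,
    ):
        self.gene_model = gene_model
        self.gain_margin = gain_margin
        self.loss_margin = loss_margin
        self.top_k_genes = top_k_genes
        self.genome_length_mb = genome_length_mb

    def _spec(self) -> CNFeatureSpec:
        return CNFeatureSpec(
            gain_margin=self.gain_margin,
            loss_margin=self.loss_margin,
            top_k_genes=self.top_k_genes,
            genome_length_mb=self.genome_length_mb,
        )

    def fit(self, X: list[CNProfile], y=None):
        if self.gene_model is None:
            raise ValueError("gene_model is required")
        self.selected_genes_ = select_top_genes(list(X), self.gene_model, self._spec())
        self.feature_names_ = feature_names(self.selected_genes_)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: list[CNProfile]) -> np.ndarray:
        if not hasattr(self, "selected_genes_"):
            raise ValueError("CNFeatureExtractor is not fitted")
        fm = build_feature_matrix(
            list(X), self.gene_model, self._spec(), self.selected_genes_
        )
        return fm.values

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
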