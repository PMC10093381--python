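"""Hierarchical subtype assignment: POLE, then MSI, then CN-high, else CN-low.

The cascade mirrors the clinical decision order: the POLE spectrum rule fires
first (a POLE-positive sample is POLE even when MSI-high), the MSI-high gate
second, and only the residue reaches the copy-number stage, where a Gaussian
naive Bayes posterior for CN cluster 4 at or above the decision threshold
yields CN-high; everything else is CN-low.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .cn_features import CNFeatureExtractor, CNFeatureSpec, build_feature_matrix
from .io import ClinicalRecord, CNProfile, GeneModel, SomaticVariantSet, SUBTYPES
from .naive_bayes import GaussianNaiveBayes, predict_posterior
from .spectrum import PoleRuleParams, ca_rate, cg_rate, compute_spectrum, is_msi_high, is_pole

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SubtypeCall:
    """Assigned subtype with the evidence that produced it."""

    sample_id: str
    subtype: str
    snv_count: int
    ca_rate: float
    cg_rate: float
    msi_high: bool
    cn_high_posterior: float | None  # None when resolved before the CN stage

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")


class SubtypeCascadeClassifier(ClassifierMixin, BaseEstimator):
    """Four-class endometrial-cancer subtype classifier.

    ``fit`` trains only the copy-number stage: it selects the most frequently
    altered genes on the training profiles and fits the Gaussian NB on CN
    cluster 4 membership (cluster labels binarized, cluster 4 positive). The
    POLE rule and MSI gate are fixed clinical rules with configurable
    thresholds, not fitted.

    Parameters
    ----------
    gene_model : GeneModel
        Gene universe for the per-gene CN features.
    pole_params : PoleRuleParams
        Thresholds of the POLE spectrum rule and numeric MSI cutoff.
    feature_spec : CNFeatureSpec
        Copy-number feature engineering parameters.
    cn_high_threshold : float
        Posterior cutoff for calling CN-high at the final stage.
    full_evidence : bool
        When true, the CN posterior is also computed (and reported) for
        samples already resolved as POLE or MSI.
    """

    def __init__(
        self,
        gene_model: GeneModel = None,
        pole_params: PoleRuleParams = None,
        feature_spec: CNFeatureSpec = None,
        cn_high_threshold: float = 0.5,
        full_evidence: bool = False,
    ):
        self.gene_model = gene_model
        self.pole_params = pole_params
        self.feature_spec = feature_spec
        self.cn_high_threshold = cn_high_threshold
        self.full_evidence = full_evidence

    def _pole_params(self) -> PoleRuleParams:
        return self.pole_params or PoleRuleParams()

    def _feature_spec(self) -> CNFeatureSpec:
        return self.feature_spec or CNFeatureSpec()

    # -- training of the CN stage ------------------------------------------

    def fit(self, X: list[CNProfile], y):
        """Fit the CN-cluster-4 stage. ``y`` is 1 for cluster 4, else 0 (or
        raw cluster labels 1-4, binarized here)."""
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            y = (y == 4).astype(int)
        spec = self._feature_spec()
        self.extractor_ = CNFeatureExtractor(
            gene_model=self.gene_model,
            gain_margin=spec.gain_margin,
            loss_margin=spec.loss_margin,
            top_k_genes=spec.top_k_genes,
            genome_length_mb=spec.genome_length_mb,
        )
        Xf = self.extractor_.fit_transform(list(X))
        self.nb_ = GaussianNaiveBayes().fit(Xf, y)
        self.selected_genes_ = self.extractor_.selected_genes_
        self.classes_ = np.asarray(SUBTYPES, dtype=object)
        return self

    def _check_fitted(self):
        if not hasattr(self, "nb_"):
            raise ValueError("cascade is not fitted: call fit or load a model file")

    def cn_posterior(self, profile: CNProfile) -> float:
        self._check_fitted()
        row = self.extractor_.transform([profile])[0]
        pos_col = int(np.where(self.nb_.classes_ == 1)[0][0])
        return float(self.nb_.predict_proba(row.reshape(1, -1))[0, pos_col])

    # -- classification ----------------------------------------------------

    def classify_sample(
        self,
        variants: SomaticVariantSet,
        clinical: ClinicalRecord,
        profile: CNProfile,
    ) -> SubtypeCall:
        ids = {variants.sample_id, clinical.sample_id, profile.sample_id}
        if len(ids) != 1:
            raise ValueError(f"sample_id mismatch across inputs: {sorted(ids)}")
        params = self._pole_params()
        spectrum = compute_spectrum(variants)
        evidence = dict(
            sample_id=variants.sample_id,
            snv_count=spectrum.total_snv,
            ca_rate=ca_rate(spectrum),
            cg_rate=cg_rate(spectrum),
        )
        if is_pole(spectrum, params):
            try:
                msi = is_msi_high(clinical, params)
            except ValueError:
                msi = False  # POLE short-circuits; MSI status not required
            post = self.cn_posterior(profile) if self.full_evidence else None
            return SubtypeCall(subtype="POLE", msi_high=msi, cn_high_posterior=post, **evidence)
        msi = is_msi_high(clinical, params)  # raises if status unknown
        if msi:
            post = self.cn_posterior(profile) if self.full_evidence else None
            return SubtypeCall(subtype="MSI", msi_high=True, cn_high_posterior=post, **evidence)
        post = self.cn_posterior(profile)
        subtype = "CN-high" if post >= self.cn_high_threshold else "CN-low"
        return SubtypeCall(subtype=subtype, msi_high=False, cn_high_posterior=post, **evidence)

    def classify_cohort(
        self,
        variants: dict[str, SomaticVariantSet],
        clinical: dict[str, ClinicalRecord],
        profiles: dict[str, CNProfile],
    ) -> list[SubtypeCall]:
        """One call per sample; errors if the three sample universes differ."""
        universes = {
            "variants": set(variants),
            "clinical": set(clinical),
            "profiles": set(profiles),
        }
        union = set.union(*universes.values())
        missing = {
            name: sorted(union - ids) for name, ids in universes.items() if union - ids
        }
        if missing:
            raise ValueError(f"samples missing from inputs: {missing}")
        return [
            self.classify_sample(variants[sid], clinical[sid], profiles[sid])
            for sid in sorted(union)
        ]

    def predict(self, X) -> np.ndarray:
        """X: sequence of (SomaticVariantSet, ClinicalRecord, CNProfile) triples."""
        return np.asarray(
            [self.classify_sample(v, c, p).subtype for v, c, p in X], dtype=object
        )

    # -- model persistence -------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        params = self._pole_params()
        spec = self._feature_spec()
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "pole_params": {
                "snv_min": params.snv_min,
                "ca_min": params.ca_min,
                "cg_max": params.cg_max,
                "msi_high_threshold": params.msi_high_threshold,
            },
            "feature_spec": {
                "gain_margin": spec.gain_margin,
                "loss_margin": spec.loss_margin,
                "top_k_genes": spec.top_k_genes,
                "genome_length_mb": spec.genome_length_mb,
            },
            "cn_high_threshold": self.cn_high_threshold,
            "selected_genes": list(self.selected_genes_),
            "gene_model": [
                [g.gene_id, g.chromosome, g.start, g.end] for g in self.gene_model
            ],
            "nb": {
                "classes": self.nb_.classes_.tolist(),
                "class_prior": self.nb_.class_prior_.tolist(),
                "theta": self.nb_.theta_.tolist(),
                "var": self.nb_.var_.tolist(),
                "epsilon": self.nb_.epsilon_,
                "n_features": self.nb_.n_features_in_,
            },
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SubtypeCascadeClassifier":
        from .io import Gene

        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {d.get('schema_version')}")
        gene_model = GeneModel(tuple(Gene(*g) for g in d["gene_model"]))
        obj = cls(
            gene_model=gene_model,
            pole_params=PoleRuleParams(**d["pole_params"]),
            feature_spec=CNFeatureSpec(**d["feature_spec"]),
            cn_high_threshold=d["cn_high_threshold"],
        )
        spec = obj._feature_spec()
        obj.extractor_ = CNFeatureExtractor(
            gene_model=gene_model,
            gain_margin=spec.gain_margin,
            loss_margin=spec.loss_margin,
            top_k_genes=spec.top_k_genes,
            genome_length_mb=spec.genome_length_mb,
        )
        obj.extractor_.selected_genes_ = tuple(d["selected_genes"])
        from .cn_features import feature_names

        obj.extractor_.feature_names_ = feature_names(obj.extractor_.selected_genes_)
        obj.extractor_.n_features_out_ = len(obj.extractor_.feature_names_)
        nb = GaussianNaiveBayes()
        nb.classes_ = np.asarray(d["nb"]["classes"])
        nb.class_prior_ = np.asarray(d["nb"]["class_prior"])
        nb.theta_ = np.asarray(d["nb"]["theta"])
        nb.var_ = np.asarray(d["nb"]["var"])
        nb.epsilon_ = d["nb"]["epsilon"]
        nb.n_features_in_ = d["nb"]["n_features"]
        obj.nb_ = nb
        obj.selected_genes_ = tuple(d["selected_genes"])
        obj.classes_ = np.asarray(SUBTYPES, dtype=object)
        return obj

    @classmethod
    def load(cls, path) -> "SubtypeCascadeClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def classify_cohort(
    variants: dict[str, SomaticVariantSet],
    clinical: dict[str, ClinicalRecord],
    profiles: dict[str, CNProfile],
    classifier: SubtypeCascadeClassifier,
) -> list[SubtypeCall]:
    """Functional wrapper over :meth:`SubtypeCascadeClassifier.classify_cohort`."""
    return classifier.classify_cohort(variants, clinical, profiles)
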