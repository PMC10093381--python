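import numpy as np
import pytest

import ecsubtypes as ec


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic 60-sample cohort used across modules."""
    return ec.simulate_cohort(config=ec.SimConfig(n_samples=60, seed=3))


@pytest.fixture(scope="session")
def fitted_cascade(small_cohort):
    """Cascade with the CN stage trained on the small cohort's cluster labels."""
    c = small_cohort
    sids = sorted(c.profiles)
    y = np.array([1 if c.labels[s] == "CN-high" else 0 for s in sids])
    clf = ec.SubtypeCascadeClassifier(gene_model=c.gene_model)
    return clf.fit([c.profiles[s] for s in sids], y)


@pytest.fixture(scope="session")
def table1():
    """Published four-class comparison matrix for a 232-sample cohort
    (rows = multi-platform reference, columns = exome-only prediction)."""
    counts = np.array(
        [
            [17, 0, 0, 0],
            [0, 58, 6, 1],
            [0, 0, 80, 10],
            [0, 0, 9, 51],
        ]
    )
    return ec.ConfusionMatrix(ec.SUBTYPES, counts, int(counts.sum()))


def make_snv(chrom, pos, ref, alt):
    return ec.VariantRecord(chrom, pos, ref, alt)


@pytest.fixture
def spectrum_factory():
    """Build a SubstitutionSpectrum from explicit class counts."""

    def _make(ca=0, cg=0, ct=0, ta=0, tc=0, tg=0):
        return ec.SubstitutionSpectrum(
            {"C>A": ca, "C>G": cg, "C>T": ct, "T>A": ta, "T>C": tc, "T>G": tg}
        )

    return _make
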