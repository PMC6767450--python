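import numpy as np
import pandas as pd
import pytest

from triovar import (
    FeatureModel,
    Genotype,
    GenotypeCall,
    MultiSampleVariant,
    VariantSite,
    generate_background_trio,
    generate_benchmark_suite,
    generate_pathogenic_pool,
    generate_phenotype_map,
    trio_pedigree,
)
from triovar.annotate import FEATURE_NAMES
from triovar.score import LabeledFeatureTable, build_training_table, train_model
from triovar.simulate import generate_annotation_pool

GT_SYMBOL = {
    "RR": Genotype.HOM_REF,
    "RA": Genotype.HET,
    "AA": Genotype.HOM_ALT,
    "..": Genotype.MISSING,
}


@pytest.fixture(scope="session")
def trio_ped():
    return trio_pedigree()


@pytest.fixture
def make_trio_variant(trio_ped):
    """Factory: trio variant from genotype symbols (child, father, mother)."""

    def _make(child="RA", father="RR", mother="RR", chrom="1", pos=1000,
              ref="A", alt="G", dp=30, gq=99.0):
        site = VariantSite(chrom, pos, ref, alt)
        calls = {}
        for sid, sym in (("child", child), ("father", father), ("mother", mother)):
            gt = GT_SYMBOL[sym]
            calls[sid] = GenotypeCall(
                sample_id=sid, gt=gt, dp=dp, gq=gq,
                ad_ref=None if gt is Genotype.MISSING else dp,
                ad_alt=None if gt is Genotype.MISSING else 0,
            )
        return MultiSampleVariant(site=site, calls=calls)

    return _make


@pytest.fixture(scope="session")
def training_pools():
    """Synthetic annotation pools: 2,000 positives, 1,000 + 1,000 negatives."""
    features = FeatureModel()
    pos = generate_annotation_pool(2000, "pathogenic", 601, pos_base=600_000_000, features=features)
    negc = generate_annotation_pool(1000, "benign", 501, pos_base=500_000_000, features=features)
    negr = generate_annotation_pool(1000, "benign", 401, pos_base=400_000_000, features=features)
    return pos, negc, negr


@pytest.fixture(scope="session")
def training_table(training_pools):
    pos, negc, negr = training_pools
    return build_training_table(pos, negc, negr, seed=17)


@pytest.fixture(scope="session")
def trained(training_table):
    """(model, cv_report) trained at the default 1000 trees / 5 folds."""
    return train_model(training_table, n_trees=1000, n_folds=5, seed=17)


@pytest.fixture(scope="session")
def separable_table():
    """Perfectly separable by construction: AF and CADD differ, rest constant."""
    n = 200
    neutral = {name: 0.0 for name in FEATURE_NAMES[1:]}
    X = np.zeros((2 * n, len(FEATURE_NAMES)))
    X[:, 1:] = 0.5
    X[:n, 0] = 0.0    # pathogenic: novel
    X[:n, 6] = 35.0   # pathogenic: high CADD
    X[n:, 0] = 0.3    # benign: common
    X[n:, 6] = 1.0
    y = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    keys = [("1", i + 1, "A", "G") for i in range(2 * n)]
    return LabeledFeatureTable(X, y, keys, neutral_reference=neutral)


@pytest.fixture(scope="session")
def background():
    """Mendelian-clean 1,000-variant synthetic trio + annotation + pedigree."""
    return generate_background_trio(1000, mendelian_error_rate=0.0, seed=101)


@pytest.fixture(scope="session")
def phenotype_resources(background):
    _, annotation, _ = background
    genes = [f"DGENE{i:05d}" for i in range(400)] + sorted(annotation["gene"].unique())
    return generate_phenotype_map(genes, seed=55)


@pytest.fixture(scope="session")
def benchmark_suite(background, phenotype_resources):
    """100 spike-in cases per simulated mode on the shared background."""
    bg, annotation, ped = background
    pool = generate_pathogenic_pool(400, seed=111, pheno_map=phenotype_resources)
    cases = generate_benchmark_suite(
        100, bg, annotation, pool, pedigree=ped, seed=112
    )
    return cases


class StubForest:
    """Deterministic stand-in classifier: P(pathogenic) = f(feature row)."""

    def __init__(self, fn):
        self._fn = fn

    def predict_proba(self, X):
        p = np.clip(np.array([self._fn(row) for row in X], dtype=float), 0.0, 1.0)
        return np.column_stack([1.0 - p, p])


@pytest.fixture
def stub_model():
    """PathogenicityModel whose score is a pluggable function of the vector."""
    from triovar.score import PathogenicityModel

    def _make(fn=lambda row: 0.5):
        neutral = {name: 0.0 for name in FEATURE_NAMES[1:]}
        return PathogenicityModel(forest=StubForest(fn), neutral_reference=neutral)

    return _make
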