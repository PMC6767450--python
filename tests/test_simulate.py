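"""Spike-in construction, read-fraction simulation, background generation."""

import numpy as np
import pytest
from scipy import stats

from triovar import (
    Genotype,
    InheritanceMode,
    SimulationParams,
    SpikeInSpec,
    VariantSite,
    generate_background_trio,
    generate_benchmark_suite,
    generate_pathogenic_pool,
    inject_variant,
    simulate_vaf,
    trio_pedigree,
)
from triovar.core import write_multisample_vcf
from triovar.simulate import FeatureModel, count_mendelian_violations


def test_het_read_fraction_matches_binomial_moments():
    rng = np.random.default_rng(1)
    dp = 100
    draws = np.array(
        [simulate_vaf(Genotype.HET, dp, seed=rng).ad_alt for _ in range(10_000)]
    )
    mean_vaf = draws.mean() / dp
    se = np.sqrt(0.25 / dp / 10_000)
    assert abs(mean_vaf - 0.5) < 3 * se


def test_hom_vaf_matches_beta_mean():
    rng = np.random.default_rng(2)
    params = SimulationParams()  # alpha=90, beta=10 -> mean 0.9
    dp = 200
    vafs = np.array(
        [simulate_vaf(Genotype.HOM_ALT, dp, params, rng).ad_alt / dp
         for _ in range(10_000)]
    )
    beta_sd = np.sqrt(90 * 10 / ((100) ** 2 * 101))
    assert abs(vafs.mean() - 0.9) < 3 * beta_sd / np.sqrt(10_000) + 1 / (2 * dp)


def test_hom_ref_always_zero_alt_reads():
    for dp in (1, 10, 500):
        assert simulate_vaf(Genotype.HOM_REF, dp, seed=3).ad_alt == 0


def test_vaf_distribution_kolmogorov_smirnov():
    """Simulated hom-alt ad/dp follows the discretized Beta at alpha=0.01."""
    rng = np.random.default_rng(4)
    dp = 500
    vafs = np.array(
        [simulate_vaf(Genotype.HOM_ALT, dp, seed=rng).ad_alt / dp
         for _ in range(10_000)]
    )
    # rounding to a 1/dp grid shifts the empirical cdf by at most 1/(2 dp),
    # negligible against the KS critical value at n = 10,000
    res = stats.kstest(vafs + rng.uniform(-0.5 / dp, 0.5 / dp, vafs.size),
                       stats.beta(90, 10).cdf)
    assert res.pvalue > 0.01


def test_vaf_input_validation():
    with pytest.raises(ValueError, match="dp"):
        simulate_vaf(Genotype.HET, 0)
    with pytest.raises(ValueError, match="beta"):
        SimulationParams(beta_alpha=0.0)
    with pytest.raises(ValueError, match="missing"):
        simulate_vaf(Genotype.MISSING, 10)


def test_vaf_deterministic_per_seed():
    a = [simulate_vaf(Genotype.HET, 50, seed=99).ad_alt for _ in range(5)]
    b = [simulate_vaf(Genotype.HET, 50, seed=99).ad_alt for _ in range(5)]
    assert a == b


# --- injection -------------------------------------------------------------

def _spec(mode, gene="DGENE00001"):
    if mode is InheritanceMode.COMPOUND_HETEROZYGOUS:
        sites = (VariantSite("5", 999_000_001, "A", "G"),
                 VariantSite("5", 999_000_014, "T", "C"))
    else:
        sites = (VariantSite("5", 999_000_001, "A", "G"),)
    return SpikeInSpec(variants=sites, mode=mode, gene=gene)


def test_recessive_injection_genotypes(background):
    bg, _, ped = background
    case = inject_variant(bg, _spec(InheritanceMode.RECESSIVE_HOMOZYGOUS),
                          pedigree=ped, seed=1)
    (inj,) = [v for v in case.variants if v.site.key in case.truth.keys]
    assert inj.call("child").gt is Genotype.HOM_ALT
    assert inj.call("father").gt is Genotype.HET
    assert inj.call("mother").gt is Genotype.HET
    assert inj.call("child").ad_alt > 0


def test_denovo_injection_parents_clean(background):
    bg, _, ped = background
    case = inject_variant(bg, _spec(InheritanceMode.DOMINANT_DENOVO),
                          pedigree=ped, seed=2)
    (inj,) = [v for v in case.variants if v.site.key in case.truth.keys]
    assert inj.call("child").gt is Genotype.HET
    for parent in ("father", "mother"):
        assert inj.call(parent).gt is Genotype.HOM_REF
        assert inj.call(parent).ad_alt == 0


def test_comphet_injection_is_trans(background):
    bg, _, ped = background
    case = inject_variant(bg, _spec(InheritanceMode.COMPOUND_HETEROZYGOUS),
                          pedigree=ped, seed=3)
    injected = [v for v in case.variants if v.site.key in case.truth.keys]
    assert len(injected) == 2
    carriers = set()
    for v in injected:
        assert v.call("child").gt is Genotype.HET
        parent_gts = {p: v.call(p).gt for p in ("father", "mother")}
        het_parents = [p for p, g in parent_gts.items() if g is Genotype.HET]
        assert len(het_parents) == 1
        carriers.add(het_parents[0])
    assert carriers == {"father", "mother"}  # one allele from each parent


def test_injection_key_collision_is_fatal(background):
    bg, _, ped = background
    existing = bg[0].site
    spec = SpikeInSpec(variants=(existing,),
                       mode=InheritanceMode.DOMINANT_DENOVO, gene="G")
    with pytest.raises(ValueError, match="background"):
        inject_variant(bg, spec, pedigree=ped, seed=0)


def test_record_count_conservation(background):
    bg, _, ped = background
    case = inject_variant(bg, _spec(InheritanceMode.COMPOUND_HETEROZYGOUS),
                          pedigree=ped, seed=5)
    assert len(case.variants) == len(bg) + 2


def test_spec_validation():
    with pytest.raises(ValueError, match="distinct"):
        SpikeInSpec(
            variants=(VariantSite("1", 1, "A", "G"), VariantSite("1", 1, "A", "G")),
            mode=InheritanceMode.COMPOUND_HETEROZYGOUS, gene="G",
        )
    with pytest.raises(ValueError, match="not simulated"):
        SpikeInSpec(variants=(VariantSite("1", 1, "A", "G"),),
                    mode=InheritanceMode.X_LINKED, gene="G")


# --- background ------------------------------------------------------------

def test_clean_background_has_no_mendelian_violations(background):
    bg, _, ped = background
    assert count_mendelian_violations(bg, ped) == 0


def test_error_rate_produces_binomial_violation_count():
    bg, _, ped = generate_background_trio(1000, mendelian_error_rate=0.01, seed=7)
    n = count_mendelian_violations(bg, ped)
    assert abs(n - 10) <= 9  # 3 SD of Binomial(1000, 0.01)


def test_background_af_respects_benign_floor(background):
    _, annotation, _ = background
    floor = FeatureModel().benign_af_floor
    af = np.fmax(annotation["af_1000g"].fillna(0), annotation["af_gnomad"].fillna(0))
    assert (af >= floor).mean() >= 0.99


def test_background_invalid_size():
    with pytest.raises(ValueError):
        generate_background_trio(0)


# --- benchmark suite -------------------------------------------------------

def test_suite_counts_and_isolation(background):
    bg, ann, ped = background
    pool = generate_pathogenic_pool(50, seed=21)
    with pytest.warns(UserWarning, match="using all"):
        cases = generate_benchmark_suite(30, bg, ann, pool, pedigree=ped, seed=22)
    # pool rows split over three modes: every row used once, none duplicated
    assert len(cases) == 50
    ids = [c.case_id for c in cases]
    assert len(set(ids)) == len(ids)
    bg_keys = {v.site.key for v in bg}
    for c in cases:
        assert not (c.truth.keys & bg_keys)


def test_suite_exact_request(background):
    bg, ann, ped = background
    pool = generate_pathogenic_pool(120, seed=23)
    cases = generate_benchmark_suite(5, bg, ann, pool, pedigree=ped, seed=24)
    per_mode = {}
    for c in cases:
        per_mode[c.mode] = per_mode.get(c.mode, 0) + 1
    assert per_mode == {m: 5 for m in
                        (InheritanceMode.RECESSIVE_HOMOZYGOUS,
                         InheritanceMode.COMPOUND_HETEROZYGOUS,
                         InheritanceMode.DOMINANT_DENOVO)}


def test_modeless_pool_gets_reproducible_random_modes(background):
    bg, ann, ped = background
    pool = generate_pathogenic_pool(60, seed=25, with_modes=False)
    a = generate_benchmark_suite(3, bg, ann, pool, pedigree=ped, seed=26)
    b = generate_benchmark_suite(3, bg, ann, pool, pedigree=ped, seed=26)
    assert [c.truth.keys for c in a] == [c.truth.keys for c in b]
    assert [c.mode for c in a] == [c.mode for c in b]


def test_emitted_vcf_byte_identical_per_seed(tmp_path):
    p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
    for p in (p1, p2):
        bg, _, ped = generate_background_trio(100, seed=31)
        case = inject_variant(bg, _spec(InheritanceMode.RECESSIVE_HOMOZYGOUS),
                              pedigree=ped, seed=32)
        write_multisample_vcf(case.variants, ped.sample_ids, p)
    assert p1.read_bytes() == p2.read_bytes()
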