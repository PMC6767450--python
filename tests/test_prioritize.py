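"""Segregation logic, compound-het pairing, quality filter and ranking."""

import itertools

import numpy as np
import pytest

from triovar import (
    FilterConfig,
    Genotype,
    GenotypeCall,
    InheritanceMode,
    MultiSampleVariant,
    Pedigree,
    PedigreeMember,
    Sex,
    VariantSite,
)
from triovar.annotate import AnnotationProfile
from triovar.prioritize import (
    compound_het_pairs,
    prioritize,
    quality_filter,
    segregation_filter,
)

from tests.conftest import GT_SYMBOL


def test_recessive_textbook_trio_kept(make_trio_variant, trio_ped):
    v = make_trio_variant(child="AA", father="RA", mother="RA")
    kept = segregation_filter([v], trio_ped, InheritanceMode.RECESSIVE_HOMOZYGOUS)
    assert kept == [v]


def test_denovo_definition(make_trio_variant, trio_ped):
    hit = make_trio_variant(child="RA", father="RR", mother="RR")
    miss = make_trio_variant(child="RA", father="RA", mother="RR", pos=2000)
    kept = segregation_filter([hit, miss], trio_ped, InheritanceMode.DOMINANT_DENOVO)
    assert kept == [hit]


def test_denovo_requires_confident_parental_reference(make_trio_variant, trio_ped):
    shallow = make_trio_variant(child="RA", father="RR", mother="RR", dp=3)
    assert not segregation_filter(
        [shallow], trio_ped, InheritanceMode.DOMINANT_DENOVO, min_dp=6
    )
    assert segregation_filter(
        [shallow], trio_ped, InheritanceMode.DOMINANT_DENOVO, min_dp=None
    )


def test_missing_genotype_strict_vs_tolerated(make_trio_variant, trio_ped):
    v = make_trio_variant(child="AA", father="..", mother="RA")
    strict = segregation_filter([v], trio_ped, InheritanceMode.RECESSIVE_HOMOZYGOUS)
    assert strict == []
    relaxed = segregation_filter(
        [v], trio_ped, InheritanceMode.RECESSIVE_HOMOZYGOUS, tolerate_missing=True
    )
    assert relaxed == [v]


def test_x_linked_unknown_sex_is_fatal(make_trio_variant):
    ped = Pedigree(
        [
            PedigreeMember("father", Sex.MALE),
            PedigreeMember("mother", Sex.FEMALE),
            PedigreeMember("child", Sex.UNKNOWN, affected=True,
                           father_id="father", mother_id="mother"),
        ]
    )
    v = make_trio_variant(child="AA", father="RR", mother="RA", chrom="X")
    with pytest.raises(ValueError, match="sex"):
        segregation_filter([v], ped, InheritanceMode.X_LINKED)


def test_mode_requiring_parents_without_them_is_fatal(make_trio_variant):
    ped = Pedigree(
        [
            PedigreeMember("child", Sex.FEMALE, affected=True),
            PedigreeMember("father", Sex.MALE),
            PedigreeMember("mother", Sex.FEMALE),
        ]
    )  # no parent *links*
    v = make_trio_variant()
    with pytest.raises(ValueError, match="parents"):
        segregation_filter([v], ped, InheritanceMode.DOMINANT_DENOVO)


# --- compound het ----------------------------------------------------------

def _gene_variants(make_trio_variant, configs, gene="G1"):
    variants = []
    for i, (c, f, m) in enumerate(configs):
        variants.append(make_trio_variant(child=c, father=f, mother=m, pos=1000 + i))
    return {gene: variants}


def test_canonical_trans_pair(make_trio_variant, trio_ped):
    gv = _gene_variants(make_trio_variant, [("RA", "RA", "RR"), ("RA", "RR", "RA")])
    pairs = compound_het_pairs(gv, trio_ped)
    (pair,) = pairs
    assert pair == frozenset({("1", 1000, "A", "G"), ("1", 1001, "A", "G")})


def test_cis_pair_rejected(make_trio_variant, trio_ped):
    gv = _gene_variants(make_trio_variant, [("RA", "RA", "RR"), ("RA", "RA", "RR")])
    assert compound_het_pairs(gv, trio_ped) == set()


def test_combinatorial_count_two_paternal_three_maternal(make_trio_variant, trio_ped):
    """Origins {P,P,M,M,M} in one gene give exactly 2x3 = 6 trans pairs."""
    configs = [("RA", "RA", "RR")] * 2 + [("RA", "RR", "RA")] * 3
    gv = _gene_variants(make_trio_variant, configs)
    assert len(compound_het_pairs(gv, trio_ped)) == 6


def test_different_genes_never_pair(make_trio_variant, trio_ped):
    gv = {
        "G1": [make_trio_variant(child="RA", father="RA", mother="RR", pos=1)],
        "G2": [make_trio_variant(child="RA", father="RR", mother="RA", pos=2)],
    }
    assert compound_het_pairs(gv, trio_ped) == set()


def test_pair_set_invariant_under_input_order(make_trio_variant, trio_ped):
    configs = [("RA", "RA", "RR"), ("RA", "RR", "RA"), ("RA", "RA", "RR"),
               ("RA", "RR", "RA"), ("RA", "RR", "RR")]
    base = _gene_variants(make_trio_variant, configs)["G1"]
    expected = compound_het_pairs({"G1": base}, trio_ped)
    for perm in itertools.permutations(base):
        assert compound_het_pairs({"G1": list(perm)}, trio_ped) == expected


# --- quality filter --------------------------------------------------------

def _annotated(make_trio_variant, pos, **profile_kwargs):
    v = make_trio_variant(pos=pos, **{k: profile_kwargs.pop(k)
                                      for k in ("dp", "gq") if k in profile_kwargs})
    p = AnnotationProfile(site=v.site, gene="G", consequence="missense", **profile_kwargs)
    return v, p


def test_quality_filter_reasons(make_trio_variant, trio_ped):
    """10 variants, 3 planted single-rule violations: 7 survive, 3 reasons."""
    clean = [_annotated(make_trio_variant, 100 + i, af_gnomad=0.001, cadd_phred=20.0)
             for i in range(7)]
    common = _annotated(make_trio_variant, 200, af_gnomad=0.05)
    v, p = _annotated(make_trio_variant, 201, af_gnomad=0.001)
    p.consequence = "synonymous"
    syn = (v, p)
    shallow = _annotated(make_trio_variant, 202, af_gnomad=0.001, dp=2)
    result = quality_filter(clean + [common, syn, shallow], FilterConfig(), trio_ped)
    assert len(result.kept) == 7
    assert set(result.removed.values()) == {
        "population frequency", "consequence", "coverage",
    }


def test_quality_filter_segdup_abb_and_missing_evidence(make_trio_variant, trio_ped):
    segdup = _annotated(make_trio_variant, 1, af_gnomad=0.001, segdup=0.99)
    noisy = _annotated(make_trio_variant, 2, af_gnomad=0.001, abb=0.1)
    nodp = _annotated(make_trio_variant, 3, af_gnomad=0.001, dp=None)
    cfg = FilterConfig(min_abb=0.5)
    result = quality_filter([segdup, noisy, nodp], cfg, trio_ped)
    assert result.removed[segdup[0].site.key] == "segmental duplication"
    assert result.removed[noisy[0].site.key] == "systematic error (ABB)"
    assert result.removed[nodp[0].site.key] == "coverage"  # missing DP fails
    # disabling the thresholds keeps everything
    relaxed = FilterConfig(max_segdup=None, min_abb=None, min_dp=None)
    assert len(quality_filter([segdup, noisy, nodp], relaxed, trio_ped).kept) == 3


@pytest.mark.parametrize(
    "tighten,relax",
    [
        (dict(max_af=0.001), dict(max_af=0.05)),
        (dict(min_dp=20), dict(min_dp=2)),
        (dict(min_gq=99.5), dict(min_gq=10.0)),
        (dict(max_segdup=0.1), dict(max_segdup=None)),
        (dict(min_abb=0.9), dict(min_abb=None)),
    ],
)
def test_filter_monotone_in_each_threshold(make_trio_variant, trio_ped, tighten, relax):
    rng = np.random.default_rng(0)
    annotated = []
    for i in range(30):
        annotated.append(
            _annotated(
                make_trio_variant, 1000 + i,
                af_gnomad=float(rng.uniform(0, 0.01)),
                segdup=float(rng.uniform(0, 1)),
                abb=float(rng.uniform(0, 1)),
                dp=int(rng.integers(3, 60)),
                gq=float(rng.uniform(15, 99)),
            )
        )
    tight_keys = {v.site.key for v, _ in
                  quality_filter(annotated, FilterConfig(**tighten), trio_ped).kept}
    loose_keys = {v.site.key for v, _ in
                  quality_filter(annotated, FilterConfig(**relax), trio_ped).kept}
    assert tight_keys <= loose_keys


# --- full pipeline ---------------------------------------------------------

def _profiles_for(variants, gene="G1", **kwargs):
    return {
        v.site.key: AnnotationProfile(site=v.site, gene=gene, consequence="missense",
                                      **kwargs)
        for v in variants
    }


def test_sole_survivor_ranks_first(make_trio_variant, trio_ped, stub_model):
    causal = make_trio_variant(child="AA", father="RA", mother="RA", pos=10)
    noise = make_trio_variant(child="RA", father="RA", mother="RR", pos=20)
    variants = [causal, noise]
    profiles = _profiles_for(variants, af_gnomad=0.0001)
    cands = prioritize(variants, profiles, trio_ped,
                       InheritanceMode.RECESSIVE_HOMOZYGOUS, stub_model())
    assert [c.key for c in cands] == [causal.site.key]
    assert cands[0].rank == 1


def test_ranking_by_score_then_af_then_position(make_trio_variant, trio_ped, stub_model):
    vs = [make_trio_variant(child="RA", father="RR", mother="RR", pos=p)
          for p in (10, 20, 30, 40)]
    profiles = {}
    afs = [0.002, 0.002, 0.001, 0.002]
    for v, af in zip(vs, afs):
        profiles[v.site.key] = AnnotationProfile(
            site=v.site, gene="G1", consequence="missense", af_gnomad=af
        )
    # desired scores: pos 40 highest, the rest tied at 0.4; the stub model
    # reads the score off the CADD feature slot
    score_of = {10: 0.4, 20: 0.4, 30: 0.4, 40: 0.9}
    for v in vs:
        profiles[v.site.key].cadd_phred = score_of[v.site.pos] * 40
    model = stub_model(lambda row: row[6] / 40.0)
    cands = prioritize(vs, profiles, trio_ped, InheritanceMode.DOMINANT_DENOVO, model)
    assert [c.variant.site.pos for c in cands] == [40, 30, 10, 20]
    assert [c.rank for c in cands] == [1, 2, 3, 4]
    # rank completeness: permutation of 1..n
    assert sorted(c.rank for c in cands) == list(range(1, len(cands) + 1))


def test_hpo_soft_tier_orders_matched_gene_first(make_trio_variant, trio_ped,
                                                 stub_model, phenotype_resources):
    pmap = phenotype_resources
    matched_gene = "DGENE00000"
    query = set(pmap.gene_terms[matched_gene])
    v1 = make_trio_variant(child="RA", father="RR", mother="RR", pos=10)
    v2 = make_trio_variant(child="RA", father="RR", mother="RR", pos=5)
    profiles = {
        v1.site.key: AnnotationProfile(site=v1.site, gene=matched_gene,
                                       consequence="missense", af_gnomad=0.001),
        v2.site.key: AnnotationProfile(site=v2.site, gene="UNRELATED",
                                       consequence="missense", af_gnomad=0.001),
    }
    model = stub_model(lambda row: 0.5)  # equal scores
    cands = prioritize([v1, v2], profiles, trio_ped, InheritanceMode.DOMINANT_DENOVO,
                       model, hpo_query=query, pheno_map=pmap)
    assert cands[0].profile.gene == matched_gene
    assert cands[0].hpo_score > 0
    strict = prioritize([v1, v2], profiles, trio_ped, InheritanceMode.DOMINANT_DENOVO,
                        model, hpo_query=query, pheno_map=pmap, hpo_strict=True)
    assert [c.profile.gene for c in strict] == [matched_gene]


def test_run_all_modes_merges_and_deduplicates(make_trio_variant, trio_ped, stub_model):
    both = make_trio_variant(child="AA", father="RA", mother="RA", pos=10)
    denovo = make_trio_variant(child="RA", father="RR", mother="RR", pos=20)
    variants = [both, denovo]
    profiles = _profiles_for(variants, af_gnomad=0.0001)
    cands = prioritize(variants, profiles, trio_ped, "all", stub_model(lambda r: 0.7))
    keys = [c.key for c in cands]
    assert len(keys) == len(set(keys)) == 2
    modes_of = {c.key: c.modes for c in cands}
    assert InheritanceMode.RECESSIVE_HOMOZYGOUS in modes_of[both.site.key]
    assert InheritanceMode.DOMINANT_DENOVO in modes_of[denovo.site.key]


def test_comphet_candidates_carry_partner(make_trio_variant, trio_ped, stub_model):
    v1 = make_trio_variant(child="RA", father="RA", mother="RR", pos=10)
    v2 = make_trio_variant(child="RA", father="RR", mother="RA", pos=20)
    profiles = _profiles_for([v1, v2], af_gnomad=0.0001)
    cands = prioritize([v1, v2], profiles, trio_ped,
                       InheritanceMode.COMPOUND_HETEROZYGOUS, stub_model())
    assert len(cands) == 2
    assert {c.partner for c in cands} == {v1.site.key, v2.site.key}
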