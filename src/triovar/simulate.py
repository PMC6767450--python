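"""Semisynthetic benchmark construction and synthetic data generation.

The benchmark emulates rare-disease trio diagnostics: known pathogenic
variants are spiked into the multisample VCF of a healthy parent-child trio
with genotypes dictated by the simulated inheritance mode, and read support
is simulated from the local sequencing depth.  Three trio modes are
simulated — recessive homozygous, recessive compound heterozygous and
dominant de novo — as these dominate parent-child trio diagnostics; the
remaining segregation filters are exercised by enumeration tests instead.

Read-fraction model: at a heterozygous call the number of alt-supporting
reads is Binomial(depth, 0.5); at a homozygous-alt call the variant allele
fraction is drawn from Beta(alpha, beta) (defaults alpha=90, beta=10,
mean 0.9 — mimicking the reference-bias shift of real hom-alt calls) and
multiplied by the depth.  Hom-ref members get zero alt reads.

The module also generates everything else needed to exercise the package
without external databases: Mendelian-consistent background trios, and
class-conditional annotation tables whose feature shifts point the way real
pathogenic/benign variants differ (pathogenic: absent from population
databases, higher conservation and impact-predictor scores; benign: common,
lower scores) — with population frequency deliberately the cleanest signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Genotype,
    GenotypeCall,
    InheritanceMode,
    MultiSampleVariant,
    Pedigree,
    PedigreeMember,
    Sex,
    VariantSite,
    is_mendelian_consistent,
    write_multisample_vcf,
)
from .phenotype import GenePhenotypeMap

__all__ = [
    "SimulationParams",
    "FeatureModel",
    "SimulatedCall",
    "SpikeInSpec",
    "BenchmarkCase",
    "trio_pedigree",
    "simulate_vaf",
    "inject_variant",
    "generate_background_trio",
    "generate_annotation_pool",
    "generate_pathogenic_pool",
    "generate_phenotype_map",
    "generate_benchmark_suite",
    "write_truth_table",
]

SIMULATED_MODES = (
    InheritanceMode.RECESSIVE_HOMOZYGOUS,
    InheritanceMode.COMPOUND_HETEROZYGOUS,
    InheritanceMode.DOMINANT_DENOVO,
)


@dataclass(frozen=True)
class SimulationParams:
    """Read-simulation knobs.

    ``beta_alpha``/``beta_beta`` parameterize the hom-alt VAF Beta
    distribution; ``het_p`` the per-read alt probability at het sites;
    ``mean_depth`` the Poisson mean for background/fallback depths; ``gq``
    the genotype quality stamped on clean simulated calls.
    """

    beta_alpha: float = 90.0
    beta_beta: float = 10.0
    het_p: float = 0.5
    mean_depth: float = 40.0
    gq: float = 99.0

    def __post_init__(self) -> None:
        if self.beta_alpha <= 0 or self.beta_beta <= 0:
            raise ValueError("beta parameters must be > 0")
        if not (0.0 < self.het_p < 1.0):
            raise ValueError("het_p must be in (0, 1)")


@dataclass
class SimulatedCall:
    gt: Genotype
    dp: int
    ad_alt: int
    gq: float

    def __post_init__(self) -> None:
        if self.ad_alt > self.dp:
            raise ValueError("ad_alt exceeds dp")


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_vaf(
    gt: Genotype,
    dp: int,
    params: SimulationParams = SimulationParams(),
    seed: int | np.random.Generator = 0,
) -> SimulatedCall:
    """Simulate alt-supporting read counts for one genotype at depth ``dp``."""
    if dp < 1:
        raise ValueError("dp must be >= 1")
    rng = _as_rng(seed)
    if gt is Genotype.HOM_REF:
        ad_alt = 0
    elif gt is Genotype.HET:
        ad_alt = int(rng.binomial(dp, params.het_p))
    elif gt is Genotype.HOM_ALT:
        vaf = float(rng.beta(params.beta_alpha, params.beta_beta))
        ad_alt = int(round(vaf * dp))
    else:
        raise ValueError("cannot simulate reads for a missing genotype")
    return SimulatedCall(gt=gt, dp=dp, ad_alt=min(ad_alt, dp), gq=params.gq)


def _call_from_sim(sample_id: str, sim: SimulatedCall) -> GenotypeCall:
    return GenotypeCall(
        sample_id=sample_id,
        gt=sim.gt,
        dp=sim.dp,
        gq=sim.gq,
        ad_ref=sim.dp - sim.ad_alt,
        ad_alt=sim.ad_alt,
    )


def trio_pedigree(
    child: str = "child",
    father: str = "father",
    mother: str = "mother",
    child_sex: Sex = Sex.FEMALE,
) -> Pedigree:
    """An affected child (daughter by default) with two healthy parents."""
    return Pedigree(
        [
            PedigreeMember(father, Sex.MALE, affected=False),
            PedigreeMember(mother, Sex.FEMALE, affected=False),
            PedigreeMember(child, child_sex, affected=True, father_id=father, mother_id=mother),
        ]
    )


# ---------------------------------------------------------------------------
# Class-conditional annotation feature model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureModel:
    """Class-conditional distributions for the 11 annotation features.

    Defaults encode the qualitative contrasts between pathogenic and benign
    coding variants: pathogenic variants are novel or ultra-rare (the
    population-frequency contrast is fully separated and is by construction
    the dominant signal), more conserved, and score higher on every impact
    predictor; benign variants are common to rare with a frequency floor
    ``benign_af_floor`` and overlapping, lower impact scores.
    """

    benign_af_floor: float = 1e-3
    pathogenic_af_ceiling: float = 1e-4
    pathogenic_novel_fraction: float = 0.7
    benign_missing_rate: float = 0.10
    pathogenic_missing_rate: float = 0.05

    def sample(self, kind: str, n: int, rng: np.random.Generator) -> pd.DataFrame:
        if kind == "benign":
            return self._sample_benign(n, rng)
        if kind == "pathogenic":
            return self._sample_pathogenic(n, rng)
        raise ValueError(f"unknown class '{kind}'")

    def _sample_benign(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        af = np.clip(10 ** rng.normal(-1.3, 0.8, n), self.benign_af_floor, 0.5)
        df = pd.DataFrame(
            {
                "af_1000g": np.clip(af * rng.uniform(0.8, 1.2, n), self.benign_af_floor, 1.0),
                "af_gnomad": np.clip(af * rng.uniform(0.8, 1.2, n), self.benign_af_floor, 1.0),
                "phastcons_primates": rng.beta(0.6, 2.5, n),
                "phastcons_mammals": rng.beta(0.6, 2.5, n),
                "phylop_primates": rng.normal(0.2, 0.8, n),
                "phylop_mammals": rng.normal(0.3, 1.0, n),
                "condel": rng.beta(2.0, 5.0, n),
                "cadd_phred": rng.gamma(2.5, 3.0, n),
                "eigen": rng.normal(-0.3, 1.0, n),
                "mutation_assessor": rng.normal(0.8, 1.0, n),
                "segdup": np.where(rng.random(n) < 0.85, 0.0, rng.uniform(0.0, 1.0, n)),
                "abb": rng.beta(6.0, 2.0, n),
            }
        )
        df["consequence"] = rng.choice(
            ["synonymous", "missense", "intronic", "utr3", "utr5", "intergenic"],
            size=n,
            p=[0.35, 0.30, 0.20, 0.05, 0.05, 0.05],
        )
        self._mask(df, self.benign_missing_rate, rng)
        return df

    def _sample_pathogenic(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        af = 10 ** rng.uniform(-5.0, np.log10(self.pathogenic_af_ceiling), n)
        novel = rng.random(n) < self.pathogenic_novel_fraction
        df = pd.DataFrame(
            {
                "af_1000g": np.where(novel, np.nan, af),
                "af_gnomad": np.where(novel, np.nan, af * rng.uniform(0.5, 1.0, n)),
                "phastcons_primates": rng.beta(4.0, 1.2, n),
                "phastcons_mammals": rng.beta(4.0, 1.2, n),
                "phylop_primates": rng.normal(2.0, 0.8, n),
                "phylop_mammals": rng.normal(2.5, 1.0, n),
                "condel": rng.beta(6.0, 2.0, n),
                "cadd_phred": np.clip(rng.normal(25.0, 6.0, n), 0.0, None),
                "eigen": rng.normal(3.0, 1.5, n),
                "mutation_assessor": rng.normal(3.0, 1.0, n),
                "segdup": np.where(rng.random(n) < 0.95, 0.0, rng.uniform(0.0, 0.5, n)),
                "abb": rng.beta(8.0, 2.0, n),
            }
        )
        df["consequence"] = rng.choice(
            ["missense", "stopgain", "splicing", "frameshift"],
            size=n,
            p=[0.70, 0.15, 0.10, 0.05],
        )
        self._mask(df, self.pathogenic_missing_rate, rng)
        return df

    @staticmethod
    def _mask(df: pd.DataFrame, rate: float, rng: np.random.Generator) -> None:
        """Blank non-frequency features at the given per-cell rate."""
        for col in (
            "phastcons_primates",
            "phastcons_mammals",
            "phylop_primates",
            "phylop_mammals",
            "condel",
            "cadd_phred",
            "eigen",
            "mutation_assessor",
            "segdup",
            "abb",
        ):
            mask = rng.random(len(df)) < rate
            df.loc[mask, col] = np.nan


_BASES = np.array(["A", "C", "G", "T"])


def _sites_frame(
    n: int,
    rng: np.random.Generator,
    pos_base: int,
    gene_prefix: str,
    variants_per_gene: int = 3,
) -> pd.DataFrame:
    chroms = [str(1 + (i % 22)) for i in range(n)]
    pos = pos_base + np.arange(n) * 101 + rng.integers(0, 50, n)
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    genes = [f"{gene_prefix}{i // variants_per_gene:05d}" for i in range(n)]
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos.astype(int),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "gene": genes,
        }
    )


def generate_annotation_pool(
    n: int,
    kind: str,
    seed: int | np.random.Generator = 0,
    pos_base: int = 400_000_000,
    gene_prefix: str | None = None,
    features: FeatureModel = FeatureModel(),
) -> pd.DataFrame:
    """A synthetic annotation table of ``n`` variants of one class.

    ``pos_base`` offsets the position space so that independently generated
    pools never collide on variant keys.
    """
    rng = _as_rng(seed)
    prefix = gene_prefix or ("PGENE" if kind == "pathogenic" else "BGENE")
    sites = _sites_frame(n, rng, pos_base, prefix)
    feats = features.sample(kind, n, rng)
    return pd.concat([sites.reset_index(drop=True), feats.reset_index(drop=True)], axis=1)


# ---------------------------------------------------------------------------
# Background trio
# ---------------------------------------------------------------------------

def generate_background_trio(
    n_variants: int,
    mendelian_error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    pedigree: Pedigree | None = None,
    params: SimulationParams = SimulationParams(),
    features: FeatureModel = FeatureModel(),
) -> tuple[list[MultiSampleVariant], pd.DataFrame, Pedigree]:
    """Generate a Mendelian-consistent benign trio plus its annotation table.

    Parent genotypes are drawn from the per-variant population frequency;
    the child inherits one allele from each parent.  Sites where nobody
    carries the alternative allele are redrawn (a VCF only reports variable
    sites).  With probability ``mendelian_error_rate`` a variant is instead
    written as a Mendelian violation (alt allele in the child, hom-ref
    parents), emulating genotyping error / de novo artifacts.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = _as_rng(seed)
    pedigree = pedigree or trio_pedigree()
    children = pedigree.trio_children()
    annotation = generate_annotation_pool(
        n_variants, "benign", rng, pos_base=1_000_000, gene_prefix="BGENE", features=features
    )
    af = np.fmax(
        annotation["af_1000g"].fillna(0.0).to_numpy(),
        annotation["af_gnomad"].fillna(0.0).to_numpy(),
    )

    variants: list[MultiSampleVariant] = []
    for i, row in enumerate(annotation.itertuples(index=False)):
        site = VariantSite(row.chrom, int(row.pos), row.ref, row.alt)
        if rng.random() < mendelian_error_rate:
            gts = _violating_genotypes(pedigree, rng)
        else:
            gts = _mendelian_genotypes(pedigree, float(af[i]), rng)
        calls: dict[str, GenotypeCall] = {}
        for m in pedigree.members:
            dp = max(1, int(rng.poisson(params.mean_depth)))
            sim = simulate_vaf(gts[m.sample_id], dp, params, rng)
            calls[m.sample_id] = _call_from_sim(m.sample_id, sim)
        variants.append(MultiSampleVariant(site=site, calls=calls))
    return variants, annotation, pedigree


def _mendelian_genotypes(
    pedigree: Pedigree, af: float, rng: np.random.Generator
) -> dict[str, Genotype]:
    """Founder genotypes from Hardy-Weinberg at ``af``; children inherit.

    Redraws until at least one member carries the alternative allele.
    """
    founders = [m for m in pedigree.members if m.father_id is None and m.mother_id is None]
    nonfounders = [m for m in pedigree.members if m not in founders]
    for _ in range(10_000):
        alleles: dict[str, tuple[int, int]] = {}
        for m in founders:
            alleles[m.sample_id] = (int(rng.random() < af), int(rng.random() < af))
        # resolve children whose parents are ready (single-generation loop
        # suffices for the two-generation pedigrees generated here)
        pending = list(nonfounders)
        while pending:
            progressed = False
            for m in list(pending):
                if m.father_id in alleles and m.mother_id in alleles:
                    pa = alleles[m.father_id][int(rng.random() < 0.5)]
                    ma = alleles[m.mother_id][int(rng.random() < 0.5)]
                    alleles[m.sample_id] = (pa, ma)
                    pending.remove(m)
                    progressed = True
            if not progressed:
                raise ValueError("pedigree parent links do not resolve")
        if any(sum(a) > 0 for a in alleles.values()):
            return {
                sid: {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}[sum(a)]
                for sid, a in alleles.items()
            }
    raise RuntimeError("failed to draw a variable site; allele frequency too low")


def _violating_genotypes(pedigree: Pedigree, rng: np.random.Generator) -> dict[str, Genotype]:
    """Hom-ref parents with an alt-carrying child: always a violation."""
    gts = {m.sample_id: Genotype.HOM_REF for m in pedigree.members}
    children = pedigree.trio_children()
    child = children[int(rng.integers(0, len(children)))] if children else pedigree.members[-1]
    gts[child.sample_id] = Genotype.HET if rng.random() < 0.5 else Genotype.HOM_ALT
    return gts


def count_mendelian_violations(
    variants: Sequence[MultiSampleVariant], pedigree: Pedigree
) -> int:
    """Number of variants where some child's genotype violates inheritance."""
    n = 0
    for v in variants:
        ok = True
        for child in pedigree.trio_children():
            c = v.calls[child.sample_id].gt
            f = v.calls[child.father_id].gt
            m = v.calls[child.mother_id].gt
            if not is_mendelian_consistent(c, f, m):
                ok = False
        if not ok:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Spike-in construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeInSpec:
    """Truth record for one semisynthetic disease trio."""

    variants: tuple[VariantSite, ...]
    mode: InheritanceMode
    gene: str
    hpo_terms: frozenset[str] = frozenset()
    depth: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in SIMULATED_MODES:
            raise ValueError(f"mode {self.mode.value} is not simulated")
        if self.mode is InheritanceMode.COMPOUND_HETEROZYGOUS:
            if len(self.variants) != 2 or self.variants[0] == self.variants[1]:
                raise ValueError("compound-het spec needs two distinct variants")
        elif len(self.variants) != 1:
            raise ValueError(f"{self.mode.value} spec needs exactly one variant")

    @property
    def keys(self) -> set[tuple]:
        return {v.key for v in self.variants}


@dataclass
class BenchmarkCase:
    """One semisynthetic trio: shared background plus injected truth records."""

    case_id: str
    variants: list[MultiSampleVariant]
    truth: SpikeInSpec
    mode: InheritanceMode
    annotation: pd.DataFrame | None = None


def _mode_genotypes(
    spec: SpikeInSpec, pedigree: Pedigree, rng: np.random.Generator
) -> list[dict[str, Genotype]]:
    """Per-member genotypes for each injected site, by inheritance mode."""
    children = [m for m in pedigree.trio_children() if m.affected]
    if not children:
        raise ValueError("spike-in requires an affected child with both parents")
    child = children[0]
    father, mother = child.father_id, child.mother_id
    others = [
        m.sample_id
        for m in pedigree.members
        if m.sample_id not in (child.sample_id, father, mother)
    ]
    base = {sid: Genotype.HOM_REF for sid in others}

    if spec.mode is InheritanceMode.RECESSIVE_HOMOZYGOUS:
        return [
            base | {child.sample_id: Genotype.HOM_ALT, father: Genotype.HET, mother: Genotype.HET}
        ]
    if spec.mode is InheritanceMode.DOMINANT_DENOVO:
        return [
            base
            | {child.sample_id: Genotype.HET, father: Genotype.HOM_REF, mother: Genotype.HOM_REF}
        ]
    # compound het: father carries one site, mother the other; which parent
    # gets the first site is a fair coin so trans phase is unbiased.
    first_paternal = bool(rng.random() < 0.5)
    carriers = (father, mother) if first_paternal else (mother, father)
    out = []
    for k in range(2):
        carrier, non_carrier = carriers[k], carriers[1 - k]
        out.append(
            base
            | {
                child.sample_id: Genotype.HET,
                carrier: Genotype.HET,
                non_carrier: Genotype.HOM_REF,
            }
        )
    return out


def _local_depths(
    background: Sequence[MultiSampleVariant],
    site: VariantSite,
    pedigree: Pedigree,
    params: SimulationParams,
) -> dict[str, int]:
    """Depth of the nearest background variant on the same chromosome.

    Falls back to ``params.mean_depth`` when the chromosome is empty.
    """
    same = [v for v in background if v.site.chrom == site.chrom]
    if not same:
        return {m.sample_id: int(params.mean_depth) for m in pedigree.members}
    nearest = min(same, key=lambda v: abs(v.site.pos - site.pos))
    out = {}
    for m in pedigree.members:
        dp = nearest.calls[m.sample_id].dp
        out[m.sample_id] = dp if dp is not None else int(params.mean_depth)
    return out


def inject_variant(
    background: Sequence[MultiSampleVariant],
    spec: SpikeInSpec,
    pedigree: Pedigree | None = None,
    params: SimulationParams = SimulationParams(),
    seed: int | np.random.Generator = 0,
    case_id: str = "case",
) -> BenchmarkCase:
    """Embed one truth variant (or pair) into a copy of the background.

    Genotypes follow the inheritance mode; read support is simulated with
    :func:`simulate_vaf` at the local background depth (or the depth given
    in the spike-in record).
    """
    rng = _as_rng(seed)
    pedigree = pedigree or trio_pedigree()
    bg_keys = {v.site.key for v in background}
    collisions = spec.keys & bg_keys
    if collisions:
        raise ValueError(f"spike-in key(s) already in background: {sorted(collisions)}")

    genotype_plans = _mode_genotypes(spec, pedigree, rng)
    injected: list[MultiSampleVariant] = []
    for site, plan in zip(spec.variants, genotype_plans):
        depths = dict(spec.depth) if spec.depth else _local_depths(background, site, pedigree, params)
        calls = {}
        for m in pedigree.members:
            dp = max(1, int(depths.get(m.sample_id, params.mean_depth)))
            sim = simulate_vaf(plan[m.sample_id], dp, params, rng)
            calls[m.sample_id] = _call_from_sim(m.sample_id, sim)
        injected.append(MultiSampleVariant(site=site, calls=calls))

    variants = sorted(
        list(background) + injected, key=lambda v: v.site.sort_key
    )
    return BenchmarkCase(case_id=case_id, variants=variants, truth=spec, mode=spec.mode)


# ---------------------------------------------------------------------------
# Pathogenic pool, phenotype resources, full suite
# ---------------------------------------------------------------------------

def generate_pathogenic_pool(
    n: int,
    seed: int | np.random.Generator = 0,
    with_modes: bool = True,
    features: FeatureModel = FeatureModel(),
    pheno_map: GenePhenotypeMap | None = None,
) -> pd.DataFrame:
    """A synthetic pool of disease variants (one gene per variant).

    Columns: variant key, gene, consequence, the 11 feature columns, and —
    when requested — an inheritance ``mode`` and semicolon-joined
    ``hpo_terms`` per row (taken from ``pheno_map`` when given).
    """
    rng = _as_rng(seed)
    pool = generate_annotation_pool(
        n, "pathogenic", rng, pos_base=900_000_000, gene_prefix="DGENE", features=features
    )
    pool["gene"] = [f"DGENE{i:05d}" for i in range(n)]  # one gene per variant
    if with_modes:
        pool["mode"] = rng.choice([m.value for m in SIMULATED_MODES], size=n)
    if pheno_map is not None:
        pool["hpo_terms"] = [
            ";".join(sorted(pheno_map.gene_terms.get(g, set()))) for g in pool["gene"]
        ]
    return pool


def generate_phenotype_map(
    genes: Sequence[str],
    seed: int | np.random.Generator = 0,
    n_branches: int = 8,
    n_leaves: int = 48,
    terms_per_gene: tuple[int, int] = (2, 4),
) -> GenePhenotypeMap:
    """A small synthetic phenotype ontology plus gene annotations.

    The ontology is a three-level DAG (root -> branch -> leaf, leaves may
    have two branch parents); every gene is annotated with a few leaf
    terms.  Term ids use a synthetic ``HP:SYN`` prefix.
    """
    import networkx as nx

    rng = _as_rng(seed)
    g = nx.DiGraph()
    root = "HP:SYN0000"
    g.add_node(root)
    branches = [f"HP:SYN1{i:03d}" for i in range(n_branches)]
    for b in branches:
        g.add_edge(b, root)
    leaves = [f"HP:SYN2{i:03d}" for i in range(n_leaves)]
    for i, leaf in enumerate(leaves):
        g.add_edge(leaf, branches[i % n_branches])
        if rng.random() < 0.3:
            g.add_edge(leaf, branches[int(rng.integers(0, n_branches))])
    gene_terms = {
        gene: set(
            rng.choice(leaves, size=int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1)), replace=False)
        )
        for gene in genes
    }
    return GenePhenotypeMap(gene_terms=gene_terms, ontology=g)


def generate_benchmark_suite(
    n_cases_per_mode: int,
    background: Sequence[MultiSampleVariant],
    background_annotation: pd.DataFrame,
    pathogenic_pool: pd.DataFrame,
    pedigree: Pedigree | None = None,
    params: SimulationParams = SimulationParams(),
    features: FeatureModel = FeatureModel(),
    seed: int = 0,
) -> list[BenchmarkCase]:
    """Build one benchmark case per drawn pool variant, per simulated mode.

    Pool rows lacking a ``mode`` column are assigned one of the three
    simulated modes uniformly at random (reproducibly per seed).  For
    compound-het cases a partner variant in the same gene is synthesized
    next to the drawn one.  Each case embeds its truth in a fresh view of
    the shared background and carries the annotation table extended with
    the truth rows.
    """
    rng = np.random.default_rng(seed)
    pool = pathogenic_pool.copy().reset_index(drop=True)
    if "mode" not in pool.columns:
        pool["mode"] = rng.choice([m.value for m in SIMULATED_MODES], size=len(pool))

    cases: list[BenchmarkCase] = []
    for mode in SIMULATED_MODES:
        rows = pool[pool["mode"] == mode.value]
        if len(rows) < n_cases_per_mode:
            warnings.warn(
                f"pool has only {len(rows)} {mode.value} variants; requested "
                f"{n_cases_per_mode}, using all"
            )
            chosen = rows
        else:
            idx = np.sort(rng.choice(len(rows), size=n_cases_per_mode, replace=False))
            chosen = rows.iloc[idx]
        for k, row in enumerate(chosen.itertuples(index=False)):
            d = row._asdict()
            site = VariantSite(str(d["chrom"]), int(d["pos"]), str(d["ref"]), str(d["alt"]))
            truth_rows = [d]
            sites = (site,)
            if mode is InheritanceMode.COMPOUND_HETEROZYGOUS:
                partner_site, partner_row = _partner_variant(d, features, rng)
                sites = (site, partner_site)
                truth_rows.append(partner_row)
            terms = frozenset(str(d.get("hpo_terms") or "").split(";")) - {""}
            spec = SpikeInSpec(
                variants=sites,
                mode=mode,
                gene=str(d["gene"]),
                hpo_terms=terms,
            )
            case = inject_variant(
                background,
                spec,
                pedigree=pedigree,
                params=params,
                seed=rng,
                case_id=f"{mode.value}_{k:04d}",
            )
            truth_df = pd.DataFrame(truth_rows)
            case.annotation = pd.concat(
                [background_annotation, truth_df], ignore_index=True
            )
            cases.append(case)
    return cases


def _partner_variant(
    d: dict, features: FeatureModel, rng: np.random.Generator
) -> tuple[VariantSite, dict]:
    """Synthesize the second pathogenic allele of a compound-het pair."""
    feats = features.sample("pathogenic", 1, rng).iloc[0].to_dict()
    site = VariantSite(str(d["chrom"]), int(d["pos"]) + 13, "A", "G")
    row = dict(d)
    row.update(feats)
    row.update({"chrom": site.chrom, "pos": site.pos, "ref": site.ref, "alt": site.alt})
    return site, row


def write_truth_table(cases: Sequence[BenchmarkCase], path: str | Path) -> None:
    """TSV truth record: case id, variant key(s), mode, gene, HPO terms."""
    rows = []
    for c in cases:
        rows.append(
            {
                "case_id": c.case_id,
                "variants": ";".join(
                    ":".join(map(str, v.key)) for v in c.truth.variants
                ),
                "mode": c.mode.value,
                "gene": c.truth.gene,
                "hpo_terms": ";".join(sorted(c.truth.hpo_terms)),
            }
        )
    pd.DataFrame(rows, columns=["case_id", "variants", "mode", "gene", "hpo_terms"]).to_csv(
        path, sep="\t", index=False
    )


def write_case_vcf(case: BenchmarkCase, pedigree: Pedigree, path: str | Path) -> None:
    """Emit one case as a standard multisample VCF."""
    write_multisample_vcf(case.variants, pedigree.sample_ids, path)
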