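"""Causal-variant prioritization for families and parent-child trios.

The pipeline mirrors clinical trio diagnostics:

1. remove variants whose genotype configuration cannot segregate with the
   chosen inheritance mode (five Mendelian hypotheses),
2. remove variants that are common in populations, of benign consequence
   classes, poorly covered in any family member, or in likely-artifact
   regions,
3. score survivors with the random-forest pathogenicity classifier,
4. optionally up-weight genes matching the patient's HPO phenotype terms,
5. rank.

Segregation semantics (pinned here; exhaustively tested against a
brute-force enumerator):

``dominant_denovo``
    every affected member is het or hom-alt; every unaffected member is
    hom-ref; each affected member's in-pedigree parents are hom-ref with
    depth >= ``min_dp`` (confident absence).
``dominant_inherited``
    every affected member carries at least one alternative allele; no
    unaffected member carries any.
``recessive_homozygous``
    every affected member is hom-alt; no unaffected member is hom-alt; each
    in-pedigree parent of an affected member is het (obligate carrier).
``compound_heterozygous``
    a variant survives iff it participates in at least one *trans* pair in
    its gene (see :func:`compound_het_pairs`).
``x_linked``
    chromosome X only; affected males are hom-alt (hemizygous calls are
    reported as hom-alt) with a het mother and hom-ref father when present;
    affected females are hom-alt; unaffected males are hom-ref and
    unaffected females are not hom-alt.

A missing genotype in any relevant member fails segregation by default;
``tolerate_missing`` relaxes missing calls to "compatible with anything".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotate import AnnotationProfile, assemble_feature_vector, max_population_af
from .core import (
    Genotype,
    InheritanceMode,
    MultiSampleVariant,
    Pedigree,
    PedigreeMember,
    Sex,
    chrom_sort_key,
)
from .phenotype import GenePhenotypeMap, hpo_gene_score
from .score import PathogenicityModel, predict_many

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "CandidateVariant",
    "FilterResult",
    "segregation_filter",
    "compound_het_pairs",
    "quality_filter",
    "prioritize",
    "SIMULATED_MODES",
]

#: Trio modes covered by the semisynthetic benchmark generator.
SIMULATED_MODES = (
    InheritanceMode.RECESSIVE_HOMOZYGOUS,
    InheritanceMode.COMPOUND_HETEROZYGOUS,
    InheritanceMode.DOMINANT_DENOVO,
)

#: Consequence classes excluded by the default (lenient) filter.
DEFAULT_EXCLUDED_CONSEQUENCES = frozenset(
    {"synonymous", "intronic", "intergenic", "utr3", "utr5"}
)


@dataclass(frozen=True)
class FilterConfig:
    """Lenient default thresholds for quality/population filtering.

    ``None`` disables the corresponding check.  Missing DP/GQ/annotation
    values fail an *enabled* minimum-threshold check.
    """

    max_af: float | None = 0.01
    min_dp: int | None = 6
    min_gq: float | None = 20.0
    excluded_consequences: frozenset[str] = DEFAULT_EXCLUDED_CONSEQUENCES
    max_segdup: float | None = 0.95
    min_abb: float | None = None
    tolerate_missing: bool = False

    def __post_init__(self) -> None:
        if self.max_af is not None and not (0.0 <= self.max_af <= 1.0):
            raise ValueError("max_af outside [0, 1]")
        if self.max_segdup is not None and not (0.0 <= self.max_segdup <= 1.0):
            raise ValueError("max_segdup outside [0, 1]")
        if self.min_abb is not None and not (0.0 <= self.min_abb <= 1.0):
            raise ValueError("min_abb outside [0, 1]")

    @classmethod
    def lenient(cls) -> "FilterConfig":
        """The default configuration, spelled out."""
        return cls()


@dataclass
class CandidateVariant:
    """One ranked output row of the prioritizer."""

    variant: MultiSampleVariant
    profile: AnnotationProfile
    score: float
    modes: set[InheritanceMode] = field(default_factory=set)
    partner: tuple | None = None
    hpo_score: float | None = None
    rank: int = 0

    @property
    def key(self) -> tuple:
        return self.variant.site.key

    def to_record(self) -> dict:
        site = self.variant.site
        p = self.profile
        return {
            "rank": self.rank,
            "chrom": site.chrom,
            "pos": site.pos,
            "ref": site.ref,
            "alt": site.alt,
            "gene": p.gene or "",
            "consequence": p.consequence,
            "score": round(self.score, 6),
            "modes": ";".join(sorted(m.value for m in self.modes)),
            "partner": "" if self.partner is None else ":".join(map(str, self.partner)),
            "hpo_score": "" if self.hpo_score is None else round(self.hpo_score, 6),
            "max_af": round(max_population_af(p), 8),
            "af_1000g": _opt(p.af_1000g),
            "af_gnomad": _opt(p.af_gnomad),
            "phastcons_primates": _opt(p.phastcons_primates),
            "phastcons_mammals": _opt(p.phastcons_mammals),
            "phylop_primates": _opt(p.phylop_primates),
            "phylop_mammals": _opt(p.phylop_mammals),
            "condel": _opt(p.condel),
            "cadd_phred": _opt(p.cadd_phred),
            "eigen": _opt(p.eigen),
            "mutation_assessor": _opt(p.mutation_assessor),
            "segdup": _opt(p.segdup),
            "abb": _opt(p.abb),
        }


def _opt(v: float | None):
    return "" if v is None else v


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------

def _trio_children(pedigree: Pedigree) -> list[PedigreeMember]:
    return [m for m in pedigree.trio_children() if m.affected]


def _require_parents(pedigree: Pedigree, mode: InheritanceMode) -> None:
    if not _trio_children(pedigree):
        raise ValueError(
            f"mode {mode.value} requires at least one affected member with both "
            "parents in the pedigree"
        )


def _compatible_denovo(
    v: MultiSampleVariant, ped: Pedigree, min_dp: int | None, tolerate: bool
) -> bool:
    for m in ped.members:
        c = v.calls[m.sample_id]
        if c.gt is Genotype.MISSING:
            if tolerate:
                continue
            return False
        if m.affected:
            if c.gt not in (Genotype.HET, Genotype.HOM_ALT):
                return False
        elif c.gt is not Genotype.HOM_REF:
            return False
    for a in ped.affected:
        for parent in ped.parents_of(a):
            if parent is None:
                continue
            pc = v.calls[parent.sample_id]
            if min_dp is not None:
                if pc.dp is None:
                    if not tolerate:
                        return False
                elif pc.dp < min_dp:
                    return False
    return True


def _compatible_dominant(v: MultiSampleVariant, ped: Pedigree, tolerate: bool) -> bool:
    for m in ped.members:
        c = v.calls[m.sample_id]
        if c.gt is Genotype.MISSING:
            if tolerate:
                continue
            return False
        if m.affected:
            if c.gt is Genotype.HOM_REF:
                return False
        elif c.gt is not Genotype.HOM_REF:
            return False
    return True


def _compatible_recessive(v: MultiSampleVariant, ped: Pedigree, tolerate: bool) -> bool:
    for m in ped.members:
        c = v.calls[m.sample_id]
        if c.gt is Genotype.MISSING:
            if tolerate:
                continue
            return False
        if m.affected:
            if c.gt is not Genotype.HOM_ALT:
                return False
        elif c.gt is Genotype.HOM_ALT:
            return False
    for a in ped.affected:
        for parent in ped.parents_of(a):
            if parent is None:
                continue
            pc = v.calls[parent.sample_id]
            if pc.gt is Genotype.MISSING:
                if tolerate:
                    continue
                return False
            if pc.gt is not Genotype.HET:
                return False
    return True


def _compatible_x_linked(v: MultiSampleVariant, ped: Pedigree, tolerate: bool) -> bool:
    if v.site.chrom != "X":
        return False
    for m in ped.members:
        if m.affected and m.sex is Sex.UNKNOWN:
            raise ValueError(
                f"x_linked mode requires a known sex for affected member '{m.sample_id}'"
            )
    for m in ped.members:
        c = v.calls[m.sample_id]
        if c.gt is Genotype.MISSING:
            if tolerate:
                continue
            return False
        if m.affected:
            if c.gt is not Genotype.HOM_ALT:
                return False
            if m.sex is Sex.MALE:
                father, mother = ped.parents_of(m)
                if father is not None:
                    fc = v.calls[father.sample_id]
                    if fc.gt is Genotype.MISSING:
                        if not tolerate:
                            return False
                    elif fc.gt is not Genotype.HOM_REF:
                        return False
                if mother is not None:
                    mc = v.calls[mother.sample_id]
                    if mc.gt is Genotype.MISSING:
                        if not tolerate:
                            return False
                    elif mc.gt is not Genotype.HET:
                        return False
        else:
            if m.sex is Sex.MALE:
                if c.gt is not Genotype.HOM_REF:
                    return False
            elif c.gt is Genotype.HOM_ALT:
                return False
    return True


def segregation_filter(
    variants: Sequence[MultiSampleVariant],
    pedigree: Pedigree,
    mode: InheritanceMode,
    genes: Mapping[tuple, str | None] | None = None,
    min_dp: int | None = 6,
    tolerate_missing: bool = False,
) -> list[MultiSampleVariant]:
    """Variants whose genotype configuration is compatible with ``mode``.

    ``genes`` (variant key -> gene symbol) is required for the
    compound-heterozygous mode, which keeps exactly the variants
    participating in at least one valid trans pair.
    """
    mode = InheritanceMode(mode)
    for v in variants:
        v.validate_against(pedigree)
    if mode is InheritanceMode.DOMINANT_DENOVO:
        _require_parents(pedigree, mode)
        return [
            v for v in variants if _compatible_denovo(v, pedigree, min_dp, tolerate_missing)
        ]
    if mode is InheritanceMode.DOMINANT_INHERITED:
        return [v for v in variants if _compatible_dominant(v, pedigree, tolerate_missing)]
    if mode is InheritanceMode.RECESSIVE_HOMOZYGOUS:
        return [v for v in variants if _compatible_recessive(v, pedigree, tolerate_missing)]
    if mode is InheritanceMode.X_LINKED:
        return [v for v in variants if _compatible_x_linked(v, pedigree, tolerate_missing)]
    # compound heterozygous
    _require_parents(pedigree, mode)
    if genes is None:
        raise ValueError("compound_heterozygous mode requires a variant->gene mapping")
    by_gene: dict[str, list[MultiSampleVariant]] = {}
    for v in variants:
        g = genes.get(v.site.key)
        if g:
            by_gene.setdefault(g, []).append(v)
    pairs = compound_het_pairs(by_gene, pedigree, tolerate_missing=tolerate_missing)
    paired_keys = {k for pair in pairs for k in pair}
    return [v for v in variants if v.site.key in paired_keys]


def _parental_origins(
    v: MultiSampleVariant,
    child: PedigreeMember,
    ped: Pedigree,
    tolerate: bool,
) -> set[str]:
    """Possible parental origins ('P'/'M') of a het call in ``child``.

    A variant is paternal when the father carries it and the mother is
    confidently hom-ref (and vice versa).  With ``tolerate``, a missing
    parental call leaves both roles open for that parent.
    """
    c = v.calls[child.sample_id]
    if c.gt is Genotype.MISSING and not tolerate:
        return set()
    if c.gt not in (Genotype.HET, Genotype.MISSING):
        return set()
    father, mother = ped.parents_of(child)
    fc = v.calls[father.sample_id]
    mc = v.calls[mother.sample_id]

    def carrier(call) -> set[bool]:
        if call.gt is Genotype.MISSING:
            return {True, False} if tolerate else set()
        return {call.gt in (Genotype.HET, Genotype.HOM_ALT)}

    f_carrier, m_carrier = carrier(fc), carrier(mc)
    origins: set[str] = set()
    if True in f_carrier and False in m_carrier:
        origins.add("P")
    if True in m_carrier and False in f_carrier:
        origins.add("M")
    return origins


def compound_het_pairs(
    gene_variants: Mapping[str, Sequence[MultiSampleVariant]],
    pedigree: Pedigree,
    tolerate_missing: bool = False,
) -> set[frozenset]:
    """Trans-configured heterozygous pairs per gene, as variant-key pairs.

    A pair is reported iff, for every affected child with both parents in
    the pedigree, the child is het at both sites and one site is inherited
    from the father only while the other comes from the mother only
    (cis pairs — both from the same parent — are rejected).  Variants in
    different genes never pair.
    """
    children = _trio_children(pedigree)
    if not children:
        raise ValueError(
            "compound_heterozygous requires an affected child with both parents"
        )
    pairs: set[frozenset] = set()
    for gene, variants in gene_variants.items():
        vs = list(variants)
        origins = [
            {ch.sample_id: _parental_origins(v, ch, pedigree, tolerate_missing) for ch in children}
            for v in vs
        ]
        for i in range(len(vs)):
            for j in range(i + 1, len(vs)):
                ok = all(
                    ("P" in origins[i][ch.sample_id] and "M" in origins[j][ch.sample_id])
                    or ("M" in origins[i][ch.sample_id] and "P" in origins[j][ch.sample_id])
                    for ch in children
                )
                if ok:
                    pairs.add(frozenset((vs[i].site.key, vs[j].site.key)))
    return pairs


# ---------------------------------------------------------------------------
# Quality / population filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    kept: list[tuple[MultiSampleVariant, AnnotationProfile]]
    removed: dict[tuple, str]


def quality_filter(
    annotated: Sequence[tuple[MultiSampleVariant, AnnotationProfile]],
    config: FilterConfig,
    pedigree: Pedigree,
) -> FilterResult:
    """Drop common, benign-class, low-quality or artifact-prone variants.

    Every removal is logged (debug level) and recorded with its reason.
    """
    kept: list[tuple[MultiSampleVariant, AnnotationProfile]] = []
    removed: dict[tuple, str] = {}
    for v, p in annotated:
        reason = _rejection_reason(v, p, config, pedigree)
        if reason is None:
            kept.append((v, p))
        else:
            removed[v.site.key] = reason
            logger.debug("filtered %s: %s", v.site.key, reason)
    return FilterResult(kept=kept, removed=removed)


def _rejection_reason(
    v: MultiSampleVariant,
    p: AnnotationProfile,
    config: FilterConfig,
    pedigree: Pedigree,
) -> str | None:
    if config.max_af is not None and max_population_af(p) > config.max_af:
        return "population frequency"
    if p.consequence in config.excluded_consequences:
        return "consequence"
    if config.min_dp is not None:
        for m in pedigree.members:
            dp = v.calls[m.sample_id].dp
            if dp is None or dp < config.min_dp:
                return "coverage"
    if config.min_gq is not None:
        for m in pedigree.members:
            gq = v.calls[m.sample_id].gq
            if gq is None or gq < config.min_gq:
                return "genotype quality"
    if config.max_segdup is not None and p.segdup is not None and p.segdup > config.max_segdup:
        return "segmental duplication"
    if config.min_abb is not None and p.abb is not None and p.abb < config.min_abb:
        return "systematic error (ABB)"
    return None


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

_ALL_MODES = tuple(InheritanceMode)


def prioritize(
    variants: Sequence[MultiSampleVariant],
    profiles: Mapping[tuple, AnnotationProfile],
    pedigree: Pedigree,
    mode: InheritanceMode | str,
    model: PathogenicityModel,
    config: FilterConfig | None = None,
    hpo_query: set[str] | None = None,
    pheno_map: GenePhenotypeMap | None = None,
    hpo_strict: bool = False,
) -> list[CandidateVariant]:
    """Filter, score and rank candidate causal variants.

    ``mode`` may be one of the five inheritance modes or ``"all"``, which
    merges the candidates of every applicable mode (variants compatible
    with several modes appear once, carrying all of them).

    Ranking: HPO-matched genes first when a query is given (soft tier; with
    ``hpo_strict`` unmatched genes are dropped instead), then score
    descending, then population frequency ascending, then (chrom, pos, ref,
    alt).  Ranks are assigned 1..n.
    """
    config = config or FilterConfig()
    if isinstance(mode, str) and mode == "all":
        modes: Iterable[InheritanceMode] = _ALL_MODES
    else:
        modes = (InheritanceMode(mode),)

    genes = {k: p.gene for k, p in profiles.items()}
    mode_hits: dict[tuple, set[InheritanceMode]] = {}
    partners: dict[tuple, tuple] = {}
    survivors: dict[tuple, MultiSampleVariant] = {}
    for m in modes:
        try:
            passed = segregation_filter(
                variants,
                pedigree,
                m,
                genes=genes,
                min_dp=config.min_dp,
                tolerate_missing=config.tolerate_missing,
            )
        except ValueError as exc:
            if len(tuple(modes)) > 1:
                warnings.warn(f"skipping mode {m.value}: {exc}")
                continue
            raise
        if m is InheritanceMode.COMPOUND_HETEROZYGOUS and passed:
            by_gene: dict[str, list[MultiSampleVariant]] = {}
            for v in passed:
                g = genes.get(v.site.key)
                if g:
                    by_gene.setdefault(g, []).append(v)
            for pair in compound_het_pairs(
                by_gene, pedigree, tolerate_missing=config.tolerate_missing
            ):
                a, b = tuple(pair)
                partners.setdefault(a, b)
                partners.setdefault(b, a)
        for v in passed:
            survivors[v.site.key] = v
            mode_hits.setdefault(v.site.key, set()).add(m)

    annotated = [
        (v, profiles.get(k) or AnnotationProfile(site=v.site))
        for k, v in survivors.items()
    ]
    result = quality_filter(annotated, config, pedigree)
    if not result.kept:
        return []

    X = np.vstack(
        [assemble_feature_vector(p, model.neutral_reference) for _, p in result.kept]
    )
    scores = predict_many(model, X)

    candidates: list[CandidateVariant] = []
    for (v, p), s in zip(result.kept, scores):
        hpo = None
        if hpo_query is not None and pheno_map is not None:
            hpo = hpo_gene_score(hpo_query, p.gene, pheno_map) if p.gene else 0.0
        candidates.append(
            CandidateVariant(
                variant=v,
                profile=p,
                score=float(s),
                modes=set(mode_hits[v.site.key]),
                partner=partners.get(v.site.key),
                hpo_score=hpo,
            )
        )

    hpo_enabled = hpo_query is not None and pheno_map is not None
    if hpo_enabled and hpo_strict:
        candidates = [c for c in candidates if (c.hpo_score or 0.0) > 0.0]

    def sort_key(c: CandidateVariant):
        tier = 0
        if hpo_enabled and not hpo_strict:
            tier = 0 if (c.hpo_score or 0.0) > 0.0 else 1
        site = c.variant.site
        return (
            tier,
            -c.score,
            max_population_af(c.profile),
            chrom_sort_key(site.chrom),
            site.pos,
            site.ref,
            site.alt,
        )

    candidates.sort(key=sort_key)
    for i, c in enumerate(candidates, start=1):
        c.rank = i
    return candidates
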