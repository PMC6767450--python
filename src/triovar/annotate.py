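"""Variant annotation profiles and model feature assembly.

The classifier consumes an ordered 11-feature vector per variant:

1.  ``max_af`` — maximum population allele frequency over 1000 Genomes and
    gnomAD.  A variant absent from both databases is treated as novel, i.e.
    frequency 0.
2-5. conservation: PhastCons and PhyloP, each for primates and mammals.
6-9. functional impact predictors: Condel, Phred-scaled CADD, Eigen,
    Mutation Assessor.
10. segmental-duplication likelihood (mismapping proxy).
11. ABB score (systematic-error estimator, consumed as an input column).

Missing values for non-frequency features are imputed with *neutral*
reference values — the expectation for a non-pathogenic variant — supplied
by the trained model (per-feature medians of its negative training set).
Missingness is explicit (``None``/NaN) everywhere before that imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import VariantSite

__all__ = [
    "FEATURE_NAMES",
    "PROFILE_FEATURE_FIELDS",
    "CONSEQUENCES",
    "AnnotationProfile",
    "normalize_consequence",
    "max_population_af",
    "assemble_feature_vector",
    "load_annotation_table",
    "profiles_from_frame",
    "feature_matrix",
]

#: Ordered model feature names.  ``max_af`` is derived from the two AF
#: columns; the remaining ten map 1:1 to profile fields.
FEATURE_NAMES: tuple[str, ...] = (
    "max_af",
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
)

#: Profile fields feeding features 2..11 (everything except max_af).
PROFILE_FEATURE_FIELDS: tuple[str, ...] = FEATURE_NAMES[1:]

_AF_FIELDS = ("af_1000g", "af_gnomad")

#: Normalized functional-consequence vocabulary (refGene-style classes).
CONSEQUENCES = frozenset(
    {
        "missense",
        "synonymous",
        "stopgain",
        "stoploss",
        "frameshift",
        "inframe_indel",
        "splicing",
        "intronic",
        "intergenic",
        "utr3",
        "utr5",
        "ncrna",
        "other",
    }
)

_CONSEQUENCE_ALIASES = {
    "nonsynonymous snv": "missense",
    "nonsynonymous": "missense",
    "missense_variant": "missense",
    "synonymous snv": "synonymous",
    "synonymous_variant": "synonymous",
    "stopgain snv": "stopgain",
    "stop_gained": "stopgain",
    "stoploss snv": "stoploss",
    "stop_lost": "stoploss",
    "frameshift insertion": "frameshift",
    "frameshift deletion": "frameshift",
    "frameshift substitution": "frameshift",
    "frameshift_variant": "frameshift",
    "nonframeshift insertion": "inframe_indel",
    "nonframeshift deletion": "inframe_indel",
    "nonframeshift substitution": "inframe_indel",
    "splice_region_variant": "splicing",
    "splice_donor_variant": "splicing",
    "splice_acceptor_variant": "splicing",
    "exonic;splicing": "splicing",
    "intron_variant": "intronic",
    "intergenic_variant": "intergenic",
    "upstream": "intergenic",
    "downstream": "intergenic",
    "utr5;utr3": "utr5",
    "3_prime_utr_variant": "utr3",
    "5_prime_utr_variant": "utr5",
    "ncrna_exonic": "ncrna",
    "ncrna_intronic": "ncrna",
    "ncrna_splicing": "ncrna",
}


def normalize_consequence(label: str | None) -> str:
    """Map a free-form consequence label onto the closed vocabulary."""
    if label is None or (isinstance(label, float) and math.isnan(label)):
        return "other"
    key = str(label).strip().lower().replace("utr3", "utr3").replace("utr5", "utr5")
    if key in CONSEQUENCES:
        return key
    return _CONSEQUENCE_ALIASES.get(key, "other")


_BOUNDED_01 = (
    "af_1000g",
    "af_gnomad",
    "phastcons_primates",
    "phastcons_mammals",
    "condel",
    "segdup",
    "abb",
)


@dataclass
class AnnotationProfile:
    """All annotation fields for one variant, with explicit missingness."""

    site: VariantSite
    gene: str | None = None
    consequence: str = "other"
    af_1000g: float | None = None
    af_gnomad: float | None = None
    phastcons_primates: float | None = None
    phastcons_mammals: float | None = None
    phylop_primates: float | None = None
    phylop_mammals: float | None = None
    condel: float | None = None
    cadd_phred: float | None = None
    eigen: float | None = None
    mutation_assessor: float | None = None
    segdup: float | None = None
    abb: float | None = None

    def __post_init__(self) -> None:
        self.consequence = normalize_consequence(self.consequence)
        for name in _BOUNDED_01:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1] at {self.site.key}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be >= 0, got {self.cadd_phred}")


def max_population_af(profile: AnnotationProfile) -> float:
    """Maximum allele frequency across population databases; 0 when novel.

    Absence from every frequency database is interpreted as "never
    observed", i.e. an allele frequency of zero — unlike every other
    feature, where missingness is imputed with a neutral expectation.
    """
    values = []
    for name in _AF_FIELDS:
        v = getattr(profile, name)
        if v is not None:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
            values.append(v)
    return max(values) if values else 0.0


def assemble_feature_vector(
    profile: AnnotationProfile, neutral_reference: Mapping[str, float]
) -> np.ndarray:
    """Build the ordered 11-feature vector, imputing missing values.

    ``neutral_reference`` must provide one value per non-AF feature; any
    missing profile field is replaced by its neutral value, present fields
    pass through unchanged, and slot 0 is :func:`max_population_af`.
    """
    absent = [f for f in PROFILE_FEATURE_FIELDS if f not in neutral_reference]
    if absent:
        raise ValueError(f"neutral reference lacks feature(s): {absent}")
    vec = np.empty(len(FEATURE_NAMES), dtype=float)
    vec[0] = max_population_af(profile)
    for i, name in enumerate(PROFILE_FEATURE_FIELDS, start=1):
        v = getattr(profile, name)
        vec[i] = float(neutral_reference[name]) if v is None else float(v)
    return vec


# ---------------------------------------------------------------------------
# Table loading
# ---------------------------------------------------------------------------

_KEY_COLUMNS = ("chrom", "pos", "ref", "alt")


def load_annotation_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> dict[tuple[str, int, str, str], AnnotationProfile]:
    """Load a delimited annotation table keyed by (chrom, pos, ref, alt).

    The delimiter is sniffed (TSV or CSV).  ``column_map`` renames file
    columns onto the canonical names; unknown columns are ignored and empty
    cells become explicit missing values.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing_cols = [c for c in _KEY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing mandatory key column(s): {missing_cols}")
    return profiles_from_frame(df, source=str(path))


def profiles_from_frame(
    df: pd.DataFrame, source: str = "<frame>"
) -> dict[tuple[str, int, str, str], AnnotationProfile]:
    """Convert an annotation DataFrame into keyed :class:`AnnotationProfile`s."""
    numeric = [f.name for f in fields(AnnotationProfile) if f.name not in ("site", "gene", "consequence")]
    profiles: dict[tuple[str, int, str, str], AnnotationProfile] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        site = VariantSite(str(d["chrom"]), int(d["pos"]), str(d["ref"]), str(d["alt"]))
        if site.key in profiles:
            raise ValueError(f"{source}: duplicate variant key {site.key}")
        kwargs = {}
        for name in numeric:
            v = d.get(name)
            kwargs[name] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        gene = d.get("gene")
        if gene is not None and (not isinstance(gene, str)) and pd.isna(gene):
            gene = None
        profiles[site.key] = AnnotationProfile(
            site=site,
            gene=gene if isinstance(gene, str) else None,
            consequence=d.get("consequence", "other"),
            **kwargs,
        )
    return profiles


def feature_matrix(
    profiles: list[AnnotationProfile] | dict,
    neutral_reference: Mapping[str, float],
) -> np.ndarray:
    """Stack feature vectors for many profiles into an (n, 11) matrix."""
    items = list(profiles.values()) if isinstance(profiles, dict) else list(profiles)
    if not items:
        return np.empty((0, len(FEATURE_NAMES)))
    return np.vstack([assemble_feature_vector(p, neutral_reference) for p in items])
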