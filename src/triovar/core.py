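"""Domain types and I/O for family-based variant analysis.

This module defines the shared vocabulary of the package — variant sites,
per-sample genotype calls, pedigrees and inheritance modes — together with
readers for multisample VCF and 6-column PED files and a writer for ranked
candidate lists.

Conventions
-----------
* Coordinates are 1-based, as in VCF; indels keep the VCF anchor base.
* Chromosome labels are normalized by stripping a leading ``chr``.
* Multi-allelic VCF records are decomposed into one record per alternative
  allele before anything downstream sees them.  When a sample carries a
  *different* alternative allele at a decomposed site, its genotype is
  recoded as homozygous reference for this record and flagged with
  ``other_alt=True`` so that compound-heterozygosity logic can still see it.
* Missing DP/GQ/AD are explicit ``None`` sentinels, never zeros.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Genotype",
    "Sex",
    "InheritanceMode",
    "VariantSite",
    "GenotypeCall",
    "MultiSampleVariant",
    "PedigreeMember",
    "Pedigree",
    "PedigreeError",
    "VcfError",
    "normalize_chrom",
    "chrom_sort_key",
    "read_pedigree",
    "read_multisample_vcf",
    "write_multisample_vcf",
    "write_candidates",
    "is_mendelian_consistent",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigree files."""


class VcfError(ValueError):
    """Raised for VCF files that cannot be interpreted."""


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def n_alt(self) -> int | None:
        """Number of alternative alleles carried, ``None`` when missing."""
        return _N_ALT[self]


_N_ALT = {
    Genotype.HOM_REF: 0,
    Genotype.HET: 1,
    Genotype.HOM_ALT: 2,
    Genotype.MISSING: None,
}


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class InheritanceMode(str, Enum):
    """The five Mendelian segregation hypotheses the prioritizer supports."""

    DOMINANT_DENOVO = "dominant_denovo"
    DOMINANT_INHERITED = "dominant_inherited"
    RECESSIVE_HOMOZYGOUS = "recessive_homozygous"
    COMPOUND_HETEROZYGOUS = "compound_heterozygous"
    X_LINKED = "x_linked"


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix (``chrX`` -> ``X``, ``chr1`` -> ``1``)."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = normalize_chrom(chrom)
    return (_CHROM_ORDER.get(c, 99), c)


@dataclass(frozen=True, order=False)
class VariantSite:
    """A single bi-allelic variant identified by (chrom, pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def sort_key(self) -> tuple[tuple[int, str], int, str, str]:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)


@dataclass
class GenotypeCall:
    """One sample's call at one site, with its quality evidence.

    ``dp``/``gq``/``ad_*`` are ``None`` when the VCF did not report them; a
    ``None`` fails any minimum-threshold quality filter unless that filter is
    disabled.
    """

    sample_id: str
    gt: Genotype
    dp: int | None = None
    gq: float | None = None
    ad_ref: int | None = None
    ad_alt: int | None = None
    other_alt: bool = False

    def __post_init__(self) -> None:
        if self.dp is not None and self.dp < 0:
            raise ValueError("dp must be >= 0")
        if (
            self.dp is not None
            and self.ad_ref is not None
            and self.ad_alt is not None
            and self.ad_ref + self.ad_alt > self.dp
        ):
            raise ValueError("ad_ref + ad_alt exceeds dp")

    @property
    def n_alt(self) -> int | None:
        return self.gt.n_alt


@dataclass
class MultiSampleVariant:
    """A variant site with one genotype call per pedigree member."""

    site: VariantSite
    calls: dict[str, GenotypeCall]

    def call(self, sample_id: str) -> GenotypeCall:
        return self.calls[sample_id]

    def validate_against(self, pedigree: "Pedigree") -> None:
        missing = [m.sample_id for m in pedigree.members if m.sample_id not in self.calls]
        if missing:
            raise VcfError(
                f"variant {self.site.key} lacks calls for pedigree member(s): {missing}"
            )


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    sex: Sex = Sex.UNKNOWN
    affected: bool = False
    father_id: str | None = None
    mother_id: str | None = None


@dataclass
class Pedigree:
    """Samples of one family, their sexes, disease status and parent links."""

    members: list[PedigreeMember]
    _by_id: dict[str, PedigreeMember] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate sample ids in pedigree")
        self._by_id = {m.sample_id: m for m in self.members}
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"parent '{pid}' of '{m.sample_id}' is not a pedigree member"
                    )
        if not self.affected:
            raise PedigreeError("pedigree has no affected member")

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> PedigreeMember:
        return self._by_id[sample_id]

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.members]

    @property
    def affected(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.affected]

    @property
    def unaffected(self) -> list[PedigreeMember]:
        return [m for m in self.members if not m.affected]

    def parents_of(self, member: PedigreeMember) -> tuple[PedigreeMember | None, PedigreeMember | None]:
        father = self._by_id.get(member.father_id) if member.father_id else None
        mother = self._by_id.get(member.mother_id) if member.mother_id else None
        return father, mother

    def trio_children(self) -> list[PedigreeMember]:
        """Members with both parents present in the pedigree."""
        return [
            m
            for m in self.members
            if m.father_id in self._by_id and m.mother_id in self._by_id
        ]

    @property
    def is_trio(self) -> bool:
        return len(self.members) == 3 and len(self.trio_children()) == 1


def read_pedigree(path: str | Path) -> Pedigree:
    """Parse a whitespace-delimited 6-column PED file.

    Columns: family, individual, father, mother, sex (1=male, 2=female,
    0=unknown), phenotype (2=affected, 1=unaffected).  Parent id ``0`` means
    "not in pedigree".
    """
    sex_map = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
    members: list[PedigreeMember] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            _fam, iid, fid, mid, sex, pheno = fields[:6]
            if sex not in sex_map:
                raise PedigreeError(f"{path}:{lineno}: invalid sex code '{sex}'")
            members.append(
                PedigreeMember(
                    sample_id=iid,
                    sex=sex_map[sex],
                    affected=(pheno == "2"),
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                )
            )
    if not members:
        raise PedigreeError(f"{path}: empty pedigree")
    return Pedigree(members)


# ---------------------------------------------------------------------------
# VCF reading (cyvcf2) with per-alt decomposition
# ---------------------------------------------------------------------------

def read_multisample_vcf(path: str | Path, pedigree: Pedigree) -> list[MultiSampleVariant]:
    """Read a multisample VCF, decomposing multi-allelic records per alt.

    Every returned record carries a call (possibly ``missing``) for each
    pedigree member.  DP/GQ/AD absent in the file become ``None``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples: list[str] = list(vcf.samples)
    absent = [s for s in pedigree.sample_ids if s not in samples]
    if absent:
        raise VcfError(f"pedigree sample(s) not in VCF header of {path}: {absent}")
    idx = {s: samples.index(s) for s in pedigree.sample_ids}

    out: list[MultiSampleVariant] = []
    for recno, rec in enumerate(vcf, start=1):
        try:
            out.extend(_decompose_record(rec, idx))
        except VcfError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise VcfError(f"{path}: malformed record #{recno} at {rec.CHROM}:{rec.POS}: {exc}") from exc
    return out


def _decompose_record(rec, idx: Mapping[str, int]) -> list[MultiSampleVariant]:
    alts = rec.ALT or []
    if not alts:
        return []
    genotypes = rec.genotypes  # [[a0, a1, phased], ...]
    dp = _format_ints(rec, "DP")
    gq = rec.gt_quals
    try:
        ad = rec.format("AD")
    except KeyError:
        ad = None

    records: list[MultiSampleVariant] = []
    for ai, alt in enumerate(alts, start=1):
        site = VariantSite(chrom=rec.CHROM, pos=int(rec.POS), ref=rec.REF, alt=str(alt))
        calls: dict[str, GenotypeCall] = {}
        for sample_id, j in idx.items():
            alleles = list(genotypes[j][:2])
            if any(a < 0 for a in alleles):
                gt = Genotype.MISSING
                other = False
            else:
                n_this = sum(1 for a in alleles if a == ai)
                other = any(a not in (0, ai) for a in alleles)
                gt = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}[n_this]
            sdp = _clean_int(dp[j]) if dp is not None else None
            sgq = _clean_float(gq[j]) if gq is not None else None
            ad_ref = ad_alt = None
            if ad is not None:
                row = ad[j]
                ad_ref = _clean_int(row[0]) if len(row) > 0 else None
                ad_alt = _clean_int(row[ai]) if len(row) > ai else None
            calls[sample_id] = GenotypeCall(
                sample_id=sample_id,
                gt=gt,
                dp=sdp,
                gq=sgq,
                ad_ref=ad_ref,
                ad_alt=ad_alt,
                other_alt=other,
            )
        records.append(MultiSampleVariant(site=site, calls=calls))
    return records


def _format_ints(rec, tag: str):
    try:
        arr = rec.format(tag)
    except KeyError:
        return None
    if arr is None:
        return None
    return arr[:, 0] if arr.ndim == 2 else arr


def _clean_int(x) -> int | None:
    try:
        v = int(x)
    except (TypeError, ValueError):
        return None
    return v if v >= 0 else None


def _clean_float(x) -> float | None:
    try:
        v = float(x)
    except (TypeError, ValueError):
        return None
    return v if v >= 0 else None


# ---------------------------------------------------------------------------
# VCF writing (deterministic plain-text serialization)
# ---------------------------------------------------------------------------

_GT_STR = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_multisample_vcf(
    variants: Iterable[MultiSampleVariant],
    sample_ids: Sequence[str],
    path: str | Path,
) -> None:
    """Serialize records to a minimal, byte-deterministic VCF 4.2 file.

    Records are sorted by (chrom, pos, ref, alt); FORMAT is ``GT:DP:GQ:AD``
    with ``.`` for absent values.
    """
    recs = sorted(variants, key=lambda v: v.site.sort_key)
    contigs = sorted({v.site.chrom for v in recs}, key=chrom_sort_key)
    lines = [
        "##fileformat=VCFv4.2",
        *[f"##contig=<ID={c}>" for c in contigs],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_ids),
    ]
    for v in recs:
        cols = [
            v.site.chrom,
            str(v.site.pos),
            ".",
            v.site.ref,
            v.site.alt,
            ".",
            ".",
            ".",
            "GT:DP:GQ:AD",
        ]
        for s in sample_ids:
            c = v.calls[s]
            dp = "." if c.dp is None else str(c.dp)
            gq = "." if c.gq is None else str(int(round(c.gq)))
            if c.ad_ref is None or c.ad_alt is None:
                ad = "."
            else:
                ad = f"{c.ad_ref},{c.ad_alt}"
            cols.append(f"{_GT_STR[c.gt]}:{dp}:{gq}:{ad}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Candidate list output
# ---------------------------------------------------------------------------

def write_candidates(candidates: Sequence, path: str | Path, xlsx: bool = False) -> None:
    """Write a ranked candidate list as CSV (optionally mirroring to XLSX).

    Each candidate must provide a ``to_record()`` mapping (rank, site fields,
    score, modes, annotations...).  Rows are written in rank order.
    """
    records = [c.to_record() for c in candidates]
    records.sort(key=lambda r: r["rank"])
    header = _candidate_header(records)
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=header, extrasaction="ignore")
        writer.writeheader()
        for r in records:
            writer.writerow(r)
    if xlsx:
        import pandas as pd

        pd.DataFrame(records, columns=header).to_excel(
            path.with_suffix(".xlsx"), index=False
        )


_LEAD_COLUMNS = [
    "rank",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "score",
    "modes",
    "partner",
    "hpo_score",
]


def _candidate_header(records: Sequence[Mapping]) -> list[str]:
    extra: list[str] = []
    for r in records:
        for k in r:
            if k not in _LEAD_COLUMNS and k not in extra:
                extra.append(k)
    if not records:
        return list(_LEAD_COLUMNS)
    return list(_LEAD_COLUMNS) + extra


# ---------------------------------------------------------------------------
# Mendelian consistency (shared by the simulator and its tests)
# ---------------------------------------------------------------------------

def is_mendelian_consistent(child: Genotype, father: Genotype, mother: Genotype) -> bool:
    """True when the child's autosomal genotype can arise from the parents.

    Missing genotypes are treated as compatible with anything.
    """
    if Genotype.MISSING in (child, father, mother):
        return True
    paternal = _gamete_alleles(father)
    maternal = _gamete_alleles(mother)
    possible = {(p + m) for p in paternal for m in maternal}
    return child.n_alt in possible


def _gamete_alleles(gt: Genotype) -> set[int]:
    return {Genotype.HOM_REF: {0}, Genotype.HET: {0, 1}, Genotype.HOM_ALT: {1}}[gt]
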