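"""Variant reading, filtering, dosage recoding and SNV-sharing analysis.

The analysis domain is a nearly monoclonal triploid population: every
specimen is (apart from new mutations) a copy of a single reference
genotype. Variants are therefore summarised per site as the alternative-
allele dosage 0-3 (0/0/0 -> 0 ... 1/1/1 -> 3), and "polymorphic sites"
are reference-homozygous positions where at least one retained specimen
carries a single-nucleotide substitution.

Filters follow the pipeline's convention: per-sample read depth in
[min_depth, max_depth], site quality >= min_site_quality, SNVs only,
sites covered in the reference, reference-heterozygous sites excluded.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "GenotypeCall",
    "VariantSite",
    "FilterConfig",
    "GenotypeMatrix",
    "SharingSummary",
    "AnnotationSummary",
    "read_vcf",
    "apply_filters",
    "recode_dosage",
    "polymorphic_partition",
    "annotate_snvs",
    "PloidyError",
]

MISSING = -1  # dosage code for a missing genotype

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


class PloidyError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site: dosage 0-3 (or missing), reads."""

    dosage: int  # MISSING if uncalled
    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.dosage != MISSING and self.dosage not in (0, 1, 2, 3):
            raise ValueError(f"dosage {self.dosage} outside 0..3")
        if not 0 <= self.alt_reads <= max(self.depth, 0):
            raise ValueError("alt_reads must be within [0, depth]")


@dataclass
class VariantSite:
    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    quality: float
    calls: dict[str, GenotypeCall]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass(frozen=True)
class FilterConfig:
    min_site_quality: float = 30.0
    min_depth: int = 20
    max_depth: int = 200
    require_reference_coverage: bool = True
    drop_reference_het: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_depth <= self.max_depth:
            raise ValueError("need 0 < min_depth <= max_depth")


def read_vcf(path, samples: list[str] | None = None) -> list[VariantSite]:
    """Parse a VCF into per-site records with triploid dosage calls.

    Multi-allelic records are split into one VariantSite per alternative
    allele; the dosage of a sample at the split site counts only that
    allele. Indel/MNP alleles are kept (is_snv False) so the filter stage
    can report what it discarded.
    """
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = samples if samples is not None else list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt_index, alt in enumerate(rec.alts, start=1):
                calls: dict[str, GenotypeCall] = {}
                for sid in sample_ids:
                    s = rec.samples[sid]
                    gt = s.get("GT")
                    if gt is None or all(a is None for a in gt):
                        dosage = MISSING
                    else:
                        if len(gt) != 3:
                            raise PloidyError(
                                f"{rec.contig}:{rec.pos} sample {sid}: "
                                f"ploidy {len(gt)}, expected 3"
                            )
                        dosage = sum(1 for a in gt if a == alt_index)
                    dp = s.get("DP")
                    ad = s.get("AD")
                    if dp is None or ad is None:
                        raise ValueError(
                            f"{rec.contig}:{rec.pos} sample {sid}: DP/AD missing"
                        )
                    calls[sid] = GenotypeCall(
                        dosage=dosage,
                        depth=int(dp),
                        alt_reads=int(ad[alt_index]),
                    )
                sites.append(
                    VariantSite(
                        contig=rec.contig,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        quality=float(rec.qual) if rec.qual is not None else 0.0,
                        calls=calls,
                    )
                )
    sites.sort(key=lambda s: (s.contig, s.position, s.alt_allele))
    return sites


def apply_filters(sites, cfg: FilterConfig, ref=None) -> list[VariantSite]:
    """Apply the SNV-site filters; total (never raises on content).

    ``ref`` is a ReferenceProfile (synthdata); when given, sites not
    covered in the reference are removed and reference-heterozygous sites
    are eliminated so polymorphic-site analysis stays on reference-
    homozygous loci.
    """
    kept = []
    for site in sites:
        if not site.is_snv:
            continue
        if site.quality < cfg.min_site_quality:
            continue
        depths = [c.depth for c in site.calls.values() if c.dosage != MISSING]
        if not depths:
            continue
        if any(d < cfg.min_depth or d > cfg.max_depth for d in depths):
            continue
        if ref is not None:
            ref_dosage = ref.dosage_at(site.contig, site.position)
            if cfg.require_reference_coverage and ref_dosage is None:
                continue
            if cfg.drop_reference_het and ref_dosage in (1, 2):
                continue
        kept.append(site)
    return kept


@dataclass
class GenotypeMatrix:
    """Samples x sites dosage matrix (int, MISSING = -1) with site keys."""

    sample_ids: list[str]
    contigs: np.ndarray  # per site
    positions: np.ndarray  # per site, 1-based
    dosage: np.ndarray  # (n_samples, n_sites)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs)
        self.positions = np.asarray(self.positions)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.shape != (len(self.sample_ids), len(self.positions)):
            raise ValueError("dosage matrix shape mismatch")
        valid = (self.dosage >= 0) & (self.dosage <= 3) | (self.dosage == MISSING)
        if not valid.all():
            raise ValueError("dosages must be 0..3 or missing (-1)")
        order = np.lexsort((self.positions, self.contigs))
        if not np.array_equal(order, np.arange(len(order))):
            self.contigs = self.contigs[order]
            self.positions = self.positions[order]
            self.dosage = self.dosage[:, order]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def presence(self) -> np.ndarray:
        """Boolean carrier matrix: dosage > 0 (missing counts as absent)."""
        return self.dosage > 0

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.dosage.T,
            columns=self.sample_ids,
        )
        df.insert(0, "contig", self.contigs)
        df.insert(1, "position", self.positions)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, groups=None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        sample_ids = [c for c in df.columns if c not in ("contig", "position")]
        return cls(
            sample_ids=sample_ids,
            contigs=df["contig"].to_numpy(),
            positions=df["position"].to_numpy(),
            dosage=df[sample_ids].to_numpy().T,
            groups=groups or {},
        )


def recode_dosage(sites: list[VariantSite], groups=None) -> GenotypeMatrix:
    """Recode triploid genotypes to the 0-3 dosage matrix.

    The mapping is the bijection 0/0/0 -> 0, 0/0/1 -> 1, 0/1/1 -> 2,
    1/1/1 -> 3 (dosage = count of alternative alleles); missing genotypes
    carry the designated missing code.
    """
    if not sites:
        raise ValueError("no sites to recode")
    sample_ids = list(sites[0].calls)
    dosage = np.empty((len(sample_ids), len(sites)), dtype=np.int16)
    for j, site in enumerate(sites):
        for i, sid in enumerate(sample_ids):
            dosage[i, j] = site.calls[sid].dosage
    return GenotypeMatrix(
        sample_ids=sample_ids,
        contigs=np.array([s.contig for s in sites]),
        positions=np.array([s.position for s in sites]),
        dosage=dosage,
        groups=groups or {},
    )


@dataclass
class SharingSummary:
    per_sample_snvs: dict[str, int]
    per_sample_unique: dict[str, int]
    shared_by_k: dict[int, int]  # k carriers -> number of sites
    fixed_sites: int  # carried by every sample
    total_polymorphic: int
    venn: dict | None = None  # group A/B shared-set overlap

    def to_json(self, path=None) -> str:
        payload = {
            "per_sample_snvs": self.per_sample_snvs,
            "per_sample_unique": self.per_sample_unique,
            "shared_by_k": {str(k): v for k, v in self.shared_by_k.items()},
            "fixed_sites": self.fixed_sites,
            "total_polymorphic": self.total_polymorphic,
            "venn": self.venn,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def polymorphic_partition(
    matrix: GenotypeMatrix,
    groups: dict[str, str] | None = None,
) -> SharingSummary:
    """Partition polymorphic sites by how many samples share them.

    Sharing is on presence/absence (dosage > 0). A site "shared within a
    group" is carried by every member of that group; the two-set Venn
    compares those shared sets between the two groups.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    groups = groups if groups is not None else matrix.groups
    present = matrix.presence()
    carriers = present.sum(axis=0)
    polymorphic = carriers > 0

    per_sample = {
        sid: int(present[i].sum()) for i, sid in enumerate(matrix.sample_ids)
    }
    unique_mask = carriers == 1
    per_unique = {
        sid: int((present[i] & unique_mask).sum())
        for i, sid in enumerate(matrix.sample_ids)
    }
    shared_by_k = dict(Counter(int(k) for k in carriers[polymorphic]))
    fixed = int((carriers == matrix.n_samples).sum())

    venn = None
    if groups:
        unknown = set(groups) - set(matrix.sample_ids)
        if unknown:
            raise KeyError(f"group labels for unknown samples: {sorted(unknown)}")
        labels = sorted(set(groups.values()))
        if len(labels) == 2:
            a, b = labels
            idx = {sid: i for i, sid in enumerate(matrix.sample_ids)}
            rows_a = [idx[s] for s, grp in groups.items() if grp == a]
            rows_b = [idx[s] for s, grp in groups.items() if grp == b]
            shared_a = present[rows_a].all(axis=0)
            shared_b = present[rows_b].all(axis=0)
            venn = {
                "groups": [a, b],
                "shared_within_A": int(shared_a.sum()),
                "shared_within_B": int(shared_b.sum()),
                "A_only": int((shared_a & ~shared_b).sum()),
                "B_only": int((shared_b & ~shared_a).sum()),
                "both": int((shared_a & shared_b).sum()),
            }
    return SharingSummary(
        per_sample_snvs=per_sample,
        per_sample_unique=per_unique,
        shared_by_k=shared_by_k,
        fixed_sites=fixed,
        total_polymorphic=int(polymorphic.sum()),
        venn=venn,
    )


TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class AnnotationSummary:
    class_counts: dict[str, int]  # coding / exon_noncoding / intronic / intergenic
    spectrum: dict[str, int]  # "G>A" -> count, 12 ordered substitutions
    transitions: int
    transversions: int
    unmatched_contigs: int  # SNVs on contigs absent from the annotation

    def class_fractions(self) -> dict[str, float]:
        total = sum(self.class_counts.values())
        return {k: v / total for k, v in self.class_counts.items()} if total else {}

    def to_tsv(self, path) -> None:
        rows = [("class", k, v) for k, v in sorted(self.class_counts.items())]
        rows += [("substitution", k, v) for k, v in sorted(self.spectrum.items())]
        rows += [
            ("spectrum", "transitions", self.transitions),
            ("spectrum", "transversions", self.transversions),
        ]
        pd.DataFrame(rows, columns=["kind", "key", "count"]).to_csv(
            path, sep="\t", index=False
        )


def _read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )
    return df


def annotate_snvs(sites: list[VariantSite], gff_path) -> AnnotationSummary:
    """Classify SNVs by gene context and tabulate the substitution spectrum.

    Classes (first match wins): coding (inside a CDS), exon_noncoding
    (inside an exon but not a CDS, i.e. UTR or noncoding exon), intronic
    (inside a gene but no exon), intergenic. GFF intervals are 1-based
    inclusive; internally half-open.
    """
    from intervaltree import IntervalTree

    gff = _read_gff3(gff_path)
    trees: dict[tuple[str, str], IntervalTree] = {}
    for _, row in gff.iterrows():
        ftype = row["type"]
        if ftype not in ("gene", "exon", "CDS"):
            continue
        key = (row["seqid"], ftype)
        trees.setdefault(key, IntervalTree()).addi(int(row["start"]), int(row["end"]) + 1)
    annotated_contigs = {seqid for seqid, _ in trees}

    class_counts = {"coding": 0, "exon_noncoding": 0, "intronic": 0, "intergenic": 0}
    spectrum: Counter = Counter()
    ts = tv = 0
    unmatched = 0
    for site in sites:
        if not site.is_snv:
            continue
        sub = f"{site.ref_allele}>{site.alt_allele}"
        spectrum[sub] += 1
        if (site.ref_allele, site.alt_allele) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
        if site.contig not in annotated_contigs:
            unmatched += 1
            class_counts["intergenic"] += 1
            continue

        def hit(ftype: str) -> bool:
            tree = trees.get((site.contig, ftype))
            return bool(tree is not None and tree.overlaps_point(site.position))

        if hit("CDS"):
            class_counts["coding"] += 1
        elif hit("exon"):
            class_counts["exon_noncoding"] += 1
        elif hit("gene"):
            class_counts["intronic"] += 1
        else:
            class_counts["intergenic"] += 1
    if unmatched:
        import warnings

        warnings.warn(
            f"{unmatched} SNVs on contigs absent from the annotation "
            "(classified intergenic)",
            stacklevel=2,
        )
    return AnnotationSummary(
        class_counts=class_counts,
        spectrum=dict(spectrum),
        transitions=ts,
        transversions=tv,
        unmatched_contigs=unmatched,
    )
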