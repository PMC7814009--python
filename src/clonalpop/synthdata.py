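"""Synthetic clonal-genome and trap-survey generators.

Emulates the data-generating process the downstream analysis assumes: a
triploid meta-population descending clonally (apomictically) from one
founder, so every specimen starts as an exact copy of the reference
genotype and differs from it only by new single-nucleotide mutations.
Mutations are placed on a fixed star-of-stars lineage (founder ->
population branches -> individual leaves): a set shared by everyone, a
private set per population, and a private set per individual. Reads are
sampled binomially around the dosage-determined allele fraction d/3, with
per-site depth drawn from a negative-binomial law (Poisson in the
zero-dispersion limit).

A separate generator produces a closed-population multi-day trap survey
with persistent marks, plus a hand-catch table (point densities and a
size distribution) for the stratified extrapolation stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markrecapture import HandCatch, TrapSurvey
from .variants import MISSING, GenotypeMatrix

__all__ = [
    "PopulationSpec",
    "ReadModel",
    "SurveySpec",
    "ReferenceProfile",
    "generate_reference_profile",
    "generate_clonal_genotypes",
    "emit_vcf",
    "inject_loh",
    "generate_trap_survey",
    "write_toy_gff",
    "CapacityError",
]

BASES = np.array(["A", "C", "G", "T"])


class CapacityError(ValueError):
    """More mutations requested than reference-homozygous sites available."""


@dataclass(frozen=True)
class PopulationSpec:
    """Layout of the synthetic clonal meta-population.

    SNV counts are per branch of the founder->population->individual
    lineage: shared_snvs_all on the root branch, private_snvs_per_population
    on each population branch, private_snvs_per_sample on each leaf.
    """

    n_populations: int = 2
    samples_per_population: int | tuple[int, ...] = 5
    n_sites: int = 20_000
    private_snvs_per_population: int = 300
    private_snvs_per_sample: int = 50
    shared_snvs_all: int = 1500
    reference_het_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_populations,
            *self.samples_per_pop,
            self.n_sites,
            self.private_snvs_per_population,
            self.private_snvs_per_sample,
            self.shared_snvs_all,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be nonnegative")
        if len(self.samples_per_pop) != self.n_populations:
            raise ValueError("samples_per_population tuple must match n_populations")
        if not 0 <= self.reference_het_fraction <= 1:
            raise ValueError("reference_het_fraction must be in [0,1]")

    @property
    def samples_per_pop(self) -> tuple[int, ...]:
        """Per-population sample counts (a scalar applies to every one)."""
        if isinstance(self.samples_per_population, int):
            return (self.samples_per_population,) * self.n_populations
        return tuple(self.samples_per_population)

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_pop)

    @property
    def total_assigned_snvs(self) -> int:
        return (
            self.shared_snvs_all
            + self.n_populations * self.private_snvs_per_population
            + self.n_samples * self.private_snvs_per_sample
        )


@dataclass(frozen=True)
class ReadModel:
    """Sequencing emulation: depth law, error rate, site quality."""

    mean_depth: float = 40.0
    depth_dispersion: float = 0.1  # variance = m + dispersion * m^2
    error_rate: float = 0.001
    qual_mean: float = 60.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be nonnegative")

    def draw_depths(self, rng: np.random.Generator, size) -> np.ndarray:
        m = self.mean_depth
        if self.depth_dispersion <= 1e-12:
            return rng.poisson(m, size=size)
        n = 1.0 / self.depth_dispersion
        return rng.negative_binomial(n, n / (n + m), size=size)


@dataclass(frozen=True)
class SurveySpec:
    """Closed-population multi-day trap survey design."""

    true_n: int = 500
    n_days: int = 10
    traps: tuple = (("T01", "shallow"),)
    capture_prob_per_trap: float = 0.05
    mature_fraction: float = 0.12  # hand-catch share above the 6 cm cutoff
    lake_area_m2: float = 92_500.0
    n_hand_sizes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.capture_prob_per_trap <= 1:
            raise ValueError("capture probability must be in [0,1]")
        if self.n_days < 2:
            raise ValueError("need at least 2 survey days")
        if self.true_n < 1:
            raise ValueError("true_n must be positive")


@dataclass
class ReferenceProfile:
    """The reference specimen's genotype, bases and coverage per site.

    dosage 0 marks reference-homozygous sites; dosage 1 or 2 marks
    heterozygous sites (the triploid AAB-style divergent haplotype).
    """

    contigs: np.ndarray
    positions: np.ndarray  # 1-based
    dosage: np.ndarray  # 0 (hom) / 1 / 2 (het)
    ref_base: np.ndarray
    alt_base: np.ndarray
    quality: np.ndarray
    depth: np.ndarray
    covered: np.ndarray  # bool

    _lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._lookup = {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(self.contigs, self.positions))
        }

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def het_mask(self) -> np.ndarray:
        return (self.dosage == 1) | (self.dosage == 2)

    def dosage_at(self, contig: str, position: int):
        """Reference dosage at a coordinate, or None if not covered."""
        i = self._lookup.get((contig, int(position)))
        if i is None or not self.covered[i]:
            return None
        return int(self.dosage[i])


def generate_reference_profile(
    n_sites: int,
    het_fraction: float,
    seed: int,
    n_contigs: int = 1,
    position_spacing: int = 100,
    qual_mean: float = 60.0,
    depth_mean: float = 40.0,
    het_dosage_probs: tuple[float, float] = (0.85, 0.15),
) -> ReferenceProfile:
    """Generate a reference genotype profile.

    Exactly floor(het_fraction * n_sites) sites are heterozygous, placed
    uniformly at random; the rest are reference-homozygous (dosage 0).
    Heterozygous dosage is 1 or 2 with ``het_dosage_probs`` odds: in an
    AAB-style triploid most heterozygous positions carry the divergent
    allele on the single B haplotype (dosage 1), so the windowed VAF
    track concentrates near 1/3 rather than splitting evenly with 2/3.
    All sites are flagged covered.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be nonnegative")
    if not 0 <= het_fraction <= 1:
        raise ValueError("het_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)

    per_contig = np.full(n_contigs, n_sites // n_contigs)
    per_contig[: n_sites % n_contigs] += 1
    contigs = np.concatenate(
        [np.full(k, f"contig_{i + 1}") for i, k in enumerate(per_contig)]
    ) if n_sites else np.array([], dtype=str)
    positions = np.concatenate(
        [1 + np.arange(k) * position_spacing for k in per_contig]
    ).astype(np.int64) if n_sites else np.array([], dtype=np.int64)

    dosage = np.zeros(n_sites, dtype=np.int8)
    n_het = int(np.floor(het_fraction * n_sites))
    het_idx = rng.choice(n_sites, size=n_het, replace=False) if n_het else np.array([], int)
    dosage[het_idx] = rng.choice([1, 2], size=n_het, p=het_dosage_probs)

    ref_base = rng.choice(BASES, size=n_sites)
    shift = rng.integers(1, 4, size=n_sites)
    base_index = np.searchsorted(BASES, ref_base)
    alt_base = BASES[(base_index + shift) % 4]

    quality = np.round(rng.normal(qual_mean, 5.0, size=n_sites), 1).clip(min=0)
    depth = rng.poisson(depth_mean, size=n_sites).clip(min=1)
    return ReferenceProfile(
        contigs=contigs,
        positions=positions,
        dosage=dosage,
        ref_base=ref_base,
        alt_base=alt_base,
        quality=quality,
        depth=depth,
        covered=np.ones(n_sites, dtype=bool),
    )


def generate_clonal_genotypes(
    spec: PopulationSpec, ref: ReferenceProfile
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Place mutations on the founder->population->individual lineage.

    Every sample starts as a copy of the reference (apomixis). Each
    mutation turns one reference-homozygous site from dosage 0 to 1 on a
    single branch; no site mutates twice. Returns the truth dosage matrix
    (all profile sites) and a table recording each mutation's site and
    branch.
    """
    if ref.n_sites != spec.n_sites:
        raise ValueError("reference profile does not cover spec.n_sites")
    rng = np.random.default_rng(spec.seed)
    hom_sites = np.flatnonzero(~ref.het_mask)
    if spec.total_assigned_snvs > hom_sites.size:
        raise CapacityError(
            f"{spec.total_assigned_snvs} SNVs requested but only "
            f"{hom_sites.size} reference-homozygous sites available"
        )
    chosen = rng.choice(hom_sites, size=spec.total_assigned_snvs, replace=False)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = chosen[cursor : cursor + k]
        cursor += k
        return out

    per_pop = spec.samples_per_pop
    sample_ids = [
        f"P{p + 1}_S{s + 1}"
        for p in range(spec.n_populations)
        for s in range(per_pop[p])
    ]
    groups = {sid: sid.split("_")[0] for sid in sample_ids}
    dosage = np.tile(ref.dosage, (spec.n_samples, 1)).astype(np.int16)

    records = []
    shared = take(spec.shared_snvs_all)
    dosage[:, shared] = 1
    records += [(int(i), "root") for i in shared]
    offsets = np.concatenate([[0], np.cumsum(per_pop)])
    for p in range(spec.n_populations):
        pop_sites = take(spec.private_snvs_per_population)
        rows = slice(int(offsets[p]), int(offsets[p + 1]))
        dosage[rows, pop_sites] = 1
        records += [(int(i), f"pop:P{p + 1}") for i in pop_sites]
    for si, sid in enumerate(sample_ids):
        leaf_sites = take(spec.private_snvs_per_sample)
        dosage[si, leaf_sites] = 1
        records += [(int(i), f"sample:{sid}") for i in leaf_sites]

    truth = GenotypeMatrix(
        sample_ids=sample_ids,
        contigs=ref.contigs.copy(),
        positions=ref.positions.copy(),
        dosage=dosage,
        groups=groups,
    )
    lineage = pd.DataFrame(records, columns=["site_index", "branch"])
    lineage["contig"] = ref.contigs[lineage["site_index"]]
    lineage["position"] = ref.positions[lineage["site_index"]]
    lineage = lineage.sort_values(["contig", "position"]).reset_index(drop=True)
    return truth, lineage


def _effective_alt_prob(dosage: np.ndarray, error_rate: float) -> np.ndarray:
    p = dosage / 3.0
    return p * (1.0 - error_rate) + (1.0 - p) * error_rate


def emit_vcf(
    truth: GenotypeMatrix,
    ref: ReferenceProfile,
    read_model: ReadModel,
    path,
    seed: int,
) -> int:
    """Write a VCF v4.2 of the variant sites of the truth matrix.

    A site is emitted when the reference is heterozygous there or any
    sample carries a nonzero dosage. Per sample: triploid GT from the
    truth dosage, DP from the depth law, AD alt count ~ Binomial(DP, p)
    with p = dosage/3 folded with the error rate. Deterministic for a
    fixed seed (byte-identical reruns). Returns the record count.
    """
    rng = np.random.default_rng(seed)
    variant_any = (truth.dosage > 0).any(axis=0)
    emit_mask = variant_any | ref.het_mask
    idx = np.flatnonzero(emit_mask)

    gt_strings = {0: "0/0/0", 1: "0/0/1", 2: "0/1/1", 3: "1/1/1", MISSING: "././."}
    qual = np.round(rng.normal(read_model.qual_mean, 3.0, size=idx.size), 1).clip(min=1)

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonalpop-synthdata\n")
        for contig in pd.unique(truth.contigs):
            length = int(truth.positions[truth.contigs == contig].max()) + 1000
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(truth.sample_ids)
            + "\n"
        )
        for row, i in enumerate(idx):
            depths = read_model.draw_depths(rng, truth.n_samples).clip(min=1)
            probs = _effective_alt_prob(
                truth.dosage[:, i].astype(float), read_model.error_rate
            )
            alts = rng.binomial(depths, probs)
            fields = [
                str(truth.contigs[i]),
                str(int(truth.positions[i])),
                ".",
                str(ref.ref_base[i]),
                str(ref.alt_base[i]),
                f"{qual[row]:.1f}",
                "PASS",
                f"NS={truth.n_samples}",
                "GT:DP:AD",
            ]
            for s in range(truth.n_samples):
                d = int(truth.dosage[s, i])
                gt = gt_strings[d]
                dp = int(depths[s])
                ad_alt = int(alts[s])
                fields.append(f"{gt}:{dp}:{dp - ad_alt},{ad_alt}")
            fh.write("\t".join(fields) + "\n")
    return int(idx.size)


def inject_loh(
    truth: GenotypeMatrix,
    ref: ReferenceProfile,
    sample: str,
    site_range: tuple[int, int],
    seed: int = 0,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Homogenize reference-het dosages for one sample in a site-index range.

    Within [start, end) heterozygous dosages collapse to the nearest
    homozygote (1 -> 0, 2 -> 3), emulating loss of heterozygosity. The
    report lists every modified site with its old and new dosage. The
    input matrix is not modified.
    """
    start, end = site_range
    if end <= start:
        raise ValueError("empty site range")
    if not 0 <= start < end <= truth.n_sites:
        raise ValueError("site range outside genome")
    if sample not in truth.sample_ids:
        raise KeyError(f"unknown sample {sample!r}")
    row = truth.sample_ids.index(sample)
    dosage = truth.dosage.copy()
    rows = []
    for i in range(start, end):
        d = int(dosage[row, i])
        if d == 1:
            new = 0
        elif d == 2:
            new = 3
        else:
            continue
        dosage[row, i] = new
        rows.append((i, str(truth.contigs[i]), int(truth.positions[i]), d, new))
    modified = GenotypeMatrix(
        sample_ids=list(truth.sample_ids),
        contigs=truth.contigs.copy(),
        positions=truth.positions.copy(),
        dosage=dosage,
        groups=dict(truth.groups),
    )
    report = pd.DataFrame(
        rows, columns=["site_index", "contig", "position", "old_dosage", "new_dosage"]
    )
    return modified, report


def generate_trap_survey(spec: SurveySpec) -> tuple[TrapSurvey, HandCatch]:
    """Simulate the closed-population survey and the hand-catch tables.

    Each day every individual is captured with probability
    1 - (1-p)^n_traps (independent traps, one shared per-trap rate) and,
    if captured, is assigned to a trap uniformly. Unmarked captures are
    marked; marks persist. The hand catch reports three point densities
    around true_N / lake_area and a two-component size distribution with
    ``mature_fraction`` of animals above the 6 cm cutoff.
    """
    rng = np.random.default_rng(spec.seed)
    n_traps = len(spec.traps)
    p_day = 1.0 - (1.0 - spec.capture_prob_per_trap) ** n_traps
    if p_day == 0:
        warnings.warn("capture probability 0: no recaptures possible", stacklevel=2)

    marked = np.zeros(spec.true_n, dtype=bool)
    rows = []
    for day in range(1, spec.n_days + 1):
        caught = rng.random(spec.true_n) < p_day
        caught_idx = np.flatnonzero(caught)
        trap_of = rng.integers(0, n_traps, size=caught_idx.size)
        for t, (trap_id, stratum_id) in enumerate(spec.traps):
            here = caught_idx[trap_of == t]
            c = here.size
            r = int(marked[here].sum())
            rows.append((day, trap_id, stratum_id, c, c - r, r))
        marked[caught_idx] = True
    survey = TrapSurvey(pd.DataFrame(rows, columns=["day", "trap_id", "stratum_id", "catch", "new_marks", "recaptures"]))

    true_density = spec.true_n / spec.lake_area_m2
    densities = np.abs(rng.normal(true_density, 0.15 * true_density, size=3))
    n_mature = rng.binomial(spec.n_hand_sizes, spec.mature_fraction)
    mature_sizes = np.clip(rng.normal(8.5, 1.0, size=n_mature), 6.1, None)
    immature_sizes = np.clip(
        rng.normal(4.5, 0.8, size=spec.n_hand_sizes - n_mature), 1.0, 5.9
    )
    sizes = np.concatenate([mature_sizes, immature_sizes])
    rng.shuffle(sizes)
    return survey, HandCatch(densities_per_m2=densities, sizes_cm=sizes)


def write_toy_gff(path, genes) -> None:
    """Write a minimal GFF3 for annotation tests.

    ``genes`` is an iterable of dicts with keys contig, start, end and
    optional exons / cds (lists of (start, end), 1-based inclusive).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, gene in enumerate(genes, start=1):
            gid = f"gene{k}"
            fh.write(
                f"{gene['contig']}\ttoy\tgene\t{gene['start']}\t{gene['end']}"
                f"\t.\t+\t.\tID={gid}\n"
            )
            for s, e in gene.get("exons", []):
                fh.write(
                    f"{gene['contig']}\ttoy\texon\t{s}\t{e}\t.\t+\t.\tParent={gid}\n"
                )
            for s, e in gene.get("cds", []):
                fh.write(
                    f"{gene['contig']}\ttoy\tCDS\t{s}\t{e}\t.\t+\t0\tParent={gid}\n"
                )
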