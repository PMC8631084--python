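"""Genotype containers with ploidy-aware semantics for autosomes, X, and mito.

The data model starts downstream of variant calling: a sites × samples matrix
of derived-allele dosages, where every entry carries an implied copy number
(ploidy) of 2 on autosomes, 1 for males / 2 for females on the X chromosome,
and 1 on the mitochondrial genome.  All population-genetic statistics in this
package consume the per-population allele counts built here.

Coordinate conventions: VCF positions are 1-based; BED-style region masks are
0-based half-open.  The conversion happens exactly once, inside the mask
membership test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1
CHROM_CLASSES = ("autosome", "X", "mito")
SEXES = ("male", "female", "unknown")

#: Pseudoautosomal regions of the X on the olive-baboon reference assembly
#: (0-based half-open), plus the 10-Mb window proximal to the PAR1 boundary
#: that shows anomalous differentiation and is excluded from X scans.
PAR1 = ("chrX", 0, 133_703)
PAR2 = ("chrX", 143_394_133, 143_691_637)
PAR1_PROXIMAL_10MB = ("chrX", 133_703, 10_133_703)


class GenotypeDataError(ValueError):
    """Raised on malformed genotype input or inconsistent metadata."""


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMask:
    """A set of genomic intervals, 0-based half-open, with a label."""

    intervals: tuple[tuple[str, int, int], ...]
    label: str = "mask"

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise GenotypeDataError(
                    f"malformed interval {chrom}:{start}-{end} (start >= end)"
                )
            if start < 0:
                raise GenotypeDataError(f"negative interval start on {chrom}")

    def member_mask(self, chrom: np.ndarray, pos_1based: np.ndarray) -> np.ndarray:
        """Boolean array: True where a site (1-based position) falls inside."""
        pos0 = np.asarray(pos_1based) - 1  # the single 1-based -> 0-based shift
        chrom = np.asarray(chrom)
        inside = np.zeros(pos0.shape, dtype=bool)
        for c, start, end in self.intervals:
            inside |= (chrom == c) & (pos0 >= start) & (pos0 < end)
        return inside

    def __or__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.intervals + other.intervals,
                          label=f"{self.label}+{other.label}")


def preset_mask(name: str) -> RegionMask:
    """Named masks used by the default X-chromosome analysis."""
    presets = {
        "par1": RegionMask((PAR1,), "par1"),
        "par2": RegionMask((PAR2,), "par2"),
        "pars": RegionMask((PAR1, PAR2), "pars"),
        "par1_proximal_10mb": RegionMask((PAR1_PROXIMAL_10MB,), "par1_proximal_10mb"),
        "x_default_exclusion": RegionMask(
            (PAR1, PAR2, PAR1_PROXIMAL_10MB), "x_default_exclusion"
        ),
    }
    try:
        return presets[name]
    except KeyError:
        raise GenotypeDataError(f"unknown preset mask {name!r}") from None


def read_bed(path: str | Path, label: str | None = None) -> RegionMask:
    """Read a BED file (first three columns) into a RegionMask."""
    intervals = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        chrom, start, end = line.split("\t")[:3]
        intervals.append((chrom, int(start), int(end)))
    return RegionMask(tuple(intervals), label or Path(path).stem)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "population", "sex"}
    missing = required - set(samples.columns)
    if missing:
        raise GenotypeDataError(f"sample sheet missing columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dupes = samples.loc[samples["sample_id"].duplicated(), "sample_id"].tolist()
        raise GenotypeDataError(f"duplicate sample ids: {dupes}")
    if samples["population"].isna().any() or (samples["population"] == "").any():
        raise GenotypeDataError("every sample needs a population label")
    bad_sex = set(samples["sex"]) - set(SEXES)
    if bad_sex:
        raise GenotypeDataError(f"unknown sex values: {sorted(bad_sex)}")
    return samples.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a headered TSV with columns sample_id, population, sex."""
    return validate_sample_sheet(pd.read_csv(path, sep="\t", dtype=str))


def read_class_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV chrom -> chromosome class (autosome/X/mito)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "chrom_class"],
                     dtype=str, comment="#")
    bad = set(df["chrom_class"]) - set(CHROM_CLASSES)
    if bad:
        raise GenotypeDataError(f"unknown chromosome classes: {sorted(bad)}")
    return dict(zip(df["chrom"], df["chrom_class"]))


def within_population_pairs(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """All unordered pairs of distinct individuals from the same population.

    These are the "same-population" comparisons used to gauge the baseline
    deviation of the f4 test: with C and D drawn from one population the
    statistic should sit at zero up to sampling noise.
    """
    samples = validate_sample_sheet(samples)
    pairs: list[tuple[str, str]] = []
    for _, grp in samples.groupby("population", sort=True):
        ids = sorted(grp["sample_id"])
        pairs.extend(itertools.combinations(ids, 2))
    return pairs


def macaque_sample_sheet() -> pd.DataFrame:
    """The 17-genome macaque panel (sample -> population symbol, sex).

    Sexes are recorded where published; samples used only for autosomal
    analyses may carry sex 'unknown'.
    """
    path = Path(__file__).parent / "data" / "macaque_samples.tsv"
    return read_sample_sheet(path)


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

def expected_ploidy(chrom_class: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Sites × samples copy-number matrix implied by class and sex."""
    chrom_class = np.asarray(chrom_class)[:, None]
    sex = np.asarray(sex)[None, :]
    ploidy = np.full((chrom_class.shape[0], sex.shape[1]), 2, dtype=np.int8)
    ploidy[(chrom_class == "X") & (sex == "male")] = 1
    ploidy[np.broadcast_to(chrom_class == "mito", ploidy.shape)] = 1
    return ploidy


@dataclass
class GenotypeMatrix:
    """Sites × samples derived-allele dosages with ploidy semantics.

    ``dosage[i, j]`` is the number of derived (ALT) copies carried by sample
    j at site i, ``MISSING`` (−1) when uncalled.  ``ploidy`` is the called
    copy number implied by chromosome class and sex.
    """

    sites: pd.DataFrame     # chrom, pos (1-based), ref, alt, chrom_class
    samples: pd.DataFrame   # sample_id, population, sex
    dosage: np.ndarray      # (n_sites, n_samples) int16, MISSING = -1

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.samples = validate_sample_sheet(self.samples)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise GenotypeDataError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.sites)}, {len(self.samples)})"
            )
        self.validate()

    # -- derived views ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def ploidy(self) -> np.ndarray:
        return expected_ploidy(self.sites["chrom_class"].to_numpy(),
                               self.samples["sex"].to_numpy())

    @property
    def called(self) -> np.ndarray:
        return self.dosage != MISSING

    def validate(self) -> None:
        dup = self.sites.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise GenotypeDataError("duplicate (chrom, pos) site records")
        if (self.sites["pos"] < 1).any():
            raise GenotypeDataError("VCF positions are 1-based; pos < 1 found")
        bad_class = set(self.sites["chrom_class"]) - set(CHROM_CLASSES)
        if bad_class:
            raise GenotypeDataError(f"unknown chrom classes {sorted(bad_class)}")
        called = self.called
        over = called & (self.dosage > self.ploidy)
        if over.any() or (self.dosage < MISSING).any():
            i, j = np.argwhere(over | (self.dosage < MISSING))[0]
            raise GenotypeDataError(
                f"dosage out of [0, ploidy] at site {i} sample "
                f"{self.samples['sample_id'].iloc[j]}"
            )
        sexed = self.samples["sex"].to_numpy() != "unknown"
        needs_sex = self.sites["chrom_class"].isin(["X", "mito"]).to_numpy()
        if needs_sex.any() and not sexed.all():
            unk = self.samples.loc[~sexed, "sample_id"].tolist()
            raise GenotypeDataError(
                f"sex must be known for samples contributing X/mito sites: {unk}"
            )

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to a boolean or integer site index, preserving order."""
        return GenotypeMatrix(self.sites.loc[np.asarray(index)].copy()
                              if np.asarray(index).dtype == bool
                              else self.sites.iloc[index].copy(),
                              self.samples.copy(), self.dosage[index])


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sheet: pd.DataFrame,
             class_map: Mapping[str, str],
             male_het_x: str = "missing") -> GenotypeMatrix:
    """Load biallelic SNVs from a VCF into a GenotypeMatrix.

    Multi-allelic and non-SNV rows are dropped (with a logged count).  Male
    genotypes on X are coerced to ploidy 1; a heterozygous male X call is set
    missing under the default policy (``male_het_x='missing'``) or raises in
    strict mode (``'error'``).
    """
    import pysam

    if male_het_x not in ("missing", "error"):
        raise GenotypeDataError("male_het_x must be 'missing' or 'error'")
    sheet = validate_sample_sheet(sheet)
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    absent = [s for s in sheet["sample_id"] if s not in vcf_samples]
    if absent:
        raise GenotypeDataError(f"sheet samples missing from VCF: {absent}")
    sex = sheet.set_index("sample_id")["sex"]

    rows, dosages = [], []
    n_dropped = n_het_male_x = 0
    for rec in vf:
        if rec.chrom not in class_map:
            n_dropped += 1
            continue
        alts = rec.alts or ()
        if (len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1
                or alts[0] not in "ACGT" or rec.ref not in "ACGT"):
            n_dropped += 1
            continue
        cls = class_map[rec.chrom]
        row = np.full(len(sheet), MISSING, dtype=np.int16)
        for j, sid in enumerate(sheet["sample_id"]):
            gt = rec.samples[sid].get("GT", (None,))
            alleles = [a for a in gt if a is not None]
            if not alleles:
                continue
            hemizygous = (cls == "mito") or (cls == "X" and sex[sid] == "male")
            if hemizygous and len(set(alleles)) > 1:
                if male_het_x == "error":
                    raise GenotypeDataError(
                        f"heterozygous hemizygous call for {sid} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                n_het_male_x += 1
                continue
            if hemizygous:
                row[j] = alleles[0]
            elif len(alleles) == 2:
                row[j] = sum(alleles)
            # a lone called allele on a diploid site stays missing
        rows.append((rec.chrom, rec.pos, rec.ref, alts[0], cls))
        dosages.append(row)

    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic/non-SNV rows", n_dropped)
    if n_het_male_x:
        logger.warning("read_vcf: %d heterozygous hemizygous calls set missing",
                       n_het_male_x)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                        "chrom_class"])
    dosage = (np.array(dosages, dtype=np.int16)
              if dosages else np.empty((0, len(sheet)), dtype=np.int16))
    return GenotypeMatrix(sites, sheet, dosage)


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a GenotypeMatrix as VCF 4.2, haploid GT on male X and mito."""
    path = Path(path)
    lengths: dict[str, int] = dict(contig_lengths or {})
    for chrom, grp in gm.sites.groupby("chrom", sort=False):
        lengths.setdefault(chrom, int(grp["pos"].max()) + 1 if len(grp) else 1)
    ploidy = gm.ploidy
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=swampx\n")
        seen = []
        for chrom in gm.sites["chrom"]:
            if chrom not in seen:
                seen.append(chrom)
        for chrom in seen or lengths:
            fh.write(f"##contig=<ID={chrom},length={lengths[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples["sample_id"]) + "\n")
        for i, site in gm.sites.iterrows():
            gts = []
            for j in range(gm.n_samples):
                d, p = gm.dosage[i, j], ploidy[i, j]
                if d == MISSING:
                    gts.append("." if p == 1 else "./.")
                elif p == 1:
                    gts.append(str(d))
                else:
                    gts.append(f"{1 if d == 2 else 0}/{1 if d >= 1 else 0}")
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}"
                     f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def apply_region_mask(gm: GenotypeMatrix, mask: RegionMask,
                      mode: str = "exclude") -> GenotypeMatrix:
    """Drop (``exclude``) or keep only (``restrict``) sites inside the mask."""
    if mode not in ("exclude", "restrict"):
        raise GenotypeDataError("mode must be 'exclude' or 'restrict'")
    inside = mask.member_mask(gm.sites["chrom"].to_numpy(),
                              gm.sites["pos"].to_numpy())
    keep = ~inside if mode == "exclude" else inside
    return gm.take_sites(keep)


def filter_complete_cases(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only sites genotyped in every sample."""
    keep = gm.called.all(axis=1)
    if not keep.any():
        logger.warning("filter_complete_cases: no complete-case sites remain")
    return gm.take_sites(keep)


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

@dataclass
class AlleleCountTable:
    """Per-population derived/total allele copies at each site."""

    sites: pd.DataFrame
    populations: list[str]
    derived: np.ndarray   # (n_pops, n_sites)
    total: np.ndarray     # (n_pops, n_sites)

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.derived = np.asarray(self.derived)
        self.total = np.asarray(self.total)
        if (self.derived < 0).any() or (self.derived > self.total).any():
            raise GenotypeDataError("derived copies outside [0, total]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def index_of(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise GenotypeDataError(f"population {population!r} not in table") \
                from None

    def counts(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.index_of(population)
        return self.derived[i], self.total[i]

    def frequencies(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.derived / self.total, np.nan)

    def subset_sites(self, index: np.ndarray) -> "AlleleCountTable":
        index = np.asarray(index)
        sites = (self.sites.loc[index] if index.dtype == bool
                 else self.sites.iloc[index])
        return AlleleCountTable(sites.copy(), list(self.populations),
                                self.derived[:, index], self.total[:, index])

    def for_class(self, chrom_class: str) -> "AlleleCountTable":
        if chrom_class == "mito":
            raise GenotypeDataError(
                "f-statistics are not defined on mito sites in this package"
            )
        return self.subset_sites(
            (self.sites["chrom_class"] == chrom_class).to_numpy()
        )


def allele_counts_by_population(
    gm: GenotypeMatrix, populations: Sequence[str] | None = None
) -> AlleleCountTable:
    """Sum dosages and ploidies per population at every site.

    X-chromosome counts pool males (1 copy) and females (2 copies); a
    singleton population is legal (its sampled genotype stands in for the
    population allele frequency).
    """
    pops = list(populations) if populations is not None else \
        sorted(gm.samples["population"].unique())
    ploidy = gm.ploidy
    called = gm.called
    derived = np.zeros((len(pops), gm.n_sites), dtype=np.int64)
    total = np.zeros_like(derived)
    pop_col = gm.samples["population"].to_numpy()
    for k, pop in enumerate(pops):
        cols = np.flatnonzero(pop_col == pop)
        if cols.size == 0:
            raise GenotypeDataError(f"population {pop!r} has no samples")
        d = gm.dosage[:, cols]
        c = called[:, cols]
        derived[k] = np.where(c, d, 0).sum(axis=1)
        total[k] = np.where(c, ploidy[:, cols], 0).sum(axis=1)
    return AlleleCountTable(gm.sites.copy(), pops, derived, total)


def per_sample_heterozygosity(gm: GenotypeMatrix) -> pd.Series:
    """Heterozygous fraction per sample over called autosomal diploid sites.

    Matches the per-sample nucleotide diversity of a complete-case SNV panel:
    heterozygous sites divided by total genotyped sites.
    """
    auto = (gm.sites["chrom_class"] == "autosome").to_numpy()
    called = gm.called[auto]
    het = (gm.dosage[auto] == 1) & called
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        rate = np.where(n_called > 0, het.sum(axis=0) / n_called, np.nan)
    return pd.Series(rate, index=gm.samples["sample_id"], name="heterozygosity")


# ---------------------------------------------------------------------------
# jackknife blocks
# ---------------------------------------------------------------------------

@dataclass
class BlockPartition:
    """Site -> jackknife block assignment (−1 for sites outside the classes)."""

    block_ids: np.ndarray          # int per site, -1 = unassigned
    blocks: pd.DataFrame           # block_id, chrom, window_start, n_sites
    block_size: int

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)


def assign_blocks(sites: pd.DataFrame, block_size: int = 5_000_000,
                  classes: Iterable[str] | None = None) -> BlockPartition:
    """Partition sites into per-chromosome half-open windows of block_size bp.

    Windows are [k·B, (k+1)·B) on the 0-based position; empty windows are
    omitted.  The partition depends only on (chrom, pos), never on site order.
    """
    if block_size <= 0:
        raise GenotypeDataError("block_size must be positive")
    chrom = sites["chrom"].to_numpy()
    window = (sites["pos"].to_numpy() - 1) // block_size  # 0-based windows
    in_class = (np.ones(len(sites), dtype=bool) if classes is None
                else sites["chrom_class"].isin(list(classes)).to_numpy())
    keys = pd.DataFrame({"chrom": chrom, "window": window})
    keys_in = keys[in_class]
    uniq = (keys_in.drop_duplicates().sort_values(["chrom", "window"])
            .reset_index(drop=True))
    lookup = {(c, w): i for i, (c, w) in enumerate(zip(uniq["chrom"],
                                                       uniq["window"]))}
    ids = np.full(len(sites), -1, dtype=np.int64)
    for i in np.flatnonzero(in_class):
        ids[i] = lookup[(chrom[i], window[i])]
    counts = np.bincount(ids[ids >= 0], minlength=len(uniq))
    blocks = pd.DataFrame({
        "block_id": np.arange(len(uniq)),
        "chrom": uniq["chrom"],
        "window_start": uniq["window"] * block_size,
        "n_sites": counts,
    })
    return BlockPartition(ids, blocks, block_size)
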