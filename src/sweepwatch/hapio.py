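"""Phased-haplotype I/O and the in-memory haplotype matrix.

Reads phased biallelic SNPs from VCF into a chromosomes x sites allele
matrix, plus the sample metadata (TSV) and analysis windows (BED) that the
downstream statistics consume.

Coordinate conventions: ``VariantSite.pos`` and ``CoreVariant.pos`` are
1-based as in VCF; windows are 0-based half-open as in BED. Conversion
happens only at the window boundary (a site is inside a window iff
``start <= pos - 1 < end``).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

PHENOTYPES = ("non_melanistic", "melanistic")
INHERITANCE_MODES = ("recessive", "dominant")
_BASES = frozenset("ACGT")


class HapIOError(ValueError):
    """Base class for typed parse errors raised by this module."""


class VcfParseError(HapIOError):
    pass


class MetadataError(HapIOError):
    pass


class WindowError(HapIOError):
    pass


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: contig, 1-based position, REF/ALT, optional quality."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfParseError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise VcfParseError(
                f"ref and alt alleles identical ({self.ref_allele}) at "
                f"{self.chrom}:{self.pos}"
            )
        for allele in (self.ref_allele, self.alt_allele):
            if len(allele) != 1 or allele.upper() not in _BASES:
                raise VcfParseError(
                    f"non-SNP allele {allele!r} at {self.chrom}:{self.pos}"
                )
        if self.quality is not None and self.quality < 0:
            raise VcfParseError(f"negative quality at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class CoreVariant:
    """The candidate causal site from which all stratification originates.

    ``derived_allele_code`` is the allele code (0 = REF, 1 = ALT) of the
    putatively causal, derived allele; ``mode`` is the inheritance mode of
    the phenotype it produces.
    """

    chrom: str
    pos: int
    derived_allele_code: int
    mode: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.derived_allele_code not in (0, 1):
            raise ValueError("derived_allele_code must be 0 or 1")
        if self.mode not in INHERITANCE_MODES:
            raise ValueError(
                f"mode must be one of {INHERITANCE_MODES}, got {self.mode!r}"
            )

    @classmethod
    def from_string(cls, spec: str, name: str = "") -> "CoreVariant":
        """Parse ``chrom:pos:derived_allele_code:mode`` (CLI shorthand)."""
        parts = spec.split(":")
        if len(parts) != 4:
            raise ValueError(
                f"core variant spec must be chrom:pos:allele:mode, got {spec!r}"
            )
        chrom, pos, code, mode = parts
        return cls(chrom, int(pos), int(code), mode, name=name)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    species: str
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise MetadataError(
                f"unknown phenotype {self.phenotype!r} for sample "
                f"{self.sample_id}; accepted tokens: {', '.join(PHENOTYPES)}"
            )


@dataclass(frozen=True)
class Window:
    """0-based half-open genomic interval with a unique label."""

    label: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise WindowError(
                f"window {self.label}: end ({self.end}) must exceed start "
                f"({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class WindowSet:
    windows: tuple[Window, ...]

    def __post_init__(self) -> None:
        labels = [w.label for w in self.windows]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise WindowError(f"duplicate window labels: {', '.join(dup)}")

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)

    def __getitem__(self, i) -> Window:
        return self.windows[i]


class HaplotypeMatrix:
    """Phased chromosomes x biallelic sites, allele codes in {0, 1}.

    Rows are individual chromosomes (two per sample for VCF input, ids
    ``<sample>_A`` / ``<sample>_B``); columns are sites sorted by
    (contig, position), strictly increasing within a contig.
    """

    def __init__(
        self,
        sites: Sequence[VariantSite],
        data: np.ndarray,
        chrom_ids: Sequence[str],
    ) -> None:
        data = np.asarray(data, dtype=np.uint8)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (chromosomes x sites)")
        if data.shape != (len(chrom_ids), len(sites)):
            raise ValueError(
                f"data shape {data.shape} does not match "
                f"{len(chrom_ids)} chromosomes x {len(sites)} sites"
            )
        if data.size and data.max() > 1:
            raise ValueError("allele codes must be 0 or 1")
        prev: tuple[str, int] | None = None
        seen_contigs: set[str] = set()
        for s in sites:
            if prev is not None and s.chrom == prev[0] and s.pos <= prev[1]:
                raise VcfParseError(
                    f"sites not strictly increasing at {s.chrom}:{s.pos}"
                )
            if prev is not None and s.chrom != prev[0] and s.chrom in seen_contigs:
                raise VcfParseError(f"contig {s.chrom} appears in two blocks")
            seen_contigs.add(s.chrom)
            prev = (s.chrom, s.pos)
        if len(set(chrom_ids)) != len(chrom_ids):
            raise ValueError("chromosome ids must be unique")
        self.sites: tuple[VariantSite, ...] = tuple(sites)
        self.data = data
        self.chrom_ids: tuple[str, ...] = tuple(chrom_ids)
        self._index = {(s.chrom, s.pos): j for j, s in enumerate(self.sites)}

    # ---- basic shape ----------------------------------------------------
    @property
    def n_chrom(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def site_chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    # ---- lookup ---------------------------------------------------------
    def site_index(self, chrom: str, pos: int) -> int:
        try:
            return self._index[(chrom, pos)]
        except KeyError:
            raise KeyError(f"no site at {chrom}:{pos} in matrix") from None

    def window_site_mask(self, window: Window) -> np.ndarray:
        pos = self.positions
        return (
            (self.site_chroms == window.chrom)
            & (pos - 1 >= window.start)
            & (pos - 1 < window.end)
        )

    def sample_of(self, chrom_id: str) -> str:
        """Sample id for a ``<sample>_<A|B>`` chromosome id."""
        stem, _, suffix = chrom_id.rpartition("_")
        if suffix not in ("A", "B") or not stem:
            raise ValueError(f"chromosome id {chrom_id!r} is not <sample>_<A|B>")
        return stem

    @property
    def sample_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for cid in self.chrom_ids:
            seen.setdefault(self.sample_of(cid), None)
        return tuple(seen)

    def rows_for_samples(self, samples: Iterable[str]) -> np.ndarray:
        wanted = set(samples)
        return np.array(
            [i for i, cid in enumerate(self.chrom_ids)
             if self.sample_of(cid) in wanted],
            dtype=np.intp,
        )

    def subset_rows(self, rows: Sequence[int]) -> "HaplotypeMatrix":
        rows = np.asarray(rows, dtype=np.intp)
        return HaplotypeMatrix(
            self.sites, self.data[rows], [self.chrom_ids[i] for i in rows]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.chrom_ids == other.chrom_ids
            and np.array_equal(self.data, other.data)
        )

    def __repr__(self) -> str:
        return (
            f"HaplotypeMatrix({self.n_chrom} chromosomes x "
            f"{self.n_sites} sites)"
        )


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

def _parse_region(region: str) -> tuple[str, int | None, int | None]:
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    start_s, _, end_s = span.partition("-")
    return chrom, int(start_s), int(end_s)


def read_phased_vcf(path: str | Path, region: str | None = None) -> HaplotypeMatrix:
    """Load phased, fully-called, biallelic SNP records into a matrix.

    ``region`` is ``chrom`` or ``chrom:start-end`` (1-based inclusive, as in
    samtools). Any missing or unphased genotype, multiallelic record or
    non-SNP allele is a hard :class:`VcfParseError` naming the record: the
    pipeline expects phasing/imputation to have been done upstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF file not found: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: VCF contains no samples")
    want = _parse_region(region) if region is not None else None

    sites: list[VariantSite] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        where = f"{rec.CHROM}:{rec.POS}"
        if want is not None:
            chrom, lo, hi = want
            if rec.CHROM != chrom:
                continue
            if lo is not None and not (lo <= rec.POS <= hi):
                continue
        if len(rec.ALT) != 1:
            raise VcfParseError(
                f"multiallelic record at {where} (ALT={','.join(rec.ALT) or '.'})"
            )
        site = VariantSite(
            rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
            quality=None if rec.QUAL is None else float(rec.QUAL),
        )
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for i, gt in enumerate(rec.genotypes):
            alleles, phased = gt[:-1], gt[-1]
            if len(alleles) != 2:
                raise VcfParseError(
                    f"non-diploid genotype for sample {samples[i]} at {where}"
                )
            a, b = alleles
            if a < 0 or b < 0:
                raise VcfParseError(
                    f"missing genotype for sample {samples[i]} at {where}"
                )
            if not phased:
                raise VcfParseError(
                    f"unphased genotype for sample {samples[i]} at {where}"
                )
            col[2 * i] = a
            col[2 * i + 1] = b
        sites.append(site)
        columns.append(col)
    vcf.close()

    data = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    )
    chrom_ids = [f"{s}_{h}" for s in samples for h in ("A", "B")]
    return HaplotypeMatrix(sites, data, chrom_ids)


def write_phased_vcf(path: str | Path, hap: HaplotypeMatrix) -> None:
    """Write the matrix as a minimal phased VCF 4.2 (gzip if path ends .gz)."""
    if hap.n_chrom % 2:
        raise ValueError("cannot write VCF: odd number of chromosomes")
    samples = []
    for i in range(0, hap.n_chrom, 2):
        a, b = hap.chrom_ids[i], hap.chrom_ids[i + 1]
        sa, sb = hap.sample_of(a), hap.sample_of(b)
        if sa != sb or not a.endswith("_A") or not b.endswith("_B"):
            raise ValueError(
                f"cannot pair chromosome ids {a!r}, {b!r} into one sample"
            )
        samples.append(sa)

    lines = ["##fileformat=VCFv4.2", "##source=sweepwatch"]
    for contig in dict.fromkeys(s.chrom for s in hap.sites):
        lines.append(f"##contig=<ID={contig}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
    )
    for j, site in enumerate(hap.sites):
        qual = "." if site.quality is None else f"{site.quality:g}"
        gts = "\t".join(
            f"{hap.data[2 * i, j]}|{hap.data[2 * i + 1, j]}"
            for i in range(len(samples))
        )
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t"
            f"{site.alt_allele}\t{qual}\tPASS\t.\tGT\t{gts}"
        )
    text = "\n".join(lines) + "\n"
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata TSV (columns sample_id, species, phenotype)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    with _open_text(path) as fh:
        try:
            df = pd.read_csv(fh, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            raise MetadataError(f"{path}: no samples (empty file)") from None
    required = {"sample_id", "species", "phenotype"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(
            f"{path}: missing required columns: {', '.join(sorted(missing))}"
        )
    if df.empty:
        raise MetadataError(f"{path}: no samples")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise MetadataError(
            f"{path}: duplicate sample ids: {', '.join(sorted(set(dup)))}"
        )
    return [
        SampleMeta(r.sample_id, r.species, r.phenotype)
        for r in df.itertuples(index=False)
    ]


def read_windows(path: str | Path) -> WindowSet:
    """Read analysis windows from BED3+name (0-based half-open)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"window BED file not found: {path}")
    windows: list[Window] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise WindowError(
                    f"{path}:{lineno}: expected BED3+name (4 columns), "
                    f"got {len(fields)}"
                )
            chrom, start, end, label = fields[:4]
            windows.append(Window(label, chrom, int(start), int(end)))
    windows.sort(key=lambda w: (w.chrom, w.start, w.end))
    ws = WindowSet(tuple(windows))
    for a, b in zip(windows, windows[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            warnings.warn(
                f"windows {a.label} and {b.label} overlap on {a.chrom}",
                stacklevel=2,
            )
    return ws
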