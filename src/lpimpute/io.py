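"""Readers and writers for the formats the pipeline touches.

The pipeline's native site universe is a list of biallelic SNPs
(:class:`SiteList`) and its native read evidence is a per-site pileup
(:class:`PileupSet` / :class:`SitePileup`).  Supported on-disk formats:

* samtools-mpileup text (read; read-bases string fully parsed),
* a simplified pileup TSV dialect (read/write) that, unlike mpileup text,
  preserves duplicate-read tallies,
* VCF 4.2 (read via cyvcf2, write via pysam) for truth/imputed genotypes
  (GT, optional GP, ``LOWCONF`` FILTER) and for haplotype panels,
* BED-like site lists (read; 0-based half-open converted at the boundary).

Positions are 1-based everywhere internally (VCF/mpileup native).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lpimpute")

_BASES = frozenset("ACGT")

#: allele codes used in per-read records
REF, ALT, OTHER = 0, 1, 2

PILEUP_TSV_COLUMNS = [
    "CHROM", "POS", "REF", "ALT",
    "REF_COUNT", "ALT_COUNT", "OTHER_COUNT", "RAW_DEPTH", "DUP_COUNT",
]


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# site universe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteList:
    """Ordered universe of biallelic autosomal SNP sites.

    Parameters
    ----------
    chrom, pos, ref, alt
        Parallel arrays; ``pos`` is 1-based and strictly increasing within
        each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "pos", np.asarray(self.pos, dtype=np.int64))
        object.__setattr__(self, "ref", np.asarray(self.ref, dtype=object))
        object.__setattr__(self, "alt", np.asarray(self.alt, dtype=object))
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n):
            raise ValueError("SiteList arrays must have equal length")
        for r, a in zip(self.ref, self.alt):
            if r not in _BASES or a not in _BASES or r == a:
                raise ValueError(f"not a biallelic SNP: ref={r!r} alt={a!r}")
        # sorted & unique within chromosome
        same = self.chrom[1:] == self.chrom[:-1] if n > 1 else np.array([], bool)
        if np.any(same & (np.diff(self.pos) <= 0)):
            raise ValueError("positions must be strictly increasing within a chromosome")

    def __len__(self) -> int:
        return len(self.pos)

    def keys(self) -> list[tuple[str, int]]:
        return list(zip(self.chrom, self.pos))

    def index(self) -> dict[tuple[str, int], int]:
        return {k: i for i, k in enumerate(self.keys())}

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, int, str, str]]) -> "SiteList":
        if not records:
            raise ValueError("empty site list")
        c, p, r, a = zip(*records)
        return cls(np.array(c, object), np.array(p), np.array(r, object), np.array(a, object))


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SitePileup:
    """Filtered read evidence at one panel site.

    ``ref_count``/``alt_count``/``other_count`` tally unique (non-duplicate)
    reads passing the base-quality filter applied by the producer;
    ``raw_depth`` counts all raw reads including duplicates and
    ``dup_count`` the duplicates among them.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int = 0
    alt_count: int = 0
    other_count: int = 0
    raw_depth: int = 0
    dup_count: int = 0
    reads: "ReadBundle | None" = None

    def __post_init__(self) -> None:
        for name in ("ref_count", "alt_count", "other_count", "raw_depth", "dup_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.ref_count + self.alt_count + self.other_count > self.raw_depth:
            raise ValueError("filtered counts exceed raw depth")


@dataclass(frozen=True)
class ReadBundle:
    """Per-read detail at one site (simulation / mpileup round-trips only)."""

    allele: np.ndarray   # codes REF/ALT/OTHER
    phred: np.ndarray    # int Phred base qualities
    is_dup: np.ndarray   # bool

    def __len__(self) -> int:
        return len(self.allele)


@dataclass(frozen=True)
class RawReadTally:
    """Raw/duplicate read totals for one sample (pre any filtering)."""

    total_reads: int
    duplicate_reads: int
    total_bases: int | None = None  # real-data mode: sequenced bases

    def __post_init__(self) -> None:
        if self.total_reads < 0 or not 0 <= self.duplicate_reads <= self.total_reads:
            raise ValueError("inconsistent read tally")


class PileupSet:
    """Array-backed pileup over a :class:`SiteList` (one row per panel site).

    Zero-depth sites are represented explicitly so coverage denominators are
    correct.  ``min_base_quality`` records the Phred threshold the stored
    counts were filtered at.  When per-read detail is retained (`reads`),
    counts can be re-derived at other thresholds.
    """

    def __init__(
        self,
        sites: SiteList,
        ref_count: np.ndarray,
        alt_count: np.ndarray,
        other_count: np.ndarray,
        raw_depth: np.ndarray,
        dup_count: np.ndarray,
        *,
        min_base_quality: int = 13,
        reads: list[ReadBundle] | None = None,
    ) -> None:
        n = len(sites)
        self.sites = sites
        self.ref_count = np.asarray(ref_count, np.int64)
        self.alt_count = np.asarray(alt_count, np.int64)
        self.other_count = np.asarray(other_count, np.int64)
        self.raw_depth = np.asarray(raw_depth, np.int64)
        self.dup_count = np.asarray(dup_count, np.int64)
        self.min_base_quality = int(min_base_quality)
        self.reads = reads
        for arr in (self.ref_count, self.alt_count, self.other_count,
                    self.raw_depth, self.dup_count):
            if arr.shape != (n,):
                raise ValueError("pileup arrays must match the site list length")
            if np.any(arr < 0):
                raise ValueError("negative pileup counts")
        if np.any(self.ref_count + self.alt_count + self.other_count
                  > self.raw_depth):
            raise ValueError("filtered counts exceed raw depth")
        if reads is not None and len(reads) != n:
            raise ValueError("per-read detail must match the site list length")

    def __len__(self) -> int:
        return len(self.sites)

    def __getitem__(self, i: int) -> SitePileup:
        s = self.sites
        return SitePileup(
            s.chrom[i], int(s.pos[i]), s.ref[i], s.alt[i],
            int(self.ref_count[i]), int(self.alt_count[i]),
            int(self.other_count[i]), int(self.raw_depth[i]),
            int(self.dup_count[i]),
            None if self.reads is None else self.reads[i],
        )

    def __iter__(self) -> Iterator[SitePileup]:
        return (self[i] for i in range(len(self)))

    @property
    def passing_depth(self) -> np.ndarray:
        """Unique reads passing the base-quality filter, per site."""
        return self.ref_count + self.alt_count + self.other_count

    @property
    def unique_depth(self) -> np.ndarray:
        return self.raw_depth - self.dup_count

    def tally(self) -> RawReadTally:
        return RawReadTally(int(self.raw_depth.sum()), int(self.dup_count.sum()))

    def counts_at_threshold(self, min_base_quality: int,
                            exclude_duplicates: bool = True) -> np.ndarray:
        """Passing read count per site at an arbitrary Phred threshold.

        Requires per-read detail unless the requested threshold equals the
        one the stored counts were produced with.
        """
        if self.reads is None:
            if min_base_quality != self.min_base_quality:
                raise ValueError(
                    f"counts were filtered at BQ>={self.min_base_quality} and no "
                    "per-read detail is available to re-filter at "
                    f"BQ>={min_base_quality}")
            if not exclude_duplicates:
                # aggregated duplicates carry no independent qualities
                return self.raw_depth.copy()
            return self.passing_depth
        out = np.zeros(len(self), np.int64)
        for i, rb in enumerate(self.reads):
            keep = rb.phred >= min_base_quality
            if exclude_duplicates:
                keep &= ~rb.is_dup
            out[i] = int(keep.sum())
        return out

    @classmethod
    def from_records(cls, records: Sequence[SitePileup],
                     min_base_quality: int = 13) -> "PileupSet":
        sites = SiteList.from_records([(p.chrom, p.pos, p.ref, p.alt) for p in records])
        reads = [p.reads for p in records]
        has_reads = all(r is not None for r in reads)
        return cls(
            sites,
            np.array([p.ref_count for p in records]),
            np.array([p.alt_count for p in records]),
            np.array([p.other_count for p in records]),
            np.array([p.raw_depth for p in records]),
            np.array([p.dup_count for p in records]),
            min_base_quality=min_base_quality,
            reads=reads if has_reads else None,
        )


def as_pileup_set(pileups: "PileupSet | Sequence[SitePileup]",
                  min_base_quality: int = 13) -> PileupSet:
    if isinstance(pileups, PileupSet):
        return pileups
    return PileupSet.from_records(list(pileups), min_base_quality=min_base_quality)


# ---------------------------------------------------------------------------
# pileup TSV dialect
# ---------------------------------------------------------------------------

def write_pileup_tsv(pileups: PileupSet, path: str) -> None:
    """Write the simplified pileup TSV dialect (native interchange).

    Unlike mpileup text this preserves raw-depth and duplicate tallies.
    """
    df = pd.DataFrame({
        "CHROM": pileups.sites.chrom, "POS": pileups.sites.pos,
        "REF": pileups.sites.ref, "ALT": pileups.sites.alt,
        "REF_COUNT": pileups.ref_count, "ALT_COUNT": pileups.alt_count,
        "OTHER_COUNT": pileups.other_count, "RAW_DEPTH": pileups.raw_depth,
        "DUP_COUNT": pileups.dup_count,
    })
    df.to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path: str, min_base_quality: int = 13) -> PileupSet:
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in PILEUP_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"pileup TSV missing columns: {missing}")
    sites = SiteList(df["CHROM"].to_numpy(object), df["POS"].to_numpy(),
                     df["REF"].to_numpy(object), df["ALT"].to_numpy(object))
    return PileupSet(
        sites, df["REF_COUNT"].to_numpy(), df["ALT_COUNT"].to_numpy(),
        df["OTHER_COUNT"].to_numpy(), df["RAW_DEPTH"].to_numpy(),
        df["DUP_COUNT"].to_numpy(), min_base_quality=min_base_quality)


# ---------------------------------------------------------------------------
# samtools-mpileup text
# ---------------------------------------------------------------------------

def _parse_bases(bases: str, quals: str, ref: str, alt: str,
                 min_bq: int, lineno: int) -> tuple[int, int, int]:
    """Parse one mpileup read-bases string into (ref, alt, other) counts.

    Handles ``^``+mapping-quality, ``$``, ``+n``/``-n`` indel runs, and the
    quality-consuming placeholders ``*``, ``>``, ``<``, ``N``.
    """
    ref_n = alt_n = other_n = 0
    alt_u = alt.upper()
    qi = 0
    i = 0
    L = len(bases)
    while i < L:
        c = bases[i]
        if c == "^":          # read start; next char is mapping quality
            i += 2
            continue
        if c == "$":          # read end marker
            i += 1
            continue
        if c in "+-":         # indel: +<n><seq> / -<n><seq>
            i += 1
            num = ""
            while i < L and bases[i].isdigit():
                num += bases[i]
                i += 1
            if not num:
                raise ParseError(f"line {lineno}: malformed indel run")
            i += int(num)
            continue
        # every remaining symbol consumes one quality character
        if qi >= len(quals):
            raise ParseError(f"line {lineno}: base/quality length mismatch")
        q = ord(quals[qi]) - 33
        qi += 1
        i += 1
        if c in "*><":        # deletion placeholder / reference skip
            continue
        if q < min_bq:
            continue
        if c in ".,":
            ref_n += 1
        elif c.upper() == alt_u:
            alt_n += 1
        elif c.upper() in "ACGTN":
            other_n += 1
        else:
            raise ParseError(f"line {lineno}: unexpected pileup symbol {c!r}")
    if qi != len(quals):
        raise ParseError(f"line {lineno}: base/quality length mismatch")
    return ref_n, alt_n, other_n


def read_mpileup(path: str, sites: SiteList, min_base_quality: int = 13,
                 strict: bool = False) -> PileupSet:
    """Read samtools-mpileup text restricted to a panel site list.

    Duplicates are assumed to have been excluded upstream (``--ff DUP``), so
    ``dup_count`` is 0 and ``raw_depth`` equals the unique-read depth.  Sites
    absent from the file yield zero-count rows so the fraction-covered
    denominator is the full panel.
    """
    n = len(sites)
    idx = sites.index()
    ref_c = np.zeros(n, np.int64)
    alt_c = np.zeros(n, np.int64)
    oth_c = np.zeros(n, np.int64)
    depth = np.zeros(n, np.int64)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"line {lineno}: expected >=6 mpileup columns")
            chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
            key = (chrom, int(pos_s))
            if key not in idx:
                msg = f"line {lineno}: site {key} not in panel site list"
                if strict:
                    raise ParseError(msg)
                warnings.warn(msg)
                continue
            j = idx[key]
            if ref.upper() != sites.ref[j]:
                warnings.warn(f"line {lineno}: REF {ref!r} differs from panel "
                              f"ref {sites.ref[j]!r}")
            r, a, o = _parse_bases(bases, quals, sites.ref[j], sites.alt[j],
                                   min_base_quality, lineno)
            ref_c[j], alt_c[j], oth_c[j] = r, a, o
            depth[j] = int(depth_s)
    depth = np.maximum(depth, ref_c + alt_c + oth_c)
    return PileupSet(sites, ref_c, alt_c, oth_c, depth, np.zeros(n, np.int64),
                     min_base_quality=min_base_quality)


def write_mpileup(pileups: PileupSet, path: str) -> None:
    """Write mpileup text from per-read detail, excluding duplicates.

    Mirrors a ``samtools mpileup --ff DUP`` product: duplicate reads are
    dropped on write, so their tallies are not recoverable from this format.
    """
    if pileups.reads is None:
        raise ValueError("mpileup output requires per-read detail (keep_reads=True)")
    code_to_char = {REF: ".", ALT: None, OTHER: "N"}
    with open(path, "w") as fh:
        for i in range(len(pileups)):
            rb = pileups.reads[i]
            keep = ~rb.is_dup
            if not np.any(keep):
                continue
            alt = pileups.sites.alt[i]
            chars = []
            quals = []
            for code, q in zip(rb.allele[keep], rb.phred[keep]):
                ch = code_to_char[int(code)]
                chars.append(alt if ch is None else ch)
                quals.append(chr(int(q) + 33))
            fh.write("\t".join([
                str(pileups.sites.chrom[i]), str(int(pileups.sites.pos[i])),
                pileups.sites.ref[i], str(len(chars)),
                "".join(chars), "".join(quals),
            ]) + "\n")


# ---------------------------------------------------------------------------
# BED-like sites
# ---------------------------------------------------------------------------

def bed_interval_to_pos(start: int, end: int) -> int:
    """Convert a 0-based half-open single-base BED interval to a 1-based position."""
    if end != start + 1:
        raise ValueError(f"BED interval [{start},{end}) is not a single base")
    return start + 1


def read_bed_sites(path: str) -> SiteList:
    """Read a BED-like sites file: CHROM, START, END, REF, ALT (tab-separated)."""
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ParseError(f"line {lineno}: need CHROM START END REF ALT")
            recs.append((f[0], bed_interval_to_pos(int(f[1]), int(f[2])),
                         f[3].upper(), f[4].upper()))
    return SiteList.from_records(recs)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _vcf_header(sites: SiteList, sample_names: Sequence[str],
                with_gp: bool, with_af: bool):
    import pysam

    header = pysam.VariantHeader()
    seen = []
    for c in sites.chrom:
        if c not in seen:
            seen.append(c)
    for c in seen:
        maxpos = int(sites.pos[sites.chrom == c].max())
        header.contigs.add(str(c), length=maxpos + 1000)
    if with_af:
        header.add_meta("INFO", items=[
            ("ID", "AF"), ("Number", "A"), ("Type", "Float"),
            ("Description", "Alternate allele frequency")])
    header.add_meta("FORMAT", items=[
        ("ID", "GT"), ("Number", "1"), ("Type", "String"),
        ("Description", "Genotype")])
    if with_gp:
        header.add_meta("FORMAT", items=[
            ("ID", "GP"), ("Number", "G"), ("Type", "Float"),
            ("Description", "Genotype posterior probabilities")])
    header.add_meta("FILTER", items=[
        ("ID", "LOWCONF"),
        ("Description", "No genotype posterior greater than the confidence threshold")])
    for s in sample_names:
        header.add_sample(str(s))
    return header


_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def write_vcf(path: str, sites: SiteList, calls: np.ndarray | None = None,
              posteriors: np.ndarray | None = None,
              low_confidence: np.ndarray | None = None,
              sample: str = "SAMPLE", af: np.ndarray | None = None) -> None:
    """Write a single-sample VCF 4.2 with GT (and GP/FILTER where given).

    ``calls`` holds genotypes in {0,1,2} (-1 → missing ``./.``).  When
    ``posteriors`` (n_sites × 3) is given, GP is emitted rounded to 6 decimal
    places and sites flagged ``low_confidence`` get FILTER ``LOWCONF``.
    """
    import pysam

    n = len(sites)
    if calls is None:
        if posteriors is None:
            calls = np.full(n, -1)
        else:
            calls = np.argmax(posteriors, axis=1)
    calls = np.asarray(calls)
    header = _vcf_header(sites, [sample], posteriors is not None, af is not None)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(n):
            rec = out.new_record(
                contig=str(sites.chrom[j]), start=int(sites.pos[j]) - 1,
                alleles=(sites.ref[j], sites.alt[j]))
            if af is not None:
                rec.info["AF"] = round(float(af[j]), 6)
            if low_confidence is not None and bool(low_confidence[j]):
                rec.filter.add("LOWCONF")
            else:
                rec.filter.add("PASS")
            g = int(calls[j])
            rec.samples[sample]["GT"] = _GT.get(g, (None, None))
            if posteriors is not None:
                rec.samples[sample]["GP"] = tuple(
                    round(float(x), 6) for x in posteriors[j])
            out.write(rec)


def write_panel_vcf(path: str, panel, samples_prefix: str = "P") -> None:
    """Write a haplotype panel as a phased multi-sample VCF with INFO/AF."""
    import pysam

    sites = panel.sites
    H, M = panel.alleles.shape
    names = [f"{samples_prefix}{i}" for i in range(H // 2)]
    header = _vcf_header(sites, names, with_gp=False, with_af=True)
    af = panel.af
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(M):
            rec = out.new_record(
                contig=str(sites.chrom[j]), start=int(sites.pos[j]) - 1,
                alleles=(sites.ref[j], sites.alt[j]))
            rec.info["AF"] = round(float(af[j]), 6)
            rec.filter.add("PASS")
            for s, name in enumerate(names):
                rec.samples[name]["GT"] = (int(panel.alleles[2 * s, j]),
                                           int(panel.alleles[2 * s + 1, j]))
                rec.samples[name].phased = True
            out.write(rec)


def read_vcf_genotypes(path: str, sites: SiteList, honor_filter: bool = True,
                       sample: int = 0) -> tuple[np.ndarray, np.ndarray | None]:
    """Read per-site genotype calls (and GP when present) from a VCF.

    Returns ``calls`` in {0,1,2} with -1 for sites that are missing, ``./.``,
    or FILTER-failed (when ``honor_filter``), aligned to ``sites``; and the
    GP matrix (n_sites × 3, NaN rows where absent) or None if the VCF has no
    GP field.
    """
    from cyvcf2 import VCF

    n = len(sites)
    idx = sites.index()
    calls = np.full(n, -1, np.int64)
    gp = None
    mismatches = []
    vcf = VCF(path)
    has_gp = any(f == "GP" for f in _format_ids(vcf))
    if has_gp:
        gp = np.full((n, 3), np.nan)
    for v in vcf:
        key = (v.CHROM, v.POS)
        if key not in idx:
            continue
        j = idx[key]
        alts = v.ALT
        if v.REF != sites.ref[j] or not alts or alts[0] != sites.alt[j]:
            mismatches.append(f"{v.CHROM}:{v.POS} {v.REF}>{','.join(alts or ['.'])}")
            continue
        if honor_filter and v.FILTER is not None:  # None means PASS/'.'
            continue
        g = v.genotypes[sample]
        a, b = g[0], g[1]
        if a < 0 or b < 0:
            continue
        calls[j] = int(a) + int(b)
        if gp is not None:
            arr = v.format("GP")
            if arr is not None:
                gp[j] = arr[sample][:3]
    vcf.close()
    if mismatches:
        raise ParseError("site/allele mismatch vs site list: " + "; ".join(mismatches))
    return calls, gp


def _format_ids(vcf) -> list[str]:
    ids = []
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            ids.append(line.split("ID=")[1].split(",")[0])
    return ids


def read_sites_vcf(path: str) -> tuple[SiteList, np.ndarray]:
    """Read a sites-defining VCF (e.g. a panel VCF); returns sites and INFO/AF.

    AF falls back to the sample-genotype allele frequency when INFO/AF is
    absent, and NaN when neither is available.
    """
    from cyvcf2 import VCF

    recs = []
    afs = []
    for v in VCF(path):
        if not v.ALT or len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # biallelic SNPs only
        recs.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        af = v.INFO.get("AF")
        if af is None:
            af = v.aaf if v.num_called else np.nan
        afs.append(float(af))
    return SiteList.from_records(recs), np.array(afs)


def read_panel_vcf(path: str):
    """Read a phased multi-sample VCF into a :class:`~lpimpute.synth.HaplotypePanel`."""
    from cyvcf2 import VCF

    from .synth import HaplotypePanel

    recs = []
    cols = []
    for v in VCF(path):
        if not v.ALT or len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue
        recs.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        col = []
        for g in v.genotypes:
            if g[0] < 0 or g[1] < 0:
                raise ParseError(f"panel VCF has missing genotype at {v.CHROM}:{v.POS}")
            col.extend([int(g[0]), int(g[1])])
        cols.append(col)
    sites = SiteList.from_records(recs)
    alleles = np.array(cols, np.uint8).T
    return HaplotypePanel(sites=sites, alleles=alleles,
                          genetic_dist=np.ones(len(sites) - 1))
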