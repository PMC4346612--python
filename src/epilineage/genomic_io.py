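"""Genomic file formats, gene models and interval primitives.

Internal coordinates are 0-based half-open throughout; GTF I/O converts
from/to the format's 1-based closed convention. Chromosome names are
normalized by stripping any ``chr`` prefix on read; writers emit the
stripped (Ensembl-style) names.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class GtfParseError(ValueError):
    pass


class CoverageFormatError(ValueError):
    pass


def normalize_chrom(name: str) -> str:
    """Strip a UCSC-style ``chr`` prefix so both dialects compare equal."""
    return name[3:] if name.startswith("chr") else name


def _open_text(path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


@dataclass(frozen=True)
class GenomeInterval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) pairs as a sorted disjoint list."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class GeneModel:
    """A gene's merged-exon structure: the coordinate frame for quantification.

    ``merged_exons`` is the interval union of all annotated transcript exons;
    ``introns`` exactly tile the gaps between consecutive merged exons. The
    TSS is the strand-aware 5' end of the merged model.
    """

    gene_id: str
    chrom: str
    strand: str
    biotype: str  # "protein_coding" or "noncoding"
    merged_exons: list[tuple[int, int]]
    introns: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.merged_exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for (s1, e1), (s2, e2) in zip(self.merged_exons, self.merged_exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError(f"gene {self.gene_id}: exons not sorted/disjoint")
        if not self.introns:
            self.introns = [
                (e1, s2) for (_, e1), (s2, _) in zip(self.merged_exons, self.merged_exons[1:])
            ]

    @classmethod
    def from_exons(cls, gene_id, chrom, strand, biotype, exons, cds=()):
        return cls(gene_id, chrom, strand, biotype, merge_intervals(exons),
                   cds=merge_intervals(cds) if cds else [])

    @property
    def start(self) -> int:
        return self.merged_exons[0][0]

    @property
    def end(self) -> int:
        return self.merged_exons[-1][1]

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (0-based exclusive end for minus-strand genes)."""
        return self.start if self.strand == "+" else self.end

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.merged_exons)

    @property
    def n_exons(self) -> int:
        return len(self.merged_exons)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_CODING_BIOTYPES = {"protein_coding"}


def read_gtf(path) -> dict[str, GeneModel]:
    """Read an Ensembl-dialect GTF into GeneModels keyed by gene_id.

    Exons of all transcripts of a gene are merged into an interval union;
    introns are the gaps within the gene span. GTF 1-based closed coordinates
    are converted to 0-based half-open. Genes with zero exon records are
    skipped with a warning; a malformed line raises GtfParseError naming the
    line number. Genes whose exons fall on more than one chromosome or strand
    are rejected.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # gene_id -> (chrom, strand, biotype)
    seen_genes: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise GtfParseError(f"line {lineno}: invalid coordinate range {start1}-{end1}")
            attrd = dict(_ATTR_RE.findall(attrs))
            gene_id = attrd.get("gene_id")
            if gene_id is None:
                raise GtfParseError(f"line {lineno}: missing gene_id attribute")
            chrom = normalize_chrom(chrom)
            biotype = attrd.get("gene_biotype", attrd.get("gene_type", "protein_coding"))
            biotype = "protein_coding" if biotype in _CODING_BIOTYPES else "noncoding"
            if gene_id not in meta:
                meta[gene_id] = (chrom, strand, biotype)
                seen_genes.append(gene_id)
            else:
                c0, s0, _ = meta[gene_id]
                if feature in ("exon", "CDS") and (c0 != chrom or s0 != strand):
                    raise GtfParseError(
                        f"line {lineno}: gene {gene_id} spans multiple chromosomes/strands")
            iv = (start1 - 1, end1)  # to 0-based half-open
            if feature == "exon":
                exons.setdefault(gene_id, []).append(iv)
            elif feature == "CDS":
                cds.setdefault(gene_id, []).append(iv)
    genes: dict[str, GeneModel] = {}
    for gid in seen_genes:
        chrom, strand, biotype = meta[gid]
        if gid not in exons:
            log.warning("gene %s has zero exon records; skipped", gid)
            continue
        if strand not in ("+", "-"):
            log.warning("gene %s has strand %r; skipped", gid, strand)
            continue
        genes[gid] = GeneModel.from_exons(gid, chrom, strand, biotype,
                                          exons[gid], cds.get(gid, ()))
    return genes


def write_gtf(genes: dict[str, GeneModel] | Iterable[GeneModel], path) -> None:
    """Write merged-exon gene models as a minimal GTF (one transcript per gene)."""
    if isinstance(genes, dict):
        genes = genes.values()
    rows = []
    for g in genes:
        bt = "protein_coding" if g.biotype == "protein_coding" else "lincRNA"
        attr = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; gene_biotype "{bt}";'
        for s, e in g.merged_exons:
            rows.append((g.chrom, s, e, g.strand, attr, "exon"))
        for s, e in g.cds:
            rows.append((g.chrom, s, e, g.strand, attr, "CDS"))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "wt") as fh:
        for chrom, s, e, strand, attr, feat in rows:
            fh.write(f"{chrom}\tepilineage\t{feat}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr}\n")


@dataclass
class CoverageTrack:
    """Per-base read depth for one sample/assay, as per-chromosome arrays."""

    data: dict[str, np.ndarray]
    assay: str = "rnaseq"
    library_total: float | None = None

    def chrom_length(self, chrom: str) -> int:
        return len(self.data.get(chrom, ()))

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth over [start, end); positions beyond the array are zero."""
        arr = self.data.get(chrom)
        if arr is None:
            return np.zeros(end - start)
        out = np.zeros(end - start)
        hi = min(end, len(arr))
        if hi > start:
            out[: hi - start] = arr[start:hi]
        return out

    def sum(self, chrom: str, start: int, end: int) -> float:
        arr = self.data.get(chrom)
        if arr is None:
            return 0.0
        return float(arr[start:min(end, len(arr))].sum())

    def breadth(self, chrom: str, start: int, end: int) -> float:
        """Fraction of bases in [start, end) with depth >= 1."""
        d = self.depth(chrom, start, end)
        return float((d >= 1).mean()) if len(d) else 0.0

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self.data.values()))


def _records_to_arrays(records: dict[str, list[tuple[int, int, float]]]) -> dict[str, np.ndarray]:
    out = {}
    for chrom, recs in records.items():
        starts = np.array([r[0] for r in recs], dtype=np.int64)
        ends = np.array([r[1] for r in recs], dtype=np.int64)
        vals = np.array([r[2] for r in recs], dtype=np.float64)
        n = int(ends.max())
        arr = np.zeros(n)
        if len(starts) == 0 or np.all(ends[:-1] <= starts[1:]):
            # sorted non-overlapping records: exact vectorized fill (values
            # placed, not accumulated, so floats round-trip bit-identically)
            occ = np.zeros(n + 1, dtype=np.int64)
            np.add.at(occ, starts, 1)
            np.add.at(occ, ends, -1)
            mask = np.cumsum(occ[:-1]) > 0
            arr[mask] = np.repeat(vals, ends - starts)
        else:
            for s, e, v in recs:  # overlapping records are summed
                arr[s:e] += v
        out[chrom] = arr
    return out


def read_coverage(path, assay: str = "rnaseq", library_total: float | None = None,
                  read_length: int = 75) -> CoverageTrack:
    """Read a bedGraph or fixed-step wiggle file into a CoverageTrack.

    Records must be sorted by start within each chromosome (unsorted input is
    an error, never silently re-sorted); overlapping records are summed;
    negative values are a format error. ``library_total`` is taken from a
    ``#library_total=N`` header if present, else from the argument, else
    estimated as (sum of all values) / read_length (logged).
    """
    header_total = None
    records: dict[str, list[tuple[int, int, float]]] = {}
    wig_state = None  # (chrom, next_pos, step, span)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"library_total\s*=\s*([0-9.eE+]+)", line)
                if m:
                    header_total = float(m.group(1))
                continue
            if line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=", 1) for p in line.split()[1:])
                chrom = normalize_chrom(kv["chrom"])
                start = int(kv["start"]) - 1  # wiggle is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                wig_state = [chrom, start, step, span]
                continue
            if line.startswith("variableStep"):
                raise CoverageFormatError(f"line {lineno}: variableStep wiggle not supported")
            fields = line.split()
            if wig_state is not None and len(fields) == 1:
                chrom, pos, step, span = wig_state
                val = float(fields[0])
                if val < 0:
                    raise CoverageFormatError(f"line {lineno}: negative coverage value {val}")
                recs = records.setdefault(chrom, [])
                if recs and pos < recs[-1][0]:
                    raise CoverageFormatError(f"line {lineno}: unsorted wiggle positions")
                recs.append((pos, pos + span, val))
                wig_state[1] = pos + step
                continue
            if len(fields) != 4:
                raise CoverageFormatError(
                    f"line {lineno}: expected bedGraph 'chrom start end value', got {len(fields)} fields")
            chrom, s, e, v = normalize_chrom(fields[0]), int(fields[1]), int(fields[2]), float(fields[3])
            if v < 0:
                raise CoverageFormatError(f"line {lineno}: negative coverage value {v}")
            if e <= s:
                raise CoverageFormatError(f"line {lineno}: empty interval")
            recs = records.setdefault(chrom, [])
            if recs and s < recs[-1][0]:
                raise CoverageFormatError(f"line {lineno}: unsorted bedGraph records")
            recs.append((s, e, v))
            wig_state = None
    if not records:
        raise CoverageFormatError("no coverage records found")
    data = _records_to_arrays(records)
    track = CoverageTrack(data, assay=assay, library_total=None)
    if header_total is not None:
        track.library_total = header_total
    elif library_total is not None:
        track.library_total = library_total
    else:
        track.library_total = track.total() / read_length
        log.info("library_total estimated from track sum / read_length (%d): %.1f",
                 read_length, track.library_total)
    return track


def _fmt(v: float) -> str:
    # repr round-trips floats exactly; integers render compactly
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write as sorted bedGraph, run-length encoding equal-depth runs; zero runs omitted."""
    with open(path, "wt") as fh:
        if track.library_total is not None:
            fh.write(f"#library_total={_fmt(track.library_total)}\n")
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            bounds = np.concatenate(([0], change, [len(arr)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v)}\n")


def write_wig(track: CoverageTrack, path) -> None:
    """Write as fixed-step (step=1) wiggle, one block per chromosome."""
    with open(path, "wt") as fh:
        if track.library_total is not None:
            fh.write(f"#library_total={_fmt(track.library_total)}\n")
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fh.write("\n".join(_fmt(v) for v in arr))
            fh.write("\n")


def read_bed(path) -> list[GenomeInterval]:
    """Read BED3/4/6 (0-based half-open) intervals."""
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"line {lineno}: BED needs >=3 columns")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomeInterval(normalize_chrom(f[0]), int(f[1]), int(f[2]),
                                      strand=strand, name=name))
    return out


def write_bed(intervals: Sequence[GenomeInterval], path) -> None:
    ivs = sorted(intervals, key=lambda i: (i.chrom, i.start, i.end))
    with open(path, "wt") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


def flag_opposite_strand_introns(genes: dict[str, GeneModel]) -> dict[tuple[str, int], bool]:
    """Flag introns overlapping >=1 bp of a merged exon of any opposite-strand gene.

    Such introns are excluded from intron-retention analysis: antisense exonic
    signal is indistinguishable from retention in non-strand-specific
    libraries. Returns {(gene_id, intron_index): bool}.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in genes.values():
        tree = trees.setdefault((g.chrom, g.strand), IntervalTree())
        for s, e in g.merged_exons:
            tree.addi(s, e)
    flags: dict[tuple[str, int], bool] = {}
    for g in genes.values():
        opp = "-" if g.strand == "+" else "+"
        tree = trees.get((g.chrom, opp))
        for i, (s, e) in enumerate(g.introns):
            flags[(g.gene_id, i)] = bool(tree.overlap(s, e)) if tree is not None else False
    return flags
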