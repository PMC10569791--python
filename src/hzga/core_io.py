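"""Core containers, format I/O and normalization primitives.

Everything downstream works with 0-based half-open intervals.  GFF3 (1-based
inclusive) is converted on read and write; BED and bedGraph are already
half-open.  Coverage is stored as step functions (run-length intervals with a
value), chains as ordered gapped alignment blocks, and counts as a features x
samples integer matrix with exon and intron rows per gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# intervals

VALID_STRANDS = {"+", "-", "."}

SUBGENOME_PATTERN = r"^(?:chr)?.*(L|S)$"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def subgenome_of(chrom: str, pattern: str = SUBGENOME_PATTERN) -> str | None:
    """Parse the subgenome letter (L/S) from a chromosome name suffix."""
    m = re.match(pattern, chrom)
    return m.group(1) if m else None


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) pairs as a sorted disjoint list."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def subtract_intervals(
    keep: list[tuple[int, int]], cut: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Base-wise set difference keep \\ cut on disjoint sorted inputs."""
    cut = merge_intervals(cut)
    out: list[tuple[int, int]] = []
    for s, e in merge_intervals(keep):
        pos = s
        for cs, ce in cut:
            if ce <= pos or cs >= e:
                continue
            if cs > pos:
                out.append((pos, cs))
            pos = max(pos, ce)
            if pos >= e:
                break
        if pos < e:
            out.append((pos, e))
    return out


def intersect_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


# ---------------------------------------------------------------------------
# annotation model


@dataclass
class Transcript:
    transcript_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons, in genomic order."""
        exons = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(exons, exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(a.chrom, a.end, b.start, a.strand)
                )
        return out


@dataclass
class Gene:
    gene_id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def union_introns(self) -> list[tuple[int, int]]:
        """Union over all transcripts' introns, as (start, end) pairs."""
        ivs = [
            (i.start, i.end) for t in self.transcripts for i in t.introns()
        ]
        return merge_intervals(ivs)


class GenomeAnnotation:
    """Hierarchical gene model: genes -> transcripts -> exons.

    ``chrom_lengths`` maps chromosome name to length (bp); ``genes`` maps
    gene id to :class:`Gene`.  The subgenome of a chromosome is parsed from
    its name suffix (configurable regex, default trailing L/S).
    """

    def __init__(
        self,
        genes: dict[str, Gene] | None = None,
        chrom_lengths: dict[str, int] | None = None,
        subgenome_pattern: str = SUBGENOME_PATTERN,
    ) -> None:
        self.genes: dict[str, Gene] = genes or {}
        self.chrom_lengths: dict[str, int] = chrom_lengths or {}
        self.subgenome_pattern = subgenome_pattern

    def add_gene(self, gene: Gene) -> None:
        self.genes[gene.gene_id] = gene

    def subgenome(self, chrom: str) -> str | None:
        return subgenome_of(chrom, self.subgenome_pattern)

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted(
            (g for g in self.genes.values() if g.chrom == chrom),
            key=lambda g: g.interval.start,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return _annotation_records(self) == _annotation_records(other)


def _annotation_records(annot: GenomeAnnotation):
    recs = []
    for gid in sorted(annot.genes):
        g = annot.genes[gid]
        recs.append((gid, g.chrom, g.interval.start, g.interval.end,
                     g.strand, g.biotype))
        for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
            recs.append((t.transcript_id,
                         tuple(sorted((e.start, e.end) for e in t.exons))))
    return recs


class GFF3ParseError(ValueError):
    pass


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise GFF3ParseError(f"malformed attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v
    return out


def read_gff3(path) -> GenomeAnnotation:
    """Read a GFF3 gene/mRNA/exon hierarchy into a :class:`GenomeAnnotation`.

    1-based inclusive GFF coordinates become 0-based half-open.  A
    ``##sequence-region`` pragma populates chromosome lengths.  Raises
    :class:`GFF3ParseError` with the line number on malformed lines, and a
    ``ValueError`` if an exon falls outside its gene span.
    """
    annot = GenomeAnnotation()
    tx_to_gene: dict[str, str] = {}
    transcripts: dict[str, Transcript] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    annot.chrom_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3ParseError(
                    f"line {lineno}: expected 9 columns, got {len(cols)}"
                )
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            try:
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as exc:
                raise GFF3ParseError(f"line {lineno}: {exc}") from exc
            attr = _parse_gff_attributes(attrs)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise GFF3ParseError(f"line {lineno}: gene without ID")
                annot.add_gene(
                    Gene(gid, iv, attr.get("biotype", "protein_coding"))
                )
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attr.get("ID"), attr.get("Parent")
                if tid is None or parent is None:
                    raise GFF3ParseError(
                        f"line {lineno}: transcript needs ID and Parent"
                    )
                tx = Transcript(tid, iv)
                transcripts[tid] = tx
                tx_to_gene[tid] = parent
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent is None or parent not in transcripts:
                    raise GFF3ParseError(
                        f"line {lineno}: exon with unknown Parent"
                    )
                transcripts[parent].exons.append(iv)
    for tid, tx in transcripts.items():
        gid = tx_to_gene[tid]
        if gid not in annot.genes:
            raise GFF3ParseError(f"transcript {tid} references unknown gene {gid}")
        gene = annot.genes[gid]
        for e in tx.exons:
            if e.start < gene.interval.start or e.end > gene.interval.end:
                raise ValueError(
                    f"exon [{e.start},{e.end}) of {tid} outside gene span of {gid}"
                )
        gene.transcripts.append(tx)
    return annot


def write_gff3(annot: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(annot.chrom_lengths):
            fh.write(
                f"##sequence-region {chrom} 1 {annot.chrom_lengths[chrom]}\n"
            )
        for gid in sorted(annot.genes):
            g = annot.genes[gid]
            iv = g.interval
            fh.write(
                f"{iv.chrom}\thzga\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={gid};biotype={g.biotype}\n"
            )
            for t in sorted(g.transcripts, key=lambda t: t.transcript_id):
                ti = t.interval
                fh.write(
                    f"{ti.chrom}\thzga\tmRNA\t{ti.start + 1}\t{ti.end}\t.\t"
                    f"{ti.strand}\t.\tID={t.transcript_id};Parent={gid}\n"
                )
                for k, e in enumerate(sorted(t.exons, key=lambda e: e.start)):
                    fh.write(
                        f"{e.chrom}\thzga\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f"{e.strand}\t.\tID={t.transcript_id}.e{k};"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            strand = cols[5] if len(cols) >= 6 else "."
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]), strand))
    return out


def write_bed(intervals: list[GenomicInterval], path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"r{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# coverage tracks


class CoverageTrack:
    """Step-function coverage over chromosomes with a library size.

    Per chromosome the track holds sorted, non-overlapping records
    ``(starts, ends, values)``.  ``mass`` over a window is
    ``sum(value * overlap_length)``; RPM/RPKM follow the mass-based
    reads-per-million convention (``1e6 * mass / library_size``).
    """

    def __init__(self, library_size: float, label: str = "",
                 strandedness: str = "unstranded") -> None:
        if library_size <= 0:
            raise ValueError("library_size must be > 0")
        self.library_size = float(library_size)
        self.label = label
        self.strandedness = strandedness
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # construction -----------------------------------------------------

    def set_records(self, chrom: str, starts, ends, values) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(values < 0):
            raise ValueError(f"negative coverage on {chrom}")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"overlapping bedGraph records on {chrom}")
        self._chroms[chrom] = (starts, ends, values)

    @classmethod
    def from_dense(cls, arrays: dict[str, np.ndarray], library_size: float,
                   label: str = "", strandedness: str = "unstranded"):
        """Build from dense per-base arrays, run-length encoding them."""
        track = cls(library_size, label, strandedness)
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.float64)
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            values = arr[starts]
            keep = values != 0
            track.set_records(chrom, starts[keep], ends[keep], values[keep])
        return track

    # queries ----------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def mass(self, chrom: str, start: int, end: int) -> float:
        """Coverage mass (value x overlap bp) in [start, end)."""
        if chrom not in self._chroms:
            return 0.0
        starts, ends, values = self._chroms[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]))

    def rpm(self, chrom: str, start: int, end: int) -> float:
        return 1e6 * self.mass(chrom, start, end) / self.library_size

    def rpkm(self, chrom: str, start: int, end: int) -> float:
        return 1e9 * self.mass(chrom, start, end) / (
            self.library_size * (end - start)
        )

    def values_per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base coverage over a window (for rules and oracles)."""
        out = np.zeros(end - start)
        if chrom not in self._chroms:
            return out
        starts, ends, values = self._chroms[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            out[max(s, start) - start: min(e, end) - start] = v
        return out

    def regions_above(self, chrom: str, cutoff: float) -> list[tuple[int, int]]:
        """Maximal intervals where coverage is strictly above ``cutoff``."""
        if chrom not in self._chroms:
            return []
        starts, ends, values = self._chroms[chrom]
        keep = values > cutoff
        return merge_intervals(
            list(zip(starts[keep].tolist(), ends[keep].tolist()))
        )


def read_bedgraph(path, library_size: float, label: str = "",
                  strandedness: str = "unstranded") -> CoverageTrack:
    """Read a bedGraph file into a :class:`CoverageTrack`.

    Overlapping records and negative values raise ``ValueError``.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "value": np.float64},
    )
    track = CoverageTrack(library_size, label, strandedness)
    for chrom, sub in df.groupby("chrom", sort=False):
        track.set_records(chrom, sub["start"].values, sub["end"].values,
                          sub["value"].values)
    return track


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.chroms):
            starts, ends, values = track._chroms[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# UCSC chains


@dataclass
class ChainAlignment:
    """One UCSC chain: ordered co-linear gapped blocks t -> q.

    Block arrays are in target (source) coordinate order.  For minus-strand
    query chains, ``q_starts`` are offsets on the reversed query sequence, as
    in the chain format.
    """

    score: float
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: int
    sizes: np.ndarray
    t_starts: np.ndarray
    q_starts: np.ndarray

    def validate(self) -> None:
        t_span = int(self.t_starts[-1] + self.sizes[-1] - self.t_starts[0])
        q_span = int(self.q_starts[-1] + self.sizes[-1] - self.q_starts[0])
        if self.t_starts[0] != self.t_start or t_span != self.t_end - self.t_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks inconsistent with target span"
            )
        if q_span != self.q_end - self.q_start:
            raise ValueError(
                f"chain {self.chain_id}: blocks inconsistent with query span"
            )

    def aligned_target_intervals(self) -> list[tuple[int, int]]:
        return [(int(s), int(s + n)) for s, n in zip(self.t_starts, self.sizes)]

    def map_base(self, t_pos: int) -> int | None:
        """Map one target base to a forward-strand query coordinate."""
        idx = np.searchsorted(self.t_starts, t_pos, side="right") - 1
        if idx < 0:
            return None
        off = t_pos - int(self.t_starts[idx])
        if off >= int(self.sizes[idx]):
            return None
        q = int(self.q_starts[idx]) + off
        if self.q_strand == "-":
            return self.q_size - 1 - q
        return q


def read_chain(path) -> list[ChainAlignment]:
    """Parse a UCSC chain file; validates block sums against header spans."""
    chains: list[ChainAlignment] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("chain"):
            raise ValueError(f"expected chain header at line {i + 1}")
        parts = line.split()
        (_, score, t_name, t_size, t_strand, t_start, t_end,
         q_name, q_size, q_strand, q_start, q_end, chain_id) = parts
        if t_strand != "+":
            raise ValueError("target strand must be +")
        sizes, dts, dqs = [], [], []
        i += 1
        while i < len(lines) and lines[i].strip():
            nums = lines[i].split()
            sizes.append(int(nums[0]))
            if len(nums) == 3:
                dts.append(int(nums[1]))
                dqs.append(int(nums[2]))
                i += 1
            else:
                i += 1
                break
        t_starts = [int(t_start)]
        q_starts = [int(q_start)]
        for k in range(len(dts)):
            t_starts.append(t_starts[-1] + sizes[k] + dts[k])
            q_starts.append(q_starts[-1] + sizes[k] + dqs[k])
        chain = ChainAlignment(
            score=float(score), t_name=t_name, t_size=int(t_size),
            t_start=int(t_start), t_end=int(t_end), q_name=q_name,
            q_size=int(q_size), q_strand=q_strand, q_start=int(q_start),
            q_end=int(q_end), chain_id=int(chain_id),
            sizes=np.array(sizes, dtype=np.int64),
            t_starts=np.array(t_starts, dtype=np.int64),
            q_starts=np.array(q_starts, dtype=np.int64),
        )
        chain.validate()
        chains.append(chain)
    return chains


def write_chain(chains: list[ChainAlignment], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} + {c.t_start} "
                f"{c.t_end} {c.q_name} {c.q_size} {c.q_strand} {c.q_start} "
                f"{c.q_end} {c.chain_id}\n"
            )
            for k in range(len(c.sizes) - 1):
                dt = int(c.t_starts[k + 1] - c.t_starts[k] - c.sizes[k])
                dq = int(c.q_starts[k + 1] - c.q_starts[k] - c.sizes[k])
                fh.write(f"{c.sizes[k]} {dt} {dq}\n")
            fh.write(f"{c.sizes[-1]}\n\n")


# ---------------------------------------------------------------------------
# counts experiment and normalization


class CountsExperiment:
    """Exon and intron count rows per gene across samples.

    ``features`` is a DataFrame with columns ``feature_id``, ``gene_id``,
    ``part`` ("exon"/"intron") and ``length`` (effective bp).  Intron feature
    ids carry an ``i_`` prefix on the gene id.  ``samples`` has columns
    ``sample_id``, ``condition``, ``batch``.  ``counts`` is a nonnegative
    integer matrix, features x samples.
    """

    def __init__(self, features: pd.DataFrame, samples: pd.DataFrame,
                 counts: np.ndarray) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(features), len(samples)):
            raise ValueError("counts shape mismatch")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(features["length"].values <= 0):
            raise ValueError("effective_length must be > 0")
        exon_genes = set(features.loc[features.part == "exon", "gene_id"])
        intron_genes = set(features.loc[features.part == "intron", "gene_id"])
        if not intron_genes <= exon_genes:
            raise ValueError("intron feature without matching exon feature")
        self.features = features.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)
        self.counts = counts.astype(np.int64)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def exon_mask(self) -> np.ndarray:
        return (self.features["part"] == "exon").values

    def library_sizes(self) -> np.ndarray:
        """Per-sample library size: total exon counts (spike-in-free)."""
        n = self.counts[self.exon_mask()].sum(axis=0).astype(float)
        if np.any(n <= 0):
            raise ValueError("zero library size in a sample")
        return n

    def subset_features(self, mask: np.ndarray) -> "CountsExperiment":
        return CountsExperiment(
            self.features[mask], self.samples, self.counts[mask]
        )

    def subset_samples(self, mask: np.ndarray) -> "CountsExperiment":
        return CountsExperiment(
            self.features, self.samples[mask], self.counts[:, mask]
        )

    def sample_indices(self, condition: str, batch: str | None = None) -> np.ndarray:
        sel = self.samples["condition"] == condition
        if batch is not None:
            sel &= self.samples["batch"] == batch
        return np.flatnonzero(sel.values)


def normalize(experiment: CountsExperiment, mode: str) -> pd.DataFrame:
    """Normalize counts to RPM, RPKM or TPM.

    RPM = 1e6 * c / N; RPKM = 1e9 * c / (N * len); TPM renormalizes per-base
    rates to sum to 1e6 per sample over **exon** features only — intron rows
    get NaN under TPM (they are reported as RPKM by convention).  N is the
    per-sample total exon count.
    """
    c = experiment.counts.astype(float)
    n = experiment.library_sizes()
    lengths = experiment.features["length"].values.astype(float)
    if mode == "RPM":
        mat = 1e6 * c / n
    elif mode == "RPKM":
        mat = 1e9 * c / (n * lengths[:, None])
    elif mode == "TPM":
        rate = c / lengths[:, None]
        exon = experiment.exon_mask()
        denom = rate[exon].sum(axis=0)
        if np.any(denom <= 0):
            raise ValueError("zero exon rate sum in a sample")
        mat = np.full_like(rate, np.nan)
        mat[exon] = 1e6 * rate[exon] / denom
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(
        mat, index=experiment.features["feature_id"].values,
        columns=experiment.samples["sample_id"].values,
    )


def read_counts_tsv(path) -> CountsExperiment:
    """Read the counts TSV (feature_id, gene_id, part, length, samples...)
    with a paired ``<path>.samples.tsv`` sample sheet."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["feature_id", "gene_id", "part", "length"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    samples = pd.read_csv(str(path) + ".samples.tsv", sep="\t",
                          dtype={"batch": str})
    features = df[meta_cols]
    counts = df[sample_cols].values
    return CountsExperiment(features, samples[["sample_id", "condition", "batch"]],
                            counts)


def write_counts_tsv(experiment: CountsExperiment, path) -> None:
    df = experiment.features.copy()
    for j, sid in enumerate(experiment.samples["sample_id"]):
        df[sid] = experiment.counts[:, j]
    df.to_csv(path, sep="\t", index=False)
    experiment.samples.to_csv(str(path) + ".samples.tsv", sep="\t", index=False)
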