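"""Clean intron feature construction by four subtraction rules.

Intron-overlapping reads report nascent transcription, but only where the
intron is free of confounding signal.  Starting from the union of each
gene's transcript introns, the builder removes:

(a) bases covered above a cutoff by maternal (pre-activation) RNA-seq on
    the same strand — maternally retained intron signal;
(b) bases overlapping an annotated exon of a different transcript form
    (same-strand by default, configurable);
(c) bases overlapping repeat/transposon intervals, regardless of strand;
(d) bases lying in introns of more than one distinct gene — transcript
    forms of the same gene may share an intron, different genes may not.

The surviving per-gene interval set and its total length (for RPKM) are the
module's product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core_io import (
    CoverageTrack,
    GenomeAnnotation,
    GenomicInterval,
    merge_intervals,
    subtract_intervals,
)

RULES = ("a_maternal_coverage", "b_exon_overlap", "c_repeat", "d_ambiguous")


@dataclass
class IntronSet:
    """Retained intron intervals per gene with removal provenance."""

    retained: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    removed: dict[str, list[tuple[int, int, str]]] = field(
        default_factory=dict
    )

    def effective_length(self, gene_id: str) -> int:
        return sum(len(iv) for iv in self.retained.get(gene_id, []))

    def lengths_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": gid, "intron_length": self.effective_length(gid)}
            for gid in sorted(self.retained)
        ]
        return pd.DataFrame(rows)


def _cut(current, cuts, gene_id, rule, removed):
    """Subtract ``cuts`` from ``current``, logging removed sub-intervals."""
    cuts = merge_intervals(cuts)
    if not cuts:
        return current
    kept = subtract_intervals(current, cuts)
    gone = subtract_intervals(current, kept)
    for s, e in gone:
        removed.setdefault(gene_id, []).append((s, e, rule))
    return kept


def build_intron_annotation(
    annot: GenomeAnnotation,
    maternal_track_plus: CoverageTrack,
    maternal_track_minus: CoverageTrack,
    repeats: list[GenomicInterval],
    coverage_cutoff: float = 2.0,
    exon_rule_stranded: bool = True,
) -> IntronSet:
    """Apply subtraction rules (a)-(d); genes with no surviving intron bases
    are omitted from the result (not an error).

    ``coverage_cutoff`` is raw per-base coverage, strictly exceeded to
    trigger removal.  Raises ``ValueError`` if the maternal tracks are not
    stranded.
    """
    for track in (maternal_track_plus, maternal_track_minus):
        if track.strandedness != "stranded":
            raise ValueError(
                "rule (a) is strand-specific: maternal tracks must be stranded"
            )

    # per-gene union introns and helper indexes
    gene_introns = {
        gid: g.union_introns() for gid, g in annot.genes.items()
    }
    exons_by_key: dict[tuple[str, str], dict[str, list[tuple[int, int]]]] = {}
    for gid, g in annot.genes.items():
        for t in g.transcripts:
            for e in t.exons:
                key = (e.chrom, e.strand if exon_rule_stranded else ".")
                exons_by_key.setdefault(key, {}).setdefault(
                    t.transcript_id, []
                ).append((e.start, e.end))
    repeats_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        repeats_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))

    out = IntronSet()
    for gid, gene in annot.genes.items():
        current = gene_introns[gid]
        if not current:
            continue
        chrom, strand = gene.chrom, gene.strand

        # (a) maternal coverage, same strand (both strands if unstranded gene)
        cov_cuts: list[tuple[int, int]] = []
        if strand in ("+", "."):
            cov_cuts += maternal_track_plus.regions_above(chrom,
                                                          coverage_cutoff)
        if strand in ("-", "."):
            cov_cuts += maternal_track_minus.regions_above(chrom,
                                                           coverage_cutoff)
        current = _cut(current, cov_cuts, gid, RULES[0], out.removed)

        # (b) exons of other transcript forms
        key = (chrom, strand if exon_rule_stranded else ".")
        own_tx = {t.transcript_id for t in gene.transcripts}
        exon_cuts = [
            iv
            for tid, ivs in exons_by_key.get(key, {}).items()
            if tid not in own_tx
            for iv in ivs
        ]
        # same-gene alternative isoform exons also interrupt the intron union
        for t in gene.transcripts:
            for e in t.exons:
                exon_cuts.append((e.start, e.end))
        # exons of the gene's own transcripts never overlap its *union*
        # introns, so including them is harmless and covers isoform overlap
        current = _cut(current, exon_cuts, gid, RULES[1], out.removed)

        # (c) repeats, unstranded
        current = _cut(current, repeats_by_chrom.get(chrom, []), gid,
                       RULES[2], out.removed)

        # (d) shared intron bases between distinct genes, unstranded
        other_cuts = [
            iv
            for ogid, og in annot.genes.items()
            if ogid != gid and og.chrom == chrom
            for iv in gene_introns[ogid]
        ]
        current = _cut(current, other_cuts, gid, RULES[3], out.removed)

        if current:
            out.retained[gid] = [
                GenomicInterval(chrom, s, e, strand) for s, e in current
            ]
    return out
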