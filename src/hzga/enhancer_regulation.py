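"""Predicted regulatory elements from summit-centered chromatin windows.

A candidate element is a 500 bp window centered on an open-chromatin
(ATAC) summit.  It is a *putative* enhancer when pooled H3K27ac coverage is
two-fold enriched over the no-antibody control with at least 1 RPKM of
pooled H3K27ac and under 1 RPKM of background; *high-confidence* when at
least three individual H3K27ac replicates and three ATAC replicates each
show the two-fold enrichment on their own.  Fold enrichments carry a 0.1
pseudocount so zero background stays defined.  Transcription-factor binding
at an element (or any homeologous region) requires >= 0.5 RPM of factor
coverage and two-fold enrichment over background in a 200 bp window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CoverageTrack, GenomeAnnotation, GenomicInterval

PSEUDOCOUNT = 0.1


def fold_enrichment(signal: float, background: float,
                    pseudocount: float = PSEUDOCOUNT) -> float:
    return (signal + pseudocount) / (background + pseudocount)


@dataclass
class RegulatoryElement:
    """A summit-centered candidate element and everything called on it."""

    element_id: str
    window: GenomicInterval
    summit: int
    pooled_k27_rpkm: float = 0.0
    pooled_noab_rpkm: float = 0.0
    pooled_fold: float = 0.0
    k27_rep_folds: list[float] = field(default_factory=list)
    atac_rep_folds: list[float] = field(default_factory=list)
    tier: str = "rejected"  # hi / lo / rejected
    locality: str = "dist"  # dist / prox
    tf_bound: dict[str, bool] = field(default_factory=dict)
    partner: GenomicInterval | None = None
    lift_pass: str = "failed"
    conservation: str = "unmapped"  # conserved / subgenome_specific / unmapped

    @property
    def putative(self) -> bool:
        return self.tier in ("hi", "lo")


# ---------------------------------------------------------------------------
# representative TSS


def select_representative_tss(
    annot: GenomeAnnotation,
    stage9_track: CoverageTrack | None = None,
) -> dict[str, tuple[str, int, str]]:
    """One TSS per gene: the most upstream (5'-most) TSS whose base has
    non-zero stage 9 RNA-seq coverage, else the most upstream TSS.

    Genes without transcripts are skipped.
    """
    out: dict[str, tuple[str, int, str]] = {}
    for gid, gene in annot.genes.items():
        if not gene.transcripts:
            continue
        minus = gene.strand == "-"
        tss_list = [
            (t.interval.end - 1 if minus else t.interval.start)
            for t in gene.transcripts
        ]
        def upstream(positions):
            return max(positions) if minus else min(positions)
        chosen = None
        if stage9_track is not None:
            covered = [
                p for p in tss_list
                if stage9_track.mass(gene.chrom, p, p + 1) > 0
            ]
            if covered:
                chosen = upstream(covered)
        if chosen is None:
            chosen = upstream(tss_list)
        out[gid] = (gene.chrom, chosen, gene.strand)
    return out


# ---------------------------------------------------------------------------
# summit filtering and element calling


def blacklist_filter(
    summits: list[GenomicInterval],
    blacklist: list[GenomicInterval],
    annot: GenomeAnnotation | None = None,
    window: int = 500,
) -> list[GenomicInterval]:
    """Drop summits whose window overlaps any blacklist interval, and
    summits on chromosomes absent from the annotation (if given)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for b in blacklist:
        by_chrom.setdefault(b.chrom, []).append((b.start, b.end))
    out = []
    half = window // 2
    for s in summits:
        if annot is not None and annot.chrom_lengths and (
            s.chrom not in annot.chrom_lengths
        ):
            continue
        c = s.center
        w = (c - half, c + half)
        if any(w[0] < e and b < w[1] for b, e in by_chrom.get(s.chrom, [])):
            continue
        out.append(s)
    return out


def _pooled_rpkm(tracks: list[CoverageTrack], chrom: str, start: int,
                 end: int) -> float:
    """Depth-weighted pooling: summed mass over summed library size."""
    mass = sum(t.mass(chrom, start, end) for t in tracks)
    lib = sum(t.library_size for t in tracks)
    return 1e9 * mass / (lib * (end - start))


def call_elements(
    summits: list[GenomicInterval],
    k27_reps: list[CoverageTrack],
    atac_reps: list[CoverageTrack],
    noab_reps: list[CoverageTrack],
    tss_map: dict[str, tuple[str, int, str]] | None = None,
    chrom_lengths: dict[str, int] | None = None,
    window: int = 500,
    fold: float = 2.0,
    min_k27_rpkm: float = 1.0,
    max_noab_rpkm: float = 1.0,
    min_reps: int = 3,
    prox_distance: int = 1000,
    pseudocount: float = PSEUDOCOUNT,
) -> list[RegulatoryElement]:
    """Tiered element calls on summit-centered windows.

    Windows extending past a chromosome end are truncated (RPKM uses the
    actual window length, preserving density).  ``tss_map`` drives the
    distal/proximal flag.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    if tss_map:
        tmp: dict[str, list[int]] = {}
        for chrom, pos, _strand in tss_map.values():
            tmp.setdefault(chrom, []).append(pos)
        tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tmp.items()}

    half = window // 2
    out = []
    for i, s in enumerate(summits):
        c = s.center
        start = max(0, c - half)
        end = c + half
        if chrom_lengths and s.chrom in chrom_lengths:
            end = min(end, chrom_lengths[s.chrom])
        k27 = _pooled_rpkm(k27_reps, s.chrom, start, end)
        noab = _pooled_rpkm(noab_reps, s.chrom, start, end)
        pooled_fold = fold_enrichment(k27, noab, pseudocount)
        el = RegulatoryElement(
            element_id=f"el{i:05d}",
            window=GenomicInterval(s.chrom, start, end),
            summit=c,
            pooled_k27_rpkm=k27,
            pooled_noab_rpkm=noab,
            pooled_fold=pooled_fold,
        )
        el.k27_rep_folds = [
            fold_enrichment(t.rpkm(s.chrom, start, end), noab, pseudocount)
            for t in k27_reps
        ]
        el.atac_rep_folds = [
            fold_enrichment(t.rpkm(s.chrom, start, end), noab, pseudocount)
            for t in atac_reps
        ]
        if pooled_fold >= fold and k27 >= min_k27_rpkm and noab < max_noab_rpkm:
            n_k27 = sum(f >= fold for f in el.k27_rep_folds)
            n_atac = sum(f >= fold for f in el.atac_rep_folds)
            el.tier = "hi" if (n_k27 >= min_reps and n_atac >= min_reps) \
                else "lo"
        if s.chrom in tss_by_chrom:
            pos = tss_by_chrom[s.chrom]
            j = np.searchsorted(pos, c)
            d = min(
                abs(c - pos[j - 1]) if j > 0 else np.inf,
                abs(pos[j] - c) if j < len(pos) else np.inf,
            )
            el.locality = "prox" if d <= prox_distance else "dist"
        out.append(el)
    return out


def call_tf_binding(
    regions: list[RegulatoryElement] | list[GenomicInterval],
    tf_track: CoverageTrack,
    noab_track: CoverageTrack,
    factor: str = "tf",
    window: int = 200,
    min_rpm: float = 0.5,
    fold: float = 2.0,
    pseudocount: float = PSEUDOCOUNT,
) -> list[bool]:
    """Bound <=> RPM >= min_rpm and pseudocounted fold >= 2 in a window
    centered on the element summit (or region midpoint).

    When ``regions`` are :class:`RegulatoryElement`, the flag is also stored
    under ``tf_bound[factor]``.
    """
    half = window // 2
    flags = []
    for r in regions:
        if isinstance(r, RegulatoryElement):
            chrom, c = r.window.chrom, r.summit
        else:
            chrom, c = r.chrom, r.center
        start, end = max(0, c - half), c + half
        rpm = tf_track.rpm(chrom, start, end)
        noab_rpm = noab_track.rpm(chrom, start, end)
        bound = rpm >= min_rpm and fold_enrichment(
            rpm, noab_rpm, pseudocount
        ) >= fold
        if isinstance(r, RegulatoryElement):
            r.tf_bound[factor] = bound
        flags.append(bound)
    return flags


# ---------------------------------------------------------------------------
# binding-proximity and density statistics


def proximity_stats(
    gene_classes: dict[str, list[str]],
    tss_map: dict[str, tuple[str, int, str]],
    bound_elements: list[RegulatoryElement],
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Distance from each gene's TSS to the nearest bound element.

    Genes on chromosomes without any bound element get a censored distance
    (the chromosome length, or the max observed distance if lengths are
    unknown).  Returns the per-gene table and the Kruskal-Wallis p-value
    across classes; classes with fewer than two genes are excluded from the
    test.
    """
    centers: dict[str, np.ndarray] = {}
    for el in bound_elements:
        centers.setdefault(el.window.chrom, []).append(el.summit)
    centers = {c: np.sort(np.array(v)) for c, v in centers.items()}

    rows = []
    for label, genes in gene_classes.items():
        for gid in genes:
            if gid not in tss_map:
                continue
            chrom, pos, _ = tss_map[gid]
            if chrom in centers:
                arr = centers[chrom]
                j = np.searchsorted(arr, pos)
                d = min(
                    abs(pos - arr[j - 1]) if j > 0 else np.inf,
                    abs(arr[j] - pos) if j < len(arr) else np.inf,
                )
                censored = False
            else:
                d = float(chrom_lengths.get(chrom, np.inf)) \
                    if chrom_lengths else np.inf
                censored = True
            rows.append({"gene_id": gid, "klass": label,
                         "distance": float(d), "censored": censored})
    df = pd.DataFrame(rows)
    finite = df[np.isfinite(df["distance"])]
    groups = [
        sub["distance"].values
        for _, sub in finite.groupby("klass")
        if len(sub) >= 2
    ]
    if len(groups) >= 2:
        p = float(stats.kruskal(*groups).pvalue)
    else:
        p = float("nan")
    return df, p


def binding_signal_near_tss(
    gene_classes: dict[str, list[str]],
    tss_map: dict[str, tuple[str, int, str]],
    tf_track: CoverageTrack,
    radius: int = 1000,
) -> tuple[pd.DataFrame, float]:
    """Summed binding signal (RPM) within ``radius`` of each TSS, with a
    Kruskal-Wallis test across gene classes."""
    rows = []
    for label, genes in gene_classes.items():
        for gid in genes:
            if gid not in tss_map:
                continue
            chrom, pos, _ = tss_map[gid]
            rpm = tf_track.rpm(chrom, max(0, pos - radius), pos + radius)
            rows.append({"gene_id": gid, "klass": label, "signal": rpm})
    df = pd.DataFrame(rows)
    groups = [sub["signal"].values for _, sub in df.groupby("klass")
              if len(sub) >= 2]
    p = float(stats.kruskal(*groups).pvalue) if len(groups) >= 2 else float("nan")
    return df, p


def density_vs_activation(
    pairs_df: pd.DataFrame,
    elements: list[RegulatoryElement],
    tss_map: dict[str, tuple[str, int, str]],
    radius: int = 50_000,
) -> dict:
    """Correlate differential element density with differential activation.

    For each gene page with both homeologs, counts subgenome-specific
    putative elements within ``radius`` of the L TSS minus those within
    ``radius`` of the S TSS, against the L-S activation log2FC difference;
    Pearson correlation with test.  The same is computed for conserved
    elements (expected null).  Pages with undefined fold changes are
    skipped; with no usable pages the correlations are reported as NaN with
    n = 0.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    spec_centers: dict[str, list[int]] = {}
    cons_centers: dict[str, list[int]] = {}
    for el in elements:
        if not el.putative:
            continue
        target = spec_centers if el.conservation == "subgenome_specific" \
            else cons_centers if el.conservation == "conserved" else None
        if target is not None:
            target.setdefault(el.window.chrom, []).append(el.summit)
    spec_centers = {c: np.sort(np.array(v)) for c, v in spec_centers.items()}
    cons_centers = {c: np.sort(np.array(v)) for c, v in cons_centers.items()}

    def count_near(centers, chrom, pos):
        if chrom not in centers:
            return 0
        arr = centers[chrom]
        return int(np.searchsorted(arr, pos + radius)
                   - np.searchsorted(arr, pos - radius))

    d_spec, d_cons, d_lfc = [], [], []
    for rec in pairs_df.itertuples():
        if not rec.L_gene or not rec.S_gene:
            continue
        if rec.L_gene not in tss_map or rec.S_gene not in tss_map:
            continue
        if not (np.isfinite(rec.L_lfc) and np.isfinite(rec.S_lfc)):
            continue
        cl, pl, _ = tss_map[rec.L_gene]
        cs, ps, _ = tss_map[rec.S_gene]
        d_spec.append(count_near(spec_centers, cl, pl)
                      - count_near(spec_centers, cs, ps))
        d_cons.append(count_near(cons_centers, cl, pl)
                      - count_near(cons_centers, cs, ps))
        d_lfc.append(rec.L_lfc - rec.S_lfc)

    def pearson(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), float("nan")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    r_spec, p_spec = pearson(d_spec, d_lfc)
    r_cons, p_cons = pearson(d_cons, d_lfc)
    return {
        "n": len(d_lfc),
        "differential": {"r": r_spec, "p": p_spec},
        "conserved": {"r": r_cons, "p": p_cons},
    }
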