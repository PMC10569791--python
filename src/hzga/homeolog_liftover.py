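"""Chain-based interval liftOver and homeologous element pairing.

LiftOver follows the UCSC minMatch semantics on aligned-base fraction: a
region maps when at least ``min_match`` of its bases fall inside aligned
blocks of the selected chain (the chain with the most aligned source bases
over the region; ties by score, then id).  The mapped span runs from the
image of the first to the last aligned source base, strand-aware.

Homeologous pairing is two-pass: the 500 bp element window is lifted with
10% minimum match; on failure a 5 kb summit-centered window is lifted, each
2.5 kb half is lifted independently, and the candidate is retained only
when both halves map and flank the 5 kb image.  An element whose partner
region overlaps a putative element on the other subgenome is *conserved*,
otherwise *subgenome-specific*; elements failing both passes are
*unmapped*.  Synteny is validated by comparing the k nearest annotated
genes on each side of the two regions through the gene-page table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ChainAlignment, GenomeAnnotation, GenomicInterval
from .enhancer_regulation import RegulatoryElement

DEFAULT_MIN_MATCH = 0.10


@dataclass
class LiftResult:
    source: GenomicInterval
    mapped: GenomicInterval | None
    matched_fraction: float
    pass_label: str  # pass1_500bp / pass2_5kb / failed
    chain_id: int | None = None
    reason: str = ""


def _aligned_bases(chain: ChainAlignment, start: int, end: int) -> int:
    t0 = chain.t_starts
    t1 = chain.t_starts + chain.sizes
    ov = np.minimum(t1, end) - np.maximum(t0, start)
    return int(np.sum(ov[ov > 0]))


def liftover(
    region: GenomicInterval,
    chains: list[ChainAlignment],
    min_match: float = DEFAULT_MIN_MATCH,
    pass_label: str = "pass1_500bp",
) -> LiftResult:
    """Map one interval through the best-covering chain."""
    cands = [c for c in chains if c.t_name == region.chrom]
    if not cands:
        return LiftResult(region, None, 0.0, "failed", None, "no_chain")
    scored = sorted(
        ((_aligned_bases(c, region.start, region.end), c.score, -c.chain_id, c)
         for c in cands),
        reverse=True, key=lambda t: t[:3],
    )
    aligned, _, _, chain = scored[0]
    frac = aligned / len(region)
    if aligned == 0 or frac < min_match:
        return LiftResult(region, None, frac, "failed", chain.chain_id,
                          "below_min_match" if aligned else "no_aligned_base")

    # first and last aligned source bases
    t0 = chain.t_starts
    t1 = chain.t_starts + chain.sizes
    mask = (t1 > region.start) & (t0 < region.end)
    idx = np.flatnonzero(mask)
    first = max(region.start, int(t0[idx[0]]))
    last = min(region.end - 1, int(t1[idx[-1]]) - 1)
    q_first = chain.map_base(first)
    q_last = chain.map_base(last)
    lo, hi = sorted((q_first, q_last))
    mapped = GenomicInterval(chain.q_name, lo, hi + 1, region.strand)
    return LiftResult(region, mapped, frac, pass_label, chain.chain_id)


def liftover_per_base(region: GenomicInterval, chain: ChainAlignment
                      ) -> dict[int, int]:
    """Exhaustive base map through one chain (independent oracle helper)."""
    out = {}
    for pos in range(region.start, region.end):
        q = chain.map_base(pos)
        if q is not None:
            out[pos] = q
    return out


# ---------------------------------------------------------------------------
# two-pass element pairing


def pair_elements(
    elements: list[RegulatoryElement],
    chains: list[ChainAlignment],
    min_match: float = DEFAULT_MIN_MATCH,
    pass2_window: int = 5000,
    require_half_near: bool = False,
    half_distance: int = 10_000,
    include_rejected: bool = False,
) -> list[RegulatoryElement]:
    """Annotate each element with its homeologous partner and conservation.

    Conservation is judged against the *putative* (hi/lo) elements of the
    other subgenome.  Rejected elements are skipped unless
    ``include_rejected`` is set.
    """
    putative_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for el in elements:
        if el.putative:
            putative_by_chrom.setdefault(el.window.chrom, []).append(
                (el.window.start, el.window.end)
            )
    for ivs in putative_by_chrom.values():
        ivs.sort()

    half2 = pass2_window // 2
    for el in elements:
        if not el.putative and not include_rejected:
            continue
        res = liftover(el.window, chains, min_match)
        if res.mapped is None:
            res = _pass2(el, chains, min_match, half2, require_half_near,
                         half_distance)
        el.lift_pass = res.pass_label
        el.partner = res.mapped
        if res.mapped is None:
            el.conservation = "unmapped"
            continue
        hit = any(
            s < res.mapped.end and res.mapped.start < e
            for s, e in putative_by_chrom.get(res.mapped.chrom, [])
        )
        el.conservation = "conserved" if hit else "subgenome_specific"
    return elements


def _pass2(el: RegulatoryElement, chains, min_match, half2,
           require_half_near, half_distance) -> LiftResult:
    c = el.summit
    chrom = el.window.chrom
    big = GenomicInterval(chrom, max(0, c - half2), c + half2)
    res = liftover(big, chains, min_match, "pass2_5kb")
    if res.mapped is None:
        return LiftResult(el.window, None, res.matched_fraction, "failed",
                          res.chain_id, res.reason)
    halves = []
    for s, e in ((big.start, c), (c, big.end)):
        if e <= s:
            return LiftResult(el.window, None, 0.0, "failed", None,
                              "degenerate_half")
        halves.append(liftover(GenomicInterval(chrom, s, e), chains,
                               min_match))
    up, down = halves
    if up.mapped is None or down.mapped is None:
        return LiftResult(el.window, None, res.matched_fraction, "failed",
                          res.chain_id, "half_unmapped")
    m = res.mapped
    if up.mapped.chrom != m.chrom or down.mapped.chrom != m.chrom:
        return LiftResult(el.window, None, res.matched_fraction, "failed",
                          res.chain_id, "half_on_other_chrom")
    center = (m.start + m.end) // 2
    lo_half, hi_half = sorted((up.mapped, down.mapped),
                              key=lambda iv: iv.start)
    flanked = lo_half.start <= center <= hi_half.end
    if require_half_near:
        flanked &= (abs(lo_half.start - m.start) <= half_distance
                    and abs(hi_half.end - m.end) <= half_distance)
    if not flanked:
        return LiftResult(el.window, None, res.matched_fraction, "failed",
                          res.chain_id, "not_flanked")
    return LiftResult(el.window, m, res.matched_fraction, "pass2_5kb",
                      res.chain_id)


# ---------------------------------------------------------------------------
# synteny validation


def synteny_check(
    source: GenomicInterval,
    partner: GenomicInterval,
    annot: GenomeAnnotation,
    genepages: pd.DataFrame,
    k: int = 5,
) -> tuple[bool, int]:
    """Compare the k nearest genes up- and downstream of both regions.

    Syntenic when at least one upstream-side and one downstream-side
    neighbor of the source shares a gene page with any neighbor of the
    partner.  Returns ``(syntenic, n_shared_pages)`` with the shared-page
    count over all neighbors (0..2k).
    """
    page_of: dict[str, str] = {}
    for rec in genepages.itertuples():
        if rec.L_gene:
            page_of[rec.L_gene] = rec.genepage_id
        if rec.S_gene:
            page_of[rec.S_gene] = rec.genepage_id

    def neighbors(region: GenomicInterval) -> tuple[list[str], list[str]]:
        genes = annot.genes_on(region.chrom)
        mid = region.center
        up = [g.gene_id for g in genes if g.interval.center < mid][-k:]
        down = [g.gene_id for g in genes if g.interval.center >= mid][:k]
        return up, down

    src_up, src_down = neighbors(source)
    p_up, p_down = neighbors(partner)
    partner_pages = {page_of.get(g) for g in p_up + p_down} - {None}
    # a side with no annotated neighbors (chromosome end) is vacuous
    up_hit = (not src_up and not p_up) or any(
        page_of.get(g) in partner_pages for g in src_up
    )
    down_hit = (not src_down and not p_down) or any(
        page_of.get(g) in partner_pages for g in src_down
    )
    src_pages = {page_of.get(g) for g in src_up + src_down} - {None}
    shared = len(src_pages & partner_pages)
    return bool(up_hit and down_hit), shared


def pairing_frame(elements: list[RegulatoryElement]) -> pd.DataFrame:
    rows = []
    for el in elements:
        rows.append({
            "element_id": el.element_id,
            "chrom": el.window.chrom,
            "start": el.window.start,
            "end": el.window.end,
            "tier": el.tier,
            "lift_pass": el.lift_pass,
            "partner_chrom": el.partner.chrom if el.partner else "",
            "partner_start": el.partner.start if el.partner else -1,
            "partner_end": el.partner.end if el.partner else -1,
            "conservation": el.conservation,
        })
    return pd.DataFrame(rows)
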