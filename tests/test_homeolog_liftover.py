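"""LiftOver semantics, two-pass pairing and synteny validation."""

import numpy as np
import pandas as pd
import pytest

from hzga import homeolog_liftover as hl
from hzga.core_io import ChainAlignment, GenomeAnnotation, GenomicInterval
from hzga.enhancer_regulation import RegulatoryElement
from hzga.synthetic_data import SimConfig, simulate_genomes

from conftest import iv


def make_chain(blocks, t_name="chrT", q_name="chrQ", t_size=100_000,
               q_size=100_000, q_strand="+", chain_id=1, score=None):
    """blocks: list of (t_start, q_start, size) in target order."""
    sizes = np.array([b[2] for b in blocks], dtype=np.int64)
    t_starts = np.array([b[0] for b in blocks], dtype=np.int64)
    q_starts = np.array([b[1] for b in blocks], dtype=np.int64)
    return ChainAlignment(
        score=score if score is not None else float(sizes.sum()),
        t_name=t_name, t_size=t_size,
        t_start=int(t_starts[0]), t_end=int(t_starts[-1] + sizes[-1]),
        q_name=q_name, q_size=q_size, q_strand=q_strand,
        q_start=int(q_starts[0]), q_end=int(q_starts[-1] + sizes[-1]),
        chain_id=chain_id, sizes=sizes, t_starts=t_starts,
        q_starts=q_starts,
    )


def oracle_map(region, chain):
    """Per-base brute-force mapping; returns (fraction, span or None)."""
    mapped = [chain.map_base(p) for p in range(region.start, region.end)]
    mapped = [q for q in mapped if q is not None]
    if not mapped:
        return 0.0, None
    return len(mapped) / len(region), (min(mapped), max(mapped) + 1)


def test_identity_chain_with_offset():
    chain = make_chain([(0, 5000, 10_000)])
    res = hl.liftover(iv("chrT", 100, 600), [chain])
    assert res.matched_fraction == pytest.approx(1.0)
    assert (res.mapped.chrom, res.mapped.start, res.mapped.end) == \
        ("chrQ", 5100, 5600)
    assert res.pass_label == "pass1_500bp"


def test_partial_overlap_fraction_and_min_match():
    # 3-block chain; region half inside an aligned block
    chain = make_chain([(0, 0, 1000), (2000, 2000, 250), (4000, 4000, 500)])
    region = iv("chrT", 1750, 2250)  # 250 of 500 bases aligned
    res = hl.liftover(region, [chain], min_match=0.1)
    frac, span = oracle_map(region, chain)
    assert frac == pytest.approx(0.5)
    assert res.matched_fraction == pytest.approx(frac)
    assert (res.mapped.start, res.mapped.end) == span
    failed = hl.liftover(region, [chain], min_match=0.6)
    assert failed.mapped is None and failed.reason == "below_min_match"


def test_no_chain_for_chromosome():
    chain = make_chain([(0, 0, 1000)])
    res = hl.liftover(iv("chrX", 0, 100), [chain])
    assert res.mapped is None and res.reason == "no_chain"


def test_minus_strand_matches_oracle_and_round_trips():
    chain = make_chain([(0, 0, 2000), (3000, 2500, 1500)], q_strand="-",
                       q_size=10_000)
    region = iv("chrT", 500, 900)
    res = hl.liftover(region, [chain])
    frac, span = oracle_map(region, chain)
    assert res.matched_fraction == pytest.approx(frac)
    assert (res.mapped.start, res.mapped.end) == span
    # round trip through the reciprocal chain recovers an overlapping region
    # (forward chrQ block [6000,7500) <-> chrT [3000,4500) reversed, and
    #  [8000,10000) <-> chrT [0,2000) reversed)
    back = make_chain(
        [(6000, 100_000 - 4500, 1500), (8000, 100_000 - 2000, 2000)],
        t_name="chrQ", q_name="chrT", q_strand="-", t_size=10_000,
        q_size=100_000,
    )
    rt = hl.liftover(res.mapped, [back])
    assert rt.mapped is not None
    assert rt.mapped.overlaps(region)


def random_chain(rng, t_size=50_000, q_size=60_000):
    n_blocks = int(rng.integers(1, 11))
    sizes = rng.integers(20, 800, n_blocks)
    t_gaps = rng.integers(0, 500, n_blocks)
    q_gaps = rng.integers(0, 500, n_blocks)
    t_starts, q_starts = [], []
    t = int(rng.integers(0, 2000))
    q = int(rng.integers(0, 2000))
    for k in range(n_blocks):
        t_starts.append(t)
        q_starts.append(q)
        t += int(sizes[k]) + int(t_gaps[k])
        q += int(sizes[k]) + int(q_gaps[k])
    strand = "+" if rng.random() < 0.5 else "-"
    return make_chain(list(zip(t_starts, q_starts, sizes)),
                      q_strand=strand, t_size=t_size, q_size=q_size)


def test_random_chains_match_per_base_oracle():
    rng = np.random.default_rng(21)
    for _ in range(40):
        chain = random_chain(rng)
        for _ in range(10):
            a = int(rng.integers(0, chain.t_end + 500))
            w = int(rng.integers(1, 1200))
            region = iv("chrT", a, a + w)
            res = hl.liftover(region, [chain], min_match=1e-9)
            frac, span = oracle_map(region, chain)
            assert res.matched_fraction == pytest.approx(frac)
            if span is None:
                assert res.mapped is None
            else:
                assert (res.mapped.start, res.mapped.end) == span


def test_min_match_monotonicity():
    rng = np.random.default_rng(22)
    chain = random_chain(rng)
    for _ in range(50):
        a = int(rng.integers(0, chain.t_end))
        region = iv("chrT", a, a + int(rng.integers(50, 900)))
        mapped_at = [
            hl.liftover(region, [chain], mm).mapped is not None
            for mm in (0.05, 0.3, 0.6, 0.9)
        ]
        # once failed, never maps again at a stricter threshold
        for earlier, later in zip(mapped_at, mapped_at[1:]):
            assert earlier or not later


def test_chain_selection_prefers_most_aligned_bases():
    small = make_chain([(0, 0, 300)], chain_id=1, score=1e9)
    big = make_chain([(0, 50_000, 900)], chain_id=2, score=1.0)
    res = hl.liftover(iv("chrT", 0, 1000), [small, big])
    assert res.chain_id == 2


# ---------------------------------------------------------------------------
# two-pass pairing


def _element(chrom, center, tier="hi", eid="e1"):
    return RegulatoryElement(
        eid, GenomicInterval(chrom, center - 250, center + 250), center,
        tier=tier,
    )


def test_pass1_element_in_large_block_is_conserved_iff_partner_called():
    chain = make_chain([(0, 0, 50_000)], t_name="chrL", q_name="chrS")
    src = _element("chrL", 10_000, eid="src")
    partner_hit = _element("chrS", 10_100, eid="hit")
    for partner, expect in ((partner_hit, "conserved"),
                            (None, "subgenome_specific")):
        els = [src] + ([partner] if partner else [])
        hl.pair_elements(els, [chain])
        assert src.lift_pass == "pass1_500bp"
        assert src.conservation == expect


def test_pass2_rescues_window_in_central_gap():
    # 1 kb gap in the target exactly around the element window
    chain = make_chain([(0, 0, 9500), (10_500, 9500, 9500)],
                       t_name="chrL", q_name="chrS")
    el = _element("chrL", 10_000)
    hl.pair_elements([el], [chain])
    assert el.lift_pass == "pass2_5kb"
    assert el.partner is not None
    assert el.conservation == "subgenome_specific"


def test_pass2_fails_when_one_half_cannot_map():
    # aligned bases only downstream of the summit: upstream half unmapped
    chain = make_chain([(10_500, 9500, 9500)], t_name="chrL", q_name="chrS")
    el = _element("chrL", 10_000)
    hl.pair_elements([el], [chain])
    assert el.lift_pass == "failed"
    assert el.conservation == "unmapped"


def test_simulated_conservation_recall(pipeline):
    truth = pipeline["ds"].truth.elements.reset_index(drop=True)
    called = pd.Series([e.conservation for e in pipeline["elements"]])
    active_called = truth["active"].values & np.array(
        [e.putative for e in pipeline["elements"]]
    )
    mapped = active_called & (called != "unmapped").values
    frac_mapped = mapped.sum() / active_called.sum()
    assert frac_mapped > 0.95
    cons = truth["conserved"].values
    t_cons = mapped & cons
    t_spec = mapped & ~cons
    assert (called[t_cons] == "conserved").mean() >= 0.9
    assert (called[t_spec] == "subgenome_specific").mean() >= 0.9


# ---------------------------------------------------------------------------
# synteny


def test_synteny_identical_order_shares_2k_pages():
    annot, chains, pages = simulate_genomes(
        SimConfig(n_genepages=40, chain_indel_rate=0.0,
                  frac_singleton_L=0.0, frac_singleton_S=0.0)
    )
    src = iv("chr1L", 40_000, 40_500)
    partner = iv("chr1S", 40_000, 40_500)
    syntenic, shared = hl.synteny_check(src, partner, annot, pages, k=5)
    assert syntenic and shared == 10


def test_translocated_partner_is_non_syntenic():
    annot, chains, pages = simulate_genomes(
        SimConfig(n_genepages=40, chain_indel_rate=0.0,
                  frac_singleton_L=0.0, frac_singleton_S=0.0)
    )
    src = iv("chr1L", 40_000, 40_500)
    partner = iv("chr2S", 40_000, 40_500)  # wrong chromosome entirely
    syntenic, shared = hl.synteny_check(src, partner, annot, pages, k=5)
    assert not syntenic and shared == 0


def test_chromosome_end_uses_available_neighbors():
    annot, chains, pages = simulate_genomes(
        SimConfig(n_genepages=40, chain_indel_rate=0.0,
                  frac_singleton_L=0.0, frac_singleton_S=0.0)
    )
    src = iv("chr1L", 3_200, 3_700)  # inside the first gene slot
    partner = iv("chr1S", 3_200, 3_700)
    syntenic, shared = hl.synteny_check(src, partner, annot, pages, k=5)
    assert syntenic
    assert 0 < shared <= 10
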