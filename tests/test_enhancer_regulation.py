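"""Element calling, TF binding, TSS selection and proximity statistics."""

import numpy as np
import pandas as pd
import pytest

from hzga import enhancer_regulation as er
from hzga.core_io import (
    CoverageTrack,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    Transcript,
)

from conftest import flat_track, iv


def _gene_two_isoforms(strand="+"):
    annot = GenomeAnnotation()
    g = Gene("g", GenomicInterval("c", 1000, 3000, strand))
    for tid, (s, e) in (("t_up", (1000, 2500)), ("t_down", (1500, 3000))):
        t = Transcript(tid, GenomicInterval("c", s, e, strand))
        t.exons = [GenomicInterval("c", s, e, strand)]
        g.transcripts.append(t)
    annot.add_gene(g)
    return annot


def test_tss_single_isoform_and_zero_coverage_rule():
    annot = _gene_two_isoforms("+")
    # upstream TSS (1000) has zero stage-9 coverage -> downstream chosen
    track = CoverageTrack(1e6)
    track.set_records("c", [1400], [2600], [3.0])
    tss = er.select_representative_tss(annot, track)
    assert tss["g"] == ("c", 1500, "+")
    # without a track: most upstream
    assert er.select_representative_tss(annot)["g"] == ("c", 1000, "+")


def test_tss_minus_strand_uses_maximum_coordinate():
    annot = _gene_two_isoforms("-")
    tss = er.select_representative_tss(annot)
    assert tss["g"] == ("c", 2999, "-")
    covered = CoverageTrack(1e6)
    covered.set_records("c", [1000], [2600], [2.0])  # 2999 uncovered
    tss2 = er.select_representative_tss(annot, covered)
    assert tss2["g"] == ("c", 2499, "-")


# ---------------------------------------------------------------------------
# blacklist


def test_blacklist_empty_is_identity_and_one_bp_overlap_removes():
    summits = [iv("c", 1000, 1001), iv("c", 5000, 5001)]
    assert er.blacklist_filter(summits, []) == summits
    # window [750,1250); blacklist overlapping by exactly 1 bp
    bl = [iv("c", 1249, 1400)]
    kept = er.blacklist_filter(summits, bl)
    assert kept == [summits[1]]


def test_blacklist_matches_brute_force_on_random_sets():
    rng = np.random.default_rng(9)
    summits = [iv("c", int(p), int(p) + 1)
               for p in rng.integers(300, 50_000, 60)]
    bl = [iv("c", int(s), int(s + w))
          for s, w in zip(rng.integers(0, 50_000, 20),
                          rng.integers(10, 2000, 20))]
    got = {s.start for s in er.blacklist_filter(summits, bl)}
    expect = set()
    for s in summits:
        w0, w1 = s.center - 250, s.center + 250
        window = set(range(w0, w1))
        hit = any(window & set(range(b.start, b.end)) for b in bl)
        if not hit:
            expect.add(s.start)
    assert got == expect


def test_blacklist_drops_unknown_chromosomes():
    annot = GenomeAnnotation(chrom_lengths={"chr1L": 10_000})
    summits = [iv("chr1L", 1000, 1001), iv("scaffold9", 1000, 1001)]
    kept = er.blacklist_filter(summits, [], annot)
    assert [s.chrom for s in kept] == ["chr1L"]


# ---------------------------------------------------------------------------
# element calling


def _uniform_tracks(k27_value, noab_value, n_k27=3, length=100_000):
    """Flat tracks with library 1e9 so window RPKM equals the base value."""
    k27 = [flat_track({"c": (k27_value, length)}) for _ in range(n_k27)]
    noab = [flat_track({"c": (noab_value, length)}) for _ in range(3)]
    return k27, noab


def test_pooled_fold_arithmetic_and_putative_call():
    k27, noab = _uniform_tracks(4.0, 0.5)
    atac = [flat_track({"c": (2.0, 100_000)}) for _ in range(3)]
    els = er.call_elements([iv("c", 5000, 5001)], k27, atac, noab)
    el = els[0]
    assert el.pooled_k27_rpkm == pytest.approx(4.0)
    assert el.pooled_noab_rpkm == pytest.approx(0.5)
    assert el.pooled_fold == pytest.approx(4.1 / 0.6)
    assert el.putative and el.tier == "hi"
    assert len(el.window) == 500


def test_two_of_three_passing_replicates_is_lo_tier():
    length = 100_000
    k27 = [flat_track({"c": (4.0, length)}) for _ in range(2)]
    k27.append(flat_track({"c": (0.6, length)}))  # third rep fails 2-fold
    noab = [flat_track({"c": (0.5, length)}) for _ in range(3)]
    atac = [flat_track({"c": (2.0, length)}) for _ in range(3)]
    els = er.call_elements([iv("c", 5000, 5001)], k27, atac, noab)
    assert els[0].tier == "lo"
    # tier monotonicity: lowering min_reps to 2 promotes it back to hi
    els2 = er.call_elements([iv("c", 5000, 5001)], k27, atac, noab,
                            min_reps=2)
    assert els2[0].tier == "hi"


def test_high_background_rejects_element():
    k27, noab = _uniform_tracks(4.0, 1.5)  # no-antibody >= 1 RPKM
    atac = [flat_track({"c": (2.0, 100_000)}) for _ in range(3)]
    els = er.call_elements([iv("c", 5000, 5001)], k27, atac, noab)
    assert els[0].tier == "rejected"


def test_element_tier_recall_on_simulated_truth(pipeline):
    truth = pipeline["ds"].truth.elements.reset_index(drop=True)
    called = pd.Series([e.tier for e in pipeline["elements"]])
    cm = pd.crosstab(truth["tier"], called)
    for tier in ("hi", "lo", "rejected"):
        recall = cm.loc[tier].get(tier, 0) / cm.loc[tier].sum()
        assert recall >= 0.9, (tier, recall)


def test_locality_matches_truth_tss_distances(pipeline):
    truth = pipeline["ds"].truth.elements.reset_index(drop=True)
    called = pd.Series([e.locality for e in pipeline["elements"]])
    assert ((called == "prox") == truth["prox"]).all()


# ---------------------------------------------------------------------------
# TF binding


def test_tf_binding_rpm_gate_and_pseudocount():
    # RPM 0.4 with fold 10: fails the RPM gate
    length = 100_000
    tf = flat_track({"c": (0.4, length)}, library_size=2e8)
    noab = flat_track({"c": (0.0, length)}, library_size=2e8)
    region = [iv("c", 5000, 5001)]
    assert er.call_tf_binding(region, tf, noab) == [False]
    # RPM 3 over zero background: fold (3.1/0.1) = 31 -> bound
    tf2 = flat_track({"c": (3.0, length)}, library_size=2e8)
    assert er.call_tf_binding(region, tf2, noab) == [True]


def test_tf_bound_recall_and_precision_on_truth(pipeline):
    truth = pipeline["ds"].truth.elements.reset_index(drop=True)
    flags = np.array([e.tf_bound["pou5f3"] for e in pipeline["elements"]])
    t = truth["tf_bound"].values
    tp = (flags & t).sum()
    assert tp / t.sum() >= 0.9
    assert tp / max(flags.sum(), 1) >= 0.9
    sox = np.array([e.tf_bound["sox3"] for e in pipeline["elements"]])
    assert (sox == flags).all()  # both factors bind the same truth set


# ---------------------------------------------------------------------------
# proximity and density


def test_element_at_tss_has_distance_zero():
    el = er.RegulatoryElement("e0", GenomicInterval("c", 750, 1250), 1000,
                              tier="hi")
    df, _ = er.proximity_stats({"x": ["g"]}, {"g": ("c", 1000, "+")}, [el])
    assert df["distance"].iloc[0] == 0.0


def test_kruskal_wallis_near_one_on_identical_distributions():
    rng = np.random.default_rng(4)
    centers = np.sort(rng.integers(0, 100_000, 30))
    els = [er.RegulatoryElement(f"e{i}",
                                GenomicInterval("c", int(c), int(c) + 500),
                                int(c) + 250, tier="hi")
           for i, c in enumerate(centers)]
    tss = {f"g{i}": ("c", int(p), "+")
           for i, p in enumerate(rng.integers(0, 100_000, 40))}
    classes = {"a": [f"g{i}" for i in range(20)],
               "b": [f"g{i}" for i in range(20, 40)]}
    _, p = er.proximity_stats(classes, tss, els)
    assert p > 0.05


def test_down_class_sits_closer_to_bound_elements(pipeline):
    ds = pipeline["ds"]
    truth = ds.truth.genes
    bound = [e for e in pipeline["elements"] if e.tf_bound.get("pou5f3")]
    classes = {
        "down": list(truth[truth.mo_target].gene_id),
        "unaffected": list(truth[truth.activated & ~truth.mo_target].gene_id),
        "unactivated": list(truth[~truth.activated].gene_id),
    }
    df, p = er.proximity_stats(classes, pipeline["tss"], bound,
                               ds.annot.chrom_lengths)
    med = df.groupby("klass")["distance"].median()
    assert med["down"] < med["unaffected"]
    assert p < 0.01


def test_density_perfect_linear_toy_gives_r_one():
    tss = {}
    els = []
    rows = []
    for i in range(10):
        base = 10_000 + i * 200_000
        tss[f"g{i}.L"] = ("cL", base, "+")
        tss[f"g{i}.S"] = ("cS", base, "+")
        for k in range(i):  # i specific elements near the L TSS
            c = base + 1000 + 600 * k
            el = er.RegulatoryElement(f"e{i}_{k}",
                                      GenomicInterval("cL", c - 250, c + 250),
                                      c, tier="hi")
            el.conservation = "subgenome_specific"
            els.append(el)
        rows.append({"genepage_id": f"p{i}", "L_gene": f"g{i}.L",
                     "S_gene": f"g{i}.S", "L_lfc": float(i), "S_lfc": 0.0,
                     "symmetry_class": "x"})
    rep = er.density_vs_activation(pd.DataFrame(rows), els, tss)
    assert rep["n"] == 10
    assert rep["differential"]["r"] == pytest.approx(1.0)


def test_density_with_no_elements_reports_nan():
    rows = [{"genepage_id": "p", "L_gene": "a", "S_gene": "b",
             "L_lfc": 1.0, "S_lfc": 0.0, "symmetry_class": "x"}]
    rep = er.density_vs_activation(
        pd.DataFrame(rows), [],
        {"a": ("cL", 100, "+"), "b": ("cS", 100, "+")})
    assert np.isnan(rep["differential"]["r"])
    with pytest.raises(ValueError, match="radius"):
        er.density_vs_activation(pd.DataFrame(rows), [], {}, radius=0)


def test_density_correlation_on_simulated_truth(pipeline):
    rep = er.density_vs_activation(pipeline["pairs_df"],
                                   pipeline["elements"], pipeline["tss"])
    assert rep["differential"]["r"] > 0
    assert rep["differential"]["p"] < 0.01
    cons = rep["conserved"]
    assert np.isnan(cons["r"]) or cons["p"] > 0.01 or abs(cons["r"]) < 0.1
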