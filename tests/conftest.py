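"""Shared fixtures: the default synthetic dataset and the full pipeline run.

The heavyweight objects are session-scoped so the default study conditions
(seed 42, 600 gene pages, 2 replicates/condition) are simulated and
analyzed once for the whole suite.
"""

import numpy as np
import pandas as pd
import pytest

from hzga import (
    activation as act,
    enhancer_regulation as er,
    homeolog_liftover as hl,
    homeolog_symmetry as hs,
)
from hzga.core_io import CoverageTrack, GenomicInterval
from hzga.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimConfig())


@pytest.fixture(scope="session")
def pipeline(default_dataset):
    """Full analysis of the default dataset, shared by downstream tests."""
    ds = default_dataset
    biotypes = {g.gene_id: g.biotype for g in ds.annot.genes.values()}
    exp = act.prefilter(ds.counts, biotypes)
    results = act.run_standard_contrasts(exp)
    calls = act.classify_activation(results, exp)
    pairs = hs.classify_symmetry(hs.build_pairs(ds.genepages, calls))
    tss = er.select_representative_tss(ds.annot)
    elements = er.call_elements(
        ds.summits, ds.tracks["h3k27ac"], ds.tracks["atac"],
        ds.tracks["noab"], tss_map=tss,
        chrom_lengths=ds.annot.chrom_lengths,
    )
    er.call_tf_binding(elements, ds.tracks["pou5f3"][0],
                       ds.tracks["noab"][0], "pou5f3")
    er.call_tf_binding(elements, ds.tracks["sox3"][0],
                       ds.tracks["noab"][0], "sox3")
    elements = hl.pair_elements(elements, ds.chains)
    return {
        "ds": ds,
        "experiment": exp,
        "results": results,
        "calls": calls,
        "pairs": pairs,
        "pairs_df": hs.pairs_frame(pairs),
        "tss": tss,
        "elements": elements,
    }


@pytest.fixture(scope="session")
def truth_symmetry(default_dataset):
    """Truth page classes in the classifier's vocabulary."""
    tp = default_dataset.truth.pages.copy()

    def label(r):
        if r.klass == "both_asymmetric":
            return "both_L_biased" if r.biased_side == "L" else "both_S_biased"
        return r.klass

    tp["sym"] = tp.apply(label, axis=1)
    return tp


def flat_track(chrom_values: dict[str, tuple[float, int]],
               library_size: float = 1e9, label: str = "",
               strandedness: str = "unstranded") -> CoverageTrack:
    """Uniform-coverage track helper: {chrom: (value, length)}."""
    t = CoverageTrack(library_size, label, strandedness)
    for chrom, (v, ln) in chrom_values.items():
        if v > 0:
            t.set_records(chrom, [0], [ln], [v])
        else:
            t.set_records(chrom, [], [], [])
    return t


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)
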