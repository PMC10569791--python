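"""Homeolog pairing and L/S activation-symmetry classification.

Gene pages link the L and S copies of each homeologous gene (or record a
singleton).  Given per-gene activation calls, every page receives exactly
one symmetry label: activated on one side only (L_only / S_only), on both
sides with or without a >2-fold bias (both_L_biased / both_S_biased /
both_symmetric), not activated, or singleton.  Category-proportion
comparisons use a Pearson chi-squared test of homogeneity, and lineage
concordance cross-tabulates whether the same homeolog drives activation in
different condition sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activation import ActivationCall, ActivationTable

SYMMETRY_CLASSES = [
    "L_only", "S_only", "both_symmetric", "both_L_biased", "both_S_biased",
    "not_activated", "singleton_L", "singleton_S",
]


@dataclass
class HomeologPair:
    genepage_id: str
    L_gene: str | None
    S_gene: str | None
    L_call: ActivationCall | None = None
    S_call: ActivationCall | None = None
    symmetry_class: str = ""


def build_pairs(genepages: pd.DataFrame,
                calls: ActivationTable) -> list[HomeologPair]:
    """Join the gene-page table with activation calls.

    A page with two genes on the same subgenome is invalid.
    """
    pairs = []
    for rec in genepages.itertuples():
        l_gene = rec.L_gene or None
        s_gene = rec.S_gene or None
        if l_gene is None and s_gene is None:
            raise ValueError(f"empty gene page {rec.genepage_id}")
        pairs.append(HomeologPair(
            genepage_id=rec.genepage_id,
            L_gene=l_gene, S_gene=s_gene,
            L_call=calls.calls.get(l_gene) if l_gene else None,
            S_call=calls.calls.get(s_gene) if s_gene else None,
        ))
    return pairs


def _matched_delta(l_call: ActivationCall, s_call: ActivationCall) -> float:
    """L-S activation log2FC difference within one feature channel."""
    li, si = l_call.activation_lfc_intron, s_call.activation_lfc_intron
    if np.isfinite(li) and np.isfinite(si):
        return li - si
    le, se = l_call.activation_lfc_exon, s_call.activation_lfc_exon
    if np.isfinite(le) and np.isfinite(se):
        return le - se
    return l_call.activation_lfc - s_call.activation_lfc


def classify_symmetry(pairs: list[HomeologPair],
                      bias_log2: float = 1.0) -> list[HomeologPair]:
    """Assign one symmetry label per pair (in place; also returned).

    Bias requires both sides activated and an absolute difference of
    activation log2 fold changes above ``bias_log2`` (default 1, i.e. the
    2-fold rule).  The difference is taken within a matched feature channel
    — intron fold changes on both sides when available, else exon — since
    exonic folds of maternal-zygotic genes are compressed by the maternal
    store and are not comparable with intronic folds.  A side whose gene is
    annotated but fails the activation call counts as not activated, so its
    partner can still be L_only/S_only.
    """
    for p in pairs:
        if p.L_gene is None:
            p.symmetry_class = "singleton_S"
            continue
        if p.S_gene is None:
            p.symmetry_class = "singleton_L"
            continue
        l_act = p.L_call.activated if p.L_call else False
        s_act = p.S_call.activated if p.S_call else False
        if l_act and s_act:
            delta = _matched_delta(p.L_call, p.S_call)
            if delta > bias_log2:
                p.symmetry_class = "both_L_biased"
            elif delta < -bias_log2:
                p.symmetry_class = "both_S_biased"
            else:
                p.symmetry_class = "both_symmetric"
        elif l_act:
            p.symmetry_class = "L_only"
        elif s_act:
            p.symmetry_class = "S_only"
        else:
            p.symmetry_class = "not_activated"
    return pairs


def pairs_frame(pairs: list[HomeologPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "genepage_id": p.genepage_id,
        "L_gene": p.L_gene or "",
        "S_gene": p.S_gene or "",
        "L_activated": bool(p.L_call and p.L_call.activated),
        "S_activated": bool(p.S_call and p.S_call.activated),
        "L_lfc": p.L_call.activation_lfc if p.L_call else np.nan,
        "S_lfc": p.S_call.activation_lfc if p.S_call else np.nan,
        "symmetry_class": p.symmetry_class,
    } for p in pairs])


def compare_category_proportions(table_a, table_b):
    """Pearson chi-squared test of homogeneity between two count vectors.

    Returns ``(chi2, dof, p)`` without continuity correction; raises on a
    zero-expected cell (merge sparse categories first).
    """
    a = np.asarray(table_a, dtype=float)
    b = np.asarray(table_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("category tables must have matching shapes")
    obs = np.vstack([a, b])
    expected = stats.contingency.expected_freq(obs)
    if np.any(expected <= 0):
        raise ValueError(
            "zero expected count in a cell; merge categories and retry"
        )
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


def lineage_concordance(
    call_sets: dict[str, list[HomeologPair]],
) -> pd.DataFrame:
    """Cross-condition concordance of homeolog activation patterns.

    For pages activated (any side) in at least two condition sets, counts
    whether the driving homeolog agrees: ``same`` (same single side or both
    sides in both), ``different`` (opposite single sides), or ``mixed``
    (single side in one set, both in the other).
    """
    if len(call_sets) < 2:
        raise ValueError("need at least two condition sets")
    single = {"L_only": "L", "S_only": "S", "singleton_L": "L",
              "singleton_S": "S"}
    both = {"both_symmetric", "both_L_biased", "both_S_biased"}
    by_page: dict[str, dict[str, str]] = {}
    for name, pairs in call_sets.items():
        for p in pairs:
            if p.symmetry_class in single:
                # singletons count only when that side is activated
                act = (p.L_call and p.L_call.activated) or (
                    p.S_call and p.S_call.activated
                )
                if p.L_gene and p.S_gene or act:
                    by_page.setdefault(p.genepage_id, {})[name] = single[
                        p.symmetry_class
                    ]
            elif p.symmetry_class in both:
                by_page.setdefault(p.genepage_id, {})[name] = "both"
    rows = []
    names = list(call_sets)
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            same = diff = mixed = 0
            for page, labels in by_page.items():
                if na not in labels or nb not in labels:
                    continue
                la, lb = labels[na], labels[nb]
                if la == lb:
                    same += 1
                elif "both" in (la, lb):
                    mixed += 1
                else:
                    diff += 1
            rows.append({"set_a": na, "set_b": nb, "same": same,
                         "different": diff, "mixed": mixed})
    return pd.DataFrame(rows)
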