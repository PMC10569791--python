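"""Cross-species dosage-maintenance analysis.

For ortholog triples (diploid outgroup gene, L homeolog, S homeolog) the
question is whether the allotetraploid maintains the *combined* ancestral
expression output despite asymmetric homeolog regulation.  The composite
L+S transcriptome is compared with the outgroup against each subgenome
alone: single-subgenome TPMs are doubled (TPM normalization is relative to
the whole allotetraploid transcriptome), log2 values of non-zero expressed
genes are Z-normalized per transcriptome, Spearman correlations are
computed on shared non-zero genes, and gene-wise residuals (outgroup minus
laevis, on the Z scale) are compared between the composite and each single
subgenome by a paired Wilcoxon signed-rank test on absolute residuals.
Dosage maintenance shows as a higher composite correlation and smaller
composite residuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

MIN_SHARED_GENES = 10


def build_vectors(
    laevis_tpm: pd.DataFrame,
    outgroup_tpm: pd.DataFrame,
    triples: pd.DataFrame,
    embryonic_tpm: float = 1.0,
    maternal_tpm: float = 1.0,
) -> pd.DataFrame:
    """Assemble per-triple expression vectors.

    ``laevis_tpm`` is indexed by gene id with columns ``stage5`` and
    ``stage9``; ``outgroup_tpm`` has columns ``outgroup_gene`` and ``tpm``;
    ``triples`` has columns ``outgroup_gene``, ``L_gene``, ``S_gene``.
    Triples referencing a missing gene are dropped (count in
    ``attrs['n_dropped']``).  Columns: outgroup, L, S, composite (= L + S),
    L_scaled / S_scaled (2x), maternal (stage-5 composite TPM >= 1) and
    embryonic_expressed (TPM > 1 at either stage).
    """
    og = outgroup_tpm.set_index("outgroup_gene")["tpm"]
    rows, dropped = [], 0
    for t in triples.itertuples():
        if (t.outgroup_gene not in og.index
                or t.L_gene not in laevis_tpm.index
                or t.S_gene not in laevis_tpm.index):
            dropped += 1
            continue
        l9 = float(laevis_tpm.at[t.L_gene, "stage9"])
        s9 = float(laevis_tpm.at[t.S_gene, "stage9"])
        l5 = float(laevis_tpm.at[t.L_gene, "stage5"])
        s5 = float(laevis_tpm.at[t.S_gene, "stage5"])
        comp = l9 + s9
        rows.append({
            "outgroup_gene": t.outgroup_gene,
            "L_gene": t.L_gene, "S_gene": t.S_gene,
            "outgroup": float(og[t.outgroup_gene]),
            "L": l9, "S": s9, "composite": comp,
            "L_scaled": 2.0 * l9, "S_scaled": 2.0 * s9,
            "maternal": (l5 + s5) >= maternal_tpm,
            "embryonic_expressed": max(comp, l5 + s5) > embryonic_tpm,
        })
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = dropped
    return out


def _znorm_log2(values: np.ndarray) -> np.ndarray:
    """log2 then Z over the vector's own non-zero entries; zeros -> NaN."""
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    nz = v > 0
    logv = np.log2(v[nz])
    sd = logv.std(ddof=0)
    if sd <= 1e-12 * max(1.0, float(np.abs(logv).max(initial=0.0))):
        raise ValueError("constant vector: Z-normalization undefined")
    out[nz] = (logv - logv.mean()) / sd
    return out


def correlate(vec_a, vec_b) -> tuple[float, float, int]:
    """Spearman rho on the intersection of non-zero genes.

    Both vectors are log2 Z-normalized over their own non-zero sets first
    (rho itself is rank-invariant to that; the Z values feed the residual
    analysis).  Returns ``(rho, pvalue, n_shared)``.
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    shared = (a > 0) & (b > 0)
    if shared.sum() < MIN_SHARED_GENES:
        raise ValueError(
            f"only {int(shared.sum())} shared non-zero genes "
            f"(need >= {MIN_SHARED_GENES})"
        )
    za, zb = _znorm_log2(a), _znorm_log2(b)
    rho, p = stats.spearmanr(za[shared], zb[shared])
    return float(rho), float(p), int(shared.sum())


def residual_test(
    outgroup, composite, single_l, single_s,
    use_absolute: bool = True,
) -> dict:
    """Does the outgroup predict the composite better than either subgenome?

    Residual per gene: Z(outgroup) - Z(laevis vector), over genes non-zero
    in all four vectors.  Paired two-sided Wilcoxon signed-rank compares
    |composite residual| against |L residual| and |S residual| (raw signed
    residuals when ``use_absolute`` is off).  Reports median absolute
    residuals, p-values and the favored side.
    """
    vecs = {
        "outgroup": np.asarray(outgroup, float),
        "composite": np.asarray(composite, float),
        "L": np.asarray(single_l, float),
        "S": np.asarray(single_s, float),
    }
    shared = np.ones(len(vecs["outgroup"]), dtype=bool)
    for v in vecs.values():
        shared &= v > 0
    z = {k: _znorm_log2(v)[shared] for k, v in vecs.items()}
    res = {k: z["outgroup"] - z[k] for k in ("composite", "L", "S")}
    if use_absolute:
        res = {k: np.abs(v) for k, v in res.items()}

    report: dict = {
        "n": int(shared.sum()),
        "median_abs_residual": {
            k: float(np.median(np.abs(v))) for k, v in res.items()
        },
    }
    for side in ("L", "S"):
        diff = res["composite"] - res[side]
        if np.allclose(diff, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(res["composite"], res[side]).pvalue)
        report[f"wilcoxon_vs_{side}"] = {
            "p": p,
            "favors": "composite" if np.median(diff) < 0 else side,
        }
    return report


def dosage_report(vectors: pd.DataFrame,
                  subset: str | None = None) -> dict:
    """Correlations and residual tests for one vector table.

    ``subset`` restricts to ``"strictly_zygotic"`` or
    ``"maternal_zygotic"`` triples; embryonic-expressed genes only.
    """
    df = vectors[vectors["embryonic_expressed"]]
    if subset == "strictly_zygotic":
        df = df[~df["maternal"]]
    elif subset == "maternal_zygotic":
        df = df[df["maternal"]]
    out: dict = {"n": len(df), "subset": subset or "all"}
    for key, col in (("composite", "composite"), ("L", "L_scaled"),
                     ("S", "S_scaled")):
        rho, p, n = correlate(df["outgroup"].values, df[col].values)
        out[f"rho_{key}"] = rho
        out[f"rho_{key}_n"] = n
    out["residuals"] = residual_test(
        df["outgroup"].values, df["composite"].values,
        df["L_scaled"].values, df["S_scaled"].values,
    )
    return out
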