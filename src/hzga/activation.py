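"""Differential activation calling on joint exon/intron count rows.

The detection model follows the standard bulk RNA-seq negative-binomial
framework: median-of-ratios size factors, per-feature method-of-moments
dispersions shrunk toward a fitted mean-dispersion trend, and a Wald test
on the log2 fold change with Benjamini-Hochberg adjustment per contrast.
A gene is *activated* when any of its feature rows (exon or intron) shows a
significant positive change in the transcription-inhibitor contrast in both
experimental batches and in the stage 9 vs stage 5 contrast; *first-wave*
when additionally significant under translation blockade (cycloheximide);
and morphant-*affected* when a morpholino contrast passes thresholds on an
activated gene.

Intron rows are the nascent-transcription channel: genes with large
maternal mRNA stores show little exonic change on activation, so the joint
exon+intron row model is what makes maternal-zygotic genes callable at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CountsExperiment, normalize

ALLOWED_BIOTYPES = {"protein_coding", "lncRNA", "pseudogene"}

DEFAULT_PADJ = 0.05
DEFAULT_LFC = 1.5
MODERATION_PSEUDOCOUNT = 4.0  # normalized counts; see differential_test


# ---------------------------------------------------------------------------
# prefilter


def prefilter(
    experiment: CountsExperiment,
    annot_biotypes: dict[str, str] | None = None,
    min_exon_rpm: float = 0.5,
    max_intron_count: int = 10,
    min_intron_rpkm: float = 0.25,
) -> CountsExperiment:
    """Remove unanalyzable rows before testing.

    Genes whose exon RPM is below ``min_exon_rpm`` in every sample are
    dropped entirely; intron rows whose raw count is <= ``max_intron_count``
    in all samples or whose RPKM is below ``min_intron_rpkm`` in all samples
    are dropped; genes outside the allowed biotypes (protein_coding, lncRNA,
    pseudogene) are dropped when a biotype map is given.
    """
    feats = experiment.features
    keep = np.ones(len(feats), dtype=bool)

    if annot_biotypes is not None:
        ok_gene = feats["gene_id"].map(
            lambda g: annot_biotypes.get(g, "protein_coding")
            in ALLOWED_BIOTYPES
        ).values
        keep &= ok_gene

    rpm = normalize(experiment, "RPM").values
    exon = experiment.exon_mask()
    low_exon = (rpm < min_exon_rpm).all(axis=1) & exon
    dead_genes = set(feats.loc[low_exon, "gene_id"])
    keep &= ~feats["gene_id"].isin(dead_genes).values

    rpkm = normalize(experiment, "RPKM").values
    intron = ~exon
    low_intron = intron & (
        (experiment.counts <= max_intron_count).all(axis=1)
        | (rpkm < min_intron_rpkm).all(axis=1)
    )
    keep &= ~low_intron

    if not keep.any():
        raise ValueError("prefilter removed every feature")
    return experiment.subset_features(keep)


# ---------------------------------------------------------------------------
# NB Wald differential test


@dataclass
class DEResult:
    """Per-feature statistics of one contrast (B over A)."""

    contrast: tuple[str, str]
    batch: str | None
    table: pd.DataFrame  # feature_id, gene_id, part, base_mean_[ab],
    #                      log2fc, moderated_log2fc, se, pvalue, padj
    dispersion_trend_only: bool = False

    def significant(self, padj: float = DEFAULT_PADJ,
                    log2fc: float = DEFAULT_LFC,
                    direction: str = "up") -> pd.Series:
        t = self.table
        ok = t["padj"] < padj
        if direction == "up":
            ok &= t["log2fc"] >= log2fc
        elif direction == "down":
            ok &= t["log2fc"] <= -log2fc
        else:
            ok &= t["log2fc"].abs() >= log2fc
        return ok


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors over features positive in all samples."""
    counts = np.asarray(counts, dtype=float)
    pos = (counts > 0).all(axis=1)
    if not pos.any():
        return np.ones(counts.shape[1])
    logc = np.log(counts[pos])
    ref = logc.mean(axis=1)
    sf = np.exp(np.median(logc - ref[:, None], axis=0))
    return sf / np.exp(np.mean(np.log(sf)))


def _fit_dispersion_trend(mu: np.ndarray, disp: np.ndarray) -> tuple[float, float]:
    """Fit disp ~ a1/mu + a0 on features with usable MoM estimates."""
    ok = (mu > 0) & (disp > 1e-7)
    if ok.sum() < 10:
        return 0.1, 1.0
    x = 1.0 / mu[ok]
    y = disp[ok]
    # one IRLS-flavoured pass: plain least squares, then re-fit without the
    # features far above the first trend (they carry true signal, not noise)
    for _ in range(2):
        A = np.vstack([np.ones_like(x), x]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a0, a1 = max(coef[0], 1e-6), max(coef[1], 1e-8)
        fit = a0 + a1 * x
        keep = y < 10 * fit
        if keep.all():
            break
        x, y = x[keep], y[keep]
    return a0, a1


def differential_test(
    experiment: CountsExperiment,
    contrast: tuple[str, str],
    batch: str | None = None,
    shrink_weight: float | None = None,
) -> DEResult:
    """NB Wald test of condition B over condition A.

    With one replicate per group the gene-wise dispersion is undefined and
    the trend estimate is used alone (flagged on the result).  The Wald
    statistic is referred to a standard normal; trend shrinkage of the
    dispersions keeps the test near-nominal at the 2-replicate depth this
    pipeline targets.
    """
    cond_a, cond_b = contrast
    ia = experiment.sample_indices(cond_a, batch)
    ib = experiment.sample_indices(cond_b, batch)
    for cond, idx in ((cond_a, ia), (cond_b, ib)):
        if len(idx) == 0:
            where = f" in batch {batch!r}" if batch else ""
            raise ValueError(f"condition {cond!r} has no samples{where}")

    counts = experiment.counts[:, np.concatenate([ia, ib])].astype(float)
    n_a, n_b = len(ia), len(ib)
    m = n_a + n_b
    sf = size_factors(counts)
    q = counts / sf
    qa, qb = q[:, :n_a], q[:, n_a:]

    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    base_mean = q.mean(axis=1)

    trend_only = min(n_a, n_b) < 2
    if trend_only:
        d_gene = np.full(len(q), np.nan)
    else:
        wvar = (qa.var(axis=1, ddof=1) * (n_a - 1)
                + qb.var(axis=1, ddof=1) * (n_b - 1)) / (m - 2)
        grand = (mu_a * n_a + mu_b * n_b) / m
        with np.errstate(divide="ignore", invalid="ignore"):
            d_gene = np.where(grand > 0,
                              (wvar - grand) / np.maximum(grand, 1e-12) ** 2,
                              np.nan)
        d_gene = np.clip(d_gene, 1e-8, 10.0)
    a0, a1 = _fit_dispersion_trend(base_mean, np.nan_to_num(d_gene, nan=0.0))
    d_trend = a0 + a1 / np.maximum(base_mean, 1e-8)
    if trend_only:
        disp = d_trend
    else:
        if shrink_weight is None:
            shrink_weight = max(0.0, (m - 2.0)) / (m + 8.0)
        disp = np.exp(
            shrink_weight * np.log(np.maximum(d_gene, 1e-8))
            + (1.0 - shrink_weight) * np.log(np.maximum(d_trend, 1e-8))
        )
        disp = np.where(np.isnan(d_gene), d_trend, disp)
    disp = np.clip(disp, 1e-8, 20.0)

    # group means on the count scale; a zero group total falls back to a
    # half-count pseudo so the fold change stays finite
    tot_sf_a, tot_sf_b = sf[:n_a].sum(), sf[n_a:].sum()
    ca, cb = counts[:, :n_a].sum(axis=1), counts[:, n_a:].sum(axis=1)
    mu_a_hat = np.where(ca > 0, ca, 0.5) / tot_sf_a
    mu_b_hat = np.where(cb > 0, cb, 0.5) / tot_sf_b
    log2fc = np.log2(mu_b_hat / mu_a_hat)

    # Wald SE from the NB GLM information: w_i = mu_i / (1 + disp * mu_i)
    w_a = np.einsum("i,j->ij", mu_a_hat, sf[:n_a])
    w_b = np.einsum("i,j->ij", mu_b_hat, sf[n_a:])
    info_a = (w_a / (1.0 + disp[:, None] * w_a)).sum(axis=1)
    info_b = (w_b / (1.0 + disp[:, None] * w_b)).sum(axis=1)
    se_ln = np.sqrt(1.0 / np.maximum(info_a, 1e-12)
                    + 1.0 / np.maximum(info_b, 1e-12))
    z = np.log(mu_b_hat / mu_a_hat) / se_ln
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue = np.minimum(np.nan_to_num(pvalue, nan=1.0), 1.0)
    identical = np.isclose(mu_a_hat, mu_b_hat)
    pvalue[identical] = 1.0
    padj = multipletests(pvalue, method="fdr_bh")[1]

    # moderated fold change: a pseudocount on the normalized-count scale
    # damps the denominator noise of near-zero baselines (shallow-replication
    # analogue of posterior LFC shrinkage); used for effect-size comparisons,
    # never for significance
    moderated = np.log2((mu_b_hat + MODERATION_PSEUDOCOUNT)
                        / (mu_a_hat + MODERATION_PSEUDOCOUNT))
    table = pd.DataFrame({
        "feature_id": experiment.features["feature_id"].values,
        "gene_id": experiment.features["gene_id"].values,
        "part": experiment.features["part"].values,
        "base_mean_a": mu_a_hat,
        "base_mean_b": mu_b_hat,
        "dispersion": disp,
        "log2fc": log2fc,
        "moderated_log2fc": moderated,
        "se_log2fc": se_ln / np.log(2.0),
        "pvalue": pvalue,
        "padj": padj,
    })
    return DEResult((cond_a, cond_b), batch, table, trend_only)


# ---------------------------------------------------------------------------
# classification


@dataclass
class ActivationCall:
    gene_id: str
    maternal: bool
    activated: bool
    first_wave: bool
    mo_effect: str  # down / up / none
    magnitude: float
    activation_lfc: float  # moderated, preferred channel (intron else exon)
    activation_lfc_exon: float = float("nan")
    activation_lfc_intron: float = float("nan")
    supporting_feature: str = "none"  # exon / intron / both / none


@dataclass
class ActivationTable:
    calls: dict[str, ActivationCall] = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.calls.values()])

    def activated_ids(self) -> set[str]:
        return {g for g, c in self.calls.items() if c.activated}

    def first_wave_ids(self) -> set[str]:
        return {g for g, c in self.calls.items() if c.first_wave}


def _gene_hits(result: DEResult, padj: float, log2fc: float,
               direction: str = "up") -> pd.DataFrame:
    sig = result.significant(padj, log2fc, direction)
    t = result.table[sig]
    return t.groupby("gene_id")["part"].agg(set)


def run_standard_contrasts(
    experiment: CountsExperiment,
    batches: tuple[str, ...] = ("a", "b"),
    chx_reference: str = "stage9_triptolide",
) -> dict[str, DEResult]:
    """The contrast set the classifier consumes.

    Activation is triptolide-controlled per batch plus a stage 9 vs stage 5
    comparison; the first-wave contrast compares cycloheximide-treated
    embryos to the transcription-inhibited reference; morpholino contrasts
    are run with and without cycloheximide.
    """
    res: dict[str, DEResult] = {}
    for b in batches:
        res[f"dmso_vs_trip_{b}"] = differential_test(
            experiment, ("stage9_triptolide", "stage9_DMSO"), batch=b
        )
    res["dmso_vs_trip_pooled"] = differential_test(
        experiment, ("stage9_triptolide", "stage9_DMSO")
    )
    res["stage9_vs_stage5"] = differential_test(
        experiment, ("stage5", "stage9_DMSO")
    )
    res["chx"] = differential_test(experiment, (chx_reference, "stage9_CHX"))
    res["mo"] = differential_test(experiment, ("stage9_DMSO", "stage9_MO"))
    res["mo_chx"] = differential_test(experiment,
                                      ("stage9_CHX", "stage9_MO_CHX"))
    return res


def classify_activation(
    results: dict[str, DEResult],
    experiment: CountsExperiment,
    padj: float = DEFAULT_PADJ,
    log2fc: float = DEFAULT_LFC,
    batches: tuple[str, ...] = ("a", "b"),
    maternal_tpm: float = 1.0,
    magnitude_pseudocount: float = 0.1,
) -> ActivationTable:
    """Combine contrasts into per-gene activation calls.

    A gene is significant in a contrast if any of its rows passes both the
    adjusted-p and fold thresholds; activated requires the inhibitor
    contrast in *both* batches and the stage contrast; first-wave adds the
    cycloheximide contrast; morphant effect is the signed call of either
    morpholino contrast on an activated gene.  Maternal status is average
    stage 5 exon TPM >= 1.  Magnitude is the maximal absolute log2 fold
    difference between average exon TPM and average intron RPKM across the
    activation contrast.
    """
    required = [f"dmso_vs_trip_{b}" for b in batches] + [
        "stage9_vs_stage5", "chx", "mo", "mo_chx", "dmso_vs_trip_pooled",
    ]
    for key in required:
        if key not in results:
            raise ValueError(f"missing required contrast {key!r}")

    batch_hits = [
        _gene_hits(results[f"dmso_vs_trip_{b}"], padj, log2fc)
        for b in batches
    ]
    stage_hits = _gene_hits(results["stage9_vs_stage5"], padj, log2fc)
    chx_hits = _gene_hits(results["chx"], padj, log2fc)
    mo_down = set(_gene_hits(results["mo"], padj, log2fc, "down").index) | set(
        _gene_hits(results["mo_chx"], padj, log2fc, "down").index
    )
    mo_up = set(_gene_hits(results["mo"], padj, log2fc, "up").index) | set(
        _gene_hits(results["mo_chx"], padj, log2fc, "up").index
    )

    # maternal status from average stage 5 exon TPM
    tpm = normalize(experiment, "TPM")
    s5 = experiment.sample_indices("stage5")
    exon = experiment.exon_mask()
    feats = experiment.features
    s5_tpm = tpm.values[:, s5][exon].mean(axis=1)
    maternal_by_gene = dict(zip(feats.loc[exon, "gene_id"], s5_tpm))

    # magnitude: exon TPM vs intron RPKM fold between DMSO and triptolide
    rpkm = normalize(experiment, "RPKM")
    idx9 = experiment.sample_indices("stage9_DMSO")
    idxt = experiment.sample_indices("stage9_triptolide")
    pc = magnitude_pseudocount
    exon_mag = np.abs(np.log2(
        (tpm.values[:, idx9][exon].mean(axis=1) + pc)
        / (tpm.values[:, idxt][exon].mean(axis=1) + pc)
    ))
    exon_mag_by_gene = dict(zip(feats.loc[exon, "gene_id"], exon_mag))
    intron = ~exon
    intron_mag = np.abs(np.log2(
        (rpkm.values[:, idx9][intron].mean(axis=1) + pc)
        / (rpkm.values[:, idxt][intron].mean(axis=1) + pc)
    ))
    intron_mag_by_gene = dict(zip(feats.loc[intron, "gene_id"], intron_mag))

    pooled = results["dmso_vs_trip_pooled"].table
    # activation effect size per channel; the preferred estimate comes from
    # the intron row when present (nascent channel), else the exon row
    lfc_channel: dict[str, dict[str, float]] = {"exon": {}, "intron": {}}
    for part in ("exon", "intron"):
        sub = pooled[pooled["part"] == part]
        lfc_channel[part] = dict(zip(sub["gene_id"], sub["moderated_log2fc"]))

    table = ActivationTable()
    for gid in feats["gene_id"].unique():
        sets = [h.get(gid, set()) for h in batch_hits] + [
            stage_hits.get(gid, set())
        ]
        activated = all(len(s) > 0 for s in sets)
        support = set().union(*sets) if activated else set()
        first_wave = activated and len(chx_hits.get(gid, set())) > 0
        if activated and gid in mo_down:
            mo_effect = "down"
        elif activated and gid in mo_up:
            mo_effect = "up"
        else:
            mo_effect = "none"
        magnitude = max(exon_mag_by_gene.get(gid, 0.0),
                        intron_mag_by_gene.get(gid, 0.0))
        if support == {"exon", "intron"}:
            supporting = "both"
        elif support:
            supporting = next(iter(support))
        else:
            supporting = "none"
        lfc_ex = lfc_channel["exon"].get(gid, float("nan"))
        lfc_in = lfc_channel["intron"].get(gid, float("nan"))
        preferred = lfc_in if np.isfinite(lfc_in) else lfc_ex
        table.calls[gid] = ActivationCall(
            gene_id=gid,
            maternal=maternal_by_gene.get(gid, 0.0) >= maternal_tpm,
            activated=activated,
            first_wave=first_wave,
            mo_effect=mo_effect,
            magnitude=float(magnitude),
            activation_lfc=float(preferred) if np.isfinite(preferred) else 0.0,
            activation_lfc_exon=float(lfc_ex),
            activation_lfc_intron=float(lfc_in),
            supporting_feature=supporting,
        )
    return table
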