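"""Synthetic allotetraploid dataset generator with known ground truth.

Emulates the data structure of an early-embryo homeolog-resolved genome
activation study: two co-linear subgenomes (L and S) related by indels and
described by UCSC chains; homeologous gene pairs plus singletons grouped
under gene pages; negative-binomial exon/intron counts across developmental
stages and drug/morpholino conditions with controlled activation effects and
homeolog bias; summit-centered enhancers with replicate-level H3K27ac/ATAC
track structure over a flat no-antibody background; transcription-factor
binding co-located with active enhancers of target genes; and an ancestral
diploid outgroup transcriptome equal to the L+S composite up to lognormal
noise.

Every stochastic choice derives from ``SimConfig.seed`` through stage-local
generators, so outputs are bit-for-bit reproducible and independent of call
order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    ChainAlignment,
    CountsExperiment,
    CoverageTrack,
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    Transcript,
)

CONDITIONS = [
    "stage5",
    "stage8",
    "stage9_DMSO",
    "stage9_triptolide",
    "stage9_CHX",
    "stage9_CHX_trip",
    "stage9_MO",
    "stage9_MO_CHX",
]

PAIRED_CLASSES = ["L_only", "S_only", "both_symmetric", "both_asymmetric"]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the package's reference conditions: 2 chromosome pairs of
    ~1.2 Mb, 600 gene pages, activation log2 fold change 4, NB dispersion
    0.05 and 2 replicates per condition and batch.
    """

    seed: int = 42
    n_genepages: int = 600
    n_chrom_pairs: int = 2
    gene_step: int = 4000

    frac_singleton_L: float = 0.05
    frac_singleton_S: float = 0.05
    frac_maternal: float = 0.6
    frac_activated: float = 0.4
    frac_first_wave_of_activated: float = 0.5
    frac_mo_target: float = 0.3
    # mix over {L_only, S_only, both_symmetric, both_asymmetric}
    homeolog_bias_mix: tuple[float, float, float, float] = (0.2, 0.2, 0.4, 0.2)

    activation_log2fc: float = 4.0
    activation_log2_sd: float = 0.0  # controlled effect; >0 adds per-gene spread
    zygotic_unit: float = 8.0          # counts per unit activation fold
    intron_fraction: float = 0.5       # intron gain relative to exon gain
    intron_background: float = 0.5     # mean intron counts without transcription
    bias_delta_log2: float = 2.0       # true L-S offset for asymmetric pages
    maternal_log2_mean: float = 8.0
    maternal_log2_sd: float = 1.5
    zygotic_low_log2_range: tuple[float, float] = (-4.0, -2.0)
    nb_dispersion: float = 0.05
    n_replicates: int = 2
    batch_maternal_factor: float = 1.3  # maternal contribution of batch "b"
    depth_log2_sd: float = 0.2

    enhancer_per_gene: int = 1
    frac_enhancer_conserved: float = 0.5
    frac_hi: float = 0.8
    frac_prox: float = 0.2
    track_background: float = 0.5
    track_amplitude: float = 4.0
    bump_sd: float = 100.0
    track_noise_sd: float = 0.2
    track_noise_bin: int = 50
    track_library: float = 1e9
    tf_effect: float = 8.0

    chain_indel_rate: float = 2e-5
    indel_size_range: tuple[int, int] = (20, 200)
    outgroup_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.n_genepages < 10:
            raise ValueError("n_genepages must be >= 10")
        for name in ("frac_singleton_L", "frac_singleton_S", "frac_maternal",
                     "frac_activated", "frac_first_wave_of_activated",
                     "frac_mo_target", "frac_enhancer_conserved", "frac_hi",
                     "frac_prox"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if abs(sum(self.homeolog_bias_mix) - 1.0) > 1e-9:
            raise ValueError("homeolog_bias_mix must sum to 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class GroundTruth:
    """Per-gene, per-page and per-element truth records, plus the genome
    objects they refer to."""

    cfg: SimConfig
    annot: GenomeAnnotation
    chains: list[ChainAlignment]
    genepages: pd.DataFrame
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    pages: pd.DataFrame = field(default_factory=pd.DataFrame)
    elements: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class SyntheticDataset:
    truth: GroundTruth
    counts: CountsExperiment
    tracks: dict[str, list[CoverageTrack]]
    summits: list[GenomicInterval]
    outgroup: pd.DataFrame

    @property
    def annot(self) -> GenomeAnnotation:
        return self.truth.annot

    @property
    def chains(self) -> list[ChainAlignment]:
        return self.truth.chains

    @property
    def genepages(self) -> pd.DataFrame:
        return self.truth.genepages


# ---------------------------------------------------------------------------
# genomes, chains, gene pages

GENE_SPAN = 1700  # 3 exons of 300 bp, 2 introns of 400 bp
GENE_OFFSET = 3000  # upstream padding so slot-0 enhancers stay on-chromosome


def _gene_model(gene_id: str, chrom: str, start: int, strand: str,
                biotype: str) -> Gene:
    iv = GenomicInterval(chrom, start, start + GENE_SPAN, strand)
    tx = Transcript(f"{gene_id}.t1", iv)
    for k in range(3):
        s = start + k * 700
        tx.exons.append(GenomicInterval(chrom, s, s + 300, strand))
    g = Gene(gene_id, iv, biotype)
    g.transcripts.append(tx)
    return g


def simulate_genomes(
    cfg: SimConfig,
) -> tuple[GenomeAnnotation, list[ChainAlignment], pd.DataFrame]:
    """Two co-linear subgenomes with indels, homeolog pairs and singletons.

    Returns the annotation (both subgenomes), chains in both directions
    (L->S and S->L, block-exact, reciprocal) and the gene-page pairing
    table with columns ``genepage_id``, ``L_gene``, ``S_gene``.
    """
    rng = cfg.rng(1)
    annot = GenomeAnnotation()
    pages = []
    chains: list[ChainAlignment] = []

    per_pair = [cfg.n_genepages // cfg.n_chrom_pairs] * cfg.n_chrom_pairs
    per_pair[-1] += cfg.n_genepages - sum(per_pair)

    page_no = 0
    biotype_pool = ["protein_coding"] * 8 + ["lncRNA", "pseudogene"]
    for ci in range(cfg.n_chrom_pairs):
        n_slots = per_pair[ci]
        chrom_l = f"chr{ci + 1}L"
        chrom_s = f"chr{ci + 1}S"
        len_l = n_slots * cfg.gene_step + 2 * GENE_OFFSET

        # indels between genes, inside [slot_end+100, slot_end+600]
        p_indel = min(1.0, cfg.chain_indel_rate * cfg.gene_step)
        t_gap_at: list[tuple[int, int, int]] = []  # (t_pos, dt, dq)
        for slot in range(n_slots - 1):
            if rng.random() < p_indel:
                pos = GENE_OFFSET + slot * cfg.gene_step + GENE_SPAN + 100 + int(
                    rng.integers(0, 500)
                )
                size = int(rng.integers(*cfg.indel_size_range))
                if rng.random() < 0.5:
                    t_gap_at.append((pos, size, 0))  # deletion in S
                else:
                    t_gap_at.append((pos, 0, size))  # insertion in S

        # chain blocks L (target) -> S (query)
        sizes, t_starts, q_starts = [], [], []
        t_pos, q_pos = 0, 0
        for pos, dt, dq in t_gap_at:
            sizes.append(pos - t_pos)
            t_starts.append(t_pos)
            q_starts.append(q_pos)
            t_pos = pos + dt
            q_pos = q_pos + (pos - t_starts[-1]) + dq
        sizes.append(len_l - t_pos)
        t_starts.append(t_pos)
        q_starts.append(q_pos)
        len_s = q_starts[-1] + sizes[-1]

        def _mk_chain(cid, tn, ts, qn, qs, sz, tst, qst):
            sz = np.array(sz, dtype=np.int64)
            return ChainAlignment(
                score=float(sz.sum()), t_name=tn, t_size=ts,
                t_start=int(tst[0]), t_end=int(tst[-1] + sz[-1]),
                q_name=qn, q_size=qs, q_strand="+",
                q_start=int(qst[0]), q_end=int(qst[-1] + sz[-1]),
                chain_id=cid,
                sizes=sz, t_starts=np.array(tst, dtype=np.int64),
                q_starts=np.array(qst, dtype=np.int64),
            )

        chains.append(_mk_chain(2 * ci + 1, chrom_l, len_l, chrom_s, len_s,
                                sizes, t_starts, q_starts))
        chains.append(_mk_chain(2 * ci + 2, chrom_s, len_s, chrom_l, len_l,
                                sizes, q_starts, t_starts))
        annot.chrom_lengths[chrom_l] = len_l
        annot.chrom_lengths[chrom_s] = len_s

        l_to_s = chains[-2]
        offsets = np.asarray(
            [l_to_s.q_starts[k] - l_to_s.t_starts[k]
             for k in range(len(sizes))]
        )

        def _s_coord(pos_l: int) -> int:
            idx = np.searchsorted(l_to_s.t_starts, pos_l, side="right") - 1
            return int(pos_l + offsets[max(idx, 0)])

        for slot in range(n_slots):
            page_no += 1
            page_id = f"page{page_no:05d}"
            start_l = GENE_OFFSET + slot * cfg.gene_step
            strand = "-" if slot % 7 == 3 else "+"
            biotype = biotype_pool[int(rng.integers(0, len(biotype_pool)))]
            u = rng.random()
            has_l = u >= cfg.frac_singleton_S
            has_s = (u >= cfg.frac_singleton_S + cfg.frac_singleton_L) or (
                u < cfg.frac_singleton_S
            )
            l_gene = s_gene = ""
            if has_l:
                l_gene = f"g{page_no:05d}.L"
                annot.add_gene(_gene_model(l_gene, chrom_l, start_l, strand,
                                           biotype))
            if has_s:
                s_gene = f"g{page_no:05d}.S"
                annot.add_gene(
                    _gene_model(s_gene, chrom_s, _s_coord(start_l), strand,
                                biotype)
                )
            pages.append({"genepage_id": page_id, "L_gene": l_gene,
                          "S_gene": s_gene})

    genepages = pd.DataFrame(pages)
    return annot, chains, genepages


# ---------------------------------------------------------------------------
# ground truth assignment


def make_ground_truth(cfg: SimConfig, annot: GenomeAnnotation,
                      chains: list[ChainAlignment],
                      genepages: pd.DataFrame) -> GroundTruth:
    """Assign activation, homeolog-bias, enhancer and binding truth."""
    rng = cfg.rng(2)
    mix = np.asarray(cfg.homeolog_bias_mix)

    page_rows, gene_rows = [], []
    for rec in genepages.itertuples():
        has_l, has_s = bool(rec.L_gene), bool(rec.S_gene)
        activated = rng.random() < cfg.frac_activated
        if not (has_l and has_s):
            klass = "singleton_L" if has_l else "singleton_S"
        elif not activated:
            klass = "not_activated"
        else:
            klass = PAIRED_CLASSES[int(rng.choice(4, p=mix))]
        if klass == "both_asymmetric":
            biased_side = "L" if rng.random() < 0.5 else "S"
        else:
            biased_side = ""

        first_wave = activated and (
            rng.random() < cfg.frac_first_wave_of_activated
        )
        mo_target = activated and (rng.random() < cfg.frac_mo_target)
        fold = (2.0 ** cfg.activation_log2fc - 1.0) * (
            2.0 ** rng.normal(0.0, cfg.activation_log2_sd)
        )

        side_gain = {"L": 0.0, "S": 0.0}
        if activated:
            if klass in ("L_only", "singleton_L"):
                side_gain["L"] = fold
            elif klass in ("S_only", "singleton_S"):
                side_gain["S"] = fold
            elif klass == "both_symmetric":
                side_gain["L"] = side_gain["S"] = fold
            elif klass == "both_asymmetric":
                hi, lo = fold, fold / 2.0 ** cfg.bias_delta_log2
                if biased_side == "L":
                    side_gain["L"], side_gain["S"] = hi, lo
                else:
                    side_gain["L"], side_gain["S"] = lo, hi

        page_rows.append({
            "genepage_id": rec.genepage_id, "L_gene": rec.L_gene,
            "S_gene": rec.S_gene, "klass": klass, "biased_side": biased_side,
            "activated": activated, "first_wave": first_wave,
            "mo_target": mo_target,
        })
        for side, gid in (("L", rec.L_gene), ("S", rec.S_gene)):
            if not gid:
                continue
            gene = annot.genes[gid]
            maternal = rng.random() < cfg.frac_maternal
            if maternal:
                m = 2.0 ** rng.normal(cfg.maternal_log2_mean,
                                      cfg.maternal_log2_sd)
            else:
                m = 2.0 ** rng.uniform(*cfg.zygotic_low_log2_range)
            gain = side_gain[side] * cfg.zygotic_unit
            gene_rows.append({
                "gene_id": gid, "genepage_id": rec.genepage_id,
                "subgenome": side, "chrom": gene.chrom,
                "start": gene.interval.start, "end": gene.interval.end,
                "strand": gene.strand, "biotype": gene.biotype,
                "maternal": maternal, "maternal_mean": m,
                "activated": gain > 0.0, "first_wave": first_wave and gain > 0,
                "mo_target": mo_target and gain > 0,
                "exon_gain": gain, "intron_gain": gain * cfg.intron_fraction,
            })

    truth = GroundTruth(cfg, annot, chains, genepages,
                        genes=pd.DataFrame(gene_rows).set_index(
                            "gene_id", drop=False),
                        pages=pd.DataFrame(page_rows).set_index(
                            "genepage_id", drop=False))
    truth.elements = _make_element_truth(cfg, truth, rng)

    # the distal/proximal truth is the rule itself: distance from element
    # center to the nearest representative TSS of any annotated gene
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in truth.genes.itertuples():
        tss_by_chrom.setdefault(g.chrom, []).append(
            _tss(g.start, g.end, g.strand)
        )
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    def _near_tss(chrom: str, center: int) -> bool:
        if chrom not in tss_by_chrom:
            return False
        arr = tss_by_chrom[chrom]
        j = int(np.searchsorted(arr, center))
        d = min(abs(center - arr[j - 1]) if j > 0 else np.inf,
                abs(arr[j] - center) if j < len(arr) else np.inf)
        return d <= 1000

    truth.elements["prox"] = [
        _near_tss(el.chrom, el.center)
        for el in truth.elements.itertuples()
    ]
    return truth


def _tss(start: int, end: int, strand: str) -> int:
    return start if strand != "-" else end - 1


def _make_element_truth(cfg: SimConfig, truth: GroundTruth,
                        rng: np.random.Generator) -> pd.DataFrame:
    l_to_s = {c.t_name: c for c in truth.chains
              if c.t_name.endswith("L")}
    rows = []
    eid = 0
    for page in truth.pages.itertuples():
        ref_gid = page.L_gene or page.S_gene
        g = truth.genes.loc[ref_gid]
        # element coordinates are laid out on L and mapped through the chain
        if g["subgenome"] == "L":
            chrom_l = g["chrom"]
            tss_l = _tss(g["start"], g["end"], g["strand"])
        else:
            chrom_l = g["chrom"].replace("S", "L")
            # co-linear layout: same slot position on L
            back = {c.t_name: c for c in truth.chains}[g["chrom"]]
            pos = back.map_base(_tss(g["start"], g["end"], g["strand"]))
            tss_l = pos if pos is not None else g["start"]
        chain = l_to_s[chrom_l]

        for k in range(cfg.enhancer_per_gene):
            prox = rng.random() < cfg.frac_prox
            dist = 500 if prox else 1500 + int(rng.integers(-150, 150))
            sign = -1 if g["strand"] != "-" else 1
            center_l = int(tss_l + sign * (dist + 600 * k))
            center_s = chain.map_base(center_l)
            if center_s is None:  # nudge onto an aligned base
                for shift in range(1, 300):
                    center_s = chain.map_base(center_l + shift)
                    if center_s is not None:
                        center_l += shift
                        break
            klass = page.klass
            if not page.activated:
                act_l = act_s = False
            elif klass == "both_symmetric":
                act_l, act_s = True, True
            elif klass == "both_asymmetric":
                if rng.random() < cfg.frac_enhancer_conserved:
                    act_l = act_s = True
                else:
                    act_l = page.biased_side == "L"
                    act_s = page.biased_side == "S"
            elif klass in ("L_only", "singleton_L"):
                act_l, act_s = True, False
            elif klass in ("S_only", "singleton_S"):
                act_l, act_s = False, True
            else:
                act_l = act_s = False
            hi = rng.random() < cfg.frac_hi
            for side, chrom, center, active, p_active in (
                ("L", chrom_l, center_l, act_l, act_s),
                ("S", chain.q_name, center_s, act_s, act_l),
            ):
                if center is None:
                    continue
                eid += 1
                rows.append({
                    "element_id": f"e{eid:05d}",
                    "genepage_id": page.genepage_id,
                    "side": side, "chrom": chrom, "center": int(center),
                    "active": bool(active),
                    "tier": ("hi" if hi else "lo") if active else "rejected",
                    "conserved": bool(active and p_active),
                    "tf_bound": bool(active and page.mo_target),
                    "prox": prox,
                })
    return pd.DataFrame(rows).set_index("element_id", drop=False)


# ---------------------------------------------------------------------------
# counts


def expected_means(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Expected NB means per feature (exon/intron rows) and condition.

    Encodes the study design: triptolide removes all zygotic signal,
    cycloheximide spares only first-wave genes, and the morpholino removes
    zygotic signal of the flagged target subset.  Batch and depth effects
    are applied downstream.
    """
    g = truth.genes
    m = g["maternal_mean"].values
    ex, inx = g["exon_gain"].values, g["intron_gain"].values
    fw, mo = g["first_wave"].values, g["mo_target"].values
    bg = cfg.intron_background

    def cond(exon_z, intron_z):
        return m + exon_z, bg + intron_z

    z = np.ones(len(g))
    zero = np.zeros(len(g))
    fw_z = np.where(fw, 1.0, 0.0)
    not_mo = np.where(mo, 0.0, 1.0)
    table = {
        "stage5": cond(zero, zero),
        "stage8": cond(0.25 * ex, 0.25 * inx),
        "stage9_DMSO": cond(ex * z, inx * z),
        "stage9_triptolide": cond(zero, zero),
        "stage9_CHX": cond(ex * fw_z, inx * fw_z),
        "stage9_CHX_trip": cond(zero, zero),
        "stage9_MO": cond(ex * not_mo, inx * not_mo),
        "stage9_MO_CHX": cond(ex * fw_z * not_mo, inx * fw_z * not_mo),
    }
    out = {}
    for c, (e_mu, i_mu) in table.items():
        out[("exon", c)] = e_mu
        out[("intron", c)] = i_mu
    df = pd.DataFrame(out, index=g["gene_id"].values)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["part", "cond"])
    return df


EXON_LEN = 900
INTRON_LEN = 800


def simulate_counts(cfg: SimConfig, truth: GroundTruth) -> CountsExperiment:
    """NB counts for all conditions x 2 batches x n_replicates."""
    rng = cfg.rng(3)
    mus = expected_means(cfg, truth)
    gene_ids = list(mus.index)

    samples = []
    for cond in CONDITIONS:
        for batch in ("a", "b"):
            for rep in range(1, cfg.n_replicates + 1):
                samples.append({
                    "sample_id": f"{cond}_{batch}{rep}",
                    "condition": cond, "batch": batch,
                })
    samples = pd.DataFrame(samples)

    feats = []
    for part in ("exon", "intron"):
        for gid in gene_ids:
            feats.append({
                "feature_id": gid if part == "exon" else f"i_{gid}",
                "gene_id": gid, "part": part,
                "length": EXON_LEN if part == "exon" else INTRON_LEN,
            })
    features = pd.DataFrame(feats)

    maternal_mean = truth.genes["maternal_mean"].values
    counts = np.zeros((len(features), len(samples)), dtype=np.int64)
    disp = cfg.nb_dispersion
    n_genes = len(gene_ids)
    for j, s in samples.iterrows():
        depth = 2.0 ** rng.normal(0.0, cfg.depth_log2_sd)
        bfac = cfg.batch_maternal_factor if s["batch"] == "b" else 1.0
        e_mu = mus[("exon", s["condition"])].values.copy()
        i_mu = mus[("intron", s["condition"])].values
        # batch effect acts on the maternal contribution only
        e_mu = e_mu + (bfac - 1.0) * maternal_mean
        mu = np.concatenate([e_mu, i_mu]) * depth
        r = 1.0 / disp
        p = r / (r + np.maximum(mu, 1e-12))
        draw = rng.negative_binomial(r, p)
        draw[mu <= 0] = 0
        counts[:, j] = draw
    assert counts.shape[0] == 2 * n_genes
    return CountsExperiment(features, samples, counts)


# ---------------------------------------------------------------------------
# coverage tracks and summits

TRACK_ASSAYS = ("h3k27ac", "atac", "noab", "pou5f3", "sox3")


def _gaussian_bump(arr: np.ndarray, center: int, amplitude: float,
                   sd: float) -> None:
    lo = max(0, int(center - 4 * sd))
    hi = min(len(arr), int(center + 4 * sd) + 1)
    if lo >= hi:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] += amplitude * np.exp(-0.5 * ((x - center) / sd) ** 2)


def simulate_tracks(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[dict[str, list[CoverageTrack]], list[GenomicInterval]]:
    """Replicate-level coverage tracks and the summit BED.

    'hi'-truth elements get H3K27ac/ATAC bumps in all 3 replicates,
    'lo'-truth elements in exactly 2, inactive elements in none; the
    no-antibody tracks are flat background.  TF tracks carry ``tf_effect``
    bumps at TF-bound elements only.  Summits list all element centers,
    active and inactive alike.
    """
    rng = cfg.rng(4)
    chrom_lengths = truth.annot.chrom_lengths
    n_reps = {"h3k27ac": 3, "atac": 3, "noab": 3, "pou5f3": 1, "sox3": 1}

    base: dict[str, dict[str, np.ndarray]] = {}
    for assay in TRACK_ASSAYS:
        for rep in range(n_reps[assay]):
            key = f"{assay}_{rep + 1}"
            base[key] = {
                c: np.full(ln, cfg.track_background)
                for c, ln in chrom_lengths.items()
            }

    for el in truth.elements.itertuples():
        if el.active:
            supported = [0, 1, 2] if el.tier == "hi" else [0, 1]
            for assay in ("h3k27ac", "atac"):
                for rep in supported:
                    _gaussian_bump(base[f"{assay}_{rep + 1}"][el.chrom],
                                   el.center, cfg.track_amplitude,
                                   cfg.bump_sd)
        if el.tf_bound:
            for assay in ("pou5f3", "sox3"):
                _gaussian_bump(base[f"{assay}_1"][el.chrom], el.center,
                               cfg.tf_effect, cfg.bump_sd)

    tracks: dict[str, list[CoverageTrack]] = {a: [] for a in TRACK_ASSAYS}
    for assay in TRACK_ASSAYS:
        for rep in range(n_reps[assay]):
            key = f"{assay}_{rep + 1}"
            arrays = {}
            for chrom, arr in base[key].items():
                if cfg.track_noise_sd > 0:
                    nbin = cfg.track_noise_bin
                    nb = math.ceil(len(arr) / nbin)
                    noise = rng.normal(0.0, cfg.track_noise_sd, nb)
                    arr = arr + np.repeat(noise, nbin)[: len(arr)]
                arrays[chrom] = np.maximum(arr, 0.0)
            tracks[assay].append(
                CoverageTrack.from_dense(arrays, cfg.track_library, key)
            )

    summits = [
        GenomicInterval(el.chrom, el.center, el.center + 1)
        for el in truth.elements.itertuples()
    ]
    return tracks, summits


# ---------------------------------------------------------------------------
# outgroup transcriptome


def simulate_outgroup(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Diploid outgroup expression: L+S composite x lognormal noise.

    Returns columns ``genepage_id``, ``outgroup_gene``, ``tpm``.  The
    composite is the expected stage-9 exon output of the page's genes, on
    an arbitrary common scale, so that a homeolog split within a page never
    changes the outgroup value.
    """
    rng = cfg.rng(5)
    g = truth.genes
    stage9 = g["maternal_mean"].values + g["exon_gain"].values
    composite = pd.Series(stage9, index=g["genepage_id"].values).groupby(
        level=0
    ).sum()
    rows = []
    for page in truth.pages.itertuples():
        level = composite.get(page.genepage_id, 0.0)
        noise = 2.0 ** rng.normal(0.0, cfg.outgroup_noise_sd)
        rows.append({
            "genepage_id": page.genepage_id,
            "outgroup_gene": f"og_{page.genepage_id}",
            "tpm": float(level * noise),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration and file output


def simulate_dataset(cfg: SimConfig | None = None) -> SyntheticDataset:
    """Run the full generator and bundle everything with its ground truth."""
    cfg = cfg or SimConfig()
    annot, chains, genepages = simulate_genomes(cfg)
    truth = make_ground_truth(cfg, annot, chains, genepages)
    counts = simulate_counts(cfg, truth)
    tracks, summits = simulate_tracks(cfg, truth)
    outgroup = simulate_outgroup(cfg, truth)
    return SyntheticDataset(truth, counts, tracks, summits, outgroup)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the dataset as GFF3/chain/bedGraph/BED/TSV/YAML files."""
    import pathlib
    import yaml

    from . import core_io

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    core_io.write_gff3(ds.annot, out / "annotation.gff3")
    core_io.write_chain(ds.chains, out / "subgenomes.chain")
    ds.genepages.to_csv(out / "genepages.tsv", sep="\t", index=False)
    core_io.write_counts_tsv(ds.counts, out / "counts.tsv")
    core_io.write_bed(ds.summits, out / "summits.bed")
    ds.outgroup.to_csv(out / "outgroup.tsv", sep="\t", index=False)
    ds.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    ds.truth.pages.to_csv(out / "truth_pages.tsv", sep="\t", index=False)
    ds.truth.elements.to_csv(out / "truth_elements.tsv", sep="\t",
                             index=False)

    sheet = []
    for assay, reps in ds.tracks.items():
        for track in reps:
            path = out / f"{track.label}.bedgraph"
            core_io.write_bedgraph(track, path)
            sheet.append({
                "sample_id": track.label, "assay": assay,
                "library_size": track.library_size,
                "path": path.name,
            })
    with open(out / "samples.yaml", "w") as fh:
        yaml.safe_dump({"tracks": sheet,
                        "config": asdict(ds.truth.cfg)}, fh)
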