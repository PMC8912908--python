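"""Synthetic cardiovascular cohorts with planted, recoverable structure.

The generator emulates the statistical structure the analysis assumes:
three healthy tissue groups (fetal-like cardiovascular progenitors, adult
heart, adult arteria) plus paired pre/post-LVAD heart-failure samples;
cell-type mixtures drawn per tissue from Dirichlet distributions; stage
effects concentrated in a designated RNA-binding-protein gene panel;
isoform switching with a tunable heart-failure reversion fraction; an
internally consistent annotation + genome so exon windows are extractable;
eCLIP-style peaks enriched on switch genes; and a labeled single-cell
negative-binomial count matrix for marker finding.  Everything planted is
recorded in :class:`GroundTruth` so each downstream stage has a recovery
test.

Bulk expression model, per gene g and sample i of tissue t:

    TPM[g, i] = (sum_k prop[i, k] * signature[g, k]) * 2^(stage_effect[g] * f(t))
                * 2^(sigma * Z[g, i])

with f = 1 for the fetal-like tissue, 0 for adult tissues, and a partial
reactivation factor for pre-LVAD heart failure.  Isoform TPMs partition the
gene TPM through a per-sample usage simplex (logistic-normal jitter around
tissue-level usage), so isoform TPMs sum exactly to the gene TPM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (DomainRecord, ExonRecord, FeatureMatrix, GeneRecord, Genome,
                 GeneSet, PeakSet, PWM, SampleRecord, TranscriptAnnotation,
                 revcomp)

CELL_TYPES = ("cardiac_muscle", "cardiac_neuron", "endothelial",
              "fibroblast", "immune", "smooth_muscle")

#: per-tissue Dirichlet concentrations; the fetal-like tissue carries almost
#: no fibroblast/immune mass
DIRICHLET = {
    "iPSC-CVPC":     {"cardiac_muscle": 30, "cardiac_neuron": 4, "endothelial": 8,
                      "fibroblast": 0.25, "immune": 0.25, "smooth_muscle": 8},
    "adult_heart":   {"cardiac_muscle": 25, "cardiac_neuron": 2, "endothelial": 8,
                      "fibroblast": 10, "immune": 4, "smooth_muscle": 4},
    "adult_arteria": {"cardiac_muscle": 1, "cardiac_neuron": 1, "endothelial": 10,
                      "fibroblast": 10, "immune": 4, "smooth_muscle": 25},
    "HF_pre":        {"cardiac_muscle": 22, "cardiac_neuron": 2, "endothelial": 8,
                      "fibroblast": 11, "immune": 5, "smooth_muscle": 5},
    "HF_post":       {"cardiac_muscle": 22, "cardiac_neuron": 2, "endothelial": 8,
                      "fibroblast": 10, "immune": 4, "smooth_muscle": 7},
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    n_ipsc: int = 40
    n_heart: int = 40
    n_arteria: int = 30
    n_hf_pairs: int = 8
    n_genes: int = 2000
    frac_multi_isoform: float = 0.5          # 2-4 isoforms each
    n_stage_de: int = 300                    # |log2FC| ~ U(2.5, 4)
    stage_lfc_range: tuple = (2.5, 4.0)
    n_rbp: int = 120                         # designated RBP panel
    rbp_fetal_bias: float = 0.85             # P(fetal-up) for stage-DE RBPs
    n_switch: int = 250                      # switch isoform pairs
    switch_delta_range: tuple = (0.3, 0.6)   # usage shift
    frac_strong_switch: float = 0.4          # pairs with >4-fold usage ratios
    hf_reversion_frac: float = 0.5           # rho: switch pairs reverting pre-LVAD
    hf_reversion_strength: float = 0.8       # how far pre-LVAD usage moves to fetal
    hf_rbp_reactivation: float = 0.5         # fraction of stage effect in pre-LVAD RBPs
    n_hf_private_switch: int = 60            # disease-specific usage shifts (pre-LVAD
    hf_private_delta_range: tuple = (0.2, 0.4)  # only), unrelated to the fetal program
    noise_sigma: float = 0.25                # lognormal sigma on log2 scale
    usage_logit_sd: float = 0.25             # per-sample usage jitter
    marker_frac_per_type: float = 0.06
    marker_lfc_range: tuple = (2.0, 4.0)
    background_type_sd: float = 0.05         # residual cell-type variation (log2)
    n_eclip_experiments: int = 8
    peak_p_specific: float = 0.6
    peak_p_background: float = 0.3
    n_pwms: int = 6
    motif_rate_set1: float = 0.6             # plant rate in fetal-exon windows
    motif_rate_set2: float = 0.2
    domain_p_fetal_exon: float = 0.55        # P(exon overlaps a protein domain)
    domain_p_other_exon: float = 0.35
    #: splice-site composition of switch-exon flanks: the fetal-preferred
    #: alternative exons get a stronger polypyrimidine tract
    splice_canonical_p: float = 0.9
    splice_ppt_t_fetal: float = 0.55
    splice_ppt_t_adult: float = 0.30
    sc_cells_per_type: int = 200
    sc_dispersion: float = 0.5
    sc_depth: int = 10000
    #: draw every tissue's mixture from the same Dirichlet, isolating planted
    #: stage effects from composition differences (the controlled condition
    #: for null-calibration and recovery experiments)
    equal_composition: bool = False
    mito_coupling: float = 0.1               # pct_mito per unit cardiac muscle
    mito_noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_stage_de > self.n_genes:
            raise ValueError("more stage-DE genes requested than genes")
        for name in ("frac_multi_isoform", "rbp_fetal_bias", "hf_reversion_frac",
                     "frac_strong_switch", "peak_p_specific", "peak_p_background",
                     "motif_rate_set1", "motif_rate_set2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_switch > int(self.n_genes * self.frac_multi_isoform):
            raise ValueError("more switch pairs requested than multi-isoform genes")


@dataclass
class GroundTruth:
    """Record of everything planted by the generator."""

    proportions: pd.DataFrame            # sample x cell type (true simplex)
    stage_de: pd.Series                  # gene -> signed log2FC (fetal vs adult)
    rbp_genes: list[str]
    switch_table: pd.DataFrame           # gene, iso_fetal, iso_adult, delta, strong, reverts
    marker_genes: dict[str, set[str]]
    peak_enriched_genes: set[str]
    signatures: pd.DataFrame             # gene x cell type mean expression
    motif_planted: dict[str, set[str]]   # pwm id -> exon ids with planted site
    tissue_usage: dict[str, pd.Series]   # tissue -> isoform -> expected usage
    hf_private_isoforms: set[str] = field(default_factory=set)
    splice_planted: dict = field(default_factory=dict)


@dataclass
class Cohort:
    config: SimConfig
    samples: list[SampleRecord]
    gene_tpm: FeatureMatrix
    iso_tpm: FeatureMatrix
    annotation: TranscriptAnnotation
    genome: Genome
    peaksets: list[PeakSet]
    pwms: list[PWM]
    gene_sets: list[GeneSet]
    domains: list[DomainRecord]
    sc_counts: pd.DataFrame              # cells x genes
    sc_labels: pd.Series
    truth: GroundTruth

    def samples_frame(self) -> pd.DataFrame:
        from .io import samples_to_frame
        return samples_to_frame(self.samples)


def _random_seq(rng, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _build_annotation_genome(cfg: SimConfig, rng, gene_ids, multi_mask,
                             n_iso_per_gene):
    """Lay genes on synthetic chromosomes; one chromosome per ~100 genes.

    Multi-isoform genes get a shared first/last exon plus one distinctive
    alternative exon per isoform, so isoform-level specificity translates
    into exon-level set differences.  Canonical GT/AG dinucleotides are
    written at every intron boundary.
    """
    genes: dict[str, GeneRecord] = {}
    transcripts: dict[str, list[str]] = {}
    exons: dict[str, ExonRecord] = {}
    transcript_gene: dict[str, str] = {}
    chrom_arrays: dict[str, np.ndarray] = {}
    iso_ids_per_gene: dict[str, list[str]] = {}
    alt_exon_of_iso: dict[str, str] = {}

    per_chrom = 100
    genes_by_chrom: dict[str, list[int]] = {}
    for gi in range(len(gene_ids)):
        genes_by_chrom.setdefault(f"chr{gi // per_chrom + 1}", []).append(gi)

    for chrom, idxs in genes_by_chrom.items():
        pos = 1000
        records = []  # (gi, exon starts/ends)
        for gi in idxs:
            gid = gene_ids[gi]
            strand = "+" if rng.random() < 0.5 else "-"
            n_iso = n_iso_per_gene[gi]
            n_ex = (n_iso + 2) if multi_mask[gi] else int(rng.integers(2, 4))
            lens = rng.integers(80, 300, size=n_ex)
            intr = rng.integers(250, 800, size=n_ex)
            starts, ends = [], []
            for k in range(n_ex):
                starts.append(pos)
                ends.append(pos + int(lens[k]))
                pos = ends[-1] + int(intr[k])
            pos += 1000
            eids = [f"{gid}_E{k}" for k in range(n_ex)]
            for k, eid in enumerate(eids):
                exons[eid] = ExonRecord(eid, chrom, starts[k], ends[k], strand)
            # transcription order
            order = eids if strand == "+" else eids[::-1]
            gene = GeneRecord(gid, gid, strand)
            genes[gid] = gene
            iso_ids = [f"{gid}_T{t}" for t in range(n_iso)]
            iso_ids_per_gene[gid] = iso_ids
            for t, tid in enumerate(iso_ids):
                if multi_mask[gi]:
                    # shared flanks + one distinctive internal exon per isoform
                    alt = eids[1 + t]
                    sel = {eids[0], alt, eids[-1]}
                    alt_exon_of_iso[tid] = alt
                else:
                    sel = set(eids)
                tx = [e for e in order if e in sel]
                transcripts[tid] = tx
                transcript_gene[tid] = gid
                gene.transcript_ids.append(tid)
            records.append((gi, starts, ends, strand))
        seq = _random_seq(rng, pos + 1000)
        # canonical splice dinucleotides at intron boundaries
        for gi, starts, ends, strand in records:
            for s, e in zip(starts, ends):
                if strand == "+":
                    seq[e:e + 2] = np.frombuffer(b"GT", dtype=np.uint8)
                    seq[s - 2:s] = np.frombuffer(b"AG", dtype=np.uint8)
                else:
                    seq[s - 2:s] = np.frombuffer(b"AC", dtype=np.uint8)
                    seq[e:e + 2] = np.frombuffer(b"CT", dtype=np.uint8)
        chrom_arrays[chrom] = seq

    ann = TranscriptAnnotation(genes, transcripts, exons, transcript_gene)
    return ann, chrom_arrays, iso_ids_per_gene, alt_exon_of_iso


def _make_pwms(cfg: SimConfig, rng) -> list[PWM]:
    pwms = []
    for m in range(cfg.n_pwms):
        L = int(rng.integers(6, 9))
        cons = rng.integers(0, 4, size=L)
        cols = np.full((L, 4), 0.05)
        cols[np.arange(L), cons] = 0.85
        pwms.append(PWM(f"M{m:02d}", f"RBP{m:02d}", cols))
    return pwms


def _plant_flanks(seq_arr, exon, profiles, rng, window=100):
    """Draw the exon's acceptor and donor flank windows from per-position
    base probabilities (written in transcription orientation)."""
    acc = _draw_profile_seq(rng, np.asarray(profiles["acceptor"], float))
    don = _draw_profile_seq(rng, np.asarray(profiles["donor"], float))
    if exon.strand == "+":
        seq_arr[exon.start - window:exon.start] = acc
        seq_arr[exon.end:exon.end + window] = don
    else:
        seq_arr[exon.end:exon.end + window] = _rc_arr(acc)
        seq_arr[exon.start - window:exon.start] = _rc_arr(don)


def _plant_motif(seq_arr, exon, pwm, rng, window=100):
    """Write the PWM consensus into the acceptor window (100 nt upstream of
    the exon start in transcription orientation)."""
    cons = pwm.consensus()
    off = int(rng.integers(0, window - len(cons)))
    if exon.strand == "+":
        start = exon.start - window + off
        seq_arr[start:start + len(cons)] = np.frombuffer(cons.encode(), dtype=np.uint8)
    else:
        rc = revcomp(cons)
        start = exon.end + window - off - len(cons)
        seq_arr[start:start + len(cons)] = np.frombuffer(rc.encode(), dtype=np.uint8)


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate a full synthetic cohort; same seed gives bit-identical output."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{g:04d}" for g in range(cfg.n_genes)]

    # --- gene architecture -------------------------------------------------
    n_multi = int(round(cfg.n_genes * cfg.frac_multi_isoform))
    multi_idx = rng.choice(cfg.n_genes, size=n_multi, replace=False)
    multi_mask = np.zeros(cfg.n_genes, dtype=bool)
    multi_mask[multi_idx] = True
    n_iso_per_gene = np.where(multi_mask, rng.integers(2, 5, size=cfg.n_genes), 1)

    ann, chrom_arrays, iso_ids_per_gene, alt_exon_of_iso = \
        _build_annotation_genome(cfg, rng, gene_ids, multi_mask, n_iso_per_gene)

    # --- cell-type signatures and markers ----------------------------------
    base = 2.0 ** rng.normal(4.3, 1.5, size=cfg.n_genes)
    log2_mult = rng.normal(0.0, cfg.background_type_sd,
                           size=(cfg.n_genes, len(CELL_TYPES)))
    marker_genes: dict[str, set[str]] = {}
    n_mark = int(round(cfg.n_genes * cfg.marker_frac_per_type))
    free = rng.permutation(cfg.n_genes)
    cursor = 0
    for k, ct in enumerate(CELL_TYPES):
        idx = free[cursor:cursor + n_mark]
        cursor += n_mark
        log2_mult[idx, :] = 0.0
        log2_mult[idx, k] = rng.uniform(*cfg.marker_lfc_range, size=len(idx))
        marker_genes[ct] = {gene_ids[i] for i in idx}
    signatures = pd.DataFrame(base[:, None] * 2.0 ** log2_mult,
                              index=gene_ids, columns=list(CELL_TYPES))

    # --- stage effects: concentrated in the RBP panel -----------------------
    rbp_genes = [gene_ids[i] for i in rng.choice(cfg.n_genes, cfg.n_rbp, replace=False)]
    n_rbp_de = min(len(rbp_genes), cfg.n_stage_de // 3)
    rbp_de = list(rng.choice(rbp_genes, size=n_rbp_de, replace=False))
    others = [g for g in gene_ids if g not in set(rbp_de)]
    other_de = list(rng.choice(others, size=cfg.n_stage_de - n_rbp_de, replace=False))
    de_genes = rbp_de + other_de
    mag = rng.uniform(*cfg.stage_lfc_range, size=cfg.n_stage_de)
    sign = np.concatenate([
        np.where(rng.random(n_rbp_de) < cfg.rbp_fetal_bias, 1.0, -1.0),
        np.where(rng.random(len(other_de)) < 0.5, 1.0, -1.0),
    ])
    stage_de = pd.Series(mag * sign, index=de_genes)
    stage_vec = pd.Series(0.0, index=gene_ids)
    stage_vec.loc[de_genes] = stage_de

    # --- samples ------------------------------------------------------------
    samples: list[SampleRecord] = []
    tissue_of: list[str] = []
    spec = ([("iPSC-CVPC", cfg.n_ipsc), ("adult_heart", cfg.n_heart),
             ("adult_arteria", cfg.n_arteria)])
    sid = 0
    subj = 0
    for tissue, n in spec:
        for _ in range(n):
            samples.append(_draw_sample(rng, f"S{sid:04d}", f"SUBJ{subj:04d}", tissue))
            tissue_of.append(tissue)
            sid += 1
            subj += 1
    for k in range(cfg.n_hf_pairs):
        subject = f"HFSUBJ{k:03d}"
        for tissue in ("HF_pre", "HF_post"):
            samples.append(_draw_sample(rng, f"S{sid:04d}", subject, tissue))
            tissue_of.append(tissue)
            sid += 1
    sample_ids = [s.sample_id for s in samples]
    n_samples = len(samples)

    # --- proportions --------------------------------------------------------
    props = np.zeros((n_samples, len(CELL_TYPES)))
    for i, t in enumerate(tissue_of):
        key = "adult_heart" if cfg.equal_composition else t
        conc = np.array([DIRICHLET[key][c] for c in CELL_TYPES])
        props[i] = rng.dirichlet(conc)
    proportions = pd.DataFrame(props, index=sample_ids, columns=list(CELL_TYPES))
    # mitochondrial load tracks cardiac-muscle content, with individual spread
    for s, cm in zip(samples, props[:, 0]):
        s.pct_mito = float(np.clip(
            0.03 + cfg.mito_coupling * cm + rng.normal(0, cfg.mito_noise_sd),
            0.01, 0.5))
        s.pct_autosomal = float(min(1.0 - s.pct_mito - rng.uniform(0.005, 0.02),
                                    1.0 - s.pct_mito))

    # --- bulk gene expression ----------------------------------------------
    expected = props @ signatures.to_numpy().T          # samples x genes
    stage_factor = np.zeros((n_samples, cfg.n_genes))
    is_fetal = np.array([t == "iPSC-CVPC" for t in tissue_of], dtype=float)
    stage_factor += np.outer(is_fetal, stage_vec.to_numpy())
    # pre-LVAD partially reactivates the fetal program of stage-DE RBPs
    is_pre = np.array([t == "HF_pre" for t in tissue_of], dtype=float)
    rbp_stage = stage_vec.copy()
    rbp_stage.loc[[g for g in gene_ids if g not in set(rbp_de)]] = 0.0
    stage_factor += cfg.hf_rbp_reactivation * np.outer(is_pre, rbp_stage.to_numpy())
    noise = rng.normal(0.0, cfg.noise_sigma, size=(n_samples, cfg.n_genes))
    gene_mat = expected * 2.0 ** (stage_factor + noise)
    gene_tpm = FeatureMatrix(pd.DataFrame(gene_mat.T, index=gene_ids,
                                          columns=sample_ids), "tpm")

    # --- isoform usage ------------------------------------------------------
    multi_genes = [gene_ids[i] for i in sorted(multi_idx)]
    switch_genes = list(rng.choice(multi_genes, size=cfg.n_switch, replace=False))
    n_strong = int(round(cfg.n_switch * cfg.frac_strong_switch))
    strong = np.zeros(cfg.n_switch, dtype=bool)
    strong[rng.choice(cfg.n_switch, size=n_strong, replace=False)] = True
    reverts = rng.random(cfg.n_switch) < cfg.hf_reversion_frac

    usage_adult: dict[str, float] = {}
    usage_fetal: dict[str, float] = {}
    switch_rows = []
    for g in gene_ids:
        isos = iso_ids_per_gene[g]
        if len(isos) == 1:
            usage_adult[isos[0]] = 1.0
            usage_fetal[isos[0]] = 1.0
            continue
        u = rng.dirichlet(np.full(len(isos), 5.0))
        for t, tid in enumerate(isos):
            usage_adult[tid] = float(u[t])
            usage_fetal[tid] = float(u[t])
    for j, g in enumerate(switch_genes):
        isos = iso_ids_per_gene[g]
        m = len(isos)
        if strong[j]:
            a = rng.uniform(0.02, 0.08)
            delta = rng.uniform(0.45, min(0.6, cfg.switch_delta_range[1]))
            b = delta + rng.uniform(0.02, 0.08)
        else:
            delta = rng.uniform(*cfg.switch_delta_range)
            a = rng.uniform(0.05, 0.25)
            b = delta + rng.uniform(0.05, min(0.3, 0.95 - delta))
        rest = 1.0 - a - b
        shares = rng.dirichlet(np.full(m - 2, 3.0)) * rest if m > 2 else []
        iso_f, iso_a = isos[0], isos[1]
        usage_adult[iso_f], usage_fetal[iso_f] = a, a + delta
        usage_adult[iso_a], usage_fetal[iso_a] = b, b - delta
        for t, tid in enumerate(isos[2:]):
            usage_adult[tid] = usage_fetal[tid] = float(shares[t])
        switch_rows.append((g, iso_f, iso_a, float(delta), bool(strong[j]),
                            bool(reverts[j])))
    switch_table = pd.DataFrame(
        switch_rows, columns=["gene", "iso_fetal", "iso_adult", "delta",
                              "strong", "reverts"])

    iso_ids = [tid for g in gene_ids for tid in iso_ids_per_gene[g]]
    ua = np.array([usage_adult[t] for t in iso_ids])
    uf = np.array([usage_fetal[t] for t in iso_ids])
    iso_pos = {tid: i for i, tid in enumerate(iso_ids)}
    upre = ua.copy()
    for g, iso_f, iso_a, delta, _strong, rev in switch_rows:
        if rev:
            for tid in (iso_f, iso_a):
                i = iso_pos[tid]
                upre[i] = ua[i] + cfg.hf_reversion_strength * (uf[i] - ua[i])
    # disease-specific usage shifts: present pre-LVAD only, independent of
    # the fetal program
    private_pool = [g for g in multi_genes if g not in set(switch_genes)
                    and len(iso_ids_per_gene[g]) >= 2]
    n_priv = min(cfg.n_hf_private_switch, len(private_pool))
    hf_private_genes = list(rng.choice(private_pool, size=n_priv, replace=False))
    hf_private_isoforms: set[str] = set()
    for g in hf_private_genes:
        isos = iso_ids_per_gene[g]
        i1, i2 = iso_pos[isos[0]], iso_pos[isos[1]]
        d = rng.uniform(*cfg.hf_private_delta_range)
        d = min(d, ua[i2] - 0.02) if ua[i2] > 0.04 else 0.0
        if d <= 0:
            continue
        upre[i1], upre[i2] = ua[i1] + d, ua[i2] - d
        hf_private_isoforms.update(isos[:2])
    tissue_usage = {"iPSC-CVPC": uf, "adult_heart": ua, "adult_arteria": ua,
                    "HF_pre": upre, "HF_post": ua}

    gene_of_iso = np.array([ann.transcript_gene[t] for t in iso_ids])
    gene_index = pd.Series(np.arange(cfg.n_genes), index=gene_ids)
    gidx = gene_index[gene_of_iso].to_numpy()
    iso_mat = np.zeros((len(iso_ids), n_samples))
    logit_noise = rng.normal(0.0, cfg.usage_logit_sd, size=(len(iso_ids), n_samples))
    for i, t in enumerate(tissue_of):
        w = tissue_usage[t] * np.exp(logit_noise[:, i])
        w = np.maximum(w, 1e-12)
        denom = np.bincount(gidx, weights=w, minlength=cfg.n_genes)
        u_sample = w / denom[gidx]
        iso_mat[:, i] = u_sample * gene_mat[i, gidx]
    iso_tpm = FeatureMatrix(pd.DataFrame(iso_mat, index=iso_ids,
                                         columns=sample_ids), "tpm")

    # --- eCLIP peaks ---------------------------------------------------------
    from .io import gene_body_intervals
    bodies = gene_body_intervals(ann)
    enriched = set(switch_genes)
    peaksets = []
    for e in range(cfg.n_eclip_experiments):
        intervals = []
        for g in gene_ids:
            p = cfg.peak_p_specific if g in enriched else cfg.peak_p_background
            if rng.random() < p:
                chrom, s, t = bodies[g]
                width = int(rng.integers(30, 120))
                left = int(rng.integers(s, max(s + 1, t - width)))
                intervals.append((chrom, left, min(left + width, t)))
        peaksets.append(PeakSet(f"ECLIP{e:02d}", f"RBP{e:02d}", "K562", intervals))

    # --- splice-site composition of switch-exon flanks -----------------------
    prof_fetal = make_splice_profiles(canonical_p=cfg.splice_canonical_p,
                                      ppt_t=cfg.splice_ppt_t_fetal)
    prof_adult = make_splice_profiles(canonical_p=cfg.splice_canonical_p,
                                      ppt_t=cfg.splice_ppt_t_adult)
    splice_planted = {"fetal_exons": set(), "adult_exons": set(),
                      "ppt_positions": list(range(-20, -4)),
                      "ppt_t_fetal": cfg.splice_ppt_t_fetal,
                      "ppt_t_adult": cfg.splice_ppt_t_adult}
    for g, iso_f, iso_a, _d, is_strong, _r in switch_rows:
        if not is_strong:
            continue
        for tid, prof, key in ((iso_f, prof_fetal, "fetal_exons"),
                               (iso_a, prof_adult, "adult_exons")):
            exon = ann.exons[alt_exon_of_iso[tid]]
            _plant_flanks(chrom_arrays[exon.chrom], exon, prof, rng)
            splice_planted[key].add(exon.exon_id)

    # --- PWMs planted in fetal-exon acceptor windows -------------------------
    pwms = _make_pwms(cfg, rng)
    planted: dict[str, set[str]] = {pwms[0].motif_id: set()}
    for g, iso_f, iso_a, _d, is_strong, _r in switch_rows:
        if not is_strong:
            continue
        for tid, rate in ((iso_f, cfg.motif_rate_set1), (iso_a, cfg.motif_rate_set2)):
            exon = ann.exons[alt_exon_of_iso[tid]]
            if rng.random() < rate:
                _plant_motif(chrom_arrays[exon.chrom], exon, pwms[0], rng)
                planted[pwms[0].motif_id].add(exon.exon_id)

    genome = Genome.from_dict({c: a.tobytes().decode() for c, a in chrom_arrays.items()})

    # --- protein domains: fetal alternative exons carry domains more often ---
    fetal_alt_exons = {alt_exon_of_iso[row[1]] for row in switch_rows if row[4]}
    domains = []
    for eid, ex in ann.exons.items():
        p = (cfg.domain_p_fetal_exon if eid in fetal_alt_exons
             else cfg.domain_p_other_exon)
        if rng.random() < p:
            off = int(rng.integers(0, max(1, (ex.end - ex.start) // 2)))
            domains.append(DomainRecord(f"DOM_{eid}", ex.chrom,
                                        ex.start + off, ex.end + 10, ex.strand))

    # --- gene sets ------------------------------------------------------------
    gene_sets = [GeneSet("RNA_BINDING", "GO", set(rbp_genes))]
    for k in range(20):
        size = int(rng.integers(30, 80))
        members = set(rng.choice(gene_ids, size=size, replace=False))
        gene_sets.append(GeneSet(f"RANDOM_SET_{k:02d}", "SIM", members))

    # --- single-cell counts ----------------------------------------------------
    sig = signatures.to_numpy()
    cells, labels = [], []
    r = 1.0 / cfg.sc_dispersion
    for k, ct in enumerate(CELL_TYPES):
        mean = sig[:, k] / sig[:, k].sum() * cfg.sc_depth
        p = r / (r + mean)
        cells.append(rng.negative_binomial(r, p, size=(cfg.sc_cells_per_type,
                                                       cfg.n_genes)))
        labels += [ct] * cfg.sc_cells_per_type
    sc_counts = pd.DataFrame(np.vstack(cells), columns=gene_ids,
                             index=[f"cell{i:04d}" for i in range(len(labels))])
    sc_labels = pd.Series(labels, index=sc_counts.index, name="cell_type")

    truth = GroundTruth(
        proportions=proportions, stage_de=stage_de, rbp_genes=rbp_genes,
        switch_table=switch_table, marker_genes=marker_genes,
        peak_enriched_genes=enriched, signatures=signatures,
        motif_planted=planted,
        tissue_usage={t: pd.Series(u, index=iso_ids) for t, u in tissue_usage.items()},
        hf_private_isoforms=hf_private_isoforms,
        splice_planted=splice_planted,
    )
    return Cohort(cfg, samples, gene_tpm, iso_tpm, ann, genome, peaksets,
                  pwms, gene_sets, domains, sc_counts, sc_labels, truth)


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write every fixture in the standard formats the readers consume.

    Returns a manifest name -> path.  Matrices are TSV (full float
    precision), annotation GTF, genome FASTA, peaks BED6, motifs
    MEME-minimal, gene sets GMT, domains BED-like, single-cell counts TSV.
    """
    import os
    from .io import (write_bed_peaks, write_domains, write_gmt,
                     write_gtf_annotation, write_meme_pwms, write_sample_table)
    os.makedirs(outdir, exist_ok=True)
    out = {}

    def path(name):
        out[name] = os.path.join(outdir, name)
        return out[name]

    write_sample_table(cohort.samples, path("samples.tsv"))
    cohort.gene_tpm.write_tsv(path("gene_tpm.tsv"))
    cohort.iso_tpm.write_tsv(path("isoform_tpm.tsv"))
    write_gtf_annotation(cohort.annotation, path("annotation.gtf"))
    cohort.genome.write_fasta(path("genome.fa"))
    peak_dir = os.path.join(outdir, "peaks")
    os.makedirs(peak_dir, exist_ok=True)
    for ps in cohort.peaksets:
        p = os.path.join(peak_dir, f"{ps.experiment_id}.bed")
        out[f"peaks/{ps.experiment_id}.bed"] = p
        write_bed_peaks(ps, p)
    write_meme_pwms(cohort.pwms, path("motifs.meme"))
    write_gmt(cohort.gene_sets, path("gene_sets.gmt"))
    write_domains(cohort.domains, path("domains.bed"))
    cohort.sc_counts.to_csv(path("sc_counts.tsv"), sep="\t")
    cohort.sc_labels.to_csv(path("sc_labels.tsv"), sep="\t")
    cohort.truth.proportions.to_csv(path("true_proportions.tsv"), sep="\t")
    return out


def _draw_sample(rng, sample_id, subject_id, tissue) -> SampleRecord:
    return SampleRecord(
        sample_id=sample_id, subject_id=subject_id, tissue=tissue,
        sex="M" if rng.random() < 0.5 else "F",
        total_reads=int(rng.lognormal(np.log(4e7), 0.2)),
        pct_autosomal=0.9, pct_mito=0.05,  # overwritten once proportions exist
    )


# ---------------------------------------------------------------------------
# splice-site composition simulator
# ---------------------------------------------------------------------------

def make_splice_profiles(window: int = 100, canonical_p: float = 0.9,
                         ppt_t: float = 0.45, ppt_c: float = 0.30,
                         overrides: dict | None = None) -> dict:
    """Per-position base probabilities for acceptor (-window..-1) and donor
    (+1..+window) flanks.

    Defaults sketch canonical metazoan splice sites: AG at acceptor -2/-1, a
    pyrimidine-rich tract (mostly T) at -20..-5, GT at donor +1/+2.
    ``overrides`` maps ("donor"|"acceptor", position) -> length-4 probability
    vector over (A, C, G, T).
    """
    acc = np.full((window, 4), 0.25)
    don = np.full((window, 4), 0.25)
    lo = (1.0 - canonical_p) / 3.0

    def _canon(mat, row, base):
        mat[row] = lo
        mat[row, "ACGT".index(base)] = canonical_p

    _canon(acc, window - 2, "A")
    _canon(acc, window - 1, "G")
    for pos in range(-20, -4):           # polypyrimidine tract
        rest = (1.0 - ppt_t - ppt_c) / 2.0
        acc[window + pos] = (rest, ppt_c, rest, ppt_t)
    _canon(don, 0, "G")
    _canon(don, 1, "T")
    profiles = {"acceptor": acc, "donor": don}
    for (side, pos), vec in (overrides or {}).items():
        vec = np.asarray(vec, dtype=float)
        if vec.min() < 0 or vec.max() > 1 or abs(vec.sum() - 1) > 1e-9:
            raise ValueError("override probabilities must form a distribution")
        idx = window + pos if pos < 0 else pos - 1
        profiles[side][idx] = vec
    return profiles


@dataclass
class SpliceSim:
    """Two exon sets with flank sequences drawn from per-position profiles."""

    set1: list[str]
    set2: list[str]
    exons: dict[str, ExonRecord]
    genome: Genome
    profiles: dict[str, dict]            # set label -> {"acceptor","donor"}

    @property
    def pair(self):
        from .splicing import ExonSetPair
        return ExonSetPair("set1_vs_set2", self.set1, "set1", self.set2, "set2")


def simulate_splice_sets(n_exons: int, profiles1: dict, profiles2: dict,
                         seed: int = 0, window: int = 100,
                         exon_len: int = 150) -> SpliceSim:
    """Plant two exon sets whose flank composition follows the given profiles.

    Exons alternate strands; flank windows are written into the genome in
    transcription orientation so extraction round-trips exactly.  n_exons = 0
    yields empty sets.
    """
    for prof in (profiles1, profiles2):
        for side in ("acceptor", "donor"):
            mat = np.asarray(prof[side], dtype=float)
            if mat.min() < 0 or mat.max() > 1:
                raise ValueError("profile probabilities outside [0,1]")
    rng = np.random.default_rng(seed)
    spacing = 2 * window + exon_len + 200
    total = 2 * n_exons * spacing + 2000
    seq = _random_seq(rng, total)
    exons: dict[str, ExonRecord] = {}
    sets: dict[str, list[str]] = {"set1": [], "set2": []}
    pos = 1000
    for i in range(2 * n_exons):
        label = "set1" if i % 2 == 0 else "set2"
        prof = profiles1 if label == "set1" else profiles2
        strand = "+" if rng.random() < 0.5 else "-"
        eid = f"{label}_ex{i // 2:04d}"
        start, end = pos, pos + exon_len
        exons[eid] = ExonRecord(eid, "chrS", start, end, strand)
        sets[label].append(eid)
        acc = _draw_profile_seq(rng, np.asarray(prof["acceptor"], float))
        don = _draw_profile_seq(rng, np.asarray(prof["donor"], float))
        if strand == "+":
            seq[start - window:start] = acc
            seq[end:end + window] = don
        else:
            seq[end:end + window] = _rc_arr(acc)
            seq[start - window:start] = _rc_arr(don)
        pos += spacing
    genome = Genome.from_dict({"chrS": seq.tobytes().decode()})
    return SpliceSim(sets["set1"], sets["set2"], exons, genome,
                     {"set1": profiles1, "set2": profiles2})


def _draw_profile_seq(rng, probs: np.ndarray) -> np.ndarray:
    cum = probs.cumsum(axis=1)
    u = rng.random(probs.shape[0])
    idx = (u[:, None] > cum).sum(axis=1)
    return _BASES[idx]


def _rc_arr(arr: np.ndarray) -> np.ndarray:
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    return comp[arr][::-1]
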