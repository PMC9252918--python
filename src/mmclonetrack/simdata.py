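"""Synthetic cohorts with known ground truth for every pipeline stage.

Three generators mirror the statistical structure of a paired early/late
myeloma study:

* signature-mixture catalogs — channels drawn multinomially from known
  signature weights over the packaged toy reference, with a configurable
  transcriptional strand asymmetry for melphalan-signature C>T mutations in
  the five SBS-MM1-typical contexts;
* paired variant sets — per-variant cancer cell fractions planted on cluster
  layouts for each evolution scenario, pushed backwards through the CCF
  transform to variant allele fractions and read counts with binomial read
  noise at WES-like depth;
* TPM matrices — log-normal background expression with planted standardized
  shifts in panel genes (proliferation index) and cancer-germline antigens
  switched on in late samples of affected patients.

All generators are deterministic under a seed, and the emitted files
round-trip through the package readers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clonevo, exprscore, sigfit
from .mutcat import (
    CHANNELS,
    MutationRecord,
    TrinucleotideCatalog,
    build_catalog,
    channel_context,
)
from .sigfit import MM1_CONTEXTS, MM1_NAME, SignatureReference, toy_reference

SCENARIOS = ("stable", "linear", "differential")

#: Planted (ccf_early, ccf_late, variant fraction) layouts per scenario.
SCENARIO_LAYOUTS: dict[str, list[tuple[float, float, float]]] = {
    "stable": [(1.0, 1.0, 0.65), (0.5, 0.5, 0.35)],
    "linear": [(1.0, 1.0, 0.6), (0.0, 0.6, 0.4)],
    # backbone, falling clone, rising clone, new subclone within the riser
    # (the late-private fraction is where treatment-induced mutations live)
    "differential": [(1.0, 1.0, 0.35), (0.75, 0.05, 0.25), (0.05, 0.85, 0.25), (0.0, 0.8, 0.15)],
}


@dataclass
class SimulationConfig:
    """Study-shaped defaults for the synthetic cohort.

    The defaults emulate the cohort conditions of a paired WES + RNA-seq
    myeloma study: ~100 exonic SNVs per sample at mean depth 100, purity in
    the 0.80-1.00 inclusion window, evolution scenarios in 58/23/19
    differential/linear/stable proportions, a melphalan-signature weight of
    0.3 among newly acquired mutations of high-dose-melphalan patients with
    2:1 transcriptional strand bias, and late-sample expression effects of
    +1 within-cohort SD on the proliferation panel plus CGA activation.
    """

    seed: int = 0
    n_patients: int = 12
    scenario_proportions: dict = field(
        default_factory=lambda: {"differential": 0.58, "linear": 0.23, "stable": 0.19}
    )
    n_variants: int = 100
    mean_depth: int = 100
    purity_range: tuple[float, float] = (0.80, 1.0)
    ccf_sigma: float = 0.05
    background_weights: dict = field(
        default_factory=lambda: {"SBS-A": 0.45, "SBS-B": 0.30, "SBS-C": 0.15, "SBS-D": 0.10}
    )
    # SBS-MM1 weight among *newly acquired* (late-private) mutations: after
    # high-dose melphalan the melphalan signature dominates the novel
    # mutation spectrum; low-dose and unexposed groups carry none by default
    mm1_weight: dict = field(
        default_factory=lambda: {"HDM": 0.60, "LDM": 0.0, "noM": 0.0}
    )
    strand_bias_ratio: float = 2.0
    genic_fraction: float = 0.7
    rna_coverage: float = 0.9
    expressed_fraction: float = 0.28
    # expression layer: per-gene cohort mean ~ N(mean, sd); per (gene,
    # patient) baseline ~ N(0, between_sd); paired early/late samples add
    # only small technical noise (paired_sd) around that shared baseline
    n_background_genes: int = 300
    expr_mean_log2: float = 2.0
    expr_sd_log2: float = 1.0
    expr_between_sd: float = 0.5
    expr_paired_sd: float = 0.02
    pi_shift_sd: float = 1.0
    pi_effect_fraction: float = 0.6
    cga_on_fraction: float = 0.5
    cga_on_count: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.scenario_proportions.values()) - 1) > 1e-9:
            raise ValueError("scenario proportions must sum to 1")
        if not all(
            v > 0
            for v in (self.ccf_sigma, self.expr_between_sd, self.expr_paired_sd, self.expr_sd_log2)
        ):
            raise ValueError("noise standard deviations must be positive")
        if self.strand_bias_ratio < 1:
            raise ValueError("strand_bias_ratio must be >= 1")


# ---------------------------------------------------------------------------
# Catalog simulation


def simulate_catalog(
    n_mutations: int,
    weights: dict[str, float],
    ref: Optional[SignatureReference] = None,
    rng: Optional[np.random.Generator] = None,
    strand_bias_ratio: float = 2.0,
    genic_fraction: float = 0.7,
    sample_id: str = "sim",
    patient_id: Optional[str] = None,
    chrom: str = "chr1",
    pos_offset: int = 1000,
) -> tuple[TrinucleotideCatalog, list[MutationRecord]]:
    """Draw a catalog plus fully annotated mutation records from a signature
    mixture.  SBS-MM1-attributed C>T mutations in the five typical contexts
    get transcribed:untranscribed odds of ``strand_bias_ratio``; all other
    genic mutations are strand-symmetric."""
    if n_mutations <= 0:
        raise ValueError("n_mutations must be positive")
    ref = ref or toy_reference()
    rng = rng if rng is not None else np.random.default_rng()
    w = np.zeros(len(ref))
    for name, wt in weights.items():
        w[ref.index_of(name)] = wt
    if abs(w.sum() - 1) > 1e-9:
        raise ValueError("signature weights must sum to 1")
    sig_idx = rng.choice(len(ref), size=n_mutations, p=w)
    records: list[MutationRecord] = []
    p_trans_biased = strand_bias_ratio / (1 + strand_bias_ratio)
    mm1_idx = ref.index_of(MM1_NAME) if MM1_NAME in ref.names else -1
    positions = pos_offset + 2 * np.arange(n_mutations)  # distinct, deterministic
    for i, s in enumerate(sig_idx):
        ch_i = rng.choice(96, p=ref.profiles[s])
        ch = CHANNELS[ch_i]
        ctx = channel_context(ch)
        ref_base, alt_base = ch[2], ch[4]
        genic = rng.random() < genic_fraction
        if genic:
            biased = s == mm1_idx and ch[2:5] == "C>T" and ctx in MM1_CONTEXTS
            p_t = p_trans_biased if biased else 0.5
            strand = "transcribed" if rng.random() < p_t else "untranscribed"
        else:
            strand = "intergenic"
        records.append(
            MutationRecord(
                patient_id=patient_id or sample_id,
                sample_id=sample_id,
                chrom=chrom,
                pos=int(positions[i]),
                ref=ref_base,
                alt=alt_base,
                alt_reads=50,
                total_reads=100,
                context=ctx,
                tx_strand=strand,
            )
        )
    catalog = build_catalog(records, sample_id=sample_id)
    return catalog, records


# ---------------------------------------------------------------------------
# Paired CCF simulation


@dataclass
class PairSim:
    """One simulated early/late sample pair with its ground truth."""

    patient_id: str
    scenario: str
    early: list[MutationRecord]
    late: list[MutationRecord]
    segments: list[clonevo.CopyNumberSegment]
    purity_early: float
    purity_late: float
    true_ccf_early: np.ndarray
    true_ccf_late: np.ndarray
    cluster_of: np.ndarray
    layout: list[tuple[float, float, float]]
    ras_shift: bool
    ras_labels: list[str] = field(default_factory=list)


def validate_layout(scenario: str, layout: Sequence[tuple[float, float, float]]) -> None:
    """A layout is consistent with its scenario when the noiseless cluster
    means classify to that scenario under the default thresholds."""
    if abs(sum(f for (_e, _l, f) in layout) - 1) > 1e-9:
        raise ValueError("layout variant fractions must sum to 1")
    sol = clonevo.CcfClusterSolution(
        clusters=[(e, l, f, 1) for (e, l, f) in layout],
        assignments=np.zeros(len(layout), dtype=int),
        model_score=0.0,
        k=len(layout),
    )
    call = clonevo.classify_evolution(sol)
    if call.pattern != scenario:
        raise ValueError(
            f"layout {list(layout)} classifies as {call.pattern!r}, not {scenario!r}; "
            f"evidence: {call.evidence}"
        )


def simulate_pair(
    cfg: SimulationConfig,
    scenario: str,
    rng: Optional[np.random.Generator] = None,
    patient_id: str = "P01",
    layout: Optional[Sequence[tuple[float, float, float]]] = None,
    plant_ras_shift: Optional[bool] = None,
    noiseless: bool = False,
) -> PairSim:
    """Simulate one paired sample under a planted evolution scenario.

    Per variant, a cluster is drawn from the layout, a true CCF pair from a
    truncated Gaussian around the cluster means (exactly 0 stays 0: the
    variant is absent at that timepoint), and VAFs are back-computed through
    the CCF transform (diploid, multiplicity 1) with binomial read noise at
    the configured depth.  With ``noiseless`` the reads encode the planted
    VAF exactly (infinite-depth limit).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    layout = list(layout or SCENARIO_LAYOUTS[scenario])
    validate_layout(scenario, layout)
    if plant_ras_shift is None:
        plant_ras_shift = scenario == "differential"
    if plant_ras_shift and scenario != "differential":
        raise ValueError("a RAS shift requires a differential layout (falling + rising clusters)")

    n = cfg.n_variants
    fracs = np.array([f for (_e, _l, f) in layout])
    cluster_of = rng.choice(len(layout), size=n, p=fracs)
    purity_e = float(rng.uniform(*cfg.purity_range))
    purity_l = float(rng.uniform(*cfg.purity_range))

    true_e = np.empty(n)
    true_l = np.empty(n)
    for i, c in enumerate(cluster_of):
        me, ml, _ = layout[c]
        true_e[i] = 0.0 if me == 0 else float(np.clip(rng.normal(me, cfg.ccf_sigma), 0.02, 1.2))
        true_l[i] = 0.0 if ml == 0 else float(np.clip(rng.normal(ml, cfg.ccf_sigma), 0.02, 1.2))

    # RAS labels: in a shift, one falling- and one rising-cluster variant get
    # different RAS hotspots; otherwise one backbone variant keeps a stable one.
    gene_of = [None] * n
    ras_labels: list[str] = []
    deltas = [l - e for (e, l, _f) in layout]
    if plant_ras_shift:
        fall_c = int(np.argmin(deltas))
        rise_c = int(np.argmax(deltas))
        i_fall = int(np.flatnonzero(cluster_of == fall_c)[0])
        i_rise = int(np.flatnonzero(cluster_of == rise_c)[0])
        gene_of[i_fall] = ("KRAS", "p.G12D")
        gene_of[i_rise] = ("NRAS", "p.Q61K")
        ras_labels = ["KRAS p.G12D", "NRAS p.Q61K"]
    else:
        stable_c = int(np.argmin(np.abs(deltas)))
        idx = np.flatnonzero(cluster_of == stable_c)
        if idx.size:
            gene_of[int(idx[0])] = ("KRAS", "p.G12V")
            ras_labels = ["KRAS p.G12V"]

    segments = [clonevo.CopyNumberSegment("chr1", 1, 500_000_000, 2, 1)]
    early: list[MutationRecord] = []
    late: list[MutationRecord] = []
    positions = 10_000 + 10 * np.arange(n)
    for i in range(n):
        base = dict(
            patient_id=patient_id,
            chrom="chr1",
            pos=int(positions[i]),
            ref="C",
            alt="T",
            context="ACA",
        )
        if gene_of[i] is not None:
            base["gene"] = gene_of[i][0]
        for ccf, purity, sample_suffix, bucket in (
            (true_e[i], purity_e, "early", early),
            (true_l[i], purity_l, "late", late),
        ):
            vaf = ccf * purity * 1 / (purity * 2 + (1 - purity) * 2)
            if noiseless:
                depth = 10**8
                alt = int(round(vaf * depth))
            else:
                depth = cfg.mean_depth
                alt = int(rng.binomial(depth, min(vaf, 1.0)))
            if ccf == 0 and alt == 0:
                continue  # variant absent at this timepoint
            rna = None
            if rng.random() < cfg.rna_coverage:
                rna = 5 if rng.random() < cfg.expressed_fraction else 0
            bucket.append(
                MutationRecord(
                    sample_id=f"{patient_id}_{sample_suffix}",
                    alt_reads=alt,
                    total_reads=depth,
                    rna_alt_reads=rna,
                    **base,
                )
            )
    return PairSim(
        patient_id=patient_id,
        scenario=scenario,
        early=early,
        late=late,
        segments=segments,
        purity_early=purity_e,
        purity_late=purity_l,
        true_ccf_early=true_e,
        true_ccf_late=true_l,
        cluster_of=cluster_of,
        layout=layout,
        ras_shift=plant_ras_shift,
        ras_labels=ras_labels,
    )


# ---------------------------------------------------------------------------
# Expression simulation


def simulate_expression(
    cfg: SimulationConfig,
    patient_ids: Sequence[str],
    panels: Optional[dict[str, exprscore.GeneSet]] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, dict]:
    """TPM matrix (genes x early/late samples) with planted effects.

    Expression is log-normal on the log2 scale: a cohort mean per gene, a
    per-(gene, patient) baseline shared by the early and late sample, and
    small paired technical noise — so paired deltas are quiet unless an
    effect is planted.  Late samples of PI-affected patients shift the
    proliferation-panel genes by ``pi_shift_sd`` between-patient standard
    deviations; CGA-affected patients switch on ``cga_on_count`` antigens
    (TPM well above the expression threshold) in the late sample only.
    Returns the matrix and a ground-truth dict of per-patient effect flags.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    panels = panels or exprscore.default_panels()
    pi_genes = sorted(panels["PI"].genes)
    cga_genes = sorted(panels["CGA"].genes)
    other_panel_genes = sorted(
        set().union(*(panels[k].genes for k in panels if k not in ("PI", "CGA")))
    )
    background = [f"GENE{i:04d}" for i in range(cfg.n_background_genes)]
    genes = background + pi_genes + other_panel_genes + cga_genes
    samples = [f"{p}_{t}" for p in patient_ids for t in ("early", "late")]

    gene_mean = rng.normal(cfg.expr_mean_log2, cfg.expr_sd_log2, size=len(genes))
    baseline = rng.normal(0.0, cfg.expr_between_sd, size=(len(genes), len(patient_ids)))
    log2 = np.repeat(gene_mean[:, None], len(samples), axis=1)
    log2 += np.repeat(baseline, 2, axis=1)  # early/late share the baseline
    log2 += rng.normal(0.0, cfg.expr_paired_sd, size=log2.shape)
    df = pd.DataFrame(log2, index=genes, columns=samples)

    pi_affected = {p: bool(rng.random() < cfg.pi_effect_fraction) for p in patient_ids}
    cga_affected = {p: bool(rng.random() < cfg.cga_on_fraction) for p in patient_ids}
    for p in patient_ids:
        if pi_affected[p]:
            df.loc[pi_genes, f"{p}_late"] += cfg.pi_shift_sd * cfg.expr_between_sd
    tpm = (2.0**df - 1.0).clip(lower=0.0)
    # CGAs are near-silent by default; affected patients express a subset late
    tpm.loc[cga_genes] = rng.uniform(0.0, 0.5, size=(len(cga_genes), len(samples)))
    for p in patient_ids:
        if cga_affected[p]:
            on = rng.choice(cga_genes, size=min(cfg.cga_on_count, len(cga_genes)), replace=False)
            tpm.loc[on, f"{p}_late"] = rng.uniform(10.0, 60.0, size=len(on))
    truth = {
        "pi_effect": pi_affected,
        "cga_effect": cga_affected,
        "pi_shift_sd": cfg.pi_shift_sd,
    }
    return exprscore.validate_expression(tpm), truth


# ---------------------------------------------------------------------------
# Whole-cohort simulation


@dataclass
class CohortSim:
    config: SimulationConfig
    reference: SignatureReference
    patients: list[str]
    scenarios: dict[str, str]
    groups: dict[str, str]
    pairs: dict[str, PairSim]
    mutations: dict[str, list[MutationRecord]]  # sample_id -> records
    purity: dict[str, float]
    tpm: pd.DataFrame
    ground_truth: dict


def _scenario_counts(cfg: SimulationConfig) -> list[str]:
    """Deterministic largest-remainder allocation of scenarios to patients."""
    props = cfg.scenario_proportions
    raw = {s: cfg.n_patients * props.get(s, 0.0) for s in SCENARIOS}
    counts = {s: int(np.floor(v)) for s, v in raw.items()}
    left = cfg.n_patients - sum(counts.values())
    for s in sorted(SCENARIOS, key=lambda s: raw[s] - counts[s], reverse=True)[:left]:
        counts[s] += 1
    out: list[str] = []
    for s in SCENARIOS:
        out.extend([s] * counts[s])
    return out


def simulate_cohort(cfg: SimulationConfig) -> CohortSim:
    """Generate a full cohort: paired variant sets with signature-annotated
    channels/strands, per-sample purity, copy-number segments, a TPM matrix
    and a ground-truth record sufficient to score every downstream stage.

    Newly acquired late-sample mutations draw their channels from the
    treatment group's signature mixture (including SBS-MM1 for HDM), while
    ancestral mutations draw from the background mixture — so the melphalan
    signature appears only in the late catalogs of exposed patients, diluted
    by the ancestral fraction.
    """
    rng = np.random.default_rng(cfg.seed)
    ref = toy_reference()
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]
    scen_list = _scenario_counts(cfg)
    scenarios = dict(zip(patients, scen_list))
    group_cycle = ["HDM", "LDM", "noM"]
    groups = {p: group_cycle[i % 3] for i, p in enumerate(patients)}

    pairs: dict[str, PairSim] = {}
    mutations: dict[str, list[MutationRecord]] = {}
    purity: dict[str, float] = {}
    sig_truth: dict[str, dict] = {}
    for p in patients:
        pair = simulate_pair(cfg, scenarios[p], rng=rng, patient_id=p)
        pairs[p] = pair
        bg = dict(cfg.background_weights)
        bg_total = sum(bg.values())
        bg = {k: v / bg_total for k, v in bg.items()}
        mm1_w = cfg.mm1_weight.get(groups[p], 0.0)
        late_mix = {k: v * (1 - mm1_w) for k, v in bg.items()}
        if mm1_w > 0:
            late_mix[MM1_NAME] = mm1_w
        # annotate channels/contexts/strands by re-drawing from the mixtures
        realized = _assign_channels(pair, bg, late_mix, ref, cfg, rng)
        mutations[f"{p}_early"] = pair.early
        mutations[f"{p}_late"] = pair.late
        purity[f"{p}_early"] = pair.purity_early
        purity[f"{p}_late"] = pair.purity_late
        sig_truth[p] = {"background": bg, "late_mix": late_mix, "realized": realized}

    tpm, expr_truth = simulate_expression(cfg, patients, rng=rng)
    ground_truth = {
        "scenario": scenarios,
        "group": groups,
        "ras_shift": {p: pairs[p].ras_shift for p in patients},
        "signature_mixtures": sig_truth,
        "strand_bias_ratio": cfg.strand_bias_ratio,
        "layouts": {p: pairs[p].layout for p in patients},
        "pi_effect": expr_truth["pi_effect"],
        "cga_effect": expr_truth["cga_effect"],
        "n_variants": {
            s: len(m) for s, m in mutations.items()
        },
    }
    return CohortSim(
        config=cfg,
        reference=ref,
        patients=patients,
        scenarios=scenarios,
        groups=groups,
        pairs=pairs,
        mutations=mutations,
        purity=purity,
        tpm=tpm,
        ground_truth=ground_truth,
    )


def _assign_channels(
    pair: PairSim,
    bg_mix: dict[str, float],
    late_mix: dict[str, float],
    ref: SignatureReference,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, dict[str, int]]:
    """Overwrite placeholder ref/alt/context/strand on pair records:
    ancestral variants (present early) draw from the background mixture,
    late-private variants from the late mixture.  Returns the realized
    per-sample signature draw counts (the per-sample true exposures)."""
    early_keys = {m.key for m in pair.early}
    p_trans = cfg.strand_bias_ratio / (1 + cfg.strand_bias_ratio)
    mm1_idx = ref.index_of(MM1_NAME)

    def mixture_vector(mix: dict[str, float]) -> np.ndarray:
        w = np.zeros(len(ref))
        for name, wt in mix.items():
            w[ref.index_of(name)] = wt
        return w / w.sum()

    w_bg, w_late = mixture_vector(bg_mix), mixture_vector(late_mix)
    assigned: dict[tuple, tuple[str, str, str, int]] = {}
    realized: dict[str, dict[str, int]] = {}
    for records, w in ((pair.early, w_bg), (pair.late, None)):
        for m in records:
            if m.key in assigned:
                ctx, alt, strand, s_prev = assigned[m.key]
                _rewrite(m, ctx, alt, strand)
                realized.setdefault(m.sample_id, {}).setdefault(ref.names[s_prev], 0)
                realized[m.sample_id][ref.names[s_prev]] += 1
                continue
            if w is None:  # late record
                wt = w_bg if m.key in early_keys else w_late
            else:
                wt = w
            s = int(rng.choice(len(ref), p=wt))
            ch = CHANNELS[int(rng.choice(96, p=ref.profiles[s]))]
            ctx = channel_context(ch)
            alt = ch[4]
            genic = rng.random() < cfg.genic_fraction
            if genic:
                biased = s == mm1_idx and ch[2:5] == "C>T" and ctx in MM1_CONTEXTS
                p_t = p_trans if biased else 0.5
                strand = "transcribed" if rng.random() < p_t else "untranscribed"
            else:
                strand = "intergenic"
            assigned[m.key] = (ctx, alt, strand, s)
            _rewrite(m, ctx, alt, strand)
            realized.setdefault(m.sample_id, {}).setdefault(ref.names[s], 0)
            realized[m.sample_id][ref.names[s]] += 1
    return realized


def _rewrite(m: MutationRecord, ctx: str, alt: str, strand: str) -> None:
    m.ref = ctx[1]
    m.alt = alt
    m.context = ctx
    m.tx_strand = strand


# ---------------------------------------------------------------------------
# File emission (round-trips through the module readers)


def write_cohort(cohort: CohortSim, outdir) -> Path:
    """Emit the cohort as the file formats the analysis stages read:
    mutation TSV, segment/purity/timeline TSVs, TPM TSV, panel GMT,
    signature reference TSV and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for sample_id, records in cohort.mutations.items():
        for m in records:
            rows.append(
                {
                    "patient_id": m.patient_id,
                    "sample_id": sample_id,
                    "chrom": m.chrom,
                    "pos": m.pos,
                    "ref": m.ref,
                    "alt": m.alt,
                    "alt_reads": m.alt_reads,
                    "total_reads": m.total_reads,
                    "context": m.context,
                    "tx_strand": m.tx_strand,
                    "gene": m.gene if m.gene else "",
                    "rna_alt_reads": m.rna_alt_reads if m.rna_alt_reads is not None else "",
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "mutations.tsv", sep="\t", index=False)

    seg_rows = []
    for p in cohort.patients:
        for seg in cohort.pairs[p].segments:
            for suffix in ("early", "late"):
                seg_rows.append(
                    {
                        "sample_id": f"{p}_{suffix}",
                        "chrom": seg.chrom,
                        "start": seg.start,
                        "end": seg.end,
                        "total_cn": seg.total_cn,
                        "minor_cn": seg.minor_cn,
                    }
                )
    pd.DataFrame(seg_rows).to_csv(outdir / "segments.tsv", sep="\t", index=False)

    pd.DataFrame(
        [{"sample_id": s, "purity": v} for s, v in cohort.purity.items()]
    ).to_csv(outdir / "purity.tsv", sep="\t", index=False)

    tl_rows = []
    for p in cohort.patients:
        for t, (suffix, label) in enumerate([("early", "diagnosis"), ("late", "PD-1")]):
            tl_rows.append(
                {
                    "patient_id": p,
                    "sample_id": f"{p}_{suffix}",
                    "timepoint": t,
                    "label": label,
                    "treatment_group": cohort.groups[p],
                }
            )
    pd.DataFrame(tl_rows).to_csv(outdir / "timeline.tsv", sep="\t", index=False)

    cohort.tpm.rename_axis("gene").to_csv(outdir / "tpm.tsv", sep="\t")
    panels = exprscore.default_panels()
    exprscore.write_gmt(panels.values(), outdir / "panels.gmt")
    cohort.reference.to_tsv(outdir / "signatures.tsv")

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(cohort.ground_truth, fh, indent=1, sort_keys=True, default=_json_default)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(cohort.config), fh, indent=1, sort_keys=True, default=_json_default)
    return outdir


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
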