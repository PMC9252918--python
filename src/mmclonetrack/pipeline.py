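"""Patient-timeline orchestration: QC, stage wiring, per-patient reports.

The pipeline consumes the file contracts the other modules define (mutation
TSV, segment/purity/timeline TSVs, TPM TSV, panel GMT, signature reference
TSV) and runs: purity QC -> catalogs -> signature fitting + strand bias ->
CCF clustering + evolution classification + RAS shift -> transcriptomic
scores -> per-patient integrated report.  A manifest records the config,
seeds and thresholds so a run is reproducible from it alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clonevo, exprscore, sigfit
from .mutcat import MutationRecord, build_catalog, stranded_counts, write_catalog_tsv
from .sigfit import SignatureReference

logger = logging.getLogger(__name__)

PURITY_MIN = 0.80  # inclusive study-entry threshold

DEFAULT_CONFIG = {
    "seed": 0,
    "n_bootstrap": 200,
    "ci_level": 0.95,
    "alpha": 0.05,
    "tau_shift": clonevo.TAU_SHIFT,
    "tau_new": clonevo.TAU_NEW,
    "tau_minor": clonevo.TAU_MINOR,
    "ccf_cap": clonevo.CCF_CAP,
    "k_max": clonevo.K_MAX,
    "n_restarts": clonevo.N_RESTARTS,
    "min_rna_alt": 1,
    "ssgsea_exponent": exprscore.SSGSEA_EXPONENT,
    "cga_tpm_threshold": exprscore.CGA_TPM_THRESHOLD,
    "pairing": "latest",  # or "first_pd"
    "pi_mode": "sum",
}


@dataclass
class PatientTimeline:
    """Ordered samples of one patient with purity and treatment annotations."""

    patient_id: str
    samples: list[dict]  # each: sample_id, timepoint, label, purity, treatment_group

    def __post_init__(self) -> None:
        tps = [s["timepoint"] for s in self.samples]
        if sorted(tps) != tps or len(set(tps)) != len(tps):
            raise ValueError(f"{self.patient_id}: timepoints must be strictly ordered")


@dataclass
class PatientReport:
    patient_id: str
    pair: Optional[tuple[str, str]] = None
    evolution: Optional[str] = None
    evolution_evidence: list = field(default_factory=list)
    ras_shift: Optional[bool] = None
    sbs_mm1_weight: Optional[float] = None
    sbs_mm1_present: Optional[bool] = None
    strand_bias_p: Optional[float] = None
    strand_bias_significant: Optional[bool] = None
    mutation_load_early: Optional[int] = None
    mutation_load_late: Optional[int] = None
    mutation_load_delta: Optional[int] = None
    expressed_fraction: Optional[float] = None
    pi_early: Optional[float] = None
    pi_late: Optional[float] = None
    pi_change_class: Optional[str] = None
    cga_early: Optional[int] = None
    cga_late: Optional[int] = None
    cga_change_class: Optional[str] = None
    ssgsea_deltas: dict = field(default_factory=dict)
    cn_flags: dict = field(default_factory=dict)
    null_reasons: dict = field(default_factory=dict)


def qc_filter(samples: pd.DataFrame, purity_min: float = PURITY_MIN):
    """Retain samples with tumor purity >= the inclusion threshold
    (inclusive).  Returns (retained, exclusion log)."""
    if "purity" not in samples.columns:
        raise ValueError("qc_filter needs a purity column")
    keep = samples["purity"] >= purity_min
    exclusions = [
        {"sample_id": r.sample_id, "reason": f"purity {r.purity:.2f} < {purity_min:.2f}"}
        for r in samples[~keep].itertuples(index=False)
    ]
    return samples[keep].reset_index(drop=True), exclusions


def mutation_load(
    muts_early: list[MutationRecord], muts_late: list[MutationRecord]
) -> dict:
    """Exonic SNV counts per timepoint with paired delta and fold change."""
    n_e, n_l = len(muts_early), len(muts_late)
    return {
        "early": n_e,
        "late": n_l,
        "delta": n_l - n_e,
        "fold": (n_l / n_e) if n_e else float("nan"),
    }


def load_config(path_or_dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict)
    unknown = set(user) - set(cfg) - {"input_dir", "out_dir"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg


def _read_mutation_table(path) -> dict[str, list[MutationRecord]]:
    from .mutcat import _read_tsv

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, list[MutationRecord]] = {}
    for sample_id in df["sample_id"].unique():
        out[sample_id] = _read_tsv(Path(path), sample_id, patient_id=sample_id)
    return out


def _pair_of(timeline: pd.DataFrame, pairing: str) -> Optional[tuple[str, str]]:
    """(early, late) sample ids: early = first retained timepoint; late =
    latest retained sample, or first PD-labelled sample with 'first_pd'."""
    tl = timeline.sort_values("timepoint")
    if len(tl) < 2:
        return None
    early = tl.iloc[0]["sample_id"]
    if pairing == "first_pd":
        pd_rows = tl.iloc[1:][tl.iloc[1:]["label"].str.startswith("PD")]
        late = pd_rows.iloc[0]["sample_id"] if len(pd_rows) else tl.iloc[-1]["sample_id"]
    else:
        late = tl.iloc[-1]["sample_id"]
    return early, late


def run_pipeline(config, input_dir=None, out_dir=None) -> dict:
    """Execute all stages on a cohort directory and write the output tables.

    Missing RNA/expression data for a patient leaves the transcriptomic
    fields null with a reason; a failed stage preserves the outputs written
    so far and marks the failure in the manifest.
    """
    cfg = load_config(config)
    input_dir = Path(input_dir or cfg.get("input_dir"))
    out_dir = Path(out_dir or cfg.get("out_dir"))
    out_dir.mkdir(parents=True, exist_ok=True)
    for key in ("mutations.tsv", "purity.tsv", "timeline.tsv", "signatures.tsv"):
        if not (input_dir / key).exists():
            raise FileNotFoundError(f"required input missing: {input_dir / key}")

    rng_root = np.random.SeedSequence(int(cfg["seed"]))
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31 - 1))
        for name, s in zip(("sigfit", "cluster"), rng_root.spawn(2))
    }
    manifest = {"config": cfg, "seeds": seeds, "stages": {}, "failed_stage": None}

    timeline = pd.read_csv(input_dir / "timeline.tsv", sep="\t")
    purity = pd.read_csv(input_dir / "purity.tsv", sep="\t")
    samples = timeline.merge(purity, on="sample_id")

    # --- QC -----------------------------------------------------------------
    retained, exclusions = qc_filter(samples)
    pd.DataFrame(exclusions or [], columns=["sample_id", "reason"]).to_csv(
        out_dir / "qc_exclusions.tsv", sep="\t", index=False
    )
    manifest["stages"]["qc"] = {"retained": len(retained), "excluded": len(exclusions)}

    # --- catalogs -----------------------------------------------------------
    muts_by_sample = _read_mutation_table(input_dir / "mutations.tsv")
    retained_ids = list(retained["sample_id"])
    catalogs = {
        s: build_catalog(muts_by_sample.get(s, []), sample_id=s) for s in retained_ids
    }
    write_catalog_tsv([catalogs[s] for s in retained_ids], out_dir / "catalogs.tsv")

    ref = SignatureReference.from_tsv(input_dir / "signatures.tsv")
    segments = _read_segments(input_dir / "segments.tsv")
    purity_of = dict(zip(purity["sample_id"], purity["purity"]))

    tpm = None
    panels = None
    if (input_dir / "tpm.tsv").exists():
        tpm = pd.read_csv(input_dir / "tpm.tsv", sep="\t", index_col=0)
        panel_path = input_dir / "panels.gmt"
        panels = exprscore.read_gmt(panel_path) if panel_path.exists() else exprscore.default_panels()

    # per-sample transcriptomic scores (cohort-level, once)
    scores = None
    if tpm is not None:
        scores = _score_samples(tpm, panels, cfg)
        scores.rename_axis("sample_id").to_csv(out_dir / "scores.tsv", sep="\t")

    # --- per-patient stages ---------------------------------------------------
    reports: list[PatientReport] = []
    exposure_frames = []
    evo_rows = []
    for i, (pid, tl) in enumerate(sorted(retained.groupby("patient_id"))):
        report = PatientReport(patient_id=pid)
        pair = _pair_of(tl, cfg["pairing"])
        if pair is None:
            report.null_reasons["pair"] = "fewer than 2 samples passed QC"
            reports.append(report)
            continue
        early_id, late_id = pair
        report.pair = pair
        muts_e = muts_by_sample.get(early_id, [])
        muts_l = muts_by_sample.get(late_id, [])

        load = mutation_load(muts_e, muts_l)
        report.mutation_load_early = load["early"]
        report.mutation_load_late = load["late"]
        report.mutation_load_delta = load["delta"]
        frac, _flags = clonevo.expressed_fraction(muts_l, min_rna_alt=cfg["min_rna_alt"])
        report.expressed_fraction = frac

        # signatures on the late catalog (where treatment signatures appear)
        cat_l = catalogs[late_id]
        if cat_l.total >= 1:
            exp = sigfit.bootstrap_ci(
                cat_l,
                ref,
                n_bootstrap=cfg["n_bootstrap"],
                level=cfg["ci_level"],
                seed=seeds["sigfit"] + i,
            )
            exposure_frames.append(exp.to_frame())
            if sigfit.MM1_NAME in exp.names:
                mm1 = exp[sigfit.MM1_NAME]
                report.sbs_mm1_weight = mm1["weight"]
                report.sbs_mm1_present = mm1["present"]
            sc = stranded_counts(muts_l, [], sample_id=late_id)
            sb = sigfit.strand_bias_test(sc, alpha=cfg["alpha"])
            report.strand_bias_p = sb.p_value
            report.strand_bias_significant = sb.significant
        else:
            report.null_reasons["signatures"] = "empty late catalog"

        # clonal evolution
        evo = _evolve_pair(
            muts_e, muts_l, segments, purity_of, early_id, late_id, cfg, seeds["cluster"] + i
        )
        report.evolution = evo["call"].pattern
        report.evolution_evidence = evo["call"].evidence
        report.ras_shift = evo["ras_shift"]
        evo_rows.append(
            {
                "patient_id": pid,
                "early": early_id,
                "late": late_id,
                "pattern": evo["call"].pattern,
                "k": evo["solution"].k,
                "ras_shift": evo["ras_shift"],
                "n_shared_variants": evo["n_variants"],
            }
        )
        report.cn_flags = clonevo.cn_locus_flags(segments.get(late_id, []))

        # transcriptomic deltas
        if scores is not None and f"{early_id}" in scores.index and f"{late_id}" in scores.index:
            _paired_scores(report, scores, early_id, late_id, pid)
        else:
            report.null_reasons["expression"] = "no TPM data for this patient"
        reports.append(report)

    if exposure_frames:
        pd.concat(exposure_frames, ignore_index=True).to_csv(
            out_dir / "exposures.tsv", sep="\t", index=False
        )
    pd.DataFrame(evo_rows).to_csv(out_dir / "evolution.tsv", sep="\t", index=False)

    # group-pooled signature fits by treatment exposure
    group_rows = []
    if "treatment_group" in retained.columns:
        late_ids = {r["patient_id"]: r["pair"][1] for r in map(asdict, reports) if r["pair"]}
        for g, sub in retained.groupby("treatment_group"):
            cats = [
                catalogs[late_ids[p]]
                for p in sub["patient_id"].unique()
                if p in late_ids and catalogs[late_ids[p]].total > 0
            ]
            if not cats:
                continue
            gexp = sigfit.group_fit(
                cats, ref, group_id=str(g), n_bootstrap=cfg["n_bootstrap"],
                level=cfg["ci_level"], seed=seeds["sigfit"],
            )
            mm1 = gexp[sigfit.MM1_NAME] if sigfit.MM1_NAME in gexp.names else None
            group_rows.append(
                {
                    "group": g,
                    "n_samples": len(cats),
                    "sbs_mm1_weight": mm1["weight"] if mm1 else np.nan,
                    "sbs_mm1_ci_low": mm1["ci_low"] if mm1 else np.nan,
                    "sbs_mm1_present": mm1["present"] if mm1 else False,
                }
            )
    pd.DataFrame(group_rows).to_csv(out_dir / "group_exposures.tsv", sep="\t", index=False)

    # correlation summary over per-sample scores
    if scores is not None:
        pairs = [
            (a, b)
            for ai, a in enumerate(["PI", "CGA_count", "mutation_load", "HLA_I", "HLA_II"])
            for b in ["PI", "CGA_count", "mutation_load", "HLA_I", "HLA_II"][ai + 1 :]
            if a in scores.columns and b in scores.columns
        ]
        loads = {s: len(muts_by_sample.get(s, [])) for s in scores.index}
        scores = scores.assign(mutation_load=pd.Series(loads))
        corr = exprscore.spearman_panel(scores, pairs)
        corr.to_csv(out_dir / "correlations.tsv", sep="\t", index=False)

    with open(out_dir / "reports.json", "w") as fh:
        json.dump([asdict(r) for r in reports], fh, indent=1, sort_keys=True, default=_json_default)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
    return {"reports": reports, "manifest": manifest, "out_dir": out_dir}


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _read_segments(path) -> dict[str, list[clonevo.CopyNumberSegment]]:
    if not Path(path).exists():
        return {}
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, list[clonevo.CopyNumberSegment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample_id, []).append(
            clonevo.CopyNumberSegment(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                total_cn=int(row.total_cn),
                minor_cn=int(row.minor_cn),
            )
        )
    return out


def _evolve_pair(muts_e, muts_l, segments, purity_of, early_id, late_id, cfg, seed) -> dict:
    segs_e = segments.get(early_id, [])
    segs_l = segments.get(late_id, [])
    ccf_e = {
        m.key: clonevo.compute_ccf(
            m, clonevo.segment_for(segs_e, m.chrom, m.pos), purity_of[early_id], cap=cfg["ccf_cap"]
        ).ccf
        for m in muts_e
    }
    ccf_l = {
        m.key: clonevo.compute_ccf(
            m, clonevo.segment_for(segs_l, m.chrom, m.pos), purity_of[late_id], cap=cfg["ccf_cap"]
        ).ccf
        for m in muts_l
    }
    keys = sorted(set(ccf_e) | set(ccf_l))
    e = [ccf_e.get(k, 0.0) for k in keys]
    l = [ccf_l.get(k, 0.0) for k in keys]
    sol = clonevo.cluster_pair(
        e, l, k_max=cfg["k_max"], n_restarts=cfg["n_restarts"], seed=seed
    )
    call = clonevo.classify_evolution(
        sol,
        tau_shift=cfg["tau_shift"],
        tau_new=cfg["tau_new"],
        tau_minor=cfg["tau_minor"],
        pair=(early_id, late_id),
    )
    gene_of = {}
    for m in list(muts_e) + list(muts_l):
        if m.gene in clonevo.RAS_GENES:
            gene_of[m.key] = f"{m.gene} {m.chrom}:{m.pos}"
    trajectories = [
        (label, ccf_e.get(k, 0.0), ccf_l.get(k, 0.0)) for k, label in gene_of.items()
    ]
    ras, _detail = clonevo.detect_ras_shift(
        trajectories, tau_shift=cfg["tau_shift"], tau_new=cfg["tau_new"], tau_minor=cfg["tau_minor"]
    )
    return {"call": call, "solution": sol, "ras_shift": ras, "n_variants": len(keys)}


def _score_samples(tpm: pd.DataFrame, panels, cfg) -> pd.DataFrame:
    cols = {}
    if "PI" in panels:
        cols["PI"] = exprscore.proliferation_index(tpm, panels["PI"], mode=cfg["pi_mode"])
    if "CGA" in panels:
        cols["CGA_count"] = exprscore.count_expressed_cgas(
            tpm, panels["CGA"], tpm_threshold=cfg["cga_tpm_threshold"]
        )
    for name in ("NFKB_index", "HLA_I", "HLA_II"):
        if name in panels:
            cols[name] = exprscore.panel_index(tpm, panels[name])
    z = exprscore.zscore_across_samples(tpm)
    for name, gs in panels.items():
        if name in ("PI", "CGA", "NFKB_index", "HLA_I", "HLA_II"):
            continue
        try:
            cols[f"ssGSEA:{name}"] = exprscore.ssgsea_score(z, gs, exponent=cfg["ssgsea_exponent"])
        except ValueError:
            logger.warning("skipping ssGSEA for %s: no genes in matrix", name)
    return pd.DataFrame(cols)


def _paired_scores(report: PatientReport, scores: pd.DataFrame, early_id, late_id, pid) -> None:
    if "PI" in scores.columns:
        pi_e, pi_l = scores.at[early_id, "PI"], scores.at[late_id, "PI"]
        change = exprscore.classify_pi_change(pi_e, pi_l, patient_id=pid)
        report.pi_early, report.pi_late = float(pi_e), float(pi_l)
        report.pi_change_class = change.cls
    if "CGA_count" in scores.columns:
        c_e, c_l = int(scores.at[early_id, "CGA_count"]), int(scores.at[late_id, "CGA_count"])
        change = exprscore.classify_cga_change(c_e, c_l, patient_id=pid)
        report.cga_early, report.cga_late = c_e, c_l
        report.cga_change_class = change.cls
    for col in scores.columns:
        if col.startswith("ssGSEA:"):
            report.ssgsea_deltas[col[7:]] = float(
                scores.at[late_id, col] - scores.at[early_id, col]
            )
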