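"""Transcriptomic scoring on TPM matrices.

All scores operate on a genes x samples TPM DataFrame.  Rank-based scores
(ssGSEA) and z-based indices (proliferation index, NFkB/HLA panels) first
log2(TPM+1)-transform and z-score each gene across samples, so scores
express a sample's standing relative to the cohort.  Threshold scores (CGA
counting, fold changes) work on the raw TPM scale.

The single-sample GSEA score is the Barbie-style running sum: genes are
ranked per sample in descending z order; at each rank the difference between
the weighted in-set ECDF (weights |z|^exponent) and the uniform out-of-set
ECDF is accumulated.  Exponent 0 makes the score purely rank-based.

Paired change classes follow fixed thresholds: the 11-gene proliferation
index change is an increase if >0.4, a high increase if >1 and a decrease
if <-0.4; the cancer-germline-antigen count is "expressed" at TPM > 2
(strict) and a paired rise of >= 3 antigens counts as increased.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PI_INCREASE = 0.4
PI_HIGH_INCREASE = 1.0
CGA_TPM_THRESHOLD = 2.0
CGA_INCREASE_DELTA = 3
SSGSEA_EXPONENT = 0.25
SPEARMAN_HIGHLIGHT = 0.45


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


def read_gmt(path) -> dict[str, GeneSet]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = GeneSet(parts[0], frozenset(g for g in parts[2:] if g))
    return sets


def write_gmt(sets: Iterable[GeneSet], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *sorted(s.genes)]) + "\n")


def validate_expression(m: pd.DataFrame) -> pd.DataFrame:
    """Check a genes x samples TPM matrix: unique ids, finite, nonnegative."""
    if m.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if m.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")
    vals = m.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("expression matrix contains non-finite values")
    if (vals < 0).any():
        raise ValueError("TPM values must be nonnegative")
    return m


def zscore_across_samples(m: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Per-gene z-score across samples, optionally after log2(TPM+1).

    Zero-variance genes become all-zero rows and are listed in
    ``result.attrs['zero_variance_genes']``.
    """
    if m.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    x = np.log2(m.astype(float) + 1.0) if log_transform else m.astype(float)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=0)
    flat = sd == 0
    sd_safe = sd.replace(0, 1.0)
    z = x.sub(mu, axis=0).div(sd_safe, axis=0)
    z.attrs["zero_variance_genes"] = list(x.index[flat])
    return z


def ssgsea_score(
    z: pd.DataFrame,
    gene_set: GeneSet,
    exponent: float = SSGSEA_EXPONENT,
    normalize: bool = False,
) -> pd.Series:
    """Per-sample single-sample GSEA running-sum score on a z-scored matrix.

    Ties in z are broken by gene id (stable, deterministic).  With
    ``normalize`` the raw running-sum is divided by the gene count, making
    scores comparable across sets of different size.
    """
    genes = z.index.to_numpy(dtype=object)
    in_set = np.isin(genes, list(gene_set.genes))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError(f"no genes of set {gene_set.name!r} are in the matrix")
    if n_in == len(genes):
        raise ValueError(f"set {gene_set.name!r} covers every gene; complement is empty")
    scores = {}
    for sample in z.columns:
        zv = z[sample].to_numpy(dtype=float)
        order = np.lexsort((genes, -zv))  # descending z, ties by gene id
        in_sorted = in_set[order]
        w = np.abs(zv[order]) ** exponent if exponent != 0 else np.ones_like(zv)
        w_in = np.where(in_sorted, w, 0.0)
        denom_in = w_in.sum()
        p_in = np.cumsum(w_in) / denom_in if denom_in > 0 else np.cumsum(in_sorted) / n_in
        p_out = np.cumsum(~in_sorted) / (len(genes) - n_in)
        score = float(np.sum(p_in - p_out))
        scores[sample] = score / len(genes) if normalize else score
    return pd.Series(scores, name=f"ssGSEA:{gene_set.name}")


def proliferation_index(
    m: pd.DataFrame,
    pi_genes: GeneSet,
    mode: str = "sum",
    min_present: int = 8,
    log_transform: bool = True,
) -> pd.Series:
    """Proliferation index: aggregate of z-scored log2(TPM+1) over the
    11-gene proliferation panel (sum by default; mean via ``mode``)."""
    present = sorted(pi_genes.genes & set(m.index))
    missing = sorted(pi_genes.genes - set(m.index))
    if len(present) < min_present:
        raise ValueError(
            f"proliferation index needs >= {min_present} of {len(pi_genes)} genes; "
            f"missing: {missing}"
        )
    z = zscore_across_samples(m, log_transform=log_transform)
    sub = z.loc[present]
    agg = sub.sum(axis=0) if mode == "sum" else sub.mean(axis=0)
    agg.name = "PI"
    return agg


@dataclass
class PairedChange:
    patient_id: str
    early: float
    late: float
    delta: float
    cls: str


def classify_pi_change(early: float, late: float, patient_id: str = "") -> PairedChange:
    """Change class for the proliferation index: high increase (delta > 1),
    increase (0.4 < delta <= 1), decrease (delta < -0.4), else no change."""
    delta = late - early
    if delta > PI_HIGH_INCREASE:
        cls = "high increase"
    elif delta > PI_INCREASE:
        cls = "increase"
    elif delta < -PI_INCREASE:
        cls = "decrease"
    else:
        cls = "no change"
    return PairedChange(patient_id, early, late, delta, cls)


def count_expressed_cgas(
    m: pd.DataFrame, cga_genes: GeneSet, tpm_threshold: float = CGA_TPM_THRESHOLD
) -> pd.Series:
    """Per-sample count of cancer-germline antigens expressed at TPM strictly
    above the threshold.  Expects a raw TPM matrix, not z-scores."""
    present = sorted(cga_genes.genes & set(m.index))
    sub = m.loc[present] if present else m.iloc[0:0]
    counts = (sub > tpm_threshold).sum(axis=0).astype(int)
    counts.name = "CGA_count"
    return counts.reindex(m.columns, fill_value=0)


def classify_cga_change(early: int, late: int, patient_id: str = "") -> PairedChange:
    """Increased iff the expressed-CGA count rises by >= 3 (mirrored for
    decreases); everything else is no change."""
    delta = late - early
    if delta >= CGA_INCREASE_DELTA:
        cls = "increased"
    elif delta <= -CGA_INCREASE_DELTA:
        cls = "decreased"
    else:
        cls = "no change"
    return PairedChange(patient_id, float(early), float(late), float(delta), cls)


def panel_index(m: pd.DataFrame, panel: GeneSet, log_transform: bool = True) -> pd.Series:
    """Mean z-scored log2(TPM+1) over a gene panel (NFkB index, HLA scores)."""
    present = sorted(panel.genes & set(m.index))
    if not present:
        raise ValueError(f"no genes of panel {panel.name!r} are in the matrix")
    z = zscore_across_samples(m, log_transform=log_transform)
    idx = z.loc[present].mean(axis=0)
    idx.name = panel.name
    return idx


def fold_change(
    m: pd.DataFrame, gene: str, early: str, late: str, pseudocount: float = 1.0
) -> tuple[float, dict[str, bool]]:
    """TPM fold change (late + c)/(early + c) with the >1.5 / >3 flags used
    for MYC-transcription concordance reporting."""
    if gene not in m.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    for s in (early, late):
        if s not in m.columns:
            raise KeyError(f"sample {s!r} not in matrix")
    fc = (float(m.at[gene, late]) + pseudocount) / (float(m.at[gene, early]) + pseudocount)
    return fc, {"fc_gt_1_5": fc > 1.5, "fc_gt_3": fc > 3.0}


def spearman_panel(
    scores: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    min_overlap: int = 5,
    highlight: float = SPEARMAN_HIGHLIGHT,
) -> pd.DataFrame:
    """Spearman rho and p per score pair on a samples x scores table.

    Pairs with fewer than ``min_overlap`` jointly non-missing samples are
    skipped with a warning row (rho = NaN).  Benjamini-Hochberg-adjusted
    q-values are reported alongside raw p.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for a, b in pairs:
        sub = scores[[a, b]].dropna()
        if len(sub) < min_overlap:
            rows.append({"score_a": a, "score_b": b, "n": len(sub), "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(sub[a], sub[b])
        rows.append({"score_a": a, "score_b": b, "n": len(sub), "rho": float(rho), "p": float(p)})
    df = pd.DataFrame(rows, columns=["score_a", "score_b", "n", "rho", "p"])
    ok = df["p"].notna()
    df["q_bh"] = np.nan
    if ok.any():
        df.loc[ok, "q_bh"] = multipletests(df.loc[ok, "p"], method="fdr_bh")[1]
    df["highlight"] = df["rho"].abs() >= highlight
    return df


# ---------------------------------------------------------------------------
# Packaged default panels (reconstructed lists; edit the GMT to change them)

_DATA_DIR = Path(__file__).parent / "data"


def default_panels() -> dict[str, GeneSet]:
    """Panels shipped with the package: PI (11 proliferation genes), CGA
    (27 hematological cancer-germline antigens), NFkB index, HLA-I/II,
    ABC transporters and exportins.  The lists are reconstructed from the
    cited literature sources and meant to be edited for real analyses."""
    return read_gmt(_DATA_DIR / "default_panels.gmt")
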