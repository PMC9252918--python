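"""Cancer cell fractions, paired-timepoint clustering and clonal evolution.

The CCF of a mutation is the fraction of tumor cells that carry it, obtained
from the variant allele fraction f, tumor purity p, local total copy number
CNt and mutation multiplicity m:

    m   = clamp(round(f/p * (p*CNt + (1-p)*2)), 1, max(CNt, 1))
    CCF = f * (p*CNt + (1-p)*2) / (p * m)

Paired early/late CCFs are clustered with 2-D Gaussian mixtures (EM with
multiple restarts, model order by BIC) — a finite-mixture stand-in for
Dirichlet-process subclonal reconstruction, sufficient because the
classification layer consumes only cluster means and weights.  Cluster
trajectories are then classified into the three canonical paired-sample
patterns: a shift in clonal dominance (differential clonal response),
acquisition of new aberrations on a retained backbone (linear evolution) or
no/minor change (stable evolution).  A RAS shift is the replacement of a
falling KRAS/NRAS-mutant clone by a rising clone with a different KRAS/NRAS
mutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .mutcat import MutationRecord

logger = logging.getLogger(__name__)

CCF_CAP = 1.5
TAU_SHIFT = 0.3   # minimum rise/fall of a cluster to count as a dominance shift
TAU_NEW = 0.25    # minimum late CCF for an emerging cluster
TAU_MINOR = 0.1   # below this a cluster is absent / a move is "minor"
K_MAX = 6
N_RESTARTS = 10

RAS_GENES = frozenset({"KRAS", "NRAS"})


@dataclass
class CopyNumberSegment:
    """Allele-specific copy-number segment, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if not 0 <= self.minor_cn <= self.total_cn:
            raise ValueError("minor_cn must be in [0, total_cn]")

    def covers(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class CcfEstimate:
    key: tuple  # (chrom, pos, ref, alt)
    sample_id: str
    ccf: float
    multiplicity: int
    tumor_cn: int
    flags: list = field(default_factory=list)


def segment_for(
    segments: Sequence[CopyNumberSegment], chrom: str, pos: int
) -> Optional[CopyNumberSegment]:
    for seg in segments:
        if seg.covers(chrom, pos):
            return seg
    return None


def compute_ccf(
    m: MutationRecord,
    seg: Optional[CopyNumberSegment],
    purity: float,
    cap: float = CCF_CAP,
) -> CcfEstimate:
    """CCF for one mutation given its covering segment and sample purity.

    With no covering segment a diploid fallback (CNt = 2) is used and the
    estimate is flagged.  Values above ``cap`` are truncated and flagged as
    likely multiplicity/copy-number errors.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    flags: list[str] = []
    if seg is None:
        cnt = 2
        flags.append("no_covering_segment")
    else:
        cnt = seg.total_cn
    vaf = m.vaf
    denom = purity * cnt + (1 - purity) * 2
    mult = int(np.clip(round(vaf / purity * denom), 1, max(cnt, 1)))
    ccf = vaf * denom / (purity * mult)
    if ccf > cap:
        flags.append("ccf_capped")
        ccf = cap
    return CcfEstimate(
        key=m.key, sample_id=m.sample_id, ccf=ccf, multiplicity=mult, tumor_cn=cnt, flags=flags
    )


@dataclass
class CcfClusterSolution:
    """Gaussian-mixture solution on paired (early, late) CCFs."""

    clusters: list[tuple[float, float, float, int]]  # (mean_early, mean_late, weight, n)
    assignments: np.ndarray
    model_score: float  # BIC of the selected model (lower is better)
    k: int
    warnings: list = field(default_factory=list)


def cluster_pair(
    ccfs_early: Sequence[float],
    ccfs_late: Sequence[float],
    k_max: int = K_MAX,
    n_restarts: int = N_RESTARTS,
    seed: Optional[int] = None,
    min_variants: int = 10,
) -> CcfClusterSolution:
    """Cluster aligned per-variant (early, late) CCF pairs.

    Fits diagonal-covariance Gaussian mixtures for k = 1..k_max with
    ``n_restarts`` seeded initializations each and selects k by BIC.
    Variants private to one timepoint should enter with CCF 0 at the other.
    Below ``min_variants`` shared variants the solution degrades to a single
    cluster with a warning.
    """
    from sklearn.mixture import GaussianMixture

    X = np.column_stack([np.asarray(ccfs_early, float), np.asarray(ccfs_late, float)])
    n = X.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 variants")
    warns: list[str] = []
    if n < min_variants:
        warns.append(f"only {n} variants; degraded single-cluster mode")
        mean = X.mean(axis=0)
        return CcfClusterSolution(
            clusters=[(float(mean[0]), float(mean[1]), 1.0, n)],
            assignments=np.zeros(n, dtype=int),
            model_score=float("nan"),
            k=1,
            warnings=warns,
        )
    best = None
    rs = np.random.RandomState(seed if seed is not None else 0)
    for k in range(1, min(k_max, n) + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=n_restarts,
            reg_covar=1e-4,
            max_iter=500,
            random_state=rs.randint(0, 2**31 - 1),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, gm, k)
    bic, gm, k = best
    labels = gm.predict(X)
    clusters = []
    for j in range(k):
        nj = int((labels == j).sum())
        clusters.append((float(gm.means_[j, 0]), float(gm.means_[j, 1]), float(gm.weights_[j]), nj))
    return CcfClusterSolution(
        clusters=clusters, assignments=labels, model_score=float(bic), k=k, warnings=warns
    )


@dataclass
class EvolutionCall:
    patient_id: str
    pair: tuple[str, str]
    pattern: str  # stable | linear | differential
    evidence: list


def classify_evolution(
    sol: CcfClusterSolution,
    tau_shift: float = TAU_SHIFT,
    tau_new: float = TAU_NEW,
    tau_minor: float = TAU_MINOR,
    patient_id: str = "",
    pair: tuple[str, str] = ("early", "late"),
) -> EvolutionCall:
    """Classify a cluster solution as differential, linear or stable.

    differential — a cluster falls by >= tau_shift while another rises by
    >= tau_shift, or a cluster vanishes (late < tau_minor from >= tau_new)
    while a distinct one emerges (early < tau_minor to >= tau_new);
    linear — an emerging cluster with the ancestral clusters retained;
    stable — otherwise (all moves minor).  Precedence is
    differential > linear > stable and every solution maps to exactly one
    pattern.
    """
    evidence: list[str] = []
    deltas = [(e, l, l - e) for (e, l, _w, _n) in sol.clusters]
    falls = [i for i, (e, l, d) in enumerate(deltas) if d <= -tau_shift]
    rises = [i for i, (e, l, d) in enumerate(deltas) if d >= tau_shift]
    vanishing = [i for i, (e, l, _d) in enumerate(deltas) if e >= tau_new and l < tau_minor]
    emerging = [i for i, (e, l, _d) in enumerate(deltas) if e < tau_minor and l >= tau_new]

    differential = (falls and rises and set(falls) != set(rises)) or (
        vanishing and emerging and set(vanishing) != set(emerging)
    )
    if differential:
        for i in falls or vanishing:
            e, l, d = deltas[i]
            evidence.append(f"cluster {i} fell {e:.2f}->{l:.2f}")
        for i in rises or emerging:
            e, l, d = deltas[i]
            evidence.append(f"cluster {i} rose {e:.2f}->{l:.2f}")
        pattern = "differential"
    elif emerging:
        for i in emerging:
            e, l, _ = deltas[i]
            evidence.append(f"cluster {i} emerged {e:.2f}->{l:.2f}")
        pattern = "linear"
    else:
        pattern = "stable"
        moved = [i for i, (_e, _l, d) in enumerate(deltas) if abs(d) >= tau_minor]
        if moved:
            evidence.append(f"clusters {moved} moved >= {tau_minor} but below shift thresholds")
    return EvolutionCall(patient_id=patient_id, pair=pair, pattern=pattern, evidence=evidence)


def detect_ras_shift(
    trajectories: Sequence[tuple[str, float, float]],
    tau_shift: float = TAU_SHIFT,
    tau_new: float = TAU_NEW,
    tau_minor: float = TAU_MINOR,
) -> tuple[bool, dict]:
    """RAS-shift call from per-mutation (label, ccf_early, ccf_late) triples.

    True iff some KRAS/NRAS mutation's CCF decreases by >= tau_shift (or
    disappears: from >= tau_new to < tau_minor) while a *different* RAS
    mutation rises by >= tau_new between the same timepoints.  Labels are
    expected as "GENE p.Change" or any unique per-mutation identifier.
    """
    falling = []
    rising = []
    for label, early, late in trajectories:
        if early - late >= tau_shift or (early >= tau_new and late < tau_minor):
            falling.append(label)
        if late - early >= tau_new:
            rising.append(label)
    shift = any(f != r for f in falling for r in rising)
    return shift, {"falling": falling, "rising": rising}


def expressed_fraction(
    muts: Sequence[MutationRecord], min_rna_alt: int = 1
) -> tuple[Optional[float], list[Optional[bool]]]:
    """Fraction of mutations with RNA evidence of expression.

    A mutation counts as expressed when its RNA alt-read count reaches
    ``min_rna_alt``.  Records without RNA data are excluded from the
    denominator (flag None); an empty denominator yields fraction None.
    """
    flags: list[Optional[bool]] = []
    for m in muts:
        if m.rna_alt_reads is None:
            flags.append(None)
        else:
            flags.append(m.rna_alt_reads >= min_rna_alt)
    informative = [f for f in flags if f is not None]
    if not informative:
        return None, flags
    return sum(informative) / len(informative), flags


# ---------------------------------------------------------------------------
# Copy-number locus flags (gain1q / amp1q21 / del17p)

DEFAULT_LOCI = {
    # toy/GRCh38-scale defaults; override per genome build in config
    "1q21": ("chr1", 143_000_000, 149_000_000),
    "17p": ("chr17", 1, 22_200_000),
}


def cn_locus_flags(
    segments: Sequence[CopyNumberSegment], loci: Optional[dict] = None
) -> dict[str, bool]:
    """gain1q (CNt == 3), amp1q21 (CNt >= 4) and del17p (CNt < 2) calls from
    the maximum/minimum total copy number over the configured loci."""
    loci = loci or DEFAULT_LOCI
    out = {"gain1q": False, "amp1q21": False, "del17p": False}
    chrom_1q, s1, e1 = loci["1q21"]
    chrom_17p, s17, e17 = loci["17p"]
    for seg in segments:
        if seg.chrom == chrom_1q and seg.start <= e1 and seg.end >= s1:
            if seg.total_cn >= 4:
                out["amp1q21"] = True
            elif seg.total_cn == 3:
                out["gain1q"] = True
        if seg.chrom == chrom_17p and seg.start <= e17 and seg.end >= s17:
            if seg.total_cn < 2:
                out["del17p"] = True
    return out
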