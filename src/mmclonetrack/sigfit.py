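"""Mutational signature refitting with bootstrap CIs and presence calls.

Known signature profiles are fit to an SBS-96 catalog by maximum likelihood
under a multinomial mixture (EM), followed by a parsimony pass that removes
signatures whose elimination costs less than a small reconstruction-cosine
threshold.  Uncertainty comes from a multinomial bootstrap of the catalog:
each replicate is refit (including parsimony, so a replicate's weight can be
exactly zero) and percentile confidence intervals are taken per signature.
A signature is called present when its CI lower bound exceeds zero — the
"95% CI > 0" rule used for the melphalan signature SBS-MM1.

The transcriptional strand-bias companion test compares transcribed versus
untranscribed C>T counts in the five SBS-MM1-typical contexts (CCA, GCA,
GCC, GCG, GCT) with an exact conditional binomial test: conditioning two
Poisson strand rates on their total makes the transcribed count binomial
with p0 = 1/2 under symmetry, so this is the exact equivalent of the Poisson
rate test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mutcat import CHANNELS, CHANNEL_INDEX, StrandedContextCounts, TrinucleotideCatalog, channel_context

MM1_NAME = "SBS-MM1"
#: Pyrimidine-strand contexts of the SBS-MM1 strand-bias pattern (C>T).
MM1_CONTEXTS = frozenset({"CCA", "GCA", "GCC", "GCG", "GCT"})

EM_TOL = 1e-8
EM_MAX_ITER = 10_000
PRUNE_EPSILON = 0.01


@dataclass
class SignatureReference:
    """Named signature profiles over the 96 channels (rows sum to 1)."""

    names: list[str]
    profiles: np.ndarray  # (n_signatures, 96)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape != (len(self.names), 96):
            raise ValueError("profiles must be (n_signatures, 96)")
        if (self.profiles < 0).any():
            raise ValueError("signature profiles must be nonnegative")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-8):
            bad = [self.names[i] for i in np.where(np.abs(sums - 1) > 1e-8)[0]]
            raise ValueError(f"profiles must sum to 1: {bad}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate signature names")

    def __len__(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, names: Sequence[str]) -> "SignatureReference":
        idx = [self.index_of(n) for n in names]
        return SignatureReference(list(names), self.profiles[idx])

    @classmethod
    def from_tsv(cls, path) -> "SignatureReference":
        """First column: channel labels; remaining columns: signatures."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if set(df.index) != set(CHANNELS):
            raise ValueError(f"{path}: channel column must cover the 96 SBS channels")
        df = df.reindex(list(CHANNELS))
        return cls(list(df.columns), df.to_numpy().T)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.profiles.T, index=list(CHANNELS), columns=self.names)
        df.index.name = "channel"
        df.to_csv(path, sep="\t")


def toy_reference(seed: int = 20220528) -> SignatureReference:
    """Packaged 5-signature toy reference including an SBS-MM1-like profile.

    Four background signatures are random sparse profiles (deterministic
    seed); the SBS-MM1-like profile concentrates 70% of its mass on C>T in
    the five melphalan-typical contexts.  Intended for tests and simulation;
    real analyses should load a user-supplied (e.g. COSMIC) matrix.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    names = ["SBS-A", "SBS-B", "SBS-C", "SBS-D", MM1_NAME]
    for _ in range(4):
        p = rng.gamma(0.3, size=96)
        profiles.append(p / p.sum())
    mm1 = rng.gamma(0.15, size=96) * 0.05
    for ctx in sorted(MM1_CONTEXTS):
        ch = f"{ctx[0]}[C>T]{ctx[2]}"
        mm1[CHANNEL_INDEX[ch]] += 1.0
    profiles.append(mm1 / mm1.sum())
    return SignatureReference(names, np.array(profiles))


@dataclass
class SignatureExposure:
    """Fitted relative signature contributions with bootstrap CIs."""

    sample_id: str
    names: list[str]
    weights: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_mutations: int
    n_bootstrap: int
    level: float = 0.95

    @property
    def present(self) -> np.ndarray:
        """Presence per signature: CI lower bound strictly above zero."""
        return self.ci_low > 0

    def __getitem__(self, name: str) -> dict:
        i = self.names.index(name)
        return {
            "weight": float(self.weights[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "present": bool(self.present[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "signature": self.names,
                "weight": self.weights,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "present": self.present,
                "n_mutations": self.n_mutations,
                "n_bootstrap": self.n_bootstrap,
            }
        )


@dataclass
class StrandBiasResult:
    """Exact-binomial comparison of transcribed vs untranscribed counts."""

    transcribed_count: int
    untranscribed_count: int
    ratio: float  # transcribed / untranscribed; nan when undefined
    p_value: float
    significant: bool
    alpha: float = 0.05
    undefined: bool = False


# ---------------------------------------------------------------------------
# EM core (batched over catalogs; zero-initialized weights stay zero, which
# implements per-replicate signature subsets)


def _em_batch(
    counts: np.ndarray,
    profiles: np.ndarray,
    w0: Optional[np.ndarray] = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> np.ndarray:
    """Maximum-likelihood mixture weights for each row of ``counts``.

    counts: (B, 96) nonnegative; profiles: (S, 96); returns (B, S) weights
    summing to 1 per row.  Convergence on mean per-mutation log-likelihood
    change < tol.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    B, S = counts.shape[0], profiles.shape[0]
    totals = counts.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("each catalog must contain at least one mutation")
    W = np.full((B, S), 1.0 / S) if w0 is None else w0.copy()
    W /= W.sum(axis=1, keepdims=True)
    P = profiles
    prev_ll = np.full(B, -np.inf)
    tiny = np.finfo(float).tiny
    for _ in range(max_iter):
        D = W @ P  # (B, 96) mixture probabilities
        np.maximum(D, tiny, out=D)
        ll = (counts * np.log(D)).sum(axis=1) / totals[:, 0]
        W = W * ((counts / D) @ P.T) / totals
        if np.all(np.abs(ll - prev_ll) < tol):
            break
        prev_ll = ll
    return W / W.sum(axis=1, keepdims=True)


def _cosine_batch(counts: np.ndarray, W: np.ndarray, P: np.ndarray) -> np.ndarray:
    recon = W @ P
    num = (counts * recon).sum(axis=1)
    den = np.linalg.norm(counts, axis=1) * np.linalg.norm(recon, axis=1)
    return np.where(den > 0, num / np.maximum(den, np.finfo(float).tiny), 0.0)


def _prune_batch(
    counts: np.ndarray,
    ref: SignatureReference,
    epsilon: float,
    protected: frozenset = frozenset(),
) -> np.ndarray:
    """Backward elimination on a batch of catalogs.

    Signatures are tried in order of increasing pooled weight; a removal is
    accepted per catalog when the reconstruction cosine similarity drops by
    less than ``epsilon``.  Protected signatures are never removed.  Removed
    signatures have weight exactly 0 in the returned matrix.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    P = ref.profiles
    B, S = counts.shape[0], P.shape[0]
    W = _em_batch(counts, P)
    cos = _cosine_batch(counts, W, P)
    order = np.argsort(W.sum(axis=0))  # least-used signatures first
    for s in order:
        if ref.names[s] in protected:
            continue
        active = W[:, s] > 0
        if not active.any():
            continue
        w0 = W.copy()
        w0[:, s] = 0.0
        # rows whose only remaining signature would vanish cannot prune s
        row_ok = w0.sum(axis=1) > 0
        trial = W.copy()
        trial[row_ok] = _em_batch(counts[row_ok], P, w0=w0[row_ok])
        cos_trial = _cosine_batch(counts, trial, P)
        accept = active & row_ok & (cos - cos_trial < epsilon)
        W[accept] = trial[accept]
        cos[accept] = cos_trial[accept]
    return W


# ---------------------------------------------------------------------------
# Public operations


def fit_exposures(
    catalog: TrinucleotideCatalog,
    ref: SignatureReference,
    prune: bool = True,
    epsilon: float = PRUNE_EPSILON,
    protected: Iterable[str] = (MM1_NAME,),
) -> np.ndarray:
    """Point-estimate signature weights for one catalog.

    EM to the multinomial maximum likelihood, then (optionally) a parsimony
    pass.  SBS-MM1 is protected from pruning by default so that its presence
    is always judged by the bootstrap CI rather than by elimination.
    """
    if catalog.total < 1:
        raise ValueError(
            "empty catalog: signature fitting needs at least one mutation "
            "(typically tens for a stable fit)"
        )
    if len(ref) == 0:
        raise ValueError("signature reference is empty")
    counts = catalog.counts[None, :].astype(float)
    if prune and len(ref) > 1:
        W = _prune_batch(counts, ref, epsilon, protected=frozenset(protected) & set(ref.names))
    else:
        W = _em_batch(counts, ref.profiles)
    return W[0]


def bootstrap_ci(
    catalog: TrinucleotideCatalog,
    ref: SignatureReference,
    n_bootstrap: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    prune: bool = True,
    epsilon: float = PRUNE_EPSILON,
) -> SignatureExposure:
    """Multinomial-bootstrap percentile CIs and presence flags.

    The catalog's mutations are resampled with replacement (multinomial on
    the normalized channel frequencies, same total) and each replicate is
    refit with full parsimony — so a replicate's weight for an unsupported
    signature is exactly zero and the CI lower bound can reach 0.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if not 0 < level < 1:
        raise ValueError("CI level must be in (0, 1)")
    point = fit_exposures(catalog, ref, prune=prune, epsilon=epsilon)
    rng = np.random.default_rng(seed)
    n = catalog.total
    p = catalog.counts / n
    boot_counts = rng.multinomial(n, p, size=n_bootstrap).astype(float)
    # drop degenerate all-zero rows cannot happen (n >= 1)
    if prune and len(ref) > 1:
        W = _prune_batch(boot_counts, ref, epsilon, protected=frozenset())
    else:
        W = _em_batch(boot_counts, ref.profiles)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    ci_low = np.percentile(W, lo_q, axis=0)
    ci_high = np.percentile(W, hi_q, axis=0)
    return SignatureExposure(
        sample_id=catalog.sample_id,
        names=list(ref.names),
        weights=point,
        ci_low=ci_low,
        ci_high=ci_high,
        n_mutations=n,
        n_bootstrap=n_bootstrap,
        level=level,
    )


def group_fit(
    catalogs: Sequence[TrinucleotideCatalog],
    ref: SignatureReference,
    group_id: str = "group",
    **kwargs,
) -> SignatureExposure:
    """Pool catalogs element-wise and fit + bootstrap the pooled catalog.

    Pooling dilutes a signature carried by few members — the behavior behind
    group-level absence calls when only a minority of samples carry SBS-MM1.
    """
    if not catalogs:
        raise ValueError("group_fit needs at least one catalog")
    pooled = TrinucleotideCatalog(
        sample_id=group_id, counts=np.sum([c.counts for c in catalogs], axis=0)
    )
    return bootstrap_ci(pooled, ref, **kwargs)


def strand_bias_test(
    sc: StrandedContextCounts,
    contexts: Iterable[str] = MM1_CONTEXTS,
    alpha: float = 0.05,
    substitution: str = "C>T",
) -> StrandBiasResult:
    """Two-sided exact binomial test of strand symmetry for C>T counts in the
    given pyrimidine-strand contexts (defaults: the SBS-MM1 pattern)."""
    t, u = sc.strand_totals(contexts=contexts, substitution=substitution)
    n = t + u
    if n == 0:
        return StrandBiasResult(0, 0, float("nan"), 1.0, False, alpha=alpha, undefined=True)
    p = stats.binomtest(t, n, 0.5, alternative="two-sided").pvalue
    ratio = t / u if u > 0 else float("inf")
    return StrandBiasResult(t, u, ratio, float(p), bool(p < alpha), alpha=alpha)


def write_exposure_tsv(exposures: Sequence[SignatureExposure], path) -> None:
    pd.concat([e.to_frame() for e in exposures], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
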