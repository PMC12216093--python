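"""Participant identification from natural-frequency maps.

Fingerprinting correlates every participant's first-instance map with
every participant's second-instance map (Kendall's tau-b over
pairwise-complete voxels, since the maps are non-Gaussian and heavily
tied on the discrete fine-frequency grid).  Each first-instance map is
matched to the second-instance map with the highest correlation; the
fraction of participants matching themselves is the identification
accuracy.  Per-subject quality metrics follow the fingerprinting
literature:

* identifiability  I_self = tau_self - mu_others
* differentiability D_self = (tau_self - mu_others) / sigma_others

where mu_others and sigma_others summarise a subject's off-diagonal
correlations (own row and column pooled).  Uncertainty comes from a
subject-level bootstrap of the accuracy; significance from a
column-relabelling permutation null, whose expected number of correct
matches is 1 (fixed points of a uniform random permutation) regardless
of cohort size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import NaturalFrequencyMap

__all__ = [
    "FingerprintResult",
    "kendall_tau",
    "build_tau_matrix",
    "identify",
    "identifiability_metrics",
    "bootstrap_accuracy_ci",
    "permutation_null",
    "group_comparisons",
    "fingerprint",
]

logger = logging.getLogger(__name__)


def kendall_tau(u: np.ndarray, v: np.ndarray) -> float:
    """Kendall's tau-b between two maps over pairwise-complete voxels.

    Positions where either map is missing (NaN) are dropped; at least
    three complete pairs are required, and a vector that is constant on
    the complete positions leaves tau undefined.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("maps must have equal length")
    ok = np.isfinite(u) & np.isfinite(v)
    if ok.sum() < 3:
        raise ValueError(f"only {int(ok.sum())} complete pairs; need >= 3")
    tau = stats.kendalltau(u[ok], v[ok], variant="b").statistic
    if not np.isfinite(tau):
        raise ValueError("tau undefined (a map is constant on complete pairs)")
    return float(tau)


def _map_vectors(
    maps1: list[NaturalFrequencyMap] | np.ndarray,
    maps2: list[NaturalFrequencyMap] | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if isinstance(maps1, np.ndarray) and isinstance(maps2, np.ndarray):
        if maps1.shape != maps2.shape:
            raise ValueError("map arrays must have the same shape")
        subjects = [f"S{i:02d}" for i in range(maps1.shape[0])]
        return np.asarray(maps1, float), np.asarray(maps2, float), subjects
    ids1 = [m.subject_id for m in maps1]
    ids2 = [m.subject_id for m in maps2]
    if set(ids1) != set(ids2):
        raise ValueError("the two map sets cover different subjects")
    order2 = {m.subject_id: m for m in maps2}
    A = np.stack([m.freq_hz for m in maps1])
    B = np.stack([order2[s].freq_hz for s in ids1])
    if A.shape[1] != B.shape[1]:
        raise ValueError("maps have different voxel counts")
    return A, B, ids1


def build_tau_matrix(
    maps1: list[NaturalFrequencyMap] | np.ndarray,
    maps2: list[NaturalFrequencyMap] | np.ndarray,
) -> np.ndarray:
    """tau[i, j] = Kendall tau-b(instance-1 map of i, instance-2 map of j)."""
    A, B, _ = _map_vectors(maps1, maps2)
    N = A.shape[0]
    tau = np.empty((N, N))
    for i in range(N):
        for j in range(N):
            tau[i, j] = kendall_tau(A[i], B[j])
    return tau


def identify(tau: np.ndarray) -> tuple[np.ndarray, float]:
    """Row-wise matching: each instance-1 map picks the most correlated
    instance-2 map.  Returns the binary match matrix and the accuracy in
    percent (diagonal matches / N).  Ties go to the lowest column index.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.ndim != 2 or tau.shape[0] != tau.shape[1]:
        raise ValueError("tau must be square")
    N = tau.shape[0]
    best = np.argmax(tau, axis=1)
    ties = np.sum(tau == tau[np.arange(N), best][:, None], axis=1) > 1
    if ties.any():
        logger.info("argmax tie in %d row(s); lowest index kept", int(ties.sum()))
    match = np.zeros_like(tau, dtype=int)
    match[np.arange(N), best] = 1
    accuracy_pct = 100.0 * float(np.trace(match)) / N
    return match, accuracy_pct


def identifiability_metrics(tau: np.ndarray) -> pd.DataFrame:
    """Per-subject tau_self, mu_others, sigma_others, I_self, D_self.

    mu/sigma_others pool the off-diagonal entries of the subject's row
    and column (2(N-1) values, sd with ddof = 1).  sigma_others = 0
    leaves D_self undefined (NaN, flagged).
    """
    tau = np.asarray(tau, dtype=float)
    N = tau.shape[0]
    if N < 3:
        raise ValueError("need at least 3 subjects")
    rows = []
    for i in range(N):
        others = np.concatenate([np.delete(tau[i, :], i), np.delete(tau[:, i], i)])
        mu = float(others.mean())
        sigma = float(others.std(ddof=1))
        if sigma <= 1e-12 * max(1.0, abs(mu)):  # degenerate up to roundoff
            sigma = 0.0
        tau_self = float(tau[i, i])
        I_self = tau_self - mu
        if sigma == 0:
            logger.warning("subject %d: sigma_others = 0; D_self undefined", i)
            D_self = np.nan
        else:
            D_self = I_self / sigma
        rows.append(
            {
                "tau_self": tau_self,
                "mu_others": mu,
                "sigma_others": sigma,
                "I_self": I_self,
                "D_self": D_self,
                "sigma_zero": sigma == 0,
            }
        )
    return pd.DataFrame(rows)


def bootstrap_accuracy_ci(
    tau: np.ndarray,
    n_boot: int = 10000,
    seed: int | None = None,
    level: float = 95.0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the identification accuracy.

    Each iteration resamples subjects with replacement, re-indexes rows
    and columns identically, re-runs the matching, and records the
    accuracy; the CI spans the 2.5th-97.5th percentiles (at the default
    level).  A resampled participant counts as correctly identified when
    its best match is any copy of itself: duplicates drawn by the
    resampling have identical tau columns, so identity — not column
    position — defines a correct match.
    """
    tau = np.asarray(tau, dtype=float)
    N = tau.shape[0]
    rng = np.random.default_rng(seed)
    acc = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, N, size=N)
        sub = tau[np.ix_(idx, idx)]
        best = np.argmax(sub, axis=1)
        acc[b] = 100.0 * np.mean(idx[best] == idx)
    half = (100.0 - level) / 2.0
    lo, hi = np.percentile(acc, [half, 100.0 - half])
    return float(lo), float(hi)


@dataclass
class PermutationNull:
    max_rate_pct: float
    p_value: float
    accuracies_pct: np.ndarray
    mean_matches: float


def permutation_null(
    tau: np.ndarray, n_perm: int = 10000, seed: int | None = None
) -> PermutationNull:
    """Column-relabelling permutation null of the identification.

    Each iteration permutes the identities of the second-instance maps
    and re-runs the matching.  Reports the highest accuracy across
    iterations and a Monte-Carlo p-value with the +1 correction:
    p = (1 + #{perm >= observed}) / (n_perm + 1).
    """
    tau = np.asarray(tau, dtype=float)
    N = tau.shape[0]
    _, observed = identify(tau)
    best_col = np.argmax(tau, axis=1)  # unchanged by relabelling
    rng = np.random.default_rng(seed)
    correct = np.empty(n_perm)
    for it in range(n_perm):
        sigma = rng.permutation(N)
        # column j of the permuted gallery holds subject sigma[j]'s map,
        # so row i matches itself iff sigma[best_col[i]] == i
        correct[it] = np.sum(sigma[best_col] == np.arange(N))
    acc = 100.0 * correct / N
    p = (1.0 + float(np.sum(acc >= observed))) / (n_perm + 1.0)
    return PermutationNull(
        max_rate_pct=float(acc.max()),
        p_value=float(p),
        accuracies_pct=acc,
        mean_matches=float(correct.mean()),
    )


@dataclass
class FingerprintResult:
    """Complete fingerprinting analysis of one cohort."""

    subjects: list[str]
    tau: np.ndarray
    match: np.ndarray
    accuracy_pct: float
    metrics: pd.DataFrame  # per-subject tau_self/mu/sigma/I/D + matched flag
    ci95: tuple[float, float]
    perm: PermutationNull
    comparisons: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Natural-frequency fingerprinting",
            "=" * 40,
            f"subjects                 {self.n_subjects}",
            f"correct matches          {int(np.trace(self.match))}/{self.n_subjects}",
            f"accuracy                 {self.accuracy_pct:.2f}%",
            f"bootstrap 95% CI         [{self.ci95[0]:.2f}, {self.ci95[1]:.2f}]%",
            f"permutation max rate     {self.perm.max_rate_pct:.2f}%",
            f"permutation p            {self.perm.p_value:.4g}",
            f"tau_self                 {m.tau_self.mean():.2f} +/- {m.tau_self.std(ddof=1):.2f}",
            f"tau_others               {m.mu_others.mean():.2f} +/- {m.mu_others.std(ddof=1):.2f}",
            f"identifiability I_self   {m.I_self.mean():.2f} +/- {m.I_self.std(ddof=1):.2f}",
            f"differentiability D_self {m.D_self.mean():.2f} +/- {m.D_self.std(ddof=1):.2f}",
        ]
        for name, st in self.comparisons.items():
            if isinstance(st, dict) and "stat" in st:
                lines.append(
                    f"{name:<24} stat={st['stat']:.3f} p={st['p']:.4g}"
                    + (f" df={st['df']:.1f}" if "df" in st else "")
                )
        return "\n".join(lines)


def group_comparisons(
    result: FingerprintResult,
    elapsed_days: np.ndarray | None = None,
    maps: list[np.ndarray] | None = None,
) -> dict:
    """Inferential statistics on a fingerprinting result.

    Returns a dict with: ``self_vs_others`` (paired t of tau_self vs
    mu_others), ``I_target_vs_nontarget`` and ``D_target_vs_nontarget``
    (Welch t), ``days_vs_tau_self`` (Pearson r), ``days_target_vs_nontarget``
    (Welch t), and ``ks_normality`` (per-map Kolmogorov-Smirnov p-values
    against a fitted normal — the motivation for using Kendall rather
    than Pearson correlations between maps).
    """
    out: dict = {}
    m = result.metrics
    matched = m["matched"].to_numpy(dtype=bool)

    t = stats.ttest_rel(m.tau_self, m.mu_others)
    out["self_vs_others"] = {"stat": float(t.statistic), "p": float(t.pvalue), "df": float(t.df)}

    for name, col in (("I_target_vs_nontarget", "I_self"), ("D_target_vs_nontarget", "D_self")):
        a = m.loc[matched, col].dropna()
        b = m.loc[~matched, col].dropna()
        if len(a) < 2 or len(b) < 2:
            logger.warning("%s skipped: a group has < 2 members", name)
            continue
        w = stats.ttest_ind(a, b, equal_var=False)
        out[name] = {"stat": float(w.statistic), "p": float(w.pvalue), "df": float(w.df)}

    if elapsed_days is not None:
        days = np.asarray(elapsed_days, dtype=float)
        if np.ptp(days) == 0:
            logger.warning("elapsed days constant; Pearson correlation skipped")
        else:
            r = stats.pearsonr(days, m.tau_self)
            out["days_vs_tau_self"] = {"stat": float(r.statistic), "p": float(r.pvalue)}
        a, b = days[matched], days[~matched]
        if len(a) >= 2 and len(b) >= 2:
            w = stats.ttest_ind(a, b, equal_var=False)
            out["days_target_vs_nontarget"] = {
                "stat": float(w.statistic),
                "p": float(w.pvalue),
                "df": float(w.df),
            }
        else:
            logger.warning("elapsed-days group comparison skipped: group too small")

    if maps is not None:
        ps = []
        for vec in maps:
            x = np.asarray(vec, dtype=float)
            x = x[np.isfinite(x)]
            if x.size < 3 or x.std() == 0:
                ps.append(np.nan)
                continue
            ks = stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
            ps.append(float(ks.pvalue))
        out["ks_normality"] = {"p_values": ps}
    return out


def fingerprint(
    maps1: list[NaturalFrequencyMap] | np.ndarray,
    maps2: list[NaturalFrequencyMap] | np.ndarray,
    n_boot: int = 10000,
    n_perm: int = 10000,
    seed: int | None = None,
    elapsed_days: np.ndarray | None = None,
) -> FingerprintResult:
    """End-to-end fingerprinting of a cohort (tau matrix through stats)."""
    A, B, subjects = _map_vectors(maps1, maps2)
    tau = build_tau_matrix(A, B)
    match, accuracy = identify(tau)
    metrics = identifiability_metrics(tau)
    metrics["subject_id"] = subjects
    metrics["matched"] = np.diag(match).astype(bool)
    ss = np.random.SeedSequence(seed).spawn(2) if seed is not None else [None, None]
    ci = bootstrap_accuracy_ci(tau, n_boot=n_boot, seed=ss[0])
    perm = permutation_null(tau, n_perm=n_perm, seed=ss[1])
    if elapsed_days is None and not isinstance(maps2, np.ndarray):
        days = np.array([m.elapsed_days for m in maps2], dtype=float)
        if np.ptp(days) > 0:
            elapsed_days = days
    result = FingerprintResult(
        subjects=subjects,
        tau=tau,
        match=match,
        accuracy_pct=accuracy,
        metrics=metrics,
        ci95=ci,
        perm=perm,
    )
    all_maps = [A[i] for i in range(A.shape[0])] + [B[i] for i in range(B.shape[0])]
    result.comparisons = group_comparisons(result, elapsed_days=elapsed_days, maps=all_maps)
    return result
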