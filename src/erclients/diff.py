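"""Differential protein abundance after siRNA knockdown.

The statistical route mirrors the established knockdown-proteomics
analysis: proteins must be detected in every experiment (repeat); missing
intensities are imputed from a per-sample down-shifted Gaussian on the
log2 scale; for each targeting siRNA an unpaired two-sample t-test of the
log2 intensities against the control group gives a per-protein t and p;
p-values are corrected by a permutation false-discovery-rate procedure
(group labels permuted between control and the tested siRNA); a protein is
called affected only when its FDR-adjusted q is below alpha for BOTH
siRNAs with the same sign of the log2 fold change.

Candidate-component triage (the route that singled out the second receptor
subunit) intersects proteins passing per-siRNA abundance thresholds in a
single-depletion and a double-depletion dataset with an interaction-partner
list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .proteome_io import LfqCohort

logger = logging.getLogger(__name__)

STAT_COLUMNS = ("mean_log2fc", "t_stat", "p_value")

# p floor for the zero-variance / unequal-means sentinel (t = +-inf)
P_FLOOR = np.finfo(float).eps


# ---------------------------------------------------------------------------
# detection filter
# ---------------------------------------------------------------------------

def filter_detected(cohorts: LfqCohort | Sequence[LfqCohort]) -> set[str]:
    """Proteins detected in every experiment of every cohort.

    "Detected" means at least one quantified (non-missing) value per group
    per experiment.  A single multi-experiment cohort may be passed, or a
    sequence of cohorts (one per experiment/run).
    """
    if isinstance(cohorts, LfqCohort):
        cohorts = [cohorts]
    if not cohorts:
        raise ValueError("at least one cohort is required")
    detected: set[str] | None = None
    for cohort in cohorts:
        present = np.ones(cohort.n_proteins, dtype=bool)
        observed = ~np.isnan(cohort.intensity)
        for exp in cohort.experiments:
            for group in cohort.groups:
                cols = cohort.sample_index(group=group, experiment=exp)
                present &= observed[:, cols].any(axis=1)
        these = {p for p, keep in zip(cohort.proteins, present) if keep}
        detected = these if detected is None else detected & these
    if not detected:
        logger.warning("detection filter left an empty protein set")
        return set()
    return detected


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing(
    cohort: LfqCohort,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int = 0,
) -> LfqCohort:
    """Impute missing intensities from a down-shifted per-sample Gaussian.

    For each sample s with observed log2 mean mu_s and sd sigma_s, missing
    cells are drawn from N(mu_s - shift*sigma_s, (width*sigma_s)^2) on the
    log2 scale — the de-facto standard for left-censored (MNAR) LFQ data.
    Observed cells are untouched.
    """
    rng = np.random.default_rng(seed)
    log2 = cohort.log2_intensity()
    out = log2.copy()
    for j in range(log2.shape[1]):
        col = log2[:, j]
        observed = col[~np.isnan(col)]
        if observed.size < 2:
            raise ValueError(
                f"sample {cohort.samples[j].name!r} has {observed.size} observed "
                "values; need >= 2 to estimate imputation parameters"
            )
        mu, sigma = observed.mean(), observed.std(ddof=1)
        missing = np.isnan(col)
        if missing.any():
            out[missing, j] = rng.normal(mu - shift * sigma, width * sigma, size=missing.sum())
    return cohort.with_intensity(np.exp2(out))


# ---------------------------------------------------------------------------
# per-siRNA statistics
# ---------------------------------------------------------------------------

def _se_df(
    a: np.ndarray, b: np.ndarray, method: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Standard error of the mean difference and degrees of freedom."""
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per group")
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if method == "student":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df = np.full(a.shape[0], float(na + nb - 2))
    elif method == "welch":
        se2a, se2b = va / na, vb / nb
        se = np.sqrt(se2a + se2b)
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
        df = np.where(np.isfinite(df), df, na + nb - 2)
    else:
        raise ValueError(f"unknown t-test method {method!r}")
    return se, df


def tune_s0(diff: np.ndarray, se: np.ndarray) -> float:
    """Automatic fudge constant for the regularized d-statistic.

    Implements the significance-analysis-of-microarrays selection: for
    candidate values s0 = the 0th, 5th, ..., 100th percentile of the
    per-protein standard errors, compute d = diff / (se + s0), bin the
    proteins into 100 standard-error quantile groups, take the MAD-based
    spread of d within each group, and choose the candidate minimizing the
    coefficient of variation of those spreads — i.e. the s0 that makes the
    d-statistic's scale independent of the (noisy, low-n) variance
    estimate.  Falls back to the median standard error for very small
    protein sets where the binning is meaningless.
    """
    n = se.size
    if n < 25:
        return float(np.median(se))
    n_bins = min(100, n // 5)
    edges = np.quantile(se, np.linspace(0.0, 1.0, n_bins + 1))
    bin_idx = np.clip(np.searchsorted(edges, se, side="right") - 1, 0, n_bins - 1)
    groups = [np.flatnonzero(bin_idx == j) for j in range(n_bins)]
    groups = [g for g in groups if g.size >= 2]
    candidates = np.percentile(se, np.arange(0, 101, 5))
    best_s0, best_cv = float(np.median(se)), np.inf
    for s0c in candidates:
        d = diff / (se + s0c)
        mads = np.array([
            np.median(np.abs(d[g] - np.median(d[g]))) / 0.6745 for g in groups
        ])
        mean = mads.mean()
        if mean <= 0:
            continue
        cv = mads.std(ddof=1) / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0c)
    return best_s0


def resolve_s0(a: np.ndarray, b: np.ndarray, method: str, s0: float | str) -> float:
    """Resolve the fudge constant: ``'auto'`` runs :func:`tune_s0` on the
    observed mean differences and standard errors."""
    if s0 == "auto":
        se, _ = _se_df(a, b, method)
        return tune_s0(a.mean(axis=1) - b.mean(axis=1), se)
    return float(s0)


def _two_sample_t(
    a: np.ndarray, b: np.ndarray, method: str = "student", s0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized unpaired two-sample statistic over rows: (diff, t, p).

    ``a`` is the siRNA block, ``b`` the control block (proteins x replicates).
    ``method`` is ``student`` (pooled variance, the plain reading of an
    "unpaired t-test") or ``welch``.  With ``s0`` = 0 this is exactly the
    classical t (p two-sided from the t distribution); ``s0`` > 0 adds a
    SAM-style fudge constant to the denominator, regularizing proteins
    whose tiny sample variance would otherwise dominate the null tail
    (the p-value from the t distribution is then conservative).
    """
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    diff = ma - mb
    se, df = _se_df(a, b, method)
    denom = se + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    # zero-variance sentinels: equal means -> t=0, p=1; unequal -> t=+-inf
    zero = denom == 0
    t = np.where(zero & (diff == 0), 0.0, t)
    t = np.where(zero & (diff > 0), np.inf, t)
    t = np.where(zero & (diff < 0), -np.inf, t)
    p = np.where(
        np.isinf(t), P_FLOOR,
        2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df),
    )
    p = np.where(zero & (diff == 0), 1.0, p)
    return diff, t, p


def per_sirna_stats(
    cohort: LfqCohort,
    sirna_group: str,
    method: str = "student",
    s0: float | str = 0.0,
) -> pd.DataFrame:
    """Per-protein log2 fold change, t statistic and two-sided p for one
    targeting siRNA against the control group.

    Replicates are pooled across experiments; the cohort must be complete
    (imputed).  With the default ``s0`` = 0 this is the classical unpaired
    t-test; ``s0='auto'`` regularizes with the median standard error.
    Returns a DataFrame indexed by accession with columns ``mean_log2fc``,
    ``t_stat``, ``p_value``.
    """
    log2 = cohort.log2_intensity()
    if np.isnan(log2).any():
        raise ValueError("cohort has missing values; run impute_missing first")
    a = log2[:, cohort.sample_index(group=sirna_group)]
    b = log2[:, cohort.sample_index(group="control")]
    if a.shape[1] == 0:
        raise ValueError(f"no samples in group {sirna_group!r}")
    s0_val = resolve_s0(a, b, method, s0)
    diff, t, p = _two_sample_t(a, b, method=method, s0=s0_val)
    return pd.DataFrame(
        {"mean_log2fc": diff, "t_stat": t, "p_value": p},
        index=pd.Index(cohort.proteins, name="accession"),
    )


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def _label_arrangements(
    n_total: int, n_control: int, n_perm: int | None, rng: np.random.Generator,
) -> list[tuple[int, ...]]:
    """Control-column index sets: exhaustive when feasible, else sampled."""
    n_exhaustive = math.comb(n_total, n_control)
    if n_exhaustive < 2:
        raise ValueError("fewer than 2 distinct label arrangements possible")
    if n_perm is None or n_exhaustive <= n_perm:
        return [tuple(c) for c in combinations(range(n_total), n_control)]
    arrangements = []
    for _ in range(n_perm):
        arrangements.append(tuple(sorted(rng.choice(n_total, size=n_control, replace=False))))
    return arrangements


def estimate_pi0(t_obs: np.ndarray, t_perm: np.ndarray) -> float:
    """SAM-style null-proportion estimate: the fraction of observed t inside
    the central quartiles of the permutation t distribution, divided by 0.5
    (capped at 1)."""
    q25, q75 = np.percentile(t_perm, [25.0, 75.0])
    central = np.mean((t_obs >= q25) & (t_obs <= q75))
    return float(min(1.0, central / 0.5))


def permutation_fdr(
    cohort: LfqCohort,
    sirna_group: str,
    t_stats: np.ndarray | pd.Series | None = None,
    n_perm: int | None = None,
    seed: int = 0,
    method: str = "student",
    s0: float | str = 0.0,
    pi0: float | None = None,
) -> pd.Series:
    """Permutation-FDR q-values for the given siRNA-vs-control contrast.

    Sample labels are permuted between the control and the tested siRNA
    group only (the untested siRNA group is ignored).  With 3 vs 3
    replicates the 20 balanced arrangements are enumerated exhaustively;
    larger designs fall back to ``n_perm`` seeded random arrangements.

    For each observed cutoff c = |t_i| the expected number of false
    positives is the median over permutations b of E_b(c) = #{|t*| >= c};
    q_i = pi0 * median_b E_b(c) / #{|t_obs| >= c}, clipped to [0, 1] and
    monotonized so q is non-increasing in |t|.  ``pi0`` defaults to the
    SAM central-quartile estimate; pass a float (e.g. 1.0) to fix it.
    """
    rng = np.random.default_rng(seed)
    log2 = cohort.log2_intensity()
    if np.isnan(log2).any():
        raise ValueError("cohort has missing values; run impute_missing first")
    sirna_cols = cohort.sample_index(group=sirna_group)
    ctrl_cols = cohort.sample_index(group="control")
    cols = np.concatenate([ctrl_cols, sirna_cols])
    X = log2[:, cols]
    n_control = len(ctrl_cols)
    n_total = X.shape[1]

    # one fudge constant, resolved on the observed labels, reused for every
    # permutation (the statistic must be identical across arrangements)
    s0_val = resolve_s0(X[:, n_control:], X[:, :n_control], method, s0)
    if t_stats is None:
        t_obs = per_sirna_stats(cohort, sirna_group, method=method,
                                s0=s0_val)["t_stat"].to_numpy()
    else:
        t_obs = np.asarray(t_stats, dtype=float)

    arrangements = _label_arrangements(n_total, n_control, n_perm, rng)
    all_cols = np.arange(n_total)
    t_perm = np.empty((len(arrangements), X.shape[0]))
    for b, ctrl in enumerate(arrangements):
        ctrl = np.asarray(ctrl)
        test = np.setdiff1d(all_cols, ctrl, assume_unique=True)
        _, t_b, _ = _two_sample_t(X[:, test], X[:, ctrl], method=method, s0=s0_val)
        t_perm[b] = t_b

    abs_obs = np.abs(t_obs)
    abs_perm = np.abs(t_perm)
    abs_perm_sorted = np.sort(abs_perm, axis=1)
    m = abs_obs.size
    # E_b(c_i) = #{j: |t*_bj| >= |t_i|} via searchsorted per permutation
    exceed = m - np.vstack([
        np.searchsorted(abs_perm_sorted[b], abs_obs, side="left")
        for b in range(len(arrangements))
    ])
    med_false = np.median(exceed, axis=0)
    n_called = m - stats.rankdata(abs_obs, method="min") + 1  # #{|t_obs| >= |t_i|}

    if pi0 is None:
        pi0 = estimate_pi0(t_obs, t_perm.ravel())
    q = np.clip(pi0 * med_false / n_called, 0.0, 1.0)

    # monotonize: q_i = min estimated FDR over all cutoffs that call protein
    # i (cutoffs <= |t_i|), which makes q non-increasing in |t|
    order = np.argsort(-abs_obs, kind="stable")
    q_desc = np.minimum.accumulate(q[order][::-1])[::-1]
    q_mono = np.empty_like(q)
    q_mono[order] = q_desc
    return pd.Series(q_mono, index=pd.Index(cohort.proteins, name="accession"), name="q_value")


def diff_table(
    cohort: LfqCohort,
    sirna_group: str,
    n_perm: int | None = None,
    seed: int = 0,
    method: str = "student",
    s0: float | str = "auto",
    pi0: float | None = None,
) -> pd.DataFrame:
    """Per-siRNA stats plus permutation-FDR q in one table.

    Unlike the low-level :func:`per_sirna_stats`, the pipeline-facing
    default here is the regularized statistic (``s0='auto'``), mirroring
    the significance-analysis-of-microarrays methodology the permutation
    FDR comes from."""
    table = per_sirna_stats(cohort, sirna_group, method=method, s0=s0)
    table["q_value"] = permutation_fdr(
        cohort, sirna_group, table["t_stat"], n_perm=n_perm, seed=seed,
        method=method, s0=s0, pi0=pi0,
    )
    return table


# ---------------------------------------------------------------------------
# calls and triage
# ---------------------------------------------------------------------------

def call_affected(
    diff_sirna1: pd.DataFrame,
    diff_sirna2: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Intersect the two per-siRNA results into affected-protein calls.

    ``negative``: q < alpha for both siRNAs and both log2 fold changes < 0;
    ``positive`` analogously; everything else ``ns``.  Proteins present in
    only one result set are excluded with a log entry.
    """
    common = diff_sirna1.index.intersection(diff_sirna2.index)
    only = len(diff_sirna1.index.symmetric_difference(diff_sirna2.index))
    if only:
        logger.info("call_affected: excluded %d proteins present in one result set only", only)
    d1 = diff_sirna1.loc[common]
    d2 = diff_sirna2.loc[common]
    sig = (d1["q_value"] < alpha) & (d2["q_value"] < alpha)
    neg = sig & (d1["mean_log2fc"] < 0) & (d2["mean_log2fc"] < 0)
    pos = sig & (d1["mean_log2fc"] > 0) & (d2["mean_log2fc"] > 0)
    call = np.where(neg, "negative", np.where(pos, "positive", "ns"))
    out = pd.DataFrame(
        {
            "mean_log2fc_sirna1": d1["mean_log2fc"],
            "t_stat_sirna1": d1["t_stat"],
            "p_value_sirna1": d1["p_value"],
            "q_value_sirna1": d1["q_value"],
            "mean_log2fc_sirna2": d2["mean_log2fc"],
            "t_stat_sirna2": d2["t_stat"],
            "p_value_sirna2": d2["p_value"],
            "q_value_sirna2": d2["q_value"],
            "call": call,
        },
        index=common,
    )
    out.index.name = "accession"
    return out


def affected_sets(calls: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(negative, positive) accession sets from a call table."""
    neg = set(calls.index[calls["call"] == "negative"])
    pos = set(calls.index[calls["call"] == "positive"])
    return neg, pos


@dataclass
class TriageResult:
    """Candidate-component triage outcome with a per-protein criteria trace."""

    candidates: set[str]
    trace: pd.DataFrame  # columns: passed_single, passed_double, in_partner_list


def _passes_both_sirnas(
    diffs: tuple[pd.DataFrame, pd.DataFrame],
    p_thresh: float,
    log2fc_cut: float,
) -> pd.Series:
    d1, d2 = diffs
    common = d1.index.intersection(d2.index)
    d1, d2 = d1.loc[common], d2.loc[common]
    ok = (
        (d1["p_value"] < p_thresh) & (d1["mean_log2fc"] < log2fc_cut)
        & (d2["p_value"] < p_thresh) & (d2["mean_log2fc"] < log2fc_cut)
    )
    return ok


def triage_candidates(
    single_diffs: tuple[pd.DataFrame, pd.DataFrame],
    double_diffs: tuple[pd.DataFrame, pd.DataFrame],
    partner_list: Iterable[str],
    p_thresh: float = 0.01,
    min_reduction: float = 0.5,
) -> TriageResult:
    """Triage candidate receptor components.

    A candidate must show p < ``p_thresh`` and a log2 fold change below
    log2(1 - ``min_reduction``) for both siRNAs in BOTH the single- and the
    double-depletion dataset, and appear in the interaction-partner list.
    The defaults (p < 0.01, >50% reduction, i.e. log2 fold < -1) are the
    published candidate-search thresholds.
    """
    partners = set(partner_list)
    if not partners:
        logger.warning("triage: empty partner list -> no candidates")
    log2fc_cut = math.log2(1.0 - min_reduction)
    passed_single = _passes_both_sirnas(single_diffs, p_thresh, log2fc_cut)
    passed_double = _passes_both_sirnas(double_diffs, p_thresh, log2fc_cut)
    universe = passed_single.index.union(passed_double.index)
    trace = pd.DataFrame(
        {
            "passed_single": passed_single.reindex(universe, fill_value=False),
            "passed_double": passed_double.reindex(universe, fill_value=False),
            "in_partner_list": [acc in partners for acc in universe],
        },
        index=universe,
    )
    trace.index.name = "accession"
    hits = trace["passed_single"] & trace["passed_double"] & trace["in_partner_list"]
    return TriageResult(candidates=set(trace.index[hits]), trace=trace)


def volcano_table(diff_by_sirna: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format projection: one row per protein per siRNA with the mean
    log2 difference and the FDR-adjusted q (volcano-plot coordinates)."""
    rows = []
    for sirna, table in diff_by_sirna.items():
        part = table[["mean_log2fc", "q_value"]].copy()
        part.insert(0, "sirna", sirna)
        rows.append(part.reset_index())
    return pd.concat(rows, ignore_index=True)


__all__ = [
    "TriageResult", "affected_sets", "call_affected", "diff_table",
    "estimate_pi0", "filter_detected", "impute_missing", "per_sirna_stats",
    "permutation_fdr", "triage_candidates", "volcano_table",
]
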