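"""Survival association of mutated gene modules.

A sample's *mutation score* for a module is the frequency-weighted count of
its mutated genes, p_j = sum_i f_i |v_ji|, with f_i the gene's total
gain+loss frequency and v_ji its -1/0/+1 state in sample j.  Samples are
dichotomized at the score cut-point minimizing the log-rank p-value over an
admissible quantile window (a min-p scan).  Because the min-p selection is
optimistically biased, module-level significance is calibrated by comparing
the module's minimal p against that of random same-size gene sets:

    perm_p = (1 + #{permuted p < real p}) / (n_perm + 1)

The same dichotomize-and-test flow applies to expression risk scores
RS_j = sum_i coeff_i E_ij built from Cox proportional-hazards coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)


@dataclass
class CutpointResult:
    """Outcome of a min-p cut-point scan."""

    cutpoint: float
    p_value: float
    statistic: float
    n_high: int
    n_low: int


@dataclass
class PermutationSummary:
    """Observed min-p log-rank p and its random-gene-set null distribution."""

    n_perm: int
    real_p: float
    permuted_ps: np.ndarray
    perm_p: float
    cutpoint: float = np.nan
    scores: pd.Series | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# scores


def sample_score(matrix: pd.DataFrame, freqs: pd.DataFrame, genes) -> pd.Series:
    """Sample-specific mutation score p_j = sum_{i in genes} f_i |v_ji|.

    ``matrix`` is the samples x genes -1/0/+1 matrix; ``freqs`` carries the
    per-gene ``heat`` column (f_gain + f_loss).
    """
    genes = sorted(set(genes), key=str)
    missing = [g for g in genes if g not in matrix.columns]
    if missing:
        raise KeyError(f"genes absent from the mutation matrix: {missing}")
    v = matrix[genes].to_numpy()
    f = freqs.loc[genes, "heat"].to_numpy(dtype=float)
    return pd.Series(np.abs(v) @ f, index=matrix.index, name="mutation_score")


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_curve(time, event) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns (times, S) where ``times`` starts at 0 with S(0) = 1 and each
    subsequent entry is a distinct event time with the survival probability
    just after it; S is non-increasing.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no survival records")
    if (time < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    ts, s = [0.0], [1.0]
    surv = 1.0
    n = len(t)
    starts = np.flatnonzero(np.r_[True, np.diff(t) > 0])
    for k, start in enumerate(starts):
        stop = starts[k + 1] if k + 1 < len(starts) else n
        d = int(e[start:stop].sum())
        if d == 0:
            continue
        at_risk = n - start
        surv *= 1.0 - d / at_risk
        ts.append(float(t[start]))
        s.append(surv)
    return np.array(ts), np.array(s)


def _logrank_grid(time, event, member: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank chi-square statistics and p-values, vectorized over columns.

    ``member`` is an (n,) or (n, C) boolean array; column c defines group 1
    of the c-th two-group comparison.  Returns (stat, p) arrays of length C.
    Columns with zero variance (no events, or a degenerate group) get
    statistic 0 and p 1 by convention.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    Z = np.asarray(member, dtype=float)
    squeeze = Z.ndim == 1
    if squeeze:
        Z = Z[:, None]
    n = len(time)
    order = np.argsort(time, kind="stable")
    t, e, Zs = time[order], event[order], Z[order]

    starts = np.flatnonzero(np.r_[True, np.diff(t) > 0])
    d = np.add.reduceat(e, starts)                       # events per distinct time
    d1 = np.add.reduceat(e[:, None] * Zs, starts, axis=0)
    suffix = np.cumsum(Zs[::-1], axis=0)[::-1]
    n1 = suffix[starts]                                  # group-1 at risk
    n_at = (n - starts).astype(float)

    ev = d > 0
    d, d1, n1, n_at = d[ev], d1[ev], n1[ev], n_at[ev]
    if d.size == 0:
        stat = np.zeros(Z.shape[1])
        p = np.ones(Z.shape[1])
        return (stat[0], p[0]) if squeeze else (stat, p)

    frac = n1 / n_at[:, None]
    U = (d1 - d[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_t = (
            d[:, None]
            * frac
            * (1.0 - frac)
            * ((n_at[:, None] - d[:, None]) / np.maximum(n_at[:, None] - 1.0, 1.0))
        )
    V = var_t.sum(axis=0)
    stat = np.where(V > 0, U * U / np.where(V > 0, V, 1.0), 0.0)
    p = np.where(V > 0, chi2.sf(stat, df=1), 1.0)
    if squeeze:
        return float(stat[0]), float(p[0])
    return stat, p


def logrank_test(time, event, groups) -> tuple[float, float]:
    """Two-group log-rank test.

    ``groups`` is a boolean/0-1 label per sample.  Returns the chi-square
    statistic U^2/V (1 df) and its p-value; with no events the statistic is
    0 and p is 1 by convention.
    """
    groups = np.asarray(groups, dtype=bool)
    if groups.all() or (~groups).all():
        raise ValueError("both groups must be non-empty")
    return _logrank_grid(time, event, groups)


# ---------------------------------------------------------------------------
# min-p dichotomization


def minp_cutpoint(
    scores, time, event, lower_q: float = 0.10, upper_q: float = 0.90
) -> CutpointResult:
    """Cut-point minimizing the log-rank p over an admissible quantile window.

    Every distinct score value c whose rank fraction #{score <= c}/n lies
    in [lower_q, upper_q] is evaluated as the split high = {score > c};
    ties in p resolve to the smaller c.  The returned p-value is the
    uncorrected minimum (optimistically biased; see :func:`permutation_p`).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    cands = np.unique(scores)
    frac = np.searchsorted(np.sort(scores), cands, side="right") / n
    ok = (frac >= lower_q) & (frac <= upper_q) & (frac < 1.0)
    cands = cands[ok]
    if cands.size == 0:
        raise ValueError("no admissible cutpoint (scores too concentrated)")
    member = scores[:, None] > cands[None, :]
    stat, p = _logrank_grid(time, event, member)
    best = np.lexsort((cands, p))[0]
    c = float(cands[best])
    return CutpointResult(
        cutpoint=c,
        p_value=float(p[best]),
        statistic=float(stat[best]),
        n_high=int((scores > c).sum()),
        n_low=int((scores <= c).sum()),
    )


# ---------------------------------------------------------------------------
# permutation calibration


def permutation_p(
    module_genes,
    matrix: pd.DataFrame,
    freqs: pd.DataFrame,
    time,
    event,
    n_perm: int = 1000,
    seed: int = 0,
    lower_q: float = 0.10,
    upper_q: float = 0.90,
    mode: str = "gene_sets",
) -> PermutationSummary:
    """Module-level survival significance against random same-size gene sets.

    ``real_p`` is the module's min-p log-rank p; each permutation redoes
    scoring, cut-point selection and the log-rank test for a uniformly
    random gene set of the same size (``mode="gene_sets"``, equivalent to
    permuting gene-row labels) or for the module's own rows with values
    shuffled independently across samples (``mode="shuffle_values"``).
    Permutations with no admissible cut-point count as p = 1.  The
    calibrated p is (1 + #{permuted p < real p}) / (n_perm + 1), strictly
    as written, hence always within [1/(n_perm+1), 1].
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if mode not in ("gene_sets", "shuffle_values"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    module_genes = sorted(set(module_genes), key=str)
    universe = list(matrix.columns)
    if len(module_genes) > len(universe):
        raise ValueError("module larger than the gene universe")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)

    scores = sample_score(matrix, freqs, module_genes)
    real = minp_cutpoint(scores, time, event, lower_q, upper_q)

    rng = np.random.default_rng(seed)
    k = len(module_genes)
    permuted = np.empty(n_perm)
    for b in range(n_perm):
        if mode == "gene_sets":
            genes_b = list(rng.choice(universe, size=k, replace=False))
            scores_b = sample_score(matrix, freqs, genes_b)
        else:
            v = matrix[module_genes].to_numpy().copy()
            for col in range(k):
                rng.shuffle(v[:, col])
            f = freqs.loc[module_genes, "heat"].to_numpy(dtype=float)
            scores_b = np.abs(v) @ f
        try:
            permuted[b] = minp_cutpoint(scores_b, time, event, lower_q, upper_q).p_value
        except ValueError:
            permuted[b] = 1.0
    perm_p = (1 + int((permuted < real.p_value).sum())) / (n_perm + 1)
    return PermutationSummary(
        n_perm=n_perm,
        real_p=real.p_value,
        permuted_ps=permuted,
        perm_p=perm_p,
        cutpoint=real.cutpoint,
        scores=scores,
    )


# ---------------------------------------------------------------------------
# expression risk score


def cox_coefficients(
    expr: pd.DataFrame,
    time,
    event,
    joint: bool = True,
    tol: float = 1e-8,
    max_steps: int = 100,
) -> pd.Series:
    """Cox proportional-hazards coefficients for a genes x samples matrix.

    Fits the partial likelihood with Breslow tie handling via lifelines.
    ``joint=True`` (default) fits one model over all genes; otherwise each
    gene is fitted univariately.  Constant expression rows get coefficient
    0 with a warning.
    """
    from lifelines import CoxPHFitter

    df = expr.T.copy()
    df.columns = [str(c) for c in df.columns]
    genes = list(df.columns)
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)

    constant = [g for g in genes if df[g].nunique() <= 1]
    if constant:
        warnings.warn(f"constant expression for {constant}; coefficients set to 0")
    fit_genes = [g for g in genes if g not in constant]

    coefs = pd.Series(0.0, index=genes, name="coef")
    kwargs = dict(
        duration_col="_time",
        event_col="_event",
        show_progress=False,
        fit_options={"precision": tol, "max_steps": max_steps},
    )
    if joint and fit_genes:
        cph = CoxPHFitter(penalizer=0.0)
        cph.fit(df[fit_genes + ["_time", "_event"]], **kwargs)
        coefs[fit_genes] = cph.params_.reindex(fit_genes).to_numpy()
    else:
        for g in fit_genes:
            cph = CoxPHFitter(penalizer=0.0)
            cph.fit(df[[g, "_time", "_event"]], **kwargs)
            coefs[g] = float(cph.params_.iloc[0])
    coefs.index = expr.index
    return coefs


def expression_risk_score(expr: pd.DataFrame, coefficients: pd.Series) -> pd.Series:
    """RS_j = sum_i coeff_i * E_ij over the coefficient genes."""
    missing = [g for g in coefficients.index if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from the expression matrix: {missing}")
    sub = expr.loc[coefficients.index]
    return pd.Series(
        coefficients.to_numpy(dtype=float) @ sub.to_numpy(dtype=float),
        index=expr.columns,
        name="risk_score",
    )


def survival_association(scores, time, event, lower_q: float = 0.10, upper_q: float = 0.90) -> dict:
    """Dichotomize scores at the min-p cut and summarize both arms.

    Convenience wrapper returning the cut-point, uncorrected log-rank p,
    group labels (high = score strictly above the cut) and the two
    Kaplan-Meier curves.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cut = minp_cutpoint(scores, time, event, lower_q, upper_q)
    high = scores > cut.cutpoint
    return {
        "cutpoint": cut.cutpoint,
        "logrank_p": cut.p_value,
        "statistic": cut.statistic,
        "high": high,
        "km_high": km_curve(time[high], event[high]),
        "km_low": km_curve(time[~high], event[~high]),
    }


def read_survival(path) -> pd.DataFrame:
    """Read a TSV with columns sample, time, event (indexed by sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = ["sample", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"survival file {path} lacks columns: {missing}")
    return df.set_index("sample")
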