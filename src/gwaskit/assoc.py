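"""Per-variant association testing, conditioning, combination, inflation.

Case-control association is a Wald test from a logistic model of status on
expected dosage plus covariates (and optional conditioning dosages); the
trio test standardizes observed-minus-expected child dosage by the
Mendelian transmission variance and reduces exactly to the classical TDT on
hard genotypes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .gwasio import DosageMatrix
from .simcohort import CaseControlCohort, TrioCohort

__all__ = [
    "logistic_assoc",
    "trio_assoc",
    "armitage_trend",
    "combine_z",
    "fixed_effect_meta",
    "genomic_inflation",
    "batch_logistic_wald",
]

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...

_MAX_ABS_BETA = 15.0  # |log OR| beyond this is treated as separation
_MAX_ITER = 40
_TOL = 1e-8


def batch_logistic_wald(
    y: np.ndarray,
    shared: np.ndarray,
    x: np.ndarray,
    chunk: int = 512,
):
    """Wald statistics for the last column of many logistic regressions.

    Fits, for every column ``x[:, j]``, the model
    ``logit P(y=1) = shared @ a_j + b_j x_j`` by Newton-Raphson, where
    ``shared`` (n x k, including the intercept) is common to all fits.

    Returns (beta, se, flag) arrays of length m. ``flag`` is "" for clean
    fits, "collinear" when x_j lies in the span of the shared columns
    (beta 0, se inf), "separation" for diverging estimates (beta +-inf,
    se nan), "nonconverged" otherwise.
    """
    y = np.asarray(y, dtype=float)
    shared = np.asarray(shared, dtype=float)
    x = np.asarray(x, dtype=float)
    n, k = shared.shape
    m = x.shape[1]
    beta = np.zeros(m)
    se = np.full(m, np.nan)
    flag = np.array([""] * m, dtype=object)

    # collinearity of x with the shared columns, via least-squares residual
    coef, *_ = np.linalg.lstsq(shared, x, rcond=None)
    resid = x - shared @ coef
    xnorm = (x**2).sum(axis=0)
    collinear = (resid**2).sum(axis=0) <= 1e-10 * np.maximum(xnorm, 1.0)
    beta[collinear] = 0.0
    se[collinear] = np.inf
    flag[collinear] = "collinear"

    todo = np.flatnonzero(~collinear)
    for start in range(0, todo.size, chunk):
        idx = todo[start : start + chunk]
        xb = x[:, idx]
        mb = idx.size
        params = np.zeros((mb, k + 1))
        params[:, 0] = np.log(y.mean() / (1 - y.mean())) if 0 < y.mean() < 1 else 0.0
        converged = np.zeros(mb, dtype=bool)
        diverged = np.zeros(mb, dtype=bool)
        hess = None
        for _ in range(_MAX_ITER):
            eta = shared @ params[:, :k].T + xb * params[:, k]
            eta = np.clip(eta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            r = y[:, None] - mu
            grad = np.empty((mb, k + 1))
            grad[:, :k] = (shared.T @ r).T
            grad[:, k] = (xb * r).sum(axis=0)
            hess = np.empty((mb, k + 1, k + 1))
            hess[:, :k, :k] = np.einsum("ni,nm,nj->mij", shared, w, shared)
            cross = np.einsum("ni,nm->mi", shared, w * xb)
            hess[:, :k, k] = cross
            hess[:, k, :k] = cross
            hess[:, k, k] = (w * xb**2).sum(axis=0)
            hess[:, np.arange(k + 1), np.arange(k + 1)] += 1e-10
            try:
                step = np.linalg.solve(hess, grad[..., None])[..., 0]
            except np.linalg.LinAlgError:
                hess[:, np.arange(k + 1), np.arange(k + 1)] += 1e-6
                step = np.linalg.solve(hess, grad[..., None])[..., 0]
            active = ~(converged | diverged)
            params[active] += step[active]
            diverged |= np.abs(params[:, k]) > _MAX_ABS_BETA
            converged |= np.max(np.abs(step), axis=1) < _TOL
            if np.all(converged | diverged):
                break
        cov = np.linalg.inv(hess)
        beta_b = params[:, k]
        se_b = np.sqrt(np.maximum(cov[:, k, k], 0))
        beta_b[diverged] = np.sign(beta_b[diverged]) * np.inf
        se_b[diverged] = np.nan
        beta[idx] = beta_b
        se[idx] = se_b
        flag_b = np.array([""] * mb, dtype=object)
        flag_b[diverged] = "separation"
        flag_b[~(converged | diverged)] = "nonconverged"
        flag[idx] = flag_b
    return beta, se, flag


def _assoc_frame(variants, beta, se, flag, n_cases=None, n_controls=None):
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(np.isfinite(se) & (se > 0), beta / se, np.nan)
        z = np.where(np.isinf(se), 0.0, z)  # collinear: no residual effect
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(z), np.nan, np.minimum(p, 1.0))
    df = pd.DataFrame(
        {
            "snp": [v.id for v in variants],
            "chr": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "effect_allele": [v.alt for v in variants],
            "other_allele": [v.ref for v in variants],
            "freq": [v.af for v in variants],
            "info": [v.info for v in variants],
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "flag": flag,
        }
    )
    if n_cases is not None:
        df.attrs["n_cases"] = int(n_cases)
    if n_controls is not None:
        df.attrs["n_controls"] = int(n_controls)
    return df


def logistic_assoc(
    cohort: CaseControlCohort,
    covariates: np.ndarray | None = None,
    condition_on: list | None = None,
) -> pd.DataFrame:
    """Per-variant logistic dosage association with Wald P-values.

    ``covariates`` defaults to the cohort's ancestry axes; ``condition_on``
    names variants (ids or indices) whose dosages enter every model as
    additional covariates. Effects are reported for the alternate allele.
    A variant collinear with the conditioning set is flagged "collinear"
    with beta 0 and P 1; separated fits carry an infinite-beta sentinel and
    a missing P.
    """
    matrix = cohort.dosages
    y = cohort.status.astype(float)
    if covariates is None:
        covariates = cohort.covariates
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    cols = [np.ones((matrix.n_samples, 1))]
    if covariates.size:
        cols.append(covariates)
    if condition_on:
        idx = _resolve_variants(matrix, condition_on)
        cols.append(matrix.dosages[:, idx])
    shared = np.hstack(cols)
    beta, se, flag = batch_logistic_wald(y, shared, matrix.dosages)
    return _assoc_frame(
        matrix.variants, beta, se, flag,
        n_cases=int(y.sum()), n_controls=int((1 - y).sum()),
    )


def _resolve_variants(matrix: DosageMatrix, names) -> np.ndarray:
    by_id = {v.id: j for j, v in enumerate(matrix.variants)}
    idx = []
    for name in names:
        if isinstance(name, (int, np.integer)):
            idx.append(int(name))
        elif name in by_id:
            idx.append(by_id[name])
        else:
            raise KeyError(f"variant {name!r} not in matrix")
    return np.array(idx, dtype=int)


def trio_assoc(trios: TrioCohort) -> pd.DataFrame:
    """Dosage-based family transmission test.

    Per trio and variant the contribution is the child dosage minus its
    Mendelian expectation (father + mother)/2; each parental dosage d acts
    as an allele-transmission probability d/2 with variance (d/2)(1-d/2).
    Z = sum(U) / sqrt(sum(Var)). On hard genotypes this equals the classical
    TDT statistic (b-c)/sqrt(b+c). Variants with zero transmission variance
    (no informative trios) get a missing P with reason.
    """
    c = trios.child.astype(float)
    f = trios.father.astype(float)
    m = trios.mother.astype(float)
    u = (c - (f + m) / 2.0).sum(axis=0)
    var = ((f / 2) * (1 - f / 2) + (m / 2) * (1 - m / 2)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, u / np.sqrt(var), np.nan)
    p = np.where(np.isnan(z), np.nan, 2.0 * stats.norm.sf(np.abs(z)))
    flag = np.where(var > 0, "", "no_informative_trios").astype(object)
    se = np.where(var > 0, np.sqrt(var), np.nan)  # se of the score sum
    variants = trios.variants or _anonymous_variants(trios.n_variants)
    df = _assoc_frame(variants, np.where(var > 0, u, np.nan), se, flag)
    df["z"] = z
    df["p"] = p
    # report beta on a per-dosage scale comparable to log RR: score/variance
    with np.errstate(invalid="ignore", divide="ignore"):
        df["beta"] = np.where(var > 0, u / var, np.nan)
        df["se"] = np.where(var > 0, 1.0 / np.sqrt(var), np.nan)
    df.attrs["n_trios"] = trios.n_trios
    return df


def _anonymous_variants(m: int):
    from .gwasio import VariantRecord

    return [
        VariantRecord(id=f"var{j}", chrom="1", pos=j + 1, ref="A", alt="G")
        for j in range(m)
    ]


def armitage_trend(counts) -> tuple[float, float]:
    """Cochran-Armitage trend chi-square (1 df) on a 2x3 genotype table.

    ``counts`` rows are (cases, controls), columns genotype dosages (0,1,2).
    Returns (chi2, two-sided P); P is nan for a degenerate margin.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 3):
        raise ValueError("expected a 2x3 table (cases/controls x genotypes 0,1,2)")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    scores = np.array([0.0, 1.0, 2.0])
    n = counts.sum()
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    if n == 0 or row[0] == 0 or row[1] == 0 or np.count_nonzero(col) < 2:
        return float("nan"), float("nan")
    num = (scores * (counts[0] - row[0] * col / n)).sum()
    p_bar = row[0] / n
    var = p_bar * (1 - p_bar) * ((scores**2 * col).sum() - (scores * col).sum() ** 2 / n)
    if var <= 0:
        return float("nan"), float("nan")
    chi2 = num**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def signed_z_from_p(p: float, direction: float) -> float:
    """Signed Z from a two-sided P and an effect direction (+-1)."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"P must be in (0, 1], got {p}")
    return float(np.sign(direction) * stats.norm.isf(p / 2.0))


def combine_z(studies: list[tuple[float, float, float]]) -> tuple[float, float]:
    """Weighted Z-score combination of independent studies.

    Each study is (two-sided P, effect direction, weight > 0); the combined
    statistic is sum(w_i Z_i) / sqrt(sum(w_i^2)). A single study returns its
    input P exactly.
    """
    if not studies:
        raise ValueError("need at least one study")
    for p, _, w in studies:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"P must be in (0, 1], got {p}")
        if w <= 0:
            raise ValueError("weights must be positive")
    if len(studies) == 1:
        p, d, _ = studies[0]
        return signed_z_from_p(p, d), p
    zs = np.array([signed_z_from_p(p, d) for p, d, _ in studies])
    ws = np.array([w for _, _, w in studies], dtype=float)
    z = float(ws @ zs / np.sqrt((ws**2).sum()))
    return z, float(2.0 * stats.norm.sf(abs(z)))


def fixed_effect_meta(betas, ses) -> dict:
    """Inverse-variance fixed-effect pooling with Cochran's Q."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1 or betas.size == 0:
        raise ValueError("betas and ses must be equal-length non-empty vectors")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float((w * betas).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    q = float((w * (betas - beta) ** 2).sum())
    return {
        "beta": beta,
        "se": se,
        "z": z,
        "p": float(2.0 * stats.norm.sf(abs(z))),
        "q": q,
        "q_df": betas.size - 1,
    }


def genomic_inflation(stats_table: pd.DataFrame) -> float:
    """Genomic inflation factor: median 1-df chi-square over its null median."""
    p = stats_table["p"].to_numpy(dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        warnings.warn("fewer than 100 variants; lambda estimate is unstable")
    if p.size == 0:
        return float("nan")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)
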