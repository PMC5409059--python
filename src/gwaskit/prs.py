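"""Polygenic-score construction and evaluation.

Builds weighted allele scores from discovery summary statistics (P-value
thresholding, optional greedy LD pruning), scores target individuals,
evaluates score-disease association with unmatched logistic or matched
conditional-logistic (pseudo-control) models, computes the
transmitted/non-transmitted trio score for a fixed locus panel, and
estimates the variance attributable to a locus panel with an optional
liability-scale conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gwasio import DosageMatrix
from .simcohort import CaseControlCohort, TrioCohort

__all__ = [
    "ScoreModel",
    "TrioScoreResult",
    "DEFAULT_PT_GRID",
    "build_score",
    "score_individuals",
    "pseudo_controls",
    "prs_association",
    "trio_transmission_score",
    "variance_explained_loci",
    "liability_scale_r2",
]

DEFAULT_PT_GRID = (5e-8, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.5, 1.0)


@dataclass
class ScoreModel:
    """Variant weights for an additive allele score.

    ``variants`` has columns snp/chr/pos/effect_allele/other_allele/weight/p;
    weights are discovery log relative risks for the effect allele.
    """

    variants: pd.DataFrame
    p_threshold: float
    pruned: bool = False
    r2_max: float = 0.25

    def __post_init__(self):
        if self.variants["snp"].duplicated().any():
            raise ValueError("duplicate variants in score model")
        if not np.all(np.isfinite(self.variants["weight"].to_numpy(float))):
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class TrioScoreResult:
    """Transmitted vs non-transmitted weighted score per trio."""

    transmitted: np.ndarray
    nontransmitted: np.ndarray
    difference: np.ndarray = field(init=False)
    mean_difference: float = field(init=False)
    sd_difference: float = field(init=False)
    t_statistic: float = field(init=False)
    p_value: float = field(init=False)
    n_trios: int = field(init=False)

    def __post_init__(self):
        self.difference = self.transmitted - self.nontransmitted
        self.n_trios = len(self.difference)
        self.mean_difference = float(self.difference.mean())
        self.sd_difference = (
            float(self.difference.std(ddof=1)) if self.n_trios > 1 else float("nan")
        )
        if self.n_trios > 1 and self.sd_difference > 0:
            t, p = stats.ttest_1samp(self.difference, 0.0)
            self.t_statistic, self.p_value = float(t), float(p)
        else:
            self.t_statistic = self.p_value = float("nan")


# ---------------------------------------------------------------------------
# model construction


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    d = dosages - dosages.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = np.nan
    corr = (d.T @ d) / len(d) / np.outer(sd, sd)
    return corr**2


def build_score(
    discovery: pd.DataFrame,
    p_threshold: float,
    prune: bool = False,
    r2_max: float = 0.25,
    ld_panel: DosageMatrix | None = None,
    maf_min: float = 0.01,
    target_info_min: float = 0.8,
    target_info: dict[str, np.ndarray] | None = None,
) -> ScoreModel:
    """Select and weight score variants from discovery summary statistics.

    Keeps variants with P <= ``p_threshold``, discovery MAF >= ``maf_min``
    and info score >= ``target_info_min`` in every target cohort (the
    discovery table's own info column, plus any arrays in ``target_info``).
    With ``prune``, variants are taken in ascending-P order and dropped when
    their LD-panel r^2 with an already kept variant reaches ``r2_max``.
    Weights are the discovery log relative risks for the effect allele.
    """
    df = discovery.copy()
    p = df["p"].to_numpy(float)
    keep = np.isfinite(p) & (p <= p_threshold)
    reasons = {"p_threshold": int((~keep).sum())}
    if "freq" in df.columns:
        freq = df["freq"].to_numpy(float)
        maf = np.minimum(freq, 1 - freq)
        maf_ok = maf >= maf_min
        reasons["maf"] = int((keep & ~maf_ok).sum())
        keep &= maf_ok
    info_arrays = []
    if "info" in df.columns:
        info_arrays.append(df["info"].to_numpy(float))
    for arr in (target_info or {}).values():
        info_arrays.append(np.asarray(arr, dtype=float))
    for arr in info_arrays:
        info_ok = arr >= target_info_min
        reasons["info"] = reasons.get("info", 0) + int((keep & ~info_ok).sum())
        keep &= info_ok
    df = df.loc[keep].copy()
    if len(df) == 0:
        binding = max(reasons, key=reasons.get)
        raise ValueError(f"no variants pass the score filters (binding filter: {binding})")

    if prune:
        if ld_panel is None:
            raise ValueError("pruning requires an LD panel")
        by_id = {v.id: j for j, v in enumerate(ld_panel.variants)}
        missing = [s for s in df["snp"] if s not in by_id]
        if missing:
            raise ValueError(f"LD panel lacks score candidates: {missing[:5]}")
        order = df.sort_values(["p", "pos"], kind="mergesort").index
        cols = {s: ld_panel.dosages[:, by_id[s]] for s in df["snp"]}
        kept: list = []
        kept_mat: list[np.ndarray] = []
        for i in order:
            snp = df.at[i, "snp"]
            x = cols[snp]
            ok = True
            xs = x - x.mean()
            xsd = xs.std()
            for kcol in kept_mat:
                denom = xsd * kcol.std()
                r = (xs @ (kcol - 0.0)) / len(x) / denom if denom > 0 else 0.0
                if r**2 >= r2_max:
                    ok = False
                    break
            if ok:
                kept.append(i)
                kept_mat.append(xs)
        df = df.loc[sorted(kept)]

    model_df = pd.DataFrame(
        {
            "snp": df["snp"].to_numpy(),
            "chr": df["chr"].to_numpy() if "chr" in df else "1",
            "pos": df["pos"].to_numpy() if "pos" in df else np.arange(len(df)),
            "effect_allele": df["effect_allele"].to_numpy(),
            "other_allele": df["other_allele"].to_numpy()
            if "other_allele" in df
            else "N",
            "weight": df["beta"].to_numpy(float),
            "p": df["p"].to_numpy(float),
            "freq": df["freq"].to_numpy(float) if "freq" in df else np.nan,
        }
    ).reset_index(drop=True)
    return ScoreModel(model_df, p_threshold, pruned=prune, r2_max=r2_max)


_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def score_individuals(model: ScoreModel, target: DosageMatrix):
    """Weighted allele score per individual.

    Dosages are oriented to each model variant's effect allele; variants
    absent from the target are imputed at twice the model frequency (a
    per-sample constant) and reported. Strand-ambiguous variants (A/T, C/G)
    with frequency near 0.5 are flagged.

    Returns (scores, report) where the report lists imputed and ambiguous
    variants.
    """
    by_id = {v.id: j for j, v in enumerate(target.variants)}
    scores = np.zeros(target.n_samples)
    notes = []
    for _, row in model.variants.iterrows():
        w = row["weight"]
        snp = row["snp"]
        if snp not in by_id:
            fallback = 2.0 * row["freq"] if np.isfinite(row.get("freq", np.nan)) else 1.0
            scores += w * fallback
            notes.append({"snp": snp, "note": "imputed_from_frequency"})
            continue
        j = by_id[snp]
        rec = target.variants[j]
        pair = (str(row["effect_allele"]).upper(), str(row["other_allele"]).upper())
        if pair in _AMBIGUOUS and np.isfinite(rec.af) and 0.4 <= rec.af <= 0.6:
            notes.append({"snp": snp, "note": "strand_ambiguous"})
        d = target.dosages[:, j]
        if row["effect_allele"] == rec.alt:
            scores += w * d
        elif row["effect_allele"] == rec.ref:
            scores += w * (2.0 - d)
        else:
            raise ValueError(
                f"effect allele {row['effect_allele']} of {snp} matches neither "
                f"target allele ({rec.ref}/{rec.alt})"
            )
    report = pd.DataFrame(notes, columns=["snp", "note"])
    return scores, report


# ---------------------------------------------------------------------------
# pseudo-controls

# _PSEUDO_TABLE[f, m, c] -> 3 pseudo-control genotypes, or -1s if the trio is
# Mendelian-inconsistent at the variant
_PSEUDO_TABLE = np.full((3, 3, 3, 3), -1, dtype=np.int8)
_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
for _f in range(3):
    for _m in range(3):
        combos = sorted(af + am for af in _ALLELES[_f] for am in _ALLELES[_m])
        for _c in range(3):
            if _c in combos:
                rest = list(combos)
                rest.remove(_c)
                _PSEUDO_TABLE[_f, _m, _c] = rest


def pseudo_controls(trios: TrioCohort, variant_index: np.ndarray | None = None):
    """Matched case/pseudo-control genotypes from trio hard calls.

    Per trio the affected child is the case; the three pseudo-controls are
    the three untransmitted combinations of parental alleles, built
    variant-by-variant. Returns (case, pseudo, valid) with shapes
    (n, m), (n, 3, m) and (n, m); ``valid`` is False where the trio is
    Mendelian-inconsistent at the variant (genotypes masked to 0 there).
    """
    f = np.asarray(trios.father, dtype=np.int8)
    m = np.asarray(trios.mother, dtype=np.int8)
    c = np.asarray(trios.child, dtype=np.int8)
    if variant_index is not None:
        variant_index = np.asarray(variant_index)
        f, m, c = f[:, variant_index], m[:, variant_index], c[:, variant_index]
    pseudo = _PSEUDO_TABLE[f, m, c]  # (n, m, 3)
    valid = pseudo[:, :, 0] >= 0
    pseudo = np.where(valid[:, :, None], pseudo, 0).transpose(0, 2, 1)
    case = np.where(valid, c, 0)
    return case, pseudo, valid


# ---------------------------------------------------------------------------
# likelihood machinery


def fit_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Newton-Raphson logistic fit; returns (params, cov, loglik, converged)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    params = np.zeros(k)
    converged = False
    cov = np.full((k, k), np.nan)
    for _ in range(max_iter):
        eta = np.clip(X @ params, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        hess[np.diag_indices(k)] += 1e-10
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        params += step
        if np.max(np.abs(step)) < tol:
            converged = True
            cov = np.linalg.inv(hess)
            break
    eta = np.clip(X @ params, -30, 30)
    loglik = float(np.sum(y * eta - np.log1p(np.exp(eta))))
    return params, cov, loglik, converged


def _null_loglik(y: np.ndarray) -> float:
    n1 = y.sum()
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return 0.0
    p = n1 / len(y)
    return float(n1 * np.log(p) + n0 * np.log(1 - p))


def nagelkerke_r2(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke pseudo-R^2 from null and full log-likelihoods."""
    cs = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    max_cs = 1.0 - np.exp((2.0 / n) * ll_null)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cs / max_cs, 0.0, 1.0))


def _conditional_logit_1d(score_case: np.ndarray, score_others: np.ndarray,
                          max_iter: int = 100, tol: float = 1e-12):
    """One-parameter conditional logistic likelihood for 1-case strata.

    ``score_case`` (S,) and ``score_others`` (S, m) hold the case and the
    non-case scores per stratum. Returns (beta, se, ll_full, ll_null,
    converged).
    """
    all_scores = np.column_stack([score_case, score_others])  # case first
    m = all_scores.shape[1]
    ll_null = float(-len(score_case) * np.log(m))
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        eta = beta * all_scores
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        denom = w.sum(axis=1)
        probs = w / denom[:, None]
        mean_s = (probs * all_scores).sum(axis=1)
        var_s = (probs * (all_scores - mean_s[:, None]) ** 2).sum(axis=1)
        grad = float((score_case - mean_s).sum())
        info = float(var_s.sum())
        if info <= 0:
            break
        step = grad / info
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 50:
            break
    eta = beta * all_scores
    shift = eta.max(axis=1, keepdims=True)
    log_denom = np.log(np.exp(eta - shift).sum(axis=1)) + shift[:, 0]
    ll_full = float((beta * score_case - log_denom).sum())
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("nan")
    return beta, se, ll_full, ll_null, converged


def prs_association(
    scores: np.ndarray,
    status: np.ndarray | None = None,
    matching: np.ndarray | None = None,
    pseudo_scores: np.ndarray | None = None,
) -> dict:
    """Association of a polygenic score with disease status.

    Unmatched: logistic regression of ``status`` on the score (Wald test,
    Nagelkerke pseudo-R^2 against the intercept-only model). Matched: pass
    per-stratum case scores in ``scores`` and the matched pseudo-control
    scores (n_strata x n_controls) in ``pseudo_scores``; the conditional
    likelihood within strata is used and the null is the equal-probability
    conditional likelihood.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if pseudo_scores is not None or matching is not None:
        if pseudo_scores is None:
            raise ValueError("matched analysis requires pseudo-control scores")
        pseudo_scores = np.asarray(pseudo_scores, dtype=float)
        if scores.std() == 0 and pseudo_scores.std() == 0:
            return {"beta": 0.0, "se": float("nan"), "p": float("nan"),
                    "r2_nagelkerke": 0.0, "converged": True, "matched": True}
        beta, se, ll1, ll0, conv = _conditional_logit_1d(scores, pseudo_scores)
        n = scores.size + pseudo_scores.size
        z = beta / se if se and np.isfinite(se) and se > 0 else float("nan")
        return {
            "beta": float(beta),
            "se": se,
            "z": z,
            "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
            "r2_nagelkerke": nagelkerke_r2(ll0, ll1, n),
            "converged": conv,
            "matched": True,
        }
    status = np.asarray(status, dtype=float)
    if scores.std() == 0:
        return {"beta": 0.0, "se": float("nan"), "p": float("nan"),
                "r2_nagelkerke": 0.0, "converged": True, "matched": False}
    X = np.column_stack([np.ones_like(scores), scores])
    params, cov, ll1, conv = fit_logistic(X, status)
    ll0 = _null_loglik(status)
    se = float(np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) else float("nan")
    z = params[1] / se if se > 0 else float("nan")
    return {
        "beta": float(params[1]),
        "se": se,
        "z": z,
        "p": float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else float("nan"),
        "r2_nagelkerke": nagelkerke_r2(ll0, ll1, len(status)),
        "converged": conv,
        "matched": False,
    }


# ---------------------------------------------------------------------------
# trio transmission score


def trio_transmission_score(trios: TrioCohort, panel: pd.DataFrame) -> TrioScoreResult:
    """Transmitted vs non-transmitted weighted allele score per trio.

    ``panel`` has columns snp/risk_allele/log_rr; snp ids must match the
    trio cohort's variants. Transmitted dosage is the child genotype and
    non-transmitted dosage is father + mother - child, both oriented to the
    risk allele and weighted by log_rr. Mendelian-inconsistent trio/variant
    pairs are masked (contribute 0 to both scores).
    """
    if not trios.variants:
        raise ValueError("trio cohort lacks variant metadata")
    by_id = {v.id: j for j, v in enumerate(trios.variants)}
    idx, flips, weights = [], [], []
    for _, row in panel.iterrows():
        snp = row["snp"]
        if snp not in by_id:
            raise KeyError(f"panel variant {snp} not in trio cohort")
        j = by_id[snp]
        rec = trios.variants[j]
        if row["risk_allele"] == rec.alt:
            flips.append(False)
        elif row["risk_allele"] == rec.ref:
            flips.append(True)
        else:
            raise ValueError(f"risk allele of {snp} matches neither trio allele")
        idx.append(j)
        weights.append(float(row["log_rr"]))
    idx = np.asarray(idx)
    flips = np.asarray(flips)
    weights = np.asarray(weights)

    c = trios.child[:, idx].astype(float)
    nt = trios.nontransmitted()[:, idx].astype(float)
    f = trios.father[:, idx]
    m = trios.mother[:, idx]
    valid = _PSEUDO_TABLE[f, m, trios.child[:, idx]][:, :, 0] >= 0
    t_or = np.where(flips, 2.0 - c, c)
    nt_or = np.where(flips, 2.0 - nt, nt)
    t_or = np.where(valid, t_or, 0.0)
    nt_or = np.where(valid, nt_or, 0.0)
    transmitted = t_or @ weights
    nontransmitted = nt_or @ weights
    return TrioScoreResult(transmitted=transmitted, nontransmitted=nontransmitted)


# ---------------------------------------------------------------------------
# variance explained by a locus panel


def _ascertained_probit_h2(G: np.ndarray, y: np.ndarray, prevalence: float,
                           case_fraction: float) -> float:
    """Liability variance of a locus panel under case-control ascertainment.

    Fits the liability-threshold (probit) model by maximum likelihood with
    the sampling correction implied by the prevalence and the sample case
    fraction: P(case | g, sampled) = expit(logit(Phi(eta)) + log s), where
    log s is the case-oversampling log odds. The genetic liability variance
    is computed over controls (population-representative at low prevalence)
    and returned as a fraction of the total liability variance v/(1+v).
    """
    from scipy import optimize

    log_s = np.log(case_fraction / (1 - case_fraction)) - np.log(
        prevalence / (1 - prevalence)
    )
    Gc = G - G.mean(axis=0)
    m = G.shape[1]

    def negll(theta):
        eta = theta[0] + Gc @ theta[1:]
        logit_adj = stats.norm.logcdf(eta) - stats.norm.logcdf(-eta) + log_s
        ll = np.where(y == 1, -np.logaddexp(0, -logit_adj),
                      -np.logaddexp(0, logit_adj))
        return -ll.sum()

    theta0 = np.zeros(m + 1)
    theta0[0] = -stats.norm.isf(prevalence)
    fit = optimize.minimize(negll, theta0, method="L-BFGS-B")
    v = float((Gc[y == 0] @ fit.x[1:]).var())
    return v / (1.0 + v)


def liability_scale_r2(r2_observed: float, prevalence: float, case_fraction: float) -> float:
    """Observed-scale (0/1) R^2 converted to the liability scale for an
    ascertained case-control sample (normal-threshold transformation)."""
    if not 0 < prevalence < 1 or not 0 < case_fraction < 1:
        raise ValueError("prevalence and case fraction must be in (0, 1)")
    k = prevalence
    p = case_fraction
    t = stats.norm.isf(k)
    z = stats.norm.pdf(t)
    c = (k * (1 - k)) ** 2 / (z**2 * p * (1 - p))
    return float(r2_observed * c)


def variance_explained_loci(
    cohort: CaseControlCohort,
    panel_index: np.ndarray,
    prevalence: float = 0.001,
) -> dict:
    """Variance in disease risk attributable to a fixed locus panel.

    Fits the joint logistic model of status on all panel dosages (collinear
    members dropped and flagged) and reports Nagelkerke pseudo-R^2 and the
    observed-scale (0/1 linear) R^2 of the fitted genetic predictor.
    ``r2_liability`` comes from an ascertainment-corrected liability
    (probit) fit using the given prevalence and the cohort case fraction;
    the linear normal-threshold conversion of the observed-scale R^2 is
    also reported as ``r2_liability_linear`` (it understates badly under
    strong ascertainment).
    """
    panel_index = np.asarray(panel_index, dtype=int)
    y = cohort.status.astype(float)
    G = cohort.dosages.dosages[:, panel_index]
    # drop collinear columns (rank-revealing QR via lstsq residuals)
    keep: list[int] = []
    dropped: list[int] = []
    basis = np.ones((len(y), 1))
    for j in range(G.shape[1]):
        x = G[:, [j]]
        coef, *_ = np.linalg.lstsq(basis, x, rcond=None)
        resid = x - basis @ coef
        if (resid**2).sum() > 1e-8 * max((x**2).sum(), 1.0):
            keep.append(j)
            basis = np.hstack([basis, x])
        else:
            dropped.append(j)
    X = np.column_stack([np.ones(len(y)), G[:, keep]])
    params, cov, ll1, conv = fit_logistic(X, y)
    ll0 = _null_loglik(y)
    r2_nag = nagelkerke_r2(ll0, ll1, len(y))
    genetic = G[:, keep] @ params[1:]
    if genetic.std() > 0:
        r2_obs = float(np.corrcoef(genetic, y)[0, 1] ** 2)
    else:
        r2_obs = 0.0
    case_fraction = y.mean()
    return {
        "r2_nagelkerke": r2_nag,
        "r2_observed": r2_obs,
        "r2_liability": _ascertained_probit_h2(
            G[:, keep], cohort.status, prevalence, case_fraction
        ),
        "r2_liability_linear": liability_scale_r2(r2_obs, prevalence, case_fraction),
        "n_loci_fitted": len(keep),
        "collinear_dropped": [int(panel_index[j]) for j in dropped],
        "converged": conv,
    }
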