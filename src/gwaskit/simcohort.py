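"""Synthetic cohorts with known ground truth.

Generates haplotype panels with block LD, case-control cohorts and
ascertained affected-child trios under a multiplicative-risk disease model,
imputation-degraded dosages with a target info score, and annotation tracks
with controllable enrichment around associated variants. Everything is
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gwasio import AnnotationTrack, DosageMatrix, VariantRecord

__all__ = [
    "HaplotypePanel",
    "RiskModel",
    "EnrichmentSpec",
    "CaseControlCohort",
    "TrioCohort",
    "AscertainmentError",
    "simulate_panel",
    "simulate_case_control",
    "simulate_liability_case_control",
    "simulate_trios",
    "dosify",
    "simulate_annotation",
]

DEFAULT_DRAW_BUDGET = 10_000_000


class AscertainmentError(RuntimeError):
    """Raised when rejection sampling exhausts its draw budget."""


@dataclass
class HaplotypePanel:
    """Binary haplotypes on a single synthetic chromosome.

    ``haplotypes`` is (2N, M) with 1 = alternate allele. ``blocks`` is a list
    of (start, stop) variant-index ranges; variants in distinct blocks are
    independent, within a block adjacent variants share a latent AR(1)
    correlation.
    """

    positions: np.ndarray
    frequencies: np.ndarray
    haplotypes: np.ndarray
    blocks: list[tuple[int, int]]
    seed: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        realized = self.haplotypes.mean(axis=0)
        if np.any(realized <= 0) or np.any(realized >= 1):
            raise ValueError("monomorphic variant in panel")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def realized_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def variant_records(self, info: float = 1.0, chrom: str = "1") -> list[VariantRecord]:
        freqs = self.realized_frequencies()
        return [
            VariantRecord(
                id=f"var{j}", chrom=chrom, pos=int(self.positions[j]),
                ref="A", alt="G", af=float(freqs[j]), info=info,
            )
            for j in range(self.n_variants)
        ]


@dataclass
class RiskModel:
    """Multiplicative per-allele disease risk on the log-odds scale.

    One copy of the risk (alternate) allele at causal variant j multiplies
    the odds by exp(log_rr[j]); the intercept is solved from the target
    prevalence, at which odds ratios approximate relative risks.
    """

    causal_indices: np.ndarray
    log_rr: np.ndarray
    prevalence: float = 0.001

    def __post_init__(self):
        self.causal_indices = np.asarray(self.causal_indices, dtype=np.int64)
        self.log_rr = np.asarray(self.log_rr, dtype=float)
        if self.causal_indices.shape != self.log_rr.shape:
            raise ValueError("causal_indices and log_rr must align")
        if not 0.0 < self.prevalence < 0.5:
            raise ValueError(f"prevalence {self.prevalence} outside (0, 0.5)")
        if not np.all(np.isfinite(self.log_rr)):
            raise ValueError("log relative risks must be finite")

    @classmethod
    def null(cls, prevalence: float = 0.001) -> "RiskModel":
        return cls(np.array([], dtype=np.int64), np.array([]), prevalence)


@dataclass
class EnrichmentSpec:
    """Parameters for a synthetic annotation track.

    ``anchor_probability`` is the chance that an interval is centred on an
    associated/causal variant rather than placed uniformly.
    """

    n_intervals: int
    mean_length: float
    anchor_probability: float
    genome_length: int
    anchor_p_max: float = 1e-4

    def __post_init__(self):
        if not 0.0 <= self.anchor_probability <= 1.0:
            raise ValueError("anchor_probability must be in [0, 1]")
        if self.mean_length <= 0:
            raise ValueError("mean_length must be positive")
        if self.n_intervals < 0 or self.genome_length <= 0:
            raise ValueError("n_intervals and genome_length must be positive")


@dataclass
class CaseControlCohort:
    """Labelled dosage cohort with optional strata and ancestry covariates."""

    dosages: DosageMatrix
    status: np.ndarray
    strata: np.ndarray
    covariates: np.ndarray  # (n, k) ancestry axes; k = 0 when unstratified

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=int)
        self.strata = np.asarray(self.strata, dtype=int)
        n = self.dosages.n_samples
        if self.status.shape != (n,) or self.strata.shape != (n,):
            raise ValueError("status/strata must align with samples")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())


@dataclass
class TrioCohort:
    """Aligned child/father/mother genotype matrices for ascertained trios.

    Matrices are hard genotypes in {0,1,2}; ``transmitted`` holds, per trio
    and variant, the alleles the child received (father's in column block 0,
    mother's in block 1), so transmitted dosage equals the child genotype by
    construction.
    """

    child: np.ndarray
    father: np.ndarray
    mother: np.ndarray
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self):
        self.child = np.asarray(self.child, dtype=np.int8)
        self.father = np.asarray(self.father, dtype=np.int8)
        self.mother = np.asarray(self.mother, dtype=np.int8)
        if not self.child.shape == self.father.shape == self.mother.shape:
            raise ValueError("trio matrices must share a shape")

    @property
    def n_trios(self) -> int:
        return self.child.shape[0]

    @property
    def n_variants(self) -> int:
        return self.child.shape[1]

    def nontransmitted(self) -> np.ndarray:
        return self.father + self.mother - self.child


# ---------------------------------------------------------------------------
# haplotype panel


def _simulate_haplotypes(
    frequencies: np.ndarray,
    blocks: list[tuple[int, int]],
    rho: float,
    n_haplotypes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian-copula haplotypes: latent AR(rho) within blocks, thresholded
    at the normal quantile of each allele frequency."""
    m = len(frequencies)
    z = np.empty((n_haplotypes, m))
    for start, stop in blocks:
        width = stop - start
        eps = rng.standard_normal((n_haplotypes, width))
        block = np.empty_like(eps)
        block[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - rho**2)
        for k in range(1, width):
            block[:, k] = rho * block[:, k - 1] + scale * eps[:, k]
        z[:, start:stop] = block
    thresholds = stats.norm.ppf(frequencies)
    haps = (z < thresholds).astype(np.int8)
    # guarantee polymorphism: flip one haplotype at monomorphic columns
    colmean = haps.mean(axis=0)
    for j in np.flatnonzero((colmean == 0) | (colmean == 1)):
        i = rng.integers(n_haplotypes)
        haps[i, j] = 1 - haps[i, j]
    return haps


def simulate_panel(
    n_haplotypes: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    block_size: int = 10,
    within_block_correlation: float = 0.0,
    genome_length: int = 10_000_000,
    seed: int = 0,
) -> HaplotypePanel:
    """Simulate a haplotype panel with block LD.

    Blocks partition the variant axis into runs of ``block_size``; variants
    in distinct blocks are independent. Positions are uniformly spaced on a
    single synthetic chromosome of ``genome_length`` bp.
    """
    if n_haplotypes < 4:
        raise ValueError(f"n_haplotypes must be >= 4, got {n_haplotypes}")
    if n_variants < 1:
        raise ValueError(f"n_variants must be >= 1, got {n_variants}")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range {maf_range} must lie within (0, 0.5]")
    if not 0.0 <= within_block_correlation < 1.0:
        raise ValueError(
            f"within_block_correlation must be in [0, 1), got {within_block_correlation}"
        )
    if block_size < 1:
        raise ValueError(f"block_size must be >= 1, got {block_size}")
    if genome_length < n_variants:
        raise ValueError("genome_length too small for n_variants")

    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=n_variants)
    blocks = [
        (start, min(start + block_size, n_variants))
        for start in range(0, n_variants, block_size)
    ]
    haps = _simulate_haplotypes(freqs, blocks, within_block_correlation, n_haplotypes, rng)
    spacing = genome_length // (n_variants + 1)
    positions = (np.arange(1, n_variants + 1) * max(spacing, 1)).astype(np.int64)
    return HaplotypePanel(positions, freqs, haps, blocks, seed)


# ---------------------------------------------------------------------------
# disease model


def _linear_predictor(genotypes: np.ndarray, model: RiskModel) -> np.ndarray:
    if model.causal_indices.size == 0:
        return np.zeros(genotypes.shape[0])
    return genotypes[:, model.causal_indices] @ model.log_rr


def _solve_intercept(panel: HaplotypePanel, model: RiskModel, rng: np.random.Generator,
                     n_probe: int = 20000) -> float:
    """Intercept of the logistic risk model matching the target prevalence,
    solved on a Monte-Carlo probe sample of genotypes."""
    g = _draw_genotypes(panel, n_probe, rng)
    eta = _linear_predictor(g, model)

    def mean_risk(alpha):
        return np.mean(1.0 / (1.0 + np.exp(-(alpha + eta)))) - model.prevalence

    lo, hi = -50.0, 10.0
    return float(optimize.brentq(mean_risk, lo, hi))


def _draw_genotypes(panel: HaplotypePanel, n: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.integers(panel.n_haplotypes, size=(n, 2))
    return panel.haplotypes[idx[:, 0]] + panel.haplotypes[idx[:, 1]]


def _stratum_panels(
    panel: HaplotypePanel, n_strata: int, shift: float, rng: np.random.Generator
) -> list[HaplotypePanel]:
    """Per-stratum panels with symmetrically shifted allele frequencies."""
    if n_strata <= 1 or shift == 0.0:
        return [panel] * max(n_strata, 1)
    panels = []
    for s in range(n_strata):
        delta = shift * (2.0 * s / (n_strata - 1) - 1.0)
        freqs = np.clip(panel.frequencies + delta, 0.01, 0.99)
        haps = _simulate_haplotypes(
            freqs, panel.blocks, _infer_rho(panel), panel.n_haplotypes, rng
        )
        panels.append(HaplotypePanel(panel.positions, freqs, haps, panel.blocks, panel.seed))
    return panels


def _infer_rho(panel: HaplotypePanel) -> float:
    """Latent correlation is not stored on the panel; reuse of the block
    machinery for stratified panels estimates it from adjacent columns."""
    rs = []
    for start, stop in panel.blocks:
        for j in range(start, stop - 1):
            a = panel.haplotypes[:, j].astype(float)
            b = panel.haplotypes[:, j + 1].astype(float)
            if a.std() > 0 and b.std() > 0:
                rs.append(np.corrcoef(a, b)[0, 1])
    return float(np.clip(np.median(rs), 0.0, 0.99)) if rs else 0.0


def simulate_case_control(
    panel: HaplotypePanel,
    model: RiskModel,
    n_cases: int,
    n_controls: int,
    n_strata: int = 1,
    stratum_freq_shift: float = 0.0,
    seed: int = 0,
    stratum_logit_shift: float = 1.5,
    draw_budget: int = DEFAULT_DRAW_BUDGET,
    target_info: float = 1.0,
) -> CaseControlCohort:
    """Simulate a labelled case-control cohort by rejection sampling.

    Disease status follows a logistic model with per-allele log odds
    ``model.log_rr`` and an intercept solved from the prevalence. With
    ``n_strata > 1`` the strata have shifted allele frequencies
    (+-``stratum_freq_shift``) and shifted baseline log odds
    (+-``stratum_logit_shift``), creating confounding; standardized stratum
    indicators are returned as ancestry covariates.
    """
    if model.causal_indices.size and model.causal_indices.max() >= panel.n_variants:
        raise ValueError("risk model refers to variants outside the panel")
    rng = np.random.default_rng(seed)
    panels = _stratum_panels(panel, n_strata, stratum_freq_shift, rng)
    n_strata = max(n_strata, 1)

    alphas, offsets, prevalences = [], [], []
    for s in range(n_strata):
        off = (
            stratum_logit_shift * (2.0 * s / (n_strata - 1) - 1.0)
            if n_strata > 1 else 0.0
        )
        offsets.append(off)
        alphas.append(_solve_intercept(panels[s], model, rng))
        # stratum prevalence after its baseline-risk offset
        g_probe = _draw_genotypes(panels[s], 2000, rng)
        eta = alphas[s] + off + _linear_predictor(g_probe, model)
        prevalences.append(float(np.mean(1.0 / (1.0 + np.exp(-eta)))))

    # cases are drawn from strata proportional to stratum prevalence and
    # controls proportional to 1 - prevalence, as pooled sampling would give
    prevalences = np.asarray(prevalences)
    per_stratum_cases = _split_proportional(n_cases, prevalences)
    per_stratum_controls = _split_proportional(n_controls, 1.0 - prevalences)

    geno_rows, status_rows, strata_rows = [], [], []
    draws = 0
    for s in range(n_strata):
        want_cases, want_controls = per_stratum_cases[s], per_stratum_controls[s]
        got_cases = got_controls = 0
        while got_cases < want_cases or got_controls < want_controls:
            need_cases = want_cases - got_cases
            batch = max(1000, int(2.0 * need_cases / max(model.prevalence, 1e-6)))
            batch = min(batch, 500_000)
            if draws + batch > draw_budget:
                batch = draw_budget - draws
                if batch <= 0:
                    raise AscertainmentError(
                        f"draw budget {draw_budget} exhausted with "
                        f"{got_cases}/{want_cases} cases in stratum {s}"
                    )
            draws += batch
            g = _draw_genotypes(panels[s], batch, rng)
            risk = 1.0 / (1.0 + np.exp(-(alphas[s] + offsets[s] + _linear_predictor(g, model))))
            affected = rng.random(batch) < risk
            for is_case, want, got in ((True, want_cases, got_cases),
                                       (False, want_controls, got_controls)):
                sel = np.flatnonzero(affected == is_case)[: want - got]
                if sel.size:
                    geno_rows.append(g[sel])
                    status_rows.append(np.full(sel.size, int(is_case)))
                    strata_rows.append(np.full(sel.size, s))
                if is_case:
                    got_cases += sel.size
                else:
                    got_controls += sel.size

    genotypes = np.vstack(geno_rows)
    status = np.concatenate(status_rows)
    strata = np.concatenate(strata_rows)
    order = rng.permutation(len(status))
    genotypes, status, strata = genotypes[order], status[order], strata[order]

    dosages = genotypes.astype(float)
    info = 1.0
    if target_info < 1.0:
        dosages = _degrade_dosages(dosages, target_info, rng)
        info = target_info

    samples = [f"S{i}" for i in range(len(status))]
    records = _records_from_genotypes(panel, dosages, info)
    matrix = DosageMatrix(samples, records, dosages)
    covariates = _stratum_covariates(strata, n_strata)
    return CaseControlCohort(matrix, status, strata, covariates)


def _split_proportional(total: int, weights: np.ndarray) -> list[int]:
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    counts = np.floor(weights * total).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(weights * total - counts))
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


def _stratum_covariates(strata: np.ndarray, n_strata: int) -> np.ndarray:
    if n_strata <= 1:
        return np.zeros((len(strata), 0))
    cols = []
    for s in range(1, n_strata):
        col = (strata == s).astype(float)
        col = (col - col.mean()) / (col.std() if col.std() > 0 else 1.0)
        cols.append(col)
    return np.column_stack(cols)


def _records_from_genotypes(panel: HaplotypePanel, dosages: np.ndarray, info: float):
    freqs = dosages.mean(axis=0) / 2.0
    return [
        VariantRecord(
            id=f"var{j}", chrom="1", pos=int(panel.positions[j]),
            ref="A", alt="G", af=float(np.clip(freqs[j], 0, 1)), info=info,
        )
        for j in range(panel.n_variants)
    ]


def simulate_liability_case_control(
    panel: HaplotypePanel,
    causal_indices: np.ndarray,
    liability_h2: float,
    prevalence: float,
    n_cases: int,
    n_controls: int,
    seed: int = 0,
    draw_budget: int = DEFAULT_DRAW_BUDGET,
) -> tuple[CaseControlCohort, np.ndarray]:
    """Liability-threshold cohort with a known genetic liability variance.

    Standardized causal genotypes get equal weights scaled so the genetic
    component explains exactly ``liability_h2`` of the unit-variance
    liability; disease is liability above the prevalence threshold. Returns
    the cohort and the per-variant liability weights used.
    """
    causal_indices = np.asarray(causal_indices, dtype=np.int64)
    if not 0.0 < liability_h2 < 1.0:
        raise ValueError("liability_h2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    freqs = panel.realized_frequencies()[causal_indices]
    raw_w = np.full(causal_indices.size, 1.0)
    scale = np.sqrt(liability_h2 / np.sum(raw_w**2 * 2 * freqs * (1 - freqs)))
    weights = raw_w * scale
    threshold = stats.norm.isf(prevalence)
    env_sd = np.sqrt(1.0 - liability_h2)
    center = 2 * freqs

    geno_rows, status_rows = [], []
    got_cases = got_controls = 0
    draws = 0
    while got_cases < n_cases or got_controls < n_controls:
        batch = max(2000, int(2.0 * (n_cases - got_cases) / max(prevalence, 1e-6)))
        batch = min(batch, 500_000)
        if draws + batch > draw_budget:
            batch = draw_budget - draws
            if batch <= 0:
                raise AscertainmentError(
                    f"draw budget {draw_budget} exhausted with {got_cases}/{n_cases} cases"
                )
        draws += batch
        g = _draw_genotypes(panel, batch, rng)
        liab = (g[:, causal_indices] - center) @ weights + env_sd * rng.standard_normal(batch)
        affected = liab > threshold
        for is_case in (True, False):
            need = (n_cases - got_cases) if is_case else (n_controls - got_controls)
            sel = np.flatnonzero(affected == is_case)[:need]
            if sel.size:
                geno_rows.append(g[sel])
                status_rows.append(np.full(sel.size, int(is_case)))
            if is_case:
                got_cases += sel.size
            else:
                got_controls += sel.size

    genotypes = np.vstack(geno_rows).astype(float)
    status = np.concatenate(status_rows)
    order = rng.permutation(len(status))
    genotypes, status = genotypes[order], status[order]
    samples = [f"S{i}" for i in range(len(status))]
    matrix = DosageMatrix(samples, _records_from_genotypes(panel, genotypes, 1.0), genotypes)
    cohort = CaseControlCohort(matrix, status, np.zeros(len(status), dtype=int),
                               np.zeros((len(status), 0)))
    return cohort, weights


# ---------------------------------------------------------------------------
# trios


def simulate_trios(
    panel: HaplotypePanel,
    model: RiskModel,
    n_trios: int,
    seed: int = 0,
    draw_budget: int = DEFAULT_DRAW_BUDGET,
) -> TrioCohort:
    """Simulate affected-child trios by rejection sampling.

    Parents are drawn from the panel haplotype pool; each parent transmits
    one of its two haplotypes chosen uniformly (no recombination); the trio
    is retained only if the child is affected under the risk model.
    Mendelian consistency is exact on the hard genotypes.
    """
    if model.causal_indices.size and model.causal_indices.max() >= panel.n_variants:
        raise ValueError("risk model refers to variants outside the panel")
    rng = np.random.default_rng(seed)
    alpha = _solve_intercept(panel, model, rng)

    child_rows, father_rows, mother_rows = [], [], []
    got = 0
    draws = 0
    while got < n_trios:
        batch = max(2000, int(2.0 * (n_trios - got) / max(model.prevalence, 1e-6)))
        batch = min(batch, 500_000)
        if draws + batch > draw_budget:
            batch = draw_budget - draws
            if batch <= 0:
                raise AscertainmentError(
                    f"draw budget {draw_budget} exhausted with {got}/{n_trios} trios"
                )
        draws += batch
        hap_idx = rng.integers(panel.n_haplotypes, size=(batch, 4))
        f1 = panel.haplotypes[hap_idx[:, 0]]
        f2 = panel.haplotypes[hap_idx[:, 1]]
        m1 = panel.haplotypes[hap_idx[:, 2]]
        m2 = panel.haplotypes[hap_idx[:, 3]]
        pick_f = rng.integers(2, size=batch)[:, None]
        pick_m = rng.integers(2, size=batch)[:, None]
        t_f = np.where(pick_f == 0, f1, f2)
        t_m = np.where(pick_m == 0, m1, m2)
        child = t_f + t_m
        risk = 1.0 / (1.0 + np.exp(-(alpha + _linear_predictor(child, model))))
        sel = np.flatnonzero(rng.random(batch) < risk)[: n_trios - got]
        if sel.size:
            child_rows.append(child[sel])
            father_rows.append(f1[sel] + f2[sel])
            mother_rows.append(m1[sel] + m2[sel])
            got += sel.size

    return TrioCohort(
        child=np.vstack(child_rows),
        father=np.vstack(father_rows),
        mother=np.vstack(mother_rows),
        variants=panel.variant_records(),
    )


# ---------------------------------------------------------------------------
# dosage degradation


def _degrade_dosages(dosages: np.ndarray, target_info: float,
                     rng: np.random.Generator, noise_share: float = 0.2) -> np.ndarray:
    """Shrink hard genotypes toward their column mean and add noise so that
    var(dosage) ~= target_info * 2p(1-p). ``noise_share`` is the fraction of
    the target variance carried by the additive noise term."""
    mean = dosages.mean(axis=0)
    var = dosages.var(axis=0)
    var = np.where(var > 0, var, 1.0)
    a = np.sqrt((1.0 - noise_share) * target_info)
    sigma = np.sqrt(noise_share * target_info * var)
    noise = rng.standard_normal(dosages.shape)
    out = np.clip(mean + a * (dosages - mean) + sigma * noise, 0.0, 2.0)
    # clipping deflates the variance; rescale around the mean to restore the
    # target ratio (a few fixed-point passes suffice)
    for _ in range(3):
        p_hat = out.mean(axis=0) / 2.0
        denom = 2.0 * p_hat * (1.0 - p_hat)
        realized = np.where(denom > 0, out.var(axis=0) / denom, target_info)
        adjust = np.sqrt(np.where(realized > 0, target_info / realized, 1.0))
        out = np.clip(out.mean(axis=0) + adjust * (out - out.mean(axis=0)), 0.0, 2.0)
    return out


def dosify(
    hard_genotypes: np.ndarray,
    target_info: float,
    seed: int = 0,
    positions: np.ndarray | None = None,
) -> DosageMatrix:
    """Turn hard genotypes into imputation-style dosages with a target info
    score (ratio var(dosage)/2p(1-p)); ``target_info=1`` returns the
    genotypes unchanged."""
    g = np.asarray(hard_genotypes)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("hard genotypes must be in {0, 1, 2}")
    if not 0.0 < target_info <= 1.0:
        raise ValueError(f"target_info must be in (0, 1], got {target_info}")
    rng = np.random.default_rng(seed)
    g = g.astype(float)
    if target_info == 1.0:
        dosages = g.copy()
    else:
        dosages = _degrade_dosages(g, target_info, rng)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    freqs = dosages.mean(axis=0) / 2.0
    records = [
        VariantRecord(
            id=f"var{j}", chrom="1", pos=int(positions[j]), ref="A", alt="G",
            af=float(np.clip(freqs[j], 0, 1)), info=target_info,
        )
        for j in range(m)
    ]
    return DosageMatrix([f"S{i}" for i in range(n)], records, dosages)


def realized_info(dosages: np.ndarray) -> np.ndarray:
    """Ratio info score var(d)/(2 p_hat (1-p_hat)) per variant column."""
    d = np.asarray(dosages, dtype=float)
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * p * (1.0 - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, d.var(axis=0) / denom, np.nan)


# ---------------------------------------------------------------------------
# annotation tracks


def simulate_annotation(
    spec: EnrichmentSpec,
    assoc: pd.DataFrame,
    seed: int = 0,
    anchor_positions: np.ndarray | None = None,
    chrom: str = "1",
) -> AnnotationTrack:
    """Simulate an annotation track with controllable enrichment.

    Each interval is anchored (centred) on a randomly chosen associated
    variant with probability ``spec.anchor_probability``, else placed
    uniformly on the genome. Anchor candidates are ``anchor_positions`` when
    given, otherwise variants with P <= ``spec.anchor_p_max``; with no
    candidates all intervals are uniform. Output is sorted and merged.
    """
    positions = assoc["pos"].to_numpy()
    if positions.size and positions.max() > spec.genome_length:
        raise ValueError("genome_length does not cover all variant positions")
    rng = np.random.default_rng(seed)
    if anchor_positions is None:
        anchor_positions = positions[assoc["p"].to_numpy() <= spec.anchor_p_max]
    anchor_positions = np.asarray(anchor_positions)

    lengths = np.maximum(
        1, rng.exponential(spec.mean_length, size=spec.n_intervals).astype(np.int64)
    )
    anchored = rng.random(spec.n_intervals) < spec.anchor_probability
    if anchor_positions.size == 0:
        anchored[:] = False
    centers = np.empty(spec.n_intervals, dtype=np.int64)
    n_anchor = int(anchored.sum())
    if n_anchor:
        centers[anchored] = rng.choice(anchor_positions, size=n_anchor)
    centers[~anchored] = rng.integers(0, spec.genome_length, size=spec.n_intervals - n_anchor)

    starts = np.clip(centers - lengths // 2, 0, spec.genome_length - 1)
    ends = np.clip(starts + lengths, 1, spec.genome_length)
    starts = np.minimum(starts, ends - 1)
    intervals = [(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    return AnnotationTrack(intervals)
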