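"""Bayesian refinement of association signals into credible variant sets.

Intervals are defined as +-0.1 cM around an index variant on a cumulative
recombination map; per-variant approximate Bayes factors are normalized into
posterior probabilities (single-causal assumption) and aggregated into the
smallest sets reaching 95%/99% cumulative probability. Multiple independent
signals within an interval are handled by conditioning each signal on the
other's lead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .assoc import logistic_assoc
from .gwasio import RecombinationMap

__all__ = [
    "CredibleSet",
    "define_interval",
    "log_approx_bayes_factor",
    "approx_bayes_factor",
    "credible_set",
    "multi_signal_refine",
]

DEFAULT_PRIOR_SD = 0.2
DEFAULT_LEVELS = (0.95, 0.99)


@dataclass
class CredibleSet:
    """Ranked variants with normalized posteriors and per-level member sets.

    ``table`` has one row per interval variant, sorted by descending
    posterior (bp position breaking ties), with columns snp/pos/log_bf/
    posterior/cumulative plus one boolean ``in_<level>`` column per level.
    ``members`` maps each level to the ordered ids of its minimal set and
    ``spans`` to that set's (start_bp, end_bp).
    """

    index_variant: str
    interval: tuple[int, int]
    table: pd.DataFrame
    members: dict[float, list[str]] = field(default_factory=dict)
    attained: dict[float, float] = field(default_factory=dict)
    spans: dict[float, tuple[int, int]] = field(default_factory=dict)


def define_interval(
    index_pos: int,
    recomb_map: RecombinationMap,
    half_width_cm: float = 0.1,
) -> tuple[int, int]:
    """Smallest bp interval extending >= ``half_width_cm`` either side of the
    index position on the cumulative-cM scale (linear interpolation),
    clipped at the map ends with a warning."""
    if not recomb_map.covers(index_pos):
        raise ValueError(
            f"index position {index_pos} outside the recombination map "
            f"[{recomb_map.positions[0]}, {recomb_map.positions[-1]}]"
        )
    cm0 = float(recomb_map.cm_at(index_pos))
    lo_cm = cm0 - half_width_cm
    hi_cm = cm0 + half_width_cm
    clipped = False
    if lo_cm < recomb_map.cumulative_cm[0]:
        lo_cm = float(recomb_map.cumulative_cm[0])
        clipped = True
    if hi_cm > recomb_map.cumulative_cm[-1]:
        hi_cm = float(recomb_map.cumulative_cm[-1])
        clipped = True
    if clipped:
        warnings.warn("interval clipped at chromosome end")
    # tolerance guards against float jitter in the interpolation
    start = int(np.floor(recomb_map.bp_at(lo_cm) + 1e-6))
    end = int(np.ceil(recomb_map.bp_at(hi_cm) - 1e-6))
    return start, end


def log_approx_bayes_factor(beta, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Log approximate Bayes factor in favour of association.

    log BF = 0.5 log(V/(V+W)) + z^2 W / (2 (V+W)) with V = se^2, W =
    prior_sd^2 and z = beta/se; a normal prior on the log relative risk.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    z2 = (beta / se) ** 2
    return 0.5 * np.log(v / (v + w)) + z2 * w / (2.0 * (v + w))


def approx_bayes_factor(beta, se, prior_sd: float = DEFAULT_PRIOR_SD):
    return np.exp(log_approx_bayes_factor(beta, se, prior_sd))


def credible_set(
    stats_in_interval: pd.DataFrame,
    levels=DEFAULT_LEVELS,
    prior_sd: float = DEFAULT_PRIOR_SD,
    index_variant: str | None = None,
    interval: tuple[int, int] | None = None,
) -> CredibleSet:
    """Credible sets from per-variant summary statistics within an interval.

    Posteriors are sum-normalized Bayes factors (equivalently
    exp(logBF - logsumexp(logBF))); each level's member set is the shortest
    prefix of the posterior-descending ranking whose cumulative probability
    reaches the level. Ties in posterior break by ascending bp position.
    """
    df = stats_in_interval
    required = {"snp", "pos", "beta", "se"}
    if not required.issubset(df.columns):
        raise ValueError(f"statistics need columns {sorted(required)}")
    ok = np.isfinite(df["beta"].to_numpy(float)) & np.isfinite(df["se"].to_numpy(float))
    df = df.loc[ok]
    if len(df) == 0:
        raise ValueError("no variants with finite statistics in the interval")
    log_bf = log_approx_bayes_factor(
        df["beta"].to_numpy(float), df["se"].to_numpy(float), prior_sd
    )
    log_post = log_bf - logsumexp(log_bf)
    posterior = np.exp(log_post)

    with np.errstate(over="ignore"):
        bf = np.exp(log_bf)  # may overflow to inf for extreme signals
    out = pd.DataFrame(
        {
            "snp": df["snp"].to_numpy(),
            "pos": df["pos"].to_numpy(),
            "bf": bf,
            "log_bf": log_bf,
            "posterior": posterior,
        }
    )
    out = out.sort_values(
        ["posterior", "pos"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["cumulative"] = out["posterior"].cumsum()

    levels = sorted(levels)
    members: dict[float, list[str]] = {}
    attained: dict[float, float] = {}
    spans: dict[float, tuple[int, int]] = {}
    for level in levels:
        k = int(np.searchsorted(out["cumulative"].to_numpy(), level) + 1)
        k = min(k, len(out))
        out[f"in_{level:g}"] = np.arange(len(out)) < k
        members[level] = out["snp"].head(k).tolist()
        attained[level] = float(out["cumulative"].iloc[k - 1])
        pos = out["pos"].head(k)
        spans[level] = (int(pos.min()), int(pos.max()))

    if index_variant is None:
        index_variant = str(out["snp"].iloc[0])
    if interval is None:
        interval = (int(df["pos"].min()), int(df["pos"].max()))
    return CredibleSet(
        index_variant=index_variant,
        interval=interval,
        table=out,
        members=members,
        attained=attained,
        spans=spans,
    )


def multi_signal_refine(
    cohort,
    interval: tuple[int, int],
    index_variant: str,
    secondary_p_threshold: float = 1e-3,
    levels=DEFAULT_LEVELS,
    prior_sd: float = DEFAULT_PRIOR_SD,
    covariates=None,
) -> list[CredibleSet]:
    """Credible sets allowing for multiple independent signals.

    The interval is re-scanned conditioning on the index variant; if any
    other variant has conditional P below ``secondary_p_threshold``, a
    second signal is declared (its lead = smallest conditional P) and each
    signal's credible set is computed from an association scan that includes
    the other signal's lead as a covariate. Otherwise a single unconditioned
    credible set is returned.
    """
    matrix = cohort.dosages
    positions = matrix.positions()
    in_iv = (positions >= interval[0]) & (positions <= interval[1])
    iv_idx = np.flatnonzero(in_iv)
    if iv_idx.size == 0:
        raise ValueError("no variants inside the interval")
    ids = {matrix.variants[j].id for j in iv_idx}
    if index_variant not in ids:
        raise ValueError(f"index variant {index_variant} not inside the interval")

    def scan(condition):
        full = logistic_assoc(cohort, covariates=covariates, condition_on=condition)
        return full.iloc[iv_idx].reset_index(drop=True)

    cond = scan([index_variant])
    others = cond[cond["snp"] != index_variant]
    finite = others[np.isfinite(others["p"].astype(float))]
    secondary = None
    if len(finite) and finite["p"].min() < secondary_p_threshold:
        secondary = str(finite.loc[finite["p"].idxmin(), "snp"])

    if secondary is None:
        marginal = scan([])
        return [
            credible_set(marginal, levels, prior_sd,
                         index_variant=index_variant, interval=interval)
        ]

    sets = []
    for lead, other in ((index_variant, secondary), (secondary, index_variant)):
        conditional = scan([other])
        conditional = conditional[conditional["snp"] != other]
        sets.append(
            credible_set(conditional, levels, prior_sd,
                         index_variant=lead, interval=interval)
        )
    return sets
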