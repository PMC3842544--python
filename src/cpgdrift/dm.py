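"""Paired differential methylation with empirical-Bayes variance moderation.

The statistic is the standard moderated paired t: per-site sample variances
of donor-pair beta differences are shrunk toward a prior ``s0^2`` carrying
``d0`` prior degrees of freedom,

    s2_post = (d0 * s0^2 + df * s2) / (d0 + df),
    t_mod   = delta / sqrt(s2_post / n_pairs),

with two-sided p-values from the t distribution on ``d0 + df`` degrees of
freedom.  ``prior_df = 0`` reduces exactly to the classical paired t-test.
Hyperparameters can be estimated by moment-matching the scaled-F
distribution of the per-site variances (the usual empirical-Bayes fit on
log variances via digamma/trigamma moments).
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .types import BetaMatrix, ModerationParams, PairedDesign, SiteStat

log = logging.getLogger(__name__)


def variance_filter(matrix: BetaMatrix, keep_fraction: float) -> BetaMatrix:
    """Keep the ``ceil(keep_fraction * n_sites)`` sites with highest
    across-sample variance of beta, preserving site order.

    This is the variance-confinement step applied before testing (the
    study kept the most variable half of the array).  Ties at the cutoff
    are broken by site order.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if matrix.values.shape[1] < 2:
        raise ValueError("variance filter needs >= 2 samples")
    n_keep = math.ceil(keep_fraction * matrix.values.shape[0])
    var = matrix.values.var(axis=1, ddof=1, skipna=True).to_numpy()
    var = np.nan_to_num(var, nan=-1.0)  # all-missing sites sort last
    # stable sort on -var keeps manifest order among ties
    order = np.argsort(-var, kind="stable")[:n_keep]
    keep_mask = np.zeros(len(var), dtype=bool)
    keep_mask[order] = True
    return BetaMatrix(matrix.values.loc[keep_mask], matrix.samples)


def pair_differences(matrix: BetaMatrix, design: PairedDesign) -> np.ndarray:
    """Sites x pairs matrix of beta differences (b - a), NaN where either
    member of a pair is missing."""
    a_cols = [p[1] for p in design.pairs]
    b_cols = [p[2] for p in design.pairs]
    for col in a_cols + b_cols:
        if col not in matrix.values.columns:
            raise ValueError(f"design sample {col!r} not in matrix")
    a = matrix.values[a_cols].to_numpy(dtype=float)
    b = matrix.values[b_cols].to_numpy(dtype=float)
    return b - a


def estimate_moderation(s2: np.ndarray, df: np.ndarray) -> ModerationParams:
    """Moment-matching fit of (d0, s0^2) from per-site variances.

    Matches the first two moments of log(s2) under the scaled-F model:
    e_i = log(s2_i) - digamma(df_i/2) + log(df_i/2) has mean
    log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond the sampling term trigamma(df_i/2).
    Sites with zero variance are excluded from the fit.
    """
    ok = (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive-variance sites to estimate moderation")
    s2, df = s2[ok], df[ok]
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=0)  # population second moment of the log-variance residuals
    target = evar - special.polygamma(1, df / 2.0).mean()
    if target <= 0:
        # variances more concordant than the sampling noise alone: infinite
        # prior df, every site shrunk fully to s0^2
        prior_df = math.inf
        prior_var = float(np.exp(emean))
        return ModerationParams(prior_df, prior_var)
    prior_df = 2.0 * _trigamma_inverse(target)
    prior_var = float(np.exp(emean + special.digamma(prior_df / 2.0) - np.log(prior_df / 2.0)))
    return ModerationParams(prior_df, prior_var)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs x > 0")
    y = 0.5 + 1.0 / x  # standard starting value
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-12 * y:
            break
    return float(y)


def paired_moderated_t(
    matrix: BetaMatrix,
    design: PairedDesign,
    moderation: ModerationParams | str = "estimate",
) -> list[SiteStat]:
    """Moderated paired t-test per site for the contrast b vs a.

    Donor pairs missing either value at a site are dropped for that site;
    sites with fewer than 2 complete pairs are dropped entirely (logged).
    ``moderation="estimate"`` fits (d0, s0^2) from the data;
    ``ModerationParams(0, ...)`` gives the classical paired t-test.
    """
    diffs = pair_differences(matrix, design)
    n_complete = np.sum(~np.isnan(diffs), axis=1)
    tested = n_complete >= 2
    n_dropped = int((~tested).sum())
    if n_dropped:
        log.info("dropping %d site(s) with < 2 complete pairs", n_dropped)
    if not tested.any():
        raise ValueError("all sites dropped: no site has >= 2 complete pairs")

    site_ids = np.asarray(matrix.site_ids)[tested]
    d = diffs[tested]
    n = n_complete[tested].astype(float)
    delta = np.nanmean(d, axis=1)
    s2 = np.nanvar(d, axis=1, ddof=1)
    df = n - 1.0

    if isinstance(moderation, str):
        if moderation not in ("estimate", "none"):
            raise ValueError(f"unknown moderation mode {moderation!r}")
        params = (
            estimate_moderation(s2, df)
            if moderation == "estimate"
            else ModerationParams(0.0, 1.0)
        )
    else:
        params = moderation

    d0, s0sq = params.prior_df, params.prior_var
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.full_like(df, np.inf)
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(s2_post / n)
    # zero-variance policy: delta == 0 -> t = 0, p = 1; delta != 0 with no
    # variance at all (only possible when d0 == 0) -> p underflows to the
    # smallest representable value rather than an exact (disallowed) zero
    t = np.where((s2_post == 0) & (delta == 0), 0.0, t)
    finite_df = np.where(np.isinf(df_total), 1e12, df_total)
    p = 2.0 * stats.t.sf(np.abs(np.where(np.isfinite(t), t, np.inf)), finite_df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return [
        SiteStat(
            cpg_id=str(site_ids[i]),
            delta=float(delta[i]),
            s2=float(s2[i]),
            df=float(df[i]),
            t_mod=float(t[i]) if np.isfinite(t[i]) else math.copysign(math.inf, delta[i]),
            p=float(p[i]),
        )
        for i in range(len(site_ids))
    ]


def adjust_pvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1) or np.any(np.isnan(p))):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_directions(
    stats_list: list[SiteStat], alpha: float = 0.05
) -> tuple[list[SiteStat], int, int]:
    """Set adjusted p-values and hyper/hypo/ns direction calls.

    A site is hyper iff adj_p < alpha and delta > 0, hypo iff adj_p < alpha
    and delta < 0.  Returns (annotated stats, n_hyper, n_hypo).
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    adj = adjust_pvalues(np.array([s.p for s in stats_list]))
    out: list[SiteStat] = []
    n_hyper = n_hypo = 0
    for s, ap in zip(stats_list, adj):
        if ap < alpha and s.delta > 0:
            direction = "hyper"
            n_hyper += 1
        elif ap < alpha and s.delta < 0:
            direction = "hypo"
            n_hypo += 1
        else:
            direction = "ns"
        out.append(replace(s, adj_p=float(ap), direction=direction))
    return out, n_hyper, n_hypo


def overlap_comparisons(direction_sets: dict[str, set[str]]) -> dict[frozenset[str], int]:
    """Full Venn decomposition of per-contrast site sets.

    Returns {frozenset of contrast names: count of sites exclusive to
    exactly that combination}.  Counts sum to the size of the union.
    """
    if len(direction_sets) < 2:
        raise ValueError("need >= 2 contrasts to compare")
    names = list(direction_sets)
    universe = set().union(*direction_sets.values())
    regions: dict[frozenset[str], int] = {}
    for site in universe:
        member = frozenset(n for n in names if site in direction_sets[n])
        regions[member] = regions.get(member, 0) + 1
    return regions


def run_contrast(
    matrix: BetaMatrix,
    condition_a: str,
    condition_b: str,
    keep_fraction: float = 0.5,
    alpha: float = 0.05,
    moderation: ModerationParams | str = "estimate",
) -> tuple[list[SiteStat], int, int]:
    """Variance-confine, test, adjust and call one paired contrast."""
    confined = variance_filter(matrix, keep_fraction) if keep_fraction < 1 else matrix
    design = PairedDesign.from_samples(confined.samples, condition_a, condition_b)
    stats_list = paired_moderated_t(confined, design, moderation)
    return call_directions(stats_list, alpha)
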