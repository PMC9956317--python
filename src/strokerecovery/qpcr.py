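"""Efficiency-corrected relative expression with randomization testing.

Implements the Pfaffl/REST computational model for group-wise qPCR
comparison: per-gene amplification efficiencies ``E`` are estimated from
dilution-series standard curves (``E = 10**(-1/slope)``), and the expression
ratio of a sample group versus a control group is

    ratio = E_target**dCt_target / E_ref**dCt_ref,
    dCt   = mean Cq(control) - mean Cq(sample),

with group means taken over animal-level means of the technical replicates
(animals, not wells, are the experimental unit).  With ``E = 2`` for both
genes this reduces exactly to the classical ``2**ddCt``.

Significance comes from a fixed-reallocation randomization test: whole
animals (their target+reference Cq pair moves together) are reallocated
between the two groups preserving group sizes, the statistic is the log
expression ratio, and the two-sided p-value counts reallocations at least as
extreme as the observed one — exhaustively when the number of distinct
reallocations is small, by Monte Carlo with add-one correction otherwise.
Dispersion of the ratio is a nonparametric bootstrap over animals within
group.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StandardCurveError

__all__ = [
    "EfficiencyResult",
    "ExpressionResult",
    "RandomizationResult",
    "DispersionResult",
    "estimate_efficiency",
    "efficiency_table",
    "animal_mean_cq",
    "expression_ratio",
    "randomization_test",
    "ratio_dispersion",
    "relative_expression_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EfficiencyResult:
    """Standard-curve fit for one primer pair."""

    gene: str
    slope: float
    intercept: float
    e: float
    r2: float
    n_points: int


def estimate_efficiency(points: pd.DataFrame, gene: str | None = None) -> EfficiencyResult:
    """Estimate amplification efficiency from a dilution series.

    Ordinary least squares of Cq on log10(input ng) over the non-NTC points;
    the efficiency is ``E = 10**(-1/slope)``.  Values outside the plausible
    [1.6, 2.1] band trigger a warning but are reported as estimated.

    Parameters
    ----------
    points : DataFrame
        Columns ``input_ng, cq`` (and optionally ``is_ntc``, ``gene``) for a
        single gene; 0-ng/no-template rows are ignored.

    Raises
    ------
    StandardCurveError
        If the fitted slope is non-negative (Cq must fall with template).
    ValueError
        If fewer than three distinct template amounts are available.
    """
    pts = points.copy()
    if gene is None:
        gene = str(pts["gene"].iloc[0]) if "gene" in pts.columns else ""
    if "is_ntc" in pts.columns:
        pts = pts[~pts["is_ntc"].astype(bool)]
    pts = pts[(pts["input_ng"] > 0) & pts["cq"].notna()]
    if pts["input_ng"].nunique() < 3:
        raise ValueError("need at least 3 distinct non-NTC template amounts")
    x = np.log10(pts["input_ng"].to_numpy(dtype=float))
    y = pts["cq"].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise StandardCurveError(
            f"invalid standard curve for {gene or 'gene'}: slope {fit.slope:.4g} >= 0")
    e = 10.0 ** (-1.0 / fit.slope)
    if not 1.6 <= e <= 2.1:
        warnings.warn(
            f"efficiency {e:.3f} for {gene or 'gene'} outside the plausible [1.6, 2.1] band",
            stacklevel=2)
    return EfficiencyResult(gene, float(fit.slope), float(fit.intercept),
                            float(e), float(fit.rvalue ** 2), len(pts))


def efficiency_table(dilution: pd.DataFrame) -> pd.DataFrame:
    """Estimate the efficiency of every gene in a dilution table."""
    rows = []
    for gene, grp in dilution.groupby("gene", sort=True):
        res = estimate_efficiency(grp, gene=gene)
        rows.append(dict(gene=gene, slope=res.slope, intercept=res.intercept,
                         e=res.e, r2=res.r2, n_points=res.n_points))
    return pd.DataFrame(rows)


def animal_mean_cq(cq: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to one Cq per animal and design cell."""
    keys = [c for c in ("animal_id", "group", "endpoint_day", "region", "hemisphere", "gene")
            if c in cq.columns]
    return cq.groupby(keys, as_index=False)["cq"].mean()


@dataclass
class ExpressionResult:
    """Efficiency-corrected expression ratio of sample vs. control group."""

    ratio: float
    dct_target: float
    dct_ref: float
    e_target: float
    e_ref: float
    n_sample: int
    n_control: int
    gene: str | None = None
    region: str | None = None
    hemisphere: str | None = None
    endpoint_day: int | None = None
    sample_group: str | None = None
    control_group: str | None = None
    p: float | None = None
    se_log: float | None = None
    se_lo: float | None = None
    se_hi: float | None = None


def expression_ratio(target_sample: Sequence[float], target_control: Sequence[float],
                     ref_sample: Sequence[float], ref_control: Sequence[float],
                     e_target: float = 2.0, e_ref: float = 2.0) -> ExpressionResult:
    """Pfaffl ratio of a sample group vs. a control group.

    Inputs are animal-level mean Cq values for the target and reference
    genes; ``dCt = mean Cq(control) - mean Cq(sample)`` per gene, and
    ``ratio = e_target**dCt_target / e_ref**dCt_ref``.
    """
    ts = np.asarray(target_sample, dtype=float)
    tc = np.asarray(target_control, dtype=float)
    rs = np.asarray(ref_sample, dtype=float)
    rc = np.asarray(ref_control, dtype=float)
    if min(ts.size, tc.size, rs.size, rc.size) < 1:
        raise ValueError("need at least one animal per group")
    if ts.size != rs.size or tc.size != rc.size:
        raise ValueError("target and reference Cq values must pair per animal")
    dct_t = float(tc.mean() - ts.mean())
    dct_r = float(rc.mean() - rs.mean())
    ratio = e_target ** dct_t / e_ref ** dct_r
    return ExpressionResult(ratio=float(ratio), dct_target=dct_t, dct_ref=dct_r,
                            e_target=e_target, e_ref=e_ref,
                            n_sample=int(ts.size), n_control=int(tc.size))


@lru_cache(maxsize=64)
def _assignment_matrix(n_total: int, n_sample: int) -> np.ndarray:
    """Boolean matrix of every way to pick the sample group from the pool."""
    combos = list(combinations(range(n_total), n_sample))
    mat = np.zeros((len(combos), n_total), dtype=bool)
    for i, combo in enumerate(combos):
        mat[i, list(combo)] = True
    return mat


def _log_ratio_stats(sel: np.ndarray, t_all: np.ndarray, r_all: np.ndarray,
                     n1: int, n2: int, log_et: float, log_er: float) -> np.ndarray:
    """Log expression ratio for each row of a sample-selection matrix."""
    sum_t = sel @ t_all
    sum_r = sel @ r_all
    mean_ts, mean_tc = sum_t / n1, (t_all.sum() - sum_t) / n2
    mean_rs, mean_rc = sum_r / n1, (r_all.sum() - sum_r) / n2
    return (mean_tc - mean_ts) * log_et - (mean_rc - mean_rs) * log_er


@dataclass(frozen=True)
class RandomizationResult:
    """Fixed-reallocation randomization test outcome."""

    p: float
    statistic: float  # observed log expression ratio
    method: str  # "exhaustive" or "monte_carlo"
    n_permutations: int


def randomization_test(target_sample, ref_sample, target_control, ref_control,
                       e_target: float = 2.0, e_ref: float = 2.0,
                       n_perm: int = 10000, seed=None,
                       exhaustive_cap: int = 20000) -> RandomizationResult:
    """Two-sided significance of the expression ratio by animal reallocation.

    The statistic is the log expression ratio.  Whole animals — their
    (target, reference) Cq pair — are reallocated between the groups
    preserving group sizes.  When the number of distinct reallocations
    ``C(n1+n2, n1)`` is at most ``exhaustive_cap`` they are enumerated and
    ``p = #{|stat| >= |observed|} / N`` (the observed allocation counts);
    otherwise ``n_perm`` random reallocations give the Monte-Carlo estimate
    ``p = (#{|stat_perm| >= |stat_obs|} + 1) / (n_perm + 1)``.
    """
    ts = np.asarray(target_sample, dtype=float)
    rs = np.asarray(ref_sample, dtype=float)
    tc = np.asarray(target_control, dtype=float)
    rc = np.asarray(ref_control, dtype=float)
    if ts.size == 0 or tc.size == 0:
        raise ValueError("both groups must be non-empty")
    if ts.size != rs.size or tc.size != rc.size:
        raise ValueError("target and reference Cq values must pair per animal")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; the p-value will be coarse",
                      stacklevel=2)

    n1, n2 = ts.size, tc.size
    n = n1 + n2
    log_et, log_er = math.log(e_target), math.log(e_ref)
    t_all = np.concatenate([ts, tc])
    r_all = np.concatenate([rs, rc])

    obs = ((tc.mean() - ts.mean()) * log_et - (rc.mean() - rs.mean()) * log_er)
    # tolerance so the observed allocation always counts itself
    tol = 1e-12 * max(1.0, abs(obs))

    if math.comb(n, n1) <= exhaustive_cap:
        sel = _assignment_matrix(n, n1)
        stat = _log_ratio_stats(sel, t_all, r_all, n1, n2, log_et, log_er)
        p = float(np.mean(np.abs(stat) >= abs(obs) - tol))
        return RandomizationResult(p, float(obs), "exhaustive", sel.shape[0])

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    sel = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(sel, order[:, :n1], True, axis=1)
    stat = _log_ratio_stats(sel, t_all, r_all, n1, n2, log_et, log_er)
    hits = int(np.sum(np.abs(stat) >= abs(obs) - tol))
    p = (hits + 1) / (n_perm + 1)
    return RandomizationResult(float(p), float(obs), "monte_carlo", n_perm)


@dataclass(frozen=True)
class DispersionResult:
    """Bootstrap dispersion of the expression ratio."""

    se_log: float
    lo: float
    hi: float
    available: bool = True


def ratio_dispersion(target_sample, ref_sample, target_control, ref_control,
                     e_target: float = 2.0, e_ref: float = 2.0,
                     B: int = 1000, seed=None) -> DispersionResult:
    """Bootstrap SE of the log ratio, resampling animals within each group.

    Returns the SE of the log expression ratio and the back-transformed
    range ``ratio * exp(-+SE)``.  With fewer than two animals in either
    group the dispersion is marked unavailable.
    """
    ts = np.asarray(target_sample, dtype=float)
    rs = np.asarray(ref_sample, dtype=float)
    tc = np.asarray(target_control, dtype=float)
    rc = np.asarray(ref_control, dtype=float)
    obs = expression_ratio(ts, tc, rs, rc, e_target, e_ref)
    if ts.size < 2 or tc.size < 2:
        return DispersionResult(float("nan"), float("nan"), float("nan"), available=False)
    rng = np.random.default_rng(seed)
    log_et, log_er = math.log(e_target), math.log(e_ref)
    idx_s = rng.integers(0, ts.size, size=(B, ts.size))
    idx_c = rng.integers(0, tc.size, size=(B, tc.size))
    dct_t = tc[idx_c].mean(axis=1) - ts[idx_s].mean(axis=1)
    dct_r = rc[idx_c].mean(axis=1) - rs[idx_s].mean(axis=1)
    log_ratios = dct_t * log_et - dct_r * log_er
    se = float(np.std(log_ratios, ddof=1))
    return DispersionResult(se, obs.ratio * math.exp(-se), obs.ratio * math.exp(se))


def relative_expression_table(cq: pd.DataFrame,
                              efficiencies: pd.DataFrame | dict | None = None,
                              n_perm: int = 10000, exhaustive_cap: int = 20000,
                              bootstrap: int = 1000, seed=None,
                              force_e2: bool = False) -> pd.DataFrame:
    """Group-wise relative expression for every gene and design cell.

    For each (gene, region, hemisphere, endpoint) the contrasts follow the
    control-group convention: stroke groups are compared against sham
    (sham is the control), and for the stroke-stroke comparison the
    well-recovered group is the control, so that ratio reads as
    poor-relative-to-good.  The reference gene normalizes every contrast;
    animals missing the reference Cq in a cell are excluded with a warning.

    Parameters
    ----------
    cq : DataFrame
        Replicate-level Cq table (``animal_id, group, endpoint_day, region,
        hemisphere, gene, replicate, cq``); the reference gene is the
        one named ``Gapdh`` (case-insensitive) unless only one gene is
        common to all cells.
    efficiencies : DataFrame or dict, optional
        Per-gene efficiency (``gene``/``e`` columns or mapping); missing or
        ``force_e2=True`` means E = 2 for every gene (classical ddCt).
    seed : int, optional
        Seeds the Monte-Carlo permutations and the bootstrap.
    """
    if isinstance(efficiencies, pd.DataFrame):
        eff = dict(zip(efficiencies["gene"], efficiencies["e"]))
    else:
        eff = dict(efficiencies or {})

    ref_gene = next((g for g in cq["gene"].unique() if g.lower() == "gapdh"), None)
    if ref_gene is None:
        raise ValueError("reference gene Gapdh not found in the Cq table")

    def e_of(gene):
        if force_e2 or not eff:
            return 2.0
        if gene not in eff:
            raise ValueError(f"no efficiency estimate for gene {gene}")
        return float(eff[gene])

    means = animal_mean_cq(cq)
    seed_seq = np.random.SeedSequence(seed if seed is not None else 0)

    rows = []
    cells = means[means["gene"] != ref_gene][
        ["gene", "region", "hemisphere", "endpoint_day"]].drop_duplicates()
    cells = cells.sort_values(["gene", "region", "hemisphere", "endpoint_day"])
    for cell in cells.itertuples(index=False):
        sub = means[(means["region"] == cell.region)
                    & (means["hemisphere"] == cell.hemisphere)
                    & (means["endpoint_day"] == cell.endpoint_day)]
        target = sub[sub["gene"] == cell.gene].set_index("animal_id")
        ref = sub[sub["gene"] == ref_gene].set_index("animal_id")

        def group_pairs(group):
            t = target[target["group"] == group]
            paired = t.index.intersection(ref.index)
            lost = t.index.difference(ref.index)
            if len(lost):
                logger.warning("excluding animals without reference Cq in %s/%s/%s d%s: %s",
                               cell.gene, cell.region, cell.hemisphere,
                               cell.endpoint_day, list(lost))
            return (t.loc[paired, "cq"].to_numpy(),
                    ref.loc[paired, "cq"].to_numpy())

        present = sorted(target["group"].unique())
        contrasts = []
        for g in ("good", "poor"):
            if g in present and "sham" in present:
                contrasts.append((g, "sham"))
        if "good" in present and "poor" in present:
            contrasts.append(("poor", "good"))

        for sample_group, control_group in contrasts:
            ts, rs = group_pairs(sample_group)
            tc, rc = group_pairs(control_group)
            if ts.size == 0 or tc.size == 0:
                continue
            e_t, e_r = e_of(cell.gene), e_of(ref_gene)
            res = expression_ratio(ts, tc, rs, rc, e_t, e_r)
            child = np.random.default_rng(seed_seq.spawn(1)[0])
            test = randomization_test(ts, rs, tc, rc, e_t, e_r,
                                      n_perm=n_perm, seed=child,
                                      exhaustive_cap=exhaustive_cap)
            disp = ratio_dispersion(ts, rs, tc, rc, e_t, e_r,
                                    B=bootstrap, seed=np.random.default_rng(seed_seq.spawn(1)[0]))
            rows.append(dict(
                gene=cell.gene, region=cell.region, hemisphere=cell.hemisphere,
                endpoint_day=cell.endpoint_day,
                sample_group=sample_group, control_group=control_group,
                dct_target=res.dct_target, dct_ref=res.dct_ref,
                e_target=e_t, e_ref=e_r, ratio=res.ratio,
                p=test.p, test_method=test.method,
                se_log=disp.se_log, se_lo=disp.lo, se_hi=disp.hi,
                n_sample=res.n_sample, n_control=res.n_control))
    return pd.DataFrame(rows)
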