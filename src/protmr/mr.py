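"""Two-sample MR estimators and sensitivity statistics.

All estimators consume a :class:`~protmr.sumstats.HarmonizedSet` (or its
DataFrame) whose rows carry per-SNP exposure and outcome betas and SEs on a
common effect allele. The causal estimate is on the outcome scale per unit
exposure — log-odds per SD of protein for a binary outcome — and is also
reported as an odds ratio with a 95% Wald interval.

Method dispatch follows common proteome-screen practice: Wald ratio for a
single instrument, inverse-variance weighting (IVW) as the primary estimator
otherwise, with MR-Egger, weighted median and the mode estimators attached
when the instrument count permits. Cochran's Q (heterogeneity) and the Egger
intercept (directional pleiotropy) make up the sensitivity report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonizedSet, InstrumentSet, SumStatsTable, harmonize

__all__ = [
    "MREstimate", "SensitivityReport", "ProteinMRResult",
    "ProteomeScreenResult",
    "wald_ratio", "ivw", "egger", "weighted_median", "mode_estimators",
    "cochran_q", "bonferroni_threshold", "run_proteome_mr",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    method: str
    beta: float
    se: float
    pval: float
    nsnp: int
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self):
        self.or_ = float(np.exp(self.beta))
        self.ci_low = float(np.exp(self.beta - _Z95 * self.se))
        self.ci_high = float(np.exp(self.beta + _Z95 * self.se))


@dataclass
class SensitivityReport:
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None


def _hdf(h) -> pd.DataFrame:
    return h.df if isinstance(h, HarmonizedSet) else h


def _cols(h):
    d = _hdf(h)
    return (d["beta_exp"].to_numpy(dtype=float),
            d["se_exp"].to_numpy(dtype=float),
            d["beta_out"].to_numpy(dtype=float),
            d["se_out"].to_numpy(dtype=float))


def _norm_p(z: float) -> float:
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float,
               se_out: float) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp with the
    first-order SE se_out / |beta_exp|."""
    if beta_exp == 0:
        raise ZeroDivisionError("null instrument: beta_exp = 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return MREstimate("wald", beta, se, _norm_p(beta / se), 1)


def _ivw_core(be, so, bo):
    w = be ** 2 / so ** 2
    beta = float(np.sum(w * (bo / be)) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    return beta, se, w


def ivw(h, random_effects: bool = False) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate with first-order
    weights (equivalent to weighted zero-intercept regression of beta_out
    on beta_exp).

    The SE uses the delta-method ratio variance
    v_j = (se_out² + betâ²·se_exp²)/beta_exp², giving
    se² = Σ w_j² v_j / (Σ w_j)² — this reduces exactly to the textbook
    (Σ w_j)^(-1/2) when exposure SEs are negligible, and keeps nominal CI
    coverage when they are not. ``random_effects`` additionally inflates
    the SE by max(1, sqrt(Q/df)).
    """
    be, se_e, bo, so = _cols(h)
    if len(be) < 2:
        raise ValueError("IVW requires at least 2 instruments")
    beta, _, w = _ivw_core(be, so, bo)
    v = (so ** 2 + beta ** 2 * se_e ** 2) / be ** 2
    se = float(np.sqrt(np.sum(w ** 2 * v)) / np.sum(w))
    if random_effects:
        q = float(np.sum(w * (bo / be - beta) ** 2))
        se *= max(1.0, np.sqrt(q / (len(be) - 1)))
    return MREstimate("ivw", beta, se, _norm_p(beta / se), len(be))


def egger(h) -> tuple[MREstimate, tuple[float, float, float]]:
    """MR-Egger: weighted least squares of beta_out on beta_exp with a free
    intercept (weights 1/se_out²), instruments oriented to beta_exp >= 0.

    Returns the slope as the causal estimate plus
    (intercept, intercept_se, intercept_pval); inference uses a t
    distribution with nsnp - 2 df.
    """
    be, _, bo, so = _cols(h)
    n = len(be)
    if n < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    sign = np.where(be < 0, -1.0, 1.0)
    x, y, w = be * sign, bo * sign, 1.0 / so ** 2
    sw = np.sum(w)
    xbar, ybar = np.sum(w * x) / sw, np.sum(w * y) / sw
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    resid = y - intercept - slope * x
    sigma2 = float(np.sum(w * resid ** 2) / (n - 2))
    se_slope = float(np.sqrt(sigma2 / sxx))
    se_int = float(np.sqrt(sigma2 * (1.0 / sw + xbar ** 2 / sxx)))
    tdist = stats.t(df=n - 2)

    def t_p(value, se):
        if se == 0.0:  # perfect fit: degenerate but well defined
            return 0.0 if value != 0.0 else 1.0
        return float(min(1.0, 2.0 * tdist.sf(abs(value / se))))

    est = MREstimate("egger", slope, se_slope, t_p(slope, se_slope), n)
    return est, (intercept, se_int, t_p(intercept, se_int))


def _weighted_median_of(ratios, weights):
    order = np.argsort(ratios, kind="stable")
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    cw = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, cw, r))


def _bootstrap_se(h, point_fn, nboot, seed):
    """Parametric bootstrap: redraw per-SNP betas from their sampling
    distributions and take the SD of the re-estimated statistic."""
    be, se_e, bo, so = _cols(h)
    rng = np.random.default_rng(seed)
    est = np.empty(nboot)
    for b in range(nboot):
        bb = be + se_e * rng.standard_normal(be.shape)
        ob = bo + so * rng.standard_normal(bo.shape)
        bb = np.where(bb == 0, 1e-300, bb)
        est[b] = point_fn(ob / bb, bb ** 2 / so ** 2)
    return float(np.std(est, ddof=1))


def weighted_median(h, nboot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted median of per-SNP ratio estimates with IVW weights,
    interpolated at cumulative weight 0.5; SE by seeded parametric
    bootstrap."""
    import warnings
    be, _, bo, so = _cols(h)
    if len(be) < 2:
        raise ValueError("weighted median requires at least 2 instruments")
    if nboot < 100:
        warnings.warn("nboot < 100: bootstrap SE will be unstable")
    beta = _weighted_median_of(bo / be, be ** 2 / so ** 2)
    se = _bootstrap_se(h, _weighted_median_of, nboot, seed)
    return MREstimate("weighted_median", beta, se,
                      _norm_p(beta / se) if se > 0 else (0.0 if beta else 1.0),
                      len(be))


def _silverman_bw(ratios, factor):
    # modified Silverman rule on the ratio estimates
    n = len(ratios)
    sd = float(np.std(ratios, ddof=1))
    iqr = float(np.subtract(*np.percentile(ratios, [75, 25]))) / 1.349
    spread = [v for v in (sd, iqr) if v > 0]
    if not spread:
        return 0.0
    return factor * 0.9 * min(spread) * n ** (-0.2)


def _kde_mode(ratios, weights, bw):
    grid = np.linspace(ratios.min() - 3 * bw, ratios.max() + 3 * bw, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / bw) ** 2)
    dens = dens @ (weights / weights.sum())
    return float(grid[np.argmax(dens)])


def mode_estimators(h, bandwidth_factor: float = 1.0, nboot: int = 1000,
                    seed: int = 0) -> tuple[MREstimate, MREstimate]:
    """Weighted and simple mode estimates: the mode of a Gaussian-kernel
    density over per-SNP ratios (IVW weights vs equal weights), bandwidth
    from a modified Silverman rule; SEs by seeded parametric bootstrap.

    If all ratios coincide the bandwidth degenerates to zero and both modes
    equal that common ratio with SE 0.
    """
    be, _, bo, so = _cols(h)
    n = len(be)
    if n < 3:
        raise ValueError("mode estimators require at least 3 instruments")
    ratios = bo / be
    bw = _silverman_bw(ratios, bandwidth_factor)
    if bw == 0.0:
        v = float(ratios[0])
        est = MREstimate("weighted_mode", v, 0.0, 0.0 if v else 1.0, n)
        simple = MREstimate("simple_mode", v, 0.0, 0.0 if v else 1.0, n)
        return est, simple

    ivw_w = be ** 2 / so ** 2
    eq_w = np.ones(n)

    def point(weights):
        def fn(r, w_ivw):
            w = w_ivw if weights is None else np.ones(len(r))
            b = _silverman_bw(r, bandwidth_factor)
            if b == 0:
                return float(r[0])
            return _kde_mode(r, w, b)
        return fn

    beta_w = _kde_mode(ratios, ivw_w, bw)
    beta_s = _kde_mode(ratios, eq_w, bw)
    se_w = _bootstrap_se(h, point(None), nboot, seed)
    se_s = _bootstrap_se(h, point("equal"), nboot, seed + 1)
    mk = lambda name, b, s: MREstimate(
        name, b, s, _norm_p(b / s) if s > 0 else (0.0 if b else 1.0), n)
    return mk("weighted_mode", beta_w, se_w), mk("simple_mode", beta_s, se_s)


def cochran_q(h) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic around the fixed-effect IVW
    estimate; returns (Q, df, p) with p from chi-square on nsnp - 1 df."""
    be, _, bo, so = _cols(h)
    if len(be) < 2:
        raise ValueError("Cochran's Q requires at least 2 instruments")
    beta, _, w = _ivw_core(be, so, bo)
    q = float(np.sum(w * (bo / be - beta) ** 2))
    df = len(be) - 1
    return q, df, float(max(stats.chi2.sf(q, df), np.finfo(float).tiny))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class ProteinMRResult:
    protein_id: str
    status: str  # "ok" | "untested"
    primary: MREstimate | None = None
    estimates: dict = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    harmonized: HarmonizedSet | None = None
    significant: bool = False


@dataclass
class ProteomeScreenResult:
    results: dict
    threshold: float
    n_tested: int
    alpha: float

    @property
    def significant_proteins(self) -> list:
        return [p for p, r in self.results.items() if r.significant]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, r in self.results.items():
            if r.status != "ok":
                rows.append({"protein": pid, "method": None, "status": r.status})
                continue
            sens = r.sensitivity
            for name, est in r.estimates.items():
                rows.append({
                    "protein": pid, "method": name, "status": "ok",
                    "beta": est.beta, "se": est.se, "pval": est.pval,
                    "or": est.or_, "ci_low": est.ci_low,
                    "ci_high": est.ci_high, "nsnp": est.nsnp,
                    "primary": name == r.primary.method,
                    "significant": r.significant and name == r.primary.method,
                    "q_stat": sens.q_stat if sens else np.nan,
                    "q_pval": sens.q_pval if sens else np.nan,
                    "egger_intercept":
                        sens.egger_intercept if sens else np.nan,
                    "egger_intercept_pval":
                        sens.egger_intercept_pval if sens else np.nan,
                })
        return pd.DataFrame(rows)


def mr_all_methods(h: HarmonizedSet, methods: str = "all",
                   nboot: int = 1000, seed: int = 0):
    """Run every estimator the instrument count permits on one harmonized
    set. Returns (primary_estimate, {method: estimate}, sensitivity_report).

    ``methods="primary"`` computes only the dispatch estimator plus the
    sensitivity statistics — the cheap path for large replicate screens.
    """
    n = h.nsnp
    d = h.df
    estimates: dict = {}
    if n == 1:
        primary = wald_ratio(d["beta_exp"].iloc[0], d["se_exp"].iloc[0],
                             d["beta_out"].iloc[0], d["se_out"].iloc[0])
        estimates["wald"] = primary
        return primary, estimates, None

    primary = ivw(h)
    estimates["ivw"] = primary
    sens_q = cochran_q(h)
    intercept = (None, None, None)
    if n >= 3:
        eg, intercept = egger(h)
        estimates["egger"] = eg
    if methods == "all":
        estimates["weighted_median"] = weighted_median(h, nboot, seed)
        if n >= 3:
            wm, sm = mode_estimators(h, nboot=nboot, seed=seed)
            estimates["weighted_mode"] = wm
            estimates["simple_mode"] = sm
    sens = SensitivityReport(sens_q[0], sens_q[1], sens_q[2], *intercept)
    return primary, estimates, sens


def run_proteome_mr(exposures: dict, outcome: SumStatsTable,
                    alpha: float = 0.05, methods: str = "all",
                    nboot: int = 1000, seed: int = 0,
                    palindrome_eaf_limit: float = 0.42
                    ) -> ProteomeScreenResult:
    """Proteome-wide screen: harmonize each protein's instruments with the
    outcome GWAS and estimate its causal effect (Wald for one instrument,
    IVW as primary otherwise), flagging significance at the Bonferroni
    threshold alpha / (number of proteins tested).

    ``exposures`` maps protein id to an :class:`InstrumentSet`. Proteins
    whose instruments cannot be harmonized are reported as "untested", never
    silently dropped.
    """
    prelim: dict = {}
    for pid, inst in exposures.items():
        if inst.n_instruments == 0:
            prelim[pid] = None
            continue
        h = harmonize(inst.table, outcome, palindrome_eaf_limit)
        prelim[pid] = h if h.nsnp else None

    tested = [p for p, h in prelim.items() if h is not None]
    threshold = bonferroni_threshold(alpha, max(len(tested), 1))

    results: dict = {}
    for i, (pid, h) in enumerate(prelim.items()):
        if h is None:
            results[pid] = ProteinMRResult(pid, "untested")
            continue
        primary, ests, sens = mr_all_methods(h, methods, nboot, seed + i)
        results[pid] = ProteinMRResult(
            pid, "ok", primary, ests, sens, h,
            significant=bool(primary.pval < threshold))
    return ProteomeScreenResult(results, threshold, len(tested), alpha)
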