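"""Group-level inference: response rates, flight metrics, PCA, SSR rates.

Contracts mirror the study's analysis plan:

* response rates — binomial (logit) GLM with likelihood-ratio chi-square
  omnibus tests per factor and Tukey-adjusted pairwise contrasts of the
  estimated group proportions;
* flight metrics — Kruskal–Wallis omnibus with Dunn's pairwise z tests,
  Benjamini–Hochberg adjusted;
* PCA on the five standardized flight variables;
* SSR spike rates — linear mixed model (REML) with a random intercept per
  sensillum, Wald F tests per term using a containment denominator-df
  convention, and Tukey-adjusted pairwise genotype contrasts.

Conventions held fixed and documented: Kruskal–Wallis/Dunn use the standard
tie correction; Tukey adjustment is via the studentized-range distribution
on |t|*sqrt(2); containment df gives between-sensillum terms sensillum-level
denominator degrees of freedom.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FLIGHT_VARIABLES = ["flight_duration_s", "prop_bouncing", "prop_voi",
                    "saccade_freq_hz", "turn_consistency"]

#: stand-in for infinite denominator df in the studentized-range distribution
_LARGE_DF = 1e6


@dataclass
class GroupComparison:
    """Omnibus statistics and pairwise contrasts for one grouped analysis."""

    factors: list[str]
    omnibus: pd.DataFrame          # term, statistic, df_num, df_den, p
    contrasts: pd.DataFrame        # contrast, estimate, se, statistic, p_raw, p_adj, method
    flags: list[str] = field(default_factory=list)


@dataclass
class PcaSummary:
    """Loadings, scores and variance fractions of the flight-variable PCA."""

    loadings: pd.DataFrame         # variables x components
    scores: pd.DataFrame           # trials x components
    variance_fractions: np.ndarray
    n_dropped: int = 0


def tukey_pvalue(t_stat: float, n_levels: int, df_den: float) -> float:
    """Tukey-family adjusted p for one pairwise statistic.

    Uses the studentized-range distribution: p = P(Q_{k, df} > |t| * sqrt(2)).
    """
    if not np.isfinite(t_stat):
        return float("nan")
    df_den = df_den if np.isfinite(df_den) else _LARGE_DF
    df_den = min(df_den, _LARGE_DF)
    return float(sps.studentized_range.sf(abs(t_stat) * np.sqrt(2.0), n_levels, df_den))


# ---------------------------------------------------------------------------
# response rates
# ---------------------------------------------------------------------------

def response_rate(table: pd.DataFrame, group_col: str = "group",
                  response_col: str = "responded") -> pd.DataFrame:
    """Responders / tested per group, with the rate as a percentage."""
    g = table.groupby(group_col)[response_col]
    out = g.agg(n="count", responders="sum").reset_index()
    out["rate_percent"] = 100.0 * out["responders"] / out["n"]
    return out


def _binomial_ll(y: np.ndarray, p: float) -> float:
    """Bernoulli log-likelihood of successes y at probability p (0 log 0 = 0)."""
    k = y.sum()
    n = len(y)
    ll = 0.0
    if k > 0:
        ll += k * np.log(p) if p > 0 else -np.inf
    if n - k > 0:
        ll += (n - k) * np.log1p(-p) if p < 1 else -np.inf
    return ll


def _two_level_lr(table: pd.DataFrame, group_col: str, response_col: str) -> tuple[float, int]:
    """Closed-form LR chi-square for a single-factor cell-means binomial model."""
    y = table[response_col].astype(float).to_numpy()
    groups = table[group_col].to_numpy()
    levels = pd.unique(groups)
    ll_full = sum(_binomial_ll(y[groups == g], y[groups == g].mean()) for g in levels)
    ll_null = _binomial_ll(y, y.mean())
    return 2.0 * (ll_full - ll_null), len(levels) - 1


def response_rate_test(table: pd.DataFrame, factors: list[str] | None = None,
                       response_col: str = "responded") -> GroupComparison:
    """Binomial GLM with LR chi-square omnibus tests and Tukey pairwise contrasts.

    ``table`` has one row per animal with a boolean ``response_col`` and one
    column per factor (default: the single factor ``group``).  With a single
    factor the omnibus statistic is computed in closed form (the cell-means
    model is saturated), which keeps it exact under complete separation; with
    several factors each term is tested by a likelihood-ratio comparison of
    additive GLM fits.  Pairwise contrasts compare observed cell proportions
    (cells = combinations of all factor levels) on the proportion scale with
    a Tukey-family adjustment; groups with a 0 or 1 proportion make the
    logistic fit separable and are flagged.
    """
    factors = factors or ["group"]
    table = table.copy()
    table[response_col] = table[response_col].astype(int)
    for f in factors:
        if table[f].nunique() < 2 and len(factors) == 1:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    flags: list[str] = []

    omnibus_rows = []
    if len(factors) == 1:
        lr, df = _two_level_lr(table, factors[0], response_col)
        omnibus_rows.append((factors[0], lr, df, np.nan, sps.chi2.sf(lr, df)))
    else:
        base = " + ".join(f"C({f})" for f in factors)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                full = smf.glm(f"{response_col} ~ {base}", data=table,
                               family=sm.families.Binomial()).fit(maxiter=200)
                for f in factors:
                    rest = " + ".join(f"C({g})" for g in factors if g != f) or "1"
                    red = smf.glm(f"{response_col} ~ {rest}", data=table,
                                  family=sm.families.Binomial()).fit(maxiter=200)
                    lr = 2.0 * (full.llf - red.llf)
                    df = int(full.df_model - red.df_model)
                    omnibus_rows.append((f, lr, df, np.nan, sps.chi2.sf(lr, df)))
            except Exception as exc:
                flags.append(f"glm_failure: {exc}")
                for f in factors:
                    omnibus_rows.append((f, np.nan, np.nan, np.nan, np.nan))

    # pairwise contrasts over the cells of all factors combined
    cell = table[factors].astype(str).agg(":".join, axis=1)
    counts = pd.DataFrame({"cell": cell, "y": table[response_col]}) \
        .groupby("cell")["y"].agg(n="count", k="sum")
    levels = list(counts.index)
    k_levels = len(levels)
    if any((counts["k"] == 0) | (counts["k"] == counts["n"])):
        flags.append("separation")
    rows = []
    for a, b in itertools.combinations(levels, 2):
        na, ka = counts.loc[a, "n"], counts.loc[a, "k"]
        nb, kb = counts.loc[b, "n"], counts.loc[b, "k"]
        pa, pb = ka / na, kb / nb
        est = pa - pb
        var = pa * (1 - pa) / na + pb * (1 - pb) / nb
        if var > 0:
            z = est / np.sqrt(var)
        else:
            z = 0.0 if est == 0 else np.inf
        p_raw = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else 0.0
        p_adj = tukey_pvalue(z, k_levels, np.inf) if np.isfinite(z) else 0.0
        rows.append((f"{a} - {b}", est, np.sqrt(var) if var > 0 else np.nan,
                     z, p_raw, p_adj, "tukey"))
    contrasts = pd.DataFrame(rows, columns=["contrast", "estimate", "se", "statistic",
                                            "p_raw", "p_adj", "method"])
    omnibus = pd.DataFrame(omnibus_rows, columns=["term", "statistic", "df_num", "df_den", "p"])
    return GroupComparison(factors=factors, omnibus=omnibus, contrasts=contrasts, flags=flags)


# ---------------------------------------------------------------------------
# flight metrics (nonparametric)
# ---------------------------------------------------------------------------

def metric_group_test(table: pd.DataFrame, value_col: str = "value",
                      group_col: str = "group") -> GroupComparison:
    """Kruskal–Wallis omnibus plus Dunn's pairwise z tests (BH-adjusted).

    Rows with missing values are dropped listwise; groups left with fewer
    than 2 values are excluded with a warning.  Ties use the standard
    correction; a table where every value is identical yields H = 0, p = 1
    and a ``ties`` flag.
    """
    t = table[[group_col, value_col]].dropna()
    n_dropped = len(table) - len(t)
    if n_dropped:
        logger.info("metric_group_test: dropped %d rows with missing values", n_dropped)
    sizes = t.groupby(group_col)[value_col].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("excluding groups with < 2 values: %s", small)
        t = t[~t[group_col].isin(small)]
    levels = sorted(t[group_col].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups with >= 2 values each")
    samples = [t.loc[t[group_col] == g, value_col].to_numpy(dtype=float) for g in levels]
    flags: list[str] = []
    if np.ptp(np.concatenate(samples)) == 0:
        h, p_omni = 0.0, 1.0
        flags.append("ties")
    else:
        h, p_omni = sps.kruskal(*samples)
    df = len(levels) - 1
    omnibus = pd.DataFrame([("group", h, df, np.nan, p_omni)],
                           columns=["term", "statistic", "df_num", "df_den", "p"])

    # Dunn's test with tie correction
    values = np.concatenate(samples)
    ranks = sps.rankdata(values)
    start = 0
    mean_ranks = {}
    for g, s in zip(levels, samples):
        mean_ranks[g] = ranks[start:start + len(s)].mean()
        start += len(s)
    n_total = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(levels, 2):
        na = sizes[a]
        nb = sizes[b]
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2 * sps.norm.sf(abs(z))
        rows.append([f"{a} - {b}", mean_ranks[a] - mean_ranks[b], se, z, p_raw])
    contrasts = pd.DataFrame(rows, columns=["contrast", "estimate", "se", "statistic", "p_raw"])
    if len(contrasts):
        contrasts["p_adj"] = multipletests(contrasts["p_raw"], method="fdr_bh")[1]
    else:
        contrasts["p_adj"] = []
    contrasts["method"] = "dunn_bh"
    return GroupComparison(factors=[group_col], omnibus=omnibus,
                           contrasts=contrasts, flags=flags)


# ---------------------------------------------------------------------------
# PCA of the five flight variables
# ---------------------------------------------------------------------------

def pca_flight(metrics: pd.DataFrame, variables: list[str] | None = None) -> PcaSummary:
    """PCA of z-scored flight variables (correlation-structure eigendecomposition).

    Rows with any missing variable (e.g. undefined turn consistency or
    non-responders) are dropped; at least 3 complete rows are required.
    Sign convention: within each component the largest-magnitude loading is
    positive.  A zero-variance variable raises an error naming it.
    """
    variables = variables or FLIGHT_VARIABLES
    data = metrics.copy()
    if "responded" in data.columns:
        data = data[data["responded"].astype(bool)]
    complete = data.dropna(subset=variables)
    n_dropped = len(data) - len(complete)
    if n_dropped:
        logger.info("pca_flight: dropped %d incomplete rows", n_dropped)
    if len(complete) < 3:
        raise ValueError(f"PCA needs >= 3 complete rows, got {len(complete)}")
    x = complete[variables].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    for name, s in zip(variables, sd):
        if s == 0:
            raise ValueError(f"variable {name!r} has zero variance")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    n_comp = len(s)
    loadings = vt.T.copy()
    scores = u * s
    for j in range(n_comp):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    frac = s ** 2 / (s ** 2).sum()
    comp_names = [f"PC{j + 1}" for j in range(n_comp)]
    idx = complete["trial_id"] if "trial_id" in complete.columns else complete.index
    return PcaSummary(
        loadings=pd.DataFrame(loadings, index=variables, columns=comp_names),
        scores=pd.DataFrame(scores, index=idx, columns=comp_names),
        variance_fractions=frac,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# SSR linear mixed model
# ---------------------------------------------------------------------------

def _containment_df(exog: np.ndarray, groups: np.ndarray,
                    term_cols: np.ndarray) -> tuple[float, bool]:
    """Containment denominator df for a Wald F test of `term_cols`.

    A term whose design columns are constant within every group (a
    between-sensillum factor such as genotype) is tested against
    sensillum-level df: n_groups - rank of the between-group design.
    Terms varying within groups use residual within-group df:
    n_obs - n_groups - (rank(X) - rank_between).
    """
    uniq = pd.unique(groups)
    n_groups = len(uniq)
    n_obs, p = exog.shape
    const_within = np.ones(p, dtype=bool)
    group_rows = {}
    for g in uniq:
        rows = exog[groups == g]
        group_rows[g] = rows[0]
        const_within &= np.all(np.abs(rows - rows[0]) < 1e-10, axis=0)
    between_design = np.array([group_rows[g] for g in uniq])[:, const_within]
    rank_between = np.linalg.matrix_rank(between_design) if between_design.size else 0
    rank_x = np.linalg.matrix_rank(exog)
    term_between = bool(np.all(const_within[term_cols]))
    if term_between:
        return float(max(n_groups - rank_between, 1)), True
    return float(max(n_obs - n_groups - (rank_x - rank_between), 1)), False


def ssr_mixed_model(points: pd.DataFrame, *, include_interaction: bool = False,
                    rate_col: str = "rate_spikes_s") -> GroupComparison:
    """REML linear mixed model for spike rates with a per-sensillum intercept.

    Fits ``rate ~ genotype + log10_dose`` (optionally with the interaction)
    with a random intercept per ``sensillum_id``; each fixed term is tested
    with a Wald F statistic using containment denominator df, and pairwise
    genotype contrasts (differences of genotype effects, i.e. contrasts of
    adjusted means at any common dose) are Tukey-adjusted.  A degenerate
    table where every rate is identical is returned as zero effects with a
    ``singular`` flag; a near-zero fitted random-intercept variance is also
    flagged ``singular``.
    """
    required = {"sensillum_id", "genotype", "log10_dose", rate_col}
    missing = required - set(points.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    data = points.dropna(subset=[rate_col]).copy()
    data["genotype"] = data["genotype"].astype(str)
    geno_levels = sorted(data["genotype"].unique())
    k = len(geno_levels)
    flags: list[str] = []

    if data[rate_col].nunique() <= 1:
        omnibus = pd.DataFrame(
            [("genotype", 0.0, k - 1, np.nan, 1.0),
             ("log10_dose", 0.0, 1, np.nan, 1.0)],
            columns=["term", "statistic", "df_num", "df_den", "p"])
        rows = [(f"{a} - {b}", 0.0, np.nan, 0.0, 1.0, 1.0, "tukey")
                for a, b in itertools.combinations(geno_levels, 2)]
        contrasts = pd.DataFrame(rows, columns=["contrast", "estimate", "se", "statistic",
                                                "p_raw", "p_adj", "method"])
        return GroupComparison(factors=["genotype", "log10_dose"], omnibus=omnibus,
                               contrasts=contrasts, flags=["singular"])

    terms = "C(genotype) + log10_dose"
    if include_interaction:
        terms += " + C(genotype):log10_dose"
    formula = f"rate ~ {terms}"
    data = data.rename(columns={rate_col: "rate"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data=data, groups=data["sensillum_id"])
        result = model.fit(reml=True)
    if not result.converged:
        flags.append("nonconverged")
    resid_var = float(result.scale)
    re_var = float(np.asarray(result.cov_re).ravel()[0])
    if re_var <= 1e-8 * max(resid_var, 1e-12):
        flags.append("singular")

    design_info = model.data.design_info
    exog = model.exog
    groups = data["sensillum_id"].to_numpy()
    beta = result.fe_params.to_numpy()
    vcov = result.cov_params().to_numpy()[:len(beta), :len(beta)]

    omnibus_rows = []
    for term in design_info.terms:
        if term.name() == "Intercept":
            continue
        sl = design_info.slice(term)
        cols = np.arange(sl.start, sl.stop)
        c = np.zeros((len(cols), len(beta)))
        for i, j in enumerate(cols):
            c[i, j] = 1.0
        cb = c @ beta
        cvc = c @ vcov @ c.T
        try:
            stat = float(cb @ np.linalg.solve(cvc, cb)) / len(cols)
        except np.linalg.LinAlgError:
            stat = np.nan
        ddf, _ = _containment_df(exog, groups, cols)
        p = sps.f.sf(stat, len(cols), ddf) if np.isfinite(stat) else np.nan
        omnibus_rows.append((term.name().replace("C(genotype)", "genotype"),
                             stat, len(cols), ddf, p))
    omnibus = pd.DataFrame(omnibus_rows, columns=["term", "statistic", "df_num", "df_den", "p"])

    # pairwise genotype contrasts: differences of genotype fixed effects
    geno_slice = None
    for term in design_info.terms:
        if term.name() == "C(genotype)":
            geno_slice = design_info.slice(term)
    contrast_rows = []
    if geno_slice is not None and k >= 2:
        effect = {geno_levels[0]: np.zeros(len(beta))}
        for i, level in enumerate(geno_levels[1:]):
            vec = np.zeros(len(beta))
            vec[geno_slice.start + i] = 1.0
            effect[level] = vec
        geno_cols = np.arange(geno_slice.start, geno_slice.stop)
        ddf_b, _ = _containment_df(exog, groups, geno_cols)
        for a, b in itertools.combinations(geno_levels, 2):
            l_vec = effect[a] - effect[b]
            est = float(l_vec @ beta)
            se = float(np.sqrt(l_vec @ vcov @ l_vec))
            t_stat = est / se if se > 0 else 0.0
            p_raw = 2 * sps.t.sf(abs(t_stat), ddf_b)
            p_adj = tukey_pvalue(t_stat, k, ddf_b)
            contrast_rows.append((f"{a} - {b}", est, se, t_stat, p_raw, p_adj, "tukey"))
    contrasts = pd.DataFrame(contrast_rows, columns=["contrast", "estimate", "se", "statistic",
                                                     "p_raw", "p_adj", "method"])
    return GroupComparison(factors=["genotype", "log10_dose"], omnibus=omnibus,
                           contrasts=contrasts, flags=flags)
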