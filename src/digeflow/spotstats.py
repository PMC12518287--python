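"""Spot-intensity statistics: log2 transform, quantile normalization, the
three per-spot significance frameworks, p-value adjustment, significant-spot
selection, and Fisher over-representation.

Three tests of the condition effect are provided per spot:

* ``kruskal`` — the rank-based Kruskal-Wallis test (chi-square p, k-1 df);
* ``mixed`` — a linear mixed model with a single random intercept (the
  biological replicate / gel), fitted by restricted maximum likelihood with
  the variance ratio profiled out, condition tested by a Wald F;
* ``moderated`` — a per-spot one-way linear model with empirical-Bayes
  variance moderation: residual variances are shrunk toward a prior variance
  s0^2 with prior degrees of freedom d0, both estimated by moment matching
  of the log residual variances to a scaled F distribution (closed forms via
  digamma/trigamma inversion).  The moderated F uses (k-1, d_g + d0) df.

The two multiple-testing adjustments exposed are Holm and Benjamini-Hochberg;
"FDR" in common usage is the same step-up procedure as BH and is accepted as
an alias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .io import CONDITIONS, SampleSheet, SpotTable

ADJUSTMENT_ALIASES = {"BH": "fdr_bh", "FDR": "fdr_bh", "Holm": "holm", "holm": "holm", "bh": "fdr_bh"}


@dataclass
class SpotTestResult:
    spot_id: str
    statistic: float
    p_raw: float
    p_adj: float
    method: str
    adjustment: str | None = None
    flag: str = ""


@dataclass
class ModerationPrior:
    """Empirical-Bayes prior for residual variances: d0 prior degrees of
    freedom (may be infinite) and s0_sq prior variance."""

    d0: float
    s0_sq: float


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def log2_and_average(table: SpotTable) -> SpotTable:
    """Log2-transform intensities and average technical duplicates.

    Columns sharing the same (organ, condition, replicate) triple are treated
    as technical duplicates of one biological sample and averaged on the log2
    scale.  Zero intensities are replaced by half the smallest positive value
    in their column (with a warning); spots with no positive value at all are
    excluded with a warning.
    """
    if table.log_transformed:
        raise ValueError("table is already log2-transformed")
    X = table.matrix.copy()

    # spots with no positive value at all are unusable on the log scale
    all_missing = ~np.any(np.isfinite(X) & (X > 0), axis=1)
    if all_missing.any():
        dropped = [s for s, m in zip(table.spot_ids, all_missing) if m]
        warnings.warn(f"excluding spots with no positive intensity: {dropped}")
        X = X[~all_missing]
        spot_ids = [s for s, m in zip(table.spot_ids, all_missing) if not m]
    else:
        spot_ids = list(table.spot_ids)

    # zero replacement, column-wise
    n_zeros = int(np.nansum(X == 0))
    if n_zeros:
        warnings.warn(f"replacing {n_zeros} zero intensities by half the "
                      "column minimum positive value")
        for j in range(X.shape[1]):
            col = X[:, j]
            pos = col[np.isfinite(col) & (col > 0)]
            if pos.size:
                col[col == 0] = pos.min() / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.log2(X)
    L[~np.isfinite(L)] = np.nan

    # average technical duplicates on the log scale
    sheet = table.sheet.frame
    key = list(zip(sheet["organ"], sheet["condition"], sheet["replicate"]))
    seen: dict[tuple, list[int]] = {}
    for j, k in enumerate(key):
        seen.setdefault(k, []).append(j)
    keep_rows, cols = [], []
    for k, idx in seen.items():
        keep_rows.append(idx[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cols.append(np.nanmean(L[:, idx], axis=1))
    new_sheet = SampleSheet(sheet.iloc[keep_rows])
    return SpotTable(
        spot_ids=spot_ids,
        matrix=np.column_stack(cols),
        sheet=new_sheet,
        log_transformed=True,
    )


def quantile_normalize(table: SpotTable) -> SpotTable:
    """Force every column onto the same empirical distribution: the mean of
    the column order statistics.  Within-column ranks are preserved; ties
    receive the average of the order statistics they span.  Missing values
    are handled by rank-based assignment over the observed entries only."""
    if not table.log_transformed:
        raise ValueError("quantile normalization expects log2 data")
    X = table.matrix
    n, m = X.shape
    out = np.full_like(X, np.nan)
    has_missing = bool(np.isnan(X).any())
    if not has_missing:
        ref = np.sort(X, axis=0).mean(axis=1)
        order = np.arange(1, n + 1, dtype=float)
        for j in range(m):
            ranks = stats.rankdata(X[:, j], method="average")
            out[:, j] = np.interp(ranks, order, ref)
    else:
        warnings.warn("missing values present: quantile normalization uses "
                      "rank-based assignment over observed entries")
        grid = (np.arange(n) + 0.5) / n
        quantiles = []
        for j in range(m):
            obs = X[~np.isnan(X[:, j]), j]
            quantiles.append(np.quantile(obs, grid))
        ref = np.mean(quantiles, axis=0)
        for j in range(m):
            obs_mask = ~np.isnan(X[:, j])
            obs = X[obs_mask, j]
            ranks = stats.rankdata(obs, method="average")
            p = (ranks - 0.5) / obs.size
            out[obs_mask, j] = np.interp(p, grid, ref)
    return replace(table, matrix=out, normalized=True)


# ---------------------------------------------------------------------------
# per-spot tests
# ---------------------------------------------------------------------------

def kruskal_test(groups: list[np.ndarray]) -> tuple[float, float, str]:
    """Kruskal-Wallis H (tie-corrected) with the chi-square p on k-1 df.

    All-identical observations leave H undefined; p is set to 1 with a flag.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if sum(len(g) > 0 for g in groups) < 2:
        raise ValueError("need at least two conditions with observations")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return float("nan"), 1.0, "constant"
    H, p = stats.kruskal(*groups)
    return float(H), float(p), ""


def _reml_neg_loglik(lam: float, y, X, Z) -> float:
    n, p = X.shape
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    rss = float(r @ Vi @ r)
    sign, logdet_V = np.linalg.slogdet(V)
    sign2, logdet_XVX = np.linalg.slogdet(XtVX)
    return 0.5 * ((n - p) * np.log(rss) + logdet_V + logdet_XVX)


def _golden_section(f, lo: float, hi: float, tol: float = 1e-8, max_iter: int = 200):
    """Golden-section minimization of a unimodal scalar function."""
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol * (1 + abs(a) + abs(b)):
            break
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def mixed_model_test(
    values: np.ndarray,
    conditions: np.ndarray,
    random_factor: np.ndarray,
    lambda_max: float = 1e4,
) -> tuple[float, float, float, str]:
    """Condition fixed effect in a random-intercept model, by profiled REML.

    The single variance ratio lambda = sigma_b^2 / sigma_e^2 is estimated by
    golden-section search on [0, lambda_max] (floored at 0), the fixed
    effects by GLS at the estimate, and the condition effect is tested with
    a Wald F.  The denominator df are n - p - (q - 1) when the random
    intercept is active and n - p when its variance collapses to zero (the
    model then degenerates to ordinary least squares, so the test reduces to
    the one-way ANOVA F).

    Returns (F, p, lambda_hat, flag).
    """
    y = np.asarray(values, dtype=float)
    mask = ~np.isnan(y)
    y = y[mask]
    conditions = np.asarray(conditions)[mask]
    random_factor = np.asarray(random_factor)[mask]
    n = y.size
    cond_levels = [c for c in CONDITIONS if c in set(conditions)] or \
        sorted(set(conditions))
    k = len(cond_levels)
    groups = sorted(set(random_factor))
    q = len(groups)
    if k < 2 or n < k + 1:
        raise ValueError("need >=2 conditions and >=2 replicates overall")
    if q >= n:
        raise ValueError("random factor has one observation per level: "
                         "variance components are not identifiable")
    # confounding check: every random group within a single condition AND
    # a single observation per group leaves no replicate information
    per_group_conditions = {g: set(conditions[random_factor == g]) for g in groups}
    if all(len(s) == 1 for s in per_group_conditions.values()) and q == k:
        raise ValueError("random factor is confounded with condition")

    X = np.column_stack(
        [np.ones(n)] + [(conditions == c).astype(float) for c in cond_levels[1:]]
    )
    Z = np.column_stack([(random_factor == g).astype(float) for g in groups])
    p = X.shape[1]

    lam = _golden_section(lambda l: _reml_neg_loglik(l, y, X, Z), 0.0, lambda_max)
    flag = ""
    if lam < 1e-6:
        lam = 0.0
        flag = "variance_component_zero"
    V = np.eye(n) + lam * Z @ Z.T
    Vi = np.linalg.inv(V)
    XtVX_inv = np.linalg.inv(X.T @ Vi @ X)
    beta = XtVX_inv @ X.T @ Vi @ y
    r = y - X @ beta
    sigma_e2 = float(r @ Vi @ r) / (n - p)
    L = np.zeros((k - 1, p))
    L[:, 1:] = np.eye(k - 1)
    cov_c = L @ XtVX_inv @ L.T * sigma_e2
    bc = L @ beta
    F = float(bc @ np.linalg.solve(cov_c, bc)) / (k - 1)
    df2 = n - p if lam == 0.0 else n - p - (q - 1)
    if df2 < 1:
        raise ValueError("no residual degrees of freedom for the Wald F")
    p_val = float(stats.f.sf(F, k - 1, df2))
    return F, p_val, lam, flag


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


def _oneway_fit(X: np.ndarray, cond_idx: np.ndarray, k: int):
    """Vectorized per-spot one-way fit (missing dropped pairwise).

    Returns (msb, s2, df_resid, n_obs) arrays over spots.
    """
    n_spots = X.shape[0]
    counts = np.zeros((n_spots, k))
    sums = np.zeros((n_spots, k))
    sq = np.zeros((n_spots, k))
    for c in range(k):
        cols = X[:, cond_idx == c]
        obs = ~np.isnan(cols)
        counts[:, c] = obs.sum(axis=1)
        sums[:, c] = np.nansum(cols, axis=1)
        sq[:, c] = np.nansum(cols ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    n_obs = counts.sum(axis=1)
    grand = sums.sum(axis=1) / n_obs
    k_eff = (counts > 0).sum(axis=1)
    ssb = np.nansum(counts * (means - grand[:, None]) ** 2, axis=1)
    sst = sq.sum(axis=1) - n_obs * grand ** 2
    ssw = np.maximum(sst - ssb, 0.0)
    df_resid = n_obs - k_eff
    with np.errstate(invalid="ignore", divide="ignore"):
        msb = ssb / (k_eff - 1)
        s2 = ssw / df_resid
    return msb, s2, df_resid, k_eff


def fit_moderation_prior(s2: np.ndarray, df: np.ndarray) -> ModerationPrior:
    """Estimate (d0, s0_sq) by moment matching of log residual variances to a
    scaled F distribution, using the digamma/trigamma closed forms."""
    ok = np.isfinite(s2) & (s2 > 0) & (df >= 1)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    n = e.size
    target = np.mean((e - e_bar) ** 2 * n / (n - 1) - polygamma(1, df / 2.0))
    if target <= 0:
        return ModerationPrior(d0=float("inf"), s0_sq=float(np.exp(e_bar)))
    half_d0 = _trigamma_inverse(target)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_bar + digamma(half_d0) - np.log(half_d0)))
    return ModerationPrior(d0=d0, s0_sq=s0_sq)


def posterior_variances(s2: np.ndarray, df: np.ndarray, prior: ModerationPrior) -> np.ndarray:
    """Shrink per-spot residual variances toward the prior:
    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)."""
    if np.isinf(prior.d0):
        return np.full_like(np.asarray(s2, dtype=float), prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)


def moderated_test(
    table: SpotTable, prior: ModerationPrior | None = None
) -> tuple[ModerationPrior, pd.DataFrame]:
    """Empirical-Bayes moderated one-way F test per spot.

    Spots with fewer than one residual degree of freedom are excluded with a
    warning.  An explicit ``prior`` overrides the moment-matching estimate
    (e.g. d0 = inf forces s2_post = s0_sq everywhere).
    """
    if not table.normalized:
        warnings.warn("moderated test on a non-normalized table")
    sheet = table.sheet
    cond_levels = [c for c in CONDITIONS if c in set(sheet.conditions)]
    cond_idx = np.array([cond_levels.index(c) for c in sheet.conditions])
    k = len(cond_levels)
    if k < 2:
        raise ValueError("need at least two conditions")
    msb, s2, df_resid, k_eff = _oneway_fit(table.matrix, cond_idx, k)

    usable = (df_resid >= 1) & (k_eff >= 2)
    if not usable.all():
        dropped = [s for s, u in zip(table.spot_ids, usable) if not u]
        warnings.warn(f"excluding spots without residual df: {dropped}")
    if prior is None:
        prior = fit_moderation_prior(s2[usable], df_resid[usable])
    s2_post = posterior_variances(s2, df_resid, prior)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = msb / s2_post
    df2 = df_resid + prior.d0
    p = np.full(len(F), np.nan)
    finite = usable & np.isfinite(df2)
    if finite.any():
        p[finite] = stats.f.sf(F[finite], k_eff[finite] - 1, df2[finite])
    at_inf = usable & np.isinf(df2)
    if at_inf.any():
        p[at_inf] = stats.chi2.sf(F[at_inf] * (k_eff[at_inf] - 1), k_eff[at_inf] - 1)
    result = pd.DataFrame(
        {
            "spot_id": table.spot_ids,
            "statistic": F,
            "p_raw": p,
            "s2": s2,
            "s2_post": s2_post,
            "df_resid": df_resid,
            "method": "moderated",
        }
    )[usable]
    return prior, result.reset_index(drop=True)


def differential_tests(
    table: SpotTable,
    method: str = "moderated",
    adjustment: str = "BH",
    random_factor: str = "replicate",
) -> pd.DataFrame:
    """Run one of the three per-spot tests over a table and adjust p-values.

    Returns a frame with spot_id, statistic, p_raw, p_adj, method,
    adjustment and flag columns, in the input spot order.
    """
    sheet = table.sheet
    conditions = sheet.conditions
    cond_levels = [c for c in CONDITIONS if c in set(conditions)]
    if method == "moderated":
        _, res = moderated_test(table)
        frame = res[["spot_id", "statistic", "p_raw"]].copy()
        flags = [""] * len(frame)
    elif method in ("kruskal", "mixed"):
        rows, flags = [], []
        rf = sheet.frame[random_factor].to_numpy()
        for i, spot in enumerate(table.spot_ids):
            y = table.matrix[i]
            if method == "kruskal":
                groups = [y[conditions == c] for c in cond_levels]
                stat, p, flag = kruskal_test(groups)
            else:
                stat, p, _, flag = mixed_model_test(y, conditions, rf)
            rows.append((spot, stat, p))
            flags.append(flag)
        frame = pd.DataFrame(rows, columns=["spot_id", "statistic", "p_raw"])
    else:
        raise ValueError(f"unknown method {method!r}")
    frame["p_adj"] = adjust_pvalues(frame["p_raw"].to_numpy(), adjustment)
    frame["method"] = method
    frame["adjustment"] = "BH" if ADJUSTMENT_ALIASES[adjustment] == "fdr_bh" else "Holm"
    frame["flag"] = flags
    return frame


# ---------------------------------------------------------------------------
# adjustment / selection / over-representation
# ---------------------------------------------------------------------------

def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Holm step-down adjusted p-values,
    monotone and capped at 1.  "FDR" is accepted as an alias of BH."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = ADJUSTMENT_ALIASES.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment {method!r}; use BH or Holm")
    return multipletests(p, method=key)[1]


def select_significant(results: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Spot ids with adjusted p below alpha, ordered by (p_adj, spot_id)."""
    if "p_adj" not in results:
        raise ValueError("results must carry adjusted p-values")
    hits = results[results["p_adj"] < alpha]
    hits = hits.sort_values(["p_adj", "spot_id"], kind="mergesort")
    return hits["spot_id"].tolist()


def overrepresentation_test(hits: set, category_members: set, universe: set) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test of category over-representation
    among hits, within a finite universe.  Returns (odds ratio, p)."""
    hits, category_members, universe = set(hits), set(category_members), set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not category_members <= universe:
        raise ValueError("hits and category members must be subsets of the universe")
    a = len(hits & category_members)
    b = len(hits - category_members)
    c = len(category_members - hits)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)
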