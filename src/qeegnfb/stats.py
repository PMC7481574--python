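"""Predictor, moderator and mediator statistics.

The repeated-measures machinery follows the classical univariate
split-plot formulation: the within-subject measures are transformed by an
orthonormal contrast basis, each within-stratum effect is tested as an
averaged (trace) F over the transformed variates, and sphericity is
handled with the Greenhouse-Geisser ε estimated from the within-error
covariance, multiplying both degrees of freedom when the factor has more
than two levels. Between-subject screens are Type-III least-squares
factorials with effect (sum-to-zero) coding. The single-predictor
discriminant surface reports Wilks' Λ = SS_within / SS_total with
Bartlett's χ² approximation, alongside the Mann-Whitney estimator of the
ROC area.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .outcomes import StatResult

__all__ = [
    "rm_anova",
    "glm_screen",
    "lda_wilks",
    "roc_auc",
    "correlate",
    "moderation_regression",
    "mann_whitney",
    "mediation_screen",
    "bh_adjust",
    "log_scores",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (off by default everywhere;
    the screens report unadjusted p-values unless the user asks)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def log_scores(x, offset: float = 1.0) -> np.ndarray:
    """Natural-log transform for right-skewed questionnaire scores (e.g.
    sleep-related breathing complaints); the +1 offset handles zeros."""
    x = np.asarray(x, float)
    if np.any(x + offset <= 0):
        raise ValueError("scores must exceed -offset for the log transform")
    return np.log(x + offset)


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------

def _effect_code(values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (effect) coding; last level is the reference."""
    levels = sorted(pd.unique(values.astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {values.name!r} has fewer than 2 levels")
    cols = []
    for lev in levels[:-1]:
        c = np.where(values.astype(str) == lev, 1.0, 0.0)
        c[values.astype(str) == levels[-1]] = -1.0
        cols.append(c)
    names = [f"{values.name}[{lev}]" for lev in levels[:-1]]
    return np.column_stack(cols), names


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.column_stack([a[:, i] * b[:, j]
                            for i in range(a.shape[1]) for j in range(b.shape[1])])


def _ss_res(y: np.ndarray, x: np.ndarray) -> float:
    if x.size == 0:
        return float(np.sum(y**2))
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(np.sum(r**2))


def _type3_table(y: np.ndarray, terms: dict[str, np.ndarray]) -> pd.DataFrame:
    """Type-III F table by full-vs-reduced model comparison (effect coding)."""
    x_full = np.column_stack(list(terms.values()))
    n = y.size
    df_res = n - np.linalg.matrix_rank(x_full)
    ss_full = _ss_res(y, x_full)
    rows = []
    for name, block in terms.items():
        if name == "Intercept":
            continue
        others = [b for k, b in terms.items() if k != name]
        x_red = np.column_stack(others)
        ss_term = _ss_res(y, x_red) - ss_full
        df_term = np.linalg.matrix_rank(x_full) - np.linalg.matrix_rank(x_red)
        if df_term == 0 or df_res == 0:
            rows.append((name, 0.0, 0, df_res, 1.0))
            continue
        ms_res = ss_full / df_res
        f = (ss_term / df_term) / ms_res if ms_res > 0 else 0.0
        p = float(spstats.f.sf(f, df_term, df_res)) if f > 0 else 1.0
        rows.append((name, float(f), int(df_term), int(df_res), p))
    return pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis orthogonal to the unit vector."""
    c = np.eye(k) - np.ones((k, k)) / k
    u, s, _ = np.linalg.svd(c)
    return u[:, : k - 1]


def gg_epsilon(sigma: np.ndarray) -> float:
    """Greenhouse-Geisser ε from a (k−1)x(k−1) contrast-space covariance."""
    ev = np.linalg.eigvalsh(sigma)
    num = ev.sum() ** 2
    den = sigma.shape[0] * np.sum(ev**2)
    return float(num / den) if den > 0 else 1.0


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str | list[str] | None = None,
    covariate: str | None = None,
    correction: bool = True,
) -> pd.DataFrame:
    """Univariate repeated-measures (split-plot) ANOVA with GG correction.

    ``data`` is long-format. One within factor; multiple between factors
    are combined into their cartesian cells for the split-plot strata
    (the factorial between-subject screens live in :func:`glm_screen`).
    Returns a table with a row per effect: the within main effect,
    within x between and within x covariate interactions (within
    stratum, GG-corrected dfs when the factor has more than two levels),
    and the between/covariate effects tested on subject means.
    """
    wide = data.pivot_table(index=subject, columns=within, values=dv)
    if wide.isna().any().any():
        n0 = wide.shape[0]
        wide = wide.dropna()
        warnings.warn(f"dropped {n0 - wide.shape[0]} subjects with incomplete cases")
    k = wide.shape[1]
    if k < 2:
        raise ValueError("need at least two within-factor levels")
    subj_info = (
        data.drop_duplicates(subject).set_index(subject).loc[wide.index]
    )
    n = wide.shape[0]
    y = wide.to_numpy()

    terms: dict[str, np.ndarray] = {"Intercept": np.ones((n, 1))}
    between_name = None
    if between is not None:
        bl = [between] if isinstance(between, str) else list(between)
        combined = subj_info[bl].astype(str).agg("|".join, axis=1)
        combined.name = "+".join(bl)
        counts = combined.value_counts()
        if (counts < 2).any():
            warnings.warn(
                f"between cells with < 2 subjects dropped from design: "
                f"{list(counts[counts < 2].index)}"
            )
            keep = combined.isin(counts[counts >= 2].index)
            y, combined = y[keep.to_numpy()], combined[keep]
            subj_info = subj_info[keep]
            n = y.shape[0]
            terms["Intercept"] = np.ones((n, 1))
        if combined.nunique() >= 2:
            block, _ = _effect_code(combined)
            between_name = combined.name
            terms[between_name] = block
        else:
            warnings.warn("between factor has a single cell; term dropped")
    cov_name = None
    if covariate is not None:
        cvals = subj_info[covariate].astype(float).to_numpy()
        if np.std(cvals) == 0:
            warnings.warn(f"covariate {covariate!r} is constant; dropped")
        else:
            terms[covariate] = (cvals - cvals.mean())[:, None]
            cov_name = covariate

    x = np.column_stack(list(terms.values()))
    contr = _orthonormal_contrasts(k)
    z = y @ contr  # n x (k-1): within stratum
    m = y.mean(axis=1)  # subject means: between stratum

    xtx_inv = np.linalg.pinv(x.T @ x)
    b = xtx_inv @ x.T @ z
    e = z.T @ z - b.T @ (x.T @ x) @ b  # within-error SSCP
    df_e = n - np.linalg.matrix_rank(x)
    sigma = e / df_e
    eps = gg_epsilon(sigma) if k > 2 else 1.0
    lo = 1.0 / (k - 1)
    eps = min(1.0, max(eps, lo))

    # column offsets of each term in x
    offs, pos = {}, 0
    for name, blockv in terms.items():
        offs[name] = list(range(pos, pos + blockv.shape[1]))
        pos += blockv.shape[1]

    rows = []

    def within_test(term: str, label: str) -> None:
        idx = offs[term]
        l_mat = np.zeros((len(idx), x.shape[1]))
        for r, c in enumerate(idx):
            l_mat[r, c] = 1.0
        lb = l_mat @ b
        mid = np.linalg.pinv(l_mat @ xtx_inv @ l_mat.T)
        h = lb.T @ mid @ lb
        df_h = len(idx)
        df1, df2 = df_h * (k - 1), df_e * (k - 1)
        ms_h = np.trace(h) / df1
        ms_e = np.trace(e) / df2
        # guard against pure roundoff when within columns are identical:
        # compare against the raw data scale, not the contrast-space scale
        tiny = 1e-20 * (np.mean(y**2) + 1.0)
        if ms_e <= tiny:
            f = 0.0 if ms_h <= tiny else float("inf")
        else:
            f = ms_h / ms_e
        use_eps = eps if (correction and k > 2) else 1.0
        d1, d2 = df1 * use_eps, df2 * use_eps
        p = float(spstats.f.sf(f, d1, d2)) if f > 0 else 1.0
        rows.append(
            dict(effect=label, F=float(f), df1=float(d1), df2=float(d2), p=p,
                 eps_gg=float(eps) if k > 2 else 1.0,
                 p_uncorrected=float(spstats.f.sf(f, df1, df2)) if f > 0 else 1.0)
        )

    within_test("Intercept", within)
    if between_name:
        within_test(between_name, f"{within}:{between_name}")
    if cov_name:
        within_test(cov_name, f"{within}:{cov_name}")

    # between stratum: subject means against the same design
    btab = _type3_table(m * np.sqrt(k), terms)  # scaling cancels in F
    for _, r in btab.iterrows():
        rows.append(
            dict(effect=r["effect"], F=r["F"], df1=float(r["df1"]),
                 df2=float(r["df2"]), p=r["p"], eps_gg=np.nan,
                 p_uncorrected=r["p"])
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GLM screen (between-subject factorial with covariate)
# ---------------------------------------------------------------------------

def glm_screen(
    frame: pd.DataFrame,
    predictor: str,
    covariate: str | None = "age",
    factors: tuple[str, ...] = ("protocol", "sex"),
    group: str = "remission",
) -> pd.DataFrame:
    """Covariate-adjusted factorial screen of one candidate predictor.

    Fits predictor ~ covariate + full factorial(group, factors) by
    Type-III least squares with effect coding and reports the F tests
    for every term involving ``group`` (the remission main effect and
    its interactions).
    """
    cols = [predictor, group, *factors] + ([covariate] if covariate else [])
    d = frame.dropna(subset=[c for c in cols if c in frame.columns])
    y = d[predictor].astype(float).to_numpy()
    n = y.size
    if n < 3:
        raise ValueError("too few complete cases")
    constant_y = np.std(y) == 0
    if constant_y:
        warnings.warn("constant predictor; all F set to 0")
    terms: dict[str, np.ndarray] = {"Intercept": np.ones((n, 1))}
    if covariate is not None:
        cv = d[covariate].astype(float).to_numpy()
        if np.std(cv) == 0:
            warnings.warn(f"covariate {covariate!r} is constant; dropped")
        else:
            terms[covariate] = (cv - cv.mean())[:, None]
    blocks: dict[str, np.ndarray] = {}
    fnames = []
    for f in (group, *factors):
        s = d[f]
        s.name = f
        if s.astype(str).nunique() < 2:
            warnings.warn(f"factor {f!r} has one level; dropped")
            continue
        blocks[f], _ = _effect_code(s)
        fnames.append(f)
    if group not in blocks:
        raise ValueError(f"grouping factor {group!r} has a single level")
    for f in fnames:
        terms[f] = blocks[f]
    for r in range(2, len(fnames) + 1):
        for combo in itertools.combinations(fnames, r):
            blk = blocks[combo[0]]
            for f in combo[1:]:
                blk = _interaction(blk, blocks[f])
            terms[":".join(combo)] = blk
    tab = _type3_table(y, terms)
    if constant_y:
        tab["F"] = 0.0
        tab["p"] = 1.0
    keep = tab["effect"].str.split(":").apply(lambda parts: group in parts)
    return tab[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# discriminant / ROC / rank statistics
# ---------------------------------------------------------------------------

def lda_wilks(scores: np.ndarray, labels: np.ndarray) -> StatResult:
    """Single-predictor discriminant test: Wilks' Λ with Bartlett's χ².

    Λ = SS_within / SS_total; χ² = −(n − 1 − (p + g)/2)·ln Λ with one
    predictor (p = 1) and g groups, df = p·(g − 1).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    groups = [scores[labels == g] for g in np.unique(labels)]
    g = len(groups)
    if g < 2 or any(gr.size < 2 for gr in groups):
        raise ValueError("need at least two groups with ≥ 2 observations each")
    n = scores.size
    ss_total = float(np.sum((scores - scores.mean()) ** 2))
    ss_within = float(sum(np.sum((gr - gr.mean()) ** 2) for gr in groups))
    if ss_total == 0:
        lam = 1.0
    else:
        lam = ss_within / ss_total
    df = 1 * (g - 1)
    if lam <= 0:
        chi2 = float("inf")
    else:
        chi2 = -(n - 1 - (1 + g) / 2.0) * np.log(lam)
    p = float(spstats.chi2.sf(chi2, df))
    return StatResult(statistic=float(lam), p=p, df=float(df),
                      name="wilks_lambda", extra={"chi2": float(chi2), "n": n})


def roc_auc(scores: np.ndarray, labels: np.ndarray, orient: bool = False):
    """Mann-Whitney estimator of the ROC area.

    Probability that a random positive outranks a random negative, ties
    counted 1/2. With ``orient=True`` returns a StatResult whose value is
    max(AUC, 1 − AUC) with the direction noted.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = spstats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    if not orient:
        return auc
    direction = "positive" if auc >= 0.5 else "negative"
    return StatResult(statistic=max(auc, 1 - auc), p=float("nan"),
                      name="auc", extra={"direction": direction, "auc_raw": auc})


def mann_whitney(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Mann-Whitney U (pairs with x > y, ties 1/2) with tie-corrected
    normal approximation, two-sided, no continuity correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    allv = np.concatenate([x, y])
    ranks = spstats.rankdata(allv)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, t_counts = np.unique(allv, return_counts=True)
    tie_term = np.sum(t_counts**3 - t_counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (u1 - mu) / np.sqrt(var)
        p = 2 * float(spstats.norm.sf(abs(z)))
    return StatResult(statistic=float(u1), p=min(1.0, p), name="mann_whitney",
                      extra={"Z": float(z), "n1": n1, "n2": n2})


# ---------------------------------------------------------------------------
# correlations / moderation / mediation
# ---------------------------------------------------------------------------

def _pearson_with_df(x: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if df <= 0:
        return r, float("nan")
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    return r, 2 * float(spstats.t.sf(abs(t), df))


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    control: np.ndarray | None = None,
) -> StatResult:
    """Pearson/Spearman correlation, optionally partial given controls.

    Spearman is Pearson on average ranks; partial correlations are the
    correlation of least-squares residuals after regressing both
    variables on the controls (rank-transformed first for Spearman),
    with df = n − 2 − (number of controls).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = None
    if control is not None:
        z = np.asarray(control, float)
        if z.ndim == 1:
            z = z[:, None]
    mask = np.isfinite(x) & np.isfinite(y)
    if z is not None:
        mask &= np.isfinite(z).all(axis=1)
    x, y = x[mask], y[mask]
    z = z[mask] if z is not None else None
    n = x.size
    k = 0 if z is None else z.shape[1]
    if n < 4 + (1 if k else 0):
        raise ValueError("too few observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance variable; correlation undefined")
        return StatResult(float("nan"), float("nan"), df=float(n - 2 - k),
                          name=method, extra={"r2": float("nan"), "n": n})
    if method == "spearman":
        x, y = spstats.rankdata(x), spstats.rankdata(y)
        if z is not None:
            z = np.column_stack([spstats.rankdata(z[:, j]) for j in range(k)])
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    if z is not None:
        design = np.column_stack([np.ones(n), z])
        bx, *_ = np.linalg.lstsq(design, x, rcond=None)
        by, *_ = np.linalg.lstsq(design, y, rcond=None)
        x = x - design @ bx
        y = y - design @ by
    df = n - 2 - k
    r, p = _pearson_with_df(x, y, df)
    return StatResult(statistic=r, p=p, df=float(df), name=method,
                      extra={"r2": r**2 if np.isfinite(r) else float("nan"), "n": n})


def moderation_regression(outcome, a, b) -> StatResult:
    """Interaction test: outcome on centered a, b and their product."""
    yv = np.asarray(outcome, float)
    av = np.asarray(a, float)
    bv = np.asarray(b, float)
    if np.std(av) == 0 or np.std(bv) == 0:
        raise ValueError("moderator variables must be non-constant")
    av = av - av.mean()
    bv = bv - bv.mean()
    x = np.column_stack([np.ones_like(av), av, bv, av * bv])
    rank = np.linalg.matrix_rank(x)
    if rank < 4:
        warnings.warn("interaction collinear with main effects")
        return StatResult(float("nan"), float("nan"), name="moderation",
                          extra={"collinear": True})
    beta, *_ = np.linalg.lstsq(x, yv, rcond=None)
    resid = yv - x @ beta
    n = yv.size
    df = n - 4
    mse = resid @ resid / df
    cov = mse * np.linalg.inv(x.T @ x)
    se = np.sqrt(cov[3, 3])
    t = beta[3] / se if se > 0 else 0.0
    p = 2 * float(spstats.t.sf(abs(t), df))
    return StatResult(statistic=float(t), p=p, df=float(df), name="moderation",
                      extra={"coef": float(beta[3]), "se": float(se)})


def mediation_screen(
    x: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    method: str = "pearson",
) -> dict:
    """Three-criterion (Baron–Kenny style) mediation screen.

    1. x must relate to the mediator m; 2. m must relate to y; 3. a
    previously significant x–y association must vanish when m is
    controlled for. The verdict is "mediation" only when all hold
    (including an initially significant x–y path).
    """
    r_xm = correlate(x, m, method)
    r_my = correlate(m, y, method)
    r_xy = correlate(x, y, method)
    r_xy_m = correlate(x, y, method, control=m)
    c1 = bool(r_xm.p < alpha)
    c2 = bool(r_my.p < alpha)
    xy_sig = bool(r_xy.p < alpha)
    c3 = bool(xy_sig and not (r_xy_m.p < alpha))
    verdict = "mediation" if (c1 and c2 and c3) else "no mediation"
    return {
        "criterion_1_x_affects_m": c1,
        "criterion_2_m_affects_y": c2,
        "xy_initially_significant": xy_sig,
        "criterion_3_xy_vanishes_controlled": c3,
        "verdict": verdict,
        "stats": {"xm": r_xm, "my": r_my, "xy": r_xy, "xy_given_m": r_xy_m},
    }
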