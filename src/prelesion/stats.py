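"""Longitudinal contrast table and weighted nested mixed-effects model.

The model for one channel/contrast is

    y_ijt = x_ijt' beta + b_i + b_ij + e_ijt

with a random patient effect ``b_i ~ N(0, sigma_p^2)``, a random lesion
effect nested in patient ``b_ij ~ N(0, sigma_l^2)``, and AR(1)-correlated
residuals over ordered visits within a lesion,
``Corr(e_ijt, e_ijt') = rho^|t - t'|`` with ``Var(e_ijt) = sigma^2 / w_i``
where ``w_i`` is the patient weight (inverse of the patient's lesion
count).  Estimation is by profiled REML over the variance ratios and the
AR(1) coefficient with a quasi-Newton search; least-square means are
reported per time level with multiplicity-adjusted tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats as sps
from statsmodels.stats.multitest import multipletests

from .rois import ROIPair

log = logging.getLogger(__name__)

CONTRASTS = ("pre_vs_overall", "pre_vs_contra", "contra_vs_overall")
NORM_CHANNELS = ("nmtr", "nt1", "nt2")


# ---------------------------------------------------------------------------
# sample table


@dataclass
class SubjectAnalysis:
    """Everything needed from one subject to emit contrast rows."""

    subject_id: str
    weeks: tuple[int, ...]
    events: list  # LesionEvent, aligned with ``pairs`` by lesion_id
    pairs: list[ROIPair]
    overall_nawm: np.ndarray
    normalized: dict[str, list[np.ndarray]]  # channel -> volume per visit
    covariates: dict = dc_field(default_factory=dict)
    voxel_volume_mm3: float = 1.0


def build_sample_table(
    analyses: list[SubjectAnalysis], exclude_final_interval: bool = True
) -> pd.DataFrame:
    """Long-format per-lesion contrast rows.

    One row per lesion x pre-onset visit x contrast x channel, holding the
    difference of ROI mean normalized intensities.  Each patient's rows
    carry weight ``1 / n_accepted_lesions(patient)``.  For monthly
    schedules the visit immediately preceding the onset interval is
    excluded via ``exclude_final_interval``.
    """
    rows = []
    for an in analyses:
        events = {ev.lesion_id: ev for ev in an.events}
        accepted = [p for p in an.pairs if p.accepted]
        if not accepted:
            continue
        if not an.overall_nawm.any():
            log.warning(
                "subject %s has empty overall NAWM; omitted", an.subject_id
            )
            continue
        weight = 1.0 / len(accepted)
        for pair in accepted:
            event = events[pair.lesion_id]
            pre_weeks = [w for w in an.weeks if w < event.first_seen_week]
            if exclude_final_interval and pre_weeks:
                pre_weeks = pre_weeks[:-1]
            if not pre_weeks:
                log.info(
                    "lesion %s/%s has no analysable pre-onset visits; "
                    "omitted",
                    an.subject_id,
                    pair.lesion_id,
                )
                continue
            residual_volume = (
                float(event.residual_mask.sum()) * an.voxel_volume_mm3
            )
            for week in pre_weeks:
                ti = an.weeks.index(week)
                for channel, volumes in an.normalized.items():
                    vol = volumes[ti]
                    mp = float(vol[pair.prelesion_mask].mean())
                    mc = float(vol[pair.contralateral_mask].mean())
                    mo = float(vol[an.overall_nawm].mean())
                    values = {
                        "pre_vs_overall": mp - mo,
                        "pre_vs_contra": mp - mc,
                        "contra_vs_overall": mc - mo,
                    }
                    for contrast, value in values.items():
                        rows.append(
                            {
                                "subject_id": an.subject_id,
                                "lesion_id": pair.lesion_id,
                                "week": week,
                                "weeks_before_onset": week
                                - event.first_seen_week,
                                "channel": channel,
                                "contrast": contrast,
                                "value": value,
                                "weight": weight,
                                "residual_volume": residual_volume,
                                **an.covariates,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design construction


@dataclass
class DesignInfo:
    time_levels: tuple
    columns: tuple[str, ...]
    lsmean_fill: dict[str, float]


def _build_design(
    df: pd.DataFrame,
    covariates: tuple[str, ...],
    time_col: str,
    weight_col: str,
) -> tuple[np.ndarray, DesignInfo]:
    """Design matrix: one dummy per time level (no intercept) plus
    covariate columns.

    Continuous covariates enter as-is, categorical covariates as
    drop-first dummies, and ``a:b`` denotes an interaction.  The
    ``lsmean_fill`` values reproduce the least-square-means convention:
    continuous covariates at their weighted sample mean, categorical
    covariates averaged equally over levels.
    """
    w = df[weight_col].to_numpy(dtype=float)
    cols: list[np.ndarray] = []
    names: list[str] = []
    fill: dict[str, float] = {}

    time_levels = tuple(sorted(df[time_col].unique()))
    for lvl in time_levels:
        cols.append((df[time_col] == lvl).to_numpy(dtype=float))
        names.append(f"{time_col}[{lvl}]")

    def term_column(name: str) -> list[tuple[str, np.ndarray, float]]:
        series = df[name]
        if pd.api.types.is_numeric_dtype(series):
            x = series.to_numpy(dtype=float)
            return [(name, x, float(np.average(x, weights=w)))]
        levels = sorted(series.astype(str).unique())
        out = []
        for lvl in levels[1:]:  # drop-first coding
            x = (series.astype(str) == lvl).to_numpy(dtype=float)
            out.append((f"{name}[{lvl}]", x, 1.0 / len(levels)))
        return out

    for cov in covariates:
        if ":" in cov:
            a, b = cov.split(":", 1)
            for na, xa, fa in term_column(a):
                for nb, xb, fb in term_column(b):
                    cols.append(xa * xb)
                    names.append(f"{na}:{nb}")
                    fill[f"{na}:{nb}"] = fa * fb
        else:
            for name, x, f in term_column(cov):
                cols.append(x)
                names.append(name)
                fill[name] = f

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [
            names[j]
            for j in range(X.shape[1])
            if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))
        ]
        raise ValueError(f"singular design; collinear columns: {bad}")
    return X, DesignInfo(
        time_levels=time_levels, columns=tuple(names), lsmean_fill=fill
    )


# ---------------------------------------------------------------------------
# REML machinery


@dataclass
class _Blocks:
    """Row bookkeeping: rows grouped by patient, lesions within patient."""

    patient_rows: list[np.ndarray]  # row indices per patient
    lesion_sizes: list[list[int]]  # visits per lesion, per patient
    lags: list[np.ndarray]  # per patient: within-lesion visit positions
    weights: np.ndarray  # one weight per patient


def _make_blocks(
    df: pd.DataFrame,
    subject_col: str,
    lesion_col: str,
    week_col: str,
    weight_col: str,
    use_week_distance: bool,
) -> tuple[pd.DataFrame, _Blocks]:
    df = df.sort_values([subject_col, lesion_col, week_col]).reset_index(
        drop=True
    )
    patient_rows, lesion_sizes, lags, weights = [], [], [], []
    for _, pdf in df.groupby(subject_col, sort=True):
        patient_rows.append(pdf.index.to_numpy())
        sizes, lag = [], []
        for _, ldf in pdf.groupby(lesion_col, sort=True):
            sizes.append(len(ldf))
            if use_week_distance:
                weeks = ldf[week_col].to_numpy(dtype=float)
                gaps = np.diff(weeks)
                step = gaps.min() if gaps.size else 1.0
                lag.extend((weeks - weeks[0]) / step)
            else:
                lag.extend(range(len(ldf)))
        lesion_sizes.append(sizes)
        lags.append(np.asarray(lag, dtype=float))
        wvals = pdf[weight_col].unique()
        if len(wvals) != 1:
            raise ValueError(
                f"weight must be constant within patient; got {wvals}"
            )
        weights.append(float(wvals[0]))
    return df, _Blocks(patient_rows, lesion_sizes, lags, np.asarray(weights))


def _patient_w_matrix(
    sizes: list[int], lag: np.ndarray, w: float, gamma_p: float,
    gamma_l: float, rho: float
) -> np.ndarray:
    """Scaled covariance W_i with Var(y_i) = sigma^2 * W_i."""
    n = sum(sizes)
    W = np.full((n, n), gamma_p)
    pos = 0
    for size in sizes:
        sl = slice(pos, pos + size)
        t = lag[pos : pos + size]
        R = rho ** np.abs(t[:, None] - t[None, :])
        W[sl, sl] += gamma_l + R / w
        pos += size
    return W


def _reml_pieces(
    y: np.ndarray,
    X: np.ndarray,
    blocks: _Blocks,
    gamma_p: float,
    gamma_l: float,
    rho: float,
):
    """Accumulate GLS quantities patient-block by patient-block."""
    p = X.shape[1]
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    ytWy = 0.0
    logdet_w = 0.0
    for rows, sizes, lag, w in zip(
        blocks.patient_rows, blocks.lesion_sizes, blocks.lags, blocks.weights
    ):
        W = _patient_w_matrix(sizes, lag, w, gamma_p, gamma_l, rho)
        c, low = linalg.cho_factor(W, lower=True, check_finite=False)
        logdet_w += 2.0 * float(np.log(np.diag(c)).sum())
        Xi = X[rows]
        yi = y[rows]
        WX = linalg.cho_solve((c, low), Xi, check_finite=False)
        Wy = linalg.cho_solve((c, low), yi, check_finite=False)
        XtWX += Xi.T @ WX
        XtWy += Xi.T @ Wy
        ytWy += float(yi @ Wy)
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(beta @ XtWy)
    sign, logdet_xtwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'W^-1X not positive definite")
    return beta, rss, logdet_w, logdet_xtwx, XtWX


def reml_loglik(
    y: np.ndarray,
    X: np.ndarray,
    blocks: _Blocks,
    sigma_p2: float,
    sigma_l2: float,
    sigma2: float,
    rho: float,
) -> float:
    """Restricted log-likelihood at explicit variance parameters.

    Matches the closed-form restricted likelihood of the multivariate
    normal with covariance built numerically (used as a brute-force
    oracle in the tests).
    """
    n, p = X.shape
    _, rss, logdet_w, logdet_xtwx, _ = _reml_pieces(
        y, X, blocks, sigma_p2 / sigma2, sigma_l2 / sigma2, rho
    )
    return -0.5 * (
        (n - p) * np.log(2.0 * np.pi)
        + (n - p) * np.log(sigma2)
        + logdet_w
        + logdet_xtwx
        + rss / sigma2
    )


@dataclass
class MixedModelResult:
    beta: np.ndarray
    bse: np.ndarray
    cov_beta: np.ndarray
    sigma_p2: float
    sigma_l2: float
    sigma2: float
    rho: float
    loglik: float
    nobs: int
    design: DesignInfo
    converged: bool = True

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=list(self.design.columns))

    def residual_correlation(self, n_visits: int) -> np.ndarray:
        """Fitted within-lesion residual correlation over visit ranks."""
        t = np.arange(n_visits)
        return self.rho ** np.abs(t[:, None] - t[None, :])


def fit_weighted_lmm(
    df: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    time_col: str = "weeks_before_onset",
    value_col: str = "value",
    weight_col: str = "weight",
    subject_col: str = "subject_id",
    lesion_col: str = "lesion_id",
    week_col: str = "week",
    use_week_distance: bool = False,
) -> MixedModelResult:
    """Fit the patient-weighted nested mixed-effects model by REML.

    ``df`` must hold one channel/contrast combination.  Deterministic
    given the data (quasi-Newton search from a fixed start).
    """
    if df[time_col].nunique() < 2:
        raise ValueError("need at least 2 time levels")
    if df[subject_col].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    df, blocks = _make_blocks(
        df, subject_col, lesion_col, week_col, weight_col, use_week_distance
    )
    X, design = _build_design(df, tuple(covariates), time_col, weight_col)
    y = df[value_col].to_numpy(dtype=float)
    n, p = X.shape

    def negdev(theta: np.ndarray) -> float:
        gamma_p, gamma_l = np.exp(theta[0]), np.exp(theta[1])
        rho = np.tanh(theta[2])
        try:
            _, rss, logdet_w, logdet_xtwx, _ = _reml_pieces(
                y, X, blocks, gamma_p, gamma_l, rho
            )
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return 1e12
        if rss <= 0:
            return 1e12
        return (
            (n - p) * np.log(rss / (n - p)) + logdet_w + logdet_xtwx
        )

    res = optimize.minimize(
        negdev,
        x0=np.array([np.log(0.5), np.log(0.5), np.arctanh(0.2)]),
        method="L-BFGS-B",
        bounds=[(-15.0, 10.0), (-15.0, 10.0), (-5.0, 5.0)],
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"REML optimization failed: {res.message}")
    gamma_p, gamma_l = np.exp(res.x[0]), np.exp(res.x[1])
    rho = float(np.tanh(res.x[2]))
    beta, rss, logdet_w, logdet_xtwx, XtWX = _reml_pieces(
        y, X, blocks, gamma_p, gamma_l, rho
    )
    # noiseless degenerate fits can push rss to (numerically) zero
    sigma2 = max(rss, np.finfo(float).tiny * n) / (n - p)
    try:
        cf = linalg.cho_factor(XtWX, check_finite=False)
        inv_xtwx = linalg.cho_solve(cf, np.eye(p), check_finite=False)
    except np.linalg.LinAlgError:
        inv_xtwx = np.linalg.pinv(XtWX)
    cov_beta = sigma2 * inv_xtwx
    loglik = reml_loglik(
        y, X, blocks, gamma_p * sigma2, gamma_l * sigma2, sigma2, rho
    )
    return MixedModelResult(
        beta=beta,
        bse=np.sqrt(np.clip(np.diag(cov_beta), 0.0, None)),
        cov_beta=cov_beta,
        sigma_p2=float(gamma_p * sigma2),
        sigma_l2=float(gamma_l * sigma2),
        sigma2=float(sigma2),
        rho=rho,
        loglik=float(loglik),
        nobs=n,
        design=design,
        converged=bool(res.success),
    )


def ls_means(
    result: MixedModelResult,
    time_levels: tuple | None = None,
    adjust: str = "holm",
    time_col: str = "weeks_before_onset",
) -> pd.DataFrame:
    """Least-square means per time level, tested against zero.

    Continuous covariates sit at their weighted sample means and
    categorical covariates are averaged equally over levels; p-values are
    multiplicity-adjusted across time levels.
    """
    design = result.design
    levels = design.time_levels if time_levels is None else tuple(time_levels)
    missing = [lvl for lvl in levels if lvl not in design.time_levels]
    if missing:
        raise ValueError(f"requested time levels absent from fit: {missing}")
    rows = []
    for lvl in levels:
        x0 = np.zeros(len(design.columns))
        for j, name in enumerate(design.columns):
            if name == f"{time_col}[{lvl}]":
                x0[j] = 1.0
            elif name in design.lsmean_fill:
                x0[j] = design.lsmean_fill[name]
        est = float(x0 @ result.beta)
        se = float(np.sqrt(max(x0 @ result.cov_beta @ x0, 0.0)))
        z = est / se if se > 0 else np.inf
        pval = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {"level": lvl, "estimate": est, "se": se, "z": z, "p": pval}
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_multiplicity(out["p"].to_numpy(), method=adjust)
    return out


def adjust_multiplicity(
    pvalues: np.ndarray, method: str = "holm"
) -> np.ndarray:
    """Adjust p-values across the levels of a categorical test."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d array")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# model-based simulation (parameter-recovery and type-I oracles)


def simulate_lmm_data(
    n_subjects: int,
    time_effects: dict,
    mean_lesions: float = 2.0,
    sigma_p: float = 0.5,
    sigma_l: float = 0.3,
    sigma: float = 0.2,
    rho: float = 0.6,
    seed: int = 0,
    week_step: int = 4,
) -> pd.DataFrame:
    """Draw data exactly from the mixed-model family.

    ``time_effects`` maps weeks_before_onset level -> fixed-effect mean.
    Residuals are AR(1) within lesion with variance ``sigma^2 / w_i``
    where ``w_i = 1 / n_lesions_i``.
    """
    rng = np.random.default_rng(seed)
    levels = sorted(time_effects)
    t = np.arange(len(levels))
    R = rho ** np.abs(t[:, None] - t[None, :])
    chol = np.linalg.cholesky(R)
    rows = []
    for i in range(n_subjects):
        n_lesions = 1 + rng.poisson(max(mean_lesions - 1.0, 0.0))
        w = 1.0 / n_lesions
        b_i = sigma_p * rng.standard_normal()
        for j in range(n_lesions):
            b_ij = sigma_l * rng.standard_normal()
            eps = (sigma / np.sqrt(w)) * (chol @ rng.standard_normal(len(levels)))
            for k, lvl in enumerate(levels):
                rows.append(
                    {
                        "subject_id": f"s{i:03d}",
                        "lesion_id": f"s{i:03d}-l{j:02d}",
                        "week": int(lvl) + len(levels) * week_step,
                        "weeks_before_onset": lvl,
                        "value": time_effects[lvl] + b_i + b_ij + eps[k],
                        "weight": w,
                    }
                )
    return pd.DataFrame(rows)


def make_blocks_for_oracle(
    df: pd.DataFrame,
    subject_col: str = "subject_id",
    lesion_col: str = "lesion_id",
    week_col: str = "week",
    weight_col: str = "weight",
    use_week_distance: bool = False,
) -> tuple[pd.DataFrame, _Blocks]:
    """Expose row bookkeeping so tests can build the dense covariance."""
    return _make_blocks(
        df, subject_col, lesion_col, week_col, weight_col, use_week_distance
    )


def build_design_for_oracle(
    df: pd.DataFrame,
    covariates: tuple[str, ...] = (),
    time_col: str = "weeks_before_onset",
    weight_col: str = "weight",
) -> tuple[np.ndarray, DesignInfo]:
    return _build_design(df, covariates, time_col, weight_col)
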