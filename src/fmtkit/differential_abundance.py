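"""Bias-corrected linear modeling of log relative abundances (LinDA-style).

Compositional count data only identify relative, not absolute, abundances:
fitting a linear model to log proportions makes every per-taxon coefficient
absorb a common shift (the log change of the unobserved total). The method
implemented here fits, per taxon, a linear model of log(winsorized
proportion + pseudocount floor) on the phase indicator with a dog-level
random intercept for repeated measures, then estimates the shared
compositional bias as the mode of the per-taxon coefficients and subtracts
it. The test statistic is the bias-corrected coefficient over its standard
error, with Benjamini-Hochberg control of the false discovery rate across
taxa.

The random-intercept model is solved by profiled REML over the single
variance ratio lambda = sigma_b^2 / sigma_e^2 (exact GLS at each candidate
lambda via the grouped Woodbury identity). When the REML estimate of lambda
sits at the zero boundary the taxon is refit with dog fixed effects, which
is the documented degenerate-variance fallback; t-tests in both paths use
the fixed-effect residual degrees of freedom for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .feature_table import AsvTable, RelAbundTable, SampleMetadata


class DaError(ValueError):
    pass


@dataclass
class DaConfig:
    prevalence_cutoff: float = 0.30
    winsor_quantile: float = 0.97
    pseudocount: float = 0.5
    adjust: str = "bh"
    random_effect: str = "dog_id"

    def __post_init__(self) -> None:
        if not 0 < self.winsor_quantile <= 1:
            raise DaError("winsor_quantile must be in (0, 1]")
        if not 0 <= self.prevalence_cutoff <= 1:
            raise DaError("prevalence_cutoff must be in [0, 1]")
        if self.pseudocount <= 0:
            raise DaError("pseudocount must be positive")
        if self.adjust != "bh":
            raise DaError(f"unknown adjustment {self.adjust!r}")


@dataclass
class DaResult:
    taxon: str
    raw_coefficient: float
    corrected_coefficient: float
    standard_error: float
    p_value: float  # test of the bias-corrected coefficient
    adjusted_p: float = float("nan")
    raw_p_value: float = float("nan")  # test of the uncorrected coefficient
    model: str = "mixed"  # "mixed" or "fixed" (degenerate-variance fallback)
    n_samples: int = 0


def prevalence_filter(table: AsvTable, cutoff: float = 0.30) -> AsvTable:
    """Keep taxa present (count >= 1) in at least `cutoff` of samples."""
    if not 0 <= cutoff <= 1:
        raise DaError("cutoff must be in [0, 1]")
    n = table.n_samples
    if n == 0 or cutoff == 0:
        return table.select_asvs(list(table.asv_ids))
    prevalence = (table.counts >= 1).sum(axis=0) / n
    keep = [a for a in table.asv_ids if prevalence[a] >= cutoff]
    return table.select_asvs(keep)


def winsorize(rel: RelAbundTable, quantile: float = 0.97) -> RelAbundTable:
    """Cap each taxon's values at its empirical `quantile` (linear
    interpolation convention); no re-normalization afterward.
    """
    if not 0 < quantile <= 1:
        raise DaError("quantile must be in (0, 1]")
    props = rel.proportions.copy()
    caps = props.quantile(quantile, axis=0, interpolation="linear")
    capped = props.clip(upper=caps, axis=1)
    # rows may now sum below 1; return the raw frame without revalidation
    out = RelAbundTable.__new__(RelAbundTable)
    out.proportions = capped
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise DaError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Random-intercept linear model (profiled REML)
# ---------------------------------------------------------------------------

@dataclass
class _LmmFit:
    beta: np.ndarray
    se: np.ndarray
    lam: float  # sigma_b^2 / sigma_e^2
    sigma2: float


def _gls_pieces(y: np.ndarray, x: np.ndarray, group_slices: list[slice], lam: float):
    """X'V^-1 X, X'V^-1 y, y'V^-1 y and log|V| for V = I + lam * Z Z'.

    Per group of size m, V_g^-1 = I - (lam / (1 + lam m)) J.
    """
    p = x.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for sl in group_slices:
        xg = x[sl]
        yg = y[sl]
        m = xg.shape[0]
        w = lam / (1.0 + lam * m)
        xs = xg.sum(axis=0)
        ys = yg.sum()
        xtvx += xg.T @ xg - w * np.outer(xs, xs)
        xtvy += xg.T @ yg - w * xs * ys
        ytvy += yg @ yg - w * ys * ys
        logdet += np.log1p(lam * m)
    return xtvx, xtvy, ytvy, logdet


def _neg_reml(lam: float, y, x, group_slices) -> float:
    n, p = x.shape
    xtvx, xtvy, ytvy, logdet = _gls_pieces(y, x, group_slices, lam)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - xtvy @ beta
    rss = max(rss, 1e-300)
    sigma2 = rss / (n - p)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    return 0.5 * ((n - p) * np.log(sigma2) + logdet + logdet_xtvx)


def fit_random_intercept(
    y: np.ndarray, x: np.ndarray, groups: np.ndarray, lam_max: float = 1e4
) -> _LmmFit:
    """REML fit of y = X beta + b_group + e with one random intercept.

    Returns GLS estimates at the REML variance ratio; lam = 0 means the
    variance component hit the boundary (caller should fall back to fixed
    effects).
    """
    order = np.argsort(groups, kind="stable")
    y = np.asarray(y, dtype=float)[order]
    x = np.asarray(x, dtype=float)[order]
    g = np.asarray(groups)[order]
    boundaries = np.flatnonzero(np.r_[True, g[1:] != g[:-1], True])
    group_slices = [slice(boundaries[i], boundaries[i + 1]) for i in range(len(boundaries) - 1)]

    res = optimize.minimize_scalar(
        lambda t: _neg_reml(np.exp(t) - 1.0, y, x, group_slices),
        bounds=(np.log(1.0), np.log(1.0 + lam_max)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x) - 1.0)
    if _neg_reml(0.0, y, x, group_slices) <= res.fun + 1e-10:
        lam = 0.0  # boundary: no evidence of between-group variance
    n, p = x.shape
    xtvx, xtvy, ytvy, _ = _gls_pieces(y, x, group_slices, lam)
    beta = np.linalg.solve(xtvx, xtvy)
    sigma2 = max(ytvy - xtvy @ beta, 0.0) / (n - p)
    cov = sigma2 * np.linalg.inv(xtvx)
    return _LmmFit(beta=beta, se=np.sqrt(np.diag(cov)), lam=lam, sigma2=sigma2)


def _fit_fixed_effects(y: np.ndarray, phase: np.ndarray, groups: np.ndarray):
    """OLS of y on phase + dog dummies; returns (coef, se, resid_df)."""
    uniq, codes = np.unique(groups, return_inverse=True)
    n = len(y)
    dummies = np.zeros((n, len(uniq) - 1))
    for k in range(1, len(uniq)):
        dummies[codes == k, k - 1] = 1.0
    x = np.column_stack([np.ones(n), phase, dummies])
    df = n - x.shape[1]
    if df <= 0:
        raise DaError("not enough residual degrees of freedom for the fixed-effect fit")
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.pinv(x.T @ x)
    return float(beta[1]), float(np.sqrt(cov[1, 1])), df


def _mode_estimate(values: np.ndarray) -> float:
    """Kernel-density mode of the coefficient distribution (bias estimate);
    median fallback below 10 taxa."""
    if len(values) < 10 or np.ptp(values) < 1e-12:
        return float(np.median(values))
    kde = stats.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def fit_da(
    rel: RelAbundTable,
    metadata: SampleMetadata,
    config: DaConfig | None = None,
    contrast: str = "pre_vs_post",
    pre_visits: tuple[str, ...] = ("endoscopy",),
    post_visits: tuple[str, ...] = ("treatment", "post_treatment"),
) -> list[DaResult]:
    """Per-taxon bias-corrected phase effect with dog random intercepts.

    `rel` should already be prevalence-filtered and winsorized (the pipeline
    wires those steps); this function log-transforms with a pseudocount
    floor of pseudocount x (smallest positive proportion in the matrix),
    fits each taxon, estimates the compositional bias as the mode of the raw
    coefficients, and BH-adjusts the corrected-coefficient p-values.
    """
    if contrast != "pre_vs_post":
        raise DaError(f"unknown contrast {contrast!r}")
    config = config or DaConfig()

    meta = metadata.frame.set_index("sample_id")
    samples, phases, dogs = [], [], []
    for s in rel.sample_ids:
        if s not in meta.index:
            continue
        visit = meta.loc[s, "visit"]
        if visit in pre_visits:
            phase = 0.0
        elif visit in post_visits:
            phase = 1.0
        else:
            continue
        samples.append(s)
        phases.append(phase)
        dogs.append(meta.loc[s, "dog_id"])
    phases = np.asarray(phases)
    dogs = np.asarray(dogs)
    per_dog = pd.DataFrame({"dog": dogs, "phase": phases})
    ok = per_dog.groupby("dog")["phase"].agg(lambda v: (v == 0).any() and (v == 1).any())
    if not ok.all():
        bad = sorted(ok.index[~ok])
        raise DaError(f"dog(s) without both pre and post samples: {bad}")
    if len(ok) < 3:
        raise DaError("need at least 3 dogs for the contrast")

    props = rel.proportions.loc[samples]
    positive = props.to_numpy()[props.to_numpy() > 0]
    if positive.size == 0:
        raise DaError("all-zero relative abundance matrix")
    floor = config.pseudocount * float(positive.min())
    logged = np.log(props.to_numpy(dtype=float) + floor)

    x = np.column_stack([np.ones(len(samples)), phases])
    fits: list[tuple[str, float, float, int, str]] = []
    dropped: list[str] = []
    n_dogs = len(np.unique(dogs))
    df_fixed = len(samples) - n_dogs - 1
    for j, taxon in enumerate(rel.taxon_ids):
        y = logged[:, j]
        if np.ptp(y) < 1e-12:
            dropped.append(taxon)
            continue
        lmm = fit_random_intercept(y, x, dogs)
        if lmm.lam == 0.0 or not np.isfinite(lmm.se[1]) or lmm.se[1] <= 0:
            coef, se, df = _fit_fixed_effects(y, phases, dogs)
            model = "fixed"
        else:
            coef, se, df = float(lmm.beta[1]), float(lmm.se[1]), df_fixed
            model = "mixed"
        fits.append((taxon, coef, se, df, model))
    if dropped:
        warnings.warn(
            f"excluding zero-variance taxa from the fit: {dropped}", UserWarning, stacklevel=2
        )
    if len(fits) < 3:
        raise DaError("fewer than 3 taxa with variance: compositional bias not estimable")

    coefs = np.array([f[1] for f in fits])
    bias = _mode_estimate(coefs)
    results = []
    for (taxon, coef, se, df, model) in fits:
        corrected = coef - bias
        p_corr = 2.0 * stats.t.sf(abs(corrected / se), df)
        p_raw = 2.0 * stats.t.sf(abs(coef / se), df)
        results.append(
            DaResult(
                taxon=taxon,
                raw_coefficient=coef,
                corrected_coefficient=corrected,
                standard_error=se,
                p_value=float(p_corr),
                raw_p_value=float(p_raw),
                model=model,
                n_samples=len(samples),
            )
        )
    adjusted = bh_adjust([r.p_value for r in results])
    for r, ap in zip(results, adjusted):
        r.adjusted_p = float(ap)
    return results


def da_table(results: list[DaResult]) -> pd.DataFrame:
    rows = [
        {
            "taxon": r.taxon,
            "raw_coefficient": r.raw_coefficient,
            "corrected_coefficient": r.corrected_coefficient,
            "standard_error": r.standard_error,
            "p_value": r.p_value,
            "adjusted_p": r.adjusted_p,
            "raw_p_value": r.raw_p_value,
            "model": r.model,
            "n_samples": r.n_samples,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "taxon", "raw_coefficient", "corrected_coefficient", "standard_error",
            "p_value", "adjusted_p", "raw_p_value", "model", "n_samples",
        ],
    )
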