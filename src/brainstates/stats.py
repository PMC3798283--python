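"""Repeated-measures statistical framework for the network metrics.

Two-way within-subject ANOVA (condition x threshold) with Mauchly's
sphericity test per effect, epsilon-corrected degrees of freedom
(Huynh-Feldt for moderate violations, epsilon_GG >= 0.75; Greenhouse-
Geisser otherwise), partial omega-squared effect sizes and Sidak-adjusted
pairwise contrasts; per-threshold one-way follow-ups; Benjamini-Yekutieli
node-wise FDR; and a repeated-measures ANCOVA of binned correlation
strength with inter-ROI distance as covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .atlas import ValidationError

_EPS_HF_CUTOFF = 0.75
_MAUCHLY_ALPHA = 0.05


# ---------------------------------------------------------------------------
# sphericity machinery

def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert-style)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1)
        c[i] /= np.linalg.norm(c[i])
    return c


def sphericity_epsilons(contrast_cov: np.ndarray, n: int
                        ) -> tuple[float, float, float, float]:
    """(Mauchly W, Mauchly p, GG epsilon, HF epsilon) from a contrast covariance.

    ``contrast_cov`` is the (k-1) x (k-1) covariance of orthonormalized
    within-subject contrasts over ``n`` subjects. For k < 3 sphericity
    holds trivially: W = 1, p = 1, both epsilons 1.
    """
    s = np.atleast_2d(np.asarray(contrast_cov, float))
    p = s.shape[0]
    if p < 2:
        return 1.0, 1.0, 1.0, 1.0
    lam = np.linalg.eigvalsh(s)
    lam = np.clip(lam, 0.0, None)
    if lam.sum() == 0:  # degenerate (constant data): trivially spherical
        return 1.0, 1.0, 1.0, 1.0
    gg = float(lam.sum() ** 2 / (p * (lam**2).sum()))
    hf_num = n * p * gg - 2.0
    hf_den = p * (n - 1 - p * gg)
    hf = float(min(1.0, hf_num / hf_den)) if hf_den > 0 else 1.0
    hf = max(hf, gg)
    # Mauchly's W with chi-square approximation
    det = float(np.prod(lam))
    tr = float(lam.sum())
    w = det / (tr / p) ** p if tr > 0 else 1.0
    f_corr = 1.0 - (2 * p**2 + p + 2) / (6.0 * p * (n - 1))
    chi2 = -(n - 1) * f_corr * np.log(max(w, 1e-300))
    df = p * (p + 1) // 2 - 1
    p_val = float(sps.chi2.sf(chi2, df)) if n - 1 > p else float("nan")
    return float(w), p_val, gg, hf


def partial_omega_squared(f: float, df_effect: float, n_observations: int) -> float:
    """Low-bias population effect size; negative estimates clipped to 0."""
    num = df_effect * (f - 1.0)
    return float(max(0.0, num / (num + n_observations)))


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family correction 1 - (1 - p)^m."""
    return float(1.0 - (1.0 - p) ** m)


# ---------------------------------------------------------------------------
# result containers

@dataclass
class EffectResult:
    name: str
    F: float
    df1: float
    df2: float
    p_uncorrected: float
    p: float
    epsilon_type: str  # "none" | "HF" | "GG"
    epsilon: float
    mauchly_w: float
    mauchly_p: float
    omega_sq_p: float

    @property
    def df1_corrected(self) -> float:
        return self.df1 * self.epsilon

    @property
    def df2_corrected(self) -> float:
        return self.df2 * self.epsilon


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    label: str = ""


def _effect_result(name: str, ss_eff: float, ss_err: float, df1: float, df2: float,
                   contrast_cov: np.ndarray | None, n: int, n_obs: int) -> EffectResult:
    ms_eff = ss_eff / df1
    ms_err = ss_err / df2
    if ms_err > 1e-24:
        f = ms_eff / ms_err
    else:
        # zero residual variance: degenerate; F is 0 for a null effect and
        # unbounded for any non-zero effect
        f = 0.0 if ms_eff <= 1e-20 else float("inf")
    if contrast_cov is not None:
        w, p_mau, gg, hf = sphericity_epsilons(contrast_cov, n)
    else:
        w, p_mau, gg, hf = 1.0, 1.0, 1.0, 1.0
    p_unc = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    eps_type, eps = "none", 1.0
    if np.isfinite(p_mau) and p_mau < _MAUCHLY_ALPHA:
        eps_type, eps = ("HF", hf) if gg >= _EPS_HF_CUTOFF else ("GG", gg)
    p_corr = float(sps.f.sf(f, df1 * eps, df2 * eps)) if np.isfinite(f) else 0.0
    return EffectResult(
        name=name, F=float(f), df1=df1, df2=df2,
        p_uncorrected=p_unc, p=p_corr,
        epsilon_type=eps_type, epsilon=float(eps),
        mauchly_w=w, mauchly_p=p_mau,
        omega_sq_p=partial_omega_squared(f, df1, n_obs) if np.isfinite(f) else 1.0,
    )


def _contrast_cov(cells: np.ndarray, contrasts: np.ndarray) -> np.ndarray:
    """Covariance of subject scores projected on orthonormal contrasts."""
    proj = cells @ contrasts.T
    return np.cov(proj, rowvar=False)


def sidak_pairwise(data: np.ndarray, level_names: list, m: int | None = None
                   ) -> pd.DataFrame:
    """Paired contrasts between condition columns, Sidak-adjusted.

    ``data`` is n_subjects x k of subject-level marginal means. With k
    levels there are k(k-1)/2 comparisons unless ``m`` overrides the
    family size.
    """
    n, k = data.shape
    pairs = list(combinations(range(k), 2))
    m = len(pairs) if m is None else m
    rows = []
    for a, b in pairs:
        diff = data[:, a] - data[:, b]
        t, p = sps.ttest_rel(data[:, a], data[:, b])
        rows.append((level_names[a], level_names[b], float(diff.mean()),
                     float(t), float(p), sidak_adjust(float(p), m)))
    return pd.DataFrame(rows, columns=["level_a", "level_b", "mean_diff",
                                       "t", "p_raw", "p_sidak"])


# ---------------------------------------------------------------------------
# ANOVA models

def _check_balanced(table: pd.DataFrame, factors: list[str]) -> None:
    counts = table.groupby(["subject"] + factors, observed=True).size()
    n_cells = len(table["subject"].unique())
    for f in factors:
        n_cells *= len(table[f].unique())
    if len(counts) != n_cells or (counts != 1).any():
        raise ValidationError("table must be complete and balanced "
                              "(exactly one value per subject x cell)")


def rm_anova_oneway(table: pd.DataFrame, factor: str = "condition",
                    value: str = "value", label: str = "") -> AnovaResult:
    """One-way repeated-measures ANOVA with sphericity handling."""
    _check_balanced(table, [factor])
    wide = table.pivot_table(index="subject", columns=factor, values=value,
                             observed=True, sort=True)
    cells = wide.to_numpy(float)
    n, k = cells.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 levels")
    grand = cells.mean()
    ss_subj = k * ((cells.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((cells.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((cells - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    contrasts = _orthonormal_contrasts(k)
    eff = _effect_result(factor, ss_cond, ss_err, k - 1.0, (n - 1.0) * (k - 1.0),
                         _contrast_cov(cells, contrasts), n, n * k)
    pw = sidak_pairwise(cells, list(wide.columns))
    return AnovaResult({factor: eff}, pairwise=pw, label=label)


def rm_anova(table: pd.DataFrame, factor_a: str = "condition",
             factor_b: str = "threshold", value: str = "value") -> AnovaResult:
    """Two-way within-subject ANOVA (both factors repeated).

    Each effect is tested against its own effect-by-subject interaction;
    sphericity is evaluated per effect on orthonormalized contrasts of the
    subject-level cell means (Kronecker contrasts for the interaction).
    """
    _check_balanced(table, [factor_a, factor_b])
    a_levels = sorted(table[factor_a].unique(), key=str)
    # preserve meaningful ordering if the column is categorical/ordered
    if isinstance(table[factor_a].dtype, pd.CategoricalDtype):
        a_levels = [l for l in table[factor_a].cat.categories if l in set(table[factor_a])]
    b_levels = sorted(table[factor_b].unique())
    subjects = sorted(table["subject"].unique(), key=str)
    n, a, b = len(subjects), len(a_levels), len(b_levels)
    cube = np.empty((n, a, b))
    piv = table.set_index(["subject", factor_a, factor_b])[value]
    for si, s in enumerate(subjects):
        for ai, al in enumerate(a_levels):
            for bi, bl in enumerate(b_levels):
                cube[si, ai, bi] = piv.loc[(s, al, bl)]

    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_abs = (
        (cube - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
         + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - grand) ** 2
    ).sum()

    n_obs = n * a * b
    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    effects = {
        factor_a: _effect_result(
            factor_a, ss_a, ss_as, a - 1.0, (n - 1.0) * (a - 1.0),
            _contrast_cov(m_sa, ca), n, n_obs),
        factor_b: _effect_result(
            factor_b, ss_b, ss_bs, b - 1.0, (n - 1.0) * (b - 1.0),
            _contrast_cov(m_sb, cb), n, n_obs),
        f"{factor_a} x {factor_b}": _effect_result(
            f"{factor_a} x {factor_b}", ss_ab, ss_abs,
            (a - 1.0) * (b - 1.0), (n - 1.0) * (a - 1.0) * (b - 1.0),
            _contrast_cov(cube.reshape(n, a * b), np.kron(ca, cb)), n, n_obs),
    }
    pw = sidak_pairwise(m_sa, a_levels)
    return AnovaResult(effects, pairwise=pw)


def per_threshold_anovas(table: pd.DataFrame, factor: str = "condition",
                         threshold: str = "threshold",
                         value: str = "value") -> list[AnovaResult]:
    """One 1-way repeated-measures ANOVA per density threshold."""
    out = []
    for t in sorted(table[threshold].unique()):
        sub = table[table[threshold] == t]
        out.append(rm_anova_oneway(sub, factor=factor, value=value,
                                   label=f"{threshold}={t}"))
    return out


def nodewise_fdr(p_values: np.ndarray, q: float = 0.05
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Yekutieli step-up (valid under dependency); (mask, p_adj)."""
    p = np.asarray(p_values, float)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_by")
    return reject, p_adj


# ---------------------------------------------------------------------------
# distance ANCOVA

@dataclass
class AncovaResult:
    condition: EffectResult
    distance: EffectResult
    interaction: EffectResult
    per_bin: list[AnovaResult]


def rm_ancova_distance(binned: pd.DataFrame) -> AncovaResult:
    """Repeated-measures ANCOVA of binned correlation strength on distance.

    ``binned`` has one row per (subject, condition, bin) with columns
    ``center_mm`` (bin-center distance) and ``mean_r``. The condition
    effect is the standard RM test on subject x condition means (averaged
    over bins). The distance effect and the condition x distance
    interaction are tested on subject-level regression slopes of mean_r on
    distance (a summary-statistics formulation: the distance effect is a
    one-sample test of the per-subject slopes, the interaction an RM-ANOVA
    of the per-subject, per-condition slopes). Empty bins are dropped.
    Follow-up: one 1-way RM-ANOVA per retained bin with Sidak contrasts.
    """
    d = binned.dropna(subset=["mean_r"]).copy()
    conditions = list(dict.fromkeys(d["condition"]))
    subjects = sorted(d["subject"].unique(), key=str)
    n, k = len(subjects), len(conditions)

    cond_means = d.pivot_table(index="subject", columns="condition",
                               values="mean_r", observed=True)
    cond_means = cond_means.reindex(index=subjects, columns=conditions)
    cells = cond_means.to_numpy(float)
    grand = cells.mean()
    ss_cond = n * ((cells.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((cells.mean(axis=1) - grand) ** 2).sum()
    ss_err = ((cells - grand) ** 2).sum() - ss_cond - ss_subj
    cond_eff = _effect_result("condition", ss_cond, ss_err, k - 1.0,
                              (n - 1.0) * (k - 1.0),
                              _contrast_cov(cells, _orthonormal_contrasts(k)),
                              n, n * k)

    # per-subject, per-condition slopes of mean_r on bin-center distance
    slopes = np.full((n, k), np.nan)
    for si, s in enumerate(subjects):
        for ci, c in enumerate(conditions):
            sub = d[(d["subject"] == s) & (d["condition"] == c)]
            if len(sub) >= 2:
                slopes[si, ci] = np.polyfit(sub["center_mm"], sub["mean_r"], 1)[0]
    if np.isnan(slopes).any():
        raise ValidationError("a subject x condition cell has < 2 distance bins")

    mean_slope = slopes.mean(axis=1)
    t, p = sps.ttest_1samp(mean_slope, 0.0)
    dist_eff = EffectResult(
        name="distance", F=float(t**2), df1=1.0, df2=float(n - 1),
        p_uncorrected=float(p), p=float(p), epsilon_type="none", epsilon=1.0,
        mauchly_w=1.0, mauchly_p=1.0,
        omega_sq_p=partial_omega_squared(float(t**2), 1.0, n),
    )

    grand_s = slopes.mean()
    ss_c = n * ((slopes.mean(axis=0) - grand_s) ** 2).sum()
    ss_s = k * ((slopes.mean(axis=1) - grand_s) ** 2).sum()
    ss_e = ((slopes - grand_s) ** 2).sum() - ss_c - ss_s
    inter_eff = _effect_result("condition x distance", ss_c, ss_e, k - 1.0,
                               (n - 1.0) * (k - 1.0),
                               _contrast_cov(slopes, _orthonormal_contrasts(k)),
                               n, n * k)

    per_bin = []
    for b in sorted(d["bin"].unique()):
        sub = d[d["bin"] == b].rename(columns={"mean_r": "value"})
        counts = sub.groupby(["subject", "condition"], observed=True).size()
        if len(sub) == n * k and (counts == 1).all():
            per_bin.append(rm_anova_oneway(sub, label=f"bin={b}"))
    return AncovaResult(cond_eff, dist_eff, inter_eff, per_bin)
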