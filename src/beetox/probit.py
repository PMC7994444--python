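"""Cross-sectional probit dose-response fits and LD50 estimation.

For each assessment time the cumulative mortality per dose group is fitted
to the natural-response-adjusted probit model

    P(dead | dose d) = c + (1 - c) * Phi(alpha + beta * log10 d)

by maximum likelihood, with ``c`` the background ("natural") mortality
estimated jointly from the control group when control deaths occurred, and
fixed at 0 otherwise.  The LD50 is the dose where the treatment-induced
(Abbott-corrected) mortality reaches 50%, i.e. ``10**(-alpha/beta)``, with
95% confidence limits from Fieller's theorem on the ratio ``-alpha/beta``.

Following classic probit-analysis practice (and the behaviour of the major
commercial implementations), when the Pearson goodness-of-fit test signals
heterogeneity (p < 0.15) the coefficient covariance is inflated by the
heterogeneity factor ``chi2/df`` and t-based critical values replace normal
ones.  An LD50 is reported as non-determinable when the dose-response slope
is not significant (Wald p >= 0.05), when the slope is non-positive, or
when Fieller's g >= 1 (no finite interval).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from beetox.io import (
    BeeRecord,
    SPECIES_REGISTRY,
    SpeciesProfile,
    StudyDesign,
    aggregate_mortality,
)

_PCLIP = 1e-12


class ProbitError(ValueError):
    """The probit model cannot be identified from the given data."""


@dataclass(frozen=True)
class ProbitFit:
    """Fitted probit dose-response model at one assessment time.

    ``cov`` is the raw ML covariance of (alpha, beta); use
    :attr:`scaled_cov` for inference, which applies the heterogeneity
    factor when it was triggered.
    """

    alpha: float
    beta: float
    cov: np.ndarray
    natural_mortality: float
    pearson_chi2: float
    df: int
    heterogeneity: float
    slope_p: float
    use_t: bool
    n_groups: int

    @property
    def scaled_cov(self) -> np.ndarray:
        return self.cov * self.heterogeneity

    def critical_value(self, alpha_level: float = 0.05) -> float:
        if self.use_t and self.df > 0:
            return float(stats.t.ppf(1 - alpha_level / 2, self.df))
        return float(stats.norm.ppf(1 - alpha_level / 2))


@dataclass(frozen=True)
class LD50Estimate:
    """LD50 point and 95% Fieller limits, per bee and (optionally) per g."""

    determinable: bool
    ld50_ng_per_bee: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    ld50_ng_per_g: float | None = None
    ci_low_g: float | None = None
    ci_high_g: float | None = None
    time: float | None = None
    se_log10: float | None = None
    reason: str | None = None


def _nll(theta, x, n, d, n0, d0, estimate_c):
    if estimate_c:
        a, b, gamma = theta
        c = expit(gamma)
    else:
        a, b = theta
        c = 0.0
    p = c + (1 - c) * stats.norm.cdf(a + b * x)
    p = np.clip(p, _PCLIP, 1 - _PCLIP)
    ll = np.sum(d * np.log(p) + (n - d) * np.log1p(-p))
    if n0 > 0:
        pc = min(max(c, _PCLIP), 1 - _PCLIP)
        ll += d0 * np.log(pc) + (n0 - d0) * np.log1p(-pc)
    return -ll


def _fd_hessian(f, theta, rel_step=1e-5):
    """Central finite-difference Hessian of a scalar function."""
    theta = np.asarray(theta, dtype=float)
    k = len(theta)
    h = rel_step * (1.0 + np.abs(theta))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(theta + ei + ej)
            fpm = f(theta + ei - ej)
            fmp = f(theta - ei + ej)
            fmm = f(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (
                4 * h[i] * h[j]
            )
    return hess


def fit_probit(
    mortality_table: Sequence[tuple],
    control: tuple | None = None,
    natural_response: str = "auto",
) -> ProbitFit:
    """Maximum-likelihood probit fit of grouped (dose, n, dead) data.

    Parameters
    ----------
    mortality_table
        Sequence of ``(dose, n_exposed, n_dead)`` for positive doses.
    control
        Optional ``(n_exposed, n_dead)`` of the control group, used to
        estimate the natural-mortality parameter ``c``.
    natural_response
        ``"auto"`` (estimate ``c`` jointly whenever a control group is
        provided — the estimate shrinks to ~0 when the control shows no
        background mortality — else fix at 0), ``"estimate"`` or
        ``"fixed_zero"``.  Fixing ``c = 0`` while the data carry background
        deaths misattributes them to the dose-response and triggers large
        heterogeneity inflation, so joint estimation is the default.
    """
    table = [(float(d), int(n), int(k)) for d, n, k in mortality_table]
    if len(table) < 3:
        raise ValueError("need at least 3 positive dose groups")
    if any(d <= 0 for d, _, _ in table):
        raise ValueError("doses must be positive")
    if any(n < 1 or k < 0 or k > n for _, n, k in table):
        raise ValueError("each group needs n >= 1 and 0 <= dead <= n")
    doses = np.array([d for d, _, _ in table])
    n = np.array([g for _, g, _ in table], dtype=float)
    d = np.array([k for _, _, k in table], dtype=float)
    if d.sum() == 0 or (n - d).sum() == 0:
        raise ProbitError(
            "mortality is constant (all alive or all dead) across doses; "
            "the dose-response slope is not identifiable"
        )
    n0, d0 = (0, 0) if control is None else (int(control[0]), int(control[1]))

    if natural_response not in ("auto", "estimate", "fixed_zero"):
        raise ValueError(f"unknown natural_response {natural_response!r}")
    estimate_c = natural_response in ("estimate", "auto") and n0 > 0

    x = np.log10(doses)
    # empirical-probit start values
    p_emp = (d + 0.5) / (n + 1.0)
    y = stats.norm.ppf(p_emp)
    beta0, alpha0 = np.polyfit(x, y, 1)
    theta0 = [alpha0, beta0]
    if estimate_c:
        theta0.append(logit(min(max(d0 / n0, 1e-3), 0.5)))

    obj = lambda th: _nll(th, x, n, d, n0, d0, estimate_c)  # noqa: E731
    res = optimize.minimize(obj, theta0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 4000})
    res = optimize.minimize(obj, res.x, method="BFGS")
    theta = res.x
    alpha, beta = float(theta[0]), float(theta[1])
    c = float(expit(theta[2])) if estimate_c else 0.0

    hess = _fd_hessian(obj, theta)
    try:
        cov_full = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_full = np.linalg.pinv(hess)
    cov = np.asarray(cov_full[:2, :2], dtype=float)

    # Pearson goodness of fit over the groups entering the likelihood
    p_hat = c + (1 - c) * stats.norm.cdf(alpha + beta * x)
    p_all = list(zip(n, d, p_hat))
    if n0 > 0 and estimate_c:
        p_all.append((float(n0), float(d0), c))
    chi2 = 0.0
    for ni, di, pi in p_all:
        pi = min(max(pi, _PCLIP), 1 - _PCLIP)
        chi2 += (di - ni * pi) ** 2 / (ni * pi * (1 - pi))
    n_params = len(theta)
    df = max(len(p_all) - n_params, 0)
    het = 1.0
    use_t = False
    if df > 0:
        gof_p = float(stats.chi2.sf(chi2, df))
        if gof_p < 0.15 and chi2 / df > 1:
            het = chi2 / df
            use_t = True

    se_b = float(np.sqrt(max(cov[1, 1], 0.0) * het))
    if se_b > 0:
        zb = beta / se_b
        if use_t and df > 0:
            slope_p = float(2 * stats.t.sf(abs(zb), df))
        else:
            slope_p = float(2 * stats.norm.sf(abs(zb)))
    else:
        slope_p = 1.0

    return ProbitFit(
        alpha=alpha,
        beta=beta,
        cov=cov,
        natural_mortality=c,
        pearson_chi2=float(chi2),
        df=df,
        heterogeneity=float(het),
        slope_p=slope_p,
        use_t=use_t,
        n_groups=len(p_all),
    )


def ld50(fit: ProbitFit, alpha_level: float = 0.05) -> LD50Estimate:
    """LD50 with Fieller confidence limits from a probit fit.

    Non-determinable when the slope is non-positive or not significantly
    different from 0 at the 5% level, or when Fieller's g >= 1 so that no
    finite confidence interval exists.  With the natural-response-adjusted
    model the LD50 solves ``Phi(alpha + beta x) = 1/2``, i.e.
    ``x = -alpha/beta`` on the log10 dose scale, independent of ``c``.
    """
    if fit.beta <= 0:
        return LD50Estimate(
            determinable=False,
            reason="dose-response slope is not positive",
        )
    if fit.slope_p >= 0.05:
        return LD50Estimate(
            determinable=False,
            reason=(
                "probit dose-response relationship not significant "
                f"(slope p = {fit.slope_p:.3f})"
            ),
        )
    a, b = fit.alpha, fit.beta
    v = fit.scaled_cov
    m = -a / b
    se = float(np.sqrt(max(v[0, 0] + 2 * m * v[0, 1] + m * m * v[1, 1], 0.0))
               / abs(b))
    crit = fit.critical_value(alpha_level)
    # Fieller set: { x : (a + b x)^2 <= crit^2 (v11 + 2 v12 x + v22 x^2) }
    qa = b * b - crit * crit * v[1, 1]
    qb = 2 * (a * b - crit * crit * v[0, 1])
    qc = a * a - crit * crit * v[0, 0]
    if qa <= 0:
        return LD50Estimate(
            determinable=False,
            reason="Fieller g >= 1: no finite confidence interval",
            se_log10=se,
        )
    disc = qb * qb - 4 * qa * qc
    if disc < 0:
        return LD50Estimate(
            determinable=False,
            reason="Fieller interval is empty",
            se_log10=se,
        )
    root = np.sqrt(disc)
    lo = (-qb - root) / (2 * qa)
    hi = (-qb + root) / (2 * qa)
    return LD50Estimate(
        determinable=True,
        ld50_ng_per_bee=float(10**m),
        ci_low=float(10**lo),
        ci_high=float(10**hi),
        se_log10=se,
    )


def ld50_per_gram(
    est: LD50Estimate, profile: SpeciesProfile
) -> LD50Estimate:
    """Express an LD50 per gram of bee body weight (ng/g)."""
    if not est.determinable:
        return est
    w = profile.mean_body_weight
    return replace(
        est,
        ld50_ng_per_g=est.ld50_ng_per_bee / w,
        ci_low_g=est.ci_low / w,
        ci_high_g=est.ci_high / w,
    )


@dataclass(frozen=True)
class LD50TableEntry:
    """One (species, treatment, time) cell of the LD50 summary table."""

    species: str
    treatment: str  # "SUL" or "SUL_FLU"
    time: float
    fit: ProbitFit | None
    estimate: LD50Estimate


# background arm used as the probit control group for each treated arm;
# the mixture arm's background is the fungicide-only arm
_CONTROL_FOR = {"SUL": ("SOLVENT", "CONTROL"), "SUL_FLU": ("FLU", "SOLVENT", "CONTROL")}


def ld50_table(
    records: Sequence[BeeRecord],
    design: StudyDesign,
    species_profiles=None,
    natural_response: str = "auto",
) -> list:
    """Per-(species, treatment, time) LD50 estimates from a full dataset.

    For each species and each of the SUL and SUL_FLU arms, cumulative
    mortality at every assessment time is fitted with :func:`fit_probit`
    (the solvent control serves as the background group for the SUL arm,
    the fungicide-only arm for the mixture arm) and summarised with
    :func:`ld50`.  Mixture LD50s are parameterised by the SUL dose at the
    fixed FLU co-dose.  Returns a list of :class:`LD50TableEntry`.
    """
    profiles = species_profiles if species_profiles is not None else SPECIES_REGISTRY
    entries = []
    species_seen = sorted({r.species for r in records})
    for species in species_seen:
        recs = [r for r in records if r.species == species]
        for arm in ("SUL", "SUL_FLU"):
            arm_recs = [r for r in recs if r.arm == arm]
            if not arm_recs:
                continue
            for time in design.assessment_times:
                agg = aggregate_mortality(recs, time, design)
                rows = agg[(agg["arm"] == arm) & (agg["sul_dose_ng"] > 0)]
                table = list(
                    rows[["sul_dose_ng", "n_exposed", "n_dead"]].itertuples(
                        index=False, name=None
                    )
                )
                control = None
                for ctrl_arm in _CONTROL_FOR[arm]:
                    crow = agg[agg["arm"] == ctrl_arm]
                    if len(crow):
                        control = (
                            int(crow["n_exposed"].sum()),
                            int(crow["n_dead"].sum()),
                        )
                        break
                try:
                    fit = fit_probit(
                        table, control=control, natural_response=natural_response
                    )
                    est = ld50(fit)
                except (ProbitError, ValueError) as exc:
                    fit = None
                    est = LD50Estimate(determinable=False, reason=str(exc))
                est = replace(est, time=time)
                if est.determinable and species in profiles:
                    est = ld50_per_gram(est, profiles[species])
                entries.append(
                    LD50TableEntry(
                        species=species, treatment=arm, time=time,
                        fit=fit, estimate=est,
                    )
                )
    return entries


def ld50_frame(entries: Sequence[LD50TableEntry]) -> pd.DataFrame:
    """Flat DataFrame view of LD50 table entries (CSV-ready)."""
    rows = []
    for e in entries:
        est = e.estimate
        rows.append(
            {
                "species": e.species,
                "treatment": e.treatment,
                "time_h": e.time,
                "determinable": est.determinable,
                "ld50_ng_per_bee": est.ld50_ng_per_bee,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "ld50_ng_per_g": est.ld50_ng_per_g,
                "ci_low_g": est.ci_low_g,
                "ci_high_g": est.ci_high_g,
            }
        )
    return pd.DataFrame(rows)
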