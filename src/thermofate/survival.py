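"""Known-fate survival estimation from first principles.

Radio-tracked animals have detection probability 1, so the likelihood of a
set of encounter histories is a product of per-interval binomial terms: an
individual at risk in an interval either survives it (probability phi) or
dies (1 - phi); censored intervals contribute nothing beyond the intervals
already survived.  Here phi is constant across occasions within an
individual and linked to individual covariates through a logit:

    logit(phi_i) = x_i' beta

The module builds encounter histories from daily fate records, maximizes
the log-likelihood numerically (with analytic gradient and Hessian),
derives seasonal survival phi^n with delta-method standard errors, and
ranks candidate covariate models by small-sample-corrected AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .io_ingest import FateRecord, LizardRecord, ValidationError

_CLIP = 1e-12


@dataclass
class EncounterHistory:
    """Per-occasion fate states plus covariates for one individual.

    ``states`` is a sequence over occasions starting at ``first_occasion``,
    each in {"survived", "died", "censored"}; "died"/"censored" terminate
    the history.
    """

    lizard_id: str
    first_occasion: int
    states: list[str]
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for k, s in enumerate(self.states):
            if s not in ("survived", "died", "censored"):
                raise ValueError(f"{self.lizard_id}: bad state {s!r}")
            if s in ("died", "censored") and k != len(self.states) - 1:
                raise ValueError(f"{self.lizard_id}: terminal state before end of history")

    @property
    def n_survived(self) -> int:
        return sum(s == "survived" for s in self.states)

    @property
    def died(self) -> bool:
        return bool(self.states) and self.states[-1] == "died"

    @property
    def n_at_risk(self) -> int:
        """Intervals with a binomial outcome (survived or died)."""
        return self.n_survived + int(self.died)


def build_histories(
    fates: list[FateRecord],
    lizards: list[LizardRecord],
    season_start,
    n_occasions: int = 13,
    occasion_length_days: int = 7,
    covariates: pd.DataFrame | None = None,
) -> list[EncounterHistory]:
    """Collapse daily fate records into fixed-length encounter occasions.

    Occasions are consecutive ``occasion_length_days``-day intervals from
    ``season_start``.  Individuals enter at the occasion containing their
    ``tracked_from`` (staggered entry).  A death is assigned to the
    occasion containing the death date; loss of signal censors the animal
    at the occasion containing its last record, which is not counted as
    survived.  ``covariates`` (indexed by lizard_id) are attached verbatim.
    """
    season_start = pd.Timestamp(season_start)
    liz_by_id = {l.lizard_id: l for l in lizards}
    fates_by_id: dict[str, list[FateRecord]] = {}
    for f in fates:
        liz = liz_by_id.get(f.lizard_id)
        if liz is None:
            raise ValidationError(f"fate for unknown lizard {f.lizard_id}")
        if not (liz.tracked_from <= f.date <= liz.tracked_to):
            raise ValidationError(
                f"{f.lizard_id}: fate on {f.date.date()} outside tracking window"
            )
        fates_by_id.setdefault(f.lizard_id, []).append(f)

    def occ_of(date: pd.Timestamp) -> int:
        return int((date - season_start).days // occasion_length_days)

    histories = []
    for lid, recs in fates_by_id.items():
        recs.sort(key=lambda r: r.date)
        liz = liz_by_id[lid]
        first = max(0, occ_of(max(liz.tracked_from, season_start)))
        if first >= n_occasions:
            continue
        death = next((r for r in recs if r.status == "dead"), None)
        censor = next((r for r in recs if r.status == "censored"), None)
        last_obs = recs[-1].date

        states: list[str] = []
        for occ in range(first, n_occasions):
            occ_end = season_start + pd.Timedelta(days=(occ + 1) * occasion_length_days - 1)
            if death is not None and occ_of(death.date) == occ:
                states.append("died")
                break
            if censor is not None and occ_of(censor.date) == occ:
                states.append("censored")
                break
            if last_obs < occ_end:
                # observation ran out mid-occasion without a confirmed fate
                if states:
                    states.append("censored")
                break
            states.append("survived")
        if not states:
            continue
        cov = {}
        if covariates is not None and lid in covariates.index:
            cov = covariates.loc[lid].to_dict()
        histories.append(
            EncounterHistory(lizard_id=lid, first_occasion=first, states=states, covariates=cov)
        )
    return histories


# ---------------------------------------------------------------------------
# formula handling

def _parse_formula(formula: str) -> list[tuple[str, ...]]:
    """Parse ``"sex * pmax + db"`` into design terms.

    Returns a list of term tuples; ``()`` is the intercept (always first),
    single names are main effects, pairs are products.  ``a*b`` expands to
    ``a + b + a:b``; ``a:b`` is the bare product.
    """
    terms: list[tuple[str, ...]] = [()]
    body = formula.split("~", 1)[-1].strip()
    if body in ("", "1"):
        return terms

    def add(t: tuple[str, ...]):
        if t not in terms:
            terms.append(t)

    for raw in body.split("+"):
        raw = raw.strip()
        if raw in ("", "1"):
            continue
        if "*" in raw:
            a, b = (s.strip() for s in raw.split("*", 1))
            add((a,)), add((b,)), add(tuple(sorted((a, b))))
        elif ":" in raw:
            a, b = (s.strip() for s in raw.split(":", 1))
            add(tuple(sorted((a, b))))
        else:
            add((raw,))
    return terms


def design_matrix(
    histories: list[EncounterHistory],
    formula: str,
    standardize: bool = True,
) -> tuple[np.ndarray, list[str], dict]:
    """Build the covariate design matrix (one row per individual).

    Continuous covariates are z-scored by default (binary 0/1 columns are
    left alone); the returned scaling dict allows mapping coefficients back
    to the natural scale.
    """
    terms = _parse_formula(formula)
    names = ["intercept"] + [":".join(t) for t in terms[1:]]
    base_vars = sorted({v for t in terms for v in t})
    raw = {}
    for v in base_vars:
        col = []
        for h in histories:
            if v not in h.covariates:
                raise ValidationError(f"{h.lizard_id}: missing covariate {v!r}")
            col.append(float(h.covariates[v]))
        raw[v] = np.asarray(col)

    scaling = {}
    cols = {v: c.copy() for v, c in raw.items()}
    if standardize:
        for v, c in cols.items():
            uniq = np.unique(c)
            if uniq.size <= 2 and set(uniq).issubset({0.0, 1.0}):
                continue  # leave binary codes alone
            sd = c.std(ddof=0)
            if sd > 0:
                scaling[v] = (float(c.mean()), float(sd))
                cols[v] = (c - c.mean()) / sd

    X = np.ones((len(histories), len(terms)))
    for j, t in enumerate(terms[1:], start=1):
        col = np.ones(len(histories))
        for v in t:
            col = col * cols[v]
        X[:, j] = col

    if X.shape[0] >= X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(f"design matrix rank-deficient for formula {formula!r}")
    return X, names, scaling


# ---------------------------------------------------------------------------
# likelihood

def _sd_vectors(histories: list[EncounterHistory]) -> tuple[np.ndarray, np.ndarray]:
    s = np.array([h.n_survived for h in histories], dtype=float)
    d = np.array([float(h.died) for h in histories])
    return s, d


def loglik(histories: list[EncounterHistory], betas, X: np.ndarray) -> float:
    """Known-fate log-likelihood sum_i [s_i log phi_i + d_i log(1 - phi_i)]."""
    s, d = _sd_vectors(histories)
    phi = np.clip(expit(X @ np.asarray(betas, dtype=float)), _CLIP, 1 - _CLIP)
    return float(np.sum(s * np.log(phi) + d * np.log1p(-phi)))


def _grad_hess(betas, X, s, d):
    phi = np.clip(expit(X @ betas), _CLIP, 1 - _CLIP)
    g = X.T @ (s * (1 - phi) - d * phi)
    w = (s + d) * phi * (1 - phi)
    H = -(X * w[:, None]).T @ X
    return g, H


@dataclass
class KnownFateFit:
    """Fitted known-fate model."""

    formula: str
    names: list[str]
    betas: np.ndarray               # on the (possibly standardized) fitting scale
    loglik: float
    K: int
    aicc: float
    vcov: np.ndarray
    phi_hat: np.ndarray             # per-individual per-occasion survival
    n_eff: int
    scaling: dict                   # covariate -> (mean, sd) used for z-scoring
    boundary: bool = False          # no deaths: phi on the boundary at 1
    converged: bool = True

    @property
    def betas_natural(self) -> np.ndarray:
        """Coefficients mapped back to the natural covariate scale.

        Only exact for formulas without interactions among rescaled
        covariates; interaction terms are returned on the fitting scale.
        """
        b = self.betas.copy()
        for j, name in enumerate(self.names):
            if ":" in name or name == "intercept":
                continue
            if name in self.scaling:
                mean, sd = self.scaling[name]
                b[0] -= self.betas[j] * mean / sd
                b[j] = self.betas[j] / sd
        return b


def fit(
    histories: list[EncounterHistory],
    formula: str = "phi ~ 1",
    standardize: bool = True,
    n_eff_convention: str = "intervals",
) -> KnownFateFit:
    """Maximum-likelihood fit of the logit-linear known-fate model.

    Quasi-Newton optimisation from a zero start with analytic gradient;
    the covariance matrix is the inverse observed information.  With no
    deaths the MLE sits on the boundary (phi = 1): the fit is flagged and
    Wald standard errors are not meaningful.
    """
    X, names, scaling = design_matrix(histories, formula, standardize=standardize)
    s, d = _sd_vectors(histories)
    if (s + d).sum() == 0:
        raise ValidationError("no at-risk intervals")
    n_eff = int((s + d).sum()) if n_eff_convention == "intervals" else len(histories)
    K = X.shape[1]

    boundary = d.sum() == 0
    if boundary:
        betas = np.zeros(K)
        betas[0] = logit(1 - _CLIP)
        ll = 0.0
        vcov = np.full((K, K), np.nan)
        phi = np.ones(len(histories))
        return KnownFateFit(
            formula=formula, names=names, betas=betas, loglik=ll, K=K,
            aicc=aicc(ll, K, n_eff), vcov=vcov, phi_hat=phi, n_eff=n_eff,
            scaling=scaling, boundary=True,
        )

    def nll(b):
        return -loglik(histories, b, X)

    def njac(b):
        g, _ = _grad_hess(b, X, s, d)
        return -g

    res = minimize(nll, np.zeros(K), jac=njac, method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 500})
    betas = res.x
    _, H = _grad_hess(betas, X, s, d)
    try:
        vcov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        vcov = np.full((K, K), np.nan)
    ll = -res.fun
    phi = expit(X @ betas)
    return KnownFateFit(
        formula=formula, names=names, betas=betas, loglik=ll, K=K,
        aicc=aicc(ll, K, n_eff), vcov=vcov, phi_hat=phi, n_eff=n_eff,
        scaling=scaling, converged=bool(res.success),
    )


def profile_phi_lower(histories: list[EncounterHistory], alpha: float = 0.05) -> float:
    """One-sided profile-likelihood lower bound for phi when no deaths occurred.

    With s survived intervals and zero deaths the profile log-likelihood is
    s*log(phi), so the bound solves 2*s*log(phi) = -chi2_1(1 - 2*alpha).
    """
    from scipy.stats import chi2

    s = sum(h.n_survived for h in histories)
    if s == 0:
        return 0.0
    crit = chi2.ppf(1 - 2 * alpha, df=1)
    return float(np.exp(-crit / (2 * s)))


def seasonal_survival(
    fit_: KnownFateFit,
    n_occasions: int,
    profile: dict[str, float] | None = None,
    x_row: np.ndarray | None = None,
) -> tuple[float, float]:
    """Cumulative survival phi^n at a covariate profile, with delta-method SE.

    ``x_row`` is the design row (on the fitting scale); default is the
    intercept-only row.  SE propagates the coefficient covariance through
    the logit link and the power.
    """
    if x_row is None:
        x_row = np.zeros(len(fit_.betas))
        x_row[0] = 1.0
        if profile:
            for j, name in enumerate(fit_.names):
                if name in profile:
                    val = profile[name]
                    if name in fit_.scaling:
                        mean, sd = fit_.scaling[name]
                        val = (val - mean) / sd
                    x_row[j] = val
    x_row = np.asarray(x_row, dtype=float)
    phi = float(expit(x_row @ fit_.betas))
    surv = phi**n_occasions
    if fit_.boundary or not np.all(np.isfinite(fit_.vcov)):
        return surv, 0.0 if fit_.boundary else float("nan")
    # d(phi^n)/dbeta = n phi^(n-1) * phi(1-phi) * x
    g = n_occasions * phi ** (n_occasions - 1) * phi * (1 - phi) * x_row
    var = float(g @ fit_.vcov @ g)
    return surv, float(np.sqrt(max(var, 0.0)))


def aicc(loglik_: float, K: int, n_eff: int) -> float:
    """Small-sample-corrected AIC: -2 logL + 2K + 2K(K+1)/(n_eff - K - 1)."""
    if n_eff <= K + 1:
        return float("nan")
    return -2.0 * loglik_ + 2.0 * K + 2.0 * K * (K + 1) / (n_eff - K - 1)


def model_table(
    histories: list[EncounterHistory],
    formulas: dict[str, str],
    standardize: bool = True,
) -> tuple[pd.DataFrame, dict[str, KnownFateFit]]:
    """Fit a candidate model set and rank by AICc.

    Returns the ranking table (model, K, loglik, AICc, delta_aicc, weight,
    support at delta < 2) and the fitted models.  Models that fail are
    listed with their failure reason and excluded from the ranking.
    """
    if len(formulas) < 2:
        raise ValueError("need at least two candidate models")
    rows, fits = [], {}
    for name, f in formulas.items():
        try:
            kf = fit(histories, f, standardize=standardize)
        except Exception as exc:  # noqa: BLE001 — converge/rank failures reported per row
            rows.append({"model": name, "formula": f, "K": np.nan, "loglik": np.nan,
                         "aicc": np.nan, "failure": str(exc)})
            continue
        fits[name] = kf
        rows.append({"model": name, "formula": f, "K": kf.K, "loglik": kf.loglik,
                     "aicc": kf.aicc, "failure": ""})
    tab = pd.DataFrame(rows)
    ok = tab["failure"] == ""
    best = tab.loc[ok, "aicc"].min()
    tab["delta_aicc"] = np.where(ok, tab["aicc"] - best, np.nan)
    rel = np.exp(-0.5 * tab.loc[ok, "delta_aicc"])
    tab.loc[ok, "weight"] = rel / rel.sum()
    tab["support"] = ok & (tab["delta_aicc"] < 2.0)
    return tab.sort_values("aicc", na_position="last").reset_index(drop=True), fits
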