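"""Model-variant selection: BIC evidence, random-effects group inference, fit quality.

Group inference treats the preferred variant as a random effect across
subjects: a variational Dirichlet posterior over group model frequencies is
estimated from per-subject model posteriors, exceedance probabilities (EP)
are obtained by Monte-Carlo sampling of that Dirichlet, the Bayesian omnibus
risk (BOR) is the posterior probability that all model frequencies are equal
(from the free-energy Bayes factor against the equal-frequency null), and the
protected exceedance probability is PXP_k = EP_k·(1−BOR) + BOR/M.

Goodness of fit uses Nagelkerke's likelihood-based R² against a uniform-
response null, with the correction that makes a perfect discrete predictor
reach exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, psi, logsumexp
from scipy.stats import beta as beta_dist

__all__ = [
    "bic",
    "EvidenceTable",
    "subject_posteriors",
    "RfxResult",
    "rfx_group_inference",
    "exceedance_probability_two_models",
    "GoodnessOfFit",
    "nagelkerke_r2",
]

N_FITTED_PARAMS = 3  # Γ, S, ε — identical for every variant


def bic(log_likelihood: float, n: int, rho: int = N_FITTED_PARAMS) -> float:
    """Bayesian information criterion ρ·ln(N) − 2·logL (lower = better)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return rho * float(np.log(n)) - 2.0 * float(log_likelihood)


@dataclass
class EvidenceTable:
    """Per subject × variant evidence feeding the group inference.

    ``bic`` is a (subjects × variants) DataFrame; rows must be complete
    (subjects excluded by the convergence criterion are simply absent).
    """

    bic: pd.DataFrame
    log_likelihood: pd.DataFrame | None = None
    n_trials: pd.Series | None = None
    rho: int = N_FITTED_PARAMS

    def __post_init__(self):
        if self.bic.isna().any().any():
            raise ValueError("evidence table must contain complete rows only")
        if not np.all(np.isfinite(self.bic.to_numpy())):
            raise ValueError("BIC values must be finite")

    @classmethod
    def from_fits(cls, fit_frame: pd.DataFrame, rho: int = N_FITTED_PARAMS,
                  exclude_boundary: bool = True) -> "EvidenceTable":
        """Build from a fit ledger (see :func:`sagloc.fitting.fits_to_frame`).

        A subject is dropped entirely if any variant's fit hit a parameter
        bound — the exclusion criterion of the comparison.
        """
        df = fit_frame.copy()
        ok_cols = [c for c in ("gamma_ok", "s_ok", "epsilon_ok") if c in df]
        if exclude_boundary and ok_cols:
            bad = df.loc[~df[ok_cols].all(axis=1), "subject_id"].unique()
            df = df[~df["subject_id"].isin(bad)]
        if df.empty:
            raise ValueError("no subjects left after boundary exclusion")
        df["bic"] = [bic(l, n, rho) for l, n in zip(df["log_likelihood"], df["n_trials"])]
        bic_tab = df.pivot(index="subject_id", columns="scheme", values="bic")
        ll_tab = df.pivot(index="subject_id", columns="scheme", values="log_likelihood")
        n_tab = df.groupby("subject_id")["n_trials"].first()
        return cls(bic_tab, ll_tab, n_tab, rho)

    @property
    def variants(self) -> list[str]:
        return list(self.bic.columns)


def subject_posteriors(evidence: EvidenceTable | pd.DataFrame,
                       mode: str = "standard") -> pd.DataFrame:
    """Per-subject posterior over variants from BIC evidence.

    ``standard`` (default): posterior ∝ exp(−BIC/2), the usual Laplace-style
    evidence approximation.  ``printed_ratio``: BIC_k / Σ_m BIC_m, a
    compatibility normalization that assigns larger posterior to the *larger*
    (worse) BIC and is close to uniform for large BIC — provided only for
    comparison with analyses that used it.
    """
    tab = evidence.bic if isinstance(evidence, EvidenceTable) else evidence
    if tab.shape[1] < 2:
        raise ValueError("need at least two variants to compare")
    x = tab.to_numpy(dtype=float)
    if mode == "standard":
        z = -0.5 * (x - x.min(axis=1, keepdims=True))
        p = np.exp(z)
    elif mode == "printed_ratio":
        p = x.copy()
        if np.any(p < 0):
            raise ValueError("printed_ratio mode requires non-negative BICs")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = p / p.sum(axis=1, keepdims=True)
    return pd.DataFrame(p, index=tab.index, columns=tab.columns)


@dataclass
class RfxResult:
    """Random-effects group inference summary."""

    variants: list
    alpha: np.ndarray                 # Dirichlet posterior over frequencies
    expected_frequencies: np.ndarray
    ep: np.ndarray                    # exceedance probabilities
    bor: float                        # Bayesian omnibus risk
    pxp: np.ndarray                   # protected exceedance probabilities
    subject_posteriors: pd.DataFrame  # refined per-subject assignments
    free_energy: float
    null_free_energy: float
    n_samples: int
    seed: int | None

    def to_dict(self) -> dict:
        return {"variants": list(self.variants),
                "alpha": self.alpha.tolist(),
                "expected_frequencies": self.expected_frequencies.tolist(),
                "ep": self.ep.tolist(), "bor": float(self.bor),
                "pxp": self.pxp.tolist(),
                "best_variant": str(self.variants[int(np.argmax(self.pxp))]),
                "per_subject_best": {
                    str(s): str(self.subject_posteriors.loc[s].idxmax())
                    for s in self.subject_posteriors.index},
                "n_samples": self.n_samples, "seed": self.seed}


def _vb_dirichlet(log_ev: np.ndarray, alpha0: float, max_iter: int, tol: float):
    n, m = log_ev.shape
    alpha = np.full(m, alpha0, dtype=float)
    u = np.full((n, m), 1.0 / m)
    for _ in range(max_iter):
        elog_r = psi(alpha) - psi(alpha.sum())
        log_u = log_ev + elog_r[None, :]
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u


def _free_energy(log_ev, u, alpha, alpha0_vec):
    """Variational free energy of the random-effects model."""
    elog_r = psi(alpha) - psi(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ulogu = np.where(u > 0, u * np.log(u), 0.0)
    f = float((u * (log_ev + elog_r[None, :])).sum() - ulogu.sum())
    f += float(gammaln(alpha0_vec.sum()) - gammaln(alpha0_vec).sum()
               + ((alpha0_vec - 1.0) * elog_r).sum())
    f -= float(gammaln(alpha.sum()) - gammaln(alpha).sum()
               + ((alpha - 1.0) * elog_r).sum())
    return f


def rfx_group_inference(posteriors: pd.DataFrame | np.ndarray,
                        n_samples: int = 1_000_000, seed: int | None = 0,
                        alpha0: float = 1.0, max_iter: int = 200,
                        tol: float = 1e-6) -> RfxResult:
    """Random-effects Bayesian model selection across subjects.

    Parameters
    ----------
    posteriors
        (subjects × variants) per-subject model posteriors (rows sum to 1).
    n_samples
        Dirichlet Monte-Carlo samples for the exceedance probabilities.
    """
    if isinstance(posteriors, pd.DataFrame):
        variants, index = list(posteriors.columns), posteriors.index
        p = posteriors.to_numpy(dtype=float)
    else:
        p = np.asarray(posteriors, dtype=float)
        variants = list(range(p.shape[1]))
        index = pd.RangeIndex(p.shape[0])
    if p.ndim != 2 or p.shape[0] < 2 or p.shape[1] < 2:
        raise ValueError("need at least two subjects and two variants")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p.sum(axis=1) <= 0):
        raise ValueError("degenerate subject posteriors")
    p = p / p.sum(axis=1, keepdims=True)
    n, m = p.shape

    log_ev = np.log(np.maximum(p, 1e-300))
    alpha0_vec = np.full(m, float(alpha0))
    alpha, u = _vb_dirichlet(log_ev, alpha0, max_iter, tol)

    f1 = _free_energy(log_ev, u, alpha, alpha0_vec)
    # null model: frequencies fixed and equal -> exact marginal likelihood
    f0 = float(logsumexp(log_ev, axis=1).sum() - n * np.log(m))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))

    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=int(n_samples))
    ep = np.bincount(np.argmax(samples, axis=1), minlength=m) / float(n_samples)

    pxp = ep * (1.0 - bor) + bor / m
    return RfxResult(variants=variants, alpha=alpha,
                     expected_frequencies=alpha / alpha.sum(), ep=ep, bor=bor,
                     pxp=pxp,
                     subject_posteriors=pd.DataFrame(u, index=index, columns=variants),
                     free_energy=f1, null_free_energy=f0,
                     n_samples=int(n_samples), seed=seed)


def exceedance_probability_two_models(alpha: np.ndarray) -> np.ndarray:
    """Analytic EP for exactly two variants: Beta tail beyond 1/2."""
    a = np.asarray(alpha, dtype=float)
    if a.shape != (2,):
        raise ValueError("analytic EP is defined for exactly two variants")
    ep1 = beta_dist.sf(0.5, a[0], a[1])
    return np.array([ep1, 1.0 - ep1])


@dataclass(frozen=True)
class GoodnessOfFit:
    """Nagelkerke's likelihood R² and its discrete-model correction R̄²."""

    r2: float
    r2_corrected: float


def nagelkerke_r2(log_likelihood_model: float, log_likelihood_null: float,
                  n: int) -> GoodnessOfFit:
    """R² = 1 − exp[−(2/N)(logL − logL₀)]; R̄² = R² / (1 − exp[(2/N)·logL₀]).

    R̄² is 0 when the model matches the uniform null and exactly 1 for a
    perfect discrete predictor (logL = 0).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    lm, l0 = float(log_likelihood_model), float(log_likelihood_null)
    r2 = 1.0 - np.exp(-(2.0 / n) * (lm - l0))
    denom = 1.0 - np.exp((2.0 / n) * l0)
    return GoodnessOfFit(float(r2), float(r2 / denom))
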