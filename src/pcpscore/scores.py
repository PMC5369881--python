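"""The PCP score and the multiplicative power-law model behind it.

The prostate-cancer predictor (PCP) combines the three serum PSA fractions
multiplicatively::

    PCP = tPSA / fPSA * sqrt(cPSA)

which is the member ``alpha * X^a * Y^b * Z^c`` of the power family
(X = tPSA, Y = fPSA, Z = cPSA) with ``alpha = 1`` and exponents
``(a, b, c) = (1, -1, 0.5)``.  The exponents are estimated from labelled
data by maximum likelihood: a logistic model for P(PCa) whose linear
predictor is linear in the log-markers, fitted by iteratively reweighted
least squares (IRLS).  Because ROC ranking is invariant under strictly
increasing transforms, the exponents are identified up to a positive
scaling; :func:`canonicalize_exponents` fixes the tPSA exponent to 1 and
snaps to a half-integer grid, which reproduces the published form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .cohort import BPH, PCA, Cohort, PatientRecord

__all__ = [
    "PowerModelSpec",
    "PCP_SPEC",
    "StabilityReport",
    "compute_pcp",
    "compute_pct_fpsa",
    "derive_cpsa",
    "power_score",
    "score_power_model",
    "fit_power_model",
    "fit_power_exponents",
    "canonicalize_exponents",
    "exponent_stability",
    "logistic_irls",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PowerModelSpec:
    """Coefficient and exponents of ``alpha * tpsa^a * fpsa^b * cpsa^c``."""

    alpha: float
    exp_tpsa: float
    exp_fpsa: float
    exp_cpsa: float
    canonical: bool = False
    status: str = "ok"  # "ok" | "separation" | "noncanonical"

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if not all(
            np.isfinite([self.exp_tpsa, self.exp_fpsa, self.exp_cpsa])
        ):
            raise ValueError("exponents must be finite")

    @property
    def exponents(self) -> np.ndarray:
        return np.array([self.exp_tpsa, self.exp_fpsa, self.exp_cpsa])

    def to_json_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "a": self.exp_tpsa,
            "b": self.exp_fpsa,
            "c": self.exp_cpsa,
            "canonical": self.canonical,
            "status": self.status,
        }

    @classmethod
    def from_json_dict(cls, doc: dict) -> "PowerModelSpec":
        return cls(
            alpha=doc["alpha"],
            exp_tpsa=doc["a"],
            exp_fpsa=doc["b"],
            exp_cpsa=doc["c"],
            canonical=doc.get("canonical", False),
            status=doc.get("status", "ok"),
        )


#: The published score: PCP = tPSA/fPSA * sqrt(cPSA).
PCP_SPEC = PowerModelSpec(1.0, 1.0, -1.0, 0.5, canonical=True)


def compute_pcp(tpsa, fpsa, cpsa):
    """PCP = tPSA / fPSA * sqrt(cPSA); vectorized, dimensionless.

    Strictly increasing in tPSA and cPSA, strictly decreasing in fPSA.
    """
    tpsa, fpsa, cpsa = np.asarray(tpsa, float), np.asarray(fpsa, float), np.asarray(cpsa, float)
    if np.any(fpsa <= 0):
        raise ValueError("fpsa must be positive")
    if np.any(cpsa < 0):
        raise ValueError("cpsa must be non-negative")
    out = tpsa / fpsa * np.sqrt(cpsa)
    return float(out) if out.ndim == 0 else out


def compute_pct_fpsa(fpsa, tpsa):
    """Free-to-total ratio %fPSA = fPSA / tPSA, in (0, 1)."""
    fpsa, tpsa = np.asarray(fpsa, float), np.asarray(tpsa, float)
    if np.any(tpsa <= 0):
        raise ValueError("tpsa must be positive")
    if np.any(fpsa <= 0) or np.any(fpsa >= tpsa):
        raise ValueError("requires 0 < fpsa < tpsa")
    out = fpsa / tpsa
    return float(out) if out.ndim == 0 else out


def derive_cpsa(tpsa, fpsa):
    """cPSA = tPSA - fPSA (complexed + free fractions sum to the total)."""
    tpsa, fpsa = np.asarray(tpsa, float), np.asarray(fpsa, float)
    if np.any(fpsa <= 0) or np.any(fpsa >= tpsa):
        raise ValueError("requires 0 < fpsa < tpsa")
    out = tpsa - fpsa
    return float(out) if out.ndim == 0 else out


def power_score(tpsa, fpsa, cpsa, spec: PowerModelSpec):
    """``alpha * tpsa^a * fpsa^b * cpsa^c`` for arrays or scalars."""
    tpsa, fpsa, cpsa = np.asarray(tpsa, float), np.asarray(fpsa, float), np.asarray(cpsa, float)
    if np.any((cpsa == 0) & (spec.exp_cpsa < 0)):
        raise ValueError("cpsa = 0 with a negative cPSA exponent")
    if (spec.alpha, spec.exp_tpsa, spec.exp_fpsa, spec.exp_cpsa) == (1.0, 1.0, -1.0, 0.5):
        # evaluate the published score in its printed form so both paths
        # agree bit-for-bit
        return compute_pcp(tpsa, fpsa, cpsa)
    out = (
        spec.alpha
        * tpsa ** spec.exp_tpsa
        * fpsa ** spec.exp_fpsa
        * cpsa ** spec.exp_cpsa
    )
    return float(out) if out.ndim == 0 else out


def score_power_model(record, spec: PowerModelSpec):
    """Score one record or a whole cohort under a power-model spec."""
    if isinstance(record, PatientRecord):
        return power_score(record.tpsa, record.fpsa, record.cpsa, spec)
    if isinstance(record, Cohort):
        return power_score(
            record.marker("tpsa"), record.marker("fpsa"), record.marker("cpsa"), spec
        )
    raise TypeError("expected PatientRecord or Cohort")


# ---------------------------------------------------------------------------
# Maximum-likelihood estimation of the exponents
# ---------------------------------------------------------------------------

def logistic_irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    penalize_intercept: bool = False,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Logistic regression by iteratively reweighted least squares.

    ``X`` includes the intercept column first.  An optional ridge penalty
    (on the non-intercept coefficients unless ``penalize_intercept``)
    stabilizes near-collinear designs.  Returns ``(beta, cov, converged,
    separated)`` where ``cov`` is the inverse penalized Fisher information
    and ``separated`` flags (quasi-)complete separation, detected as fitted
    log-odds escaping beyond +-30 while classifying perfectly.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    pen = np.full(p, ridge)
    if not penalize_intercept:
        pen[0] = 0.0
    beta = np.zeros(p)
    converged = separated = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -700, 700)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu) - pen * beta
        H = (X.T * w) @ X + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            H = H + np.eye(p) * 1e-8
            step = np.linalg.solve(H, grad)
        # dampen huge Newton steps (separation drives |beta| to infinity)
        norm = np.linalg.norm(step)
        if norm > 50:
            step *= 50 / norm
        beta = beta + step
        if np.linalg.norm(step) < tol * (1 + np.linalg.norm(beta)):
            converged = True
            break
        if np.max(np.abs(X @ beta)) > 30:
            eta = X @ beta
            if np.all((eta > 0) == (y > 0.5)):
                separated = True
                break
    eta = np.clip(X @ beta, -700, 700)
    # ridge can pin a separable fit at a finite optimum; a fit that
    # classifies every training point correctly means the data are
    # linearly separable, so flag it regardless of |beta|
    if not separated and np.all(eta != 0) and np.all((eta > 0) == (y > 0.5)):
        separated = True
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X.T * w) @ X + np.diag(pen)
    cov = np.linalg.pinv(H)
    return beta, cov, converged, separated


def fit_power_exponents(
    tpsa, fpsa, cpsa, labels, ridge: float = 1e-4
) -> PowerModelSpec:
    """ML fit of the power-model exponents on raw marker arrays.

    Fits the logistic model with linear predictor ``b0 + a log tpsa +
    b log fpsa + c log cpsa`` by IRLS and returns ``alpha = exp(b0)``
    with the raw (unrounded) exponents.  Rows outside the log domain
    (non-positive markers, fpsa >= tpsa) are dropped with a logged count.
    A small ridge penalty (default 1e-4, never on the intercept) guards
    against the near-collinearity induced by the additive constraint
    cPSA ~ tPSA - fPSA.  Complete separation is flagged via
    ``status='separation'``.
    """
    t = np.asarray(tpsa, float)
    f = np.asarray(fpsa, float)
    c = np.asarray(cpsa, float)
    y = np.asarray(labels, int)
    ok = (t > 0) & (f > 0) & (f < t) & (c > 0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info(
            "fit_power_exponents: dropped %d records outside the log domain",
            n_dropped,
        )
    y = y[ok]
    if len(np.unique(y)) < 2:
        raise ValueError("need both diagnosis classes")
    X = np.column_stack(
        [np.ones(ok.sum()), np.log(t[ok]), np.log(f[ok]), np.log(c[ok])]
    )
    beta, _, _, separated = logistic_irls(X, y, ridge=ridge)
    return PowerModelSpec(
        alpha=float(np.exp(np.clip(beta[0], -700, 700))),
        exp_tpsa=float(beta[1]),
        exp_fpsa=float(beta[2]),
        exp_cpsa=float(beta[3]),
        canonical=False,
        status="separation" if separated else "ok",
    )


def fit_power_model(cohort: Cohort, ridge: float = 1e-4) -> PowerModelSpec:
    """ML fit of the power-model exponents for a labelled cohort.

    See :func:`fit_power_exponents` for the model and its numerics; the
    diagnosis labels are taken from the cohort (PCa = 1).
    """
    return fit_power_exponents(
        cohort.marker("tpsa"),
        cohort.marker("fpsa"),
        cohort.marker("cpsa"),
        cohort.labels(),
        ridge=ridge,
    )


def canonicalize_exponents(
    spec: PowerModelSpec, grid: float = 0.5
) -> PowerModelSpec:
    """Rescale so the tPSA exponent is 1, drop alpha, snap to a grid.

    Positive rescaling and the coefficient leave the ROC ordering of the
    score unchanged, so the canonical form is score-equivalent to the raw
    fit up to the rounding step.  If the tPSA exponent is 0 the spec
    cannot be normalized and is returned unrounded with
    ``status='noncanonical'``.
    """
    if spec.exp_tpsa == 0:
        return replace(spec, status="noncanonical")

    def snap(x: float) -> float:
        return round(x / grid) * grid

    s = spec.exp_tpsa
    return PowerModelSpec(
        alpha=1.0,
        exp_tpsa=snap(1.0),
        exp_fpsa=snap(spec.exp_fpsa / s),
        exp_cpsa=snap(spec.exp_cpsa / s),
        canonical=True,
        status=spec.status,
    )


@dataclass(frozen=True)
class StabilityReport:
    """Bootstrap stability of the fitted exponents.

    ``samples`` holds the raw per-resample exponents (B x 3, columns a, b,
    c); ``canonical_match_rate`` is the fraction of resamples whose
    canonical exponents equal the published (1, -1, 0.5).
    """

    samples: np.ndarray
    n_requested: int
    n_failed: int
    seed: int
    canonical_match_rate: float
    grid: float = 0.5

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.samples.std(axis=0, ddof=1) if len(self.samples) > 1 else np.zeros(3)

    def percentile_interval(self, level: float = 0.95) -> np.ndarray:
        lo = (1 - level) / 2 * 100
        return np.percentile(self.samples, [lo, 100 - lo], axis=0)


def exponent_stability(
    data: Cohort | tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    B: int = 200,
    seed: int = 0,
    ridge: float = 1e-4,
    grid: float = 0.5,
) -> StabilityReport:
    """Refit the power model on B stratified bootstrap resamples.

    ``data`` is either a labelled :class:`Cohort` or a ``(tpsa, fpsa,
    cpsa, labels)`` tuple of aligned arrays.  Resampling is within
    diagnosis class so every resample keeps both classes.  Resamples that
    fail to fit (separation) are excluded and counted.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if isinstance(data, Cohort):
        t, f, c = (data.marker(m) for m in ("tpsa", "fpsa", "cpsa"))
        y = data.labels()
    else:
        t, f, c, y = (np.asarray(v) for v in data)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    if len(idx_pos) == 0 or len(idx_neg) == 0:
        raise ValueError("need both diagnosis classes")
    samples = []
    matches = 0
    n_failed = 0
    target = PCP_SPEC.exponents
    for _ in range(B):
        take = np.concatenate(
            [rng.choice(idx_pos, len(idx_pos)), rng.choice(idx_neg, len(idx_neg))]
        )
        spec = fit_power_exponents(t[take], f[take], c[take], y[take], ridge=ridge)
        if spec.status == "separation":
            n_failed += 1
            continue
        samples.append(spec.exponents)
        canon = canonicalize_exponents(spec, grid=grid)
        if np.allclose(canon.exponents, target):
            matches += 1
    if not samples:
        raise RuntimeError("all bootstrap refits failed")
    samples = np.vstack(samples)
    return StabilityReport(
        samples=samples,
        n_requested=B,
        n_failed=n_failed,
        seed=seed,
        canonical_match_rate=matches / len(samples),
        grid=grid,
    )
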