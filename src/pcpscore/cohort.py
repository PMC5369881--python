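"""Synthetic patient cohorts for PSA-based prostate-cancer prediction studies.

The generator emulates a biopsy-confirmed clinical cohort of men with total
PSA between 2 and 20 ng/mL, split into two strata ([2, 10) and [10, 20)
ng/mL) and two diagnosis groups (prostate cancer, PCa, vs benign prostatic
hyperplasia, BPH).  Within each group, total PSA (tPSA) follows a lognormal
distribution truncated to the stratum bounds; the free-to-total ratio
(%fPSA) follows a Beta distribution on (0, 1); free PSA is fPSA =
%fPSA x tPSA and complexed PSA is cPSA = tPSA - fPSA up to a small
multiplicative noise, reflecting that the complexed and free fractions sum
to the total only approximately.

Group medians are matched to a reference cohort via
:func:`calibrate_generator`, which solves for the tPSA log-location and the
%fPSA Beta mean deterministically and then verifies the result by
simulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PCA",
    "BPH",
    "GROUPS",
    "DEFAULT_STRATA",
    "DEFAULT_COUNTS",
    "REFERENCE_MEDIANS",
    "ADDITIVITY_RTOL",
    "PatientRecord",
    "GroupParams",
    "GeneratorConfig",
    "Cohort",
    "CohortError",
    "CalibrationError",
    "default_config",
    "generate_cohort",
    "calibrate_generator",
    "calibrated_config",
    "stratify",
    "scale_counts",
    "relabel_by_logit",
    "sample_power_direction",
]

log = logging.getLogger(__name__)

PCA = "PCa"
BPH = "BPH"
GROUPS = (PCA, BPH)

#: Half-open tPSA strata in ng/mL: [2, 10) and [10, 20).
DEFAULT_STRATA: tuple[tuple[float, float], ...] = ((2.0, 10.0), (10.0, 20.0))

#: Per-group subject counts per stratum in the reference clinical cohort.
DEFAULT_COUNTS: dict[str, tuple[int, ...]] = {PCA: (54, 48), BPH: (579, 147)}

#: Group-wise marker medians of the reference cohort (tPSA/fPSA/cPSA in
#: ng/mL, %fPSA dimensionless).  These are the calibration targets for the
#: default generator; the PCP score median is deliberately not among them.
REFERENCE_MEDIANS: dict[str, dict[str, float]] = {
    PCA: {"tpsa": 9.2, "fpsa": 1.0, "cpsa": 8.0, "pct_fpsa": 0.13},
    BPH: {"tpsa": 5.5, "fpsa": 1.0, "cpsa": 4.4, "pct_fpsa": 0.19},
}

#: Tolerated relative departure of fPSA + cPSA from tPSA.
ADDITIVITY_RTOL = 0.05


class CohortError(ValueError):
    """Invalid cohort, record, or generator configuration."""


class CalibrationError(RuntimeError):
    """Median calibration failed; carries per-marker diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class PatientRecord:
    """One subject: serum PSA fractions (ng/mL) plus diagnosis label.

    Invariants: ``tpsa > 0``, ``0 < fpsa < tpsa``, ``cpsa > 0`` and
    ``|fpsa + cpsa - tpsa| <= 0.05 * tpsa`` (the free and complexed
    fractions sum to the total within assay tolerance).
    """

    id: str
    age: float
    diagnosis: str
    tpsa: float
    fpsa: float
    cpsa: float

    def __post_init__(self) -> None:
        if self.diagnosis not in GROUPS:
            raise CohortError(f"unknown diagnosis label {self.diagnosis!r}")
        if self.age <= 0:
            raise CohortError(f"record {self.id}: non-positive age")
        if not (self.tpsa > 0 and 0 < self.fpsa < self.tpsa and self.cpsa > 0):
            raise CohortError(
                f"record {self.id}: marker triplet "
                f"({self.tpsa}, {self.fpsa}, {self.cpsa}) violates "
                "0 < fpsa < tpsa, cpsa > 0"
            )
        if abs(self.fpsa + self.cpsa - self.tpsa) > ADDITIVITY_RTOL * self.tpsa:
            raise CohortError(
                f"record {self.id}: fpsa + cpsa departs from tpsa by more "
                f"than {ADDITIVITY_RTOL:.0%}"
            )


@dataclass(frozen=True)
class GroupParams:
    """Distribution parameters for one diagnosis group.

    ``log_loc``/``log_scale`` parameterize the parent lognormal of tPSA
    (one pair per stratum; the same parent is typically shared and only the
    truncation differs).  ``pct_fpsa_mean``/``pct_fpsa_conc`` are the Beta
    mean/concentration of the free-to-total ratio.
    """

    log_loc: tuple[float, ...]
    log_scale: tuple[float, ...]
    pct_fpsa_mean: float
    pct_fpsa_conc: float

    def __post_init__(self) -> None:
        if len(self.log_loc) != len(self.log_scale):
            raise CohortError("log_loc and log_scale lengths differ")
        if any(s <= 0 for s in self.log_scale):
            raise CohortError("log_scale must be positive")
        if not 0 < self.pct_fpsa_mean < 1 or self.pct_fpsa_conc <= 0:
            raise CohortError("%fPSA Beta parameters outside (0,1)/positive")

    def beta_ab(self) -> tuple[float, float]:
        m, k = self.pct_fpsa_mean, self.pct_fpsa_conc
        return m * k, (1.0 - m) * k


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort draw (seed mandatory)."""

    seed: int
    strata: tuple[tuple[float, float], ...] = DEFAULT_STRATA
    counts: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS)
    )
    params: Mapping[str, GroupParams] = field(default_factory=dict)
    additivity_noise: float = 0.02
    age_mean: float = 71.6
    age_sd: float = 7.0
    age_min: float = 40.0

    def __post_init__(self) -> None:
        for lo, hi in self.strata:
            if not 0 < lo < hi:
                raise CohortError(f"invalid stratum bounds ({lo}, {hi})")
        for group, ns in self.counts.items():
            if group not in GROUPS:
                raise CohortError(f"unknown group {group!r}")
            if len(ns) != len(self.strata) or any(n < 0 for n in ns):
                raise CohortError("counts must be non-negative, one per stratum")
        if not 0 <= self.additivity_noise <= ADDITIVITY_RTOL:
            raise CohortError(
                f"additivity noise must lie in [0, {ADDITIVITY_RTOL}]"
            )

    # -- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "seed": int(self.seed),
            "strata": [list(b) for b in self.strata],
            "counts": {g: list(map(int, ns)) for g, ns in self.counts.items()},
            "params": {
                g: {
                    "log_loc": list(p.log_loc),
                    "log_scale": list(p.log_scale),
                    "pct_fpsa_mean": p.pct_fpsa_mean,
                    "pct_fpsa_conc": p.pct_fpsa_conc,
                }
                for g, p in self.params.items()
            },
            "additivity_noise": self.additivity_noise,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_min": self.age_min,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        doc = json.loads(text)
        return cls(
            seed=doc["seed"],
            strata=tuple(tuple(b) for b in doc["strata"]),
            counts={g: tuple(ns) for g, ns in doc["counts"].items()},
            params={
                g: GroupParams(
                    log_loc=tuple(p["log_loc"]),
                    log_scale=tuple(p["log_scale"]),
                    pct_fpsa_mean=p["pct_fpsa_mean"],
                    pct_fpsa_conc=p["pct_fpsa_conc"],
                )
                for g, p in doc["params"].items()
            },
            additivity_noise=doc["additivity_noise"],
            age_mean=doc["age_mean"],
            age_sd=doc["age_sd"],
            age_min=doc["age_min"],
        )


class Cohort:
    """An ordered collection of :class:`PatientRecord` with stratum bounds."""

    def __init__(
        self,
        records: Iterable[PatientRecord],
        strata: Sequence[tuple[float, float]] = DEFAULT_STRATA,
    ):
        self.records: list[PatientRecord] = list(records)
        self.strata = tuple(tuple(b) for b in strata)
        for rec in self.records:
            if not any(lo <= rec.tpsa < hi for lo, hi in self.strata):
                raise CohortError(
                    f"record {rec.id}: tpsa {rec.tpsa} outside strata "
                    f"{self.strata}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Cohort)
            and self.strata == other.strata
            and self.records == other.records
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "age": [r.age for r in self.records],
                "diagnosis": [r.diagnosis for r in self.records],
                "tpsa": [r.tpsa for r in self.records],
                "fpsa": [r.fpsa for r in self.records],
                "cpsa": [r.cpsa for r in self.records],
            }
        )

    def labels(self, positive: str = PCA) -> np.ndarray:
        """0/1 outcome vector (1 = ``positive`` diagnosis)."""
        return np.array([r.diagnosis == positive for r in self.records], int)

    def marker(self, name: str) -> np.ndarray:
        return np.array([getattr(r, name) for r in self.records], float)


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def _trunc_lognorm_sample(
    rng: np.random.Generator,
    n: int,
    mu: float,
    sigma: float,
    lo: float,
    hi: float,
) -> np.ndarray:
    """Inverse-CDF draw from lognormal(mu, sigma) truncated to [lo, hi)."""
    a = stats.norm.cdf((np.log(lo) - mu) / sigma)
    b = stats.norm.cdf((np.log(hi) - mu) / sigma)
    if b - a < 1e-9:
        raise CohortError(
            f"truncation mass ~0 for lognormal({mu:.3g}, {sigma:.3g}) "
            f"on [{lo}, {hi})"
        )
    u = rng.uniform(a, b, size=n)
    x = np.exp(mu + sigma * stats.norm.ppf(u))
    # inverse-CDF round-off can land exactly on the open upper bound
    return np.clip(x, lo, np.nextafter(hi, lo))


def _trunc_lognorm_cdf(x, mu, sigma, lo, hi):
    a = stats.norm.cdf((np.log(lo) - mu) / sigma)
    b = stats.norm.cdf((np.log(hi) - mu) / sigma)
    if b - a < 1e-12:
        return np.where(np.asarray(x) >= hi, 1.0, 0.0)
    z = stats.norm.cdf((np.log(np.clip(x, lo, hi)) - mu) / sigma)
    return (z - a) / (b - a)


def default_config(seed: int = 0) -> GeneratorConfig:
    """Reference-cohort configuration, calibrated at import cost zero.

    The tPSA log-locations are the deterministic solutions of
    :func:`calibrate_generator` for the reference medians with
    ``log_scale = 0.5`` and ``pct_fpsa_conc = 15``; they are recomputed
    on the fly (cheap closed-form root finding, no simulation).
    """
    cfg = GeneratorConfig(seed=seed, params=_solve_params(REFERENCE_MEDIANS))
    return cfg


DEFAULT_LOG_SCALE = 0.5
DEFAULT_PCT_FPSA_CONC = 15.0


def _solve_group_mu(
    target_median: float,
    sigma: float,
    strata: Sequence[tuple[float, float]],
    counts: Sequence[int],
) -> float:
    """Log-location whose stratum-count-weighted mixture median hits target."""
    w = np.asarray(counts, float)
    if w.sum() == 0:
        raise CalibrationError("cannot calibrate a group with zero count")
    w = w / w.sum()

    def pooled_cdf_minus_half(mu: float) -> float:
        acc = 0.0
        for wi, (lo, hi) in zip(w, strata):
            acc += wi * float(_trunc_lognorm_cdf(target_median, mu, sigma, lo, hi))
        return acc - 0.5

    lo_all = min(lo for lo, _ in strata)
    hi_all = max(hi for _, hi in strata)
    return optimize.brentq(
        pooled_cdf_minus_half, np.log(lo_all) + 0.05, np.log(hi_all) + 1.5
    )


def _solve_beta_mean(target_median: float, conc: float) -> float:
    """Beta mean whose median (at given concentration) equals the target."""
    if not 0 < target_median < 0.9:
        raise CalibrationError(
            f"%fPSA median target {target_median} outside (0, 0.9); a ratio "
            "near 1 implies cPSA near 0, violating record invariants"
        )

    def med_err(m: float) -> float:
        return stats.beta.ppf(0.5, m * conc, (1 - m) * conc) - target_median

    return optimize.brentq(med_err, 1e-4, 0.95)


def _solve_params(
    targets: Mapping[str, Mapping[str, float]],
    strata: Sequence[tuple[float, float]] = DEFAULT_STRATA,
    counts: Mapping[str, Sequence[int]] | None = None,
    log_scale: float = DEFAULT_LOG_SCALE,
    conc: float = DEFAULT_PCT_FPSA_CONC,
) -> dict[str, GroupParams]:
    counts = counts or DEFAULT_COUNTS
    out = {}
    for group, med in targets.items():
        mu = _solve_group_mu(med["tpsa"], log_scale, strata, counts[group])
        m = _solve_beta_mean(med["pct_fpsa"], conc)
        out[group] = GroupParams(
            log_loc=tuple(mu for _ in strata),
            log_scale=tuple(log_scale for _ in strata),
            pct_fpsa_mean=m,
            pct_fpsa_conc=conc,
        )
    return out


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a cohort with exactly the configured per-group/stratum counts.

    Deterministic for a fixed config (the seed is part of the config).
    """
    rng = np.random.default_rng(config.seed)
    records: list[PatientRecord] = []
    for group in GROUPS:
        if group not in config.counts:
            continue
        if group not in config.params:
            raise CohortError(f"no distribution parameters for group {group}")
        p = config.params[group]
        for si, ((lo, hi), n) in enumerate(zip(config.strata, config.counts[group])):
            if n == 0:
                continue
            t = _trunc_lognorm_sample(rng, n, p.log_loc[si], p.log_scale[si], lo, hi)
            a_, b_ = p.beta_ab()
            r = rng.beta(a_, b_, size=n)
            f = r * t
            eps = rng.uniform(-config.additivity_noise, config.additivity_noise, n)
            c = (t - f) * (1.0 + eps)
            age = _truncated_normal_age(rng, n, config)
            for j in range(n):
                records.append(
                    PatientRecord(
                        id=f"{group}-s{si}-{j:05d}",
                        age=float(age[j]),
                        diagnosis=group,
                        tpsa=float(t[j]),
                        fpsa=float(f[j]),
                        cpsa=float(c[j]),
                    )
                )
    return Cohort(records, config.strata)


def _truncated_normal_age(rng, n, config):
    a = (config.age_min - config.age_mean) / config.age_sd
    return stats.truncnorm.ppf(
        rng.uniform(size=n), a, np.inf, loc=config.age_mean, scale=config.age_sd
    )


def stratify(cohort: Cohort, bounds: tuple[float, float]) -> Cohort:
    """Records whose tPSA lies in the half-open interval ``[lo, hi)``."""
    lo, hi = bounds
    if not lo < hi:
        raise CohortError(f"invalid interval [{lo}, {hi})")
    return Cohort(
        (r for r in cohort if lo <= r.tpsa < hi), strata=((lo, hi),)
    )


def scale_counts(
    counts: Mapping[str, Sequence[int]], n_per_group: int
) -> dict[str, tuple[int, ...]]:
    """Scale each group's stratum counts to total ``n_per_group``, keeping
    the stratum proportions (largest-remainder rounding)."""
    out = {}
    for group, ns in counts.items():
        ns = np.asarray(ns, float)
        if ns.sum() == 0:
            out[group] = tuple(0 for _ in ns)
            continue
        exact = ns / ns.sum() * n_per_group
        base = np.floor(exact).astype(int)
        rem = n_per_group - base.sum()
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:rem]] += 1
        out[group] = tuple(int(x) for x in base)
    return out


def calibrate_generator(
    target_medians: Mapping[str, Mapping[str, float]],
    config0: GeneratorConfig,
    n_check: int = 10_000,
    rtol: float = 0.10,
) -> GeneratorConfig:
    """Calibrate per-group tPSA log-location and %fPSA mean to the targets.

    Only the tPSA and %fPSA medians are solved for (deterministically, by
    root finding on the analytic truncated-mixture quantile and the Beta
    median); fPSA and cPSA medians emerge through fPSA = %fPSA x tPSA and
    cPSA = tPSA - fPSA.  The result is then verified on a simulated draw of
    ``n_check`` subjects per group (stratum proportions preserved): all
    targeted markers present in ``target_medians`` must match within
    ``rtol`` relative error, else :class:`CalibrationError` is raised with
    per-marker diagnostics.
    """
    for group, med in target_medians.items():
        if "tpsa" not in med or "pct_fpsa" not in med:
            raise CalibrationError(
                f"group {group}: targets must include tpsa and pct_fpsa"
            )
    ref = next(iter(config0.params.values()), None)
    params = _solve_params(
        target_medians,
        strata=config0.strata,
        counts=config0.counts,
        log_scale=ref.log_scale[0] if ref else DEFAULT_LOG_SCALE,
        conc=ref.pct_fpsa_conc if ref else DEFAULT_PCT_FPSA_CONC,
    )
    config = replace(config0, params=params)

    check_cfg = replace(
        config, counts=scale_counts(config.counts, n_check)
    )
    sim = generate_cohort(check_cfg)
    df = sim.to_dataframe()
    df["pct_fpsa"] = df.fpsa / df.tpsa
    diagnostics: dict[str, dict[str, float]] = {}
    failures = []
    for group, med in target_medians.items():
        sub = df[df.diagnosis == group]
        diag = {}
        for marker, target in med.items():
            got = float(sub[marker].median())
            rel = abs(got - target) / abs(target)
            diag[marker] = {"target": target, "simulated": got, "rel_err": rel}
            if rel > rtol:
                failures.append(f"{group}/{marker}: {got:.4g} vs {target:.4g}")
        diagnostics[group] = diag
    if failures:
        raise CalibrationError(
            "calibration check failed for " + "; ".join(failures), diagnostics
        )
    log.info("calibration verified at n=%d/group within %.0f%%", n_check, rtol * 100)
    return config


def calibrated_config(seed: int = 0, n_check: int = 10_000) -> GeneratorConfig:
    """Default configuration calibrated and verified against the reference
    medians (:data:`REFERENCE_MEDIANS`)."""
    return calibrate_generator(
        REFERENCE_MEDIANS, GeneratorConfig(seed=seed), n_check=n_check
    )


#: Default log-marker covariance for :func:`sample_power_direction`:
#: moderately correlated, well-conditioned (unlike a real PSA panel, the
#: complexed fraction varies freely so all three exponents stay
#: identifiable).
_POWER_SIM_COV = np.array(
    [
        [0.25, 0.10, 0.08],
        [0.10, 0.30, 0.05],
        [0.08, 0.05, 0.25],
    ]
)
_POWER_SIM_MEAN = np.log([6.0, 1.0, 5.0])


def sample_power_direction(
    n_per_group: int,
    direction: Sequence[float] = (1.0, -1.0, 0.5),
    strength: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Marker triplets whose true log-odds is linear along ``direction``.

    Log-markers (log tPSA, log fPSA, log cPSA) are trivariate normal with
    equal covariance in both classes and a between-class mean shift of
    ``Sigma @ (strength * direction)``, so by the Gaussian discriminant
    identity the population log-odds is exactly linear in the log-markers
    with coefficient vector ``strength * direction``.  Used as ground
    truth for exponent-recovery checks; note the draws deliberately relax
    the additivity constraint cPSA ~ tPSA - fPSA (which would leave the
    cPSA exponent unidentifiable) and therefore do not form a
    :class:`Cohort`.

    Returns ``(tpsa, fpsa, cpsa, labels)`` with ``n_per_group`` subjects
    per class, controls first.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(direction, float) * strength
    delta = _POWER_SIM_COV @ beta
    L = np.linalg.cholesky(_POWER_SIM_COV)
    z0 = _POWER_SIM_MEAN + rng.standard_normal((n_per_group, 3)) @ L.T
    z1 = _POWER_SIM_MEAN + delta + rng.standard_normal((n_per_group, 3)) @ L.T
    X = np.exp(np.vstack([z0, z1]))
    y = np.r_[np.zeros(n_per_group, int), np.ones(n_per_group, int)]
    return X[:, 0], X[:, 1], X[:, 2], y


def relabel_by_logit(
    cohort: Cohort,
    scores: np.ndarray,
    intercept: float,
    slope: float,
    seed: int,
) -> Cohort:
    """Reassign diagnoses by a logistic law on a per-subject score.

    P(PCa | score s) = expit(intercept + slope * s).  Useful for building
    cohorts whose true log-odds is exactly linear in a chosen score, e.g.
    to test recovery of the score's functional form.
    """
    scores = np.asarray(scores, float)
    if scores.shape != (len(cohort),):
        raise CohortError("scores must align with cohort records")
    rng = np.random.default_rng(seed)
    p = 1.0 / (1.0 + np.exp(-(intercept + slope * scores)))
    y = rng.uniform(size=len(cohort)) < p
    recs = [
        replace(r, diagnosis=PCA if yi else BPH)
        for r, yi in zip(cohort.records, y)
    ]
    return Cohort(recs, cohort.strata)
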