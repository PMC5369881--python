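"""End-to-end orchestration: descriptive table, per-stratum evaluation,
operating points, and a deterministic report bundle.

The pipeline mirrors the reference study's structure: descriptive
statistics (Table 1 analogue) are built on the pooled 2-20 ng/mL cohort,
while logistic/ROC evaluation (Tables 2-3) and the three-level threshold
analysis (Table 4) run separately within each tPSA stratum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BPH, Cohort, DEFAULT_STRATA, PCA
from .evaluate import bootstrap_auc, bootstrap_hl, hosmer_lemeshow, univariate_logistic
from .scores import compute_pcp, compute_pct_fpsa
from .thresholds import three_level_table

__all__ = [
    "RunConfig",
    "DescriptiveTable",
    "MARKER_ORIENTATIONS",
    "marker_frame",
    "build_table1",
    "evaluate_stratum",
    "run_pipeline",
]

log = logging.getLogger(__name__)

#: Evaluation markers and whether low values indicate cancer.
MARKER_ORIENTATIONS: dict[str, bool] = {
    "tpsa": False,
    "fpsa": False,
    "pct_fpsa": True,
    "cpsa": False,
    "pcp": False,
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; fully determines its outputs."""

    seed: int
    strata: tuple[tuple[float, float], ...] = DEFAULT_STRATA
    markers: tuple[str, ...] = tuple(MARKER_ORIENTATIONS)
    bootstrap_B: int = 1000
    hl_groups: int = 10
    sens_target: float = 0.90
    spec_target: float = 0.90

    def __post_init__(self) -> None:
        ordered = sorted(self.strata)
        for (lo1, hi1), (lo2, _) in zip(ordered[:-1], ordered[1:]):
            if lo2 < hi1:
                raise ValueError("strata overlap")


@dataclass(frozen=True)
class DescriptiveTable:
    """Per-group cohort description: n, mean age, marker medians, p-values.

    Markers are compared with Mann-Whitney rank-sum tests (skewed PSA
    scales), age with a two-sample t test.
    """

    n: dict[str, int]
    age_mean: dict[str, float]
    medians: dict[str, dict[str, float]]  # marker -> group -> median
    p_values: dict[str, float]  # marker or "age" -> p

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variable": "n",
                PCA: self.n[PCA],
                BPH: self.n[BPH],
                "p_value": np.nan,
            },
            {
                "variable": "age_mean",
                PCA: self.age_mean[PCA],
                BPH: self.age_mean[BPH],
                "p_value": self.p_values["age"],
            },
        ]
        for marker, med in self.medians.items():
            rows.append(
                {
                    "variable": f"{marker}_median",
                    PCA: med[PCA],
                    BPH: med[BPH],
                    "p_value": self.p_values[marker],
                }
            )
        return pd.DataFrame(rows, columns=["variable", PCA, BPH, "p_value"])


def marker_frame(cohort: Cohort) -> pd.DataFrame:
    """Cohort dataframe augmented with %fPSA and PCP columns."""
    df = cohort.to_dataframe()
    df["pct_fpsa"] = compute_pct_fpsa(df.fpsa.to_numpy(), df.tpsa.to_numpy())
    df["pcp"] = compute_pcp(
        df.tpsa.to_numpy(), df.fpsa.to_numpy(), df.cpsa.to_numpy()
    )
    return df


def build_table1(cohort: Cohort) -> DescriptiveTable:
    """Descriptive table on the pooled cohort: medians + rank-sum p-values."""
    df = marker_frame(cohort)
    groups = {g: df[df.diagnosis == g] for g in (PCA, BPH)}
    if any(len(sub) == 0 for sub in groups.values()):
        raise ValueError("both diagnosis groups must be present")
    medians: dict[str, dict[str, float]] = {}
    p_values: dict[str, float] = {}
    for marker in ("tpsa", "fpsa", "cpsa", "pct_fpsa", "pcp"):
        medians[marker] = {
            g: float(sub[marker].median()) for g, sub in groups.items()
        }
        p_values[marker] = float(
            stats.mannwhitneyu(
                groups[PCA][marker], groups[BPH][marker], alternative="two-sided"
            ).pvalue
        )
    p_values["age"] = float(
        stats.ttest_ind(groups[PCA].age, groups[BPH].age).pvalue
    )
    return DescriptiveTable(
        n={g: int(len(sub)) for g, sub in groups.items()},
        age_mean={g: float(sub.age.mean()) for g, sub in groups.items()},
        medians=medians,
        p_values=p_values,
    )


def evaluate_stratum(
    df: pd.DataFrame,
    config: RunConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-marker logistic/ROC/bootstrap evaluation within one stratum.

    Returns (evaluation table, AUC replicate dump, HL p-value dump); one
    evaluation row per marker with slope, OR and CI, Wald p, AUC with
    percentile CI, and the in-sample Hosmer-Lemeshow test.
    """
    labels = (df.diagnosis == PCA).to_numpy().astype(int)
    rows = []
    auc_reps: dict[str, np.ndarray] = {}
    hl_reps: dict[str, np.ndarray] = {}
    child = np.random.SeedSequence(seed).spawn(len(config.markers))
    for marker, ss in zip(config.markers, child):
        lower = MARKER_ORIENTATIONS[marker]
        x = df[marker].to_numpy()
        fit = univariate_logistic(x, labels)
        hl = hosmer_lemeshow(fit.fitted, labels, g=config.hl_groups)
        s_auc, s_hl = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
        if config.bootstrap_B > 0:
            est = bootstrap_auc(
                x, labels, lower_is_positive=lower, B=config.bootstrap_B, seed=s_auc
            )
            auc_point, ci_lo, ci_hi = est.point, est.ci_low, est.ci_high
            auc_reps[marker] = est.replicates
            hl_reps[marker] = bootstrap_hl(
                x, labels, B=config.bootstrap_B, seed=s_hl, g=config.hl_groups
            )
        else:
            from .evaluate import auc as auc_fn

            auc_point = auc_fn(x, labels, lower_is_positive=lower)
            ci_lo = ci_hi = np.nan
        rows.append(
            {
                "marker": marker,
                "orientation": "lower" if lower else "higher",
                "slope": fit.slope,
                "odds_ratio": fit.odds_ratio,
                "or_ci_low": fit.or_ci_low,
                "or_ci_high": fit.or_ci_high,
                "p_value": fit.p_value,
                "p_display": fit.p_display(),
                "separation": fit.separation,
                "auc": round(auc_point, 3),
                "auc_ci_low": round(float(ci_lo), 3) if np.isfinite(ci_lo) else np.nan,
                "auc_ci_high": round(float(ci_hi), 3) if np.isfinite(ci_hi) else np.nan,
                "hl_chi2": hl.statistic,
                "hl_df": hl.df,
                "hl_p": hl.p_value,
            }
        )
    eval_table = pd.DataFrame(rows)
    auc_dump = pd.DataFrame(auc_reps)
    hl_dump = pd.DataFrame(
        {k: pd.Series(v) for k, v in hl_reps.items()}
    )
    return eval_table, auc_dump, hl_dump


def run_pipeline(
    cohort: Cohort,
    config: RunConfig,
    out_dir: str | Path | None = None,
) -> dict:
    """Full analysis bundle; deterministic for a fixed config.

    Per stratum: evaluation table (logistic + AUC + HL), bootstrap
    replicate dumps, and the three-level operating-point table; plus the
    pooled descriptive table.  When ``out_dir`` is given, CSVs and a
    summary JSON are written there.
    """
    df_all = marker_frame(cohort)
    bundle: dict = {
        "config": {
            "seed": config.seed,
            "strata": [list(b) for b in config.strata],
            "markers": list(config.markers),
            "bootstrap_B": config.bootstrap_B,
            "hl_groups": config.hl_groups,
            "sens_target": config.sens_target,
            "spec_target": config.spec_target,
        },
        "n_total": len(cohort),
        "table1": build_table1(cohort).to_frame(),
        "strata": {},
    }
    stratum_seeds = np.random.SeedSequence(config.seed).spawn(len(config.strata))
    for (lo, hi), ss in zip(config.strata, stratum_seeds):
        key = f"{lo:g}-{hi:g}"
        sub = df_all[(df_all.tpsa >= lo) & (df_all.tpsa < hi)]
        if sub.diagnosis.nunique() < 2:
            raise RuntimeError(
                f"stratum {key}: need both diagnosis classes (stage: evaluate)"
            )
        seed = int(ss.generate_state(1)[0] % (2**31))
        eval_table, auc_dump, hl_dump = evaluate_stratum(sub, config, seed)
        labels = (sub.diagnosis == PCA).to_numpy().astype(int)
        markers = {
            m: (sub[m].to_numpy(), MARKER_ORIENTATIONS[m]) for m in config.markers
        }
        table4 = three_level_table(
            markers, labels, config.sens_target, config.spec_target
        )
        bundle["strata"][key] = {
            "n": int(len(sub)),
            "n_pos": int(labels.sum()),
            "evaluation": eval_table,
            "auc_replicates": auc_dump,
            "hl_replicates": hl_dump,
            "operating_points": table4,
        }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["table1"].to_csv(out_dir / "table1.csv", index=False, lineterminator="\n")
    summary = {"config": bundle["config"], "n_total": bundle["n_total"], "strata": {}}
    summary["table1"] = json.loads(bundle["table1"].to_json(orient="records"))
    for key, st in bundle["strata"].items():
        tag = key.replace("-", "_")
        st["evaluation"].to_csv(
            out_dir / f"evaluation_{tag}.csv", index=False, lineterminator="\n"
        )
        st["operating_points"].to_csv(
            out_dir / f"operating_points_{tag}.csv", index=False, lineterminator="\n"
        )
        if len(st["auc_replicates"]):
            st["auc_replicates"].to_csv(
                out_dir / f"auc_replicates_{tag}.csv", index=False, lineterminator="\n"
            )
            st["hl_replicates"].to_csv(
                out_dir / f"hl_replicates_{tag}.csv", index=False, lineterminator="\n"
            )
        summary["strata"][key] = {
            "n": st["n"],
            "n_pos": st["n_pos"],
            "evaluation": json.loads(st["evaluation"].to_json(orient="records")),
            "operating_points": json.loads(
                st["operating_points"].to_json(orient="records")
            ),
        }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    log.info("report bundle written to %s", out_dir)
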