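"""End-to-end study orchestration.

Runs every applicable correction formula over a cohort, compares each
corrected series (and the raw GAT series) against DCT with paired
statistics and Bland–Altman analysis, checks normality of the difference
series, and assembles everything into a serializable report with
machine-readable CSV/JSON exports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (
    BlandAltmanResult,
    NormalityResult,
    PairedComparison,
    bland_altman,
    ks_normality,
    paired_compare,
)
from .cohort import Cohort
from .corrections import FORMULA_IDS, correct_cohort, get_formula
from .errors import DependencyError, InsufficientDataError

logger = logging.getLogger(__name__)

UNCORRECTED = "uncorrected"


@dataclass(frozen=True)
class StudyConfig:
    """Knobs for one pipeline run."""

    formulas: tuple[str, ...] = FORMULA_IDS
    loa_k: float = 2.0
    alpha: float = 0.05
    ks_n_mc: int = 2000
    ks_seed: int = 0
    formula_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "StudyConfig":
        agree = cfg.get("agreement", {})
        return cls(
            formulas=tuple(cfg.get("formulas", FORMULA_IDS)),
            loa_k=float(agree.get("k", 2.0)),
            alpha=float(agree.get("alpha", 0.05)),
            ks_n_mc=int(agree.get("ks_n_mc", 2000)),
            ks_seed=int(agree.get("ks_seed", 0)),
            formula_overrides=dict(cfg.get("corrections", {})),
        )


@dataclass
class FormulaRow:
    """All agreement results for one corrected series vs DCT."""

    formula_id: str
    comparison: PairedComparison
    bland_altman: BlandAltmanResult
    normality: NormalityResult | None


@dataclass
class StudyReport:
    """Full study output: per-formula agreement rows plus provenance."""

    cohort_label: str
    n: int
    cohort_summary: dict
    rows: dict[str, FormulaRow]
    skipped: dict[str, str]
    ranking: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        def row_dict(row: FormulaRow) -> dict:
            c, b = row.comparison, row.bland_altman
            out = {
                "n": c.n,
                "mean_diff": c.mean_diff,
                "sd_diff": c.sd_diff,
                "mean_absdiff": c.mean_absdiff,
                "sd_absdiff": c.sd_absdiff,
                "t_stat": c.t_stat,
                "p_value": c.p_value,
                "loa_low": b.loa_low,
                "loa_high": b.loa_high,
                "loa_k": b.k,
                "fixed_bias": b.fixed_bias,
                "prop_slope": b.prop_slope,
                "prop_p": b.prop_p,
                "prop_bias": b.prop_bias,
            }
            if row.normality is not None:
                out["ks_statistic"] = row.normality.statistic
                out["ks_p"] = row.normality.p_value
            return out

        return {
            "cohort": {"label": self.cohort_label, "n": self.n,
                       **self.cohort_summary},
            "rows": {k: row_dict(v) for k, v in self.rows.items()},
            "skipped": self.skipped,
            "ranking": self.ranking,
            "provenance": self.provenance,
        }

    # -- tabular exports --------------------------------------------------

    def signed_table(self) -> pd.DataFrame:
        """Per-formula signed DCT - corrected-GAT differences (2 decimals)."""
        rows = [
            {
                "formula": k,
                "mean_diff": round(r.comparison.mean_diff, 2),
                "sd_diff": round(r.comparison.sd_diff, 2),
                "p_value": float(f"{r.comparison.p_value:.3g}"),
            }
            for k, r in self.rows.items()
        ]
        return pd.DataFrame(rows)

    def absolute_table(self) -> pd.DataFrame:
        """Per-formula absolute differences, ranked best-first."""
        rows = [
            {
                "formula": k,
                "mean_absdiff": round(self.rows[k].comparison.mean_absdiff, 2),
                "sd_absdiff": round(self.rows[k].comparison.sd_absdiff, 2),
            }
            for k in self.ranking
        ]
        return pd.DataFrame(rows)

    def bland_altman_coordinates(self, formula_id: str) -> pd.DataFrame:
        b = self.rows[formula_id].bland_altman
        return pd.DataFrame({"mean": b.means, "difference": b.diffs})

    def write(self, outdir) -> list[Path]:
        """Write report.json, table CSVs and per-formula BA coordinates."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        p = outdir / "report.json"
        p.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        written.append(p)
        p = outdir / "table2.csv"
        self.signed_table().to_csv(p, index=False)
        written.append(p)
        p = outdir / "table3.csv"
        self.absolute_table().to_csv(p, index=False)
        written.append(p)
        for k in self.rows:
            p = outdir / f"blandaltman_{k}.csv"
            self.bland_altman_coordinates(k).to_csv(p, index=False)
            written.append(p)
        return written


def _summarize(cohort: Cohort) -> dict:
    diff = cohort.iop_dct - cohort.iop_gat
    return {
        "age_mean": float(cohort.age.mean()),
        "age_sd": float(cohort.age.std(ddof=1)) if len(cohort) > 1 else 0.0,
        "cct_mean": float(cohort.cct_um.mean()),
        "dct_mean": float(cohort.iop_dct.mean()),
        "dct_sd": float(cohort.iop_dct.std(ddof=1)) if len(cohort) > 1 else 0.0,
        "gat_mean": float(cohort.iop_gat.mean()),
        "gat_sd": float(cohort.iop_gat.std(ddof=1)) if len(cohort) > 1 else 0.0,
        "diff_mean": float(diff.mean()),
        "diff_sd": float(diff.std(ddof=1)) if len(cohort) > 1 else 0.0,
    }


def run_study(cohort: Cohort, config: StudyConfig | None = None,
              run_normality: bool = True) -> StudyReport:
    """Run the full agreement analysis over a cohort.

    For the raw GAT series and every enabled formula whose input
    requirements the cohort satisfies: corrected series, signed and
    absolute paired comparison vs DCT, Bland–Altman, and (optionally) a
    Monte-Carlo KS normality check of the difference series.  Formulas with
    unmet requirements are skipped with a logged warning and recorded in
    the report.  Deterministic given cohort and config.
    """
    if len(cohort) == 0:
        raise InsufficientDataError("cannot analyse an empty cohort")
    config = config or StudyConfig()
    dct = cohort.iop_dct
    series: dict[str, np.ndarray] = {UNCORRECTED: cohort.iop_gat}
    skipped: dict[str, str] = {}
    for fid in config.formulas:
        get_formula(fid)  # raise early on unknown ids
        try:
            series[fid] = correct_cohort(
                fid, cohort, overrides=config.formula_overrides.get(fid)
            )
        except DependencyError as exc:
            logger.warning("skipping %s: %s", fid, exc)
            skipped[fid] = str(exc)

    rows: dict[str, FormulaRow] = {}
    for label, corrected in series.items():
        comp = paired_compare(dct, corrected, label=f"DCT-{label}")
        ba = bland_altman(dct, corrected, k=config.loa_k, alpha=config.alpha,
                          label=f"DCT-{label}")
        norm = None
        if run_normality and len(cohort) >= 5:
            norm = ks_normality(
                dct - corrected, n_mc=config.ks_n_mc, seed=config.ks_seed,
                label=f"DCT-{label}",
            )
        rows[label] = FormulaRow(label, comp, ba, norm)

    ranking = sorted(rows, key=lambda k: (rows[k].comparison.mean_absdiff, k))
    provenance = {
        "software": f"iopcorr {__version__}",
        "config": {
            "formulas": list(config.formulas),
            "loa_k": config.loa_k,
            "alpha": config.alpha,
            "ks_n_mc": config.ks_n_mc,
            "ks_seed": config.ks_seed,
            "formula_overrides": config.formula_overrides,
        },
    }
    return StudyReport(
        cohort_label=cohort.label,
        n=len(cohort),
        cohort_summary=_summarize(cohort),
        rows=rows,
        skipped=skipped,
        ranking=ranking,
        provenance=provenance,
    )


__all__ = ["StudyConfig", "StudyReport", "FormulaRow", "run_study", "UNCORRECTED"]
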