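"""End-to-end run: ingest -> annotate -> tabulate -> fit.

One call produces the study's full output surface as plain CSV/JSON files:
frequency tables (season, month, weekday, LR3, LR5, moon day, day of
year), the five contrast models, Tukey letters for weekday and LR5, both
cyclic smoothers (with bands; moon day 30 dropped), and — when hunting-bag
statistics are supplied — the report-rate table.  A manifest records the
configuration, an input checksum, per-stage row counts and every output
file, so re-running on the same input is byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import annotate_records, frequency_table, report_rate
from .config import StudyConfig
from .linear import CategoryContrastModel
from .records import read_records
from .smoothing import CyclicSmoother

__all__ = ["RunManifest", "run_pipeline", "MODEL_SPECS"]

#: The five contrast models: name -> (table, coding, reference).
MODEL_SPECS = {
    "model1_season": ("season", "successive", None),
    "model2_month": ("month", "successive", None),
    "model3_weekday": ("weekday", "successive", None),
    "model4_lr3": ("lr3", "treatment", "DL"),
    "model5_lr5": ("lr5", "treatment", "NbD"),
}

_TABLES = ("season", "month", "weekday", "lr3", "lr5", "moon_day", "day_of_year")


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config: dict
    input_path: str
    input_sha256: str
    version: str
    stage_counts: dict
    outputs: list

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(
    records_path: str | Path,
    config: StudyConfig,
    out_dir: str | Path,
    hunting_counts: dict[int, int] | None = None,
    smoother_k: int = 10,
) -> RunManifest:
    """Run every analysis stage on a record CSV and write all outputs.

    Any stage failure raises with the stage named; completed stages up to
    that point are reflected in the partially written output directory.
    """
    records_path = Path(records_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage_counts: dict = {}
    stage = "ingest"
    try:
        records, report = read_records(records_path, config)
        stage_counts["ingest"] = report.as_dict()
        if not records:
            raise ValueError("no records retained at ingest")

        stage = "annotate"
        annotated = annotate_records(records, config)
        annotated_path = out_dir / "annotated.csv"
        annotated.to_csv(annotated_path, index=False)
        outputs.append(annotated_path.name)
        stage_counts["annotate"] = {"rows": len(annotated)}

        stage = "tabulate"
        tables = {}
        for by in _TABLES:
            table = frequency_table(annotated, by)
            tables[by] = table
            path = out_dir / f"freq_{by}.csv"
            table.long_form().to_csv(path, index=False)
            outputs.append(path.name)
        stage_counts["tabulate"] = {
            by: {"total": t.total, "excluded": t.excluded} for by, t in tables.items()
        }

        stage = "fit_linear"
        for name, (by, coding, ref) in MODEL_SPECS.items():
            result = CategoryContrastModel(tables[by], coding=coding, reference=ref).fit()
            coef = result.summary()
            w, p = result.normality()
            coef_path = out_dir / f"{name}_coefficients.csv"
            coef.to_csv(coef_path, index_label="term")
            outputs.append(coef_path.name)
            stage_counts.setdefault("fit_linear", {})[name] = {
                "r_squared": result.rsquared,
                "shapiro_w": w,
                "shapiro_p": p,
            }
        for by in ("weekday", "lr5"):
            tukey = CategoryContrastModel(tables[by]).fit().tukey_hsd()
            letters = pd.DataFrame(
                {"category": list(tukey.letters), "letters": list(tukey.letters.values())}
            )
            path = out_dir / f"tukey_{by}.csv"
            letters.merge(
                tables[by].summary().reset_index(names="category"), on="category"
            ).to_csv(path, index=False)
            outputs.append(path.name)

        stage = "fit_smoothers"
        smoother_summaries = {}
        for by, period in (("day_of_year", 365.0), ("moon_day", 29.0)):
            fit = CyclicSmoother.from_counts(annotated, by, period=period, k=smoother_k).fit()
            grid = np.arange(1.0, period + 1.0)
            curve_path = out_dir / f"smooth_{by}.csv"
            fit.bands(grid).to_csv(curve_path, index=False)
            outputs.append(curve_path.name)
            smoother_summaries[by] = fit.summary() | {"peak": fit.peak_location()}
        summary_path = out_dir / "smoothers.json"
        summary_path.write_text(json.dumps(smoother_summaries, indent=2))
        outputs.append(summary_path.name)
        stage_counts["fit_smoothers"] = smoother_summaries

        if hunting_counts is not None:
            stage = "report_rate"
            police = annotated.groupby("year").size().to_dict()
            rates = report_rate(police, hunting_counts)
            path = out_dir / "report_rates.csv"
            rates.to_csv(path, index=False)
            outputs.append(path.name)
            stage_counts["report_rate"] = {"years": len(rates) - 1}
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed ({exc}); completed: "
            f"{sorted(stage_counts)}"
        ) from exc

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        input_path=str(records_path),
        input_sha256=_sha256(records_path),
        version=__version__,
        stage_counts=stage_counts,
        outputs=outputs,
    )
    manifest.save(out_dir / "manifest.json")
    return manifest
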